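"""Synthetic high-content foci screens with known ground truth.

Emulates a 384-well, multi-plate RNAi screen read out as per-cell foci
counts after irradiation: a G1/S/G2 DNA-content mixture (G2 stain at twice
the G1 level), a mean-foci curve that is flat and near zero through G1 and
rises with DNA content so it crosses the gating level at a known
intensity, negative-binomial per-cell counts, additive row/column/plate
artifacts on the expected-foci scale, scrambled negative and
focus-protein-knockdown positive control wells, empty outer columns, and a
designated fraction of true hit genes whose foci formation is suppressed
multiplicatively.  Two replicate runs share gene effects but draw
independent noise and artifacts.  Everything is driven by one integer
seed; identical seeds give identical output.

A score-level generator (:func:`simulate_score_pairs`) produces duplicate
gene-score maps directly — planted correlated hits atop uncorrelated
nulls — for studying rank merging and candidate sizing at genome scale
without simulating cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .io import (
    ROLE_EMPTY,
    ROLE_NEGATIVE,
    ROLE_POSITIVE,
    ROLE_SAMPLE,
    GeneSet,
    PlateLayout,
    rc_to_well,
    well_to_rc,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ScreenSimulation",
    "NetworkModule",
    "simulate_screen",
    "simulate_network",
    "simulate_gene_sets",
    "simulate_score_pairs",
]


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic screen.

    DNA intensities are in arbitrary stain units with the G1 mode at
    ``g1_intensity`` and the G2 mode at twice that; the mean-foci curve is
    ``g1_foci_rate`` below ``foci_rise_start`` and rises linearly with
    slope ``foci_slope`` (foci per intensity unit) above it, so it crosses
    a level L at ``foci_rise_start + (L - g1_foci_rate) / foci_slope``.
    Artifacts are additive shifts in expected foci per cell: one row and
    one column vector per replicate run plus a per-plate offset — the
    additive structure the three-way polish assumes.
    """

    seed: int
    n_plates: int = 20
    n_rows: int = 16
    n_cols: int = 24
    empty_outer_cols: bool = True
    cells_per_well: int = 200            # Poisson mean of cells seeded per well
    # DNA-content mixture
    phase_weights: tuple = (0.55, 0.30, 0.15)   # G1, S, G2
    g1_intensity: float = 100.0
    intensity_cv: float = 0.12           # lognormal sigma of G1/G2 components
    # mean-foci curve
    g1_foci_rate: float = 0.2
    foci_rise_start: float = 110.0
    foci_slope: float = 0.05
    foci_dispersion: float = 5.0         # negative-binomial size; inf -> Poisson
    count_model: str = "negbinom"        # or "poisson"
    # perturbation effects (multiplicative on the foci curve)
    hit_fraction: float = 0.02
    hit_effect: float = 0.3
    positive_control_effect: float = 0.1
    n_negative_controls: int = 8
    n_positive_controls: int = 8
    # artifacts (additive, expected-foci units)
    row_artifact_sd: float = 0.3
    col_artifact_sd: float = 0.3
    plate_artifact_sd: float = 0.3
    artifact_mode: str = "additive"      # "multiplicative" probes misspecification
    replicate_noise_sd: float = 0.1      # extra per-well shift, independent per run
    n_replicates: int = 2

    def __post_init__(self):
        if not np.isclose(sum(self.phase_weights), 1.0):
            raise ConfigError("phase weights must sum to 1")
        if not (0.0 <= self.hit_fraction <= 1.0):
            raise ConfigError("hit_fraction must lie in [0, 1]")
        if self.hit_effect < 0 or self.positive_control_effect < 0:
            raise ConfigError("effects must be non-negative")
        if self.foci_slope < 0 or self.g1_foci_rate < 0:
            raise ConfigError("foci rates must be non-negative")
        if self.count_model not in ("negbinom", "poisson"):
            raise ConfigError(f"unknown count model {self.count_model!r}")
        if self.artifact_mode not in ("additive", "multiplicative"):
            raise ConfigError(f"unknown artifact mode {self.artifact_mode!r}")
        if self.seed is None:
            raise ConfigError("a seed is mandatory")

    def true_cutoff(self, foci_level: float = 2.0) -> float:
        """Intensity where the configured mean-foci curve crosses the level."""
        if self.foci_slope == 0:
            raise ConfigError("flat foci curve never crosses the gating level")
        return self.foci_rise_start + (foci_level - self.g1_foci_rate) / self.foci_slope

    def compact(self, **overrides) -> "SimulationConfig":
        """A small screen (6 plates, 80 cells/well) for quick runs."""
        return replace(self, n_plates=6, cells_per_well=80, **overrides)


@dataclass
class GroundTruth:
    """What the generator actually did, for validating the pipeline."""

    gene_effects: pd.Series               # gene -> multiplicative effect
    hit_genes: set
    true_cutoff: float
    artifacts: dict                       # rep -> dict(row=..., col=..., plate=...)
    well_stats: dict                      # rep -> DataFrame of gated generative means


@dataclass
class ScreenSimulation:
    cells: dict                           # rep name -> per-cell DataFrame
    layouts: dict                         # plate_id -> PlateLayout
    truth: GroundTruth
    config: SimulationConfig

    def expected_crossing(self, rep: str = "rep1",
                          foci_level: float = 2.0) -> float:
        """Intensity where this run's realized mean-foci curve crosses the level.

        The pooled curve observed in one run is the configured per-cell
        curve diluted by the average perturbation effect across wells and
        shifted by the run's mean row/column/plate artifact; this returns
        the crossing of that realized curve (the quantity the gating
        estimator actually estimates), as opposed to
        :meth:`SimulationConfig.true_cutoff`, the configured ideal.
        """
        cfg = self.config
        art = self.truth.artifacts[rep]
        effs, arts = [], []
        for p, plate_id in enumerate(sorted(self.layouts)):
            layout = self.layouts[plate_id]
            for well in layout.nonempty_wells:
                role = layout.role(well)
                if role == ROLE_NEGATIVE:
                    effs.append(1.0)
                elif role == ROLE_POSITIVE:
                    effs.append(cfg.positive_control_effect)
                else:
                    effs.append(float(self.truth.gene_effects[layout.genes[well]]))
                r, c = well_to_rc(well, cfg.n_rows, cfg.n_cols)
                arts.append(art["row"][r] + art["col"][c] + art["plate"][p])
        mean_eff = float(np.mean(effs))
        mean_art = float(np.mean(arts))
        target_rate = (foci_level - mean_art) / mean_eff
        if cfg.foci_slope == 0 or target_rate < cfg.g1_foci_rate:
            raise ConfigError("realized mean-foci curve never crosses the level")
        return cfg.foci_rise_start + (target_rate - cfg.g1_foci_rate) / cfg.foci_slope


def _build_layouts(config: SimulationConfig, rng: np.random.Generator):
    """Assign genes and control roles to wells; identical for both runs."""
    inner_cols = list(range(config.n_cols))
    if config.empty_outer_cols:
        inner_cols = inner_cols[1:-1]
    n_ctrl = config.n_negative_controls + config.n_positive_controls
    inner_wells = [(r, c) for c in inner_cols for r in range(config.n_rows)]
    if n_ctrl > len(inner_wells):
        raise ConfigError("more control wells than inner wells")

    layouts = {}
    gene_wells = []  # (plate, well, gene)
    counter = 0
    for p in range(config.n_plates):
        plate_id = f"P{p + 1:02d}"
        # controls interleave down the first and last inner columns
        ctrl = {}
        for i in range(config.n_negative_controls):
            ctrl[(i * 2 % config.n_rows, inner_cols[0])] = ROLE_NEGATIVE
        for i in range(config.n_positive_controls):
            ctrl[((i * 2 + 1) % config.n_rows, inner_cols[-1])] = ROLE_POSITIVE
        roles, genes = {}, {}
        for r in range(config.n_rows):
            for c in range(config.n_cols):
                well = rc_to_well(r, c)
                if c not in inner_cols:
                    roles[well] = ROLE_EMPTY
                elif (r, c) in ctrl:
                    roles[well] = ctrl[(r, c)]
                else:
                    counter += 1
                    gene = f"GENE{counter:05d}"
                    roles[well] = ROLE_SAMPLE
                    genes[well] = gene
                    gene_wells.append((plate_id, well, gene))
        layouts[plate_id] = PlateLayout(
            plate_id, config.n_rows, config.n_cols, roles, genes
        )
    return layouts, gene_wells


def _foci_mean(config: SimulationConfig, intensity: np.ndarray) -> np.ndarray:
    rise = np.clip(intensity - config.foci_rise_start, 0.0, None)
    return config.g1_foci_rate + config.foci_slope * rise


def _draw_intensities(config: SimulationConfig, n: int, rng) -> np.ndarray:
    w = np.asarray(config.phase_weights)
    phase = rng.choice(3, size=n, p=w / w.sum())
    x = np.empty(n)
    sigma = config.intensity_cv
    g1 = phase == 0
    g2 = phase == 2
    s = phase == 1
    x[g1] = config.g1_intensity * np.exp(rng.normal(0.0, sigma, g1.sum()))
    x[g2] = 2 * config.g1_intensity * np.exp(rng.normal(0.0, sigma, g2.sum()))
    x[s] = rng.uniform(
        1.05 * config.g1_intensity, 1.95 * config.g1_intensity, s.sum()
    )
    return x


def _draw_counts(config: SimulationConfig, mean: np.ndarray, rng) -> np.ndarray:
    mean = np.clip(mean, 1e-3, None)
    if config.count_model == "poisson" or not np.isfinite(config.foci_dispersion):
        return rng.poisson(mean)
    k = config.foci_dispersion
    # NB as Poisson-gamma mixture keeps the draw fully vectorized
    lam = rng.gamma(shape=k, scale=mean / k)
    return rng.poisson(lam)


def simulate_screen(config: SimulationConfig) -> ScreenSimulation:
    """Generate per-cell tables for duplicate runs plus ground truth."""
    root = np.random.SeedSequence(config.seed)
    layout_seq, effects_seq, *rep_seqs = root.spawn(2 + config.n_replicates)
    rng_layout = np.random.default_rng(layout_seq)
    rng_eff = np.random.default_rng(effects_seq)

    layouts, gene_wells = _build_layouts(config, rng_layout)
    genes = [g for _, _, g in gene_wells]
    n_genes = len(genes)
    n_hits = int(round(config.hit_fraction * n_genes))
    hit_idx = rng_eff.choice(n_genes, size=n_hits, replace=False)
    effects = np.ones(n_genes)
    effects[hit_idx] = config.hit_effect
    gene_effects = pd.Series(effects, index=genes, name="effect")
    hit_genes = set(gene_effects.index[hit_idx])
    cutoff = config.true_cutoff()

    cells, artifacts, well_stats = {}, {}, {}
    for rep_i, seq in enumerate(rep_seqs, start=1):
        rng = np.random.default_rng(seq)
        rep = f"rep{rep_i}"
        row_art = rng.normal(0.0, config.row_artifact_sd, config.n_rows)
        col_art = rng.normal(0.0, config.col_artifact_sd, config.n_cols)
        plate_art = rng.normal(0.0, config.plate_artifact_sd, config.n_plates)
        artifacts[rep] = {"row": row_art, "col": col_art, "plate": plate_art}

        frames, stat_rows = [], []
        plate_ids = sorted(layouts)
        for p, plate_id in enumerate(plate_ids):
            layout = layouts[plate_id]
            wells = layout.nonempty_wells
            n_cells = rng.poisson(config.cells_per_well, len(wells))
            total = int(n_cells.sum())
            x = _draw_intensities(config, total, rng)
            base = _foci_mean(config, x)

            well_col = np.repeat(wells, n_cells)
            eff = np.empty(total)
            art = np.empty(total)
            pos = 0
            for well, n in zip(wells, n_cells):
                role = layout.role(well)
                if role == ROLE_NEGATIVE:
                    e = 1.0
                elif role == ROLE_POSITIVE:
                    e = config.positive_control_effect
                else:
                    e = gene_effects[layout.genes[well]]
                r, c = well_to_rc(well, config.n_rows, config.n_cols)
                a = row_art[r] + col_art[c] + plate_art[p]
                a += rng.normal(0.0, config.replicate_noise_sd)
                eff[pos:pos + n] = e
                art[pos:pos + n] = a
                pos += n

            if config.artifact_mode == "additive":
                mean = base * eff + art
            else:
                mean = base * eff * np.exp(art)
            mean = np.clip(mean, 0.01, None)
            counts = _draw_counts(config, mean, rng)

            frames.append(
                pd.DataFrame(
                    {
                        "plate": plate_id,
                        "well": well_col,
                        "cell": np.concatenate(
                            [np.arange(1, n + 1) for n in n_cells]
                        ),
                        "dna_intensity": x,
                        "foci_count": counts,
                    }
                )
            )
            # gated generative means: expectation of the readout given the
            # realized intensities of cells above the true cutoff
            gated = x >= cutoff
            df_idx = pd.DataFrame(
                {"well": well_col, "mean": mean, "gated": gated}
            )
            grp = df_idx[df_idx["gated"]].groupby("well")["mean"]
            gen_mean = grp.mean()
            gen_var = grp.var(ddof=0)
            gen_n = grp.size()
            for well in wells:
                stat_rows.append(
                    (
                        plate_id,
                        well,
                        layout.role(well),
                        float(gen_mean.get(well, np.nan)),
                        float(gen_var.get(well, np.nan)),
                        int(gen_n.get(well, 0)),
                    )
                )
        cells[rep] = pd.concat(frames, ignore_index=True)
        well_stats[rep] = pd.DataFrame(
            stat_rows,
            columns=["plate", "well", "role", "gen_mean_gated",
                     "gen_var_gated", "n_gated"],
        )

    truth = GroundTruth(gene_effects, hit_genes, cutoff, artifacts, well_stats)
    return ScreenSimulation(cells, layouts, truth, config)


# ---------------------------------------------------------------------------
# score-level duplicate screens


def simulate_score_pairs(
    n_genes: int = 10_000,
    hit_fraction: float = 0.02,
    hit_shift: float = -3.0,
    hit_spread: float = 1.0,
    hit_noise: float = 0.2,
    seed: int = 0,
) -> tuple[pd.Series, pd.Series, set]:
    """Duplicate gene-score maps: correlated planted hits atop iid nulls.

    Null genes draw independent standard-normal scores in each replicate.
    Hit genes carry a gene-specific latent effect drawn uniformly on
    ``hit_shift +/- hit_spread`` that both replicates observe with small
    residual noise (``hit_noise`` SD): a real suppressor phenotype is
    highly reproducible between duplicate runs, while null-gene scores are
    pure plate noise.  Returns (scores_rep1, scores_rep2, hits).
    """
    rng = np.random.default_rng(seed)
    genes = [f"GENE{i + 1:05d}" for i in range(n_genes)]
    n_hits = int(round(hit_fraction * n_genes))
    hit_idx = rng.choice(n_genes, size=n_hits, replace=False)
    latent = np.zeros(n_genes)
    latent[hit_idx] = rng.uniform(
        hit_shift - hit_spread, hit_shift + hit_spread, n_hits
    )
    noise_sd = np.ones(n_genes)
    noise_sd[hit_idx] = hit_noise
    s1 = latent + rng.normal(0.0, 1.0, n_genes) * noise_sd
    s2 = latent + rng.normal(0.0, 1.0, n_genes) * noise_sd
    hits = {genes[i] for i in hit_idx}
    return (
        pd.Series(s1, index=genes),
        pd.Series(s2, index=genes),
        hits,
    )


# ---------------------------------------------------------------------------
# networks and gene sets


@dataclass
class NetworkModule:
    genes: list
    p_edge: float = 0.9
    conf_low: float = 0.7
    conf_high: float = 1.0


def simulate_network(
    genes, module_spec, background_density: float = 0.01, seed: int = 0
) -> pd.DataFrame:
    """Planted-module random network as a (gene_a, gene_b, confidence) table.

    Modules are dense high-confidence cliques-with-dropout; background
    edges connect arbitrary pairs at ``background_density`` with uniform
    confidence.  Overlapping modules are rejected.
    """
    genes = [str(g) for g in genes]
    seen = set()
    for mod in module_spec:
        mg = set(map(str, mod.genes))
        if mg & seen:
            raise ConfigError("network modules must not overlap")
        if not mg <= set(genes):
            raise ConfigError("module genes must come from the gene list")
        seen |= mg
    rng = np.random.default_rng(seed)
    edges = {}
    for mod in module_spec:
        mg = sorted(map(str, mod.genes))
        for i, a in enumerate(mg):
            for b in mg[i + 1:]:
                if rng.random() < mod.p_edge:
                    edges[(a, b)] = rng.uniform(mod.conf_low, mod.conf_high)
    if background_density > 0:
        arr = sorted(genes)
        for i, a in enumerate(arr):
            js = np.flatnonzero(rng.random(len(arr) - i - 1) < background_density)
            for j in js:
                b = arr[i + 1 + j]
                key = (a, b)
                if key not in edges:
                    edges[key] = rng.uniform(0.0, 1.0)
    rows = [(a, b, c) for (a, b), c in sorted(edges.items())]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "confidence"])


def simulate_gene_sets(
    genes,
    n_sets: int = 50,
    set_size_range: tuple = (10, 60),
    planted_candidate_bias: float = 1.0,
    candidates=None,
    seed: int = 0,
) -> dict:
    """Random gene sets, optionally one set biased toward a candidate list.

    With ``planted_candidate_bias`` b > 1 and a candidate list given, the
    set named SET_PLANTED samples candidate genes with weight b versus 1
    for the rest, over-representing them by roughly that factor.
    """
    genes = [str(g) for g in genes]
    lo, hi = set_size_range
    if hi > len(genes):
        raise ConfigError("set size range exceeds the gene universe")
    rng = np.random.default_rng(seed)
    sets = {}
    for i in range(n_sets):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False)
        sets[f"SET{i + 1:03d}"] = GeneSet(
            f"random set {i + 1}", frozenset(members)
        )
    if planted_candidate_bias > 1.0:
        if not candidates:
            raise ConfigError("a candidate list is required to plant a biased set")
        cand = {str(g) for g in candidates}
        w = np.array([planted_candidate_bias if g in cand else 1.0 for g in genes])
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(genes, size=size, replace=False, p=w / w.sum())
        sets["SET_PLANTED"] = GeneSet(
            "candidate-biased set", frozenset(members)
        )
    return sets
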