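"""DNA-content cell-cycle gating for foci screens.

Homologous-recombination foci form only in S/G2, so G1 cells dilute the
per-well readout.  The screen's rule: pool cells, bin them by DNA-stain
intensity into equal-count quantile bins, and place the G1-to-S cut-off at
the intensity where the mean foci count per bin first reaches a target
level (default 2).  Cells below the cut-off are discarded; wells are then
summarized over the surviving S/G2 cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import GatingError, LayoutError, QCError
from .io import ROLE_EMPTY, ROLE_NEGATIVE, ROLE_POSITIVE, _as_layout_map

__all__ = [
    "GatingCurve",
    "estimate_g1_cutoff",
    "gate_sg2",
    "summarize_wells",
    "qc_control_separation",
]


@dataclass
class GatingCurve:
    """Mean-foci-versus-DNA-intensity curve over quantile bins.

    ``cutoff`` is the interpolated intensity where the curve first reaches
    ``foci_level``; ``None`` when the curve never gets there.
    """

    bin_edges: np.ndarray        # length n_bins + 1, intensity units
    bin_centers: np.ndarray      # mean intensity within each bin
    bin_mean_foci: np.ndarray
    bin_cell_counts: np.ndarray
    foci_level: float
    cutoff: float | None

    @property
    def n_bins(self) -> int:
        return len(self.bin_centers)

    def bin_width_at_cutoff(self) -> float:
        """Spacing of bin centers around the crossing (the local resolution)."""
        if self.cutoff is None:
            raise GatingError("no cutoff: the curve never reaches foci_level")
        i = int(np.searchsorted(self.bin_centers, self.cutoff))
        i = min(max(i, 1), self.n_bins - 1)
        return float(self.bin_centers[i] - self.bin_centers[i - 1])


def estimate_g1_cutoff(
    cells: pd.DataFrame, n_bins: int = 50, foci_level: float = 2.0
) -> GatingCurve:
    """Estimate the G1-to-S DNA-intensity cut-off from pooled cells.

    Cells are split into ``n_bins`` equal-count bins by dna_intensity.
    Scanning bins in increasing intensity, the cut-off is linearly
    interpolated between the centers of the last bin whose mean foci count
    is below ``foci_level`` and the first subsequent bin at or above it.
    """
    if len(cells) < n_bins:
        raise GatingError(
            f"{len(cells)} cells cannot fill {n_bins} quantile bins; "
            "reduce n_bins"
        )
    x = cells["dna_intensity"].to_numpy(dtype=float)
    f = cells["foci_count"].to_numpy(dtype=float)
    order = np.argsort(x, kind="stable")
    x, f = x[order], f[order]
    # equal-count split; duplicate-heavy data may make some bins uneven,
    # but counts always sum to the input size
    idx = np.array_split(np.arange(len(x)), n_bins)
    centers = np.array([x[i].mean() for i in idx])
    means = np.array([f[i].mean() for i in idx])
    counts = np.array([len(i) for i in idx])
    edges = np.concatenate(([x[0]], [x[i[-1]] for i in idx]))

    cutoff = None
    above = means >= foci_level
    if above.any():
        i = int(np.argmax(above))  # first bin at/above the target level
        if i == 0:
            cutoff = float(centers[0])
        else:
            c0, c1 = centers[i - 1], centers[i]
            m0, m1 = means[i - 1], means[i]
            cutoff = float(c0 + (foci_level - m0) * (c1 - c0) / (m1 - m0))
    return GatingCurve(edges, centers, means, counts, float(foci_level), cutoff)


def gate_sg2(cells: pd.DataFrame, cutoff: float | None) -> pd.DataFrame:
    """Retain S/G2 cells: exactly those with dna_intensity >= cutoff."""
    if cutoff is None:
        raise GatingError(
            "cutoff is absent; call estimate_g1_cutoff first or skip gating "
            "explicitly"
        )
    return cells[cells["dna_intensity"] >= cutoff].reset_index(drop=True)


_STATISTICS = {
    "mean": lambda f: float(np.mean(f)),
    "median": lambda f: float(np.median(f)),
    "fraction_positive": lambda f: float(np.mean(f >= 1)),
}


def summarize_wells(
    cells: pd.DataFrame,
    layouts,
    min_cells: int = 20,
    cutoff: float | None = None,
    statistic: str = "mean",
) -> pd.DataFrame:
    """Aggregate (gated) cells into one readout per non-empty layout well.

    If ``cutoff`` is given the gate is applied here and both the total and
    the gated cell counts are reported; otherwise the input is taken as
    already gated.  Wells with fewer than ``min_cells`` gated cells get a
    missing readout.
    """
    if statistic not in _STATISTICS:
        raise ValueError(f"unknown statistic {statistic!r}")
    stat = _STATISTICS[statistic]
    layouts = _as_layout_map(layouts)

    offending = []
    for plate, sub in cells.groupby("plate"):
        layout = layouts.get(str(plate))
        if layout is None:
            offending.extend(f"{plate}:{w}" for w in sub["well"].unique())
            continue
        for well in sub["well"].unique():
            if layout.role(well) == ROLE_EMPTY:
                offending.append(f"{plate}:{well}")
    if offending:
        raise LayoutError(
            "cells found in wells absent from the layout: "
            + ", ".join(sorted(offending)[:10])
        )

    gated = gate_sg2(cells, cutoff) if cutoff is not None else cells
    totals = cells.groupby(["plate", "well"]).size()
    per_well = gated.groupby(["plate", "well"])["foci_count"]
    n_gated = per_well.size()
    readouts = per_well.apply(lambda s: stat(s.to_numpy(dtype=float)))

    rows = []
    for plate_id in sorted(layouts):
        layout = layouts[plate_id]
        for well in layout.nonempty_wells:
            key = (plate_id, well)
            nt = int(totals.get(key, 0))
            ng = int(n_gated.get(key, 0))
            readout = float(readouts[key]) if ng >= min_cells else np.nan
            rows.append(
                (
                    plate_id,
                    well,
                    layout.role(well),
                    layout.genes.get(well, ""),
                    nt,
                    ng,
                    readout,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "well", "role", "gene",
            "n_cells_total", "n_cells_gated", "readout",
        ],
    )


def qc_control_separation(summaries: pd.DataFrame) -> pd.DataFrame:
    """Per-plate separation between negative and positive control wells.

    Reports means, SDs, pooled SD, Student's t with p-value, and SSMD.
    A plate is flagged when the positive-control mean is not below the
    negative-control mean (the positive control knocks down the focus-forming
    protein itself and must reduce foci).
    """
    rows = []
    for plate, sub in summaries.groupby("plate", sort=True):
        neg = sub.loc[sub["role"] == ROLE_NEGATIVE, "readout"].dropna().to_numpy()
        pos = sub.loc[sub["role"] == ROLE_POSITIVE, "readout"].dropna().to_numpy()
        if len(neg) < 2 or len(pos) < 2:
            raise QCError(
                f"plate {plate}: need >=2 negative and >=2 positive control "
                f"wells with readouts (got {len(neg)}/{len(pos)})"
            )
        nm, pm = float(neg.mean()), float(pos.mean())
        nv, pv = float(neg.var(ddof=1)), float(pos.var(ddof=1))
        dof = len(neg) + len(pos) - 2
        pooled = np.sqrt(((len(neg) - 1) * nv + (len(pos) - 1) * pv) / dof)
        import warnings as _warnings

        with np.errstate(divide="ignore", invalid="ignore"), \
                _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            t, p = stats.ttest_ind(neg, pos, equal_var=True)
        denom = np.sqrt(nv + pv)
        ssmd = (nm - pm) / denom if denom > 0 else np.inf * np.sign(nm - pm)
        rows.append(
            (
                plate, len(neg), len(pos), nm, pm,
                float(np.sqrt(nv)), float(np.sqrt(pv)), float(pooled),
                float(t), float(p), float(ssmd), bool(pm >= nm),
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "plate", "n_neg", "n_pos", "neg_mean", "pos_mean",
            "neg_sd", "pos_sd", "pooled_sd", "t_stat", "p_value",
            "ssmd", "flagged",
        ],
    )
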