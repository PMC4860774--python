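"""3D B-score normalization of plate-based screens.

The readouts of one screen run are stacked into a row x column x plate
cube and decomposed additively,

    y[r, c, p] = overall + row[r] + col[c] + plate[p] + residual[r, c, p],

by a three-way median polish: sweeps along rows, columns and plates each
subtract the median of the current residuals along that axis and
accumulate it into the corresponding effect.  Estimating row and column
effects from the whole cube (rather than per plate) makes them robust, and
the plate-effect vector captures plate-to-plate variation in the same fit.
The residuals, divided by 1.4826 times their median absolute deviation
(the robust normal-consistent scale), are the 3D B-scores: a score of -2
sits two robust standard deviations below the screen-wide level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import AssemblyError, DecompositionError
from .io import ROLE_SAMPLE, _as_layout_map, well_to_rc

__all__ = [
    "MAD_SCALE",
    "ScreenCube",
    "PolishDecomposition",
    "BScoreCube",
    "median_polish_3d",
    "scaled_mad",
    "bscore_from_residuals",
    "normalize_screen",
    "zscore_baseline",
    "NormalizedScreen",
]

#: Normal-consistency factor: 1 / Phi^-1(3/4), printed to the precision the
#: B-score literature uses.  MAD times this constant estimates the SD of a
#: normal population.
MAD_SCALE = 1.4826


@dataclass
class ScreenCube:
    """Row x column x plate readout array; NaN marks missing/masked wells."""

    values: np.ndarray                      # float, shape (R, C, P)
    plate_ids: list
    row_labels: list | None = None
    col_labels: list | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise AssemblyError("ScreenCube values must be 3-dimensional")
        if self.values.shape[2] != len(self.plate_ids):
            raise AssemblyError("plate_ids length does not match cube depth")
        if self.row_labels is None:
            self.row_labels = list(range(self.values.shape[0]))
        if self.col_labels is None:
            self.col_labels = list(range(self.values.shape[1]))

    @property
    def observed(self) -> np.ndarray:
        return np.isfinite(self.values)


@dataclass
class PolishDecomposition:
    """Additive fit from the three-way median polish.

    On every observed cell, overall + row + col + plate effect + residual
    reproduces the input to numerical tolerance.
    """

    overall: float
    row_effects: np.ndarray
    col_effects: np.ndarray
    plate_effects: np.ndarray
    residuals: np.ndarray       # NaN where the cube was masked
    n_iterations: int
    converged: bool

    def fitted(self) -> np.ndarray:
        return (
            self.overall
            + self.row_effects[:, None, None]
            + self.col_effects[None, :, None]
            + self.plate_effects[None, None, :]
        )


@dataclass
class BScoreCube:
    scores: np.ndarray          # NaN where masked
    mad_scaled: float           # the 1.4826 x MAD scale that was divided out
    degenerate: bool = False    # raw MAD was zero; scores forced to 0
    per_plate_scale: np.ndarray | None = None


def _check_slices(observed: np.ndarray, plate_ids) -> None:
    for axis, name, labels in (
        (0, "row", None),
        (1, "column", None),
        (2, "plate", plate_ids),
    ):
        counts = observed.sum(axis=tuple(i for i in range(3) if i != axis))
        dead = np.flatnonzero(counts == 0)
        if dead.size:
            label = labels[dead[0]] if labels is not None else int(dead[0])
            raise DecompositionError(
                f"{name} slice {label} has no observed wells; cannot polish"
            )


def median_polish_3d(
    cube: ScreenCube, max_iter: int = 20, tol: float = 1e-6
) -> PolishDecomposition:
    """Three-way median polish over a masked screen cube.

    Each iteration sweeps rows, then columns, then plates, subtracting the
    median of the current residuals along that axis (over observed cells
    only); after every full iteration the median of each effect vector is
    re-absorbed into the overall term.  Iteration stops when the total
    absolute adjustment falls below ``tol`` times the total absolute value
    of the observed data, or at ``max_iter``.
    """
    values = cube.values
    observed = cube.observed
    if not observed.any():
        raise DecompositionError("cube has no observed values")
    if not np.isfinite(values[observed]).all():
        raise DecompositionError("observed values must be finite")
    _check_slices(observed, cube.plate_ids)

    R, C, P = values.shape
    residuals = values.copy()
    overall = 0.0
    row_eff = np.zeros(R)
    col_eff = np.zeros(C)
    plate_eff = np.zeros(P)
    scale = np.abs(values[observed]).sum()
    threshold = tol * (scale if scale > 0 else 1.0)

    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        adjustment = 0.0
        for axis, eff in ((0, row_eff), (1, col_eff), (2, plate_eff)):
            other = tuple(i for i in range(3) if i != axis)
            med = np.nanmedian(residuals, axis=other)
            med = np.where(np.isfinite(med), med, 0.0)
            shape = [1, 1, 1]
            shape[axis] = -1
            residuals -= med.reshape(shape)
            eff += med
            adjustment += np.abs(med).sum()
        for eff in (row_eff, col_eff, plate_eff):
            m = float(np.median(eff))
            eff -= m
            overall += m
            adjustment += abs(m)
        if adjustment <= threshold:
            converged = True
            break

    residuals[~observed] = np.nan
    return PolishDecomposition(
        overall=float(overall),
        row_effects=row_eff,
        col_effects=col_eff,
        plate_effects=plate_eff,
        residuals=residuals,
        n_iterations=n_iter,
        converged=converged,
    )


def scaled_mad(values) -> float:
    """1.4826 times the median absolute deviation about the median.

    NaNs are ignored; at least one finite value is required.
    """
    x = np.asarray(values, dtype=float).ravel()
    x = x[np.isfinite(x)]
    if x.size == 0:
        raise ValueError("scaled_mad of an empty sample is undefined")
    return float(MAD_SCALE * np.median(np.abs(x - np.median(x))))


def bscore_from_residuals(
    decomposition: PolishDecomposition, mad_scope: str = "global"
) -> BScoreCube:
    """Scale polish residuals to B-scores.

    The default divides all residuals by one screen-wide 1.4826 x MAD so a
    single scale applies to every plate; ``mad_scope="per-plate"`` rescales
    each plate by its own MAD instead.  A zero MAD (no spread) yields all-zero
    scores with the degenerate flag set.
    """
    res = decomposition.residuals
    if mad_scope == "global":
        mad = scaled_mad(res)
        if mad == 0.0:
            scores = np.where(np.isfinite(res), 0.0, np.nan)
            return BScoreCube(scores, 0.0, degenerate=True)
        return BScoreCube(res / mad, mad)
    if mad_scope == "per-plate":
        P = res.shape[2]
        scales = np.array([scaled_mad(res[:, :, p]) for p in range(P)])
        degenerate = bool(np.any(scales == 0.0))
        safe = np.where(scales == 0.0, np.inf, scales)
        scores = res / safe[None, None, :]
        scores[np.isfinite(res) & (scores == 0.0)] = 0.0
        global_mad = scaled_mad(res)
        return BScoreCube(scores, global_mad, degenerate, per_plate_scale=scales)
    raise ValueError(f"unknown mad_scope {mad_scope!r}")


@dataclass
class NormalizedScreen:
    """Normalization result for one replicate run."""

    cube: ScreenCube
    decomposition: PolishDecomposition
    bscores: BScoreCube
    well_scores: pd.DataFrame           # plate, well, gene, role, score
    gene_scores: pd.Series = field(repr=False)  # gene -> score (median over wells)


def assemble_cube(
    summaries: pd.DataFrame, layouts, include_controls: bool = False
) -> ScreenCube:
    """Stack well summaries of one replicate into a ScreenCube.

    Control wells are masked by default: they are shifted by design and
    would bias the row/column medians of the polish.
    """
    layouts = _as_layout_map(layouts)
    geometries = {(l.n_rows, l.n_cols) for l in layouts.values()}
    if len(geometries) != 1:
        raise AssemblyError(f"plates of differing geometry: {sorted(geometries)}")
    (n_rows, n_cols), = geometries
    plate_ids = sorted(summaries["plate"].astype(str).unique())
    for pid in plate_ids:
        if pid not in layouts:
            raise AssemblyError(f"no layout for plate {pid!r}")

    values = np.full((n_rows, n_cols, len(plate_ids)), np.nan)
    for rec in summaries.itertuples(index=False):
        pid = str(rec.plate)
        if not include_controls and rec.role != ROLE_SAMPLE:
            continue
        r, c = well_to_rc(rec.well, n_rows, n_cols)
        values[r, c, plate_ids.index(pid)] = rec.readout

    # rows/columns that no layout ever uses (e.g. empty outer columns) are
    # structural holes, not data: drop them from the polished cube
    structural = np.zeros((n_rows, n_cols), dtype=bool)
    for layout in layouts.values():
        for well in layout.nonempty_wells:
            r, c = well_to_rc(well, n_rows, n_cols)
            structural[r, c] = True
    keep_rows = np.flatnonzero(structural.any(axis=1))
    keep_cols = np.flatnonzero(structural.any(axis=0))
    values = values[np.ix_(keep_rows, keep_cols, np.arange(len(plate_ids)))]
    return ScreenCube(
        values, plate_ids,
        row_labels=list(keep_rows), col_labels=list(keep_cols),
    )


def normalize_screen(
    summaries: pd.DataFrame,
    layouts,
    include_controls: bool = False,
    max_iter: int = 20,
    tol: float = 1e-6,
    mad_scope: str = "global",
) -> NormalizedScreen:
    """Full 3D B-score normalization of one replicate run.

    Assembles the screen cube from well summaries (empty and, by default,
    control wells masked), runs the three-way median polish, scales the
    residuals to B-scores, and maps well scores back to genes; genes
    represented by several wells collapse by the median of their scores.
    """
    layouts = _as_layout_map(layouts)
    cube = assemble_cube(summaries, layouts, include_controls=include_controls)
    decomposition = median_polish_3d(cube, max_iter=max_iter, tol=tol)
    bscores = bscore_from_residuals(decomposition, mad_scope=mad_scope)

    row_pos = {lbl: i for i, lbl in enumerate(cube.row_labels)}
    col_pos = {lbl: i for i, lbl in enumerate(cube.col_labels)}
    rows = []
    for rec in summaries.itertuples(index=False):
        pid = str(rec.plate)
        layout = layouts[pid]
        r, c = well_to_rc(rec.well, layout.n_rows, layout.n_cols)
        if r not in row_pos or c not in col_pos:
            continue
        score = bscores.scores[row_pos[r], col_pos[c], cube.plate_ids.index(pid)]
        if np.isfinite(score):
            rows.append((pid, rec.well, rec.gene, rec.role, float(score)))
    well_scores = pd.DataFrame(
        rows, columns=["plate", "well", "gene", "role", "score"]
    )
    sample = well_scores[
        (well_scores["role"] == ROLE_SAMPLE) & (well_scores["gene"] != "")
    ]
    gene_scores = sample.groupby("gene")["score"].median()
    gene_scores.name = "score"
    return NormalizedScreen(cube, decomposition, bscores, well_scores, gene_scores)


def zscore_baseline(summaries: pd.DataFrame) -> pd.Series:
    """Naive per-plate z-scores (no polish); comparison baseline only.

    Each sample well is standardized by its own plate's sample-well mean
    and SD, then gene scores collapse by median as in normalize_screen.
    """
    sample = summaries[
        (summaries["role"] == ROLE_SAMPLE) & summaries["readout"].notna()
    ].copy()

    def _z(s):
        sd = s.std(ddof=1)
        return (s - s.mean()) / (sd if sd > 0 else 1.0)

    sample["score"] = sample.groupby("plate")["readout"].transform(_z)
    out = sample.groupby("gene")["score"].median()
    out.name = "score"
    return out
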