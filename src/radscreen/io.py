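"""Readers and writers for every file the screen pipeline touches.

Formats are deliberately plain: delimited text for per-cell tables, plate
layouts, well summaries and score tables; three-column TSV for weighted
gene networks; GMT for gene-set collections.  Input delimiters are
auto-detected among comma and tab; writers always emit tab-separated text
with a ``#`` comment header carrying the tool version (and seed, when the
content is derived from a simulation).

Well addresses follow plate-reader convention: letter row + number column
("B03").  Internally everything is 0-based ``(row, col)``.
"""

from __future__ import annotations

import string
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import numpy as np
import pandas as pd

from .exceptions import FormatError, LayoutError, ValidationError

__all__ = [
    "PlateLayout",
    "CellRecord",
    "GeneSet",
    "well_to_rc",
    "rc_to_well",
    "read_cell_table",
    "read_layouts",
    "write_layouts",
    "read_network",
    "write_network",
    "read_gene_sets",
    "write_gene_sets",
    "read_gene_scores",
    "write_gene_scores",
    "read_well_summaries",
    "write_well_summaries",
]

VERSION = "0.1.0"

ROLE_SAMPLE = "sample"
ROLE_NEGATIVE = "negative_control"
ROLE_POSITIVE = "positive_control"
ROLE_EMPTY = "empty"
VALID_ROLES = frozenset({ROLE_SAMPLE, ROLE_NEGATIVE, ROLE_POSITIVE, ROLE_EMPTY})

_ROW_LETTERS = string.ascii_uppercase


class CellRecord(NamedTuple):
    """One segmented cell: plate, well address, id, DNA stain, foci count."""

    plate_id: str
    well: str
    cell_id: int
    dna_intensity: float
    foci_count: int


class GeneSet(NamedTuple):
    description: str
    genes: frozenset


def well_to_rc(well: str, n_rows: int = 16, n_cols: int = 24) -> tuple[int, int]:
    """Convert "B03" to 0-based ``(row, col)``; validates against the grid."""
    well = well.strip().upper()
    if len(well) < 2 or well[0] not in _ROW_LETTERS or not well[1:].isdigit():
        raise LayoutError(f"malformed well address {well!r}")
    r = _ROW_LETTERS.index(well[0])
    c = int(well[1:]) - 1
    if not (0 <= r < n_rows and 0 <= c < n_cols):
        raise LayoutError(
            f"well {well!r} outside the {n_rows}x{n_cols} plate grid"
        )
    return r, c


def rc_to_well(row: int, col: int) -> str:
    """Convert 0-based ``(row, col)`` to a zero-padded address like "B03"."""
    if row < 0 or row >= 26 or col < 0:
        raise LayoutError(f"row/col indices out of range: ({row}, {col})")
    return f"{_ROW_LETTERS[row]}{col + 1:02d}"


@dataclass
class PlateLayout:
    """Role map of one multi-well plate.

    ``roles`` assigns each listed well one of sample / negative_control /
    positive_control / empty; sample wells carry a gene id in ``genes``.
    Wells inside the grid but absent from ``roles`` are treated as empty.
    """

    plate_id: str
    n_rows: int = 16
    n_cols: int = 24
    roles: dict = field(default_factory=dict)
    genes: dict = field(default_factory=dict)

    def __post_init__(self):
        for well, role in self.roles.items():
            well_to_rc(well, self.n_rows, self.n_cols)
            if role not in VALID_ROLES:
                raise LayoutError(f"unknown role {role!r} for well {well}")
            if role == ROLE_SAMPLE and well not in self.genes:
                raise LayoutError(f"sample well {well} has no gene id")
        for well in self.genes:
            if self.roles.get(well) != ROLE_SAMPLE:
                raise LayoutError(f"gene assigned to non-sample well {well}")

    def role(self, well: str) -> str:
        return self.roles.get(well, ROLE_EMPTY)

    @property
    def sample_wells(self) -> list:
        return sorted(w for w, r in self.roles.items() if r == ROLE_SAMPLE)

    @property
    def negative_wells(self) -> list:
        return sorted(w for w, r in self.roles.items() if r == ROLE_NEGATIVE)

    @property
    def positive_wells(self) -> list:
        return sorted(w for w, r in self.roles.items() if r == ROLE_POSITIVE)

    @property
    def nonempty_wells(self) -> list:
        return sorted(w for w, r in self.roles.items() if r != ROLE_EMPTY)


def _detect_sep(path) -> str:
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            return "\t" if "\t" in line else ","
    return "\t"


def _header(seed=None) -> str:
    line = f"# radscreen {VERSION}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def _as_layout_map(layouts) -> Mapping:
    if isinstance(layouts, PlateLayout):
        return {layouts.plate_id: layouts}
    return layouts


# ---------------------------------------------------------------------------
# per-cell tables


def read_cell_table(path, layouts) -> pd.DataFrame:
    """Read a per-cell measurement table and validate it against layouts.

    Expected header columns: plate, well, cell, dna_intensity, foci_count.
    Records in empty-role wells are dropped with a warning; the drop count
    is stored in ``df.attrs["n_empty_dropped"]``.
    """
    layouts = _as_layout_map(layouts)
    df = pd.read_csv(path, sep=_detect_sep(path), comment="#")
    required = ["plate", "well", "cell", "dna_intensity", "foci_count"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"cell table {path} is missing column {col!r}")
    df = df[required].copy()
    df["plate"] = df["plate"].astype(str)
    df["well"] = df["well"].astype(str).str.strip().str.upper()
    # zero-pad column numbers so "B3" and "B03" compare equal
    df["well"] = df["well"].str[0] + df["well"].str[1:].astype(int).map(
        "{:02d}".format
    )

    bad = np.flatnonzero(df["foci_count"].to_numpy() < 0)
    if bad.size:
        raise ValidationError(
            f"negative foci_count at data row {bad[0] + 1} of {path}"
        )
    bad = np.flatnonzero(df["dna_intensity"].to_numpy() < 0)
    if bad.size:
        raise ValidationError(
            f"negative dna_intensity at data row {bad[0] + 1} of {path}"
        )

    keep = np.ones(len(df), dtype=bool)
    for plate, sub in df.groupby("plate"):
        if plate not in layouts:
            raise LayoutError(f"cell table references unknown plate {plate!r}")
        layout = layouts[plate]
        for well in sub["well"].unique():
            well_to_rc(well, layout.n_rows, layout.n_cols)
            if layout.role(well) == ROLE_EMPTY:
                keep[sub.index[sub["well"] == well]] = False
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(
            f"dropped {n_dropped} cell record(s) in empty-role wells",
            stacklevel=2,
        )
    out = df.loc[keep].reset_index(drop=True)
    out.attrs["n_empty_dropped"] = n_dropped
    return out


def write_cell_table(cells: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        cells.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# plate layouts


def read_layouts(path, n_rows: int = 16, n_cols: int = 24) -> dict:
    """Read a layout table (plate, well, role, gene) into PlateLayout objects."""
    df = pd.read_csv(
        path, sep=_detect_sep(path), comment="#", keep_default_na=False
    )
    for col in ("plate", "well", "role"):
        if col not in df.columns:
            raise FormatError(f"layout file {path} is missing column {col!r}")
    layouts = {}
    for plate, sub in df.groupby("plate", sort=True):
        roles, genes = {}, {}
        for rec in sub.itertuples(index=False):
            well = str(rec.well).strip().upper()
            roles[well] = rec.role
            gene = str(getattr(rec, "gene", "")).strip()
            if gene:
                genes[well] = gene
        layouts[str(plate)] = PlateLayout(
            plate_id=str(plate), n_rows=n_rows, n_cols=n_cols,
            roles=roles, genes=genes,
        )
    return layouts


def write_layouts(layouts, path, seed=None) -> None:
    layouts = _as_layout_map(layouts)
    rows = []
    for plate_id in sorted(layouts):
        layout = layouts[plate_id]
        for well in sorted(layout.roles):
            rows.append(
                (plate_id, well, layout.roles[well], layout.genes.get(well, ""))
            )
    df = pd.DataFrame(rows, columns=["plate", "well", "role", "gene"])
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# weighted gene networks


def read_network(path, min_confidence: float = 0.0) -> pd.DataFrame:
    """Read a 3-column (gene_a, gene_b, confidence) edge list.

    Self-edges are dropped; symmetric duplicates collapse keeping the
    maximum confidence; edges below ``min_confidence`` are removed.
    """
    sep = _detect_sep(path)
    # header optional: sniff whether the third field of the first row is numeric
    header = 0
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split(sep)
            if len(fields) >= 3:
                try:
                    float(fields[2])
                    header = None
                except ValueError:
                    header = 0
            break
    df = pd.read_csv(
        path, sep=sep, comment="#", header=header,
        names=["gene_a", "gene_b", "confidence"],
        usecols=[0, 1, 2],
    )
    if len(df) == 0:
        return df
    conf = df["confidence"].to_numpy(dtype=float)
    if np.any((conf < 0) | (conf > 1)) or np.any(~np.isfinite(conf)):
        raise ValidationError(f"confidence outside [0, 1] in {path}")
    df = df[df["gene_a"].astype(str) != df["gene_b"].astype(str)]
    a = df[["gene_a", "gene_b"]].astype(str).to_numpy()
    lo, hi = np.minimum(a[:, 0], a[:, 1]), np.maximum(a[:, 0], a[:, 1])
    df = pd.DataFrame(
        {"gene_a": lo, "gene_b": hi, "confidence": df["confidence"].to_numpy()}
    )
    df = (
        df.groupby(["gene_a", "gene_b"], as_index=False)["confidence"].max()
    )
    df = df[df["confidence"] >= min_confidence].reset_index(drop=True)
    return df


def write_network(edges: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        edges.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)


def read_gene_sets(path) -> dict:
    """Read a GMT file: name, description, then member genes, tab-separated."""
    sets = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"GMT line {ln}: expected name, description and >=1 member"
                )
            name, desc = fields[0], fields[1]
            members = frozenset(g for g in fields[2:] if g)
            if not members:
                raise ValidationError(f"GMT line {ln}: gene set {name!r} is empty")
            sets[name] = GeneSet(desc, members)
    return sets


def write_gene_sets(sets: Mapping, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        for name in sorted(sets):
            gs = sets[name]
            fh.write("\t".join([name, gs.description, *sorted(gs.genes)]) + "\n")


# ---------------------------------------------------------------------------
# gene score tables

_SCORE_FLOATS = (
    "score_rep1", "score_rep2", "rank_rep1", "rank_rep2", "rank_sum",
    "hrr_score",
)
_SCORE_BOOLS = ("hit_rep1", "hit_rep2", "sign_concordant")


def write_gene_scores(table: pd.DataFrame, path, seed=None) -> None:
    """Write a per-gene score table; missing values become empty fields."""
    df = table.copy()
    if df.index.name == "gene":
        df = df.reset_index()
    if "gene" not in df.columns:
        raise FormatError("gene score table must carry a 'gene' column or index")
    with open(path, "w") as fh:
        fh.write(_header(seed))
        df.to_csv(fh, sep="\t", index=False)


def read_gene_scores(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=_detect_sep(path), comment="#")
    if "gene" not in df.columns:
        raise FormatError(f"score table {path} has no 'gene' column")
    df = df.set_index("gene")
    for col in df.columns:
        if col in _SCORE_BOOLS:
            df[col] = df[col].astype("boolean")
        elif col == "merged_rank":
            df[col] = df[col].astype(int)
        elif col in _SCORE_FLOATS:
            df[col] = df[col].astype(float)
    return df


# ---------------------------------------------------------------------------
# well summaries


def write_well_summaries(summaries: pd.DataFrame, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header(seed))
        summaries.to_csv(fh, sep="\t", index=False)


def read_well_summaries(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep=_detect_sep(path), comment="#", keep_default_na=True,
        na_values=[""],
    )
    for col in ("plate", "well", "role", "readout"):
        if col not in df.columns:
            raise FormatError(f"well summary {path} is missing column {col!r}")
    df["plate"] = df["plate"].astype(str)
    if "gene" in df.columns:
        df["gene"] = df["gene"].fillna("")
    return df
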