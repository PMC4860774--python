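"""Replicate merging, candidate sizing, hit calling and composite scoring.

Duplicate screen runs are merged by rank summation: each replicate's gene
scores are ranked ascending (most suppressive = rank 1, average ranks at
ties) and the rank sums order the merged list.  The candidate-list size is
chosen by scanning list sizes from 50 upward in steps of 25 and keeping
the size whose top genes show the best between-replicate score
correlation.  Hits are genes scoring strictly below a threshold (default
-2, i.e. two robust SDs below the screen level).  A composite HRR score —
the per-gene product of this screen's score and an orthogonal
recombination-activity screen's score — flags genes suppressive in both.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import MergeError
from .network import hypergeometric_upper_tail

__all__ = [
    "MergedScreen",
    "CandidateSizing",
    "OverlapResult",
    "rank_and_merge",
    "size_candidate_list",
    "call_hits",
    "hrr_composite_score",
    "overlap_fraction",
]


@dataclass
class MergedScreen:
    """Merged duplicate runs: ranked table plus the unmatched side report."""

    table: pd.DataFrame            # indexed by gene, sorted by merged_rank
    only_rep1: pd.Series           # genes scored in replicate 1 only
    only_rep2: pd.Series


def rank_and_merge(scores_rep1, scores_rep2) -> MergedScreen:
    """Merge two replicate score maps into a rank-sum-ordered table.

    Only genes scored in both replicates are ranked (others are reported
    separately — rank sums are undefined for them).  Ties in rank_sum are
    broken by mean score (more negative first), then lexical gene id.
    """
    s1 = pd.Series(scores_rep1, dtype=float).dropna()
    s2 = pd.Series(scores_rep2, dtype=float).dropna()
    shared = s1.index.intersection(s2.index)
    if len(shared) == 0:
        raise MergeError("replicates share no scored genes")
    only1 = s1.drop(shared)
    only2 = s2.drop(shared)
    s1, s2 = s1[shared], s2[shared]

    table = pd.DataFrame(
        {
            "score_rep1": s1,
            "score_rep2": s2,
            "rank_rep1": stats.rankdata(s1.to_numpy()),
            "rank_rep2": stats.rankdata(s2.to_numpy()),
        },
        index=shared,
    )
    table.index.name = "gene"
    table["rank_sum"] = table["rank_rep1"] + table["rank_rep2"]
    table["mean_score"] = (table["score_rep1"] + table["score_rep2"]) / 2.0
    table = table.sort_values(
        by=["rank_sum", "mean_score", "gene"],
        ascending=[True, True, True],
        kind="stable",
    )
    table["merged_rank"] = np.arange(1, len(table) + 1)
    return MergedScreen(table, only1, only2)


@dataclass
class CandidateSizing:
    """Correlation sweep over candidate-list sizes."""

    sizes: np.ndarray
    correlations: np.ndarray     # NaN where undefined (degenerate variance)
    chosen_size: int | None
    method: str = "pearson"

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"size": self.sizes, "correlation": self.correlations})


def size_candidate_list(
    merged,
    start: int = 50,
    step: int = 25,
    max_size: int | None = None,
    method: str = "pearson",
) -> CandidateSizing:
    """Choose the candidate-list size maximizing replicate correlation.

    For each size N (start, start+step, ...), correlates the two
    replicates' scores over the top N genes of the merged list; the first
    maximum wins.  Sizes beyond the gene count truncate the sweep with a
    warning; sizes with undefined correlation (constant scores) are
    recorded as missing and skipped.
    """
    table = merged.table if isinstance(merged, MergedScreen) else merged
    n_genes = len(table)
    if max_size is None:
        max_size = n_genes
    if max_size > n_genes:
        import warnings

        warnings.warn(
            f"max_size {max_size} exceeds the {n_genes} merged genes; "
            "sweep truncated",
            stacklevel=2,
        )
        max_size = n_genes
    corr_fn = {"pearson": stats.pearsonr, "spearman": stats.spearmanr}[method]

    sizes, corrs = [], []
    for n in range(start, max_size + 1, step):
        top = table.iloc[:n]
        a = top["score_rep1"].to_numpy()
        b = top["score_rep2"].to_numpy()
        if np.std(a) == 0 or np.std(b) == 0:
            r = np.nan
        else:
            r = float(corr_fn(a, b).statistic)
        sizes.append(n)
        corrs.append(r)
    sizes = np.array(sizes, dtype=int)
    corrs = np.array(corrs, dtype=float)
    valid = np.isfinite(corrs)
    chosen = int(sizes[valid][np.argmax(corrs[valid])]) if valid.any() else None
    return CandidateSizing(sizes, corrs, chosen, method)


def call_hits(scores, threshold: float = -2.0) -> set:
    """Genes scoring strictly below the threshold ("lower than -2")."""
    s = pd.Series(scores, dtype=float).dropna()
    return set(s.index[s < threshold])


def hrr_composite_score(score_screen1, score_screen2) -> pd.DataFrame:
    """Per-gene product of two screens' scores, with sign concordance.

    Genes negative in both screens (candidate suppressors of both
    readouts) get a suppressor_rank ordering them by descending product;
    discordant sign patterns are kept — high-foci/low-activity genes are
    informative too (late-acting repair factors).  Commutative in its two
    inputs.
    """
    s1 = pd.Series(score_screen1, dtype=float).dropna()
    s2 = pd.Series(score_screen2, dtype=float).dropna()
    shared = s1.index.intersection(s2.index)
    if len(shared) == 0:
        raise MergeError("the two screens share no scored genes")
    df = pd.DataFrame(
        {"score_a": s1[shared], "score_b": s2[shared]}, index=shared
    )
    df.index.name = "gene"
    df["hrr_score"] = df["score_a"] * df["score_b"]
    df["sign_concordant"] = (
        ((df["score_a"] < 0) & (df["score_b"] < 0))
        | ((df["score_a"] > 0) & (df["score_b"] > 0))
    )
    both_neg = (df["score_a"] < 0) & (df["score_b"] < 0)
    df["suppressor_rank"] = np.nan
    order = df.loc[both_neg, "hrr_score"].sort_values(ascending=False)
    df.loc[order.index, "suppressor_rank"] = np.arange(1, both_neg.sum() + 1)
    return df.sort_index()


@dataclass
class OverlapResult:
    n_overlap: int
    fraction: float              # |A n B| / |A|
    p_value: float               # hypergeometric upper tail


def overlap_fraction(gene_set_a, gene_set_b, universe) -> OverlapResult:
    """Overlap of A with B as a fraction of A, with enrichment p-value."""
    universe = set(universe)
    a = set(gene_set_a) & universe
    b = set(gene_set_b) & universe
    if not a:
        raise ValueError("gene set A is empty within the universe")
    k = len(a & b)
    p = hypergeometric_upper_tail(len(universe), len(b), len(a), k)
    return OverlapResult(k, k / len(a), p)
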