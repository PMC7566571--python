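"""Ranked-list motif-enrichment landscapes and target fold-change statistics.

The landscape follows the Sylamer idea: order genes from most down- to most
up-regulated, and at successive leading-set cutoffs compute a signed
-log10 hypergeometric P-value for over/under-representation of genes whose
3'UTR contains a site word.  Positive values mean enrichment in the leading
(down-regulated) set.  The counting unit is gene-level presence/absence of
the word, with no composition correction; both choices are recorded in the
landscape metadata.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

DE_COLUMNS = ("gene", "log2fc", "adj_p")


def validate_de_table(table: pd.DataFrame, *, require_adj_p: bool = False) -> pd.DataFrame:
    """Check a differential-expression table (gene, log2fc, adj_p)."""
    missing = [c for c in ("gene", "log2fc") if c not in table.columns]
    if missing:
        raise ValueError(f"DE table lacks columns {missing}")
    if table.empty:
        raise ValueError("DE table is empty")
    if table["gene"].duplicated().any():
        dupes = table.loc[table["gene"].duplicated(), "gene"].unique()[:5]
        raise ValueError(f"duplicate genes in DE table, e.g. {list(dupes)}")
    if table["log2fc"].isna().any():
        raise ValueError("missing log2fc values in DE table")
    if require_adj_p:
        if "adj_p" not in table.columns or table["adj_p"].isna().any():
            raise ValueError("adj_p required but missing")
        bad = (table["adj_p"] < 0) | (table["adj_p"] > 1)
        if bad.any():
            raise ValueError("adj_p values outside [0, 1]")
    return table


def rank_genes(table: pd.DataFrame, direction: str = "down_to_up") -> list[str]:
    """Order genes from most down- to most up-regulated.

    All genes are kept regardless of significance.  Ties in log2fc are
    broken lexicographically by gene identifier, so the ranking is a
    deterministic function of the table contents irrespective of row order.
    """
    if direction != "down_to_up":
        raise ValueError(f"unsupported direction {direction!r}")
    validate_de_table(table)
    ordered = table.sort_values(["log2fc", "gene"], kind="mergesort")
    return ordered["gene"].tolist()


@dataclass
class EnrichmentLandscape:
    """Signed -log10 hypergeometric P per leading-set cutoff for one word."""

    word: str
    cutoffs: np.ndarray
    values: np.ndarray
    n_genes: int
    n_with_word: int
    n_dropped_no_utr: int = 0
    metadata: dict = field(default_factory=dict)

    def peak(self) -> tuple[int, float]:
        """(cutoff, value) of the maximum enrichment."""
        i = int(np.argmax(self.values))
        return int(self.cutoffs[i]), float(self.values[i])


def word_landscape(
    ranked: Iterable[str],
    utrome: Mapping[str, str],
    word: str,
    step: int = 100,
) -> EnrichmentLandscape:
    """Hypergeometric enrichment landscape of a site word along a ranked list.

    At cutoff ``t`` with ``N`` ranked genes, ``K`` of which contain the word
    and ``x`` of those in the leading ``t``: the value is
    ``-log10 P(X >= x)`` when ``x/t >= K/N`` (enriched in the leading set)
    and ``+log10 P(X <= x)`` otherwise, ``X ~ Hypergeometric(N, K, t)``.
    Genes without a UTR are dropped (count logged and recorded).
    """
    word = word.upper().replace("T", "U")
    if not 6 <= len(word) <= 8:
        raise ValueError(f"word length must be 6-8 nt, got {len(word)}")
    ranked = list(ranked)
    kept = [g for g in ranked if g in utrome]
    n_dropped = len(ranked) - len(kept)
    if n_dropped:
        logger.info("word_landscape: dropped %d ranked genes without a UTR", n_dropped)
    if not kept:
        raise ValueError("no ranked gene has a UTR")
    n = len(kept)
    if not 0 < step <= n:
        raise ValueError(f"step must be in (0, {n}], got {step}")

    has_word = np.array(
        [word in utrome[g].upper().replace("T", "U") for g in kept], dtype=bool
    )
    k_total = int(has_word.sum())
    cum_hits = np.cumsum(has_word)

    cutoffs = list(range(step, n + 1, step))
    if not cutoffs or cutoffs[-1] != n:
        cutoffs.append(n)
    cutoffs_arr = np.array(cutoffs, dtype=int)

    values = np.zeros(len(cutoffs_arr), dtype=float)
    for i, t in enumerate(cutoffs_arr):
        x = int(cum_hits[t - 1])
        if k_total == 0:
            values[i] = 0.0
            continue
        if x / t >= k_total / n:
            p = stats.hypergeom.sf(x - 1, n, k_total, t)
            values[i] = -np.log10(max(p, np.finfo(float).tiny))
        else:
            p = stats.hypergeom.cdf(x, n, k_total, t)
            values[i] = np.log10(max(p, np.finfo(float).tiny))
    return EnrichmentLandscape(
        word=word,
        cutoffs=cutoffs_arr,
        values=values,
        n_genes=n,
        n_with_word=k_total,
        n_dropped_no_utr=n_dropped,
        metadata={"counting": "gene presence/absence", "composition_correction": "none"},
    )


def _direction_mask(table: pd.DataFrame, direction: str, alpha: float) -> pd.Series:
    sig = table["adj_p"] < alpha
    if direction == "up":
        return sig & (table["log2fc"] > 0)
    if direction == "down":
        return sig & (table["log2fc"] < 0)
    if direction == "no_change":
        return ~(sig & (table["log2fc"] != 0))
    raise ValueError(f"direction must be up/down/no_change, got {direction!r}")


def percent_targets(
    table: pd.DataFrame,
    targets: set[str],
    direction: str,
    alpha: float = 0.05,
) -> float:
    """Percentage of a direction class (up/down/no_change) that are targets.

    Classes are defined by adj_p < alpha and the sign of log2fc; significant
    genes with log2fc exactly 0 count as no_change.  An empty class yields
    NaN (undefined), never zero.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0, 1), got {alpha}")
    validate_de_table(table, require_adj_p=True)
    mask = _direction_mask(table, direction, alpha)
    n_class = int(mask.sum())
    if n_class == 0:
        return float("nan")
    n_target = int(table.loc[mask, "gene"].isin(targets).sum())
    return 100.0 * n_target / n_class


def target_fc_summary(table: pd.DataFrame, targets: set[str], stat: str = "mean") -> float:
    """Mean or median log2 fold change over a target set's member genes."""
    validate_de_table(table)
    vals = table.loc[table["gene"].isin(targets), "log2fc"]
    if vals.empty:
        return float("nan")
    if stat == "mean":
        return float(vals.mean())
    if stat == "median":
        return float(vals.median())
    raise ValueError(f"stat must be mean or median, got {stat!r}")


@dataclass
class CumulativeFractionCurve:
    """Empirical CDF of log2 fold changes for a gene set."""

    grid: np.ndarray       # sorted member log2fc values
    fractions: np.ndarray  # fraction of the set at or below each grid value

    def value_at(self, cutoff: float) -> float:
        """Fraction of the set with log2fc <= cutoff."""
        return float(np.searchsorted(self.grid, cutoff, side="right") / len(self.grid))


def cumulative_fraction(table: pd.DataFrame, gene_set: set[str]) -> CumulativeFractionCurve:
    """Empirical CDF of log2fc over a gene set present in the table."""
    validate_de_table(table)
    vals = np.sort(table.loc[table["gene"].isin(gene_set), "log2fc"].to_numpy())
    if vals.size == 0:
        raise ValueError("gene set does not intersect the DE table")
    return CumulativeFractionCurve(
        grid=vals, fractions=np.arange(1, vals.size + 1) / vals.size
    )


def compare_target_distributions(
    table: pd.DataFrame,
    set_a: set[str],
    set_b: set[str],
    test: str = "mannwhitney",
) -> tuple[float, float]:
    """Two-sided comparison of log2fc distributions of two gene sets.

    Defaults to the Mann-Whitney U test; ``test='ttest'`` selects Welch's
    t-test instead.  Both sets need at least two members in the table.
    """
    validate_de_table(table)
    a = table.loc[table["gene"].isin(set_a), "log2fc"].to_numpy()
    b = table.loc[table["gene"].isin(set_b), "log2fc"].to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("both gene sets need >= 2 members present in the table")
    if test == "mannwhitney":
        res = stats.mannwhitneyu(a, b, alternative="two-sided")
    elif test == "ttest":
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown test {test!r}")
    return float(res.statistic), float(res.pvalue)
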