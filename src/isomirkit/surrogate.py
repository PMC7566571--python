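"""Host-gene surrogate correlation across a compendium of DE studies.

For an intronic miRNA whose expression is rarely measured directly, the fold
change of its host gene (here typically *WWP2* for miR-140) serves as a
surrogate.  Across many differential-expression studies where the host gene
changes significantly, the mean log2 fold change of predicted miRNA targets
is regressed on the host-gene log2 fold change; a negative slope is the
signature of genuine target repression.  Per-study summaries also carry the
percentage of targets among significantly up-/down-regulated genes and
their ratio, plus a random-gene control set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import percent_targets, target_fc_summary, validate_de_table

logger = logging.getLogger(__name__)


@dataclass
class StudyComparison:
    """One differential-expression comparison with its host-gene row."""

    study_id: str
    de: pd.DataFrame
    host_log2fc: float
    host_adj_p: float

    @classmethod
    def from_table(cls, study_id: str, de: pd.DataFrame, host: str) -> "StudyComparison":
        validate_de_table(de, require_adj_p=True)
        row = de.loc[de["gene"] == host]
        if row.empty:
            raise KeyError(f"host gene {host!r} absent from study {study_id!r}")
        return cls(
            study_id=study_id,
            de=de,
            host_log2fc=float(row["log2fc"].iloc[0]),
            host_adj_p=float(row["adj_p"].iloc[0]),
        )


@dataclass
class SurrogateSummary:
    """Per-study target statistics keyed by target-set identifier.

    ``enrichment_up_down`` is pct_up / pct_down; it is NaN (missing) when
    either percentage is undefined or the denominator is zero, and such
    studies are excluded from ratio means downstream.
    """

    study_id: str
    host_log2fc: float
    mean_target_log2fc: dict[str, float] = field(default_factory=dict)
    pct_targets_up: dict[str, float] = field(default_factory=dict)
    pct_targets_down: dict[str, float] = field(default_factory=dict)
    enrichment_up_down: dict[str, float] = field(default_factory=dict)


@dataclass
class RegressionResult:
    """OLS of mean target log2FC on host-gene log2FC across studies."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    slope_stderr: float
    n_studies: int


def filter_studies(
    compendium: Sequence[StudyComparison],
    host: str,
    alpha: float = 0.05,
) -> list[StudyComparison]:
    """Retain studies where the host gene changed significantly.

    No fold-change cutoff is applied.  Studies lacking the host gene are
    dropped with a logged count before filtering.
    """
    if not compendium:
        raise ValueError("empty compendium")
    present = [s for s in compendium if (s.de["gene"] == host).any()]
    n_missing = len(compendium) - len(present)
    if n_missing:
        logger.info("filter_studies: dropped %d studies lacking host %s", n_missing, host)
    return [s for s in present if s.host_adj_p < alpha]


def study_summary(
    study: StudyComparison,
    target_sets: Mapping[str, set[str]],
    *,
    random_set_size: int = 500,
    rng_seed: int = 0,
    alpha: float = 0.05,
) -> SurrogateSummary:
    """Per-study target statistics, plus a seeded random-gene control.

    The control set (key ``"random"``) is drawn without replacement from the
    study's gene universe; drawing is reproducible for a fixed seed and
    independent of DE-table row order.
    """
    validate_de_table(study.de, require_adj_p=True)
    # sort by gene so results (including float summation order) do not
    # depend on the row order of the input table
    de = study.de.sort_values("gene", kind="mergesort").reset_index(drop=True)
    study = StudyComparison(study.study_id, de, study.host_log2fc, study.host_adj_p)
    genes = list(de["gene"])
    rng = np.random.default_rng(rng_seed)
    size = min(random_set_size, len(genes))
    random_set = set(rng.choice(genes, size=size, replace=False))

    all_sets = dict(target_sets)
    all_sets["random"] = random_set

    summary = SurrogateSummary(study_id=study.study_id, host_log2fc=study.host_log2fc)
    for name, targets in all_sets.items():
        if not set(targets) & set(genes):
            summary.mean_target_log2fc[name] = float("nan")
            summary.pct_targets_up[name] = float("nan")
            summary.pct_targets_down[name] = float("nan")
            summary.enrichment_up_down[name] = float("nan")
            continue
        summary.mean_target_log2fc[name] = target_fc_summary(study.de, set(targets), "mean")
        up = percent_targets(study.de, set(targets), "up", alpha)
        down = percent_targets(study.de, set(targets), "down", alpha)
        summary.pct_targets_up[name] = up
        summary.pct_targets_down[name] = down
        if np.isnan(up) or np.isnan(down) or down == 0:
            summary.enrichment_up_down[name] = float("nan")
        else:
            summary.enrichment_up_down[name] = up / down
    return summary


def regress_targets_vs_host(
    summaries: Sequence[SurrogateSummary],
    target_set_id: str,
) -> RegressionResult:
    """OLS of mean target log2FC on host log2FC; r^2 is squared Pearson r.

    The slope's P-value is the two-sided t-test of slope != 0.  Requires at
    least three studies with a defined mean and non-degenerate host-FC
    variance.
    """
    pairs = [
        (s.host_log2fc, s.mean_target_log2fc[target_set_id])
        for s in summaries
        if not np.isnan(s.mean_target_log2fc.get(target_set_id, float("nan")))
    ]
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 studies with defined means, have {len(pairs)}")
    x = np.array([p[0] for p in pairs])
    y = np.array([p[1] for p in pairs])
    if np.ptp(x) == 0:
        raise ValueError("degenerate host-FC variance: all host log2FC equal")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_value=float(res.pvalue),
        slope_stderr=float(res.stderr),
        n_studies=len(pairs),
    )


def cumulative_mean_trend(
    summaries: Sequence[SurrogateSummary],
    target_set_id: str,
    branch: str,
    metric: str = "mean_target_log2fc",
) -> pd.DataFrame:
    """Cumulative-mean trend line over studies ordered by host-gene change.

    ``from_most_up`` starts at the study with the largest host log2FC and
    walks toward no change; ``from_most_down`` starts at the most negative.
    The k-th point is the mean of the first k studies in branch order;
    studies with a missing metric value are skipped.
    """
    if branch not in ("from_most_up", "from_most_down"):
        raise ValueError(f"branch must be from_most_up/from_most_down, got {branch!r}")
    rows = [
        (s.host_log2fc, getattr(s, metric)[target_set_id], s.study_id)
        for s in summaries
        if not np.isnan(getattr(s, metric).get(target_set_id, float("nan")))
    ]
    if not rows:
        raise ValueError("no summaries with a defined metric value")
    rows.sort(key=lambda r: (r[0], r[2]), reverse=(branch == "from_most_up"))
    vals = np.array([r[1] for r in rows])
    cum = np.cumsum(vals) / np.arange(1, len(vals) + 1)
    return pd.DataFrame(
        {
            "study_id": [r[2] for r in rows],
            "host_log2fc": [r[0] for r in rows],
            "cumulative_mean": cum,
        }
    )


def group_contrast(
    summaries: Sequence[SurrogateSummary],
    target_set_id: str,
    metric: str = "mean_target_log2fc",
) -> tuple[dict[str, float], float]:
    """Host-down vs host-up group means with a two-sided Welch t-test.

    Groups are defined by the sign of the host log2FC; studies at exactly
    zero belong to neither and their count is logged.  Missing metric values
    are excluded; a group left empty (or with < 2 values) is an error rather
    than a silently collapsed comparison.
    """
    down, up = [], []
    n_zero = 0
    for s in summaries:
        v = getattr(s, metric).get(target_set_id, float("nan"))
        if np.isnan(v):
            continue
        if s.host_log2fc < 0:
            down.append(v)
        elif s.host_log2fc > 0:
            up.append(v)
        else:
            n_zero += 1
    if n_zero:
        logger.info("group_contrast: %d studies with host log2FC exactly 0 excluded", n_zero)
    if len(down) < 2 or len(up) < 2:
        raise ValueError(
            f"need >= 2 defined values per group, have down={len(down)}, up={len(up)}"
        )
    res = stats.ttest_ind(down, up, equal_var=False)
    means = {"host_down": float(np.mean(down)), "host_up": float(np.mean(up))}
    return means, float(res.pvalue)
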