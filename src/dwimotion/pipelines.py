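"""The three analysis aims as composable pipeline stages.

Aim 1 — cohort characterization: per-cohort motion distributions,
mean-vs-median skew, per-axis anisotropy, cumulative time courses, and
rank-sum comparisons across diagnostic groups.

Aim 2 — intra-subject scan–rescan bias: each subject's two same-session
scans are labeled less-/more-motion, the 120 subjects with the largest
motion gap are selected, and every bundle feature and connectome metric
is tested for a paired less-vs-more difference (signed-rank, BH FDR per
domain). Because the paired scans are the same brain on the same day,
any systematic difference is a motion artifact.

Aim 3 — movers vs non-movers: subjects whose every session sits in the
top (bottom) quartile of the pooled session-motion distribution are
labeled movers (non-movers); features are compared between groups with
an OLS adjusting for age and sex, BH-corrected per domain.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ValidationError
from .graph_metrics import METRIC_NAMES
from .motion_descriptors import MotionSummary, cumulative_curves, skew_diagnostic
from .simulate import MACRO_MEASURES, MICRO_MEASURES
from .stats_core import bh_fdr, glm_group_effect, signed_rank_grid, wilcoxon_rank_sum

logger = logging.getLogger(__name__)

__all__ = [
    "ScanRecord",
    "BiasResultGrid",
    "assign_scan_rescan",
    "select_top_movers_diff",
    "paired_bias_test",
    "paired_bias_test_matrix",
    "classify_movers",
    "mover_group_diff",
    "cohort_report",
    "group_motion_comparison",
    "DOMAIN_MEASURES",
]

DOMAIN_MEASURES: dict[str, tuple[str, ...]] = {
    "micro": MICRO_MEASURES,
    "macro": MACRO_MEASURES,
    "conn": METRIC_NAMES,
}


@dataclass
class ScanRecord:
    """One scan's demographics plus its motion summary."""

    subject: str
    session: str
    scan_index: int
    cohort: str
    age: float | None
    sex: str | None
    dx: str | None
    summary: MotionSummary

    def __post_init__(self) -> None:
        if self.scan_index not in (1, 2):
            raise ValidationError("scan_index must be 1 or 2")
        if self.age is not None and self.age < 0:
            raise ValidationError("age must be non-negative")


@dataclass
class BiasResultGrid:
    """Per-feature results of a paired or group comparison.

    ``table`` has one row per feature with columns measure, bundle,
    pct_change, statistic (or coef/se for GLM grids), p, q, reject.
    """

    table: pd.DataFrame
    domain: str
    alpha: float

    @property
    def n_tests(self) -> int:
        return len(self.table)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return (self.table["measure"].nunique(), self.table["bundle"].nunique())

    @property
    def n_significant(self) -> int:
        return int(self.table["reject"].sum())


def assign_scan_rescan(session: Sequence[ScanRecord]) -> tuple[ScanRecord, ScanRecord]:
    """Label a session's two scans (less_motion, more_motion) by mean
    relative movement per volume; ties go to scan_index 1 as less."""
    scans = sorted(session, key=lambda r: r.scan_index)
    if len(scans) != 2:
        raise ValidationError(f"scan-rescan sessions need exactly 2 scans, got {len(scans)}")
    a, b = scans
    if a.summary.mean_rel_mm_per_vol <= b.summary.mean_rel_mm_per_vol:
        return a, b
    return b, a


def select_top_movers_diff(
    sessions: Mapping[str, tuple[ScanRecord, ScanRecord]], k: int = 120
) -> list[str]:
    """The k subjects with the greatest (more − less) motion difference,
    in descending-difference order; boundary ties break toward the
    lexicographically smaller subject id."""
    if k > len(sessions):
        raise ValidationError(f"k={k} exceeds the {len(sessions)} available sessions")
    diffs = {
        subj: more.summary.mean_rel_mm_per_vol - less.summary.mean_rel_mm_per_vol
        for subj, (less, more) in sessions.items()
    }
    ordered = sorted(diffs, key=lambda s: (-diffs[s], s))
    return ordered[:k]


def _pivot_domain(table: pd.DataFrame, domain: str) -> pd.DataFrame:
    """Subject × (measure, bundle) wide matrix for one feature domain."""
    measures = DOMAIN_MEASURES[domain]
    sub = table[table["measure"].isin(measures)]
    if sub.empty:
        raise ValidationError(f"no features for domain {domain!r}")
    wide = sub.pivot_table(
        index="subject", columns=["measure", "bundle"], values="value", aggfunc="first"
    )
    if wide.isna().any().any():
        raise ValidationError(f"domain {domain!r}: missing feature values for some subjects")
    return wide


def paired_bias_test(
    less_table: pd.DataFrame,
    more_table: pd.DataFrame,
    domain: str,
    alpha: float = 0.05,
    group_ratio: bool = False,
) -> BiasResultGrid:
    """Test every feature of one domain for a paired less-vs-more
    difference.

    Per feature: signed-rank test on the per-subject (more − less)
    differences; all of the domain's p-values go into one BH correction
    at ``alpha``. Percent change is the mean over subjects of
    100·(more−less)/less (subjects with less == 0 are excluded from
    that mean only, with a logged count); ``group_ratio=True`` reports
    100·(mean(more)−mean(less))/mean(less) instead. Features whose
    differences are all zero are reported with p = 1.
    """
    if domain not in DOMAIN_MEASURES:
        raise ValidationError(f"unknown domain {domain!r}")
    less = _pivot_domain(less_table, domain)
    more = _pivot_domain(more_table, domain)
    if not less.index.equals(more.index):
        unpaired = set(less.index).symmetric_difference(more.index)
        raise ValidationError(f"unpaired subject(s): {sorted(unpaired)[:5]}")
    if not less.columns.equals(more.columns):
        raise ValidationError("less/more tables differ in features")
    n_pairs = len(less)
    if n_pairs < 6:
        logger.warning("only %d pairs: paired tests will be low-powered", n_pairs)

    return paired_bias_test_matrix(
        less.to_numpy(),
        more.to_numpy(),
        measures=[m for m, _ in less.columns],
        bundles=[b for _, b in less.columns],
        domain=domain,
        alpha=alpha,
        group_ratio=group_ratio,
    )


def paired_bias_test_matrix(
    L: np.ndarray,
    M: np.ndarray,
    measures: Sequence[str],
    bundles: Sequence[str],
    domain: str = "micro",
    alpha: float = 0.05,
    group_ratio: bool = False,
) -> BiasResultGrid:
    """Matrix-level core of :func:`paired_bias_test`.

    ``L`` and ``M`` are (n_subjects, n_features) less-/more-motion value
    matrices aligned on subjects; ``measures``/``bundles`` name the
    feature columns. Used directly when features are already in memory
    as matrices (e.g. large replicate suites).
    """
    L = np.asarray(L, dtype=float)
    M = np.asarray(M, dtype=float)
    if L.shape != M.shape or L.ndim != 2:
        raise ValidationError("less/more matrices must have equal (n, m) shapes")
    diffs = M - L
    pvals = signed_rank_grid(diffs)
    fdr = bh_fdr(pvals, alpha=alpha)

    if group_ratio:
        pct = 100.0 * (M.mean(axis=0) - L.mean(axis=0)) / L.mean(axis=0)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(L != 0.0, 100.0 * diffs / np.where(L == 0.0, np.nan, L), np.nan)
        n_zero = int((L == 0.0).sum())
        if n_zero:
            logger.info("%d zero-baseline values excluded from percent change", n_zero)
        pct = np.nanmean(ratio, axis=0)

    rows = pd.DataFrame(
        {
            "measure": list(measures),
            "bundle": list(bundles),
            "pct_change": pct,
            "p": pvals,
            "q": fdr.q,
            "reject": fdr.reject,
        }
    )
    return BiasResultGrid(table=rows, domain=domain, alpha=alpha)


def classify_movers(
    records: Sequence[ScanRecord], pct: float = 25.0
) -> dict[str, str]:
    """Label each subject mover / non_mover / neither.

    Thresholds are the pct-th and (100−pct)-th percentiles (linear
    interpolation) of the pooled per-session mean movement. A subject is
    a non-mover iff *all* of its sessions fall below the low threshold,
    a mover iff all fall above the high threshold.
    """
    records = list(records)
    if not records:
        raise ValidationError("classify_movers needs at least one record")
    values = np.asarray([r.summary.mean_rel_mm_per_vol for r in records])
    if values.size < 4:
        raise ValidationError("need >= 4 sessions in the pooled distribution")
    low = float(np.percentile(values, pct))
    high = float(np.percentile(values, 100.0 - pct))
    labels: dict[str, str] = {}
    by_subject: dict[str, list[float]] = {}
    for r, v in zip(records, values):
        by_subject.setdefault(r.subject, []).append(float(v))
    for subj, vals in by_subject.items():
        if all(v < low for v in vals):
            labels[subj] = "non_mover"
        elif all(v > high for v in vals):
            labels[subj] = "mover"
        else:
            labels[subj] = "neither"
    return labels


def mover_group_diff(
    features: pd.DataFrame,
    labels: Mapping[str, str],
    demographics: pd.DataFrame,
    domain: str,
    alpha: float = 0.05,
) -> BiasResultGrid:
    """Mover-vs-non-mover comparison of one feature domain.

    Per feature: OLS of the value on group (mover = 1) + age + sex, the
    group coefficient being the effect of interest; BH correction over
    the domain at ``alpha``. ``demographics`` needs columns subject,
    age, sex. Subjects labeled ``neither`` are excluded; missing
    covariates are dropped listwise with a logged count.
    """
    wide = _pivot_domain(features, domain)
    demo = demographics.set_index("subject")
    rows = []
    group_map = {"non_mover": 0.0, "mover": 1.0}
    subjects = [s for s in wide.index if labels.get(s) in group_map]
    if not subjects:
        raise ValidationError("no subjects labeled mover or non_mover")
    g = np.asarray([group_map[labels[s]] for s in subjects])
    if g.min() == g.max():
        raise ValidationError("one of the groups is empty")
    if (g == 1).sum() < 2 or (g == 0).sum() < 2:
        raise ValidationError("need >= 2 subjects per group")
    demo_sub = demo.loc[subjects]
    age = demo_sub["age"].to_numpy(dtype=float)
    sex = (demo_sub["sex"].astype(str).str.upper() == "M").to_numpy(dtype=float)
    keep = np.isfinite(age)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("dropping %d subject(s) with missing covariates", n_drop)
    sub_wide = wide.loc[np.asarray(subjects)[keep]]
    g, age, sex = g[keep], age[keep], sex[keep]

    coefs, ses, pvals = [], [], []
    for col in sub_wide.columns:
        coef, se, p = glm_group_effect(sub_wide[col].to_numpy(), g, age, sex)
        coefs.append(coef)
        ses.append(se)
        pvals.append(p)
    fdr = bh_fdr(np.asarray(pvals), alpha=alpha)
    table = pd.DataFrame(
        {
            "measure": [m for m, _ in sub_wide.columns],
            "bundle": [b for _, b in sub_wide.columns],
            "coef": coefs,
            "se": ses,
            "p": pvals,
            "q": fdr.q,
            "reject": fdr.reject,
        }
    )
    return BiasResultGrid(table=table, domain=domain, alpha=alpha)


def cohort_report(records: Sequence[ScanRecord], span: float = 0.3) -> dict:
    """Per-cohort motion characterization (distributions, skew, axis
    anisotropy, cumulative time course). JSON-serializable."""
    records = list(records)
    if not records:
        raise ValidationError("cohort_report needs at least one record")
    report: dict = {}
    by_cohort: dict[str, list[ScanRecord]] = {}
    for r in records:
        by_cohort.setdefault(r.cohort, []).append(r)
    for cohort, recs in sorted(by_cohort.items()):
        summaries = [r.summary for r in recs]
        mm_vol = np.asarray([s.mean_rel_mm_per_vol for s in summaries])
        mm_min = np.asarray([s.mean_rel_mm_per_min for s in summaries])
        trans = np.vstack([s.trans_rate_per_min for s in summaries])
        rot = np.vstack([s.rot_rate_per_min for s in summaries])
        mean_of_means, mean_of_medians, skewed = skew_diagnostic(summaries)
        _, (grid, curve) = cumulative_curves(summaries, span=span)
        report[cohort] = {
            "n_scans": len(recs),
            "mm_per_vol": {"mean": float(mm_vol.mean()), "median": float(np.median(mm_vol))},
            "mm_per_min": {"mean": float(mm_min.mean()), "median": float(np.median(mm_min))},
            "trans_mm_per_min": {
                axis: float(trans[:, i].mean()) for i, axis in enumerate(("LR", "PA", "IS"))
            },
            "rot_deg_per_min": {
                axis: float(rot[:, i].mean()) for i, axis in enumerate(("LR", "PA", "IS"))
            },
            "skew": {
                "mean_of_means": mean_of_means,
                "mean_of_medians": mean_of_medians,
                "mean_greater_than_median": bool(skewed),
            },
            "cumulative": {"minutes": grid.tolist(), "mm": curve.tolist()},
        }
    return report


def group_motion_comparison(
    records: Sequence[ScanRecord], grouping: str = "dx", alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise rank-sum comparisons of mean movement between diagnosis
    groups, run within each cohort and BH-corrected across all
    comparisons and cohorts."""
    records = list(records)
    rows = []
    by_cohort: dict[str, list[ScanRecord]] = {}
    for r in records:
        by_cohort.setdefault(r.cohort, []).append(r)
    for cohort, recs in sorted(by_cohort.items()):
        groups: dict[str, list[float]] = {}
        for r in recs:
            key = getattr(r, grouping)
            if key:
                groups.setdefault(str(key), []).append(r.summary.mean_rel_mm_per_vol)
        usable = {k: v for k, v in groups.items() if len(v) >= 2}
        names = sorted(usable)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                a, b = names[i], names[j]
                res = wilcoxon_rank_sum(usable[a], usable[b])
                rows.append(
                    {
                        "cohort": cohort,
                        "group_a": a,
                        "group_b": b,
                        "n_a": len(usable[a]),
                        "n_b": len(usable[b]),
                        "median_a": float(np.median(usable[a])),
                        "median_b": float(np.median(usable[b])),
                        "statistic": res.statistic,
                        "p": res.p,
                    }
                )
    if not rows:
        raise ValidationError("need at least two groups with >= 2 records each")
    out = pd.DataFrame(rows)
    fdr = bh_fdr(out["p"].to_numpy(), alpha=alpha)
    out["q"] = fdr.q
    out["reject"] = fdr.reject
    return out
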