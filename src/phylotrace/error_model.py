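"""Intra-library trinucleotide-context (TNC) background error model.

A targeted cfDNA library carries, at every non-variant panel position, a small
number of consensus-read errors whose rate depends strongly on the
substitution's trinucleotide context.  This module estimates those per-class
error rates (ER = DAO/DDP with an exact Poisson confidence interval), applies
the pre-calling variant quality filters, and collapses the qualified classes
into four depth-weighted "D-groups" whose average rates form the Poisson
background of the sample-level ctDNA test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .core_io import BackgroundCounts, TrackedVariant, VariantCounts, collapse_context

__all__ = [
    "TncErrorRate",
    "DGroupModel",
    "FilterReport",
    "garwood_interval",
    "pam_1d",
    "compute_tnc_error_rates",
    "apply_quality_filters",
    "vaf_outlier_filter",
    "build_d_groups",
]


# ---------------------------------------------------------------------------
# exact Poisson (Garwood) interval
# ---------------------------------------------------------------------------


def garwood_interval(count: int, confidence: float = 0.95) -> tuple[float, float]:
    """Exact two-sided Poisson confidence interval for an observed count.

    Chi-square formulation: lower = chi2(alpha/2, 2k)/2 (0 when k = 0),
    upper = chi2(1 - alpha/2, 2k + 2)/2.
    """
    alpha = 1.0 - confidence
    lo = 0.0 if count == 0 else stats.chi2.ppf(alpha / 2, 2 * count) / 2.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * count + 2) / 2.0
    return lo, hi


@dataclass(frozen=True)
class TncErrorRate:
    """Error rate of one collapsed trinucleotide-context alternate class."""

    tnc_alt: str
    er: float
    ci_low: float
    ci_high: float
    dao_total: int
    ddp_total: int
    usable: bool = True


# ---------------------------------------------------------------------------
# exact 1-D PAM (partitioning around medoids)
# ---------------------------------------------------------------------------


def _segment_cost(prefix: np.ndarray, order: np.ndarray, values: np.ndarray,
                  i: int, j: int) -> float:
    """L1 cost of the sorted segment [i, j] about its medoid (a member point)."""
    mid = (i + j) // 2
    med = values[order[mid]]
    left = med * (mid - i + 1) - (prefix[mid + 1] - prefix[i])
    right = (prefix[j + 1] - prefix[mid + 1]) - med * (j - mid)
    return left + right


def pam_1d(values: Sequence[float], k: int) -> np.ndarray:
    """Exact k-medoids on one-dimensional data.

    In one dimension the optimal k-medoid partition under L1 cost is
    contiguous on the sorted values, so an exhaustive dynamic programme over
    contiguous segments is exact (no heuristic swaps).  Ties prefer earlier
    split indices.  Returns integer labels (0..k-1 ordered by value) aligned
    with the input order.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if k < 1:
        raise ValueError("k must be >= 1")
    k = min(k, n)
    order = np.argsort(x, kind="stable")
    sorted_x = x[order]
    prefix = np.concatenate([[0.0], np.cumsum(sorted_x)])

    def cost(i: int, j: int) -> float:
        return _segment_cost(prefix, order, x, i, j)

    INF = float("inf")
    best = np.full((n + 1, k + 1), INF)
    back = np.zeros((n + 1, k + 1), dtype=int)
    best[0, 0] = 0.0
    for j in range(1, n + 1):
        gmax = min(k, j)
        for g in range(1, gmax + 1):
            for i in range(g - 1, j):  # last segment covers sorted positions i..j-1
                if best[i, g - 1] == INF:
                    continue
                c = best[i, g - 1] + cost(i, j - 1)
                if c < best[j, g] - 1e-15:
                    best[j, g] = c
                    back[j, g] = i
                # ties keep the earliest split (smallest i), i.e. first assignment
    labels_sorted = np.zeros(n, dtype=int)
    j, g = n, k
    while g > 0:
        i = back[j, g]
        labels_sorted[i:j] = g - 1
        j, g = i, g - 1
    labels = np.empty(n, dtype=int)
    labels[order] = labels_sorted
    return labels


# ---------------------------------------------------------------------------
# TNC error-rate estimation
# ---------------------------------------------------------------------------


def compute_tnc_error_rates(
    background_counts: Iterable[BackgroundCounts] | pd.DataFrame,
    vaf_exclusion: float = 0.01,
    confidence: float = 0.95,
) -> list[TncErrorRate]:
    """Estimate per-class background error rates for one library.

    ``background_counts`` is either a list of pre-aggregated
    :class:`BackgroundCounts` (positions with per-alternate VAF above
    ``vaf_exclusion`` already excluded upstream) or a per-position DataFrame
    with columns ``tnc, alt, dao, ddp``, in which case the VAF exclusion is
    applied here before aggregating into the 96 collapsed classes.
    """
    if isinstance(background_counts, pd.DataFrame):
        df = background_counts.copy()
        vaf = np.where(df["ddp"] > 0, df["dao"] / df["ddp"].replace(0, np.nan), 0.0)
        df = df[~(vaf > vaf_exclusion)]
        df["tnc_alt"] = [collapse_context(t, a) for t, a in zip(df["tnc"], df["alt"])]
        agg = df.groupby("tnc_alt", sort=True)[["dao", "ddp"]].sum()
        pairs = [(cls, int(r.dao), int(r.ddp)) for cls, r in agg.iterrows()]
    else:
        pairs = [(b.tnc_alt, b.dao_total, b.ddp_total) for b in background_counts]

    out = []
    for cls, dao, ddp in pairs:
        if ddp <= 0:
            out.append(TncErrorRate(cls, float("nan"), float("nan"), float("nan"),
                                    dao, ddp, usable=False))
            continue
        lo, hi = garwood_interval(dao, confidence)
        out.append(TncErrorRate(cls, dao / ddp, lo / ddp, hi / ddp, dao, ddp))
    return out


# ---------------------------------------------------------------------------
# quality filters
# ---------------------------------------------------------------------------

FILTER_FLAGS = (
    "off_target",
    "read_strand_bias",
    "sequencing_strand_bias",
    "background_error_rate",
    "vaf_outlier",
)


@dataclass
class FilterReport:
    """Per-variant per-sample filter flags; ``passes`` means no flag set and
    the variant is not hard-filtered upstream."""

    table: pd.DataFrame

    def passing(self, sample_id: str | None = None) -> set[str]:
        t = self.table
        if sample_id is not None:
            t = t[t["sample_id"] == sample_id]
        return set(t.loc[t["passes"], "variant_id"])

    def flags_for(self, sample_id: str, variant_id: str) -> dict[str, bool]:
        t = self.table
        row = t[(t["sample_id"] == sample_id) & (t["variant_id"] == variant_id)]
        if row.empty:
            raise KeyError((sample_id, variant_id))
        r = row.iloc[0]
        return {f: bool(r[f]) for f in FILTER_FLAGS}


def _strand_bias_pvals(strand: pd.DataFrame | None, min_alt: int) -> dict:
    """Two-sided binomial test of the alternate-read strand split against the
    depth strand split.  Returns {(sample, variant): biased?}."""
    out: dict = {}
    if strand is None:
        return out
    for row in strand.itertuples(index=False):
        alt_total = int(row.dao_fwd) + int(row.dao_rev)
        dep_total = int(row.ddp_fwd) + int(row.ddp_rev)
        if alt_total < min_alt or dep_total == 0 or row.ddp_fwd == 0 or row.ddp_rev == 0:
            out[(row.sample_id, row.variant_id)] = (False, 1.0)
            continue
        p_exp = row.ddp_fwd / dep_total
        pval = stats.binomtest(int(row.dao_fwd), alt_total, p_exp).pvalue
        out[(row.sample_id, row.variant_id)] = (None, pval)
    return out


def wilson_interval(dao: int, ddp: int, confidence: float = 0.95) -> tuple[float, float]:
    if ddp == 0:
        return (0.0, 1.0)
    lo, hi = proportion_confint(dao, ddp, alpha=1 - confidence, method="wilson")
    return float(lo), float(hi)


def vaf_outlier_filter(
    passing_variants: Sequence[str],
    counts: Mapping[str, VariantCounts],
    confidence: float = 0.95,
    max_outliers: int = 3,
) -> set[str]:
    """VAF outlier removal by k=2 partitioning-around-medoids.

    The high-VAF cluster is removed iff (a) the Wilson intervals of the
    boundary members (lowest of the high cluster, highest of the low cluster)
    do not overlap and (b) the high cluster holds at most ``max_outliers``
    variants.  Fewer than four variants with depth: no-op.
    """
    with_depth = [v for v in passing_variants if counts[v].ddp > 0]
    if len(with_depth) < 4:
        return set()
    vafs = np.array([counts[v].raw_vaf for v in with_depth])
    if np.allclose(vafs, vafs[0]):
        return set()
    labels = pam_1d(vafs, 2)
    high = [v for v, l in zip(with_depth, labels) if l == 1]
    low = [v for v, l in zip(with_depth, labels) if l == 0]
    if not high or not low or len(high) > max_outliers:
        return set()
    low_top = max(low, key=lambda v: counts[v].raw_vaf)
    high_bottom = min(high, key=lambda v: counts[v].raw_vaf)
    _, low_hi = wilson_interval(counts[low_top].dao, counts[low_top].ddp, confidence)
    high_lo, _ = wilson_interval(counts[high_bottom].dao, counts[high_bottom].ddp, confidence)
    if high_lo > low_hi:
        return set(high)
    return set()


def apply_quality_filters(
    variants: Sequence[TrackedVariant],
    counts: Sequence[VariantCounts],
    tnc_table: Sequence[TncErrorRate],
    er_upper_limit: float = 1e-4,
    off_target_ids: set[str] | frozenset[str] = frozenset(),
    read_strand: pd.DataFrame | None = None,
    seq_strand: pd.DataFrame | None = None,
    strand_bias_p: float = 0.01,
    strand_bias_min_alt: int = 5,
) -> FilterReport:
    """Apply the pre-calling variant quality filters.

    Order: off-target (annotation pass-through), strand-bias (optional
    strand-split tables with columns ``sample_id, variant_id, dao_fwd,
    dao_rev, ddp_fwd, ddp_rev``), background-error-rate (class upper
    confidence bound above ``er_upper_limit``, or class unusable), then the
    VAF outlier filter over the survivors of the preceding filters.
    """
    er_by_class = {t.tnc_alt: t for t in tnc_table}
    var_by_id = {v.variant_id: v for v in variants}
    read_p = _strand_bias_pvals(read_strand, strand_bias_min_alt)
    seq_p = _strand_bias_pvals(seq_strand, strand_bias_min_alt)

    rows = []
    by_sample: dict[str, list[VariantCounts]] = {}
    for c in counts:
        by_sample.setdefault(c.sample_id, []).append(c)

    for sample_id, sample_counts in by_sample.items():
        count_by_id = {c.variant_id: c for c in sample_counts}
        pre_pass: list[str] = []
        flag_rows: dict[str, dict] = {}
        for c in sample_counts:
            v = var_by_id.get(c.variant_id)
            if v is None:
                continue
            flags = dict.fromkeys(FILTER_FLAGS, False)
            flags["off_target"] = c.variant_id in off_target_ids
            for key, store, flag in ((read_p, "read_strand_bias", None),
                                     (seq_p, "sequencing_strand_bias", None)):
                rec = key.get((sample_id, c.variant_id))
                if rec is not None:
                    fixed, pval = rec
                    flags[store] = bool(fixed) if fixed is not None else pval < strand_bias_p
            cls = er_by_class.get(v.tnc_alt)
            if cls is None or not cls.usable or cls.ci_high > er_upper_limit:
                flags["background_error_rate"] = True
            flag_rows[c.variant_id] = flags
            if not any(flags.values()) and not v.hard_filtered:
                pre_pass.append(c.variant_id)
        outliers = vaf_outlier_filter(pre_pass, count_by_id)
        for vid, flags in flag_rows.items():
            flags["vaf_outlier"] = vid in outliers
            v = var_by_id[vid]
            rows.append({
                "sample_id": sample_id,
                "variant_id": vid,
                **flags,
                "hard_filtered": v.hard_filtered,
                "passes": not any(flags.values()) and not v.hard_filtered,
            })
    return FilterReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# D-groups
# ---------------------------------------------------------------------------


@dataclass
class DGroupModel:
    """Depth-weighted D-group background rates.

    ``group_of_class`` maps each qualified 96-class key onto a group index;
    ``weighted_er`` holds the DDP-weighted mean error rate of each group.
    """

    group_of_class: dict[str, int]
    weighted_er: dict[int, float]
    class_rates: dict[str, TncErrorRate]

    def rate_for_class(self, tnc_alt: str) -> float | None:
        """D-group weighted rate for a class; None if the class did not qualify."""
        g = self.group_of_class.get(tnc_alt)
        return None if g is None else self.weighted_er[g]

    def class_er(self, tnc_alt: str) -> float | None:
        """Raw class-specific error rate (for variant-level calls)."""
        t = self.class_rates.get(tnc_alt)
        return t.er if t is not None and t.usable else None

    def variant_lookup(self, variants: Iterable[TrackedVariant]) -> dict[str, float]:
        out = {}
        for v in variants:
            r = self.rate_for_class(v.tnc_alt)
            if r is not None:
                out[v.variant_id] = r
        return out


def build_d_groups(
    tnc_table: Sequence[TncErrorRate],
    variants: Sequence[TrackedVariant] = (),
    k: int = 4,
    er_upper_limit: float = 1e-4,
) -> DGroupModel:
    """Cluster qualified class error rates into k D-groups (1-D exact PAM) and
    compute the DDP-weighted average rate of each group."""
    qualified = [t for t in tnc_table if t.usable and t.ci_high <= er_upper_limit]
    if not qualified:
        return DGroupModel({}, {}, {t.tnc_alt: t for t in tnc_table})
    rates = np.array([t.er for t in qualified])
    n_distinct = len(np.unique(rates))
    k_eff = min(k, n_distinct)
    if k_eff < k:
        warnings.warn(
            f"only {n_distinct} distinct qualified error rates; using {k_eff} D-groups",
            stacklevel=2,
        )
    labels = pam_1d(rates, k_eff)
    weighted: dict[int, float] = {}
    for g in range(k_eff):
        members = [t for t, l in zip(qualified, labels) if l == g]
        num = sum(t.er * t.ddp_total for t in members)
        den = sum(t.ddp_total for t in members)
        weighted[g] = num / den if den > 0 else float(np.mean([t.er for t in members]))
    return DGroupModel(
        {t.tnc_alt: int(l) for t, l in zip(qualified, labels)},
        weighted,
        {t.tnc_alt: t for t in tnc_table},
    )
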