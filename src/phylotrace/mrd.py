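"""Sample- and variant-level ctDNA detection by exact Poisson tests.

The sample-level call compares the summed deep alternate observations (DAO)
across all filter-passing tracked variants with the number expected from
background error alone (lambda = sum of DDP x D-group weighted error rate)
using a one-tailed exact Poisson test, p = P(X >= observed).  Variant-level
calls use the variant's own trinucleotide-class error rate.  The module also
derives the library's minimal detectable allele fraction (MDAF), the minimal
detectable clonal ctDNA level (MDCL), the clonal ctDNA level itself, and the
volume-based shedding classifier separating probable biological low-shedders
from probable technical negatives among ctDNA-negative tumours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .core_io import TrackedVariant, VariantCounts
from .error_model import DGroupModel, FilterReport

__all__ = [
    "MrdResult",
    "VariantCall",
    "SheddingCall",
    "SheddingModel",
    "poisson_upper_tail",
    "poisson_detection_threshold",
    "call_sample_mrd",
    "call_variant",
    "clonal_ctdna_level",
    "minimal_detectable_af",
    "minimal_detectable_clonal_level",
    "fit_shedding_model",
    "classify_shedding",
]


def poisson_upper_tail(observed: int, lam: float) -> float:
    """p = P(X >= observed) for X ~ Poisson(lam); 1.0 when observed == 0."""
    if observed <= 0:
        return 1.0
    if lam <= 0:
        return 0.0
    return float(stats.poisson.sf(observed - 1, lam))


def poisson_detection_threshold(lam: float, alpha: float = 0.01) -> int:
    """Smallest integer k with P(X >= k | lam) < alpha (k >= 1)."""
    if lam <= 0:
        return 1
    k = max(1, int(stats.poisson.ppf(1 - alpha, lam)) - 1)
    while poisson_upper_tail(k, lam) >= alpha:
        k += 1
    return k


# ---------------------------------------------------------------------------
# result records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MrdResult:
    sample_id: str
    observed_dao: int
    expected_dao: float
    p_value: float
    positive: bool
    alpha: float = 0.01
    n_passing: int = 0
    clonal_ctdna_level: float = float("nan")
    mdaf: float = float("nan")
    mdcl: float = float("nan")


@dataclass(frozen=True)
class VariantCall:
    variant_id: str
    sample_id: str
    p_value: float
    detected: bool
    er_unusable: bool = False


@dataclass(frozen=True)
class SheddingCall:
    patient_id: str
    predicted_log10_level: float
    ci_low_log10: float
    ci_high_log10: float
    mdcl: float
    category: str  # low_shedder | technical_negative


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------


def call_sample_mrd(
    counts: Sequence[VariantCounts],
    filter_report: FilterReport,
    dgroup_model: DGroupModel,
    variants: Sequence[TrackedVariant],
    alpha: float = 0.01,
) -> MrdResult:
    """Sample-level ctDNA call over all filter-passing tracked variants."""
    sample_ids = {c.sample_id for c in counts}
    if len(sample_ids) != 1:
        raise ValueError(f"counts span {len(sample_ids)} samples; expected one")
    sample_id = sample_ids.pop()
    var_by_id = {v.variant_id: v for v in variants}
    passing = filter_report.passing(sample_id)
    observed = 0
    lam = 0.0
    n_passing = 0
    for c in counts:
        if c.variant_id not in passing:
            continue
        v = var_by_id.get(c.variant_id)
        if v is None:
            continue
        rate = dgroup_model.rate_for_class(v.tnc_alt)
        if rate is None:
            continue
        observed += c.dao
        lam += c.ddp * rate
        n_passing += 1
    if n_passing == 0:
        warnings.warn(f"sample {sample_id}: no passing variants; MRD negative by default",
                      stacklevel=2)
        return MrdResult(sample_id, 0, 0.0, 1.0, False, alpha, 0)
    p = poisson_upper_tail(observed, lam)
    return MrdResult(sample_id, observed, lam, p, p < alpha, alpha, n_passing)


def call_variant(
    count: VariantCounts,
    tnc_er: float | None,
    alpha: float = 0.01,
) -> VariantCall:
    """Variant-level detection using the variant's own class error rate."""
    if tnc_er is None or (isinstance(tnc_er, float) and math.isnan(tnc_er)):
        return VariantCall(count.variant_id, count.sample_id, 1.0, False, er_unusable=True)
    lam = count.ddp * tnc_er
    p = poisson_upper_tail(count.dao, lam)
    return VariantCall(count.variant_id, count.sample_id, p, p < alpha)


def _expected_error_reads(
    counts: Sequence[VariantCounts],
    variants: Sequence[TrackedVariant],
    dgroup_model: DGroupModel,
    subset_ids: set[str],
) -> tuple[int, float, int]:
    """(sum DAO, sum DDP x class er, sum DDP) over the given variant ids."""
    var_by_id = {v.variant_id: v for v in variants}
    dao = ddp = 0
    expected = 0.0
    for c in counts:
        if c.variant_id not in subset_ids:
            continue
        v = var_by_id[c.variant_id]
        er = dgroup_model.class_er(v.tnc_alt)
        if er is None:
            er = dgroup_model.rate_for_class(v.tnc_alt) or 0.0
        dao += c.dao
        ddp += c.ddp
        expected += c.ddp * er
    return dao, expected, ddp


def clonal_ctdna_level(
    counts: Sequence[VariantCounts],
    variants: Sequence[TrackedVariant],
    dgroup_model: DGroupModel,
) -> float:
    """Mean mutant-read fraction across clonal positions after background
    subtraction: max(0, (sum DAO - floor(expected error)) / sum DDP).

    NaN when no clonal variant carries depth.
    """
    clonal_ids = {v.variant_id for v in variants if v.is_clonal and not v.hard_filtered}
    dao, expected, ddp = _expected_error_reads(counts, variants, dgroup_model, clonal_ids)
    if ddp == 0:
        return float("nan")
    return max(0.0, (dao - math.floor(expected)) / ddp)


def minimal_detectable_af(
    counts: Sequence[VariantCounts],
    dgroup_model: DGroupModel,
    variants: Sequence[TrackedVariant],
    n_subsample: int | None = None,
    alpha: float = 0.01,
    seed: int | None = None,
) -> float:
    """Minimal detectable allele fraction: the smallest panel-wide VAF whose
    read count would trigger a positive call given the background lambda.

    Optionally evaluates a random subsample of tracked mutations (seeded), to
    study the effect of panel size.
    """
    var_by_id = {v.variant_id: v for v in variants}
    usable = [c for c in counts
              if c.variant_id in var_by_id
              and not var_by_id[c.variant_id].hard_filtered
              and dgroup_model.rate_for_class(var_by_id[c.variant_id].tnc_alt) is not None]
    if n_subsample is not None and n_subsample < len(usable):
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(usable), size=n_subsample, replace=False)
        usable = [usable[i] for i in sorted(idx)]
    lam = sum(c.ddp * dgroup_model.rate_for_class(var_by_id[c.variant_id].tnc_alt)
              for c in usable)
    total_ddp = sum(c.ddp for c in usable)
    if total_ddp == 0:
        return float("nan")
    k_star = poisson_detection_threshold(lam, alpha)
    return k_star / total_ddp


def minimal_detectable_clonal_level(
    counts: Sequence[VariantCounts],
    variants: Sequence[TrackedVariant],
    dgroup_model: DGroupModel,
    alpha: float = 0.01,
) -> float:
    """MDCL = (k* - floor(lambda_panel)) / sum clonal DDP, where k* is the
    panel-wide minimal read count for a positive call.  All real mutant reads
    are conservatively assumed clonal."""
    var_by_id = {v.variant_id: v for v in variants}
    lam = 0.0
    for c in counts:
        v = var_by_id.get(c.variant_id)
        if v is None or v.hard_filtered:
            continue
        rate = dgroup_model.rate_for_class(v.tnc_alt)
        if rate is not None:
            lam += c.ddp * rate
    clonal_ids = {v.variant_id for v in variants if v.is_clonal and not v.hard_filtered}
    ddp_clonal = sum(c.ddp for c in counts if c.variant_id in clonal_ids)
    if ddp_clonal == 0:
        return float("nan")
    k_star = poisson_detection_threshold(lam, alpha)
    return max(0, k_star - math.floor(lam)) / ddp_clonal


# ---------------------------------------------------------------------------
# shedding regression
# ---------------------------------------------------------------------------


@dataclass
class SheddingModel:
    """OLS of log10 clonal ctDNA level on log10 tumour volume and histology."""

    result: object
    histology_levels: tuple[str, str] = ("adeno", "squamous_other")

    @property
    def params(self) -> pd.Series:
        return self.result.params


def fit_shedding_model(cohort_table: pd.DataFrame) -> SheddingModel:
    """Fit the shedding regression on ctDNA-positive cases.

    ``cohort_table`` columns: ``log10_volume``, ``histology`` (one of
    ``adeno``/``squamous_other``), ``log10_level``.
    """
    df = cohort_table.copy()
    levels = sorted(df["histology"].unique())
    bad = set(levels) - {"adeno", "squamous_other"}
    if bad:
        raise ValueError(f"unknown histology value(s): {sorted(bad)}")
    if len(levels) < 2:
        raise ValueError("need both histology groups to estimate the histology coefficient")
    counts = df["histology"].value_counts()
    if (counts < 3).any():
        raise ValueError("need at least 3 cases per histology group")
    X = sm.add_constant(pd.DataFrame({
        "log10_volume": df["log10_volume"].astype(float),
        "histology_squamous_other": (df["histology"] == "squamous_other").astype(float),
    }))
    result = sm.OLS(df["log10_level"].astype(float), X).fit()
    return SheddingModel(result)


def classify_shedding(
    fit: SheddingModel,
    volume: float,
    histology: str,
    mdcl: float,
    patient_id: str = "",
    confidence: float = 0.95,
) -> SheddingCall:
    """Classify a ctDNA-negative tumour as probable biological low-shedder or
    probable technical negative.

    The lower bound of the 95% prediction interval (new observation) for the
    predicted clonal ctDNA level is compared with the library's MDCL; a bound
    at or above MDCL means detection was expected (low-shedder), below means
    the library could not have seen it (technical negative).
    """
    if volume is None or (isinstance(volume, float) and math.isnan(volume)):
        raise ValueError("tumour volume required for shedding classification")
    X = pd.DataFrame({
        "const": [1.0],
        "log10_volume": [math.log10(volume)],
        "histology_squamous_other": [1.0 if histology == "squamous_other" else 0.0],
    })
    pred = fit.result.get_prediction(X)
    frame = pred.summary_frame(alpha=1 - confidence)
    lo, hi = float(frame["obs_ci_lower"].iloc[0]), float(frame["obs_ci_upper"].iloc[0])
    mean = float(frame["mean"].iloc[0])
    category = "low_shedder" if 10.0 ** lo >= mdcl else "technical_negative"
    return SheddingCall(patient_id, mean, lo, hi, mdcl, category)
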