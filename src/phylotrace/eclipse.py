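"""Copy-number-aware subclonal deconvolution for low tumour-fraction cfDNA.

The procedure runs in ten steps per plasma sample: (1) denoise VAFs by
subtracting grouped background-error expectations, (2) estimate ctDNA tumour
purity from clonal mutations, (3) convert VAFs to cancer cell fractions
(CCFs) per mutation and per clone, (4) flag clones with incoherent CCF
distributions, (5, 6) call clone and whole-tumour presence with summed
one-sided Poisson tests, (7, 8, 9) derive minimal detectable CCFs and purity,
and (10) test each subclone for a complete clonal sweep.

The forward model tying everything together is

    VAF = P * m * CCF / (P * CNt + (1 - P) * CNn)

with P the ctDNA tumour purity, m the mutation multiplicity, and CNt/CNn the
total tumour/normal copy number at the locus.  Step 2 solves it for P at
CCF = 1 (clonal mutations); step 3 solves it for CCF.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans

from .core_io import SampleManifest, TrackedVariant, VariantCounts
from .mrd import poisson_detection_threshold, poisson_upper_tail

__all__ = [
    "DenoisedVariant",
    "CloneEstimate",
    "SampleEstimate",
    "denoise_vafs",
    "estimate_tumour_purity",
    "compute_ccfs",
    "flag_poor_quality_clones",
    "calibrate_ccf_sd_threshold",
    "call_clone_presence",
    "call_tumour_presence",
    "min_detectable_ccf",
    "representative_min_ccf",
    "min_detectable_purity",
    "test_clonal_sweep",
    "naive_vaf_ccf",
    "expected_vaf",
    "purity_from_vaf",
    "ccf_from_vaf",
    "run_eclipse_sample",
]


# ---------------------------------------------------------------------------
# forward model and its inversions
# ---------------------------------------------------------------------------


def expected_vaf(purity: float, m: float, ccf: float,
                 cn_tumour: float, cn_normal: float = 2.0) -> float:
    """Forward model: expected VAF of a mutation at the given CCF and purity."""
    denom = purity * cn_tumour + (1.0 - purity) * cn_normal
    return purity * m * ccf / denom


def purity_from_vaf(vaf: float, m: float, cn_tumour: float, cn_normal: float = 2.0) -> float:
    """Invert the forward model for purity at CCF = 1 (clonal mutation)."""
    vaf = max(0.0, vaf)
    denom = m - vaf * (cn_tumour - cn_normal)
    if denom <= 0:
        return 1.0
    return vaf * cn_normal / denom


def ccf_from_vaf(vaf: float, purity: float, m: float,
                 cn_tumour: float, cn_normal: float = 2.0) -> float:
    """Invert the forward model for CCF at known purity (uncapped)."""
    if purity <= 0:
        return float("nan")
    vaf = max(0.0, vaf)
    return vaf * (purity * cn_tumour + (1.0 - purity) * cn_normal) / (purity * m)


# ---------------------------------------------------------------------------
# records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DenoisedVariant:
    variant_id: str
    sample_id: str
    denoised_vaf: float  # may be negative; clamped only inside formulas
    error_group: int
    expected_error_reads: float
    dao: int
    ddp: int


@dataclass
class CloneEstimate:
    clone_id: str
    sample_id: str
    ccf: float = float("nan")
    presence_p: float = float("nan")
    present: bool = False
    min_detectable_ccf: float = float("nan")
    sweep_p: float = float("nan")
    sweep: bool = False
    sweep_evaluable: bool = False
    poor_quality: bool = False
    normalised_sd: float = float("nan")
    n_mutations: int = 0
    is_clonal_cluster: bool = False


@dataclass
class SampleEstimate:
    sample_id: str
    ctdna_purity: float = float("nan")
    clonal_ctdna_level: float = float("nan")
    tumour_present_p: float = float("nan")
    tumour_present: bool = False
    minimal_detectable_purity: float = float("nan")
    representative_min_ccf: float = float("nan")
    input_ng: float = float("nan")
    high_subclone_sensitivity: bool = False


# ---------------------------------------------------------------------------
# step 1: VAF denoising
# ---------------------------------------------------------------------------


def denoise_vafs(
    clone_variants: Sequence[TrackedVariant],
    counts: Mapping[str, VariantCounts],
    per_variant_error: Mapping[str, float],
    max_groups: int = 4,
) -> list[DenoisedVariant]:
    """Denoise one clone's VAFs by grouped background subtraction.

    Variants are clustered (1-D k-means on expected error reads er x DDP)
    into g groups, g = min(max_groups, floor(total expected error reads)) but
    at least 1, so each group carries roughly >= 1 expected mutant read; a
    clone with total expected error below two reads keeps a single group.
    Each variant's denoised VAF is (DAO - group mean expected error) / DDP.
    """
    usable = [v for v in clone_variants
              if not v.hard_filtered and v.variant_id in counts]
    if not usable:
        return []
    err = np.array([
        per_variant_error.get(v.variant_id, 0.0) * counts[v.variant_id].ddp
        for v in usable
    ])
    total = float(err.sum())
    g = int(min(max_groups, max(1, math.floor(total))))
    g = min(g, len(np.unique(err)))
    if g <= 1:
        labels = np.zeros(len(usable), dtype=int)
    else:
        # deterministic init at evenly spaced quantiles of the 1-D feature
        qs = np.quantile(err, np.linspace(0, 1, 2 * g + 1)[1::2])
        km = KMeans(n_clusters=g, init=qs.reshape(-1, 1), n_init=1, random_state=0)
        labels = km.fit_predict(err.reshape(-1, 1))
    out = []
    for v, lab, e in zip(usable, labels, err):
        c = counts[v.variant_id]
        group_mean = float(err[labels == lab].mean())
        vaf = (c.dao - group_mean) / c.ddp if c.ddp > 0 else float("nan")
        out.append(DenoisedVariant(v.variant_id, c.sample_id, vaf, int(lab),
                                   float(e), c.dao, c.ddp))
    return out


# ---------------------------------------------------------------------------
# step 2: ctDNA tumour purity
# ---------------------------------------------------------------------------


def estimate_tumour_purity(
    clonal_denoised: Sequence[DenoisedVariant],
    variants: Mapping[str, TrackedVariant],
) -> float:
    """Mean per-clonal-mutation purity estimate, clamped to [0, 1].

    Each clonal mutation gives P_i = VAF * CNn / (m - VAF * (CNt - CNn));
    negative denoised VAFs enter as zero.  NaN when no clonal mutation is
    evaluable (no depth or missing copy-number annotation).
    """
    vals = []
    for d in clonal_denoised:
        v = variants[d.variant_id]
        if not v.has_cn_annotation or d.ddp == 0 or math.isnan(d.denoised_vaf):
            continue
        vals.append(purity_from_vaf(d.denoised_vaf, v.multiplicity, v.cn_tumour, v.cn_normal))
    if not vals:
        return float("nan")
    return float(np.clip(np.mean(vals), 0.0, 1.0))


# ---------------------------------------------------------------------------
# step 3: CCFs per mutation and clone
# ---------------------------------------------------------------------------


def compute_ccfs(
    denoised: Sequence[DenoisedVariant],
    variants: Mapping[str, TrackedVariant],
    purity: float,
    cap: float = 1.0,
) -> pd.DataFrame:
    """Per-mutation CCFs (capped at 1) for one sample.

    Returns a DataFrame with columns ``variant_id, clone_id, ccf, raw_ccf``;
    the raw (uncapped) value is retained for diagnostics.  Empty when
    purity <= 0 or undefined.
    """
    rows = []
    if purity is None or purity <= 0 or math.isnan(purity):
        return pd.DataFrame(columns=["variant_id", "clone_id", "ccf", "raw_ccf"])
    for d in denoised:
        v = variants[d.variant_id]
        if not v.has_cn_annotation or d.ddp == 0 or math.isnan(d.denoised_vaf):
            continue
        raw = ccf_from_vaf(d.denoised_vaf, purity, v.multiplicity, v.cn_tumour, v.cn_normal)
        rows.append({"variant_id": d.variant_id, "clone_id": v.clone_id,
                     "ccf": min(cap, raw), "raw_ccf": raw})
    return pd.DataFrame(rows, columns=["variant_id", "clone_id", "ccf", "raw_ccf"])


# ---------------------------------------------------------------------------
# step 4: poor-quality clone flagging
# ---------------------------------------------------------------------------


def flag_poor_quality_clones(
    ccf_table: pd.DataFrame,
    threshold: float = 0.56,
) -> pd.DataFrame:
    """Flag clones whose per-mutation CCF spread is implausibly wide.

    The normalised SD (coefficient of variation, sample SD / mean of the
    per-mutation CCFs) is compared with ``threshold``; single-mutation clones
    and zero-mean clones are not flaggable.
    Returns columns ``clone_id, normalised_sd, poor_quality``.
    """
    rows = []
    for clone_id, grp in ccf_table.groupby("clone_id", sort=True):
        ccfs = grp["ccf"].to_numpy(dtype=float)
        if len(ccfs) < 2 or np.mean(ccfs) == 0:
            rows.append({"clone_id": clone_id, "normalised_sd": float("nan"),
                         "poor_quality": False})
            continue
        cv = float(np.std(ccfs, ddof=1) / np.mean(ccfs))
        rows.append({"clone_id": clone_id, "normalised_sd": cv,
                     "poor_quality": cv > threshold})
    return pd.DataFrame(rows, columns=["clone_id", "normalised_sd", "poor_quality"])


def calibrate_ccf_sd_threshold(
    clonal_cluster_cvs: Sequence[float],
    default: float = 0.56,
    quantile: float = 0.95,
    min_samples: int = 5,
) -> float:
    """Data-driven poor-quality threshold: the upper 95% bound of the
    normalised SDs observed for clonal clusters in high-purity (> 5%)
    samples, where clone composition is trusted.  Falls back to ``default``
    with a warning when fewer than ``min_samples`` qualifying values exist.
    """
    vals = np.asarray([v for v in clonal_cluster_cvs if not math.isnan(v)], dtype=float)
    if len(vals) < min_samples:
        warnings.warn(
            f"only {len(vals)} qualifying clonal clusters; keeping default threshold {default}",
            stacklevel=2,
        )
        return default
    return float(np.quantile(vals, quantile, method="higher"))


# ---------------------------------------------------------------------------
# steps 5-6: presence calls
# ---------------------------------------------------------------------------


def _sum_signal_and_error(
    variant_ids: Sequence[str],
    counts: Mapping[str, VariantCounts],
    per_variant_error: Mapping[str, float],
) -> tuple[int, float, int, int]:
    dao = ddp = n = 0
    lam = 0.0
    for vid in variant_ids:
        c = counts.get(vid)
        if c is None:
            continue
        dao += c.dao
        ddp += c.ddp
        lam += c.ddp * per_variant_error.get(vid, 0.0)
        n += 1
    return dao, lam, ddp, n


def _presence_variants(variants: Sequence[TrackedVariant]) -> list[str]:
    return [v.variant_id for v in variants if not v.hard_filtered and not v.mid_filtered]


def call_clone_presence(
    clone_variants: Sequence[TrackedVariant],
    counts: Mapping[str, VariantCounts],
    per_variant_error: Mapping[str, float],
    alpha: float = 0.01,
) -> tuple[float, bool]:
    """One-sided Poisson test of a clone's summed signal against its summed
    expected background (hard- and mid-filtered variants excluded)."""
    ids = _presence_variants(clone_variants)
    dao, lam, ddp, n = _sum_signal_and_error(ids, counts, per_variant_error)
    if n == 0 or ddp == 0:
        return float("nan"), False
    p = poisson_upper_tail(dao, lam)
    return p, p < alpha


def call_tumour_presence(
    all_variants: Sequence[TrackedVariant],
    counts: Mapping[str, VariantCounts],
    per_variant_error: Mapping[str, float],
    alpha: float = 0.01,
) -> tuple[float, bool]:
    """Whole-panel presence call; identical test to clone presence."""
    return call_clone_presence(all_variants, counts, per_variant_error, alpha)


# ---------------------------------------------------------------------------
# steps 7-9: detection limits
# ---------------------------------------------------------------------------


def _mean_annotation(variants: Sequence[TrackedVariant]) -> tuple[float, float, float]:
    ms = [v.multiplicity for v in variants if v.has_cn_annotation]
    cnts = [v.cn_tumour for v in variants if v.has_cn_annotation]
    cnns = [v.cn_normal for v in variants if v.has_cn_annotation]
    if not ms:
        return float("nan"), float("nan"), 2.0
    return float(np.mean(ms)), float(np.mean(cnts)), float(np.mean(cnns))


def min_detectable_ccf(
    clone_variants: Sequence[TrackedVariant],
    counts: Mapping[str, VariantCounts],
    per_variant_error: Mapping[str, float],
    purity: float,
    alpha: float = 0.01,
) -> float:
    """Smallest CCF of this clone that would yield a positive presence call.

    k* mutant reads are required across the clone (Poisson threshold on the
    summed background lambda); the equivalent per-mutation VAF is k* spread
    over the clone's total depth, converted to CCF with the clone-average
    multiplicity and copy number at the sample's purity.
    """
    if purity is None or purity <= 0 or math.isnan(purity):
        return float("nan")
    ids = _presence_variants(clone_variants)
    dao, lam, ddp, n = _sum_signal_and_error(ids, counts, per_variant_error)
    if n == 0 or ddp == 0:
        return float("nan")
    k_star = poisson_detection_threshold(lam, alpha)
    vaf_min = k_star / ddp
    m, cnt, cnn = _mean_annotation([v for v in clone_variants if v.variant_id in ids])
    if math.isnan(m):
        return float("nan")
    return ccf_from_vaf(vaf_min, purity, m, cnt, cnn)


def representative_min_ccf(
    variants: Sequence[TrackedVariant],
    counts: Mapping[str, VariantCounts],
    per_variant_error: Mapping[str, float],
    purity: float,
    n_mut: int = 4,
    alpha: float = 0.01,
) -> float:
    """Minimal detectable CCF for a hypothetical subclone of ``n_mut``
    mutations carrying the sample-average subclonal error and depth; a single
    comparable sensitivity figure per sample."""
    if purity is None or purity <= 0 or math.isnan(purity):
        return float("nan")
    sub = [v for v in variants
           if not v.is_clonal and not v.hard_filtered and not v.mid_filtered
           and v.variant_id in counts and counts[v.variant_id].ddp > 0]
    if not sub:
        return float("nan")
    mean_err = float(np.mean([
        per_variant_error.get(v.variant_id, 0.0) * counts[v.variant_id].ddp for v in sub
    ]))
    mean_ddp = float(np.mean([counts[v.variant_id].ddp for v in sub]))
    lam = n_mut * mean_err
    k_star = poisson_detection_threshold(lam, alpha)
    vaf_min = k_star / (n_mut * mean_ddp)
    m, cnt, cnn = _mean_annotation(sub)
    if math.isnan(m):
        return float("nan")
    return ccf_from_vaf(vaf_min, purity, m, cnt, cnn)


def min_detectable_purity(
    variants: Sequence[TrackedVariant],
    counts: Mapping[str, VariantCounts],
    per_variant_error: Mapping[str, float],
    alpha: float = 0.01,
) -> float:
    """Purity equivalent to the minimal panel-wide read count for a positive
    tumour-presence call, via the clonal (CCF = 1) inversion with the
    panel-average multiplicity and copy number."""
    ids = _presence_variants(variants)
    dao, lam, ddp, n = _sum_signal_and_error(ids, counts, per_variant_error)
    if n == 0 or ddp == 0:
        return float("nan")
    k_star = poisson_detection_threshold(lam, alpha)
    vaf_min = k_star / ddp
    m, cnt, cnn = _mean_annotation([v for v in variants if v.variant_id in set(ids)])
    if math.isnan(m):
        return float("nan")
    return purity_from_vaf(vaf_min, m, cnt, cnn)


# ---------------------------------------------------------------------------
# step 10: clonal sweeps
# ---------------------------------------------------------------------------


def test_clonal_sweep(
    clone_ccfs: Sequence[float],
    clonal_ccfs: Sequence[float],
    p_threshold: float = 0.05,
    ccf_threshold: float = 0.90,
    alternative: str = "less",
) -> tuple[float, bool, bool]:
    """Test whether a subclone is indistinguishable from 100% CCF.

    A Wilcoxon rank-sum test compares the subclone's per-mutation CCFs with
    the clonal cluster's (one-sided, subclone below clonal, by default).  A
    sweep is called when the test cannot place the subclone below the clonal
    CCFs (p > ``p_threshold``) and the mean subclone CCF is at least
    ``ccf_threshold``.  Returns (p, sweep, evaluable); fewer than two CCFs on
    either side is not evaluable.
    """
    a = np.asarray(clone_ccfs, dtype=float)
    b = np.asarray(clonal_ccfs, dtype=float)
    if len(a) < 2 or len(b) < 2:
        return float("nan"), False, False
    if np.array_equal(a, b) or (np.all(a == a[0]) and np.all(b == a[0])):
        p = 1.0
    else:
        p = float(stats.mannwhitneyu(a, b, alternative=alternative).pvalue)
    sweep = (p > p_threshold) and (float(np.mean(a)) >= ccf_threshold)
    return p, sweep, True


def naive_vaf_ccf(subclone_vafs: Sequence[float], clonal_vafs: Sequence[float]) -> float:
    """Copy-number-unaware comparator: mean subclonal VAF / mean clonal VAF."""
    clonal_mean = float(np.mean(clonal_vafs))
    if clonal_mean == 0:
        return float("nan")
    return float(np.mean(subclone_vafs)) / clonal_mean


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def run_eclipse_sample(
    variants: Sequence[TrackedVariant],
    counts: Sequence[VariantCounts],
    per_variant_error: Mapping[str, float],
    alpha: float = 0.01,
    sd_threshold: float = 0.56,
    sweep_p: float = 0.05,
    sweep_ccf: float = 0.90,
    representative_n_mut: int = 4,
    high_sens_level: float = 0.001,
    high_sens_ng: float = 10.0,
    input_ng: float = float("nan"),
) -> tuple[SampleEstimate, list[CloneEstimate], pd.DataFrame]:
    """Run the full ten-step procedure for one plasma sample.

    Returns the sample-level estimate, per-clone estimates, and the
    per-mutation CCF table.
    """
    sample_ids = {c.sample_id for c in counts}
    if len(sample_ids) != 1:
        raise ValueError("counts must belong to a single sample")
    sample_id = sample_ids.pop()
    count_by_id = {c.variant_id: c for c in counts}
    var_by_id = {v.variant_id: v for v in variants}

    by_clone: dict[str, list[TrackedVariant]] = {}
    for v in variants:
        by_clone.setdefault(v.clone_id, []).append(v)

    # step 1 per clone
    denoised: list[DenoisedVariant] = []
    for clone_id in sorted(by_clone):
        denoised.extend(denoise_vafs(by_clone[clone_id], count_by_id, per_variant_error))
    den_by_id = {d.variant_id: d for d in denoised}

    # step 2
    clonal_denoised = [d for d in denoised if var_by_id[d.variant_id].is_clonal]
    purity = estimate_tumour_purity(clonal_denoised, var_by_id)

    # clonal ctDNA level (for the sensitivity tier)
    clonal_ids = [v.variant_id for v in variants
                  if v.is_clonal and not v.hard_filtered and v.variant_id in count_by_id]
    dao_c = sum(count_by_id[i].dao for i in clonal_ids)
    ddp_c = sum(count_by_id[i].ddp for i in clonal_ids)
    err_c = sum(count_by_id[i].ddp * per_variant_error.get(i, 0.0) for i in clonal_ids)
    clonal_level = (max(0.0, (dao_c - math.floor(err_c)) / ddp_c)
                    if ddp_c > 0 else float("nan"))

    # step 3
    ccf_table = compute_ccfs(denoised, var_by_id, purity)

    # step 4
    quality = flag_poor_quality_clones(ccf_table, sd_threshold)
    quality_by_clone = {r.clone_id: r for r in quality.itertuples(index=False)}

    # steps 5 and 10 per clone; 6-9 per sample
    clonal_ccfs = (ccf_table[ccf_table["variant_id"].isin(set(clonal_ids))]["ccf"]
                   .to_numpy(dtype=float))
    clones: list[CloneEstimate] = []
    for clone_id in sorted(by_clone):
        cv = by_clone[clone_id]
        est = CloneEstimate(clone_id, sample_id)
        est.is_clonal_cluster = all(v.is_clonal for v in cv)
        est.n_mutations = sum(1 for v in cv if not v.hard_filtered and v.variant_id in count_by_id)
        est.presence_p, est.present = call_clone_presence(
            cv, count_by_id, per_variant_error, alpha)
        clone_ccf_rows = ccf_table[ccf_table["clone_id"] == clone_id]
        if not clone_ccf_rows.empty:
            est.ccf = float(clone_ccf_rows["ccf"].mean())
        q = quality_by_clone.get(clone_id)
        if q is not None:
            est.normalised_sd = q.normalised_sd
            est.poor_quality = bool(q.poor_quality)
        est.min_detectable_ccf = min_detectable_ccf(
            cv, count_by_id, per_variant_error, purity, alpha)
        if not est.is_clonal_cluster:
            est.sweep_p, est.sweep, est.sweep_evaluable = test_clonal_sweep(
                clone_ccf_rows["ccf"].to_numpy(dtype=float), clonal_ccfs,
                p_threshold=sweep_p, ccf_threshold=sweep_ccf)
        clones.append(est)

    sample = SampleEstimate(sample_id)
    sample.ctdna_purity = purity
    sample.clonal_ctdna_level = clonal_level
    sample.tumour_present_p, sample.tumour_present = call_tumour_presence(
        variants, count_by_id, per_variant_error, alpha)
    sample.minimal_detectable_purity = min_detectable_purity(
        variants, count_by_id, per_variant_error, alpha)
    sample.representative_min_ccf = representative_min_ccf(
        variants, count_by_id, per_variant_error, purity,
        n_mut=representative_n_mut, alpha=alpha)
    sample.input_ng = input_ng
    sample.high_subclone_sensitivity = bool(
        not math.isnan(clonal_level) and clonal_level >= high_sens_level
        and not math.isnan(input_ng) and input_ng >= high_sens_ng
    )
    return sample, clones, ccf_table
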