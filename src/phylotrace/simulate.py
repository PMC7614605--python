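"""Synthetic sequencing-library generator.

Emulates UMI-consensus count data from a tumour-informed targeted cfDNA
panel: a clone phylogeny with nested cancer cell fractions, per-mutation
multiplicity and copy number (including whole-genome-doubled clonal
mutations), a 96-class trinucleotide-context error profile, molecule
sampling at DNA-input-limited depth, and background counts over the panel's
non-variant region of interest.  Every generator is a pure function of
(config, seed).

Depth model: 1 ng of human DNA contains about 303 haploid genome copies
(3.3 pg per haploid genome), so a library from ``input_ng`` nanograms at
conversion efficiency ``e`` yields on average ``input_ng * 303 * e``
consensus molecules per locus; per-variant deep depth is drawn Poisson
around that value (optionally capped).  Mutant reads are Binomial(depth,
expected VAF + class error).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (BackgroundCounts, CloneTree, TrackedVariant,
                      VariantCounts, collapse_context)
from .eclipse import expected_vaf, purity_from_vaf

__all__ = [
    "GENOMES_PER_NG",
    "SimulationConfig",
    "GroundTruth",
    "all_96_classes",
    "simulate_error_profile",
    "simulate_tree",
    "simulate_panel_variants",
    "simulate_plasma_sample",
    "simulate_patient",
    "simulate_spikein_bench",
    "simulate_mock_panels",
    "purity_for_clonal_level",
    "bench_mrd_sensitivity",
    "bench_mrd_specificity",
    "bench_clone_presence_specificity",
    "bench_subclone_detection_sensitivity",
    "bench_ccf_recovery",
]

GENOMES_PER_NG = 303.0  # haploid genome copies per ng (3.3 pg / haploid genome)

_BASES = "ACGT"
_TRANSITIONS = {("C", "T"), ("T", "C"), ("A", "G"), ("G", "A")}


def all_96_classes() -> list[str]:
    """The 96 reverse-complement-collapsed trinucleotide substitution classes."""
    keys = set()
    for l, ref, r in itertools.product(_BASES, _BASES, _BASES):
        for alt in _BASES:
            if alt == ref:
                continue
            keys.add(collapse_context(f"{l}{ref}{r}", alt))
    assert len(keys) == 96
    return sorted(keys)


@dataclass
class SimulationConfig:
    """Study-condition parameters of the generator.

    Defaults reproduce the conditions of the assay being emulated: ~50-200
    tracked mutations per panel, per-variant consensus depth set by DNA input
    (median input ~23 ng) at conversion efficiency 0.6, a log-normal 96-class
    error profile with median 1e-5 and transitions elevated ~5x over
    transversions, and a quarter of clonal mutations carried at multiplicity
    2 on whole-genome-doubled backgrounds.
    """

    seed: int = 0
    n_clones: int = 5
    n_clonal_mutations: int = 126
    n_mutations_per_subclone: int = 4
    input_ng: float = 23.0
    conversion_efficiency: float = 0.6
    depth_cap: int | None = None
    error_median: float = 1e-5
    error_sigma: float = 0.8
    transition_factor: float = 5.0
    wgd_fraction: float = 0.25
    background_positions_per_class: int = 300
    metastasis_unique_fraction: float = 0.0


@dataclass
class GroundTruth:
    tree: CloneTree
    clone_ccf: dict[str, float]
    purity: float
    variant_vaf: dict[str, float]
    clonal_level: float = float("nan")


def simulate_error_profile(rng: np.random.Generator,
                           median: float = 1e-5,
                           sigma: float = 0.8,
                           transition_factor: float = 5.0) -> dict[str, float]:
    """Log-normal error rates across the 96 classes; transition classes are
    multiplied by ``transition_factor``."""
    out = {}
    for cls in all_96_classes():
        ctx, _, alt = cls.partition(">")
        base = math.exp(rng.normal(math.log(median), sigma))
        if (ctx[1], alt) in _TRANSITIONS:
            base *= transition_factor
        out[cls] = min(base, 0.5)
    return out


def purity_for_clonal_level(level: float, m: float = 1.0,
                            cn_tumour: float = 2.0, cn_normal: float = 2.0) -> float:
    """Purity at which the mean clonal VAF equals the requested clonal ctDNA
    level (inverse of the forward model at CCF = 1)."""
    return purity_from_vaf(level, m, cn_tumour, cn_normal)


# ---------------------------------------------------------------------------
# phylogeny with nested CCFs
# ---------------------------------------------------------------------------


def simulate_tree(
    rng: np.random.Generator,
    n_clones: int,
    min_subclone_ccf: float = 0.05,
    metastasis_unique_fraction: float = 0.0,
) -> tuple[CloneTree, dict[str, float]]:
    """Random rooted clone tree with stick-breaking CCFs.

    The root (clonal cluster) sits at CCF 1; every parent's children receive
    Dirichlet-partitioned fractions of the parent's CCF, so parent >= sum of
    children by construction.  A configurable fraction of subclones is
    flagged metastasis-unique (not part of the primary tumour).
    """
    if n_clones < 1:
        raise ValueError("n_clones must be >= 1")
    names = ["clonal"] + [f"clone_{chr(ord('a') + i)}" if i < 26 else f"clone_{i}"
                          for i in range(n_clones - 1)]
    parent: dict[str, str | None] = {names[0]: None}
    for i in range(1, n_clones):
        parent[names[i]] = names[int(rng.integers(i))]
    tree_children: dict[str, list[str]] = {n: [] for n in names}
    for c, p in parent.items():
        if p is not None:
            tree_children[p].append(c)
    ccf: dict[str, float] = {names[0]: 1.0}
    for node in names:  # construction order is parent-before-child
        kids = tree_children[node]
        if not kids:
            continue
        fracs = rng.dirichlet(np.ones(len(kids) + 1))[:-1]
        for k, f in zip(kids, fracs):
            ccf[k] = max(min_subclone_ccf, float(ccf[node] * f))
        # re-scale if the floor pushed the children above the parent
        total = sum(ccf[k] for k in kids)
        if total > ccf[node]:
            for k in kids:
                ccf[k] *= ccf[node] / total
    primary = {n: True for n in names}
    subclones = names[1:]
    n_met = int(round(metastasis_unique_fraction * len(subclones)))
    if n_met:
        # metastasis-unique clones are drawn among the leaves
        leaves = [n for n in subclones if not tree_children[n]]
        for n in rng.choice(leaves, size=min(n_met, len(leaves)), replace=False):
            primary[str(n)] = False
    return CloneTree(parent, primary), ccf


# ---------------------------------------------------------------------------
# panel construction
# ---------------------------------------------------------------------------


def simulate_panel_variants(
    rng: np.random.Generator,
    tree: CloneTree,
    config: SimulationConfig,
    classes: Sequence[str] | None = None,
) -> list[TrackedVariant]:
    """Tracked-variant table for one patient: clonal mutations on the root
    cluster (a ``wgd_fraction`` of them at multiplicity 2 / CNt 4), and
    ``n_mutations_per_subclone`` diploid-multiplicity-1 mutations per
    subclone."""
    classes = list(classes) if classes is not None else all_96_classes()
    variants: list[TrackedVariant] = []
    counter = 0

    def make(clone_id: str, is_clonal: bool, m: float, cnt: float) -> TrackedVariant:
        nonlocal counter
        counter += 1
        cls = classes[int(rng.integers(len(classes)))]
        ctx, _, alt = cls.partition(">")
        return TrackedVariant(
            variant_id=f"v{counter:05d}", chrom=f"chr{1 + counter % 22}",
            pos=1_000_000 + counter, ref=ctx[1], alt=alt, tnc=ctx,
            clone_id=clone_id, is_clonal=is_clonal,
            multiplicity=m, cn_tumour=cnt, cn_normal=2.0,
        )

    for _ in range(config.n_clonal_mutations):
        if rng.random() < config.wgd_fraction:
            variants.append(make(tree.root, True, 2.0, 4.0))
        else:
            variants.append(make(tree.root, True, 1.0, 2.0))
    for clone in tree.topological_order():
        if clone == tree.root:
            continue
        for _ in range(config.n_mutations_per_subclone):
            variants.append(make(clone, False, 1.0, 2.0))
    return variants


# ---------------------------------------------------------------------------
# library sampling
# ---------------------------------------------------------------------------


def simulate_plasma_sample(
    rng: np.random.Generator,
    sample_id: str,
    variants: Sequence[TrackedVariant],
    truth: GroundTruth,
    error_profile: Mapping[str, float],
    config: SimulationConfig,
) -> tuple[list[VariantCounts], list[BackgroundCounts]]:
    """Draw one library's consensus counts from the forward model.

    Per-variant depth ~ Poisson(input_ng x 303 x efficiency), mutant reads
    ~ Binomial(depth, expected VAF + class error); background counts are
    Binomial over ``background_positions_per_class`` positions per class at
    comparable depth.
    """
    genomes = config.input_ng * GENOMES_PER_NG * config.conversion_efficiency
    counts: list[VariantCounts] = []
    for v in variants:
        ddp = int(rng.poisson(genomes))
        if config.depth_cap is not None:
            ddp = min(ddp, config.depth_cap)
        ccf = truth.clone_ccf.get(v.clone_id, 0.0)
        vaf = expected_vaf(truth.purity, v.multiplicity, ccf, v.cn_tumour, v.cn_normal)
        truth.variant_vaf[v.variant_id] = vaf
        er = error_profile.get(v.tnc_alt, 0.0)
        p = min(1.0, vaf + er)
        dao = int(rng.binomial(ddp, p)) if ddp > 0 else 0
        counts.append(VariantCounts(sample_id, v.variant_id, dao, ddp))
    background: list[BackgroundCounts] = []
    for cls in sorted(error_profile):
        ddp_total = int(rng.poisson(genomes * config.background_positions_per_class))
        dao_total = int(rng.binomial(ddp_total, min(1.0, error_profile[cls]))) if ddp_total else 0
        background.append(BackgroundCounts(sample_id, cls, dao_total, ddp_total))
    return counts, background


def simulate_patient(
    seed: int,
    config: SimulationConfig | None = None,
    purity: float | None = None,
    clonal_level: float | None = None,
    sample_id: str = "s1",
) -> tuple[list[TrackedVariant], list[VariantCounts], list[BackgroundCounts],
           dict[str, float], GroundTruth]:
    """One patient, one plasma sample, end to end.

    Returns (variants, counts, background, error_profile, truth).  The
    sample's purity may be given directly or via a target clonal ctDNA level
    (converted through the panel's mean clonal multiplicity/copy number).
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(seed)
    tree, ccf = simulate_tree(rng, config.n_clones,
                              metastasis_unique_fraction=config.metastasis_unique_fraction)
    variants = simulate_panel_variants(rng, tree, config)
    if purity is None:
        level = 0.001 if clonal_level is None else clonal_level
        clonal = [v for v in variants if v.is_clonal]
        m = float(np.mean([v.multiplicity for v in clonal]))
        cnt = float(np.mean([v.cn_tumour for v in clonal]))
        purity = purity_for_clonal_level(level, m, cnt)
    profile = simulate_error_profile(rng, config.error_median, config.error_sigma,
                                     config.transition_factor)
    truth = GroundTruth(tree=tree, clone_ccf=ccf, purity=purity, variant_vaf={})
    counts, background = simulate_plasma_sample(rng, sample_id, variants, truth,
                                                profile, config)
    clonal_ids = {v.variant_id for v in variants if v.is_clonal}
    dao = sum(c.dao for c in counts if c.variant_id in clonal_ids)
    ddp = sum(c.ddp for c in counts if c.variant_id in clonal_ids)
    truth.clonal_level = dao / ddp if ddp else float("nan")
    return variants, counts, background, profile, truth


# ---------------------------------------------------------------------------
# spike-in dilution bench
# ---------------------------------------------------------------------------


def simulate_spikein_bench(
    seed: int,
    allele_fractions: Sequence[float] = (0.0, 3e-5, 5e-5, 1e-4, 3e-4, 1e-3),
    inputs_ng: Sequence[float] = (2.0, 10.0, 20.0, 40.0, 80.0),
    panel_sizes: Sequence[int] = (50,),
    replicates: int = 12,
    conversion_efficiency: float = 0.6,
    error_median: float = 1e-5,
    error_sigma: float = 0.8,
) -> pd.DataFrame:
    """Dilution-series library grid mirroring contrived spike-in experiments.

    Variant DNA is "spiked" at target allele fraction into a clean
    background; every (AF, input, panel size) cell is replicated.  Returns a
    long table with one row per library: the truth label (target AF) plus the
    per-library panel counts and background class totals encoded as object
    columns, ready for the caller-sensitivity benches.  AF = 0 replicates
    form the specificity stream.
    """
    rng = np.random.default_rng(seed)
    classes = all_96_classes()
    rows = []
    lib = 0
    for af in allele_fractions:
        for ng in inputs_ng:
            for n_panel in panel_sizes:
                for rep in range(replicates):
                    lib += 1
                    profile = simulate_error_profile(rng, error_median, error_sigma)
                    genomes = ng * GENOMES_PER_NG * conversion_efficiency
                    cls_draw = [classes[int(i)] for i in rng.integers(len(classes), size=n_panel)]
                    ddp = rng.poisson(genomes, size=n_panel)
                    ers = np.array([profile[c] for c in cls_draw])
                    dao = rng.binomial(ddp, np.minimum(1.0, af + ers))
                    bg_ddp = rng.poisson(genomes * 300, size=len(classes))
                    bg_dao = rng.binomial(bg_ddp, [min(1.0, profile[c]) for c in classes])
                    rows.append({
                        "library_id": f"lib{lib:05d}", "target_af": af,
                        "input_ng": ng, "panel_size": n_panel, "replicate": rep,
                        "classes": cls_draw, "ddp": ddp, "dao": dao,
                        "bg_classes": classes, "bg_ddp": bg_ddp, "bg_dao": bg_dao,
                    })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# mock panels for specificity
# ---------------------------------------------------------------------------


def simulate_mock_panels(
    template: pd.DataFrame,
    position_pool: pd.DataFrame,
    n_panels: int,
    seed: int,
    max_depth_delta: float = 2000.0,
) -> list[pd.DataFrame]:
    """Build mock tumour signatures from a library's background positions.

    ``template`` (columns ``tnc_alt, ddp``) describes the true tracked
    variants; ``position_pool`` (columns ``pos_id, tnc_alt, ddp, dao,
    is_variant, is_population_snp``) the candidate background positions.  For
    each mock signature every template variant is replaced by an unused
    background position of the same error class whose depth differs by at
    most ``max_depth_delta``; positions are never reused across signatures
    and never overlap true variants or known polymorphisms.  Fewer signatures
    are returned (with a warning) when eligible positions run out.
    """
    import warnings

    rng = np.random.default_rng(seed)
    pool = position_pool[
        ~position_pool["is_variant"].astype(bool)
        & ~position_pool["is_population_snp"].astype(bool)
    ].copy()
    used: set = set()
    panels: list[pd.DataFrame] = []
    for _ in range(n_panels):
        chosen = []
        ok = True
        for t in template.itertuples(index=False):
            cand = pool[
                (pool["tnc_alt"] == t.tnc_alt)
                & ((pool["ddp"] - t.ddp).abs() <= max_depth_delta)
                & ~pool["pos_id"].isin(used)
            ]
            if cand.empty:
                ok = False
                break
            pick = cand.iloc[int(rng.integers(len(cand)))]
            used.add(pick["pos_id"])
            chosen.append(pick)
        if not ok:
            warnings.warn(
                f"eligible background positions exhausted after {len(panels)} mock panels",
                stacklevel=2,
            )
            break
        panels.append(pd.DataFrame(chosen).reset_index(drop=True))
    return panels


# ---------------------------------------------------------------------------
# benches: caller operating characteristics under known truth
# ---------------------------------------------------------------------------


def _mrd_call_on_library(rng: np.random.Generator, af: float, input_ng: float,
                         efficiency: float, panel_size: int,
                         error_median: float = 1e-5, error_sigma: float = 0.8,
                         alpha: float = 0.01,
                         background_positions_per_class: int = 300,
                         null_from_estimate: bool = False) -> bool:
    """Simulate one library and run the full calling pipeline on it:
    error-model estimation from its own background, quality filters, and the
    sample-level exact Poisson test.  Returns the MRD call.

    ``null_from_estimate`` draws the tracked-position counts from the
    library's own estimated class error rates (a correctly specified null,
    isolating the exact test's operating characteristics from estimation
    noise).
    """
    from .error_model import apply_quality_filters, build_d_groups, compute_tnc_error_rates
    from .mrd import call_sample_mrd

    classes = all_96_classes()
    profile = simulate_error_profile(rng, error_median, error_sigma)
    genomes = input_ng * GENOMES_PER_NG * efficiency

    bg_ddp = rng.poisson(genomes * background_positions_per_class, size=len(classes))
    bg_dao = rng.binomial(bg_ddp, [min(1.0, profile[c]) for c in classes])
    background = [BackgroundCounts("lib", c, int(a), int(d))
                  for c, a, d in zip(classes, bg_dao, bg_ddp)]
    rates = compute_tnc_error_rates(background)

    cls_draw = [classes[int(i)] for i in rng.integers(len(classes), size=panel_size)]
    ddp = rng.poisson(genomes, size=panel_size)
    if null_from_estimate:
        est = {t.tnc_alt: t.er for t in rates if t.usable}
        ers = np.array([est.get(c, 0.0) for c in cls_draw])
    else:
        ers = np.array([profile[c] for c in cls_draw])
    dao = rng.binomial(ddp, np.minimum(1.0, af + ers))

    variants = []
    counts = []
    for i, cls in enumerate(cls_draw):
        ctx, _, alt = cls.partition(">")
        variants.append(TrackedVariant(
            variant_id=f"v{i}", chrom="chr1", pos=1000 + i, ref=ctx[1], alt=alt,
            tnc=ctx, clone_id="clonal", is_clonal=True, multiplicity=1.0,
            cn_tumour=2.0))
        counts.append(VariantCounts("lib", f"v{i}", int(dao[i]), int(ddp[i])))

    report = apply_quality_filters(variants, counts, rates)
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model = build_d_groups(rates, variants)
        result = call_sample_mrd(counts, report, model, variants, alpha=alpha)
    return result.positive


def bench_mrd_sensitivity(seed: int, n_reps: int = 200, af: float = 1e-4,
                          input_ng: float = 20.0,
                          efficiencies: Sequence[float] = (0.5, 0.75, 1.0),
                          panel_size: int = 50, alpha: float = 0.01) -> dict[float, float]:
    """Sensitivity of the sample-level caller on spiked libraries, per
    conversion efficiency."""
    out = {}
    for j, eff in enumerate(efficiencies):
        rng = np.random.default_rng((seed + 1) * 1000 + j)
        hits = sum(_mrd_call_on_library(rng, af, input_ng, eff, panel_size, alpha=alpha)
                   for _ in range(n_reps))
        out[eff] = hits / n_reps
    return out


def bench_mrd_specificity(seed: int, n_reps: int = 1000, input_ng: float = 20.0,
                          efficiency: float = 0.6, panel_size: int = 50,
                          alpha: float = 0.01) -> float:
    """Empirical false-positive fraction on ctDNA-free libraries (the
    exact-test conservativeness check)."""
    rng = np.random.default_rng(seed)
    sizes = rng.integers(50, 201, size=n_reps)
    hits = sum(
        _mrd_call_on_library(rng, 0.0, input_ng, efficiency, int(n), alpha=alpha,
                             null_from_estimate=True)
        for n in sizes
    )
    return hits / n_reps


def bench_clone_presence_specificity(seed: int, n_reps: int = 1000,
                                     n_mut: int = 4, depth: float = 2000.0,
                                     error_median: float = 1e-5,
                                     error_sigma: float = 0.8,
                                     alpha: float = 0.01) -> float:
    """Empirical false-detection fraction of the summed presence test over
    simulated absent subclones (background-only signal)."""
    from .eclipse import call_clone_presence

    rng = np.random.default_rng(seed)
    classes = all_96_classes()
    hits = 0
    for _ in range(n_reps):
        profile = simulate_error_profile(rng, error_median, error_sigma)
        cls = [classes[int(i)] for i in rng.integers(len(classes), size=n_mut)]
        ddp = rng.poisson(depth, size=n_mut)
        ers = np.array([profile[c] for c in cls])
        dao = rng.binomial(ddp, np.minimum(1.0, ers))
        variants = []
        counts = {}
        err = {}
        for i, c in enumerate(cls):
            ctx, _, alt = c.partition(">")
            variants.append(TrackedVariant(
                variant_id=f"v{i}", chrom="chr1", pos=1000 + i, ref=ctx[1],
                alt=alt, tnc=ctx, clone_id="a", is_clonal=False,
                multiplicity=1.0, cn_tumour=2.0))
            counts[f"v{i}"] = VariantCounts("lib", f"v{i}", int(dao[i]), int(ddp[i]))
            err[f"v{i}"] = ers[i]
        _, present = call_clone_presence(variants, counts, err, alpha=alpha)
        hits += present
    return hits / n_reps


def bench_subclone_detection_sensitivity(seed: int, n_reps: int = 500,
                                         ccf: float = 0.2,
                                         clonal_level: float = 0.001,
                                         input_ng: float = 10.0,
                                         conversion_efficiency: float = 0.6,
                                         n_mut: int = 4,
                                         error_median: float = 1e-5,
                                         error_sigma: float = 0.8,
                                         alpha: float = 0.01) -> float:
    """Detection rate of a subclone of ``n_mut`` mutations at the given CCF
    and clonal ctDNA level, using the summed presence test with the true
    class error as background."""
    from .eclipse import call_clone_presence

    rng = np.random.default_rng(seed)
    classes = all_96_classes()
    purity = purity_for_clonal_level(clonal_level)
    vaf = expected_vaf(purity, 1.0, ccf, 2.0)
    genomes = input_ng * GENOMES_PER_NG * conversion_efficiency
    hits = 0
    for _ in range(n_reps):
        profile = simulate_error_profile(rng, error_median, error_sigma)
        cls = [classes[int(i)] for i in rng.integers(len(classes), size=n_mut)]
        ddp = rng.poisson(genomes, size=n_mut)
        ers = np.array([profile[c] for c in cls])
        dao = rng.binomial(ddp, np.minimum(1.0, vaf + ers))
        variants = []
        counts = {}
        err = {}
        for i, c in enumerate(cls):
            ctx, _, alt = c.partition(">")
            variants.append(TrackedVariant(
                variant_id=f"v{i}", chrom="chr1", pos=1000 + i, ref=ctx[1],
                alt=alt, tnc=ctx, clone_id="a", is_clonal=False,
                multiplicity=1.0, cn_tumour=2.0))
            counts[f"v{i}"] = VariantCounts("lib", f"v{i}", int(dao[i]), int(ddp[i]))
            err[f"v{i}"] = ers[i]
        _, present = call_clone_presence(variants, counts, err, alpha=alpha)
        hits += present
    return hits / n_reps


def bench_ccf_recovery(seed: int, n_patients: int = 70,
                       median_clonal_level: float = 0.009,
                       level_sigma: float = 0.6,
                       input_ng: float = 23.0,
                       conversion_efficiency: float = 0.32,
                       alpha: float = 0.01) -> pd.DataFrame:
    """Synthetic-cohort CCF recovery for the deconvolution.

    Each patient draws 3-8 clones, a clonal ctDNA level log-normal around the
    cohort median, and a library at realistic depth (~2,200x per variant at
    the default input and conversion); the per-variant error fed to the
    deconvolution is estimated from the library's own background.  Returns
    one row per detected subclone with estimated and true CCF.
    """
    from .error_model import compute_tnc_error_rates
    from .eclipse import run_eclipse_sample

    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        n_clones = int(rng.integers(3, 9))
        level = median_clonal_level * math.exp(rng.normal(0.0, level_sigma))
        cfg = SimulationConfig(
            seed=seed, n_clones=n_clones, input_ng=input_ng,
            conversion_efficiency=conversion_efficiency,
            n_mutations_per_subclone=int(rng.integers(3, 9)),
        )
        pseed = int(rng.integers(2**31))
        variants, counts, background, profile, truth = simulate_patient(
            pseed, cfg, clonal_level=level)
        rates = compute_tnc_error_rates(background)
        est_er = {t.tnc_alt: t.er for t in rates if t.usable}
        per_err = {v.variant_id: est_er.get(v.tnc_alt, 0.0) for v in variants}
        sample, clones, _ = run_eclipse_sample(variants, counts, per_err,
                                               alpha=alpha, input_ng=input_ng)
        for c in clones:
            if c.is_clonal_cluster or not c.present or math.isnan(c.ccf):
                continue
            rows.append({
                "patient": i, "clone_id": c.clone_id,
                "true_ccf": truth.clone_ccf[c.clone_id],
                "est_ccf": c.ccf,
                "clonal_level": truth.clonal_level,
                "purity_true": truth.purity,
                "purity_est": sample.ctdna_purity,
            })
    return pd.DataFrame(rows)
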