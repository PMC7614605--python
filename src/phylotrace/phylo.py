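"""Phylogeny-aware post-processing of per-clone plasma estimates.

Covers ancestral presence inference (an ancestor of a detected clone must be
present), parent/child CCF consistency, classification of metastatic
dissemination at relapse (monoclonal vs polyclonal, monophyletic vs
polyphyletic), the single-region "clonal illusion" reanalysis, and long-format
longitudinal trajectory tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import CloneTree, TrackedVariant, VariantCounts
from .eclipse import CloneEstimate, SampleEstimate, run_eclipse_sample

__all__ = [
    "DisseminationCall",
    "IllusionRecord",
    "infer_presence_with_ancestry",
    "enforce_ccf_nesting",
    "classify_from_flags",
    "classify_dissemination",
    "single_region_reanalysis",
    "rank_auc",
    "trajectory_table",
]


@dataclass(frozen=True)
class DisseminationCall:
    patient_id: str
    source: str  # tissue | cfDNA
    clonality: str  # monoclonal | polyclonal | unevaluable
    phyletic: str  # monophyletic | polyphyletic | not_applicable
    seeding_clones: tuple[str, ...] = ()


@dataclass(frozen=True)
class IllusionRecord:
    mutation_id: str
    selected_region: str
    region_clonal: bool
    truth_label: str  # clonal | clonal_illusion
    plasma_ccf: float


# ---------------------------------------------------------------------------
# ancestral presence
# ---------------------------------------------------------------------------


def infer_presence_with_ancestry(
    tree: CloneTree,
    detected: set[str] | Sequence[str],
) -> dict[str, str | None]:
    """Transitive-closure presence: every ancestor of a detected clone is
    present.  Returns clone -> 'detected' | 'inferred' | None."""
    detected = set(detected)
    out: dict[str, str | None] = {c: None for c in tree.parent}
    for c in detected:
        out[c] = "detected"
    for c in detected:
        for anc in tree.ancestors(c):
            if out[anc] is None:
                out[anc] = "inferred"
    return out


# ---------------------------------------------------------------------------
# CCF nesting
# ---------------------------------------------------------------------------


def enforce_ccf_nesting(
    tree: CloneTree,
    clone_ccfs: Mapping[str, float],
    mode: str = "paper",
) -> dict[str, float]:
    """Reconcile parent and child clone CCFs along the tree.

    mode='paper' caps a parent at the sum of its children's CCFs (parent :=
    min(parent, sum children)) whenever it has children with estimates;
    mode='pigeonhole' applies the standard nesting constraint instead,
    raising the parent to at least the sum of its children.  Children are
    processed before parents so adjustments propagate rootward.
    """
    if mode not in ("paper", "pigeonhole"):
        raise ValueError(f"unknown mode {mode!r}")
    adjusted = dict(clone_ccfs)
    for clone in reversed(tree.topological_order()):
        kids = [k for k in tree.children[clone] if k in adjusted]
        if not kids or clone not in adjusted:
            continue
        child_sum = sum(adjusted[k] for k in kids)
        if mode == "paper":
            adjusted[clone] = min(adjusted[clone], child_sum)
        else:
            adjusted[clone] = max(adjusted[clone], child_sum)
    return adjusted


# ---------------------------------------------------------------------------
# dissemination classification
# ---------------------------------------------------------------------------


def _is_chain(tree: CloneTree, clones: Sequence[str]) -> bool:
    """True when the clones are pairwise comparable under ancestry (all on
    one root-to-leaf path)."""
    cl = list(clones)
    for i in range(len(cl)):
        for j in range(i + 1, len(cl)):
            a, b = cl[i], cl[j]
            if not (tree.is_ancestor(a, b) or tree.is_ancestor(b, a)):
                return False
    return True


def classify_from_flags(
    tree: CloneTree,
    detected: set[str] | Sequence[str],
    below_100: set[str] | Sequence[str],
    patient_id: str = "",
    source: str = "cfDNA",
) -> DisseminationCall:
    """Classify metastatic dissemination from per-clone flags.

    ``detected`` are the primary-tumour subclones present in the relapse
    sample; ``below_100`` those whose CCF distribution is significantly below
    100%.  Monoclonal: the detected clones form a single root-to-leaf chain
    and none is below 100% (one expanding lineage explains them all).
    Otherwise polyclonal; monophyletic when the seeding clones still lie on
    one chain, polyphyletic when they span branches.
    """
    detected = set(detected)
    below = set(below_100) & detected
    if not detected:
        return DisseminationCall(patient_id, source, "unevaluable", "not_applicable")
    chain = _is_chain(tree, sorted(detected))
    if chain and not below:
        deepest = max(detected, key=lambda c: (tree.depth(c), c))
        return DisseminationCall(patient_id, source, "monoclonal", "not_applicable",
                                 (deepest,))
    # polyclonal: seeding set = detected-subtree leaves, plus every below-100%
    # clone, plus (for each below-100% clone) the lineage that carries the
    # remaining cells — its nearest detected proper ancestor, or the trunk
    seeding: set[str] = set()
    for c in detected:
        if not any(d in detected for d in tree.descendants(c)):
            seeding.add(c)
    for c in below:
        seeding.add(c)
        anc = next((a for a in tree.ancestors(c) if a in detected), None)
        seeding.add(anc if anc is not None else tree.root)
    phyletic = "monophyletic" if _is_chain(tree, sorted(seeding)) else "polyphyletic"
    return DisseminationCall(patient_id, source, "polyclonal", phyletic,
                             tuple(sorted(seeding)))


def classify_dissemination(
    tree: CloneTree,
    clone_estimates: Sequence[CloneEstimate],
    patient_id: str = "",
    source: str = "cfDNA",
    p_threshold: float = 0.05,
    ccf_threshold: float = 0.90,
) -> DisseminationCall:
    """Classify dissemination from one relapse sample's clone estimates.

    Only primary-tumour subclones are considered; metastasis-unique clones
    (seeded into surgically excised lymph nodes / intrapulmonary metastases),
    poor-quality clones and the clonal cluster itself are excluded.  A
    detected clone counts as below 100% CCF when its rank-sum p-value against
    the clonal cluster is < ``p_threshold`` and its mean CCF is below
    ``ccf_threshold``.
    """
    detected: set[str] = set()
    below: set[str] = set()
    for est in clone_estimates:
        if est.is_clonal_cluster or est.poor_quality:
            continue
        if not tree.primary_tumour.get(est.clone_id, True):
            continue
        if not est.present:
            continue
        detected.add(est.clone_id)
        if (est.sweep_evaluable and not math.isnan(est.sweep_p)
                and est.sweep_p < p_threshold and est.ccf < ccf_threshold):
            below.add(est.clone_id)
    return classify_from_flags(tree, detected, below, patient_id, source)


# ---------------------------------------------------------------------------
# clonal illusion
# ---------------------------------------------------------------------------


def rank_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """Rank-based AUC (mid-rank ties): probability a positive outranks a
    negative."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    order = pd.Series(s).rank(method="average").to_numpy()
    return float((order[y].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def single_region_reanalysis(
    region_ccfs: pd.DataFrame,
    variants: Sequence[TrackedVariant],
    counts: Sequence[VariantCounts],
    per_variant_error: Mapping[str, float],
    seed: int,
    region_annotations: Mapping[str, pd.DataFrame] | None = None,
    clonal_ccf: float = 0.90,
) -> tuple[list[IllusionRecord], dict]:
    """Re-analyse a patient as if only a single tissue region had been biopsied.

    ``region_ccfs``: per-mutation tissue CCFs, index = variant_id, one column
    per region.  One region is drawn uniformly (seeded); mutations are
    re-labelled clonal iff their CCF in that region exceeds ``clonal_ccf``,
    optional ``region_annotations[region]`` (columns ``variant_id,
    multiplicity, cn_tumour``) replace the multi-region annotation, and the
    deconvolution is re-run with mutation-specific CCFs only.  Mutations
    clonal in the selected region are labelled ``clonal`` when clonal in every
    region and ``clonal_illusion`` otherwise; the plasma CCF serves as the
    score separating the two.

    Returns the per-mutation records and a summary with the rank AUC and a
    stratified-bootstrap 95% CI (500 resamples).
    """
    regions = list(region_ccfs.columns)
    if len(regions) < 2:
        return [], {"auc": float("nan"), "n": 0, "skipped": "single-region tumour"}
    rng = np.random.default_rng(seed)
    region = regions[int(rng.integers(len(regions)))]

    ann: dict[str, tuple[float, float]] = {}
    if region_annotations and region in region_annotations:
        for r in region_annotations[region].itertuples(index=False):
            ann[r.variant_id] = (float(r.multiplicity), float(r.cn_tumour))

    relabelled: list[TrackedVariant] = []
    for v in variants:
        if v.variant_id not in region_ccfs.index:
            continue
        r_ccf = float(region_ccfs.loc[v.variant_id, region])
        is_clonal = r_ccf > clonal_ccf
        m, cnt = ann.get(v.variant_id, (v.multiplicity, v.cn_tumour))
        relabelled.append(
            TrackedVariant(
                variant_id=v.variant_id, chrom=v.chrom, pos=v.pos, ref=v.ref,
                alt=v.alt, tnc=v.tnc,
                clone_id="region_clonal" if is_clonal else "region_subclonal",
                is_clonal=is_clonal, multiplicity=m, cn_tumour=cnt,
                cn_normal=v.cn_normal, hard_filtered=v.hard_filtered,
                mid_filtered=v.mid_filtered,
            )
        )
    _, _, ccf_table = run_eclipse_sample(relabelled, list(counts), per_variant_error)
    plasma_ccf = dict(zip(ccf_table["variant_id"], ccf_table["ccf"]))

    records: list[IllusionRecord] = []
    for v in relabelled:
        if not v.is_clonal:
            continue
        all_ccfs = region_ccfs.loc[v.variant_id]
        truth = "clonal" if bool((all_ccfs > clonal_ccf).all()) else "clonal_illusion"
        records.append(IllusionRecord(
            v.variant_id, region, True, truth,
            plasma_ccf.get(v.variant_id, float("nan")),
        ))

    scored = [r for r in records if not math.isnan(r.plasma_ccf)]
    scores = np.array([r.plasma_ccf for r in scored])
    labels = np.array([r.truth_label == "clonal" for r in scored])
    auc = rank_auc(scores, labels) if len(scored) else float("nan")
    ci = (float("nan"), float("nan"))
    if len(scored) and not math.isnan(auc):
        pos_ix = np.flatnonzero(labels)
        neg_ix = np.flatnonzero(~labels)
        boots = []
        for _ in range(500):
            bp = rng.choice(pos_ix, len(pos_ix), replace=True)
            bn = rng.choice(neg_ix, len(neg_ix), replace=True)
            ix = np.concatenate([bp, bn])
            boots.append(rank_auc(scores[ix], labels[ix]))
        boots = [b for b in boots if not math.isnan(b)]
        if boots:
            ci = (float(np.quantile(boots, 0.025)), float(np.quantile(boots, 0.975)))
    summary = {"auc": auc, "auc_ci": ci, "n": len(scored), "region": region}
    return records, summary


# ---------------------------------------------------------------------------
# trajectories
# ---------------------------------------------------------------------------


def trajectory_table(
    tree: CloneTree,
    samples: Sequence[tuple[SampleEstimate, Sequence[CloneEstimate]]],
    tracked_per_clone: Mapping[str, int] | None = None,
    nesting_mode: str = "paper",
) -> pd.DataFrame:
    """Long-format clone x sample trajectory table.

    Columns: clone_id, sample_id, ccf, adjusted_ccf (nesting-reconciled),
    clone_ctdna_purity (adjusted CCF x sample ctDNA purity), provenance
    (detected/inferred/absent).  Clones without any usable tracked mutation
    (``tracked_per_clone`` count of non-hard-filtered cfDNA mutations) are
    dropped.
    """
    keep = set(tree.parent)
    if tracked_per_clone is not None:
        keep = {c for c in keep if tracked_per_clone.get(c, 0) >= 1}
    rows = []
    for sample_est, clone_ests in samples:
        by_clone = {c.clone_id: c for c in clone_ests}
        raw = {c: by_clone[c].ccf for c in keep
               if c in by_clone and not math.isnan(by_clone[c].ccf)}
        adjusted = enforce_ccf_nesting(tree, raw, mode=nesting_mode)
        detected = {c for c, e in by_clone.items() if e.present and c in keep}
        provenance = infer_presence_with_ancestry(tree, detected)
        purity = sample_est.ctdna_purity
        for clone_id in sorted(keep):
            ccf = raw.get(clone_id, 0.0)
            adj = adjusted.get(clone_id, 0.0)
            prov = provenance.get(clone_id)
            present = prov is not None
            rows.append({
                "clone_id": clone_id,
                "sample_id": sample_est.sample_id,
                "ccf": ccf if present else 0.0,
                "adjusted_ccf": adj if present else 0.0,
                "clone_ctdna_purity": (adj * purity) if present and not math.isnan(purity) else 0.0,
                "provenance": prov if prov is not None else "absent",
            })
    return pd.DataFrame(rows, columns=[
        "clone_id", "sample_id", "ccf", "adjusted_ccf", "clone_ctdna_purity", "provenance",
    ])
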