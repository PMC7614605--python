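# phylotrace

Tumour-informed circulating tumour DNA (ctDNA) analysis for minimal residual
disease (MRD) detection and subclonal deconvolution at very low tumour
fractions (<1%), as encountered after curative-intent resection of solid
tumours such as early-stage NSCLC.

A patient-specific panel tracks tens to hundreds of mutations identified in
the resected tumour. UMI-consensus sequencing of plasma cell-free DNA yields,
per tracked position, deep alternate observations (DAO) and deep depth (DDP).
`phylotrace` answers three questions from those counts:

1. **Is tumour DNA present?** Background error is estimated per library from
   non-variant panel positions in each of the 96 reverse-complement-collapsed
   trinucleotide-context (TNC) substitution classes, ER = DAO/DDP with an
   exact Poisson (Garwood) confidence interval. After quality filters
   (background-error, strand-bias, off-target, VAF-outlier), qualified class
   rates are clustered into four depth-weighted "D-groups" and the summed
   observed signal is tested against λ = Σ DDP·ER with a one-tailed exact
   Poisson test, p = P(X ≥ observed); p < 0.01 calls the sample positive.
2. **Which subclones are present, and how large are they?** A ten-step
   copy-number-aware deconvolution: VAF denoising by grouped error
   subtraction; ctDNA tumour purity from clonal mutations; per-mutation
   cancer cell fractions (CCF) via

       VAF = P·m·CCF / (P·CNt + (1−P)·CNn)

   (P purity, m multiplicity, CNt/CNn tumour/normal total copy number);
   quality flagging by normalised CCF SD; summed Poisson presence calls per
   clone and per tumour; minimal detectable CCF/purity; and a rank-sum test
   for complete clonal sweeps.
3. **How did the tumour spread?** Phylogeny-aware post-processing classifies
   relapse as monoclonal vs polyclonal (and monophyletic vs polyphyletic)
   seeding, infers ancestral clone presence, reconciles parent/child CCFs,
   quantifies "clonal illusion" (mutations clonal in one tissue region but
   subclonal tumour-wide) from plasma CCFs, and exports longitudinal clone
   trajectories.

A forward simulator generates synthetic libraries (clone phylogenies with
nested CCFs, copy number/multiplicity including whole-genome-doubled clonal
mutations, log-normal 96-class error profiles, DNA-input-limited consensus
depth at 303 haploid genome copies per ng) plus spike-in dilution and
mock-panel benches for operating-characteristic estimation.

## Worked example

```python
import phylotrace as pt

# one synthetic patient: 5 clones, ~0.9% clonal ctDNA level, 23 ng input
variants, counts, background, profile, truth = pt.simulate_patient(
    7, pt.SimulationConfig(seed=7, n_clones=5), clonal_level=0.009)

# error model -> filters -> D-groups -> sample-level MRD call
tnc = pt.compute_tnc_error_rates(background)
report = pt.apply_quality_filters(variants, counts, tnc)
model = pt.build_d_groups(tnc, variants)
res = pt.call_sample_mrd(counts, report, model, variants)

# subclonal deconvolution with the library's own class error rates
per_err = {v.variant_id: (model.class_er(v.tnc_alt) or 0.0) for v in variants}
sample, clones, _ = pt.run_eclipse_sample(variants, counts, per_err, input_ng=23.0)
```

Output:

```
MRD positive: True  p=0  observed DAO=4337  expected=10.31
clonal ctDNA level: 0.8893%
ctDNA purity: 0.0143 (truth 0.0145)
representative minimal detectable CCF: 0.025
  clonal   CCF=0.926 (truth 1.000) present=True poor_quality=False
  clone_a  CCF=0.363 (truth 0.388) present=True poor_quality=False
  clone_b  CCF=0.016 (truth 0.047) present=True poor_quality=True
  clone_c  CCF=0.385 (truth 0.342) present=True poor_quality=False
  clone_d  CCF=0.047 (truth 0.047) present=True poor_quality=True
```

Reading this: 4,337 mutant consensus reads were observed where ~10 were
expected from error alone, so the sample is unambiguously ctDNA positive at
a clonal ctDNA level of 0.89%. The inferred ctDNA purity (fraction of
cfDNA-contributing cells that are tumour) is 1.43% against a simulated truth
of 1.45%, and the two large subclones are recovered within a few CCF points.
The two ~5%-CCF subclones sit near this library's detection limit; their CCF
estimates are noisy and are flagged `poor_quality` (per-mutation CCF spread
above the 0.56 normalised-SD threshold), which excludes them from downstream
dissemination classification.

The same pipeline is available from the shell:

```sh
phylotrace simulate --seed 7 --out sim/
phylotrace errormodel --background sim/background.tsv --variants sim/variants.tsv \
    --counts sim/counts.tsv --out model.json
phylotrace mrd --model model.json --variants sim/variants.tsv \
    --counts sim/counts.tsv --seed 7 --out mrd.tsv
phylotrace eclipse --model model.json --variants sim/variants.tsv \
    --counts sim/counts.tsv --manifest sim/manifest.tsv --out eclipse/
phylotrace disseminate --clones eclipse/clone_estimates.tsv --tree sim/tree.tsv \
    --sample s1 --out dissemination.tsv
```

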