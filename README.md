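# pavpedigree

Presence/absence-variation (PAV) analytics for backbone-cultivar pedigrees.

Elite crop breeding often revolves around a single *backbone* cultivar that
is crossed repeatedly to produce new lines. Sequencing such a pedigree — the
backbone, its two parents and its progenies — and genotyping a broad
diversity population against the backbone's genome turns every structural
variant into a biallelic *presence/absence* marker: a sample either carries
the reference (backbone-like) segment or the alternative allele. This
package implements the full analytical chain on top of such data:

- **PAV map construction** — per-sample dual-caller SV consensus under a
  strict >50% reciprocal-overlap rule (insertions match by breakpoint
  proximity and length ratio), cross-sample single-linkage merging into a
  non-redundant segment map, pan/core saturation curves, and genomic-context
  annotation (exon > intron > promoter > interval).
- **Segment classification** — source categories from the parents' alleles
  (Parent#1-inherited, Parent#2-inherited, reference-specific, biparental)
  and per-trait favorable/deleterious orientation from a Welch t-test on the
  polarity-oriented trait (so "favorable" always means losing the segment
  worsens the trait).
- **PAV-GWAS filter cascade** — a covariate-adjusted linear scan
  (trait ~ presence + presence-matrix PCs) with raw marker threshold
  P ≤ 0.01, divergence threshold P ≤ 0.05, and an expression/context gate;
  eQTL links (log2(TPM+1) ~ presence), SV–Gene–Phenotype triplets labelled
  consistent/conflict by the sign product of the trait and expression
  effects, and allelic-pair detection at shared loci.
- **Heredity** — retention counts over the progenies, pairwise category
  stability t-tests, and the pedigree→population *bottleneck* contrast
  (segments retained by <6 pedigree members vs >12).
- **Sub-grouping** — multiplicative-update NMF of the binary segment-retain
  matrix S ≈ W·H, feature-number selection by silhouette of k-means on W,
  argmax sub-group assignment, region-preference medians with hierarchical
  clustering, and the SG1/SG2 ratio vs trait correlation.
- **Fingerprint scoring** — tf·idf per segment with
  tf = pedigree carriers / 20 and idf = log10(733 / population carriers);
  scores strictly above 2 flag pedigree fingerprint segments (FPS).
- **Trait prediction** — cross-validated RBF-kernel support-vector
  regression from the functional segments, reporting held-out Pearson r.
- **Synthetic pedigree generator** — a fully seeded simulator of the whole
  design (2 parents + 18 progenies + 733-cultivar population, ~13k
  segments) with planted categories, transmission probabilities, trait
  effects, cis expression links, region-structured sub-groups and
  fingerprint segments, plus noisy dual-caller call emulation — so every
  stage is testable against ground truth.

## Worked example

```python
import pavpedigree as pp
from pavpedigree import RunConfig, run_pipeline
from pavpedigree.simulate import SimConfig

cfg = RunConfig(
    out_dir="run1", seed=1,
    simulate=SimConfig(seed=1, n_segments=2000, n_population=400,
                       n_functional=30, fp_planted=20),
)
run_pipeline(cfg)
```

The run directory then contains the merged PAV map, category/effect tables,
the functional pool, retention and bottleneck statistics, sub-group
assignments, fingerprint scores, per-trait predictions and a `manifest.json`
echoing every threshold. On this configuration the manifest reports, among
others:

```
merge        n_consensus_records = 1831
gwas         pool_size = 29,  n_triplets = 29
heredity     bottleneck mean_low = 0.161, mean_high = 0.503, p = 4.2e-34
subgroup     f_star = 2, sg_ratio_pearson_r = -0.73 (disease index)
fingerprint  n_fps = 20
predict      fiber_length r = 0.93, disease_index r = 0.88
```

i.e. the dual-caller merge recovers the pedigree-visible segments, the
filter cascade recovers essentially all planted 1-SD effects, segments
poorly retained in the pedigree sit at ~3× lower population frequency, the
two planted geographic sub-groups are recovered with the expected negative
ratio–disease correlation, all 20 planted fingerprint segments score above
the threshold, and held-out SVR predictions track the planted additive
signal.

The same pipeline is scriptable from the shell:

```bash
pavpedigree run-all --config run.yaml
pavpedigree fingerprint --config run.yaml --seed 9
```

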