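# clonephy

Joint Bayesian reconstruction of the subclonal composition and evolutionary
history of a tumor from whole-genome sequencing read counts, integrating
simple somatic mutations (SSMs) with subclonal copy-number variants (CNVs).

Bulk tumor sequencing mixes reads from genetically distinct cell
populations. For an SSM at a diploid locus, the variant allele frequency
(VAF) is half the fraction φ of cells carrying it, so clustering VAFs
recovers subclonal lineages — *unless* a CNV overlaps the locus, in which
case the VAF depends on the copy number *and* on whether the CNV happened
before, after, or on a different branch than the SSM. `clonephy` models this
explicitly: each CNV enters the clone tree as a *pseudo-SSM* whose read
counts encode its population frequency, and the expected VAF of every
overlapped SSM is computed from the tree itself.

## Model

Cell populations are nodes of a rooted tree drawn from a tree-structured
stick-breaking process TSSB(α, γ, H). Auxiliary masses η_v ≥ 0 (the fraction
of cells belonging exactly to node v) satisfy Σ_v η_v = 1, and population
frequencies follow φ_v = η_v + Σ_{w∈children(v)} φ_w, which enforces the
clonal constraint φ_parent ≥ Σ φ_children. For each SSM *i*, walking every
node *u* accumulates the average reference- and variant-bearing copies per
cell, N^r_i and N^v_i, according to which of five situations holds at *u*
(no SSM / SSM, with or without a governing CNV found by ascending toward
the root, and the SSM↔CNV event order). Reference read counts are then

    a_i | d_i ~ Binomial(d_i, ζ_i),   ζ_i = (N^r_i(1−ε) + N^v_i ε) / (N^r_i + N^v_i)

with per-mutation sequencing error ε. With a single CNV of copy number
C = C^m + C^p at frequency φ_c overlapping an SSM at frequency φ_s, this
reduces to the closed forms

    SSM → CNV:          x = (C^m φ_c + (φ_s − φ_c)) / (2(1 − φ_c) + C φ_c)
    CNV → SSM, or
    separate branches:  x = φ_s / (2(1 − φ_c) + C φ_c)

Unphased SSMs average the maternal/paternal likelihoods; an SSM can never
arise after a homozygous deletion of its locus. Inference is MCMC: slice
sampling of mutation–node assignments over the lazy TSSB, conjugate stick
updates, merge proposals, and Metropolis–Hastings updates of η with an
asymmetric Dirichlet proposal (shared tree across multiple samples, with
per-sample η). The reported point estimate is the sampled tree with the
highest complete-data likelihood.

## Worked example

Simulate the illustrative tumor — 25% normal cells (A), 25% a lineage B
carrying SSM1–4, 50% a descendant lineage C adding SSM5–8 plus a homozygous
deletion of the SSM4 locus — at read depth 60, and reconstruct it:

```sh
clonephy simulate --design figure-example --read-depth 60 --seed 1 --out sim
clonephy run --ssms sim/ssms.tsv --cnvs sim/cnvs.tsv --out run --smoke --seed 1
clonephy evaluate --chain run/chain.jsonl --truth sim/truth.json
```

The summary reports the pruned best tree (output abridged):

```
population_count: 3
best_log_likelihood: -28.87
node 0  parent –  phi 1.000  []
node 1  parent 0  phi 0.733  [s1, s2, s3, s4]
node 2  parent 1  phi 0.474  [cnv_cnv1, s5, s6, s7, s8]

{"auprc": 0.852, "population_count_error": 0}
```

The chain A → B → C is recovered with φ ≈ (1.0, 0.73, 0.47) against the
true (1.0, 0.75, 0.5). The deleted SSM4 (observed VAF ≈ 0.25, the same as
SSM5–8) is correctly placed in lineage B with SSM1–3: its low VAF is
explained by the loss of its locus in C, not by membership in C. A
VAF-clustering method without the copy-number correction groups it with
SSM5–8. `population_count_error` is the signed difference between the
number of populations in the pruned maximum-likelihood tree and the truth;
`auprc` scores the posterior-averaged SSM co-clustering matrix against the
true one over unordered pairs.

Full sampler settings default to 2,500 iterations (100 burn-in) with 5,000
inner Metropolis–Hastings steps at Dirichlet scale 100; `--smoke` selects
the reduced 500/50/500 profile used throughout the test suite.

## Input formats

SSMs: TSV with `id`, `a` (reference reads), `d` (total reads; both
comma-separated across samples), optional `mu_r`, `mu_v`, `epsilon`,
`chrom`, `pos`, `phase`. CNVs: TSV with `id`, `chrom`, `start`, `end`
(0-based half-open), `C`, `Cm`, `Cp` (blank allowed only for C < 2), `phi`
per sample, and `support_depth` (the pseudo-SSM read depth, reflecting
confidence in φ). See `docs/methods.md` for the model details, parameter
defaults and known limitations.
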