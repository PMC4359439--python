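# Methods

## Observation model

For SSM *i* in sample *s*, the data are the reference read count a_is out of
d_is total reads. Absent CNVs, a read drawn from a cell of the variant
population shows the reference allele with probability μ^v = 0.5
(heterozygous mutation) and one from the reference population with
μ^r = 1 − ε, giving

    a_is ~ Binomial(d_is, (1 − φ̃_is) μ^r_i + φ̃_is μ^v_i)

where φ̃_is is the population frequency of the SSM's node. With CNVs the
success probability is ζ_is = (N^r(1−ε) + N^v ε)/(N^r + N^v), with N^r and
N^v accumulated over every tree node u with mass η_u:

| situation at u (governing CNV by nearest ancestor-or-self) | N^r +=        | N^v += |
|---|---|---|
| no SSM, no CNV                                             | 2 η_u         | 0      |
| no SSM, CNV with total copy number C                       | η_u C         | 0      |
| SSM, no CNV                                                | η_u           | η_u    |
| SSM after CNV (requires C ≥ 1)                             | η_u max(0, C−1) | η_u  |
| SSM before CNV, SSM on maternal copy                       | η_u C^p       | η_u C^m |

The paternal-copy case swaps C^m and C^p; unphased SSMs average the two
phased *likelihoods* (not log-likelihoods) jointly across samples, and the
average is taken only when a SSM-before-CNV population with C^m ≠ C^p
exists (otherwise the two branches coincide). Two constraints are treated
as structural zeros rather than soft penalties: a locus deleted in every
population (N^r + N^v = 0) and an SSM placed after a homozygous deletion of
its locus (C = 0, no copy left to mutate). The second constraint is what
makes the worked-example tumor identifiable: without it, placing the
deleted SSM *in* the deletion-carrying lineage fits the read counts almost
as well as the correct earlier placement.

An SSM and its governing CNV assigned to the same node are treated as
CNV-then-SSM; the within-node order is unobservable, and this is the only
choice that needs no phasing. When several CNVs overlap one locus, the
nearest ancestor-or-self CNV governs each population (ties at one node
broken by input order); the copy numbers of the governing CNV are applied
as absolute values. Sequential amplifications along one branch are
therefore approximated by the nearest event — a known limitation.

## CNVs as pseudo-SSMs

Each CNV with per-sample frequency φ enters the tree as a heterozygous
binary pseudo-mutation with d = `support_depth` total reads and
b = round(d·φ/2) variant reads (round half away from zero; "nearest whole
number" needs a tie rule and this one is sign-symmetric). `support_depth`
defaults to twice the dataset's mean SSM read depth and is the single knob
expressing confidence in φ — a user with a confidence interval for φ should
set d so a Binomial(d, φ/2) interval matches it; no interval-matching
solver is provided. SSMs inside the CNV's interval (0-based, half-open, the
convention CNV callers emit) are associated to it; the pseudo-SSM's own
likelihood is the diploid binomial above, while its *placement* also drives
the five-case accumulation of every associated SSM.

## Prior and sampler

The tree prior is a tree-structured stick-breaking process: depth sticks
ν_v ~ Beta(1, α λ^depth) and width sticks ψ ~ Beta(1, γ), materialized
lazily to depth 15. Defaults: α = 25, λ = 0.25 (the α λ^depth pseudo-counts
keep mass at the shallow depths where tumor lineages live), γ = 1. All
three are config keys; sensitivity is left to the user. Reducing γ tightens
the unallocated sibling mass and with it the rate at which transient
singleton branches appear.

The root node represents the whole sample (the η construction forces
φ_root = 1 per sample) and by default holds no mutations, so η_root models
the non-cancerous fraction (`root_can_hold_mutations` overrides). The base
measure for a new node's mass is Uniform(0, η_parent), subtracted from the
parent, which preserves Σ η = 1 exactly.

One MCMC iteration runs, in order:

1. **Stick updates** — conjugate Beta posteriors given assignment counts.
2. **Assignment slice sampling** — per mutation, a slice level is drawn
   under its current log-likelihood; candidates come from quantile descent
   through the stick measure (creating nodes lazily where the draw lands in
   unallocated mass) with the search interval shrinking toward the current
   node's path after each rejection. Pseudo-SSM moves also score the SSMs
   their CNV overlaps, since those likelihoods depend on the CNV's
   placement.
3. **Merge proposals** — each mutation-bearing node proposes relocating all
   its mutations to its parent, a sibling or a child, together with a
   Uniform(0, η_v) share of its mass, accepted on the complete-data
   posterior ratio. Cluster formation can strand one true population across
   two nodes of nearly equal φ, a state single-mutation moves escape only
   by an unguided random walk; the merge move collapses it directly. The
   reverse (split) proposal is not made, so posterior mass on duplicate-φ
   node pairs is deliberately suppressed — a bias toward parsimonious
   trees that does not affect genuinely distinct clusters, whose merge
   proposals fail on the data term.
4. **η Metropolis–Hastings** — `mh_iterations` block proposals per sample
   from Dirichlet(scale·η + 0.01); the floor keeps zero-mass nodes
   proposable. Acceptance multiplies the likelihood ratios across samples
   (one global move; the clonal constraints hold per sample by
   construction) with the asymmetric-proposal correction; the prior over η
   is taken flat on the simplex. Mutation-free leaves are culled and
   mutation-free internal nodes spliced into their parent throughout — both
   operations conserve η exactly and are likelihood-neutral, because an
   empty node's five-case classification always coincides with its
   parent's.

Defaults follow the reference protocol: 2,500 iterations, 100 burn-in,
5,000 MH steps, Dirichlet scale 100; the smoke profile (500/50/500) is used
in tests. All randomness derives from one seed via spawned generator
streams, so runs are bit-reproducible. Each recorded sample stores the
serialized tree and its complete-data log likelihood — the read-count
likelihood plus Σ_i log w_{z_i}, the stick mass of each mutation's node.
Ranking trees by data likelihood alone favors fragmented clusterings
(every extra cluster fits its empirical VAF exactly); the assignment-mass
term is the model's own complexity penalty. Convergence is monitored with
the likelihood trace and its autocorrelation function, both written by the
CLI.

## Synthetic data

The generator draws d ~ Poisson(r) (zeros resampled — a zero-depth SSM is
unobservable) and a ~ Binomial(d, ζ) with ζ computed from the ground-truth
tree by the same five-case accumulation the inference uses, at ε = 0; for a
diploid locus this is the textbook a ~ Binomial(d, 1 − φ_u + 0.5 φ_u).
Three designs:

* **Linear/branching multi-population designs** at the standard lineage
  proportions (3 populations: 0.44/0.11; 4: 0.56/0.25/0.06; 5:
  0.64/0.36/0.16/0.04; 6: 0.71/0.44/0.25/0.11/0.03). Branching proportions
  are not standardized; the generator reuses the linear magnitudes with the
  two deepest lineages as siblings, which satisfies every parent–child sum
  constraint.
* **The worked-example tumor** (A 25% normal → B 25%, SSM1–4 → C 50%,
  SSM5–8 + homozygous deletion of the SSM4 locus), expected VAFs 37.5% for
  SSM1–3 and 25% for SSM4–8.
* **The CNV scenario**: 20% normal → 40% CNV-free lineage (500 SSMs) → 40%
  descendant (200 SSMs) carrying an amplification (C=3, C^m=2, C^p=1) or
  deletion (C=1) over half of a 10 Mb toy contig (only overlap fractions
  matter). Ancestral SSMs inside the region are assigned a generating copy
  (recorded as phase) so their expected VAF follows the SSM-before-CNV
  closed form.

What the generator does **not** emulate: mapping artifacts, strand or
position biases, overdispersion beyond binomial, subclonal CNV calling
error (φ_c and C are taken as exact), germline contamination of the variant
calls, or kataegis-style clustered mutation processes. Passing recovery
tests therefore demonstrates correctness of the model and sampler under
the model's own assumptions, not robustness to caller noise.

## Numerical choices and degenerate inputs

Binomial log-pmfs are computed from gammaln with probabilities clipped to
[1e-300, 1−1e-16]; likelihood-equivalence tests between the vectorized
engine and the per-mutation reference path hold to 1e-8 (association order
differs). Best-tree ties break to the earliest iteration. A mutation with
no feasible placement keeps its current node for that sweep. C = 1 without
phasing is stored as (C^m, C^p) = (0, 1) and flagged unphased; the two
breakdowns are exchangeable under the unphased averaging. Amplifications
(C ≥ 2) without a maternal/paternal breakdown are rejected at load time.
Default ε = 0.001 when the SSM table omits it (μ^r defaults to 1 − ε).

## Known limitations

Tumor-level: no back-mutation or locus re-gain (infinite sites for SSMs),
tree-shaped clonality only (no convergent evolution), CNV copy numbers and
frequencies trusted from the upstream caller. Statistical: the
nonparametric prior can over-segment when very many SSMs characterize each
population — genuinely extreme read-count outliers earn their own small
node; no post-hoc small-cluster removal is applied. At shallow depths
(~60×) with few SSMs per lineage, VAF clusters separated by ~2σ are not
reliably recoverable by any method; recovery statements in the tests are
calibrated to deep (≥200×), many-SSM designs, and the worked example at
depth 60 is reliably correct in its discriminating feature (the deleted
SSM is never co-clustered with its deletion) rather than in every
mutation's membership. Problem sizes in the test suite (hundreds of SSMs,
500-iteration smoke chains, five replicate seeds) were chosen as the
smallest designs at which these properties are stable.
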