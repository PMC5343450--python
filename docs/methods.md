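# Methods

## Model

A patient series is an ordered sequence of samples from one cancer:
matched normal, optionally a pre-invasive DCIS, the primary tumor, and
one or two metastases (synchronous lymph-node sALN, asynchronous distant
aDM). Somatic evolution is modelled as a rooted clone tree: each edge
carries the set of mutations newly acquired by the child clone, branch
mutation sets are pairwise disjoint, and a sample is a mixture of clones
with fractions summing to 1 over its malignant cells.

A mutation's cancer-cell fraction (CCF) in a sample is the summed
fraction of clones whose lineage contains it. At a copy-number-neutral
heterozygous position the expected variant allele frequency is

    E[BAF] = purity × CCF × 0.5

so a fully clonal mutation sits at the sample's diploid heterozygous
level `L = purity × 0.5`. An optional multiplicity mode generalises the
clonal expectation to `purity·m / (purity·CN_t + (1−purity)·2)` for
mutations at multiplicity `m` on total tumor copy number `CN_t`,
emulating hyperploid tumors; it defaults to off because all route logic
is based on copy-number-neutral heterozygous positions.

## Filtering and presence

The multi-sample somatic filter retains a candidate site iff the normal
BAF is below 0.02, depth is at least 50 reads in every sample (normal
included), and at least one tumor sample shows BAF ≥ 0.05. For retained
sites, presence in the other tumor samples is rescued down to BAF ≥ 0.025
when depth strictly exceeds 200 reads. A site in the rescue BAF zone
[0.025, 0.05) without that depth is genuinely ambiguous; we expose it as
a third `uncertain` state rather than resolving it silently, and report
how many uncertain calls each run produced. Downstream, uncertain is
treated as absent by default (configurable), and an uncertain call never
advances a mutation's first appearance.

Known SNPs are removed when their annotated population allele frequency
strictly exceeds 1%; unannotated sites count as frequency 0. SNV clusters
— any run of more than 2 variants spanning ≤ 100 bp on one chromosome —
are removed entirely; window and count are conventions (no standard value
exists) and are configurable. Curation of repetitive or error-prone
regions is represented by a declarative exclusion-interval list (BED at
the boundary, 1-based inclusive internally) instead of manual alignment
review, which keeps the step reproducible.

## Purity

When purity is not supplied it is estimated from the BAF distribution of
present mutations: a Gaussian kernel density (fixed bandwidth 0.012 on
the BAF axis) is evaluated on [0, 0.75]; local maxima with at least 25%
of the peak density are major modes; the clonal cluster is the major mode
at the highest BAF, its location refined by three rounds of symmetric
trimmed mean (±0.03) which is unbiased for the cluster centre where the
smoothed argmax is not; purity = 2 × location, clipped at 1. The
estimator refuses samples with fewer than 10 present mutations and
user-supplied purity always takes priority. Limitation: below purity
≈ 0.5 at depth 300 the clonal cluster and a subclone at CCF ≈ 0.7 overlap
within binomial noise and the estimate degrades — mode-based purity
estimation is intrinsically unreliable at low tumor content, so supplying
an external estimate there is recommended.

## Clonality, subclones, purification

Clonality is called per (mutation, sample) against the lowered level
`L(1 − τ)` with the exact two-sided Clopper–Pearson 95% CI for BAF:
clonal when the CI reaches the level, subclonal when it lies wholly
below. The relative tolerance τ = 0.2 absorbs moderate purity error and
mild copy-number distortion; both τ and the CI level are configurable.
The boundary is intentionally coarse: mutations at CCF near `1 − τ`
straddle it and split between calls, which downstream logic tolerates
because route decisions rest on presence patterns, not clonality.

Mutations are grouped into subclones by exact match of the discrete
signature (first appearance, per-sample presence, per-sample clonality).
Exact matching is deterministic and mirrors set-based reasoning on
frequency plots; it deliberately avoids distance-based VAF clustering
(no Dirichlet-process deconvolution — a non-goal). A group needs at
least two mutations to be a subclone; singletons are listed separately
and never drive route calls, since a single mutation can be artifactual.
A subclone subclonal in an earlier sample and clonal in a later one is a
purification event, naming its member mutations.

## Route classification

Mutations are partitioned by the exact set of tumor samples carrying
them; the trunk is the set present in every tumor sample. Per metastasis
M, rules are evaluated most-specific-first:

1. **met_to_met from M′**: |(M ∩ M′) \ primary| ≥ `min_evidence` (default
   2, reusing the subclone threshold) and |(primary ∩ M) \ M′| ≤
   `containment_tolerance` (default 0, strict set logic). Because this
   containment evidence is symmetric whenever the shared-exclusive
   mutations lie on the common founder lineage, the candidate source must
   additionally precede M in progression order — a synchronous metastasis
   can seed a later relapse, not the reverse. Every met_to_met call
   carries a mandatory caveat string: an unsampled primary subclone could
   mimic the pattern.
2. **parallel**: some primary subclone (≥ 2 mutations) is absent from M
   while M shares at least `min_evidence` mutations with the primary
   (it descends from the same lineage).
3. **linear**: every primary subclone's mutations are present in M up to
   the containment tolerance.
4. otherwise **unresolved** — misfits degrade to unresolved rather than
   to a wrong definite route.

Concordance between primary and each metastasis is reported as
`round(100 · |primary ∩ M| / |primary|)`, descriptive output only; no
concordance cutoff enters the route call.

The clone tree is assembled by presence-set containment: each subclone
attaches under the smallest strict superset, samples attach as leaves
under the most derived subclone present in them, branch lengths are
mutation counts. Two subclones with properly overlapping, non-nested
presence sets cannot be placed on one tree; both are flagged
`unresolved` instead of being silently repaired. Serialisation is Newick
(via dendropy) plus a JSON payload with full evidence.

## Synthetic data

The simulator emulates targeted deep sequencing of a progression series:
branch mutation counts uniform in [10, 60] (giving per-patient totals in
the low hundreds, matching the 44–531 range of real targeted panels),
tumor purity drawn uniformly from 0.3–0.9 per sample unless fixed
(within the 0.24–0.95 range such series show), mean depth 300 reads
(within the 200–613× targeted-sequencing range), per-site depth Poisson
floored at 1 read, alt counts Binomial(depth, E[BAF] + ε) with per-base
error ε = 0.001. The primary is a subclone chain (terminal clone at 45%
of malignant cells by default, ancestors splitting the rest); metastases
hold their founder clone plus a private derived clone at 70%, so
metastasis-exclusive mutations occur subclonally as observed in real
series. Artifact injection adds the record classes the filters exist to
remove: germline heterozygous SNPs (BAF ≈ 0.5 everywhere, annotated
population AF drawn 80% common / 20% rare), low-BAF artifacts, and
clustered runs of 3 variants per 100 bp. All randomness flows from one
integer seed, and fixture writes are byte-identical under a fixed seed.

What the simulator does *not* model: read-level effects (mapping error,
strand bias), indels, copy-number variation unless the multiplicity mode
is enabled, sequencing batch effects, and spatial sampling of the
primary. Passing tests therefore demonstrate correctness of the
inference logic under the stated noise model, not robustness to every
artifact of real sequencing.

## Problem sizes and numerical choices

Simulation-based checks use 100 replicates per route (depth 300) for
route recovery, 200 replicates for purity recovery (trunk 50–60
mutations, a sample size where the clonal cluster is well populated),
and 50 replicates for purification coverage (seeding subclone fraction
0.2–0.5, depth 500, purity fixed at 0.8, a mid-range tumor content).
Exact binomial CIs are computed vectorised from the beta quantile
function; BAF at zero depth is defined as 0 (such sites fail the depth
filter regardless); ties in clone-tree placement are broken
deterministically by set size then identifier.
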