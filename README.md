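# cloneroute

Clonality analysis and metastasis seeding-route inference for
multi-sample tumor progression series.

## The problem

When several lesions of one cancer patient are sequenced — a pre-invasive
lesion (DCIS), the primary tumor, a synchronous axillary lymph-node
metastasis (sALN) and/or an asynchronous distant metastasis (aDM) — the
pattern of somatic mutations shared between the lesions encodes how each
metastasis emerged:

* **linear progression** — the metastasis was seeded by the most advanced
  clone of the primary tumor, so every primary subclone's mutations are
  carried into the metastasis;
* **parallel progression** — the metastasis was seeded by an earlier clone
  while more advanced clones remained private to the primary tumor;
* **metastasis-to-metastasis seeding** — one metastasis was founded by
  cells disseminated from another, evidenced by mutations the two
  metastases share that are not detectable in the primary tumor, with
  everything the later metastasis shares with the primary also present in
  the earlier one.

`cloneroute` implements the full inference chain from per-mutation,
per-sample read counts (targeted deep sequencing, 200–600×) to a
per-metastasis route call, for analysts working with matched multi-sample
tumor series.

## The method

For a site with `k` alt reads out of `n`, the B-allele frequency is
`BAF = k / n`. The pipeline stages are:

1. **Multi-sample somatic filtering** — a candidate mutation is retained
   iff normal `BAF < 0.02`, depth `≥ 50×` in *all* samples, and
   `BAF ≥ 0.05` in at least one tumor sample. Known SNPs with population
   allele frequency `> 1%`, variants in SNV clusters (more than 2 variants
   per 100 bp) and variants in user-supplied exclusion intervals are
   removed.
2. **Presence rescue** — in the remaining tumor samples a retained
   mutation is called present down to `BAF ≥ 0.025` provided depth
   exceeds `200×`; a rescue-zone site without that depth is reported as
   `uncertain`, never silently resolved.
3. **Clonality** — a clonal heterozygous diploid mutation is expected at
   `BAF ≈ purity × 0.5` (the diploid heterozygous level `L`). A mutation
   is *clonal* in a sample when the exact binomial 95% CI for its BAF
   reaches `L(1 − τ)` (default `τ = 0.2`), *subclonal* when the CI lies
   wholly below. Purity is user-supplied or estimated as twice the
   highest-BAF major mode of the BAF distribution (`PurityEstimator`);
   the estimator refuses samples with fewer than 10 present mutations.
4. **Subclones and purification** — mutations sharing an identical
   (first appearance, presence, clonality) signature form a subclone when
   at least two of them agree; a subclone that is subclonal in an earlier
   sample and clonal in a later one is a *purification event*, evidence
   of the later lesion's subclonal origin.
5. **Route classification** — per metastasis, the most specific pattern
   wins: metastasis-to-metastasis (≥ 2 shared-exclusive mutations, full
   primary-containment in the source, source earlier in progression),
   then parallel, then linear; otherwise `unresolved`.

A clonal-evolution simulator (`simulate_series`) generates series with a
known clone tree, seeding topology, purity and binomial read-count noise,
so every stage is testable against exact truth.

## Worked example

```python
import json
import cloneroute as cr

sim = cr.simulate_series("met_to_met", seed=11, purity=0.6)
result = cr.run_pipeline(sim.table, sim.series)
for rc in result.route_calls:
    print(rc.metastasis, rc.route, rc.source, rc.evidence)
print(result.newick)
```

prints

```
sALN linear primary {'primary_subclones': 2, 'containment_violations': 0}
aDM met_to_met sALN {'shared_exclusive': 35, 'containment_violations': 0}
(((((SC6:9,aDM:0)SC4:31,(SC7:9,sALN:0)SC5:31)SC2:35)SC3:32,primary:0)SC1:50)normal;
```

The sALN is called linear (both primary subclones are carried into it,
zero containment violations). The aDM is called metastasis-to-metastasis
seeded from the sALN: 35 mutations shared by the two metastases are not
detectable in the primary, and every mutation the aDM shares with the
primary is also in the sALN. The Newick tree arranges the recovered
subclones by presence-set containment with branch lengths equal to the
mutation counts acquired on each edge; the aDM leaf attaches inside the
sALN lineage. Every `met_to_met` call carries a caveat that an unsampled
primary subclone could mimic the pattern.

The same pipeline runs from the shell:

```bash
cloneroute simulate --route met_to_met --seed 11 --out fixture/
cloneroute run-all --variants fixture/variants.tsv \
                   --samples fixture/samples.tsv --out run/
cloneroute config --init pipeline.yaml   # all thresholds, editable
```

Real data enter as a multi-sample TSV (`chrom, pos, ref, alt`, then
`<sample>_depth/_alt/_baf` triplets) or a multi-sample VCF with per-sample
`DP`/`AD` fields, plus a sample-metadata TSV
(`sample_id, step_label, order_index, purity, mean_depth`).

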