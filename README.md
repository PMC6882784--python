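# clonevo

Subclonal evolution analysis for multi-region tumors from engineered
mouse pancreatic-cancer models (KPC / KPTC), and a ground-truthed
synthetic cohort generator to validate every stage of it.

Genetically engineered mice develop pancreatic tumors from defined
knock-in mutations (*Kras* G12D, *Trp53* R172H, optionally one *Tgfbr2*
allele lost), so any further somatic change observed in the tumor is
evidence of continuing evolution after initiation. Sampling each tumor
as three regions (T1–T3) and combining targeted read counts, array-CGH
copy number, germline SNP allele counts and a qPCR purity assay, the
package reconstructs which mutations arose when, in what fraction of
cancer cells, and in what hierarchical order.

## The models at the core

**Purity** — a qPCR assay on the un-recombined LSL cassette, fitted as
`Ct = A·purity + B` on a standard dilution series and inverted per
sample.

**Copy number** — the observed tumor/normal log2 ratio of a segment is

```
log2R = log2((p·CN_T + (1 − p)·CN_N) / CN_N)
```

for purity `p`; probe tracks are segmented (recursive binary splitting
with an interior-window alternative and a permutation test), merged by
the 3-SD undo rule, and inverted to integer `CN_T`. Focal events are
homozygous deletions (`CN_T = 0`) or amplifications (`CN_T ≥ 5`) under
4 Mb with ≥ 5 probes on autosomes; cross-region and cross-mouse identity
uses a 50% overlap/union rule; chromosomes ≥ 50% altered are large-scale
events.

**Allelic imbalance** — a one-copy loss shifts the tumor minor allele
frequency of a germline heterozygous SNP from 0.5 to
`MAF = (1 − p)/(2 − p)`; the per-sample decision threshold is calibrated
by binomial simulation at the sample's coverage (10,000 SNPs, subset
averaging over 10, max-F1 threshold subject to sensitivity and
specificity > 0.8), and genes are tested with a one-tailed paired t test
on the 10 nearest informative SNPs, BH-corrected.

**Cancer cell prevalence** — a mutation in a fraction `C` of cancer
cells with multiplicity `m` has expected VAF

```
v_exp = p·m·C / (p·CN_T + (1 − p)·CN_N)
```

with variant reads Binomial(DP, v_exp); the likelihood over a 0.01 grid
of C gives the point estimate and interval, multiplicity is deduced
where only one value is feasible, and mutations are clustered across
regions (DBSCAN with silhouette selection, affinity propagation
fallback).

**Trees** — under the infinite sites assumption ancestors have higher
prevalence than descendants and siblings obey the sum rule; all rooted
labeled trees over the clusters (root = knock-in cluster) are enumerated
exactly and scored by precedence + sum-rule violations; all minimal-cost
trees are reported and classified linear / branched, with a flag for two
synchronous primary tumors.

## Worked example

Simulate one mouse with a linear two-cluster truth and run every stage:

```python
from clonevo.simulate import simulate_mouse, Genome
from clonevo.pipeline import run_mouse, default_config

genome = Genome(chromosomes={"chr1": 10_000_000, "chr2": 10_000_000,
                             "chr3": 10_000_000, "chrX": 5_000_000})
mouse = simulate_mouse(seed=11, topology="linear", genome=genome,
                       n_snps=400, n_mut_per_cluster=5)
report = run_mouse(mouse, default_config(11))
```

With truth purities {T1: 0.700, T2: 0.751, T3: 0.464}, this prints (via
the report dict):

```
est. purity   {'T1': 0.6958, 'T2': 0.7397, 'T3': 0.4723}
T1 segments   9 | focal: [('Amp', 'chr2', 7227255, 7647256),
                          ('HD', 'chr3', 4998077, 6958078)]
validated     8 | heterogeneity: {'ubiquitous': 8}
cluster 0 n = 3 mean = [0.97, 0.96, 1.0]
cluster 1 n = 5 mean = [0.7867, 0.716, 0.705]
phylogeny     {'n_minimal_trees': 1, 'cost': 0, 'topology': 'linear',
               'synchronous_primary': False}
newick        ((C1)C0)root;[cost=0]
```

The qPCR inversion recovers each region's purity to ~0.01; the planted
focal amplification and deletion are found; all eight validated
non-transgene mutations are present in every region (ubiquitous); the
two prevalence clusters (clonal at ~1.0, subclonal at ~0.74) produce a
single zero-violation tree, the chain root → C0 → C1 — a linear
evolution verdict matching the generator truth.

The same stages are available from the shell:

```
clonevo simulate --seed 11 --n-mice 12 --outdir cohort/
clonevo run-cohort --seed 11 --n-mice 12 --outdir results/
clonevo purity --standards std.tsv --samples ct.tsv
clonevo cna --probes T1.probes.tsv --genes genes.bed --purity 0.7 \
            --seed 1 --out-seg T1.seg
```

`run-cohort` writes per-mouse reports (JSON), SEG/TSV artifacts, Newick
and DOT trees, plus a cohort summary with mutation burden, heterogeneity
fractions, focal-event recurrence across mice and the linear/branched
tally.

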