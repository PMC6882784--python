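# Methods

`clonevo` reconstructs the subclonal composition and evolutionary history
of multi-region tumors from engineered mouse pancreatic-cancer models
(KPC: knock-in *Kras* G12D + *Trp53* R172H; KPTC: additionally one
*Tgfbr2* allele lost). Each tumor is sampled as three regions (T1–T3);
the inputs per region are targeted amplicon read counts at candidate
somatic mutations, aCGH probe log ratios, germline heterozygous SNP
allele counts, and qPCR purity-assay readouts. This note records the
models, the tunable parameters, and the design decisions taken where the
problem was genuinely open.

## Tumor purity

The qPCR assay amplifies the un-recombined LSL cassette, present only in
non-tumor cells, so the cycle threshold rises with tumor-cell fraction.
A standard dilution series (0, 10, 20, 40, 60, 80, 100% tumor DNA, in
triplicate) is fitted by ordinary least squares as `Ct = A·purity + B`;
sample purity is the mean of per-replicate inversions `(Ct − B)/A`,
clamped to [0, 1]. The regression uses all replicate points rather than
replicate means — it weighs the same information either way for a
balanced design, and raw points keep the residual diagnostics honest.
Out-of-range inversions are clamped, not rejected: assay noise can push
an estimate slightly past the extreme standards.

## Copy number

The observed tumor/normal log2 ratio of a segment with tumor copy number
`CN_T` (normal `CN_N = 2` on autosomes) in a sample of purity `p` is

    log2R = log2((p·CN_T + (1 − p)·CN_N) / CN_N)

Probe tracks are segmented per chromosome by recursive binary splitting.
At each stage the best mean-shift candidate is either a single split or
an interior window (lengths on a geometric grid), scored by the square
root of the residual-sum-of-squares reduction; the interior-window
alternative matters because a short focal deletion in the middle of a
chromosome barely moves any single-split statistic. Significance is
assessed by a permutation test (default alpha 0.01, 199 permutations,
seeded — segmentation is deterministic given the seed). Over-segmentation
is then undone by merging adjacent segments whose means differ by less
than 3 pooled within-segment standard deviations, iterated to a fixpoint
(most-similar pair first, so the operation is idempotent and
order-independent).

Segment means are inverted through the mixture relation,
`CN_real = CN_N·(2^log2R − (1 − p)) / p`, and rounded half-up to integer
`CN_T` (floored at 0). Classes: HD (`CN_T = 0`), loss, neutral, gain,
Amp (`CN_T ≥ 5`, i.e. a gain of at least three copies over diploid).

Focal events are HD/Amp segments spanning < 4 Mb, covering ≥ 5 probes,
on autosomes; same-class events with boundaries < 100 kb apart are
merged, and events that do not overlap the coding span of at least one
gene (≥ 1 bp) are dropped. The focal size limit is configurable; 4 Mb is
the operational default. Events from different regions (or different
mice, for cohort recurrence) of the same class with interval
overlap/union ≥ 0.5 are identified transitively as one event; status is
ubiquitous / partially shared / private by region support. Large-scale
gains and losses are chromosomes where same-direction altered segments
cumulatively span ≥ 50% of the segmented length (cumulative rather than
single-segment — segmentation noise should not break an arm-level call
into innocuous pieces). Internal coordinates are 0-based half-open; SEG
I/O converts from/to 1-based inclusive.

## Allelic imbalance

A germline heterozygous SNP has minor allele frequency (MAF) 0.5 in
normal tissue; in a tumor region where one parental copy is lost,
contamination by normal cells leaves an expected tumor MAF of
`(1 − p)/(2 − p)`. Because this approaches 0.5 at low purity, the
decision threshold is calibrated per sample: 10,000 hypothetical SNPs
per class (loss vs balanced) are simulated binomially at the sample's
coverage (we use the median depth of informative SNPs; the summary
statistic is not dictated by the model and the median is robust), MAFs
are averaged over disjoint consecutive blocks of 10 (1,000 points per
class), and thresholds 0–0.50 in steps of 0.01 are scored. Among
thresholds with sensitivity and specificity both above 0.8 the maximum-F1
threshold is chosen; if none qualifies the sample is flagged as lacking
power and contributes nothing downstream.

Gene-level testing takes the 10 informative SNPs (tumor and normal depth
≥ 20) nearest the gene midpoint (mean of start/end coordinates; distance
ties broken toward the lower coordinate), and compares tumor vs normal
MAF with a one-tailed paired t test (tumor < normal). Pairing is our
choice — the tumor and normal MAFs are measured at the same positions,
so the paired test is the natural one-tailed t test here. A gene is
flagged when its Benjamini–Hochberg FDR (corrected once per sample
across all tested genes) is below 5% and its mean tumor MAF falls below
the calibrated threshold. Per mouse, the AI gene set is the union over
powered regions. Cohort enrichment per gene is an upper-tail binomial
test of k-of-n mice at the background rate (mean per-mouse AI fraction,
computed over powered mice), BH-corrected over genes.

## Cancer cell prevalence and multiplicity

A mutation carried by a fraction `C` of cancer cells, with `m` mutated
copies per cell, has expected variant allele frequency

    v_exp = p·m·C / (p·CN_T + (1 − p)·CN_N)

The variant read count is Binomial(r_tot, v_exp). The likelihood is
evaluated on a grid of C from 0 to 1 in steps of 0.01 and normalized — a
discrete posterior under a flat prior. The point estimate is the grid
argmax and the interval is the central 95% of the normalized mass
(expanded to contain the argmax in skewed corner cases); the
construction of the interval is our choice, as is reporting the MAP
rather than the posterior mean (the MAP matches the closed-form maximum
`min(1, v̂·(p·CN_T + (1−p)·CN_N)/(p·m))` to within one grid step, which
makes it independently checkable).

Multiplicity: at `CN_T ∈ {1, 2}` only `m = 1` is plausible. In gained
segments every `m ∈ [1, CN_T]` is enumerated and values implying a raw
prevalence above 1 + 0.05 are ruled out (the 0.05 slack absorbs binomial
noise at ~300× coverage); if more than one m survives the prevalence is
missing. Zero variant reads give prevalence 0 regardless of m. Mutations
falling in `CN_T = 0` segments are reported missing with a warning — the
read model has no support there.

Regions are excluded from prevalence analysis when the maximum VAF over
all mutations is ≤ 0.02 or when no copy-number profile exists; exclusions
are first-class report entries and shrink the denominator for the
ubiquitous / partially shared / private categorization.

Mutations are clustered on their per-region prevalence vectors with
DBSCAN over a radius sweep (0.02–0.30, step 0.02, minimum neighborhood
2); the radius with the best silhouette wins, subject to quality gates
(silhouette ≥ 0.25, ≤ 20% noise points; residual noise attached to the
nearest centroid). When no density solution qualifies, affinity
propagation provides the fallback grouping. Rows with missing values are
clustered on the regions shared by all mutations when one exists,
otherwise excluded and reported as singletons.

## Mutation QC

Discovery (exome) filter per region: depth ≥ 10, variant reads ≥ 3,
VAF ≥ 1%, at least one variant read per strand. Validation (targeted
amplicon, higher depth and error): VAF ≥ 1%, variant reads ≥ 5, forward
variant reads ≥ 3 and reverse variant reads ≥ 3, each in at least one
region (the criteria may be met in different regions). Per-region
presence for the spatial categories — which no external definition pins
down — is VAF ≥ 1% with ≥ 3 variant reads. Knock-in transgene mutations
are excluded from the categorization.

## Subclone trees

Under the infinite sites assumption an ancestor's prevalence is at least
its descendant's in every region, and siblings' prevalences sum to at
most their parent's. Each ordered cluster pair is tested for admissible
ancestry: i may parent j unless some region has
`mean_j − mean_i > z(α)·sqrt(sd_i² + sd_j²)` (one-sided, default α 0.05,
sd floored at 0.02 so small clusters are not spuriously ordered). Every
rooted labeled tree over the clusters — `n^(n−2)` of them, enumerated
exactly via Prüfer sequences, cached per size, practical to 8 clusters —
is scored by the number of parent–child precedence violations plus the
number of per-region sum-rule violations (children sum > parent + 0.10).
All minimal-cost trees are returned in deterministic order; ties are
reported, not broken silently, and topology is only labeled when the
minimal set agrees unanimously. The root is the knock-in transgene
cluster (prevalence fixed at 1 in every region — every cancer cell
carries the knock-ins by construction of the model system), added when
absent. Exhaustive search replaces heuristic tree search deliberately:
at 2–7 clusters per tumor, exactness is affordable and testable.

Topology: linear when every node has at most one child, branched
otherwise. Two synchronous primary tumors are flagged when the root has
≥ 2 children and no non-root cluster sits at prevalence ≥ 0.5 in every
analyzed region — two independently initiated tumors share no clonal
expansion beyond the transgenes.

## Synthetic cohorts

The generator produces the study design downstream stages assume: 12
mice (half KPC, half KPTC), 3 regions each, 2–7 mutation clusters with
linear / branched / two-primary truth trees, per-region purity drawn in
(0.45, 0.95), amplicon read counts Binomial at Poisson-300× depth with
50/50 binomial strand splits, probe log ratios at 10 kb spacing with
Gaussian noise (sd 0.15) and a floor of −6 on the log ratio (arrays
saturate rather than diverge on pure-sample homozygous deletions),
germline SNP counts at Poisson-70× depth, and qPCR standards with Ct
linear in purity (slope 10 Ct per purity unit, intercept 20, noise sd
0.15) — linear so that the fitted standard-curve model is well-specified;
the assay's true chemistry is not modeled. Cluster prevalence matrices
obey the sum rule exactly and are pairwise separated by ≥ 0.15 (max over
regions) so that clusters are in principle recoverable; linear chains use
a margin-guaranteed descending ladder, branched and two-primary trees use
budgeted rejection sampling. Branched (non-two-primary) trees always
include one high-prevalence clonal expansion so the synchronous-primary
signature stays exclusive to two-primary truths. Multiplicity is 1
except in gained segments, where it is uniform on [1, CN_T]. The spatial
arrangement of subclones across regions is drawn freely subject to the
tree — no external constraint pins it down.

The default genome is a scaled-down set of six 30 Mb autosomes plus a
20 Mb chrX (tests and the reproduction script scale further, down to
three or four chromosomes of 8–10 Mb) so that complete cohorts run in
seconds; chromosome count and lengths do not enter any statistic the
pipeline computes, only the amount of data. What the generator does not
emulate: sequencing error and mapping artifacts, indels, read-level data,
GC/wave artifacts on arrays, subclonal copy number, and kinship between
regions beyond the prevalence matrix. Passing tests therefore demonstrate
correctness of the statistical machinery under the stated model, not
robustness to real-data artifacts upstream of these inputs.

## Numerical choices

Grid step 0.01 for prevalence and thresholds; binomial likelihoods in
log space with max-shift normalization; half-up integer rounding for
copy number (deterministic, no banker's rounding); posterior argmax ties
resolved toward the lower grid value; permutation p-values computed as
(1 + exceedances)/(1 + permutations); all randomness flows from a single
master seed through named sub-seeds (`SeedSequence`), so every artifact
is byte-reproducible. Degenerate inputs (empty tracks, single purity
level, all-zero likelihoods, fewer than two informative SNPs or usable
mutations) raise or warn explicitly rather than returning silent
defaults.

## Known limitations

Cluster-level (not mutation-level) tree search; no subclonal copy
number; no joint Bayesian clustering across regions (each mutation's
prevalence is estimated independently before clustering); exhaustive
tree search is capped at 8 clusters; the DBSCAN radius sweep can
over-split when cluster separation approaches the noise scale, in which
case ties and ambiguous topology are reported rather than resolved.
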