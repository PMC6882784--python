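"""Ground-truthed synthetic multi-region tumor cohorts.

Generates cohorts with the statistical structure of a multi-region mouse
pancreatic-cancer study: per mouse, a subclone truth tree rooted at the
knock-in transgene cluster with per-region cancer cell prevalences
obeying the sum rule, binomially sampled amplicon read counts at ~300x
for each mutation (expected VAF from the purity/copy-number/prevalence
relation), probe-level aCGH log ratios with Gaussian noise, germline
heterozygous SNP allele counts at ~70x, and a qPCR purity standard curve
with per-region sample readouts.  Every quantity the downstream stages
estimate (purity, integer copy number, allelic imbalance, prevalence,
tree topology) has a recorded truth value.

The genome is a scaled-down set of autosomes plus chrX so that full
pipelines run in seconds; all rates, depths and noise levels mirror the
study design (three regions per tumor, 2-7 mutation clusters, purity
drawn in (0, 1], linear / branched / two-primary topologies).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .prevalence import expected_vaf

__all__ = [
    "Genome",
    "DEFAULT_GENOME",
    "TruthTree",
    "SimulatedMouse",
    "simulate_tree",
    "simulate_mutation_reads",
    "simulate_acgh",
    "simulate_snp_counts",
    "simulate_qpcr",
    "simulate_mouse",
    "simulate_cohort",
    "make_genes",
    "neutral_profile",
    "plant_event",
]

TOPOLOGIES = ("linear", "branched", "two_primary")

# aCGH ratios saturate at the low end; floor the tumor/normal mixture ratio
LOG2R_FLOOR = -6.0


@dataclass(frozen=True)
class Genome:
    """Chromosome names and lengths of the simulated genome."""

    chromosomes: dict

    @property
    def autosomes(self) -> list[str]:
        return [c for c in self.chromosomes if c not in ("chrX", "chrY")]

    def total_autosomal_length(self) -> int:
        return sum(self.chromosomes[c] for c in self.autosomes)


DEFAULT_GENOME = Genome(
    chromosomes={f"chr{i}": 30_000_000 for i in range(1, 7)} | {"chrX": 20_000_000}
)


def make_genes(genome: Genome, n_per_chrom: int = 40, seed: int = 0) -> pd.DataFrame:
    """Synthetic gene coordinate table (BED-like, 0-based half-open)."""
    rng = np.random.default_rng(seed)
    rows = []
    k = 0
    for chrom, length in genome.chromosomes.items():
        starts = np.sort(rng.integers(0, length - 200_000, size=n_per_chrom))
        for s in starts:
            size = int(rng.integers(20_000, 200_000))
            rows.append((chrom, int(s), int(s) + size, f"Gene{k:04d}"))
            k += 1
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "gene"])


# ---------------------------------------------------------------------------
# copy number profiles


def neutral_profile(genome: Genome, cn: int = 2) -> pd.DataFrame:
    rows = [(c, 0, l, cn) for c, l in genome.chromosomes.items()]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_t"])


def plant_event(profile: pd.DataFrame, chrom: str, start: int, end: int, cn_t: int) -> pd.DataFrame:
    """Overwrite ``[start, end)`` on ``chrom`` with copy number ``cn_t``."""
    rows = []
    for r in profile.itertuples(index=False):
        if r.chrom != chrom or r.end <= start or r.start >= end:
            rows.append(tuple(r))
            continue
        if r.start < start:
            rows.append((r.chrom, r.start, start, r.cn_t))
        rows.append((r.chrom, max(r.start, start), min(r.end, end), cn_t))
        if r.end > end:
            rows.append((r.chrom, end, r.end, r.cn_t))
    out = pd.DataFrame(rows, columns=["chrom", "start", "end", "cn_t"])
    return out.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def _cn_at(profile: pd.DataFrame, chrom: str, pos: int) -> int:
    sel = profile[(profile["chrom"] == chrom) & (profile["start"] <= pos) & (profile["end"] > pos)]
    if len(sel) == 0:
        return 2
    return int(sel["cn_t"].iloc[0])


# ---------------------------------------------------------------------------
# truth trees


@dataclass
class TruthTree:
    """Ground-truth subclone hierarchy.

    ``parents[k]`` is the parent of cluster k (-1 for the root cluster 0,
    the knock-in transgene cluster); ``prevalence[k, r]`` is the fraction
    of cancer cells in region r carrying cluster k's mutations.
    """

    parents: list
    prevalence: np.ndarray
    topology: str

    @property
    def n_clusters(self) -> int:
        return len(self.parents)

    @property
    def n_regions(self) -> int:
        return self.prevalence.shape[1]

    def children(self, k: int) -> list[int]:
        return [i for i, p in enumerate(self.parents) if p == k]

    def check_sum_rule(self, tol: float = 1e-9) -> bool:
        for k in range(self.n_clusters):
            kids = self.children(k)
            if kids and np.any(
                self.prevalence[kids].sum(axis=0) > self.prevalence[k] + tol
            ):
                return False
        return True


def _pairwise_separated(C: np.ndarray, margin: float) -> bool:
    n = C.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            if np.max(np.abs(C[i] - C[j])) < margin:
                return False
    return True


def _sample_shape(n_clusters: int, topology: str, rng) -> list[int]:
    if topology == "linear":
        return [-1] + list(range(n_clusters - 1))
    if topology == "two_primary":
        parents = [-1, 0, 0]
        for k in range(3, n_clusters):
            parents.append(int(rng.integers(1, k)))
        return parents
    # branched: random attachment, forced to contain a multifurcation
    for _ in range(100):
        parents = [-1] + [int(rng.integers(0, k)) for k in range(1, n_clusters)]
        counts = np.bincount([p for p in parents if p >= 0], minlength=n_clusters)
        if np.any(counts >= 2):
            return parents
    parents[-1] = parents[-2]  # force siblings
    return parents


def _linear_ladder(n, n_regions, margin, rng) -> np.ndarray | None:
    """Decreasing prevalence ladder for a chain, margin-separated by design."""
    depth = n - 1
    # stay >= one margin below the root cluster (prevalence 1 everywhere)
    top = 1.0 - rng.uniform(1.05, 1.5) * margin
    lo_gap = 1.05 * margin
    hi_gap = max(lo_gap + 1e-6, min(1.8 * margin, (top - 0.02) / max(depth - 1, 1)))
    if hi_gap < lo_gap:
        return None
    gaps = rng.uniform(lo_gap, hi_gap, size=max(depth - 1, 0))
    base = np.concatenate([[top], top - np.cumsum(gaps)])
    if base[-1] < 0:
        return None
    C = np.zeros((n, n_regions))
    C[0] = 1.0
    for r in range(n_regions):
        # region 0 keeps the exact ladder so margin separation is guaranteed
        scale = 1.0 if r == 0 else rng.uniform(0.88, 1.0)
        jitter = np.zeros(depth) if r == 0 else rng.uniform(-0.02, 0.02, size=depth)
        vals = np.clip(np.sort(base * scale + jitter)[::-1], 0.0, 0.98)
        C[1:, r] = np.round(vals, 3)
    return C


def _fill_prevalence(parents, n_regions, topology, margin, rng) -> np.ndarray | None:
    n = len(parents)
    if topology == "linear":
        return _linear_ladder(n, n_regions, margin, rng)
    C = np.zeros((n, n_regions))
    C[0] = 1.0
    if topology == "two_primary":
        # two root lineages with disjoint high-prevalence region support
        h1, h2 = rng.uniform(0.55, 0.9, size=2)
        m1, m2 = rng.uniform(0.05, 0.35, size=2)
        if m1 + m2 > 1:
            m1, m2 = m1 / (m1 + m2 + 0.1), m2 / (m1 + m2 + 0.1)
        C[1, 0] = h1
        C[2, n_regions - 1] = h2
        mid = list(range(1, n_regions - 1))
        for r in mid:
            C[1, r] = m1
            C[2, r] = m2
        start = 3
    else:
        start = 1
    budget = {}  # node -> remaining per-region budget for further children
    for k in range(n):
        budget[k] = C[k].copy() if k < start else None
    budget[0] = C[0] - C[[1, 2]].sum(axis=0) if topology == "two_primary" else C[0].copy()
    for k in range(1, start):
        budget[k] = C[k].copy()
    for k in range(start, n):
        pa = parents[k]
        b = budget[pa]
        if topology == "branched" and k == 1:
            # a high-prevalence clonal expansion in every region, so that a
            # plain branched tumor is distinguishable from synchronous
            # primaries (which lack any ubiquitous high-prevalence cluster)
            C[k] = np.round(rng.uniform(0.55, 0.9, size=n_regions), 3)
        else:
            frac = rng.uniform(0.2, 0.9, size=n_regions)
            C[k] = np.round(frac * np.maximum(b - 0.02, 0.0), 3)
        budget[pa] = b - C[k]
        budget[k] = C[k].copy()
    return C


def simulate_tree(
    n_clusters: int,
    topology: str,
    n_regions: int = 3,
    seed: int = 0,
    margin: float = 0.15,
    max_tries: int = 2000,
) -> TruthTree:
    """Draw a ground-truth subclone tree.

    ``n_clusters`` counts the root (knock-in) cluster; 2-7 mutation groups
    per tumor is the realistic range.  Prevalences obey the sum rule in
    every region and cluster prevalence vectors are pairwise separated by
    at least ``margin`` (max over regions) so that the clusters are
    recoverable downstream.
    """
    if n_clusters < 2:
        raise ValueError("need at least 2 clusters (root + one descendant)")
    if topology not in TOPOLOGIES:
        raise ValueError(f"topology must be one of {TOPOLOGIES}")
    if topology == "two_primary" and n_clusters < 3:
        raise ValueError("two_primary requires >= 3 clusters (root + 2 lineages)")
    if topology == "branched" and n_clusters < 3:
        raise ValueError("branched requires >= 3 clusters (a node with 2 children)")
    if topology == "two_primary" and n_regions < 2:
        raise ValueError("two_primary requires >= 2 regions for disjoint support")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        parents = _sample_shape(n_clusters, topology, rng)
        C = _fill_prevalence(parents, n_regions, topology, margin, rng)
        if C is None or not _pairwise_separated(C, margin):
            continue
        tree = TruthTree(parents=parents, prevalence=C, topology=topology)
        if tree.check_sum_rule():
            return tree
    raise RuntimeError(
        f"could not draw a margin-separated tree (n_clusters={n_clusters}, "
        f"margin={margin}) in {max_tries} tries"
    )


# ---------------------------------------------------------------------------
# read counts, probes, SNPs, qPCR


def simulate_mutation_reads(
    tree: TruthTree,
    n_mut_per_cluster: int,
    coverage_mean: float,
    purity_per_region,
    cn_profiles: dict[str, pd.DataFrame] | None,
    seed: int = 0,
    genome: Genome = DEFAULT_GENOME,
    region_names: list[str] | None = None,
    n_transgenes: int = 2,
) -> pd.DataFrame:
    """Binomial amplicon read counts for every mutation in every region.

    The variant read count in region r is Binomial(total, v_exp) with
    v_exp from the prevalence relation using the region's purity, the
    mutation's multiplicity and the local tumor copy number; totals are
    Poisson around ``coverage_mean`` and variant reads split between
    strands as Binomial(var, 0.5).  Multiplicity is 1 unless the mutation
    lands in a gained segment, where it is uniform on [1, CN_T].  The
    first ``n_transgenes`` mutations of the root cluster are flagged as
    knock-in transgene mutations.
    """
    if coverage_mean <= 0:
        raise ValueError("coverage_mean must be positive")
    rng = np.random.default_rng(seed)
    purity = np.asarray(purity_per_region, dtype=float)
    n_regions = tree.n_regions
    if region_names is None:
        region_names = [f"T{i + 1}" for i in range(n_regions)]
    if cn_profiles is None:
        cn_profiles = {r: neutral_profile(genome) for r in region_names}
    autos = genome.autosomes
    lengths = np.array([genome.chromosomes[c] for c in autos], dtype=float)
    chrom_p = lengths / lengths.sum()

    rows = []
    mut_id = 0
    for cluster in range(tree.n_clusters):
        for i in range(n_mut_per_cluster):
            for _ in range(100):
                chrom = autos[int(rng.choice(len(autos), p=chrom_p))]
                pos = int(rng.integers(0, genome.chromosomes[chrom]))
                cns = [_cn_at(cn_profiles[r], chrom, pos) for r in region_names]
                if min(cns) >= 1:
                    break
            min_cn = min(cns)
            m = 1 if min_cn <= 2 else int(rng.integers(1, min_cn + 1))
            is_tg = cluster == 0 and i < n_transgenes
            row = {
                "mut_id": f"M{mut_id:03d}",
                "cluster": cluster,
                "chrom": chrom,
                "pos": pos,
                "m": m,
                "is_transgene": bool(is_tg),
            }
            for r_idx, r in enumerate(region_names):
                C = float(tree.prevalence[cluster, r_idx])
                p = float(purity[r_idx])
                cn_t = cns[r_idx]
                v = expected_vaf(p, min(m, cn_t), C, cn_t) if C > 0 else 0.0
                tot = int(rng.poisson(coverage_mean))
                var = int(rng.binomial(tot, v)) if tot > 0 else 0
                fwd = int(rng.binomial(var, 0.5)) if var > 0 else 0
                row[f"cn_{r}"] = cn_t
                row[f"tot_{r}"] = tot
                row[f"var_{r}"] = var
                row[f"fwd_{r}"] = fwd
                row[f"rev_{r}"] = var - fwd
            rows.append(row)
            mut_id += 1
    return pd.DataFrame(rows)


def simulate_acgh(
    cn_profile: pd.DataFrame,
    purity: float,
    probe_spacing: int = 10_000,
    noise_sd: float = 0.15,
    seed: int = 0,
    cn_n: int = 2,
) -> pd.DataFrame:
    """Probe-level log2 tumor/normal ratios for one region.

    Each probe's expected value is log2((p*CN_T + (1-p)*CN_N) / CN_N) for
    the segment it falls in, with additive Gaussian noise; the mixture
    ratio is floored so a homozygous deletion in a pure sample saturates
    rather than diverging, as hybridization arrays do.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for seg in cn_profile.itertuples(index=False):
        pos = np.arange(seg.start, seg.end, probe_spacing)
        if len(pos) == 0:
            continue
        mix = (purity * seg.cn_t + (1 - purity) * cn_n) / cn_n
        base = np.log2(mix) if mix > 0 else LOG2R_FLOOR
        base = max(base, LOG2R_FLOOR)
        vals = base + rng.normal(0.0, noise_sd, size=len(pos)) if noise_sd > 0 else np.full(len(pos), base)
        rows.append(pd.DataFrame({"chrom": seg.chrom, "pos": pos, "log2ratio": vals}))
    out = pd.concat(rows, ignore_index=True)
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


def simulate_snp_counts(
    regions_with_loss: list[tuple],
    purity: float,
    coverage: float = 70,
    n_snps: int = 2000,
    seed: int = 0,
    genome: Genome = DEFAULT_GENOME,
    normal_coverage: float | None = None,
) -> pd.DataFrame:
    """Germline heterozygous SNP allele counts in tumor and matched normal.

    ``regions_with_loss`` lists ``(chrom, start, end)`` intervals where one
    parental copy is lost in the tumor.  Normal counts are
    Binomial(DP, 0.5); tumor counts at SNPs inside a loss interval are
    binomial with the lost allele's expected frequency (1-p)/(2-p), the
    lost allele chosen at random per SNP, and 0.5 elsewhere.  Depths are
    Poisson around ``coverage`` (tumor) and ``normal_coverage``.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    rng = np.random.default_rng(seed)
    if normal_coverage is None:
        normal_coverage = coverage
    autos = genome.autosomes
    lengths = np.array([genome.chromosomes[c] for c in autos], dtype=float)
    chrom_idx = rng.choice(len(autos), size=n_snps, p=lengths / lengths.sum())
    q_loss = (1 - purity) / (2 - purity)
    rows = []
    for i in range(n_snps):
        chrom = autos[int(chrom_idx[i])]
        pos = int(rng.integers(0, genome.chromosomes[chrom]))
        in_loss = any(c == chrom and s <= pos < e for c, s, e in regions_with_loss)
        n_dp = max(int(rng.poisson(normal_coverage)), 1)
        t_dp = max(int(rng.poisson(coverage)), 1)
        n_ref = int(rng.binomial(n_dp, 0.5))
        if in_loss:
            lost_is_ref = bool(rng.integers(0, 2))
            q = q_loss if lost_is_ref else 1 - q_loss
            t_ref = int(rng.binomial(t_dp, q))
        else:
            t_ref = int(rng.binomial(t_dp, 0.5))
        rows.append((chrom, pos, t_ref, t_dp - t_ref, n_ref, n_dp - n_ref, in_loss))
    out = pd.DataFrame(
        rows, columns=["chrom", "pos", "t_ref", "t_alt", "n_ref", "n_alt", "in_loss"]
    )
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


QPCR_STANDARDS = (0.0, 0.1, 0.2, 0.4, 0.6, 0.8, 1.0)


def simulate_qpcr(
    sample_purities: dict[str, float],
    standards=QPCR_STANDARDS,
    slope: float = 10.0,
    intercept: float = 20.0,
    noise_sd: float = 0.15,
    n_replicates: int = 3,
    seed: int = 0,
):
    """qPCR standard-curve readouts and per-sample Cts.

    Ct rises linearly with tumor purity (the assay's template, the
    un-recombined LSL cassette, is depleted in tumor cells); standards at
    the study's dilution levels are read in triplicate with Gaussian
    noise.  Returns ``(standards_df, samples_df)``.
    """
    rng = np.random.default_rng(seed)
    std_rows = [
        (float(x), float(slope * x + intercept + rng.normal(0, noise_sd)))
        for x in standards
        for _ in range(n_replicates)
    ]
    standards_df = pd.DataFrame(std_rows, columns=["purity_fraction", "ct"])
    smp_rows = [
        (name, rep, float(slope * p + intercept + rng.normal(0, noise_sd)))
        for name, p in sample_purities.items()
        for rep in range(n_replicates)
    ]
    samples_df = pd.DataFrame(smp_rows, columns=["sample", "replicate", "ct"])
    return standards_df, samples_df


# ---------------------------------------------------------------------------
# whole-mouse / cohort assembly


@dataclass
class SimulatedMouse:
    """One simulated mouse with all per-region inputs and the ground truth."""

    mouse_id: str
    genotype: str
    regions: list
    purity: dict
    tree: TruthTree
    mutations: pd.DataFrame
    cn_profiles: dict = field(default_factory=dict)
    probes: dict = field(default_factory=dict)
    snps: dict = field(default_factory=dict)
    loss_regions: dict = field(default_factory=dict)
    qpcr_standards: pd.DataFrame | None = None
    qpcr_samples: pd.DataFrame | None = None
    genome: Genome = DEFAULT_GENOME


def _region_cn_profile(genome: Genome, rng, recurrent_deletion=None,
                       random_focal=True):
    """A per-region profile with one arm-level event and a couple of focal ones."""
    profile = neutral_profile(genome)
    autos = genome.autosomes
    # one large-scale event spanning >= 50% of a chromosome
    chrom = autos[int(rng.integers(0, len(autos)))]
    length = genome.chromosomes[chrom]
    span = int(rng.uniform(0.55, 0.95) * length)
    start = int(rng.integers(0, length - span))
    cn = int(rng.choice([1, 3]))
    profile = plant_event(profile, chrom, start, start + span, cn)
    if random_focal:
        # one focal amplification and one focal deletion (< 4 Mb, >= 5 probes)
        for cn_focal in (int(rng.integers(5, 9)), 0):
            fchrom = autos[int(rng.integers(0, len(autos)))]
            fsize = int(rng.integers(200_000, 2_000_000))
            fstart = int(rng.integers(0, genome.chromosomes[fchrom] - fsize))
            profile = plant_event(profile, fchrom, fstart, fstart + fsize, cn_focal)
    if recurrent_deletion is not None:
        c, s, e = recurrent_deletion
        profile = plant_event(profile, c, s, e, 0)
    return profile


def simulate_mouse(
    mouse_id: str = "KPC1",
    genotype: str = "KPC",
    n_regions: int = 3,
    seed: int = 0,
    topology: str | None = None,
    n_clusters: int | None = None,
    coverage_mean: float = 300.0,
    snp_coverage: float = 70.0,
    n_snps: int = 1500,
    n_mut_per_cluster: int = 5,
    probe_spacing: int = 10_000,
    acgh_noise_sd: float = 0.15,
    margin: float = 0.15,
    purity_range: tuple = (0.45, 0.95),
    genome: Genome = DEFAULT_GENOME,
    recurrent_deletion: tuple | None = None,
    random_focal: bool = True,
    with_acgh: bool = True,
    with_snps: bool = True,
) -> SimulatedMouse:
    """Simulate one mouse end to end; fully deterministic under ``seed``."""
    rng = np.random.default_rng(seed)
    regions = [f"T{i + 1}" for i in range(n_regions)]
    if topology is None:
        topology = str(rng.choice(TOPOLOGIES))
    if n_clusters is None:
        lo = 2 if topology == "linear" else 3
        n_clusters = int(rng.integers(lo, 8))
    purity = {r: float(rng.uniform(*purity_range)) for r in regions}
    tree = simulate_tree(
        n_clusters, topology, n_regions, seed=int(rng.integers(2**31)), margin=margin
    )
    cn_profiles = {
        r: _region_cn_profile(genome, rng, recurrent_deletion, random_focal)
        for r in regions
    }
    mutations = simulate_mutation_reads(
        tree,
        n_mut_per_cluster,
        coverage_mean,
        [purity[r] for r in regions],
        cn_profiles,
        seed=int(rng.integers(2**31)),
        genome=genome,
        region_names=regions,
    )
    probes, snps, loss_regions = {}, {}, {}
    for r in regions:
        if with_acgh:
            probes[r] = simulate_acgh(
                cn_profiles[r],
                purity[r],
                probe_spacing=probe_spacing,
                noise_sd=acgh_noise_sd,
                seed=int(rng.integers(2**31)),
            )
        loss = [
            (s.chrom, int(s.start), int(s.end))
            for s in cn_profiles[r].itertuples(index=False)
            if s.cn_t == 1 and s.chrom not in ("chrX", "chrY")
        ]
        loss_regions[r] = loss
        if with_snps:
            snps[r] = simulate_snp_counts(
                loss,
                purity[r],
                coverage=snp_coverage,
                n_snps=n_snps,
                seed=int(rng.integers(2**31)),
                genome=genome,
            )
    standards_df, samples_df = simulate_qpcr(
        purity, seed=int(rng.integers(2**31))
    )
    return SimulatedMouse(
        mouse_id=mouse_id,
        genotype=genotype,
        regions=regions,
        purity=purity,
        tree=tree,
        mutations=mutations,
        cn_profiles=cn_profiles,
        probes=probes,
        snps=snps,
        loss_regions=loss_regions,
        qpcr_standards=standards_df,
        qpcr_samples=samples_df,
        genome=genome,
    )


def simulate_cohort(
    n_mice: int = 12,
    seed: int = 0,
    recurrent_deletion: tuple | None = ("chr3", 10_000_000, 10_250_000),
    recurrent_fraction: float = 0.75,
    **mouse_kwargs,
) -> list[SimulatedMouse]:
    """A cohort of mice, half KPC and half KPTC, mixed topologies.

    A recurrent focal deletion is planted in ``recurrent_fraction`` of the
    mice (one region each) to exercise cross-mouse event matching.
    """
    if n_mice < 1:
        raise ValueError("cohort needs at least one mouse")
    rng = np.random.default_rng(seed)
    n_recurrent = int(round(recurrent_fraction * n_mice))
    mice = []
    for i in range(n_mice):
        genotype = "KPC" if i < (n_mice + 1) // 2 else "KPTC"
        planted = recurrent_deletion if (recurrent_deletion and i < n_recurrent) else None
        mice.append(
            simulate_mouse(
                mouse_id=f"{genotype}{i + 1}",
                genotype=genotype,
                seed=int(rng.integers(2**31)),
                recurrent_deletion=planted,
                **mouse_kwargs,
            )
        )
    return mice
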