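"""Exome-wide allelic imbalance detection from germline heterozygous SNPs.

A germline heterozygous SNP has minor allele frequency (MAF) 0.5 in normal
tissue.  In a tumor region where one parental copy is lost, normal-cell
contamination shifts the expected tumor MAF to

    MAF_tumor = (1 - p) / (2 - p)

for tumor purity p.  Because this expectation approaches 0.5 at low purity,
the MAF threshold separating balanced from imbalanced positions must be
calibrated per sample: read counts for a batch of hypothetical SNPs are
simulated binomially at the sample's coverage for the loss class and the
balanced class, subset-averaged, and a threshold grid is scored for
sensitivity/specificity/F1.  Gene-level imbalance is then called from the
ten informative SNPs nearest the gene midpoint with a one-tailed paired
t test, Benjamini-Hochberg corrected across genes, with the mean tumor MAF
required to fall below the calibrated threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "expected_loss_maf",
    "ThresholdCalibration",
    "calibrate_threshold",
    "gene_ai_test",
    "sample_ai_calls",
    "mouse_ai_union",
    "ai_enrichment",
]


def expected_loss_maf(p: float) -> float:
    """Expected tumor MAF at a one-copy-loss locus for purity ``p``."""
    if not 0 <= p <= 1:
        raise ValueError(f"purity must be in [0, 1], got {p}")
    return (1 - p) / (2 - p)


@dataclass(frozen=True)
class ThresholdCalibration:
    """Per-sample MAF threshold calibration result.

    ``lacking_power`` is set when no threshold achieves sensitivity and
    specificity both above ``min_sens_spec`` — typically at low purity,
    where the loss-class MAF is indistinguishable from 0.5.
    """

    purity: float
    coverage: int
    threshold: float | None
    sensitivity: float
    specificity: float
    f1: float
    lacking_power: bool


def calibrate_threshold(
    p: float,
    coverage: int,
    n_snps: int = 10_000,
    subset_size: int = 10,
    grid_step: float = 0.01,
    min_sens_spec: float = 0.8,
    seed: int = 0,
) -> ThresholdCalibration:
    """Simulation-based calibration of the per-sample MAF threshold.

    Simulates minor-allele read counts for ``n_snps`` hypothetical SNPs in
    the one-copy-loss class (success probability ``(1-p)/(2-p)``) and the
    balanced class (0.5) at the given coverage, averages MAF over disjoint
    subsets of ``subset_size`` (10,000 SNPs -> 1,000 points per class), and
    sweeps thresholds 0..0.50 in ``grid_step`` increments scoring the rule
    "subset mean MAF below threshold = imbalance".  Among thresholds with
    sensitivity and specificity both exceeding ``min_sens_spec``, the one
    with maximum F1 is returned; if none qualifies the sample is flagged
    as lacking power.
    """
    if coverage < 1:
        raise ValueError("coverage must be >= 1")
    if not 0 < p <= 1:
        raise ValueError("purity must be in (0, 1]")
    if n_snps % subset_size != 0:
        raise ValueError("subset_size must divide n_snps")

    rng = np.random.default_rng(seed)
    q = expected_loss_maf(p)
    loss_counts = rng.binomial(coverage, q, size=n_snps)
    norm_counts = rng.binomial(coverage, 0.5, size=n_snps)
    loss_maf = np.minimum(loss_counts, coverage - loss_counts) / coverage
    norm_maf = np.minimum(norm_counts, coverage - norm_counts) / coverage
    loss_pts = loss_maf.reshape(-1, subset_size).mean(axis=1)
    norm_pts = norm_maf.reshape(-1, subset_size).mean(axis=1)

    thresholds = np.round(np.arange(0.0, 0.50 + 1e-9, grid_step), 10)
    best = None
    for t in thresholds:
        tp = float((loss_pts < t).mean())  # sensitivity
        tn = float((norm_pts >= t).mean())  # specificity
        n_tp = (loss_pts < t).sum()
        n_fp = (norm_pts < t).sum()
        prec = n_tp / (n_tp + n_fp) if (n_tp + n_fp) else 0.0
        f1 = 2 * prec * tp / (prec + tp) if (prec + tp) else 0.0
        if tp > min_sens_spec and tn > min_sens_spec:
            if best is None or f1 > best[0] + 1e-12:
                best = (f1, float(t), tp, tn)
    if best is None:
        return ThresholdCalibration(p, coverage, None, 0.0, 0.0, 0.0, True)
    f1, t, sens, spec = best
    return ThresholdCalibration(p, coverage, t, sens, spec, f1, False)


def _maf(ref: np.ndarray, alt: np.ndarray) -> np.ndarray:
    dp = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(dp > 0, np.minimum(ref, alt) / dp, np.nan)


def gene_ai_test(
    gene_start: int,
    gene_end: int,
    snps: pd.DataFrame,
    k: int = 10,
    min_dp: int = 20,
):
    """Test one gene for allelic imbalance from its nearest informative SNPs.

    ``snps`` must carry columns ``pos, t_ref, t_alt, n_ref, n_alt``.
    Positions with tumor or normal depth below ``min_dp`` are uninformative
    and never selected.  The ``k`` informative SNPs closest to the gene
    midpoint (mean of start and end; distance ties broken by lower
    coordinate) are compared between tumor and normal with a one-tailed
    paired t test (alternative: tumor MAF < normal MAF).

    Returns ``(p_value, mean_tumor_maf, n_snps_used)`` or ``None`` when
    fewer than two informative SNPs exist (the gene is skipped with a
    warning).
    """
    mid = (gene_start + gene_end) / 2.0
    t_dp = snps["t_ref"].to_numpy() + snps["t_alt"].to_numpy()
    n_dp = snps["n_ref"].to_numpy() + snps["n_alt"].to_numpy()
    informative = (t_dp >= min_dp) & (n_dp >= min_dp)
    if informative.sum() < 2:
        warnings.warn(f"gene at {gene_start}-{gene_end}: <2 informative SNPs, skipped")
        return None
    sub = snps.loc[informative].copy()
    dist = np.abs(sub["pos"].to_numpy() - mid)
    order = np.lexsort((sub["pos"].to_numpy(), dist))
    sel = sub.iloc[order[: min(k, len(order))]]
    t_maf = _maf(sel["t_ref"].to_numpy(float), sel["t_alt"].to_numpy(float))
    n_maf = _maf(sel["n_ref"].to_numpy(float), sel["n_alt"].to_numpy(float))
    if np.allclose(t_maf, n_maf):
        pval = 1.0
    else:
        pval = float(stats.ttest_rel(t_maf, n_maf, alternative="less").pvalue)
        if np.isnan(pval):
            pval = 1.0
    return pval, float(np.mean(t_maf)), int(len(sel))


def sample_ai_calls(
    genes: pd.DataFrame,
    snps: pd.DataFrame,
    threshold: float,
    k: int = 10,
    min_dp: int = 20,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Gene-level allelic imbalance calls for one tumor region.

    Runs :func:`gene_ai_test` for every gene (columns ``gene, chrom, start,
    end``; SNPs matched within chromosome), applies Benjamini-Hochberg
    correction across all tested genes, and flags a gene as AI when its
    FDR is below ``fdr`` and its mean tumor MAF is below the calibrated
    ``threshold``.
    """
    rows = []
    for g in genes.itertuples(index=False):
        chrom_snps = snps[snps["chrom"] == g.chrom]
        res = gene_ai_test(g.start, g.end, chrom_snps, k=k, min_dp=min_dp)
        if res is None:
            continue
        pval, mean_t_maf, n_used = res
        rows.append((g.gene, g.chrom, pval, mean_t_maf, n_used))
    out = pd.DataFrame(rows, columns=["gene", "chrom", "p", "mean_tumor_maf", "n_snps"])
    if len(out):
        out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
        out["ai"] = (out["fdr"] < fdr) & (out["mean_tumor_maf"] < threshold)
    else:
        out["fdr"] = []
        out["ai"] = []
    return out


def mouse_ai_union(region_calls: dict[str, set | None]) -> set:
    """Per-mouse AI gene set: union over powered regions.

    ``region_calls`` maps region id to the region's AI gene set, or ``None``
    for regions flagged as lacking power (which contribute nothing).
    """
    powered = [s for s in region_calls.values() if s is not None]
    if not powered:
        raise ValueError("no powered region available for AI union")
    out: set = set()
    for s in powered:
        out |= set(s)
    return out


def ai_enrichment(indicator: pd.DataFrame) -> pd.DataFrame:
    """Cohort-level enrichment of per-gene allelic imbalance.

    ``indicator`` is a genes x mice boolean matrix (index = gene).  The
    background rate is the mean per-mouse fraction of AI genes; each gene's
    enrichment is the upper-tail binomial probability of observing at least
    its number of AI mice at the background rate, BH-corrected over genes.
    """
    mat = indicator.astype(bool)
    n_mice = mat.shape[1]
    if n_mice == 0:
        raise ValueError("indicator matrix has no mice")
    background = float(mat.mean(axis=0).mean())
    k = mat.sum(axis=1).to_numpy()
    pvals = stats.binom.sf(k - 1, n_mice, background)
    pvals = np.where(k == 0, 1.0, pvals)
    out = pd.DataFrame(
        {"gene": mat.index, "n_ai_mice": k, "p": pvals},
    ).reset_index(drop=True)
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1] if len(out) else []
    return out
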