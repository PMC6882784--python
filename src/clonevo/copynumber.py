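"""Purity-corrected copy number from array-CGH log ratios.

The observed tumor/normal log2 ratio of a segment in a sample with tumor
purity ``p`` is

    log2R_obs = log2((p*CN_T + (1 - p)*CN_N) / CN_N)

where CN_T and CN_N are the integer copy numbers in tumor and normal
cells.  Probe tracks are segmented by recursive binary splitting with a
permutation significance test, over-segmentation is undone by merging
adjacent segments whose means lie within 3 pooled standard deviations,
and segment means are inverted through the relation above to integer
tumor copy number.  Focal events are homozygous deletions (HD, CN_T = 0)
or amplifications (Amp, CN_T >= 5) under 4 Mb covering at least five
probes on autosomes, with nearby same-class events merged; events are
matched across tumor regions by a 50% overlap/union rule, and chromosome
arms gained or lost over at least half their length are reported as
large-scale aberrations.

Coordinates are 0-based half-open throughout; SEG I/O converts to and
from the 1-based inclusive convention.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "segment_track",
    "merge_undo",
    "purity_correct",
    "correct_segments",
    "classify_cn",
    "call_focal_events",
    "match_events_across_regions",
    "call_large_scale",
    "gene_alteration_fraction",
]

SEX_CHROMS = {"chrX", "chrY", "X", "Y"}

SEGMENT_COLUMNS = ["chrom", "start", "end", "n_probes", "seg_mean", "seg_sd"]


# ---------------------------------------------------------------------------
# segmentation


def _window_lengths(n: int, min_size: int):
    L = max(min_size, 2)
    out = []
    while L <= n // 2:
        out.append(L)
        L *= 2
    return out


def _best_change(x: np.ndarray, min_size: int):
    """Best mean-shift candidate: a single split or an interior window.

    Returns ``(stat, (i, j))`` where ``j == len(x)`` denotes a plain split at
    ``i`` and ``j < len(x)`` an interior arc [i, j) whose mean differs from
    the rest.  The statistic is sqrt(m*(n-m)/n) * |mean_in - mean_out| (the
    square root of the residual-sum-of-squares reduction), so short focal
    dips and amplifications compete on equal footing with long-arm shifts.
    """
    n = len(x)
    cs = np.concatenate([[0.0], np.cumsum(x)])
    total = cs[-1]
    k = np.arange(1, n)
    mean_l = cs[1:-1] / k
    mean_r = (total - cs[1:-1]) / (n - k)
    stat = np.sqrt(k * (n - k) / n) * np.abs(mean_l - mean_r)
    if min_size > 1:
        stat[: min_size - 1] = -np.inf
        stat[n - min_size :] = -np.inf
    best = int(np.argmax(stat))
    best_stat, best_span = float(stat[best]), (best + 1, n)
    for L in _window_lengths(n, min_size):
        win = cs[L:] - cs[:-L]  # sums of all windows of length L
        mean_in = win / L
        mean_out = (total - win) / (n - L)
        wstat = np.sqrt(L * (n - L) / n) * np.abs(mean_in - mean_out)
        i = int(np.argmax(wstat))
        if wstat[i] > best_stat:
            best_stat, best_span = float(wstat[i]), (i, i + L)
    return best_stat, best_span


def _change_significant(x, stat, rng, alpha, n_perm, min_size):
    count = 0
    for _ in range(n_perm):
        s, _ = _best_change(rng.permutation(x), min_size)
        if s >= stat:
            count += 1
    return (1 + count) / (1 + n_perm) <= alpha


def _segment_values(x, rng, alpha, n_perm, min_size):
    """Recursive binary segmentation of one value array -> list of (lo, hi)."""
    out = []

    def recurse(lo, hi):
        n = hi - lo
        if n < 2 * min_size:
            out.append((lo, hi))
            return
        stat, (i, j) = _best_change(x[lo:hi], min_size)
        if not np.isfinite(stat) or not _change_significant(
            x[lo:hi], stat, rng, alpha, n_perm, min_size
        ):
            out.append((lo, hi))
            return
        if j >= n:  # plain split
            recurse(lo, lo + i)
            recurse(lo + i, hi)
        else:  # interior window: split out [i, j)
            if i >= min_size:
                recurse(lo, lo + i)
                recurse(lo + i, lo + j)
            else:  # left stub too small for its own segment
                recurse(lo, lo + j)
            if n - j >= min_size:
                recurse(lo + j, hi)
            elif j < n:  # keep coverage: right stub becomes a short segment
                out.append((lo + j, hi))

    recurse(0, len(x))
    return sorted(out)


def segment_track(
    probes: pd.DataFrame,
    alpha: float = 0.01,
    seed: int = 0,
    n_perm: int = 199,
    min_size: int = 2,
) -> pd.DataFrame:
    """Segment a probe log-ratio track into constant-copy-number intervals.

    Parameters
    ----------
    probes : DataFrame with columns ``chrom, pos, log2ratio``, probes sorted
        by position within each chromosome.
    alpha : permutation significance level for accepting a changepoint.
    seed : seed for the permutation null; fixed seed gives identical output.
    n_perm : number of permutations per candidate split.
    min_size : minimum number of probes per segment.

    Returns
    -------
    DataFrame with columns ``chrom, start, end, n_probes, seg_mean, seg_sd``
    (0-based half-open, boundaries at probe positions), covering every probe
    with contiguous non-overlapping segments.
    """
    if len(probes) == 0:
        raise ValueError("empty probe track")
    rng = np.random.default_rng(seed)
    rows = []
    for chrom, grp in probes.groupby("chrom", sort=False):
        pos = grp["pos"].to_numpy()
        if np.any(np.diff(pos) < 0):
            raise ValueError(f"probes not sorted by position on {chrom}")
        x = grp["log2ratio"].to_numpy(dtype=float)
        for lo, hi in _segment_values(x, rng, alpha, n_perm, min_size):
            xs = x[lo:hi]
            rows.append(
                (
                    chrom,
                    int(pos[lo]),
                    int(pos[hi - 1]) + 1,
                    hi - lo,
                    float(xs.mean()),
                    float(xs.std(ddof=1)) if hi - lo > 1 else 0.0,
                )
            )
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# undo-style merging


def _pooled_sd(n1, s1, n2, s2):
    w1, w2 = max(n1 - 1, 0), max(n2 - 1, 0)
    if w1 + w2 == 0:
        return 0.0
    return float(np.sqrt((w1 * s1**2 + w2 * s2**2) / (w1 + w2)))


def _combine(a, b):
    n = a["n_probes"] + b["n_probes"]
    mean = (a["n_probes"] * a["seg_mean"] + b["n_probes"] * b["seg_mean"]) / n
    m2 = (
        max(a["n_probes"] - 1, 0) * a["seg_sd"] ** 2
        + max(b["n_probes"] - 1, 0) * b["seg_sd"] ** 2
        + a["n_probes"] * b["n_probes"] / n * (a["seg_mean"] - b["seg_mean"]) ** 2
    )
    sd = float(np.sqrt(m2 / (n - 1))) if n > 1 else 0.0
    return {
        "chrom": a["chrom"],
        "start": a["start"],
        "end": b["end"],
        "n_probes": int(n),
        "seg_mean": float(mean),
        "seg_sd": sd,
    }


def merge_undo(segments: pd.DataFrame, n_sd: float = 3.0) -> pd.DataFrame:
    """Remove splits between adjacent segments with near-identical means.

    Adjacent segments within a chromosome whose means differ by less than
    ``n_sd`` pooled within-segment standard deviations are merged; the most
    similar pair is merged first and the pass repeats until a fixpoint, so
    the operation is idempotent.
    """
    segs = [row._asdict() if hasattr(row, "_asdict") else dict(row) for _, row in segments.iterrows()]
    changed = True
    while changed:
        changed = False
        best = None
        for i in range(len(segs) - 1):
            a, b = segs[i], segs[i + 1]
            if a["chrom"] != b["chrom"]:
                continue
            sd = _pooled_sd(a["n_probes"], a["seg_sd"], b["n_probes"], b["seg_sd"])
            diff = abs(a["seg_mean"] - b["seg_mean"])
            if diff < n_sd * sd or diff == 0.0:
                ratio = diff / sd if sd > 0 else 0.0
                if best is None or ratio < best[0]:
                    best = (ratio, i)
        if best is not None:
            i = best[1]
            segs[i : i + 2] = [_combine(segs[i], segs[i + 1])]
            changed = True
    return pd.DataFrame(segs, columns=SEGMENT_COLUMNS)


# ---------------------------------------------------------------------------
# purity correction


def purity_correct(log2r_obs: float, p: float, cn_n: int = 2):
    """Invert the observed log ratio to tumor copy number.

    Returns ``(real_cn, cn_t)`` where ``real_cn = CN_N*(2**log2R - (1-p))/p``
    and ``cn_t`` is ``real_cn`` rounded half-up to the nearest integer,
    floored at 0.
    """
    if not 0 < p <= 1:
        raise ValueError(f"purity must be in (0, 1], got {p}")
    if cn_n < 1:
        raise ValueError("CN_N must be >= 1")
    real = cn_n * (2.0 ** np.asarray(log2r_obs, dtype=float) - (1 - p)) / p
    cn_t = np.maximum(np.floor(real + 0.5), 0).astype(int)
    if np.ndim(log2r_obs) == 0:
        return float(real), int(cn_t)
    return real, cn_t


def classify_cn(cn_t: int, cn_n: int = 2) -> str:
    if cn_t == 0:
        return "HD"
    if cn_t >= cn_n + 3:
        return "Amp"
    if cn_t < cn_n:
        return "loss"
    if cn_t > cn_n:
        return "gain"
    return "neutral"


def correct_segments(segments: pd.DataFrame, p: float, cn_n: int = 2) -> pd.DataFrame:
    """Attach purity-corrected real and integer copy number to segments."""
    out = segments.copy()
    real, cn_t = purity_correct(out["seg_mean"].to_numpy(dtype=float), p, cn_n)
    out["cn_real"] = real
    out["cn_t"] = cn_t
    out["cn_class"] = [classify_cn(c, cn_n) for c in cn_t]
    return out


# ---------------------------------------------------------------------------
# focal and large-scale event calling


def _overlapping_genes(chrom, start, end, genes: pd.DataFrame):
    g = genes[(genes["chrom"] == chrom) & (genes["start"] < end) & (genes["end"] > start)]
    return sorted(g["gene"].tolist())


def call_focal_events(
    segments: pd.DataFrame,
    genes: pd.DataFrame,
    size_limit: int = 4_000_000,
    min_probes: int = 5,
    merge_gap: int = 100_000,
    cn_n: int = 2,
) -> pd.DataFrame:
    """Call focal homozygous deletions and amplifications.

    Keeps segments with CN_T = 0 (HD) or CN_T >= CN_N + 3 (Amp) that span
    less than ``size_limit``, cover at least ``min_probes`` probes and lie
    on autosomes; merges same-class events whose boundaries are less than
    ``merge_gap`` apart; drops events that do not overlap the coding span
    of at least one gene.

    Returns a DataFrame ``class, chrom, start, end, n_probes, genes``.
    """
    if "cn_t" not in segments.columns:
        raise ValueError("segments must carry purity-corrected cn_t")
    cand = segments[
        segments["cn_class"].isin(["HD", "Amp"])
        & ((segments["end"] - segments["start"]) < size_limit)
        & (segments["n_probes"] >= min_probes)
        & ~segments["chrom"].isin(SEX_CHROMS)
    ].sort_values(["chrom", "start"])

    merged: list[dict] = []
    for row in cand.itertuples(index=False):
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev["chrom"] == row.chrom
            and prev["class"] == row.cn_class
            and row.start - prev["end"] < merge_gap
        ):
            prev["end"] = max(prev["end"], row.end)
            prev["n_probes"] += row.n_probes
        else:
            merged.append(
                {
                    "class": row.cn_class,
                    "chrom": row.chrom,
                    "start": int(row.start),
                    "end": int(row.end),
                    "n_probes": int(row.n_probes),
                }
            )
    out = []
    for ev in merged:
        gl = _overlapping_genes(ev["chrom"], ev["start"], ev["end"], genes)
        if gl:
            ev["genes"] = ",".join(gl)
            out.append(ev)
    return pd.DataFrame(out, columns=["class", "chrom", "start", "end", "n_probes", "genes"])


def _overlap_union(a_start, a_end, b_start, b_end) -> float:
    inter = min(a_end, b_end) - max(a_start, b_start)
    if inter <= 0:
        return 0.0
    union = max(a_end, b_end) - min(a_start, b_start)
    return inter / union


def match_events_across_regions(
    events_by_group: dict[str, pd.DataFrame],
    min_overlap_union: float = 0.5,
    n_groups_total: int | None = None,
) -> pd.DataFrame:
    """Identify shared focal events across tumor regions (or across mice).

    Events of the same class whose intervals share an overlap/union of at
    least ``min_overlap_union`` are assigned one cross-group event id
    (transitively).  Evolutionary status follows group support: ubiquitous
    (all groups), partially shared (more than one but not all) or private
    (one group).  ``n_groups_total`` defaults to the number of groups with
    any event table supplied (analyzed groups).
    """
    frames = []
    for group, df in events_by_group.items():
        d = df.copy()
        d["group"] = group
        frames.append(d)
    if n_groups_total is None:
        n_groups_total = len(events_by_group)
    all_ev = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["class", "chrom", "start", "end", "group"])
    )
    n = len(all_ev)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            a, b = all_ev.iloc[i], all_ev.iloc[j]
            if a["class"] != b["class"] or a["chrom"] != b["chrom"]:
                continue
            if _overlap_union(a["start"], a["end"], b["start"], b["end"]) >= min_overlap_union:
                parent[find(i)] = find(j)

    roots = [find(i) for i in range(n)]
    ids = {r: k for k, r in enumerate(sorted(set(roots), key=roots.index))}
    all_ev["event_id"] = [ids[r] for r in roots]
    support = all_ev.groupby("event_id")["group"].nunique()
    status = {}
    for eid, ngrp in support.items():
        if ngrp >= n_groups_total:
            status[eid] = "ubiquitous"
        elif ngrp > 1:
            status[eid] = "partially_shared"
        else:
            status[eid] = "private"
    all_ev["status"] = all_ev["event_id"].map(status)
    return all_ev


def call_large_scale(
    segments: pd.DataFrame,
    cn_n: int = 2,
    min_frac: float = 0.5,
    include_sex: bool = False,
) -> pd.DataFrame:
    """Label chromosomes with large-scale copy gain or loss.

    A chromosome is called gained (lost) when segments with CN_T above
    (below) CN_N cumulatively span at least ``min_frac`` of the chromosome's
    segmented length.
    """
    if "cn_t" not in segments.columns:
        raise ValueError("segments must carry purity-corrected cn_t")
    rows = []
    for chrom, grp in segments.groupby("chrom", sort=False):
        if not include_sex and chrom in SEX_CHROMS:
            continue
        total = float((grp["end"] - grp["start"]).sum())
        span = grp["end"] - grp["start"]
        gained = float(span[grp["cn_t"] > cn_n].sum())
        lost = float(span[grp["cn_t"] < cn_n].sum())
        if gained / total >= min_frac:
            call = "gain"
        elif lost / total >= min_frac:
            call = "loss"
        else:
            call = "none"
        rows.append((chrom, gained / total, lost / total, call))
    return pd.DataFrame(rows, columns=["chrom", "frac_gain", "frac_loss", "call"])


def gene_alteration_fraction(segments: pd.DataFrame, genes: pd.DataFrame, cn_n: int = 2) -> float:
    """Fraction of genes overlapping a segment with altered copy number."""
    if len(genes) == 0:
        raise ValueError("gene table is empty")
    altered = segments[segments["cn_t"] != cn_n]
    hit = 0
    for g in genes.itertuples(index=False):
        sel = altered[
            (altered["chrom"] == g.chrom)
            & (altered["start"] < g.end)
            & (altered["end"] > g.start)
        ]
        if len(sel):
            hit += 1
    return hit / len(genes)
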