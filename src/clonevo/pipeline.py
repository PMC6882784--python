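"""End-to-end per-mouse and cohort orchestration.

Runs purity estimation, copy-number calling, allelic-imbalance analysis,
mutation QC, prevalence estimation/clustering and tree reconstruction for
one mouse, then aggregates a cohort summary (mutation burden, spatial
heterogeneity fractions, focal-event recurrence across mice, topology
tally).  Every stage records the thresholds it used and any region
exclusions, and all randomness is routed through one master seed so a
rerun with the same seed and config is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from . import ai as ai_mod
from . import copynumber as cn_mod
from . import io as io_mod
from . import mutqc as qc_mod
from . import phylogeny as phylo_mod
from . import prevalence as prev_mod
from . import purity as purity_mod
from .simulate import SimulatedMouse, make_genes

__all__ = ["default_config", "stage_seed", "run_mouse", "run_cohort"]


def default_config(seed: int = 0) -> dict:
    return {
        "seed": int(seed),
        "focal_size_limit": 4_000_000,
        "focal_min_probes": 5,
        "focal_merge_gap": 100_000,
        "segment_alpha": 0.01,
        "precedence_alpha": 0.05,
        "sum_tolerance": 0.10,
        "ai_fdr": 0.05,
        "ai_k": 10,
        "ai_min_dp": 20,
        "low_vaf_cut": 0.02,
        "cn_n": 2,
    }


def stage_seed(master_seed: int, *key: int) -> int:
    """Deterministic per-stage sub-seed derived from the master seed."""
    return int(np.random.SeedSequence([int(master_seed), *map(int, key)]).generate_state(1)[0] % (2**31))


def _cn_at_position(segments: pd.DataFrame, chrom: str, pos: int, cn_n: int) -> int:
    sel = segments[
        (segments["chrom"] == chrom) & (segments["start"] <= pos) & (segments["end"] > pos)
    ]
    if len(sel) == 0:
        return cn_n
    return int(sel["cn_t"].iloc[0])


def run_mouse(
    mouse: SimulatedMouse,
    config: dict | None = None,
    genes: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every analysis stage for one mouse and return the JSON report."""
    cfg = default_config() | (config or {})
    seed = cfg["seed"]
    cn_n = cfg["cn_n"]
    if genes is None:
        genes = make_genes(mouse.genome, seed=0)
    report: dict = {
        "mouse_id": mouse.mouse_id,
        "genotype": mouse.genotype,
        "config": {k: v for k, v in sorted(cfg.items())},
        "exclusions": [],
    }

    # --- purity from the qPCR standard curve -----------------------------
    curve = purity_mod.fit_standard_curve(
        mouse.qpcr_standards["purity_fraction"], mouse.qpcr_standards["ct"]
    )
    purity_est = {}
    for r in mouse.regions:
        cts = mouse.qpcr_samples.loc[mouse.qpcr_samples["sample"] == r, "ct"]
        purity_est[r] = purity_mod.estimate_purity(cts, curve)
    report["purity"] = {
        "curve": {"A": curve.slope, "B": curve.intercept, "r_squared": curve.r_squared},
        "estimates": {r: round(purity_est[r], 4) for r in mouse.regions},
    }

    # --- copy number per region ------------------------------------------
    segments = {}
    focal_by_region = {}
    report["copy_number"] = {}
    for k, r in enumerate(mouse.regions):
        if r not in mouse.probes:
            report["exclusions"].append({"region": r, "stage": "copy_number",
                                         "reason": "no probe track"})
            continue
        segs = cn_mod.segment_track(
            mouse.probes[r], alpha=cfg["segment_alpha"], seed=stage_seed(seed, 1, k)
        )
        segs = cn_mod.merge_undo(segs)
        p = max(purity_est[r], 0.01)
        segs = cn_mod.correct_segments(segs, p, cn_n)
        segments[r] = segs
        focal = cn_mod.call_focal_events(
            segs, genes,
            size_limit=cfg["focal_size_limit"],
            min_probes=cfg["focal_min_probes"],
            merge_gap=cfg["focal_merge_gap"],
            cn_n=cn_n,
        )
        focal_by_region[r] = focal
        large = cn_mod.call_large_scale(segs, cn_n=cn_n)
        report["copy_number"][r] = {
            "n_segments": int(len(segs)),
            "focal_events": focal.to_dict("records"),
            "large_scale": large[large["call"] != "none"].to_dict("records"),
            "gene_alteration_fraction": round(
                cn_mod.gene_alteration_fraction(segs, genes, cn_n), 4
            ),
        }
    if len(focal_by_region) >= 2:
        matched = cn_mod.match_events_across_regions(focal_by_region)
        report["copy_number"]["cross_region_events"] = matched.to_dict("records")

    # --- allelic imbalance per region, union over powered regions --------
    report["allelic_imbalance"] = {}
    region_ai_sets: dict = {}
    for k, r in enumerate(mouse.regions):
        if r not in mouse.snps:
            report["exclusions"].append({"region": r, "stage": "allelic_imbalance",
                                         "reason": "no SNP counts"})
            continue
        snps = mouse.snps[r]
        dp = snps["t_ref"] + snps["t_alt"]
        informative = dp[dp >= cfg["ai_min_dp"]]
        coverage = int(informative.median()) if len(informative) else 0
        calib = ai_mod.calibrate_threshold(
            max(purity_est[r], 0.01), max(coverage, 1), seed=stage_seed(seed, 2, k)
        )
        entry = {
            "coverage": coverage,
            "lacking_power": calib.lacking_power,
            "threshold": calib.threshold,
            "sensitivity": calib.sensitivity,
            "specificity": calib.specificity,
        }
        if calib.lacking_power:
            region_ai_sets[r] = None
            report["exclusions"].append({"region": r, "stage": "allelic_imbalance",
                                         "reason": "lacking power"})
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                calls = ai_mod.sample_ai_calls(
                    genes, snps, calib.threshold,
                    k=cfg["ai_k"], min_dp=cfg["ai_min_dp"], fdr=cfg["ai_fdr"],
                )
            ai_genes = set(calls.loc[calls["ai"], "gene"])
            region_ai_sets[r] = ai_genes
            entry["n_ai_genes"] = len(ai_genes)
        report["allelic_imbalance"][r] = entry
    powered = {r: s for r, s in region_ai_sets.items() if s is not None}
    report["allelic_imbalance"]["union"] = (
        sorted(ai_mod.mouse_ai_union(region_ai_sets)) if powered else []
    )

    # --- mutation QC ------------------------------------------------------
    muts = mouse.mutations.copy()
    muts["validated"] = [
        qc_mod.validation_filter(
            {r: (row[f"tot_{r}"], row[f"var_{r}"], row[f"fwd_{r}"], row[f"rev_{r}"])
             for r in mouse.regions}
        )
        for _, row in muts.iterrows()
    ]
    validated = muts[muts["validated"]].reset_index(drop=True)
    analyzed = prev_mod.exclude_low_vaf_regions(
        validated, mouse.regions,
        regions_with_cn=set(segments) if segments else None,
        max_vaf_cut=cfg["low_vaf_cut"],
    )
    for r in mouse.regions:
        if r not in analyzed:
            report["exclusions"].append({"region": r, "stage": "prevalence",
                                         "reason": "low VAF or missing copy-number profile"})
    het = qc_mod.categorize_heterogeneity(validated, analyzed) if analyzed else pd.Series(dtype=object)
    validated["heterogeneity"] = het
    counts = het[het != "transgene"].value_counts().to_dict()
    report["mutation_qc"] = {
        "n_candidates": int(len(muts)),
        "n_validated": int(len(validated)),
        "n_validated_non_transgene": int((~validated["is_transgene"]).sum()),
        "heterogeneity": {k: int(v) for k, v in sorted(counts.items())},
        "analyzed_regions": analyzed,
    }

    # --- prevalence estimation and clustering ----------------------------
    usable = validated[~validated["is_transgene"]].reset_index(drop=True)
    prev_rows = []
    for _, row in usable.iterrows():
        entry = {"mut_id": row["mut_id"]}
        for r in analyzed:
            p = max(purity_est[r], 0.01)
            cn_t = (
                _cn_at_position(segments[r], row["chrom"], row["pos"], cn_n)
                if r in segments
                else cn_n
            )
            try:
                est = prev_mod.resolve_multiplicity(
                    int(row[f"var_{r}"]), int(row[f"tot_{r}"]), p, max(cn_t, 0), cn_n
                )
            except ValueError:
                est = prev_mod.PrevalenceEstimate(
                    prev_mod.GRID.copy(), np.full_like(prev_mod.GRID, np.nan),
                    np.nan, np.nan, np.nan, missing=True,
                )
            entry[f"ccp_{r}"] = est.point
            entry[f"ccp_lo_{r}"] = est.ci_low
            entry[f"ccp_hi_{r}"] = est.ci_high
            entry[f"m_{r}"] = est.multiplicity
            entry[f"missing_{r}"] = est.missing
        prev_rows.append(entry)
    prev_df = pd.DataFrame(prev_rows)
    report["prevalence"] = {"n_mutations": int(len(prev_df)), "regions": analyzed}

    clusters = []
    if len(prev_df) >= 2 and analyzed:
        X = prev_df[[f"ccp_{r}" for r in analyzed]].to_numpy(dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clusters = prev_mod.cluster_by_prevalence(
                X, mutation_ids=prev_df["mut_id"].tolist(), seed=stage_seed(seed, 3)
            )
    report["clusters"] = [
        {
            "cluster_id": c.cluster_id,
            "n_members": len(c.members),
            "members": list(c.members),
            "mean": [round(float(v), 4) for v in np.atleast_1d(c.mean)],
            "sd": [round(float(v), 4) for v in np.atleast_1d(c.sd)],
        }
        for c in clusters
    ]

    # --- phylogeny --------------------------------------------------------
    report["phylogeny"] = {}
    real = [c for c in clusters if c.cluster_id >= 0]
    if 1 <= len(real) <= phylo_mod.MAX_CLUSTERS:
        means = {f"C{c.cluster_id}": np.nan_to_num(np.atleast_1d(c.mean), nan=0.0) for c in real}
        sds = {f"C{c.cluster_id}": np.nan_to_num(np.atleast_1d(c.sd), nan=0.0) for c in real}
        trees = phylo_mod.enumerate_trees(
            means, sds, alpha=cfg["precedence_alpha"], sum_tol=cfg["sum_tolerance"]
        )
        labels = {phylo_mod.classify_topology(t) for t in trees}
        topo, sync = (labels.pop() if len(labels) == 1 else (None, None))
        report["phylogeny"] = {
            "n_minimal_trees": len(trees),
            "cost": trees[0].cost,
            "topology": topo,
            "synchronous_primary": sync,
            "newick": [phylo_mod.to_newick(t) for t in trees[:10]],
        }
        report["phylogeny"]["dot"] = phylo_mod.to_dot(trees[0])
    elif len(real) > phylo_mod.MAX_CLUSTERS:
        report["phylogeny"] = {"error": "too many clusters for exhaustive search"}

    if outdir is not None:
        _write_mouse_artifacts(outdir, mouse, report, segments, validated, prev_df)
    return report


def _write_mouse_artifacts(outdir, mouse, report, segments, validated, prev_df):
    out = Path(outdir) / mouse.mouse_id
    out.mkdir(parents=True, exist_ok=True)
    for r, segs in segments.items():
        io_mod.write_seg(segs, out / f"{r}.seg", sample=f"{mouse.mouse_id}_{r}")
    io_mod.write_mutations(validated, out / "mutations_validated.tsv")
    if len(prev_df):
        io_mod.write_mutations(prev_df, out / "prevalence.tsv")
    for i, nwk in enumerate(report.get("phylogeny", {}).get("newick", [])):
        (out / f"tree_{i}.nwk").write_text(nwk + "\n")
    if "dot" in report.get("phylogeny", {}):
        (out / "tree_0.dot").write_text(report["phylogeny"]["dot"] + "\n")
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, sort_keys=True, indent=1)


def run_cohort(
    mice: list[SimulatedMouse],
    config: dict | None = None,
    genes: pd.DataFrame | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every mouse and aggregate the cohort summary.

    A failed stage in one mouse never aborts the cohort; exclusions are
    first-class report entries.
    """
    if not mice:
        raise ValueError("empty cohort")
    cfg = default_config() | (config or {})
    if genes is None:
        genes = make_genes(mice[0].genome, seed=0)
    reports = []
    for i, mouse in enumerate(mice):
        mcfg = dict(cfg)
        mcfg["seed"] = stage_seed(cfg["seed"], 100 + i)
        reports.append(run_mouse(mouse, mcfg, genes=genes, outdir=outdir))

    burden = [r["mutation_qc"]["n_validated_non_transgene"] for r in reports]
    het_frac = {}
    for cls in ("ubiquitous", "partially_shared", "private"):
        het_frac[cls] = [
            r["mutation_qc"]["heterogeneity"].get(cls, 0) for r in reports
        ]
    topo_tally: dict = {"linear": 0, "branched": 0, "synchronous_primary": 0, "ambiguous": 0}
    for r in reports:
        topo = r.get("phylogeny", {}).get("topology")
        if topo is None:
            topo_tally["ambiguous"] += 1
        else:
            topo_tally[topo] += 1
            if r["phylogeny"].get("synchronous_primary"):
                topo_tally["synchronous_primary"] += 1

    # recurrence of focal events across mice: one merged event table per mouse
    per_mouse_events = {}
    for r in reports:
        evs = []
        for region, entry in r["copy_number"].items():
            if region == "cross_region_events":
                continue
            evs.extend(entry["focal_events"])
        if evs:
            df = pd.DataFrame(evs)[["class", "chrom", "start", "end"]]
            per_mouse_events[r["mouse_id"]] = df.drop_duplicates().reset_index(drop=True)
    recurrence = []
    if len(per_mouse_events) >= 2:
        matched = cn_mod.match_events_across_regions(
            per_mouse_events, n_groups_total=len(mice)
        )
        for eid, grp in matched.groupby("event_id"):
            recurrence.append(
                {
                    "class": grp["class"].iloc[0],
                    "chrom": grp["chrom"].iloc[0],
                    "start": int(grp["start"].min()),
                    "end": int(grp["end"].max()),
                    "n_mice": int(grp["group"].nunique()),
                    "mice": sorted(grp["group"].unique().tolist()),
                }
            )
        recurrence.sort(key=lambda e: (-e["n_mice"], e["chrom"], e["start"]))

    summary = {
        "n_mice": len(mice),
        "mutation_burden": {
            "per_mouse": burden,
            "mean": round(float(np.mean(burden)), 3),
            "sd": round(float(np.std(burden, ddof=1)), 3) if len(burden) > 1 else 0.0,
        },
        "heterogeneity_counts": het_frac,
        "topology_tally": topo_tally,
        "focal_recurrence": recurrence[:20],
        "config": {k: v for k, v in sorted(cfg.items())},
    }
    result = {"summary": summary, "mice": reports}
    if outdir is not None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "cohort_summary.json", "w") as fh:
            json.dump(result, fh, sort_keys=True, indent=1)
    return result
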