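"""Readers and writers for the plain-text formats the pipeline consumes.

Internal coordinates are 0-based half-open (BED convention); SEG files are
converted from/to the 1-based inclusive convention on the way in and out.
Mutation tables travel as TSV with per-region count columns
(``tot_<region>, var_<region>, fwd_<region>, rev_<region>``) or as a
minimal VCF in which each tumor region is a sample with DP/AD/ADF/ADR
FORMAT fields.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "read_seg",
    "write_seg",
    "read_bed",
    "write_bed",
    "read_probes",
    "write_probes",
    "read_snps",
    "write_snps",
    "read_mutations",
    "write_mutations",
    "read_mutation_vcf",
    "write_mutation_vcf",
    "read_qpcr_standards",
    "write_qpcr_standards",
]

SEG_COLUMNS = ["sample", "chrom", "start", "end", "num_probes", "seg_mean"]


def read_seg(path) -> pd.DataFrame:
    """Read a SEG file into internal 0-based half-open segments."""
    df = pd.read_csv(path, sep="\t")
    df.columns = [c.lower().replace(".", "_") for c in df.columns]
    rename = {"id": "sample", "chromosome": "chrom", "loc_start": "start",
              "loc_end": "end", "num_mark": "num_probes"}
    df = df.rename(columns=rename)
    out = df[["sample", "chrom", "start", "end", "num_probes", "seg_mean"]].copy()
    out["start"] = out["start"].astype(int) - 1  # 1-based inclusive -> 0-based half-open
    out["end"] = out["end"].astype(int)
    out = out.rename(columns={"num_probes": "n_probes"})
    return out


def write_seg(segments: pd.DataFrame, path, sample: str = "sample") -> None:
    out = pd.DataFrame(
        {
            "sample": sample,
            "chrom": segments["chrom"],
            "start": segments["start"].astype(int) + 1,
            "end": segments["end"].astype(int),
            "num_probes": segments["n_probes"].astype(int),
            "seg_mean": segments["seg_mean"],
        }
    )
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_bed(path) -> pd.DataFrame:
    """BED (chrom, start, end, name) -> gene table."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "gene"]
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(genes: pd.DataFrame, path) -> None:
    genes[["chrom", "start", "end", "gene"]].to_csv(
        path, sep="\t", index=False, header=False
    )


def read_probes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["chrom", "pos", "log2ratio"]]


def write_probes(probes: pd.DataFrame, path) -> None:
    probes[["chrom", "pos", "log2ratio"]].to_csv(
        path, sep="\t", index=False, float_format="%.6g"
    )


def read_snps(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = ["chrom", "pos", "t_ref", "t_alt", "n_ref", "n_alt"]
    return df[[c for c in df.columns if c in need + ["in_loss"]]]


def write_snps(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False)


def read_mutations(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_mutations(mutations: pd.DataFrame, path) -> None:
    mutations.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_qpcr_standards(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return df[["purity_fraction", "ct"]]


def write_qpcr_standards(standards: pd.DataFrame, path) -> None:
    standards.to_csv(path, sep="\t", index=False, float_format="%.6g")


# ---------------------------------------------------------------------------
# minimal VCF with per-region allelic counts


def write_mutation_vcf(mutations: pd.DataFrame, regions: list[str], path,
                       contig_lengths: dict[str, int] | None = None) -> None:
    """Write mutations as a minimal VCF; each tumor region is a sample.

    FORMAT fields: DP (depth), AD (ref,alt depths), ADF/ADR (alt reads on
    forward/reverse strand).  Ref/alt alleles default to N/A placeholders
    when the table does not carry them.
    """
    import pysam

    header = pysam.VariantHeader()
    chroms = list(dict.fromkeys(mutations["chrom"]))
    for c in chroms:
        length = (contig_lengths or {}).get(c, 500_000_000)
        header.contigs.add(c, length=length)
    header.formats.add("DP", 1, "Integer", "Total read depth")
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("ADF", 1, "Integer", "Alt reads on forward strand")
    header.formats.add("ADR", 1, "Integer", "Alt reads on reverse strand")
    header.info.add("CLUSTER", 1, "String", "Truth or inferred cluster id")
    header.info.add("TRANSGENE", 0, "Flag", "Knock-in transgene mutation")
    for r in regions:
        header.add_sample(r)
    with pysam.VariantFile(str(path), "w", header=header) as vf:
        for row in mutations.itertuples(index=False):
            rec = vf.new_record(
                contig=row.chrom,
                start=int(row.pos),
                stop=int(row.pos) + 1,
                alleles=(getattr(row, "ref", "N"), getattr(row, "alt", "A")),
                id=str(row.mut_id),
            )
            if hasattr(row, "cluster"):
                rec.info["CLUSTER"] = str(row.cluster)
            if getattr(row, "is_transgene", False):
                rec.info["TRANSGENE"] = True
            for r in regions:
                tot = int(getattr(row, f"tot_{r}"))
                var = int(getattr(row, f"var_{r}"))
                rec.samples[r]["DP"] = tot
                rec.samples[r]["AD"] = (tot - var, var)
                rec.samples[r]["ADF"] = int(getattr(row, f"fwd_{r}"))
                rec.samples[r]["ADR"] = int(getattr(row, f"rev_{r}"))
            vf.write(rec)


def read_mutation_vcf(path) -> pd.DataFrame:
    """Read a minimal per-region-count VCF back into the mutation table."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vf:
        regions = list(vf.header.samples)
        for rec in vf:
            row = {
                "mut_id": rec.id,
                "chrom": rec.contig,
                "pos": rec.start,
                "ref": rec.ref,
                "alt": rec.alts[0] if rec.alts else "N",
                "is_transgene": "TRANSGENE" in rec.info,
            }
            if "CLUSTER" in rec.info:
                row["cluster"] = rec.info["CLUSTER"]
            for r in regions:
                s = rec.samples[r]
                row[f"tot_{r}"] = int(s["DP"])
                row[f"var_{r}"] = int(s["AD"][1])
                row[f"fwd_{r}"] = int(s["ADF"])
                row[f"rev_{r}"] = int(s["ADR"])
            rows.append(row)
    return pd.DataFrame(rows)
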