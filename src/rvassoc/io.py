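"""Readers and writers for the pipeline's interchange formats.

VCF 4.2 (GT/DP per sample) is the interchange format between the calling
and association stages; annotation (gene, functional class) travels in a
sidecar TSV keyed by (chrom, pos, ref, alt). Phenotypes, gene sets,
read summaries and truth tables are plain TSV.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .calling import SiteCall
from .core import (
    MISSING,
    Cohort,
    DataError,
    GenotypeMatrix,
    SiteReads,
    TruthTable,
    VariantTable,
)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=rvassoc
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=PHAT,Number=1,Type=Float,Description="ML population alt-allele frequency">
##INFO=<ID=LRT,Number=1,Type=Float,Description="2x log likelihood ratio vs monomorphic null">
##INFO=<ID=BQP,Number=1,Type=Float,Description="Base-quality rank-sum p">
##INFO=<ID=SBP,Number=1,Type=Float,Description="Strand-bias Fisher p">
##FILTER=<ID=BQ_RANKSUM,Description="Minor-allele base qualities significantly low">
##FILTER=<ID=STRAND_BIAS,Description="Allele-strand association">
##FILTER=<ID=DEPTH_MAPQ,Description="Extreme depth or low mapping quality">
"""

_GT = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def write_vcf(
    gm: GenotypeMatrix,
    path: str | os.PathLike,
    calls: list[SiteCall] | None = None,
) -> None:
    """Write a genotype matrix as an uncompressed VCF 4.2 text file.

    When per-site ``calls`` are supplied (aligned with the matrix rows),
    INFO carries the allele-frequency estimate, LRT statistic and filter
    p-values, and FILTER names any failed filter.
    """
    v = gm.variants
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig in dict.fromkeys(v.chrom):
            fh.write(f"##contig=<ID={contig}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(gm.sample_ids)
            + "\n"
        )
        for j in range(gm.n_variants):
            info = "."
            filt = "PASS"
            if calls is not None:
                c = calls[j]
                info = (
                    f"PHAT={c.af.p_hat:.6g};LRT={c.lrt_statistic:.6g};"
                    f"BQP={c.bq_p:.6g};SBP={c.strand_p:.6g}"
                )
                fails = [
                    name
                    for name, ok in (
                        ("BQ_RANKSUM", c.keep_bq),
                        ("STRAND_BIAS", c.keep_strand),
                        ("DEPTH_MAPQ", c.keep_depth_mapq),
                    )
                    if not ok
                ]
                filt = ";".join(fails) if fails else "PASS"
            fields = [
                v.chrom[j], str(int(v.pos[j])), ".", v.ref[j], v.alt[j],
                ".", filt, info, "GT:DP" if gm.depth is not None else "GT",
            ]
            for i in range(gm.n_samples):
                gt = _GT[int(gm.dosage[j, i])]
                if gm.depth is not None:
                    gt += f":{int(gm.depth[j, i])}"
                fields.append(gt)
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | os.PathLike) -> GenotypeMatrix:
    """Read bi-allelic SNVs from a VCF into a genotype matrix skeleton.

    Dosage is the alternate-allele count as stored (orient with
    :func:`orient_minor` before minor-allele analyses). Multi-allelic or
    non-SNV records are skipped with a warning counter on the returned
    matrix (``gm.n_skipped``). Gene and class annotation default to
    placeholders until :func:`attach_annotation` is applied.
    """
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom, pos, ref, alt, dosages, depths = [], [], [], [], [], []
    n_skipped = 0
    has_dp = True
    for rec in vcf:
        if len(rec.ALT) != 1 or len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            n_skipped += 1
            continue
        chrom.append(rec.CHROM)
        pos.append(rec.POS)
        ref.append(rec.REF)
        alt.append(rec.ALT[0])
        row = np.empty(len(samples), dtype=np.int8)
        for i, g in enumerate(rec.genotypes):
            a, b = g[0], g[1]
            row[i] = MISSING if a < 0 or b < 0 else a + b
        dosages.append(row)
        try:
            dp = rec.format("DP")
        except KeyError:
            dp = None
        if dp is None:
            has_dp = False
            depths.append(np.zeros(len(samples), dtype=np.int64))
        else:
            depths.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int64))
    n = len(chrom)
    table = VariantTable(
        chrom, np.array(pos, dtype=np.int64) if n else np.empty(0, np.int64),
        ref, alt, ["NA"] * n, ["non-silent"] * n,
    )
    gm = GenotypeMatrix(
        table,
        samples,
        np.vstack(dosages) if n else np.empty((0, len(samples)), np.int8),
        depth=np.vstack(depths) if (n and has_dp) else None,
    )
    gm.n_skipped = n_skipped
    return gm


def orient_minor(gm: GenotypeMatrix) -> GenotypeMatrix:
    """Flip dosages at sites where the alternate allele is the major one."""
    d = gm.dosage.copy()
    obs = d != MISSING
    alleles = 2 * obs.sum(axis=1)
    counts = np.where(obs, d, 0).sum(axis=1)
    af = np.where(alleles > 0, counts / np.maximum(alleles, 1), 0.0)
    flip = af > 0.5
    d[flip] = np.where(obs[flip], 2 - d[flip], MISSING)
    return GenotypeMatrix(gm.variants, gm.sample_ids, d, depth=gm.depth)


def write_phenotypes(cohort: Cohort, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "sample": cohort.sample_ids,
            "status": np.where(cohort.is_case, "case", "control"),
            "age": cohort.age.astype(int),
        }
    ).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str | os.PathLike) -> Cohort:
    """Read a sample/status/age TSV; statuses are case-insensitive."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = {"sample", "status", "age"}
    if not required <= set(df.columns):
        raise DataError(f"phenotype file needs columns {sorted(required)}")
    status = df["status"].str.lower()
    bad = sorted(set(status) - {"case", "control"})
    if bad:
        raise DataError(f"unknown status labels: {', '.join(bad)}")
    dup = df["sample"][df["sample"].duplicated()].tolist()
    if dup:
        raise DataError(f"duplicate sample ids: {', '.join(sorted(set(dup)))}")
    return Cohort(
        df["sample"].tolist(),
        (status == "case").to_numpy(),
        df["age"].to_numpy(float),
    )


def check_samples(gm: GenotypeMatrix, cohort: Cohort) -> None:
    """Require every VCF sample to be present in the phenotype table."""
    missing = sorted(set(gm.sample_ids) - set(cohort.sample_ids))
    if missing:
        raise DataError(f"samples missing from phenotypes: {', '.join(missing)}")


def align_cohort(gm: GenotypeMatrix, cohort: Cohort) -> Cohort:
    """Reorder the cohort to the genotype matrix's sample order."""
    check_samples(gm, cohort)
    index = {s: i for i, s in enumerate(cohort.sample_ids)}
    return cohort.subset(np.array([index[s] for s in gm.sample_ids]))


def write_annotation(variants: VariantTable, path: str | os.PathLike) -> None:
    pd.DataFrame(
        {
            "chrom": variants.chrom,
            "pos": variants.pos,
            "ref": variants.ref,
            "alt": variants.alt,
            "gene": variants.gene,
            "class": variants.vclass,
        }
    ).to_csv(path, sep="\t", index=False)


def attach_annotation(gm: GenotypeMatrix, path: str | os.PathLike) -> GenotypeMatrix:
    """Merge a sidecar annotation TSV into the matrix's variant table."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    required = {"chrom", "pos", "ref", "alt", "gene", "class"}
    if not required <= set(df.columns):
        raise DataError(f"annotation file needs columns {sorted(required)}")
    key = dict(
        zip(
            zip(df["chrom"], df["pos"], df["ref"], df["alt"]),
            zip(df["gene"], df["class"]),
        )
    )
    v = gm.variants
    genes, classes = [], []
    unannotated = []
    for j in range(v.n_variants):
        k = (v.chrom[j], int(v.pos[j]), v.ref[j], v.alt[j])
        if k not in key:
            unannotated.append(f"{k[0]}:{k[1]}")
            continue
        g, c = key[k]
        genes.append(g)
        classes.append(c)
    if unannotated:
        raise DataError(f"variants without annotation: {', '.join(unannotated[:10])}")
    table = VariantTable(v.chrom, v.pos, v.ref, v.alt, genes, classes)
    return GenotypeMatrix(table, gm.sample_ids, gm.dosage, gm.maf, gm.depth)


def write_gene_sets(sets: dict[str, set[str]], path: str | os.PathLike) -> None:
    """One set per line: name, then member genes, tab-separated."""
    with open(path, "w") as fh:
        for name in sorted(sets):
            fh.write("\t".join([name, *sorted(sets[name])]) + "\n")


def read_gene_sets(path: str | os.PathLike) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if not parts or not parts[0]:
                continue
            if parts[0] in out:
                raise DataError(f"line {lineno}: duplicate set {parts[0]!r}")
            out[parts[0]] = {g for g in parts[1:] if g}
    return out


def write_site_reads(sites: list[SiteReads], sample_ids: list[str], path: str | os.PathLike) -> None:
    """Read summaries as TSV: one row per site per sample, quals comma-joined."""
    with open(path, "w") as fh:
        fh.write(
            "chrom\tpos\tref\talt\tsample\tref_fwd\tref_rev\talt_fwd\talt_rev"
            "\tref_quals\talt_quals\tmapq\n"
        )
        for s in sites:
            for i, sid in enumerate(sample_ids):
                fh.write(
                    "\t".join(
                        [
                            s.chrom, str(s.pos), s.ref, s.alt, sid,
                            str(int(s.ref_fwd[i])), str(int(s.ref_rev[i])),
                            str(int(s.alt_fwd[i])), str(int(s.alt_rev[i])),
                            ",".join(map(str, s.ref_quals[i])) or ".",
                            ",".join(map(str, s.alt_quals[i])) or ".",
                            f"{s.mean_mapq:g}",
                        ]
                    )
                    + "\n"
                )


def read_site_reads(path: str | os.PathLike) -> tuple[list[SiteReads], list[str]]:
    df = pd.read_csv(
        path, sep="\t",
        dtype={"chrom": str, "ref": str, "alt": str, "sample": str,
               "ref_quals": str, "alt_quals": str},
    )
    sites: list[SiteReads] = []
    sample_ids: list[str] | None = None

    def parse_quals(s: str) -> np.ndarray:
        if s == "." or s == "" or pd.isna(s):
            return np.empty(0, dtype=np.int64)
        return np.array([int(x) for x in s.split(",")], dtype=np.int64)

    for (chrom, pos, ref, alt), grp in df.groupby(
        ["chrom", "pos", "ref", "alt"], sort=False
    ):
        ids = grp["sample"].tolist()
        if sample_ids is None:
            sample_ids = ids
        elif ids != sample_ids:
            raise DataError(f"inconsistent sample order at {chrom}:{pos}")
        sites.append(
            SiteReads(
                chrom, int(pos), ref, alt,
                grp["ref_fwd"].to_numpy(np.int64),
                grp["ref_rev"].to_numpy(np.int64),
                grp["alt_fwd"].to_numpy(np.int64),
                grp["alt_rev"].to_numpy(np.int64),
                [parse_quals(q) for q in grp["ref_quals"]],
                [parse_quals(q) for q in grp["alt_quals"]],
                float(grp["mapq"].iloc[0]),
            )
        )
    return sites, sample_ids or []


def write_truth(truth: TruthTable, variants: VariantTable, path_prefix: str | os.PathLike) -> None:
    """Truth tables as TSV: per-site MAF + genotypes, and causal genes."""
    prefix = Path(path_prefix)
    pd.DataFrame(
        {
            "chrom": variants.chrom,
            "pos": variants.pos,
            "gene": variants.gene,
            "class": variants.vclass,
            "true_maf": truth.site_maf,
        }
    ).to_csv(f"{prefix}.sites.tsv", sep="\t", index=False)
    np.savetxt(f"{prefix}.genotypes.tsv", truth.genotypes, fmt="%d", delimiter="\t")
    with open(f"{prefix}.causal_genes.txt", "w") as fh:
        for g in sorted(truth.causal_genes):
            fh.write(g + "\n")
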