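"""Readers and writers for the pipeline's file formats.

FASTA goes through Biopython, VCF through pysam; GFF3 uses a minimal
canonical reader/writer covering the gene/CDS subset this pipeline emits
(write-then-read is the identity on these records and malformed input
raises with the offending line number).  Tabular formats (genotype calls,
phenotypes, map, cluster summaries, sample QC) are tab-separated and read
with pandas.

Genotype-call files use the {AA, AB, BB, NC} alphabet; internally calls are
the single-letter codes {A, H, B, U}.
"""

from __future__ import annotations

import os
from collections.abc import Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    CALL_TO_CODE,
    CODE_TO_CALL,
    ClusterSummary,
    Gene,
    SampleQc,
    GeneticMap,
    LinkageGroup,
    SyntheticGenome,
    VariantRecord,
)


class FormatError(ValueError):
    """Malformed input file; message names the offending line."""


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(chromosomes: dict[str, str], path: str) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in chromosomes.items()
    ]
    SeqIO.write(records, path, "fasta")


def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


# ---------------------------------------------------------------------------
# GFF3 (gene + CDS subset)


def write_gff3(genes: Sequence[Gene], path: str, source: str = "cicerchip") -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            fh.write(
                f"{g.chrom}\t{source}\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t."
                f"\tID={g.name}\n"
            )
            exons = g.exons if g.strand == "+" else tuple(reversed(g.exons))
            phase = 0
            for s, e in exons:
                fh.write(
                    f"{g.chrom}\t{source}\tCDS\t{s}\t{e}\t.\t{g.strand}\t{phase}"
                    f"\tParent={g.name}\n"
                )
                phase = (3 - ((e - s + 1 - phase) % 3)) % 3


def read_gff3(path: str) -> list[Gene]:
    genes: dict[str, dict] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}:{lineno}: expected 9 tab-separated columns"
                )
            chrom, _src, ftype, start_s, end_s, _score, strand, _phase, attrs = fields
            try:
                start, end = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates")
            if start < 1 or end < start:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {start}-{end} (end < start?)"
                )
            if strand not in "+-":
                raise FormatError(f"{path}:{lineno}: bad strand {strand!r}")
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            if ftype == "gene":
                name = attr.get("ID")
                if not name:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[name] = {"chrom": chrom, "strand": strand, "exons": []}
                order.append(name)
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if parent not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: CDS with unknown Parent {parent!r}"
                    )
                genes[parent]["exons"].append((start, end))
    out = []
    for name in order:
        g = genes[name]
        out.append(
            Gene(
                name=name,
                chrom=g["chrom"],
                strand=g["strand"],
                exons=tuple(sorted(g["exons"])),
            )
        )
    return out


# ---------------------------------------------------------------------------
# VCF (v4.2 via pysam)


def _vcf_header(contigs: dict[str, int]) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.info.add("AC", "A", "Integer", "Alternate allele counts")
    header.info.add("AN", 1, "Integer", "Total observed alleles")
    return header


def write_vcf(
    variants: Sequence[VariantRecord], contigs: dict[str, int], path: str
) -> None:
    header = _vcf_header(contigs)
    with pysam.VariantFile(path, "w", header=header) as vcf:
        for v in variants:
            rec = vcf.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                alleles=(v.ref, *v.alts),
                qual=v.qual,
            )
            if v.id != ".":
                rec.id = v.id
            rec.info["AC"] = tuple(v.allele_counts[1:])
            rec.info["AN"] = sum(v.allele_counts)
            vcf.write(rec)


def read_vcf(path: str) -> list[VariantRecord]:
    out = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            alts = tuple(rec.alts or ())
            ac = rec.info.get("AC", ())
            if isinstance(ac, int):
                ac = (ac,)
            an = int(rec.info.get("AN", 0))
            counts = (an - sum(ac), *[int(c) for c in ac])
            out.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=alts,
                    qual=float(rec.qual if rec.qual is not None else 0.0),
                    allele_counts=counts,
                    id=rec.id or ".",
                )
            )
    return out


# ---------------------------------------------------------------------------
# genotype-call matrix TSV


def write_calls(calls: pd.DataFrame, path: str) -> None:
    """Write an internal-coded call matrix using the AA/AB/BB/NC alphabet."""
    external = calls.replace(CODE_TO_CALL)
    external.to_csv(path, sep="\t", index_label="marker")


def read_calls(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="marker", dtype=str)
    bad = ~df.isin(list(CALL_TO_CODE))
    if bad.to_numpy().any():
        row = df.index[bad.any(axis=1)][0]
        lineno = list(df.index).index(row) + 2  # + header line, 1-based
        raise FormatError(
            f"{path}:{lineno}: call outside {{AA, AB, BB, NC}} at marker {row}"
        )
    return df.replace(CALL_TO_CODE)


# ---------------------------------------------------------------------------
# phenotype TSV


PHENO_COLUMNS = ["sample", "trait", "environment", "location", "year", "value"]


def write_phenotypes(pheno: pd.DataFrame, path: str) -> None:
    pheno[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"year": str})
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# genetic-map TSV


def write_map(gmap: GeneticMap, path: str) -> None:
    rows = []
    for lg in gmap.groups:
        for m, p in zip(lg.markers, lg.positions_cm):
            rows.append((lg.name, m, p))
    pd.DataFrame(rows, columns=["group", "marker", "position_cm"]).to_csv(
        path, sep="\t", index=False
    )


def read_map(path: str) -> GeneticMap:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("group", "marker", "position_cm") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing columns {missing}")
    groups = []
    for name, sub in df.groupby("group", sort=False):
        pos = sub["position_cm"].tolist()
        if any(b < a for a, b in zip(pos, pos[1:])):
            raise FormatError(f"{path}: positions not non-decreasing in {name}")
        groups.append(
            LinkageGroup(
                name=str(name), markers=sub["marker"].astype(str).tolist(),
                positions_cm=[float(p) for p in pos],
            )
        )
    return GeneticMap(groups=groups)


# ---------------------------------------------------------------------------
# cluster-summary and sample-QC TSV


CLUSTER_COLUMNS = ["marker", "genotype", "n", "mean_x", "sd_x", "mean_y", "sd_y"]


def write_clusters(clusters: dict[str, list[ClusterSummary]], path: str) -> None:
    rows = []
    for marker, cl in clusters.items():
        for c in cl:
            rows.append((marker, c.genotype, c.n, c.mean_x, c.sd_x, c.mean_y, c.sd_y))
    pd.DataFrame(rows, columns=CLUSTER_COLUMNS).to_csv(path, sep="\t", index=False)


def read_clusters(path: str) -> dict[str, list[ClusterSummary]]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in CLUSTER_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing columns {missing}")
    out: dict[str, list[ClusterSummary]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.marker), []).append(
            ClusterSummary(
                genotype=str(row.genotype), n=int(row.n),
                mean_x=float(row.mean_x), sd_x=float(row.sd_x),
                mean_y=float(row.mean_y), sd_y=float(row.sd_y),
            )
        )
    return out


def write_sample_qc(samples: Sequence[SampleQc], path: str) -> None:
    pd.DataFrame(
        [(s.sample_id, s.dqc, s.call_rate) for s in samples],
        columns=["sample", "dqc", "call_rate"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_qc(path: str) -> list[SampleQc]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("sample", "dqc", "call_rate") if c not in df.columns]
    if missing:
        raise FormatError(f"{path}:1: missing columns {missing}")
    return [
        SampleQc(sample_id=str(r.sample), dqc=float(r.dqc), call_rate=float(r.call_rate))
        for r in df.itertuples(index=False)
    ]


def genome_from_files(fasta_path: str, gff_path: str) -> SyntheticGenome:
    return SyntheticGenome(
        chromosomes=read_fasta(fasta_path), genes=read_gff3(gff_path)
    )


def file_checksum(path: str) -> str:
    import hashlib

    h = hashlib.sha256()
    with open(path, "rb") as fh:
        h.update(fh.read())
    return h.hexdigest()
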