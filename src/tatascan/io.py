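"""Readers and writers: promoter FASTA, SNP tables (TSV and a minimal
VCF adapter), and marker-call tables.

FASTA header grammar: ``>GENE|tss=<int>|strand=+``. TSV tables are
UTF-8, tab-separated, '.' decimal separator, deterministic row order.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    HeaderFormatError,
    PromoterRecord,
    SnpRecord,
    AnnotationRecord,
)

SNP_COLUMNS = ["rsid", "gene", "offset", "ref", "alt"]


def _parse_header(header: str) -> tuple[str, int, str]:
    parts = header.split("|")
    if len(parts) != 3:
        raise HeaderFormatError(
            f"header {header!r}: expected 'GENE|tss=<int>|strand=+'"
        )
    gene, tss_part, strand_part = parts
    if not gene or not tss_part.startswith("tss=") or not strand_part.startswith("strand="):
        raise HeaderFormatError(
            f"header {header!r}: expected 'GENE|tss=<int>|strand=+'"
        )
    try:
        tss = int(tss_part[4:])
    except ValueError as exc:
        raise HeaderFormatError(f"header {header!r}: tss is not an integer") from exc
    return gene, tss, strand_part[7:]


def read_promoters(path: str | os.PathLike) -> list[PromoterRecord]:
    """Read 70-bp promoters from FASTA, preserving input order."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        gene, tss, strand = _parse_header(rec.id)
        records.append(
            PromoterRecord(gene_id=gene, sequence=str(rec.seq), tss=tss,
                           strand=strand)
        )
    return records


def write_promoters(records: Iterable[PromoterRecord],
                    path: str | os.PathLike) -> None:
    seqs = [
        SeqRecord(Seq(r.sequence),
                  id=f"{r.gene_id}|tss={r.tss}|strand={r.strand}",
                  description="")
        for r in records
    ]
    SeqIO.write(seqs, str(path), "fasta")


def read_snps(path: str | os.PathLike) -> list[SnpRecord]:
    """Read a SNP table: TSV with columns rsid, gene, offset, ref, alt."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SNP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"SNP table {path}: missing column(s) {sorted(missing)}")
    return [
        SnpRecord(rsid=row.rsid, gene_id=row.gene, offset=int(row.offset),
                  ref_allele=row.ref, alt_allele=row.alt)
        for row in df.itertuples()
    ]


def write_snps(snps: Iterable[SnpRecord], path: str | os.PathLike) -> None:
    df = pd.DataFrame(
        [(s.rsid, s.gene_id, s.offset, s.ref_allele, s.alt_allele)
         for s in snps],
        columns=SNP_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_snps_vcf(path: str | os.PathLike,
                  promoters: Sequence[PromoterRecord]) -> list[SnpRecord]:
    """Minimal VCF adapter: accepts SNV rows only and converts genomic
    coordinates to TSS offsets via the promoter FASTA metadata.

    The VCF CHROM field must match a promoter's gene_id, and POS is
    interpreted on the same assembly as the promoter's tss. Sense
    strand only: offset = POS - tss, required to fall in [-70, -1].
    Non-SNV records (indels, multi-allelic rows) are rejected.
    """
    from cyvcf2 import VCF

    by_gene = {p.gene_id: p for p in promoters}
    snps = []
    for var in VCF(str(path)):
        if var.CHROM not in by_gene:
            raise ValueError(f"VCF record at {var.CHROM}:{var.POS}: no promoter "
                             f"with gene_id {var.CHROM!r}")
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            raise ValueError(
                f"VCF record at {var.CHROM}:{var.POS}: only biallelic SNVs "
                "are supported"
            )
        promoter = by_gene[var.CHROM]
        offset = var.POS - promoter.tss
        rsid = var.ID or f"{var.CHROM}:{var.POS}"
        snps.append(
            SnpRecord(rsid=rsid, gene_id=var.CHROM, offset=offset,
                      ref_allele=var.REF, alt_allele=var.ALT[0])
        )
    return snps


def read_annotations(path: str | os.PathLike) -> list[AnnotationRecord]:
    """Annotation TSV: gene, expression_direction, potential_effect[, citation]."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    return [
        AnnotationRecord(gene_id=row.gene,
                         expression_direction=row.expression_direction,
                         potential_effect=row.potential_effect,
                         citation_tag=getattr(row, "citation", ""))
        for row in df.itertuples()
    ]


def marker_calls_frame(calls) -> pd.DataFrame:
    """Tabulate MarkerCall objects: per-allele K_D in nM with errors,
    delta, Z, alpha, decision, rank."""
    rows = []
    for c in calls:
        rows.append({
            "rsid": c.rsid,
            "gene": c.gene_id,
            "kd_wt_nM": c.kd_wt_nM,
            "kd_wt_se_ln": c.se_wt,
            "kd_min_nM": c.kd_min_nM,
            "kd_min_se_ln": c.se_min,
            "delta_ln_kd": c.delta_ln_kd,
            "z": c.z,
            "alpha": c.alpha,
            "decision": c.decision,
            "rho": c.rank_rho or "",
            "expression_ratio": c.expression_ratio,
        })
    return pd.DataFrame(
        rows,
        columns=["rsid", "gene", "kd_wt_nM", "kd_wt_se_ln", "kd_min_nM",
                 "kd_min_se_ln", "delta_ln_kd", "z", "alpha", "decision",
                 "rho", "expression_ratio"],
    )


def write_marker_calls(calls, path: str | os.PathLike) -> None:
    marker_calls_frame(calls).to_csv(path, sep="\t", index=False)
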