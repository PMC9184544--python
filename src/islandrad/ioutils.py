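"""Readers and writers for the pipeline's interchange formats.

FASTA (80-column wrap, A/C/G/T/N), a VCF v4.2 subset (biallelic SNVs,
FORMAT GT:DP:GQ, diploid unphased genotypes), species-label TSV, QC and
distance TSVs.  VCF positions are 1-based on disk and 0-based in memory.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from islandrad.popgen import DistanceHierarchy, NormalizedDistance
from islandrad.qc import QCReport
from islandrad.structure import GenotypeMatrix, PCAResult, VariantRecord

log = logging.getLogger(__name__)

_VALID = set("ACGTN")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into id -> sequence; uppercase-normalized, A/C/G/T/N only.

    A character outside the alphabet raises with the record id and offset.
    """
    out: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = next((i for i, ch in enumerate(seq) if ch not in _VALID), None)
        if bad is not None:
            raise ValueError(f"invalid base {seq[bad]!r} in record {rec.id!r} at offset {bad}")
        out[rec.id] = seq
    return out


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    """Write id -> sequence as FASTA wrapped at 80 columns."""
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(records)


def write_vcf(
    gm: GenotypeMatrix,
    path: str | Path,
    contig_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a GenotypeMatrix as a minimal VCF v4.2 with GT:DP:GQ."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=islandrad\n")
        if contig_lengths:
            for contig, ln in contig_lengths.items():
                fh.write(f"##contig=<ID={contig},length={ln}>\n")
        else:
            for contig in dict.fromkeys(v.contig for v in gm.variants):
                fh.write(f"##contig=<ID={contig}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">\n')
        fh.write('##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples) + "\n")
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}
        for i, v in enumerate(gm.variants):
            fields = [v.contig, str(v.pos0 + 1), ".", v.ref, v.alt, ".", ".", ".", "GT:DP:GQ"]
            for j in range(gm.n_samples):
                dp = int(gm.dp[i, j]) if gm.dp is not None else 0
                gq = int(gm.gq[i, j]) if gm.gq is not None else 0
                fields.append(f"{gt_str[int(gm.dosage[i, j])]}:{dp}:{gq}")
            fh.write("\t".join(fields) + "\n")


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read the VCF v4.2 subset back into a GenotypeMatrix.

    Multi-allelic records and indels are skipped with a logged warning;
    positions move to the internal 0-based convention.  A missing DP or GQ
    FORMAT field leaves the corresponding array as None, and downstream
    filters that need it will raise by name.
    """
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    variants: list[VariantRecord] = []
    dosage_rows, dp_rows, gq_rows = [], [], []
    skipped_multi = skipped_indel = 0
    has_dp = has_gq = True
    for rec in vcf:
        if len(rec.ALT) != 1:
            skipped_multi += 1
            continue
        if len(rec.REF) != 1 or len(rec.ALT[0]) != 1:
            skipped_indel += 1
            continue
        variants.append(VariantRecord(rec.CHROM, rec.POS - 1, rec.REF, rec.ALT[0]))
        gts = rec.gt_types.astype(np.int8)  # gts012: 0,1,2 and 3=missing
        gts[gts == 3] = -1
        dosage_rows.append(gts)
        dp = rec.format("DP")
        if dp is None:
            has_dp = False
        else:
            dp_rows.append(np.where(dp[:, 0] < 0, 0, dp[:, 0]).astype(np.int32))
        gq = rec.format("GQ")
        if gq is None:
            has_gq = False
        else:
            gq_rows.append(np.where(gq[:, 0] < 0, 0, gq[:, 0]).astype(np.int32))
    if skipped_multi:
        log.warning("read_vcf: skipped %d multi-allelic records", skipped_multi)
    if skipped_indel:
        log.warning("read_vcf: skipped %d indel records", skipped_indel)
    n = len(variants)
    dosage = np.vstack(dosage_rows) if n else np.empty((0, len(samples)), np.int8)
    return GenotypeMatrix(
        samples=samples,
        variants=variants,
        dosage=dosage,
        dp=np.vstack(dp_rows) if (has_dp and dp_rows) else None,
        gq=np.vstack(gq_rows) if (has_gq and gq_rows) else None,
    )


def read_labels(path: str | Path) -> dict[str, str]:
    """Read an individual -> species TSV (with or without a header line)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        ind, sp = line.split("\t")
        if ind == "individual" and sp == "species":
            continue
        out[ind] = sp
    return out


def write_qc_reports(reports, path: str | Path) -> None:
    """QC reports as TSV: alignment id, pi_sites, missing_frac, gc_frac, pass."""
    with open(path, "w") as fh:
        fh.write("alignment\tpi_sites\tmissing_frac\tgc_frac\tpass\n")
        for r in reports:
            fh.write(
                f"{r.alignment_id}\t{r.pi_sites}\t{r.missing_frac:.6f}\t{r.gc_frac:.6f}\t{int(r.passed)}\n"
            )


def write_distances(hierarchy: DistanceHierarchy, path: str | Path) -> None:
    """Distances as TSV: pair, n segments, raw, normalized, stratum."""
    with open(path, "w") as fh:
        fh.write("individual_a\tindividual_b\tn_segments\traw\tnormalized\tstratum\n")
        for name, stratum in (
            ("focal_vs_each", hierarchy.focal_vs_each),
            ("within_species", hierarchy.within_species),
            ("between_species", hierarchy.between_species),
        ):
            for d in stratum:
                fh.write(f"{d.pair[0]}\t{d.pair[1]}\t{d.n_segments}\t{d.raw:.8g}\t{d.value:.8g}\t{name}\n")


def write_pca(result: PCAResult, path: str | Path) -> None:
    """Sample coordinates plus a trailing variance-explained row block."""
    k = result.coordinates.shape[1]
    with open(path, "w") as fh:
        fh.write("sample\t" + "\t".join(f"PC{i+1}" for i in range(k)) + "\n")
        for s, row in zip(result.samples, result.coordinates):
            fh.write(s + "\t" + "\t".join(f"{x:.8g}" for x in row) + "\n")
        fh.write(
            "#variance_explained\t"
            + "\t".join(f"{x:.4f}" for x in result.variance_explained[:k])
            + "\n"
        )
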