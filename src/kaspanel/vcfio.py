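"""Variant records and file I/O.

The in-memory unit of the screening pipeline is :class:`VariantRecord`, a
plain dataclass holding one multi-sample VCF site: coordinates, alleles,
site quality, the GATK-style INFO annotations used for hard filtering
(QD, FS, MQ, MQRankSum, ReadPosRankSum) and unphased per-sample genotypes.

Cohort VCFs are read with :mod:`cyvcf2` and written with :mod:`pysam`;
genotype matrices travel as TSV (rows = loci, columns = samples, calls
coded 0/1/2 copies of the minor allele, ``.`` = missing).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
import pysam
from cyvcf2 import VCF

#: INFO annotations consumed by the hard filter, in canonical order.
ANNOTATION_KEYS = ("QD", "FS", "MQ", "MQRankSum", "ReadPosRankSum")

#: genotype call for an untyped sample
MISSING_GT: Optional[tuple[int, int]] = None


@dataclass
class VariantRecord:
    """One VCF site with per-sample diploid genotypes.

    ``genotypes`` holds one ``(a, b)`` pair of allele indices per sample
    (0 = REF, 1.. = ALT), or ``None`` for a missing call. ``tags`` carries
    pipeline labels such as ``FIRSTOK``.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alts: tuple[str, ...]
    qual: Optional[float] = None
    annotations: dict[str, float] = field(default_factory=dict)
    genotypes: list[Optional[tuple[int, int]]] = field(default_factory=list)
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        for alt in self.alts:
            if alt == self.ref:
                raise ValueError(f"ALT equals REF ({alt}) at {self.chrom}:{self.pos}")
        n_alleles = 1 + len(self.alts)
        for gt in self.genotypes:
            if gt is not None and not all(0 <= a < n_alleles for a in gt):
                raise ValueError(
                    f"genotype {gt} out of range at {self.chrom}:{self.pos}"
                )

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and all(len(a) == 1 for a in self.alts)

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}_{self.pos}"

    def genotype_counts(self) -> tuple[int, int, int]:
        """(hom-ref, het, hom-alt) counts over non-missing biallelic calls."""
        n0 = n1 = n2 = 0
        for gt in self.genotypes:
            if gt is None:
                continue
            dose = (gt[0] > 0) + (gt[1] > 0)
            if dose == 0:
                n0 += 1
            elif dose == 1:
                n1 += 1
            else:
                n2 += 1
        return n0, n1, n2

    def missing_fraction(self) -> float:
        if not self.genotypes:
            return 0.0
        return sum(gt is None for gt in self.genotypes) / len(self.genotypes)

    def alt_frequency(self) -> Optional[float]:
        """ALT allele frequency over non-missing calls; None if all missing."""
        n0, n1, n2 = self.genotype_counts()
        n = n0 + n1 + n2
        if n == 0:
            return None
        return (n1 + 2 * n2) / (2 * n)

    def minor_allele_frequency(self) -> Optional[float]:
        p = self.alt_frequency()
        if p is None:
            return None
        return min(p, 1.0 - p)


def _build_header(
    contigs: Mapping[str, int], samples: Sequence[str]
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    header.add_meta(
        "INFO", items=[("ID", "QD"), ("Number", 1), ("Type", "Float"),
                       ("Description", "Variant confidence normalized by depth")]
    )
    header.add_meta(
        "INFO", items=[("ID", "FS"), ("Number", 1), ("Type", "Float"),
                       ("Description", "Phred-scaled strand bias Fisher p")]
    )
    header.add_meta(
        "INFO", items=[("ID", "MQ"), ("Number", 1), ("Type", "Float"),
                       ("Description", "RMS mapping quality")]
    )
    header.add_meta(
        "INFO", items=[("ID", "MQRankSum"), ("Number", 1), ("Type", "Float"),
                       ("Description", "Mapping quality rank-sum Z")]
    )
    header.add_meta(
        "INFO", items=[("ID", "ReadPosRankSum"), ("Number", 1), ("Type", "Float"),
                       ("Description", "Read position rank-sum Z")]
    )
    header.add_meta(
        "FORMAT", items=[("ID", "GT"), ("Number", 1), ("Type", "String"),
                         ("Description", "Genotype")]
    )
    for s in samples:
        header.add_sample(s)
    return header


def write_vcf(
    records: Iterable[VariantRecord],
    path: str | os.PathLike,
    contigs: Mapping[str, int],
    samples: Sequence[str],
) -> None:
    """Write records as an uncompressed multi-sample VCF (unphased GT only)."""
    header = _build_header(contigs, samples)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for rec in records:
            site = out.new_record(
                contig=rec.chrom,
                start=rec.pos - 1,
                stop=rec.pos - 1 + len(rec.ref),
                alleles=(rec.ref, *rec.alts),
            )
            site.qual = rec.qual
            for key in ANNOTATION_KEYS:
                if key in rec.annotations:
                    site.info[key] = rec.annotations[key]
            for i, gt in enumerate(rec.genotypes):
                site.samples[i]["GT"] = gt if gt is not None else (None, None)
                site.samples[i].phased = False
            out.write(site)


def read_vcf(path: str | os.PathLike) -> tuple[list[VariantRecord], list[str]]:
    """Read a VCF (plain or bgzipped) into records; returns (records, samples)."""
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for v in vcf:
        annotations = {}
        for key in ANNOTATION_KEYS:
            val = v.INFO.get(key)
            if val is not None:
                annotations[key] = float(val)
        genotypes: list[Optional[tuple[int, int]]] = []
        for g in v.genotypes:  # [a, b, phased]
            a, b = g[0], g[1]
            genotypes.append(None if a < 0 or b < 0 else (a, b))
        records.append(
            VariantRecord(
                chrom=v.CHROM,
                pos=v.POS,
                ref=v.REF,
                alts=tuple(v.ALT),
                qual=None if v.QUAL is None else float(v.QUAL),
                annotations=annotations,
                genotypes=genotypes,
            )
        )
    vcf.close()
    return records, samples


def write_genotype_tsv(
    calls: pd.DataFrame, path: str | os.PathLike
) -> None:
    """Write a loci x samples matrix of 0/1/2 minor-allele doses ('.' = missing)."""
    out = calls.copy()
    out = out.astype(object).where(~calls.isna(), ".")
    out = out.map(lambda v: v if v == "." else str(int(v)))
    out.to_csv(path, sep="\t", index_label="locus_id")


def read_genotype_tsv(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genotype TSV back into a float matrix with NaN for missing."""
    df = pd.read_csv(path, sep="\t", index_col="locus_id", dtype=str)
    return df.replace(".", pd.NA).astype("Float64").astype(float)
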