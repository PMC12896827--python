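"""KASP assay construction for panel SNPs.

A Kompetitive Allele-Specific PCR (KASP) assay interrogates one biallelic
SNP with three primers: two allele-specific forward primers that differ
only at their 3' terminal base (each carrying a universal 5' fluorescent
tail — FAM for the first allele, VIC for the second) and one common
reverse primer downstream of the SNP. The master mix couples each tail to
its fluorophore, so endpoint fluorescence reads out the genotype. Primer
premixes combine F1:F2:R at a 1:1:3 volume ratio.

This module extracts the +/-150 bp flanking context of each SNP from the
reference, builds the tailed primers by simple geometry (allele base at
the 3' end of the forward body; reverse primer as the reverse complement
of a fixed window downstream), and writes an orderable assay sheet.
Thermodynamic optimisation (Tm, secondary structure) is deliberately out
of scope — primer geometry is configuration.
"""

from __future__ import annotations

import json
import os
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

#: universal KASP tail sequences (5' -> 3')
FAM_TAIL = "GAAGGTGACCAAGTTCATGCT"
VIC_TAIL = "GAAGGTCGGAGTCAACGGATT"

#: F1 : F2 : common-reverse volume ratio in the primer premix
PREMIX_RATIO = (1, 1, 3)

DEFAULT_FLANK = 150


@dataclass(frozen=True)
class FlankContext:
    """Reference context around one SNP (flanks up to 150 bp each side)."""

    chrom: str
    pos: int  # 1-based
    left: str
    ref_base: str
    right: str

    @property
    def sequence(self) -> str:
        return self.left + self.ref_base + self.right


@dataclass(frozen=True)
class KaspAssay:
    """One locus's primer set: FAM/VIC-tailed forwards plus common reverse."""

    locus_id: str
    chrom: str
    pos: int
    allele_fam: str
    allele_vic: str
    f1: str  # FAM tail + allele-specific body ending in allele_fam
    f2: str  # VIC tail + allele-specific body ending in allele_vic
    reverse: str
    premix_ratio: tuple[int, int, int] = PREMIX_RATIO


def extract_flanks(
    reference: Fasta | os.PathLike | str,
    chrom: str,
    pos: int,
    flank: int = DEFAULT_FLANK,
) -> FlankContext:
    """Pull the SNP base and up to ``flank`` bp either side from the reference.

    Flanks are truncated (with a warning) at chromosome ends.
    """
    fasta = reference if isinstance(reference, Fasta) else Fasta(str(reference))
    if chrom not in fasta:
        raise KeyError(f"chromosome {chrom!r} not in reference")
    length = len(fasta[chrom])
    if not (1 <= pos <= length):
        raise ValueError(f"position {pos} outside {chrom} (length {length})")
    start = max(1, pos - flank)
    end = min(length, pos + flank)
    if start > pos - flank or end < pos + flank:
        warnings.warn(
            f"{chrom}:{pos}: flank truncated at chromosome boundary", stacklevel=2
        )
    left = str(fasta[chrom][start - 1 : pos - 1]).upper()
    ref_base = str(fasta[chrom][pos - 1]).upper()
    right = str(fasta[chrom][pos : end]).upper()
    return FlankContext(chrom=chrom, pos=pos, left=left, ref_base=ref_base, right=right)


def design_kasp_primers(
    context: FlankContext,
    alleles: Sequence[str],
    body_length: int = 22,
    reverse_offset: int = 30,
    reverse_length: int = 22,
    locus_id: str | None = None,
) -> KaspAssay:
    """Build the three-primer KASP set for one SNP.

    The allele-specific body is the last ``body_length - 1`` bases of the
    left flank followed by the allele base, so each allele sits at the 3'
    terminus where extension is most discriminating. The common reverse
    primer is the reverse complement of the plus-strand window beginning
    ``reverse_offset`` bases to the right of the SNP. The first allele
    (conventionally the reference allele) maps to FAM, the second to VIC.
    """
    a1, a2 = alleles
    if len(a1) != 1 or len(a2) != 1:
        raise ValueError("KASP design requires single-base alleles")
    if a1 == a2:
        raise ValueError("alleles must differ")
    if body_length < 1 or body_length - 1 > len(context.left):
        raise ValueError(
            f"left flank ({len(context.left)} bp) too short for body length "
            f"{body_length}"
        )
    stem = context.left[len(context.left) - (body_length - 1) :]
    if reverse_offset + reverse_length > len(context.right):
        raise ValueError(
            f"right flank ({len(context.right)} bp) too short for reverse primer "
            f"(offset {reverse_offset} + length {reverse_length})"
        )
    window = context.right[reverse_offset : reverse_offset + reverse_length]
    reverse = str(Seq(window).reverse_complement())
    return KaspAssay(
        locus_id=locus_id or f"{context.chrom}_{context.pos}",
        chrom=context.chrom,
        pos=context.pos,
        allele_fam=a1,
        allele_vic=a2,
        f1=FAM_TAIL + stem + a1,
        f2=VIC_TAIL + stem + a2,
        reverse=reverse,
    )


_SHEET_COLUMNS = ["locus_id", "role", "dye", "allele", "sequence", "premix_part"]


def write_assay_sheet(assays: Sequence[KaspAssay], path: str | os.PathLike) -> None:
    """One CSV row per primer (3 per assay), with premix parts recorded."""
    if not assays:
        raise ValueError("no assays to write")
    seen = set()
    for a in assays:
        if a.locus_id in seen:
            raise ValueError(f"duplicate locus ID {a.locus_id}")
        seen.add(a.locus_id)
    rows = []
    for a in assays:
        r1, r2, r3 = a.premix_ratio
        rows.append([a.locus_id, "F1", "FAM", a.allele_fam, a.f1, r1])
        rows.append([a.locus_id, "F2", "VIC", a.allele_vic, a.f2, r2])
        rows.append([a.locus_id, "R", "", "", a.reverse, r3])
    pd.DataFrame(rows, columns=_SHEET_COLUMNS).to_csv(path, index=False)


def read_assay_sheet(path: str | os.PathLike) -> list[KaspAssay]:
    """Re-parse an assay sheet into assay objects (round-trips the writer)."""
    df = pd.read_csv(path, keep_default_na=False)
    assays = []
    for locus_id, grp in df.groupby("locus_id", sort=False):
        by_role = {row["role"]: row for _, row in grp.iterrows()}
        f1, f2, rev = by_role["F1"], by_role["F2"], by_role["R"]
        chrom, _, pos = str(locus_id).rpartition("_")
        assays.append(
            KaspAssay(
                locus_id=str(locus_id),
                chrom=chrom,
                pos=int(pos),
                allele_fam=f1["allele"],
                allele_vic=f2["allele"],
                f1=f1["sequence"],
                f2=f2["sequence"],
                reverse=rev["sequence"],
                premix_ratio=(
                    int(f1["premix_part"]),
                    int(f2["premix_part"]),
                    int(rev["premix_part"]),
                ),
            )
        )
    return assays


def write_assay_json(assays: Sequence[KaspAssay], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(a) for a in assays], fh, indent=2)
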