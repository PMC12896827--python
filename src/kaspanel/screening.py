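"""Candidate-SNP screening from a joint-genotyped cohort VCF.

The screen reproduces a marker-development workflow for a small resequenced
cohort: GATK-style hard filtering on site annotations, restriction to
isolated biallelic SNPs (no other variant within a fixed window, protecting
future primer-binding context), a high-confidence quality tag (``FIRSTOK``,
QUAL >= 1000), VCFtools-style population filters (minor allele frequency,
completeness, Hardy-Weinberg), and finally an informativeness band on the
Botstein polymorphism information content (PIC).

All inequalities are inclusive: a site sitting exactly on a threshold
passes. Annotations absent from a record (rank-sum statistics are undefined
at sites without both homozygote classes) skip their criterion rather than
fail it, mirroring how GATK's VariantFiltration treats missing annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

from .popgen import hwe_test_from_counts, pic_biallelic
from .vcfio import VariantRecord


@dataclass(frozen=True)
class HardFilterThresholds:
    """Inclusive bounds on site quality and INFO annotations."""

    qd_min: float = 2.0
    qual_min: float = 30.0
    fs_max: float = 60.0
    mq_min: float = 40.0
    mqranksum_min: float = -12.5
    readposranksum_min: float = -8.0


@dataclass(frozen=True)
class ScreenConfig:
    """Every threshold of the screening pipeline, with published defaults."""

    stage1: HardFilterThresholds = field(default_factory=HardFilterThresholds)
    stage2: HardFilterThresholds = field(
        default_factory=lambda: HardFilterThresholds(qual_min=1000.0)
    )
    isolation_window: int = 100  # bp; exclude if another variant is <= window away
    maf_min: float = 0.05
    max_missing_fraction: float = 0.0  # VCFtools --max-missing 1
    hwe_alpha: float = 0.001
    pic_min: float = 0.2
    pic_max: float = 0.5
    hwe_method: Literal["exact", "chi2"] = "exact"

    def __post_init__(self) -> None:
        if not (0.0 <= self.pic_min <= self.pic_max <= 1.0):
            raise ValueError("PIC band must satisfy 0 <= low <= high <= 1")
        if self.isolation_window < 0:
            raise ValueError("isolation window must be >= 0")


@dataclass
class CandidateSNP:
    """A surviving biallelic SNP with its cohort-level summary."""

    locus_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float  # minor allele frequency in the discovery cohort
    pic: float
    flags: dict[str, bool] = field(default_factory=dict)


def evaluate_hard_filter(
    record: VariantRecord, thresholds: HardFilterThresholds
) -> tuple[bool, list[str], list[str]]:
    """Apply the annotation hard filter to one record.

    Returns ``(passed, failed, missing)`` where ``failed`` names each
    violated criterion and ``missing`` each annotation that was absent and
    therefore skipped.
    """
    failed: list[str] = []
    missing: list[str] = []

    if record.qual is None:
        missing.append("QUAL")
    elif record.qual < thresholds.qual_min:
        failed.append("QUAL")

    checks = (
        ("QD", thresholds.qd_min, "min"),
        ("FS", thresholds.fs_max, "max"),
        ("MQ", thresholds.mq_min, "min"),
        ("MQRankSum", thresholds.mqranksum_min, "min"),
        ("ReadPosRankSum", thresholds.readposranksum_min, "min"),
    )
    for key, bound, kind in checks:
        value = record.annotations.get(key)
        if value is None:
            missing.append(key)
        elif (kind == "min" and value < bound) or (kind == "max" and value > bound):
            failed.append(key)

    return not failed, failed, missing


def apply_hard_filter(
    records: Iterable[VariantRecord], thresholds: HardFilterThresholds
) -> list[VariantRecord]:
    return [r for r in records if evaluate_hard_filter(r, thresholds)[0]]


FIRSTOK = "FIRSTOK"


def tag_high_confidence(
    records: Iterable[VariantRecord], thresholds: HardFilterThresholds
) -> list[VariantRecord]:
    """Tag (never delete) records meeting the high-confidence thresholds."""
    tagged = []
    for rec in records:
        passed, _, _ = evaluate_hard_filter(rec, thresholds)
        tags = set(rec.tags)
        if passed:
            tags.add(FIRSTOK)
        else:
            tags.discard(FIRSTOK)
        tagged.append(replace(rec, tags=tags))
    return tagged


def select_isolated_biallelic(
    records: Sequence[VariantRecord], window: int = 100
) -> list[VariantRecord]:
    """Keep biallelic SNPs with no other variant within ``window`` bp.

    Isolation is checked against *all* input records, SNP or not: a
    candidate is dropped if any other variant sits at distance <= window
    on the same chromosome. Output is sorted by (chromosome, position).
    """
    ordered = sorted(records, key=lambda r: (r.chrom, r.pos))
    kept: list[VariantRecord] = []
    for i, rec in enumerate(ordered):
        if not (rec.is_snp and rec.is_biallelic):
            continue
        crowded = False
        if i > 0:
            prev = ordered[i - 1]
            if prev.chrom == rec.chrom and rec.pos - prev.pos <= window:
                crowded = True
        if i + 1 < len(ordered):
            nxt = ordered[i + 1]
            if nxt.chrom == rec.chrom and nxt.pos - rec.pos <= window:
                crowded = True
        if not crowded:
            kept.append(rec)
    return kept


def popgen_prefilter(
    records: Iterable[VariantRecord],
    maf_min: float = 0.05,
    max_missing_fraction: float = 0.0,
    hwe_alpha: float = 0.001,
    hwe_method: Literal["exact", "chi2"] = "exact",
) -> list[VariantRecord]:
    """VCFtools-style site filters: --maf, --max-missing, --hwe.

    A locus passes when its minor allele frequency over non-missing
    genotypes is >= ``maf_min``, its missing-call fraction is
    <= ``max_missing_fraction``, and its Hardy-Weinberg p-value is
    >= ``hwe_alpha``. Loci with no typed genotypes are removed.
    """
    kept = []
    for rec in records:
        if rec.missing_fraction() > max_missing_fraction:
            continue
        maf = rec.minor_allele_frequency()
        if maf is None or maf < maf_min:
            continue
        counts = rec.genotype_counts()
        if hwe_test_from_counts(*counts, method=hwe_method) < hwe_alpha:
            continue
        kept.append(rec)
    return kept


def pic_band_filter(
    records: Iterable[VariantRecord], low: float = 0.2, high: float = 0.5
) -> list[VariantRecord]:
    """Keep loci whose cohort PIC lies in [low, high] (inclusive)."""
    kept = []
    for rec in records:
        p = rec.alt_frequency()
        if p is None:
            continue
        if low <= pic_biallelic(p) <= high:
            kept.append(rec)
    return kept


def _to_candidate(rec: VariantRecord) -> CandidateSNP:
    p = rec.alt_frequency()
    assert p is not None
    return CandidateSNP(
        locus_id=rec.locus_id,
        chrom=rec.chrom,
        pos=rec.pos,
        ref=rec.ref,
        alt=rec.alts[0],
        maf=min(p, 1 - p),
        pic=pic_biallelic(p),
        flags={
            "hard_filter": True,
            "isolated_biallelic": True,
            "firstok": True,
            "popgen": True,
            "pic_band": True,
        },
    )


def screen_candidates(
    records: Sequence[VariantRecord], config: ScreenConfig | None = None
) -> tuple[list[CandidateSNP], dict[str, int]]:
    """Run the full screen and report per-stage survivor counts.

    Stage order: annotation hard filter -> isolated biallelic SNPs ->
    high-confidence (FIRSTOK) requirement -> population filters
    (MAF / completeness / HWE) -> isolation re-check -> PIC band.
    The isolation re-check matters because earlier stages can remove a
    locus's only close neighbour or vice versa; it is run against the
    loci surviving the population filters.
    """
    config = config or ScreenConfig()
    report: dict[str, int] = {"input": len(records)}

    stage = apply_hard_filter(records, config.stage1)
    report["hard_filter"] = len(stage)

    stage = select_isolated_biallelic(stage, config.isolation_window)
    report["isolated_biallelic"] = len(stage)

    stage = [r for r in tag_high_confidence(stage, config.stage2) if FIRSTOK in r.tags]
    report["firstok"] = len(stage)

    stage = popgen_prefilter(
        stage,
        config.maf_min,
        config.max_missing_fraction,
        config.hwe_alpha,
        config.hwe_method,
    )
    report["popgen"] = len(stage)

    stage = select_isolated_biallelic(stage, config.isolation_window)
    report["isolated_recheck"] = len(stage)

    stage = pic_band_filter(stage, config.pic_min, config.pic_max)
    report["pic_band"] = len(stage)

    candidates = [_to_candidate(r) for r in stage]
    return candidates, report
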