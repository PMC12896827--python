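"""Synthetic inputs with known truth for every pipeline stage.

Three generators stand in for the sequencing products a marker-development
study starts from:

* :func:`simulate_reference` — random chromosome-level reference sequences
  with a controlled GC fraction (a synthetic stand-in for a real assembly).
* :func:`simulate_cohort_vcf` — a joint-genotyped cohort VCF for a small
  resequenced panel, with GATK-style site annotations (QD, FS, MQ,
  MQRankSum, ReadPosRankSum) drawn from configurable laws and genotypes
  drawn under Hardy-Weinberg equilibrium at each site's simulated allele
  frequency. Defaults put every record comfortably inside the screening
  pass region, so that :func:`plant_violations` can then overwrite chosen
  records to fail exactly one criterion each and emit a truth table — the
  oracle against which the screening stages are checked.
* :func:`simulate_genotype_matrix` — population genotype matrices under an
  inbreeding-adjusted Hardy-Weinberg law with configurable minor allele
  frequency, inbreeding coefficient f and missingness, for parameter-
  recovery checks of the diversity statistics.

All generators are deterministic under their seed.
"""

from __future__ import annotations

import copy
import os
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .popgen import GenotypeMatrix, hwe_test_from_counts, pic_biallelic
from .vcfio import VariantRecord, write_vcf

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class ReferenceModel:
    """Synthetic reference genome: chromosome lengths and base composition."""

    chromosomes: Mapping[str, int]
    gc_fraction: float = 0.41
    seed: int = 0

    def __post_init__(self) -> None:
        for name, length in self.chromosomes.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length")
        if not (0.0 <= self.gc_fraction <= 1.0):
            raise ValueError("GC fraction must lie in [0, 1]")


def simulate_reference(spec: ReferenceModel) -> dict[str, str]:
    """Draw one random sequence per chromosome; identical seed, identical bases."""
    rng = np.random.default_rng(spec.seed)
    gc = spec.gc_fraction
    probs = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return {
        name: "".join(rng.choice(_BASES, size=length, p=probs))
        for name, length in spec.chromosomes.items()
    }


def write_fasta(sequences: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def write_fasta_index_tsv(
    sequences: Mapping[str, str], path: str | os.PathLike
) -> None:
    """Chromosome-length table (name, length) in FASTA-index style."""
    pd.DataFrame(
        {"name": list(sequences), "length": [len(s) for s in sequences.values()]}
    ).to_csv(path, sep="\t", index=False, header=False)


@dataclass(frozen=True)
class AnnotationLaws:
    """Uniform ranges for QUAL and the INFO annotations of simulated sites.

    Defaults sit well inside the hard-filter pass region (including the
    QUAL >= 1000 high-confidence tag), so an unmodified cohort survives
    screening in full.
    """

    qual: tuple[float, float] = (1200.0, 3000.0)
    qd: tuple[float, float] = (15.0, 35.0)
    fs: tuple[float, float] = (0.0, 10.0)
    mq: tuple[float, float] = (50.0, 60.0)
    mqranksum: tuple[float, float] = (-2.0, 2.0)
    readposranksum: tuple[float, float] = (-2.0, 2.0)

    def draw(self, rng: np.random.Generator) -> tuple[float, dict[str, float]]:
        qual = rng.uniform(*self.qual)
        info = {
            "QD": rng.uniform(*self.qd),
            "FS": rng.uniform(*self.fs),
            "MQ": rng.uniform(*self.mq),
            "MQRankSum": rng.uniform(*self.mqranksum),
            "ReadPosRankSum": rng.uniform(*self.readposranksum),
        }
        return qual, info


@dataclass
class CohortSim:
    """A simulated joint-genotyped cohort, writable as VCF v4.2."""

    records: list[VariantRecord]
    contigs: dict[str, int]
    samples: list[str]

    def write(self, path: str | os.PathLike) -> None:
        write_vcf(self.records, path, self.contigs, self.samples)


def _draw_hwe_genotypes(
    rng: np.random.Generator, n_samples: int, maf: float
) -> list[tuple[int, int]]:
    """Unphased genotypes multinomially drawn from (p^2, 2pq, q^2)."""
    q = maf
    p = 1.0 - q
    counts = rng.multinomial(n_samples, [p * p, 2 * p * q, q * q])
    gts = [(0, 0)] * counts[0] + [(0, 1)] * counts[1] + [(1, 1)] * counts[2]
    rng.shuffle(gts)
    return gts


def _passes_popgen(gts: Sequence[tuple[int, int]]) -> bool:
    """Clean-record guard: empirical MAF, HWE and PIC inside the screen bands."""
    n1 = sum((a != b) for a, b in gts)
    n2 = sum((a == b == 1) for a, b in gts)
    n0 = len(gts) - n1 - n2
    alt = (n1 + 2 * n2) / (2 * len(gts))
    maf = min(alt, 1 - alt)
    if maf < 0.05:
        return False
    if hwe_test_from_counts(n0, n1, n2, method="exact") < 0.001:
        return False
    return 0.2 <= pic_biallelic(alt) <= 0.5


def simulate_cohort_vcf(
    reference: Mapping[str, str],
    n_samples: int = 12,
    snp_density: float = 1 / 2000,
    maf_law: Optional[Callable[[np.random.Generator], float]] = None,
    annotation_laws: AnnotationLaws = AnnotationLaws(),
    seed: int = 0,
    ensure_clean: bool = True,
) -> CohortSim:
    """Simulate the post-variant-calling cohort VCF for a resequenced panel.

    Per chromosome the variant count is Binomial(length, density) and
    positions are drawn without replacement (so coordinates are unique and
    strictly increasing). Each site gets a simulated minor allele frequency
    from ``maf_law`` (default Uniform(0.2, 0.5)), HWE genotypes at that
    frequency, and annotations from ``annotation_laws``.

    With ``ensure_clean`` (default) genotype draws that would fail the
    population filters by sampling noise at small n are redrawn, falling
    back to the rounded Hardy-Weinberg expectation; this is what makes the
    unmodified cohort a guaranteed-pass baseline for planted-violation
    oracles.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples for a cohort")
    rng = np.random.default_rng(seed)
    maf_law = maf_law or (lambda r: r.uniform(0.2, 0.5))
    records: list[VariantRecord] = []
    contigs = {name: len(seq) for name, seq in reference.items()}
    for chrom, seq in reference.items():
        length = len(seq)
        n_sites = rng.binomial(length, snp_density)
        if n_sites > length:
            raise ValueError("variant density too high: positions collide")
        positions = np.sort(rng.choice(length, size=n_sites, replace=False)) + 1
        for pos in positions:
            ref_base = seq[pos - 1]
            alt_base = rng.choice([b for b in "ACGT" if b != ref_base])
            maf = float(maf_law(rng))
            gts = _draw_hwe_genotypes(rng, n_samples, maf)
            if ensure_clean:
                for _ in range(20):
                    if _passes_popgen(gts):
                        break
                    gts = _draw_hwe_genotypes(rng, n_samples, maf)
                else:
                    gts = _balanced_hwe_genotypes(rng, n_samples, maf)
            qual, info = annotation_laws.draw(rng)
            records.append(
                VariantRecord(
                    chrom=chrom,
                    pos=int(pos),
                    ref=ref_base,
                    alts=(str(alt_base),),
                    qual=qual,
                    annotations=info,
                    genotypes=list(gts),
                )
            )
    samples = [f"ind{i + 1:02d}" for i in range(n_samples)]
    return CohortSim(records=records, contigs=contigs, samples=samples)


def _balanced_hwe_genotypes(
    rng: np.random.Generator, n_samples: int, maf: float
) -> list[tuple[int, int]]:
    """Rounded-expectation HWE configuration at the target frequency."""
    minor = max(4, round(2 * n_samples * maf))  # >= 4 keeps PIC above 0.2
    hom_minor = round(minor * minor / (4 * n_samples))
    het = minor - 2 * hom_minor
    gts = (
        [(0, 0)] * (n_samples - het - hom_minor)
        + [(0, 1)] * het
        + [(1, 1)] * hom_minor
    )
    rng.shuffle(gts)
    return gts


@dataclass(frozen=True)
class ViolationSpec:
    """How many records to rewrite so they fail each screening criterion.

    ``proximity_pairs`` plants pairs: for each pair a clean companion SNP
    is inserted 50 bp from an existing record so that both fall to the
    isolation rule. All other plants modify one record in place.
    """

    qd: int = 0
    qual: int = 0
    fs: int = 0
    mq: int = 0
    mqranksum: int = 0
    readposranksum: int = 0
    firstok_qual: int = 0  # passes QUAL >= 30 but misses the 1000 tag bar
    multiallelic: int = 0
    proximity_pairs: int = 0
    low_maf: int = 0
    missingness: int = 0
    hwe: int = 0
    pic_out_of_band: int = 0

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"{f.name} count must be non-negative")

    def total_victims(self) -> int:
        return sum(getattr(self, f.name) for f in fields(self))

    def expected_stage_removals(self) -> dict[str, int]:
        """Records each pipeline stage should reject, per the plant design."""
        return {
            "hard_filter": self.qd + self.qual + self.fs + self.mq
            + self.mqranksum + self.readposranksum,
            "isolated_biallelic": self.multiallelic + 2 * self.proximity_pairs,
            "firstok": self.firstok_qual,
            "popgen": self.low_maf + self.missingness + self.hwe,
            "isolated_recheck": 0,
            "pic_band": self.pic_out_of_band,
        }


def _genotypes_for_counts(
    rng: np.random.Generator, counts: tuple[int, int, int]
) -> list[tuple[int, int]]:
    n0, n1, n2 = counts
    gts = [(0, 0)] * n0 + [(0, 1)] * n1 + [(1, 1)] * n2
    rng.shuffle(gts)
    return gts


def plant_violations(
    cohort: CohortSim, spec: ViolationSpec, seed: int = 0
) -> tuple[CohortSim, dict[str, list[str]]]:
    """Overwrite clean records so each fails exactly one screening criterion.

    Returns the modified cohort (a copy) plus a truth table mapping each
    criterion to the locus IDs planted for it. Victims are drawn only from
    records that survive the default screen on the unmodified cohort, so
    each plant is the *marginal* cause of its record's rejection and the
    screened survivor set of the planted cohort equals the clean survivor
    set minus the truth table. Raises when the cohort does not hold enough
    (or suitably isolated) clean records.
    """
    from .screening import screen_candidates

    if spec.total_victims() == 0:
        return cohort, {}
    rng = np.random.default_rng(seed)
    records = copy.deepcopy(cohort.records)
    survivors, _ = screen_candidates(cohort.records)
    survivor_ids = {c.locus_id for c in survivors}
    pool = [i for i, r in enumerate(records) if r.locus_id in survivor_ids]
    if spec.total_victims() > len(pool):
        raise ValueError(
            f"requested {spec.total_victims()} plants but only {len(pool)} "
            "screen-clean records available"
        )
    order = [pool[i] for i in rng.permutation(len(pool))]
    truth: dict[str, list[str]] = {}

    def pop_victims(count: int) -> list[int]:
        if count > len(order):
            raise ValueError("not enough clean records left to plant violations")
        out = order[:count]
        del order[:count]
        return out

    n_cohort = len(cohort.samples)

    def plant_scalar(name: str, mutate) -> None:
        count = getattr(spec, name)
        if not count:
            return
        ids = []
        for idx in pop_victims(count):
            mutate(records[idx])
            ids.append(records[idx].locus_id)
        truth[name] = sorted(ids)

    plant_scalar("qd", lambda r: r.annotations.__setitem__("QD", 1.0))
    plant_scalar("qual", lambda r: setattr(r, "qual", 20.0))
    plant_scalar("fs", lambda r: r.annotations.__setitem__("FS", 80.0))
    plant_scalar("mq", lambda r: r.annotations.__setitem__("MQ", 30.0))
    plant_scalar("mqranksum", lambda r: r.annotations.__setitem__("MQRankSum", -15.0))
    plant_scalar(
        "readposranksum",
        lambda r: r.annotations.__setitem__("ReadPosRankSum", -10.0),
    )
    plant_scalar("firstok_qual", lambda r: setattr(r, "qual", 500.0))

    def add_alt(r: VariantRecord) -> None:
        extra = next(b for b in "ACGT" if b != r.ref and b not in r.alts)
        r.alts = (*r.alts, extra)

    plant_scalar("multiallelic", add_alt)

    def set_counts(counts: tuple[int, int, int]):
        def mutate(r: VariantRecord) -> None:
            r.genotypes = _genotypes_for_counts(rng, counts)

        return mutate

    # one heterozygote in the cohort: MAF 1/(2n) < 0.05 for n <= 12
    plant_scalar("low_maf", set_counts((n_cohort - 1, 1, 0)))

    def knock_out(r: VariantRecord) -> None:
        r.genotypes = list(r.genotypes)
        r.genotypes[int(rng.integers(len(r.genotypes)))] = None

    plant_scalar("missingness", knock_out)

    # no heterozygotes at 50:50 allele frequency: extreme HWE violation,
    # MAF and PIC stay inside their bands
    half = n_cohort // 2
    plant_scalar("hwe", set_counts((n_cohort - half, 0, half)))

    # two heterozygotes: MAF 2/(2n) passes 0.05 at n=12 but PIC ~ 0.14 < 0.2
    plant_scalar("pic_out_of_band", set_counts((n_cohort - 2, 2, 0)))

    if spec.proximity_pairs:
        window = 100
        by_pos = sorted(range(len(records)), key=lambda i: (records[i].chrom, records[i].pos))
        rank = {idx: k for k, idx in enumerate(by_pos)}
        clearance = 2 * window + 60

        def well_separated(idx: int) -> bool:
            k = rank[idx]
            rec = records[idx]
            for j in (k - 1, k + 1):
                if 0 <= j < len(by_pos):
                    other = records[by_pos[j]]
                    if other.chrom == rec.chrom and abs(other.pos - rec.pos) <= clearance:
                        return False
            return True

        ids = []
        companions = []
        planted = 0
        while planted < spec.proximity_pairs:
            candidates = [i for i in order if well_separated(i)]
            if not candidates:
                raise ValueError("no sufficiently isolated records left for proximity pairs")
            idx = candidates[0]
            order.remove(idx)
            victim = records[idx]
            companion_pos = victim.pos + window // 2
            donor = records[order[0]] if order else victim
            companion = VariantRecord(
                chrom=victim.chrom,
                pos=companion_pos,
                ref=victim.ref,
                alts=victim.alts,
                qual=victim.qual,
                annotations=dict(victim.annotations),
                genotypes=list(donor.genotypes),
            )
            companions.append(companion)
            ids.extend([victim.locus_id, companion.locus_id])
            planted += 1
        records.extend(companions)
        truth["proximity_pairs"] = sorted(ids)

    records.sort(key=lambda r: (r.chrom, r.pos))
    return CohortSim(records=records, contigs=dict(cohort.contigs),
                     samples=list(cohort.samples)), truth


@dataclass(frozen=True)
class PopulationSimSpec:
    """Population sample under an inbreeding-adjusted Hardy-Weinberg law.

    Genotype frequencies at a locus with minor allele frequency q and
    inbreeding coefficient f are p^2 + f p q (hom major), 2pq(1 - f)
    (het) and q^2 + f p q (hom minor), clipped at zero and renormalized.
    """

    n_individuals: int
    mafs: Sequence[float]
    inbreeding: float = 0.0
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("need at least one individual")
        for q in self.mafs:
            if not (0.0 < q <= 0.5):
                raise ValueError(f"MAF must lie in (0, 0.5], got {q}")
        if not (-1.0 <= self.inbreeding <= 1.0):
            raise ValueError("inbreeding coefficient must lie in [-1, 1]")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing rate must lie in [0, 1)")


def genotype_law(q: float, f: float) -> np.ndarray:
    """(hom-major, het, hom-minor) frequencies under inbreeding f."""
    p = 1.0 - q
    raw = np.array([p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q])
    raw = np.clip(raw, 0.0, None)
    return raw / raw.sum()


def simulate_genotype_matrix(spec: PopulationSimSpec) -> GenotypeMatrix:
    """Multinomial genotype draws per locus, with missingness, as a matrix."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_individuals
    rows = []
    for q in spec.mafs:
        counts = rng.multinomial(n, genotype_law(q, spec.inbreeding))
        calls = np.repeat([0.0, 1.0, 2.0], counts)
        rng.shuffle(calls)
        if spec.missing_rate > 0:
            calls[rng.random(n) < spec.missing_rate] = np.nan
        rows.append(calls)
    frame = pd.DataFrame(
        rows,
        index=[f"locus{i + 1:04d}" for i in range(len(spec.mafs))],
        columns=[f"ind{j + 1:04d}" for j in range(n)],
    )
    return GenotypeMatrix(frame)
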