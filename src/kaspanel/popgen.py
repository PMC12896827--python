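"""Per-locus diversity statistics for biallelic genotype matrices.

Implements the GenAlEx-style report used to validate a marker panel on a
population sample: number of alleles (Na), effective number of alleles
(Ne = 1/sum p_i^2), Shannon-Wiener index (I = -sum p_i ln p_i, in nats),
observed and expected heterozygosity (Ho, He = 1 - sum p_i^2, no
small-sample correction), inbreeding coefficient F_IS = (He - Ho)/He,
major allele frequency (MAF, frequency of the *most common* allele — the
convention of marker-validation reports; the screening module's ``maf_min``
thresholds the minor allele, as VCFtools does), Botstein's polymorphism
information content, and a Hardy-Weinberg test (chi-square or exact).

Botstein's PIC for allele frequencies p_1..p_n:

    PIC = 1 - sum_i p_i^2 - sum_{i<j} 2 p_i^2 p_j^2

which for a biallelic locus reduces to ``1 - (p^2 + q^2) - 2 p^2 q^2``.

The exact HWE test enumerates the distribution of the heterozygote count
conditional on the observed allele counts and sums the probabilities of
all configurations no more likely than the observed one (the standard
two-sided exact test used by VCFtools/PLINK).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "GenotypeMatrix",
    "LocusSummary",
    "allele_frequencies",
    "effective_alleles",
    "shannon_index",
    "expected_heterozygosity",
    "pic",
    "pic_biallelic",
    "hwe_test",
    "hwe_test_from_counts",
    "locus_summary",
    "panel_summary",
    "rounded_report",
    "round3",
    "counts_from_summary",
    "infer_typed_n",
]


@dataclass
class GenotypeMatrix:
    """Loci x samples biallelic calls: 0/1/2 copies of the minor allele.

    Backed by a float DataFrame with NaN for missing calls; rows are locus
    IDs, columns sample IDs.
    """

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        values = self.calls.to_numpy(dtype=float)
        ok = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("genotype calls must be 0, 1, 2 or missing")

    @property
    def locus_ids(self) -> list[str]:
        return list(self.calls.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.calls.columns)

    def locus_calls(self, locus_id: str) -> np.ndarray:
        return self.calls.loc[locus_id].to_numpy(dtype=float)


@dataclass
class LocusSummary:
    """One row of a marker-validation diversity table."""

    locus_id: str
    n_typed: int
    na: int
    ne: float
    shannon: float
    ho: float
    he: float
    fis: float
    maf: float  # major allele frequency
    pic: float
    hwe_p: float

    def hwe_flag(self, alpha: float = 0.05) -> str:
        """'NS' if the locus conforms to HWE at ``alpha``, '*' otherwise."""
        return "*" if self.hwe_p < alpha else "NS"


def _counts_from_calls(calls: Iterable[float]) -> tuple[int, int, int]:
    n0 = n1 = n2 = 0
    for c in calls:
        if c is None or (isinstance(c, float) and math.isnan(c)):
            continue
        if c == 0:
            n0 += 1
        elif c == 1:
            n1 += 1
        elif c == 2:
            n2 += 1
        else:
            raise ValueError(f"invalid call {c!r}")
    return n0, n1, n2


def allele_frequencies(calls: Iterable[float]) -> tuple[tuple[float, float], int]:
    """Biallelic allele frequencies (major-coded, minor) over typed samples.

    Returns ``((p, q), n_typed)`` with p the frequency of the allele coded
    0 (the cohort-major allele) and q = 1 - p. Raises on an all-missing
    locus.
    """
    n0, n1, n2 = _counts_from_calls(calls)
    n = n0 + n1 + n2
    if n == 0:
        raise ValueError("locus has no typed genotypes")
    q = (n1 + 2 * n2) / (2 * n)
    return (1.0 - q, q), n


def effective_alleles(freqs: Sequence[float]) -> float:
    """Effective number of alleles Ne = 1 / sum p_i^2."""
    return 1.0 / sum(p * p for p in freqs)


def shannon_index(freqs: Sequence[float]) -> float:
    """Shannon-Wiener diversity I = -sum p_i ln p_i (natural log)."""
    return -sum(p * math.log(p) for p in freqs if p > 0)


def expected_heterozygosity(freqs: Sequence[float]) -> float:
    """He = 1 - sum p_i^2 (no small-sample correction)."""
    return 1.0 - sum(p * p for p in freqs)


def pic(freqs: Sequence[float]) -> float:
    """Botstein polymorphism information content for any allele count."""
    freqs = list(freqs)
    if any(p < 0 for p in freqs):
        raise ValueError("allele frequencies must be non-negative")
    homozygosity = sum(p * p for p in freqs)
    cross = sum(
        2 * freqs[i] ** 2 * freqs[j] ** 2
        for i in range(len(freqs) - 1)
        for j in range(i + 1, len(freqs))
    )
    return 1.0 - homozygosity - cross


def pic_biallelic(p: float) -> float:
    """PIC for a biallelic locus with allele frequencies p and 1-p."""
    q = 1.0 - p
    return 1.0 - (p * p + q * q) - 2 * p * p * q * q


def _hwe_chi2(n0: int, n1: int, n2: int) -> float:
    n = n0 + n1 + n2
    p = (2 * n0 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = (n * p * p, 2 * n * p * q, n * q * q)
    stat = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), expected))
    return float(chi2_dist.sf(stat, df=1))


def _hwe_exact(n0: int, n1: int, n2: int) -> float:
    """Two-sided exact test conditional on allele counts.

    Sums, over heterozygote counts h with the parity of the minor allele
    count, the probabilities P(h | n, minor) that do not exceed the
    probability of the observed count.
    """
    n = n0 + n1 + n2
    minor = min(2 * n0 + n1, 2 * n2 + n1)
    if minor == 0:
        return 1.0
    hets = range(minor % 2, minor + 1, 2)
    logprobs = {}
    for h in hets:
        hom_minor = (minor - h) // 2
        hom_major = n - h - hom_minor
        if hom_major < 0:
            continue
        logprobs[h] = (
            math.lgamma(n + 1)
            - math.lgamma(hom_major + 1)
            - math.lgamma(hom_minor + 1)
            - math.lgamma(h + 1)
            + h * math.log(2)
            + math.lgamma(minor + 1)
            + math.lgamma(2 * n - minor + 1)
            - math.lgamma(2 * n + 1)
        )
    obs = n1
    if obs not in logprobs:
        raise ValueError(f"heterozygote count {obs} inconsistent with allele counts")
    # sum probabilities <= P(observed), with a tiny relative guard for
    # floating-point ties between equally likely configurations
    p_obs = math.exp(logprobs[obs])
    total = sum(
        math.exp(lp) for lp in logprobs.values() if math.exp(lp) <= p_obs * (1 + 1e-12)
    )
    return min(1.0, total)


def hwe_test_from_counts(
    n0: int, n1: int, n2: int, method: Literal["chi2", "exact"] = "chi2"
) -> float:
    """Hardy-Weinberg p-value from (hom-major, het, hom-minor) counts."""
    if min(n0, n1, n2) < 0:
        raise ValueError("genotype counts must be non-negative")
    if n0 + n1 + n2 < 1:
        raise ValueError("need at least one typed genotype")
    if method == "chi2":
        return _hwe_chi2(n0, n1, n2)
    if method == "exact":
        return _hwe_exact(n0, n1, n2)
    raise ValueError(f"unknown HWE method {method!r}")


def hwe_test(
    calls: Iterable[float], method: Literal["chi2", "exact"] = "chi2"
) -> float:
    return hwe_test_from_counts(*_counts_from_calls(calls), method=method)


def locus_summary(
    calls: Iterable[float],
    locus_id: str = "",
    hwe_method: Literal["chi2", "exact"] = "chi2",
) -> LocusSummary:
    """All diversity indices for one biallelic locus."""
    calls = list(calls)
    (p, q), n = allele_frequencies(calls)
    n0, n1, n2 = _counts_from_calls(calls)
    he = expected_heterozygosity((p, q))
    ho = n1 / n
    return LocusSummary(
        locus_id=locus_id,
        n_typed=n,
        na=int(p > 0) + int(q > 0),
        ne=effective_alleles((p, q)),
        shannon=shannon_index((p, q)),
        ho=ho,
        he=he,
        fis=(he - ho) / he if he > 0 else 0.0,
        maf=max(p, q),
        pic=pic((p, q)),
        hwe_p=hwe_test_from_counts(n0, n1, n2, method=hwe_method),
    )


def round3(x: float) -> float:
    """Half-up rounding to 3 decimals, applied only at report time."""
    return float(
        Decimal(repr(float(x))).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP)
    )


_REPORT_COLUMNS = ["Na", "Ne", "I", "Ho", "He", "Fis", "MAF", "PIC"]


def panel_summary(
    matrix: GenotypeMatrix,
    hwe_method: Literal["chi2", "exact"] = "chi2",
    hwe_alpha: float = 0.05,
) -> tuple[list[LocusSummary], pd.DataFrame]:
    """Per-locus summaries plus a report table with an unweighted means row.

    The report carries full-precision columns; ``*_3dp`` views rounded
    half-up to 3 decimals are attached for publication-style output.
    """
    if not matrix.locus_ids:
        raise ValueError("genotype matrix has no loci")
    summaries = [
        locus_summary(matrix.locus_calls(lid), lid, hwe_method)
        for lid in matrix.locus_ids
    ]
    rows = {
        s.locus_id: [s.na, s.ne, s.shannon, s.ho, s.he, s.fis, s.maf, s.pic]
        for s in summaries
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=_REPORT_COLUMNS)
    table["HWE_p"] = [s.hwe_p for s in summaries]
    table["HWE"] = [s.hwe_flag(hwe_alpha) for s in summaries]
    table["n"] = [s.n_typed for s in summaries]
    means = table[_REPORT_COLUMNS].mean()
    mean_row = means.to_dict() | {"HWE_p": float("nan"), "HWE": "", "n": ""}
    table.loc["Mean"] = mean_row
    return summaries, table


def rounded_report(table: pd.DataFrame) -> pd.DataFrame:
    """3-decimal (half-up) view of a panel report for serialization."""
    out = table.copy()
    for col in _REPORT_COLUMNS + ["HWE_p"]:
        out[col] = [round3(v) if pd.notna(v) else v for v in out[col]]
    return out


def infer_typed_n(ho: float, candidates: Sequence[int] = (30, 29, 28)) -> int:
    """Smallest-error sample size reconciling a printed Ho with integer counts."""
    return min(candidates, key=lambda n: abs(round(ho * n) - ho * n))


def counts_from_summary(ho: float, maf: float, n: int) -> tuple[int, int, int]:
    """Reconstruct (hom-major, het, hom-minor) from printed Ho, MAF and n.

    MAF here is the *major* allele frequency (>= 0.5). The reconstruction
    rounds the heterozygote and minor-allele counts to integers and raises
    when no non-negative integer genotype configuration is consistent with
    the inputs.
    """
    if not (0.0 <= ho <= 1.0):
        raise ValueError(f"Ho must be in [0, 1], got {ho}")
    if not (0.5 <= maf <= 1.0):
        raise ValueError(f"major allele frequency must be in [0.5, 1], got {maf}")
    het = round(ho * n)
    minor_alleles = round((1.0 - maf) * 2 * n)
    hom_minor = round((minor_alleles - het) / 2)
    if hom_minor < 0:
        raise ValueError(
            f"irreconcilable summary: het count {het} exceeds "
            f"minor allele count {minor_alleles} at n={n}"
        )
    hom_major = n - het - hom_minor
    if hom_major < 0:
        raise ValueError(
            f"irreconcilable summary: {het} hets + {hom_minor} minor homozygotes "
            f"exceed n={n}"
        )
    return hom_major, het, hom_minor
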