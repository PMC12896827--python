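"""Published summaries of the 19-marker Yangtze finless porpoise KASP panel.

The validated panel of 19 biallelic SNP markers was scored on ~30
individuals from the Poyang Lake population; the published per-locus
report gives, for each marker, its genomic position, alleles, observed
heterozygosity (Ho) and major allele frequency (MAF). Those two printed
proportions, together with the typed sample count, determine the full
genotype-count configuration of each locus — so the whole diversity table
(Ne, Shannon index, He, F_IS, PIC, HWE tests) can be recomputed from this
module's inputs.

``PANEL_RECORDS`` holds the printed inputs only; everything else is
derived at run time by :func:`reconstruct_panel_counts` /
:func:`reconstruct_panel_matrix`.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .popgen import GenotypeMatrix, counts_from_summary, infer_typed_n

#: (locus_id, position, alleles, Ho, major allele frequency) as published.
#: Sample size is nominally 30; loci where Ho resolves only at n = 29 had
#: one failed genotype call.
PANEL_RECORDS: list[tuple[str, str, str, float, float]] = [
    ("Snp03", "Chr02_3578746", "C/T", 0.300, 0.583),
    ("Snp04", "Chr02_90116171", "A/G", 0.367, 0.650),
    ("Snp08", "Chr04_6297226", "A/G", 0.267, 0.600),
    ("Snp09", "Chr04_71791661", "T/C", 0.567, 0.617),
    ("Snp12", "Chr04_84395785", "A/G", 0.300, 0.717),
    ("Snp14", "Chr04_106682173", "G/A", 0.586, 0.534),
    ("Snp19", "Chr07_50780006", "G/C", 0.433, 0.517),
    ("Snp20", "Chr07_85509514", "C/A", 0.586, 0.707),
    ("Snp25", "Chr11_27764344", "G/A", 0.367, 0.550),
    ("Snp29", "Chr13_83891862", "T/C", 0.233, 0.717),
    ("Snp30", "Chr14_13332465", "A/G", 0.333, 0.800),
    ("Snp31", "Chr15_1462494", "T/G", 0.467, 0.633),
    ("Snp32", "Chr16_55868804", "G/A", 0.333, 0.767),
    ("Snp34", "Chr17_23473466", "A/C", 0.448, 0.638),
    ("Snp35", "Chr17_66317367", "T/G", 0.333, 0.537),
    ("Snp36", "Chr18_33806104", "G/A", 0.448, 0.603),
    ("Snp46", "ChrX_31038355", "T/C", 0.033, 0.850),
    ("Snp47", "ChrX_33057094", "C/T", 0.103, 0.741),
    ("Snp48", "ChrX_37770280", "G/T", 0.167, 0.683),
]


def panel_maf_table() -> pd.DataFrame:
    """Printed per-locus inputs as a DataFrame indexed by locus ID."""
    df = pd.DataFrame(
        PANEL_RECORDS, columns=["locus_id", "position", "alleles", "ho", "maf"]
    )
    return df.set_index("locus_id")


def reconstruct_panel_counts() -> dict[str, tuple[int, int, int]]:
    """(hom-major, het, hom-minor) per locus, inferred from printed Ho/MAF."""
    out = {}
    for locus_id, _, _, ho, maf in PANEL_RECORDS:
        n = infer_typed_n(ho)
        out[locus_id] = counts_from_summary(ho, maf, n)
    return out


def reconstruct_panel_matrix(seed: int = 0) -> GenotypeMatrix:
    """Genotype matrix realizing the reconstructed per-locus counts.

    Column order within each locus is a seeded shuffle; loci typed in
    fewer than 30 individuals carry missing calls for the remainder.
    """
    rng = np.random.default_rng(seed)
    n_max = 30
    rows = {}
    for locus_id, counts in reconstruct_panel_counts().items():
        calls = np.repeat([0.0, 1.0, 2.0], counts)
        calls = np.concatenate([calls, np.full(n_max - len(calls), np.nan)])
        rng.shuffle(calls)
        rows[locus_id] = calls
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"ind{j + 1:02d}" for j in range(n_max)]
    )
    return GenotypeMatrix(frame)
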