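"""End-to-end orchestration: simulate -> screen -> select -> design -> stats.

A :class:`RunConfig` carries every path, threshold and seed of one run.
:func:`run_pipeline` executes the stages in order, writes all interchange
artifacts into the output directory, and records a manifest (package
version, seed, SHA-256 of each input, per-stage record counts) so a run
can be reproduced bit-for-bit from its config and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import pandas as pd
from pyfaidx import Fasta

from . import __version__
from .kasp import design_kasp_primers, extract_flanks, write_assay_json, write_assay_sheet
from .panel import PanelSpec, sample_even_panel_with_bins
from .popgen import GenotypeMatrix, panel_summary, rounded_report
from .screening import CandidateSNP, ScreenConfig, screen_candidates
from .simulate import ReferenceModel, simulate_cohort_vcf, simulate_reference, write_fasta
from .vcfio import read_genotype_tsv, read_vcf, write_genotype_tsv

logger = logging.getLogger("kaspanel")


@dataclass
class RunConfig:
    """Flat configuration for one pipeline run (key = value serializable)."""

    out_dir: str
    reference_fasta: Optional[str] = None  # None: simulate a reference
    cohort_vcf: Optional[str] = None  # None: simulate the cohort
    genotype_tsv: Optional[str] = None  # None: derive from cohort at panel loci
    seed: int = 0
    # simulation (used only when inputs are not supplied)
    sim_chromosomes: str = "Chr01:400000,Chr02:300000"
    sim_gc: float = 0.41
    sim_samples: int = 12
    sim_density: float = 1 / 2000
    # screening thresholds
    maf_min: float = 0.05
    max_missing: float = 0.0
    hwe_alpha: float = 0.001
    window: int = 100
    pic_min: float = 0.2
    pic_max: float = 0.5
    screen_hwe_method: str = "exact"
    # panel
    panel_size: int = 50
    allocation: str = "proportional"
    # assay design
    flank: int = 150
    body_length: int = 22
    reverse_offset: int = 30
    reverse_length: int = 22
    # reporting
    stats_hwe_method: str = "chi2"
    stats_alpha: float = 0.05
    log_level: str = "INFO"

    def to_text(self) -> str:
        lines = []
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            lines.append(f"{f.name} = {'' if value is None else value}")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "RunConfig":
        kwargs = {}
        types = {f.name: f for f in dataclasses.fields(cls)}
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, raw = line.partition("=")
            key, raw = key.strip(), raw.strip()
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            if raw == "":
                kwargs[key] = None
                continue
            base = types[key].type
            if base in ("int", int):
                kwargs[key] = int(raw)
            elif base in ("float", float):
                kwargs[key] = float(raw)
            else:
                kwargs[key] = raw
        return cls(**kwargs)

    def screen_config(self) -> ScreenConfig:
        return ScreenConfig(
            isolation_window=self.window,
            maf_min=self.maf_min,
            max_missing_fraction=self.max_missing,
            hwe_alpha=self.hwe_alpha,
            pic_min=self.pic_min,
            pic_max=self.pic_max,
            hwe_method=self.screen_hwe_method,  # type: ignore[arg-type]
        )

    def parsed_chromosomes(self) -> dict[str, int]:
        out = {}
        for part in self.sim_chromosomes.split(","):
            name, _, length = part.strip().partition(":")
            out[name] = int(length)
        return out


def _sha256(path: str | os.PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_candidates_tsv(
    candidates: list[CandidateSNP], path: str | os.PathLike,
    bins: Optional[list[int]] = None,
) -> None:
    rows = []
    for i, c in enumerate(candidates):
        row = {
            "locus_id": c.locus_id, "chrom": c.chrom, "pos": c.pos,
            "ref": c.ref, "alt": c.alt, "maf": c.maf, "pic": c.pic,
            "flags": ";".join(k for k, v in c.flags.items() if v),
        }
        if bins is not None:
            row["bin"] = bins[i]
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_candidates_tsv(path: str | os.PathLike) -> list[CandidateSNP]:
    df = pd.read_csv(path, sep="\t")
    return [
        CandidateSNP(
            locus_id=r.locus_id, chrom=str(r.chrom), pos=int(r.pos),
            ref=str(r.ref), alt=str(r.alt), maf=float(r.maf), pic=float(r.pic),
            flags={k: True for k in str(getattr(r, "flags", "")).split(";") if k},
        )
        for r in df.itertuples()
    ]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dictionary (also written to disk)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)
    logger.info("thresholds: %s", config.screen_config())
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "stages": [],
        "inputs": {},
        "counts": {},
    }

    # stage 1: inputs (simulated unless supplied)
    if config.reference_fasta is None:
        ref_model = ReferenceModel(
            chromosomes=config.parsed_chromosomes(),
            gc_fraction=config.sim_gc,
            seed=config.seed,
        )
        sequences = simulate_reference(ref_model)
        reference_fasta = out / "reference.fa"
        write_fasta(sequences, reference_fasta)
    else:
        reference_fasta = Path(config.reference_fasta)
    if config.cohort_vcf is None:
        fasta = Fasta(str(reference_fasta))
        sequences = {name: str(fasta[name][:]) for name in fasta.keys()}
        cohort = simulate_cohort_vcf(
            sequences,
            n_samples=config.sim_samples,
            snp_density=config.sim_density,
            seed=config.seed + 1,
        )
        cohort_vcf = out / "cohort.vcf"
        cohort.write(cohort_vcf)
    else:
        cohort_vcf = Path(config.cohort_vcf)
    manifest["stages"].append("simulate")
    manifest["inputs"]["reference_fasta"] = _sha256(reference_fasta)
    manifest["inputs"]["cohort_vcf"] = _sha256(cohort_vcf)

    # stage 2: screening
    records, _ = read_vcf(cohort_vcf)
    candidates, counts = screen_candidates(records, config.screen_config())
    write_candidates_tsv(candidates, out / "candidates.tsv")
    (out / "stage_counts.json").write_text(json.dumps(counts, indent=2))
    manifest["stages"].append("screen")
    manifest["counts"] = counts
    if not candidates:
        logger.warning("screening produced no candidates")

    # stage 3: panel selection
    lengths = {name: len(Fasta(str(reference_fasta))[name]) for name in Fasta(str(reference_fasta)).keys()}
    target = min(config.panel_size, len(candidates))
    if target < config.panel_size:
        logger.warning(
            "panel target %d reduced to %d (candidate pool)", config.panel_size, target
        )
    spec = PanelSpec(
        target_size=target,
        chromosome_lengths=lengths,
        seed=config.seed + 2,
        allocation=config.allocation,  # type: ignore[arg-type]
    )
    picks = sample_even_panel_with_bins(candidates, spec)
    write_candidates_tsv([c for c, _ in picks], out / "panel.tsv", bins=[b for _, b in picks])
    manifest["stages"].append("select_panel")
    manifest["counts"]["panel"] = len(picks)

    # stage 4: KASP assay design
    fasta = Fasta(str(reference_fasta))
    assays = []
    for cand, _ in picks:
        ctx = extract_flanks(fasta, cand.chrom, cand.pos, config.flank)
        assays.append(
            design_kasp_primers(
                ctx,
                (cand.ref, cand.alt),
                body_length=config.body_length,
                reverse_offset=config.reverse_offset,
                reverse_length=config.reverse_length,
                locus_id=cand.locus_id,
            )
        )
    if assays:
        write_assay_sheet(assays, out / "assays.csv")
        write_assay_json(assays, out / "assays.json")
    manifest["stages"].append("design_kasp")
    manifest["counts"]["assays"] = len(assays)

    # stage 5: diversity statistics
    if config.genotype_tsv is not None:
        matrix = GenotypeMatrix(read_genotype_tsv(config.genotype_tsv))
        manifest["inputs"]["genotype_tsv"] = _sha256(config.genotype_tsv)
    else:
        matrix = _matrix_from_records(records, [c for c, _ in picks])
        write_genotype_tsv(matrix.calls, out / "genotypes.tsv")
    if matrix is not None and matrix.locus_ids:
        _, table = panel_summary(
            matrix,
            hwe_method=config.stats_hwe_method,  # type: ignore[arg-type]
            hwe_alpha=config.stats_alpha,
        )
        rounded_report(table).to_csv(out / "diversity.tsv", sep="\t", index_label="locus_id")
        manifest["counts"]["stats_loci"] = len(table) - 1
    manifest["stages"].append("stats")

    (out / "config.txt").write_text(config.to_text())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def _matrix_from_records(records, panel: list[CandidateSNP]) -> GenotypeMatrix:
    """Minor-allele dose matrix for the panel loci from cohort genotypes."""
    wanted = {c.locus_id for c in panel}
    rows = {}
    for rec in records:
        if rec.locus_id not in wanted:
            continue
        alt = rec.alt_frequency()
        flip = alt is not None and alt > 0.5  # code minor-allele copies
        calls = []
        for gt in rec.genotypes:
            if gt is None:
                calls.append(float("nan"))
            else:
                dose = (gt[0] > 0) + (gt[1] > 0)
                calls.append(float(2 - dose if flip else dose))
        rows[rec.locus_id] = calls
    n = max((len(v) for v in rows.values()), default=0)
    frame = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"ind{j + 1:02d}" for j in range(n)]
    )
    return GenotypeMatrix(frame)
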