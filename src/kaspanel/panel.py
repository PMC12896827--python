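"""Evenly distributed, seeded subsampling of candidate SNPs into a panel.

Marker panels are drawn in two steps: per-chromosome quotas (largest-
remainder apportionment, proportional to chromosome length or equal per
chromosome), then within each chromosome the candidate span is cut into
quota-many equal-width positional bins and one candidate is drawn uniformly
per bin. Bins that hold no candidate hand their slot to the nearest
non-empty bins, so the panel size always equals the target whenever the
chromosome holds enough candidates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np

from .screening import CandidateSNP


@dataclass(frozen=True)
class PanelSpec:
    """Target size, chromosome lengths, seed and allocation mode."""

    target_size: int
    chromosome_lengths: Mapping[str, int]
    seed: int
    allocation: Literal["proportional", "equal"] = "proportional"

    def __post_init__(self) -> None:
        if self.target_size < 0:
            raise ValueError("target size must be non-negative")


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integer apportionment of ``total`` proportional to ``weights``."""
    if weights.sum() == 0:
        raise ValueError("all weights are zero")
    ideal = weights / weights.sum() * total
    floors = np.floor(ideal).astype(int)
    remainder = total - floors.sum()
    # stable order: largest fractional part first, ties by index
    frac_order = np.lexsort((np.arange(len(ideal)), -(ideal - floors)))
    floors[frac_order[:remainder]] += 1
    return floors


def allocate_quotas(
    candidates: Sequence[CandidateSNP], spec: PanelSpec
) -> dict[str, int]:
    """Per-chromosome slot counts summing exactly to the target.

    Chromosomes with no candidates get no slots; a quota exceeding a
    chromosome's candidate count is capped and the deficit re-apportioned
    among chromosomes with spare candidates.
    """
    if spec.target_size > len(candidates):
        raise ValueError(
            f"target {spec.target_size} exceeds {len(candidates)} candidates"
        )
    available: dict[str, int] = {}
    for c in candidates:
        available[c.chrom] = available.get(c.chrom, 0) + 1
    chroms = sorted(available)
    if spec.allocation == "proportional":
        weights = np.array(
            [float(spec.chromosome_lengths.get(ch, 0)) for ch in chroms]
        )
        if weights.sum() == 0:  # no length info: fall back to candidate counts
            weights = np.array([float(available[ch]) for ch in chroms])
    else:
        weights = np.ones(len(chroms))

    quotas = dict.fromkeys(chroms, 0)
    remaining = spec.target_size
    active = list(chroms)
    w = {ch: wt for ch, wt in zip(chroms, weights)}
    while remaining > 0:
        vec = np.array([w[ch] if w[ch] > 0 else 1e-9 for ch in active])
        alloc = _largest_remainder(vec, remaining)
        remaining = 0
        next_active = []
        for ch, extra in zip(active, alloc):
            room = available[ch] - quotas[ch]
            used = min(int(extra), room)
            quotas[ch] += used
            remaining += int(extra) - used
            if quotas[ch] < available[ch]:
                next_active.append(ch)
        active = next_active
        if remaining > 0 and not active:
            raise ValueError("cannot satisfy target: candidates exhausted")
    return quotas


def sample_even_panel(
    candidates: Sequence[CandidateSNP], spec: PanelSpec
) -> list[CandidateSNP]:
    """Draw the panel: one seeded uniform pick per positional bin.

    Returns candidates sorted by (chromosome, position); when the target is
    feasible the result has exactly ``spec.target_size`` members and the
    per-chromosome counts equal the quotas.
    """
    return [c for c, _ in sample_even_panel_with_bins(candidates, spec)]


def sample_even_panel_with_bins(
    candidates: Sequence[CandidateSNP], spec: PanelSpec
) -> list[tuple[CandidateSNP, int]]:
    """As :func:`sample_even_panel`, pairing each pick with its bin index."""
    quotas = allocate_quotas(candidates, spec)
    rng = np.random.default_rng(spec.seed)
    by_chrom: dict[str, list[CandidateSNP]] = {}
    for c in candidates:
        by_chrom.setdefault(c.chrom, []).append(c)

    panel: list[tuple[CandidateSNP, int]] = []
    for chrom in sorted(by_chrom):
        quota = quotas.get(chrom, 0)
        if quota == 0:
            continue
        cands = sorted(by_chrom[chrom], key=lambda c: c.pos)
        lo, hi = cands[0].pos, cands[-1].pos
        span = max(hi - lo, 1)

        def bin_of(c: CandidateSNP) -> int:
            return min(int((c.pos - lo) / span * quota), quota - 1)

        if quota >= len(cands):
            panel.extend((c, bin_of(c)) for c in cands)
            continue
        bins: list[list[CandidateSNP]] = [[] for _ in range(quota)]
        for c in cands:
            bins[bin_of(c)].append(c)
        chosen: list[tuple[CandidateSNP, int]] = []
        deficits: list[int] = []
        for b, members in enumerate(bins):
            if members:
                chosen.append((members[int(rng.integers(len(members)))], b))
            else:
                deficits.append(b)
        # backfill empty-bin slots from the nearest bins with unused candidates
        taken = {id(c) for c, _ in chosen}
        for b in deficits:
            pool_order = sorted(range(quota), key=lambda k: (abs(k - b), k))
            pick = None
            for k in pool_order:
                spare = [c for c in bins[k] if id(c) not in taken]
                if spare:
                    pick = spare[int(rng.integers(len(spare)))]
                    break
            if pick is None:  # cannot happen while quota <= len(cands)
                raise ValueError(f"infeasible quota on {chrom}")
            taken.add(id(pick))
            chosen.append((pick, b))
        panel.extend(chosen)
    return sorted(panel, key=lambda cb: (cb[0].chrom, cb[0].pos))
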