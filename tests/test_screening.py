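"""Screening stages: boundary behaviour, oracle equivalence, invariants."""

import dataclasses
import random

import numpy as np
import pytest
from scipy.stats import chi2 as chi2_dist

from kaspanel.screening import (
    FIRSTOK,
    HardFilterThresholds,
    ScreenConfig,
    evaluate_hard_filter,
    pic_band_filter,
    popgen_prefilter,
    screen_candidates,
    select_isolated_biallelic,
    tag_high_confidence,
)
from kaspanel.simulate import ViolationSpec, plant_violations
from kaspanel.vcfio import VariantRecord


def make_record(chrom="Chr01", pos=1000, ref="A", alts=("G",), qual=2000.0,
                qd=25.0, fs=5.0, mq=55.0, mqrs=0.0, rprs=0.0, genotypes=None):
    return VariantRecord(
        chrom=chrom, pos=pos, ref=ref, alts=tuple(alts), qual=qual,
        annotations={"QD": qd, "FS": fs, "MQ": mq, "MQRankSum": mqrs,
                     "ReadPosRankSum": rprs},
        genotypes=genotypes or [(0, 1)] * 6 + [(0, 0)] * 6,
    )


class TestHardFilter:
    def test_all_boundaries_inclusive(self):
        rec = make_record(qual=30.0, qd=2.0, fs=60.0, mq=40.0, mqrs=-12.5, rprs=-8.0)
        passed, failed, missing = evaluate_hard_filter(rec, HardFilterThresholds())
        assert passed and not failed and not missing

    def test_single_violation_named(self):
        rec = make_record(qd=1.99)
        passed, failed, _ = evaluate_hard_filter(rec, HardFilterThresholds())
        assert not passed and failed == ["QD"]

    def test_absent_annotation_skipped_and_flagged(self):
        rec = make_record()
        del rec.annotations["MQRankSum"]
        passed, failed, missing = evaluate_hard_filter(rec, HardFilterThresholds())
        assert passed and missing == ["MQRankSum"]

    def test_matches_bruteforce_on_random_records(self):
        rng = random.Random(0)
        th = HardFilterThresholds()
        for _ in range(300):
            rec = make_record(
                qual=rng.uniform(0, 100), qd=rng.uniform(0, 5),
                fs=rng.uniform(40, 80), mq=rng.uniform(30, 50),
                mqrs=rng.uniform(-15, 0), rprs=rng.uniform(-10, 0),
            )
            expected = (
                rec.qual >= 30.0 and rec.annotations["QD"] >= 2.0
                and rec.annotations["FS"] <= 60.0 and rec.annotations["MQ"] >= 40.0
                and rec.annotations["MQRankSum"] >= -12.5
                and rec.annotations["ReadPosRankSum"] >= -8.0
            )
            assert evaluate_hard_filter(rec, th)[0] == expected


class TestFirstok:
    def test_below_1000_not_tagged(self):
        (rec,) = tag_high_confidence(
            [make_record(qual=999.9)], HardFilterThresholds(qual_min=1000.0)
        )
        assert FIRSTOK not in rec.tags

    def test_at_1000_tagged(self):
        (rec,) = tag_high_confidence(
            [make_record(qual=1000.0)], HardFilterThresholds(qual_min=1000.0)
        )
        assert FIRSTOK in rec.tags

    def test_never_deletes_records(self, cohort):
        tagged = tag_high_confidence(
            cohort.records, HardFilterThresholds(qual_min=1000.0)
        )
        assert len(tagged) == len(cohort.records)
        brute = sum(r.qual >= 1000.0 for r in cohort.records)
        assert sum(FIRSTOK in r.tags for r in tagged) == brute


class TestIsolation:
    def test_lone_snp_retained(self):
        assert len(select_isolated_biallelic([make_record()], 100)) == 1

    def test_boundary_distance_100_removes_101_keeps(self):
        pair = [make_record(pos=1000), make_record(pos=1100)]
        assert select_isolated_biallelic(pair, 100) == []
        pair = [make_record(pos=1000), make_record(pos=1101)]
        assert len(select_isolated_biallelic(pair, 100)) == 2

    def test_non_snp_neighbour_still_crowds(self):
        indel = make_record(pos=1050, ref="AT", alts=("A",))
        kept = select_isolated_biallelic([make_record(pos=1000), indel], 100)
        assert kept == []

    def test_multiallelic_removed_but_crowds_others(self):
        tri = make_record(pos=1000, alts=("G", "T"))
        snp = make_record(pos=1050)
        assert select_isolated_biallelic([tri, snp], 100) == []

    def test_matches_all_pairs_bruteforce(self):
        rng = random.Random(7)
        records = [
            make_record(chrom=rng.choice(["c1", "c2"]), pos=rng.randrange(1, 20_000))
            for _ in range(400)
        ]
        # deduplicate coordinates: generator guarantees uniqueness upstream
        seen, unique = set(), []
        for r in records:
            if (r.chrom, r.pos) not in seen:
                seen.add((r.chrom, r.pos))
                unique.append(r)
        kept = select_isolated_biallelic(unique, 100)
        brute = [
            r for r in unique
            if all(
                o is r or o.chrom != r.chrom or abs(o.pos - r.pos) > 100
                for o in unique
            )
        ]
        assert sorted(r.locus_id for r in kept) == sorted(r.locus_id for r in brute)


class TestPopgenPrefilter:
    def test_any_missing_genotype_fails_complete_requirement(self):
        rec = make_record(genotypes=[(0, 1)] * 6 + [(0, 0)] * 5 + [None])
        assert popgen_prefilter([rec], max_missing_fraction=0.0) == []

    def test_maf_threshold_at_24_alleles(self):
        singleton = make_record(genotypes=[(0, 1)] + [(0, 0)] * 11)
        doubleton = make_record(genotypes=[(0, 1)] * 2 + [(0, 0)] * 10)
        assert popgen_prefilter([singleton]) == []
        assert len(popgen_prefilter([doubleton])) == 1

    def test_hwe_exact_rejects_extreme_het_deficit(self):
        # 25 hom-major, 1 het, 4 hom-minor: exact p < 0.001
        gts = [(0, 0)] * 25 + [(0, 1)] + [(1, 1)] * 4
        rec = make_record(genotypes=gts)
        assert popgen_prefilter([rec], hwe_alpha=0.001, hwe_method="exact") == []

    def test_all_missing_locus_removed(self):
        rec = make_record(genotypes=[None] * 12)
        assert popgen_prefilter([rec], max_missing_fraction=1.0) == []


class TestPicBand:
    def test_half_half_locus_kept(self):
        rec = make_record(genotypes=[(0, 1)] * 12)  # p = q = 0.5, PIC = 0.375
        assert len(pic_band_filter([rec], 0.2, 0.5)) == 1

    def test_monomorphic_removed(self):
        rec = make_record(genotypes=[(0, 0)] * 12)
        assert pic_band_filter([rec], 0.2, 0.5) == []

    def test_rare_het_below_band(self):
        rec = make_record(genotypes=[(0, 1)] * 2 + [(0, 0)] * 10)  # PIC ~ 0.141
        assert pic_band_filter([rec], 0.2, 0.5) == []


class TestScreenPipeline:
    def test_clean_cohort_only_loses_natural_close_pairs(self, cohort):
        candidates, counts = screen_candidates(cohort.records)
        assert counts["hard_filter"] == counts["input"]
        assert counts["firstok"] == counts["isolated_biallelic"]
        assert counts["pic_band"] == counts["isolated_biallelic"]
        assert len(candidates) == counts["pic_band"]

    def test_planted_cohort_stage_counts_match_truth(self, cohort):
        spec = ViolationSpec(
            qd=3, qual=2, fs=2, mq=2, mqranksum=1, readposranksum=1,
            firstok_qual=3, multiallelic=3, proximity_pairs=3,
            low_maf=3, missingness=3, hwe=3, pic_out_of_band=3,
        )
        planted, truth = plant_violations(cohort, spec, seed=17)
        clean_cands, clean = screen_candidates(cohort.records)
        planted_cands, counts = screen_candidates(planted.records)
        expected = spec.expected_stage_removals()
        order = ["hard_filter", "isolated_biallelic", "firstok", "popgen",
                 "isolated_recheck", "pic_band"]
        prev_c, prev_p = clean["input"], counts["input"]
        for stage in order:
            natural = prev_c - clean[stage]
            assert prev_p - counts[stage] == natural + expected[stage], stage
            prev_c, prev_p = clean[stage], counts[stage]
        # recall and precision of the planted truth table are both 1
        victims = set(sum(truth.values(), []))
        assert {c.locus_id for c in planted_cands} == (
            {c.locus_id for c in clean_cands} - victims
        )

    def test_idempotent_on_survivors(self, cohort):
        candidates, _ = screen_candidates(cohort.records)
        survivor_ids = {c.locus_id for c in candidates}
        survivors = [r for r in cohort.records if r.locus_id in survivor_ids]
        again, counts = screen_candidates(survivors)
        assert {c.locus_id for c in again} == survivor_ids
        assert counts["pic_band"] == counts["input"]

    def test_output_sorted_and_input_order_independent(self, cohort):
        candidates, _ = screen_candidates(cohort.records)
        shuffled = list(cohort.records)
        random.Random(3).shuffle(shuffled)
        candidates2, _ = screen_candidates(shuffled)
        ids = [(c.chrom, c.pos) for c in candidates]
        assert ids == sorted(ids)
        assert ids == [(c.chrom, c.pos) for c in candidates2]

    @pytest.mark.parametrize(
        "relax",
        [
            {"maf_min": 0.01},
            {"hwe_alpha": 0.0001},
            {"pic_min": 0.05},
            {"pic_max": 0.8},
            {"max_missing_fraction": 0.5},
            {"isolation_window": 50},
        ],
    )
    def test_relaxing_thresholds_never_shrinks_survivors(self, cohort, relax):
        planted, _ = plant_violations(
            cohort,
            ViolationSpec(low_maf=3, missingness=3, hwe=3, pic_out_of_band=3,
                          proximity_pairs=3),
            seed=23,
        )
        strict, _ = screen_candidates(planted.records, ScreenConfig())
        relaxed, _ = screen_candidates(
            planted.records, dataclasses.replace(ScreenConfig(), **relax)
        )
        assert {c.locus_id for c in strict} <= {c.locus_id for c in relaxed}

    def test_matches_bruteforce_screen_on_synthetic_cohort(self, cohort):
        """Full pipeline equals an independent per-record re-implementation."""
        planted, _ = plant_violations(
            cohort,
            ViolationSpec(qd=4, qual=4, fs=4, firstok_qual=4, multiallelic=4,
                          low_maf=4, missingness=4, hwe=4, pic_out_of_band=4),
            seed=29,
        )
        records = planted.records
        config = ScreenConfig(hwe_method="chi2")
        candidates, _ = screen_candidates(records, config)

        def brute(records):
            def hard_ok(r, qual_min):
                a = r.annotations
                return (r.qual >= qual_min and a["QD"] >= 2.0 and a["FS"] <= 60.0
                        and a["MQ"] >= 40.0 and a["MQRankSum"] >= -12.5
                        and a["ReadPosRankSum"] >= -8.0)

            stage = [r for r in records if hard_ok(r, 30.0)]
            stage = [
                r for r in stage
                if len(r.alts) == 1 and len(r.ref) == 1 and len(r.alts[0]) == 1
                and all(o is r or o.chrom != r.chrom or abs(o.pos - r.pos) > 100
                        for o in stage)
            ]
            stage = [r for r in stage if hard_ok(r, 1000.0)]
            out = []
            for r in stage:
                gts = [g for g in r.genotypes if g is not None]
                if len(gts) < len(r.genotypes):
                    continue
                alt = sum((g[0] > 0) + (g[1] > 0) for g in gts) / (2 * len(gts))
                if min(alt, 1 - alt) < 0.05:
                    continue
                n1 = sum(g[0] != g[1] for g in gts)
                n2 = sum(g == (1, 1) for g in gts)
                n0 = len(gts) - n1 - n2
                n = len(gts)
                p = (2 * n0 + n1) / (2 * n)
                q = 1 - p
                if 0 < p < 1:
                    exp = (n * p * p, 2 * n * p * q, n * q * q)
                    stat = sum((o - e) ** 2 / e for o, e in zip((n0, n1, n2), exp))
                    if chi2_dist.sf(stat, 1) < 0.001:
                        continue
                pic = 1 - (alt**2 + (1 - alt) ** 2) - 2 * alt**2 * (1 - alt) ** 2
                if not (0.2 <= pic <= 0.5):
                    continue
                out.append(r.locus_id)
            return sorted(out)

        assert sorted(c.locus_id for c in candidates) == brute(records)
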