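"""Genomic-scar counting, HR-status calls, methylation and TMB."""

import numpy as np
import pandas as pd
import pytest

import hrdimmune as h
from hrdimmune.genome import MB
from hrdimmune.scars import (
    HR_DEFICIENT,
    HR_PROFICIENT,
    HrdScore,
    call_brca1_methylation,
    classify_hr_status,
    compute_tmb,
    count_loh,
    count_lst,
    count_tai,
    hrd_score,
    locate_promoter_probes,
)

from conftest import make_profile, random_profile
from oracle_scars import oracle_loh, oracle_lst, oracle_tai


class TestLoh:
    def test_empty_profile_counts_zero(self, toy_genome):
        profile = make_profile([], genome=toy_genome)
        assert count_loh(profile) == 0

    def test_large_interstitial_loh_counts_once(self):
        # 20 Mb LOH on a 100 Mb chromosome counts; whole-chromosome LOH does not
        p1 = make_profile([("chr1", 10 * MB, 30 * MB - 1, 2, 0)])
        assert count_loh(p1) == 1
        p2 = make_profile([("chr1", 1, 100 * MB, 2, 0)])
        assert count_loh(p2) == 0

    def test_size_threshold_is_strict(self):
        rows = [("chr1", 1 + i * 10 * MB, (i + 1) * 10 * MB, 1, 0) for i in range(10)]
        assert count_loh(make_profile(rows)) == 0  # all 10 Mb, below 15 Mb
        exactly_15 = make_profile([("chr1", 1, 15 * MB, 2, 0)])
        assert count_loh(exactly_15) == 0  # > 15 Mb required, not >=

    def test_total_zero_excluded(self):
        # homozygous deletion is not LOH-with-retention
        p = make_profile([("chr1", 1 * MB, 30 * MB, 0, 0)])
        assert count_loh(p) == 0


class TestTai:
    def test_balanced_diploid_genome_scores_zero(self, toy_genome):
        rows = [
            (ann.name, 1, ann.length, 2, 1) for ann in toy_genome.chromosomes.values()
        ]
        assert count_tai(make_profile(rows)) == 0

    def test_telomeric_imbalance_not_crossing_centromere(self):
        # chr1 centromere at 48-52 Mb; a 15 Mb imbalanced segment at the p end
        p = make_profile([("chr1", 1, 15 * MB, 3, 1)])
        assert count_tai(p) == 1
        # extended across the whole centromere: no longer counted
        p2 = make_profile([("chr1", 1, 60 * MB, 3, 1)])
        assert count_tai(p2) == 0

    def test_interstitial_imbalance_not_counted(self):
        p = make_profile([("chr1", 20 * MB, 40 * MB, 3, 1)])
        assert count_tai(p) == 0

    def test_q_telomere_counts(self):
        p = make_profile([("chr1", 80 * MB, 100 * MB, 3, 1)])
        assert count_tai(p) == 1


class TestLst:
    def test_single_segment_per_chromosome(self, toy_genome):
        rows = [
            (ann.name, 1, ann.length, 2, 1) for ann in toy_genome.chromosomes.values()
        ]
        assert count_lst(make_profile(rows)) == 0

    def test_two_adjacent_large_segments_one_transition(self):
        p = make_profile(
            [("chr1", 1, 12 * MB, 2, 1), ("chr1", 12 * MB + 1, 24 * MB, 3, 1)]
        )
        assert count_lst(p) == 1

    def test_retained_middle_segment_blocks_transitions(self):
        # a 5 Mb middle state survives the 3 Mb filter; neither adjacent
        # pair is then two >= 10 Mb segments
        p = make_profile(
            [
                ("chr1", 1, 12 * MB, 2, 1),
                ("chr1", 12 * MB + 1, 17 * MB, 4, 2),
                ("chr1", 17 * MB + 1, 29 * MB, 3, 1),
            ]
        )
        assert count_lst(p) == 0

    def test_small_middle_segment_smoothed_away(self):
        # a 2 Mb blip merges into the larger neighbour, leaving one transition
        p = make_profile(
            [
                ("chr1", 1, 12 * MB, 2, 1),
                ("chr1", 12 * MB + 1, 14 * MB, 4, 2),
                ("chr1", 14 * MB + 1, 29 * MB, 3, 1),
            ]
        )
        assert count_lst(p) == 1

    def test_arm_boundary_blocks_transition(self, toy_genome):
        # two large segments meeting inside the centromere are on
        # different arms and produce no transition
        ann = toy_genome["chr1"]
        p = make_profile(
            [
                ("chr1", ann.cen_start - 20 * MB, ann.cen_start + 1 * MB, 2, 1),
                ("chr1", ann.cen_start + 1 * MB + 1, ann.cen_end + 20 * MB, 3, 1),
            ]
        )
        assert count_lst(p) == 0


class TestOracleEquivalence:
    def test_random_profiles_match_literal_scan(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            profile = random_profile(rng)
            assert count_loh(profile) == oracle_loh(profile)
            assert count_tai(profile) == oracle_tai(profile)
            assert count_lst(profile) == oracle_lst(profile)

    def test_balanced_diploid_segment_never_changes_counts(self):
        rng = np.random.default_rng(8)
        for _ in range(40):
            profile = random_profile(rng)
            base = hrd_score(profile)
            # append a balanced (2,1) segment in a random unoccupied spot
            seg = profile.segments
            for ann in profile.genome.chromosomes.values():
                used = seg[seg["chrom"] == ann.name]
                free_start = (used["end"].max() + 2) if len(used) else 1
                if free_start + MB < ann.length:
                    extra = pd.concat(
                        [
                            seg,
                            pd.DataFrame(
                                [
                                    {
                                        "chrom": ann.name,
                                        "start": int(free_start),
                                        "end": int(ann.length),
                                        "total_cn": 2,
                                        "minor_cn": 1,
                                    }
                                ]
                            ),
                        ],
                        ignore_index=True,
                    )
                    augmented = make_profile(
                        list(extra.itertuples(index=False, name=None)),
                        genome=profile.genome,
                    )
                    new = hrd_score(augmented)
                    assert (new.loh_count, new.tai_count) == (
                        base.loh_count,
                        base.tai_count,
                    )
                    break


class TestHrdScoreAndStatus:
    def test_empty_profile_all_zero(self, toy_genome):
        s = hrd_score(make_profile([], genome=toy_genome))
        assert (s.loh_count, s.tai_count, s.lst_count, s.total) == (0, 0, 0, 0)

    def test_total_is_component_sum_and_meets_threshold(self):
        s = HrdScore(20, 12, 10)
        assert s.total == 42
        assert classify_hr_status(s, None).status == HR_DEFICIENT

    @pytest.mark.parametrize(
        "total,tbrca,expected",
        [
            (41, False, HR_PROFICIENT),  # strict threshold
            (42, False, HR_DEFICIENT),  # >= 42 inclusive
            (0, True, HR_DEFICIENT),  # deleterious BRCA1/2 alone suffices
        ],
    )
    def test_status_rule(self, total, tbrca, expected):
        score = HrdScore(total, 0, 0)
        brca = (
            pd.DataFrame([{"gene": "BRCA1", "consequence": "frameshift"}])
            if tbrca
            else pd.DataFrame(columns=["gene", "consequence"])
        )
        assert classify_hr_status(score, brca).status == expected

    def test_status_monotone_in_score(self):
        # raising the score never flips deficient back to proficient
        statuses = [
            classify_hr_status(HrdScore(t, 0, 0), None).status for t in range(0, 90, 3)
        ]
        first_deficient = statuses.index(HR_DEFICIENT)
        assert all(s == HR_DEFICIENT for s in statuses[first_deficient:])

    def test_malformed_segment_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="end < start"):
            make_profile([("chr1", 10 * MB, 5 * MB, 2, 1)], genome=toy_genome)

    def test_unknown_chromosome_rejected(self, toy_genome):
        with pytest.raises(ValueError, match="unannotated"):
            make_profile([("chr99", 1, 2 * MB, 2, 1)], genome=toy_genome)


class TestMethylation:
    @pytest.mark.parametrize("beta,expected", [(0.95, True), (0.90, False), (0.05, False)])
    def test_silencing_cutoff_is_strict(self, beta, expected):
        call = call_brca1_methylation(pd.Series({"cg13782816": beta}))
        assert call.silenced is expected
        assert not call.missing

    def test_missing_probe_is_flagged_not_false(self):
        call = call_brca1_methylation(pd.Series({"cgOTHER": 0.5}))
        assert call.missing
        assert call.silenced is None


class TestPromoterProbes:
    TSS = pd.DataFrame(
        [
            {"gene": "PLUS", "chrom": "chr1", "tss": 100_000, "strand": "+"},
            {"gene": "MINUS", "chrom": "chr1", "tss": 200_000, "strand": "-"},
        ]
    )

    def probes(self, positions):
        return pd.DataFrame(
            [{"probe": f"p{i}", "chrom": "chr1", "pos": p} for i, p in enumerate(positions)]
        )

    def test_closed_upstream_boundary(self):
        hits = locate_promoter_probes(self.probes([100_000 - 1500]), self.TSS)
        assert set(hits["gene"]) == {"PLUS"}

    def test_downstream_limit_excluded(self):
        hits = locate_promoter_probes(self.probes([100_000 + 501]), self.TSS)
        assert hits.empty

    def test_minus_strand_upstream_flipped(self):
        # upstream of a minus-strand gene lies at larger genomic coordinates
        hits = locate_promoter_probes(self.probes([200_000 + 1500]), self.TSS)
        assert set(hits["gene"]) == {"MINUS"}
        hits2 = locate_promoter_probes(self.probes([200_000 - 501]), self.TSS)
        assert hits2.empty

    def test_unknown_strand_skipped_with_warning(self):
        tss = pd.DataFrame([{"gene": "X", "chrom": "chr1", "tss": 1000, "strand": "?"}])
        with pytest.warns(UserWarning, match="unknown strand"):
            hits = locate_promoter_probes(self.probes([1000]), tss)
        assert hits.empty


class TestTmb:
    def test_empty_table(self):
        assert compute_tmb(pd.DataFrame(columns=["sample", "consequence"])) == 0

    def test_counts_configured_nonsynonymous_set(self):
        rows = (
            [{"sample": "s", "chrom": "1", "pos": i, "ref": "C", "alt": "T",
              "consequence": "missense"} for i in range(3)]
            + [{"sample": "s", "chrom": "1", "pos": 10 + i, "ref": "C", "alt": "T",
                "consequence": "synonymous"} for i in range(2)]
            + [{"sample": "s", "chrom": "1", "pos": 20, "ref": "CA", "alt": "C",
                "consequence": "frameshift"}]
        )
        assert compute_tmb(pd.DataFrame(rows)) == 4

    def test_duplicate_rows_counted_once(self):
        row = {"sample": "s", "chrom": "1", "pos": 5, "ref": "C", "alt": "T",
               "consequence": "missense"}
        assert compute_tmb(pd.DataFrame([row, row, row])) == 1
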