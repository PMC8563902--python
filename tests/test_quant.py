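import math

import numpy as np
import pandas as pd
import pytest

from oracles import distinct_dedup_keys, recount_pileup
from trnam1a.quant import (
    CallConfig,
    M1AStoichiometryModel,
    call_m1a58,
    dedup,
    differential_m1a,
    mismatch_rate,
    pileup,
    position_mismatch_table,
)
from trnam1a.simulate import (
    SimTruth,
    default_truth,
    make_trna_reference,
    simulate_trna_alignments,
)


def _frame(rows):
    return pd.DataFrame(rows, columns=["read_id", "ref_id", "ref_start", "umi", "seq", "pairs"])


class TestDedup:
    def test_same_position_same_umi_collapsed(self):
        frame = _frame(
            [
                ("r1", "t1", 0, "AAAAAAAAAA", "ACGT", None),
                ("r2", "t1", 0, "AAAAAAAAAA", "ACGT", None),
                ("r3", "t1", 0, "CCCCCCCCCC", "ACGT", None),
            ]
        )
        out = dedup(frame)
        assert len(out) == 2
        assert set(out["umi"]) == {"AAAAAAAAAA", "CCCCCCCCCC"}
        # representative is the first in stable read-id order
        assert "r1" in set(out["read_id"])

    def test_same_umi_different_position_both_kept(self):
        frame = _frame(
            [
                ("r1", "t1", 0, "AAAAAAAAAA", "ACGT", None),
                ("r2", "t1", 5, "AAAAAAAAAA", "ACGT", None),
            ]
        )
        assert len(dedup(frame)) == 2

    def test_missing_umi_rejected(self):
        frame = _frame([("r1", "t1", 0, None, "ACGT", None)])
        with pytest.raises(ValueError):
            dedup(frame)

    def test_idempotent_and_matches_key_set_oracle(self, refs20, truth20):
        aln, _ = simulate_trna_alignments(refs20, truth20, 10000, False, "A", seed=13)
        once = dedup(aln)
        assert len(once) == len(distinct_dedup_keys(aln))
        twice = dedup(once)
        pd.testing.assert_frame_equal(once, twice)
        assert len(once) <= len(aln)


class TestPileup:
    def test_exact_reads_counted(self, refs4):
        ref = refs4[0]
        frame = _frame(
            [(f"r{i}", ref.ref_id, 0, "A" * 10, ref.sequence, None) for i in range(10)]
        )
        pile = pileup(frame, refs4)
        assert pile.counts_at(ref.ref_id, ref.a58_index).tolist() == [10, 0, 0, 0]
        assert pile.coverage(ref.ref_id, 0) == 10

    def test_single_substitution_counted(self, refs4):
        ref = refs4[0]
        mutated = ref.sequence[: ref.a58_index] + "G" + ref.sequence[ref.a58_index + 1 :]
        rows = [(f"r{i}", ref.ref_id, 0, "A" * 10, ref.sequence, None) for i in range(9)]
        rows.append(("r9", ref.ref_id, 0, "A" * 10, mutated, None))
        pile = pileup(_frame(rows), refs4)
        assert pile.counts_at(ref.ref_id, ref.a58_index).tolist() == [9, 0, 1, 0]

    def test_n_bases_skipped_and_gaps_counted_as_deletions(self, refs4):
        ref = refs4[0]
        seq = "N" + ref.sequence[1:10]
        pairs = [(k, k + 1) for k in range(9)]  # read base k vs ref k+1
        pairs.insert(0, (None, 0))  # deletion at ref position 0
        frame = _frame([("r0", ref.ref_id, 0, "A" * 10, seq, pairs)])
        pile = pileup(frame, refs4)
        assert pile.deletions[ref.ref_id][0] == 1
        assert pile.coverage(ref.ref_id, 1) == 0  # the N contributes nothing

    def test_unknown_reference_rejected(self, refs4):
        frame = _frame([("r0", "nope", 0, "A" * 10, "ACGT", None)])
        with pytest.raises(ValueError):
            pileup(frame, refs4)

    def test_totals_match_bruteforce_recount(self, refs20, truth20):
        aln, _ = simulate_trna_alignments(refs20, truth20, 5000, False, "A", seed=17)
        pile = pileup(aln, refs20)
        expected = recount_pileup(aln, refs20)
        base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
        for ref in refs20:
            counts = pile.base_counts[ref.ref_id]
            brute = np.zeros_like(counts)
            for (pos, base), n in expected[ref.ref_id].items():
                brute[pos, base_idx[base]] = n
            assert (counts == brute).all()


class TestMismatchRate:
    def test_arithmetic(self):
        assert mismatch_rate(np.array([900, 20, 50, 30]), "A") == pytest.approx(0.10)
        assert mismatch_rate(np.array([100, 0, 0, 0]), "A") == 0.0

    def test_zero_coverage_is_nan_not_zero(self):
        rate = mismatch_rate(np.array([0, 0, 0, 0]), "A")
        assert math.isnan(rate)

    def test_deletions_optional(self):
        counts = np.array([90, 0, 0, 0])
        assert mismatch_rate(counts, "A", deletions=10) == 0.0
        assert mismatch_rate(counts, "A", deletions=10,
                             count_deletions_as_mismatch=True) == pytest.approx(0.1)


class TestCalling:
    def _paired_pileups(self, refs, stoich, seed, cov=1000, err=0.0, eff=1.0):
        truth = SimTruth(
            trna=pd.DataFrame(
                {"ref_id": [r.ref_id for r in refs],
                 "stoich_condA": stoich, "stoich_condB": stoich}
            ),
            demethylation_efficiency=eff,
            sequencing_error_rate=err,
            pcr_duplication_mean=0.0,
        )
        n = cov * len(refs)
        alu, _ = simulate_trna_alignments(refs, truth, n, False, "A", seed=seed)
        ald, _ = simulate_trna_alignments(refs, truth, n, True, "A", seed=seed + 1)
        return pileup(dedup(alu), refs), pileup(dedup(ald), refs)

    def test_end_to_end_stoichiometry_recovery(self, refs4):
        pu, pdm = self._paired_pileups(refs4, 0.45, seed=31, err=0.002)
        calls = call_m1a58(pu, pdm, refs4)
        for row in calls.itertuples(index=False):
            assert row.called
            se = math.sqrt(0.45 * 0.55 / row.cov_untreated)
            assert abs(row.stoichiometry - 0.45) < 3 * se + 0.002
            assert row.delta > 0.4

    def test_pure_sequencing_error_not_called(self, refs4):
        pu, pdm = self._paired_pileups(refs4, 0.0, seed=37, err=0.004)
        calls = call_m1a58(pu, pdm, refs4)
        assert not calls["called"].any()
        assert calls["min_cov_ok"].all()

    def test_complete_demethylation_gives_exact_zero(self, refs4):
        pu, pdm = self._paired_pileups(refs4, 0.9, seed=41, err=0.0, eff=1.0)
        calls = call_m1a58(pu, pdm, refs4)
        assert (calls["mism_demethylated"] == 0.0).all()

    def test_uncovered_site_recorded_not_dropped(self, refs4):
        empty = pileup(_frame([]), refs4)
        calls = call_m1a58(empty, empty, refs4)
        assert len(calls) == len(refs4)
        assert not calls["min_cov_ok"].any()
        assert not calls["called"].any()
        assert calls["mism_untreated"].isna().all()

    def test_model_results_summary_and_position_table(self, refs4):
        pu, pdm = self._paired_pileups(refs4, 0.5, seed=43, err=0.002)
        res = M1AStoichiometryModel(pu, pdm, refs4).fit()
        text = res.summary()
        assert "m1A58" in text and refs4[0].ref_id in text
        table = position_mismatch_table(pu)
        sub = table[(table["ref_id"] == refs4[0].ref_id)
                    & (table["position"] == refs4[0].a58_index + 1)]
        assert sub["mismatch_rate"].iloc[0] == pytest.approx(0.5, abs=0.06)


class TestDifferential:
    def _calls(self, rows):
        return pd.DataFrame(
            rows,
            columns=["ref_id", "position", "cov_untreated", "cov_demethylated",
                     "mism_untreated", "mism_demethylated", "delta", "stoichiometry",
                     "se", "min_cov_ok", "called", "band"],
        )

    def test_elevation_arithmetic(self):
        a = self._calls([("t1", 58, 1000, 1000, 0.50, 0.0, 0.50, 0.50, 0.01, True, True, "medium")])
        b = self._calls([("t1", 58, 1000, 1000, 0.62, 0.0, 0.62, 0.62, 0.01, True, True, "medium")])
        out = differential_m1a(a, b)
        row = out.iloc[0]
        assert row["elevated_in_B"]
        assert row["diff"] == pytest.approx(0.12)
        assert row["band"] == "medium"  # from the lower condition

    def test_high_methylation_saturation_not_elevated(self):
        a = self._calls([("t1", 58, 1000, 1000, 0.95, 0.0, 0.95, 0.95, 0.01, True, True, "high")])
        b = self._calls([("t1", 58, 1000, 1000, 0.95, 0.0, 0.95, 0.95, 0.01, True, True, "high")])
        assert not differential_m1a(a, b)["elevated_in_B"].any()

    def test_missing_condition_flagged_and_excluded(self):
        a = self._calls([("t1", 58, 1000, 1000, 0.5, 0.0, 0.5, 0.5, 0.01, True, True, "medium")])
        b = self._calls([("t2", 58, 1000, 1000, 0.7, 0.0, 0.7, 0.7, 0.01, True, True, "medium")])
        out = differential_m1a(a, b)
        assert out["missing_condition"].all()
        assert not out["elevated_in_B"].any()

    def test_planted_elevated_set_recovered_end_to_end(self, refs20):
        truth = default_truth(refs20, seed=5, pcr_duplication_mean=0.0)
        n = 4000 * len(refs20)
        frames = {}
        for k, (cond, arm, dem) in enumerate(
            [("A", "u", False), ("A", "d", True), ("B", "u", False), ("B", "d", True)]
        ):
            aln, _ = simulate_trna_alignments(refs20, truth, n, dem, cond, seed=500 + k)
            frames[(cond, arm)] = pileup(dedup(aln), refs20)
        calls_a = call_m1a58(frames[("A", "u")], frames[("A", "d")], refs20)
        calls_b = call_m1a58(frames[("B", "u")], frames[("B", "d")], refs20)
        out = differential_m1a(calls_a, calls_b).set_index("ref_id")
        expected = truth.trna.set_index("ref_id")["elevated_in_B"]
        assert (out["elevated_in_B"].reindex(expected.index) == expected).all()


def test_call_config_validation():
    with pytest.raises(ValueError):
        CallConfig(delta_min=0.0)
    with pytest.raises(ValueError):
        CallConfig(band_medium=0.9, band_high=0.3)
    cfg = CallConfig()
    assert cfg.band(0.95) == "high"
    assert cfg.band(0.5) == "medium"
    assert cfg.band(0.1) == "low"
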