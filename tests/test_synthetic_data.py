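"""Generators: library designs, landscape, counts, reads, traces."""

import numpy as np
import pandas as pd
import pytest

from sniperkit.library_model import annotate_mismatches, classify_pam
from sniperkit.synthetic_data import (
    DesignError,
    FretPopulationSpec,
    LibraryDesignSpec,
    build_library,
    default_landscape,
    landscape_activity,
    simulate_counts,
    simulate_reads,
    simulate_traces,
    truth_from_landscape,
)


class TestBuildLibrary:
    def test_pam_scan_emits_all_256(self):
        spec = LibraryDesignSpec(
            n_guides=1, pam_scan=True, mismatch_targets_per_guide=0
        )
        pairs = build_library(spec, seed=0)
        assert len(pairs) == 256
        assert len({p.pam4 for p in pairs}) == 256

    def test_mismatch_panel_scale(self):
        """30 guides x 98 mismatched targets -> 2,940 mismatched pairs
        plus the 30 matched pairs."""
        spec = LibraryDesignSpec(n_guides=30, mismatch_targets_per_guide=98)
        pairs = build_library(spec, seed=1)
        matched = [p for p in pairs if not p.n_designed_mismatches()]
        mismatched = [p for p in pairs if p.n_designed_mismatches()]
        assert len(matched) == 30
        assert len(mismatched) == 2940

    def test_round_trip_annotations(self):
        """Designed mismatches equal re-annotated mismatches for every
        generated pair."""
        spec = LibraryDesignSpec(n_guides=5, mismatch_targets_per_guide=20)
        for pair in build_library(spec, seed=2):
            recomputed = annotate_mismatches(
                pair.spacer, pair.protospacer, pair.expression_system
            )
            assert recomputed == pair.mismatches

    def test_deterministic_given_seed(self):
        spec = LibraryDesignSpec(n_guides=3, mismatch_targets_per_guide=5)
        a = build_library(spec, seed=7)
        b = build_library(spec, seed=7)
        assert [(p.pair_id, p.spacer, p.context) for p in a] == [
            (p.pair_id, p.spacer, p.context) for p in b
        ]
        c = build_library(spec, seed=8)
        assert [p.context for p in a] != [p.context for p in c]

    def test_single_class_mix_respected(self):
        spec = LibraryDesignSpec(
            n_guides=3,
            mismatch_targets_per_guide=10,
            mismatch_counts={1: 1.0},
            class_mix={"transversion": 1.0},
        )
        for pair in build_library(spec, seed=3):
            for m in pair.mismatches:
                if not m.five_prime_g:
                    assert m.mclass == "transversion"

    def test_invalid_mix_rejected(self):
        with pytest.raises(ValueError):
            LibraryDesignSpec(class_mix={"wobble": 0.5})


class TestLandscape:
    def test_pam_factor_ordering(self):
        lp = default_landscape()
        spec = LibraryDesignSpec(
            n_guides=1, pam_scan=True, mismatch_targets_per_guide=0
        )
        pairs = build_library(spec, seed=4)
        by_class = {}
        for p in pairs:
            by_class.setdefault(classify_pam(p.pam), []).append(
                landscape_activity(p, lp)
            )
        assert np.mean(by_class["NGG"]) > np.mean(by_class["NGH"])
        assert np.mean(by_class["NGH"]) > np.mean(by_class["nonNG"])

    def test_non_ng_pam_is_at_most_1pct_of_ngg_twin(self):
        lp = default_landscape()
        spec = LibraryDesignSpec(
            n_guides=1, pam_scan=True, mismatch_targets_per_guide=0
        )
        pairs = build_library(spec, seed=5)
        # twin pairs share everything but the PAM bases themselves; compare
        # through the PAM factor directly
        ngg = [p for p in pairs if p.pam_class == "NGG"]
        nonng = [p for p in pairs if p.pam_class == "nonNG"]
        assert (
            lp.pam_factors["nonNG"] / lp.pam_factors["NGG"] <= 0.01
        )
        assert max(landscape_activity(p, lp) for p in nonng) < min(
            landscape_activity(p, lp) for p in ngg
        ) * 0.25

    def test_three_transversions_below_5pct_of_matched(self):
        lp = default_landscape()
        spec = LibraryDesignSpec(
            n_guides=10,
            mismatch_targets_per_guide=3,
            mismatch_counts={3: 1.0},
            class_mix={"transversion": 1.0},
        )
        pairs = build_library(spec, seed=6)
        matched = {p.pair_id: p for p in pairs if not p.n_designed_mismatches()}
        for p in pairs:
            if p.n_designed_mismatches() != 3:
                continue
            guide = p.pair_id.rsplit("_", 1)[0] + "_matched"
            ratio = landscape_activity(p, lp) / landscape_activity(
                matched[guide], lp
            )
            assert ratio < 0.05

    def test_order_invariance(self):
        lp = default_landscape()
        spec = LibraryDesignSpec(n_guides=4, mismatch_targets_per_guide=5)
        pairs = build_library(spec, seed=7)
        vals = {p.pair_id: landscape_activity(p, lp) for p in pairs}
        for p in reversed(pairs):
            assert landscape_activity(p, lp) == vals[p.pair_id]


class TestSimulateCounts:
    def _pairs_truth(self, n=50, freq=25.0, bg=0.0):
        spec = LibraryDesignSpec(n_guides=n, mismatch_targets_per_guide=0)
        pairs = build_library(spec, seed=8)
        truth = pd.DataFrame(
            {
                "pair_id": [p.pair_id for p in pairs],
                "true_indel_freq": freq,
                "background_pct": bg,
            }
        ).set_index("pair_id")
        return pairs, truth

    def test_zero_depth_gives_zero_counts(self):
        pairs, truth = self._pairs_truth(5)
        counts = simulate_counts(pairs, truth, depth=0, seed=9)
        assert (counts["total_reads"] == 0).all()
        assert (counts["indel_reads"] == 0).all()

    def test_binomial_mean_recovery(self):
        pairs, truth = self._pairs_truth(500, freq=25.0)
        counts = simulate_counts(
            pairs, truth, depth=10_000, seed=10, days=(4,), replicates=(1,)
        )
        frac = counts["indel_reads"] / counts["total_reads"]
        se = np.sqrt(0.25 * 0.75 / 10_000) / np.sqrt(len(counts))
        assert abs(frac.mean() - 0.25) < 3 * se * np.sqrt(1.5)  # overdispersion

    def test_background_only_corrects_to_zero(self):
        from sniperkit.indel_quant import apply_filters

        pairs, truth = self._pairs_truth(300, freq=0.0, bg=8.0)
        counts = simulate_counts(
            pairs, truth, depth=5000, seed=11, days=(4,), replicates=(1,)
        )
        out = apply_filters(counts)
        # corrected frequencies centred at zero: mean raw equals background
        assert out["raw_pct"].mean() == pytest.approx(8.0, abs=0.3)
        assert out["corrected_pct"].mean() < 0.3

    def test_deterministic(self):
        pairs, truth = self._pairs_truth(10)
        a = simulate_counts(pairs, truth, depth=100, seed=12)
        b = simulate_counts(pairs, truth, depth=100, seed=12)
        pd.testing.assert_frame_equal(a, b)


class TestSimulateReads:
    def _pair(self):
        spec = LibraryDesignSpec(n_guides=1, mismatch_targets_per_guide=0)
        return build_library(spec, seed=13)[0]

    def test_zero_probability_zero_error_reproduces_reference(self):
        pair = self._pair()
        reads = simulate_reads(pair, 0.0, 50, seed=14, error_rate=0.0)
        assert len({seq for _, seq, _ in reads}) == 1

    def test_p1_all_reads_carry_indels(self):
        from sniperkit.indel_quant import call_indel
        from sniperkit.synthetic_data import READ_FLANK_3, READ_FLANK_5

        pair = self._pair()
        ref = READ_FLANK_5 + pair.context + READ_FLANK_3
        reads = simulate_reads(pair, 100.0, 200, seed=15, error_rate=0.0)
        assert all(call_indel(s, ref) == "indel" for _, s, _ in reads)

    def test_headers_carry_no_truth(self):
        pair = self._pair()
        reads = simulate_reads(pair, 50.0, 5, seed=16)
        for rid, _, _ in reads:
            assert "50" not in rid.split("_")[-1] or rid.startswith("read_")


class TestSimulateTraces:
    def test_donor_only_traces_have_near_zero_acceptor(self):
        spec = FretPopulationSpec(donor_only_frac=1.0)
        traces = simulate_traces(spec, 50, seed=17)
        for t in traces:
            e = t.efficiency()
            assert np.nanmean(e) < 0.15

    def test_no_transitions_when_prob_zero(self):
        from sniperkit.smfret_unwind import transition_fraction

        spec = FretPopulationSpec(transition_prob=0.0)
        traces = simulate_traces(spec, 500, seed=18)
        assert transition_fraction(traces) == 0.0

    def test_resolvability_guard(self):
        with pytest.raises(ValueError):
            FretPopulationSpec(e_low_mean=0.5, e_high_mean=0.55, e_low_sd=0.06)

    def test_deterministic(self):
        spec = FretPopulationSpec()
        a = simulate_traces(spec, 20, seed=19)
        b = simulate_traces(spec, 20, seed=19)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.donor, tb.donor)
            np.testing.assert_array_equal(ta.acceptor, tb.acceptor)
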