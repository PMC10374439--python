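"""Specificity, PAM-compatibility, stratification and trade-off summaries."""

import numpy as np
import pandas as pd
import pytest

from sniperkit.indel_quant import apply_filters, merge_replicates
from sniperkit.specificity_stats import (
    SelectionError,
    UndefinedSpecificity,
    annotation_frame,
    pam_profile,
    positionwise_specificity,
    relative_activity,
    select_comparable_guides,
    specificity,
    specificity_table,
    stratify_by_mismatch,
    tradeoff_summary,
)
from sniperkit.synthetic_data import (
    LibraryDesignSpec,
    build_library,
    default_landscape,
    simulate_counts,
    truth_from_landscape,
)


class TestRatios:
    @pytest.mark.parametrize(
        "on,off,expected",
        [(50, 0, 1.0), (50, 50, 0.0), (80, 20, 0.75)],
    )
    def test_specificity_values(self, on, off, expected):
        assert specificity(on, off) == pytest.approx(expected)

    @pytest.mark.parametrize("off,on,expected", [(0, 50, 0.0), (25, 50, 0.5)])
    def test_relative_activity_values(self, off, on, expected):
        assert relative_activity(off, on) == pytest.approx(expected)

    def test_complementarity(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            on = rng.uniform(0.1, 100)
            off = rng.uniform(0, 100)
            assert specificity(on, off) + relative_activity(off, on) == pytest.approx(
                1.0
            )

    def test_zero_on_target_undefined(self):
        with pytest.raises(UndefinedSpecificity):
            specificity(0.0, 5.0)


@pytest.fixture(scope="module")
def screen():
    """A small simulated screen: counts -> pooled -> filtered."""
    spec = LibraryDesignSpec(n_guides=12, mismatch_targets_per_guide=24)
    pairs = build_library(spec, seed=21)
    lp = default_landscape()
    truth = truth_from_landscape(pairs, lp, background_pct=1.0)
    counts = simulate_counts(pairs, truth, depth=3000, seed=22)
    filtered = apply_filters(merge_replicates(counts))
    passed = filtered[filtered["passed_filters"]]
    ann = annotation_frame(pairs)
    return pairs, lp, truth, counts, passed, ann


class TestSpecificityTable:
    def test_identity_per_record(self, screen):
        *_, passed, ann = screen
        table = specificity_table(passed, ann)
        assert len(table) > 0
        np.testing.assert_allclose(
            table["specificity"] + table["relative_activity"], 1.0
        )

    def test_pooling_invariance(self, screen):
        """Summaries on pooled replicates equal summaries on the
        summed-count table (pooling is summation by construction)."""
        pairs, lp, truth, counts, passed, ann = screen
        summed = counts.groupby(["pair_id", "variant", "day"], as_index=False).agg(
            total_reads=("total_reads", "sum"),
            indel_reads=("indel_reads", "sum"),
            background_pct=("background_pct", "mean"),
        )
        filt2 = apply_filters(summed)
        passed2 = filt2[filt2["passed_filters"]]
        t1 = specificity_table(passed, ann).sort_values("pair_id").reset_index(drop=True)
        t2 = specificity_table(passed2, ann).sort_values("pair_id").reset_index(drop=True)
        np.testing.assert_allclose(
            t1["specificity"].to_numpy(), t2["specificity"].to_numpy()
        )

    def test_permutation_invariance(self, screen):
        *_, passed, ann = screen
        shuffled = passed.sample(frac=1.0, random_state=1)
        t1 = specificity_table(passed, ann)
        t2 = specificity_table(shuffled, ann)
        m1 = t1.set_index(["pair_id", "day"])["specificity"].sort_index()
        m2 = t2.set_index(["pair_id", "day"])["specificity"].sort_index()
        pd.testing.assert_series_equal(m1, m2)


class TestPamProfile:
    def test_ngg_ranks_first_under_the_landscape(self):
        spec = LibraryDesignSpec(
            n_guides=2, pam_scan=True, mismatch_targets_per_guide=0
        )
        pairs = build_library(spec, seed=23)
        lp = default_landscape()
        truth = truth_from_landscape(pairs, lp, background_pct=0.5)
        counts = simulate_counts(pairs, truth, depth=2000, seed=24)
        filtered = apply_filters(merge_replicates(counts))
        passed = filtered[filtered["passed_filters"]]
        ann = annotation_frame(pairs)
        _, per_class = pam_profile(passed, ann)
        assert per_class.iloc[0]["pam_class"] == "NGG"

    def test_single_record_group_mean(self, screen):
        *_, ann = screen
        freq = pd.DataFrame(
            {
                "pair_id": [ann["pair_id"].iloc[0]],
                "variant": "v",
                "day": 4,
                "corrected_pct": [42.0],
            }
        )
        per_pam4, per_class = pam_profile(freq, ann)
        assert per_pam4["mean_pct"].iloc[0] == pytest.approx(42.0)
        assert per_class["mean_pct"].iloc[0] == pytest.approx(42.0)


class TestStratification:
    def test_wobble_more_tolerated_than_transversion(self):
        """With class penalty 0.8 vs 0.1 in the truth, the wobble
        stratum's median relative activity exceeds the transversion
        stratum's."""
        spec = LibraryDesignSpec(
            n_guides=10,
            mismatch_targets_per_guide=20,
            mismatch_counts={1: 1.0},
            class_mix={"wobble": 0.5, "transversion": 0.5},
        )
        pairs = build_library(spec, seed=25)
        lp = default_landscape()
        truth = truth_from_landscape(pairs, lp, background_pct=0.5)
        counts = simulate_counts(pairs, truth, depth=3000, seed=26)
        filtered = apply_filters(merge_replicates(counts))
        passed = filtered[filtered["passed_filters"]]
        ann = annotation_frame(pairs)
        table = specificity_table(passed, ann)
        strata = stratify_by_mismatch(table).set_index("stratum")
        assert (
            strata.loc["class_wobble", "median_relative_activity"]
            > strata.loc["class_transversion", "median_relative_activity"]
        )

    def test_more_mismatches_less_activity(self, screen):
        *_, passed, ann = screen
        table = specificity_table(passed, ann)
        strata = stratify_by_mismatch(table).set_index("stratum")
        present = [
            s for s in ("1_mismatch", "2_mismatch", "3_mismatch") if s in strata.index
        ]
        meds = [strata.loc[s, "median_relative_activity"] for s in present]
        assert meds == sorted(meds, reverse=True)


class TestPositionProfile:
    def test_profile_matches_planted_penalties(self):
        """Mean specificity per position tracks 1 - penalty when the
        truth encodes per-position penalties."""
        lp = default_landscape()
        spec = LibraryDesignSpec(
            n_guides=20,
            mismatch_targets_per_guide=20,
            mismatch_counts={1: 1.0},
            class_mix={"transversion": 1.0},
        )
        pairs = build_library(spec, seed=27)
        truth = truth_from_landscape(pairs, lp, background_pct=0.5)
        counts = simulate_counts(pairs, truth, depth=5000, seed=28)
        filtered = apply_filters(merge_replicates(counts))
        passed = filtered[filtered["passed_filters"]]
        ann = annotation_frame(pairs)
        table = specificity_table(passed, ann)
        prof = positionwise_specificity(table).set_index("position_pam")
        from scipy import stats

        truth_spec = {
            p: 1.0 - lp.class_factors["transversion"] * lp.position_factors[p - 1]
            for p in prof.index
        }
        rho = stats.spearmanr(
            prof["mean_specificity"], [truth_spec[p] for p in prof.index]
        )[0]
        assert rho > 0.8


class TestTradeoffAndSelection:
    def test_single_record_point(self, screen):
        pairs, lp, truth, counts, passed, ann = screen
        table = specificity_table(passed, ann)
        points = tradeoff_summary(passed, table, ann)
        assert len(points) == 1
        assert 0 <= points[0].general_specificity <= 1

    def test_two_variants_ordered(self, screen):
        pairs, lp, truth, counts, passed, ann = screen
        table = specificity_table(passed, ann)
        # clone the variant with uniformly halved off-target activity:
        # strictly higher specificity, same activity
        passed_hi = passed.copy()
        passed_hi["variant"] = "HiFi"
        table_hi = table.copy()
        table_hi["variant"] = "HiFi"
        table_hi["specificity"] = 1 - (1 - table_hi["specificity"]) / 2
        points = tradeoff_summary(
            pd.concat([passed, passed_hi]),
            pd.concat([table, table_hi]),
            ann,
        )
        by_name = {p.variant: p for p in points}
        assert (
            by_name["HiFi"].general_specificity
            > by_name["Sniper2L"].general_specificity
        )

    def test_select_comparable_guides_fixture(self):
        """30 comparable + 70 divergent guides at tolerance 5%: exactly
        the 30 selected."""
        rng = np.random.default_rng(31)
        rows = []
        for i in range(100):
            base = rng.uniform(20, 80)
            offset = rng.uniform(0, 4) if i < 30 else rng.uniform(10, 40)
            for variant, val in (("A", base), ("B", base + offset)):
                rows.append(
                    {
                        "guide_id": f"g{i:03d}",
                        "variant": variant,
                        "day": 4,
                        "corrected_pct": val,
                    }
                )
        selected = select_comparable_guides(pd.DataFrame(rows), tolerance=5.0)
        assert selected == [f"g{i:03d}" for i in range(30)]

    def test_tolerance_extremes(self):
        df = pd.DataFrame(
            {
                "guide_id": ["g1", "g1", "g2", "g2"],
                "variant": ["A", "B", "A", "B"],
                "day": 4,
                "corrected_pct": [10.0, 10.0, 10.0, 90.0],
            }
        )
        assert select_comparable_guides(df, tolerance=100.0) == ["g1", "g2"]
        assert select_comparable_guides(df, tolerance=0.0) == ["g1"]

    def test_no_overlap_raises(self):
        df = pd.DataFrame(
            {
                "guide_id": ["g1", "g2"],
                "variant": ["A", "B"],
                "day": 4,
                "corrected_pct": [10.0, 20.0],
            }
        )
        with pytest.raises(SelectionError):
            select_comparable_guides(df, tolerance=5.0)
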