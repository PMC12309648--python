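"""Classification, length-weight conversion, biomass aggregation, pairing."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mpameta.assembly import (
    aggregate_replicate_biomass,
    classify_protection,
    classify_target_status,
    encode_lengths,
    length_to_weight,
    summarize_pairs,
)
from mpameta.exceptions import (
    InvalidArgumentError,
    MissingDataError,
)


class TestClassifyTargetStatus:
    def test_positive_catch_is_targeted(self):
        assert classify_target_status({"A": 1000.0, "B": 0.0}) == {
            "A": "targeted",
            "B": "nontargeted",
        }

    def test_low_volume_bycatch_reclassified(self):
        got = classify_target_status({"A": 5.0, "B": 500.0}, bycatch_threshold=10)
        assert got == {"A": "nontargeted", "B": "targeted"}

    def test_override_wins_for_cryptic_species(self):
        got = classify_target_status({"A": 0.0}, overrides={"A": "targeted"})
        assert got == {"A": "targeted"}

    def test_negative_catch_rejected(self):
        with pytest.raises(InvalidArgumentError):
            classify_target_status({"A": -1.0})


class TestClassifyProtection:
    @pytest.fixture()
    def regulations(self):
        ecos = ["surf_zone", "kelp_forest", "shallow_reef", "deep_reef"]
        rows = []
        for eco in ecos:
            rows.append(("smr1", eco, False, False))  # formal reserve
            rows.append(("salmon_smca", eco, True, False))  # salmon take only
            rows.append(("finfish_smca", eco, True, eco == "kelp_forest"))
        return pd.DataFrame(
            rows,
            columns=["mpa_id", "ecosystem", "allows_take", "take_affects_ecosystem"],
        )

    def test_formal_reserve_is_no_take(self, regulations):
        assert classify_protection("smr1", "kelp_forest", regulations) == "no_take"

    def test_salmon_only_take_is_de_facto_no_take(self, regulations):
        # salmon take cannot affect reef or surf residents
        for eco in ["surf_zone", "kelp_forest", "shallow_reef", "deep_reef"]:
            assert classify_protection("salmon_smca", eco, regulations) == "no_take"

    def test_take_affecting_residents_is_partial(self, regulations):
        assert (
            classify_protection("finfish_smca", "kelp_forest", regulations)
            == "partial_take"
        )
        assert (
            classify_protection("finfish_smca", "surf_zone", regulations) == "no_take"
        )

    def test_missing_row_signals(self, regulations):
        with pytest.raises(MissingDataError):
            classify_protection("ghost", "kelp_forest", regulations)


class TestLengthToWeight:
    @pytest.mark.parametrize(
        "length, a, b, expected",
        [(2, 1, 3, 8.0), (10, 0.01, 3.0, 10.0), (1, 5, 2, 5.0)],
    )
    def test_power_law(self, length, a, b, expected):
        assert length_to_weight(length, a, b) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(0, 1, 3), (2, 0, 3), (2, 1, 0), (-1, 1, 3)])
    def test_nonpositive_inputs_rejected(self, bad):
        with pytest.raises(InvalidArgumentError):
            length_to_weight(*bad)


def make_species(ids, a=1.0, b=3.0, mean_length=2.0):
    return pd.DataFrame(
        {
            "species_id": ids,
            "lw_a": a,
            "lw_b": b,
            "mean_length_cm": mean_length,
        }
    )


def obs_row(replicate, species, count, lengths="", **kw):
    row = {
        "mpa_id": "A",
        "ecosystem": "kelp_forest",
        "year": 2019,
        "side": "inside",
        "replicate_id": replicate,
        "species_id": species,
        "count": count,
        "lengths": lengths,
    }
    row.update(kw)
    return row


class TestAggregateReplicateBiomass:
    def test_single_fish_and_explicit_zero_status(self):
        obs = pd.DataFrame([obs_row("r1", "t1", 1, "2.0")])
        out = aggregate_replicate_biomass(
            obs, make_species(["t1"]), {"t1": "targeted"}
        )
        by_status = out.set_index("status")["biomass"]
        assert by_status["targeted"] == pytest.approx(8.0)
        assert by_status["nontargeted"] == pytest.approx(0.0)

    def test_two_fish_hand_sum(self):
        obs = pd.DataFrame([obs_row("r1", "t1", 2, "2.00;3.00")])
        out = aggregate_replicate_biomass(
            obs, make_species(["t1"]), {"t1": "targeted"}
        )
        assert out.set_index("status")["biomass"]["targeted"] == pytest.approx(35.0)

    def test_empty_replicate_gets_both_zero_rows(self):
        obs = pd.DataFrame([obs_row("r1", "t1", 0)])
        out = aggregate_replicate_biomass(
            obs, make_species(["t1"]), {"t1": "targeted"}
        )
        assert len(out) == 2
        assert (out["biomass"] == 0).all()

    def test_count_without_lengths_uses_mean_length(self):
        obs = pd.DataFrame([obs_row("r1", "t1", 3)])
        out = aggregate_replicate_biomass(
            obs, make_species(["t1"], mean_length=2.0), {"t1": "targeted"}
        )
        assert out.set_index("status")["biomass"]["targeted"] == pytest.approx(24.0)

    def test_unresolvable_species_listed(self):
        obs = pd.DataFrame([obs_row("r1", "mystery", 1, "2.0")])
        with pytest.raises(MissingDataError, match="mystery"):
            aggregate_replicate_biomass(obs, make_species(["t1"]), {"t1": "targeted"})

    def test_length_count_mismatch_rejected(self):
        obs = pd.DataFrame([obs_row("r1", "t1", 3, "2.0;3.0")])
        with pytest.raises(InvalidArgumentError):
            aggregate_replicate_biomass(obs, make_species(["t1"]), {"t1": "targeted"})

    @given(
        st.lists(st.floats(1.0, 50.0), min_size=1, max_size=12),
        st.integers(1, 11),
    )
    @settings(max_examples=50, deadline=None)
    def test_additivity_and_conservation(self, lengths, split_at):
        """Splitting one replicate's fish between two rows conserves biomass,
        and total biomass equals the sum of individual fish weights."""
        split_at = min(split_at, len(lengths))
        first, second = lengths[:split_at], lengths[split_at:]
        species = make_species(["t1"], a=0.02, b=2.9)
        whole = pd.DataFrame(
            [obs_row("r1", "t1", len(lengths), encode_lengths(lengths))]
        )
        rows = [obs_row("r1", "t1", len(first), encode_lengths(first))]
        if second:
            rows.append(obs_row("r1", "t1", len(second), encode_lengths(second)))
        parts = pd.DataFrame(rows)
        status = {"t1": "targeted"}
        total_whole = aggregate_replicate_biomass(whole, species, status)[
            "biomass"
        ].sum()
        total_parts = aggregate_replicate_biomass(parts, species, status)[
            "biomass"
        ].sum()
        by_hand = sum(0.02 * L**2.9 for L in lengths)
        assert total_whole == pytest.approx(total_parts, rel=1e-12)
        assert total_whole == pytest.approx(by_hand, rel=1e-9)

    def test_status_partition(self, surveys, species_frame):
        """Targeted plus nontargeted biomass equals total biomass per replicate."""
        status = {
            s: "targeted" for s in species_frame["species_id"]
        }
        all_targeted = aggregate_replicate_biomass(surveys, species_frame, status)
        split_status = {
            row.species_id: "targeted" if row.targeted_truth else "nontargeted"
            for row in species_frame.itertuples()
        }
        split = aggregate_replicate_biomass(surveys, species_frame, split_status)
        keys = ["mpa_id", "ecosystem", "year", "side", "replicate_id"]
        total_a = all_targeted.groupby(keys)["biomass"].sum()
        total_b = split.groupby(keys)["biomass"].sum()
        pd.testing.assert_series_equal(total_a, total_b, rtol=1e-12)


class TestSummarizePairs:
    def biomass_rows(self, values, side, status="targeted"):
        return [
            {
                "mpa_id": "A",
                "ecosystem": "kelp_forest",
                "year": 2019,
                "side": side,
                "replicate_id": f"{side}{i}",
                "status": status,
                "biomass": v,
            }
            for i, v in enumerate(values)
        ]

    def test_hand_computed_summary(self):
        rb = pd.DataFrame(
            self.biomass_rows([2.0, 4.0], "inside")
            + self.biomass_rows([1.0, 1.0], "outside")
        )
        pairs, excl = summarize_pairs(rb)
        assert excl.empty
        row = pairs.iloc[0]
        assert row["mean_inside"] == pytest.approx(3.0)
        assert row["sd_inside"] == pytest.approx(np.sqrt(2.0))
        assert row["n_inside"] == 2
        assert row["mean_outside"] == pytest.approx(1.0)
        assert row["sd_outside"] == pytest.approx(0.0)

    def test_single_replicate_flagged(self):
        rb = pd.DataFrame(
            self.biomass_rows([2.0], "inside") + self.biomass_rows([1.0, 3.0], "outside")
        )
        pairs, _ = summarize_pairs(rb)
        row = pairs.iloc[0]
        assert row["sd_inside"] == 0.0 and row["sd_undefined"]

    def test_identical_sides_symmetric(self):
        rb = pd.DataFrame(
            self.biomass_rows([1.0, 2.0], "inside")
            + self.biomass_rows([1.0, 2.0], "outside")
        )
        pairs, _ = summarize_pairs(rb)
        assert pairs.iloc[0]["mean_inside"] == pairs.iloc[0]["mean_outside"]

    def test_missing_side_reported_not_dropped_silently(self):
        rb = pd.DataFrame(self.biomass_rows([2.0, 4.0], "inside"))
        pairs, excl = summarize_pairs(rb)
        assert pairs.empty
        assert excl.iloc[0]["reason"] == "missing_side"
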