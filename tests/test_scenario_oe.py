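"""Reference-condition transform, assemblage prediction and the O/E ratio."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oefish import _schema as S
from oefish.errors import ConfigurationError, ConsistencyError, DataError, SchemaError
from oefish.scenario_oe import (
    ScenarioSpec,
    apply_reference_transform,
    compute_oe,
    default_reference_scenario,
    oe_frame,
    predict_assemblage,
    sets_from_frame,
)
from oefish.sdm_engine import fit_species_model
from oefish.synthetic_data import generate_reaches


def test_overlapping_rule_sets_are_rejected():
    with pytest.raises(ConfigurationError):
        ScenarioSpec(set_to={"a": 1.0}, cap_at={"a": 0.5})


def test_yaml_roundtrip(tmp_path):
    spec = default_reference_scenario()
    spec.to_yaml(tmp_path / "ref.yaml")
    loaded = ScenarioSpec.from_yaml(tmp_path / "ref.yaml")
    assert loaded == spec


class TestReferenceTransform:
    def test_nutrient_ceilings_cap_only_where_exceeded(self, small_world):
        _, reaches, _, _ = small_world
        row = reaches.iloc[[0]].copy()
        row[S.NO3N] = 0.25   # above the nitrate ceiling
        row[S.DRP] = 0.01    # above the DRP ceiling
        out = apply_reference_transform(row, default_reference_scenario())
        assert out[S.NO3N].iloc[0] == 0.11
        assert out[S.DRP].iloc[0] == 0.006
        row[S.NO3N] = 0.05   # below the ceiling: untouched
        out = apply_reference_transform(row, default_reference_scenario())
        assert out[S.NO3N].iloc[0] == 0.05

    def test_set_to_and_substitution(self, small_world):
        _, reaches, _, _ = small_world
        out = apply_reference_transform(reaches, default_reference_scenario())
        assert (out[S.US_NATIVE] == 1.0).all()
        assert (out[S.US_PASTURE] == 0.0).all()
        assert (out[S.RIP_NATIVE_PCT] == 100.0).all()
        np.testing.assert_array_equal(out[S.RIP_SHADE], reaches[S.RIP_SHADE_PREHUMAN])

    def test_untouched_columns_identical_and_input_not_mutated(self, small_world):
        _, reaches, _, _ = small_world
        snapshot = reaches.copy(deep=True)
        out = apply_reference_transform(reaches, default_reference_scenario())
        pd.testing.assert_frame_equal(reaches, snapshot)  # no mutation
        spec = default_reference_scenario()
        untouched = [c for c in reaches.columns if c not in spec.columns | set(spec.set_to)]
        pd.testing.assert_frame_equal(out[untouched], reaches[untouched])

    def test_idempotence(self, small_world):
        _, reaches, _, _ = small_world
        spec = default_reference_scenario()
        once = apply_reference_transform(reaches, spec)
        twice = apply_reference_transform(once, spec)
        pd.testing.assert_frame_equal(once, twice)

    def test_missing_companion_column_is_a_schema_error(self, small_world):
        _, reaches, _, _ = small_world
        broken = reaches.drop(columns=[S.RIP_SHADE_PREHUMAN])
        with pytest.raises(SchemaError):
            apply_reference_transform(broken, default_reference_scenario())

    def test_non_numeric_values_are_a_data_error(self, small_world):
        _, reaches, _, _ = small_world
        broken = reaches.copy()
        broken.loc[broken.index[3], S.NO3N] = "high"
        with pytest.raises(DataError):
            apply_reference_transform(broken, default_reference_scenario())

    def test_empty_scenario_is_the_identity(self, small_world):
        _, reaches, _, _ = small_world
        out = apply_reference_transform(reaches, ScenarioSpec())
        pd.testing.assert_frame_equal(out, reaches)


class TestComputeOe:
    def test_forced_arithmetic(self):
        results = compute_oe(
            current_sets={"r": {"a", "b"}},
            reference_sets={"r": {"a", "b", "c", "d"}},
        )
        (res,) = results
        assert res.observed_set == {"a", "b"}
        assert res.ratio == 0.5

    def test_unexpected_species_do_not_count_toward_observed(self):
        (res,) = compute_oe({"r": {"a", "x"}}, {"r": {"a", "b"}})
        assert res.observed_set == {"a"}
        assert res.ratio == 0.5

    def test_empty_expectation_is_undefined(self):
        (res,) = compute_oe({"r": {"a"}}, {"r": set()})
        assert res.ratio is None
        assert res.undefined_reason
        frame = oe_frame([res])
        assert np.isnan(frame.loc["r", "ratio"])

    def test_exotic_species_are_a_contract_violation(self):
        with pytest.raises(ConsistencyError):
            compute_oe({"r": {"trout"}}, {"r": {"trout"}}, exotic_species={"trout"})

    def test_mismatched_reach_sets_are_an_error(self):
        with pytest.raises(ConsistencyError):
            compute_oe({"r1": set()}, {"r2": set()})

    @given(
        st.dictionaries(
            st.integers(0, 20),
            st.tuples(
                st.sets(st.sampled_from("abcdef")),
                st.sets(st.sampled_from("abcdef")),
            ),
            max_size=15,
        )
    )
    def test_observed_is_subset_and_ratio_bounded(self, world):
        current = {r: cur for r, (cur, _) in world.items()}
        reference = {r: ref for r, (_, ref) in world.items()}
        for res in compute_oe(current, reference):
            assert res.observed_set <= res.expected_set
            if res.ratio is not None:
                assert 0.0 <= res.ratio <= 1.0
                assert res.ratio == res.o_count / res.e_count

    def test_null_scenario_identity(self):
        sets = {"r1": {"a", "b"}, "r2": {"c"}, "r3": set()}
        for res in compute_oe(sets, sets):
            if res.e_count > 0:
                assert res.ratio == 1.0
            else:
                assert res.ratio is None


@pytest.fixture(scope="module")
def toy_bundles(fast_brt):
    """Two tiny fitted species over a synthetic reach table."""
    from oefish.synthetic_data import SyntheticConfig

    cfg = SyntheticConfig(n_reaches=400, n_sites=400, n_species=2, seed=19)
    reaches = generate_reaches(cfg)
    rng = np.random.default_rng(2)
    bundles = []
    for i, col in enumerate([S.JAN_AIR_TEMP, S.SEG_SLOPE]):
        x = reaches[col].to_numpy()
        z = (x - x.mean()) / x.std()
        y = (rng.uniform(size=len(z)) < 1 / (1 + np.exp(-3 * z))).astype(int)
        b = fit_species_model(y, reaches, fast_brt, species=f"toy{i}", native=True)
        bundles.append(b.with_threshold(0.5, 0.8))
    return reaches, bundles


class TestPredictAssemblage:
    def test_threshold_is_required(self, toy_bundles, fast_brt):
        reaches, bundles = toy_bundles
        from dataclasses import replace

        bad = replace(bundles[0])
        bad.threshold = None
        with pytest.raises(ConfigurationError):
            predict_assemblage([bad], reaches)

    def test_matches_direct_thresholding(self, toy_bundles):
        from oefish.sdm_engine import predict_probability
        from oefish.threshold_select import call_presence

        reaches, bundles = toy_bundles
        pred = predict_assemblage(bundles, reaches)
        for b in bundles:
            expected = call_presence(
                predict_probability(b, reaches).probabilities, b.threshold
            ).astype(bool)
            np.testing.assert_array_equal(pred.native[b.species].to_numpy(), expected)

    def test_deterministic_and_separates_exotics(self, toy_bundles):
        reaches, bundles = toy_bundles
        bundles = [bundles[0], bundles[1]]
        bundles[1].native = False
        a = predict_assemblage(bundles, reaches)
        b = predict_assemblage(bundles, reaches)
        pd.testing.assert_frame_equal(a.native, b.native)
        assert list(a.native.columns) == ["toy0"]
        assert list(a.exotic.columns) == ["toy1"]
        bundles[1].native = True  # restore shared fixture state

    def test_sets_from_frame_inverts_calls(self, toy_bundles):
        reaches, bundles = toy_bundles
        pred = predict_assemblage(bundles, reaches)
        sets = sets_from_frame(pred.native)
        first = pred.native.index[0]
        assert sets[first] == set(pred.native.columns[pred.native.loc[first]])
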