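"""Pressure attribution, prediction agreement and the NMDS ordination."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from oefish.attribution import fit_attribution, nmds_influences, percent_agreement
from oefish.errors import ConsistencyError, DegenerateTargetError
from oefish.scenario_oe import OEResult
from oefish.sdm_engine import BRTConfig


def _oe(values, index):
    return [
        OEResult(r, frozenset("ab"), frozenset("a"), None if np.isnan(v) else float(v))
        for r, v in zip(index, values)
    ]


@pytest.fixture(scope="module")
def pressure_table():
    rng = np.random.default_rng(31)
    n = 1000
    return pd.DataFrame(
        {
            "no3n": rng.gamma(2.0, 0.2, n),
            "dam": rng.integers(0, 2, n),
            "rip_oe": rng.uniform(0, 1, n),
            "flat": np.ones(n),
        },
        index=[f"r{i}" for i in range(n)],
    )


class TestFitAttribution:
    def test_noiseless_monotone_target_is_recovered(self, pressure_table, fast_brt):
        target = 1.0 / (1.0 + pressure_table["no3n"])  # noiseless, monotone in one pressure
        result = fit_attribution(_oe(target.to_numpy(), pressure_table.index),
                                 pressure_table, fast_brt)
        assert result.cv_correlation > 0.95
        ranked = sorted(result.relative_influence.items(), key=lambda kv: -kv[1])
        assert ranked[0][0] == "no3n"
        assert ranked[0][1] > 50.0
        assert sum(result.relative_influence.values()) == pytest.approx(100.0, abs=1e-6)

    def test_permuted_target_has_no_signal(self, pressure_table, fast_brt):
        rng = np.random.default_rng(8)
        target = rng.permutation(1.0 / (1.0 + pressure_table["no3n"].to_numpy()))
        result = fit_attribution(_oe(target, pressure_table.index), pressure_table, fast_brt)
        assert abs(result.cv_correlation) < 0.15

    def test_constant_pressure_has_zero_influence(self, pressure_table, fast_brt):
        target = 1.0 / (1.0 + pressure_table["no3n"])
        result = fit_attribution(_oe(target.to_numpy(), pressure_table.index),
                                 pressure_table, fast_brt)
        assert result.relative_influence["flat"] == 0.0

    def test_undefined_oe_reaches_never_enter_the_fit(self, pressure_table, fast_brt):
        target = (1.0 / (1.0 + pressure_table["no3n"])).to_numpy()
        target[:100] = np.nan
        result = fit_attribution(_oe(target, pressure_table.index), pressure_table, fast_brt)
        assert result.n_reaches_used == len(pressure_table) - 100

    def test_too_few_reaches_is_an_error(self, pressure_table, fast_brt):
        with pytest.raises(ConsistencyError):
            fit_attribution(_oe(np.ones(30) * 0.5, pressure_table.index[:30]),
                            pressure_table.iloc[:30], fast_brt)

    def test_constant_target_is_degenerate(self, pressure_table, fast_brt):
        with pytest.raises(DegenerateTargetError):
            fit_attribution(_oe(np.full(200, 0.7), pressure_table.index[:200]),
                            pressure_table.iloc[:200], fast_brt)


class TestPercentAgreement:
    def _frames(self, a, b, species=("x", "y")):
        idx = [f"r{i}" for i in range(len(a))]
        return (
            pd.DataFrame(a, index=idx, columns=species),
            pd.DataFrame(b, index=idx, columns=species),
        )

    def test_identity_and_complement(self):
        rng = np.random.default_rng(1)
        calls = rng.integers(0, 2, (50, 2)).astype(bool)
        a, b = self._frames(calls, calls)
        result = percent_agreement(a, b)
        assert (result.per_species == 100.0).all() and result.mean == 100.0
        a, b = self._frames(calls, ~calls)
        assert (percent_agreement(a, b).per_species == 0.0).all()

    def test_counts_matching_reaches(self):
        a_calls = np.zeros((100, 1), dtype=bool)
        b_calls = a_calls.copy()
        b_calls[:7, 0] = True  # 93 of 100 reaches agree
        a, b = self._frames(a_calls, b_calls, species=("x",))
        assert percent_agreement(a, b).per_species["x"] == pytest.approx(93.0)

    def test_symmetric_and_complements_hamming(self):
        rng = np.random.default_rng(6)
        a, b = self._frames(rng.integers(0, 2, (80, 2)), rng.integers(0, 2, (80, 2)))
        ab, ba = percent_agreement(a, b), percent_agreement(b, a)
        pd.testing.assert_series_equal(ab.per_species, ba.per_species)
        hamming = 100.0 * (a.to_numpy() != b.to_numpy()).mean(axis=0)
        np.testing.assert_allclose(ab.per_species.to_numpy(), 100.0 - hamming)

    def test_mismatched_tables_are_an_error(self):
        a, _ = self._frames(np.zeros((5, 2)), np.zeros((5, 2)))
        b = a.iloc[:4]
        with pytest.raises(ConsistencyError):
            percent_agreement(a, b)


def _stub_bundle(name, influence):
    class _B:
        species = name
        relative_influence = influence
        native = True

    return _B()


def _stress1(coords, D):
    """Independent Kruskal stress-1 evaluation of a configuration."""
    iu = np.triu_indices(len(coords), k=1)
    dist = pdist(coords)
    disparity = IsotonicRegression().fit(D[iu], dist).predict(D[iu])
    return np.sqrt(((dist - disparity) ** 2).sum() / (dist**2).sum())


class TestNmds:
    def test_identical_species_have_zero_input_distance(self):
        bundles = [
            _stub_bundle("a", {"t": 60.0, "s": 40.0}),
            _stub_bundle("b", {"t": 60.0, "s": 40.0}),
            _stub_bundle("c", {"t": 10.0, "s": 90.0}),
        ]
        result = nmds_influences(bundles, seed=0)
        D = squareform(pdist(result.input_matrix.to_numpy()))
        assert D[0, 1] == 0.0 and D[0, 2] > 0

    def test_equidistant_triple_embeds_exactly(self):
        bundles = [
            _stub_bundle("a", {"u": 100.0}),
            _stub_bundle("b", {"v": 100.0}),
            _stub_bundle("c", {"w": 100.0}),
        ]
        result = nmds_influences(bundles, seed=0)
        assert result.stress < 1e-3
        d = pdist(result.coordinates.to_numpy())
        assert d.max() / d.min() == pytest.approx(1.0, abs=0.01)

    def test_top_k_truncation(self):
        influence = {f"c{i}": float(i + 1) for i in range(8)}  # c7 largest
        bundles = [_stub_bundle(s, influence) for s in "abc"]
        result = nmds_influences(bundles, k_top=3, seed=0)
        row = result.input_matrix.loc["a"]
        assert (row[["c7", "c6", "c5"]] > 0).all()
        assert (row[["c0", "c1", "c2", "c3", "c4"]] == 0).all()

    def test_stress_competitive_with_reference_solver(self):
        rng = np.random.default_rng(17)
        influence_matrix = rng.uniform(0, 30, (10, 6))
        bundles = [
            _stub_bundle(f"sp{i}", {f"c{j}": float(v) for j, v in enumerate(row)})
            for i, row in enumerate(influence_matrix)
        ]
        result = nmds_influences(bundles, k_top=5, seed=3, n_starts=20)
        D = squareform(pdist(result.input_matrix.to_numpy()))
        reference = MDS(
            n_components=2, metric=False, dissimilarity="precomputed",
            n_init=20, random_state=0, normalized_stress=True, max_iter=500,
        )
        reference.fit(D)
        assert result.stress <= reference.stress_ + 0.02

    def test_stress_is_isometry_invariant(self):
        rng = np.random.default_rng(9)
        bundles = [
            _stub_bundle(f"sp{i}", {f"c{j}": float(v) for j, v in enumerate(row)})
            for i, row in enumerate(rng.uniform(0, 30, (8, 5)))
        ]
        result = nmds_influences(bundles, seed=1)
        D = squareform(pdist(result.input_matrix.to_numpy()))
        base = _stress1(result.coordinates.to_numpy(), D)
        assert base == pytest.approx(result.stress, abs=1e-6)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        transformed = result.coordinates.to_numpy() @ rot * np.array([1, -1]) + 3.5
        assert _stress1(transformed, D) == pytest.approx(base, abs=1e-9)

    def test_dimensionality_guards(self):
        bundles = [_stub_bundle("a", {"u": 1.0}), _stub_bundle("b", {"u": 2.0})]
        with pytest.raises(ValueError):
            nmds_influences(bundles, seed=0)
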