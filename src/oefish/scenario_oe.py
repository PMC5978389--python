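"""Reference-condition scenarios and the observed/expected (O/E) ratio.

A *reference condition* is a declarative near-natural covariate state: some
covariates are overwritten with constants (full native cover, zero pasture),
some are capped only where they exceed a ceiling (nutrient concentrations),
and some are substituted from a companion column (riparian shade under
complete pre-human vegetation).  Predicting species assemblages under both
the current and the reference covariates, and comparing them per reach, gives
the O/E biotic index: the number of species predicted present today *and*
expected under reference conditions, divided by the number expected.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import _schema as S
from .errors import ConfigurationError, ConsistencyError, DataError, SchemaError
from .sdm_engine import SpeciesModelBundle, predict_probability
from .threshold_select import call_presence

__all__ = [
    "ScenarioSpec",
    "OEResult",
    "AssemblagePrediction",
    "default_reference_scenario",
    "apply_reference_transform",
    "predict_assemblage",
    "compute_oe",
    "oe_frame",
    "sets_from_frame",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative covariate overrides defining a scenario.

    Parameters
    ----------
    set_to
        Covariate -> constant; the column is overwritten everywhere.
    cap_at
        Covariate -> ceiling; values are reduced to the ceiling only where
        they exceed it ("where exceeded" semantics — never raised).
    substitute_from
        Covariate -> companion column whose values replace it.
    """

    set_to: dict[str, float] = field(default_factory=dict)
    cap_at: dict[str, float] = field(default_factory=dict)
    substitute_from: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [set(self.set_to), set(self.cap_at), set(self.substitute_from)]
        for i in range(3):
            for j in range(i + 1, 3):
                overlap = keys[i] & keys[j]
                if overlap:
                    raise ConfigurationError(
                        f"scenario covariates appear in more than one rule: {sorted(overlap)}"
                    )

    @property
    def columns(self) -> set[str]:
        """All reach-table columns the scenario reads or writes."""
        return (
            set(self.set_to)
            | set(self.cap_at)
            | set(self.substitute_from)
            | set(self.substitute_from.values())
        )

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(
            set_to={k: float(v) for k, v in (raw.get("set_to") or {}).items()},
            cap_at={k: float(v) for k, v in (raw.get("cap_at") or {}).items()},
            substitute_from=dict(raw.get("substitute_from") or {}),
        )

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "set_to": dict(self.set_to),
                    "cap_at": dict(self.cap_at),
                    "substitute_from": dict(self.substitute_from),
                },
                fh,
                sort_keys=True,
            )


def default_reference_scenario() -> ScenarioSpec:
    """The default near-natural reference state.

    Full native upstream and riparian cover, no pasture, riparian shade at its
    pre-human value, and nutrient concentrations capped at the upper range
    observed in rivers of high ecological health: nitrate-N 0.11 mg/L and
    dissolved reactive phosphorus 0.006 mg/L.
    """
    return ScenarioSpec(
        set_to={S.US_NATIVE: 1.0, S.US_PASTURE: 0.0, S.RIP_NATIVE_PCT: 100.0},
        cap_at={S.NO3N: 0.11, S.DRP: 0.006},
        substitute_from={S.RIP_SHADE: S.RIP_SHADE_PREHUMAN},
    )


def apply_reference_transform(reaches: pd.DataFrame, spec: ScenarioSpec) -> pd.DataFrame:
    """Return a copy of ``reaches`` with the scenario's covariate state applied.

    The input table is never mutated; untouched columns are identical to the
    input.  Capping is idempotent and only ever lowers values.
    """
    missing = spec.columns - set(reaches.columns)
    if missing:
        raise SchemaError(f"scenario refers to absent columns: {sorted(missing)}")

    out = reaches.copy()
    touched = list(spec.set_to) + list(spec.cap_at) + list(spec.substitute_from.values())
    for col in touched:
        if not pd.api.types.is_numeric_dtype(out[col]):
            coerced = pd.to_numeric(out[col], errors="coerce")
            bad = out.index[coerced.isna() & out[col].notna()]
            if len(bad):
                raise DataError(f"non-numeric values in column {col!r} at rows {list(bad[:5])}")
            out[col] = coerced
    for col, value in spec.set_to.items():
        out[col] = float(value)
    for col, ceiling in spec.cap_at.items():
        out[col] = np.minimum(out[col].to_numpy(dtype=float), float(ceiling))
    for col, companion in spec.substitute_from.items():
        out[col] = out[companion].to_numpy()
    return out


@dataclass
class AssemblagePrediction:
    """Thresholded species sets per reach, natives and exotics kept apart."""

    native: pd.DataFrame   # bool, reaches x native species
    exotic: pd.DataFrame   # bool, reaches x exotic species
    excluded: dict         # reach_id -> reason (e.g. out-of-class mask)


def predict_assemblage(
    bundles: list[SpeciesModelBundle], reaches: pd.DataFrame
) -> AssemblagePrediction:
    """Predict the species set of every reach from fitted, thresholded models.

    A species belongs to a reach's set iff its predicted capture probability
    is greater than or equal to its Kappa-optimal threshold.  Reaches outside
    any bundle's retained river classes are excluded with a reason, never
    silently predicted.
    """
    for b in bundles:
        if b.threshold is None:
            raise ConfigurationError(f"bundle for {b.species!r} has no threshold")

    index = reaches.index
    excluded: dict = {}
    calls: dict[str, np.ndarray] = {}
    for b in bundles:
        pred = predict_probability(b, reaches)
        for reach, reason in pred.masked.items():
            excluded.setdefault(reach, reason)
        calls[b.species] = call_presence(pred.probabilities, b.threshold)

    keep = index.difference(pd.Index(excluded), sort=False)
    keep_pos = index.get_indexer(keep)
    native = {b.species: calls[b.species][keep_pos].astype(bool) for b in bundles if b.native}
    exotic = {b.species: calls[b.species][keep_pos].astype(bool) for b in bundles if not b.native}
    return AssemblagePrediction(
        native=pd.DataFrame(native, index=keep),
        exotic=pd.DataFrame(exotic, index=keep),
        excluded=excluded,
    )


@dataclass(frozen=True)
class OEResult:
    """Observed/expected outcome for one reach.

    ``expected_set`` (E) is the species set predicted under reference
    conditions; ``observed_set`` (O) is the present-day predicted set
    restricted to E, so O is a subset of E and the ratio lies in [0, 1].
    When E is empty the ratio is undefined (``None``) with a reason code.
    """

    reach_id: object
    expected_set: frozenset
    observed_set: frozenset
    ratio: float | None
    undefined_reason: str | None = None

    @property
    def e_count(self) -> int:
        return len(self.expected_set)

    @property
    def o_count(self) -> int:
        return len(self.observed_set)


def compute_oe(
    current_sets: dict,
    reference_sets: dict,
    exotic_species: set | frozenset = frozenset(),
) -> list[OEResult]:
    """Per-reach O/E from present-day and reference species sets.

    Species present today but *not* expected under reference conditions do
    not count toward O; exotic species must not appear in either input.
    """
    if set(current_sets) != set(reference_sets):
        raise ConsistencyError("current and reference sets cover different reaches")
    exotic = set(exotic_species)
    results = []
    for reach in reference_sets:
        expected = frozenset(reference_sets[reach])
        current = frozenset(current_sets[reach])
        bad = (expected | current) & exotic
        if bad:
            raise ConsistencyError(f"exotic species {sorted(bad)} in O/E input at reach {reach}")
        observed = current & expected
        if expected:
            results.append(OEResult(reach, expected, observed, len(observed) / len(expected)))
        else:
            results.append(OEResult(reach, expected, observed, None, "no species expected (E=0)"))
    return results


def oe_frame(results: list[OEResult]) -> pd.DataFrame:
    """Tabulate O/E results (one row per reach; undefined ratios are NaN)."""
    return pd.DataFrame(
        {
            "reach_id": [r.reach_id for r in results],
            "e_count": [r.e_count for r in results],
            "o_count": [r.o_count for r in results],
            "ratio": [np.nan if r.ratio is None else r.ratio for r in results],
            "flag": [r.undefined_reason or "" for r in results],
        }
    ).set_index("reach_id")


def sets_from_frame(calls: pd.DataFrame) -> dict:
    """Boolean reach x species table -> {reach_id: set of species present}."""
    cols = np.asarray(calls.columns)
    values = calls.to_numpy(dtype=bool)
    return {reach: set(cols[row]) for reach, row in zip(calls.index, values)}
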