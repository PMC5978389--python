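"""Synthetic river network, fish survey records, and ground truth.

Real inputs for an O/E fish indicator are a national reach database with
environmental covariates and a survey database of electric-fishing records.
Neither is bundled here; this module generates stand-ins with the statistical
structure the analysis assumes, plus the ground truth those stand-ins were
drawn from, so every downstream stage can be tested end to end:

* a reach table with correlated geographic/climatic covariates and an
  anthropogenic gradient (pasture, nutrients, riparian loss, downstream
  dams), including the pre-human riparian shade companion column the
  reference scenario substitutes in;
* per-species occurrence-probability functions — logistic in a handful of
  covariates with a quadratic temperature optimum and one pairwise
  interaction, with anthropogenic suppression entering through pasture,
  nutrient-excess, riparian-loss and dam terms scaled by a single
  ``impact_strength`` knob (0 = pristine world, true O/E = 1 wherever E > 0);
* a survey table with the record structure the filter stage expects (year,
  month, method, surveyed reach length, repeat visits), where a configurable
  fraction of records violate each filter rule;
* a truth-side O/E oracle computed from the true probabilities.

The generator has no spatial topology: reaches are exchangeable rows whose
covariates are correlated through latent gradients, which is the structure
the models consume.  Detection is a single multiplicative probability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _schema as S
from .errors import ConfigurationError, ConsistencyError
from .scenario_oe import ScenarioSpec, apply_reference_transform, default_reference_scenario

__all__ = [
    "SyntheticConfig",
    "SpeciesTruth",
    "TruthTable",
    "generate_reaches",
    "make_truth",
    "generate_surveys",
    "true_oe",
    "bayes_auc",
    "write_synthetic_dataset",
]

# Scales that turn raw anthropogenic covariates into O(1) pressure terms.
_NO3N_CEILING, _NO3N_SCALE = 0.11, 0.5
_DRP_CEILING, _DRP_SCALE = 0.006, 0.02
_SHADE_MAX = 0.8

# Range of the per-species response-sharpness multiplier (separability regime).
SHARPNESS_RANGE = (1.2, 3.5)

_GEN_FLAGS = ["_gen_pre2000", "_gen_off_season", "_gen_non_electric", "_gen_short_reach"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic world.

    ``n_covariates`` counts additional uninformative noise covariates
    appended to the core environmental set (the models should learn to
    ignore them).  ``impact_strength`` scales anthropogenic suppression of
    occurrence; ``detection_prob`` multiplies the true occurrence probability
    when survey presences are drawn.  ``class_labels`` assigns river classes
    by the given mixing proportions.
    """

    n_reaches: int = 2000
    n_sites: int = 1500
    n_species: int = 8
    n_covariates: int = 3
    impact_strength: float = 1.0
    detection_prob: float = 1.0
    seed: int = 42
    class_labels: tuple[tuple[str, float], ...] = (
        ("A", 0.40),
        ("C", 0.30),
        ("G", 0.20),
        ("H", 0.10),
    )
    # Fractions of survey records violating each filter rule, and of sites
    # with repeat visits.
    frac_pre2000: float = 0.08
    frac_off_season: float = 0.08
    frac_non_electric: float = 0.08
    frac_short_reach: float = 0.08
    frac_repeat_sites: float = 0.15

    def __post_init__(self) -> None:
        if self.n_reaches < 1 or self.n_sites < 1 or self.n_species < 1:
            raise ConfigurationError("n_reaches, n_sites and n_species must be positive")
        if self.n_covariates < 0:
            raise ConfigurationError("n_covariates must be nonnegative")
        if self.n_sites > self.n_reaches:
            raise ConfigurationError("n_sites must not exceed n_reaches")
        if self.impact_strength < 0:
            raise ConfigurationError("impact_strength must be nonnegative")
        if not 0 < self.detection_prob <= 1:
            raise ConfigurationError("detection_prob must lie in (0, 1]")
        props = [p for _, p in self.class_labels]
        if not props or any(p < 0 for p in props) or abs(sum(props) - 1.0) > 1e-9:
            raise ConfigurationError("class mixing proportions must be nonnegative and sum to 1")
        for name in (
            "frac_pre2000",
            "frac_off_season",
            "frac_non_electric",
            "frac_short_reach",
            "frac_repeat_sites",
        ):
            if not 0 <= getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must lie in [0, 1)")


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def generate_reaches(cfg: SyntheticConfig) -> pd.DataFrame:
    """One row per reach, covariates correlated through two latent gradients.

    A geographic gradient (inland/upland) drives slope, temperature, flood
    frequency and distance to coast; a development gradient, concentrated in
    the lowlands, drives pasture (hence nutrients), riparian loss and dams.
    Pasture and native cover are negatively correlated by construction and
    nutrients rise with pasture.  Deterministic given the seed.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_reaches

    upland = rng.beta(1.6, 1.6, n)                         # 0 = coastal lowland, 1 = headwater
    develop = np.clip(0.55 * (1 - upland) + 0.45 * rng.beta(2.0, 2.0, n), 0, 1)

    pasture = np.clip(0.95 * develop + rng.normal(0, 0.12, n), 0, 1)
    other_cover = rng.beta(1.0, 10.0, n)
    native = np.clip(1.0 - pasture - other_cover, 0, 1)

    no3n = np.clip(0.02 + 1.2 * pasture**1.3 * np.exp(rng.normal(0, 0.35, n)), 0, 5.54)
    drp = np.clip(0.002 + 0.02 * pasture * np.exp(rng.normal(0, 0.4, n)), 0, 0.10)

    rip_native = np.clip(100.0 * (1.0 - develop * rng.beta(5, 2, n)) + rng.normal(0, 5, n), 0, 100)
    shade_prehuman = _SHADE_MAX * rng.beta(6, 2, n)
    shade = shade_prehuman * np.clip(0.25 + 0.75 * rip_native / 100 + rng.normal(0, 0.05, n), 0, 1)

    dam = (rng.random(n) < np.clip(0.05 + 0.30 * develop, 0, 1)).astype(int)

    slope = np.clip(np.exp(rng.normal(0, 0.9, n)) * (0.2 + 3.0 * upland), 0, 29.7)
    temp = np.clip(19.8 - 7.0 * upland + rng.normal(0, 1.2, n), 0, 19.8)
    flood = np.clip(1.8 + rng.gamma(3.0, 3.0, n) * (0.5 + upland), 0, 39.0)
    dist_coast = np.clip(432.8 * upland**2.5 * np.exp(rng.normal(0, 0.3, n)), 0.01, 432.8)

    labels = [name for name, _ in cfg.class_labels]
    props = np.asarray([p for _, p in cfg.class_labels], dtype=float)
    river_class = rng.choice(labels, size=n, p=props / props.sum())

    frame = pd.DataFrame(
        {
            S.REACH_ID: [f"R{i:05d}" for i in range(n)],
            S.RIVER_CLASS: river_class,
            S.US_NATIVE: native,
            S.US_PASTURE: pasture,
            S.RIP_NATIVE_PCT: rip_native,
            S.RIP_SHADE: shade,
            S.RIP_SHADE_PREHUMAN: shade_prehuman,
            S.NO3N: no3n,
            S.DRP: drp,
            S.DS_DAM: dam,
            S.SEG_SLOPE: slope,
            S.JAN_AIR_TEMP: temp,
            S.FLOOD_FREQ: flood,
            S.DIST_COAST: dist_coast,
        }
    )
    for j in range(cfg.n_covariates):
        frame[f"noise_{j}"] = rng.normal(0, 1, n)
    return frame.set_index(S.REACH_ID)


@dataclass(frozen=True)
class SpeciesTruth:
    """One species' true occurrence-probability function.

    The linear predictor combines standardised natural covariates (always
    including a quadratic January-air-temperature optimum and one pairwise
    interaction) minus ``impact_strength`` times a nonnegative-weighted sum of
    anthropogenic pressure terms.  For native species every pressure weight is
    nonnegative, so the response is monotonically non-increasing in each
    anthropogenic covariate and the reference transform can only raise the
    probability.  Exotic species get the opposite sign (they benefit from
    degradation); they never enter the O/E.
    """

    name: str
    native: bool
    intercept: float
    linear: dict[str, float]          # standardised natural covariate -> coefficient
    quad_center_z: float              # temperature optimum on the z-scale
    quad_strength: float
    interaction: tuple[str, str, float]
    impact: dict[str, float]          # pressure channel -> nonnegative weight
    scaler: dict[str, tuple[float, float]]  # covariate -> (mean, std)
    sharpness: float = 1.0            # scales the natural linear predictor; higher = more separable

    def probability(self, reaches: pd.DataFrame, impact_strength: float) -> np.ndarray:
        z = {
            c: (reaches[c].to_numpy(dtype=float) - m) / s for c, (m, s) in self.scaler.items()
        }
        lp = np.zeros(len(reaches))
        for cov, coef in self.linear.items():
            lp += coef * z[cov]
        zt = z[S.JAN_AIR_TEMP]
        lp -= self.quad_strength * (zt - self.quad_center_z) ** 2
        a, b, coef = self.interaction
        lp += coef * z[a] * z[b]
        lp = self.intercept + self.sharpness * lp

        pressure = np.zeros(len(reaches))
        get = lambda col: reaches[col].to_numpy(dtype=float)
        weights = self.impact
        if "pasture" in weights:
            pressure += weights["pasture"] * get(S.US_PASTURE)
        if "no3n" in weights:
            pressure += weights["no3n"] * np.maximum(get(S.NO3N) - _NO3N_CEILING, 0) / _NO3N_SCALE
        if "drp" in weights:
            pressure += weights["drp"] * np.maximum(get(S.DRP) - _DRP_CEILING, 0) / _DRP_SCALE
        if "dam" in weights:
            pressure += weights["dam"] * get(S.DS_DAM)
        if "rip_loss" in weights:
            pressure += weights["rip_loss"] * (1.0 - get(S.RIP_NATIVE_PCT) / 100.0)
        if "shade_loss" in weights:
            pressure += weights["shade_loss"] * (_SHADE_MAX - get(S.RIP_SHADE)) / _SHADE_MAX
        sign = 1.0 if self.native else -1.0
        return _sigmoid(lp - sign * impact_strength * pressure)


@dataclass
class TruthTable:
    """Ground truth for one synthetic world.

    Per reach and species: true current occurrence probability, true
    reference probability (the same response function evaluated on the
    reference-transformed covariates), and Bernoulli presence draws under
    each state.  ``oe_true`` is the truth-side O/E oracle at 0.5 thresholds.
    """

    species: list[SpeciesTruth]
    scenario: ScenarioSpec
    impact_strength: float
    current_prob: pd.DataFrame
    reference_prob: pd.DataFrame
    current_draw: pd.DataFrame
    reference_draw: pd.DataFrame
    oe_true: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        for frame in (self.current_prob, self.reference_prob):
            v = frame.to_numpy()
            if v.min() < 0 or v.max() > 1:
                raise ValueError("truth probabilities must lie in [0, 1]")
        self.oe_true = true_oe(self, thresholds=0.5)

    @property
    def species_names(self) -> list[str]:
        return [sp.name for sp in self.species]

    @property
    def native_names(self) -> list[str]:
        return [sp.name for sp in self.species if sp.native]

    @property
    def exotic_names(self) -> list[str]:
        return [sp.name for sp in self.species if not sp.native]


# Per-channel sensitivity ranges, set so that at impact_strength = 1 the
# majority of reaches deviate from their reference assemblage (O/E < 1) and
# the true O/E spreads broadly over [0, 1] — the regime an O/E indicator is
# designed for, rather than a mostly-intact world.
_PRESSURE_RANGES = {
    "pasture": (1.6, 4.0),
    "no3n": (1.0, 3.0),
    "drp": (0.6, 2.0),
    "dam": (1.0, 4.0),
    "rip_loss": (0.6, 2.0),
    "shade_loss": (0.4, 1.2),
}


def make_truth(
    reaches: pd.DataFrame,
    cfg: SyntheticConfig,
    scenario: ScenarioSpec | None = None,
) -> TruthTable:
    """Draw species response functions and evaluate truth over the reaches.

    Roughly a quarter of the species (at least one when there are four or
    more) are exotic.  Intercepts are calibrated so current prevalence lands
    in a realistic 0.25-0.60 band.  The reference probabilities are obtained
    by applying the scenario transform to the reach table and re-evaluating
    the same response functions.
    """
    scenario = scenario if scenario is not None else default_reference_scenario()
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    natural_pool = [S.SEG_SLOPE, S.FLOOD_FREQ, S.DIST_COAST]
    scale_cols = [S.JAN_AIR_TEMP] + natural_pool
    scaler = {
        c: (float(reaches[c].mean()), float(reaches[c].std(ddof=0)) or 1.0) for c in scale_cols
    }

    n_exotic = cfg.n_species // 4 if cfg.n_species >= 4 else 0
    species: list[SpeciesTruth] = []
    reference_reaches = apply_reference_transform(reaches, scenario)
    for i in range(cfg.n_species):
        native = i < cfg.n_species - n_exotic
        n_extra = int(rng.integers(1, len(natural_pool) + 1))
        extra = list(rng.choice(natural_pool, size=n_extra, replace=False))
        linear = {S.JAN_AIR_TEMP: float(rng.uniform(0.3, 1.0) * rng.choice([-1, 1]))}
        for cov in extra:
            linear[cov] = float(rng.uniform(0.6, 1.6) * rng.choice([-1, 1]))
        active = list(linear)
        a, b = rng.choice(active, size=2, replace=False) if len(active) >= 2 else (active[0],) * 2
        interaction = (str(a), str(b), float(rng.uniform(0.3, 0.8) * rng.choice([-1, 1])))

        channels = [c for c in _PRESSURE_RANGES if rng.random() < 0.7]
        if not channels:
            channels = [str(rng.choice(list(_PRESSURE_RANGES)))]
        impact = {c: float(rng.uniform(*_PRESSURE_RANGES[c])) for c in channels}

        sp = SpeciesTruth(
            name=f"sp{i + 1:02d}",
            native=native,
            intercept=0.0,
            linear=linear,
            quad_center_z=float(rng.uniform(-1.0, 1.0)),
            quad_strength=float(rng.uniform(0.3, 1.0)),
            interaction=interaction,
            impact=impact,
            scaler=scaler,
            sharpness=float(rng.uniform(*SHARPNESS_RANGE)),
        )
        # Calibrate the intercept against the *reference* world so natives are
        # broadly expected there: the species that survive the prevalence rule
        # are by construction the common ones, and common native fish are
        # expected across most of the network under reference conditions (the
        # O/E design premise — reference assemblages are rich, deviation from
        # them is impact-driven).  Current prevalence then falls wherever the
        # impact terms put it.
        target = float(rng.uniform(0.75, 0.95))
        raw = np.clip(
            sp.probability(reference_reaches, cfg.impact_strength), 1e-9, 1 - 1e-9
        )
        raw_lp = np.log(raw / (1 - raw))
        intercept = float(np.log(target / (1 - target)) - np.median(raw_lp))
        sp = SpeciesTruth(**{**sp.__dict__, "intercept": intercept})
        species.append(sp)

    current = pd.DataFrame(
        {sp.name: sp.probability(reaches, cfg.impact_strength) for sp in species},
        index=reaches.index,
    )
    reference = pd.DataFrame(
        {sp.name: sp.probability(reference_reaches, cfg.impact_strength) for sp in species},
        index=reaches.index,
    )
    draw_rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    current_draw = (draw_rng.random(current.shape) < current.to_numpy()).astype(int)
    reference_draw = (draw_rng.random(reference.shape) < reference.to_numpy()).astype(int)
    return TruthTable(
        species=species,
        scenario=scenario,
        impact_strength=cfg.impact_strength,
        current_prob=current,
        reference_prob=reference,
        current_draw=pd.DataFrame(current_draw, index=current.index, columns=current.columns),
        reference_draw=pd.DataFrame(
            reference_draw, index=reference.index, columns=reference.columns
        ),
    )


def generate_surveys(
    reaches: pd.DataFrame, truth: TruthTable, cfg: SyntheticConfig
) -> pd.DataFrame:
    """Survey records with presences drawn from the truth.

    ``n_sites`` reaches are sampled without replacement; a fraction of sites
    receive repeat visits, and each record independently violates each filter
    rule (pre-2000 year, off-season month, non-electric method, short reach)
    with its configured probability.  Presence of each species is Bernoulli
    (true current probability x detection probability), drawn independently
    per record.  Generator-side ``_gen_*`` flag columns record which
    violations were injected; the ingest stage ignores them.
    """
    missing = truth.current_prob.index.difference(reaches.index)
    if len(missing) or len(truth.current_prob.index) != len(reaches.index):
        raise ConsistencyError("truth table does not cover the reach table")

    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    site_reaches = rng.choice(reaches.index.to_numpy(), size=cfg.n_sites, replace=False)

    rows = []
    for s_idx, reach in enumerate(site_reaches):
        n_records = 1
        if rng.random() < cfg.frac_repeat_sites:
            n_records += int(rng.integers(1, 3))
        for _ in range(n_records):
            pre2000 = rng.random() < cfg.frac_pre2000
            off_season = rng.random() < cfg.frac_off_season
            non_electric = rng.random() < cfg.frac_non_electric
            short_reach = rng.random() < cfg.frac_short_reach
            year = int(rng.integers(1985, 2000) if pre2000 else rng.integers(2000, 2018))
            month = int(rng.choice([4, 5, 6, 7, 8, 9, 10, 11]) if off_season else rng.choice([12, 1, 2, 3]))
            method = str(rng.choice(["net", "trap"])) if non_electric else "efi"
            length = float(rng.uniform(20, 149) if short_reach else rng.uniform(150, 500))
            probs = truth.current_prob.loc[reach].to_numpy() * cfg.detection_prob
            presence = (rng.random(len(probs)) < probs).astype(int)
            rows.append(
                {
                    S.SITE_ID: f"S{s_idx:05d}",
                    S.REACH_ID: reach,
                    S.DATE: f"{year:04d}-{month:02d}-{int(rng.integers(1, 29)):02d}",
                    S.METHOD: method,
                    S.REACH_LENGTH_M: round(length, 1),
                    "_gen_pre2000": pre2000,
                    "_gen_off_season": off_season,
                    "_gen_non_electric": non_electric,
                    "_gen_short_reach": short_reach,
                    **dict(zip(truth.current_prob.columns, presence)),
                }
            )
    return pd.DataFrame(rows)


def true_oe(truth: TruthTable, thresholds) -> pd.Series:
    """Truth-side O/E oracle: the pipeline's counting rules on true probabilities.

    ``thresholds`` is a scalar or a per-species mapping in [0, 1].  Native
    species only; E from reference probabilities, O from the intersection of
    current and reference calls; NaN where E = 0.
    """
    natives = truth.native_names
    if np.isscalar(thresholds):
        thr = {sp: float(thresholds) for sp in natives}
    else:
        thr = {sp: float(thresholds[sp]) for sp in natives}
    bad = [sp for sp, t in thr.items() if not 0 <= t <= 1]
    if bad:
        raise ValueError(f"thresholds outside [0, 1] for {bad}")

    thr_vec = np.array([thr[sp] for sp in natives])
    ref = truth.reference_prob[natives].to_numpy() >= thr_vec
    cur = truth.current_prob[natives].to_numpy() >= thr_vec
    e = ref.sum(axis=1)
    o = (ref & cur).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ratio = np.where(e > 0, o / np.maximum(e, 1), np.nan)
    return pd.Series(ratio, index=truth.reference_prob.index, name="oe_true")


def bayes_auc(probs) -> float:
    """Separability ceiling of a Bernoulli generating process.

    For labels drawn as Bernoulli(q_i) and scored by q_i itself (the Bayes
    score), returns P(score_pos > score_neg) + 0.5 P(tie) over a random
    positive/negative pair — the large-sample AUC an ideal model could reach
    on this site set.  Sorting-based, O(n log n).
    """
    q = np.asarray(probs, dtype=float)
    if q.size == 0 or q.min() < 0 or q.max() > 1:
        raise ValueError("probs must be a nonempty array within [0, 1]")
    total_pos = q.sum()
    total_neg = (1 - q).sum()
    if total_pos == 0 or total_neg == 0:
        raise ValueError("degenerate process: one class has zero mass")
    values, inverse = np.unique(q, return_inverse=True)
    pos_mass = np.bincount(inverse, weights=q)
    neg_mass = np.bincount(inverse, weights=1 - q)
    neg_below = np.concatenate([[0.0], np.cumsum(neg_mass)[:-1]])
    wins = (pos_mass * neg_below).sum()
    ties = (pos_mass * neg_mass).sum()
    return float((wins + 0.5 * ties) / (total_pos * total_neg))


def write_synthetic_dataset(out_dir, cfg: SyntheticConfig) -> dict[str, Path]:
    """Generate and write reach, survey and truth tables as CSV (+ config YAML)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reaches = generate_reaches(cfg)
    truth = make_truth(reaches, cfg)
    surveys = generate_surveys(reaches, truth, cfg)

    paths = {
        "reaches": out / "reaches.csv",
        "surveys": out / "surveys.csv",
        "truth_current_prob": out / "truth_current_prob.csv",
        "truth_reference_prob": out / "truth_reference_prob.csv",
        "truth_oe": out / "truth_oe.csv",
        "config": out / "synthetic_config.yaml",
    }
    reaches.to_csv(paths["reaches"])
    surveys.to_csv(paths["surveys"], index=False)
    truth.current_prob.to_csv(paths["truth_current_prob"])
    truth.reference_prob.to_csv(paths["truth_reference_prob"])
    truth.oe_true.to_csv(paths["truth_oe"])
    with open(paths["config"], "w") as fh:
        yaml.safe_dump(
            {
                **{k: getattr(cfg, k) for k in cfg.__dataclass_fields__ if k != "class_labels"},
                "class_labels": [[name, prop] for name, prop in cfg.class_labels],
                "species": [
                    {"name": sp.name, "native": sp.native} for sp in truth.species
                ],
            },
            fh,
            sort_keys=False,
        )
    return paths
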