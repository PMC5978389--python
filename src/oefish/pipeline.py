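"""End-to-end orchestration: ingest -> fit -> threshold -> scenario -> O/E -> attribution.

One :class:`RunConfig` fixes everything about a run: input tables (or a
synthetic generator configuration), the filter parameters, the boosting
regime, the reference scenario, and a single global seed that is fanned out
to per-stage seeds by stable hashing so each stage is independently
reproducible.  The run writes plain delimited text and JSON only, and ends
with a manifest recording configuration hash, seeds, stage row counts, model
summaries and output digests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _schema as S
from .attribution import fit_attribution, nmds_influences
from .errors import ConfigurationError, UnfittableSpeciesError
from .scenario_oe import (
    ScenarioSpec,
    apply_reference_transform,
    compute_oe,
    default_reference_scenario,
    oe_frame,
    predict_assemblage,
    sets_from_frame,
)
from .sdm_engine import BRTConfig, fit_species_model
from .survey_ingest import (
    MIN_REACH_LENGTH_M,
    MIN_YEAR,
    SUMMER_MONTHS,
    class_filter,
    collinearity_screen,
    filter_surveys,
    load_surveys,
    prevalence_filter,
    records_from_frame,
)
from .synthetic_data import SyntheticConfig, generate_reaches, generate_surveys, make_truth
from .threshold_select import select_threshold

__all__ = ["RunConfig", "run_pipeline", "stage_seed", "demo_config"]


def stage_seed(global_seed: int, stage: str) -> int:
    """Stable per-stage seed below 2**31, derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    Either ``reaches_path``/``surveys_path`` point at CSV tables (with
    ``species``/``exotic_species`` naming the survey presence columns), or
    ``synthetic`` requests generation.  Filter defaults are the standard
    regime: year >= 2000, summer months (Dec-Mar), electric fishing,
    >= 150 m of surveyed reach, species at >= 150 sites, classes with
    >= 1,000 survey sites.
    """

    out_dir: Path
    synthetic: SyntheticConfig | None = None
    reaches_path: Path | None = None
    surveys_path: Path | None = None
    species: list[str] | None = None
    exotic_species: list[str] = field(default_factory=list)
    brt: BRTConfig = field(default_factory=BRTConfig)
    scenario: ScenarioSpec = field(default_factory=default_reference_scenario)
    min_year: int = MIN_YEAR
    months: frozenset = SUMMER_MONTHS
    min_reach_length: float = MIN_REACH_LENGTH_M
    min_species_sites: int = 150
    min_class_sites: int = 1000
    grid_step: float = 0.005
    seed: int = 0
    run_attribution: bool = True
    run_nmds: bool = True

    def config_hash(self) -> str:
        def default(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return dataclasses.asdict(obj)
            if isinstance(obj, (frozenset, set)):
                return sorted(obj)
            if isinstance(obj, Path):
                return str(obj)
            raise TypeError(type(obj))

        payload = dataclasses.asdict(self)
        payload.pop("out_dir", None)  # where outputs land is not semantic config
        return hashlib.sha256(
            json.dumps(payload, default=default, sort_keys=True).encode()
        ).hexdigest()[:16]


def demo_config(out_dir, seed: int = 42, scale: float = 1.0) -> RunConfig:
    """The demo world: 2,000 reaches, 8 species, strong anthropogenic gradient.

    Filter thresholds for species prevalence and class sample size are scaled
    to the demo's site count (150 presence sites and 150 class sites at
    ~1,500 surveyed sites) so the filters bind without emptying the dataset.
    ``scale`` shrinks the world proportionally for quick smoke runs.
    """
    n_reaches = max(50, int(2000 * scale))
    cfg = SyntheticConfig(
        n_reaches=n_reaches,
        n_sites=n_reaches,
        n_species=8,
        seed=seed,
    )
    return RunConfig(
        out_dir=Path(out_dir),
        synthetic=cfg,
        brt=BRTConfig(seed=stage_seed(seed, "brt")),
        min_species_sites=max(10, int(150 * scale)),
        min_class_sites=max(10, int(150 * scale)),
        seed=seed,
    )


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute every stage in order and return the run manifest.

    Any stage failure propagates as an exception naming the stage via its
    message; outputs written before the failure are flagged stale in no
    manifest (the manifest is only written on success).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": cfg.config_hash(),
        "global_seed": cfg.seed,
        "stages": {},
        "outputs": {},
    }

    # -- stage 1: inputs ---------------------------------------------------
    if cfg.synthetic is not None:
        reaches = generate_reaches(cfg.synthetic)
        truth = make_truth(reaches, cfg.synthetic)
        surveys_frame = generate_surveys(reaches, truth, cfg.synthetic)
        species = truth.species_names
        exotic = set(truth.exotic_names)
        reaches.to_csv(out / "reaches.csv")
        surveys_frame.to_csv(out / "surveys.csv", index=False)
        records = records_from_frame(surveys_frame, species)
    else:
        if cfg.reaches_path is None or cfg.surveys_path is None:
            raise ConfigurationError("need reaches_path and surveys_path (or a synthetic config)")
        for p in (cfg.reaches_path, cfg.surveys_path):
            if not Path(p).exists():
                raise ConfigurationError(f"input file not found: {p}")
        if not cfg.species:
            raise ConfigurationError("species columns must be named for file inputs")
        reaches = pd.read_csv(cfg.reaches_path).set_index(S.REACH_ID)
        records = load_surveys(cfg.surveys_path, cfg.species)
        species = list(cfg.species)
        exotic = set(cfg.exotic_species)
        truth = None
    manifest["stages"]["inputs"] = {"n_reaches": len(reaches), "n_survey_records": len(records)}

    # -- stage 2: record filters ------------------------------------------
    filter_seed = stage_seed(cfg.seed, "site_dedup")
    retained, record_report = filter_surveys(
        records,
        seed=filter_seed,
        min_year=cfg.min_year,
        months=cfg.months,
        min_reach_length=cfg.min_reach_length,
    )
    modelled_species, species_report = prevalence_filter(retained, cfg.min_species_sites)
    classes, class_report = class_filter(retained, reaches, cfg.min_class_sites)
    class_set = set(classes)
    retained = [r for r in retained if str(reaches.loc[r.reach_id, S.RIVER_CLASS]) in class_set]
    reaches_in_class = reaches[reaches[S.RIVER_CLASS].astype(str).isin(class_set)]
    manifest["stages"]["filters"] = {
        "records": record_report.to_dict(),
        "species": species_report.to_dict(),
        "classes": class_report.to_dict(),
        "n_training_sites": len(retained),
        "n_reaches_in_class": len(reaches_in_class),
        "seed": filter_seed,
    }
    reports = {
        "records": record_report.to_dict(),
        "species": species_report.to_dict(),
        "classes": class_report.to_dict(),
    }
    (out / "filter_report.json").write_text(json.dumps(reports, indent=1))

    screen = collinearity_screen(reaches_in_class, covariates=None)
    screen.r.to_csv(out / "collinearity_r.csv")
    screen.p.to_csv(out / "collinearity_p.csv")

    # -- stage 3: per-species BRT fits + thresholds ------------------------
    train_sites = pd.DataFrame(
        {
            "site_reach": [r.reach_id for r in retained],
            **{sp: [int(sp in r.presence) for r in retained] for sp in modelled_species},
        }
    )
    X_train = reaches_in_class.loc[train_sites["site_reach"]]
    bundles = []
    skipped = {}
    for sp in modelled_species:
        y = train_sites[sp].to_numpy()
        try:
            bundle = fit_species_model(
                y,
                X_train,
                dataclasses.replace(cfg.brt, seed=stage_seed(cfg.seed, f"fit:{sp}")),
                species=sp,
                native=sp not in exotic,
                allowed_classes=class_set,
            )
        except UnfittableSpeciesError as exc:
            skipped[sp] = str(exc)
            continue
        pred = bundle.ensemble.predict(
            X_train[bundle.feature_names].to_numpy(dtype=float), num_iteration=bundle.n_trees
        )
        thr = select_threshold(y, np.clip(pred, 0, 1), grid_step=cfg.grid_step, species=sp)
        bundle = bundle.with_threshold(thr.threshold, thr.kappa)
        bundles.append(bundle)

    models_dir = out / "models"
    for b in bundles:
        b.save(models_dir)
    summary = pd.DataFrame(
        {
            "species": [b.species for b in bundles],
            "native": [b.native for b in bundles],
            "cv_auc": [b.cv_auc for b in bundles],
            "n_trees": [b.n_trees for b in bundles],
            "learning_rate": [b.learning_rate for b in bundles],
            "threshold": [b.threshold for b in bundles],
            "kappa": [b.kappa_at_threshold for b in bundles],
            "prevalence": [b.prevalence for b in bundles],
        }
    ).set_index("species")
    summary.to_csv(out / "model_summary.csv")
    manifest["stages"]["models"] = {
        "fitted": summary.reset_index().to_dict(orient="records"),
        "skipped": skipped,
    }

    # -- stage 4: scenario predictions and O/E -----------------------------
    reference_reaches = apply_reference_transform(reaches_in_class, cfg.scenario)
    current_pred = predict_assemblage(bundles, reaches_in_class)
    reference_pred = predict_assemblage(bundles, reference_reaches)
    oe = compute_oe(
        sets_from_frame(current_pred.native),
        sets_from_frame(reference_pred.native),
        exotic_species=exotic,
    )
    oe_table = oe_frame(oe)
    oe_table.to_csv(out / "oe.csv")
    long_rows = [
        {"reach_id": r.reach_id, "species": sp, "role": role}
        for r in oe
        for role, members in (("expected", r.expected_set), ("observed", r.observed_set))
        for sp in sorted(members)
    ]
    pd.DataFrame(long_rows, columns=["reach_id", "species", "role"]).to_csv(
        out / "oe_species_long.csv", index=False
    )
    defined = oe_table["ratio"].notna()
    manifest["stages"]["oe"] = {
        "n_reaches": len(oe_table),
        "n_defined": int(defined.sum()),
        "mean_ratio": float(oe_table.loc[defined, "ratio"].mean()) if defined.any() else None,
    }

    # -- stage 5: attribution + ordination --------------------------------
    if cfg.run_attribution:
        pressures = pd.DataFrame(
            {
                S.DS_DAM: reaches_in_class[S.DS_DAM],
                S.NO3N: reaches_in_class[S.NO3N],
                S.DRP: reaches_in_class[S.DRP],
                "rip_oe": reaches_in_class[S.RIP_NATIVE_PCT] / 100.0,
            },
            index=reaches_in_class.index,
        )
        for sp in current_pred.exotic.columns:
            pressures[f"exotic_{sp}"] = current_pred.exotic[sp].astype(int)
        attribution = fit_attribution(
            oe,
            pressures,
            dataclasses.replace(cfg.brt, seed=stage_seed(cfg.seed, "attribution")),
        )
        attr_payload = {
            "cv_correlation": attribution.cv_correlation,
            "relative_influence": attribution.relative_influence,
            "n_reaches_used": attribution.n_reaches_used,
            "n_trees": attribution.n_trees,
            "learning_rate": attribution.learning_rate,
        }
        (out / "attribution.json").write_text(json.dumps(attr_payload, indent=1))
        manifest["stages"]["attribution"] = attr_payload

    if cfg.run_nmds and len(bundles) >= 3:
        ordination = nmds_influences(bundles, seed=stage_seed(cfg.seed, "nmds"))
        ordination.coordinates.to_csv(out / "nmds_coordinates.csv")
        manifest["stages"]["nmds"] = {"stress": ordination.stress}

    for path in sorted(out.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            manifest["outputs"][str(path.relative_to(out))] = _digest(path)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
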