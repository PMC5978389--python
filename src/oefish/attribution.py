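"""Attribution of O/E to anthropogenic pressures, prediction agreement, NMDS.

Once a per-reach O/E index exists, the natural follow-up questions are:
which human pressures explain the deviations (a boosted-tree regression of
O/E on pressure covariates, summarised by a cross-validated correlation and
relative influences); how well do two independent sets of predicted
distributions agree (per-species percent agreement); and how do species
group by the environmental variables that drive them (non-metric
multidimensional scaling of their top influence vectors).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import pearsonr
from sklearn.isotonic import IsotonicRegression

from .errors import ConsistencyError, DegenerateTargetError
from .scenario_oe import OEResult
from .sdm_engine import BRTConfig, SpeciesModelBundle, _fit_boosted, _relative_influence

__all__ = [
    "AttributionResult",
    "OrdinationResult",
    "AgreementResult",
    "fit_attribution",
    "percent_agreement",
    "nmds_influences",
]


@dataclass
class AttributionResult:
    """BRT regression of O/E on pressures.

    ``cv_correlation`` is the Pearson correlation between pooled out-of-fold
    predictions and the O/E values; ``relative_influence`` each pressure's
    percentage share of total loss reduction (sums to 100).
    """

    cv_correlation: float
    relative_influence: dict[str, float]
    n_reaches_used: int
    n_trees: int
    learning_rate: float


def fit_attribution(
    oe: list[OEResult], pressures: pd.DataFrame, cfg: BRTConfig
) -> AttributionResult:
    """Model defined-O/E reaches against pressure covariates.

    Reaches with undefined O/E (no species expected) never enter the fit.
    The boosting regime is the same as for the occurrence models but with
    squared-error loss, since O/E is continuous.
    """
    defined = {r.reach_id: r.ratio for r in oe if r.ratio is not None}
    index = pressures.index.intersection(pd.Index(defined), sort=False)
    if len(index) < 50:
        raise ConsistencyError(
            f"attribution needs >= 50 defined-O/E reaches with pressures (got {len(index)})"
        )
    y = np.asarray([defined[r] for r in index], dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateTargetError("O/E is constant across reaches; nothing to attribute")
    X_df = pressures.loc[index].select_dtypes(include=[np.number])
    X = X_df.to_numpy(dtype=float)

    booster, n_trees, lr, oof, _folds, _log = _fit_boosted(X, y, cfg, "regression")
    r = float(pearsonr(oof, y).statistic)
    return AttributionResult(
        cv_correlation=r,
        relative_influence=_relative_influence(booster, list(X_df.columns)),
        n_reaches_used=len(index),
        n_trees=n_trees,
        learning_rate=lr,
    )


@dataclass
class AgreementResult:
    per_species: pd.Series  # percent agreement in [0, 100]
    mean: float


def percent_agreement(set_a: pd.DataFrame, set_b: pd.DataFrame) -> AgreementResult:
    """Per-species percent agreement between two reach x species call tables.

    100 x (matching reaches / total reaches) per species, plus the
    across-species mean.  Symmetric, and equal to 100 minus the per-species
    Hamming percentage.
    """
    if not set_a.index.equals(set_b.index) or list(set_a.columns) != list(set_b.columns):
        raise ConsistencyError("prediction tables must share reach index and species columns")
    if len(set_a) == 0:
        raise ConsistencyError("empty prediction tables")
    match = set_a.to_numpy(dtype=bool) == set_b.to_numpy(dtype=bool)
    per_species = pd.Series(100.0 * match.mean(axis=0), index=set_a.columns)
    return AgreementResult(per_species=per_species, mean=float(per_species.mean()))


@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame  # species x dims
    stress: float              # Kruskal stress-1 of the best start
    input_matrix: pd.DataFrame  # species x covariate (top-k influences, others 0)


def _kruskal_nmds(D: np.ndarray, dims: int, rng: np.random.Generator, n_iter: int = 300,
                  tol: float = 1e-7) -> tuple[np.ndarray, float]:
    """One NMDS run: SMACOF updates against monotone-regressed disparities.

    Alternates an isotonic regression of configuration distances on the
    input dissimilarities (producing disparities that respect their rank
    order) with a Guttman-transform update of the configuration.  Kruskal
    stress-1 = sqrt(sum((d_ij - dhat_ij)^2) / sum(d_ij^2)) is tracked and the
    iteration stops as soon as it fails to improve, so the reported stress is
    non-increasing across iterations.
    """
    n = D.shape[0]
    iu = np.triu_indices(n, k=1)
    delta = D[iu]
    X = rng.normal(scale=delta.mean() or 1.0, size=(n, dims))
    iso = IsotonicRegression(increasing=True, out_of_bounds="clip")
    best_stress = np.inf
    best_X = X.copy()
    for _ in range(n_iter):
        dist = pdist(X)
        disparity = iso.fit(delta, dist).predict(delta)
        denom = (dist**2).sum()
        stress = np.sqrt(((dist - disparity) ** 2).sum() / denom) if denom > 0 else 0.0
        if stress >= best_stress - tol:
            if stress < best_stress:
                best_stress, best_X = stress, X.copy()
            break
        best_stress, best_X = stress, X.copy()
        # Guttman transform toward the disparities
        dist_safe = np.where(dist <= 1e-12, 1e-12, dist)
        ratio = squareform(disparity / dist_safe)
        B = -ratio
        np.fill_diagonal(B, ratio.sum(axis=1))
        X = B @ X / n
    return best_X, float(best_stress)


def nmds_influences(
    bundles: list[SpeciesModelBundle],
    k_top: int = 5,
    dims: int = 2,
    seed: int = 0,
    n_starts: int = 20,
) -> OrdinationResult:
    """Ordinate species by their most influential environmental variables.

    Each species contributes its ``k_top`` largest relative influences (all
    other covariates set to 0); Euclidean distances between these vectors are
    embedded in ``dims`` dimensions by NMDS minimising Kruskal stress-1, best
    of ``n_starts`` seeded random starts.  Coordinates are identifiable only
    up to rotation/reflection/translation.
    """
    if len(bundles) < 3:
        raise ValueError("NMDS needs at least 3 species")
    if len(bundles) < dims + 1:
        raise ValueError(f"{len(bundles)} species cannot span {dims} dimensions")
    covariates = sorted({c for b in bundles for c in b.relative_influence})
    matrix = pd.DataFrame(0.0, index=[b.species for b in bundles], columns=covariates)
    for b in bundles:
        top = sorted(b.relative_influence.items(), key=lambda kv: -kv[1])[:k_top]
        for cov, val in top:
            matrix.loc[b.species, cov] = val

    D = squareform(pdist(matrix.to_numpy()))
    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float] | None = None
    for _ in range(n_starts):
        X, stress = _kruskal_nmds(D, dims, rng)
        if best is None or stress < best[1]:
            best = (X, stress)
    coords, stress = best
    return OrdinationResult(
        coordinates=pd.DataFrame(
            coords, index=matrix.index, columns=[f"nmds{i + 1}" for i in range(dims)]
        ),
        stress=stress,
        input_matrix=matrix,
    )
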