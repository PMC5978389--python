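"""Survey ingest, record filtering, and the collinearity screen.

The analysis set is built from raw survey records by a fixed sequence of
filters: keep records sampled from 2000 onward, during the summer window
(December through March inclusive), by electric fishing, over at least 150 m
of reach; then keep exactly one record per site (chosen uniformly at random,
keyed by site id so the choice is order-independent); then keep species
present at >= 150 distinct sites and river classes holding >= 1,000 survey
sites.  Every removal is accounted for in a :class:`FilterReport` so that
removed + retained always reconciles with the input.
"""

from __future__ import annotations

import datetime as dt
import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _schema as S
from .errors import ConsistencyError

__all__ = [
    "SurveyRecord",
    "FilterReport",
    "records_from_frame",
    "load_surveys",
    "filter_surveys",
    "prevalence_filter",
    "class_filter",
    "collinearity_screen",
    "CollinearityReport",
]

SUMMER_MONTHS = frozenset({12, 1, 2, 3})
MIN_YEAR = 2000
MIN_REACH_LENGTH_M = 150.0


@dataclass(frozen=True)
class SurveyRecord:
    """One sampling event; ``date`` is None when the raw value was unparseable."""

    site_id: str
    reach_id: str
    date: dt.date | None
    method: str
    reach_length_m: float
    presence: frozenset

    @property
    def electric(self) -> bool:
        return self.method.strip().lower() in S.ELECTRIC_METHODS


@dataclass
class FilterReport:
    """Audit trail for one filter stage: input = retained + sum(removed)."""

    stage: str
    n_input: int
    removed: dict[str, int] = field(default_factory=dict)
    n_retained: int = 0
    details: dict = field(default_factory=dict)

    @property
    def conserved(self) -> bool:
        return self.n_input == self.n_retained + sum(self.removed.values())

    def to_dict(self) -> dict:
        return {
            "stage": self.stage,
            "n_input": self.n_input,
            "removed": dict(self.removed),
            "n_retained": self.n_retained,
            "details": self.details,
        }


def _parse_date(value) -> dt.date | None:
    if isinstance(value, dt.date):
        return value
    try:
        return dt.date.fromisoformat(str(value).strip()[:10])
    except ValueError:
        return None


def records_from_frame(frame: pd.DataFrame, species_columns: list[str]) -> list[SurveyRecord]:
    """Build records from a survey table; unknown columns are ignored."""
    missing = [c for c in S.SURVEY_FIELDS if c not in frame.columns]
    if missing:
        raise ConsistencyError(f"survey table lacks columns: {missing}")
    missing_sp = [c for c in species_columns if c not in frame.columns]
    if missing_sp:
        raise ConsistencyError(f"survey table lacks species columns: {missing_sp}")
    records = []
    for row in frame.itertuples(index=False):
        r = row._asdict()
        present = frozenset(sp for sp in species_columns if int(r[sp]) == 1)
        records.append(
            SurveyRecord(
                site_id=str(r[S.SITE_ID]),
                reach_id=str(r[S.REACH_ID]),
                date=_parse_date(r[S.DATE]),
                method=str(r[S.METHOD]),
                reach_length_m=float(r[S.REACH_LENGTH_M]),
                presence=present,
            )
        )
    return records


def load_surveys(path, species_columns: list[str]) -> list[SurveyRecord]:
    """Read a delimited survey table (CSV, or TSV by .tsv extension)."""
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    return records_from_frame(pd.read_csv(path, sep=sep), species_columns)


def _site_choice(seed: int, site_id: str, n: int) -> int:
    """Deterministic uniform choice among a site's records, order-independent."""
    digest = hashlib.sha256(f"{seed}:{site_id}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % n


def filter_surveys(
    records: list[SurveyRecord],
    seed: int,
    min_year: int = MIN_YEAR,
    months: frozenset = SUMMER_MONTHS,
    min_reach_length: float = MIN_REACH_LENGTH_M,
) -> tuple[list[SurveyRecord], FilterReport]:
    """Apply the record filters, then deduplicate to one record per site.

    Rules are applied in a fixed order (unparseable date, pre-``min_year``,
    off-season, non-electric method, short reach) and a record is charged to
    the first rule it violates.  Per site, the retained record is chosen
    uniformly at random from the site's surviving records, keyed by
    (seed, site id), so the result does not depend on input order.
    """
    report = FilterReport(stage="record_filters", n_input=len(records))
    removed = {k: 0 for k in ("bad_date", "pre_year", "off_season", "non_electric", "short_reach", "duplicate_site")}
    passing: list[SurveyRecord] = []
    for rec in records:
        if rec.date is None:
            removed["bad_date"] += 1
        elif rec.date.year < min_year:
            removed["pre_year"] += 1
        elif rec.date.month not in months:
            removed["off_season"] += 1
        elif not rec.electric:
            removed["non_electric"] += 1
        elif rec.reach_length_m < min_reach_length:
            removed["short_reach"] += 1
        else:
            passing.append(rec)

    by_site: dict[str, list[SurveyRecord]] = {}
    for rec in passing:
        by_site.setdefault(rec.site_id, []).append(rec)
    retained: list[SurveyRecord] = []
    for site_id in sorted(by_site):
        group = sorted(
            by_site[site_id],
            key=lambda r: (r.date.isoformat(), r.reach_id, r.reach_length_m, r.method, tuple(sorted(r.presence))),
        )
        keep = group[_site_choice(seed, site_id, len(group))]
        retained.append(keep)
        removed["duplicate_site"] += len(group) - 1

    report.removed = removed
    report.n_retained = len(retained)
    report.details = {"n_sites": len(by_site), "seed": seed}
    return retained, report


def prevalence_filter(
    records: list[SurveyRecord], min_sites: int = 150
) -> tuple[list[str], FilterReport]:
    """Species present at >= ``min_sites`` distinct sites (counting sites, not records)."""
    sites_per_species: dict[str, set] = {}
    for rec in records:
        for sp in rec.presence:
            sites_per_species.setdefault(sp, set()).add(rec.site_id)
    counts = {sp: len(sites) for sp, sites in sites_per_species.items()}
    kept = sorted(sp for sp, c in counts.items() if c >= min_sites)
    dropped = sorted(sp for sp in counts if sp not in kept)
    report = FilterReport(
        stage="species_prevalence",
        n_input=len(counts),
        removed={"below_min_sites": len(dropped)},
        n_retained=len(kept),
        details={"site_counts": counts, "removed_species": dropped, "min_sites": min_sites},
    )
    if not records:
        report.details["warning"] = "no survey records supplied"
    return kept, report


def class_filter(
    records: list[SurveyRecord], reaches: pd.DataFrame, min_sites: int = 1000
) -> tuple[list[str], FilterReport]:
    """River classes holding >= ``min_sites`` survey sites.

    Model fitting and all downstream prediction are restricted to the
    retained classes, so over-extrapolation into unsurveyed environments is
    avoided.
    """
    unknown = sorted({r.reach_id for r in records} - set(reaches.index.astype(str)))
    if unknown:
        raise ConsistencyError(f"survey records reference unknown reaches: {unknown[:5]}")
    reach_class = reaches[S.RIVER_CLASS].astype(str)
    sites_per_class: dict[str, set] = {}
    for rec in records:
        sites_per_class.setdefault(reach_class.loc[rec.reach_id], set()).add(rec.site_id)
    counts = {c: len(s) for c, s in sites_per_class.items()}
    kept = sorted(c for c, n in counts.items() if n >= min_sites)
    report = FilterReport(
        stage="river_classes",
        n_input=len(counts),
        removed={"below_min_sites": len(counts) - len(kept)},
        n_retained=len(kept),
        details={"site_counts": counts, "min_sites": min_sites},
    )
    return kept, report


@dataclass
class CollinearityReport:
    """Pairwise Pearson screen; a report only — no variables are removed."""

    r: pd.DataFrame
    p: pd.DataFrame
    flagged: list[str]  # zero-variance covariates whose pairs are undefined


def collinearity_screen(
    reaches: pd.DataFrame, covariates: list[str] | None = None
) -> CollinearityReport:
    """Pearson r and two-sided p for every covariate pair.

    Symmetric with unit diagonal; zero-variance covariates yield NaN for
    their pairs and are flagged rather than raising.
    """
    cols = covariates or [c for c in reaches.columns if pd.api.types.is_numeric_dtype(reaches[c])]
    data = reaches[cols].astype(float)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    flagged = [c for c in cols if np.nanstd(data[c].to_numpy()) == 0]
    for i in range(k):
        for j in range(i + 1, k):
            pair = data[[cols[i], cols[j]]].dropna()
            if cols[i] in flagged or cols[j] in flagged or len(pair) < 3:
                r[i, j] = r[j, i] = np.nan
                p[i, j] = p[j, i] = np.nan
                continue
            res = stats.pearsonr(pair[cols[i]], pair[cols[j]])
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
    for i, c in enumerate(cols):
        if c in flagged:
            r[i, i] = np.nan
    return CollinearityReport(
        r=pd.DataFrame(r, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        flagged=flagged,
    )
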