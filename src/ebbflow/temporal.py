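"""Pseudo-autocorrelation of community dissimilarity over tidal time steps.

For one site, the chronologically first sampling event is the reference.
Time step 0 collects all pairwise Bray–Curtis dissimilarities among the
reference event's replicates; step t >= 1 collects all (reference replicate,
event-t replicate) cross pairs. If the community is stable over tides, every
step's distribution should look like step 0; a water-mass changeover shows up
as a step whose dissimilarities jump well above the reference level. Each
step carries the event-level covariate changes (salinity delta, hours since
reference, tidal changes elapsed) for the companion rank tests and linear
models.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from skbio import DistanceMatrix

from .io_core import SampleMetadata, ValidationError

__all__ = ["TimeStep", "TimestepSeries", "timestep_series", "kruskal_steps",
           "dissimilarity_model"]


@dataclass(frozen=True)
class TimeStep:
    step: int
    event_id: str
    values: tuple[float, ...]  # Bray–Curtis pairs
    d_salinity: float  # event mean minus reference mean (ppt)
    d_time_hours: float
    tidal_changes: int

    def median(self) -> float:
        return float(np.median(self.values)) if self.values else float("nan")


@dataclass(frozen=True)
class TimestepSeries:
    site_id: str
    steps: tuple[TimeStep, ...]  # step 0 first, then by event timestamp

    def to_json_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "steps": [
                {"step": s.step, "event_id": s.event_id,
                 "values": list(s.values), "d_salinity": s.d_salinity,
                 "d_time_hours": s.d_time_hours,
                 "tidal_changes": s.tidal_changes,
                 "median": s.median()}
                for s in self.steps
            ],
        }


def timestep_series(dist: DistanceMatrix, metadata: SampleMetadata,
                    site_id: str) -> TimestepSeries:
    """Build the per-site time-step series from a replicate distance matrix."""
    ids = set(dist.ids)
    meta = metadata.records
    site = meta[(meta["site_id"] == site_id) & (meta["role"] == "field")]
    site = site.loc[[r for r in site.index if r in ids]]
    if site.empty:
        raise ValidationError(f"no replicates of site {site_id!r} in the matrix")
    event_times = site.groupby("event_id")["timestamp"].min().sort_values(
        kind="stable")
    events = list(event_times.index)
    if len(events) < 2:
        raise ValidationError(f"site {site_id!r} has fewer than 2 events")
    reps_by_event = {e: list(site.index[site["event_id"] == e]) for e in events}
    ref = events[0]
    ref_reps = reps_by_event[ref]
    ref_sal = float(pd.to_numeric(site.loc[ref_reps, "salinity_ppt"]).mean())
    ref_time = event_times.iloc[0]
    tide_seq = [site.loc[reps_by_event[e][0], "tide_direction"] for e in events]

    steps = [TimeStep(
        step=0, event_id=ref,
        values=tuple(float(dist[a, b])
                     for a, b in itertools.combinations(ref_reps, 2)),
        d_salinity=0.0, d_time_hours=0.0, tidal_changes=0,
    )]
    for t, event in enumerate(events[1:], start=1):
        reps = reps_by_event[event]
        sal = float(pd.to_numeric(site.loc[reps, "salinity_ppt"]).mean())
        dt = (event_times[event] - ref_time).total_seconds() / 3600.0
        changes = sum(
            1 for a, b in zip(tide_seq[:t], tide_seq[1:t + 1]) if a != b
        )
        steps.append(TimeStep(
            step=t, event_id=event,
            values=tuple(float(dist[a, b]) for a in ref_reps for b in reps),
            d_salinity=sal - ref_sal, d_time_hours=dt, tidal_changes=changes,
        ))
    return TimestepSeries(site_id=site_id, steps=tuple(steps))


def kruskal_steps(series: TimestepSeries) -> dict:
    """Omnibus Kruskal–Wallis across steps plus each step vs. step 0.

    Tie-corrected H with a chi-square reference; steps with fewer than two
    values are skipped with a warning.
    """
    groups = {s.step: list(s.values) for s in series.steps}
    usable = {t: v for t, v in groups.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValidationError("need >= 2 steps with >= 2 values each")
    skipped = sorted(set(groups) - set(usable))
    if skipped:
        warnings.warn(f"skipping step(s) with < 2 values: {skipped}", stacklevel=2)
    out: dict = {"omnibus": _kruskal(list(usable.values())), "steps": {}}
    if 0 in usable:
        for t in sorted(usable):
            if t == 0:
                continue
            out["steps"][t] = _kruskal([usable[0], usable[t]])
    return out


def _kruskal(groups: list[list[float]]) -> dict:
    concat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(concat) == 0:  # identical values: no evidence, H = 0
        return {"statistic": 0.0, "p_value": 1.0}
    h, p = stats.kruskal(*groups)
    return {"statistic": float(h), "p_value": float(p)}


def dissimilarity_model(series: TimestepSeries) -> pd.DataFrame:
    """OLS of pair-level dissimilarity on |salinity change| and time since
    reference, with intercept. Returns a coefficient table with columns
    estimate / std_error / t_value (NaN rows for predictors dropped as
    constant)."""
    if len(series.steps) < 3:
        raise ValidationError("need >= 3 steps with covariates")
    rows = []
    for s in series.steps:
        for v in s.values:
            rows.append((v, abs(s.d_salinity), s.d_time_hours))
    df = pd.DataFrame(rows, columns=["dissimilarity", "abs_d_salinity",
                                     "d_time_hours"])
    predictors = []
    dropped = []
    for name in ("abs_d_salinity", "d_time_hours"):
        if df[name].nunique() > 1:
            predictors.append(name)
        else:
            dropped.append(name)
            warnings.warn(
                f"predictor {name!r} is constant; coefficient undefined",
                stacklevel=2,
            )
    if not predictors:
        raise ValidationError("all predictors constant")
    x = sm.add_constant(df[predictors])
    fit = sm.OLS(df["dissimilarity"], x).fit()
    table = pd.DataFrame({
        "estimate": fit.params, "std_error": fit.bse, "t_value": fit.tvalues,
    })
    for name in dropped:
        table.loc[name] = [np.nan, np.nan, np.nan]
    return table
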