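"""Association tests between community identity and the sampling design.

Community labels are carried at the sampling-event level (each event's
majority label): Fisher's exact test against geographic site, a Pearson
chi-square against tidal direction, and logistic regressions against tidal
height and against the water-mass covariates (salinity, temperature). The
covariate model is expected to separate completely on realistic data — fresh
cold water carries community 2 — so separation is detected and flagged, not
treated as a failure.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_core import SampleMetadata, ValidationError
from .ordination import CommunityAssignment

__all__ = [
    "LogisticFit",
    "AssociationReport",
    "fisher_exact",
    "chisq_test",
    "logistic_model",
    "community_association_report",
]


# ---------------------------------------------------------------------------
# Fisher's exact test for 2 x K tables


def _log_choose(n: int, k: int) -> float:
    return math.lgamma(n + 1) - math.lgamma(k + 1) - math.lgamma(n - k + 1)


def fisher_exact(contingency) -> float:
    """Exact conditional p-value for a 2 x K integer table.

    Enumerates every table with the observed margins; the two-sided p-value
    sums the probabilities of tables no more probable than the observed one
    (probability-mass ordering, the convention of the classical test).
    """
    obs = np.asarray(contingency, dtype=np.int64)
    if obs.ndim != 2 or obs.shape[0] != 2 or obs.shape[1] < 2:
        raise ValidationError("contingency must be 2 x K with K >= 2")
    if (obs < 0).any():
        raise ValidationError("counts must be non-negative")
    row = obs.sum(axis=1)
    col = obs.sum(axis=0)
    if (row == 0).any() or (col == 0).any():
        warnings.warn("a margin is zero; p = 1", stacklevel=2)
        return 1.0
    n, r1 = int(obs.sum()), int(row[0])
    log_denom = _log_choose(n, r1)

    def table_logp(top: tuple[int, ...]) -> float:
        return sum(_log_choose(int(c), a) for c, a in zip(col, top)) - log_denom

    logp_obs = table_logp(tuple(obs[0]))
    cut = logp_obs + 1e-7  # tolerate round-off in "no more probable"

    total = 0.0
    k = len(col)

    def recurse(j: int, remaining: int, acc: float) -> None:
        nonlocal total
        if j == k - 1:
            if 0 <= remaining <= col[j]:
                logp = acc + _log_choose(int(col[j]), remaining) - log_denom
                if logp <= cut:
                    total += math.exp(logp)
            return
        lo = max(0, remaining - int(col[j + 1:].sum()))
        hi = min(int(col[j]), remaining)
        for a in range(lo, hi + 1):
            recurse(j + 1, remaining - a, acc + _log_choose(int(col[j]), a))

    recurse(0, r1, 0.0)
    return min(1.0, float(total))


def chisq_test(contingency, correction: bool = False) -> tuple[float, int, float]:
    """Pearson chi-square for a contingency table (no continuity correction
    by default); returns (statistic, df, p)."""
    obs = np.asarray(contingency, dtype=float)
    if obs.ndim != 2 or (obs < 0).any():
        raise ValidationError("contingency must be a non-negative 2-d table")
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected == 0).any():
        raise ValidationError(
            "a zero expected cell; use Fisher's exact test instead"
        )
    diff = np.abs(obs - expected)
    if correction:
        diff = np.maximum(0.0, diff - 0.5)
    stat = float((diff ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return stat, df, float(stats.chi2.sf(stat, df))


# ---------------------------------------------------------------------------
# logistic regression with separation handling


@dataclass(frozen=True)
class LogisticFit:
    params: pd.Series
    std_errors: pd.Series
    null_deviance: float
    deviance: float
    separated: bool
    converged: bool
    n_iter: int

    def to_json_dict(self) -> dict:
        return {
            "params": {k: float(v) for k, v in self.params.items()},
            "std_errors": {k: float(v) for k, v in self.std_errors.items()},
            "null_deviance": self.null_deviance,
            "deviance": self.deviance,
            "separated": self.separated,
            "converged": self.converged,
        }


def _bernoulli_deviance(y: np.ndarray, mu: np.ndarray) -> float:
    mu = np.clip(mu, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log1p(-mu)))


def logistic_model(response, predictors, max_iter: int = 100,
                   tol: float = 1e-10) -> LogisticFit:
    """Maximum-likelihood logit fit by iteratively reweighted least squares.

    ``predictors`` is a mapping name -> vector (or a DataFrame); an intercept
    is always included. Complete separation (residual deviance collapsing
    toward zero under capped iterations) sets ``separated`` instead of
    raising.
    """
    y = np.asarray(response, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValidationError("response must be binary 0/1")
    if y.min() == y.max():
        raise ValidationError("response is constant; nothing to model")
    xdf = pd.DataFrame(predictors)
    if xdf.shape[1] == 0:
        xdf = pd.DataFrame(index=range(len(y)))  # intercept-only fit
    if len(xdf) != len(y):
        raise ValidationError("response/predictor length mismatch")
    names = ["intercept", *xdf.columns.astype(str)]
    x = np.column_stack([np.ones(len(y)), xdf.to_numpy(dtype=float)])

    beta = np.zeros(x.shape[1])
    dev = _bernoulli_deviance(y, np.full_like(y, 0.5))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = x @ beta
        mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
        w = np.clip(mu * (1 - mu), 1e-12, None)
        z = eta + (y - mu) / w
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(x * sw[:, None], z * sw, rcond=None)
        dev_new = _bernoulli_deviance(y, 1.0 / (1.0 + np.exp(
            -np.clip(x @ beta_new, -35, 35))))
        step = np.max(np.abs(beta_new - beta))
        beta = beta_new
        if abs(dev - dev_new) < tol and step < 1e-8:
            dev = dev_new
            converged = True
            break
        dev = dev_new

    mu = 1.0 / (1.0 + np.exp(-np.clip(x @ beta, -35, 35)))
    w = np.clip(mu * (1 - mu), 1e-12, None)
    xtwx = (x * w[:, None]).T @ x
    try:
        cov = np.linalg.pinv(xtwx)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:  # pragma: no cover
        se = np.full(len(beta), np.nan)
    p_null = y.mean()
    null_dev = _bernoulli_deviance(y, np.full_like(y, p_null))
    separated = dev < 1e-6
    return LogisticFit(
        params=pd.Series(beta, index=names),
        std_errors=pd.Series(se, index=names),
        null_deviance=null_dev,
        deviance=float(min(dev, null_dev)),
        separated=bool(separated),
        converged=bool(converged or separated),
        n_iter=it,
    )


# ---------------------------------------------------------------------------
# event-level report


@dataclass(frozen=True)
class AssociationReport:
    fisher_site_p: float
    site_table: pd.DataFrame
    chisq_tide: tuple[float, int, float] | None
    logistic_height: LogisticFit | None
    logistic_covariates: LogisticFit | None

    def to_json_dict(self) -> dict:
        return {
            "fisher_site_p": self.fisher_site_p,
            "site_table": self.site_table.to_dict(),
            "chisq_tide": None if self.chisq_tide is None else {
                "statistic": self.chisq_tide[0], "df": self.chisq_tide[1],
                "p_value": self.chisq_tide[2]},
            "logistic_height": None if self.logistic_height is None
            else self.logistic_height.to_json_dict(),
            "logistic_covariates": None if self.logistic_covariates is None
            else self.logistic_covariates.to_json_dict(),
        }


def community_association_report(assignment: CommunityAssignment,
                                 metadata: SampleMetadata) -> AssociationReport:
    """Run the three community-association tests at the sampling-event level."""
    if assignment.event_labels is None:
        raise ValidationError("assignment lacks event-level labels "
                              "(pass metadata to assign_communities)")
    events = assignment.event_labels
    meta = metadata.records[metadata.records["role"] == "field"]
    ev = meta.groupby("event_id").agg(
        site_id=("site_id", "first"),
        tide_direction=("tide_direction", "first"),
        tidal_height_m=("tidal_height_m", "mean"),
        salinity_ppt=("salinity_ppt", "mean"),
        temperature_c=("temperature_c", "mean"),
    ).loc[events.index]
    labels = events.to_numpy()

    site_table = pd.crosstab(labels, ev["site_id"])
    site_table = site_table.reindex([1, 2], fill_value=0)
    fisher_p = fisher_exact(site_table.to_numpy())

    chisq = None
    if len(np.unique(labels)) > 1 and ev["tide_direction"].nunique() > 1:
        tide_table = pd.crosstab(labels, ev["tide_direction"]).reindex(
            [1, 2], fill_value=0)
        chisq = chisq_test(tide_table.to_numpy())

    y = (labels == 2).astype(float)
    height_fit = covar_fit = None
    if 0 < y.sum() < len(y):
        height_fit = logistic_model(y, {"tidal_height_m":
                                        ev["tidal_height_m"].to_numpy()})
        cov = ev[["salinity_ppt", "temperature_c"]].copy()
        ok = cov.notna().all(axis=1).to_numpy()
        if ok.sum() >= 4 and 0 < y[ok].sum() < ok.sum():
            covar_fit = logistic_model(
                y[ok],
                {"salinity_ppt": cov["salinity_ppt"].to_numpy()[ok],
                 "temperature_c": cov["temperature_c"].to_numpy()[ok]},
            )
    return AssociationReport(
        fisher_site_p=fisher_p,
        site_table=site_table,
        chisq_tide=chisq,
        logistic_height=height_fit,
        logistic_covariates=covar_fit,
    )
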