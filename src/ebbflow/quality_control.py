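"""Three-step decontamination chain and rarefaction for OTU count tables.

The chain, in the order it is meant to be run:

1. **Occupancy filter** — treat the PCR replicates of each water sample
   (bottle) as repeated detection trials and fit, per OTU, a two-component
   false-positive occupancy mixture: with probability psi a sample is truly
   occupied and each replicate detects with probability ``p11``; otherwise
   detections are false positives occurring with probability ``p10``
   (``p11 >= p10``). OTUs whose best sample-level conditional occupancy
   probability falls below a threshold (default 0.80) are discarded —
   this removes rare spurious OTUs whose scattered detections look like
   contamination rather than occupancy.
2. **Contamination subtraction** — the positive-control replicates estimate,
   per OTU, the maximum proportional representation attributable to
   cross-sample leakage (tag jumping); that proportion is subtracted from
   every field replicate in proportion space, flooring at zero.
3. **Discordant-replicate drop** — within each bottle, replicates whose
   Bray–Curtis dissimilarity to their siblings exceeds a threshold (fitted
   from the pooled among-replicate dissimilarity distribution, or fixed) are
   removed; bottles left with fewer than two replicates are dropped whole.

Finally, **rarefaction** subsamples every surviving replicate to a common
read depth without replacement.

Each step returns a :class:`QCReport` stage record so read/OTU accounting is
auditable end to end.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial.distance import pdist, squareform

from .io_core import Dataset, OTUTable, ValidationError

__all__ = [
    "DetectionHistory",
    "OccupancyEstimate",
    "ContaminationProfile",
    "QCReport",
    "StageRecord",
    "build_detection_histories",
    "occupancy_loglik",
    "conditional_occupancy",
    "fit_occupancy",
    "fit_occupancy_all",
    "occupancy_filter",
    "control_profile",
    "subtract_contamination",
    "replicate_dissimilarities",
    "fit_dissimilarity_threshold",
    "drop_discordant",
    "rarefy",
    "retention_percentage",
]

_EPS = 1e-6
DEFAULT_P10_MAX = 0.2


class ConfigurationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# bookkeeping


@dataclass(frozen=True)
class StageRecord:
    stage: str
    reads_in: int
    reads_out: int
    otus_in: int
    otus_out: int
    replicates_dropped: tuple[str, ...] = ()
    samples_dropped: tuple[str, ...] = ()
    threshold: float | None = None

    def __post_init__(self) -> None:
        if self.reads_out > self.reads_in or self.otus_out > self.otus_in:
            raise ValidationError(
                f"stage {self.stage!r} increased reads or OTUs"
            )

    def to_json_dict(self) -> dict:
        return {
            "stage": self.stage,
            "reads_in": self.reads_in,
            "reads_out": self.reads_out,
            "otus_in": self.otus_in,
            "otus_out": self.otus_out,
            "replicates_dropped": list(self.replicates_dropped),
            "samples_dropped": list(self.samples_dropped),
            "threshold": self.threshold,
        }


@dataclass
class QCReport:
    stages: list[StageRecord] = field(default_factory=list)

    def add(self, record: StageRecord) -> None:
        self.stages.append(record)

    def to_json_dict(self) -> dict:
        return {"stages": [s.to_json_dict() for s in self.stages]}

    def retained_read_percentage(self) -> float:
        """100 x (reads after replicate QC) / (reads input to the occupancy filter)."""
        by_name = {s.stage: s for s in self.stages}
        try:
            reads_in = by_name["occupancy_filter"].reads_in
            reads_out = by_name["drop_discordant"].reads_out
        except KeyError as exc:
            raise ValidationError(f"QC report missing stage {exc}") from exc
        return retention_percentage(reads_in, reads_out)


def retention_percentage(reads_in: int, reads_out: int) -> float:
    if reads_in <= 0:
        raise ValidationError("reads_in must be positive")
    return 100.0 * reads_out / reads_in


def _stage(name: str, before: OTUTable, after: OTUTable, *,
           replicates_dropped: Iterable[str] = (),
           samples_dropped: Iterable[str] = (),
           threshold: float | None = None) -> StageRecord:
    return StageRecord(
        stage=name,
        reads_in=before.total_reads(),
        reads_out=after.total_reads(),
        otus_in=before.n_otus,
        otus_out=after.n_otus,
        replicates_dropped=tuple(replicates_dropped),
        samples_dropped=tuple(samples_dropped),
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# step 1: site-occupancy false-positive model


@dataclass(frozen=True)
class DetectionHistory:
    """Per-OTU detection record: for each water sample (bottle), the number of
    PCR replicates attempted (K) and the number with the OTU detected (d)."""

    otu_id: str
    sample_ids: tuple[str, ...]
    n_trials: tuple[int, ...]  # K_s
    n_detections: tuple[int, ...]  # d_s

    def __post_init__(self) -> None:
        if not all(1 <= k for k in self.n_trials):
            raise ValidationError("every sample needs >= 1 PCR replicate")
        if not all(0 <= d <= k for d, k in zip(self.n_detections, self.n_trials)):
            raise ValidationError("detections must satisfy 0 <= d <= K")
        if sum(self.n_detections) < 1:
            raise ValidationError(
                f"history for {self.otu_id!r} has no detections"
            )

    def aggregated(self) -> list[tuple[int, int, int]]:
        """Unique (K, d) pairs with multiplicities."""
        counts: dict[tuple[int, int], int] = {}
        for k, d in zip(self.n_trials, self.n_detections):
            counts[(k, d)] = counts.get((k, d), 0) + 1
        return [(k, d, m) for (k, d), m in sorted(counts.items())]


@dataclass(frozen=True)
class OccupancyEstimate:
    otu_id: str
    psi: float
    p11: float
    p10: float
    loglik: float
    sample_ids: tuple[str, ...]
    conditional: tuple[float, ...]  # Pr(occupied | d_s, K_s) per sample
    otu_score: float  # max over samples


def build_detection_histories(dataset: Dataset) -> list[DetectionHistory]:
    """One history per OTU with >= 1 detection among field replicates.

    Positive-control replicates are excluded; K_s comes from the metadata
    bottle nesting and detection means count > 0.
    """
    bottles = dataset.metadata.bottles()
    usable = {b: reps for b, reps in bottles.items() if len(reps) >= 1}
    table = dataset.table
    sample_ids = tuple(sorted(usable))
    detected = {
        b: (table.counts[usable[b]].to_numpy() > 0).sum(axis=1)
        for b in sample_ids
    }
    n_trials = tuple(len(usable[b]) for b in sample_ids)
    histories = []
    for i, otu in enumerate(table.otu_ids):
        d = tuple(int(detected[b][i]) for b in sample_ids)
        if sum(d) >= 1:
            histories.append(DetectionHistory(otu, sample_ids, n_trials, d))
    return histories


def _log_binom_pmf(k: int, d: int, p: float) -> float:
    p = min(max(p, 0.0), 1.0)
    if d > 0 and p == 0.0:
        return -math.inf
    if d < k and p == 1.0:
        return -math.inf
    out = math.log(math.comb(k, d))
    if d:
        out += d * math.log(p)
    if k - d:
        out += (k - d) * math.log1p(-p)
    return out


def occupancy_loglik(psi: float, p11: float, p10: float,
                     pairs: Sequence[tuple[int, int, int]]) -> float:
    """Log likelihood of the two-component mixture over aggregated (K, d, mult)."""
    total = 0.0
    for k, d, mult in pairs:
        la = _log_binom_pmf(k, d, p11)
        lb = _log_binom_pmf(k, d, p10)
        ta = -math.inf if psi <= 0 else math.log(psi) + la
        tb = -math.inf if psi >= 1 else math.log1p(-psi) + lb
        m = max(ta, tb)
        if m == -math.inf:
            return -math.inf
        total += mult * (m + math.log(math.exp(ta - m) + math.exp(tb - m)))
    return total


def conditional_occupancy(d: int, k: int, psi: float, p11: float, p10: float) -> float:
    """Pr(sample occupied | d detections in k replicates) at fixed parameters."""
    la = _log_binom_pmf(k, d, p11)
    lb = _log_binom_pmf(k, d, p10)
    ta = -math.inf if psi <= 0 else math.log(psi) + la
    tb = -math.inf if psi >= 1 else math.log1p(-psi) + lb
    if ta == -math.inf and tb == -math.inf:
        return 0.0
    m = max(ta, tb)
    num = math.exp(ta - m)
    return num / (num + math.exp(tb - m))


_STARTS = [
    (0.5, 0.8, 0.1),
    (0.2, 0.5, 0.5),
    (0.8, 0.9, 0.05),
    (0.5, 0.3, 0.9),
    (0.05, 0.9, 0.3),
    (0.95, 0.5, 0.01),
]


def _candidate_estimate(history: DetectionHistory, psi: float, p11: float,
                        p10: float, loglik: float) -> OccupancyEstimate:
    cond = tuple(
        conditional_occupancy(d, k, psi, p11, p10)
        for k, d in zip(history.n_trials, history.n_detections)
    )
    return OccupancyEstimate(
        otu_id=history.otu_id, psi=psi, p11=p11, p10=p10, loglik=loglik,
        sample_ids=history.sample_ids, conditional=cond,
        otu_score=max(cond),
    )


def fit_occupancy(history: DetectionHistory, *, p10_max: float = DEFAULT_P10_MAX,
                  n_grid: int = 11) -> OccupancyEstimate:
    """Maximum-likelihood fit of (psi, p11, p10) with p10 <= min(p11, p10_max).

    Multi-start bounded optimization (L-BFGS-B over psi, p11 and the ratio
    r = p10 / min(p11, p10_max)) with a coarse-grid fallback. The likelihood
    is flat in psi whenever p11 = p10 fits the detections as well as any true
    mixture; among candidates tied at the maximum the one with the smallest
    occupancy score is returned, so occupancy is never claimed on evidence
    indistinguishable from uniform false positives.
    """
    pairs = history.aggregated()

    def unpack(x: np.ndarray) -> tuple[float, float, float]:
        psi, p11, r = x
        return float(psi), float(p11), float(r * min(p11, p10_max))

    def nll(x: np.ndarray) -> float:
        return -occupancy_loglik(*unpack(x), pairs)

    total_k = sum(k * m for k, _, m in pairs)
    total_d = sum(d * m for _, d, m in pairs)
    phat = total_d / total_k

    # coarse grid: best few points double as extra starts and as a fallback
    gv = np.linspace(_EPS, 1 - _EPS, n_grid)
    grid_pts = [(psi, p11, r) for psi in gv for p11 in gv for r in gv]
    grid_scores = [nll(np.array(p)) for p in grid_pts]
    order = np.argsort(grid_scores)
    starts = _STARTS + [grid_pts[i] for i in order[:3]]
    # deterministic probes for the two ridge branches
    starts.append((_EPS, min(1 - _EPS, max(phat * 2, 0.5)),
                   min(1.0, phat / p10_max) if p10_max else 0.0))
    starts.append((1 - _EPS, max(phat, _EPS), _EPS))

    bounds = [(_EPS, 1 - _EPS), (_EPS, 1 - _EPS), (0.0, 1.0)]
    candidates: list[tuple[float, tuple[float, float, float]]] = []
    for x0 in starts:
        res = optimize.minimize(nll, np.array(x0), method="L-BFGS-B", bounds=bounds)
        if np.isfinite(res.fun):
            candidates.append((-float(res.fun), unpack(res.x)))
    best_grid = (-float(grid_scores[order[0]]), unpack(np.array(grid_pts[order[0]])))
    candidates.append(best_grid)
    if not candidates:  # pragma: no cover - grid always yields a candidate
        raise RuntimeError("occupancy fit failed; best grid point "
                           f"{best_grid}")

    best_ll = max(ll for ll, _ in candidates)
    tol = 1e-6 * max(1.0, abs(best_ll))
    tied = [
        _candidate_estimate(history, *params, ll)
        for ll, params in candidates
        if ll >= best_ll - tol
    ]
    return min(tied, key=lambda est: (est.psi, est.otu_score))


def fit_occupancy_all(histories: Iterable[DetectionHistory],
                      **kwargs) -> list[OccupancyEstimate]:
    """Fit every history, caching on the multiset of (K, d) pairs.

    The likelihood depends on the detection history only through that
    multiset, so OTUs with identical aggregated histories (very common:
    ubiquitous OTUs are detected in every replicate) share one fit.
    """
    cache: dict[tuple, OccupancyEstimate] = {}
    out = []
    for h in histories:
        key = tuple(h.aggregated())
        hit = cache.get(key)
        if hit is None:
            hit = cache[key] = fit_occupancy(h, **kwargs)
        if hit.otu_id == h.otu_id:
            out.append(hit)
        else:
            cond = tuple(
                conditional_occupancy(d, k, hit.psi, hit.p11, hit.p10)
                for k, d in zip(h.n_trials, h.n_detections)
            )
            out.append(OccupancyEstimate(
                otu_id=h.otu_id, psi=hit.psi, p11=hit.p11, p10=hit.p10,
                loglik=hit.loglik, sample_ids=h.sample_ids,
                conditional=cond, otu_score=max(cond),
            ))
    return out


def occupancy_filter(dataset: Dataset, estimates: Iterable[OccupancyEstimate],
                     threshold: float = 0.80, score: str = "psi"
                     ) -> tuple[Dataset, StageRecord]:
    """Drop OTU rows whose estimated probability of occurrence is below
    ``threshold``.

    ``score`` selects the probability used: the occupancy estimate ``psi``
    (default — scattered false-positive detections keep psi-hat low even when
    the fit reads them as rare true occupancy) or ``max_conditional`` (the
    best sample-level conditional occupancy, which retains an OTU credibly
    present in even a single sample). OTUs with zero field detections have no
    estimate; they carry score 0 and are removed for any positive threshold.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in [0, 1], got {threshold}")
    if score not in ("psi", "max_conditional"):
        raise ConfigurationError(f"unknown score {score!r}")
    scores = {
        e.otu_id: (e.psi if score == "psi" else e.otu_score)
        for e in estimates
    }
    keep = [o for o in dataset.table.otu_ids if scores.get(o, 0.0) >= threshold]
    table = dataset.table.select_otus(keep)
    record = _stage("occupancy_filter", dataset.table, table, threshold=threshold)
    return Dataset(table, dataset.metadata), record


# ---------------------------------------------------------------------------
# step 2: positive-control contamination subtraction


@dataclass(frozen=True)
class ContaminationProfile:
    """Per-OTU maximum proportional representation across control replicates."""

    proportions: pd.Series  # indexed by otu_id, values in [0, 1]

    def __post_init__(self) -> None:
        v = self.proportions.to_numpy(dtype=float)
        if v.size and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValidationError("contamination proportions must lie in [0, 1]")

    def get(self, otu_id: str) -> float:
        return float(self.proportions.get(otu_id, 0.0))


def control_profile(dataset: Dataset) -> ContaminationProfile:
    controls = dataset.metadata.control_replicates()
    if not controls:
        raise ValidationError(
            "no positive-control replicates present; skip the contamination-"
            "subtraction stage explicitly if this is intended"
        )
    ctrl = dataset.table.select_replicates(controls)
    depths = ctrl.depths()
    nonzero = depths[depths > 0].index
    if not len(nonzero):
        raise ValidationError("all control replicates are empty")
    props = (ctrl.counts[nonzero] / depths[nonzero]).max(axis=1)
    return ContaminationProfile(props)


def subtract_contamination(dataset: Dataset, profile: ContaminationProfile
                           ) -> tuple[Dataset, StageRecord]:
    """Subtract each OTU's control proportion from field replicates.

    Works in proportion space per replicate (p' = max(0, p - c)), flooring
    back to integer counts against the replicate's original depth; no
    renormalization. Control replicates are removed from the output and OTUs
    reduced to all zeros are dropped.
    """
    field_ids = dataset.metadata.field_replicates()
    tab = dataset.table.select_replicates(field_ids)
    depths = tab.depths()
    empty = list(depths[depths == 0].index)
    if empty:
        warnings.warn(f"dropping zero-depth replicate(s): {empty}", stacklevel=2)
        keep = [r for r in field_ids if r not in set(empty)]
        tab = tab.select_replicates(keep)
        depths = tab.depths()
    c = np.array([profile.get(o) for o in tab.otu_ids])[:, None]
    # floor((p - c) * T) computed as floor(count - c*T): exact when c*T is
    # integral (in particular bit-identical for c = 0)
    adjusted = tab.counts.to_numpy() - c * depths.to_numpy()[None, :]
    new_counts = np.maximum(0.0, np.floor(adjusted + 1e-9))
    out_tab = OTUTable(pd.DataFrame(
        new_counts.astype(np.int64), index=tab.counts.index, columns=tab.counts.columns
    )).drop_empty_otus()
    record = _stage(
        "subtract_contamination", dataset.table, out_tab,
        replicates_dropped=[*dataset.metadata.control_replicates(), *empty],
    )
    meta = dataset.metadata.select(out_tab.replicate_ids)
    return Dataset(out_tab, meta), record


# ---------------------------------------------------------------------------
# step 3: discordant PCR replicates


def _bottle_bc_matrix(tab: OTUTable, reps: list[str], normalize: bool) -> np.ndarray:
    x = tab.counts[reps].to_numpy(dtype=float).T
    if normalize:
        sums = x.sum(axis=1, keepdims=True)
        if (sums == 0).any():
            raise ValidationError(
                f"all-zero replicate among {reps}; cannot form proportions"
            )
        x = x / sums
    return squareform(pdist(x, metric="braycurtis"), checks=False)


def replicate_dissimilarities(dataset: Dataset, normalize: bool = True
                              ) -> list[tuple[str, tuple[str, str], float]]:
    """All within-bottle pairwise Bray–Curtis values among field replicates."""
    bottles = {b: r for b, r in dataset.metadata.bottles().items() if len(r) >= 2}
    if not bottles:
        raise ValidationError("no bottle has >= 2 replicates")
    out = []
    for bottle, reps in sorted(bottles.items()):
        m = _bottle_bc_matrix(dataset.table, reps, normalize)
        for i, j in itertools.combinations(range(len(reps)), 2):
            out.append((bottle, (reps[i], reps[j]), float(m[i, j])))
    return out


_FAMILIES = {
    "normal": stats.norm,
    "lognormal": stats.lognorm,
    "gamma": stats.gamma,
    "beta": stats.beta,
}


def fit_dissimilarity_threshold(values: Sequence[float],
                                q: float = 0.975
                                ) -> tuple[str, tuple[float, ...], float]:
    """Fit candidate distributions to among-replicate dissimilarities by ML,
    pick by AIC, and return that family's ``q`` quantile as the threshold.

    The 97.5% default reproduces the upper bound of a central 95% interval.
    """
    v = np.asarray(values, dtype=float)
    if v.size < 10:
        raise ValidationError("need >= 10 dissimilarity values to fit")
    if (v < 0).any() or (v > 1).any():
        raise ValidationError("dissimilarities must lie in [0, 1]")
    if np.ptp(v) == 0:
        raise ValidationError(
            "all dissimilarities identical; supply a manual threshold instead"
        )
    eps = 1e-9
    clipped = np.clip(v, eps, 1 - eps)
    fits: dict[str, tuple[tuple[float, ...], float]] = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for name, dist in _FAMILIES.items():
            try:
                if name == "normal":
                    params = dist.fit(v)
                elif name == "beta":
                    params = dist.fit(clipped, floc=0, fscale=1)
                else:
                    params = dist.fit(clipped, floc=0)
                ll = float(np.sum(dist.logpdf(clipped, *params)))
            except Exception:  # a family can fail on odd data; skip it
                continue
            if np.isfinite(ll):
                # 2 free parameters each (loc/scale fixed where applicable)
                fits[name] = (params, 2 * 2 - 2 * ll)
    if not fits:
        raise ValidationError("no candidate distribution could be fitted")
    best = min(fits, key=lambda k: fits[k][1])
    params = fits[best][0]
    threshold = float(_FAMILIES[best].ppf(q, *params))
    return best, tuple(float(p) for p in params), threshold


def drop_discordant(dataset: Dataset, threshold: float,
                    normalize: bool = True) -> tuple[Dataset, StageRecord]:
    """Iteratively remove, per bottle, the replicate most dissimilar to its
    siblings while any within-bottle pair exceeds ``threshold``; bottles left
    with fewer than two replicates are dropped whole.
    """
    if not 0.0 < threshold <= 1.0:
        raise ConfigurationError(f"threshold must be in (0, 1], got {threshold}")
    dropped_reps: list[str] = []
    dropped_bottles: list[str] = []
    survivors: list[str] = []
    for bottle, reps in sorted(dataset.metadata.bottles().items()):
        reps = list(reps)
        if len(reps) < 2:
            dropped_bottles.append(bottle)
            dropped_reps.extend(reps)
            continue
        m = _bottle_bc_matrix(dataset.table, reps, normalize)
        active = list(range(len(reps)))
        while len(active) >= 2:
            sub = m[np.ix_(active, active)]
            if sub.max() <= threshold:
                break
            mean_diss = sub.sum(axis=1) / (len(active) - 1)
            # ties resolved toward the lexicographically smallest replicate id
            top = np.flatnonzero(mean_diss == mean_diss.max())
            worst = min((reps[active[i]], i) for i in top)[1]
            dropped_reps.append(reps[active.pop(worst)])
        if len(active) < 2:
            dropped_bottles.append(bottle)
            dropped_reps.extend(reps[i] for i in active)
        else:
            survivors.extend(reps[i] for i in active)
    keep = [r for r in dataset.table.replicate_ids if r in set(survivors)]
    tab = dataset.table.select_replicates(keep).drop_empty_otus()
    record = _stage(
        "drop_discordant", dataset.table, tab,
        replicates_dropped=dropped_reps, samples_dropped=dropped_bottles,
        threshold=threshold,
    )
    return Dataset(tab, dataset.metadata.select(keep)), record


# ---------------------------------------------------------------------------
# rarefaction


def rarefy(dataset: Dataset, depth: int = 18_500, seed: int = 0
           ) -> tuple[Dataset, StageRecord]:
    """Subsample every replicate to exactly ``depth`` reads without
    replacement (multivariate hypergeometric); shallower replicates are
    dropped and reported. Deterministic given ``seed``.
    """
    if depth < 1:
        raise ConfigurationError("depth must be >= 1")
    depths = dataset.table.depths()
    if (depths < depth).all():
        raise ValidationError(
            f"no replicate has >= {depth} reads (max is {int(depths.max())})"
        )
    rng = np.random.default_rng(seed)
    shallow = list(depths[depths < depth].index)
    keep = [r for r in dataset.table.replicate_ids if depths[r] >= depth]
    cols = {}
    for rep in keep:
        counts = dataset.table.counts[rep].to_numpy()
        cols[rep] = rng.multivariate_hypergeometric(counts, depth)
    tab = OTUTable(pd.DataFrame(cols, index=dataset.table.counts.index)).drop_empty_otus()
    record = _stage(
        "rarefy", dataset.table, tab,
        replicates_dropped=shallow, threshold=float(depth),
    )
    return Dataset(tab, dataset.metadata.select(keep)), record
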