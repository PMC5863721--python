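"""Ordination and community delimitation.

NMDS embeds the Bray–Curtis matrix for visual confirmation of community
structure; the two-community split itself is made algorithmic (average-
linkage hierarchical clustering cut at two groups) so downstream association
tests are deterministic. A correspondence analysis constrained by the binary
community label then ranks OTUs by how strongly they discriminate the two
water-mass communities; the high-leverage set is the OTUs with large absolute
scores and enough reads to matter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from skbio import DistanceMatrix
from sklearn.manifold import MDS
from sklearn.metrics import silhouette_score

from .io_core import OTUTable, SampleMetadata, ValidationError

__all__ = [
    "NMDSResult",
    "CommunityAssignment",
    "CCAResult",
    "nmds",
    "assign_communities",
    "cca_constrained",
    "high_leverage_otus",
]


@dataclass(frozen=True)
class NMDSResult:
    coordinates: pd.DataFrame  # replicates x k, column means 0
    stress: float  # Kruskal stress-1
    n_starts: int
    best_start_seed: int
    converged: bool


@dataclass(frozen=True)
class CommunityAssignment:
    labels: pd.Series  # replicate_id -> community label (1-based)
    silhouette: float
    bottle_labels: pd.Series | None = None  # majority per bottle
    event_labels: pd.Series | None = None  # majority per event

    def to_json_dict(self) -> dict:
        return {
            "labels": {str(k): int(v) for k, v in self.labels.items()},
            "silhouette": self.silhouette,
            "bottle_labels": None if self.bottle_labels is None else
            {str(k): int(v) for k, v in self.bottle_labels.items()},
            "event_labels": None if self.event_labels is None else
            {str(k): int(v) for k, v in self.event_labels.items()},
        }


@dataclass(frozen=True)
class CCAResult:
    otu_scores: pd.Series  # score on the single constrained axis
    replicate_scores: pd.Series
    singular_value: float
    constrained_inertia_fraction: float
    total_inertia: float


def nmds(dist: DistanceMatrix, k: int = 2, n_starts: int = 20,
         max_iter: int = 500, tol: float = 1e-7, seed: int = 0) -> NMDSResult:
    """Non-metric MDS minimizing Kruskal stress-1 (best of ``n_starts``).

    Alternates isotonic (pool-adjacent-violators) disparities with SMACOF
    configuration updates; deterministic for a given seed.
    """
    d = np.asarray(dist.data, dtype=float)
    if not np.isfinite(d).all():
        raise ValidationError("distance matrix contains non-finite values")
    n = d.shape[0]
    if n < k + 2:
        raise ValidationError(f"need at least {k + 2} samples for {k}-d NMDS")
    model = MDS(
        n_components=k, metric=False, n_init=n_starts, max_iter=max_iter,
        eps=tol, dissimilarity="precomputed", random_state=seed,
        normalized_stress=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        coords = model.fit_transform(d)
    coords = coords - coords.mean(axis=0, keepdims=True)
    return NMDSResult(
        coordinates=pd.DataFrame(coords, index=list(dist.ids),
                                 columns=[f"NMDS{i + 1}" for i in range(k)]),
        stress=float(model.stress_),
        n_starts=n_starts,
        best_start_seed=seed,
        converged=bool(model.n_iter_ < max_iter),
    )


def assign_communities(dist: DistanceMatrix, n_communities: int = 2,
                       metadata: SampleMetadata | None = None) -> CommunityAssignment:
    """Average-linkage clustering of the dissimilarity matrix cut at
    ``n_communities``, with labels canonicalized so community 1 is the
    cluster spanning the most distinct sites (falling back to the larger
    cluster when no metadata is given).
    """
    ids = list(dist.ids)
    n = len(ids)
    if n_communities > n:
        raise ValidationError("more communities requested than samples")
    d = np.asarray(dist.data, dtype=float)
    if np.allclose(d, 0):
        warnings.warn("all samples identical; degenerate single community",
                      stacklevel=2)
        labels = pd.Series(1, index=ids)
        return _with_majorities(labels, 0.0, metadata)
    z = linkage(squareform(d, checks=False), method="average")
    raw = fcluster(z, t=n_communities, criterion="maxclust")
    labels = pd.Series(raw, index=ids)

    # canonical order: most distinct sites first, then cluster size, then id
    def sort_key(cluster: int):
        members = labels.index[labels == cluster]
        n_sites = (
            metadata.records.loc[members, "site_id"].nunique()
            if metadata is not None else 0
        )
        return (-n_sites, -len(members), str(min(members)))

    order = sorted(pd.unique(labels), key=sort_key)
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = labels.map(relabel)
    if labels.nunique() > 1:
        sil = float(silhouette_score(d, labels.to_numpy(), metric="precomputed"))
    else:
        warnings.warn("degenerate clustering: a single community", stacklevel=2)
        sil = 0.0
    return _with_majorities(labels, sil, metadata)


def _with_majorities(labels: pd.Series, sil: float,
                     metadata: SampleMetadata | None) -> CommunityAssignment:
    bottle = event = None
    if metadata is not None:
        meta = metadata.records.loc[labels.index]
        grp = pd.DataFrame({"label": labels, "bottle": meta["bottle_id"],
                            "event": meta["event_id"]})
        majority = lambda s: int(s.value_counts().idxmax())
        bottle = grp.groupby("bottle")["label"].agg(majority)
        event = grp.groupby("event")["label"].agg(majority)
    return CommunityAssignment(labels=labels, silhouette=sil,
                               bottle_labels=bottle, event_labels=event)


def cca_constrained(table: OTUTable, labels: CommunityAssignment) -> CCAResult:
    """Correspondence analysis of the count table constrained by the binary
    community label.

    Chi-square standardization ``Q = D_r^{-1/2} (P - r c') D_c^{-1/2}``; the
    replicate dimension of Q is projected onto the column-mass-weighted span
    of the community indicator, and the fitted matrix is decomposed by SVD.
    OTU scores are principal row coordinates (chi-square-metric left singular
    vectors scaled by the singular value), the scaling under which the
    conventional |score| > 0.7 cutoff is interpreted; the axis sign is fixed
    so the community-2 centroid is positive.
    """
    reps = table.replicate_ids
    missing = [r for r in reps if r not in labels.labels.index]
    if missing:
        raise ValidationError(f"replicates without community label: {missing[:5]}")
    y = labels.labels.loc[reps].to_numpy()
    groups = np.unique(y)
    if len(groups) < 2:
        raise ValidationError("need both communities represented")
    x = table.counts.to_numpy(dtype=float)
    grand = x.sum()
    col_sums = x.sum(axis=0)
    for g in groups:
        if col_sums[y == g].sum() == 0:
            raise ValidationError(f"community {g} has zero total reads")
    p = x / grand
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    r_safe = np.where(r > 0, r, 1.0)
    q = (p - np.outer(r, c)) / np.sqrt(np.outer(r_safe, c))
    total_inertia = float((q ** 2).sum())

    # weighted projector onto span{1, community indicator} in the c metric
    z = np.column_stack([np.ones_like(c), (y == groups[-1]).astype(float)])
    w = z * np.sqrt(c)[:, None]
    u_w, s_w, _ = np.linalg.svd(w, full_matrices=False)
    u_w = u_w[:, s_w > 1e-12 * s_w.max()]
    q_fit = (q @ u_w) @ u_w.T
    fitted_ss = float((q_fit ** 2).sum())

    u, s, vt = np.linalg.svd(q_fit, full_matrices=False)
    s1 = float(s[0])
    otu_scores = u[:, 0] * s1 / np.sqrt(r_safe)
    otu_scores[r == 0] = 0.0
    rep_scores = vt[0] / np.sqrt(c)
    comm2 = y == (2 if 2 in groups else groups[-1])
    if rep_scores[comm2].mean() < 0:
        otu_scores, rep_scores = -otu_scores, -rep_scores
    return CCAResult(
        otu_scores=pd.Series(otu_scores, index=table.otu_ids),
        replicate_scores=pd.Series(rep_scores, index=reps),
        singular_value=s1,
        constrained_inertia_fraction=fitted_ss / total_inertia if total_inertia else 0.0,
        total_inertia=total_inertia,
    )


def high_leverage_otus(cca: CCAResult, table: OTUTable, score_min: float = 0.7,
                       count_min: int = 1000) -> pd.Series:
    """OTUs with |score| strictly above ``score_min`` and at least
    ``count_min`` total reads, sorted by |score| descending."""
    totals = table.counts.sum(axis=1)
    scores = cca.otu_scores.reindex(table.otu_ids)
    mask = (scores.abs() > score_min) & (totals >= count_min)
    out = scores[mask]
    return out.iloc[np.argsort(-out.abs().to_numpy(), kind="stable")]
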