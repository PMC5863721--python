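"""Sequential (Type-I) PERMANOVA on a dissimilarity matrix.

Partitions the total sum of squares of a distance matrix among an ordered
list of categorical design factors — here the nested field design
tide / site / sampling event / bottle, with PCR replicates as residuals —
and attaches permutation p-values.

Following the standard development: Gower-center the squared distances,
``G = -1/2 J D^2 J`` with ``J = I - 11'/N``; each term's indicator matrix is
residualized against the intercept and all preceding terms, giving an
orthogonal projector ``H_k`` with ``SS_k = tr(H_k G)``; the residual picks up
what no term explains. Pseudo-F compares term and residual mean squares and
its null distribution comes from freely relabeling the samples (rows and
columns of D together). When the number of distinct relabelings is small the
permutation distribution is enumerated exhaustively and the p-value is exact;
otherwise it is Monte-Carlo sampled with the add-one correction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from sympy.utilities.iterables import multiset_permutations

from .io_core import SampleMetadata, ValidationError

__all__ = ["TermResult", "PermanovaResult", "permanova", "WHOLE_DATASET_TERMS",
           "PER_SITE_TERMS"]

WHOLE_DATASET_TERMS = ["tide_direction", "site_id", "event_id", "bottle_id"]
PER_SITE_TERMS = ["tide_direction", "event_id", "bottle_id"]


@dataclass(frozen=True)
class TermResult:
    name: str
    df: int
    ss: float
    r2: float
    pseudo_f: float | None
    p_value: float | None


@dataclass(frozen=True)
class PermanovaResult:
    terms: tuple[TermResult, ...]
    residual_df: int
    residual_ss: float
    residual_r2: float
    total_ss: float
    n_perm: int
    exhaustive: bool

    def r2(self, term: str) -> float:
        for t in self.terms:
            if t.name == term:
                return t.r2
        raise KeyError(term)

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {"term": t.name, "df": t.df, "ss": t.ss, "r2": t.r2,
             "pseudo_f": t.pseudo_f, "p_value": t.p_value}
            for t in self.terms
        ]
        rows.append({"term": "Residual", "df": self.residual_df,
                     "ss": self.residual_ss, "r2": self.residual_r2,
                     "pseudo_f": None, "p_value": None})
        rows.append({"term": "Total", "df": self.residual_df + sum(t.df for t in self.terms),
                     "ss": self.total_ss, "r2": 1.0, "pseudo_f": None,
                     "p_value": None})
        return pd.DataFrame(rows)

    def to_json_dict(self) -> dict:
        return {
            "terms": [t.__dict__ for t in self.terms],
            "residual": {"df": self.residual_df, "ss": self.residual_ss,
                         "r2": self.residual_r2},
            "total_ss": self.total_ss,
            "n_perm": self.n_perm,
            "exhaustive": self.exhaustive,
        }


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def _indicator(codes: np.ndarray, n_levels: int) -> np.ndarray:
    z = np.zeros((codes.size, n_levels))
    z[np.arange(codes.size), codes] = 1.0
    return z


def _sequential_bases(label_arrays: list[np.ndarray], n: int,
                      rank_tol: float = 1e-8) -> list[np.ndarray]:
    """Orthonormal basis per term, each residualized against everything before."""
    basis = np.ones((n, 1)) / math.sqrt(n)  # intercept
    out = []
    for codes in label_arrays:
        z = _indicator(codes, codes.max() + 1)
        resid = z - basis @ (basis.T @ z)
        u, s, _ = np.linalg.svd(resid, full_matrices=False)
        rank = int((s > rank_tol * max(s[0], 1.0)).sum()) if s.size else 0
        u = u[:, :rank]
        out.append(u)
        if rank:
            basis = np.hstack([basis, u])
    return out


def _term_ss(bases: list[np.ndarray], g: np.ndarray) -> np.ndarray:
    return np.array([
        float(np.einsum("ij,ij->", u, g @ u)) if u.shape[1] else 0.0
        for u in bases
    ])


def _pseudo_f(ss: np.ndarray, dfs: np.ndarray, ss_res: float, df_res: int) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ms = np.where(dfs > 0, ss / np.maximum(dfs, 1), np.nan)
        return ms / (ss_res / df_res)


def permanova(dist: DistanceMatrix, metadata: SampleMetadata,
              terms: list[str] | None = None, n_perm: int = 999,
              seed: int = 0) -> PermanovaResult:
    """Sequential PERMANOVA of ``dist`` on the metadata factors ``terms``.

    Terms are fitted in the given order (Type-I); a term constant across all
    samples gets df 0, SS 0 and an undefined p-value with a warning. With
    ``n_perm = 0`` only the partition (df/SS/R2/pseudo-F) is computed.
    """
    terms = list(terms) if terms is not None else list(WHOLE_DATASET_TERMS)
    ids = list(dist.ids)
    missing = [i for i in ids if i not in set(metadata.replicate_ids)]
    if missing:
        raise ValidationError(f"distance labels missing from metadata: {missing[:5]}")
    meta = metadata.records.loc[ids]
    for t in terms:
        if t not in meta.columns:
            raise ValidationError(f"unknown term {t!r}")
    n = len(ids)
    label_arrays = []
    label_tuples = list(zip(*[meta[t].astype(str) for t in terms])) if terms else []
    for t in terms:
        vals = meta[t].astype(str)
        if vals.nunique() == 1:
            warnings.warn(f"term {t!r} is constant; df 0, p undefined", stacklevel=2)
        label_arrays.append(pd.factorize(vals)[0])

    g = _gower_center(np.asarray(dist.data, dtype=float))
    ss_total = float(np.trace(g))
    bases = _sequential_bases(label_arrays, n)
    dfs = np.array([u.shape[1] for u in bases])
    ss = _term_ss(bases, g)
    df_res = n - 1 - int(dfs.sum())
    if df_res <= 0:
        raise ValidationError("design saturates the data; no residual df")
    ss_res = ss_total - float(ss.sum())
    f_obs = _pseudo_f(ss, dfs, ss_res, df_res)

    p_values: list[float | None] = [None] * len(terms)
    exhaustive = False
    if n_perm > 0:
        n_distinct = _count_distinct_relabelings(label_tuples)
        exceed = np.zeros(len(terms))
        if n_distinct is not None and n_distinct <= n_perm:
            exhaustive = True
            total = 0
            uniq: dict[tuple, int] = {}
            codes_seq = [uniq.setdefault(t, len(uniq)) for t in label_tuples]
            inv = {v: k for k, v in uniq.items()}
            for arrangement in multiset_permutations(codes_seq):
                order_bases = _relabelled_bases(arrangement, inv, len(terms), n)
                ss_p = _term_ss(order_bases, g)
                f_p = _pseudo_f(ss_p, dfs, ss_total - float(ss_p.sum()), df_res)
                exceed += _geq(f_p, f_obs)
                total += 1
            denom = total
            p_raw = exceed / denom
        else:
            rng = np.random.default_rng(seed)
            for _ in range(n_perm):
                perm = rng.permutation(n)
                gp = g[np.ix_(perm, perm)]
                ss_p = _term_ss(bases, gp)
                f_p = _pseudo_f(ss_p, dfs, ss_total - float(ss_p.sum()), df_res)
                exceed += _geq(f_p, f_obs)
            p_raw = (1.0 + exceed) / (1.0 + n_perm)
        p_values = [float(p) if dfs[k] > 0 else None for k, p in enumerate(p_raw)]

    term_results = tuple(
        TermResult(
            name=t, df=int(dfs[k]), ss=float(ss[k]),
            r2=float(ss[k] / ss_total),
            pseudo_f=float(f_obs[k]) if dfs[k] > 0 else None,
            p_value=p_values[k],
        )
        for k, t in enumerate(terms)
    )
    return PermanovaResult(
        terms=term_results, residual_df=df_res, residual_ss=ss_res,
        residual_r2=float(ss_res / ss_total), total_ss=ss_total,
        n_perm=n_perm, exhaustive=exhaustive,
    )


def _geq(f_perm: np.ndarray, f_obs: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(f_obs), 0.0, (f_perm >= f_obs - 1e-12).astype(float))


def _count_distinct_relabelings(label_tuples: list[tuple]) -> int | None:
    """N! / prod(group sizes!) — None on overflow-scale designs."""
    n = len(label_tuples)
    if n > 170:
        return None
    counts: dict[tuple, int] = {}
    for t in label_tuples:
        counts[t] = counts.get(t, 0) + 1
    total = math.factorial(n)
    for c in counts.values():
        total //= math.factorial(c)
    return total


def _relabelled_bases(arrangement: list[int], code_to_tuple: dict[int, tuple],
                      n_terms: int, n: int) -> list[np.ndarray]:
    """Rebuild per-term bases for one distinct arrangement of joint labels."""
    tuples = [code_to_tuple[c] for c in arrangement]
    label_arrays = []
    for k in range(n_terms):
        levels: dict[str, int] = {}
        codes = np.array([levels.setdefault(t[k], len(levels)) for t in tuples])
        label_arrays.append(codes)
    return _sequential_bases(label_arrays, n)
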