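"""Bray–Curtis and Jaccard dissimilarity matrices between PCR replicates.

Bray–Curtis BC(x, y) = sum|x_i - y_i| / sum(x_i + y_i) on read-count vectors;
by default the columns are first converted to proportions so that replicates
of unequal depth are comparable (after rarefaction the two conventions agree).
Jaccard dissimilarity is 1 - |A & B| / |A | B| on OTU presence sets, presence
meaning count >= 1.
"""

from __future__ import annotations

from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from .io_core import OTUTable, ValidationError

__all__ = ["bray_curtis", "jaccard"]


def _check_table(table: OTUTable) -> None:
    if table.n_replicates < 2:
        raise ValidationError("need at least 2 replicates for a distance matrix")
    depths = table.depths()
    zero = depths[depths == 0]
    if len(zero):
        raise ValidationError(f"all-zero replicate(s): {list(zero.index)}")


def bray_curtis(table: OTUTable, normalize: bool = True) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between replicate columns.

    Parameters
    ----------
    table : OTUTable
    normalize : bool
        When True (default) compute on column-relative proportions; when
        False, on raw counts.
    """
    _check_table(table)
    x = table.proportions().to_numpy().T if normalize else table.counts.to_numpy().T
    d = squareform(pdist(x.astype(float), metric="braycurtis"), checks=False)
    return DistanceMatrix(d, ids=table.replicate_ids)


def jaccard(table: OTUTable) -> DistanceMatrix:
    """Jaccard dissimilarity on OTU presence/absence (count >= 1)."""
    _check_table(table)
    x = (table.counts.to_numpy().T > 0)
    d = squareform(pdist(x, metric="jaccard"), checks=False)
    return DistanceMatrix(d, ids=table.replicate_ids)
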