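import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2_contingency
from skbio import DistanceMatrix

from conftest import make_metadata
from ebbflow.io_core import OTUTable, ValidationError
from ebbflow.ordination import (
    CommunityAssignment,
    assign_communities,
    cca_constrained,
    high_leverage_otus,
    nmds,
)


def block_distance_matrix(sizes, within, between, seed=0):
    rng = np.random.default_rng(seed)
    n = sum(sizes)
    labels = np.repeat(np.arange(len(sizes)), sizes)
    d = np.where(labels[:, None] == labels[None, :], within, between).astype(float)
    d += rng.uniform(0, 0.02, size=(n, n))
    d = (d + d.T) / 2
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(d, ids=[f"r{i}" for i in range(n)]), labels


class TestNMDS:
    def test_planar_configuration_embeds_with_low_stress(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [0.5, 0.5],
                        [0.2, 0.8]], dtype=float)
        d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
        dm = DistanceMatrix(d, ids=[f"p{i}" for i in range(len(pts))])
        res = nmds(dm, k=2, n_starts=8, seed=0)
        assert res.stress < 0.01
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_deterministic_given_seed(self):
        dm, _ = block_distance_matrix([5, 5], 0.1, 0.8)
        r1 = nmds(dm, seed=7)
        r2 = nmds(dm, seed=7)
        pd.testing.assert_frame_equal(r1.coordinates, r2.coordinates)
        assert r1.stress == r2.stress

    def test_two_groups_separate_in_embedding(self):
        dm, labels = block_distance_matrix([6, 6], 0.1, 0.8, seed=1)
        res = nmds(dm, seed=0)
        xy = res.coordinates.to_numpy()
        within, between = [], []
        for i in range(12):
            for j in range(i + 1, 12):
                dist = np.linalg.norm(xy[i] - xy[j])
                (within if labels[i] == labels[j] else between).append(dist)
        assert min(between) > max(within)

    def test_too_few_samples_rejected(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.raises(ValidationError):
            nmds(dm, k=2, seed=0)


class TestAssignCommunities:
    def test_planted_partition_recovered(self):
        dm, labels = block_distance_matrix([6, 4], 0.1, 0.7, seed=2)
        res = assign_communities(dm, 2)
        got = res.labels.to_numpy()
        expect = labels + 1
        assert (np.all(got == expect) or np.all(got == (3 - expect)))
        assert res.silhouette > 0.5

    def test_degenerate_identical_samples_warn(self):
        dm = DistanceMatrix(np.zeros((4, 4)), ids=list("abcd"))
        with pytest.warns(UserWarning, match="identical"):
            res = assign_communities(dm, 2)
        assert res.silhouette == 0.0

    def test_label_one_spans_more_sites(self):
        dm, _ = block_distance_matrix([6, 3], 0.1, 0.7, seed=3)
        rows = []
        for i in range(9):
            site = f"s{i % 3}" if i < 6 else "s9"  # first cluster: 3 sites
            rows.append({"replicate_id": f"r{i}", "bottle_id": f"b{i}",
                         "event_id": f"e{i}", "site_id": site})
        meta = make_metadata(rows)
        res = assign_communities(dm, 2, meta)
        assert set(res.labels.iloc[:6]) == {1}
        assert set(res.labels.iloc[6:]) == {2}
        assert res.event_labels is not None

    def test_too_many_communities_rejected(self):
        dm = DistanceMatrix(np.ones((3, 3)) - np.eye(3), ids=list("abc"))
        with pytest.raises(ValidationError):
            assign_communities(dm, 5)


def two_community_table(seed=0, n_otus=40, n_each=6, depth=4000,
                        n_up=6, fold=30.0):
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0, 1, n_otus)
    p2 = base.copy()
    p2[:n_up] *= fold
    cols, y = {}, []
    for j in range(2 * n_each):
        label = 1 if j < n_each else 2
        prof = base if label == 1 else p2
        cols[f"r{j}"] = rng.multinomial(depth, prof / prof.sum())
        y.append(label)
    table = OTUTable(pd.DataFrame(cols, index=[f"O{i}" for i in range(n_otus)]))
    labels = CommunityAssignment(
        labels=pd.Series(y, index=table.replicate_ids), silhouette=1.0)
    return table, labels


class TestCCA:
    def test_no_signal_limit(self):
        table, labels = two_community_table(seed=1, n_up=0)
        res = cca_constrained(table, labels)
        assert res.constrained_inertia_fraction < 0.2
        assert res.otu_scores.abs().max() < 0.3

    def test_exclusive_otu_scores_positive_and_large(self):
        table, labels = two_community_table(seed=2)
        counts = table.counts.copy()
        counts.loc["EXC"] = 0
        reps2 = [r for r in table.replicate_ids
                 if labels.labels[r] == 2]
        counts.loc["EXC", reps2] = 300
        table2 = OTUTable(counts)
        res = cca_constrained(table2, labels)
        assert res.otu_scores["EXC"] > 0
        assert res.otu_scores.abs().rank(pct=True)["EXC"] > 0.95

    def test_total_inertia_is_chisquare_over_n(self):
        table, labels = two_community_table(seed=3)
        res = cca_constrained(table, labels)
        x = table.counts.to_numpy()
        x = x[x.sum(axis=1) > 0]
        chi2 = chi2_contingency(x, correction=False).statistic
        assert res.total_inertia == pytest.approx(chi2 / x.sum(), abs=1e-9)

    def test_order_invariance_up_to_sign(self):
        table, labels = two_community_table(seed=4)
        res1 = cca_constrained(table, labels)
        rng = np.random.default_rng(0)
        rp = rng.permutation(table.n_replicates)
        op = rng.permutation(table.n_otus)
        shuffled = OTUTable(table.counts.iloc[op, rp])
        res2 = cca_constrained(shuffled, labels)
        s1 = res1.otu_scores.sort_index()
        s2 = res2.otu_scores.sort_index()
        assert np.allclose(s1, s2, atol=1e-9) or np.allclose(s1, -s2, atol=1e-9)
        # sign convention makes them equal, not flipped
        assert np.allclose(s1, s2, atol=1e-9)

    def test_single_community_rejected(self):
        table, labels = two_community_table(seed=5)
        one = CommunityAssignment(
            labels=pd.Series(1, index=table.replicate_ids), silhouette=0.0)
        with pytest.raises(ValidationError):
            cca_constrained(table, one)

    def test_matches_vegan_species_scores(self, tmp_path):
        """Independent oracle: vegan's cca() with scaling-2 species scores."""
        table, labels = two_community_table(seed=6, n_otus=25, n_each=5)
        tsv = tmp_path / "counts.tsv"
        table.counts.to_csv(tsv, sep="\t")
        out = tmp_path / "scores.csv"
        script = tmp_path / "cca.R"
        script.write_text(textwrap.dedent(f"""
            library(vegan)
            x <- read.delim("{tsv}", row.names=1)
            y <- factor(c(rep(1, 5), rep(2, 5)))
            m <- cca(t(x) ~ y)
            sp <- scores(m, display="species", choices=1, scaling=2)
            write.csv(sp, "{out}")
        """))
        subprocess.run(["Rscript", "--vanilla", str(script)], check=True,
                       capture_output=True)
        veg = pd.read_csv(out, index_col=0)["CCA1"]
        ours = cca_constrained(table, labels).otu_scores
        ratio = (veg / ours).dropna()
        sign = np.sign(ratio.median())
        np.testing.assert_allclose(ours.loc[veg.index] * sign, veg, atol=1e-6)


class TestHighLeverage:
    def _cca(self, scores):
        from ebbflow.ordination import CCAResult
        return CCAResult(
            otu_scores=pd.Series(scores),
            replicate_scores=pd.Series(dtype=float),
            singular_value=1.0, constrained_inertia_fraction=0.5,
            total_inertia=1.0)

    def _table(self, totals):
        return OTUTable(pd.DataFrame({"r1": list(totals.values())},
                                     index=list(totals)))

    def test_read_count_and_score_cutoffs(self):
        cca = self._cca({"A": 0.71, "B": 0.70, "C": -0.9, "D": 2.0})
        table = self._table({"A": 999, "B": 5000, "C": 5000, "D": 1000})
        out = high_leverage_otus(cca, table, 0.7, 1000)
        # A: score ok but 999 reads; B: exactly 0.70 is excluded (strict >)
        assert list(out.index) == ["D", "C"]

    def test_empty_result_is_not_an_error(self):
        cca = self._cca({"A": 0.1})
        out = high_leverage_otus(cca, self._table({"A": 10_000}))
        assert len(out) == 0
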