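import dataclasses
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import SMALL_SIM, make_dataset
from ebbflow.io_core import ValidationError
from ebbflow.quality_control import (
    DEFAULT_P10_MAX,
    DetectionHistory,
    OccupancyEstimate,
    QCReport,
    build_detection_histories,
    conditional_occupancy,
    control_profile,
    drop_discordant,
    fit_dissimilarity_threshold,
    fit_occupancy,
    fit_occupancy_all,
    occupancy_filter,
    occupancy_loglik,
    rarefy,
    replicate_dissimilarities,
    retention_percentage,
    subtract_contamination,
)
from ebbflow.synthetic_data import generate_dataset


def two_bottle_dataset():
    meta = [
        {"replicate_id": f"b1.r{i}", "bottle_id": "b1"} for i in range(3)
    ] + [
        {"replicate_id": f"b2.r{i}", "bottle_id": "b2"} for i in range(3)
    ]
    counts = {
        "b1.r0": [3, 0, 10], "b1.r1": [0, 0, 10], "b1.r2": [1, 0, 10],
        "b2.r0": [0, 0, 10], "b2.r1": [0, 0, 10], "b2.r2": [0, 0, 10],
    }
    return make_dataset(counts, meta)


class TestDetectionHistories:
    def test_detection_counts_per_bottle(self):
        ds = two_bottle_dataset()
        hist = {h.otu_id: h for h in build_detection_histories(ds)}
        h = hist["O0"]  # counts 3,0,1 in bottle 1 -> K=3, d=2
        assert h.n_trials == (3, 3)
        assert h.n_detections == (2, 0)

    def test_all_zero_otu_has_no_history(self):
        ds = two_bottle_dataset()
        ids = {h.otu_id for h in build_detection_histories(ds)}
        assert "O1" not in ids  # all-zero row
        assert ids == {"O0", "O2"}

    def test_bookkeeping_on_simulated_design(self, small_sim):
        dataset, truth = small_sim
        cfg = truth.config
        n_bottles = cfg.n_sites * cfg.n_events_per_site * cfg.n_bottles_per_event
        for h in build_detection_histories(dataset):
            assert len(h.n_trials) == n_bottles
            assert all(k == cfg.n_pcr_per_bottle for k in h.n_trials)


class TestOccupancyModel:
    def test_conditional_occupancy_worked_case(self):
        # psi=0.5, p11=0.8, p10=0.05, one sample with d=1 of K=3:
        # 0.016 / (0.016 + 0.0225625)
        got = conditional_occupancy(1, 3, 0.5, 0.8, 0.05)
        assert got == pytest.approx(0.4149, abs=1e-4)

    def test_conditional_monotone_in_detections(self):
        vals = [conditional_occupancy(d, 5, 0.4, 0.7, 0.1) for d in range(6)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))

    def test_saturated_detection_forces_occupancy(self):
        h = DetectionHistory("x", tuple(f"s{i}" for i in range(30)),
                             (3,) * 30, (3,) * 30)
        est = fit_occupancy(h)
        assert est.otu_score >= 0.99
        assert est.psi >= 0.99

    def test_estimate_invariants(self, small_sim):
        dataset, _ = small_sim
        hist = build_detection_histories(dataset)
        for est in fit_occupancy_all(hist[:40]):
            assert est.p11 >= est.p10
            assert 0.0 <= est.otu_score <= 1.0
            assert est.loglik <= 1e-9

    @pytest.mark.parametrize("pairs", [
        # scattered false-positive-like detections
        (((3, 0, 29), (3, 1, 6), (3, 2, 1))),
        # strong heterogeneous occupancy
        (((3, 0, 10), (3, 2, 5), (3, 3, 21))),
        # moderate homogeneous detection
        (((3, 1, 12), (3, 2, 18), (3, 3, 6))),
    ])
    def test_optimum_beats_brute_force_grid(self, pairs):
        """The returned likelihood is >= every point of a 21^3 grid over the
        model's parameter space (psi, p11, p10 <= min(p11, p10_max))."""
        samples, trials, dets = [], [], []
        i = 0
        for k, d, m in pairs:
            for _ in range(m):
                samples.append(f"s{i}"); trials.append(k); dets.append(d)
                i += 1
        h = DetectionHistory("x", tuple(samples), tuple(trials), tuple(dets))
        est = fit_occupancy(h)
        agg = h.aggregated()
        grid = np.linspace(1e-6, 1 - 1e-6, 21)
        best = -np.inf
        for psi, p11 in itertools.product(grid, grid):
            for p10 in np.linspace(0.0, min(p11, DEFAULT_P10_MAX), 21):
                best = max(best, occupancy_loglik(psi, p11, p10, agg))
        assert est.loglik >= best - 1e-6


def _estimates(scores: dict) -> list:
    return [
        OccupancyEstimate(otu_id=o, psi=s, p11=0.9, p10=0.01, loglik=-1.0,
                          sample_ids=("s1",), conditional=(s,), otu_score=s)
        for o, s in scores.items()
    ]


class TestOccupancyFilter:
    def test_threshold_is_strict_below(self):
        ds = two_bottle_dataset()
        est = _estimates({"O0": 0.80, "O2": 0.799})
        out, rec = occupancy_filter(ds, est, 0.80)
        assert out.table.otu_ids == ["O0"]
        assert rec.otus_in == 3 and rec.otus_out == 1

    def test_zero_threshold_is_identity(self):
        ds = two_bottle_dataset()
        out, _ = occupancy_filter(ds, _estimates({"O0": 0.5}), 0.0)
        assert out.table.equals(ds.table)

    def test_bad_threshold_rejected(self):
        ds = two_bottle_dataset()
        with pytest.raises(Exception, match="threshold"):
            occupancy_filter(ds, [], 1.01)


def control_dataset():
    meta = [
        {"replicate_id": "f1", "bottle_id": "b1"},
        {"replicate_id": "f2", "bottle_id": "b1"},
        {"replicate_id": "c1", "bottle_id": "cb", "event_id": "ce",
         "site_id": "ctrl", "role": "positive_control"},
        {"replicate_id": "c2", "bottle_id": "cb", "event_id": "ce",
         "site_id": "ctrl", "role": "positive_control"},
    ]
    counts = {
        "f1": [250, 700, 50], "f2": [100, 850, 50],
        "c1": [10, 0, 90], "c2": [30, 0, 70],
    }
    return make_dataset(counts, meta)


class TestContamination:
    def test_profile_is_max_of_control_proportions(self):
        prof = control_profile(control_dataset())
        assert prof.get("O0") == pytest.approx(0.30)
        assert prof.get("O1") == 0.0
        assert prof.get("O2") == pytest.approx(0.90)

    def test_no_controls_is_instructive_error(self, small_sim):
        dataset, _ = small_sim
        field_only = dataclasses.replace(
            dataset,
            table=dataset.field_table(),
            metadata=dataset.metadata.select(dataset.metadata.field_replicates()),
        )
        with pytest.raises(ValidationError, match="skip"):
            control_profile(field_only)

    def test_subtraction_rule(self):
        ds = control_dataset()
        prof = control_profile(ds)
        out, rec = subtract_contamination(ds, prof)
        # f1: depth 1000, O0 count 250, c=0.30 -> floor((0.25-0.30)*1000) -> 0
        assert "O0" not in out.table.otu_ids or out.table.counts.loc["O0", "f1"] == 0
        # O1: c=0 -> unchanged
        assert out.table.counts.loc["O1", "f1"] == 700
        # controls removed
        assert set(out.table.replicate_ids) == {"f1", "f2"}
        assert rec.reads_out <= rec.reads_in

    def test_worked_proportion_example(self):
        meta = [{"replicate_id": "f1", "bottle_id": "b1"},
                {"replicate_id": "c1", "bottle_id": "cb", "event_id": "ce",
                 "site_id": "ctrl", "role": "positive_control"}]
        counts = {"f1": [250, 750], "c1": [10, 90]}
        ds = make_dataset(counts, meta)
        prof = control_profile(ds)
        assert prof.get("O0") == pytest.approx(0.10)
        out, _ = subtract_contamination(ds, prof)
        # p' = 0.25 - 0.10 = 0.15 -> floor(0.15 * 1000) = 150
        assert out.table.counts.loc["O0", "f1"] == 150

    def test_zero_profile_bit_identical_on_fields(self, small_sim):
        dataset, _ = small_sim
        zero = control_profile(dataclasses.replace(dataset))
        zero = dataclasses.replace(zero, proportions=zero.proportions * 0.0)
        out, _ = subtract_contamination(dataset, zero)
        field = dataset.field_table().drop_empty_otus()
        assert out.table.equals(field)


class TestReplicateDissimilarities:
    def test_pairs_and_identical_replicates(self):
        meta = [{"replicate_id": f"r{i}", "bottle_id": "b1"} for i in range(3)]
        ds = make_dataset({"r0": [5, 5], "r1": [5, 5], "r2": [5, 5]}, meta)
        out = replicate_dissimilarities(ds)
        assert len(out) == 3  # C(3,2)
        assert all(v == 0.0 for _, _, v in out)

    def test_requires_a_multi_replicate_bottle(self):
        ds = make_dataset({"r0": [1, 2]}, [{"replicate_id": "r0"}])
        with pytest.raises(ValidationError):
            replicate_dissimilarities(ds)


class TestDissimilarityThreshold:
    def test_beta_recovery_against_closed_form(self):
        """Beta(2,8) samples: family selected is beta and the threshold is
        close to the true 97.5% quantile (0.4825 by closed form)."""
        true_q = stats.beta.ppf(0.975, 2, 8)
        hits, close = 0, 0
        for seed in range(10):
            v = np.random.default_rng(seed).beta(2, 8, 500)
            family, _, thr = fit_dissimilarity_threshold(v)
            hits += family == "beta"
            close += abs(thr - true_q) <= 0.05
        assert hits >= 9
        assert close >= 9

    def test_constant_values_rejected(self):
        with pytest.raises(ValidationError, match="manual threshold"):
            fit_dissimilarity_threshold([0.3] * 50)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            fit_dissimilarity_threshold([0.1, 0.2, 0.3])


class TestDropDiscordant:
    def test_concordant_bottle_untouched(self):
        meta = [{"replicate_id": f"r{i}", "bottle_id": "b1"} for i in range(3)]
        ds = make_dataset({"r0": [10, 10], "r1": [11, 9], "r2": [10, 11]}, meta)
        out, rec = drop_discordant(ds, 0.49)
        assert out.table.n_replicates == 3
        assert not rec.replicates_dropped

    def test_outlier_replicate_removed(self):
        meta = [{"replicate_id": r, "bottle_id": "b1"} for r in ("A", "B", "C")]
        ds = make_dataset({"A": [90, 10], "B": [88, 12], "C": [5, 95]}, meta)
        out, rec = drop_discordant(ds, 0.49)
        assert set(out.table.replicate_ids) == {"A", "B"}
        assert rec.replicates_dropped == ("C",)
        assert not rec.samples_dropped

    def test_two_replicate_bottle_dropped_whole(self):
        meta = [{"replicate_id": r, "bottle_id": "b1"} for r in ("A", "B")]
        ds = make_dataset({"A": [90, 10], "B": [10, 90]}, meta)
        out, rec = drop_discordant(ds, 0.6)
        assert out.table.n_replicates == 0
        assert rec.samples_dropped == ("b1",)
        assert set(rec.replicates_dropped) == {"A", "B"}


class TestRarefy:
    def test_conservation_and_bounds(self, small_sim):
        dataset, truth = small_sim
        depth = truth.config.reads_per_replicate - 200
        out, rec = rarefy(dataset, depth, seed=1)
        assert (out.table.depths() == depth).all()
        orig = dataset.table.counts.loc[out.table.counts.index,
                                        out.table.replicate_ids]
        assert (out.table.counts.to_numpy() <= orig.to_numpy()).all()
        assert rec.reads_out <= rec.reads_in

    def test_shallow_replicate_dropped_and_reported(self):
        meta = [{"replicate_id": "deep", "bottle_id": "b1"},
                {"replicate_id": "shallow", "bottle_id": "b1"}]
        ds = make_dataset({"deep": [900, 200], "shallow": [40, 40]}, meta)
        out, rec = rarefy(ds, 100, seed=0)
        assert out.table.replicate_ids == ["deep"]
        assert rec.replicates_dropped == ("shallow",)

    def test_depth_above_all_is_error(self):
        ds = make_dataset({"r0": [5, 5]}, [{"replicate_id": "r0"}])
        with pytest.raises(ValidationError):
            rarefy(ds, 100, seed=0)

    def test_deterministic_and_stable_across_draws(self, default_sim):
        """Two rarefaction draws of the same replicate differ by a tiny
        Bray–Curtis distance (the draws are interchangeable)."""
        dataset, truth = default_sim
        d1, _ = rarefy(dataset, 18_500, seed=1)
        d1b, _ = rarefy(dataset, 18_500, seed=1)
        assert d1.table.equals(d1b.table)
        d2, _ = rarefy(dataset, 18_500, seed=2)
        rep = dataset.metadata.field_replicates()[0]
        a = d1.table.counts[rep].reindex(dataset.table.counts.index, fill_value=0)
        b = d2.table.counts[rep].reindex(dataset.table.counts.index, fill_value=0)
        bc = np.abs(a - b).sum() / (a + b).sum()
        assert bc < 0.05


def test_retention_percentage_formula():
    assert retention_percentage(200, 150) == pytest.approx(75.0)
    with pytest.raises(ValidationError):
        retention_percentage(0, 0)


def test_qc_chain_is_monotone(small_sim):
    """Every stage of the chain can only shrink reads and OTUs."""
    dataset, _ = small_sim
    report = QCReport()
    est = fit_occupancy_all(build_detection_histories(dataset))
    dataset, rec = occupancy_filter(dataset, est, 0.80)
    report.add(rec)
    dataset, rec = subtract_contamination(dataset, control_profile(dataset))
    report.add(rec)
    dataset, rec = drop_discordant(dataset, 0.49)
    report.add(rec)
    dataset, rec = rarefy(dataset, 1500, seed=0)
    report.add(rec)
    for stage in report.stages:
        assert stage.reads_out <= stage.reads_in
        assert stage.otus_out <= stage.otus_in
    assert report.retained_read_percentage() <= 100.0
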