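"""Synthetic eDNA metabarcoding datasets with known ground truth.

Emulates the nested tidal field design: ``n_sites`` shore sites, each visited
``n_events_per_site`` times over successive tides, three 1-L bottles per
visit, three PCR replicates per bottle, sequenced to ~2e4 reads each.

The generative model works in log-abundance space so that the hierarchical
variance components compose additively:

1. two latent water-mass community profiles (log-normal relative abundances;
   community 2 is community 1 with a planted enrichment of a known OTU
   subset — a bloom in the fresh/cold intrusion),
2. per-site, per-event, per-bottle and per-PCR log-normal perturbations;
   site differences dominate, PCR (amplification) noise exceeds bottle
   noise as in real amplicon data, and the pure event effect is near zero —
   events differ when the water mass does,
3. water-mass labels: the estuarine (last) site sees the community-2
   intrusion during part of its events, and the label drives the
   salinity/temperature covariates — tide itself is a pure label by default
   (tide_effect_sd = 0), so "tide explains the least variance" is the
   simulator's null truth,
4. read counts drawn multinomially per replicate,
5. nuisance processes: rare spurious OTUs appearing independently at 1–5
   reads, and tag-jump style cross-contamination between field samples and
   the positive (ostrich-like) controls.

Everything needed to score the QC chain — community labels and profiles,
spurious OTU ids, the contaminant OTU and its leak rates, the planted
differential OTUs — is returned as :class:`SyntheticTruth`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_core import (
    METADATA_COLUMNS,
    Dataset,
    OTUTable,
    SampleMetadata,
    read_metadata,
    read_otu_table,
    validate_dataset,
    write_metadata,
    write_otu_table,
)

__all__ = ["SimConfig", "SyntheticTruth", "generate_dataset", "write_fixture", "read_fixture"]

CONTAMINANT_OTU_ID = "OTU_contaminant"


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic world; defaults mirror the field design."""

    n_sites: int = 3
    n_events_per_site: int = 4
    n_bottles_per_event: int = 3
    n_pcr_per_bottle: int = 3
    n_otus: int = 500
    reads_per_replicate: int = 20_000
    # log-scale perturbation SDs; site dominates, PCR (amplification)
    # noise exceeds bottle noise as in real amplicon data, and the pure
    # event effect is near zero — events differ when the water mass does
    site_effect_sd: float = 0.6
    event_effect_sd: float = 0.05
    bottle_effect_sd: float = 0.10
    pcr_effect_sd: float = 0.40
    tide_effect_sd: float = 0.0
    base_profile_sd: float = 1.0
    n_differential_otus: int = 40
    differential_log_fold: float = 4.0  # ~55-fold enrichment in community 2
    community2_event_fraction: float = 0.25
    salinity_means: tuple[float, float] = (27.0, 17.0)  # ppt, community 1 / 2
    temperature_means: tuple[float, float] = (10.0, 8.0)  # degrees C
    covariate_sd: float = 1.0
    n_spurious_otus: int = 50
    spurious_false_detect_p: float = 0.05
    tagjump_rate: float = 0.02
    contaminant_otu_reads_in_controls: float = 0.95
    n_positive_controls: int = 3
    event_spacing_hours: float = 6.5
    seed: int = 0
    # optional override of per-event community labels, keyed (site_idx, event_idx)
    community_overrides: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("n_sites", "n_events_per_site", "n_bottles_per_event",
                     "n_pcr_per_bottle", "n_otus", "reads_per_replicate"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("site_effect_sd", "event_effect_sd", "bottle_effect_sd",
                     "pcr_effect_sd", "tide_effect_sd", "base_profile_sd",
                     "covariate_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        for name in ("community2_event_fraction", "spurious_false_detect_p",
                     "tagjump_rate", "contaminant_otu_reads_in_controls"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.n_spurious_otus < 0 or self.n_spurious_otus >= self.n_otus:
            raise ConfigurationError("n_spurious_otus must be in [0, n_otus)")
        if self.n_differential_otus > self.n_otus - self.n_spurious_otus:
            raise ConfigurationError("more differential OTUs than real OTUs")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of one simulated dataset."""

    community_labels: dict[str, int]  # event_id -> 1 or 2
    profiles: dict[int, np.ndarray]  # community -> relative abundance over otu_ids
    otu_ids: list[str]
    spurious_otu_ids: list[str]
    differential_otu_ids: list[str]
    contaminant_otu_id: str
    control_leak_proportions: np.ndarray  # expected control proportion per OTU
    contaminant_max_leak_rate: float  # max injected field proportion of contaminant
    config: SimConfig

    def to_json_dict(self) -> dict:
        d = {
            "community_labels": self.community_labels,
            "profiles": {str(k): v.tolist() for k, v in self.profiles.items()},
            "otu_ids": list(self.otu_ids),
            "spurious_otu_ids": list(self.spurious_otu_ids),
            "differential_otu_ids": list(self.differential_otu_ids),
            "contaminant_otu_id": self.contaminant_otu_id,
            "control_leak_proportions": self.control_leak_proportions.tolist(),
            "contaminant_max_leak_rate": self.contaminant_max_leak_rate,
            "config": {
                k: (list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.config).items()
                if k != "community_overrides"
            },
        }
        d["config"]["community_overrides"] = {
            f"{s}:{e}": int(v) for (s, e), v in self.config.community_overrides.items()
        }
        return d

    @staticmethod
    def from_json_dict(d: dict) -> "SyntheticTruth":
        cfg = dict(d["config"])
        cfg["salinity_means"] = tuple(cfg["salinity_means"])
        cfg["temperature_means"] = tuple(cfg["temperature_means"])
        cfg["community_overrides"] = {
            tuple(int(x) for x in k.split(":")): v
            for k, v in cfg.get("community_overrides", {}).items()
        }
        return SyntheticTruth(
            community_labels={k: int(v) for k, v in d["community_labels"].items()},
            profiles={int(k): np.asarray(v) for k, v in d["profiles"].items()},
            otu_ids=list(d["otu_ids"]),
            spurious_otu_ids=list(d["spurious_otu_ids"]),
            differential_otu_ids=list(d["differential_otu_ids"]),
            contaminant_otu_id=d["contaminant_otu_id"],
            control_leak_proportions=np.asarray(d["control_leak_proportions"]),
            contaminant_max_leak_rate=float(d["contaminant_max_leak_rate"]),
            config=SimConfig(**cfg),
        )


def _softmax_log_profile(log_base: np.ndarray, *perturbations: np.ndarray) -> np.ndarray:
    z = log_base + sum(perturbations)
    z = z - z.max()
    p = np.exp(z)
    return p / p.sum()


def generate_dataset(config: SimConfig = SimConfig()) -> tuple[Dataset, SyntheticTruth]:
    """Draw one dataset + truth; bit-reproducible for a given config/seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)

    n_real = config.n_otus - config.n_spurious_otus
    real_ids = [f"OTU_{i + 1:04d}" for i in range(n_real)]
    spurious_ids = [f"OTU_{i + 1:04d}" for i in range(n_real, config.n_otus)]
    otu_ids = real_ids + spurious_ids + [CONTAMINANT_OTU_ID]
    n_total = len(otu_ids)

    # latent community profiles over real OTUs (log scale)
    # community 2 (the fresh/cold intrusion) is marked by a bloom of a known
    # OTU subset; compositional closure suppresses the remaining (marine)
    # taxa relatively, so both directions of change are represented
    log_c1 = rng.normal(0.0, config.base_profile_sd, size=n_real)
    diff_idx = rng.choice(n_real, size=config.n_differential_otus, replace=False)
    log_c2 = log_c1.copy()
    log_c2[diff_idx] += config.differential_log_fold
    differential_ids = [real_ids[i] for i in sorted(diff_idx)]

    tide_vectors = {
        "incoming": rng.normal(0.0, config.tide_effect_sd, size=n_real),
        "outgoing": rng.normal(0.0, config.tide_effect_sd, size=n_real),
    }

    start = pd.Timestamp("2017-03-01T08:00:00")
    meta_rows: list[dict] = []
    columns: dict[str, np.ndarray] = {}
    expected_props: list[np.ndarray] = []  # per field replicate, over real OTUs
    community_labels: dict[str, int] = {}

    for s in range(config.n_sites):
        site_id = f"site{s + 1}"
        site_vec = rng.normal(0.0, config.site_effect_sd, size=n_real)
        for e in range(config.n_events_per_site):
            event_id = f"{site_id}.e{e + 1}"
            # community 2 intrudes only at the estuarine site (the last one),
            # mirroring the freshwater-influenced end of the fjord; the
            # per-event probability is scaled so community2_event_fraction
            # stays the expected fraction of all events
            p2 = min(1.0, config.community2_event_fraction * config.n_sites)
            estuarine = s == config.n_sites - 1
            if (s, e) in config.community_overrides:
                comm = int(config.community_overrides[(s, e)])
            elif estuarine and 0.0 < p2 < 1.0:
                if e == 0:
                    # the estuarine site hosts both water masses within the
                    # sampling window: round(p2 * n_events) of its events see
                    # the fresh/cold intrusion, at random positions
                    k = int(round(p2 * config.n_events_per_site))
                    k = max(1, min(config.n_events_per_site - 1, k))
                    pos = rng.choice(config.n_events_per_site, size=k,
                                     replace=False)
                    estuarine_labels = [
                        2 if i in set(pos.tolist()) else 1
                        for i in range(config.n_events_per_site)
                    ]
                comm = estuarine_labels[e]
            elif estuarine:
                comm = 2 if p2 >= 1.0 else 1
            else:
                comm = 1
            community_labels[event_id] = comm
            log_base = log_c1 if comm == 1 else log_c2
            event_vec = rng.normal(0.0, config.event_effect_sd, size=n_real)
            tide = "incoming" if e % 2 == 0 else "outgoing"
            timestamp = start + pd.Timedelta(hours=config.event_spacing_hours * e)
            salinity = rng.normal(config.salinity_means[comm - 1], config.covariate_sd)
            temperature = rng.normal(config.temperature_means[comm - 1], config.covariate_sd)
            tidal_height = rng.uniform(0.2, 3.0)
            for b in range(config.n_bottles_per_event):
                bottle_id = f"{event_id}.b{b + 1}"
                bottle_vec = rng.normal(0.0, config.bottle_effect_sd, size=n_real)
                for r in range(config.n_pcr_per_bottle):
                    rep_id = f"{bottle_id}.r{r + 1}"
                    # reaction-to-reaction quality varies: the amplification
                    # noise scale is itself log-normal (heavy-tailed pairs,
                    # as in real replicate dissimilarity distributions)
                    pcr_scale = config.pcr_effect_sd * np.exp(
                        rng.normal(0.0, 0.6))
                    pcr_vec = rng.normal(0.0, pcr_scale, size=n_real)
                    p = _softmax_log_profile(
                        log_base, site_vec, event_vec, tide_vectors[tide],
                        bottle_vec, pcr_vec,
                    )
                    expected_props.append(p)
                    counts = np.zeros(n_total, dtype=np.int64)
                    counts[:n_real] = rng.multinomial(config.reads_per_replicate, p)
                    columns[rep_id] = counts
                    meta_rows.append({
                        "replicate_id": rep_id,
                        "bottle_id": bottle_id,
                        "event_id": event_id,
                        "site_id": site_id,
                        "tide_direction": tide,
                        "tidal_height_m": tidal_height,
                        "salinity_ppt": salinity,
                        "temperature_c": temperature,
                        "timestamp": timestamp,
                        "role": "field",
                    })

    field_ids = list(columns)
    mean_field_prop = np.mean(expected_props, axis=0)  # over real OTUs

    # spurious OTUs: sporadic low-count appearances in field replicates
    if config.n_spurious_otus:
        for rep_id in field_ids:
            hits = rng.random(config.n_spurious_otus) < config.spurious_false_detect_p
            if hits.any():
                reads = rng.integers(1, 6, size=int(hits.sum()))
                idx = np.flatnonzero(hits) + n_real
                columns[rep_id][idx] += reads

    # contaminant leakage into field replicates (tag jumping), rate <= lambda
    leak_rates = rng.uniform(0.0, config.tagjump_rate, size=len(field_ids))
    for rep_id, rate in zip(field_ids, leak_rates):
        columns[rep_id][n_total - 1] += int(round(rate * config.reads_per_replicate))
    contaminant_max_leak_rate = float(leak_rates.max()) if len(leak_rates) else 0.0

    # positive controls: contaminant-dominated, receiving tag-jump leakage
    # lambda * (field mean proportion) from every field OTU
    control_q = np.zeros(n_total)
    control_q[:n_real] = config.tagjump_rate * mean_field_prop
    control_q[n_total - 1] = config.contaminant_otu_reads_in_controls
    control_q = control_q / control_q.sum()
    for c in range(config.n_positive_controls):
        rep_id = f"control.b1.r{c + 1}"
        columns[rep_id] = rng.multinomial(config.reads_per_replicate, control_q)
        meta_rows.append({
            "replicate_id": rep_id,
            "bottle_id": "control.b1",
            "event_id": "control.e1",
            "site_id": "control",
            "tide_direction": np.nan,
            "tidal_height_m": np.nan,
            "salinity_ppt": np.nan,
            "temperature_c": np.nan,
            "timestamp": start,
            "role": "positive_control",
        })

    table = OTUTable(pd.DataFrame(columns, index=otu_ids))
    meta_df = pd.DataFrame(meta_rows).set_index("replicate_id")
    metadata = SampleMetadata(meta_df)
    dataset = validate_dataset(table, metadata)

    def _full_profile(log_base: np.ndarray) -> np.ndarray:
        prof = np.zeros(n_total)
        p = np.exp(log_base - log_base.max())
        prof[:n_real] = p / p.sum()
        return prof

    truth = SyntheticTruth(
        community_labels=community_labels,
        profiles={1: _full_profile(log_c1), 2: _full_profile(log_c2)},
        otu_ids=otu_ids,
        spurious_otu_ids=spurious_ids,
        differential_otu_ids=differential_ids,
        contaminant_otu_id=CONTAMINANT_OTU_ID,
        control_leak_proportions=control_q,
        contaminant_max_leak_rate=contaminant_max_leak_rate,
        config=config,
    )
    return dataset, truth


def write_fixture(dataset: Dataset, truth: SyntheticTruth, out_dir: str | Path) -> None:
    """Write otu_table.tsv, metadata.tsv and truth.json; round-trips via io_core."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_otu_table(dataset.table, out / "otu_table.tsv")
    write_metadata(dataset.metadata, out / "metadata.tsv")
    with (out / "truth.json").open("w", encoding="utf-8") as fh:
        json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)


def read_fixture(fixture_dir: str | Path) -> tuple[Dataset, SyntheticTruth]:
    d = Path(fixture_dir)
    table = read_otu_table(d / "otu_table.tsv")
    metadata = read_metadata(d / "metadata.tsv")
    with (d / "truth.json").open("r", encoding="utf-8") as fh:
        truth = SyntheticTruth.from_json_dict(json.load(fh))
    return validate_dataset(table, metadata), truth
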