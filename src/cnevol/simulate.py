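"""Clonal-evolution simulator with full ground truth.

Each patient is a rooted tree of clones descending from a near-diploid
founder.  Along every branch a Poisson number of segmental events occurs;
an event picks one haplotype, a contiguous run of segments (geometric run
length, mean 3), and a sign, and applies +/-1 with zero absorption --
exactly the event model the minimum-event distance counts.  Leaves are
the sampled clones.

Tree shape follows ``topology_mode``: ``star`` attaches every leaf to the
root (independent seeding from the primary), ``branched`` grows a random
bifurcating tree by sequential attachment (metastasis-to-metastasis
spread).  ``expansion_mode='clusters'`` plants tight clonal clusters by
shrinking within-cluster branch event counts, the signature the CE index
is designed to detect.  Survival times are exponential with the hazard
scaled by ``exp(group_log_hr)`` for patients in the high-risk group, with
administrative censoring at a fixed horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .profiles import AlleleProfile, PatientDataset, SampleRecord, Segment, write_cohort

__all__ = ["SimulationConfig", "SimulationTruth", "simulate_patient", "simulate_cohort", "apply_events"]

SITES = ("Om", "Ov", "P", "RPG", "SBM", "LOv")
TIMEPOINT_CYCLE = ("biopsy", "surgery", "surgery")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_patients: int = 10
    samples_per_patient: int = 6
    n_segments: int = 40
    het_fraction: float = 0.5
    events_per_branch: float = 6.0
    topology_mode: str = "branched"  # "star" | "branched"
    expansion_mode: str = "none"  # "none" | "clusters"
    n_clusters: int = 2
    cluster_tightness: float = 0.05
    internal_edge_events: float | None = None  # clusters mode: hub-branch event rate
    mean_run_length: float = 3.0
    baseline_hazard: float = 1.0 / 500.0  # per day
    group_log_hr: float = 0.0
    censoring_fraction: float = 0.0
    cellularity_low_fraction: float = 0.0  # planted QC failures

    def __post_init__(self):
        if self.events_per_branch < 0 or self.baseline_hazard <= 0:
            raise ValueError("rates must be non-negative")
        for f in (self.het_fraction, self.censoring_fraction, self.cellularity_low_fraction):
            if not 0.0 <= f <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if self.topology_mode not in ("star", "branched"):
            raise ValueError(f"unknown topology_mode {self.topology_mode!r}")
        if self.expansion_mode not in ("none", "clusters"):
            raise ValueError(f"unknown expansion_mode {self.expansion_mode!r}")


@dataclass
class SimulationTruth:
    """Ground truth for one simulated patient."""

    patient_id: str
    parent: dict[str, str | None]  # node -> parent (root maps to None)
    branch_events: dict[str, list[tuple[str, int, int, int]]]  # node -> [(hap, start, end, sign)]
    founder_a: tuple[int, ...]
    founder_b: tuple[int, ...]
    leaf_cluster: dict[str, int] = field(default_factory=dict)

    def n_events(self, node: str) -> int:
        return len(self.branch_events.get(node, []))

    def path_events(self, leaf: str) -> int:
        """Total simulated events from the founder to a leaf."""
        total, node = 0, leaf
        while node is not None:
            total += self.n_events(node)
            node = self.parent[node]
        return total

    def pair_events(self, leaf_u: str, leaf_v: str) -> int:
        """Simulated events separating two leaves (sum to their MRCA)."""
        anc_u = {}
        node, depth = leaf_u, 0
        while node is not None:
            anc_u[node] = depth
            depth += self.n_events(node)
            node = self.parent[node]
        # walk up from v until a shared ancestor
        total_v, node = 0, leaf_v
        while node not in anc_u:
            total_v += self.n_events(node)
            node = self.parent[node]
        # events from u up to that ancestor
        total_u, m = 0, leaf_u
        while m != node:
            total_u += self.n_events(m)
            m = self.parent[m]
        return total_u + total_v


def apply_events(
    hap_a: np.ndarray, hap_b: np.ndarray, events: list[tuple[str, int, int, int]]
) -> tuple[np.ndarray, np.ndarray]:
    """Replay an event list (haplotype, start, end, sign) with zero absorption."""
    a, b = hap_a.copy(), hap_b.copy()
    for hap, start, end, sign in events:
        vec = a if hap == "a" else b
        seg = vec[start : end + 1]
        seg[seg > 0] += sign
        np.clip(seg, 0, None, out=seg)
    return a, b


def _draw_events(rng: np.random.Generator, n_events: int, n_segments: int, mean_run: float):
    events = []
    for _ in range(n_events):
        hap = "a" if rng.random() < 0.5 else "b"
        run = 1 + rng.geometric(1.0 / mean_run) - 1  # geometric on {1, 2, ...}
        start = int(rng.integers(0, n_segments))
        end = min(n_segments - 1, start + run - 1)
        sign = 1 if rng.random() < 0.5 else -1
        events.append((hap, start, end, sign))
    return events


def simulate_patient(
    config: SimulationConfig, patient_id: str = "SIM1", rng: np.random.Generator | None = None
) -> tuple[PatientDataset, SimulationTruth]:
    """Simulate one patient's sampled clones and the generating history."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_seg, n_leaves = config.n_segments, config.samples_per_patient
    het = rng.random(n_seg) < config.het_fraction
    founder_a = np.where(het, 2, 1).astype(np.int64)
    founder_b = np.ones(n_seg, dtype=np.int64)

    leaves = [f"{patient_id}_S{i + 1}" for i in range(n_leaves)]
    parent: dict[str, str | None] = {"root": None}
    children: dict[str, list[str]] = {"root": []}
    leaf_cluster: dict[str, int] = {}

    def rate_for(node: str) -> float:
        if config.expansion_mode == "clusters":
            if node in leaf_cluster:
                return config.events_per_branch * config.cluster_tightness
            if config.internal_edge_events is not None:
                return config.internal_edge_events  # long internal (hub) edges
        return config.events_per_branch

    if config.topology_mode == "star" and config.expansion_mode == "none":
        for leaf in leaves:
            parent[leaf] = "root"
            children["root"].append(leaf)
    elif config.expansion_mode == "clusters":
        k = min(config.n_clusters, n_leaves)
        hubs = []
        for c in range(k):
            hub = f"{patient_id}_C{c + 1}"
            parent[hub] = "root"
            children["root"].append(hub)
            children[hub] = []
            hubs.append(hub)
        for i, leaf in enumerate(leaves):
            hub = hubs[i % k]
            parent[leaf] = hub
            children[hub].append(leaf)
            leaf_cluster[leaf] = i % k
    else:  # branched: sequential random attachment, bifurcating
        parent[leaves[0]] = "root"
        children["root"].append(leaves[0])
        attachable = [leaves[0]]
        for idx, leaf in enumerate(leaves[1:], start=2):
            host = attachable[int(rng.integers(0, len(attachable)))]
            inner = f"{patient_id}_I{idx}"
            gp = parent[host]
            children[gp][children[gp].index(host)] = inner
            parent[inner] = gp
            children[inner] = [host, leaf]
            parent[host] = inner
            parent[leaf] = inner
            attachable.extend([leaf, inner])

    branch_events: dict[str, list[tuple[str, int, int, int]]] = {}
    profiles_by_node: dict[str, tuple[np.ndarray, np.ndarray]] = {"root": (founder_a, founder_b)}

    def descend(node: str) -> None:
        for child in children.get(node, []):
            n_ev = int(rng.poisson(rate_for(child)))
            ev = _draw_events(rng, n_ev, n_seg, config.mean_run_length)
            branch_events[child] = ev
            profiles_by_node[child] = apply_events(*profiles_by_node[node], ev)
            descend(child)

    descend("root")

    bounds = np.linspace(0, 1_000_000 * n_seg, n_seg + 1, dtype=np.int64)
    segments = tuple(
        Segment("1", int(bounds[i]) + 1, int(bounds[i + 1])) for i in range(n_seg)
    )
    profiles, records = [], []
    for i, leaf in enumerate(leaves):
        a, b = profiles_by_node[leaf]
        major, minor = np.maximum(a, b), np.minimum(a, b)
        profiles.append(AlleleProfile(leaf, segments, tuple(int(x) for x in major), tuple(int(x) for x in minor)))
        low = rng.random() < config.cellularity_low_fraction
        cell = float(rng.uniform(0.05, 0.45)) if low else float(rng.uniform(0.5, 0.95))
        records.append(
            SampleRecord(
                sample_id=leaf,
                patient_id=patient_id,
                site=SITES[i % len(SITES)],
                timepoint=TIMEPOINT_CYCLE[i % len(TIMEPOINT_CYCLE)],
                cellularity=cell,
            )
        )
    dataset = PatientDataset(patient_id, profiles, records)
    truth = SimulationTruth(
        patient_id=patient_id,
        parent=parent,
        branch_events=branch_events,
        founder_a=tuple(int(x) for x in founder_a),
        founder_b=tuple(int(x) for x in founder_b),
        leaf_cluster=leaf_cluster,
    )
    return dataset, truth


def simulate_cohort(
    config: SimulationConfig,
    out_dir: str | Path | None = None,
    samples_per_patient: list[int] | None = None,
) -> tuple[list[PatientDataset], list[SimulationTruth], "pd.DataFrame"]:
    """Simulate a cohort and (optionally) write the three TSVs + truth JSON.

    Patients alternate deterministically between the low-risk and
    high-risk survival groups; high-risk hazard is scaled by
    ``exp(group_log_hr)``.  The administrative censoring horizon is the
    (1 - censoring_fraction) quantile of the baseline survival time, so a
    censoring fraction of zero observes every event.
    """
    import pandas as pd

    rng = np.random.default_rng(config.seed)
    datasets, truths, clin_rows = [], [], []
    if config.censoring_fraction > 0:
        horizon = float(-np.log(config.censoring_fraction) / config.baseline_hazard)
    else:
        horizon = np.inf
    for i in range(config.n_patients):
        pid = f"SIM{i + 1:03d}"
        cfg = config
        if samples_per_patient is not None:
            cfg = SimulationConfig(**{**config.__dict__, "samples_per_patient": samples_per_patient[i]})
        ds, truth = simulate_patient(cfg, patient_id=pid, rng=rng)
        datasets.append(ds)
        truths.append(truth)
        high_risk = i % 2 == 1
        hazard = config.baseline_hazard * np.exp(config.group_log_hr if high_risk else 0.0)
        t_pfs = float(rng.exponential(1.0 / hazard))
        t_os = t_pfs + float(rng.exponential(1.0 / hazard))
        pfs, pfs_event = (min(t_pfs, horizon), t_pfs <= horizon)
        os_, os_event = (min(t_os, horizon), t_os <= horizon)
        clin_rows.append(
            {
                "patient_id": pid,
                "pfs_days": max(1.0, round(pfs, 1)),
                "pfs_event": int(pfs_event),
                "os_days": max(1.0, round(os_, 1)),
                "os_event": int(os_event),
                "stage": "IV" if high_risk else "IIIC",
                "age_bracket": ["I", "II", "III", "IV", "V", "VI"][i % 6],
                "residual_disease": ["none", "<1cm", ">1cm"][i % 3],
                "true_group": int(high_risk),
            }
        )
    clinical = pd.DataFrame(clin_rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_cohort(datasets, out / "segments.tsv", out / "metadata.tsv")
        clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        truth_json = {
            t.patient_id: {
                "parent": t.parent,
                "branch_events": t.branch_events,
                "founder_a": list(t.founder_a),
                "founder_b": list(t.founder_b),
                "leaf_cluster": t.leaf_cluster,
            }
            for t in truths
        }
        (out / "truth.json").write_text(json.dumps(truth_json, indent=1, sort_keys=True))
    return datasets, truths, clinical
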