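"""Group-level network construction: cluster subjects' STEPs into group
STEPs and infer latency-synchronization edges between them.

Clustering runs per frequency band and polarity in three stages: (a) every
subject STEP seeds a candidate cluster collecting, from each subject, the
nearest STEP inside the spatiotemporal windows; (b) a greedy pass selects
disjoint clusters by coverage; (c) each selected cluster is aggregated into
a group STEP by member-wise medians and a voxel vote.  Two group STEPs are
connected when the inter-STEP latency difference (peak-to-peak or rise
onset-to-onset) stays within the synchronization window for at least the
coverage-threshold fraction of subjects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict

import numpy as np

from .io import rle_decode, rle_encode, MODEL_SCHEMA_VERSION
from .preprocess import GridGeometry
from .segmentation import Peak, Step


@dataclass
class ModelConfig:
    """Windows and thresholds of the group model.

    coverage_threshold : minimum fraction of subjects a group STEP or edge
        must represent (0.70 by default).
    temporal_window_ms / spatial_window_px : clustering windows around a seed
        peak; spatial distance is Chebyshev in grid pixels.
    sync_window_ms : maximum |delta-t| for two STEPs to count as synchronized.
    voxel_vote : fraction of members that must contain a voxel (after peak
        alignment) for it to enter the group STEP.
    edge_cohort_gate : additionally require that the subjects contributing to
        both endpoint STEPs cover the coverage threshold of the whole cohort.
    """

    coverage_threshold: float = 0.70
    temporal_window_ms: float = 50.0
    spatial_window_px: float = 4.0
    sync_window_ms: float = 30.0
    voxel_vote: float = 0.5
    edge_cohort_gate: bool = True


@dataclass(frozen=True)
class MemberInfo:
    """Per-subject contribution to a group STEP (peak and rise onset)."""

    subject_id: str
    peak: Peak
    rise_time_ms: float


@dataclass
class CandidateCluster:
    """A seed STEP plus, per subject, the closest in-window STEP."""

    seed: Step
    members: dict[str, tuple[Step, float]]  # subject -> (step, normalized dist)

    @property
    def spread(self) -> float:
        if not self.members:
            return np.inf
        return float(np.mean([nd for _, nd in self.members.values()]))

    def coverage(self, n_subjects: int) -> float:
        return len(self.members) / n_subjects


@dataclass
class GroupStep:
    id: str
    band: str
    polarity: int
    peak: Peak
    voxels: np.ndarray
    amplitudes: np.ndarray
    rise_time_ms: float
    members: dict[str, MemberInfo]
    coverage: float


@dataclass
class NetworkEdge:
    id: str
    step_a: str
    step_b: str
    kind: str              # "peak_sync" or "rise_sync"
    delta_t_ms: float      # group median over in-window subjects, signed b - a
    coverage: float        # fraction of common-member subjects in the window


@dataclass
class BnaModel:
    """Reference network for one condition: group STEPs plus edges."""

    condition: str
    bands: list[str]
    geometry: GridGeometry
    times_ms: np.ndarray
    group_steps: list[GroupStep]
    edges: list[NetworkEdge]
    config: ModelConfig
    n_subjects: int

    def step_by_id(self, step_id: str) -> GroupStep:
        for gs in self.group_steps:
            if gs.id == step_id:
                return gs
        raise KeyError(step_id)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        shape = (self.geometry.n_lr, self.geometry.n_ap, len(self.times_ms))
        mask_idx = np.flatnonzero(self.geometry.mask.ravel())
        dt = (
            float(self.times_ms[1] - self.times_ms[0])
            if len(self.times_ms) > 1 else 1.0
        )
        steps = []
        for gs in self.group_steps:
            r = np.ravel_multi_index(
                (gs.voxels[:, 0], gs.voxels[:, 1], gs.voxels[:, 2]), shape
            )
            order = np.argsort(r)
            steps.append({
                "id": gs.id,
                "band": gs.band,
                "polarity": gs.polarity,
                "peak": asdict(gs.peak),
                "voxel_runs": rle_encode(r[order]),
                "amplitudes": [round(float(a), 6) for a in gs.amplitudes[order]],
                "rise_time_ms": gs.rise_time_ms,
                "coverage": gs.coverage,
                "members": {
                    s: {"peak": asdict(m.peak), "rise_time_ms": m.rise_time_ms}
                    for s, m in sorted(gs.members.items())
                },
            })
        return {
            "schema_version": MODEL_SCHEMA_VERSION,
            "condition": self.condition,
            "bands": list(self.bands),
            "geometry": {
                "n_lr": self.geometry.n_lr,
                "n_ap": self.geometry.n_ap,
                "mask_runs": rle_encode(mask_idx),
            },
            "time_axis": {"t0_ms": float(self.times_ms[0]), "dt_ms": dt,
                          "n": len(self.times_ms)},
            "group_steps": steps,
            "edges": [asdict(e) for e in self.edges],
            "parameters": asdict(self.config),
            "n_subjects": self.n_subjects,
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "BnaModel":
        g = doc["geometry"]
        mask = np.zeros(g["n_lr"] * g["n_ap"], dtype=bool)
        mask[rle_decode(g["mask_runs"])] = True
        geometry = GridGeometry(n_lr=g["n_lr"], n_ap=g["n_ap"],
                                mask=mask.reshape(g["n_lr"], g["n_ap"]))
        ta = doc["time_axis"]
        times = ta["t0_ms"] + ta["dt_ms"] * np.arange(ta["n"])
        shape = (g["n_lr"], g["n_ap"], ta["n"])
        steps = []
        for sd in doc["group_steps"]:
            r = rle_decode(sd["voxel_runs"])
            x, y, t = np.unravel_index(r, shape)
            steps.append(GroupStep(
                id=sd["id"],
                band=sd["band"],
                polarity=sd["polarity"],
                peak=Peak(**sd["peak"]),
                voxels=np.column_stack([x, y, t]).astype(np.int64),
                amplitudes=np.asarray(sd["amplitudes"], dtype=float),
                rise_time_ms=sd["rise_time_ms"],
                members={
                    s: MemberInfo(subject_id=s, peak=Peak(**m["peak"]),
                                  rise_time_ms=m["rise_time_ms"])
                    for s, m in sd["members"].items()
                },
                coverage=sd["coverage"],
            ))
        return cls(
            condition=doc["condition"],
            bands=list(doc["bands"]),
            geometry=geometry,
            times_ms=times,
            group_steps=steps,
            edges=[NetworkEdge(**e) for e in doc["edges"]],
            config=ModelConfig(**doc["parameters"]),
            n_subjects=doc["n_subjects"],
        )


# ---------------------------------------------------------------------------
# Stage (a): candidate enumeration
# ---------------------------------------------------------------------------

def _step_sort_key(st: Step):
    return (st.peak.t_idx, st.peak.x, st.peak.y, -abs(st.peak.amplitude_uv),
            st.subject_id)


def _norm_dist(seed: Peak, other: Peak, config: ModelConfig,
               dt_ms: float) -> tuple[float, float, float]:
    dt = abs(other.t_ms - seed.t_ms)
    cheb = max(abs(other.x - seed.x), abs(other.y - seed.y))
    nd = max(dt / config.temporal_window_ms, cheb / config.spatial_window_px)
    return nd, dt, cheb


def enumerate_candidate_clusters(
    steps: list[Step],
    config: ModelConfig,
    n_subjects: int | None = None,
) -> list[CandidateCluster]:
    """Map all optional clusters: one candidate per seed STEP, collecting the
    closest in-window, same band/polarity STEP of every subject.

    Candidates whose coverage falls below the threshold are discarded.
    ``steps`` must all belong to one band and polarity; the caller groups.
    """
    if not steps:
        return []
    subjects = sorted({st.subject_id for st in steps})
    if n_subjects is None:
        n_subjects = len(subjects)
    by_subject: dict[str, list[Step]] = {s: [] for s in subjects}
    for st in steps:
        by_subject[st.subject_id].append(st)
    for s in subjects:
        by_subject[s].sort(key=_step_sort_key)

    candidates = []
    for seed in sorted(steps, key=_step_sort_key):
        members: dict[str, tuple[Step, float]] = {seed.subject_id: (seed, 0.0)}
        for subj in subjects:
            if subj == seed.subject_id:
                continue
            best = None
            for st in by_subject[subj]:
                dt = abs(st.peak.t_ms - seed.peak.t_ms)
                if dt > config.temporal_window_ms:
                    continue
                cheb = max(abs(st.peak.x - seed.peak.x),
                           abs(st.peak.y - seed.peak.y))
                if cheb > config.spatial_window_px:
                    continue
                nd = max(dt / config.temporal_window_ms,
                         cheb / config.spatial_window_px)
                key = (nd, dt, cheb, _step_sort_key(st))
                if best is None or key < best[0]:
                    best = (key, st, nd)
            if best is not None:
                members[subj] = (best[1], best[2])
        cand = CandidateCluster(seed=seed, members=members)
        if cand.coverage(n_subjects) >= config.coverage_threshold:
            candidates.append(cand)
    return candidates


# ---------------------------------------------------------------------------
# Stage (b): greedy selection
# ---------------------------------------------------------------------------

def greedy_select_clusters(
    candidates: list[CandidateCluster],
    config: ModelConfig,
    n_subjects: int,
) -> list[CandidateCluster]:
    """Iteratively pick the best candidate (highest coverage; ties broken by
    smaller mean normalized spread, then earlier seed peak), remove its
    member STEPs from all remaining candidates, and stop when no candidate
    reaches the coverage threshold.  Each STEP joins at most one cluster."""
    alive = [
        CandidateCluster(seed=c.seed, members=dict(c.members))
        for c in candidates
    ]
    selected: list[CandidateCluster] = []
    used: set[int] = set()
    while alive:
        for c in alive:
            c.members = {
                s: (st, nd) for s, (st, nd) in c.members.items()
                if id(st) not in used
            }
        alive = [
            c for c in alive
            if c.coverage(n_subjects) >= config.coverage_threshold
        ]
        if not alive:
            break
        best = min(
            alive,
            key=lambda c: (
                -c.coverage(n_subjects), c.spread, _step_sort_key(c.seed)
            ),
        )
        selected.append(best)
        used.update(id(st) for st, _ in best.members.values())
        alive.remove(best)
    return selected


# ---------------------------------------------------------------------------
# Stage (c): group STEP aggregation
# ---------------------------------------------------------------------------

def build_group_step(
    cluster: CandidateCluster,
    step_id: str,
    times_ms: np.ndarray,
    shape: tuple[int, int, int],
    config: ModelConfig,
    n_subjects: int,
) -> GroupStep:
    """Aggregate a selected cluster into a group STEP.

    Group peak location/time is the member-wise median (rounded to the
    grid); each member's voxels are shifted by its peak offset to the group
    peak, voxels present in at least ``voxel_vote`` of members are kept, and
    their amplitudes are averaged over the contributing members.
    """
    member_steps = [st for st, _ in cluster.members.values()]
    px = int(np.rint(np.median([st.peak.x for st in member_steps])))
    py = int(np.rint(np.median([st.peak.y for st in member_steps])))
    pt = int(np.rint(np.median([st.peak.t_idx for st in member_steps])))
    px = min(max(px, 0), shape[0] - 1)
    py = min(max(py, 0), shape[1] - 1)
    pt = min(max(pt, 0), shape[2] - 1)

    counts: dict[tuple[int, int, int], int] = {}
    sums: dict[tuple[int, int, int], float] = {}
    for st in member_steps:
        off = np.array([px - st.peak.x, py - st.peak.y, pt - st.peak.t_idx])
        shifted = st.voxels + off
        ok = np.all((shifted >= 0) & (shifted < np.array(shape)), axis=1)
        for (x, y, t), a in zip(shifted[ok], st.amplitudes[ok]):
            key = (int(x), int(y), int(t))
            counts[key] = counts.get(key, 0) + 1
            sums[key] = sums.get(key, 0.0) + float(a)
    n_members = len(member_steps)
    need = config.voxel_vote * n_members
    kept = sorted(k for k, c in counts.items() if c >= need)
    voxels = np.array(kept, dtype=np.int64).reshape(-1, 3)
    amps = np.array([sums[k] / counts[k] for k in kept])
    rise = float(times_ms[voxels[:, 2].min()]) if len(voxels) else float(
        times_ms[pt]
    )
    peak_amp = sums[(px, py, pt)] / counts[(px, py, pt)]
    polarity = member_steps[0].polarity
    members = {
        s: MemberInfo(subject_id=s, peak=st.peak, rise_time_ms=st.rise_time_ms)
        for s, (st, _) in sorted(cluster.members.items())
    }
    return GroupStep(
        id=step_id,
        band=member_steps[0].band,
        polarity=polarity,
        peak=Peak(x=px, y=py, t_idx=pt, t_ms=float(times_ms[pt]),
                  amplitude_uv=float(peak_amp)),
        voxels=voxels,
        amplitudes=amps,
        rise_time_ms=rise,
        members=members,
        coverage=cluster.coverage(n_subjects),
    )


# ---------------------------------------------------------------------------
# Functional connectivity
# ---------------------------------------------------------------------------

def infer_connections(
    group_steps: list[GroupStep],
    n_subjects: int,
    config: ModelConfig,
) -> list[NetworkEdge]:
    """Emit a synchronization edge for every STEP pair and kind whose
    per-subject latency difference stays within the synchronization window
    for at least the coverage-threshold fraction of the subjects
    contributing to both STEPs (and, with the cohort gate, whose common
    members themselves cover the threshold fraction of the cohort)."""
    edges: list[NetworkEdge] = []
    n_edge = 0
    for i in range(len(group_steps)):
        for j in range(i + 1, len(group_steps)):
            a, b = group_steps[i], group_steps[j]
            common = sorted(set(a.members) & set(b.members))
            if not common:
                continue
            if config.edge_cohort_gate and (
                len(common) / n_subjects < config.coverage_threshold
            ):
                continue
            for kind in ("peak_sync", "rise_sync"):
                if kind == "peak_sync":
                    dts = np.array([
                        b.members[s].peak.t_ms - a.members[s].peak.t_ms
                        for s in common
                    ])
                else:
                    dts = np.array([
                        b.members[s].rise_time_ms - a.members[s].rise_time_ms
                        for s in common
                    ])
                inside = np.abs(dts) <= config.sync_window_ms
                cov = inside.mean()
                if cov >= config.coverage_threshold:
                    edges.append(NetworkEdge(
                        id=f"e{n_edge:02d}",
                        step_a=a.id,
                        step_b=b.id,
                        kind=kind,
                        delta_t_ms=float(np.median(dts[inside])),
                        coverage=float(cov),
                    ))
                    n_edge += 1
    return edges


# ---------------------------------------------------------------------------
# Full model
# ---------------------------------------------------------------------------

def build_model(
    steps: list[Step],
    config: ModelConfig,
    condition: str,
    geometry: GridGeometry,
    times_ms: np.ndarray,
    n_subjects: int | None = None,
) -> BnaModel:
    """Cluster subject STEPs (per band and polarity) and infer edges.

    ``steps`` are all subjects' STEPs for one condition and visit.  The
    result is invariant to subject order.  A cohort producing zero group
    STEPs yields a valid empty model (with a warning).
    """
    subjects = sorted({st.subject_id for st in steps})
    if n_subjects is None:
        n_subjects = len(subjects)
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects to build a group model")
    bands = sorted({st.band for st in steps})
    shape = (geometry.n_lr, geometry.n_ap, len(times_ms))

    clusters: list[CandidateCluster] = []
    for band in bands:
        for pol in (1, -1):
            sub = [st for st in steps if st.band == band and st.polarity == pol]
            if not sub:
                continue
            cands = enumerate_candidate_clusters(sub, config, n_subjects)
            clusters.extend(greedy_select_clusters(cands, config, n_subjects))

    # deterministic ordering of group steps: time, band, polarity, location
    def cluster_key(c: CandidateCluster):
        return (c.seed.peak.t_idx, c.seed.band, -c.seed.polarity,
                c.seed.peak.x, c.seed.peak.y)

    clusters.sort(key=cluster_key)
    group_steps = [
        build_group_step(c, f"s{k:02d}", np.asarray(times_ms, float), shape,
                         config, n_subjects)
        for k, c in enumerate(clusters)
    ]
    edges = infer_connections(group_steps, n_subjects, config)
    if not group_steps:
        warnings.warn(
            f"no group STEP reached coverage {config.coverage_threshold} "
            f"for condition {condition!r}", stacklevel=2,
        )
    return BnaModel(
        condition=condition,
        bands=bands,
        geometry=geometry,
        times_ms=np.asarray(times_ms, dtype=float),
        group_steps=group_steps,
        edges=edges,
        config=config,
        n_subjects=n_subjects,
    )
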