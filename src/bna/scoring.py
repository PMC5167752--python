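"""Score individual subjects against a reference network.

For every group STEP the best-matching subject STEP (same band and polarity,
inside the model's spatiotemporal windows) contributes a topographic
correlation score and the STEP's global field power (GFP); for every network
edge the subject's peak and rise-onset latency differences are extracted.
Features are z-scored with training-set statistics before classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import GeometryMismatchError
from .network import BnaModel, GroupStep, NetworkEdge
from .segmentation import Step, Peak


def _ravel_voxels(voxels: np.ndarray, shape: tuple[int, int, int]) -> np.ndarray:
    return np.ravel_multi_index((voxels[:, 0], voxels[:, 1], voxels[:, 2]), shape)


def topo_cov(
    s_voxels: np.ndarray, s_amps: np.ndarray,
    g_voxels: np.ndarray, g_amps: np.ndarray,
    shape: tuple[int, int, int],
) -> float:
    """Spatiotemporal covariance of two STEPs over their voxel overlap.

    Each STEP's mean amplitude is taken over its own voxels; the sum of
    deviation products runs over the voxels valid in both STEPs.  Disjoint
    voxel sets give 0.
    """
    rs = _ravel_voxels(s_voxels, shape)
    rg = _ravel_voxels(g_voxels, shape)
    os_ = np.argsort(rs)
    og = np.argsort(rg)
    _, is_, ig = np.intersect1d(rs[os_], rg[og], assume_unique=True,
                                return_indices=True)
    if is_.size == 0:
        return 0.0
    ms = float(np.mean(s_amps))
    mg = float(np.mean(g_amps))
    return float(np.sum(
        (s_amps[os_][is_] - ms) * (g_amps[og][ig] - mg)
    ))


def topo_corr(
    s_voxels: np.ndarray, s_amps: np.ndarray,
    g_voxels: np.ndarray, g_amps: np.ndarray,
    shape: tuple[int, int, int],
) -> float:
    """Topographic correlation coefficient in [-1, 1].

    Normalizes :func:`topo_cov` by the STEP variances computed over the same
    overlap region (Cauchy-Schwarz keeps the ratio within [-1, 1]).  Returns
    0 for disjoint supports or zero overlap variance.  Spatiotemporal window
    gating is applied by :func:`match_step`, which passes only in-window
    candidates here.
    """
    rs = _ravel_voxels(s_voxels, shape)
    rg = _ravel_voxels(g_voxels, shape)
    os_ = np.argsort(rs)
    og = np.argsort(rg)
    _, is_, ig = np.intersect1d(rs[os_], rg[og], assume_unique=True,
                                return_indices=True)
    if is_.size == 0:
        return 0.0
    ds = s_amps[os_][is_] - float(np.mean(s_amps))
    dg = g_amps[og][ig] - float(np.mean(g_amps))
    vs = float(np.sum(ds * ds))
    vg = float(np.sum(dg * dg))
    if vs == 0.0 or vg == 0.0:
        return 0.0
    return float(np.sum(ds * dg) / np.sqrt(vs * vg))


def gfp(amplitudes: np.ndarray, mode: str = "mean_square") -> float:
    """Global field power of a STEP: mean of squared voxel amplitudes
    (``mean_square``) or its square root (``rms``)."""
    amplitudes = np.asarray(amplitudes, dtype=float)
    if amplitudes.size == 0:
        return 0.0
    ms = float(np.mean(amplitudes ** 2))
    if mode == "mean_square":
        return ms
    if mode == "rms":
        return float(np.sqrt(ms))
    raise ValueError(f"unknown gfp mode {mode!r}")


def topo_corr_steps(
    st_s: Step,
    st_g: Step | GroupStep,
    shape: tuple[int, int, int],
    temporal_window_ms: float | None = None,
    spatial_window_px: float | None = None,
) -> float:
    """Topographic correlation between a subject STEP and a reference STEP,
    gated by the spatiotemporal windows: a subject peak outside the windows
    around the reference peak scores exactly 0."""
    if temporal_window_ms is not None and spatial_window_px is not None:
        if not _in_windows(st_s.peak, st_g.peak,
                           temporal_window_ms, spatial_window_px):
            return 0.0
    return topo_corr(st_s.voxels, st_s.amplitudes,
                     st_g.voxels, st_g.amplitudes, shape)


def _in_windows(subject_peak: Peak, group_peak: Peak,
                temporal_window_ms: float, spatial_window_px: float) -> bool:
    if abs(subject_peak.t_ms - group_peak.t_ms) > temporal_window_ms:
        return False
    cheb = max(abs(subject_peak.x - group_peak.x),
               abs(subject_peak.y - group_peak.y))
    return cheb <= spatial_window_px


@dataclass
class MatchResult:
    """Outcome of matching one group STEP to a subject's STEP set.

    When no subject STEP satisfies the spatiotemporal windows, both scores
    are 0 by convention and ``subject_step`` is None.
    """

    group_step_id: str
    subject_step: Step | None
    topo_score: float
    gfp: float


def match_step(
    subject_steps: list[Step],
    group_step: GroupStep,
    shape: tuple[int, int, int],
    temporal_window_ms: float,
    spatial_window_px: float,
    gfp_mode: str = "mean_square",
) -> MatchResult:
    """Select, among the subject's same-band same-polarity STEPs inside the
    windows around the group peak, the one maximizing the topographic
    correlation; score it."""
    best: tuple[float, tuple, Step] | None = None
    for st in subject_steps:
        if st.band != group_step.band or st.polarity != group_step.polarity:
            continue
        if not _in_windows(st.peak, group_step.peak,
                           temporal_window_ms, spatial_window_px):
            continue
        score = topo_corr(st.voxels, st.amplitudes,
                          group_step.voxels, group_step.amplitudes, shape)
        tie = (st.peak.t_idx, st.peak.x, st.peak.y)
        if best is None or (-score, tie) < (-best[0], best[1]):
            best = (score, tie, st)
    if best is None:
        return MatchResult(group_step_id=group_step.id, subject_step=None,
                           topo_score=0.0, gfp=0.0)
    score, _, st = best
    return MatchResult(
        group_step_id=group_step.id,
        subject_step=st,
        topo_score=score,
        gfp=gfp(st.amplitudes, gfp_mode),
    )


def connection_features(
    matches: dict[str, MatchResult],
    edges: list[NetworkEdge],
) -> dict[str, tuple[float, float]]:
    """Per edge: the subject's signed peak-time and rise-onset differences
    (b minus a, ms); (0, 0) when either endpoint is unmatched."""
    out: dict[str, tuple[float, float]] = {}
    for edge in edges:
        ma = matches.get(edge.step_a)
        mb = matches.get(edge.step_b)
        if (ma is None or mb is None
                or ma.subject_step is None or mb.subject_step is None):
            out[edge.id] = (0.0, 0.0)
            continue
        sa, sb = ma.subject_step, mb.subject_step
        out[edge.id] = (
            float(sb.peak.t_ms - sa.peak.t_ms),
            float(sb.rise_time_ms - sa.rise_time_ms),
        )
    return out


@dataclass
class FeatureTable:
    """Per subject-condition observation feature matrix.

    ``values`` holds one row per observation and one column per feature
    (feature names encode network, STEP/edge and feature kind);
    ``meta`` carries subject, visit and condition per row; ``scaling``
    records the training mean/sd once :func:`scale_features` has run.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    scaling: pd.DataFrame | None = None

    @property
    def labels(self) -> pd.Series:
        return self.meta["condition"]


def score_subject(
    subject_steps: list[Step],
    model: BnaModel,
    gfp_mode: str = "mean_square",
) -> tuple[dict[str, MatchResult], dict[str, tuple[float, float]]]:
    """Match and score one subject-condition STEP set against one model."""
    shape = (model.geometry.n_lr, model.geometry.n_ap, len(model.times_ms))
    for st in subject_steps:
        if st.shape != shape:
            raise GeometryMismatchError(
                f"step grid {st.shape} does not match model grid {shape}"
            )
    matches = {
        gs.id: match_step(
            subject_steps, gs, shape,
            model.config.temporal_window_ms,
            model.config.spatial_window_px,
            gfp_mode,
        )
        for gs in model.group_steps
    }
    return matches, connection_features(matches, model.edges)


def feature_columns(models: dict[str, BnaModel]) -> list[str]:
    cols = []
    for name, model in models.items():
        for gs in model.group_steps:
            cols.append(f"{name}/{gs.id}/topo")
            cols.append(f"{name}/{gs.id}/gfp")
        for e in model.edges:
            cols.append(f"{name}/{e.id}/dt_peak")
            cols.append(f"{name}/{e.id}/dt_rise")
    return cols


def build_feature_table(
    step_sets: dict[tuple[str, str, str], list[Step]],
    models: dict[str, BnaModel],
    gfp_mode: str = "mean_square",
    unmatched: str = "zero",
) -> FeatureTable:
    """One row per (subject, visit, condition) STEP set; columns concatenate,
    over all reference models, per-STEP {topo, gfp} and per-edge
    {dt_peak, dt_rise} features.

    ``unmatched`` controls features whose STEP (or either edge endpoint)
    found no in-window match: ``"zero"`` (default convention) or ``"mean"``
    (impute the column mean over the matched observations).
    """
    if unmatched not in ("zero", "mean"):
        raise ValueError(f"unknown unmatched mode {unmatched!r}")
    geoms = [(m.geometry.n_lr, m.geometry.n_ap, len(m.times_ms))
             for m in models.values()]
    if len(set(geoms)) > 1:
        raise GeometryMismatchError("reference models differ in grid geometry")
    cols = feature_columns(models)
    rows = []
    miss_rows = []
    meta_rows = []
    index = []
    for (subject, visit, condition) in sorted(step_sets):
        steps = step_sets[(subject, visit, condition)]
        row: dict[str, float] = {}
        miss: dict[str, bool] = {}
        for name, model in models.items():
            matches, conn = score_subject(steps, model, gfp_mode)
            for gs in model.group_steps:
                m = matches[gs.id]
                row[f"{name}/{gs.id}/topo"] = m.topo_score
                row[f"{name}/{gs.id}/gfp"] = m.gfp
                miss[f"{name}/{gs.id}/topo"] = m.subject_step is None
                miss[f"{name}/{gs.id}/gfp"] = m.subject_step is None
            for e in model.edges:
                dt_peak, dt_rise = conn[e.id]
                row[f"{name}/{e.id}/dt_peak"] = dt_peak
                row[f"{name}/{e.id}/dt_rise"] = dt_rise
                unmatched_edge = (
                    matches[e.step_a].subject_step is None
                    or matches[e.step_b].subject_step is None
                )
                miss[f"{name}/{e.id}/dt_peak"] = unmatched_edge
                miss[f"{name}/{e.id}/dt_rise"] = unmatched_edge
        rows.append([row[c] for c in cols])
        miss_rows.append([miss[c] for c in cols])
        meta_rows.append((subject, visit, condition))
        index.append(f"{subject}|{visit}|{condition}")
    values = pd.DataFrame(rows, columns=cols, index=index)
    meta = pd.DataFrame(meta_rows, columns=["subject", "visit", "condition"],
                        index=index)
    if unmatched == "mean" and index:
        missing = pd.DataFrame(miss_rows, columns=cols, index=index)
        for c in cols:
            m = missing[c]
            if m.any() and not m.all():
                values.loc[m, c] = values.loc[~m, c].mean()
    return FeatureTable(values=values, meta=meta)


def scale_features(table: FeatureTable, train_index: list[str]) -> FeatureTable:
    """Z-score every column with training-row statistics (population sd).

    Columns with zero training sd are set to 0 everywhere and flagged in the
    scaling record; test rows are scaled with the training statistics.
    """
    train = table.values.loc[train_index]
    mean = train.mean(axis=0)
    sd = train.std(axis=0, ddof=0)
    constant = sd == 0.0
    safe_sd = sd.mask(constant, 1.0)
    scaled = (table.values - mean) / safe_sd
    scaled.loc[:, constant] = 0.0
    scaling = pd.DataFrame({"mean": mean, "sd": sd, "constant": constant})
    return FeatureTable(values=scaled, meta=table.meta.copy(), scaling=scaling)
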