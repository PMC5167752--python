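"""Synthetic multi-subject oddball ERP generator with known ground truth.

Each simulated component is a separable spatiotemporal kernel: a
Gaussian-windowed cosine at its band's center frequency (latency jittered
per subject and visit) times a 2-D Gaussian over the projected electrode
positions (center jittered per subject).  Trials are the sum of the
applicable components plus white noise; a configurable fraction of trials
receives a square high-amplitude excursion on one random channel to exercise
artifact rejection.  Realized per-subject latencies, amplitudes and centers
are stored so every downstream stage has a parameter-recovery surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .errors import ComponentWindowError, InvalidConfigError
from .io import ERPRecord, Montage
from .preprocess import BAND_CENTER_HZ, project_montage

ARTIFACT_AMPLITUDE_UV = 150.0
ARTIFACT_DURATION_MS = 50.0


@dataclass(frozen=True)
class ComponentSpec:
    """Ground-truth description of one simulated ERP component.

    ``amplitude_uv`` is signed (sign encodes polarity); ``center_2d`` and
    ``spatial_sd`` are in grid-fraction units of the projected scalp;
    ``carrier_band`` names the frequency band whose center frequency drives
    the temporal oscillation.  ``center_jitter`` draws a per-subject uniform
    topography shift in [-j, +j] per axis.  Components sharing a
    ``jitter_group`` share one latency-jitter draw per subject and visit, so
    their latency difference is fixed across the cohort.
    """

    name: str
    latency_ms: float
    amplitude_uv: float
    carrier_band: str
    center_2d: tuple[float, float]
    spatial_sd: float = 0.12
    latency_jitter_sd_ms: float = 10.0
    amplitude_jitter_sd_uv: float = 0.5
    center_jitter: float = 0.0
    jitter_group: str | None = None
    conditions: tuple[str, ...] = ("Target",)

    def __post_init__(self) -> None:
        if self.carrier_band not in BAND_CENTER_HZ:
            raise InvalidConfigError(f"unknown carrier band {self.carrier_band!r}")
        if self.spatial_sd <= 0:
            raise InvalidConfigError("spatial_sd must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Study-level simulation parameters (oddball defaults: 600 trials, 80 %
    Frequent / 10 % Target / 10 % Novel, 256 Hz, -200..800 ms epochs)."""

    n_subjects: int = 40
    n_visits: int = 1
    n_trials: int = 600
    condition_proportions: dict = field(
        default_factory=lambda: {"Frequent": 0.8, "Target": 0.1, "Novel": 0.1}
    )
    sampling_rate_hz: float = 256.0
    epoch_window_ms: tuple[float, float] = (-200.0, 800.0)
    noise_sd_uv: float = 20.0
    between_subject_amp_sd_uv: float = 1.0
    artifact_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trials <= 0:
            raise InvalidConfigError("n_trials must be positive")
        total = sum(self.condition_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(
                f"condition proportions sum to {total}, expected 1"
            )
        start, end = self.epoch_window_ms
        if not (start < 0.0 < end):
            raise InvalidConfigError("epoch window must straddle the stimulus")

    def times_ms(self) -> np.ndarray:
        start, end = self.epoch_window_ms
        dt = 1000.0 / self.sampling_rate_hz
        n = int(round((end - start) / dt)) + 1
        return start + dt * np.arange(n)

    def trial_counts(self) -> dict[str, int]:
        return {
            cond: int(round(p * self.n_trials))
            for cond, p in self.condition_proportions.items()
        }


@dataclass
class SimulatedDataset:
    """Simulated cohort: averaged ERPs (and optionally raw epochs) per
    subject x visit x condition, plus realized ground truth."""

    montage: Montage
    config: SimConfig
    components: list[ComponentSpec]
    times_ms: np.ndarray
    erps: dict[tuple[str, str, str], ERPRecord]
    epochs: dict[tuple[str, str, str], np.ndarray] | None
    ground_truth: dict[tuple[str, str, str], dict]

    def subject_ids(self) -> list[str]:
        return sorted({k[0] for k in self.erps})


def temporal_kernel(times_ms: np.ndarray, latency_ms: float, band: str) -> np.ndarray:
    """Gaussian-windowed cosine at the band's center frequency.

    The envelope sd is a quarter carrier period, so the effective support
    (+-3 sd) spans 1.5 cycles and the kernel has a single dominant extremum
    at the latency.
    """
    f = BAND_CENTER_HZ[band]
    sd_ms = 0.25 * 1000.0 / f
    dt = times_ms - latency_ms
    return np.exp(-0.5 * (dt / sd_ms) ** 2) * np.cos(2e-3 * np.pi * f * dt)


def spatial_kernel(pos2d: np.ndarray, center: tuple[float, float],
                   spatial_sd: float) -> np.ndarray:
    """2-D Gaussian weight per electrode over projected positions."""
    d2 = np.sum((pos2d - np.asarray(center)) ** 2, axis=1)
    return np.exp(-0.5 * d2 / spatial_sd ** 2)


def component_template(
    comp: ComponentSpec,
    pos2d: np.ndarray,
    times_ms: np.ndarray,
    latency_ms: float | None = None,
    amplitude_uv: float | None = None,
    center: tuple[float, float] | None = None,
) -> np.ndarray:
    """Noise-free channels x time contribution of one component."""
    lat = comp.latency_ms if latency_ms is None else latency_ms
    amp = comp.amplitude_uv if amplitude_uv is None else amplitude_uv
    ctr = comp.center_2d if center is None else center
    g = temporal_kernel(times_ms, lat, comp.carrier_band)
    w = spatial_kernel(pos2d, ctr, comp.spatial_sd)
    return amp * np.outer(w, g)


def default_components() -> list[ComponentSpec]:
    """Oddball component set: Target N100/P200/P300, Novel N100/P300 and a
    small Frequent N100, at canonical latencies, bands and topographies
    (posterior Target P300, central Novel P300)."""
    return [
        ComponentSpec(name="Frequent-N100", latency_ms=100, amplitude_uv=-4,
                      carrier_band="theta", center_2d=(0.5, 0.60),
                      conditions=("Frequent",)),
        ComponentSpec(name="Target-N100", latency_ms=100, amplitude_uv=-6,
                      carrier_band="theta", center_2d=(0.5, 0.60),
                      conditions=("Target",)),
        ComponentSpec(name="Target-P200", latency_ms=180, amplitude_uv=6,
                      carrier_band="theta", center_2d=(0.5, 0.55),
                      conditions=("Target",)),
        ComponentSpec(name="Target-P300", latency_ms=375, amplitude_uv=10,
                      carrier_band="delta", center_2d=(0.5, 0.35),
                      spatial_sd=0.15, conditions=("Target",)),
        ComponentSpec(name="Novel-N100", latency_ms=145, amplitude_uv=-6,
                      carrier_band="theta", center_2d=(0.5, 0.60),
                      conditions=("Novel",)),
        ComponentSpec(name="Novel-P300", latency_ms=335, amplitude_uv=10,
                      carrier_band="delta", center_2d=(0.5, 0.50),
                      spatial_sd=0.15, conditions=("Novel",)),
    ]


def synthetic_head_montage(radius_cm: float = 9.0) -> Montage:
    """A 37-electrode spherical-cap montage (synthetic stand-in for a
    recording cap): a vertex electrode plus four rings down to the equator,
    positions on an ideal head sphere in centimeters."""
    rings = [(0.0, 1), (22.5, 6), (45.0, 10), (67.5, 12), (90.0, 8)]
    labels: list[str] = []
    pos = []
    k = 0
    for theta_deg, count in rings:
        th = np.deg2rad(theta_deg)
        for i in range(count):
            phi = 2 * np.pi * i / count + (0.0 if count == 1 else np.pi / count)
            pos.append([
                radius_cm * np.sin(th) * np.cos(phi),
                radius_cm * np.sin(th) * np.sin(phi),
                radius_cm * np.cos(th),
            ])
            labels.append(f"E{k:02d}")
            k += 1
    return Montage(labels=labels, pos3d=np.array(pos))


def simulate_dataset(
    config: SimConfig,
    components: list[ComponentSpec] | None = None,
    montage: Montage | None = None,
    return_epochs: bool = False,
) -> SimulatedDataset:
    """Generate a multi-subject, multi-visit oddball dataset.

    With ``return_epochs=False`` the averaged ERP is drawn directly as
    template plus white noise of sd ``noise_sd_uv / sqrt(n_condition_trials)``
    (the sampling distribution of the trial mean), which is statistically
    equivalent to averaging the individual trials and much faster.  Raw
    trials (required when ``artifact_fraction > 0``) are returned with
    ``return_epochs=True``.
    """
    if components is None:
        components = default_components()
    if montage is None:
        montage = synthetic_head_montage()
    if montage.n_channels < 16:
        raise InvalidConfigError("montage must have at least 16 electrodes")
    if montage.pos2d is None:
        montage = project_montage(montage)
    if config.artifact_fraction > 0 and not return_epochs:
        raise InvalidConfigError(
            "artifact injection requires return_epochs=True"
        )

    times = config.times_ms()
    start, end = config.epoch_window_ms
    for comp in components:
        if not (start <= comp.latency_ms <= end):
            raise ComponentWindowError(
                f"component {comp.name!r} latency {comp.latency_ms} ms outside "
                f"epoch window {config.epoch_window_ms}"
            )

    rng = np.random.default_rng(config.seed)
    counts = config.trial_counts()
    conditions = sorted(config.condition_proportions)
    erps: dict[tuple[str, str, str], ERPRecord] = {}
    epochs: dict[tuple[str, str, str], np.ndarray] = {}
    truth: dict[tuple[str, str, str], dict] = {}

    for si in range(config.n_subjects):
        subject = f"sub{si:03d}"
        # per-subject traits: amplitude scale and topography shift
        scales = {}
        centers = {}
        for comp in components:
            rel_sd = (
                config.between_subject_amp_sd_uv / abs(comp.amplitude_uv)
                if comp.amplitude_uv != 0 else 0.0
            )
            scales[comp.name] = rng.normal(1.0, rel_sd) if rel_sd > 0 else 1.0
            if comp.center_jitter > 0:
                shift = rng.uniform(-comp.center_jitter, comp.center_jitter, 2)
            else:
                shift = np.zeros(2)
            centers[comp.name] = (comp.center_2d[0] + shift[0],
                                  comp.center_2d[1] + shift[1])
        for vi in range(config.n_visits):
            visit = f"V{vi + 1}"
            group_jitter: dict[str, float] = {}
            realized = {}
            for comp in components:
                gkey = comp.jitter_group or f"__{comp.name}"
                if gkey not in group_jitter:
                    group_jitter[gkey] = (
                        rng.normal(0.0, comp.latency_jitter_sd_ms)
                        if comp.latency_jitter_sd_ms > 0 else 0.0
                    )
                lat = comp.latency_ms + group_jitter[gkey]
                amp = comp.amplitude_uv * scales[comp.name]
                if comp.amplitude_jitter_sd_uv > 0:
                    amp += rng.normal(0.0, comp.amplitude_jitter_sd_uv)
                realized[comp.name] = {
                    "latency_ms": float(lat),
                    "amplitude_uv": float(amp),
                    "center_2d": tuple(float(c) for c in centers[comp.name]),
                }
            for cond in conditions:
                n_cond = counts[cond]
                if n_cond <= 0:
                    continue
                template = np.zeros((montage.n_channels, times.size))
                for comp in components:
                    if cond not in comp.conditions:
                        continue
                    r = realized[comp.name]
                    template += component_template(
                        comp, montage.pos2d, times,
                        latency_ms=r["latency_ms"],
                        amplitude_uv=r["amplitude_uv"],
                        center=r["center_2d"],
                    )
                key = (subject, visit, cond)
                truth[key] = {
                    name: realized[name] for name in realized
                    if cond in next(c for c in components if c.name == name).conditions
                }
                if return_epochs:
                    noise = (
                        rng.standard_normal((n_cond, *template.shape))
                        * config.noise_sd_uv
                    )
                    trials = template[None, :, :] + noise
                    if config.artifact_fraction > 0:
                        n_art = int(round(config.artifact_fraction * n_cond))
                        art_idx = rng.choice(n_cond, size=n_art, replace=False)
                        dur = max(
                            1, int(round(ARTIFACT_DURATION_MS
                                         * config.sampling_rate_hz / 1000.0))
                        )
                        for tr in art_idx:
                            ch = int(rng.integers(montage.n_channels))
                            t0 = int(rng.integers(0, times.size - dur + 1))
                            sign = 1.0 if rng.random() < 0.5 else -1.0
                            trials[tr, ch, t0:t0 + dur] += (
                                sign * ARTIFACT_AMPLITUDE_UV
                            )
                    epochs[key] = trials
                    erp_data = trials.mean(axis=0)
                else:
                    if config.noise_sd_uv > 0:
                        erp_data = template + (
                            config.noise_sd_uv / np.sqrt(n_cond)
                        ) * rng.standard_normal(template.shape)
                    else:
                        erp_data = template.copy()
                erps[key] = ERPRecord(
                    subject_id=subject, visit_id=visit, condition=cond,
                    sampling_rate_hz=config.sampling_rate_hz,
                    times_ms=times, data=erp_data,
                )
    return SimulatedDataset(
        montage=montage,
        config=config,
        components=list(components),
        times_ms=times,
        erps=erps,
        epochs=epochs if return_epochs else None,
        ground_truth=truth,
    )


# ---------------------------------------------------------------------------
# YAML configuration (CLI)
# ---------------------------------------------------------------------------

def load_sim_config(path) -> tuple[SimConfig, list[ComponentSpec]]:
    """Read a simulation YAML file: a ``config`` mapping (SimConfig fields)
    and a ``components`` list (ComponentSpec fields); missing sections fall
    back to the package defaults."""
    doc = yaml.safe_load(open(path)) or {}
    cfg_kwargs = dict(doc.get("config", {}))
    if "epoch_window_ms" in cfg_kwargs:
        cfg_kwargs["epoch_window_ms"] = tuple(cfg_kwargs["epoch_window_ms"])
    config = SimConfig(**cfg_kwargs)
    comps = []
    for cd in doc.get("components", []):
        cd = dict(cd)
        cd["center_2d"] = tuple(cd["center_2d"])
        if "conditions" in cd:
            cd["conditions"] = tuple(cd["conditions"])
        comps.append(ComponentSpec(**cd))
    return config, comps or default_components()
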