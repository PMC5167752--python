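"""Pre-processing: artifact rejection, averaging, band-pass decomposition and
high-resolution scalp-grid interpolation.

Each subject-condition ERP is decomposed into four conventional frequency
bands and, per band, interpolated onto a fixed 33 x 37 pixel scalp grid
(left-right x anterior-posterior), giving one 3-D amplitude volume per band.
These volumes are the input to STEP segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.interpolate import RBFInterpolator

from .errors import (
    AllEpochsRejectedError,
    DegenerateMontageError,
    FilterLengthError,
    InterpolationError,
    MontageError,
)
from .io import ERPRecord, Montage

#: Conventional EEG frequency bands, Hz.  Edges overlap slightly by design
#: (delta/theta share 3-4 Hz, theta/alpha share 7-8 Hz).
FREQUENCY_BANDS: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (3.0, 8.0),
    "alpha": (7.0, 13.0),
    "beta": (12.0, 30.0),
}

#: Center frequency of each band (midpoint of the edges), used by the
#: simulator as the carrier frequency of a component in that band.
BAND_CENTER_HZ: dict[str, float] = {
    "delta": 2.0,
    "theta": 5.5,
    "alpha": 10.0,
    "beta": 20.0,
}

#: Electrodes are projected into a disk of this grid-fraction radius around
#: the grid center, leaving a margin inside the head mask (radius 0.5).
HEAD_RADIUS_FRACTION = 0.45


@dataclass
class GridGeometry:
    """Fixed scalp grid: first axis left-right, second anterior-posterior.

    The default 33 x 37 grid gives roughly four times the spatial resolution
    of a 10-20 electrode placement.  ``mask`` marks pixels inside the
    projected head area; activity outside the mask is undefined (NaN).
    """

    n_lr: int = 33
    n_ap: int = 37
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self._default_mask()
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (self.n_lr, self.n_ap):
            raise ValueError("mask shape does not match grid dimensions")

    def _default_mask(self) -> np.ndarray:
        u, v = self.pixel_fractions()
        return (u - 0.5) ** 2 + (v - 0.5) ** 2 <= 0.25 + 1e-12

    def pixel_fractions(self) -> tuple[np.ndarray, np.ndarray]:
        """Grid-fraction coordinates of every pixel, each shaped (n_lr, n_ap)."""
        u = np.linspace(0.0, 1.0, self.n_lr)[:, None]
        v = np.linspace(0.0, 1.0, self.n_ap)[None, :]
        return np.broadcast_to(u, (self.n_lr, self.n_ap)), np.broadcast_to(
            v, (self.n_lr, self.n_ap)
        )

    @property
    def pixel_size(self) -> tuple[float, float]:
        """Grid-fraction extent of one pixel along each axis."""
        return 1.0 / (self.n_lr - 1), 1.0 / (self.n_ap - 1)

    def __eq__(self, other) -> bool:  # geometry identity for model checks
        return (
            isinstance(other, GridGeometry)
            and self.n_lr == other.n_lr
            and self.n_ap == other.n_ap
            and np.array_equal(self.mask, other.mask)
        )


@dataclass
class BandVolume:
    """One frequency band's scalp activity: (left-right, anterior-posterior,
    time) amplitude array in microvolts, NaN outside the head mask."""

    band: str
    data: np.ndarray
    times_ms: np.ndarray
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        expected = (self.geometry.n_lr, self.geometry.n_ap, self.times_ms.size)
        if self.data.shape != expected:
            raise ValueError(f"volume shape {self.data.shape} != {expected}")


# ---------------------------------------------------------------------------
# Artifact rejection and averaging
# ---------------------------------------------------------------------------

def reject_artifacts(
    epochs: np.ndarray,
    montage: Montage,
    amp_limit_uv: float = 100.0,
    bad_channel_fraction: float = 0.2,
    neighbor_corr_min: float = 0.4,
    sd_limit: float = 7.0,
    k_neighbors: int = 4,
) -> tuple[np.ndarray, list[dict]]:
    """Remove noisy channels (by repair) and noisy epochs (by deletion).

    Channels are marked bad when the fraction of their samples exceeding
    ``amp_limit_uv`` in magnitude is above ``bad_channel_fraction``, or when
    they are dissimilar to their surroundings: correlation with the mean of
    their ``k_neighbors`` nearest neighbors below ``neighbor_corr_min``
    while also carrying outlier power (sd above twice the median channel
    sd — the signature of a broken electrode; low-amplitude channels far
    from the active sources are legitimately weakly correlated and are
    kept).  Bad channels are replaced by the average of their nearest good
    neighbors.  Epochs are dropped when any
    sample lies strictly outside +-``amp_limit_uv`` (a sample at exactly the
    limit is retained) or deviates from the channel's across-trial mean by
    more than ``sd_limit`` standard deviations.

    Returns the surviving epochs and a log of every removal with the rule
    that triggered it.
    """
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 2:
        raise ValueError("need at least 2 epochs of shape (trials, channels, time)")
    n_trials, n_ch, _ = epochs.shape
    if n_ch != montage.n_channels:
        raise MontageError("epoch channel count does not match montage")
    log: list[dict] = []

    # nearest neighbors by 3-D electrode distance
    d = np.linalg.norm(montage.pos3d[:, None, :] - montage.pos3d[None, :, :], axis=2)
    np.fill_diagonal(d, np.inf)
    neighbor_idx = np.argsort(d, axis=1)[:, :k_neighbors]

    flat = epochs.transpose(1, 0, 2).reshape(n_ch, -1)  # channel x (trial*time)
    bad = np.zeros(n_ch, dtype=bool)
    over_frac = np.mean(np.abs(flat) > amp_limit_uv, axis=1)
    for ch in np.flatnonzero(over_frac > bad_channel_fraction):
        bad[ch] = True
        log.append({"kind": "channel", "index": int(ch), "rule": "amplitude"})
    ch_power = flat.std(axis=1)
    power_floor = 2.0 * np.median(ch_power)
    for ch in range(n_ch):
        if bad[ch] or ch_power[ch] <= power_floor:
            continue
        ref = flat[neighbor_idx[ch]].mean(axis=0)
        x, y = flat[ch], ref
        sx, sy = x.std(), y.std()
        corr = 0.0 if sx == 0 or sy == 0 else float(
            np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
        )
        if corr < neighbor_corr_min:
            bad[ch] = True
            log.append({"kind": "channel", "index": int(ch), "rule": "dissimilarity"})

    repaired = epochs.copy()
    good = ~bad
    if bad.any():
        if not good.any():
            raise AllEpochsRejectedError("every channel marked bad")
        for ch in np.flatnonzero(bad):
            order = np.argsort(d[ch])
            donors = [j for j in order if good[j]][:k_neighbors]
            repaired[:, ch, :] = repaired[:, donors, :].mean(axis=1)

    # epoch rejection on the repaired data
    ch_mean = repaired.transpose(1, 0, 2).reshape(n_ch, -1).mean(axis=1)
    ch_sd = repaired.transpose(1, 0, 2).reshape(n_ch, -1).std(axis=1)
    keep = np.ones(n_trials, dtype=bool)
    for tr in range(n_trials):
        if np.any(np.abs(repaired[tr]) > amp_limit_uv):
            keep[tr] = False
            log.append({"kind": "epoch", "index": tr, "rule": "amplitude"})
            continue
        dev = np.abs(repaired[tr] - ch_mean[:, None])
        lim = sd_limit * ch_sd[:, None]
        if np.any(dev[ch_sd > 0, :] > lim[ch_sd > 0, :]):
            keep[tr] = False
            log.append({"kind": "epoch", "index": tr, "rule": "sd"})
    if not keep.any():
        raise AllEpochsRejectedError("all epochs rejected")
    return repaired[keep], log


def average_epochs(
    epochs: np.ndarray,
    times_ms: np.ndarray,
    sampling_rate_hz: float,
    subject_id: str = "",
    visit_id: str = "",
    condition: str = "",
    baseline: bool = True,
) -> ERPRecord:
    """Pointwise mean across trials; optionally subtract the pre-stimulus
    (t < 0) mean per channel."""
    epochs = np.asarray(epochs, dtype=float)
    if epochs.ndim != 3 or epochs.shape[0] < 1:
        raise ValueError("need at least 1 epoch")
    erp = epochs.mean(axis=0)
    times_ms = np.asarray(times_ms, dtype=float)
    if baseline:
        pre = times_ms < 0
        if pre.any():
            erp = erp - erp[:, pre].mean(axis=1, keepdims=True)
    return ERPRecord(
        subject_id=subject_id,
        visit_id=visit_id,
        condition=condition,
        sampling_rate_hz=sampling_rate_hz,
        times_ms=times_ms,
        data=erp,
    )


# ---------------------------------------------------------------------------
# Band-pass decomposition
# ---------------------------------------------------------------------------

def design_bandpass(band: str, sampling_rate_hz: float, n_samples: int) -> np.ndarray:
    """Least-squares linear-phase FIR band-pass for one named band.

    Filter length is 3 cycles of the band's lower edge, capped at
    ``n_samples - 1`` and forced odd (type I).
    """
    f1, f2 = FREQUENCY_BANDS[band]
    nyq = sampling_rate_hz / 2.0
    if nyq <= f2:
        raise FilterLengthError(
            f"sampling rate {sampling_rate_hz} Hz too low for band {band}"
        )
    numtaps = int(round(3.0 * sampling_rate_hz / f1))
    numtaps = min(numtaps, n_samples - 1)
    if numtaps % 2 == 0:
        numtaps -= 1
    if numtaps < 5:
        raise FilterLengthError("signal too short for band-pass filtering")
    tw_low = min(0.5 * f1, 2.0)
    tw_high = min(0.25 * f2, 2.0)
    f_stop_hi = min(f2 + tw_high, 0.999 * nyq)
    bands = [0.0, max(f1 - tw_low, 1e-3), f1, f2, f_stop_hi, nyq]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return signal.firls(numtaps, bands, desired, fs=sampling_rate_hz)


def bandpass_decompose(
    record: ERPRecord, bands: tuple[str, ...] | None = None
) -> dict[str, np.ndarray]:
    """Decompose an ERP into band-limited channel x time matrices.

    Each band's FIR filter is applied forward then reversed (zero net phase);
    edge transients are handled by symmetric padding of one filter length.
    """
    if bands is None:
        bands = tuple(FREQUENCY_BANDS)
    out: dict[str, np.ndarray] = {}
    n = record.times_ms.size
    for band in bands:
        b = design_bandpass(band, record.sampling_rate_hz, n)
        out[band] = signal.filtfilt(
            b, [1.0], record.data, axis=-1, padtype="even", padlen=len(b) - 1
        )
    return out


# ---------------------------------------------------------------------------
# Montage projection and grid interpolation
# ---------------------------------------------------------------------------

def _fit_sphere_center(pos: np.ndarray) -> np.ndarray:
    """Least-squares sphere center of a point cloud.

    Solves the linear system from |p - c|^2 = R^2; degenerate (coplanar)
    clouds fall back to the centroid.
    """
    A = np.column_stack([2.0 * pos, np.ones(len(pos))])
    b = np.sum(pos ** 2, axis=1)
    sol, _, rank, _ = np.linalg.lstsq(A, b, rcond=None)
    if rank < 4:
        return pos.mean(axis=0)
    return sol[:3]


def project_montage(
    montage: Montage, head_radius_fraction: float = HEAD_RADIUS_FRACTION
) -> Montage:
    """Fill ``pos2d`` by azimuthal-equidistant projection about the vertex.

    Electrode positions are centered on their least-squares sphere center
    (robust to cap-only montages, whose centroid sits above the head
    center); each electrode maps to planar radius equal to its arc angle
    from the vertex (+z), preserving left-right (u) and anterior-posterior
    (v) orientation.  The result is rescaled so the outermost electrode sits
    at ``head_radius_fraction`` from the grid center, in [0, 1]^2
    grid-fraction coordinates.
    """
    pos = montage.pos3d - _fit_sphere_center(montage.pos3d)
    r = np.linalg.norm(pos, axis=1)
    if np.any(r < 1e-12):
        raise DegenerateMontageError("electrode at the head center")
    if r.std() / r.mean() >= 0.2:
        raise MontageError("electrodes do not lie near a head-centered sphere")
    if np.all(np.abs(pos[:, 2]) < 1e-9 * r.mean()):
        raise DegenerateMontageError("montage coplanar through the head center")
    unit = pos / r[:, None]
    theta = np.arccos(np.clip(unit[:, 2], -1.0, 1.0))  # arc angle from vertex
    rho = np.hypot(unit[:, 0], unit[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        dir_x = np.where(rho > 1e-12, unit[:, 0] / rho, 0.0)
        dir_y = np.where(rho > 1e-12, unit[:, 1] / rho, 0.0)
    px = theta * dir_x
    py = theta * dir_y
    max_r = np.hypot(px, py).max()
    if max_r < 1e-12:
        raise DegenerateMontageError("all electrodes at the vertex")
    s = head_radius_fraction / max_r
    pos2d = np.column_stack([0.5 + s * px, 0.5 + s * py])
    return Montage(labels=list(montage.labels), pos3d=montage.pos3d.copy(),
                   pos2d=pos2d)


def interpolate_grid(
    band_matrices: dict[str, np.ndarray],
    montage: Montage,
    geometry: GridGeometry,
    times_ms: np.ndarray,
) -> list[BandVolume]:
    """Interpolate band-limited electrode data onto the scalp grid.

    Per band, a thin-plate spline surface through the projected electrode
    values is evaluated at every masked pixel for every time sample; pixels
    outside the mask are NaN.  The spline interpolates exactly (no smoothing)
    and reproduces affine fields, so constant inputs give constant maps.
    """
    if montage.pos2d is None:
        raise MontageError("montage not projected; call project_montage first")
    if montage.n_channels < 4:
        raise InterpolationError("need at least 4 electrodes for the spline")
    u, v = geometry.pixel_fractions()
    pts = np.column_stack([u[geometry.mask], v[geometry.mask]])
    volumes = []
    for band, mat in band_matrices.items():
        interp = RBFInterpolator(
            montage.pos2d, np.asarray(mat, dtype=float),
            kernel="thin_plate_spline", degree=1,
        )
        vals = interp(pts)  # (n_masked_pixels, n_times)
        data = np.full(
            (geometry.n_lr, geometry.n_ap, len(times_ms)), np.nan, dtype=float
        )
        data[geometry.mask, :] = vals
        volumes.append(
            BandVolume(band=band, data=data, times_ms=np.asarray(times_ms, float),
                       geometry=geometry)
        )
    return volumes
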