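"""Spatiotemporal parcellation of band-limited scalp volumes into STEPs.

A STEP (spatiotemporal parcel) is a local extremum of the amplitude in time
and space (the peak) together with its half-amplitude surroundings: the
26-connected set of voxels sharing the peak's polarity whose absolute
amplitude is at least half the peak's.  The rise time of a STEP is the
earliest time at which any of its voxels is active.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .preprocess import BandVolume

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_FOOT_NO_CENTER = np.ones((3, 3, 3), dtype=bool)
_FOOT_NO_CENTER[1, 1, 1] = False


@dataclass(frozen=True)
class Peak:
    """A spatiotemporal extremum: grid location, time and signed amplitude."""

    x: int          # left-right pixel index
    y: int          # anterior-posterior pixel index
    t_idx: int      # sample index
    t_ms: float
    amplitude_uv: float

    @property
    def polarity(self) -> int:
        return 1 if self.amplitude_uv >= 0 else -1


@dataclass
class Step:
    """A spatiotemporal parcel: peak plus half-amplitude surroundings."""

    band: str
    peak: Peak
    voxels: np.ndarray          # (n, 3) int array of (x, y, t_idx)
    amplitudes: np.ndarray      # (n,) microvolts, same order as voxels
    rise_time_ms: float
    shape: tuple[int, int, int]  # grid shape the voxel indices live on
    times_ms: np.ndarray        # full time axis of the source volume
    subject_id: str = ""
    condition: str = ""
    visit_id: str = ""
    _ravel: np.ndarray | None = field(default=None, repr=False, compare=False)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def polarity(self) -> int:
        return self.peak.polarity

    def raveled(self) -> np.ndarray:
        """Sorted raveled voxel indices on the step's grid (cached)."""
        if self._ravel is None:
            r = np.ravel_multi_index(
                (self.voxels[:, 0], self.voxels[:, 1], self.voxels[:, 2]),
                self.shape,
            )
            order = np.argsort(r)
            object.__setattr__(self, "_ravel", r[order])
            self.voxels = self.voxels[order]
            self.amplitudes = self.amplitudes[order]
        return self._ravel


def auto_min_amplitude(volume: BandVolume, factor: float = 0.5) -> float:
    """Noise-floor threshold: ``factor`` times the volume's robust amplitude
    spread (median absolute deviation scaled to a Gaussian sd)."""
    vals = volume.data[np.isfinite(volume.data)]
    mad = np.median(np.abs(vals - np.median(vals)))
    return float(factor * 1.4826 * mad)


def detect_peaks(volume: BandVolume, min_abs_amplitude: float = 0.0) -> list[Peak]:
    """Find every strict 26-neighborhood extremum with |amplitude| at or
    above ``min_abs_amplitude``.

    A voxel is a positive peak when strictly greater than all finite
    neighbors, a negative peak when strictly smaller; boundary voxels (mask
    edge, first/last sample) compare against existing neighbors only.
    Plateaus of equal value are not strict extrema; a plateau that is a
    strict regional extremum contributes its earliest-time, lowest-index
    voxel.  Peaks are returned sorted by time then |amplitude| descending.
    """
    data = volume.data
    finite = np.isfinite(data)
    lo = np.where(finite, data, -np.inf)
    hi = np.where(finite, data, np.inf)
    nmax = ndimage.maximum_filter(lo, footprint=_FOOT_NO_CENTER,
                                  mode="constant", cval=-np.inf)
    nmin = ndimage.minimum_filter(hi, footprint=_FOOT_NO_CENTER,
                                  mode="constant", cval=np.inf)
    big = np.abs(data) >= min_abs_amplitude
    peaks_mask = finite & big & ((data > nmax) | (data < nmin))
    coords = [tuple(c) for c in np.argwhere(peaks_mask)]

    # plateau candidates: tie with the neighborhood extremum but never beaten
    tie_max = finite & big & (data == nmax)
    tie_min = finite & big & (data == nmin)
    for tie, is_max in ((tie_max, True), (tie_min, False)):
        if not tie.any():
            continue
        labels, n_lab = ndimage.label(tie, structure=_STRUCT26)
        for lab in range(1, n_lab + 1):
            members = np.argwhere(labels == lab)
            vals = data[tuple(members.T)]
            if not np.all(vals == vals[0]):
                continue  # mixed-value tie region is not a plateau
            region = labels == lab
            halo = ndimage.binary_dilation(region, structure=_STRUCT26) & ~region
            halo &= finite
            outside = data[halo]
            if outside.size and (
                np.all(outside < vals[0]) if is_max else np.all(outside > vals[0])
            ):
                rep = min(map(tuple, members), key=lambda c: (c[2], c[0], c[1]))
                coords.append(rep)

    peaks = [
        Peak(x=int(x), y=int(y), t_idx=int(t),
             t_ms=float(volume.times_ms[t]),
             amplitude_uv=float(data[x, y, t]))
        for (x, y, t) in coords
    ]
    peaks.sort(key=lambda p: (p.t_idx, -abs(p.amplitude_uv), p.x, p.y))
    return peaks


def _component_containing(mask: np.ndarray, seed: tuple[int, int, int],
                          t_half: int = 16, s_half: int = 8) -> np.ndarray:
    """Voxel coordinates of the 26-connected component of ``mask`` containing
    ``seed``, found inside an adaptively grown crop window."""
    shape = mask.shape
    hx, hy, ht = s_half, s_half, t_half
    while True:
        x0 = max(seed[0] - hx, 0)
        x1 = min(seed[0] + hx + 1, shape[0])
        y0 = max(seed[1] - hy, 0)
        y1 = min(seed[1] + hy + 1, shape[1])
        t0 = max(seed[2] - ht, 0)
        t1 = min(seed[2] + ht + 1, shape[2])
        sub = mask[x0:x1, y0:y1, t0:t1]
        labels, _ = ndimage.label(sub, structure=_STRUCT26)
        lab = labels[seed[0] - x0, seed[1] - y0, seed[2] - t0]
        comp = labels == lab
        touches = (
            (x0 > 0 and comp[0].any()) or (x1 < shape[0] and comp[-1].any())
            or (y0 > 0 and comp[:, 0].any()) or (y1 < shape[1] and comp[:, -1].any())
            or (t0 > 0 and comp[:, :, 0].any())
            or (t1 < shape[2] and comp[:, :, -1].any())
        )
        if not touches:
            vox = np.argwhere(comp)
            vox[:, 0] += x0
            vox[:, 1] += y0
            vox[:, 2] += t0
            return vox
        hx *= 2
        hy *= 2
        ht *= 2
        if hx > shape[0] and hy > shape[1] and ht > shape[2]:
            # crop covers the whole volume; one final full-volume pass
            labels, _ = ndimage.label(mask, structure=_STRUCT26)
            return np.argwhere(labels == labels[seed])


def extract_step(
    volume: BandVolume,
    peak: Peak,
    subject_id: str = "",
    condition: str = "",
    visit_id: str = "",
) -> Step:
    """Grow a STEP from a detected peak.

    The voxel set is the 26-connected component, containing the peak, of all
    voxels sharing the peak's sign whose absolute amplitude is at least half
    the peak's absolute amplitude.  Rise time is the earliest time sample in
    that set.
    """
    data = volume.data
    thr = abs(peak.amplitude_uv) / 2.0
    with np.errstate(invalid="ignore"):
        if peak.polarity > 0:
            mask = data >= thr
        else:
            mask = data <= -thr
    mask &= np.isfinite(data)
    vox = _component_containing(mask, (peak.x, peak.y, peak.t_idx))
    amps = data[vox[:, 0], vox[:, 1], vox[:, 2]]
    rise = float(volume.times_ms[vox[:, 2].min()])
    return Step(
        band=volume.band,
        peak=peak,
        voxels=vox,
        amplitudes=amps,
        rise_time_ms=rise,
        shape=data.shape,
        times_ms=volume.times_ms,
        subject_id=subject_id,
        condition=condition,
        visit_id=visit_id,
    )


def segment_subject(
    volumes: list[BandVolume],
    min_abs_amplitude: float | str = "auto",
    min_voxels: int = 1,
    subject_id: str = "",
    condition: str = "",
    visit_id: str = "",
) -> list[Step]:
    """Segment all of a subject-condition's band volumes into STEPs.

    ``min_abs_amplitude`` may be a microvolt value or ``"auto"`` (half the
    per-volume robust noise estimate).  STEPs from different peaks may
    overlap in voxels; parcels smaller than ``min_voxels`` are discarded.
    """
    steps: list[Step] = []
    for vol in volumes:
        thr = (
            auto_min_amplitude(vol)
            if isinstance(min_abs_amplitude, str)
            else float(min_abs_amplitude)
        )
        for peak in detect_peaks(vol, thr):
            st = extract_step(vol, peak, subject_id=subject_id,
                              condition=condition, visit_id=visit_id)
            if st.n_voxels >= min_voxels:
                steps.append(st)
    return steps
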