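"""Readers and writers for montages, ERP matrices, network models and feature tables.

All on-disk formats are plain text: whitespace-delimited ``.sfp`` montages,
tab-separated ERP matrices with ``#key=value`` metadata lines, and a JSON
document for network models.  Writers are deterministic: stable key order and
fixed float formatting, so identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import (
    MetadataError,
    ModelParseError,
    MontageError,
    SchemaVersionError,
    SpacingError,
)

MODEL_SCHEMA_VERSION = 1

#: Conditions of the three-stimulus auditory oddball task.  The set is
#: extensible; these are the canonical names used throughout.
ODDBALL_CONDITIONS = ("Frequent", "Target", "Novel")


@dataclass
class Montage:
    """Electrode labels with 3-D head positions and, once projected, 2-D
    grid-fraction positions.

    Attributes
    ----------
    labels : list of str
        Unique electrode names, in file order.
    pos3d : ndarray, shape (n, 3)
        Cartesian positions in arbitrary head units (x: right, y: anterior,
        z: up).
    pos2d : ndarray, shape (n, 2) or None
        Projected (u, v) positions in [0, 1]^2 grid-fraction coordinates;
        ``None`` until :func:`bna.preprocess.project_montage` has run.
    """

    labels: list[str]
    pos3d: np.ndarray
    pos2d: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pos3d = np.asarray(self.pos3d, dtype=float)
        if len(self.labels) != len(set(self.labels)):
            raise MontageError("duplicate electrode labels")
        if self.pos3d.shape != (len(self.labels), 3):
            raise MontageError(
                f"pos3d shape {self.pos3d.shape} does not match "
                f"{len(self.labels)} labels"
            )

    @property
    def n_channels(self) -> int:
        return len(self.labels)


@dataclass
class ERPRecord:
    """One averaged ERP: channels x time in microvolts, with identity metadata."""

    subject_id: str
    visit_id: str
    condition: str
    sampling_rate_hz: float
    times_ms: np.ndarray
    data: np.ndarray

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=float)
        self.data = np.asarray(self.data, dtype=float)
        check_uniform_times(self.times_ms, self.sampling_rate_hz)
        if self.data.ndim != 2 or self.data.shape[1] != self.times_ms.size:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with "
                f"{self.times_ms.size} time samples"
            )

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]


def check_uniform_times(times_ms: np.ndarray, sampling_rate_hz: float,
                        rtol: float = 1e-6) -> None:
    """Raise :class:`SpacingError` unless times are strictly increasing and
    uniformly spaced at 1000 / sampling_rate_hz milliseconds."""
    times_ms = np.asarray(times_ms, dtype=float)
    if times_ms.size < 2:
        return
    dt = np.diff(times_ms)
    expected = 1000.0 / sampling_rate_hz
    if np.any(dt <= 0):
        raise SpacingError("time axis not strictly increasing")
    if not np.allclose(dt, expected, rtol=rtol, atol=expected * rtol):
        raise SpacingError(
            f"time axis not uniformly spaced at {expected:.6g} ms"
        )


# ---------------------------------------------------------------------------
# Montage files (sfp-style: label x y z, one electrode per line)
# ---------------------------------------------------------------------------

def read_montage(path: str | Path) -> Montage:
    """Read a whitespace-delimited label-x-y-z montage file.

    File order is preserved; ``pos2d`` is left unset.
    """
    labels: list[str] = []
    coords: list[list[float]] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 4:
            raise MontageError(f"{path}:{lineno}: expected 'label x y z'")
        label = parts[0]
        try:
            xyz = [float(p) for p in parts[1:]]
        except ValueError as exc:
            raise MontageError(f"{path}:{lineno}: non-numeric coordinate") from exc
        if label in labels:
            raise MontageError(f"{path}:{lineno}: duplicate label {label!r}")
        labels.append(label)
        coords.append(xyz)
    if len(labels) < 3:
        raise MontageError(f"{path}: montage needs at least 3 electrodes")
    return Montage(labels=labels, pos3d=np.array(coords))


def write_montage(montage: Montage, path: str | Path) -> None:
    lines = [
        f"{lab}\t{x:.6f}\t{y:.6f}\t{z:.6f}"
        for lab, (x, y, z) in zip(montage.labels, montage.pos3d)
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ERP matrices (TSV with #key=value metadata lines)
# ---------------------------------------------------------------------------

_ERP_META_KEYS = ("subject", "visit", "condition", "sampling_rate_hz")


def write_erp(record: ERPRecord, path: str | Path,
              channel_labels: list[str] | None = None) -> None:
    """Write an ERP record as tab-separated text.

    Header row is ``time_ms`` followed by channel labels; one row per time
    sample; metadata in ``#key=value`` comment lines.  Values are formatted
    with 6 significant digits (round-trip stable at that precision).
    """
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(record.n_channels)]
    if len(channel_labels) != record.n_channels:
        raise ValueError("channel label count does not match data rows")
    out = [
        f"#subject={record.subject_id}",
        f"#visit={record.visit_id}",
        f"#condition={record.condition}",
        f"#sampling_rate_hz={record.sampling_rate_hz:.6g}",
        "\t".join(["time_ms", *channel_labels]),
    ]
    for j, t in enumerate(record.times_ms):
        # times carry extra digits so the uniform-spacing invariant survives
        row = [f"{t:.10g}"] + [f"{v:.6g}" for v in record.data[:, j]]
        out.append("\t".join(row))
    Path(path).write_text("\n".join(out) + "\n")


def read_erp(path: str | Path) -> tuple[ERPRecord, list[str]]:
    """Read an ERP TSV; returns the record and the channel labels."""
    meta: dict[str, str] = {}
    header: list[str] | None = None
    rows: list[list[float]] = []
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("=")
            meta[key.strip()] = value.strip()
            continue
        parts = line.split("\t")
        if header is None:
            if parts[0] != "time_ms":
                raise MetadataError(f"{path}: first data line must be the header")
            header = parts
            continue
        rows.append([float(p) for p in parts])
    missing = [k for k in _ERP_META_KEYS if k not in meta]
    if missing:
        raise MetadataError(f"{path}: missing metadata lines: {missing}")
    if header is None or not rows:
        raise MetadataError(f"{path}: no data rows")
    arr = np.array(rows)
    return (
        ERPRecord(
            subject_id=meta["subject"],
            visit_id=meta["visit"],
            condition=meta["condition"],
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            times_ms=arr[:, 0],
            data=arr[:, 1:].T,
        ),
        header[1:],
    )


# ---------------------------------------------------------------------------
# Voxel-set run-length encoding (shared by step and model serialization)
# ---------------------------------------------------------------------------

def rle_encode(sorted_indices: np.ndarray) -> list[list[int]]:
    """Encode a sorted array of non-negative ints as [start, run_length] pairs."""
    idx = np.asarray(sorted_indices, dtype=np.int64)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) != 1)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [idx.size - 1]))
    return [[int(idx[s]), int(e - s + 1)] for s, e in zip(starts, ends)]


def rle_decode(runs: list[list[int]]) -> np.ndarray:
    if not runs:
        return np.zeros(0, dtype=np.int64)
    return np.concatenate(
        [np.arange(start, start + length, dtype=np.int64) for start, length in runs]
    )


# ---------------------------------------------------------------------------
# STEP files (per subject-condition JSON, same voxel encoding as models)
# ---------------------------------------------------------------------------

def write_steps(steps: list, path: str | Path) -> None:
    """Serialize one subject-condition STEP list as JSON."""
    if not steps:
        doc = {"schema_version": MODEL_SCHEMA_VERSION, "steps": []}
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))
        return
    first = steps[0]
    t = first.times_ms
    dt = float(t[1] - t[0]) if len(t) > 1 else 1.0
    items = []
    for st in steps:
        r = st.raveled()
        items.append({
            "band": st.band,
            "peak": {
                "x": st.peak.x, "y": st.peak.y, "t_idx": st.peak.t_idx,
                "t_ms": st.peak.t_ms, "amplitude_uv": st.peak.amplitude_uv,
            },
            "voxel_runs": rle_encode(r),
            "amplitudes": [round(float(a), 6) for a in st.amplitudes],
            "rise_time_ms": st.rise_time_ms,
        })
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "subject": first.subject_id,
        "visit": first.visit_id,
        "condition": first.condition,
        "shape": list(first.shape),
        "time_axis": {"t0_ms": float(t[0]), "dt_ms": dt, "n": int(len(t))},
        "steps": items,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_steps(path: str | Path) -> list:
    from .segmentation import Peak, Step  # deferred

    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(f"{path}: unknown schema version")
    if not doc["steps"]:
        return []
    shape = tuple(doc["shape"])
    ta = doc["time_axis"]
    times = ta["t0_ms"] + ta["dt_ms"] * np.arange(ta["n"])
    out = []
    for sd in doc["steps"]:
        r = rle_decode(sd["voxel_runs"])
        x, y, t = np.unravel_index(r, shape)
        out.append(Step(
            band=sd["band"],
            peak=Peak(**sd["peak"]),
            voxels=np.column_stack([x, y, t]).astype(np.int64),
            amplitudes=np.asarray(sd["amplitudes"], dtype=float),
            rise_time_ms=sd["rise_time_ms"],
            shape=shape,
            times_ms=times,
            subject_id=doc["subject"],
            condition=doc["condition"],
            visit_id=doc["visit"],
        ))
    return out


# ---------------------------------------------------------------------------
# Feature tables (TSV, one row per subject-condition observation)
# ---------------------------------------------------------------------------

def write_feature_table(table, path: str | Path) -> None:
    """Write a feature table as TSV: subject/visit/condition columns then one
    column per feature."""
    import pandas as pd

    df = pd.concat([table.meta, table.values], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_feature_table(path: str | Path):
    import pandas as pd

    from .scoring import FeatureTable  # deferred

    df = pd.read_csv(path, sep="\t", dtype={"subject": str, "visit": str})
    meta = df[["subject", "visit", "condition"]].copy()
    values = df.drop(columns=["subject", "visit", "condition"]).astype(float)
    index = [
        f"{s}|{v}|{c}"
        for s, v, c in zip(meta["subject"], meta["visit"], meta["condition"])
    ]
    meta.index = index
    values.index = index
    return FeatureTable(values=values, meta=meta)


# ---------------------------------------------------------------------------
# Model JSON
# ---------------------------------------------------------------------------

def write_model(model, path: str | Path) -> None:
    """Serialize a :class:`bna.network.BnaModel` as a schema-versioned JSON
    document.  Voxel sets are stored run-length-encoded over raveled grid
    indices; amplitudes in raveled order."""
    Path(path).write_text(json.dumps(model.to_dict(), indent=1, sort_keys=True))


def read_model(path: str | Path):
    from .network import BnaModel  # deferred: io must not hard-depend on network

    try:
        doc = json.loads(Path(path).read_text())
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ModelParseError(f"{path}: unreadable or truncated model file") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise SchemaVersionError(
            f"{path}: unknown schema version {version!r} "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    return BnaModel.from_dict(doc)
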