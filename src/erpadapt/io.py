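"""File formats: native recording container, EDF interchange, epoch container.

The native container keeps samples language-agnostic and metadata
human-readable: ``<stem>.eeg`` holds channel-major 32-bit little-endian floats
in µV, and ``<stem>.json`` holds the rate, channel labels and positions, the
event list, impedances, and (optionally) the generator's ground-truth log.

A minimal EDF exporter (16-bit, 1-second data records, 0.1 µV resolution) is
provided for interoperability; events are encoded losslessly on an extra
status channel.  Reading EDF uses mne when available.
"""

from __future__ import annotations

import json
import struct
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .generator import ContinuousRecording
from .layout import ROI_CHANNELS, SensorLayout, make_layout
from .preprocessing import EpochSet

__all__ = [
    "FormatError",
    "write_recording",
    "read_recording",
    "write_edf",
    "read_edf",
    "write_epochs",
    "read_epochs",
]

BLOCK_TYPES = ("uniform_human", "uniform_cat", "alternating")
CATEGORIES = ("human", "cat")


class FormatError(ValueError):
    """Raised when a container is missing or malformed."""


def _stem(path: str | Path) -> Path:
    p = Path(path)
    return p.with_suffix("") if p.suffix in (".eeg", ".json") else p


def write_recording(rec: ContinuousRecording, path: str | Path, ground_truth=None) -> Path:
    """Write ``<stem>.eeg`` (float32 µV, channel-major) + ``<stem>.json``."""
    stem = _stem(path)
    stem.parent.mkdir(parents=True, exist_ok=True)
    data32 = np.ascontiguousarray(rec.data, dtype="<f4")
    (stem.with_suffix(".eeg")).write_bytes(data32.tobytes())
    sidecar = {
        "rate_hz": rec.rate_hz,
        "n_channels": rec.n_channels,
        "n_samples": rec.n_samples,
        "labels": list(rec.layout.labels),
        "positions": np.asarray(rec.layout.positions).tolist(),
        "roi_sets": {k: list(v) for k, v in rec.layout.roi_sets.items()},
        "impedances": np.asarray(rec.impedances, dtype=float).tolist(),
        "events": rec.events.to_dict(orient="records"),
    }
    if ground_truth is not None:
        sidecar["ground_truth"] = json.loads(
            ground_truth if isinstance(ground_truth, str) else ground_truth.to_json()
        )
    stem.with_suffix(".json").write_text(json.dumps(sidecar))
    return stem


def read_recording(path: str | Path) -> ContinuousRecording:
    """Load a native container; raises FormatError naming any missing field."""
    stem = _stem(path)
    sidecar_path = stem.with_suffix(".json")
    data_path = stem.with_suffix(".eeg")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    if not data_path.exists():
        raise FormatError(f"missing sample file {data_path}")
    meta = json.loads(sidecar_path.read_text())
    for fieldname in ("rate_hz", "n_channels", "n_samples", "labels", "positions",
                      "impedances", "events"):
        if fieldname not in meta:
            raise FormatError(f"sidecar is missing required field {fieldname!r}")
    raw = np.frombuffer(data_path.read_bytes(), dtype="<f4")
    n_ch, n_s = meta["n_channels"], meta["n_samples"]
    if raw.size != n_ch * n_s:
        raise FormatError(
            f"sample file holds {raw.size} values, sidecar promises {n_ch}x{n_s}"
        )
    layout = SensorLayout(
        labels=tuple(meta["labels"]),
        positions=np.asarray(meta["positions"], dtype=float),
        roi_sets={k: tuple(v) for k, v in meta.get("roi_sets", {}).items()},
    )
    events = pd.DataFrame(meta["events"], columns=["sample", "category", "block_id", "block_type"])
    return ContinuousRecording(
        data=raw.reshape(n_ch, n_s).astype(np.float64),
        rate_hz=float(meta["rate_hz"]),
        events=events,
        impedances=np.asarray(meta["impedances"], dtype=float),
        layout=layout,
    )


# ---------------------------------------------------------------------------
# EDF interchange

_PHYS_MAX_UV = 3276.7  # 0.1 µV per bit at 16-bit range


def _event_code(category: str, block_type: str, block_id: int) -> int:
    return 1 + CATEGORIES.index(category) + 2 * BLOCK_TYPES.index(block_type) + 6 * int(block_id)


def _decode_event(code: int) -> tuple[str, str, int]:
    v = int(code) - 1
    return CATEGORIES[v % 2], BLOCK_TYPES[(v // 2) % 3], v // 6


def _pad(text: str, width: int) -> bytes:
    return text[:width].ljust(width).encode("ascii")


def write_edf(rec: ContinuousRecording, path: str | Path) -> Path:
    """Export to EDF: 16-bit samples at 0.1 µV resolution, 1-s data records.

    Events are written losslessly on a final ``Status`` channel (one nonzero
    sample per stimulus onset, code encoding category/block type/block id);
    the record is zero-padded to a whole number of seconds.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rate = int(round(rec.rate_hz))
    n_records = int(np.ceil(rec.n_samples / rate))
    n_pad = n_records * rate
    ns = rec.n_channels + 1

    stim = np.zeros(n_pad, dtype=np.int16)
    for row in rec.events.itertuples(index=False):
        stim[row.sample] = _event_code(row.category, row.block_type, row.block_id)

    scaled = np.clip(rec.data / _PHYS_MAX_UV * 32767.0, -32768, 32767)
    digital = np.zeros((ns, n_pad), dtype="<i2")
    digital[:-1, : rec.n_samples] = np.round(scaled).astype("<i2")
    digital[-1] = stim

    hdr = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X synthetic repetition/adaptation EEG", 80),
            _pad("01.01.20", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (ns + 1)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(ns), 4),
        ]
    )
    labels = list(rec.layout.labels) + ["Status"]
    dims = ["uV"] * rec.n_channels + [""]
    pmins = [f"{-_PHYS_MAX_UV:.1f}"] * rec.n_channels + ["-32768"]
    pmaxs = [f"{_PHYS_MAX_UV:.1f}"] * rec.n_channels + ["32767"]
    sig_hdr = b"".join(
        [
            b"".join(_pad(lb, 16) for lb in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad(d, 8) for d in dims),
            b"".join(_pad(p, 8) for p in pmins),
            b"".join(_pad(p, 8) for p in pmaxs),
            b"".join(_pad("-32768", 8) for _ in labels),
            b"".join(_pad("32767", 8) for _ in labels),
            b"".join(_pad("", 80) for _ in labels),
            b"".join(_pad(str(rate), 8) for _ in labels),
            b"".join(_pad("", 32) for _ in labels),
        ]
    )
    with open(path, "wb") as fh:
        fh.write(hdr + sig_hdr)
        for r in range(n_records):
            fh.write(digital[:, r * rate : (r + 1) * rate].tobytes())
    return path


def read_edf(path: str | Path) -> ContinuousRecording:
    """Import an EDF recording (requires mne); assumes µV when units are absent.

    Channel positions are not stored in EDF, so the deterministic spherical
    stand-in layout is attached positionally; events are decoded from the
    ``Status`` channel if present.
    """
    try:
        import mne
    except ImportError as err:  # pragma: no cover - mne is an optional extra
        raise ImportError("reading EDF requires the optional dependency mne") from err
    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    names = raw.ch_names
    data = raw.get_data()  # SI units (V) for channels mne recognized as EEG
    if "Status" in names:
        stim_idx = names.index("Status")
        stim = data[stim_idx]
        # mne may have rescaled the status channel; recover integer codes
        scale = 1e6 if np.nanmax(np.abs(stim)) < 1.0 else 1.0
        stim = np.round(stim * scale).astype(int)
        rows = []
        for s in np.flatnonzero(stim):
            cat, bt, bid = _decode_event(stim[s])
            rows.append((int(s), cat, bid, bt))
        events = pd.DataFrame(rows, columns=["sample", "category", "block_id", "block_type"])
        keep = [i for i in range(len(names)) if i != stim_idx]
        data = data[keep]
        names = [names[i] for i in keep]
    else:
        warnings.warn("EDF has no Status channel; event list will be empty")
        events = pd.DataFrame(columns=["sample", "category", "block_id", "block_type"])
    warnings.warn("EDF carries no calibrated unit metadata here; assuming µV")
    data_uv = data * 1e6
    ref = make_layout(max(len(names), 16))
    layout = SensorLayout(
        labels=tuple(names),
        positions=ref.positions[: len(names)],
        roi_sets=dict(ROI_CHANNELS) if set(sum(map(list, ROI_CHANNELS.values()), [])) <= set(names) else {},
    )
    return ContinuousRecording(
        data=data_uv,
        rate_hz=float(raw.info["sfreq"]),
        events=events,
        impedances=np.zeros(len(names)),
        layout=layout,
    )


# ---------------------------------------------------------------------------
# epoch container


def write_epochs(epochs: EpochSet, path: str | Path) -> Path:
    """Write ``<stem>.epochs`` (float32) + ``<stem>.json`` masks/labels sidecar."""
    stem = Path(path)
    stem = stem.with_suffix("") if stem.suffix in (".epochs", ".json") else stem
    stem.parent.mkdir(parents=True, exist_ok=True)
    data32 = np.ascontiguousarray(epochs.data, dtype="<f4")
    stem.with_suffix(".epochs").write_bytes(data32.tobytes())
    sidecar = {
        "shape": list(epochs.data.shape),
        "rate_hz": epochs.rate_hz,
        "times_ms": epochs.times_ms.tolist(),
        "labels": epochs.labels.to_dict(orient="records"),
        "bad_channel_mask": epochs.bad_channel_mask.astype(int).tolist(),
        "interpolated_mask": epochs.interpolated_mask.astype(int).tolist(),
        "rejected": epochs.rejected.astype(int).tolist(),
        "reject_reason": list(map(str, epochs.reject_reason)),
        "globally_bad_channels": list(epochs.globally_bad_channels),
        "layout_labels": list(epochs.layout.labels),
        "layout_positions": np.asarray(epochs.layout.positions).tolist(),
        "layout_roi_sets": {k: list(v) for k, v in epochs.layout.roi_sets.items()},
    }
    stem.with_suffix(".json").write_text(json.dumps(sidecar))
    return stem


def read_epochs(path: str | Path) -> EpochSet:
    stem = Path(path)
    stem = stem.with_suffix("") if stem.suffix in (".epochs", ".json") else stem
    sidecar_path = stem.with_suffix(".json")
    if not sidecar_path.exists():
        raise FormatError(f"missing sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    shape = tuple(meta["shape"])
    raw = np.frombuffer(stem.with_suffix(".epochs").read_bytes(), dtype="<f4")
    if raw.size != int(np.prod(shape)):
        raise FormatError("epoch data size does not match sidecar shape")
    layout = SensorLayout(
        labels=tuple(meta["layout_labels"]),
        positions=np.asarray(meta["layout_positions"], dtype=float),
        roi_sets={k: tuple(v) for k, v in meta["layout_roi_sets"].items()},
    )
    return EpochSet(
        data=raw.reshape(shape).astype(np.float64),
        times_ms=np.asarray(meta["times_ms"], dtype=float),
        labels=pd.DataFrame(meta["labels"]),
        layout=layout,
        rate_hz=float(meta["rate_hz"]),
        bad_channel_mask=np.asarray(meta["bad_channel_mask"], dtype=bool),
        interpolated_mask=np.asarray(meta["interpolated_mask"], dtype=bool),
        rejected=np.asarray(meta["rejected"], dtype=bool),
        reject_reason=np.asarray(meta["reject_reason"], dtype=object),
        globally_bad_channels=tuple(meta["globally_bad_channels"]),
    )
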