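"""Preprocessing chain: continuous recording -> clean, average-referenced epochs.

The chain runs, in order: zero-phase 30-Hz low-pass filtering, segmentation
into epochs from -100 to +500 ms around stimulus onset, per-epoch conditioning
(epoch-mean removal, linear detrend, 100-ms pre-stimulus baseline), impedance-
and amplitude-based bad-channel marking (any sample beyond +-150 µV), rejection
of epochs with more than 12 bad channels, spherical-spline interpolation of the
remaining bad channels, and re-referencing to the average of all electrodes.
All thresholds are parameters with those values as defaults.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.signal import butter, filtfilt

from .design import CONDITION_OF_TRIAL
from .generator import ContinuousRecording
from .layout import SensorLayout
from .spline import interpolation_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "EpochSet",
    "PreprocessingParams",
    "QCReport",
    "lowpass_filter",
    "reject_impedance",
    "segment_epochs",
    "condition_epochs",
    "mark_bad_amplitude",
    "interpolate_spline",
    "rereference_average",
    "run_preprocessing",
]


@dataclass
class EpochSet:
    """Epoched EEG with per-epoch labels, bad-channel masks and rejection flags."""

    data: np.ndarray  # (n_epochs, n_channels, n_samples), µV
    times_ms: np.ndarray  # sample grid, -100 .. +496 ms at 250 Hz
    labels: pd.DataFrame  # per-epoch: category, block_id, block_type [, condition]
    layout: SensorLayout
    rate_hz: float
    bad_channel_mask: np.ndarray = None  # (n_epochs, n_channels) bool
    interpolated_mask: np.ndarray = None  # provenance of replaced channels
    rejected: np.ndarray = None  # (n_epochs,) bool
    reject_reason: np.ndarray = None  # (n_epochs,) object
    globally_bad_channels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        n_ep, n_ch, _ = self.data.shape
        if self.bad_channel_mask is None:
            self.bad_channel_mask = np.zeros((n_ep, n_ch), dtype=bool)
        if self.interpolated_mask is None:
            self.interpolated_mask = np.zeros((n_ep, n_ch), dtype=bool)
        if self.rejected is None:
            self.rejected = np.zeros(n_ep, dtype=bool)
        if self.reject_reason is None:
            self.reject_reason = np.full(n_ep, "", dtype=object)

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_pre(self) -> int:
        return int(np.sum(self.times_ms < 0))

    def copy(self) -> "EpochSet":
        return EpochSet(
            data=self.data.copy(),
            times_ms=self.times_ms.copy(),
            labels=self.labels.copy(),
            layout=self.layout,
            rate_hz=self.rate_hz,
            bad_channel_mask=self.bad_channel_mask.copy(),
            interpolated_mask=self.interpolated_mask.copy(),
            rejected=self.rejected.copy(),
            reject_reason=self.reject_reason.copy(),
            globally_bad_channels=self.globally_bad_channels,
        )


@dataclass(frozen=True)
class PreprocessingParams:
    """Tunable constants of the preprocessing chain."""

    cutoff_hz: float = 30.0
    window_ms: tuple[float, float] = (-100.0, 500.0)
    impedance_threshold: float = 200.0
    amplitude_limit_uV: float = 150.0
    max_bad_channels: int = 12
    spline_m: int = 4
    spline_regularization: float = 1e-5
    spline_tol: float = 1e-10
    spline_max_terms: int = 50
    #: optional ocular-correction hook applied to the continuous recording
    #: after filtering (identity by default; a full ICA workflow is out of
    #: scope for this package and can be plugged in here).
    ocular_hook: Callable[[ContinuousRecording], ContinuousRecording] | None = None


@dataclass
class QCReport:
    """Epoch accounting produced after the full chain."""

    n_events: int
    n_segmented: int
    n_rejected: int
    n_retained: int
    n_interpolated: int  # (epoch, channel) pairs replaced by interpolation
    globally_bad_channels: tuple[str, ...]
    per_condition: pd.DataFrame  # condition, n_epochs, n_rejected, n_retained, n_interpolated


def lowpass_filter(rec: ContinuousRecording, cutoff_hz: float = 30.0) -> ContinuousRecording:
    """Zero-phase Butterworth low-pass (4th order, forward-backward)."""
    nyq = rec.rate_hz / 2.0
    if cutoff_hz >= nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must be below Nyquist ({nyq} Hz)")
    b, a = butter(4, cutoff_hz / nyq, btype="low")
    out = rec.copy()
    out.data = filtfilt(b, a, out.data, axis=1)
    return out


def reject_impedance(rec: ContinuousRecording, threshold: float = 200.0) -> tuple[str, ...]:
    """Channels whose recorded impedance exceeds the threshold (globally bad)."""
    imp = np.asarray(rec.impedances, dtype=float)
    if imp.size == 0:
        logger.warning("no impedance values recorded; impedance screening skipped")
        return ()
    idx = np.flatnonzero(imp > threshold)
    return tuple(rec.layout.labels[i] for i in idx)


def segment_epochs(
    rec: ContinuousRecording, window_ms: tuple[float, float] = (-100.0, 500.0)
) -> EpochSet:
    """Cut one epoch per event on the half-open window [start, stop) ms.

    The sample at t = 0 belongs to the post-stimulus segment.  Events whose
    window would run past either end of the recording are dropped with a
    logged warning.
    """
    rate = rec.rate_hz
    i0 = int(round(window_ms[0] * rate / 1000.0))
    i1 = int(round(window_ms[1] * rate / 1000.0))
    n_len = i1 - i0
    times = (np.arange(i0, i1) * 1000.0) / rate

    keep_rows, slabs = [], []
    for row in rec.events.itertuples(index=False):
        lo, hi = row.sample + i0, row.sample + i1
        if lo < 0 or hi > rec.n_samples:
            logger.warning("event at sample %d exceeds the record; epoch dropped", row.sample)
            continue
        keep_rows.append(row)
        slabs.append(rec.data[:, lo:hi])
    data = (
        np.stack(slabs, axis=0)
        if slabs
        else np.empty((0, rec.n_channels, n_len))
    )
    labels = pd.DataFrame(keep_rows, columns=rec.events.columns).drop(columns=["sample"])
    labels = labels.reset_index(drop=True)
    return EpochSet(data=data, times_ms=times, labels=labels, layout=rec.layout, rate_hz=rate)


def condition_epochs(epochs: EpochSet) -> EpochSet:
    """Per channel per epoch: remove epoch mean, linear trend, then baseline.

    The final step subtracts the mean of the pre-stimulus samples, so every
    retained epoch has (numerically) zero pre-stimulus mean afterwards.
    """
    out = epochs.copy()
    x = out.data
    x -= x.mean(axis=2, keepdims=True)
    n = x.shape[2]
    t = np.arange(n) - (n - 1) / 2.0
    slope = (x @ t) / (t @ t)
    x -= slope[..., None] * t
    n_pre = out.n_pre
    x -= x[:, :, :n_pre].mean(axis=2, keepdims=True)
    return out


def mark_bad_amplitude(
    epochs: EpochSet,
    limit_uV: float = 150.0,
    max_bad_channels: int = 12,
    globally_bad: tuple[str, ...] = (),
) -> EpochSet:
    """Mark channels exceeding +-limit in any sample; reject overloaded epochs.

    A channel is bad within an epoch iff any of its samples exceeds the limit
    in absolute value, or the channel is globally bad (impedance screening).
    Epochs with more than ``max_bad_channels`` bad channels are flagged
    rejected.
    """
    out = epochs.copy()
    mask = np.any(np.abs(out.data) > limit_uV, axis=2)
    if globally_bad:
        mask[:, out.layout.indices(globally_bad)] = True
    out.bad_channel_mask = mask
    over = mask.sum(axis=1) > max_bad_channels
    newly = over & ~out.rejected
    out.rejected = out.rejected | over
    out.reject_reason[newly] = "bad_channels"
    out.globally_bad_channels = tuple(globally_bad)
    return out


def interpolate_spline(
    epochs: EpochSet,
    m: int = 4,
    regularization: float = 1e-5,
    tol: float = 1e-10,
    max_terms: int = 50,
) -> EpochSet:
    """Replace bad channels of retained epochs by spherical-spline estimates.

    Only good channels enter the fit; already-good channels are untouched and
    the bad-channel masks are kept for provenance (``interpolated_mask``
    records what was replaced).  Epochs with too few good channels for the
    spline basis are rejected with a logged reason instead.
    """
    out = epochs.copy()
    pos = out.layout.positions
    mask = out.bad_channel_mask
    todo = np.flatnonzero(~out.rejected & mask.any(axis=1))
    # group epochs sharing a mask pattern to reuse the interpolation matrix
    patterns: dict[bytes, list[int]] = {}
    for e in todo:
        patterns.setdefault(mask[e].tobytes(), []).append(e)
    for key, eps in patterns.items():
        bad = np.flatnonzero(np.frombuffer(key, dtype=bool))
        good = np.setdiff1d(np.arange(out.data.shape[1]), bad)
        try:
            A = interpolation_matrix(
                pos[good], pos[bad], m=m, regularization=regularization,
                tol=tol, max_terms=max_terms,
            )
        except np.linalg.LinAlgError:
            logger.warning(
                "epochs %s: %d good channels are too few for the spline basis; rejected",
                eps, good.size,
            )
            out.rejected[eps] = True
            out.reject_reason[eps] = "too_few_good_channels"
            continue
        for e in eps:
            out.data[e][bad] = A @ out.data[e][good]
            out.interpolated_mask[e][bad] = True
    return out


def rereference_average(epochs: EpochSet) -> EpochSet:
    """Re-express every channel relative to the instantaneous all-channel mean."""
    out = epochs.copy()
    out.data -= out.data.mean(axis=1, keepdims=True)
    return out


def _condition_codes(labels: pd.DataFrame) -> pd.Series:
    return pd.Series(
        [CONDITION_OF_TRIAL[(bt, c)] for bt, c in zip(labels["block_type"], labels["category"])],
        index=labels.index,
        name="condition",
    )


def run_preprocessing(
    rec: ContinuousRecording, params: PreprocessingParams | None = None
) -> tuple[EpochSet, QCReport]:
    """Run the full chain and account for every epoch in a QC report."""
    params = params or PreprocessingParams()
    filtered = lowpass_filter(rec, params.cutoff_hz)
    if params.ocular_hook is not None:
        filtered = params.ocular_hook(filtered)
    globally_bad = reject_impedance(filtered, params.impedance_threshold)
    epochs = segment_epochs(filtered, params.window_ms)
    epochs = condition_epochs(epochs)
    epochs = mark_bad_amplitude(
        epochs, params.amplitude_limit_uV, params.max_bad_channels, globally_bad
    )
    epochs = interpolate_spline(
        epochs, params.spline_m, params.spline_regularization,
        params.spline_tol, params.spline_max_terms,
    )
    epochs = rereference_average(epochs)

    conds = _condition_codes(epochs.labels)
    interp_per_epoch = epochs.interpolated_mask.sum(axis=1)
    per_cond = pd.DataFrame(
        {
            "condition": conds,
            "rejected": epochs.rejected,
            "interpolated": np.where(epochs.rejected, 0, interp_per_epoch),
        }
    ).groupby("condition").agg(
        n_epochs=("rejected", "size"),
        n_rejected=("rejected", "sum"),
        n_interpolated=("interpolated", "sum"),
    ).reset_index()
    per_cond["n_retained"] = per_cond["n_epochs"] - per_cond["n_rejected"]
    report = QCReport(
        n_events=len(rec.events),
        n_segmented=epochs.n_epochs,
        n_rejected=int(epochs.rejected.sum()),
        n_retained=int((~epochs.rejected).sum()),
        n_interpolated=int(epochs.interpolated_mask[~epochs.rejected].sum()),
        globally_bad_channels=globally_bad,
        per_condition=per_cond,
    )
    logger.info(
        "preprocessing: %d events, %d epochs, %d rejected, %d channel interpolations",
        report.n_events, report.n_segmented, report.n_rejected, report.n_interpolated,
    )
    return epochs, report
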