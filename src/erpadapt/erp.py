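"""Condition-wise ERP averaging and P1 / N170 / N290 peak extraction.

Epochs are labeled with the four probe/adaptor conditions (FF, FC, CC, CF),
averaged per condition (probe-synchronized algebraic mean over retained
epochs), and component peaks are measured per electrode inside group-specific
windows:

* adults:  P1 maximum in 112-148 ms, N170 minimum in 148-192 ms
* infants: P1 maximum in 160-208 ms, N290 minimum in 232-324 ms

Per-electrode peak values are averaged within the three occipital electrode
arrays (peak-then-average).  Peak-to-peak measures subtract the preceding P1
maximum from the N peak, guarding against baseline drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import CONDITION_OF_TRIAL
from .preprocessing import EpochSet

__all__ = [
    "ConditionLabel",
    "ERPWaveform",
    "PeakMeasure",
    "COMPONENT_WINDOWS_MS",
    "MIN_EPOCHS",
    "assign_conditions",
    "average_condition",
    "extract_peak",
    "roi_average",
    "peak_to_peak",
    "measure_subject",
]

#: inclusive component windows (ms) per (group, component)
COMPONENT_WINDOWS_MS = {
    ("adult", "P1"): (112.0, 148.0),
    ("adult", "N"): (148.0, 192.0),
    ("infant", "P1"): (160.0, 208.0),
    ("infant", "N"): (232.0, 324.0),
}

#: minimum number of averaged epochs for a usable condition ERP
MIN_EPOCHS = {"infant": 20, "adult": 0}

ROIS = ("left", "midline", "right")


@dataclass(frozen=True)
class ConditionLabel:
    """Probe/adaptor category pair; code is probe followed by adaptor."""

    probe: str  # 'human' or 'cat'
    adaptor: str

    _CODE = {"human": "F", "cat": "C"}

    @property
    def code(self) -> str:
        return self._CODE[self.probe] + self._CODE[self.adaptor]

    @classmethod
    def from_code(cls, code: str) -> "ConditionLabel":
        rev = {"F": "human", "C": "cat"}
        return cls(probe=rev[code[0]], adaptor=rev[code[1]])


@dataclass
class ERPWaveform:
    """Per-condition average waveform with its epoch count."""

    condition: str
    data: np.ndarray  # (n_channels, n_samples)
    times_ms: np.ndarray
    n_epochs: int
    min_epochs: int
    layout: object

    @property
    def valid(self) -> bool:
        return self.n_epochs >= max(self.min_epochs, 1)


@dataclass(frozen=True)
class PeakMeasure:
    """Amplitude/latency of one component at one electrode or ROI."""

    component: str  # 'P1' or 'N'
    amplitude_uV: float
    latency_ms: float
    window_ms: tuple[float, float]
    polarity: str  # 'max' for P1, 'min' for N
    site: str  # electrode label or ROI name
    peak_to_peak_uV: float | None = None  # N only: N amplitude - P1 amplitude


def assign_conditions(epochs: EpochSet, first_trial_policy: str = "include") -> EpochSet:
    """Attach probe/adaptor condition codes to every epoch.

    Uniform-human trials are FF, uniform-cat trials CC; in alternating blocks
    human probes are FC and cat probes CF.  ``first_trial_policy`` controls
    block-initial trials, which have no within-block adaptor: ``include``
    (default) keeps their code; ``exclude`` flags them rejected.
    """
    if first_trial_policy not in ("include", "exclude"):
        raise ValueError(f"unknown first_trial_policy {first_trial_policy!r}")
    out = epochs.copy()
    try:
        codes = [
            CONDITION_OF_TRIAL[(bt, c)]
            for bt, c in zip(out.labels["block_type"], out.labels["category"])
        ]
    except KeyError as err:
        raise ValueError(f"unknown block type/category pair: {err.args[0]}") from None
    out.labels = out.labels.assign(condition=codes)
    if first_trial_policy == "exclude":
        first = out.labels["block_id"].ne(out.labels["block_id"].shift()).to_numpy()
        newly = first & ~out.rejected
        out.rejected = out.rejected | first
        out.reject_reason[newly] = "block_initial"
    return out


def average_condition(
    epochs: EpochSet, condition: str, min_epochs: int | None = None, group: str | None = None
) -> ERPWaveform:
    """Algebraic mean over the condition's retained epochs.

    ``valid`` is False when fewer than ``min_epochs`` epochs contribute
    (default: 20 for infants, 0 for adults); such waveforms are excluded
    from further analyses rather than raising.
    """
    if "condition" not in epochs.labels:
        raise ValueError("epochs have no condition labels; run assign_conditions first")
    if min_epochs is None:
        min_epochs = MIN_EPOCHS[group] if group is not None else 20
    sel = (epochs.labels["condition"] == condition).to_numpy() & ~epochs.rejected
    n = int(sel.sum())
    data = (
        epochs.data[sel].mean(axis=0)
        if n
        else np.full(epochs.data.shape[1:], np.nan)
    )
    return ERPWaveform(
        condition=condition, data=data, times_ms=epochs.times_ms,
        n_epochs=n, min_epochs=min_epochs, layout=epochs.layout,
    )


def extract_peak(erp: ERPWaveform, component: str, group: str) -> dict[str, PeakMeasure]:
    """Per-electrode peak measures over the three occipital ROI arrays.

    The amplitude is the extreme sample value inside the closed component
    window (maximum for P1, minimum for N); its time is the latency.  Ties
    resolve to the earliest sample.
    """
    window = COMPONENT_WINDOWS_MS[(group, component)]
    t = erp.times_ms
    if window[0] < t[0] or window[1] > t[-1]:
        raise ValueError(f"window {window} outside the epoch time axis")
    in_win = np.flatnonzero((t >= window[0] - 1e-9) & (t <= window[1] + 1e-9))
    polarity = "max" if component == "P1" else "min"
    out: dict[str, PeakMeasure] = {}
    for roi in ROIS:
        for lb in erp.layout.roi_sets[roi]:
            wav = erp.data[erp.layout.index(lb), in_win]
            k = int(np.argmax(wav)) if polarity == "max" else int(np.argmin(wav))
            out[lb] = PeakMeasure(
                component=component,
                amplitude_uV=float(wav[k]),
                latency_ms=float(t[in_win[k]]),
                window_ms=window,
                polarity=polarity,
                site=lb,
            )
    return out


def roi_average(per_electrode: dict[str, PeakMeasure], roi: str, layout) -> PeakMeasure:
    """Arithmetic mean of per-electrode peak values within one channel set.

    Peaks first, then average: the ROI amplitude and latency are the means of
    the already-extracted per-electrode values, not the peak of the averaged
    waveform.
    """
    labels = layout.roi_sets[roi]
    missing = [lb for lb in labels if lb not in per_electrode]
    if missing:
        raise KeyError(f"missing electrode measures for ROI {roi!r}: {missing}")
    ms = [per_electrode[lb] for lb in labels]
    first = ms[0]
    return PeakMeasure(
        component=first.component,
        amplitude_uV=float(np.mean([m.amplitude_uV for m in ms])),
        latency_ms=float(np.mean([m.latency_ms for m in ms])),
        window_ms=first.window_ms,
        polarity=first.polarity,
        site=roi,
    )


def peak_to_peak(n: PeakMeasure, p1: PeakMeasure) -> float:
    """N-component amplitude minus the preceding P1 amplitude (µV).

    Negative-going for N components; both measures must come from the same
    site."""
    if n.component != "N" or p1.component != "P1":
        raise ValueError("expected an N measure and a P1 measure, in that order")
    if n.site != p1.site:
        raise ValueError(f"site mismatch: {n.site!r} vs {p1.site!r}")
    return float(n.amplitude_uV - p1.amplitude_uV)


def waveform_roi_peak(erp: ERPWaveform, component: str, group: str, roi: str) -> PeakMeasure:
    """Alternative mode: peak of the ROI-averaged waveform (for sensitivity
    analyses; the default elsewhere is peak-then-average)."""
    window = COMPONENT_WINDOWS_MS[(group, component)]
    t = erp.times_ms
    in_win = np.flatnonzero((t >= window[0] - 1e-9) & (t <= window[1] + 1e-9))
    wav = erp.data[erp.layout.roi_indices(roi)].mean(axis=0)[in_win]
    polarity = "max" if component == "P1" else "min"
    k = int(np.argmax(wav)) if polarity == "max" else int(np.argmin(wav))
    return PeakMeasure(
        component=component, amplitude_uV=float(wav[k]), latency_ms=float(t[in_win[k]]),
        window_ms=window, polarity=polarity, site=roi,
    )


def measure_subject(
    epochs: EpochSet,
    group: str,
    subject: int | str = 0,
    min_epochs: int | None = None,
    mode: str = "peak_then_average",
) -> pd.DataFrame:
    """Tidy long-format peak table for one subject's labeled epochs.

    One row per condition x ROI x component with columns subject, group,
    condition, roi, component, amplitude, peak_to_peak, latency, n_epochs.
    Conditions with too few epochs are omitted.
    """
    if mode not in ("peak_then_average", "roi_waveform_peak"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for cond in ("FF", "FC", "CC", "CF"):
        erp = average_condition(epochs, cond, min_epochs=min_epochs, group=group)
        if not erp.valid:
            continue
        if mode == "peak_then_average":
            per_p1 = extract_peak(erp, "P1", group)
            per_n = extract_peak(erp, "N", group)
            for roi in ROIS:
                p1 = roi_average(per_p1, roi, erp.layout)
                nn = roi_average(per_n, roi, erp.layout)
                rows.append(
                    (subject, group, cond, roi, "P1", p1.amplitude_uV, np.nan,
                     p1.latency_ms, erp.n_epochs)
                )
                rows.append(
                    (subject, group, cond, roi, "N", nn.amplitude_uV,
                     peak_to_peak(nn, p1), nn.latency_ms, erp.n_epochs)
                )
        else:
            for roi in ROIS:
                p1 = waveform_roi_peak(erp, "P1", group, roi)
                nn = waveform_roi_peak(erp, "N", group, roi)
                rows.append(
                    (subject, group, cond, roi, "P1", p1.amplitude_uV, np.nan,
                     p1.latency_ms, erp.n_epochs)
                )
                rows.append(
                    (subject, group, cond, roi, "N", nn.amplitude_uV,
                     peak_to_peak(nn, p1), nn.latency_ms, erp.n_epochs)
                )
    return pd.DataFrame(
        rows,
        columns=[
            "subject", "group", "condition", "roi", "component",
            "amplitude", "peak_to_peak", "latency", "n_epochs",
        ],
    )
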