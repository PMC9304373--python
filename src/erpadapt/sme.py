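"""Bootstrapped standardized measurement error (bSME) of ERP scores.

The bSME of a subject's ERP score is the standard deviation of that score
across bootstrap resamples of the subject's retained epochs: resample the
condition's epochs with replacement (same N), average, reduce to the ROI, and
score, repeatedly.  It quantifies how much the measured score would vary under
a replication of the same recording and is therefore a per-subject
data-quality index, to be compared against between-subject variability.

For linear scores (e.g., the mean amplitude in a window) the bSME converges to
the classical standard error sigma / sqrt(N); for peak scores it inherits an
upward bias from extremum-picking, which is a property of the score itself
and is deliberately not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .erp import COMPONENT_WINDOWS_MS
from .preprocessing import EpochSet

__all__ = ["SMEResult", "bootstrap_sme", "SCORES"]

SCORES = ("peak", "mean", "peak_to_peak")


@dataclass(frozen=True)
class SMEResult:
    condition: str
    roi: str
    score: str
    n_epochs: int
    n_boot: int
    bsme_uV: float | None  # None when undefined (< 2 epochs)
    seed: int

    @property
    def defined(self) -> bool:
        return self.bsme_uV is not None


def _score_replicates(
    avg: np.ndarray, in_p1: np.ndarray, in_n: np.ndarray, score: str
) -> np.ndarray:
    """Score per replicate from (n_boot, n_roi_channels, n_samples) averages."""
    if score == "mean":
        return avg[:, :, in_n].mean(axis=2).mean(axis=1)
    n_amp = avg[:, :, in_n].min(axis=2).mean(axis=1)  # peak-then-average
    if score == "peak":
        return n_amp
    p1_amp = avg[:, :, in_p1].max(axis=2).mean(axis=1)
    return n_amp - p1_amp


def bootstrap_sme(
    epochs: EpochSet,
    condition: str,
    roi: str,
    score: str,
    group: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> SMEResult:
    """bSME of an N-component score for one condition at one ROI.

    ``score`` is one of ``peak`` (windowed N minimum, per electrode then
    ROI-averaged), ``mean`` (mean amplitude in the N window), or
    ``peak_to_peak`` (N minimum minus preceding P1 maximum).  With fewer
    than two retained epochs the bSME is undefined and flagged missing.
    """
    if score not in SCORES:
        raise ValueError(f"unknown score {score!r}; expected one of {SCORES}")
    if "condition" not in epochs.labels:
        raise ValueError("epochs have no condition labels; run assign_conditions first")
    sel = np.flatnonzero(
        (epochs.labels["condition"] == condition).to_numpy() & ~epochs.rejected
    )
    n = sel.size
    if n < 2:
        return SMEResult(condition, roi, score, n, n_boot, None, seed)

    t = epochs.times_ms
    wp = COMPONENT_WINDOWS_MS[(group, "P1")]
    wn = COMPONENT_WINDOWS_MS[(group, "N")]
    in_p1 = np.flatnonzero((t >= wp[0] - 1e-9) & (t <= wp[1] + 1e-9))
    in_n = np.flatnonzero((t >= wn[0] - 1e-9) & (t <= wn[1] + 1e-9))
    roi_idx = epochs.layout.roi_indices(roi)
    x = epochs.data[np.ix_(sel, roi_idx)]  # (n, n_roi, n_samples)

    rng = np.random.default_rng(seed)
    scores = np.empty(n_boot)
    # chunked to bound memory at large n_boot
    chunk = max(1, int(5e7 // max(x.size // n, 1)))
    for lo in range(0, n_boot, chunk):
        hi = min(lo + chunk, n_boot)
        draws = rng.integers(0, n, size=(hi - lo, n))
        avg = x[draws].mean(axis=1)
        scores[lo:hi] = _score_replicates(avg, in_p1, in_n, score)
    return SMEResult(
        condition, roi, score, n, n_boot, float(np.std(scores, ddof=1)), seed
    )
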