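"""Sensor layouts for high-density EEG simulation.

Real geodesic-net electrode coordinates are proprietary, so the package ships a
deterministic quasi-uniform stand-in: points placed on the unit sphere by the
golden-spiral construction.  Channel labels follow the ``E1``..``En`` convention
of 128-channel geodesic nets.  For the 128-channel layout, the three occipital
regions of interest used for N170/N290 extraction (left: E63, E64, E69, E70;
midline: E68, E73, E82, E76; right: E100, E96, E95, E90) are mapped onto a
spatially coherent occipital patch of the spiral so that a posterior scalp
topography actually covers them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorLayout", "make_layout", "ROI_CHANNELS", "OCCIPITAL_CENTER"]

#: ROI channel labels (left, midline, right occipital sites).
ROI_CHANNELS: dict[str, tuple[str, ...]] = {
    "left": ("E63", "E64", "E69", "E70"),
    "midline": ("E68", "E73", "E82", "E76"),
    "right": ("E100", "E96", "E95", "E90"),
}

#: Unit vector toward the occipital pole of the stand-in sphere
#: (posterior-inferior; x = left-right, y = posterior-anterior, z = up).
OCCIPITAL_CENTER = np.array([0.0, -0.9138115486202573, -0.40613846605344767])


@dataclass(frozen=True)
class SensorLayout:
    """Channel labels, unit-sphere positions, and named ROI channel groups."""

    labels: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit norm rows
    roi_sets: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.labels) != len(set(self.labels)):
            raise ValueError("channel labels must be unique")
        pos = np.asarray(self.positions, dtype=float)
        if pos.shape != (len(self.labels), 3):
            raise ValueError("positions must be (n_channels, 3)")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must lie on the unit sphere")
        for name, chans in self.roi_sets.items():
            missing = set(chans) - set(self.labels)
            if missing:
                raise ValueError(f"ROI {name!r} references unknown channels {missing}")

    @property
    def n_channels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def indices(self, labels) -> np.ndarray:
        return np.array([self.index(lb) for lb in labels], dtype=int)

    def roi_indices(self, roi: str) -> np.ndarray:
        return self.indices(self.roi_sets[roi])


def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - (2.0 * i + 1.0) / n
    phi = np.pi * (1.0 + np.sqrt(5.0)) * i
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    return pts / np.linalg.norm(pts, axis=1, keepdims=True)


def make_layout(n_channels: int) -> SensorLayout:
    """Build the deterministic spherical stand-in layout.

    Parameters
    ----------
    n_channels
        Number of electrodes; at least 16.

    Returns
    -------
    SensorLayout
        Labels ``E1``..``En``; for ``n_channels == 128`` the occipital ROI
        labels are assigned to the 12 spiral points nearest the occipital
        pole (left ROI = most leftward four, right ROI = most rightward
        four, midline ROI = the rest), and ``roi_sets`` is populated.
    """
    if n_channels < 16:
        raise ValueError(f"n_channels must be >= 16, got {n_channels}")
    pts = _golden_spiral(n_channels)
    labels = [f"E{i + 1}" for i in range(n_channels)]
    roi_sets: dict[str, tuple[str, ...]] = {}

    if n_channels == 128:
        # Relabel so ROI channel names land on a coherent occipital patch.
        cos = pts @ OCCIPITAL_CENTER
        patch = np.argsort(-cos)[:12]  # 12 channels nearest the occipital pole
        by_x = patch[np.argsort(pts[patch, 0])]
        left_idx, mid_idx, right_idx = by_x[:4], by_x[4:8], by_x[8:]
        assignment: dict[int, str] = {}
        for group, idx in (("left", left_idx), ("midline", mid_idx), ("right", right_idx)):
            # within a group, assign labels in a fixed (posteriority) order
            order = idx[np.argsort(-(pts[idx] @ OCCIPITAL_CENTER))]
            for pos_i, lab in zip(order, ROI_CHANNELS[group]):
                assignment[int(pos_i)] = lab
        taken = set(assignment.values())
        spare = iter(lb for lb in labels if lb not in taken)
        labels = [assignment.get(i, None) for i in range(n_channels)]
        labels = [lb if lb is not None else next(spare) for lb in labels]
        roi_sets = dict(ROI_CHANNELS)

    return SensorLayout(labels=tuple(labels), positions=pts, roi_sets=roi_sets)
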