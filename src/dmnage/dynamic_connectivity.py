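"""Sliding-window dynamic connectivity and the temporal-variability statistic.

The scan is segmented into T overlapping windows (default width 100 s, step
6 s); a Pearson FC matrix is computed in each. Region k's connectivity
profile in window i, F(i, k), is its FC to the other n-1 regions (self entry
excluded). Node-wise temporal variability is

    V_k = 1 - mean_{i < j} corr(F(i, k), F(j, k)),

the average over all T(T-1)/2 unordered window pairs (equivalent to the
symmetric i != j average), and network variability V is the mean of V_k over
all regions. Both lie in [0, 2]: 0 means perfectly stable windowed
connectivity, values above 1 mean anti-correlated profiles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_core import TimeSeriesMatrix
from .static_connectivity import FcMatrix, fc_matrix

__all__ = [
    "WindowSpec",
    "DfcStack",
    "window_plan",
    "dfc_stack",
    "node_variability",
    "network_variability",
    "all_node_variabilities",
]


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window layout in both seconds and volumes.

    Windows are half-open 0-based volume ranges [start, start + width_vol);
    trailing volumes that do not fill a window are dropped.
    """

    width_s: float
    step_s: float
    tr_s: float
    width_vol: int
    step_vol: int
    n_windows: int

    @property
    def windows(self) -> list[tuple[int, int]]:
        return [
            (i * self.step_vol, i * self.step_vol + self.width_vol)
            for i in range(self.n_windows)
        ]


@dataclass(frozen=True)
class DfcStack:
    """Ordered windowed FC matrices for one subject."""

    spec: WindowSpec
    matrices: tuple[FcMatrix, ...]

    def __post_init__(self) -> None:
        if len(self.matrices) < 2:
            raise ValueError("a dFC stack needs at least 2 windows")
        n = self.matrices[0].n_rois
        if any(m.n_rois != n for m in self.matrices):
            raise ValueError("all windowed matrices must share n_rois")

    @property
    def n_windows(self) -> int:
        return len(self.matrices)

    @property
    def n_rois(self) -> int:
        return self.matrices[0].n_rois


def window_plan(n_volumes: int, tr_s: float, width_s: float, step_s: float) -> WindowSpec:
    """Plan the maximal set of full sliding windows for a scan.

    Width and step must be positive exact multiples of the TR;
    T = floor((n_volumes - width_vol) / step_vol) + 1 and must be >= 2 for
    any variability computation.
    """
    if width_s <= 0 or step_s <= 0 or tr_s <= 0:
        raise ValueError("width, step and TR must be positive")
    width_vol = width_s / tr_s
    step_vol = step_s / tr_s
    if abs(width_vol - round(width_vol)) > 1e-9 or abs(step_vol - round(step_vol)) > 1e-9:
        raise ValueError(
            f"window width {width_s}s / step {step_s}s are not integer multiples of TR {tr_s}s"
        )
    width_vol = int(round(width_vol))
    step_vol = int(round(step_vol))
    if width_vol > n_volumes:
        raise ValueError(f"window of {width_vol} volumes exceeds scan length {n_volumes}")
    t = (n_volumes - width_vol) // step_vol + 1
    if t < 2:
        raise ValueError(
            f"only {t} full window fits ({n_volumes} volumes, width {width_vol}); "
            "variability needs at least 2"
        )
    return WindowSpec(
        width_s=width_s, step_s=step_s, tr_s=tr_s,
        width_vol=width_vol, step_vol=step_vol, n_windows=t,
    )


def dfc_stack(ts: TimeSeriesMatrix, spec: WindowSpec, transform: bool = False) -> DfcStack:
    """Compute the windowed FC matrix in every window of the plan.

    A zero-variance ROI inside any window is an error naming both the window
    and the ROI.
    """
    if spec.windows[-1][1] > ts.n_volumes:
        raise ValueError("window plan extends past the end of the time series")
    mats = []
    for i, (a, b) in enumerate(spec.windows):
        seg = ts.data[a:b]
        try:
            mats.append(fc_matrix(
                TimeSeriesMatrix(ts.subject_id, ts.tr_s, seg, ts.roi_labels),
                transform=transform,
            ))
        except ValueError as exc:
            raise ValueError(f"window {i} (volumes {a}:{b}): {exc}") from exc
    return DfcStack(spec=spec, matrices=tuple(mats))


def _profiles(stack: DfcStack, k: int) -> np.ndarray:
    """(T, n_rois - 1) matrix of region k's windowed connectivity profiles."""
    idx = [j for j in range(stack.n_rois) if j != k]
    return np.stack([m.values[k, idx] for m in stack.matrices])


def node_variability(stack: DfcStack, k: int) -> float:
    """Temporal variability V_k of region k's windowed connectivity profile."""
    prof = _profiles(stack, k)
    sd = prof.std(axis=1)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"zero-variance connectivity profile for ROI {k} in window {bad}")
    c = np.corrcoef(prof)
    t = stack.n_windows
    iu = np.triu_indices(t, k=1)
    v = 1.0 - float(c[iu].mean())
    # clamp corrcoef rounding at the [0, 2] boundaries
    return min(max(v, 0.0), 2.0)


def all_node_variabilities(stack: DfcStack) -> np.ndarray:
    return np.array([node_variability(stack, k) for k in range(stack.n_rois)])


def network_variability(stack: DfcStack) -> float:
    """Network temporal variability V: the mean of V_k over all regions."""
    return float(all_node_variabilities(stack).mean())
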