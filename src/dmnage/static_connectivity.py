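"""Static functional connectivity: Pearson FC matrices and within-network strength.

Functional connectivity (FC) between two regions is the Pearson correlation
of their signal time courses over the full scan. Within-network FC strength
is the mean FC over all n(n-1)/2 unordered region pairs (diagonal excluded);
for the 58-region default-mode network that is 1653 pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_core import TimeSeriesMatrix

__all__ = ["FcMatrix", "SubjectMetrics", "fc_matrix", "count_pairs", "within_network_strength"]

#: atanh(1 - 1e-7) is finite; perfect correlations are clipped here before the
#: Fisher transform so the matrix stays representable.
_CLIP = 1.0 - 1e-7


@dataclass(frozen=True)
class FcMatrix:
    """Symmetric region-by-region connectivity matrix.

    ``transformed`` marks whether Fisher's r-to-z (atanh) has been applied to
    the off-diagonal entries; the diagonal is kept at the raw value 1 and is
    excluded from every average either way.
    """

    values: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        object.__setattr__(self, "values", v)

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class SubjectMetrics:
    """The two per-subject outcomes with the window parameters used."""

    subject_id: str
    fc_strength: float
    dfc_variability: float
    window_width_s: float
    step_s: float


def fc_matrix(ts: TimeSeriesMatrix | np.ndarray, transform: bool = False) -> FcMatrix:
    """Pearson correlation matrix across ROI columns.

    Parameters
    ----------
    ts : TimeSeriesMatrix or (volumes, rois) array
    transform : apply Fisher's r-to-z (atanh) to the off-diagonal entries.
        Off-diagonal |r| = 1 is clipped to 1 - 1e-7 with a warning so the
        transform stays finite.

    Raises
    ------
    ValueError : if any ROI column has zero variance (the error names it).
    """
    if isinstance(ts, TimeSeriesMatrix):
        data = ts.data
        labels = ts.roi_labels
    else:
        data = np.asarray(ts, dtype=float)
        labels = tuple(str(i) for i in range(data.shape[1]))
    sd = data.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        names = [labels[i] for i in dead[:5]]
        raise ValueError(f"zero-variance ROI series: {names}")
    r = np.corrcoef(data, rowvar=False)
    # guard numerical overshoot from corrcoef
    np.clip(r, -1.0, 1.0, out=r)
    np.fill_diagonal(r, 1.0)
    if transform:
        off = ~np.eye(r.shape[0], dtype=bool)
        if np.any(np.abs(r[off]) >= 1.0):
            warnings.warn("off-diagonal |r| = 1 clipped to 1 - 1e-7 before atanh")
            r[off] = np.clip(r[off], -_CLIP, _CLIP)
        z = r.copy()
        z[off] = np.arctanh(r[off])
        return FcMatrix(values=z, transformed=True)
    return FcMatrix(values=r, transformed=False)


def count_pairs(n_rois: int) -> int:
    """Number of unordered ROI pairs, n(n-1)/2."""
    if n_rois < 2:
        raise ValueError("need at least 2 ROIs")
    return n_rois * (n_rois - 1) // 2


def within_network_strength(fc: FcMatrix) -> float:
    """Mean of the strict upper triangle of the FC matrix (diagonal excluded)."""
    v = fc.values
    iu = np.triu_indices(fc.n_rois, k=1)
    vals = v[iu]
    if not np.all(np.isfinite(vals)):
        raise ValueError("non-finite off-diagonal FC values")
    return float(vals.mean())
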