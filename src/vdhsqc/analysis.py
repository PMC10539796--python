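"""Downstream comparison utilities.

Trace-against-trace similarity (vd rows vs J-res or 1D projections),
multiplet metrics (resolved line positions and integrals, e.g. the
1:2:1 pseudo-triplet check), region zeroing, and scanning a query
multiplet through the vd spectrum to find its 13C row.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from scipy.signal import find_peaks

from .processing import parabolic_refine
from .spectra import Spectrum2D, Trace1D

__all__ = [
    "MultipletMetrics",
    "trace_similarity",
    "multiplet_metrics",
    "zero_region",
    "scan_match",
]


@dataclass(frozen=True)
class MultipletMetrics:
    """Resolved lines of a multiplet.

    ``positions_hz`` are offsets from the integral-weighted multiplet
    centre, strictly increasing; ``integrals`` are normalized so the
    smallest line is 1 (a 1:2:1 pseudo-triplet reads [1, 2, 1]).
    """

    positions_hz: Tuple[float, ...]
    integrals: Tuple[float, ...]
    n_resolved: int

    def __post_init__(self) -> None:
        if self.n_resolved:
            if any(i <= 0 for i in self.integrals):
                raise ValueError("line integrals must be positive")
            if any(b <= a for a, b in zip(self.positions_hz, self.positions_hz[1:])):
                raise ValueError("line positions must be strictly increasing")


def _common_grid(a: Trace1D, b: Trace1D, region: Tuple[float, float]):
    """Resample both traces by linear interpolation onto the finer of the
    two grids over ``region`` (a ppm interval)."""
    lo, hi = sorted(region)
    lo = max(lo, a.axis.right_edge_ppm, b.axis.right_edge_ppm)
    hi = min(hi, a.axis.left_edge_ppm, b.axis.left_edge_ppm)
    if hi <= lo:
        raise ValueError("empty overlap between the traces over the region")
    step = min(a.axis.ppm_per_point, b.axis.ppm_per_point)
    grid = np.arange(lo, hi, step)

    def resample(tr: Trace1D) -> np.ndarray:
        ppm = tr.axis.ppm_scale()[::-1]            # ascending for interp
        return np.interp(grid, ppm, tr.intensities[::-1])

    return resample(a), resample(b)


def trace_similarity(a: Trace1D, b: Trace1D, region: Tuple[float, float]) -> float:
    """Pearson correlation of mean-centred intensities over a ppm region.

    Scale-free: sensitive to the multiplet *shape*, not the amplitude.
    Returns 0.0 when either trace has no variance over the region.
    """
    ya, yb = _common_grid(a, b, region)
    ya = ya - ya.mean()
    yb = yb - yb.mean()
    na, nb = np.linalg.norm(ya), np.linalg.norm(yb)
    if na == 0.0 or nb == 0.0:
        return 0.0
    return float(np.clip(ya @ yb / (na * nb), -1.0, 1.0))


def multiplet_metrics(trace: Trace1D, threshold: float) -> MultipletMetrics:
    """Locate resolved maxima (prominence >= ``threshold``) and integrate
    each line between its flanking minima.

    Boundaries between adjacent lines sit at the interior minimum; the
    outermost lines integrate to the trace ends.  Positions are
    parabolically refined and reported as Hz offsets from the
    integral-weighted centre.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    y = trace.intensities
    peaks, _ = find_peaks(y, prominence=threshold)
    if len(peaks) == 0:
        return MultipletMetrics((), (), 0)

    bounds = [0]
    for left, right in zip(peaks[:-1], peaks[1:]):
        bounds.append(left + int(np.argmin(y[left:right + 1])))
    bounds.append(len(y) - 1)

    dhz = trace.axis.hz_per_point
    hz = trace.axis.index_to_hz(np.arange(len(y)))
    positions, integrals = [], []
    for k, p in enumerate(peaks):
        seg = slice(bounds[k], bounds[k + 1] + 1)
        integrals.append(float(np.sum(y[seg]) * dhz))
        refined = parabolic_refine(y, int(p))
        positions.append(float(trace.axis.index_to_hz(refined)))
    integrals = np.array(integrals)
    positions = np.array(positions)
    center = float(np.sum(positions * integrals) / np.sum(integrals))
    offsets = positions - center
    order = np.argsort(offsets)
    integrals = integrals[order] / integrals.min()
    return MultipletMetrics(
        positions_hz=tuple(offsets[order]),
        integrals=tuple(integrals),
        n_resolved=len(peaks),
    )


def zero_region(
    obj: Union[Trace1D, Spectrum2D],
    regions: Union[Tuple[float, float], Sequence[Tuple[float, float]]],
) -> Union[Trace1D, Spectrum2D]:
    """Return a copy with intensities inside the ppm region(s) set to zero.

    For a :class:`Spectrum2D` the regions select f2 (proton) columns
    across all rows.  Idempotent; the output integral equals the input
    integral minus the region integral exactly.
    """
    if isinstance(regions, tuple) and len(regions) == 2 \
            and np.isscalar(regions[0]):
        regions = [regions]
    axis = obj.axis if isinstance(obj, Trace1D) else obj.f2_axis
    ppm = axis.ppm_scale()
    mask = np.zeros(axis.n_points, dtype=bool)
    for lo, hi in regions:
        lo, hi = sorted((lo, hi))
        if hi > axis.left_edge_ppm or lo < axis.right_edge_ppm:
            raise ValueError(
                f"region ({lo}, {hi}) ppm outside the axis range "
                f"[{axis.right_edge_ppm:.6g}, {axis.left_edge_ppm:.6g}]"
            )
        mask |= (ppm >= lo) & (ppm <= hi)
    if isinstance(obj, Trace1D):
        out = obj.intensities.copy()
        out[mask] = 0.0
        return Trace1D(out, obj.axis, dict(obj.origin))
    out2 = obj.data.copy()
    out2[:, mask] = 0.0
    return Spectrum2D(out2, obj.f1_axis, obj.f2_axis, obj.label,
                      dict(obj.provenance))


def scan_match(
    vd: Spectrum2D,
    query: Trace1D,
    region: Tuple[float, float],
) -> List[Tuple[float, float]]:
    """Rank every 13C row of ``vd`` by shape similarity to a query trace.

    Returns ``[(f1_ppm, similarity), ...]`` sorted by similarity
    descending (ties broken by f1 index).  Rows with no signal over the
    region score 0.  The high-resolution multiplet pattern, not just the
    chemical shift, drives the match.
    """
    results = []
    for r in range(vd.f1_axis.n_points):
        row = Trace1D(vd.data[r], vd.f2_axis,
                      {"f1_index": r, "f1_ppm": float(vd.f1_axis.index_to_ppm(r))})
        sim = trace_similarity(row, query, region)
        results.append((float(vd.f1_axis.index_to_ppm(r)), sim, r))
    results.sort(key=lambda t: (-t[1], t[2]))
    return [(ppm, sim) for ppm, sim, _ in results]
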