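"""Time-to-frequency processing: apodization, zero filling, Fourier transform.

The chain implemented here is the ordinary 2D absorption-mode processing
of States-type hypercomplex data: window and transform t2, build the
complex t1 interferogram from the cosine/sine components, window and
transform t1, keep the real part.  Frequency points are mapped so that
index 0 of every dimension is the downfield edge (see
:class:`~vdhsqc.axes.FrequencyAxis`).

Resolution reduction — deliberately truncating t2 before the transform to
collapse multiplet fine structure into one peak per doublet component —
is the first stage of the virtual-decoupling pipeline and lives here too.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import numpy as np

from .axes import FrequencyAxis
from .spectra import RawFID2D, Spectrum2D

__all__ = [
    "ProcessingParams",
    "apodization_window",
    "process_2d",
    "reduce_resolution",
    "parabolic_refine",
]


@dataclass(frozen=True)
class ProcessingParams:
    """Window / zero-fill choices, one set per dimension.

    Window kinds
    ------------
    ``"none"``
        No apodization.
    ``"em"``
        Exponential multiplication ``exp(-pi * lb * t)``; adds ``lb`` Hz of
        Lorentzian width.
    ``"gm"``
        Lorentz-to-Gauss ``exp(pi*|lb|*t - t^2 * pi*|lb| / (2*gb*aq))``:
        removes ``|lb|`` Hz of Lorentzian width and substitutes a Gaussian
        whose width is controlled by ``gb`` (fraction of the acquisition
        time at which the Gaussian apex sits).  The standard choice when
        line tails must not bias integrals.
    ``"sine"``
        Cosine half-bell over the acquired points.
    ``"qsine"``
        Squared-cosine half-bell — the usual indirect-dimension window:
        its truncation sidelobes are far below the cosine bell's.

    Zero-fill targets are final point counts and must be >= the acquired
    counts; ``None`` keeps the acquired count.
    """

    wdw_f2: str = "none"
    lb_f2: float = 0.0
    gb_f2: float = 0.2
    zf_f2: Optional[int] = None
    wdw_f1: str = "qsine"
    lb_f1: float = 0.0
    zf_f1: Optional[int] = None

    def f2_window(self, n_acq: int, sw_hz: float) -> np.ndarray:
        return apodization_window(self.wdw_f2, n_acq, sw_hz, self.lb_f2, self.gb_f2)

    def f1_window(self, n_acq: int, sw_hz: float) -> np.ndarray:
        return apodization_window(self.wdw_f1, n_acq, sw_hz, self.lb_f1, 0.2)


def apodization_window(kind: str, n_acq: int, sw_hz: float, lb_hz: float,
                       gb: float = 0.2) -> np.ndarray:
    """Apodization window over ``n_acq`` acquired points (dwell = 1/sw_hz)."""
    t = np.arange(n_acq) / sw_hz
    if kind == "none":
        return np.ones(n_acq)
    if kind == "em":
        if lb_hz < 0:
            raise ValueError("em window requires lb_hz >= 0")
        return np.exp(-np.pi * lb_hz * t)
    if kind == "gm":
        if gb <= 0:
            raise ValueError("gm window requires gb > 0")
        aq = n_acq / sw_hz
        a = np.pi * abs(lb_hz)
        b = a / (2.0 * gb * aq) if lb_hz != 0 else 0.0
        return np.exp(a * t - b * t * t)
    if kind == "sine":
        # cosine half-bell: 1 at t=0, 0 at the last acquired point + 1
        return np.cos(0.5 * np.pi * np.arange(n_acq) / n_acq)
    if kind == "qsine":
        # squared cosine half-bell (Hann-type): far lower truncation
        # sidelobes than the plain cosine bell
        return np.cos(0.5 * np.pi * np.arange(n_acq) / n_acq) ** 2
    raise ValueError(f"unknown window kind {kind!r}")


def _ft_axis(data: np.ndarray, n_out: int, axis: int) -> np.ndarray:
    """Zero-fill to ``n_out`` along ``axis``, FFT, and reorder bins so that
    output index 0 is the +sw/2 (downfield) edge and frequency decreases
    with index."""
    n_in = data.shape[axis]
    if n_out < n_in:
        raise ValueError("zero-fill target below acquired size")
    shape = list(data.shape)
    shape[axis] = n_out
    buf = np.zeros(shape, dtype=np.complex128)
    sl = [slice(None)] * data.ndim
    sl[axis] = slice(0, n_in)
    buf[tuple(sl)] = data
    ft = np.fft.fft(buf, axis=axis)
    # bin k holds frequency k * (sw/n_out) mod sw; axis index i wants
    # frequency sw/2 - i * sw/n_out  =>  bin (n_out//2 - i) mod n_out
    order = (n_out // 2 - np.arange(n_out)) % n_out
    return np.take(ft, order, axis=axis)


def _halve_first_point(data: np.ndarray, axis: int) -> np.ndarray:
    """Scale the first time-domain point by 0.5 (standard correction that
    removes the constant baseline offset of the discrete FT)."""
    out = data.copy()
    sl = [slice(None)] * data.ndim
    sl[axis] = 0
    out[tuple(sl)] = out[tuple(sl)] * 0.5
    return out


def process_2d(raw: RawFID2D, proc: Optional[ProcessingParams] = None) -> Spectrum2D:
    """Transform hypercomplex raw data into a real absorption-mode spectrum.

    Axes are recalibrated for zero filling (same width and left edge, more
    points).  Processing is linear in the input amplitude.
    """
    if proc is None:
        proc = ProcessingParams()
    n_t1, n_t2 = raw.n_t1, raw.n_t2
    n_acq2 = raw.n_t2_acquired
    zf2 = proc.zf_f2 if proc.zf_f2 is not None else n_t2
    zf1 = proc.zf_f1 if proc.zf_f1 is not None else n_t1
    if zf2 < n_t2 or zf1 < n_t1:
        raise ValueError("zero-fill target below acquired size")

    w2 = np.zeros(n_t2)
    w2[:n_acq2] = proc.f2_window(n_acq2, raw.f2_axis.sw_hz)
    td = raw.data * w2[None, :]
    td = _halve_first_point(td, axis=1)
    rows = _ft_axis(td, zf2, axis=1)

    # States: interferogram = Re(cos rows) + i Re(sin rows)
    interf = rows[0::2].real + 1j * rows[1::2].real
    w1 = proc.f1_window(n_t1, raw.f1_axis.sw_hz)
    interf = interf * w1[:, None]
    interf = _halve_first_point(interf, axis=0)
    spec = _ft_axis(interf, zf1, axis=0).real

    return Spectrum2D(
        data=spec,
        f1_axis=raw.f1_axis.with_n_points(zf1),
        f2_axis=raw.f2_axis.with_n_points(zf2),
        label=raw.label,
        provenance={
            **raw.provenance,
            "processing": {
                "wdw_f2": proc.wdw_f2, "lb_f2": proc.lb_f2, "gb_f2": proc.gb_f2,
                "zf_f2": zf2, "wdw_f1": proc.wdw_f1, "lb_f1": proc.lb_f1,
                "zf_f1": zf1, "n_t2_acquired": n_acq2,
            },
        },
    )


def _rows_to_fids(spec: Spectrum2D) -> np.ndarray:
    """Reconstruct complex t2 FIDs from the real rows of a processed
    spectrum (Hilbert-transform step): the inverse FT of an absorption row
    is (s(t) + conj(s(-t)))/2, so for a decayed causal FID the first half
    recovers s(t)/2."""
    n = spec.f2_axis.n_points
    order = (n // 2 - np.arange(n)) % n
    # invert the bin reordering done at FT time
    inv = np.empty(n, dtype=int)
    inv[order] = np.arange(n)
    fbins = spec.data[:, inv]
    g = np.fft.ifft(fbins, axis=1)
    fid = np.zeros_like(g)
    fid[:, 0] = g[:, 0]
    fid[:, 1:n // 2] = 2.0 * g[:, 1:n // 2]
    return fid


def reduce_resolution(
    source: Union[RawFID2D, Spectrum2D],
    n_t2_keep: int,
    lb_hz: float = 2.0,
    zero_fill_to: Optional[int] = None,
    proc: Optional[ProcessingParams] = None,
    taper: str = "none",
) -> Spectrum2D:
    """Reprocess the direct dimension with only ``n_t2_keep`` time points.

    Truncating t2 destroys the J fine structure of each doublet component
    on purpose, leaving a single (broad) peak per component; ``lb_hz`` of
    exponential broadening plus an optional ``taper`` window over the
    kept points (``"qsine"`` — squared cosine — suppresses the sinc
    sidelobes a hard truncation otherwise rings with; the pipeline uses
    it) smooth the cut, and the truncated FID may be zero filled to
    ``zero_fill_to`` points so peak centroids can be read off a finer
    digital grid (zero filling adds no J information).  With the default
    ``taper="none"``, full length and zero broadening the operation is
    the identity.

    When only a frequency-domain :class:`Spectrum2D` is available the
    complex rows are rebuilt by Hilbert transform and inverse-transformed
    first; this is an approximation (the result carries the window of the
    original processing on top of ``lb_hz``) and is flagged in the
    provenance metadata.
    """
    if n_t2_keep < 4:
        raise ValueError("n_t2_keep must be >= 4")
    if lb_hz < 0:
        raise ValueError("lb_hz must be >= 0")
    zf2 = zero_fill_to if zero_fill_to is not None else n_t2_keep
    if zf2 < n_t2_keep:
        raise ValueError("zero_fill_to must be >= n_t2_keep")

    if isinstance(source, RawFID2D):
        if n_t2_keep > source.n_t2:
            raise ValueError(
                f"n_t2_keep={n_t2_keep} exceeds the {source.n_t2} available t2 points"
            )
        tw = apodization_window(taper, n_t2_keep, source.f2_axis.sw_hz, 0.0)
        td = source.data[:, :n_t2_keep] * tw[None, :]
        trunc = RawFID2D(
            data=td,
            f1_axis=source.f1_axis,
            f2_axis=source.f2_axis.with_n_points(n_t2_keep),
            label=source.label,
            n_t2_acquired=min(source.n_t2_acquired, n_t2_keep),
            acquisition=source.acquisition,
            provenance={**source.provenance, "reduced_resolution": n_t2_keep},
        )
        if proc is None:
            proc = ProcessingParams()
        proc = replace(proc, wdw_f2="em", lb_f2=lb_hz, zf_f2=zf2)
        return process_2d(trunc, proc)

    # frequency-domain fallback
    spec = source
    n = spec.f2_axis.n_points
    if n_t2_keep > n // 2:
        raise ValueError(
            "Hilbert-reconstructed FIDs are only valid over the first half of "
            f"the grid: n_t2_keep={n_t2_keep} > {n // 2}"
        )
    fids = _rows_to_fids(spec)[:, :n_t2_keep]
    w = apodization_window(taper, n_t2_keep, spec.f2_axis.sw_hz, 0.0) \
        * apodization_window("em", n_t2_keep, spec.f2_axis.sw_hz, lb_hz)
    td = _halve_first_point(fids * w[None, :], axis=1)
    out = _ft_axis(td, zf2, axis=1).real
    return Spectrum2D(
        data=out,
        f1_axis=spec.f1_axis,
        f2_axis=spec.f2_axis.with_n_points(zf2),
        label=spec.label,
        provenance={
            **spec.provenance,
            "reduced_resolution": n_t2_keep,
            "hilbert_reconstructed": True,
            "lb_hz": lb_hz,
        },
    )


def parabolic_refine(y: np.ndarray, i: int) -> float:
    """Sub-point position of an extremum by parabolic interpolation through
    the point ``i`` and its two neighbours; returns a fractional index."""
    if i <= 0 or i >= len(y) - 1:
        return float(i)
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(i)
    return i + 0.5 * (y0 - y2) / denom
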