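"""Time-frequency image construction: the classifier input tensors.

Each segment channel goes through synchrosqueezing (or plain CWT magnitude
on the same linear grid), a 0-50 Hz band limit, magnitude, a bilinear
resize to 128 x 128 and per-channel min-max normalization; the channels are
stacked in montage order into an ``H x W x C`` tensor in ``[0, 1]``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .segmentation import Label, LabeledSegment
from .synchrosqueezing import (
    CWTMap,
    ScaleGrid,
    SWTMap,
    WaveletSpec,
    cwt,
    interpolate_cwt_magnitude,
    make_scale_grid,
    phase_transform,
    synchrosqueeze,
)

__all__ = ["TFImage", "band_limit", "to_magnitude", "resize_bilinear", "build_image"]

log = logging.getLogger(__name__)

DEFAULT_SIZE = 128
#: A log-scale CWT grid cannot reach 0 Hz; the nominal 0-50 Hz band is
#: realized as [0.5, 50] Hz.
DEFAULT_FMIN = 0.5
DEFAULT_FMAX = 50.0


@dataclass
class TFImage:
    """``H x W x C`` image tensor in [0, 1] plus segment provenance."""

    pixels: np.ndarray
    label: Label
    record_id: str
    start: float
    duration: float

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3:
            raise ValueError("pixels must be H x W x C")
        if not np.isfinite(self.pixels).all():
            raise ValueError("non-finite pixel values")
        if self.pixels.min() < 0 or self.pixels.max() > 1:
            raise ValueError("pixel values must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.pixels.shape


def band_limit(
    swt_map: SWTMap, fmin: float = DEFAULT_FMIN, fmax: float = DEFAULT_FMAX
) -> SWTMap:
    """Drop frequency rows outside ``[fmin, fmax]``."""
    keep = (swt_map.freqs >= fmin) & (swt_map.freqs <= fmax)
    if not keep.any():
        raise ValueError(
            f"band [{fmin}, {fmax}] Hz does not overlap the map's grid "
            f"[{swt_map.freqs[0]}, {swt_map.freqs[-1]}] Hz"
        )
    return SWTMap(
        coeffs=swt_map.coeffs[keep],
        freqs=swt_map.freqs[keep],
        times=swt_map.times,
    )


def to_magnitude(swt_map: SWTMap, log_scale: bool = False) -> np.ndarray:
    """Elementwise ``|T|`` (optionally ``log1p|T|``)."""
    mag = np.abs(swt_map.coeffs)
    return np.log1p(mag) if log_scale else mag


def resize_bilinear(
    matrix: np.ndarray, out_h: int = DEFAULT_SIZE, out_w: int = DEFAULT_SIZE
) -> np.ndarray:
    """Bilinear resize with half-pixel-center sampling (no corner
    alignment); output values stay within the input's min/max range.

    A 1-pixel input dimension falls back to nearest-neighbor along that
    axis (logged).
    """
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2:
        raise ValueError("expected a 2-D matrix")
    h0, w0 = m.shape
    if h0 < 2 or w0 < 2:
        log.warning("resize input %dx%d has a 1-pixel axis; using nearest", h0, w0)

    def axis_coords(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        src = (np.arange(n_out) + 0.5) * n_in / n_out - 0.5
        src = np.clip(src, 0.0, n_in - 1.0)
        lo = np.floor(src).astype(int)
        hi = np.minimum(lo + 1, n_in - 1)
        frac = src - lo
        return lo, hi, frac

    r_lo, r_hi, r_f = axis_coords(h0, out_h)
    c_lo, c_hi, c_f = axis_coords(w0, out_w)
    if h0 == 1:
        r_f = np.zeros_like(r_f)
    if w0 == 1:
        c_f = np.zeros_like(c_f)

    top = m[r_lo][:, c_lo] * (1 - c_f) + m[r_lo][:, c_hi] * c_f
    bot = m[r_hi][:, c_lo] * (1 - c_f) + m[r_hi][:, c_hi] * c_f
    return top * (1 - r_f[:, None]) + bot * r_f[:, None]


def _normalize(mat: np.ndarray) -> np.ndarray:
    lo, hi = mat.min(), mat.max()
    if hi <= lo:
        return np.zeros_like(mat)
    return (mat - lo) / (hi - lo)


def build_image(
    segment: LabeledSegment,
    wavelet: WaveletSpec | None = None,
    grid: ScaleGrid | None = None,
    freq_bins: int = DEFAULT_SIZE,
    *,
    transform: str = "swt",
    fmin: float = DEFAULT_FMIN,
    fmax: float = DEFAULT_FMAX,
    out_size: int = DEFAULT_SIZE,
    log_scale: bool = False,
    global_normalize: bool = False,
) -> TFImage:
    """Build the classifier input tensor for one segment.

    Per channel: transform (``swt`` or ``cwt``-on-linear-grid) ->
    band limit -> magnitude -> bilinear resize -> min-max normalization
    (per channel by default); channels are stacked in montage order.
    """
    if transform not in ("swt", "cwt"):
        raise ValueError(f"unknown transform {transform!r}")
    wavelet = wavelet or WaveletSpec()
    if grid is None:
        grid = make_scale_grid(segment.fs, fmin, fmax, wavelet=wavelet)
    if not np.isfinite(segment.data).all():
        raise ValueError("segment contains non-finite samples")

    planes = []
    lin_freqs = np.linspace(grid.fmin, grid.fmax, freq_bins)
    for ch in range(segment.data.shape[0]):
        x = segment.data[ch]
        cmap = cwt(x, wavelet, grid, derivative=(transform == "swt"))
        if transform == "swt":
            smap = synchrosqueeze(cmap, phase_transform(cmap), freq_bins)
        else:
            smap = SWTMap(
                coeffs=interpolate_cwt_magnitude(cmap, lin_freqs).astype(complex),
                freqs=lin_freqs,
                times=cmap.times,
            )
        mag = to_magnitude(band_limit(smap, fmin, fmax), log_scale=log_scale)
        planes.append(resize_bilinear(mag, out_size, out_size))

    stack = np.stack(planes, axis=-1)
    if global_normalize:
        stack = _normalize(stack)
    else:
        stack = np.stack([_normalize(stack[..., c]) for c in range(stack.shape[-1])], axis=-1)
    return TFImage(
        pixels=stack.astype(np.float32),
        label=segment.label,
        record_id=segment.record_id,
        start=segment.start,
        duration=segment.duration,
    )
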