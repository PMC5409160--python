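"""Fourier-domain directional filters for propagating shear waves.

A real displacement field u(x, t) traveling toward +x concentrates its
discrete Fourier energy in the two (k_x, omega) quadrants where
sign(k_x) * sign(omega) = -1 (conjugate halves of one propagation sense
under numpy's forward-transform sign convention).  The quadrant filter
passes those quadrants, zeroes the complementary pair, and sets the
k_x = 0 and omega = 0 boundary lines to an intermediate value (default
0.5) to avoid ringing from sharp filter edges.

Higher-dimensional filters multiply the quadrant mask by an angular
weight cos^q(theta) about the assumed propagation direction u in spatial
frequency space, with negative cosines clamped to zero so backward waves
are rejected rather than passed by an even power.  The product is
symmetrized under simultaneous negation of all frequency axes
(max of the mask and its mirror), so filtering a real field returns a
real field.

Filter dimensionality refers to the number of transformed axes:
2-D -> (x, t) per depth, 3-D -> (x, z, t) on the imaging plane,
4-D -> (x, y, z, t) on the full volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .phantom import DisplacementField, GridSpec

__all__ = [
    "FilterSpec",
    "FilterArray",
    "quadrant_filter",
    "angular_filter",
    "build_filter",
    "apply_filter",
    "apply_filter_array",
]

#: sign(k_x) * sign(omega) of the passing quadrants for +x-traveling waves
#: under numpy's FFT convention (fixed by the functional pass/reject test).
_PASS_SIGN = -1


@dataclass(frozen=True)
class FilterSpec:
    """Directional-filter configuration.

    dimensionality: 2, 3 or 4 transformed axes; u: unit propagation
    direction in the spatial-frequency subspace (2 components for 3-D,
    3 for 4-D; ignored for 2-D); q: angular cosine exponent;
    boundary_value: weight on the zero-frequency quadrant boundaries.
    """

    dimensionality: int
    u: tuple[float, ...] | None = None
    q: float = 2.0
    boundary_value: float = 0.5

    def __post_init__(self) -> None:
        if self.dimensionality not in (2, 3, 4):
            raise ValueError(f"dimensionality must be 2, 3 or 4, got {self.dimensionality}")
        if self.q < 0:
            raise ValueError("q must be >= 0")
        if not (0.0 <= self.boundary_value <= 1.0):
            raise ValueError("boundary_value must be in [0, 1]")
        expected = {2: 0, 3: 2, 4: 3}[self.dimensionality]
        if self.u is None:
            default = {2: None, 3: (1.0, 0.0), 4: (1.0, 0.0, 0.0)}[self.dimensionality]
            object.__setattr__(self, "u", default)
        elif expected == 0:
            raise ValueError("2-D filter takes no propagation direction u")
        else:
            u = np.asarray(self.u, dtype=float)
            if u.shape != (expected,):
                raise ValueError(
                    f"{self.dimensionality}-D filter needs a {expected}-component u"
                )
            norm = np.linalg.norm(u)
            if norm < 1e-12:
                raise ValueError("u must be nonzero")
            object.__setattr__(self, "u", tuple(u / norm))


@dataclass
class FilterArray:
    """Filter weights on the unshifted discrete-frequency grid, with the
    frequency coordinate arrays for each transformed axis."""

    weights: np.ndarray
    axes: tuple[np.ndarray, ...]

    def __post_init__(self) -> None:
        if self.weights.ndim != len(self.axes):
            raise ValueError("one frequency axis required per weight dimension")
        if np.any(self.weights < -1e-12) or np.any(self.weights > 1 + 1e-12):
            raise ValueError("filter weights must lie in [0, 1]")


def _negate(arr: np.ndarray) -> np.ndarray:
    """Map W(k) -> W(-k) on the unshifted FFT layout (index i -> (-i) mod n)."""
    idx = [(-np.arange(n)) % n for n in arr.shape]
    return arr[np.ix_(*idx)]


def quadrant_filter(
    kx_axis: np.ndarray, omega_axis: np.ndarray, boundary_value: float = 0.5
) -> FilterArray:
    """2-D (k_x, omega) mask passing +x-traveling waves.

    Weight 1 on the quadrant pair with sign(k_x)*sign(omega) = -1, 0 on the
    complementary pair, `boundary_value` on the k_x = 0 and omega = 0 lines.
    """
    kx = np.asarray(kx_axis, dtype=float)
    om = np.asarray(omega_axis, dtype=float)
    if not (np.any(kx == 0) and np.any(om == 0)):
        raise ValueError("frequency axes must include zero frequency")
    sgn = np.sign(kx)[:, None] * np.sign(om)[None, :]
    w = np.where(sgn == _PASS_SIGN, 1.0, 0.0)
    # zero-frequency lines, plus the sign-ambiguous Nyquist lines of
    # even-length axes (self-conjugate bins: negation symmetry must hold
    # exactly for the filtered field to be real)
    self_neg_kx = (2 * np.arange(kx.size)) % kx.size == 0
    self_neg_om = (2 * np.arange(om.size)) % om.size == 0
    w[self_neg_kx, :] = boundary_value
    w[:, self_neg_om] = boundary_value
    return FilterArray(w, (kx, om))


def angular_filter(
    k_axes: Sequence[np.ndarray], u: Sequence[float], q: float
) -> FilterArray:
    """Spatial-frequency weight cos^q(theta) about direction u.

    cos(theta) = (u . k) / (|u||k|); negative cosines are clamped to zero
    (backward directions rejected) and the k = 0 point is set to 1.
    """
    u = np.asarray(u, dtype=float)
    norm = np.linalg.norm(u)
    if norm < 1e-12:
        raise ValueError("u must be nonzero")
    u = u / norm
    if len(k_axes) != u.size:
        raise ValueError(f"{u.size}-component u needs {u.size} frequency axes")
    grids = np.meshgrid(*[np.asarray(a, dtype=float) for a in k_axes], indexing="ij")
    dot = sum(ui * g for ui, g in zip(u, grids))
    mag = np.sqrt(sum(g**2 for g in grids))
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.where(mag > 0, dot / np.where(mag > 0, mag, 1.0), 1.0)
    w = np.clip(cos, 0.0, None) ** q
    w[mag == 0] = 1.0
    return FilterArray(w, tuple(np.asarray(a, dtype=float) for a in k_axes))


def _freq_axes(spec: FilterSpec, grid: GridSpec) -> tuple[np.ndarray, ...]:
    dx, dy, dz = grid.spacing
    nx, ny, nz, nt = grid.shape
    kx = np.fft.fftfreq(nx, dx)
    om = np.fft.fftfreq(nt, 1.0 / grid.prf)
    if spec.dimensionality == 2:
        return (kx, om)
    kz = np.fft.fftfreq(nz, dz)
    if spec.dimensionality == 3:
        return (kx, kz, om)
    ky = np.fft.fftfreq(ny, dy)
    return (kx, ky, kz, om)


def build_filter(spec: FilterSpec, grid: GridSpec) -> FilterArray:
    """Construct the directional filter for a field on `grid`.

    2-D: quadrant mask over (k_x, omega).  3-D: angular weight over
    (k_x, k_z) times the quadrant mask, broadcast over k_z.  4-D: angular
    weight over (k_x, k_y, k_z) times the quadrant mask.  Products are
    symmetrized under joint frequency negation so filtered output is real.
    """
    axes = _freq_axes(spec, grid)
    quad = quadrant_filter(axes[0], axes[-1], spec.boundary_value).weights
    if spec.dimensionality == 2:
        return FilterArray(quad, axes)
    ang = angular_filter(axes[:-1], spec.u, spec.q).weights
    raw = ang[..., None] * quad.reshape(
        (quad.shape[0],) + (1,) * (ang.ndim - 1) + (quad.shape[1],)
    )
    sym = np.maximum(raw, _negate(raw))
    return FilterArray(sym, axes)


def apply_filter_array(data: np.ndarray, weights: np.ndarray, axes: tuple[int, ...]) -> np.ndarray:
    """FFT over `axes`, multiply by `weights` (broadcast over the rest),
    inverse FFT, real part."""
    spectrum = np.fft.fftn(data, axes=axes)
    shape = [1] * data.ndim
    for ax, n in zip(axes, weights.shape):
        shape[ax] = n
    filtered = np.fft.ifftn(spectrum * weights.reshape(shape), axes=axes)
    imag_max = np.max(np.abs(filtered.imag))
    real_max = np.max(np.abs(filtered.real))
    if real_max > 0 and imag_max > 1e-6 * real_max:
        raise RuntimeError(
            f"filter not symmetric: imaginary residue {imag_max:.3g} vs real {real_max:.3g}"
        )
    return np.ascontiguousarray(filtered.real)


def apply_filter(field: DisplacementField, spec: FilterSpec) -> DisplacementField:
    """Directionally filter a displacement field.

    2-D: each depth of the y = 0 plane is transformed over (x, t);
    3-D: the y = 0 plane is transformed over (x, z, t); 4-D: the full
    (x, y, z, t) volume.  For 2-D/3-D specs the returned field keeps a
    singleton y axis at the imaging plane.
    """
    if not np.all(np.isfinite(field.data)):
        raise ValueError("field contains non-finite values")
    filt = build_filter(spec, field.grid)
    prov = dict(field.provenance)
    prov["filter"] = {
        "dim": spec.dimensionality,
        "u": spec.u,
        "q": spec.q,
        "boundary_value": spec.boundary_value,
    }
    if spec.dimensionality == 4:
        data = apply_filter_array(field.data, filt.weights, axes=(0, 1, 2, 3))
        return DisplacementField(data, field.grid, prov)

    iy = field.y_zero_index()
    plane = field.data[:, iy, :, :]  # (x, z, t)
    if spec.dimensionality == 2:
        # one 2-D (x, t) transform per depth == a single FFT over axes (0, 2)
        data = apply_filter_array(plane, filt.weights, axes=(0, 2))
        prov["filter"]["per_depth"] = True
    else:
        data = apply_filter_array(plane, filt.weights, axes=(0, 1, 2))
    y0 = float(field.grid.y[iy])
    new_grid = GridSpec(
        (field.grid.extents[0], (y0, y0), field.grid.extents[2]),
        field.grid.spacing,
        field.grid.prf,
        field.grid.duration,
    )
    return DisplacementField(data[:, None, :, :], new_grid, prov)
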