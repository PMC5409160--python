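"""Time-of-flight shear wave speed reconstruction.

Speed images are estimated from (filtered) displacement fields by
normalized cross-correlation of displacement-through-time traces taken a
fixed patch separation `p` pixels apart.  The time lag of the correlation
peak is refined with a three-point parabolic (Jacobsen) subsample fit, and
the signed component speed is V = p * dx / dt.  Component maps are fused
over a (w - p + 1)-wide neighborhood with weights CC^2 / r (squared peak
correlation coefficient over Euclidean pixel distance), and components are
combined into the wave speed via

    V_2D = Vx Vz / sqrt(Vx^2 + Vz^2)
    V_3D = Vx Vy Vz / sqrt(Vx^2 Vy^2 + Vx^2 Vz^2 + Vy^2 Vz^2)

which are the slowness-vector identities 1/V^2 = sum_i 1/V_i^2; a
component whose lag is below one interpolated sample (speed unbounded) is
flagged invalid and drops out of the sum, which implements the
infinite-component limits of the combination formulas.

Signed speeds are kept through fusion; the magnitude is taken only when
the final map is rendered.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from scipy.fft import next_fast_len

from .phantom import DisplacementField, upsample_time

__all__ = [
    "PatchConfig",
    "VelocityComponentMap",
    "SWSMap",
    "xcorr_lag",
    "patch_velocity",
    "fuse_components_2d",
    "fuse_components_3d",
    "combine_2d",
    "combine_3d",
    "median_filter_map",
    "reconstruct",
]


@dataclass(frozen=True)
class PatchConfig:
    """Estimation kernel: patch separation p and fusion window w (pixels),
    working temporal rate prf (kHz) and pixel pitch spacing (mm)."""

    p: int = 6
    w: int = 10
    prf: float = 50.0
    spacing: float = 0.2
    #: a fused component whose magnitude falls below this fraction of the
    #: weighted-mean magnitude of its constituent estimates is dominated by
    #: sign cancellation (antisymmetric propagation about a symmetry plane,
    #: where the true component speed is unbounded) and is flagged invalid
    cancel_fraction: float = 0.25

    def __post_init__(self) -> None:
        if not (0 < self.p < self.w):
            raise ValueError(f"need 0 < p < w, got p={self.p}, w={self.w}")
        if not (0.0 <= self.cancel_fraction < 1.0):
            raise ValueError("cancel_fraction must be in [0, 1)")
        if (self.w - self.p) % 2 != 0:
            raise ValueError(f"w - p must be even, got w={self.w}, p={self.p}")
        if self.prf <= 0 or self.spacing <= 0:
            raise ValueError("prf and spacing must be positive")

    @property
    def half_window(self) -> int:
        """h' = (w - p) / 2, the fusion neighborhood half-width."""
        return (self.w - self.p) // 2


@dataclass
class VelocityComponentMap:
    """Signed per-pixel speed estimates for one axis, with the peak
    normalized correlation coefficient and a validity mask."""

    V: np.ndarray
    CC: np.ndarray
    valid: np.ndarray

    def __post_init__(self) -> None:
        if not (self.V.shape == self.CC.shape == self.valid.shape):
            raise ValueError("V, CC and valid must share a shape")
        if np.any(np.abs(self.CC[self.valid]) > 1 + 1e-9):
            raise ValueError("correlation coefficients must lie in [-1, 1]")


@dataclass
class SWSMap:
    """Reconstructed shear wave speed image (2-D) or volume (3-D), m/s."""

    speeds: np.ndarray
    valid: np.ndarray
    axes: tuple[np.ndarray, ...] | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.speeds.shape != self.valid.shape:
            raise ValueError("speeds and valid must share a shape")
        if not np.all(np.isfinite(self.speeds[self.valid])):
            raise ValueError("speeds must be finite where valid")


# ---------------------------------------------------------------------------
# cross-correlation lag estimation
# ---------------------------------------------------------------------------


def _xcorr_batch(a: np.ndarray, b: np.ndarray, prf: float):
    """Normalized cross-correlation peak lag for batches of trace pairs.

    a, b: (..., nt).  Returns (dt_ms, peak_cc, valid); dt > 0 when b lags a.
    """
    nt = a.shape[-1]
    na = a - a.mean(axis=-1, keepdims=True)
    nb = b - b.mean(axis=-1, keepdims=True)
    ea = np.sum(na**2, axis=-1)
    eb = np.sum(nb**2, axis=-1)
    nonconst = (ea > 0) & (eb > 0)

    nfft = next_fast_len(2 * nt - 1)
    fa = np.fft.rfft(na, nfft)
    fb = np.fft.rfft(nb, nfft)
    cc_circ = np.fft.irfft(fb * np.conj(fa), nfft)
    # lags -(nt-1) .. (nt-1): negative lags wrap to the tail of the circular
    # correlation
    cc = np.concatenate([cc_circ[..., nfft - (nt - 1):], cc_circ[..., :nt]], axis=-1)

    idx = np.argmax(cc, axis=-1)
    nlag = 2 * nt - 1
    boundary = (idx == 0) | (idx == nlag - 1)
    idx_c = np.clip(idx, 1, nlag - 2)
    take = np.take_along_axis
    c0 = take(cc, idx_c[..., None], -1)[..., 0]
    cm = take(cc, (idx_c - 1)[..., None], -1)[..., 0]
    cp = take(cc, (idx_c + 1)[..., None], -1)[..., 0]
    denom = cm - 2.0 * c0 + cp
    with np.errstate(divide="ignore", invalid="ignore"):
        delta = np.where(denom < 0, (cm - cp) / (2.0 * denom), 0.0)
    lag = idx - (nt - 1) + np.where(boundary, 0.0, delta)
    dt = lag / prf

    norm = np.sqrt(np.where(nonconst, ea * eb, 1.0))
    peak = np.clip(c0 / norm, -1.0, 1.0)
    valid = nonconst & ~boundary
    return dt, peak, valid


def xcorr_lag(sig_a: np.ndarray, sig_b: np.ndarray, prf: float):
    """Time lag (ms) between two equal-length traces and the peak
    normalized correlation coefficient.

    Positive lag means sig_b is a delayed copy of sig_a.  Raises on
    constant signals (the normalization is undefined); a peak on the
    correlation boundary is returned with valid=False.

    Returns (dt_ms, peak_cc, valid).
    """
    a = np.asarray(sig_a, dtype=float)
    b = np.asarray(sig_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("signals must be equal-length 1-D arrays")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("constant signal: normalized correlation undefined")
    dt, peak, valid = _xcorr_batch(a[None, :], b[None, :], prf)
    return float(dt[0]), float(peak[0]), bool(valid[0])


# ---------------------------------------------------------------------------
# per-axis component estimation
# ---------------------------------------------------------------------------


def patch_velocity(
    slab: np.ndarray,
    axis: int,
    cfg: PatchConfig,
    spacing: float | None = None,
) -> VelocityComponentMap:
    """Signed speed component along `axis` from trace pairs p pixels apart.

    `slab` has spatial axes first and time last; `axis` indexes a spatial
    axis.  The two traces straddle the center pixel at offsets -p//2 and
    +ceil(p/2).  Estimates with |dt| below one working-rate sample are
    unbounded and flagged invalid, as are centers whose patch leaves the
    slab.
    """
    slab = np.asarray(slab, dtype=float)
    ndim_sp = slab.ndim - 1
    if not (0 <= axis < ndim_sp):
        raise ValueError(f"axis {axis} not a spatial axis of a {slab.ndim}-D slab")
    dx = cfg.spacing if spacing is None else spacing
    p = cfg.p
    n = slab.shape[axis]
    if n < p + 1:
        raise ValueError(f"slab length {n} along axis {axis} too small for p={p}")
    lo = p // 2

    a = np.take(slab, np.arange(0, n - p), axis=axis)
    b = np.take(slab, np.arange(p, n), axis=axis)
    # flatten all non-time axes for batch correlation, in manageable chunks
    a2 = np.moveaxis(a, -1, 0).reshape(a.shape[-1], -1).T
    b2 = np.moveaxis(b, -1, 0).reshape(b.shape[-1], -1).T
    nrow = a2.shape[0]
    nfft = next_fast_len(2 * slab.shape[-1] - 1)
    rows_per_chunk = max(1, int(2e8 / (nfft * 16)))
    dt = np.empty(nrow)
    cc = np.empty(nrow)
    ok = np.empty(nrow, dtype=bool)
    for s in range(0, nrow, rows_per_chunk):
        sl = slice(s, min(s + rows_per_chunk, nrow))
        dt[sl], cc[sl], ok[sl] = _xcorr_batch(a2[sl], b2[sl], cfg.prf)

    shp = a.shape[:-1]
    dt = dt.reshape(shp)
    cc = cc.reshape(shp)
    ok = ok.reshape(shp)

    min_dt = 1.0 / cfg.prf  # one interpolated sample
    ok = ok & (np.abs(dt) >= min_dt - 1e-12)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(ok, p * dx / np.where(dt == 0, np.inf, dt), 0.0)

    full_shape = slab.shape[:-1]
    V = np.zeros(full_shape)
    CC = np.zeros(full_shape)
    valid = np.zeros(full_shape, dtype=bool)
    center = [slice(None)] * ndim_sp
    center[axis] = slice(lo, lo + shp[axis])
    center = tuple(center)
    V[center] = v
    CC[center] = cc
    valid[center] = ok
    return VelocityComponentMap(V, CC, valid)


# ---------------------------------------------------------------------------
# correlation/distance-weighted fusion
# ---------------------------------------------------------------------------


def _distance_kernel(h: int, ndim: int) -> np.ndarray:
    """1/r over integer offsets in [-h, h]^ndim, with r = 1 at the center."""
    coords = np.meshgrid(*([np.arange(-h, h + 1)] * ndim), indexing="ij")
    r = np.sqrt(sum(c**2 for c in coords)).astype(float)
    r[tuple([h] * ndim)] = 1.0
    return 1.0 / r

def _fuse(vcm: VelocityComponentMap, cfg: PatchConfig, comp_axis: int) -> VelocityComponentMap:
    h = cfg.half_window
    kern = _distance_kernel(h, vcm.V.ndim)
    wgt = np.where(vcm.valid, vcm.CC**2, 0.0)
    num = ndimage.correlate(vcm.V * wgt, kern, mode="constant", cval=0.0)
    den = ndimage.correlate(wgt, kern, mode="constant", cval=0.0)
    num_cc = ndimage.correlate(vcm.CC * wgt, kern, mode="constant", cval=0.0)
    num_mag = ndimage.correlate(np.abs(vcm.V) * wgt, kern, mode="constant", cval=0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fused = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
        fused_cc = np.where(den > 0, num_cc / np.where(den > 0, den, 1.0), 0.0)
        mag = np.where(den > 0, num_mag / np.where(den > 0, den, 1.0), 0.0)
    # sign-cancellation gate: see PatchConfig.cancel_fraction
    valid = (den > 0) & (np.abs(fused) >= cfg.cancel_fraction * mag)
    # edge policy: the w-window (fusion reach plus patch reach on the
    # component axis) must fit inside the field
    for ax in range(vcm.V.ndim):
        margin = cfg.w // 2 if ax == comp_axis else h
        if margin > 0:
            sl = [slice(None)] * vcm.V.ndim
            sl[ax] = slice(0, margin)
            valid[tuple(sl)] = False
            sl[ax] = slice(vcm.V.shape[ax] - margin, None)
            valid[tuple(sl)] = False
    return VelocityComponentMap(fused, np.clip(fused_cc, -1, 1), valid)


def fuse_components_2d(
    vx: VelocityComponentMap, vz: VelocityComponentMap, cfg: PatchConfig
) -> tuple[VelocityComponentMap, VelocityComponentMap]:
    """CC^2/r-weighted mean of each component map over the
    (w - p + 1)^2 neighborhood; invalid estimates get zero weight."""
    if vx.V.shape != vz.V.shape or vx.V.ndim != 2:
        raise ValueError("component maps must be co-registered 2-D arrays")
    return _fuse(vx, cfg, comp_axis=0), _fuse(vz, cfg, comp_axis=1)


def fuse_components_3d(
    vx: VelocityComponentMap,
    vy: VelocityComponentMap,
    vz: VelocityComponentMap,
    cfg: PatchConfig,
) -> tuple[VelocityComponentMap, VelocityComponentMap, VelocityComponentMap]:
    """As fuse_components_2d, over the cubic (w - p + 1)^3 neighborhood."""
    if not (vx.V.shape == vy.V.shape == vz.V.shape) or vx.V.ndim != 3:
        raise ValueError("component maps must be co-registered 3-D arrays")
    return (_fuse(vx, cfg, 0), _fuse(vy, cfg, 1), _fuse(vz, cfg, 2))


# ---------------------------------------------------------------------------
# component combination
# ---------------------------------------------------------------------------


def _combine(components: list[VelocityComponentMap], axes, meta) -> SWSMap:
    """Slowness-sum combination: 1/V^2 = sum over valid components of
    1/V_i^2, sign from the product of valid component signs.  Invalid
    components implement the unbounded-speed limits exactly."""
    shape = components[0].V.shape
    s2 = np.zeros(shape)
    nvalid = np.zeros(shape, dtype=int)
    sign = np.ones(shape)
    for c in components:
        ok = c.valid & (c.V != 0)
        with np.errstate(divide="ignore"):
            s2 += np.where(ok, 1.0 / np.where(ok, c.V, 1.0) ** 2, 0.0)
        sign *= np.where(ok, np.sign(c.V), 1.0)
        nvalid += ok.astype(int)
    valid = nvalid > 0
    speeds = np.zeros(shape)
    pos = valid & (s2 > 0)
    speeds[pos] = sign[pos] / np.sqrt(s2[pos])
    return SWSMap(speeds, valid, axes, dict(meta or {}))


def combine_2d(
    vx_bar: VelocityComponentMap,
    vz_bar: VelocityComponentMap,
    axes=None,
    meta=None,
) -> SWSMap:
    """V_2D = Vx Vz / sqrt(Vx^2 + Vz^2); where one component is invalid
    (unbounded), the other is returned (the limit of the formula)."""
    return _combine([vx_bar, vz_bar], axes, meta)


def combine_3d(
    vx_bar: VelocityComponentMap,
    vy_bar: VelocityComponentMap,
    vz_bar: VelocityComponentMap,
    axes=None,
    meta=None,
) -> SWSMap:
    """V_3D = Vx Vy Vz / sqrt(Vx^2 Vy^2 + Vx^2 Vz^2 + Vy^2 Vz^2), with
    per-component unbounded limits (one invalid component reduces to the
    2-D formula, two to the remaining component)."""
    return _combine([vx_bar, vy_bar, vz_bar], axes, meta)


# ---------------------------------------------------------------------------
# post-processing and orchestration
# ---------------------------------------------------------------------------


def median_filter_map(swsmap: SWSMap, size_mm: float, spacing) -> SWSMap:
    """NaN-aware median filter of physical size `size_mm`, converted to an
    odd pixel kernel per axis (rounded up).  Invalid pixels do not
    contribute; a pixel stays valid if any neighbor in its kernel is."""
    spacing = np.broadcast_to(np.asarray(spacing, dtype=float), (swsmap.speeds.ndim,))
    ks = [max(1, int(np.ceil(size_mm / s - 1e-9)) | 1) for s in spacing]
    data = np.where(swsmap.valid, swsmap.speeds, np.nan)
    pads = [(k // 2, k // 2) for k in ks]
    padded = np.pad(data, pads, mode="constant", constant_values=np.nan)
    win = sliding_window_view(padded, ks)
    win = win.reshape(win.shape[: swsmap.speeds.ndim] + (-1,))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN windows
        med = np.nanmedian(win, axis=-1)
    valid = np.isfinite(med)
    med = np.where(valid, med, 0.0)
    meta = dict(swsmap.meta)
    meta["median_mm"] = float(size_mm)
    return SWSMap(med, valid, swsmap.axes, meta)


def default_patch_config(spacing: float, prf: float = 50.0) -> PatchConfig:
    """p=6/w=10 at fine sampling; p=4/w=8 once spacing reaches 0.3 mm."""
    if spacing >= 0.3 - 1e-9:
        return PatchConfig(p=4, w=8, prf=prf, spacing=spacing)
    return PatchConfig(p=6, w=10, prf=prf, spacing=spacing)


def reconstruct(
    field: DisplacementField,
    mode: str = "image2d",
    cfg: PatchConfig | None = None,
    median_mm: float | None = None,
    working_prf: float = 50.0,
) -> SWSMap:
    """Full SWS reconstruction of a displacement field.

    Upsamples time traces to `working_prf` (kHz), estimates component
    speeds per axis (x and z on the y = 0 plane for ``image2d``; x, y and
    z for ``volume3d``), fuses and combines them, applies the physical
    median filter (0.5 mm default, 1.5 mm for 0.3 mm-sampled data) and
    renders speed magnitudes with a validity mask.
    """
    if mode not in ("image2d", "volume3d"):
        raise ValueError(f"mode must be 'image2d' or 'volume3d', got {mode!r}")
    pitch = max(field.grid.spacing[0], field.grid.spacing[2])
    if cfg is None:
        cfg = default_patch_config(pitch, prf=working_prf)
    if median_mm is None:
        # 0.5 mm at fine sampling, 1.5 mm once the data are decimated to
        # 0.3 mm
        median_mm = 1.5 if pitch >= 0.3 - 1e-9 else 0.5

    if field.grid.prf < working_prf:
        field = upsample_time(field, working_prf)
    cfg = PatchConfig(cfg.p, cfg.w, field.grid.prf, cfg.spacing)

    gx, gy, gz = field.grid.x, field.grid.y, field.grid.z
    dx, dy, dz = field.grid.spacing
    if mode == "image2d":
        slab = field.y_zero_plane()
        for ax, n in enumerate(slab.shape[:-1]):
            if n < cfg.w + 1:
                raise ValueError(
                    f"field too small for w={cfg.w} along spatial axis {ax} (n={n})"
                )
        vx = patch_velocity(slab, 0, cfg, spacing=dx)
        vz = patch_velocity(slab, 1, cfg, spacing=dz)
        fx, fz = fuse_components_2d(vx, vz, cfg)
        sws = combine_2d(fx, fz, axes=(gx, gz))
        sws = median_filter_map(sws, median_mm, (dx, dz))
    else:
        for ax, n in enumerate(field.data.shape[:-1]):
            if n < cfg.w + 1:
                raise ValueError(
                    f"field too small for w={cfg.w} along spatial axis {ax} (n={n})"
                )
        vx = patch_velocity(field.data, 0, cfg, spacing=dx)
        vy = patch_velocity(field.data, 1, cfg, spacing=dy)
        vz = patch_velocity(field.data, 2, cfg, spacing=dz)
        fx, fy, fz = fuse_components_3d(vx, vy, vz, cfg)
        sws = combine_3d(fx, fy, fz, axes=(gx, gy, gz))
        sws = median_filter_map(sws, median_mm, (dx, dy, dz))

    sws.speeds = np.abs(sws.speeds)  # magnitude at final rendering
    sws.meta.update(
        mode=mode,
        p=cfg.p,
        w=cfg.w,
        working_prf_khz=field.grid.prf,
        provenance=dict(field.provenance),
    )
    return sws
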