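"""Container I/O and run configuration.

Displacement fields and SWS maps are stored in HDF5: dataset
``displacement`` with axis order (x, y, z, t) and grid metadata as
attributes (``dx_mm``, ``dy_mm``, ``dz_mm``, ``prf_khz``, ``origin_mm``,
``provenance``); maps as dataset ``sws`` plus ``valid`` and coordinate
axes.  Run configurations are YAML/JSON dictionaries mirroring the
excitation-table field names (A, sigma_x, sigma_y, sigma_z, z0, t_on).
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import yaml

from .dirfilt import FilterSpec
from .phantom import (
    DisplacementField,
    ExcitationSpec,
    GridSpec,
    MaterialSpec,
    PhantomSpec,
)
from .sws import SWSMap

__all__ = [
    "save_field",
    "load_field",
    "save_sws_map",
    "load_sws_map",
    "save_sws_png",
    "load_config",
    "specs_from_config",
]


def save_field(path, field: DisplacementField) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("displacement", data=field.data)
        g = field.grid
        ds.attrs["dx_mm"], ds.attrs["dy_mm"], ds.attrs["dz_mm"] = g.spacing
        ds.attrs["prf_khz"] = g.prf
        ds.attrs["duration_ms"] = g.duration
        ds.attrs["origin_mm"] = [g.extents[i][0] for i in range(3)]
        ds.attrs["provenance"] = json.dumps(field.provenance, default=str)


def load_field(path) -> DisplacementField:
    with h5py.File(path, "r") as f:
        ds = f["displacement"]
        data = ds[()]
        spacing = (float(ds.attrs["dx_mm"]), float(ds.attrs["dy_mm"]), float(ds.attrs["dz_mm"]))
        origin = [float(v) for v in ds.attrs["origin_mm"]]
        prf = float(ds.attrs["prf_khz"])
        duration = float(ds.attrs["duration_ms"])
        provenance = json.loads(ds.attrs["provenance"])
    extents = tuple(
        (origin[i], round(origin[i] + spacing[i] * (data.shape[i] - 1), 9))
        for i in range(3)
    )
    grid = GridSpec(extents, spacing, prf, duration)
    return DisplacementField(data, grid, provenance)


def save_sws_map(path, swsmap: SWSMap) -> None:
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("sws", data=swsmap.speeds)
        f.create_dataset("valid", data=swsmap.valid.astype(np.uint8))
        if swsmap.axes is not None:
            for i, ax in enumerate(swsmap.axes):
                f.create_dataset(f"axis{i}_mm", data=np.asarray(ax))
        ds.attrs["meta"] = json.dumps(swsmap.meta, default=str)


def load_sws_map(path) -> SWSMap:
    with h5py.File(path, "r") as f:
        speeds = f["sws"][()]
        valid = f["valid"][()].astype(bool)
        axes = []
        for i in range(speeds.ndim):
            name = f"axis{i}_mm"
            if name in f:
                axes.append(f[name][()])
        meta = json.loads(f["sws"].attrs["meta"])
    return SWSMap(speeds, valid, tuple(axes) if axes else None, meta)


def save_sws_png(path, swsmap: SWSMap, vmax: float | None = None,
                 lesion_center=None, lesion_radius=None) -> None:
    """Render a 2-D SWS map to PNG, optionally outlining the true lesion."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if swsmap.speeds.ndim != 2:
        raise ValueError("PNG export is for 2-D maps")
    img = np.where(swsmap.valid, swsmap.speeds, np.nan)
    fig, ax = plt.subplots(figsize=(5, 5))
    extent = None
    if swsmap.axes is not None:
        x, z = swsmap.axes
        extent = (x[0], x[-1], z[-1], z[0])
    im = ax.imshow(img.T, extent=extent, vmin=0, vmax=vmax, cmap="viridis")
    fig.colorbar(im, ax=ax, label="SWS (m/s)")
    if lesion_center is not None and lesion_radius is not None:
        circ = plt.Circle(lesion_center, lesion_radius, fill=False,
                          color="magenta", linestyle="-.")
        ax.add_patch(circ)
    ax.set_xlabel("lateral x (mm)")
    ax.set_ylabel("depth z (mm)")
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------


def load_config(path) -> dict:
    """Parse a YAML (or JSON) run configuration file."""
    text = Path(path).read_text()
    return yaml.safe_load(text)


def _material_from(d: dict) -> MaterialSpec:
    return MaterialSpec(E=float(d["E"]), rho=float(d.get("rho", 1.0)),
                        nu=float(d.get("nu", 0.495)))


def specs_from_config(cfg: dict):
    """Validate a config dict and build the domain specs.

    Returns (phantom, excitation, grid, noise, filter_specs, estimator)
    where noise is {'snr_db', 'seeds'} and estimator holds the
    reconstruction settings.  All module invariants are checked by the
    spec constructors before any compute.
    """
    ph = cfg["phantom"]
    phantom = PhantomSpec(
        background=_material_from(ph["background"]),
        lesion=_material_from(ph.get("lesion", ph["background"])),
        lesion_center=tuple(float(v) for v in ph.get("center", (5.0, 0.0, 21.0))),
        lesion_radius=float(ph.get("radius", 2.5)),
    )
    ex = cfg["excitation"]
    if "sigma" in ex:
        sigma = tuple(float(v) for v in ex["sigma"])
    else:
        sigma = (float(ex["sigma_x"]), float(ex["sigma_y"]), float(ex["sigma_z"]))
    center = tuple(
        float(v) for v in ex.get("center", (0.0, 0.0, ex.get("z0", 21.0)))
    )
    excitation = ExcitationSpec(A=float(ex["A"]), center=center, sigma=sigma,
                                t_on=float(ex["t_on"]))
    gr = cfg["grid"]
    spacing = gr["spacing"]
    if np.isscalar(spacing):
        spacing = (float(spacing),) * 3
    else:
        spacing = tuple(float(v) for v in spacing)
    grid = GridSpec(
        extents=tuple((float(a), float(b)) for a, b in gr["extents"]),
        spacing=spacing,
        prf=float(gr["prf"]),
        duration=float(gr["duration"]),
    )
    noise = dict(cfg.get("noise", {}))
    noise.setdefault("snr_db", None)
    noise.setdefault("seeds", [0])
    filter_specs = []
    for fd in cfg.get("filters", []):
        filter_specs.append(
            FilterSpec(
                dimensionality=int(fd["dim"]),
                u=tuple(fd["u"]) if "u" in fd else None,
                q=float(fd.get("q", 2.0)),
                boundary_value=float(fd.get("boundary_value", 0.5)),
            )
        )
    estimator = dict(cfg.get("estimator", {}))
    estimator.setdefault("mode", "image2d")
    estimator.setdefault("working_prf", 50.0)
    return phantom, excitation, grid, noise, filter_specs, estimator
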