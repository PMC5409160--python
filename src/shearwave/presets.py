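"""Canonical study configurations.

Materials, excitations and grids of the spherical-lesion SWEI study:
a 3 kPa background with a 5-mm-diameter inclusion of 6, 12 or 18.75 kPa
centered at 21 mm depth and 5 mm lateral offset from the push axis, probed
by Gaussian ARFI excitations (all with z0 = 21 mm, sigma_z = 4.25 mm and
an 80 µs push):

    Excitation 1: sigma_x = sigma_y = 0.21 mm, A = 0.11 dyn (1:1 aspect)
    Excitation 2: sigma_x = 0.21, sigma_y = 0.85 mm, A = 0.11 dyn (1:4)
    Excitation 3: sigma_x = sigma_y = 0.43 mm, A = 0.05 dyn (1:1, broad)

Two grids are provided: `full_scale_grid` is the full simulation sampling
(0.1 mm, 10 kHz, 12 ms, depths 10-30 mm), and `desk_grid` is a reduced
0.2 mm grid sized so end-to-end experiments run on a laptop while keeping
the same phantom, excitation, noise and kernel parameters.
"""

from __future__ import annotations

from .phantom import ExcitationSpec, GridSpec, MaterialSpec, PhantomSpec

__all__ = [
    "BACKGROUND_E_KPA",
    "LESION_E_KPA",
    "material",
    "background_material",
    "lesion_phantom",
    "homogeneous_phantom",
    "excitation",
    "full_scale_grid",
    "desk_grid",
    "desk_homogeneous_grid",
    "SNR_DB",
    "WORKING_PRF_KHZ",
]

BACKGROUND_E_KPA = 3.0
LESION_E_KPA = (6.0, 12.0, 18.75)
LESION_CENTER_MM = (5.0, 0.0, 21.0)
LESION_RADIUS_MM = 2.5
SNR_DB = 25.0
WORKING_PRF_KHZ = 50.0

_EXCITATIONS = {
    1: dict(A=0.11, sigma=(0.21, 0.21, 4.25)),
    2: dict(A=0.11, sigma=(0.21, 0.85, 4.25)),
    3: dict(A=0.05, sigma=(0.43, 0.43, 4.25)),
}


def material(E_kpa: float) -> MaterialSpec:
    """Nearly incompressible elastic material (rho = 1 g/cm^3, nu = 0.495)."""
    return MaterialSpec(E=E_kpa, rho=1.0, nu=0.495)


def background_material() -> MaterialSpec:
    return material(BACKGROUND_E_KPA)


def lesion_phantom(lesion_E_kpa: float) -> PhantomSpec:
    """Spherical-lesion phantom: 5-mm inclusion at (5, 0, 21) mm."""
    return PhantomSpec(
        background=background_material(),
        lesion=material(lesion_E_kpa),
        lesion_center=LESION_CENTER_MM,
        lesion_radius=LESION_RADIUS_MM,
    )


def homogeneous_phantom(E_kpa: float = BACKGROUND_E_KPA) -> PhantomSpec:
    """Uniform phantom (lesion material equals the background)."""
    m = material(E_kpa)
    return PhantomSpec(m, m, LESION_CENTER_MM, LESION_RADIUS_MM)


def excitation(number: int = 1) -> ExcitationSpec:
    """Gaussian ARFI excitation 1, 2 or 3, pushed at (0, 0, 21) mm."""
    try:
        params = _EXCITATIONS[number]
    except KeyError:
        raise ValueError(f"excitation must be 1, 2 or 3, got {number}") from None
    return ExcitationSpec(A=params["A"], center=(0.0, 0.0, 21.0),
                          sigma=params["sigma"], t_on=0.08)


def full_scale_grid() -> GridSpec:
    """Full-scale sampling: 0.1 mm spacing, 10 kHz, 12 ms, depths 10-30 mm."""
    return GridSpec(
        extents=((0.0, 20.0), (-5.0, 5.0), (10.0, 30.0)),
        spacing=(0.1, 0.1, 0.1),
        prf=10.0,
        duration=12.0,
    )


def desk_grid() -> GridSpec:
    """Reduced grid for desk-scale experiments: 0.2 mm spacing, extents
    trimmed to the region the wave reaches within 12 ms."""
    return GridSpec(
        extents=((0.0, 11.6), (-3.0, 3.0), (14.6, 27.0)),
        spacing=(0.2, 0.2, 0.2),
        prf=10.0,
        duration=12.0,
    )


def desk_homogeneous_grid() -> GridSpec:
    """Smaller grid for homogeneous parameter-recovery runs."""
    return GridSpec(
        extents=((0.0, 10.0), (-1.6, 1.6), (17.0, 25.0)),
        spacing=(0.2, 0.2, 0.2),
        prf=10.0,
        duration=12.0,
    )
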