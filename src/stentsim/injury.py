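"""Injury initialization and the synthetic stent-stress generator.

Stent deployment crushes the tissue under the struts; sites whose
compressive minimum principal stress exceeds the viability threshold
``sigma_crit`` lose their cells and receive the acute post-injury initial
conditions (matrix-degrading factors and growth stimulus). The matrix
itself is not removed instantaneously — MDF-driven degradation resorbs it
over the following weeks.

The synthetic generator replaces a finite-element expansion result with a
parametric field that reproduces its qualitative injury pattern for a
corrugated-ring stent: compressive stress concentrated in bands under the
strut rings, decaying radially outward through the wall, and amplified at
the stent end rings and at the crown junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .lattice import Lattice, OCC_NONE, WALL
from .params import ConfigurationError, Geometry


def apply_injury(lat: Lattice, params) -> int:
    """Threshold the mapped stress field.

    A site is injured iff its stress is strictly below ``-sigma_crit``
    (compression negative; equality at the threshold is uninjured). At
    injured sites the occupant is removed, MDF is set to ``mdf_init`` and
    G to ``g_init``. Idempotent. Returns the injured-site count.
    """
    injured = lat.stress < -params.sigma_crit
    lat.occupant[injured] = OCC_NONE
    lat.mdf[injured] = params.mdf_init
    lat.g[injured] = params.g_init
    return int(injured.sum())


@dataclass
class StentSpec:
    """Parametric corrugated-ring stent footprint.

    ``peak_stress`` is the maximum compressive magnitude of the generated
    field (kPa), reached on the end rings and (slightly below) at crown
    junctions; plain strut segments on interior rings carry
    ``peak_stress / end_factor``.
    """

    n_crowns: int = 4
    n_rings: int = 5
    strut_width: float = 0.15    # axial Gaussian footprint (2*sigma), mm
    axial_amp: float | None = None   # crown corrugation amplitude, mm
    peak_stress: float = 60.0    # kPa, compressive magnitude
    end_factor: float = 1.5      # end/junction amplification, >= 1
    radial_decay: float = 0.25   # e-folding depth into the wall, mm
    jitter: float = 0.0          # relative multiplicative noise

    def validate(self) -> None:
        if self.n_crowns < 1 or self.n_rings < 1:
            raise ConfigurationError("stent needs >= 1 crown and >= 1 ring")
        if self.end_factor < 1:
            raise ConfigurationError("end_factor must be >= 1")
        if self.peak_stress < 0 or self.strut_width <= 0 or self.radial_decay <= 0:
            raise ConfigurationError("stent stress parameters must be positive")


def synthetic_stress_field(spec: StentSpec, geometry: Geometry,
                           r, theta, z) -> np.ndarray:
    """Compressive stress magnitude (kPa, >= 0) of the strut pattern at
    cylindrical coordinates ``(r, theta, z)`` (broadcastable arrays)."""
    spec.validate()
    z_lo, z_hi = geometry.stent_z
    pitch = (z_hi - z_lo) / spec.n_rings
    amp = spec.axial_amp if spec.axial_amp is not None else 0.3 * pitch
    w = spec.strut_width / 2.0
    base = spec.peak_stress / spec.end_factor
    depth = np.maximum(r - geometry.r_inner, 0.0)
    radial = np.exp(-depth / spec.radial_decay)

    mag = np.zeros(np.broadcast(r, theta, z).shape)
    for i in range(spec.n_rings):
        zc = z_lo + (i + 0.5) * pitch
        phase = 0.0 if i % 2 == 0 else np.pi
        corrug = np.sin(spec.n_crowns * theta + phase)
        z_strut = zc + amp * corrug
        axial = np.exp(-((z - z_strut) ** 2) / (2.0 * w ** 2))
        # end rings carry the full peak; interior crown junctions get 80%
        # of the amplification so the global maximum sits on the end rings
        if i == 0 or i == spec.n_rings - 1:
            level = np.full_like(corrug, spec.peak_stress)
        else:
            junction = np.abs(corrug) > 0.95
            level = np.where(
                junction, base * (1.0 + 0.8 * (spec.end_factor - 1.0)), base
            )
        mag = np.maximum(mag, level * axial * radial)
    return mag


def generate_synthetic_stent_stress(spec: StentSpec, lat: Lattice,
                                    geometry: Geometry,
                                    rng: np.random.Generator | None = None) -> None:
    """Assign the synthetic compressive field to the lattice wall sites
    (stress stored signed: compression negative). Deterministic unless
    ``spec.jitter > 0`` and an rng is supplied."""
    spec.validate()
    x, y, z = lat.site_centers()
    r = np.sqrt(x[:, None, None] ** 2 + y[None, :, None] ** 2)
    theta = np.arctan2(y[None, :, None], x[:, None, None])
    mag = synthetic_stress_field(spec, geometry, r, theta, z[None, None, :])
    if spec.jitter > 0.0 and rng is not None:
        mag = np.maximum(mag * (1.0 + spec.jitter * rng.standard_normal(mag.shape)), 0.0)
    wall = lat.domain == WALL
    lat.stress[wall] = -mag[wall]
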