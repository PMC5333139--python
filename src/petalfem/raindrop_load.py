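"""Statically equivalent raindrop loading on the lamina.

A terminal-velocity raindrop (default: 2 mm sphere at 6 m/s) is converted to
a single equivalent static force.  Two standard closures are exposed:

momentum   F = rho * (pi d^3 / 6) * v / tau, with contact time tau = d / v,
           i.e. F = rho * pi * d^2 * v^2 / 6
stagnation F = (rho v^2) * pi * r_c^2  (stagnation pressure over the
           contact disc of radius r_c)

The force is applied normal to the local surface, spread over the nodes
inside the contact radius with a cosine taper; the sum of nodal force
magnitudes equals F exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np

from .corolla_geometry import LaminaMesh

__all__ = ["RaindropSpec", "impact_force", "distribute_load", "impact_point"]

log = logging.getLogger(__name__)

MM = 1e-3


@dataclass(frozen=True)
class RaindropSpec:
    diameter: float = 0.002       # m
    velocity: float = 6.0         # m/s
    water_density: float = 1000.0  # kg/m^3
    impact_center: tuple[float, float] = (0.5, 0.8)  # (u, v) surface coords
    contact_radius: float = 0.001  # m, default d/2
    model: str = "momentum"

    def validate(self) -> None:
        if self.diameter <= 0 or self.water_density <= 0 or self.contact_radius <= 0:
            raise ValueError("diameter, density and contact_radius must be positive")
        if self.velocity < 0:
            raise ValueError("velocity must be >= 0")
        u, v = self.impact_center
        if not (0.0 <= u <= 1.0 and 0.0 <= v <= 1.0):
            raise ValueError("impact_center (u, v) must lie within [0, 1]^2")
        if self.model not in ("momentum", "stagnation"):
            raise ValueError(f"unknown raindrop model {self.model!r}")


def impact_force(spec: RaindropSpec) -> float:
    """Equivalent static impact force in newtons."""
    spec.validate()
    rho, d, v = spec.water_density, spec.diameter, spec.velocity
    if spec.model == "momentum":
        return rho * np.pi * d ** 2 * v ** 2 / 6.0
    return rho * v ** 2 * np.pi * spec.contact_radius ** 2


def impact_point(mesh: LaminaMesh, spec: RaindropSpec) -> np.ndarray:
    """Surface point (mm) closest to the requested (u, v) impact center."""
    uv = mesh.surface_param
    d2 = (uv[:, 0] - spec.impact_center[0]) ** 2 \
        + (uv[:, 1] - spec.impact_center[1]) ** 2
    return mesh.nodes[int(np.argmin(d2))]


def distribute_load(mesh: LaminaMesh, spec: RaindropSpec,
                    F: float | None = None) -> np.ndarray:
    """Nodal load vector (6 DOF/node, SI) for the raindrop force.

    Nodes within ``contact_radius`` of the impact point receive forces along
    their local surface normals with a cosine taper cos(pi/2 * r/R); the
    magnitudes are normalized so their sum equals F.  If no node falls in
    the radius, the nearest node takes the full load.
    """
    spec.validate()
    if F is None:
        F = impact_force(spec)
    center = impact_point(mesh, spec)
    r = np.linalg.norm(mesh.nodes - center, axis=1) * MM  # m
    R = spec.contact_radius
    # cosine-tapered contact pressure integrated over tributary nodal areas,
    # so the distribution converges to a fixed pressure footprint under mesh
    # refinement
    areas = mesh.element_areas()
    trib = np.zeros(mesh.n_nodes)
    for k in range(3):
        np.add.at(trib, mesh.triangles[:, k], areas / 3.0)
    w = trib * np.where(r < R, np.cos(0.5 * np.pi * np.minimum(r / R, 1.0)), 0.0)
    if w.sum() <= 0:
        nearest = int(np.argmin(r))
        log.warning("no mesh node within contact radius %.3g m; "
                    "applying full load at node %d", R, nearest)
        w = np.zeros(mesh.n_nodes)
        w[nearest] = 1.0
    mags = F * w / w.sum()

    normals = mesh.node_normals()
    # load pushes against the cup (toward -z side of the surface)
    sign = -np.sign(normals[:, 2])
    sign[sign == 0] = -1.0
    forces = normals * (mags * sign)[:, None]

    load = np.zeros(6 * mesh.n_nodes)
    load[0::6] = forces[:, 0]
    load[1::6] = forces[:, 1]
    load[2::6] = forces[:, 2]
    return load
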