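"""Equivalent (von Mises) elastic strain fields and summaries.

The scalar reported by commercial structural solvers for elastic analyses:

    eps_eq = 1/(1 + nu') * sqrt(1/2 * [(e1-e2)^2 + (e2-e3)^2 + (e3-e1)^2])

over principal strains e_i, with nu' the effective Poisson ratio.  The
normalization makes eps_eq equal the axial strain in a uniaxial-stress state
when nu' matches the material's Poisson ratio.

Shell surface strains are plane-stress states; the through-thickness strain
e_z = -nu/(1-nu) * (e_x + e_y) is reconstructed before the principal
decomposition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .corolla_geometry import LaminaMesh

__all__ = ["StrainSummary", "equivalent_strain", "equivalent_strain_field",
           "summarize"]


def equivalent_strain(strain_tensor: np.ndarray, nu_eff: float) -> float:
    """Equivalent elastic strain of one symmetric 3x3 small-strain tensor."""
    t = np.asarray(strain_tensor, dtype=float)
    if t.shape != (3, 3):
        raise ValueError("strain tensor must be 3x3")
    if np.max(np.abs(t - t.T)) > 1e-9:
        raise ValueError("strain tensor is not symmetric (asymmetry > 1e-9)")
    if not (0.0 <= nu_eff < 0.5):
        raise ValueError("nu_eff must be in [0, 0.5)")
    e = np.linalg.eigvalsh(t)
    s = (e[0] - e[1]) ** 2 + (e[1] - e[2]) ** 2 + (e[2] - e[0]) ** 2
    return float(np.sqrt(0.5 * s) / (1.0 + nu_eff))


def equivalent_strain_field(surface_strain: np.ndarray,
                            nu_eff: np.ndarray) -> np.ndarray:
    """Vectorized equivalent strain for per-element plane-stress states.

    surface_strain: (m, 3) rows (eps_x, eps_y, gamma_xy); e_z is recovered
    from the plane-stress condition with each element's nu.
    """
    ex, ey, g = surface_strain[:, 0], surface_strain[:, 1], surface_strain[:, 2]
    ez = -nu_eff / (1.0 - nu_eff) * (ex + ey)
    c = 0.5 * (ex + ey)
    r = np.sqrt((0.5 * (ex - ey)) ** 2 + (0.5 * g) ** 2)
    e1, e2, e3 = c + r, c - r, ez
    s = (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2
    return np.sqrt(0.5 * s) / (1.0 + nu_eff)


@dataclass
class StrainSummary:
    max_equivalent_strain: float
    argmax_element: int
    argmax_location: tuple[float, float]  # (u, v)
    field: np.ndarray
    apical_fraction: float

    def to_dict(self) -> dict:
        return {
            "max_equivalent_strain": self.max_equivalent_strain,
            "argmax_element": self.argmax_element,
            "argmax_location": list(self.argmax_location),
            "apical_fraction": self.apical_fraction,
        }


def summarize(solution, mesh: LaminaMesh) -> StrainSummary:
    """Locate the strain maximum and the apical share of high-strain elements.

    apical_fraction: among the top-decile-strain elements, the share whose
    centroid lies in the apical half (v > 0.5).  Ties at the maximum break
    to the lowest element id (np.argmax convention).
    """
    field = solution.equivalent_strain
    if field.size == 0:
        raise ValueError("empty strain field")
    arg = int(np.argmax(field))
    elem_v = mesh.surface_param[mesh.triangles, 1].mean(axis=1)
    elem_u = mesh.surface_param[mesh.triangles, 0].mean(axis=1)
    thresh = np.quantile(field, 0.9)
    top = field >= thresh
    apical = float(np.mean(elem_v[top] > 0.5)) if top.any() else 0.0
    return StrainSummary(
        max_equivalent_strain=float(field[arg]),
        argmax_element=arg,
        argmax_location=(float(elem_u[arg]), float(elem_v[arg])),
        field=field,
        apical_fraction=apical,
    )
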