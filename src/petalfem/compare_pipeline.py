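"""Paired with/without-sclereid comparison under identical raindrop loading.

Model A carries a sampled sclereid beam network on the lamina shell; model B
is the identical lamina, load and parenchyma with the network removed.
Holding geometry, load and parenchyma fixed isolates the sclereid effect;
the headline quantity is the max-equivalent-strain ratio max_B / max_A
("how much more a sclereid-free corolla deforms").

Because the parenchyma modulus is a free parameter of the model (soft ground
tissue is not tabulated for these organs), ``calibrate_parenchyma`` tunes it
once by bisection so the strain ratio matches a target; the calibration
trace, seed and configuration hash are carried in every report.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import scipy.sparse as sp
from scipy.stats import spearmanr

from . import __version__
from .corolla_geometry import LaminaSpec, LaminaMesh, build_lamina, mesh_quality
from .fem_core import (BeamSection, GlobalSystem, MaterialSpec, assemble,
                       solve_static)
from .raindrop_load import RaindropSpec, distribute_load, impact_force
from .sclereid_synth import SpeciesProfile, density_field, sample_network
from .strain_post import StrainSummary, summarize

__all__ = [
    "ComparisonReport",
    "default_config",
    "load_config",
    "run_comparison",
    "correlate_strain_density",
    "calibrate_parenchyma",
]


def default_config() -> dict:
    return {
        "seed": 1,
        "lamina": {"length": 15.0, "width": 10.0, "thickness": 0.3,
                   "curvature_depth": 2.0, "target_edge_length": 0.35},
        "sclereids": {"name": "sinensis_petal", "target_coverage": 0.5,
                      "gradient": "apical", "cell_length_range": [100.0, 300.0],
                      "branches_per_cell": [2, 6],
                      "branch_length_fraction": 0.5,
                      "beam_radius": 30.0, "influence_halfwidth": 50.0},
        "materials": {"E_sclereid": 0.5e9, "nu_sclereid": 0.4,
                      "E_parenchyma": 10e6, "nu_parenchyma": 0.3},
        "raindrop": {"diameter": 0.002, "velocity": 6.0,
                     "water_density": 1000.0, "impact_center": [0.5, 0.8],
                     "contact_radius": 0.001, "model": "momentum"},
        # in the closed bud neighboring petals and sepals overlap the lamina
        # margin; 'pinned' restrains margin translations (rotations free),
        # 'free' leaves the margin a pure cantilever edge
        "supports": {"margin": "pinned"},
    }


def load_config(path_or_dict) -> dict:
    """Load a YAML config file (or pass a dict through), filling defaults."""
    cfg = default_config()
    if path_or_dict is None:
        return cfg
    if isinstance(path_or_dict, (str, Path)):
        import yaml

        user = yaml.safe_load(Path(path_or_dict).read_text()) or {}
    else:
        user = dict(path_or_dict)
    for key, val in user.items():
        if key in cfg and isinstance(cfg[key], dict) and isinstance(val, dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    return cfg


def _objects(cfg: dict):
    lam = LaminaSpec(seed=cfg["seed"], **cfg["lamina"])
    sc = dict(cfg["sclereids"])
    prof = SpeciesProfile(
        name=sc["name"], target_coverage=sc["target_coverage"],
        gradient=sc["gradient"],
        cell_length_range=tuple(sc["cell_length_range"]),
        branches_per_cell=tuple(sc["branches_per_cell"]),
        branch_length_fraction=sc["branch_length_fraction"],
        beam_radius=sc["beam_radius"],
        influence_halfwidth=sc["influence_halfwidth"])
    mat = MaterialSpec(**cfg["materials"])
    rd = dict(cfg["raindrop"])
    rd["impact_center"] = tuple(rd["impact_center"])
    rain = RaindropSpec(**rd)
    return lam, prof, mat, rain


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _PairedModels:
    """Cached paired systems on one mesh + network + load.

    The shell stiffness is linear in the parenchyma modulus, so the shell
    block is assembled once at a reference modulus and rescaled exactly
    during calibration sweeps; beams are assembled once.
    """

    E_REF = 1e6  # Pa

    def __init__(self, mesh: LaminaMesh, network, materials: MaterialSpec,
                 rain: RaindropSpec, margin: str = "pinned"):
        if margin not in ("pinned", "free"):
            raise ValueError(f"unknown margin support {margin!r}")
        self.mesh = mesh
        self.network = network
        self.materials = materials
        self.margin = margin
        ref = MaterialSpec(E_sclereid=materials.E_sclereid,
                           nu_sclereid=materials.nu_sclereid,
                           E_parenchyma=self.E_REF,
                           nu_parenchyma=materials.nu_parenchyma)
        self._shell = assemble(mesh, None, ref).stiffness
        both = assemble(mesh, network, ref) if network is not None and \
            len(network.node_ties) else None
        self._beams = (both.stiffness - self._shell) if both is not None else None
        self.load = distribute_load(mesh, rain)

    def solve_pair(self, E_parenchyma: float):
        mat = MaterialSpec(E_sclereid=self.materials.E_sclereid,
                           nu_sclereid=self.materials.nu_sclereid,
                           E_parenchyma=E_parenchyma,
                           nu_parenchyma=self.materials.nu_parenchyma)
        scale = E_parenchyma / self.E_REF
        Ks = (scale * self._shell).tocsr()
        Ka = (Ks + self._beams).tocsr() if self._beams is not None else Ks
        sols = []
        for K in (Ka, Ks):
            sys_ = GlobalSystem(stiffness=K, load=self.load.copy(),
                                fixed_dofs=np.array([], dtype=np.int64),
                                mesh=self.mesh, materials=mat,
                                n_beams=len(self.network.node_ties)
                                if self.network is not None else 0)
            sys_.fix_nodes(self.mesh.base_nodes)
            if self.margin == "pinned":
                bn = self.mesh.boundary_nodes()
                dofs = (6 * bn[:, None] + np.arange(3)).ravel()
                sys_.fixed_dofs = np.unique(
                    np.concatenate([sys_.fixed_dofs, dofs]))
            sols.append(solve_static(sys_))
        return sols  # [with sclereids (A), without (B)]


def correlate_strain_density(strain_field: np.ndarray,
                             density: np.ndarray) -> float:
    """Spearman rank correlation between per-element strain and sclereid
    density; ties mid-ranked.  Constant input -> NaN with a warning."""
    strain_field = np.asarray(strain_field, dtype=float)
    density = np.asarray(density, dtype=float)
    if strain_field.shape != density.shape:
        raise ValueError("fields must share the element set")
    if np.ptp(strain_field) == 0 or np.ptp(density) == 0:
        warnings.warn("constant field: Spearman correlation undefined",
                      stacklevel=2)
        return float("nan")
    rho, _ = spearmanr(strain_field, density)
    return float(rho)


@dataclass
class CalibrationRecord:
    E_parenchyma: float
    target_ratio: float
    achieved_ratio: float
    seed: int
    trace: list  # (E, ratio) iterates
    bracket: tuple[float, float]


@dataclass
class SeedResult:
    seed: int
    coverage: float
    n_cells: int
    n_beams: int
    max_strain_with: float
    max_strain_without: float
    strain_ratio: float
    density_strain_correlation: float
    summary_with: StrainSummary
    summary_without: StrainSummary


@dataclass
class ComparisonReport:
    config: dict
    config_hash: str
    version: str
    impact_force_N: float
    seeds: list[int]
    results: list[SeedResult]
    ratio_mean: float
    ratio_sd: float
    mesh_quality: dict
    calibration: CalibrationRecord | None = None

    @property
    def strain_ratio(self) -> float:
        return self.ratio_mean

    def to_dict(self) -> dict:
        d = {
            "schema_version": 1,
            "package_version": self.version,
            "config": self.config,
            "config_hash": self.config_hash,
            "impact_force_N": self.impact_force_N,
            "seeds": self.seeds,
            "strain_ratio_mean": self.ratio_mean,
            "strain_ratio_sd": self.ratio_sd,
            "mesh_quality": self.mesh_quality,
            "per_seed": [
                {"seed": r.seed, "coverage": r.coverage, "n_cells": r.n_cells,
                 "n_beams": r.n_beams,
                 "max_strain_with": r.max_strain_with,
                 "max_strain_without": r.max_strain_without,
                 "strain_ratio": r.strain_ratio,
                 "density_strain_correlation": r.density_strain_correlation,
                 "summary_with": r.summary_with.to_dict(),
                 "summary_without": r.summary_without.to_dict()}
                for r in self.results],
        }
        if self.calibration is not None:
            d["calibration"] = asdict(self.calibration)
        return d


def _one_seed(mesh: LaminaMesh, prof: SpeciesProfile, mat: MaterialSpec,
              rain: RaindropSpec, seed: int, margin: str = "pinned"
              ) -> SeedResult:
    from .sclereid_synth import coverage_fraction

    net = sample_network(mesh, prof, seed=seed)
    pair = _PairedModels(mesh, net if net.n_cells else None, mat, rain,
                         margin=margin)
    sol_a, sol_b = pair.solve_pair(mat.E_parenchyma)
    sum_a = summarize(sol_a, mesh)
    sum_b = summarize(sol_b, mesh)
    dens = density_field(net, mesh)
    rho = correlate_strain_density(sum_a.field, dens) if net.n_cells else float("nan")
    cov = coverage_fraction(net, mesh) if net.n_cells else 0.0
    ratio = sum_b.max_equivalent_strain / sum_a.max_equivalent_strain
    return SeedResult(
        seed=seed, coverage=cov, n_cells=net.n_cells,
        n_beams=len(net.node_ties),
        max_strain_with=sum_a.max_equivalent_strain,
        max_strain_without=sum_b.max_equivalent_strain,
        strain_ratio=ratio, density_strain_correlation=rho,
        summary_with=sum_a, summary_without=sum_b)


def run_comparison(config=None, seeds=None, out_dir=None,
                   calibration: CalibrationRecord | None = None) -> ComparisonReport:
    """Run the paired comparison for one or more network seeds.

    Both models share the mesh, raindrop load and parenchyma; only the
    sclereid network differs.  ``seeds`` defaults to 5 consecutive seeds
    starting at the config seed; per-seed ratios plus mean +/- sd are
    reported (the seed spread is this pipeline's own disclosure of network
    stochasticity).
    """
    cfg = load_config(config)
    lam, prof, mat, rain = _objects(cfg)
    if seeds is None:
        seeds = [cfg["seed"] + k for k in range(5)]
    mesh = build_lamina(lam)
    quality = mesh_quality(mesh)
    margin = cfg.get("supports", {}).get("margin", "pinned")

    results = [_one_seed(mesh, prof, mat, rain, s, margin) for s in seeds]
    ratios = np.array([r.strain_ratio for r in results])
    report = ComparisonReport(
        config=cfg, config_hash=_config_hash(cfg), version=__version__,
        impact_force_N=impact_force(rain),
        seeds=list(seeds), results=results,
        ratio_mean=float(ratios.mean()),
        ratio_sd=float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0,
        mesh_quality=quality.to_dict(),
        calibration=calibration)

    if out_dir is not None:
        _export(report, mesh, prof, mat, rain, Path(out_dir))
    return report


def _export(report, mesh, prof, mat, rain, out: Path) -> None:
    from . import io as pio

    out.mkdir(parents=True, exist_ok=True)
    r0 = report.results[0]
    net = sample_network(mesh, prof, seed=r0.seed)
    dens = density_field(net, mesh)
    pio.write_vtu(out / "model_with_sclereids.vtu", mesh,
                  cell_data={"equivalent_elastic_strain": r0.summary_with.field,
                             "sclereid_density": dens})
    pio.write_vtu(out / "model_without_sclereids.vtu", mesh,
                  cell_data={"equivalent_elastic_strain":
                             r0.summary_without.field})
    pio.write_quality_csv(out / "mesh_quality.csv", mesh_quality(mesh))
    pio.write_network_csv(out / "sclereid_network.csv", net)
    (out / "comparison_report.json").write_text(
        json.dumps(report.to_dict(), indent=2, default=float))


def calibrate_parenchyma(config=None, target_ratio: float = 2.3,
                         bracket: tuple[float, float] = (1e6, 100e6),
                         tol: float = 0.05, max_iter: int = 60
                         ) -> CalibrationRecord:
    """Bisection on the parenchyma modulus to hit a target strain ratio.

    The ratio max_B/max_A decreases monotonically in E_parenchyma (stiffer
    parenchyma makes the sclereid contribution relatively weaker), so a
    bracketing bisection at the config's seed converges to
    |ratio - target| < tol.  Raises if the target lies outside the ratios
    achievable inside the bracket.
    """
    if target_ratio <= 1.0:
        raise ValueError("target_ratio must be > 1")
    cfg = load_config(config)
    lam, prof, mat, rain = _objects(cfg)
    mesh = build_lamina(lam)
    net = sample_network(mesh, prof, seed=cfg["seed"])
    if net.n_cells == 0:
        raise ValueError("empty sclereid network: ratio target unreachable "
                         "(achieved ratio 1.0)")
    margin = cfg.get("supports", {}).get("margin", "pinned")
    pair = _PairedModels(mesh, net, mat, rain, margin=margin)

    def ratio(E: float) -> float:
        sol_a, sol_b = pair.solve_pair(E)
        return (summarize(sol_b, mesh).max_equivalent_strain
                / summarize(sol_a, mesh).max_equivalent_strain)

    lo, hi = bracket
    trace = []
    r_lo, r_hi = ratio(lo), ratio(hi)
    trace += [(lo, r_lo), (hi, r_hi)]
    if not (min(r_lo, r_hi) - tol <= target_ratio <= max(r_lo, r_hi) + tol):
        raise ValueError(
            f"target ratio {target_ratio} unreachable in bracket "
            f"{bracket}: achieved range [{min(r_lo, r_hi):.3f}, "
            f"{max(r_lo, r_hi):.3f}]")
    # ratio decreases with E: keep lo (high ratio) / hi (low ratio) bracket
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # bisect in log space (moduli span decades)
        r_mid = ratio(mid)
        trace.append((mid, r_mid))
        if abs(r_mid - target_ratio) < tol:
            return CalibrationRecord(
                E_parenchyma=float(mid), target_ratio=target_ratio,
                achieved_ratio=float(r_mid), seed=cfg["seed"],
                trace=[(float(a), float(b)) for a, b in trace],
                bracket=bracket)
        if r_mid > target_ratio:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"calibration did not converge in {max_iter} "
                       f"iterations; last ratio {trace[-1][1]:.4f}")
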