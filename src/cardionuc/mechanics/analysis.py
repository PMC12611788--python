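"""Post-processing and condition studies for the nuclear pre-stress model."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .materials import (CageParams, ConditionSpec, CytoplasmParams, Geometry,
                        LoadRamp, NucleusParams, CONDITIONS)
from .mesh import CAGE, CYTOPLASM, NE, NUCLEOPLASM
from . import fem
from .fem import FEModel, FESolution, build_model, solve_prestress


def homogeneous_farfield(cyto: CytoplasmParams,
                         rho0_fraction: float = 1.0) -> dict:
    """Closed-form far field of the contractile cytoplasm alone.

    With the cell ends held (eps_zz = 0) and the lateral surface free
    (sigma_rr = sigma_theta = 0), the uniform solution of the myofibril
    law has radial strain eps = -rhobar0 / (2 Kbar + 2 mubar / 3) and the
    axial tension follows by substitution.
    """
    eff = cyto.effective(rho0_fraction)
    eps = -eff.rhobar0 / (2.0 * eff.Kbar + 2.0 * eff.mubar / 3.0)
    sigma_zz = (2.0 * eff.Kbar - 4.0 * eff.mubar / 3.0) * eps + eff.rhobar0
    return {"eps_rr": float(eps), "sigma_zz": float(sigma_zz)}


def nuclear_shape(sol: FESolution) -> dict:
    """Deformed nuclear length, width, aspect ratio and volume.

    Length/width are measured on the outer NE boundary (the quarter model
    gives half-length along z and half-width along r); the volume is the
    revolution integral over the deformed nucleoplasm + NE elements.
    """
    mesh = sol.model.mesh
    ring = mesh.ring_nodes["ne_outer"]
    dp = mesh.corner_points[ring] + sol.u[ring]
    length = 2.0 * float(dp[:, 1].max())
    width = 2.0 * float(dp[:, 0].max())
    if length <= 0 or width <= 0:
        raise ValueError("non-simple deformed nuclear boundary")
    volume = nuclear_volume(sol)
    ar = length / width if length >= width else width / length
    return {"length": length, "width": width,
            "aspect_ratio": ar, "volume": volume,
            "elongated_axially": length >= width}


def nuclear_volume(sol: FESolution) -> float:
    """Nuclear volume (µm^3) by quadrature over the deformed mesh."""
    mesh = sol.model.mesh
    sel = (mesh.subdomain == NUCLEOPLASM) | (mesh.subdomain == NE)
    pts = mesh.corner_points + sol.u[: len(mesh.corner_points)]
    t = mesh.corner_triangles[sel]
    a, b, c = pts[t[:, 0]], pts[t[:, 1]], pts[t[:, 2]]
    ab, ac = b - a, c - a
    area = 0.5 * np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    r_cent = (a[:, 0] + b[:, 0] + c[:, 0]) / 3.0
    # half the solid of revolution (quarter section -> upper half) doubled
    return float(2.0 * 2.0 * np.pi * (area * r_cent).sum())


def nuclear_volume_boundary(sol: FESolution) -> float:
    """Independent volume route: revolution of the deformed NE-outer
    boundary polyline, V = 2 * integral pi r(z)^2 dz over the half."""
    mesh = sol.model.mesh
    ring = mesh.ring_nodes["ne_outer"]
    dp = mesh.corner_points[ring] + sol.u[ring]
    order = np.argsort(dp[:, 1])
    z, r = dp[order, 1], dp[order, 0]
    return float(2.0 * np.pi * np.trapezoid(r ** 2, z))


def principal_stress_location(sol: FESolution,
                              tip_fraction: float = 0.7) -> dict:
    """Locate the maximum principal (most tensile) NE stress.

    The NE arc with deformed |z| beyond ``tip_fraction`` of the deformed
    nuclear half-length counts as the tip region; the rest is the
    mid-section.  An all-zero field is flagged as undefined.
    """
    ne_pts = sol.qp_sub == NE
    if not np.any(ne_pts):
        raise ValueError("solution has no NE quadrature points")
    s = sol.stress[ne_pts]
    if np.allclose(s, 0.0):
        return {"location": "undefined", "max_principal": 0.0,
                "tip_max": 0.0, "mid_max": 0.0}
    # principal stresses of the axisymmetric tensor: eigvals of the (r,z)
    # block plus the hoop component
    srr, szz, sth, srz = s.T
    mean_rz = 0.5 * (srr + szz)
    rad = np.sqrt((0.5 * (srr - szz)) ** 2 + srz ** 2)
    p_max = np.maximum(mean_rz + rad, sth)
    zq = sol.qp[ne_pts, 1] + sol.qp_u[ne_pts, 1]
    shape = nuclear_shape(sol)
    half_len = shape["length"] / 2.0
    tip = zq > tip_fraction * half_len
    tip_max = float(p_max[tip].max()) if np.any(tip) else -np.inf
    mid_max = float(p_max[~tip].max()) if np.any(~tip) else -np.inf
    location = "tip" if tip_max >= mid_max else "mid"
    return {"location": location,
            "max_principal": float(max(tip_max, mid_max)),
            "tip_max": tip_max, "mid_max": mid_max}


def cytoplasm_farfield_stress(sol: FESolution, r: float = 20.0,
                              z: float = 25.0) -> float:
    """Axial cytoplasm stress (kPa) at a probe far from the cage."""
    return float(sol.stress_at(r, z, subdomain=CYTOPLASM)[1])


def cage_axial_compression_range(sol: FESolution) -> tuple[float, float]:
    """(min, max) magnitude of axial compressive stress over the cage.

    Positive numbers are compression; a tensile axial stress anywhere in
    the cage would appear as a negative minimum.
    """
    szz = sol.stress[sol.qp_sub == CAGE, 1]
    comp = -szz
    return float(comp.min()), float(comp.max())


def volume_change(sol_a: FESolution, sol_b: FESolution) -> float:
    """Relative nuclear volume change 100*|V_b - V_a|/V_a (percent)."""
    va = nuclear_volume(sol_a)
    vb = nuclear_volume(sol_b)
    return float(100.0 * abs(vb - va) / va)


def _model_for(cond: ConditionSpec, geometry=None, cyto=None, cage=None,
               nuc=None, mesh=None, mesh_density: int = 0) -> FEModel:
    nuc = replace(nuc or NucleusParams(), E_ne=cond.E_ne)
    return build_model(geometry=geometry, cyto=cyto, nuc=nuc,
                       cage=cage, cage_scale=cond.cage_scale,
                       mesh=mesh, mesh_density=mesh_density)


def solve_condition(cond: ConditionSpec | str, ramp: LoadRamp = None,
                    **model_kw) -> FESolution:
    if isinstance(cond, str):
        cond = CONDITIONS[cond]
    model = _model_for(cond, **model_kw)
    return solve_prestress(model, ramp)


def compare_conditions(conditions=("WT", "LMNA", "LINC", "LMNA_LINC"),
                       ramp: LoadRamp = None, **model_kw) -> pd.DataFrame:
    """Nuclear shape metrics for a list of condition presets."""
    rows = []
    for c in conditions:
        cond = CONDITIONS[c] if isinstance(c, str) else c
        sol = solve_condition(cond, ramp, **model_kw)
        shape = nuclear_shape(sol)
        loc = principal_stress_location(sol)
        rows.append({"condition": cond.name, "E_ne": cond.E_ne,
                     "cage_scale": cond.cage_scale, **shape,
                     "stress_location": loc["location"],
                     "max_principal_ne_stress": loc["max_principal"]})
    return pd.DataFrame(rows)


def detect_instability(model: FEModel, cage_stress_grid,
                       tol: float = 0.02, ramp: LoadRamp = None) -> dict:
    """Smallest cage stress whose solution shows tip-dominant NE stress.

    Scans a monotone grid of sigma_MT values (kPa); classifies each
    converged solution with :func:`principal_stress_location`; a
    continuation failure is itself recorded as instability.  The bracket
    between the last 'mid' and first 'tip' grid point is refined by
    bisection to ``tol`` (kPa).
    """
    grid = np.asarray(cage_stress_grid, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("cage_stress_grid must be strictly increasing")

    def classify(sig: float) -> str:
        m = replace_cage_stress(model, sig)
        try:
            sol = solve_prestress(m, ramp)
        except fem.ConvergenceError:
            return "tip"         # loss of continuation counts as unstable
        return principal_stress_location(sol)["location"]

    labels = [classify(s) for s in grid]
    if "tip" not in labels:
        return {"critical_sigma_MT": None, "status": "none in range",
                "grid": grid, "labels": labels}
    first_tip = labels.index("tip")
    if first_tip == 0:
        return {"critical_sigma_MT": float(grid[0]),
                "status": "tip at grid start", "grid": grid, "labels": labels}
    lo, hi = grid[first_tip - 1], grid[first_tip]
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if classify(mid) == "tip":
            hi = mid
        else:
            lo = mid
    return {"critical_sigma_MT": float(0.5 * (lo + hi)), "status": "found",
            "grid": grid, "labels": labels}


def replace_cage_stress(model: FEModel, sigma_MT: float) -> FEModel:
    """Model with the same mesh/stiffness but a different cage stress."""
    cage = replace(model.cage, sigma_MT=sigma_MT)
    m = build_model(geometry=model.geometry, cyto=model.cyto, nuc=model.nuc,
                    cage=cage, cage_scale=model.cage_scale, mesh=model.mesh)
    return m


def enrichment_to_cage_scale(enrichment: float,
                             e_phys: float = 2.0) -> float:
    """Map an imaging perinuclear enrichment ratio onto the cage scale.

    The physiological enrichment ``e_phys`` corresponds to the full cage
    (scale 1); the mapping is linear in both the active stress and the
    cage stiffness.  This is a modelling convention, exposed for
    configuration.
    """
    if enrichment < 0:
        raise ValueError("enrichment must be non-negative")
    return enrichment / e_phys


def sweep_enrichment(enrichment_grid, condition: str = "WT",
                     mapping=enrichment_to_cage_scale,
                     ramp: LoadRamp = None, **model_kw) -> pd.DataFrame:
    """Aspect ratio and stress location as a function of MT enrichment."""
    base = CONDITIONS[condition]
    rows = []
    for e in np.asarray(enrichment_grid, dtype=float):
        cond = ConditionSpec(f"{condition}@e={e:g}", E_ne=base.E_ne,
                             cage_scale=mapping(e))
        try:
            sol = solve_condition(cond, ramp, **model_kw)
        except fem.ConvergenceError:
            rows.append({"enrichment": e, "cage_scale": cond.cage_scale,
                         "aspect_ratio": np.nan, "location": "non-converged",
                         "converged": False})
            continue
        shape = nuclear_shape(sol)
        loc = principal_stress_location(sol)
        rows.append({"enrichment": e, "cage_scale": cond.cage_scale,
                     "aspect_ratio": shape["aspect_ratio"],
                     "location": loc["location"], "converged": True})
    return pd.DataFrame(rows)


def mt_buckling_force(flexural_rigidity: float = 2.2e-23,
                      wavelength_um: float = 2.5) -> float:
    """Euler critical force (N) for a microtubule buckling at the
    observed wavelength.

    A buckle of wavelength lambda corresponds to an effective column
    length of lambda/2 (one half-wave), so F = pi^2 EI / (lambda/2)^2.
    Default flexural rigidity 2.2e-23 N m^2 is the standard microtubule
    value; 2.5 µm is the middle of the observed 2-3 µm wavelength band.
    """
    if flexural_rigidity <= 0 or wavelength_um <= 0:
        raise ValueError("rigidity and wavelength must be positive")
    L = wavelength_um * 1e-6 / 2.0
    return float(np.pi ** 2 * flexural_rigidity / L ** 2)
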