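"""Configuration loading and field export for the FE model."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .materials import (CageParams, ConditionSpec, CytoplasmParams, Geometry,
                        LoadRamp, NucleusParams)
from .fem import FESolution
from .mesh import SUBDOMAIN_NAMES


def load_config(path) -> dict:
    """Read a JSON or YAML model configuration.

    Recognised blocks: ``geometry``, ``cytoplasm``, ``nucleus``, ``cage``,
    ``ramp`` (list of [rho_fraction, mt_fraction] pairs) and
    ``conditions`` (name -> {E_ne, cage_scale}).  Missing blocks fall back
    to the physiological defaults.
    """
    path = Path(path)
    text = path.read_text()
    raw = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    out = {
        "geometry": Geometry(**raw.get("geometry", {})),
        "cytoplasm": CytoplasmParams(**raw.get("cytoplasm", {})),
        "nucleus": NucleusParams(**raw.get("nucleus", {})),
        "cage": CageParams(**raw.get("cage", {})),
    }
    if "ramp" in raw:
        out["ramp"] = LoadRamp(steps=[tuple(s) for s in raw["ramp"]])
    if "conditions" in raw:
        out["conditions"] = {
            name: ConditionSpec(name=name, **block)
            for name, block in raw["conditions"].items()}
    return out


def solution_summary(sol: FESolution) -> pd.DataFrame:
    """One-row scalar summary of a converged solution."""
    from .analysis import (cage_axial_compression_range,
                           cytoplasm_farfield_stress, nuclear_shape,
                           principal_stress_location)
    shape = nuclear_shape(sol)
    loc = principal_stress_location(sol)
    cmin, cmax = cage_axial_compression_range(sol)
    return pd.DataFrame([{
        **shape,
        "stress_location": loc["location"],
        "max_principal_ne_stress": loc["max_principal"],
        "cytoplasm_farfield_szz": cytoplasm_farfield_stress(sol),
        "cage_compression_min": cmin,
        "cage_compression_max": cmax,
    }])


def export_vtk(sol: FESolution, path) -> None:
    """Write the solution as a legacy-ASCII VTK unstructured grid.

    Corner (P1) triangulation with nodal displacements and element
    subdomain ids plus element-mean stress components, viewable in
    ParaView.  The axisymmetric section is written in the (r, z) plane.
    """
    mesh = sol.model.mesh
    pts = mesh.corner_points
    tris = mesh.corner_triangles
    n_pt, n_el = len(pts), len(tris)
    nq = len(sol.qp_weight) // n_el
    s_el = sol.stress.reshape(n_el, nq, 4).mean(axis=1)
    u = sol.u[:n_pt]
    lines = ["# vtk DataFile Version 3.0", "axisymmetric pre-stress solution",
             "ASCII", "DATASET UNSTRUCTURED_GRID", f"POINTS {n_pt} double"]
    lines += [f"{r:.8g} {z:.8g} 0" for r, z in pts]
    lines.append(f"CELLS {n_el} {4 * n_el}")
    lines += [f"3 {a} {b} {c}" for a, b, c in tris]
    lines.append(f"CELL_TYPES {n_el}")
    lines += ["5"] * n_el
    lines.append(f"POINT_DATA {n_pt}")
    lines.append("VECTORS displacement double")
    lines += [f"{ur:.8g} {uz:.8g} 0" for ur, uz in u]
    lines.append(f"CELL_DATA {n_el}")
    lines.append("SCALARS subdomain int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(s)) for s in mesh.subdomain]
    for j, comp in enumerate(("sigma_rr", "sigma_zz", "sigma_theta",
                              "sigma_rz")):
        lines.append(f"SCALARS {comp} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{v:.8g}" for v in s_el[:, j]]
    Path(path).write_text("\n".join(lines) + "\n")


def subdomain_name(sid: int) -> str:
    return SUBDOMAIN_NAMES[sid]
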