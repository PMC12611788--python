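"""Axisymmetric P2 finite-element kernel for the pre-stress model.

Small-strain axisymmetric elasticity in (r, z) with per-subdomain isotropic
moduli and isotropic eigenstress (active) contributions:

  cytoplasm:   sigma = C(Kbar, mubar) : eps + rhobar0 * I
  MT cage:     sigma = C(K_MT, mu_MT) : eps - sigma_MT * I
  nucleoplasm: sigma = C(K_ch, mu_ch) : eps
  NE + lamina: sigma = C(K_ne, mu_ne) : eps      (nu -> 0.5, volume-preserving)

Strain ordering: (eps_rr, eps_zz, eps_theta, gamma_rz).  Boundary
conditions: u_r = 0 on the symmetry axis r = 0, u_z = 0 on the cell
midplane z = 0 and on the constrained cell end z = L/2; the lateral
surface r = R is traction free.  The 2*pi revolution factor is dropped
throughout (it cancels in the equilibrium equations) and reinstated only
where physical volumes or forces are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .materials import (CageParams, CytoplasmParams, Geometry, LoadRamp,
                        NucleusParams, bulk_shear)
from .mesh import CAGE, CYTOPLASM, NE, NUCLEOPLASM, QuarterMesh, \
    build_quarter_mesh

# 6-point degree-4 Dunavant rule (barycentric permutations; weights sum to 1)
_A1, _W1 = 0.445948490915965, 0.223381589678011
_A2, _W2 = 0.091576213509771, 0.109951743655322
QUAD_XY = np.array([
    [_A1, _A1], [1 - 2 * _A1, _A1], [_A1, 1 - 2 * _A1],
    [_A2, _A2], [1 - 2 * _A2, _A2], [_A2, 1 - 2 * _A2],
])
QUAD_W = np.array([_W1, _W1, _W1, _W2, _W2, _W2])


def _p2_shape(xi: float, eta: float):
    l0, l1, l2 = 1.0 - xi - eta, xi, eta
    N = np.array([l0 * (2 * l0 - 1), l1 * (2 * l1 - 1), l2 * (2 * l2 - 1),
                  4 * l0 * l1, 4 * l1 * l2, 4 * l2 * l0])
    dN = np.array([
        [1 - 4 * l0, 1 - 4 * l0],
        [4 * l1 - 1, 0.0],
        [0.0, 4 * l2 - 1],
        [4 * (l0 - l1), -4 * l1],
        [4 * l2, 4 * l1],
        [-4 * l2, 4 * (l0 - l2)],
    ])
    return N, dN


def _dmatrix(K: float, mu: float) -> np.ndarray:
    lam2 = K - 2.0 * mu / 3.0
    D = np.full((4, 4), 0.0)
    D[:3, :3] = lam2
    D[0, 0] = D[1, 1] = D[2, 2] = lam2 + 2.0 * mu
    D[3, 3] = mu
    return D


class ConvergenceError(RuntimeError):
    def __init__(self, msg: str, last_fraction: float):
        super().__init__(msg)
        self.last_fraction = last_fraction


@dataclass
class FEModel:
    """Assembled model: mesh, materials, and load operators."""
    geometry: Geometry
    cyto: CytoplasmParams
    nuc: NucleusParams
    cage: CageParams
    mesh: QuarterMesh
    cage_scale: float = 1.0            # scales the cage active stress
    cage_stiffness_scale: float = 1.0  # scales the cage passive moduli
    homogeneous: bool = False  # contractile cytoplasm in all subdomains
    # populated by build_model
    K: sp.csr_matrix = None
    f_rho: np.ndarray = None     # load for unit rho0 fraction
    f_mt: np.ndarray = None      # load for unit sigma_MT fraction
    free: np.ndarray = None      # free dof indices
    fixed_r: np.ndarray = None   # node ids with u_r = 0
    fixed_z: np.ndarray = None   # node ids with u_z = 0
    end_nodes: np.ndarray = None  # node ids on the constrained end z = L/2
    _lu: object = field(default=None, repr=False)

    @property
    def n_dof(self) -> int:
        return 2 * self.mesh.n_nodes


def build_model(geometry: Geometry = None, cyto: CytoplasmParams = None,
                nuc: NucleusParams = None, cage: CageParams = None,
                mesh_density: int = 0, cage_scale: float = 1.0,
                cage_stiffness_scale: float = None, mesh: QuarterMesh = None,
                homogeneous: bool = False) -> FEModel:
    """Mesh the quarter domain and assemble stiffness and load operators.

    ``mesh_density`` is the uniform-refinement level over the default
    resolution.  ``cage_scale`` multiplies the cage's active compressive
    stress (the MT-enrichment / LINC-disruption dial); the cage's passive
    moduli stay at their baseline by default, representing the crowded
    perinuclear material that remains when microtubules are lost --
    driving them to zero would mechanically decouple the nucleus from the
    contracting cytoplasm, which is an artifact of the subdomain topology
    rather than a physical state.  Set ``cage_stiffness_scale`` to scale
    the passive moduli as well.
    """
    geometry = geometry or Geometry()
    cyto = cyto or CytoplasmParams()
    nuc = nuc or NucleusParams()
    cage = cage or CageParams()
    if mesh is None:
        from .mesh import refine
        mesh = refine(geometry, level=mesh_density) if mesh_density else \
            build_quarter_mesh(geometry)
    model = FEModel(geometry=geometry, cyto=cyto, nuc=nuc, cage=cage,
                    mesh=mesh, cage_scale=cage_scale,
                    cage_stiffness_scale=(1.0 if cage_stiffness_scale is None
                                          else cage_stiffness_scale),
                    homogeneous=homogeneous)
    _assemble(model)
    return model


def _material_tables(model: FEModel):
    """Per-subdomain (D matrix, eigenstress coefficients) tables.

    Eigenstress sigma0 = rho_coef * ramp_rho + mt_coef * ramp_mt, isotropic.
    """
    eff = model.cyto.effective()
    K_ch, mu_ch = bulk_shear(model.nuc.E_chromatin, model.nuc.nu_chromatin)
    K_ne, mu_ne = bulk_shear(model.nuc.E_ne, model.nuc.nu_ne)
    cs = model.cage_scale
    css = model.cage_stiffness_scale
    D = {
        NUCLEOPLASM: _dmatrix(K_ch, mu_ch),
        NE: _dmatrix(K_ne, mu_ne),
        CAGE: _dmatrix(css * model.cage.K_MT, css * model.cage.mu_MT),
        CYTOPLASM: _dmatrix(eff.Kbar, eff.mubar),
    }
    rho_coef = {NUCLEOPLASM: 0.0, NE: 0.0, CAGE: 0.0, CYTOPLASM: eff.rhobar0}
    mt_coef = {NUCLEOPLASM: 0.0, NE: 0.0,
               CAGE: -cs * model.cage.sigma_MT, CYTOPLASM: 0.0}
    # the soft nucleoplasm takes the stiffening log-volumetric law
    # sigma_m = K ln(J)/J with J = 1 + eps_kk (consistent with K at J = 1);
    # its tangent at zero strain is the linear bulk modulus
    vol_nl = {NUCLEOPLASM: K_ch}
    if model.homogeneous:
        D = {s: _dmatrix(eff.Kbar, eff.mubar) for s in D}
        rho_coef = {s: eff.rhobar0 for s in rho_coef}
        mt_coef = {s: 0.0 for s in mt_coef}
        vol_nl = {}
    return D, rho_coef, mt_coef, vol_nl


def _bbar_bmatrices(mesh: QuarterMesh, invJ: np.ndarray, detJ: np.ndarray):
    """Mean-dilatation (B-bar) strain-displacement matrices per quad point.

    The volumetric part of B is replaced by its element average, which
    removes volumetric locking and pressure checkerboarding in the nearly
    incompressible NE shell and nucleoplasm (harmless elsewhere).
    Returns (B_all[q], w_all[q]) with w = quad weight * detJ/2 * r.
    """
    pts, tri = mesh.points, mesh.triangles
    n_el = mesh.n_elements
    el_pts = pts[tri]
    nq = len(QUAD_W)
    B_all = np.zeros((nq, n_el, 4, 12))
    w_all = np.zeros((nq, n_el))
    bvol = np.zeros((nq, n_el, 12))
    for q in range(nq):
        xi, eta = QUAD_XY[q]
        N, dN = _p2_shape(xi, eta)
        dNp = np.einsum("aj,eij->eai", dN, invJ)
        r_q = el_pts[:, :, 0] @ N
        B = np.zeros((n_el, 4, 12))
        B[:, 0, 0::2] = dNp[:, :, 0]
        B[:, 1, 1::2] = dNp[:, :, 1]
        B[:, 2, 0::2] = N[None, :] / r_q[:, None]
        B[:, 3, 0::2] = dNp[:, :, 1]
        B[:, 3, 1::2] = dNp[:, :, 0]
        B_all[q] = B
        w_all[q] = QUAD_W[q] * 0.5 * detJ * r_q
        bvol[q] = B[:, 0] + B[:, 1] + B[:, 2]
    wsum = w_all.sum(axis=0)
    bvol_bar = np.einsum("qe,qek->ek", w_all, bvol) / wsum[:, None]
    for q in range(nq):
        corr = (bvol_bar - bvol[q]) / 3.0
        for i in range(3):
            B_all[q][:, i, :] += corr
    return B_all, w_all


def _assemble(model: FEModel) -> None:
    mesh = model.mesh
    pts, tri = mesh.points, mesh.triangles
    n_el = mesh.n_elements
    Dtab, rho_tab, mt_tab, vol_nl = _material_tables(model)
    Dlin = dict(Dtab)
    for sd, Kv in vol_nl.items():
        Dlin[sd] = Dtab[sd] - _dmatrix(Kv, 0.0)   # keep deviatoric part only

    corners = mesh.corner_points[mesh.corner_triangles]   # (n_el, 3, 2)
    J = np.stack([corners[:, 1] - corners[:, 0],
                  corners[:, 2] - corners[:, 0]], axis=1)  # (n_el, 2, 2) rows
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1] / detJ
    invJ[:, 0, 1] = -J[:, 0, 1] / detJ
    invJ[:, 1, 0] = -J[:, 1, 0] / detJ
    invJ[:, 1, 1] = J[:, 0, 0] / detJ

    Ke = np.zeros((n_el, 12, 12))
    fe_rho = np.zeros((n_el, 12))
    fe_mt = np.zeros((n_el, 12))
    Del = np.stack([Dlin[s] for s in model.subdomain_list()])
    rho_el = np.array([rho_tab[s] for s in model.subdomain_list()])
    mt_el = np.array([mt_tab[s] for s in model.subdomain_list()])
    el_pts = pts[tri]                                      # (n_el, 6, 2)

    iso = np.array([1.0, 1.0, 1.0, 0.0])
    B_all, w_all = _bbar_bmatrices(mesh, invJ, detJ)
    for q in range(len(QUAD_W)):
        B = B_all[q]
        wq = w_all[q]
        DB = np.einsum("eij,ejk->eik", Del, B)
        Ke += wq[:, None, None] * np.einsum("eji,ejk->eik", B, DB)
        # separate unit-load vectors for the two active (eigenstress) terms
        fe_rho -= (wq * rho_el)[:, None] * np.einsum("eji,j->ei", B, iso)
        fe_mt -= (wq * mt_el)[:, None] * np.einsum("eji,j->ei", B, iso)

    dof = np.empty((n_el, 12), dtype=int)
    dof[:, 0::2] = 2 * tri
    dof[:, 1::2] = 2 * tri + 1
    rows = np.repeat(dof, 12, axis=1).ravel()
    cols = np.tile(dof, (1, 12)).ravel()
    K = sp.coo_matrix((Ke.ravel(), (rows, cols)),
                      shape=(model.n_dof, model.n_dof)).tocsr()
    f_rho = np.zeros(model.n_dof)
    f_mt = np.zeros(model.n_dof)
    np.add.at(f_rho, dof.ravel(), fe_rho.ravel())
    np.add.at(f_mt, dof.ravel(), fe_mt.ravel())

    zh = model.geometry.cell_length / 2.0
    on_axis = np.isclose(pts[:, 0], 0.0)
    on_mid = np.isclose(pts[:, 1], 0.0)
    on_end = np.isclose(pts[:, 1], zh)
    fixed = np.zeros(model.n_dof, dtype=bool)
    fixed[2 * np.where(on_axis)[0]] = True          # u_r = 0 on axis
    fixed[2 * np.where(on_mid | on_end)[0] + 1] = True  # u_z = 0 mid + end
    model.K = K
    model.f_rho = f_rho
    model.f_mt = f_mt
    wsum = w_all.sum(axis=0)
    bvol_bar = np.zeros((n_el, 12))
    # recompute the element-mean volumetric operator used by B-bar
    bv = np.zeros((len(QUAD_W), n_el, 12))
    for q in range(len(QUAD_W)):
        bv[q] = B_all[q][:, 0] + B_all[q][:, 1] + B_all[q][:, 2]
    bvol_bar = bv[0]            # element-constant by construction of B-bar
    Kvol_el = np.array([vol_nl.get(s, 0.0) for s in model.subdomain_list()])
    model._vol = (np.where(Kvol_el > 0)[0], Kvol_el, bvol_bar, wsum, dof)
    model._ops = (B_all, w_all)
    model.free = np.where(~fixed)[0]
    model.fixed_r = np.where(on_axis)[0]
    model.fixed_z = np.where(on_mid | on_end)[0]
    model.end_nodes = np.where(on_end)[0]
    model._lu = None


def _factorize(model: FEModel):
    if model._lu is None:
        Kff = model.K[model.free][:, model.free].tocsc()
        model._lu = spla.splu(Kff)
    return model._lu


@dataclass
class FESolution:
    """Converged displacement solution with recovered fields.

    Stresses/strains are sampled at element quadrature points; ``qp``
    holds their undeformed (r, z) coordinates, ``qp_sub`` the subdomain id.
    """
    model: FEModel
    u: np.ndarray                # (n_nodes, 2) nodal displacements, µm
    ramp_fractions: tuple        # final (rho0 fraction, sigma_MT fraction)
    qp: np.ndarray               # (n_qp, 2) quad-point coordinates
    qp_sub: np.ndarray           # (n_qp,) subdomain ids
    strain: np.ndarray           # (n_qp, 4) (rr, zz, theta, rz[eng])
    stress: np.ndarray           # (n_qp, 4) kPa
    qp_weight: np.ndarray        # (n_qp,) quadrature weight r*detJ/2 (per rad)
    qp_u: np.ndarray             # (n_qp, 2) displacement at quad points

    @property
    def deformed_points(self) -> np.ndarray:
        return self.model.mesh.points + self.u

    def contractility(self) -> np.ndarray:
        """Rest contractility tensor rho_ij (rr, zz, theta, rz) in the
        cytoplasm, from the strain field and the feedback moduli."""
        eff = self.model.cyto.effective()
        e = self.strain
        ekk = e[:, 0] + e[:, 1] + e[:, 2]
        rho = np.zeros_like(e)
        dev = e.copy()
        for i in range(3):
            dev[:, i] -= ekk / 3.0
        rho[:, :3] = (self.ramp_fractions[0] * eff.rhobar0
                      + eff.Kbar_rho * ekk)[:, None] + 2 * eff.mubar_rho * dev[:, :3]
        rho[:, 3] = eff.mubar_rho * e[:, 3]   # engineering shear -> tensor x2
        mask = self.qp_sub == CYTOPLASM
        rho[~mask] = 0.0
        return rho

    def stress_at(self, r: float, z: float, subdomain: int = None):
        """Stress at the quadrature point nearest to (r, z) (undeformed
        coordinates), optionally restricted to one subdomain."""
        sel = np.arange(len(self.qp)) if subdomain is None else \
            np.where(self.qp_sub == subdomain)[0]
        d = np.hypot(self.qp[sel, 0] - r, self.qp[sel, 1] - z)
        return self.stress[sel[np.argmin(d)]]


def _vol_state(model: FEModel, u: np.ndarray):
    """(J, sigma_m, dsigma_m/deps_kk) per nonlinear-volume element."""
    idx, Kvol, bvol_bar, wsum, dof = model._vol
    if len(idx) == 0:
        return idx, None, None, None
    ue = u[dof[idx]]
    J = 1.0 + np.einsum("ek,ek->e", bvol_bar[idx], ue)
    if np.any(J <= 0.05):
        raise ConvergenceError("volumetric collapse (J <= 0.05)", np.nan)
    K = Kvol[idx]
    sm = K * np.log(J) / J
    dsm = K * (1.0 - np.log(J)) / J ** 2
    return idx, J, sm, dsm


def _vol_residual(model: FEModel, u: np.ndarray) -> np.ndarray:
    idx, J, sm, _ = _vol_state(model, u)
    r = np.zeros(model.n_dof)
    if len(idx) == 0:
        return r
    _, Kvol, bvol_bar, wsum, dof = model._vol
    re = (wsum[idx] * sm)[:, None] * bvol_bar[idx]
    np.add.at(r, dof[idx].ravel(), re.ravel())
    return r


def _vol_tangent(model: FEModel, u: np.ndarray) -> sp.csr_matrix:
    idx, J, _, dsm = _vol_state(model, u)
    if len(idx) == 0:
        return None
    _, Kvol, bvol_bar, wsum, dof = model._vol
    coef = wsum[idx] * dsm
    blocks = coef[:, None, None] * np.einsum(
        "ei,ej->eij", bvol_bar[idx], bvol_bar[idx])
    d = dof[idx]
    rows = np.repeat(d, 12, axis=1).ravel()
    cols = np.tile(d, (1, 12)).ravel()
    return sp.coo_matrix((blocks.ravel(), (rows, cols)),
                         shape=(model.n_dof, model.n_dof)).tocsr()


def _solve_step(model: FEModel, u: np.ndarray, fr: float, fm: float,
                newton_tol: float, max_newton: int) -> bool:
    """Newton iteration to equilibrium at one load level; updates u."""
    free = model.free
    f = fr * model.f_rho + fm * model.f_mt
    scale = max(np.linalg.norm(f[free]), 1e-30)
    linear = len(model._vol[0]) == 0
    for it in range(max_newton):
        res = (model.K @ u + _vol_residual(model, u) - f)[free]
        if np.linalg.norm(res) <= newton_tol * scale:
            return True
        if linear:
            du = _factorize(model).solve(res)
        else:
            Kt = model.K + _vol_tangent(model, u)
            Ktff = Kt[free][:, free].tocsc()
            du = spla.splu(Ktff).solve(res)
        u[free] -= du
    return False


def solve_prestress(model: FEModel, ramp: LoadRamp = None,
                    newton_tol: float = 1e-8,
                    max_newton: int = 12) -> FESolution:
    """Quasi-static continuation to the fully loaded state.

    The active loads (rho0, sigma_MT) are ramped proportionally; each
    step is solved by Newton iteration on the residual (linear elasticity
    plus the nucleoplasm's stiffening volumetric law).  A failed step is
    retried with halved increments; persistent failure raises
    :class:`ConvergenceError` carrying the last converged ramp fraction,
    which callers use for instability bracketing.
    """
    ramp = ramp or LoadRamp()
    ramp.validate()
    u = np.zeros(model.n_dof)
    prev = (0.0, 0.0)
    last_ok = 0.0
    for i, (fr, fm) in enumerate(ramp.steps):
        targets = [(fr, fm)]
        depth = 0
        while targets:
            tr, tm = targets[-1]
            u_try = u.copy()
            try:
                ok = _solve_step(model, u_try, tr, tm, newton_tol, max_newton)
            except ConvergenceError:
                ok = False
            if ok:
                u = u_try
                prev = (tr, tm)
                last_ok = max(tr, tm)
                targets.pop()
            else:
                depth += 1
                if depth > 6:
                    raise ConvergenceError(
                        f"Newton failed at ramp step {i}", last_ok)
                mid = (0.5 * (prev[0] + tr), 0.5 * (prev[1] + tm))
                targets.append(mid)
    return _recover(model, u, ramp.steps[-1] if ramp.steps else (0.0, 0.0))


def _recover(model: FEModel, u_flat: np.ndarray, fractions) -> FESolution:
    mesh = model.mesh
    pts, tri = mesh.points, mesh.triangles
    n_el = mesh.n_elements
    Dtab, rho_tab, mt_tab, vol_nl = _material_tables(model)
    Dlin = dict(Dtab)
    for sd, Kv in vol_nl.items():
        Dlin[sd] = Dtab[sd] - _dmatrix(Kv, 0.0)
    corners = mesh.corner_points[mesh.corner_triangles]
    J = np.stack([corners[:, 1] - corners[:, 0],
                  corners[:, 2] - corners[:, 0]], axis=1)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    invJ = np.empty_like(J)
    invJ[:, 0, 0] = J[:, 1, 1] / detJ
    invJ[:, 0, 1] = -J[:, 0, 1] / detJ
    invJ[:, 1, 0] = -J[:, 1, 0] / detJ
    invJ[:, 1, 1] = J[:, 0, 0] / detJ
    el_pts = pts[tri]
    ue = np.stack([u_flat[0::2][tri], u_flat[1::2][tri]], axis=2)  # (el,6,2)

    nq = len(QUAD_W)
    qp = np.empty((n_el * nq, 2))
    qp_sub = np.repeat(model.subdomain_list(), nq)
    strain = np.empty((n_el * nq, 4))
    stress = np.empty((n_el * nq, 4))
    qweight = np.empty(n_el * nq)
    qp_u = np.empty((n_el * nq, 2))
    Del = np.stack([Dlin[s] for s in model.subdomain_list()])
    sig0 = (fractions[0] * np.array([rho_tab[s] for s in model.subdomain_list()])
            + fractions[1] * np.array([mt_tab[s] for s in model.subdomain_list()]))
    # nonlinear-volume elements contribute their mean stress sigma_m(J)
    sig0 = np.array(sig0, dtype=float)
    idx, Jv, sm, _ = _vol_state(model, u_flat)
    if len(idx):
        sig0[idx] += sm
    B_all, w_all = _bbar_bmatrices(mesh, invJ, detJ)
    u_el = np.empty((n_el, 12))
    u_el[:, 0::2] = ue[:, :, 0]
    u_el[:, 1::2] = ue[:, :, 1]
    for q in range(nq):
        xi, eta = QUAD_XY[q]
        N, _ = _p2_shape(xi, eta)
        x_q = np.einsum("a,eaj->ej", N, el_pts)
        u_q = np.einsum("a,eaj->ej", N, ue)
        eps = np.einsum("eij,ej->ei", B_all[q], u_el)
        sig = np.einsum("eij,ej->ei", Del, eps)
        sig[:, :3] += sig0[:, None]
        sl = slice(q, n_el * nq, nq)
        qp[sl] = x_q
        qp_u[sl] = u_q
        strain[sl] = eps
        stress[sl] = sig
        qweight[sl] = w_all[q]
    return FESolution(model=model, u=np.stack([u_flat[0::2], u_flat[1::2]],
                                              axis=1),
                      ramp_fractions=tuple(fractions),
                      qp=qp, qp_sub=np.repeat(model.subdomain_list(), nq),
                      strain=strain, stress=stress, qp_weight=qweight,
                      qp_u=qp_u)


def free_residual(model: FEModel, sol: FESolution) -> float:
    """Relative equilibrium residual at the free dofs (force balance)."""
    fr, fm = sol.ramp_fractions
    f = fr * model.f_rho + fm * model.f_mt
    u = sol.u.ravel()
    res = (model.K @ u + _vol_residual(model, u) - f)[model.free]
    scale = max(np.linalg.norm(f[model.free]), 1e-30)
    return float(np.linalg.norm(res) / scale)


def end_reaction(model: FEModel, sol: FESolution) -> float:
    """Net axial reaction force (per radian) on the constrained end z=L/2,
    from consistent nodal forces K u - f restricted to the end nodes."""
    fr, fm = sol.ramp_fractions
    f = fr * model.f_rho + fm * model.f_mt
    u = sol.u.ravel()
    g = model.K @ u + _vol_residual(model, u) - f
    return float(g[2 * model.end_nodes + 1].sum())


def end_stress_integral(sol: FESolution) -> float:
    """Axial force (per radian) from integrating the recovered sigma_zz
    field over the constrained end cross-section z = L/2."""
    model = sol.model
    mesh = model.mesh
    zh = model.geometry.cell_length / 2.0
    pts, tri = mesh.points, mesh.triangles
    Dtab, rho_tab, mt_tab, _vnl = _material_tables(model)
    fr, fm = sol.ramp_fractions
    on_end = np.isclose(mesh.corner_points[:, 1], zh)
    u_flat = sol.u.ravel()
    # 3-point Gauss on [0, 1]
    g = np.array([0.5 - np.sqrt(15) / 10, 0.5, 0.5 + np.sqrt(15) / 10])
    gw = np.array([5 / 18, 4 / 9, 5 / 18])
    # reference-edge parametrisations: edge m joins corners m and (m+1)%3
    ref = {0: lambda t: (t, 0 * t), 1: lambda t: (1 - t, t),
           2: lambda t: (0 * t, 1 - t)}
    total = 0.0
    for e, corners in enumerate(mesh.corner_triangles):
        for m in range(3):
            a, b = corners[m], corners[(m + 1) % 3]
            if not (on_end[a] and on_end[b]):
                continue
            pa, pb = mesh.corner_points[a], mesh.corner_points[b]
            length = abs(pb[0] - pa[0])
            c3 = mesh.corner_points[mesh.corner_triangles[e]]
            J = np.stack([c3[1] - c3[0], c3[2] - c3[0]])
            invJ = np.linalg.inv(J)
            sig0 = fr * rho_tab[mesh.subdomain[e]] + fm * mt_tab[mesh.subdomain[e]]
            D = Dtab[mesh.subdomain[e]]
            ue = np.stack([u_flat[0::2][tri[e]], u_flat[1::2][tri[e]]], axis=1)
            for t, w in zip(g, gw):
                xi, eta = ref[m](t)
                N, dN = _p2_shape(float(xi), float(eta))
                dNp = dN @ invJ.T
                r = float(N @ pts[tri[e], 0])
                ur = float(N @ ue[:, 0])
                eps = np.array([float(dNp[:, 0] @ ue[:, 0]),
                                float(dNp[:, 1] @ ue[:, 1]),
                                ur / r,
                                float(dNp[:, 1] @ ue[:, 0]
                                      + dNp[:, 0] @ ue[:, 1])])
                szz = float(D[1] @ eps) + sig0
                total += w * szz * r * length
    return float(total)


# convenience: subdomain id per element, used by assembly/recovery
def _subdomain_list(self: FEModel) -> np.ndarray:
    return self.mesh.subdomain


FEModel.subdomain_list = _subdomain_list
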