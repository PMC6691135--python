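"""Numerical solution of the reaction-diffusion equation in spine geometries.

The governing equation is

    dC/dt + f(C) = D * laplacian(C)

with f(C) = C/tau (linear buffering/degradation) or Michaelis-Menten
f(C) = V_max*C/(K_M + C), time-dependent Neumann influx on the tagged
membrane regions, and a Robin outlet J_N = K_N*C on the neck cap.

Two schemes are provided:

``solve_radial_shell``
    spherically symmetric 1D scheme (P1 elements on a radial grid with the
    r^2 volume weight) for the spherical shell with uniform fluxes.
``solve_axisymmetric``
    P1 finite elements on the triangulated meridian half-plane with the
    2*pi*r revolution weight, for every geometry family and flux layout.

Both use first-order implicit (backward Euler) time stepping with a lumped
mass matrix; the Michaelis-Menten nonlinearity is evaluated lagged (on the
previous step), which keeps the system matrix constant so it is factorized
once per run.  A discrete mass-balance residual is recorded at every step;
with the matched quadrature used here it is zero to solver roundoff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .fluxes import FluxModel, j_er, j_pm
from .geometry import (
    BoundaryLayout,
    MeshedDomain,
    SpineGeometry,
    TAG_ER,
    TAG_PM_EFFLUX,
    TAG_PM_INFLUX,
    TAG_PM_NECK,
    tri_areas,
)

__all__ = [
    "KineticsSpec",
    "SolverConfig",
    "Solution",
    "solve_radial_shell",
    "solve_axisymmetric",
    "apply_kinetics",
]


@dataclass(frozen=True)
class KineticsSpec:
    """Cytosolic decay kinetics.

    ``linear``: rate C/tau.  ``michaelis_menten``: rate V_max*C/(K_M+C)
    with the convention V_max = C_max_ref/tau, so both kinds share the
    time constant ``tau`` at the reference concentration scale.
    """

    kind: str = "linear"
    tau: float = 50.0  # ms
    V_max: float = 0.0  # uM/ms
    K_M: float = 1.0  # uM

    def __post_init__(self):
        if self.kind not in ("linear", "michaelis_menten"):
            raise ValueError(f"unknown kinetics kind {self.kind!r}")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.kind == "michaelis_menten" and (self.K_M <= 0 or self.V_max < 0):
            raise ValueError("Michaelis-Menten needs K_M > 0 and V_max >= 0")

    @classmethod
    def michaelis_menten(cls, C_max_ref: float, tau: float, K_M: float) -> "KineticsSpec":
        """Build MM kinetics from a reference peak concentration: V_max = C_max_ref/tau."""
        return cls("michaelis_menten", tau=tau, V_max=C_max_ref / tau, K_M=K_M)


def apply_kinetics(C_value, kinetics: KineticsSpec):
    """Pointwise decay rate (uM/ms) for a concentration value or array."""
    C = np.asarray(C_value, dtype=float)
    if kinetics.kind == "linear":
        out = C / kinetics.tau
    else:
        out = kinetics.V_max * C / (kinetics.K_M + C)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class SolverConfig:
    """Discretization settings: D in um^2/ms, dt and horizon in ms."""

    D: float = 0.01  # um^2/ms (= 10 um^2/s)
    dt: float = 0.05  # ms
    T: float = 100.0  # ms
    n_r: int = 200  # radial nodes (1D scheme)
    n_s: int = 16  # across-gap intervals (2D scheme)
    n_phi: int = 96  # polar intervals (2D scheme)
    output_stride: int = 1
    scheme: str = "implicit_euler"
    # negativity gates, relative to the running / final maximum |C|.
    # Sharply localized influx on strongly anisotropic mapped cells
    # produces benign P1 undershoots up to ~1e-4 of the eventual peak in
    # the earliest frames (larger relative to the tiny running maximum
    # there); a flux-sign error drives C negative at order one.  The
    # per-step gate only catches catastrophes, the final gate is the real
    # assertion.
    neg_tol_rel: float = 5e-2
    neg_tol_final: float = 5e-4

    def __post_init__(self):
        if self.D <= 0:
            raise ValueError("D must be positive")
        if self.dt <= 0 or self.T < self.dt:
            raise ValueError("need dt > 0 and T >= dt")
        if self.scheme != "implicit_euler":
            raise ValueError(f"unknown time-integration scheme {self.scheme!r}")


@dataclass
class Solution:
    """Concentration frames on a discretization plus quadrature metadata.

    ``C`` has shape (n_frames, n_dofs).  ``node_weights`` are the lumped
    volume weights (um^3, revolution factor included) so that
    ``node_weights @ C[k]`` is the total amount at frame k.  ``grad_op``
    maps nodal values to per-cell gradient components and ``cell_volumes``
    are the matching quadrature weights for volume averages of cell fields.
    """

    kind: str  # "radial" | "axisym"
    times: np.ndarray
    C: np.ndarray
    node_weights: np.ndarray
    grad_op: tuple  # sparse operators mapping nodes -> cell gradient comps
    cell_volumes: np.ndarray
    geom: SpineGeometry
    flux: FluxModel
    kinetics: KineticsSpec
    config: SolverConfig
    layout: Optional[BoundaryLayout] = None
    mesh: Optional[MeshedDomain] = None
    r_nodes: Optional[np.ndarray] = None
    mass_residual: np.ndarray = field(default_factory=lambda: np.zeros(0))

    @property
    def volume(self) -> float:
        return float(self.node_weights.sum())

    def total_amount(self) -> np.ndarray:
        return self.C @ self.node_weights

    def mean_series(self) -> np.ndarray:
        return self.total_amount() / self.volume

    def grad_magnitude_cells(self) -> np.ndarray:
        """Per-frame, per-cell gradient magnitude, shape (n_frames, n_cells)."""
        comps = [self.C @ G.T for G in self.grad_op]
        return np.sqrt(sum(c * c for c in comps))

    def max_location(self, frame: int) -> np.ndarray:
        """Coordinates (r, z) — or radius for the 1D scheme — of the nodal max."""
        i = int(np.argmax(self.C[frame]))
        if self.kind == "axisym":
            return self.mesh.nodes[i]
        return np.array([self.r_nodes[i]])

    def min_location(self, frame: int) -> np.ndarray:
        i = int(np.argmin(self.C[frame]))
        if self.kind == "axisym":
            return self.mesh.nodes[i]
        return np.array([self.r_nodes[i]])


# ---------------------------------------------------------------------------
# shared implicit-Euler driver
# ---------------------------------------------------------------------------

def _march(
    M_lump: np.ndarray,
    K: sp.spmatrix,
    R_robin: Optional[sp.spmatrix],
    load_of_t,
    kinetics: KineticsSpec,
    config: SolverConfig,
    allow_negative: bool,
):
    """Backward-Euler loop; returns (times, frames, residuals)."""
    n = M_lump.size
    dt = config.dt
    n_steps = int(round(config.T / dt))
    A = sp.diags(M_lump / dt) + config.D * K
    if R_robin is not None:
        A = A + R_robin
    linear = kinetics.kind == "linear"
    if linear:
        A = A + sp.diags(M_lump / kinetics.tau)
    lu = spla.splu(A.tocsc())

    C = np.zeros(n)
    frames = [C.copy()]
    times = [0.0]
    residuals = np.empty(n_steps)
    c_absmax = 0.0
    for k in range(n_steps):
        t1 = (k + 1) * dt
        F = load_of_t(t1)
        rhs = M_lump * C / dt + F
        if not linear:
            decay_prev = apply_kinetics(C, kinetics)
            rhs = rhs - M_lump * decay_prev
        C_new = lu.solve(rhs)

        # mass balance: (M(C1-C0))/dt = 1'F - 1'R C1 - decay_total
        dmass = float(M_lump @ (C_new - C)) / dt
        influx = float(F.sum())
        robin = float((R_robin @ C_new).sum()) if R_robin is not None else 0.0
        if linear:
            decay = float(M_lump @ C_new) / kinetics.tau
        else:
            decay = float(M_lump @ decay_prev)
        scale = max(abs(dmass), abs(influx), abs(robin), abs(decay), 1e-300)
        residuals[k] = abs(dmass - influx + robin + decay) / scale

        c_absmax = max(c_absmax, float(np.max(np.abs(C_new))) if n else 0.0)
        if not allow_negative:
            floor = -config.neg_tol_rel * max(c_absmax, 1e-300)
            cmin = float(C_new.min())
            if cmin < floor:
                raise RuntimeError(
                    f"negative concentration {cmin:.3e} uM at t={t1:.3f} ms "
                    "(beyond the roundoff floor); check boundary-flux signs"
                )
        C = C_new
        if (k + 1) % config.output_stride == 0 or k == n_steps - 1:
            frames.append(C.copy())
            times.append(t1)
    frames = np.asarray(frames)
    if not allow_negative and frames.size:
        gmin, gmax = float(frames.min()), float(frames.max())
        if gmin < -config.neg_tol_final * max(gmax, 1e-300):
            raise RuntimeError(
                f"negative concentration {gmin:.3e} uM (|min|/max = "
                f"{abs(gmin) / max(gmax, 1e-300):.2e}); check boundary-flux signs"
            )
    return np.asarray(times), frames, residuals


# ---------------------------------------------------------------------------
# 1D spherically symmetric scheme
# ---------------------------------------------------------------------------

def solve_radial_shell(
    geom: SpineGeometry,
    flux: FluxModel,
    kinetics: KineticsSpec,
    config: SolverConfig,
    with_neck_robin: bool = False,
) -> Solution:
    """Radial scheme for the spherical shell with uniform membrane fluxes.

    The neck outlet breaks spherical symmetry; by default it is off
    (``J_N = 0``, the configuration of the uniformly driven sphere).  With
    ``with_neck_robin=True`` the Robin sink is smeared uniformly over the
    outer surface — only used for coarse invariance checks.
    """
    if geom.family != "sphere_shell":
        raise ValueError("radial scheme requires the sphere_shell family")
    R_i, R_o = geom.R_i, geom.R_o
    r = np.linspace(R_i, R_o, config.n_r)
    h = np.diff(r)

    # P1 stiffness and lumped mass with the 4*pi*r^2 weight
    w = 4.0 * math.pi
    k_elem = w * (r[1:] ** 3 - r[:-1] ** 3) / 3.0 / h**2  # int r^2 dr * (1/h)^2
    K = sp.diags(
        [
            np.concatenate([k_elem, [0.0]]) + np.concatenate([[0.0], k_elem]),
            -k_elem,
            -k_elem,
        ],
        [0, -1, 1],
        format="csr",
    )
    # consistent mass row sums: int L_i r^2 dr via 3-pt Gauss per element
    gx = np.array([-math.sqrt(3.0 / 5.0), 0.0, math.sqrt(3.0 / 5.0)])
    gw = np.array([5.0, 8.0, 5.0]) / 9.0
    M_lump = np.zeros_like(r)
    for e in range(r.size - 1):
        xm, hw = 0.5 * (r[e] + r[e + 1]), 0.5 * h[e]
        xg = xm + hw * gx
        wg = hw * gw * w * xg**2
        L1 = (r[e + 1] - xg) / h[e]
        M_lump[e] += float((wg * L1).sum())
        M_lump[e + 1] += float((wg * (1 - L1)).sum())

    A_pm = w * R_o**2
    A_er = w * R_i**2
    robin = None
    if with_neck_robin:
        robin = sp.csr_matrix(
            ([flux.K_N * A_pm], ([r.size - 1], [r.size - 1])), shape=(r.size, r.size)
        )

    def load(t):
        F = np.zeros(r.size)
        F[-1] = j_pm(t, flux) * A_pm
        F[0] = j_er(t, flux) * A_er
        return F

    times, frames, resid = _march(M_lump, K, robin, load, kinetics, config, False)

    # gradient operator: per-cell dC/dr with exact shell volumes
    n_cells = r.size - 1
    rows = np.repeat(np.arange(n_cells), 2)
    cols = np.stack([np.arange(n_cells), np.arange(1, r.size)], axis=1).ravel()
    vals = np.stack([-1.0 / h, 1.0 / h], axis=1).ravel()
    G = sp.csr_matrix((vals, (rows, cols)), shape=(n_cells, r.size))
    cell_vol = w * (r[1:] ** 3 - r[:-1] ** 3) / 3.0

    return Solution(
        kind="radial",
        times=times,
        C=frames,
        node_weights=M_lump,
        grad_op=(G,),
        cell_volumes=cell_vol,
        geom=geom,
        flux=flux,
        kinetics=kinetics,
        config=config,
        r_nodes=r,
        mass_residual=resid,
    )


# ---------------------------------------------------------------------------
# 2D axisymmetric P1 finite elements
# ---------------------------------------------------------------------------

def _assemble_axisym(mesh: MeshedDomain):
    """Vectorized P1 assembly of the r-weighted mass and stiffness matrices.

    Exact integration of the linear-in-r weight: on a triangle with vertex
    radii (r1, r2, r3), int L_a L_b L_c dA = 2A a!b!c!/(a+b+c+2)!.
    The 2*pi revolution factor is included.
    """
    nodes, tris = mesh.nodes, mesh.tris
    p = nodes[tris]  # (nt, 3, 2)
    A = tri_areas(nodes, tris)
    r = p[:, :, 0]
    twopi = 2.0 * math.pi

    # gradients of barycentric coords
    x, y = p[:, :, 0], p[:, :, 1]
    bmat = np.stack(
        [y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1
    ) / (2 * A)[:, None]
    cmat = np.stack(
        [x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1
    ) / (2 * A)[:, None]

    r_bar = r.mean(axis=1)
    nt = len(tris)
    Ke = np.empty((nt, 3, 3))
    Me = np.empty((nt, 3, 3))
    for i in range(3):
        for j in range(3):
            Ke[:, i, j] = twopi * (bmat[:, i] * bmat[:, j] + cmat[:, i] * cmat[:, j]) * A * r_bar
            if i == j:
                others = [k for k in range(3) if k != i]
                Me[:, i, j] = twopi * A * (
                    r[:, i] / 10.0 + (r[:, others[0]] + r[:, others[1]]) / 30.0
                )
            else:
                k = 3 - i - j
                Me[:, i, j] = twopi * A * (
                    (r[:, i] + r[:, j]) / 30.0 + r[:, k] / 60.0
                )

    n = len(nodes)
    rows = np.repeat(tris, 3, axis=1).ravel()
    cols = np.tile(tris, (1, 3)).ravel()
    K = sp.csr_matrix((Ke.ravel(), (rows, cols)), shape=(n, n))
    M = sp.csr_matrix((Me.ravel(), (rows, cols)), shape=(n, n))
    M_lump = np.asarray(M.sum(axis=1)).ravel()

    # per-cell gradient operators and cell volumes
    nt_idx = np.repeat(np.arange(nt), 3)
    Gx = sp.csr_matrix((bmat.ravel(), (nt_idx, tris.ravel())), shape=(nt, n))
    Gz = sp.csr_matrix((cmat.ravel(), (nt_idx, tris.ravel())), shape=(nt, n))
    cell_vol = twopi * r_bar * A
    return K, M_lump, Gx, Gz, cell_vol


def _facet_load_vectors(mesh: MeshedDomain):
    """Nodal load vectors (int 2*pi*r*L_i ds) per boundary tag, and the
    Robin boundary matrix for the neck."""
    nodes = mesh.nodes
    n = len(nodes)
    twopi = 2.0 * math.pi
    loads = {}
    robin_rows, robin_cols, robin_vals = [], [], []
    for (a, b), tag in zip(mesh.facets, mesh.facet_tags):
        pa, pb = nodes[a], nodes[b]
        ln = float(np.hypot(*(pb - pa)))
        ra, rb = pa[0], pb[0]
        if tag in (TAG_PM_INFLUX, TAG_ER, TAG_PM_EFFLUX):
            v = loads.setdefault(tag, np.zeros(n))
            v[a] += twopi * ln * (ra / 3.0 + rb / 6.0)
            v[b] += twopi * ln * (rb / 3.0 + ra / 6.0)
        elif tag == TAG_PM_NECK:
            # boundary mass: int 2*pi*r L_i L_j ds with linear r
            robin_rows += [a, b, a, b]
            robin_cols += [a, b, b, a]
            robin_vals += [
                twopi * ln * (ra / 4.0 + rb / 12.0),
                twopi * ln * (rb / 4.0 + ra / 12.0),
                twopi * ln * (ra + rb) / 12.0,
                twopi * ln * (ra + rb) / 12.0,
            ]
    robin = None
    if robin_vals:
        robin = sp.csr_matrix((robin_vals, (robin_rows, robin_cols)), shape=(n, n))
    return loads, robin


def solve_axisymmetric(
    mesh: MeshedDomain,
    flux: FluxModel,
    kinetics: KineticsSpec,
    config: SolverConfig,
) -> Solution:
    """Backward-Euler P1 solution on a tagged meridian mesh.

    Neumann data (J_PM on the influx region, J_ER on the ER membrane,
    -J_PM on the anti-periodic efflux cap) enter as boundary load vectors;
    the neck Robin sink contributes a boundary mass matrix scaled by K_N;
    the symmetry axis carries the natural zero-flux condition.
    """
    K, M_lump, Gx, Gz, cell_vol = _assemble_axisym(mesh)
    loads, robin_mass = _facet_load_vectors(mesh)
    robin = None
    if robin_mass is not None:
        robin = flux.K_N * robin_mass

    F_pm = loads.get(TAG_PM_INFLUX)
    F_er = loads.get(TAG_ER)
    F_out = loads.get(TAG_PM_EFFLUX)

    def load(t):
        F = np.zeros(M_lump.size)
        jp = j_pm(t, flux)
        if F_pm is not None:
            F += jp * F_pm
        if F_er is not None:
            F += j_er(t, flux) * F_er
        if F_out is not None:
            F -= jp * F_out
        return F

    allow_negative = mesh.layout.influx == "antiperiodic"
    times, frames, resid = _march(
        M_lump, K, robin, load, kinetics, config, allow_negative
    )
    return Solution(
        kind="axisym",
        times=times,
        C=frames,
        node_weights=M_lump,
        grad_op=(Gx, Gz),
        cell_volumes=cell_vol,
        geom=mesh.geom,
        flux=flux,
        kinetics=kinetics,
        config=config,
        layout=mesh.layout,
        mesh=mesh,
        mass_residual=resid,
    )
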