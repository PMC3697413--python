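"""Hyperelastic warping: image energy, image forces, and the driver.

Registration deforms the FE model built on the template (end-diastolic)
volume toward the target (end-systolic) volume.  Two couplings act:

* local image forces, the negative gradient of the image energy
  U = psi/2 (T(X) - S(phi(X)))^2 integrated over the mesh, sampled at the
  Gauss points (template at reference positions, target at deformed ones);
* a subject-specific active contraction whose activation is the active
  penalty psi_a times Ct, the signed template-target intensity mismatch
  averaged per element and then over all elements.  Contraction is thereby
  driven by residual misregistration and shuts off as alignment improves.

Both penalties follow the pseudo-time schedule of the analysis, run from
t = 0 to t = 1: psi ramps linearly over the whole course, psi_a ramps
linearly until the knot (default 2/3) and is then held constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .imaging import Image3D, sample_gradient, sample_intensity
from .lvmesh import FiberField, HexMesh, gauss_points, shape_functions
from .mechanics import (
    ActiveParams,
    FEAssembly,
    InvertedElementError,
    PassiveParams,
    SolverError,
)

__all__ = [
    "PenaltySchedule",
    "RegistrationResult",
    "RegistrationError",
    "image_energy",
    "image_forces",
    "average_intensity_mismatch",
    "penalty_schedule",
    "base_constraints",
    "register",
]


class RegistrationError(RuntimeError):
    """A pseudo-time step failed to converge."""

    def __init__(self, step: int, t: float, residual: float | None):
        super().__init__(
            f"registration failed at step {step} (t = {t:.3f}); "
            f"last residual {residual}"
        )
        self.step = step
        self.residual = residual


@dataclass(frozen=True)
class PenaltySchedule:
    """Penalty magnitudes and their pseudo-time ramps.

    psi_max : image penalty scale reached at t = 1; psi_a_max : active
    penalty scale reached at the knot; knot : pseudo-time at which psi_a
    plateaus (default 2/3 of the analysis).
    """

    psi_max: float = 1e-3
    psi_a_max: float = 3e-3
    knot: float = 2.0 / 3.0

    def __post_init__(self):
        if self.psi_max < 0 or self.psi_a_max < 0:
            raise ValueError("penalty scales must be >= 0")
        if not 0.0 < self.knot <= 1.0:
            raise ValueError(f"knot must be in (0, 1], got {self.knot}")


@dataclass
class RegistrationResult:
    """Pseudo-time history of a warping run.

    displacements : (n_steps + 1, n_nodes, 3) nodal u(X), mm, including the
    t = 0 state; times, psi, psi_a, ct, activation : per-step traces;
    energy : image energy at the step's psi; mismatch : psi-independent
    image energy (psi = 1), comparable across steps; converged : per step.
    """

    times: np.ndarray
    displacements: np.ndarray
    ct: np.ndarray
    activation: np.ndarray
    psi: np.ndarray
    psi_a: np.ndarray
    energy: np.ndarray
    mismatch: np.ndarray
    converged: np.ndarray

    @property
    def final_displacement(self) -> np.ndarray:
        return self.displacements[-1]


def penalty_schedule(t: float, schedule: PenaltySchedule) -> tuple[float, float]:
    """(psi, psi_a) at pseudo-time t in [0, 1].

    psi = t * psi_max; psi_a ramps linearly to psi_a_max at the knot and is
    held constant afterwards.
    """
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"pseudo-time must be in [0, 1], got {t}")
    psi = t * schedule.psi_max
    psi_a = min(t / schedule.knot, 1.0) * schedule.psi_a_max
    return psi, psi_a


class _ImageSampler:
    """Template/target sampling at the mesh Gauss points for a given u."""

    def __init__(self, template: Image3D, target: Image3D, mesh: HexMesh,
                 assembly: FEAssembly | None = None):
        self.template = template
        self.target = target
        self.mesh = mesh
        self.asm = assembly if assembly is not None else FEAssembly(mesh)
        self.N = shape_functions(gauss_points())  # (G, 8)
        self.Xgp = mesh.gauss_coords()  # (E, G, 3)
        self.T_ref = sample_intensity(
            template, self.Xgp.reshape(-1, 3)
        ).reshape(self.Xgp.shape[:2])
        self.detJ = self.asm.detJ0  # (E, G), weights 1

    def deformed_points(self, u: np.ndarray) -> np.ndarray:
        ue = u[self.mesh.elements]  # (E, 8, 3)
        return self.Xgp + np.einsum("ga,eax->egx", self.N, ue)

    def mismatch_field(self, u: np.ndarray) -> np.ndarray:
        """(T(X) - S(phi(X))) at each Gauss point, (E, G)."""
        x = self.deformed_points(u)
        S = sample_intensity(self.target, x.reshape(-1, 3)).reshape(x.shape[:2])
        return self.T_ref - S

    def energy(self, u: np.ndarray, psi: float) -> float:
        d = self.mismatch_field(u)
        return float(0.5 * psi * np.sum(d**2 * self.detJ))

    def forces(self, u: np.ndarray, psi: float) -> np.ndarray:
        """Nodal image forces = -d(energy)/du, (n_nodes, 3)."""
        x = self.deformed_points(u)
        flat = x.reshape(-1, 3)
        S = sample_intensity(self.target, flat).reshape(x.shape[:2])
        G = sample_gradient(self.target, flat).reshape(x.shape + ())
        G = G.reshape(x.shape[0], x.shape[1], 3)
        d = self.T_ref - S
        # f_a = sum_g psi * d * gradS * N_a * detJ
        fe = psi * np.einsum("eg,egx,ga,eg->eax", d, G, self.N, self.detJ)
        f = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(f, self.mesh.elements.ravel(), fe.reshape(-1, 3))
        return f

    def gauss_newton_stiffness(self, u: np.ndarray, psi: float) -> sp.csr_matrix:
        """SPD Gauss-Newton part of -d(forces)/du: psi gradS gradS^T N_a N_b."""
        x = self.deformed_points(u)
        G = sample_gradient(self.target, x.reshape(-1, 3)).reshape(
            x.shape[0], x.shape[1], 3
        )
        # element blocks (E, 8, 3, 8, 3)
        Ke = psi * np.einsum(
            "egx,egy,ga,gb,eg->eaxby", G, G, self.N, self.N, self.detJ
        )
        rows = self.asm._rows
        cols = self.asm._cols
        return sp.coo_matrix(
            (Ke.reshape(-1, 24 * 24).ravel(), (rows, cols)),
            shape=(self.asm.n_dof, self.asm.n_dof),
        ).tocsr()

    def ct(self, u: np.ndarray) -> float:
        """Mean signed intensity mismatch over the mesh (per-element means
        averaged over all elements)."""
        return float(self.mismatch_field(u).mean(axis=1).mean())

    def ct_gradient(self, u: np.ndarray) -> np.ndarray:
        """d(Ct)/du, (n_nodes, 3): Ct falls as the mesh moves up the target
        intensity gradient."""
        x = self.deformed_points(u)
        G = sample_gradient(self.target, x.reshape(-1, 3)).reshape(
            x.shape[0], x.shape[1], 3
        )
        w = 1.0 / (self.mesh.n_elems * G.shape[1])
        ge = -w * np.einsum("egx,ga->eax", G, self.N)
        g = np.zeros((self.mesh.n_nodes, 3))
        np.add.at(g, self.mesh.elements.ravel(), ge.reshape(-1, 3))
        return g


def image_energy(
    template: Image3D,
    target: Image3D,
    mesh: HexMesh,
    displacements: np.ndarray,
    psi: float,
) -> float:
    """Gauss-quadrature image energy: psi/2 (T(X) - S(phi))^2 over the mesh."""
    if psi < 0:
        raise ValueError("psi must be >= 0")
    return _ImageSampler(template, target, mesh).energy(displacements, psi)


def image_forces(
    template: Image3D,
    target: Image3D,
    mesh: HexMesh,
    displacements: np.ndarray,
    psi: float,
) -> np.ndarray:
    """Nodal image-based forces: psi (T - S(phi)) dS/dphi assembled with the
    element shape functions; equals minus the displacement gradient of
    :func:`image_energy`."""
    if psi < 0:
        raise ValueError("psi must be >= 0")
    return _ImageSampler(template, target, mesh).forces(displacements, psi)


def average_intensity_mismatch(
    template: Image3D,
    target: Image3D,
    mesh: HexMesh,
    displacements: np.ndarray | None = None,
) -> float:
    """The activation drive Ct: signed (T - S) averaged per element, then
    over all elements of the mesh."""
    if mesh.n_elems == 0:
        raise ValueError("mesh has no elements")
    u = np.zeros((mesh.n_nodes, 3)) if displacements is None else displacements
    return _ImageSampler(template, target, mesh).ct(u)


def base_constraints(mesh: HexMesh) -> np.ndarray:
    """Boundary conditions for the LV registration, (n_nodes, 3) bool mask.

    Basal-plane nodes are fixed longitudinally (z); in-plane rigid modes
    (two translations + rotation about the long axis) are removed by fixing
    the tangential dof of the basal nodes nearest the four cardinal
    directions, where the tangential direction is a coordinate axis.
    """
    z = mesh.node_coords[:, 2]
    base = np.isclose(z, z.max())
    fixed = np.zeros((mesh.n_nodes, 3), dtype=bool)
    fixed[base, 2] = True
    x, y = mesh.node_coords[:, 0], mesh.node_coords[:, 1]
    theta = np.mod(np.arctan2(y, x), 2 * np.pi)
    for ang, dof in [(0.0, 1), (np.pi / 2, 0), (np.pi, 1), (3 * np.pi / 2, 0)]:
        dd = np.abs(np.angle(np.exp(1j * (theta - ang))))
        cand = np.where(base)[0]
        k = cand[np.argmin(dd[cand])]
        fixed[cand[np.isclose(theta[cand], theta[k])], dof] = True
    return fixed


def register(
    template: Image3D,
    target: Image3D,
    mesh: HexMesh,
    fibers: FiberField,
    passive: PassiveParams | None = None,
    active: ActiveParams | None = None,
    schedule: PenaltySchedule | None = None,
    n_steps: int = 30,
    active_on: bool = True,
    fixed: np.ndarray | None = None,
    tol: float = 0.02,
    max_iter: int = 40,
    signed_ct: bool = True,
    max_step: float | None = 2.0,
    image_stiffness: bool = True,
) -> RegistrationResult:
    """Run the pseudo-time warping analysis from t = 0 to t = 1.

    At each of ``n_steps`` equal increments the penalties are updated, the
    activation is set to psi_a * Ct (clamped at zero; Ct from the current
    configuration, absolute-valued if ``signed_ct`` is False), and
    equilibrium between internal stresses and the image forces is re-solved
    with the previous displacement as the initial guess.  The image forces
    are configuration dependent and are re-evaluated at every Newton
    iteration; by default their Gauss-Newton stiffness is included in the
    tangent for robustness.

    Returns the stored displacement history with Ct, energy and mismatch
    traces.  Raises :class:`RegistrationError` if a step fails to converge.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    passive = passive if passive is not None else PassiveParams()
    active_params = active if active is not None else ActiveParams()
    schedule = schedule if schedule is not None else PenaltySchedule()
    if fixed is None:
        fixed = base_constraints(mesh)

    asm = FEAssembly(mesh)
    sampler = _ImageSampler(template, target, mesh, asm)
    n_nodes = mesh.n_nodes
    u = np.zeros((n_nodes, 3))

    times = np.linspace(0.0, 1.0, n_steps + 1)
    disp = np.zeros((n_steps + 1, n_nodes, 3))
    ct_tr = np.zeros(n_steps + 1)
    act_tr = np.zeros(n_steps + 1)
    psi_tr = np.zeros(n_steps + 1)
    psia_tr = np.zeros(n_steps + 1)
    en_tr = np.zeros(n_steps + 1)
    mis_tr = np.zeros(n_steps + 1)
    conv = np.ones(n_steps + 1, dtype=bool)

    ct_tr[0] = sampler.ct(u)
    mis_tr[0] = sampler.energy(u, 1.0)

    mask = (~fixed).ravel()
    free = ~fixed

    def advance(u_in, t_sub):
        """Equilibrium at pseudo-time t_sub starting from u_in.

        Newton iteration on r(u) = f_int(u, act(u)) - f_img(u), where the
        activation act(u) = psi_a * Ct(u) (clamped at zero) is itself
        configuration dependent: the mismatch average is a function of the
        current deformation map, so contraction is self-limiting within the
        solve.  The tangent couples this feedback exactly through a
        rank-one Sherman-Morrison update (d f_int/d act) x (d act/d u) on
        top of the material tangent and the Gauss-Newton image stiffness.
        """
        import scipy.sparse.linalg as spla

        psi, psi_a = penalty_schedule(t_sub, schedule)

        def act_of(ct):
            if not active_on or psi_a == 0.0:
                return 0.0
            drive = ct if signed_ct else abs(ct)
            return max(psi_a * drive, 0.0)

        def resid(uu):
            ct_ = sampler.ct(uu)
            a_ = act_of(ct_)
            r_ = asm.internal_forces(uu, fibers.vectors, passive, active_params, a_)
            if psi > 0:
                r_ = r_ - sampler.forces(uu, psi)
            return r_, ct_, a_

        u = u_in.copy()
        r, ct, act = resid(u)
        rnorm = np.linalg.norm(r[free])
        load = sampler.forces(u, psi) if psi > 0 else np.zeros_like(u)
        ref = max(np.linalg.norm(load[free]), rnorm, 1e-12)
        if rnorm <= tol * ref:
            return u, ct, act, psi, psi_a

        for _ in range(max_iter):
            K = asm.tangent(u, fibers.vectors, passive, active_params, act)
            if psi > 0 and image_stiffness:
                K = K + sampler.gauss_newton_stiffness(u, psi)
            lu = spla.splu(K[mask][:, mask].tocsc())
            y1 = lu.solve(-r.ravel()[mask])
            if act > 0.0 and signed_ct:
                g = asm.activation_sensitivity(
                    u, fibers.vectors, passive, active_params, act
                )
                c = psi_a * sampler.ct_gradient(u)
                gv, cv = g.ravel()[mask], c.ravel()[mask]
                y2 = lu.solve(gv)
                denom = 1.0 + cv @ y2
                if abs(denom) > 1e-8:
                    y1 = y1 - y2 * (cv @ y1) / denom
            du = np.zeros(3 * mesh.n_nodes)
            du[mask] = y1
            du = du.reshape(-1, 3)
            if max_step is not None:
                mx = np.abs(du).max()
                if mx > max_step:
                    du *= max_step / mx
            step, trial = 1.0, None
            for _ls in range(12):
                try:
                    trial = resid(u + step * du)
                except InvertedElementError:
                    step *= 0.5
                    trial = None
                    continue
                if np.linalg.norm(trial[0][free]) < rnorm or step < 1e-3:
                    break
                step *= 0.5
            if trial is None:
                raise SolverError("step inverts elements", residual=rnorm)
            u = u + step * du
            r, ct, act = trial
            rnorm = np.linalg.norm(r[free])
            if rnorm <= tol * ref:
                return u, ct, act, psi, psi_a
        raise SolverError(
            f"registration step stalled at relative residual {rnorm / ref:.3e}",
            residual=rnorm,
        )

    for k in range(1, n_steps + 1):
        t = times[k]
        # adaptive substepping: a failed increment is bisected (down to 1/8
        # of the nominal step) before the whole run is declared failed
        try:
            u, ct, activation, psi, psi_a = advance(u, t)
        except SolverError as exc:
            t_lo, n_sub = times[k - 1], 2
            done = False
            while n_sub <= 8 and not done:
                u_try = u
                try:
                    for t_sub in np.linspace(t_lo, t, n_sub + 1)[1:]:
                        u_try, ct, activation, psi, psi_a = advance(u_try, t_sub)
                    done = True
                except SolverError as exc2:
                    exc = exc2
                    n_sub *= 2
            if not done:
                raise RegistrationError(k, t, exc.residual) from exc
            u = u_try

        disp[k] = u
        ct_tr[k] = ct
        act_tr[k] = activation
        psi_tr[k] = psi
        psia_tr[k] = psi_a
        en_tr[k] = sampler.energy(u, psi)
        mis_tr[k] = sampler.energy(u, 1.0)

    return RegistrationResult(
        times=times,
        displacements=disp,
        ct=ct_tr,
        activation=act_tr,
        psi=psi_tr,
        psi_a=psia_tr,
        energy=en_tr,
        mismatch=mis_tr,
        converged=conv,
    )
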