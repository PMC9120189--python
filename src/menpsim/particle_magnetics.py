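"""Lumped (zero-dimensional) physics of core-shell magnetoelectric nanoparticles.

A magnetoelectric nanoparticle (MENP) couples an electric field to its
magnetization through two linear constitutive laws joined by mechanics: the
piezoelectric shell (barium titanate, BTO) converts an electric field into
stress, and the magnetostrictive core (cobalt ferrite, CFO) converts stress
into a magnetoelastic contribution to the effective magnetic field that its
superparamagnetic moment responds to.  This module implements that chain as a
self-consistent fixed point on a single representative particle:

    E  --(piezoelectric e-matrix)-->  S
    M  --(magnetostriction)------->  eps_me  --(elastic closure)-->  S
    S, H  --(magnetoelastic field)->  H_eff
    H_eff --(Langevin)------------->  M

Spatially resolved elasticity and demagnetization are deliberately outside
scope; the analytic uniformly-magnetized-sphere field is provided as a
surrogate for spatial field maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import yaml

MU0 = 4.0e-7 * np.pi  # vacuum permeability, T*m/A
KB = 1.380649e-23  # Boltzmann constant, J/K

__all__ = [
    "MU0",
    "KB",
    "MaterialProps",
    "ParticleSpec",
    "LumpedState",
    "MHCurve",
    "load_materials",
    "get_material",
    "langevin",
    "thermal_beta",
    "equilibrium_magnetization",
    "composite_magnetization",
    "magnetostrictive_strain",
    "piezo_stress",
    "effective_field",
    "solve_lumped_me",
    "mh_curve",
    "sphere_dipole_field",
    "voigt_to_tensor",
    "tensor_to_voigt",
    "deviator",
]

# Voigt index pairs in 11, 22, 33, 23, 13, 12 order.
_VOIGT_PAIRS = ((0, 0), (1, 1), (2, 2), (1, 2), (0, 2), (0, 1))


def voigt_to_tensor(v: np.ndarray) -> np.ndarray:
    """Expand a 6-vector of stresses (11,22,33,23,13,12) to a symmetric 3x3."""
    v = np.asarray(v, dtype=float)
    t = np.zeros((3, 3))
    for k, (i, j) in enumerate(_VOIGT_PAIRS):
        t[i, j] = v[k]
        t[j, i] = v[k]
    return t


def tensor_to_voigt(t: np.ndarray) -> np.ndarray:
    """Collapse a symmetric 3x3 stress tensor to the 6-vector convention."""
    t = np.asarray(t, dtype=float)
    return np.array([t[i, j] for (i, j) in _VOIGT_PAIRS])


def deviator(t: np.ndarray) -> np.ndarray:
    """Traceless (deviatoric) part of a 3x3 tensor."""
    t = np.asarray(t, dtype=float)
    return t - np.trace(t) / 3.0 * np.eye(3)


def _upper_triangle_to_symmetric(flat: Sequence[float], n: int = 6) -> np.ndarray:
    """Rebuild a symmetric n x n matrix from its column-major upper triangle."""
    flat = list(flat)
    if len(flat) != n * (n + 1) // 2:
        raise ValueError(f"expected {n*(n+1)//2} entries, got {len(flat)}")
    m = np.zeros((n, n))
    k = 0
    for j in range(n):
        for i in range(j + 1):
            m[i, j] = flat[k]
            m[j, i] = flat[k]
            k += 1
    return m


@dataclass
class MaterialProps:
    """Physical constants of one constituent material.

    Fields mirror the constant table of the model: electrical conductivity
    ``sigma`` (S/m), initial susceptibility ``chi0``, saturation
    magnetostriction ``lambda_s`` (dimensionless; ppm on input), mass density
    (kg/m^3), saturation magnetization ``Ms`` (A/m), Poisson ratio, relative
    permittivity diagonal, Young's modulus (Pa), 6x6 stiffness (Pa) and the
    3x6 piezoelectric stress-coupling matrix e (C/m^2).  Fields a material
    does not possess are ``None``.
    """

    name: str
    sigma: float
    density: float
    chi0: Optional[float] = None
    lambda_s: Optional[float] = None
    Ms: Optional[float] = None
    poisson: Optional[float] = None
    eps_r: Optional[np.ndarray] = None
    youngs: Optional[float] = None
    elasticity_voigt: Optional[np.ndarray] = None
    coupling_voigt: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.density <= 0:
            raise ValueError(f"{self.name}: density must be positive")
        if self.Ms is not None and self.Ms < 0:
            raise ValueError(f"{self.name}: Ms must be non-negative")
        if self.eps_r is not None:
            self.eps_r = np.asarray(self.eps_r, dtype=float)
            if np.any(self.eps_r < 1.0):
                raise ValueError(f"{self.name}: relative permittivity < 1")
        if self.coupling_voigt is not None:
            self.coupling_voigt = np.asarray(self.coupling_voigt, dtype=float)
            if self.coupling_voigt.shape != (3, 6):
                raise ValueError(f"{self.name}: coupling matrix must be 3x6")
        if self.elasticity_voigt is not None:
            self.elasticity_voigt = np.asarray(self.elasticity_voigt, dtype=float)
            if self.elasticity_voigt.shape != (6, 6):
                raise ValueError(f"{self.name}: elasticity matrix must be 6x6")
            if not np.allclose(self.elasticity_voigt, self.elasticity_voigt.T):
                raise ValueError(f"{self.name}: elasticity matrix not symmetric")
            eigs = np.linalg.eigvalsh(self.elasticity_voigt)
            if eigs.min() < -1e-6 * abs(eigs).max():
                # Tabulated constants are kept verbatim even when the printed
                # matrix is not positive-semidefinite; the lumped solver does
                # not use the shell stiffness, so this is a warning only.
                warnings.warn(
                    f"{self.name}: elasticity matrix is not positive-semidefinite",
                    stacklevel=2,
                )


def _material_from_dict(d: dict) -> MaterialProps:
    el = d.get("elasticity_voigt_GPa")
    if el is not None:
        el = _upper_triangle_to_symmetric(el) * 1e9
    youngs = d.get("youngs_GPa")
    lam = d.get("lambda_s_ppm")
    return MaterialProps(
        name=d["name"],
        sigma=float(d["sigma"]),
        density=float(d["density"]),
        chi0=d.get("chi0"),
        lambda_s=None if lam is None else float(lam) * 1e-6,
        Ms=d.get("Ms"),
        poisson=d.get("poisson"),
        eps_r=d.get("eps_r"),
        youngs=None if youngs is None else float(youngs) * 1e9,
        elasticity_voigt=el,
        coupling_voigt=d.get("coupling_voigt"),
    )


def load_materials(path: Optional[str] = None) -> dict[str, MaterialProps]:
    """Load the material database (shipped table, or a user YAML override)."""
    if path is None:
        text = resources.files("menpsim.data").joinpath("materials.yaml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return {key: _material_from_dict(val) for key, val in raw.items()}


_MATERIALS: Optional[dict[str, MaterialProps]] = None


def get_material(key: str) -> MaterialProps:
    """Return a shipped material by key (e.g. 'cobalt_ferrite', 'spion')."""
    global _MATERIALS
    if _MATERIALS is None:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _MATERIALS = load_materials()
    try:
        return _MATERIALS[key]
    except KeyError:
        raise KeyError(
            f"unknown material {key!r}; available: {sorted(_MATERIALS)}"
        ) from None


@dataclass
class ParticleSpec:
    """Core-shell particle geometry and thermal environment."""

    r_total: float  # m
    r_core: float  # m
    core_material: MaterialProps
    shell_material: Optional[MaterialProps] = None
    temperature: float = 300.0  # K

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_core <= self.r_total:
            raise ValueError("require 0 <= r_core <= r_total")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def f_core(self) -> float:
        """Core volume fraction (r_core/r_total)^3."""
        if self.r_total == 0:
            return 0.0
        return (self.r_core / self.r_total) ** 3

    @property
    def core_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.r_core**3

    @property
    def total_volume(self) -> float:
        return 4.0 / 3.0 * np.pi * self.r_total**3


@dataclass
class LumpedState:
    """Self-consistent state of the lumped magnetoelectric solver."""

    M: np.ndarray  # A/m
    S: np.ndarray  # Pa, 3x3
    E: np.ndarray  # V/m
    H: np.ndarray  # A/m
    H_eff: np.ndarray  # A/m
    eps_me: np.ndarray  # dimensionless, 3x3
    converged: bool
    iterations: int


@dataclass
class MHCurve:
    """Sampled magnetization curve M(H) along a field axis.

    Odd-symmetric and monotone by construction; callable, with linear
    interpolation between samples.
    """

    H: np.ndarray  # A/m
    M: np.ndarray  # A/m
    metadata: dict = field(default_factory=dict)

    def __call__(self, h, strict: bool = False):
        h = np.asarray(h, dtype=float)
        if strict and (h.min() < self.H[0] or h.max() > self.H[-1]):
            raise ValueError("drive exceeds tabulated M-H range")
        return np.interp(h, self.H, self.M)

    def to_text(self, path: str) -> None:
        header = "H_A_per_m M_A_per_m"
        for k, v in self.metadata.items():
            header = f"{k}: {v}\n" + header
        np.savetxt(path, np.column_stack([self.H, self.M]), header=header)


def langevin(x):
    """Langevin function L(x) = coth(x) - 1/x, with a series branch near 0.

    Odd, strictly increasing, bounded by (-1, 1); L(0) = 0 by the limit.
    """
    x = np.asarray(x, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    out = np.empty_like(x)
    small = np.abs(x) < 1e-4
    xs = x[small]
    # Maclaurin series x/3 - x^3/45 + 2x^5/945; truncation < 1e-21 here.
    out[small] = xs / 3.0 - xs**3 / 45.0 + 2.0 * xs**5 / 945.0
    xl = x[~small]
    out[~small] = 1.0 / np.tanh(xl) - 1.0 / xl
    return out[0] if scalar else out


def thermal_beta(spec: ParticleSpec) -> float:
    """Langevin steepness beta = mu0 * Ms * V_core / (kB * T), in m/A.

    beta*|H| is the dimensionless ratio of the Zeeman energy of the core's
    saturated moment to the thermal energy.
    """
    Ms = spec.core_material.Ms
    if Ms is None or Ms <= 0:
        raise ValueError("core material must have Ms > 0")
    return MU0 * Ms * spec.core_volume / (KB * spec.temperature)


def equilibrium_magnetization(
    H_eff: np.ndarray, spec: ParticleSpec, beta: Optional[float] = None
) -> np.ndarray:
    """Thermal-equilibrium core magnetization M = Ms * L(beta|H_eff|) * H_eff_hat."""
    H_eff = np.asarray(H_eff, dtype=float)
    Ms = spec.core_material.Ms
    if Ms is None or Ms <= 0:
        raise ValueError("core material must have Ms > 0")
    if spec.core_volume == 0.0:
        warnings.warn("zero core volume: magnetization is identically zero", stacklevel=2)
        return np.zeros(3)
    if beta is None:
        beta = thermal_beta(spec)
    h = np.linalg.norm(H_eff)
    if h == 0.0:
        return np.zeros(3)
    return Ms * langevin(beta * h) * H_eff / h


def composite_magnetization(spec: ParticleSpec, M_core: np.ndarray) -> np.ndarray:
    """Volume-averaged particle magnetization; the shell contributes nothing."""
    return spec.f_core * np.asarray(M_core, dtype=float)


def magnetostrictive_strain(M: np.ndarray, mat: MaterialProps) -> np.ndarray:
    """Magnetostrictive strain eps_me = (3/2)(lambda_s/Ms^2) dev(M (x) M).

    Traceless, and invariant under M -> -M (quadratic in M).
    """
    if mat.Ms is None or mat.Ms == 0:
        raise ValueError(f"{mat.name}: Ms must be nonzero for magnetostriction")
    if mat.lambda_s is None:
        raise ValueError(f"{mat.name}: lambda_s is not set")
    M = np.asarray(M, dtype=float)
    return 1.5 * mat.lambda_s / mat.Ms**2 * deviator(np.outer(M, M))


def piezo_stress(
    E: np.ndarray, mat: MaterialProps, S0: Optional[np.ndarray] = None
) -> np.ndarray:
    """Zero-strain piezoelectric stress S = S0 - E . e (Voigt contraction).

    The converse piezoelectric effect at clamped strain: each Voigt stress
    component j picks up -sum_i E_i e[i, j].  Returns a full 3x3 tensor.
    """
    if mat.coupling_voigt is None:
        raise ValueError(f"{mat.name}: no piezoelectric coupling matrix")
    E = np.asarray(E, dtype=float)
    s_voigt = -E @ mat.coupling_voigt
    S = voigt_to_tensor(s_voigt)
    if S0 is not None:
        S = S + np.asarray(S0, dtype=float)
    return S


def effective_field(
    H: np.ndarray, S: np.ndarray, M: np.ndarray, mat: MaterialProps
) -> np.ndarray:
    """Magnetoelastic effective field H_eff = H + (3 lambda_s/(mu0 Ms^2)) dev(S) M."""
    if mat.Ms is None or mat.Ms == 0:
        raise ValueError(f"{mat.name}: Ms must be nonzero")
    H = np.asarray(H, dtype=float)
    lam = mat.lambda_s or 0.0
    if lam == 0.0:
        return H.copy()
    return H + 3.0 * lam / (MU0 * mat.Ms**2) * deviator(np.asarray(S, float)) @ np.asarray(M, float)


def _isotropic_stress(strain: np.ndarray, youngs: float, poisson: float) -> np.ndarray:
    """Isotropic Hooke's law sigma = 2 mu eps + lambda tr(eps) I."""
    lam = youngs * poisson / ((1 + poisson) * (1 - 2 * poisson))
    mu = youngs / (2 * (1 + poisson))
    return 2.0 * mu * strain + lam * np.trace(strain) * np.eye(3)


def solve_lumped_me(
    spec: ParticleSpec,
    H_applied: np.ndarray,
    E_applied: np.ndarray,
    tol: float = 1e-10,
    max_iter: int = 500,
    damping: float = 0.5,
    kappa: float = 1.0,
    clamp: float = 0.0,
    strict: bool = False,
    M0: Optional[np.ndarray] = None,
) -> LumpedState:
    """Solve the lumped magnetoelectric fixed point for one particle.

    The stress on the core is the piezoelectric stress of the shell
    (transmitted with factor ``kappa``, default 1: fully transmitted) minus
    ``clamp`` times the elastic back-stress of the core's own
    magnetostrictive strain (isotropic stiffness closure).  A free particle
    deforms with its magnetostrictive eigenstrain, which is then stress-free,
    so ``clamp`` defaults to 0; ``clamp=1`` models a rigidly constrained
    core.  ``M`` is damped-iterated until the relative update |dM|/Ms falls
    below ``tol``; the damping halves automatically whenever the residual
    grows, which stabilizes the strongly self-coupled clamped regime.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    H_applied = np.asarray(H_applied, dtype=float)
    E_applied = np.asarray(E_applied, dtype=float)
    core = spec.core_material
    shell = spec.shell_material
    Ms = core.Ms
    if Ms is None or Ms <= 0:
        raise ValueError("core material must have Ms > 0")
    beta = thermal_beta(spec) if spec.core_volume > 0 else None
    lam = core.lambda_s or 0.0

    S_piezo = np.zeros((3, 3))
    if shell is not None and shell.coupling_voigt is not None and np.any(E_applied):
        S_piezo = kappa * piezo_stress(E_applied, shell)

    M = np.zeros(3) if M0 is None else np.asarray(M0, dtype=float).copy()
    S = S_piezo.copy()
    eps_me = np.zeros((3, 3))
    H_eff = H_applied.copy()
    converged = False
    iterations = 0
    alpha = damping
    prev_step = np.inf
    for iterations in range(1, max_iter + 1):
        if lam != 0.0:
            eps_me = magnetostrictive_strain(M, core)
            S = S_piezo
            if clamp != 0.0:
                S = S - clamp * _isotropic_stress(eps_me, core.youngs, core.poisson)
            H_eff = effective_field(H_applied, S, M, core)
        else:
            H_eff = H_applied
        M_new = equilibrium_magnetization(H_eff, spec, beta=beta)
        step = M_new - M
        step_norm = np.linalg.norm(step)
        if step_norm > prev_step:
            alpha = max(alpha * 0.5, 1.0 / 64.0)
        prev_step = step_norm
        M = M + alpha * step
        if step_norm / Ms < tol:
            converged = True
            # One final undamped evaluation so the reported state is exact.
            M = M_new
            break
    if not converged and strict:
        raise RuntimeError(f"lumped solver did not converge in {max_iter} iterations")
    return LumpedState(
        M=M, S=S, E=E_applied, H=H_applied, H_eff=H_eff, eps_me=eps_me,
        converged=converged, iterations=iterations,
    )


def mh_curve(
    spec: ParticleSpec,
    H_max: float,
    n_points: int = 201,
    composite: bool = True,
    direction: Sequence[float] = (0.0, 0.0, 1.0),
) -> MHCurve:
    """Sample the equilibrium magnetization curve over [-H_max, H_max].

    Odd symmetry is enforced by construction: the positive branch is sampled
    and mirrored.  ``composite=True`` volume-averages over the whole particle
    (shell diluting the core signal); otherwise the core magnetization is
    returned.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if H_max <= 0:
        raise ValueError("H_max must be positive")
    dhat = np.asarray(direction, dtype=float)
    dhat = dhat / np.linalg.norm(dhat)
    n_half = n_points // 2 + 1
    h_pos = np.linspace(0.0, H_max, n_half)
    beta = thermal_beta(spec)
    m_pos = np.empty(n_half)
    for i, h in enumerate(h_pos):
        Mvec = equilibrium_magnetization(h * dhat, spec, beta=beta)
        if composite:
            Mvec = composite_magnetization(spec, Mvec)
        m_pos[i] = Mvec @ dhat
    H = np.concatenate([-h_pos[:0:-1], h_pos])
    M = np.concatenate([-m_pos[:0:-1], m_pos])
    meta = {
        "core_material": spec.core_material.name,
        "r_core_nm": spec.r_core * 1e9,
        "r_total_nm": spec.r_total * 1e9,
        "temperature_K": spec.temperature,
        "composite": composite,
    }
    return MHCurve(H=H, M=M, metadata=meta)


def sphere_dipole_field(
    M: np.ndarray, r_particle: float, points: np.ndarray
) -> np.ndarray:
    """Magnetic flux density of a uniformly magnetized sphere (T).

    Inside: uniform B = (2/3) mu0 M.  Outside: point dipole of moment
    M * V_sphere.  Points are Cartesian coordinates (m) relative to the
    sphere center; shape (..., 3).
    """
    M = np.asarray(M, dtype=float)
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    r = np.linalg.norm(pts, axis=-1)
    B = np.empty_like(pts)
    inside = r <= r_particle
    B[inside] = 2.0 / 3.0 * MU0 * M
    out = ~inside
    if np.any(out):
        m = M * 4.0 / 3.0 * np.pi * r_particle**3
        ro = r[out][:, None]
        rhat = pts[out] / ro
        B[out] = MU0 / (4 * np.pi) * (3.0 * (rhat @ m)[:, None] * rhat - m) / ro**3
    return B.reshape(np.shape(points))
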