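"""Constitutive laws for the pelvis model.

Three material behaviours are covered:

* isotropic linear elasticity for bone (with derived bulk and shear moduli),
* a piecewise-linear, tension-only strain--stiffness law for the sacroiliac
  and sacrotuberous ligaments,
* a compression-only polynomial tangent-modulus law for the sacrocaudal
  joint, together with a 3-parameter Mooney--Rivlin hyperelastic fit to its
  stress--strain curve.

Internal unit regime: newtons, millimetres and megapascals
(1 MPa * mm^2 = 1 N).  Young's moduli quoted in pascals are converted on
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "IsotropicElasticity",
    "LigamentLaw",
    "JointLaw",
    "MooneyRivlin3",
    "derive_isotropic",
    "ligament_stiffness",
    "ligament_force",
    "ligament_energy",
    "joint_tangent_modulus",
    "joint_stress",
    "mr_uniaxial_stress",
    "fit_mooney_rivlin",
    "BONE",
]


# --------------------------------------------------------------------------
# Bone: isotropic elasticity
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IsotropicElasticity:
    """Isotropic linear-elastic constants with derived moduli (all Pa)."""

    E: float
    nu: float
    K: float = field(init=False)
    G: float = field(init=False)

    def __post_init__(self) -> None:
        if not (self.E > 0):
            raise ValueError(f"Young's modulus must be positive, got {self.E}")
        if not (0 <= self.nu < 0.5):
            raise ValueError(
                f"Poisson's ratio must lie in [0, 0.5), got {self.nu}"
            )
        object.__setattr__(self, "K", self.E / (3.0 * (1.0 - 2.0 * self.nu)))
        object.__setattr__(self, "G", self.E / (2.0 * (1.0 + self.nu)))


def derive_isotropic(E: float, nu: float) -> IsotropicElasticity:
    """Derive bulk and shear moduli from Young's modulus and Poisson's ratio.

    K = E / (3(1 - 2nu)),  G = E / (2(1 + nu)).
    """
    return IsotropicElasticity(E=E, nu=nu)


#: Cortical-bone default used for the pelvic bones (human-derived values).
BONE = derive_isotropic(1.7e10, 0.3)


# --------------------------------------------------------------------------
# Ligaments: piecewise-linear tension-only stiffness
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LigamentLaw:
    """Tension-only ligament law: stiffness (N/mm) as a step function of strain.

    The default bands are <2.5%, 2.5--5%, 5--10% and >10% tensile strain with
    stiffnesses 39, 55, 103 and 100 N/mm.  Bands are half-open, closed on the
    left, so a strain of exactly 0.10 falls in the last band.  Stiffness (and
    hence force) is identically zero for non-positive strain: the element has
    no resistance in compression.

    Stiffness is force per unit *elongation*; the force at elongation d is the
    integral of the stiffness from 0 to d, which keeps the force--elongation
    curve continuous across band boundaries even though the stiffness steps.
    """

    strain_breakpoints: tuple[float, ...] = (0.025, 0.05, 0.10)
    band_stiffness: tuple[float, ...] = (39.0, 55.0, 103.0, 100.0)
    tension_only: bool = True

    def __post_init__(self) -> None:
        bp = np.asarray(self.strain_breakpoints, dtype=float)
        ks = np.asarray(self.band_stiffness, dtype=float)
        if bp.ndim != 1 or ks.ndim != 1 or ks.size != bp.size + 1:
            raise ValueError(
                "need n breakpoints and n+1 stiffness bands, got "
                f"{bp.size} and {ks.size}"
            )
        if not np.all(np.diff(bp) > 0) or not np.all(bp > 0):
            raise ValueError("strain breakpoints must be positive and increasing")
        if np.any(ks < 0):
            raise ValueError("band stiffnesses must be non-negative")

    # Precomputed per-unit-rest-length force/energy at each breakpoint would
    # be cached on a mutable class; with a frozen dataclass we recompute --
    # the arrays are tiny and this is never a hot path.

    def _edges(self) -> tuple[np.ndarray, np.ndarray]:
        bp = np.asarray(self.strain_breakpoints, dtype=float)
        ks = np.asarray(self.band_stiffness, dtype=float)
        return np.concatenate([[0.0], bp]), ks

    def stiffness(self, strain):
        """Tangent stiffness in N/mm at the given tensile strain (0 if <= 0)."""
        edges, ks = self._edges()
        s = np.asarray(strain, dtype=float)
        idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, ks.size - 1)
        out = np.where(s > 0, ks[idx], 0.0)
        return out if out.ndim else float(out)

    def force(self, strain, rest_length):
        """Tensile force in N at the given strain for a spring of rest length L0.

        Closed-form integral of the stepped stiffness over elongation
        d = strain * L0; zero for strain <= 0.  ``rest_length`` may be an
        array matching ``strain``.
        """
        rest_length = np.asarray(rest_length, dtype=float)
        if np.any(rest_length <= 0):
            raise ValueError(f"rest length must be positive, got {rest_length}")
        edges, ks = self._edges()
        # cumulative force per unit rest length at each band edge
        f_at_edge = np.concatenate([[0.0], np.cumsum(ks[:-1] * np.diff(edges))])
        s = np.asarray(strain, dtype=float)
        idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, ks.size - 1)
        f_unit = f_at_edge[idx] + ks[idx] * (s - edges[idx])
        out = np.where(s > 0, f_unit * rest_length, 0.0)
        return out if out.ndim else float(out)

    def energy(self, strain, rest_length):
        """Stored elastic energy in N*mm; C1 antiderivative of the force."""
        rest_length = np.asarray(rest_length, dtype=float)
        if np.any(rest_length <= 0):
            raise ValueError(f"rest length must be positive, got {rest_length}")
        edges, ks = self._edges()
        widths = np.diff(edges)
        f_at_edge = np.concatenate([[0.0], np.cumsum(ks[:-1] * widths)])
        # energy per unit rest_length^2 at each band edge
        e_at_edge = np.concatenate(
            [[0.0], np.cumsum(f_at_edge[:-1] * widths + 0.5 * ks[:-1] * widths**2)]
        )
        s = np.asarray(strain, dtype=float)
        idx = np.clip(np.searchsorted(edges, s, side="right") - 1, 0, ks.size - 1)
        ds = s - edges[idx]
        e_unit = e_at_edge[idx] + f_at_edge[idx] * ds + 0.5 * ks[idx] * ds**2
        out = np.where(s > 0, e_unit * rest_length**2, 0.0)
        return out if out.ndim else float(out)


def ligament_stiffness(law: LigamentLaw, strain):
    return law.stiffness(strain)


def ligament_force(law: LigamentLaw, strain, rest_length: float):
    return law.force(strain, rest_length)


def ligament_energy(law: LigamentLaw, strain, rest_length: float):
    return law.energy(strain, rest_length)


# --------------------------------------------------------------------------
# Sacrocaudal joint: compression-only polynomial law
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class JointLaw:
    """Compression-only sacrocaudal joint law.

    The tangent modulus grows with compressive strain magnitude eps:

        E(eps) = a*eps + b*eps**2          (MPa, eps > 0 in compression)

    and integrates to the normal-stress magnitude

        sigma(eps) = (a/2)*eps**2 + (b/3)*eps**3.

    With the default a = 20.71 MPa and b = 234 MPa the stress coefficients
    are 10.355 and 78 MPa.  Both modulus and stress vanish for eps <= 0: the
    joint does not resist separation of the bones it connects.
    """

    a: float = 20.71
    b: float = 234.0
    compression_only: bool = True

    @property
    def stress_coeff_quadratic(self) -> float:
        return self.a / 2.0

    @property
    def stress_coeff_cubic(self) -> float:
        return self.b / 3.0

    def tangent_modulus(self, eps_c):
        """Tangent modulus (MPa) at compressive strain magnitude eps_c."""
        e = np.asarray(eps_c, dtype=float)
        out = np.where(e > 0, self.a * e + self.b * e**2, 0.0)
        return out if out.ndim else float(out)

    def stress(self, eps_c):
        """Compressive normal stress magnitude (MPa) at strain magnitude eps_c."""
        e = np.asarray(eps_c, dtype=float)
        out = np.where(
            e > 0, self.stress_coeff_quadratic * e**2 + self.stress_coeff_cubic * e**3, 0.0
        )
        return out if out.ndim else float(out)

    def energy_density(self, eps_c):
        """Strain-energy density (MPa = N*mm/mm^3): integral of the stress."""
        e = np.asarray(eps_c, dtype=float)
        out = np.where(e > 0, (self.a / 6.0) * e**3 + (self.b / 12.0) * e**4, 0.0)
        return out if out.ndim else float(out)


def joint_tangent_modulus(law: JointLaw, eps_c):
    return law.tangent_modulus(eps_c)


def joint_stress(law: JointLaw, eps_c):
    return law.stress(eps_c)


# --------------------------------------------------------------------------
# Mooney-Rivlin 3-parameter hyperelastic fit
# --------------------------------------------------------------------------

def _mr_invariant_basis(stretch):
    """Derivatives d/d(lambda) of (I1-3), (I2-3) and (I1-3)(I2-3).

    Uniaxial incompressible kinematics: lambda1 = lambda,
    lambda2 = lambda3 = lambda^{-1/2}, so I1 = lambda^2 + 2/lambda and
    I2 = 2*lambda + lambda^{-2}.  The nominal uniaxial stress of
    W = c10 (I1-3) + c01 (I2-3) + c11 (I1-3)(I2-3) is the dot product of
    (c10, c01, c11) with this basis.
    """
    lam = np.asarray(stretch, dtype=float)
    i1 = lam**2 + 2.0 / lam
    i2 = 2.0 * lam + lam**-2
    di1 = 2.0 * lam - 2.0 * lam**-2
    di2 = 2.0 - 2.0 * lam**-3
    return np.stack([di1, di2, di1 * (i2 - 3.0) + (i1 - 3.0) * di2], axis=-1)


@dataclass(frozen=True)
class MooneyRivlin3:
    """3-parameter Mooney--Rivlin solid (incompressible), coefficients in MPa.

    ``fit_range`` and ``max_rel_error`` document the provenance of fitted
    instances (range of compressive strain magnitude covered and the worst
    relative residual against the joint stress curve over that range).
    """

    c10: float
    c01: float
    c11: float
    fit_range: tuple[float, float] | None = None
    max_rel_error: float | None = None

    def strain_energy_density(self, stretch):
        """W(lambda) in MPa under uniaxial incompressible kinematics."""
        lam = np.asarray(stretch, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("stretch must be positive")
        i1 = lam**2 + 2.0 / lam
        i2 = 2.0 * lam + lam**-2
        out = (
            self.c10 * (i1 - 3.0)
            + self.c01 * (i2 - 3.0)
            + self.c11 * (i1 - 3.0) * (i2 - 3.0)
        )
        return out if out.ndim else float(out)

    def uniaxial_nominal_stress(self, stretch):
        """Nominal (first Piola-Kirchhoff) uniaxial stress dW/dlambda, MPa."""
        lam = np.asarray(stretch, dtype=float)
        if np.any(lam <= 0):
            raise ValueError("stretch must be positive")
        basis = _mr_invariant_basis(lam)
        out = basis @ np.array([self.c10, self.c01, self.c11])
        return out if np.ndim(out) else float(out)

    def uniaxial_true_stress(self, stretch):
        """Cauchy uniaxial stress lambda * dW/dlambda (incompressible), MPa."""
        lam = np.asarray(stretch, dtype=float)
        out = lam * self.uniaxial_nominal_stress(lam)
        return out if np.ndim(out) else float(out)

    # --- joint-element interface (compressive-strain-magnitude convention) --

    @staticmethod
    def _stretch_from_eps(eps_c):
        # logarithmic compressive strain magnitude -> axial stretch
        return np.exp(-np.asarray(eps_c, dtype=float))

    def stress(self, eps_c):
        """Compressive stress magnitude (MPa) at log-strain magnitude eps_c."""
        e = np.asarray(eps_c, dtype=float)
        lam = self._stretch_from_eps(np.where(e > 0, e, 0.0))
        out = np.where(e > 0, -self.uniaxial_true_stress(lam), 0.0)
        return out if out.ndim else float(out)

    def energy_density(self, eps_c):
        """Strain-energy density (MPa) at log-strain magnitude eps_c (0 if <= 0)."""
        e = np.asarray(eps_c, dtype=float)
        lam = self._stretch_from_eps(np.where(e > 0, e, 0.0))
        out = np.where(e > 0, self.strain_energy_density(lam), 0.0)
        return out if out.ndim else float(out)


def mr_uniaxial_stress(p: MooneyRivlin3, stretch):
    """Nominal uniaxial stress (MPa) of an incompressible MR solid."""
    return p.uniaxial_nominal_stress(stretch)


def fit_mooney_rivlin(
    law: JointLaw,
    fit_range: tuple[float, float] = (0.01, 0.30),
    n_samples: int = 60,
) -> MooneyRivlin3:
    """Fit a 3-parameter Mooney--Rivlin solid to the joint stress curve.

    The joint law's compressive stress magnitude is sampled uniformly over
    ``fit_range`` (compressive strain magnitude, interpreted as logarithmic
    strain, so the axial stretch is exp(-eps)).  The Mooney--Rivlin true
    stress is linear in (c10, c01, c11), so the fit is a relative-error
    weighted linear least-squares problem -- deterministic, no iteration.
    The worst relative residual over the sample is recorded on the result.
    """
    lo, hi = float(fit_range[0]), float(fit_range[1])
    if not (0.0 < lo < hi <= 0.35):
        raise ValueError(f"fit range must satisfy 0 < lo < hi <= 0.35, got {fit_range}")
    if n_samples < 10:
        raise ValueError(f"need at least 10 samples, got {n_samples}")
    eps = np.linspace(lo, hi, int(n_samples))
    lam = np.exp(-eps)
    # target: true-stress magnitude = joint stress; MR true stress = lam * P
    target = -law.stress(eps)  # compressive -> negative axial stress
    basis = _mr_invariant_basis(lam) * lam[:, None]
    w = 1.0 / np.abs(target)
    coef, *_ = np.linalg.lstsq(basis * w[:, None], target * w, rcond=None)
    pred = basis @ coef
    max_rel = float(np.max(np.abs(pred - target) / np.abs(target)))
    if not np.all(np.isfinite(coef)):
        raise RuntimeError(f"Mooney-Rivlin fit did not converge: coefficients {coef}")
    return MooneyRivlin3(
        c10=float(coef[0]),
        c01=float(coef[1]),
        c11=float(coef[2]),
        fit_range=(lo, hi),
        max_rel_error=max_rel,
    )
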