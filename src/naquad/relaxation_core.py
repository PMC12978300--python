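"""Forward model for quadrupolar relaxation of Na+ exchanging between three sites.

Sodium counterions in an aqueous surfactant solution visit three environments:
free ions in bulk water, ions following small pentamer clusters, and (above
the critical micelle concentration) ions diffusing on or inside micelles.
Exchange between the sites is fast on the NMR timescale, so the observed
longitudinal and transverse relaxation rates and the translational diffusion
coefficient are population-weighted averages over the sites.

The spin-3/2 single-exponential rate expressions used throughout are

    R1 = (pi^2/10) chi^2 [2 J(w0) + 8 J(2 w0)]
    R2 = (pi^2/10) chi^2 [3 J(0) + 5 J(w0) + 2 J(2 w0)]

with the single-correlation-time Lorentzian J(w) = 2 tau / (1 + (w tau)^2)
and chi the effective quadrupolar coupling (Hz).  In extreme narrowing
(w0 tau << 1) both rates collapse to 2 pi^2 chi^2 tau.

The bulk site is represented by its *measured* reference rates (dilute NaCl),
which is equivalent to back-computing a bulk spectral density under the shared
coupling; see :func:`bulk_spectral_density`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from . import constants as c

__all__ = [
    "NucleusContext",
    "QuadrupolarCoupling",
    "SiteFractions",
    "SiteMotion",
    "DiffusionModel",
    "ExperimentCondition",
    "lorentzian_spectral_density",
    "aggregate_spectral_density",
    "bulk_spectral_density",
    "total_spectral_density",
    "rates_from_spectral_densities",
    "single_site_rates",
    "relaxation_rates",
    "micelle_surfactant_fraction",
    "arrhenius_tau",
    "tau_from_surface_diffusion",
    "effective_tau_with_exchange",
    "stokes_einstein_diffusion",
    "obstruction_factor",
    "aggregate_diffusion",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusContext:
    """Spin system of the observed nucleus.

    Parameters
    ----------
    larmor_frequency : float
        Resonance frequency nu0 in Hz (e.g. 132 MHz for 23Na at 11.7 T).
    gyromagnetic_ratio : float
        In rad s^-1 T^-1; needed for pulsed-field-gradient diffusion.
    spin : float
        Spin quantum number; fixed at 3/2 for 23Na.
    """

    larmor_frequency: float = c.LARMOR_RELAXATION_HZ
    gyromagnetic_ratio: float = c.SODIUM_GAMMA
    spin: float = c.SODIUM_SPIN

    def __post_init__(self) -> None:
        if self.larmor_frequency <= 0:
            raise ValueError("larmor_frequency must be positive")

    @property
    def angular_frequency(self) -> float:
        """Angular Larmor frequency w0 = 2 pi nu0 in rad/s."""
        return 2.0 * math.pi * self.larmor_frequency


@dataclass(frozen=True)
class QuadrupolarCoupling:
    """Effective quadrupolar coupling chi in Hz.

    When used as a fit parameter it is constrained to 99-119 kHz, the range
    established for sodium/surfactant headgroup environments.
    """

    chi: float

    FIT_LOWER: float = field(default=99.0e3, repr=False)
    FIT_UPPER: float = field(default=119.0e3, repr=False)

    def __post_init__(self) -> None:
        if self.chi <= 0:
            raise ValueError("chi must be positive")

    @classmethod
    def from_khz(cls, chi_khz: float) -> "QuadrupolarCoupling":
        return cls(chi=chi_khz * 1e3)

    @property
    def chi_khz(self) -> float:
        return self.chi / 1e3

    def in_fit_bounds(self) -> bool:
        return self.FIT_LOWER <= self.chi <= self.FIT_UPPER


@dataclass(frozen=True)
class SiteFractions:
    """Molar fractions of Na+ over the three sites.

    ``P_a`` is the fraction associated with aggregates (clusters + micelles),
    ``P_b = 1 - P_a`` the free bulk fraction.  Within the aggregates, ``X_m``
    is the micelle share and ``X_c = 1 - X_m`` the cluster share, so the
    absolute site populations are ``X_m * P_a`` (micelle), ``X_c * P_a``
    (cluster) and ``P_b`` (bulk); they sum to one by construction.
    """

    P_a: float
    X_m: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.P_a <= 1.0:
            raise ValueError(f"P_a must lie in [0, 1], got {self.P_a}")
        if not 0.0 <= self.X_m <= 1.0:
            raise ValueError(f"X_m must lie in [0, 1], got {self.X_m}")

    @property
    def P_b(self) -> float:
        return 1.0 - self.P_a

    @property
    def X_c(self) -> float:
        return 1.0 - self.X_m

    @property
    def micelle(self) -> float:
        """Absolute micelle-site population X_m * P_a."""
        return self.X_m * self.P_a

    @property
    def cluster(self) -> float:
        """Absolute cluster-site population X_c * P_a."""
        return self.X_c * self.P_a


@dataclass(frozen=True)
class SiteMotion:
    """Correlation times of the aggregate sites and bulk reference rates.

    Parameters
    ----------
    tau_m, tau_c : float
        Micelle and cluster correlation times, s.
    bulk_R1, bulk_R2 : float
        Measured relaxation rates of free Na+ (dilute NaCl reference), s^-1.
    tau_res : float
        Mean residence time of an ion in the micelle, s.  Defaults to
        infinity, i.e. exchange does not shorten the micelle correlation
        time; see :func:`effective_tau_with_exchange`.
    """

    tau_m: float
    tau_c: float
    bulk_R1: float
    bulk_R2: float
    tau_res: float = math.inf

    def __post_init__(self) -> None:
        for name in ("tau_m", "tau_c", "bulk_R1", "bulk_R2", "tau_res"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def tau_m_effective(self) -> float:
        """Micelle correlation time shortened by exchange, if tau_res finite."""
        return effective_tau_with_exchange(self.tau_m, self.tau_res)


@dataclass(frozen=True)
class ExperimentCondition:
    """A (concentration, temperature) sample point."""

    concentration: float  # mM
    temperature: float  # K
    cmc: float = c.CMC_MM  # mM

    def __post_init__(self) -> None:
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")
        if self.cmc <= 0:
            raise ValueError("cmc must be positive")


@dataclass(frozen=True)
class DiffusionModel:
    """Translational diffusion of the exchange-averaged Na+ ensemble.

    The unrestricted diffusion coefficient of each aggregate species is the
    Stokes-Einstein value kT/(6 pi eta R) for a sphere of its hydrodynamic
    radius, reduced by a geometric obstruction factor 1/(1 + phi/2) where phi
    is the volume fraction of aggregate-bound surfactant (concentration above
    the CMC times a partial molar volume).  Free ions keep the measured bulk
    coefficient ``D_b``.
    """

    D_b: float  # bulk Na+ diffusion, m^2/s
    viscosity: float  # solvent viscosity at the sample temperature, Pa s
    R_micelle: float = c.MICELLE_RADIUS  # m
    R_cluster: float = c.CLUSTER_RADIUS  # m
    partial_molar_volume: float = c.PARTIAL_MOLAR_VOLUME  # m^3/mol

    def __post_init__(self) -> None:
        for name in ("D_b", "viscosity", "R_micelle", "R_cluster",
                     "partial_molar_volume"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def volume_fraction(self, cond: ExperimentCondition) -> float:
        """Volume fraction phi of aggregate-bound surfactant.

        mM converts to mol/m^3 one-to-one, so phi = v_bar * (C - CMC)+.
        """
        bound_conc = max(cond.concentration - cond.cmc, 0.0)  # mol/m^3
        phi = self.partial_molar_volume * bound_conc
        if phi >= 1.0:
            raise ValueError(f"volume fraction {phi:.3f} >= 1 is unphysical")
        return phi


# ---------------------------------------------------------------------------
# spectral densities
# ---------------------------------------------------------------------------

def _check_harmonic(n: int) -> None:
    if n not in (0, 1, 2):
        raise ValueError(f"harmonic n must be 0, 1 or 2, got {n!r}")


def lorentzian_spectral_density(tau: float, n: int, ctx: NucleusContext) -> float:
    """Single-correlation-time Lorentzian spectral density J(n w0).

    J(w) = 2 tau / (1 + (w tau)^2), evaluated at w = n * w0.  For n = 0 the
    value 2 tau is independent of the field; in the extreme-narrowing limit
    (w0 tau << 1) every harmonic approaches 2 tau.
    """
    _check_harmonic(n)
    if tau <= 0:
        raise ValueError(f"correlation time must be positive, got {tau}")
    w = n * ctx.angular_frequency * tau
    return 2.0 * tau / (1.0 + w * w)


def aggregate_spectral_density(fractions: SiteFractions, motion: SiteMotion,
                               n: int, ctx: NucleusContext) -> float:
    """Aggregate-site spectral density: micelle/cluster weighted Lorentzians.

    j_a = X_m J(tau_m) + X_c J(tau_c); reduces to the pure cluster density
    when X_m = 0 (below the CMC).
    """
    j_m = lorentzian_spectral_density(motion.tau_m_effective, n, ctx)
    j_c = lorentzian_spectral_density(motion.tau_c, n, ctx)
    return fractions.X_m * j_m + fractions.X_c * j_c


def bulk_spectral_density(motion: SiteMotion, n: int, ctx: NucleusContext,
                          chi: QuadrupolarCoupling) -> float:
    """Bulk spectral density back-computed from the measured reference rates.

    Free Na+ is close to extreme narrowing, so J1 = J2 is fixed by the
    measured bulk R1 and J0 absorbs the small measured R1/R2 difference:

        J1 = J2 = R1_bulk / (pi^2 chi^2)
        J0 = (10 R2_bulk / (pi^2 chi^2) - 7 J1) / 3

    Relaxation rates evaluated from these densities reproduce the measured
    bulk rates exactly, making the weighted three-site model consistent with
    the NaCl calibration without introducing a bulk correlation time.
    """
    _check_harmonic(n)
    chi2 = chi.chi * chi.chi
    j1 = motion.bulk_R1 / (math.pi**2 * chi2)
    if n in (1, 2):
        return j1
    return (10.0 * motion.bulk_R2 / (math.pi**2 * chi2) - 7.0 * j1) / 3.0


def total_spectral_density(fractions: SiteFractions, motion: SiteMotion,
                           n: int, ctx: NucleusContext,
                           chi: QuadrupolarCoupling) -> float:
    """Population-weighted spectral density of the exchanging ensemble.

    j_n = P_a j_a + P_b j_b; affine in P_a.
    """
    j_a = aggregate_spectral_density(fractions, motion, n, ctx)
    j_b = bulk_spectral_density(motion, n, ctx, chi)
    return fractions.P_a * j_a + fractions.P_b * j_b


# ---------------------------------------------------------------------------
# relaxation rates
# ---------------------------------------------------------------------------

def rates_from_spectral_densities(j0: float, j1: float, j2: float,
                                  chi: QuadrupolarCoupling) -> tuple[float, float]:
    """Spin-3/2 single-exponential (R1, R2) from the three spectral densities."""
    pref = c.RATE_PREFACTOR * chi.chi * chi.chi
    r1 = pref * (c.R1_WEIGHTS[1] * j1 + c.R1_WEIGHTS[2] * j2)
    r2 = pref * (c.R2_WEIGHTS[0] * j0 + c.R2_WEIGHTS[1] * j1 + c.R2_WEIGHTS[2] * j2)
    return r1, r2


def single_site_rates(tau: float, ctx: NucleusContext,
                      chi: QuadrupolarCoupling) -> tuple[float, float]:
    """(R1, R2) of a single site with one Lorentzian correlation time."""
    j = [lorentzian_spectral_density(tau, n, ctx) for n in (0, 1, 2)]
    return rates_from_spectral_densities(*j, chi)


def relaxation_rates(fractions: SiteFractions, motion: SiteMotion,
                     ctx: NucleusContext,
                     chi: QuadrupolarCoupling) -> tuple[float, float]:
    """Observed (R1, R2) of the fast-exchanging three-site ensemble.

    Equivalent to the additive decomposition
    ``R = P_a * R_aggregate + P_b * R_bulk_measured`` because the rates are
    linear in the spectral densities.
    """
    j = [total_spectral_density(fractions, motion, n, ctx, chi)
         for n in (0, 1, 2)]
    return rates_from_spectral_densities(*j, chi)


# ---------------------------------------------------------------------------
# correlation-time laws
# ---------------------------------------------------------------------------

def micelle_surfactant_fraction(cond: ExperimentCondition) -> float:
    """Fraction of surfactant in micelles, X_m = (C - CMC)/C, clamped at 0.

    Below the CMC there are no micelles and X_m = 0 exactly.
    """
    return max(0.0, (cond.concentration - cond.cmc) / cond.concentration)


def arrhenius_tau(A_m: float, E_m: float, T: float) -> float:
    """Micelle correlation time from the Arrhenius law for its inverse.

    tau_m(T) = [A_m exp(-E_m / (R T))]^-1 with A_m in s^-1 and E_m in J/mol.
    """
    if A_m <= 0 or T <= 0:
        raise ValueError("A_m and T must be positive")
    return math.exp(E_m / (c.GAS_CONSTANT * T)) / A_m


def tau_from_surface_diffusion(R: float, D_s: float) -> float:
    """Correlation time of diffusion on a spherical interface: R^2 / (6 D_s)."""
    if R <= 0 or D_s <= 0:
        raise ValueError("R and D_s must be positive")
    return R * R / (6.0 * D_s)


def effective_tau_with_exchange(tau_m: float, tau_res: float) -> float:
    """Harmonic combination of surface motion and micelle residence.

    1/tau_eff = 1/tau_m + 1/tau_res; the shorter timescale dominates.  With
    residence times orders of magnitude longer than tau_m the correction is
    negligible, which is why exchange is omitted from the default fits.
    """
    if tau_m <= 0 or tau_res <= 0:
        raise ValueError("tau_m and tau_res must be positive")
    if math.isinf(tau_res):
        return tau_m
    return 1.0 / (1.0 / tau_m + 1.0 / tau_res)


# ---------------------------------------------------------------------------
# translational diffusion
# ---------------------------------------------------------------------------

def stokes_einstein_diffusion(temperature: float, viscosity: float,
                              radius: float) -> float:
    """Unrestricted sphere diffusion D0 = kT / (6 pi eta R)."""
    if min(temperature, viscosity, radius) <= 0:
        raise ValueError("temperature, viscosity and radius must be positive")
    return c.BOLTZMANN * temperature / (6.0 * math.pi * viscosity * radius)


def obstruction_factor(phi: float) -> float:
    """Spherical-cell obstruction of diffusion by suspended aggregates.

    D/D0 = 1/(1 + phi/2); equals 1 exactly at phi = 0.
    """
    if not 0.0 <= phi < 1.0:
        raise ValueError(f"volume fraction must lie in [0, 1), got {phi}")
    return 1.0 / (1.0 + phi / 2.0)


def aggregate_diffusion(model: DiffusionModel, cond: ExperimentCondition,
                        fractions: SiteFractions) -> tuple[float, float]:
    """(D_a, D_eff): aggregate-site and exchange-averaged diffusion, m^2/s.

    D_a = X_m D_m^tr + X_c D_c with Stokes-Einstein sphere coefficients
    reduced by the obstruction factor, and D_eff = P_a D_a + P_b D_b.
    """
    phi = model.volume_fraction(cond)
    obst = obstruction_factor(phi)
    d_m = stokes_einstein_diffusion(cond.temperature, model.viscosity,
                                    model.R_micelle) * obst
    d_c = stokes_einstein_diffusion(cond.temperature, model.viscosity,
                                    model.R_cluster) * obst
    d_a = fractions.X_m * d_m + fractions.X_c * d_c
    d_eff = fractions.P_a * d_a + fractions.P_b * model.D_b
    return d_a, d_eff
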