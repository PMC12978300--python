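"""Physical constants and documented defaults for the sodium decanoate system.

All internal quantities are strict SI (s, Hz, m, K, Pa s). Interfaces that
accept field-friendly units (kHz couplings, Angstrom radii, mM concentrations)
convert exactly once on entry.

The default tables below encode the study conditions for aqueous sodium
decanoate in D2O: bulk reference rates measured on dilute NaCl, pentamer
cluster correlation times and micelle surface-diffusion coefficients taken
from molecular-dynamics estimates, and the geometry of the two aggregate
species (27.0 A micelle, 6.4 A pentamer cluster).
"""

from __future__ import annotations

import math

# -- fundamental constants ---------------------------------------------------
GAS_CONSTANT = 8.314  # J mol^-1 K^-1
BOLTZMANN = 1.380649e-23  # J K^-1

# 23Na gyromagnetic ratio, rad s^-1 T^-1
SODIUM_GAMMA = 7.0808493e7
# spin quantum number of 23Na
SODIUM_SPIN = 1.5

# -- spectrometer ------------------------------------------------------------
# 23Na Larmor frequency at 11.7 T (relaxation) and 14.1 T (diffusion)
LARMOR_RELAXATION_HZ = 132.0e6
LARMOR_DIFFUSION_HZ = 159.0e6

# -- spin-3/2 single-exponential rate convention -----------------------------
# R1 = (pi^2/10) chi^2 (2 J1 + 8 J2)
# R2 = (pi^2/10) chi^2 (3 J0 + 5 J1 + 2 J2)
# with the Lorentzian spectral density J(n w0) = 2 tau / (1 + (n w0 tau)^2).
# In extreme narrowing both rates reduce to 2 pi^2 chi^2 tau.  The effective
# coupling chi absorbs the asymmetry factor of the field gradient.
RATE_PREFACTOR = math.pi**2 / 10.0
R1_WEIGHTS = (0.0, 2.0, 8.0)  # weights of J0, J1, J2 in R1
R2_WEIGHTS = (3.0, 5.0, 2.0)  # weights of J0, J1, J2 in R2

# -- surfactant system defaults ---------------------------------------------
CMC_MM = 100.0  # critical micelle concentration, mM
MICELLE_RADIUS = 27.0e-10  # hydrodynamic micelle radius, m
CLUSTER_RADIUS = 6.4e-10  # pentamer cluster radius, m

# partial molar volume of decanoate used for the obstruction volume fraction,
# m^3 mol^-1 (0.19 L/mol)
PARTIAL_MOLAR_VOLUME = 0.19e-3

# pentamer-cluster correlation times from MD, s
TAU_C_BY_TEMPERATURE = {275.0: 0.42e-9, 283.0: 0.34e-9, 295.0: 0.29e-9}

# micelle surface-diffusion coefficients from MD MSD analysis, m^2/s
SURFACE_DIFFUSION_BY_TEMPERATURE = {275.0: 7.4e-10, 283.0: 9.1e-10, 295.0: 10.6e-10}

# D2O solvent viscosity, Pa s (literature values for heavy water; the solvent
# here is 99% D2O).  Only the 295 K entry enters the diffusion forward model
# because translational diffusion is measured at a single temperature.
VISCOSITY_D2O_BY_TEMPERATURE = {275.0: 2.18e-3, 283.0: 1.65e-3, 295.0: 1.18e-3}

# bulk Na+ diffusion coefficient measured on 10 mM NaCl at 295 K, m^2/s
BULK_DIFFUSION_295K = 10.7e-10

# measured bulk (10 mM NaCl) relaxation rates, s^-1, keyed by temperature
_BULK_MEASURED = {295.0: (22.1, 22.8), 283.0: (30.4, 31.0)}


def arrhenius_extrapolated_rate(rate_hi: float, t_hi: float, rate_lo: float,
                                t_lo: float, t: float) -> float:
    """Extrapolate a thermally activated rate to temperature ``t``.

    Fits ``rate = A exp(Ea / (R T))`` through two reference points (rates of
    slow-motion NMR relaxation grow on cooling, hence the positive exponent)
    and evaluates it at ``t``.
    """
    slope = math.log(rate_lo / rate_hi) / (1.0 / t_lo - 1.0 / t_hi)
    return rate_hi * math.exp(slope * (1.0 / t - 1.0 / t_hi))


def default_bulk_references() -> dict[float, tuple[float, float]]:
    """Bulk-reference (R1, R2) pairs per temperature, s^-1.

    295 K and 283 K are measured on dilute NaCl; the 275 K pair is an
    Arrhenius extrapolation of the two measured temperatures, since no
    low-temperature bulk measurement is available.
    """
    refs = dict(_BULK_MEASURED)
    r1 = arrhenius_extrapolated_rate(_BULK_MEASURED[295.0][0], 295.0,
                                     _BULK_MEASURED[283.0][0], 283.0, 275.0)
    r2 = arrhenius_extrapolated_rate(_BULK_MEASURED[295.0][1], 295.0,
                                     _BULK_MEASURED[283.0][1], 283.0, 275.0)
    refs[275.0] = (r1, r2)
    return refs


# default experimental grid: concentrations (mM) and temperatures (K)
CONCENTRATIONS_MM = (50.0, 300.0, 700.0)
TEMPERATURES_K = (275.0, 283.0, 295.0)
DIFFUSION_TEMPERATURE_K = 295.0

ANGSTROM = 1e-10
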