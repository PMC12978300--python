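"""Compiled Metropolis-Hastings kernel for the global relaxation fit.

The likelihood is evaluated millions of times per chain, so the forward
model is duplicated here in scalar numba-compiled form.  The Python-level
forward model in :mod:`naquad.inference` is the reference implementation;
a unit test pins the two paths against each other.

Row encoding (all arrays aligned with the dataset row order):

* ``obs_code``: 0 = R1, 1 = R2, 2 = D
* ``conc_idx``: index into the per-concentration P_a parameters
* ``temp_idx``: index into the unique-temperature arrays
* ``xm``: micelle share X_m of the row's concentration
* ``tauc``: cluster correlation time at the row's temperature, s
* ``bulk``: measured bulk value of the row's observable (rate or D)
* ``da``: parameter-independent aggregate diffusion D_a for D rows, else 0

Parameter vectors:

* model 1: ``[A_m, E_m, P_a(1..n_conc), chi]`` (Arrhenius micelle time)
* model 2: ``[R_m, P_a(1..n_conc), chi]`` (fixed surface diffusion per T)
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_GAS = 8.314
_PREF = math.pi**2 / 10.0


@njit(cache=True)
def _site_rates(tau: float, omega0: float) -> tuple[float, float]:
    """Spin-3/2 (R1, R2)/chi^2 of a single Lorentzian site (prefactor included)."""
    j0 = 2.0 * tau
    w1 = omega0 * tau
    w2 = 2.0 * omega0 * tau
    j1 = 2.0 * tau / (1.0 + w1 * w1)
    j2 = 2.0 * tau / (1.0 + w2 * w2)
    r1 = _PREF * (2.0 * j1 + 8.0 * j2)
    r2 = _PREF * (3.0 * j0 + 5.0 * j1 + 2.0 * j2)
    return r1, r2


@njit(cache=True)
def loglik(model_id, theta, omega0,
           obs_code, conc_idx, temp_idx, xm, tauc, bulk, da,
           y, sig, temps, d_surf, d_bulk):
    """Gaussian log-likelihood of one parameter vector (bounds not checked)."""
    n_temps = temps.size
    tau_m = np.empty(n_temps)
    if model_id == 1:
        a_m = theta[0]
        e_m = theta[1]
        chi = theta[theta.size - 1]
        pa_off = 2
        for k in range(n_temps):
            tau_m[k] = math.exp(e_m / (_GAS * temps[k])) / a_m
    else:
        r_m = theta[0]
        chi = theta[theta.size - 1]
        pa_off = 1
        for k in range(n_temps):
            tau_m[k] = r_m * r_m / (6.0 * d_surf[k])
    chi2 = chi * chi
    ll = 0.0
    for r in range(y.size):
        p_a = theta[pa_off + conc_idx[r]]
        if obs_code[r] == 2:
            m = p_a * da[r] + (1.0 - p_a) * d_bulk
        else:
            tm = tau_m[temp_idx[r]]
            r1m, r2m = _site_rates(tm, omega0)
            r1c, r2c = _site_rates(tauc[r], omega0)
            if obs_code[r] == 0:
                r_agg = chi2 * (xm[r] * r1m + (1.0 - xm[r]) * r1c)
            else:
                r_agg = chi2 * (xm[r] * r2m + (1.0 - xm[r]) * r2c)
            m = p_a * r_agg + (1.0 - p_a) * bulk[r]
        z = (y[r] - m) / sig[r]
        ll += -0.5 * z * z - math.log(sig[r])
    ll -= 0.5 * y.size * math.log(2.0 * math.pi)
    return ll


@njit(cache=True)
def run_chain(model_id, theta0, lo, hi, scales0, n_sweeps, n_burn,
              tune_interval, seed, omega0,
              obs_code, conc_idx, temp_idx, xm, tauc, bulk, da,
              y, sig, temps, d_surf, d_bulk):
    """Componentwise Metropolis-Hastings with burn-in scale adaptation.

    One sweep updates every component once with a Gaussian proposal; priors
    are uniform on [lo, hi].  During burn-in each proposal scale is adjusted
    every ``tune_interval`` sweeps toward ~30% acceptance.  Returns the full
    chain (n_sweeps, k), the post-burn-in acceptance rate per component, and
    the final scales.
    """
    np.random.seed(seed)
    k = theta0.size
    theta = theta0.copy()
    scales = scales0.copy()
    chain = np.empty((n_sweeps, k))
    acc_post = np.zeros(k)
    acc_window = np.zeros(k)
    ll = loglik(model_id, theta, omega0, obs_code, conc_idx, temp_idx, xm,
                tauc, bulk, da, y, sig, temps, d_surf, d_bulk)
    for s in range(n_sweeps):
        for i in range(k):
            old = theta[i]
            theta[i] = old + scales[i] * np.random.normal()
            if theta[i] < lo[i] or theta[i] > hi[i]:
                theta[i] = old
                continue
            ll_new = loglik(model_id, theta, omega0, obs_code, conc_idx,
                            temp_idx, xm, tauc, bulk, da, y, sig, temps,
                            d_surf, d_bulk)
            if math.log(np.random.random()) < ll_new - ll:
                ll = ll_new
                acc_window[i] += 1.0
                if s >= n_burn:
                    acc_post[i] += 1.0
            else:
                theta[i] = old
        chain[s] = theta
        if s < n_burn and (s + 1) % tune_interval == 0:
            for i in range(k):
                rate = acc_window[i] / tune_interval
                scales[i] *= math.exp(1.5 * (rate - 0.3))
                upper = 0.5 * (hi[i] - lo[i])
                if scales[i] > upper:
                    scales[i] = upper
                acc_window[i] = 0.0
        elif (s + 1) % tune_interval == 0:
            for i in range(k):
                acc_window[i] = 0.0
    n_post = n_sweeps - n_burn
    for i in range(k):
        acc_post[i] /= n_post
    return chain, acc_post, scales
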