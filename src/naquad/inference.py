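"""Global MCMC fit of the three-site relaxation/diffusion model.

Two parameterizations of the micelle correlation time are fitted to a grid
of R1/R2 (all temperatures) and D (one temperature) observations:

* **model 1** — tau_m follows an Arrhenius law, adjustable pre-exponential
  factor A_m and activation energy E_m (6 free parameters for three
  concentrations: A_m, E_m, one aggregate fraction P_a per concentration,
  and the quadrupolar coupling chi);
* **model 2** — tau_m = R_m^2 / (6 D_s(T)) with the surface-diffusion
  coefficients D_s fixed at their MD estimates and a single shared radius
  R_m adjustable (5 free parameters).

The sampler is a componentwise Metropolis-Hastings chain with uniform priors
on explicit bounds, proposal scales auto-tuned during burn-in, and central
99% credible intervals taken from the post-burn-in chain.  A compiled kernel
(:mod:`naquad._mh`) carries the hot loop; the Python-level forward model here
is the reference the kernel is tested against.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from . import constants as c
from . import _mh
from .relaxation_core import (DiffusionModel, ExperimentCondition,
                              NucleusContext, QuadrupolarCoupling,
                              SiteFractions, SiteMotion, aggregate_diffusion,
                              arrhenius_tau, micelle_surfactant_fraction,
                              relaxation_rates, tau_from_surface_diffusion)

__all__ = [
    "RelaxationDataset",
    "Model1Params",
    "Model2Params",
    "ParameterBounds",
    "MCMCSettings",
    "PosteriorSummary",
    "forward_model",
    "log_likelihood",
    "mcmc_fit",
    "site_fraction_table",
    "split_rhat",
]

ModelName = Literal["model1", "model2"]

OBSERVABLES = ("R1", "R2", "D")
_OBS_CODE = {"R1": 0, "R2": 1, "D": 2}


def _normalize_model(model: Union[ModelName, int]) -> ModelName:
    if model in ("model1", 1):
        return "model1"
    if model in ("model2", 2):
        return "model2"
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# dataset
# ---------------------------------------------------------------------------

@dataclass
class RelaxationDataset:
    """Observed relaxation/diffusion grid plus the fixed calibrations.

    ``observations`` columns: concentration_mM, temperature_K, observable
    (R1 | R2 | D, rates in s^-1, D in m^2/s), value, sigma.  The fixed
    ingredients of the forward model travel with the dataset: measured bulk
    references per temperature, MD cluster correlation times, MD surface
    diffusion coefficients (model 2), the CMC, and the solvent viscosity
    used for Stokes-Einstein aggregate diffusion.
    """

    observations: pd.DataFrame
    bulk_references: Mapping[float, tuple[float, float]] = field(
        default_factory=c.default_bulk_references)
    bulk_diffusion: Mapping[float, float] = field(
        default_factory=lambda: {c.DIFFUSION_TEMPERATURE_K: c.BULK_DIFFUSION_295K})
    tau_c: Mapping[float, float] = field(
        default_factory=lambda: dict(c.TAU_C_BY_TEMPERATURE))
    surface_diffusion: Mapping[float, float] = field(
        default_factory=lambda: dict(c.SURFACE_DIFFUSION_BY_TEMPERATURE))
    viscosity: Mapping[float, float] = field(
        default_factory=lambda: dict(c.VISCOSITY_D2O_BY_TEMPERATURE))
    cmc: float = c.CMC_MM
    micelle_radius: float = c.MICELLE_RADIUS
    cluster_radius: float = c.CLUSTER_RADIUS
    partial_molar_volume: float = c.PARTIAL_MOLAR_VOLUME
    larmor_frequency: float = c.LARMOR_RELAXATION_HZ
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        df = self.observations
        required = {"concentration_mM", "temperature_K", "observable",
                    "value", "sigma"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"observations missing columns {sorted(missing)}")
        if not set(df["observable"]).issubset(OBSERVABLES):
            raise ValueError("observable must be one of R1, R2, D")
        if (df["sigma"] <= 0).any():
            raise ValueError("all sigma must be positive")
        if len(self.concentrations) < 2:
            raise ValueError("need at least 2 concentrations for a global fit")
        for (conc, temp), grp in df[df["observable"] != "D"].groupby(
                ["concentration_mM", "temperature_K"]):
            if not {"R1", "R2"}.issubset(set(grp["observable"])):
                raise ValueError(
                    f"({conc} mM, {temp} K) lacks an R1/R2 pair")
        for temp in df.loc[df["observable"] != "D", "temperature_K"].unique():
            if float(temp) not in self.bulk_references:
                raise ValueError(f"no bulk reference rates at {temp} K")
            if float(temp) not in self.tau_c:
                raise ValueError(f"no cluster correlation time at {temp} K")

    @property
    def concentrations(self) -> tuple[float, ...]:
        return tuple(sorted(self.observations["concentration_mM"].unique()))

    @property
    def temperatures(self) -> tuple[float, ...]:
        return tuple(sorted(self.observations["temperature_K"].unique()))

    @property
    def nucleus(self) -> NucleusContext:
        return NucleusContext(larmor_frequency=self.larmor_frequency)

    def diffusion_model(self, temperature: float) -> DiffusionModel:
        return DiffusionModel(D_b=self.bulk_diffusion[temperature],
                              viscosity=self.viscosity[temperature],
                              R_micelle=self.micelle_radius,
                              R_cluster=self.cluster_radius,
                              partial_molar_volume=self.partial_molar_volume)

    def to_csv(self, path: str | Path, header_comment: str | None = None) -> None:
        with open(path, "w") as fh:
            if header_comment:
                fh.write(f"# {header_comment}\n")
            self.observations.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, **kwargs) -> "RelaxationDataset":
        df = pd.read_csv(path, comment="#")
        return cls(observations=df, **kwargs)


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Model1Params:
    """Arrhenius parameterization: A_m (s^-1), E_m (J/mol), P_a per
    concentration (temperature independent), chi (Hz)."""

    A_m: float
    E_m: float
    P_a: Mapping[float, float]
    chi: float

    def tau_m(self, temperature: float) -> float:
        return arrhenius_tau(self.A_m, self.E_m, temperature)

    def to_theta(self, concentrations: Sequence[float]) -> np.ndarray:
        return np.array([self.A_m, self.E_m,
                         *[self.P_a[cc] for cc in concentrations], self.chi])

    @classmethod
    def from_theta(cls, theta: np.ndarray,
                   concentrations: Sequence[float]) -> "Model1Params":
        return cls(A_m=theta[0], E_m=theta[1],
                   P_a={cc: theta[2 + i] for i, cc in enumerate(concentrations)},
                   chi=theta[-1])


@dataclass(frozen=True)
class Model2Params:
    """Surface-diffusion parameterization: shared radius R_m (m), P_a per
    concentration, chi (Hz); D_s(T) is fixed data, not a parameter."""

    R_m: float
    P_a: Mapping[float, float]
    chi: float

    def tau_m(self, temperature: float,
              surface_diffusion: Mapping[float, float]) -> float:
        return tau_from_surface_diffusion(self.R_m,
                                          surface_diffusion[temperature])

    def to_theta(self, concentrations: Sequence[float]) -> np.ndarray:
        return np.array([self.R_m,
                         *[self.P_a[cc] for cc in concentrations], self.chi])

    @classmethod
    def from_theta(cls, theta: np.ndarray,
                   concentrations: Sequence[float]) -> "Model2Params":
        return cls(R_m=theta[0],
                   P_a={cc: theta[1 + i] for i, cc in enumerate(concentrations)},
                   chi=theta[-1])


@dataclass(frozen=True)
class ParameterBounds:
    """Uniform-prior support.  Defaults: broad physical ranges for A_m, E_m
    and R_m; the coupling constrained to the literature window 99-119 kHz."""

    A_m: tuple[float, float] = (1e10, 1e16)  # s^-1
    E_m: tuple[float, float] = (5e3, 60e3)  # J/mol
    P_a: tuple[float, float] = (0.0, 1.0)
    chi: tuple[float, float] = (99e3, 119e3)  # Hz
    R_m: tuple[float, float] = (5e-10, 27e-10)  # m

    def arrays(self, model: ModelName,
               n_conc: int) -> tuple[np.ndarray, np.ndarray]:
        if model == "model1":
            pairs = [self.A_m, self.E_m] + [self.P_a] * n_conc + [self.chi]
        else:
            pairs = [self.R_m] + [self.P_a] * n_conc + [self.chi]
        lo, hi = zip(*pairs)
        return np.array(lo), np.array(hi)


# ---------------------------------------------------------------------------
# forward model and likelihood
# ---------------------------------------------------------------------------

def _tau_m_by_temperature(params, dataset: RelaxationDataset) -> dict[float, float]:
    if isinstance(params, Model1Params):
        return {t: params.tau_m(t) for t in dataset.temperatures}
    return {t: params.tau_m(t, dataset.surface_diffusion)
            for t in dataset.temperatures}


def forward_model(params: Union[Model1Params, Model2Params],
                  dataset: RelaxationDataset) -> np.ndarray:
    """Model values for every observation row, in dataset row order."""
    ctx = dataset.nucleus
    chi = QuadrupolarCoupling(params.chi)
    tau_m = _tau_m_by_temperature(params, dataset)
    out = np.empty(len(dataset.observations))
    for k, row in enumerate(dataset.observations.itertuples(index=False)):
        conc = float(row.concentration_mM)
        temp = float(row.temperature_K)
        cond = ExperimentCondition(concentration=conc, temperature=temp,
                                   cmc=dataset.cmc)
        fractions = SiteFractions(P_a=params.P_a[conc],
                                  X_m=micelle_surfactant_fraction(cond))
        if row.observable == "D":
            _, d_eff = aggregate_diffusion(dataset.diffusion_model(temp),
                                           cond, fractions)
            out[k] = d_eff
        else:
            r1b, r2b = dataset.bulk_references[temp]
            motion = SiteMotion(tau_m=tau_m[temp], tau_c=dataset.tau_c[temp],
                                bulk_R1=r1b, bulk_R2=r2b)
            r1, r2 = relaxation_rates(fractions, motion, ctx, chi)
            out[k] = r1 if row.observable == "R1" else r2
    return out


def log_likelihood(params: Union[Model1Params, Model2Params],
                   dataset: RelaxationDataset,
                   bounds: Optional[ParameterBounds] = None) -> float:
    """Gaussian log-likelihood; -inf outside the uniform prior bounds."""
    bounds = bounds or ParameterBounds()
    model: ModelName = ("model1" if isinstance(params, Model1Params)
                        else "model2")
    concs = dataset.concentrations
    theta = params.to_theta(concs)
    lo, hi = bounds.arrays(model, len(concs))
    if np.any(theta < lo) or np.any(theta > hi):
        return -math.inf
    y = dataset.observations["value"].to_numpy(float)
    sig = dataset.observations["sigma"].to_numpy(float)
    m = forward_model(params, dataset)
    return float(-0.5 * np.sum(((y - m) / sig) ** 2) - np.sum(np.log(sig))
                 - 0.5 * y.size * math.log(2.0 * math.pi))


def _prepare_arrays(dataset: RelaxationDataset) -> dict[str, np.ndarray]:
    """Flatten the dataset into the kernel's row encoding."""
    df = dataset.observations
    concs = dataset.concentrations
    temps = np.array(dataset.temperatures)
    conc_index = {cc: i for i, cc in enumerate(concs)}
    temp_index = {t: i for i, t in enumerate(temps)}
    n = len(df)
    obs_code = np.empty(n, np.int64)
    conc_idx = np.empty(n, np.int64)
    temp_idx = np.empty(n, np.int64)
    xm = np.empty(n)
    tauc = np.empty(n)
    bulk = np.zeros(n)
    da = np.zeros(n)
    d_bulk = 0.0
    for k, row in enumerate(df.itertuples(index=False)):
        conc = float(row.concentration_mM)
        temp = float(row.temperature_K)
        cond = ExperimentCondition(concentration=conc, temperature=temp,
                                   cmc=dataset.cmc)
        obs_code[k] = _OBS_CODE[row.observable]
        conc_idx[k] = conc_index[conc]
        temp_idx[k] = temp_index[temp]
        x = micelle_surfactant_fraction(cond)
        xm[k] = x
        if row.observable == "D":
            # D_a is independent of the fit parameters: precompute it
            dm = dataset.diffusion_model(temp)
            d_a, _ = aggregate_diffusion(dm, cond, SiteFractions(P_a=1.0, X_m=x))
            da[k] = d_a
            d_bulk = dm.D_b
            tauc[k] = 1.0  # unused
        else:
            tauc[k] = dataset.tau_c[temp]
            r1b, r2b = dataset.bulk_references[temp]
            bulk[k] = r1b if row.observable == "R1" else r2b
    d_surf = np.array([dataset.surface_diffusion.get(float(t), np.nan)
                       for t in temps])
    return dict(obs_code=obs_code, conc_idx=conc_idx, temp_idx=temp_idx,
                xm=xm, tauc=tauc, bulk=bulk, da=da,
                y=df["value"].to_numpy(float),
                sig=df["sigma"].to_numpy(float),
                temps=temps, d_surf=d_surf, d_bulk=d_bulk)


def _kernel_loglik(model: ModelName, theta: np.ndarray,
                   dataset: RelaxationDataset) -> float:
    """Compiled-path log-likelihood (exposed for the consistency test)."""
    arr = _prepare_arrays(dataset)
    omega0 = dataset.nucleus.angular_frequency
    return float(_mh.loglik(1 if model == "model1" else 2, theta, omega0,
                            arr["obs_code"], arr["conc_idx"], arr["temp_idx"],
                            arr["xm"], arr["tauc"], arr["bulk"], arr["da"],
                            arr["y"], arr["sig"], arr["temps"],
                            arr["d_surf"], arr["d_bulk"]))


# ---------------------------------------------------------------------------
# sampler front end
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MCMCSettings:
    """Sampler configuration.  ``seed`` is mandatory for reproducibility."""

    seed: int
    n_steps: int = 200_000
    burn_in_fraction: float = 0.2
    tune_interval: int = 500
    proposal_scales: Optional[np.ndarray] = None

    @property
    def n_burn(self) -> int:
        return int(self.n_steps * self.burn_in_fraction)


@dataclass
class PosteriorSummary:
    """Post-burn-in chains with means, 99% credible intervals and diagnostics."""

    model: ModelName
    param_names: list[str]
    chain: np.ndarray  # full chain, (n_steps, k)
    n_burn: int
    acceptance_rate: dict[str, float]
    seed: int
    concentrations: tuple[float, ...]
    temperatures: tuple[float, ...]
    surface_diffusion: dict[float, float]

    def __post_init__(self) -> None:
        post = self.posterior_chain
        self.means = {p: float(post[:, i].mean())
                      for i, p in enumerate(self.param_names)}
        self.ci99 = {p: tuple(np.percentile(post[:, i], [0.5, 99.5]))
                     for i, p in enumerate(self.param_names)}
        self.rhat = {p: split_rhat(post[:, i])
                     for i, p in enumerate(self.param_names)}

    @property
    def posterior_chain(self) -> np.ndarray:
        return self.chain[self.n_burn:]

    def parameter_samples(self, name: str) -> np.ndarray:
        return self.posterior_chain[:, self.param_names.index(name)]

    def tau_m_summary(self) -> pd.DataFrame:
        """Posterior mean and 99% CI of tau_m at each temperature (ns)."""
        rows = []
        for t in self.temperatures:
            if self.model == "model1":
                a = self.parameter_samples("A_m")
                e = self.parameter_samples("E_m")
                tau = np.exp(e / (c.GAS_CONSTANT * t)) / a
            else:
                r = self.parameter_samples("R_m")
                tau = r * r / (6.0 * self.surface_diffusion[t])
            lo, hi = np.percentile(tau, [0.5, 99.5])
            rows.append({"temperature_K": t, "tau_m_ns": tau.mean() * 1e9,
                         "ci99_lo_ns": lo * 1e9, "ci99_hi_ns": hi * 1e9})
        return pd.DataFrame(rows)

    def boundary_proximity(self, bounds: ParameterBounds) -> dict[str, float]:
        """Distance of each posterior mean to its nearest bound, in posterior
        standard deviations.  Small values flag a posterior piled on its
        prior edge."""
        out = {}
        lo, hi = bounds.arrays(self.model, len(self.concentrations))
        post = self.posterior_chain
        for i, p in enumerate(self.param_names):
            sd = post[:, i].std()
            if sd == 0:
                out[p] = 0.0
                continue
            out[p] = float(min(self.means[p] - lo[i], hi[i] - self.means[p]) / sd)
        return out

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "seed": self.seed,
            "parameters": self.param_names,
            "means": self.means,
            "ci99": {k: list(v) for k, v in self.ci99.items()},
            "rhat": self.rhat,
            "acceptance_rate": self.acceptance_rate,
            "tau_m": self.tau_m_summary().to_dict(orient="records"),
        }

    def save_json(self, path: str | Path, extra: Optional[dict] = None) -> None:
        payload = self.to_dict()
        if extra:
            payload.update(extra)
        Path(path).write_text(json.dumps(payload, indent=2))


def split_rhat(samples: np.ndarray, n_splits: int = 4) -> float:
    """Split-chain potential scale reduction factor on a single chain.

    The chain is cut into ``n_splits`` contiguous segments that are treated
    as independent chains in the classic between/within variance ratio.
    Values near 1 indicate the segments agree; > 1.1 flags poor mixing.
    """
    n = samples.size // n_splits
    if n < 2:
        return float("nan")
    segs = samples[: n * n_splits].reshape(n_splits, n)
    w = segs.var(axis=1, ddof=1).mean()
    b = n * segs.mean(axis=1).var(ddof=1)
    if w == 0:
        return 1.0
    return float(math.sqrt((n - 1) / n + b / (n * w)))


def _param_names(model: ModelName, concentrations: Sequence[float]) -> list[str]:
    pa = [f"P_a_{int(cc)}mM" for cc in concentrations]
    if model == "model1":
        return ["A_m", "E_m", *pa, "chi"]
    return ["R_m", *pa, "chi"]


def _least_squares_start(model: ModelName, dataset: RelaxationDataset,
                         bounds: ParameterBounds) -> np.ndarray:
    """Deterministic bounded least-squares initialization of the chain."""
    concs = dataset.concentrations
    lo, hi = bounds.arrays(model, len(concs))
    if model == "model1":
        x0 = np.array([1e13, 20e3, *[0.3] * len(concs), 110e3])
        scale = np.array([1e13, 1e4, *[1.0] * len(concs), 1e5])
    else:
        x0 = np.array([15e-10, *[0.3] * len(concs), 110e3])
        scale = np.array([1e-9, *[1.0] * len(concs), 1e5])
    y = dataset.observations["value"].to_numpy(float)
    sig = dataset.observations["sigma"].to_numpy(float)
    make = Model1Params.from_theta if model == "model1" else Model2Params.from_theta

    def resid(theta):
        return (forward_model(make(theta, concs), dataset) - y) / sig

    eps = 1e-9 * (hi - lo)
    fit = least_squares(resid, x0, bounds=(lo + eps, hi - eps),
                        x_scale=scale, method="trf")
    return fit.x


def mcmc_fit(dataset: RelaxationDataset, model: Union[ModelName, int],
             settings: MCMCSettings,
             bounds: Optional[ParameterBounds] = None) -> PosteriorSummary:
    """Run the global Metropolis-Hastings fit and summarize the posterior.

    The chain starts from a deterministic bounded least-squares solution,
    adapts its componentwise proposal scales during the burn-in, and is
    bit-reproducible under a fixed :class:`MCMCSettings` seed.  Warnings are
    emitted for acceptance rates outside [0.05, 0.7] and split-chain
    R-hat > 1.1.
    """
    model = _normalize_model(model)
    bounds = bounds or ParameterBounds()
    concs = dataset.concentrations
    names = _param_names(model, concs)
    theta0 = _least_squares_start(model, dataset, bounds)
    lo, hi = bounds.arrays(model, len(concs))
    if settings.proposal_scales is not None:
        scales0 = np.asarray(settings.proposal_scales, dtype=float)
    else:
        scales0 = 0.05 * np.abs(theta0) + 1e-9 * (hi - lo)
    arr = _prepare_arrays(dataset)
    omega0 = dataset.nucleus.angular_frequency
    chain, acc, _ = _mh.run_chain(
        1 if model == "model1" else 2, theta0, lo, hi, scales0,
        settings.n_steps, settings.n_burn, settings.tune_interval,
        settings.seed % (2**31), omega0,
        arr["obs_code"], arr["conc_idx"], arr["temp_idx"], arr["xm"],
        arr["tauc"], arr["bulk"], arr["da"], arr["y"], arr["sig"],
        arr["temps"], arr["d_surf"], arr["d_bulk"])
    summary = PosteriorSummary(
        model=model, param_names=names, chain=chain, n_burn=settings.n_burn,
        acceptance_rate={p: float(a) for p, a in zip(names, acc)},
        seed=settings.seed, concentrations=concs,
        temperatures=dataset.temperatures,
        surface_diffusion={float(k): float(v)
                           for k, v in dataset.surface_diffusion.items()})
    for p, a in summary.acceptance_rate.items():
        if not 0.05 <= a <= 0.7:
            warnings.warn(f"acceptance rate {a:.2f} for {p} outside [0.05, 0.7]",
                          stacklevel=2)
    for p, r in summary.rhat.items():
        if r > 1.1:
            warnings.warn(f"split-chain R-hat {r:.3f} for {p} exceeds 1.1",
                          stacklevel=2)
    return summary


def site_fraction_table(posterior: PosteriorSummary,
                        dataset: RelaxationDataset) -> pd.DataFrame:
    """Site populations per concentration with 99% credible intervals.

    Columns: micelle (X_m P_a), cluster (X_c P_a), bulk (P_b), each with
    [lo, hi] 99% bounds.  X_m is fixed by the concentration bookkeeping
    X_m = (C - CMC)/C, so every row sums to one exactly.
    """
    rows = []
    for cc in posterior.concentrations:
        cond = ExperimentCondition(concentration=cc, temperature=295.0,
                                   cmc=dataset.cmc)
        xm = micelle_surfactant_fraction(cond)
        pa = posterior.parameter_samples(f"P_a_{int(cc)}mM")
        entry = {"concentration_mM": cc}
        for label, samples in (("micelle", xm * pa),
                               ("cluster", (1.0 - xm) * pa),
                               ("bulk", 1.0 - pa)):
            lo, hi = np.percentile(samples, [0.5, 99.5])
            entry[label] = float(samples.mean())
            entry[f"{label}_ci99_lo"] = float(lo)
            entry[f"{label}_ci99_hi"] = float(hi)
        rows.append(entry)
    return pd.DataFrame(rows)
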