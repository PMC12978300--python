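"""Synthetic data with known ground truth for every pipeline stage.

The generators stand in for the spectrometer and the MD engine: noisy
relaxation/diffusion grids from the three-site forward model, raw decay
curves on the experimental acquisition grids, and ion trajectories (surface
random walks and two-state exchange) whose generating parameters are known
exactly.  Every generator is deterministic under its seed and records its
ground truth in the output metadata, so estimator round trips can be tested
without any external data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd

from . import constants as c
from .exp_reduction import CurveKind, DecayCurve, stejskal_tanner_b
from .inference import (Model1Params, Model2Params, RelaxationDataset,
                        forward_model)
from .md_analysis import IonTrajectory
from .relaxation_core import NucleusContext

__all__ = [
    "GroundTruth",
    "TrajectorySpec",
    "default_model1_truth",
    "default_model2_truth",
    "generate_dataset",
    "generate_decay_curves",
    "generate_sphere_walk",
    "generate_exchange_trajectory",
    "censored_mean_estimate",
]


# ---------------------------------------------------------------------------
# relaxation/diffusion datasets
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruth:
    """Generating parameters for a synthetic relaxation/diffusion grid.

    ``params`` is a fitted-parameter object (either micelle-time law); the
    measurement grid defaults to the experimental design of the study:
    R1/R2 at three concentrations and three temperatures, D at 295 K only,
    with 2% relative Gaussian noise.
    """

    params: Union[Model1Params, Model2Params]
    noise_level: float = 0.02
    seed: int = 0
    concentrations: tuple[float, ...] = c.CONCENTRATIONS_MM
    temperatures: tuple[float, ...] = c.TEMPERATURES_K
    diffusion_temperature: float = c.DIFFUSION_TEMPERATURE_K

    @property
    def model(self) -> str:
        return "model1" if isinstance(self.params, Model1Params) else "model2"


def default_model1_truth(noise_level: float = 0.02, seed: int = 0) -> GroundTruth:
    """Arrhenius-law truth at the study's fitted values.

    A_m = 1.6e13 s^-1, E_m = 20.9 kJ/mol (tau_m = 0.59/0.46/0.32 ns at
    275/283/295 K), chi = 117 kHz, aggregate fractions P_a = 0.03/0.38/0.59
    at 50/300/700 mM.
    """
    params = Model1Params(A_m=1.6e13, E_m=20.9e3,
                          P_a={50.0: 0.03, 300.0: 0.38, 700.0: 0.59},
                          chi=117.0e3)
    return GroundTruth(params=params, noise_level=noise_level, seed=seed)


def default_model2_truth(noise_level: float = 0.02, seed: int = 0) -> GroundTruth:
    """Surface-diffusion truth: R_m = 14.5 A, chi = 117 kHz,
    P_a = 0.03/0.37/0.57 at 50/300/700 mM."""
    params = Model2Params(R_m=14.5e-10,
                          P_a={50.0: 0.03, 300.0: 0.37, 700.0: 0.57},
                          chi=117.0e3)
    return GroundTruth(params=params, noise_level=noise_level, seed=seed)


def _grid_rows(truth: GroundTruth) -> pd.DataFrame:
    rows = []
    for cc in truth.concentrations:
        for tt in truth.temperatures:
            for obs in ("R1", "R2"):
                rows.append({"concentration_mM": cc, "temperature_K": tt,
                             "observable": obs})
        rows.append({"concentration_mM": cc,
                     "temperature_K": truth.diffusion_temperature,
                     "observable": "D"})
    return pd.DataFrame(rows)


def generate_dataset(truth: GroundTruth, **dataset_kwargs) -> RelaxationDataset:
    """Forward-model grid plus relative Gaussian noise at ``truth.noise_level``.

    ``sigma`` columns carry the noise level times the noiseless model value.
    At zero noise the dataset equals the forward model exactly (sigma then
    falls back to 2% for likelihood weighting).  The ground truth is stored
    in ``dataset.meta``.
    """
    rng = np.random.default_rng(truth.seed)
    df = _grid_rows(truth)
    df["value"] = 0.0
    sigma_level = truth.noise_level if truth.noise_level > 0 else 0.02
    df["sigma"] = 1.0
    dataset = RelaxationDataset(observations=df, **dataset_kwargs)
    clean = forward_model(truth.params, dataset)
    noise = rng.standard_normal(clean.size) * truth.noise_level * np.abs(clean)
    df = dataset.observations
    df["value"] = clean + noise
    df["sigma"] = sigma_level * np.abs(clean)
    dataset.meta.update({"model": truth.model, "seed": truth.seed,
                         "noise_level": truth.noise_level,
                         "truth": truth.params})
    return dataset


# ---------------------------------------------------------------------------
# decay curves on the experimental acquisition grids
# ---------------------------------------------------------------------------

# inversion recovery: 8 log-spaced delays over 1 ms .. 0.5 s
IR_DELAYS = np.logspace(math.log10(0.001), math.log10(0.5), 8)
# CPMG: echo spacing 0.49 ms, echo counts log-spaced over 2 .. 400
CPMG_ECHO_TIME = 0.49e-3
CPMG_ECHO_COUNTS = np.unique(np.rint(
    np.logspace(math.log10(2), math.log10(400), 8)).astype(int))
# PGSTE: 16 gradient steps up to 0.70 T/m (70 G/cm)
PGSTE_GRADIENTS = np.linspace(0.0, 0.70, 16)
PGSTE_DELTA = 2e-3  # gradient pulse, s
PGSTE_BIG_DELTA = 16e-3  # diffusion delay, s
# emulated inversion efficiency: a realistic, slightly imperfect 180 pulse
IR_EFFICIENCY = 0.95


def generate_decay_curves(truth: GroundTruth,
                          ctx: Optional[NucleusContext] = None,
                          **dataset_kwargs) -> dict[tuple, DecayCurve]:
    """Raw decay curves for every grid point of the ground truth.

    Returns a dict keyed by (kind, concentration_mM, temperature_K).
    Inversion-recovery and CPMG curves are generated at every concentration
    and temperature from the forward-model R1/R2; Stejskal-Tanner ramps at
    the diffusion temperature from the forward-model D.  Gaussian noise of
    ``truth.noise_level`` times the signal amplitude is added.
    """
    ctx = ctx or NucleusContext()
    rng = np.random.default_rng(truth.seed + 1)
    clean_truth = GroundTruth(params=truth.params, noise_level=0.0,
                              seed=truth.seed,
                              concentrations=truth.concentrations,
                              temperatures=truth.temperatures,
                              diffusion_temperature=truth.diffusion_temperature)
    ds = generate_dataset(clean_truth, **dataset_kwargs)
    df = ds.observations
    curves: dict[tuple, DecayCurve] = {}
    for row in df.itertuples(index=False):
        key_ct = (float(row.concentration_mM), float(row.temperature_K))
        if row.observable == "R1":
            signal = 1.0 - 2.0 * IR_EFFICIENCY * np.exp(-row.value * IR_DELAYS)
            signal = signal + rng.standard_normal(signal.size) * truth.noise_level
            curves[("inversion_recovery", *key_ct)] = DecayCurve(
                kind=CurveKind.INVERSION_RECOVERY, abscissa=IR_DELAYS.copy(),
                signal=signal)
        elif row.observable == "R2":
            t = CPMG_ECHO_COUNTS * CPMG_ECHO_TIME
            signal = np.exp(-row.value * t)
            signal = signal + rng.standard_normal(signal.size) * truth.noise_level
            curves[("cpmg", *key_ct)] = DecayCurve(
                kind=CurveKind.CPMG, abscissa=t, signal=signal)
        else:
            b = stejskal_tanner_b(PGSTE_GRADIENTS, PGSTE_DELTA,
                                  PGSTE_BIG_DELTA, ctx.gyromagnetic_ratio)
            signal = np.exp(-row.value * b)
            signal = signal + rng.standard_normal(signal.size) * truth.noise_level
            curves[("pgste", *key_ct)] = DecayCurve(
                kind=CurveKind.PGSTE, gradients=PGSTE_GRADIENTS.copy(),
                delta=PGSTE_DELTA, Delta=PGSTE_BIG_DELTA, signal=signal)
    return curves


# ---------------------------------------------------------------------------
# ion trajectories
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectorySpec:
    """Generator settings for synthetic ion trajectories.

    The sphere walk emulates an ion diffusing laterally on a spherical
    interface of radius ``sphere_radius`` with coefficient ``D_surface``,
    tethered radially with ``radial_softness`` RMS fluctuation (AR(1) with
    ``radial_corr_time``).  The exchange generator switches each ion between
    an inside shell (``sphere_radius``) and an outside shell
    (``outside_radius``) as a two-state Markov process with the given rates;
    the true mean dwell time inside is 1/unbind_rate.
    """

    n_ions: int = 50
    duration: float = 5e-9  # s
    dt: float = 1e-12  # s
    sphere_radius: float = 14.5 * c.ANGSTROM
    D_surface: float = 10.6e-10  # m^2/s
    radial_softness: float = 1.0 * c.ANGSTROM  # RMS radial fluctuation
    radial_corr_time: float = 5e-12  # s
    com_diffusion: float = 0.0  # aggregate COM diffusion, m^2/s
    box: Optional[float] = None  # periodic box edge, m
    bind_rate: float = 1.0 / 12e-9  # s^-1
    unbind_rate: float = 1.0 / 12e-9  # s^-1
    outside_radius: float = 50.0 * c.ANGSTROM
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ions <= 0 or self.duration <= 0 or self.dt <= 0:
            raise ValueError("n_ions, duration and dt must be positive")
        if self.dt > 1.05e-12:
            # frame spacing above ~1 ps under-resolves the surface walk
            raise ValueError("time step must be <= 1 ps")

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.dt)) + 1


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.standard_normal((n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def generate_sphere_walk(spec: TrajectorySpec) -> IonTrajectory:
    """Brownian walk of ions constrained near a spherical interface.

    Tangential steps have per-axis variance 2 D dt (two tangential degrees
    of freedom, hence local MSD = 4 D t); the radius relaxes toward
    ``sphere_radius`` as an AR(1) tether.  Optional aggregate COM diffusion
    shifts all ions coherently; the COM track is recorded so the analysis
    must undo it.  Ground truth is stored in ``meta``.
    """
    rng = np.random.default_rng(spec.seed)
    n_f, n_i = spec.n_frames, spec.n_ions
    step_sigma = math.sqrt(2.0 * spec.D_surface * spec.dt)
    rho = math.exp(-spec.dt / spec.radial_corr_time)
    innov = spec.radial_softness * math.sqrt(1.0 - rho * rho)

    unit = _random_unit_vectors(rng, n_i)
    radial_dev = rng.standard_normal(n_i) * spec.radial_softness
    com = np.zeros(3)
    com_sigma = math.sqrt(2.0 * spec.com_diffusion * spec.dt)

    positions = np.empty((n_f, n_i, 3))
    com_track = np.empty((n_f, 3))
    positions[0] = (spec.sphere_radius + radial_dev)[:, None] * unit + com
    com_track[0] = com
    for f in range(1, n_f):
        step = rng.standard_normal((n_i, 3)) * step_sigma
        # remove the radial component: diffusion is tangential
        step -= np.einsum("ij,ij->i", step, unit)[:, None] * unit
        moved = unit * spec.sphere_radius + step
        unit = moved / np.linalg.norm(moved, axis=1, keepdims=True)
        radial_dev = rho * radial_dev + rng.standard_normal(n_i) * innov
        if com_sigma > 0:
            com = com + rng.standard_normal(3) * com_sigma
        positions[f] = (spec.sphere_radius + radial_dev)[:, None] * unit + com
        com_track[f] = com
    times = np.arange(n_f) * spec.dt
    if spec.box is not None:
        positions = positions - spec.box * np.floor(positions / spec.box + 0.5)
        com_track = com_track - spec.box * np.floor(com_track / spec.box + 0.5)
    return IonTrajectory(times=times, positions=positions,
                         aggregate_com=com_track, box=spec.box,
                         meta={"generator": "sphere_walk",
                               "D_surface": spec.D_surface,
                               "sphere_radius": spec.sphere_radius,
                               "seed": spec.seed})


def generate_exchange_trajectory(spec: TrajectorySpec) -> IonTrajectory:
    """Two-state bind/unbind trajectories for residence-time analysis.

    Each ion switches between an inside shell (radius ``sphere_radius``) and
    an outside shell (``outside_radius``) with per-step switching
    probabilities 1 - exp(-rate dt).  Initial states are drawn from the
    Markov stationary distribution bind/(bind + unbind).  The positions are
    only meant to carry the radial state; they are not a dynamical model of
    the outside phase.  True mean dwell time inside (1/unbind_rate) and the
    censoring caveat are recorded in ``meta``.
    """
    if spec.bind_rate <= 0 or spec.unbind_rate <= 0:
        raise ValueError("bind and unbind rates must be positive")
    rng = np.random.default_rng(spec.seed)
    n_f, n_i = spec.n_frames, spec.n_ions
    p_unbind = 1.0 - math.exp(-spec.unbind_rate * spec.dt)
    p_bind = 1.0 - math.exp(-spec.bind_rate * spec.dt)
    p_inside0 = spec.bind_rate / (spec.bind_rate + spec.unbind_rate)

    inside = rng.random(n_i) < p_inside0
    states = np.empty((n_f, n_i), dtype=bool)
    states[0] = inside
    flips = rng.random((n_f - 1, n_i))
    for f in range(1, n_f):
        flip = np.where(states[f - 1],
                        flips[f - 1] < p_unbind,
                        flips[f - 1] < p_bind)
        states[f] = states[f - 1] ^ flip
    radii = np.where(states, spec.sphere_radius, spec.outside_radius)
    directions = _random_unit_vectors(rng, n_i)
    positions = radii[:, :, None] * directions[None, :, :]
    times = np.arange(n_f) * spec.dt
    return IonTrajectory(
        times=times, positions=positions,
        aggregate_com=np.zeros((n_f, 3)),
        meta={"generator": "exchange", "true_mean_dwell": 1.0 / spec.unbind_rate,
              "stationary_inside_fraction": p_inside0, "seed": spec.seed,
              "censoring": "events truncated at trajectory edges are kept at "
                           "their observed length, biasing the mean downward "
                           "when dwells approach the trajectory duration; see "
                           "censored_mean_estimate"})


def censored_mean_estimate(mean_dwell: float, mean_outside: float,
                           duration: float, dt: float,
                           min_duration: float, n_ions: int = 2000,
                           seed: int = 12345) -> float:
    """Expected *observed* mean residence time under edge censoring.

    Simulates the two-state dwell process alone (no coordinates) with the
    same event rules as the residence analysis — edge-truncated intervals
    kept, intervals shorter than ``min_duration`` discarded — and returns
    the mean event length.  This quantifies the downward censoring bias of
    the estimator relative to the true ``mean_dwell``.
    """
    rng = np.random.default_rng(seed)
    n_f = int(round(duration / dt)) + 1
    p_u = 1.0 - math.exp(-dt / mean_dwell)
    p_b = 1.0 - math.exp(-dt / mean_outside)
    p0 = p_b / (p_b + p_u)
    state = rng.random(n_ions) < p0
    run = np.where(state, 1, 0)
    durations: list[float] = []
    for _ in range(n_f - 1):
        u = rng.random(n_ions)
        flip = np.where(state, u < p_u, u < p_b)
        ending = state & flip
        done = run[ending] * dt
        durations.extend(done[done >= min_duration])
        run = np.where(flip, 0, run)
        state = state ^ flip
        run = run + state
    done = run[state] * dt  # edge-censored final runs
    durations.extend(done[done >= min_duration])
    return float(np.mean(durations))
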