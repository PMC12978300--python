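"""Surface diffusion and residence times of ions from coordinate trajectories.

Given ion coordinates around a surfactant aggregate, this module estimates

* the surface diffusion coefficient D_s from the initial slope of the
  time- and ion-averaged mean square displacement in a reference frame where
  the aggregate centre of mass is fixed, using the quasi-two-dimensional
  convention MSD = 4 D_s t appropriate for motion on an interface; and
* residence times: contiguous intervals an ion spends within a boundary
  radius of the aggregate centre of mass, keeping intervals of at least a
  minimum duration ("events") and averaging their lengths.  Ions that stay
  inside for the whole trajectory contribute one full-length event, so the
  mean is censored downward relative to the true dwell time when dwellings
  are comparable to the trajectory length.

Aggregate rotation is deliberately *not* removed by default: for a micelle
the relaxing motion is a mixture of surface diffusion and reorientation, and
the COM-frame MSD captures that mixture.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import constants as c
from .relaxation_core import tau_from_surface_diffusion

__all__ = [
    "IonTrajectory",
    "MsdResult",
    "ResidenceEvents",
    "com_frame",
    "msd_initial_slope",
    "residence_times",
    "read_trajectory_table",
    "write_trajectory_table",
    "read_trajectory_xyz",
]

DEFAULT_BOUNDARY = 35.0 * c.ANGSTROM
DEFAULT_MIN_DURATION = 100e-12
DEFAULT_FIT_WINDOW = 100e-12


@dataclass
class IonTrajectory:
    """Time-stamped ion coordinates, optionally with an aggregate COM track.

    ``positions`` has shape (n_frames, n_ions, 3) in metres on a uniform time
    grid ``times`` (s).  ``aggregate_com`` (n_frames, 3) is the centre of
    mass of the aggregate per frame; ``box`` is the periodic cubic box edge
    in metres (None for already-unwrapped coordinates).  ``meta`` carries
    generator ground truth when the trajectory is synthetic.
    """

    times: np.ndarray
    positions: np.ndarray
    aggregate_com: Optional[np.ndarray] = None
    box: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_ions, 3)")
        if self.times.size != self.positions.shape[0]:
            raise ValueError("times and positions disagree on frame count")
        steps = np.diff(self.times)
        if steps.size and not np.allclose(steps, steps[0], rtol=1e-6):
            raise ValueError("time step must be uniform")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")
        if self.aggregate_com is not None:
            self.aggregate_com = np.asarray(self.aggregate_com, dtype=float)
            if self.aggregate_com.shape != (self.times.size, 3):
                raise ValueError("aggregate_com must have shape (n_frames, 3)")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_ions(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])


@dataclass(frozen=True)
class MsdResult:
    """MSD curve and the diffusion coefficient from its initial slope."""

    lags: np.ndarray  # s
    msd: np.ndarray  # m^2
    D_s: float  # m^2/s, slope/4 over the fit window
    fit_window: float  # s
    intercept: float  # m^2, nuisance offset absorbing fast radial jitter
    n_ions_used: int
    tau_m: Optional[float] = None  # s, R^2/(6 D_s) when a radius is supplied


@dataclass(frozen=True)
class ResidenceEvents:
    """Qualifying residence events within the boundary radius."""

    boundary_radius: float  # m
    min_duration: float  # s
    event_durations: np.ndarray  # s, one entry per event
    n_full_trajectory: int  # events spanning the entire trajectory

    @property
    def n_events(self) -> int:
        return int(self.event_durations.size)

    @property
    def mean_residence(self) -> float:
        """Mean event duration tau_res; NaN when no event qualifies."""
        if self.event_durations.size == 0:
            return float("nan")
        return float(self.event_durations.mean())


# ---------------------------------------------------------------------------
# frame transforms
# ---------------------------------------------------------------------------

def _unwrap(series: np.ndarray, box: float) -> np.ndarray:
    """Undo periodic wrapping along axis 0 by minimum-image continuity."""
    d = np.diff(series, axis=0)
    d -= box * np.round(d / box)
    return np.concatenate([series[:1], series[:1] + np.cumsum(d, axis=0)])


def com_frame(traj: IonTrajectory) -> IonTrajectory:
    """Re-express ion positions relative to the aggregate centre of mass.

    When a periodic box is present, both the ion tracks and the COM track are
    unwrapped by minimum-image continuity before subtraction, so an ion
    crossing the boundary keeps a continuous displacement history.
    """
    if traj.aggregate_com is None:
        raise ValueError("trajectory has no aggregate_com track")
    pos, com = traj.positions, traj.aggregate_com
    if traj.box is not None:
        pos = _unwrap(pos, traj.box)
        com = _unwrap(com, traj.box)
    rel = pos - com[:, None, :]
    return IonTrajectory(times=traj.times.copy(), positions=rel,
                         aggregate_com=np.zeros_like(com), box=None,
                         meta=dict(traj.meta))


# ---------------------------------------------------------------------------
# mean square displacement
# ---------------------------------------------------------------------------

def msd_initial_slope(traj: IonTrajectory,
                      fit_window: float = DEFAULT_FIT_WINDOW,
                      boundary_radius: Optional[float] = DEFAULT_BOUNDARY,
                      radius: Optional[float] = None,
                      max_lag: Optional[float] = None) -> MsdResult:
    """Time- and ion-averaged MSD and D_s = slope/4 on [0, fit_window].

    Expects a COM-frame trajectory.  Averaging origins are restricted to
    (origin, ion) pairs where the ion lies within ``boundary_radius`` of the
    aggregate centre at the origin ("in proximity to the aggregate"); pass
    ``boundary_radius=None`` to average over all ions.  A straight line with
    a free intercept is fitted to the MSD over the window — the intercept
    absorbs uncorrelated radial jitter — and the reported coefficient is
    slope/4 per the quasi-2D interface convention.  If ``radius`` is given,
    the correlation time R^2/(6 D_s) is attached.
    """
    dt = traj.dt
    n_window = int(round(fit_window / dt))
    if n_window < 10:
        raise ValueError("fit window must span at least 10 time steps")
    n_max = n_window if max_lag is None else int(round(max_lag / dt))
    n_max = min(n_max, traj.n_frames - 1)
    if n_window > traj.n_frames // 3:
        warnings.warn("fit window exceeds a third of the trajectory; "
                      "MSD statistics will be poor", stacklevel=2)

    pos = traj.positions
    if boundary_radius is not None:
        inside = np.linalg.norm(pos, axis=2) < boundary_radius  # (frames, ions)
        n_ions_used = int(np.any(inside, axis=0).sum())
        if n_ions_used == 0:
            raise ValueError("no ion ever enters the boundary radius")
    else:
        inside = np.ones(pos.shape[:2], dtype=bool)
        n_ions_used = traj.n_ions

    lags = np.arange(1, n_max + 1)
    msd = np.empty(n_max)
    for i, lag in enumerate(lags):
        d = pos[lag:] - pos[:-lag]
        sq = np.einsum("fij,fij->fi", d, d)
        w = inside[:-lag]
        total = w.sum()
        msd[i] = (sq * w).sum() / total if total else np.nan
    lags_s = lags * dt

    fit_mask = lags <= n_window
    t_fit = np.concatenate([[0.0], lags_s[fit_mask]])
    y_fit = np.concatenate([[0.0], msd[fit_mask]])
    slope, intercept = np.polyfit(t_fit, y_fit, 1)
    if not np.isfinite(slope) or slope <= 0:
        raise ValueError("MSD has no positive initial slope (stationary ions?)")
    d_s = slope / 4.0
    tau_m = tau_from_surface_diffusion(radius, d_s) if radius else None
    return MsdResult(lags=lags_s, msd=msd, D_s=d_s, fit_window=n_window * dt,
                     intercept=intercept, n_ions_used=n_ions_used, tau_m=tau_m)


# ---------------------------------------------------------------------------
# residence times
# ---------------------------------------------------------------------------

def residence_times(traj: IonTrajectory,
                    boundary_radius: float = DEFAULT_BOUNDARY,
                    min_duration: float = DEFAULT_MIN_DURATION) -> ResidenceEvents:
    """Contiguous within-boundary intervals per ion, averaged over events.

    Works on a COM-frame trajectory.  Intervals shorter than ``min_duration``
    are discarded; intervals truncated by the trajectory edges are kept at
    their observed length, and an ion inside for the whole trajectory
    contributes a single event of the full trajectory length.  Emits a
    warning and an empty result when no event qualifies.
    """
    dt = traj.dt
    r = np.linalg.norm(traj.positions, axis=2)  # (frames, ions)
    inside = r < boundary_radius
    durations: list[float] = []
    n_full = 0
    n_frames = traj.n_frames
    for i in range(traj.n_ions):
        col = inside[:, i]
        # run-length encode the inside mask
        edges = np.flatnonzero(np.diff(col.astype(np.int8)))
        starts = np.concatenate([[0], edges + 1])
        ends = np.concatenate([edges + 1, [n_frames]])
        for s, e in zip(starts, ends):
            if not col[s]:
                continue
            length = (e - s) * dt
            if length >= min_duration:
                durations.append(length)
                if e - s == n_frames:
                    n_full += 1
    if not durations:
        warnings.warn("no residence event met the minimum duration",
                      stacklevel=2)
    return ResidenceEvents(boundary_radius=boundary_radius,
                           min_duration=min_duration,
                           event_durations=np.asarray(durations, dtype=float),
                           n_full_trajectory=n_full)


# ---------------------------------------------------------------------------
# trajectory I/O
# ---------------------------------------------------------------------------
# Plain-text table: columns (frame, ion, x_A, y_A, z_A) in Angstrom, one row
# per ion per frame, with optional COM rows using ion id -1.  The time step
# is declared in a "# dt_ps = <value>" comment.

def write_trajectory_table(traj: IonTrajectory, path: str | Path,
                           header_comment: str | None = None) -> None:
    n_f, n_i = traj.n_frames, traj.n_ions
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        fh.write(f"# dt_ps = {traj.dt * 1e12:.6f}\n")
        if traj.box is not None:
            fh.write(f"# box_A = {traj.box / c.ANGSTROM:.6f}\n")
        fh.write("# frame ion x_A y_A z_A   (ion -1 = aggregate COM)\n")
        for f in range(n_f):
            if traj.aggregate_com is not None:
                x, y, z = traj.aggregate_com[f] / c.ANGSTROM
                fh.write(f"{f} -1 {x:.6f} {y:.6f} {z:.6f}\n")
            for i in range(n_i):
                x, y, z = traj.positions[f, i] / c.ANGSTROM
                fh.write(f"{f} {i} {x:.6f} {y:.6f} {z:.6f}\n")


def read_trajectory_table(path: str | Path) -> IonTrajectory:
    dt = None
    box = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "dt_ps" in line:
                    dt = float(line.split("=")[1].split()[0]) * 1e-12
                elif "box_A" in line:
                    box = float(line.split("=")[1].split()[0]) * c.ANGSTROM
            else:
                break
    if dt is None:
        raise ValueError("trajectory table lacks a '# dt_ps = ...' declaration")
    data = np.loadtxt(path, comments="#")
    frames = data[:, 0].astype(int)
    ions = data[:, 1].astype(int)
    xyz = data[:, 2:5] * c.ANGSTROM
    n_frames = frames.max() + 1
    ion_ids = np.unique(ions[ions >= 0])
    n_ions = ion_ids.size
    positions = np.full((n_frames, n_ions, 3), np.nan)
    com = None
    if np.any(ions == -1):
        com = np.full((n_frames, 3), np.nan)
        mask = ions == -1
        com[frames[mask]] = xyz[mask]
    id_index = {ion: k for k, ion in enumerate(ion_ids)}
    for row in range(data.shape[0]):
        if ions[row] >= 0:
            positions[frames[row], id_index[ions[row]]] = xyz[row]
    times = np.arange(n_frames) * dt
    return IonTrajectory(times=times, positions=positions,
                         aggregate_com=com, box=box)


def read_trajectory_xyz(path: str | Path, dt: float,
                        com_element: str = "X") -> IonTrajectory:
    """Read a multi-frame XYZ file via MDAnalysis (optional dependency).

    Atoms named ``com_element`` are interpreted as the aggregate COM track;
    all other atoms are ions.  ``dt`` is the frame spacing in seconds.
    """
    try:
        import MDAnalysis as mda
    except ImportError as exc:  # pragma: no cover - optional extra
        raise ImportError("XYZ input requires the MDAnalysis extra") from exc
    u = mda.Universe(str(path), format="XYZ")
    names = u.atoms.names
    com_sel = names == com_element
    frames = []
    com_frames = []
    for _ in u.trajectory:
        frames.append(u.atoms.positions[~com_sel] * c.ANGSTROM)
        if com_sel.any():
            com_frames.append(u.atoms.positions[com_sel][0] * c.ANGSTROM)
    positions = np.asarray(frames)
    com = np.asarray(com_frames) if com_frames else None
    times = np.arange(positions.shape[0]) * dt
    return IonTrajectory(times=times, positions=positions, aggregate_com=com)
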