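"""Collapse kinetics of force-quenched disordered peptides.

After a stretching force is released, a disordered peptide collapses; the
time to first reach the collapsed state (end-to-end distance <= 1.5 nm)
behaves approximately as an exponential first-passage process.  The lifetime
of the extended state is estimated by least-squares fitting of
N(t) = n_total * (1 - exp(-t / tau)) to the cumulative count of collapse
events, with a parametric-bootstrap confidence interval.  The module also
computes the polyproline-II (PPII) dihedral fraction used to track backbone
conformation along stretching.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = [
    "EndToEndTrajectory",
    "PassageRecord",
    "CollapseFit",
    "DihedralSeries",
    "read_trajectories",
    "write_trajectory",
    "read_dihedrals",
    "first_passage_times",
    "cumulative_events",
    "fit_exponential_cumulative",
    "fit_lifetime",
    "ppii_fraction",
    "PPII_WINDOW",
]

#: Default PPII region of the Ramachandran map, degrees: (phi range, psi range).
PPII_WINDOW = ((-100.0, -50.0), (120.0, 180.0))


@dataclass
class EndToEndTrajectory:
    """End-to-end distance time series of one collapse simulation."""

    time_ns: np.ndarray
    distance_nm: np.ndarray
    trajectory_id: str = ""

    def __post_init__(self) -> None:
        self.time_ns = np.asarray(self.time_ns, dtype=float)
        self.distance_nm = np.asarray(self.distance_nm, dtype=float)
        if self.time_ns.shape != self.distance_nm.shape:
            raise ValueError("time and distance must have equal length")
        if len(self.time_ns) == 0:
            raise ValueError("trajectory is empty")
        if np.any(np.diff(self.time_ns) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.distance_nm < 0):
            raise ValueError("distances must be non-negative")


@dataclass(frozen=True)
class PassageRecord:
    """First-passage time of one trajectory, or censoring at its end."""

    time_ns: float
    censored: bool
    trajectory_id: str = ""


@dataclass
class CollapseFit:
    """Exponential lifetime estimate of the extended state."""

    tau_ns: float
    tau_ci_ns: tuple[float, float]
    n_events: int
    n_censored: int
    n_total: int
    at_bound: bool = False

    def __post_init__(self) -> None:
        if self.n_events + self.n_censored != self.n_total:
            raise ValueError("n_events + n_censored must equal n_total")
        if not self.tau_ns > 0:
            raise ValueError("tau must be > 0")


@dataclass
class DihedralSeries:
    """Per-frame, per-residue backbone dihedrals (degrees, in (-180, 180])."""

    table: pd.DataFrame  # columns: frame, residue, phi_deg, psi_deg

    def __post_init__(self) -> None:
        required = {"frame", "residue", "phi_deg", "psi_deg"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"dihedral table needs columns {sorted(required)}")
        ang = self.table[["phi_deg", "psi_deg"]].to_numpy()
        if np.any(ang <= -180) or np.any(ang > 180):
            raise ValueError("angles must lie in (-180, 180]")


def read_trajectories(source) -> list[EndToEndTrajectory]:
    """Read (time_ns, distance_nm) TSV trajectories from a file or directory."""
    src = Path(source)
    paths = (
        sorted(
            p
            for ext in ("*.tsv", "*.txt")
            for p in src.glob(ext)
            if p.stem != "truth"  # ground-truth tables next to synthetic data
        )
        if src.is_dir()
        else [src]
    )
    out = []
    for path in paths:
        data = np.loadtxt(path, comments="#", ndmin=2)
        out.append(
            EndToEndTrajectory(
                time_ns=data[:, 0], distance_nm=data[:, 1], trajectory_id=path.stem
            )
        )
    return out


def write_trajectory(traj: EndToEndTrajectory, path) -> None:
    with open(path, "w") as fh:
        fh.write("#time_ns\tdistance_nm\n")
        for t, z in zip(traj.time_ns, traj.distance_nm):
            fh.write(f"{t:.6f}\t{z:.6f}\n")


def read_dihedrals(path) -> DihedralSeries:
    """Read a long-format dihedral TSV (frame, residue, phi_deg, psi_deg)."""
    return DihedralSeries(pd.read_csv(path, sep="\t", comment="#"))


def first_passage_times(
    trajectories, threshold_nm: float = 1.5
) -> list[PassageRecord]:
    """First time each trajectory reaches the collapsed state.

    The crossing time of the threshold is linearly interpolated between
    frames; a trajectory that starts at or below the threshold has passage
    time 0, and one that never crosses is censored at its final time.
    """
    records = []
    for traj in trajectories:
        z = traj.distance_nm
        t = traj.time_ns
        below = np.nonzero(z <= threshold_nm)[0]
        if len(below) == 0:
            records.append(
                PassageRecord(float(t[-1]), censored=True, trajectory_id=traj.trajectory_id)
            )
            continue
        i = below[0]
        if i == 0:
            # Already collapsed at the first recorded frame.
            records.append(
                PassageRecord(0.0, censored=False, trajectory_id=traj.trajectory_id)
            )
            continue
        frac = (z[i - 1] - threshold_nm) / (z[i - 1] - z[i])
        tc = t[i - 1] + frac * (t[i] - t[i - 1])
        records.append(
            PassageRecord(float(tc), censored=False, trajectory_id=traj.trajectory_id)
        )
    return records


def cumulative_events(records, grid_ns) -> np.ndarray:
    """Number of uncensored events with passage time <= t, on a grid."""
    grid = np.asarray(grid_ns, dtype=float)
    if np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be increasing")
    times = np.sort([r.time_ns for r in records if not r.censored])
    return np.searchsorted(times, grid, side="right").astype(int)


def _sse_tau(log_tau: float, t: np.ndarray, n_obs: np.ndarray, n_total: float) -> float:
    tau = np.exp(log_tau)
    return float(np.sum((n_obs - n_total * (1.0 - np.exp(-t / tau))) ** 2))


def fit_exponential_cumulative(
    t, n_obs, n_total: float, constrain_plateau: bool = True
):
    """Fit N(t) = A * (1 - exp(-t/tau)) to a cumulative event curve.

    With ``constrain_plateau`` the plateau A is fixed at ``n_total``
    (censored trajectories inform the plateau but not the curve); otherwise
    A is profiled out in closed form at each tau.  Returns ``(tau, A,
    at_bound)``.
    """
    t = np.asarray(t, dtype=float)
    n_obs = np.asarray(n_obs, dtype=float)
    if len(t) == 0:
        raise ValueError("empty curve")
    tmax = float(t.max())
    lo, hi = np.log(max(tmax, 1e-12) * 1e-4), np.log(max(tmax, 1e-12) * 1e4)

    if constrain_plateau:
        obj = lambda lt: _sse_tau(lt, t, n_obs, n_total)
    else:

        def obj(lt):
            y = 1.0 - np.exp(-t / np.exp(lt))
            denom = float(np.sum(y * y))
            a = float(np.sum(n_obs * y)) / denom if denom > 0 else 0.0
            return float(np.sum((n_obs - a * y) ** 2))

    res = minimize_scalar(obj, bounds=(lo, hi), method="bounded", options={"xatol": 1e-12})
    tau = float(np.exp(res.x))
    if constrain_plateau:
        a = float(n_total)
    else:
        y = 1.0 - np.exp(-t / tau)
        a = float(np.sum(n_obs * y) / np.sum(y * y))
    at_bound = bool(res.x - lo < 1e-6 or hi - res.x < 1e-6)
    return tau, a, at_bound


def fit_lifetime(
    records,
    n_total: int | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    constrain_plateau: bool = True,
) -> CollapseFit:
    """Exponential lifetime of the extended state from passage records.

    Least-squares fit of the cumulative collapse count against
    ``n_total * (1 - exp(-t/tau))`` evaluated at the observed event times.
    The 95% confidence interval comes from a parametric bootstrap: ``n_boot``
    seeded resamples of ``n_total`` exponential passage times at the fitted
    tau, censored at the longest observed time when the data themselves
    contain censored trajectories.
    """
    records = list(records)
    events = sorted(r.time_ns for r in records if not r.censored)
    n_cens = sum(1 for r in records if r.censored)
    if len(events) < 3:
        raise ValueError("need at least 3 uncensored events to fit a lifetime")
    if n_total is None:
        n_total = len(records)
    t = np.asarray(events)
    n_obs = np.arange(1, len(events) + 1, dtype=float)
    tau, _, at_bound = fit_exponential_cumulative(
        t, n_obs, n_total, constrain_plateau=constrain_plateau
    )

    rng = np.random.default_rng(seed)
    censor_at = max(r.time_ns for r in records) if n_cens > 0 else np.inf
    taus = []
    for _ in range(n_boot):
        draws = rng.exponential(tau, size=n_total)
        ev = np.sort(draws[draws <= censor_at])
        if len(ev) < 3:
            continue
        tb, _, _ = fit_exponential_cumulative(
            ev, np.arange(1, len(ev) + 1, dtype=float), n_total,
            constrain_plateau=constrain_plateau,
        )
        taus.append(tb)
    if taus:
        # Basic (reflected) bootstrap interval on the log scale -- the
        # appropriate construction for a positive scale parameter whose
        # estimator is right-skewed at small n.
        llo, lhi = np.percentile(np.log(taus), [2.5, 97.5])
        ci = (np.exp(2 * np.log(tau) - lhi), np.exp(2 * np.log(tau) - llo))
    else:
        ci = (float("nan"), float("nan"))
    return CollapseFit(
        tau_ns=tau,
        tau_ci_ns=(float(ci[0]), float(ci[1])),
        n_events=len(events),
        n_censored=n_cens,
        n_total=n_total,
        at_bound=at_bound,
    )


def ppii_fraction(dihedrals: DihedralSeries, region=PPII_WINDOW) -> pd.Series:
    """Per-frame fraction of residues in the PPII region of (phi, psi).

    The default window (phi in [-100, -50], psi in [120, 180] degrees)
    brackets the canonical PPII point (-75, +145).  Returns a Series indexed
    by frame with values in [0, 1].
    """
    tab = dihedrals.table
    if len(tab) == 0:
        raise ValueError("empty residue set")
    (phi_lo, phi_hi), (psi_lo, psi_hi) = region
    in_region = (
        (tab["phi_deg"] >= phi_lo)
        & (tab["phi_deg"] <= phi_hi)
        & (tab["psi_deg"] >= psi_lo)
        & (tab["psi_deg"] <= psi_hi)
    )
    return in_region.groupby(tab["frame"]).mean()
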