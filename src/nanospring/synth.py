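"""Seeded synthetic-data generators emulating the study's instruments.

Four generators stand in for the AFM instrument, the umbrella-sampling MD
engine, the force-quench MD engine, and the FTIR spectrometer:

* WLC-shaped retract traces with a terminal cohesin-dockerin double rupture
  (branch separation 8 nm in contour-length space), per-trace contour
  lengths from a truncated normal, white Gaussian force noise, and a random
  contact point and force offset;
* Boltzmann samples under harmonic umbrella biases on a known PMF, drawn by
  inverse-CDF sampling on a fine grid;
* one-dimensional overdamped Langevin collapse trajectories on an effective
  end-to-end-distance potential with a barrier-separated extended basin
  (near-exponential first-passage times);
* multi-Gaussian amide-I plates with a linear baseline and per-well noise
  over replicate wells and carriers.

Every generator is driven by a single explicitly seeded random stream and
emits machine-readable ground truth alongside its data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .afm import ForceDistanceTrace
from .collapse import EndToEndTrajectory
from .ftir import FWHM_TO_SD, IRSpectrum
from .pmf import UmbrellaWindow
from .wlc import KB_KJ_PER_MOL_K, WLCParams, wlc_extension, wlc_force

__all__ = [
    "gen_fd_traces",
    "gen_umbrella_samples",
    "gen_collapse_trajectories",
    "gen_amide1_spectra",
    "quartic_double_well",
    "harmonic_potential",
    "wlc_pmf",
]


def gen_fd_traces(
    n_traces: int,
    lc_mean_nm: float = 94.0,
    lc_sd_nm: float = 43.0,
    lc_min_nm: float = 20.0,
    lp_nm: float = 0.37,
    noise_sd_pN: float = 5.0,
    specific_fraction: float = 0.8,
    separation_nm: float = 8.0,
    rupture_force_range_pN: tuple[float, float] = (150.0, 300.0),
    contact_range_nm: tuple[float, float] = (5.0, 20.0),
    baseline_offset_range_pN: tuple[float, float] = (-20.0, 20.0),
    point_spacing_nm: float = 0.25,
    tail_nm: float = 50.0,
    temperature_K: float = 300.0,
    seed: int = 0,
):
    """Synthetic AFM retract traces with ground truth.

    Each trace follows a WLC branch from a random contact point up to a
    first rupture; specific traces continue on a second branch whose contour
    length is ``separation_nm`` larger (the receptor-ligand fingerprint)
    before detaching to the baseline.  Non-specific traces show a single
    rupture or no adhesion at all (half/half).  Defaults reproduce the
    experimental population: Lc ~ Normal(94, 43) truncated above 20 nm,
    Lp = 0.37 nm, 5 pN force noise.

    Returns ``(traces, truth)`` where ``truth`` is a DataFrame with one row
    per trace.
    """
    if not 0.0 <= specific_fraction <= 1.0:
        raise ValueError("specific_fraction must be in [0, 1]")
    for name, v in [
        ("lc_sd_nm", lc_sd_nm),
        ("noise_sd_pN", noise_sd_pN),
        ("point_spacing_nm", point_spacing_nm),
    ]:
        if v < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = np.random.default_rng(seed)
    traces, rows = [], []
    for i in range(n_traces):
        lc = -np.inf
        while lc <= lc_min_nm:
            lc = rng.normal(lc_mean_nm, lc_sd_nm)
        contact = rng.uniform(*contact_range_nm)
        offset = rng.uniform(*baseline_offset_range_pN)
        specific = bool(rng.uniform() < specific_fraction)
        no_adhesion = (not specific) and bool(rng.uniform() < 0.5)

        p1 = WLCParams(lp_nm, lc, temperature_K)
        f1 = rng.uniform(*rupture_force_range_pN)
        x1 = wlc_extension(p1, f1)
        if specific:
            p2 = WLCParams(lp_nm, lc + separation_nm, temperature_K)
            # Redraw until the second branch extends visibly past the first.
            for _ in range(100):
                f2 = rng.uniform(*rupture_force_range_pN)
                x2 = wlc_extension(p2, f2)
                if x2 > x1 + 2 * point_spacing_nm:
                    break
            else:
                f2, x2 = f1, wlc_extension(p2, f1)
        else:
            f2, x2 = np.nan, x1

        d_end = contact + x2 + tail_nm
        d = np.arange(0.0, d_end, point_spacing_nm)
        force = np.zeros_like(d)
        if not no_adhesion:
            ext = d - contact
            b1 = (ext > 0) & (ext <= x1)
            force[b1] = wlc_force(p1, ext[b1])
            if specific:
                b2 = (ext > x1) & (ext <= x2)
                force[b2] = wlc_force(p2, ext[b2])
        force = force + offset + rng.normal(0.0, noise_sd_pN, size=len(d))
        trace_id = f"trace_{i:04d}"
        traces.append(ForceDistanceTrace(trace_id, d, force))
        rows.append(
            dict(
                trace_id=trace_id,
                specific=specific,
                no_adhesion=no_adhesion,
                lc_nm=lc,
                lp_nm=lp_nm,
                contact_nm=contact,
                baseline_pN=offset,
                rupture1_pN=f1 if not no_adhesion else np.nan,
                rupture2_pN=f2 if specific else np.nan,
                separation_nm=separation_nm if specific else np.nan,
            )
        )
    return traces, pd.DataFrame(rows)


def harmonic_potential(curvature_kJ_mol_nm2: float, center_nm: float = 0.0):
    """U(z) = 0.5 * a * (z - z0)^2 in kJ/mol."""

    def u(z):
        return 0.5 * curvature_kJ_mol_nm2 * (np.asarray(z) - center_nm) ** 2

    return u


def quartic_double_well(
    barrier_kJ_mol: float = 4.0, midpoint_nm: float = 2.75, half_width_nm: float = 1.75
):
    """Double well with minima at midpoint +- half_width and a central barrier."""

    def u(z):
        s = (np.asarray(z) - midpoint_nm) ** 2 - half_width_nm**2
        return barrier_kJ_mol * s**2 / half_width_nm**4

    return u


def wlc_pmf(params: WLCParams, z_grid_nm: np.ndarray):
    """PMF (kJ/mol) obtained by integrating a WLC force curve from z=0."""
    from scipy.integrate import cumulative_trapezoid

    from .wlc import KJ_PER_MOL_NM_AS_PN

    f = wlc_force(params, z_grid_nm)  # pN
    g = cumulative_trapezoid(f / KJ_PER_MOL_NM_AS_PN, z_grid_nm, initial=0.0)
    return g


def gen_umbrella_samples(
    potential,
    window_centers_nm=None,
    spring_kJ_mol_nm2: float = 500.0,
    n_samples_per_window=5000,
    temperature_K: float = 300.0,
    grid_step_nm: float = 1e-3,
    grid_pad_nm: float = 0.6,
    seed: int = 0,
):
    """Boltzmann samples under harmonic umbrella biases on a known PMF.

    ``potential`` maps z (nm) to energy (kJ/mol).  Per window, samples are
    drawn from p(z) proportional to exp(-(U(z) + 0.5 k (z-c)^2)/kBT) by
    inverse-CDF interpolation on a fine grid.  Window layout defaults to
    the study protocol: centers 0.4 to 7.0 nm in 0.4 nm steps with
    k = 500 kJ/mol/nm^2.  ``n_samples_per_window`` may be a scalar or a
    per-window sequence (emulating asymmetric sampling times).

    Returns ``(windows, truth)`` with ``truth`` a DataFrame of the exact PMF
    on the sampling grid.
    """
    if window_centers_nm is None:
        window_centers_nm = np.arange(0.4, 7.0 + 1e-9, 0.4)
    centers = np.asarray(window_centers_nm, dtype=float)
    counts = np.broadcast_to(
        np.asarray(n_samples_per_window, dtype=int), centers.shape
    )
    kt = KB_KJ_PER_MOL_K * temperature_K
    sigma = np.sqrt(kt / spring_kJ_mol_nm2)
    lo = max(centers.min() - max(grid_pad_nm, 6 * sigma), 1e-6)
    hi = centers.max() + max(grid_pad_nm, 6 * sigma)
    grid = np.arange(lo, hi, grid_step_nm)
    u_grid = np.asarray(potential(grid), dtype=float)

    rng = np.random.default_rng(seed)
    windows = []
    for c, n in zip(centers, counts):
        energy = u_grid + 0.5 * spring_kJ_mol_nm2 * (grid - c) ** 2
        w = np.exp(-(energy - energy.min()) / kt)
        total = np.trapezoid(w, grid)
        if not np.isfinite(total) or total <= 0:
            raise ValueError(f"biased density vanishes for window at {c:g} nm")
        cdf = np.concatenate([[0.0], np.cumsum((w[1:] + w[:-1]) / 2 * np.diff(grid))])
        cdf /= cdf[-1]
        # strictly increasing section for interpolation
        keep = np.concatenate([[True], np.diff(cdf) > 0])
        samples = np.interp(rng.uniform(size=n), cdf[keep], grid[keep])
        windows.append(UmbrellaWindow(float(c), spring_kJ_mol_nm2, samples))
    truth = pd.DataFrame({"z_nm": grid, "pmf_kJ_mol": u_grid - u_grid.min()})
    return windows, truth


def gen_collapse_trajectories(
    n_traj: int = 20,
    z_start_nm: float = 4.5,
    potential=None,
    diffusion_nm2_ns: float = 1.5,
    dt_ns: float = 0.002,
    t_max_ns: float = 200.0,
    threshold_nm: float = 1.5,
    z_max_nm: float = 7.0,
    record_stride: int = 5,
    temperature_K: float = 300.0,
    seed: int = 0,
):
    """Overdamped Langevin collapse trajectories on an effective potential.

    Updates z <- z - (D/kBT) U'(z) dt + sqrt(2 D dt) xi with a reflecting
    boundary at ``z_max_nm`` (the chain's maximal extension) and at zero.
    Each trajectory is recorded every ``record_stride`` steps until it
    first reaches ``threshold_nm`` (the collapsed state) or ``t_max_ns``.
    The default potential is a quartic double well whose extended basin is
    separated from the collapsed one by a thermal-scale barrier, giving
    near-exponential first-passage times on the few-ns scale.

    Returns ``(trajectories, truth)``; truth records the exact first crossing
    time of each trajectory (NaN when censored).
    """
    if z_start_nm <= threshold_nm:
        raise ValueError("z_start must lie above the collapse threshold")
    if potential is None:
        potential = quartic_double_well()
    kt = KB_KJ_PER_MOL_K * temperature_K
    # Numeric derivative and stability check against the stiffest curvature.
    zg = np.linspace(0.0, z_max_nm, 2048)
    ug = np.asarray(potential(zg), dtype=float)
    d2 = np.gradient(np.gradient(ug, zg), zg)
    relax = kt / (diffusion_nm2_ns * max(float(np.max(np.abs(d2))), 1e-12))
    if dt_ns > 0.5 * relax:
        raise ValueError(
            f"dt={dt_ns:g} ns too large for potential stiffness "
            f"(stable limit ~{0.5 * relax:g} ns)"
        )

    def grad(z):
        h = 1e-5
        return (np.asarray(potential(z + h)) - np.asarray(potential(z - h))) / (2 * h)

    rng = np.random.default_rng(seed)
    n_steps = int(round(t_max_ns / dt_ns))
    z = np.full(n_traj, float(z_start_nm))
    active = np.ones(n_traj, dtype=bool)
    crossing = np.full(n_traj, np.nan)
    crossing_z = np.full(n_traj, np.nan)
    strided_t = [0.0]
    strided_z = [z.copy()]
    amp = np.sqrt(2.0 * diffusion_nm2_ns * dt_ns)
    for step in range(1, n_steps + 1):
        if not active.any():
            break
        xi = rng.standard_normal(n_traj)
        z_new = z - (diffusion_nm2_ns / kt) * grad(z) * dt_ns + amp * xi
        # reflecting boundaries at full collapse and maximal extension
        z_new = np.where(z_new < 0.0, -z_new, z_new)
        z_new = np.where(z_new > z_max_nm, 2 * z_max_nm - z_new, z_new)
        t_now = step * dt_ns
        hit = active & (z_new <= threshold_nm)
        crossing[hit] = t_now
        crossing_z[hit] = z_new[hit]
        active &= ~hit
        if step % record_stride == 0:
            strided_t.append(t_now)
            strided_z.append(z_new.copy())
        z = z_new
    strided_t = np.asarray(strided_t)
    strided_mat = np.vstack(strided_z)  # (records, n_traj)
    trajectories = []
    for j in range(n_traj):
        if np.isnan(crossing[j]):
            t_j, z_j = strided_t, strided_mat[:, j]
        else:
            keep = strided_t < crossing[j]
            t_j = np.append(strided_t[keep], crossing[j])
            z_j = np.append(strided_mat[keep, j], crossing_z[j])
        trajectories.append(
            EndToEndTrajectory(
                time_ns=t_j, distance_nm=z_j, trajectory_id=f"traj_{j:03d}"
            )
        )
    truth = pd.DataFrame(
        {
            "trajectory_id": [t.trajectory_id for t in trajectories],
            "first_passage_ns": crossing,
            "censored": np.isnan(crossing),
        }
    )
    return trajectories, truth


def gen_amide1_spectra(
    components=((1625.0, 14.0, 0.9), (1650.0, 18.0, 1.4), (1680.0, 12.0, 0.7)),
    baseline_slope: float = -2e-4,
    baseline_offset: float = 0.05,
    noise_sd: float = 1e-3,
    n_wells: int = 9,
    n_carriers: int = 4,
    region: tuple[float, float] = (1600.0, 1715.0),
    grid_step_cm1: float = 1.0,
    seed: int = 0,
):
    """Synthetic amide-I plate: replicate wells of a Gaussian mixture.

    ``components`` are (center_cm1, fwhm_cm1, area) triples; centers must
    lie within ``region``.  Each well receives the same mixture plus a
    linear baseline and independent Gaussian noise on a 1 cm^-1 grid.  The
    default three-component layout mimics beta-sheet / random-coil /
    turn amide-I sub-bands.

    Returns ``(spectra, truth)`` with one IRSpectrum per (carrier, well) and
    a truth DataFrame of the generating components.
    """
    for c, f, a in components:
        if not region[0] <= c <= region[1]:
            raise ValueError(f"component center {c:g} outside region {region}")
        if f <= 0 or a <= 0:
            raise ValueError("component fwhm and area must be > 0")
    rng = np.random.default_rng(seed)
    wn = np.arange(region[0], region[1] + grid_step_cm1 / 2, grid_step_cm1)
    signal = np.zeros_like(wn)
    for c, f, a in components:
        sd = f / FWHM_TO_SD
        height = a / (sd * np.sqrt(2 * np.pi))
        signal += height * np.exp(-0.5 * ((wn - c) / sd) ** 2)
    baseline = baseline_offset + baseline_slope * (wn - wn[0])
    spectra = []
    for ci in range(n_carriers):
        for wi in range(n_wells):
            noise = rng.normal(0.0, noise_sd, size=len(wn))
            spectra.append(
                IRSpectrum(
                    wavenumber_cm1=wn.copy(),
                    absorbance=signal + baseline + noise,
                    well_id=f"well_{wi:02d}",
                    carrier_id=f"carrier_{ci}",
                )
            )
    truth = pd.DataFrame(
        [
            {"center_cm1": c, "fwhm_cm1": f, "area": a}
            for c, f, a in components
        ]
    )
    return spectra, truth
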