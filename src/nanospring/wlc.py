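"""Worm-like chain (WLC) entropic elasticity.

The worm-like chain describes a semi-flexible polymer by two lengths: the
persistence length ``Lp`` (stiffness against bending; ~0.4 nm for an
unstructured polypeptide) and the contour length ``Lc`` (fully extended
length).  The restoring force at end-to-end extension ``x`` follows the
Marko-Siggia interpolation

    F(x) = (kB*T / Lp) * [ 1/(4*(1 - x/Lc)^2) - 1/4 + x/Lc ],

which is the near-universal convention for fitting AFM pulling data in the
piconewton force range.  This module provides the forward model, its
bracketed inverse, nonlinear least-squares fitting of force-extension data,
and the residue-count back-of-envelope contour-length estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np

__all__ = [
    "KB_PN_NM_PER_K",
    "KB_KJ_PER_MOL_K",
    "KJ_PER_MOL_NM_AS_PN",
    "WLCParams",
    "WLCFit",
    "wlc_force",
    "wlc_extension",
    "fit_wlc",
    "expected_contour_length",
]

#: Boltzmann constant in pN nm / K.
KB_PN_NM_PER_K = 0.0138065
#: Boltzmann constant in kJ / (mol K).
KB_KJ_PER_MOL_K = 0.0083144621
#: Unit conversion: 1 kJ mol^-1 nm^-1 expressed in pN.
KJ_PER_MOL_NM_AS_PN = 1.6606


@dataclass(frozen=True)
class WLCParams:
    """Parameters of a worm-like chain.

    Attributes
    ----------
    persistence_length_nm : float
        Bending persistence length Lp in nm, > 0.
    contour_length_nm : float
        Fully-extended contour length Lc in nm, > 0.
    temperature_K : float
        Absolute temperature, > 0.  Defaults to 300 K, the simulation
        temperature used throughout.
    """

    persistence_length_nm: float
    contour_length_nm: float
    temperature_K: float = 300.0

    def __post_init__(self) -> None:
        if not (self.persistence_length_nm > 0):
            raise ValueError("persistence_length_nm must be > 0")
        if not (self.contour_length_nm > 0):
            raise ValueError("contour_length_nm must be > 0")
        if not (self.temperature_K > 0):
            raise ValueError("temperature_K must be > 0")

    @property
    def kT_pN_nm(self) -> float:
        """Thermal energy kB*T in pN nm."""
        return KB_PN_NM_PER_K * self.temperature_K


@dataclass
class WLCFit:
    """Result of a least-squares WLC fit to force-extension data."""

    params: WLCParams
    param_uncertainties: dict[str, float]
    residual_norm: float
    n_points: int
    fit_window: tuple[int, int] = (0, -1)
    fixed_mask: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_free = sum(1 for v in self.fixed_mask.values() if not v) or 0
        if self.n_points < n_free + 1:
            raise ValueError("n_points must exceed the number of free parameters")
        if self.residual_norm < 0:
            raise ValueError("residual_norm must be >= 0")


def _ms_bracket(u: np.ndarray) -> np.ndarray:
    """Dimensionless Marko-Siggia bracket as a function of u = x/Lc."""
    return 1.0 / (4.0 * (1.0 - u) ** 2) - 0.25 + u


def wlc_force(params: WLCParams, extension_nm):
    """Force (pN) of a WLC at the given extension(s) in nm.

    Strictly increasing in extension; diverges as the extension approaches
    the contour length.  Raises ``ValueError`` for extensions outside
    ``[0, Lc)``.
    """
    x = np.asarray(extension_nm, dtype=float)
    lc = params.contour_length_nm
    if np.any(x < 0):
        raise ValueError("extension must be non-negative")
    if np.any(x >= lc):
        raise ValueError("extension must be smaller than the contour length")
    f = (params.kT_pN_nm / params.persistence_length_nm) * _ms_bracket(x / lc)
    return float(f) if np.isscalar(extension_nm) else f


def wlc_extension(params: WLCParams, force_pN):
    """Extension (nm) at which a WLC exerts the given force(s) in pN.

    The Marko-Siggia force is strictly increasing on [0, Lc), so the inverse
    is unique.  Solved by bisection on ``[0, Lc*(1 - 1e-12)]`` to an absolute
    tolerance of ``1e-9 * Lc``.
    """
    f = np.asarray(force_pN, dtype=float)
    if np.any(f < 0):
        raise ValueError("force must be non-negative")
    lc = params.contour_length_nm
    phi = f * params.persistence_length_nm / params.kT_pN_nm
    lo = np.zeros_like(phi)
    hi = np.full_like(phi, 1.0 - 1e-12)
    # ~64 bisection steps reach u-resolution ~1e-19, far below 1e-9*Lc in x.
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        too_low = _ms_bracket(mid) < phi
        lo = np.where(too_low, mid, lo)
        hi = np.where(too_low, hi, mid)
    x = 0.5 * (lo + hi) * lc
    x = np.where(f == 0, 0.0, x)
    return float(x) if np.isscalar(force_pN) else x


def _model_force(x: np.ndarray, lp: float, lc: float, kt: float) -> np.ndarray:
    """Forward model tolerant of x >= Lc (clipped) for use inside fitting."""
    u = np.clip(x / lc, 0.0, 1.0 - 1e-9)
    return (kt / lp) * _ms_bracket(u)


def fit_wlc(
    points,
    fixed: dict[str, float] | None = None,
    initial: WLCParams | None = None,
    temperature_K: float = 300.0,
    fit_window: tuple[int, int] | None = None,
) -> WLCFit:
    """Least-squares WLC fit to (extension_nm, force_pN) pairs.

    Parameters
    ----------
    points : sequence of (float, float) or (N, 2) array
        Extension (nm, non-negative) and force (pN) samples.
    fixed : dict, optional
        Parameters to hold fixed, keyed by ``"persistence_length_nm"`` and/or
        ``"contour_length_nm"``.
    initial : WLCParams, optional
        Starting values; defaults to Lp = 0.4 nm and Lc slightly above the
        largest observed extension.
    temperature_K : float
        Temperature entering kB*T (not fitted).
    fit_window : (int, int), optional
        Index range recorded in the result for provenance.

    The objective is unweighted least squares on force.  Standard errors come
    from the local quadratic approximation of the objective at the optimum.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be a sequence of (extension, force) pairs")
    x, f = pts[:, 0], pts[:, 1]
    if np.any(x < 0):
        raise ValueError("extensions must be non-negative")
    if not np.all(np.isfinite(pts)):
        raise ValueError("points must be finite")
    fixed = dict(fixed or {})
    unknown = set(fixed) - {"persistence_length_nm", "contour_length_nm"}
    if unknown:
        raise ValueError(f"unknown fixed parameters: {sorted(unknown)}")
    n_free = 2 - len(fixed)
    if len(pts) < n_free + 1:
        raise ValueError(
            f"need at least {n_free + 1} points for {n_free} free parameters"
        )
    if np.allclose(f, 0.0):
        raise ValueError("degenerate fit: all forces are zero")

    kt = KB_PN_NM_PER_K * temperature_K
    xmax = float(x.max())
    lp0 = initial.persistence_length_nm if initial else 0.4
    lc0 = initial.contour_length_nm if initial else max(xmax * 1.1, 1e-3)

    p = lmfit.Parameters()
    p.add(
        "lp",
        value=fixed.get("persistence_length_nm", lp0),
        min=1e-4,
        max=1e3,
        vary="persistence_length_nm" not in fixed,
    )
    p.add(
        "lc",
        value=fixed.get("contour_length_nm", lc0),
        min=max(xmax * (1 + 1e-9), 1e-6),
        max=1e6,
        vary="contour_length_nm" not in fixed,
    )
    if not p["lc"].vary and p["lc"].value <= xmax:
        raise ValueError("fixed contour length must exceed the largest extension")

    def residual(pars):
        return _model_force(x, pars["lp"].value, pars["lc"].value, kt) - f

    result = lmfit.minimize(residual, p, method="leastsq")
    lp_fit, lc_fit = result.params["lp"], result.params["lc"]
    fitted = WLCParams(float(lp_fit.value), float(lc_fit.value), temperature_K)
    stderr = {
        "persistence_length_nm": float(lp_fit.stderr) if lp_fit.stderr else float("nan"),
        "contour_length_nm": float(lc_fit.stderr) if lc_fit.stderr else float("nan"),
    }
    return WLCFit(
        params=fitted,
        param_uncertainties=stderr,
        residual_norm=float(np.sqrt(np.sum(np.asarray(result.residual) ** 2))),
        n_points=len(pts),
        fit_window=fit_window if fit_window is not None else (0, len(pts) - 1),
        fixed_mask={
            "persistence_length_nm": "persistence_length_nm" in fixed,
            "contour_length_nm": "contour_length_nm" in fixed,
        },
    )


def expected_contour_length(
    n_residues: int, rise_per_residue_nm: float = 0.32, linker_nm: float = 0.0
) -> float:
    """Back-of-envelope contour length: residues x rise + linker (nm).

    With 0.32 nm per amino acid, a 283-residue construct plus a 20 nm
    PEG/anchor linker gives ~110 nm.
    """
    if n_residues < 0:
        raise ValueError("n_residues must be >= 0")
    if rise_per_residue_nm < 0 or linker_nm < 0:
        raise ValueError("lengths must be >= 0")
    return n_residues * rise_per_residue_nm + linker_nm
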