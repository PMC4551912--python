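"""Modified Hill model of promoter activity and its least-squares fit.

The transfer function relating maximum expression velocity to inducer
concentration I is

    v(I) = V_min + V_max * I^h / (I^h + K_L^h),

where V_max and V_min are the maximal and basal promoter activities, h the
Hill coefficient, and K_L the lumped half-maximal parameter. K_L is fitted as
a single lumped value; mechanistically it is the product K * K_d * K_p * T of
the promoter-binding equilibrium constant, the inducer-regulator dissociation
constant, the inducer partition coefficient, and the regulator concentration,
which cannot be deconvolved from dose-response data alone.

Parameter standard errors are the square roots of the diagonal of the
least-squares covariance matrix (residual-variance scaled).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .errors import FitError

_PARAM_NAMES = ("v_max", "v_min", "h", "k_half")


def hill_velocity(
    concentration,
    v_max: float,
    v_min: float,
    h: float,
    k_half: float,
):
    """Evaluate v(I); exact V_min at I = 0 and monotone non-decreasing in I
    for V_max >= 0. Vectorized over concentration."""
    c = np.asarray(concentration, dtype=float)
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        logc = np.where(c > 0, np.log(np.where(c > 0, c, 1.0)), 0.0)
        # I^h/(I^h+K^h) computed via the logistic of h*log(I/K) for stability
        occ = np.where(c > 0, 1.0 / (1.0 + np.exp(-h * (logc - np.log(k_half)))), 0.0)
    out = v_min + v_max * occ
    return float(out) if np.isscalar(concentration) else out


@dataclass
class HillFit:
    """Fitted transfer-function parameters with uncertainties."""

    v_max: float
    v_min: float
    h: float
    k_half: float
    se: dict[str, float]
    cov: np.ndarray
    rss: float
    n_points: int
    excluded_concentrations: tuple[float, ...] = ()
    n_restarts: int = 0

    @property
    def params(self) -> dict[str, float]:
        return {
            "v_max": self.v_max,
            "v_min": self.v_min,
            "h": self.h,
            "k_half": self.k_half,
        }

    def predict(self, concentration):
        return hill_velocity(concentration, self.v_max, self.v_min, self.h, self.k_half)


def _initial_guesses(conc: np.ndarray, vel: np.ndarray) -> list[np.ndarray]:
    """Multi-start initializations: Hill fits are multimodal in (h, K_L)."""
    vmax0 = float(vel.max() - vel.min())
    vmin0 = float(vel.min())
    nonzero = conc[conc > 0]
    k0 = float(np.exp(np.mean(np.log(nonzero))))
    inits = [np.array([vmax0, vmin0, 1.0, k0])]
    for kf in (0.1, 10.0):
        inits.append(np.array([vmax0, vmin0, 1.0, k0 * kf]))
    for h0 in (0.7, 2.0, 4.0):
        inits.append(np.array([vmax0, vmin0, h0, k0]))
    return inits


def fit_hill(
    concentrations: Sequence[float],
    velocities: Sequence[float],
    exclude: Sequence[float] = (),
    max_nfev: int = 20000,
) -> HillFit:
    """Non-linear least-squares fit of the modified Hill function to
    (concentration, max velocity) points.

    All replicate points are fitted individually so the covariance matrix
    reflects replicate scatter. ``exclude`` lists concentrations to omit
    before fitting (e.g. doses rejected for toxicity); matching is by
    np.isclose. Parameters are unbounded (a plain least-squares fit), so a
    slightly negative basal velocity is reported rather than clipped.
    """
    conc = np.asarray(concentrations, dtype=float)
    vel = np.asarray(velocities, dtype=float)
    if conc.shape != vel.shape:
        raise ValueError("concentrations and velocities must have equal length")
    keep = np.ones(conc.size, dtype=bool)
    excluded = []
    for x in exclude:
        hit = np.isclose(conc, x, rtol=1e-9, atol=0.0)
        if hit.any():
            keep &= ~hit
            excluded.append(float(x))
    conc, vel = conc[keep], vel[keep]
    n_distinct = np.unique(conc).size
    if n_distinct < 4:
        raise FitError(
            f"need >= 4 distinct concentrations after exclusion, got {n_distinct}"
        )
    if np.ptp(vel) == 0.0:
        raise FitError("degenerate fit: all velocities are equal")

    best = None
    best_rss = np.inf
    n_ok = 0
    for p0 in _initial_guesses(conc, vel):
        try:
            popt, pcov = curve_fit(
                hill_velocity, conc, vel, p0=p0, maxfev=max_nfev
            )
        except (RuntimeError, ValueError):
            continue
        if not np.all(np.isfinite(popt)) or popt[2] <= 0 or popt[3] <= 0:
            continue
        rss = float(np.sum((vel - hill_velocity(conc, *popt)) ** 2))
        n_ok += 1
        if best is None or rss < best_rss:
            best, best_rss = (popt, pcov), rss
    if best is None:
        raise FitError("Hill fit failed to converge from every start", best_rss=None)
    popt, pcov = best
    se = {
        name: float(np.sqrt(pcov[i, i])) if np.isfinite(pcov[i, i]) else float("nan")
        for i, name in enumerate(_PARAM_NAMES)
    }
    return HillFit(
        v_max=float(popt[0]),
        v_min=float(popt[1]),
        h=float(popt[2]),
        k_half=float(popt[3]),
        se=se,
        cov=np.asarray(pcov),
        rss=best_rss,
        n_points=int(conc.size),
        excluded_concentrations=tuple(excluded),
        n_restarts=n_ok,
    )


@dataclass(frozen=True)
class LumpedDecomposition:
    """Documentation-grade decomposition of K_L into K * K_d * K_p * T."""

    K: float | None = None  # promoter-binding equilibrium constant
    K_d: float | None = None  # inducer-regulator dissociation constant
    K_p: float | None = None  # intracellular/extracellular partition coefficient
    T: float | None = None  # regulator concentration


def compose_half_max(decomp: LumpedDecomposition) -> float:
    """Compose the lumped half-maximal parameter from its four factors."""
    factors = (decomp.K, decomp.K_d, decomp.K_p, decomp.T)
    if any(f is None for f in factors):
        raise ValueError("all four factors must be present to compose K_L")
    return float(np.prod([float(f) for f in factors]))


def decomposition_consistent(
    decomp: LumpedDecomposition, k_half: float, rtol: float = 0.01
) -> bool:
    """Check a stored K_L against the composed product (mismatch > rtol flags
    inconsistency)."""
    return bool(np.isclose(compose_half_max(decomp), k_half, rtol=rtol, atol=0.0))
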