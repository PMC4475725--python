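"""Auxiliary relaxometry: decay fits, R1rho conversion, NOE, shift slopes.

Routine single-residue relaxation computations that sit around the exchange
analysis: weighted exponential-decay fits (15N R1, R1rho, translational
diffusion), conversion of rotating-frame R1rho rates to R2, steady-state
heteronuclear NOE ratios with error propagation, R_2,eff from peak
intensities, amide-proton temperature coefficients with the hydrogen-bond
cutoff, and concentration-scaling slopes of matched rate sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "DecayFitter",
    "fit_decay",
    "r1rho_to_r2",
    "het_noe",
    "r2eff_from_intensities",
    "temp_coefficient",
    "TempCoefficient",
    "scaling_slope",
    "ScalingSlope",
    "TEMPCO_CUTOFF_PPB_PER_K",
]

# amide 1H temperature-coefficient cutoff separating hydrogen-bonded
# (protected) amides from solvent-exposed ones, ppb/K
TEMPCO_CUTOFF_PPB_PER_K = -4.6


class DecayFitter(BaseEstimator):
    """Weighted least-squares fit of a single-exponential decay.

    Model: I(x) = I0 exp(-rate * x), where x is a relaxation delay (s) for
    R1/R1rho series or a squared gradient strength (G^2) for translational
    diffusion, in which case ``rate`` is the diffusion decay constant d.

    Attributes
    ----------
    rate_, rate_sigma_ : fitted decay rate and its covariance error
    i0_, i0_sigma_ : fitted amplitude and error
    flags_ : ["non_decaying"] when the best rate is <= 0
    """

    def __init__(self, allow_negative=True):
        self.allow_negative = allow_negative

    def fit(self, x, intensities, sigmas=None):
        x = np.asarray(x, dtype=float)
        i_obs = np.asarray(intensities, dtype=float)
        if len(x) < 3:
            raise ValueError("need at least 3 points for a decay fit")
        if np.any(i_obs <= 0):
            raise ValueError("intensities must be positive")
        s = (np.ones_like(i_obs) if sigmas is None
             else np.asarray(sigmas, dtype=float))
        if np.any(s <= 0):
            raise ValueError("sigmas must be positive")
        # linearized start, then nonlinear refinement
        slope, logi0 = np.polyfit(x, np.log(i_obs), 1)
        lo_rate = -np.inf if self.allow_negative else 0.0

        def resid(p):
            return (p[0] * np.exp(-p[1] * x) - i_obs) / s

        res = least_squares(resid, [np.exp(logi0), -slope],
                            bounds=([0.0, lo_rate], [np.inf, np.inf]))
        j = res.jac
        try:
            cov = np.linalg.pinv(j.T @ j)
            if sigmas is None and len(x) > 2:
                cov = cov * 2 * res.cost / (len(x) - 2)
            perr = np.sqrt(np.clip(np.diag(cov), 0, None))
        except np.linalg.LinAlgError:
            perr = np.array([np.nan, np.nan])
        self.i0_, self.rate_ = float(res.x[0]), float(res.x[1])
        self.i0_sigma_, self.rate_sigma_ = float(perr[0]), float(perr[1])
        self.flags_ = ["non_decaying"] if self.rate_ <= 1e-12 else []
        return self


def fit_decay(x, intensities, sigmas=None):
    """Fit I = I0 exp(-rate x); returns (rate, i0, rate_sigma, flags)."""
    f = DecayFitter().fit(x, intensities, sigmas)
    return f.rate_, f.i0_, f.rate_sigma_, f.flags_


def r1rho_to_r2(r1rho: float, r1: float, delta: float, b_sl: float) -> float:
    """Convert a rotating-frame rate to R2 via the tilted-frame relation.

    R_1rho = R_2 cos^2(theta) + R_1 sin^2(theta) with
    theta = arctan(delta / B_SL), where delta is the resonance offset and
    B_SL the spin-lock strength (both Hz).  Note this is the convention in
    which theta is measured from the spin-lock direction; textbook
    treatments often quote the complementary angle with sin/cos swapped.
    """
    if b_sl <= 0:
        raise ValueError("spin-lock strength must be > 0 (Hz)")
    theta = np.arctan(delta / b_sl)
    c2 = np.cos(theta) ** 2
    if c2 < 1e-6:
        raise ValueError("pathological tilt angle: cos^2(theta) ~ 0")
    return float((r1rho - r1 * np.sin(theta) ** 2) / c2)


def het_noe(i_sat, i_unsat, sigma_sat=0.0, sigma_unsat=0.0):
    """Steady-state heteronuclear NOE = I_sat / I_unsat with ratio errors.

    Returns (noe, sigma) with
    sigma = |noe| sqrt((s_sat/I_sat)^2 + (s_unsat/I_unsat)^2).
    """
    if i_unsat == 0:
        raise ValueError("reference (unsaturated) intensity must be nonzero")
    noe = i_sat / i_unsat
    sig = 0.0
    if sigma_sat or sigma_unsat:
        if i_sat == 0:
            sig = abs(sigma_sat / i_unsat)
        else:
            sig = abs(noe) * np.sqrt(
                (sigma_sat / i_sat) ** 2 + (sigma_unsat / i_unsat) ** 2
            )
    return float(noe), float(sig)


def r2eff_from_intensities(i: float, i0: float, t_cpmg: float) -> float:
    """R_2,eff = -(1/T_CPMG) ln(I / I0) from constant-time peak intensities."""
    if i <= 0 or i0 <= 0:
        raise ValueError("intensities must be positive")
    if t_cpmg <= 0:
        raise ValueError("t_cpmg must be positive")
    return float(-np.log(i / i0) / t_cpmg)


@dataclass(frozen=True)
class TempCoefficient:
    slope_ppb_per_k: float
    sigma: float
    intercept_ppm: float
    protected: bool  # hydrogen-bonded classification (slope > cutoff)


def temp_coefficient(temperatures_k, shifts_ppm,
                     cutoff=TEMPCO_CUTOFF_PPB_PER_K) -> TempCoefficient:
    """Amide 1H temperature coefficient (ppb/K) by ordinary least squares.

    Amides with slopes above the cutoff (default -4.6 ppb/K) are classified
    as hydrogen-bonded/protected; a slope exactly at the cutoff is not
    (strict inequality).
    """
    t = np.asarray(temperatures_k, dtype=float)
    d = np.asarray(shifts_ppm, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 temperatures")
    coef, cov = np.polyfit(t, d, 1, cov="unscaled")
    # rescale covariance by residual variance when there are enough points;
    # with exactly 3 points polyfit's scaled covariance is singular-prone
    resid = d - np.polyval(coef, t)
    dof = len(t) - 2
    scale = float(resid @ resid) / dof if dof > 0 else 0.0
    slope_ppb = 1000.0 * coef[0]
    sig = 1000.0 * float(np.sqrt(max(cov[0, 0] * scale, 0.0)))
    return TempCoefficient(
        slope_ppb_per_k=float(slope_ppb), sigma=sig,
        intercept_ppm=float(coef[1]), protected=bool(slope_ppb > cutoff),
    )


@dataclass(frozen=True)
class ScalingSlope:
    slope: float
    intercept: float
    slope_sigma: float
    intercept_sigma: float
    diffusion_ratio: float | None = None

    @property
    def viscosity_consistent(self) -> bool | None:
        """Is the slope within 2 sigma of the supplied diffusion-coefficient
        ratio (i.e. rate differences explained by viscosity alone)?"""
        if self.diffusion_ratio is None:
            return None
        return bool(abs(self.slope - self.diffusion_ratio)
                    <= 2 * self.slope_sigma)


def scaling_slope(rates_x, rates_y, diffusion_ratio=None) -> ScalingSlope:
    """Least-squares line y = m x + c through matched per-residue rates.

    Used to test whether relaxation rates at two protein concentrations
    differ only by solution viscosity: the fitted slope is compared against
    an independently measured ratio of translational diffusion coefficients.
    """
    x = np.asarray(rates_x, dtype=float)
    y = np.asarray(rates_y, dtype=float)
    if len(x) != len(y):
        raise ValueError("rate sets must be matched")
    if len(x) < 3:
        raise ValueError("need at least 3 matched residues")
    if np.std(x) < 1e-12:
        raise ValueError("degenerate x variance")
    coef, cov = np.polyfit(x, y, 1, cov=True)
    return ScalingSlope(
        slope=float(coef[0]), intercept=float(coef[1]),
        slope_sigma=float(np.sqrt(cov[0, 0])),
        intercept_sigma=float(np.sqrt(cov[1, 1])),
        diffusion_ratio=diffusion_ratio,
    )
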