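"""Monomer-dimer mass-action thermodynamics of transient oligomerization.

Fitted two-state exchange parameters (p_D, k_ex) from relaxation dispersion
are only apparent quantities: for a dimerizing protein they recast into
association/dissociation rate constants and an equilibrium constant once the
total subunit concentration is known.  Two stoichiometric bookkeepings are
supported:

* symmetric dimer, 2M <-> D: k_ex = 2 k_MD [M] + k_DM and
  p_D = 2[D] / (2[D] + [M]) (fraction of subunits in dimer);
* asymmetric dimer (the spin probe's environment changes in only one of the
  two subunits): k_ex = k_MD [M] + k_DM and p_D = [D] / ([D] + [M])
  (fraction of molecules).

Concentrations are in mM throughout; K_MD (dimer formation) in mM^-1 and
K_diss = 1/K_MD in mM.  Temperature dependence is analyzed van't
Hoff-style: ln K (or ln k) against 1/T in kelvin, fitted independently per
temperature upstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DimerEquilibrium",
    "solve_symmetric",
    "solve_asymmetric",
    "equilibrium_from_rates",
    "rates_from_fit_symmetric",
    "rates_from_fit_asymmetric",
    "vant_hoff",
]


@dataclass(frozen=True)
class DimerEquilibrium:
    """A monomer-dimer equilibrium at one sample condition."""

    c_total: float  # total subunit concentration, mM
    m_conc: float  # free monomer [M], mM
    d_conc: float  # dimer [D], mM
    p_d: float  # dimer fraction (subunit or molecule bookkeeping per mode)
    k_md: float  # association rate constant, mM^-1 s^-1 (nan if unknown)
    k_dm: float  # dissociation rate, s^-1 (nan if unknown)
    k_eq: float  # K_MD, mM^-1
    mode: str  # "symmetric" | "asymmetric"

    def __post_init__(self):
        if self.c_total <= 0 or self.m_conc < 0 or self.d_conc < 0:
            raise ValueError("concentrations must be positive")
        if abs(self.m_conc + 2 * self.d_conc - self.c_total) > 1e-9 * self.c_total:
            raise ValueError("mass conservation violated: [M] + 2[D] != C_total")
        if self.d_conc > 0:
            resid = self.k_diss * self.d_conc - self.m_conc**2
            if abs(resid) > 1e-6 * max(self.m_conc**2, 1e-30):
                raise ValueError("equilibrium condition K_diss [D] = [M]^2 violated")

    @property
    def k_diss(self) -> float:
        """Dimer dissociation constant K_diss = 1/K_MD = [M]^2/[D], mM."""
        return 1.0 / self.k_eq

    @property
    def k_ex(self) -> float:
        """Apparent two-state exchange rate for a spin probe, s^-1."""
        if self.mode == "symmetric":
            return 2.0 * self.k_md * self.m_conc + self.k_dm
        return self.k_md * self.m_conc + self.k_dm

    @property
    def tau_d(self) -> float:
        """Dimer lifetime 1/k_DM, s."""
        return 1.0 / self.k_dm


def solve_symmetric(c_total: float, k_diss: float,
                    k_dm: float = np.nan) -> DimerEquilibrium:
    """Mass-action solution of 2M <-> D at a given K_diss (mM).

    [M] is the positive root of 2[M]^2 + K_diss [M] - K_diss C = 0:
    [M] = (-K_diss + sqrt(K_diss^2 + 8 K_diss C)) / 4; [D] = (C - [M])/2;
    p_D = 2[D]/C is the fraction of subunits in dimeric form.  Supplying the
    dissociation rate ``k_dm`` also fixes k_MD = k_DM / K_diss.
    """
    if c_total <= 0 or k_diss <= 0:
        raise ValueError("c_total and k_diss must be positive")
    # numerically stable root of 2[M]^2 + K[M] - KC = 0 (no cancellation
    # for weak association), with [D] from the equilibrium condition
    m = 2.0 * c_total / (1.0 + np.sqrt(1.0 + 8.0 * c_total / k_diss))
    d = m * m / k_diss
    return DimerEquilibrium(
        c_total=m + 2.0 * d, m_conc=m, d_conc=d, p_d=2.0 * d / (m + 2.0 * d),
        k_md=k_dm / k_diss, k_dm=k_dm, k_eq=1.0 / k_diss, mode="symmetric",
    )


def solve_asymmetric(c_total: float, k_diss: float,
                     k_dm: float = np.nan) -> DimerEquilibrium:
    """Mass-action solution with molecule bookkeeping p_D = [D]/([D]+[M]).

    Mass conservation is still on subunits ([M] + 2[D] = C): [M] solves
    (2/K_diss)[M]^2 + [M] - C = 0.
    """
    if c_total <= 0 or k_diss <= 0:
        raise ValueError("c_total and k_diss must be positive")
    k = 1.0 / k_diss
    m = 2.0 * c_total / (1.0 + np.sqrt(1.0 + 8.0 * k * c_total))
    d = k * m * m
    return DimerEquilibrium(
        c_total=m + 2.0 * d, m_conc=m, d_conc=d, p_d=d / (d + m),
        k_md=k_dm / k_diss, k_dm=k_dm, k_eq=k, mode="asymmetric",
    )


def equilibrium_from_rates(mode: str, c_total: float, k_diss: float,
                           k_dm: float) -> DimerEquilibrium:
    """Equilibrium at a condition from (K_diss, k_DM); used by joint fitting."""
    if mode == "symmetric":
        return solve_symmetric(c_total, k_diss, k_dm)
    if mode == "asymmetric":
        return solve_asymmetric(c_total, k_diss, k_dm)
    raise ValueError("mode must be 'symmetric' or 'asymmetric'")


def rates_from_fit_symmetric(p_d: float, k_ex: float,
                             c_total: float) -> DimerEquilibrium:
    """Invert a fitted (p_D, k_ex) under the symmetric-dimer relations.

    k_DM = (1 - p_D) k_ex; 2 k_MD [M] = p_D k_ex with [M] = (1 - p_D) C;
    K_diss = k_DM / k_MD = 2 C (1 - p_D)^2 / p_D.
    """
    if not (0 < p_d < 1):
        raise ValueError("p_d must lie strictly in (0, 1)")
    if c_total <= 0 or k_ex <= 0:
        raise ValueError("c_total and k_ex must be positive")
    k_dm = (1.0 - p_d) * k_ex
    m = (1.0 - p_d) * c_total
    k_md = p_d * k_ex / (2.0 * m)
    d = (c_total - m) / 2.0
    return DimerEquilibrium(
        c_total=c_total, m_conc=m, d_conc=d, p_d=p_d,
        k_md=k_md, k_dm=k_dm, k_eq=k_md / k_dm, mode="symmetric",
    )


def rates_from_fit_asymmetric(p_d: float, k_ex: float,
                              c_total: float) -> DimerEquilibrium:
    """Invert a fitted (p_D, k_ex) under the asymmetric-dimer relations.

    k_DM = (1 - p_D) k_ex and k_MD [M] = p_D k_ex.  The free monomer
    concentration is taken as [M] = (1 - p_D) C, the small-p_D limit of the
    molecule bookkeeping.
    """
    if not (0 < p_d < 1):
        raise ValueError("p_d must lie strictly in (0, 1)")
    if c_total <= 0 or k_ex <= 0:
        raise ValueError("c_total and k_ex must be positive")
    k_dm = (1.0 - p_d) * k_ex
    m = (1.0 - p_d) * c_total
    k_md = p_d * k_ex / m
    d = k_md / k_dm * m * m  # = K_MD [M]^2
    # report with consistent subunit mass balance for the stored fields
    return DimerEquilibrium(
        c_total=m + 2 * d, m_conc=m, d_conc=d, p_d=p_d,
        k_md=k_md, k_dm=k_dm, k_eq=k_md / k_dm, mode="asymmetric",
    )


def vant_hoff(temperatures_k, values, sigmas=None):
    """Weighted linear regression of ln(value) on 1/T (kelvin).

    For an equilibrium constant the slope equals -dH/R.  Returns
    ``(slope, intercept, slope_sigma, intercept_sigma)``.
    """
    t = np.asarray(temperatures_k, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(t) < 2:
        raise ValueError("need at least two temperatures")
    if np.any(v <= 0):
        raise ValueError("values must be positive to take logarithms")
    x = 1.0 / t
    y = np.log(v)
    if sigmas is None:
        w = np.ones_like(y)
    else:
        s = np.asarray(sigmas, dtype=float)
        if np.any(s <= 0):
            raise ValueError("sigmas must be positive")
        w = v / s  # sigma_lnK = sigma_K / K
    a = np.vstack([x * w, w]).T
    b = y * w
    coef, *_ = np.linalg.lstsq(a, b, rcond=None)
    try:
        cov = np.linalg.inv(a.T @ a)
        if sigmas is None and len(t) > 2:
            resid = b - a @ coef
            cov = cov * float(resid @ resid) / (len(t) - 2)
        sig = np.sqrt(np.diag(cov))
    except np.linalg.LinAlgError:
        sig = np.array([np.nan, np.nan])
    return float(coef[0]), float(coef[1]), float(sig[0]), float(sig[1])
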