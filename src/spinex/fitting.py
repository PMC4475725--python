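"""Least-squares fitting of CEST and CPMG profiles to exchange models.

Fitters are scikit-learn style estimators: construct with hyperparameters,
call ``fit(profiles)``, read fitted attributes (trailing underscore) or the
collected :class:`FitResult`.  Module-level functions wrap the estimators.

The three-state analysis follows a staged protocol: an exhaustive grid
search over (k_AB,ex, k_BC,ex, p_H, p_I) with the ground-to-excited shift
difference fixed from CEST dip positions and only per-residue nuisance
parameters (hidden-state shift, intrinsic rates) optimized at each node,
followed by unconstrained refinement started from the best grid nodes.

All uncertainties are 1-sigma covariance-matrix errors from the weighted
Jacobian at the solution; chi2_red is the error-normalized sum of squared
residuals divided by (n_data - n_free_params).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

from . import thermo
from .exchange import (
    CESTProfile,
    DispersionProfile,
    ExchangeModel,
    build_three_state,
    build_two_state,
    simulate_cest,
    simulate_cpmg,
)

__all__ = [
    "FitResult",
    "GridSpec",
    "Chi2Surface",
    "TwoStateFitter",
    "DimerLinkedFitter",
    "ThreeStateGridSearch",
    "ThreeStateRefiner",
    "GaussianDipExtractor",
    "DipSet",
    "fit_two_state",
    "grid_search_three_state",
    "refine_three_state",
    "state_lifetime",
    "extract_dips",
    "estimate_cest_noise",
    "duplicate_errors",
    "BOUNDS",
]

# default parameter bounds (external scale)
BOUNDS = {
    "population": (1e-4, 0.5),
    "k_ex": (1.0, 1e5),  # s^-1
    "dw": (-30.0, 30.0),  # ppm
    "rate": (0.1, 100.0),  # intrinsic R1/R2, s^-1
    "k_diss": (1e-2, 1e4),  # mM
}


@dataclass
class FitResult:
    """Outcome of a least-squares exchange fit."""

    params: dict[str, float]
    errors: dict[str, float]
    chi2_red: float
    n_data: int
    n_params: int
    model_kind: str
    flags: list[str] = field(default_factory=list)
    scheme: int | None = None

    def __post_init__(self):
        if not np.isfinite(self.chi2_red) or self.chi2_red < 0:
            raise ValueError("chi2_red must be finite and non-negative")

    @property
    def lifetimes(self) -> dict[str, float]:
        """Derived excited-state lifetimes (s) from the fitted rates."""
        out = {}
        if "p_e" in self.params and "k_ex" in self.params:
            k_eg = (1.0 - self.params["p_e"]) * self.params["k_ex"]
            if k_eg > 0:
                out["tau_e"] = 1.0 / k_eg
        if "k_dm" in self.params and self.params["k_dm"] > 0:
            out["tau_d"] = 1.0 / self.params["k_dm"]
        if self.scheme is not None and "p_h" in self.params:
            try:
                out["tau_h"] = _tau_h_from_params(self.scheme, self.params)
            except (KeyError, ZeroDivisionError):
                pass
        return out

    def as_dict(self) -> dict:
        d = {
            "params": dict(self.params),
            "errors": dict(self.errors),
            "chi2_red": self.chi2_red,
            "n_data": self.n_data,
            "n_params": self.n_params,
            "model_kind": self.model_kind,
            "flags": list(self.flags),
            "lifetimes": self.lifetimes,
        }
        if self.scheme is not None:
            d["scheme"] = self.scheme
        return d


def _tau_h_from_params(scheme: int, params: Mapping[str, float]) -> float:
    """Lifetime of the excited state H: tau_H = 1/k_off,H.

    For the chain N-I-H (scheme 1) the only exit from H is to I:
    k_off,H = k_BC,ex * p_I/(p_H + p_I); for I-N-H (scheme 2) H exits to N;
    for N-H-I (scheme 3) H exits both to N and to I.
    """
    p_h, p_i = params["p_h"], params["p_i"]
    p_n = 1.0 - p_h - p_i
    k_ab, k_bc = params["k_ab_ex"], params["k_bc_ex"]
    if scheme == 1:
        k_off = k_bc * p_i / (p_h + p_i)
    elif scheme == 2:
        k_off = k_bc * p_n / (p_n + p_h)
    elif scheme == 3:
        k_off = k_ab * p_n / (p_n + p_h) + k_bc * p_i / (p_h + p_i)
    else:
        raise KeyError(scheme)
    if k_off <= 0:
        raise ZeroDivisionError("zero exit rate: infinite lifetime")
    return 1.0 / k_off


def state_lifetime(obj, state: str) -> float:
    """Lifetime (s) of ``state``: 1 / (sum of exit rates from the state).

    ``obj`` may be an :class:`ExchangeModel` (exit rates read off the
    generator diagonal) or a three-state :class:`FitResult` (rates derived
    from the fitted edge k_ex values and populations).
    """
    if isinstance(obj, ExchangeModel):
        try:
            i = obj.state_labels.index(state)
        except ValueError:
            raise ValueError(f"state {state!r} not in model") from None
        exit_rate = -obj.rate_matrix[i, i]
        if exit_rate <= 0:
            raise ValueError(f"state {state!r} has zero exit rate (infinite lifetime)")
        return 1.0 / exit_rate
    if isinstance(obj, FitResult):
        if obj.scheme is not None and state == "H":
            return _tau_h_from_params(obj.scheme, obj.params)
        if state in ("E", "D") and obj.lifetimes:
            key = "tau_e" if state == "E" else "tau_d"
            if key in obj.lifetimes:
                return obj.lifetimes[key]
        raise ValueError(f"cannot derive lifetime of {state!r} from this fit")
    raise TypeError("expected ExchangeModel or FitResult")


# ---------------------------------------------------------------------------
# parameter vector plumbing


class _ParamVector:
    """Named parameter vector with per-parameter bounds and log10 scaling."""

    def __init__(self):
        self.names: list[str] = []
        self.x0: list[float] = []
        self.lo: list[float] = []
        self.hi: list[float] = []
        self.log: list[bool] = []

    def add(self, name, x0, bounds, log=False):
        lo, hi = bounds
        x0 = min(max(x0, lo * 1.0000001), hi * 0.9999999)
        if log:
            x0, lo, hi = np.log10(x0), np.log10(lo), np.log10(hi)
        self.names.append(name)
        self.x0.append(float(x0))
        self.lo.append(float(lo))
        self.hi.append(float(hi))
        self.log.append(log)

    def decode(self, x) -> dict[str, float]:
        return {
            n: (float(10.0**v) if lg else float(v))
            for n, v, lg in zip(self.names, x, self.log)
        }

    def scale_errors(self, x, sig_internal) -> dict[str, float]:
        out = {}
        for n, v, s, lg in zip(self.names, x, sig_internal, self.log):
            out[n] = float(s * 10.0**v * np.log(10.0)) if lg else float(s)
        return out


def _covariance_sigmas(res) -> np.ndarray:
    """1-sigma errors from the weighted Jacobian at the solution."""
    j = res.jac
    try:
        cov = np.linalg.pinv(j.T @ j)
        return np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        return np.full(j.shape[1], np.nan)


def _simulate_for_profile(model: ExchangeModel, profile) -> np.ndarray:
    if isinstance(profile, CESTProfile):
        return simulate_cest(model, profile.experiment).intensity_ratio
    return simulate_cpmg(model, profile.experiment).r2_eff


def _observed(profile) -> np.ndarray:
    return (
        profile.intensity_ratio
        if isinstance(profile, CESTProfile)
        else profile.r2_eff
    )


def _check_profiles(profiles) -> list:
    profiles = list(profiles)
    if not profiles:
        raise ValueError("need at least one profile")
    for p in profiles:
        if np.any(p.errors <= 0):
            raise ValueError(
                f"profile {p.residue_id}: errors must be positive for fitting"
            )
    return profiles


def _residue_order(profiles) -> list[str]:
    seen: dict[str, None] = {}
    for p in profiles:
        seen.setdefault(str(p.residue_id), None)
    return list(seen)


class _ExchangeFitterBase(BaseEstimator):
    """Shared multi-start trust-region least-squares machinery."""

    def _minimize(self, pv: _ParamVector, residual_fn, rng: np.random.Generator):
        x0 = np.asarray(pv.x0, dtype=float)
        lo, hi = np.asarray(pv.lo), np.asarray(pv.hi)
        best = None
        n_data = len(residual_fn(x0))
        dof = max(n_data - len(x0), 1)
        for start in range(max(self.n_starts, 1)):
            if start == 0:
                xs = x0
            else:
                span = np.minimum(hi - lo, 4.0)
                xs = np.clip(x0 + rng.normal(0, 1, len(x0)) * 0.05 * span, lo, hi)
            try:
                res = least_squares(
                    residual_fn, xs, bounds=(lo, hi), method="trf",
                    ftol=1e-10, xtol=1e-8, gtol=1e-10,
                )
            except (ValueError, np.linalg.LinAlgError):
                continue
            if best is None or res.cost < best.cost:
                best = res
            if 2 * best.cost / dof <= self.chi2_accept:
                break
        if best is None:
            raise RuntimeError("all optimization starts failed")
        return best, n_data, dof


# ---------------------------------------------------------------------------
# two-state fitter


class TwoStateFitter(_ExchangeFitterBase):
    """Global two-state exchange fit of CEST and/or CPMG profiles.

    Parameters
    ----------
    shared : tuple of str
        Exchange parameters shared across all supplied profiles; any of
        ``("p_e", "k_ex")`` not listed is fitted per residue instead.
    init : dict or None
        Starting-value overrides: ``p_e``, ``k_ex``, ``dw`` (scalar or
        mapping residue -> ppm), ``r2``, ``r1``.
    n_starts : int
        Multi-start count; perturbed restarts stop early once
        chi2_red <= ``chi2_accept``.
    seed : int
        Seed for restart perturbations (the fit is otherwise deterministic
        given the data).

    Attributes
    ----------
    result_ : FitResult
    p_e_, k_ex_ : fitted global exchange parameters (when shared)
    dw_ : dict residue -> fitted shift difference, ppm
    chi2_red_ : float
    """

    def __init__(self, shared=("p_e", "k_ex"), init=None, n_starts=5,
                 chi2_accept=1.3, seed=0):
        self.shared = shared
        self.init = init
        self.n_starts = n_starts
        self.chi2_accept = chi2_accept
        self.seed = seed

    def _build_vector(self, profiles, residues):
        init = dict(self.init or {})
        pv = _ParamVector()
        for scope in (["global"] if "p_e" in self.shared else residues):
            pv.add(f"p_e[{scope}]", init.get("p_e", 0.02), BOUNDS["population"])
        for scope in (["global"] if "k_ex" in self.shared else residues):
            pv.add(f"k_ex[{scope}]", init.get("k_ex", 500.0), BOUNDS["k_ex"],
                   log=True)
        dw_init = init.get("dw", {})
        for r in residues:
            d0 = dw_init.get(r, 2.0) if isinstance(dw_init, Mapping) else dw_init
            pv.add(f"dw[{r}]", d0 if d0 else 2.0, BOUNDS["dw"])
        for i, p in enumerate(profiles):
            if isinstance(p, DispersionProfile):
                pv.add(f"r2[{i}]", init.get("r2", max(float(np.min(p.r2_eff)), 0.5)),
                       BOUNDS["rate"])
            else:
                top = float(np.max(p.intensity_ratio))
                r1_0 = init.get(
                    "r1",
                    -np.log(min(max(top, 1e-3), 0.999)) / p.experiment.t_cest,
                )
                pv.add(f"r2[{i}]", init.get("r2", 12.0), BOUNDS["rate"])
                pv.add(f"r1[{i}]", max(r1_0, 0.2), BOUNDS["rate"])
        return pv

    def fit(self, profiles):
        profiles = _check_profiles(profiles)
        residues = _residue_order(profiles)
        pv = self._build_vector(profiles, residues)

        def residual(x):
            q = pv.decode(x)
            out = []
            for i, p in enumerate(profiles):
                r = str(p.residue_id)
                p_e = q.get("p_e[global]", q.get(f"p_e[{r}]"))
                k_ex = q.get("k_ex[global]", q.get(f"k_ex[{r}]"))
                m = build_two_state(
                    p_e, 1.0 / ((1.0 - p_e) * k_ex),
                    shifts=[0.0, q[f"dw[{r}]"]],
                    r1=q.get(f"r1[{i}]", 1.0), r2=q[f"r2[{i}]"],
                )
                out.append((_simulate_for_profile(m, p) - _observed(p)) / p.errors)
            return np.concatenate(out)

        rng = np.random.default_rng(self.seed)
        best, n_data, dof = self._minimize(pv, residual, rng)
        params = pv.decode(best.x)
        sig = pv.scale_errors(best.x, _covariance_sigmas(best))
        flags = [] if best.success else ["non_converged"]
        lo, hi = BOUNDS["population"]
        for k in (k for k in params if k.startswith("p_e")):
            if params[k] <= lo * 1.01 or params[k] >= hi * 0.99:
                flags.append(f"{k}_at_bound")
        clean = {k.replace("[global]", ""): v for k, v in params.items()}
        clean_sig = {k.replace("[global]", ""): v for k, v in sig.items()}
        self.result_ = FitResult(
            params=clean, errors=clean_sig, chi2_red=float(2 * best.cost / dof),
            n_data=n_data, n_params=len(pv.names), model_kind="two_state",
            flags=flags,
        )
        self.p_e_ = clean.get("p_e")
        self.k_ex_ = clean.get("k_ex")
        self.dw_ = {r: clean[f"dw[{r}]"] for r in residues}
        self.chi2_red_ = self.result_.chi2_red
        return self


def fit_two_state(profiles, init=None, shared=("p_e", "k_ex"), **kw) -> FitResult:
    """Fit profiles to a two-state exchange model; see :class:`TwoStateFitter`."""
    return TwoStateFitter(shared=shared, init=init, **kw).fit(profiles).result_


# ---------------------------------------------------------------------------
# concentration-linked (monomer-dimer) fitter


class DimerLinkedFitter(_ExchangeFitterBase):
    """Joint fit of profiles across protein concentrations under mass action.

    The excited-state population at each concentration is tied to a single
    dimer dissociation constant K_diss: p_D and k_ex at each condition follow
    from the mass-action solution and (K_diss, k_DM); see :mod:`spinex.thermo`
    for the symmetric and asymmetric bookkeeping.  Global parameters are
    K_diss (mM) and the dimer dissociation rate k_DM (s^-1); shift
    differences are per residue, intrinsic rates per profile.  Every profile
    must carry a :class:`~spinex.exchange.Condition` with its concentration.
    """

    def __init__(self, mode="symmetric", init=None, n_starts=5,
                 chi2_accept=1.3, seed=0):
        self.mode = mode
        self.init = init
        self.n_starts = n_starts
        self.chi2_accept = chi2_accept
        self.seed = seed

    def fit(self, profiles):
        if self.mode not in ("symmetric", "asymmetric"):
            raise ValueError("mode must be 'symmetric' or 'asymmetric'")
        profiles = _check_profiles(profiles)
        for p in profiles:
            if p.condition is None:
                raise ValueError("DimerLinkedFitter requires profile conditions")
        residues = _residue_order(profiles)
        init = dict(self.init or {})
        pv = _ParamVector()
        pv.add("k_diss", init.get("k_diss", 50.0), BOUNDS["k_diss"], log=True)
        pv.add("k_dm", init.get("k_dm", 300.0), BOUNDS["k_ex"], log=True)
        dw_init = init.get("dw", {})
        for r in residues:
            d0 = dw_init.get(r, 2.0) if isinstance(dw_init, Mapping) else dw_init
            pv.add(f"dw[{r}]", d0 if d0 else 2.0, BOUNDS["dw"])
        for i, p in enumerate(profiles):
            if isinstance(p, DispersionProfile):
                pv.add(f"r2[{i}]", max(float(np.min(p.r2_eff)), 0.5),
                       BOUNDS["rate"])
            else:
                top = float(np.max(p.intensity_ratio))
                r1_0 = -np.log(min(max(top, 1e-3), 0.999)) / p.experiment.t_cest
                pv.add(f"r2[{i}]", init.get("r2", 12.0), BOUNDS["rate"])
                pv.add(f"r1[{i}]", max(r1_0, 0.2), BOUNDS["rate"])

        def residual(x):
            q = pv.decode(x)
            out = []
            for i, p in enumerate(profiles):
                eq = thermo.equilibrium_from_rates(
                    self.mode, p.condition.concentration,
                    q["k_diss"], q["k_dm"],
                )
                m = build_two_state(
                    eq.p_d, 1.0 / ((1.0 - eq.p_d) * eq.k_ex),
                    shifts=[0.0, q[f"dw[{p.residue_id}]"]],
                    r1=q.get(f"r1[{i}]", 1.0), r2=q[f"r2[{i}]"],
                )
                out.append((_simulate_for_profile(m, p) - _observed(p)) / p.errors)
            return np.concatenate(out)

        rng = np.random.default_rng(self.seed)
        best, n_data, dof = self._minimize(pv, residual, rng)
        params = pv.decode(best.x)
        sig = pv.scale_errors(best.x, _covariance_sigmas(best))
        self.result_ = FitResult(
            params=params, errors=sig, chi2_red=float(2 * best.cost / dof),
            n_data=n_data, n_params=len(pv.names),
            model_kind=f"dimer_{self.mode}",
            flags=[] if best.success else ["non_converged"],
        )
        self.k_diss_ = params["k_diss"]
        self.k_dm_ = params["k_dm"]
        self.chi2_red_ = self.result_.chi2_red
        return self


# ---------------------------------------------------------------------------
# three-state grid search + refinement


@dataclass(frozen=True)
class GridSpec:
    """Axes of the (p_H, p_I, k_AB,ex, k_BC,ex) search grid."""

    p_h_axis: np.ndarray
    p_i_axis: np.ndarray
    k_ab_axis: np.ndarray
    k_bc_axis: np.ndarray

    def __post_init__(self):
        for name in ("p_h_axis", "p_i_axis", "k_ab_axis", "k_bc_axis"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))

    @classmethod
    def preset(cls, name: str) -> "GridSpec":
        """Per-process presets.

        ``process_I`` (transient dimerization): 11 log-spaced points spanning
        10-2016 s^-1 on both rate axes, 16 linear points 0.5-23% on both
        population axes.  ``process_II`` (local helix folding): 10 linear
        population points 0.5-14%, 16 log-spaced rate points 10-11529 s^-1.
        """
        if name == "process_I":
            rates = np.geomspace(10.0, 2016.0, 11)
            pops = np.linspace(0.005, 0.23, 16)
            return cls(pops, pops, rates, rates)
        if name == "process_II":
            rates = np.geomspace(10.0, 11529.0, 16)
            pops = np.linspace(0.005, 0.14, 10)
            return cls(pops, pops, rates, rates)
        raise ValueError(f"unknown preset {name!r}")

    @property
    def shape(self):
        return (len(self.p_h_axis), len(self.p_i_axis),
                len(self.k_ab_axis), len(self.k_bc_axis))

    def nodes(self):
        for idx in itertools.product(*map(range, self.shape)):
            ih, ii, ia, ib = idx
            yield idx, (self.p_h_axis[ih], self.p_i_axis[ii],
                        self.k_ab_axis[ia], self.k_bc_axis[ib])


@dataclass
class Chi2Surface:
    """chi2_red over the search grid, per residue and summed."""

    grid: GridSpec
    scheme: int
    per_residue: dict[str, np.ndarray]
    total: np.ndarray

    def top_seeds(self, n: int = 10) -> list[dict]:
        """Lowest-chi2 nodes ranked ascending; ties broken by smaller
        k_AB,ex then smaller k_BC,ex (prefer the better-determined
        slower-exchange regime)."""
        flat = []
        for idx, (p_h, p_i, k_ab, k_bc) in self.grid.nodes():
            flat.append((float(self.total[idx]), k_ab, k_bc, p_h, p_i))
        flat.sort(key=lambda t: (t[0], t[1], t[2]))
        return [
            {"chi2_red": c, "p_h": ph, "p_i": pi, "k_ab_ex": ka, "k_bc_ex": kb}
            for c, ka, kb, ph, pi in flat[:n]
        ]


def _inner_node_fit(profiles, scheme, p_h, p_i, k_ab, k_bc, dw_nh):
    """chi2_red at one grid node: optimize nuisance parameters only."""
    has_cest = any(isinstance(p, CESTProfile) for p in profiles)
    lo, hi = BOUNDS["rate"]

    def residual(x):
        dw_ni = x[0]
        r1n = x[4] if has_cest else 1.0
        m = build_three_state(
            scheme, p_h, p_i, k_ab, k_bc,
            shifts=[0.0, dw_ni, dw_nh], r1=r1n, r2=(x[1], x[3], x[2]),
        )
        return np.concatenate(
            [(_simulate_for_profile(m, p) - _observed(p)) / p.errors
             for p in profiles]
        )

    n_par = 5 if has_cest else 4
    n_data = sum(len(_observed(p)) for p in profiles)
    dof = max(n_data - n_par, 1)
    best = np.inf
    # two starts: hidden state resonating near the ground or near the
    # excited state (the two ways I escapes detection in a two-dip profile)
    for dw0 in (0.0, dw_nh):
        x0 = [dw0, 12.0, 12.0, 12.0] + ([1.0] if has_cest else [])
        lb = [BOUNDS["dw"][0]] + [lo] * (n_par - 1)
        ub = [BOUNDS["dw"][1]] + [hi] * (n_par - 1)
        try:
            # node fits only rank grid points; modest tolerances suffice
            res = least_squares(residual, x0, bounds=(lb, ub), method="trf",
                                ftol=1e-6, xtol=1e-6)
        except (ValueError, np.linalg.LinAlgError):
            continue
        best = min(best, 2 * res.cost / dof)
    return best


class ThreeStateGridSearch(BaseEstimator):
    """Stage one of the three-state protocol: exhaustive chi2_red surfaces.

    At each grid node (p_H, p_I, k_AB,ex, k_BC,ex), and per residue, only
    the hidden-state shift difference and intrinsic relaxation rates are
    optimized; the ground-to-excited shift ``dw_nh`` (ppm, per residue) is
    held fixed at the CEST dip separation.  Per-residue surfaces are summed;
    a failed inner fit records +inf at that node and the search continues.
    """

    def __init__(self, grid: GridSpec, schemes=(1, 2, 3)):
        self.grid = grid
        self.schemes = schemes

    def fit(self, profiles, dw_nh: Mapping[str, float]):
        profiles = _check_profiles(profiles)
        residues = _residue_order(profiles)
        by_res = {r: [p for p in profiles if str(p.residue_id) == r]
                  for r in residues}
        self.surfaces_ = {}
        for scheme in self.schemes:
            per_res = {r: np.full(self.grid.shape, np.inf) for r in residues}
            for idx, (p_h, p_i, k_ab, k_bc) in self.grid.nodes():
                for r in residues:
                    per_res[r][idx] = _inner_node_fit(
                        by_res[r], scheme, p_h, p_i, k_ab, k_bc, dw_nh[r]
                    )
            total = np.sum([per_res[r] for r in residues], axis=0)
            self.surfaces_[scheme] = Chi2Surface(
                grid=self.grid, scheme=scheme, per_residue=per_res, total=total
            )
        return self


def grid_search_three_state(profiles, grid, dw_nh,
                            schemes=(1, 2, 3)) -> dict[int, Chi2Surface]:
    """Grid-search chi2_red surfaces per scheme; see :class:`ThreeStateGridSearch`."""
    return ThreeStateGridSearch(grid, schemes=schemes).fit(
        profiles, dw_nh
    ).surfaces_


class ThreeStateRefiner(_ExchangeFitterBase):
    """Stage two: unconstrained refinement from the best grid nodes.

    All parameters vary: global (p_H, p_I, k_AB,ex, k_BC,ex), per-residue
    shift differences (dw_NH released from its CEST-fixed value, dw_NI free)
    and per-profile intrinsic rates.  The lowest-chi2_red solution over the
    supplied seeds is returned; identical seeds give identical results.
    """

    def __init__(self, scheme=1, n_starts=1, chi2_accept=0.0, seed=0):
        self.scheme = scheme
        self.n_starts = n_starts
        self.chi2_accept = chi2_accept
        self.seed = seed

    def fit(self, profiles, seeds, dw_nh: Mapping[str, float]):
        profiles = _check_profiles(profiles)
        residues = _residue_order(profiles)
        best_result = None
        for seed_node in seeds:
            pv = _ParamVector()
            pv.add("p_h", seed_node["p_h"], BOUNDS["population"])
            pv.add("p_i", seed_node["p_i"], BOUNDS["population"])
            pv.add("k_ab_ex", seed_node["k_ab_ex"], BOUNDS["k_ex"], log=True)
            pv.add("k_bc_ex", seed_node["k_bc_ex"], BOUNDS["k_ex"], log=True)
            for r in residues:
                pv.add(f"dw_nh[{r}]", dw_nh[r], BOUNDS["dw"])
                pv.add(f"dw_ni[{r}]", seed_node.get("dw_ni", 0.0), BOUNDS["dw"])
            for i, p in enumerate(profiles):
                pv.add(f"r2n[{i}]",
                       max(float(np.min(p.r2_eff)), 0.5)
                       if isinstance(p, DispersionProfile) else 12.0,
                       BOUNDS["rate"])
                pv.add(f"r2h[{i}]", 12.0, BOUNDS["rate"])
                pv.add(f"r2i[{i}]", 12.0, BOUNDS["rate"])
                if isinstance(p, CESTProfile):
                    pv.add(f"r1n[{i}]", 1.0, BOUNDS["rate"])

            def residual(x, pv=pv):
                q = pv.decode(x)
                out = []
                for i, p in enumerate(profiles):
                    r = str(p.residue_id)
                    m = build_three_state(
                        self.scheme, q["p_h"], q["p_i"],
                        q["k_ab_ex"], q["k_bc_ex"],
                        shifts=[0.0, q[f"dw_ni[{r}]"], q[f"dw_nh[{r}]"]],
                        r1=q.get(f"r1n[{i}]", 1.0),
                        r2=(q[f"r2n[{i}]"], q[f"r2i[{i}]"], q[f"r2h[{i}]"]),
                    )
                    out.append(
                        (_simulate_for_profile(m, p) - _observed(p)) / p.errors
                    )
                return np.concatenate(out)

            rng = np.random.default_rng(self.seed)
            try:
                res, n_data, dof = self._minimize(pv, residual, rng)
            except RuntimeError:
                continue
            chi2_red = float(2 * res.cost / dof)
            if best_result is None or chi2_red < best_result.chi2_red:
                params = pv.decode(res.x)
                sig = pv.scale_errors(res.x, _covariance_sigmas(res))
                best_result = FitResult(
                    params=params, errors=sig, chi2_red=chi2_red,
                    n_data=n_data, n_params=len(pv.names),
                    model_kind="three_state", scheme=self.scheme,
                    flags=[] if res.success else ["non_converged"],
                )
        if best_result is None:
            raise RuntimeError("refinement failed from every seed")
        self.result_ = best_result
        self.chi2_red_ = best_result.chi2_red
        return self


def refine_three_state(profiles, seeds, dw_nh, scheme=1, **kw) -> FitResult:
    """Refine a three-state fit from grid seeds; see :class:`ThreeStateRefiner`."""
    return ThreeStateRefiner(scheme=scheme, **kw).fit(
        profiles, seeds, dw_nh
    ).result_


# ---------------------------------------------------------------------------
# CEST dip utilities


@dataclass
class DipSet:
    """Gaussian dips fitted to a CEST profile, sorted by amplitude (desc)."""

    positions: np.ndarray  # ppm
    amplitudes: np.ndarray
    widths: np.ndarray  # Gaussian sigma, ppm
    baseline: float
    merged: bool = False

    @property
    def major(self) -> float:
        return float(self.positions[0])

    @property
    def minor_shift(self) -> float:
        """Shift difference x_minor - x_major (ppm) of the second dip."""
        if len(self.positions) < 2:
            raise ValueError("no minor dip resolved")
        return float(self.positions[1] - self.positions[0])


class GaussianDipExtractor(BaseEstimator):
    """Fit a CEST profile to a constant baseline minus a sum of Gaussians.

    Model: y(x) = b - sum_i A_i exp(-(x - x_i)^2 / (2 w_i^2)).  One extra
    broad component beyond ``n_dips`` is included to absorb the non-Gaussian
    saturation wings of the main dip, which otherwise bias the minor-dip
    center toward the major dip; only the ``n_dips`` dip components are
    reported.  Candidate centers come from the deepest smoothed local
    regions separated by at least ``min_separation`` ppm.  Dips whose fitted
    centers fall within one linewidth of a stronger dip, or whose amplitude
    collapses below ``min_amplitude``, are dropped and the result flagged
    as merged.
    """

    def __init__(self, n_dips=2, min_amplitude=1e-3, min_separation=1.2):
        self.n_dips = n_dips
        self.min_amplitude = min_amplitude
        self.min_separation = min_separation

    @staticmethod
    def _fit_components(x, y, sigma, centers, depth, step, span):
        """Fit len(centers) bounded dip Gaussians plus one broad auxiliary."""
        x0, lo, hi = [float(np.max(y))], [0.0], [2.0]
        # dip centers stay near their detected candidates and dip widths stay
        # dip-like; only the auxiliary component may be broad, so it cannot
        # swallow a dip while a dip component wanders into the baseline
        wiggle = max(1.0, 2 * step)
        for i in centers:
            x0 += [max(float(depth[i]), 0.01), float(x[i]), max(3 * step, 0.2)]
            lo += [0.0, float(x[i]) - wiggle, step / 2]
            hi += [2.0, float(x[i]) + wiggle, min(2.5, span)]
        # auxiliary broad component at the deepest dip (background wings)
        x0 += [0.05, float(x[centers[0]]), min(3.0, span)]
        lo += [0.0, float(x.min()) - 1.0, step / 2]
        hi += [2.0, float(x.max()) + 1.0, span]
        n_comp = len(centers) + 1

        def model(p):
            out = np.full_like(x, p[0], dtype=float)
            for k in range(n_comp):
                a, c, w = p[1 + 3 * k: 4 + 3 * k]
                out -= a * np.exp(-((x - c) ** 2) / (2 * w * w))
            return out

        res = least_squares(
            lambda p: (model(p) - y) / sigma, x0, bounds=(lo, hi), method="trf"
        )
        return res.x, model(res.x), float(res.cost)

    def fit(self, profile: CESTProfile):
        if self.n_dips not in (1, 2, 3):
            raise ValueError("n_dips must be 1, 2 or 3")
        from scipy.signal import find_peaks

        x = profile.offsets
        y = profile.intensity_ratio
        depth = 1.0 - y
        step = float(np.median(np.abs(np.diff(x)))) if len(x) > 1 else 0.1
        span = float(x.max() - x.min()) if len(x) > 1 else 1.0
        sigma = np.where(profile.errors > 0, profile.errors, 1.0)
        # ~1 ppm smoothing: wide enough to suppress point noise, narrow
        # enough not to smear a shoulder dip into the main saturation dip
        win = int(np.clip(round(1.0 / step), 1, min(7, len(x))))
        win += 1 - win % 2  # odd
        smooth = np.convolve(depth, np.ones(win) / win, mode="same")
        sep = max(self.min_separation, 3 * step)
        dist = max(int(np.ceil(sep / step)), 1)
        # first candidate: most prominent peak of the smoothed depth
        # (prominence, not raw depth, so shoulders/oscillation lobes of the
        # saturation dip do not masquerade as separate dips)
        peaks, props = find_peaks(smooth, distance=dist, prominence=0.0)
        if len(peaks):
            depth_ranked = [int(i) for i in peaks[np.argsort(-props["prominences"])]]
            centers = [depth_ranked[0]]
        else:
            depth_ranked = []
            centers = [int(np.argmax(smooth))]
        # Further dips are placed greedily: candidates come from both the
        # smoothed-depth ranking and the residual left after fitting the
        # dips found so far (a minor dip on the shoulder of the saturation
        # dip is often not a local extremum of the raw profile but stands
        # out once the fitted components are subtracted); each candidate is
        # tried with a full fit and the lowest-cost placement wins.
        while len(centers) < self.n_dips:
            _, fitted, _ = self._fit_components(x, y, sigma, centers, depth,
                                                step, span)
            resid = fitted - y  # positive where an unmodeled dip remains
            rsm = np.convolve(resid, np.ones(3) / 3.0, mode="same")
            rp, rprops = find_peaks(rsm, distance=dist, prominence=0.0)
            pool: list[int] = []
            for i in [int(j) for j in rp[np.argsort(-rprops["prominences"])][:3]] \
                    + depth_ranked[1:3]:
                if (all(abs(x[i] - x[j]) > sep for j in centers)
                        and i not in pool):
                    pool.append(i)
            if not pool:
                centers.append(centers[-1])
                continue
            best_cand, best_cost = pool[0], np.inf
            for cand in pool:
                _, _, cost = self._fit_components(
                    x, y, sigma, centers + [cand], depth, step, span)
                if cost < best_cost:
                    best_cand, best_cost = cand, cost
            centers.append(best_cand)
        p, _, _ = self._fit_components(x, y, sigma, centers, depth, step, span)
        amps = np.array([p[1 + 3 * k] for k in range(self.n_dips)])
        cens = np.array([p[2 + 3 * k] for k in range(self.n_dips)])
        wids = np.array([p[3 + 3 * k] for k in range(self.n_dips)])
        srt = np.argsort(-amps)
        amps, cens, wids = amps[srt], cens[srt], wids[srt]
        keep, merged = [0], False
        for k in range(1, self.n_dips):
            # "one linewidth" = FWHM of the wider of the pair
            lw = 2.355 * max(wids[k], max(wids[j] for j in keep))
            if amps[k] < self.min_amplitude or any(
                abs(cens[k] - cens[j]) < lw for j in keep
            ):
                merged = True
            else:
                keep.append(k)
        if merged and len(keep) < self.n_dips and len(keep) >= 1:
            # refit with fewer components so the surviving centers are not
            # distorted by a redundant Gaussian sharing one physical dip
            sub = GaussianDipExtractor(
                n_dips=len(keep), min_amplitude=self.min_amplitude,
                min_separation=self.min_separation,
            ).fit(profile)
            self.dips_ = DipSet(
                positions=sub.dips_.positions,
                amplitudes=sub.dips_.amplitudes,
                widths=sub.dips_.widths,
                baseline=sub.dips_.baseline,
                merged=True,
            )
            return self
        self.dips_ = DipSet(
            positions=cens[keep], amplitudes=amps[keep], widths=wids[keep],
            baseline=float(p[0]), merged=merged,
        )
        return self


def extract_dips(profile: CESTProfile, n_dips: int = 2) -> DipSet:
    """Positions/widths/amplitudes of CEST dips via a sum-of-Gaussians fit."""
    return GaussianDipExtractor(n_dips=n_dips).fit(profile).dips_


def estimate_cest_noise(profile: CESTProfile, baseline_mask=None) -> float:
    """Noise sigma of a CEST profile from the scatter in its baseline.

    ``baseline_mask`` selects offsets far from all dips; if omitted, points
    with intensity ratio within 25% of the profile's dynamic range of its
    maximum are used.  A linear trend is removed before taking the standard
    deviation, so a constant or sloped baseline does not inflate the result.
    """
    y = profile.intensity_ratio
    x = profile.offsets
    if baseline_mask is None:
        rng_ = np.max(y) - np.min(y)
        baseline_mask = y >= np.max(y) - 0.25 * (rng_ + 1e-12)
    mask = np.asarray(baseline_mask, bool)
    if mask.sum() < 5:
        raise ValueError("need at least 5 baseline points")
    coeff = np.polyfit(x[mask], y[mask], 1)
    resid = y[mask] - np.polyval(coeff, x[mask])
    return float(np.std(resid, ddof=2))


def duplicate_errors(
    groups: Sequence[Sequence[float]],
    intensities: np.ndarray | None = None,
    t_cpmg: float | None = None,
    floor: float = 0.0,
) -> float | np.ndarray:
    """Pooled intensity sigma from duplicate measurements.

    ``groups`` is a sequence of repeated-intensity groups (each >= 2 values
    measured at the same nu_CPMG).  Returns the pooled standard deviation
    sigma_I, floored at ``floor``; if ``intensities`` and ``t_cpmg`` are
    given it is instead propagated point-by-point to R_2,eff errors via
    sigma_R = sigma_I / (I * T_CPMG).
    """
    groups = [np.asarray(g, dtype=float) for g in groups if len(g) >= 2]
    if not groups:
        raise ValueError("need at least one duplicate group of >= 2 points")
    if len(groups) == 1:
        warnings.warn("single duplicate group: pooled sigma is poorly determined",
                      stacklevel=2)
    num = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    den = sum(len(g) - 1 for g in groups)
    sigma_i = max(float(np.sqrt(num / den)), floor)
    if intensities is None:
        return sigma_i
    if t_cpmg is None or t_cpmg <= 0:
        raise ValueError("t_cpmg required to propagate to R_2,eff")
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities <= 0):
        raise ValueError("intensities must be positive")
    return sigma_i / (intensities * t_cpmg)
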