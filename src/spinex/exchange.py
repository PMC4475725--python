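"""Chemical-exchange models and Bloch-McConnell forward simulation.

This module defines N-state first-order exchange models between protein
conformers (a visible ground state in equilibrium with sparsely populated,
"invisible" excited states) and simulates the two relaxation experiments
that probe them on the millisecond timescale:

* CEST -- a weak B1 field is stepped across the spectrum while longitudinal
  magnetization evolves for a time T_CEST; exchange transfers saturation
  from an excited state to the ground-state peak, producing a minor dip in
  the I/I0 profile at the excited-state chemical shift.

* CPMG relaxation dispersion -- the effective transverse relaxation rate
  R_2,eff is measured as a function of the refocusing-pulse rate nu_CPMG
  applied during a constant-time element T_CPMG; exchange broadening (R_ex)
  is progressively refocused at high pulse rates.

Simulations numerically propagate the Bloch-McConnell equations: CEST uses
the full 3N x 3N generator (x, y, z magnetization per state), CPMG the
N x N complex generator for transverse magnetization with ideal,
instantaneous 180-degree pulses (complex conjugation).

Conventions: the shift difference of an excited state is
``excited - ground`` in ppm, so an upfield minor state has a negative
difference; B1 is a single nominal amplitude applied along x; CEST starts
from thermal equilibrium (population-weighted z magnetization) and reads
out ground-state z magnetization only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import scipy.linalg

__all__ = [
    "ExchangeModel",
    "CESTExperiment",
    "CPMGExperiment",
    "Condition",
    "CESTProfile",
    "DispersionProfile",
    "ppm_to_rad",
    "build_two_state",
    "build_three_state",
    "reduce_asymmetric_dimer",
    "simulate_cest",
    "simulate_cpmg",
    "rex_closed_form",
    "GAMMA_RATIO",
]

# gyromagnetic ratios relative to 1H, for converting a spectrometer's 1H
# frequency label to the Larmor frequency of the observed nucleus.
# Values are the standard frequency ratios (Xi) used for indirect
# referencing; supplied for convenience, never applied implicitly.
GAMMA_RATIO = {"1H": 1.0, "15N": 0.101329118, "13C": 0.251449530}

_POP_TOL = 1e-12
_BALANCE_TOL = 1e-9


def ppm_to_rad(delta_ppm, nucleus_freq: float):
    """Convert a chemical-shift difference (ppm) to angular frequency (rad/s).

    ``nucleus_freq`` is the Larmor frequency of the observed nucleus in MHz,
    so 1 ppm corresponds to ``nucleus_freq`` Hz.  Sign-preserving;
    vectorizes over ``delta_ppm``.
    """
    delta_ppm = np.asarray(delta_ppm, dtype=float)
    nucleus_freq = float(nucleus_freq)
    if not np.all(np.isfinite(delta_ppm)) or not np.isfinite(nucleus_freq):
        raise ValueError("ppm_to_rad requires finite inputs")
    if nucleus_freq <= 0:
        raise ValueError("nucleus_freq must be positive (MHz)")
    out = 2.0 * np.pi * delta_ppm * nucleus_freq
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ExchangeModel:
    """An N-state first-order exchange model.

    ``rate_matrix`` is the population-conservation generator: entry ``K[i, j]``
    (i != j) is the rate constant (s^-1) for j -> i and columns sum to zero.
    State 0 is the observable ground state.
    """

    state_labels: tuple[str, ...]
    populations: np.ndarray
    shifts: np.ndarray  # ppm, one per state
    r1: np.ndarray  # s^-1, longitudinal
    r2: np.ndarray  # s^-1, transverse
    rate_matrix: np.ndarray  # s^-1, (N, N) generator
    topology: str = "two_state"  # "two_state" | "linear_A_B_C"

    def __post_init__(self):
        n = len(self.state_labels)
        for name in ("populations", "shifts", "r1", "r2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValueError(f"{name} must have one entry per state")
            object.__setattr__(self, name, arr)
        k = np.asarray(self.rate_matrix, dtype=float)
        if k.shape != (n, n):
            raise ValueError("rate_matrix must be (N, N)")
        object.__setattr__(self, "rate_matrix", k)
        self.validate()

    @property
    def n_states(self) -> int:
        return len(self.state_labels)

    def validate(self) -> None:
        p, k = self.populations, self.rate_matrix
        if np.any(p < -_POP_TOL) or np.any(p > 1 + _POP_TOL):
            raise ValueError("populations must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-10:
            raise ValueError("populations must sum to 1")
        if np.max(np.abs(k.sum(axis=0))) > 1e-8 * max(1.0, np.max(np.abs(k))):
            raise ValueError("rate_matrix columns must sum to zero")
        if np.max(np.abs(k)) > 1e8:
            raise ValueError("pathological exchange rates (> 1e8 s^-1)")
        n = self.n_states
        for i in range(n):
            for j in range(i + 1, n):
                flux_ij = p[j] * k[i, j]  # j -> i
                flux_ji = p[i] * k[j, i]  # i -> j
                scale = max(flux_ij, flux_ji, 1e-30)
                if abs(flux_ij - flux_ji) > _BALANCE_TOL * scale + 1e-12:
                    raise ValueError(
                        f"detailed balance violated on edge "
                        f"{self.state_labels[i]}-{self.state_labels[j]}"
                    )
        if self.topology == "linear_A_B_C" and n == 3:
            # states are stored ground-first; adjacency is encoded by which
            # off-diagonal rates are nonzero, checked here: exactly two edges.
            edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                     if k[i, j] != 0 or k[j, i] != 0]
            if len(edges) > 2:
                raise ValueError("linear topology admits only two edges")

    def with_shifts(self, shifts: Sequence[float]) -> "ExchangeModel":
        return replace(self, shifts=np.asarray(shifts, dtype=float))


@dataclass(frozen=True)
class CESTExperiment:
    """CEST acquisition parameters."""

    b1_field: float  # saturation field strength, Hz
    t_cest: float  # saturation delay, s
    offsets: np.ndarray  # irradiation positions, ppm
    nucleus_freq: float  # Larmor frequency of observed nucleus, MHz

    def __post_init__(self):
        object.__setattr__(self, "offsets", np.asarray(self.offsets, dtype=float))
        if self.b1_field <= 0:
            raise ValueError("b1_field must be > 0")
        if self.t_cest <= 0:
            raise ValueError("t_cest must be > 0")
        d = np.diff(self.offsets)
        if len(self.offsets) > 1 and not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("offsets must be strictly monotonic")
        if self.nucleus_freq <= 0:
            raise ValueError("nucleus_freq must be > 0 (MHz)")


@dataclass(frozen=True)
class CPMGExperiment:
    """Constant-time CPMG acquisition parameters."""

    nu_cpmg: np.ndarray  # refocusing frequencies, Hz
    t_cpmg: float  # constant relaxation delay, s
    nucleus_freq: float  # MHz

    def __post_init__(self):
        nu = np.asarray(self.nu_cpmg, dtype=float)
        object.__setattr__(self, "nu_cpmg", nu)
        if np.any(nu <= 0):
            raise ValueError("nu_cpmg values must be > 0")
        if self.t_cpmg <= 0:
            raise ValueError("t_cpmg must be > 0")
        n_cycles = nu * self.t_cpmg
        if np.max(np.abs(n_cycles - np.round(n_cycles))) > 1e-6:
            raise ValueError(
                "each nu_cpmg must give an integer number of cycles in t_cpmg"
            )
        if self.nucleus_freq <= 0:
            raise ValueError("nucleus_freq must be > 0 (MHz)")


@dataclass(frozen=True)
class Condition:
    """Sample condition under which a profile was measured or simulated."""

    concentration: float  # total subunit concentration, mM
    temperature: float  # degrees C
    b0_label: float  # spectrometer identified by its 1H frequency, MHz

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("concentration must be > 0 (mM)")
        if not (0.0 <= self.temperature <= 100.0):
            raise ValueError("temperature must be within [0, 100] C")


@dataclass
class CESTProfile:
    """A CEST intensity-ratio profile for one residue and nucleus."""

    residue_id: str
    nucleus: str
    intensity_ratio: np.ndarray
    errors: np.ndarray
    experiment: CESTExperiment
    condition: Condition | None = None

    def __post_init__(self):
        self.intensity_ratio = np.asarray(self.intensity_ratio, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        n = len(self.experiment.offsets)
        if len(self.intensity_ratio) != n or len(self.errors) != n:
            raise ValueError("offsets, ratios and errors must have equal length")
        if np.any(self.errors < 0):
            raise ValueError("errors must be >= 0")

    @property
    def offsets(self) -> np.ndarray:
        return self.experiment.offsets


@dataclass
class DispersionProfile:
    """A CPMG dispersion profile (R_2,eff vs nu_CPMG) for one residue."""

    residue_id: str
    nucleus: str
    r2_eff: np.ndarray
    errors: np.ndarray
    experiment: CPMGExperiment
    condition: Condition | None = None

    def __post_init__(self):
        self.r2_eff = np.asarray(self.r2_eff, dtype=float)
        self.errors = np.asarray(self.errors, dtype=float)
        n = len(self.experiment.nu_cpmg)
        if len(self.r2_eff) != n or len(self.errors) != n:
            raise ValueError("nu_cpmg, r2_eff and errors must have equal length")
        if np.any(~np.isfinite(self.r2_eff)):
            raise ValueError("r2_eff must be finite")
        if np.any(self.errors < 0):
            raise ValueError("errors must be >= 0")

    @property
    def nu_cpmg(self) -> np.ndarray:
        return self.experiment.nu_cpmg


# ---------------------------------------------------------------------------
# model builders


def build_two_state(
    p_e: float,
    tau_e: float,
    shifts: Sequence[float],
    r1: float | Sequence[float] = 1.0,
    r2: float | Sequence[float] = 10.0,
) -> ExchangeModel:
    """Two-state ground (G) / excited (E) exchange from (p_E, tau_E).

    tau_E is the excited-state lifetime: k_EG = 1/tau_E; detailed balance
    gives k_GE = p_E k_EG / (1 - p_E) and k_ex = k_GE + k_EG.
    """
    if not (0 <= p_e < 0.5):
        raise ValueError("p_e must lie in [0, 0.5): the ground state must dominate")
    if tau_e <= 0:
        raise ValueError("tau_e must be > 0")
    k_eg = 1.0 / tau_e
    k_ge = p_e * k_eg / (1.0 - p_e)
    k = np.array([[-k_ge, k_eg], [k_ge, -k_eg]])
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), (2,)).copy()
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), (2,)).copy()
    return ExchangeModel(
        state_labels=("G", "E"),
        populations=np.array([1.0 - p_e, p_e]),
        shifts=np.asarray(shifts, dtype=float),
        r1=r1,
        r2=r2,
        rate_matrix=k,
        topology="two_state",
    )


_SCHEME_CHAINS = {
    1: ("N", "I", "H"),  # on-pathway intermediate
    2: ("I", "N", "H"),  # off-pathway from the ground state
    3: ("N", "H", "I"),  # off-pathway from the excited state
}


def build_three_state(
    scheme: int,
    p_h: float,
    p_i: float,
    k_ab_ex: float,
    k_bc_ex: float,
    shifts: Sequence[float],
    r1: float | Sequence[float] = 1.0,
    r2: float | Sequence[float] = 10.0,
) -> ExchangeModel:
    """Linear three-state model N / I / H in one of three chain orders.

    ``scheme`` selects the chain: 1: N-I-H, 2: I-N-H, 3: N-H-I.  For a chain
    edge A<->B with summed rate k_ex, the pair rates follow from the edge
    populations: k_AB = k_ex p_B/(p_A+p_B) and k_BA = k_ex p_A/(p_A+p_B),
    which enforces detailed balance on the edge.

    ``shifts``, ``r1`` and ``r2`` are given in state order (N, I, H);
    states are stored in that order with N (ground) first.
    """
    if scheme not in _SCHEME_CHAINS:
        raise ValueError("scheme must be 1, 2 or 3")
    if p_h < 0 or p_i < 0 or p_h + p_i >= 1:
        raise ValueError("populations must satisfy p_h, p_i >= 0 and p_h + p_i < 1")
    if k_ab_ex <= 0 or k_bc_ex <= 0:
        raise ValueError("exchange rates must be > 0")
    labels = ("N", "I", "H")
    pops = {"N": 1.0 - p_h - p_i, "I": p_i, "H": p_h}
    chain = _SCHEME_CHAINS[scheme]
    idx = {lab: i for i, lab in enumerate(labels)}
    k = np.zeros((3, 3))
    for (a, b), kex in zip(zip(chain, chain[1:]), (k_ab_ex, k_bc_ex)):
        pa, pb = pops[a], pops[b]
        tot = pa + pb
        if tot <= 0:
            continue
        k_ab = kex * pb / tot  # a -> b
        k_ba = kex * pa / tot  # b -> a
        ia, ib = idx[a], idx[b]
        k[ib, ia] += k_ab
        k[ia, ib] += k_ba
    k -= np.diag(k.sum(axis=0))
    r1 = np.broadcast_to(np.asarray(r1, dtype=float), (3,)).copy()
    r2 = np.broadcast_to(np.asarray(r2, dtype=float), (3,)).copy()
    return ExchangeModel(
        state_labels=labels,
        populations=np.array([pops["N"], pops["I"], pops["H"]]),
        shifts=np.asarray(shifts, dtype=float),
        r1=r1,
        r2=r2,
        rate_matrix=k,
        topology="linear_A_B_C",
    )


def reduce_asymmetric_dimer(
    k_md: float,
    k_dm: float,
    monomer_conc: float,
    omega_m: float,
    omega_d1: float,
    r1: float = 1.0,
    r2: float = 10.0,
) -> ExchangeModel:
    """Pseudo-two-state model for asymmetric dimerization, M <-> D.

    For a probe whose environment changes in only one of the two dimer
    subunits (the other subunit keeps the monomer shift, omega_D2 = omega_M)
    and identical intrinsic R_2 in both states, the three-state transverse
    Bloch-McConnell equations collapse to a two-state form with forward rate
    k_MD [M] and reverse rate k_DM, so that
    p_D = k_MD [M] / (k_MD [M] + k_DM) and k_ex = k_MD [M] + k_DM.
    """
    if k_md < 0 or k_dm <= 0 or monomer_conc <= 0:
        raise ValueError("rates and concentration must be positive")
    kf = k_md * monomer_conc
    p_d = kf / (kf + k_dm)
    k = np.array([[-kf, k_dm], [kf, -k_dm]])
    return ExchangeModel(
        state_labels=("M", "D1"),
        populations=np.array([1.0 - p_d, p_d]),
        shifts=np.array([omega_m, omega_d1], dtype=float),
        r1=np.array([r1, r1], dtype=float),
        r2=np.array([r2, r2], dtype=float),  # Eq-form assumption: equal R2
        rate_matrix=k,
        topology="two_state",
    )


# ---------------------------------------------------------------------------
# propagators


def _batched_propagate(a: np.ndarray, t: float, m0: np.ndarray) -> np.ndarray:
    """exp(a*t) @ m0 for a stack of small generators via batched eigendecomposition.

    Falls back to scipy's scaling-and-squaring expm for any member whose
    eigendecomposition is ill-conditioned.
    """
    try:
        w, v = np.linalg.eig(a)
        c = np.linalg.solve(v, m0[..., None] if m0.ndim == a.ndim - 1 else m0)
        out = (v @ (np.exp(w * t)[..., None] * c))[..., 0]
        if np.all(np.isfinite(out)):
            return out
    except np.linalg.LinAlgError:
        pass
    out = np.empty(a.shape[:-1], dtype=complex)
    for i in range(a.shape[0]):
        out[i] = scipy.linalg.expm(a[i] * t) @ (m0[i] if m0.ndim > 1 else m0)
    return out


def cest_generator(
    model: ExchangeModel, offsets_ppm: np.ndarray, b1_field: float, nucleus_freq: float
) -> np.ndarray:
    """Stack of 3N x 3N Bloch-McConnell generators, one per irradiation offset.

    Per-state block (x, y, z ordering), with Delta the offset of the state's
    resonance from the irradiation position (rad/s) and w1 = 2 pi B1 along x:

        dMx/dt = -R2 Mx + Delta My
        dMy/dt = -Delta Mx - R2 My + w1 Mz
        dMz/dt =           - w1 My  - R1 Mz

    plus the exchange generator acting identically on all three components.
    """
    n = model.n_states
    offs = np.asarray(offsets_ppm, dtype=float)
    w1 = 2.0 * np.pi * b1_field
    n_off = len(offs)
    a = np.zeros((n_off, 3 * n, 3 * n))
    # exchange part
    a += np.kron(model.rate_matrix, np.eye(3))[None, :, :]
    for i in range(n):
        delta = ppm_to_rad(1.0, nucleus_freq) * (model.shifts[i] - offs)  # (n_off,)
        sl = slice(3 * i, 3 * i + 3)
        a[:, 3 * i + 0, 3 * i + 0] += -model.r2[i]
        a[:, 3 * i + 1, 3 * i + 1] += -model.r2[i]
        a[:, 3 * i + 2, 3 * i + 2] += -model.r1[i]
        a[:, 3 * i + 0, 3 * i + 1] += delta
        a[:, 3 * i + 1, 3 * i + 0] += -delta
        a[:, 3 * i + 1, 3 * i + 2] += w1
        a[:, 3 * i + 2, 3 * i + 1] += -w1
    return a


def simulate_cest(
    model: ExchangeModel,
    exp: CESTExperiment,
    condition: Condition | None = None,
    residue_id: str = "sim",
    nucleus: str = "15N",
) -> CESTProfile:
    """Noiseless CEST profile by matrix-exponential propagation.

    Magnetization starts at thermal equilibrium (population-weighted z per
    state); the reported ratio is the ground-state z magnetization after
    t_cest normalized by its value at t = 0.  Errors are zero-filled.
    """
    model.validate()
    a = cest_generator(model, exp.offsets, exp.b1_field, exp.nucleus_freq)
    n = model.n_states
    m0 = np.zeros(3 * n)
    m0[2::3] = model.populations
    m0_stack = np.broadcast_to(m0, (a.shape[0], 3 * n))
    mt = _batched_propagate(a, exp.t_cest, m0_stack.astype(complex))
    ratio = np.real(mt[:, 2]) / model.populations[0]
    return CESTProfile(
        residue_id=residue_id,
        nucleus=nucleus,
        intensity_ratio=ratio,
        errors=np.zeros_like(ratio),
        experiment=exp,
        condition=condition,
    )


def cpmg_generator(model: ExchangeModel, nucleus_freq: float) -> np.ndarray:
    """N x N complex generator for transverse magnetization (one M+ per state).

    Offsets are taken relative to the ground-state shift: a uniform shift of
    all states adds a global phase that the echo train refocuses.
    """
    omega = ppm_to_rad(1.0, nucleus_freq) * (model.shifts - model.shifts[0])
    return (
        model.rate_matrix.astype(complex)
        + np.diag(1j * omega - model.r2.astype(complex))
    )


def simulate_cpmg(
    model: ExchangeModel,
    exp: CPMGExperiment,
    condition: Condition | None = None,
    residue_id: str = "sim",
    nucleus: str = "15N",
) -> DispersionProfile:
    """Noiseless CPMG dispersion profile.

    For each nu_CPMG the element (tau - 180 - tau), tau = 1/(4 nu), is
    applied 2 n times with n = t_cpmg * nu (the CPMGExperiment invariant
    guarantees n integral), exactly filling t_cpmg.  The 180-degree pulses
    are ideal and instantaneous (complex conjugation).  The readout is
    R_2,eff = -(1/T) ln(|sum_i M_i(T)| / |sum_i M_i(0)|).
    """
    model.validate()
    a = cpmg_generator(model, exp.nucleus_freq)
    w, v = np.linalg.eig(a)
    v_inv = np.linalg.inv(v)
    m_init = model.populations.astype(complex)
    i0 = np.abs(m_init.sum())
    r2eff = np.empty(len(exp.nu_cpmg))
    for k, nu in enumerate(exp.nu_cpmg):
        n_cycles = int(round(nu * exp.t_cpmg))
        tau = 1.0 / (4.0 * nu)
        p = (v * np.exp(w * tau)) @ v_inv  # exp(a * tau)
        m = m_init
        for _ in range(2 * n_cycles):
            m = p @ np.conj(p @ m)
        r2eff[k] = -np.log(np.abs(m.sum()) / i0) / exp.t_cpmg
    return DispersionProfile(
        residue_id=residue_id,
        nucleus=nucleus,
        r2_eff=r2eff,
        errors=np.zeros_like(r2eff),
        experiment=exp,
        condition=condition,
    )


def rex_closed_form(p_e: float, k_ex: float, delta_omega: float) -> float:
    """Slow-exchange estimate of the exchange broadening R_ex (s^-1).

    R_ex = p_G p_E k_ex dw^2 / (k_ex^2 + dw^2) with p_G = 1 - p_E and dw in
    rad/s.  Exact in the limit k_ex << |dw| where R_ex -> p_G p_E k_ex and
    is independent of the static field.
    """
    if not (0 < p_e < 1):
        raise ValueError("p_e must lie in (0, 1)")
    if not np.isfinite(k_ex) or not np.isfinite(delta_omega):
        raise ValueError("inputs must be finite")
    dw2 = delta_omega * delta_omega
    return (1.0 - p_e) * p_e * k_ex * dw2 / (k_ex * k_ex + dw2)
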