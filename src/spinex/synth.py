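"""Synthetic multi-residue, multi-condition CEST/CPMG dataset generation.

The generator emulates the statistical structure of a relaxation study of
an aggregation-prone two-state-folding protein whose free-energy landscape
carries four simultaneous millisecond exchange processes:

* **I** - transient native-like dimerization: concentration-dependent,
  large upfield shift differences (3.8-8.3 ppm) for interface reporters,
  population tied to a symmetric monomer-dimer equilibrium
  (K_diss = 85 mM; ~3% dimer, 3 ms lifetime at 1.3 mM, 25C).
* **II** - local folding of a loop helix: concentration-independent,
  shift differences up to ~10 ppm for loop residues (2.1%, 13 ms at 25C).
* **III** - non-native symmetric dimerization: small shifts (<= 1.5 ppm),
  R_ex increasing with temperature (3.3%, 6.0 ms at 1.3 mM, 25C).
* **IV** - non-native asymmetric dimerization (the probe's environment
  changes in only one dimer subunit): R_ex decreasing with temperature
  (2.1%, 1.6 ms at 1.3 mM, 25C).

plus exchange-free null probes, so classifier false-positive rates are
measurable.  Populations of the intermolecular processes are rescaled
across concentrations through mass action; temperature dependence is
encoded as per-temperature (K_diss, k_DM) or (p, tau) tables because the
study fits temperatures independently.

The study's own dispersion data for process I carry much smaller apparent
exchange amplitudes than the CEST-derived thermodynamics imply (the
native-dimer interface senses several concurrent processes, degrading its
CPMG profiles); the generator reproduces that discordance by giving
process I separate CEST and CPMG parameter channels (see docs/methods.md).
Mutant datasets analogous to loop-folding-deficient (process II abolished,
IV attenuated) and oligomerization-deficient variants can be generated for
the classifier's confirmation criteria.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import thermo
from .exchange import (
    CESTExperiment,
    CESTProfile,
    Condition,
    CPMGExperiment,
    DispersionProfile,
    build_two_state,
    reduce_asymmetric_dimer,
    simulate_cest,
    simulate_cpmg,
    GAMMA_RATIO,
)

__all__ = [
    "ProcessTruth",
    "ProbeSpec",
    "ScenarioSpec",
    "ScenarioBundle",
    "default_scenario",
    "generate_residue",
    "generate_four_process_scenario",
    "default_cpmg_ladder",
]

# Reference-condition ground truths (total subunit concentration 1.3 mM,
# 25C): excited-state population and lifetime per process.
REFERENCE_POPULATIONS = {"I": 0.03, "II": 0.021, "III": 0.033, "IV": 0.021}
REFERENCE_LIFETIMES_S = {"I": 0.003, "II": 0.013, "III": 0.006, "IV": 0.0016}
NATIVE_DIMER_KDISS_MM = 85.0
REFERENCE_CONC_MM = 1.3


def _kex_from(p: float, tau: float) -> float:
    """k_ex = k_EG + k_GE from an excited population and lifetime."""
    return 1.0 / ((1.0 - p) * tau)


@dataclass(frozen=True)
class ProcessTruth:
    """Ground-truth kinetics of one exchange process.

    ``kind`` is one of ``unimolecular`` (per-temperature (p_e, tau_e)),
    ``dimer_symmetric`` or ``dimer_asymmetric`` (per-temperature
    (k_diss mM, k_dm s^-1), rescaled across concentration by mass action).
    ``tables`` maps temperature (C) -> parameter dict; ``cpmg_tables``,
    when given, overrides the kinetics seen by CPMG observables (used for
    process I, whose dispersion-visible amplitude is attenuated).
    """

    process: str
    kind: str
    tables: Mapping[float, Mapping[str, float]]
    cpmg_tables: Mapping[float, Mapping[str, float]] | None = None

    def params_at(self, temperature: float, channel: str = "cest"):
        tabs = (self.cpmg_tables
                if channel == "cpmg" and self.cpmg_tables is not None
                else self.tables)
        try:
            return tabs[temperature]
        except KeyError:
            raise ValueError(
                f"process {self.process}: no ground truth at {temperature} C"
            ) from None


@dataclass(frozen=True)
class ProbeSpec:
    """One residue's membership and spectroscopic parameters."""

    residue_id: str
    process: str  # "I" | "II" | "III" | "IV" | "none"
    dw: float  # excited-state shift difference, ppm
    r2: float  # intrinsic transverse rate at 25C, s^-1
    r1: float = 1.0
    interface_burial: bool = False
    in_loop: bool = False


def default_cpmg_ladder(t_cpmg: float = 0.03, n: int = 20) -> np.ndarray:
    """nu_CPMG ladder of ``n`` points, 33.3-1000 Hz, integer cycles in T."""
    cycles = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10, 11, 12, 14, 16, 18, 20, 22, 24,
              26, 30][:n]
    return np.array(cycles, dtype=float) / t_cpmg


@dataclass
class ScenarioSpec:
    """Full specification of a synthetic four-process study."""

    processes: dict[str, ProcessTruth]
    roster: list[ProbeSpec]
    concentrations: tuple[float, ...] = (0.7, 2.0, 3.5)  # mM
    temperatures: tuple[float, ...] = (25.0, 35.0)  # C
    fields: tuple[float, ...] = (600.0, 800.0)  # 1H MHz
    nucleus: str = "15N"
    cest_b1: tuple[float, ...] = (31.0, 59.0)  # Hz
    cest_t: float = 0.35  # s
    cest_concentrations: tuple[float, ...] = (0.7, 1.3)  # mM, 25C only
    cest_field: float = 600.0  # 1H MHz
    cest_offsets: np.ndarray = field(
        default_factory=lambda: np.arange(-13.5, 4.51, 0.5)
    )
    t_cpmg: float = 0.03  # s
    nu_cpmg: np.ndarray = field(default_factory=default_cpmg_ladder)
    noise_cest: float = 0.01  # sigma on I/I0
    noise_r2eff: float = 0.2  # sigma on R_2,eff, s^-1
    seed: int = 0


@dataclass
class ScenarioBundle:
    """Generated dataset plus ground truth."""

    cpmg: list[DispersionProfile]
    cest: list[CESTProfile]
    truth: pd.DataFrame  # residue_id, process, dw, burial, loop
    native_shifts: dict[str, float]  # expected minor-dip shift for I probes
    loop_residues: set[str]
    mutants: dict[str, dict]  # name -> {cpmg, cest, eliminates, condition}
    reference_residues: list[str]  # large-shift process-I reporters
    seed: int


def _default_truths() -> dict[str, ProcessTruth]:
    """Study-condition kinetics for the four processes.

    25C entries derive from the reference-condition populations/lifetimes;
    35C entries encode the observed directions of temperature response
    (R_ex of I and III increase, IV decreases; II stays weak) with
    magnitudes chosen as typical for a few-kcal/mol association enthalpy.
    """
    c0 = REFERENCE_CONC_MM
    # process I, CEST channel: native dimerization at the reference dissociation constant
    tab_i = {25.0: {"k_diss": NATIVE_DIMER_KDISS_MM,
                    "k_dm": 1.0 / REFERENCE_LIFETIMES_S["I"]},
             35.0: {"k_diss": 60.0, "k_dm": 500.0}}
    # process I, CPMG channel: dispersion-consistent amplitude (~1% excited
    # population at 1.5 mM with k_ex ~ 280 s^-1 -> max R_ex ~ 2.8 s^-1)
    tab_i_cpmg = {25.0: {"k_diss": 294.0, "k_dm": 277.2},
                  35.0: {"k_diss": 294.0, "k_dm": 490.0}}
    # process II: unimolecular local folding
    tab_ii = {25.0: {"p_e": REFERENCE_POPULATIONS["II"],
                     "tau_e": REFERENCE_LIFETIMES_S["II"]},
              35.0: {"p_e": 0.026, "tau_e": 0.009}}
    # process III: symmetric non-native dimer; invert the reference fit
    p3, t3 = REFERENCE_POPULATIONS["III"], REFERENCE_LIFETIMES_S["III"]
    eq3 = thermo.rates_from_fit_symmetric(p3, _kex_from(p3, t3), c0)
    tab_iii = {25.0: {"k_diss": eq3.k_diss, "k_dm": eq3.k_dm},
               35.0: {"k_diss": 0.715 * eq3.k_diss, "k_dm": 1.5 * eq3.k_dm}}
    # process IV: asymmetric non-native dimer
    p4, t4 = REFERENCE_POPULATIONS["IV"], REFERENCE_LIFETIMES_S["IV"]
    eq4 = thermo.rates_from_fit_asymmetric(p4, _kex_from(p4, t4), c0)
    tab_iv = {25.0: {"k_diss": eq4.k_diss, "k_dm": eq4.k_dm},
              35.0: {"k_diss": eq4.k_diss, "k_dm": 2.0 * eq4.k_dm}}
    return {
        "I": ProcessTruth("I", "dimer_symmetric", tab_i, cpmg_tables=tab_i_cpmg),
        "II": ProcessTruth("II", "unimolecular", tab_ii),
        "III": ProcessTruth("III", "dimer_symmetric", tab_iii),
        "IV": ProcessTruth("IV", "dimer_asymmetric", tab_iv),
    }


def _default_roster(rng: np.random.Generator) -> list[ProbeSpec]:
    """80-probe roster: 16 I, 16 II, 20 III, 16 IV, 12 null."""
    roster: list[ProbeSpec] = []
    counter = 1

    def add(process, dw, burial=False, loop=False):
        nonlocal counter
        roster.append(ProbeSpec(
            residue_id=f"r{counter:03d}", process=process, dw=float(dw),
            r2=float(rng.uniform(9.0, 14.0)), r1=float(rng.uniform(0.9, 1.4)),
            interface_burial=burial, in_loop=loop,
        ))
        counter += 1

    # interface reporters first (the analogs of the large-shift residues
    # used for the reference fit), then the rest of the interface set
    for dw in (-8.3, -8.1, -3.8, -8.0):
        add("I", dw, burial=True)
    for _ in range(12):
        add("I", -rng.uniform(3.8, 8.3), burial=True)
    for _ in range(16):
        add("II", -rng.uniform(3.0, 10.0), loop=True)
    for _ in range(20):
        add("III", rng.choice([-1, 1]) * rng.uniform(0.9, 1.5))
    for _ in range(16):
        add("IV", rng.choice([-1, 1]) * rng.uniform(1.0, 1.5))
    for _ in range(12):
        add("none", 0.0)
    return roster


def default_scenario(seed: int = 0) -> ScenarioSpec:
    """The default four-process study specification."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    return ScenarioSpec(processes=_default_truths(),
                        roster=_default_roster(rng), seed=seed)


# ---------------------------------------------------------------------------
# forward generation


def _model_at_condition(truth: ProcessTruth, probe: ProbeSpec,
                        condition: Condition, channel: str, scale: float = 1.0):
    """Exchange model for one probe at one condition (None = no exchange)."""
    r2 = probe.r2 * (0.85 if condition.temperature >= 30.0 else 1.0)
    if truth is None or scale == 0.0:
        return build_two_state(0.0, 1.0, shifts=[0.0, 0.0],
                               r1=probe.r1, r2=r2)
    pars = truth.params_at(condition.temperature, channel)
    if truth.kind == "unimolecular":
        p_e = pars["p_e"] * scale
        return build_two_state(p_e, pars["tau_e"], shifts=[0.0, probe.dw],
                               r1=probe.r1, r2=r2)
    k_diss = pars["k_diss"] / scale
    if truth.kind == "dimer_symmetric":
        eq = thermo.solve_symmetric(condition.concentration, k_diss,
                                    pars["k_dm"])
        if eq.p_d >= 0.5:
            raise ValueError(
                f"condition outside model validity: p_D = {eq.p_d:.2f} >= 0.5"
            )
        return build_two_state(eq.p_d, 1.0 / eq.k_dm,
                               shifts=[0.0, probe.dw], r1=probe.r1, r2=r2)
    if truth.kind == "dimer_asymmetric":
        eq = thermo.solve_asymmetric(condition.concentration, k_diss,
                                     pars["k_dm"])
        if eq.p_d >= 0.5:
            raise ValueError(
                f"condition outside model validity: p_D = {eq.p_d:.2f} >= 0.5"
            )
        return reduce_asymmetric_dimer(eq.k_md, eq.k_dm, eq.m_conc,
                                       omega_m=0.0, omega_d1=probe.dw,
                                       r1=probe.r1, r2=r2)
    raise ValueError(f"unknown process kind {truth.kind!r}")


def generate_residue(truth: ProcessTruth | None, probe: ProbeSpec,
                     experiments: Sequence, condition: Condition,
                     rng: np.random.Generator, spec: ScenarioSpec,
                     scale: float = 1.0):
    """Noisy CEST/CPMG profiles for one probe at one condition.

    The noiseless curves come from the Bloch-McConnell forward models; the
    population of concentration-dependent processes is rescaled through
    mass action at the condition's concentration; i.i.d. Gaussian noise at
    the configured sigma is added.  Deterministic for a given generator
    state.
    """
    out = []
    for exp in experiments:
        if isinstance(exp, CPMGExperiment):
            model = _model_at_condition(truth, probe, condition, "cpmg", scale)
            prof = simulate_cpmg(model, exp, condition=condition,
                                 residue_id=probe.residue_id,
                                 nucleus=spec.nucleus)
            prof.r2_eff = prof.r2_eff + rng.normal(
                0.0, spec.noise_r2eff, len(prof.r2_eff))
            prof.errors = np.full(len(prof.r2_eff), spec.noise_r2eff)
        else:
            model = _model_at_condition(truth, probe, condition, "cest", scale)
            prof = simulate_cest(model, exp, condition=condition,
                                 residue_id=probe.residue_id,
                                 nucleus=spec.nucleus)
            prof.intensity_ratio = prof.intensity_ratio + rng.normal(
                0.0, spec.noise_cest, len(prof.intensity_ratio))
            prof.errors = np.full(len(prof.intensity_ratio), spec.noise_cest)
        out.append(prof)
    return out


def _nucleus_freq(spec: ScenarioSpec, field_1h: float) -> float:
    return field_1h * GAMMA_RATIO[spec.nucleus]


def generate_four_process_scenario(spec: ScenarioSpec | None = None,
                                   seed: int | None = None) -> ScenarioBundle:
    """Generate the full four-process dataset bundle with truth labels.

    CPMG profiles are produced for every probe over the concentration x
    temperature x static-field grid; CEST profiles (two B1 fields) for the
    large-shift probes (processes I and II) at the CEST concentrations.
    A loop-folding-deficient mutant dataset (process II abolished, IV
    attenuated, I at its dispersion-consistent parameters) is generated at
    1.5 mM for the reference fit and the confirmation criteria.
    """
    if spec is None:
        spec = default_scenario(seed=0 if seed is None else seed)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 7]))
    truths = spec.processes
    cpmg_profiles: list[DispersionProfile] = []
    cest_profiles: list[CESTProfile] = []

    for probe in spec.roster:
        truth = truths.get(probe.process)
        for conc in spec.concentrations:
            for temp in spec.temperatures:
                for b0 in spec.fields:
                    cond = Condition(conc, temp, b0)
                    exp = CPMGExperiment(spec.nu_cpmg, spec.t_cpmg,
                                         _nucleus_freq(spec, b0))
                    cpmg_profiles += generate_residue(
                        truth, probe, [exp], cond, rng, spec)
        if probe.process in ("I", "II"):
            for conc in spec.cest_concentrations:
                cond = Condition(conc, 25.0, spec.cest_field)
                exps = [CESTExperiment(b1, spec.cest_t, spec.cest_offsets,
                                       _nucleus_freq(spec, spec.cest_field))
                        for b1 in spec.cest_b1]
                cest_profiles += generate_residue(
                    truth, probe, exps, cond, rng, spec)

    # mutant analog: loop folding abolished, asymmetric oligomer attenuated
    mutant_cond = Condition(1.5, 25.0, 600.0)
    mutant_cpmg: list[DispersionProfile] = []
    mutant_cest: list[CESTProfile] = []
    for probe in spec.roster:
        truth = truths.get(probe.process)
        scale = {"II": 0.0, "IV": 0.3}.get(probe.process, 1.0)
        for b0 in spec.fields:
            cond = Condition(1.5, 25.0, b0)
            exp = CPMGExperiment(spec.nu_cpmg, spec.t_cpmg,
                                 _nucleus_freq(spec, b0))
            mutant_cpmg += generate_residue(truth, probe, [exp], cond, rng,
                                            spec, scale=scale)
        if probe.process in ("I", "II"):
            exps = [CESTExperiment(b1, spec.cest_t, spec.cest_offsets,
                                   _nucleus_freq(spec, 600.0))
                    for b1 in spec.cest_b1]
            mutant_cest += generate_residue(truth, probe, exps, mutant_cond,
                                            rng, spec, scale=scale)

    truth_rows = [
        {"residue_id": p.residue_id,
         "process": p.process if p.process != "none" else "unassigned",
         "dw": p.dw, "interface_burial": p.interface_burial,
         "in_loop": p.in_loop, "seed": spec.seed}
        for p in spec.roster
    ]
    native_shifts = {p.residue_id: p.dw for p in spec.roster
                     if p.process == "I"}
    loop_residues = {p.residue_id for p in spec.roster if p.in_loop}
    return ScenarioBundle(
        cpmg=cpmg_profiles,
        cest=cest_profiles,
        truth=pd.DataFrame(truth_rows),
        native_shifts=native_shifts,
        loop_residues=loop_residues,
        mutants={"loop_deficient": {
            "cpmg": mutant_cpmg, "cest": mutant_cest,
            "eliminates": {"II"}, "condition": mutant_cond,
        }},
        reference_residues=[p.residue_id for p in spec.roster[:4]],
        seed=spec.seed,
    )
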