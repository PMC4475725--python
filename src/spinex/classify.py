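"""Assignment of residue probes to exchange processes I-IV.

Four millisecond-timescale exchange processes can coexist in an aggregation-
prone protein: transient native-like dimerization (I), local folding of a
loop helix (II), and two distinct non-native oligomerization events (III,
IV).  Individual spin probes are sorted among them from the behaviour of
their exchange broadening R_ex across sample conditions:

* concentration dependence: ratio R = R_ex(high C)/R_ex(low C) with
  R > 1.4 and R/sigma_R >= 3 marks an intermolecular (oligomerization)
  process;
* temperature dependence: D = |R_ex(35C) - R_ex(25C)| > 1 s^-1 with
  D/sigma_D >= 3; the sign separates processes III (increasing) and IV
  (decreasing);
* CEST minor-dip shifts matched against the known chemical shifts of the
  mature native dimer (criterion for I) or localized to the folding loop
  (criterion for II);
* an upper bound on R_ex attainable by the native-dimerization process,
  computed from a reference two-state fit of its large-shift reporters via
  the slow-exchange relation R_ex = p_G p_E k_ex dw^2/(k_ex^2 + dw^2):
  probes whose measured R_ex exceeds the bound cannot belong to it.

The decision cascade is deterministic; conflicting evidence yields an
explicit ``unassigned`` with a conflict report, never a silent choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.base import BaseEstimator

from .exchange import DispersionProfile, rex_closed_form
from .fitting import FitResult, extract_dips

__all__ = [
    "ClassifierConfig",
    "ConditionKey",
    "cond_key",
    "ResidueRexRecord",
    "ProcessAssignment",
    "TestOutcome",
    "rex_from_profile",
    "concentration_test",
    "temperature_test",
    "eq1_bound",
    "ProcessClassifier",
    "assign_processes",
    "records_from_profiles",
]

ConditionKey = tuple[float, float, float]  # (concentration mM, temp C, field MHz)


def cond_key(concentration: float, temperature: float, b0_label: float) -> ConditionKey:
    """Normalized lookup key for a sample condition."""
    return (round(float(concentration), 3), round(float(temperature), 2),
            round(float(b0_label), 1))


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds and condition keys of the classification criteria.

    Defaults are the study's values: concentration ratio > 1.4 at >= 3 sigma,
    temperature difference > 1 s^-1 at >= 3 sigma, R_ex > 5 s^-1 to call a
    probe exchange-active, minimum CEST dip separation of 3 ppm for the
    local-folding criterion.  The native-shift match tolerance is 1.0 ppm:
    the apparent CEST dip of a millisecond-lifetime state is displaced from
    its true shift by up to ~0.7 ppm (exchange displacement ~ k_EG^2/dw plus
    overlap skew), so a tighter window rejects genuine matches.  Interface
    burial is a precomputed annotation (buried surface > 2 A^2 between
    monomer and native dimer).
    """

    ratio_threshold: float = 1.4
    ratio_significance: float = 3.0
    temp_threshold: float = 1.0  # s^-1
    temp_significance: float = 3.0
    active_rex: float = 5.0  # s^-1
    shift_match_tol: float = 1.0  # ppm
    min_dip_shift: float = 3.0  # ppm
    vanish_rex: float = 1.0  # s^-1; "exchange gone" in a mutant
    conc_high: ConditionKey = cond_key(3.5, 25.0, 600.0)
    conc_low: ConditionKey = cond_key(0.7, 25.0, 600.0)
    temp_high: ConditionKey = cond_key(2.0, 35.0, 800.0)
    temp_low: ConditionKey = cond_key(2.0, 25.0, 800.0)
    selection: ConditionKey = cond_key(3.5, 25.0, 800.0)


@dataclass
class ResidueRexRecord:
    """Per-probe R_ex measurements across conditions plus annotations."""

    residue_id: str
    nucleus: str = "15N"
    rex: dict[ConditionKey, tuple[float, float]] = field(default_factory=dict)
    cest_dip_shift: float | None = None  # minor - major, ppm
    interface_burial: bool = False

    def get(self, key: ConditionKey):
        return self.rex.get(key)


@dataclass(frozen=True)
class TestOutcome:
    passed: bool
    value: float
    sigma: float
    reason: str | None = None


@dataclass
class ProcessAssignment:
    """Residue -> process label with the evidence trail."""

    labels: dict[str, str]
    evidence: dict[str, list[str]]
    conflicts: dict[str, list[str]]

    def __getitem__(self, residue_id: str) -> str:
        return self.labels[str(residue_id)]


def rex_from_profile(profile: DispersionProfile):
    """R_ex = R_2,eff(nu_min) - R_2,eff(nu_max) with propagated error."""
    nu = profile.nu_cpmg
    if len(nu) < 2:
        raise ValueError("need at least two dispersion points")
    i_min, i_max = int(np.argmin(nu)), int(np.argmax(nu))
    rex = float(profile.r2_eff[i_min] - profile.r2_eff[i_max])
    sig = float(np.hypot(profile.errors[i_min], profile.errors[i_max]))
    return rex, sig


def concentration_test(rex_high, rex_low, config=ClassifierConfig()) -> TestOutcome:
    """Concentration-dependence test on the R_ex ratio.

    R = R_ex(high)/R_ex(low); pass iff R > 1.4 and R/sigma_R >= 3 (defaults).
    A non-positive low-concentration R_ex makes the ratio undefined: fail
    with a reason, never an exception.
    """
    vh, sh = rex_high
    vl, sl = rex_low
    if vl <= 0:
        return TestOutcome(False, np.nan, np.nan,
                           "low-concentration R_ex <= 0: ratio undefined")
    r = vh / vl
    sig = abs(r) * np.sqrt((sh / vh) ** 2 + (sl / vl) ** 2) if vh != 0 else np.inf
    passed = (r > config.ratio_threshold
              and sig > 0 and r / sig >= config.ratio_significance)
    return TestOutcome(bool(passed), float(r), float(sig), None)


def temperature_test(rex_hot, rex_cold, config=ClassifierConfig()):
    """Temperature-dependence test on |R_ex(35C) - R_ex(25C)|.

    Returns (direction, TestOutcome) with direction one of "increasing",
    "decreasing" or "fail"; pass iff D > 1 s^-1 and D/sigma_D >= 3
    (defaults).
    """
    vh, sh = rex_hot
    vc, sc = rex_cold
    diff = vh - vc
    d = abs(diff)
    sig = float(np.hypot(sh, sc))
    passed = d > config.temp_threshold and sig > 0 and d / sig >= config.temp_significance
    if not passed:
        return "fail", TestOutcome(False, float(d), sig, None)
    return ("increasing" if diff > 0 else "decreasing",
            TestOutcome(True, float(d), sig, None))


def eq1_bound(reference, delta_omega_grid=None) -> float:
    """Maximum R_ex attainable by a reference two-state process.

    ``reference`` is a :class:`FitResult` (or a (p_e, k_ex) pair) from
    fitting the process's large-shift reporters.  The slow-exchange relation
    is maximized over shift differences: analytically sup R_ex = p_G p_E k_ex
    as |dw| -> infinity; a finite ``delta_omega_grid`` (rad/s) restricts the
    maximization to physically plausible shifts.  Measured R_ex above the
    bound excludes membership of the reference process.
    """
    if isinstance(reference, FitResult):
        p_e, k_ex = reference.params["p_e"], reference.params["k_ex"]
    else:
        p_e, k_ex = reference
    if p_e <= 0:
        return 0.0
    if delta_omega_grid is None:
        return float((1.0 - p_e) * p_e * k_ex)
    return float(max(rex_closed_form(p_e, k_ex, dw)
                     for dw in np.asarray(delta_omega_grid, float)))


class ProcessClassifier(BaseEstimator):
    """Deterministic decision cascade assigning probes to processes I-IV.

    (a) concentration-independent probes with a large CEST minor dip inside
    the folding-loop residue set -> II; (b) concentration-dependent probes
    whose CEST dip matches the native-dimer shift table AND that carry the
    dimer-interface burial annotation -> I; (c) concentration-dependent,
    temperature-increasing probes whose R_ex exceeds the process-I reference
    bound -> III; (d) concentration-dependent, temperature-decreasing -> IV;
    (e) otherwise unassigned.  Mutant datasets, when supplied, confirm or
    flag assignments of processes the mutant eliminates.

    Parameters
    ----------
    reference_bound : float
        Max R_ex of the native-dimerization reference (s^-1); see
        :func:`eq1_bound`.
    native_shifts : mapping residue -> expected minor-dip shift (ppm)
        Shift differences to the mature native dimer.
    loop_residues : set of residue ids forming the folding loop.
    mutant_eliminates : mapping mutant name -> set of process labels that
        the mutant abolishes (e.g. {"G85R": {"II"}}).
    config : ClassifierConfig
    """

    def __init__(self, reference_bound=np.inf, native_shifts=None,
                 loop_residues=None, mutant_eliminates=None,
                 config=ClassifierConfig()):
        self.reference_bound = reference_bound
        self.native_shifts = native_shifts
        self.loop_residues = loop_residues
        self.mutant_eliminates = mutant_eliminates
        self.config = config

    # -- single-record cascade ----------------------------------------------
    def _classify_one(self, rec: ResidueRexRecord):
        cfg = self.config
        native = self.native_shifts or {}
        loops = self.loop_residues or set()
        evidence, conflicts = [], []

        rex_h, rex_l = rec.get(cfg.conc_high), rec.get(cfg.conc_low)
        if rex_h is not None and rex_l is not None:
            conc = concentration_test(rex_h, rex_l, cfg)
        else:
            conc = TestOutcome(False, np.nan, np.nan, "missing concentration pair")
        if conc.passed:
            evidence.append(f"concentration-dependent (R={conc.value:.2f})")

        direction = "fail"
        rex_t_h, rex_t_l = rec.get(cfg.temp_high), rec.get(cfg.temp_low)
        if rex_t_h is not None and rex_t_l is not None:
            direction, temp = temperature_test(rex_t_h, rex_t_l, cfg)
            if temp.passed:
                evidence.append(f"temperature-{direction} (D={temp.value:.2f})")

        dip = rec.cest_dip_shift
        has_large_dip = dip is not None and abs(dip) >= cfg.min_dip_shift
        shift_match = (
            dip is not None
            and str(rec.residue_id) in native
            and abs(dip - native[str(rec.residue_id)]) <= cfg.shift_match_tol
        )
        sel = rec.get(cfg.selection)
        rex_sel = sel[0] if sel is not None else (
            rex_t_l[0] if rex_t_l is not None else np.nan
        )

        # (a) unimolecular local folding
        if not conc.passed and has_large_dip and str(rec.residue_id) in loops:
            evidence.append("concentration-independent large dip in loop set")
            return "II", evidence, conflicts
        # (b) native dimerization
        if conc.passed and shift_match and rec.interface_burial:
            evidence.append("CEST dip matches native-dimer shift; interface buried")
            return "I", evidence, conflicts
        # (c) / (d) non-native oligomers, separated by temperature sign
        cand_iii = (conc.passed and direction == "increasing"
                    and np.isfinite(rex_sel) and rex_sel > self.reference_bound)
        cand_iv = conc.passed and direction == "decreasing"
        if cand_iii and cand_iv:  # unreachable by sign, kept as explicit guard
            conflicts.append("passes both III and IV criteria")
            return "unassigned", evidence, conflicts
        if cand_iii:
            evidence.append(
                f"R_ex={rex_sel:.2f} above process-I bound {self.reference_bound:.2f}"
            )
            return "III", evidence, conflicts
        if cand_iv:
            return "IV", evidence, conflicts
        if conc.passed and direction == "increasing":
            conflicts.append(
                "concentration-dependent and temperature-increasing but below "
                "the process-I bound and no native-shift match"
            )
        return "unassigned", evidence, conflicts

    def fit(self, records: Sequence[ResidueRexRecord],
            mutant_records: Mapping[str, Sequence[ResidueRexRecord]] | None = None):
        records = list(records)
        concs = {k[0] for r in records for k in r.rex}
        temps = {k[1] for r in records for k in r.rex}
        if len(concs) < 2 or len(temps) < 2:
            raise ValueError(
                "records must span >= 2 concentrations and >= 2 temperatures"
            )
        labels, evidence, conflicts = {}, {}, {}
        for rec in records:
            rid = str(rec.residue_id)
            lab, ev, cf = self._classify_one(rec)
            labels[rid], evidence[rid], conflicts[rid] = lab, ev, cf
        if mutant_records and self.mutant_eliminates:
            by_mutant = {
                name: {str(r.residue_id): r for r in recs}
                for name, recs in mutant_records.items()
            }
            for name, eliminated in self.mutant_eliminates.items():
                recs = by_mutant.get(name, {})
                for rid, lab in labels.items():
                    if lab not in eliminated or rid not in recs:
                        continue
                    mrec = recs[rid]
                    vals = [v for v, _ in mrec.rex.values()]
                    dip_gone = (mrec.cest_dip_shift is None
                                or abs(mrec.cest_dip_shift)
                                < self.config.min_dip_shift)
                    rex_gone = (not vals
                                or max(vals) < self.config.vanish_rex)
                    if dip_gone and rex_gone:
                        evidence[rid].append(f"confirmed: vanishes in {name}")
                    else:
                        conflicts[rid].append(
                            f"assigned {lab} but exchange persists in {name}"
                        )
        self.assignment_ = ProcessAssignment(labels, evidence, conflicts)
        self.labels_ = labels
        return self

    def predict(self, records: Sequence[ResidueRexRecord]) -> np.ndarray:
        """Labels for ``records`` using the configured cascade (stateless)."""
        return np.array([self._classify_one(r)[0] for r in records])


def assign_processes(records, reference_fit=None, native_shifts=None,
                     loop_residues=None, mutant_records=None,
                     mutant_eliminates=None,
                     config=ClassifierConfig()) -> ProcessAssignment:
    """Classify probes into processes I-IV; see :class:`ProcessClassifier`.

    ``reference_fit`` is the two-state :class:`FitResult` of the
    native-dimerization reference reporters (or a (p_e, k_ex) pair); its
    slow-exchange bound caps the R_ex any process-I probe can show.
    """
    bound = np.inf if reference_fit is None else eq1_bound(reference_fit)
    clf = ProcessClassifier(
        reference_bound=bound, native_shifts=native_shifts,
        loop_residues=loop_residues, mutant_eliminates=mutant_eliminates,
        config=config,
    )
    clf.fit(records, mutant_records=mutant_records)
    return clf.assignment_


def records_from_profiles(cpmg_profiles, cest_profiles=(), burial=None,
                          min_dip_amplitude=0.03) -> list[ResidueRexRecord]:
    """Build classification records from profile collections.

    R_ex (+- sigma) is taken per CPMG profile at its condition; the CEST
    minor-dip shift is extracted once per residue by the sum-of-Gaussians
    fit, using the lowest-B1, highest-concentration profile (narrowest dips,
    deepest minor state), kept only when a resolved second dip of amplitude
    >= ``min_dip_amplitude`` is found.  ``burial`` is a precomputed set of
    residue ids with >2 A^2 interface burial.
    """
    burial = set(map(str, burial or ()))
    records: dict[str, ResidueRexRecord] = {}
    for p in cpmg_profiles:
        if p.condition is None:
            raise ValueError("profiles need conditions to build records")
        rid = str(p.residue_id)
        rec = records.setdefault(
            rid, ResidueRexRecord(residue_id=rid, nucleus=p.nucleus,
                                  interface_burial=rid in burial)
        )
        key = cond_key(p.condition.concentration, p.condition.temperature,
                       p.condition.b0_label)
        rec.rex[key] = rex_from_profile(p)
    best_cest: dict[str, tuple[tuple, object]] = {}
    for p in cest_profiles:
        rid = str(p.residue_id)
        conc = p.condition.concentration if p.condition is not None else 0.0
        rank = (-p.experiment.b1_field, conc)  # low B1 first, then high conc
        if rid not in best_cest or rank > best_cest[rid][0]:
            best_cest[rid] = (rank, p)
    for rid, (_, p) in best_cest.items():
        rec = records.setdefault(
            rid, ResidueRexRecord(residue_id=rid, nucleus=p.nucleus,
                                  interface_burial=rid in burial)
        )
        try:
            dips = extract_dips(p, n_dips=2)
        except (ValueError, RuntimeError):
            continue
        if (len(dips.positions) >= 2 and not dips.merged
                and dips.amplitudes[1] >= min_dip_amplitude):
            rec.cest_dip_shift = dips.minor_shift
    return list(records.values())
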