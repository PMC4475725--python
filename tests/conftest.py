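"""Shared fixtures: the four-process scenario is generated once per session
(and classified once) because several modules test against it."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

import spinex.classify as cl

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
import spinex.fitting as ft
import spinex.synth as sy

N15_PER_1H = 0.101329118  # 15N/1H Larmor frequency ratio


@pytest.fixture(scope="session")
def scenario_bundle():
    return sy.generate_four_process_scenario(sy.default_scenario(seed=1))


@pytest.fixture(scope="session")
def scenario_classification(scenario_bundle):
    """Reference fit, records and assignment for the default scenario."""
    bundle = scenario_bundle
    mut = bundle.mutants["loop_deficient"]
    ref_profs = [p for p in mut["cpmg"]
                 if p.residue_id in bundle.reference_residues]
    dw_init = {r: bundle.native_shifts[r] for r in bundle.reference_residues}
    ref_fit = ft.fit_two_state(
        ref_profs, init={"dw": dw_init, "p_e": 0.02, "k_ex": 300.0})
    records = cl.records_from_profiles(
        bundle.cpmg, bundle.cest,
        burial=list(bundle.truth.query("interface_burial").residue_id))
    mutant_records = cl.records_from_profiles(mut["cpmg"], mut["cest"])
    assignment = cl.assign_processes(
        records, reference_fit=ref_fit,
        native_shifts=bundle.native_shifts,
        loop_residues=bundle.loop_residues,
        mutant_records={"loop_deficient": mutant_records},
        mutant_eliminates={"loop_deficient": {"II"}})
    truth = dict(zip(bundle.truth.residue_id, bundle.truth.process))
    return {"bundle": bundle, "ref_fit": ref_fit, "records": records,
            "assignment": assignment, "truth": truth}


@pytest.fixture
def cpmg_ladder():
    t = 0.03
    return np.array([1, 2, 3, 4, 6, 8, 10, 14, 20, 30]) / t, t
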