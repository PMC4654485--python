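"""Canonical pathway model: structure, unit conversions, perturbation grammar."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hifmir import (
    Perturbation,
    Protocol,
    READOUTS,
    apply_perturbations,
    build_canonical_model,
    copies_to_concentration,
    o2_percent_to_concentration,
    run_protocol,
)
from hifmir.errors import ConfigurationError, DomainError
from hifmir.network import validate_model
from hifmir.pathway import SUBNETWORKS


def test_canonical_structure_counts(model):
    rep = validate_model(model)
    assert rep["species"] == 47
    assert rep["reactions"] == 57
    assert rep["parameters"] == 91
    assert rep["violations"] == []


def test_two_compartments(model):
    assert sorted(c.id for c in model.compartments) == ["cytoplasm", "nucleus"]
    assert all(s.compartment in ("cytoplasm", "nucleus") for s in model.species)


def test_subnetwork_roster_covers_all_species(model):
    roster = [s for group in SUBNETWORKS.values() for s in group]
    assert len(roster) == len(set(roster)) == 47
    assert set(roster) == set(model.species_ids())


def test_every_mir_has_fast_free_and_slow_bound_decay(model):
    p = model.parameters
    assert p["kd_let7_free"] > p["kd_let7_ago1"]
    assert p["kd_mir15a_free"] > p["kd_mir15a_risc"]


def test_pbody_asymmetry(model):
    """p-body decay slower than the free cytoplasmic decay; exit flux small."""
    p = model.parameters
    assert p["kd_ago1_mrna_pb"] < p["kd_ago1_mrna"]
    assert p["kd_dicer_mrna_pb"] < p["kd_dicer_mrna"]
    assert p["kd_vegf_mrna_pb"] < p["kd_vegf_mrna"]
    assert p["k_pbody_exit_ago1"] < p["k_pbody_ago1"] * 1e-3  # entry uses uM^-1
    assert p["k_pbody_exit_vegf"] < p["k_pbody_vegf"]


@pytest.mark.parametrize("pct,expected", [
    (21.0, 209.0),
    (2.0, 19.9),
    (0.0, 0.0),
])
def test_o2_conversion_anchors(pct, expected):
    assert o2_percent_to_concentration(pct) == pytest.approx(expected, rel=5e-3)


def test_o2_conversion_domain():
    with pytest.raises(DomainError):
        o2_percent_to_concentration(-0.1)
    with pytest.raises(DomainError):
        o2_percent_to_concentration(25.0)


@given(p1=st.floats(0, 21), p2=st.floats(0, 21))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_o2_conversion_linear_and_invertible(p1, p2):
    c1, c2 = o2_percent_to_concentration(p1), o2_percent_to_concentration(p2)
    mid = o2_percent_to_concentration((p1 + p2) / 2.0)
    assert mid == pytest.approx((c1 + c2) / 2.0, abs=1e-9)
    assert (c1 < c2) == (p1 < p2) or p1 == p2


@pytest.mark.parametrize("copies,vol,expected", [
    (0, 1.0, 0.0),
    (602214, 1.0, 1.0),            # Avogadro arithmetic: 1 uM in 1 pL
    (1e4, 1.0, 1.6605e-2),
])
def test_copies_conversion(copies, vol, expected):
    assert copies_to_concentration(copies, vol) == pytest.approx(expected, rel=1e-3)


def test_copies_conversion_domain():
    with pytest.raises(DomainError):
        copies_to_concentration(-1)
    with pytest.raises(DomainError):
        copies_to_concentration(100, 0.0)


def test_overexpression_bumps_initial_condition(model):
    m2 = apply_perturbations(model, [
        Perturbation("mrna_overexpression", "AGO1_mRNA", 0.04)])
    base = model.get_species("AGO1_mRNA").initial_concentration
    assert m2.get_species("AGO1_mRNA").initial_concentration == pytest.approx(
        base + 0.04)
    # original untouched
    assert model.get_species("AGO1_mRNA").initial_concentration == base


def test_sirna_silencing_sets_dose_and_kd(model):
    m2 = apply_perturbations(model, [
        Perturbation("sirna_silencing", "TTP_mRNA", 0.01, kd=5e-4)])
    assert m2.get_species("siRNA_TTP").initial_concentration == pytest.approx(0.01)
    assert m2.parameters["kd_sirna_ttp"] == pytest.approx(5e-4)


def test_unknown_perturbation_targets_raise(model):
    with pytest.raises(ConfigurationError):
        apply_perturbations(model, [
            Perturbation("mrna_overexpression", "nonexistent", 0.1)])
    with pytest.raises(ConfigurationError):
        apply_perturbations(model, [Perturbation("mir_mimic", "miR999", 0.1)])
    with pytest.raises(ConfigurationError):
        Perturbation("sirna_silencing", "TTP_mRNA", -1.0)


def test_zero_dose_perturbations_are_bitwise_noops(model, steady_state):
    """Any zero-dose treatment reproduces the untreated trajectory exactly."""
    prot = Protocol(o2_percent=2.0, duration=120.0, output_every=5.0)
    base = run_protocol(model, prot, initial_state=steady_state)
    for kind, target in [("mir_antagonist", "let7"),
                         ("mir_mimic", "miR15a"),
                         ("sirna_silencing", "TTP_mRNA"),
                         ("mrna_overexpression", "AGO1_mRNA"),
                         ("cocl2", "CoCl2")]:
        prot_p = Protocol(o2_percent=2.0, duration=120.0, output_every=5.0,
                          perturbations=(Perturbation(kind, target, 0.0),))
        tc = run_protocol(model, prot_p, initial_state=steady_state)
        assert np.array_equal(tc.concentrations, base.concentrations), kind


def test_severed_hif_induction_leaves_targets_basal(model, steady_state):
    """With HIF-driven transcription Vmax at ~0, hypoxia leaves let-7 and TTP
    near their basal levels (positivity constraints forbid exactly 0)."""
    m = model.with_parameters({"Vm_let7": 1e-30, "Vm_ttp": 1e-30})
    from hifmir import find_normoxic_steady_state, relative_expression
    ss = find_normoxic_steady_state(m)
    tc = run_protocol(m, Protocol(o2_percent=2.0, duration=1440.0,
                                  output_every=10.0), initial_state=ss)
    let7 = relative_expression(tc, READOUTS["total_let7"])
    ttp = tc.column("TTP") / tc.column("TTP")[0]
    assert np.all(np.abs(let7 - 1.0) < 0.25)
    assert np.all(np.abs(ttp - 1.0) < 0.25)


def test_no_hydroxylases_hif_rises_to_synthesis_decay_balance(model):
    """With PHD2 and FIH removed, normoxic total HIF-1a rises monotonically
    toward the synthesis/decay plateau (hydroxylation was the only
    O2-dependent sink)."""
    m = model.with_initial_concentrations({
        "PHD2": 0.0, "FIH": 0.0, "PHD2_Fe_DG": 0.0, "FIH_Fe_DG": 0.0,
        "PHD2_Fe_DG_O2": 0.0, "FIH_Fe_DG_O2": 0.0})
    from hifmir.network import StateVector
    ic = StateVector({s.id: s.initial_concentration for s in m.species})
    tc = run_protocol(m, Protocol(o2_percent=21.0, duration=2880.0,
                                  output_every=30.0), initial_state=ic)
    hif = READOUTS["total_hif1a"].total(tc)
    diffs = np.diff(hif)
    assert np.all(diffs > -1e-12)
    assert hif[-1] > 10 * hif[0]


def test_mir15a_transcription_is_o2_independent(model):
    """The pre-miR-15a production flux is identical at 21% and 1% O2 for a
    fixed state (constitutive transcription)."""
    from hifmir.network import StateVector, rate
    rxn = next(r for r in model.reactions
               if r.products == (("pre_miR15a", 1),) and not r.reactants)
    s21 = StateVector({s.id: s.initial_concentration for s in model.species})
    vals = dict(s21.values)
    vals["O2"] = o2_percent_to_concentration(1.0)
    s1 = StateVector(vals)
    assert rate(rxn, s21, model.parameters) == rate(rxn, s1, model.parameters)


def test_cocl2_raises_hif_above_normoxic_steady_state(model, steady_state):
    tc = run_protocol(model, Protocol(
        o2_percent=21.0, duration=1440.0, output_every=10.0,
        perturbations=(Perturbation("cocl2", "CoCl2", 200.0),)),
        initial_state=steady_state)
    hif = READOUTS["total_hif1a"].total(tc)
    assert hif[-1] > 1.2 * hif[0]
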