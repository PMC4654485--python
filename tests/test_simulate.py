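"""Protocol layer: pre-equilibration, hypoxia switching, readouts."""

import numpy as np
import pytest

from hifmir import (
    Perturbation,
    Protocol,
    READOUTS,
    ReadoutDefinition,
    TimeCourse,
    find_normoxic_steady_state,
    free_vegf_mrna_fraction,
    onset_delay,
    relative_expression,
    run_protocol,
    total_vegf_produced,
)
from hifmir.errors import DomainError, NormalizationError
from hifmir.network import (
    Compartment,
    ModelDefinition,
    Parameter,
    ParameterSet,
    RateLaw,
    Reaction,
    SpeciesDef,
)


def test_steady_state_of_synthesis_decay_is_ks_over_kd():
    comp = (Compartment("cytoplasm", "c"),)
    sp = (SpeciesDef("A", "cytoplasm", "protein", 0.0),
          SpeciesDef("O2", "cytoplasm", "small_molecule", 209.0, boundary=True))
    rx = (Reaction("syn", (), (("A", 1),), RateLaw("constant", {"k": "ks"})),
          Reaction("dec", (("A", 1),), (), RateLaw("mass_action_1", {"k": "kd"})))
    ps = ParameterSet({"ks": Parameter(0.01, "uM/min", "user"),
                       "kd": Parameter(0.001, "1/min", "user")})
    m = ModelDefinition(comp, sp, rx, ps)
    ss = find_normoxic_steady_state(m)
    assert ss.values["A"] == pytest.approx(10.0, rel=1e-6)


def test_steady_state_invariance_over_48h(tc_normoxia):
    """At 21% O2 with no perturbation every species stays within 1% of its
    pre-equilibrated value over 48 h."""
    c = tc_normoxia.concentrations
    ref = np.maximum(c[0], 1e-12)
    assert np.max(np.abs(c - c[0]) / ref) < 0.01


def test_first_row_equals_initial_state(tc_hypoxia_2pct, steady_state):
    sids = tc_hypoxia_2pct.species_ids
    row0 = dict(zip(sids, tc_hypoxia_2pct.concentrations[0]))
    for s in sids:
        if s == "O2":
            continue
        assert row0[s] == pytest.approx(steady_state.values[s], rel=1e-9)


def test_hif_overshoot_shape_at_2pct(tc_hypoxia_2pct):
    """Total HIF-1a rises, peaks within the first ~14 h, then declines toward
    a plateau above baseline."""
    hif = relative_expression(tc_hypoxia_2pct, READOUTS["total_hif1a"])
    t = tc_hypoxia_2pct.time
    ipeak = int(np.argmax(hif))
    assert 240 <= t[ipeak] <= 840       # peak between 4 h and 14 h
    assert hif[ipeak] > 2.0             # strong induction
    assert hif[-1] < 0.8 * hif[ipeak]   # declines after the peak
    assert hif[-1] > 1.5                # plateau stays above baseline


def test_ttp_silencing_delays_hif_peak(model, tc_hypoxia_2pct, steady_state):
    """Silencing TTP (siRNA, Kd 1 nM) lengthens the initial HIF overshoot."""
    dose = 20 * steady_state.values["TTP_mRNA"]
    tc = run_protocol(model, Protocol(
        o2_percent=2.0, duration=2880.0,
        perturbations=(Perturbation("sirna_silencing", "TTP_mRNA", dose),)))
    h0 = relative_expression(tc_hypoxia_2pct, READOUTS["total_hif1a"])
    h1 = relative_expression(tc, READOUTS["total_hif1a"])
    t_peak0 = tc_hypoxia_2pct.time[np.argmax(h0)]
    t_peak1 = tc.time[np.argmax(h1)]
    assert t_peak1 > t_peak0


def test_relative_expression_identities(tc_hypoxia_2pct):
    trace = relative_expression(tc_hypoxia_2pct, READOUTS["total_ago1"])
    assert trace[0] == 1.0


def test_relative_expression_hand_built():
    tc = TimeCourse(time=np.array([0.0, 60.0]),
                    concentrations=np.array([[1.0], [2.0]]),
                    species_ids=("A",))
    rd = ReadoutDefinition("a", ("A",))
    assert relative_expression(tc, rd) == pytest.approx([1.0, 2.0])
    zero = TimeCourse(time=np.array([0.0, 1.0]),
                      concentrations=np.zeros((2, 1)), species_ids=("A",))
    with pytest.raises(NormalizationError):
        relative_expression(zero, rd)


def test_ago1_dips_below_one_after_delay(tc_hypoxia_2pct):
    """Total AGO1 stays near baseline initially, then declines below 1."""
    ago = relative_expression(tc_hypoxia_2pct, READOUTS["total_ago1"])
    assert ago[120] > 0.95        # little change in the first 2 h
    assert ago[-1] < 0.9          # clear decline by 48 h
    assert np.min(ago) < 0.9


def test_total_vegf_produced_rectangle_oracle(model):
    """Constant free VEGF mRNA m with translation rate kt over T minutes
    integrates to kt*m*T."""
    kt = model.parameters["kt_vegf"]
    sids = model.species_ids()
    n = len(sids)
    T, mconc = 120.0, 3e-5
    time = np.linspace(0, T, 121)
    conc = np.zeros((len(time), n))
    conc[:, sids.index("VEGF_mRNA")] = mconc
    tc = TimeCourse(time=time, concentrations=conc, species_ids=sids)
    assert total_vegf_produced(tc, model) == pytest.approx(kt * mconc * T)
    conc0 = np.zeros_like(conc)
    tc0 = TimeCourse(time=time, concentrations=conc0, species_ids=sids)
    assert total_vegf_produced(tc0, model) == 0.0
    with pytest.raises(DomainError):
        total_vegf_produced(tc, model, span=500.0)


def test_vegf_production_higher_in_hypoxia(model, tc_hypoxia_2pct):
    tc21 = run_protocol(model, Protocol(o2_percent=21.0, duration=1440.0,
                                        output_every=10.0))
    v2 = total_vegf_produced(tc_hypoxia_2pct, model, span=1440.0)
    v21 = total_vegf_produced(tc21, model, span=1440.0)
    assert v2 > v21


def test_free_vegf_mrna_fraction_bounds(tc_hypoxia_2pct):
    frac = free_vegf_mrna_fraction(tc_hypoxia_2pct)
    assert np.all(frac >= 0.0) and np.all(frac <= 1.0)


def test_free_fraction_all_free():
    sids = ("VEGF_mRNA", "VEGF_mRNA_RISC", "VEGF_mRNA_pbody")
    conc = np.zeros((3, 3))
    conc[:, 0] = 1e-4
    tc = TimeCourse(time=np.array([0., 1., 2.]), concentrations=conc,
                    species_ids=sids)
    assert free_vegf_mrna_fraction(tc) == pytest.approx([1.0, 1.0, 1.0])


def test_onset_delay_closed_form_oracle():
    """Exponential saturation c(t) = c0 + (1 - e^(-t/tau)); the 5%-of-120-min
    rise time has a closed form used as the oracle."""
    tau = 100.0
    t = np.linspace(0, 200, 2001)
    c = 1.0 + (1.0 - np.exp(-t / tau))
    tc = TimeCourse(time=t, concentrations=c[:, None], species_ids=("A",))
    rise120 = 1.0 - np.exp(-120.0 / tau)
    expected = -tau * np.log(1.0 - 0.05 * rise120)
    assert onset_delay(tc, "A") == pytest.approx(expected, rel=1e-3)


def test_onset_delay_degenerate_cases():
    t = np.linspace(0, 200, 201)
    flat = TimeCourse(time=t, concentrations=np.ones((201, 1)),
                      species_ids=("A",))
    assert np.isnan(onset_delay(flat, "A"))
    step = TimeCourse(time=t, concentrations=np.ones((201, 1)) * 2.0,
                      species_ids=("A",))
    step.concentrations[0, 0] = 2.0  # instantaneous step at t=0 (already up)
    assert np.isnan(onset_delay(step, "A")) or onset_delay(step, "A") == 0.0


def test_vegf_transcription_onset_delay_is_minutes_scale(model, steady_state):
    """VEGF mRNA induction after hypoxia onset shows a short transcriptional
    delay (tens of minutes, not hours)."""
    tc = run_protocol(model, Protocol(o2_percent=2.0, duration=240.0,
                                      output_every=0.5),
                      initial_state=steady_state)
    d = onset_delay(tc, "VEGF_mRNA")
    assert 1.0 <= d <= 60.0


def test_tolerance_robustness(model, steady_state):
    """Halving solver tolerances changes the 24-h VEGF readout by < 0.1%."""
    base = run_protocol(model, Protocol(o2_percent=2.0, duration=1440.0,
                                        output_every=10.0),
                        initial_state=steady_state)
    tight = run_protocol(model, Protocol(o2_percent=2.0, duration=1440.0,
                                         output_every=10.0,
                                         rtol=5e-9, atol=5e-13),
                         initial_state=steady_state)
    v0 = total_vegf_produced(base, model)
    v1 = total_vegf_produced(tight, model)
    assert abs(v1 - v0) / v0 < 1e-3
    h0 = relative_expression(base, READOUTS["total_hif1a"])[-1]
    h1 = relative_expression(tight, READOUTS["total_hif1a"])[-1]
    assert abs(h1 - h0) / h0 < 1e-3


def test_o2_monotonicity_of_total_hif(model):
    """48-h-end total HIF-1a decreases as O2 rises through the graded levels."""
    ends = []
    for o2 in (0.5, 1.0, 2.0, 5.0, 21.0):
        tc = run_protocol(model, Protocol(o2_percent=o2, duration=2880.0,
                                          output_every=30.0))
        ends.append(READOUTS["total_hif1a"].total(tc)[-1])
    assert all(a > b for a, b in zip(ends, ends[1:]))
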