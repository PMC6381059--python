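"""Component inputs: amplitude laws, phases, sign discipline, crosstalk."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from conftest import make_settings
from scfield import FieldParams, TrialTimeline
from scfield.field import mirror_permutation, node_positions
from scfield.inputs import (EXCITATORY, INHIBITORY, INPUT_NAMES, EventClock,
                            InputBank, apply_crosstalk, sum_inputs)
from scfield.protocol import LEVELS, VARIED_ATTRIBUTES, resolve_settings


def make_bank(task="pro", default="medium", params=None, timeline=None,
              **levels):
    params = params or FieldParams()
    timeline = timeline or TrialTimeline()
    settings = make_settings(task=task, default=default, **levels)
    attrs = resolve_settings(settings, params, timeline)
    clock = EventClock(timeline.fixation_acquired_t, timeline.fixation_off_t,
                       timeline.stimulus_on_t)
    return InputBank(attrs, clock, params, timeline)


class TestVisualTransient:
    def test_zero_before_afferent_delay(self):
        bank = make_bank()
        for t in (-500.0, 0.0, 25.0, 50.0):
            assert np.all(bank.vector("visual_transient", t) == 0.0)

    def test_rises_to_cap_then_fades_to_zero(self):
        bank = make_bank()
        peaks = [bank.vector("visual_transient", t).max()
                 for t in np.arange(51.0, 400.0)]
        assert max(peaks) == pytest.approx(8.0)
        assert max(peaks) <= 8.0 + 1e-9
        assert peaks[-1] == 0.0
        # fade begins after the cap is reached (~51 ms after response onset)
        assert bank.phase("visual_transient", 80.0) == "rising"
        assert bank.phase("visual_transient", 150.0) == "fading"
        assert bank.phase("visual_transient", 350.0) == "idle"

    def test_centered_on_stimulus(self):
        bank = make_bank()
        v = bank.vector("visual_transient", 80.0)
        x = node_positions(bank.params)
        assert x[np.argmax(v)] == pytest.approx(2.5)


class TestAutomatedMotor:
    def test_holds_at_cap_until_saccade(self):
        bank = make_bank(automated_motor_ror="medium",
                         automated_motor_max="medium")
        # ror 6 %/ms, max 6: cap reached ~95 steps after the 60 ms delay
        v_late1 = bank.vector("automated_motor", 300.0)
        v_late2 = bank.vector("automated_motor", 500.0)
        assert v_late1.max() == pytest.approx(6.0)
        np.testing.assert_array_equal(v_late1, v_late2)

    def test_zero_ror_is_identically_zero(self):
        params, timeline = FieldParams(), TrialTimeline()
        settings = make_settings()
        attrs = resolve_settings(settings, params, timeline)
        from dataclasses import replace
        attrs["automated_motor"] = replace(attrs["automated_motor"], ror=0.0)
        clock = EventClock(-1000.0, -200.0, 0.0)
        bank = InputBank(attrs, clock, params, timeline)
        for t in (0.0, 100.0, 400.0):
            assert np.all(bank.vector("automated_motor", t) == 0.0)


class TestFixationInputs:
    def test_automated_fixation_fade_timing(self):
        bank = make_bank()
        # at MaxVal 6 until fixation offset (-200) + 60 ms delay
        assert bank.vector("automated_fixation", -150.0).max() == \
            pytest.approx(6.0)
        v = bank.vector("automated_fixation", -139.0)
        assert v.max() < 6.0  # first decrement right after -140 ms
        # fully faded ~57 steps later, well before stimulus onset
        assert np.all(bank.vector("automated_fixation", -80.0) == 0.0)

    def test_voluntary_fixation_decay_synchronized_with_voluntary_onset(self):
        bank = make_bank(shared_onset_delay="small",
                         voluntary_fixation_max="medium")
        assert bank.vector("voluntary_fixation", 140.0).max() == \
            pytest.approx(6.0)
        assert bank.vector("voluntary_fixation", 141.0).max() < 6.0
        # decay completes after max / (amp * ror) ~ 57.1 ms
        assert bank.vector("voluntary_fixation", 140.0 + 58.0).max() == 0.0
        assert bank.vector("voluntary_fixation", 140.0 + 57.0).max() > 0.0


class TestVoluntaryMotor:
    def test_anti_task_mirrors_goal(self):
        bank = make_bank(task="anti")
        v = bank.vector("voluntary_motor", 300.0)
        x = node_positions(bank.params)
        assert x[np.argmax(v)] == pytest.approx(-2.5)

    def test_pro_task_aligned_with_stimulus(self):
        bank = make_bank(task="pro")
        v = bank.vector("voluntary_motor", 300.0)
        am = bank.vector("automated_motor", 300.0)
        assert np.argmax(v) == np.argmax(am)

    def test_uncapped_accumulation(self):
        bank = make_bank(voluntary_motor_ror="large",
                         shared_onset_delay="small")
        v = bank.vector("voluntary_motor", 140.0 + 200.0)
        assert v.max() == pytest.approx(1.05 * 0.15 * 200.0)  # 31.5 > any cap


class TestVoluntaryPreparation:
    def test_reaches_max_exactly_at_stimulus_onset(self):
        for level, mx in [("small", 4.0), ("medium", 6.0), ("large", 8.0)]:
            bank = make_bank(voluntary_preparation_max=level)
            v = bank.vector("voluntary_preparation", 0.0)
            assert v.max() == pytest.approx(mx)
            before = bank.vector("voluntary_preparation", -100.0)
            assert before.max() < mx

    def test_two_peaks_symmetric(self):
        bank = make_bank(task="anti")
        v = bank.vector("voluntary_preparation", 0.0)
        mirror = mirror_permutation(bank.params)
        np.testing.assert_allclose(v, v[mirror], atol=1e-12)

    def test_zero_before_onset(self):
        bank = make_bank(shared_onset_delay="large")
        assert np.all(bank.vector("voluntary_preparation", -831.0) == 0.0)
        assert bank.vector("voluntary_preparation", -829.0).max() > 0.0


class TestInhibitoryInputs:
    def test_gate_wall_and_opening(self):
        bank = make_bank(task="anti", inhibitory_gate_max="large",
                         shared_onset_delay="small")
        v0 = bank.vector("inhibitory_gate", 0.0)
        np.testing.assert_allclose(v0, -8.0)  # uniform wall, whole field
        # before the opening saturates at zero, its peak sits at the goal
        v = bank.vector("inhibitory_gate", 200.0)
        x = node_positions(bank.params)
        assert -8.0 < v.max() < 0.0
        assert x[np.argmax(v)] == pytest.approx(-2.5)
        assert bank.vector("inhibitory_gate", 400.0).max() <= 0.0

    def test_peripheral_notch_spares_fovea(self):
        bank = make_bank(peripheral_inhibition_max="large")
        v = bank.vector("peripheral_inhibition", -500.0)
        x = node_positions(bank.params)
        assert v[x == 0.0] == pytest.approx(0.0)
        # at the stimulus site the notch is negligible: inhibition ~ -max
        at_stim = v[np.argmin(np.abs(x - 2.5))]
        assert at_stim == pytest.approx(-8.0, abs=2e-3)

    def test_uniform_release(self):
        bank = make_bank(peripheral_inhibition_ror="medium",
                         shared_onset_delay="small")
        t0, t1 = 160.0, 161.0
        d = bank.vector("peripheral_inhibition", t1) \
            - bank.vector("peripheral_inhibition", t0)
        rising = d > 0
        assert rising.any()
        np.testing.assert_allclose(d[rising], d[rising][0], atol=1e-12)


@given(t=st.floats(-1000.0, 600.0),
       idx=st.tuples(*[st.integers(0, 2) for _ in range(10)]),
       task=st.sampled_from(["pro", "anti"]))
def test_sign_discipline_and_caps(t, idx, task):
    """Inputs 1-6 are >= 0 everywhere at all times; 7-8 <= 0; capped inputs
    never exceed their MaxVal."""
    levels = {a: LEVELS[i] for a, i in zip(VARIED_ATTRIBUTES, idx)}
    bank = make_bank(task=task, **levels)
    vecs = bank.vectors(t)
    for name in EXCITATORY:
        assert np.all(vecs[name] >= 0.0), name
    for name in INHIBITORY:
        assert np.all(vecs[name] <= 0.0), name
    for name in INPUT_NAMES:
        mv = bank.attrs[name].max_val
        if mv is not None:
            assert np.abs(vecs[name]).max() <= mv + 1e-9, name


@given(idx=st.tuples(*[st.integers(0, 2) for _ in range(10)]),
       t=st.floats(0.0, 600.0))
def test_pro_anti_mirror_relation(idx, t):
    """For identical settings the anti bank equals the pro bank with the
    voluntary-motor and inhibitory-gate inputs mirrored about fixation."""
    levels = {a: LEVELS[i] for a, i in zip(VARIED_ATTRIBUTES, idx)}
    pro = make_bank(task="pro", **levels)
    anti = make_bank(task="anti", **levels)
    mirror = mirror_permutation(pro.params)
    for name in INPUT_NAMES:
        vp, va = pro.vector(name, t), anti.vector(name, t)
        if name in ("voluntary_motor", "inhibitory_gate"):
            np.testing.assert_allclose(va, vp[mirror], atol=1e-12)
        else:
            np.testing.assert_allclose(va, vp, atol=1e-12)


class TestCrosstalk:
    def test_stated_arithmetic(self):
        mirror = mirror_permutation(FieldParams())
        am = np.zeros(100)
        vm = np.zeros(100)
        x = node_positions(FieldParams())
        i_right = int(np.argmin(np.abs(x - 2.5)))
        i_left = int(np.argmin(np.abs(x + 2.5)))
        am[i_right] = 4.0
        vm[i_left] = 8.0  # flips onto the right site
        adj = apply_crosstalk(vm, am, 0.25, mirror)
        assert adj[i_right] == pytest.approx(4.0 - 0.25 * 8.0)

    def test_clamped_at_zero(self):
        mirror = mirror_permutation(FieldParams())
        am = np.full(100, 1.0)
        vm = np.full(100, 8.0)
        adj = apply_crosstalk(vm, am, 0.25, mirror)
        np.testing.assert_array_equal(adj, 0.0)

    def test_identity_before_voluntary_onset(self):
        mirror = mirror_permutation(FieldParams())
        am = np.linspace(0, 5, 100)
        adj = apply_crosstalk(np.zeros(100), am, 0.25, mirror)
        np.testing.assert_array_equal(adj, am)


class TestSumInputs:
    def test_additivity_and_linearity(self):
        bank = make_bank()
        t = 100.0
        vecs = bank.vectors(t)
        total = sum_inputs(vecs)
        np.testing.assert_allclose(total,
                                   np.sum([vecs[n] for n in INPUT_NAMES],
                                          axis=0), atol=1e-12)
        doubled = {n: 2.0 * v for n, v in vecs.items()}
        np.testing.assert_allclose(sum_inputs(doubled), 2.0 * total,
                                   atol=1e-12)

    def test_gaussian_peak_against_wall(self):
        vecs = {n: np.zeros(100) for n in INPUT_NAMES}
        from scfield.field import gaussian_profile
        k = gaussian_profile(2.5, FieldParams())
        vecs["automated_motor"] = 6.0 * k / 1.05
        vecs["inhibitory_gate"] = np.full(100, -8.0)
        total = sum_inputs(vecs)
        assert total.max() == pytest.approx(-2.0)


def test_synchrony_of_voluntary_onsets():
    """Inputs 4, 5, 7, 8 change phase at exactly stimulus onset + shared
    delay; input 6 at fixation acquisition + shared delay."""
    bank = make_bank(shared_onset_delay="medium")  # delay 155
    before, after = 155.0, 156.0
    for name in ("voluntary_motor", "voluntary_fixation", "inhibitory_gate",
                 "peripheral_inhibition"):
        v0 = bank.vector(name, before)
        v1 = bank.vector(name, after)
        assert not np.array_equal(v0, v1), name
        v_pre = bank.vector(name, before - 1.0)
        np.testing.assert_array_equal(v_pre, v0)
    # preparation: starts at -1000 + 155
    assert np.all(bank.vector("voluntary_preparation", -845.0) == 0.0)
    assert bank.vector("voluntary_preparation", -844.0).max() > 0.0
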