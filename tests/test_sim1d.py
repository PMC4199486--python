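"""1D oscillator array: phases, kinematic waves, stripes and staging."""

import numpy as np
import pytest

import cadwave as cw
from cadwave.gradient import GradientDescriptors, TemporalGradient
from cadwave.sim1d import roman


def _static(plateau=1.0, border=0.4, slope=2.5, t_start=13.5):
    return TemporalGradient(GradientDescriptors(plateau, border, slope),
                            t_on=t_start, tau=0.0, retraction_onset=np.inf,
                            retraction_speed=0.0)


# -- phase integration ------------------------------------------------------

def test_posterior_cell_completes_one_cycle_in_three_hours(static_wt):
    cfg = cw.SimConfig1D(t_start=13.5, t_end=16.5)
    pat = cw.simulate_1d(cfg, static_wt)
    assert pat.posterior_phase[-1] == pytest.approx(1.0, abs=1e-6)


def test_cells_anterior_of_border_never_oscillate_or_express(wt_pattern):
    anterior = wt_pattern.x < 0.38  # clear of the steady border at 0.40
    assert np.all(wt_pattern.phi[:, anterior] == 0.0)
    assert np.all(wt_pattern.expr[:, anterior] == 0)


def test_zero_gradient_abolishes_expression():
    tg = _static(plateau=0.0, border=0.4, slope=2.5)
    pat = cw.simulate_1d(cw.SimConfig1D(t_end=20.0), tg)
    assert np.all(pat.expr == 0)
    assert np.all(pat.phi == 0.0)


def test_phase_nondecreasing_everywhere(wt_pattern):
    assert np.all(np.diff(wt_pattern.phi, axis=0) >= 0)


def test_simulation_matches_analytic_oracle_for_static_gradient(static_wt):
    cfg = cw.SimConfig1D(t_start=13.5, t_end=20.0)
    pat = cw.simulate_1d(cfg, static_wt)
    expected = cw.analytic_phase(static_wt.steady, cfg, pat.x[None, :],
                                 pat.times[:, None])
    assert np.max(np.abs(pat.phi - expected)) <= cfg.dt * cfg.omega_ref


def test_analytic_phase_examples_and_static_guard(static_wt):
    cfg = cw.SimConfig1D(t_start=13.5, t_end=23.0)
    assert cw.analytic_phase(static_wt.steady, cfg, 0.95, 19.5) == pytest.approx(2.0)
    assert cw.analytic_phase(static_wt.steady, cfg, 0.4, 20.0) == 0.0
    with pytest.raises(ValueError, match="static"):
        cw.analytic_phase(cw.condition_preset("WT"), cfg, 0.5, 15.0)


# -- wild-type timing -------------------------------------------------------

def test_wt_posterior_cycle_durations(wt_pattern):
    """Buildup slows the first cycle to 3.5 h; later cycles run at 3 h."""
    durations = cw.posterior_cycle_durations(wt_pattern)
    assert len(durations) == 3  # exactly three cycles in the 13.5-23 h window
    assert durations[0] == pytest.approx(3.5, abs=0.1)
    assert durations[1] == pytest.approx(3.0, abs=0.05)
    assert durations[2] == pytest.approx(3.0, abs=0.05)


def test_first_cycle_ends_at_17_hours(wt_pattern):
    t_end_cycle1 = float(np.interp(1.0, wt_pattern.posterior_phase, wt_pattern.times))
    assert t_end_cycle1 == pytest.approx(17.0, abs=0.05)


def test_buildup_slows_only_the_first_cycle():
    tg = TemporalGradient(GradientDescriptors(1.0, 0.4, 2.5), t_on=13.5, tau=0.5)
    pat = cw.simulate_1d(cw.SimConfig1D(t_end=26.0), tg)
    durations = cw.posterior_cycle_durations(pat)
    static_period = 3.0
    assert durations[0] > durations[1]
    for d in durations[1:]:
        assert d == pytest.approx(static_period, abs=0.01)


def test_halving_the_plateau_doubles_static_cycle_durations():
    full = cw.simulate_1d(cw.SimConfig1D(t_end=23.0), _static(plateau=1.0))
    # halved gradient level everywhere halves the frequency
    half = cw.simulate_1d(cw.SimConfig1D(t_end=26.0), _static(plateau=0.5, slope=1.25))
    d_full = cw.posterior_cycle_durations(full)
    d_half = cw.posterior_cycle_durations(half)
    for a, b in zip(d_half, d_full):
        assert a == pytest.approx(2 * b, rel=1e-3)


def test_too_short_run_yields_no_cycles(static_wt):
    pat = cw.simulate_1d(cw.SimConfig1D(t_start=13.5, t_end=14.5), static_wt)
    assert cw.posterior_cycle_durations(pat) == []


# -- stripe detection -------------------------------------------------------

def test_detect_isolated_run():
    row = np.zeros(100, dtype=int)
    row[30:50] = 1
    stripes, border = cw.detect_stripes(row)
    assert len(stripes) == 1
    s = stripes[0]
    assert s.complete
    assert s.width == pytest.approx(20 / 100)
    assert border == pytest.approx(30 / 100)


def test_all_high_row_is_one_incomplete_run():
    stripes, border = cw.detect_stripes(np.ones(50, dtype=int))
    assert len(stripes) == 1
    assert not stripes[0].complete
    assert border == 0.0


def test_all_zero_row_has_no_stripes_and_no_border():
    stripes, border = cw.detect_stripes(np.zeros(40, dtype=int))
    assert stripes == [] and border is None


def test_single_cell_slivers_suppressed():
    row = np.zeros(60, dtype=int)
    row[10] = 1
    row[20:25] = 1
    stripes, border = cw.detect_stripes(row)
    assert len(stripes) == 1
    assert border == pytest.approx(20 / 60)


def test_stripe_borders_sit_on_half_cycle_phase_contours(static_wt):
    """Stripe borders coincide with phase level sets {0.5, 1.0, 1.5, ...}."""
    cfg = cw.SimConfig1D(t_start=13.5, t_end=20.0)
    pat = cw.simulate_1d(cfg, static_wt)
    t = 19.8  # posterior phase = 2.1: three high bands, posterior-most open
    idx = pat.frame_at(t)
    stripes, _ = cw.detect_stripes(pat.expr[idx])
    d = static_wt.steady
    # closed form: on the ramp, phase phi = omega_ref*slope*(x-border)*(t-t0)
    def x_at_phase(phi):
        return d.border + phi * cfg.g_ref / (cfg.omega_ref * d.slope * (t - cfg.t_start))
    cell = 1.0 / cfg.n_cells
    expected_edges = []
    for s in stripes:
        expected_edges.append(s.anterior)
        expected_edges.append(s.posterior)
    # high bands are phi in [0,0.5), [1,1.5), [2,2.1]; their edges sit at the
    # domain border, the half-cycle contours, and the posterior pole
    analytic = [d.border, x_at_phase(0.5), x_at_phase(1.0), x_at_phase(1.5),
                x_at_phase(2.0), 1.0]
    assert len(expected_edges) == len(analytic)
    for got, want in zip(expected_edges, analytic):
        assert got == pytest.approx(want, abs=1.5 * cell)


def test_waves_travel_posterior_to_anterior(wt_pattern):
    """The newest wave's anterior edge moves only anteriorly while it lives."""
    frames = range(wt_pattern.frame_at(17.2), wt_pattern.frame_at(19.8), 20)
    edges = []
    for idx in frames:
        stripes, _ = cw.detect_stripes(wt_pattern.expr[idx])
        incomplete = [s for s in stripes if not s.complete]
        if incomplete:
            edges.append(incomplete[-1].anterior)
    assert len(edges) >= 5
    assert np.all(np.diff(edges) <= 1e-12)


def test_stripes_shrink_with_decreasing_rate_under_static_gradient(static_wt):
    cfg = cw.SimConfig1D(t_start=13.5, t_end=20.0)
    pat = cw.simulate_1d(cfg, static_wt)
    widths = []
    for t in (15.5, 16.5, 17.5, 18.5, 19.5):
        stripes, _ = cw.detect_stripes(pat.expr[pat.frame_at(t)])
        complete = [s for s in stripes if s.complete]
        widths.append(complete[0].width)  # anterior-most completed stripe
    shrink = -np.diff(widths)
    cell = 1.0 / cfg.n_cells
    assert np.all(shrink > 0)  # strictly shrinking
    assert np.all(np.diff(shrink) <= cell + 1e-12)  # at a decreasing rate


# -- staging ----------------------------------------------------------------

@pytest.mark.parametrize("n, numeral", [(1, "I"), (2, "II"), (3, "III"), (4, "IV"), (9, "IX")])
def test_roman_numerals(n, numeral):
    assert roman(n) == numeral


def test_classify_stage_labels():
    tg = _static(plateau=1.0, border=0.0, slope=2.5, t_start=13.5)
    pat = cw.simulate_1d(cw.SimConfig1D(t_end=23.0), tg)  # posterior phi = (t-13.5)/3
    assert cw.classify_stage(pat, 13.5 + 0.6).label == "I.1"   # phi = 0.2
    assert cw.classify_stage(pat, 13.5 + 2.1).label == "I.0"   # phi = 0.7
    assert cw.classify_stage(pat, 13.5 + 3.9).label == "II.1"  # phi = 1.3
    with pytest.raises(ValueError):
        cw.classify_stage(pat, 30.0)


# -- preset phenotypes ------------------------------------------------------

@pytest.fixture(scope="module")
def preset_runs():
    cfg = cw.SimConfig1D()
    return {name: cw.simulate_1d(cfg, cw.condition_preset(name))
            for name in cw.CONDITIONS}


@pytest.fixture(scope="module")
def preset_runs_long():
    # slow knockdowns need more than the blastoderm window to cycle twice
    cfg = cw.SimConfig1D(t_end=28.0)
    return {name: cw.simulate_1d(cfg, cw.condition_preset(name))
            for name in cw.CONDITIONS}


def _final_border(pat):
    stripes, border = cw.detect_stripes(pat.expr[-1])
    assert border is not None
    return border


def _first_stripe_width_at(pat, t):
    stripes, _ = cw.detect_stripes(pat.expr[pat.frame_at(t)])
    complete = [s for s in stripes if s.complete]
    return complete[0].width if complete else np.nan


def test_knockdown_borders_order_as_observed(preset_runs):
    borders = {k: _final_border(p) for k, p in preset_runs.items()}
    assert borders["lgs"] > borders["WT"]          # posterior shift
    assert borders["cad_mild"] > borders["WT"]
    assert borders["pan"] < borders["WT"]          # anterior shift
    assert borders["zen1"] < borders["WT"]
    assert borders["WT"] < borders["lgs_zen1"] < borders["lgs"]


def test_knockdown_cycle_durations_order_as_observed(preset_runs_long):
    durations = {k: cw.posterior_cycle_durations(p)
                 for k, p in preset_runs_long.items()}
    wt2 = durations["WT"][1]
    for slow in ("lgs", "cad_mild", "pan"):
        assert durations[slow][0] > durations["WT"][0]
        assert durations[slow][1] > wt2
    # zen1 timing matches WT
    assert durations["zen1"][0] == pytest.approx(durations["WT"][0], abs=0.05)
    assert durations["zen1"][1] == pytest.approx(wt2, abs=0.05)


def test_pan_stripes_are_wider_than_wt(preset_runs):
    t = 20.0  # both conditions have a completed first stripe by then
    assert _first_stripe_width_at(preset_runs["pan"], t) > \
        _first_stripe_width_at(preset_runs["WT"], t)
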