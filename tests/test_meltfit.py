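"""Melting-curve pipeline: reading, normalisation, derivative, fits, selection."""

import io

import numpy as np
import pytest

from tropofit import meltfit, reference, simulate, thermo
from tropofit.errors import (
    DegenerateCurveError,
    InputError,
    ParameterError,
    ParseError,
)

from conftest import random_valid_model, run_melt_pipeline


# ---------------------------------------------------------------------------
# read_melt


def test_read_wellformed_csv(tmp_path):
    t = np.round(np.arange(10.0, 50.1, 0.1), 4)
    s = np.linspace(-10, -2, t.size)
    path = tmp_path / "melt.csv"
    path.write_text(
        "temperature_C,signal\n" + "\n".join(f"{a},{b}" for a, b in zip(t, s))
    )
    curve = meltfit.read_melt(path)
    assert curve.temperature.size == 401
    assert np.allclose(curve.temperature, t)


def test_read_sorts_descending_temperatures():
    text = "30,1\n20,2\n10,3\n"
    curve = meltfit.read_melt(io.StringIO(text))
    assert list(curve.temperature) == [10.0, 20.0, 30.0]
    assert list(curve.signal) == [3.0, 2.0, 1.0]


def test_read_averages_duplicate_temperatures():
    curve = meltfit.read_melt(io.StringIO("10,1\n10,3\n20,5\n"))
    assert list(curve.temperature) == [10.0, 20.0]
    assert list(curve.signal) == [2.0, 5.0]


def test_read_single_column_is_parse_error():
    with pytest.raises((ParseError, InputError)):
        meltfit.read_melt(io.StringIO("10\n20\n30\n"))


def test_read_nonnumeric_row_reports_line():
    with pytest.raises(ParseError) as err:
        meltfit.read_melt(io.StringIO("temperature,signal\n10,1\n20,oops\n30,3\n"))
    assert err.value.line == 2


# ---------------------------------------------------------------------------
# normalisation


def test_normalize_roundtrips_generating_fraction(wt_model, wt_curve):
    norm = meltfit.normalize_melt(wt_curve)
    truth = thermo.fraction_unfolded(wt_model, norm.temperature)
    assert np.max(np.abs(norm.fraction - truth)) < 1e-3


def test_normalize_constant_signal_is_degenerate():
    curve = meltfit.MeltCurve(np.arange(5.0, 55.0, 0.5), np.full(100, -7.0))
    with pytest.raises(DegenerateCurveError):
        meltfit.normalize_melt(curve)


def test_normalize_is_idempotent_on_unit_sigmoid(wt_model):
    t = np.arange(10.0, 50.1, 0.1)
    f = thermo.fraction_unfolded(wt_model, t)
    curve = meltfit.MeltCurve(t, f)
    norm = meltfit.normalize_melt(curve)
    assert np.max(np.abs(norm.fraction - f)) < 1e-3


def test_normalize_requires_window_coverage(wt_model):
    t = np.arange(15.0, 50.1, 0.1)
    curve = meltfit.MeltCurve(t, thermo.fraction_unfolded(wt_model, t))
    with pytest.raises(InputError):
        meltfit.normalize_melt(curve)


def test_normalize_linear_mode_handles_sloped_baselines():
    model = thermo.single_transition_model(
        30.0, -450.0, baseline_folded=(-10.0, 0.01), baseline_unfolded=(-2.0, 0.02)
    )
    curve = simulate.gen_melt(simulate.MeltSimSpec(model=model))[0]
    norm = meltfit.normalize_melt(curve, baseline_mode="linear")
    truth = thermo.fraction_unfolded(model, norm.temperature)
    assert np.max(np.abs(norm.fraction - truth)) < 0.02


# ---------------------------------------------------------------------------
# derivative


def test_derivative_peaks_at_tm(wt_curve):
    norm = meltfit.normalize_melt(wt_curve)
    deriv = meltfit.first_derivative(norm)
    peak_t = deriv.temperature[np.argmax(deriv.dfdT)]
    assert abs(peak_t - 34.1) <= 0.1 + 1e-9  # within one grid step


def test_derivative_of_linear_ramp_is_constant():
    t = np.arange(10.0, 50.1, 0.1)
    norm = meltfit.NormalizedMelt(t, (t - 10.0) / 40.0)
    deriv = meltfit.first_derivative(norm)
    assert np.allclose(deriv.dfdT, 1.0 / 40.0, atol=1e-9)


def test_derivative_two_separated_transitions_has_two_maxima(biphasic_model):
    curve = simulate.gen_melt(simulate.MeltSimSpec(model=biphasic_model))[0]
    deriv = meltfit.first_derivative(meltfit.normalize_melt(curve))
    y = deriv.dfdT
    interior = [
        i
        for i in range(1, y.size - 1)
        if y[i] >= y[i - 1] and y[i] > y[i + 1] and y[i] > 0.1 * y.max()
    ]
    assert len(interior) == 2


def test_derivative_integrates_to_total_fraction_change(wt_curve):
    norm = meltfit.normalize_melt(wt_curve)
    deriv = meltfit.first_derivative(norm)
    integral = np.trapezoid(deriv.dfdT, deriv.temperature)
    assert integral == pytest.approx(1.0, rel=0.02)


def test_derivative_smoothing_window_validation(wt_curve):
    norm = meltfit.normalize_melt(wt_curve)
    with pytest.raises(ParameterError):
        meltfit.first_derivative(norm, smoothing_window=0.01)
    with pytest.raises(ParameterError):
        meltfit.first_derivative(norm, smoothing_window=30.0)


# ---------------------------------------------------------------------------
# Gaussian deconvolution


def test_gaussian_selffit_recovers_exact_mean():
    t = np.arange(10.0, 50.1, 0.1)
    mu, sd = 31.7, 2.3
    y = np.exp(-0.5 * ((t - mu) / sd) ** 2) / (sd * np.sqrt(2 * np.pi))
    deriv = meltfit.DerivativeCurve(t, y, smoothing_window=1.0)
    res = meltfit.fit_gaussians(deriv, 1)
    assert res.gaussian_components[0].mean == pytest.approx(mu, abs=1e-6)


def test_single_gaussian_recovers_wt_tm(wt_model):
    _, _, gauss = run_melt_pipeline(wt_model, n_components=1)
    assert gauss.gaussian_components[0].mean == pytest.approx(34.1, abs=0.3)


def test_two_gaussians_recover_biphasic_parameters(biphasic_model):
    _, _, gauss = run_melt_pipeline(biphasic_model, n_components=2)
    means = [c.mean for c in gauss.gaussian_components]
    areas = [c.area for c in gauss.gaussian_components]
    assert means[0] == pytest.approx(29.2, abs=0.3)
    assert means[1] == pytest.approx(43.2, abs=0.3)
    assert areas[0] == pytest.approx(0.60, abs=0.03)


def test_gaussian_areas_always_sum_to_one(wt_model, biphasic_model):
    for model, n in ((wt_model, 1), (biphasic_model, 2)):
        _, _, gauss = run_melt_pipeline(model, n_components=n)
        assert sum(c.area for c in gauss.gaussian_components) == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# model selection


def test_selection_single_transition_returns_one(wt_model):
    _, deriv, _ = run_melt_pipeline(wt_model, n_components=1)
    n, _ = meltfit.select_n_components(deriv)
    assert n == 1


def test_selection_biphasic_with_noise_returns_two():
    model = reference.unfolding_model("E129K", True)  # 29.3 / 38.1, 0.6/0.4
    curves = simulate.gen_melt(simulate.MeltSimSpec(model=model, noise_sd=0.005, seed=7))
    norm = meltfit.normalize_melt(curves[0])
    deriv = meltfit.first_derivative(norm)
    n, table = meltfit.select_n_components(deriv)
    assert n == 2
    assert table["delta"] > table["threshold"]


def test_selection_unresolvable_close_transitions_returns_one():
    model = thermo.two_transition_model(30.0, -400.0, 31.0, -400.0, amplitude1=0.5)
    _, deriv, _ = run_melt_pipeline(model, n_components=1)
    n, _ = meltfit.select_n_components(deriv)
    assert n == 1


def test_selection_no_false_positives_across_seeds(wt_model):
    """With one generating transition and sd ≤ 0.01, selection never says 2."""
    for seed in range(100):
        curves = simulate.gen_melt(
            simulate.MeltSimSpec(model=wt_model, noise_sd=0.01, seed=seed)
        )
        deriv = meltfit.first_derivative(meltfit.normalize_melt(curves[0]))
        n, _ = meltfit.select_n_components(deriv)
        assert n == 1, f"false positive at seed {seed}"


# ---------------------------------------------------------------------------
# direct van't Hoff fit


def test_vant_hoff_recovers_wt_enthalpy(wt_model):
    norm, _, gauss = run_melt_pipeline(wt_model, n_components=1)
    res = meltfit.fit_vant_hoff(norm, 1, init_from=gauss)
    assert res.transitions[0].dh == pytest.approx(-455.8, abs=5.0)
    assert res.transitions[0].tm == pytest.approx(34.1, abs=0.1)


def test_vant_hoff_recovers_double_mutant_enthalpy():
    model = reference.unfolding_model("A18T/E31K", False)
    norm, _, gauss = run_melt_pipeline(model, n_components=1)
    res = meltfit.fit_vant_hoff(norm, 1, init_from=gauss)
    assert res.transitions[0].dh == pytest.approx(-276.0, abs=5.0)


def test_vant_hoff_selfconsistency_zero_noise_rss(wt_model):
    t = np.arange(10.0, 50.1, 0.1)
    norm = meltfit.NormalizedMelt(t, thermo.fraction_unfolded(wt_model, t))
    res = meltfit.fit_vant_hoff(norm, 1)
    assert res.rss < 1e-10


def test_vant_hoff_flags_enthalpy_at_bounds():
    model = thermo.single_transition_model(30.0, -55.0)  # near the lower |dH| bound
    curve = simulate.gen_melt(simulate.MeltSimSpec(model=model, grid=(0.0, 60.0, 0.1)))[0]
    norm = meltfit.normalize_melt(curve)
    res = meltfit.fit_vant_hoff(norm, 1)
    # either fitted cleanly inside bounds or flagged; never silently clipped
    dh = abs(res.transitions[0].dh)
    assert dh >= 50.0
    if dh <= 50.1:
        assert res.warnings


# ---------------------------------------------------------------------------
# pipeline-level invariants


@pytest.mark.parametrize("n_transitions", [1, 2])
@pytest.mark.parametrize("draw", range(3))
def test_noise_free_roundtrip_recovers_parameters(n_transitions, draw):
    """Simulate→analyse recovers Tm to 0.3 °C and |ΔH| to 2% for valid models."""
    rng = np.random.default_rng(100 * n_transitions + draw)
    model = random_valid_model(rng, n_transitions)
    norm, _, gauss = run_melt_pipeline(model, n_components=n_transitions)
    res = meltfit.fit_vant_hoff(norm, n_transitions, init_from=gauss)
    for fitted, truth in zip(res.transitions, model.transitions):
        assert fitted.tm == pytest.approx(truth.tm, abs=0.3)
        assert abs(fitted.dh) == pytest.approx(abs(truth.dh), rel=0.02)


def test_noisy_single_transition_median_tm_error(wt_model):
    """At fraction-noise sd 0.01 the median |Tm error| stays below 0.5 °C."""
    errors = []
    for seed in range(100):
        # noise in fraction units on a unit-span signal
        curves = simulate.gen_melt(simulate.MeltSimSpec(model=wt_model, noise_sd=0.01, seed=seed))
        norm = meltfit.normalize_melt(curves[0])
        deriv = meltfit.first_derivative(norm)
        gauss = meltfit.fit_gaussians(deriv, 1)
        errors.append(abs(gauss.gaussian_components[0].mean - 34.1))
    assert np.median(errors) < 0.5


def test_heating_direction_invariance(wt_curve):
    res_fwd = meltfit.analyze_melt(wt_curve, components=1)
    rows = list(zip(wt_curve.temperature, wt_curve.signal))[::-1]
    text = "temperature,signal\n" + "\n".join(f"{float(t)!r},{float(s)!r}" for t, s in rows)
    flipped = meltfit.read_melt(io.StringIO(text))
    res_rev = meltfit.analyze_melt(flipped, components=1)
    assert res_fwd.transitions[0].tm == pytest.approx(res_rev.transitions[0].tm, abs=1e-6)
    assert res_fwd.transitions[0].dh == pytest.approx(res_rev.transitions[0].dh, abs=1e-4)


def test_replicate_averaging_reduces_to_mean():
    t = np.arange(10.0, 50.5, 0.5)
    c1 = meltfit.MeltCurve(t, np.ones_like(t))
    c2 = meltfit.MeltCurve(t, 3 * np.ones_like(t))
    avg = meltfit.average_melts([c1, c2])
    assert np.allclose(avg.signal, 2.0)
    assert avg.meta["n_replicates_averaged"] == 2


def test_replicate_averaging_interpolates_other_grids(wt_model):
    spec = simulate.MeltSimSpec(model=wt_model)
    c1 = simulate.gen_melt(spec)[0]
    t2 = np.arange(9.95, 50.4, 0.07)
    c2 = meltfit.MeltCurve(t2, thermo.signal_from_fraction(wt_model, t2))
    avg = meltfit.average_melts([c1, c2])
    assert avg.temperature.size == c1.temperature.size
    assert np.max(np.abs(avg.signal - c1.signal)) < 1e-3
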