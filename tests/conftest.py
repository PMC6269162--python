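import numpy as np
import pytest

from tropofit import meltfit, reference, simulate, thermo


@pytest.fixture
def wt_model():
    """Noise-free single-transition model of unacetylated wild type."""
    return reference.unfolding_model("WT", False)


@pytest.fixture
def biphasic_model():
    """Acetylated double-mutant model: two transitions, 0.6/0.4 split."""
    return reference.unfolding_model("A18T/E31K", True)


@pytest.fixture
def wt_curve(wt_model):
    return simulate.gen_melt(simulate.MeltSimSpec(model=wt_model))[0]


def run_melt_pipeline(model, n_components=None, noise_sd=0.0, seed=0, replicates=1):
    """Simulate one melt and run normalise → derivative → Gaussians (+ count)."""
    curves = simulate.gen_melt(
        simulate.MeltSimSpec(model=model, noise_sd=noise_sd, seed=seed, replicates=replicates)
    )
    curve = meltfit.average_melts(curves) if replicates > 1 else curves[0]
    norm = meltfit.normalize_melt(curve)
    deriv = meltfit.first_derivative(norm)
    if n_components is None:
        n_components, _ = meltfit.select_n_components(deriv)
    gauss = meltfit.fit_gaussians(deriv, n_components)
    return norm, deriv, gauss


def random_valid_model(rng: np.random.Generator, n_transitions: int = 1) -> thermo.UnfoldingModel:
    """Draw a well-separated, identifiable unfolding model inside the window."""
    if n_transitions == 1:
        tm = rng.uniform(20.0, 42.0)
        dh = -rng.uniform(200.0, 700.0)
        return thermo.single_transition_model(tm, dh)
    tm1 = rng.uniform(20.0, 32.0)
    tm2 = tm1 + rng.uniform(6.0, 14.0)
    amp1 = rng.uniform(0.2, 0.8)
    return thermo.two_transition_model(
        tm1, -rng.uniform(250.0, 600.0), tm2, -rng.uniform(250.0, 600.0), amplitude1=amp1
    )
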