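"""Two-state van't Hoff model of coiled-coil thermal unfolding.

A tropomyosin melt is modelled as one or two independent two-state
(folded ⇌ unfolded) transitions.  Each transition ``i`` contributes

    K_i(T) = exp( (|ΔH_i| / R) · (1/Tm_i − 1/T) )      (temperatures in kelvin)
    f_i(T) = K_i / (1 + K_i)

and the overall unfolded fraction is the amplitude-weighted sum
``f(T) = Σ a_i · f_i(T)`` with ``Σ a_i = 1``.  ΔCp is taken as zero, so a
single enthalpy governs each transition; at ``T = Tm`` the unfolded fraction
of a transition is exactly one half and its slope is ``|ΔH|/(4·R·Tm²)``.

Enthalpies are reported with the convention used throughout this package:
printed ΔH values are negative (signal-loss convention), while internally
the unfolding equilibrium uses the positive magnitude so that K grows with
temperature.  All public interfaces take °C; kelvin is internal only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidModelError

#: Gas constant, J·mol⁻¹·K⁻¹.
R = 8.314

#: °C → K offset.
KELVIN_OFFSET = 273.15


@dataclass(frozen=True)
class Transition:
    """One two-state unfolding event.

    Parameters
    ----------
    tm : float
        Melting midpoint, °C.
    dh : float
        van't Hoff enthalpy, kJ·mol⁻¹, in the reporting sign convention
        (typically negative); only the magnitude enters the model.
    amplitude : float
        Fraction of the total unfolding signal carried by this transition,
        in (0, 1].
    """

    tm: float
    dh: float
    amplitude: float = 1.0

    def __post_init__(self):
        if not (np.isfinite(self.tm) and np.isfinite(self.dh) and np.isfinite(self.amplitude)):
            raise InvalidModelError(f"non-finite transition parameters: {self}")
        if abs(self.dh) <= 0:
            raise InvalidModelError("|dH| must be positive")
        if not (0.0 < self.amplitude <= 1.0):
            raise InvalidModelError(f"amplitude {self.amplitude} outside (0, 1]")

    @property
    def dh_magnitude(self) -> float:
        """Unfolding enthalpy magnitude, kJ·mol⁻¹."""
        return abs(self.dh)

    @property
    def tm_kelvin(self) -> float:
        return self.tm + KELVIN_OFFSET


@dataclass(frozen=True)
class UnfoldingModel:
    """One- or two-transition unfolding model with linear signal baselines.

    ``baseline_folded`` and ``baseline_unfolded`` are ``(intercept, slope)``
    pairs of the raw-signal baselines, evaluated as ``intercept + slope·T``
    with T in °C.
    """

    transitions: tuple[Transition, ...]
    baseline_folded: tuple[float, float] = (0.0, 0.0)
    baseline_unfolded: tuple[float, float] = (1.0, 0.0)

    def __post_init__(self):
        trans = tuple(self.transitions)
        if not (1 <= len(trans) <= 2):
            raise InvalidModelError("model must have 1 or 2 transitions")
        if list(t.tm for t in trans) != sorted(t.tm for t in trans):
            trans = tuple(sorted(trans, key=lambda t: t.tm))
        object.__setattr__(self, "transitions", trans)
        total = sum(t.amplitude for t in trans)
        if abs(total - 1.0) > 1e-9:
            raise InvalidModelError(f"amplitudes sum to {total}, expected 1")
        for name in ("baseline_folded", "baseline_unfolded"):
            b = getattr(self, name)
            if len(b) != 2 or not all(np.isfinite(v) for v in b):
                raise InvalidModelError(f"{name} must be a finite (intercept, slope) pair")


def transition_fraction(tm: float, dh_magnitude_kj: float, temperature_c: np.ndarray) -> np.ndarray:
    """Unfolded fraction of a single two-state transition on a °C grid."""
    t_k = np.asarray(temperature_c, dtype=float) + KELVIN_OFFSET
    tm_k = tm + KELVIN_OFFSET
    ln_k = (dh_magnitude_kj * 1e3 / R) * (1.0 / tm_k - 1.0 / t_k)
    # logistic form avoids overflow for large |ln K|
    return 1.0 / (1.0 + np.exp(-ln_k))


def fraction_unfolded(model: UnfoldingModel, temperature_c: np.ndarray) -> np.ndarray:
    """Overall unfolded fraction f(T) on a strictly increasing °C grid.

    Returns values in [0, 1], non-decreasing in T.  At each transition's Tm
    that transition contributes exactly half its amplitude.
    """
    t = np.asarray(temperature_c, dtype=float)
    if t.ndim != 1 or t.size < 1:
        raise InvalidModelError("temperature grid must be a 1-D array")
    if t.size > 1 and not np.all(np.diff(t) > 0):
        raise InvalidModelError("temperature grid must be strictly increasing")
    f = np.zeros_like(t)
    for tr in model.transitions:
        f += tr.amplitude * transition_fraction(tr.tm, tr.dh_magnitude, t)
    return np.clip(f, 0.0, 1.0)


def signal_from_fraction(model: UnfoldingModel, temperature_c: np.ndarray) -> np.ndarray:
    """Raw CD signal: folded/unfolded linear baselines mixed by f(T)."""
    t = np.asarray(temperature_c, dtype=float)
    f = fraction_unfolded(model, t)
    bf = model.baseline_folded[0] + model.baseline_folded[1] * t
    bu = model.baseline_unfolded[0] + model.baseline_unfolded[1] * t
    return bf * (1.0 - f) + bu * f


def dfdt_at_tm(transition: Transition) -> float:
    """Analytic slope of a single transition's unfolded fraction at its Tm.

    Equals |ΔH| / (4·R·Tm²) per kelvin (identical per °C).
    """
    tm_k = transition.tm_kelvin
    return transition.dh_magnitude * 1e3 / (4.0 * R * tm_k**2)


def single_transition_model(tm: float, dh: float, **baselines) -> UnfoldingModel:
    """Convenience constructor for a one-transition model."""
    return UnfoldingModel(transitions=(Transition(tm=tm, dh=dh, amplitude=1.0),), **baselines)


def two_transition_model(
    tm1: float, dh1: float, tm2: float, dh2: float, amplitude1: float = 0.6, **baselines
) -> UnfoldingModel:
    """Convenience constructor for a two-transition model (amplitudes a, 1−a)."""
    return UnfoldingModel(
        transitions=(
            Transition(tm=tm1, dh=dh1, amplitude=amplitude1),
            Transition(tm=tm2, dh=dh2, amplitude=1.0 - amplitude1),
        ),
        **baselines,
    )
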