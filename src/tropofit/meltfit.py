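"""CD melting-curve analysis pipeline.

The pipeline mirrors standard practice for coiled-coil thermal denaturation
followed at 222 nm: the raw trace is normalised to fraction unfolded over a
10–50 °C window, a smoothed first derivative is computed, one or two
Gaussians are fitted to the derivative to locate melting midpoints (Tm),
the number of transitions is chosen by a corrected information criterion,
and finally the full van't Hoff model is fitted directly to the normalised
curve to obtain enthalpies and amplitude fractions.

Two ΔH estimates are available: the canonical direct model fit, and a
secondary derivative-based estimate ``|ΔH| = 4·R·Tm²·h`` where ``h`` is the
Gaussian peak height of df/dT (the analytic slope identity at the midpoint).
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

from . import thermo
from .errors import (
    DegenerateCurveError,
    FitFailureError,
    InputError,
    ParameterError,
    ParseError,
)

__all__ = [
    "MeltCurve",
    "NormalizedMelt",
    "DerivativeCurve",
    "GaussianComponent",
    "MeltFitResult",
    "read_melt",
    "average_melts",
    "normalize_melt",
    "first_derivative",
    "fit_gaussians",
    "select_n_components",
    "fit_vant_hoff",
    "analyze_melt",
]

#: Default normalisation window, °C.
DEFAULT_WINDOW = (10.0, 50.0)

#: Default derivative smoothing window, °C.
DEFAULT_SMOOTH = 1.0

#: Information-criterion improvement required to accept a second component.
DEFAULT_SELECTION_THRESHOLD = 10.0

#: Smallest Gaussian area fraction that counts as a real transition.
MIN_COMPONENT_AREA = 0.1

#: Bounds on |ΔH| during the direct fit, kJ·mol⁻¹.
DH_BOUNDS = (50.0, 1500.0)


@dataclass
class MeltCurve:
    """Raw 222 nm melt trace with assay metadata."""

    temperature: np.ndarray
    signal: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperature.size < 2:
            raise InputError("melt curve needs at least 2 points")
        if not np.all(np.isfinite(self.signal)) or not np.all(np.isfinite(self.temperature)):
            raise InputError("melt curve contains non-finite values")
        if not np.all(np.diff(self.temperature) > 0):
            raise InputError("temperature grid must be strictly increasing")


@dataclass
class NormalizedMelt:
    """Fraction-unfolded curve; metadata carried through from the source."""

    temperature: np.ndarray
    fraction: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class DerivativeCurve:
    """Smoothed first derivative of the unfolded fraction, per °C."""

    temperature: np.ndarray
    dfdT: np.ndarray
    smoothing_window: float
    meta: dict = field(default_factory=dict)


@dataclass(frozen=True)
class GaussianComponent:
    """One Gaussian fitted to df/dT: mean and sd in °C, normalised area."""

    mean: float
    sd: float
    area: float

    @property
    def height(self) -> float:
        """Peak height of the component, fraction·°C⁻¹ (before area renormalisation)."""
        return self.area / (self.sd * math.sqrt(2.0 * math.pi))


@dataclass
class MeltFitResult:
    """Combined Gaussian-deconvolution and van't Hoff fit report."""

    transitions: tuple[thermo.Transition, ...]
    n_components: int
    gaussian_components: tuple[GaussianComponent, ...]
    rss: float
    model_selection: dict = field(default_factory=dict)
    dh_from_derivative: tuple[float, ...] = ()
    warnings: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_components": self.n_components,
            "transitions": [
                {"tm_C": t.tm, "dh_kj_mol": t.dh, "amplitude": t.amplitude}
                for t in self.transitions
            ],
            "gaussian_components": [
                {"mean_C": g.mean, "sd_C": g.sd, "area": g.area}
                for g in self.gaussian_components
            ],
            "dh_from_derivative_kj_mol": list(self.dh_from_derivative),
            "rss": self.rss,
            "model_selection": self.model_selection,
            "warnings": list(self.warnings),
            "meta": self.meta,
        }


# ---------------------------------------------------------------------------
# I/O


def read_melt(path, meta: dict | None = None) -> MeltCurve:
    """Read a two-column (temperature °C, signal) table, comma or tab separated.

    An optional single header row is tolerated.  Rows are sorted by
    temperature and duplicate temperatures averaged.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text()
    else:  # file-like
        text = path.read()
    try:
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python", comment="#")
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise ParseError(f"could not parse melt table: {exc}") from exc
    # headerless files: pandas will have absorbed the first numeric row as header
    try:
        float(str(df.columns[0]))
        df = pd.read_csv(io.StringIO(text), sep=None, engine="python", comment="#", header=None)
    except ValueError:
        pass
    if df.shape[1] < 2:
        raise ParseError("melt table must have two columns (temperature, signal)")
    sub = df.iloc[:, :2].copy()
    sub.columns = ["temperature", "signal"]
    numeric = sub.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        first_bad = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError("non-numeric row in melt table", line=first_bad + 1)
    grouped = numeric.groupby("temperature", as_index=False)["signal"].mean()
    grouped = grouped.sort_values("temperature")
    if len(grouped) < 2:
        raise InputError("melt table has fewer than 2 distinct temperatures")
    return MeltCurve(
        temperature=grouped["temperature"].to_numpy(),
        signal=grouped["signal"].to_numpy(),
        meta=dict(meta or {}),
    )


def average_melts(curves: list[MeltCurve]) -> MeltCurve:
    """Pointwise mean of replicate melts on the first replicate's grid.

    Other replicates are linearly interpolated onto that grid before
    averaging, which is how triplicate unfolding profiles are combined.
    """
    if not curves:
        raise InputError("no curves to average")
    grid = curves[0].temperature
    stack = [curves[0].signal]
    for c in curves[1:]:
        stack.append(np.interp(grid, c.temperature, c.signal))
    meta = dict(curves[0].meta)
    meta["n_replicates_averaged"] = len(curves)
    return MeltCurve(temperature=grid, signal=np.mean(stack, axis=0), meta=meta)


# ---------------------------------------------------------------------------
# normalisation and differentiation


def _moving_mean(y: np.ndarray, n: int) -> np.ndarray:
    """Centred moving mean; odd-reflection padding keeps linear trends exact at the edges."""
    if n <= 1:
        return y.copy()
    half = n // 2
    wlen = 2 * half + 1
    if wlen >= y.size:
        raise ParameterError("smoothing window covers the whole trace")
    ypad = np.pad(y, half, mode="reflect", reflect_type="odd")
    return np.convolve(ypad, np.full(wlen, 1.0 / wlen), mode="valid")


def _window_points(temperature: np.ndarray, window_c: float) -> int:
    step = float(np.median(np.diff(temperature)))
    return max(1, int(round(window_c / step)))


def normalize_melt(
    curve: MeltCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    baseline_mode: str = "minmax",
    smooth: float = 0.5,
    noise_floor: float = 1e-12,
) -> NormalizedMelt:
    """Convert a raw melt trace to fraction unfolded over the window.

    With ``baseline_mode="minmax"`` the folded/unfolded reference signals are
    the extrema of a lightly smoothed trace within the window; the reference
    closer to the low-temperature side is taken as folded.  With ``"linear"``,
    straight baselines are fitted to the outer 15% of the window on each side
    and evaluated pointwise.  The fraction is clamped to [0, 1].
    """
    lo, hi = window
    t, s = curve.temperature, curve.signal
    if t[0] > lo + 1e-9 or t[-1] < hi - 1e-9:
        raise InputError(
            f"curve spans [{t[0]:g}, {t[-1]:g}] °C but the normalisation window is "
            f"[{lo:g}, {hi:g}] °C"
        )
    inside = (t >= lo) & (t <= hi)
    smoothed = _moving_mean(s, _window_points(t, smooth))
    s_win = smoothed[inside]
    t_win = t[inside]

    if baseline_mode == "minmax":
        i_min, i_max = int(np.argmin(s_win)), int(np.argmax(s_win))
        if abs(s_win[i_max] - s_win[i_min]) <= noise_floor:
            raise DegenerateCurveError("flat signal: min and max coincide within the noise floor")
        # folded reference = extremum on the low-temperature side
        if t_win[i_min] <= t_win[i_max]:
            folded, unfolded = s_win[i_min], s_win[i_max]
        else:
            folded, unfolded = s_win[i_max], s_win[i_min]
        fraction = (s - folded) / (unfolded - folded)
    elif baseline_mode == "linear":
        span = hi - lo
        pre = inside & (t <= lo + 0.15 * span)
        post = inside & (t >= hi - 0.15 * span)
        pf = np.polyfit(t[pre], s[pre], 1)
        pu = np.polyfit(t[post], s[post], 1)
        bf, bu = np.polyval(pf, t), np.polyval(pu, t)
        denom = bu - bf
        if np.max(np.abs(denom[inside])) <= noise_floor:
            raise DegenerateCurveError("flat signal: baselines coincide within the noise floor")
        fraction = (s - bf) / denom
    else:
        raise ParameterError(f"unknown baseline_mode {baseline_mode!r}")

    return NormalizedMelt(
        temperature=t.copy(), fraction=np.clip(fraction, 0.0, 1.0), meta=dict(curve.meta)
    )


def first_derivative(norm: NormalizedMelt, smoothing_window: float = DEFAULT_SMOOTH) -> DerivativeCurve:
    """df/dT of the smoothed fraction: central differences, one-sided ends."""
    t, f = norm.temperature, norm.fraction
    if t.size < 5:
        raise InputError("derivative requires at least 5 points")
    step = float(np.median(np.diff(t)))
    if smoothing_window < step:
        raise ParameterError(
            f"smoothing window {smoothing_window:g} °C below grid spacing {step:g} °C"
        )
    if smoothing_window > (t[-1] - t[0]) / 2:
        raise ParameterError("smoothing window exceeds half the temperature span")
    smoothed = _moving_mean(f, _window_points(t, smoothing_window))
    dfdT = np.gradient(smoothed, t)
    return DerivativeCurve(
        temperature=t.copy(), dfdT=dfdT, smoothing_window=smoothing_window, meta=dict(norm.meta)
    )


# ---------------------------------------------------------------------------
# Gaussian deconvolution of the derivative


def _initial_peaks(
    deriv: DerivativeCurve, n: int, min_separation_c: float = 3.0
) -> list[tuple[float, float]]:
    """(temperature, height) of the n largest well-separated derivative maxima.

    Peaks are picked on an extra-smoothed copy of df/dT so that noise
    maxima do not seed the fit; candidates closer than ``min_separation_c``
    collapse into one.  Ties in height break toward the lower temperature.
    Falls back to the global maximum (plus a quarter-span offset guess)
    when fewer maxima than requested survive.
    """
    from scipy.signal import find_peaks

    t, y = deriv.temperature, deriv.dfdT
    step = float(np.median(np.diff(t)))
    ys = _moving_mean(y, _window_points(t, 1.0))
    cand, _ = find_peaks(ys, distance=max(1, int(round(min_separation_c / step))))
    if cand.size == 0:
        cand = np.asarray([int(np.argmax(ys))])
    order = sorted(cand, key=lambda i: (-ys[i], t[i]))
    peaks = [(float(t[i]), float(max(ys[i], 1e-9))) for i in order[:n]]
    while len(peaks) < n:
        offset = (t[-1] - t[0]) / 4.0
        peaks.append((min(peaks[0][0] + offset, float(t[-1])), peaks[0][1] / 2.0))
    return sorted(peaks)


def fit_gaussians(deriv: DerivativeCurve, n_components: int) -> MeltFitResult:
    """Fit a sum of ``n_components`` Gaussians to df/dT.

    Means initialise at the highest derivative maxima (lower temperature
    first on ties).  Components are returned in ascending mean order with
    areas renormalised to sum to one; a secondary ΔH estimate per component
    comes from the midpoint slope identity |ΔH| = 4·R·Tm²·height.
    """
    if n_components not in (1, 2):
        raise ParameterError("n_components must be 1 or 2")
    t, y = deriv.temperature, deriv.dfdT
    step = float(np.median(np.diff(t)))

    def run_fit(peaks):
        model = None
        params = None
        for k, (mu, height) in enumerate(peaks, start=1):
            g = lmfit.models.GaussianModel(prefix=f"g{k}_")
            model = g if model is None else model + g
            p = g.make_params()
            sd0 = 2.0
            p[f"g{k}_center"].set(value=mu, min=float(t[0]), max=float(t[-1]))
            p[f"g{k}_sigma"].set(value=sd0, min=step, max=(t[-1] - t[0]))
            p[f"g{k}_amplitude"].set(value=max(height, 1e-6) * sd0 * math.sqrt(2 * math.pi), min=0.0)
            params = p if params is None else params.update(p) or params
        try:
            return model.fit(y, params, x=t)
        except Exception as exc:
            raise FitFailureError(f"Gaussian fit failed: {exc}") from exc

    peaks = _initial_peaks(deriv, n_components)
    out = run_fit(peaks)
    if n_components == 2:
        # one bounded restart if a component collapsed onto the other:
        # re-seed the second Gaussian at the largest positive residual
        areas = [out.params[f"g{k}_amplitude"].value for k in (1, 2)]
        total = sum(areas)
        if total > 0 and min(areas) / total < 0.01:
            resid = y - out.best_fit
            i = int(np.argmax(resid))
            retry = sorted([peaks[0], (float(t[i]), float(max(resid[i], 1e-9)))])
            out2 = run_fit(retry)
            if np.sum(out2.residual**2) < np.sum(out.residual**2):
                out = out2
    if not out.success:
        raise FitFailureError("Gaussian fit did not converge", diagnostics={"lmfit": out.message})

    comps = []
    for k in range(1, n_components + 1):
        comps.append(
            GaussianComponent(
                mean=float(out.params[f"g{k}_center"].value),
                sd=float(out.params[f"g{k}_sigma"].value),
                area=float(out.params[f"g{k}_amplitude"].value),
            )
        )
    comps.sort(key=lambda c: c.mean)
    total_area = sum(c.area for c in comps)
    if total_area <= 0:
        raise FitFailureError("Gaussian fit collapsed to zero area")
    heights = [c.height for c in comps]
    comps = [replace(c, area=c.area / total_area) for c in comps]

    dh_secondary = tuple(
        -(4.0 * thermo.R * (c.mean + thermo.KELVIN_OFFSET) ** 2 * h) / 1e3
        for c, h in zip(comps, heights)
    )
    transitions = tuple(
        thermo.Transition(tm=c.mean, dh=dh, amplitude=c.area)
        for c, dh in zip(comps, dh_secondary)
    )
    n_pts = y.size
    n_par = 3 * n_components
    rss = float(np.sum(out.residual**2))
    aicc = _aicc(rss, n_pts, n_par)
    return MeltFitResult(
        transitions=transitions,
        n_components=n_components,
        gaussian_components=tuple(comps),
        rss=rss,
        model_selection={f"aicc_{n_components}": aicc},
        dh_from_derivative=dh_secondary,
        meta=dict(deriv.meta),
    )


def _aicc(rss: float, n: int, k: int) -> float:
    """Small-sample-corrected AIC for Gaussian residuals."""
    rss = max(rss, 1e-300)
    aic = n * math.log(rss / n) + 2 * k
    if n - k - 1 > 0:
        aic += 2 * k * (k + 1) / (n - k - 1)
    return aic


def select_n_components(
    deriv: DerivativeCurve,
    threshold: float = DEFAULT_SELECTION_THRESHOLD,
    min_component_area: float = MIN_COMPONENT_AREA,
) -> tuple[int, dict]:
    """Choose 1 vs 2 transitions from the derivative curve.

    Returns 2 only when the two-component fit improves the corrected
    information criterion by more than ``threshold`` AND the two means are
    separated by more than twice the larger fitted sd AND the minor
    component carries at least ``min_component_area`` of the total area
    (a tiny second Gaussian fitting the skew tail of a two-state peak is
    not a transition); otherwise 1.  Also returns the criterion table.
    """
    results = {}
    errors = {}
    for n in (1, 2):
        try:
            results[n] = fit_gaussians(deriv, n)
        except FitFailureError as exc:
            errors[n] = exc
    if not results:
        raise FitFailureError("both 1- and 2-component Gaussian fits failed", diagnostics=errors)
    if 2 not in results:
        return 1, {"aicc_1": results[1].model_selection["aicc_1"], "aicc_2": None}
    if 1 not in results:
        return 2, {"aicc_1": None, "aicc_2": results[2].model_selection["aicc_2"]}
    a1 = results[1].model_selection["aicc_1"]
    a2 = results[2].model_selection["aicc_2"]
    comps = results[2].gaussian_components
    separation = abs(comps[1].mean - comps[0].mean)
    resolved = separation > 2.0 * max(c.sd for c in comps)
    minor_area = min(c.area for c in comps)
    table = {
        "aicc_1": a1,
        "aicc_2": a2,
        "delta": a1 - a2,
        "threshold": threshold,
        "separation_C": separation,
        "resolved": resolved,
        "minor_area": minor_area,
        "min_component_area": min_component_area,
    }
    n_sel = 2 if (a1 - a2 > threshold and resolved and minor_area >= min_component_area) else 1
    return n_sel, table


# ---------------------------------------------------------------------------
# direct van't Hoff fit


def fit_vant_hoff(
    norm: NormalizedMelt,
    n_components: int,
    init_from: MeltFitResult | None = None,
) -> MeltFitResult:
    """Direct nonlinear least-squares fit of the unfolding model to f(T).

    Initialised from the Gaussian deconvolution when supplied (Tm ← means,
    amplitudes ← areas, |ΔH| ← 4·R·Tm²·peak-height).  An affine nuisance
    (offset, scale) absorbs the min–max normalisation of truncated
    transitions so the thermodynamic parameters stay unbiased.  ΔH is
    reported negated, per the signal-loss sign convention.
    """
    if n_components not in (1, 2):
        raise ParameterError("n_components must be 1 or 2")
    t, f = norm.temperature, norm.fraction

    params = lmfit.Parameters()
    if init_from is not None and len(init_from.transitions) >= n_components:
        init = init_from.transitions[:n_components]
        tms = [tr.tm for tr in init]
        dhs = [min(max(tr.dh_magnitude, DH_BOUNDS[0] * 1.2), DH_BOUNDS[1] / 1.2) for tr in init]
        amp1 = init[0].amplitude
    else:
        peaks = _initial_peaks(first_derivative(norm), n_components)
        tms = [p[0] for p in peaks]
        dhs = [
            min(max(4.0 * thermo.R * (mu + thermo.KELVIN_OFFSET) ** 2 * h / 1e3, DH_BOUNDS[0] * 1.2), DH_BOUNDS[1] / 1.2)
            for mu, h in peaks
        ]
        amp1 = 0.6 if n_components == 2 else 1.0
    for k in range(n_components):
        params.add(f"tm{k+1}", value=tms[k], min=float(t[0]) - 5.0, max=float(t[-1]) + 5.0)
        params.add(f"dh{k+1}", value=dhs[k], min=DH_BOUNDS[0], max=DH_BOUNDS[1])
    if n_components == 2:
        params.add("amp1", value=min(max(amp1, 0.05), 0.95), min=0.01, max=0.99)
    params.add("offset", value=0.0, min=-0.3, max=0.3)
    params.add("scale", value=1.0, min=0.5, max=1.5)

    def predict(p) -> np.ndarray:
        out = np.zeros_like(t)
        amps = [p["amp1"].value, 1.0 - p["amp1"].value] if n_components == 2 else [1.0]
        for k in range(n_components):
            out += amps[k] * thermo.transition_fraction(p[f"tm{k+1}"].value, p[f"dh{k+1}"].value, t)
        return p["offset"].value + p["scale"].value * out

    def residual(p):
        return predict(p) - f

    minres = lmfit.minimize(residual, params, method="leastsq")
    if not minres.success:
        raise FitFailureError("van't Hoff fit did not converge", diagnostics={"lmfit": minres.message})
    p = minres.params
    order = sorted(range(n_components), key=lambda k: p[f"tm{k+1}"].value)
    amps = [p["amp1"].value, 1.0 - p["amp1"].value] if n_components == 2 else [1.0]
    transitions = tuple(
        thermo.Transition(tm=float(p[f"tm{k+1}"].value), dh=-float(p[f"dh{k+1}"].value), amplitude=float(amps[k]))
        for k in order
    )
    warnings = []
    for k in range(n_components):
        dh = p[f"dh{k+1}"].value
        if dh <= DH_BOUNDS[0] * 1.001 or dh >= DH_BOUNDS[1] * 0.999:
            warnings.append(f"|dH| of transition {k+1} at bound ({dh:.1f} kJ/mol)")
    rss = float(np.sum(np.asarray(minres.residual) ** 2))
    gauss = init_from.gaussian_components if init_from is not None else ()
    return MeltFitResult(
        transitions=transitions,
        n_components=n_components,
        gaussian_components=tuple(gauss),
        rss=rss,
        model_selection=dict(init_from.model_selection) if init_from is not None else {},
        dh_from_derivative=init_from.dh_from_derivative if init_from is not None else (),
        warnings=tuple(warnings),
        meta=dict(norm.meta),
    )


# ---------------------------------------------------------------------------
# one-call pipeline


def analyze_melt(
    curve: MeltCurve,
    window: tuple[float, float] = DEFAULT_WINDOW,
    baseline_mode: str = "minmax",
    smoothing_window: float = DEFAULT_SMOOTH,
    components: int | str = "auto",
    selection_threshold: float = DEFAULT_SELECTION_THRESHOLD,
) -> MeltFitResult:
    """Full pipeline: normalise → differentiate → deconvolve → van't Hoff fit."""
    norm = normalize_melt(curve, window=window, baseline_mode=baseline_mode)
    deriv = first_derivative(norm, smoothing_window=smoothing_window)
    if components == "auto":
        n_sel, table = select_n_components(deriv, threshold=selection_threshold)
    else:
        n_sel, table = int(components), {}
    gauss = fit_gaussians(deriv, n_sel)
    gauss.model_selection.update(table)
    return fit_vant_hoff(norm, n_sel, init_from=gauss)
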