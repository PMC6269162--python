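"""Actin–tropomyosin co-sedimentation analysis.

Gel densitometry of pellet fractions is converted to fractional saturation
θ of the actin filament by tropomyosin, the free tropomyosin concentration
is obtained by subtracting the bound amount from the total, and the Hill
equation

    θ(free) = θ_max · free^n / (K50^n + free^n)

is fitted to yield K50% (free Tpm at half saturation) and the Hill
coefficient n.  Because tropomyosin polymerises end-to-end on actin, K50%
is an apparent half-saturation constant, not a true dissociation constant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .errors import CalibrationError, DataError, InputError, UnidentifiableError

__all__ = [
    "BindingSeries",
    "HillFit",
    "saturation_from_density",
    "free_tpm",
    "hill_curve",
    "fit_hill",
    "read_binding",
    "analyze_binding",
]

#: Default actin monomers per bound tropomyosin dimer.
DEFAULT_STOICHIOMETRY = 4.0


@dataclass
class BindingSeries:
    """One co-sedimentation titration at fixed actin concentration."""

    actin_total: float  # μM
    tpm_total: np.ndarray  # μM, ascending
    density_tpm: np.ndarray | None = None
    density_actin: np.ndarray | None = None
    theta: np.ndarray | None = None
    free: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.tpm_total = np.asarray(self.tpm_total, dtype=float)
        if self.tpm_total.size < 5:
            raise InputError("binding series needs at least 5 points")
        if not np.all(np.diff(self.tpm_total) > 0):
            raise InputError("tpm_total must be strictly increasing")
        for name in ("density_tpm", "density_actin", "theta", "free"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.shape != self.tpm_total.shape:
                    raise InputError(f"{name} length does not match tpm_total")
                setattr(self, name, v)


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters with standard errors from the fit covariance."""

    k50: float  # μM
    n_hill: float
    theta_max: float
    se_k50: float
    se_n_hill: float
    rss: float

    def to_dict(self) -> dict:
        return {
            "k50_uM": self.k50,
            "se_k50_uM": self.se_k50,
            "n_hill": self.n_hill,
            "se_n_hill": self.se_n_hill,
            "theta_max": self.theta_max,
            "rss": self.rss,
        }


def saturation_from_density(
    density_tpm: np.ndarray,
    density_actin: np.ndarray,
    calibration_ratio: float | None = None,
) -> np.ndarray:
    """Fractional saturation from pellet band densities.

    ``calibration_ratio`` is the Tpm/actin density ratio at full saturation.
    When not supplied it is estimated as the mean ratio of the two highest
    points (the apparent plateau), provided those points have levelled off
    (within 20% of each other); otherwise a calibration error is raised.
    θ is clamped to [0, 1].
    """
    d_tpm = np.asarray(density_tpm, dtype=float)
    d_act = np.asarray(density_actin, dtype=float)
    if np.any(d_act <= 0):
        raise DataError("actin band density must be positive everywhere")
    if np.any(d_tpm < 0):
        raise DataError("tropomyosin band density must be non-negative")
    ratio = d_tpm / d_act
    if calibration_ratio is None:
        top = np.sort(ratio)[-2:]
        if top[0] <= 0 or (top[1] - top[0]) / top[1] > 0.2:
            raise CalibrationError(
                "no saturation plateau detectable; supply calibration_ratio explicitly"
            )
        calibration_ratio = float(np.mean(top))
    if calibration_ratio <= 0:
        raise CalibrationError("calibration_ratio must be positive")
    return np.clip(ratio / calibration_ratio, 0.0, 1.0)


def free_tpm(
    tpm_total: np.ndarray,
    theta: np.ndarray,
    actin_total: float,
    stoichiometry: float = DEFAULT_STOICHIOMETRY,
) -> np.ndarray:
    """Free tropomyosin by bound subtraction: free = total − θ·(actin/s), floored at 0.

    ``stoichiometry`` is the number of actin monomers covered per bound Tpm
    dimer, so ``actin_total/stoichiometry`` is the binding-site capacity in
    Tpm units.
    """
    if stoichiometry < 1:
        raise InputError("stoichiometry must be ≥ 1 actin monomer per Tpm")
    total = np.asarray(tpm_total, dtype=float)
    th = np.asarray(theta, dtype=float)
    bound = th * (actin_total / stoichiometry)
    free = total - bound
    if np.any(free < -0.05 * np.maximum(total, 1e-12)):
        import warnings

        warnings.warn(
            "computed free Tpm is negative beyond noise tolerance; "
            "densitometry calibration is likely wrong",
            stacklevel=2,
        )
    return np.maximum(free, 0.0)


def hill_curve(free: np.ndarray, k50: float, n_hill: float, theta_max: float = 1.0) -> np.ndarray:
    """The Hill isotherm θ(free)."""
    free = np.asarray(free, dtype=float)
    out = np.zeros_like(free)
    pos = free > 0
    fn = free[pos] ** n_hill
    out[pos] = theta_max * fn / (k50**n_hill + fn)
    return out


def fit_hill(series: BindingSeries) -> HillFit:
    """Least-squares Hill fit of θ against free Tpm.

    Requires θ and free to be present on the series (run
    :func:`saturation_from_density` and :func:`free_tpm` first, or load them
    directly).  Bounds: K50 ∈ (0, 10·max(free)], n ∈ (0.2, 10],
    θ_max ∈ (0, 1.05].
    """
    if series.theta is None or series.free is None:
        raise InputError("series must carry theta and free before Hill fitting")
    theta = series.theta
    free = series.free
    span = theta.max() - theta.min()
    if span < 0.2 or theta.max() < 0.3:
        raise UnidentifiableError(
            "series does not sample the binding transition; Hill parameters unidentifiable"
        )

    max_free = float(np.max(free))
    params = lmfit.Parameters()
    # initial K50 at the free concentration closest to half the plateau
    half = 0.5 * float(np.max(theta))
    k0 = float(free[np.argmin(np.abs(theta - half))])
    params.add("k50", value=max(k0, 1e-3), min=1e-6, max=10.0 * max_free)
    params.add("n_hill", value=1.5, min=0.2, max=10.0)
    params.add("theta_max", value=min(float(np.max(theta)), 1.0), min=1e-3, max=1.05)

    def residual(p):
        return hill_curve(free, p["k50"].value, p["n_hill"].value, p["theta_max"].value) - theta

    out = lmfit.minimize(residual, params, method="leastsq")
    p = out.params

    def stderr(name: str) -> float:
        e = p[name].stderr
        return float(e) if e is not None and np.isfinite(e) else float("nan")

    return HillFit(
        k50=float(p["k50"].value),
        n_hill=float(p["n_hill"].value),
        theta_max=float(p["theta_max"].value),
        se_k50=stderr("k50"),
        se_n_hill=stderr("n_hill"),
        rss=float(np.sum(np.asarray(out.residual) ** 2)),
    )


def read_binding(path, actin_total: float = 10.0, meta: dict | None = None) -> BindingSeries:
    """Read a binding CSV.

    Expected columns: ``tpm_total_uM``, ``density_tpm_pellet``,
    ``density_actin_pellet``; optional ``free_uM`` and ``theta`` columns
    bypass the densitometry stages.
    """
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.strip().lower(): c for c in df.columns}
    if "tpm_total_um" not in cols:
        raise InputError("binding table must have a tpm_total_uM column")
    order = np.argsort(df[cols["tpm_total_um"]].to_numpy())
    df = df.iloc[order]

    def col(name):
        return df[cols[name]].to_numpy(dtype=float) if name in cols else None

    return BindingSeries(
        actin_total=actin_total,
        tpm_total=df[cols["tpm_total_um"]].to_numpy(dtype=float),
        density_tpm=col("density_tpm_pellet"),
        density_actin=col("density_actin_pellet"),
        theta=col("theta"),
        free=col("free_um"),
        meta=dict(meta or {}),
    )


def analyze_binding(
    series: BindingSeries,
    stoichiometry: float = DEFAULT_STOICHIOMETRY,
    calibration_ratio: float | None = None,
) -> tuple[BindingSeries, HillFit]:
    """Densitometry → θ → free → Hill fit, skipping stages already present."""
    if series.theta is None:
        if series.density_tpm is None or series.density_actin is None:
            raise InputError("series has neither theta nor band densities")
        series.theta = saturation_from_density(
            series.density_tpm, series.density_actin, calibration_ratio
        )
    if series.free is None:
        series.free = free_tpm(series.tpm_total, series.theta, series.actin_total, stoichiometry)
    return series, fit_hill(series)
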