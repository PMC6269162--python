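"""Synthetic-data generators with known ground truth.

Every analysis stage in the package can be exercised offline because this
module emits the same raw objects the instruments would: CD melt traces
(forward van't Hoff model plus additive Gaussian signal noise), pellet
densitometry series for actin co-sedimentation (mass-balance-consistent
free/bound partitioning plus multiplicative density noise), and coiled-coil
test sequences with a known heptad register.

All generators are pure functions of their spec: the same spec (seed
included) always produces identical output.  Replicate ``r`` of a melt uses
``seed + r`` so replicates are independent but individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import brentq

from . import thermo
from .binding import BindingSeries, hill_curve
from .coil import HEPTAD_LETTERS, RegisterAnchor, letter_from_anchor
from .errors import SimSpecError
from .meltfit import MeltCurve

__all__ = [
    "MeltSimSpec",
    "BindingSimSpec",
    "gen_melt",
    "gen_binding",
    "gen_sequence",
    "DEFAULT_TPM_TOTALS",
]

#: Default total-Tpm titration, μM: 10 points spanning 0.2–16 μM
#: (geometric spacing, matching the decade-plus range of a gel titration).
DEFAULT_TPM_TOTALS = tuple(np.geomspace(0.2, 16.0, 10))


@dataclass(frozen=True)
class MeltSimSpec:
    """Specification of a synthetic CD melt experiment."""

    model: thermo.UnfoldingModel
    grid: tuple[float, float, float] = (10.0, 50.0, 0.1)  # start, end, step °C
    noise_sd: float = 0.0  # raw-signal units
    seed: int = 0
    replicates: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        start, end, step = self.grid
        if step <= 0:
            raise SimSpecError("grid step must be positive")
        if start > 10.0 or end < 50.0:
            raise SimSpecError("grid must cover the 10-50 °C normalisation window")
        if self.noise_sd < 0:
            raise SimSpecError("noise_sd must be non-negative")
        if self.replicates < 1:
            raise SimSpecError("at least one replicate required")

    @property
    def temperatures(self) -> np.ndarray:
        start, end, step = self.grid
        n = int(round((end - start) / step)) + 1
        return start + step * np.arange(n)


def gen_melt(spec: MeltSimSpec) -> list[MeltCurve]:
    """Generate replicate melt traces from the forward model plus noise."""
    t = spec.temperatures
    clean = thermo.signal_from_fraction(spec.model, t)
    curves = []
    for r in range(spec.replicates):
        rng = np.random.default_rng(spec.seed + r)
        noise = rng.normal(0.0, spec.noise_sd, size=t.size) if spec.noise_sd > 0 else 0.0
        meta = dict(spec.meta)
        meta.update({"replicate": r, "seed": spec.seed + r, "noise_sd": spec.noise_sd})
        curves.append(MeltCurve(temperature=t.copy(), signal=clean + noise, meta=meta))
    return curves


@dataclass(frozen=True)
class BindingSimSpec:
    """Specification of a synthetic co-sedimentation titration."""

    k50: float  # μM
    n_hill: float = 1.5
    theta_max: float = 1.0
    actin_total: float = 10.0  # μM
    stoichiometry: float = 4.0  # actin monomers per Tpm dimer
    tpm_totals: tuple[float, ...] = DEFAULT_TPM_TOTALS
    density_noise_cv: float = 0.0
    calibration_ratio: float = 0.5  # Tpm/actin density ratio at full saturation
    density_actin: float = 1000.0  # arbitrary units, constant loading control
    seed: int = 0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k50 <= 0 or self.actin_total <= 0 or self.calibration_ratio <= 0:
            raise SimSpecError("concentrations and calibration must be positive")
        if any(c <= 0 for c in self.tpm_totals):
            raise SimSpecError("tpm_totals must be positive")
        if list(self.tpm_totals) != sorted(self.tpm_totals):
            raise SimSpecError("tpm_totals must be ascending")


def _solve_free(total: float, spec: BindingSimSpec) -> float:
    """Mass-balance fixed point: free + θ(free)·capacity = total.

    The left side is strictly increasing in free, so the root is unique;
    solved by bracketed bisection to 1e-12 μM.
    """
    capacity = spec.actin_total / spec.stoichiometry

    def balance(free: float) -> float:
        th = hill_curve(np.asarray([free]), spec.k50, spec.n_hill, spec.theta_max)[0]
        return free + th * capacity - total

    return brentq(balance, 0.0, total, xtol=1e-12)


def gen_binding(spec: BindingSimSpec) -> BindingSeries:
    """Generate a self-consistent binding series with noisy densitometry.

    Ground-truth ``free`` and ``theta`` honour the mass balance to better
    than 1e-9 μM and are stored on the returned series alongside the noisy
    band densities (the analysis pipeline normally overwrites them from the
    densities; tests can compare against the stored truth in
    ``meta['true_theta']`` / ``meta['true_free']``).
    """
    rng = np.random.default_rng(spec.seed)
    totals = np.asarray(spec.tpm_totals, dtype=float)
    free = np.array([_solve_free(tot, spec) for tot in totals])
    theta = hill_curve(free, spec.k50, spec.n_hill, spec.theta_max)
    d_act = np.full(totals.shape, spec.density_actin)
    noise = rng.normal(0.0, spec.density_noise_cv, size=totals.size) if spec.density_noise_cv > 0 else 0.0
    d_tpm = theta * spec.calibration_ratio * d_act * (1.0 + noise)
    meta = dict(spec.meta)
    meta.update(
        {
            "true_theta": theta.copy(),
            "true_free": free.copy(),
            "k50": spec.k50,
            "n_hill": spec.n_hill,
            "theta_max": spec.theta_max,
            "stoichiometry": spec.stoichiometry,
            "calibration_ratio": spec.calibration_ratio,
            "seed": spec.seed,
        }
    )
    return BindingSeries(
        actin_total=spec.actin_total,
        tpm_total=totals,
        density_tpm=np.maximum(d_tpm, 0.0),
        density_actin=d_act,
        meta=meta,
    )


#: Default residue per heptad letter used by :func:`gen_sequence`:
#: leucine at the a/d core; e and g positions alternate glutamate/lysine
#: along the sequence; everything else alanine.
def _fill_residue(letter: str, eg_counter: int) -> str:
    if letter in "ad":
        return "L"
    if letter in "eg":
        return "E" if eg_counter % 2 == 0 else "K"
    return "A"


def gen_sequence(
    length: int,
    register_anchor: RegisterAnchor,
    placements: dict[int, str] | None = None,
    record_id: str = "synthetic_coil",
) -> SeqRecord:
    """Build a deterministic coiled-coil test sequence with a known register.

    ``placements`` pins specific residues at 1-based positions (overriding
    the letter-based fill rules); conflicting placements raise
    :class:`SimSpecError`.  Returns a Biopython ``SeqRecord`` whose
    description records the anchor for round-tripping through FASTA.
    """
    items = list(placements.items()) if hasattr(placements, "items") else list(placements or [])
    seen: dict[int, str] = {}
    for pos, aa in items:
        if not (1 <= pos <= length):
            raise SimSpecError(f"placement position {pos} outside sequence of length {length}")
        if len(aa) != 1:
            raise SimSpecError(f"placement at {pos} must be a single residue, got {aa!r}")
        if pos in seen and seen[pos] != aa.upper():
            raise SimSpecError(f"conflicting placements at position {pos}")
        seen[pos] = aa.upper()

    residues = []
    eg_counter = 0
    for pos in range(1, length + 1):
        letter = letter_from_anchor(register_anchor, pos)
        if pos in seen:
            residues.append(seen[pos])
        else:
            residues.append(_fill_residue(letter, eg_counter))
        if letter in "eg":
            eg_counter += 1
    return SeqRecord(
        Seq("".join(residues)),
        id=record_id,
        description=f"anchor={register_anchor.residue_index}:{register_anchor.letter}",
    )
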