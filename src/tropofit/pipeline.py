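"""End-to-end orchestration: simulate → analyse → compare.

`run_replica` drives the whole parameter-recovery experiment: for every
configured protein/state it generates synthetic melts (and optionally a
binding series) from the configured ground-truth parameters, pushes them
through the analysis pipeline, and records recovered vs configured values
with pass/fail flags at the configured tolerances.  Reports serialise
deterministically (stable key order, fixed float formatting) so a rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import binding, meltfit, reference, simulate, thermo

__all__ = ["RunConfig", "ProteinSpec", "ReplicaReport", "run_replica", "compare_to_reference", "table1_config"]


@dataclass(frozen=True)
class ProteinSpec:
    """One protein/state entry of a replica run."""

    name: str
    transitions: tuple[tuple[float, float], ...]  # (tm °C, dh kJ/mol) per transition
    acetylated: bool = False
    low_amplitude: float = reference.BIPHASIC_LOW_AMPLITUDE  # used when biphasic
    k50: float | None = None  # μM; binding stage skipped when None
    n_hill: float = 1.5

    def model(self) -> thermo.UnfoldingModel:
        if len(self.transitions) == 1:
            return thermo.single_transition_model(*self.transitions[0])
        (tm1, dh1), (tm2, dh2) = self.transitions
        return thermo.two_transition_model(tm1, dh1, tm2, dh2, amplitude1=self.low_amplitude)

    @property
    def key(self) -> str:
        return f"{'Ac-' if self.acetylated else ''}{self.name}"


@dataclass
class RunConfig:
    """Declarative configuration of a replica run."""

    proteins: list[ProteinSpec]
    window: tuple[float, float] = meltfit.DEFAULT_WINDOW
    smoothing_window: float = meltfit.DEFAULT_SMOOTH
    baseline_mode: str = "minmax"
    components: str = "auto"
    selection_threshold: float = meltfit.DEFAULT_SELECTION_THRESHOLD
    actin_total: float = 10.0
    stoichiometry: float = binding.DEFAULT_STOICHIOMETRY
    melt_noise_sd: float = 0.0
    binding_noise_cv: float = 0.0
    replicates: int = 1
    seed: int = 0
    tm_tolerance: float = 0.3  # °C
    dh_rel_tolerance: float = 0.02
    amplitude_tolerance: float = 0.03
    k50_rel_tolerance: float = 0.02

    def __post_init__(self):
        names = [p.key for p in self.proteins]
        if len(names) != len(set(names)):
            raise ValueError("protein/state keys must be unique")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        proteins = [
            ProteinSpec(
                name=p["name"],
                transitions=tuple(tuple(t) for t in p["transitions"]),
                acetylated=bool(p.get("acetylated", False)),
                low_amplitude=float(p.get("low_amplitude", reference.BIPHASIC_LOW_AMPLITUDE)),
                k50=p.get("k50"),
                n_hill=float(p.get("n_hill", 1.5)),
            )
            for p in raw.pop("proteins", [])
        ]
        if "window" in raw:
            raw["window"] = tuple(raw["window"])
        return cls(proteins=proteins, **raw)


def table1_config(**overrides) -> RunConfig:
    """Config covering every reference variant/state (0.5 M salt), noise-free."""
    proteins = [
        ProteinSpec(
            name=name,
            transitions=tuple(reference.THERMAL_PARAMS[(name, ac)]),
            acetylated=ac,
            k50=reference.K50_PARAMS.get((name, ac)),
        )
        for name, ac in reference.all_variants()
    ]
    return RunConfig(proteins=proteins, **overrides)


@dataclass
class ReplicaReport:
    """Recovered vs configured parameters for every protein in a run."""

    entries: list[dict]
    config_summary: dict

    @property
    def all_passed(self) -> bool:
        return all(e.get("passed", False) for e in self.entries if "error" not in e)

    def to_dict(self) -> dict:
        return {"config": self.config_summary, "proteins": self.entries}

    def to_json(self) -> str:
        return json.dumps(_round_floats(self.to_dict()), indent=2, sort_keys=True)


def _round_floats(obj, ndigits: int = 4):
    if isinstance(obj, float):
        return round(obj, ndigits)
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def _analyze_protein(spec: ProteinSpec, config: RunConfig, seed: int) -> dict:
    model = spec.model()
    melt_spec = simulate.MeltSimSpec(
        model=model,
        noise_sd=config.melt_noise_sd,
        seed=seed,
        replicates=config.replicates,
        meta={"protein": spec.name, "acetylated": spec.acetylated},
    )
    curves = simulate.gen_melt(melt_spec)
    curve = meltfit.average_melts(curves) if len(curves) > 1 else curves[0]
    result = meltfit.analyze_melt(
        curve,
        window=config.window,
        baseline_mode=config.baseline_mode,
        smoothing_window=config.smoothing_window,
        components=config.components if config.components == "auto" else len(spec.transitions),
        selection_threshold=config.selection_threshold,
    )

    true_tms = [t[0] for t in spec.transitions]
    true_dhs = [t[1] for t in spec.transitions]
    rec_tms = [t.tm for t in result.transitions]
    rec_dhs = [t.dh for t in result.transitions]
    rec_amps = [t.amplitude for t in result.transitions]

    checks = {"n_components": result.n_components == len(spec.transitions)}
    if checks["n_components"]:
        checks["tm"] = all(
            abs(a - b) <= config.tm_tolerance for a, b in zip(rec_tms, true_tms)
        )
        checks["dh"] = all(
            abs(abs(a) - abs(b)) / abs(b) <= config.dh_rel_tolerance
            for a, b in zip(rec_dhs, true_dhs)
        )
        if len(spec.transitions) == 2:
            checks["amplitude"] = abs(rec_amps[0] - spec.low_amplitude) <= config.amplitude_tolerance

    entry = {
        "protein": spec.name,
        "acetylated": spec.acetylated,
        "true_tm_C": true_tms,
        "recovered_tm_C": rec_tms,
        "true_dh_kj_mol": true_dhs,
        "recovered_dh_kj_mol": rec_dhs,
        "recovered_amplitudes": rec_amps,
        "n_components": result.n_components,
        "checks": checks,
    }

    if spec.k50 is not None:
        bind_spec = simulate.BindingSimSpec(
            k50=spec.k50,
            n_hill=spec.n_hill,
            actin_total=config.actin_total,
            stoichiometry=config.stoichiometry,
            density_noise_cv=config.binding_noise_cv,
            seed=seed,
        )
        series = simulate.gen_binding(bind_spec)
        series.theta = binding.saturation_from_density(
            series.density_tpm, series.density_actin, bind_spec.calibration_ratio
        )
        series.free = binding.free_tpm(
            series.tpm_total, series.theta, series.actin_total, config.stoichiometry
        )
        hill = binding.fit_hill(series)
        entry["true_k50_uM"] = spec.k50
        entry["recovered_k50_uM"] = hill.k50
        entry["recovered_n_hill"] = hill.n_hill
        checks["k50"] = abs(hill.k50 - spec.k50) / spec.k50 <= config.k50_rel_tolerance

    entry["passed"] = all(checks.values())
    return entry


def run_replica(config: RunConfig, out_dir=None) -> ReplicaReport:
    """Run the full simulate→analyse comparison for every configured protein.

    Failures in one protein are recorded and do not stop the run.  When
    ``out_dir`` is given, writes ``replica_report.json`` and a tidy
    ``replica_report.csv`` there.
    """
    entries = []
    for i, spec in enumerate(config.proteins):
        try:
            entries.append(_analyze_protein(spec, config, seed=config.seed + 1000 * i))
        except Exception as exc:  # keep going; record the failure
            entries.append(
                {
                    "protein": spec.name,
                    "acetylated": spec.acetylated,
                    "error": f"{type(exc).__name__}: {exc}",
                    "passed": False,
                }
            )
    summary = {
        "baseline_mode": config.baseline_mode,
        "smoothing_window_C": config.smoothing_window,
        "window_C": list(config.window),
        "components": config.components,
        "selection_threshold": config.selection_threshold,
        "stoichiometry": config.stoichiometry,
        "actin_total_uM": config.actin_total,
        "melt_noise_sd": config.melt_noise_sd,
        "binding_noise_cv": config.binding_noise_cv,
        "replicates": config.replicates,
        "seed": config.seed,
        "tolerances": {
            "tm_C": config.tm_tolerance,
            "dh_rel": config.dh_rel_tolerance,
            "amplitude": config.amplitude_tolerance,
            "k50_rel": config.k50_rel_tolerance,
        },
    }
    report = ReplicaReport(entries=entries, config_summary=summary)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "replica_report.json").write_text(report.to_json() + "\n")
        _write_tidy_csv(report, out_dir / "replica_report.csv")
    return report


def _write_tidy_csv(report: ReplicaReport, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(
            ["protein", "acetylated", "transition", "true_tm_C", "recovered_tm_C",
             "true_dh_kj_mol", "recovered_dh_kj_mol", "recovered_amplitude", "passed"]
        )
        for e in report.entries:
            if "error" in e:
                w.writerow([e["protein"], e["acetylated"], "", "", "", "", "", "", "error"])
                continue
            for k in range(len(e["true_tm_C"])):
                rec_tm = e["recovered_tm_C"][k] if k < len(e["recovered_tm_C"]) else ""
                rec_dh = e["recovered_dh_kj_mol"][k] if k < len(e["recovered_dh_kj_mol"]) else ""
                rec_a = e["recovered_amplitudes"][k] if k < len(e["recovered_amplitudes"]) else ""
                w.writerow(
                    [e["protein"], e["acetylated"], k + 1,
                     f"{e['true_tm_C'][k]:.1f}", _fmt(rec_tm, 1),
                     f"{e['true_dh_kj_mol'][k]:.1f}", _fmt(rec_dh, 1),
                     _fmt(rec_a, 3), e["passed"]]
                )


def _fmt(v, nd: int) -> str:
    return f"{v:.{nd}f}" if isinstance(v, float) else str(v)


def compare_to_reference(report: ReplicaReport, reference_table: dict, tm_tolerance: float = 0.3) -> dict:
    """Compare recovered Tm values against an external reference table.

    ``reference_table`` maps ``(protein, acetylated)`` to a list of Tm °C.
    Missing keys are reported as absent rather than raising.
    """
    out = {}
    for e in report.entries:
        key = (e["protein"], e["acetylated"])
        label = f"{'Ac-' if e['acetylated'] else ''}{e['protein']}"
        if "error" in e:
            out[label] = {"status": "error", "detail": e["error"]}
            continue
        if key not in reference_table:
            out[label] = {"status": "absent"}
            continue
        ref_tms = list(reference_table[key])
        rec = e["recovered_tm_C"]
        if len(rec) != len(ref_tms):
            out[label] = {"status": "component-mismatch", "recovered": rec, "reference": ref_tms}
            continue
        deltas = [abs(a - b) for a, b in zip(sorted(rec), sorted(ref_tms))]
        out[label] = {
            "status": "pass" if max(deltas) <= tm_tolerance else "fail",
            "abs_delta_C": deltas,
        }
    return out
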