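"""Published thermal and binding parameters for Cdc8 tropomyosin variants.

These are the reported in-vitro values for fission-yeast tropomyosin
(wild type and the A18T, E31K, E129K and A18T/E31K substitution variants)
in unacetylated and N-terminally acetylated forms, measured in 0.5 M salt:
melting midpoints Tm (°C) and van't Hoff enthalpies ΔH (kJ·mol⁻¹, negative
per the signal-loss convention), plus actin-binding half-saturation
constants K50% (μM) at 10 μM actin.  The two acetylated mutants unfold
biphasically; their low-temperature transition carries ~60% of the CD
amplitude.

They serve as *generator inputs* for parameter-recovery experiments: the
simulator builds synthetic data from them and the analysis pipeline must
get them back.
"""

from __future__ import annotations

from . import thermo

#: Amplitude fraction of the lower transition in biphasic acetylated melts.
BIPHASIC_LOW_AMPLITUDE = 0.6

#: (name, acetylated) → list of (Tm °C, ΔH kJ·mol⁻¹) per transition, 0.5 M salt.
THERMAL_PARAMS: dict[tuple[str, bool], list[tuple[float, float]]] = {
    ("WT", False): [(34.1, -455.8)],
    ("WT", True): [(35.4, -555.7)],
    ("A18T", False): [(29.3, -315.4)],
    ("A18T", True): [(30.5, -342.3)],
    ("E129K", False): [(29.4, -331.1)],
    ("E129K", True): [(29.3, -481.7), (38.1, -403.6)],
    ("E31K", False): [(32.2, -447.2)],
    ("E31K", True): [(35.9, -571.3)],
    ("A18T/E31K", False): [(27.9, -276.0)],
    ("A18T/E31K", True): [(29.2, -256.8), (43.2, -466.2)],
}

#: (name, acetylated) → K50%, μM, at 10 μM actin.
K50_PARAMS: dict[tuple[str, bool], float] = {
    ("WT", False): 2.54,
    ("WT", True): 0.62,
    ("E129K", False): 4.69,
    ("E129K", True): 1.65,
}


def unfolding_model(name: str, acetylated: bool) -> thermo.UnfoldingModel:
    """Forward model for one variant/state from the reference table."""
    entries = THERMAL_PARAMS[(name, acetylated)]
    if len(entries) == 1:
        (tm, dh), = entries
        return thermo.single_transition_model(tm, dh)
    (tm1, dh1), (tm2, dh2) = entries
    return thermo.two_transition_model(tm1, dh1, tm2, dh2, amplitude1=BIPHASIC_LOW_AMPLITUDE)


def all_variants() -> list[tuple[str, bool]]:
    """Every (name, acetylated) pair in the thermal table, stable order."""
    return list(THERMAL_PARAMS)
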