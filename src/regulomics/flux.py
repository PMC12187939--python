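"""Pentose-phosphate-pathway flux from [1,2-¹³C]-glucose tracing.

Glucose routed through the oxidative PPP loses C1 as CO₂ and returns to
glycolysis producing M1-labeled lactate, while glucose passing straight
through glycolysis yields M2-labeled lactate. The PPP flux relative to
glycolysis is therefore

    flux = glucose_consumption_rate × Lac_M1 / (Lac_M1 + Lac_M2),

optionally normalized to a control group's flux. M1/M2 may be fractional
abundances or raw intensities — the ratio is scale-invariant — but must be
natural-abundance corrected upstream.
"""

from __future__ import annotations

from typing import Optional

import pandas as pd


def relative_ppp_flux(
    glucose_consumption_rate: float,
    lac_m1: float,
    lac_m2: float,
    control_flux: Optional[float] = None,
) -> float:
    """PPP flux relative to glycolysis; ≥0 and bounded by the consumption rate
    (before control normalization)."""
    if glucose_consumption_rate <= 0:
        raise ValueError("glucose consumption rate must be positive")
    if lac_m1 < 0 or lac_m2 < 0:
        raise ValueError("isotopologue values must be non-negative")
    total = lac_m1 + lac_m2
    if total == 0:
        raise ValueError("Lac_M1 + Lac_M2 = 0: flux undefined")
    flux = glucose_consumption_rate * lac_m1 / total
    if control_flux is not None:
        if control_flux <= 0:
            raise ValueError("control flux must be positive")
        flux /= control_flux
    return flux


def glucose_consumption_rate(
    conc_start: float,
    conc_end: float,
    volume: float,
    hours: float,
    cell_count: float,
) -> float:
    """Helper: (conc_start − conc_end)·volume / (hours·cell_count).

    Units carry through from the inputs (e.g., mM·mL → µmol per hour per
    cell when volume is in mL).
    """
    if hours <= 0 or cell_count <= 0:
        raise ValueError("hours and cell_count must be positive")
    return (conc_start - conc_end) * volume / (hours * cell_count)


def flux_table(samples: pd.DataFrame) -> pd.DataFrame:
    """Vectorized flux over a (sample, rate, lac_m1, lac_m2[, control_group])
    table; adds ``flux`` and, per control group, ``relative_flux`` columns.

    Rows sharing a ``control_group`` label are normalized by the mean flux
    of rows whose ``sample`` equals that label.
    """
    out = samples.copy()
    out["flux"] = [
        relative_ppp_flux(r.rate, r.lac_m1, r.lac_m2)
        for r in out.itertuples()
    ]
    if "control_group" in out.columns:
        control_means = out.groupby("sample")["flux"].mean()
        out["relative_flux"] = [
            r.flux / control_means[r.control_group]
            if pd.notna(r.control_group) and r.control_group in control_means
            else float("nan")
            for r in out.itertuples()
        ]
    return out
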