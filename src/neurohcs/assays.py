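"""MTT and LDH plate-reader normalization to percent of vehicle control.

MTT (absorbance at 570 nm) reads mitochondrial metabolism; LDH (492 nm)
reads membrane damage via enzyme leakage into the medium.  Both are
normalised per culture to the vehicle-group mean, so the output is scale-
invariant to any per-culture gain.  Triton-X 100 control wells are carried
through as labelled rows but excluded from the group statistics.
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["ASSAY_WAVELENGTH_NM", "AssayResult", "normalize_assay"]

ASSAY_WAVELENGTH_NM = {"mtt": 570, "ldh": 492}
TRITON_LABEL = "triton_x"


@dataclass
class AssayResult:
    per_culture: pd.DataFrame  # culture, group, mean_absorbance, n_wells, pct_of_vehicle
    summary: pd.DataFrame      # group, mean_pct, sd_pct, n
    controls: pd.DataFrame     # Triton-X control well means per culture


def normalize_assay(
    table: pd.DataFrame,
    assay: str,
    vehicle_label: str = "vehicle",
    blank: float | None = None,
    control_labels: tuple[str, ...] = (TRITON_LABEL,),
) -> AssayResult:
    """Per-culture percent-of-vehicle for a plate-reader absorbance table.

    ``blank`` optionally subtracts a constant blank absorbance before
    normalization (default: none, matching a protocol without blank wells).
    % = 100 * mean(group wells) / mean(vehicle wells), per culture.
    """
    if assay not in ASSAY_WAVELENGTH_NM:
        raise ValueError(f"assay must be one of {tuple(ASSAY_WAVELENGTH_NM)}")
    required = {"culture", "group", "absorbance"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"absorbance table lacks columns {sorted(missing)}")
    df = table.copy()
    if "wavelength" in df.columns:
        expected = ASSAY_WAVELENGTH_NM[assay]
        if not (df["wavelength"] == expected).all():
            raise ValueError(
                f"{assay} assay expects wavelength {expected} nm only"
            )
    if (df["absorbance"] < 0).any():
        raise ValueError("absorbance must be >= 0")
    if blank is not None:
        df["absorbance"] = df["absorbance"] - blank

    is_control = df["group"].isin(control_labels)
    controls = (df[is_control]
                .groupby(["culture", "group"], as_index=False)
                .agg(mean_absorbance=("absorbance", "mean"),
                     n_wells=("absorbance", "size")))
    df = df[~is_control]

    per_culture = (df.groupby(["culture", "group"], as_index=False)
                   .agg(mean_absorbance=("absorbance", "mean"),
                        n_wells=("absorbance", "size")))
    veh = (per_culture[per_culture["group"] == vehicle_label]
           .set_index("culture")["mean_absorbance"])
    if veh.empty:
        raise ValueError(f"vehicle group {vehicle_label!r} missing")
    if (veh <= 0).any():
        raise ValueError("vehicle mean absorbance <= 0 after blanking")
    per_culture["pct_of_vehicle"] = (
        100.0 * per_culture["mean_absorbance"]
        / per_culture["culture"].map(veh).to_numpy()
    )
    summary = (per_culture.groupby("group", as_index=False)
               .agg(mean_pct=("pct_of_vehicle", "mean"),
                    sd_pct=("pct_of_vehicle", lambda v: v.std(ddof=1)),
                    n=("pct_of_vehicle", "size")))
    return AssayResult(per_culture=per_culture, summary=summary, controls=controls)
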