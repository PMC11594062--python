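"""Efficiency-corrected relative quantification for qPCR Cq tables.

The quantification model is the standard efficiency-corrected one:

    RQ  = E ** (Cq_calibrator - Cq_sample)
    NRQ = RQ_target / geometric_mean(RQ_reference genes)

with the per-culture vehicle sample as calibrator, so percent-of-control
values are culture-paired (the statistical plan treats culture as a factor).
Replicate Cq values are arithmetic-averaged before quantification.
Amplification efficiency E (fold per cycle) can be estimated from raw
fluorescence curves with a window-of-linearity fit: the window of
consecutive cycles whose log-fluorescence is most linear gives
E = 10 ** slope.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import VEHICLE_LABEL

__all__ = [
    "WolFit",
    "estimate_efficiency_wol",
    "estimate_gene_efficiency",
    "mean_replicate_cq",
    "relative_quantity",
    "relative_quantities",
    "normalize_expression",
    "percent_of_control",
    "analyze_cq_table",
]

DEFAULT_REFERENCE_GENES = ("Actb", "Rplp0", "Rpl19")


@dataclass
class WolFit:
    """Window-of-linearity efficiency estimate for one reaction."""

    efficiency: float
    window: tuple[int, int]  # [start, stop) cycle indices, 0-based
    slope: float             # log10 fluorescence per cycle
    r_squared: float
    clamped: bool = False


def estimate_efficiency_wol(
    fluorescence: np.ndarray,
    window_size: int = 5,
    baseline_cycles: int = 5,
    min_efficiency: float = 1.1,
    plateau_fraction: float = 0.08,
    noise_floor_sd: float = 5.0,
    clamp: tuple[float, float] = (1.0, 2.2),
) -> WolFit:
    """Estimate amplification efficiency from one raw fluorescence curve.

    The mean of the first ``baseline_cycles`` readings is subtracted, then
    every window of ``window_size`` consecutive cycles with all-positive
    baseline-corrected values is fit by linear regression of
    log10(fluorescence) on cycle.  The window maximising R^2 wins;
    E = 10 ** slope.  Two validity filters keep the window inside the
    exponential phase: windows whose implied efficiency falls below
    ``min_efficiency`` (the flat plateau and baseline) are skipped, and so
    are windows reaching above ``plateau_fraction`` of the curve's maximum
    corrected fluorescence, where saturation compresses the slope, or
    dipping below ``noise_floor_sd`` baseline standard deviations, where
    chance linearity in the noise dominates.
    Estimates outside ``clamp`` are clamped and flagged.
    """
    f = np.asarray(fluorescence, dtype=np.float64)
    if f.ndim != 1 or f.size < 10:
        raise ValueError("need a 1-D curve with >= 10 cycles")
    if np.any(f < 0):
        raise ValueError("fluorescence readings must be non-negative")
    if window_size < 3:
        raise ValueError("window_size must be >= 3")
    baseline = f[:baseline_cycles].mean() if baseline_cycles > 0 else 0.0
    corrected = f - baseline
    cycles = np.arange(f.size, dtype=np.float64)
    ceiling = plateau_fraction * corrected.max()
    floor = (noise_floor_sd * float(np.std(f[:baseline_cycles]))
             if baseline_cycles > 1 else 0.0)
    best: WolFit | None = None
    for start in range(f.size - window_size + 1):
        seg = corrected[start:start + window_size]
        if np.any(seg <= floor) or seg.max() > ceiling:
            continue
        x = cycles[start:start + window_size]
        y = np.log10(seg)
        res = sps.linregress(x, y)
        eff = 10.0 ** res.slope
        if eff <= min_efficiency:
            continue
        r2 = res.rvalue**2
        if best is None or r2 > best.r_squared:
            best = WolFit(eff, (start, start + window_size), res.slope, r2)
    if best is None:
        raise ValueError(
            "no window of all-positive baseline-corrected values with an "
            "exponential rise; cannot estimate efficiency"
        )
    lo, hi = clamp
    if not (lo < best.efficiency <= hi):
        clamped = float(np.clip(best.efficiency, np.nextafter(lo, hi), hi))
        warnings.warn(
            f"window-of-linearity efficiency {best.efficiency:.3f} outside "
            f"({lo}, {hi}]; clamped to {clamped:.3f}",
            stacklevel=2,
        )
        best = WolFit(clamped, best.window, best.slope, best.r_squared, clamped=True)
    return best


def estimate_gene_efficiency(curves: Sequence[np.ndarray], **wol_kwargs) -> float:
    """Per-gene amplification efficiency: mean of window-of-linearity
    estimates across a primer set's reactions.

    Averaging across reactions is how the estimate is used for
    quantification; it suppresses the per-curve noise of the window fit.
    Reactions without a usable exponential window are skipped; at least one
    must succeed.
    """
    estimates = []
    for curve in curves:
        try:
            estimates.append(estimate_efficiency_wol(curve, **wol_kwargs).efficiency)
        except ValueError:
            continue
    if not estimates:
        raise ValueError("no reaction yielded a usable efficiency estimate")
    return float(np.mean(estimates))


def mean_replicate_cq(cq_table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of replicate Cq values per (culture, group, gene)."""
    required = {"culture", "group", "gene", "cq"}
    missing = required - set(cq_table.columns)
    if missing:
        raise ValueError(f"Cq table lacks columns {sorted(missing)}")
    return (cq_table.groupby(["culture", "group", "gene"], as_index=False)
            .agg(cq=("cq", "mean"), n_replicates=("cq", "size")))


def relative_quantity(sample_cq, efficiency: float, calibrator_cq) -> float:
    """RQ = E ** (Cq_calibrator - Cq_sample); E must exceed 1."""
    if efficiency <= 1.0:
        raise ValueError("efficiency must be > 1")
    return efficiency ** (np.asarray(calibrator_cq) - np.asarray(sample_cq))


def relative_quantities(
    cq_table: pd.DataFrame,
    efficiencies: Mapping[str, float] | None = None,
    control_label: str = VEHICLE_LABEL,
) -> pd.DataFrame:
    """Per-(culture, group, gene) RQ against the per-culture control sample."""
    mean_cq = mean_replicate_cq(cq_table)
    eff = {g: 2.0 for g in mean_cq["gene"].unique()}
    if efficiencies:
        eff.update(efficiencies)
    cal = (mean_cq[mean_cq["group"] == control_label]
           .set_index(["culture", "gene"])["cq"])
    if cal.empty:
        raise ValueError(f"control group {control_label!r} missing from the table")
    out = mean_cq.copy()
    key = pd.MultiIndex.from_frame(out[["culture", "gene"]])
    if not key.isin(cal.index).all():
        missing = out.loc[~key.isin(cal.index), ["culture", "gene"]]
        raise ValueError(
            f"control sample missing for {missing.drop_duplicates().to_dict('records')}"
        )
    cal_cq = cal.loc[key].to_numpy()
    e = out["gene"].map(eff).to_numpy(dtype=np.float64)
    out["rq"] = e ** (cal_cq - out["cq"].to_numpy())
    return out


def normalize_expression(
    rq_table: pd.DataFrame,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
) -> pd.DataFrame:
    """Divide each RQ by the geometric mean of the reference-gene RQs of the
    same sample (multi-reference normalization)."""
    refs = [g for g in reference_genes if g in set(rq_table["gene"])]
    if not refs:
        raise ValueError("no reference gene present in the table")
    ref_rows = rq_table[rq_table["gene"].isin(refs)]
    if (ref_rows["rq"] <= 0).any():
        raise ValueError("reference RQ <= 0: cannot form a geometric mean")
    nf = (ref_rows.groupby(["culture", "group"])["rq"]
          .apply(lambda v: float(sps.gmean(v)))
          .rename("norm_factor"))
    out = rq_table.merge(nf, on=["culture", "group"], how="left")
    out["nrq"] = out["rq"] / out["norm_factor"]
    return out


def percent_of_control(
    nrq_table: pd.DataFrame,
    control_label: str = VEHICLE_LABEL,
) -> pd.DataFrame:
    """Across-culture mean +/- SD of 100 * NRQ_group / NRQ_control per gene.

    The control row is 100 +/- 0 by construction.  With a single culture the
    SD is reported as missing (sample SD undefined at n = 1).
    """
    ctrl = (nrq_table[nrq_table["group"] == control_label]
            .set_index(["culture", "gene"])["nrq"])
    if ctrl.empty:
        raise ValueError(f"control group {control_label!r} missing")
    if (ctrl == 0).any():
        raise ValueError("control NRQ of 0: percent of control undefined")
    df = nrq_table.copy()
    key = pd.MultiIndex.from_frame(df[["culture", "gene"]])
    df["pct_of_control"] = 100.0 * df["nrq"].to_numpy() / ctrl.loc[key].to_numpy()
    summary = (df.groupby(["gene", "group"], as_index=False)
               .agg(mean_pct=("pct_of_control", "mean"),
                    sd_pct=("pct_of_control", lambda v: v.std(ddof=1)),
                    n=("pct_of_control", "size")))
    return summary


@dataclass
class QpcrResult:
    per_culture: pd.DataFrame  # culture/group/gene with rq, nrq, pct_of_control
    summary: pd.DataFrame      # gene/group with mean_pct, sd_pct, n


def analyze_cq_table(
    cq_table: pd.DataFrame,
    efficiencies: Mapping[str, float] | None = None,
    reference_genes: Sequence[str] = DEFAULT_REFERENCE_GENES,
    control_label: str = VEHICLE_LABEL,
) -> QpcrResult:
    """Full relative-quantification pipeline: replicate-mean Cq -> RQ ->
    reference-normalised NRQ -> percent-of-control table."""
    rq = relative_quantities(cq_table, efficiencies, control_label)
    nrq = normalize_expression(rq, reference_genes)
    ctrl = (nrq[nrq["group"] == control_label]
            .set_index(["culture", "gene"])["nrq"])
    key = pd.MultiIndex.from_frame(nrq[["culture", "gene"]])
    nrq = nrq.copy()
    nrq["pct_of_control"] = 100.0 * nrq["nrq"].to_numpy() / ctrl.loc[key].to_numpy()
    summary = percent_of_control(nrq, control_label)
    return QpcrResult(per_culture=nrq, summary=summary)
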