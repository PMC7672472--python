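"""Assay statistics: AUC, resistance value, cross-reactivity, signal gain.

The digestion readout integrates the whole fluorescence time course rather
than relying on a single time point: the area under the curve (AUC) is
proportional to how long stainable DNA survives digestion. Ligand-conferred
protection is quantified by the resistance value

    R = (AUC1 - AUC0) / AUC0

where AUC1 and AUC0 are the areas with and without ligand, and ligand
specificity by the cross-reactivity relative to the reference target

    CR% = 100 * (AUC_L - AUC0) / (AUC_T - AUC0),

which reduces to 100 * R_L / R_T whenever the two share the control AUC.
The strand-displacement assay is summarised by the signal gain
S = (F - F0)/F0 and its cross-reactivity 100 * S_L / S_T.

Replicate aggregation uses a common control denominator: AUC0 is the mean
over control-replicate AUCs, each ligand replicate i yields
R_i = (AUC1_i - AUC0)/AUC0, and the condition is reported as mean +/- SD
over the R_i. When ligand and control wells were read on different grids the
control is linearly interpolated onto the ligand grid and both integrals run
over the overlap of the two spans only (no extrapolation).
"""

from __future__ import annotations

from collections import defaultdict
from typing import Optional, Sequence

import numpy as np
from pydantic import BaseModel, ConfigDict, Field

from .errors import (
    DegenerateControlError,
    InsufficientDataError,
    InvalidReferenceError,
)
from .models import PlateExperiment, ResistanceResult, SDReadout, TimeCourse


class AUCValue(BaseModel):
    """Trapezoid area under one fluorescence time course (a.u. * min)."""

    model_config = ConfigDict(frozen=True)

    value: float
    n_points: int = Field(ge=2)
    t_span: float = Field(gt=0)


def auc(tc: TimeCourse, *, include_t0: bool = True) -> AUCValue:
    """Composite-trapezoid AUC over the recorded grid (irregular grids are
    fine). ``include_t0=False`` drops the t=0 read before integrating, for
    sensitivity analysis of whether the initial read belongs in the area."""
    times = np.asarray(tc.times, dtype=float)
    values = np.asarray(tc.fluorescence, dtype=float)
    if not include_t0:
        times, values = times[1:], values[1:]
    if len(times) < 2:
        raise InsufficientDataError(
            f"AUC needs at least 2 points, got {len(times)} for well {tc.key}"
        )
    area = float(np.trapezoid(values, times))
    return AUCValue(
        value=area, n_points=len(times), t_span=float(times[-1] - times[0])
    )


def resistance_value(auc_ligand: AUCValue, auc_control: AUCValue) -> float:
    """R = (AUC1 - AUC0)/AUC0. May be negative; never clipped."""
    if auc_control.value <= 0:
        raise DegenerateControlError(
            f"control AUC must be positive, got {auc_control.value}"
        )
    return (auc_ligand.value - auc_control.value) / auc_control.value


def cross_reactivity(auc_l: AUCValue, auc_t: AUCValue, auc_0: AUCValue) -> float:
    """CR% = 100 * (AUC_L - AUC0)/(AUC_T - AUC0); requires the reference
    target to protect (AUC_T > AUC0)."""
    if auc_t.value <= auc_0.value:
        raise InvalidReferenceError(
            "reference target does not protect the aptamer "
            f"(AUC_T={auc_t.value} <= AUC_0={auc_0.value})"
        )
    # ratio first so CR(reference) is exactly 100 in floating point
    return 100.0 * ((auc_l.value - auc_0.value) / (auc_t.value - auc_0.value))


def signal_gain(f: float, f0: float) -> float:
    """Strand-displacement signal gain S = (F - F0)/F0; negative values are
    allowed (dye-attenuation artifacts)."""
    if f0 <= 0:
        raise DegenerateControlError(f"F0 must be positive, got {f0}")
    return (f - f0) / f0


def sd_cross_reactivity(s_l: float, s_t: float) -> SDReadout:
    """Strand-displacement cross-reactivity 100 * S_L / S_T, reported raw;
    a negative value is flagged artifact-suspect rather than clipped."""
    if s_t <= 0:
        raise InvalidReferenceError(
            f"reference signal gain must be positive, got {s_t}"
        )
    cr = 100.0 * s_l / s_t
    flag = "artifact-suspect" if cr < 0 else ""
    return SDReadout(ligand_id="", signal_gain=s_l, cr_percent=cr, quality_flag=flag)


# ---------------------------------------------------------------------------
# plate-level aggregation


def _overlap_auc(times: np.ndarray, values: np.ndarray, lo: float, hi: float) -> float:
    """Trapezoid AUC of a piecewise-linear curve restricted to [lo, hi]."""
    grid = times[(times > lo) & (times < hi)]
    grid = np.concatenate(([lo], grid, [hi]))
    vals = np.interp(grid, times, values)
    return float(np.trapezoid(vals, grid))


def _condition_aucs(
    ligand_wells: Sequence[TimeCourse],
    control_wells: Sequence[TimeCourse],
    include_t0: bool,
) -> tuple[list[float], float]:
    """Per-replicate ligand AUCs and the mean control AUC, on the overlap of
    the ligand and control grids."""
    start = 0 if include_t0 else 1
    lig_t = [np.asarray(tc.times[start:], dtype=float) for tc in ligand_wells]
    ctl_t = [np.asarray(tc.times[start:], dtype=float) for tc in control_wells]
    for arr, tc in zip(lig_t + ctl_t, list(ligand_wells) + list(control_wells)):
        if len(arr) < 2:
            raise InsufficientDataError(f"well {tc.key} has fewer than 2 usable points")
    lo = max(arr[0] for arr in lig_t + ctl_t)
    hi = min(arr[-1] for arr in lig_t + ctl_t)
    if hi <= lo:
        raise InsufficientDataError("ligand and control grids do not overlap")
    lig_aucs = [
        _overlap_auc(t, np.asarray(tc.fluorescence[start:], dtype=float), lo, hi)
        for t, tc in zip(lig_t, ligand_wells)
    ]
    ctl_aucs = [
        _overlap_auc(t, np.asarray(tc.fluorescence[start:], dtype=float), lo, hi)
        for t, tc in zip(ctl_t, control_wells)
    ]
    return lig_aucs, float(np.mean(ctl_aucs))


def replicate_resistances(
    experiment: PlateExperiment,
    aptamer_id: str,
    ligand_id: str,
    *,
    include_t0: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-replicate resistance values of one aptamer-ligand concentration
    series, for dose-response fitting.

    Returns paired arrays (concentrations, R values), one entry per ligand
    replicate, all sharing the aptamer's mean control AUC as denominator.
    The concentration-0 control contributes R = 0 entries (one per control
    replicate) so the fit is anchored at the origin.
    """
    controls = experiment.controls(aptamer_id)
    if not controls:
        raise DegenerateControlError(f"no control wells for {aptamer_id}")
    by_conc: dict[float, list[TimeCourse]] = defaultdict(list)
    for tc in experiment.timecourses:
        if tc.aptamer_id == aptamer_id and tc.ligand_id == ligand_id and not tc.is_control:
            by_conc[tc.concentration].append(tc)
    if not by_conc:
        raise InsufficientDataError(
            f"no ligand wells for ({aptamer_id}, {ligand_id})"
        )
    concs: list[float] = []
    r_vals: list[float] = []
    for conc in sorted(by_conc):
        lig_aucs, auc0 = _condition_aucs(by_conc[conc], controls, include_t0)
        if auc0 <= 0:
            raise DegenerateControlError(
                f"control AUC for {aptamer_id} is not positive ({auc0})"
            )
        for a in lig_aucs:
            concs.append(conc)
            r_vals.append((a - auc0) / auc0)
    # control replicates against the shared mean control AUC
    ctl_aucs, auc0 = _condition_aucs(controls, controls, include_t0)
    for a in ctl_aucs:
        concs.append(0.0)
        r_vals.append((a - auc0) / auc0)
    order = np.argsort(concs, kind="stable")
    return np.asarray(concs)[order], np.asarray(r_vals)[order]


def resistance_table(
    experiment: PlateExperiment, *, include_t0: bool = True
) -> list[ResistanceResult]:
    """Resistance values for every (aptamer, ligand, concentration) condition
    in a plate, against that aptamer's ligand-free control.

    Per-replicate R_i share the mean control AUC as denominator; the
    condition reports mean and (for n >= 2) SD over replicates. Negative
    mean R is flagged ``"negative"``.
    """
    groups: dict[tuple[str, str, float], list[TimeCourse]] = defaultdict(list)
    for tc in experiment.timecourses:
        if not tc.is_control:
            groups[(tc.aptamer_id, tc.ligand_id, tc.concentration)].append(tc)

    results: list[ResistanceResult] = []
    for (aptamer_id, ligand_id, concentration), wells in sorted(groups.items()):
        controls = experiment.controls(aptamer_id)
        if not controls:  # pragma: no cover - PlateExperiment enforces this
            raise DegenerateControlError(f"no control wells for {aptamer_id}")
        lig_aucs, auc0 = _condition_aucs(wells, controls, include_t0)
        if auc0 <= 0:
            raise DegenerateControlError(
                f"control AUC for {aptamer_id} is not positive ({auc0})"
            )
        r_values = [(a - auc0) / auc0 for a in lig_aucs]
        mean = float(np.mean(r_values))
        sd = float(np.std(r_values, ddof=1)) if len(r_values) >= 2 else None
        results.append(
            ResistanceResult(
                aptamer_id=aptamer_id,
                ligand_id=ligand_id,
                concentration=concentration,
                resistance_mean=mean,
                resistance_sd=sd,
                n_replicates=len(r_values),
                quality_flag="negative" if mean < 0 else "",
            )
        )
    return results
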