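"""Screening calls, specificity profiles and apparent-affinity estimation.

``call_binders`` turns a panel of resistance values at one shared screening
concentration into binder / non-binder calls by a simple threshold (default
0.1, far below the binder cluster and far above the non-binder noise).
``build_profile`` converts per-ligand resistance values into cross-reactivity
percentages relative to the reference target; because all conditions of one
aptamer share the control AUC, CR% = 100 * R_L / R_T exactly. Entries below
the significance bound (default 10%) are annotated not-significant.

``fit_dose_response`` fits the rectangular hyperbola
R(c) = r_max * c / (k_half + c) to a resistance-versus-concentration series
by bounded least squares. The hyperbola is the occupancy-proxy model: if
protection scales with fraction bound, R inherits the binding isotherm and
k_half estimates the apparent affinity. Confidence intervals come from a
seeded stratified bootstrap because replicate counts are tiny.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    InsufficientDataError,
    InvalidParameterError,
    InvalidReferenceError,
    PlateValidationError,
)
from .models import (
    CrossReactivityEntry,
    DoseResponseFit,
    ResistanceResult,
    ScreenCall,
)

DEFAULT_THRESHOLD = 0.1
CR_SIGNIFICANCE_PERCENT = 10.0
BOOTSTRAP_RESAMPLES = 200


def call_binders(
    results: Sequence[ResistanceResult],
    threshold: float = DEFAULT_THRESHOLD,
) -> list[ScreenCall]:
    """Threshold a single-concentration panel into binder / non-binder calls.

    Requires one result per candidate, all at the same screening
    concentration (mixed-concentration panels are refused: resistance is not
    concentration-standardised across candidates otherwise). A candidate
    exactly at the threshold is called a binder. Output is sorted by
    resistance descending. A companion z-score (R_mean / R_sd) is reported
    but does not influence the call.
    """
    seen: set[str] = set()
    for r in results:
        if r.aptamer_id in seen:
            raise PlateValidationError(f"duplicate aptamer id {r.aptamer_id!r}")
        seen.add(r.aptamer_id)
    concentrations = {r.concentration for r in results}
    if len(concentrations) > 1:
        raise InvalidParameterError(
            "screening requires a single shared concentration, got "
            f"{sorted(concentrations)}"
        )
    calls = []
    for r in results:
        z = None
        if r.resistance_sd is not None and r.resistance_sd > 0:
            z = r.resistance_mean / r.resistance_sd
        calls.append(
            ScreenCall(
                aptamer_id=r.aptamer_id,
                resistance_mean=r.resistance_mean,
                resistance_sd=r.resistance_sd,
                call="binder" if r.resistance_mean >= threshold else "non-binder",
                threshold_used=threshold,
                zscore=z,
            )
        )
    calls.sort(key=lambda c: (-c.resistance_mean, c.aptamer_id))
    return calls


def build_profile(
    results: Sequence[ResistanceResult],
    reference_ligand: str,
    *,
    significance_percent: float = CR_SIGNIFICANCE_PERCENT,
) -> list[CrossReactivityEntry]:
    """Per-ligand cross-reactivity profile of one aptamer.

    All results must share the aptamer (and its control), so
    CR% = 100 * R_L / R_T. The reference entry is set to exactly 100;
    entries with CR below ``significance_percent`` are annotated
    not-significant; negative CR is reported raw with an artifact-suspect
    flag.
    """
    aptamers = {r.aptamer_id for r in results}
    if len(aptamers) > 1:
        raise InvalidParameterError(
            f"profile requires a single aptamer, got {sorted(aptamers)}"
        )
    by_ligand = {r.ligand_id: r for r in results}
    if reference_ligand not in by_ligand:
        raise InvalidReferenceError(
            f"reference ligand {reference_ligand!r} not present in results"
        )
    r_t = by_ligand[reference_ligand].resistance_mean
    if r_t <= 0:
        raise InvalidReferenceError(
            f"reference ligand {reference_ligand!r} does not protect (R = {r_t})"
        )
    entries = []
    for ligand_id, res in sorted(by_ligand.items()):
        if ligand_id == reference_ligand:
            cr = 100.0
        else:
            cr = 100.0 * res.resistance_mean / r_t
        entries.append(
            CrossReactivityEntry(
                ligand_id=ligand_id,
                cr_percent=cr,
                reference_ligand_id=reference_ligand,
                significant=cr >= significance_percent,
                quality_flag="artifact-suspect" if cr < 0 else "",
            )
        )
    entries.sort(key=lambda e: (-e.cr_percent, e.ligand_id))
    return entries


def _hyperbola(params: np.ndarray, c: np.ndarray) -> np.ndarray:
    r_max, k_half = params
    return r_max * c / (k_half + c)


def _fit_once(c: np.ndarray, r: np.ndarray) -> tuple[float, float, float, bool]:
    r_max0 = float(max(np.max(r), 1e-6))
    half = r_max0 / 2.0
    above = np.nonzero(r >= half)[0]
    k0 = float(c[above[0]]) if len(above) and c[above[0]] > 0 else float(np.median(c[c > 0]))
    sol = least_squares(
        lambda p: _hyperbola(p, c) - r,
        x0=[r_max0, max(k0, 1e-6)],
        bounds=([0.0, 1e-12], [np.inf, np.inf]),
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
    )
    r_max, k_half = sol.x
    rss = float(np.sum(sol.fun**2))
    return float(k_half), float(r_max), rss, bool(sol.success)


def fit_dose_response(
    concentrations: Sequence[float],
    resistances: Sequence[float],
    *,
    n_boot: int = BOOTSTRAP_RESAMPLES,
    seed: int = 0,
) -> DoseResponseFit:
    """Fit R(c) = r_max * c / (k_half + c) to a concentration series.

    ``concentrations`` may contain repeated values (replicates). Requires at
    least 4 distinct concentrations including 0. A flat response (all R <= 0
    within numerical noise of zero) returns the documented non-binder
    sentinel (``converged=False``, NaN parameters) rather than raising.
    Bootstrap CIs (percentile, ``n_boot`` seeded resamples stratified by
    concentration) are attached when ``n_boot > 0``.
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(resistances, dtype=float)
    if c.shape != r.shape:
        raise InvalidParameterError("concentrations and resistances differ in length")
    if not np.all(np.isfinite(r)) or not np.all(np.isfinite(c)) or np.any(c < 0):
        raise InvalidParameterError("inputs must be finite and concentrations >= 0")
    distinct = np.unique(c)
    if len(distinct) < 4 or 0.0 not in distinct:
        raise InsufficientDataError(
            "need >= 4 distinct concentrations including 0, got "
            f"{distinct.tolist()}"
        )
    if np.all(r <= 0.0):
        return DoseResponseFit(
            k_half=math.nan,
            r_max=math.nan,
            rss=float(np.sum(r**2)),
            converged=False,
            ci_k_half=None,
            n_points=len(c),
        )

    k_half, r_max, rss, ok = _fit_once(c, r)
    ci = None
    if n_boot > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), len(c)]))
        groups = [np.nonzero(c == v)[0] for v in distinct]
        boots = []
        for _ in range(n_boot):
            idx = np.concatenate(
                [g[rng.integers(0, len(g), size=len(g))] for g in groups]
            )
            rb = r[idx]
            if np.all(rb <= 0.0):
                continue
            kb, _, _, okb = _fit_once(c[idx], rb)
            if okb and np.isfinite(kb):
                boots.append(kb)
        if boots:
            lo, hi = np.percentile(boots, [2.5, 97.5])
            ci = (float(lo), float(hi))
    return DoseResponseFit(
        k_half=k_half,
        r_max=r_max,
        rss=rss,
        converged=ok,
        ci_k_half=ci,
        n_points=len(c),
    )
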