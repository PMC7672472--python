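"""Synthetic digestion and strand-displacement fluorescence time courses.

The generator encodes the mechanistic picture behind the exonuclease
protection assay: a 5'->3' exonuclease digests unbound aptamer at an
exponential rate ``k_unprotected``; a ligand-bound aptamer is trimmed only
down to a protected major product of P of its N nucleotides, which is then
degraded slowly (``k_leak``). The DNA-staining dye reports total stainable
nucleotides, taken proportional to retained length, so the protected product
contributes a fraction omega = P/N of the intact-aptamer signal.

Two exchange regimes are offered because the kinetics of bound/unbound
interconversion relative to digestion are not identified by plate data:

* ``slow`` (default): each aptamer molecule stays in the state it occupied
  when the enzyme arrived, so a fraction theta (the equilibrium fraction
  bound) follows the protected pathway and 1 - theta the unprotected one::

      F(t) = B + A * [ (1-theta) * exp(-k_u t)
                       + theta * (omega + (1-omega) exp(-k_u t)) * exp(-k_leak t) ]

* ``fast``: occupancy re-equilibrates faster than digestion, giving a single
  exponential with the occupancy-weighted rate
  ``k_eff = (1-theta) k_u + theta k_leak``.

Occupancy comes from a single-site isotherm under ligand excess (the assay
uses ~1 uM aptamer against >= 25 uM ligand, so free ~ total ligand):
``theta = c / (kd_app + c)``.

Observed fluorescence adds multiplicative Gaussian noise (constant CV) and
is clipped at zero. All randomness flows from a master seed through a
documented counter scheme, so any single well is reproducible in isolation.
"""

from __future__ import annotations

import logging
import math
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .errors import ConfigurationError, InvalidParameterError, InvalidScheduleError
from .models import (
    CONTROL_LIGAND,
    AptamerSpec,
    BindingParams,
    DigestionParams,
    LigandCondition,
    PlateExperiment,
    SamplingSchedule,
    SDParams,
    TimeCourse,
)

logger = logging.getLogger(__name__)

#: Ratio of ligand to aptamer concentration below which the ligand-excess
#: assumption (free ~ total ligand) becomes questionable.
LIGAND_EXCESS_RATIO = 10.0


def fraction_bound(
    concentration: float,
    kd_app: Optional[float],
    *,
    aptamer_concentration: Optional[float] = None,
) -> float:
    """Equilibrium fraction of aptamer bound at ligand concentration ``c``.

    Single-site isotherm under ligand excess: ``theta = c / (kd_app + c)``.
    ``kd_app = None`` is the non-binder sentinel and returns 0 at any
    concentration. If ``aptamer_concentration`` is given, a warning is logged
    when the ligand is not in >= 10-fold excess (ligand depletion would bias
    the isotherm there).
    """
    if concentration < 0:
        raise InvalidParameterError(f"concentration must be >= 0, got {concentration}")
    if kd_app is None or concentration == 0:
        if kd_app is not None and (not math.isfinite(kd_app) or kd_app <= 0):
            raise InvalidParameterError(f"kd_app must be positive, got {kd_app}")
        return 0.0
    if not math.isfinite(kd_app) or kd_app <= 0:
        raise InvalidParameterError(f"kd_app must be positive, got {kd_app}")
    if (
        aptamer_concentration is not None
        and concentration < LIGAND_EXCESS_RATIO * aptamer_concentration
    ):
        logger.warning(
            "ligand at %.3g uM is < %.0fx the aptamer concentration (%.3g uM); "
            "the ligand-excess isotherm may be biased",
            concentration,
            LIGAND_EXCESS_RATIO,
            aptamer_concentration,
        )
    return concentration / (kd_app + concentration)


def expected_fluorescence(
    t: float | np.ndarray,
    theta: float,
    aptamer: AptamerSpec,
    params: DigestionParams,
) -> float | np.ndarray:
    """Noiseless model fluorescence at time ``t`` minutes.

    Vectorised over ``t``. See the module docstring for the two exchange
    regimes; ``theta`` is the equilibrium fraction bound in [0, 1].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidParameterError("t must be >= 0")
    if not 0.0 <= theta <= 1.0:
        raise InvalidParameterError(f"theta must be in [0, 1], got {theta}")
    a, b = params.amplitude, params.background
    k_u, k_l = params.k_unprotected, params.k_leak
    omega = aptamer.protected_fraction
    if params.exchange_mode == "slow":
        unbound = (1.0 - theta) * np.exp(-k_u * t)
        bound = theta * (omega + (1.0 - omega) * np.exp(-k_u * t)) * np.exp(-k_l * t)
        out = b + a * (unbound + bound)
    elif params.exchange_mode == "fast":
        k_eff = (1.0 - theta) * k_u + theta * k_l
        out = b + a * np.exp(-k_eff * t)
    else:  # pragma: no cover - pydantic already restricts the literal
        raise ConfigurationError(f"unknown exchange_mode {params.exchange_mode!r}")
    return float(out) if out.ndim == 0 else out


def _rng_for_well(seed: int | np.random.SeedSequence, well_index: int) -> np.random.Generator:
    """Deterministic per-well generator: child ``well_index`` of the master
    seed via ``SeedSequence([seed, well_index])`` (the counter scheme)."""
    if isinstance(seed, np.random.SeedSequence):
        entropy = seed.entropy
    else:
        entropy = int(seed)
    return np.random.default_rng(np.random.SeedSequence([entropy, well_index]))


def simulate_timecourse(
    aptamer: AptamerSpec,
    condition: LigandCondition,
    binding: Optional[BindingParams],
    params: DigestionParams,
    schedule: SamplingSchedule,
    seed: int,
    *,
    replicate: int = 1,
    well_index: int = 0,
) -> TimeCourse:
    """Simulate one well: noiseless model curve times ``(1 + eps_t)`` with
    i.i.d. ``eps_t ~ Normal(0, noise_cv)``, clipped at zero.

    ``binding = None`` (no entry for the pair) is treated as a non-binder.
    Identical seed, well_index and inputs give identical output.
    """
    if binding is not None and not condition.is_control:
        if (
            binding.aptamer_id != aptamer.aptamer_id
            or binding.ligand_id != condition.ligand_id
        ):
            raise InvalidParameterError(
                f"binding entry {binding.aptamer_id}/{binding.ligand_id} does not "
                f"match well {aptamer.aptamer_id}/{condition.ligand_id}"
            )
    try:
        times = np.asarray(schedule.times, dtype=float)
    except Exception as exc:  # pragma: no cover
        raise InvalidScheduleError(str(exc)) from exc

    kd = binding.kd_app if binding is not None else None
    theta = fraction_bound(condition.concentration, kd)
    clean = expected_fluorescence(times, theta, aptamer, params)
    if params.noise_cv > 0:
        rng = _rng_for_well(seed, well_index)
        eps = rng.normal(0.0, params.noise_cv, size=times.shape)
        observed = np.clip(clean * (1.0 + eps), 0.0, None)
    else:
        observed = np.asarray(clean, dtype=float)
    return TimeCourse(
        aptamer_id=aptamer.aptamer_id,
        ligand_id=condition.ligand_id if not condition.is_control else CONTROL_LIGAND,
        concentration=condition.concentration,
        replicate=replicate,
        times=tuple(times.tolist()),
        fluorescence=tuple(float(v) for v in observed),
    )


def _binding_lookup(
    binding_table: Iterable[BindingParams],
) -> Mapping[tuple[str, str], BindingParams]:
    table: dict[tuple[str, str], BindingParams] = {}
    for entry in binding_table:
        key = (entry.aptamer_id, entry.ligand_id)
        if key in table:
            raise InvalidParameterError(f"duplicate binding entry for {key}")
        table[key] = entry
    return table


def simulate_panel(
    aptamers: Sequence[AptamerSpec],
    conditions: Sequence[LigandCondition],
    binding_table: Iterable[BindingParams],
    n_replicates: int,
    params: DigestionParams,
    schedule: SamplingSchedule,
    seed: int,
) -> PlateExperiment:
    """Simulate a full plate: one time course per (aptamer, condition,
    replicate), plus an automatically added ligand-free control condition
    for every aptamer when none is supplied.

    A missing binding entry for an (aptamer, ligand) pair is treated as a
    non-binder and logged, not raised. Wells are enumerated in a fixed order
    (aptamer, then condition with the control first, then replicate); the
    enumeration index is the per-well sub-seed counter, so the whole panel is
    bit-reproducible for a fixed master seed.
    """
    if n_replicates < 1:
        raise InvalidParameterError("n_replicates must be >= 1")
    table = _binding_lookup(binding_table)

    run_conditions: list[LigandCondition] = list(conditions)
    if not any(c.is_control for c in run_conditions):
        run_conditions.insert(
            0, LigandCondition(ligand_id=CONTROL_LIGAND, concentration=0.0)
        )
    else:
        run_conditions.sort(key=lambda c: 0 if c.is_control else 1)

    timecourses: list[TimeCourse] = []
    well_index = 0
    for aptamer in aptamers:
        for condition in run_conditions:
            binding = None
            if not condition.is_control:
                binding = table.get((aptamer.aptamer_id, condition.ligand_id))
                if binding is None:
                    logger.info(
                        "no binding entry for (%s, %s); treating as non-binder",
                        aptamer.aptamer_id,
                        condition.ligand_id,
                    )
            for replicate in range(1, n_replicates + 1):
                timecourses.append(
                    simulate_timecourse(
                        aptamer,
                        condition,
                        binding,
                        params,
                        schedule,
                        seed,
                        replicate=replicate,
                        well_index=well_index,
                    )
                )
                well_index += 1
    provenance = {
        "generator": "exoprofile.simulate.simulate_panel",
        "seed": str(seed),
        "n_replicates": str(n_replicates),
        "exchange_mode": params.exchange_mode,
    }
    return PlateExperiment(timecourses=tuple(timecourses), provenance=provenance)


def simulate_sd_readout(
    condition: LigandCondition,
    binding: Optional[BindingParams],
    sd: SDParams,
    seed: int,
) -> tuple[float, float]:
    """Simulate one strand-displacement measurement: ``(F_observed, F0)``.

    The quenched complex emits ``F_q = (1 - quench_efficiency) * f_max``. A
    ligand displaces the quencher strand by the fraction
    ``delta = max_displacement * c / (kd_sd + c)`` (0 for a non-binder), so
    the true signal is ``F_q + (f_max - F_q) * delta``. The observed signal
    is multiplied by the ligand's ``dye_artifact_factor`` — fluorophore
    attenuation/enhancement artifacts act here and only here, which is what
    makes the strand-displacement readout fragile where the dye-based
    digestion readout is not. ``F0`` is measured without ligand and without
    artifact.
    """
    f_q = (1.0 - sd.quench_efficiency) * sd.f_max
    c = condition.concentration
    if binding is None or not binding.is_binder or c == 0:
        delta = 0.0
    else:
        delta = sd.max_displacement * c / (sd.kd_sd + c)
    f_true = f_q + (sd.f_max - f_q) * delta
    f_obs = condition.dye_artifact_factor * f_true
    f0_obs = f_q
    if sd.noise_cv > 0:
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
        f_obs = max(0.0, f_obs * (1.0 + rng.normal(0.0, sd.noise_cv)))
        f0_obs = max(0.0, f0_obs * (1.0 + rng.normal(0.0, sd.noise_cv)))
    return float(f_obs), float(f0_obs)
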