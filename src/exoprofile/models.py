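"""Domain types for the exonuclease-protection profiling pipeline.

The models mirror the experiment: a panel of DNA aptamer candidates
(:class:`AptamerSpec`), per-pair apparent affinities (:class:`BindingParams`),
the phenomenological digestion kinetics (:class:`DigestionParams`), the
ligand conditions on the plate (:class:`LigandCondition`), the destructive
sampling schedule (:class:`SamplingSchedule`), and the recorded fluorescence
trajectories (:class:`TimeCourse`, grouped into :class:`PlateExperiment`).

Result records (:class:`ResistanceResult`, :class:`CrossReactivityEntry`,
:class:`SDReadout`, :class:`ScreenCall`, :class:`DoseResponseFit`) carry the
assay statistics downstream and into the CSV writers.

All models are immutable (``frozen=True``) and validate their invariants on
construction; invariant violations raise pydantic ``ValidationError``.
"""

from __future__ import annotations

import math
from typing import Literal, Optional

from pydantic import BaseModel, ConfigDict, Field, model_validator

#: ligand_id used for the ligand-free (concentration 0) control wells.
CONTROL_LIGAND = "none"

#: Sentinel accepted in binding tables for a ligand with no measurable binding.
NON_BINDER = "NB"

_IUPAC_DNA = set("ACGTRYSWKMBDHVN")


class AptamerSpec(BaseModel):
    """One aptamer candidate: identity, optional sequence, full length N and
    the length P of the ligand-protected major digestion product."""

    model_config = ConfigDict(frozen=True)

    aptamer_id: str = Field(min_length=1)
    full_length_nt: int = Field(gt=0)
    protected_length_nt: int = Field(gt=0)
    sequence: Optional[str] = None

    @model_validator(mode="after")
    def _check(self) -> "AptamerSpec":
        if self.protected_length_nt > self.full_length_nt:
            raise ValueError(
                f"{self.aptamer_id}: protected_length_nt "
                f"({self.protected_length_nt}) exceeds full_length_nt "
                f"({self.full_length_nt})"
            )
        if self.sequence is not None:
            seq = self.sequence.upper()
            if len(seq) != self.full_length_nt:
                raise ValueError(
                    f"{self.aptamer_id}: sequence length {len(seq)} != "
                    f"full_length_nt {self.full_length_nt}"
                )
            bad = set(seq) - _IUPAC_DNA
            if bad:
                raise ValueError(
                    f"{self.aptamer_id}: non-IUPAC DNA characters {sorted(bad)}"
                )
        return self

    @property
    def protected_fraction(self) -> float:
        """P/N — the fraction of stainable nucleotides retained in the
        protected product."""
        return self.protected_length_nt / self.full_length_nt


class BindingParams(BaseModel):
    """Apparent dissociation constant of one aptamer-ligand pair in uM.

    ``kd_app = None`` is the non-binder sentinel: no binding at any tested
    concentration (written as ``NB`` in binding-table CSVs).
    """

    model_config = ConfigDict(frozen=True)

    aptamer_id: str
    ligand_id: str
    kd_app: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "BindingParams":
        if self.kd_app is not None:
            if not math.isfinite(self.kd_app) or self.kd_app <= 0:
                raise ValueError(
                    f"kd_app must be finite and positive, got {self.kd_app}"
                )
        return self

    @property
    def is_binder(self) -> bool:
        return self.kd_app is not None


class DigestionParams(BaseModel):
    """Phenomenological first-order digestion kinetics.

    ``k_unprotected`` is the decay rate of unbound/unprotected aptamer
    (per minute); ``k_leak`` the slow residual digestion of the
    ligand-protected product. ``amplitude`` and ``background`` are the
    fluorescence of intact aptamer and the signal floor (a.u.). Noise is
    multiplicative Gaussian with coefficient of variation ``noise_cv``.
    ``exchange_mode`` selects whether bound/unbound interconversion is slow
    or fast relative to digestion.
    """

    model_config = ConfigDict(frozen=True)

    k_unprotected: float = Field(gt=0)
    k_leak: float = Field(ge=0, default=0.0)
    amplitude: float = Field(gt=0, default=1000.0)
    background: float = Field(ge=0, default=0.0)
    noise_cv: float = Field(ge=0, default=0.0)
    exchange_mode: Literal["slow", "fast"] = "slow"

    @model_validator(mode="after")
    def _check(self) -> "DigestionParams":
        if self.k_leak >= self.k_unprotected:
            raise ValueError(
                "k_leak must be strictly smaller than k_unprotected "
                f"(got k_leak={self.k_leak}, k_unprotected={self.k_unprotected})"
            )
        return self


class LigandCondition(BaseModel):
    """One ligand condition on the plate. ``concentration = 0`` denotes the
    ligand-free control; ``dye_artifact_factor`` multiplies the observed
    fluorophore signal in the strand-displacement readout (1 = no artifact)."""

    model_config = ConfigDict(frozen=True)

    ligand_id: str
    concentration: float = Field(ge=0)
    dye_artifact_factor: float = Field(gt=0, default=1.0)

    @property
    def is_control(self) -> bool:
        return self.concentration == 0.0


class SamplingSchedule(BaseModel):
    """Destructive sampling times in minutes, starting at 0, plus the
    aptamer-ligand pre-incubation time (metadata only)."""

    model_config = ConfigDict(frozen=True)

    times: tuple[float, ...]
    incubation_min: float = Field(ge=0, default=60.0)

    @model_validator(mode="after")
    def _check(self) -> "SamplingSchedule":
        t = self.times
        if len(t) < 4:
            raise ValueError(f"schedule needs at least 4 time points, got {len(t)}")
        if t[0] != 0.0:
            raise ValueError(f"first sampling time must be 0, got {t[0]}")
        if any(b <= a for a, b in zip(t, t[1:])):
            raise ValueError("sampling times must be strictly increasing")
        return self

    @classmethod
    def regular(
        cls, span_min: float, step_min: float, incubation_min: float = 60.0
    ) -> "SamplingSchedule":
        """Evenly spaced schedule from 0 to ``span_min`` inclusive."""
        n = int(round(span_min / step_min))
        times = tuple(i * step_min for i in range(n + 1))
        return cls(times=times, incubation_min=incubation_min)


class SDParams(BaseModel):
    """Strand-displacement assay parameters: unquenched fluorophore signal
    ``f_max``, quencher-strand quench efficiency, apparent half-saturation of
    displacement ``kd_sd`` (uM) and the maximal displaceable fraction."""

    model_config = ConfigDict(frozen=True)

    f_max: float = Field(gt=0)
    quench_efficiency: float = Field(ge=0.0, le=1.0)
    kd_sd: float = Field(gt=0)
    max_displacement: float = Field(ge=0.0, le=1.0)
    noise_cv: float = Field(ge=0, default=0.0)


class TimeCourse(BaseModel):
    """One well's fluorescence trajectory with its condition metadata."""

    model_config = ConfigDict(frozen=True)

    aptamer_id: str
    ligand_id: str
    concentration: float = Field(ge=0)
    replicate: int = Field(ge=1)
    times: tuple[float, ...]
    fluorescence: tuple[float, ...]

    @model_validator(mode="after")
    def _check(self) -> "TimeCourse":
        if len(self.times) != len(self.fluorescence):
            raise ValueError(
                f"times ({len(self.times)}) and fluorescence "
                f"({len(self.fluorescence)}) differ in length"
            )
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ValueError("times must be strictly increasing")
        if any(f < 0 for f in self.fluorescence):
            raise ValueError("fluorescence values must be non-negative")
        return self

    @property
    def key(self) -> tuple[str, str, float, int]:
        return (self.aptamer_id, self.ligand_id, self.concentration, self.replicate)

    @property
    def is_control(self) -> bool:
        return self.concentration == 0.0


class PlateExperiment(BaseModel):
    """A collection of time courses plus free-text provenance.

    Invariants: well keys (aptamer, ligand, concentration, replicate) are
    unique, and every aptamer measured with a ligand also carries at least
    one ligand-free (concentration 0) control.
    """

    model_config = ConfigDict(frozen=True)

    timecourses: tuple[TimeCourse, ...]
    provenance: dict[str, str] = Field(default_factory=dict)

    @model_validator(mode="after")
    def _check(self) -> "PlateExperiment":
        seen: set[tuple] = set()
        with_ligand: set[str] = set()
        with_control: set[str] = set()
        for tc in self.timecourses:
            if tc.key in seen:
                raise ValueError(f"duplicate well key {tc.key}")
            seen.add(tc.key)
            if tc.is_control:
                with_control.add(tc.aptamer_id)
            else:
                with_ligand.add(tc.aptamer_id)
        missing = sorted(with_ligand - with_control)
        if missing:
            raise ValueError(
                f"aptamers without a ligand-free control: {missing}"
            )
        return self

    def controls(self, aptamer_id: str) -> tuple[TimeCourse, ...]:
        """All concentration-0 wells of one aptamer."""
        return tuple(
            tc
            for tc in self.timecourses
            if tc.aptamer_id == aptamer_id and tc.is_control
        )


class ResistanceResult(BaseModel):
    """Replicate-summarised resistance value R = (AUC1 - AUC0)/AUC0 for one
    aptamer-ligand-concentration condition. ``resistance_sd`` is None for a
    single replicate. Negative R is reported raw and flagged."""

    model_config = ConfigDict(frozen=True)

    aptamer_id: str
    ligand_id: str
    concentration: float
    resistance_mean: float
    resistance_sd: Optional[float] = None
    n_replicates: int = Field(ge=1)
    quality_flag: str = ""

    @model_validator(mode="after")
    def _check(self) -> "ResistanceResult":
        if self.resistance_sd is not None and self.resistance_sd < 0:
            raise ValueError("resistance_sd must be non-negative")
        if self.n_replicates == 1 and self.resistance_sd is not None:
            raise ValueError("resistance_sd requires at least 2 replicates")
        return self


class CrossReactivityEntry(BaseModel):
    """Cross-reactivity of one ligand relative to the reference target, in
    percent; the reference's own entry is exactly 100."""

    model_config = ConfigDict(frozen=True)

    ligand_id: str
    cr_percent: float
    reference_ligand_id: str
    significant: bool = True
    quality_flag: str = ""


class SDReadout(BaseModel):
    """Strand-displacement result for one ligand: signal gain
    S = (F - F0)/F0 and cross-reactivity 100*S_L/S_T."""

    model_config = ConfigDict(frozen=True)

    ligand_id: str
    signal_gain: float
    cr_percent: Optional[float] = None
    quality_flag: str = ""


class ScreenCall(BaseModel):
    """Binder / non-binder call for one candidate at the screening
    concentration; call = binder iff resistance_mean >= threshold."""

    model_config = ConfigDict(frozen=True)

    aptamer_id: str
    resistance_mean: float
    resistance_sd: Optional[float] = None
    call: Literal["binder", "non-binder"]
    threshold_used: float
    zscore: Optional[float] = None

    @model_validator(mode="after")
    def _check(self) -> "ScreenCall":
        expected = "binder" if self.resistance_mean >= self.threshold_used else "non-binder"
        if self.call != expected:
            raise ValueError("call inconsistent with threshold rule")
        return self


class DoseResponseFit(BaseModel):
    """Rectangular-hyperbola fit R(c) = r_max * c / (k_half + c).

    ``k_half`` is the apparent half-saturation concentration (uM) of the
    resistance dose-response — an apparent affinity, not a calorimetric Kd.
    ``converged = False`` with NaN parameters is the documented non-binder
    sentinel for flat (all-zero) response vectors.
    """

    model_config = ConfigDict(frozen=True)

    k_half: float
    r_max: float
    rss: float
    converged: bool
    ci_k_half: Optional[tuple[float, float]] = None
    n_points: int = 0

    @model_validator(mode="after")
    def _check(self) -> "DoseResponseFit":
        if self.converged:
            if not (self.k_half > 0):
                raise ValueError("converged fit requires k_half > 0")
            if self.r_max < 0:
                raise ValueError("converged fit requires r_max >= 0")
        return self
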