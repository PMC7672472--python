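"""Tabular I/O: time-course CSVs, FASTA aptamer panels, binding tables,
result tables.

Time courses travel in a long-format CSV, one row per plate read::

    aptamer_id,ligand_id,concentration_uM,replicate,time_min,fluorescence_au

Long format is what plate readers export and keeps the grouping explicit.
Aptamer panels are FASTA with key=value attributes on the header line
(``>MMC1 protected_length=42``); the sequence length defines the full length
N. Binding tables are CSV with one row per (aptamer, ligand, condition):
``aptamer_id,ligand_id,kd_app_uM,concentration_uM,dye_artifact_factor``
with ``NB`` in ``kd_app_uM`` marking a non-binder.

All writers are deterministic (fixed column order, stable sort, atomic
write-to-temp-then-rename) so identical inputs give byte-identical files.
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from pydantic import BaseModel, ValidationError

from .errors import DataError, PlateValidationError, SchemaError
from .models import (
    AptamerSpec,
    BindingParams,
    CrossReactivityEntry,
    DoseResponseFit,
    LigandCondition,
    PlateExperiment,
    ResistanceResult,
    ScreenCall,
    SDReadout,
    TimeCourse,
)

logger = logging.getLogger(__name__)

TIMECOURSE_COLUMNS = [
    "aptamer_id",
    "ligand_id",
    "concentration_uM",
    "replicate",
    "time_min",
    "fluorescence_au",
]

BINDING_COLUMNS = [
    "aptamer_id",
    "ligand_id",
    "kd_app_uM",
    "concentration_uM",
    "dye_artifact_factor",
]

#: Default protected-product length when the FASTA header carries none: the
#: exonuclease trims a few (3-6) nucleotides from the 5' end before a bound
#: ligand stalls it, so P defaults to N - 5.
DEFAULT_TRIM_NT = 5

RESULT_SCHEMAS: dict[str, list[str]] = {
    "resistance": [
        "aptamer_id",
        "ligand_id",
        "concentration_uM",
        "resistance_mean",
        "resistance_sd",
        "n_replicates",
        "quality_flag",
    ],
    "cross_reactivity": [
        "ligand_id",
        "cr_percent",
        "reference_ligand_id",
        "significant",
        "quality_flag",
    ],
    "screen_calls": [
        "aptamer_id",
        "resistance_mean",
        "resistance_sd",
        "call",
        "threshold_used",
        "zscore",
    ],
    "dose_response_fits": [
        "aptamer_id",
        "ligand_id",
        "k_half_uM",
        "r_max",
        "rss",
        "converged",
        "ci_k_half_low",
        "ci_k_half_high",
        "n_points",
    ],
    "sd_comparison": [
        "ligand_id",
        "signal_gain",
        "sd_cr_percent",
        "resistance_mean",
        "exo_cr_percent",
        "quality_flag",
    ],
}


def _atomic_write(df: pd.DataFrame, path: Path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.", suffix=".tmp")
    try:
        with os.fdopen(fd, "w", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


# ---------------------------------------------------------------------------
# time courses


def write_timecourses(experiment: PlateExperiment, path: Union[str, Path]) -> None:
    """Write a plate to the long-format CSV (stable row order)."""
    rows = []
    for tc in sorted(experiment.timecourses, key=lambda t: t.key):
        for t, f in zip(tc.times, tc.fluorescence):
            rows.append(
                {
                    "aptamer_id": tc.aptamer_id,
                    "ligand_id": tc.ligand_id,
                    "concentration_uM": tc.concentration,
                    "replicate": tc.replicate,
                    "time_min": t,
                    "fluorescence_au": f,
                }
            )
    df = pd.DataFrame(rows, columns=TIMECOURSE_COLUMNS)
    _atomic_write(df, Path(path))


def read_timecourses(path: Union[str, Path]) -> PlateExperiment:
    """Read a long-format time-course CSV into a validated plate.

    Rows are grouped by (aptamer, ligand, concentration, replicate) and
    sorted by time within each group. Raises :class:`SchemaError` for a
    missing column, :class:`DataError` for duplicated reads or otherwise
    broken groups, :class:`PlateValidationError` for plate-level invariant
    violations (e.g. an aptamer without its ligand-free control).
    """
    path = Path(path)
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in TIMECOURSE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    key_cols = ["aptamer_id", "ligand_id", "concentration_uM", "replicate"]
    dup = df.duplicated(subset=key_cols + ["time_min"])
    if dup.any():
        first = df.loc[dup.idxmax(), key_cols + ["time_min"]].to_dict()
        raise DataError(f"{path}: duplicated read for {first}")

    timecourses = []
    for key, group in df.groupby(key_cols, sort=True):
        group = group.sort_values("time_min")
        try:
            timecourses.append(
                TimeCourse(
                    aptamer_id=str(key[0]),
                    ligand_id=str(key[1]),
                    concentration=float(key[2]),
                    replicate=int(key[3]),
                    times=tuple(group["time_min"].astype(float)),
                    fluorescence=tuple(group["fluorescence_au"].astype(float)),
                )
            )
        except ValidationError as exc:
            raise DataError(f"{path}: invalid time course for {key}: {exc}") from exc
    try:
        return PlateExperiment(
            timecourses=tuple(timecourses), provenance={"source": str(path)}
        )
    except ValidationError as exc:
        raise PlateValidationError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# aptamer panels (FASTA)


def _parse_header_attrs(description: str) -> dict[str, str]:
    attrs = {}
    for token in description.split()[1:]:
        if "=" in token:
            k, _, v = token.partition("=")
            attrs[k] = v
    return attrs


def read_aptamer_panel(path: Union[str, Path]) -> list[AptamerSpec]:
    """Read a FASTA aptamer panel.

    The header may carry ``protected_length=<int>``; without it the
    protected product defaults to N - 5 (5'-end trim). Duplicate ids and
    protected lengths exceeding the sequence length are errors; an empty
    file yields an empty list with a warning.
    """
    path = Path(path)
    specs: list[AptamerSpec] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            raise PlateValidationError(f"{path}: duplicate aptamer id {record.id!r}")
        seen.add(record.id)
        seq = str(record.seq).upper()
        n = len(seq)
        attrs = _parse_header_attrs(record.description)
        if "protected_length" in attrs:
            p = int(attrs["protected_length"])
        else:
            p = max(1, n - DEFAULT_TRIM_NT)
        try:
            specs.append(
                AptamerSpec(
                    aptamer_id=record.id,
                    sequence=seq,
                    full_length_nt=n,
                    protected_length_nt=p,
                )
            )
        except ValidationError as exc:
            raise PlateValidationError(f"{path}: record {record.id!r}: {exc}") from exc
    if not specs:
        logger.warning("aptamer panel %s contains no records", path)
    return specs


def write_aptamer_panel(specs: Sequence[AptamerSpec], path: Union[str, Path]) -> None:
    """Write a panel back to FASTA with protected_length attributes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = []
    for spec in specs:
        lines.append(f">{spec.aptamer_id} protected_length={spec.protected_length_nt}")
        lines.append(spec.sequence or "N" * spec.full_length_nt)
    path.write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# binding tables / conditions


def read_binding_table(
    path: Union[str, Path],
) -> tuple[list[BindingParams], list[LigandCondition]]:
    """Read a binding/conditions CSV.

    Returns the binding entries (one per (aptamer, ligand) pair) and the
    distinct ligand conditions (ligand, concentration, artifact factor).
    ``NB`` (or an empty field) in ``kd_app_uM`` marks a non-binder.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"kd_app_uM": str})
    missing = [c for c in BINDING_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    bindings: dict[tuple[str, str], BindingParams] = {}
    conditions: dict[tuple[str, float, float], LigandCondition] = {}
    for _, row in df.iterrows():
        apt, lig = str(row["aptamer_id"]), str(row["ligand_id"])
        raw_kd = row["kd_app_uM"]
        if pd.isna(raw_kd) or str(raw_kd).strip().upper() == "NB":
            kd = None
        else:
            kd = float(raw_kd)
        entry = BindingParams(aptamer_id=apt, ligand_id=lig, kd_app=kd)
        key = (apt, lig)
        if key in bindings and bindings[key] != entry:
            raise DataError(f"{path}: conflicting binding entries for {key}")
        bindings[key] = entry
        factor = row.get("dye_artifact_factor", 1.0)
        factor = 1.0 if pd.isna(factor) else float(factor)
        cond = LigandCondition(
            ligand_id=lig,
            concentration=float(row["concentration_uM"]),
            dye_artifact_factor=factor,
        )
        conditions[(lig, cond.concentration, factor)] = cond
    return list(bindings.values()), list(conditions.values())


# ---------------------------------------------------------------------------
# result tables


def resistance_frame(results: Iterable[ResistanceResult]) -> pd.DataFrame:
    rows = [
        {
            "aptamer_id": r.aptamer_id,
            "ligand_id": r.ligand_id,
            "concentration_uM": r.concentration,
            "resistance_mean": r.resistance_mean,
            "resistance_sd": r.resistance_sd,
            "n_replicates": r.n_replicates,
            "quality_flag": r.quality_flag,
        }
        for r in results
    ]
    df = pd.DataFrame(rows, columns=RESULT_SCHEMAS["resistance"])
    return df.sort_values(
        ["aptamer_id", "ligand_id", "concentration_uM"], ignore_index=True
    )


def cross_reactivity_frame(entries: Iterable[CrossReactivityEntry]) -> pd.DataFrame:
    rows = [
        {
            "ligand_id": e.ligand_id,
            "cr_percent": e.cr_percent,
            "reference_ligand_id": e.reference_ligand_id,
            "significant": e.significant,
            "quality_flag": e.quality_flag,
        }
        for e in entries
    ]
    df = pd.DataFrame(rows, columns=RESULT_SCHEMAS["cross_reactivity"])
    return df.sort_values(
        ["cr_percent", "ligand_id"], ascending=[False, True], ignore_index=True
    )


def screen_calls_frame(calls: Iterable[ScreenCall]) -> pd.DataFrame:
    rows = [
        {
            "aptamer_id": c.aptamer_id,
            "resistance_mean": c.resistance_mean,
            "resistance_sd": c.resistance_sd,
            "call": c.call,
            "threshold_used": c.threshold_used,
            "zscore": c.zscore,
        }
        for c in calls
    ]
    df = pd.DataFrame(rows, columns=RESULT_SCHEMAS["screen_calls"])
    return df.sort_values(
        ["resistance_mean", "aptamer_id"], ascending=[False, True], ignore_index=True
    )


def dose_response_frame(
    fits: Iterable[tuple[str, str, DoseResponseFit]],
) -> pd.DataFrame:
    """Rows of (aptamer_id, ligand_id, fit)."""
    rows = []
    for aptamer_id, ligand_id, fit in fits:
        lo, hi = fit.ci_k_half if fit.ci_k_half is not None else (None, None)
        rows.append(
            {
                "aptamer_id": aptamer_id,
                "ligand_id": ligand_id,
                "k_half_uM": fit.k_half,
                "r_max": fit.r_max,
                "rss": fit.rss,
                "converged": fit.converged,
                "ci_k_half_low": lo,
                "ci_k_half_high": hi,
                "n_points": fit.n_points,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_SCHEMAS["dose_response_fits"])
    return df.sort_values(["aptamer_id", "ligand_id"], ignore_index=True)


def sd_comparison_frame(
    rows: Iterable[tuple[SDReadout, Optional[ResistanceResult], Optional[float]]],
) -> pd.DataFrame:
    """Rows of (sd readout, matching digestion result, digestion CR%)."""
    out = []
    for sd, res, exo_cr in rows:
        out.append(
            {
                "ligand_id": sd.ligand_id,
                "signal_gain": sd.signal_gain,
                "sd_cr_percent": sd.cr_percent,
                "resistance_mean": res.resistance_mean if res is not None else None,
                "exo_cr_percent": exo_cr,
                "quality_flag": sd.quality_flag,
            }
        )
    df = pd.DataFrame(out, columns=RESULT_SCHEMAS["sd_comparison"])
    return df.sort_values(["ligand_id"], ignore_index=True)


def write_results(
    tables: Mapping[str, Union[pd.DataFrame, Iterable[BaseModel]]],
    out_dir: Union[str, Path],
) -> dict[str, Path]:
    """Write result tables as ``<name>.csv`` under ``out_dir``.

    Known table names get their fixed schema and sort order (empty inputs
    produce header-only files); already-built DataFrames are written as-is.
    Returns the written paths. Output is deterministic and atomic.
    """
    builders = {
        "resistance": resistance_frame,
        "cross_reactivity": cross_reactivity_frame,
        "screen_calls": screen_calls_frame,
    }
    out_dir = Path(out_dir)
    written: dict[str, Path] = {}
    for name in sorted(tables):
        content = tables[name]
        if isinstance(content, pd.DataFrame):
            df = content
        elif name in builders:
            df = builders[name](content)  # type: ignore[arg-type]
        else:
            raise SchemaError(
                f"unknown result table {name!r}; pass a DataFrame or use one of "
                f"{sorted(builders)}"
            )
        path = out_dir / f"{name}.csv"
        _atomic_write(df, path)
        written[name] = path
    return written
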