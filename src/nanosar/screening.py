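"""Plate-level screening pipeline: spectra -> normalized responses -> categories.

Workflow emulated: each 96-well plate carries triplicate sample wells per
analyte, blank wells (buffer + vehicle) and a dopamine (DA) reference for
plate-matched normalization.  A baseline spectrum (F0) is read before
analyte addition; timed reads follow, with the 30 min read used as F by
default.  Responses are blank-subtracted, integrated, expressed as
dF/F = (F - F0)/F0, averaged over replicates and divided by the plate's
dopamine response, so the reference is exactly 1.00.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .spectra import (
    EmissionSpectrum,
    compute_dff,
    extract_peak_response,
    integrate_spectrum,
    subtract_blank,
)

__all__ = [
    "PlateWell",
    "ResponseRecord",
    "ResponseCategory",
    "classify_response",
    "normalize_to_reference",
    "load_plate",
    "process_plate",
    "responses_to_frame",
    "CATEGORY_ORDER",
]


class ResponseCategory(enum.Enum):
    """Four response groups relative to dopamine, plus the caption gaps."""

    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    UNASSIGNED = "unassigned"


#: Partial order used for monotonicity checks (unassigned excluded).
CATEGORY_ORDER = {
    ResponseCategory.IV: 0,
    ResponseCategory.III: 1,
    ResponseCategory.II: 2,
    ResponseCategory.I: 3,
}


def classify_response(normalized: float) -> ResponseCategory:
    """Map a dopamine-normalized response to its response group.

    Group I >= 1.00; group II in [0.75, 1.00); group III in [0.15, 0.50];
    group IV < 0.10.  The intervals (0.10, 0.15) and (0.50, 0.75) are not
    covered by any group definition and map to ``UNASSIGNED`` so the
    ambiguity stays visible downstream.
    """
    if not math.isfinite(normalized):
        raise ValueError(f"normalized response must be finite, got {normalized}")
    if normalized >= 1.00:
        return ResponseCategory.I
    if normalized >= 0.75:
        return ResponseCategory.II
    if 0.15 <= normalized <= 0.50:
        return ResponseCategory.III
    if normalized < 0.10:
        return ResponseCategory.IV
    return ResponseCategory.UNASSIGNED


@dataclass
class PlateWell:
    """One well: a baseline read plus timed reads after analyte addition."""

    well_id: str
    analyte_id: str
    role: str  # sample | blank | reference
    baseline: EmissionSpectrum
    reads: dict[float, EmissionSpectrum] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.role not in ("sample", "blank", "reference"):
            raise ValueError(f"unknown well role {self.role!r}")
        for t in self.reads:
            if t < 0:
                raise ValueError(f"negative timepoint {t} in well {self.well_id}")


@dataclass
class ResponseRecord:
    """Per-analyte optical response aggregated over replicate wells."""

    analyte_id: str
    F0: float
    F: float
    dff: float
    dff_peak94: float | None = None
    normalized: float | None = None
    n_replicates: int = 1
    sd: float = float("nan")
    category: ResponseCategory | None = None


def normalize_to_reference(
    records: list[ResponseRecord],
    reference_id: str,
    use_peak: bool = False,
) -> list[ResponseRecord]:
    """Divide each record's dF/F by the reference analyte's dF/F.

    The reference (dopamine on a matched plate) ends up at exactly 1.0.
    """
    by_id = {r.analyte_id: r for r in records}
    if reference_id not in by_id:
        raise ValueError(f"reference analyte {reference_id!r} not present")

    def response_of(r: ResponseRecord) -> float:
        if use_peak:
            if r.dff_peak94 is None:
                raise ValueError(f"no (9,4) peak response for {r.analyte_id!r}")
            return r.dff_peak94
        return r.dff

    ref = response_of(by_id[reference_id])
    if ref == 0:
        raise ValueError(f"reference {reference_id!r} has zero dF/F; cannot normalize")
    for r in records:
        r.normalized = 1.0 if r.analyte_id == reference_id else response_of(r) / ref
        r.category = classify_response(r.normalized)
    return records


# ---------------------------------------------------------------------------
# Plate CSV ingestion
# ---------------------------------------------------------------------------

def load_plate(
    plate_csv,
    map_csv,
    baseline_timepoint: float = 0.0,
) -> list[PlateWell]:
    """Read a long-format plate CSV plus a plate map into PlateWell objects.

    The plate CSV has columns well_id, timepoint_min, wavelength_nm,
    intensity; the map CSV has well_id, analyte_id, role.  The read at
    ``baseline_timepoint`` (default 0 min) is the F0 baseline.
    """
    plate = pd.read_csv(plate_csv)
    pmap = pd.read_csv(map_csv).set_index("well_id")
    required = {"well_id", "timepoint_min", "wavelength_nm", "intensity"}
    missing = required - set(plate.columns)
    if missing:
        raise ValueError(f"plate CSV missing columns: {sorted(missing)}")

    wells: list[PlateWell] = []
    for well_id, wdf in plate.groupby("well_id", sort=True):
        if well_id not in pmap.index:
            raise ValueError(f"well {well_id!r} absent from plate map")
        reads: dict[float, EmissionSpectrum] = {}
        baseline = None
        for t, tdf in wdf.groupby("timepoint_min"):
            tdf = tdf.sort_values("wavelength_nm")
            spec = EmissionSpectrum(
                tdf["wavelength_nm"].to_numpy(), tdf["intensity"].to_numpy()
            )
            if t == baseline_timepoint:
                baseline = spec
            else:
                reads[float(t)] = spec
        if baseline is None:
            raise ValueError(
                f"well {well_id!r} lacks a baseline read at t = {baseline_timepoint} min"
            )
        wells.append(
            PlateWell(
                well_id=str(well_id),
                analyte_id=str(pmap.loc[well_id, "analyte_id"]),
                role=str(pmap.loc[well_id, "role"]),
                baseline=baseline,
                reads=reads,
            )
        )
    return wells


def _mean_blank(wells: list[PlateWell], timepoint: float) -> tuple[EmissionSpectrum, EmissionSpectrum] | None:
    """Average blank baseline and timed-read spectra, or None if no blanks."""
    blanks = [w for w in wells if w.role == "blank"]
    if not blanks:
        return None
    base = blanks[0].baseline
    b0 = np.mean([w.baseline.intensity for w in blanks], axis=0)
    bt = np.mean([w.reads[timepoint].intensity for w in blanks], axis=0)
    return (
        EmissionSpectrum(base.wavelength, b0),
        EmissionSpectrum(base.wavelength, bt),
    )


def process_plate(
    wells: list[PlateWell],
    reference_id: str = "DA",
    timepoint: float = 30.0,
    peak_window: tuple[float, float] | None = None,
    normalization: str = "mean_dff",
) -> list[ResponseRecord]:
    """Full plate pipeline: blank subtraction, integration, dF/F, normalization.

    ``normalization`` selects replicate aggregation: ``mean_dff`` (default)
    averages per-well dF/F before taking the ratio to the reference mean;
    ``ratio_of_means`` takes mean(F)/mean(F0) - 1 per analyte first.
    """
    if normalization not in ("mean_dff", "ratio_of_means"):
        raise ValueError(f"unknown normalization {normalization!r}")
    blank = _mean_blank(wells, timepoint)

    per_analyte: dict[str, list[tuple[float, float, float | None]]] = {}
    for w in wells:
        if w.role == "blank":
            continue
        if timepoint not in w.reads:
            raise ValueError(
                f"well {w.well_id!r} has no read at t = {timepoint} min "
                f"(available: {sorted(w.reads)})"
            )
        base, read = w.baseline, w.reads[timepoint]
        if blank is not None:
            base = subtract_blank(base, blank[0])
            read = subtract_blank(read, blank[1])
        F0 = integrate_spectrum(base)
        F = integrate_spectrum(read)
        peak = (
            extract_peak_response(base, read, peak_window)
            if peak_window is not None
            else None
        )
        per_analyte.setdefault(w.analyte_id, []).append((F0, F, peak))

    records: list[ResponseRecord] = []
    for analyte_id, rows in sorted(per_analyte.items()):
        F0s = np.array([r[0] for r in rows])
        Fs = np.array([r[1] for r in rows])
        dffs = np.array([compute_dff(f0, f) for f0, f in zip(F0s, Fs)])
        peaks = [r[2] for r in rows]
        if normalization == "mean_dff":
            dff = float(dffs.mean())
        else:
            dff = compute_dff(float(F0s.mean()), float(Fs.mean()))
        records.append(
            ResponseRecord(
                analyte_id=analyte_id,
                F0=float(F0s.mean()),
                F=float(Fs.mean()),
                dff=dff,
                dff_peak94=(
                    float(np.mean([p for p in peaks]))
                    if all(p is not None for p in peaks)
                    else None
                ),
                n_replicates=len(rows),
                sd=float(dffs.std(ddof=1)) if len(rows) > 1 else float("nan"),
            )
        )
    return normalize_to_reference(records, reference_id)


def responses_to_frame(records: list[ResponseRecord]) -> pd.DataFrame:
    """Tabulate response records in the output CSV schema."""
    return pd.DataFrame(
        {
            "analyte_id": [r.analyte_id for r in records],
            "F0": [r.F0 for r in records],
            "F": [r.F for r in records],
            "dff": [r.dff for r in records],
            "dff_peak94": [r.dff_peak94 for r in records],
            "normalized": [r.normalized for r in records],
            "category": [r.category.value if r.category else None for r in records],
            "n": [r.n_replicates for r in records],
            "sd": [r.sd for r in records],
        }
    )
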