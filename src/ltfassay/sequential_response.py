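"""Sequential-treatment (core needle biopsy) response pipeline.

Each well is its own control: the fold change of the cumulative-production
slope between the treatment and control phases quantifies response, banded
into increase / no change / decrease.  Includes replicate aggregation
(maximum fold change, any-replicate increase), cross-design concordance,
and a RECIST percent-change helper.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._errors import InvalidParameterError, UndefinedStatisticError
from .quantitation import (
    CENSOR_CAPPED_ULOQ,
    TIME_TOLERANCE_H,
    AnalytePanel,
    WellSeries,
    rate_of_change,
)

logger = logging.getLogger(__name__)

CLASS_INCREASE = "increase"
CLASS_NO_CHANGE = "no_change"
CLASS_DECREASE = "decrease"
CLASS_INDETERMINATE = "indeterminate"

#: fold-change bands: increase > 1.5, no change in [0.5, 1.5], decrease < 0.5
DEFAULT_BANDS = (0.5, 1.5)


@dataclass
class SlopeFC:
    """Per well x analyte slope fold-change record."""

    specimen_id: str
    well_id: str
    analyte: str
    control_slope: float | None
    treatment_slope: float | None
    fc: float | None
    fc_class: str


@dataclass
class ConcordanceRow:
    analyte: str
    n_pairs: int
    n_concordant: int
    percent_concordant: int  # nearest integer
    discordant: list[str]


def phase_slope(
    series: WellSeries,
    analyte: str,
    phase_label: str,
    tol_h: float = TIME_TOLERANCE_H,
    exclude_capped: bool = True,
) -> float:
    """OLS slope (pg/mL/h) of cumulative concentration within one phase.

    A sample belongs to the phase when its time lies inside the phase
    window with ``tol_h`` tolerance, so the boundary sample terminating
    the control window also initiates the treatment window.  ULOQ-capped
    samples are excluded (capping flattens slopes); fewer than two usable
    points raises :class:`UndefinedStatisticError`.
    """
    phase = series.phase(phase_label)
    in_phase = [
        s
        for s in series.analyte_samples(analyte)
        if phase.t_start_h - tol_h <= s.t_h <= phase.t_end_h + tol_h
    ]
    usable = in_phase
    if exclude_capped:
        usable = [s for s in in_phase if s.censor != CENSOR_CAPPED_ULOQ]
        if len(usable) < len(in_phase):
            logger.info(
                "phase_slope well=%s analyte=%s phase=%s excluded %d "
                "ULOQ-capped points",
                series.well_id, analyte, phase_label, len(in_phase) - len(usable),
            )
    if len(usable) < 2:
        raise UndefinedStatisticError(
            f"well {series.well_id}, analyte {analyte}, phase {phase_label}: "
            f"only {len(usable)} usable point(s)"
        )
    return rate_of_change([s.t_h for s in usable], [s.conc_pg_ml for s in usable])


def slope_fc(
    control_slope: float,
    treatment_slope: float,
    epsilon: float = 0.0,
) -> tuple[float | None, bool]:
    """Treatment/control slope fold change with a guarded division.

    Returns ``(fc, valid)``; when the control slope is at or below
    ``epsilon`` the result is ``(None, False)`` — flagged indeterminate,
    never a silent division.
    """
    if epsilon < 0:
        raise InvalidParameterError("epsilon must be >= 0")
    if control_slope is None or treatment_slope is None or control_slope <= epsilon:
        return None, False
    return treatment_slope / control_slope, True


def default_epsilon(lloq: float, phase_duration_h: float) -> float:
    """Control-slope floor: below LLOQ/duration the control rate is noise."""
    if phase_duration_h <= 0:
        raise InvalidParameterError("phase duration must be positive")
    return lloq / phase_duration_h


def classify_fc(fc: float | None, bands: tuple[float, float] = DEFAULT_BANDS) -> str:
    """Band a fold change: > upper -> increase, [lower, upper] -> no change,
    < lower -> decrease; ``None`` passes through as indeterminate."""
    lower, upper = bands
    if not (0 < lower < upper):
        raise InvalidParameterError(f"bad bands {bands}")
    if fc is None or not np.isfinite(fc):
        return CLASS_INDETERMINATE
    if fc > upper:
        return CLASS_INCREASE
    if fc < lower:
        return CLASS_DECREASE
    return CLASS_NO_CHANGE


def well_slope_fc(
    series: WellSeries,
    analyte: str,
    panel: AnalytePanel | None = None,
    control_label: str = "IgG",
    bands: tuple[float, float] = DEFAULT_BANDS,
    tol_h: float = TIME_TOLERANCE_H,
    epsilon: float | None = None,
) -> SlopeFC:
    """Full slope-FC record for one well and analyte.

    The control phase is the schedule entry labelled ``control_label``;
    the treatment phase is the following entry.  ``epsilon`` defaults to
    LLOQ / control-phase duration when a panel is supplied, else 0.
    Undefined slopes yield an indeterminate record instead of raising.
    """
    control_phase = series.phase(control_label)
    later = [p for p in series.schedule if p.t_start_h >= control_phase.t_end_h]
    if not later:
        raise InvalidParameterError(
            f"well {series.well_id}: no treatment phase after {control_label!r}"
        )
    treatment_label = later[0].treatment
    if epsilon is None:
        epsilon = (
            default_epsilon(panel[analyte].lloq, control_phase.duration_h)
            if panel is not None
            else 0.0
        )
    try:
        c = phase_slope(series, analyte, control_label, tol_h)
        t = phase_slope(series, analyte, treatment_label, tol_h)
    except UndefinedStatisticError as exc:
        logger.info("well_slope_fc indeterminate: %s", exc)
        return SlopeFC(
            series.specimen_id, series.well_id, analyte, None, None, None,
            CLASS_INDETERMINATE,
        )
    fc, valid = slope_fc(c, t, epsilon)
    return SlopeFC(
        series.specimen_id, series.well_id, analyte, c, t, fc,
        classify_fc(fc, bands) if valid else CLASS_INDETERMINATE,
    )


def aggregate_replicates(results: list[SlopeFC]) -> dict:
    """Specimen/analyte-level aggregation over replicate wells.

    Reports the maximum valid fold change and whether any replicate was
    classified as an increase; all-indeterminate replicates flag the
    specimen as unevaluable.
    """
    if not results:
        raise InvalidParameterError("no replicate results supplied")
    valid = [r for r in results if r.fc is not None]
    if not valid:
        return {
            "max_fc": None,
            "any_increase": False,
            "unevaluable": True,
            "n_replicates": len(results),
            "n_valid": 0,
        }
    return {
        "max_fc": max(r.fc for r in valid),
        "any_increase": any(r.fc_class == CLASS_INCREASE for r in valid),
        "unevaluable": False,
        "n_replicates": len(results),
        "n_valid": len(valid),
    }


def concordance(
    crosswell_classes: pd.DataFrame,
    sequential_classes: pd.DataFrame,
) -> pd.DataFrame:
    """Per-analyte class concordance between the two designs.

    Inputs are specimen x analyte class-label frames; specimens present in
    both (with non-missing, determinate classes) are compared per analyte.
    Percent concordance is rounded to the nearest integer.
    """
    shared_specimens = crosswell_classes.index.intersection(sequential_classes.index)
    shared_analytes = crosswell_classes.columns.intersection(sequential_classes.columns)
    rows = []
    for analyte in shared_analytes:
        pairs = []
        for sp in shared_specimens:
            a = crosswell_classes.at[sp, analyte]
            b = sequential_classes.at[sp, analyte]
            if (
                pd.isna(a) or pd.isna(b)
                or CLASS_INDETERMINATE in (a, b)
            ):
                continue
            pairs.append((sp, a, b))
        if not pairs:
            continue
        matches = [sp for sp, a, b in pairs if a == b]
        rows.append(
            ConcordanceRow(
                analyte=analyte,
                n_pairs=len(pairs),
                n_concordant=len(matches),
                percent_concordant=int(round(100.0 * len(matches) / len(pairs))),
                discordant=[sp for sp, a, b in pairs if a != b],
            )
        )
    if not rows:
        raise InvalidParameterError("no comparable specimen/analyte pairs")
    return pd.DataFrame([vars(r) for r in rows])


def recist_percent_change(baseline_mm: float, followup_mm: float) -> dict:
    """Percent change in lesion diameter and the partial-response flag.

    Partial response requires a reduction greater than 30% of baseline.
    """
    if baseline_mm <= 0:
        raise InvalidParameterError("baseline diameter must be positive")
    if followup_mm < 0:
        raise InvalidParameterError("follow-up diameter must be >= 0")
    pct = 100.0 * (followup_mm - baseline_mm) / baseline_mm
    return {"percent_change": pct, "partial_response": pct < -30.0}
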