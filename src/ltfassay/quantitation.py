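"""Assay-level preprocessing and QC of multiplex secretome measurements.

Defines the analyte panel (quantitation limits, exclusion status) and the
per-well measurement series, plus censoring, panel-coverage, replicate
variability, and rate-of-change operations.

Units are fixed package-wide: concentrations in pg/mL, time in hours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._errors import InvalidParameterError, UndefinedStatisticError

logger = logging.getLogger(__name__)

#: censor flag vocabulary
CENSOR_NONE = "none"
CENSOR_BELOW_LLOQ = "below_lloq"
CENSOR_CAPPED_ULOQ = "capped_uloq"
CENSOR_LEVELS = (CENSOR_NONE, CENSOR_BELOW_LLOQ, CENSOR_CAPPED_ULOQ)

#: default tolerance (h) when matching a nominal time point against the
#: approximate ~4/~20/~48 h sampling grid
TIME_TOLERANCE_H = 2.0


@dataclass(frozen=True)
class AnalyteSpec:
    """Quantitation limits and exclusion status for one analyte."""

    name: str
    lloq: float
    uloq: float
    excluded: bool = False
    exclusion_reason: str = ""

    def __post_init__(self):
        if not (0 < self.lloq < self.uloq):
            raise InvalidParameterError(
                f"analyte {self.name!r}: require 0 < lloq < uloq, "
                f"got lloq={self.lloq}, uloq={self.uloq}"
            )


@dataclass
class AnalytePanel:
    """An ordered collection of :class:`AnalyteSpec` with unique names."""

    analytes: list[AnalyteSpec]

    def __post_init__(self):
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InvalidParameterError(f"duplicate analyte names: {dupes}")

    def __len__(self) -> int:
        return len(self.analytes)

    def __contains__(self, name: str) -> bool:
        return any(a.name == name for a in self.analytes)

    def __getitem__(self, name: str) -> AnalyteSpec:
        for a in self.analytes:
            if a.name == name:
                return a
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    @property
    def active_names(self) -> list[str]:
        """Names of analytes not flagged as excluded."""
        return [a.name for a in self.analytes if not a.excluded]

    def with_exclusions(self, excluded: dict[str, str]) -> "AnalytePanel":
        """Return a copy with the given ``{name: reason}`` marked excluded."""
        out = []
        for a in self.analytes:
            if a.name in excluded:
                out.append(replace(a, excluded=True, exclusion_reason=excluded[a.name]))
            else:
                out.append(a)
        return AnalytePanel(out)

    def to_dict(self) -> dict:
        return {
            "analytes": [
                {
                    "name": a.name,
                    "lloq": a.lloq,
                    "uloq": a.uloq,
                    "excluded": a.excluded,
                    "exclusion_reason": a.exclusion_reason,
                }
                for a in self.analytes
            ]
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnalytePanel":
        return cls([AnalyteSpec(**a) for a in d["analytes"]])


# 30-plex secretome panel used as the package default.  Limits are generic
# placeholders (real kits publish per-lot limits); the six analytes flagged
# here are routinely undetectable in conditioned media and ship pre-excluded.
_DEFAULT_LOW_ANALYTES = ("CD40L", "EGF", "FGF basic", "IL-12p70", "IL-15", "FLT-3L")
_DEFAULT_PANEL_NAMES = (
    "CCL2", "CCL3", "CCL4", "CCL5", "CD40L", "CXCL9", "CXCL10", "EGF",
    "FGF basic", "FLT-3L", "G-CSF", "GM-CSF", "Granzyme B", "IFNg", "IL-1b",
    "IL-1Ra", "IL-2", "IL-4", "IL-6", "IL-7", "IL-8", "IL-10", "IL-12p70",
    "IL-13", "IL-15", "IL-17A", "PD-L1", "TNFa", "TRAIL", "VEGF",
)


def default_panel(lloq: float = 10.0, uloq: float = 10000.0,
                  mark_low_excluded: bool = False) -> AnalytePanel:
    """Build the default 30-analyte panel with uniform quantitation limits.

    Parameters
    ----------
    mark_low_excluded:
        If True, pre-mark the six habitually-undetectable analytes as
        excluded (otherwise exclusion is derived from data by
        :func:`exclude_low_analytes`).
    """
    analytes = [
        AnalyteSpec(
            name=n,
            lloq=lloq,
            uloq=uloq,
            excluded=mark_low_excluded and n in _DEFAULT_LOW_ANALYTES,
            exclusion_reason=(
                "consistently below LLOQ"
                if mark_low_excluded and n in _DEFAULT_LOW_ANALYTES
                else ""
            ),
        )
        for n in _DEFAULT_PANEL_NAMES
    ]
    return AnalytePanel(analytes)


@dataclass(frozen=True)
class Phase:
    """One contiguous treatment interval of a well's schedule."""

    t_start_h: float
    t_end_h: float
    treatment: str

    def __post_init__(self):
        if not self.t_end_h > self.t_start_h:
            raise InvalidParameterError(
                f"phase {self.treatment!r}: t_end_h ({self.t_end_h}) must exceed "
                f"t_start_h ({self.t_start_h})"
            )

    @property
    def duration_h(self) -> float:
        return self.t_end_h - self.t_start_h


@dataclass(frozen=True)
class Sample:
    """A single measured concentration at one time point."""

    t_h: float
    analyte: str
    conc_pg_ml: float
    censor: str = CENSOR_NONE

    def __post_init__(self):
        if self.conc_pg_ml < 0:
            raise InvalidParameterError(
                f"negative concentration {self.conc_pg_ml} for {self.analyte}"
            )
        if self.censor not in CENSOR_LEVELS:
            raise InvalidParameterError(f"unknown censor flag {self.censor!r}")


@dataclass
class WellSeries:
    """One culture well: treatment schedule plus time-stamped measurements."""

    specimen_id: str
    well_id: str
    design: str  # "crosswell" | "sequential"
    schedule: list[Phase]
    samples: list[Sample] = field(default_factory=list)

    def __post_init__(self):
        if self.design not in ("crosswell", "sequential"):
            raise InvalidParameterError(f"unknown design {self.design!r}")
        phases = sorted(self.schedule, key=lambda p: p.t_start_h)
        for a, b in zip(phases, phases[1:]):
            if not math.isclose(a.t_end_h, b.t_start_h, abs_tol=1e-9):
                raise InvalidParameterError(
                    f"well {self.well_id}: schedule gap/overlap between "
                    f"{a.treatment} (ends {a.t_end_h}) and {b.treatment} "
                    f"(starts {b.t_start_h})"
                )
        self.schedule = phases
        for analyte in {s.analyte for s in self.samples}:
            ts = [s.t_h for s in self.samples if s.analyte == analyte]
            if len(ts) != len(set(ts)):
                raise InvalidParameterError(
                    f"well {self.well_id}: duplicate time points for {analyte}"
                )

    @property
    def analytes(self) -> list[str]:
        return sorted({s.analyte for s in self.samples})

    @property
    def treatments(self) -> list[str]:
        return [p.treatment for p in self.schedule]

    def analyte_samples(self, analyte: str) -> list[Sample]:
        """Samples for one analyte, sorted by time."""
        return sorted(
            (s for s in self.samples if s.analyte == analyte), key=lambda s: s.t_h
        )

    def phase(self, treatment: str) -> Phase:
        for p in self.schedule:
            if p.treatment == treatment:
                return p
        raise KeyError(
            f"well {self.well_id}: no phase {treatment!r} in schedule "
            f"{self.treatments}"
        )

    def sample_at(self, analyte: str, t_h: float,
                  tol_h: float = TIME_TOLERANCE_H) -> Sample | None:
        """The sample for ``analyte`` nearest ``t_h`` within ``tol_h``, or None."""
        cands = [s for s in self.analyte_samples(analyte) if abs(s.t_h - t_h) <= tol_h]
        if not cands:
            return None
        return min(cands, key=lambda s: abs(s.t_h - t_h))


def apply_censoring(series: WellSeries, panel: AnalytePanel) -> WellSeries:
    """Apply LLOQ/ULOQ censoring rules to every sample of a well.

    Values above ULOQ are set to the ULOQ and flagged ``capped_uloq``.
    Values below LLOQ keep their numeric value but are flagged
    ``below_lloq``.  Idempotent: flags are sticky and capped values sit
    exactly at the ULOQ, so a second application is a no-op.
    """
    unknown = sorted({s.analyte for s in series.samples} - set(panel.names))
    if unknown:
        raise InvalidParameterError(
            f"well {series.well_id}: analytes not in panel: {unknown}"
        )
    out: list[Sample] = []
    n_capped = n_low = 0
    for s in series.samples:
        spec = panel[s.analyte]
        if s.conc_pg_ml > spec.uloq:
            out.append(replace(s, conc_pg_ml=spec.uloq, censor=CENSOR_CAPPED_ULOQ))
            n_capped += 1
        elif s.censor == CENSOR_CAPPED_ULOQ and s.conc_pg_ml == spec.uloq:
            out.append(s)  # sticky flag: already capped in a previous pass
        elif s.conc_pg_ml < spec.lloq:
            out.append(replace(s, censor=CENSOR_BELOW_LLOQ))
            n_low += 1
        else:
            out.append(replace(s, censor=CENSOR_NONE))
    if n_capped or n_low:
        logger.info(
            "censoring well=%s capped_uloq=%d below_lloq=%d",
            series.well_id, n_capped, n_low,
        )
    return WellSeries(
        specimen_id=series.specimen_id,
        well_id=series.well_id,
        design=series.design,
        schedule=list(series.schedule),
        samples=out,
    )


def exclude_low_analytes(
    wells: list[WellSeries],
    panel: AnalytePanel,
    frac_below_threshold: float = 0.95,
) -> AnalytePanel:
    """Mark analytes consistently below LLOQ across the cohort as excluded.

    An analyte is excluded when the fraction of its measurements falling
    below the LLOQ is >= ``frac_below_threshold`` over all supplied wells.
    """
    if not (0 < frac_below_threshold <= 1):
        raise InvalidParameterError(
            f"frac_below_threshold must be in (0, 1], got {frac_below_threshold}"
        )
    if not wells:
        raise InvalidParameterError("no wells supplied")
    below: dict[str, int] = {}
    total: dict[str, int] = {}
    for w in wells:
        for s in w.samples:
            total[s.analyte] = total.get(s.analyte, 0) + 1
            if s.conc_pg_ml < panel[s.analyte].lloq:
                below[s.analyte] = below.get(s.analyte, 0) + 1
    exclusions = {}
    for name, n in total.items():
        frac = below.get(name, 0) / n
        if frac >= frac_below_threshold:
            exclusions[name] = f"below LLOQ in {frac:.0%} of {n} samples"
    if exclusions:
        logger.info("excluding analytes: %s", sorted(exclusions))
    return panel.with_exclusions(exclusions)


def pct_above_lloq(
    wells: list[WellSeries],
    panel: AnalytePanel,
    mode: str = "endpoint",
) -> float:
    """Percentage of non-excluded panel analytes detected above LLOQ.

    ``mode="endpoint"`` (default) counts an analyte as detected when its
    final-time-point measurement in at least one well is at or above LLOQ;
    ``mode="any"`` accepts any time point.
    """
    if mode not in ("endpoint", "any"):
        raise InvalidParameterError(f"unknown mode {mode!r}")
    if not wells:
        raise InvalidParameterError("no wells supplied")
    active = panel.active_names
    if not active:
        raise InvalidParameterError("panel has no non-excluded analytes")
    detected: set[str] = set()
    for w in wells:
        for analyte in w.analytes:
            if analyte not in active:
                continue
            samples = w.analyte_samples(analyte)
            if mode == "endpoint":
                samples = samples[-1:]
            if any(s.conc_pg_ml >= panel[analyte].lloq for s in samples):
                detected.add(analyte)
    return 100.0 * len(detected) / len(active)


def replicate_cv(
    wells: list[WellSeries],
    analyte: str,
    t_h: float,
    tol_h: float = TIME_TOLERANCE_H,
    drop_below_lloq: bool = True,
) -> float:
    """Coefficient of variation (%) across replicate wells at one time point.

    Below-LLOQ values are excluded (with a logged note) by default.  Raises
    :class:`UndefinedStatisticError` when fewer than two usable values
    remain or the mean is zero — never a silent zero.
    """
    values = []
    n_dropped = 0
    for w in wells:
        s = w.sample_at(analyte, t_h, tol_h)
        if s is None:
            continue
        if drop_below_lloq and s.censor == CENSOR_BELOW_LLOQ:
            n_dropped += 1
            continue
        values.append(s.conc_pg_ml)
    if n_dropped:
        logger.info(
            "replicate_cv analyte=%s t=%sh dropped %d below-LLOQ values",
            analyte, t_h, n_dropped,
        )
    if len(values) < 2:
        raise UndefinedStatisticError(
            f"CV undefined for {analyte} at {t_h} h: only {len(values)} usable "
            f"replicate value(s)"
        )
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        raise UndefinedStatisticError(f"CV undefined for {analyte}: zero mean")
    return float(100.0 * arr.std(ddof=1) / mean)


def rate_of_change(times_h, values) -> float:
    """Ordinary least-squares slope of ``values`` against ``times_h``.

    With exactly two points this equals the difference quotient.
    """
    t = np.asarray(times_h, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise InvalidParameterError("times and values must be 1-D and equal length")
    if t.size < 2:
        raise InvalidParameterError("need at least 2 points for a slope")
    if len(np.unique(t)) != t.size:
        raise InvalidParameterError(f"duplicate time points in {t.tolist()}")
    tc = t - t.mean()
    return float(np.dot(tc, y - y.mean()) / np.dot(tc, tc))
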