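"""Synthetic data generators with known ground truth.

Provides (1) spatial cell maps (homogeneous Poisson or Thomas cluster
process) standing in for a stained tumor cross-section, (2) specimen
cohorts with biomarker status and hidden responder flags, and (3)
longitudinal cumulative-cytokine well series for both the cross-well and
sequential treatment designs, with two-level lognormal noise and
LLOQ/ULOQ censoring.

RNG contract: every generator takes one root seed; child streams are
spawned deterministically per specimen / well via ``numpy``'s
``SeedSequence`` so outputs are reproducible and order-independent.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

from ._errors import InvalidParameterError
from .crosswell_response import SpecimenRecord
from .quantitation import AnalytePanel, Phase, Sample, WellSeries, apply_censoring

MARKER_VOCABULARY = ("CD3+",)

#: reference fragment count for the well-to-well CV scaling law
REFERENCE_LTF_COUNT = 200

_TUMOR_TYPES = ("melanoma", "lung", "colorectal", "ovarian", "head and neck", "kidney")


@dataclass
class CellMap:
    """A 2-D marked point set plus a binary tissue mask.

    Coordinates are continuous micrometres with the origin at the map's
    lower-left corner; the mask raster uses half-open pixel intervals of
    ``mask_resolution_um`` micrometres and is indexed ``mask[iy, ix]``.
    """

    width_um: float
    height_um: float
    x_um: np.ndarray
    y_um: np.ndarray
    markers: np.ndarray
    mask: np.ndarray
    mask_resolution_um: float

    def __post_init__(self):
        if self.width_um <= 0 or self.height_um <= 0:
            raise InvalidParameterError("map extents must be positive")
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.markers = np.asarray(self.markers, dtype=object)
        if not (len(self.x_um) == len(self.y_um) == len(self.markers)):
            raise InvalidParameterError("point arrays must share length")
        inside = (
            (self.x_um >= 0) & (self.x_um <= self.width_um)
            & (self.y_um >= 0) & (self.y_um <= self.height_um)
        )
        if not np.all(inside):
            raise InvalidParameterError("points fall outside the map extent")

    @property
    def n_points(self) -> int:
        return len(self.x_um)

    @property
    def points(self) -> list[tuple[float, float, str]]:
        return list(zip(self.x_um.tolist(), self.y_um.tolist(), self.markers.tolist()))

    @property
    def tissue_area_mm2(self) -> float:
        return float(self.mask.sum()) * (self.mask_resolution_um / 1000.0) ** 2

    def mask_at(self, x_um: np.ndarray, y_um: np.ndarray) -> np.ndarray:
        """Vectorized mask lookup for point coordinates."""
        res = self.mask_resolution_um
        ny, nx = self.mask.shape
        ix = np.minimum((np.asarray(x_um) / res).astype(int), nx - 1)
        iy = np.minimum((np.asarray(y_um) / res).astype(int), ny - 1)
        return self.mask[iy, ix]


@dataclass(frozen=True)
class CohortSpec:
    """Ground-truth description of a synthetic specimen cohort."""

    n_specimens: int
    biomarker_positive_fraction: float
    responder_prob_given_positive: float
    responder_prob_given_negative: float
    responsive_analytes: tuple[str, ...]
    effect_theta: float
    seed: int = 0
    n_replicates: int = 3

    def __post_init__(self):
        for name in (
            "biomarker_positive_fraction",
            "responder_prob_given_positive",
            "responder_prob_given_negative",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise InvalidParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_specimens < 1:
            raise InvalidParameterError("n_specimens must be >= 1")
        if self.effect_theta < 0:
            raise InvalidParameterError("effect_theta must be >= 0")


@dataclass
class KineticsSpec:
    """Per-analyte accumulation rates, noise levels and sampling grid.

    ``baseline_rate`` is pg/mL/h per analyte at ``REFERENCE_LTF_COUNT``
    fragments per well; rates scale linearly with ``ltf_count``.
    ``well_cv_percent`` is the well-to-well lognormal CV at the reference
    fragment count and follows ``cv(n) = cv_ref * sqrt(ref / n)``.
    ``noise_on`` selects where measurement noise attaches: to each phase's
    accumulated increment (default — samples of an ongoing accumulation
    stay monotone) or to the sampled cumulative value.
    """

    baseline_rate: dict[str, float]
    well_cv_percent: float = 20.0
    measurement_cv_percent: float = 20.0
    timepoints_h: tuple[float, ...] = (4.0, 20.0, 48.0)
    schedule: tuple[tuple[float, float, str], ...] = (
        (0.0, 20.0, "IgG"),
        (20.0, 48.0, "ICI"),
    )
    ltf_count: int = REFERENCE_LTF_COUNT
    noise_on: str = "increment"

    def __post_init__(self):
        if any(r <= 0 for r in self.baseline_rate.values()):
            raise InvalidParameterError("baseline rates must be positive")
        tp = tuple(self.timepoints_h)
        if any(b <= a for a, b in zip(tp, tp[1:])):
            raise InvalidParameterError("timepoints must be strictly increasing")
        phases = sorted(self.schedule, key=lambda p: p[0])
        for (s0, e0, _), (s1, _, _) in zip(phases, phases[1:]):
            if abs(e0 - s1) > 1e-9:
                raise InvalidParameterError("schedule intervals must be contiguous")
        if self.noise_on not in ("increment", "cumulative"):
            raise InvalidParameterError(f"unknown noise_on {self.noise_on!r}")
        if self.ltf_count < 1:
            raise InvalidParameterError("ltf_count must be >= 1")

    @property
    def effective_well_cv_percent(self) -> float:
        return well_cv_for_count(
            self.ltf_count, self.well_cv_percent, REFERENCE_LTF_COUNT
        )


def well_cv_for_count(
    n_ltf: int, cv_ref_percent: float = 20.0, n_ref: int = REFERENCE_LTF_COUNT
) -> float:
    """Well-to-well CV as a function of fragment count: cv_ref * sqrt(n_ref/n).

    A square-root sampling law (variance shrinks with fragment count); the
    true dependence is an empirical question, so this default is overridable
    wherever it is consumed.
    """
    if n_ltf < 1:
        raise InvalidParameterError("fragment count must be >= 1")
    return cv_ref_percent * np.sqrt(n_ref / n_ltf)


def _lognormal_factor(rng: np.random.Generator, cv_percent: float, size=None):
    """Unit-mean multiplicative lognormal noise with the given CV."""
    if cv_percent <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = np.sqrt(np.log1p((cv_percent / 100.0) ** 2))
    return rng.lognormal(-sigma**2 / 2, sigma, size=size)


def gen_cellmap(
    width_um: float,
    height_um: float,
    process: str = "poisson",
    intensity_per_mm2: float = 1000.0,
    cluster_params: dict | None = None,
    seed: int = 0,
    mask: np.ndarray | None = None,
    mask_resolution_um: float = 10.0,
    marker: str = "CD3+",
) -> CellMap:
    """Simulate a marked point pattern on a rectangular tissue map.

    ``process="poisson"`` draws a homogeneous Poisson pattern;
    ``process="thomas"`` draws a Thomas cluster process (Poisson parents,
    Gaussian-displaced offspring) with ``cluster_params`` providing
    ``parent_rate`` (parents/mm^2) and ``sigma_um``.  The offspring mean is
    derived as ``intensity / parent_rate`` so the expected total count
    equals ``intensity_per_mm2 * tissue area`` for both processes.
    """
    if width_um <= 0 or height_um <= 0:
        raise InvalidParameterError("extents must be positive")
    if intensity_per_mm2 < 0:
        raise InvalidParameterError("intensity must be >= 0")
    if process not in ("poisson", "thomas"):
        raise InvalidParameterError(f"unknown process {process!r}")
    rng = np.random.default_rng(seed)
    if mask is None:
        nx = max(1, int(round(width_um / mask_resolution_um)))
        ny = max(1, int(round(height_um / mask_resolution_um)))
        mask = np.ones((ny, nx), dtype=bool)
    area_mm2 = width_um * height_um / 1e6

    if process == "poisson" or intensity_per_mm2 == 0:
        n = rng.poisson(intensity_per_mm2 * area_mm2)
        x = rng.uniform(0, width_um, n)
        y = rng.uniform(0, height_um, n)
    else:
        cp = dict(cluster_params or {})
        parent_rate = cp.get("parent_rate", 20.0)
        sigma_um = cp.get("sigma_um", 50.0)
        if parent_rate <= 0 or sigma_um <= 0:
            raise InvalidParameterError("thomas cluster params must be positive")
        mean_offspring = cp.get("mean_offspring", intensity_per_mm2 / parent_rate)
        if mean_offspring <= 0:
            raise InvalidParameterError("mean_offspring must be positive")
        # pad the window so clusters centred just outside still contribute
        pad = 4.0 * sigma_um
        pw, ph = width_um + 2 * pad, height_um + 2 * pad
        n_parents = rng.poisson(parent_rate * pw * ph / 1e6)
        px = rng.uniform(-pad, width_um + pad, n_parents)
        py = rng.uniform(-pad, height_um + pad, n_parents)
        n_off = rng.poisson(mean_offspring, n_parents)
        x = np.repeat(px, n_off) + rng.normal(0, sigma_um, int(n_off.sum()))
        y = np.repeat(py, n_off) + rng.normal(0, sigma_um, int(n_off.sum()))
        keep = (x >= 0) & (x <= width_um) & (y >= 0) & (y <= height_um)
        x, y = x[keep], y[keep]

    m = CellMap(
        width_um=width_um,
        height_um=height_um,
        x_um=x,
        y_um=y,
        markers=np.array([marker] * len(x), dtype=object),
        mask=mask,
        mask_resolution_um=mask_resolution_um,
    )
    keep = m.mask_at(m.x_um, m.y_um)  # thin to the tissue mask
    m.x_um, m.y_um, m.markers = m.x_um[keep], m.y_um[keep], m.markers[keep]
    return m


def gen_cohort(cohort: CohortSpec, panel: AnalytePanel) -> list[SpecimenRecord]:
    """Draw a specimen cohort with biomarker status and hidden responder flags."""
    if len(panel) == 0:
        raise InvalidParameterError("empty analyte panel")
    unknown = set(cohort.responsive_analytes) - set(panel.names)
    if unknown:
        raise InvalidParameterError(
            f"responsive analytes not in panel: {sorted(unknown)}"
        )
    root = np.random.SeedSequence(cohort.seed)
    children = root.spawn(cohort.n_specimens)
    records = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        positive = rng.random() < cohort.biomarker_positive_fraction
        p_resp = (
            cohort.responder_prob_given_positive
            if positive
            else cohort.responder_prob_given_negative
        )
        responder = rng.random() < p_resp
        records.append(
            SpecimenRecord(
                specimen_id=f"S{i + 1:03d}",
                tumor_type=_TUMOR_TYPES[i % len(_TUMOR_TYPES)],
                biomarker_status="positive" if positive else "negative",
                n_replicates=cohort.n_replicates,
                design="crosswell",
                truth={
                    "responder": bool(responder),
                    "effect_theta": cohort.effect_theta,
                    "responsive_analytes": list(cohort.responsive_analytes),
                },
            )
        )
    return records


def _simulate_well(
    specimen: SpecimenRecord,
    kinetics: KineticsSpec,
    panel: AnalytePanel,
    design: str,
    well_id: str,
    schedule: list[Phase],
    rng: np.random.Generator,
) -> WellSeries:
    theta = specimen.truth.get("effect_theta", 1.0)
    responsive = set(specimen.truth.get("responsive_analytes", ()))
    responder = specimen.truth.get("responder", False)
    scale = kinetics.ltf_count / REFERENCE_LTF_COUNT
    well_cv = kinetics.effective_well_cv_percent
    samples = []
    for analyte, base_rate in kinetics.baseline_rate.items():
        rate0 = base_rate * scale * _lognormal_factor(rng, well_cv)
        cumulative = 0.0
        prev_t = schedule[0].t_start_h
        for t in kinetics.timepoints_h:
            # integrate the phase-dependent rate over (prev_t, t]
            increment = 0.0
            for phase in schedule:
                lo = max(prev_t, phase.t_start_h)
                hi = min(t, phase.t_end_h)
                if hi <= lo:
                    continue
                boost = (
                    theta
                    if (
                        responder
                        and analyte in responsive
                        and phase.treatment != "IgG"
                    )
                    else 1.0
                )
                increment += rate0 * boost * (hi - lo)
            if kinetics.noise_on == "increment":
                cumulative += increment * _lognormal_factor(
                    rng, kinetics.measurement_cv_percent
                )
                observed = cumulative
            else:
                cumulative += increment
                observed = cumulative * _lognormal_factor(
                    rng, kinetics.measurement_cv_percent
                )
            samples.append(Sample(t_h=t, analyte=analyte, conc_pg_ml=observed))
            prev_t = t
    series = WellSeries(
        specimen_id=specimen.specimen_id,
        well_id=well_id,
        design=design,
        schedule=schedule,
        samples=samples,
    )
    return apply_censoring(series, panel)


def gen_well_series(
    specimen: SpecimenRecord,
    kinetics: KineticsSpec,
    panel: AnalytePanel,
    design: str = "sequential",
    seed: int = 0,
) -> list[WellSeries]:
    """Simulate the culture wells of one specimen.

    ``design="sequential"``: each replicate well follows ``kinetics.schedule``
    (control phase then treatment phase within the same well).
    ``design="crosswell"``: each replicate contributes one control well (IgG
    for the whole culture) and one treated well (the schedule's non-control
    label for the whole culture).
    """
    if design not in ("crosswell", "sequential"):
        raise InvalidParameterError(f"unknown design {design!r}")
    phases = [Phase(*p) for p in kinetics.schedule]
    t0, t1 = phases[0].t_start_h, phases[-1].t_end_h
    treatment_labels = [p.treatment for p in phases if p.treatment != "IgG"]
    treated_label = treatment_labels[0] if treatment_labels else "ICI"

    # crc32 keys the child stream to the specimen id reproducibly across runs
    root = np.random.SeedSequence(
        [seed, zlib.crc32(specimen.specimen_id.encode("utf-8"))]
    )
    wells: list[WellSeries] = []
    if design == "sequential":
        if len(phases) < 2:
            raise InvalidParameterError("sequential design needs >= 2 phases")
        children = root.spawn(specimen.n_replicates)
        for i, child in enumerate(children):
            wells.append(
                _simulate_well(
                    specimen, kinetics, panel, design,
                    f"{specimen.specimen_id}-seq{i + 1}", phases,
                    np.random.default_rng(child),
                )
            )
    else:
        children = root.spawn(2 * specimen.n_replicates)
        for i in range(specimen.n_replicates):
            wells.append(
                _simulate_well(
                    specimen, kinetics, panel, design,
                    f"{specimen.specimen_id}-ctrl{i + 1}",
                    [Phase(t0, t1, "IgG")],
                    np.random.default_rng(children[2 * i]),
                )
            )
            wells.append(
                _simulate_well(
                    specimen, kinetics, panel, design,
                    f"{specimen.specimen_id}-trt{i + 1}",
                    [Phase(t0, t1, treated_label)],
                    np.random.default_rng(children[2 * i + 1]),
                )
            )
    return wells


def default_kinetics(
    panel: AnalytePanel,
    rate_pg_ml_h: float = 30.0,
    dead_analytes: tuple[str, ...] = (),
    dead_rate_pg_ml_h: float = 0.05,
    **kwargs,
) -> KineticsSpec:
    """Convenience KineticsSpec: uniform baseline rates, optional dead analytes.

    ``dead_analytes`` accumulate so slowly they stay below any realistic
    LLOQ, emulating a panel subset that is consistently undetectable.
    """
    rates = {
        name: (dead_rate_pg_ml_h if name in dead_analytes else rate_pg_ml_h)
        for name in panel.names
    }
    return KineticsSpec(baseline_rate=rates, **kwargs)
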