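"""In silico tissue fragmentation and randomized pooling.

Cuts a :class:`~ltfassay.synthetic_data.CellMap` into slices or cuboid
fragments, pools fragments randomly into wells of matched total tissue
area, and quantifies the cross-pool coefficient of variation of marker
counts.  Also provides closed-form geometry calculators for cuboid
fragments and core-needle-biopsy slicing.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from shapely.geometry import box

from ._errors import InsufficientTissueError, InvalidParameterError
from .synthetic_data import CellMap

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FragmentationScheme:
    """How to cut a map: square cuboids of ``edge_um`` or parallel strips.

    Fragments whose tissue fraction falls below ``min_tissue_fraction`` are
    discarded at the cutting stage.  Strips run parallel to the y-axis by
    default (``orientation="y"``); anisotropic clustered tissue makes the
    orientation matter, hence the knob.
    """

    mode: str  # "slice" | "cuboid"
    edge_um: float | None = None
    slice_width_um: float | None = None
    min_tissue_fraction: float = 0.5
    orientation: str = "y"

    def __post_init__(self):
        if self.mode not in ("slice", "cuboid"):
            raise InvalidParameterError(f"unknown mode {self.mode!r}")
        size = self.edge_um if self.mode == "cuboid" else self.slice_width_um
        if size is None or size <= 0:
            raise InvalidParameterError(
                f"{self.mode} scheme requires a positive "
                f"{'edge_um' if self.mode == 'cuboid' else 'slice_width_um'}"
            )
        if not (0 <= self.min_tissue_fraction <= 1):
            raise InvalidParameterError("min_tissue_fraction must be in [0, 1]")
        if self.orientation not in ("x", "y"):
            raise InvalidParameterError("orientation must be 'x' or 'y'")


@dataclass
class Fragment:
    """One cut piece: its footprint, tissue content and marker counts."""

    polygon: object  # shapely Polygon (axis-aligned box)
    tissue_fraction: float
    marker_counts: dict[str, int] = field(default_factory=dict)

    @property
    def nominal_area_mm2(self) -> float:
        return self.polygon.area / 1e6

    @property
    def tissue_area_mm2(self) -> float:
        return self.tissue_fraction * self.nominal_area_mm2

    def count(self, marker: str) -> int:
        return self.marker_counts.get(marker, 0)


@dataclass
class PoolSamplingResult:
    """Randomized pooling outcome: per-pool marker counts and their CV."""

    scheme: FragmentationScheme
    n_pools: int
    pool_target_mm2: float
    per_pool_counts: list[int]
    cv_percent: float
    seed: int


@dataclass(frozen=True)
class CuboidGeometry:
    edge_um: float
    face_area_mm2: float
    volume_mm3: float


@dataclass(frozen=True)
class CnbGeometry:
    core_diameter_mm: float
    core_length_mm: float
    slice_thickness_um: float
    cut_angle_deg: float
    n_slices: int
    slice_area_mm2: float
    total_volume_mm3: float


def cut(cellmap: CellMap, scheme: FragmentationScheme) -> list[Fragment]:
    """Cut the map into a regular grid of cuboids or parallel strips.

    Fragments tile the map's bounding box; each point lands in exactly one
    fragment.  A fragment size exceeding the map extent degrades to a
    single fragment with a warning rather than an error.
    """
    if cellmap.mask.sum() == 0:
        raise InvalidParameterError("map has an empty tissue mask")
    w, h = cellmap.width_um, cellmap.height_um
    if scheme.mode == "cuboid":
        ex = ey = scheme.edge_um
    elif scheme.orientation == "y":  # strips parallel to the y-axis
        ex, ey = scheme.slice_width_um, h
    else:
        ex, ey = w, scheme.slice_width_um
    if ex > w and ey > h:
        warnings.warn(
            "fragment size exceeds map extent; returning a single fragment",
            stacklevel=2,
        )
    nx = max(1, math.ceil(w / ex))
    ny = max(1, math.ceil(h / ey))

    # integral image of the mask for O(1) per-fragment tissue area
    res = cellmap.mask_resolution_um
    ii = np.zeros((cellmap.mask.shape[0] + 1, cellmap.mask.shape[1] + 1), dtype=np.int64)
    ii[1:, 1:] = np.cumsum(np.cumsum(cellmap.mask, axis=0), axis=1)
    mny, mnx = cellmap.mask.shape

    def tissue_px(x0, x1, y0, y1):
        i0 = min(int(round(x0 / res)), mnx)
        i1 = min(int(round(x1 / res)), mnx)
        j0 = min(int(round(y0 / res)), mny)
        j1 = min(int(round(y1 / res)), mny)
        return ii[j1, i1] - ii[j0, i1] - ii[j1, i0] + ii[j0, i0]

    # assign every point to its grid cell in one vectorized pass
    gx = np.minimum((cellmap.x_um / ex).astype(int), nx - 1)
    gy = np.minimum((cellmap.y_um / ey).astype(int), ny - 1)
    cell_idx = gy * nx + gx
    labels = sorted(set(cellmap.markers.tolist()))
    counts_by_label = {
        lab: np.bincount(
            cell_idx[cellmap.markers == lab], minlength=nx * ny
        )
        for lab in labels
    }

    fragments: list[Fragment] = []
    n_discarded = 0
    px_per_full = (ex / res) * (ey / res)
    for j in range(ny):
        y0, y1 = j * ey, (j + 1) * ey
        for i in range(nx):
            x0, x1 = i * ex, (i + 1) * ex
            frac = tissue_px(x0, min(x1, w), y0, min(y1, h)) / px_per_full
            frac = min(1.0, frac)
            if frac < scheme.min_tissue_fraction:
                n_discarded += 1
                continue
            idx = j * nx + i
            fragments.append(
                Fragment(
                    polygon=box(x0, y0, x1, y1),
                    tissue_fraction=frac,
                    marker_counts={
                        lab: int(counts_by_label[lab][idx]) for lab in labels
                    },
                )
            )
    if n_discarded:
        logger.info(
            "cut: discarded %d fragments below min_tissue_fraction=%.2f",
            n_discarded, scheme.min_tissue_fraction,
        )
    return fragments


def pool_and_count(
    fragments: list[Fragment],
    pool_area_mm2: float,
    n_pools: int,
    marker: str = "CD3+",
    seed: int = 0,
    scheme: FragmentationScheme | None = None,
) -> PoolSamplingResult:
    """Randomly pool fragments (without replacement) and count a marker.

    Fragments are shuffled and greedily accumulated into pools until each
    pool's summed tissue area reaches ``pool_area_mm2``.  Raises
    :class:`InsufficientTissueError` (naming the achievable pool count)
    when the tissue runs out.
    """
    if n_pools < 2:
        raise InvalidParameterError("need at least 2 pools for a CV")
    if pool_area_mm2 <= 0:
        raise InvalidParameterError("pool_area_mm2 must be positive")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(fragments))
    pools: list[int] = []
    current_count, current_area = 0, 0.0
    for k in order:
        f = fragments[k]
        current_count += f.count(marker)
        current_area += f.tissue_area_mm2
        if current_area >= pool_area_mm2:
            pools.append(current_count)
            current_count, current_area = 0, 0.0
            if len(pools) == n_pools:
                break
    if len(pools) < n_pools:
        raise InsufficientTissueError(
            f"insufficient tissue: only {len(pools)} pools of "
            f"{pool_area_mm2} mm^2 achievable (requested {n_pools})",
            achievable_pools=len(pools),
        )
    arr = np.asarray(pools, dtype=float)
    mean = arr.mean()
    cv = float(100.0 * arr.std(ddof=1) / mean) if mean > 0 else float("nan")
    return PoolSamplingResult(
        scheme=scheme,
        n_pools=n_pools,
        pool_target_mm2=pool_area_mm2,
        per_pool_counts=[int(c) for c in pools],
        cv_percent=cv,
        seed=seed,
    )


def cv_by_size(
    cellmap: CellMap,
    edge_list_um: list[float],
    pool_area_mm2: float,
    n_pools: int,
    n_randomizations: int = 20,
    seed: int = 0,
    marker: str = "CD3+",
    slice_width_um: float = 300.0,
    min_tissue_fraction: float = 0.0,
) -> pd.DataFrame:
    """CV distributions over randomized poolings, per fragment size.

    Cuts the map once per scheme (the slice baseline plus every edge
    length), repeats the randomized pooling ``n_randomizations`` times per
    scheme, and compares each edge's CV distribution against the slice
    baseline with a two-sided Mann-Whitney U test.
    """
    if len(edge_list_um) < 1:
        raise InvalidParameterError("need at least one edge length")
    if n_randomizations < 2:
        raise InvalidParameterError(
            "need >= 2 randomizations to form a CV distribution"
        )
    schemes = [
        ("slice", FragmentationScheme(
            mode="slice", slice_width_um=slice_width_um,
            min_tissue_fraction=min_tissue_fraction,
        )),
    ] + [
        (f"cuboid_{int(e)}um", FragmentationScheme(
            mode="cuboid", edge_um=e, min_tissue_fraction=min_tissue_fraction,
        ))
        for e in edge_list_um
    ]
    seeds = np.random.SeedSequence(seed).generate_state(n_randomizations)
    rows = []
    cv_store: dict[str, np.ndarray] = {}
    for label, scheme in schemes:
        fragments = cut(cellmap, scheme)
        cvs = np.array([
            pool_and_count(
                fragments, pool_area_mm2, n_pools, marker, int(s), scheme
            ).cv_percent
            for s in seeds
        ])
        cv_store[label] = cvs
        rows.append({
            "label": label,
            "mode": scheme.mode,
            "size_um": scheme.edge_um if scheme.mode == "cuboid" else slice_width_um,
            "median_cv_percent": float(np.median(cvs)),
            "cvs": cvs.tolist(),
        })
    baseline = cv_store["slice"]
    for row in rows:
        if row["label"] == "slice":
            row["p_vs_slice"] = float("nan")
        else:
            _, p = mannwhitneyu(
                cv_store[row["label"]], baseline, alternative="two-sided"
            )
            row["p_vs_slice"] = float(p)
    return pd.DataFrame(rows)


def cuboid_geometry(edge_um: float) -> CuboidGeometry:
    """Closed-form face area (mm^2) and volume (mm^3) of a cuboid fragment."""
    if edge_um <= 0:
        raise InvalidParameterError("edge must be positive")
    edge_mm = edge_um / 1000.0
    return CuboidGeometry(
        edge_um=edge_um, face_area_mm2=edge_mm**2, volume_mm3=edge_mm**3
    )


def cnb_geometry(
    core_diameter_mm: float,
    core_length_mm: float,
    slice_thickness_um: float,
    cut_angle_deg: float = 90.0,
) -> CnbGeometry:
    """Slice a cylindrical core-needle biopsy at a given angle.

    The core is modelled as a cylinder of the given diameter and length.
    At 90 degrees slices are circular discs; at angle theta the cross
    section is an ellipse with semi-axes d/2 and d/(2 sin theta) and each
    slice advances thickness/sin(theta) along the core axis, so fewer
    slices fit.  Slice volume is cross-section x axial advance, hence the
    total never exceeds the cylinder volume.
    """
    if not (0 < cut_angle_deg <= 90):
        raise InvalidParameterError("cut angle must be in (0, 90] degrees")
    if core_diameter_mm <= 0 or core_length_mm <= 0 or slice_thickness_um <= 0:
        raise InvalidParameterError("core dimensions must be positive")
    thickness_mm = slice_thickness_um / 1000.0
    if thickness_mm >= core_length_mm:
        raise InvalidParameterError("slice thickness must be below core length")
    sin_t = math.sin(math.radians(cut_angle_deg))
    axial_advance_mm = thickness_mm / sin_t
    n_slices = math.floor(core_length_mm / axial_advance_mm)
    slice_area_mm2 = math.pi * (core_diameter_mm / 2) * (core_diameter_mm / (2 * sin_t))
    total_volume_mm3 = n_slices * math.pi * (core_diameter_mm / 2) ** 2 * axial_advance_mm
    return CnbGeometry(
        core_diameter_mm=core_diameter_mm,
        core_length_mm=core_length_mm,
        slice_thickness_um=slice_thickness_um,
        cut_angle_deg=cut_angle_deg,
        n_slices=n_slices,
        slice_area_mm2=slice_area_mm2,
        total_volume_mm3=total_volume_mm3,
    )
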