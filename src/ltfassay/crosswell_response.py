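"""Cross-well (resection) response pipeline.

Per-specimen treated-vs-control cytokine differences are standardized per
analyte with a MAD-trimmed modified Z-score, saturated to +/-10, thresholded
into upregulation calls, clustered with Ward linkage, and tested for
enrichment against biomarker status.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.stats import fisher_exact, mannwhitneyu, ttest_ind

from ._errors import InvalidParameterError, UndefinedStatisticError
from .quantitation import TIME_TOLERANCE_H, AnalytePanel, WellSeries

logger = logging.getLogger(__name__)

BIOMARKER_LEVELS = ("positive", "negative", "unknown")

#: defaults of the modified-Z pipeline
TRIM_K = 2.0
SCALE_C = 0.6745
SATURATION = 10.0
UPREGULATION_THRESHOLD = 5.0

#: fallback scale factor when the trimmed MAD collapses to zero: the mean
#: absolute deviation is rescaled to be consistent for a normal sample
MEANAD_CONSISTENCY = 1.4826


@dataclass
class SpecimenRecord:
    """Metadata for one tumor specimen, plus optional simulation ground truth."""

    specimen_id: str
    tumor_type: str
    biomarker_status: str  # composite PD-L1 / MMR / MSI call
    n_replicates: int = 3
    design: str = "crosswell"
    truth: dict = field(default_factory=dict)  # generator-only: responder flag etc.

    def __post_init__(self):
        if self.biomarker_status not in BIOMARKER_LEVELS:
            raise InvalidParameterError(
                f"biomarker_status must be one of {BIOMARKER_LEVELS}, "
                f"got {self.biomarker_status!r}"
            )
        if self.n_replicates < 1:
            raise InvalidParameterError("n_replicates must be >= 1")


def cumulative_difference(
    wells: list[WellSeries],
    analyte: str,
    t_end_h: float,
    control_label: str = "IgG",
    tol_h: float = TIME_TOLERANCE_H,
) -> float:
    """Treated-minus-control difference in cumulative endpoint concentration.

    Wells whose schedule consists solely of ``control_label`` phases form
    the control arm; all other wells form the treated arm.  Returns
    mean(treated endpoint) - mean(control endpoint) in pg/mL.
    """
    control, treated = [], []
    for w in wells:
        arm = control if set(w.treatments) == {control_label} else treated
        s = w.sample_at(analyte, t_end_h, tol_h)
        if s is not None:
            arm.append(s.conc_pg_ml)
    if not control or not treated:
        raise InvalidParameterError(
            f"analyte {analyte}: need both arms at t={t_end_h} h "
            f"(control n={len(control)}, treated n={len(treated)})"
        )
    return float(np.mean(treated) - np.mean(control))


def mad_trimmed_modz(
    values,
    trim_k: float = TRIM_K,
    scale_c: float = SCALE_C,
    saturation: float = SATURATION,
) -> np.ndarray:
    """MAD-trimmed modified Z-scores, saturated to ``+/-saturation``.

    Steps: (1) median m and MAD of the input; (2) keep values within
    ``trim_k`` MADs of m; (3) recompute median m* and MAD* on the kept set;
    (4) z = scale_c * (x - m*) / MAD* for every input value; (5) clip to
    the saturation bounds.  NaNs pass through as NaN.

    When MAD* is zero the scale falls back to 1.4826 times the mean
    absolute deviation of the trimmed set; if that is also zero every
    score is 0 (degenerate spread).  Both fallbacks are logged.
    """
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise InvalidParameterError(
            f"need >= 3 finite values, got {int(finite.sum())}"
        )
    xf = x[finite]
    m = np.median(xf)
    mad = np.median(np.abs(xf - m))
    trimmed = xf[np.abs(xf - m) <= trim_k * mad]
    m_star = np.median(trimmed)
    mad_star = np.median(np.abs(trimmed - m_star))
    if mad_star == 0:
        mad_star = MEANAD_CONSISTENCY * np.mean(np.abs(trimmed - m_star))
        logger.info("mad_trimmed_modz: MAD*=0, falling back to scaled mean AD")
    z = np.full_like(x, np.nan)
    if mad_star == 0:
        logger.info("mad_trimmed_modz: degenerate spread, all scores set to 0")
        z[finite] = 0.0
    else:
        with np.errstate(over="ignore"):  # tiny MAD* saturates anyway
            z[finite] = scale_c * (xf - m_star) / mad_star
    return np.clip(z, -saturation, saturation)


def build_response_matrix(
    deltas: pd.DataFrame,
    axis: str = "analyte",
    trim_k: float = TRIM_K,
    scale_c: float = SCALE_C,
    saturation: float = SATURATION,
) -> pd.DataFrame:
    """Standardize a specimen x analyte delta table into modified Z-scores.

    ``axis="analyte"`` (default) scores each analyte across specimens —
    "upregulated relative to the cohort"; ``axis="specimen"`` scores each
    specimen across analytes.
    """
    if axis not in ("analyte", "specimen"):
        raise InvalidParameterError(f"axis must be 'analyte' or 'specimen', got {axis!r}")
    work = deltas if axis == "analyte" else deltas.T
    out = work.apply(
        lambda col: pd.Series(
            mad_trimmed_modz(col.to_numpy(), trim_k, scale_c, saturation),
            index=col.index,
        ),
        axis=0,
    )
    return out if axis == "analyte" else out.T


def call_upregulated(
    matrix: pd.DataFrame,
    threshold: float = UPREGULATION_THRESHOLD,
) -> tuple[pd.DataFrame, pd.Series]:
    """Threshold a response matrix into upregulation calls.

    Returns ``(calls, counts)``: a boolean matrix (z >= threshold, missing
    values are never called) and per-specimen call counts.
    """
    n_missing = int(matrix.isna().to_numpy().sum())
    if n_missing:
        logger.info("call_upregulated: %d missing values treated as not-called", n_missing)
    calls = matrix.ge(threshold).fillna(False)
    counts = calls.sum(axis=1)
    counts.name = "n_upregulated"
    return calls, counts


def ward_cluster(
    matrix: pd.DataFrame,
    max_missing_frac: float = 0.2,
) -> dict:
    """Ward-linkage clustering of specimens and analytes.

    Missing values are imputed with 0 (the "no change" score); rows or
    columns missing more than ``max_missing_frac`` of entries are an error.
    Returns leaf orders for heatmap rendering plus both linkage trees.
    """
    if matrix.empty:
        raise InvalidParameterError("empty response matrix")
    row_missing = matrix.isna().mean(axis=1)
    col_missing = matrix.isna().mean(axis=0)
    if (row_missing > max_missing_frac).any() or (col_missing > max_missing_frac).any():
        bad_rows = list(matrix.index[row_missing > max_missing_frac])
        bad_cols = list(matrix.columns[col_missing > max_missing_frac])
        raise InvalidParameterError(
            f"too many missing values for clustering: rows {bad_rows}, "
            f"columns {bad_cols}"
        )
    n_imputed = int(matrix.isna().to_numpy().sum())
    if n_imputed:
        logger.info("ward_cluster: imputed %d missing values with 0", n_imputed)
    # sort labels first so linkage tie-breaking is deterministic by label order
    mat = matrix.sort_index(axis=0).sort_index(axis=1).fillna(0.0)
    x = mat.to_numpy(dtype=float)
    specimen_linkage = linkage(x, method="ward")
    analyte_linkage = linkage(x.T, method="ward")
    return {
        "specimen_order": [mat.index[i] for i in leaves_list(specimen_linkage)],
        "analyte_order": [mat.columns[i] for i in leaves_list(analyte_linkage)],
        "specimen_linkage": specimen_linkage,
        "analyte_linkage": analyte_linkage,
        "n_imputed": n_imputed,
    }


def biomarker_enrichment(
    matrix: pd.DataFrame,
    calls: pd.DataFrame,
    statuses: pd.Series,
    threshold: float = UPREGULATION_THRESHOLD,
) -> dict:
    """Compare response between biomarker-positive and -negative specimens.

    Three views: (a) per-specimen upregulated-analyte counts compared by a
    two-sided Mann-Whitney U test; (b) per-analyte Z-scores compared
    likewise; (c) per-analyte 2x2 call-by-status tables tested with a
    two-sided Fisher exact test (odds ratios included).
    """
    statuses = pd.Series(statuses).reindex(matrix.index)
    pos = matrix.index[statuses == "positive"]
    neg = matrix.index[statuses == "negative"]
    if len(pos) < 2 or len(neg) < 2:
        raise InvalidParameterError(
            f"need >= 2 specimens per biomarker group, got positive={len(pos)}, "
            f"negative={len(neg)}"
        )
    counts = calls.sum(axis=1)
    u, p_counts = mannwhitneyu(
        counts.loc[pos], counts.loc[neg], alternative="two-sided"
    )
    per_analyte = []
    for analyte in matrix.columns:
        zp = matrix.loc[pos, analyte].dropna()
        zn = matrix.loc[neg, analyte].dropna()
        if len(zp) >= 2 and len(zn) >= 2 and not (
            np.all(zp.to_numpy() == zp.iloc[0]) and np.all(zn.to_numpy() == zn.iloc[0])
            and zp.iloc[0] == zn.iloc[0]
        ):
            _, p_mwu = mannwhitneyu(zp, zn, alternative="two-sided")
        else:
            p_mwu = 1.0
        a = int(calls.loc[pos, analyte].sum())
        b = len(pos) - a
        c = int(calls.loc[neg, analyte].sum())
        d = len(neg) - c
        odds, p_fisher = fisher_exact([[a, b], [c, d]], alternative="two-sided")
        per_analyte.append(
            {
                "analyte": analyte,
                "p_mwu": float(p_mwu),
                "p_fisher": float(p_fisher),
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "table": [[a, b], [c, d]],
            }
        )
    return {
        "count_comparison": {
            "p": float(p_counts),
            "statistic": float(u),
            "median_positive": float(counts.loc[pos].median()),
            "median_negative": float(counts.loc[neg].median()),
            "n_positive": int(len(pos)),
            "n_negative": int(len(neg)),
        },
        "per_analyte": per_analyte,
        "threshold": threshold,
    }


def detection_power(
    fold_change: float = 2.0,
    cv: float = 0.2,
    n_per_arm: int = 5,
    alpha: float = 0.05,
    n_sims: int = 1000,
    seed: int = 0,
) -> float:
    """Empirical power of a cross-well two-sample t-test for a fold change.

    Both arms are lognormal with the given coefficient of variation; the
    treated arm's mean is ``fold_change`` times the control mean.  Returns
    the fraction of ``n_sims`` simulations with two-sided p < alpha.
    """
    if n_per_arm < 2:
        raise InvalidParameterError("need >= 2 replicates per arm")
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(np.log1p(cv**2))
    mu_ctrl = -sigma**2 / 2  # unit-mean control arm
    ctrl = rng.lognormal(mu_ctrl, sigma, size=(n_sims, n_per_arm))
    trt = rng.lognormal(mu_ctrl + np.log(fold_change), sigma, size=(n_sims, n_per_arm))
    _, p = ttest_ind(trt, ctrl, axis=1)
    return float(np.mean(p < alpha))


def crosswell_deltas(
    wells_by_specimen: dict[str, list[WellSeries]],
    panel: AnalytePanel,
    t_end_h: float,
    control_label: str = "IgG",
) -> pd.DataFrame:
    """Assemble the specimen x analyte cumulative-difference table.

    Missing arms yield NaN (logged) rather than an error so a sparse cohort
    still produces a matrix.
    """
    analytes = panel.active_names
    rows = {}
    for specimen_id, wells in wells_by_specimen.items():
        row = {}
        for analyte in analytes:
            try:
                row[analyte] = cumulative_difference(
                    wells, analyte, t_end_h, control_label
                )
            except InvalidParameterError:
                logger.info(
                    "crosswell_deltas: missing arm for specimen=%s analyte=%s",
                    specimen_id, analyte,
                )
                row[analyte] = np.nan
        rows[specimen_id] = row
    if not rows:
        raise UndefinedStatisticError("no specimens supplied")
    return pd.DataFrame.from_dict(rows, orient="index").loc[:, analytes]
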