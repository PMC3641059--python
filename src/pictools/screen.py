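"""Per-strain statistical hit calling for the translocation PPI screen.

For every prey strain, normalized colocalization scores from the +rapamycin
fields are compared against the vehicle fields with a one-tailed
heteroscedastic (Welch) t-test; a strain is significant at p < 0.02,
equivalently log10(1/p) > 1.699. Because significance alone also passes
preys whose absolute recruitment is negligible, a secondary filter requires
the +RAP/−RAP colocalization ratio to exceed ``min_ratio``; a hit must pass
both. No multiple-testing correction is applied by default (the decision
rule thresholds raw p across the panel); Benjamini–Hochberg is available as
an option.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .coloc import ColocRecord, EmptyMaskError, colocalization_area, recruitment_ratio
from .config import PipelineConfig
from .imgproc import Field2C, local_threshold, subtract_background

__all__ = [
    "PreyResult",
    "DegenerateDataError",
    "welch_one_tailed",
    "call_hits",
    "process_field",
    "run_screen",
    "run_screen_fields",
    "simulate_null_pvalues",
    "SCREEN_COLUMNS",
]

logger = logging.getLogger(__name__)

SCREEN_COLUMNS = [
    "strain",
    "ratio",
    "t",
    "df",
    "p",
    "log10_inv_p",
    "significant",
    "negligible",
    "hit",
]


class DegenerateDataError(ValueError):
    """Raised when both groups have zero variance (t undefined)."""


@dataclass(frozen=True)
class PreyResult:
    """Hit-calling result for one prey strain."""

    strain: str
    ratio: float
    t_stat: float
    df: float
    p_one_tailed: float
    log_inv_p: float
    significant: bool
    negligible: bool
    hit: bool


def welch_one_tailed(
    x_plus: Sequence[float], x_minus: Sequence[float]
) -> tuple[float, float, float]:
    """One-tailed Welch t-test (alternative: mean(x_plus) > mean(x_minus)).

    Sample variances (n−1 denominators) and Welch–Satterthwaite degrees of
    freedom; returns (t, df, upper-tail p).
    """
    a = np.asarray(x_plus, dtype=float)
    b = np.asarray(x_minus, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("scores must be finite")
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if va == 0 and vb == 0:
        raise DegenerateDataError("both groups have zero variance")
    sa = va / a.size
    sb = vb / b.size
    t = (a.mean() - b.mean()) / math.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (sa**2 / (a.size - 1) + sb**2 / (b.size - 1))
    p = float(stats.t.sf(t, df))
    return float(t), float(df), p


def _welch_batch(x_plus: np.ndarray, x_minus: np.ndarray) -> np.ndarray:
    """Vectorized one-tailed Welch p-values, one test per row."""
    va = x_plus.var(axis=1, ddof=1)
    vb = x_minus.var(axis=1, ddof=1)
    sa = va / x_plus.shape[1]
    sb = vb / x_minus.shape[1]
    t = (x_plus.mean(axis=1) - x_minus.mean(axis=1)) / np.sqrt(sa + sb)
    df = (sa + sb) ** 2 / (
        sa**2 / (x_plus.shape[1] - 1) + sb**2 / (x_minus.shape[1] - 1)
    )
    return stats.t.sf(t, df)


def simulate_null_pvalues(
    n_preys: int,
    n_fields: int = 9,
    rng: np.random.Generator | None = None,
    mean: float = 0.1,
    sd: float = 0.03,
    sd_ratio_max: float = 3.0,
) -> np.ndarray:
    """One-tailed Welch p-values for simulated null preys (no recruitment).

    Each prey contributes two groups of ``n_fields`` per-field scores drawn
    from Gaussians with equal means; the vehicle-group standard deviation is
    scaled by a per-prey factor in [1, ``sd_ratio_max``] so the
    heteroscedastic case is exercised. Used for type-I-error calibration of
    the hit-calling rule.
    """
    rng = np.random.default_rng(rng)
    ratios = rng.uniform(1.0, sd_ratio_max, size=n_preys)
    x_plus = rng.normal(mean, sd, size=(n_preys, n_fields))
    x_minus = rng.normal(mean, sd * ratios[:, None], size=(n_preys, n_fields))
    return _welch_batch(x_plus, x_minus)


def call_hits(
    results: Iterable[tuple[str, float, float, float, float]],
    p_cut: float = 0.02,
    min_ratio: float = 2.0,
    bh_correct: bool = False,
) -> list[PreyResult]:
    """Apply the significance and negligible-recruitment filters.

    ``results`` yields (strain, ratio, t, df, p). A strain is significant
    when p < ``p_cut``; negligible when ratio < ``min_ratio`` (the
    quantitative surrogate for visual inspection of weak recruiters); a hit
    is significant and not negligible. With ``bh_correct`` the p-values are
    Benjamini–Hochberg adjusted before thresholding.
    """
    if not 0.0 < p_cut < 1.0:
        raise ValueError("p_cut must lie in (0, 1)")
    rows = list(results)
    pvals = np.array([r[4] for r in rows], dtype=float)
    p_eff = stats.false_discovery_control(pvals) if (bh_correct and len(rows)) else pvals
    out = []
    for (strain, ratio, t, df, p), pe in zip(rows, p_eff):
        significant = bool(pe < p_cut)
        negligible = bool(ratio < min_ratio)
        out.append(
            PreyResult(
                strain=strain,
                ratio=float(ratio),
                t_stat=float(t),
                df=float(df),
                p_one_tailed=float(p),
                log_inv_p=float(-np.log10(p)),
                significant=significant,
                negligible=negligible,
                hit=significant and not negligible,
            )
        )
    return out


def process_field(field: Field2C, params: PipelineConfig | None = None) -> ColocRecord:
    """Segment both channels of a field and measure colocalization.

    Rolling-ball background subtraction then local-mean thresholding is
    applied identically to both channels (pipeline defaults: ball radius
    115 px, threshold radius 5, offset 12).
    """
    params = params or PipelineConfig()
    red = subtract_background(field.red, params.bg_radius_px)
    green = subtract_background(field.green, params.bg_radius_px)
    red_mask = local_threshold(
        red, params.thr_radius_px, params.thr_offset, source_channel="red"
    )
    green_mask = local_threshold(
        green, params.thr_radius_px, params.thr_offset, source_channel="green"
    )
    return colocalization_area(
        green_mask,
        red_mask,
        strain=field.strain,
        condition=field.condition,
        field_index=field.field_index,
    )


def run_screen_fields(
    fields: Iterable[Field2C] | Iterator[Field2C],
    params: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the full screen on an iterable of fields (streaming).

    Fields are grouped by strain and condition, scored per field, tested per
    strain (+RAP vs −RAP Welch, one tail), and assembled into the screen
    table sorted by log10(1/p) descending. Strains missing a condition or
    with fewer than two usable fields per condition are skipped with a
    warning; a strain whose score variance is zero in both conditions is
    recorded with p = 1 (no evidence of recruitment).
    """
    params = params or PipelineConfig()
    by_strain: dict[str, dict[str, list[ColocRecord]]] = {}
    for fld in fields:
        try:
            rec = process_field(fld, params)
        except EmptyMaskError:
            logger.warning(
                "skipping field %s/%s/%d: empty red mask",
                fld.strain,
                fld.condition,
                fld.field_index,
            )
            continue
        by_strain.setdefault(fld.strain, {}).setdefault(fld.condition, []).append(rec)

    rows = []
    for strain in sorted(by_strain):
        groups = by_strain[strain]
        plus = groups.get("plusRAP", [])
        minus = groups.get("minusRAP", [])
        if len(plus) < 2 or len(minus) < 2:
            logger.warning("skipping strain %s: missing condition or <2 fields", strain)
            continue
        s_plus = [r.s for r in plus]
        s_minus = [r.s for r in minus]
        try:
            t, df, p = welch_one_tailed(s_plus, s_minus)
        except DegenerateDataError:
            logger.warning("strain %s: zero variance in both conditions; p set to 1", strain)
            t, df, p = 0.0, float(len(s_plus) + len(s_minus) - 2), 1.0
        ratio = recruitment_ratio(plus, minus, pseudocount=params.pseudocount).ratio
        rows.append((strain, ratio, t, df, p))

    results = call_hits(rows, p_cut=params.p_cut, min_ratio=params.min_ratio)
    table = pd.DataFrame(
        [
            (
                r.strain,
                r.ratio,
                r.t_stat,
                r.df,
                r.p_one_tailed,
                r.log_inv_p,
                r.significant,
                r.negligible,
                r.hit,
            )
            for r in results
        ],
        columns=SCREEN_COLUMNS,
    )
    return table.sort_values("log10_inv_p", ascending=False).reset_index(drop=True)


def run_screen(
    manifest: pd.DataFrame | str,
    params: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Run the screen from a plate manifest of per-field TIFF paths.

    The manifest (CSV path or DataFrame) must have columns strain,
    condition, field_index, red_path, green_path.
    """
    from .io import iter_manifest_fields, read_manifest

    if isinstance(manifest, str):
        manifest = read_manifest(manifest)
    return run_screen_fields(iter_manifest_fields(manifest), params)
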