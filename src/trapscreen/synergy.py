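"""Median-effect dose-response and combination-index analysis.

The median-effect equation relates dose D to fraction affected fa:

    fa / (1 - fa) = (D / Dm)^m

where Dm is the median-effect dose (the dose giving 50% effect; the IC50
under this model) and m the sigmoidicity slope. Taking logs makes the model
linear, so each single-drug series is fitted by ordinary least squares of
log10(fa/(1-fa)) on log10(D).

For a combination point (d1, d2) producing effect fa, the combination index
in the mutually exclusive form is

    CI = d1 / Dx1(fa) + d2 / Dx2(fa),    Dx_i(fa) = Dm_i (fa/(1-fa))^(1/m_i)

the sum of each administered dose relative to the dose of that drug alone
required for the same effect. CI < 1 indicates synergy, CI = 1 additivity
and CI > 1 antagonism. The normalized isobologram plots each point at
(d1/Dx1, d2/Dx2) against the additivity line x + y = 1.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("trapscreen")

#: fa exclusion window for fitting: the logit transform diverges at 0 and 1.
FA_MIN_DEFAULT = 0.005
FA_MAX_DEFAULT = 0.995

SIGNIFICANCE_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


@dataclass(frozen=True)
class MedianEffectFit:
    """Per-drug median-effect parameters from the log-linearized fit.

    ``r`` is the correlation coefficient of the linear regression;
    ``n_points`` the number of (dose, fa) pairs used after exclusion;
    ``n_excluded`` the number excluded for fa outside the usable window.
    ``valid`` is False when the fitted slope is non-positive, in which case
    dose extrapolation is meaningless.
    """

    m: float
    Dm: float
    r: float
    n_points: int
    n_excluded: int = 0
    valid: bool = True


@dataclass(frozen=True)
class CIResult:
    """Combination index at one measured combination point.

    ``dx1``/``dx2`` are the single-drug doses required for the observed
    effect ``fa``; ``ci = d1/dx1 + d2/dx2``; interpretation is the strict
    three-way rule (synergy below 1, additive at 1, antagonism above 1).
    """

    d1: float
    d2: float
    fa: float
    dx1: float
    dx2: float
    ci: float
    interpretation: str


def interpret_ci(ci: float) -> str:
    if ci < 1:
        return "synergy"
    if ci == 1:
        return "additive"
    return "antagonism"


# ---------------------------------------------------------------------------
# Plate normalization
# ---------------------------------------------------------------------------


def normalize_viability(
    plate: pd.DataFrame,
    vehicle: Sequence[float] | np.ndarray,
    blank: Sequence[float] | np.ndarray = (),
) -> pd.DataFrame:
    """Convert raw signal to percent viability and fraction affected.

    percent_viability = 100 (raw - mean blank) / (mean vehicle - mean blank);
    fa = 1 - percent_viability / 100 clipped to [0, 1] (clips are logged:
    signal above the vehicle mean, e.g. growth stimulation, clips fa to 0).
    ``plate`` needs a ``raw_signal`` column; other columns pass through.
    """
    vehicle = np.asarray(vehicle, dtype=float)
    if vehicle.size == 0:
        raise ValueError("at least one vehicle well is required")
    blank_mean = float(np.mean(blank)) if len(blank) else 0.0
    vehicle_mean = float(np.mean(vehicle))
    if vehicle_mean <= blank_mean:
        raise ValueError(
            f"uninterpretable plate: mean vehicle signal ({vehicle_mean}) does "
            f"not exceed mean blank ({blank_mean})"
        )
    out = plate.copy()
    pct = 100.0 * (out["raw_signal"] - blank_mean) / (vehicle_mean - blank_mean)
    out["percent_viability"] = pct
    fa = 1.0 - pct / 100.0
    n_clipped = int(((fa < 0) | (fa > 1)).sum())
    if n_clipped:
        logger.info("normalize_viability: clipped fa to [0, 1] for %d wells", n_clipped)
    out["fa"] = fa.clip(0.0, 1.0)
    return out


# ---------------------------------------------------------------------------
# Median-effect fit and derived doses
# ---------------------------------------------------------------------------


def fit_median_effect(
    points: Sequence[tuple[float, float]],
    fa_min: float = FA_MIN_DEFAULT,
    fa_max: float = FA_MAX_DEFAULT,
) -> MedianEffectFit:
    """OLS fit of the log-linearized median-effect equation.

    ``points`` are (dose µM, fraction affected) pairs; doses must be
    positive. Points with fa outside (fa_min, fa_max) are excluded and
    counted. m is the slope of log10(fa/(1-fa)) on log10(dose);
    Dm = 10^(-intercept/m). A non-positive slope yields ``valid=False`` with
    the diagnostics retained.
    """
    doses = np.array([p[0] for p in points], dtype=float)
    fas = np.array([p[1] for p in points], dtype=float)
    if np.any(doses <= 0):
        raise ValueError("all doses must be positive")
    usable = (fas > fa_min) & (fas < fa_max)
    n_excluded = int((~usable).sum())
    if usable.sum() < 2:
        raise ValueError(
            f"need at least 2 points with fa in ({fa_min}, {fa_max}); "
            f"have {int(usable.sum())} usable of {len(points)}"
        )
    x = np.log10(doses[usable])
    y = np.log10(fas[usable] / (1.0 - fas[usable]))
    if np.allclose(x, x[0]):
        raise ValueError("all usable doses identical; slope is undefined")
    res = stats.linregress(x, y)
    m = float(res.slope)
    if m <= 0:
        logger.warning(
            "fit_median_effect: non-positive slope %.4g (r=%.3f); fit flagged invalid",
            m,
            res.rvalue,
        )
        return MedianEffectFit(
            m=m, Dm=math.nan, r=float(res.rvalue), n_points=int(usable.sum()),
            n_excluded=n_excluded, valid=False,
        )
    Dm = float(10.0 ** (-res.intercept / m))
    return MedianEffectFit(
        m=m, Dm=Dm, r=float(res.rvalue), n_points=int(usable.sum()),
        n_excluded=n_excluded,
    )


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dose of a single drug producing fraction affected ``fa``:
    Dx = Dm (fa/(1-fa))^(1/m). Strictly increasing in fa for m > 0."""
    if not fit.valid:
        raise ValueError("invalid fit (non-positive slope)")
    if not 0.0 < fa < 1.0:
        raise ValueError(f"fa must lie strictly in (0, 1); got {fa}")
    return fit.Dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def combination_index(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    point: tuple[float, float, float],
) -> CIResult:
    """Combination index at a measured (d1, d2, fa) point, mutually
    exclusive form: CI = d1/Dx1(fa) + d2/Dx2(fa)."""
    d1, d2, fa = point
    if d1 < 0 or d2 < 0 or d1 + d2 <= 0:
        raise ValueError("need d1, d2 >= 0 with d1 + d2 > 0")
    dx1 = dose_for_effect(fit1, fa)
    dx2 = dose_for_effect(fit2, fa)
    ci = d1 / dx1 + d2 / dx2
    return CIResult(d1, d2, fa, dx1, dx2, ci, interpret_ci(ci))


def combination_indices(
    fit1: MedianEffectFit,
    fit2: MedianEffectFit,
    combo: pd.DataFrame,
    aggregate: bool = True,
) -> list[CIResult]:
    """CI per combination point of a long-format table with columns
    drug1_dose, drug2_dose, fa (and optionally replicate).

    With ``aggregate`` (default), fa is averaged across replicates per dose
    pair before computing one CI per pair; otherwise one CI is computed per
    replicate row, exposing the dispersion.
    """
    df = combo[(combo["drug1_dose"] > 0) | (combo["drug2_dose"] > 0)]
    if aggregate:
        df = (
            df.groupby(["drug1_dose", "drug2_dose"], as_index=False)["fa"].mean()
        )
    return [
        combination_index(fit1, fit2, (row.drug1_dose, row.drug2_dose, row.fa))
        for row in df.itertuples(index=False)
    ]


def normalized_isobologram(
    ci_results: Sequence[CIResult],
) -> list[tuple[float, float, float]]:
    """Normalized isobologram coordinates (d1/Dx1, d2/Dx2, fa) per point.

    x + y equals the combination index exactly; points under the diagonal
    x + y = 1 indicate synergy.
    """
    return [(r.d1 / r.dx1, r.d2 / r.dx2, r.fa) for r in ci_results]


# ---------------------------------------------------------------------------
# Replicate statistics
# ---------------------------------------------------------------------------


def significance_label(p: float) -> str:
    for threshold, label in SIGNIFICANCE_THRESHOLDS:
        if p < threshold:
            return label
    return ""


def paired_t_test(
    a: Sequence[float], b: Sequence[float]
) -> tuple[float, float, str]:
    """Classical paired t-test on the differences a - b.

    Returns (t, two-sided p, significance label) with labels '***', '**',
    '*' below 0.001, 0.01, 0.05. Degenerate zero-variance differences: a
    nonzero mean difference is reported as t = ±inf, p = 0; identical pairs
    as t = 0, p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValueError("need at least 2 pairs")
    diff = a - b
    if np.allclose(diff.std(ddof=1), 0.0):
        if np.allclose(diff.mean(), 0.0):
            return 0.0, 1.0, ""
        t = math.inf if diff.mean() > 0 else -math.inf
        return t, 0.0, significance_label(0.0)
    t, p = stats.ttest_rel(a, b)
    return float(t), float(p), significance_label(float(p))


def summarize_replicates(
    records: pd.DataFrame,
    value: str,
    by: Sequence[str],
) -> pd.DataFrame:
    """Mean and standard error (sd/sqrt(n), ddof=1) of ``value`` per
    condition defined by the ``by`` columns. With a single replicate the SE
    is reported as missing."""
    grouped = records.groupby(list(by))[value]
    out = grouped.agg(mean="mean", n="count")
    sd = grouped.std(ddof=1)
    out["se"] = sd / np.sqrt(out["n"])
    out.loc[out["n"] == 1, "se"] = np.nan
    return out.reset_index()


# ---------------------------------------------------------------------------
# Whole-plate analysis
# ---------------------------------------------------------------------------


def analyze_plate(
    plate: pd.DataFrame,
    fa_min: float = FA_MIN_DEFAULT,
    fa_max: float = FA_MAX_DEFAULT,
) -> dict:
    """Fit both single-drug series of a long-format combination plate and
    compute CI and isobologram coordinates for every combination point.

    ``plate`` columns: drug1_dose, drug2_dose, replicate, fa (use
    ``normalize_viability`` first when starting from raw signal). Single-drug
    rows have the other dose at zero. Returns a dict with ``fits`` (per
    drug), ``ci`` (mean-fa CI per dose pair), ``ci_per_replicate`` and
    ``isobologram``. An invalid fit leaves the CI tables empty with a
    prominent warning.
    """
    single1 = plate[(plate["drug1_dose"] > 0) & (plate["drug2_dose"] == 0)]
    single2 = plate[(plate["drug2_dose"] > 0) & (plate["drug1_dose"] == 0)]
    combo = plate[(plate["drug1_dose"] > 0) & (plate["drug2_dose"] > 0)]
    fit1 = fit_median_effect(
        list(zip(single1["drug1_dose"], single1["fa"])), fa_min, fa_max
    )
    fit2 = fit_median_effect(
        list(zip(single2["drug2_dose"], single2["fa"])), fa_min, fa_max
    )
    result: dict = {"fits": {"drug1": fit1, "drug2": fit2}}
    if not (fit1.valid and fit2.valid):
        logger.warning(
            "analyze_plate: invalid median-effect fit (non-positive slope); "
            "CI table left empty"
        )
        result.update(ci=[], ci_per_replicate=[], isobologram=[])
        return result
    ci = combination_indices(fit1, fit2, combo, aggregate=True) if len(combo) else []
    ci_rep = (
        combination_indices(fit1, fit2, combo, aggregate=False) if len(combo) else []
    )
    result["ci"] = ci
    result["ci_per_replicate"] = ci_rep
    result["isobologram"] = normalized_isobologram(ci)
    return result
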