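"""Median-effect drug-synergy quantification (Fa / CI / DRI).

The median-effect model links dose D to fraction affected fa:

    fa / (1 - fa) = (D / Dm)^m

with Dm the median-effect dose (EC50) and m the sigmoidicity slope.  Fitting
is ordinary least squares on the linearised form log10(fa/(1-fa)) vs
log10(D).  For a combination at effect fa the combination index in the
mutually exclusive (no cross-term) form is

    CI = sum_i D_i / Dx_i(fa),     Dx_i(fa) = Dm_i * (fa/(1-fa))^(1/m_i)

with CI < 1 synergy, = 1 Loewe additivity, > 1 antagonism, and the per-drug
dose-reduction index DRI_i = Dx_i / D_i.  Three-drug combinations treat a
fixed-ratio pair as a single entity (entity dose = sum of component doses),
fitted like a drug, combined with the third drug.  Potent synergy requires a
point with Fa > 0.7 and CI < 0.7 in every varied-drug orientation tested.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .containers import ComboPoint, MedianEffectFit, SynergyAssessment

__all__ = [
    "fa_growth",
    "clamp_fa",
    "fit_median_effect",
    "dose_for_effect",
    "effective_conc",
    "combination_index",
    "ci_from_equivalent_doses",
    "dose_reduction_index",
    "classify_potent",
    "three_drug_ci",
    "growth_series_normalize",
    "fit_table",
    "combo_points_from_table",
]

FA_CLAMP = (0.005, 0.995)


def fa_growth(x_combo: float, x_ctl: float) -> float:
    """Fraction affected for growth: fa = 1 - X_treated / X_control.

    0 means no effect, 1 complete growth inhibition.  The raw value is
    returned; clamp with :func:`clamp_fa` before median-effect fitting.
    """
    if x_ctl <= 0:
        raise ValueError("control cell number must be positive")
    return 1.0 - x_combo / x_ctl


def clamp_fa(fa: float, lo: float = FA_CLAMP[0], hi: float = FA_CLAMP[1]) -> float:
    """Make fa usable by the linearised fit.

    Values already strictly inside (0, 1) pass through untouched; fa <= 0 or
    >= 1 (where the logit is undefined) are pulled to the band edges.
    """
    if fa <= 0:
        return lo
    if fa >= 1:
        return hi
    return float(fa)


def fit_median_effect(
    doses, fas, drug: str = "drug", clamp: bool = True
) -> MedianEffectFit:
    """OLS fit of the linearised median-effect equation.

    log10(fa/(1-fa)) = m*log10(D) - m*log10(Dm).  Requires >= 2 distinct
    doses with fa strictly inside (0, 1) (after optional clamping of values
    at or beyond the boundaries).
    """
    d = np.asarray(doses, dtype=float)
    f = np.asarray(fas, dtype=float)
    if d.shape != f.shape:
        raise ValueError("doses and fa values must align")
    if (d <= 0).any():
        raise ValueError("doses must be positive")
    if clamp:
        f = np.array([clamp_fa(v) for v in f])
    keep = (f > 0) & (f < 1)
    d, f = d[keep], f[keep]
    if np.unique(d).size < 2:
        raise ValueError("median-effect fit needs >= 2 distinct usable doses")
    x = np.log10(d)
    y = np.log10(f / (1.0 - f))
    if np.ptp(x) == 0:
        raise ValueError("zero dose variance")
    res = stats.linregress(x, y)
    if res.slope <= 0:
        raise ValueError(
            f"non-positive median-effect slope ({res.slope:.3g}); "
            "response does not increase with dose"
        )
    dm = 10.0 ** (-res.intercept / res.slope)
    return MedianEffectFit(drug=drug, m=float(res.slope), dm=float(dm),
                           r_fit=float(res.rvalue), n_points_used=int(d.size))


def dose_for_effect(fit: MedianEffectFit, fa: float) -> float:
    """Dx: the dose of this drug alone producing effect fa."""
    if not 0 < fa < 1:
        raise ValueError("fa must be strictly inside (0, 1)")
    return fit.dm * (fa / (1.0 - fa)) ** (1.0 / fit.m)


def effective_conc(fit: MedianEffectFit, level: float) -> float:
    """EC at a percent effect level: EC50 = Dm, EC75 = Dx(0.75), ..."""
    if not 0 < level < 100:
        raise ValueError("level must be in (0, 100) percent")
    return dose_for_effect(fit, level / 100.0)


def combination_index(
    combo_doses: dict[str, float],
    fa: float,
    fits: dict[str, MedianEffectFit],
    exclusive: bool = True,
) -> ComboPoint:
    """CI and per-drug DRI for one combination point.

    Mutually exclusive form (default): CI = sum_i D_i / Dx_i(fa).  The
    non-exclusive variant adds the two-drug cross term
    (D_1 D_2)/(Dx_1 Dx_2).
    """
    missing = [d for d in combo_doses if d not in fits]
    if missing:
        raise ValueError(f"no median-effect fit for: {missing}")
    dx = {d: dose_for_effect(fits[d], fa) for d in combo_doses}
    return _combo_point(combo_doses, fa, dx, exclusive)


def ci_from_equivalent_doses(
    combo_doses: dict[str, float],
    equivalent_doses: dict[str, float],
    fa: float = float("nan"),
    exclusive: bool = True,
) -> ComboPoint:
    """CI directly from measured single-drug equivalent doses Dx.

    Used when the iso-effective single doses are known (e.g. read off
    matched in vivo dose-response data) rather than derived from a fit.
    """
    if set(combo_doses) != set(equivalent_doses):
        raise ValueError("combo and equivalent doses must name the same drugs")
    return _combo_point(combo_doses, fa, dict(equivalent_doses), exclusive)


def _combo_point(
    combo_doses: dict[str, float], fa: float, dx: dict[str, float], exclusive: bool
) -> ComboPoint:
    terms = {}
    for drug, dose in combo_doses.items():
        if dose < 0:
            raise ValueError("combo doses must be non-negative")
        if dx[drug] <= 0:
            raise ValueError("equivalent doses must be positive")
        terms[drug] = dose / dx[drug]
    ci = sum(terms.values())
    if not exclusive:
        active = [d for d, dose in combo_doses.items() if dose > 0]
        if len(active) == 2:
            ci += terms[active[0]] * terms[active[1]]
    dri = {d: (dx[d] / combo_doses[d] if combo_doses[d] > 0 else float("inf"))
           for d in combo_doses}
    return ComboPoint(doses=dict(combo_doses), fa=fa, dx=dx, ci=float(ci), dri=dri)


def dose_reduction_index(dx: float, d_combo: float) -> float:
    """DRI = single-drug equivalent dose / combo dose; > 1 means dose saving."""
    if d_combo <= 0:
        raise ValueError("combo dose must be positive")
    return dx / d_combo


def classify_potent(
    points: dict[str, list[ComboPoint]],
    fa_min: float = 0.7,
    ci_max: float = 0.7,
) -> SynergyAssessment:
    """Potent-synergy call over varied-drug orientations.

    ``points`` maps each orientation (which drug was varied) to its Fa-CI
    points; the combination is potent iff every orientation contains at least
    one point with fa > fa_min and CI < ci_max.
    """
    if not points:
        raise ValueError("need at least one orientation")
    potent = all(
        any(p.fa > fa_min and p.ci < ci_max for p in pts)
        for pts in points.values()
    )
    return SynergyAssessment(points=points, potent=potent,
                             fa_min=fa_min, ci_max=ci_max)


def three_drug_ci(
    pair_doses: pd.DataFrame,
    pair_fas,
    third_fit: MedianEffectFit,
    combo_rows: pd.DataFrame,
    ratio_tolerance: float = 0.01,
    pair_name: str = "pair",
) -> list[ComboPoint]:
    """Three-drug CI with the fixed-ratio pair treated as one entity.

    ``pair_doses`` has one column per pair component (dose-escalation rows at
    a fixed ratio; drift beyond ``ratio_tolerance`` is an error); the entity
    dose is the row sum.  ``combo_rows`` carries columns for the two pair
    components, the third drug, and ``fa``.  CI(fa) = D_pair/Dx_pair(fa) +
    D_third/Dx_third(fa).
    """
    comp = list(pair_doses.columns)
    if len(comp) != 2:
        raise ValueError("the pair entity needs exactly two component columns")
    ratios = pair_doses[comp[1]] / pair_doses[comp[0]]
    r0 = float(ratios.iloc[0])
    if (np.abs(ratios / r0 - 1.0) > ratio_tolerance).any():
        raise ValueError(
            f"pair dose ratio drifts beyond {ratio_tolerance:.0%}; "
            "the pair cannot be fitted as a single entity"
        )
    entity_dose = pair_doses.sum(axis=1).to_numpy()
    pair_fit = fit_median_effect(entity_dose, pair_fas, drug=pair_name)

    points = []
    for _, row in combo_rows.iterrows():
        fa = float(row["fa"])
        d_pair = float(row[comp[0]] + row[comp[1]])
        d_third = float(row[third_fit.drug])
        fits = {pair_name: pair_fit, third_fit.drug: third_fit}
        points.append(
            combination_index({pair_name: d_pair, third_fit.drug: d_third}, fa, fits)
        )
    return points


def growth_series_normalize(series: pd.DataFrame) -> pd.Series:
    """Normalise growth curves to day 0 per replicate, then average.

    ``series`` is timepoints x replicates with the day-0 row labelled 0.
    Feeds :func:`fa_growth` with treated vs vehicle values at a matched day.
    """
    if 0 not in series.index:
        raise ValueError("growth series must include a day-0 row")
    day0 = series.loc[0]
    if (day0 <= 0).any():
        raise ValueError("day-0 values must be positive in every replicate")
    return (series / day0).mean(axis=1)


# ---------------------------------------------------------------------------
# table-level drivers (standard dose-response dialect)

_DOSE_COLS = ["drug1_dose", "drug2_dose", "drug3_dose"]


def _table_fa(table: pd.DataFrame) -> pd.Series:
    """Fraction affected per row: growth rows via 1 - X/X_ctl, apoptotic
    index rows taken directly as a fraction."""
    fa = pd.Series(index=table.index, dtype=float)
    for i, row in table.iterrows():
        if row["effect_type"] == "apoptotic_index":
            fa.loc[i] = float(row["effect_value"])
        else:
            fa.loc[i] = fa_growth(float(row["effect_value"]),
                                  float(row["control_value"]))
    return fa


def fit_table(table: pd.DataFrame) -> dict[str, MedianEffectFit]:
    """Fit a median-effect curve per drug from its single-drug rows."""
    fa = _table_fa(table)
    fits: dict[str, MedianEffectFit] = {}
    doses = table[_DOSE_COLS].to_numpy(dtype=float)
    for j, col in enumerate(_DOSE_COLS):
        single = (doses[:, j] > 0) & (np.delete(doses, j, axis=1) == 0).all(axis=1)
        if single.sum() >= 2:
            drug = f"drug{j + 1}"
            fits[drug] = fit_median_effect(doses[single, j], fa[single],
                                           drug=drug)
    return fits


def combo_points_from_table(
    table: pd.DataFrame,
    fits: dict[str, MedianEffectFit] | None = None,
    exclusive: bool = True,
) -> list[ComboPoint]:
    """CI/DRI for every combination row (>= 2 nonzero doses) of a table."""
    if fits is None:
        fits = fit_table(table)
    fa = _table_fa(table)
    points = []
    doses = table[_DOSE_COLS].to_numpy(dtype=float)
    for i in range(len(table)):
        active = {f"drug{j + 1}": doses[i, j]
                  for j in range(3) if doses[i, j] > 0}
        if len(active) < 2:
            continue
        fa_i = clamp_fa(fa.iloc[i])
        points.append(combination_index(active, fa_i, fits, exclusive=exclusive))
    return points
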