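"""Group-level inference and lesion quantification.

Covers the factorial comparison of tract measures (two-way ANOVA of
blindsight status x lesion side, Type-II sums of squares by default for
the unbalanced 12-vs-5 design), independent-samples t-tests (pooled
variance by default, Welch by flag), Pearson and age-partial
correlations between behaviour and microstructure, and lesion
volume / lobe-overlap summaries. No multiple-testing correction is
applied; reports annotate the number of tests run.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

from .errors import DesignError, RegistrationError, UndefinedStatisticError
from .io import ScalarVolume

__all__ = [
    "AnovaResult",
    "LesionSummary",
    "two_way_anova",
    "two_sample_t",
    "pearson_corr",
    "partial_corr",
    "lesion_summary",
]

logger = logging.getLogger(__name__)


@dataclass
class AnovaResult:
    """F and p for both main effects and the interaction."""

    F_A: float
    p_A: float
    df_A: int
    F_B: float
    p_B: float
    df_B: int
    F_interaction: float
    p_interaction: float
    df_interaction: int
    df_error: int
    ss_type: int = 2


@dataclass
class LesionSummary:
    """Lesion volume and percent-of-lobe overlaps for one participant."""

    participant: str
    lesion_volume_mm3: float
    lobe_overlap_pct: dict[str, float] = field(default_factory=dict)


def two_way_anova(
    table: pd.DataFrame,
    response: str,
    factor_a: str,
    factor_b: str,
    ss_type: int = 2,
) -> AnovaResult:
    """Two-way fixed-effects ANOVA with interaction.

    Type-II sums of squares by default (conventional for unbalanced
    designs without interaction-driven hypotheses); Type I/III
    available through ``ss_type``. Every factor-level cell must be
    populated.
    """
    for f in (factor_a, factor_b):
        if table[f].nunique() < 2:
            raise DesignError(f"factor {f!r} needs >= 2 levels")
    counts = table.groupby([factor_a, factor_b], observed=True).size()
    for a in table[factor_a].unique():
        for b in table[factor_b].unique():
            if (a, b) not in counts.index:
                raise DesignError(f"empty cell ({factor_a}={a!r}, {factor_b}={b!r})")
    n_cells = table[factor_a].nunique() * table[factor_b].nunique()
    if len(table) <= n_cells:
        raise DesignError(
            f"saturated design: {len(table)} observations for {n_cells} cells "
            "leaves no residual degrees of freedom"
        )
    data = table.rename(columns={response: "_y", factor_a: "_a", factor_b: "_b"})
    model = smf.ols("_y ~ C(_a) * C(_b)", data=data).fit()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on tiny designs
        aov = sm.stats.anova_lm(model, typ=ss_type)
    row_a, row_b, row_ab = "C(_a)", "C(_b)", "C(_a):C(_b)"
    resid_row = "Residual"
    return AnovaResult(
        F_A=float(aov.loc[row_a, "F"]),
        p_A=float(aov.loc[row_a, "PR(>F)"]),
        df_A=int(aov.loc[row_a, "df"]),
        F_B=float(aov.loc[row_b, "F"]),
        p_B=float(aov.loc[row_b, "PR(>F)"]),
        df_B=int(aov.loc[row_b, "df"]),
        F_interaction=float(aov.loc[row_ab, "F"]),
        p_interaction=float(aov.loc[row_ab, "PR(>F)"]),
        df_interaction=int(aov.loc[row_ab, "df"]),
        df_error=int(aov.loc[resid_row, "df"]),
        ss_type=ss_type,
    )


def two_sample_t(
    group_a: np.ndarray, group_b: np.ndarray, equal_var: bool = True
) -> tuple[float, float, float]:
    """Two-sided independent-samples t-test; pooled variance by default.

    Returns (t, p, df). Two zero-variance groups with equal means give
    t = 0, p = 1 by convention.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise UndefinedStatisticError("each group needs >= 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            df = len(a) + len(b) - 2
            return 0.0, 1.0, float(df)
        raise UndefinedStatisticError("zero variance in both groups with unequal means")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = len(a) + len(b) - 2 if equal_var else float(res.df)
    return float(res.statistic), float(res.pvalue), float(df)


def pearson_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Pearson r with two-sided p from the t transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise UndefinedStatisticError("need n >= 3 paired values")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for zero-variance input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def partial_corr(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float]:
    """Partial correlation of x and y controlling for covariate z.

    Computed as the Pearson correlation of the residuals of x and y
    after least-squares regression on z (with intercept); p is
    two-sided from the t transform with n - 3 degrees of freedom. A
    constant covariate falls back to the plain correlation with a
    warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    n = len(x)
    if not (len(y) == len(z) == n) or n < 4:
        raise UndefinedStatisticError("need n >= 4 triples")
    if z.std() == 0:
        warnings.warn("covariate has zero variance; falling back to plain correlation",
                      stacklevel=2)
        return pearson_corr(x, y)
    design = np.column_stack([np.ones(n), z])
    rx = x - design @ np.linalg.lstsq(design, x, rcond=None)[0]
    ry = y - design @ np.linalg.lstsq(design, y, rcond=None)[0]
    if rx.std() == 0 or ry.std() == 0:
        raise UndefinedStatisticError("residuals have zero variance after removing covariate")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 3
    r_clamped = min(max(r, -1.0 + 1e-15), 1.0 - 1e-15)
    t = r_clamped * np.sqrt(df / (1.0 - r_clamped ** 2))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return r, p


def lesion_summary(
    lesion_mask: ScalarVolume,
    lobe_masks: dict[str, ScalarVolume],
    participant: str = "",
) -> LesionSummary:
    """Lesion volume (mm^3) and overlap with each lobe as % of lobe volume.

    All masks must share the lesion mask's grid and affine; resampling
    between grids is out of scope.
    """
    lesion = np.asarray(lesion_mask.data) > 0.5
    voxel_vol = lesion_mask.voxel_volume_mm3
    overlaps: dict[str, float] = {}
    for name, lobe in lobe_masks.items():
        if lobe.data.shape != lesion_mask.data.shape or not np.allclose(
            lobe.affine, lesion_mask.affine
        ):
            raise RegistrationError(
                f"lobe mask {name!r} is not on the lesion mask's grid/affine"
            )
        lobe_vox = np.asarray(lobe.data) > 0.5
        lobe_total = int(lobe_vox.sum())
        if lobe_total == 0:
            overlaps[name] = 0.0
            continue
        overlaps[name] = 100.0 * int((lesion & lobe_vox).sum()) / lobe_total
    return LesionSummary(
        participant=participant,
        lesion_volume_mm3=float(lesion.sum()) * voxel_vol,
        lobe_overlap_pct=overlaps,
    )
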