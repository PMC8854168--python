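"""Synonymous-normalised DNM burden tests and ascertainment-differential
contribution estimates.

Each case cohort is compared with the control cohort in a 2x2 table

    a = case DNMs of the tested class      b = case synonymous DNMs
    c = control DNMs of the tested class   d = control synonymous DNMs

so that cross-study differences in DNM detection rate cancel through the
synonymous denominators.  Per cohort, p-values for the four tested classes
(LoF, Dmis, Pfun, Tmis) form one Benjamini-Hochberg family (m = 4).

The "ascertainment differential" f = 1 - (c/d)/(a/b) is the estimated
fraction of case DNMs of that class that are involved in aetiology; times
the per-trio DNM rate a/N it gives the fraction of probands attributable to
the class.  Negative differentials (class depleted in cases) are reported
as-is but clipped to zero for patient contributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .classify import BURDEN_CLASSES, ClassCountMatrix

logger = logging.getLogger(__name__)

Z_95 = stats.norm.ppf(0.975)


def _check_cells(a: int, b: int, c: int, d: int) -> None:
    for name, v in zip("abcd", (a, b, c, d)):
        if v < 0:
            raise ValueError(f"cell {name} is negative ({v})")
        if v != int(v):
            raise ValueError(f"cell {name} is not an integer ({v})")


def fisher_two_tailed(a: int, b: int, c: int, d: int) -> float:
    """Two-tailed Fisher exact p for the 2x2 table [[a, b], [c, d]].

    The two-tailed convention sums hypergeometric probabilities of all
    tables with the observed margins that are no more probable than the
    observed table (the convention of standard exact-test implementations).
    """
    _check_cells(a, b, c, d)
    if a + b + c + d == 0:
        raise ValueError("all cells zero: no data")
    return float(stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")[1])


@dataclass(frozen=True)
class OddsRatioCI:
    """Cross-product odds ratio with a Wald confidence interval on log OR."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    #: True when the Haldane-Anscombe 0.5 correction was applied (zero cell).
    haldane: bool = False

    def __iter__(self):
        return iter((self.odds_ratio, self.ci_low, self.ci_high))


def odds_ratio_ci(a: int, b: int, c: int, d: int, level: float = 0.95) -> OddsRatioCI:
    """Sample odds ratio (a*d)/(b*c) with a Wald CI on the log scale.

    With any zero cell, 0.5 is added to all four cells (Haldane-Anscombe)
    and the result is flagged.  Two zero cells in one table row leave the
    ratio undefined; NaNs are returned, flagged.
    """
    _check_cells(a, b, c, d)
    if (a == 0 and b == 0) or (c == 0 and d == 0) or (a == 0 and c == 0) or (b == 0 and d == 0):
        return OddsRatioCI(math.nan, math.nan, math.nan, haldane=True)
    cells = [float(a), float(b), float(c), float(d)]
    haldane = any(v == 0 for v in cells)
    if haldane:
        cells = [v + 0.5 for v in cells]
    aa, bb, cc, dd = cells
    or_ = (aa * dd) / (bb * cc)
    z = stats.norm.ppf(0.5 + level / 2.0)
    se = math.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    log_or = math.log(or_)
    return OddsRatioCI(
        odds_ratio=or_,
        ci_low=math.exp(log_or - z * se),
        ci_high=math.exp(log_or + z * se),
        haldane=haldane,
    )


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def burden_table(
    matrix: ClassCountMatrix,
    control_label: str = "control",
    classes: Sequence[str] = BURDEN_CLASSES,
) -> pd.DataFrame:
    """Burden tests of every case cohort against the control cohort.

    Returns one row per (cohort != control) x class with the 2x2 cells,
    odds ratio, Wald CI, two-tailed Fisher p and the BH-adjusted p computed
    within each cohort across its tested classes.
    """
    if control_label not in matrix.cohorts:
        raise ValueError(f"control cohort {control_label!r} not in matrix")
    d = matrix.class_count(control_label, "synonymous")
    if d <= 0:
        raise ValueError("control cohort has no synonymous DNMs; cannot normalise")
    rows = []
    for cohort in matrix.cohorts:
        if cohort == control_label:
            continue
        b = matrix.class_count(cohort, "synonymous")
        if b <= 0:
            raise ValueError(f"cohort {cohort!r} has no synonymous DNMs; cannot normalise")
        for cls in classes:
            a = matrix.class_count(cohort, cls)
            c = matrix.class_count(control_label, cls)
            orci = odds_ratio_ci(a, b, c, d)
            rows.append(
                {
                    "disorder": cohort,
                    "variant_class": cls,
                    "a": a, "b": b, "c": c, "d": d,
                    "odds_ratio": orci.odds_ratio,
                    "ci_low": orci.ci_low,
                    "ci_high": orci.ci_high,
                    "haldane": orci.haldane,
                    "p": fisher_two_tailed(a, b, c, d),
                }
            )
    out = pd.DataFrame(rows)
    out["p_adj"] = np.nan
    for cohort in out["disorder"].unique():
        mask = out["disorder"] == cohort
        out.loc[mask, "p_adj"] = bh_adjust(out.loc[mask, "p"].to_numpy())
    return out


def ascertainment_differential(a: int, b: int, c: int, d: int) -> float:
    """Fraction of case DNMs of a class implicated in aetiology.

    f = 1 - (c/d)/(a/b): one minus the ratio of the control to the case
    class-per-synonymous rate.  May be negative (class depleted in cases);
    negative values are reported, not clipped.
    """
    _check_cells(a, b, c, d)
    if a == 0 or b == 0 or d == 0:
        raise ValueError("a, b and d must be positive to form the rate ratio")
    return 1.0 - (c / d) / (a / b)


def patient_contribution(f: float, class_count: int, n_trios: int) -> float:
    """Fraction of probands attributable to a DNM class.

    max(f, 0) * class_count / n_trios: the implicated fraction times the
    per-trio DNM rate of the class.  A negative differential contributes
    nothing (and is noted in the log).
    """
    if n_trios <= 0:
        raise ValueError("n_trios must be positive")
    if class_count < 0:
        raise ValueError("class_count must be non-negative")
    if f < 0:
        logger.info("negative implicated fraction %.4f clipped to 0 (class depleted)", f)
        f = 0.0
    return f * class_count / n_trios


def contribution_table(
    matrix: ClassCountMatrix,
    control_label: str = "control",
    classes: Sequence[str] = ("LoF", "Dmis", "Pfun"),
) -> pd.DataFrame:
    """Ascertainment differentials and patient contributions per cohort x class.

    Fractions are returned on the unit scale; multiply by 100 for the
    percentage presentation.
    """
    if control_label not in matrix.cohorts:
        raise ValueError(f"control cohort {control_label!r} not in matrix")
    d = matrix.class_count(control_label, "synonymous")
    rows = []
    for cohort in matrix.cohorts:
        if cohort == control_label:
            continue
        b = matrix.class_count(cohort, "synonymous")
        n = int(matrix.n_trios.loc[cohort])
        for cls in classes:
            a = matrix.class_count(cohort, cls)
            c = matrix.class_count(control_label, cls)
            f = ascertainment_differential(a, b, c, d)
            rows.append(
                {
                    "disorder": cohort,
                    "variant_class": cls,
                    "implicated_fraction": f,
                    "patient_contribution": patient_contribution(f, a, n),
                }
            )
    return pd.DataFrame(rows)
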