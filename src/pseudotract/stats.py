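"""Success-rate accounting, paired method comparison, confidence
ellipses and metric-vs-ventriculomegaly correlation.

The method-comparison table mirrors the layout used to compare the
pseudo-atlas extraction against atlas-based extraction: per (tract,
metric) row, Pearson r with its two-sided p, the mean difference, and
a two-sided paired t-test p, with pairwise deletion of subjects
missing either method and the surviving n reported. The printed mean
difference follows the convention that a negative value means the
pseudo-atlas metric is higher (difference = comparator - pseudo-atlas).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "success_rate",
    "attempted_count",
    "compare_methods",
    "method_comparison_table",
    "confidence_ellipse",
    "metric_vs_ei",
    "EllipseSummary",
    "ComparisonRow",
]


def success_rate(generated: int, attempted: int) -> float:
    """Percentage of attempted tracts generated, half-up to 1 decimal."""
    if attempted <= 0:
        raise ValueError("attempted must be > 0")
    if not (0 <= generated <= attempted):
        raise ValueError("need 0 <= generated <= attempted")
    pct = Decimal(100 * generated) / Decimal(attempted)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def attempted_count(recipes, n_subjects: int) -> int:
    """Tract instances attempted: n_subjects x (midline + 2 x bilateral)."""
    per_subject = sum(1 if r.laterality == "midline" else 2 for r in recipes)
    return int(n_subjects) * per_subject


@dataclass(frozen=True)
class ComparisonRow:
    r: float | None  # Pearson correlation (None if undefined)
    r_p: float | None
    mean_difference: float | None  # mean(a - b)
    t_p: float | None  # two-sided paired t-test p
    n: int
    insufficient: bool = False


def compare_methods(a, b) -> ComparisonRow:
    """Paired comparison of two per-subject metric vectors.

    Pairs with either side missing (NaN/None) are dropped; with fewer
    than 3 complete pairs the row is marked insufficient. The mean
    difference is mean(a - b); r is missing when either vector is
    constant (correlation undefined).
    """
    a = np.asarray([np.nan if v is None else v for v in a], float)
    b = np.asarray([np.nan if v is None else v for v in b], float)
    if a.shape != b.shape:
        raise ValueError("vectors must be aligned by subject")
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    n = int(ok.sum())
    if n < 3:
        return ComparisonRow(r=None, r_p=None, mean_difference=None, t_p=None, n=n, insufficient=True)
    mean_diff = float(np.mean(a - b))
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        r, r_p = None, None
    else:
        rr = sps.pearsonr(a, b)
        r, r_p = float(rr.statistic), float(rr.pvalue)
    d = a - b
    if np.allclose(d, d[0]):
        # zero-variance differences: t is 0 when the constant is 0, else infinite
        t_p = 1.0 if abs(d[0]) < 1e-300 else 0.0
    else:
        t_p = float(sps.ttest_rel(a, b).pvalue)
    return ComparisonRow(r=r, r_p=r_p, mean_difference=mean_diff, t_p=t_p, n=n)


def method_comparison_table(pseudo: pd.DataFrame, comparator: pd.DataFrame) -> pd.DataFrame:
    """Per-(tract, metric) comparison rows between two extraction methods.

    Inputs are long tables with columns ``subject``, ``tract`` and the
    metric columns ``FA``/``MD`` (bilaterally averaged upstream). The
    printed mean difference is comparator - pseudo-atlas, so a negative
    value means the pseudo-atlas method reported the higher metric.
    """
    rows = []
    tracts = sorted(set(pseudo["tract"]) & set(comparator["tract"]))
    for tract in tracts:
        p = pseudo[pseudo["tract"] == tract].set_index("subject")
        c = comparator[comparator["tract"] == tract].set_index("subject")
        subjects = sorted(set(p.index) | set(c.index))
        for metric in ("FA", "MD"):
            if metric not in p.columns or metric not in c.columns:
                continue
            pv = [p[metric].get(s, np.nan) for s in subjects]
            cv = [c[metric].get(s, np.nan) for s in subjects]
            row = compare_methods(cv, pv)  # difference = comparator - pseudo
            rows.append(
                {
                    "tract": tract,
                    "metric": metric,
                    "r": None if row.r is None else round(row.r, 3),
                    "r_p": row.r_p,
                    "mean_difference": None if row.mean_difference is None else round(row.mean_difference, 4),
                    "t_p": row.t_p,
                    "n": row.n,
                    "insufficient": row.insufficient,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EllipseSummary:
    center: tuple
    covariance: np.ndarray
    level: float
    semi_axes: tuple
    angle_deg: float  # orientation of the major axis, CCW from +x
    degenerate: bool = False


def confidence_ellipse(x, y, level: float = 0.95) -> EllipseSummary:
    """Contour of the fitted bivariate normal containing ``level`` mass.

    Semi-axes are sqrt(chi2_2(level) * covariance eigenvalues); the
    orientation comes from the leading covariance eigenvector.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or x.size != y.size:
        raise ValueError("confidence ellipse needs >= 3 aligned pairs")
    if not (0 < level < 1):
        raise ValueError("level must lie in (0, 1)")
    cov = np.cov(np.vstack([x, y]))
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    degenerate = bool(evals[-1] <= 1e-300)
    q = sps.chi2.ppf(level, df=2)
    semi = tuple(np.sqrt(np.maximum(q * evals, 0.0)))
    angle = float(np.degrees(np.arctan2(evecs[1, 0], evecs[0, 0])) % 180.0)
    return EllipseSummary(
        center=(float(x.mean()), float(y.mean())),
        covariance=cov,
        level=level,
        semi_axes=semi,
        angle_deg=angle,
        degenerate=degenerate,
    )


def metric_vs_ei(metric, ei) -> dict:
    """OLS slope + Pearson r + two-sided p of a metric against Evans' index."""
    m = np.asarray([np.nan if v is None else v for v in metric], float)
    e = np.asarray([np.nan if v is None else v for v in ei], float)
    ok = np.isfinite(m) & np.isfinite(e)
    m, e = m[ok], e[ok]
    if m.size < 3:
        raise ValueError("metric-vs-EI correlation needs >= 3 complete pairs")
    if np.ptp(e) == 0:
        return {"slope": None, "r": None, "p": None, "n": int(m.size), "undefined": True}
    res = sps.linregress(e, m)
    return {
        "slope": float(res.slope),
        "r": float(res.rvalue),
        "p": float(res.pvalue),
        "n": int(m.size),
        "undefined": False,
    }
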