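"""Behavioral, expression, radiologic and histologic endpoint traits.

* Paw-withdrawal threshold: lowest filament force eliciting nocifensive
  responses in at least 3 of 5 applications, censored at the largest
  filament (26 g); reported as the left/right paw average, optionally
  normalised to the pre-operative (week 0) value.
* qPCR: relative expression 2^-(Ct_gene - Ct_Gapdh); fold change against the
  same-sex sham group mean after 1% ROUT outlier removal.
* Radiographs: per-level percent height change from baseline and the percent
  change of the mean height across the punctured levels (L3/4-L5/6) --
  note the latter is the change of the averages, not the average of the
  per-level changes.
* Histology: 5-category 0-2 subscores from three raters; the total grade is
  the sum of the rater-averaged subscores (0-10 scale).
"""
from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import LineString, Point

from .config import HISTOLOGY_CATEGORIES, PUNCTURED_LEVELS


class PhenotypeError(ValueError):
    pass


# ---------------------------------------------------------------------------
# von Frey

def von_frey_threshold(forces, counts, min_responses: int = 3,
                       n_applications: int = 5) -> float:
    """Call the paw-withdrawal threshold for one paw at one session.

    ``forces`` must be ascending; the threshold is the smallest force whose
    response count reaches ``min_responses``; a paw that never reaches it is
    censored at the maximal filament.
    """
    forces = np.asarray(forces, dtype=float)
    counts = np.asarray(counts)
    if forces.size != counts.size or forces.size == 0:
        raise PhenotypeError("forces and counts must align and be non-empty")
    if np.any(np.diff(forces) <= 0):
        raise PhenotypeError("filament forces must be strictly ascending")
    if np.any((counts < 0) | (counts > n_applications)):
        raise PhenotypeError(f"counts must lie in [0, {n_applications}]")
    hits = np.nonzero(counts >= min_responses)[0]
    return float(forces[hits[0]]) if hits.size else float(forces[-1])


def paw_average_and_normalize(left_g: float, right_g: float,
                              baseline_g: float | None = None):
    """Average the two hindpaws; normalise to the week-0 average if given."""
    if left_g is None or right_g is None or np.isnan(left_g) or np.isnan(right_g):
        return np.nan, np.nan
    thr = (left_g + right_g) / 2.0
    norm = thr / baseline_g if baseline_g and baseline_g > 0 else np.nan
    return thr, norm


def von_frey_table(filament_responses: pd.DataFrame,
                   min_responses: int = 3) -> pd.DataFrame:
    """Per animal x week thresholds (paw-averaged) and week-0-normalised values."""
    recs = []
    for (aid, week, paw), g in filament_responses.groupby(
            ["animal_id", "week", "paw"], sort=True):
        g = g.sort_values("force_g")
        thr = von_frey_threshold(g["force_g"].values, g["response_count"].values,
                                 min_responses)
        recs.append(dict(animal_id=aid, week=week, paw=paw, threshold_g=thr))
    paws = pd.DataFrame(recs).pivot_table(index=["animal_id", "week"],
                                          columns="paw", values="threshold_g")
    out = []
    for (aid, week), row in paws.iterrows():
        thr, _ = paw_average_and_normalize(row.get("left"), row.get("right"))
        out.append(dict(animal_id=aid, week=week, threshold_g=thr))
    out = pd.DataFrame(out)
    base = out.query("week == 0").set_index("animal_id")["threshold_g"]
    out["normalized_threshold"] = out.apply(
        lambda r: r.threshold_g / base[r.animal_id]
        if r.animal_id in base.index and base[r.animal_id] > 0 else np.nan,
        axis=1)
    return out


# ---------------------------------------------------------------------------
# radiographic IVD height

def ivd_height_from_borders(cranial_border, caudal_border,
                            n_samples: int = 100) -> float:
    """Mean disc height between two manually traced vertebral borders.

    Evenly resamples each polyline by arclength and averages the
    point-to-polyline distances in both directions (symmetrised mean).
    """
    cr = LineString(np.asarray(cranial_border, dtype=float))
    ca = LineString(np.asarray(caudal_border, dtype=float))
    if cr.crosses(ca):
        raise PhenotypeError("vertebral border polylines must not cross")

    def mean_dist(src: LineString, dst: LineString) -> float:
        ds = np.linspace(0.0, src.length, n_samples)
        return float(np.mean([dst.distance(src.interpolate(d)) for d in ds]))

    return 0.5 * (mean_dist(cr, ca) + mean_dist(ca, cr))


def height_percent_change(heights: pd.DataFrame,
                          punctured_levels=PUNCTURED_LEVELS) -> pd.DataFrame:
    """Per-level and punctured-average percent height change per animal.

    The punctured-average change is ``100 * (mean6 - mean0) / mean0`` over
    the punctured levels, which differs from the mean of per-level changes.
    """
    wide = heights.pivot_table(index=["animal_id", "level"], columns="timepoint",
                               values="height_mm")
    recs = []
    for aid, g in wide.groupby(level="animal_id"):
        g = g.droplevel("animal_id")
        row = {"animal_id": aid}
        for level, r in g.iterrows():
            h0, h6 = r.get("baseline", np.nan), r.get("6wk", np.nan)
            row[f"height_pct_{level}"] = (100.0 * (h6 - h0) / h0
                                          if h0 and np.isfinite(h0) else np.nan)
        punct = g.loc[[lv for lv in punctured_levels if lv in g.index]]
        if len(punct) == len(punctured_levels) and punct.notna().all().all():
            m0, m6 = punct["baseline"].mean(), punct["6wk"].mean()
            row["height_pct_punctured"] = 100.0 * (m6 - m0) / m0
        else:
            row["height_pct_punctured"] = np.nan
        recs.append(row)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# qPCR expression

def relative_expression(ct_gene: float, ct_gapdh: float) -> float:
    """Delta-Ct relative expression 2^-(Ct_gene - Ct_Gapdh)."""
    if ct_gene is None or ct_gapdh is None or np.isnan(ct_gene) or np.isnan(ct_gapdh):
        return np.nan
    return float(2.0 ** (-(ct_gene - ct_gapdh)))


def rout_outliers(values, q_percent: float = 1.0) -> np.ndarray:
    """Robust outlier detection on a single group (constant model).

    Robust centre is the median; the robust scale (RSDR) is the 68.27th
    percentile of the absolute residuals with an n/(n-1) small-sample
    correction.  Each standardised residual gets a two-sided t p-value
    (df = n-1); candidates are examined outside-in and the i-th largest
    residual is declared (together with all larger ones) when its p-value
    falls below the step-up threshold ``i * Q / n`` -- the Benjamini-Hochberg
    geometry restricted to at most 30% of the points.  Groups smaller than 4
    return an empty mask with a warning.
    """
    v = np.asarray(values, dtype=float)
    mask = np.zeros(v.size, dtype=bool)
    n = v.size
    if n < 4:
        warnings.warn("rout_outliers: fewer than 4 values, no outliers flagged")
        return mask
    res = np.abs(v - np.median(v))
    rsdr = np.percentile(res, 68.27) * n / (n - 1)
    if rsdr == 0:
        return mask
    order = np.argsort(res)[::-1]
    q = q_percent / 100.0
    cap = max(1, int(np.floor(0.3 * n)))
    pvals = 2.0 * stats.t.sf(res[order[:cap]] / rsdr, df=n - 1)
    k_star = 0
    for k in range(cap, 0, -1):  # step-up: largest k with p_(k) <= k*Q/n
        if pvals[k - 1] <= k * q / n:
            k_star = k
            break
    mask[order[:k_star]] = True
    return mask


def expression_table(ct_records: pd.DataFrame, animals: pd.DataFrame,
                     q_percent: float = 1.0) -> pd.DataFrame:
    """Relative expression, ROUT outlier flags and fold changes per animal.

    Fold change is relative to the same-sex sham mean for the same gene and
    DRG level, computed after removing ROUT outliers within each
    sex x injury x gene x level group.  Flagged values keep their relative
    expression but get a missing fold change, so they drop out of downstream
    group statistics while remaining in the record.
    """
    ct = ct_records.pivot_table(index=["animal_id", "drg_level"], columns="gene",
                                values="ct").reset_index()
    rows = []
    for _, r in ct.iterrows():
        for gene in ("Calca", "Tac1"):
            rows.append(dict(animal_id=r.animal_id, drg_level=r.drg_level,
                             gene=gene,
                             rel_expr=relative_expression(r.get(gene), r.get("Gapdh"))))
    expr = pd.DataFrame(rows).merge(
        animals[["animal_id", "sex", "injury_group"]], on="animal_id")

    expr["outlier"] = False
    for _, g in expr.groupby(["sex", "injury_group", "gene", "drg_level"]):
        ok = g["rel_expr"].notna()
        if ok.sum() >= 4:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = rout_outliers(g.loc[ok, "rel_expr"].values, q_percent)
            expr.loc[g.index[ok], "outlier"] = m

    sham_means = (expr.query("injury_group == 'sham' and not outlier")
                  .groupby(["sex", "gene", "drg_level"])["rel_expr"].mean())
    def fold(r):
        if r.outlier or np.isnan(r.rel_expr):
            return np.nan
        key = (r.sex, r.gene, r.drg_level)
        return r.rel_expr / sham_means[key] if key in sham_means.index else np.nan
    expr["fold_change"] = expr.apply(fold, axis=1)
    return expr.drop(columns=["sex", "injury_group"])


# ---------------------------------------------------------------------------
# histology

def total_degeneration_grade(histology: pd.DataFrame) -> pd.DataFrame:
    """Rater-averaged subscores per category and the 0-10 total grade."""
    if ((histology["subscore"] < 0) | (histology["subscore"] > 2)).any():
        raise PhenotypeError("histology subscores must lie in [0, 2]")
    cat_means = histology.pivot_table(index="animal_id", columns="category",
                                      values="subscore", aggfunc="mean")
    missing = set(HISTOLOGY_CATEGORIES) - set(cat_means.columns)
    if missing:
        raise PhenotypeError(f"missing histology categories: {sorted(missing)}")
    out = cat_means[list(HISTOLOGY_CATEGORIES)].copy()
    out.columns = [f"grade_{c}" for c in out.columns]
    out["grade_total"] = out.sum(axis=1)
    return out.reset_index()
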