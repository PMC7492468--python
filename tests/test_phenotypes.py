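"""Endpoint-trait oracles: threshold calling, disc-height geometry, delta-Ct
expression, robust outlier flagging, histology grading."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from discnet.config import DEFAULT_FILAMENTS
from discnet.phenotypes import (
    PhenotypeError,
    height_percent_change,
    ivd_height_from_borders,
    paw_average_and_normalize,
    relative_expression,
    rout_outliers,
    total_degeneration_grade,
    von_frey_threshold,
)

F = np.asarray(DEFAULT_FILAMENTS)


# ---------------------------------------------------------------------------
# von Frey

@pytest.mark.parametrize("counts,expected", [
    ([5] * 11, 0.4),                      # saturated responder
    ([2] * 11, 26.0),                     # censored non-responder
    ([0] * 11, 26.0),
    ([0, 1, 2, 3, 5] + [5] * 6, 1.4),     # first >=3 rule
    ([0, 0, 0, 0, 0, 0, 3, 0, 0, 0, 0], 6.0),
])
def test_von_frey_threshold_rule(counts, expected):
    assert von_frey_threshold(F, counts) == expected


def test_von_frey_threshold_validation():
    with pytest.raises(PhenotypeError):
        von_frey_threshold([1.0, 0.5], [0, 0])
    with pytest.raises(PhenotypeError):
        von_frey_threshold(F, [6] * 11)
    with pytest.raises(PhenotypeError):
        von_frey_threshold([], [])


@settings(deadline=None, max_examples=200)
@given(st.lists(st.integers(0, 5), min_size=11, max_size=11),
       st.integers(0, 10), st.integers(0, 5))
def test_von_frey_monotone_in_counts_and_censored(counts, idx, bump):
    """Raising any response count never raises the called threshold; calls
    never exceed the maximal filament."""
    base = von_frey_threshold(F, counts)
    more = list(counts)
    more[idx] = min(5, more[idx] + bump)
    assert von_frey_threshold(F, more) <= base <= 26.0


def test_paw_average_and_normalize():
    assert paw_average_and_normalize(6, 6)[0] == 6
    assert paw_average_and_normalize(4, 8)[0] == 6
    thr, norm = paw_average_and_normalize(2, 4, baseline_g=6.0)
    assert (thr, norm) == (3.0, 0.5)
    thr, norm = paw_average_and_normalize(6, 6, baseline_g=6.0)
    assert norm == 1.0
    assert np.isnan(paw_average_and_normalize(np.nan, 4)[0])


# ---------------------------------------------------------------------------
# IVD height geometry

def test_height_parallel_lines():
    cr = [(0, 1), (5, 1)]
    ca = [(0, 0), (5, 0)]
    assert ivd_height_from_borders(cr, ca) == pytest.approx(1.0, rel=1e-9)


def test_height_rotation_invariance():
    c, s = np.cos(np.pi / 6), np.sin(np.pi / 6)
    R = np.array([[c, -s], [s, c]])
    cr = (np.array([(0, 1), (5, 1)], float) @ R.T)
    ca = (np.array([(0, 0), (5, 0)], float) @ R.T)
    assert ivd_height_from_borders(cr, ca) == pytest.approx(1.0, rel=1e-9)


def test_height_wedge_matches_dense_numeric_oracle():
    """Wedge about a hinge: symmetrised mean distance vs a dense oracle."""
    L, alpha = 4.0, 0.05
    eps = 1e-6  # borders meet near, but not at, the hinge
    ca = [(0.0, 0.0), (L, 0.0)]
    cr = [(0.0, eps), (L * np.cos(alpha), eps + L * np.sin(alpha))]
    got = ivd_height_from_borders(cr, ca, n_samples=400)

    # oracle: brute force with 20000 points per border and exact
    # point-to-segment distances via numpy only
    def seg_dist(p, a, b):
        ab = b - a
        t = np.clip(((p - a) @ ab) / (ab @ ab), 0, 1)
        return np.linalg.norm(p - (a + t[:, None] * ab), axis=1)

    A = np.array(ca, float)
    B = np.array(cr, float)
    sa = np.linspace(0, 1, 20000)[:, None] * (A[1] - A[0]) + A[0]
    sb = np.linspace(0, 1, 20000)[:, None] * (B[1] - B[0]) + B[0]
    oracle = 0.5 * (seg_dist(sa, B[0], B[1]).mean() + seg_dist(sb, A[0], A[1]).mean())
    assert got == pytest.approx(oracle, rel=1e-2)
    assert got == pytest.approx(L / 2 * np.tan(alpha), rel=0.05)


def test_height_crossing_borders_rejected():
    with pytest.raises(PhenotypeError):
        ivd_height_from_borders([(0, -1), (5, 1)], [(0, 1), (5, -1)])


# ---------------------------------------------------------------------------
# percent height change

def _height_df(aid, levels, h0, h6):
    rows = []
    for lv, a, b in zip(levels, h0, h6):
        rows.append(dict(animal_id=aid, level=lv, timepoint="baseline", height_mm=a))
        rows.append(dict(animal_id=aid, level=lv, timepoint="6wk", height_mm=b))
    return pd.DataFrame(rows)


PUNCT = ("L3/4", "L4/5", "L5/6")


def test_height_percent_change_basics():
    df = _height_df("a", PUNCT, [1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
    out = height_percent_change(df, PUNCT).iloc[0]
    assert out["height_pct_punctured"] == pytest.approx(0.0)
    df = _height_df("a", PUNCT, [1.0, 1.0, 1.0], [0.8, 0.8, 0.8])
    out = height_percent_change(df, PUNCT).iloc[0]
    assert out["height_pct_punctured"] == pytest.approx(-20.0)


def test_height_percent_change_average_of_means_not_mean_of_changes():
    df = _height_df("a", PUNCT, [1.0, 1.2, 0.8], [0.9, 1.2, 0.6])
    out = height_percent_change(df, PUNCT).iloc[0]
    # hand computation: mean0 = 1.0, mean6 = 0.9 -> -10%
    assert out["height_pct_punctured"] == pytest.approx(-10.0)
    per_level_mean = np.mean([out[f"height_pct_{lv}"] for lv in PUNCT])
    assert per_level_mean != pytest.approx(-10.0)  # the two formulas differ


@settings(deadline=None, max_examples=50)
@given(st.floats(0.1, 10.0))
def test_height_percent_change_scale_invariant(c):
    df = _height_df("a", PUNCT, [1.0, 1.2, 0.8], [0.9, 1.15, 0.7])
    base = height_percent_change(df, PUNCT).iloc[0]["height_pct_punctured"]
    df2 = df.assign(height_mm=df["height_mm"] * c)
    scaled = height_percent_change(df2, PUNCT).iloc[0]["height_pct_punctured"]
    assert scaled == pytest.approx(base, rel=1e-9)


def test_height_percent_change_missing_level_gives_missing_trait():
    df = _height_df("a", PUNCT[:2], [1.0, 1.2], [0.9, 1.15])
    out = height_percent_change(df, PUNCT).iloc[0]
    assert np.isnan(out["height_pct_punctured"])


# ---------------------------------------------------------------------------
# expression

def test_relative_expression_examples():
    assert relative_expression(20.0, 20.0) == 1.0
    assert relative_expression(21.0, 20.0) == 0.5
    assert np.isnan(relative_expression(np.nan, 20.0))


# ---------------------------------------------------------------------------
# ROUT

def test_rout_flags_single_wild_value():
    mask = rout_outliers([0.95, 1.0, 1.05, 1.02, 0.98, 10.0])
    assert mask.tolist() == [False] * 5 + [True]


def test_rout_identical_values_no_outliers():
    assert not rout_outliers([2.0] * 8).any()


def test_rout_small_group_warns_and_returns_empty():
    with pytest.warns(UserWarning):
        assert not rout_outliers([1.0, 2.0, 30.0]).any()


def _rout_reference(values, q=0.01):
    """Independent reference coding of the robust-FDR outlier procedure."""
    v = np.asarray(values, float)
    n = v.size
    res = np.abs(v - np.median(v))
    rsdr = np.percentile(res, 68.27) * n / (n - 1)
    mask = np.zeros(n, bool)
    if rsdr == 0:
        return mask
    idx = np.argsort(-res)
    cap = max(1, int(0.3 * n))
    best = 0
    for k in range(1, cap + 1):
        p = 2 * stats.t.sf(res[idx[k - 1]] / rsdr, n - 1)
        if p <= k * q / n:
            best = k
    mask[idx[:best]] = True
    return mask


def test_rout_contaminated_normal_simulation_matches_reference(rng):
    """n=12 with one 8-SD contaminant, 1000 reps: identical masks to an
    independently coded reference, high detection, low false-flag rate."""
    det = fp = 0
    for _ in range(1000):
        v = rng.normal(size=12)
        v[0] += 8.0
        m = rout_outliers(v)
        assert m.tolist() == _rout_reference(v).tolist()
        det += m[0]
        fp += m[1:].any()
    assert det / 1000 > 0.85
    assert fp / 1000 < 0.05


def test_rout_clean_gaussian_rarely_flags(rng):
    flagged = sum(rout_outliers(rng.normal(size=12)).any() for _ in range(1000))
    assert flagged / 1000 <= 0.05


# ---------------------------------------------------------------------------
# histology grade

def _hist(subs_by_rater):
    cats = ("af_integrity", "afnp_border", "np_cellularity", "np_matrix", "endplate")
    rows = []
    for r, subs in enumerate(subs_by_rater, 1):
        for c, s in zip(cats, subs):
            rows.append(dict(animal_id="a", rater=r, category=c, subscore=s))
    return pd.DataFrame(rows)


def test_grade_scale_extremes():
    assert total_degeneration_grade(_hist([[0] * 5] * 3)).iloc[0]["grade_total"] == 0
    assert total_degeneration_grade(_hist([[2] * 5] * 3)).iloc[0]["grade_total"] == 10


def test_grade_rater_averaging():
    g = total_degeneration_grade(_hist([
        [1, 1, 1, 1, 1], [2, 1, 1, 1, 1], [0, 1, 1, 1, 1]])).iloc[0]
    assert g["grade_af_integrity"] == pytest.approx(1.0)
    assert g["grade_total"] == pytest.approx(5.0)


def test_grade_out_of_range_rejected():
    with pytest.raises(PhenotypeError):
        total_degeneration_grade(_hist([[3, 0, 0, 0, 0]]))
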