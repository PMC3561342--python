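import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from hkatlas.core import InvalidInputError
from hkatlas.mdad import (GroupExtremes, accumulated_ratio_table, group_extremes,
                          mdad, mdad_table, mdad_test_summary, ratios,
                          wilcoxon_signed_rank)
from tests.conftest import make_matrix


def ext(max_n, min_n, max_c, min_c, gene="g"):
    return GroupExtremes(gene, max_n, min_n, max_c, min_c)


def test_mdad_hand_arithmetic():
    # equal spans and mid-levels -> both zero
    md, ad = mdad(ext(8, 2, 8, 2))
    assert md == pytest.approx(0.0) and ad == pytest.approx(0.0)
    # wider span in cancer: MD = log2(8/2) - log2(32/2) = 2 - 4 = -2
    md, ad = mdad(ext(8, 2, 32, 2))
    assert md == pytest.approx(-2.0)
    # higher mid-level in cancer: AD = (3+1)/2 - (5+3)/2 = -2
    md, ad = mdad(ext(8, 2, 32, 8))
    assert ad == pytest.approx(-2.0)


def test_mdad_undefined_on_zero_extreme():
    with pytest.raises(InvalidInputError):
        mdad(ext(0, 0, 8, 2))


def test_ratios_hand_cases():
    assert ratios(ext(8, 2, 16, 2)) == (0.5, 1.0)
    maxr, minr = ratios(ext(0, 0, 16, 2))  # off in normal
    assert maxr == 0.0 and minr == 0.0
    maxr, minr = ratios(ext(8, 2, 0, 0))   # off in cancer
    assert math.isinf(maxr) and math.isinf(minr)
    with pytest.raises(InvalidInputError):
        ratios(ext(0, 0, 0, 0))


def test_group_extremes_positive_min_only():
    m = make_matrix([[4.0, 0.0, 1.0, 8.0, 2.0]], "nnncc")
    (e,) = group_extremes(m)
    assert (e.max_n, e.min_n) == (4.0, 1.0)  # 0 excluded from the min
    assert (e.max_c, e.min_c) == (8.0, 2.0)


def test_md_ad_antisymmetric_under_group_swap():
    rng = np.random.default_rng(6)
    vals = rng.lognormal(1.0, 1.0, (40, 7))
    m = make_matrix(vals, "nnnnccc")
    swapped = m.with_swapped_groups()
    a = mdad_table(m)
    b = mdad_table(swapped)
    np.testing.assert_allclose(a["MD"], -b["MD"])
    np.testing.assert_allclose(a["AD"], -b["AD"])
    # ratios invert under swap
    np.testing.assert_allclose(a["maxR"], 1.0 / b["maxR"])


def test_mdad_table_skips_all_silent_and_flags_one_sided():
    m = make_matrix(
        [[0, 0, 0, 0, 0], [0, 0, 0, 4, 2], [4, 2, 1, 0, 0], [4, 2, 1, 8, 2]],
        "nnncc",
    )
    t = mdad_table(m)
    assert "g1" not in t.index  # silent everywhere
    assert bool(t.loc["g2", "only_on_in_cancer"])
    assert t.loc["g2", "maxR"] == 0.0
    assert bool(t.loc["g3", "only_on_in_normal"])
    assert math.isinf(t.loc["g3", "maxR"])
    assert np.isnan(t.loc["g2", "MD"]) and not np.isnan(t.loc["g4", "MD"])


# ------------------------------------------------------------- signed rank


def exhaustive_signflip_p(values):
    """Literal 2^n enumeration oracle for the exact two-sided p-value."""
    d = np.asarray(values, float)
    d = d[d != 0]
    ranks = sps.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    ws = [np.asarray(signs) @ ranks
          for signs in itertools.product([0, 1], repeat=len(d))]
    ws = np.asarray(ws)
    p_le = np.mean(ws <= w_obs + 1e-9)
    p_ge = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def test_wilcoxon_spec_example_all_negative():
    res = wilcoxon_signed_rank([-1.0, -2.0, -3.0])
    assert res.method == "exact"
    assert res.p_value == pytest.approx(0.25)  # 2 * (1/8)
    assert res.z < 0


def test_wilcoxon_all_zero_rejected():
    with pytest.raises(InvalidInputError):
        wilcoxon_signed_rank([0.0, 0.0])


def test_wilcoxon_exact_matches_exhaustive_enumeration():
    rng = np.random.default_rng(12)
    for _ in range(25):
        n = int(rng.integers(2, 11))
        vals = np.round(rng.normal(0.2, 1.0, n), 1)  # rounding forces ties
        vals = vals[vals != 0]
        if vals.size == 0:
            continue
        res = wilcoxon_signed_rank(vals)
        assert res.p_value == pytest.approx(exhaustive_signflip_p(vals), abs=1e-12)


def test_wilcoxon_exact_matches_scipy_closed_form():
    """For tie-free data scipy's exact mode is an independent closed-form
    oracle (n <= 12)."""
    rng = np.random.default_rng(13)
    for _ in range(20):
        n = int(rng.integers(4, 13))
        vals = rng.normal(0.3, 1.0, n)
        res = wilcoxon_signed_rank(vals)
        ref = sps.wilcoxon(vals, alternative="two-sided", mode="exact")
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)


def test_wilcoxon_normal_approximation_close_at_n15():
    rng = np.random.default_rng(14)
    worst = 0.0
    for _ in range(20):
        vals = rng.normal(0.4, 1.0, 15)
        exact = wilcoxon_signed_rank(vals).p_value
        ref = sps.wilcoxon(vals, alternative="two-sided", mode="approx",
                           correction=True)
        worst = max(worst, abs(exact - ref.pvalue))
    assert worst <= 0.02


def test_wilcoxon_z_sign_follows_shift():
    up = wilcoxon_signed_rank([1.0, 2.0, 3.0, 4.0, 0.5])
    down = wilcoxon_signed_rank([-1.0, -2.0, -3.0, -4.0, -0.5])
    assert up.z > 0 > down.z
    assert up.p_value == pytest.approx(down.p_value)


def test_wilcoxon_symmetric_data_not_rejected():
    res = wilcoxon_signed_rank([-2.0, -1.0, 1.0, 2.0])
    assert res.p_value == 1.0
    assert not res.reject


def test_wilcoxon_large_n_uses_normal_approx():
    rng = np.random.default_rng(15)
    vals = rng.normal(0.5, 1.0, 60)
    res = wilcoxon_signed_rank(vals)
    assert res.method == "normal"
    ref = sps.wilcoxon(vals, alternative="two-sided", mode="approx", correction=True)
    assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)


# -------------------------------------------------------------- summaries


def _planted_table(n=200, shift=-0.8, seed=0):
    rng = np.random.default_rng(seed)
    md = rng.normal(shift, 0.5, n)
    ad = rng.normal(shift, 0.5, n)
    return pd.DataFrame(
        {"MD": md, "AD": ad,
         "maxR": np.exp(rng.normal(0, 0.3, n)), "minR": np.exp(rng.normal(0, 0.3, n))},
        index=[f"g{i}" for i in range(n)],
    )


def test_summary_detects_planted_negative_shift():
    t = _planted_table()
    s = mdad_test_summary(t)
    assert s.loc["MD_all", "reject"] == 1 and s.loc["MD_all", "z"] < 0
    assert s.loc["AD_all", "reject"] == 1 and s.loc["AD_all", "z"] < 0
    assert s.loc["AD_all", "gene_count"] == 200


def test_summary_per_status_counts_partition_all():
    t = _planted_table(n=90)
    statuses = pd.Series(
        ["constant"] * 30 + ["moderate_variable"] * 40 + ["variable"] * 20,
        index=t.index,
    )
    s = mdad_test_summary(t, statuses)
    counts = [s.loc[f"MD_{k}", "gene_count"]
              for k in ("constant", "moderate_variable", "variable")]
    assert sum(counts) == s.loc["MD_all", "gene_count"] == 90


def test_accumulated_ratio_percentages():
    t = pd.DataFrame(
        {"maxR": [0.5, 1.0, 2.0], "minR": [0.9, 1.1, 3.0],
         "MD": [0.0] * 3, "AD": [0.0] * 3},
        index=["a", "b", "c"],
    )
    acc = accumulated_ratio_table(t)
    assert acc.loc["all", "gene_count"] == 3
    assert acc.loc["all", "maxR_le_cutoff_pct"] == pytest.approx(66.67)
    assert acc.loc["all", "minR_le_cutoff_pct"] == pytest.approx(33.33)
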