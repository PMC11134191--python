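"""Genome scans: trimmed-chi2 FST outliers, PC-based outliers, union logic."""

import numpy as np
import pytest
from scipy.stats import chi2

from domestiscan.genoscan import (ScanConfig, bh_qvalues, fit_trimmed_chi2,
                                  fst_outlier_scan, make_clumped_neutral,
                                  pc_outlier_scan, pca_scores, theta_nocorr,
                                  union_outliers)
from domestiscan.qcfilter import FilterConfig
from domestiscan.simpop import SimConfig, StrainSpec, assemble_panel

from conftest import make_dataset


# ---------------------------------------------------------------------------
# BH q-values
# ---------------------------------------------------------------------------

def test_bh_qvalues_match_statsmodels_and_are_monotone():
    from statsmodels.stats.multitest import multipletests

    rng = np.random.default_rng(0)
    p = rng.uniform(0, 1, 200)
    q = bh_qvalues(p)
    _, q_ref, _, _ = multipletests(p, method="fdr_bh")
    np.testing.assert_allclose(q, q_ref, atol=1e-12)
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)


def test_bh_qvalues_nan_passthrough():
    q = bh_qvalues(np.array([0.01, np.nan, 0.5]))
    assert np.isnan(q[1]) and np.isfinite(q[0])


# ---------------------------------------------------------------------------
# Trimmed scaled-chi2 fit
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("df_true", [1.0, 3.0])
def test_trimmed_chi2_fit_recovers_parameters(df_true):
    rng = np.random.default_rng(1)
    theta_bar = 0.04
    x = chi2.rvs(df_true, size=4000, random_state=rng) * theta_bar / df_true
    tb, df = fit_trimmed_chi2(x, 0.05)
    assert tb == pytest.approx(theta_bar, rel=0.10)
    assert df == pytest.approx(df_true, rel=0.25)


def test_trimmed_chi2_fit_needs_data():
    with pytest.raises(ValueError):
        fit_trimmed_chi2(np.array([0.1] * 5))


# ---------------------------------------------------------------------------
# theta' and the FST scan
# ---------------------------------------------------------------------------

def test_theta_nocorr_range_and_he():
    g1 = np.array([[0], [0], [0], [0]], dtype=np.int8)
    g2 = np.array([[2], [2], [2], [2]], dtype=np.int8)
    theta, he = theta_nocorr([g1, g2])
    assert theta[0] == pytest.approx(1.0)  # opposite fixation
    assert he[0] == pytest.approx(0.5)


def two_group_panel(seed, n_loci=600, shift_loci=(), shift=0.4, n=60):
    """Half wild / half selected samples; optional frequency-shifted loci."""
    rng = np.random.default_rng(seed)
    p = rng.uniform(0.15, 0.85, n_loci)
    g_w = rng.binomial(2, p, (n // 2, n_loci)).astype(np.int8)
    p2 = p.copy()
    for j in shift_loci:
        p2[j] = np.clip(p2[j] + shift, 0.02, 0.98)
    g_s = rng.binomial(2, p2, (n // 2, n_loci)).astype(np.int8)
    g = np.vstack([g_w, g_s])
    pops = ["PW"] * (n // 2) + ["PS"] * (n // 2)
    return make_dataset(g, positions=np.arange(1, n_loci + 1) * 10_000,
                        chrom=["chr%d" % (1 + j // (n_loci // 4)) for j in range(n_loci)],
                        pops=pops, classes={"PS": "selected"})


def test_fst_scan_hmin_exclusion():
    ds = two_group_panel(2)
    # force one locus to tiny expected heterozygosity
    ds.genotypes[:, 0] = 0
    ds.genotypes[0, 0] = 1  # He ~ 0.016 < 0.1
    table = fst_outlier_scan(ds, ds, ScanConfig())
    assert np.isnan(table.loc[0, "fst_p"])
    assert not table.loc[0, "outlier_fst"]


def test_fst_scan_flags_shifted_locus_not_null():
    ds = two_group_panel(3, shift_loci=(5,), shift=0.6)
    table = fst_outlier_scan(ds, ds, ScanConfig())
    assert table.loc[5, "outlier_fst"]
    null_flags = table.drop(index=5)["outlier_fst"]
    assert null_flags.mean() <= 0.01


def test_fst_scan_null_false_positive_rate():
    """Pure sampling null: the flagged fraction stays near the q cutoff."""
    ds = two_group_panel(4)
    table = fst_outlier_scan(ds, ds, ScanConfig())
    assert table["outlier_fst"].mean() <= 0.05 + 0.01


# ---------------------------------------------------------------------------
# PC scan
# ---------------------------------------------------------------------------

def test_pc1_separates_two_group_panel():
    ds = two_group_panel(5, shift_loci=tuple(range(0, 80)), shift=0.5)
    scores, eig = pca_scores(ds, n_pc=3)
    cls = (ds.class_labels() == "selected").astype(float)
    r = np.corrcoef(scores[:, 0], cls)[0, 1]
    assert abs(r) > 0.5


def test_pc_scan_ranks_gradient_marker_high():
    ds = two_group_panel(6, shift_loci=tuple(range(0, 40)), shift=0.5)
    # marker 0 shifted strongly: aligns with the dominant PC gradient
    table = pc_outlier_scan(ds, ds, ScanConfig(K=1))
    ranks = table["mahalanobis_d2"].rank(ascending=False)
    assert ranks.iloc[0] <= 60  # top decile of 600


def test_pc_scan_null_false_positive_rate():
    ds = two_group_panel(7)
    table = pc_outlier_scan(ds, ds, ScanConfig(K=2))
    assert table["outlier_pc"].mean() <= 0.05 + 0.01


# ---------------------------------------------------------------------------
# Union and clumped-neutral
# ---------------------------------------------------------------------------

def test_union_published_arithmetic():
    """918 and 327 outliers sharing 71 markers union to 1174."""
    fst = [f"s{i}" for i in range(327)]
    pc = [f"p{i}" for i in range(918 - 71)] + [f"s{i}" for i in range(71)]
    res = union_outliers(fst, pc)
    assert res["n_fst"] == 327 and res["n_pc"] == 918
    assert res["n_shared"] == 71
    assert res["n_union"] == 327 + 918 - 71 == 1174


def test_union_disjoint_and_identical():
    assert union_outliers(list("abcdefghij"), list("klmno"))["n_union"] == 15
    assert union_outliers(list("abcdefg"), list("abcdefg"))["n_union"] == 7


def test_make_clumped_neutral_excludes_outliers(demo_full, demo_clumped, demo_scan):
    full, _ = demo_full
    table, _ = demo_scan
    union = table.loc[table["outlier_union"], "marker_id"].tolist()
    neutral = make_clumped_neutral(full, union, FilterConfig())
    assert not set(neutral.markers.ids) & set(union)
    # empty union reduces to plain clumping
    plain = make_clumped_neutral(full, [], FilterConfig())
    assert list(plain.markers.ids) == list(demo_clumped.markers.ids)
    with pytest.raises(ValueError):
        make_clumped_neutral(full, list(full.markers.ids), FilterConfig())


def test_scan_invariant_to_marker_and_sample_order(demo_full, demo_clumped, demo_scan):
    full, _ = demo_full
    table, _ = demo_scan
    rng = np.random.default_rng(10)
    perm_s = rng.permutation(full.n_samples)
    shuffled = full.subset_samples(perm_s)
    t2 = fst_outlier_scan(shuffled, demo_clumped, ScanConfig())
    np.testing.assert_allclose(
        table["theta_nocorr"].to_numpy(), t2["theta_nocorr"].to_numpy(),
        atol=1e-12, equal_nan=True)


def test_demo_scan_recall(demo, demo_scan):
    """Union outliers recover at least half of the planted parallel loci."""
    _, truth = demo
    table, counts = demo_scan
    sel_ids = {truth.marker_ids[i] for i, _ in truth.selected_loci}
    union = set(table.loc[table["outlier_union"], "marker_id"])
    assert len(union & sel_ids) / len(sel_ids) >= 0.5
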