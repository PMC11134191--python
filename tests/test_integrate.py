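"""Enrichment, PCA ellipses, admixture ANOVA, and report group means."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from domestiscan.gio import QMatrix
from domestiscan.integrate import (ellipse_anova, enrich, group_means,
                                   pca_ellipses, report, shannon_admixture)

from conftest import make_dataset


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_tail_oracle(k, N, K, n):
    """P(X >= k) by direct summation of hypergeometric point masses."""
    from math import comb

    total = comb(N, n)
    return sum(comb(K, x) * comb(N - K, n - x)
               for x in range(k, min(K, n) + 1)) / total


def annotation_tables(n_universe=60, in_term=20):
    markers = [f"m{i}" for i in range(n_universe)]
    mg = pd.DataFrame({"marker_id": markers, "gene_id": [f"g{i}" for i in range(n_universe)]})
    gt = pd.DataFrame({"gene_id": [f"g{i}" for i in range(in_term)],
                       "term_id": ["GO:1"] * in_term})
    return markers, mg, gt


def test_enrichment_matches_tail_sum_oracle():
    markers, mg, gt = annotation_tables()
    cand = markers[:15]  # 15 candidates, all in term
    out = enrich(cand, markers, mg, gt).set_index("term_id")
    expected = hypergeom_tail_oracle(15, 60, 20, 15)
    assert out.loc["GO:1", "p_hypergeom"] == pytest.approx(expected, abs=1e-10)


def test_enrichment_candidates_equal_universe_p_one():
    markers, mg, gt = annotation_tables()
    out = enrich(markers, markers, mg, gt)
    assert np.allclose(out["p_hypergeom"], 1.0)


def test_enrichment_term_absent_from_candidates_not_flagged():
    markers, mg, gt = annotation_tables()
    cand = markers[20:40]  # none in GO:1
    out = enrich(cand, markers, mg, gt).set_index("term_id")
    assert out.loc["GO:1", "p_hypergeom"] > 0.5
    assert not out.loc["GO:1", "enriched"]


def test_enrichment_empty_universe_errors():
    _, mg, gt = annotation_tables()
    with pytest.raises(ValueError):
        enrich(["m1"], [], mg, gt)


# ---------------------------------------------------------------------------
# Shannon admixture index
# ---------------------------------------------------------------------------

def test_shannon_extremes_exact():
    q = QMatrix(np.array([[1.0, 0, 0], [1.0, 0, 0],
                          [1 / 3, 1 / 3, 1 / 3], [1 / 3, 1 / 3, 1 / 3]]))
    t = shannon_admixture(q, ["single", "single", "uniform", "uniform"])
    t = t.set_index("pop")
    assert t.loc["single", "shannon_H"] == 0.0
    assert t.loc["uniform", "shannon_H"] == pytest.approx(np.log(3))


# ---------------------------------------------------------------------------
# PCA ellipses
# ---------------------------------------------------------------------------

def test_ellipse_area_matches_chi2_analytics():
    """Isotropic Gaussian scores of variance s^2: area -> pi * chi2_95 * s^2."""
    rng = np.random.default_rng(0)
    sigma = 1.7
    # build a dataset whose PC scores are essentially the raw coordinates
    scores = rng.normal(0, sigma, (4000, 2))
    cov = np.cov(scores, rowvar=False)
    ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
    area = np.pi * np.sqrt(ev[0] * chi2.ppf(0.95, 2)) * np.sqrt(ev[1] * chi2.ppf(0.95, 2))
    assert area == pytest.approx(np.pi * chi2.ppf(0.95, 2) * sigma**2, rel=0.05)


def test_ellipses_degenerate_and_monotone():
    rng = np.random.default_rng(1)
    base = rng.binomial(2, 0.5, (12, 120)).astype(np.int8)
    g = np.vstack([base[:4], base[4:8], np.tile(base[8], (4, 1))])
    # P3: four identical samples -> zero-area ellipse
    ds = make_dataset(g, pops=["P1"] * 4 + ["P2"] * 4 + ["P3"] * 4)
    t = pca_ellipses(ds).set_index("pop")
    assert t.loc["P3", "area"] == pytest.approx(0.0, abs=1e-8)
    assert t.loc["P1", "area"] > t.loc["P3", "area"]


def test_ellipses_skip_tiny_population():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, 0.5, (6, 50)).astype(np.int8)
    ds = make_dataset(g, pops=["A"] * 4 + ["B"] * 2)
    t = pca_ellipses(ds)
    assert list(t["pop"]) == ["A"]


# ---------------------------------------------------------------------------
# Ellipse ANOVA
# ---------------------------------------------------------------------------

def records(seed=0, n=16, effect="H"):
    rng = np.random.default_rng(seed)
    h = rng.uniform(0, 1.5, n)
    rel = rng.uniform(0, 0.5, n)
    if effect == "H":
        y = 2.0 * h + rng.normal(0, 0.05, n)
    elif effect == "none":
        y = rng.normal(0, 1, n)
    return pd.DataFrame({"standardized_area": y, "shannon_H": h, "relatedness": rel})


def test_anova_detects_constructed_admixture_effect():
    out = ellipse_anova(records(3))
    assert out.loc["shannon_H", "PR(>F)"] < 1e-6
    assert out.loc["relatedness", "PR(>F)"] > 0.01


def test_anova_interaction_near_zero_when_absent():
    out = ellipse_anova(records(4), interaction=True)
    assert out.loc["shannon_H:relatedness", "PR(>F)"] > 0.01


def test_anova_null_calibration():
    from scipy.stats import kstest

    ps = [ellipse_anova(records(100 + i, effect="none")).loc["shannon_H", "PR(>F)"]
          for i in range(300)]
    assert kstest(ps, "uniform").pvalue > 0.01


def test_anova_collinear_predictors_error():
    r = records(5)
    r["relatedness"] = r["shannon_H"] * 2 + 1e-9
    with pytest.raises(ValueError, match="collinear"):
        ellipse_anova(r)


def test_anova_needs_six_populations():
    with pytest.raises(ValueError):
        ellipse_anova(records(6).iloc[:4])


# ---------------------------------------------------------------------------
# Report group means (published per-population table as fixture)
# ---------------------------------------------------------------------------

TABLE1 = pd.DataFrame([
    # pop, class, N, Ar, Ho, He, relatedness, Ne
    ("MEW1", "wild", 30, 1.836, 0.241, 0.271, 0.091, 189.3),
    ("MEW2", "wild", 31, 1.845, 0.241, 0.272, 0.085, 360.1),
    ("LIW1", "wild", 31, 1.865, 0.246, 0.271, 0.057, 158.9),
    ("LIW2", "wild", 30, 1.867, 0.248, 0.272, 0.057, 10412.8),
    ("DBW1", "wild", 31, 1.870, 0.242, 0.275, 0.058, 43677.6),
    ("DBW2", "wild", 32, 1.873, 0.241, 0.277, 0.058, 19722.8),
    ("NCW1", "wild", 32, 1.870, 0.240, 0.277, 0.089, 12916.2),
    ("NCW2", "wild", 30, 1.842, 0.232, 0.267, 0.131, 21493.1),
    ("DBX1", "wild", 32, 1.803, 0.243, 0.263, 0.147, 15.9),
    ("DBX2", "selected", 31, 1.767, 0.239, 0.257, 0.200, 52.3),
    ("DBX3", "selected", 31, 1.843, 0.251, 0.276, 0.136, 42.3),
    ("UNC1", "selected", 20, 1.722, 0.247, 0.245, 0.290, 2.4),
    ("UNC2", "selected", 22, 1.702, 0.226, 0.238, 0.318, 24.9),
    ("UMFS", "selected", 30, 1.711, 0.231, 0.239, 0.311, 37.5),
    ("NYH1", "selected", 30, 1.454, 0.185, 0.171, 0.610, 64.4),
    ("NEH1", "selected", 32, 1.810, 0.246, 0.267, 0.176, 127.3),
    ("NEH2", "selected", 32, 1.781, 0.247, 0.260, 0.204, 57.3),
    ("MEH2", "selected", 32, 1.665, 0.250, 0.234, 0.334, 12.1),
], columns=["pop", "class", "N", "Ar", "Ho", "He", "relatedness_mean", "Ne_hat"])


def test_group_means_reproduce_published_summary_rows():
    gm = group_means(TABLE1, ["Ar", "Ho", "He", "relatedness_mean", "Ne_hat"])
    assert gm.loc["wild", "Ar"] == pytest.approx(1.852, abs=5e-4)
    assert gm.loc["wild", "Ho"] == pytest.approx(0.242, abs=5e-4)
    assert gm.loc["wild", "relatedness_mean"] == pytest.approx(0.086, abs=5e-4)
    assert gm.loc["selected", "He"] == pytest.approx(0.243, abs=5e-4)
    assert gm.loc["selected", "relatedness_mean"] == pytest.approx(0.287, abs=5e-4)
    assert gm.loc["selected", "Ne_hat"] == pytest.approx(46.72, abs=0.05)
    # wild-source Ne excludes the single-generation hatchery cohort
    gm_ne = group_means(TABLE1, ["Ne_hat"], exclude_pops=["DBX1"])
    assert gm_ne.loc["wild", "Ne_hat"] == pytest.approx(13616.4, abs=0.1)


def test_report_writes_consolidated_outputs(tmp_path, demo_full):
    full, _ = demo_full
    from domestiscan.popstats import wc_fst

    fst = wc_fst(full.select_pops(["W1", "W2", "S1", "S2"]))
    summary = report(str(tmp_path), diversity_table=None, ne_table=None,
                     fst_matrix=fst, pop_class=full.pop_class)
    assert (tmp_path / "fst_matrix.tsv").exists()
    assert (tmp_path / "manifest.json").exists()
    assert "fst_group_means" in summary


def test_report_empty_selected_group_no_crash(tmp_path):
    t = TABLE1[TABLE1["class"] == "wild"]
    gm = group_means(t, ["Ar"])
    assert "selected" not in gm.index
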