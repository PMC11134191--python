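"""ROH calling vs a brute-force oracle, window-parameter formulas, F_ROH."""

import numpy as np
import pandas as pd
import pytest

from domestiscan.gio import MISSING, MarkerMap
from domestiscan.roh import (RohParams, call_roh_matrix, compute_window_params,
                             froh, pi_hat_matrix, roh_incidence,
                             simulated_homozygote_l_total)

from conftest import make_dataset


def markers_for(positions, chrom="chr1"):
    return MarkerMap(pd.DataFrame({
        "id": [f"m{i}" for i in range(len(positions))],
        "chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}))


def test_window_params_published_example():
    """n_s=141676, n_i=539, het=0.24, alpha=0.05 gives L=78 and t=0.012."""
    L, t = compute_window_params(141_676, 539, 0.24, alpha=0.05, n_out=0)
    assert L == 78
    assert t == pytest.approx(0.012)


def test_window_params_monotone_in_heterozygosity():
    Ls = [compute_window_params(10_000, 100, h)[0] for h in (0.05, 0.2, 0.5, 0.9)]
    assert Ls == sorted(Ls, reverse=True)
    assert Ls[-1] >= 1


def test_window_params_input_validation():
    with pytest.raises(ValueError):
        compute_window_params(100, 10, 0.0)
    with pytest.raises(ValueError):
        compute_window_params(0, 10, 0.3)


def loose_params(**kw):
    base = dict(min_len_bp=10_000, min_density_bp_per_snp=50_000,
                max_gap_bp=1_000_000)
    base.update(kw)
    return RohParams(**base)


def test_fully_homozygous_individual_spans_each_chromosome():
    pos = np.arange(1, 101) * 10_000
    mk = MarkerMap(pd.concat([markers_for(pos, "chr1").table,
                              markers_for(pos, "chr2").table]).reset_index(drop=True))
    g = np.zeros((1, 200), dtype=np.int8)
    segs = call_roh_matrix(g, mk, L=20, t=0.05, params=loose_params(), sample_ids=["a"])
    assert len(segs) == 2
    assert set(segs["chrom"]) == {"chr1", "chr2"}
    assert (segs["n_snps"] == 100).all()


def test_alternating_heterozygotes_yield_no_segments():
    g = np.tile(np.array([1, 0], dtype=np.int8), 50)[None, :]
    mk = markers_for(np.arange(1, 101) * 10_000)
    segs = call_roh_matrix(g, mk, L=20, t=0.05, params=loose_params(), sample_ids=["a"])
    assert len(segs) == 0


def test_planted_tract_with_one_embedded_het():
    """3-Mb homozygous tract + 1 het inside a heterozygous background."""
    rng = np.random.default_rng(0)
    m = 400
    pos = np.sort(rng.choice(np.arange(1, 10_000_000), m, replace=False))
    g = rng.binomial(2, 0.5, m).astype(np.int8)  # het-rich background
    tract = (pos >= 3_000_000) & (pos <= 6_000_000)
    g[tract] = 0
    het_idx = np.flatnonzero(tract)[len(np.flatnonzero(tract)) // 2]
    g[het_idx] = 1
    mk = markers_for(pos)
    params = loose_params(min_len_bp=200_000)
    # hit threshold high enough that chance homozygous stretches flanking the
    # tract are not marked in-ROH (they would otherwise add flanking hets)
    L, t = 40, 0.125
    segs = call_roh_matrix(g[None, :], mk, L, t, params, ["a"])
    big = segs[segs["length_bp"] > 1_000_000]
    assert len(big) == 1
    seg = big.iloc[0]
    assert seg["length_class"] == "2-4Mb"
    # boundaries within one window of the planted tract
    span = pos[tract]
    assert abs(seg["start_bp"] - span[0]) <= pos[min(het_idx + L, m - 1)] - pos[het_idx]
    oracle = call_roh_matrix(g[None, :], mk, L, t, params, ["a"], bruteforce=True)
    pd.testing.assert_frame_equal(segs, oracle)


@pytest.mark.parametrize("seed", range(10))
def test_caller_equals_bruteforce_oracle_random(seed):
    """Random genotypes/parameters: windowed caller == windowless oracle."""
    rng = np.random.default_rng(seed)
    m = int(rng.integers(60, 300))
    pos = np.sort(rng.choice(np.arange(1, 5_000_000), m, replace=False))
    g = rng.choice([0, 1, 2, MISSING], size=(2, m),
                   p=[0.45, 0.25, 0.2, 0.1]).astype(np.int8)
    mk = markers_for(pos)
    L = int(rng.integers(5, 40))
    t = float(rng.uniform(0.01, 0.3))
    params = RohParams(min_len_bp=int(rng.choice([10_000, 200_000])),
                       min_density_bp_per_snp=int(rng.choice([50_000, 200_000])),
                       max_gap_bp=int(rng.choice([200_000, 1_000_000])),
                       max_het_in_window=int(rng.integers(0, 3)),
                       max_missing_in_window=int(rng.integers(0, 6)))
    fast = call_roh_matrix(g, mk, L, t, params, ["a", "b"])
    slow = call_roh_matrix(g, mk, L, t, params, ["a", "b"], bruteforce=True)
    pd.testing.assert_frame_equal(fast, slow)


def test_froh_arithmetic():
    segs = pd.DataFrame({"sample": ["a", "a"], "chrom": ["chr1", "chr2"],
                         "start_bp": [1, 1], "end_bp": [2, 2], "n_snps": [9, 9],
                         "length_bp": [60_000_000, 8_400_000],
                         "length_class": [">8Mb", "4-8Mb"]})
    t = froh(segs, l_total_bp=684_000_000, samples=["a", "b"], min_len=1_000_000)
    assert t.set_index("sample").loc["a", "froh"] == pytest.approx(0.1)
    assert t.set_index("sample").loc["b", "froh"] == 0.0
    with pytest.raises(ValueError):
        froh(segs, 0, ["a"])


def test_l_total_bounds_individual_sums():
    pos = np.arange(1, 201) * 25_000
    mk = markers_for(pos)
    params = loose_params()
    l_total = simulated_homozygote_l_total(mk, L=20, t=0.05, params=params)
    rng = np.random.default_rng(1)
    g = rng.choice([0, 2], size=(3, 200)).astype(np.int8)  # all-homozygous panel
    segs = call_roh_matrix(g, mk, 20, 0.05, params, ["a", "b", "c"])
    per_sample = segs.groupby("sample")["length_bp"].sum()
    assert (per_sample <= l_total).all()


def test_roh_incidence_shared_tract():
    pos = np.arange(1, 101) * 10_000
    mk = markers_for(pos)
    segs = pd.DataFrame({"sample": ["a", "b"], "chrom": "chr1",
                         "start_bp": [200_000, 200_000], "end_bp": [400_000, 400_000],
                         "n_snps": 21, "length_bp": 200_000, "length_class": "0.2-0.5Mb"})
    inc, islands = roh_incidence(segs, mk, n_individuals=2)
    inside = (pos >= 200_000) & (pos <= 400_000)
    assert np.all(inc[inside] == 1.0)
    assert np.all(inc[~inside] == 0.0)
    assert len(islands) >= 1


def test_roh_incidence_empty():
    mk = markers_for(np.arange(1, 11) * 1000)
    inc, islands = roh_incidence(pd.DataFrame(columns=["sample", "chrom", "start_bp",
                                                       "end_bp"]), mk, 5)
    assert np.all(inc == 0) and islands == []


def test_pi_hat_detects_duplicates():
    rng = np.random.default_rng(2)
    g = rng.binomial(2, rng.uniform(0.2, 0.8, 400), (10, 400)).astype(np.int8)
    g[1] = g[0]  # duplicate pair
    ph = pi_hat_matrix(g)
    assert ph[0, 1] > 0.95
    others = ph[np.triu_indices(10, 1)]
    assert np.median(others) < 0.3


def test_demo_froh_contrast(demo_roh):
    """Selected strains carry an order-of-magnitude more ROH than wild."""
    from scipy.stats import kruskal

    _, _, ft = demo_roh
    w = ft.loc[ft["class"] == "wild", "froh"]
    s = ft.loc[ft["class"] == "selected", "froh"]
    assert s.mean() > w.mean()
    assert kruskal(w, s).pvalue < 0.01
    assert ft["froh"].between(0, 1).all()
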