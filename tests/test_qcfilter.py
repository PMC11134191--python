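"""QC cascade and LD clumping, checked against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest

from domestiscan.gio import MISSING
from domestiscan.qcfilter import (FilterConfig, apply_filters, hwe_exact_pvalue,
                                  ld_clump, ld_clump_bruteforce)
from domestiscan.gio import RegionSet

from conftest import make_dataset


# ---------------------------------------------------------------------------
# HWE exact test vs full-enumeration oracle
# ---------------------------------------------------------------------------

def hwe_enumeration_oracle(n_ref, n_het, n_alt):
    """Direct enumeration over all genotype configurations with the observed
    allele counts; probabilities from the multinomial/hypergeometric identity."""
    n = n_ref + n_het + n_alt
    n_a = 2 * n_ref + n_het
    configs = []
    for h in range(0, min(n_a, 2 * n - n_a) + 1):
        if (n_a - h) % 2:
            continue
        ra = (n_a - h) // 2
        aa = n - ra - h
        if ra < 0 or aa < 0:
            continue
        logp = (h * math.log(2) + math.lgamma(n + 1) - math.lgamma(ra + 1)
                - math.lgamma(h + 1) - math.lgamma(aa + 1))
        configs.append((h, logp))
    mx = max(lp for _, lp in configs)
    probs = {h: math.exp(lp - mx) for h, lp in configs}
    z = sum(probs.values())
    probs = {h: p / z for h, p in probs.items()}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


@pytest.mark.parametrize("counts", [
    (25, 50, 25), (50, 0, 50), (10, 5, 3), (3, 14, 3), (1, 1, 1), (40, 20, 0),
])
def test_hwe_exact_matches_enumeration(counts):
    assert hwe_exact_pvalue(*counts) == pytest.approx(
        hwe_enumeration_oracle(*counts), abs=1e-12)


def test_hwe_fixed_heterozygote_deficit_is_extreme():
    assert hwe_exact_pvalue(50, 0, 50) < 1e-6


def test_hwe_monomorphic_is_one():
    assert hwe_exact_pvalue(30, 0, 0) == 1.0


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def cascade_fixture():
    """Panel with one labeled violation per filtering step.

    20 samples in two populations; marker roles:
      m0 inside excluded region; m1 pooled MAF 0.025 (< 0.05); m2 MAF exactly
      0.05 (kept); m3 call rate 0.90 in P2 only; m4 violates HWE in both pops;
      m5..m14 clean. Sample s0 has >10% missing (2 of the 13 markers that
      survive the marker steps before it); no other sample crosses 10%.
    """
    rng = np.random.default_rng(42)
    n, m = 20, 15
    g = rng.binomial(1, 0.5, (n, m)).astype(np.int8) + rng.binomial(1, 0.5, (n, m)).astype(np.int8)
    g[:, 1] = 0
    g[0, 1] = 1                      # 1/40 copies -> MAF 0.025
    g[:, 2] = 0
    g[1, 2] = g[2, 2] = 1            # 2/40 -> MAF exactly 0.05
    g[:, 3] = 1
    g[10, 3] = MISSING               # P2 call rate 9/10 = 0.90 < 0.95
    g[:, 4] = np.array([0, 2] * 10)  # no hets at p=0.5: HWE violation
    g[0, 5] = g[0, 6] = MISSING      # s0: 2/13 = 15% missing after marker steps
    pops = ["P1"] * 10 + ["P2"] * 10
    return make_dataset(g, positions=np.arange(1, m + 1) * 100_000, pops=pops)


def test_cascade_counts_match_constructed_truth():
    ds = cascade_fixture()
    regions = RegionSet([("chr1", 0, 150_000)])  # only m0 at pos 100000
    full, rep = apply_filters(ds, FilterConfig(), regions)
    steps = rep.set_index("step")
    assert steps.loc["regions", "markers_removed"] == 1
    assert steps.loc["maf", "markers_removed"] == 1          # m1 only; m2 kept
    assert steps.loc["sample_missing", "samples_removed"] == 1
    assert steps.loc["pop_callrate", "markers_removed"] == 1  # m3
    assert steps.loc["hwe", "markers_removed"] == 1           # m4
    # telescoping: retained_k = retained_{k-1} - removed_k
    r = rep["markers_retained"].to_numpy()
    d = rep["markers_removed"].to_numpy()
    assert np.all(r[1:] == r[:-1] - d[1:])
    assert "m2" in full.markers.ids


def test_maf_boundary_inclusive_keep():
    ds = cascade_fixture()
    full, _ = apply_filters(ds, FilterConfig())
    assert "m2" in full.markers.ids      # MAF exactly 0.05 retained
    assert "m1" not in full.markers.ids  # MAF 0.025 removed


def test_filtering_is_idempotent():
    ds = cascade_fixture()
    full, _ = apply_filters(ds, FilterConfig())
    again, rep = apply_filters(full, FilterConfig())
    assert again.n_markers == full.n_markers
    assert again.n_samples == full.n_samples
    assert rep["markers_removed"].sum() == 0


def test_all_markers_removed_raises():
    ds = cascade_fixture()
    with pytest.raises(ValueError, match="no markers"):
        apply_filters(ds, FilterConfig(maf_min=0.9999))


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def correlated_panel(seed, n=40, m=60, window_frac=0.5):
    """One chromosome of markers with blocky LD (duplicated/perturbed columns)."""
    rng = np.random.default_rng(seed)
    base = rng.binomial(2, rng.uniform(0.1, 0.9, m // 3), (n, m // 3)).astype(np.int8)
    cols = [base[:, rng.integers(0, base.shape[1])] for _ in range(m)]
    g = np.stack(cols, axis=1)
    flip = rng.random(g.shape) < 0.15
    g[flip] = rng.integers(0, 3, int(flip.sum()))
    pos = np.sort(rng.choice(np.arange(1, 200_000), size=m, replace=False))
    return make_dataset(g, positions=pos)


@pytest.mark.parametrize("seed", range(5))
def test_clump_equals_bruteforce_oracle(seed):
    ds = correlated_panel(seed)
    cfg = FilterConfig(clump_window_bp=10_000, clump_r2_max=0.2)
    fast = ld_clump(ds, cfg)
    slow = ld_clump_bruteforce(ds, cfg)
    assert list(fast.markers.ids) == list(slow.markers.ids)


def test_clump_output_has_no_violating_pair():
    ds = correlated_panel(99, m=80)
    cfg = FilterConfig(clump_window_bp=15_000, clump_r2_max=0.3)
    out = ld_clump(ds, cfg)
    pos = out.markers.pos
    g = out.genotypes.astype(float)
    for i, j in itertools.combinations(range(out.n_markers), 2):
        if pos[j] - pos[i] <= cfg.clump_window_bp:
            r = np.corrcoef(g[:, i], g[:, j])[0, 1]
            if not np.isnan(r):
                assert r * r < cfg.clump_r2_max


def test_clump_drops_lower_maf_member():
    # two perfectly correlated SNPs 5 kb apart, MAF 0.3 vs 0.2
    g = np.zeros((10, 2), dtype=np.int8)
    g[:3, 0] = 2          # freq 0.3
    g[:2, 1] = 2          # freq 0.2 -- correlated with marker 0 (r2 >= 0.2)
    ds = make_dataset(g, positions=[1000, 6000])
    out = ld_clump(ds, FilterConfig())
    assert list(out.markers.ids) == ["m0"]


def test_clump_respects_window():
    g = np.zeros((10, 2), dtype=np.int8)
    g[:5, 0] = 2
    g[:5, 1] = 2          # r2 = 1 but 15 kb apart
    ds = make_dataset(g, positions=[1000, 16_000])
    out = ld_clump(ds, FilterConfig(clump_window_bp=10_000))
    assert out.n_markers == 2


def test_clump_idempotent():
    ds = correlated_panel(7)
    cfg = FilterConfig()
    once = ld_clump(ds, cfg)
    twice = ld_clump(once, cfg)
    assert list(once.markers.ids) == list(twice.markers.ids)
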