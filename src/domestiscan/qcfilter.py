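"""SNP quality-control cascade and LD clumping ("full SNPs" / "clumped SNPs").

The filtering cascade runs in a fixed order -- excluded regions, pooled minor
allele frequency, per-sample missingness, per-population call rate, and a
per-population exact Hardy-Weinberg test -- and reports telescoping per-step
counts. Clumping greedily thins markers so that no retained pair within a
sliding window exceeds an r-squared threshold, keeping the higher-MAF member
of each violating pair.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .gio import MISSING, GenotypeDataset, RegionSet

log = logging.getLogger("domestiscan")


@dataclass
class FilterConfig:
    maf_min: float = 0.05
    sample_missing_max: float = 0.10
    pop_callrate_min: float = 0.95
    hwe_p_min: float = 0.01
    hwe_pop_frac: float = 0.5
    clump_window_bp: int = 10_000
    clump_r2_max: float = 0.2
    loading_outlier_rounds: int = 0   # snp_autoSVD-style pruning, off by default
    loading_outlier_z: float = 6.0

    def __post_init__(self) -> None:
        for name in ("maf_min", "sample_missing_max", "pop_callrate_min",
                     "hwe_p_min", "hwe_pop_frac", "clump_r2_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if self.clump_window_bp <= 0:
            raise ValueError("clump_window_bp must be > 0")


# ---------------------------------------------------------------------------
# Exact HWE test
# ---------------------------------------------------------------------------

def hwe_exact_pvalue(n_aa_hom: int, n_het: int, n_alt_hom: int) -> float:
    """Two-sided exact Hardy-Weinberg test probability.

    Sums, over all heterozygote counts compatible with the observed allele
    counts, the conditional probabilities that are <= the observed outcome's
    probability (no mid-p correction).
    """
    if min(n_aa_hom, n_het, n_alt_hom) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_aa_hom + n_het + n_alt_hom
    if n < 1:
        raise ValueError("need at least one genotype")
    n_a = 2 * n_aa_hom + n_het
    n_b = 2 * n - n_a
    rare = min(n_a, n_b)
    if rare == 0:
        return 1.0  # monomorphic: single possible outcome
    hets = np.arange(rare % 2, rare + 1, 2)

    def logprob(h):
        hom_a = (n_a - h) // 2
        hom_b = (n_b - h) // 2
        return (h * np.log(2.0) + gammaln(n + 1)
                - gammaln(hom_a + 1) - gammaln(h + 1) - gammaln(hom_b + 1))

    lp = logprob(hets)
    lp -= lp.max()
    prob = np.exp(lp)
    prob /= prob.sum()
    obs = prob[hets == n_het]
    if len(obs) == 0:
        raise ValueError("heterozygote count incompatible with allele counts")
    return float(min(1.0, prob[prob <= obs[0] * (1 + 1e-12)].sum()))


def hwe_pvalues_per_pop(ds: GenotypeDataset) -> pd.DataFrame:
    """Exact HWE p-value per (population, marker); NaN-free (all-missing -> 1)."""
    out = {}
    for pop in ds.pops():
        g = ds.genotypes[ds.samples_of(pop)]
        pvals = np.ones(ds.n_markers)
        n_ref = (g == 0).sum(axis=0)
        n_het = (g == 1).sum(axis=0)
        n_alt = (g == 2).sum(axis=0)
        for j in range(ds.n_markers):
            if n_ref[j] + n_het[j] + n_alt[j] >= 1:
                pvals[j] = hwe_exact_pvalue(int(n_ref[j]), int(n_het[j]), int(n_alt[j]))
        out[pop] = pvals
    return pd.DataFrame(out, index=ds.markers.ids)


# ---------------------------------------------------------------------------
# Filtering cascade
# ---------------------------------------------------------------------------

def _pooled_maf(ds: GenotypeDataset) -> np.ndarray:
    p = ds.allele_freq()
    return np.minimum(p, 1.0 - p)


def apply_filters(ds: GenotypeDataset, cfg: FilterConfig,
                  regions: RegionSet | None = None
                  ) -> tuple[GenotypeDataset, pd.DataFrame]:
    """Run the full QC cascade, returning the "full SNPs" dataset + report.

    Steps, in order: excluded-region removal; pooled MAF < maf_min removed
    (exactly maf_min is kept); samples with > sample_missing_max missing
    removed; markers with call rate < pop_callrate_min in any single
    population removed; markers out of HWE (p < hwe_p_min) in >= hwe_pop_frac
    of populations removed.
    """
    if len(ds.pops()) < 2:
        raise ValueError("need >= 2 populations")
    report = []
    cur = ds

    def record(step, markers_removed, samples_removed):
        report.append({
            "step": step,
            "markers_removed": int(markers_removed),
            "markers_retained": cur.n_markers,
            "samples_removed": int(samples_removed),
            "samples_retained": cur.n_samples,
        })

    record("input", 0, 0)

    # 1. excluded regions
    if regions is not None and len(regions):
        keep = ~regions.mask(cur.markers)
        removed = int((~keep).sum())
        cur = cur.subset_markers(np.flatnonzero(keep))
    else:
        removed = 0
    record("regions", removed, 0)

    # 2. pooled MAF
    maf = _pooled_maf(cur)
    keep = ~(maf < cfg.maf_min - 1e-12)  # NaN-safe: all-missing loci kept here
    keep |= np.isnan(maf)
    cur = cur.subset_markers(np.flatnonzero(keep))
    record("maf", int((~keep).sum()), 0)

    # 3. sample missingness
    miss = (cur.genotypes == MISSING).mean(axis=1)
    keep_s = miss <= cfg.sample_missing_max
    removed_s = int((~keep_s).sum())
    cur = cur.subset_samples(np.flatnonzero(keep_s))
    record("sample_missing", 0, removed_s)

    # 4. per-population call rate
    bad = np.zeros(cur.n_markers, dtype=bool)
    for pop in cur.pops():
        g = cur.genotypes[cur.samples_of(pop)]
        callrate = (g != MISSING).mean(axis=0)
        bad |= callrate < cfg.pop_callrate_min - 1e-12
    cur = cur.subset_markers(np.flatnonzero(~bad))
    record("pop_callrate", int(bad.sum()), 0)

    # 5. HWE across populations
    pvals = hwe_pvalues_per_pop(cur)
    frac_out = (pvals.to_numpy() < cfg.hwe_p_min).mean(axis=1)
    keep = frac_out < cfg.hwe_pop_frac
    cur = cur.subset_markers(np.flatnonzero(keep))
    record("hwe", int((~keep).sum()), 0)

    if cur.n_markers == 0:
        raise ValueError("no markers survived the filtering cascade")
    rep = pd.DataFrame(report)
    return cur, rep


# ---------------------------------------------------------------------------
# LD clumping
# ---------------------------------------------------------------------------

def _pair_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete."""
    both = (x != MISSING) & (y != MISSING)
    if both.sum() < 2:
        return np.nan
    xv = x[both].astype(float)
    yv = y[both].astype(float)
    vx = xv.var()
    vy = yv.var()
    if vx == 0 or vy == 0:
        return np.nan
    c = ((xv - xv.mean()) * (yv - yv.mean())).mean()
    return float(c * c / (vx * vy))


def ld_clump(ds: GenotypeDataset, cfg: FilterConfig) -> GenotypeDataset:
    """Greedy LD clumping per chromosome.

    A single left-to-right pass: for every surviving pair with separation
    <= clump_window_bp and r-squared >= clump_r2_max, the lower-MAF member is
    dropped (ties keep the smaller-position marker). Equivalent to iterated
    elimination of the first violating pair in (position, position) order.
    """
    maf = _pooled_maf(ds)
    keep = np.ones(ds.n_markers, dtype=bool)
    chrom = ds.markers.chrom
    pos = ds.markers.pos
    g = ds.genotypes
    for c in ds.markers.chroms():
        idx = np.flatnonzero(chrom == c)
        cpos = pos[idx]
        m = len(idx)
        for a in range(m):
            i = idx[a]
            if not keep[i]:
                continue
            b = a + 1
            while b < m and cpos[b] - cpos[a] <= cfg.clump_window_bp:
                j = idx[b]
                if keep[j]:
                    r2 = _pair_r2(g[:, i], g[:, j])
                    if not np.isnan(r2) and r2 >= cfg.clump_r2_max:
                        if maf[j] < maf[i] or np.isnan(maf[j]):
                            keep[j] = False
                        elif maf[i] < maf[j] or np.isnan(maf[i]):
                            keep[i] = False
                            break
                        else:  # tie: keep the left (smaller position) marker
                            keep[j] = False
                b += 1
    out = ds.subset_markers(np.flatnonzero(keep))
    if cfg.loading_outlier_rounds > 0:
        out = loading_outlier_prune(out, cfg.loading_outlier_rounds, cfg.loading_outlier_z)
    return out


def loading_outlier_prune(ds: GenotypeDataset, rounds: int = 5,
                          z_thresh: float = 6.0, n_pc: int = 10) -> GenotypeDataset:
    """Iteratively remove markers with extreme PCA loadings.

    Recomputes PCs each round and drops markers whose loading z-score exceeds
    ``z_thresh`` on any of the first ``n_pc`` components; stops early when a
    round removes nothing.
    """
    cur = ds
    for _ in range(rounds):
        x = cur.genotypes.astype(float)
        x[cur.genotypes == MISSING] = np.nan
        mean = np.nanmean(x, axis=0)
        x = np.where(np.isnan(x), mean, x) - mean
        sd = x.std(axis=0)
        sd[sd == 0] = 1.0
        x /= sd
        k = min(n_pc, min(x.shape) - 1)
        if k < 1:
            break
        u, sv, vt = np.linalg.svd(x, full_matrices=False)
        load = vt[:k].T  # markers x k
        z = (load - load.mean(axis=0)) / np.where(load.std(axis=0) == 0, 1, load.std(axis=0))
        bad = (np.abs(z) > z_thresh).any(axis=1)
        if not bad.any():
            break
        log.info("loading_outlier_prune: dropping %d markers", int(bad.sum()))
        cur = cur.subset_markers(np.flatnonzero(~bad))
    return cur


def ld_clump_bruteforce(ds: GenotypeDataset, cfg: FilterConfig) -> GenotypeDataset:
    """O(n^2) reference clumping: repeatedly eliminate the first violating pair.

    Independent oracle for :func:`ld_clump`; rescans all pairs from scratch
    after every elimination.
    """
    maf = _pooled_maf(ds)
    chrom = ds.markers.chrom
    pos = ds.markers.pos
    g = ds.genotypes
    keep = np.ones(ds.n_markers, dtype=bool)
    while True:
        violated = None
        alive = np.flatnonzero(keep)
        for ai in range(len(alive)):
            for bi in range(ai + 1, len(alive)):
                i, j = alive[ai], alive[bi]
                if chrom[i] != chrom[j] or pos[j] - pos[i] > cfg.clump_window_bp:
                    continue
                r2 = _pair_r2(g[:, i], g[:, j])
                if not np.isnan(r2) and r2 >= cfg.clump_r2_max:
                    violated = (i, j)
                    break
            if violated:
                break
        if violated is None:
            break
        i, j = violated
        if maf[j] < maf[i] or np.isnan(maf[j]):
            keep[j] = False
        elif maf[i] < maf[j] or np.isnan(maf[i]):
            keep[i] = False
        else:
            keep[j] = False
    return ds.subset_markers(np.flatnonzero(keep))
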