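"""Per-population diversity, pairwise relatedness, and Weir-Cockerham FST.

Missing data are handled pairwise-complete per locus throughout; loci with
fewer than two non-missing genotypes in a population are skipped for that
statistic.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .gio import MISSING, GenotypeDataset

log = logging.getLogger("domestiscan")


# ---------------------------------------------------------------------------
# Weir & Cockerham (1984) variance components
# ---------------------------------------------------------------------------

def wc_fst_components(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-locus W&C (1984) variance components a, b, c.

    Parameters
    ----------
    groups : list of dosage matrices (samples x loci), one per population.

    Returns per-locus arrays (a, b, c); loci unusable in any population
    (fewer than 2 non-missing calls) or monomorphic across all populations
    are returned as NaN in all three components.
    """
    r = len(groups)
    if r < 2:
        raise ValueError("need >= 2 populations")
    n = np.stack([(g != MISSING).sum(axis=0) for g in groups]).astype(float)      # (r, L)
    tot = np.stack([np.where(g != MISSING, g, 0).sum(axis=0) for g in groups]).astype(float)
    het = np.stack([((g == 1)).sum(axis=0) for g in groups]).astype(float)
    valid = (n >= 2).all(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = tot / (2.0 * n)
        h = het / n
        nbar = n.mean(axis=0)
        nc = (r * nbar - (n**2).sum(axis=0) / (r * nbar)) / (r - 1.0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        hbar = (n * h).sum(axis=0) / (r * nbar)

        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - s2 * (r - 1) / r - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - s2 * (r - 1) / r
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2.0

    mono = (pbar <= 0) | (pbar >= 1)
    bad = ~valid | mono | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def wc_fst_counts(groups: list[np.ndarray]) -> float:
    """Multilocus theta (ratio of sums) from per-population dosage matrices."""
    a, b, c = wc_fst_components(groups)
    num = np.nansum(a)
    den = np.nansum(a + b + c)
    return float(num / den) if den != 0 else np.nan


def wc_fst_per_locus(groups: list[np.ndarray]) -> np.ndarray:
    """Per-locus theta = a / (a+b+c); NaN for unusable loci."""
    a, b, c = wc_fst_components(groups)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


def wc_fst(ds: GenotypeDataset, mode: str = "all-pairs"):
    """Pairwise (or pooled two-group) multilocus Weir-Cockerham theta.

    mode="all-pairs" returns a symmetric DataFrame over populations with a
    zero diagonal; mode="groups" pools samples by pop_class (wild vs
    selected) and returns a scalar theta.
    """
    if mode == "groups":
        cls = ds.class_labels()
        g_wild = ds.genotypes[cls == "wild"]
        g_sel = ds.genotypes[cls == "selected"]
        if len(g_wild) < 2 or len(g_sel) < 2:
            raise ValueError("need >= 2 samples in both wild and selected groups")
        return wc_fst_counts([g_wild, g_sel])
    pops = ds.pops()
    mat = pd.DataFrame(0.0, index=pops, columns=pops)
    sub = {p: ds.genotypes[ds.samples_of(p)] for p in pops}
    for p1, p2 in itertools.combinations(pops, 2):
        theta = wc_fst_counts([sub[p1], sub[p2]])
        mat.loc[p1, p2] = mat.loc[p2, p1] = theta
    return mat


def group_mean_fst(fst: pd.DataFrame, pop_class: dict[str, str]) -> dict[str, float]:
    """Mean pairwise theta within/between the wild and selected groups."""
    out = {"wild-wild": [], "wild-selected": [], "selected-selected": []}
    pops = list(fst.index)
    for p1, p2 in itertools.combinations(pops, 2):
        key = "-".join(sorted((pop_class[p1], pop_class[p2]), reverse=True))
        key = {"wild-wild": "wild-wild", "wild-selected": "wild-selected",
               "selected-wild": "wild-selected", "selected-selected": "selected-selected"}[key]
        out[key].append(fst.loc[p1, p2])
    return {k: (float(np.mean(v)) if v else np.nan) for k, v in out.items()}


# ---------------------------------------------------------------------------
# Diversity indices
# ---------------------------------------------------------------------------

def _rarefied_ar(alt_counts: np.ndarray, n2: np.ndarray, g: int) -> np.ndarray:
    """Per-locus rarefied allelic richness for biallelic loci.

    Ar = sum over alleles of [1 - C(2n - c_a, g) / C(2n, g)] with allele
    counts c_a out of 2n gene copies, rarefied to g copies.
    """
    def log_comb(n, k):
        with np.errstate(invalid="ignore"):
            out = gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)
        return out

    denom = log_comb(n2, g)
    ar = np.zeros(len(alt_counts), dtype=float)
    for c in (alt_counts, n2 - alt_counts):
        keep = n2 - c >= g
        term = np.zeros_like(ar)
        term[keep] = np.exp(log_comb(n2[keep] - c[keep], g) - denom[keep])
        ar += 1.0 - term
    return ar


def diversity(ds: GenotypeDataset) -> pd.DataFrame:
    """Table-1-style per-population diversity indices.

    Ho = mean fraction of heterozygous calls; He = unbiased expected
    heterozygosity 2pq * 2n/(2n-1) averaged over loci; Ar = allelic richness
    rarefied to g = 2 x (global minimum per-locus non-missing sample count
    across populations); relatedness = mean/sd of pairwise Ritland estimates.
    """
    pops = ds.pops()
    # global rarefaction depth (hierfstat convention: comparable across pops)
    min_n = np.inf
    per_pop = {}
    for p in pops:
        g = ds.genotypes[ds.samples_of(p)]
        nonmiss = (g != MISSING).sum(axis=0)
        usable = nonmiss >= 1
        if not usable.all():
            log.info("diversity: pop %s has %d all-missing loci (skipped)", p, int((~usable).sum()))
        if usable.any():
            min_n = min(min_n, int(nonmiss[usable].min()))
        per_pop[p] = g
    g_depth = 2 * int(min_n) if np.isfinite(min_n) else 2

    rows = []
    for p in pops:
        g = per_pop[p]
        obs = g != MISSING
        n = obs.sum(axis=0).astype(float)
        ok = n >= 2
        het = (g == 1).sum(axis=0)
        with np.errstate(invalid="ignore"):
            ho = het[ok] / n[ok]
            freq = np.where(obs, g, 0).sum(axis=0)[ok] / (2.0 * n[ok])
            n2 = 2.0 * n[ok]
            he = 2.0 * freq * (1 - freq) * n2 / (n2 - 1.0)
        alt_counts = np.where(obs, g, 0).sum(axis=0)[ok].astype(float)
        ar = _rarefied_ar(alt_counts, n2, g_depth)
        rel = ritland_relatedness(ds, p)
        rows.append({
            "pop": p, "class": ds.pop_class[p], "N": g.shape[0],
            "Ar": float(np.mean(ar)), "Ho": float(np.mean(ho)), "He": float(np.mean(he)),
            "relatedness_mean": rel["mean"], "relatedness_sd": rel["sd"],
        })
    out = pd.DataFrame(rows)
    out.attrs["rarefaction_g"] = g_depth
    return out


# ---------------------------------------------------------------------------
# Ritland relatedness
# ---------------------------------------------------------------------------

def ritland_pairwise(g: np.ndarray) -> np.ndarray:
    """Pairwise Ritland relatedness matrix for one population's dosages.

    Per locus, with x_a in {0, 0.5, 1} the proportion of allele a carried by
    individual x and p_a the within-population allele frequency:
    r_l = 2 * [ sum_a x_a * y_a / p_a - 1 ]; the multilocus estimate is the
    mean of r_l over polymorphic loci where both genotypes are present.
    Scaled so clones have expectation 1 and unrelated pairs 0.
    """
    obs = g != MISSING
    n = obs.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, np.where(obs, g, 0).sum(axis=0) / (2.0 * n), np.nan)
    poly = (p > 0) & (p < 1) & (n >= 2)
    x = np.where(obs, g / 2.0, np.nan)[:, poly]
    p = p[poly]
    q = 1.0 - p
    n_ind = g.shape[0]
    out = np.full((n_ind, n_ind), np.nan)
    for i in range(n_ind):
        xi = x[i]
        for j in range(i + 1, n_ind):
            yj = x[j]
            both = ~np.isnan(xi) & ~np.isnan(yj)
            if not both.any():
                continue
            rl = 2.0 * (xi[both] * yj[both] / p[both]
                        + (1 - xi[both]) * (1 - yj[both]) / q[both] - 1.0)
            out[i, j] = out[j, i] = float(np.mean(rl))
    return out


def ritland_relatedness(ds: GenotypeDataset, pop: str) -> dict:
    """Population mean/sd of pairwise Ritland relatedness plus the matrix."""
    g = ds.genotypes[ds.samples_of(pop)]
    mat = ritland_pairwise(g)
    iu = np.triu_indices(mat.shape[0], k=1)
    vals = mat[iu]
    vals = vals[~np.isnan(vals)]
    return {"matrix": mat,
            "mean": float(np.mean(vals)) if len(vals) else np.nan,
            "sd": float(np.std(vals, ddof=1)) if len(vals) > 1 else np.nan}
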