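"""Dual genome-scan outlier detection on the pooled wild-vs-selected contrast.

Two independent scans are run on the full SNP set, with neutral
parameterization on the clumped set:

* an FST-based scan: per-locus uncorrected differentiation theta' for the
  two pooled groups, with the neutral distribution modelled as a scaled
  chi-square -- theta' * df / theta_bar ~ chi2(df) -- fitted by maximum
  likelihood to the symmetrically trimmed clumped-set values (loci with
  expected heterozygosity >= Hmin only), and right-tail p-values for all
  full-set loci;
* a PC-based scan: z-scores from regressing each marker's dosages on the K
  leading principal-component score vectors of the clumped matrix, robust
  Mahalanobis distance of the z-vectors rescaled by the genomic inflation
  factor, chi-square(K) p-values.

q-values are Benjamini-Hochberg in both scans; the union of the two outlier
sets (deduplicated by marker id) is the combined-outlier list.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2

from .gio import MISSING, GenotypeDataset
from .qcfilter import FilterConfig, ld_clump

log = logging.getLogger("domestiscan")


@dataclass
class ScanConfig:
    hmin: float = 0.1
    q_threshold: float = 0.05
    trim_fraction: float = 0.05
    K: int | None = None          # None -> largest-eigengap choice among first 10

    def __post_init__(self) -> None:
        if not 0 < self.trim_fraction < 0.5:
            raise ValueError("trim_fraction must be in (0, 0.5)")


def bh_qvalues(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg q-values (monotone non-decreasing in p); NaN-safe."""
    p = np.asarray(p, dtype=float)
    q = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    ps = p[ok]
    m = len(ps)
    if m == 0:
        return q
    order = np.argsort(ps, kind="mergesort")
    ranked = ps[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(ranked, 1.0)
    q[ok] = out
    return q


# ---------------------------------------------------------------------------
# FST-based scan (trimmed scaled-chi-square null)
# ---------------------------------------------------------------------------

def theta_nocorr(groups: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Per-locus uncorrected FST ratio and pooled expected heterozygosity.

    theta' = s^2 / (pbar(1-pbar) + s^2/r): the among-group variance of allele
    frequency over the total, without the finite-sample correction terms, so
    it is nonnegative and its null scale/df can be absorbed by the fitted
    scaled chi-square.
    """
    r = len(groups)
    n = np.stack([(g != MISSING).sum(axis=0) for g in groups]).astype(float)
    tot = np.stack([np.where(g != MISSING, g, 0).sum(axis=0) for g in groups]).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = tot / (2.0 * n)
        nbar = n.mean(axis=0)
        pbar = (n * p).sum(axis=0) / (r * nbar)
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1.0) * nbar)
        he = 2.0 * pbar * (1.0 - pbar)
        theta = s2 / (pbar * (1 - pbar) + s2 / r)
    bad = (n < 2).any(axis=0) | (pbar <= 0) | (pbar >= 1)
    theta[bad] = np.nan
    he[bad] = np.nan
    return theta, he


def fit_trimmed_chi2(values: np.ndarray, trim_fraction: float = 0.05
                     ) -> tuple[float, float]:
    """ML fit of (theta_bar, df) for x * df / theta_bar ~ chi2(df).

    The sample is trimmed symmetrically (``trim_fraction`` in each tail) and
    the likelihood accounts for the truncation. Restarts from three fixed df
    values before giving up.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if len(x) < 20:
        raise ValueError(f"too few loci to fit the neutral distribution ({len(x)})")
    lo = np.quantile(x, trim_fraction)
    hi = np.quantile(x, 1.0 - trim_fraction)
    xt = x[(x >= lo) & (x <= hi)]

    def nll(params):
        log_tb, log_df = params
        tb, df = np.exp(log_tb), np.exp(log_df)
        scale = df / tb
        z = xt * scale
        ll = chi2.logpdf(z, df) + np.log(scale)
        norm = chi2.cdf(hi * scale, df) - chi2.cdf(lo * scale, df)
        if norm <= 0:
            return 1e12
        return -(ll.sum() - len(xt) * np.log(norm))

    best = None
    for df0 in (1.0, 2.0, 5.0):
        res = minimize(nll, x0=[np.log(np.mean(xt)), np.log(df0)], method="Nelder-Mead",
                       options={"maxiter": 2000, "xatol": 1e-8, "fatol": 1e-10})
        if res.success and (best is None or res.fun < best.fun):
            best = res
    if best is None:
        raise RuntimeError(
            f"trimmed chi-square fit failed: n={len(xt)}, range=[{lo:.4g},{hi:.4g}]")
    tb, df = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    return tb, df


def fst_outlier_scan(full_ds: GenotypeDataset, neutral_ds: GenotypeDataset,
                     cfg: ScanConfig | None = None) -> pd.DataFrame:
    """FST-scan columns for every full-set marker.

    Neutral parameterization on the clumped set; testing on the full set.
    Loci with He < Hmin get NaN p/q and are never outliers.
    """
    cfg = cfg or ScanConfig()
    cls = full_ds.class_labels()
    groups_full = [full_ds.genotypes[cls == "wild"], full_ds.genotypes[cls == "selected"]]
    if min(len(g) for g in groups_full) < 2:
        raise ValueError("both wild and selected groups need >= 2 samples")
    theta_full, he_full = theta_nocorr(groups_full)

    cls_n = neutral_ds.class_labels()
    groups_n = [neutral_ds.genotypes[cls_n == "wild"], neutral_ds.genotypes[cls_n == "selected"]]
    theta_n, he_n = theta_nocorr(groups_n)
    fit_vals = theta_n[(he_n >= cfg.hmin) & np.isfinite(theta_n)]
    theta_bar, df = fit_trimmed_chi2(fit_vals, cfg.trim_fraction)
    log.info("fst scan null fit: theta_bar=%.4g df=%.3g on %d clumped loci",
             theta_bar, df, len(fit_vals))

    p = np.full(full_ds.n_markers, np.nan)
    testable = (he_full >= cfg.hmin) & np.isfinite(theta_full)
    p[testable] = chi2.sf(theta_full[testable] * df / theta_bar, df)
    q = bh_qvalues(p)
    return pd.DataFrame({
        "marker_id": full_ds.markers.ids,
        "theta_nocorr": theta_full, "He": he_full,
        "fst_p": p, "fst_q": q,
        "outlier_fst": np.where(np.isnan(q), False, q < cfg.q_threshold),
    })


# ---------------------------------------------------------------------------
# PC-based scan
# ---------------------------------------------------------------------------

def _scaled_imputed(ds: GenotypeDataset) -> np.ndarray:
    """Mean-imputed, allele-frequency-scaled dosage matrix (samples x loci)."""
    x = ds.genotypes.astype(float)
    x[ds.genotypes == MISSING] = np.nan
    p = np.nanmean(x, axis=0) / 2.0
    x = np.where(np.isnan(x), 2.0 * p, x)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = np.sqrt(2.0 * p * (1.0 - p))
    sd[~np.isfinite(sd) | (sd == 0)] = 1.0
    return (x - 2.0 * p) / sd


def pca_scores(ds: GenotypeDataset, n_pc: int = 10) -> tuple[np.ndarray, np.ndarray]:
    """Leading PC scores (samples x n_pc) and eigenvalues of the scaled matrix."""
    z = _scaled_imputed(ds)
    n_pc = min(n_pc, min(z.shape) - 1)
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    scores = u[:, :n_pc] * s[:n_pc]
    eigvals = s[:n_pc] ** 2 / max(z.shape[0] - 1, 1)
    return scores, eigvals


def choose_k(eigvals: np.ndarray, k_max: int = 10) -> int:
    """Largest-eigenvalue-gap rule among the first k_max components."""
    ev = np.asarray(eigvals)[:k_max]
    if len(ev) < 2:
        return 1
    gaps = ev[:-1] - ev[1:]
    return int(np.argmax(gaps) + 1)


def pc_outlier_scan(full_ds: GenotypeDataset, neutral_ds: GenotypeDataset,
                    cfg: ScanConfig | None = None) -> pd.DataFrame:
    """PC-scan columns (Mahalanobis distances, null-calibrated p, BH q) per marker.

    PCs come from the clumped (neutral-parameterization) matrix; every
    full-set marker is regressed on the K PC score vectors and the robust
    Mahalanobis distance of its z-score vector is computed. The null is
    calibrated on the clumped-set distances by the same trimmed
    scaled-chi-square ML fit used by the FST scan (a free effective df
    absorbs the genomic inflation that a single median-based factor cannot,
    which matters when drift is strong); the classical genomic inflation
    factor is still reported.
    """
    cfg = cfg or ScanConfig()
    scores, eigvals = pca_scores(neutral_ds, n_pc=10)
    k = cfg.K if cfg.K is not None else choose_k(eigvals)
    if k > min(full_ds.n_samples, neutral_ds.n_markers):
        raise ValueError(f"K={k} exceeds sample/marker count")
    u = scores[:, :k]
    qmat, _ = np.linalg.qr(u - u.mean(axis=0))
    n = full_ds.n_samples

    y = full_ds.genotypes.astype(float)
    y[full_ds.genotypes == MISSING] = np.nan
    mu = np.nanmean(y, axis=0)
    y = np.where(np.isnan(y), mu, y) - mu
    beta = qmat.T @ y                      # (k, L); Q orthonormal
    rss = (y**2).sum(axis=0) - (beta**2).sum(axis=0)
    dof = max(n - k - 1, 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sigma = np.sqrt(np.maximum(rss, 0) / dof)
        z = beta / sigma                   # (k, L)
    zero_var = (y.var(axis=0) == 0) | ~np.isfinite(z).all(axis=0)
    zt = z.T.copy()
    zt[zero_var] = np.nan

    good = ~zero_var
    zg = zt[good]
    if k == 1:
        from scipy.stats import median_abs_deviation
        scale = median_abs_deviation(zg[:, 0], scale="normal")
        center = np.median(zg[:, 0])
        d2 = ((zg[:, 0] - center) / max(scale, 1e-12)) ** 2
    else:
        from sklearn.covariance import MinCovDet
        mcd = MinCovDet(random_state=0).fit(zg)
        d2 = mcd.mahalanobis(zg)
    gif = np.median(d2) / chi2.median(k)
    d2_full = np.full(full_ds.n_markers, np.nan)
    d2_full[good] = d2

    # null parameterization on the clumped subset of the distances: the
    # inflation factor is the max quantile ratio against chi2(K), so the
    # calibrated null stochastically dominates the empirical clumped-set
    # distances -- conservative when drift makes the tail heavier than chi2
    in_neutral = np.isin(full_ds.markers.ids, neutral_ds.markers.ids)
    null_d2 = d2_full[in_neutral & good]
    if len(null_d2) < 20:
        null_d2 = d2
    n_null = len(null_d2)
    qs = np.array([0.5, 0.9, 0.99, 0.999, 1.0 - 5.0 / n_null, 1.0 - 2.0 / n_null])
    qs = np.unique(qs[(qs > 0) & (qs < 1.0 - 0.5 / n_null)])
    gif_tail = float(np.max(np.quantile(null_d2, qs) / chi2.ppf(qs, k)))
    p = np.full(full_ds.n_markers, np.nan)
    p[good] = chi2.sf(d2 / max(gif_tail, 1e-12), k)
    q = bh_qvalues(p)
    return pd.DataFrame({
        "marker_id": full_ds.markers.ids,
        "mahalanobis_d2": d2_full, "pc_p": p, "pc_q": q,
        "outlier_pc": np.where(np.isnan(q), False, q < cfg.q_threshold),
        "K": k, "gif": gif,
    })


# ---------------------------------------------------------------------------
# Union + clumped-neutral construction
# ---------------------------------------------------------------------------

def union_outliers(fst_ids: list[str], pc_ids: list[str]) -> dict:
    """Deduplicated union of the two outlier sets, in stable input order."""
    fst_set, pc_set = set(fst_ids), set(pc_ids)
    shared = fst_set & pc_set
    union = list(dict.fromkeys(list(fst_ids) + list(pc_ids)))
    return {"union": union, "n_fst": len(fst_set), "n_pc": len(pc_set),
            "n_shared": len(shared), "n_union": len(union)}


def scan(full_ds: GenotypeDataset, neutral_ds: GenotypeDataset,
         cfg: ScanConfig | None = None) -> tuple[pd.DataFrame, dict]:
    """Run both scans and merge into one per-marker table plus union counts."""
    cfg = cfg or ScanConfig()
    fst = fst_outlier_scan(full_ds, neutral_ds, cfg)
    pc = pc_outlier_scan(full_ds, neutral_ds, cfg)
    table = fst.merge(pc, on="marker_id")
    table["outlier_union"] = table["outlier_fst"] | table["outlier_pc"]
    counts = union_outliers(
        table.loc[table["outlier_fst"], "marker_id"].tolist(),
        table.loc[table["outlier_pc"], "marker_id"].tolist())
    return table, counts


def make_clumped_neutral(full_ds: GenotypeDataset, union_ids: list[str],
                         filter_cfg: FilterConfig | None = None) -> GenotypeDataset:
    """Full set minus union outliers, re-clumped ("clumped neutral SNPs")."""
    filter_cfg = filter_cfg or FilterConfig()
    drop = set(union_ids)
    keep = np.array([m not in drop for m in full_ds.markers.ids])
    if not keep.any():
        raise ValueError("all markers are outliers; nothing left to clump")
    return ld_clump(full_ds.subset_markers(np.flatnonzero(keep)), filter_cfg)
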