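"""LD-decay curves, Hill-Weir drift-recombination fit, and half-decay ANOVA.

Within-chromosome pairwise r-squared values (up to a maximum separation) are
binned into equal-width distance bins; the bin means are fitted with the
Hill & Weir expectation of r-squared under drift-recombination equilibrium
for a finite sample of n chromosomes, and the half-decay distance is the
separation at which the fitted curve falls to half of its zero-distance
value. A two-factor ANOVA (population type x chromosome, sequential sums of
squares) compares half-decay distances.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import brentq, least_squares

from .gio import GenotypeDataset
from .ne_ld import PairwiseR2


def hill_weir_expected_r2(C, n: float):
    """Hill-Weir expected r-squared at scaled recombination C = c * d.

    E[r^2] = [(10+C)/((2+C)(11+C))] * [1 + ((3+C)(12+12C+C^2))/(n(2+C)(11+C))]
    with n the number of sampled chromosomes (2 x individuals).
    """
    C = np.asarray(C, dtype=float)
    t1 = (10.0 + C) / ((2.0 + C) * (11.0 + C))
    t2 = 1.0 + ((3.0 + C) * (12.0 + 12.0 * C + C**2)) / (n * (2.0 + C) * (11.0 + C))
    return t1 * t2


def binned_ld(ds: GenotypeDataset, pop: str, chrom: str, max_dist: int = 500_000,
              n_bins: int = 100, subsample: int = 30, seed: int = 0) -> pd.DataFrame:
    """Mean r-squared in equal-width distance bins for one population/chromosome.

    A seeded subsample of individuals is used; all within-chromosome pairs
    with separation <= max_dist contribute. Empty bins are recorded with
    n_pairs = 0 (they are excluded from fitting).
    """
    sel = ds.samples_of(pop)
    rng = np.random.default_rng(seed)
    if len(sel) > subsample:
        sel = np.sort(rng.choice(sel, size=subsample, replace=False))
    midx = np.flatnonzero(ds.markers.chrom == chrom)
    if len(midx) < 2:
        raise ValueError(f"chromosome {chrom} has < 2 markers")
    g = ds.genotypes[np.ix_(sel, midx)]
    pos = ds.markers.pos[midx]

    r2, _ = PairwiseR2(g).r2()
    i, j = np.triu_indices(len(midx), k=1)
    dist = pos[j] - pos[i]
    vals = r2[i, j]
    ok = (dist <= max_dist) & ~np.isnan(vals)
    dist, vals = dist[ok], vals[ok]
    width = max_dist / n_bins
    bins = np.minimum((dist / width).astype(int), n_bins - 1)
    n_pairs = np.bincount(bins, minlength=n_bins)
    sums = np.bincount(bins, weights=vals, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(n_pairs > 0, sums / np.maximum(n_pairs, 1), np.nan)
    return pd.DataFrame({
        "midpoint_bp": (np.arange(n_bins) + 0.5) * width,
        "mean_r2": means,
        "n_pairs": n_pairs,
    })


def hill_weir_fit(bins: pd.DataFrame, n_chromosomes_sampled: int) -> tuple[float, float]:
    """Fit the per-bp recombination scale c and return (c, half-decay bp).

    Nonlinear least squares of bin-mean r-squared on bin midpoints, weighted
    by pair counts, restarted from three fixed initial values. The half-decay
    distance solves E[r^2](c*d) = E[r^2](0) / 2 on the fitted curve.
    """
    use = bins[(bins["n_pairs"] > 0) & bins["mean_r2"].notna()]
    if len(use) < 5:
        raise ValueError(f"need >= 5 non-empty bins, got {len(use)}")
    d = use["midpoint_bp"].to_numpy(float)
    y = use["mean_r2"].to_numpy(float)
    w = np.sqrt(use["n_pairs"].to_numpy(float))
    n = float(n_chromosomes_sampled)

    def resid(logc):
        return w * (hill_weir_expected_r2(np.exp(logc) * d, n) - y)

    med_d = np.median(d)
    best = None
    for c0 in (0.1 / med_d, 3.0 / med_d, 100.0 / med_d):
        sol = least_squares(resid, x0=[np.log(c0)], method="lm", max_nfev=2000)
        cost = float(np.sum(sol.fun**2))
        if sol.success and (best is None or cost < best[0]):
            best = (cost, float(np.exp(sol.x[0])))
    if best is None:
        raise RuntimeError(
            f"Hill-Weir fit did not converge (bins={len(use)}, r2 range "
            f"[{y.min():.3f},{y.max():.3f}])")
    c = best[1]
    e0 = float(hill_weir_expected_r2(0.0, n))
    target = e0 / 2.0

    def f(C):
        return float(hill_weir_expected_r2(C, n)) - target

    # the curve decreases from E(0) to ~1/n; if it never crosses, report inf
    if f(1e12) > 0:
        return c, np.inf
    c_star = brentq(f, 1e-12, 1e12, xtol=1e-10, rtol=1e-12)
    return c, c_star / c


def decay_curves(ds: GenotypeDataset, max_dist: int = 500_000, n_bins: int = 100,
                 subsample: int = 30, seed: int = 0) -> pd.DataFrame:
    """Half-decay table over all (population, chromosome) combinations."""
    rows = []
    for pop in ds.pops():
        n_ind = min(len(ds.samples_of(pop)), subsample)
        for chrom in ds.markers.chroms():
            bins = binned_ld(ds, pop, chrom, max_dist, n_bins, subsample, seed)
            try:
                c, half = hill_weir_fit(bins, 2 * n_ind)
            except (ValueError, RuntimeError):
                continue
            rows.append({"pop": pop, "class": ds.pop_class[pop], "chrom": chrom,
                         "c_per_bp": c, "half_decay_bp": half})
    return pd.DataFrame(rows)


def decay_anova(table: pd.DataFrame, response: str = "half_decay_bp",
                class_col: str = "class", chrom_col: str = "chrom") -> pd.DataFrame:
    """Two-factor ANOVA with interaction, sequential (type-I) sums of squares."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = table.rename(columns={response: "y", class_col: "cls", chrom_col: "chrom"})
    if df["cls"].nunique() < 2 or df["chrom"].nunique() < 2:
        raise ValueError("need >= 2 levels of both factors")
    counts = df.groupby(["cls", "chrom"]).size().unstack(fill_value=0)
    if (counts == 0).any().any():
        empty = [(c, ch) for c in counts.index for ch in counts.columns
                 if counts.loc[c, ch] == 0]
        raise ValueError(f"singular design: empty cells {empty[:3]}")
    model = smf.ols("y ~ C(cls) * C(chrom)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=1)
    if np.isclose(df["y"].var(ddof=0), 0.0):  # degenerate: constant response
        table["F"] = [0.0] * (len(table) - 1) + [np.nan]
        table["PR(>F)"] = [1.0] * (len(table) - 1) + [np.nan]
    table.index = [i.replace("C(cls)", "class").replace("C(chrom)", "chrom")
                   for i in table.index]
    return table
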