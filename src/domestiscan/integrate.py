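"""Cross-cutting analyses and final report tables.

Hypergeometric enrichment of outlier markers in annotation terms, PCA
confidence-ellipse areas with the Shannon-Wiener admixture index and their
two-way ANOVA, and the consolidated per-population summary tables with
group (wild vs selected) means.
"""

from __future__ import annotations

import itertools
import json
import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2, hypergeom

from .gio import MISSING, GenotypeDataset, QMatrix
from .genoscan import bh_qvalues

log = logging.getLogger("domestiscan")


# ---------------------------------------------------------------------------
# Term enrichment
# ---------------------------------------------------------------------------

def enrich(candidates: list[str], universe: list[str],
           marker_gene: pd.DataFrame, gene_term: pd.DataFrame,
           fdr: float = 0.1) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    A marker is "in a term" when any of its genes carries the term. The
    universe is the annotated marker list; candidates outside the universe
    are ignored (counts stay nested).
    """
    if not universe:
        raise ValueError("empty universe")
    m2g = marker_gene.groupby("marker_id")["gene_id"].agg(set)
    g2t = gene_term.groupby("gene_id")["term_id"].agg(set)

    def terms_of(marker):
        out = set()
        for gene in m2g.get(marker, ()):  # markers without genes annotate nothing
            out |= g2t.get(gene, set())
        return out

    uni = list(dict.fromkeys(universe))
    cand = [m for m in dict.fromkeys(candidates) if m in set(uni)]
    uni_terms = {m: terms_of(m) for m in uni}
    all_terms = sorted(set().union(*uni_terms.values()) if uni_terms else set())
    n_uni = len(uni)
    n_cand = len(cand)
    rows = []
    for term in all_terms:
        k_uni = sum(1 for m in uni if term in uni_terms[m])
        k_cand = sum(1 for m in cand if term in uni_terms[m])
        p = float(hypergeom.sf(k_cand - 1, n_uni, k_uni, n_cand))
        rows.append({"term_id": term, "n_candidate_in_term": k_cand,
                     "n_candidate": n_cand, "n_universe_in_term": k_uni,
                     "n_universe": n_uni, "p_hypergeom": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = bh_qvalues(out["p_hypergeom"].to_numpy())
        out["enriched"] = out["fdr_q"] < fdr
        out = out.sort_values("p_hypergeom", kind="mergesort").reset_index(drop=True)
    return out


# ---------------------------------------------------------------------------
# PCA ellipses + admixture
# ---------------------------------------------------------------------------

CHI2_2_95 = float(chi2.ppf(0.95, 2))  # 5.991...


def pca_ellipses(ds: GenotypeDataset, min_samples: int = 3) -> pd.DataFrame:
    """95% confidence-ellipse geometry per population on PCs 1-2.

    A and B are the semi-major/semi-minor axes from the eigenvalues of the
    per-population 2x2 score covariance scaled by the chi-square(2) 95%
    quantile; area = pi * A * B; standardized_area is the z-score of areas
    across populations.
    """
    from .genoscan import pca_scores

    scores, _ = pca_scores(ds, n_pc=2)
    rows = []
    for pop in ds.pops():
        idx = ds.samples_of(pop)
        if len(idx) < min_samples:
            log.warning("pca_ellipses: population %s has <%d samples, skipped",
                        pop, min_samples)
            continue
        sub = scores[idx][:, :2]
        cov = np.cov(sub, rowvar=False, ddof=1)
        ev = np.sort(np.linalg.eigvalsh(cov))[::-1]
        ev = np.maximum(ev, 0.0)
        a = float(np.sqrt(ev[0] * CHI2_2_95))
        b = float(np.sqrt(ev[1] * CHI2_2_95))
        rows.append({"pop": pop, "class": ds.pop_class[pop],
                     "semi_major": a, "semi_minor": b, "area": np.pi * a * b})
    out = pd.DataFrame(rows)
    if len(out) > 1 and out["area"].std(ddof=0) > 0:
        out["standardized_area"] = (out["area"] - out["area"].mean()) / out["area"].std(ddof=1)
    else:
        out["standardized_area"] = 0.0
    return out


def shannon_admixture(q: QMatrix, pop_of_sample: list[str]) -> pd.DataFrame:
    """Shannon-Wiener index of the population-mean admixture vector.

    H = -sum_k qbar_k ln qbar_k per population; H = 0 for a single cluster
    and ln K for perfectly uniform admixture.
    """
    labels = np.asarray(pop_of_sample)
    rows = []
    for pop in dict.fromkeys(labels):
        qbar = q.q[labels == pop].mean(axis=0)
        nz = qbar[qbar > 0]
        rows.append({"pop": pop, "shannon_H": float(-(nz * np.log(nz)).sum())})
    return pd.DataFrame(rows)


def ellipse_anova(records: pd.DataFrame, interaction: bool = False) -> pd.DataFrame:
    """Two-way ANOVA of standardized ellipse area on admixture H and relatedness.

    Sequential (type-I) F tests of ``standardized_area ~ shannon_H +
    relatedness`` with an optional interaction term.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    need = {"standardized_area", "shannon_H", "relatedness"}
    if not need <= set(records.columns):
        raise ValueError(f"records must have columns {sorted(need)}")
    if len(records) < 6:
        raise ValueError("need >= 6 populations for the two-way ANOVA")
    r = np.corrcoef(records["shannon_H"], records["relatedness"])[0, 1]
    if abs(r) > 0.99:
        raise ValueError(f"collinear predictors (|r| = {abs(r):.3f})")
    formula = "standardized_area ~ shannon_H + relatedness"
    if interaction:
        formula += " + shannon_H:relatedness"
    model = smf.ols(formula, data=records).fit()
    return sm.stats.anova_lm(model, typ=1)


# ---------------------------------------------------------------------------
# Report tables
# ---------------------------------------------------------------------------

def group_means(table: pd.DataFrame, value_cols: list[str], class_col: str = "class",
                exclude_pops: list[str] | None = None, pop_col: str = "pop"
                ) -> pd.DataFrame:
    """Per-class means of selected columns, optionally excluding populations."""
    t = table
    if exclude_pops:
        t = t[~t[pop_col].isin(set(exclude_pops))]
    if class_col not in t.columns or t.empty:
        return pd.DataFrame(columns=value_cols)
    return t.groupby(class_col)[value_cols].mean()


def fst_group_summary(fst: pd.DataFrame, pop_class: dict[str, str]) -> dict[str, float]:
    """Mean pairwise FST within/between groups (wild-wild, wild-selected, ...)."""
    from .popstats import group_mean_fst

    return group_mean_fst(fst, pop_class)


def report(out_dir: str, *, diversity_table: pd.DataFrame | None = None,
           ne_table: pd.DataFrame | None = None,
           fst_matrix: pd.DataFrame | None = None,
           fst_matrix_outliers: pd.DataFrame | None = None,
           pop_class: dict[str, str] | None = None,
           froh_table: pd.DataFrame | None = None,
           scan_table: pd.DataFrame | None = None,
           manifest: dict | None = None) -> dict:
    """Write the consolidated TSV report + manifest; return the summary dict."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    summary: dict = {}

    if diversity_table is not None:
        t = diversity_table.copy()
        if ne_table is not None and len(ne_table):
            t = t.merge(ne_table[["pop", "Ne_hat", "ci_low", "ci_high"]], on="pop", how="left")
        t.to_csv(os.path.join(out_dir, "diversity_ne.tsv"), sep="\t", index=False)
        cols = [c for c in ("Ar", "Ho", "He", "relatedness_mean", "Ne_hat") if c in t.columns]
        gm = group_means(t.replace([np.inf], np.nan), cols)
        gm.to_csv(os.path.join(out_dir, "diversity_ne_group_means.tsv"), sep="\t")
        summary["diversity_group_means"] = gm.to_dict()

    if fst_matrix is not None and pop_class is not None:
        fst_matrix.to_csv(os.path.join(out_dir, "fst_matrix.tsv"), sep="\t")
        summary["fst_group_means"] = fst_group_summary(fst_matrix, pop_class)
        if fst_matrix_outliers is not None:
            fst_matrix_outliers.to_csv(os.path.join(out_dir, "fst_matrix_outliers.tsv"), sep="\t")
            summary["fst_group_means_outliers"] = fst_group_summary(fst_matrix_outliers, pop_class)

    if froh_table is not None and len(froh_table):
        froh_table.to_csv(os.path.join(out_dir, "froh.tsv"), sep="\t", index=False)
        summary["froh_group_means"] = froh_table.groupby("class")["froh"].mean().to_dict()

    if scan_table is not None:
        scan_table.to_csv(os.path.join(out_dir, "scan.tsv"), sep="\t", index=False)
        summary["n_outlier_fst"] = int(scan_table["outlier_fst"].sum())
        summary["n_outlier_pc"] = int(scan_table["outlier_pc"].sum())
        summary["n_outlier_union"] = int(scan_table["outlier_union"].sum())

    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump({"manifest": manifest or {}, "summary_keys": sorted(summary)}, fh,
                  indent=1, default=str)
    with open(os.path.join(out_dir, "summary.json"), "w") as fh:
        json.dump(summary, fh, indent=1, default=str)
    return summary
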