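"""Random-Forest distillation of outlier SNPs into a minimal discriminant panel.

A stratified-bootstrap random forest (per-tree bootstrap of equal size from
each class, so unbalanced designs get equal representation) supplies the
out-of-bag error rate (OOB-ER). Tuning loops the tree count up to a maximum
and an mtry grid derived from the panel size; marker selection is a two-step
backward purge: (1) rank markers by permutation importance and pick a
conservative top-fraction candidate list (one fraction above the OOB-ER
minimizer); (2) iteratively drop the lowest mean-importance marker (mean of
three replicate forests) down to two markers, keeping the panel with the
lowest OOB-ER (ties favor the smaller panel). The final panel is validated
with a DAPC-style classifier: linear discriminant analysis on principal
components explaining >= 90% of panel variance, scored by leave-one-out
prediction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeClassifier

log = logging.getLogger("domestiscan")


def mtry_grid(p: int) -> list[int]:
    """Candidate mtry values: sqrt(p), 2 sqrt(p), 0.1p, 0.2p, p/3, p (floors)."""
    if p < 1:
        raise ValueError("p must be >= 1")
    root = int(np.floor(np.sqrt(p)))
    cand = [root, 2 * root, int(np.floor(0.1 * p)), int(np.floor(0.2 * p)),
            int(np.floor(p / 3)), p]
    out = []
    for v in cand:
        v = min(max(v, 1), p)
        if v not in out:
            out.append(v)
    return out


@dataclass
class RfConfig:
    ntree_max: int = 1000
    n_purge_replicates: int = 3
    train_fraction: float = 2.0 / 3.0
    top_fractions: tuple[float, ...] = (0.01, 0.02, 0.05, 0.10, 0.20)
    seed: int = 0

    def __post_init__(self) -> None:
        if not all(0 < f <= 1 for f in self.top_fractions):
            raise ValueError("top_fractions must be in (0, 1]")
        if self.ntree_max < 1:
            raise ValueError("ntree_max must be >= 1")


def impute_by_class(x: np.ndarray, y: np.ndarray, missing: int = -1) -> np.ndarray:
    """Mean-impute missing dosages within each class (forests need complete data)."""
    out = x.astype(float).copy()
    out[x == missing] = np.nan
    for cls in np.unique(y):
        rows = y == cls
        mu = np.nanmean(out[rows], axis=0)
        mu = np.where(np.isnan(mu), np.nanmean(out, axis=0), mu)
        mu = np.where(np.isnan(mu), 0.0, mu)
        block = out[rows]
        nan_mask = np.isnan(block)
        block[nan_mask] = np.broadcast_to(mu, block.shape)[nan_mask]
        out[rows] = block
    return out


class StratifiedForest:
    """Random forest with per-class bootstrap size = min class count.

    Tracks OOB votes per tree so the OOB error curve over the number of trees
    comes from a single fit.
    """

    def __init__(self, ntree: int, mtry: int, seed: int = 0, max_depth=None):
        self.ntree = ntree
        self.mtry = mtry
        self.seed = seed
        self.max_depth = max_depth

    def fit(self, x: np.ndarray, y: np.ndarray) -> "StratifiedForest":
        rng = np.random.default_rng(self.seed)
        classes, y_idx = np.unique(y, return_inverse=True)
        if len(classes) < 2:
            raise ValueError("need >= 2 classes")
        self.classes_ = classes
        n, p = x.shape
        per_class = int(min(np.bincount(y_idx)))
        class_rows = [np.flatnonzero(y_idx == c) for c in range(len(classes))]
        self.trees_: list[DecisionTreeClassifier] = []
        self.oob_rows_: list[np.ndarray] = []
        votes = np.zeros((n, len(classes)), dtype=np.int32)
        self.oob_error_curve_ = np.full(self.ntree, np.nan)
        self._x, self._y_idx = x, y_idx
        mtry = min(self.mtry, p)
        for t in range(self.ntree):
            boot = np.concatenate([rng.choice(rows, size=per_class, replace=True)
                                   for rows in class_rows])
            oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
            tree = DecisionTreeClassifier(
                max_features=mtry, max_depth=self.max_depth,
                random_state=int(rng.integers(2**31 - 1)))
            tree.fit(x[boot], y_idx[boot])
            if len(oob):
                pred = tree.predict(x[oob])
                votes[oob, pred] += 1
            self.trees_.append(tree)
            self.oob_rows_.append(oob)
            voted = votes.sum(axis=1) > 0
            if voted.any():
                maj = votes[voted].argmax(axis=1)
                self.oob_error_curve_[t] = float(np.mean(maj != y_idx[voted]))
        self._votes = votes
        return self

    def oob_error(self) -> float:
        return float(self.oob_error_curve_[-1])

    def permutation_importance(self, rng: np.random.Generator | None = None) -> np.ndarray:
        """Mean decrease in OOB accuracy when each feature is permuted.

        All p permuted copies of the sample matrix are stacked so each tree
        predicts once, instead of once per feature.
        """
        rng = rng or np.random.default_rng(self.seed + 1)
        x, y_idx = self._x, self._y_idx
        n, p = x.shape
        base = self.oob_error()
        perm = rng.permutation(n)
        big = np.tile(x, (p, 1))
        for f in range(p):
            big[f * n:(f + 1) * n, f] = x[perm, f]
        votes = np.zeros((p, n, len(self.classes_)), dtype=np.int32)
        for tree, oob in zip(self.trees_, self.oob_rows_):
            if not len(oob):
                continue
            rows = (oob[None, :] + n * np.arange(p)[:, None]).ravel()
            pred = tree.predict(big[rows]).reshape(p, len(oob))
            for f in range(p):
                votes[f, oob, pred[f]] += 1
        imp = np.zeros(p)
        for f in range(p):
            voted = votes[f].sum(axis=1) > 0
            if voted.any():
                err = float(np.mean(votes[f][voted].argmax(axis=1) != y_idx[voted]))
                imp[f] = err - base
        return imp


def _one_se_pick(grid: np.ndarray, errors: np.ndarray, n: int):
    """First grid point whose error is within 1 SE of the minimum."""
    errors = np.asarray(errors, dtype=float)
    best = np.nanmin(errors)
    se = np.sqrt(max(best * (1 - best), 1e-12) / n)
    ok = np.flatnonzero(errors <= best + se)
    return grid[ok[0]], errors[ok[0]]


def tune_forest(x: np.ndarray, y: np.ndarray, cfg: RfConfig | None = None
                ) -> tuple[int, int, dict]:
    """Choose (ntree, mtry) by OOB-ER: tree-count curve first, then mtry grid."""
    cfg = cfg or RfConfig()
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ValueError("need >= 2 classes to tune a forest")
    x = impute_by_class(x, y)
    n, p = x.shape
    default_mtry = max(int(np.floor(np.sqrt(p))), 1)
    forest = StratifiedForest(cfg.ntree_max, default_mtry, seed=cfg.seed).fit(x, y)
    curve = forest.oob_error_curve_
    ntrees = np.arange(1, cfg.ntree_max + 1)
    stable = ntrees >= min(20, cfg.ntree_max)  # ignore the noisy first trees
    ntree_star, _ = _one_se_pick(ntrees[stable], curve[stable], n)
    grid = mtry_grid(p)
    errs = []
    for m in grid:
        f = StratifiedForest(int(ntree_star), m, seed=cfg.seed + 7 * m).fit(x, y)
        errs.append(f.oob_error())
    mtry_star, err_star = _one_se_pick(np.array(grid), np.array(errs), n)
    diag = {"oob_curve": curve, "mtry_grid": grid, "mtry_errors": errs,
            "oob_at_choice": float(err_star)}
    return int(ntree_star), int(mtry_star), diag


@dataclass
class PanelResult:
    candidate_idx: np.ndarray
    trace: pd.DataFrame          # panel_size, oob_er, oob_sd
    final_idx: np.ndarray        # indices into the input marker axis
    ntree: int
    mtry: int
    step1: pd.DataFrame = field(default_factory=pd.DataFrame)


def _replicate_forest(x, y, ntree, mtry, seed, n_rep, importance=True):
    errs, imps = [], []
    for r in range(n_rep):
        f = StratifiedForest(ntree, min(mtry, x.shape[1]), seed=seed + r).fit(x, y)
        errs.append(f.oob_error())
        if importance:
            imps.append(f.permutation_importance())
    imp = np.mean(imps, axis=0) if imps else None
    return float(np.mean(errs)), float(np.std(errs)), imp


def backward_purge(x: np.ndarray, y: np.ndarray, cfg: RfConfig | None = None,
                   ntree: int | None = None, mtry: int | None = None) -> PanelResult:
    """Two-step backward purge of an outlier-marker panel.

    Step 1 ranks all markers by permutation importance and evaluates OOB-ER on
    nested top-fraction subsets, taking the fraction one notch above the
    minimizer as a conservative candidate list. Step 2 repeatedly removes the
    lowest mean-importance marker (3 replicate forests per iteration) down to
    two markers; the panel minimizing mean OOB-ER wins (ties: smaller panel).
    """
    cfg = cfg or RfConfig()
    y = np.asarray(y)
    x = impute_by_class(x, y)
    n, p = x.shape
    if p < 3:
        raise ValueError("need >= 3 candidate markers to purge")
    if ntree is None or mtry is None:
        ntree, mtry, _ = tune_forest(x, y, cfg)

    _, _, imp_full = _replicate_forest(x, y, ntree, mtry, cfg.seed, cfg.n_purge_replicates)
    order = np.argsort(-imp_full, kind="mergesort")

    fracs = sorted(set(min(f, 1.0) for f in cfg.top_fractions))
    # the published fractions presume ~1000 candidates; with a small outlier
    # list they all truncate to a useless pool, so fall back to the full list
    if int(np.ceil(max(fracs) * p)) < min(p, 20):
        fracs.append(1.0)
    sizes, errs = [], []
    for k in sorted({max(int(np.ceil(f * p)), 2) for f in fracs}):
        sub = order[:k]
        e, _, _ = _replicate_forest(x[:, sub], y, ntree, mtry, cfg.seed + 101,
                                    cfg.n_purge_replicates, importance=False)
        sizes.append(k)
        errs.append(e)
    step1 = pd.DataFrame({"panel_size": sizes, "oob_er": errs})
    imin = int(np.argmin(errs))
    # conservative: one subset size above the minimizer, to hedge ranking noise
    take = min(imin + 1, len(sizes) - 1)
    candidate = order[:sizes[take]]
    log.info("backward_purge: step-1 candidates = %d of %d markers",
             len(candidate), p)

    panel = list(candidate)
    trace_rows = []
    panels = []
    while len(panel) >= 2:
        e, sd, imp = _replicate_forest(x[:, panel], y, ntree, mtry,
                                       cfg.seed + 1000 + len(panel), cfg.n_purge_replicates)
        trace_rows.append({"panel_size": len(panel), "oob_er": e, "oob_sd": sd})
        panels.append(list(panel))
        if len(panel) == 2:
            break
        panel.pop(int(np.argmin(imp)))
    trace = pd.DataFrame(trace_rows)
    # one-SE parsimony: the smallest panel whose mean OOB-ER is within one
    # replicate standard error of the minimum (plain arg-min overfits the
    # OOB noise toward large panels; ties always favor the smaller panel)
    errs = trace["oob_er"].to_numpy()
    sds = trace["oob_sd"].to_numpy()
    imin = int(np.argmin(errs))
    best_err = float(errs[imin])
    se = max(np.sqrt(max(best_err * (1 - best_err), 1e-12) / n), 1.0 / (2 * n))
    eligible = np.flatnonzero(errs <= best_err + se)
    final = panels[int(eligible[-1])]  # rows are ordered by shrinking size
    return PanelResult(candidate_idx=np.asarray(candidate), trace=trace,
                       final_idx=np.asarray(final), ntree=ntree, mtry=mtry,
                       step1=step1)


# ---------------------------------------------------------------------------
# DAPC-style validation
# ---------------------------------------------------------------------------

def dapc_confusion(x: np.ndarray, y: np.ndarray, var_explained: float = 0.90
                   ) -> tuple[pd.DataFrame, float]:
    """Leave-one-out DAPC confusion matrix and overall accuracy.

    PCA scores retaining >= var_explained of the panel variance feed a linear
    discriminant classifier; each sample is predicted with itself held out.
    Singular within-class covariances trigger a PC-count reduction.
    """
    from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

    y = np.asarray(y)
    x = impute_by_class(x, y)
    xc = x - x.mean(axis=0)
    u, s, _ = np.linalg.svd(xc, full_matrices=False)
    var = s**2
    frac = np.cumsum(var) / var.sum()
    n_pc = int(np.searchsorted(frac, var_explained) + 1)
    n_pc = min(n_pc, x.shape[0] - 2, x.shape[1])
    scores = u[:, :n_pc] * s[:n_pc]

    n = len(y)
    pred = np.empty(n, dtype=y.dtype)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        k = n_pc
        while k >= 1:
            try:
                lda = LinearDiscriminantAnalysis()
                lda.fit(scores[mask, :k], y[mask])
                pred[i] = lda.predict(scores[i:i + 1, :k])[0]
                break
            except np.linalg.LinAlgError:
                log.warning("dapc: singular covariance, reducing PCs to %d", k - 1)
                k -= 1
        else:
            pred[i] = pd.Series(y[mask]).mode()[0]
    classes = np.unique(y)
    conf = pd.DataFrame(0, index=classes, columns=classes)
    for t, pr in zip(y, pred):
        conf.loc[t, pr] += 1
    acc = float(np.mean(pred == y))
    return conf, acc
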