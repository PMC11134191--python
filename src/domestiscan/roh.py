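"""Sliding-window runs-of-homozygosity calling, F_ROH, and ROH islands.

The window size L and per-SNP hit threshold t are computed from the panel
(or per population, with ``RohParams.global_window=False``):

    L = ceil( ln(alpha / (n_s * n_i)) / ln(1 - mean_het) )
    t = (N_out + 1) / L, truncated to 3 decimals

with alpha the tolerated false-positive ROH rate, n_s the SNPs genotyped per
individual, n_i the number of individuals, and mean_het the mean SNP
heterozygosity. A window of L consecutive SNPs qualifies as homozygous when
it has at most 1 heterozygous call and at most 5 missing; a SNP is "in ROH"
when the fraction of qualifying windows covering it reaches t. Maximal runs
of in-ROH SNPs become segments, subject to a per-segment heterozygote
allowance, a minimum SNP count (L), a gap split, and length/density filters.

F_ROH divides each individual's summed ROH length (segments above a length
floor, 1 Mb by default) by L_TOTAL, the summed ROH length recovered from a
simulated fully homozygous individual on the same marker map and parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .gio import MISSING, GenotypeDataset, MarkerMap

log = logging.getLogger("domestiscan")

LENGTH_CLASSES = [(200_000, 500_000, "0.2-0.5Mb"), (500_000, 1_000_000, "0.5-1Mb"),
                  (1_000_000, 2_000_000, "1-2Mb"), (2_000_000, 4_000_000, "2-4Mb"),
                  (4_000_000, 8_000_000, "4-8Mb"), (8_000_000, np.inf, ">8Mb")]


@dataclass
class RohParams:
    alpha: float = 0.05
    n_out: int = 0
    max_het_in_window: int = 1
    max_missing_in_window: int = 5
    max_het_in_segment: int = 1
    min_len_bp: int = 200_000
    min_density_bp_per_snp: int = 50_000
    max_gap_bp: int = 1_000_000
    min_pop_size: int = 15          # populations at or below this are skipped
    sample_callrate_min: float = 0.90
    marker_callrate_min: float = 0.95
    pi_hat_max: float = 0.95
    global_window: bool = True      # L, t from the whole panel (not per pop)
    L: int | None = None            # override the computed window size
    t: float | None = None


def compute_window_params(n_s: int, n_i: int, mean_het: float,
                          alpha: float = 0.05, n_out: int = 0) -> tuple[int, float]:
    """Population-specific window length L and hit threshold t.

    L is rounded up (longer windows are conservative against false-positive
    ROH); t is truncated, not rounded, to 3 decimals.
    """
    if n_s < 1 or n_i < 1:
        raise ValueError("n_s and n_i must be >= 1")
    if not 0 < mean_het < 1:
        raise ValueError("mean_het must be in (0, 1)")
    L = math.ceil(math.log(alpha / (n_s * n_i)) / math.log(1.0 - mean_het))
    L = max(L, 1)
    t = math.floor((n_out + 1) / L * 1000.0) / 1000.0
    return L, t


def _length_class(length_bp: int) -> str:
    for lo, hi, name in LENGTH_CLASSES:
        if lo <= length_bp < hi:
            return name
    return "<0.2Mb"


def _segments_one_chrom(g: np.ndarray, pos: np.ndarray, L: int, t: float,
                        p: RohParams) -> list[tuple[int, int, int]]:
    """ROH segments (start_idx, end_idx, n_snps) for one individual/chromosome."""
    m = len(g)
    if m < L:
        return []
    het = (g == 1).astype(np.int32)
    mis = (g == MISSING).astype(np.int32)
    ch = np.concatenate([[0], np.cumsum(het)])
    cm = np.concatenate([[0], np.cumsum(mis)])
    n_win = m - L + 1
    w_het = ch[L:] - ch[:-L]
    w_mis = cm[L:] - cm[:-L]
    qual = (w_het <= p.max_het_in_window) & (w_mis <= p.max_missing_in_window)
    cq = np.concatenate([[0], np.cumsum(qual.astype(np.int32))])
    idx = np.arange(m)
    lo = np.maximum(0, idx - L + 1)
    hi = np.minimum(idx, n_win - 1)
    n_cover = hi - lo + 1
    n_hit = cq[hi + 1] - cq[lo]
    frac = n_hit / n_cover
    in_roh = frac >= t - 1e-12

    segs: list[tuple[int, int, int]] = []
    j = 0
    while j < m:
        if not in_roh[j]:
            j += 1
            continue
        k = j
        while k + 1 < m and in_roh[k + 1]:
            k += 1
        # split the run at inter-SNP gaps exceeding the allowed interval,
        # then greedily at every het beyond the per-segment allowance
        cut_starts = [j]
        for q in range(j, k):
            if pos[q + 1] - pos[q] > p.max_gap_bp:
                cut_starts.append(q + 1)
        cut_starts.append(k + 1)
        pieces = []
        for a, b in zip(cut_starts[:-1], cut_starts[1:]):
            b -= 1
            start, n_het = a, 0
            for q in range(a, b + 1):
                if het[q]:
                    n_het += 1
                    if n_het > p.max_het_in_segment:
                        pieces.append((start, q - 1))
                        start, n_het = q, 1
            pieces.append((start, b))
        for a, b in pieces:
            n_snps = b - a + 1
            if n_snps < L:
                continue
            length = int(pos[b] - pos[a])
            if length < p.min_len_bp:
                continue
            if length / n_snps > p.min_density_bp_per_snp:
                continue
            segs.append((a, b, n_snps))
        j = k + 1
    return segs


def _segments_one_chrom_bruteforce(g, pos, L, t, p: RohParams):
    """Windowless re-implementation of the same calling rules (test oracle)."""
    m = len(g)
    if m < L:
        return []
    qual = []
    for w in range(m - L + 1):
        win = g[w:w + L]
        qual.append(int(np.sum(win == 1)) <= p.max_het_in_window
                    and int(np.sum(win == MISSING)) <= p.max_missing_in_window)
    in_roh = []
    for i in range(m):
        hits = tot = 0
        for w in range(m - L + 1):
            if w <= i <= w + L - 1:
                tot += 1
                hits += qual[w]
        in_roh.append(tot > 0 and hits / tot >= t - 1e-12)
    segs = []
    i = 0
    while i < m:
        if not in_roh[i]:
            i += 1
            continue
        k = i
        while k + 1 < m and in_roh[k + 1]:
            k += 1
        parts, start = [], i
        for q in range(i, k):
            if pos[q + 1] - pos[q] > p.max_gap_bp:
                parts.append((start, q))
                start = q + 1
        parts.append((start, k))
        het_split = []
        for a, b in parts:
            s, seen = a, []
            for q in range(a, b + 1):
                if g[q] == 1:
                    seen.append(q)
                    if len(seen) > p.max_het_in_segment:
                        het_split.append((s, q - 1))
                        s, seen = q, [q]
            het_split.append((s, b))
        for a, b in het_split:
            n_snps = b - a + 1
            length = int(pos[b] - pos[a])
            if (n_snps >= L and length >= p.min_len_bp
                    and length / n_snps <= p.min_density_bp_per_snp):
                segs.append((a, b, n_snps))
        i = k + 1
    return segs


def call_roh_matrix(genotypes: np.ndarray, markers: MarkerMap, L: int, t: float,
                    params: RohParams, sample_ids: list[str],
                    bruteforce: bool = False) -> pd.DataFrame:
    """Call ROH on a raw dosage matrix with fixed window parameters."""
    fn = _segments_one_chrom_bruteforce if bruteforce else _segments_one_chrom
    rows = []
    chrom = markers.chrom
    pos = markers.pos
    for c in markers.chroms():
        midx = np.flatnonzero(chrom == c)
        cpos = pos[midx]
        for si, sid in enumerate(sample_ids):
            g = genotypes[si, midx]
            for a, b, n_snps in fn(g, cpos, L, t, params):
                length = int(cpos[b] - cpos[a])
                rows.append({"sample": sid, "chrom": c, "start_bp": int(cpos[a]),
                             "end_bp": int(cpos[b]), "n_snps": n_snps,
                             "length_bp": length, "length_class": _length_class(length)})
    return pd.DataFrame(rows, columns=["sample", "chrom", "start_bp", "end_bp",
                                       "n_snps", "length_bp", "length_class"])


# ---------------------------------------------------------------------------
# PI_HAT duplicate screen (method-of-moments IBD, PLINK-style)
# ---------------------------------------------------------------------------

def pi_hat_matrix(g: np.ndarray, max_markers: int = 5000, seed: int = 0) -> np.ndarray:
    """Method-of-moments PI_HAT for all pairs on a marker subset."""
    rng = np.random.default_rng(seed)
    m = g.shape[1]
    if m > max_markers:
        keep = np.sort(rng.choice(m, size=max_markers, replace=False))
        g = g[:, keep]
    obs = g != MISSING
    n = obs.sum(axis=0)
    with np.errstate(invalid="ignore"):
        p = np.where(n > 0, np.where(obs, g, 0).sum(axis=0) / (2.0 * n), np.nan)
    poly = (p > 0.01) & (p < 0.99)
    g = g[:, poly]
    p = p[poly]
    q = 1 - p
    # expected IBS-state probabilities given 0/1 alleles shared IBD
    e0_z0 = 2 * p**2 * q**2
    e1_z0 = 4 * p**3 * q + 4 * p * q**3
    e1_z1 = 2 * p**2 * q + 2 * p * q**2
    n_ind = g.shape[0]
    out = np.zeros((n_ind, n_ind))
    gm = g.astype(float)
    gm[g == MISSING] = np.nan
    for i in range(n_ind):
        for j in range(i + 1, n_ind):
            both = ~np.isnan(gm[i]) & ~np.isnan(gm[j])
            d = np.abs(gm[i, both] - gm[j, both])
            ibs0 = float(np.sum(d == 2))
            ibs1 = float(np.sum(d == 1))
            s0 = e0_z0[both].sum()
            s1_0 = e1_z0[both].sum()
            s1_1 = e1_z1[both].sum()
            z0 = min(max(ibs0 / s0 if s0 > 0 else 0.0, 0.0), 1.0)
            z1 = (ibs1 - s1_0 * z0) / s1_1 if s1_1 > 0 else 0.0
            z1 = min(max(z1, 0.0), 1.0 - z0)
            z2 = 1.0 - z0 - z1
            out[i, j] = out[j, i] = z2 + 0.5 * z1
    return out


# ---------------------------------------------------------------------------
# Pipeline: per-population QC + calling + F_ROH
# ---------------------------------------------------------------------------

def call_roh(ds: GenotypeDataset, params: RohParams | None = None
             ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Population-by-population ROH calling with the standard QC.

    Per population: individuals with call rate below the cutoff are dropped,
    near-duplicates (PI_HAT above threshold) removed, low-call-rate markers
    dropped; populations at or below the size floor are skipped with a
    warning. Window parameters are recomputed per population unless
    overridden. Returns (segments, per-population metadata incl. L, t and the
    simulated-homozygote L_TOTAL).
    """
    p = params or RohParams()
    global_Lt = None
    if p.L is not None:
        t = p.t if p.t is not None else math.floor(1000.0 * (p.n_out + 1) / p.L) / 1000.0
        global_Lt = (p.L, t)
    elif p.global_window:
        obs = ds.genotypes != MISSING
        with np.errstate(invalid="ignore"):
            het_by_snp = (ds.genotypes == 1).sum(axis=0) / np.maximum(obs.sum(axis=0), 1)
        global_Lt = compute_window_params(ds.n_markers, ds.n_samples,
                                          float(np.nanmean(het_by_snp)), p.alpha, p.n_out)
    seg_frames, meta = [], []
    for pop in ds.pops():
        idx = ds.samples_of(pop)
        g = ds.genotypes[idx]
        sids = [ds.sample_ids[i] for i in idx]
        callrate = (g != MISSING).mean(axis=1)
        keep = callrate > p.sample_callrate_min
        g, sids = g[keep], [s for s, k in zip(sids, keep) if k]
        if len(sids) > 1:
            ph = pi_hat_matrix(g)
            drop = set()
            for i in range(len(sids)):
                for j in range(i + 1, len(sids)):
                    if ph[i, j] > p.pi_hat_max and j not in drop and i not in drop:
                        drop.add(j)
            if drop:
                log.warning("roh: pop %s dropping %d near-duplicate samples", pop, len(drop))
                keep2 = [i for i in range(len(sids)) if i not in drop]
                g, sids = g[keep2], [sids[i] for i in keep2]
        if len(sids) <= p.min_pop_size:
            log.warning("roh: population %s has %d samples (<= %d), skipped",
                        pop, len(sids), p.min_pop_size)
            continue
        mkeep = (g != MISSING).mean(axis=0) >= p.marker_callrate_min
        g = g[:, mkeep]
        markers = ds.markers.subset(np.flatnonzero(mkeep))
        obs = g != MISSING
        with np.errstate(invalid="ignore"):
            het_by_snp = np.where(obs.sum(axis=0) > 0,
                                  (g == 1).sum(axis=0) / np.maximum(obs.sum(axis=0), 1), np.nan)
        mean_het = float(np.nanmean(het_by_snp))
        if global_Lt is not None:
            L, t = global_Lt
        else:
            L, t = compute_window_params(g.shape[1], len(sids), mean_het, p.alpha, p.n_out)
        segs = call_roh_matrix(g, markers, L, t, p, sids)
        l_total = simulated_homozygote_l_total(markers, L, t, p)
        seg_frames.append(segs)
        meta.append({"pop": pop, "n_samples": len(sids), "n_markers": g.shape[1],
                     "mean_het": mean_het, "L": L, "t": t, "l_total_bp": l_total,
                     "samples": sids})
    segments = (pd.concat(seg_frames, ignore_index=True) if seg_frames
                else pd.DataFrame(columns=["sample", "chrom", "start_bp", "end_bp",
                                           "n_snps", "length_bp", "length_class"]))
    return segments, pd.DataFrame(meta)


def simulated_homozygote_l_total(markers: MarkerMap, L: int, t: float,
                                 params: RohParams) -> int:
    """L_TOTAL: summed ROH length of a fully homozygous simulated individual."""
    g = np.zeros((1, len(markers)), dtype=np.int8)
    segs = call_roh_matrix(g, markers, L, t, params, ["__homozygote__"])
    return int(segs["length_bp"].sum())


def froh(segments: pd.DataFrame, l_total_bp: float, samples: list[str],
         min_len: int = 1_000_000) -> pd.DataFrame:
    """Per-sample F_ROH = sum of qualifying segment lengths / L_TOTAL."""
    if l_total_bp <= 0:
        raise ValueError("l_total_bp must be > 0")
    use = segments[segments["length_bp"] > min_len] if len(segments) else segments
    sums = use.groupby("sample")["length_bp"].sum() if len(use) else pd.Series(dtype=float)
    rows = [{"sample": s, "sum_roh_bp": float(sums.get(s, 0.0)),
             "l_total_bp": float(l_total_bp),
             "froh": float(sums.get(s, 0.0)) / l_total_bp} for s in samples]
    return pd.DataFrame(rows)


def froh_all(segments: pd.DataFrame, meta: pd.DataFrame, ds: GenotypeDataset,
             min_len: int = 1_000_000) -> pd.DataFrame:
    """F_ROH for every retained sample, using its population's L_TOTAL."""
    frames = []
    for _, row in meta.iterrows():
        t = froh(segments[segments["sample"].isin(row["samples"])],
                 row["l_total_bp"], row["samples"], min_len)
        t["pop"] = row["pop"]
        t["class"] = ds.pop_class[row["pop"]]
        frames.append(t)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["sample", "sum_roh_bp", "l_total_bp", "froh", "pop", "class"])


def roh_incidence(segments: pd.DataFrame, markers: MarkerMap, n_individuals: int,
                  island_quantile: float = 0.99) -> tuple[np.ndarray, list]:
    """Per-marker fraction of individuals whose ROH cover it, plus islands.

    Islands are maximal runs of markers whose incidence is at or above the
    given quantile of the positive part of the track.
    """
    inc = np.zeros(len(markers))
    chrom = markers.chrom
    pos = markers.pos
    for _, seg in segments.iterrows():
        sel = (chrom == seg["chrom"]) & (pos >= seg["start_bp"]) & (pos <= seg["end_bp"])
        inc[sel] += 1
    inc = inc / max(n_individuals, 1)
    islands = []
    if inc.max() > 0:
        thresh = np.quantile(inc, island_quantile)
        thresh = max(thresh, 1e-12)
        above = inc >= thresh
        for c in markers.chroms():
            midx = np.flatnonzero(chrom == c)
            a = above[midx]
            j = 0
            while j < len(a):
                if a[j]:
                    k = j
                    while k + 1 < len(a) and a[k + 1]:
                        k += 1
                    islands.append((c, int(pos[midx[j]]), int(pos[midx[k]])))
                    j = k + 1
                else:
                    j += 1
    return inc, islands
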