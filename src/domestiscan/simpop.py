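"""Forward Wright-Fisher simulator of wild populations and derived captive strains.

The simulator is the pipeline's test substrate: it produces a multi-chromosome
SNP panel for several wild progenitor populations plus captive strains derived
from them by 1-17 generations of small-N breeding, optional admixture crosses
between strains, and per-locus viability selection -- together with ground
truth (pedigree inbreeding, realized number of breeders per generation, the
selected-locus list, and identity-by-descent tracts from founder labels).

Model choices (deliberately minimal, but sufficient to create background LD,
LD decay, drift differentiation and ROH):

* each chromosome has a fixed genetic length (default 1 Morgan); crossovers
  are Poisson with no interference;
* wild populations start from a Beta-distributed spread of allele frequencies
  around shared ancestral frequencies (the Beta F parameter is calibrated for
  the extra drift accumulated during burn-in so the realized mean pairwise
  Weir-Cockerham FST lands near the requested target), then run >=20
  burn-in generations of random mating at ``wild_Ne`` to build linkage
  disequilibrium;
* captive strains draw sexed broodstock each generation, mate randomly across
  sexes with (optionally overdispersed) family sizes, and apply viability
  selection multiplying survival by (1+s) per selected-allele copy;
* no mutation (array SNPs pre-exist); monomorphic markers are retained.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gio import GenotypeDataset, MarkerMap, write_popmap, write_vcf


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class StrainSpec:
    """Breeding history of one captive strain."""

    name: str
    source_pop: str
    n_broodstock_female: int
    n_broodstock_male: int
    generations: int
    selected_loci: list[tuple[int, float]] = field(default_factory=list)  # (marker index, s)
    admix_from: tuple[str, float] | None = None  # (other strain, founder proportion)
    cohort_size: int = 200
    overdispersion: float = 0.0  # Gamma-shape knob for sweepstakes variance

    def __post_init__(self) -> None:
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.n_broodstock_female < 1 or self.n_broodstock_male < 1:
            raise ValueError("need at least one broodstock of each sex")
        for _, s in self.selected_loci:
            if s < 0:
                raise ValueError("selection coefficient s must be >= 0")


@dataclass
class SimConfig:
    n_chrom: int = 10
    chrom_len_bp: int = 10_000_000
    n_markers_per_chrom: int = 300
    wild_Ne: int = 600
    n_wild_pops: int = 4
    wild_Fst_target: float = 0.03
    strain_specs: list[StrainSpec] = field(default_factory=list)
    seed: int = 0
    burn_in: int = 20
    samples_per_pop: int = 30
    morgans_per_chrom: float = 1.0
    calibration_rounds: int = 2
    anchor_freq: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_len_bp", "n_markers_per_chrom", "wild_Ne",
                     "n_wild_pops", "samples_per_pop"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0.0 <= self.wild_Fst_target <= 0.1:
            raise ValueError("wild_Fst_target must be in [0, 0.1]")
        if self.burn_in < 20:
            raise ValueError("burn_in must be >= 20 generations")


def subseed(seed: int, name: str) -> int:
    """Deterministic sub-seed for a named stage (stable across stage toggles)."""
    return (int(seed) * 1_000_003 + zlib.crc32(name.encode())) % (2**31 - 1)


# ---------------------------------------------------------------------------
# Genome machinery
# ---------------------------------------------------------------------------

@dataclass
class Genome:
    """Marker coordinates shared by every simulated population."""

    markers: MarkerMap
    chrom_slices: list[slice]
    gpos: list[np.ndarray]  # genetic position (Morgans) per chromosome
    morgans: float

    @classmethod
    def sample(cls, cfg: SimConfig, rng: np.random.Generator) -> "Genome":
        rows = []
        slices, gpos = [], []
        start = 0
        for c in range(cfg.n_chrom):
            chrom = f"chr{c + 1}"
            pos = np.sort(rng.choice(np.arange(1, cfg.chrom_len_bp + 1),
                                     size=cfg.n_markers_per_chrom, replace=False))
            for p in pos:
                rows.append((f"c{c + 1:02d}_p{int(p):09d}", chrom, int(p), "A", "G"))
            slices.append(slice(start, start + len(pos)))
            gpos.append(pos / cfg.chrom_len_bp * cfg.morgans_per_chrom)
            start += len(pos)
        return cls(MarkerMap(pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])),
                   slices, gpos, cfg.morgans_per_chrom)

    @property
    def n_markers(self) -> int:
        return len(self.markers)


@dataclass
class Population:
    """Internal haplotype store: alleles (N, 2, M) plus optional founder labels."""

    haps: np.ndarray                 # int8, (N, 2, M)
    labels: np.ndarray | None = None  # int32, (N, 2, M) founder-haplotype ids

    @property
    def size(self) -> int:
        return self.haps.shape[0]

    def dosages(self) -> np.ndarray:
        return self.haps.sum(axis=1).astype(np.int8)


def _meiosis(rng, genome: Genome, parent_haps, parent_labels=None):
    """Vectorized meiosis: one gamete per row of ``parent_haps``.

    parent_haps : (G, 2, M) parental diplotypes (already gathered per gamete).
    Returns (G, M) gamete alleles (and labels when given), using identical
    crossover points for both tracks.
    """
    G = parent_haps.shape[0]
    out = np.empty((G, genome.n_markers), dtype=parent_haps.dtype)
    out_lab = None
    if parent_labels is not None:
        out_lab = np.empty((G, genome.n_markers), dtype=parent_labels.dtype)
    for sl, gp in zip(genome.chrom_slices, genome.gpos):
        m = sl.stop - sl.start
        k = rng.poisson(genome.morgans, G)
        total = int(k.sum())
        xpos = rng.uniform(0.0, genome.morgans, total)
        gam_idx = np.repeat(np.arange(G), k)
        ci = np.searchsorted(gp, xpos)
        flips = np.zeros((G, m + 1), dtype=np.int16)
        np.add.at(flips, (gam_idx, ci), 1)
        start = rng.integers(0, 2, G).astype(np.int16)
        which = (np.cumsum(flips[:, :m], axis=1) + start[:, None]) % 2
        h0 = parent_haps[:, 0, sl]
        h1 = parent_haps[:, 1, sl]
        out[:, sl] = np.where(which == 0, h0, h1)
        if out_lab is not None:
            out_lab[:, sl] = np.where(which == 0, parent_labels[:, 0, sl], parent_labels[:, 1, sl])
    return out, out_lab


def _offspring(rng, genome, pop: Population, mothers, fathers) -> Population:
    """Form one offspring per (mother, father) index pair."""
    gm, lm = _meiosis(rng, genome, pop.haps[mothers],
                      None if pop.labels is None else pop.labels[mothers])
    gf, lf = _meiosis(rng, genome, pop.haps[fathers],
                      None if pop.labels is None else pop.labels[fathers])
    haps = np.stack([gm, gf], axis=1)
    labels = None if pop.labels is None else np.stack([lm, lf], axis=1)
    return Population(haps, labels)


def _random_pairs(rng, n_ind, n_off):
    """Random distinct (mother, father) pairs for a monoecious population."""
    mothers = rng.integers(0, n_ind, n_off)
    fathers = rng.integers(0, n_ind, n_off)
    clash = mothers == fathers
    while clash.any():
        fathers[clash] = rng.integers(0, n_ind, int(clash.sum()))
        clash = mothers == fathers
    return mothers, fathers


# ---------------------------------------------------------------------------
# Wild populations
# ---------------------------------------------------------------------------

@dataclass
class WildSim:
    genome: Genome
    populations: dict[str, Population]
    ancestral_freq: np.ndarray
    realized_fst: float

    def export(self, pop: str, n: int, rng: np.random.Generator) -> np.ndarray:
        """Dosage matrix for ``n`` sampled individuals of one population."""
        p = self.populations[pop]
        idx = rng.choice(p.size, size=n, replace=False)
        return p.dosages()[idx]


def _mean_pairwise_theta(genome: Genome, pops: dict[str, Population], max_n: int = 60) -> float:
    from .popstats import wc_fst_counts

    names = list(pops)
    thetas = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            g1 = pops[names[i]].dosages()[:max_n]
            g2 = pops[names[j]].dosages()[:max_n]
            thetas.append(wc_fst_counts([g1, g2]))
    return float(np.mean(thetas))


def simulate_wild(cfg: SimConfig, genome: Genome | None = None) -> WildSim:
    """Simulate ``n_wild_pops`` wild populations with background LD.

    Per-population starting allele frequencies are Beta-spread around shared
    ancestral frequencies; the Beta F is calibrated (analytically, then by a
    short measure-and-adjust loop) so that the realized mean pairwise
    Weir-Cockerham FST approximates ``wild_Fst_target`` after ``burn_in``
    generations of random-mating drift at ``wild_Ne``.
    """
    root = np.random.default_rng(subseed(cfg.seed, "wild"))
    if genome is None:
        genome = Genome.sample(cfg, root)
    anc = root.uniform(0.05, 0.95, genome.n_markers)
    for idx, p in cfg.anchor_freq.items():
        anc[idx] = p

    # drift accumulated during burn-in, as an inbreeding-style F
    drift = 1.0 - (1.0 - 1.0 / (2.0 * cfg.wild_Ne)) ** cfg.burn_in
    target = cfg.wild_Fst_target
    if target > 0 and target < 0.25 * drift:
        raise ValueError(
            f"infeasible wild_Fst_target {target}: burn-in drift alone contributes ~{drift:.4f}")
    f_beta = max(0.0, 1.0 - (1.0 - target) / (1.0 - drift))

    realized = np.nan
    pops: dict[str, Population] = {}
    tol = max(0.01, 0.3 * target)
    for attempt in range(max(1, cfg.calibration_rounds)):
        rng = np.random.default_rng(subseed(cfg.seed, f"wild_round{attempt}"))
        pops = {}
        for k in range(cfg.n_wild_pops):
            if f_beta > 1e-9:
                a = anc * (1.0 - f_beta) / f_beta
                b = (1.0 - anc) * (1.0 - f_beta) / f_beta
                p0 = rng.beta(a, b)
            else:
                p0 = anc.copy()
            haps = (rng.random((cfg.wild_Ne, 2, genome.n_markers)) < p0).astype(np.int8)
            pop = Population(haps)
            for _ in range(cfg.burn_in):
                mothers, fathers = _random_pairs(rng, pop.size, cfg.wild_Ne)
                pop = _offspring(rng, genome, pop, mothers, fathers)
            pops[f"W{k + 1}"] = pop
        if cfg.n_wild_pops < 2:
            realized = np.nan
            break
        realized = _mean_pairwise_theta(genome, pops)
        if abs(realized - target) <= tol:
            break
        # one multiplicative nudge of the Beta spread, then give up gracefully
        f_beta = float(np.clip(f_beta + (target - realized), 0.0, 0.5))
    return WildSim(genome, pops, anc, realized)


# ---------------------------------------------------------------------------
# Captive strains
# ---------------------------------------------------------------------------

@dataclass
class StrainTruth:
    name: str
    expected_nb: list[float]          # 4NfNm/(Nf+Nm) per generation
    demographic_nb: list[float]       # family-size-corrected Nb per generation
    pedigree_f: np.ndarray            # per final-cohort individual
    selected_loci: list[tuple[int, float]]
    admix_fraction: np.ndarray | None  # per-individual admixture ancestry
    ibd_tracts: list[list[tuple[str, int, int]]]  # per exported individual

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "expected_nb": self.expected_nb,
            "demographic_nb": self.demographic_nb,
            "pedigree_f": np.asarray(self.pedigree_f).tolist(),
            "selected_loci": [[int(i), float(s)] for i, s in self.selected_loci],
            "admix_fraction": None if self.admix_fraction is None
            else np.asarray(self.admix_fraction).tolist(),
            "n_ibd_tracts": [len(t) for t in self.ibd_tracts],
        }


def _crow_denniston_nb(counts_f: np.ndarray, counts_m: np.ndarray) -> float:
    """Nb from realized family sizes, per sex, combined harmonically."""
    def one_sex(k):
        n, kbar = len(k), k.mean()
        if kbar <= 0:
            return np.nan
        vk = k.var(ddof=0)
        denom = kbar - 1.0 + vk / kbar
        if denom <= 0:
            return np.inf
        return (n * kbar - 2.0) / denom
    ne_f, ne_m = one_sex(counts_f), one_sex(counts_m)
    if not np.isfinite(ne_f) or not np.isfinite(ne_m):
        return np.inf
    return 4.0 * ne_f * ne_m / (ne_f + ne_m)


def _viability_select(rng, cohort: Population, selected: list[tuple[int, float]]) -> np.ndarray:
    """Boolean survivor mask under multiplicative per-copy viability (1+s).

    Fitness is relative: survival probabilities are normalized by the batch
    maximum, which preserves the selection differential while keeping
    absolute survival realistic for multi-locus selection.
    """
    if not selected:
        return np.ones(cohort.size, dtype=bool)
    idx = np.array([i for i, _ in selected])
    s = np.array([sv for _, sv in selected])
    dos = cohort.haps[:, :, idx].sum(axis=1)  # (N, n_sel)
    logw = (dos * np.log1p(s)).sum(axis=1)
    w = np.exp(logw - logw.max())
    return rng.random(cohort.size) < w


def derive_strain(wild: WildSim, spec: StrainSpec, seed: int,
                  strain_pool: dict[str, Population] | None = None
                  ) -> tuple[Population, StrainTruth]:
    """Breed a captive strain from a wild source population.

    Each generation samples sexed broodstock, mates randomly across sexes with
    Poisson (optionally overdispersed) family sizes, applies viability
    selection at the configured loci, and records pedigree-based truth.
    """
    rng = np.random.default_rng(subseed(seed, f"strain_{spec.name}"))
    source = wild.populations[spec.source_pop]
    n_found = spec.n_broodstock_female + spec.n_broodstock_male
    if n_found > source.size:
        raise ValueError("broodstock counts exceed wild population size")

    # --- founders, possibly mixed from another strain -------------------
    from_admix = np.zeros(n_found, dtype=bool)
    if spec.admix_from is not None:
        other_name, prop = spec.admix_from
        if strain_pool is None or other_name not in strain_pool:
            raise ValueError(f"admixture source strain {other_name!r} not available")
        n_admix = int(round(prop * n_found))
        from_admix[rng.choice(n_found, size=n_admix, replace=False)] = True
    n_src = int((~from_admix).sum())
    src_idx = rng.choice(source.size, size=n_src, replace=False)
    founders_haps = np.empty((n_found, 2, wild.genome.n_markers), dtype=np.int8)
    founders_haps[~from_admix] = source.haps[src_idx]
    if from_admix.any():
        other = strain_pool[spec.admix_from[0]]
        o_idx = rng.choice(other.size, size=int(from_admix.sum()), replace=False)
        founders_haps[from_admix] = other.haps[o_idx]
    labels = np.arange(2 * n_found, dtype=np.int32).reshape(n_found, 2, 1)
    labels = np.broadcast_to(labels, founders_haps.shape).copy()
    label_is_admix = np.repeat(from_admix, 2)  # founder-haplotype id -> origin
    cohort = Population(founders_haps, labels)

    # sexes and kinship of the founding broodstock
    females = np.arange(spec.n_broodstock_female)
    males = np.arange(spec.n_broodstock_female, n_found)
    kin = np.eye(n_found) * 0.5  # founders unrelated, non-inbred

    expected_nb, demographic_nb = [], []
    fem_idx, male_idx = females, males
    for gen in range(1, spec.generations + 1):
        nf, nm = len(fem_idx), len(male_idx)
        expected_nb.append(4.0 * nf * nm / (nf + nm))

        def parent_probs(n):
            if spec.overdispersion > 0:
                w = rng.gamma(1.0 / spec.overdispersion, spec.overdispersion, n)
                return w / w.sum()
            return np.full(n, 1.0 / n)

        survivors_h, survivors_l, survivors_m, survivors_f = [], [], [], []
        n_have, tries = 0, 0
        pf, pm = parent_probs(nf), parent_probs(nm)
        while n_have < spec.cohort_size:
            if tries >= 30:
                raise RuntimeError(
                    f"strain {spec.name}: population extinct under selection at generation {gen}")
            batch = max(spec.cohort_size, 2 * (spec.cohort_size - n_have))
            mothers = fem_idx[rng.choice(nf, batch, p=pf)]
            fathers = male_idx[rng.choice(nm, batch, p=pm)]
            off = _offspring(rng, wild.genome, cohort, mothers, fathers)
            alive = _viability_select(rng, off, spec.selected_loci)
            survivors_h.append(off.haps[alive])
            survivors_l.append(off.labels[alive])
            survivors_m.append(mothers[alive])
            survivors_f.append(fathers[alive])
            n_have += int(alive.sum())
            tries += 1
        haps = np.concatenate(survivors_h)[: spec.cohort_size]
        labs = np.concatenate(survivors_l)[: spec.cohort_size]
        moms = np.concatenate(survivors_m)[: spec.cohort_size]
        dads = np.concatenate(survivors_f)[: spec.cohort_size]

        counts_f = np.bincount(moms, minlength=cohort.size)[fem_idx].astype(float)
        counts_m = np.bincount(dads, minlength=cohort.size)[male_idx].astype(float)
        demographic_nb.append(_crow_denniston_nb(counts_f, counts_m))

        # kinship recursion: offspring x offspring from parental kinships
        kmm = kin[np.ix_(moms, moms)]
        kmf = kin[np.ix_(moms, dads)]
        kfm = kin[np.ix_(dads, moms)]
        kff = kin[np.ix_(dads, dads)]
        new_kin = 0.25 * (kmm + kmf + kfm + kff)
        f_off = kin[moms, dads]
        np.fill_diagonal(new_kin, 0.5 * (1.0 + f_off))
        kin = new_kin
        cohort = Population(haps, labs)

        if gen < spec.generations:
            perm = rng.permutation(cohort.size)
            fem_idx = perm[: spec.n_broodstock_female]
            male_idx = perm[spec.n_broodstock_female:
                            spec.n_broodstock_female + spec.n_broodstock_male]

    pedigree_f = np.diag(kin) * 2.0 - 1.0
    admix_fraction = None
    if spec.admix_from is not None:
        admix_fraction = label_is_admix[cohort.labels].mean(axis=(1, 2))

    # IBD tracts from founder labels (autozygosity per individual)
    tracts: list[list[tuple[str, int, int]]] = []
    chroms = wild.genome.markers.chroms()
    pos = wild.genome.markers.pos
    auto = cohort.labels[:, 0, :] == cohort.labels[:, 1, :]
    for i in range(cohort.size):
        ind_tracts = []
        for ci, sl in enumerate(wild.genome.chrom_slices):
            a = auto[i, sl]
            p = pos[sl]
            j = 0
            while j < len(a):
                if a[j]:
                    k = j
                    while k + 1 < len(a) and a[k + 1]:
                        k += 1
                    ind_tracts.append((chroms[ci], int(p[j]), int(p[k])))
                    j = k + 1
                else:
                    j += 1
        tracts.append(ind_tracts)

    truth = StrainTruth(spec.name, expected_nb, demographic_nb, pedigree_f,
                        spec.selected_loci, admix_fraction, tracts)
    return cohort, truth


# ---------------------------------------------------------------------------
# Panel assembly
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    strains: dict[str, StrainTruth]
    realized_wild_fst: float
    selected_loci: list[tuple[int, float]]
    marker_ids: np.ndarray
    sample_pedigree_f: dict[str, float]  # per exported sample id

    def to_dict(self) -> dict:
        return {
            "realized_wild_fst": self.realized_wild_fst,
            "selected_loci": [[int(i), float(s)] for i, s in self.selected_loci],
            "selected_marker_ids": [str(self.marker_ids[i]) for i, _ in self.selected_loci],
            "strains": {k: v.to_dict() for k, v in self.strains.items()},
            "sample_pedigree_f": self.sample_pedigree_f,
        }


def default_demo_config(seed: int = 0) -> SimConfig:
    """The default demonstration panel: 6 wild populations, 6 captive strains.

    Mirrors the sampling design of a multi-strain domestication study: several
    wild progenitor populations with modest differentiation, plus independent
    strains with 3-6 generations of small-N breeding. Ten parallel
    domestication-selected loci (the mid-chromosome marker of every
    chromosome, anchored to ancestral frequency 0.5) are shared by all
    strains with s = 1.0 -- parallel selection across independent strains is
    what the pooled wild-vs-selected scan is designed to detect. Strain S6 is
    an admixture cross (half its founders from strain S1).
    """
    cfg = SimConfig(seed=seed, n_wild_pops=6)
    m = cfg.n_markers_per_chrom
    sel_idx = [c * m + m // 2 for c in range(cfg.n_chrom)]
    sel = [(i, 1.0) for i in sel_idx]
    cfg.anchor_freq = {i: 0.5 for i in sel_idx}
    cfg.strain_specs = [
        StrainSpec("S1", "W1", 12, 8, 4, selected_loci=sel),
        StrainSpec("S2", "W2", 10, 10, 5, selected_loci=sel),
        StrainSpec("S3", "W3", 15, 10, 3, selected_loci=sel),
        StrainSpec("S4", "W4", 8, 8, 6, selected_loci=sel),
        StrainSpec("S5", "W5", 20, 15, 3, selected_loci=sel),
        StrainSpec("S6", "W1", 12, 12, 3, selected_loci=sel, admix_from=("S1", 0.5)),
        StrainSpec("S7", "W2", 10, 10, 4, selected_loci=sel),
        StrainSpec("S8", "W6", 12, 10, 5, selected_loci=sel),
        StrainSpec("S9", "W3", 10, 8, 4, selected_loci=sel),
    ]
    return cfg


def assemble_panel(cfg: SimConfig, out_dir=None) -> tuple[GenotypeDataset, SimTruth]:
    """Simulate the full panel and (optionally) write VCF/popmap/truth JSON."""
    wild = simulate_wild(cfg)
    rng = np.random.default_rng(subseed(cfg.seed, "assemble"))

    genos, ids, pop_of_sample, pop_class = [], [], {}, {}
    sample_f: dict[str, float] = {}

    for pop in wild.populations:
        dos = wild.export(pop, min(cfg.samples_per_pop, wild.populations[pop].size), rng)
        for i in range(dos.shape[0]):
            sid = f"{pop}_{i + 1:03d}"
            ids.append(sid)
            pop_of_sample[sid] = pop
            sample_f[sid] = 0.0
        pop_class[pop] = "wild"
        genos.append(dos)

    strain_pool: dict[str, Population] = {}
    truths: dict[str, StrainTruth] = {}
    all_selected: dict[int, float] = {}
    for spec in cfg.strain_specs:
        cohort, truth = derive_strain(wild, spec, cfg.seed, strain_pool)
        strain_pool[spec.name] = cohort
        idx = rng.choice(cohort.size, size=min(cfg.samples_per_pop, cohort.size), replace=False)
        dos = cohort.dosages()[idx]
        for rank, i in enumerate(idx):
            sid = f"{spec.name}_{rank + 1:03d}"
            ids.append(sid)
            pop_of_sample[sid] = spec.name
            sample_f[sid] = float(truth.pedigree_f[i])
        pop_class[spec.name] = "selected"
        genos.append(dos)
        truth.pedigree_f = truth.pedigree_f[idx]
        truth.ibd_tracts = [truth.ibd_tracts[i] for i in idx]
        if truth.admix_fraction is not None:
            truth.admix_fraction = truth.admix_fraction[idx]
        truths[spec.name] = truth
        for i, s in spec.selected_loci:
            all_selected[i] = max(all_selected.get(i, 0.0), s)

    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sample ids in assembled panel")
    ds = GenotypeDataset(np.concatenate(genos, axis=0), ids, pop_of_sample,
                         pop_class, wild.genome.markers)
    ds.validate()
    truth = SimTruth(truths, wild.realized_fst, sorted(all_selected.items()),
                     wild.genome.markers.ids, sample_f)

    if out_dir is not None:
        import os
        os.makedirs(out_dir, exist_ok=True)
        write_vcf(ds, os.path.join(out_dir, "panel.vcf"))
        write_popmap(ds, os.path.join(out_dir, "popmap.tsv"))
        with open(os.path.join(out_dir, "truth.json"), "w") as fh:
            json.dump(truth.to_dict(), fh, indent=1)
    return ds, truth
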