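"""Genotype I/O and the in-memory data model shared by the whole pipeline.

The central container is :class:`GenotypeDataset`: a samples x markers matrix of
alt-allele dosages (0/1/2, -1 for missing) for unphased diploid biallelic SNP
data, plus a marker map (chromosome, 1-based position, alleles), a sample ->
population map and a population -> class (wild/selected) map.

Internal coordinates are 0-based half-open; VCF POS is converted on I/O and BED
input is taken as already 0-based half-open.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger("domestiscan")

MISSING = -1

_MAP_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class PopmapError(ValueError):
    """Sample/population-map mismatch."""


def _as_marker_frame(markers) -> pd.DataFrame:
    df = pd.DataFrame(markers, columns=_MAP_COLUMNS) if not isinstance(markers, pd.DataFrame) else markers.copy()
    missing = set(_MAP_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"marker map missing columns: {sorted(missing)}")
    df = df.reset_index(drop=True)
    df["pos"] = df["pos"].astype(np.int64)
    return df


@dataclass
class MarkerMap:
    """Per-marker metadata: id, chrom, 1-based bp position, (ref, alt) alleles.

    Markers are kept sorted by (chrom, pos); positions must be unique within a
    chromosome.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = _as_marker_frame(self.table)

    def __len__(self) -> int:
        return len(self.table)

    @property
    def ids(self) -> np.ndarray:
        return self.table["id"].to_numpy()

    @property
    def chrom(self) -> np.ndarray:
        return self.table["chrom"].to_numpy()

    @property
    def pos(self) -> np.ndarray:
        return self.table["pos"].to_numpy()

    def chroms(self) -> list[str]:
        """Chromosome labels in map order."""
        return list(dict.fromkeys(self.table["chrom"]))

    def sort_order(self) -> np.ndarray:
        """Stable order sorting by (chrom-first-appearance, pos)."""
        chrom_rank = {c: i for i, c in enumerate(self.chroms())}
        ranks = self.table["chrom"].map(chrom_rank).to_numpy()
        return np.lexsort((self.pos, ranks))

    def is_sorted(self) -> bool:
        order = self.sort_order()
        return bool(np.all(order == np.arange(len(order))))

    def validate(self) -> None:
        if not self.is_sorted():
            raise ValueError("marker map not sorted by (chrom, pos)")
        for c, grp in self.table.groupby("chrom", sort=False):
            if grp["pos"].duplicated().any():
                raise ValueError(f"duplicate positions on chromosome {c}")

    def subset(self, idx) -> "MarkerMap":
        return MarkerMap(self.table.iloc[np.asarray(idx)].reset_index(drop=True))


@dataclass
class GenotypeDataset:
    """Diploid biallelic genotype panel with population labels.

    Attributes
    ----------
    genotypes : int8 ndarray, shape (n_samples, n_markers)
        Alt-allele dosage in {0, 1, 2}; ``MISSING`` (-1) for no-calls.
    sample_ids : list of str
    pop_of_sample : dict sample -> population label
    pop_class : dict population -> "wild" | "selected"
    markers : MarkerMap
    """

    genotypes: np.ndarray
    sample_ids: list[str]
    pop_of_sample: dict[str, str]
    pop_class: dict[str, str]
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)

    # -- shape helpers -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def pops(self) -> list[str]:
        """Population labels in order of first appearance among samples."""
        return list(dict.fromkeys(self.pop_of_sample[s] for s in self.sample_ids))

    def pop_labels(self) -> np.ndarray:
        return np.array([self.pop_of_sample[s] for s in self.sample_ids])

    def class_labels(self) -> np.ndarray:
        return np.array([self.pop_class[self.pop_of_sample[s]] for s in self.sample_ids])

    def samples_of(self, pop: str) -> np.ndarray:
        labels = self.pop_labels()
        return np.flatnonzero(labels == pop)

    # -- subsetting ----------------------------------------------------
    def subset_markers(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        return replace(self, genotypes=self.genotypes[:, idx], markers=self.markers.subset(idx))

    def subset_samples(self, idx) -> "GenotypeDataset":
        idx = np.asarray(idx)
        ids = [self.sample_ids[i] for i in idx]
        pom = {s: self.pop_of_sample[s] for s in ids}
        pops = set(pom.values())
        pc = {p: c for p, c in self.pop_class.items() if p in pops}
        return replace(self, genotypes=self.genotypes[idx], sample_ids=ids,
                       pop_of_sample=pom, pop_class=pc)

    def select_pops(self, pops) -> "GenotypeDataset":
        keep = [i for i, s in enumerate(self.sample_ids) if self.pop_of_sample[s] in set(pops)]
        return self.subset_samples(keep)

    # -- basic statistics ----------------------------------------------
    def allele_freq(self, sample_idx=None) -> np.ndarray:
        """Pooled alt-allele frequency per marker (NaN where all missing)."""
        g = self.genotypes if sample_idx is None else self.genotypes[np.asarray(sample_idx)]
        obs = g != MISSING
        n = obs.sum(axis=0)
        tot = np.where(obs, g, 0).sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n > 0, tot / (2.0 * n), np.nan)

    def validate(self) -> None:
        g = self.genotypes
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D")
        if g.shape[0] != len(self.sample_ids):
            raise ValueError("sample count mismatch")
        if g.shape[1] != len(self.markers):
            raise ValueError("marker count does not equal map length")
        bad = ~np.isin(g, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("dosages must be in {0,1,2,missing}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        for s in self.sample_ids:
            if s not in self.pop_of_sample:
                raise PopmapError(f"sample {s!r} has no population")
        for p in set(self.pop_of_sample[s] for s in self.sample_ids):
            if p not in self.pop_class:
                raise ValueError(f"population {p!r} has no class")
            if self.pop_class[p] not in ("wild", "selected"):
                raise ValueError(f"population class must be wild/selected, got {self.pop_class[p]!r}")
        self.markers.validate()


@dataclass
class RegionSet:
    """Genomic intervals, 0-based half-open (standard BED semantics)."""

    intervals: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for chrom, start, end in self.intervals:
            if not start < end:
                raise ValueError(f"empty/inverted interval {chrom}:{start}-{end}")

    def __len__(self) -> int:
        return len(self.intervals)

    def mask(self, markers: MarkerMap) -> np.ndarray:
        """Boolean per-marker array: True where the marker falls in a region."""
        hit = np.zeros(len(markers), dtype=bool)
        chrom = markers.chrom
        pos0 = markers.pos - 1  # 1-based bp -> 0-based coordinate
        for c, start, end in self.intervals:
            hit |= (chrom == c) & (pos0 >= start) & (pos0 < end)
        return hit


@dataclass
class QMatrix:
    """Per-sample admixture proportions across K clusters (rows sum to 1)."""

    q: np.ndarray
    sample_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if self.q.ndim != 2:
            raise ValueError("Q matrix must be 2-D")
        if (self.q < -1e-9).any():
            raise ValueError("admixture proportions must be nonnegative")
        sums = self.q.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-3:
            bad = int(np.argmax(np.abs(sums - 1.0)))
            raise ValueError(f"Q row {bad} sums to {sums[bad]:.4f}, not 1")
        self.q = self.q / sums[:, None]

    @property
    def k(self) -> int:
        return self.q.shape[1]


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_popmap(path) -> tuple[dict[str, str], dict[str, str]]:
    """Read a 2/3-column popmap TSV: sample, population[, class]."""
    pop_of_sample: dict[str, str] = {}
    pop_class: dict[str, str] = {}
    warned_default = False
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (2, 3):
                raise ValueError(f"{path}:{ln}: expected 2 or 3 columns, got {len(parts)}")
            sample, pop = parts[0], parts[1]
            pop_of_sample[sample] = pop
            if len(parts) == 3:
                cls = parts[2]
                if cls not in ("wild", "selected"):
                    raise ValueError(f"{path}:{ln}: class must be wild/selected, got {cls!r}")
                if pop_class.get(pop, cls) != cls:
                    raise ValueError(f"{path}:{ln}: conflicting class for population {pop!r}")
                pop_class[pop] = cls
            else:
                if not warned_default:
                    log.warning("popmap %s has no class column; defaulting populations to 'wild'", path)
                    warned_default = True
                pop_class.setdefault(pop, "wild")
    for pop in set(pop_of_sample.values()):
        pop_class.setdefault(pop, "wild")
    return pop_of_sample, pop_class


def read_vcf(path, popmap_path) -> GenotypeDataset:
    """Load a biallelic-SNP VCF (GT field only) plus its popmap.

    Multi-allelic or non-SNP records are skipped with a logged count. Samples
    missing from the popmap raise :class:`PopmapError` naming the sample.
    """
    from cyvcf2 import VCF

    pop_of_sample, pop_class = read_popmap(popmap_path)
    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    absent = [s for s in samples if s not in pop_of_sample]
    if absent:
        raise PopmapError(f"samples absent from popmap: {absent[:5]}")

    rows = []
    geno_cols = []
    skipped = 0
    for var in vcf:
        alts = var.ALT
        if len(alts) != 1 or len(var.REF) != 1 or len(alts[0]) != 1:
            skipped += 1
            continue
        # gts012: 0/1/2 dosage, 3 = missing
        g = np.asarray(var.gt_types, dtype=np.int8)
        g[g == 3] = MISSING
        geno_cols.append(g)
        vid = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        rows.append((vid, var.CHROM, var.POS, var.REF, alts[0]))
    if skipped:
        log.warning("read_vcf: skipped %d non-biallelic-SNP records", skipped)
    if rows:
        geno = np.stack(geno_cols, axis=1)
    else:
        geno = np.zeros((len(samples), 0), dtype=np.int8)
    markers = MarkerMap(pd.DataFrame(rows, columns=_MAP_COLUMNS))
    ds = GenotypeDataset(geno, samples, pop_of_sample, pop_class, markers)
    if len(markers) and not markers.is_sorted():
        log.info("read_vcf: input markers unsorted; sorting by (chrom, pos)")
        ds = ds.subset_markers(markers.sort_order())
    ds.validate()
    return ds


def write_vcf(ds: GenotypeDataset, path) -> None:
    """Write the dataset as a minimal VCF 4.2 with GT calls only."""
    gt_str = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    tab = ds.markers.table
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=domestiscan\n")
        for chrom in ds.markers.chroms():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(ds.sample_ids) + "\n")
        g = ds.genotypes
        for j in range(ds.n_markers):
            row = tab.iloc[j]
            calls = "\t".join(gt_str[int(x)] for x in g[:, j])
            fh.write(f"{row.chrom}\t{row.pos}\t{row.id}\t{row.ref}\t{row.alt}"
                     f"\t.\tPASS\t.\tGT\t{calls}\n")


def write_popmap(ds: GenotypeDataset, path) -> None:
    with open(path, "w") as fh:
        for s in ds.sample_ids:
            pop = ds.pop_of_sample[s]
            fh.write(f"{s}\t{pop}\t{ds.pop_class[pop]}\n")


def read_regions(path) -> RegionSet:
    """Read a BED file of excluded regions (0-based half-open)."""
    intervals = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED line needs >=3 fields")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start >= end:
                raise ValueError(f"{path}:{ln}: start must be < end")
            intervals.append((parts[0], start, end))
    return RegionSet(intervals)


def read_qmatrix(path, has_sample_column: bool | None = None) -> QMatrix:
    """Read a tab-delimited admixture-proportion matrix.

    Rows are renormalized only if their sum is within 1e-3 of 1; anything
    further off raises a line-numbered error.
    """
    rows, ids = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if has_sample_column is None:
                try:
                    float(parts[0])
                    has_sample_column = False
                except ValueError:
                    has_sample_column = True
            if has_sample_column:
                ids.append(parts[0])
                parts = parts[1:]
            try:
                vec = [float(x) for x in parts]
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: malformed Q row") from exc
            if abs(sum(vec) - 1.0) > 1e-3:
                raise ValueError(f"{path}:{ln}: Q row sums to {sum(vec):.4f}, not 1")
            rows.append(vec)
    if rows and len({len(r) for r in rows}) != 1:
        raise ValueError(f"{path}: inconsistent column counts")
    return QMatrix(np.array(rows, dtype=float), ids or None)


def read_annotation(marker_gene_path, gene_term_path):
    """Read marker->gene and gene->term 2-column TSV tables.

    Returns (marker_gene, gene_term) DataFrames with columns
    (marker_id, gene_id) and (gene_id, term_id).
    """
    def _read(path, cols):
        recs = []
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise ValueError(f"{path}:{ln}: expected 2 columns, got {len(parts)}")
                recs.append(parts)
        return pd.DataFrame(recs, columns=cols)

    return (_read(marker_gene_path, ["marker_id", "gene_id"]),
            _read(gene_term_path, ["gene_id", "term_id"]))
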