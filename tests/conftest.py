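"""Shared fixtures: tiny handcrafted datasets and one session-scoped demo run."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import pytest

from domestiscan.gio import GenotypeDataset, MarkerMap
from domestiscan.qcfilter import FilterConfig, apply_filters, ld_clump
from domestiscan.simpop import assemble_panel, default_demo_config

logging.getLogger("domestiscan").setLevel(logging.ERROR)


def make_dataset(genotypes, positions=None, chrom=None, pops=None, classes=None,
                 sample_prefix="s") -> GenotypeDataset:
    """Small GenotypeDataset from a dosage matrix (helper for handcrafted cases)."""
    g = np.asarray(genotypes, dtype=np.int8)
    n, m = g.shape
    positions = np.arange(1, m + 1) * 1000 if positions is None else np.asarray(positions)
    chrom = ["chr1"] * m if chrom is None else list(chrom)
    ids = [f"{sample_prefix}{i}" for i in range(n)]
    pops = ["P1"] * n if pops is None else list(pops)
    classes = classes or {}
    pop_class = {p: classes.get(p, "wild") for p in set(pops)}
    markers = MarkerMap(pd.DataFrame({
        "id": [f"m{j}" for j in range(m)], "chrom": chrom,
        "pos": positions, "ref": "A", "alt": "G"}))
    ds = GenotypeDataset(g, ids, dict(zip(ids, pops)), pop_class, markers)
    ds.validate()
    return ds


@pytest.fixture(scope="session")
def demo():
    """The default demonstration panel (seed 1) with its simulator truth."""
    return assemble_panel(default_demo_config(seed=1))


@pytest.fixture(scope="session")
def demo_full(demo):
    ds, _ = demo
    full, report = apply_filters(ds, FilterConfig())
    return full, report


@pytest.fixture(scope="session")
def demo_clumped(demo_full):
    full, _ = demo_full
    return ld_clump(full, FilterConfig())


@pytest.fixture(scope="session")
def demo_scan(demo_full, demo_clumped):
    from domestiscan.genoscan import scan

    full, _ = demo_full
    return scan(full, demo_clumped)


@pytest.fixture(scope="session")
def demo_decay(demo_full):
    from domestiscan.lddecay import decay_curves

    full, _ = demo_full
    return decay_curves(full, seed=5)


@pytest.fixture(scope="session")
def demo_roh(demo_full):
    from domestiscan.roh import RohParams, call_roh, froh_all

    full, _ = demo_full
    segments, meta = call_roh(full, RohParams())
    return segments, meta, froh_all(segments, meta, full)


@pytest.fixture(scope="session")
def demo_ne(demo_full):
    from domestiscan.ne_ld import estimate_ne_all

    full, _ = demo_full
    return estimate_ne_all(full, n_snps=2000, seed=3, compute_ci=False)


@pytest.fixture(scope="session")
def demo_panel(demo_full, demo_scan):
    from domestiscan.panelrf import RfConfig, backward_purge, dapc_confusion

    full, _ = demo_full
    table, _ = demo_scan
    union = table.loc[table["outlier_union"], "marker_id"].tolist()
    keep = np.flatnonzero(np.isin(full.markers.ids, union))
    x = full.genotypes[:, keep]
    y = full.class_labels()
    result = backward_purge(x, y, RfConfig(ntree_max=200, seed=5))
    conf, acc = dapc_confusion(x[:, result.final_idx], y)
    return result, conf, acc
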