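"""Shared fixtures: small synthetic libraries and fragment files."""

from __future__ import annotations

import numpy as np
import pytest

from sebula.fragments import HclcTable
from sebula.model import SebulaModel, fit_model
from sebula.simulate import SimConfig, hclc_table_from_sim, simulate_hclc


@pytest.fixture(scope="session")
def sim20() -> tuple:
    """Standard benchmark library: 10,000 cells, 20% pair-sum doublets."""
    sim = simulate_hclc(SimConfig(n_cells=10_000, doublet_prop=0.2, seed=1))
    return sim, hclc_table_from_sim(sim)


@pytest.fixture(scope="session")
def model20(sim20) -> SebulaModel:
    _, table = sim20
    return fit_model(table, 0)


@pytest.fixture(scope="session")
def null_table() -> HclcTable:
    """Pure singlet library (no doublets)."""
    sim = simulate_hclc(SimConfig(n_cells=10_000, doublet_prop=0.0, seed=7))
    return hclc_table_from_sim(sim)


@pytest.fixture()
def toy_fragments(tmp_path):
    """Write a tiny hand-crafted fragment file plus whitelist."""
    rows = [
        # cellA: three overlapping fragments on chr1 -> one locus
        ("chr1", 100, 200, "A", 1),
        ("chr1", 120, 210, "A", 2),
        ("chr1", 150, 260, "A", 1),
        # cellA: isolated fragment, no locus
        ("chr1", 5000, 5100, "A", 1),
        # cellB: one fragment overlapping cellA's locus region
        ("chr1", 190, 300, "B", 1),
        # cellB: own locus on chr2
        ("chr2", 40, 140, "B", 1),
        ("chr2", 60, 150, "B", 1),
        ("chr2", 80, 160, "B", 1),
        # chrX fragment: filtered by autosome default
        ("chrX", 10, 100, "A", 1),
        # oversize insert: filtered
        ("chr1", 0, 950, "B", 1),
    ]
    path = tmp_path / "fragments.tsv"
    with open(path, "w") as fh:
        fh.write("# comment line\n")
        for r in rows:
            fh.write("\t".join(str(v) for v in r) + "\n")
    barcodes = tmp_path / "barcodes.txt"
    barcodes.write_text("A\nB\nC\n")
    return path, barcodes
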