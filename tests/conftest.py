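"""Shared fixtures: hand-built toy tables and seeded synthetic panels."""

from __future__ import annotations

import numpy as np
import pytest

from breedcomp import (
    BNConfig,
    ChromosomeTable,
    GenotypeTable,
    MarkerRecord,
    SampleRecord,
    balding_nichols_panel,
    fit_reference,
    panel_layout,
)


@pytest.fixture
def toy_markers() -> list[MarkerRecord]:
    return [
        MarkerRecord("m1", "1", 100, "A", "G"),
        MarkerRecord("m2", "1", 200, "C", "T"),
        MarkerRecord("m3", "2", 50, "G", "A"),
    ]


@pytest.fixture
def toy_table(toy_markers) -> GenotypeTable:
    samples = [
        SampleRecord("s1", "alpha"),
        SampleRecord("s2", "beta"),
    ]
    calls = np.array([[2, 1, 0], [0, -1, 2]], dtype=np.int8)
    return GenotypeTable(toy_markers, samples, calls)


@pytest.fixture
def small_chrom_table() -> ChromosomeTable:
    return ChromosomeTable(("1", "2", "3"), (100.0, 80.0, 60.0))


def _two_breed_opposite_table(n_per_breed: int = 3, n_markers: int = 8) -> GenotypeTable:
    """Two breeds fixed for opposite alleles at every marker."""
    markers = [MarkerRecord(f"m{j}", "1", 10 + j * 10, "A", "G") for j in range(n_markers)]
    samples = [SampleRecord(f"a{i}", "alpha") for i in range(n_per_breed)] + [
        SampleRecord(f"b{i}", "beta") for i in range(n_per_breed)
    ]
    calls = np.vstack(
        [np.full((n_per_breed, n_markers), 2), np.full((n_per_breed, n_markers), 0)]
    ).astype(np.int8)
    return GenotypeTable(markers, samples, calls)


@pytest.fixture
def opposite_breeds_table() -> GenotypeTable:
    return _two_breed_opposite_table()


@pytest.fixture(scope="session")
def small_panel():
    """K=3, light marker set: fast fits for unit tests."""
    cfg = BNConfig(n_breeds=3, n_per_breed=20, n_markers=600, fst=0.2, seed=11)
    panel, haps, freqs = balding_nichols_panel(cfg)
    return panel, haps, freqs


@pytest.fixture(scope="session")
def study_panel():
    """The study-scale panel: K=5 breeds, 50 each, 7,000 markers, F=0.2."""
    cfg = BNConfig(n_breeds=5, n_per_breed=50, n_markers=7000, fst=0.2, seed=1)
    panel, haps, freqs = balding_nichols_panel(cfg)
    return panel, haps, freqs


@pytest.fixture(scope="session")
def study_model(study_panel):
    panel, _haps, _freqs = study_panel
    model, centroids = fit_reference(panel.table, shrinkage=True)
    return model, centroids


@pytest.fixture(scope="session")
def study_layout(study_panel):
    panel, _haps, _freqs = study_panel
    return panel_layout(panel)
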