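"""Synthetic multi-breed data with known ground truth.

Real multi-breed genotype collections are proprietary, so every other
module is exercised against generated panels.  Breed allele frequencies
follow the Balding-Nichols model: around an ancestral frequency p drawn
uniformly from configurable bounds, each breed draws
p_k ~ Beta(p (1-F)/F, (1-p)(1-F)/F), giving E[p_k] = p and
Var[p_k] = F p (1-p).  The single differentiation knob F plays the role
that drift and selection play in real breed divergence; the default
desk-scale panel (K=5 breeds, 50 per breed, 7,000 markers) mirrors a
curated 50-per-breed panel genotyped on a ~7k cross-assay marker
intersection.

The model has no linkage disequilibrium and no breed-specific demography;
markers are exchangeable given their frequencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chromosomes import ChromosomeTable
from .curation import ReferencePanel
from .genotype_io import GenotypeTable, MarkerManifest, MarkerRecord, SampleRecord
from .simulate import GenomeLayout


@dataclass(frozen=True)
class BNConfig:
    """Balding-Nichols panel configuration."""

    n_breeds: int = 5
    n_per_breed: int = 50
    n_markers: int = 7000
    fst: float = 0.2
    freq_bounds: tuple[float, float] = (0.1, 0.9)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_breeds < 2:
            raise ValueError("need at least 2 breeds")
        if self.n_markers < 1:
            raise ValueError("need at least 1 marker")
        if not 0.0 < self.fst < 1.0:
            raise ValueError("F must be in (0, 1)")
        lo, hi = self.freq_bounds
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("frequency bounds must satisfy 0 < lo < hi < 1")


def place_markers(
    n_markers: int, chrom_table: ChromosomeTable, rng: np.random.Generator
) -> list[MarkerRecord]:
    """Scatter markers uniformly over a chromosome table (largest-remainder
    allocation of counts proportional to length, positions sorted)."""
    lengths = np.array([chrom_table.length_bp(c) for c in chrom_table.labels],
                       dtype=float)
    quota = n_markers * lengths / lengths.sum()
    counts = np.floor(quota).astype(int)
    for i in np.argsort(-(quota - counts))[: n_markers - counts.sum()]:
        counts[i] += 1
    markers: list[MarkerRecord] = []
    idx = 0
    for c, cnt in zip(chrom_table.labels, counts):
        L = chrom_table.length_bp(c)
        pos = np.unique(rng.integers(1, L, size=cnt, dtype=np.int64))
        while pos.size < cnt:  # duplicate collisions are vanishingly rare
            extra = rng.integers(1, L, size=cnt - pos.size, dtype=np.int64)
            pos = np.unique(np.concatenate([pos, extra]))
        pos.sort()
        for p in pos:
            markers.append(MarkerRecord(f"SNP{idx:06d}", c, int(p), "A", "G"))
            idx += 1
    return markers


def balding_nichols_panel(
    config: BNConfig, chrom_table: ChromosomeTable | None = None
) -> tuple[ReferencePanel, np.ndarray, np.ndarray]:
    """Generate a K-breed panel: (panel, phased haplotypes, breed frequencies).

    Haplotypes have shape (K*n, 2, S) with allele 1 = the counted A1
    allele; frequencies have shape (K, S) and are the per-breed
    Balding-Nichols draws (frequency of allele 1).
    """
    rng = np.random.default_rng(config.seed)
    chrom_table = chrom_table or ChromosomeTable.umd31()
    markers = place_markers(config.n_markers, chrom_table, rng)

    lo, hi = config.freq_bounds
    p_anc = rng.uniform(lo, hi, size=config.n_markers)
    F = config.fst
    a = p_anc * (1.0 - F) / F
    b = (1.0 - p_anc) * (1.0 - F) / F
    breed_freqs = rng.beta(a, b, size=(config.n_breeds, config.n_markers))

    n_total = config.n_breeds * config.n_per_breed
    haplotypes = np.empty((n_total, 2, config.n_markers), dtype=np.uint8)
    samples: list[SampleRecord] = []
    for k in range(config.n_breeds):
        sl = slice(k * config.n_per_breed, (k + 1) * config.n_per_breed)
        haplotypes[sl] = (
            rng.random((config.n_per_breed, 2, config.n_markers)) < breed_freqs[k]
        ).astype(np.uint8)
        samples.extend(
            SampleRecord(f"breed{k + 1}_s{i:03d}", f"breed{k + 1}", "synthetic")
            for i in range(config.n_per_breed)
        )
    calls = haplotypes.sum(axis=1).astype(np.int8)
    table = GenotypeTable(markers, samples, calls)
    return ReferencePanel(table), haplotypes, breed_freqs


def panel_layout(
    panel: ReferencePanel, chrom_table: ChromosomeTable | None = None
) -> GenomeLayout:
    """Resolve a panel's marker map against a chromosome table."""
    return GenomeLayout(chrom_table or ChromosomeTable.umd31(),
                        tuple(panel.table.markers))


def make_admixed_samples(
    panel: ReferencePanel,
    haplotypes: np.ndarray,
    layout: GenomeLayout,
    pairs: Sequence[tuple[str, str]],
    lam: float,
    rng: np.random.Generator,
) -> tuple[GenotypeTable, dict[str, dict[str, float]]]:
    """Plant admixed samples: each chromosome copy comes from a random
    member of breed A with probability ``lam``, else breed B.

    Returned samples carry breed A as their (false) breed of registry;
    the second return value maps sample id to its realized, length-
    weighted true composition.
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError("lam must be in [0, 1]")
    table = panel.table
    by_breed = {b: [i for i, s in enumerate(table.samples) if s.breed == b]
                for b in table.breeds}
    samples: list[SampleRecord] = []
    calls = np.empty((len(pairs), table.n_markers), dtype=np.int8)
    truths: dict[str, dict[str, float]] = {}
    total_bp = layout.covered_length_bp
    for i, (ba, bb) in enumerate(pairs):
        for b in (ba, bb):
            if b not in by_breed:
                raise KeyError(f"breed {b} not in panel")
        sid = f"admix{i:03d}_{ba}x{bb}"
        hap = np.empty((2, table.n_markers), dtype=np.uint8)
        truth = {ba: 0.0, bb: 0.0}
        for c, (j, k) in layout.slices.items():
            L = layout.chrom_table.length_bp(c)
            for h in range(2):
                src_breed = ba if rng.random() < lam else bb
                donor = int(rng.choice(by_breed[src_breed]))
                donor_hap = int(rng.integers(2))
                hap[h, j:k] = haplotypes[donor, donor_hap, j:k]
                truth[src_breed] += L / (2.0 * total_bp)
        calls[i] = hap.sum(axis=0)
        samples.append(SampleRecord(sid, ba, "synthetic"))
        truths[sid] = truth
    return GenotypeTable(list(table.markers), samples, calls), truths


def make_manifests(
    marker_names: Sequence[str],
    n_assays: int,
    overlap: int,
    rng: np.random.Generator,
) -> list[MarkerManifest]:
    """Assay manifests sharing a designed intersection of ``overlap`` names.

    A random core of ``overlap`` markers appears on every assay; each
    remaining marker is assigned to exactly one assay, so for two or more
    assays the intersection is exactly the core.
    """
    names = list(marker_names)
    if overlap > len(names):
        raise ValueError(f"overlap {overlap} exceeds {len(names)} markers")
    if n_assays < 1:
        raise ValueError("need at least one assay")
    perm = rng.permutation(len(names))
    core = [names[i] for i in perm[:overlap]]
    rest = [names[i] for i in perm[overlap:]]
    extras: list[list[str]] = [[] for _ in range(n_assays)]
    for i, name in enumerate(rest):
        extras[i % n_assays].append(name)
    manifests = []
    for a in range(n_assays):
        content = sorted(core + extras[a], key=names.index)
        manifests.append(MarkerManifest(f"assay{a + 1}", tuple(content)))
    return manifests


def founder_pedigree(table: GenotypeTable) -> "PedigreeGraph":
    """A pedigree declaring every sample a herdbook founder of its breed."""
    from .pedigree import PedigreeGraph, PedigreeRecord

    return PedigreeGraph(
        PedigreeRecord(s.id, None, None, s.breed or "unknown", founder=True)
        for s in table.samples
    )


def backcross_pedigree(
    n_backcrosses: int, breed_a: str = "breedA", breed_b: str = "breedB"
) -> tuple["PedigreeGraph", str]:
    """A grading-up series: F1 then repeated backcrosses to purebred sires
    of ``breed_a``.  Returns (graph, id of the final-generation animal)
    whose expected breed_a fraction is 1 - 1/2^(n_backcrosses + 1)."""
    from .pedigree import PedigreeGraph, PedigreeRecord

    records = [
        PedigreeRecord("foundA0", None, None, breed_a, founder=True),
        PedigreeRecord("foundB0", None, None, breed_b, founder=True),
        PedigreeRecord("x0", "foundA0", "foundB0", breed_a),
    ]
    last = "x0"
    for g in range(1, n_backcrosses + 1):
        sire = f"foundA{g}"
        records.append(PedigreeRecord(sire, None, None, breed_a, founder=True))
        records.append(PedigreeRecord(f"x{g}", sire, last, breed_a))
        last = f"x{g}"
    return PedigreeGraph(records), last
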