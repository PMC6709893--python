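"""Forward simulation of admixed genomes with breed-of-origin tracking.

Starting from phased reference haplotypes labeled by breed, each
generation of random mating samples two distinct parents and draws one
recombinant gamete per parent and chromosome.  The crossover count per
chromosome is Poisson with mean = chromosome length in Mb / 100 (about
1 cM/Mb; e.g. ~1.58 Morgans for bovine chromosome 1 on UMD3.1),
breakpoints uniform in physical position, no interference.  Alleles and
origin labels travel together, so every simulated allele knows which
breed it came from.

The exact ("true") composition of an individual attributes to each allele
the genomic fragment reaching from the midpoint of the interval to the
previous marker to the midpoint of the interval to the next (chromosome
ends extend to 0 and L), sums fragments per origin breed across both
haplotypes, and divides by twice the autosomal length so the vector sums
to 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .chromosomes import ChromosomeTable
from .genotype_io import GenotypeTable, MarkerRecord, SampleRecord


@dataclass(frozen=True)
class GenomeLayout:
    """Marker map resolved against a chromosome table.

    Markers must be sorted by chromosome (table order) then position, with
    strictly increasing positions within a chromosome and no position past
    the chromosome end.
    """

    chrom_table: ChromosomeTable
    markers: tuple[MarkerRecord, ...]
    # per-chromosome [start, stop) marker index ranges, in table order
    slices: dict[str, tuple[int, int]] = field(init=False, repr=False)
    fragment_bp: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        positions = np.array([m.position_bp for m in self.markers], dtype=np.int64)
        chroms = [m.chromosome for m in self.markers]
        slices: dict[str, tuple[int, int]] = {}
        frag = np.zeros(len(self.markers), dtype=float)
        j = 0
        order = {c: i for i, c in enumerate(self.chrom_table.labels)}
        last_order = -1
        while j < len(self.markers):
            c = chroms[j]
            if c not in order:
                raise ValueError(f"marker {self.markers[j].name}: chromosome {c} "
                                 "not in chromosome table")
            if order[c] <= last_order:
                raise ValueError("markers not sorted by chromosome-table order")
            last_order = order[c]
            k = j
            while k < len(self.markers) and chroms[k] == c:
                k += 1
            pos = positions[j:k]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"chromosome {c}: marker positions not strictly increasing")
            L = self.chrom_table.length_bp(c)
            if pos[-1] > L:
                raise ValueError(
                    f"chromosome {c}: marker at {pos[-1]} bp exceeds length {L} bp"
                )
            # fragment boundaries: 0, midpoints, L
            bounds = np.concatenate(([0.0], (pos[:-1] + pos[1:]) / 2.0, [float(L)]))
            frag[j:k] = np.diff(bounds)
            slices[c] = (j, k)
            j = k
        object.__setattr__(self, "slices", slices)
        object.__setattr__(self, "fragment_bp", frag)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def covered_length_bp(self) -> float:
        """Total length of chromosomes carrying markers (normalizer basis)."""
        return float(sum(self.chrom_table.length_bp(c) for c in self.slices))

    @property
    def positions_bp(self) -> np.ndarray:
        return np.array([m.position_bp for m in self.markers], dtype=np.int64)


@dataclass
class SimIndividual:
    """One simulated diploid: phased alleles and per-allele breed of origin."""

    id: str
    generation: int
    alleles: np.ndarray   # (2, n_markers) uint8 in {0, 1}
    origins: np.ndarray   # (2, n_markers) int16 breed indices


@dataclass
class SimCohort:
    """Non-overlapping generations of simulated individuals plus ground truth."""

    layout: GenomeLayout
    breed_labels: tuple[str, ...]
    generations: dict[int, list[SimIndividual]] = field(default_factory=dict)

    def true_composition(self, individual: SimIndividual) -> np.ndarray:
        return true_composition(individual, self.layout, len(self.breed_labels))

    def true_compositions(self, generation: int) -> np.ndarray:
        return np.stack([
            self.true_composition(ind) for ind in self.generations[generation]
        ])

    def genotype_table(self, generation: int, assay: str | None = None) -> GenotypeTable:
        """Dosage table for one generation (dosage counts the A1 allele,
        which is haplotype value 1)."""
        inds = self.generations[generation]
        calls = np.stack([ind.alleles.sum(axis=0) for ind in inds]).astype(np.int8)
        samples = [SampleRecord(ind.id, None, assay) for ind in inds]
        return GenotypeTable(list(self.layout.markers), samples, calls)

    def write_truth_tsv(self, generation: int, dest) -> None:
        from .genotype_io import _open_text

        comps = self.true_compositions(generation)
        with _open_text(dest, "w") as fh:
            fh.write("id\t" + "\t".join(self.breed_labels) + "\n")
            for ind, row in zip(self.generations[generation], comps):
                fh.write(ind.id + "\t" + "\t".join(f"{v:.6f}" for v in row) + "\n")

    def write_segments_tsv(self, generation: int, dest) -> None:
        """Origin segments as chrom, start, end (0-based half-open), hap, breed."""
        from .genotype_io import _open_text

        pos = self.layout.positions_bp
        with _open_text(dest, "w") as fh:
            fh.write("id\tchrom\tstart\tend\thaplotype\tbreed\n")
            for ind in self.generations[generation]:
                for c, (j, k) in self.layout.slices.items():
                    L = self.layout.chrom_table.length_bp(c)
                    bounds = np.concatenate(
                        ([0.0], (pos[j:k - 1] + pos[j + 1:k]) / 2.0, [float(L)])
                    ) if k - j > 1 else np.array([0.0, float(L)])
                    for h in range(2):
                        runs = _runs(ind.origins[h, j:k])
                        for start_i, stop_i, origin in runs:
                            fh.write(
                                f"{ind.id}\t{c}\t{int(bounds[start_i])}\t"
                                f"{int(bounds[stop_i])}\t{h}\t"
                                f"{self.breed_labels[origin]}\n"
                            )


def _runs(values: np.ndarray) -> list[tuple[int, int, int]]:
    """Contiguous equal-value runs as (start, stop, value) index triples."""
    out = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            out.append((start, i, int(values[start])))
            start = i
    return out


def founder_individuals(
    haplotypes: np.ndarray,
    breeds: Sequence[str],
    breed_labels: Sequence[str],
    ids: Sequence[str] | None = None,
) -> list[SimIndividual]:
    """Wrap phased reference haplotypes (n, 2, S) as generation-0 individuals
    whose every allele is labeled with the carrier's own breed."""
    haplotypes = np.asarray(haplotypes, dtype=np.uint8)
    n = haplotypes.shape[0]
    index = {b: i for i, b in enumerate(breed_labels)}
    ids = list(ids) if ids is not None else [f"ref{i}" for i in range(n)]
    out = []
    for i in range(n):
        origins = np.full_like(haplotypes[i], index[breeds[i]], dtype=np.int16)
        out.append(SimIndividual(ids[i], 0, haplotypes[i].copy(), origins))
    return out


def draw_crossovers(length_mb: float, rng: np.random.Generator) -> np.ndarray:
    """Crossover breakpoints for one chromosome: Poisson(length_mb / 100)
    count, positions uniform on (0, length_mb), sorted.  Returned in Mb."""
    n_x = int(rng.poisson(length_mb / 100.0))
    return np.sort(rng.uniform(0.0, length_mb, size=n_x))


def make_gamete(
    parent: SimIndividual,
    layout: GenomeLayout,
    rng: np.random.Generator,
    recombination: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """One recombinant gamete: per chromosome, Poisson(L_Mb/100) crossovers
    at uniform physical positions, starting strand by fair coin.

    Returns (alleles, origins), each of length n_markers.
    """
    alleles = np.empty(layout.n_markers, dtype=np.uint8)
    origins = np.empty(layout.n_markers, dtype=np.int16)
    pos = layout.positions_bp
    for c, (j, k) in layout.slices.items():
        L_mb = layout.chrom_table.length_mb(c)
        breaks = draw_crossovers(L_mb, rng) if recombination else np.empty(0)
        start = int(rng.integers(2))
        if breaks.size == 0:
            strand = np.full(k - j, start)
        else:
            strand = (start + np.searchsorted(breaks * 1e6, pos[j:k], side="left")) % 2
        idx = np.arange(j, k)
        alleles[j:k] = parent.alleles[strand, idx]
        origins[j:k] = parent.origins[strand, idx]
    return alleles, origins


def simulate_generations(
    reference: Sequence[SimIndividual],
    layout: GenomeLayout,
    breed_labels: Sequence[str],
    n_generations: int,
    n_out: int,
    rng: np.random.Generator,
    recombination: bool = True,
) -> SimCohort:
    """Random mating for ``n_generations`` non-overlapping generations.

    Each offspring draws two *distinct* parents uniformly from the
    previous generation (no selfing) and one gamete from each.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    cohort = SimCohort(layout, tuple(breed_labels), {0: list(reference)})
    for g in range(1, n_generations + 1):
        prev = cohort.generations[g - 1]
        if len(prev) < 2:
            raise ValueError(f"generation {g - 1} has fewer than 2 individuals")
        offspring = []
        for i in range(n_out):
            pi = rng.choice(len(prev), size=2, replace=False)
            a1, o1 = make_gamete(prev[pi[0]], layout, rng, recombination)
            a2, o2 = make_gamete(prev[pi[1]], layout, rng, recombination)
            offspring.append(SimIndividual(
                f"g{g}_{i}", g, np.stack([a1, a2]), np.stack([o1, o2])
            ))
        cohort.generations[g] = offspring
    return cohort


def true_composition(
    individual: SimIndividual, layout: GenomeLayout, n_breeds: int
) -> np.ndarray:
    """Exact breed composition from traced origins and midpoint fragments.

    Each allele contributes its marker's fragment length to its origin
    breed; totals are divided by 2 x covered autosomal length so the
    result lies on the simplex.
    """
    frag = layout.fragment_bp
    counts = (
        np.bincount(individual.origins[0], weights=frag, minlength=n_breeds)
        + np.bincount(individual.origins[1], weights=frag, minlength=n_breeds)
    )
    return counts / (2.0 * layout.covered_length_bp)
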