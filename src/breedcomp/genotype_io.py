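"""Genotype container plus PLINK-text and EIGENSTRAT readers/writers.

The analysis-ready object is a :class:`GenotypeTable`: a samples x markers
matrix of counted-allele dosages (0/1/2, ``-1`` for missing) together with
the marker map and per-sample metadata (breed of registry, genotyping
assay).  Dosage counts the A1 allele, defined as the first non-missing
allele symbol encountered for that marker in file order, which matches the
PLINK text convention and makes allele-orientation flips detectable.

Multi-assay datasets are combined by intersecting assay manifests (plain
marker-name lists), extracting the shared markers from each per-assay
table, and merging with per-marker allele reconciliation: a pure A1/A2
swap flips dosages d -> 2 - d; A/T and C/G strand-ambiguous markers are
merged only on an exact allele match because a swap there is
indistinguishable from a strand flip.
"""

from __future__ import annotations

import io
import os
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

MISSING = -1
VALID_ALLELES = frozenset("ACGT0")
_AMBIGUOUS_PAIRS = {frozenset({"A", "T"}), frozenset({"C", "G"})}


class GenotypeParseError(ValueError):
    """Malformed PED/MAP/EIGENSTRAT content."""


def _chrom_key(label: str) -> tuple[int, int | str]:
    """Sort key: numeric chromosomes first in numeric order, then others."""
    return (0, int(label)) if label.isdigit() else (1, label)


@dataclass(frozen=True)
class MarkerRecord:
    """One SNP: name, map position and the (A1, A2) allele pair."""

    name: str
    chromosome: str
    position_bp: int
    a1: str
    a2: str

    def __post_init__(self) -> None:
        if self.position_bp < 0:
            raise ValueError(f"marker {self.name}: negative position")
        for a in (self.a1, self.a2):
            if a not in VALID_ALLELES:
                raise ValueError(f"marker {self.name}: invalid allele {a!r}")
        if self.a1 == self.a2 and self.a1 != "0":
            raise ValueError(f"marker {self.name}: identical alleles {self.a1}")

    @property
    def allele_set(self) -> frozenset:
        return frozenset(a for a in (self.a1, self.a2) if a != "0")

    @property
    def is_strand_ambiguous(self) -> bool:
        return self.allele_set in _AMBIGUOUS_PAIRS


@dataclass(frozen=True)
class SampleRecord:
    id: str
    breed: str | None = None
    assay: str | None = None


@dataclass
class GenotypeTable:
    """Samples x markers dosage matrix with marker map and sample metadata."""

    markers: list[MarkerRecord]
    samples: list[SampleRecord]
    calls: np.ndarray  # (n_samples, n_markers) int8; -1 = missing

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.markers)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.markers)} markers"
            )
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError("calls contain values outside {0,1,2,missing}")
        names = [m.name for m in self.markers]
        if len(set(names)) != len(names):
            raise ValueError("duplicate marker names")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def sample_ids(self) -> list[str]:
        return [s.id for s in self.samples]

    @property
    def breeds(self) -> list[str]:
        """Distinct breed labels in order of first appearance."""
        seen: dict[str, None] = {}
        for s in self.samples:
            if s.breed is not None:
                seen.setdefault(s.breed, None)
        return list(seen)

    def breed_of(self, sample_id: str) -> str | None:
        return self.samples[self.sample_ids.index(sample_id)].breed

    # -- subsetting ------------------------------------------------------

    def subset_markers(self, names: Sequence[str]) -> "GenotypeTable":
        index = {m.name: j for j, m in enumerate(self.markers)}
        missing = [n for n in names if n not in index]
        if missing:
            raise KeyError(f"markers absent from table: {missing[:10]}")
        cols = [index[n] for n in names]
        return GenotypeTable(
            [self.markers[j] for j in cols], list(self.samples), self.calls[:, cols]
        )

    def subset_samples(self, indices: Sequence[int]) -> "GenotypeTable":
        idx = list(indices)
        return GenotypeTable(
            list(self.markers), [self.samples[i] for i in idx], self.calls[idx, :]
        )

    def allele_freqs(self) -> np.ndarray:
        """Per-marker A1 frequency from non-missing calls (nan if all missing)."""
        calls = np.ma.masked_equal(self.calls, MISSING)
        return np.asarray(calls.mean(axis=0).filled(np.nan), dtype=float) / 2.0


@dataclass(frozen=True)
class MarkerManifest:
    """Marker content of one genotyping assay (ordered, duplicate-free)."""

    assay: str
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError(f"manifest {self.assay}: duplicate marker names")

    def __len__(self) -> int:
        return len(self.names)

    @classmethod
    def read(cls, source, assay: str | None = None) -> "MarkerManifest":
        """Read a plain-text manifest, one marker name per line."""
        with _open_text(source) as fh:
            names = tuple(line.strip() for line in fh if line.strip())
        label = assay or (os.path.basename(str(source)) if isinstance(source, (str, os.PathLike)) else "manifest")
        return cls(label, names)

    def write(self, dest) -> None:
        with _open_text(dest, "w") as fh:
            fh.write("\n".join(self.names) + "\n")


def _open_text(source, mode: str = "r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode)
    if isinstance(source, io.IOBase) or hasattr(source, "read") or hasattr(source, "write"):
        # caller-owned handle; wrap so the context manager does not close it
        class _NoClose:
            def __init__(self, fh):
                self.fh = fh

            def __enter__(self):
                return self.fh

            def __exit__(self, *exc):
                return False

        return _NoClose(source)
    raise TypeError(f"cannot open {type(source)!r}")


# ---------------------------------------------------------------------------
# PLINK text (PED + MAP)
# ---------------------------------------------------------------------------


def read_map(map_source) -> list[tuple[str, str, int]]:
    """Read a 4-column PLINK MAP file -> [(chrom, name, position_bp), ...]."""
    out: list[tuple[str, str, int]] = []
    seen: set[str] = set()
    with _open_text(map_source) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 4:
                raise GenotypeParseError(
                    f"MAP line {lineno}: expected 4 columns, got {len(fields)}"
                )
            chrom, name, _cm, bp = fields
            if name in seen:
                raise GenotypeParseError(f"MAP line {lineno}: duplicate marker {name}")
            seen.add(name)
            out.append((chrom, name, int(bp)))
    return out


def read_plink_text(ped_source, map_source, assay: str | None = None) -> GenotypeTable:
    """Read PED + MAP text genotypes into a :class:`GenotypeTable`.

    The PED family-ID column is taken as breed-of-registry.  Dosage counts
    the A1 allele (first non-missing symbol per marker in file order);
    "0 0" and half-missing calls become missing.
    """
    map_records = read_map(map_source)
    n_markers = len(map_records)

    samples: list[SampleRecord] = []
    rows: list[np.ndarray] = []
    with _open_text(ped_source) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6 + 2 * n_markers:
                raise GenotypeParseError(
                    f"PED line {lineno}: expected {6 + 2 * n_markers} fields "
                    f"for {n_markers} markers, got {len(fields)}"
                )
            fid, iid = fields[0], fields[1]
            samples.append(SampleRecord(id=iid, breed=fid, assay=assay))
            rows.append(np.array(fields[6:], dtype="U1"))
    if not samples:
        raise GenotypeParseError("PED file contains no samples")

    alleles = np.stack(rows).reshape(len(samples), n_markers, 2)
    bad = np.setdiff1d(np.unique(alleles), sorted(VALID_ALLELES))
    if bad.size:
        raise GenotypeParseError(f"invalid allele symbols in PED: {bad.tolist()}")

    markers: list[MarkerRecord] = []
    calls = np.full((len(samples), n_markers), MISSING, dtype=np.int8)
    for j, (chrom, name, bp) in enumerate(map_records):
        col = alleles[:, j, :]
        flat = col.ravel()  # sample-major scan order
        observed = flat[flat != "0"]
        if observed.size == 0:
            a1, a2 = "0", "0"
        else:
            a1 = str(observed[0])
            rest = np.unique(observed[observed != a1])
            if rest.size > 1:
                raise GenotypeParseError(
                    f"marker {name}: more than two alleles {sorted({a1, *rest})}"
                )
            a2 = str(rest[0]) if rest.size else "0"
        markers.append(MarkerRecord(name, chrom, bp, a1, a2))
        nonmissing = np.all(col != "0", axis=1)
        calls[nonmissing, j] = (col[nonmissing] == a1).sum(axis=1)

    return GenotypeTable(markers, samples, calls)


def write_plink_text(table: GenotypeTable, ped_dest, map_dest) -> None:
    """Write a table back to PED + MAP text.

    PED carries no allele-order metadata, so a reader orients dosage by
    first occurrence; for tables that were themselves read from PED (or
    EIGENSTRAT) this makes write/read a faithful inverse.
    """
    with _open_text(map_dest, "w") as fh:
        for m in table.markers:
            fh.write(f"{m.chromosome}\t{m.name}\t0\t{m.position_bp}\n")
    pair = {2: lambda m: (m.a1, m.a1), 1: lambda m: (m.a1, m.a2),
            0: lambda m: (m.a2, m.a2), MISSING: lambda m: ("0", "0")}
    with _open_text(ped_dest, "w") as fh:
        for i, s in enumerate(table.samples):
            fields = [s.breed or "0", s.id, "0", "0", "0", "-9"]
            for j, m in enumerate(table.markers):
                fields.extend(pair[int(table.calls[i, j])](m))
            fh.write(" ".join(fields) + "\n")


# ---------------------------------------------------------------------------
# EIGENSTRAT (geno / snp / ind)
# ---------------------------------------------------------------------------


def write_eigenstrat(table: GenotypeTable, geno_dest, snp_dest, ind_dest) -> None:
    """Write EIGENSTRAT text: geno has one digit row per marker (9 = missing)."""
    digits = table.calls.T.astype(np.int16).copy()
    digits[digits == MISSING] = 9
    with _open_text(geno_dest, "w") as fh:
        for row in digits:
            fh.write("".join(map(str, row)) + "\n")
    with _open_text(snp_dest, "w") as fh:
        for m in table.markers:
            fh.write(
                f"{m.name}\t{m.chromosome}\t0.0\t{m.position_bp}\t{m.a1}\t{m.a2}\n"
            )
    with _open_text(ind_dest, "w") as fh:
        for s in table.samples:
            fh.write(f"{s.id}\tU\t{s.breed or 'Unknown'}\n")


def read_eigenstrat(geno_source, snp_source, ind_source) -> GenotypeTable:
    markers: list[MarkerRecord] = []
    with _open_text(snp_source) as fh:
        for line in fh:
            if not line.strip():
                continue
            name, chrom, _gpos, bp, a1, a2 = line.split()
            markers.append(MarkerRecord(name, chrom, int(bp), a1, a2))
    samples: list[SampleRecord] = []
    with _open_text(ind_source) as fh:
        for line in fh:
            if not line.strip():
                continue
            sid, _sex, breed = line.split()
            samples.append(SampleRecord(id=sid, breed=breed))
    rows = []
    with _open_text(geno_source) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != len(samples):
                raise GenotypeParseError(
                    f"geno line {lineno}: {len(line)} digits for {len(samples)} samples"
                )
            rows.append([int(c) for c in line])
    calls = np.array(rows, dtype=np.int8).T if rows else np.zeros((len(samples), 0), np.int8)
    calls[calls == 9] = MISSING
    return GenotypeTable(markers, samples, calls)


# ---------------------------------------------------------------------------
# Manifest intersection and multi-assay merging
# ---------------------------------------------------------------------------


def intersect_manifests(
    manifests: Sequence[MarkerManifest],
    reference_map: Sequence[MarkerRecord] | None = None,
) -> list[str]:
    """Marker names present on every assay manifest.

    Order is genome order (chromosome, then bp) of ``reference_map`` when
    given, else the order of the first manifest.  Set-intersection makes the
    result independent of manifest input order.
    """
    if not manifests:
        raise ValueError("at least one manifest is required")
    common = set(manifests[0].names)
    for mf in manifests[1:]:
        common &= set(mf.names)
    if reference_map is not None:
        mapped = [m.name for m in sorted(
            reference_map, key=lambda m: (_chrom_key(m.chromosome), m.position_bp)
        )]
        unmapped = common - set(mapped)
        if unmapped:
            raise KeyError(
                f"{len(unmapped)} intersection markers absent from reference map, "
                f"e.g. {sorted(unmapped)[:5]}"
            )
        return [n for n in mapped if n in common]
    return [n for n in manifests[0].names if n in common]


def _reconcile_column(ref: MarkerRecord, other: MarkerRecord, col: np.ndarray) -> np.ndarray:
    """Align one table's dosage column to the reference allele orientation."""
    if (other.a1, other.a2) == (ref.a1, ref.a2):
        return col
    # monomorphic-in-one-table cases: '0' acts as a wildcard on A2
    if other.a1 == ref.a1 and "0" in (other.a2, ref.a2):
        return col
    swapped = other.a1 == ref.a2 and (
        other.a2 == ref.a1 or "0" in (other.a2, ref.a1)
    )
    if swapped:
        if ref.is_strand_ambiguous:
            raise ValueError(
                f"marker {ref.name}: A/T or C/G alleles swapped between tables; "
                "strand-ambiguous, cannot reconcile"
            )
        flipped = col.copy()
        nm = flipped != MISSING
        flipped[nm] = 2 - flipped[nm]
        return flipped
    raise ValueError(
        f"marker {ref.name}: incompatible alleles "
        f"({ref.a1}/{ref.a2} vs {other.a1}/{other.a2})"
    )


def extract_and_merge(
    tables: Sequence[GenotypeTable], marker_list: Sequence[str]
) -> GenotypeTable:
    """Restrict each table to ``marker_list`` and stack samples.

    Allele coding is reconciled to the first table per marker (A1/A2 swap
    flips d -> 2-d).  A sample id seen in several tables must carry
    consistent non-missing calls; its rows are merged, missing cells filled
    from later tables.
    """
    if not tables:
        raise ValueError("no tables to merge")
    subsets = [t.subset_markers(marker_list) for t in tables]
    ref_markers = list(subsets[0].markers)

    errors: list[str] = []
    aligned: list[np.ndarray] = [subsets[0].calls]
    merged_markers = list(ref_markers)
    for t in subsets[1:]:
        calls = t.calls.copy()
        for j, (ref, other) in enumerate(zip(merged_markers, t.markers)):
            try:
                calls[:, j] = _reconcile_column(ref, other, t.calls[:, j])
            except ValueError as exc:
                errors.append(str(exc))
                continue
            # adopt the more informative allele pair when reference had A2='0'
            if ref.a2 == "0" and other.a1 == ref.a1 and other.a2 != "0":
                merged_markers[j] = replace(ref, a2=other.a2)
        aligned.append(calls)
    if errors:
        raise ValueError("allele reconciliation failed:\n" + "\n".join(errors))

    samples: list[SampleRecord] = []
    index: dict[str, int] = {}
    rows: list[np.ndarray] = []
    for t, calls in zip(subsets, aligned):
        for i, s in enumerate(t.samples):
            if s.id not in index:
                index[s.id] = len(rows)
                samples.append(s)
                rows.append(calls[i].copy())
            else:
                prev = rows[index[s.id]]
                both = (prev != MISSING) & (calls[i] != MISSING)
                if np.any(prev[both] != calls[i][both]):
                    raise ValueError(
                        f"sample {s.id}: conflicting non-missing calls across tables"
                    )
                fill = (prev == MISSING) & (calls[i] != MISSING)
                prev[fill] = calls[i][fill]

    merged = GenotypeTable(merged_markers, samples, np.stack(rows))
    order = sorted(
        range(merged.n_markers),
        key=lambda j: (_chrom_key(merged.markers[j].chromosome),
                       merged.markers[j].position_bp),
    )
    return GenotypeTable(
        [merged.markers[j] for j in order], merged.samples, merged.calls[:, order]
    )
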