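"""Iterative reference-panel curation.

Candidate animals carry a breed-of-registry label that may be wrong or may
hide recent admixture, so panel membership is earned, not declared.  The
driver alternates model refits with filters:

1. fit + self-assign; retain candidates with own-breed ancestry >= theta_initial
2. cap each breed at cap_initial by seeded random subsampling
3. drop undistinguishable breeds / merge near-identical ones
4. for open-herdbook breeds, replace graded-up candidates with pedigree
   fullbloods
5. fit + self-assign; remove members assigned <= theta_purge to their breed
6. fit + self-assign; retain members with >= theta_final
7. cap each breed at cap_final

The model is refit after every membership change because self-assignment
proportions depend on panel composition; stale weights would bias later
passes.  Every retain/remove decision is written to an audit trail.  A
breed eliminated outright (all members filtered, as happens when two
breeds cannot be distinguished) is recorded and curation continues.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ancestry import AncestryEstimate, fit_reference, self_assign
from .genotype_io import GenotypeTable, SampleRecord
from .pedigree import PedigreeGraph, is_fullblood

THRESHOLD_GRID = (0.90, 0.85, 0.80, 0.75, 0.70)


@dataclass(frozen=True)
class CurationConfig:
    """Thresholds, caps and breed edits for the curation driver."""

    theta_initial: float = 0.97    # retain >= at the first supervised pass
    theta_purge: float = 0.60      # remove <= after fullblood replacement
    theta_final: float = 0.85      # final membership requirement
    threshold_grid: tuple[float, ...] = THRESHOLD_GRID
    cap_initial: int = 200
    cap_final: int = 50
    drop_breeds: tuple[str, ...] = ()
    merge_map: Mapping[str, str] = field(default_factory=dict)
    open_breeds: tuple[str, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("theta_initial", "theta_purge", "theta_final"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name}={v} outside (0, 1)")
        if self.cap_initial < 1 or self.cap_final < 1:
            raise ValueError("caps must be >= 1")
        merged = set(self.merge_map)
        if merged & set(self.drop_breeds):
            raise ValueError("merge_map breeds overlap drop_breeds")

    @classmethod
    def from_yaml(cls, source) -> "CurationConfig":
        import yaml

        from .genotype_io import _open_text

        with _open_text(source) as fh:
            data = yaml.safe_load(fh) or {}
        for key in ("threshold_grid", "drop_breeds", "open_breeds"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        if "merge_map" in data and data["merge_map"] is None:
            data["merge_map"] = {}
        return cls(**data)


@dataclass(frozen=True)
class AuditRecord:
    pass_label: str
    action: str       # e.g. retain / remove / drop-breed / relabel / insert
    sample_id: str    # "*" for breed-level events
    breed: str
    value: float | None
    decision: str


@dataclass
class CurationAudit:
    records: list[AuditRecord] = field(default_factory=list)

    def add(self, *args) -> None:
        self.records.append(AuditRecord(*args))

    @property
    def passes(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.records:
            seen.setdefault(r.pass_label, None)
        return list(seen)

    def for_pass(self, label: str) -> list[AuditRecord]:
        return [r for r in self.records if r.pass_label == label]

    def write_tsv(self, dest) -> None:
        from .genotype_io import _open_text

        with _open_text(dest, "w") as fh:
            fh.write("pass\taction\tsample\tbreed\tvalue\tdecision\n")
            for r in self.records:
                v = "" if r.value is None else f"{r.value:.6f}"
                fh.write(
                    f"{r.pass_label}\t{r.action}\t{r.sample_id}\t{r.breed}\t{v}\t{r.decision}\n"
                )


@dataclass
class ReferencePanel:
    """A genotype table whose samples carry validated breed labels."""

    table: GenotypeTable
    audit: CurationAudit | None = None

    @property
    def breeds(self) -> list[str]:
        return self.table.breeds

    def breed_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.table.samples:
            counts[s.breed] = counts.get(s.breed, 0) + 1
        return counts


# ---------------------------------------------------------------------------
# Individual curation operations
# ---------------------------------------------------------------------------


def threshold_filter(
    estimates: Sequence[AncestryEstimate],
    breed_of_registry: Mapping[str, str],
    theta: float,
    mode: str = "retain-ge",
) -> tuple[list[str], list[str]]:
    """Partition samples by own-breed ancestry against ``theta``.

    ``retain-ge`` keeps proportion >= theta (equality retained: "at least");
    ``remove-le`` removes proportion <= theta (equality removed).
    """
    if mode not in ("retain-ge", "remove-le"):
        raise ValueError(f"unknown mode {mode!r}")
    retained: list[str] = []
    removed: list[str] = []
    for est in estimates:
        breed = breed_of_registry.get(est.sample_id)
        if breed is None:
            raise KeyError(f"sample {est.sample_id} has no breed of registry")
        own = est.proportion_for(breed) if breed in est.breeds else 0.0
        if mode == "retain-ge":
            (retained if own >= theta else removed).append(est.sample_id)
        else:
            (removed if own <= theta else retained).append(est.sample_id)
    return retained, removed


def _breed_rng(seed: int, breed: str) -> np.random.Generator:
    # independent stream per breed: adding a breed never perturbs others
    return np.random.default_rng([seed, zlib.crc32(breed.encode())])


def balanced_subsample(table: GenotypeTable, cap: int, seed: int) -> GenotypeTable:
    """Per breed: keep a seeded random sample of ``cap`` when count exceeds
    it, else all.  Original sample order is preserved."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    keep: set[int] = set()
    by_breed: dict[str, list[int]] = {}
    for i, s in enumerate(table.samples):
        by_breed.setdefault(s.breed, []).append(i)
    for breed, idx in by_breed.items():
        if len(idx) <= cap:
            keep.update(idx)
        else:
            chosen = _breed_rng(seed, breed).choice(len(idx), size=cap, replace=False)
            keep.update(idx[c] for c in chosen)
    return table.subset_samples(sorted(keep))


def apply_breed_edits(
    table: GenotypeTable,
    drop_breeds: Sequence[str] = (),
    merge_map: Mapping[str, str] | None = None,
) -> GenotypeTable:
    """Drop whole breeds and/or relabel breeds to merged group labels."""
    merge_map = dict(merge_map or {})
    present = set(table.breeds)
    unknown = (set(drop_breeds) | set(merge_map)) - present
    if unknown:
        raise KeyError(f"unknown breed names: {sorted(unknown)}")
    keep = [i for i, s in enumerate(table.samples) if s.breed not in set(drop_breeds)]
    sub = table.subset_samples(keep)
    samples = [
        SampleRecord(s.id, merge_map.get(s.breed, s.breed), s.assay)
        for s in sub.samples
    ]
    return GenotypeTable(list(sub.markers), samples, sub.calls)


def replace_with_fullbloods(
    table: GenotypeTable,
    pool: GenotypeTable,
    pedigree: PedigreeGraph,
    open_breeds: Sequence[str],
    cap: int | None = None,
    seed: int = 0,
    audit: CurationAudit | None = None,
    pass_label: str = "fullblood-replacement",
) -> GenotypeTable:
    """For open-herdbook breeds, swap graded-up members for pedigree fullbloods.

    Members of an open breed failing the fullblood test are removed and
    genotyped fullbloods from ``pool`` inserted (then capped).  A breed
    with no available fullbloods is retained unchanged with a warning (the
    limited-import behavior for breeds whose foreign fullbloods are
    inaccessible).
    """
    audit = audit if audit is not None else CurationAudit()
    current_ids = set(table.sample_ids)
    drop: set[str] = set()
    insert: list[int] = []
    for breed in open_breeds:
        members = [s for s in table.samples if s.breed == breed]
        fullblood_pool = [
            i for i, s in enumerate(pool.samples)
            if s.breed == breed and s.id in pedigree and is_fullblood(pedigree, s.id, breed)
        ]
        if not fullblood_pool:
            warnings.warn(
                f"open-herdbook breed {breed}: no genotyped fullbloods available; "
                "retaining purebred members as-is"
            )
            audit.add(pass_label, "no-fullbloods", "*", breed, None, "breed retained as-is")
            continue
        for s in members:
            if not (s.id in pedigree and is_fullblood(pedigree, s.id, breed)):
                drop.add(s.id)
                audit.add(pass_label, "remove", s.id, breed, None, "not fullblood by pedigree")
        pool_ids = {pool.samples[i].id for i in fullblood_pool}
        for i in fullblood_pool:
            sid = pool.samples[i].id
            if sid not in current_ids and sid not in drop:
                insert.append(i)
                audit.add(pass_label, "insert", sid, breed, None, "pedigree fullblood")

    kept_idx = [i for i, s in enumerate(table.samples) if s.id not in drop]
    merged_samples = [table.samples[i] for i in kept_idx]
    merged_calls = [table.calls[kept_idx, :]]
    if insert:
        pool_sub = pool.subset_markers(table.marker_names).subset_samples(insert)
        merged_samples.extend(pool_sub.samples)
        merged_calls.append(pool_sub.calls)
    out = GenotypeTable(list(table.markers), merged_samples, np.vstack(merged_calls))
    if cap is not None:
        out = balanced_subsample(out, cap, seed)
    return out


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------


def _registry(table: GenotypeTable) -> dict[str, str]:
    return {s.id: s.breed for s in table.samples}


def _drop_unfittable_breeds(
    table: GenotypeTable, audit: CurationAudit, pass_label: str
) -> GenotypeTable:
    """Remove breeds left with <2 samples (unfittable); record eliminations."""
    counts: dict[str, int] = {}
    for s in table.samples:
        counts[s.breed] = counts.get(s.breed, 0) + 1
    doomed = {b for b, c in counts.items() if c < 2}
    for b in doomed:
        audit.add(pass_label, "breed-eliminated", "*", b, None,
                  f"{counts[b]} member(s) left; breed removed")
    if not doomed:
        return table
    keep = [i for i, s in enumerate(table.samples) if s.breed not in doomed]
    return table.subset_samples(keep)


def _filter_pass(
    table: GenotypeTable,
    theta: float,
    mode: str,
    audit: CurationAudit,
    pass_label: str,
) -> GenotypeTable:
    """Refit the model, self-assign, and threshold-filter; audit everything."""
    model, centroids = fit_reference(table, shrinkage=False)
    estimates = self_assign(table, model, centroids)
    registry = _registry(table)
    retained, removed = threshold_filter(estimates, registry, theta, mode)
    own = {e.sample_id: (e.proportion_for(registry[e.sample_id])
                         if registry[e.sample_id] in e.breeds else 0.0)
           for e in estimates}
    for sid in retained:
        audit.add(pass_label, "retain", sid, registry[sid], own[sid], f"own >= {theta}"
                  if mode == "retain-ge" else f"own > {theta}")
    for sid in removed:
        audit.add(pass_label, "remove", sid, registry[sid], own[sid], f"own < {theta}"
                  if mode == "retain-ge" else f"own <= {theta}")
    keep = set(retained)
    out = table.subset_samples([i for i, s in enumerate(table.samples) if s.id in keep])
    for b in set(table.breeds) - set(out.breeds):
        audit.add(pass_label, "breed-eliminated", "*", b, None,
                  "all members removed by threshold")
    return _drop_unfittable_breeds(out, audit, pass_label)


def curate(
    candidates: GenotypeTable,
    config: CurationConfig,
    pedigree: PedigreeGraph | None = None,
) -> tuple[ReferencePanel, CurationAudit]:
    """Run the full multi-pass curation pipeline (see module docstring)."""
    audit = CurationAudit()
    table = _drop_unfittable_breeds(candidates, audit, "input")

    table = _filter_pass(table, config.theta_initial, "retain-ge", audit,
                         "initial-threshold")
    before = table.sample_ids
    table = balanced_subsample(table, config.cap_initial, config.seed)
    kept = set(table.sample_ids)
    for sid in before:
        if sid not in kept:
            audit.add("initial-cap", "remove", sid, "", None,
                      f"random cap {config.cap_initial}")

    if config.drop_breeds or config.merge_map:
        for b in config.drop_breeds:
            audit.add("breed-edits", "drop-breed", "*", b, None, "configured drop")
        for b, g in dict(config.merge_map).items():
            audit.add("breed-edits", "relabel", "*", b, None, f"merged into {g}")
        table = apply_breed_edits(table, config.drop_breeds, config.merge_map)

    if pedigree is not None and config.open_breeds:
        table = replace_with_fullbloods(
            table, candidates, pedigree, config.open_breeds,
            cap=config.cap_initial, seed=config.seed, audit=audit,
        )
        table = _drop_unfittable_breeds(table, audit, "fullblood-replacement")

    table = _filter_pass(table, config.theta_purge, "remove-le", audit, "purge")
    table = _filter_pass(table, config.theta_final, "retain-ge", audit,
                         "final-threshold")

    before = table.sample_ids
    table = balanced_subsample(table, config.cap_final, config.seed)
    kept = set(table.sample_ids)
    for sid in before:
        if sid not in kept:
            audit.add("final-cap", "remove", sid, "", None,
                      f"random cap {config.cap_final}")

    return ReferencePanel(table, audit), audit
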