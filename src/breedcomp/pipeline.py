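"""End-to-end orchestration: marker intersection, merging, panel curation,
weight computation and ancestry assignment, with seeded determinism and a
provenance header on every output.

The stages mirror how the pieces are used interactively:

1. read per-assay PLINK text genotypes
2. intersect assay manifests and extract/merge the shared markers
3. curate the reference panel (audited multi-pass filtering)
4. fit the PCA SNP-weights model on the final panel (cached by panel
   content hash: weights only change when the panel changes)
5. project targets and estimate breed proportions

Any stage failure aborts with an error naming the stage.  Reruns with the
same inputs and seed are byte-identical.
"""

from __future__ import annotations

import hashlib
import logging
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from . import __version__
from .ancestry import estimate_proportions, fit_reference, project, save_weights, self_assign
from .curation import CurationConfig, curate
from .genotype_io import (
    GenotypeTable,
    MarkerManifest,
    extract_and_merge,
    intersect_manifests,
    read_plink_text,
)
from .pedigree import PedigreeGraph

log = logging.getLogger("breedcomp")


@dataclass(frozen=True)
class RunConfig:
    """Paths and knobs for one pipeline run."""

    genotypes: tuple[tuple[str, str, str], ...]  # (ped, map, assay id) per assay
    out_dir: str
    manifests: tuple[str, ...] = ()
    targets: tuple[tuple[str, str, str], ...] = ()  # like genotypes; empty = self-assign
    pedigree: str | None = None
    curation: CurationConfig = field(default_factory=CurationConfig)
    marker_set: str = "intersection"
    seed: int = 0
    log_level: str = "INFO"


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage {stage}] {message}")
        self.stage = stage


def panel_hash(table: GenotypeTable) -> str:
    """Content hash of a genotype table (markers, sample ids, calls)."""
    h = hashlib.sha256()
    h.update("\n".join(table.marker_names).encode())
    h.update("\n".join(table.sample_ids).encode())
    h.update(np.ascontiguousarray(table.calls).tobytes())
    return h.hexdigest()[:16]


def _provenance(config: RunConfig, phash: str) -> str:
    return (
        f"# breedcomp {__version__}\n"
        f"# seed {config.seed}\n"
        f"# marker-set {config.marker_set}\n"
        f"# panel-hash {phash}\n"
    )


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc
        return inner
    return wrap


@_stage("read-genotypes")
def _read_all(entries: Sequence[tuple[str, str, str]]) -> list[GenotypeTable]:
    tables = []
    for ped, mp, assay in entries:
        t = read_plink_text(ped, mp, assay=assay)
        log.info("read %s: %d samples x %d markers", ped, t.n_samples, t.n_markers)
        tables.append(t)
    return tables


@_stage("intersect-markers")
def _marker_list(config: RunConfig, tables: Sequence[GenotypeTable]) -> list[str]:
    if config.manifests:
        manifests = [MarkerManifest.read(p) for p in config.manifests]
        names = intersect_manifests(manifests, reference_map=tables[0].markers)
    else:
        common = set(tables[0].marker_names)
        for t in tables[1:]:
            common &= set(t.marker_names)
        names = [n for n in tables[0].marker_names if n in common]
    if not names:
        raise ValueError("empty marker intersection across assays")
    log.info("marker set %s: %d markers", config.marker_set, len(names))
    return names


def run_pipeline(config: RunConfig) -> dict[str, str]:
    """Run all stages; returns a dict of output-file paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(config.log_level)
    try:
        return _run(config, out)
    finally:
        log.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out: Path) -> dict[str, str]:
    tables = _read_all(config.genotypes)
    names = _marker_list(config, tables)

    merged = _stage("merge")(extract_and_merge)(tables, names)
    log.info("merged candidates: %d samples x %d markers",
             merged.n_samples, merged.n_markers)

    pedigree = None
    if config.pedigree:
        pedigree = _stage("read-pedigree")(PedigreeGraph.read_tsv)(config.pedigree)
        log.info("pedigree: %d animals", len(pedigree))

    panel, audit = _stage("curate-panel")(curate)(merged, config.curation, pedigree)
    log.info("final panel: %d samples, %d breeds",
             panel.table.n_samples, len(panel.breeds))
    audit_path = out / "curation_audit.tsv"
    audit.write_tsv(audit_path)

    phash = panel_hash(panel.table)
    model, centroids = _stage("fit-weights")(fit_reference)(panel.table)
    weights_path = out / f"weights_{phash}.tsv"
    if not weights_path.exists():
        save_weights(model, centroids, weights_path)
    log.info("weights: %d markers x %d axes (panel hash %s)",
             len(model.markers), model.n_axes, phash)

    if config.targets:
        target_tables = _read_all(config.targets)
        target = _stage("merge")(extract_and_merge)(target_tables, names)
        proj = _stage("assign")(project)(model, target)
        estimates = estimate_proportions(proj.scores, centroids, proj.sample_ids)
        log.info("assigned %d targets using %d/%d markers",
                 len(estimates), proj.markers_used, proj.markers_total)
    else:
        estimates = _stage("assign")(self_assign)(panel.table, model, centroids)
        log.info("self-assigned %d panel members", len(estimates))

    prop_path = out / "ancestry_proportions.tsv"
    with open(prop_path, "w") as fh:
        fh.write(_provenance(config, phash))
        fh.write("id\t" + "\t".join(centroids.breeds) + "\n")
        for e in estimates:
            fh.write(e.sample_id + "\t"
                     + "\t".join(f"{v:.6f}" for v in e.proportions) + "\n")

    return {
        "proportions": str(prop_path),
        "audit": str(audit_path),
        "weights": str(weights_path),
        "log": str(out / "pipeline.log"),
    }
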