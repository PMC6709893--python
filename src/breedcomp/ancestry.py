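"""SNP-weights global ancestry model.

A reference panel of K pure breeds defines per-marker allele frequencies
and a PCA of the normalized genotype matrix.  Per-marker "SNP weights" map
any normalized genotype vector onto the retained principal axes without
re-running PCA, so target animals are scored one at a time against a fixed
panel.  Breed proportions are then obtained by expressing a target's score
as a convex combination of the K breed centroids in PC space.

Model choices
-------------
* M = K - 1 axes by default: K centroids span at most K-1 dimensions, so
  the simplex-constrained system is square.
* Normalization x = (d - 2p) / sqrt(2 p (1 - p)) with reference-panel
  frequencies p; missing calls impute to the mean (0 after centering).
* Out-of-sample projections are attenuated relative to in-sample scores
  (the usual high-dimensional PCA shrinkage); a per-axis multiplicative
  correction is calibrated by leave-one-out refits on a subset of the
  reference samples.
* Frequencies come from the reference panel only and are never updated by
  target data, so estimates are independent of which other targets are
  analyzed alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .genotype_io import MISSING, GenotypeTable, MarkerRecord

SIMPLEX_TOL = 1e-9


@dataclass(frozen=True)
class AncestryEstimate:
    """Per-sample breed proportions on the K-simplex."""

    sample_id: str
    breeds: tuple[str, ...]
    proportions: np.ndarray
    raw: np.ndarray | None = None  # pre-clip solution, for diagnostics

    def __post_init__(self) -> None:
        p = np.asarray(self.proportions, dtype=float)
        if np.any(p < -SIMPLEX_TOL) or np.any(p > 1 + SIMPLEX_TOL):
            raise ValueError("proportions outside [0, 1]")
        if abs(p.sum() - 1.0) > 1e-6:
            raise ValueError(f"proportions sum to {p.sum()}, not 1")

    def proportion_for(self, breed: str) -> float:
        return float(self.proportions[self.breeds.index(breed)])

    @property
    def top_breed(self) -> str:
        return self.breeds[int(np.argmax(self.proportions))]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.breeds, map(float, self.proportions)))


@dataclass(frozen=True)
class BreedCentroids:
    """Mean reference PC score per breed (K x M)."""

    breeds: tuple[str, ...]
    coords: np.ndarray

    def __post_init__(self) -> None:
        if len(self.breeds) < 2:
            raise ValueError("at least two breeds required")
        if self.coords.shape[0] != len(self.breeds):
            raise ValueError("centroid row count does not match breed count")


@dataclass
class PCAModel:
    """Reference-panel PCA with per-marker projection weights.

    ``snp_weights`` is scaled so a reference sample's normalized genotype
    row times the weights reproduces its ``ref_scores`` row exactly;
    ``shrink`` holds per-axis multiplicative corrections (>= 1) applied to
    out-of-sample projections.
    """

    markers: list[MarkerRecord]        # retained (polymorphic) markers
    allele_freqs: np.ndarray           # per retained marker, in (0, 1)
    sample_ids: list[str]
    eigenvalues: np.ndarray            # descending, length M
    trace: float                       # sum of ALL covariance eigenvalues
    ref_scores: np.ndarray             # n_ref x M
    snp_weights: np.ndarray            # n_markers x M
    shrink: np.ndarray                 # length M, each >= 1
    dropped_markers: list[str] = field(default_factory=list)

    @property
    def n_axes(self) -> int:
        return len(self.eigenvalues)

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]


def normalize(
    calls: np.ndarray, allele_freqs: np.ndarray
) -> np.ndarray:
    """Standardize dosages: x = (d - 2p) / sqrt(2 p (1-p)); missing -> 0.

    Frequencies must be strictly inside (0, 1); monomorphic markers are the
    caller's responsibility to drop (see :func:`fit_reference`).
    """
    calls = np.asarray(calls)
    p = np.asarray(allele_freqs, dtype=float)
    if calls.shape[-1] != p.shape[0]:
        raise ValueError(
            f"{calls.shape[-1]} call columns vs {p.shape[0]} frequencies"
        )
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("allele frequencies must be strictly in (0, 1)")
    x = (calls.astype(float) - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    x[calls == MISSING] = 0.0
    return x


def _panel_table(panel) -> GenotypeTable:
    # accept either a bare GenotypeTable or anything exposing .table
    return panel if isinstance(panel, GenotypeTable) else panel.table


def fit_reference(
    panel,
    n_axes: int | None = None,
    shrinkage: bool = True,
    max_loo: int = 20,
) -> tuple[PCAModel, BreedCentroids]:
    """Fit the reference PCA, SNP weights and breed centroids.

    Parameters
    ----------
    panel
        GenotypeTable (or ReferencePanel) whose samples carry breed labels.
    n_axes
        Retained axes M; defaults to K - 1 for K breeds.
    shrinkage
        Calibrate per-axis out-of-sample corrections by leave-one-out
        refits on ``min(max_loo, N)`` evenly spaced reference samples.
        With ``False`` all factors are 1.
    """
    table = _panel_table(panel)
    breeds = table.breeds
    K = len(breeds)
    if K < 2:
        raise ValueError("reference panel must contain at least two breeds")
    counts = {b: sum(s.breed == b for s in table.samples) for b in breeds}
    small = [b for b, c in counts.items() if c < 2]
    if small:
        raise ValueError(f"breeds with fewer than 2 samples: {small}")
    M = K - 1 if n_axes is None else int(n_axes)
    if table.n_samples < M + 1:
        raise ValueError(f"need at least {M + 1} samples for {M} axes")

    freqs = table.allele_freqs()
    keep = np.isfinite(freqs) & (freqs > 0.0) & (freqs < 1.0)
    dropped = [m.name for m, k in zip(table.markers, keep) if not k]
    markers = [m for m, k in zip(table.markers, keep) if k]
    p = freqs[keep]
    if not markers:
        raise ValueError("no polymorphic markers in reference panel")

    X = normalize(table.calls[:, keep], p)
    n, m = X.shape
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    tol = s[0] * max(n, m) * np.finfo(float).eps
    rank = int(np.sum(s > tol))
    if rank < M:
        raise ValueError(
            f"reference genotypes have rank {rank}; cannot retain {M} axes"
        )
    eigenvalues = (s**2) / m
    trace = float(eigenvalues.sum())

    ref_scores = U[:, :M].copy()
    snp_weights = (Vt[:M, :] / s[:M, None]).T  # X @ W = U[:, :M]
    # deterministic sign: largest-magnitude loading positive per axis
    for a in range(M):
        j = int(np.argmax(np.abs(snp_weights[:, a])))
        if snp_weights[j, a] < 0:
            snp_weights[:, a] *= -1.0
            ref_scores[:, a] *= -1.0

    model = PCAModel(
        markers=markers,
        allele_freqs=p,
        sample_ids=table.sample_ids,
        eigenvalues=eigenvalues[:M].copy(),
        trace=trace,
        ref_scores=ref_scores,
        snp_weights=snp_weights,
        shrink=np.ones(M),
        dropped_markers=dropped,
    )
    if shrinkage:
        model.shrink = _calibrate_shrinkage(table, model, max_loo=max_loo)

    breed_idx = {b: [i for i, smp in enumerate(table.samples) if smp.breed == b]
                 for b in breeds}
    coords = np.stack([ref_scores[breed_idx[b]].mean(axis=0) for b in breeds])
    centroids = BreedCentroids(tuple(breeds), coords)
    return model, centroids


def _calibrate_shrinkage(
    table: GenotypeTable, model: PCAModel, max_loo: int = 20
) -> np.ndarray:
    """Per-axis mean of |in-sample| / |out-of-sample| score over LOO refits.

    For each held-out sample the panel is refit without it and the sample
    projected out-of-sample; the ratio of its full-model in-sample score
    magnitude to the held-out projection magnitude estimates the axis
    attenuation.  Because near-degenerate eigenvalues leave the retained
    subspace basis arbitrary, each leave-one-out model's axes are first
    aligned to the full model's by orthogonal Procrustes on the shared
    reference samples.  Ratios from near-zero scores are skipped; the
    final factor is clamped at 1 (projection is attenuated, never
    inflated).
    """
    n = table.n_samples
    M = model.n_axes
    held = np.unique(np.linspace(0, n - 1, min(max_loo, n)).round().astype(int))
    sums = np.zeros(M)
    counts = np.zeros(M)
    scale = np.sqrt(np.mean(model.ref_scores**2, axis=0))
    for i in held:
        rest = [j for j in range(n) if j != i]
        sub = table.subset_samples(rest)
        if len(sub.breeds) < 2 or any(
            sum(s.breed == b for s in sub.samples) < 2 for b in sub.breeds
        ):
            continue
        loo_model, _ = fit_reference(sub, n_axes=M, shrinkage=False)
        out = project(loo_model, table.subset_samples([i]), apply_shrink=False).scores[0]
        # align LOO axes to the full model's on the shared samples
        u, _, vt = np.linalg.svd(loo_model.ref_scores.T @ model.ref_scores[rest])
        rotation = u @ vt
        out = out @ rotation
        full = model.ref_scores[i]
        for a in range(M):
            if abs(full[a]) < 0.05 * scale[a] or abs(out[a]) < 1e-12:
                continue
            sums[a] += abs(full[a]) / abs(out[a])
            counts[a] += 1
    shrink = np.ones(M)
    ok = counts > 0
    shrink[ok] = np.maximum(1.0, sums[ok] / counts[ok])
    return shrink


@dataclass(frozen=True)
class ProjectionResult:
    scores: np.ndarray          # n_samples x M
    markers_used: int
    markers_total: int
    sample_ids: tuple[str, ...]


def project(
    model: PCAModel, table: GenotypeTable, apply_shrink: bool = True
) -> ProjectionResult:
    """Project target genotypes onto the reference axes via SNP weights.

    Markers are aligned to the model by name and allele (an A1/A2 swap
    flips dosage); model markers absent from the target assay impute to
    the mean and contribute 0.  Fails if fewer than half the model markers
    are present.
    """
    model_index = {m.name: j for j, m in enumerate(model.markers)}
    n_model = len(model.markers)
    cols = np.full((table.n_samples, n_model), MISSING, dtype=np.int8)
    used = 0
    for jt, mt in enumerate(table.markers):
        jm = model_index.get(mt.name)
        if jm is None:
            continue
        ref = model.markers[jm]
        col = table.calls[:, jt]
        if (mt.a1, mt.a2) == (ref.a1, ref.a2) or (mt.a1 == ref.a1 and "0" in (mt.a2, ref.a2)):
            cols[:, jm] = col
        elif mt.a1 == ref.a2 and (mt.a2 == ref.a1 or "0" in (mt.a2, ref.a1)):
            flipped = col.copy()
            nm = flipped != MISSING
            flipped[nm] = 2 - flipped[nm]
            cols[:, jm] = flipped
        else:
            raise ValueError(
                f"marker {mt.name}: target alleles {mt.a1}/{mt.a2} incompatible "
                f"with model {ref.a1}/{ref.a2}"
            )
        used += 1
    if used < 0.5 * n_model:
        raise ValueError(
            f"only {used}/{n_model} model markers present in target; "
            "projection unreliable"
        )
    X = normalize(cols, model.allele_freqs)
    scores = X @ model.snp_weights
    if apply_shrink:
        scores = scores * model.shrink
    return ProjectionResult(scores, used, n_model, tuple(table.sample_ids))


def estimate_proportions(
    scores: np.ndarray,
    centroids: BreedCentroids,
    sample_ids: Sequence[str] | None = None,
) -> list[AncestryEstimate]:
    """Breed proportions from PC scores: solve for the convex combination
    of breed centroids matching each score, clip negatives, renormalize.

    Solves the square system [centroids^T; 1...1] a = [score; 1] (requires
    M = K - 1); the unconstrained solution is preserved in ``raw``.
    """
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    K = len(centroids.breeds)
    M = centroids.coords.shape[1]
    if M != K - 1:
        raise ValueError(f"need M = K - 1 axes (K={K}, M={M})")
    if scores.shape[1] != M:
        raise ValueError(f"scores have {scores.shape[1]} axes, centroids {M}")
    A = np.vstack([centroids.coords.T, np.ones(K)])
    if np.linalg.cond(A) > 1e12:
        raise ValueError(
            f"centroid system singular (coincident centroids among "
            f"{centroids.breeds})"
        )
    B = np.vstack([scores.T, np.ones(scores.shape[0])])
    raw = np.linalg.solve(A, B).T  # n x K
    clipped = np.clip(raw, 0.0, None)
    props = clipped / clipped.sum(axis=1, keepdims=True)
    ids = list(sample_ids) if sample_ids is not None else [
        f"sample{i}" for i in range(scores.shape[0])
    ]
    return [
        AncestryEstimate(sid, centroids.breeds, props[i], raw=raw[i])
        for i, sid in enumerate(ids)
    ]


def self_assign(panel, model: PCAModel, centroids: BreedCentroids) -> list[AncestryEstimate]:
    """Assign each reference-panel member using its own in-sample scores.

    No shrinkage is applied: in-sample scores are exact by construction.
    """
    table = _panel_table(panel)
    if table.sample_ids != model.sample_ids:
        raise ValueError("model was not fitted on this panel (sample ids differ)")
    return estimate_proportions(model.ref_scores, centroids, table.sample_ids)


# ---------------------------------------------------------------------------
# SNP-weight file serialization
# ---------------------------------------------------------------------------


def save_weights(model: PCAModel, centroids: BreedCentroids, dest) -> None:
    """Tab-separated weight file: header block then one line per marker."""
    from .genotype_io import _open_text

    with _open_text(dest, "w") as fh:
        fh.write(f"# axes\t{model.n_axes}\n")
        fh.write("# eigenvalues\t" + "\t".join(f"{v:.10g}" for v in model.eigenvalues) + "\n")
        fh.write(f"# trace\t{model.trace:.10g}\n")
        fh.write("# shrink\t" + "\t".join(f"{v:.10g}" for v in model.shrink) + "\n")
        for b, row in zip(centroids.breeds, centroids.coords):
            fh.write(f"# centroid\t{b}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
        for m, p, w in zip(model.markers, model.allele_freqs, model.snp_weights):
            fh.write(
                f"{m.name}\t{m.chromosome}\t{m.position_bp}\t{m.a1}\t{m.a2}\t"
                f"{p:.10g}\t" + "\t".join(f"{v:.10g}" for v in w) + "\n"
            )


def load_weights(source) -> tuple[PCAModel, BreedCentroids]:
    """Read a weight file written by :func:`save_weights`.

    The returned model carries no reference scores or sample ids (they are
    not needed for projection); ``ref_scores`` is empty.
    """
    from .genotype_io import _open_text

    eigenvalues = trace = shrink = None
    n_axes = None
    breeds: list[str] = []
    cent_rows: list[list[float]] = []
    markers: list[MarkerRecord] = []
    freqs: list[float] = []
    weights: list[list[float]] = []
    with _open_text(source) as fh:
        for line in fh:
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if fields[0] == "# axes":
                n_axes = int(fields[1])
            elif fields[0] == "# eigenvalues":
                eigenvalues = np.array(fields[1:], dtype=float)
            elif fields[0] == "# trace":
                trace = float(fields[1])
            elif fields[0] == "# shrink":
                shrink = np.array(fields[1:], dtype=float)
            elif fields[0] == "# centroid":
                breeds.append(fields[1])
                cent_rows.append([float(v) for v in fields[2:]])
            else:
                name, chrom, bp, a1, a2, p, *w = fields
                markers.append(MarkerRecord(name, chrom, int(bp), a1, a2))
                freqs.append(float(p))
                weights.append([float(v) for v in w])
    if n_axes is None or eigenvalues is None or trace is None or shrink is None:
        raise ValueError("weight file missing header block")
    model = PCAModel(
        markers=markers,
        allele_freqs=np.array(freqs),
        sample_ids=[],
        eigenvalues=eigenvalues,
        trace=trace,
        ref_scores=np.zeros((0, n_axes)),
        snp_weights=np.array(weights),
        shrink=shrink,
    )
    return model, BreedCentroids(tuple(breeds), np.array(cent_rows))
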