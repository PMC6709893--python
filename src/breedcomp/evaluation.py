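"""Summary statistics for ancestry estimates.

Covers the quantities used to judge a reference panel and an estimator:
per-breed min/mean/max/sd of self-assigned own-breed ancestry,
small-component pruning (drop proportions below a floor, renormalize),
per-individual correlation between true and estimated composition
vectors, and the fraction of individuals clearing each correlation
threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ancestry import AncestryEstimate


@dataclass(frozen=True)
class AssignmentSummary:
    """Per-breed own-breed proportion statistics."""

    table: pd.DataFrame  # index breed; columns n, min, mean, max, sd

    def row(self, breed: str) -> pd.Series:
        return self.table.loc[breed]


def summarize_self_assignment(
    estimates: Sequence[AncestryEstimate],
    breed_of_registry: Mapping[str, str],
    expected_breeds: Sequence[str] | None = None,
) -> AssignmentSummary:
    """Per-breed min/mean/max (and sd) of own-breed assigned proportion.

    Breeds named in ``expected_breeds`` but carrying no samples are
    omitted with a warning.
    """
    rows: dict[str, list[float]] = {}
    for est in estimates:
        breed = breed_of_registry.get(est.sample_id)
        if breed is None:
            raise KeyError(f"sample {est.sample_id} has no breed of registry")
        own = est.proportion_for(breed) if breed in est.breeds else 0.0
        rows.setdefault(breed, []).append(own)
    for breed in expected_breeds or ():
        if breed not in rows:
            warnings.warn(f"breed {breed} has no samples; omitted from summary")
    data = {
        breed: {
            "n": len(v),
            "min": float(np.min(v)),
            "mean": float(np.mean(v)),
            "max": float(np.max(v)),
            "sd": float(np.std(v, ddof=1)) if len(v) > 1 else 0.0,
        }
        for breed, v in rows.items()
    }
    df = pd.DataFrame(data).T[["n", "min", "mean", "max", "sd"]]
    df["n"] = df["n"].astype(int)
    return AssignmentSummary(df)


def prune_small(estimate: AncestryEstimate, floor: float = 0.03) -> AncestryEstimate:
    """Drop breed proportions strictly below ``floor`` and renormalize.

    The floor is strict ("less than"): a component exactly at the floor is
    kept.  All components below the floor is an error, not an empty
    estimate.
    """
    p = np.asarray(estimate.proportions, dtype=float)
    keep = p >= floor
    if not keep.any():
        raise ValueError(
            f"all components of {estimate.sample_id} below floor {floor}"
        )
    pruned = np.where(keep, p, 0.0)
    pruned = pruned / pruned.sum()
    return AncestryEstimate(estimate.sample_id, estimate.breeds, pruned,
                            raw=estimate.raw)


def composition_correlation(true_vec: np.ndarray, est_vec: np.ndarray) -> float:
    """Product-moment correlation across the breed components of one
    individual's true and estimated composition vectors.

    Returns nan (with a warning) when either vector has zero variance
    across components, e.g. a uniform composition.
    """
    t = np.asarray(true_vec, dtype=float)
    e = np.asarray(est_vec, dtype=float)
    if t.shape != e.shape:
        raise ValueError(f"shape mismatch {t.shape} vs {e.shape}")
    if np.std(t) == 0.0 or np.std(e) == 0.0:
        warnings.warn("zero variance across components; correlation undefined")
        return float("nan")
    return float(np.corrcoef(t, e)[0, 1])


def correlation_classes(
    r_values: Sequence[float], thresholds: Sequence[float]
) -> dict[float, float]:
    """Fraction of individuals with r >= each threshold (nan excluded)."""
    thresholds = sorted(thresholds)
    r = np.asarray(r_values, dtype=float)
    r = r[np.isfinite(r)]
    if r.size == 0:
        return {t: float("nan") for t in thresholds}
    return {float(t): float(np.mean(r >= t)) for t in thresholds}


def plot_composition_bars(
    estimates: Sequence[AncestryEstimate], dest, sort_by_top: bool = True
):
    """Stacked-bar chart of per-individual breed proportions (cohort view)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not estimates:
        raise ValueError("no estimates to plot")
    breeds = estimates[0].breeds
    mat = np.stack([e.proportions for e in estimates])
    if sort_by_top:
        order = np.lexsort((-mat.max(axis=1), mat.argmax(axis=1)))
        mat = mat[order]
    fig, ax = plt.subplots(figsize=(max(6, len(estimates) / 12), 3.5))
    bottom = np.zeros(len(mat))
    x = np.arange(len(mat))
    for k, breed in enumerate(breeds):
        ax.bar(x, mat[:, k], bottom=bottom, width=1.0, label=breed)
        bottom += mat[:, k]
    ax.set_xlim(-0.5, len(mat) - 0.5)
    ax.set_ylim(0, 1)
    ax.set_ylabel("ancestry proportion")
    ax.set_xlabel("individual")
    ax.legend(fontsize=7, ncol=min(len(breeds), 6), loc="upper center",
              bbox_to_anchor=(0.5, -0.18))
    fig.tight_layout()
    fig.savefig(dest, dpi=150)
    plt.close(fig)
    return dest
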