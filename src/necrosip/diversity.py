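"""Community diversity summaries: rarefied alpha diversity and Bray-Curtis PCoA.

Libraries are re-sampled without replacement (multivariate hypergeometric) to
a common depth before alpha-diversity comparison; beta diversity is the
Bray-Curtis dissimilarity with a principal-coordinates embedding.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import CountTable, ValidationError

__all__ = [
    "DistanceMatrix",
    "OrdinationResult",
    "rarefy",
    "alpha_diversity",
    "rarefied_alpha_diversity",
    "bray_curtis",
    "pcoa",
]


@dataclass(frozen=True)
class DistanceMatrix:
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.sample_ids)
        if v.shape != (n, n):
            raise ValidationError("distance matrix shape must match sample ids")
        if not np.allclose(v, v.T):
            raise ValidationError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValidationError("distance matrix diagonal must be zero")
        object.__setattr__(self, "values", v)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)


@dataclass(frozen=True)
class OrdinationResult:
    """PCoA embedding: coordinates (samples x axes) for the positive
    eigenvalues, all eigenvalues reported (negatives included, axes dropped)."""

    sample_ids: list[str]
    coordinates: np.ndarray
    eigenvalues: np.ndarray
    proportion_explained: np.ndarray

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PCo{i+1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids, columns=cols)

    def plot(self, ax=None, labels: bool = False):
        """Scatter of the first two coordinate axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4))
        xy = self.coordinates[:, :2]
        ax.scatter(xy[:, 0], xy[:, 1], s=25)
        if labels:
            for sid, (x, y) in zip(self.sample_ids, xy):
                ax.annotate(sid, (x, y), fontsize=7)
        pe = self.proportion_explained
        ax.set_xlabel(f"PCo1 ({pe[0]:.1%})")
        if len(pe) > 1:
            ax.set_ylabel(f"PCo2 ({pe[1]:.1%})")
        return ax


def rarefy(
    table: CountTable,
    depth: int,
    n_resamples: int = 100,
    seed: int | np.random.Generator = 0,
) -> Iterator[tuple[int, CountTable, list[str]]]:
    """Yield re-sampled count tables at a fixed per-sample read depth.

    Each resample draws ``depth`` reads *without replacement* (multivariate
    hypergeometric) independently for every sample.  Samples with fewer than
    ``depth`` total reads are excluded and reported in the third element of
    each yielded tuple.  Fully seeded and reproducible.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    if n_resamples < 1:
        raise ValidationError("n_resamples must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    depths = table.sample_depths()
    kept = [s for s in table.sample_ids if depths[s] >= depth]
    excluded = [s for s in table.sample_ids if depths[s] < depth]
    if not kept:
        raise ValidationError(f"no sample reaches depth {depth}")
    counts = table.counts[kept].to_numpy()
    for r in range(n_resamples):
        resampled = np.empty_like(counts)
        for j in range(counts.shape[1]):
            resampled[:, j] = rng.multivariate_hypergeometric(
                counts[:, j], depth, method="marginals"
            )
        df = pd.DataFrame(resampled, index=table.counts.index, columns=kept)
        yield r, CountTable(df), excluded


def alpha_diversity(counts: Sequence[int] | np.ndarray) -> dict[str, float]:
    """Observed phylotype richness and Shannon entropy (natural log) of one sample."""
    c = np.asarray(counts, dtype=float)
    if c.sum() <= 0:
        raise ValidationError("alpha diversity of an all-zero sample is undefined")
    if (c < 0).any():
        raise ValidationError("negative counts")
    p = c[c > 0] / c.sum()
    return {
        "observed_phylotypes": float((c > 0).sum()),
        "shannon": float(-(p * np.log(p)).sum()),
    }


def rarefied_alpha_diversity(
    table: CountTable, depth: int, n_resamples: int = 100, seed: int = 0
) -> pd.DataFrame:
    """Mean alpha-diversity metrics over rarefaction resamples, per sample."""
    acc: dict[str, list[dict[str, float]]] = {}
    excluded: list[str] = []
    for _, sub, excl in rarefy(table, depth, n_resamples, seed):
        excluded = excl
        for sid in sub.sample_ids:
            acc.setdefault(sid, []).append(alpha_diversity(sub.counts[sid].to_numpy()))
    rows = []
    for sid, metrics in acc.items():
        rows.append(
            {
                "sample_id": sid,
                "depth": depth,
                "n_resamples": len(metrics),
                "observed_phylotypes": float(
                    np.mean([m["observed_phylotypes"] for m in metrics])
                ),
                "shannon": float(np.mean([m["shannon"] for m in metrics])),
            }
        )
    df = pd.DataFrame(rows)
    df.attrs["excluded_samples"] = excluded
    return df


def bray_curtis(table: CountTable | pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarities between samples (columns).

    d(j,k) = sum_i |x_ij - x_ik| / sum_i (x_ij + x_ik); works identically on
    counts or relative abundances of equal-depth samples.
    """
    df = table.counts if isinstance(table, CountTable) else table
    if df.shape[1] < 2:
        raise ValidationError("need at least two samples")
    x = df.to_numpy(float).T  # samples in rows for pdist
    if np.any(x.sum(axis=1) <= 0):
        raise ValidationError("zero-sum sample in distance computation")
    return DistanceMatrix(list(df.columns), squareform(pdist(x, metric="braycurtis")))


def pcoa(d: DistanceMatrix, *, correction: str | None = None) -> OrdinationResult:
    """Principal coordinates analysis of a distance matrix.

    Double-centers -d^2/2 (Gower), eigendecomposes, and returns coordinates
    (eigenvector * sqrt(eigenvalue)) for the positive eigenvalues only.  All
    eigenvalues are reported, sorted non-increasing; negative ones (possible
    for non-Euclidean dissimilarities such as Bray-Curtis) keep no axis.
    ``correction='cailliez'`` adds the Cailliez constant to all off-diagonal
    distances first, making the matrix Euclidean-embeddable.
    """
    dm = d.values
    n = dm.shape[0]
    if correction == "cailliez":
        dm = _cailliez(dm)
    elif correction is not None:
        raise ValidationError(f"unknown correction {correction!r}")
    a = -0.5 * dm**2
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = centerer @ a @ centerer
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    positive = eigval > max(eigval.max(), 0.0) * 1e-12
    coords = eigvec[:, positive] * np.sqrt(eigval[positive])
    total = eigval[eigval > 0].sum()
    prop = np.where(eigval > 0, eigval / total, 0.0) if total > 0 else np.zeros(n)
    return OrdinationResult(
        sample_ids=list(d.sample_ids),
        coordinates=coords,
        eigenvalues=eigval,
        proportion_explained=prop[positive],
    )


def _cailliez(dm: np.ndarray) -> np.ndarray:
    """Smallest constant c such that d_ij + c (i != j) is Euclidean-embeddable."""
    n = dm.shape[0]
    d1 = -0.5 * dm**2
    d2 = -0.5 * dm
    j = np.eye(n) - np.ones((n, n)) / n
    upper = np.hstack([np.zeros((n, n)), 2.0 * j @ d1 @ j])
    lower = np.hstack([-np.eye(n), -4.0 * j @ d2 @ j])
    c = float(np.max(np.real(np.linalg.eigvals(np.vstack([upper, lower])))))
    out = dm + max(c, 0.0)
    np.fill_diagonal(out, 0.0)
    return out
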