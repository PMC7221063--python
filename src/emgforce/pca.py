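"""Per-grid representative-signal extraction by principal component analysis.

Each grid's mean-removed envelope matrix X (channels x samples) is
decomposed as Y = A X, where the rows of A are the eigenvectors of the
channel covariance matrix and the rows of Y are the uncorrelated
principal-component score time series. Components are kept until the
cumulative variance-explained fraction reaches a threshold (0.85 by
default); on clean single-activation grids the first component alone
typically clears it.

Two cross-cycle rules make model inputs consistent:

* ``harmonize_component_counts`` — the number of components per grid is the
  minimum count over all training cycles, and held-out cycles use exactly
  that count with the variance threshold ignored.
* ``minmax_normalize`` — one global (min, max) pair over all grids'
  selected component values scales inputs to [0, 1]; the stored bounds are
  reused (without clipping) on held-out cycles.

Eigenvector sign is fixed so each component correlates nonnegatively with
the grid-mean envelope, giving force-tracking components positive polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .preprocessing import EnvelopeMatrix

__all__ = [
    "PCADecomposition",
    "RepresentativeSignal",
    "MinMaxBounds",
    "fit_pca",
    "select_components",
    "extract_fixed_components",
    "harmonize_component_counts",
    "minmax_normalize",
    "apply_minmax",
]


@dataclass(frozen=True)
class PCADecomposition:
    """Full eigendecomposition of one grid's envelope covariance."""

    scores: np.ndarray  # (M, samples) component time series
    loadings: np.ndarray  # (M, M), rows are unit-norm eigenvectors
    eigenvalues: np.ndarray  # (M,), nonincreasing
    channel_mean: np.ndarray  # (M,) removed before decomposition
    grid_id: int

    @property
    def variance_fractions(self) -> np.ndarray:
        total = self.eigenvalues.sum()
        if total <= 0:
            return np.zeros_like(self.eigenvalues)
        return self.eigenvalues / total

    def reconstruct(self) -> np.ndarray:
        """Invert the transform: A^T Y + mean recovers the input matrix."""
        return self.loadings.T @ self.scores + self.channel_mean[:, None]


@dataclass(frozen=True)
class RepresentativeSignal:
    """Selected principal components of one grid for one cycle."""

    components: np.ndarray  # (N, samples)
    weights: np.ndarray  # (N, M) loading rows
    eigenvalues: np.ndarray  # (N,)
    variance_explained_cumulative: np.ndarray  # (N,) fractions of total
    grid_id: int

    @property
    def n_selected(self) -> int:
        return self.components.shape[0]


@dataclass(frozen=True)
class MinMaxBounds:
    """Global (min, max) component values used for input scaling."""

    lo: float
    hi: float


def fit_pca(env: EnvelopeMatrix | np.ndarray, grid_id: int | None = None) -> PCADecomposition:
    """Full PCA of a (channels, samples) envelope matrix.

    The channel-wise temporal mean is removed, the channel covariance is
    eigendecomposed, and scores are computed as Y = A X_centered with
    eigenvalues sorted descending. Covariance (not correlation) is used:
    channels share units, so no per-channel standardization is wanted.
    """
    if isinstance(env, EnvelopeMatrix):
        X = env.values
        gid = env.grid_id
    else:
        X = np.asarray(env, dtype=float)
        gid = -1 if grid_id is None else grid_id
    if grid_id is not None:
        gid = grid_id
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a (channels >= 2, samples) matrix")
    if X.shape[1] <= X.shape[0]:
        raise ValueError("need more samples than channels")
    if not np.isfinite(X).all():
        raise ValueError("non-finite values in envelope matrix")

    mean = X.mean(axis=1)
    Xc = X - mean[:, None]
    cov = (Xc @ Xc.T) / (X.shape[1] - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    A = evecs[:, order].T  # rows are eigenvectors
    scores = A @ Xc

    # sign convention: component tracks the grid-mean envelope positively
    grid_mean = Xc.mean(axis=0)
    if grid_mean.std() > 0:
        gm = grid_mean - grid_mean.mean()
        corr = scores @ gm
        flip = corr < 0
        A[flip] *= -1.0
        scores[flip] *= -1.0

    return PCADecomposition(
        scores=scores, loadings=A, eigenvalues=evals, channel_mean=mean, grid_id=gid
    )


def select_components(
    decomp: PCADecomposition, threshold: float = 0.85
) -> RepresentativeSignal:
    """Keep the smallest N components whose cumulative variance >= threshold."""
    frac = decomp.variance_fractions
    cum = np.cumsum(frac)
    n = int(np.searchsorted(cum, threshold) + 1)
    n = min(n, frac.size)
    return extract_fixed_components(decomp, n)


def extract_fixed_components(decomp: PCADecomposition, n: int) -> RepresentativeSignal:
    """Take exactly ``n`` leading components, ignoring the variance threshold.

    This is the held-out-cycle path: the component count was fixed on the
    training cycles and must match regardless of this cycle's spectrum.
    """
    if not 1 <= n <= decomp.eigenvalues.size:
        raise ValueError(f"component count {n} outside [1, {decomp.eigenvalues.size}]")
    cum = np.cumsum(decomp.variance_fractions)
    return RepresentativeSignal(
        components=decomp.scores[:n],
        weights=decomp.loadings[:n],
        eigenvalues=decomp.eigenvalues[:n],
        variance_explained_cumulative=cum[:n],
        grid_id=decomp.grid_id,
    )


def harmonize_component_counts(per_cycle_counts) -> int:
    """Fixed component count for a grid: minimum over training cycles."""
    counts = list(per_cycle_counts)
    if not counts:
        raise ValueError("need at least one training cycle")
    if any(c < 1 for c in counts):
        raise ValueError("component counts must be >= 1")
    return int(min(counts))


def _stack(components) -> np.ndarray:
    if isinstance(components, (list, tuple)):
        return np.vstack([np.atleast_2d(np.asarray(c, dtype=float)) for c in components])
    return np.atleast_2d(np.asarray(components, dtype=float))


def minmax_normalize(components) -> tuple[np.ndarray, MinMaxBounds]:
    """Scale component values to [0, 1] with one global bound pair.

    ``components`` is anything stackable into an (m, samples) matrix — all
    selected components across the four grids of a cycle set. The transform
    is x' = (x - min) / (max - min) with one (min, max) pair over every
    component value in the set. A monotone (sign-preserving) map is
    essential here: component scores are zero-mean, so rectifying them
    would fold rising and falling force phases onto the same input value
    and make the EMG-force mapping non-injective. The sign convention fixed
    at extraction already orients each component to track force positively.
    """
    P = _stack(components)
    lo, hi = float(P.min()), float(P.max())
    if hi == lo:
        raise ValueError("degenerate input: all component values identical")
    bounds = MinMaxBounds(lo=lo, hi=hi)
    return apply_minmax(P, bounds), bounds


def apply_minmax(components, bounds: MinMaxBounds) -> np.ndarray:
    """Apply stored min-max bounds; held-out values may leave [0, 1] (no clip)."""
    return (_stack(components) - bounds.lo) / (bounds.hi - bounds.lo)
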