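"""Evaluation metrics for force estimation and muscle activation.

Implements the quantities used to score an EMG-driven force estimator:

* ``rmsd`` — root-mean-square difference between normalized measured and
  estimated force (both on the [0, 1] normalized-force scale).
* ``r_squared`` — goodness of fit, 1 - SS_res / SS_tot. May be negative for
  fits worse than the mean predictor; no flooring is applied.
* ``pearson_r`` — sample Pearson correlation.
* ``activation_level`` — per-grid activation index I_j = sum over the grid's
  32 channels of RMS(channel)^2, computed on 128-channel-normalized
  envelopes. The grid with the largest I is the dominant muscle group of the
  contraction cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CycleScore",
    "ActivationLevel",
    "rmsd",
    "r_squared",
    "pearson_r",
    "activation_level",
    "score_cycle",
]


@dataclass(frozen=True)
class CycleScore:
    """Scores for one contraction cycle: RMSD, R², r, sample count."""

    rmsd: float
    r2: float
    r: float
    n: int


@dataclass(frozen=True)
class ActivationLevel:
    """Per-grid activation-level index I for one contraction cycle."""

    per_grid_I: np.ndarray  # shape (n_grids,), nonnegative
    force_level: float | None = None  # %MVC label, informational

    @property
    def dominant_grid(self) -> int:
        """Index of the grid with the highest activation level."""
        return int(np.argmax(self.per_grid_I))


def _as_1d_pair(y, yhat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float).ravel()
    yhat = np.asarray(yhat, dtype=float).ravel()
    if y.shape != yhat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {yhat.shape}")
    if y.size == 0:
        raise ValueError("empty input")
    return y, yhat


def rmsd(y, yhat) -> float:
    """Root-mean-square difference sqrt(mean((y - yhat)^2))."""
    y, yhat = _as_1d_pair(y, yhat)
    return float(np.sqrt(np.mean((y - yhat) ** 2)))


def r_squared(y, yhat) -> float:
    """Goodness of fit 1 - SS_res/SS_tot; y is the measured reference.

    Raises if y is constant (the total sum of squares vanishes and the
    statistic is undefined).
    """
    y, yhat = _as_1d_pair(y, yhat)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        raise ValueError("R² undefined: reference signal is constant")
    ss_res = float(np.sum((y - yhat) ** 2))
    return 1.0 - ss_res / ss_tot


def pearson_r(a, b) -> float:
    """Sample Pearson correlation coefficient."""
    a, b = _as_1d_pair(a, b)
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("correlation undefined for constant input")
    return float(np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))


def activation_level(
    envelopes, force_level: float | None = None, channels_per_grid: int = 32
) -> ActivationLevel:
    """Activation-level index I_j per grid from normalized envelope matrices.

    Parameters
    ----------
    envelopes : sequence of (channels, samples) arrays
        One matrix per grid, already normalized jointly by the maximum
        absolute value over all channels of the cycle.
    force_level : optional %MVC label carried through to the result.
    channels_per_grid : expected channel count per grid (32 for a 4x8 grid).
    """
    values = []
    for g, env in enumerate(envelopes):
        env = np.asarray(env, dtype=float)
        if env.ndim != 2 or env.shape[0] != channels_per_grid:
            raise ValueError(
                f"grid {g}: expected {channels_per_grid} channel rows, got {env.shape}"
            )
        rms = np.sqrt(np.mean(env**2, axis=1))
        values.append(float(np.sum(rms**2)))
    return ActivationLevel(per_grid_I=np.asarray(values), force_level=force_level)


def score_cycle(y, yhat) -> CycleScore:
    """Bundle RMSD, R² and r for one measured/estimated force pair."""
    y_arr, _ = _as_1d_pair(y, yhat)
    return CycleScore(
        rmsd=rmsd(y, yhat),
        r2=r_squared(y, yhat),
        r=pearson_r(y, yhat),
        n=int(y_arr.size),
    )
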