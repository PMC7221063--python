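"""Mean impact value: perturbation-based ranking of model inputs.

Given a trained force-estimation model and the sample matrix P (m inputs x
n samples) of a contraction cycle, each input row P_k is scaled up and down
by 10% in turn (the other rows untouched), the model is evaluated on both
perturbed matrices, and the mean output difference

    MIV_k = mean_over_samples( f(P'_k) - f(P''_k) )

is the impact of input k. Inputs are ranked by |MIV| (descending); when a
muscle grid contributes several inputs the grid's priority is the maximum
|MIV| among them. Signs are kept internally — a negative MIV means the
output falls when the input grows — but all ranking uses magnitudes.

Perturbation acts on the model-input scale (the min-max-normalized
component signals), i.e. where the sample matrix lives in the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .dbn import DBNModel, predict

__all__ = ["MIVReport", "compute_miv", "aggregate_by_grid"]


@dataclass(frozen=True)
class MIVReport:
    """Per-input (and optionally per-grid) mean impact values."""

    per_input_miv: np.ndarray  # (m,) signed
    per_input_rank: np.ndarray  # input indices ordered by |MIV| descending
    perturbation_fraction: float
    n_samples: int
    input_to_grid: tuple[int, ...] | None = None
    per_grid_miv: dict[int, float] | None = None  # grid -> max |MIV|
    grid_rank: tuple[int, ...] | None = None  # grids ordered by priority

    @property
    def top_input(self) -> int:
        return int(self.per_input_rank[0])

    @property
    def top_grid(self) -> int | None:
        return None if self.grid_rank is None else int(self.grid_rank[0])


def _rank_desc(values: np.ndarray) -> np.ndarray:
    # ties broken by lower index: lexsort's last key dominates
    return np.lexsort((np.arange(values.size), -values))


def compute_miv(
    model: DBNModel, samples: np.ndarray, perturbation: float = 0.10
) -> MIVReport:
    """MIV of every input of a trained model on an (m, n) sample matrix."""
    if not model.finetuned:
        raise ValueError("model must be fine-tuned before computing MIV")
    P = np.atleast_2d(np.asarray(samples, dtype=float))
    m, n = P.shape
    if m != model.layer_sizes[0]:
        raise ValueError(f"model expects {model.layer_sizes[0]} inputs, got {m}")
    if n < 1:
        raise ValueError("need at least one sample")
    mivs = np.empty(m)
    for k in range(m):
        up = P.copy()
        down = P.copy()
        up[k] *= 1.0 + perturbation
        down[k] *= 1.0 - perturbation
        r_up = predict(model, up.T)
        r_down = predict(model, down.T)
        mivs[k] = float(np.mean(r_up - r_down))
    return MIVReport(
        per_input_miv=mivs,
        per_input_rank=_rank_desc(np.abs(mivs)),
        perturbation_fraction=perturbation,
        n_samples=n,
    )


def aggregate_by_grid(report: MIVReport, input_to_grid) -> MIVReport:
    """Fold per-input MIVs into per-grid priorities (max |MIV| per grid).

    ``input_to_grid`` maps each input index to its grid; every input must
    be covered. Grids are ranked by their value, ties broken by lower grid
    index.
    """
    mapping = tuple(int(g) for g in input_to_grid)
    m = report.per_input_miv.size
    if len(mapping) != m:
        raise ValueError(f"mapping covers {len(mapping)} inputs, model has {m}")
    grids = sorted(set(mapping))
    per_grid = {
        g: float(np.max(np.abs(report.per_input_miv[[i for i, gg in enumerate(mapping) if gg == g]])))
        for g in grids
    }
    vals = np.array([per_grid[g] for g in grids])
    order = _rank_desc(vals)
    grid_rank = tuple(grids[i] for i in order)
    return replace(
        report, input_to_grid=mapping, per_grid_miv=per_grid, grid_rank=grid_rank
    )
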