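"""Raw HD-sEMG to normalized envelope matrices.

The per-cycle chain: bad-channel repair -> 20 Hz FIR high-pass ->
full-wave rectification -> 100 ms moving average -> per-cycle
normalization (force by its own maximum, envelopes by the single maximum
absolute value over all 128 channels of the cycle).

Channel repair runs before filtering because saturated channels would
otherwise corrupt the filter transients of their neighbors' replacements.
The high-pass is applied forward-backward (zero phase) so envelopes stay
time-aligned with the force channel; the moving average shrinks its window
at the edges instead of zero-padding so cycle boundaries carry no bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .synthetic import GRID_COLS, GRID_ROWS, ContractionCycle

__all__ = [
    "PreprocessConfig",
    "EnvelopeMatrix",
    "repair_bad_channels",
    "highpass",
    "envelope",
    "normalize_cycle",
    "preprocess_cycle",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Tunable preprocessing parameters.

    ``amp_floor``/``amp_ceiling`` bound the plausible peak amplitude of a
    channel (recording units); ``mad_factor`` flags channels whose sample
    variance exceeds the grid median by more than this many median absolute
    deviations. ``apply_highpass`` can be disabled when the acquisition
    hardware already band-passed the signal.
    """

    hp_cutoff_hz: float = 20.0
    hp_order: int = 80
    ma_window_ms: float = 100.0
    amp_floor: float = 1e-7
    amp_ceiling: float = 1e3
    mad_factor: float = 5.0
    apply_highpass: bool = True


@dataclass(frozen=True)
class EnvelopeMatrix:
    """Nonnegative (channels, samples) envelope matrix for one grid."""

    values: np.ndarray
    grid_id: int
    rate_hz: float
    #: max-abs constant the 128-channel normalization divided by (None if raw)
    normalization_record: float | None = None


def _grid_neighbors(ch: int) -> list[int]:
    """4-connected neighbors of a channel on the 4x8 electrode grid."""
    r, c = divmod(ch, GRID_COLS)
    out = []
    if r > 0:
        out.append(ch - GRID_COLS)
    if r < GRID_ROWS - 1:
        out.append(ch + GRID_COLS)
    if c > 0:
        out.append(ch - 1)
    if c < GRID_COLS - 1:
        out.append(ch + 1)
    return out


def repair_bad_channels(
    raw: np.ndarray,
    lo: float = PreprocessConfig.amp_floor,
    hi: float = PreprocessConfig.amp_ceiling,
    mad_factor: float = PreprocessConfig.mad_factor,
) -> tuple[np.ndarray, list[int]]:
    """Flag and repair implausible channels of one grid.

    A channel is flagged when its peak absolute amplitude falls below ``lo``
    or above ``hi``, or when its sample variance exceeds the grid median
    variance by more than ``mad_factor`` median absolute deviations.
    Flagged channels are replaced by the sample-wise mean of their valid
    4-connected neighbors on the 4x8 grid (edge channels use the neighbors
    that exist; a flagged channel with no valid neighbor falls back to the
    mean of all valid channels).
    """
    raw = np.asarray(raw, dtype=float)
    if raw.ndim != 2 or raw.shape[0] != GRID_ROWS * GRID_COLS:
        raise ValueError(f"expected ({GRID_ROWS * GRID_COLS}, samples) matrix, got {raw.shape}")
    peak = np.abs(raw).max(axis=1)
    flagged = (peak < lo) | (peak > hi)
    var = raw.var(axis=1)
    med = np.median(var)
    mad = np.median(np.abs(var - med))
    if mad > 0:
        flagged |= var > med + mad_factor * mad
    if flagged.all():
        raise ValueError("unrecoverable grid: every channel flagged as bad")
    if not flagged.any():
        return raw, []
    repaired = raw.copy()
    valid = ~flagged
    fallback = raw[valid].mean(axis=0)
    for ch in np.flatnonzero(flagged):
        nbrs = [n for n in _grid_neighbors(ch) if valid[n]]
        repaired[ch] = raw[nbrs].mean(axis=0) if nbrs else fallback
    return repaired, [int(i) for i in np.flatnonzero(flagged)]


def highpass(
    x: np.ndarray,
    rate_hz: float,
    cutoff_hz: float = PreprocessConfig.hp_cutoff_hz,
    order: int = PreprocessConfig.hp_order,
) -> np.ndarray:
    """Zero-phase Hann-window FIR high-pass along the last axis.

    ``order`` is the FIR filter order (order + 1 taps). Applied
    forward-backward so the net delay is zero; the effective magnitude
    response is the square of the designed filter's.
    """
    x = np.asarray(x, dtype=float)
    if rate_hz <= 2 * cutoff_hz:
        raise ValueError("sampling rate must exceed twice the cutoff")
    numtaps = order + 1
    if x.shape[-1] < 3 * numtaps:
        raise ValueError(
            f"signal too short for filtering: {x.shape[-1]} < {3 * numtaps} samples"
        )
    taps = highpass_taps(rate_hz, cutoff_hz, order)
    return sps.filtfilt(taps, [1.0], x, axis=-1)


def highpass_taps(
    rate_hz: float,
    cutoff_hz: float = PreprocessConfig.hp_cutoff_hz,
    order: int = PreprocessConfig.hp_order,
) -> np.ndarray:
    """Hann-window FIR high-pass by spectral inversion (exact DC null).

    A unity-DC-gain windowed-sinc low-pass is subtracted from a unit
    impulse, so the high-pass rejects DC exactly rather than to within the
    window's scaling error.
    """
    numtaps = order + 1
    lp = sps.firwin(numtaps, cutoff_hz, fs=rate_hz, window="hann")
    hp = -lp
    hp[order // 2] += 1.0
    return hp


def envelope(
    x: np.ndarray, rate_hz: float, window_ms: float = PreprocessConfig.ma_window_ms
) -> np.ndarray:
    """Full-wave rectification followed by a centered moving average.

    The averaging window shrinks at the edges (true mean of the available
    samples), so output length equals input length with no zero-padding
    bias.
    """
    x = np.asarray(x, dtype=float)
    win = int(round(window_ms * rate_hz / 1000.0))
    if win < 1:
        raise ValueError("window shorter than one sample")
    rect = np.abs(x)
    n = x.shape[-1]
    # centered sliding-window sum via cumulative sums (matches an ndarray
    # convolution with a length-`win` boxcar in "same" mode)
    left = (win - 1) // 2  # samples taken after the center (convolution flip)
    csum = np.cumsum(rect, axis=-1)
    csum = np.concatenate([np.zeros(rect.shape[:-1] + (1,)), csum], axis=-1)
    hi = np.minimum(np.arange(n) + left + 1, n)
    lo = np.maximum(np.arange(n) + left + 1 - win, 0)
    sums = csum[..., hi] - csum[..., lo]
    return sums / (hi - lo)


def normalize_cycle(
    envelopes: list[EnvelopeMatrix], force: np.ndarray
) -> tuple[list[EnvelopeMatrix], np.ndarray]:
    """Per-cycle normalization of envelopes (jointly) and force (by its max).

    All grids of the cycle share one constant: the maximum absolute envelope
    value over all 128 channels, so inter-grid amplitude relations survive.
    """
    force = np.asarray(force, dtype=float)
    fmax = float(np.abs(force).max()) if force.size else 0.0
    if fmax == 0.0:
        raise ValueError("degenerate cycle: flat zero force")
    emax = max(float(np.abs(e.values).max()) for e in envelopes)
    if emax == 0.0:
        raise ValueError("degenerate cycle: silent EMG")
    normed = [
        EnvelopeMatrix(
            values=e.values / emax,
            grid_id=e.grid_id,
            rate_hz=e.rate_hz,
            normalization_record=emax,
        )
        for e in envelopes
    ]
    return normed, force / fmax


def preprocess_cycle(
    cycle: ContractionCycle, config: PreprocessConfig = PreprocessConfig()
) -> tuple[list[EnvelopeMatrix], np.ndarray, dict[int, list[int]]]:
    """Run the full chain on one contraction cycle.

    Returns the four normalized envelope matrices, the normalized force
    trace, and a grid -> repaired-channel-indices map.
    """
    envs = []
    repaired_map: dict[int, list[int]] = {}
    for g in cycle.grids:
        repaired, flags = repair_bad_channels(
            g.values, config.amp_floor, config.amp_ceiling, config.mad_factor
        )
        repaired_map[g.grid_id] = flags
        if config.apply_highpass:
            repaired = highpass(repaired, g.rate_hz, config.hp_cutoff_hz, config.hp_order)
        env = envelope(repaired, g.rate_hz, config.ma_window_ms)
        envs.append(EnvelopeMatrix(values=env, grid_id=g.grid_id, rate_hz=g.rate_hz))
    normed, force = normalize_cycle(envs, cycle.force)
    return normed, force, repaired_map
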