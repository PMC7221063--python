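"""Synthetic multi-grid HD-sEMG session generator with known ground truth.

Emulates an isometric-contraction recording session: a subject tracks a
guided force profile (sinusoidal cycles at 20/40/60 %MVC, 6 s each, repeated
several times per level) while four 4x8 electrode grids record surface EMG
at 1 kHz, monopolar, alongside a synchronously sampled force channel.

The raw EMG of a channel is modelled as amplitude-modulated band-limited
noise:

    channel(g, c, t) = spatial_map[g][c] * activation_g(t) * carrier(t) + noise
    activation_g(t)  = grid_gains[g] * force(t) ** exponent[g]

where the carrier is unit-variance 20-500 Hz Gaussian noise, independent per
channel (an optional within-grid correlation parameter mixes in a shared
carrier). This is an amplitude-modulation model, not a motor-unit action
potential train: it reproduces the envelope/activation structure every
downstream stage consumes, which is what makes the pipeline testable with
known ground truth.

Ground-truth activation traces, the dominant grid (argmax of ``grid_gains``)
and injected bad channels are stored on each generated cycle so oracle tests
can verify recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import signal as sps

__all__ = [
    "ForceProfile",
    "MuscleModel",
    "GridRecording",
    "ContractionCycle",
    "make_force_profile",
    "synthesize_cycle",
    "synthesize_session",
    "save_session",
    "load_session",
    "GRID_ROWS",
    "GRID_COLS",
    "DEFAULT_MUSCLE_LABELS",
]

GRID_ROWS = 4
GRID_COLS = 8
N_GRIDS = 4
CHANNELS_PER_GRID = GRID_ROWS * GRID_COLS

#: Grid-to-muscle assignment used by default (elbow-flexion montage).
DEFAULT_MUSCLE_LABELS = ("BB+BR", "TB", "BRD", "EDC")


@dataclass(frozen=True)
class ForceProfile:
    """Target force profile for one contraction cycle.

    ``sinusoid`` runs one raised-cosine cycle: zero at both ends, peaking at
    ``amplitude_fraction`` (of MVC) mid-cycle. ``ramp_hold`` ramps up over
    the first third, holds the plateau for the middle third, ramps down over
    the last third. ``staircase`` climbs ``n_steps`` equal-amplitude,
    equal-duration plateaus to the full amplitude.
    """

    pattern: str = "sinusoid"  # sinusoid | ramp_hold | staircase
    amplitude_fraction: float = 0.6
    duration_s: float = 6.0
    rate_hz: float = 1000.0
    n_steps: int = 3  # staircase only

    def __post_init__(self):
        if self.pattern not in ("sinusoid", "ramp_hold", "staircase"):
            raise ValueError(f"unknown pattern {self.pattern!r}")
        if self.duration_s <= 0 or self.rate_hz <= 0:
            raise ValueError("duration_s and rate_hz must be positive")
        if not 0 < self.amplitude_fraction <= 1:
            raise ValueError("amplitude_fraction must be in (0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.rate_hz))


def make_force_profile(p: ForceProfile) -> np.ndarray:
    """Generate the target force trace (fraction of MVC) for a profile."""
    n = p.n_samples
    t = np.arange(n) / p.rate_hz
    if p.pattern == "sinusoid":
        trace = p.amplitude_fraction * (1.0 - np.cos(2 * np.pi * t / p.duration_s)) / 2.0
    elif p.pattern == "ramp_hold":
        third = p.duration_s / 3.0
        up = np.clip(t / third, 0.0, 1.0)
        down = np.clip((p.duration_s - t) / third, 0.0, 1.0)
        trace = p.amplitude_fraction * np.minimum(up, down)
    else:  # staircase
        step = np.minimum(
            np.floor(t / p.duration_s * p.n_steps) + 1, p.n_steps
        )
        trace = p.amplitude_fraction * step / p.n_steps
    return trace


@dataclass(frozen=True)
class MuscleModel:
    """Ground-truth generative parameters for a four-muscle recording.

    Exactly one grid is dominant: the argmax of ``grid_gains`` (ties are
    rejected). ``nonlinearity_exponent`` lets a grid's activation be a
    nonlinear function of force (exponent 1 = proportional).
    """

    grid_gains: tuple[float, ...] = (1.0, 0.45, 0.35, 0.25)
    nonlinearity_exponent: tuple[float, ...] = (1.0, 1.2, 1.0, 1.1)
    spatial_maps: tuple[np.ndarray, ...] | None = None  # 4 of (4, 8), nonneg
    #: slow neural-drive fluctuation per grid, relative to the activation
    #: peak: the dominant muscle tracks the target faithfully while
    #: co-active muscles drift, so their envelopes correlate less with force
    drive_noise_sd: tuple[float, ...] = (0.02, 0.12, 0.12, 0.12)
    noise_sd: float = 0.01
    noise_correlation: float = 0.0  # within-grid carrier correlation in [0, 1)
    force_jitter_sd: float = 0.0  # low-pass tracking-error noise on measured force
    bad_channels: tuple[tuple[int, int], ...] = ()  # (grid, channel) pairs
    bad_channel_mode: str = "saturated"  # saturated | dead
    muscle_labels: tuple[str, ...] = DEFAULT_MUSCLE_LABELS
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_gains) != N_GRIDS:
            raise ValueError("grid_gains must have 4 entries")
        if len(self.drive_noise_sd) != N_GRIDS or any(s < 0 for s in self.drive_noise_sd):
            raise ValueError("drive_noise_sd must be 4 nonnegative values")
        if any(g < 0 for g in self.grid_gains):
            raise ValueError("grid_gains must be nonnegative")
        gains = np.asarray(self.grid_gains)
        top = gains.max()
        if np.sum(gains == top) != 1:
            raise ValueError("exactly one grid must be dominant (no gain ties)")
        if self.spatial_maps is not None:
            for m in self.spatial_maps:
                arr = np.asarray(m)
                if arr.shape != (GRID_ROWS, GRID_COLS) or (arr < 0).any():
                    raise ValueError("spatial_maps must be nonnegative (4, 8) arrays")
        if not 0 <= self.noise_correlation < 1:
            raise ValueError("noise_correlation must be in [0, 1)")
        if self.bad_channel_mode not in ("saturated", "dead"):
            raise ValueError("bad_channel_mode must be 'saturated' or 'dead'")

    @property
    def dominant_grid(self) -> int:
        return int(np.argmax(self.grid_gains))

    def resolved_spatial_maps(self) -> list[np.ndarray]:
        """Spatial maps, generating smooth default bumps from the seed if unset."""
        if self.spatial_maps is not None:
            return [np.asarray(m, dtype=float) for m in self.spatial_maps]
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0x3A95]))
        maps = []
        rows, cols = np.mgrid[0:GRID_ROWS, 0:GRID_COLS]
        for _ in range(N_GRIDS):
            r0 = rng.uniform(0.5, GRID_ROWS - 1.5)
            c0 = rng.uniform(1.0, GRID_COLS - 2.0)
            sig_r = rng.uniform(1.0, 2.0)
            sig_c = rng.uniform(1.5, 3.0)
            bump = np.exp(-(((rows - r0) / sig_r) ** 2 + ((cols - c0) / sig_c) ** 2))
            m = 0.2 + 0.8 * bump
            # unit RMS: electrode coverage is comparable across muscles, so
            # relative intensity between grids is carried by grid_gains alone
            maps.append(m / np.sqrt(np.mean(m**2)))
        return maps


@dataclass(frozen=True)
class GridRecording:
    """One electrode grid's raw multichannel time series."""

    values: np.ndarray  # (32, samples)
    grid_id: int
    muscle: str
    rate_hz: float

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class ContractionCycle:
    """One repetition: force trace + four grid recordings + ground truth."""

    force: np.ndarray  # measured force, fraction of MVC
    target_force: np.ndarray  # guided profile (equals force if no jitter)
    grids: tuple[GridRecording, ...]
    rate_hz: float
    level: float  # amplitude fraction of MVC for this cycle
    rep_index: int = 0
    seed: int | None = None
    true_activations: np.ndarray | None = None  # (4, samples)
    bad_channels: tuple[tuple[int, int], ...] = ()
    dominant_grid: int | None = None

    @property
    def n_samples(self) -> int:
        return self.force.size


def _band_limited_noise(rng: np.random.Generator, n: int, rate_hz: float,
                        shape: tuple[int, ...]) -> np.ndarray:
    """Unit-variance 20-500 Hz Gaussian noise carriers, one per row."""
    white = rng.standard_normal(shape + (n,))
    nyq = rate_hz / 2.0
    hi = min(500.0, 0.99 * nyq)
    taps = sps.firwin(101, [20.0, hi], fs=rate_hz, pass_zero=False, window="hann")
    carrier = sps.filtfilt(taps, [1.0], white, axis=-1)
    sd = carrier.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return carrier / sd


def synthesize_cycle(
    m: MuscleModel, p: ForceProfile, *, seed: int | None = None, rep_index: int = 0
) -> ContractionCycle:
    """Generate one contraction cycle from a muscle model and force profile.

    Fully reproducible: the same (model, profile, seed) triple yields
    bit-identical arrays. Random draws never depend on gain values, so
    scaling a gain scales the affected channels exactly proportionally.
    """
    cycle_seed = m.seed if seed is None else seed
    rng = np.random.default_rng(np.random.SeedSequence([cycle_seed, 0xC1C1E]))
    n = p.n_samples
    target = make_force_profile(p)

    force = target
    if m.force_jitter_sd > 0:
        jitter = rng.standard_normal(n)
        taps = sps.firwin(101, 2.0, fs=p.rate_hz, window="hann")
        jitter = sps.filtfilt(taps, [1.0], jitter)
        jitter *= m.force_jitter_sd / max(jitter.std(), 1e-12)
        force = np.clip(target + jitter, 0.0, None)

    maps = m.resolved_spatial_maps()
    rho = m.noise_correlation
    grids = []
    activations = np.empty((N_GRIDS, n))
    for g in range(N_GRIDS):
        drive = force ** m.nonlinearity_exponent[g]
        if m.drive_noise_sd[g] > 0:
            slow = rng.standard_normal(n)
            taps = sps.firwin(201, 3.0, fs=p.rate_hz, window="hann")
            slow = sps.filtfilt(taps, [1.0], slow)
            slow /= max(slow.std(), 1e-12)
            drive = np.clip(drive + m.drive_noise_sd[g] * drive.max() * slow, 0.0, None)
        act = m.grid_gains[g] * drive
        activations[g] = act
        own = _band_limited_noise(rng, n, p.rate_hz, (CHANNELS_PER_GRID,))
        if rho > 0:
            shared = _band_limited_noise(rng, n, p.rate_hz, (1,))
            carrier = np.sqrt(1 - rho) * own + np.sqrt(rho) * shared
        else:
            carrier = own
        additive = rng.standard_normal((CHANNELS_PER_GRID, n))
        weights = maps[g].ravel()[:, None]
        raw = weights * act[None, :] * carrier + m.noise_sd * additive
        grids.append(
            GridRecording(
                values=raw, grid_id=g, muscle=m.muscle_labels[g], rate_hz=p.rate_hz
            )
        )

    # corrupt the requested channels after clean synthesis
    if m.bad_channels:
        scale = max(float(np.abs(np.concatenate([g.values for g in grids])).max()), 1.0)
        for g_idx, ch in m.bad_channels:
            vals = grids[g_idx].values
            if m.bad_channel_mode == "saturated":
                bad = np.full(n, 50.0 * scale)
                bad[:: max(n // 20, 1)] *= -1.0  # occasional polarity spikes
            else:
                bad = np.zeros(n)
            vals[ch] = bad

    return ContractionCycle(
        force=force,
        target_force=target,
        grids=tuple(grids),
        rate_hz=p.rate_hz,
        level=p.amplitude_fraction,
        rep_index=rep_index,
        seed=cycle_seed,
        true_activations=activations,
        bad_channels=tuple(m.bad_channels),
        dominant_grid=m.dominant_grid,
    )


def synthesize_session(
    m: MuscleModel,
    levels=(0.2, 0.4, 0.6),
    reps_per_level: int = 10,
    *,
    duration_s: float = 6.0,
    rate_hz: float = 1000.0,
    pattern: str = "sinusoid",
) -> list[ContractionCycle]:
    """Generate a full session: ``reps_per_level`` cycles at each force level.

    Each cycle gets a unique sub-seed spawned deterministically from the
    model seed, so sessions are reproducible while cycles stay independent.
    """
    levels = tuple(levels)
    if not levels:
        raise ValueError("levels must be non-empty")
    if reps_per_level < 3:
        raise ValueError("reps_per_level must be >= 3 for train/validation splits")
    root = np.random.SeedSequence([m.seed, 0x5E5510])
    sub_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(len(levels) * reps_per_level)]
    cycles = []
    i = 0
    for level in levels:
        profile = ForceProfile(
            pattern=pattern,
            amplitude_fraction=level,
            duration_s=duration_s,
            rate_hz=rate_hz,
        )
        for rep in range(reps_per_level):
            cycles.append(
                synthesize_cycle(m, profile, seed=sub_seeds[i], rep_index=rep)
            )
            i += 1
    return cycles


# ---------------------------------------------------------------------------
# Session disk layout: one directory per cycle with force.csv, grid<k>.csv,
# activation.csv (ground truth) and meta.yaml.
# ---------------------------------------------------------------------------

def save_session(cycles: list[ContractionCycle], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, cyc in enumerate(cycles):
        cdir = outdir / f"cycle_{i:03d}"
        cdir.mkdir(exist_ok=True)
        t = np.arange(cyc.n_samples) / cyc.rate_hz
        pd.DataFrame({"t_s": t, "force_fraction": cyc.force}).to_csv(
            cdir / "force.csv", index=False
        )
        for g in cyc.grids:
            cols = {f"ch{c + 1:02d}": g.values[c] for c in range(g.n_channels)}
            pd.DataFrame(cols).to_csv(cdir / f"grid{g.grid_id + 1}.csv", index=False)
        if cyc.true_activations is not None:
            pd.DataFrame(
                {f"grid{g + 1}": cyc.true_activations[g] for g in range(N_GRIDS)}
            ).to_csv(cdir / "activation.csv", index=False)
        meta = {
            "seed": cyc.seed,
            "level": float(cyc.level),
            "rep_index": int(cyc.rep_index),
            "rate_hz": float(cyc.rate_hz),
            "muscles": {g.grid_id + 1: g.muscle for g in cyc.grids},
            "bad_channels": [list(map(int, bc)) for bc in cyc.bad_channels],
            "dominant_grid": cyc.dominant_grid,
        }
        with open(cdir / "meta.yaml", "w") as fh:
            yaml.safe_dump(meta, fh)


def load_session(indir) -> list[ContractionCycle]:
    indir = Path(indir)
    cycle_dirs = sorted(d for d in indir.iterdir() if d.is_dir() and d.name.startswith("cycle_"))
    if not cycle_dirs:
        raise FileNotFoundError(f"no cycle_* directories under {indir}")
    cycles = []
    for cdir in cycle_dirs:
        with open(cdir / "meta.yaml") as fh:
            meta = yaml.safe_load(fh)
        force_df = pd.read_csv(cdir / "force.csv")
        force = force_df["force_fraction"].to_numpy()
        rate = float(meta["rate_hz"])
        grids = []
        for g in range(N_GRIDS):
            df = pd.read_csv(cdir / f"grid{g + 1}.csv")
            grids.append(
                GridRecording(
                    values=df.to_numpy().T,
                    grid_id=g,
                    muscle=meta["muscles"][g + 1],
                    rate_hz=rate,
                )
            )
        act_path = cdir / "activation.csv"
        acts = pd.read_csv(act_path).to_numpy().T if act_path.exists() else None
        cycles.append(
            ContractionCycle(
                force=force,
                target_force=force,
                grids=tuple(grids),
                rate_hz=rate,
                level=float(meta["level"]),
                rep_index=int(meta["rep_index"]),
                seed=meta.get("seed"),
                true_activations=acts,
                bad_channels=tuple(tuple(bc) for bc in meta.get("bad_channels", [])),
                dominant_grid=meta.get("dominant_grid"),
            )
        )
    return cycles
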