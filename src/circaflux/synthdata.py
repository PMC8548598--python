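"""Synthetic data with known ground truth for every pipeline stage.

Emulates the study design end to end: damped ~24 h Per2::Luc-like
luminescence traces with baseline drift and Gaussian noise, bioluminescence
image stacks tiled by ROI-sized blocks with cosmic-ray-like single-pixel
spikes, feeding-fasting protocol schedules (H/L media switched on a daily
cycle followed by free running), a first-order-uptake metabolite
concentration model, and rhythmic-vs-flat gene expression matrices sampled
every 4 h over 24 h with replicates and negative-binomial count noise.

Every generator is seeded and bit-reproducible, and every generator's
noise-free limit agrees with its closed form, so downstream estimators can
be tested against exact truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .core import ImageStack, InvalidInputError, TraceSet

DEFAULT_DT_H = 0.5  # default trace sampling interval, hours (30 min frames)


# ---------------------------------------------------------------------------
# luminescence traces
# ---------------------------------------------------------------------------

@dataclass
class TraceTruth:
    """Ground-truth parameters for one damped-sinusoid luminescence trace.

    The generating model is

        y(t) = baseline_offset + trend_slope * t
               + amplitude * exp(-t / damping_tau_h)
                 * sin(2*pi*t/period_h + 2*pi*phase0_h/period_h)
               + Normal(0, noise_sd)

    with ``damping_tau_h = inf`` meaning an undamped oscillation.
    """

    period_h: float = 24.0
    phase0_h: float = 0.0
    amplitude: float = 1.0
    damping_tau_h: float = math.inf
    baseline_offset: float = 0.0
    trend_slope: float = 0.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.period_h <= 0:
            raise InvalidInputError("period_h must be positive")
        if self.amplitude < 0:
            raise InvalidInputError("amplitude must be non-negative")
        if self.noise_sd < 0:
            raise InvalidInputError("noise_sd must be non-negative")
        if self.damping_tau_h <= 0:
            raise InvalidInputError("damping_tau_h must be positive (or inf)")

    def clean_values(self, t: np.ndarray) -> np.ndarray:
        """Noise-free model values on grid ``t`` (hours)."""
        t = np.asarray(t, dtype=float)
        decay = np.exp(-t / self.damping_tau_h) if math.isfinite(self.damping_tau_h) else 1.0
        phase = 2 * np.pi * t / self.period_h + 2 * np.pi * self.phase0_h / self.period_h
        return (self.baseline_offset + self.trend_slope * t
                + self.amplitude * decay * np.sin(phase))


def gen_trace(truth: TraceTruth, t_grid: Sequence[float],
              name: str = "trace", condition: str | None = None) -> TraceSet:
    """Generate one seeded synthetic luminescence trace on ``t_grid`` (hours)."""
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or t.size < 2 or np.any(np.diff(t) <= 0):
        raise InvalidInputError("t_grid must be strictly increasing")
    rng = np.random.default_rng(truth.seed)
    y = truth.clean_values(t)
    if truth.noise_sd > 0:
        y = y + rng.normal(0.0, truth.noise_sd, size=t.size)
    return TraceSet(t, y[:, None], [name], condition)


def default_grid(duration_h: float = 144.0, dt_h: float = DEFAULT_DT_H,
                 t0_h: float = 0.0) -> np.ndarray:
    """30-min sampling grid covering ``duration_h`` hours (6 days default)."""
    n = int(round(duration_h / dt_h)) + 1
    return t0_h + dt_h * np.arange(n)


# ---------------------------------------------------------------------------
# image stacks
# ---------------------------------------------------------------------------

class SyntheticStack(NamedTuple):
    """Image stack plus the ground truth used to build it."""

    stack: ImageStack
    spikes: list[tuple[int, int, int]]  # (frame, row, col) of injected spikes
    clean: ImageStack                   # noise- and spike-free frames
    traces: TraceSet                    # per-ROI generating traces (row-major)


def gen_image_stack(truths: Sequence[Sequence[TraceTruth]],
                    t_grid: Sequence[float],
                    roi_size_px: int,
                    *,
                    frame_shape: tuple[int, int] | None = None,
                    pixel_noise_sd: float = 0.0,
                    spike_rate: float = 0.0,
                    spike_amp: float = 0.0,
                    seed: int = 0,
                    as_uint16: bool = False) -> SyntheticStack:
    """Build a bioluminescence time-lapse stack from a grid of trace truths.

    Each ROI-sized block of every frame carries the value of its generating
    trace at that frame's timestamp, plus optional Gaussian pixel (shot-like)
    noise and Poisson-placed single-pixel spikes of amplitude ``spike_amp``
    that emulate cosmic-ray artifacts.  Ground-truth spike coordinates are
    returned so removal can be scored exactly.
    """
    truth_grid = np.asarray(truths, dtype=object)
    if truth_grid.ndim != 2:
        raise InvalidInputError("truths must be a 2-D grid of TraceTruth")
    gr, gc = truth_grid.shape
    if frame_shape is None:
        frame_shape = (gr * roi_size_px, gc * roi_size_px)
    if frame_shape != (gr * roi_size_px, gc * roi_size_px):
        raise InvalidInputError(
            f"ROI grid {gr}x{gc} of {roi_size_px}px ROIs does not tile frame {frame_shape}")
    t = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise InvalidInputError("t_grid must be strictly increasing")

    names, cols = [], []
    for i in range(gr):
        for j in range(gc):
            ts = gen_trace(truth_grid[i, j], t, name=f"r{i}c{j}")
            names.append(f"r{i}c{j}")
            cols.append(ts.values[:, 0])
    traces = TraceSet(t, np.column_stack(cols), names)

    n_t = t.size
    frames = np.empty((n_t, *frame_shape), dtype=float)
    block = traces.values.reshape(n_t, gr, gc)
    frames[:] = np.repeat(np.repeat(block, roi_size_px, axis=1), roi_size_px, axis=2)
    clean = ImageStack(frames.copy(), t)

    # separate child streams keep base frames identical when noise/spikes off
    noise_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[0])
    spike_rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(2)[1])
    if pixel_noise_sd > 0:
        frames += noise_rng.normal(0.0, pixel_noise_sd, size=frames.shape)
    spikes: list[tuple[int, int, int]] = []
    if spike_rate > 0:
        n_px = frame_shape[0] * frame_shape[1]
        for k in range(n_t):
            n_spk = min(int(spike_rng.poisson(spike_rate)), n_px)
            if n_spk == 0:
                continue
            flat = spike_rng.choice(n_px, size=n_spk, replace=False)
            rr, cc = np.unravel_index(flat, frame_shape)
            frames[k, rr, cc] += spike_amp
            spikes.extend((k, int(r), int(c)) for r, c in zip(rr, cc))

    stack = ImageStack(frames, t)
    if as_uint16:
        stack = stack.astype_uint16()
    return SyntheticStack(stack, spikes, clean, traces)


# ---------------------------------------------------------------------------
# feeding-fasting protocols
# ---------------------------------------------------------------------------

ORDERS = ("HL", "LH", "HH", "LL")


@dataclass
class Protocol:
    """A cyclic two-phase medium-delivery protocol followed by free running.

    ``order`` names the media of the first and second phase of each cycle
    (H = high glucose/insulin feeding medium, L = low fasting medium);
    ``duty`` gives the two phase durations in hours and must sum to
    ``cycle_period_h``.  ``media`` stores (glucose mM, insulin nM) for each
    medium; both are free parameters of the generator.
    """

    cycle_period_h: float = 24.0
    duty: tuple[float, float] = (12.0, 12.0)
    order: str = "HL"
    n_cycles: int = 3
    start_zt_h: float = 0.0
    media: dict = field(default_factory=lambda: {"H": (25.0, 10.0), "L": (2.0, 0.0)})

    def __post_init__(self) -> None:
        if self.order not in ORDERS:
            raise InvalidInputError(f"order must be one of {ORDERS}")
        if abs(self.duty[0] + self.duty[1] - self.cycle_period_h) > 1e-9:
            raise InvalidInputError("duty phases must sum to cycle_period_h")
        if min(self.duty) < 0:
            raise InvalidInputError("duty phases must be non-negative")
        if self.n_cycles < 1:
            raise InvalidInputError("n_cycles must be >= 1")


@dataclass
class Schedule:
    """Piecewise-constant media state: intervals, switch times, FR start."""

    intervals: list[tuple[float, float, str]]  # (t_start, t_end, 'H'|'L')
    switch_times: list[float]                  # all boundaries after t=start
    free_run_start_h: float


def protocol_schedule(p: Protocol) -> Schedule:
    """Expand a protocol into its media intervals and switch times."""
    states = (p.order[0], p.order[1])
    intervals: list[tuple[float, float, str]] = []
    switches: list[float] = []
    t = p.start_zt_h
    for _ in range(p.n_cycles):
        for state, dur in zip(states, p.duty):
            if dur <= 0:
                continue
            intervals.append((t, t + dur, state))
            t += dur
            switches.append(t)
    return Schedule(intervals, switches, t)


def protocol_concentration(p: Protocol, k_uptake: float,
                           c_h: float, c_l: float,
                           t_grid: Sequence[float]) -> np.ndarray:
    """Representative metabolite concentration under a delivery protocol.

    Between medium changes the concentration depletes by first-order
    cellular uptake, ``dC/dt = -k*C``; at each change it is reset to the
    incoming medium's concentration (``c_h`` or ``c_l``).  After the last
    cycle no further resets occur (free running) and the decay continues
    from the final reset.
    """
    if k_uptake < 0:
        raise InvalidInputError("k_uptake must be non-negative")
    sched = protocol_schedule(p)
    t = np.asarray(t_grid, dtype=float)
    starts = np.array([iv[0] for iv in sched.intervals])
    c0 = np.array([c_h if iv[2] == "H" else c_l for iv in sched.intervals])
    idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, starts.size - 1)
    return c0[idx] * np.exp(-k_uptake * np.maximum(t - starts[idx], 0.0))


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

@dataclass
class ExprTruth:
    """Ground truth for a rhythmic-vs-flat gene expression matrix.

    Rhythmic genes follow ``cpm(t) = baseline*(1 + A*cos(2*pi*(t-lag)/T))``
    with negative-binomial count noise (variance ``mu + dispersion*mu^2``);
    flat genes sit at constant baseline.  ``lag_h``/``rel_amplitude``/
    ``baseline_cpm`` may be scalars (shared) or per-gene arrays; ``lag_h``
    of None draws lags uniformly on [0, period_h).
    """

    n_genes: int = 1000
    frac_rhythmic: float = 0.2
    period_h: float = 24.0
    lag_h: float | Sequence[float] | None = None
    rel_amplitude: float | Sequence[float] = 0.5
    baseline_cpm: float | Sequence[float] = 100.0
    dispersion: float = 0.1
    timepoints_h: tuple[float, ...] = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0)
    n_replicates: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1:
            raise InvalidInputError("n_genes must be >= 1")
        if not 0.0 <= self.frac_rhythmic <= 1.0:
            raise InvalidInputError("frac_rhythmic must lie in [0, 1]")
        tp = np.asarray(self.timepoints_h, dtype=float)
        if tp.size > 2 and not np.allclose(np.diff(tp), np.diff(tp)[0]):
            raise InvalidInputError("timepoints_h must be equally spaced")
        if np.any(np.asarray(self.rel_amplitude, dtype=float) > 1.0):
            raise InvalidInputError("rel_amplitude > 1 gives negative means")
        if self.lag_h is not None:
            lag = np.asarray(self.lag_h, dtype=float)
            if np.any(lag < 0) or np.any(lag >= self.period_h):
                raise InvalidInputError("lag_h must lie in [0, period_h)")


class ExprData(NamedTuple):
    counts: pd.DataFrame       # genes x samples
    annot: pd.DataFrame        # sample, timepoint_h, replicate
    truth: pd.DataFrame        # per-gene class, lag, amplitude, baseline


def _per_gene(value, n: int, rng: np.random.Generator | None = None,
              period: float | None = None) -> np.ndarray:
    if value is None:
        return rng.uniform(0.0, period, size=n)
    arr = np.asarray(value, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.size != n:
        raise InvalidInputError("per-gene parameter length mismatch")
    return arr


def gen_expr_matrix(truth: ExprTruth) -> ExprData:
    """Generate a seeded gene-by-sample count matrix with its truth table.

    With the default six 4-h timepoints and four replicates the mean counts
    are on the cpm scale directly (implicit constant library size), so the
    matrix can feed cpm filtering and amplitude thresholds unchanged.
    """
    rng = np.random.default_rng(truth.seed)
    n_r = int(round(truth.frac_rhythmic * truth.n_genes))
    n_genes = truth.n_genes
    tp = np.asarray(truth.timepoints_h, dtype=float)
    samples = [(t, r) for t in tp for r in range(1, truth.n_replicates + 1)]
    sample_names = [f"t{int(t):02d}_r{r}" for t, r in samples]
    t_vec = np.array([t for t, _ in samples])

    lags = np.zeros(n_genes)
    amps = np.zeros(n_genes)
    lags[:n_r] = _per_gene(truth.lag_h, n_r, rng, truth.period_h)
    amps[:n_r] = _per_gene(truth.rel_amplitude, n_r)
    base = _per_gene(truth.baseline_cpm, n_genes)

    mu = base[:, None] * (1.0 + amps[:, None]
                          * np.cos(2 * np.pi * (t_vec[None, :] - lags[:, None])
                                   / truth.period_h))
    mu = np.maximum(mu, 0.0)
    if truth.dispersion > 0:
        r = 1.0 / truth.dispersion
        p = r / (r + mu)
        counts = rng.negative_binomial(r, p)
    else:
        counts = rng.poisson(mu)

    genes = [f"g{i:05d}" for i in range(n_genes)]
    counts_df = pd.DataFrame(counts.astype(float), index=genes, columns=sample_names)
    annot = pd.DataFrame({"sample": sample_names,
                          "timepoint_h": t_vec,
                          "replicate": [r for _, r in samples]})
    truth_df = pd.DataFrame({"gene": genes,
                             "is_rhythmic": [i < n_r for i in range(n_genes)],
                             "period_h": truth.period_h,
                             "lag_h": lags,
                             "rel_amplitude": amps,
                             "baseline_cpm": base})
    return ExprData(counts_df, annot, truth_df.set_index("gene"))
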