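"""Trial-frequency decomposition of reaction-time series.

A subject's RTs, indexed by trial number, form a discrete "time" series in
which the sampling unit is one trial.  Convolving that series with a bank of
complex Gabor (Morlet) wavelets yields power as a function of trial and of
frequency in cycles per trial — a trial x frequency map of when, and on what
trial scale, performance fluctuates.

The wavelet at center frequency f_G is

    G(dt) = (1 / (sqrt(2*pi) * sigma_G)) * exp(-dt^2 / (2*sigma_G^2)
                                               + i * 2*pi * f_G * dt)

with envelope SD sigma_G = 0.5 / f_G trials and a nominal support (window) of
4*sigma_G trials, realized as the nearest odd tap count >= 4*sigma_G so the
kernel is symmetric about its center.  Frequencies are laid out on a grid with
step 1/T cycles per trial (0.0033 for a 300-trial session) up to a
configurable maximum, 0.5 cycles/trial (the Nyquist limit on the trial index)
by default.

The series is mean-centered before convolution — without centering the DC
offset of ~1200 ms would dominate every low frequency — and zero-padded at the
edges.  Bins whose kernel support overhangs the series edges are flagged in a
cone-of-influence mask so statistics can optionally exclude them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import RTSeries

__all__ = [
    "FrequencyGrid",
    "Kernel",
    "TFTMap",
    "frequency_grid",
    "make_kernel",
    "decompose",
    "group_mean_map",
]

DEFAULT_F_MAX = 0.5  # cycles/trial; Nyquist on the trial index
MIN_TRIALS = 8


@dataclass(frozen=True)
class FrequencyGrid:
    """Frequency axis for a series of T trials: multiples of 1/T up to f_max."""

    T: int
    f_max: float
    frequencies: np.ndarray

    @property
    def step(self) -> float:
        return 1.0 / self.T

    @property
    def n_frequencies(self) -> int:
        return int(self.frequencies.size)


def frequency_grid(T: int, f_max: float = DEFAULT_F_MAX) -> FrequencyGrid:
    """Build the frequency grid {1/T, 2/T, ...} up to ``f_max`` cycles/trial."""
    if T < MIN_TRIALS:
        raise ValueError(f"series too short for a usable grid: T={T} < {MIN_TRIALS}")
    if not (0.0 < f_max <= 0.5):
        raise ValueError(f"f_max must be in (0, 0.5], got {f_max}")
    n = int(np.floor(f_max * T + 1e-9))
    if n < 1:
        raise ValueError(f"no grid frequency at or below f_max={f_max} for T={T}")
    freqs = np.arange(1, n + 1, dtype=float) / T
    return FrequencyGrid(T=int(T), f_max=float(f_max), frequencies=freqs)


@dataclass(frozen=True)
class Kernel:
    """Discrete complex Gabor kernel for one center frequency."""

    f_G: float
    sigma_G: float
    taps: np.ndarray
    center_index: int

    @property
    def n_taps(self) -> int:
        return int(self.taps.size)

    @property
    def half_width(self) -> int:
        return self.center_index


def make_kernel(f_G: float) -> Kernel:
    """Build the Gabor kernel at ``f_G`` cycles/trial.

    sigma_G = 0.5 / f_G; the nominal 4*sigma_G support is realized as the
    nearest odd integer number of taps >= 4*sigma_G, centered at index
    (n_taps - 1) / 2.
    """
    if not f_G > 0:
        raise ValueError(f"f_G must be positive, got {f_G}")
    sigma = 0.5 / f_G
    nominal = 4.0 * sigma
    n_taps = int(np.ceil(nominal))
    if n_taps % 2 == 0:
        n_taps += 1
    center = (n_taps - 1) // 2
    dt = np.arange(n_taps, dtype=float) - center
    taps = (1.0 / (np.sqrt(2.0 * np.pi) * sigma)) * np.exp(
        -(dt**2) / (2.0 * sigma**2) + 1j * 2.0 * np.pi * f_G * dt
    )
    return Kernel(f_G=float(f_G), sigma_G=float(sigma), taps=taps, center_index=center)


@dataclass
class TFTMap:
    """Trial x frequency power map for one subject (or a group average).

    ``power[t, k]`` is the squared modulus of the wavelet coefficient at trial
    ``t`` and frequency ``grid.frequencies[k]``; ``coi_mask[t, k]`` is True
    where the kernel support extends past the series edges (cone of
    influence).
    """

    power: np.ndarray
    grid: FrequencyGrid
    coi_mask: np.ndarray
    subject_id: str | None = None

    def __post_init__(self) -> None:
        self.power = np.asarray(self.power, dtype=float)
        self.coi_mask = np.asarray(self.coi_mask, dtype=bool)
        expected = (self.grid.T, self.grid.n_frequencies)
        if self.power.shape != expected:
            raise ValueError(f"power shape {self.power.shape} != {expected}")
        if self.coi_mask.shape != expected:
            raise ValueError(f"coi_mask shape {self.coi_mask.shape} != {expected}")
        if np.any(self.power < 0):
            raise ValueError("power must be nonnegative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.power.shape

    def trial_marginal(self, exclude_coi: bool = False) -> np.ndarray:
        """Total power per trial, summed over frequencies.

        With ``exclude_coi`` the edge-contaminated bins are dropped from the
        sum (trials where every bin is edge-contaminated yield 0).
        """
        if exclude_coi:
            return np.where(self.coi_mask, 0.0, self.power).sum(axis=1)
        return self.power.sum(axis=1)

    def frequency_marginal(self, exclude_coi: bool = False) -> np.ndarray:
        """Total power per frequency, summed over trials."""
        if exclude_coi:
            return np.where(self.coi_mask, 0.0, self.power).sum(axis=0)
        return self.power.sum(axis=0)


def decompose(series: RTSeries | np.ndarray, grid: FrequencyGrid,
              subject_id: str | None = None) -> TFTMap:
    """Decompose an RT series into its trial x frequency power map.

    The series is mean-centered, then correlated with the Gabor kernel at
    every grid frequency (zero-padding beyond the series edges):

        power[t, k] = | sum_j x(t + dt_j) * conj(taps_k[j]) |^2

    The result is deterministic given its inputs.
    """
    if isinstance(series, RTSeries):
        x = series.values
    else:
        x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise ValueError("series must be 1-D")
    T = x.size
    if T != grid.T:
        raise ValueError(f"series length {T} != grid.T {grid.T}")
    x = x - x.mean()

    F = grid.n_frequencies
    power = np.empty((T, F))
    coi = np.zeros((T, F), dtype=bool)
    t_idx = np.arange(T)
    for k, f in enumerate(grid.frequencies):
        kern = make_kernel(f)
        # correlation with the kernel == convolution with the reversed
        # conjugate taps; slice the center-aligned T samples of the full
        # convolution (kernels may be longer than the series)
        full = np.convolve(x, np.conj(kern.taps[::-1]))
        coef = full[kern.center_index:kern.center_index + T]
        power[:, k] = np.abs(coef) ** 2
        h = kern.half_width
        coi[:, k] = (t_idx < h) | (t_idx > T - 1 - h)
    return TFTMap(power=power, grid=grid, coi_mask=coi, subject_id=subject_id)


def group_mean_map(maps: list[TFTMap]) -> TFTMap:
    """Element-wise mean power over subjects; COI is the union of the inputs'."""
    if not maps:
        raise ValueError("need at least one map")
    grid = maps[0].grid
    shape = maps[0].shape
    for m in maps[1:]:
        if m.shape != shape or m.grid.T != grid.T or \
                m.grid.n_frequencies != grid.n_frequencies:
            raise ValueError("maps have heterogeneous dimensions")
    power = np.mean([m.power for m in maps], axis=0)
    coi = np.logical_or.reduce([m.coi_mask for m in maps])
    return TFTMap(power=power, grid=grid, coi_mask=coi)
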