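"""Synthetic reaction-time sessions with controlled variability structure.

Two classical summaries — mean RT and RT_SD — cannot distinguish *how*
trial-to-trial variability unfolds: the same standard deviation can come from
noise that is uniformly elevated throughout, from a few strong bursts, from
many short bursts, or from a slow drift.  This module generates all of these:

* :func:`generate_profile` draws one of four archetype profiles (``uniform``,
  ``sparse_bursts``, ``dense_bursts``, ``slow_drift``) and rescales the
  deviations so the sample SD equals the requested target *exactly*, making
  "identical SD, different structure" a constructive property rather than an
  asymptotic one.
* :func:`simulate_session` draws a full time-estimation session (default 300
  trials): Gaussian tonic noise around a mean RT, optional burst epochs in
  which the noise SD is multiplied by a factor, and an independent per-trial
  probability of producing no response at all.
* :func:`simulate_cohort` draws two groups of sessions with per-subject seeds
  derived deterministically from one master seed.
* :func:`apply_tonic_shift` adds a constant to every present RT — the model
  of a treatment that moves the overall response level without touching the
  fluctuation profile.

Default calibration (control-like group): mean RT 1171 ms, tonic SD 247 ms,
no bursts.  Patient-like group: mean RT 1137 ms, tonic SD 247 ms plus 4 burst
epochs of 16 trials at 3x SD, which puts the expected session RT_SD near
405 ms (total variance sigma^2 * (1 + frac * (m^2 - 1)) with burst fraction
frac = 64/300 and multiplier m = 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .behavior import RTSeries, Session

__all__ = [
    "ProfileSpec",
    "GroupParams",
    "CohortSpec",
    "PROFILE_KINDS",
    "generate_profile",
    "simulate_session",
    "simulate_cohort",
    "apply_tonic_shift",
    "control_like",
    "patient_like",
]

PROFILE_KINDS = ("uniform", "sparse_bursts", "dense_bursts", "slow_drift")

DEFAULT_T = 300
DEFAULT_MEAN_RT = 1171.0  # ms, control-like
DEFAULT_TARGET_SD = 247.0  # ms, control-like RT_SD


@dataclass(frozen=True)
class ProfileSpec:
    """Parameters for one archetype RT profile.

    ``n_epochs`` / ``epoch_length`` / ``burst_sd_multiplier`` apply to the
    burst kinds only; ``drift_freq`` (cycles/trial) to ``slow_drift`` only.
    """

    kind: str
    T: int = DEFAULT_T
    target_sd: float = DEFAULT_TARGET_SD
    mean_rt: float = DEFAULT_MEAN_RT
    n_epochs: int = 3
    epoch_length: int = 20
    burst_sd_multiplier: float = 5.0
    drift_freq: float = 0.01
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in PROFILE_KINDS:
            raise ValueError(f"kind must be one of {PROFILE_KINDS}, got {self.kind!r}")
        if not self.target_sd > 0:
            raise ValueError("target_sd must be positive")
        if self.T < 2:
            raise ValueError("need T >= 2")
        if self.kind.endswith("bursts") and self.n_epochs * self.epoch_length >= self.T:
            raise ValueError("burst epochs must not fill the whole session")


def _place_epochs(rng: np.random.Generator, T: int, n_epochs: int,
                  epoch_length: int) -> list[tuple[int, int]]:
    """Randomly place non-overlapping [start, end) epochs inside [0, T)."""
    epochs: list[tuple[int, int]] = []
    for _ in range(200):
        if len(epochs) == n_epochs:
            break
        start = int(rng.integers(0, T - epoch_length + 1))
        cand = (start, start + epoch_length)
        if all(cand[1] <= s or cand[0] >= e for s, e in epochs):
            epochs.append(cand)
    if len(epochs) < n_epochs:
        raise RuntimeError("could not place non-overlapping burst epochs")
    return sorted(epochs)


def generate_profile(spec: ProfileSpec) -> RTSeries:
    """Draw one archetype profile and rescale to the exact target SD.

    The deviation process depends on the kind:

    * ``uniform`` — i.i.d. Gaussian noise;
    * ``sparse_bursts`` — Gaussian noise whose SD is multiplied inside a few
      randomly placed epochs;
    * ``dense_bursts`` — the same with more, shorter epochs and a milder
      multiplier;
    * ``slow_drift`` — a low-frequency sinusoid plus Gaussian noise.

    Deviations are then centered and rescaled so the sample SD (n-1
    denominator) equals ``spec.target_sd`` exactly, and ``spec.mean_rt`` is
    added.  The output is fully determined by ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    T = spec.T
    if spec.kind == "uniform":
        dev = rng.standard_normal(T)
        epochs: list[tuple[int, int]] = []
    elif spec.kind in ("sparse_bursts", "dense_bursts"):
        if spec.kind == "dense_bursts":
            n_epochs = max(2 * spec.n_epochs, spec.n_epochs + 1)
            length = max(spec.epoch_length // 2, 2)
            mult = 1.0 + 0.5 * (spec.burst_sd_multiplier - 1.0)
        else:
            n_epochs, length, mult = spec.n_epochs, spec.epoch_length, \
                spec.burst_sd_multiplier
        epochs = _place_epochs(rng, T, n_epochs, length)
        sd = np.ones(T)
        for s, e in epochs:
            sd[s:e] = mult
        dev = rng.standard_normal(T) * sd
    else:  # slow_drift
        phase = rng.uniform(0, 2 * np.pi)
        t = np.arange(T)
        # drift carries most of the variance; noise keeps it non-degenerate
        dev = 1.4 * np.sin(2 * np.pi * spec.drift_freq * t + phase) \
            + 0.4 * rng.standard_normal(T)
        epochs = []
    dev = dev - dev.mean()
    s = dev.std(ddof=1)
    if s == 0:  # astronomically unlikely; degenerate draw
        raise RuntimeError("degenerate deviation draw (zero variance)")
    values = spec.mean_rt + dev * (spec.target_sd / s)
    series = RTSeries(values=values, valid_mask=np.ones(T, dtype=bool))
    series.epochs = epochs  # burst placement, for localization checks
    return series


@dataclass(frozen=True)
class GroupParams:
    """Generative parameters for one group of subjects.

    ``burst_*`` parameters describe intermittent high-variability epochs:
    ``n_bursts`` epochs of ``burst_length`` trials in which the tonic noise SD
    is multiplied by ``burst_sd_multiplier``.  ``miss_prob`` is the
    independent per-trial probability of no key press.
    """

    mean_rt: float = DEFAULT_MEAN_RT
    tonic_sd: float = DEFAULT_TARGET_SD
    n_bursts: int = 0
    burst_length: int = 16
    burst_sd_multiplier: float = 3.0
    burst_window: tuple[int, int] | None = None  # restrict placement, [start, end)
    miss_prob: float = 0.0
    T: int = DEFAULT_T

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_prob <= 1.0):
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.tonic_sd < 0:
            raise ValueError("tonic_sd must be nonnegative")

    def expected_sd(self) -> float:
        """Expected session RT_SD implied by the tonic/burst mixture."""
        frac = self.n_bursts * self.burst_length / self.T
        return self.tonic_sd * np.sqrt(
            1.0 + frac * (self.burst_sd_multiplier**2 - 1.0))


def control_like() -> GroupParams:
    """Healthy-control calibration: mean RT 1171 ms, RT_SD 247 ms, ~1% misses."""
    return GroupParams(mean_rt=1171.0, tonic_sd=247.0, n_bursts=0,
                       miss_prob=0.01)


def patient_like() -> GroupParams:
    """Patient-like calibration: intermittent variability bursts on a
    control-like tonic floor; expected RT_SD ~ 405 ms, ~4% misses."""
    return GroupParams(mean_rt=1137.0, tonic_sd=247.0, n_bursts=4,
                       burst_length=16, burst_sd_multiplier=3.0,
                       miss_prob=0.04)


@dataclass(frozen=True)
class CohortSpec:
    """Two groups of simulated subjects plus a master seed."""

    n_a: int
    n_b: int
    params_a: GroupParams = field(default_factory=control_like)
    params_b: GroupParams = field(default_factory=patient_like)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise ValueError("need at least 2 subjects per group")


def simulate_session(params: GroupParams, subject_id: str = "sim",
                     seed: int | np.random.Generator | None = None) -> Session:
    """Draw one full time-estimation session.

    RTs are Gaussian around ``params.mean_rt`` with SD ``params.tonic_sd``,
    multiplied by ``params.burst_sd_multiplier`` inside randomly placed burst
    epochs (restricted to ``params.burst_window`` when given).  Each trial is
    independently missed (no key press, RT absent) with ``params.miss_prob``.
    Draws are clipped at 0 ms.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    T = params.T
    sd = np.full(T, float(params.tonic_sd))
    if params.n_bursts > 0:
        if params.burst_window is not None:
            window_len = params.burst_window[1] - params.burst_window[0]
            cap = window_len  # an explicit window may be filled completely
        else:
            window_len = T
            cap = 0.8 * T  # unconstrained bursts must stay intermittent
        if params.n_bursts * params.burst_length > cap:
            raise ValueError(
                f"{params.n_bursts} bursts of {params.burst_length} trials do "
                f"not fit in a window of {window_len} trials")
        if params.burst_window is not None:
            lo, hi = params.burst_window
            sub = _place_epochs(rng, hi - lo, params.n_bursts, params.burst_length)
            epochs = [(s + lo, e + lo) for s, e in sub]
        else:
            epochs = _place_epochs(rng, T, params.n_bursts, params.burst_length)
        for s, e in epochs:
            sd[s:e] *= params.burst_sd_multiplier
    rts = params.mean_rt + sd * rng.standard_normal(T)
    np.clip(rts, 0.0, None, out=rts)
    if params.miss_prob > 0:
        rts[rng.random(T) < params.miss_prob] = np.nan
    return Session(subject_id=subject_id, rts=rts)


def simulate_cohort(spec: CohortSpec) -> tuple[list[Session], list[Session]]:
    """Draw both groups; per-subject streams spawn from the master seed."""
    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_a + spec.n_b)
    group_a = [
        simulate_session(spec.params_a, subject_id=f"a{i:03d}",
                         seed=np.random.default_rng(children[i]))
        for i in range(spec.n_a)
    ]
    group_b = [
        simulate_session(spec.params_b, subject_id=f"b{i:03d}",
                         seed=np.random.default_rng(children[spec.n_a + i]))
        for i in range(spec.n_b)
    ]
    return group_a, group_b


def apply_tonic_shift(session: Session, shift: float) -> Session:
    """Shift every present RT by a constant; missed trials stay missed.

    Models a treatment that moves the overall response level (tonic effect)
    while leaving the trial-to-trial fluctuation profile untouched: the RT_SD
    and the wavelet power map are invariant, but response classification (and
    hence accuracy counts) can change.  Shifted RTs are clipped at 0 ms.
    """
    if not np.isfinite(shift):
        raise ValueError("shift must be finite")
    rts = session.rts.copy()
    present = ~np.isnan(rts)
    rts[present] = np.clip(rts[present] + shift, 0.0, None)
    return Session(subject_id=session.subject_id, rts=rts,
                   block_size=session.block_size)
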