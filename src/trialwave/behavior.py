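"""Response classification and reaction-time series construction for the
time-estimation task.

Subjects estimate a 1200 ms interval and press a button when they believe it
has elapsed.  A response is scored by when it lands relative to the target:

* ``correct`` — within 200 ms of the target, i.e. in [1000, 1400] ms,
* ``early``   — in [400, 1000) ms,
* ``late``    — in (1400, 2000] ms,
* ``missed``  — before 400 ms, after 2000 ms, or no key press at all.

The window boundaries 1000 and 1400 ms count as correct; the outer boundaries
400 and 2000 ms count as early/late.  This closed-correct convention makes the
four classes an exact partition of [0, inf) plus "no response".

Missed trials carry no usable RT but the wavelet decomposition needs a
contiguous series, so :func:`build_rt_series` fills gaps by linear
interpolation between the nearest valid neighbors (edge gaps take the nearest
valid value) and records which positions were imputed in a validity mask.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ResponseClass",
    "Session",
    "RTSeries",
    "BehaviorSummary",
    "classify_response",
    "summarize_session",
    "build_rt_series",
]

# Response windows in ms after cue onset.
EARLY_MIN = 400.0
CORRECT_MIN = 1000.0
CORRECT_MAX = 1400.0
LATE_MAX = 2000.0
TARGET_MS = 1200.0

DEFAULT_TRIALS = 300
DEFAULT_BLOCK_SIZE = 100


class ResponseClass(str, enum.Enum):
    """Outcome category of a single time-estimation response."""

    CORRECT = "correct"
    EARLY = "early"
    LATE = "late"
    MISSED = "missed"


def classify_response(rt: float | None) -> ResponseClass:
    """Classify a single response time (ms) into its outcome category.

    Parameters
    ----------
    rt
        Response time in milliseconds since cue onset, or ``None`` / NaN if no
        key press occurred.

    Returns
    -------
    ResponseClass
        Exactly one of correct / early / late / missed.

    Raises
    ------
    ValueError
        If ``rt`` is negative.
    """
    if rt is None or (isinstance(rt, float) and math.isnan(rt)):
        return ResponseClass.MISSED
    rt = float(rt)
    if rt < 0:
        raise ValueError(f"response time must be nonnegative, got {rt}")
    if CORRECT_MIN <= rt <= CORRECT_MAX:
        return ResponseClass.CORRECT
    if EARLY_MIN <= rt < CORRECT_MIN:
        return ResponseClass.EARLY
    if CORRECT_MAX < rt <= LATE_MAX:
        return ResponseClass.LATE
    return ResponseClass.MISSED


@dataclass
class Session:
    """One subject's run of the time-estimation task.

    ``rts`` holds one value per trial in presentation order; NaN marks trials
    with no key press.  The default session is three blocks of 100 trials.
    """

    subject_id: str
    rts: np.ndarray
    block_size: int = DEFAULT_BLOCK_SIZE

    def __post_init__(self) -> None:
        self.rts = np.asarray(self.rts, dtype=float)
        if self.rts.ndim != 1 or self.rts.size == 0:
            raise ValueError("rts must be a non-empty 1-D array")
        present = self.rts[~np.isnan(self.rts)]
        if np.any(present < 0):
            raise ValueError("response times must be nonnegative")

    @property
    def n_trials(self) -> int:
        return int(self.rts.size)

    def classes(self) -> list[ResponseClass]:
        """Per-trial outcome categories."""
        return [classify_response(None if np.isnan(v) else float(v)) for v in self.rts]


@dataclass
class RTSeries:
    """A contiguous reaction-time series ready for decomposition.

    ``valid_mask`` is False where the original response was missed and the
    value was imputed.
    """

    values: np.ndarray
    valid_mask: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.values.shape != self.valid_mask.shape:
            raise ValueError("values and valid_mask must have the same shape")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("series values must be finite")

    def __len__(self) -> int:
        return int(self.values.size)


@dataclass
class BehaviorSummary:
    """Counts per response class plus RT mean and variability for one session.

    ``mean_rt`` / ``sd_rt`` are computed over all non-missed responses
    (early + correct + late) and are NaN when fewer than one / two such
    responses exist.  ``sd_rt`` uses the sample (n-1) denominator — this is
    the classical RT-variability (RT_SD) summary of intra-individual
    variability.
    """

    subject_id: str
    n_correct: int
    n_early: int
    n_late: int
    n_missed: int
    mean_rt: float
    sd_rt: float

    @property
    def n_trials(self) -> int:
        return self.n_correct + self.n_early + self.n_late + self.n_missed

    def to_dict(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_correct": self.n_correct,
            "n_early": self.n_early,
            "n_late": self.n_late,
            "n_missed": self.n_missed,
            "mean_rt": self.mean_rt,
            "sd_rt": self.sd_rt,
        }

    def to_json(self) -> str:
        d = self.to_dict()
        for k in ("mean_rt", "sd_rt"):
            if math.isnan(d[k]):
                d[k] = None
        return json.dumps(d)


def summarize_session(session: Session, rt_over: str = "scored") -> BehaviorSummary:
    """Count response classes and compute RT mean / SD for a session.

    ``rt_over`` selects which responses enter ``mean_rt`` / ``sd_rt``:
    ``"scored"`` (default) uses early + correct + late responses only —
    presses outside the 400–2000 ms scoring window are excluded along with
    absent responses; ``"present"`` uses every key press regardless of
    classification.  The class counts are unaffected.
    """
    if rt_over not in ("scored", "present"):
        raise ValueError(f"rt_over must be 'scored' or 'present', got {rt_over!r}")
    counts = {c: 0 for c in ResponseClass}
    scored: list[float] = []
    for v in session.rts:
        cls = classify_response(None if np.isnan(v) else float(v))
        counts[cls] += 1
        if rt_over == "scored":
            if cls is not ResponseClass.MISSED:
                scored.append(float(v))
        elif not np.isnan(v):
            scored.append(float(v))
    scored_arr = np.asarray(scored)
    mean_rt = float(np.mean(scored_arr)) if scored_arr.size >= 1 else float("nan")
    sd_rt = float(np.std(scored_arr, ddof=1)) if scored_arr.size >= 2 else float("nan")
    return BehaviorSummary(
        subject_id=session.subject_id,
        n_correct=counts[ResponseClass.CORRECT],
        n_early=counts[ResponseClass.EARLY],
        n_late=counts[ResponseClass.LATE],
        n_missed=counts[ResponseClass.MISSED],
        mean_rt=mean_rt,
        sd_rt=sd_rt,
    )


def build_rt_series(session: Session) -> RTSeries:
    """Build the contiguous RT series the wavelet decomposition consumes.

    Non-missed trials keep their observed RT.  Missed trials (no press, or a
    press outside [400, 2000] ms) are imputed by linear interpolation between
    the nearest valid neighbors; gaps at the edges take the nearest valid
    value.  The returned mask is False at imputed positions so downstream
    statistics can discount them.

    Raises
    ------
    ValueError
        If fewer than two trials carry a valid (non-missed) RT.
    """
    rts = session.rts
    valid = np.array(
        [classify_response(None if np.isnan(v) else float(v)) is not ResponseClass.MISSED
         for v in rts],
        dtype=bool,
    )
    n_valid = int(valid.sum())
    if n_valid < 2:
        raise ValueError(
            f"subject {session.subject_id!r}: need at least 2 non-missed trials, "
            f"got {n_valid}"
        )
    idx = np.arange(rts.size)
    # np.interp extends with the nearest valid value beyond the first/last knot.
    values = np.interp(idx, idx[valid], rts[valid])
    values[valid] = rts[valid]  # keep observed values bit-exact
    return RTSeries(values=values, valid_mask=valid)
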