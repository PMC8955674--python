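"""Four-category welfare/pain rubric for tumor-bearing mice (0-4 total).

Each category scores 0 or 1:

* physiological — body weight changed by more than 10% since the previous
  measurement, body temperature outside the normal murine range
  (35.8-37.4 C), or diarrhea/bloody stool;
* posture — hunched posture;
* appearance — rough hair coat, pinched face, distended/swollen abdomen, or
  reluctance to move;
* activity — any period longer than 30 s without a movement/grooming event
  during the (default 5 min) observation, boundary gaps included.

A total of 0 is a normal mouse; 4 is the most painful presentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ValidationError

#: Normal murine body-temperature range, degrees C.
NORMAL_TEMP_RANGE = (35.8, 37.4)

#: Relative body-weight change treated as abnormal.
WEIGHT_CHANGE_FRAC = 0.10

#: Inactivity gap (s) scoring positive in the activity category.
INACTIVITY_GAP_S = 30.0


@dataclass
class PainObservation:
    """One welfare observation of one mouse at one timepoint."""

    body_weight: float                    # g
    body_temp: float                      # degrees C
    prev_body_weight: float | None = None  # g; absent on the first observation
    diarrhea: bool = False
    hunched_posture: bool = False
    rough_hair_coat: bool = False
    pinched_face: bool = False
    distended_abdomen: bool = False
    reluctance_to_move: bool = False
    activity_event_times: tuple = ()      # s within the observation
    observation_duration: float = 300.0   # s

    def __post_init__(self) -> None:
        if self.body_weight <= 0:
            raise ValidationError(f"body_weight must be > 0 g, got {self.body_weight}")
        if self.prev_body_weight is not None and self.prev_body_weight <= 0:
            raise ValidationError("prev_body_weight must be > 0 g when present")
        if not np.isfinite(self.body_temp):
            raise ValidationError("body_temp must be finite")
        if self.observation_duration <= 0:
            raise ValidationError("observation_duration must be > 0 s")
        events = np.asarray(self.activity_event_times, dtype=float)
        if events.size and (events.min() < 0 or events.max() > self.observation_duration):
            raise ValidationError("activity events must lie within [0, duration]")
        self.activity_event_times = tuple(sorted(float(t) for t in events))


@dataclass(frozen=True)
class PainScore:
    physiological: int
    posture: int
    appearance: int
    activity: int

    @property
    def total(self) -> int:
        return self.physiological + self.posture + self.appearance + self.activity


def score_physiological(obs: PainObservation, temp_above_only: bool = False) -> int:
    """Weight change > 10%, abnormal temperature, or diarrhea.

    The weight criterion is skipped on a first observation (no previous
    weight).  Temperature scores when outside the normal range in either
    direction by default; ``temp_above_only`` restricts it to hyperthermia.
    """
    weight_flag = False
    if obs.prev_body_weight is not None:
        rel = abs(obs.body_weight - obs.prev_body_weight) / obs.prev_body_weight
        weight_flag = rel > WEIGHT_CHANGE_FRAC
    lo, hi = NORMAL_TEMP_RANGE
    temp_flag = obs.body_temp > hi if temp_above_only else not (lo <= obs.body_temp <= hi)
    return int(weight_flag or temp_flag or obs.diarrhea)


def score_posture(obs: PainObservation) -> int:
    """1 iff hunched posture."""
    return int(obs.hunched_posture)


def score_appearance(obs: PainObservation) -> int:
    """1 iff any appearance sign (coat, face, abdomen, reluctance to move)."""
    return int(
        obs.rough_hair_coat
        or obs.pinched_face
        or obs.distended_abdomen
        or obs.reluctance_to_move
    )


def score_activity(obs: PainObservation) -> int:
    """1 iff any inter-event gap strictly exceeds 30 s.

    Gaps from the observation start to the first event and from the last
    event to the end count; a mouse with no events at all scores 1.
    """
    boundaries = (0.0,) + obs.activity_event_times + (obs.observation_duration,)
    gaps = np.diff(boundaries)
    return int(bool(np.any(gaps > INACTIVITY_GAP_S)))


def total_pain_score(obs: PainObservation, temp_above_only: bool = False) -> PainScore:
    """All four category scores; ``.total`` is their sum in [0, 4]."""
    return PainScore(
        physiological=score_physiological(obs, temp_above_only=temp_above_only),
        posture=score_posture(obs),
        appearance=score_appearance(obs),
        activity=score_activity(obs),
    )
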