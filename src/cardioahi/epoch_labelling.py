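"""Respiratory-event epoch labelling on the 30-second clinical grid.

An epoch is a respiratory-event (RE) epoch when a single event overlaps it
by at least 10 s, or when it starts strictly less than 5 s after an event
ends ("after event" rule, capturing the bradycardia-tachycardia and
arousal aftermath). Epochs are half-open intervals [30k, 30k+30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import EPOCH_SECONDS, RespiratoryEvent, SleepWakeSequence

MIN_OVERLAP_S = 10.0  # inclusive
AFTER_EVENT_S = 5.0   # strict

CHARACTERISATIONS = ("none", "obstructive_apnea", "hypopnea", "central_apnea",
                     "mixed_apnea", "after_event")
AFTER_COMBINATIONS = ("not_applicable", "after", "no_after", "pure_after")


@dataclass
class EpochLabelSet:
    """Per-epoch RE labels, characterisation and analysability mask."""

    re_class: np.ndarray          # bool
    characterisation: np.ndarray  # object, one of CHARACTERISATIONS
    after_combination: np.ndarray  # object, one of AFTER_COMBINATIONS
    analysable: np.ndarray        # bool

    def __post_init__(self) -> None:
        self.re_class = np.asarray(self.re_class, dtype=bool)
        self.characterisation = np.asarray(self.characterisation, dtype=object)
        self.after_combination = np.asarray(self.after_combination, dtype=object)
        self.analysable = np.asarray(self.analysable, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.re_class.size

    def copy(self) -> "EpochLabelSet":
        return EpochLabelSet(self.re_class.copy(), self.characterisation.copy(),
                             self.after_combination.copy(), self.analysable.copy())


def _overlap(event: RespiratoryEvent, k: int) -> float:
    start, end = k * EPOCH_SECONDS, (k + 1) * EPOCH_SECONDS
    return max(0.0, min(event.end, end) - max(event.onset, start))


def _clip_events(events, n_epochs):
    total = n_epochs * EPOCH_SECONDS
    clipped = []
    for e in events:
        if e.onset >= total:
            warnings.warn(f"event at {e.onset}s beyond recording end: dropped",
                          stacklevel=3)
            continue
        if e.end > total:
            warnings.warn(f"event at {e.onset}s extends beyond recording end: "
                          "clipped", stacklevel=3)
            if total - e.onset < 10.0:
                # too short after clipping to remain a scorable event; keep
                # the original object so the 10-s invariant is not violated
                clipped.append(e)
                continue
            e = RespiratoryEvent(e.kind, e.onset, total - e.onset,
                                 e.desaturation, e.arousal)
        clipped.append(e)
    return clipped


def label_re_epochs(events: Sequence[RespiratoryEvent],
                    n_epochs: int) -> EpochLabelSet:
    """Label each 30-s epoch as RE / non-RE.

    Rule 1 (overlap): some single event covers >= 10 s of the epoch.
    Rule 2 (after event): the epoch starts < 5 s (strictly) after an
    event's end; an event ending exactly on the epoch boundary triggers
    the rule (distance 0).
    """
    events = _clip_events(events, n_epochs)
    re_class = np.zeros(n_epochs, dtype=bool)
    after_trigger = np.zeros(n_epochs, dtype=bool)
    for e in events:
        k0 = max(0, int(e.onset // EPOCH_SECONDS))
        k1 = min(n_epochs - 1, int(np.ceil(e.end / EPOCH_SECONDS)))
        for k in range(k0, k1 + 1):
            if _overlap(e, k) >= MIN_OVERLAP_S:
                re_class[k] = True
        # after rule: epoch k starts within [0, 5) s after the event end
        k_after = int(np.ceil(e.end / EPOCH_SECONDS))
        if k_after < n_epochs and 0.0 <= k_after * EPOCH_SECONDS - e.end < AFTER_EVENT_S:
            after_trigger[k_after] = True
            re_class[k_after] = True
    labels = EpochLabelSet(
        re_class=re_class,
        characterisation=np.full(n_epochs, "none", dtype=object),
        after_combination=np.full(n_epochs, "not_applicable", dtype=object),
        analysable=np.ones(n_epochs, dtype=bool),
    )
    labels._after_trigger = after_trigger  # carried for characterisation
    return labels


def characterise_epochs(events: Sequence[RespiratoryEvent],
                        labels: EpochLabelSet) -> EpochLabelSet:
    """Assign per-epoch characterisation and after-event combination tags.

    The characterisation is the kind of the event with the longest overlap
    in the epoch; when the 5-s after rule fired for the epoch the
    ``after_event`` tag takes precedence. ``after_combination``
    distinguishes RE-epochs with both an after-trigger and a >=10-s event
    overlap ("after"), only the overlap ("no_after"), and only the
    trigger ("pure_after").
    """
    n = labels.n_epochs
    events = _clip_events(events, n)
    out = labels.copy()
    after_trigger = getattr(labels, "_after_trigger", None)
    if after_trigger is None:
        after_trigger = np.zeros(n, dtype=bool)
    out._after_trigger = after_trigger

    for k in range(n):
        overlaps = [(_overlap(e, k), i, e) for i, e in enumerate(events)]
        overlaps = [(o, i, e) for o, i, e in overlaps if o > 0]
        longest = max(overlaps, key=lambda t: (t[0], -t[1]))[2] if overlaps else None
        has_long_overlap = any(o >= MIN_OVERLAP_S for o, _, _ in overlaps)
        if after_trigger[k]:
            out.characterisation[k] = "after_event"
        elif longest is not None:
            out.characterisation[k] = longest.kind
        if out.re_class[k]:
            if after_trigger[k] and has_long_overlap:
                out.after_combination[k] = "after"
            elif after_trigger[k]:
                out.after_combination[k] = "pure_after"
            else:
                out.after_combination[k] = "no_after"
    return out


def apply_sleep_mask(labels: EpochLabelSet,
                     stages: SleepWakeSequence) -> EpochLabelSet:
    """Mark wake epochs as not analysable."""
    if len(stages) != labels.n_epochs:
        raise ValueError(
            f"hypnogram length {len(stages)} != epoch count {labels.n_epochs}")
    out = labels.copy()
    out._after_trigger = getattr(labels, "_after_trigger",
                                 np.zeros(labels.n_epochs, bool))
    out.analysable = stages.is_sleep.copy()
    return out


def export_labels(path, labels: EpochLabelSet) -> None:
    import pandas as pd
    pd.DataFrame({
        "epoch_index": np.arange(labels.n_epochs),
        "re_class": labels.re_class.astype(int),
        "characterisation": labels.characterisation,
        "after_combination": labels.after_combination,
        "analysable": labels.analysable.astype(int),
    }).to_csv(path, index=False)
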