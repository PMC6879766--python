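"""R-peak detection, inter-beat-interval derivation and cleaning.

The detector follows the classical Hamilton-Tompkins scheme: band-pass
filtering of the QRS band, differentiation, rectification, moving-window
integration and an adaptive dual-estimate (signal/noise) threshold, with a
final refinement step that relocates each detection to the local extremum
of the filtered signal within +/-50 ms. Interval cleaning applies the
physiological range rule (0.5-2 s) followed by the ectopic-pair rule
(consecutive-interval ratio > 1.5 tags both intervals).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import signal

from .io_formats import ECGRecord

IBI_MIN_S = 0.5
IBI_MAX_S = 2.0
ECTOPIC_RATIO = 1.5
ECTOPIC_FRACTION_LIMIT = 0.03
MISSING_FEATURE_FRACTION = 0.70
LOW_COVERAGE_EPOCH_FRACTION = 0.30
REFINEMENT_WINDOW_S = 0.05  # narrower than half the shortest admissible IBI


@dataclass
class RPeakSeries:
    """Detected R-peak times, strictly increasing, in seconds."""

    peak_times: np.ndarray
    record_id: str = "record"

    def __post_init__(self) -> None:
        t = np.asarray(self.peak_times, dtype=float)
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("peak times must be strictly increasing")
        self.peak_times = t

    def __len__(self) -> int:
        return self.peak_times.size


@dataclass
class IBISeries:
    """Inter-beat intervals with a validity mask and rejection reasons.

    ``onsets[i]`` is the time of the beat opening interval ``i``;
    ``values[i]`` its length in seconds. ``reason`` holds ``"ok"``,
    ``"out_of_range"`` or ``"ectopic"`` per interval; an interval is valid
    iff its reason is ``"ok"``.
    """

    onsets: np.ndarray
    values: np.ndarray
    reason: np.ndarray = field(default=None)  # type: ignore[assignment]
    record_id: str = "record"

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.reason is None:
            self.reason = np.full(self.values.size, "ok", dtype=object)
        else:
            self.reason = np.asarray(self.reason, dtype=object)
        if self.onsets.size != self.values.size or self.onsets.size != self.reason.size:
            raise ValueError("onsets, values and reason must have equal length")
        if np.any(self.values <= 0):
            raise ValueError("interval values must be positive")
        if self.onsets.size > 1 and not np.all(np.diff(self.onsets) > 0):
            raise ValueError("interval onsets must be strictly increasing")

    @property
    def valid(self) -> np.ndarray:
        return self.reason == "ok"

    def __len__(self) -> int:
        return self.values.size

    def copy(self) -> "IBISeries":
        return IBISeries(self.onsets.copy(), self.values.copy(),
                         self.reason.copy(), self.record_id)


@dataclass
class ExclusionVerdict:
    """Advisory recording-level exclusion decision."""

    excluded: bool
    reasons: tuple

    def __post_init__(self) -> None:
        self.reasons = tuple(self.reasons)
        if self.excluded != bool(self.reasons):
            raise ValueError("excluded iff reasons nonempty")


# ---------------------------------------------------------------------------
# R-peak detection
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: ECGRecord) -> RPeakSeries:
    """Detect R peaks in a single-lead ECG.

    Returns an empty series (with a warning) for flat signals. Detection
    is polarity-invariant: refinement searches the extremum of the
    absolute band-passed signal.
    """
    fs = ecg.sampling_rate
    if fs < 100:
        raise ValueError("R-peak detection requires sampling_rate >= 100 Hz")
    x = np.asarray(ecg.samples, dtype=float)
    if x.size < int(fs) or np.ptp(x) == 0:
        warnings.warn("flat or too-short ECG signal: no peaks detected",
                      stacklevel=2)
        return RPeakSeries(np.empty(0), ecg.record_id)

    sos = signal.butter(2, [8.0, 20.0], btype="bandpass", fs=fs, output="sos")
    filt = signal.sosfiltfilt(sos, x)
    det = np.abs(np.diff(filt, prepend=filt[0]))
    win = max(1, int(round(0.08 * fs)))
    det = np.convolve(det, np.ones(win) / win, mode="same")

    refractory = int(round(0.25 * fs))
    cand, _ = signal.find_peaks(det, distance=refractory)
    if cand.size == 0:
        warnings.warn("no QRS candidates found", stacklevel=2)
        return RPeakSeries(np.empty(0), ecg.record_id)

    # adaptive dual-estimate thresholding
    head = det[: int(2 * fs)]
    spk = float(np.percentile(head, 98)) if head.size else float(det.max())
    npk = float(np.percentile(head, 50)) if head.size else 0.0
    accepted = []
    for p in cand:
        thr = npk + 0.3125 * (spk - npk)
        if det[p] > thr:
            accepted.append(p)
            spk = 0.125 * det[p] + 0.875 * spk
        else:
            npk = 0.125 * det[p] + 0.875 * npk
    if not accepted:
        warnings.warn("no QRS candidates above threshold", stacklevel=2)
        return RPeakSeries(np.empty(0), ecg.record_id)

    # refinement: local extremum of |filtered| within +/-50 ms
    half = max(1, int(round(REFINEMENT_WINDOW_S * fs)))
    absf = np.abs(filt)
    refined = []
    for p in accepted:
        lo, hi = max(0, p - half), min(x.size, p + half + 1)
        refined.append(lo + int(np.argmax(absf[lo:hi])))
    refined = np.unique(refined)
    # drop refined peaks collapsing inside the refractory period
    keep = [refined[0]]
    for p in refined[1:]:
        if p - keep[-1] >= refractory:
            keep.append(p)
    return RPeakSeries(np.asarray(keep, dtype=float) / fs, ecg.record_id)


# ---------------------------------------------------------------------------
# IBI derivation and cleaning
# ---------------------------------------------------------------------------

def ibis_from_peaks(peaks: RPeakSeries) -> IBISeries:
    """Inter-beat intervals as time distances between consecutive peaks."""
    t = peaks.peak_times
    if t.size < 2:
        raise ValueError("need at least 2 peaks to form intervals")
    return IBISeries(onsets=t[:-1], values=np.diff(t), record_id=peaks.record_id)


def reject_invalid_ibis(ibis: IBISeries) -> IBISeries:
    """Apply physiological-range and ectopic-pair rejection.

    Stage 1 tags intervals outside [0.5, 2] s as ``out_of_range``.
    Stage 2 sweeps consecutive interval pairs that are both still valid
    and contiguous in time (they share a beat) and tags both ``ectopic``
    when the ratio current/preceding exceeds 1.5 strictly. Existing tags
    are never reverted, so the operation is idempotent.
    """
    out = ibis.copy()
    rng = (out.values > IBI_MAX_S) | (out.values < IBI_MIN_S)
    out.reason[rng & (out.reason == "ok")] = "out_of_range"
    ends = out.onsets + out.values
    for i in range(1, len(out)):
        if out.reason[i] != "ok" or out.reason[i - 1] != "ok":
            continue
        if abs(ends[i - 1] - out.onsets[i]) > 1e-9:
            continue  # gap between intervals: ratio not meaningful
        if out.values[i] / out.values[i - 1] > ECTOPIC_RATIO:
            out.reason[i - 1] = "ectopic"
            out.reason[i] = "ectopic"
    return out


def exclusion_check(ibis: IBISeries, features=None,
                    technical_fault: bool = False) -> ExclusionVerdict:
    """Recording-level exclusion verdict.

    A recording is excluded when more than 3% of its intervals are tagged
    ectopic, or when more than 30% of its epochs miss at least 70% of the
    features, or on a reported technical fault. The verdict is advisory.
    """
    reasons = []
    if technical_fault:
        reasons.append("technical")
    if len(ibis):
        ectopic_frac = np.mean(ibis.reason == "ectopic")
        if ectopic_frac > ECTOPIC_FRACTION_LIMIT:
            reasons.append("ectopic_fraction")
    if features is not None and features.n_epochs:
        missing = np.isnan(features.values)
        per_epoch = missing.mean(axis=1)
        low = np.mean(per_epoch >= MISSING_FEATURE_FRACTION)
        if low > LOW_COVERAGE_EPOCH_FRACTION:
            reasons.append("feature_coverage")
    return ExclusionVerdict(excluded=bool(reasons), reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# IBI CSV import/export (bypass for ECG processing)
# ---------------------------------------------------------------------------

def read_ibis_csv(path, record_id: Optional[str] = None) -> IBISeries:
    table = pd.read_csv(path)
    if not {"onset_s", "ibi_s"}.issubset(table.columns):
        raise ValueError(f"IBI file {path} needs columns onset_s, ibi_s")
    return IBISeries(onsets=table["onset_s"].to_numpy(float),
                     values=table["ibi_s"].to_numpy(float),
                     record_id=record_id or str(path))


def write_ibis_csv(path, ibis: IBISeries, valid_only: bool = False) -> None:
    mask = ibis.valid if valid_only else np.ones(len(ibis), bool)
    pd.DataFrame({"onset_s": ibis.onsets[mask],
                  "ibi_s": ibis.values[mask]}).to_csv(path, index=False)
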