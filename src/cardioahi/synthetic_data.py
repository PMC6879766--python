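"""Synthetic sleep recordings with known ground truth.

The generator produces, per recording: a sleep/wake hypnogram on the 30-s
grid, non-overlapping respiratory events placed only in sleep with
Poisson-like gaps, an inter-beat-interval series carrying the
cardiovascular signature of each event, optional ectopic-beat injection
with a log of the injected sites, and an optional template-rendered ECG
for exercising the R-peak detector.

The event signature follows the classic cyclical heart-rate variation of
obstructive apnea: a progressive bradycardia (interval lengthening)
during the event and a sharp post-event tachycardia (interval shortening
within ~5 s of the event end), the aftermath the "after event" epoch rule
is designed to capture. Hypopneas are drawn so that they survive the 4%
desaturation / arousal harmonisation rule, keeping the generator's AHI an
exact ground truth. The simulated world is deliberately simple: no
respiration-locked amplitude modulation, no sleep-stage-dependent HRV, no
realistic artifact spectrum.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_formats import (EPOCH_SECONDS, ECGRecord, RespiratoryEvent,
                         SleepWakeSequence)
from .preprocessing import IBISeries

EVENT_REFRACTORY_S = 10.0  # minimum gap after an event before the next


@dataclass(frozen=True)
class SimulationConfig:
    """Stated world of one synthetic recording.

    Durations in hours/seconds as named; response magnitudes are
    fractional changes of the baseline inter-beat interval.
    """

    duration_h: float = 8.0
    target_ahi: float = 15.0
    event_mix: tuple = (("obstructive_apnea", 0.30), ("hypopnea", 0.55),
                        ("central_apnea", 0.10), ("mixed_apnea", 0.05))
    event_duration_mean_s: float = 22.0
    event_duration_sd_s: float = 8.0
    event_duration_min_s: float = 10.0
    event_duration_max_s: float = 60.0
    arousal_probability: float = 0.6
    baseline_ibi_s: float = 1.0
    ibi_noise_sd: float = 0.025
    rsa_amplitude: float = 0.02   # respiratory sinus arrhythmia
    rsa_freq_hz: float = 0.25
    lf_amplitude: float = 0.015   # baroreflex-band oscillation
    lf_freq_hz: float = 0.095
    bradycardia_depth: float = 0.12
    tachycardia_surge: float = 0.15
    response_lag_s: float = 2.0
    tachycardia_duration_s: float = 8.0
    wake_fraction: float = 0.15
    wake_bout_epochs: float = 4.0
    wake_ibi_factor: float = 0.93  # wake runs at a slightly higher heart rate
    ectopic_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        mix = dict(self.event_mix)
        if abs(sum(mix.values()) - 1.0) > 1e-9:
            raise ValueError("event mix fractions must sum to 1")
        if self.target_ahi < 0:
            raise ValueError("target_ahi must be >= 0")
        if self.event_duration_min_s < 10.0:
            raise ValueError("respiratory events last at least 10 s")


@dataclass
class SimulatedRecording:
    """One generated recording with its full ground truth."""

    record_id: str
    config: SimulationConfig
    ibis: IBISeries
    beat_times: np.ndarray
    events: list
    stages: SleepWakeSequence
    true_ahi: float
    ectopic_beat_times: np.ndarray
    movement_windows: list  # (start_s, end_s) of arousal movement bursts

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    def render_ecg(self, sampling_rate: float = 128.0,
                   seed: Optional[int] = None) -> ECGRecord:
        return render_ecg(self, sampling_rate=sampling_rate, seed=seed)


def _hypnogram(rng, n_epochs: int, wake_fraction: float,
               wake_bout_epochs: float) -> np.ndarray:
    """Two-state Markov hypnogram with the requested stationary wake
    fraction and mean wake bout length."""
    if wake_fraction <= 0:
        return np.zeros(n_epochs, dtype=bool)
    if wake_fraction >= 1:
        return np.ones(n_epochs, dtype=bool)
    p_ws = 1.0 / wake_bout_epochs                      # wake -> sleep
    p_sw = p_ws * wake_fraction / (1.0 - wake_fraction)  # sleep -> wake
    wake = np.zeros(n_epochs, dtype=bool)
    state = rng.random() < wake_fraction
    for k in range(n_epochs):
        wake[k] = state
        if state:
            state = not (rng.random() < p_ws)
        else:
            state = rng.random() < p_sw
    return wake


def _sleep_segments(wake: np.ndarray) -> list:
    """Contiguous sleep runs as (start_s, end_s)."""
    segs = []
    start = None
    for k, w in enumerate(wake):
        if not w and start is None:
            start = k * EPOCH_SECONDS
        elif w and start is not None:
            segs.append((start, k * EPOCH_SECONDS))
            start = None
    if start is not None:
        segs.append((start, wake.size * EPOCH_SECONDS))
    return segs


def _place_events(rng, cfg: SimulationConfig, segments: list) -> list:
    """Non-overlapping events inside sleep segments, exponential-weight
    gaps, exact target count when feasible."""
    sleep_s = sum(b - a for a, b in segments)
    sleep_h = sleep_s / 3600.0
    n_target = int(round(cfg.target_ahi * sleep_h))
    if n_target == 0:
        return []
    durations = np.clip(
        rng.normal(cfg.event_duration_mean_s, cfg.event_duration_sd_s,
                   size=n_target),
        cfg.event_duration_min_s, cfg.event_duration_max_s)
    need = durations.sum() + n_target * EVENT_REFRACTORY_S
    if need > 0.95 * sleep_s:
        raise ValueError(
            f"target AHI {cfg.target_ahi} infeasible: events need {need:.0f}s "
            f"of {sleep_s:.0f}s sleep")
    # allocate counts to segments by capacity-constrained largest remainder
    caps = [max(0, int((b - a) //
                       (cfg.event_duration_mean_s + EVENT_REFRACTORY_S)))
            for a, b in segments]
    lengths = np.array([b - a for a, b in segments], dtype=float)
    quota = lengths / lengths.sum() * n_target
    counts = np.minimum(np.floor(quota).astype(int), caps)
    order = np.argsort(-(quota - np.floor(quota)))
    for i in list(order) + list(range(len(segments))) * 3:
        if counts.sum() >= n_target:
            break
        if counts[i] < caps[i]:
            counts[i] += 1
    kinds_all = [k for k, _ in cfg.event_mix]
    probs = np.array([p for _, p in cfg.event_mix])
    events = []
    d_idx = 0
    for (a, b), k in zip(segments, counts):
        if k == 0:
            continue
        durs = durations[d_idx:d_idx + k]
        d_idx += k
        free = (b - a) - durs.sum() - k * EVENT_REFRACTORY_S
        if free < 0:  # segment turned out too tight; drop surplus events
            keep = 0
            acc = 0.0
            for d in durs:
                if acc + d + EVENT_REFRACTORY_S > (b - a):
                    break
                acc += d + EVENT_REFRACTORY_S
                keep += 1
            durs = durs[:keep]
            k = keep
            if k == 0:
                continue
            free = (b - a) - durs.sum() - k * EVENT_REFRACTORY_S
        gaps = rng.exponential(1.0, size=k + 1)
        gaps = gaps / gaps.sum() * free
        t = a
        for i in range(k):
            t += gaps[i]
            onset = t
            dur = float(durs[i])
            kind = kinds_all[rng.choice(len(kinds_all), p=probs)]
            arousal = bool(rng.random() < cfg.arousal_probability)
            if kind == "hypopnea":
                # drawn to survive the 4%-desaturation/arousal rule so the
                # generated AHI stays exact ground truth
                if arousal:
                    desat = float(np.clip(rng.normal(3.8, 1.0), 2.0, 8.0))
                else:
                    desat = float(np.clip(rng.normal(5.0, 0.8), 4.0, 8.0))
            else:
                desat = float(np.clip(rng.normal(5.0, 2.0), 0.0, 12.0))
            events.append(RespiratoryEvent(kind, onset, dur, desat, arousal))
            t = onset + dur + EVENT_REFRACTORY_S
    events.sort(key=lambda e: e.onset)
    return events


def _modulation_grid(cfg: SimulationConfig, duration_s: float, events: list,
                     wake: np.ndarray) -> np.ndarray:
    """Multiplicative IBI modulation sampled on a 1-s grid."""
    n = int(np.ceil(duration_s)) + 2
    mod = np.ones(n)
    t = np.arange(n, dtype=float)
    lag = cfg.response_lag_s
    for e in events:
        a, b = e.onset + lag, e.end + lag
        during = (t >= a) & (t < b)
        if np.any(during):
            ramp = (t[during] - a) / max(b - a, 1.0)
            mod[during] *= 1.0 + cfg.bradycardia_depth * ramp
        after = (t >= b) & (t < b + cfg.tachycardia_duration_s)
        if np.any(after):
            decay = 1.0 - (t[after] - b) / cfg.tachycardia_duration_s
            mod[after] *= 1.0 - cfg.tachycardia_surge * decay
    epoch_idx = np.minimum((t // EPOCH_SECONDS).astype(int), wake.size - 1)
    mod[wake[epoch_idx]] *= cfg.wake_ibi_factor
    return mod


def generate_recording(config: SimulationConfig,
                       record_id: str = "sim") -> SimulatedRecording:
    """Generate one fully annotated synthetic recording.

    Identical configuration (including seed) yields identical output.
    """
    rng = np.random.default_rng(config.seed)
    duration_s = config.duration_h * 3600.0
    n_epochs = int(duration_s // EPOCH_SECONDS)
    wake = _hypnogram(rng, n_epochs, config.wake_fraction,
                      config.wake_bout_epochs)
    segments = _sleep_segments(wake)
    sleep_h = sum(b - a for a, b in segments) / 3600.0
    if sleep_h == 0 and config.target_ahi > 0:
        raise ValueError("no sleep epochs: target AHI infeasible")
    events = _place_events(rng, config, segments) if sleep_h > 0 else []
    true_ahi = len(events) / sleep_h if sleep_h > 0 else 0.0

    mod = _modulation_grid(config, duration_s, events, wake)
    beats = [0.0]
    t = 0.0
    two_pi = 2 * np.pi
    while t < duration_s:
        base = config.baseline_ibi_s * (
            1.0
            + config.rsa_amplitude * np.sin(two_pi * config.rsa_freq_hz * t)
            + config.lf_amplitude * np.sin(two_pi * config.lf_freq_hz * t))
        ibi = base * mod[min(int(t), mod.size - 1)]
        ibi += rng.normal(0.0, config.ibi_noise_sd)
        ibi = max(0.3, ibi)
        t += ibi
        beats.append(t)
    beats = np.asarray(beats)

    # ectopic injection: pull a beat forward, producing a short-then-long
    # interval pair; the injection log is the ground truth for rejection
    ectopic_times = []
    if config.ectopic_rate > 0 and beats.size > 6:
        candidates = np.arange(2, beats.size - 2)
        n_ect = rng.binomial(candidates.size, config.ectopic_rate)
        if n_ect:
            chosen = np.sort(rng.choice(candidates, size=n_ect, replace=False))
            # keep injections isolated so each yields a clean pair
            keep = [chosen[0]]
            for c in chosen[1:]:
                if c - keep[-1] > 3:
                    keep.append(c)
            for c in keep:
                shift = 0.38 * (beats[c] - beats[c - 1])
                beats[c] -= shift
                ectopic_times.append(beats[c])
    ectopic_times = np.asarray(ectopic_times)

    ibis = IBISeries(onsets=beats[:-1], values=np.diff(beats),
                     record_id=record_id)
    stages = SleepWakeSequence(
        np.where(wake, "wake", "sleep").astype(object))
    movement = [(e.end, e.end + 5.0) for e in events if e.arousal]
    return SimulatedRecording(record_id=record_id, config=config, ibis=ibis,
                              beat_times=beats, events=events, stages=stages,
                              true_ahi=true_ahi,
                              ectopic_beat_times=ectopic_times,
                              movement_windows=movement)


# ---------------------------------------------------------------------------
# ECG rendering (template QRS convolution at the simulated beat times)
# ---------------------------------------------------------------------------

def _qrs_template(fs: float) -> np.ndarray:
    """Simple QRS-like wavelet: sharp R peak with Q/S dips, ~100 ms."""
    t = np.arange(-0.05, 0.05, 1.0 / fs)
    r = np.exp(-0.5 * (t / 0.008) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.025) / 0.008) ** 2)
    s = -0.2 * np.exp(-0.5 * ((t - 0.025) / 0.008) ** 2)
    return r + q + s


def render_ecg(rec: SimulatedRecording, sampling_rate: float = 128.0,
               seed: Optional[int] = None) -> ECGRecord:
    """Render the beat train as a template ECG.

    Movement bursts (post-arousal and wake) add broadband noise that the
    activity-count feature is designed to pick up.
    """
    fs = sampling_rate
    rng = np.random.default_rng(rec.config.seed + 101 if seed is None else seed)
    duration_s = rec.config.duration_h * 3600.0
    n = int(round(duration_s * fs))
    x = np.zeros(n + int(fs))
    idx = np.round(rec.beat_times * fs).astype(int)
    idx = idx[(idx >= 0) & (idx < x.size)]
    x[idx] = 1.0
    x = np.convolve(x, _qrs_template(fs), mode="same")[:n]
    tgrid = np.arange(n) / fs
    x += 0.05 * np.sin(2 * np.pi * 0.3 * tgrid)  # baseline wander
    x += rng.normal(0.0, 0.01, size=n)
    for a, b in rec.movement_windows:
        i0, i1 = int(a * fs), min(n, int(b * fs))
        if i1 > i0:
            x[i0:i1] += rng.normal(0.0, 0.15, size=i1 - i0)
    wake = ~rec.stages.is_sleep
    for k in np.flatnonzero(wake):
        if rng.random() < 0.3:  # occasional wake movement
            i0 = int(k * EPOCH_SECONDS * fs)
            i1 = min(n, i0 + int(10 * fs))
            x[i0:i1] += rng.normal(0.0, 0.12, size=max(0, i1 - i0))
    return ECGRecord(samples=x, sampling_rate=fs,
                     record_id=rec.record_id)


# ---------------------------------------------------------------------------
# Populations
# ---------------------------------------------------------------------------

SEVERITY_AHI_RANGES = {
    "normal": (0.0, 4.5),
    "mild": (5.0, 14.0),
    "moderate": (15.0, 29.0),
    "severe": (30.0, 55.0),
}


def _subject_variation(rng, cfg: SimulationConfig) -> dict:
    """Between-subject physiological heterogeneity.

    Real sleep-clinic populations span wide resting heart rates, HRV
    levels, autonomic response magnitudes and sleep quality; a population
    of identical subjects would let absolute feature levels carry all the
    class signal, which no real cohort allows. Jitter is multiplicative
    around the template values.
    """
    return dict(
        baseline_ibi_s=cfg.baseline_ibi_s * float(rng.uniform(0.80, 1.15)),
        ibi_noise_sd=cfg.ibi_noise_sd * float(rng.uniform(0.7, 1.5)),
        rsa_amplitude=cfg.rsa_amplitude * float(rng.uniform(0.6, 1.4)),
        lf_amplitude=cfg.lf_amplitude * float(rng.uniform(0.6, 1.4)),
        bradycardia_depth=cfg.bradycardia_depth * float(rng.uniform(0.7, 1.3)),
        tachycardia_surge=cfg.tachycardia_surge * float(rng.uniform(0.7, 1.3)),
        arousal_probability=float(np.clip(
            cfg.arousal_probability * rng.uniform(0.7, 1.3), 0.0, 1.0)),
        wake_fraction=float(np.clip(
            cfg.wake_fraction * rng.uniform(0.6, 1.6), 0.03, 0.40)),
    )


def generate_population(n: int, severity_mix: dict,
                        config_template: SimulationConfig,
                        seed: int = 0, heterogeneous: bool = True) -> list:
    """Generate ``n`` recordings matching a severity mix.

    Class counts follow the mix by largest-remainder construction;
    per-class target AHIs are drawn uniformly inside the class bounds and
    subjects get individually jittered physiology (disable with
    ``heterogeneous=False`` for controlled experiments). Per-recording
    seeds derive from the master seed, so the same master seed reproduces
    the identical population.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    classes = list(severity_mix)
    fracs = np.array([severity_mix[c] for c in classes], dtype=float)
    fracs = fracs / fracs.sum()
    quota = fracs * n
    counts = np.floor(quota).astype(int)
    order = np.argsort(-(quota - counts))
    for i in order:
        if counts.sum() >= n:
            break
        counts[i] += 1
    rng = np.random.default_rng(seed)
    child_seeds = np.random.SeedSequence(seed).generate_state(n) % (2 ** 31)
    recordings = []
    i = 0
    for cls, cnt in zip(classes, counts):
        lo, hi = SEVERITY_AHI_RANGES[cls]
        for _ in range(cnt):
            ahi = float(rng.uniform(lo, hi))
            overrides = (_subject_variation(rng, config_template)
                         if heterogeneous else {})
            cfg = dataclasses.replace(config_template, target_ahi=ahi,
                                      seed=int(child_seeds[i]), **overrides)
            recordings.append(generate_recording(cfg, record_id=f"sim{i:03d}"))
            i += 1
    return recordings
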