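"""Per-epoch cardiovascular feature extraction from inter-beat intervals.

Each feature family is computed on a time window centred on the 30-s
epoch the value is assigned to. A value is computed only when the valid
intervals cover at least half of the (nominal) window and at least 1/6 of
the central 30 s (5 s); otherwise the value is missing (NaN). Windows
truncated at the recording edges keep their nominal length for the
coverage test, so edge epochs of long-window families are usually missing.

Families and windows:

======================  ==========  ========================================
family                  window [s]  features
======================  ==========  ========================================
hrv_time                300         14 time-domain statistics of the IBIs
hrv_freq                300         7 spectral powers/ratios (VLF/LF/HF)
dfa                     360         3 detrended-fluctuation exponents
dfa_progressive         60          short-window scaling exponent
dfa_windowed            360         mean of 60-s sub-window exponents
sample_entropy          300         SampEn(m=2, r=0.2*SD)
multiscale_entropy      540         SampEn at coarse-grain scales 1..20
activity_counts         30          rectified high-passed ECG per epoch
======================  ==========  ========================================

Families defined only in external methodological work can be attached via
the plugin registry with their own window size; they then flow through
optimisation and classification transparently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal, stats

from .io_formats import EPOCH_SECONDS, ECGRecord
from .preprocessing import IBISeries

ALLOWED_WINDOWS = (30.0, 60.0, 90.0, 150.0, 300.0, 360.0, 540.0)

FAMILY_WINDOWS = {
    "hrv_time": 300.0,
    "hrv_freq": 300.0,
    "dfa": 360.0,
    "dfa_progressive": 60.0,
    "dfa_windowed": 360.0,
    "sample_entropy": 300.0,
    "multiscale_entropy": 540.0,
    "activity_counts": 30.0,
}

RESAMPLE_HZ = 4.0
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.40)


@dataclass(frozen=True)
class FeatureSpec:
    """Name, family and window of one feature column."""

    name: str
    family: str
    window: float

    def __post_init__(self):
        if self.window not in ALLOWED_WINDOWS:
            raise ValueError(f"window {self.window} not in {ALLOWED_WINDOWS}")


@dataclass
class FeatureMatrix:
    """Epochs x features table; NaN marks missing values."""

    record_id: str
    columns: list
    values: np.ndarray  # (n_epochs, n_features)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.columns):
            raise ValueError("values shape must be (n_epochs, n_features)")

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def names(self) -> list:
        return [c.name for c in self.columns]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.names)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, na_rep="NA")


# ---------------------------------------------------------------------------
# Coverage rule
# ---------------------------------------------------------------------------

def _covered(onsets, ends, a: float, b: float) -> float:
    """Total length of intervals [onsets, ends] intersected with [a, b)."""
    if onsets.size == 0 or b <= a:
        return 0.0
    return float(np.clip(np.minimum(ends, b) - np.maximum(onsets, a),
                         0.0, None).sum())


def epoch_coverage_ok(ibis: IBISeries, window_start: float,
                      window_end: float) -> bool:
    """Coverage test for one feature window.

    Valid intervals must cover at least half of the nominal window length
    and at least 5 s (1/6) of the central 30 s. ``window_start`` may be
    negative and ``window_end`` may exceed the recording end (truncated
    edge windows); the nominal length is still ``window_end -
    window_start``.
    """
    mask = ibis.valid
    onsets = ibis.onsets[mask]
    ends = onsets + ibis.values[mask]
    nominal = window_end - window_start
    centre = 0.5 * (window_start + window_end)
    cov_window = _covered(onsets, ends, window_start, window_end)
    cov_centre = _covered(onsets, ends, centre - 15.0, centre + 15.0)
    return cov_window >= 0.5 * nominal and cov_centre >= 5.0


# ---------------------------------------------------------------------------
# Family implementations (each returns dict name -> value, NaN if undefined)
# ---------------------------------------------------------------------------

def _window_values(ibis: IBISeries, a: float, b: float):
    """Valid intervals whose onset lies in [a, b): (onsets, values)."""
    m = ibis.valid & (ibis.onsets >= a) & (ibis.onsets < b)
    return ibis.onsets[m], ibis.values[m]


HRV_TIME_NAMES = ["mean_ibi", "median_ibi", "sdnn", "rmssd", "sdsd", "pnn50",
                  "pnn20", "iqr_ibi", "range_ibi", "cv_ibi", "skew_ibi",
                  "kurt_ibi", "mean_hr", "sd_hr"]


def _hrv_time(onsets, values) -> dict:
    out = dict.fromkeys(HRV_TIME_NAMES, np.nan)
    if values.size < 2:
        return out
    diffs = np.diff(values)
    hr = 60.0 / values
    sd = float(np.std(values, ddof=1))
    out.update(
        mean_ibi=float(np.mean(values)),
        median_ibi=float(np.median(values)),
        sdnn=sd,
        rmssd=float(np.sqrt(np.mean(diffs ** 2))),
        sdsd=float(np.std(diffs, ddof=1)) if diffs.size > 1 else np.nan,
        pnn50=float(np.mean(np.abs(diffs) > 0.050)),
        pnn20=float(np.mean(np.abs(diffs) > 0.020)),
        iqr_ibi=float(np.subtract(*np.percentile(values, [75, 25]))),
        range_ibi=float(np.ptp(values)),
        cv_ibi=sd / float(np.mean(values)) if np.mean(values) > 0 else np.nan,
        skew_ibi=float(stats.skew(values)) if sd > 0 else np.nan,
        kurt_ibi=float(stats.kurtosis(values)) if sd > 0 else np.nan,
        mean_hr=float(np.mean(hr)),
        sd_hr=float(np.std(hr, ddof=1)),
    )
    return out


HRV_FREQ_NAMES = ["vlf_power", "lf_power", "hf_power", "total_power",
                  "lf_hf_ratio", "lf_nu", "hf_nu"]


def _resample_tachogram(onsets, values, a, b, fs=RESAMPLE_HZ):
    """Evenly resampled IBI series over [a, b) by linear interpolation."""
    t = np.arange(a, b, 1.0 / fs)
    mid = onsets + values / 2.0
    return t, np.interp(t, mid, values)


def _band_power(freqs, psd, band) -> float:
    m = (freqs >= band[0]) & (freqs < band[1])
    if not np.any(m):
        return 0.0
    return float(np.trapezoid(psd[m], freqs[m]))


def _hrv_freq(onsets, values, a, b) -> dict:
    out = dict.fromkeys(HRV_FREQ_NAMES, np.nan)
    if values.size < 4:
        return out
    _, x = _resample_tachogram(onsets, values, a, b)
    if np.ptp(x) == 0:
        return out
    nper = min(x.size, int(150 * RESAMPLE_HZ))
    freqs, psd = signal.welch(x, fs=RESAMPLE_HZ, nperseg=nper,
                              detrend="linear")
    vlf = _band_power(freqs, psd, VLF_BAND)
    lf = _band_power(freqs, psd, LF_BAND)
    hf = _band_power(freqs, psd, HF_BAND)
    total = vlf + lf + hf
    out.update(vlf_power=vlf, lf_power=lf, hf_power=hf, total_power=total)
    out["lf_hf_ratio"] = lf / hf if hf > 0 else np.nan
    denom = lf + hf
    if denom > 0:
        out["lf_nu"] = lf / denom
        out["hf_nu"] = hf / denom
    return out


def dfa_exponent(x: np.ndarray, scales: np.ndarray) -> float:
    """Detrended fluctuation analysis scaling exponent.

    Integrates the mean-removed series, computes the RMS of linear
    detrending residuals in non-overlapping boxes of each scale and
    returns the slope of log F(n) against log n.
    """
    x = np.asarray(x, dtype=float)
    scales = np.asarray([s for s in scales if s <= x.size // 2], dtype=int)
    if x.size < 8 or scales.size < 2 or np.ptp(x) == 0:
        return np.nan
    y = np.cumsum(x - x.mean())
    fluct = []
    for n in scales:
        n_boxes = y.size // n
        seg = y[: n_boxes * n].reshape(n_boxes, n)
        t = np.arange(n)
        # per-box linear fit via least squares on the shared design
        tm = t - t.mean()
        denom = (tm ** 2).sum()
        slope = seg @ tm / denom
        resid = seg - seg.mean(axis=1, keepdims=True) - slope[:, None] * tm
        fluct.append(np.sqrt(np.mean(resid ** 2)))
    fluct = np.asarray(fluct)
    good = fluct > 0
    if good.sum() < 2:
        return np.nan
    coef = np.polyfit(np.log(scales[good]), np.log(fluct[good]), 1)
    return float(coef[0])


DFA_SCALES_SHORT = np.arange(4, 17)
DFA_SCALES_LONG = np.unique(np.round(np.geomspace(16, 64, 10)).astype(int))
DFA_SCALES_ALL = np.unique(np.round(np.geomspace(4, 64, 14)).astype(int))


def _dfa(values) -> dict:
    return {
        "dfa_alpha1": dfa_exponent(values, DFA_SCALES_SHORT),
        "dfa_alpha2": dfa_exponent(values, DFA_SCALES_LONG),
        "dfa_alpha_all": dfa_exponent(values, DFA_SCALES_ALL),
    }


def _dfa_progressive(values) -> dict:
    return {"dfa_progressive": dfa_exponent(values, np.arange(4, 13))}


def _dfa_windowed(onsets, values, a, b) -> dict:
    """Mean short-scale exponent over 60-s sub-windows of the window."""
    exps = []
    for w0 in np.arange(a, b, 60.0):
        m = (onsets >= w0) & (onsets < w0 + 60.0)
        e = dfa_exponent(values[m], np.arange(4, 13))
        if np.isfinite(e):
            exps.append(e)
    return {"dfa_windowed": float(np.mean(exps)) if exps else np.nan}


def sample_entropy(x: np.ndarray, m: int = 2, r: Optional[float] = None) -> float:
    """Sample entropy SampEn(m, r) of a 1-D series.

    ``r`` defaults to 0.2 times the series SD. Undefined (NaN) for
    constant series or when no template matches exist.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < m + 2:
        return np.nan
    sd = np.std(x)
    if sd == 0:
        return np.nan
    if r is None:
        r = 0.2 * sd

    def count_matches(mm):
        templ = np.lib.stride_tricks.sliding_window_view(x, mm)
        # Chebyshev distances between all template pairs
        d = np.abs(templ[:, None, :] - templ[None, :, :]).max(axis=2)
        iu = np.triu_indices(templ.shape[0], k=1)
        return int(np.sum(d[iu] <= r))

    b = count_matches(m)
    a = count_matches(m + 1)
    if b == 0 or a == 0:
        return np.nan
    return float(-np.log(a / b))


def _sample_entropy_family(values) -> dict:
    return {"sampen": sample_entropy(values)}


def multiscale_entropy(x: np.ndarray, scales=range(1, 21)) -> dict:
    """Coarse-grained sample entropy at integer scales."""
    x = np.asarray(x, dtype=float)
    out = {}
    r = 0.2 * np.std(x) if x.size else None
    for s in scales:
        n = x.size // s
        if n >= 10:
            cg = x[: n * s].reshape(n, s).mean(axis=1)
            out[f"mse_{s}"] = sample_entropy(cg, r=r)
        else:
            out[f"mse_{s}"] = np.nan
    return out


def activity_counts(ecg: ECGRecord, n_epochs: int,
                    highpass_hz: float = 10.0) -> np.ndarray:
    """ECG-derived movement surrogate: rectified high-passed amplitude
    integrated per 30-s epoch."""
    fs = ecg.sampling_rate
    sos = signal.butter(2, highpass_hz, btype="highpass", fs=fs, output="sos")
    filt = np.abs(signal.sosfiltfilt(sos, ecg.samples))
    spe = int(round(EPOCH_SECONDS * fs))
    counts = np.full(n_epochs, np.nan)
    for k in range(n_epochs):
        seg = filt[k * spe:(k + 1) * spe]
        if seg.size:
            counts[k] = float(seg.sum() / fs)
    return counts


# ---------------------------------------------------------------------------
# Registry and matrix extraction
# ---------------------------------------------------------------------------

FAMILY_FEATURE_NAMES = {
    "hrv_time": HRV_TIME_NAMES,
    "hrv_freq": HRV_FREQ_NAMES,
    "dfa": ["dfa_alpha1", "dfa_alpha2", "dfa_alpha_all"],
    "dfa_progressive": ["dfa_progressive"],
    "dfa_windowed": ["dfa_windowed"],
    "sample_entropy": ["sampen"],
    "multiscale_entropy": [f"mse_{s}" for s in range(1, 21)],
    "activity_counts": ["activity"],
}

DEFAULT_FAMILIES = tuple(FAMILY_FEATURE_NAMES)


@dataclass
class FeatureRegistry:
    """Enabled feature families plus externally registered plugins.

    A plugin provides ``func(onsets, values, window_start, window_end) ->
    dict`` mapping its feature names to values, computed from the valid
    intervals in the window; it participates in the coverage rule and the
    downstream optimisation like any built-in family.
    """

    families: tuple = DEFAULT_FAMILIES
    plugins: dict = field(default_factory=dict)

    def register_plugin(self, name: str, window: float, feature_names,
                        func: Callable) -> None:
        if window not in ALLOWED_WINDOWS:
            raise ValueError(f"window {window} not in {ALLOWED_WINDOWS}")
        self.plugins[name] = (window, list(feature_names), func)

    def specs(self) -> list:
        specs = []
        for fam in self.families:
            w = FAMILY_WINDOWS[fam]
            specs.extend(FeatureSpec(n, fam, w)
                         for n in FAMILY_FEATURE_NAMES[fam])
        for name, (w, names, _) in self.plugins.items():
            specs.extend(FeatureSpec(n, "plugin", w) for n in names)
        return specs


def compute_feature_family(ibis: IBISeries, family: str, epoch_index: int,
                           ecg: Optional[ECGRecord] = None,
                           n_epochs: Optional[int] = None) -> dict:
    """Values of one family for one epoch; NaN where coverage fails."""
    window = FAMILY_WINDOWS[family]
    centre = epoch_index * EPOCH_SECONDS + 15.0
    a, b = centre - window / 2.0, centre + window / 2.0
    names = FAMILY_FEATURE_NAMES[family]
    if family == "activity_counts":
        if ecg is None:
            return {"activity": np.nan}
        counts = activity_counts(ecg, n_epochs or ecg.n_epochs)
        return {"activity": counts[epoch_index]}
    if not epoch_coverage_ok(ibis, a, b):
        return dict.fromkeys(names, np.nan)
    onsets, values = _window_values(ibis, a, b)
    if family == "hrv_time":
        return _hrv_time(onsets, values)
    if family == "hrv_freq":
        return _hrv_freq(onsets, values, a, b)
    if family == "dfa":
        return _dfa(values)
    if family == "dfa_progressive":
        return _dfa_progressive(values)
    if family == "dfa_windowed":
        return _dfa_windowed(onsets, values, a, b)
    if family == "sample_entropy":
        return _sample_entropy_family(values)
    if family == "multiscale_entropy":
        return multiscale_entropy(values)
    raise ValueError(f"unknown feature family {family!r}")


def extract_feature_matrix(ibis: IBISeries, ecg: Optional[ECGRecord],
                           n_epochs: int,
                           registry: Optional[FeatureRegistry] = None
                           ) -> FeatureMatrix:
    """Per-epoch feature matrix for one recording.

    Windows are centred on each epoch; edge windows are truncated but the
    coverage test uses the nominal window length, so edge epochs of
    long-window families come out missing. All values are finite or NaN.
    """
    registry = registry or FeatureRegistry()
    specs = registry.specs()
    values = np.full((n_epochs, len(specs)), np.nan)
    col = {s.name: j for j, s in enumerate(specs)}

    act = None
    if "activity_counts" in registry.families and ecg is not None:
        act = activity_counts(ecg, n_epochs)

    for fam in registry.families:
        if fam == "activity_counts":
            if act is not None:
                values[:, col["activity"]] = act
            continue
        window = FAMILY_WINDOWS[fam]
        for k in range(n_epochs):
            centre = k * EPOCH_SECONDS + 15.0
            a, b = centre - window / 2.0, centre + window / 2.0
            if not epoch_coverage_ok(ibis, a, b):
                continue
            onsets, vals = _window_values(ibis, a, b)
            if fam == "hrv_time":
                res = _hrv_time(onsets, vals)
            elif fam == "hrv_freq":
                res = _hrv_freq(onsets, vals, a, b)
            elif fam == "dfa":
                res = _dfa(vals)
            elif fam == "dfa_progressive":
                res = _dfa_progressive(vals)
            elif fam == "dfa_windowed":
                res = _dfa_windowed(onsets, vals, a, b)
            elif fam == "sample_entropy":
                res = _sample_entropy_family(vals)
            elif fam == "multiscale_entropy":
                res = multiscale_entropy(vals)
            else:  # pragma: no cover
                raise ValueError(fam)
            for name, v in res.items():
                values[k, col[name]] = v

    for pname, (window, names, func) in registry.plugins.items():
        for k in range(n_epochs):
            centre = k * EPOCH_SECONDS + 15.0
            a, b = centre - window / 2.0, centre + window / 2.0
            if not epoch_coverage_ok(ibis, a, b):
                continue
            onsets, vals = _window_values(ibis, a, b)
            res = func(onsets, vals, a, b)
            for name, v in res.items():
                values[k, col[name]] = v

    values[~np.isfinite(values)] = np.nan
    return FeatureMatrix(record_id=ibis.record_id, columns=specs, values=values)
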