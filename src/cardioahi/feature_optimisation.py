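"""Greedy per-feature transformation optimisation.

Each feature is transformed, per recording, by a chain of at most five
transformations drawn from a fixed catalogue. Every transformation
belongs to a group, and a transformation may follow another only when the
predecessor's group is listed among its input groups (the raw feature is
group 0); this connection graph prunes meaningless orders such as
clipping outliers after the distribution has already been reshaped. The
search is greedy: at each depth all legal successors are scored with the
absolute mean standardized distance (AMSD) between the RE and non-RE
epoch classes, pooled over all training recordings,

    AMSD = |mean_RE - mean_nonRE| / sd_all,

with the population (n-denominator) standard deviation over the pooled
epochs of both classes. Ties break toward the earliest catalogue entry;
the search stops when no successor strictly improves the AMSD.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import signal, stats


class AMSDUndefinedError(ValueError):
    """AMSD is undefined (single class or zero pooled variance)."""


# ---------------------------------------------------------------------------
# AMSD
# ---------------------------------------------------------------------------

def amsd(values, labels) -> float:
    """Absolute mean standardized distance between the two epoch classes.

    Missing (NaN) values are ignored. Raises :class:`AMSDUndefinedError`
    when either class has no finite values or the pooled population SD is
    zero.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    finite = np.isfinite(values)
    pos = values[finite & labels]
    neg = values[finite & ~labels]
    if pos.size == 0 or neg.size == 0:
        raise AMSDUndefinedError("both classes must have finite values")
    pooled = values[finite]
    sd = float(np.std(pooled))  # population convention
    if sd == 0:
        raise AMSDUndefinedError("zero pooled standard deviation")
    return abs(float(pos.mean()) - float(neg.mean())) / sd


def amsd_score(values, labels) -> float:
    """AMSD, with undefined cases scored 0 for the greedy search."""
    try:
        return amsd(values, labels)
    except AMSDUndefinedError:
        return 0.0


# ---------------------------------------------------------------------------
# Transformation catalogue
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TransformationSpec:
    """One parameterised transformation from the catalogue."""

    name: str
    group: int
    parameters: tuple = ()  # sorted (key, value) pairs; hashable

    @property
    def params(self) -> dict:
        return dict(self.parameters)

    def to_dict(self) -> dict:
        return {"name": self.name, "group": self.group,
                "parameters": self.params}

    @staticmethod
    def from_dict(d: dict) -> "TransformationSpec":
        return TransformationSpec(d["name"], int(d["group"]),
                                  tuple(sorted(d.get("parameters", {}).items())))


@dataclass
class TransformationChain:
    """Ordered transformation chain for one feature with its AMSD."""

    feature_name: str
    specs: list = field(default_factory=list)
    achieved_amsd: float = 0.0

    def __len__(self) -> int:
        return len(self.specs)

    def to_dict(self) -> dict:
        return {"feature_name": self.feature_name,
                "achieved_amsd": self.achieved_amsd,
                "specs": [s.to_dict() for s in self.specs]}

    @staticmethod
    def from_dict(d: dict) -> "TransformationChain":
        return TransformationChain(
            d["feature_name"],
            [TransformationSpec.from_dict(s) for s in d["specs"]],
            float(d["achieved_amsd"]))


# (name, group, input-groups, parameter grid) in fixed catalogue order
_WINDOWS = (7, 15, 23, 31)
_ALIGNMENTS = ("backward", "forward", "centred")
_WIN_PARAMS = [{"window": w, "alignment": a} for w in _WINDOWS for a in _ALIGNMENTS]
_CUTOFFS = [{"cutoff": c} for c in (0.25, 0.5, 0.75)]

CATALOGUE_DEF = [
    ("Winsor", 1, {0, 4, 6, 7, 8, 9},
     [{"bounds": (1, 99)}, {"bounds": (5, 95)}]),
    ("Median", 2, {0, 1}, [{}]),
    ("Z-score", 3, {0, 1, 4}, [{}]),
    ("Percentile", 3, {0, 1, 4}, [{}]),
    ("Amplitude", 3, {0, 1, 4}, [{}]),
    ("Box-Cox", 4, {0, 1, 6, 7, 8, 9}, [{}]),
    ("Histogram", 4, {0, 1, 6, 7, 8, 9}, [{}]),
    ("Quantile", 4, {0, 1, 6, 7, 8, 9},
     [{"distribution": d} for d in ("normal", "exponential", "uniform")]),
    ("Tukey-Ladder", 4, {0, 1, 6, 7, 8, 9}, [{}]),
    ("Time-shift", 5, {0}, [{"shift": -1}, {"shift": 1}]),
    ("MAD", 6, {0, 5}, _WIN_PARAMS),
    ("SD", 6, {0, 5}, _WIN_PARAMS),
    ("Abs", 6, {0, 5}, [{}]),
    ("Diff", 6, {0, 5}, [{}]),
    ("Int", 6, {0, 5}, [{}]),
    ("Average", 7, {0, 5, 6}, _WIN_PARAMS),
    ("Median-filter", 7, {0, 5, 6}, _WIN_PARAMS),
    ("LPF", 7, {0, 5, 6}, _CUTOFFS),
    ("Subtract-Median", 8, {0, 5, 6, 7}, _WIN_PARAMS),
    ("HPF", 8, {0, 5, 6, 7}, _CUTOFFS),
    ("Exponential", 9, {0, 5, 6, 7, 8},
     [{"exponent": "square"}, {"exponent": "square_root"}]),
    ("Log", 9, {0, 5, 6, 7, 8}, [{}]),
]

INPUT_GROUPS = {name: frozenset(inputs) for name, _, inputs, _ in CATALOGUE_DEF}
GROUP_OF = {name: group for name, group, _, _ in CATALOGUE_DEF}

CATALOGUE: list = []
for _name, _group, _inputs, _grids in CATALOGUE_DEF:
    for _p in _grids:
        CATALOGUE.append(TransformationSpec(_name, _group,
                                            tuple(sorted(_p.items()))))
MAX_CHAIN_LENGTH = 5


def valid_successor_specs(chain: TransformationChain) -> list:
    """All parameterised transformations that may legally extend a chain."""
    if len(chain) >= MAX_CHAIN_LENGTH:
        return []
    last_group = chain.specs[-1].group if chain.specs else 0
    return [s for s in CATALOGUE if last_group in INPUT_GROUPS[s.name]]


# ---------------------------------------------------------------------------
# Transformation implementations (per-recording, NaN-propagating)
# ---------------------------------------------------------------------------

_EPS_FRACTION = 1e-6


def _positive_shift(x: np.ndarray) -> np.ndarray:
    """Shift a series so its finite minimum is strictly positive."""
    finite = x[np.isfinite(x)]
    if finite.size == 0:
        return x
    lo = finite.min()
    if lo > 0:
        return x
    span = np.ptp(finite)
    eps = _EPS_FRACTION * (span if span > 0 else 1.0) + 1e-12
    return x - lo + eps


def _pad_windows(x: np.ndarray, window: int, alignment: str) -> np.ndarray:
    """(n, window) view of x with NaN padding per alignment."""
    if alignment == "backward":
        left, right = window - 1, 0
    elif alignment == "forward":
        left, right = 0, window - 1
    elif alignment == "centred":
        left = (window - 1) // 2
        right = window - 1 - left
    else:
        raise ValueError(f"unknown alignment {alignment!r}")
    padded = np.concatenate([np.full(left, np.nan), x, np.full(right, np.nan)])
    return np.lib.stride_tricks.sliding_window_view(padded, window)


def _windowed(x, window, alignment, reducer):
    w = _pad_windows(x, window, alignment)
    with np.errstate(all="ignore"):
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore", RuntimeWarning)
            out = reducer(w)
    out[~np.isfinite(x)] = np.nan
    return out


def _nan_mad(w):
    med = np.nanmedian(w, axis=1, keepdims=True)
    return np.nanmean(np.abs(w - med), axis=1)


def _butterworth(x: np.ndarray, cutoff: float, btype: str) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth on the epoch-indexed series.

    NaNs are bridged by linear interpolation for filtering and restored
    afterwards so missingness propagates.
    """
    finite = np.isfinite(x)
    if finite.sum() < 12:
        return np.full_like(x, np.nan)
    idx = np.arange(x.size)
    filled = np.interp(idx, idx[finite], x[finite])
    b, a = signal.butter(2, cutoff, btype=btype)
    y = signal.filtfilt(b, a, filled)
    y[~finite] = np.nan
    return y


_BOXCOX_GRID = np.linspace(-2.0, 2.0, 41)


def _boxcox_mle(vals: np.ndarray) -> np.ndarray:
    """Box-Cox transform with the ML lambda chosen on a fixed grid.

    The profile log-likelihood -n/2 log var(y_lambda) + (lambda-1) sum
    log x is evaluated on a 41-point grid over [-2, 2]; the grid keeps the
    estimate deterministic and avoids optimiser overhead for the many
    small per-recording fits of the greedy search.
    """
    n = vals.size
    logx = np.log(vals)
    slog = logx.sum()
    best_llf, best_y = -np.inf, None
    for lam in _BOXCOX_GRID:
        y = logx if lam == 0.0 else (vals ** lam - 1.0) / lam
        var = y.var()
        if var <= 0:
            continue
        llf = -0.5 * n * np.log(var) + (lam - 1.0) * slog
        if llf > best_llf:
            best_llf, best_y = llf, y
    return best_y if best_y is not None else logx


def _skewness(vals: np.ndarray) -> float:
    m = vals.mean()
    d = vals - m
    m2 = np.mean(d ** 2)
    if m2 == 0:
        return 0.0
    return float(np.mean(d ** 3) / m2 ** 1.5)


_TUKEY_LADDER = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0)


def _tukey_ladder(x: np.ndarray) -> np.ndarray:
    """Power-ladder transform choosing the exponent that minimises the
    absolute skewness of the recording's finite values."""
    xp = _positive_shift(x)
    finite = np.isfinite(xp)
    vals = xp[finite]
    if vals.size < 3 or np.ptp(vals) == 0:
        return x.copy()
    best, best_skew = None, np.inf
    for lam in _TUKEY_LADDER:
        if lam == 0.0:
            cand = np.log(vals)
        elif lam > 0:
            cand = vals ** lam
        else:
            cand = -(vals ** lam)  # negated to preserve ordering
        sk = abs(_skewness(cand))
        if np.isfinite(sk) and sk < best_skew:
            best, best_skew = lam, sk
    if best is None:
        return x.copy()
    out = np.full_like(x, np.nan)
    if best == 0.0:
        out[finite] = np.log(vals)
    elif best > 0:
        out[finite] = vals ** best
    else:
        out[finite] = -(vals ** best)
    return out


def apply_transformation(series, spec: TransformationSpec) -> np.ndarray:
    """Apply one transformation to one recording's feature series.

    All statistics (percentiles, medians, Box-Cox parameter, quantile
    maps) come from the recording itself. Missing values propagate;
    windowed operators ignore missing values inside the window.
    """
    x = np.asarray(series, dtype=float).copy()
    finite = np.isfinite(x)
    name, p = spec.name, spec.params
    if finite.sum() == 0:
        return x

    if name == "Winsor":
        lo, hi = np.nanpercentile(x, list(p["bounds"]))
        return np.clip(x, lo, hi)
    if name == "Median":
        return x - np.nanmedian(x)
    if name == "Z-score":
        mu, sd = np.nanmean(x), np.nanstd(x)  # population SD
        return (x - mu) / sd if sd > 0 else x - mu
    if name == "Percentile":
        out = np.full_like(x, np.nan)
        vals = x[finite]
        if vals.size == 1:
            out[finite] = 0.0
            return out
        ranks = stats.rankdata(vals)
        out[finite] = (ranks - 1) / (vals.size - 1)
        return out
    if name == "Amplitude":
        peak = np.nanmax(np.abs(x))
        return x / peak if peak > 0 else x
    if name == "Box-Cox":
        vals = _positive_shift(x)[finite]
        if np.ptp(vals) == 0:
            return np.where(finite, 0.0, np.nan)
        bc = _boxcox_mle(vals)
        out = np.full_like(x, np.nan)
        sd = np.std(bc)
        out[finite] = (bc - bc.mean()) / sd if sd > 0 else bc - bc.mean()
        return out
    if name == "Histogram":
        vals = x[finite]
        if np.ptp(vals) == 0:
            return np.where(finite, 0.0, np.nan)
        counts, edges = np.histogram(vals, bins=10)
        cdf = np.cumsum(counts) / vals.size
        idx = np.clip(np.digitize(vals, edges[1:-1]), 0, 9)
        out = np.full_like(x, np.nan)
        out[finite] = cdf[idx]
        return out
    if name == "Quantile":
        vals = x[finite]
        n = vals.size
        q = stats.rankdata(vals) / (n + 1)
        dist = p["distribution"]
        if dist == "normal":
            mapped = stats.norm.ppf(q)
        elif dist == "exponential":
            mapped = stats.expon.ppf(q)
        elif dist == "uniform":
            mapped = q
        else:
            raise ValueError(f"unknown reference distribution {dist!r}")
        out = np.full_like(x, np.nan)
        out[finite] = mapped
        return out
    if name == "Tukey-Ladder":
        return _tukey_ladder(x)
    if name == "Time-shift":
        out = np.full_like(x, np.nan)
        s = p["shift"]
        if s > 0:
            out[s:] = x[:-s]
        else:
            out[:s] = x[-s:]
        return out
    if name == "MAD":
        return _windowed(x, p["window"], p["alignment"], _nan_mad)
    if name == "SD":
        return _windowed(x, p["window"], p["alignment"],
                         lambda w: np.nanstd(w, axis=1))
    if name == "Abs":
        return np.abs(x)
    if name == "Diff":
        out = np.full_like(x, np.nan)
        out[1:] = x[1:] - x[:-1]
        return out
    if name == "Int":
        # cumulative sum after mean removal; missing values contribute
        # nothing to the running sum but stay missing in the output
        centred = np.where(finite, x - np.nanmean(x), 0.0)
        out = np.cumsum(centred)
        out[~finite] = np.nan
        return out
    if name == "Average":
        return _windowed(x, p["window"], p["alignment"],
                         lambda w: np.nanmean(w, axis=1))
    if name == "Median-filter":
        return _windowed(x, p["window"], p["alignment"],
                         lambda w: np.nanmedian(w, axis=1))
    if name == "LPF":
        return _butterworth(x, p["cutoff"], "lowpass")
    if name == "Subtract-Median":
        med = _windowed(x, p["window"], p["alignment"],
                        lambda w: np.nanmedian(w, axis=1))
        return x - med
    if name == "HPF":
        return _butterworth(x, p["cutoff"], "highpass")
    if name == "Exponential":
        if p["exponent"] == "square":
            return x ** 2
        return np.sign(x) * np.sqrt(np.abs(x))  # signed root, defined on R
    if name == "Log":
        xp = _positive_shift(x)
        out = np.full_like(x, np.nan)
        out[finite] = np.log(xp[finite])
        return out
    raise ValueError(f"unknown transformation {name!r}")


def apply_chain(series, chain: TransformationChain) -> np.ndarray:
    """Replay a chain on one recording's series."""
    x = np.asarray(series, dtype=float)
    for spec in chain.specs:
        x = apply_transformation(x, spec)
    return x


# ---------------------------------------------------------------------------
# Greedy search
# ---------------------------------------------------------------------------

def optimise_feature(series_per_recording: Sequence[np.ndarray],
                     labels_per_recording: Sequence[np.ndarray],
                     feature_name: str = "feature",
                     max_depth: int = MAX_CHAIN_LENGTH,
                     catalogue: Optional[list] = None) -> TransformationChain:
    """Greedy chain search maximising the pooled AMSD for one feature.

    Transformations are applied per recording; the AMSD pools the epochs
    of all recordings. The search keeps the single best successor at each
    depth (ties to the earliest catalogue entry) and stops when no
    successor strictly improves the score or the depth cap is reached.
    Degenerate features (all missing, constant, or single-class labels)
    yield an empty chain with AMSD 0.
    """
    current = [np.asarray(s, dtype=float).copy() for s in series_per_recording]
    labels = np.concatenate([np.asarray(l, dtype=bool)
                             for l in labels_per_recording])
    base = amsd_score(np.concatenate(current), labels)
    chain = TransformationChain(feature_name, [], base)
    if base == 0.0 and not np.any(np.isfinite(np.concatenate(current))):
        return chain
    pool = CATALOGUE if catalogue is None else catalogue
    depth_cap = min(max_depth, MAX_CHAIN_LENGTH)
    while len(chain) < depth_cap:
        last_group = chain.specs[-1].group if chain.specs else 0
        best_spec, best_score, best_series = None, chain.achieved_amsd, None
        for spec in pool:
            if last_group not in INPUT_GROUPS[spec.name]:
                continue
            transformed = [apply_transformation(s, spec) for s in current]
            score = amsd_score(np.concatenate(transformed), labels)
            if score > best_score:
                best_spec, best_score, best_series = spec, score, transformed
        if best_spec is None:
            break
        chain.specs.append(best_spec)
        chain.achieved_amsd = best_score
        current = best_series
    return chain


def save_chains(path, chains: Sequence[TransformationChain]) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_dict() for c in chains], fh, indent=2)


def load_chains(path) -> list:
    with open(path) as fh:
        return [TransformationChain.from_dict(d) for d in json.load(fh)]
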