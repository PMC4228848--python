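"""Half-amplitude threshold idealization and per-patch summaries.

A multi-channel patch recording is reduced to an event list (open level,
onset, duration) by assigning each sample to level k when the
baseline-corrected current lies nearest k times the unitary amplitude —
i.e. crosses the half-amplitude thresholds (k - 1/2)*A — with a small
hysteresis band to suppress chatter at the thresholds, after a piecewise
baseline estimated from all-closed stretches has been removed.  Events
shorter than the dead time are absorbed into their neighbors.

From the event list the module computes the patch summaries used
downstream: NPo as level-weighted open occupancy (with the literal
open/(open+closed) aggregate also reported), Po = NPo/n with n the maximum
number of simultaneously open channels observed, maximal open sojourn
durations (patches contain several channels, so only open dwell times are
analyzed, never closed kinetics), exponential dwell-time mixtures fitted by
EM with dead-time left-truncation and BIC model selection, and a Gaussian
fit to the unitary (level-1) amplitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit as _njit
except ImportError:  # pragma: no cover
    _njit = None

__all__ = [
    "IdealizedRecord",
    "PatchSummary",
    "DwellTimeFit",
    "AmplitudeFit",
    "NoOpenEventsError",
    "track_baseline",
    "estimate_unitary_amplitude",
    "idealize_half_amplitude",
    "compute_npo",
    "extract_open_dwells",
    "fit_dwell_exponentials",
    "fit_amplitude_histogram",
    "summarize_patch",
]


class NoOpenEventsError(ValueError):
    """Raised when an operation requires open events and none exist."""


# ---------------------------------------------------------------------------
# baseline tracking
# ---------------------------------------------------------------------------

def _half_sample_mode(x: np.ndarray) -> float:
    """Robust mode via the recursive half-sample (shorth) estimator."""
    y = np.sort(np.asarray(x, float))
    while len(y) > 3:
        h = (len(y) + 1) // 2
        widths = y[h - 1:] - y[: len(y) - h + 1]
        i = int(np.argmin(widths))
        y = y[i: i + h]
    return float(np.median(y))


def track_baseline(
    samples: np.ndarray,
    dt_ms: float,
    unitary_amplitude: float | None = None,
    segment_ms: float = 1000.0,
) -> np.ndarray:
    """Piecewise baseline from samples classified as all-closed.

    The trace is cut into segments (default 1 s).  Within each segment the
    baseline is the median of the closed-classified samples — below the
    half-amplitude threshold when the unitary amplitude is known, refined
    iteratively — or a robust mode estimate when it is not.  Segment values
    are linearly interpolated (and linearly extrapolated at the ends), which
    removes slow drift exactly for locally linear drift.  A segment with no
    detectable closed samples falls back to the global estimate with a
    warning.
    """
    x = np.asarray(samples, float)
    if x.size == 0:
        raise ValueError("empty trace")
    seg_len = max(int(round(segment_ms / dt_ms)), 1)
    n_seg = max(int(math.ceil(len(x) / seg_len)), 1)
    centers = np.empty(n_seg)
    values = np.empty(n_seg)
    global_b = None
    for i in range(n_seg):
        seg = x[i * seg_len: (i + 1) * seg_len]
        centers[i] = (i * seg_len + len(seg) / 2.0 - 0.5)
        if unitary_amplitude is not None:
            b = float(np.median(seg))
            closed = seg
            for _ in range(3):
                closed = seg[seg < b + 0.5 * unitary_amplitude]
                if closed.size == 0:
                    break
                b = float(np.median(closed))
            if closed.size == 0:
                if global_b is None:
                    global_b = _half_sample_mode(x)
                warnings.warn(
                    "segment with no closed samples; using global baseline",
                    stacklevel=2,
                )
                b = global_b
            values[i] = b
        else:
            values[i] = _half_sample_mode(seg)
    idx = np.arange(len(x), dtype=float)
    if n_seg == 1:
        return np.full(len(x), values[0])
    baseline = np.interp(idx, centers, values)
    # linear extrapolation beyond the first/last segment centers
    s0 = (values[1] - values[0]) / (centers[1] - centers[0])
    s1 = (values[-1] - values[-2]) / (centers[-1] - centers[-2])
    left = idx < centers[0]
    right = idx > centers[-1]
    baseline[left] = values[0] + s0 * (idx[left] - centers[0])
    baseline[right] = values[-1] + s1 * (idx[right] - centers[-1])
    return baseline


def estimate_unitary_amplitude(
    samples: np.ndarray, baseline: np.ndarray | float = 0.0
) -> float:
    """Rough unitary amplitude for ``--amplitude auto``.

    Noise scale is taken from the median absolute deviation around the
    baseline; samples beyond 4 sigma are open-level candidates and the
    level-1 amplitude is their robust mode.
    """
    x = np.asarray(samples, float) - baseline
    mad = float(np.median(np.abs(x - np.median(x))))
    sigma = 1.4826 * mad if mad > 0 else float(np.std(x))
    candidates = x[x > 4.0 * sigma]
    if candidates.size < 10:
        raise NoOpenEventsError("too few supra-threshold samples to estimate amplitude")
    a1 = _half_sample_mode(candidates)
    # restrict to the first open level and re-estimate
    level1 = candidates[(candidates > 0.5 * a1) & (candidates < 1.5 * a1)]
    return _half_sample_mode(level1) if level1.size else a1


# ---------------------------------------------------------------------------
# half-amplitude quantization with hysteresis
# ---------------------------------------------------------------------------

def _quantize_py(x, inv_a, h_frac, max_level):  # pragma: no cover - numba preferred
    n = x.shape[0]
    out = np.empty(n, np.int16)
    level = int(min(max(round(x[0] * inv_a), 0), max_level))
    out[0] = level
    for i in range(1, n):
        v = x[i] * inv_a
        up = int(math.floor(v - h_frac + 0.5))
        dn = int(math.floor(v + h_frac + 0.5))
        if up > level:
            level = up
        elif dn < level:
            level = dn
        if level < 0:
            level = 0
        elif level > max_level:
            level = max_level
        out[i] = level
    return out


if _njit is not None:
    _quantize = _njit(cache=True, nogil=True)(_quantize_py)
else:  # pragma: no cover
    _quantize = _quantize_py


@dataclass
class IdealizedRecord:
    """Gap-free tiling of the trace by constant-level events."""

    levels: np.ndarray       # int level per event
    starts_ms: np.ndarray    # event onset
    durations_ms: np.ndarray
    total_duration_ms: float
    n_levels_observed: int
    baseline: np.ndarray | None = field(default=None, repr=False)
    truncated: bool = False  # True when max_levels clipped the record
    dt_ms: float | None = None

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.durations_ms):
            raise ValueError("levels and durations must align")
        if np.any(self.durations_ms <= 0):
            raise ValueError("event durations must be positive")

    def __len__(self) -> int:
        return len(self.levels)


def _events_from_levels(level: np.ndarray, dt_ms: float):
    change = np.flatnonzero(np.diff(level)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(level)]))
    return level[starts].astype(int), starts * dt_ms, (ends - starts) * dt_ms


def _merge_dead_time(levels, durations, dead_time_ms):
    """Absorb events shorter than the dead time into the longer neighbor
    (previous neighbor on ties), then re-merge equal adjacent levels."""
    lv = list(map(int, levels))
    du = list(map(float, durations))
    changed = True
    while changed and len(lv) > 1:
        changed = False
        i = 0
        while i < len(lv):
            if du[i] < dead_time_ms and len(lv) > 1:
                if i == 0:
                    j = 1
                elif i == len(lv) - 1:
                    j = i - 1
                else:
                    j = i - 1 if du[i - 1] >= du[i + 1] else i + 1
                lv[i] = lv[j]
                changed = True
            i += 1
        # merge adjacent equal levels
        mlv, mdu = [lv[0]], [du[0]]
        for l, d in zip(lv[1:], du[1:]):
            if l == mlv[-1]:
                mdu[-1] += d
            else:
                mlv.append(l)
                mdu.append(d)
        lv, du = mlv, mdu
    return np.array(lv), np.array(du)


def idealize_half_amplitude(
    samples: np.ndarray,
    baseline: np.ndarray | float,
    unitary_amplitude: float,
    dt_ms: float,
    max_levels: int = 4,
    dead_time_ms: float | None = None,
    hysteresis_frac: float = 0.1,
) -> IdealizedRecord:
    """Threshold idealization of a baseline-corrected trace.

    A sample belongs to level k when the corrected current is within half an
    amplitude of k*A, i.e. has crossed (k - 1/2)*A; transitions additionally
    require overshooting the threshold by ``hysteresis_frac * A``.  Events
    shorter than the dead time (default two sampling intervals) are absorbed
    into their neighbors.  If more than ``max_levels`` simultaneous openings
    occur the record is clipped at ``max_levels`` and flagged.
    """
    if unitary_amplitude <= 0:
        raise ValueError("unitary_amplitude must be positive")
    x = np.asarray(samples, float) - baseline
    if x.size == 0:
        raise ValueError("empty trace")
    if dead_time_ms is None:
        dead_time_ms = 2.0 * dt_ms
    raw_max = int(math.floor(float(np.max(x)) / unitary_amplitude + 0.5))
    truncated = raw_max > max_levels
    level = _quantize(
        np.ascontiguousarray(x, dtype=np.float64),
        1.0 / unitary_amplitude,
        float(hysteresis_frac),
        int(max_levels),
    )
    levels, starts, durations = _events_from_levels(level, dt_ms)
    if dead_time_ms > 0 and len(levels) > 1:
        levels, durations = _merge_dead_time(levels, durations, dead_time_ms)
        starts = np.concatenate(([0.0], np.cumsum(durations)[:-1]))
    rec = IdealizedRecord(
        levels=levels,
        starts_ms=starts,
        durations_ms=durations,
        total_duration_ms=len(x) * dt_ms,
        n_levels_observed=int(levels.max()),
        baseline=np.broadcast_to(np.asarray(baseline, float), x.shape).copy(),
        truncated=truncated,
        dt_ms=dt_ms,
    )
    return rec


# ---------------------------------------------------------------------------
# per-patch summaries
# ---------------------------------------------------------------------------

@dataclass
class PatchSummary:
    """NPo/Po and aggregate open/closed times of one idealized patch."""

    npo: float               # level-weighted open occupancy
    po: float                # npo / n_max
    n_max: int               # maximum simultaneous open channels observed
    to_ms: float             # sum of level-weighted open time
    tc_ms: float             # complementary closed time (level-weighted)
    npo_literal: float       # unweighted open/(open+closed) aggregate
    total_duration_ms: float
    mean_open_dwell_ms: float = math.nan
    amplitude_pA: float = math.nan


def compute_npo(record: IdealizedRecord) -> PatchSummary:
    """NPo, Po and open/closed time aggregates from an event list.

    Primary definition (field convention): NPo = sum(level * duration) /
    total duration, the time-weighted mean number of open channels; Po =
    NPo/n with n the maximum observed level.  The literal unweighted
    open/(open+closed) ratio is reported alongside.
    """
    total = float(record.total_duration_ms)
    if total <= 0:
        raise ValueError("record has zero duration")
    lv = record.levels
    du = record.durations_ms
    to = float(np.sum(lv * du))
    n_max = int(lv.max())
    npo = to / total
    po = npo / n_max if n_max > 0 else 0.0
    tc = total * n_max - to
    open_time = float(np.sum(du[lv >= 1]))
    npo_literal = open_time / total
    return PatchSummary(
        npo=npo,
        po=po,
        n_max=n_max,
        to_ms=to,
        tc_ms=tc,
        npo_literal=npo_literal,
        total_duration_ms=total,
    )


def extract_open_dwells(record: IdealizedRecord) -> np.ndarray:
    """Durations of maximal sojourns at any open level (level >= 1).

    A sojourn runs from the first departure from level 0 to the next return
    to level 0; passages between open levels (1 -> 2 -> 1) stay within a
    single dwell.  Closed durations are never emitted.
    """
    dwells = []
    acc = 0.0
    for lv, du in zip(record.levels, record.durations_ms):
        if lv >= 1:
            acc += du
        elif acc > 0:
            dwells.append(acc)
            acc = 0.0
    if acc > 0:
        dwells.append(acc)
    return np.asarray(dwells)


# ---------------------------------------------------------------------------
# exponential dwell-time mixtures (EM, dead-time left truncation, BIC)
# ---------------------------------------------------------------------------

@dataclass
class DwellTimeFit:
    """Exponential mixture fit: components are (weight, tau_ms) pairs."""

    components: list[tuple[float, float]]
    log_likelihood: float
    n_components: int
    bic: dict[int, float]
    converged: bool = True

    @property
    def taus(self) -> list[float]:
        return [t for _, t in self.components]

    @property
    def weights(self) -> list[float]:
        return [w for w, _ in self.components]

    @property
    def mean_tau(self) -> float:
        return float(sum(w * t for w, t in self.components))


_WEIGHT_FLOOR = 1e-4


def _em_exponential(t, k, rng, max_iter=500, tol=1e-10):
    """EM for a k-component exponential mixture on shifted data t >= 0."""
    n = len(t)
    mean_t = float(np.mean(t))
    q = np.quantile(t, np.linspace(0.15, 0.85, k)) if k > 1 else np.array([mean_t])
    taus = np.clip(q * np.exp(rng.uniform(-0.3, 0.3, k)), 1e-6, None)
    w = np.full(k, 1.0 / k)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        log_dens = np.log(w)[None, :] - np.log(taus)[None, :] - t[:, None] / taus[None, :]
        m = log_dens.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.sum(np.exp(log_dens - m), axis=1))
        ll = float(np.sum(lse))
        r = np.exp(log_dens - lse[:, None])
        nk = r.sum(axis=0)
        w = np.clip(nk / n, _WEIGHT_FLOOR, None)
        w /= w.sum()
        taus = np.clip((r * t[:, None]).sum(axis=0) / np.clip(nk, 1e-300, None), 1e-9, None)
        if abs(ll - ll_old) < tol * (1.0 + abs(ll)):
            converged = True
            break
        ll_old = ll
    return w, taus, ll, converged


def fit_dwell_exponentials(
    durations: np.ndarray,
    max_components: int = 3,
    dead_time_ms: float = 0.0,
    n_restarts: int = 5,
    seed: int = 0,
) -> DwellTimeFit:
    """Maximum-likelihood exponential mixture for open dwell times.

    The likelihood is left-truncated at the dead time: because exponentials
    are memoryless, fitting the mixture to ``t - dead_time`` leaves the
    component taus unchanged while the truncated-scale weights are mapped
    back with w_k proportional to v_k * exp(dead_time / tau_k).  Candidate
    models with 1..``max_components`` terms are fitted (5 restarts each on a
    deterministic seed schedule) and the number of terms is selected by BIC.
    """
    t_raw = np.asarray(durations, float)
    if len(t_raw) < 10:
        raise ValueError("need at least 10 dwell times")
    if np.any(t_raw <= dead_time_ms):
        warnings.warn("dwells at/below the dead time dropped from the fit", stacklevel=2)
        t_raw = t_raw[t_raw > dead_time_ms]
    t = t_raw - dead_time_ms
    t = np.clip(t, 1e-9, None)
    n = len(t)
    best_by_k: dict[int, tuple] = {}
    bic: dict[int, float] = {}
    for k in range(1, max_components + 1):
        best = None
        for r in range(n_restarts):
            rng = np.random.default_rng(seed * 1000 + 97 * k + r)
            w, taus, ll, conv = _em_exponential(t, k, rng)
            if best is None or ll > best[2]:
                best = (w, taus, ll, conv)
        w, taus, ll, conv = best
        bic[k] = -2.0 * ll + (2 * k - 1) * math.log(n)
        best_by_k[k] = best
    k_sel = min(bic, key=bic.get)
    w, taus, ll, conv = best_by_k[k_sel]
    if not conv:
        warnings.warn("EM did not converge; best-so-far returned", stacklevel=2)
    # map truncated-scale weights back to the untruncated mixture
    w_orig = w * np.exp(np.clip(dead_time_ms / taus, None, 700.0))
    w_orig /= w_orig.sum()
    order = np.argsort(taus)
    components = [(float(w_orig[i]), float(taus[i])) for i in order]
    return DwellTimeFit(
        components=components,
        log_likelihood=float(ll),
        n_components=int(k_sel),
        bic=bic,
        converged=bool(conv),
    )


# ---------------------------------------------------------------------------
# amplitude fitting
# ---------------------------------------------------------------------------

@dataclass
class AmplitudeFit:
    """Gaussian fit to the unitary (level-1) amplitude distribution."""

    mean: float
    sd: float
    n_events: int
    goodness: float          # RMS deviation of the event-mean histogram from the fit
    histogram: tuple[np.ndarray, np.ndarray] | None = field(default=None, repr=False)


def fit_amplitude_histogram(
    samples: np.ndarray,
    record: IdealizedRecord,
    baseline: np.ndarray | float = 0.0,
    min_duration_ms: float = 1.0,
    edge_trim_ms: float = 0.3,
) -> AmplitudeFit:
    """Gaussian amplitude fit from level-1 event means.

    Level-1 events at least ``min_duration_ms`` long contribute the mean of
    their baseline-corrected samples, trimmed by ``edge_trim_ms`` at both
    edges to exclude filter rise/fall; the Gaussian (mean, sd) is the sample
    MLE over those event means.  Raises :class:`NoOpenEventsError` when no
    event qualifies.
    """
    if record.dt_ms is None:
        raise ValueError("record lacks a sampling interval")
    x = np.asarray(samples, float) - baseline
    dt = record.dt_ms
    trim = int(round(edge_trim_ms / dt))
    means = []
    for lv, start, du in zip(record.levels, record.starts_ms, record.durations_ms):
        if lv != 1 or du < min_duration_ms:
            continue
        i0 = int(round(start / dt))
        i1 = int(round((start + du) / dt))
        j0, j1 = i0 + trim, i1 - trim
        if j1 <= j0:
            j0, j1 = i0, i1
        means.append(float(np.mean(x[j0:j1])))
    if not means:
        if not np.any(record.levels >= 1):
            raise NoOpenEventsError("record contains no open events")
        raise NoOpenEventsError(
            "no level-1 event longer than min_duration_ms survives dead-time filtering"
        )
    arr = np.asarray(means)
    mu = float(np.mean(arr))
    sd = float(np.std(arr, ddof=1)) if len(arr) > 1 else 0.0
    sd = max(sd, 1e-9)
    counts, edges = np.histogram(arr, bins="auto", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    model = np.exp(-0.5 * ((centers - mu) / sd) ** 2) / (sd * math.sqrt(2 * math.pi))
    goodness = float(np.sqrt(np.mean((counts - model) ** 2)))
    return AmplitudeFit(
        mean=mu, sd=sd, n_events=len(arr), goodness=goodness,
        histogram=(counts, edges),
    )


def summarize_patch(
    samples: np.ndarray,
    record: IdealizedRecord,
    baseline: np.ndarray | float = 0.0,
    dead_time_ms: float = 0.0,
    max_dwell_components: int = 3,
    seed: int = 0,
) -> PatchSummary:
    """Full per-patch summary: NPo/Po plus dwell and amplitude fits."""
    summary = compute_npo(record)
    dwells = extract_open_dwells(record)
    if len(dwells) >= 10:
        fit = fit_dwell_exponentials(
            dwells,
            max_components=max_dwell_components,
            dead_time_ms=dead_time_ms,
            seed=seed,
        )
        summary.mean_open_dwell_ms = fit.mean_tau
    elif len(dwells):
        summary.mean_open_dwell_ms = float(np.mean(dwells))
    try:
        amp = fit_amplitude_histogram(samples, record, baseline)
        summary.amplitude_pA = amp.mean
    except NoOpenEventsError:
        pass
    return summary
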