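"""Synthetic patch-clamp data with known ground truth.

Two generators live here:

* a continuous-time Markov-chain (CTMC) gating simulator that produces exact
  per-channel state paths for a patch of independent identical channels, and
  renders them into a sampled, noisy, low-pass-filtered current trace; and
* a multi-patch experiment generator that produces long-format measurement
  tables (per-patch open probability, mean open dwell, unitary amplitude for
  paired control/H2S phases) with patch-level random intercepts on the logit
  scale — the statistical structure the mixed-model analysis assumes.

Defaults emulate excised-patch BK recordings at +30 mV with 0.5 uM free
Ca2+: 20 kHz sampling, 1 kHz Gaussian low-pass, a ~5 pA unitary current,
and condition presets whose stationary open probabilities and mean open
dwell times span the magnitudes typical of GH-cell recordings.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .stats import inverse_logit, logit

__all__ = [
    "GatingModel",
    "ChannelPath",
    "SimulatedTrace",
    "ExperimentDesign",
    "simulate_gating",
    "render_trace",
    "simulate_trace",
    "simulate_experiment",
    "gating_preset",
    "GATING_PRESETS",
    "CONDITION_PRESETS",
    "GAUSSIAN_SIGMA_MS_PER_KHZ",
]

# -3 dB point of a Gaussian kernel: |H(f)| = exp(-(2 pi f sigma)^2 / 2) = 2^-1/2
# at f = fc  =>  sigma_ms = sqrt(ln 2) / (2 pi fc_kHz).
GAUSSIAN_SIGMA_MS_PER_KHZ = math.sqrt(math.log(2.0)) / (2.0 * math.pi)

DEFAULT_DT_MS = 0.05          # 20 kHz sampling
DEFAULT_FILTER_KHZ = 1.0      # offline low-pass
DEFAULT_UNITARY_PA = 5.0      # unitary current at +30 mV (config choice)
DEFAULT_NOISE_SD_PA = 0.625   # SNR = amplitude/noise = 8


@dataclass
class GatingModel:
    """CTMC over gating states with a 0/1 conductance per state.

    ``rates`` is the generator matrix in 1/ms: ``rates[i, j]`` (i != j) is the
    transition rate from state i to state j; diagonal entries make rows sum
    to zero.  ``n_channels`` independent identical channels share the model.
    """

    conductance: np.ndarray
    rates: np.ndarray
    n_channels: int = 1
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.conductance = np.asarray(self.conductance, dtype=int)
        self.rates = np.asarray(self.rates, dtype=float)
        k = len(self.conductance)
        if self.rates.shape != (k, k):
            raise ValueError("rate matrix shape must match number of states")
        off = self.rates.copy()
        np.fill_diagonal(off, 0.0)
        if np.any(off < 0):
            raise ValueError("off-diagonal rates must be >= 0")
        if not np.allclose(self.rates.sum(axis=1), 0.0, atol=1e-10):
            raise ValueError("generator rows must sum to 0")
        if not (np.any(self.conductance > 0) and np.any(self.conductance == 0)):
            raise ValueError("need at least one open and one closed state")
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        # warn when no open state is reachable from some state
        reach = (off > 0) | np.eye(k, dtype=bool)
        for _ in range(k):
            reach = reach | (reach @ reach)
        if np.any(~(reach @ (self.conductance > 0))):
            warnings.warn("some states cannot reach any open state", stacklevel=2)

    @classmethod
    def two_state(
        cls, tau_open_ms: float, tau_closed_ms: float, n_channels: int = 1
    ) -> "GatingModel":
        """C <-> O model with mean open/closed sojourns tau_open/tau_closed."""
        if tau_open_ms <= 0 or tau_closed_ms <= 0:
            raise ValueError("dwell time constants must be positive")
        ko = 1.0 / tau_closed_ms  # opening rate (leaving C)
        kc = 1.0 / tau_open_ms    # closing rate (leaving O)
        rates = np.array([[-ko, ko], [kc, -kc]])
        return cls(
            conductance=np.array([0, 1]),
            rates=rates,
            n_channels=n_channels,
            labels=("C", "O"),
        )

    def stationary(self) -> np.ndarray:
        """Stationary distribution of the chain (left null vector of Q)."""
        k = len(self.conductance)
        a = np.vstack([self.rates.T, np.ones(k)])
        b = np.zeros(k + 1)
        b[-1] = 1.0
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        return np.clip(pi, 0.0, None) / np.clip(pi, 0.0, None).sum()

    def stationary_po(self) -> float:
        """Stationary per-channel open probability."""
        return float(self.stationary() @ (self.conductance > 0))


@dataclass
class ChannelPath:
    """Exact piecewise-constant state path: state ``states[i]`` holds on
    [times[i], times[i+1]) and the last state holds to ``duration_ms``."""

    times: np.ndarray
    states: np.ndarray
    duration_ms: float

    def sojourn_durations(self) -> np.ndarray:
        edges = np.append(self.times, self.duration_ms)
        return np.diff(edges)


def simulate_gating(
    model: GatingModel, duration_ms: float, seed: int | np.random.Generator
) -> list[ChannelPath]:
    """Exact event-driven CTMC simulation of each channel in the patch.

    Holding times are exponential with the state's total exit rate; jumps
    follow the embedded chain.  Initial states are drawn from the stationary
    distribution so finite traces are unbiased for occupancy.
    """
    if duration_ms <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    k = len(model.conductance)
    exit_rates = -np.diag(model.rates)
    jump_probs = model.rates.copy()
    np.fill_diagonal(jump_probs, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        jump_probs = np.where(
            exit_rates[:, None] > 0, jump_probs / exit_rates[:, None], 0.0
        )
    pi = model.stationary()
    paths = []
    for _ in range(model.n_channels):
        t = 0.0
        s = int(rng.choice(k, p=pi))
        times = [0.0]
        states = [s]
        while True:
            rate = exit_rates[s]
            if rate <= 0:
                break  # absorbing state
            t += rng.exponential(1.0 / rate)
            if t >= duration_ms:
                break
            s = int(rng.choice(k, p=jump_probs[s]))
            times.append(t)
            states.append(s)
        paths.append(
            ChannelPath(
                times=np.array(times), states=np.array(states), duration_ms=duration_ms
            )
        )
    return paths


def _occupancy_open_fraction(model: GatingModel, paths: list[ChannelPath]) -> float:
    """Time-weighted mean number of open channels divided by n_channels."""
    total = 0.0
    for p in paths:
        open_state = (model.conductance[p.states] > 0).astype(float)
        total += float(open_state @ p.sojourn_durations())
    return total / (model.n_channels * paths[0].duration_ms)


def _open_dwells_from_path(model: GatingModel, path: ChannelPath) -> np.ndarray:
    """Maximal open sojourns of one channel, scanning the exact event path."""
    open_flags = model.conductance[path.states] > 0
    durs = path.sojourn_durations()
    dwells = []
    acc = 0.0
    for flag, d in zip(open_flags, durs):
        if flag:
            acc += d
        elif acc > 0:
            dwells.append(acc)
            acc = 0.0
    if acc > 0:
        dwells.append(acc)  # open at trace end
    return np.array(dwells)


def sample_level_path(
    model: GatingModel, paths: list[ChannelPath], dt_ms: float, n_samples: int
) -> np.ndarray:
    """Number of simultaneously open channels at each sample instant k*dt."""
    t = np.arange(n_samples) * dt_ms
    level = np.zeros(n_samples, dtype=np.int16)
    for p in paths:
        idx = np.searchsorted(p.times, t, side="right") - 1
        level += (model.conductance[p.states[idx]] > 0).astype(np.int16)
    return level


@dataclass
class SimulatedTrace:
    """Sampled current trace plus the ground-truth gating manifest."""

    dt_ms: float
    samples: np.ndarray          # pA
    unitary_amplitude: float     # pA
    noise_sd: float              # pA (pre-filter)
    filter_cutoff_khz: float | None
    ground_truth: dict = field(default_factory=dict)

    @property
    def duration_ms(self) -> float:
        return len(self.samples) * self.dt_ms

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self.samples)) * self.dt_ms / 1000.0


def render_trace(
    model: GatingModel,
    paths: list[ChannelPath],
    unitary_amplitude: float = DEFAULT_UNITARY_PA,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    dt_ms: float = DEFAULT_DT_MS,
    filter_cutoff_khz: float | None = DEFAULT_FILTER_KHZ,
    seed: int | np.random.Generator = 0,
) -> SimulatedTrace:
    """Render state paths into a sampled current trace.

    current = unitary_amplitude * (open channels at sample) + white Gaussian
    noise, then Gaussian low-pass with -3 dB at ``filter_cutoff_khz``.
    The manifest records everything needed to score an idealization:
    the sampled ground-truth level path, occupancy NPo/Po, the exact open
    dwell list, amplitude, noise and filter settings.
    """
    if dt_ms <= 0:
        raise ValueError("dt must be positive")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    duration_ms = paths[0].duration_ms
    n = int(round(duration_ms / dt_ms))
    level = sample_level_path(model, paths, dt_ms, n)
    current = unitary_amplitude * level.astype(float)
    if noise_sd > 0:
        current = current + rng.normal(0.0, noise_sd, n)
    applied_cutoff: float | None = filter_cutoff_khz
    if filter_cutoff_khz is not None:
        nyquist_khz = 1.0 / (2.0 * dt_ms)
        if filter_cutoff_khz >= nyquist_khz:
            warnings.warn("filter cutoff at/above Nyquist; filter skipped", stacklevel=2)
            applied_cutoff = None
        else:
            sigma_samples = GAUSSIAN_SIGMA_MS_PER_KHZ / filter_cutoff_khz / dt_ms
            current = gaussian_filter1d(current, sigma_samples, mode="nearest")
    npo_true = _occupancy_open_fraction(model, paths) * model.n_channels
    dwells = np.concatenate(
        [_open_dwells_from_path(model, p) for p in paths]
    ) if paths else np.array([])
    truth = {
        "n_channels": model.n_channels,
        "level_per_sample": level,
        "true_npo": npo_true,
        "true_po": npo_true / model.n_channels,
        "true_mean_open_dwell_ms": float(dwells.mean()) if dwells.size else math.nan,
        "true_open_dwells_ms": dwells,
        "stationary_po": model.stationary_po(),
        "unitary_amplitude": unitary_amplitude,
    }
    return SimulatedTrace(
        dt_ms=dt_ms,
        samples=current,
        unitary_amplitude=unitary_amplitude,
        noise_sd=noise_sd,
        filter_cutoff_khz=applied_cutoff,
        ground_truth=truth,
    )


def simulate_trace(
    model: GatingModel,
    duration_ms: float,
    seed: int,
    unitary_amplitude: float = DEFAULT_UNITARY_PA,
    noise_sd: float = DEFAULT_NOISE_SD_PA,
    dt_ms: float = DEFAULT_DT_MS,
    filter_cutoff_khz: float | None = DEFAULT_FILTER_KHZ,
) -> SimulatedTrace:
    """Convenience wrapper: simulate gating then render, with derived sub-seeds."""
    rng = np.random.default_rng(seed)
    gate_seed, noise_seed = rng.integers(0, 2**31 - 1, size=2)
    paths = simulate_gating(model, duration_ms, int(gate_seed))
    return render_trace(
        model,
        paths,
        unitary_amplitude=unitary_amplitude,
        noise_sd=noise_sd,
        dt_ms=dt_ms,
        filter_cutoff_khz=filter_cutoff_khz,
        seed=int(noise_seed),
    )


# ---------------------------------------------------------------------------
# Condition presets: stationary Po and mean open dwell (ms) per experimental
# condition, magnitudes typical of GH3/GH4 recordings.  These parameterize
# the simulator only; they are simulation fixtures, not analysis targets.
# ---------------------------------------------------------------------------

CONDITION_PRESETS: dict[str, dict[str, float]] = {
    "ATP0": {"po": 0.0152, "dwell_ms": 0.74},
    "ATP1": {"po": 0.0887, "dwell_ms": 2.02},
    "PKA": {"po": 0.1087, "dwell_ms": 1.78},
    "PKG": {"po": 0.0724, "dwell_ms": 1.56},
    "PKCsu": {"po": 0.0443, "dwell_ms": 1.78},
    "PKCin": {"po": 0.0740, "dwell_ms": 1.50},
    "STS": {"po": 0.0468, "dwell_ms": 1.50},
    "OA": {"po": 0.3075, "dwell_ms": 1.70},
}

GATING_PRESETS: dict[str, dict[str, float]] = {
    f"gh3-{name.lower()}": dict(preset) for name, preset in CONDITION_PRESETS.items()
}

_CONDITIONS_NORMALIZED = {k.lower(): v for k, v in CONDITION_PRESETS.items()}


def condition_preset(name: str) -> dict[str, float]:
    """Case-insensitive lookup of a condition preset (Po, mean dwell)."""
    try:
        return _CONDITIONS_NORMALIZED[name.lower()]
    except KeyError:
        raise KeyError(f"unknown condition {name!r}") from None


def gating_preset(name: str, n_channels: int = 2) -> GatingModel:
    """Two-state model with the preset's stationary Po and mean open dwell."""
    key = name.lower()
    if key in GATING_PRESETS:
        preset = GATING_PRESETS[key]
    elif key in _CONDITIONS_NORMALIZED:
        preset = _CONDITIONS_NORMALIZED[key]
    else:
        raise KeyError(f"unknown gating preset {name!r}")
    tau_open = preset["dwell_ms"]
    po = preset["po"]
    tau_closed = tau_open * (1.0 - po) / po
    return GatingModel.two_state(tau_open, tau_closed, n_channels=n_channels)


@dataclass
class ExperimentDesign:
    """Multi-patch paired control/H2S design on the logit-Po scale.

    Each patch draws one random intercept shared by its control and H2S
    rows; the H2S phase adds ``h2s_effect_logit``.  Dwell times are drawn
    lognormal around the condition preset, amplitudes Gaussian.
    """

    cell_line: str = "GH3"
    conditions: tuple[str, ...] = ("ATP1",)
    n_patches: int = 12
    h2s_effect_logit: float = 0.65
    patch_sd: float = 0.55       # random-intercept SD, logit scale
    residual_sd: float = 0.25    # within-patch residual SD, logit scale
    baseline_logit: dict[str, float] | None = None
    dwell_log_sd: float = 0.35
    dwell_h2s_effect_log: float = 0.0
    amplitude_pA: float = DEFAULT_UNITARY_PA
    amplitude_sd: float = 0.3

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise ValueError("n_patches must be >= 1")
        for c in self.conditions:
            if self.baseline_logit is None:
                condition_preset(c)  # raises KeyError for unknown conditions

    def baseline(self, condition: str) -> float:
        if self.baseline_logit is not None:
            return self.baseline_logit[condition]
        return logit(condition_preset(condition)["po"])


def simulate_experiment(design: ExperimentDesign, seed: int) -> pd.DataFrame:
    """Long-format measurement table with paired control/H2S rows per patch.

    Columns: cell_line, patch_id, condition, phase, po, dwell_ms,
    amplitude_pA.  Ground-truth generative parameters are attached in
    ``df.attrs``.  Po values are strictly inside (0, 1) by construction
    (finite logits plus Gaussian noise).
    """
    rng = np.random.default_rng(seed)
    rows = []
    patch_counter = 0
    for cond in design.conditions:
        base = design.baseline(cond)
        try:
            dwell_mu = math.log(condition_preset(cond)["dwell_ms"])
        except KeyError:
            dwell_mu = math.log(1.5)
        for _ in range(design.n_patches):
            patch_counter += 1
            pid = f"{design.cell_line}-{cond}-p{patch_counter:03d}"
            intercept = rng.normal(0.0, design.patch_sd)
            for phase in ("control", "H2S"):
                eta = base + intercept + rng.normal(0.0, design.residual_sd)
                log_dwell = dwell_mu + rng.normal(0.0, design.dwell_log_sd)
                if phase == "H2S":
                    eta += design.h2s_effect_logit
                    log_dwell += design.dwell_h2s_effect_log
                amp = abs(rng.normal(design.amplitude_pA, design.amplitude_sd))
                rows.append(
                    {
                        "cell_line": design.cell_line,
                        "patch_id": pid,
                        "condition": cond,
                        "phase": phase,
                        "po": inverse_logit(eta),
                        "dwell_ms": math.exp(log_dwell),
                        "amplitude_pA": amp,
                    }
                )
    df = pd.DataFrame(rows)
    df.attrs["design"] = {
        "cell_line": design.cell_line,
        "conditions": list(design.conditions),
        "n_patches": design.n_patches,
        "h2s_effect_logit": design.h2s_effect_logit,
        "patch_sd": design.patch_sd,
        "residual_sd": design.residual_sd,
        "seed": int(seed),
    }
    return df
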