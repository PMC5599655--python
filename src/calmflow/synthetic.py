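"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a within-subject two-condition design: every
participant is recorded under AC (air conditioner, with airflow) and RS
(radiant system, without airflow) in one season (cooling or heating).  Per
participant x condition it produces

* a 10-channel EEG recording (8 scalp channels + A1/A2) with session
  annotations.  Signal model per scalp channel and session:
  ``x(t) = pink noise (spectral slope beta) + sum_bands a sin(2 pi f_c t + phi)``
  with one carrier frequency per band and
  ``a = RS mean * participant jitter + AC offset + session noise``.
  A1/A2 carry an attenuated copy of the common noise so re-referencing
  changes values without touching the planted band amplitudes;
* a time-perception task log: six button presses per session, the first
  session tone-guided (presses exactly every 10 s), later sessions with
  random 10-s estimates whose mean is longer under RS by ``ttl_effect/6``;
* environmental series (temperature, humidity, velocity) drawn to match
  configured medians/IQRs;
* first/last thermogram frames: a two-component mixture (skin ellipse over
  background) plus Gaussian noise, with the ground-truth mask kept.

Seeding: one master seed; every (participant, condition, stream) gets a
sub-seed through a fixed counter scheme, so adding participants never
changes existing participants' data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .spectral import ALL_CHANNELS, SCALP_CHANNELS, Recording
from .thermography import ThermogramFrame

CONDITIONS = ("AC", "RS")
_COND_CODE = {"AC": 0, "RS": 1}
_STREAM = {"traits": 0, "eeg": 1, "task": 2, "thermo": 3, "env": 4}

#: per-band (RS mean amplitude uV, additive AC offset uV)
DEFAULT_BAND_EFFECT: dict[str, tuple[float, float]] = {
    "delta": (3.0, 0.0),
    "theta": (2.0, 0.0),
    "alpha": (4.0, 0.0),
    "beta": (1.5, 0.4),
    "gamma": (0.8, 0.3),
}

#: one carrier frequency per band (Hz), chosen on-bin for 0.5 s and 3 s blocks
DEFAULT_CARRIERS: dict[str, float] = {
    "delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 40.0,
}

#: per-season, per-condition (median, IQR) environmental targets
DEFAULT_ENV_TARGETS: dict[str, dict[str, dict[str, tuple[float, float]]]] = {
    "cooling": {
        "AC": {"temperature": (25.0, 1.6), "humidity": (64.0, 1.8),
               "velocity": (1.1, 0.46)},
        "RS": {"temperature": (24.0, 1.0), "humidity": (63.0, 2.8),
               "velocity": (0.0033, 0.22)},
    },
    "heating": {
        "AC": {"temperature": (26.0, 0.28), "humidity": (24.0, 4.0),
               "velocity": (0.61, 0.18)},
        "RS": {"temperature": (26.0, 0.50), "humidity": (24.0, 3.4),
               "velocity": (0.071, 0.053)},
    },
}

#: skin-cluster mean temperature (degC) per season, condition and time point;
#: airflow cools (cooling) or heats (heating) the skin by the end, the
#: radiant condition leaves it unchanged
DEFAULT_SKIN_TEMPERATURE: dict[str, dict[tuple[str, str], float]] = {
    "cooling": {("AC", "first"): 33.0, ("AC", "last"): 31.5,
                ("RS", "first"): 33.0, ("RS", "last"): 33.0},
    "heating": {("AC", "first"): 32.0, ("AC", "last"): 33.5,
                ("RS", "first"): 32.0, ("RS", "last"): 32.0},
}


@dataclass(frozen=True)
class OutlierSpec:
    """One planted perturbation.

    kinds: ``delta_amplitude`` (set the participant's delta-band RS mean to
    ``value`` uV in both conditions), ``ttl_shift`` (add ``value`` seconds
    to the free-counting sessions' total duration, spread over the six
    intervals, both conditions) and ``experimenter_error`` (a pass-through
    hard-error flag; ``value`` ignored).
    """

    participant: int
    kind: str
    value: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("delta_amplitude", "ttl_shift",
                             "experimenter_error"):
            raise ValueError(f"unknown perturbation kind {self.kind!r}")


@dataclass
class SimulationConfig:
    """Generating parameters for one synthetic cohort."""

    n_participants: int = 12
    season: str = "cooling"
    sampling_rate: float = 1000.0          # Hz
    n_sessions: int = 5
    session_length: float = 60.0           # s, guided session exactly this
    session_jitter: float = 0.10           # +-fraction on later sessions
    band_effect: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BAND_EFFECT))
    carrier_freqs: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CARRIERS))
    noise_sigma_uV: float = 2.0            # pink-noise SD per channel
    noise_exponent: float = 1.0            # 1/f^beta slope
    ref_noise_coeff: float = 0.2           # A1/A2 = coeff * common noise
    participant_amp_sigma: float = 0.10    # lognormal sigma, per participant
    session_amp_sigma_uV: float = 0.10     # additive SD per cell amplitude
    env_targets: dict[str, dict[str, tuple[float, float]]] | None = None
    env_n_samples: int = 600
    ttl_effect: float = 6.0                # s added to RS total per session
    ttl_interval_sigma: float = 1.0        # s, SD of one 10-s estimate
    thermo_skin: dict[tuple[str, str], float] | None = None
    thermo_background: float = 25.0        # degC
    thermo_noise_sigma: float = 0.3        # degC, per pixel
    thermo_participant_sigma: float = 0.3  # degC, per participant/time point
    thermo_shape: tuple[int, int] = (40, 30)
    outlier_plan: list[OutlierSpec] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.season not in DEFAULT_ENV_TARGETS:
            raise ValueError(f"unknown season {self.season!r}")
        if self.env_targets is None:
            self.env_targets = {c: dict(v) for c, v in
                                DEFAULT_ENV_TARGETS[self.season].items()}
        if self.thermo_skin is None:
            self.thermo_skin = dict(DEFAULT_SKIN_TEMPERATURE[self.season])
        self.validate()

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if self.n_sessions < 2:
            raise ValueError("n_sessions must be >= 2")
        top_edge = 55.0
        if self.sampling_rate <= 2 * top_edge:
            raise ValueError("sampling_rate must exceed twice the top band "
                             f"edge ({2 * top_edge} Hz)")
        for name, (mean, offset) in self.band_effect.items():
            if not (math.isfinite(mean) and math.isfinite(offset)):
                raise ValueError(f"non-finite band effect for {name!r}")
            if mean < 0 or offset < 0:
                raise ValueError(f"band effect for {name!r} must be >= 0")
            if name not in self.carrier_freqs:
                raise ValueError(f"no carrier frequency for band {name!r}")
        for scalar in (self.noise_sigma_uV, self.session_length,
                       self.ttl_interval_sigma, self.thermo_noise_sigma,
                       self.thermo_participant_sigma,
                       self.participant_amp_sigma, self.session_amp_sigma_uV):
            if not math.isfinite(scalar) or scalar < 0:
                raise ValueError("config scalars must be finite and >= 0")
        if not math.isfinite(self.ttl_effect):
            raise ValueError("ttl_effect must be finite")
        for cond in CONDITIONS:
            if cond not in self.env_targets:
                raise ValueError(f"env_targets missing condition {cond!r}")
            for var, (med, iqr) in self.env_targets[cond].items():
                if not (math.isfinite(med) and math.isfinite(iqr)):
                    raise ValueError(f"non-finite env target {var!r}")
                if var == "velocity" and med < 0:
                    raise ValueError("velocity median must be >= 0")
                if iqr < 0:
                    raise ValueError("IQR must be >= 0")
        for spec in self.outlier_plan:
            if not 1 <= spec.participant <= self.n_participants:
                raise ValueError(f"outlier plan references unknown "
                                 f"participant {spec.participant}")

    @property
    def participants(self) -> list[int]:
        return list(range(1, self.n_participants + 1))


@dataclass
class TaskLog:
    """Button-press timestamps per session; TTL is the last press time."""

    participant: int
    condition: str
    presses: dict[int, np.ndarray]

    def ttl(self, session: int) -> float:
        return float(self.presses[session][-1])

    @property
    def sessions(self) -> list[int]:
        return sorted(self.presses)


@dataclass
class SyntheticCohort:
    config: SimulationConfig
    recordings: dict[tuple[int, str], Recording]
    environment: dict[str, pd.DataFrame]
    task_logs: dict[tuple[int, str], TaskLog]
    thermograms: dict[tuple[int, str, str], ThermogramFrame]
    thermogram_masks: dict[tuple[int, str, str], np.ndarray]
    truth: dict[str, Any]

    def ttl_table(self) -> pd.DataFrame:
        """Tidy TTLs with their differential from the guided first session."""
        rows = []
        for (pid, cond), log in self.task_logs.items():
            base = log.ttl(1)
            for s in log.sessions:
                rows.append((pid, cond, s, log.ttl(s), log.ttl(s) - base))
        return pd.DataFrame(rows, columns=["participant", "condition",
                                           "session", "ttl_s",
                                           "ttl_differential_s"])


def _rng(config: SimulationConfig, participant: int, condition: str,
         stream: str, seed: int | None = None) -> np.random.Generator:
    base = config.seed if seed is None else seed
    key = (int(base), int(participant), _COND_CODE.get(condition, 9),
           _STREAM[stream])
    return np.random.default_rng(np.random.SeedSequence(key))


def pink_noise(rng: np.random.Generator, n: int, exponent: float,
               sigma: float) -> np.ndarray:
    """Gaussian 1/f^exponent noise of length n, standardised to SD sigma."""
    if sigma == 0 or n < 2:
        return np.zeros(n)
    n_freq = n // 2 + 1
    freqs = np.arange(n_freq, dtype=float)
    shape = np.zeros(n_freq)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spec = (rng.standard_normal(n_freq) + 1j * rng.standard_normal(n_freq))
    spec *= shape
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x * (sigma / sd) if sd > 0 else x


def _participant_band_jitter(config: SimulationConfig, participant: int,
                             seed: int | None) -> dict[str, float]:
    """Per-participant lognormal amplitude factor, shared by both
    conditions so planted AC-RS offsets survive exactly."""
    rng = _rng(config, participant, "AC", "traits", seed)  # condition-free
    bands = sorted(config.band_effect)
    draws = rng.standard_normal(len(bands))
    s = config.participant_amp_sigma
    return {b: float(np.exp(s * z - 0.5 * s * s)) for b, z in
            zip(bands, draws)}


def _planted_band_effect(config: SimulationConfig,
                         participant: int) -> dict[str, tuple[float, float]]:
    eff = dict(config.band_effect)
    for spec in config.outlier_plan:
        if spec.participant == participant and spec.kind == "delta_amplitude":
            _, off = eff.get("delta", (0.0, 0.0))
            eff["delta"] = (float(spec.value), off)
    return eff


def generate_eeg_recording(participant: int, condition: str,
                           config: SimulationConfig,
                           seed: int | None = None) -> Recording:
    """One session-annotated 10-channel recording; deterministic given
    (participant, condition, seed)."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config.validate()
    rng = _rng(config, participant, condition, "eeg", seed)
    fs = config.sampling_rate
    jitter = _participant_band_jitter(config, participant, seed)
    effect = _planted_band_effect(config, participant)
    bands = sorted(effect)

    # session lengths: guided first session exact, later ones jittered
    lengths = [config.session_length]
    for _ in range(config.n_sessions - 1):
        lengths.append(config.session_length
                       * (1.0 + config.session_jitter
                          * (2.0 * rng.random() - 1.0)))
    n_scalp = len(SCALP_CHANNELS)
    chunks, spans, t0 = [], [], 0.0
    true_amplitudes: dict[tuple[int, str], float] = {}
    for s_idx, length in enumerate(lengths, start=1):
        n = int(round(length * fs))
        t = np.arange(n) / fs
        common = pink_noise(rng, n, config.noise_exponent,
                            config.noise_sigma_uV)
        scalp = np.tile(common, (n_scalp, 1))
        for band in bands:
            rs_mean, offset = effect[band]
            amp = rs_mean * jitter[band] + (offset if condition == "AC"
                                            else 0.0)
            amp += config.session_amp_sigma_uV * rng.standard_normal()
            amp = max(amp, 0.0)
            true_amplitudes[(s_idx, band)] = amp
            phases = rng.uniform(0.0, 2.0 * np.pi, size=n_scalp)
            f_c = config.carrier_freqs[band]
            scalp += amp * np.sin(2.0 * np.pi * f_c * t[None, :]
                                  + phases[:, None])
        ref = config.ref_noise_coeff * common
        chunks.append(np.vstack([scalp, ref, ref]))
        spans.append((s_idx, t0, t0 + n / fs))
        t0 += n / fs
    samples = np.concatenate(chunks, axis=1)
    return Recording(samples=samples, sampling_rate=fs,
                     channel_labels=ALL_CHANNELS, session_spans=spans,
                     participant=participant, condition=condition,
                     meta={"true_amplitudes": true_amplitudes,
                           "season": config.season})


def generate_environment(condition: str, config: SimulationConfig,
                         seed: int | None = None) -> pd.DataFrame:
    """Time-stamped environmental series matching the configured targets.

    Temperature and humidity are normal (sigma = IQR / 1.349); velocity is
    lognormal parameterised so its median and IQR converge to the targets
    while staying non-negative.  Zero IQR gives a constant series.
    """
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    targets = config.env_targets.get(condition)
    if not targets:
        raise ValueError(f"no environmental targets for {condition!r}")
    rng = _rng(config, 0, condition, "env", seed)
    n = config.env_n_samples
    out = {"timestamp_s": np.arange(n, dtype=float)}
    z75 = 0.6744897501960817  # standard normal 75th percentile
    for var, (med, iqr) in targets.items():
        if iqr == 0:
            vals = np.full(n, med)
        elif var == "velocity":
            if med <= 0:
                raise ValueError("lognormal velocity needs median > 0")
            sigma = math.asinh(iqr / (2.0 * med)) / z75
            vals = med * np.exp(sigma * rng.standard_normal(n))
        else:
            vals = med + (iqr / (2.0 * z75)) * rng.standard_normal(n)
            if var == "humidity":
                vals = np.clip(vals, 0.0, 100.0)
        out[var] = vals
    df = pd.DataFrame(out)
    df.attrs["condition"] = condition
    df.attrs["season"] = config.season
    return df


def generate_task_log(participant: int, condition: str,
                      config: SimulationConfig,
                      seed: int | None = None) -> TaskLog:
    """Six press timestamps per session; session 1 tone-guided (exact 10-s
    intervals), later sessions drawn around 10 s + ttl_effect/6 under RS."""
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    config.validate()
    rng = _rng(config, participant, condition, "task", seed)
    shift_total = sum(spec.value for spec in config.outlier_plan
                      if spec.participant == participant
                      and spec.kind == "ttl_shift")
    n_press = 6
    mean_interval = 10.0 + (config.ttl_effect / n_press
                            if condition == "RS" else 0.0)
    mean_interval += shift_total / n_press
    presses: dict[int, np.ndarray] = {
        1: 10.0 * np.arange(1, n_press + 1)}
    for s in range(2, config.n_sessions + 1):
        intervals = mean_interval + config.ttl_interval_sigma \
            * rng.standard_normal(n_press)
        intervals = np.clip(intervals, 0.25, None)
        presses[s] = np.cumsum(intervals)
    return TaskLog(participant=participant, condition=condition,
                   presses=presses)


def generate_thermogram(participant: int, condition: str, when: str,
                        config: SimulationConfig, seed: int | None = None
                        ) -> tuple[ThermogramFrame, np.ndarray]:
    """One two-component thermogram frame and its ground-truth skin mask."""
    if when not in ("first", "last"):
        raise ValueError(f"when must be 'first' or 'last', got {when!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    t_skin = config.thermo_skin[(condition, when)]
    t_bg = config.thermo_background
    if t_skin == t_bg:
        warnings.warn("skin and background temperatures equal; "
                      "clustering is unidentifiable", stacklevel=2)
    rng = _rng(config, participant, condition, "thermo", seed)
    rows, cols = config.thermo_shape
    r = (np.arange(rows)[:, None] - (rows - 1) / 2.0) / (rows / 2.0)
    c = (np.arange(cols)[None, :] - (cols - 1) / 2.0) / (cols / 2.0)
    mask = (r / 0.7) ** 2 + (c / 0.6) ** 2 <= 1.0  # centred skin ellipse
    # physiological between-participant spread of the skin mean, drawn per
    # time point so paired first-last differences are not noise-free
    offsets = config.thermo_participant_sigma * rng.standard_normal(2)
    offset = offsets[0] if when == "first" else offsets[1]
    frame = np.where(mask, t_skin + offset, t_bg).astype(float)
    noise_first = config.thermo_noise_sigma * rng.standard_normal(
        (rows, cols))
    noise_last = config.thermo_noise_sigma * rng.standard_normal((rows, cols))
    frame = frame + (noise_first if when == "first" else noise_last)
    return (ThermogramFrame(temperatures=frame, participant=participant,
                            condition=condition, when=when), mask)


def generate_cohort(config: SimulationConfig,
                    seed: int | None = None) -> SyntheticCohort:
    """Assemble the full synthetic cohort and its ground truth."""
    config.validate()
    recordings, task_logs, thermos, masks = {}, {}, {}, {}
    for pid in config.participants:
        for cond in CONDITIONS:
            recordings[(pid, cond)] = generate_eeg_recording(
                pid, cond, config, seed)
            task_logs[(pid, cond)] = generate_task_log(pid, cond, config,
                                                       seed)
            for when in ("first", "last"):
                frame, mask = generate_thermogram(pid, cond, when, config,
                                                  seed)
                thermos[(pid, cond, when)] = frame
                masks[(pid, cond, when)] = mask
    environment = {cond: generate_environment(cond, config, seed)
                   for cond in CONDITIONS}
    truth = {
        "band_effect": dict(config.band_effect),
        "ttl_effect": config.ttl_effect,
        "outlier_plan": [vars(s) for s in config.outlier_plan],
        "experimenter_errors": [s.participant for s in config.outlier_plan
                                if s.kind == "experimenter_error"],
        "thermo_skin": {f"{cond}:{when}": v for (cond, when), v
                        in config.thermo_skin.items()},
        "true_amplitudes": {f"{pid}:{cond}":
                            {f"{s}:{b}": a for (s, b), a in
                             recordings[(pid, cond)]
                             .meta["true_amplitudes"].items()}
                            for (pid, cond) in recordings},
    }
    return SyntheticCohort(config=config, recordings=recordings,
                           environment=environment, task_logs=task_logs,
                           thermograms=thermos, thermogram_masks=masks,
                           truth=truth)
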