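"""Synthetic home-monitoring cohort generator.

Generates statistically structured stand-ins for overnight wearable
recordings: stage-structured hypnograms from a Markov chain with sleep-cycle
modulation, ECG with stage-dependent heart rate / heart-rate variability and
respiratory sinus arrhythmia, three-axis chest accelerometry combining a
posture-dependent gravity vector with respiratory chest-wall displacement
along a body-fixed axis plus wake-time motion bursts, and cohort-level
longitudinal structure (baseline night B1, intervention nights I1-I7 with
restricted time in bed, follow-up F1).

Everything is deterministic under the seeds carried by the parameter
objects. Defaults live in ``defaults.yaml`` next to this module.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import yaml
from scipy import signal as sps

from .types import (
    CLASS_STAGES,
    EPOCH_SEC,
    EPOCHS_PER_HOUR,
    AccelTrace,
    Hypnogram,
    NightRecord,
    Stage,
)

__all__ = [
    "HypnogramParams",
    "PhysioParams",
    "CohortPlan",
    "load_defaults",
    "default_hypnogram_params",
    "default_physio_params",
    "default_cohort_plan",
    "transition_from_stationary",
    "stationary_distribution",
    "generate_hypnogram",
    "generate_night",
    "generate_cohort",
]

SAMPLE_RATE = 125.0  # Hz, both ECG and accelerometry

# Device-frame gravity directions for the four canonical lying postures.
# z is the anterior chest normal, so supine/prone put gravity along +/-z
# (parallel to the default respiratory axis) and the lateral postures put it
# along +/-y.
_POSTURE_GRAVITY = {
    "supine": np.array([0.0, 0.0, 1.0]),
    "left_lateral": np.array([0.0, 1.0, 0.0]),
    "right_lateral": np.array([0.0, -1.0, 0.0]),
    "prone": np.array([0.0, 0.0, -1.0]),
}


class ParameterError(ValueError):
    """Raised when generator parameters violate their invariants."""


def load_defaults() -> dict:
    """Load the editable default-parameter file shipped with the package."""
    text = resources.files("cardiosleep").joinpath("defaults.yaml").read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# Parameter objects
# ---------------------------------------------------------------------------


@dataclass
class HypnogramParams:
    """Parameters of the stage-sequence model.

    The chain runs on the 30-s epoch grid over the four scoring classes
    (WAKE, N1N2, N3, REM). ``transition`` is row-stochastic in the class
    order of :data:`cardiosleep.types.CLASS_STAGES`. ``n3_front_loading``
    exponentially decays the probability of *entering* N3 with each
    successive sleep cycle, emulating the front-loading of slow-wave sleep;
    ``mean_cycle_min`` sets the cycle clock and the within-cycle REM
    modulation (REM entry is suppressed early in a cycle and favoured late,
    with unit mean so the long-run stage mix is preserved).
    """

    transition: np.ndarray
    mean_cycle_min: float = 90.0
    sol_min: float = 16.7
    n3_front_loading: float = 0.05
    seed: int = 0
    initial_stage: Stage | None = None
    # Present when the matrix was built from a stationary mix; used by
    # generate_cohort to inject longitudinal %N3 trends.
    stationary: np.ndarray | None = None
    switching_rate: float | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        if self.transition.shape != (4, 4):
            raise ParameterError("transition matrix must be 4x4")
        if np.any(self.transition < -1e-12) or np.any(self.transition > 1 + 1e-12):
            raise ParameterError("transition probabilities must lie in [0, 1]")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ParameterError("transition matrix rows must sum to 1")
        if self.mean_cycle_min <= 0:
            raise ParameterError("mean_cycle_min must be positive")
        if self.n3_front_loading < 0:
            raise ParameterError("n3_front_loading must be >= 0")


@dataclass
class PhysioParams:
    """Stage-dependent cardiorespiratory and movement parameters.

    Rates are in beats/min or breaths/min keyed by the four scoring classes;
    ``resp_axis`` is the body-fixed unit vector of respiratory chest-wall
    displacement in the device frame.
    """

    hr_by_stage: dict[Stage, float]
    hrv_sd_by_stage: dict[Stage, float]  # ms
    resp_rate_by_stage: dict[Stage, float]
    resp_irregularity_by_stage: dict[Stage, float]
    resp_axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    resp_amplitude_g: float = 0.01
    posture_change_rate: float = 1.5  # events/hour
    wake_motion_burst_rate: float = 30.0  # events/hour of wake
    rsa_amp_sec: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        self.resp_axis = np.asarray(self.resp_axis, dtype=float)
        n = np.linalg.norm(self.resp_axis)
        if abs(n - 1.0) > 1e-9:
            if n == 0:
                raise ParameterError("resp_axis must be a unit vector")
            self.resp_axis = self.resp_axis / n
        for d in (self.hr_by_stage, self.hrv_sd_by_stage, self.resp_rate_by_stage):
            for s in CLASS_STAGES:
                if d[s] < 0:
                    raise ParameterError("stage-dependent rates must be >= 0")
        if self.posture_change_rate < 0 or self.wake_motion_burst_rate < 0:
            raise ParameterError("event rates must be >= 0")


@dataclass
class CohortPlan:
    """Longitudinal cohort layout: who is recorded, when, and how restricted.

    ``srt_tib_restriction_min`` minutes are removed from time in bed on the
    first intervention night I1, relaxing linearly to zero at follow-up F1.
    ``n3_trend_per_night`` drifts the generated %N3 (share of sleep) by that
    many percentage points per successive intervention night.
    """

    n_participants: int = 13
    night_labels: tuple[str, ...] = (
        "B1", "I1", "I2", "I3", "I4", "I5", "I6", "I7", "F1",
    )
    baseline_tib_min: float = 461.0
    tib_between_sd_min: float = 25.0
    tib_within_sd_min: float = 8.0
    srt_tib_restriction_min: float = 120.0
    n3_trend_per_night: float = -1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 3:
            raise ParameterError("need at least 3 participants")
        if len(set(self.night_labels)) != len(self.night_labels):
            raise ParameterError("night labels must be unique per participant")


# ---------------------------------------------------------------------------
# Transition-matrix construction
# ---------------------------------------------------------------------------


def transition_from_stationary(pi: np.ndarray, switching_rate: float) -> np.ndarray:
    """Build a 4x4 row-stochastic matrix with stationary distribution ``pi``.

    Uses a constant switching rate ``r``: off-diagonals ``P[i, j] = r*pi[j]``
    and diagonals ``1 - r*(1 - pi[i])``, which leaves ``pi`` stationary for
    any ``r`` and gives mean bout lengths ``1 / (r*(1 - pi[i]))`` epochs.
    """
    pi = np.asarray(pi, dtype=float)
    if pi.shape != (4,) or np.any(pi < 0):
        raise ParameterError("stationary distribution must be 4 non-negative values")
    pi = pi / pi.sum()
    r = float(switching_rate)
    if not 0 < r <= 1:
        raise ParameterError("switching_rate must be in (0, 1]")
    P = r * np.tile(pi, (4, 1))
    np.fill_diagonal(P, 1.0 - r * (1.0 - pi))
    if np.any(P < 0):
        raise ParameterError("switching_rate too large for this stationary mix")
    return P


def stationary_distribution(P: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix by eigen-decomposition."""
    w, v = np.linalg.eig(P.T)
    k = int(np.argmin(np.abs(w - 1.0)))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


def _params_from_defaults(d: dict, seed: int) -> "HypnogramParams":
    h = d["hypnogram"]
    pi = np.array([h["stationary"][s.name] for s in CLASS_STAGES])
    return HypnogramParams(
        transition=transition_from_stationary(pi, h["switching_rate"]),
        mean_cycle_min=h["mean_cycle_min"],
        sol_min=h["sol_min"],
        n3_front_loading=h["n3_front_loading"],
        seed=seed,
        stationary=pi / pi.sum(),
        switching_rate=h["switching_rate"],
    )


def default_hypnogram_params(seed: int = 0) -> HypnogramParams:
    return _params_from_defaults(load_defaults(), seed)


def default_physio_params(seed: int = 0) -> PhysioParams:
    p = load_defaults()["physio"]

    def by_stage(key: str) -> dict[Stage, float]:
        return {s: float(p[key][s.name]) for s in CLASS_STAGES}

    return PhysioParams(
        hr_by_stage=by_stage("hr_by_stage"),
        hrv_sd_by_stage=by_stage("hrv_sd_by_stage"),
        resp_rate_by_stage=by_stage("resp_rate_by_stage"),
        resp_irregularity_by_stage=by_stage("resp_irregularity_by_stage"),
        resp_axis=np.array(p["resp_axis"], dtype=float),
        resp_amplitude_g=float(p["resp_amplitude_g"]),
        posture_change_rate=float(p["posture_change_rate"]),
        wake_motion_burst_rate=float(p["wake_motion_burst_rate"]),
        rsa_amp_sec=float(p["rsa_amp_sec"]),
        seed=seed,
    )


def default_cohort_plan(seed: int = 0) -> CohortPlan:
    c = load_defaults()["cohort"]
    return CohortPlan(
        n_participants=int(c["n_participants"]),
        baseline_tib_min=float(c["baseline_tib_min"]),
        tib_between_sd_min=float(c["tib_between_sd_min"]),
        tib_within_sd_min=float(c["tib_within_sd_min"]),
        srt_tib_restriction_min=float(c["srt_tib_restriction_min"]),
        n3_trend_per_night=float(c["n3_trend_per_night"]),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Hypnogram generation
# ---------------------------------------------------------------------------


def _simulate_stages(
    params: HypnogramParams, n_epochs: int, rng: np.random.Generator
) -> np.ndarray:
    """One realisation of the stage chain (without the REM-bout guarantee)."""
    stages = np.empty(n_epochs, dtype=np.int64)
    cycle_epochs = params.mean_cycle_min * 60.0 / EPOCH_SEC

    if params.initial_stage is None:
        # Initial wake run: geometric sleep-onset latency with mean sol_min.
        mean_epochs = max(params.sol_min * 60.0 / EPOCH_SEC, 1.0)
        sol = int(rng.geometric(1.0 / mean_epochs))
        sol = min(sol, n_epochs)
        stages[:sol] = Stage.WAKE
        cur = int(Stage.N1N2)
        start = sol
    else:
        cur = int(params.initial_stage)
        start = 0
    if start >= n_epochs:
        return stages

    onset = start
    stages[start] = cur
    for k in range(start + 1, n_epochs):
        row = params.transition[cur].copy()
        t_since_onset = k - onset
        cycle_idx = int(t_since_onset // cycle_epochs)
        phase = (t_since_onset % cycle_epochs) / cycle_epochs
        if cur != int(Stage.N3):
            # front-load N3: entry probability decays across cycles
            row[Stage.N3] *= math.exp(-params.n3_front_loading * cycle_idx)
        if cur != int(Stage.REM):
            # REM favoured late in the cycle; factor has unit mean over phase
            row[Stage.REM] *= 0.25 + 1.5 * phase
        row /= row.sum()
        cur = int(rng.choice(4, p=row))
        stages[k] = cur
    return stages


def generate_hypnogram(params: HypnogramParams, duration_hr: float) -> Hypnogram:
    """Generate one night's stage sequence on the 30-s epoch grid.

    Returns ``ceil(duration_hr * 120)`` epochs. The night begins with a wake
    run whose expected length equals ``params.sol_min`` (unless an explicit
    ``initial_stage`` is set), then follows the transition chain with
    sleep-cycle modulation. For nights of three hours or more, realisations
    with no REM bout (a few percent of draws under the default chain) are
    redrawn so every returned hypnogram contains REM sleep.
    """
    if not 0 < duration_hr <= 10:
        raise ParameterError("duration_hr must be in (0, 10]")
    n_epochs = math.ceil(duration_hr * EPOCHS_PER_HOUR)
    rng = np.random.default_rng(params.seed)
    stages = _simulate_stages(params, n_epochs, rng)
    if duration_hr >= 3 and params.initial_stage is None:
        tries = 0
        while not np.any(stages == Stage.REM) and tries < 50:
            stages = _simulate_stages(params, n_epochs, rng)
            tries += 1
    return Hypnogram(stages)


# ---------------------------------------------------------------------------
# Waveform generation
# ---------------------------------------------------------------------------


def _per_sample(values_by_stage: dict[Stage, float], stages: np.ndarray,
                spe: int) -> np.ndarray:
    lut = np.zeros(6)
    for s, v in values_by_stage.items():
        lut[int(s)] = v
    return np.repeat(lut[stages], spe)


def _smooth(x: np.ndarray, fs: float, cutoff_hz: float) -> np.ndarray:
    b, a = sps.butter(2, cutoff_hz / (fs / 2), btype="low")
    return sps.filtfilt(b, a, x)


def _respiration_phase(
    hyp_stages: np.ndarray, phys: PhysioParams, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Instantaneous respiratory phase (radians) per sample."""
    spe = int(round(EPOCH_SEC * fs))
    n = hyp_stages.size * spe
    rate_hz = _per_sample(
        {s: phys.resp_rate_by_stage[s] / 60.0 for s in CLASS_STAGES},
        hyp_stages, spe,
    )
    irr = _per_sample(phys.resp_irregularity_by_stage, hyp_stages, spe)
    # slowly varying fractional rate jitter (~0.05 Hz bandwidth)
    jitter = _smooth(rng.standard_normal(n), fs, 0.05)
    sd = jitter.std()
    if sd > 0:
        jitter /= sd
    rate_hz = rate_hz * (1.0 + irr * jitter)
    rate_hz = _smooth(rate_hz, fs, 0.1)  # soften stage-boundary steps
    rate_hz = np.clip(rate_hz, 0.05, 1.0)
    return 2.0 * np.pi * np.cumsum(rate_hz) / fs


def _gravity_series(
    n: int, fs: float, phys: PhysioParams, rng: np.random.Generator
) -> tuple[np.ndarray, list[int]]:
    """Piecewise-constant unit gravity vector with smooth posture changes.

    Returns the (n, 3) gravity series and the sample indices of posture
    events (used to co-locate movement bursts).
    """
    names = list(_POSTURE_GRAVITY)

    def draw_orientation() -> np.ndarray:
        g = _POSTURE_GRAVITY[names[int(rng.integers(len(names)))]].copy()
        tilt = rng.normal(0.0, 0.08, size=3)  # ~5 degree random tilt
        g = g + tilt
        return g / np.linalg.norm(g)

    g = np.empty((n, 3))
    events: list[int] = []
    cur = draw_orientation()
    i = 0
    rate = phys.posture_change_rate
    while i < n:
        if rate <= 0:
            g[i:] = cur
            break
        hold_sec = rng.exponential(3600.0 / rate)
        j = min(n, i + int(hold_sec * fs))
        g[i:j] = cur
        if j >= n:
            break
        events.append(j)
        nxt = draw_orientation()
        # 3-second smooth rotation between orientations
        m = min(n - j, int(3.0 * fs))
        w = np.linspace(0.0, 1.0, m)[:, None]
        seg = (1 - w) * cur + w * nxt
        seg /= np.linalg.norm(seg, axis=1, keepdims=True)
        g[j:j + m] = seg
        i = j + m
        cur = nxt
    return g, events


def _beat_times(
    hyp_stages: np.ndarray, phys: PhysioParams, resp_phase: np.ndarray,
    fs: float, rng: np.random.Generator,
) -> np.ndarray:
    """R-peak times (seconds): stage-dependent mean RR and SD plus RSA."""
    duration = hyp_stages.size * EPOCH_SEC
    times = []
    t = float(rng.uniform(0.0, 0.5))
    while t < duration:
        stage = Stage(hyp_stages[min(int(t // EPOCH_SEC), hyp_stages.size - 1)])
        if not stage.is_scored:
            stage = Stage.WAKE
        mean_rr = 60.0 / phys.hr_by_stage[stage]
        sd_rr = phys.hrv_sd_by_stage[stage] / 1000.0
        idx = min(int(t * fs), resp_phase.size - 1)
        rr = (
            mean_rr
            + rng.normal(0.0, sd_rr)
            + phys.rsa_amp_sec * math.sin(resp_phase[idx])
        )
        rr = min(max(rr, 0.3), 2.0)
        times.append(t)
        t += rr
    return np.asarray(times)


def _ecg_waveform(
    beat_times: np.ndarray, n: int, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Template-based ECG: Gaussian R wave plus a low T wave at each beat."""
    ecg = np.zeros(n)
    tt = np.arange(-0.05, 0.35, 1.0 / fs)
    template = np.exp(-0.5 * (tt / 0.012) ** 2) + 0.2 * np.exp(
        -0.5 * ((tt - 0.25) / 0.05) ** 2
    )
    half = int(round(0.05 * fs))
    for bt in beat_times:
        i0 = int(round(bt * fs)) - half
        j0, j1 = max(i0, 0), min(i0 + template.size, n)
        if j1 > j0:
            ecg[j0:j1] += template[j0 - i0 : j1 - i0]
    # measurement noise and a little baseline wander
    ecg += 0.02 * rng.standard_normal(n)
    t = np.arange(n) / fs
    ecg += 0.05 * np.sin(2 * np.pi * 0.05 * t + rng.uniform(0, 2 * np.pi))
    return ecg


def generate_night(hyp: Hypnogram, phys: PhysioParams) -> NightRecord:
    """Generate aligned ECG and accelerometry at 125 Hz for one hypnogram.

    The accelerometer is a slowly varying unit gravity vector (posture) plus
    sinusoid-like respiratory displacement along ``phys.resp_axis``, wake-time
    motion bursts, and sensor noise. The ECG carries stage information through
    its inter-beat intervals (stage mean and SD plus respiratory sinus
    arrhythmia), not through beat morphology.
    """
    if len(hyp) == 0:
        raise ParameterError("hypnogram must be non-empty")
    fs = SAMPLE_RATE
    spe = int(round(EPOCH_SEC * fs))
    n = len(hyp) * spe
    rng = np.random.default_rng(phys.seed)

    resp_phase = _respiration_phase(hyp.stages, phys, fs, rng)
    resp_disp = phys.resp_amplitude_g * np.sin(resp_phase)

    gravity, posture_events = _gravity_series(n, fs, phys, rng)
    acc = gravity + resp_disp[:, None] * phys.resp_axis[None, :]

    # wake-time motion bursts (band-limited noise on all axes)
    wake_samples = np.repeat(hyp.stages == Stage.WAKE, spe)
    wake_idx = np.flatnonzero(wake_samples)
    if wake_idx.size and phys.wake_motion_burst_rate > 0:
        wake_hours = wake_idx.size / fs / 3600.0
        n_bursts = rng.poisson(phys.wake_motion_burst_rate * wake_hours)
        b, a = sps.butter(2, [1.0 / (fs / 2), 8.0 / (fs / 2)], btype="band")
        starts = list(rng.choice(wake_idx, size=n_bursts)) if n_bursts else []
        for i0 in starts + posture_events:
            dur = int(rng.uniform(0.5, 2.0) * fs)
            j1 = min(int(i0) + dur, n)
            burst = sps.lfilter(b, a, rng.standard_normal((j1 - int(i0), 3)), axis=0)
            acc[int(i0):j1] += 0.2 * burst
    acc += 0.002 * rng.standard_normal((n, 3))

    beat_times = _beat_times(hyp.stages, phys, resp_phase, fs, rng)
    ecg = _ecg_waveform(beat_times, n, fs, rng)
    if wake_idx.size:
        ecg[wake_samples] += 0.03 * rng.standard_normal(wake_idx.size)

    return NightRecord(
        participant_id="",
        night_label="B1",
        ecg=ecg,
        ecg_rate=fs,
        accel=AccelTrace(acc, rate=fs),
        hypnogram=hyp,
    )


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------


def _night_position(label: str) -> int:
    """Position of a night within the protocol: B1 -> 0, Ik -> k, F1 -> 8."""
    if label == "B1":
        return 0
    if label == "F1":
        return 8
    return int(label[1:])


def _shift_n3(params: HypnogramParams, delta_pp: float) -> HypnogramParams:
    """Shift the chain's %N3 share of sleep by ``delta_pp`` percentage points."""
    if params.stationary is None or params.switching_rate is None:
        raise ParameterError(
            "n3 trend injection needs params built from a stationary mix "
            "(see transition_from_stationary)"
        )
    pi = params.stationary.copy()
    sleep = pi[1:].sum()
    shares = pi[1:] / sleep
    n3 = np.clip(shares[1] + delta_pp / 100.0, 0.02, 0.9)
    other = 1.0 - n3
    scale = other / (shares[0] + shares[2])
    shares = np.array([shares[0] * scale, n3, shares[2] * scale])
    pi = np.concatenate([[pi[0]], shares * sleep])
    return replace(
        params,
        transition=transition_from_stationary(pi, params.switching_rate),
        stationary=pi,
    )


def generate_cohort(
    plan: CohortPlan,
    hparams: HypnogramParams,
    phys: PhysioParams,
    with_waveforms: bool = False,
) -> list[NightRecord]:
    """Generate a longitudinal cohort of participant-nights.

    Per participant, time in bed is reduced by ``plan.srt_tib_restriction_min``
    on I1 relative to B1 and relaxes linearly back to the baseline at F1;
    the chain's %N3 share of sleep drifts by ``plan.n3_trend_per_night``
    percentage points per successive intervention night. With
    ``with_waveforms=False`` (the default) only hypnograms are generated,
    which is sufficient for sleep-architecture analyses and keeps large
    cohorts cheap; pass ``True`` to synthesise the full 125 Hz waveforms.
    """
    ss = np.random.SeedSequence(plan.seed)
    records: list[NightRecord] = []
    for p in range(plan.n_participants):
        pid = f"P{p + 1:02d}"
        p_rng = np.random.default_rng(ss.spawn(1)[0])
        base_tib = plan.baseline_tib_min + p_rng.normal(0, plan.tib_between_sd_min)
        base_tib = float(np.clip(base_tib, 240.0, 590.0))
        for label in plan.night_labels:
            pos = _night_position(label)
            if pos == 0:
                restriction = 0.0
            else:
                restriction = plan.srt_tib_restriction_min * (8 - pos) / 7.0
            tib = base_tib - restriction + p_rng.normal(0, plan.tib_within_sd_min)
            tib = float(np.clip(tib, 120.0, 600.0))

            delta_pp = plan.n3_trend_per_night * max(pos - 1, 0)
            night_h = _shift_n3(hparams, delta_pp) if delta_pp else hparams
            seed_pair = ss.spawn(1)[0].generate_state(2)
            night_h = replace(night_h, seed=int(seed_pair[0] % (2**31)))
            hyp = generate_hypnogram(night_h, tib / 60.0)
            if with_waveforms:
                night_phys = replace(phys, seed=int(seed_pair[1] % (2**31)))
                rec = generate_night(hyp, night_phys)
                rec.participant_id, rec.night_label = pid, label
            else:
                rec = NightRecord(
                    participant_id=pid,
                    night_label=label,
                    ecg=None,
                    accel=None,
                    hypnogram=hyp,
                )
            records.append(rec)
    return records
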