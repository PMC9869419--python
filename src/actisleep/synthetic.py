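"""Synthetic wrist-device records with sleep-stage-dependent structure.

Generates, per subject, a hypnogram (first-order Markov chain over the five
AASM stages W/R/S1/S2/S3 at 30-s epochs) and a 24 Hz multichannel record:
tri-axial acceleration with stage-dependent movement bursts, PPG green/IR
count baselines, and a sparse RR channel (interval in ms at beat samples,
zero elsewhere — zero encodes "no beat").

The default stage profile encodes the physiology the downstream features
rely on: heart rate falls and variability shrinks with sleep depth, movement
is frequent in wake and nearly absent in N3, and PPG baselines separate wake
from sleep but overlap between sleep stages (a slow optical drift dominates
the small between-stage differences).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

SAMPLE_RATE_HZ = 24
EPOCH_S = 30
STAGES = ("W", "R", "S1", "S2", "S3")

RECORD_COLUMNS = ["t", "ax", "ay", "az", "green", "ir", "rr"]

# minimum physiological NN interval; the truncated-normal floor for beats
MIN_NN_MS = 300.0

ACCEL_NOISE_G = 0.003


@dataclass(frozen=True)
class StageParams:
    """Generative parameters for one sleep stage.

    mean_nn/sdnn are the stage's normal-to-normal interval mean and SD in
    ms; ectopic_rate is the per-beat probability of an ectopic perturbation
    (a >20% jump, so Malik cleaning has work to do); movement_rate is the
    expected number of movement bursts per 30-s epoch; burst_amp the burst
    acceleration amplitude in g; green/ir baselines are PPG count levels.
    """

    stage: str
    mean_nn: float
    sdnn: float
    ectopic_rate: float
    movement_rate: float
    burst_amp: float
    green_baseline: float
    ir_baseline: float

    def __post_init__(self) -> None:
        if self.mean_nn <= 0:
            raise ValueError(f"mean_nn must be > 0, got {self.mean_nn}")
        if self.sdnn < 0:
            raise ValueError(f"sdnn must be >= 0, got {self.sdnn}")
        if not 0.0 <= self.ectopic_rate <= 1.0:
            raise ValueError(f"ectopic_rate must be in [0, 1], got {self.ectopic_rate}")
        if self.movement_rate < 0:
            raise ValueError(f"movement_rate must be >= 0, got {self.movement_rate}")
        if self.green_baseline < 0 or self.ir_baseline < 0:
            raise ValueError("PPG baselines must be non-negative")


#: Default five-stage profile. Heart rate decreases and movement vanishes
#: with depth (W > R >= S1 >= S2 >= S3 in movement_rate); green/IR levels
#: are high in wake (skin contact/perfusion change) and close together
#: within sleep.
DEFAULT_STAGE_PARAMS: dict[str, StageParams] = {
    "W": StageParams("W", mean_nn=780.0, sdnn=55.0, ectopic_rate=0.02,
                     movement_rate=4.0, burst_amp=0.5,
                     green_baseline=5600.0, ir_baseline=4250.0),
    "R": StageParams("R", mean_nn=860.0, sdnn=48.0, ectopic_rate=0.01,
                     movement_rate=1.2, burst_amp=0.3,
                     green_baseline=4950.0, ir_baseline=3890.0),
    "S1": StageParams("S1", mean_nn=920.0, sdnn=38.0, ectopic_rate=0.01,
                      movement_rate=1.0, burst_amp=0.25,
                      green_baseline=4900.0, ir_baseline=3870.0),
    "S2": StageParams("S2", mean_nn=990.0, sdnn=26.0, ectopic_rate=0.005,
                      movement_rate=0.5, burst_amp=0.2,
                      green_baseline=4860.0, ir_baseline=3850.0),
    "S3": StageParams("S3", mean_nn=1070.0, sdnn=16.0, ectopic_rate=0.002,
                      movement_rate=0.1, burst_amp=0.15,
                      green_baseline=4830.0, ir_baseline=3830.0),
}

#: Default per-epoch stage transition matrix, row/column order = STAGES.
#: Self-transition probabilities give mean dwell times of a few minutes,
#: a plausible adult sleep architecture at the 30-s epoch scale.
DEFAULT_TRANSITIONS = np.array(
    [
        # W     R     S1    S2    S3
        [0.90, 0.01, 0.07, 0.02, 0.00],  # W
        [0.02, 0.93, 0.02, 0.03, 0.00],  # R
        [0.04, 0.03, 0.85, 0.08, 0.00],  # S1
        [0.01, 0.02, 0.03, 0.90, 0.04],  # S2
        [0.00, 0.00, 0.01, 0.06, 0.93],  # S3
    ]
)

# slow optical drift shared by green/IR channels, AR(1) at epoch scale;
# stationary SD ~= DRIFT_SIGMA / sqrt(1 - rho^2) ~= 128 counts, comparable
# to the between-sleep-stage baseline gaps
PPG_DRIFT_RHO = 0.95
PPG_DRIFT_SIGMA = 40.0
PPG_SAMPLE_NOISE = 25.0

# slow autonomic drift of the NN baseline, AR(1) at epoch scale (ms)
NN_DRIFT_RHO = 0.9
NN_DRIFT_SIGMA = 9.0


@dataclass
class RawRecord:
    """One subject's multichannel 24 Hz record.

    ``rr`` is sparse: the NN interval in ms at the sample nearest each beat,
    zero at every non-beat sample.
    """

    subject_id: str
    t: np.ndarray
    ax: np.ndarray
    ay: np.ndarray
    az: np.ndarray
    green: np.ndarray
    ir: np.ndarray
    rr: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("ax", "ay", "az", "green", "ir", "rr"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"channel {name!r} length != len(t)")

    @property
    def duration_s(self) -> float:
        return len(self.t) / SAMPLE_RATE_HZ

    @property
    def n_epochs(self) -> int:
        return int(self.duration_s // EPOCH_S)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t, "ax": self.ax, "ay": self.ay, "az": self.az,
                "green": self.green, "ir": self.ir, "rr": self.rr,
            }
        )


def validate_transition_matrix(tm: np.ndarray) -> np.ndarray:
    tm = np.asarray(tm, dtype=float)
    if tm.shape != (len(STAGES), len(STAGES)):
        raise ValueError(f"transition matrix must be {len(STAGES)}x{len(STAGES)}, got {tm.shape}")
    if np.any(tm < 0) or np.any(tm > 1):
        raise ValueError("transition probabilities must be in [0, 1]")
    rowsums = tm.sum(axis=1)
    if not np.allclose(rowsums, 1.0, atol=1e-12):
        bad = np.argmax(np.abs(rowsums - 1.0))
        raise ValueError(f"row {bad} ({STAGES[bad]}) sums to {rowsums[bad]!r}, not 1")
    return tm


def simulate_hypnogram(
    tm: np.ndarray | None = None,
    n_epochs: int = 960,
    initial_stage: str = "W",
    seed: int = 0,
) -> list[str]:
    """Sample a stage sequence from a first-order Markov chain.

    Returns ``n_epochs`` labels; the first is ``initial_stage``.
    """
    tm = validate_transition_matrix(DEFAULT_TRANSITIONS if tm is None else tm)
    if n_epochs < 1:
        raise ValueError("n_epochs must be >= 1")
    if initial_stage not in STAGES:
        raise ValueError(f"unknown stage {initial_stage!r}")
    rng = np.random.default_rng(seed)
    cum = np.cumsum(tm, axis=1)
    u = rng.random(n_epochs - 1)
    idx = STAGES.index(initial_stage)
    out = [initial_stage]
    for ui in u:
        idx = int(np.searchsorted(cum[idx], ui, side="right"))
        idx = min(idx, len(STAGES) - 1)  # guard against u landing on 1.0
        out.append(STAGES[idx])
    return out


def _check_params(hypnogram: list[str], params: dict[str, StageParams]) -> None:
    missing = sorted(set(hypnogram) - set(params))
    if missing:
        raise KeyError(f"no StageParams for stage(s): {missing}")


def simulate_rr(
    hypnogram: list[str],
    params: dict[str, StageParams] | None = None,
    seed: int = 0,
    drift_sigma: float = 0.0,
    drift_rho: float = NN_DRIFT_RHO,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate beat times (s) and NN intervals (ms) over a hypnogram.

    Intervals are Normal(mean_nn, sdnn) truncated below at 300 ms; with
    probability ``ectopic_rate`` a beat is perturbed by 25-50% of its
    predecessor. Beat generation runs continuously so cumulative beat times
    tile the epochs. ``drift_sigma`` > 0 adds a slow AR(1) baseline drift
    (updated once per epoch) on top of the stage mean, used by
    :func:`simulate_record` to keep adjacent stages from being trivially
    separable.
    """
    params = DEFAULT_STAGE_PARAMS if params is None else params
    _check_params(hypnogram, params)
    rng = np.random.default_rng(seed)
    total_s = len(hypnogram) * EPOCH_S
    times, intervals = [], []
    t = 0.0
    drift = 0.0
    last_epoch = -1
    while t < total_s:
        epoch = min(int(t // EPOCH_S), len(hypnogram) - 1)
        if epoch != last_epoch:
            drift = drift_rho * drift + rng.normal(0.0, drift_sigma) if drift_sigma > 0 else 0.0
            last_epoch = epoch
        p = params[hypnogram[epoch]]
        nn = max(MIN_NN_MS, rng.normal(p.mean_nn + drift, p.sdnn))
        if p.ectopic_rate > 0 and rng.random() < p.ectopic_rate:
            prev = intervals[-1] if intervals else nn
            sign = 1.0 if rng.random() < 0.5 else -1.0
            nn = max(MIN_NN_MS, nn + sign * rng.uniform(0.25, 0.5) * prev)
        t += nn / 1000.0
        if t > total_s:
            break
        times.append(t)
        intervals.append(nn)
    return np.asarray(times), np.asarray(intervals)


def simulate_accel(
    hypnogram: list[str],
    params: dict[str, StageParams] | None = None,
    seed: int = 0,
    noise_g: float = ACCEL_NOISE_G,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate tri-axial 24 Hz acceleration (g) over a hypnogram.

    Gravity sits wholly on z (1 g); each epoch receives Poisson(movement_rate)
    damped-oscillation bursts (0.5-2 s, 1-3 Hz, amplitude burst_amp) on a
    random axis direction, plus Gaussian sensor noise.
    """
    params = DEFAULT_STAGE_PARAMS if params is None else params
    _check_params(hypnogram, params)
    rng = np.random.default_rng(seed)
    n = len(hypnogram) * EPOCH_S * SAMPLE_RATE_HZ
    t = np.arange(n) / SAMPLE_RATE_HZ
    ax = rng.normal(0.0, noise_g, n)
    ay = rng.normal(0.0, noise_g, n)
    az = 1.0 + rng.normal(0.0, noise_g, n)
    for e, stage in enumerate(hypnogram):
        p = params[stage]
        for _ in range(rng.poisson(p.movement_rate)):
            start = e * EPOCH_S + rng.uniform(0.0, EPOCH_S)
            dur = rng.uniform(0.5, 2.0)
            freq = rng.uniform(1.0, 3.0)
            i0 = int(start * SAMPLE_RATE_HZ)
            i1 = min(n, int((start + dur) * SAMPLE_RATE_HZ))
            if i1 <= i0:
                continue
            tau = t[i0:i1] - start
            osc = p.burst_amp * np.exp(-3.0 * tau / dur) * np.sin(2 * np.pi * freq * tau)
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            ax[i0:i1] += direction[0] * osc
            ay[i0:i1] += direction[1] * osc
            az[i0:i1] += direction[2] * osc
    return ax, ay, az


def simulate_ppg(
    hypnogram: list[str],
    params: dict[str, StageParams] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Simulate green/IR PPG count channels at 24 Hz.

    Stage baseline + a slow shared AR(1) drift (epoch scale) + white sample
    noise. The drift SD is comparable to the gaps between sleep-stage
    baselines, so within sleep the channels overlap between stages while
    wake remains clearly elevated.
    """
    params = DEFAULT_STAGE_PARAMS if params is None else params
    _check_params(hypnogram, params)
    rng = np.random.default_rng(seed)
    spe = EPOCH_S * SAMPLE_RATE_HZ
    n = len(hypnogram) * spe
    green = np.empty(n)
    ir = np.empty(n)
    drift = 0.0
    for e, stage in enumerate(hypnogram):
        drift = PPG_DRIFT_RHO * drift + rng.normal(0.0, PPG_DRIFT_SIGMA)
        p = params[stage]
        sl = slice(e * spe, (e + 1) * spe)
        green[sl] = p.green_baseline + drift + rng.normal(0.0, PPG_SAMPLE_NOISE, spe)
        ir[sl] = p.ir_baseline + 0.8 * drift + rng.normal(0.0, PPG_SAMPLE_NOISE, spe)
    return np.clip(green, 0.0, None), np.clip(ir, 0.0, None)


def simulate_record(
    subject_id: str,
    hypnogram: list[str],
    params: dict[str, StageParams] | None = None,
    seed: int = 0,
) -> RawRecord:
    """Assemble the full 24 Hz multichannel record for one hypnogram."""
    params = DEFAULT_STAGE_PARAMS if params is None else params
    ss = np.random.SeedSequence(seed)
    s_rr, s_acc, s_ppg = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    n = len(hypnogram) * EPOCH_S * SAMPLE_RATE_HZ
    t = np.arange(n) / SAMPLE_RATE_HZ
    ax, ay, az = simulate_accel(hypnogram, params, seed=s_acc)
    green, ir = simulate_ppg(hypnogram, params, seed=s_ppg)
    beat_times, intervals = simulate_rr(
        hypnogram, params, seed=s_rr, drift_sigma=NN_DRIFT_SIGMA
    )
    rr = np.zeros(n)
    idx = np.clip(np.round(beat_times * SAMPLE_RATE_HZ).astype(int), 0, n - 1)
    rr[idx] = intervals
    return RawRecord(subject_id, t, ax, ay, az, green, ir, rr)


def simulate_cohort(
    n_subjects: int = 30,
    n_epochs: int = 960,
    params: dict[str, StageParams] | None = None,
    tm: np.ndarray | None = None,
    seed: int = 0,
) -> list[tuple[RawRecord, list[str]]]:
    """Simulate a cohort of (record, hypnogram) pairs; default 30 subjects
    of 8 h (960 epochs) each."""
    ss = np.random.SeedSequence(seed)
    out = []
    for i, child in enumerate(ss.spawn(n_subjects)):
        s1, s2 = [int(s.generate_state(1)[0] % (2**31)) for s in child.spawn(2)]
        # sleepers start awake; stage mix evolves from there
        hyp = simulate_hypnogram(tm, n_epochs=n_epochs, initial_stage="W", seed=s1)
        rec = simulate_record(f"S{i + 1:02d}", hyp, params, seed=s2)
        out.append((rec, hyp))
    return out


# ---------------------------------------------------------------------------
# CSV round-trip

def write_record(record: RawRecord, path) -> None:
    record.to_frame().to_csv(path, index=False, float_format="%.6f")


def read_record(path, subject_id: str | None = None) -> RawRecord:
    df = pd.read_csv(path)
    if list(df.columns) != RECORD_COLUMNS:
        raise ValueError(
            f"malformed record header: expected {RECORD_COLUMNS}, got {list(df.columns)}"
        )
    t = df["t"].to_numpy()
    if len(t) > 1:
        dt = np.diff(t)
        bad = np.flatnonzero(dt <= 0)
        if bad.size:
            # +2: diff index -> second row of the offending pair, 1-based data row
            raise ValueError(f"non-monotone time at data row {bad[0] + 2}")
    if subject_id is None:
        subject_id = "unknown"
    return RawRecord(
        subject_id, t,
        df["ax"].to_numpy(), df["ay"].to_numpy(), df["az"].to_numpy(),
        df["green"].to_numpy(), df["ir"].to_numpy(), df["rr"].to_numpy(),
    )


def write_hypnogram(hypnogram: list[str], path) -> None:
    pd.DataFrame({"epoch_index": np.arange(len(hypnogram)), "stage": hypnogram}).to_csv(
        path, index=False
    )


def read_hypnogram(path) -> list[str]:
    df = pd.read_csv(path)
    if list(df.columns) != ["epoch_index", "stage"]:
        raise ValueError(f"malformed hypnogram header: {list(df.columns)}")
    unknown = sorted(set(df["stage"]) - set(STAGES))
    if unknown:
        raise ValueError(f"unknown stage label(s): {unknown}")
    return list(df["stage"])
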