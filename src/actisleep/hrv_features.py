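"""Heart-rate-variability features per 30-s epoch.

Roughly 29 variables across four domains:

* time domain      — heart-rate summaries (mean/std/max/min HR), NN summaries
                     (mean/median/range), SDNN, RMSSD, SDSD, NN50/pNN50,
                     NN20/pNN20, CVSD, CVNNI;
* geometric        — triangular index (total beat count over the modal
                     histogram bin at 7.8125 ms bin width);
* frequency domain — VLF/LF/HF band powers from a Welch periodogram of the
                     NN series resampled to 4 Hz, LF/HF ratio, normalised
                     LF/HF, total power;
* non-linear       — Poincare-plot SD1/SD2 and derived sympathetic/vagal
                     indices (CSI, CVI, modified CSI).

Time-domain, geometric and non-linear features are computed on the 30-s
epoch itself; spectral features use a trailing 5-min window ending at the
epoch's end, the standard short-term HRV window — a 30-s stretch cannot
resolve the LF band, let alone VLF. VLF stays undefined (NaN) even on 5 min
(its 0.003 Hz band edge would need ~11 min) and is reported missing.

All standard deviations are population (ddof=0) standard deviations.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal

from .rr_preprocess import RRSeries

EPOCH_S = 30.0
DEFAULT_FREQ_WINDOW_S = 300.0
MIN_BEATS_PER_EPOCH = 10

TRIANGULAR_BIN_MS = 7.8125  # 1/128 s

#: HRV band edges in Hz.
BANDS = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}

RESAMPLE_HZ = 4.0
WELCH_NPERSEG = 256

TIME_DOMAIN_FEATURES = [
    "mean_hr", "std_hr", "max_hr", "min_hr",
    "mean_nni", "median_nni", "range_nni",
    "sdnn", "rmssd", "sdsd", "cvsd", "cvnni",
    "nn50", "pnn50", "nn20", "pnn20",
]
GEOMETRIC_FEATURES = ["triangular_index"]
FREQUENCY_FEATURES = ["vlf", "lf", "hf", "total_power", "lf_hf_ratio", "lfnu", "hfnu"]
NONLINEAR_FEATURES = ["sd1", "sd2", "sd_ratio", "csi", "cvi", "modified_csi"]

#: Canonical column order of the per-epoch feature table.
FEATURE_COLUMNS = (
    TIME_DOMAIN_FEATURES + GEOMETRIC_FEATURES + FREQUENCY_FEATURES + NONLINEAR_FEATURES
)


def time_domain(intervals) -> dict[str, float]:
    """Time-domain HRV statistics of an NN interval sequence (ms)."""
    nn = np.asarray(intervals, dtype=float)
    if nn.size < 2:
        raise ValueError(f"need >= 2 intervals, got {nn.size}")
    hr = 60000.0 / nn
    diff = np.diff(nn)
    rmssd = float(np.sqrt(np.mean(diff**2)))
    mean_nni = float(np.mean(nn))
    sdnn = float(np.std(nn))
    return {
        "mean_hr": float(np.mean(hr)),
        "std_hr": float(np.std(hr)),
        "max_hr": float(np.max(hr)),
        "min_hr": float(np.min(hr)),
        "mean_nni": mean_nni,
        "median_nni": float(np.median(nn)),
        "range_nni": float(np.max(nn) - np.min(nn)),
        "sdnn": sdnn,
        "rmssd": rmssd,
        "sdsd": float(np.std(diff)),
        "cvsd": rmssd / mean_nni,
        "cvnni": sdnn / mean_nni,
        "nn50": int(np.sum(np.abs(diff) > 50.0)),
        "pnn50": 100.0 * np.sum(np.abs(diff) > 50.0) / diff.size,
        "nn20": int(np.sum(np.abs(diff) > 20.0)),
        "pnn20": 100.0 * np.sum(np.abs(diff) > 20.0) / diff.size,
    }


def triangular_index(intervals, bin_width: float = TRIANGULAR_BIN_MS) -> float:
    """Total NN count divided by the height of the modal histogram bin.

    Bins are aligned at integer multiples of ``bin_width`` (default
    7.8125 ms = 1/128 s).
    """
    nn = np.asarray(intervals, dtype=float)
    if nn.size < 1:
        raise ValueError("need >= 1 interval")
    lo = np.floor(nn.min() / bin_width) * bin_width
    hi = np.ceil(nn.max() / bin_width) * bin_width
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges.size < 2:
        edges = np.array([lo, lo + bin_width])
    counts, _ = np.histogram(nn, bins=edges)
    return float(nn.size / counts.max())


def frequency_domain(
    times,
    intervals,
    resample_hz: float = RESAMPLE_HZ,
    bands: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """Welch band powers of the NN series (ms^2).

    The beat series is linearly resampled to a uniform ``resample_hz`` grid
    over the beat-time span, mean-removed, and fed to a Welch periodogram
    (Hann window, segments of up to 256 samples, 50% overlap); band powers
    are trapezoidal integrals over the band. A band whose lower edge cannot
    be resolved on the window (duration < 2 / lower edge) is reported NaN,
    as is the LF/HF ratio when HF is zero or missing.
    """
    bands = BANDS if bands is None else bands
    t = np.asarray(times, dtype=float)
    nn = np.asarray(intervals, dtype=float)
    out = {k: np.nan for k in FREQUENCY_FEATURES}
    if t.size < 4:
        return out
    duration = t[-1] - t[0]
    grid = np.arange(t[0], t[-1], 1.0 / resample_hz)
    if grid.size < 8:
        return out
    x = np.interp(grid, t, nn)
    x = x - x.mean()
    nperseg = min(WELCH_NPERSEG, grid.size)
    f, pxx = signal.welch(
        x, fs=resample_hz, window="hann", nperseg=nperseg,
        noverlap=nperseg // 2, detrend="constant",
    )
    powers = {}
    for name, (lo, hi) in bands.items():
        if duration < 2.0 / lo:
            powers[name] = np.nan
            continue
        mask = (f >= lo) & (f < hi)
        powers[name] = float(np.trapezoid(pxx[mask], f[mask])) if mask.sum() >= 2 else np.nan
    out.update(powers)
    defined = [v for v in powers.values() if not np.isnan(v)]
    out["total_power"] = float(np.sum(defined)) if defined else np.nan
    lf, hf = powers.get("lf", np.nan), powers.get("hf", np.nan)
    if not np.isnan(lf) and not np.isnan(hf):
        out["lf_hf_ratio"] = lf / hf if hf > 0 else np.nan
        denom = lf + hf
        if denom > 0:
            out["lfnu"] = 100.0 * lf / denom
            out["hfnu"] = 100.0 * hf / denom
    return out


def poincare(intervals) -> dict[str, float]:
    """Poincare (Lorenz) plot dispersions and autonomic indices.

    SD1 = sqrt(var(diff)/2) is the short-axis (beat-to-beat) dispersion,
    SD2 = sqrt(2 var(NN) - var(diff)/2) the long-axis dispersion
    (population variances). CSI = SD2/SD1; CVI = log10(16 SD1 SD2), the
    Toichi L*T form with L = 4 SD2, T = 4 SD1; modified CSI = L^2/T.
    """
    nn = np.asarray(intervals, dtype=float)
    if nn.size < 3:
        raise ValueError(f"need >= 3 intervals, got {nn.size}")
    diff = np.diff(nn)
    var_d = float(np.var(diff))
    var_nn = float(np.var(nn))
    sd1 = float(np.sqrt(var_d / 2.0))
    sd2 = float(np.sqrt(max(0.0, 2.0 * var_nn - var_d / 2.0)))
    out = {"sd1": sd1, "sd2": sd2, "sd_ratio": np.nan, "csi": np.nan,
           "cvi": np.nan, "modified_csi": np.nan}
    if sd1 > 0:
        out["sd_ratio"] = sd2 / sd1
        out["csi"] = sd2 / sd1
        out["modified_csi"] = (4.0 * sd2) ** 2 / (4.0 * sd1)
    if sd1 > 0 and sd2 > 0:
        out["cvi"] = float(np.log10(16.0 * sd1 * sd2))
    return out


def extract_epoch_features(
    rr: RRSeries,
    epoch_index: int,
    epoch_s: float = EPOCH_S,
    freq_window_s: float = DEFAULT_FREQ_WINDOW_S,
    min_beats: int = MIN_BEATS_PER_EPOCH,
) -> dict[str, float]:
    """Full HRV feature vector for one 30-s epoch.

    Beats belong to epoch i when their time lies in [i*30, (i+1)*30)
    (half-open). Time-domain, geometric and non-linear features use the
    epoch's beats; spectral features use the trailing ``freq_window_s``
    window ending at the epoch's end. Epochs with fewer than ``min_beats``
    beats are flagged and all features reported NaN.
    """
    t0, t1 = epoch_index * epoch_s, (epoch_index + 1) * epoch_s
    in_epoch = (rr.times >= t0) & (rr.times < t1)
    n_beats = int(in_epoch.sum())
    feats: dict[str, float] = {c: np.nan for c in FEATURE_COLUMNS}
    feats["epoch_index"] = epoch_index
    feats["n_beats"] = n_beats
    if n_beats < min_beats:
        feats["flag"] = "too_few_beats"
        return feats
    feats["flag"] = "ok"
    nn = rr.intervals[in_epoch]
    feats.update(time_domain(nn))
    feats["triangular_index"] = triangular_index(nn)
    feats.update(poincare(nn))
    in_window = (rr.times >= t1 - freq_window_s) & (rr.times < t1)
    feats.update(frequency_domain(rr.times[in_window], rr.intervals[in_window]))
    return feats


def extract_features_table(
    rr: RRSeries,
    n_epochs: int,
    epoch_s: float = EPOCH_S,
    freq_window_s: float = DEFAULT_FREQ_WINDOW_S,
    min_beats: int = MIN_BEATS_PER_EPOCH,
) -> pd.DataFrame:
    """Per-epoch HRV feature table for epochs 0..n_epochs-1."""
    rows = [
        extract_epoch_features(rr, i, epoch_s=epoch_s,
                               freq_window_s=freq_window_s, min_beats=min_beats)
        for i in range(n_epochs)
    ]
    df = pd.DataFrame(rows)
    return df[["epoch_index", "n_beats", "flag"] + FEATURE_COLUMNS]
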