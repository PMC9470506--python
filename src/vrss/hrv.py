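"""Frequency-domain heart-rate-variability analysis.

The pipeline follows standard short-term HRV practice: R-peak detection on a
single-lead ECG, artifact flagging on the RR-interval series, segmentation
into consecutive 5-minute epochs, cubic-spline resampling of the tachogram to
an even 4 Hz grid, and a Hann-windowed FFT periodogram integrated over the
conventional frequency bands

    VLF  [0.003, 0.04) Hz
    LF   [0.04, 0.15) Hz
    HF   [0.15, 0.4) Hz
    TP   (0, 0.4] Hz  (DC bin excluded)

All band powers are reported in ms^2; LF/HF is dimensionless.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.interpolate import CubicSpline

from .errors import EmptySeriesError, InvalidParameterError, UnusableEpochError

# Band edges in Hz.  Half-open [low, high) for the named bands; total power
# integrates (0, 0.4] so the shared edges are never double-counted and the
# DC bin never enters.
VLF_BAND = (0.003, 0.04)
LF_BAND = (0.04, 0.15)
HF_BAND = (0.15, 0.4)
TP_BAND = (0.0, 0.4)

RESAMPLE_HZ = 4.0
MIN_VALID_BEATS = 60
MIN_EPOCH_SPAN_S = 240.0


@dataclass
class ECGRecord:
    """Single-lead ECG trace in arbitrary voltage units."""

    samples: np.ndarray
    fs_hz: float
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs_hz <= 0:
            raise InvalidParameterError("fs_hz must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise InvalidParameterError("ECG samples must be finite")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.fs_hz

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        np.savetxt(path, self.samples, fmt="%.6f", header="ecg", comments="")
        sidecar = {"fs_hz": self.fs_hz, "start_time": self.start_time}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))

    @classmethod
    def from_csv(cls, path: str | Path) -> "ECGRecord":
        path = Path(path)
        samples = np.loadtxt(path, skiprows=1)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        return cls(samples=samples, fs_hz=meta["fs_hz"],
                   start_time=meta.get("start_time", 0.0))


@dataclass
class RRSeries:
    """Timestamped RR intervals with per-interval validity flags.

    ``beat_times[i]`` is the time (s) of the beat terminating interval ``i``
    and ``rr_ms[i]`` the interval's length.  Artifact handling never deletes
    rows; cleaning only clears the ``valid`` flag so the original series is
    always recoverable.
    """

    beat_times: np.ndarray
    rr_ms: np.ndarray
    valid: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.beat_times = np.asarray(self.beat_times, dtype=float)
        self.rr_ms = np.asarray(self.rr_ms, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.rr_ms.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if len(self.rr_ms) != len(self.beat_times) or len(self.valid) != len(self.rr_ms):
            raise InvalidParameterError("beat_times, rr_ms and valid must align")
        if len(self.beat_times) > 1 and np.any(np.diff(self.beat_times) <= 0):
            raise InvalidParameterError("beat_times must be strictly increasing")
        if np.any(self.rr_ms[self.valid] <= 0):
            raise InvalidParameterError("valid RR intervals must be positive")

    def __len__(self) -> int:
        return len(self.rr_ms)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def valid_rr(self) -> np.ndarray:
        return self.rr_ms[self.valid]

    @property
    def valid_times(self) -> np.ndarray:
        return self.beat_times[self.valid]

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "beat_time_s": self.beat_times,
            "rr_ms": self.rr_ms,
            "valid": self.valid.astype(int),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RRSeries":
        df = pd.read_csv(path)
        valid = df["valid"].astype(bool).to_numpy() if "valid" in df else None
        return cls(beat_times=df["beat_time_s"].to_numpy(),
                   rr_ms=df["rr_ms"].to_numpy(), valid=valid)


@dataclass
class SpectralResult:
    """Per-epoch frequency-domain indices (band powers in ms^2)."""

    epoch_label: str
    mean_rr: float
    vlf: float
    lf: float
    hf: float
    tp: float
    lf_hf: float | None
    n_valid_beats: int

    @property
    def lf_hf_defined(self) -> bool:
        return self.lf_hf is not None

    def as_dict(self) -> dict:
        return {
            "epoch": self.epoch_label,
            "mean_rr": self.mean_rr,
            "vlf": self.vlf,
            "lf": self.lf,
            "hf": self.hf,
            "tp": self.tp,
            "lf_hf": np.nan if self.lf_hf is None else self.lf_hf,
            "n_valid_beats": self.n_valid_beats,
        }


def detect_r_peaks(ecg: ECGRecord, refractory_s: float = 0.25) -> RRSeries:
    """Locate R waves and return the RR tachogram.

    A simplified Pan–Tompkins front end: the trace is band-passed to the QRS
    band (5–30 Hz), its squared derivative is smoothed with a 150 ms moving
    window, and candidate peaks above an amplitude threshold (40 % of the
    98th percentile of the detection function) and separated by a refractory
    period are refined to the local maximum of the raw signal within
    +/-60 ms.
    """
    if ecg.duration_s < 10.0:
        raise InvalidParameterError("need at least 10 s of ECG signal")
    fs = ecg.fs_hz
    x = ecg.samples - np.mean(ecg.samples)
    sos = sps.butter(2, [5.0, min(30.0, 0.45 * fs)], btype="bandpass",
                     fs=fs, output="sos")
    xf = sps.sosfiltfilt(sos, x)
    det = np.gradient(xf) ** 2
    win = max(int(0.15 * fs), 1)
    det = np.convolve(det, np.ones(win) / win, mode="same")
    top = np.percentile(det, 98)
    if top <= 0:
        raise EmptySeriesError("no detectable beats in ECG")
    peaks, _ = sps.find_peaks(det, height=0.4 * top, distance=max(int(refractory_s * fs), 1))
    if len(peaks) < 2:
        raise EmptySeriesError("no detectable beats in ECG")
    # refine to the raw-signal maximum near each detection-function peak
    half = max(int(0.06 * fs), 1)
    refined = []
    for p in peaks:
        lo, hi = max(p - half, 0), min(p + half + 1, len(x))
        refined.append(lo + int(np.argmax(x[lo:hi])))
    refined = np.unique(refined)
    beat_t = ecg.start_time + refined / fs
    rr_ms = np.diff(refined) / fs * 1000.0
    return RRSeries(beat_times=beat_t[1:], rr_ms=rr_ms)


def clean_rr(rr: RRSeries, max_rel_change: float = 0.20,
             absolute_bounds_ms: tuple[float, float] = (300.0, 2000.0)) -> RRSeries:
    """Flag artifactual RR intervals; never deletes rows.

    An interval is invalid if it falls outside ``absolute_bounds_ms`` or if it
    differs from the previous *valid* interval by more than ``max_rel_change``
    (fractional).  If more than 20 % of intervals end up flagged a warning is
    recorded in ``meta['warnings']`` so downstream stages can reject the epoch.
    """
    if len(rr) == 0:
        raise EmptySeriesError("cannot clean an empty RR series")
    lo, hi = absolute_bounds_ms
    valid = rr.valid.copy()
    prev = None
    for i in range(len(rr)):
        if not valid[i]:
            continue
        v = rr.rr_ms[i]
        if not (lo <= v <= hi):
            valid[i] = False
            continue
        if prev is not None and abs(v - prev) / prev > max_rel_change:
            valid[i] = False
            continue
        prev = v
    meta = dict(rr.meta)
    frac = 1.0 - valid.sum() / len(valid)
    warnings = list(meta.get("warnings", []))
    if frac > 0.20:
        warnings.append(f"clean_rr flagged {frac:.1%} of intervals")
    meta["warnings"] = warnings
    meta["flagged_fraction"] = float(frac)
    return RRSeries(beat_times=rr.beat_times, rr_ms=rr.rr_ms, valid=valid, meta=meta)


def segment_epochs(rr: RRSeries,
                   epoch_defs: list[tuple[str, float, float]]) -> list[RRSeries]:
    """Slice an RR series into labelled half-open windows [start_s, end_s).

    An interval belongs to the epoch containing its terminating beat.  Epochs
    with fewer than 60 valid intervals are returned with
    ``meta['usable'] = False`` rather than raising, so a session with one bad
    epoch still yields the others.
    """
    for label, start, end in epoch_defs:
        if end <= start:
            raise InvalidParameterError(f"epoch {label!r} has end <= start")
    out = []
    for label, start, end in epoch_defs:
        mask = (rr.beat_times >= start) & (rr.beat_times < end)
        seg = RRSeries(beat_times=rr.beat_times[mask], rr_ms=rr.rr_ms[mask],
                       valid=rr.valid[mask],
                       meta={"label": label, "start_s": start, "end_s": end})
        seg.meta["usable"] = seg.n_valid >= MIN_VALID_BEATS
        out.append(seg)
    return out


def _band_power(freqs: np.ndarray, psd: np.ndarray, low: float, high: float,
                *, closed_right: bool = False) -> float:
    if closed_right:
        mask = (freqs > low) & (freqs <= high)
    else:
        mask = (freqs >= low) & (freqs < high)
    if not mask.any():
        return 0.0
    df = freqs[1] - freqs[0]
    return float(np.sum(psd[mask]) * df)


def spectral_powers(rr_epoch: RRSeries, epoch_label: str | None = None) -> SpectralResult:
    """Compute band powers for one epoch of RR data.

    Valid intervals are interpolated with a cubic spline onto an even 4 Hz
    grid spanning the valid beats (invalid beats are bridged by the spline,
    not concatenated out, so the time base stays intact), the tachogram is
    linearly detrended and a Hann-windowed one-sided periodogram is
    integrated over each band.  The window is power-normalised (scipy's
    density scaling) so that the integral of the PSD equals the variance of
    the detrended signal.
    """
    label = epoch_label if epoch_label is not None else rr_epoch.meta.get("label", "")
    t = rr_epoch.valid_times
    y = rr_epoch.valid_rr
    if len(y) < MIN_VALID_BEATS or (len(t) > 0 and t[-1] - t[0] < MIN_EPOCH_SPAN_S):
        raise UnusableEpochError(
            f"epoch {label!r}: need >= {MIN_VALID_BEATS} valid beats spanning "
            f">= {MIN_EPOCH_SPAN_S:.0f} s (got {len(y)} beats)")
    mean_rr = float(np.mean(y))
    if np.ptp(y) == 0:
        return SpectralResult(label, mean_rr, 0.0, 0.0, 0.0, 0.0, None, len(y))
    spline = CubicSpline(t, y)
    n = int(np.floor((t[-1] - t[0]) * RESAMPLE_HZ)) + 1
    grid = t[0] + np.arange(n) / RESAMPLE_HZ
    tach = spline(grid)
    freqs, psd = sps.periodogram(tach, fs=RESAMPLE_HZ, window="hann",
                                 detrend="linear", scaling="density")
    vlf = _band_power(freqs, psd, *VLF_BAND)
    lf = _band_power(freqs, psd, *LF_BAND)
    hf = _band_power(freqs, psd, *HF_BAND)
    tp = _band_power(freqs, psd, *TP_BAND, closed_right=True)
    lf_hf = lf / hf if hf > 0 else None
    return SpectralResult(label, mean_rr, vlf, lf, hf, tp, lf_hf, len(y))


def lf_hf_ratio(spec: SpectralResult) -> float | None:
    """LF/HF sympathovagal-balance ratio; ``None`` when HF power is zero."""
    if spec.hf == 0:
        return None
    return spec.lf / spec.hf


def analyse_session(rr: RRSeries,
                    epoch_defs: list[tuple[str, float, float]],
                    max_rel_change: float = 0.20,
                    absolute_bounds_ms: tuple[float, float] = (300.0, 2000.0),
                    ) -> list[SpectralResult]:
    """Clean, segment and spectrally analyse a whole recording session.

    Unusable epochs yield a SpectralResult row of NaNs so the output always
    has one row per requested epoch.
    """
    cleaned = clean_rr(rr, max_rel_change=max_rel_change,
                       absolute_bounds_ms=absolute_bounds_ms)
    results = []
    for seg in segment_epochs(cleaned, epoch_defs):
        label = seg.meta["label"]
        try:
            results.append(spectral_powers(seg))
        except UnusableEpochError:
            results.append(SpectralResult(label, np.nan, np.nan, np.nan,
                                          np.nan, np.nan, None, seg.n_valid))
    return results


def spectral_table(results_by_participant: dict[str, list[SpectralResult]]) -> pd.DataFrame:
    """Long-format table: one row per participant-epoch."""
    rows = []
    for pid, specs in results_by_participant.items():
        for s in specs:
            row = {"participant": pid}
            row.update(s.as_dict())
            rows.append(row)
    return pd.DataFrame(rows)
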