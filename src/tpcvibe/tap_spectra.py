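"""From raw multichannel tap recordings to normalized power spectra and peaks.

The processing chain mirrors an impact-excitation measurement: detect tap
onsets on an envelope, cut equal-length segments, align them by
cross-correlation and sum coherently, take the squared-magnitude FFT, and
normalize each channel at a reference frequency (15 kHz by default).
Averaging across spectra happens in the linear power domain; dB is for
display only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "MIC_DIRECTIONS",
    "Recording",
    "TapEnsemble",
    "AveragedSpectrum",
    "PeakSet",
    "AmplitudeMap",
    "detect_taps",
    "coherent_sum",
    "power_spectrum",
    "average_spectra",
    "pick_peaks",
    "amplitude_map",
    "read_recording",
    "write_recording",
    "load_manifest",
]

#: Microphone direction labels with unit vectors (mesh frame): four around
#: the sides and four in a plane facing the ventral (-z) surface.
MIC_DIRECTIONS: dict[str, np.ndarray] = {
    "anterior": np.array([0.0, 1.0, 0.0]),
    "posterior": np.array([0.0, -1.0, 0.0]),
    "lateral": np.array([1.0, 0.0, 0.0]),
    "proximal": np.array([-1.0, 0.0, 0.0]),
    "ventral_1": np.array([0.3, 0.3, -1.0]) / np.linalg.norm([0.3, 0.3, 1.0]),
    "ventral_2": np.array([-0.3, 0.3, -1.0]) / np.linalg.norm([0.3, 0.3, 1.0]),
    "ventral_3": np.array([0.3, -0.3, -1.0]) / np.linalg.norm([0.3, 0.3, 1.0]),
    "ventral_4": np.array([-0.3, -0.3, -1.0]) / np.linalg.norm([0.3, 0.3, 1.0]),
}


@dataclass
class Recording:
    """Multichannel recording of repeated taps at one location."""

    samples: np.ndarray  # (channels, time), linear amplitude units
    rate: float  # Hz
    mic_ids: list[str]
    mic_directions: list[str] = field(default_factory=list)
    tap_location_id: int = 0

    def __post_init__(self):
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if not self.rate > 0:
            raise ValueError("sample rate must be positive")
        if self.samples.shape[0] < 1:
            raise ValueError("at least one channel required")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass(frozen=True)
class TapEnsemble:
    """Aligned fixed-length segments per tap (taps x channels x window)."""

    segments: np.ndarray
    onsets: np.ndarray
    window_samples: int
    rate: float
    shifts: np.ndarray  # applied per-tap alignment shifts, samples


@dataclass
class AveragedSpectrum:
    """Per-channel power spectrum, each channel normalized at ``norm_freq``."""

    frequencies_hz: np.ndarray
    power: np.ndarray  # (channels, bins), >= 0
    norm_freq_hz: float
    counts: int = 1
    mic_ids: list[str] = field(default_factory=list)
    tap_location_id: int = 0

    @property
    def bin_width_hz(self) -> float:
        return float(self.frequencies_hz[1] - self.frequencies_hz[0])

    def nearest_bin(self, freq_hz: float) -> int:
        return int(np.argmin(np.abs(self.frequencies_hz - freq_hz)))

    def channel_mean(self) -> np.ndarray:
        return self.power.mean(axis=0)

    def db(self) -> np.ndarray:
        """Power in dB for display."""
        return 10 * np.log10(np.maximum(self.power, 1e-300))


@dataclass(frozen=True)
class PeakSet:
    """Ascending resonance-peak frequencies with prominence and merge flags."""

    frequencies_hz: np.ndarray
    prominences_db: np.ndarray
    merged: np.ndarray  # bool per peak
    band_hz: tuple[float, float]
    bin_width_hz: float

    def __len__(self) -> int:
        return len(self.frequencies_hz)


@dataclass(frozen=True)
class AmplitudeMap:
    """Normalized power per (tap location, microphone) at one query frequency."""

    table: pd.DataFrame  # columns: tap_location_id, mic_id, frequency_hz, amplitude
    query_freq_hz: float

    def matrix(self) -> pd.DataFrame:
        return self.table.pivot(
            index="tap_location_id", columns="mic_id", values="amplitude"
        )

    def reduced(self, how: str = "max") -> pd.Series:
        """Per-location amplitude reduced over microphones (``max`` or ``mean``)."""
        if how not in ("max", "mean"):
            raise ValueError("reduce must be 'max' or 'mean'")
        return getattr(self.matrix(), how)(axis=1)


# ---------------------------------------------------------------------------
# onset detection and coherent summation
# ---------------------------------------------------------------------------


def detect_taps(
    rec: Recording,
    threshold_k: float = 8.0,
    refractory_ms: float = 100.0,
) -> np.ndarray:
    """Tap onset sample indices from a robust envelope threshold.

    The envelope is the absolute channel-summed signal smoothed by a 1 ms
    moving average; onsets are rising crossings of ``median + k * MAD``,
    merged within the refractory interval.
    """
    env = np.abs(rec.samples.sum(axis=0))
    width = max(1, int(round(1e-3 * rec.rate)))
    env = np.convolve(env, np.ones(width) / width, mode="same")
    med = np.median(env)
    mad = np.median(np.abs(env - med))
    thr = med + threshold_k * max(mad, 1e-300)
    above = env > thr
    rising = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above[0]:
        rising = np.concatenate([[0], rising])
    if len(rising) == 0:
        raise ValueError("no taps detected above threshold")
    refractory = int(round(refractory_ms * 1e-3 * rec.rate))
    onsets = [int(rising[0])]
    for i in rising[1:]:
        if i - onsets[-1] >= refractory:
            onsets.append(int(i))
    return np.asarray(onsets)


def _align_shift(ref: np.ndarray, seg: np.ndarray, max_lag: int) -> float:
    """Sub-sample lag that best aligns ``seg`` to ``ref`` (positive = delay)."""
    n = len(ref)
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    c = np.fft.irfft(np.fft.rfft(ref, nfft) * np.conj(np.fft.rfft(seg, nfft)), nfft)
    lags = np.concatenate([np.arange(0, max_lag + 1), np.arange(-max_lag, 0)])
    vals = np.concatenate([c[: max_lag + 1], c[-max_lag:]])
    i = int(np.argmax(vals))
    lag = float(lags[i])
    # parabolic refinement around the peak
    cm = c[(int(lag) - 1) % nfft]
    c0 = c[int(lag) % nfft]
    cp = c[(int(lag) + 1) % nfft]
    denom = cm - 2 * c0 + cp
    if denom < 0:
        lag += 0.5 * (cm - cp) / denom
    return lag


def _fractional_shift(x: np.ndarray, shift: float) -> np.ndarray:
    """Delay ``x`` by ``shift`` samples (may be fractional) via FFT phase ramp."""
    n = x.shape[-1]
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    freqs = np.fft.rfftfreq(nfft)
    ramp = np.exp(-2j * np.pi * freqs * shift)
    return np.fft.irfft(np.fft.rfft(x, nfft) * ramp, nfft)[..., :n]


def coherent_sum(
    rec: Recording,
    onsets: Sequence[int],
    window_s: float = 0.5,
    align: bool = True,
    max_lag_ms: float = 5.0,
) -> tuple[TapEnsemble, np.ndarray]:
    """Cut per-tap segments, align them to the first, and sum per channel.

    The window is ``window_s`` or the smallest inter-onset gap, whichever is
    shorter, so windows never overlap.  Returns the ensemble and the stacked
    waveform ``(channels, window)``.
    """
    onsets = np.asarray(onsets, dtype=np.int64)
    if len(onsets) < 2:
        raise ValueError("coherent summation needs at least 2 onsets")
    if np.any(np.diff(onsets) <= 0):
        raise ValueError("onsets must be strictly increasing")
    win = int(round(window_s * rec.rate))
    win = min(win, int(np.diff(onsets).min()))
    if win < 2:
        raise ValueError("window collapses to fewer than 2 samples")
    last = onsets[-1] + win
    if last > rec.n_samples:
        raise ValueError("window overruns the end of the recording")
    segs = np.stack([rec.samples[:, o : o + win] for o in onsets])  # (taps, ch, win)

    shifts = np.zeros(len(onsets))
    if align:
        # correlate the differentiated channel sum: differentiation whitens
        # the spectrum so high-frequency content sharpens the peak, giving
        # sub-sample delay estimates
        sums = segs.sum(axis=1)
        dsums = np.diff(sums, axis=1)
        max_lag = max(1, int(round(max_lag_ms * 1e-3 * rec.rate)))
        for i in range(1, len(onsets)):
            shifts[i] = _align_shift(dsums[0], dsums[i], max_lag)
        aligned = np.stack(
            [
                _fractional_shift(segs[i], shifts[i]) if shifts[i] != 0 else segs[i]
                for i in range(len(onsets))
            ]
        )
    else:
        aligned = segs
    stacked = aligned.sum(axis=0)
    ensemble = TapEnsemble(
        segments=aligned,
        onsets=onsets,
        window_samples=win,
        rate=rec.rate,
        shifts=shifts,
    )
    return ensemble, stacked


# ---------------------------------------------------------------------------
# spectra
# ---------------------------------------------------------------------------


def power_spectrum(
    stacked: np.ndarray,
    rate: float,
    norm_freq_hz: float = 15000.0,
    mic_ids: Sequence[str] | None = None,
    tap_location_id: int = 0,
) -> AveragedSpectrum:
    """Squared-magnitude FFT per channel, normalized at ``norm_freq_hz``.

    FFT length is the next power of two at or above the window length;
    each channel is divided by its own power at the bin nearest the
    normalization frequency.
    """
    stacked = np.atleast_2d(np.asarray(stacked, dtype=np.float64))
    if not norm_freq_hz < rate / 2:
        raise ValueError("normalization frequency must be below Nyquist")
    n = stacked.shape[1]
    nfft = 1 << int(np.ceil(np.log2(n)))
    freqs = np.fft.rfftfreq(nfft, d=1.0 / rate)
    power = np.abs(np.fft.rfft(stacked, nfft, axis=1)) ** 2
    nbin = int(np.argmin(np.abs(freqs - norm_freq_hz)))
    ref = power[:, nbin]
    if np.any(ref <= 0):
        raise ValueError("zero power at the normalization bin")
    power = power / ref[:, None]
    return AveragedSpectrum(
        frequencies_hz=freqs,
        power=power,
        norm_freq_hz=norm_freq_hz,
        counts=1,
        mic_ids=list(mic_ids) if mic_ids is not None else [],
        tap_location_id=tap_location_id,
    )


def average_spectra(
    spectra: Sequence[AveragedSpectrum], over: str = "locations"
) -> AveragedSpectrum:
    """Arithmetic mean of normalized power per bin, in the power domain.

    ``over='locations'`` averages the list elementwise keeping channels;
    ``over='microphones'`` also collapses channels; ``'both'`` is the same
    as ``'microphones'`` after the list average.
    """
    if over not in ("locations", "microphones", "both"):
        raise ValueError(f"unknown averaging axis {over!r}")
    if len(spectra) == 0:
        raise ValueError("no spectra to average")
    f0 = spectra[0].frequencies_hz
    for s in spectra[1:]:
        if len(s.frequencies_hz) != len(f0) or not np.allclose(s.frequencies_hz, f0):
            raise ValueError("spectra are on different frequency grids")
    power = np.mean([s.power for s in spectra], axis=0)
    if over in ("microphones", "both"):
        power = power.mean(axis=0, keepdims=True)
    return AveragedSpectrum(
        frequencies_hz=f0,
        power=power,
        norm_freq_hz=spectra[0].norm_freq_hz,
        counts=sum(s.counts for s in spectra),
        mic_ids=spectra[0].mic_ids if over == "locations" else [],
    )


def _width_3db(pdb: np.ndarray, i: int) -> float:
    """Width in bins of the peak at index ``i`` at 3 dB below its top."""
    level = pdb[i] - 3.0
    left = i
    while left > 0 and pdb[left - 1] >= level:
        left -= 1
    right = i
    while right < len(pdb) - 1 and pdb[right + 1] >= level:
        right += 1
    return float(right - left)


def pick_peaks(
    spec: AveragedSpectrum,
    band_hz: tuple[float, float] = (100.0, 6000.0),
    min_prominence_db: float = 10.0,
    min_height_db: float = 10.0,
    merge_width_bins: float = 2.0,
    width_limit_bins: float | None = None,
) -> PeakSet:
    """Local maxima of the channel-mean spectrum (dB) within a band.

    Peaks need ``min_prominence_db`` of prominence and must rise at least
    ``min_height_db`` above the band's median level (suppresses noise-floor
    wiggles).  A peak is flagged ``merged`` when a neighboring peak sits
    closer than the resolution limit — ``merge_width_bins`` bins or the
    peak's own 3 dB width, whichever is larger — since two modes that close
    cannot be separated in the spectrum.  When the expected single-mode
    width is known, ``width_limit_bins`` additionally flags any peak whose
    3 dB width exceeds it (a lone wide peak may hide several modes).
    """
    from scipy.signal import find_peaks

    lo, hi = band_hz
    f = spec.frequencies_hz
    if lo < f[0] or hi > f[-1]:
        raise ValueError("band extends outside the spectrum range")
    sel = (f >= lo) & (f <= hi)
    fband = f[sel]
    pdb = 10 * np.log10(np.maximum(spec.channel_mean()[sel], 1e-300))
    floor = np.median(pdb)
    idx, props = find_peaks(
        pdb, prominence=min_prominence_db, height=floor + min_height_db
    )
    widths = np.array([_width_3db(pdb, i) for i in idx])
    merged = np.zeros(len(idx), dtype=bool)
    for k in range(len(idx)):
        limit = max(merge_width_bins, widths[k])
        if k > 0 and idx[k] - idx[k - 1] <= limit:
            merged[k] = True
        if k < len(idx) - 1 and idx[k + 1] - idx[k] <= limit:
            merged[k] = True
        if width_limit_bins is not None and widths[k] > width_limit_bins:
            merged[k] = True
    return PeakSet(
        frequencies_hz=fband[idx],
        prominences_db=props["prominences"],
        merged=merged,
        band_hz=(lo, hi),
        bin_width_hz=spec.bin_width_hz,
    )


def amplitude_map(
    spectra: Mapping[int, AveragedSpectrum], query_freq_hz: float
) -> AmplitudeMap:
    """Per (location, mic) normalized power at the bin nearest the query."""
    rows = []
    for loc in sorted(spectra):
        s = spectra[loc]
        if not s.frequencies_hz[0] <= query_freq_hz <= s.frequencies_hz[-1]:
            raise ValueError("query frequency outside the spectrum band")
        b = s.nearest_bin(query_freq_hz)
        mic_ids = s.mic_ids or [f"ch{c}" for c in range(s.power.shape[0])]
        for c, mic in enumerate(mic_ids):
            rows.append(
                {
                    "tap_location_id": loc,
                    "mic_id": mic,
                    "frequency_hz": s.frequencies_hz[b],
                    "amplitude": s.power[c, b],
                }
            )
    return AmplitudeMap(table=pd.DataFrame(rows), query_freq_hz=query_freq_hz)


# ---------------------------------------------------------------------------
# audio IO
# ---------------------------------------------------------------------------

_PCM_SCALE = {np.dtype(np.int16): 2**15, np.dtype(np.int32): 2**31}


def read_recording(
    path: str | Path,
    mic_ids: Sequence[str] | None = None,
    mic_directions: Sequence[str] | None = None,
    tap_location_id: int = 0,
) -> Recording:
    """Read a WAV file (PCM 16/32-bit or float32) as a Recording."""
    rate, data = wavfile.read(path)
    if data.ndim == 1:
        data = data[:, None]
    scale = _PCM_SCALE.get(data.dtype, None)
    data = data.T.astype(np.float64)
    if scale is not None:
        data = data / scale
    nch = data.shape[0]
    return Recording(
        samples=data,
        rate=float(rate),
        mic_ids=list(mic_ids) if mic_ids else [f"ch{c}" for c in range(nch)],
        mic_directions=list(mic_directions) if mic_directions else [],
        tap_location_id=tap_location_id,
    )


def write_recording(path: str | Path, rec: Recording) -> None:
    """Write a Recording as a float32 WAV (channels interleaved)."""
    wavfile.write(path, int(rec.rate), rec.samples.T.astype(np.float32))


def load_manifest(path: str | Path) -> dict[int, Recording]:
    """Load recordings listed in a manifest CSV.

    Columns: ``file, tap_location_id, mic_id, mic_direction``.  Rows sharing
    a ``tap_location_id`` may point at one multichannel file (listed once
    per channel, in channel order) or at per-microphone mono files.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    need = {"file", "tap_location_id", "mic_id", "mic_direction"}
    if not need <= set(df.columns):
        raise ValueError(f"manifest must have columns {sorted(need)}")
    out: dict[int, Recording] = {}
    for loc, grp in df.groupby("tap_location_id"):
        files = grp["file"].tolist()
        mic_ids = grp["mic_id"].astype(str).tolist()
        dirs = grp["mic_direction"].astype(str).tolist()
        unique_files = list(dict.fromkeys(files))
        for f in unique_files:
            if not (path.parent / f).exists():
                raise FileNotFoundError(f"manifest references missing file {f!r}")
        if len(unique_files) == 1:
            rec = read_recording(
                path.parent / unique_files[0],
                mic_ids=mic_ids,
                mic_directions=dirs,
                tap_location_id=int(loc),
            )
            if rec.n_channels != len(mic_ids):
                raise ValueError(
                    f"file {unique_files[0]!r} has {rec.n_channels} channels, "
                    f"manifest lists {len(mic_ids)} mics"
                )
        else:
            chans = []
            rate = None
            for f in files:
                r = read_recording(path.parent / f)
                if r.n_channels != 1:
                    raise ValueError(f"per-mic file {f!r} must be mono")
                if rate is None:
                    rate = r.rate
                elif r.rate != rate:
                    raise ValueError("mixed sample rates within one location")
                chans.append(r.samples[0])
            n = min(len(c) for c in chans)
            rec = Recording(
                samples=np.stack([c[:n] for c in chans]),
                rate=float(rate),
                mic_ids=mic_ids,
                mic_directions=dirs,
                tap_location_id=int(loc),
            )
        out[int(loc)] = rec
    return out
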