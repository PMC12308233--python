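"""Hydrophone calibration and corpus ingest.

Digital WAV samples are mapped to sound pressure in micro-pascal from the
recorder chain description (hydrophone sensitivity, gain, ADC full scale):

    pressure_uPa = raw * adc_fullscale_volts / 10**((sensitivity_db + gain_db) / 20)

after which the per-segment mean is removed. Only the end-to-end value
``sensitivity_db + gain_db`` matters; no frequency-dependent response is
modeled. Analysis never upsamples: band-specific rates are reached by
polyphase rational resampling with an anti-alias low-pass cut at 0.9 x the
target Nyquist frequency.
"""

from __future__ import annotations

import math
import re
import warnings
from dataclasses import dataclass, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from reefpam import wavio

__all__ = [
    "RecorderSpec",
    "CalibratedSegment",
    "calibrate",
    "resample",
    "scan_corpus",
]

#: fraction of full scale above which a sample counts as clipped
_CLIP_LEVEL = 0.999
#: fraction of clipped samples that triggers the clipping warning
_CLIP_FRACTION = 1e-3

_FILENAME_RE = re.compile(r"^(?P<site>.+)_(?P<date>\d{8})_(?P<time>\d{6})\.wav$")


@dataclass(frozen=True)
class RecorderSpec:
    """Recorder chain description needed to map WAV samples to pressure.

    Parameters
    ----------
    sensitivity_db : float
        Hydrophone sensitivity in dB re 1 V uPa^-1 (negative).
    gain_db : float
        Recorder gain in dB, additive to the sensitivity.
    adc_fullscale_volts : float
        Voltage mapped to digital full scale.
    native_rate : int
        Sampling rate of the recordings in Hz.
    duty_record_minutes : float or None
        Minutes recorded at the top of each hour (None = continuous).
    duty_usable_minutes : float or None
        Usable minutes per recording; the unusable tail is discarded.
    """

    sensitivity_db: float
    gain_db: float = 0.0
    adc_fullscale_volts: float = 1.0
    native_rate: int = 44100
    duty_record_minutes: float | None = None
    duty_usable_minutes: float | None = None

    def __post_init__(self) -> None:
        if self.sensitivity_db >= 0:
            raise ValueError("hydrophone sensitivity must be negative (dB re 1 V uPa^-1)")
        if self.adc_fullscale_volts <= 0:
            raise ValueError("ADC full-scale voltage must be positive")
        if self.native_rate not in (44100, 48000):
            warnings.warn(
                f"native rate {self.native_rate} Hz is unusual for study-like data",
                stacklevel=2,
            )
        if self.duty_usable_minutes is not None and self.duty_record_minutes is not None:
            if self.duty_usable_minutes > self.duty_record_minutes:
                raise ValueError("usable minutes cannot exceed recorded minutes")

    @property
    def fullscale_upa(self) -> float:
        """Pressure in uPa that maps to digital full scale."""
        return self.adc_fullscale_volts / 10 ** ((self.sensitivity_db + self.gain_db) / 20)

    def to_dict(self) -> dict:
        return {
            "sensitivity_db": self.sensitivity_db,
            "gain_db": self.gain_db,
            "adc_fullscale_volts": self.adc_fullscale_volts,
            "native_rate": self.native_rate,
            "duty_record_minutes": self.duty_record_minutes,
            "duty_usable_minutes": self.duty_usable_minutes,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecorderSpec":
        return cls(**d)


@dataclass
class CalibratedSegment:
    """Timestamped pressure series in uPa for one site."""

    site_id: str
    start_time: datetime
    sample_rate: int
    pressure: np.ndarray
    clipped: bool = False

    def __post_init__(self) -> None:
        self.pressure = np.asarray(self.pressure)
        if self.pressure.dtype not in (np.float32, np.float64):
            self.pressure = self.pressure.astype(np.float64)
        if not np.all(np.isfinite(self.pressure)):
            raise ValueError("pressure series contains non-finite samples")
        if self.sample_rate <= 0:
            raise ValueError("sample rate must be positive")

    @property
    def duration(self) -> float:
        """Duration in seconds."""
        return self.pressure.size / self.sample_rate


def calibrate(
    raw: np.ndarray,
    spec: RecorderSpec,
    *,
    site_id: str = "",
    start_time: datetime | None = None,
    sample_rate: int | None = None,
) -> CalibratedSegment:
    """Convert normalized WAV samples in [-1, 1] to calibrated pressure.

    The segment mean is subtracted (DC removal). If more than 0.1% of the
    samples sit at >= 99.9% of full scale the segment is flagged as clipped
    and a warning is emitted.
    """
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size and np.max(np.abs(raw)) > 1.0 + 1e-9:
        raise ValueError("raw samples must lie within [-1, 1]")
    clipped = False
    if raw.size:
        frac = np.mean(np.abs(raw) >= _CLIP_LEVEL)
        if frac > _CLIP_FRACTION:
            clipped = True
            warnings.warn(
                f"segment appears clipped: {frac:.2%} of samples at full scale",
                stacklevel=2,
            )
    pressure = raw * spec.fullscale_upa
    if pressure.size:
        pressure = pressure - pressure.mean()
    return CalibratedSegment(
        site_id=site_id,
        start_time=start_time or datetime(2000, 1, 1),
        sample_rate=int(sample_rate or spec.native_rate),
        pressure=pressure,
        clipped=clipped,
    )


def _antialias_filter(up: int, down: int, source_rate: float, target_rate: float) -> np.ndarray:
    """Low-pass FIR for polyphase resampling, cut at 0.9 x target Nyquist.

    The transition band is 10% of the target Nyquist so that levels up to
    0.8 x Nyquist are preserved; Kaiser window sized for ~60 dB stopband.
    """
    nyq_t = target_rate / 2.0
    fs_up = source_rate * up
    cutoff = 0.9 * nyq_t
    width = 0.1 * nyq_t
    numtaps, beta = signal.kaiserord(60.0, width / (fs_up / 2.0))
    numtaps |= 1  # odd length, type-I linear phase
    # resample_poly scales the supplied coefficients by `up` itself
    return signal.firwin(numtaps, cutoff, window=("kaiser", beta), fs=fs_up)


def resample(segment: CalibratedSegment, target_rate: int) -> CalibratedSegment:
    """Rational polyphase resampling to a lower analysis rate.

    Raises on upsampling requests: the analysis chain only ever moves down
    in rate (48 kHz -> 44.1 kHz for the high band, anything -> 4 kHz for the
    low band). Timestamps are preserved.
    """
    target_rate = int(target_rate)
    if target_rate > segment.sample_rate:
        raise ValueError(
            f"upsampling {segment.sample_rate} -> {target_rate} Hz is not supported"
        )
    if target_rate == segment.sample_rate:
        return segment
    g = math.gcd(target_rate, segment.sample_rate)
    up, down = target_rate // g, segment.sample_rate // g
    h = _antialias_filter(up, down, segment.sample_rate, target_rate)
    out = signal.resample_poly(
        segment.pressure, up, down, window=h.astype(segment.pressure.dtype)
    )
    n_expected = round(segment.pressure.size * target_rate / segment.sample_rate)
    out = out[:n_expected]
    return replace(segment, sample_rate=target_rate, pressure=out)


def scan_corpus(
    directory,
    site_metadata: pd.DataFrame,
) -> tuple[pd.DataFrame, list[str]]:
    """Inventory the WAV files of one or more corpus directories.

    Filenames must follow ``<site>_<YYYYMMDD>_<HHMMSS>.wav``. Returns the
    inventory (site, start_time, duration, rate, path, duplicate flag)
    sorted by site and time, plus the list of unparseable filenames.
    Files from different directories that claim the same site and start
    time (e.g. merged deployments) are flagged as duplicates.

    ``site_metadata`` must be indexed by (or contain a column) ``site`` and
    carry at least ``protection`` and ``location``; a file whose site is
    missing from the table raises a :class:`KeyError` naming the file.
    """
    if isinstance(directory, (str, Path)):
        directories = [Path(directory)]
    else:
        directories = [Path(d) for d in directory]
    meta = site_metadata
    if "site" in meta.columns:
        meta = meta.set_index("site")
    rows: list[dict] = []
    rejects: list[str] = []
    paths = sorted(p for d in directories for p in d.glob("*.wav"))
    for path in paths:
        m = _FILENAME_RE.match(path.name)
        if not m:
            rejects.append(path.name)
            continue
        try:
            start = datetime.strptime(m["date"] + m["time"], "%Y%m%d%H%M%S")
        except ValueError:
            rejects.append(path.name)
            continue
        site = m["site"]
        if site not in meta.index:
            raise KeyError(f"site {site!r} (file {path.name}) missing from site metadata")
        rate, n = wavio.wav_info(path)
        rows.append(
            {
                "site": site,
                "start_time": start,
                "duration": n / rate,
                "rate": rate,
                "path": str(path),
                "protection": meta.loc[site, "protection"],
                "location": meta.loc[site, "location"],
            }
        )
    inv = pd.DataFrame(
        rows,
        columns=["site", "start_time", "duration", "rate", "path", "protection", "location"],
    )
    if len(inv):
        inv = inv.sort_values(["site", "start_time"], kind="stable").reset_index(drop=True)
        inv["duplicate"] = inv.duplicated(["site", "start_time"], keep=False)
    else:
        inv["duplicate"] = pd.Series(dtype=bool)
    return inv, rejects
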