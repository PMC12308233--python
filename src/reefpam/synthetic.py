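"""Synthetic coral-reef soundscape generator.

Emulates the statistical structure that the analysis pipeline assumes for
reef recordings:

* **Snap trains** — snapping-shrimp-like broadband transients: a Poisson
  process of exponentially damped sinusoids with per-snap center frequency
  drawn from a normal distribution (default around 5 kHz) and lognormal
  amplitudes (heavy-ish tail mimicking the spread of snap source levels).
* **Fish chorus** — a Gaussian spectral bump below 2 kHz (default centered
  at 300 Hz): only the chorus PSD matters to the pipeline, so it is modeled
  as band-shaped Gaussian noise rather than summed fish pulses.
* **Ambient noise** — power-law ("pink-ish") sea noise, default
  -10 dB/decade referenced at 1 kHz.
* **Diel cycle** — day and night differ in snap rate and chorus level.
* **Group offsets** — dB offsets keyed by (protection, year, band, period),
  the injected effects the statistical layer must recover.

Two recording protocols are emulated: a "2015"-style duty-cycled recorder
(48 kHz, 5 min at the top of each hour of which 4.4 min are usable) and a
"2021"-style continuous recorder (44.1 kHz). The generator writes 24-bit
PCM WAV, scaled so the largest plausible pressure maps to at most half of
digital full scale, and writes the matching recorder specs so that
calibration inverts generation exactly.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, datetime, time, timedelta
from pathlib import Path

import numpy as np
import pandas as pd

from reefpam import wavio
from reefpam.calibration import CalibratedSegment, RecorderSpec

__all__ = [
    "SiteInfo",
    "ScenarioConfig",
    "GroundTruth",
    "SurveyEffects",
    "make_snap_kernel",
    "simulate_segment",
    "simulate_campaign",
    "simulate_survey",
    "default_sites",
]

PROTECTIONS = ("MPA", "nMPA")
LOCATIONS = ("West", "Northwest", "North", "East")
BANDS = ("LF", "HF")
PERIODS = ("day", "night")

#: lognormal sigma (natural log) of snap amplitudes
SNAP_AMP_SIGMA = 0.8
#: envelope threshold terminating the snap kernel (1% of peak)
_KERNEL_ENVELOPE_FLOOR = 0.01

#: nominal local start clock times of the generated day / night segments
_PERIOD_START = {"day": time(12, 0, 0), "night": time(22, 0, 0)}


@dataclass(frozen=True)
class SiteInfo:
    site_id: str
    protection: str
    location: str

    def __post_init__(self) -> None:
        if self.protection not in PROTECTIONS:
            raise ValueError(f"protection must be one of {PROTECTIONS}")
        if self.location not in LOCATIONS:
            raise ValueError(f"location must be one of {LOCATIONS}")


def default_sites() -> list[SiteInfo]:
    """Eight sites: an MPA/nMPA couplet at each of four locations."""
    return [
        SiteInfo(f"{p}{loc}", p, loc)
        for loc in LOCATIONS
        for p in PROTECTIONS
    ]


@dataclass(frozen=True)
class Protocol:
    """Recording protocol of one sampling year."""

    native_rate: int
    sensitivity_db: float
    gain_db: float
    duty_record_minutes: float | None = None
    duty_usable_minutes: float | None = None
    start_date: date = date(2021, 2, 1)


def default_protocols() -> dict[str, Protocol]:
    return {
        "2015": Protocol(48000, -181.0, 10.0, 5.0, 4.4, date(2015, 2, 1)),
        "2021": Protocol(44100, -170.0, 2.0, None, None, date(2021, 2, 1)),
    }


@dataclass
class ScenarioConfig:
    """Generative parameters of a synthetic monitoring campaign.

    Defaults reflect the monitored system: eight sites in four MPA/nMPA
    couplets, a nocturnally enhanced fish chorus near 300 Hz, snap trains
    centered near 5 kHz that are denser at night, and quiet pink ambient
    noise. ``group_offsets`` maps (protection, year, band, period) to a dB
    offset applied to the corresponding source level; these are the injected
    effects the pipeline must recover.
    """

    sites: list[SiteInfo] = field(default_factory=default_sites)
    years: list[str] = field(default_factory=lambda: ["2015", "2021"])
    protocols: dict[str, Protocol] = field(default_factory=default_protocols)
    n_days_per_site: int = 3
    segment_minutes_per_period: float = 5.0
    shrimp_rate_day: float = 1500.0  # snaps s^-1, aggregate near+far crackle
    shrimp_rate_night: float = 3000.0
    shrimp_fc_mean: float = 5000.0  # Hz
    shrimp_fc_sd: float = 300.0
    snap_tau: float = 2.0e-4  # s
    snap_amp_scale: float = 5.0e4  # uPa, lognormal median of snap peak pressure
    snap_amp_sigma: float = SNAP_AMP_SIGMA
    chorus_f0: float = 300.0  # Hz
    chorus_bandwidth: float = 100.0  # Hz, FWHM of the spectral bump
    chorus_level_day: float = 68.0  # dB re 1 uPa^2 Hz^-1 at the bump peak
    chorus_level_night: float = 72.0
    ambient_level: float = 45.0  # dB re 1 uPa^2 Hz^-1 at 1 kHz
    ambient_slope: float = -10.0  # dB/decade
    group_offsets: dict[tuple[str, str, str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.shrimp_rate_day < 0 or self.shrimp_rate_night < 0:
            raise ValueError("snap rates must be >= 0")
        if not (0 < self.shrimp_fc_mean - 3 * self.shrimp_fc_sd):
            raise ValueError("shrimp_fc_mean - 3 sd must be positive")
        if not (self.shrimp_fc_mean + 3 * self.shrimp_fc_sd < 22050):
            raise ValueError("shrimp_fc_mean + 3 sd must stay below 22.05 kHz")
        if not (0 < self.chorus_f0 < 2000):
            raise ValueError("chorus_f0 must lie in (0, 2000) Hz")
        if self.segment_minutes_per_period <= 0:
            raise ValueError("segment_minutes_per_period must be positive")
        if self.snap_tau <= 0:
            raise ValueError("snap_tau must be positive")
        for key in self.group_offsets:
            p, y, b, per = key
            if p not in PROTECTIONS or b not in BANDS or per not in PERIODS or y not in self.years:
                raise ValueError(f"invalid group_offsets key {key}")

    # -- derived quantities -------------------------------------------------

    def offset_db(self, protection: str, year: str, band: str, period: str) -> float:
        return float(self.group_offsets.get((protection, year, band, period), 0.0))

    def chorus_level(self, period: str) -> float:
        return self.chorus_level_day if period == "day" else self.chorus_level_night

    def shrimp_rate(self, period: str) -> float:
        return self.shrimp_rate_day if period == "day" else self.shrimp_rate_night

    def _gaussian_variance_upper(self, nyquist: float) -> float:
        """Upper bound on the variance of the Gaussian components (uPa^2)."""
        f = np.linspace(1.0, nyquist, 4096)
        amb = 10 ** ((self.ambient_level + self.ambient_slope * np.log10(f / 1000.0)) / 10)
        max_off = max([0.0, *self.group_offsets.values()])
        lvl = max(self.chorus_level_day, self.chorus_level_night) + max_off
        sig = self.chorus_bandwidth / 2.355
        cho = 10 ** (lvl / 10) * np.exp(-0.5 * ((f - self.chorus_f0) / sig) ** 2)
        return float(np.trapezoid(amb + cho, f))

    def fullscale_upa(self, nyquist: float = 22050.0) -> float:
        """Digital full scale in uPa for the written corpus (factor-2 headroom).

        Derived analytically from the scenario so the recorder spec is fixed
        before any audio is generated: snap peaks are bounded at the e^(4 sigma)
        lognormal quantile and the Gaussian components at 5 standard deviations.
        """
        max_off = max([0.0, *self.group_offsets.values()])
        snap_peak = self.snap_amp_scale * math.exp(5 * self.snap_amp_sigma) * 10 ** (max_off / 20)
        gauss_peak = 5.0 * math.sqrt(self._gaussian_variance_upper(nyquist))
        return 2.0 * (snap_peak + gauss_peak)

    def recorder_spec(self, year: str) -> RecorderSpec:
        """Recorder spec whose calibration exactly inverts the generated WAVs."""
        proto = self.protocols[year]
        sens_gain = proto.sensitivity_db + proto.gain_db
        v_fs = self.fullscale_upa() * 10 ** (sens_gain / 20)
        return RecorderSpec(
            sensitivity_db=proto.sensitivity_db,
            gain_db=proto.gain_db,
            adc_fullscale_volts=v_fs,
            native_rate=proto.native_rate,
            duty_record_minutes=proto.duty_record_minutes,
            duty_usable_minutes=proto.duty_usable_minutes,
        )

    def to_dict(self) -> dict:
        return {
            "sites": [[s.site_id, s.protection, s.location] for s in self.sites],
            "years": list(self.years),
            "protocols": {
                y: {
                    "native_rate": p.native_rate,
                    "sensitivity_db": p.sensitivity_db,
                    "gain_db": p.gain_db,
                    "duty_record_minutes": p.duty_record_minutes,
                    "duty_usable_minutes": p.duty_usable_minutes,
                    "start_date": p.start_date.isoformat(),
                }
                for y, p in self.protocols.items()
            },
            "n_days_per_site": self.n_days_per_site,
            "segment_minutes_per_period": self.segment_minutes_per_period,
            "shrimp_rate_day": self.shrimp_rate_day,
            "shrimp_rate_night": self.shrimp_rate_night,
            "shrimp_fc_mean": self.shrimp_fc_mean,
            "shrimp_fc_sd": self.shrimp_fc_sd,
            "snap_tau": self.snap_tau,
            "snap_amp_scale": self.snap_amp_scale,
            "snap_amp_sigma": self.snap_amp_sigma,
            "chorus_f0": self.chorus_f0,
            "chorus_bandwidth": self.chorus_bandwidth,
            "chorus_level_day": self.chorus_level_day,
            "chorus_level_night": self.chorus_level_night,
            "ambient_level": self.ambient_level,
            "ambient_slope": self.ambient_slope,
            "group_offsets": [[*k, v] for k, v in sorted(self.group_offsets.items())],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        if "sites" in d:
            d["sites"] = [SiteInfo(*row) for row in d["sites"]]
        if "protocols" in d:
            d["protocols"] = {
                y: Protocol(
                    native_rate=p["native_rate"],
                    sensitivity_db=p["sensitivity_db"],
                    gain_db=p["gain_db"],
                    duty_record_minutes=p.get("duty_record_minutes"),
                    duty_usable_minutes=p.get("duty_usable_minutes"),
                    start_date=date.fromisoformat(p["start_date"]),
                )
                for y, p in d["protocols"].items()
            }
        if "group_offsets" in d:
            d["group_offsets"] = {
                (p, y, b, per): float(v) for p, y, b, per, v in d["group_offsets"]
            }
        return cls(**d)


@dataclass
class GroundTruth:
    """Injected per-segment truths: one row per segment x band."""

    table: pd.DataFrame

    COLUMNS = (
        "site",
        "protection",
        "location",
        "year",
        "date",
        "period",
        "band",
        "true_peak_freq_hz",
        "true_peak_level_db",
        "group_offset_db",
        "n_snaps",
    )


# ---------------------------------------------------------------------------
# snap kernel and segment synthesis
# ---------------------------------------------------------------------------


def make_snap_kernel(
    fc: float,
    tau: float,
    sample_rate: float,
    n_samples: int | None = None,
) -> np.ndarray:
    """Unit-peak exponentially damped sinusoid p(t) = e^(-t/tau) sin(2 pi fc t).

    Sampled until the envelope drops below 1% of its peak, i.e.
    ``ceil(tau * ln(100) * sample_rate)`` samples, unless ``n_samples``
    overrides the length. Raises if ``fc`` is at or above Nyquist.
    """
    if fc <= 0 or tau <= 0 or sample_rate <= 0:
        raise ValueError("fc, tau and sample_rate must be positive")
    if fc >= sample_rate / 2:
        raise ValueError(
            f"snap center frequency {fc} Hz would alias at {sample_rate} Hz sampling"
        )
    if n_samples is None:
        n_samples = math.ceil(tau * math.log(100.0) * sample_rate)
    t = np.arange(n_samples) / sample_rate
    p = np.exp(-t / tau) * np.sin(2 * np.pi * fc * t)
    peak = np.max(np.abs(p))
    if peak > 0:
        p /= peak
    return p


def _segment_seed(scenario: ScenarioConfig, site: str, year: str, day: int, period: str):
    key = f"{site}|{year}|{day}|{period}"
    return np.random.SeedSequence(
        [scenario.seed, *(b for b in key.encode())]
    )


def _gaussian_psd(freqs: np.ndarray, scenario: ScenarioConfig, chorus_level_db: float) -> np.ndarray:
    """One-sided PSD (uPa^2/Hz) of ambient + chorus at the given frequencies."""
    f = np.maximum(freqs, freqs[1] if freqs.size > 1 else 1.0).astype(np.float32)
    amb = 10 ** ((scenario.ambient_level + scenario.ambient_slope * np.log10(f / np.float32(1000.0))) / 10)
    sig = scenario.chorus_bandwidth / 2.355
    cho = np.float32(10 ** (chorus_level_db / 10)) * np.exp(
        -0.5 * ((freqs.astype(np.float32) - np.float32(scenario.chorus_f0)) / np.float32(sig)) ** 2
    )
    return amb + cho


def _synth_gaussian(psd: np.ndarray, n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Real Gaussian noise of length n whose one-sided PSD is ``psd``.

    Synthesized in single precision: the 24-bit quantization of the written
    corpus dominates any float32 rounding by orders of magnitude.
    """
    from scipy import fft as sp_fft

    n_bins = psd.size
    sigma = np.sqrt(psd * fs * n / 4.0).astype(np.float32)
    z = (
        rng.standard_normal(n_bins, dtype=np.float32)
        + 1j * rng.standard_normal(n_bins, dtype=np.float32)
    ) * sigma
    z[0] = 0.0  # mean-free
    if n % 2 == 0:
        z[-1] = z[-1].real * math.sqrt(2.0)  # Nyquist bin is real
    return sp_fft.irfft(z, n)


def _snap_train_psd_peak_db(scenario: ScenarioConfig, rate_hz: float, sample_rate: float) -> float:
    """Expected one-sided PSD (dB) of the snap train at its resonance.

    Campbell's theorem for a filtered Poisson process:
    S(f) = 2 * lambda * E[A^2] * |K(f)|^2 with K the continuous-time kernel
    transform (approximated by DFT / fs of the sampled kernel at fc_mean).
    """
    if rate_hz <= 0:
        return -np.inf
    k = make_snap_kernel(scenario.shrimp_fc_mean, scenario.snap_tau, sample_rate)
    spec = np.abs(np.fft.rfft(k, 8192)) / sample_rate
    e_a2 = scenario.snap_amp_scale**2 * math.exp(2 * scenario.snap_amp_sigma**2)
    s_peak = 2.0 * rate_hz * e_a2 * float(np.max(spec) ** 2)
    return 10 * math.log10(s_peak)


def _add_snaps(
    x: np.ndarray,
    starts: np.ndarray,
    fcs: np.ndarray,
    amps: np.ndarray,
    tau: float,
    fs: float,
    chunk: int = 65536,
) -> None:
    """Scatter-add damped-sinusoid snaps into ``x`` in place, vectorized.

    Work is n_snaps x kernel_length regardless of strategy, so snaps are
    built as (chunk, klen) matrices and accumulated with ``np.add.at``;
    kernels are truncated at the signal end rather than wrapped.
    """
    n = x.size
    klen = math.ceil(tau * math.log(100.0) * fs)
    t = np.arange(klen) / fs
    env = np.exp(-t / tau)
    # quantize fc onto a fine grid (step << analysis bin width) so unit-peak
    # kernels can be precomputed once instead of per snap
    fc_lo, fc_hi = float(fcs.min()), float(fcs.max())
    n_grid = 257
    grid = np.linspace(fc_lo, fc_hi, n_grid) if fc_hi > fc_lo else np.array([fc_lo])
    bank = env[None, :] * np.sin(2 * np.pi * np.outer(grid, t))
    peak = np.abs(bank).max(axis=1)
    peak[peak == 0] = 1.0
    bank = (bank / peak[:, None]).astype(np.float32)
    gidx = (
        np.rint((fcs - fc_lo) / (fc_hi - fc_lo) * (len(grid) - 1)).astype(np.intp)
        if fc_hi > fc_lo
        else np.zeros(fcs.size, dtype=np.intp)
    )
    offs = np.arange(klen)
    amps32 = amps.astype(np.float32)
    for i0 in range(0, starts.size, chunk):
        s = slice(i0, min(i0 + chunk, starts.size))
        k = bank[gidx[s]] * amps32[s][:, None]
        idx = starts[s][:, None] + offs[None, :]
        over = idx >= n  # truncate kernels at the segment end
        if over.any():
            k[over] = 0.0
            idx[over] = 0
        np.add.at(x, idx, k)


def simulate_segment(
    scenario: ScenarioConfig,
    site: SiteInfo,
    year: str,
    day_index: int,
    period: str,
) -> tuple[CalibratedSegment, pd.DataFrame]:
    """Generate one site x day x period pressure segment plus ground truth.

    The segment is ambient + chorus Gaussian noise (synthesized jointly in
    the frequency domain — the two components are independent Gaussians, so
    their sum is drawn directly from the summed PSD) plus a Poisson snap
    train. Deterministic given the scenario seed and the segment coordinates.
    """
    if period not in PERIODS:
        raise ValueError(f"period must be one of {PERIODS}")
    proto = scenario.protocols[year]
    fs = proto.native_rate
    minutes = scenario.segment_minutes_per_period
    if proto.duty_record_minutes is not None:
        minutes = min(minutes, proto.duty_record_minutes)
    n = int(round(minutes * 60 * fs))
    rng = np.random.default_rng(_segment_seed(scenario, site.site_id, year, day_index, period))

    lf_off = scenario.offset_db(site.protection, year, "LF", period)
    hf_off = scenario.offset_db(site.protection, year, "HF", period)
    chorus_level = scenario.chorus_level(period) + lf_off

    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    x = _synth_gaussian(_gaussian_psd(freqs, scenario, chorus_level), n, fs, rng)

    rate = scenario.shrimp_rate(period)
    n_snaps = 0
    if rate > 0:
        n_snaps = int(rng.poisson(rate * minutes * 60))
        starts = rng.integers(0, n, size=n_snaps)
        fcs = rng.normal(scenario.shrimp_fc_mean, scenario.shrimp_fc_sd, size=n_snaps)
        fcs = np.clip(fcs, 10.0, 0.95 * fs / 2)
        amps = scenario.snap_amp_scale * np.exp(
            rng.normal(0.0, scenario.snap_amp_sigma, size=n_snaps)
        ) * 10 ** (hf_off / 20)
        _add_snaps(x, starts, fcs, amps, scenario.snap_tau, fs)

    # drop the unusable tail of a duty-cycled take
    if proto.duty_usable_minutes is not None:
        n_usable = int(round(proto.duty_usable_minutes * 60 * fs))
        x = x[: min(n_usable, x.size)]

    d = proto.start_date + timedelta(days=day_index)
    start_time = datetime.combine(d, _PERIOD_START[period])
    seg = CalibratedSegment(
        site_id=site.site_id,
        start_time=start_time,
        sample_rate=fs,
        pressure=x - x.dtype.type(x.mean(dtype=np.float64)),
    )

    hf_level = _snap_train_psd_peak_db(scenario, rate, fs)
    gt = pd.DataFrame(
        [
            {
                "site": site.site_id,
                "protection": site.protection,
                "location": site.location,
                "year": year,
                "date": d.isoformat(),
                "period": period,
                "band": "LF",
                "true_peak_freq_hz": scenario.chorus_f0,
                "true_peak_level_db": chorus_level,
                "group_offset_db": lf_off,
                "n_snaps": n_snaps,
            },
            {
                "site": site.site_id,
                "protection": site.protection,
                "location": site.location,
                "year": year,
                "date": d.isoformat(),
                "period": period,
                "band": "HF",
                "true_peak_freq_hz": scenario.shrimp_fc_mean,
                "true_peak_level_db": hf_level + hf_off,
                "group_offset_db": hf_off,
                "n_snaps": n_snaps,
            },
        ],
        columns=list(GroundTruth.COLUMNS),
    )
    return seg, gt


# ---------------------------------------------------------------------------
# campaign and survey
# ---------------------------------------------------------------------------


def simulate_campaign(
    scenario: ScenarioConfig,
    out_dir: str | Path,
    *,
    survey_effects: "SurveyEffects | None" = None,
) -> dict:
    """Write a full synthetic corpus: WAVs, ground truth, survey, metadata.

    One WAV per site x year x day x period, named
    ``<site>_<YYYYMMDD>_<HHMMSS>.wav`` at the year protocol's native rate.
    Recorder specs (one per year) and site metadata are written alongside so
    the ingest path is self-contained. Deterministic under the scenario seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    gt_rows: list[pd.DataFrame] = []
    written: set[str] = set()
    for site in scenario.sites:
        for year in scenario.years:
            for day in range(scenario.n_days_per_site):
                for period in PERIODS:
                    seg, gt = simulate_segment(scenario, site, year, day, period)
                    fname = (
                        f"{site.site_id}_{seg.start_time:%Y%m%d}_{seg.start_time:%H%M%S}.wav"
                    )
                    if fname in written:
                        raise FileExistsError(f"output filename collision: {fname}")
                    written.add(fname)
                    spec = scenario.recorder_spec(year)
                    wavio.write_wav(
                        out_dir / fname,
                        seg.pressure / spec.fullscale_upa,
                        seg.sample_rate,
                        bit_depth=24,
                    )
                    gt_rows.append(gt)
    ground_truth = pd.concat(gt_rows, ignore_index=True)
    ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)

    meta = pd.DataFrame(
        [
            {"site": s.site_id, "protection": s.protection, "location": s.location}
            for s in scenario.sites
        ]
    )
    meta.to_csv(out_dir / "sites.csv", index=False)

    specs = {y: scenario.recorder_spec(y).to_dict() for y in scenario.years}
    (out_dir / "recorder_specs.json").write_text(json.dumps(specs, indent=2, sort_keys=True))

    survey = simulate_survey(scenario, survey_effects or SurveyEffects())
    survey.to_csv(out_dir / "survey.csv", index=False)

    return {
        "n_wav": len(written),
        "ground_truth": ground_truth,
        "survey": survey,
        "site_metadata": meta,
        "recorder_specs": {y: scenario.recorder_spec(y) for y in scenario.years},
        "out_dir": out_dir,
    }


#: fish species pool (family, species) — MPA-only species sit at the end so a
#: positive richness offset widens the protected-site pool
_SPECIES_POOL = [
    ("Chaetodontidae", "Chaetodon_ornatissimus"),
    ("Chaetodontidae", "Chaetodon_reticulatus"),
    ("Chaetodontidae", "Chaetodon_pelewensis"),
    ("Holocentridae", "Sargocentron_microstoma"),
    ("Holocentridae", "Myripristis_berndti"),
    ("Holocentridae", "Neoniphon_sammara"),
    ("Pomacentridae", "Stegastes_nigricans"),
    ("Pomacentridae", "Chromis_viridis"),
    ("Pomacentridae", "Dascyllus_flavicaudus"),
    ("Acanthuridae", "Ctenochaetus_striatus"),
    ("Acanthuridae", "Acanthurus_nigrofuscus"),
    ("Scaridae", "Chlorurus_spilurus"),
    ("Serranidae", "Epinephelus_hexagonatus"),
    ("Labridae", "Thalassoma_hardwicke"),
    ("Balistidae", "Balistapus_undulatus"),
    ("Mullidae", "Parupeneus_multifasciatus"),
    ("Lethrinidae", "Gnathodentex_aureolineatus"),
    ("Cirrhitidae", "Paracirrhites_arcatus"),
]

#: ten benthic categories and their baseline percent cover
_BENTHIC_BASE = {
    "sand": 10.0,
    "rubble": 8.0,
    "dead_coral": 7.0,
    "pavement": 15.0,
    "turf_algae": 15.0,
    "macroalgae": 10.0,
    "crustose_coralline": 5.0,
    "Acropora": 12.0,
    "Porites": 10.0,
    "Pocillopora": 8.0,
}

_CORAL_CATEGORIES = ("Acropora", "Porites", "Pocillopora")
_ALGAE_CATEGORIES = ("turf_algae", "macroalgae", "crustose_coralline")


@dataclass
class SurveyEffects:
    """Protection-group offsets injected into the synthetic survey.

    ``richness_offset`` widens the MPA species pool by that many species;
    ``cover_offsets`` adds percentage points to MPA mean cover of the named
    benthic categories (compensated by the untouched categories so covers
    still sum to 100); ``abundance_multiplier`` scales MPA expected counts.
    """

    richness_offset: int = 0
    cover_offsets: dict[str, float] = field(default_factory=dict)
    abundance_multiplier: float = 1.0


def _cover_target(effects: SurveyEffects, protected: bool) -> np.ndarray:
    base = np.array(list(_BENTHIC_BASE.values()))
    cats = list(_BENTHIC_BASE)
    target = base.copy()
    if protected and effects.cover_offsets:
        touched = np.zeros(len(cats), dtype=bool)
        for cat, off in effects.cover_offsets.items():
            if cat not in _BENTHIC_BASE:
                raise KeyError(f"unknown benthic category {cat!r}")
            i = cats.index(cat)
            target[i] += off
            touched[i] = True
        if np.any(target < 0):
            warnings.warn("cover offsets drove a category below 0%; clipping", stacklevel=2)
            target = np.clip(target, 0.0, None)
            target *= 100.0 / target.sum()
        else:
            # rescale only the untouched categories so touched means are exact
            rest = (~touched).nonzero()[0]
            deficit = 100.0 - target[touched].sum()
            target[rest] *= deficit / target[rest].sum()
    return target


def simulate_survey(
    scenario: ScenarioConfig,
    effects: SurveyEffects | None = None,
    *,
    n_sites: int | None = None,
    seed_offset: int = 0,
) -> pd.DataFrame:
    """Synthetic fish and benthic survey table, one row per site.

    Fish counts are lognormal-Poisson per species (log-mean jittered per
    site); species richness is the number of species with a positive count;
    benthic covers are Dirichlet-distributed around group target percentages
    and sum to 100 exactly.
    """
    effects = effects or SurveyEffects()
    sites = scenario.sites
    if n_sites is not None:
        if n_sites < 2:
            raise ValueError("a survey needs at least 2 sites")
        # replicate the couplet structure out to n_sites for calibration studies
        sites = [
            SiteInfo(
                f"S{i:03d}",
                PROTECTIONS[i % 2],
                LOCATIONS[(i // 2) % len(LOCATIONS)],
            )
            for i in range(n_sites)
        ]
    if len(sites) < 2:
        raise ValueError("a survey needs at least 2 sites")
    rng = np.random.default_rng(
        np.random.SeedSequence([scenario.seed, 777, seed_offset])
    )
    base_pool = 12
    species = [name for _, name in _SPECIES_POOL]
    rows = []
    for site in sites:
        protected = site.protection == "MPA"
        pool = base_pool + (effects.richness_offset if protected else 0)
        pool = int(np.clip(pool, 0, len(species)))
        lam0 = 6.0 * (effects.abundance_multiplier if protected else 1.0)
        row: dict = {
            "site": site.site_id,
            "protection": site.protection,
            "location": site.location,
        }
        counts = np.zeros(len(species), dtype=int)
        lam = lam0 * np.exp(rng.normal(0.0, 0.5, size=pool))
        counts[:pool] = rng.poisson(lam)
        for sp, c in zip(species, counts):
            row[sp] = int(c)
        row["abundance"] = int(counts.sum())
        row["richness"] = int(np.count_nonzero(counts))
        target = _cover_target(effects, protected)
        cover = 100.0 * rng.dirichlet(np.maximum(60.0 * target / 100.0, 1e-3))
        for cat, val in zip(_BENTHIC_BASE, cover):
            row[f"cover_{cat}"] = float(val)
        row["coral_cover"] = float(sum(cover[list(_BENTHIC_BASE).index(c)] for c in _CORAL_CATEGORIES))
        row["algae_cover"] = float(sum(cover[list(_BENTHIC_BASE).index(c)] for c in _ALGAE_CATEGORIES))
        rows.append(row)
    return pd.DataFrame(rows)
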