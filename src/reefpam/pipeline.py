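"""In-memory campaign analysis: scenario -> feature table without disk I/O.

The WAV-writing route (``simulate_campaign`` + ``scan_corpus`` +
``aggregate_features``) and this in-memory route produce the same feature
table up to 24-bit quantization, which is orders of magnitude below any
feature tolerance; the in-memory route is the convenient one for
simulation studies that sweep scenarios.
"""

from __future__ import annotations

import pandas as pd

from reefpam.calibration import resample
from reefpam.spectral import (
    BandConfig,
    assign_period,
    compute_psd_frames,
    extract_band_features,
    median_psd,
    moon_phase,
)
from reefpam.synthetic import PERIODS, ScenarioConfig, simulate_segment

__all__ = ["features_from_scenario"]


def features_from_scenario(
    scenario: ScenarioConfig,
    bands: list[BandConfig] | None = None,
) -> pd.DataFrame:
    """Feature table (one row per site x day x period x band) for a scenario.

    Each segment is generated, resampled to the band analysis rates, framed,
    median-pooled and reduced to PSD_Fpeak / gammaFpeak — the same chain the
    disk pipeline runs on calibrated WAV audio.
    """
    if bands is None:
        bands = [BandConfig.lf(), BandConfig.hf()]
    rows = []
    for site in scenario.sites:
        for year in scenario.years:
            for day in range(scenario.n_days_per_site):
                for period in PERIODS:
                    seg, _ = simulate_segment(scenario, site, year, day, period)
                    p, anchor = assign_period(seg.start_time)
                    assert p == period
                    for band in bands:
                        rs = resample(seg, band.analysis_rate)
                        freqs, frames = compute_psd_frames(rs, band)
                        ms = median_psd(
                            frames, freqs, band, site=site.site_id, day=anchor, period=period
                        )
                        feat = extract_band_features(ms)
                        rows.append(
                            {
                                "site": site.site_id,
                                "date": anchor.isoformat(),
                                "period": period,
                                "band": band.name,
                                "psd_fpeak_db": feat.psd_fpeak_db,
                                "gamma_fpeak_hz": feat.gamma_fpeak_hz,
                                "n_frames": ms.n_frames,
                                "protection": site.protection,
                                "location": site.location,
                                "year": year,
                                "moon_phase": moon_phase(anchor),
                            }
                        )
    return pd.DataFrame(rows)
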