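# reefpam

Passive-acoustic-monitoring (PAM) analysis of coral-reef soundscapes, as a
tested, reusable Python pipeline — plus a synthetic soundscape generator
that makes the whole chain verifiable against known ground truth.

Reef soundscapes carry ecological signal in two bands: fish choruses below
2 kHz ("mass phenomena") and the broadband crackle of snapping shrimp
between 2 and 22 kHz. Monitoring programs compare these signals across
years, and between marine protected areas (MPA) and adjacent unprotected
controls (nMPA). `reefpam` is for ecoacousticians and quantitative
ecologists who need that comparison to be reproducible end to end: from raw
WAV samples to calibrated µPa pressure, to per-band median spectra, to the
acoustic features, to mixed-model inference with an honest instrumentation
error margin.

## What it computes

**Features.** For each band the recording is resampled (LF: 4 kHz, 256-point
FFT, 75% overlap; HF: 44.1 kHz, 64-point FFT, 50% overlap; Kaiser windows)
and the per-bin median PSD over all frames of one site × calendar day ×
diel period (day 07:00–17:00, night 19:00–05:00) is formed in the linear
domain. Two features summarize each median spectrum:

- `PSD_Fpeak` — the maximum of the median PSD, in dB re 1 µPa² Hz⁻¹;
- `γFpeak` — the frequency at which that maximum occurs.

**Inference.** Each feature is modeled as

    response ~ protection × year + moon_phase,  random intercept ~ location

fit by REML, with type-II Wald χ² tests per fixed term. Because different
years used different recorder chains, a level difference counts as
significant only when p < 0.05 **and** |Δ| > 3 dB. Survey metrics (fish
abundance, species richness, benthic cover) get the same mixed-model
treatment, and community composition is related to benthic plus acoustic
features by canonical correspondence analysis (CCA, ter Braak formulation,
verified against a direct eigenproblem solve and scikit-bio).

**Generator.** `ScenarioConfig` describes a campaign: sites in MPA/nMPA
couplets, years with their recording protocols (48 kHz duty-cycled vs
44.1 kHz continuous), snap-train density and resonance, chorus frequency and
diel levels, ambient slope, and dB `group_offsets` keyed by
(protection, year, band, period) — the injected effects the pipeline must
recover. Identical seeds give byte-identical corpora.

## Worked example

```python
import reefpam as rp
from reefpam.pipeline import features_from_scenario
from reefpam.spectral import BandConfig
from reefpam.synthetic import ScenarioConfig

offsets = {(p, "2021", "LF", "night"): 4.0 for p in ("MPA", "nMPA")}
scenario = ScenarioConfig(n_days_per_site=2, segment_minutes_per_period=1.0,
                          group_offsets=offsets, seed=1)
table = features_from_scenario(scenario)          # one row per site/day/period/band

night_lf = table[(table.band == "LF") & (table.period == "night")]
summary = rp.summarize_group_differences(night_lf, "psd_fpeak_db", "year")
result = rp.fit_ancova(night_lf, "psd_fpeak_db")
call = rp.apply_3db_rule(summary.overall_difference, result.terms["year"].p)
print(round(summary.overall_difference, 2), result.terms["year"].p, call.verdict)
```

prints

```
3.92 6.5173932116367985e-37 significant
```

— the +4 dB nocturnal low-frequency offset injected into the 2021 group is
recovered as a 3.92 dB increase in nocturnal `PSD_Fpeak`, the mixed-model
year term is overwhelming, and the 3 dB rule confirms the call. The same
campaign's low-band `γFpeak` averages 294.4 Hz against a 300 Hz chorus
(bin-quantized at 15.625 Hz), and the high-band `γFpeak` averages 4.82 kHz
against a 5 kHz snap resonance (bin width 689 Hz).

The same analysis runs from disk through the CLI:

```bash
reefpam simulate --out corpus --seed 1
reefpam features --corpus corpus --out features.csv
reefpam stats --features features.csv --survey corpus/survey.csv --out report/
```

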