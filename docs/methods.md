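# Methods

`reefpam` implements a desk-scale version of a passive-acoustic-monitoring
(PAM) analysis for coral-reef soundscapes: calibrated pressure recovery from
single-channel WAV recordings, band-specific power spectral density (PSD)
features extracted from median spectra, and a statistical layer that compares
protection regimes and sampling years while respecting the instrumentation
error between recording systems. Because field recordings are large, a
synthetic soundscape generator with known ground truth stands in for them:
every end-to-end claim the test suite makes is a recovery claim against
quantities the generator injected.

## Signal model of the generator

A generated segment is the sum of three independent processes, in µPa:

1. **Ambient noise** — Gaussian noise with a power-law one-sided PSD
   `S_amb(f) = L_amb + m·log10(f / 1 kHz)` in dB re 1 µPa² Hz⁻¹, default
   `L_amb = 45` dB at 1 kHz and `m = −10` dB/decade, a quiet "pink-ish" sea
   state. Synthesis is by frequency-domain shaping of white Gaussian noise
   (one inverse real FFT per segment).
2. **Fish chorus** — a Gaussian spectral bump
   `S_cho(f) = L_cho · exp(−(f − f₀)² / 2σ²)` with `f₀ = 300` Hz, full width
   at half maximum 100 Hz (`σ = FWHM / 2.355`), and peak levels
   `L_cho = 68` dB (day) / `72` dB (night). Only the chorus PSD matters to
   the downstream analysis, so the chorus is modeled as band-shaped noise
   rather than as summed fish pulses. Because ambient and chorus are
   independent Gaussians, they are drawn jointly from the summed PSD in a
   single synthesis pass.
3. **Snap train** — a Poisson process of exponentially damped sinusoids
   `p(t) = e^(−t/τ) sin(2π f_c t)` with `τ = 0.2` ms, per-snap center
   frequency `f_c ~ N(5000, 300²)` Hz, and lognormal amplitudes (median
   `5·10⁴` µPa, log-sd 0.8). Default rates are 1500 snaps s⁻¹ (day) and
   3000 snaps s⁻¹ (night).

The snap rates deserve a note. A hydrophone on a healthy reef hears the
superposed crackle of very many near and far snapping shrimp, and the field
observable the pipeline extracts — the *median* spectrum over 1.45 ms
analysis frames — peaks at the snap resonance only if most frames contain
snap energy. A sparse train (tens of snaps per second) leaves the median
frame snap-free, and the high-band peak collapses onto the band edge set by
the ambient slope. The defaults therefore model the aggregate crackle as a
dense train of mostly modest amplitudes; the per-snap rate and amplitude
scale are both configurable, and the fc-recovery property is only claimed
for the dense regime.

**Diel structure and group effects.** Day segments start at 12:00 and night
segments at 22:00 local clock, inside the analysis windows 07:00–17:00 and
19:00–05:00. `group_offsets` maps `(protection, year, band, period)` to a dB
offset applied to the chorus level (LF) or snap amplitudes (HF); these are
the effects the statistical layer must recover, and they are recorded
exactly in the ground-truth table.

**Recording protocols.** Two protocols are emulated: a duty-cycled recorder
(48 kHz, sensitivity −181 dB re 1 V µPa⁻¹, gain 10 dB, 5 min recorded per
hour of which 4.4 min are usable — the unusable 0.6 min is discarded from
the end of the take) and a continuous recorder (44.1 kHz, sensitivity
−170 dB, gain 2 dB). WAVs are written as mono 24-bit PCM named
`<site>_<YYYYMMDD>_<HHMMSS>.wav`. The ADC full-scale voltage is derived
analytically from the scenario (lognormal e^(4σ) snap-peak bound plus 5
Gaussian standard deviations, times a factor-2 headroom) so that the
recorder spec is fixed before any audio exists, generated pressure occupies
at most about half of full scale, and calibration exactly inverts
generation. With that headroom the 24-bit quantization noise is ~3·10⁻⁶ of
the signal RMS. Generation runs in single precision; that error is two
orders of magnitude below the 24-bit floor.

## Calibration and resampling

Calibration is the linear map
`p = raw · V_fs / 10^((S + G)/20)` followed by per-segment mean subtraction
(the simplest DC-removal; it avoids leakage into bin 0). Only the sum
`S + G` matters; no frequency-dependent response is modeled. Segments with
more than 0.1% of samples at ≥ 99.9% full scale are flagged as clipped.

Band rates are reached by polyphase rational resampling (never upsampling):
48 → 44.1 kHz for the high band and anything → 4 kHz for the low band. The
anti-alias FIR cuts at 0.9 × the target Nyquist with a transition band of
0.1 × Nyquist, Kaiser-designed for 60 dB stopband. That keeps the PSD flat
(≪ 0.5 dB) up to 0.8 × Nyquist and rejects out-of-band tones by better
than 50 dB; it also means content in the top tenth of the high band is
attenuated for 48 kHz material, an unavoidable property of any 48 → 44.1
conversion chain.

## Spectral features

Two band configurations are fixed by design:

| band | analysis rate | FFT length | overlap | bin width | search range |
|------|--------------:|-----------:|--------:|----------:|--------------|
| LF   | 4 kHz         | 256        | 75%     | 15.625 Hz | (0, 2000] Hz |
| HF   | 44.1 kHz      | 64         | 50%     | 689.0625 Hz | [2000, 22000] Hz |

Frames are Kaiser-windowed (shape β = 5 by default; the sidelobe/width
trade-off is not critical and all acceptance properties hold for
β ∈ {3, 5, 8}); the one-sided PSD uses the standard density scaling
`2 |X_k|² / (f_s Σw²)` with no doubling at DC and Nyquist. Frames never
straddle file boundaries and a trailing partial frame is dropped.

For each site × calendar day × diel period the per-bin **median** over all
frames is taken in the linear power domain and then converted to dB (an
even count uses the midpoint of the central pair; zero-power bins floor at
−200 dB, configurable). The night anchored to date D spans D 19:00 to D+1
05:00 and is one replicate of D. Two features summarize each median
spectrum: `PSD_Fpeak` (the maximum, dB re 1 µPa² Hz⁻¹) and `γFpeak` (the
frequency of the maximum, ties broken toward the lowest frequency). The low
band excludes the DC bin from the search so mooring-like noise cannot win.

A numerical caveat worth stating: for Gaussian noise the per-bin frame PSDs
are approximately exponential, so the *median* spectrum sits at ln 2 ≈ 0.69
of the mean spectrum. Parseval-type checks in this package therefore
integrate the frame-*mean* PSD (which matches the variance to well under
1%), and a dedicated property test pins the median-integrated ratio at
ln 2. Median-based PSD_Fpeak values share this downward bias; it cancels in
every group *difference*, which is what the statistical layer consumes.

The `average_db_audit` Δ — the gap between averaging dB values directly and
averaging in linear power — is reported per cell; it is non-negative by
Jensen's inequality and zero only for constant input.

The moon-phase covariate is the synodic fraction
`frac((t − t_newmoon) / 29.530588853 d)` with the 2000-01-06 18:14 epoch;
0 ≈ new moon, 0.5 ≈ full moon. It enters the models linearly; a sin/cos
circular encoding is easy to add but off by default since the linear
fraction is what the reference analysis used.

## Statistical layer

**Mixed ANCOVA.** Each response (PSD_Fpeak or γFpeak per band × period) is
modeled as `response ~ protection * year + moon_phase` with a random
intercept per location couplet, fit by REML (statsmodels `MixedLM`). Note
the optimizer: L-BFGS can stall at an inferior REML optimum on
near-boundary problems, so the fit cascades bfgs → powell → lbfgs and keeps
the first converged result. Type-II Wald χ² tests are produced per fixed
term by refitting without any term that *contains* the tested term (main
effects are tested in the additive model; the interaction and the covariate
in the full model) and jointly testing the term's coefficients. When the
location variance hits the zero boundary this reproduces ordinary
least-squares type-II ANCOVA to ~10⁻⁴ relative, which is the test-suite
oracle. Zero-variance fits are reported with a boundary flag, not raised.

**The 3 dB rule.** Because the two sampling years used different recorder
chains, a level difference is called significant only when `p < α = 0.05`
*and* |difference| > 3 dB. The rule is monotone: raising the magnitude or
lowering p can never turn a significant call non-significant.

**Survey ANOVA.** Fish abundance, species richness and benthic cover
percentages are compared between protection groups with the same
mixed-model machinery (single fixed factor). Null simulations show the
asymptotic Wald χ² is honestly calibrated (rejection ≈ 0.05) for tables of
about 50+ sites; at 16–24 sites it is anti-conservative (0.09–0.12), which
is a property of Wald tests at small residual df, not of the
implementation. The calibration studies in the acceptance layer therefore
use 96-row ANCOVA tables and 64-site survey tables.

**CCA.** Canonical correspondence analysis follows the ter Braak
formulation: with `P` the community matrix scaled to unit total, row masses
`r`, column masses `c`, the chi-square standardized matrix
`Q = D_r^{−1/2}(P − r cᵀ) D_c^{−1/2}` is regressed (rows weighted by
`√r`) on the centered constraints, and the fitted matrix is decomposed by
SVD. Constrained eigenvalues are squared singular values; residual axes
come from the complement; total inertia is `ΣQ²`. All-zero rows/columns and
aliased constraint columns are dropped with warnings. The implementation is
checked against a brute-force projection-plus-eigensolve oracle and against
scikit-bio's CCA at 10⁻⁸. Community input is relative abundance per site.
Reference ordination figures describe their input as Bray–Curtis based
even though CCA is intrinsically a chi-square-metric method; this package
performs standard chi-square CCA and flags the ambiguity rather than
emulating a hybrid.

## Problem sizes and determinism

Simulation studies are sized for a single CPU: the effect-recovery study
uses the full design (8 sites × 2 years × 3 days × 5-minute segments) on
the low band; the γFpeak-shift study uses 4 sites × 30 s segments; null
calibration uses 1000 replicates of directly simulated feature/survey
tables (no audio). Every stochastic path is driven by
`numpy.random.SeedSequence` keyed on the scenario seed and the segment
coordinates, so a scenario reproduces byte-identical WAV corpora and
tables, and campaigns are trivially parallelizable by segment.

## Known limitations

- No propagation, directionality, recorder self-noise, or vessel noise;
  the generator emulates the *statistical* structure the pipeline assumes,
  so passing tests demonstrate correct recovery of that structure, not
  robustness to every feature of field audio.
- Snap and chorus source levels in µPa are not calibrated against field
  data; defaults place outputs in plausible dB ranges only.
- The HF ground-truth peak level uses Campbell's theorem with the kernel at
  the mean center frequency; it is an expected (mean) level, while the
  pipeline reports median-based levels, so only level *differences* are
  compared against it.
- Aggregation order: one median spectrum is computed per site × day ×
  period from all pooled frames (rather than per file and then averaged);
  with stationary segments the two differ negligibly, but the choice is
  fixed here.
- γFpeak is quantized to analysis bins (15.6 Hz / 689 Hz); recovered shifts
  are only meaningful to one bin.
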