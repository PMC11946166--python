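# Methods

`opusnirs` implements an analysis chain for two-performer continuous-wave
fNIRS recordings made during live concert performances, together with a
synthetic concert generator that provides known ground truth for testing
the chain end to end. This note documents the models, the default
parameters and why they were chosen, the numerical conventions, and the
limitations a user should keep in mind.

## Recording model and geometry

A recording is a strictly positive raw-intensity matrix [samples x
wavelength-channels] at a default 75 Hz, with free-text labelled events.
The default montage is an 18-pair right-hemisphere layout in four optode
groups (4 + 4 + 5 + 5 pairs); the two 5-pair groups each contain one
short-separation channel (SSC). With two laser wavelengths (762 nm and
842 nm — deoxy-dominant and oxy-dominant sides of the ~800 nm isosbestic
point) this yields 36 wavelength-channels: 2 x 16 conventional + 2 x 2
short.

No published optode coordinates exist for this cap class (positions are
registered by hand on the acquisition software's head model), so the
default coordinates are nominal: exact chord-separation placement on an
80 mm sphere, long pairs at 30 mm and short pairs at 8 mm separation —
standard CW-fNIRS practice. The coordinate frame is right-handed RAS in
millimetres with origin at mid-head. The montage is explicitly labelled
nominal geometry; users with digitized positions supply their own YAML
montage or SNIRF probe.

Two performers are recorded on separate machines sharing streamed event
labels. Synchronization is a pure clock translation: the offset is the
mean over shared labels of the onset differences, residuals per label are
reported, and a residual above a configurable tolerance (default 0.1 s —
a package default, since streaming latency was not characterized) is an
error. No drift term is modelled; a shared-trigger setup justifies the
translation-only model. Re-synchronizing an already aligned recording is
refused rather than silently double-shifting.

## Channel-space preprocessing

The chain follows the common Homer-style stream:

1. **Optical density**: dOD(t) = -ln(I(t)/mean_t I), per channel. The
   per-channel temporal mean is the reference — the usual convention where
   the method names the step but not the reference.
2. **Bad-channel screening**: a channel is flagged when the coefficient of
   variation of its raw intensity exceeds 0.15 (dropouts, decoupling) or
   falls below 1e-9 (dead channel). Thresholds are package defaults and
   are logged with the mask. Flagged channels are masked, not deleted, so
   the 36-channel bookkeeping is stable downstream.
3. **Band-pass**: zero-phase (forward-backward) 3rd-order Butterworth,
   defaults 0.01-0.5 Hz. The 0.5 Hz upper edge keeps the hemodynamic band
   and attenuates cardiac pulsation (~1.2 Hz) by well over 20 dB; the low
   edge and order are package defaults, exposed in the configuration.
4. **MBLL inversion**: per pair and sample the 2x2 spectral system
   dOD(lambda) = [eps_HbO(lambda) dHbO + eps_HbR(lambda) dHbR] · L is
   solved. By default L = 1, so concentrations carry molar·mm units (the
   concentration-times-partial-path product CW-fNIRS actually determines);
   enabling path-length scaling divides by distance · DPF (default DPF 6.0
   at both wavelengths) and yields molar. The shipped extinction table
   (`data/extinction_hb.csv`) holds nominal adult HbO2/HHb values at
   762/842 nm interpolated from the widely used compiled spectra; the
   matrix condition number is reported and a singular table is an error.
5. **Block averaging**: pointwise mean across equal-length [start, end)
   epochs with optional per-epoch baseline-mean subtraction; across-epoch
   SD accompanies the mean.

## Short-channel correction

The correction operates on *per-piece summary means* (time-mean HbT per
pair within each piece): the mean of the two SSC values is subtracted from
every long channel, and a negative result is clamped to exactly zero and
flagged low-trust. Both SSCs are pooled (no nearest-SSC pairing). A
sample-wise subtraction of the instantaneous SSC mean trace exists as a
clearly labelled extension, off by default. HbT is the default quantity;
chromophore-wise correction is a configuration option. The companion
dominance report gives mean(SSC)/mean(long) per piece and the fraction of
long channels zeroed — a compact diagnostic of recordings dominated by
superficial physiology.

## Segmentation protocols

Pieces come from "<id>/start" / "<id>/end" event pairs; unmatched labels
are warned about and excluded, and an end before its start is an error.
Three windowing protocols are derived per piece:

| protocol     | baseline            | analysis window          | eligibility |
|--------------|---------------------|--------------------------|-------------|
| whole_piece  | none                | [start, end)             | any piece   |
| initial      | [start-5 s, start)  | [start, start+20 s)      | >= 20 s, 5 s pre-roll |
| mid          | [start-20 s, start) | [start+60 s, start+120 s) within a [start, start+180 s) model span | > 180 s strictly, 20 s pre-roll |

All time-to-sample conversion is floor(t · fs) with half-open intervals,
so 20 s at 75 Hz is exactly 1500 samples. "Longer than three minutes" is
read strictly (a 180.0 s piece is excluded). Baseline correction is
baseline-window mean subtraction per channel/vertex before averaging.
Overlapping pieces (attacca transitions) are allowed but flagged.

## Forward and inverse source model

The template cortex is a Fibonacci-lattice spherical cap of exactly
10,000 vertices at 67 mm radius (13 mm beneath the nominal scalp sphere),
oriented beneath the montage and triangulated by planar Delaunay of the
cap projection. It is bookkeeping geometry, not anatomy; meshes and scout
files from real segmentations can be supplied instead.

Photon fluence uses the extrapolated-boundary Green's function of the
diffusion approximation in a homogeneous semi-infinite medium
(isotropic source at depth 1/mu_s', negative image source across the
extrapolated boundary, effective reflection coefficient 0.493). Default
optical properties are generic adult-head values per wavelength (mu_a
0.019/0.021 per mm, mu_s' 1.1/1.0 per mm at 762/842 nm) and are a
configuration table. Channel sensitivity is the adjoint (Rytov) form
A[ch, v] = Phi(s→v) Phi(v→d) / Phi(s→d), long channels only. Fluences are
tabulated per vertex within a 100 mm range; a vertex beyond range borrows
the fluence of the physically closest tabulated vertex, ties resolved to
the lowest vertex index.

The inverse is a depth-weighted Tikhonov minimum-norm estimate per
wavelength: x = R Aᵀ (A R Aᵀ + λI)⁻¹ y with source-covariance diagonal
R_v = ||a_v||^(-2p), depth exponent p = 0.5, and the depth prior clipped
at 10² times its minimum (the standard weight-limit convention; without
the clip, vertices the montage barely senses amplify noise without
bound). λ defaults to trace(A R Aᵀ)/n_ch/SNR² with SNR 3. The two
wavelength images are converted vertex-wise to HbO/HbR through the same
2x2 extinction system; HbT is their sum. Short channels never enter the
inverse, and no superficial-noise removal stage is applied inside the
source model — the SSC correction above is the only superficial handling,
applied in channel space.

Because the sensitivity is normalized and the mesh truncates the head,
source estimates share the molar·mm-style relative scale of the channel
quantities; the package makes no claim of absolute concentration.

Expected resolution honesty: with 16 long channels the point-spread of
the estimate is of order 2-3 cm. The tests require a noiseless single
source to be localized within 15 mm and two sources separated well beyond
the point spread to be individually recovered within 20 mm at SNR 10;
sources ~10 mm apart are explicitly allowed to merge.

## ROI dissection and confidence intervals

A scout is a named vertex set. The scout average of a source estimate is
the plain mean over (scout vertices x window samples) — equivalently the
sum multiplied by the reciprocal of the vertex count and sample count.
The per-concert statistic is the Student-t interval

    CI = mean(X) ± T · SEM,  SEM = sd(X)/sqrt(n),  T = t_(1-alpha/2, n-1)

computed over X = the per-piece scout-averaged summaries within a concert
(the choice of sample is configurable and recorded in output metadata;
the literal one-sided upper form is available via a flag). Trend tables
order these statistics by concert index; concerts with lost recordings
become explicit gap rows with NaN statistics — missing data is never
interpolated.

Default scouts on the template mesh are geodesic patches sized to the
reference dissection counts on a 10,000-vertex cortex: PRG 107, POG 97,
STG 92, rIFG 144 vertices. They preserve the bookkeeping of an
atlas-based dissection, not its anatomy; real scout files (TSV/JSON) are
user-suppliable.

## Synthetic concert generator

The generator emulates the statistical structure the chain assumes, with
every component controlled by a seeded `GroundTruth`:

- **Cortical activation**: per-scout boxcar (piece on/off) convolved with
  a canonical double-gamma HRF (unit peak ~5 s after onset, undershoot
  from the late gamma), forward-projected through the same sensitivity
  matrix into long-channel dOD. Default peak amplitudes 2.0/1.6/1.2/2.0
  µM·mm (PRG/POG/STG/rIFG) with dHbR = -dHbO/3.
- **Across-concert trend**: the rIFG amplitude declines linearly to 0.1 of
  its initial value across the seven-concert series.
- **Superficial physiology**: one shared trace per recording — Mayer wave
  ~0.1 Hz (0.1 µM·mm), respiration ~0.25 Hz (0.05), cardiac ~1.2 Hz
  (0.2; removed by the band-pass), and a slow positive drift (0.1) —
  added *undiluted* to the short channels and with coupling coefficient
  1.0 to the long channels. The shared-trace assumption is exactly what
  makes averaged-SSC subtraction meaningful, and is stated here
  explicitly.
- **Hair/pigmentation attenuation**: a per-performer multiplicative factor
  on the cortical contribution only (first 0.35, second 1.0), reproducing
  the scenario in which one performer's conventional channels are
  dominated by superficial signal and the SSC-dominance diagnostic fires.
- **Noise and artifacts**: white detector noise (OD sd 5e-6 per sample at
  75 Hz, on the package's normalized-sensitivity OD scale; the meaningful
  quantity is the resulting SNR, at which a 24-epoch block average
  recovers the injected response within 10%), plus sparse
  exponential-decay motion spikes (0.1/min, 5e-3 OD).
- **Events**: "<piece>/start"/"<piece>/end" pairs plus a shared "sync"
  marker; optional Gaussian labelling jitter (sd 1 s class), off by
  default.
- Intensities are produced by inverting the OD model around per-channel
  lognormal baselines, guaranteeing strict positivity; identical seeds
  give identical recordings.

The default seven-concert fixture uses a nine-piece programme of which
exactly five pieces exceed three minutes (durations 90/200/120/240/300/
150/360/420/170 s, 20 s gaps — declared study conditions, since real
piece durations are not on record), and reproduces the loss pattern:
concert 4 missing for the first performer, concerts 4 and 6 for the
second.

What the generator does **not** emulate: realistic anatomy and fluence
heterogeneity, spatially varying superficial physiology (the shared trace
makes SSC correction exact by construction — real scalp signal decorrelates
across the head, so real-world correction is worse), serially correlated
1/f noise, optode-coupling drift, and performer state (anxiety,
habituation). Passing tests therefore demonstrate the chain's internal
correctness and its behaviour under the stated assumptions, not expected
performance on real concert recordings — where, as the dominance
diagnostic makes visible, superficial signal can dominate.

## Numerical choices and degenerate inputs

- Intervals are half-open everywhere; sample index = floor(t · fs).
- Fluence nearest-vertex ties break to the lowest vertex index.
- The MBLL system is refused when the extinction matrix is singular;
  path-length scaling is refused at zero source-detector distance.
- A piece failing a protocol precondition is skipped with a reason, not
  an error; a zero-length piece is an error.
- Source estimation decimates the band-limited (<= 0.5 Hz) dOD to 5 Hz
  before the solve — a lossless step given the band, keeping
  10,000-vertex estimates small; the decimation factor is configurable.
- The t quantile comes from scipy.stats; sample SD uses the n-1
  denominator.

## Known limitations

- The nominal montage and toy cortex support bookkeeping and simulation,
  not anatomical inference; PRG/POG separability in particular is beyond
  the montage's resolution.
- The minimum-norm estimate inherits the usual amplitude bias toward
  well-sensed vertices; amplitudes are comparable across conditions, not
  absolute.
- The SSC correction operates on per-piece summaries (with a labelled
  sample-wise extension); it is not a GLM-based short-channel regression.
- Whole-piece protocol values have no baseline reference by design and
  should be compared only within a recording.
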