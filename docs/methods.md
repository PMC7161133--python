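# Methods

## Signal model and simulator

Each cardiac source (one maternal, up to two fetal) is a rotating
current dipole. Morphology is a sum of Gaussians over cardiac phase θ
∈ [−π, π): one Gaussian per wave (P, Q, R, S, T) per dipole axis,
with the R wave centred at θ = 0. Beat times come from i.i.d. Gaussian
inter-beat intervals (mean 60/HR, sd chosen so the heart-rate sd in
bpm matches the requested value; truncated to 30–300 bpm); phase ramps
linearly by 2π per beat, so each complex's duration stretches with its
RR interval — this is the main source of beat-to-beat morphology
variation, and it is what the maternal template's per-beat fit must
absorb. The first beat falls half an interval after recording start so
no complex is clipped at the edges.

Volume conduction is an infinite homogeneous medium: the potential of
dipole **m** at distance vector **r** is φ = k (m·r̂)/|r|², with gain
k = 2×10⁴ µV·cm²/mV chosen once so the default maternal source
projects an abdominal QRS of a few hundred µV. Bipolar channels are
formed by a derivation matrix (each measurement electrode against a
common reference; the ground electrode contributes nothing). This
reproduces the two behaviours that matter for twin separation:
amplitude falls with distance to the fetal heart, and dipoles pointing
toward vs away from an electrode flip the QRS polarity — so the two
fetuses deflect the midline channel in opposite directions.

The canonical heart frame puts the electrical long axis (apex
direction) on axis 1; the QRS third-axis amplitude is small (0.03 of
the long axis) so that flipping presentation — a 180° rotation about
the maternal transverse axis — reverses the dominant QRS axis almost
exactly, as the normal-heart-axis assumption implies. In the maternal
frame a cephalic fetus projects its long axis cranially (+y), breech
caudally.

Default study conditions (all configurable): 6 channels at 500 Hz;
maternal HR 85 ± 3 bpm; fetal HRs 140 ± 4 (right side, cephalic) and
155 ± 4 bpm (left side, breech) — distinct rates keep the trains
asynchronous; channel-averaged fetal:maternal QRS amplitude near
1:10; baseline wander 30 µV below 0.7 Hz; powerline 20 µV at 50 Hz
(Dutch mains; configurable to 60 Hz); white noise 5 µV. Every
stochastic element is driven by one scenario seed through spawned
generators, so identical scenarios reproduce identical recordings and
the mixture minus the returned per-source clean signals equals the
noise exactly.

What the simulator does **not** emulate: fetal movement during the
recording, uterine activity (EHG), multi-layer volume conduction
(vernix caseosa), electrode contact artifacts, and maternal
arrhythmia. Passing tests therefore demonstrate the pipeline's
correctness under quasi-stationary geometry and additive stationary
noise, not robustness to motion or contact artifacts in clinical
recordings.

## Preprocessing

Fourth-order Butterworth filters applied forward-backward
(zero-phase): high-pass 1 Hz, low-pass 90 Hz, notch 50 Hz with 2 Hz
bandwidth (second-order prototype, one harmonic by default). The
passband retains the fetal QRS band (~10–70 Hz). Zero phase is
mandated so detected R-peak times are unbiased for beat-to-beat FHR.

## Maternal suppression

R peaks are detected per channel with an 8–40 Hz zero-phase band
envelope (polarity-insensitive), 250 ms refractory, threshold at 0.4 ×
the envelope's 99th percentile, peaks refined to the band-passed
extremum. Channel choice: among channels whose train is plausible
(rate 40–160 bpm, RR coefficient of variation ≤ 0.25), the one with
the largest median QRS-band amplitude at the peaks — amplitude, not
beat count, because a regular *fetal* rhythm can fall inside the
maternal rate band, while the maternal ECG is always the
amplitude-dominant abdominal source.

The template is an exponentially forgetting running mean (forgetting
factor 0.9) of beat-aligned windows, 250 ms pre-R to 350 ms post-R
(covering P-QRS-T at maternal rates while staying inside the median
RR at 85 bpm; a window beyond the median RR is rejected). "Dynamic"
subtraction: each beat is fitted per channel and per segment (P, QRS
±60 ms, T) with two regressors — the template and its time derivative
(absorbing sub-sample misalignment) — with one robust reweighting
pass that masks >3σ outlier samples so a fetal QRS crossing the
window is not absorbed into the fit (and hence not subtracted out of
the fetal signal). Overlapping windows are truncated at RR midpoints;
windows crossing the recording edge are skipped with a logged
warning; samples outside all windows are bit-identical to the input.
The subtraction leaves a small constant offset inside the windows
(only windowed content is removed); amplitude measurements downstream
are therefore always baseline-corrected.

## Twin separation

Candidate QRS trains are detected per channel on the residual (10–45
Hz envelope, 200 ms refractory, 100–200 bpm band). Trains are grouped
by regularity and mutual beat coincidence: the most regular plausible
train (cv ≤ 0.3) seeds cluster one; the most regular train sharing
<30% of its beats (30 ms tolerance) seeds cluster two. Channels seeing
a mixture of both fetuses produce irregular RR series and are never
selected as representatives.

Weights: each train's beat-locked average complex is deflated from
the mixture before forming the *other* train's ensemble-QRS matrix M
(channels × ±60 ms window), so cross-contamination does not cap the
achievable suppression. The weight for fetus i is constrained to the
orthogonal complement of the other fetus's reliably estimated
ensemble-QRS directions — directions whose singular value exceeds
max(0.01 σ₁, 10 × the trailing-spectrum floor), so all three dipole
axes are nulled exactly in the noise-free case while poorly estimated
noisy directions are left to the averaging stages — and within that
complement maximizes own-QRS energy wᵀMMᵀw against wᵀCw, where C is
the covariance of the non-beat-locked background (maternal
subtraction leftover plus noise) with a ridge of 0.1 × mean own-QRS
power. The ridge makes the weight tend to the matched filter when
interference is negligible and keeps whitening fully active when it
dominates. If the null constraint removes >85% of own-QRS energy the
mixing vectors are collinear and a *twins-not-separable* error with
diagnostics is raised. A `manual` mode accepts user-specified weights
verbatim. Labels are deterministic: the lower-rate train is fetus A.

Distinctness: fraction of A-beats with a B-beat within 30 ms, overall
and in sliding 60 s windows; any window above 0.5 flags possible
same-source duplication (independent rhythms coincide only at the
chance rate ≈ 2·tol·rate ≈ 0.15).

## Ensemble averaging

Windows 100 ms pre-R to 300 ms post-R (QRS and T at fetal rates).
Edge-crossing beats are dropped and counted. Artifact rejection
(default on, disableable) correlates each beat against the pointwise
median beat — in the QRS region of the channel where the median beat
is strongest, because whole-window multi-channel correlation is
dominated by asynchronous interference — and drops beats below 0.5.
The ensemble records the per-channel standard error of the mean
(interference surviving the average), which the VCG stage uses as
channel weights. Averaging shrinks noise as 1/√N and attenuates the
asynchronous co-twin similarly.

## Vectorcardiogram and presentation

The fetal heart is localized by minimizing the relative misfit of a
single-dipole model over a coarse 2 cm grid, followed by a bounded
Nelder-Mead polish; rows are weighted by inverse ensemble noise. The
search box spans the measurement electrodes laterally but stops ~4 cm
cranial of their median height: the patch is laid out with its lower
rows over the uterus, and an unbounded search lets maternal leftover
near the fundus electrode capture the fit. Ultrasound-derived
coordinates can be supplied instead and take precedence.

The loop is the weighted least-squares dipole inverse of the
(baseline-corrected) ensemble at every sample; the lead-field
condition number is reported and a rank-deficient geometry (e.g.
collinear electrodes) raises an error. The dominant axis is the
principal direction of the QRS loop segment (±60 ms), signed by the
maximal-excursion point — more stable under ensemble contamination
than the single farthest loop point. Presentation: cephalic if the
axis's craniocaudal component exceeds +0.1, breech below −0.1,
otherwise *indeterminate* (never a guess). Side is the sign of the
localized heart's transverse coordinate. When comparing the same
fetus across presentations the heart is localized once and both loops
are inverted at that position (the heart does not move when the
presentation label flips).

## FHR output

Rates are 60/RR per successive detected beat pair. Intervals implying
<30 or >300 bpm are gap-masked; adjacent-interval jumps >25 bpm are
flagged (a missed beat at 140 bpm produces a plausible ≈70 bpm
interval that only the jump detector catches). Display traces are 4
Hz sample-and-hold; gaps propagate as missing values — a monitor must
never invent heart rate. Evaluation against simulator truth uses
one-to-one nearest matching at 50 ms tolerance (sensitivity, PPV) and
FHR RMSE over intervals whose both endpoints matched.

## Problem sizes and numerical choices

The test suite simulates 45–120 s recordings for unit-level checks, a
10-minute recording for the twin-tracking checks, and forty 45 s
randomized scenarios for blinded presentation recovery; these sizes
give a few hundred to ~1500 beats per rhythm, enough that
ensemble-derived quantities are stable. The acceptance script uses
60 s noise-free runs (~135 fetal beats each). Seeds are fixed
throughout; every stochastic operation is reproducible. Degenerate
inputs (zero signal, empty beat trains, windows off the recording
edge, rank-deficient geometry, coincident source and electrode) raise
descriptive errors rather than propagating NaNs.

## Known limitations

- The infinite-homogeneous-medium lead field ignores tissue layers;
  absolute VCG amplitudes are in arbitrary (mV-equivalent) units.
- Heart localization has an intrinsic depth ambiguity (condition
  numbers ~3–10); the presentation call depends only on the axis sign
  and tolerates several cm of localization error, but loop *shape*
  accuracy degrades away from the true position.
- Separation assumes two distinguishable mixing signatures; true
  mixing collinearity (hearts nearly coincident) is reported as an
  error, not resolved.
- The RR model is stationary Gaussian; spectral heart-rate-variability
  structure (and its clinical analysis) is out of scope.
- Blind source separation is deliberately not used; separation relies
  on beat-train structure and linear combinations only.
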