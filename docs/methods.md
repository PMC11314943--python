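# Methods

`radarposture` implements a complete bedside multi-radar sleep-posture
pipeline: a physics-motivated simulator of impulse-radio ultra-wideband
(IR-UWB) radar frames, static-clutter suppression, projection of 1D range
profiles onto a bed-aligned 2D grid (the Spatial Radar Echo Map, SREM), a
multiview CNN posture classifier, and a pre-planned radar-subset ablation
protocol.  This note records the models, the assumptions, the defaults and
why, and what the synthetic experiments do and do not demonstrate.

## Geometry and hardware model

The bed frame puts the origin at the headboard-left mattress corner, x
across the 90 cm width, y along the 196 cm length.  Eight radar slots
surround the bed: HL, HC, HR behind the headboard looking in +y, and
S1..S5 along one long side at 15 cm spacing looking in +x, all offset
20 cm outward from the bed edge.  The reference setup states edge offsets,
spacings and mounting heights but no absolute coordinates, so the defaults
place the head radars at x = 20, 45, 70 cm and the side radars at
y = 30..90 cm (upper-body biased, consistent with side radars aimed at
body, torso and limbs); both are plain config values that can be
overridden via the JSON geometry schema.

Each radar reports a range profile of 1536 fast-time bins over a 9.87 m
frame, i.e. 0.643 cm per bin, at 20 frames/s, with a usable azimuth sector
of ±65° about boresight.  The hardware table of the reference system also
lists a 2.0 m detection-range setting with 312 bins; bin count and maximum
range are therefore free parameters constrained only by
`bin_length = max_range / n_bins`, with the 1536-bin values as defaults.
Mounting heights exist in the geometry (`heights=True`) but distances are
evaluated in the bed plane by default, because the echo-map algorithm is
strictly two-dimensional; a `3d` distance mode is available.  Cell
positions use the cell-center convention, which keeps the map symmetric
and avoids a zero-distance singularity when a radar coincides with a grid
corner.

## Synthetic data generator

No public dataset of bedside IR-UWB recordings with posture labels exists,
so the generator is a first-class, tested component, not a fixture.  A
body is 11 point scatterers (head, shoulders, chest, abdomen, hips,
thighs, lower legs) whose layout encodes the posture:

* supine — midline template, legs extended;
* lateral log / half-stomach / fetal — body shifted 8 cm toward the lying
  side with the transverse spread compressed to 60 % (stacked shoulders
  and hips); fetal pulls both lower-leg scatterers cranially (shorter
  longitudinal extent than log), half-stomach flexes only the top leg
  (asymmetric);
* prone — midline, trunk reflectivity reduced to 70 % (the back presents
  a weaker specular return than the chest) and the head scatterer offset
  8 cm toward the turned side.

Right-side postures are exact mirror images of the left templates about
the bed midline before jitter, which gives the generator a provable
mirror-equivariance property.  Per-subject width/height multipliers are
drawn once per subject (σ = 0.08/0.06, clipped to ±20 %); per-sample
anatomical jitter is 1.5 cm in position and 8 % in reflectivity.

A frame is synthesised as the superposition of per-scatterer returns.
The received signal is modelled as a sum of P discrete multipath
components plus channel noise, y(t) = Σᵢ Aᵢ δ(t − τᵢ) + n(t); after
discretisation each scatterer deposits amplitude

    A = reflectivity × blanket_attenuation × cos-taper(azimuth) / R^k

at its fractional range bin (R in metres, floored at 0.3 m; path-loss
exponent k = 2 by default — a one-way spreading law on a reflectivity
map, as no radar equation is prescribed for this task).  The delta is
broadened by a Gaussian point-spread of σ = 16.6 bins, matching the
c/(2·B) ≈ 0.107 m range resolution of a 1.4 GHz-bandwidth pulse.  Static
room clutter (a deterministic ring-down decay plus two fixed furniture
returns) is added identically to every pulse, and i.i.d. Gaussian noise
(σ = 0.02) on top.

**Scintillation.** Body returns are multiplied by a per-pulse factor
1 + σ_s·ε (σ_s = 0.15, ε ~ N(0,1), clipped at zero).  This represents the
residual micro-motion of a breathing sleeper and is what makes slow-time
mean subtraction meaningful: a perfectly frozen body would be cancelled
together with the clutter, leaving the pipeline nothing to classify.  The
scintillation carries no temporal structure — vital-sign waveforms,
posture transitions and any slow-time feature extraction are deliberately
out of scope.  With `scintillation=0` the generator produces strictly
static frames (every slow-time column identical), which is the regime the
energy-invariance tests exercise.

**Blankets** are modelled as multiplicative attenuation (thick 0.5,
medium 0.7, thin 0.85) plus a weak diffuse return 5 cm in front of each
scatterer scaling with (1 − attenuation).  The reference experiment
treats blankets as conditions, not a model, so these factors are
assumptions chosen to degrade, but not destroy, class separability.

Datasets follow the factorial design subjects × 9 postures × 3 blanket
conditions × 3 trials (70 subjects gives the reference 5670 samples).
Reproducibility is keyed hierarchically: every (subject, posture,
blanket, trial, radar) cell has its own child RNG derived from the root
seed and the cell indices, so any subset regenerates identically
regardless of generation order.

## Preprocessing

Clutter suppression subtracts each range bin's slow-time mean,
X′[n,m] = X[n,m] − (1/M) Σᵢ X[n,i].  (The published formula reuses the
bin count N as the averaging length; per-bin averaging over slow time is
the standard clutter-removal reading and is what is implemented.)  The
operation exactly removes any slow-time-constant component, leaves every
bin with zero mean, and is idempotent.  The 1D intensity profile is then
the per-bin RMS over slow time (`envelope`, default — robust to per-pulse
fluctuation) or the magnitude of one chosen pulse (`column`, the literal
"frame at a specific time instance" reading).  Profiles are non-negative
magnitudes by default because the map interpolation treats them as
intensities.

## Spatial Radar Echo Map

The bed grid defaults to one bin per cell (0.643 cm), giving
int(90/0.643) × int(196/0.643) = 139 × 304 cells.  For each cell at
distance D from the radar, with bin spacing d, the bracketing bins
b_small = ⌊D/d⌋ and b_large = ⌈D/d⌉ are blended.  The published recipe
weights b_small by (D mod d)/d and b_large by the complement — i.e. the
*nearer* bin gets the *smaller* weight, the inverse of standard linear
interpolation.  Both weightings are implemented (`as_printed`, the
default, for fidelity; `corrected` for conventional interpolation); the
weights sum to one in either mode, so the choice redistributes intensity
between neighbouring bins rather than changing totals.  Cells whose
b_large would fall past the last bin get zero (clamping would smear the
final bin over the rest of the map), and cells outside the ±65° azimuth
sector are zeroed by default, producing the sector-shaped maps the
method describes; unmasked mode reproduces the literal algorithm.
Multi-frame accumulation (summing per-profile maps) is provided; the
default pipeline uses a single profile per sample.

Views are stacked in the fixed canonical order HL, HC, HR, S1..S5 and
min-max normalised per view to [0, 1] (a constant view normalises to
zeros rather than NaN).  Per-view normalisation equalises the large
range-dependent amplitude differences between radars at the cost of
erasing absolute intensity; relative structure within a view survives.

## Multiview CNN

One shared convolutional backbone embeds each view; an element-wise
pooling across the view axis fuses the embeddings; a fully connected head
classifies.  Pooling is element-wise max by default (the original
multiview-CNN design), with mean pooling available; max pooling makes the
model invariant to view order and indifferent to view count, which is
what allows retraining under arbitrary radar subsets.

No deep-learning framework is a dependency: the layers (3×3 same-padding
convolution via im2col, ReLU, 2×2 max pool, global average pooling,
dense, residual and densely-connected blocks), softmax cross-entropy and
AdamW are implemented in NumPy with explicit backward passes, and every
analytic gradient is verified against central finite differences in the
test suite.  Three backbones are provided at CPU scale: `tiny_cnn`
(3 conv blocks, 16/32/64 channels, ~28 k parameters, the default),
`resnet_mini` (residual blocks) and `densenet_mini` (dense
concatenation blocks).  The full-scale extractors of the reference study
(ResNet-50, DenseNet-121, EfficientNet-B0, PHResNet-50, Attention-56,
Swin) are registered as stubs that fail with guidance; two of them are
reported non-convergent on this task in the original evaluation, and
their published per-configuration accuracies ship as a fixture instead
(see below).

Training uses cross-entropy with AdamW at learning rate 0.001 and betas
(0.9, 0.999) — the recipe prescribed for this task — with weight decay
0.01 on weights only, batch size 16, 30 epochs by default (both
unstated upstream, config-exposed).  Inputs are SREMs bilinearly resized
to 32×32; at tiny-backbone scale nothing is gained from larger inputs and
training stays in seconds-to-minutes on one CPU core.  No pretrained
weights exist for single-channel echo maps, so initialisation is He
normal from the model seed.  Training is bit-reproducible given the seed.

Labels come in two granularities: the 9-class fine scheme (S, L.Log,
L.Sto, L.Fet, R.Log, R.Sto, R.Fet, L.Pr, R.Pr) and the 4-class coarse
scheme (Supine ← S; Left ← L.Log/L.Sto/L.Fet; Right ← R.Log/R.Sto/R.Fet;
Prone ← L.Pr/R.Pr).

## Ablation protocol

The registry holds the 22 pre-planned radar subsets of the reference
protocol (baseline; single-head-radar variants; side-radar removal with
the central head radar retained; down to the 2-radar {S3, HC} setting),
with radar counts 8,7,7,7,6,6,6,5×6,4×7,3,2.  Splits are subject-wise
(all samples of a subject on one side) at the 55:15 proportion scaled to
the available subject count, and one shared split is used across all
configurations so that accuracy differences reflect the radar masks
alone; each configuration retrains from scratch with a seed offset of
1000 × config_id.  Because views are normalised independently, slicing a
pre-computed 8-view stack is exactly equivalent to rebuilding stacks
under the mask.

Radar-count aggregation averages accuracy per (model, count) and rounds
half-up to 3 decimals.  The group mean is computed in exact decimal
arithmetic on the printed values: binary floating point misrounds
borderline cases (the mean of 0.698, 0.707, 0.698, 0.708, 0.691, 0.707
is exactly 0.7015, whose float is 0.70149999…), and decimal arithmetic
reproduces the arithmetic done on the published numbers.  The published
per-configuration accuracies of the four reference backbones are packaged
(`data/reference_accuracies.csv`) so this aggregation is verifiable
without any retraining.

## Problem sizes and what the experiments show

The synthetic experiments run at desk scale, chosen once: 20 subjects ×
9 postures × thin blanket × 1 trial (180 samples), 16 pulses per frame,
32×32 inputs, `tiny_cnn`, 15 training epochs, subject-wise 16:4 split.
Under these conditions the held-out 4-class accuracy is ≈ 0.86–0.92 and
the 8-radar baseline scores at least as high as the 2-radar configuration
when averaged over 3 seeds.

These results demonstrate that the pipeline is *internally consistent* —
the maps preserve enough posture geometry for a small classifier to
recover labels across unseen subjects, and more radars do not hurt.  They
do not validate physical fidelity: the phantom is a caricature (11 point
scatterers, no limbs' continuous surfaces, no real tissue scattering, no
vital-sign modulation, no multipath off walls or bed frame), blanket
effects are a guessed attenuation model, and the published real-data
accuracies (e.g. 0.804 coarse baseline) are context, not a target —
they cannot be reproduced without the withheld human dataset.

## Numerical choices and degenerate inputs

* Interpolation weights always sum to one; D mod d = 0 collapses both
  modes to the single exact bin.
* Map generation caches the per-(radar, grid) projection (bin indices,
  weights, sector mask), which dominates SREM cost.
* Min-max normalisation of a constant view returns zeros, never NaN.
* Clutter suppression refuses single-pulse frames (the mean would null
  the signal).
* Max-pool gradient ties route to the first maximum; the view-pool
  gradient routes to the argmax view per feature.
* Path-loss range is floored at 0.3 m to avoid near-field blow-up.
* Scatterers beyond a radar's unambiguous range contribute nothing (no
  wrap-around), and the RNG stream is kept aligned so geometry changes
  do not shift downstream draws.

## Known limitations

* No elevation/antenna-pattern model beyond the hard azimuth cutoff with
  a cosine taper.
* No temporal features: single-instant maps only, by design.
* The NumPy network trains single-threaded; the heavy published
  backbones are out of scope and their accuracies enter only as packaged
  reference numbers.
* Phantom realism is unvalidated by construction; acceptance rests on
  class separability and algorithmic invariants, not physical fidelity.
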