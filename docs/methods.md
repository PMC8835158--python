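# Methods

`eegdyn` implements a complete spatio-temporal analysis of resting-state
EEG — microstate segmentation for the temporal dimension, omega spatial
complexity for the spatial dimension, a two-group statistical battery,
and nested cross-validated SVM classification — together with a
synthetic-cohort generator that plants known ground truth so every stage
can be validated end to end.

## Preprocessing

A continuous recording (time x channel, µV) is band-pass filtered
0.5-45 Hz with a Hamming-window FIR (transition width ~1 Hz at the low
edge). The symmetric FIR is applied in a single centred pass by FFT
convolution with reflect padding; a linear-phase kernel applied this way
is exactly zero-phase, and it avoids the slow time-domain path that
forward-backward filtering takes for long kernels. A 50 Hz IIR notch
(zero-phase, Q=30) follows when it lies below Nyquist. The signal is cut
into non-overlapping 2-s epochs (trailing partial epoch discarded),
re-referenced to the common average, and screened by a deterministic
amplitude criterion: any epoch exceeding ±100 µV on any channel is
dropped. Manual independent-component artifact removal is intentionally
not offered — it is operator-dependent and irreproducible; the amplitude
screen is sufficient for synthetic data and a reasonable default for
clean resting recordings.

The analysis montage is a fixed 30-channel 10/10 layout (a 32-electrode
cap recorded against CPz with AFz ground). Two 7-channel regional sets
are defined on it: anterior {Fp1, Fp2, F7, F3, Fz, F4, F8} and posterior
{T5, T6, P3, P4, Pz, O1, O2}.

## Microstate analysis (temporal dynamics)

Epochs are further filtered to 2-20 Hz. Because that band's low edge
would require an FIR longer than a 2-s epoch, this stage uses a
zero-phase 4th-order Butterworth (applied forward and backward), which
meets the same passband/stopband behaviour the tests assert (10 Hz
within 1 dB; 1 Hz and 30 Hz attenuated by at least 20 dB).

Global field power, GFP(t) = sqrt(Σᵢ(vᵢ(t) − v̄(t))²/n), is the spatial
standard deviation of the scalp map. Topographies at strict local GFP
maxima (never epoch boundaries) carry the highest signal-to-noise and
are the clustering input; per subject at most 1000 peak maps are kept by
even subsampling (300 in the cohort-scale tests).

**TAAHC.** Topographic Atomize & Agglomerate Hierarchical Clustering
starts from singleton clusters and repeatedly *atomizes* the cluster
contributing least to global explained variance, reassigning each of its
member maps to the surviving cluster whose prototype correlates best
with it, until K=4 clusters remain. Polarity is ignored: similarity is
the absolute spatial (Pearson) correlation of average-referenced maps,
and each prototype is the first principal direction of its member maps
(the sign-invariant generalization of the mean map). Member maps are
weighted by squared GFP. The procedure is fully deterministic; ties
break toward the lowest cluster index. K is fixed at 4; no model-order
selection is attempted.

**Group decomposition** is two-stage: each subject's peak maps are
clustered to 4 prototypes, the pooled subject prototypes are clustered
again to 4 group maps. This weights subjects equally regardless of how
many peaks they contribute. Group prototypes are assigned canonical A-D
identities by solving the 4x4 assignment problem that maximizes total
absolute correlation with built-in template maps (A: left-posterior to
right-anterior gradient, B: its mirror, C: anterior-posterior, D:
fronto-central focal), constructed from the electrode layout.

**Backfitting** labels each GFP peak with the prototype of highest
absolute correlation; every other sample inherits the label of the
nearest peak within its epoch (ties to the earlier peak). No temporal
smoothing or minimum-duration pruning is applied by default. Goodness
of fit is the global explained variance,
GEV = Σₜ(GFP(t)·corr(v(t), p_label(t)))² / Σₜ GFP(t)².

**Parameters.** Per class: mean lifetime (ms) of complete segments
(segments truncated by an epoch boundary are excluded from lifetime and
occurrence, since their true extent is unknown, but still count toward
contribution), occurrence (complete segments per second), contribution
(percent of samples), and the 4x4 transition-probability matrix counted
over adjacent within-epoch segment pairs (zero diagonal, rows
normalized; 12 informative cells). Contributions sum to 100% by
construction; all quantities are invariant to global sign and amplitude
scaling of the data.

## Omega complexity (spatial dynamics)

Per 2-s epoch each channel is Hann-tapered and Fourier transformed
(0.5 Hz bins). For each bin f the cross-spectral matrix C(f) is the
average over epochs of the outer product u(f)u(f)ᴴ of the channel
coefficient vector. Averaging across epochs is essential: a single
epoch's outer product is rank one, so omega computed per epoch would
degenerate to 1 identically. Eigenvalues of C(f) are trace-normalized,
λ'ᵢ = λᵢ/Σλ, and

Ω(f) = exp(−Σᵢ λ'ᵢ ln λ'ᵢ),  with 0·ln 0 := 0.

Ω ranges from 1 (a single spatial mode — complete synchronization) to K,
the channel count (uniform spectrum — no synchronization), and is
invariant to global rescaling of the data. Band values are arithmetic
means of per-bin omega over seven bands — delta 1-3.5, theta 4-7.5,
alpha-1 8-10, alpha-2 11-13, beta-1 13-20, beta-2 20-30, gamma
30-45 Hz — with shared edges resolved half-open [low, high), so the
13 Hz bin belongs to beta-1 only. Scopes: global (30x30) and
anterior/posterior regional (7x7) matrices. Only trace normalization is
applied by default, matching the definition exactly; a
correlation-normalized variant (unit-diagonal rescaling before the
eigen-decomposition, removing per-channel power differences) is
available behind the ``normalize="correlation"`` flag.

Finite-sample note: C(f) estimated from E epochs has rank ≤ E, so the
global Ω is bounded by min(30, E) and biased downward when E is small.
The cohort generator's default 60-s recordings give 30 epochs precisely
so the global matrix can reach full rank; short test fixtures accept the
bias since group contrasts affect both groups equally.

## Synthetic cohorts

A recording is signal + structured noise with every generative choice
exposed:

- **State sequence**: semi-Markov. Per-class lifetimes are gamma
  distributed with shape 4 (positive, unimodal, far fewer implausibly
  short segments than an exponential) around per-class means (default
  80 ms; the canonical resting range is 60-120 ms). Successive classes
  follow a row-stochastic, zero-diagonal transition matrix (uniform by
  default, or proportional to requested occurrence rates), so adjacent
  segments always differ.
- **Signal**: prototype[label(t)] x a unit-variance 8-12 Hz noise
  carrier (the dominant resting rhythm, inside the 2-20 Hz analysis
  band) x amplitude (15 µV). Prototypes are seeded jittered copies of
  the canonical templates, pairwise |r| < 0.8.
- **Noise**: white sensor noise mixed (weight 0.6) with spatially
  smooth noise whose channel covariance decays exponentially with
  electrode distance (e-folding 0.5 head radii) — plain white noise is
  unrealistically easy to cluster. Total noise power is signal power /
  SNR (default SNR 10).
- **Band components**: optional narrow-band processes (defaults:
  beta-2 20-30 Hz and gamma 30-45 Hz at 0.4 x signal power) in which
  each channel carries sqrt(ρ) of a common source plus sqrt(1−ρ) of its
  own source. ρ (default 0.2) sets the band's expected synchronization;
  raising it lowers omega in that band.
- **Mode-mixture generator**: for synchronization studies alone,
  channels are partitioned round-robin over n_modes independent
  band-limited sources; with balanced equal-weight partitions the
  planted omega equals the mode count.

**Cohorts** have two groups ("HC", "ScD"). A named effect map rescales
group-2 generator parameters — by default class-B occurrence x1.3
(transition-matrix column scaling), class-C mean duration x1/1.3
(which also lowers class-C contribution), and +0.25 common-mode share
in beta-2/gamma (lowering omega there). Each affected subject draws an
effect strength ~ N(1, 0.2) that interpolates the multipliers, and the
symptom score is a linear function of that strength plus Gaussian noise
(SD 2.5), clipped into disjoint screening windows (controls 0-13,
subclinical 14-27 on a BDI-II-like 0-63 scale). All randomness descends
from one SeedSequence, so cohorts are bit-reproducible.

What the generator does *not* emulate: volume-conducted dipolar sources
or any forward head model, 1/f background spectra, ocular/muscle
artifacts, eyes-open data, nonstationarity across the session, or
inter-subject topographic variability (one prototype set per cohort).
Passing tests therefore demonstrate correctness of the algorithms and
sensitivity under idealized resting-like structure, not performance on
real clinical recordings.

## Statistics

Mixed repeated-measures ANOVA (between: group; within: microstate class,
transition pair, or scalp region) uses pingouin's implementation.
When the within factor has more than two levels and Mauchly's test
rejects sphericity at p < 0.05, Greenhouse-Geisser-corrected p-values
are reported for the within and interaction effects (the interaction
correction recomputed from the GG epsilon, which pingouin applies only
to the within row). Partial η² = SS_effect/(SS_effect+SS_error). A
structurally degenerate effect (0/0, e.g. the between-group test on
contributions, which sum to 100 for every subject) is reported as F=0,
p=1. Post hoc group comparisons are independent t-tests with Bonferroni
correction (p_adj = min(1, m·p)) and pooled-SD Cohen's d. Non-normal
data fall back to the two-sample rank-sum test (exact enumeration for
tie-free samples up to n=25 per group, tie-corrected normal
approximation with continuity correction beyond). Symptom-score
associations use Spearman's rank correlation.

## Classification

Feature sets mirror the discriminative indicators: microstate =
{occurrence B, duration C, contribution C}; omega = {anterior and
posterior theta, beta-2, gamma; global beta-2, gamma}; combined = their
union. Features are z-scored with statistics fitted on training rows
only (constant features dropped with a warning). SVMs with linear and
Gaussian-RBF kernels are tuned by grid search over C ∈ 10^{−2..2} and
(RBF) gamma ∈ 10^{−3..1}, five log steps each, inside a nested
cross-validation: leave-one-out outer loop, stratified 5-fold inner loop
(shuffled with a fixed seed; folds shrink automatically if a class has
fewer members). Scaling and tuning live inside the inner pipeline, so
the held-out subject never leaks into them — a property asserted
structurally in the tests by refitting a fold without its held-out row
and reproducing its prediction exactly. Accuracy is the mean out-of-fold
correctness; AUC is computed from the pooled out-of-fold decision values
(per-fold AUC is undefined for single-subject folds) and equals the
tie-adjusted Mann-Whitney probability.

One caveat of this design is worth knowing: leave-one-out removes one
subject, so every outer training set is imbalanced by one against the
held-out subject's class; with a plain SVM this anti-correlates the
pooled decision offsets with the held-out labels and biases null-data
AUC well below 0.5 (≈0.39 at n=40 in our measurements). The SVMs
therefore use balanced class weights by default, which compensates the
per-fold imbalance and restores chance-level null AUC (≈0.48 at n=40)
while leaving balanced-training behaviour unchanged.

## Numerical and degenerate-input choices

- Spatial correlation is the Pearson correlation of average-referenced
  maps; zero-norm maps are mapped to zero correlation.
- Cross-spectral eigenvalues are clipped at zero before normalization;
  a zero-trace matrix raises rather than returning a value.
- GFP peaks require strictly larger neighbours; plateaus yield no peak.
- Epochs without any GFP peak fall back to per-sample assignment in
  backfitting.
- TAAHC and class ordering are deterministic; all stochastic stages
  (generator, inner CV shuffling) take explicit seeds.

## Problem sizes used in validation

The validation suite runs cohorts of 20 subjects per group with 60-s
recordings at 250 Hz (30 clean 2-s epochs per subject, peak maps capped
at 300/subject), 50 replicate cohorts for effect-direction recovery,
100 small null cohorts (6/group, 20 s) for type-I calibration, and 50
label shuffles for the permutation-null AUC — sizes at which all
sampling-based checks are stable on a single CPU.

## Known limitations

- Peak-based backfitting cannot resolve segments shorter than the GFP
  inter-peak interval (about half a carrier period, ~50 ms at 10 Hz);
  such segments merge into neighbours, biasing the shortest class's
  recovered lifetime upward (~+18% at a planted 60 ms mean, ~+7% on the
  cohort mean across classes). Label-level segment statistics are
  unbiased; the limit is intrinsic to peak-based labelling, and real
  microstate lifetimes are subject to the same resolution effect.
- Global omega needs at least as many epochs as channels to be
  rank-unconstrained (see above).
- The classifier reports generalization on cohorts of this size only;
  no claim is made about transfer to real patient data.
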