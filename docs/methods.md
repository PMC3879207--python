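# Methods

## Scope and data flow

The package models how the internal organisation of a simple two-TF
enhancer — alternating binding motifs for pMad (the Dpp/BMP signalling
effector) and Tinman (an NK-2 homeodomain factor) — controls the
robustness of its activity in two embryonic tissues, the midgut visceral
mesoderm (VM) and the heart. Three layers connect sequence to biology:
sequence design (PWMs → motif instances → spacers → assembled CRMs),
image-based quantification (embryo images → per-domain activity calls →
penetrance/expressivity), and a thermodynamic occupancy model fitted to
those measurements.

## Sequence design

**Information content and trimming.** A PWM column's information content
is its relative entropy versus the background, `Σ p log2(p/q)` in bits.
The default background is uniform (0.25 per base); an A/T-rich preset
(A/T = 0.3, G/C = 0.2) is provided for motif-comparison-style scoring.
Columns are trimmed from each end while IC < 0.4 bits; trimming stops at
the first informative column, so interior low-IC columns survive. The
trimmed PWM's per-column argmax gives the motif instance; argmax ties
break lexicographically (A < C < G < T) for determinism.

**Log-odds scoring.** PWM probabilities receive a pseudocount of 1e-3
(renormalized) before log-odds, purely to keep zero entries finite; it is
negligible elsewhere.

**Spacer optimisation.** A neutral spacer must avoid creating binding
sites, including sites bridging the spacer/motif junction, so candidate
spacers are scored on `left_flank + spacer + right_flank` with the maximum
log-odds over all PWMs, offsets and strands. The search is a greedy
random-restart hill climb (default 20 restarts, single-base substitution
moves, strict-decrease acceptance), deterministic per seed. On exhaustive
6-bp test cases it lands within the configured tolerance of the global
minimum; nothing stronger is claimed for longer spacers.

**Coordinates.** Assembled CRMs use 0-based half-open intervals on the
plus strand; an antisense site stores the reverse complement of its motif
instance and is annotated strand `-` in BED6 output.

## Occupancy model

**States and weights.** Every subset of bound sites is a configuration;
the unbound configuration has weight 1. Base weights: `a0` per bound pMad,
`b0` per bound Tin, both fixed at 1 by default (configurable, not fitted),
so four parameters at most are estimated. Weights are accumulated in log
space; base weights are floored at 1e-300 so that "unbindable" limiting
cases stay finite.

**Cooperativity geometry.** Bound proteins carry spherical interaction
volumes; two spheres of radius `r` whose centres sit at the
motif-proximal edges (so the centre separation equals the labelled
edge-to-edge gap `d`) overlap by the normalized lens volume
`omega(d,r) = (4r+d)(2r−d)²/(16r³)` for `d < 2r`, else 0 — equal to 1 at
`d = 0` and 5/16 at `d = r`. The radius is `r_antisense` or `r_sense`
according to the orientation of the Tin site participating in the
contact. A cooperative pair multiplies the weight by `1 + (q1−1)·omega`,
chosen so that zero overlap reduces exactly to independent binding and
full overlap gives the full factor `q1`. In the `higher_order` variant a
contiguous bound pMad-Tin-pMad or Tin-pMad-Tin triple additionally
contributes `1 + (q2−1)·min(omega_left, omega_right)` — a chain is as
strong as its weaker contact. The triple factor multiplies (rather than
replaces) the two pair factors; the alternative convention would change
the meaning of `q2` but not the model class.

**Activity.** A configuration is productive when it contains at least one
fully bound, interacting minimal unit: any pMad-Tin pair with
`omega > 0` under `pairs_only`, or the tissue's minimal triple
(pMad-Tin-pMad for VM, Tin-pMad-Tin for heart) with both contacts under
`higher_order`. Activity is the probability mass of productive
configurations, `p = Σ_productive w / Z`. Note `p` is continuous in the
radii except at contact boundaries `d = 2r`, where the productive set
changes discontinuously; the synthetic study conditions keep the true
radii away from these boundaries.

**Observables.** Each tissue is scored in four domains, treated as
independent: `expressivity = p` and `penetrance = 1 − (1−p)^4`. An
identity link (`penetrance = p`) is selectable in the fit configuration.

**Homotypic extension.** Identical-TF adjacent pairs (e.g. pMad-pMad) are
not cooperative by default; an opt-in flag treats them as `q1` pairs with
the antisense radius. It is an extension, not part of the fitted model.

**Fitting.** Parameters `(q1, q2, r_sense, r_antisense)` minimize the
summed squared penetrance and expressivity misfit over all measured CRMs
(missing observations are skipped). The search is fully deterministic:
a coarse grid (q log-spaced over [1, 1000], 13 points per axis; radii
0–15 bp in 0.5 bp steps), two local grid refinements (q spacing ÷4 and
radius spacing ÷5 per round), then a Nelder–Mead polish in
`(log q1, log q2, r_s, r_a)` accepted only if it improves the residual.
Ties on the grid resolve to the first (lowest-index) optimum.

**Identifiability.** With 12 CRM lines at 100 embryos each, the radii are
sharply identified (simulation recovery well within ±1 bp; the contact
pattern brackets each radius and the omega magnitudes pin it). The two
cooperative weights are not separately well identified at this sample
size: the penetrance link saturates above `p ≈ 0.5`, leaving roughly a
dozen expressivity values (SE ≈ 0.06) to split two multiplicative weights
whose effects co-vary across the design family. Noiseless data recover
all four parameters essentially exactly, but Bernoulli sampling noise
moves the fitted `(q1, q2)` along a flat ridge by factors of ~2–3 in
either direction while leaving predictions nearly unchanged. Conclusions
should therefore rest on the radii and on model-variant comparisons, not
on point values of `q1` and `q2`.

**Cross-validation.** Leave-two-out iterates over all C(12,2) = 66 design
pairs, refits on the remaining ten and predicts the held-out pair. The
tolerance curve reports the fraction of held-out penetrance/expressivity
predictions within each absolute tolerance; the reference curve is the
analytic expectation for predictions drawn uniformly from [0, 1],
`E[min(o+t,1) − max(o−t,0)]` averaged over the held-out observations.

## Quantification

Both channels are background-subtracted by morphological opening with a
disk (default radius 25 px, larger than any tissue domain), a white
top-hat, which is non-negative by construction; within one disk radius of
the image border the background estimate is unreliable. The tissue channel
is smoothed (Gaussian, sigma 1 px) and thresholded (Otsu by default, fixed
threshold and inverted-contrast options); the mask is closed with a 5 px
disk and connected components of area ≤ 200 px (strictly-greater survives,
8-connectivity) are removed. Region outlines are the mask pixels whose
4-neighbourhood leaves the region.

**CRM positivity.** Training-based segmentation with
an interactive tool is avoided in favour of deterministic intensity rules — a
scope reduction that keeps the pipeline free of training state. The
default positivity rule is robust rather than Otsu-based, because Otsu
misbehaves on images with no true signal (it bisects pure noise): a pixel
is positive when its background-subtracted, smoothed intensity exceeds
`median + 5·1.4826·MAD` of the non-tissue pixels and an absolute floor
(0.1); a domain is called active when ≥ 2% of its pixels (and ≥ 10 pixels)
are positive, which suppresses isolated noise pixels. Otsu-over-tissue and
fixed thresholds remain selectable. An embryo is active when any positive
pixel overlaps the tissue mask (same minimum-count guard); by
construction an embryo with an active domain is active.

**Metrics.** Penetrance is the active fraction of the scored population;
expressivity is the mean per-embryo fraction of active domains (the
expressivity subset is typically smaller — ~16 staged embryos). Errors are
embryo-level bootstrap standard deviations (1000 resamples, seeded).
Expressivity may exceed penetrance when the expressivity subset differs
from the full population; no ordering between the two is assumed.

## Synthetic data: what it does and does not emulate

The generator draws, per CRM line, 100 embryos whose four domains are
independent Bernoulli(p) with `p` computed from a ground-truth model; the
first 16 embryos form the expressivity subset. An optional embryo-level
shared draw (`domain_correlation`) probes the independence assumption.
Images are schematic dorsal views: an elliptical body, four rectangular
domains (960 px each) along the anterior-posterior axis, a linear
background ramp (amplitude 0.15), unit-amplitude domain signal and
Gaussian speckle (sd 0.05); the CRM channel lights exactly the true-active
domains. Ground-truth masks and the domain partition accompany every
image, and the partition is used for domain scoring (the original
workflow assigned domains by eye; real images require a label map).

Default ground-truth parameters are `q1 = 10, q2 = 5, r_sense = 2.5,
r_antisense = 3.9` bp, chosen so the predicted activity profile of the
design family reproduces the qualitative measured profile: antisense
2 bp gaps saturated, 4–6 bp intermediate, 8 bp silent, sense silent beyond
4 bp — and so the radii sit inside, not on, their contact boundaries.

What passing tests on these data do **not** show: robustness to embryo
staging and orientation variability, anatomically realistic domain
shapes, signal amplification nonlinearities of in situ hybridisation, or
correlated inter-domain biology; the image geometry is a test harness for
the operators, not a rendering of an embryo.

## Numerical and design choices

* 2^n enumeration is exact and capped at n = 20 sites; fitting-scale
  designs have n ≤ 6 and evaluation is vectorized over parameter grids
  with a ~32 MB chunk cap.
* The partition function is accumulated in log space (logsumexp).
* Heart and VM are fitted independently (separate parameter sets).
* The Tin motif instance is 9 bp so that alternating designs reproduce
  the conventional pMad-pMad spacing labels (gap + 9 + gap: 13 bp at 2 bp gaps,
  25 bp at 8 bp gaps); the short three-site and single-pair designs use
  the antisense 4 bp configuration of the six-site CRM they derive from.
* The stand-in measurement tables shipped for the pMad-Tin family are
  synthetic reconstructions: embryo counts chosen to reproduce the
  headline penetrance/expressivity values (VM A4/A6 penetrance 0.91,
  expressivity 1 and 0.59; heart A4 0.89, S4 0.48, A6 0); unreported
  entries are NaN and excluded from residuals.

## Known limitations

* Brinker competition, TF concentration gradients and chromatin position
  effects are outside the model; activity is a function of motif
  arrangement only.
* Activity is discontinuous at contact boundaries (`gap = 2r`); fitted
  radii adjacent to a measured gap should be interpreted as an interval.
* `q1`/`q2` point estimates are weakly identified at realistic sample
  sizes (see *Identifiability*).
* Expressivity scoring assumes a supplied or ground-truth domain
  partition; automatic anatomical domain assignment is not attempted.
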