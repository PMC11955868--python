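# Methods

## Coordinate conventions and co-registration

All angles are degrees, measured from the top (12 o'clock) of the
displayed cross-section and increasing clockwise; a point at angle θ and
radius r sits at Cartesian (r·sin θ, r·cos θ). The cuff's two longitudinal
pad rings are collapsed to one angular coordinate per stimulating pair
(both pads of a pair share an angular position), modelled as a point on
the nerve-boundary circle. Default pair angles are equally spaced,
k·360/14; explicit angles can be configured.

Each fascicle is co-registered onto the unit-disc template by keeping its
polar angle about the nerve centre and choosing its template radius so
that its distance to the nearest electrode (placed on the unit circle)
equals the original centroid-to-electrode distance divided by the nerve
radius; areas are rescaled by 1/R². Along the fascicle's angular ray this
is a quadratic with two roots; the root nearest the fascicle's original
normalized radius is taken (for a circular nerve the construction reduces
exactly to normalization by R, and the output is invariant to uniform
rescaling of all millimetre coordinates). Equidistant-electrode ties break
to the lowest pair index, within a 10⁻⁹·R tolerance so that the
deterministic tie-break also fires on trigonometric rounding.

The nerve radius used throughout (and as the synthetic default) derives
from the mean cross-sectional area, 2.68 mm² → R ≈ 0.92 mm. The separately
reported ~6.6 mm "diameter" is inconsistent with that area (it would imply
~34 mm²) and is not used.

## Maps, rotation and atlases

Group maps are W×W rasters (default W = 256) over the unit disc; a pixel
is 1 iff its centre falls inside a projected fascicle disc of the group
(equivalent disc radius √(area/π)) and inside the nerve disc. Organ labels
map to functional groups as: cardiac → cardiac-efferent; cardiopulmonary →
cardiac-afferent *and* pulmonary; laryngopulmonary → laryngeal *and*
pulmonary. The dual memberships reflect fibre content: a cardiopulmonary
fascicle carries afferents of both cardiac and pulmonary origin, so it
belongs to both regional maps (an assumption of this package; the
alternative of exclusive assignment would make the cardiac-afferent and
pulmonary regions disjoint by construction, contradicting their observed
≈90% relative overlap).

Per-animal maps are rotated so the cardiac-efferent CoM sits at 0°. When
several cardiac-efferent fascicles exist the area-weighted CoM of the
whole group map is used (cohorts carry ≈1.2 ± 0.5 such fascicles, so this
usually is a single fascicle). Rotation resamples nearest-neighbour —
binary maps must stay binary for atlas semantics — and re-applies the
nerve-disc mask; pixel counts are conserved to well under 2% for blobs of
≥5-pixel radius at W = 256. Atlases are pixel-wise means of rotated
same-group maps: for binary inputs the mean is already the normalized
atlas (1 ⇔ the group is present there in every animal). Response atlases
additionally divide by their own maximum so the atlas peak is 1, since
per-animal response maps are themselves max-normalized to [0, 1].

## Response extraction and back-projection

Per electrode pair, the response is the extremum (signed value of largest
absolute deviation from baseline) of the 2 s moving-average-smoothed
signal within the response window, expressed as % change from the mean raw
signal over the baseline window immediately preceding onset; multiple
epochs are averaged. The extremum rather than the window mean is used so
the same statistic handles the delayed (≈tens of seconds) reflex responses
seen after vagotomy without modality-specific code. Defaults: baseline
window = the full preceding off period; response window = the on period
plus the off period shortened by twice the smoothing constant, so a
neighbouring pair's smoothed response cannot leak in. For post-vagotomy
sessions the pipeline shortens the baseline window by the reflex delay so
the previous pair's delayed tail does not contaminate the next baseline.
Both windows are configuration-exposed.

Back-projection paints |% change| per pair, normalized by the maximum over
pairs, onto the pair's angular-Voronoi sector (every template pixel whose
angle is nearest that pair's angle; boundary ties to the lower index);
unstimulated pairs paint 0. Magnitudes are used because atlas semantics
are [0, 1]; polarity is kept in the per-pair response table. Effective
pairs are those with |response| ≥ 75% of the per-sweep maximum.

A sweep enters maps and statistics only if its maximal |% change| clears a
noise floor estimated from the trace itself (MAD of the first difference,
scaled by the smoothing window and a z = 5 guard, relative to the signal
level). A sweep in which no fibres of the target group were activated —
e.g. the cardiac-afferent protocol in an animal without cardiopulmonary
fascicles — yields only spurious noise extrema; mapping it would inject an
arbitrary CoM. The gate is deliberately signal-vs-noise, not
concentration-based: genuinely broad responses (laryngeal EMG responds on
every pair at cardiac-level amplitudes) must pass.

## Spatial statistics

CoMs are value-weighted Cartesian means of pixel centres, reported in
polar form; maps whose CoM falls within one pixel of the origin are
flagged degenerate (angle undefined, reported 0). Area/overlap matrices
use binarized maps: diag(G) = |pixels(G)|/|nerve disc|, offdiag(G, H) the
analogous intersection fraction; τ = 0.5 binarizes atlases, any-positive
binarizes per-animal binary maps. Relative overlap of A with B is
100·offdiag/diag(A), rounded half-up to integer percent, matching how
these figures are conventionally reported.

Angular comparisons run a one-way ANOVA on linearized angles with Tukey
HSD adjusted pairwise comparisons (Bonferroni available by config; a
Watson–Williams circular test is provided behind a flag but is not the
default, since the standard analysis for these data is a plain ANOVA on
rotation-aligned angles). Linearization unwraps each group's angles about
that group's own circular mean (mapped into (−180, 180]): the
cardiac-afferent cluster sits near ±180° in the rotated frame, and naive
unwrapping about 0 would split it across the seam and destroy its mean.
Groups with fewer than two observations are excluded with a warning.

Two separation estimates are reported for cardiac efferent vs afferent:
the per-animal wrapped mean ± SD (the conventional summary), and the
magnitude of the circular mean of signed per-animal offsets. The wrapped
per-animal separation is bounded by 180°, so its arithmetic mean is biased
low whenever the truth is near 180° and per-animal CoMs are noisy; the
circular-mean form and the atlas-level CoM separation are unbiased and are
the pipeline's point estimates.

## Synthetic cohorts

Counts per organ class are rounded normal draws (means/SDs 1.2 ± 0.5
cardiac, 10.2 ± 1.8 laryngeal, 10.4 ± 1.9 pulmonary, 1.4 ± 0.6
cardiopulmonary, 6 ± 2 laryngopulmonary; floored at 0, cardiac at 1).
Fibre labels follow the observed per-class mixtures (cardiac 100%
efferent; cardiopulmonary afferent; laryngeal 82/18 efferent/mixed;
pulmonary 89/11 afferent/mixed; laryngopulmonary 57/13/30
afferent/efferent/mixed). Efferent fascicles cluster about a per-animal
efferent axis (drawn uniformly unless configured), afferent ones about
axis + separation (default 180°), mixed ones pick a side at random; the
angular cluster SD defaults to 25°. Fascicle radii are uniform on
0.06–0.14 mm (diameters 120–280 µm, ≈35% packing at 29 fascicles — typical
fascicle calibre and fascicular fraction for this nerve).

Placement draws all positions first (angle from the cluster, radius
uniform in area within the boundary margin) and then resolves disc
overlaps by symmetric pairwise push-apart with boundary clamping,
over-relaxed and jittered out of jammed cycles, restarting from fresh
draws if a packing does not converge. Symmetric pushes keep the realized
angular distribution unbiased (over 200 nerves the circular mean of
afferent-minus-efferent fascicle angles recovers the configured separation
to within ~1°), but dense clusters necessarily spread: at the default
composition the realized cluster SD is ≈40°, a geometric consequence of
packing ~12 afferent-side discs into a ~±25° wedge. Real nerves showed
much larger between-animal variation still (per-animal CE–CA separations
of 179 ± 55° ex vivo, 200 ± 137° in vivo), so the generator is the
cleaner, not the harder, condition.

The activation model is deterministic: a fascicle of a responsive group is
activated when pulse amplitude reaches its group threshold (defaults 0.15,
0.8, 1.0, 5.0 mA for laryngeal, pulmonary, cardiac-efferent,
cardiac-afferent — the ordering behind "laryngeal thresholds are far below
cardiac ones"), weighted by exp(−Δθ²/2σ²) with σ = 25° of angular
selectivity per pair (the selectivity of a single pair is not quantified
by the source data; σ is a free parameter chosen so that ≈2 pairs elicit
≥75% of the maximal cardiac response). Pair magnitude = modality gain ×
Σ(weight × normalized area); gains (160, 900, 400 %/unit-area for HR,
ETCO₂, EMG-RMS) are calibrated so that default cohorts produce ≈−8% peak
HR changes and large respiratory/EMG deflections. HR baseline is
80 b.p.m. (mid-range of intra-operative monitoring limits), traces are
sampled at 10 Hz (sufficient for epoch statistics; pulse-level waveforms
are out of scope), noise is additive Gaussian.

Vagotomy gates the HR pathways: intact → cardiac-efferent bradycardia
with no latency; right-distal → delayed (default 10 s) afferent reflex
whose direction is a fixed per-animal trait (tachycardia with probability
0.6, bradycardia 0.4 — no stimulus-parameter correlate being modelled);
right + left → reflex bradycardia abolished (it ran through left-vagal
efferents), reflex tachycardia (sympathetically mediated) retained.
ETCO₂ and laryngeal EMG pathways are outside the gated loop and are not
affected by cervical vagotomy state in this model. Everything is
deterministic given (seed, animal index); noise-free, delay-free sessions
invert exactly (to <10⁻⁶) through response extraction.

### What the generator does and does not emulate

It reproduces composition, exclusivity of cardiac-efferent fascicles,
bimodal organization, selective-response magnitudes and vagotomy logic —
the features the mapping and statistics stages consume. It does not
emulate non-circular nerve outlines, fascicle merging/splitting along the
nerve, ECG morphology, pulse-level stimulation artefacts, current spread
beyond the Gaussian angular weight, or between-animal variation in nerve
size. Passing tests therefore validate the pipeline's geometry, inversion
and statistics under idealized anatomy, not segmentation or signal
conditioning of raw recordings. One idealization is visible in the
statistics: synthetic pulmonary and cardiac-afferent clusters share one
axis with small spread, so their CoMs separate significantly in the ANOVA,
whereas the real cohort (with its much larger spread) found exactly these
two regions non-separated.

## Numerical choices and degenerate inputs

- W = 256 default raster; pixel-centre-in-disc rasterization; sector pixel
  counts agree across the 14 sectors to <0.2% at this resolution.
- Rounding of reported percents is half-up.
- Tie-breaks: equidistant electrodes and sector boundaries go to the lower
  pair index.
- An empty group map cannot be aligned or given a CoM (errors); an empty
  responsive group in simulation is not an error (baseline + noise trace).
- Baselines ≤ 0 for HR/ETCO₂ abort extraction (invalid physiology).
- Atlas binarization τ = 0.5; per-animal binary maps binarize at any
  positive value. Which maps feed an overlap matrix (per-animal mean vs
  atlas-based) is reported separately; both paths are computed.

## Problem sizes

Default analysis cohorts are 5 fascicle-traced nerves and 10 stimulation
animals (4 sweeps each) at W = 256, matching the study design; unit and
property tests run reduced rasters (W = 7–128) and the type-I-error check
runs 1000 label-shuffled replicates of 10 CoMs.

## Known limitations

- The between-technique overlap of synthetic cohorts is much smaller than
  observed between real techniques, because synthetic fascicle discs are
  compact while sector maps are coarse; the between-technique numbers are
  reported but are not calibration targets.
- The Watson–Williams implementation uses the standard high-concentration
  correction and is inaccurate for very dispersed samples (mean resultant
  < ~0.45).
- Reported relative overlaps recomputed from rounded two-decimal matrices
  can differ by ±1–2% from figures derived from unrounded source data;
  only the self-consistent ones are asserted in tests.
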