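# Methods

This note records the models, numerical choices and known limits of
`polarpath`, module by module.

## Single-sphere Mie / Mueller engine (`polarpath.mie`)

Mie coefficients use the Wiscombe truncation order `x + 4·x^{1/3} + 2`, a
downward recurrence for the logarithmic derivative D_n(mx) and upward
recurrences for the Riccati–Bessel functions at x. Both study configurations
converge comfortably in double precision: the polystyrene phantom sphere
(x ≈ 6.84, 1.04 µm at 635 nm in water) and the dental sphere approximation of
enamel prisms (x ≈ 52.3, 5.75 µm at 543.5 nm in interprismatic substance,
indices 1.619/1.573). Refractive indices are real: absorption inside spheres,
coatings and size distributions are out of scope.

The Mueller elements are tabulated on a uniform angular grid (default 0.25°,
finer than any claim made from them) as `m11 = (|S1|²+|S2|²)/2`,
`m12 = (|S2|²−|S1|²)/2`, `m33 = Re(S2 S1*)`, `m34 = Im(S2 S1*)`. Exact
identities used as tests: m33(0) = m11(0), m33(180) = −m11(180),
m12 = m34 = 0 at both poles, |m12|,|m33|,|m34| ≤ m11 everywhere, and
m11² = m12² + m33² + m34² (a sphere is a pure Mueller–Jones scatterer, so
full polarization is preserved at the single-event level).

The *orthogonalization interval* is the largest contiguous angular run
containing 180° on which the matched scattered component (U for +45° linear
incidence, V for right-circular — identical by the block structure) is
negative. Strict negativity uses a dead band of 10⁻¹²·max(m11) so grid-level
rounding cannot open or close an interval. The onset is reported at grid
resolution; for the phantom sphere it computes to 131.25°, i.e. the backward
cone opens ~4° wider than the nominal "exact backscatter ± 45°" reading.
Minor Mie oscillations do not fragment the interval at these parameters (the
profile is strictly negative from onset to 180°) — this was checked
numerically rather than assumed. For the dental configuration only the sign
property (mean m33 < 0 over the backward hemisphere) is asserted: the
detailed lobe shape depends on poorly constrained tissue parameters and the
sphere idealization of the prisms.

Number density for a target scattering coefficient is ρ = μs/σ_sca with
σ_sca = Q_sca·πr². Q_sca from the coefficient series is cross-checked in the
tests against numerical integration of (|S1|²+|S2|²)·sinθ — two independent
routes through the same amplitudes.

A degenerate, index-matched sphere (zero contrast) returns an all-zero table
flagged `degenerate=True` with a warning instead of raising, so parameter
sweeps crossing the matching point survive; sampling or density conversion
from such a table raises.

## Polarized Monte Carlo (`polarpath.montecarlo`)

Photon packets carry position, an orthonormal triad (v, w, u) and a Stokes
vector referenced to (v, w). One event:

1. sample θ by inverse CDF of m11(θ)·sinθ (trapezoid CDF on the table grid —
   the marginal in θ is exact because the φ-dependent term integrates to
   zero);
2. sample φ by rejection from 1 + (m12/m11)(Q cos 2φ + U sin 2φ) under the
   envelope 1 + |m12/m11|·√(Q²+U²) (acceptance ≥ ½; a 10⁴-iteration cap
   signals a malformed envelope);
3. rotate the frame by φ about u, deflect by θ in the new (u, v) plane, apply
   the normalized Mueller matrix and renormalize to unit packet weight (the
   angular sampling already carried the intensity weighting);
4. re-orthonormalize the triad (Gram–Schmidt) every event, keeping the
   orthonormality error at the 10⁻⁹ level over arbitrarily many events.

Carrying the frame explicitly is algebraically equivalent to classical
meridian-plane bookkeeping; it avoids meridian projections at every event.

Free paths are exponential with rate μs. Absorption (μa, default 0 — water is
transparent at these wavelengths) attenuates the detected weight as
exp(−μa·pathlength) rather than terminating packets. Boundaries are
index-matched: packets exit at the first face crossing, with no Fresnel
reflection or refraction — matching the experimental design this emulates
(the cuvette angled specifically to discard specular boundary reflections).
No Fresnel option is provided. Packets are killed after 10⁵ events (counted
in metadata; at the study conditions the cap is never approached).

Detection accepts packets leaving the illuminated (top) face within a
configurable cone (default half-angle 15°). The detection basis is
e₁ = x̂ − (x̂·u)u normalized, e₂ = u×e₁ — for exact backscatter this is
(x̂, −ŷ, −ẑ), a right-handed frame looking back along the return beam. The
handedness flip means a packet whose physical polarization orientation never
changed shows U with opposite sign in the detection frame; the analyzer split

```
co_linear  = (I − sign(U_in)·U_det)/2     co_circular  = (I + sign(V_in)·V_det)/2
cross_linear = (I + sign(U_in)·U_det)/2   cross_circular = (I − sign(V_in)·V_det)/2
```

encodes exactly that, and reproduces the physical fact that singly
backscattered (orthogonalized) light lands in the co-linear and
cross-circular channels. Per pixel the detector accumulates the four channel
intensities, the photon count, unweighted scattering-event and pathlength
totals, and channel-intensity-weighted scattering-event totals — the latter
are what per-channel N maps divide.

Randomness is one splitmix64 counter stream per packet, derived from the
master seed, so results are bit-reproducible regardless of execution order.
The kernel is numba-compiled (~1.3×10⁴ packets/s on one core for the phantom
configuration, whose detected packets average ~50 scattering events).

**Validation against the only desk-scale oracle.** In a dilute slab
(optical thickness 0.08, 0.2 µm spheres with g ≈ 0.31, wide 20 cm lateral
extent so no single-scattered photon is lost through the sides), the
exit-angle distribution of singly scattered detected packets matches
m11(180°−α)·sinα times the closed-form depth-attenuation factor
[1 − e^{−τ(1+sec α)}]/(1+sec α) by chi-square, and their mean detection-frame
V equals m33/m11 at the corresponding angle, bin by bin.

## Spatial analysis (`polarpath.spatial`)

All regions live in physical millimetres on the detector plane; a pixel
belongs to a region when its centre does (no partial-area weighting), so
every aggregate equals a per-pixel enumeration exactly — the property tests
assert this against brute-force loops. Rectangle and lobe orientations are
measured from the incident polarization axis, whose image-frame angle each
simulation result records (−45° for the default −45° linear beam, so the
"perpendicular axis" is the image anti-diagonal).

N maps divide channel-weighted event totals by channel intensity per pixel.
The validity mask keeps pixels with at least `min_photons` detected
(default 5): the per-pixel ratio is *unbiased* at any count ≥ 1 but noisy at
small counts, so the default favors stable per-pixel values for maps and
small-region readouts. For *regional aggregates at reduced packet counts*
(the Npp reductions), the analysis uses `min_photons=1`: averaging thousands
of pixels suppresses the ratio noise, whereas masking dim pixels biases the
full-image baseline, because the dim pixels are precisely the far-field,
high-N ones. At 3–6×10⁶ packets with a 30° cone every pixel of the 20 mm
field is hit and this question disappears.

Radial profiles use 1-pixel-wide annuli by default; azimuthal (lobe) profiles
use 72 bins of 5°, smoothed with a 3-bin circular moving mean; peaks are
local maxima above the circular mean. Four-lobed patterns are resolved with
margin; very weak lobes (the co-linear parallel pair at reduced scale) may
stay below the circular-mean threshold, which the tests treat as acceptable —
the claim tested is that all detected peaks lie on the expected axes and the
perpendicular pair dominates.

**Npp reduction scale effects.** The headline region-gating numbers are
computed at 3–6×10⁶ packets (the experiment-matched simulations use ~10⁸).
At this scale, with a full-image-length × 1.5 mm rectangle, the perpendicular
reduction converges to ~30% and the 45°-axis reduction to ~17%
(seed-to-seed spread ±0.5 points), versus 36%/24% at full scale — the
far-field N estimates, which dominate the full-image baseline, are still
slightly low at desk scale. The exact rectangle geometry genuinely matters
and is not uniquely determined: shortening the rectangle to 14 mm raises the
pair to ~37%/26%. The defaults fix length = full image extent and width =
1.5 mm (the one width the study design states); the acceptance test prints
the sensitivity sweep and requires the perpendicular > 45° ordering across
all of it. The detector acceptance cone moves these reductions by ≲1 point
between 15° and 30° (verified at equal packet counts); the wide cone is used
for reduced-scale runs purely for photon economy.

## Tooth statistics (`polarpath.toothstats`)

The t-score follows the stated formula literally: S is the sample standard
deviation (ddof = 1) of all data points pooled across both groups. This is
not the classical pooled-variance two-sample t (available via
`method="classical"`): under an effect, the between-group separation inflates
S, making the score conservative; under the null it tracks Student's t with
n₁+n₂−2 degrees of freedom closely (measured two-sided 5%-criterion rejection
≈ 6–7% over 500 synthetic replicates). The reported p-value uses that
reference distribution and is labelled an interpretation. S = 0 (all points
identical) implies equal means, so t is reported as 0 with a warning rather
than raising or returning infinity.

The synthetic generator emulates the *structure* of the tooth measurements,
not enamel physics: per spot and channel,
`image = (core·f_core·G(σ_core) + bg·f_bg·G(σ_bg))·h + noise`, where G are
radial Gaussians (core σ = 1 mm for the 3 mm illumination spot; background
σ = 4 mm for the diffuse, depolarized field), h is a per-spot log-normal
factor shared by both channels (spot placement and local surface condition —
this shared factor is also what strings the polarimetric-map points along a
line), and the additive pixel noise is clipped at zero. Demineralization
multiplies the core by the per-channel reduction factor (default 0.6, a 40%
drop) and leaves the background untouched by default — the class contrast is
interior-concentrated, which is the geometry the region selection exploits.
Defaults follow the measurement design: 7 samples × 2 sides × 2 spots = 28
points per channel. What passing tests show is therefore that the *pipeline*
ranks interior-region metrics above full-image metrics whenever the contrast
is interior-concentrated and spot heterogeneity dominates the noise; they say
nothing about effect sizes in real teeth, where surface curvature, beam
centring and tooth-to-tooth correlations (absent from the generator) all
enter. Spots are generated independently — with real repeated measures per
tooth the null calibration of the t criterion would be optimistic.

The five-metric battery: (a) co-linear full-image sum, (b) co-linear sum over
the 3 mm disc ∩ 1.5 mm-wide perpendicular rectangle, (c) cross-circular
full-image sum, (d) cross-circular 3 mm-disc sum, (e) the (b) and (d) points
pooled as one doubled-size sample. Pooling mixes two intensity scales; with
the default amplitudes they are comparable, and the doubling property
(|t_e| ≥ |t_b| on duplicated data) holds by construction. The polarimetric
map pairs each spot's two channel sums and summarizes separation as the best
single-threshold accuracy along the first principal axis of the point cloud —
a deliberately simple, scale-equivariant summary.

## I/O and CLI (`polarpath.io`, `polarpath.cli`)

Configs are flat `key = value` text validated against per-command schemas
(unknown keys rejected, errors name the key). Results travel as HDF5 with a
JSON metadata echo (seed, counts, full configuration, format version) so any
derived figure can be regenerated from the container; TIFF export is offered
for imaging tools. Physical quantities keep the units of the domain
(nm, µm, mm, cm, cm⁻¹) with the unit embedded in every key name. The CLI is
a thin layer over the library and logs version, seed and a config hash per
invocation.

## Problem sizes

Reduced-scale defaults used by the test suite and the acceptance script:
3–5×10⁶ packets on a 101×101-pixel, 20 mm field for the phantom run
(full-scale experiments and simulations use ~10⁸ packets on 400×400 pixels);
1.6×10⁷ packets for the dilute single-scattering validation (trivially fast —
almost no multiple scattering); 500 null + 100 effect replicates at 64×64
pixels for the synthetic tooth pipeline. Seeds are fixed in tests; the
acceptance script takes its seed on the command line.
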