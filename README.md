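# polarpath

Polarimetric depth selectivity in turbid, tissue-like media: a Mie /
Stokes–Mueller single-scattering engine, a polarization-tracking Monte Carlo
simulator of backscattered co/cross-polarized images, spatial field-selection
analysis of scattering-count maps, and the two-group intensity statistics used
to tell sound from demineralized tooth enamel.

## The problem

Backscattered polarized light carries depth information. A single
reflection-like, large-angle scattering event *orthogonalizes* the
polarization state (+45° linear → −45° linear; right-circular →
left-circular), and can redirect a photon straight back out of the medium —
so orthogonalized light preferentially samples the surface and near-surface.
State-preserving photons instead follow arc-like forward-scattering paths and
penetrate deeper. Because of a reference-frame flip on propagation reversal,
orthogonalized light appears in the **co-linear** and **cross-circular**
detection channels. Selecting the right *regions* of those images pushes the
sensitivity further toward the surface:

* pixels near the illumination spot (both channels), and
* pixels along the axis **perpendicular to the incident polarization vector**
  (co-linear channel), where the four-lobed backscatter pattern concentrates
  its least-scattered light.

This matters wherever the diagnostic signal lives in a thin superficial
layer: the driving application is early enamel demineralization (tooth
decay), whose surface roughening and sub-surface scattering lower the
co-linear and cross-circular backscatter intensities.

## The model

**Single scattering.** For a homogeneous sphere, the far-field Mueller
operator on the Stokes vector (I, Q, U, V) has the block form

```
[I']   [ m11  m12   0    0  ] [I]
[Q'] = [ m12  m11   0    0  ] [Q]      m11 = (|S1|² + |S2|²)/2
[U']   [  0    0   m33  m34 ] [U]      m12 = (|S2|² − |S1|²)/2
[V']   [  0    0  −m34  m33 ] [V]      m33 = Re(S2 S1*),  m34 = Im(S2 S1*)
```

with S1(θ), S2(θ) the Mie amplitude functions. Incident +45° linear light
scatters with U_out = ±m33 and right-circular with V_out = ±m33 — the two
channels are exactly equivalent at the single-scattering level, and m33 < 0
marks orthogonalization.

**Multiple scattering.** Photon packets carry a Stokes vector in a local
orthonormal frame through exponential free paths (step ∝ −ln ξ/μs). Each
event samples (θ, φ) from the polarization-dependent phase function
p ∝ m11·I + m12·(Q cos 2φ + U sin 2φ), applies the Mueller matrix in the
scattering plane, and renormalizes the packet weight. Packets exiting the
illuminated face inside an acceptance cone are analyzed in a fixed lab frame
into co/cross linear and circular channels, with per-pixel tallies of
intensity, photon count, scattering events and pathlength.

**Depth proxy and statistics.** The per-pixel mean scattering count
N = (events)/(photons) proxies sampling depth; Npp is its mean over a region,
and 100·(1 − Npp_region/Npp_full) measures how much shallower a region
samples. Group differences between normal and demineralized surfaces are
scored with

```
t = (x̄1 − x̄2) / sqrt(S² (1/n1 + 1/n2))
```

where S is the standard deviation of all data points pooled across both
groups.

## Worked example

`examples/depth_gating_regions.py` runs a reduced-scale (10⁶ packet)
simulation of the enamel-like phantom — 1.04 µm polystyrene spheres in water,
μs = 25 cm⁻¹, 2.2 cm cube, 3 mm beam of −45° linear 635 nm light — and
prints:

```
full-image co-linear Npp: 54.1 scattering events/photon/pixel
rectangle at   0.0 deg (parallel axis     ): Npp =  41.2, reduction vs full =  23.9%
rectangle at  45.0 deg (45 deg axis       ): Npp =  44.9, reduction vs full =  17.0%
rectangle at  90.0 deg (perpendicular axis): Npp =  39.2, reduction vs full =  27.5%
rectangle at 135.0 deg (45 deg axis       ): Npp =  45.1, reduction vs full =  16.6%
radius (mm) | co-linear N | cross-linear N
     1.0    |     17.7    |     24.0
     3.0    |     35.3    |     36.8
     5.0    |     45.8    |     46.3
```

Reading: light collected in the rectangle perpendicular to the incident
polarization has undergone the fewest scattering events (largest Npp
reduction), i.e. it sampled shallowest; co-linear photons scatter less than
cross-linear ones near the beam and the two converge with radius as the field
depolarizes. The other examples cover the single-scattering
orthogonalization interval (`mie_orthogonalization.py`, onset 131.25° for the
phantom sphere), the four-lobed pattern orientations
(`phantom_backscatter.py`: cross-linear peaks at 45/135/225/315°, co-linear
on the 0/90° axes), and the tooth statistics
(`tooth_statistics.py`: interior-region t ≈ 3.9–4.0 vs full-image t ≈ 2.2,
pooled t ≈ 5.1, 93% polarimetric-map separability).

A thin CLI mirrors the library: `polarpath mie-profile | simulate | analyze |
synth | tooth-stats` (see `polarpath --help`); simulation results travel as
HDF5 containers with a full config echo.

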