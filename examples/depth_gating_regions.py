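"""Sampling-depth gating by spatial region selection of the co-linear image.

Builds the per-pixel mean scattering-count map N (a sampling-depth proxy) from
a reduced-scale phantom simulation and compares the Npp of rectangles oriented
perpendicular to, and at 45 deg from, the incident polarization vector.
Light in the perpendicular rectangle has scattered least, i.e. sampled
shallowest.
"""

import numpy as np

from polarpath import (
    POLYSTYRENE_PHANTOM,
    BeamSpec,
    DetectorConfig,
    ImageGeometry,
    MediumSpec,
    compare_rectangle_orientations,
    radial_profile,
    run_simulation,
    scatter_count_map,
)

medium = MediumSpec(mie=POLYSTYRENE_PHANTOM, mus_per_cm=25.0)
result = run_simulation(
    medium,
    BeamSpec(),
    DetectorConfig(acceptance_deg=30.0),
    n_packets=1_000_000,
    seed=7,
)
geom = ImageGeometry.from_result(result)

nmap = scatter_count_map(
    result.channel_nscatter["co_linear"], result.channels["co_linear"], min_photons=1
)
full_npp = nmap.values[nmap.mask].mean()
print(f"full-image co-linear Npp: {full_npp:.1f} scattering events/photon/pixel")

sweep = compare_rectangle_orientations(
    nmap, geom, length_mm=20.0, width_mm=1.5, angles_deg=[0, 45, 90, 135]
)
for row in sweep.itertuples():
    tag = {90.0: "perpendicular axis", 0.0: "parallel axis"}.get(
        row.angle_deg, "45 deg axis"
    )
    print(
        f"rectangle at {row.angle_deg:5.1f} deg ({tag:18s}): "
        f"Npp = {row.npp:5.1f}, reduction vs full = {row.reduction_pct:5.1f}%"
    )
print(
    "  -> the perpendicular rectangle yields the largest Npp reduction:\n"
    "     selecting it reads out the shallowest-sampling light"
)

nco = scatter_count_map(
    result.channel_nscatter["co_linear"], result.channels["co_linear"], 1
)
ncx = scatter_count_map(
    result.channel_nscatter["cross_linear"], result.channels["cross_linear"], 1
)
pco = radial_profile(nco.values, geom, bin_width_mm=2.0, mask=nco.mask)
pcx = radial_profile(ncx.values, geom, bin_width_mm=2.0, mask=ncx.mask)
print("radius (mm) | co-linear N | cross-linear N")
for r, a, b in zip(pco.bin_centers_mm[:5], pco.mean[:5], pcx.mean[:5]):
    print(f"   {r:5.1f}    |   {a:6.1f}    |   {b:6.1f}")
print("  -> co-linear photons scatter less near the beam, then both converge")
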