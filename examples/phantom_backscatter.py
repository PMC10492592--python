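"""Polarized Monte Carlo backscatter imaging of a microsphere suspension.

Runs a reduced-scale simulation of the enamel-like phantom (1.04 um
polystyrene spheres in water, mu_s = 25 /cm, 2.2 cm cube) illuminated by a
3 mm disc of -45 deg linearly polarized 635 nm light, then quantifies the
four-lobed co/cross-linear backscatter patterns.
"""

import numpy as np

from polarpath import (
    POLYSTYRENE_PHANTOM,
    BeamSpec,
    DetectorConfig,
    ImageGeometry,
    MediumSpec,
    lobe_profile,
    run_simulation,
)

medium = MediumSpec(mie=POLYSTYRENE_PHANTOM, mus_per_cm=25.0)
beam = BeamSpec(diameter_mm=3.0, incident_state="linear_minus45")
detector = DetectorConfig(nx=101, ny=101, field_mm=20.0, acceptance_deg=30.0)

result = run_simulation(medium, beam, detector, n_packets=500_000, seed=42)
print(
    f"launched {result.launched:,} packets, detected {result.detected:,} "
    f"({100 * result.detected / result.launched:.2f}% backscattered into the cone)"
)

geom = ImageGeometry.from_result(result)
for channel in ("co_linear", "cross_linear"):
    prof = lobe_profile(result.channels[channel], geom, 2.0, 6.0, n_bins=36)
    peaks = ", ".join(f"{p:.0f}" for p in prof.peaks_deg)
    print(f"{channel:12s}: azimuthal peaks at {peaks} deg (rel. to polarization axis)")
print(
    "  -> cross-linear lobes sit at the 45 deg axes ('+' pattern), co-linear\n"
    "     lobes on the parallel/perpendicular axes ('x' pattern); the angles\n"
    "     are degrees from the incident polarization vector"
)
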