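"""Single-sphere polarization response: where does backscatter orthogonalize?

Computes the angular Mueller table of a 1.04 um polystyrene sphere in water at
635 nm, the matched polarization profile for +45 deg linear (equivalently
right-circular) incidence, and the backward angular interval over which a
single event flips the polarization state.
"""

import numpy as np

from polarpath import (
    POLYSTYRENE_PHANTOM,
    StokesVector,
    compute_mueller_table,
    number_density_for_mus,
    orthogonalization_interval,
    polar_intensity_profile,
)

table = compute_mueller_table(POLYSTYRENE_PHANTOM)
print(f"size parameter x      : {POLYSTYRENE_PHANTOM.size_parameter:.3f}")
print(f"scattering efficiency : {table.scattering_efficiency:.4f}")
print(f"anisotropy g          : {table.anisotropy_g:.4f}")

profile = polar_intensity_profile(table, StokesVector.linear_plus45())
onset, end = orthogonalization_interval(profile)
print(f"orthogonalization interval (polar-display): {onset:.2f} - {end:.2f} deg")
print("  -> a single scattering event inside this backward cone flips the")
print("     polarization state; such reflection-like events favor shallow paths")

rho = number_density_for_mus(POLYSTYRENE_PHANTOM, 25.0)
print(f"number density for mu_s = 25 /cm: {rho:.4g} spheres/cm^3")

for theta in (0.0, 90.0, 135.0, 180.0):
    m11, _, m33, _ = table.elements_at(theta)
    print(f"theta = {theta:5.1f} deg: m33/m11 = {m33 / m11:+.3f}")
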