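"""Single-sphere Mie scattering and the scattering-angle-resolved Mueller matrix.

For a homogeneous dielectric sphere the far-field single-scattering operator on
the Stokes vector ``(I, Q, U, V)`` has the block form

.. code-block:: text

    [I']   [ m11  m12   0    0  ] [I]
    [Q'] = [ m12  m11   0    0  ] [Q]
    [U']   [  0    0   m33  m34 ] [U]
    [V']   [  0    0  -m34  m33 ] [V]

where every independent element is a function of the scattering angle ``theta``
(0 deg = forward, 180 deg = exact backscatter).  The elements follow from the
Mie amplitude functions ``S1(theta)``, ``S2(theta)``::

    m11 = (|S1|^2 + |S2|^2) / 2      m12 = (|S2|^2 - |S1|^2) / 2
    m33 = Re(S2 S1*)                 m34 = Im(S2 S1*)

The sign of the ``m33``-governed component of the scattered Stokes vector
decides whether +45 deg linear (equivalently right-circular) light is
*preserved* or *orthogonalized* by a single event: ``m33 < 0`` in the backward
hemisphere marks reflection-like events that flip the polarization state.
Those events are the physical handle for shallow-depth gating, because a
single large-angle event can redirect a photon back out of the medium,
whereas state-preserving photons must follow deeper, arc-like forward paths.

Sign conventions used across the package: ``Q > 0`` is horizontal (x-axis)
linear polarization, ``U > 0`` is +45 deg linear (from x toward y), and
``V > 0`` is right-circular in the receiver-frame optics convention, always
relative to the local propagation direction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

__all__ = [
    "MieParameters",
    "StokesVector",
    "MuellerAngularTable",
    "AngularProfile",
    "compute_mueller_table",
    "scatter_stokes",
    "polar_intensity_profile",
    "orthogonalization_interval",
    "number_density_for_mus",
    "POLYSTYRENE_PHANTOM",
    "DENTAL_ENAMEL",
]


@dataclass(frozen=True)
class MieParameters:
    """Optical inputs of a single-sphere scattering problem.

    Parameters
    ----------
    wavelength_nm : float
        Vacuum wavelength of the illumination, in nanometres.
    host_index : float
        Real refractive index of the surrounding (host) medium.
    sphere_index : float
        Real refractive index of the sphere.
    diameter_um : float
        Sphere diameter, in micrometres.
    """

    wavelength_nm: float
    host_index: float
    sphere_index: float
    diameter_um: float

    def __post_init__(self) -> None:
        if not self.wavelength_nm > 0:
            raise ValueError("wavelength_nm must be > 0")
        if not self.diameter_um > 0:
            raise ValueError("diameter_um must be > 0")
        if self.host_index < 1.0:
            raise ValueError("host_index must be >= 1")
        if not self.sphere_index > 0:
            raise ValueError("sphere_index must be > 0")

    @property
    def size_parameter(self) -> float:
        """Dimensionless size parameter ``x = pi d n_host / lambda_vac``."""
        return math.pi * self.diameter_um * 1e3 * self.host_index / self.wavelength_nm

    @property
    def relative_index(self) -> float:
        """Sphere index relative to the host, ``m = n_s / n_m``."""
        return self.sphere_index / self.host_index

    @property
    def radius_cm(self) -> float:
        return 0.5 * self.diameter_um * 1e-4

    @property
    def geometric_cross_section_cm2(self) -> float:
        return math.pi * self.radius_cm**2


#: 1.04 um polystyrene sphere in water, 635 nm illumination -- the microsphere
#: suspension used as an enamel-like tissue phantom (mu_s matched to enamel).
POLYSTYRENE_PHANTOM = MieParameters(
    wavelength_nm=635.0, host_index=1.33, sphere_index=1.59, diameter_um=1.04
)

#: Enamel prisms approximated as spheres in interprismatic substance,
#: 543.5 nm illumination (green HeNe).  First-order dental scattering model.
DENTAL_ENAMEL = MieParameters(
    wavelength_nm=543.5, host_index=1.573, sphere_index=1.619, diameter_um=5.75
)


@dataclass(frozen=True)
class StokesVector:
    """Polarization state ``(I, Q, U, V)`` in common arbitrary intensity units.

    Physicality requires ``I >= 0`` and ``I^2 >= Q^2 + U^2 + V^2`` (equality
    for fully polarized states); the constructor enforces this up to a small
    numerical slack.
    """

    i: float
    q: float
    u: float
    v: float

    _REL_SLACK = 1e-9

    def __post_init__(self) -> None:
        scale = max(abs(self.i), abs(self.q), abs(self.u), abs(self.v), 1e-300)
        slack = self._REL_SLACK * scale * scale + 1e-300
        if self.i < -slack:
            raise ValueError("Stokes I must be non-negative")
        if self.q**2 + self.u**2 + self.v**2 > self.i**2 + slack:
            raise ValueError("unphysical Stokes vector: I^2 < Q^2 + U^2 + V^2")

    @classmethod
    def from_array(cls, arr) -> "StokesVector":
        i, q, u, v = (float(c) for c in arr)
        return cls(i, q, u, v)

    def as_array(self) -> np.ndarray:
        return np.array([self.i, self.q, self.u, self.v], dtype=float)

    @property
    def degree_of_polarization(self) -> float:
        if self.i == 0:
            return 0.0
        return math.sqrt(self.q**2 + self.u**2 + self.v**2) / self.i

    def is_physical(self, rtol: float = 1e-9) -> bool:
        return (
            self.i >= -rtol
            and self.q**2 + self.u**2 + self.v**2 <= self.i**2 * (1 + rtol) + rtol
        )

    # canonical pure states
    @classmethod
    def unpolarized(cls) -> "StokesVector":
        return cls(1.0, 0.0, 0.0, 0.0)

    @classmethod
    def linear_plus45(cls) -> "StokesVector":
        return cls(1.0, 0.0, 1.0, 0.0)

    @classmethod
    def linear_minus45(cls) -> "StokesVector":
        return cls(1.0, 0.0, -1.0, 0.0)

    @classmethod
    def circular_right(cls) -> "StokesVector":
        return cls(1.0, 0.0, 0.0, 1.0)

    @classmethod
    def circular_left(cls) -> "StokesVector":
        return cls(1.0, 0.0, 0.0, -1.0)


@dataclass(frozen=True)
class MuellerAngularTable:
    """Independent single-sphere Mueller elements tabulated over scattering angle.

    Attributes
    ----------
    theta_deg : ndarray
        Strictly increasing scattering angles in degrees, covering [0, 180].
    m11, m12, m33, m34 : ndarray
        Mueller elements per angle (un-normalized Mie intensity units).
    scattering_efficiency : float
        ``Q_sca`` from the same coefficient series.
    anisotropy_g : float
        Mean cosine of the scattering angle under the ``m11`` phase function.
    params : MieParameters
        The inputs the table was computed from.
    degenerate : bool
        True when the sphere is index-matched to the host (no scattering).
    """

    theta_deg: np.ndarray
    m11: np.ndarray
    m12: np.ndarray
    m33: np.ndarray
    m34: np.ndarray
    scattering_efficiency: float
    anisotropy_g: float
    params: MieParameters
    degenerate: bool = False

    def __post_init__(self) -> None:
        n = self.theta_deg.size
        for name in ("m11", "m12", "m33", "m34"):
            if getattr(self, name).size != n:
                raise ValueError("element arrays must match the angle grid")
        if n < 2 or not np.all(np.diff(self.theta_deg) > 0):
            raise ValueError("theta_deg must be strictly increasing")
        if self.theta_deg[0] != 0.0 or abs(self.theta_deg[-1] - 180.0) > 1e-9:
            raise ValueError("theta_deg must span [0, 180]")
        if not -1.0 <= self.anisotropy_g <= 1.0:
            raise ValueError("anisotropy_g must lie in [-1, 1]")

    def elements_at(self, theta_deg: float) -> Tuple[float, float, float, float]:
        """Linearly interpolated ``(m11, m12, m33, m34)`` at ``theta_deg``."""
        if not 0.0 <= theta_deg <= 180.0:
            raise ValueError("theta_deg must lie in [0, 180]")
        t = float(theta_deg)
        return (
            float(np.interp(t, self.theta_deg, self.m11)),
            float(np.interp(t, self.theta_deg, self.m12)),
            float(np.interp(t, self.theta_deg, self.m33)),
            float(np.interp(t, self.theta_deg, self.m34)),
        )

    @property
    def scattering_cross_section_cm2(self) -> float:
        """sigma_sca = Q_sca * pi r^2, in cm^2."""
        return self.scattering_efficiency * self.params.geometric_cross_section_cm2


@dataclass(frozen=True)
class AngularProfile:
    """Signed polarization-intensity profile over scattering angle.

    ``value[i]`` is the matched scattered component (U for +45 deg linear
    input, V for right-circular input) at ``theta_deg[i]``; negative values
    mark orthogonalization.  ``reference_scale`` (max ``m11``) sets the
    dead-band used when locating sign changes on a discrete grid.
    """

    theta_deg: np.ndarray
    value: np.ndarray
    component: str  # "u_out" or "v_out"
    reference_scale: float

    def __post_init__(self) -> None:
        if self.theta_deg.size != self.value.size:
            raise ValueError("theta_deg and value must have equal length")
        if self.theta_deg.size < 2 or not np.all(np.diff(self.theta_deg) > 0):
            raise ValueError("theta_deg must be strictly increasing")


def _mie_coefficients(x: float, m: float) -> Tuple[np.ndarray, np.ndarray]:
    """Mie coefficients a_n, b_n for real relative index m and size parameter x.

    Truncation at the Wiscombe order ``x + 4 x^{1/3} + 2``; the logarithmic
    derivative D_n(mx) is generated by downward recurrence (stable), the
    Riccati-Bessel functions psi_n, chi_n at x by upward recurrence.
    """
    nmax = int(math.ceil(x + 4.0 * x ** (1.0 / 3.0) + 2.0))
    mx = m * x
    nmx = int(max(nmax, math.ceil(abs(mx)))) + 16
    d = np.zeros(nmx + 1, dtype=np.complex128)
    for n in range(nmx, 0, -1):
        d[n - 1] = n / mx - 1.0 / (d[n] + n / mx)
    d = d[1 : nmax + 1]

    psi = np.empty(nmax + 1)
    chi = np.empty(nmax + 1)
    psi[0], chi[0] = math.sin(x), math.cos(x)
    psi_prev, chi_prev = math.cos(x), -math.sin(x)  # order -1
    for n in range(1, nmax + 1):
        fac = (2 * n - 1) / x
        psi[n] = fac * psi[n - 1] - (psi[n - 2] if n >= 2 else psi_prev)
        chi[n] = fac * chi[n - 1] - (chi[n - 2] if n >= 2 else chi_prev)
    xi = psi - 1j * chi

    n = np.arange(1, nmax + 1)
    fa = d / m + n / x
    fb = d * m + n / x
    a = (fa * psi[1:] - psi[:-1]) / (fa * xi[1:] - xi[:-1])
    b = (fb * psi[1:] - psi[:-1]) / (fb * xi[1:] - xi[:-1])
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ArithmeticError(
            f"Mie series failed to converge at truncation order {nmax}"
        )
    return a, b


def _amplitude_functions(
    a: np.ndarray, b: np.ndarray, mu: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Amplitude functions S1, S2 on a grid of mu = cos(theta)."""
    s1 = np.zeros(mu.shape, dtype=np.complex128)
    s2 = np.zeros(mu.shape, dtype=np.complex128)
    pi_prev = np.zeros_like(mu)  # pi_0
    pi_cur = np.ones_like(mu)  # pi_1
    for order in range(1, a.size + 1):
        tau = order * mu * pi_cur - (order + 1) * pi_prev
        f = (2 * order + 1) / (order * (order + 1))
        s1 += f * (a[order - 1] * pi_cur + b[order - 1] * tau)
        s2 += f * (a[order - 1] * tau + b[order - 1] * pi_cur)
        pi_next = ((2 * order + 1) * mu * pi_cur - (order + 1) * pi_prev) / order
        pi_prev, pi_cur = pi_cur, pi_next
    return s1, s2


def _efficiencies(a: np.ndarray, b: np.ndarray, x: float) -> Tuple[float, float]:
    """(Q_sca, g) from the coefficient sums."""
    n = np.arange(1, a.size + 1, dtype=float)
    qsca = (2.0 / x**2) * np.sum((2 * n + 1) * (np.abs(a) ** 2 + np.abs(b) ** 2))
    cross = np.sum((2 * n + 1) / (n * (n + 1)) * np.real(a * np.conj(b)))
    seq = np.sum(
        n[:-1]
        * (n[:-1] + 2)
        / (n[:-1] + 1)
        * np.real(a[:-1] * np.conj(a[1:]) + b[:-1] * np.conj(b[1:]))
    )
    g = 4.0 / (x**2 * qsca) * (seq + cross) if qsca > 0 else 0.0
    return float(qsca), float(g)


def compute_mueller_table(
    params: MieParameters, angle_resolution_deg: float = 0.25
) -> MuellerAngularTable:
    """Tabulate the single-sphere Mueller elements on a uniform angular grid.

    Parameters
    ----------
    params : MieParameters
    angle_resolution_deg : float
        Uniform grid spacing in degrees; must divide 180 and lie in (0, 1].

    Returns
    -------
    MuellerAngularTable

    Notes
    -----
    An index-matched sphere (``n_s == n_m``) scatters nothing; that degenerate
    case is flagged on the returned table (with a RuntimeWarning) rather than
    raising, so that configuration sweeps crossing the matching point survive.
    """
    if not 0.0 < angle_resolution_deg <= 1.0:
        raise ValueError("angle_resolution_deg must lie in (0, 1]")
    n_steps = int(round(180.0 / angle_resolution_deg))
    if abs(n_steps * angle_resolution_deg - 180.0) > 1e-9:
        raise ValueError("angle_resolution_deg must divide 180 evenly")
    theta = np.linspace(0.0, 180.0, n_steps + 1)

    x = params.size_parameter
    m = params.relative_index
    if abs(m - 1.0) < 1e-9:
        warnings.warn(
            "index-matched sphere: zero contrast gives forward-only trivial "
            "scattering (degenerate table)",
            RuntimeWarning,
        )
        zeros = np.zeros_like(theta)
        return MuellerAngularTable(
            theta_deg=theta,
            m11=zeros,
            m12=zeros.copy(),
            m33=zeros.copy(),
            m34=zeros.copy(),
            scattering_efficiency=0.0,
            anisotropy_g=1.0,
            params=params,
            degenerate=True,
        )

    a, b = _mie_coefficients(x, m)
    mu = np.cos(np.radians(theta))
    s1, s2 = _amplitude_functions(a, b, mu)
    m11 = 0.5 * (np.abs(s1) ** 2 + np.abs(s2) ** 2)
    m12 = 0.5 * (np.abs(s2) ** 2 - np.abs(s1) ** 2)
    c = s2 * np.conj(s1)
    qsca, g = _efficiencies(a, b, x)
    return MuellerAngularTable(
        theta_deg=theta,
        m11=m11,
        m12=m12,
        m33=c.real,
        m34=c.imag,
        scattering_efficiency=qsca,
        anisotropy_g=g,
        params=params,
    )


def scatter_stokes(
    table: MuellerAngularTable, s_in: StokesVector, theta_deg: float
) -> StokesVector:
    """Apply the single-scattering Mueller matrix at ``theta_deg`` to ``s_in``.

    The incident and scattered Stokes vectors are both referenced to the
    scattering plane.  Elements are interpolated linearly on the table grid.
    """
    m11, m12, m33, m34 = table.elements_at(theta_deg)
    return StokesVector(
        i=m11 * s_in.i + m12 * s_in.q,
        q=m12 * s_in.i + m11 * s_in.q,
        u=m33 * s_in.u + m34 * s_in.v,
        v=-m34 * s_in.u + m33 * s_in.v,
    )


def polar_intensity_profile(
    table: MuellerAngularTable, incident: StokesVector
) -> AngularProfile:
    """Signed scattered intensity of the component matching the incident state.

    For incident +45 deg linear light ``[1, 0, 1, 0]`` the matched component
    is ``U_out``; for incident right-circular light ``[1, 0, 0, 1]`` it is
    ``V_out``.  Both reduce to the same ``m33(theta)`` column of the sphere
    Mueller matrix, which is the linear/circular equivalency this package
    leans on: a negative value means the state was orthogonalized.
    """
    arr = incident.as_array()
    if np.allclose(arr, [1.0, 0.0, 1.0, 0.0], atol=1e-9):
        value = table.m33 * incident.u + table.m34 * incident.v
        component = "u_out"
    elif np.allclose(arr, [1.0, 0.0, 0.0, 1.0], atol=1e-9):
        value = -table.m34 * incident.u + table.m33 * incident.v
        component = "v_out"
    else:
        raise ValueError(
            "incident state must be pure +45 deg linear [1,0,1,0] "
            "or right-circular [1,0,0,1]"
        )
    ref = float(np.max(table.m11)) if table.m11.size else 0.0
    return AngularProfile(
        theta_deg=table.theta_deg.copy(),
        value=np.asarray(value, dtype=float),
        component=component,
        reference_scale=ref,
    )


def orthogonalization_interval(
    profile: AngularProfile,
) -> Optional[Tuple[float, float]]:
    """Largest contiguous angular interval containing 180 deg with negative value.

    Returns ``(theta_onset, theta_end)`` in the polar-display convention: the
    physical interval ``[theta_onset, 180]`` mirrors to ``[180, 360 -
    theta_onset]``, so ``theta_end = 360 - theta_onset``.  Returns ``None``
    when the profile is not orthogonalized at exact backscatter.

    Values within a small dead-band of zero (``1e-12`` of the table's peak
    ``m11``) are treated as zero so that grid-level noise does not create
    spurious crossings.
    """
    deadband = 1e-12 * max(profile.reference_scale, float(np.max(np.abs(profile.value))), 1e-300)
    negative = profile.value < -deadband
    if not negative[-1]:
        return None
    idx = profile.value.size - 1
    while idx > 0 and negative[idx - 1]:
        idx -= 1
    onset = float(profile.theta_deg[idx])
    return onset, 360.0 - onset


def number_density_for_mus(params: MieParameters, target_mus_per_cm: float) -> float:
    """Sphere number density (cm^-3) yielding a target scattering coefficient.

    ``rho = mu_s / sigma_sca`` with ``sigma_sca`` from the Mie scattering
    efficiency and the geometric cross-section.  Raises for a non-positive
    target and for an index-matched (zero cross-section) sphere.
    """
    if not target_mus_per_cm > 0:
        raise ValueError("target_mus_per_cm must be > 0")
    if abs(params.relative_index - 1.0) < 1e-9:
        raise ValueError("index-matched sphere has zero scattering cross-section")
    a, b = _mie_coefficients(params.size_parameter, params.relative_index)
    qsca, _ = _efficiencies(a, b, params.size_parameter)
    sigma = qsca * params.geometric_cross_section_cm2
    if sigma <= 0:
        raise ValueError("scattering cross-section is zero")
    return target_mus_per_cm / sigma
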