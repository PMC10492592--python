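"""Polarization-tracking Monte Carlo transport of photon packets in a turbid slab.

Each photon packet carries a full Stokes vector referenced to a local
orthonormal triad ``(v, w, u)``: ``u`` is the propagation direction, ``v`` the
"parallel" transverse axis and ``w = u x v``.  A scattering event samples the
polar angle ``theta`` from the ``m11``-weighted phase function and the azimuth
``phi`` from the polarization-dependent conditional

    p(theta, phi)  proportional to  m11(theta) I + m12(theta) (Q cos 2phi + U sin 2phi),

rotates the Stokes reference into the scattering plane, applies the sphere
Mueller matrix, and renormalizes the packet back to unit weight (the angular
sampling already carries the intensity weighting).  Carrying the frame
explicitly is algebraically equivalent to the classical meridian-plane
bookkeeping but avoids repeated meridian projections.

Backscattered packets that exit the illuminated (top) face inside a
configurable acceptance cone are analyzed in a fixed lab detection frame.
Reversing the propagation direction flips the transverse frame handedness, so
a packet whose physical polarization orientation on the optical table is
unchanged shows a sign-flipped ``U`` in the detection frame; the co/cross
analyzer split below accounts for that, which is why singly backscattered
(orthogonalized) light lands in the *co*-linear and *cross*-circular channels.

The simulation is deterministic for a given seed: every packet owns a
counter-based (splitmix64) random stream derived from the master seed, so the
result does not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from numba import njit

from .mie import (
    MieParameters,
    MuellerAngularTable,
    StokesVector,
    compute_mueller_table,
)

__all__ = [
    "MediumSpec",
    "BeamSpec",
    "DetectorConfig",
    "DetectorGrid",
    "PhotonPacket",
    "PhaseSamplingTable",
    "SimulationResult",
    "CHANNELS",
    "launch_packet",
    "sample_beam_positions",
    "propagate_step",
    "scatter_event",
    "rotate_stokes",
    "detect_packet",
    "run_simulation",
]

CHANNELS = ("co_linear", "cross_linear", "co_circular", "cross_circular")

_INCIDENT_STATES = {
    "linear_minus45": (1.0, 0.0, -1.0, 0.0),
    "linear_plus45": (1.0, 0.0, 1.0, 0.0),
    "circular_right": (1.0, 0.0, 0.0, 1.0),
    "circular_left": (1.0, 0.0, 0.0, -1.0),
}

#: incident polarization axis in the image frame (deg CCW from +x), used by
#: the spatial analysis to orient regions relative to the polarization vector.
_POL_AXIS_DEG = {
    "linear_minus45": -45.0,
    "linear_plus45": 45.0,
    "circular_right": 0.0,
    "circular_left": 0.0,
}

RESULT_FORMAT_VERSION = "1"


# --------------------------------------------------------------------------
# specifications
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class MediumSpec:
    """Cubic (or box) suspension of identical spheres.

    ``mus_per_cm`` is the scattering coefficient; ``mua_per_cm`` (default 0,
    water is transparent at the red wavelengths used here) attenuates packet
    weight along the accumulated pathlength.  ``box_cm = (Lx, Ly, Lz)`` with
    the beam entering the top face ``z = 0`` at normal incidence; ``x`` and
    ``y`` span ``[-L/2, L/2]``.
    """

    mie: MieParameters
    mus_per_cm: float
    mua_per_cm: float = 0.0
    box_cm: Tuple[float, float, float] = (2.2, 2.2, 2.2)

    def __post_init__(self) -> None:
        if not self.mus_per_cm > 0:
            raise ValueError("mus_per_cm must be > 0")
        if self.mua_per_cm < 0:
            raise ValueError("mua_per_cm must be >= 0")
        if len(self.box_cm) != 3 or any(not l > 0 for l in self.box_cm):
            raise ValueError("box_cm dimensions must be positive")

    @property
    def optical_thickness(self) -> float:
        return self.mus_per_cm * self.box_cm[2]


@dataclass(frozen=True)
class BeamSpec:
    """Flat-field, normally incident, polarized illumination disc."""

    diameter_mm: float = 3.0
    incident_state: str = "linear_minus45"
    profile: str = "flat_field"

    def __post_init__(self) -> None:
        if not self.diameter_mm > 0:
            raise ValueError("diameter_mm must be > 0")
        if self.incident_state not in _INCIDENT_STATES:
            raise ValueError(
                f"incident_state must be one of {sorted(_INCIDENT_STATES)}"
            )
        if self.profile != "flat_field":
            raise ValueError("only the flat_field beam profile is supported")

    @property
    def radius_cm(self) -> float:
        return 0.05 * self.diameter_mm

    def initial_stokes(self) -> StokesVector:
        return StokesVector(*_INCIDENT_STATES[self.incident_state])

    @property
    def pol_axis_deg(self) -> float:
        return _POL_AXIS_DEG[self.incident_state]

    @property
    def analyzer_signs(self) -> Tuple[float, float]:
        """(su, sv): signs of the incident U and V used by the analyzer split.

        co_linear   = (I - su * U_det) / 2      cross_linear   = (I + su * U_det) / 2
        co_circular = (I + sv * V_det) / 2      cross_circular = (I - sv * V_det) / 2

        The minus sign on the linear pair encodes the detection-frame flip:
        the physical orientation parallel to the incident vector appears with
        opposite U once the propagation direction is reversed.
        """
        _, _, u0, v0 = _INCIDENT_STATES[self.incident_state]
        su = u0 if u0 != 0.0 else 1.0
        sv = v0 if v0 != 0.0 else 1.0
        return su, sv


@dataclass(frozen=True)
class DetectorConfig:
    """Backscatter detector: pixel grid centred on the beam axis."""

    nx: int = 101
    ny: int = 101
    field_mm: float = 20.0
    acceptance_deg: float = 15.0

    def __post_init__(self) -> None:
        if self.nx < 1 or self.ny < 1:
            raise ValueError("pixel counts must be >= 1")
        if not self.field_mm > 0:
            raise ValueError("field_mm must be > 0")
        if not 0 < self.acceptance_deg <= 90:
            raise ValueError("acceptance_deg must lie in (0, 90]")

    @property
    def field_cm(self) -> float:
        return 0.1 * self.field_mm


# --------------------------------------------------------------------------
# compiled primitives (shared by the per-packet API and the bulk kernel)
# --------------------------------------------------------------------------

_GOLDEN = np.uint64(0x9E3779B97F4A7C15)


@njit(cache=True, fastmath=True)
def _mix64(z):
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, fastmath=True)
def _u01(state):
    """Advance a splitmix64 stream; return (state, uniform in (0, 1))."""
    state = state + _GOLDEN
    z = _mix64(state)
    return state, ((z >> np.uint64(11)) + np.uint64(1)) * (1.0 / 9007199254740993.0)


@njit(cache=True, fastmath=True)
def _packet_stream(seed, packet_index):
    """Independent per-packet stream state derived from the master seed."""
    return _mix64(np.uint64(seed) ^ (np.uint64(packet_index) * _GOLDEN))


@njit(cache=True, fastmath=True)
def _sample_theta_index(cdf, xi):
    """Invert the tabulated phase-function CDF: (segment index, fraction)."""
    lo = 0
    hi = cdf.size - 1
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if cdf[mid] < xi:
            lo = mid
        else:
            hi = mid
    seg = cdf[hi] - cdf[lo]
    f = 0.5 if seg <= 0.0 else (xi - cdf[lo]) / seg
    return lo, f


@njit(cache=True, fastmath=True)
def _scatter_transform(
    ux, uy, uz, vx, vy, vz, wx, wy, wz, qs, us, vs, theta, phi, r12, r33, r34
):
    """Deterministic part of one scattering event.

    Rotates the transverse frame by ``phi`` about ``u``, deflects by ``theta``
    in the new (u, v) plane, applies the normalized Mueller matrix
    (elements divided by m11) and renormalizes the packet to unit weight.
    Returns the re-orthonormalized triad and the new (Q, U, V).
    """
    cp = math.cos(phi)
    sp = math.sin(phi)
    v1x = vx * cp + wx * sp
    v1y = vy * cp + wy * sp
    v1z = vz * cp + wz * sp
    w1x = -vx * sp + wx * cp
    w1y = -vy * sp + wy * cp
    w1z = -vz * sp + wz * cp

    c2p = cp * cp - sp * sp
    s2p = 2.0 * sp * cp
    q1 = qs * c2p + us * s2p
    u1 = -qs * s2p + us * c2p

    ct = math.cos(theta)
    st = math.sin(theta)
    nux = ux * ct + v1x * st
    nuy = uy * ct + v1y * st
    nuz = uz * ct + v1z * st
    nvx = v1x * ct - ux * st
    nvy = v1y * ct - uy * st
    nvz = v1z * ct - uz * st

    i2 = 1.0 + r12 * q1
    if i2 <= 0.0:
        i2 = 1e-300
    inv = 1.0 / i2
    q2 = (r12 + q1) * inv
    u2 = (r33 * u1 + r34 * vs) * inv
    v2 = (-r34 * u1 + r33 * vs) * inv

    # re-orthonormalize the triad to hold the 1e-9 orthonormality invariant
    norm = math.sqrt(nux * nux + nuy * nuy + nuz * nuz)
    nux /= norm
    nuy /= norm
    nuz /= norm
    dot = nvx * nux + nvy * nuy + nvz * nuz
    nvx -= dot * nux
    nvy -= dot * nuy
    nvz -= dot * nuz
    norm = math.sqrt(nvx * nvx + nvy * nvy + nvz * nvz)
    nvx /= norm
    nvy /= norm
    nvz /= norm
    nwx = nuy * nvz - nuz * nvy
    nwy = nuz * nvx - nux * nvz
    nwz = nux * nvy - nuy * nvx
    return nux, nuy, nuz, nvx, nvy, nvz, nwx, nwy, nwz, q2, u2, v2


@njit(cache=True, fastmath=True)
def _detection_stokes(ux, uy, uz, vx, vy, vz, wx, wy, wz, qs, us, vs):
    """Rotate the packet Stokes vector into the fixed lab detection frame.

    The detection basis is ``e1 = normalize(x_lab - (x_lab . u) u)``,
    ``e2 = u x e1``; for exact backscatter (u = -z) that is ``(x, -y, -z)``,
    a right-handed frame looking back along the return beam.
    """
    e1x = 1.0 - ux * ux
    e1y = -ux * uy
    e1z = -ux * uz
    norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    if norm < 1e-9:
        # propagation along lab x: fall back to the y axis as reference
        e1x = -uy * ux
        e1y = 1.0 - uy * uy
        e1z = -uy * uz
        norm = math.sqrt(e1x * e1x + e1y * e1y + e1z * e1z)
    e1x /= norm
    e1y /= norm
    e1z /= norm
    cpsi = vx * e1x + vy * e1y + vz * e1z
    spsi = wx * e1x + wy * e1y + wz * e1z
    c2 = cpsi * cpsi - spsi * spsi
    s2 = 2.0 * cpsi * spsi
    qd = qs * c2 + us * s2
    ud = -qs * s2 + us * c2
    return qd, ud, vs


@njit(cache=True, fastmath=True)
def _sample_phi(state, qs, us, r12):
    """Rejection-sample the scattering azimuth for the current Stokes state."""
    amp = math.sqrt(qs * qs + us * us)
    env = 1.0 + abs(r12) * amp
    for _ in range(10000):
        state, x1 = _u01(state)
        state, x2 = _u01(state)
        phi = 2.0 * math.pi * x1
        c2p = math.cos(2.0 * phi)
        s2p = math.sin(2.0 * phi)
        p = 1.0 + r12 * (qs * c2p + us * s2p)
        if x2 * env <= p:
            return state, phi
    raise RuntimeError("azimuth rejection-sampling iteration cap exceeded")


@njit(cache=True, fastmath=True)
def _run_kernel(
    n_packets,
    seed,
    mus,
    mua,
    hx,
    hy,
    lz,
    beam_r,
    q0,
    u0,
    v0,
    su,
    sv,
    thetas,
    cdf,
    r12t,
    r33t,
    r34t,
    nx,
    ny,
    field_cm,
    accept_cos,
    max_events,
    record,
    rec_cap,
):
    channels = np.zeros((4, ny, nx))
    ch_nscatter = np.zeros((4, ny, nx))
    count = np.zeros((ny, nx))
    nsc_img = np.zeros((ny, nx))
    path_img = np.zeros((ny, nx))
    n_detected = 0
    n_missed = 0
    n_capped = 0
    pitch = field_cm / nx
    pitchy = field_cm / ny
    half = 0.5 * field_cm
    halfy = 0.5 * field_cm
    rec = np.zeros((rec_cap if record else 1, 8))
    n_rec = 0

    for ip in range(n_packets):
        state = _packet_stream(seed, ip)
        state, xr = _u01(state)
        state, xa = _u01(state)
        r = beam_r * math.sqrt(xr)
        ang = 2.0 * math.pi * xa
        x = r * math.cos(ang)
        y = r * math.sin(ang)
        z = 0.0
        ux, uy, uz = 0.0, 0.0, 1.0
        vx, vy, vz = 1.0, 0.0, 0.0
        wx, wy, wz = 0.0, 1.0, 0.0
        qs, us, vs = q0, u0, v0
        nsc = 0
        path = 0.0

        while True:
            state, xi = _u01(state)
            step = -math.log(xi) / mus

            # distance to the nearest boundary along u
            tb = 1e300
            face = -1
            if ux > 0.0:
                t = (hx - x) / ux
                if t < tb:
                    tb = t
                    face = 0
            elif ux < 0.0:
                t = (-hx - x) / ux
                if t < tb:
                    tb = t
                    face = 1
            if uy > 0.0:
                t = (hy - y) / uy
                if t < tb:
                    tb = t
                    face = 2
            elif uy < 0.0:
                t = (-hy - y) / uy
                if t < tb:
                    tb = t
                    face = 3
            if uz > 0.0:
                t = (lz - z) / uz
                if t < tb:
                    tb = t
                    face = 5
            elif uz < 0.0:
                t = -z / uz
                if t < tb:
                    tb = t
                    face = 4

            if tb <= step:
                # exits the medium (index-matched boundaries)
                x += ux * tb
                y += uy * tb
                z += uz * tb
                path += tb
                if face == 4 and (-uz) >= accept_cos:
                    ix = int(math.floor((x + half) / pitch))
                    iy = int(math.floor((y + halfy) / pitchy))
                    if 0 <= ix < nx and 0 <= iy < ny:
                        qd, ud, vd = _detection_stokes(
                            ux, uy, uz, vx, vy, vz, wx, wy, wz, qs, us, vs
                        )
                        wgt = math.exp(-mua * path) if mua > 0.0 else 1.0
                        col = 0.5 * (1.0 - su * ud) * wgt
                        cxl = 0.5 * (1.0 + su * ud) * wgt
                        coc = 0.5 * (1.0 + sv * vd) * wgt
                        cxc = 0.5 * (1.0 - sv * vd) * wgt
                        channels[0, iy, ix] += col
                        channels[1, iy, ix] += cxl
                        channels[2, iy, ix] += coc
                        channels[3, iy, ix] += cxc
                        ch_nscatter[0, iy, ix] += col * nsc
                        ch_nscatter[1, iy, ix] += cxl * nsc
                        ch_nscatter[2, iy, ix] += coc * nsc
                        ch_nscatter[3, iy, ix] += cxc * nsc
                        count[iy, ix] += 1.0
                        nsc_img[iy, ix] += nsc
                        path_img[iy, ix] += path
                        n_detected += 1
                        if record and n_rec < rec_cap:
                            rec[n_rec, 0] = x
                            rec[n_rec, 1] = y
                            rec[n_rec, 2] = -uz
                            rec[n_rec, 3] = qd
                            rec[n_rec, 4] = ud
                            rec[n_rec, 5] = vd
                            rec[n_rec, 6] = nsc
                            rec[n_rec, 7] = path
                            n_rec += 1
                    else:
                        n_missed += 1
                break

            # interior: advance and scatter
            x += ux * step
            y += uy * step
            z += uz * step
            path += step
            if nsc >= max_events:
                n_capped += 1
                break

            state, xt = _u01(state)
            lo, f = _sample_theta_index(cdf, xt)
            theta = thetas[lo] + f * (thetas[lo + 1] - thetas[lo])
            r12 = r12t[lo] + f * (r12t[lo + 1] - r12t[lo])
            r33 = r33t[lo] + f * (r33t[lo + 1] - r33t[lo])
            r34 = r34t[lo] + f * (r34t[lo + 1] - r34t[lo])
            state, phi = _sample_phi(state, qs, us, r12)
            (
                ux, uy, uz, vx, vy, vz, wx, wy, wz, qs, us, vs
            ) = _scatter_transform(
                ux, uy, uz, vx, vy, vz, wx, wy, wz,
                qs, us, vs, theta, phi, r12, r33, r34,
            )
            nsc += 1

    return (
        channels,
        ch_nscatter,
        count,
        nsc_img,
        path_img,
        n_detected,
        n_missed,
        n_capped,
        rec[:n_rec].copy(),
    )


# --------------------------------------------------------------------------
# phase-function sampling table
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhaseSamplingTable:
    """Tabulated sampling machinery derived from a MuellerAngularTable.

    ``cdf`` is the cumulative distribution of ``m11(theta) sin(theta)`` on the
    table grid (trapezoid rule), used for inverse-CDF sampling of the polar
    angle; ``r12, r33, r34`` are the Mueller elements normalized by ``m11``.
    """

    theta_rad: np.ndarray
    cdf: np.ndarray
    r12: np.ndarray
    r33: np.ndarray
    r34: np.ndarray

    @classmethod
    def from_table(cls, table: MuellerAngularTable) -> "PhaseSamplingTable":
        if table.degenerate:
            raise ValueError("cannot sample a degenerate (index-matched) table")
        th = np.radians(table.theta_deg)
        pdf = table.m11 * np.sin(th)
        seg = 0.5 * (pdf[1:] + pdf[:-1]) * np.diff(th)
        cdf = np.concatenate([[0.0], np.cumsum(seg)])
        cdf /= cdf[-1]
        with np.errstate(divide="ignore", invalid="ignore"):
            safe = np.where(table.m11 > 0, table.m11, 1.0)
        return cls(
            theta_rad=th,
            cdf=cdf,
            r12=np.asarray(table.m12 / safe, dtype=float),
            r33=np.asarray(table.m33 / safe, dtype=float),
            r34=np.asarray(table.m34 / safe, dtype=float),
        )

    def sample_theta(self, xi: np.ndarray) -> np.ndarray:
        """Vectorized inverse-CDF sampling; returns angles in radians."""
        return np.interp(xi, self.cdf, self.theta_rad)


# --------------------------------------------------------------------------
# per-packet API
# --------------------------------------------------------------------------


@dataclass
class PhotonPacket:
    """Mutable state of one photon packet during transport."""

    position: np.ndarray
    direction: np.ndarray
    frame_v: np.ndarray
    stokes: StokesVector
    n_scatter: int = 0
    pathlength_cm: float = 0.0
    alive: bool = True
    exit_face: Optional[str] = None

    @property
    def frame_w(self) -> np.ndarray:
        return np.cross(self.direction, self.frame_v)

    def frame_orthonormality_error(self) -> float:
        u, v = self.direction, self.frame_v
        return max(
            abs(float(u @ u) - 1.0),
            abs(float(v @ v) - 1.0),
            abs(float(u @ v)),
        )


def sample_beam_positions(
    beam: BeamSpec, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Uniform start positions on the flat-field beam disc; (n, 2) array in cm."""
    r = beam.radius_cm * np.sqrt(rng.random(n))
    ang = 2.0 * np.pi * rng.random(n)
    return np.column_stack([r * np.cos(ang), r * np.sin(ang)])


def launch_packet(beam: BeamSpec, rng: np.random.Generator) -> PhotonPacket:
    """Launch one packet: uniform on the beam disc, normally incident, pure state."""
    (xy,) = sample_beam_positions(beam, 1, rng)
    return PhotonPacket(
        position=np.array([xy[0], xy[1], 0.0]),
        direction=np.array([0.0, 0.0, 1.0]),
        frame_v=np.array([1.0, 0.0, 0.0]),
        stokes=beam.initial_stokes(),
    )


_FACES = {0: "+x", 1: "-x", 2: "+y", 3: "-y", 4: "top", 5: "bottom"}


def _boundary_distance(
    position: np.ndarray, direction: np.ndarray, medium: MediumSpec
) -> Tuple[float, str]:
    hx, hy = medium.box_cm[0] / 2, medium.box_cm[1] / 2
    lz = medium.box_cm[2]
    bounds_lo = np.array([-hx, -hy, 0.0])
    bounds_hi = np.array([hx, hy, lz])
    tb, face = math.inf, ""
    for axis in range(3):
        d = direction[axis]
        if d > 0:
            t = (bounds_hi[axis] - position[axis]) / d
            name = _FACES[(0, 2, 5)[axis]]
        elif d < 0:
            t = (bounds_lo[axis] - position[axis]) / d
            name = _FACES[(1, 3, 4)[axis]]
        else:
            continue
        if t < tb:
            tb, face = t, name
    return tb, face


def propagate_step(
    packet: PhotonPacket, medium: MediumSpec, rng: np.random.Generator
) -> PhotonPacket:
    """One exponential free-path step; exits (and deactivates) at a boundary.

    Step length ``s = -ln(xi) / mu_s``.  If the sampled step crosses a
    boundary the packet is moved exactly onto the boundary, marked dead, and
    ``exit_face`` records which face it left through (no scattering-count
    increment on exit).
    """
    if not packet.alive:
        raise ValueError("packet is not alive")
    xi = 1.0 - rng.random()  # in (0, 1]
    step = -math.log(xi) / medium.mus_per_cm
    tb, face = _boundary_distance(packet.position, packet.direction, medium)
    if tb <= step:
        packet.position = packet.position + packet.direction * tb
        packet.pathlength_cm += tb
        packet.alive = False
        packet.exit_face = face
    else:
        packet.position = packet.position + packet.direction * step
        packet.pathlength_cm += step
    return packet


def rotate_stokes(stokes: StokesVector, phi_rad: float) -> StokesVector:
    """Rotate the Stokes reference frame by ``phi`` about the propagation axis."""
    c2 = math.cos(2.0 * phi_rad)
    s2 = math.sin(2.0 * phi_rad)
    return StokesVector(
        i=stokes.i,
        q=stokes.q * c2 + stokes.u * s2,
        u=-stokes.q * s2 + stokes.u * c2,
        v=stokes.v,
    )


def scatter_event(
    packet: PhotonPacket,
    table: MuellerAngularTable,
    rng: np.random.Generator,
    sampling: Optional[PhaseSamplingTable] = None,
    forced_angles: Optional[Tuple[float, float]] = None,
) -> PhotonPacket:
    """Scatter the packet once off a sphere described by ``table``.

    ``(theta, phi)`` are sampled from the polarization-dependent phase
    function unless ``forced_angles`` (radians) is given, which is useful for
    deterministic checks.  The deterministic frame/Stokes update is the same
    compiled transform the bulk kernel uses.
    """
    if not packet.alive:
        raise ValueError("packet is not alive")
    if sampling is None:
        sampling = PhaseSamplingTable.from_table(table)
    s = packet.stokes
    qs, us, vs = s.q / s.i, s.u / s.i, s.v / s.i
    if forced_angles is not None:
        theta, phi = forced_angles
        idx = min(
            np.searchsorted(sampling.theta_rad, theta) , sampling.theta_rad.size - 1
        )
        lo = max(idx - 1, 0)
        span = sampling.theta_rad[lo + 1] - sampling.theta_rad[lo]
        f = (theta - sampling.theta_rad[lo]) / span if span > 0 else 0.0
    else:
        lo, f = _sample_theta_index(sampling.cdf, 1.0 - rng.random())
        theta = sampling.theta_rad[lo] + f * (
            sampling.theta_rad[lo + 1] - sampling.theta_rad[lo]
        )
        phi = None
    r12 = sampling.r12[lo] + f * (sampling.r12[lo + 1] - sampling.r12[lo])
    r33 = sampling.r33[lo] + f * (sampling.r33[lo + 1] - sampling.r33[lo])
    r34 = sampling.r34[lo] + f * (sampling.r34[lo + 1] - sampling.r34[lo])
    if phi is None:
        amp = math.sqrt(qs * qs + us * us)
        env = 1.0 + abs(r12) * amp
        for _ in range(10000):
            cand = 2.0 * math.pi * rng.random()
            p = 1.0 + r12 * (
                qs * math.cos(2 * cand) + us * math.sin(2 * cand)
            )
            if rng.random() * env <= p:
                phi = cand
                break
        else:
            raise RuntimeError("azimuth rejection-sampling iteration cap exceeded")

    u, v, w = packet.direction, packet.frame_v, packet.frame_w
    out = _scatter_transform(
        u[0], u[1], u[2], v[0], v[1], v[2], w[0], w[1], w[2],
        qs, us, vs, theta, phi, r12, r33, r34,
    )
    packet.direction = np.array(out[0:3])
    packet.frame_v = np.array(out[3:6])
    packet.stokes = StokesVector(1.0, out[9], out[10], out[11])
    packet.n_scatter += 1
    return packet


# --------------------------------------------------------------------------
# detection
# --------------------------------------------------------------------------


@dataclass
class DetectorGrid:
    """Accumulating backscatter detector (per-pixel analyzer channels)."""

    config: DetectorConfig
    beam: BeamSpec
    channels: np.ndarray = field(init=False)
    channel_nscatter: np.ndarray = field(init=False)
    photon_count: np.ndarray = field(init=False)
    nscatter_total: np.ndarray = field(init=False)
    pathlength_total: np.ndarray = field(init=False)
    n_detected: int = 0
    n_missed: int = 0

    def __post_init__(self) -> None:
        shape = (self.config.ny, self.config.nx)
        self.channels = np.zeros((4,) + shape)
        self.channel_nscatter = np.zeros((4,) + shape)
        self.photon_count = np.zeros(shape)
        self.nscatter_total = np.zeros(shape)
        self.pathlength_total = np.zeros(shape)

    def add(self, packet: PhotonPacket) -> bool:
        """Bin an exiting packet; returns False when it misses the grid extent.

        Precondition: the packet left through the top face inside the
        acceptance cone (checked; ValueError otherwise).
        """
        if packet.exit_face != "top":
            raise ValueError("packet did not exit through the illuminated face")
        cos_exit = -packet.direction[2]
        if cos_exit < math.cos(math.radians(self.config.acceptance_deg)) - 1e-12:
            raise ValueError("packet exits outside the acceptance cone")
        cfg = self.config
        pitch_x = cfg.field_cm / cfg.nx
        pitch_y = cfg.field_cm / cfg.ny
        ix = int(math.floor((packet.position[0] + cfg.field_cm / 2) / pitch_x))
        iy = int(math.floor((packet.position[1] + cfg.field_cm / 2) / pitch_y))
        if not (0 <= ix < cfg.nx and 0 <= iy < cfg.ny):
            self.n_missed += 1
            return False
        u, v, w = packet.direction, packet.frame_v, packet.frame_w
        s = packet.stokes
        qd, ud, vd = _detection_stokes(
            u[0], u[1], u[2], v[0], v[1], v[2], w[0], w[1], w[2],
            s.q / s.i, s.u / s.i, s.v / s.i,
        )
        su, sv = self.beam.analyzer_signs
        wgt = s.i
        vals = (
            0.5 * (1.0 - su * ud) * wgt,
            0.5 * (1.0 + su * ud) * wgt,
            0.5 * (1.0 + sv * vd) * wgt,
            0.5 * (1.0 - sv * vd) * wgt,
        )
        for ch, val in enumerate(vals):
            self.channels[ch, iy, ix] += val
            self.channel_nscatter[ch, iy, ix] += val * packet.n_scatter
        self.photon_count[iy, ix] += 1
        self.nscatter_total[iy, ix] += packet.n_scatter
        self.pathlength_total[iy, ix] += packet.pathlength_cm
        self.n_detected += 1
        return True


def detect_packet(packet: PhotonPacket, grid: DetectorGrid) -> DetectorGrid:
    """Accumulate one exiting packet on the detector grid (see DetectorGrid.add)."""
    grid.add(packet)
    return grid


# --------------------------------------------------------------------------
# full simulation
# --------------------------------------------------------------------------


@dataclass
class SimulationResult:
    """Backscattered polarimetric images plus per-pixel transport bookkeeping.

    ``channels`` maps analyzer names to intensity images; ``channel_nscatter``
    holds the intensity-weighted scattering-event totals used to build
    per-channel N maps; ``photon_count`` / ``nscatter_total`` /
    ``pathlength_total`` are per-pixel unweighted packet tallies.
    """

    channels: Dict[str, np.ndarray]
    channel_nscatter: Dict[str, np.ndarray]
    photon_count: np.ndarray
    nscatter_total: np.ndarray
    pathlength_total: np.ndarray
    launched: int
    detected: int
    missed: int
    capped: int
    seed: int
    pol_axis_deg: float
    detector: DetectorConfig
    medium_echo: dict
    beam_echo: dict
    detections: Optional[Dict[str, np.ndarray]] = None
    format_version: str = RESULT_FORMAT_VERSION

    @property
    def total_intensity(self) -> np.ndarray:
        return self.channels["co_linear"] + self.channels["cross_linear"]


def run_simulation(
    medium: MediumSpec,
    beam: BeamSpec,
    detector: DetectorConfig = DetectorConfig(),
    n_packets: int = 1_000_000,
    seed: int = 0,
    max_events: int = 100_000,
    angle_resolution_deg: float = 0.25,
    table: Optional[MuellerAngularTable] = None,
    record_detections: bool = False,
    record_capacity: Optional[int] = None,
) -> SimulationResult:
    """Run the polarized Monte Carlo and accumulate backscattered images.

    Deterministic for a given ``seed`` (per-packet counter-based streams).
    ``record_detections`` additionally returns per-detection exit positions,
    exit-angle cosines, detection-frame Stokes components, scattering counts
    and pathlengths (up to ``record_capacity`` rows), which the
    single-scattering validation uses.
    """
    if n_packets < 1:
        raise ValueError("n_packets must be >= 1")
    if table is None:
        table = compute_mueller_table(medium.mie, angle_resolution_deg)
    sampling = PhaseSamplingTable.from_table(table)
    s0 = beam.initial_stokes()
    su, sv = beam.analyzer_signs
    cap = int(record_capacity or min(n_packets, 2_000_000))

    (
        channels,
        ch_nsc,
        count,
        nsc_img,
        path_img,
        detected,
        missed,
        capped,
        rec,
    ) = _run_kernel(
        n_packets,
        np.uint64(seed),
        medium.mus_per_cm,
        medium.mua_per_cm,
        medium.box_cm[0] / 2.0,
        medium.box_cm[1] / 2.0,
        medium.box_cm[2],
        beam.radius_cm,
        s0.q,
        s0.u,
        s0.v,
        su,
        sv,
        sampling.theta_rad,
        sampling.cdf,
        sampling.r12,
        sampling.r33,
        sampling.r34,
        detector.nx,
        detector.ny,
        detector.field_cm,
        math.cos(math.radians(detector.acceptance_deg)),
        max_events,
        record_detections,
        cap,
    )
    detections = None
    if record_detections:
        detections = {
            "x_cm": rec[:, 0],
            "y_cm": rec[:, 1],
            "cos_exit": rec[:, 2],
            "q_det": rec[:, 3],
            "u_det": rec[:, 4],
            "v_det": rec[:, 5],
            "n_scatter": rec[:, 6].astype(np.int64),
            "pathlength_cm": rec[:, 7],
        }
    from dataclasses import asdict

    return SimulationResult(
        channels={name: channels[i] for i, name in enumerate(CHANNELS)},
        channel_nscatter={name: ch_nsc[i] for i, name in enumerate(CHANNELS)},
        photon_count=count,
        nscatter_total=nsc_img,
        pathlength_total=path_img,
        launched=n_packets,
        detected=int(detected),
        missed=int(missed),
        capped=int(capped),
        seed=int(seed),
        pol_axis_deg=beam.pol_axis_deg,
        detector=detector,
        medium_echo={
            "mus_per_cm": medium.mus_per_cm,
            "mua_per_cm": medium.mua_per_cm,
            "box_cm": list(medium.box_cm),
            "mie": asdict(medium.mie),
        },
        beam_echo={
            "diameter_mm": beam.diameter_mm,
            "incident_state": beam.incident_state,
            "profile": beam.profile,
        },
        detections=detections,
    )
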