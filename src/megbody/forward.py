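"""Magnetic forward model for a homogeneous spherical conductor.

The field of a current dipole inside a conducting sphere has the closed
form (Sarvas): with sensor position ``r``, dipole position ``r0`` and
moment ``q`` (A·m), ``a = r - r0``,

    F      = a (r a + r^2 - r0·r)
    grad F = (a^2/r + a·r/a + 2a + 2r) r - (a + 2r + a·r/a) r0
    B(r)   = mu0 / (4 pi F^2) * (F (q x r0) - ((q x r0)·r) grad F)

Two structural properties follow immediately and are relied on throughout:
a radial dipole (q parallel to r0) is silent outside the sphere, and B is
linear in q. The lead field collects the projection of B onto each
sensor's pickup orientation for a unit dipole along each source
orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, SensorArray, SourceSpace

MU0_OVER_4PI = 1e-7  # T·m/A


@dataclass(frozen=True)
class LeadField:
    """Gain matrix (channels x vertices, tesla per A·m) plus conductor geometry."""

    gain: np.ndarray
    center: np.ndarray  # (3,) conductor centre, metres
    radius: float  # conductor radius, metres

    @property
    def n_channels(self) -> int:
        return self.gain.shape[0]

    @property
    def n_vertices(self) -> int:
        return self.gain.shape[1]

    def subset_channels(self, mask: np.ndarray) -> "LeadField":
        return LeadField(gain=self.gain[mask], center=self.center, radius=self.radius)


def sarvas_field(
    r: np.ndarray, r0: np.ndarray, q: np.ndarray, center: np.ndarray | None = None
) -> np.ndarray:
    """Magnetic field vector(s) at sensors ``r`` of dipole(s) ``q`` at ``r0``.

    Broadcasts over an (S, 3) sensor array and a (D, 3) dipole array,
    returning (S, D, 3) in tesla. Positions in metres, moments in A·m.
    """
    r = np.atleast_2d(np.asarray(r, dtype=float))
    r0 = np.atleast_2d(np.asarray(r0, dtype=float))
    q = np.atleast_2d(np.asarray(q, dtype=float))
    if center is not None:
        r = r - center
        r0 = r0 - center

    rs = r[:, None, :]  # (S,1,3)
    r0s = r0[None, :, :]  # (1,D,3)
    qs = q[None, :, :]

    a_vec = rs - r0s
    a = np.linalg.norm(a_vec, axis=-1)  # (S,D)
    rn = np.linalg.norm(rs, axis=-1)  # (S,1)
    adotr = np.sum(a_vec * rs, axis=-1)  # (S,D)
    r0dotr = np.sum(r0s * rs, axis=-1)

    F = a * (rn * a + rn**2 - r0dotr)
    coef_r = a**2 / rn + adotr / a + 2.0 * a + 2.0 * rn
    coef_r0 = a + 2.0 * rn + adotr / a
    gradF = coef_r[..., None] * rs - coef_r0[..., None] * r0s

    qxr0 = np.cross(qs, r0s)  # (1|S, D, 3)
    qxr0_dot_r = np.sum(qxr0 * rs, axis=-1)  # (S,D)

    B = MU0_OVER_4PI / F[..., None] ** 2 * (
        F[..., None] * qxr0 - qxr0_dot_r[..., None] * gradF
    )
    return B


def compute_lead_field(
    sensors: SensorArray,
    sources: SourceSpace,
    center: np.ndarray | None = None,
    radius: float | None = None,
) -> LeadField:
    """Lead-field matrix mapping unit dipole moments to sensor readings.

    ``gain[c, v]`` is the projection onto channel ``c``'s pickup orientation
    of the Sarvas field of a 1 A·m dipole at vertex ``v`` along the vertex
    orientation. Raises :class:`GeometryError` if any sensor lies inside or
    any source outside the conductor.
    """
    if center is None:
        center = np.zeros(3)
    center = np.asarray(center, dtype=float)
    src_r = np.linalg.norm(sources.positions - center, axis=1)
    sens_r = np.linalg.norm(sensors.positions - center, axis=1)
    if radius is None:
        radius = 0.5 * (src_r.max() + sens_r.min())
    if np.any(sens_r <= radius):
        raise GeometryError("all sensors must lie strictly outside the conductor")
    if np.any(src_r >= radius):
        raise GeometryError("all sources must lie strictly inside the conductor")

    B = sarvas_field(sensors.positions, sources.positions, sources.orientations, center)
    gain = np.einsum("svk,sk->sv", B, sensors.orientations)
    return LeadField(gain=np.ascontiguousarray(gain), center=center, radius=float(radius))
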