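"""Sensor-helmet and cortical-shell geometry for a spherical head model.

The head is modelled as a homogeneous conducting sphere. Sensors sit on a
hemispherical helmet shell 2 cm outside the scalp, each with a radial
pickup orientation (axial magnetometer approximation). Sources sit on a
"cortical" shell at 0.85 of the head radius, with tangential orientations
standing in for cortical-surface normals (the radial component of a dipole
in a spherical conductor is magnetically silent, so only the tangential
part is ever visible to MEG).

Coordinate convention: +x right, +y anterior, +z superior, origin at the
sphere centre.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))

#: fraction of channels tagged frontal with the default helmet (40 of 160)
FRONTAL_FRACTION = 0.25

# unit axes used for region tagging
_POSTERIOR_INFERIOR = np.array([0.0, -1.0, -0.5]) / np.linalg.norm([0.0, -1.0, -0.5])
_OCCIPITAL_POLE = np.array([0.0, -1.0, -0.2]) / np.linalg.norm([0.0, -1.0, -0.2])
_ANTERIOR = np.array([0.0, 1.0, 0.35]) / np.linalg.norm([0.0, 1.0, 0.35])


class GeometryError(ValueError):
    """Raised when sensor/source positions violate the conductor geometry."""


@dataclass(frozen=True)
class SensorArray:
    """MEG channel geometry: positions (m), radial unit orientations, region tags."""

    channel_ids: np.ndarray  # (n,) str
    positions: np.ndarray  # (n, 3) metres
    orientations: np.ndarray  # (n, 3) unit vectors
    region: np.ndarray  # (n,) str in {frontal, occipitotemporal, other}

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.orientations, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise GeometryError("sensor orientations must be unit vectors")

    @property
    def n_channels(self) -> int:
        return len(self.channel_ids)

    def subset(self, mask: np.ndarray) -> "SensorArray":
        return SensorArray(
            channel_ids=self.channel_ids[mask],
            positions=self.positions[mask],
            orientations=self.orientations[mask],
            region=self.region[mask],
        )


@dataclass(frozen=True)
class SourceSpace:
    """Dipole grid on a spherical cortical shell.

    Orientations are unit vectors tangential to the shell; region tags mark
    the body-selective occipitotemporal patch (``eba``), the fusiform-like
    patch (``fba``), an early-visual patch (``early_visual``) and
    ``background``.
    """

    positions: np.ndarray  # (n, 3) metres
    orientations: np.ndarray  # (n, 3) unit vectors
    region: np.ndarray  # (n,) str

    @property
    def n_vertices(self) -> int:
        return len(self.positions)

    def vertices_in(self, region: str) -> np.ndarray:
        return np.flatnonzero(self.region == region)


def _fibonacci_cap(n: int, cos_theta_min: float, phase: float = 0.0) -> np.ndarray:
    """n unit vectors quasi-uniformly covering the cap z/r >= cos_theta_min."""
    i = np.arange(n)
    z = 1.0 - (1.0 - cos_theta_min) * (i + 0.5) / n
    phi = GOLDEN_ANGLE * i + phase
    s = np.sqrt(np.clip(1.0 - z**2, 0.0, None))
    return np.column_stack([s * np.cos(phi), s * np.sin(phi), z])


def _tangential_orientations(units: np.ndarray) -> np.ndarray:
    """Deterministic tangential unit vector per point (twisted theta-hat)."""
    n = len(units)
    z_axis = np.array([0.0, 0.0, 1.0])
    # theta-hat, falling back to x-hat at the pole
    th = np.cross(np.cross(z_axis, units), units)
    bad = np.linalg.norm(th, axis=1) < 1e-9
    th[bad] = [1.0, 0.0, 0.0]
    th /= np.linalg.norm(th, axis=1, keepdims=True)
    ph = np.cross(units, th)
    ang = GOLDEN_ANGLE * np.arange(n)
    ori = np.cos(ang)[:, None] * th + np.sin(ang)[:, None] * ph
    return ori / np.linalg.norm(ori, axis=1, keepdims=True)


def build_geometry(
    n_channels: int = 160,
    n_vertices: int = 4004,
    head_radius: float = 0.09,
    seed: int = 0,
    helmet_gap: float = 0.02,
    source_shell: float = 0.85,
) -> tuple[SensorArray, SourceSpace]:
    """Build the sensor helmet and the source shell.

    Sensors lie on a shell at ``head_radius + helmet_gap`` covering the upper
    ~2/3 of the sphere (a whole-head helmet); sources on a shell at
    ``source_shell * head_radius``. Region tags are purely geometric: the
    anterior quarter of the helmet is ``frontal`` (blink-contaminated
    channels), a posterior-inferior cone is ``occipitotemporal``. Source
    regions: two bilateral posterior-inferior-lateral patches (``eba``), a
    ventral posterior patch (``fba``), an occipital-pole patch
    (``early_visual``), remainder ``background``.

    Deterministic given ``seed`` (the seed only rotates the azimuthal phase
    of the two lattices, modelling between-subject helmet/head alignment).
    """
    if head_radius <= 0:
        raise ValueError(f"head_radius must be positive, got {head_radius}")
    if n_channels < 8:
        raise ValueError("need at least 8 channels")
    if n_vertices < 16:
        raise ValueError("need at least 16 vertices")

    rng = np.random.default_rng(seed)
    sens_phase, src_phase = rng.uniform(0, 2 * np.pi, size=2)

    # helmet: polar cap down to ~125 degrees (covers temporal/occipital sites)
    sens_units = _fibonacci_cap(n_channels, np.cos(np.deg2rad(125.0)), sens_phase)
    sens_pos = (head_radius + helmet_gap) * sens_units
    sens_ori = sens_units.copy()  # radial pickup

    region = np.full(n_channels, "other", dtype=object)
    ant = sens_units @ _ANTERIOR
    # polar-angle cut about the anterior axis so a fixed fraction is frontal
    n_frontal = int(round(FRONTAL_FRACTION * n_channels))
    if n_frontal > 0:
        cut = np.sort(ant)[::-1][n_frontal - 1]
        region[ant >= cut] = "frontal"
    ot = sens_units @ _POSTERIOR_INFERIOR
    region[(ot > np.cos(np.deg2rad(60.0))) & (region != "frontal")] = "occipitotemporal"

    sensors = SensorArray(
        channel_ids=np.array([f"MEG{i:03d}" for i in range(n_channels)], dtype=object),
        positions=sens_pos,
        orientations=sens_ori,
        region=np.asarray(region, dtype=object),
    )

    # cortical shell: near-full sphere, sparing an inferior cap (brainstem/neck)
    src_units = _fibonacci_cap(n_vertices, np.cos(np.deg2rad(150.0)), src_phase)
    src_pos = source_shell * head_radius * src_units
    src_ori = _tangential_orientations(src_units)

    src_region = np.full(n_vertices, "background", dtype=object)
    for sign in (+1.0, -1.0):
        c = np.array([sign * 0.65, -0.6, -0.35])
        c /= np.linalg.norm(c)
        src_region[src_units @ c > np.cos(np.deg2rad(18.0))] = "eba"
    fba_c = np.array([0.0, -0.55, -0.75])
    fba_c /= np.linalg.norm(fba_c)
    fba = (src_units @ fba_c > np.cos(np.deg2rad(16.0))) & (src_region == "background")
    src_region[fba] = "fba"
    ev = (src_units @ _OCCIPITAL_POLE > np.cos(np.deg2rad(12.0))) & (
        src_region == "background"
    )
    src_region[ev] = "early_visual"

    sources = SourceSpace(
        positions=src_pos,
        orientations=src_ori,
        region=np.asarray(src_region, dtype=object),
    )
    return sensors, sources
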