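"""Nominal grid-of-spheres phantom geometry and synthetic rasterization.

The reference phantom is a cubic cartesian grid of thin-walled, water-filled
spheres (table-tennis balls) glued at a fixed center-to-center pitch.  A block
of spheres in the middle slice is left out so a cardiac implant can be placed
at the magnet isocenter.  Because the water spheres are bright on a dark
background, each one acts as a 3D fiducial: comparing sphere positions,
volumes, shapes and gray values between a reference scan and an implant scan
quantifies the susceptibility-induced distortion field.

This module holds the nominal geometry (:class:`PhantomSpec`), the simple
in-memory volume container used throughout the package (:class:`Volume`),
closed-form geometry helpers used by the uncertainty analysis, and an
antialiased rasterizer that turns a spec into a synthetic reference volume.

Coordinate conventions
----------------------
World coordinates are in millimetres with the origin at the phantom/grid
center, which coincides with the magnet isocenter in the intended setup.
Voxels follow the voxel-center convention: the world position of voxel
``(i, j, k)`` is ``origin + (i, j, k) * spacing``.  Grid indices are 0-based
triples; phantom axes map to patient axes as X: left-right, Y: foot-head,
Z: bottom-up.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "PhantomSpec",
    "Volume",
    "default_spec",
    "nominal_water_volume",
    "equivalent_diameter",
    "rasterize",
]

#: Default mapping of volume axes to patient axes.
DEFAULT_ORIENTATION: tuple[str, str, str] = ("left-right", "foot-head", "bottom-up")

# Grid center (3,3,3) and its four in-plane neighbours in the middle Z-slice
# are omitted to leave space for the implant holder.
DEFAULT_OMITTED: frozenset[tuple[int, int, int]] = frozenset(
    {(3, 3, 3), (2, 3, 3), (4, 3, 3), (3, 2, 3), (3, 4, 3)}
)


def _as_triple(value, name: str) -> tuple[float, float, float]:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (3,))
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")
    return (float(arr[0]), float(arr[1]), float(arr[2]))


@dataclass(frozen=True)
class PhantomSpec:
    """Nominal geometry of the grid-of-spheres reference phantom.

    Parameters
    ----------
    grid_shape
        Number of spheres along each phantom axis.
    center_spacing
        Center-to-center distance of neighbouring spheres, mm.
    sphere_outer_diameter
        Outer diameter of each sphere shell, mm.
    shell_thickness
        Plastic wall thickness, mm; the water radius is
        ``sphere_outer_diameter / 2 - shell_thickness``.
    omitted_indices
        Grid-index triples with no sphere (the implant space).
    axis_orientation
        Labels mapping volume axes to patient axes.
    water_gray, background_gray
        Dimensionless intensities assigned to water and background when the
        spec is rasterized.  Exposure correction later maps any scan onto a
        comparable range, so only their ordering matters.
    """

    grid_shape: tuple[int, int, int] = (7, 7, 7)
    center_spacing: float = 40.0
    sphere_outer_diameter: float = 40.17
    shell_thickness: float = 0.2
    omitted_indices: frozenset[tuple[int, int, int]] = DEFAULT_OMITTED
    axis_orientation: tuple[str, str, str] = DEFAULT_ORIENTATION
    water_gray: float = 1.0
    background_gray: float = 0.0

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.grid_shape)
        if len(shape) != 3 or any(n < 1 for n in shape):
            raise ValueError(f"grid_shape must be a positive triple, got {self.grid_shape!r}")
        object.__setattr__(self, "grid_shape", shape)
        if not 0 <= self.shell_thickness < self.sphere_outer_diameter / 2:
            raise ValueError(
                f"shell_thickness must lie in [0, diameter/2), got {self.shell_thickness}"
            )
        # Touching shells are fine (the real balls are glued together); only
        # the bright water regions must not overlap.
        if self.center_spacing < self.sphere_outer_diameter - 2 * self.shell_thickness:
            raise ValueError(
                "center_spacing must be >= the water diameter (water regions must "
                f"not overlap): {self.center_spacing} < "
                f"{self.sphere_outer_diameter - 2 * self.shell_thickness}"
            )
        if not self.water_gray > self.background_gray:
            raise ValueError("water_gray must exceed background_gray (bright spheres)")
        omitted = frozenset(tuple(int(i) for i in idx) for idx in self.omitted_indices)
        full = {
            (i, j, k)
            for i in range(shape[0])
            for j in range(shape[1])
            for k in range(shape[2])
        }
        if not omitted <= full:
            raise ValueError(f"omitted_indices outside the grid: {sorted(omitted - full)}")
        object.__setattr__(self, "omitted_indices", omitted)

    # -- geometry ---------------------------------------------------------

    @property
    def water_radius(self) -> float:
        """Inner (water) radius of one sphere, mm."""
        return self.sphere_outer_diameter / 2 - self.shell_thickness

    @property
    def nominal_ball_radius(self) -> float:
        """Nominal outer radius of one sphere, mm (used by the critical radius)."""
        return self.sphere_outer_diameter / 2

    def present_indices(self) -> list[tuple[int, int, int]]:
        """All grid indices that carry a sphere, in lexicographic order."""
        nx, ny, nz = self.grid_shape
        return [
            (i, j, k)
            for i in range(nx)
            for j in range(ny)
            for k in range(nz)
            if (i, j, k) not in self.omitted_indices
        ]

    @property
    def n_present(self) -> int:
        return int(np.prod(self.grid_shape)) - len(self.omitted_indices)

    def center(self, index: Sequence[int]) -> np.ndarray:
        """World position (mm) of the sphere center at a grid index."""
        idx = np.asarray(index, dtype=float)
        half = (np.asarray(self.grid_shape, dtype=float) - 1) / 2
        return (idx - half) * self.center_spacing

    def centers(self) -> np.ndarray:
        """World positions of all present sphere centers, shape (n_present, 3)."""
        return np.array([self.center(idx) for idx in self.present_indices()])

    def iter_spheres(self) -> Iterator[tuple[tuple[int, int, int], np.ndarray]]:
        for idx in self.present_indices():
            yield idx, self.center(idx)

    # -- serialization ----------------------------------------------------

    def to_json(self) -> str:
        payload = {
            "grid_shape": list(self.grid_shape),
            "center_spacing": self.center_spacing,
            "sphere_outer_diameter": self.sphere_outer_diameter,
            "shell_thickness": self.shell_thickness,
            "omitted_indices": sorted(list(i) for i in self.omitted_indices),
            "axis_orientation": list(self.axis_orientation),
            "water_gray": self.water_gray,
            "background_gray": self.background_gray,
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PhantomSpec":
        payload = json.loads(text)
        return cls(
            grid_shape=tuple(payload["grid_shape"]),
            center_spacing=payload["center_spacing"],
            sphere_outer_diameter=payload["sphere_outer_diameter"],
            shell_thickness=payload["shell_thickness"],
            omitted_indices=frozenset(tuple(i) for i in payload["omitted_indices"]),
            axis_orientation=tuple(payload["axis_orientation"]),
            water_gray=payload["water_gray"],
            background_gray=payload["background_gray"],
        )

    def with_omitted(self, omitted) -> "PhantomSpec":
        return replace(self, omitted_indices=frozenset(tuple(i) for i in omitted))


@dataclass
class Volume:
    """A 3D scalar lattice with world geometry in millimetres.

    ``data[i, j, k]`` sits at world position ``origin + (i, j, k) * spacing``
    (voxel-center convention).
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    orientation: tuple[str, str, str] = DEFAULT_ORIENTATION

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"volume data must be 3D, got shape {self.data.shape}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("volume data must be finite everywhere")
        self.spacing = _as_triple(self.spacing, "spacing")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = _as_triple(self.origin, "origin")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel, mm^3."""
        return float(np.prod(self.spacing))

    def index_to_world(self, index) -> np.ndarray:
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * np.asarray(self.spacing)

    def world_to_index(self, world) -> np.ndarray:
        return (np.asarray(world, dtype=float) - np.asarray(self.origin)) / np.asarray(self.spacing)

    def axis_coordinates(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """World coordinates of the voxel centers along each axis."""
        return tuple(
            self.origin[a] + self.spacing[a] * np.arange(self.shape[a]) for a in range(3)
        )  # type: ignore[return-value]

    def world_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) world positions of the first and last voxel centers."""
        lo = np.asarray(self.origin)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.spacing)
        return lo, hi

    def copy(self, data: np.ndarray | None = None) -> "Volume":
        return Volume(
            data=self.data.copy() if data is None else data,
            spacing=self.spacing,
            origin=self.origin,
            orientation=self.orientation,
        )

    def total_intensity(self) -> float:
        return float(self.data.sum())


def default_spec() -> PhantomSpec:
    """The as-built phantom: 7x7x7 spheres at 40 mm pitch, 40.17 mm outer
    diameter, 0.2 mm wall, five central spheres omitted for the implant."""
    return PhantomSpec()


def nominal_water_volume(outer_diameter: float, shell_thickness: float) -> float:
    """Closed-form water volume of one sphere, mm^3.

    ``(4/3) * pi * (outer_diameter/2 - shell_thickness)**3``; the wall is
    subtracted because only the water inside it produces signal.
    """
    if not (math.isfinite(outer_diameter) and math.isfinite(shell_thickness)):
        raise ValueError("non-finite sphere dimensions")
    if shell_thickness < 0 or outer_diameter <= 2 * shell_thickness:
        raise ValueError(
            f"non-physical sphere: outer diameter {outer_diameter} mm, "
            f"wall {shell_thickness} mm"
        )
    r = outer_diameter / 2 - shell_thickness
    return 4.0 / 3.0 * math.pi * r**3


def equivalent_diameter(volume: float) -> float:
    """Diameter (mm) of the sphere holding a given volume (mm^3).

    Inverts ``V = (pi/6) d^3``; used to translate reconstructed-volume spreads
    into a spatial uncertainty.
    """
    if not math.isfinite(volume) or volume <= 0:
        raise ValueError(f"volume must be positive, got {volume}")
    return float((6.0 * volume / math.pi) ** (1.0 / 3.0))


def _occupancy_patch(
    residual: np.ndarray,
    spacing: np.ndarray,
    water_radius: float,
    supersampling: int,
) -> np.ndarray:
    """Sub-voxel water occupancy of the voxels around one sphere center.

    ``residual`` is the offset (mm) of the sphere center from the nearest
    voxel center.  Returns occupancies in [0, 1] on a cubic patch of local
    voxel offsets, computed by midpoint supersampling of each voxel.
    """
    half = np.ceil(water_radius / spacing).astype(int) + 1
    s = supersampling
    occ_axes = []
    # Separable squared distances: per axis, distance of each subsample to the
    # center, then combine by broadcasting.
    sub = (np.arange(s) + 0.5) / s - 0.5
    for a in range(3):
        offs = np.arange(-half[a], half[a] + 1)
        pos = (offs[:, None] + sub[None, :]) * spacing[a] - residual[a]
        occ_axes.append(pos**2)
    d2 = (
        occ_axes[0][:, None, None, :, None, None]
        + occ_axes[1][None, :, None, None, :, None]
        + occ_axes[2][None, None, :, None, None, :]
    )
    inside = d2 <= water_radius**2
    return inside.reshape(
        occ_axes[0].shape[0], occ_axes[1].shape[0], occ_axes[2].shape[0], s**3
    ).mean(axis=3)


def rasterize(
    spec: PhantomSpec,
    spacing=2.0,
    supersampling: int = 4,
) -> Volume:
    """Rasterize the phantom into a synthetic reference volume.

    Voxels inside a present sphere's water region carry ``water_gray``, all
    others ``background_gray``; boundary voxels carry the partial-volume mix
    estimated by midpoint supersampling (``supersampling**3`` points per
    voxel).  The volume extent covers the grid plus one sphere diameter of
    margin, with a voxel centered on the phantom center (world origin).

    Deterministic: identical spec, spacing and supersampling yield
    bit-identical volumes.
    """
    sp = np.asarray(_as_triple(spacing, "spacing"))
    if np.any(sp <= 0):
        raise ValueError(f"spacing must be positive, got {spacing}")
    if int(supersampling) < 1:
        raise ValueError(f"supersampling must be >= 1, got {supersampling}")
    supersampling = int(supersampling)
    if np.any(sp > spec.sphere_outer_diameter):
        raise ValueError(
            f"voxel spacing {tuple(sp)} exceeds the sphere diameter "
            f"{spec.sphere_outer_diameter} mm; spheres would be unresolvable"
        )

    half_extent = (np.asarray(spec.grid_shape) - 1) / 2 * spec.center_spacing
    half_extent = half_extent + spec.sphere_outer_diameter
    n = 2 * np.ceil(half_extent / sp).astype(int) + 1
    origin = -(n - 1) / 2 * sp
    data = np.full(tuple(n), float(spec.background_gray))

    contrast = spec.water_gray - spec.background_gray
    patches: dict[tuple, np.ndarray] = {}
    for _, center in spec.iter_spheres():
        ic = np.rint((center - origin) / sp).astype(int)
        residual = center - (origin + ic * sp)
        key = tuple(np.round(residual / sp, 9))
        patch = patches.get(key)
        if patch is None:
            patch = _occupancy_patch(residual, sp, spec.water_radius, supersampling)
            patches[key] = patch
        half = (np.asarray(patch.shape) - 1) // 2
        lo = ic - half
        hi = ic + half + 1
        src_lo = np.maximum(0, -lo)
        src_hi = np.asarray(patch.shape) - np.maximum(0, hi - n)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, n)
        dst = data[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        # Combine by maximum, not sum: neighbouring shells touch tangentially,
        # and summing the two sub-voxel caps at a contact point would raster a
        # bright bridge above the water/background midpoint that the dark
        # plastic walls prevent in the real phantom.
        np.maximum(
            dst,
            spec.background_gray
            + contrast
            * patch[src_lo[0] : src_hi[0], src_lo[1] : src_hi[1], src_lo[2] : src_hi[2]],
            out=dst,
        )

    return Volume(
        data=data,
        spacing=tuple(sp),
        origin=tuple(origin),
        orientation=spec.axis_orientation,
    )
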