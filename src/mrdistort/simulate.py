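"""Synthetic implant-artifact simulator.

Susceptibility differences between an implant and the surrounding water
perturb the static B0 field; in conventional frequency encoding the local
off-resonance shifts signal along the readout direction, and strong
perturbations additionally dephase the signal into a void around the device.
This module emulates those artifact *qualities* with a point-dipole
off-resonance field, a readout-direction displacement proportional to the
local field, an optional signal void where the field magnitude is large, and
a multiplicative gray-value change — enough to exercise every distortion
metric with a known ground truth.  It makes no claim to reproduce any real
device's artifact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

from .phantom import Volume

__all__ = [
    "ImplantFieldModel",
    "DisplacementField",
    "dipole_offresonance",
    "displacement_from_field",
    "field_on_volume",
    "warp",
    "apply_distortion",
    "add_noise",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass(frozen=True)
class ImplantFieldModel:
    """Parameters of the synthetic implant artifact.

    moment
        Scaled dipole strength (mm^3 * field units); 0 gives the identity.
    position
        Implant position in world mm (default: isocenter).
    b0_axis
        Main-field direction; 'y' matches the foot-head bore axis.
    readout_axis
        Axis along which off-resonance displaces signal.
    displacement_scale
        mm of displacement per unit of field value.
    void_level
        Field magnitude above which the signal is suppressed to background
        (infinite by default = no void).
    intensity_gain
        Multiplicative gray-value factor applied after warping.
    """

    moment: float = 0.0
    position: tuple[float, float, float] = (0.0, 0.0, 0.0)
    readout_axis: str = "x"
    b0_axis: str = "y"
    displacement_scale: float = 1.0
    void_level: float = math.inf
    intensity_gain: float = 1.0

    def __post_init__(self) -> None:
        if not math.isfinite(self.moment) or self.moment < 0:
            raise ValueError(f"moment must be finite and >= 0, got {self.moment}")
        pos = tuple(float(p) for p in self.position)
        if len(pos) != 3 or not all(math.isfinite(p) for p in pos):
            raise ValueError(f"position must be a finite triple, got {self.position!r}")
        object.__setattr__(self, "position", pos)
        for name in ("readout_axis", "b0_axis"):
            if getattr(self, name) not in _AXES:
                raise ValueError(f"{name} must be one of {sorted(_AXES)}")
        for name in ("displacement_scale", "intensity_gain"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if math.isnan(self.void_level):
            raise ValueError("void_level must not be NaN")

    def with_moment(self, moment: float) -> "ImplantFieldModel":
        return replace(self, moment=moment)


@dataclass
class DisplacementField:
    """Per-voxel displacement vectors (mm) on a volume's grid."""

    vectors: np.ndarray  # (nx, ny, nz, 3)
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError(f"vectors must have shape (nx, ny, nz, 3), got {self.vectors.shape}")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("displacement vectors must be finite")

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def save(self, path):
        """Write the ground-truth field as a 4D NIfTI (last axis = x/y/z)."""
        import nibabel as nib

        affine = np.eye(4)
        affine[:3, :3] = np.diag(self.spacing)
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.vectors, affine), str(path))
        return path


def dipole_offresonance(model: ImplantFieldModel, points) -> np.ndarray:
    """Point-dipole off-resonance at world positions (mm).

    Returns ``m * (3 cos^2 theta - 1) / r^3`` with ``r`` the distance to the
    implant position and ``theta`` the polar angle against the main-field
    axis.  Evaluation at the singular point itself is rejected.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    rel = pts - np.asarray(model.position)
    r2 = np.einsum("...i,...i->...", rel, rel)
    if np.any(r2 == 0):
        raise ValueError("off-resonance field is singular at the implant position")
    axis = np.zeros(3)
    axis[_AXES[model.b0_axis]] = 1.0
    cos = (rel @ axis) / np.sqrt(r2)
    values = model.moment * (3.0 * cos**2 - 1.0) / r2**1.5
    return values if np.asarray(points).ndim > 1 else values[0]


def displacement_from_field(
    field_values: np.ndarray, readout_axis: str, displacement_scale: float
) -> np.ndarray:
    """Displacement vectors from an off-resonance field.

    Off-resonance mis-maps signal along the frequency-encoding direction
    only, so the displacement is ``displacement_scale * field`` along
    ``readout_axis`` and zero elsewhere.
    """
    values = np.asarray(field_values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("field values must be finite")
    if readout_axis not in _AXES:
        raise ValueError(f"readout_axis must be one of {sorted(_AXES)}")
    disp = np.zeros(values.shape + (3,))
    disp[..., _AXES[readout_axis]] = displacement_scale * values
    return disp


def field_on_volume(
    model: ImplantFieldModel, volume: Volume, r_min: float | None = None
) -> np.ndarray:
    """Dipole field sampled at every voxel center of a volume.

    The singularity is regularized by clamping the distance to ``r_min``
    (default: half the smallest voxel spacing), since the implant position
    may coincide with a voxel center.
    """
    if r_min is None:
        r_min = 0.5 * min(volume.spacing)
    ax = volume.axis_coordinates()
    rel = [ax[a] - model.position[a] for a in range(3)]
    r2 = (
        rel[0][:, None, None] ** 2
        + rel[1][None, :, None] ** 2
        + rel[2][None, None, :] ** 2
    )
    r2 = np.maximum(r2, r_min**2)
    b = rel[_AXES[model.b0_axis]]
    shape = [1, 1, 1]
    shape[_AXES[model.b0_axis]] = -1
    cos2 = b.reshape(shape) ** 2 / r2
    return model.moment * (3.0 * cos2 - 1.0) / r2**1.5


def warp(volume: Volume, displacement: np.ndarray, fill_value: float = 0.0) -> Volume:
    """Pull back a volume through a displacement field.

    ``out(x) = in(x - d(x))`` with trilinear interpolation, so image features
    move *by* ``d``.  ``displacement`` is broadcast against
    ``volume.shape + (3,)``; a uniform ``(3,)`` vector translates the whole
    volume.
    """
    disp = np.asarray(displacement, dtype=float)
    disp = np.broadcast_to(disp, volume.shape + (3,))
    if not np.all(np.isfinite(disp)):
        raise ValueError("displacement must be finite")
    idx = np.indices(volume.shape, dtype=float)
    coords = [
        idx[a] - disp[..., a] / volume.spacing[a] for a in range(3)
    ]
    out = map_coordinates(
        volume.data, coords, order=1, mode="constant", cval=float(fill_value)
    )
    return volume.copy(data=out)


def apply_distortion(
    volume: Volume, model: ImplantFieldModel, fill_value: float = 0.0
) -> tuple[Volume, DisplacementField]:
    """Apply the full synthetic artifact to a volume.

    The volume is pulled back through the dipole-readout displacement field,
    multiplied by ``intensity_gain``, and set to ``fill_value`` where the
    field magnitude exceeds ``void_level``.  Returns the distorted volume and
    the exact displacement field used, so pipeline tests can compare
    recovered metrics against ground truth.
    """
    if model.moment == 0:
        disp = np.zeros(volume.shape + (3,))
        out = volume.data * model.intensity_gain
    else:
        field = field_on_volume(model, volume)
        disp = displacement_from_field(field, model.readout_axis, model.displacement_scale)
        out = warp(volume, disp, fill_value=fill_value).data * model.intensity_gain
        if math.isfinite(model.void_level):
            out = np.where(np.abs(field) > model.void_level, float(fill_value), out)
    distorted = volume.copy(data=out)
    gt = DisplacementField(vectors=disp, spacing=volume.spacing, origin=volume.origin)
    return distorted, gt


def add_noise(volume: Volume, sigma: float, seed: int) -> Volume:
    """Additive Gaussian noise with an explicit seed (deterministic)."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    rng = np.random.default_rng(seed)
    return volume.copy(data=volume.data + rng.normal(0.0, sigma, size=volume.shape))
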