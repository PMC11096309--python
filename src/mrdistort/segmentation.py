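"""Seeded multi-label reaction-diffusion segmentation of the grid spheres.

Each present sphere of the phantom grid is segmented by its own region grown
from a seed at the nominal sphere center.  Growth follows a bistable
reaction-diffusion front: per label ``l`` a concentration field ``u_l`` on
the voxel lattice evolves under

    du_l/dt = D * lap(u_l) + k * u_l * (1 - U) * (I - theta),   U = sum_m u_m,

with ``I`` the exposure-corrected image intensity, ``theta`` the gray
threshold, explicit Euler time stepping, a 6-neighbour Laplacian and ``u``
clamped to [0, 1].  For a single label (``U = u``) this is the classical
bistable form ``u (1 - u)(I - theta)``; with several labels the shared
saturation term ``(1 - U)`` makes the fronts *compete*: once a sphere is
claimed by its own front, a neighbouring front arriving later through a
distortion-induced bright bridge ("shunt") finds no free capacity and cannot
invade.  Narrow bridges additionally stall fronts on their own, because the
transverse diffusive loss into sub-threshold surroundings exceeds the
reactive gain inside the channel.  Both effects together give the shunt
robustness that plain thresholding or watershed-style region growing lacks.

A voxel is claimed when the total concentration U exceeds 1/2 (equivalent
to u > 1/2 for a single label) and goes to the argmax label (ties break to
the lowest label for determinism), and
each label is pruned to the connected component containing its seed so every
segmented sphere is 6-connected.

For efficiency each label evolves on a cubic box around its seed (fronts are
local: a sphere never legitimately grows far beyond its own grid cell); the
coupling field ``U`` is accumulated globally each step, so competition
between neighbouring boxes is exact.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import PhantomSpec, Volume

__all__ = [
    "RDParameters",
    "Seed",
    "SeedMap",
    "BallLabelMap",
    "EmptyLabelError",
    "seed_from_grid",
    "evolve",
    "extract_surface",
]


class EmptyLabelError(ValueError):
    """Raised when an operation needs voxels of a label that has none.

    Distinct from the *disappeared* flag: a disappeared ball still has a
    (tiny) voxel set; an empty label has none at all.
    """


@dataclass(frozen=True)
class RDParameters:
    """Numerical parameters of the reaction-diffusion evolution.

    diffusion
        D, lattice units^2 per unit time.
    reaction
        k, reactive gain per unit time.  Larger values sharpen the front and
        pin it more tightly to the ``I = theta`` contour.
    threshold
        theta, the normalized gray threshold separating water from
        background (volumes are exposure-corrected to [0, 1] first).
    step
        Explicit-Euler time step.  Must satisfy the diffusion stability
        bound ``step * diffusion * 2 * dim <= 1`` (unit lattice spacing);
        steps close to the bound leave the lattice checkerboard mode
        undamped, so the default stays well below it.
    max_iterations, tol
        Stopping rule: stop when the largest per-step concentration change
        falls below ``tol``, else after ``max_iterations`` with a warning.
    box_halfwidth_mm
        Half-width of the per-label evolution box around each seed; bounds
        how far a front may travel and the memory footprint.
    min_voxels
        Labels smaller than this count as *disappeared* downstream.
    """

    diffusion: float = 0.2
    reaction: float = 4.0
    threshold: float = 0.5
    step: float = 0.4
    max_iterations: int = 2000
    tol: float = 1e-4
    box_halfwidth_mm: float = 30.0
    min_voxels: int = 8

    def __post_init__(self) -> None:
        for name in ("diffusion", "reaction", "threshold", "step", "tol", "box_halfwidth_mm"):
            if not math.isfinite(getattr(self, name)) or getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.max_iterations < 1 or self.min_voxels < 1:
            raise ValueError("max_iterations and min_voxels must be >= 1")
        if self.step * self.diffusion * 6.0 > 1.0 + 1e-12:
            raise ValueError(
                "explicit-diffusion stability bound violated: "
                f"step * D * 6 = {self.step * self.diffusion * 6:.3f} > 1"
            )


@dataclass(frozen=True)
class Seed:
    label: int
    grid_index: tuple[int, int, int]
    center: tuple[float, float, float]
    weak: bool = False


@dataclass
class SeedMap:
    """One spherical seed per present grid position."""

    seeds: list[Seed]
    radius_mm: float
    spec: PhantomSpec

    def __len__(self) -> int:
        return len(self.seeds)


@dataclass
class BallLabelMap:
    """Multi-label segmentation result congruent with the input volume.

    ``labels`` holds 0 for background and the seed label elsewhere; every
    label's voxel set is 6-connected and maps to exactly one grid index.
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float]
    label_to_index: dict[int, tuple[int, int, int]]
    counts: dict[int, int]
    weak_labels: frozenset[int] = frozenset()
    displaced_labels: frozenset[int] = frozenset()
    converged: bool = True
    iterations: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("label lattice must be 3D")

    @property
    def label_ids(self) -> list[int]:
        return sorted(self.label_to_index)

    def voxel_indices(self, label: int) -> np.ndarray:
        """Voxel index triples of a label, shape (n, 3)."""
        if label not in self.label_to_index:
            raise KeyError(f"unknown label {label}")
        return np.argwhere(self.labels == label)


def seed_from_grid(
    spec: PhantomSpec, volume: Volume, threshold: float = 0.5
) -> SeedMap:
    """Place one spherical seed per present sphere at the nominal centers.

    The seed radius is a quarter of the nominal sphere radius — small enough
    to sit inside even a strongly displaced or shrunken sphere.  Seeds whose
    entire extent lies below ``threshold`` intensity are retained but
    flagged weak (their sphere may have vanished into the signal void).
    """
    lo, hi = volume.world_bounds()
    radius = spec.nominal_ball_radius / 4.0
    seeds: list[Seed] = []
    sp = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    for label, (gidx, center) in enumerate(spec.iter_spheres(), start=1):
        if np.any(center < lo) or np.any(center > hi):
            raise ValueError(
                f"sphere {gidx} at {tuple(center)} mm lies outside the volume "
                f"extent {tuple(lo)}..{tuple(hi)} mm"
            )
        ic = np.rint((center - origin) / sp).astype(int)
        half = np.ceil(radius / sp).astype(int)
        sl = tuple(
            slice(max(0, ic[a] - half[a]), min(volume.shape[a], ic[a] + half[a] + 1))
            for a in range(3)
        )
        patch = volume.data[sl]
        coords = np.meshgrid(
            *(origin[a] + sp[a] * np.arange(sl[a].start, sl[a].stop) for a in range(3)),
            indexing="ij",
        )
        d2 = sum((coords[a] - center[a]) ** 2 for a in range(3))
        inside = d2 <= radius**2
        weak = bool(inside.any() and not (patch[inside] >= threshold).any())
        seeds.append(Seed(label=label, grid_index=gidx, center=tuple(center), weak=weak))
    return SeedMap(seeds=seeds, radius_mm=radius, spec=spec)


def _box_slices(ic: np.ndarray, halfwidth: np.ndarray) -> tuple[slice, slice, slice]:
    return tuple(slice(int(ic[a] - halfwidth[a]), int(ic[a] + halfwidth[a] + 1)) for a in range(3))


def evolve(
    volume: Volume, seed_map: SeedMap, params: RDParameters = RDParameters()
) -> BallLabelMap:
    """Run the competing-front reaction-diffusion evolution to completion.

    ``volume`` should be exposure-corrected so intensities are comparable
    with ``params.threshold``.  Returns the label map; non-convergence
    within ``max_iterations`` issues a warning and returns the partial
    result.
    """
    if not seed_map.seeds:
        return BallLabelMap(
            labels=np.zeros(volume.shape, dtype=np.int32),
            spacing=volume.spacing,
            origin=volume.origin,
            label_to_index={},
            counts={},
        )

    sp = np.asarray(volume.spacing)
    origin = np.asarray(volume.origin)
    w = np.ceil(params.box_halfwidth_mm / sp).astype(int)
    pad = tuple((int(w[a]), int(w[a])) for a in range(3))
    intensity = np.pad(
        volume.data.astype(np.float32), pad, constant_values=np.float32(0.0)
    )
    padded_origin = origin - w * sp

    seeds = sorted(seed_map.seeds, key=lambda s: s.label)
    n_lab = len(seeds)
    box_shape = tuple(int(2 * w[a] + 1) for a in range(3))

    slices = []
    u = np.zeros((n_lab,) + box_shape, dtype=np.float32)
    intensity_boxes = np.empty((n_lab,) + box_shape, dtype=np.float32)
    for li, seed in enumerate(seeds):
        center = np.asarray(seed.center)
        ic = np.rint((center - padded_origin) / sp).astype(int)
        sl = _box_slices(ic, w)
        slices.append(sl)
        intensity_boxes[li] = intensity[sl]
        axes = [
            padded_origin[a] + sp[a] * np.arange(sl[a].start, sl[a].stop) - center[a]
            for a in range(3)
        ]
        d2 = (
            axes[0][:, None, None] ** 2
            + axes[1][None, :, None] ** 2
            + axes[2][None, None, :] ** 2
        )
        u[li][d2 <= seed_map.radius_mm**2] = 1.0

    theta = np.float32(params.threshold)
    # Static per-voxel reactive drive.  The driving intensity is clamped to
    # [0, 1]: the front evolution only needs the sign and a bounded magnitude
    # of I - theta, and uncorrected over-unity intensities would push the
    # explicit reaction step beyond its relaxation limit (sustained
    # oscillation instead of convergence).
    drive = params.reaction * (np.clip(intensity_boxes, 0.0, 1.0) - theta)
    dt = np.float32(params.step)
    diff = np.float32(params.diffusion)

    # Preallocated buffers: the update runs a few hundred times over ~40 MB
    # of state, so avoiding per-step allocations matters.
    coupling = np.zeros_like(intensity)
    u_boxes = np.empty_like(u)
    u_pad = np.zeros((n_lab,) + tuple(b + 2 for b in box_shape), dtype=np.float32)
    lap = np.empty_like(u)
    scratch = np.empty_like(u)
    inner = (slice(None), slice(1, -1), slice(1, -1), slice(1, -1))
    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        coupling[:] = 0.0
        for li in range(n_lab):
            coupling[slices[li]] += u[li]
        for li in range(n_lab):
            u_boxes[li] = coupling[slices[li]]

        u_pad[inner] = u
        np.copyto(lap, u_pad[:, 2:, 1:-1, 1:-1])
        lap += u_pad[:, :-2, 1:-1, 1:-1]
        lap += u_pad[:, 1:-1, 2:, 1:-1]
        lap += u_pad[:, 1:-1, :-2, 1:-1]
        lap += u_pad[:, 1:-1, 1:-1, 2:]
        lap += u_pad[:, 1:-1, 1:-1, :-2]
        np.multiply(u, np.float32(6.0), out=scratch)
        lap -= scratch
        lap *= diff
        # reaction: u * (1 - U) * drive, accumulated into the increment
        np.subtract(np.float32(1.0), u_boxes, out=scratch)
        scratch *= drive
        scratch *= u
        lap += scratch
        lap *= dt
        # keep the pre-update state in `scratch` to measure the true change
        np.copyto(scratch, u)
        u += lap
        np.clip(u, 0.0, 1.0, out=u)
        np.subtract(u, scratch, out=scratch)
        np.abs(scratch, out=scratch)
        delta = float(scratch.max())
        if delta < params.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"reaction-diffusion evolution did not converge within "
            f"{params.max_iterations} iterations (last change {delta:.2e}); "
            "returning the partial result",
            RuntimeWarning,
            stacklevel=2,
        )

    # Final labeling: a voxel is claimed when the *total* concentration U
    # exceeds 1/2 (for one label this is the plain u > 1/2 rule; with
    # competing fronts it keeps marginal boundary voxels whose capacity the
    # fronts share); ownership goes to the argmax label, with strict '>'
    # during the ascending-label sweep breaking ties to the lowest label
    # deterministically.
    coupling[:] = 0.0
    for li in range(n_lab):
        coupling[slices[li]] += u[li]
    best = np.zeros_like(intensity)
    lab = np.zeros(intensity.shape, dtype=np.int32)
    for li, seed in enumerate(seeds):
        view = best[slices[li]]
        mask = u[li] > view
        view[mask] = u[li][mask]
        lab[slices[li]][mask] = seed.label
    lab[coupling <= 0.5] = 0
    crop = tuple(slice(int(w[a]), int(w[a]) + volume.shape[a]) for a in range(3))
    labels = lab[crop]

    # Keep only the 6-connected component containing each seed.
    structure = ndimage.generate_binary_structure(3, 1)
    label_to_index: dict[int, tuple[int, int, int]] = {}
    counts: dict[int, int] = {}
    displaced: set[int] = set()
    for li, seed in enumerate(seeds):
        label_to_index[seed.label] = seed.grid_index
        sl = tuple(
            slice(max(0, s.start - int(w[a])), min(volume.shape[a], s.stop - int(w[a])))
            for a, s in enumerate(slices[li])
        )
        sub = labels[sl]
        mask = sub == seed.label
        n_vox = int(mask.sum())
        if n_vox == 0:
            counts[seed.label] = 0
            continue
        comp, _ = ndimage.label(mask, structure=structure)
        seed_vox = np.rint((np.asarray(seed.center) - origin) / sp).astype(int)
        local = seed_vox - np.array([s.start for s in sl])
        keep = 0
        if np.all(local >= 0) and np.all(local < np.asarray(sub.shape)):
            keep = int(comp[tuple(local)])
        if keep == 0:
            sizes = np.bincount(comp.ravel())
            sizes[0] = 0
            keep = int(np.argmax(sizes))
            displaced.add(seed.label)
        drop = mask & (comp != keep)
        if drop.any():
            sub[drop] = 0
        counts[seed.label] = int((sub == seed.label).sum())

    weak = frozenset(s.label for s in seeds if s.weak)
    return BallLabelMap(
        labels=labels,
        spacing=volume.spacing,
        origin=volume.origin,
        label_to_index=label_to_index,
        counts=counts,
        weak_labels=weak,
        displaced_labels=frozenset(displaced),
        converged=converged,
        iterations=iterations,
    )


def extract_surface(label_map: BallLabelMap, label: int) -> np.ndarray:
    """Surface voxels of a label: those with a differently-labeled 6-neighbour.

    The discrete morphological gradient of the label mask; lattice-boundary
    voxels count as surface.  Returns index triples, shape (n, 3).
    """
    if label not in label_map.label_to_index:
        raise KeyError(f"unknown label {label}")
    mask = label_map.labels == label
    if not mask.any():
        raise EmptyLabelError(f"label {label} has no voxels")
    structure = ndimage.generate_binary_structure(3, 1)
    interior = ndimage.binary_erosion(mask, structure=structure, border_value=0)
    return np.argwhere(mask & ~interior)
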