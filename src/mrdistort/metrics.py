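"""Per-ball descriptors and comparative distortion metrics.

Non-comparative metrics describe one segmented sphere: the gravity center
(unweighted voxel centroid), the volume V (voxel count times voxel volume),
the mean gray value GV, and the out-of-round measure

    ORM = RM / Rm - 1,

where RM and Rm are the means of the upper and lower 5th percentile of the
center-to-surface radii; the percentile trimming suppresses outliers from
rough segmented surfaces.  ORM = 0 for a perfect sphere, and ORM = 1 means
the longest dimension is twice the shortest.

Comparative metrics relate a sphere in an implant ("distorted") scan to its
homologous sphere, i.e. the same grid index, in the implant-free reference
scan:

    dCL  = |center_d - center_r|            (mm)
    dV   = (V_d - V_r) / V_r
    dORM = ORM_d - ORM_r
    dGV  = (GV_d - GV_r) / GV_r
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .phantom import Volume
from .segmentation import BallLabelMap, EmptyLabelError, extract_surface

__all__ = [
    "BallDescriptor",
    "ComparativeRecord",
    "METRIC_NAMES",
    "out_of_round",
    "describe_ball",
    "describe_scan",
    "match_homologous",
    "compare",
    "compare_scans",
    "summarize",
    "descriptors_to_frame",
    "records_to_frame",
]

#: Canonical names of the comparative metrics.
METRIC_NAMES = ("dCL", "dV", "dORM", "dGV")


@dataclass(frozen=True)
class BallDescriptor:
    """Shape, position and intensity of one segmented sphere."""

    grid_index: tuple[int, int, int]
    center: tuple[float, float, float]
    volume_mm3: float
    mean_gray: float
    r_upper: float  # RM: mean of the upper 5th-percentile radii, mm
    r_lower: float  # Rm: mean of the lower 5th-percentile radii, mm
    out_of_round: float
    n_voxels: int
    disappeared: bool


@dataclass(frozen=True)
class ComparativeRecord:
    """Homologous-pair deltas between an implant scan and the reference."""

    grid_index: tuple[int, int, int]
    dCL: float
    dV: float
    dORM: float
    dGV: float
    disappeared: bool
    ref_center: tuple[float, float, float]

    def value(self, metric: str) -> float:
        if metric not in METRIC_NAMES:
            raise KeyError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
        return getattr(self, metric)


def out_of_round(radii) -> float:
    """ORM of a sample of center-to-surface radii.

    RM (Rm) is the mean of the radii at or above (at or below) the 95th
    (5th) linear-interpolation percentile.
    """
    r = np.asarray(radii, dtype=float).ravel()
    if r.size == 0:
        raise ValueError("radius sample is empty")
    if np.any(r <= 0) or not np.all(np.isfinite(r)):
        raise ValueError("radii must be positive and finite")
    p5, p95 = np.percentile(r, [5.0, 95.0])
    r_upper = float(r[r >= p95].mean())
    r_lower = float(r[r <= p5].mean())
    return r_upper / r_lower - 1.0


def describe_ball(
    volume: Volume, label_map: BallLabelMap, label: int, min_voxels: int = 8
) -> BallDescriptor:
    """Descriptor of one labeled sphere.

    Balls with fewer than ``min_voxels`` voxels are still measured but
    flagged *disappeared* (strongly suppressed by the implant's signal
    void); a ball with no voxels at all gets NaN shape fields.
    """
    grid_index = label_map.label_to_index[label]
    idx = label_map.voxel_indices(label)
    if idx.shape[0] == 0:
        return BallDescriptor(
            grid_index=grid_index,
            center=(math.nan,) * 3,
            volume_mm3=0.0,
            mean_gray=math.nan,
            r_upper=math.nan,
            r_lower=math.nan,
            out_of_round=math.nan,
            n_voxels=0,
            disappeared=True,
        )
    sp = np.asarray(label_map.spacing)
    origin = np.asarray(label_map.origin)
    center = origin + idx.mean(axis=0) * sp
    voxel_volume = float(np.prod(sp))
    values = volume.data[tuple(idx.T)]
    surface = extract_surface(label_map, label)
    radii = np.linalg.norm((surface * sp + origin) - center, axis=1)
    radii = radii[radii > 0] if np.any(radii > 0) else radii
    if radii.size == 0 or np.all(radii == 0):
        # single-voxel ball: its own surface, zero radius
        r_upper = r_lower = orm = 0.0
    else:
        p5, p95 = np.percentile(radii, [5.0, 95.0])
        r_upper = float(radii[radii >= p95].mean())
        r_lower = float(radii[radii <= p5].mean())
        orm = r_upper / r_lower - 1.0
    return BallDescriptor(
        grid_index=grid_index,
        center=tuple(center),
        volume_mm3=idx.shape[0] * voxel_volume,
        mean_gray=float(values.mean()),
        r_upper=r_upper,
        r_lower=r_lower,
        out_of_round=orm,
        n_voxels=int(idx.shape[0]),
        disappeared=idx.shape[0] < min_voxels,
    )


def describe_scan(
    volume: Volume, label_map: BallLabelMap, min_voxels: int = 8
) -> dict[tuple[int, int, int], BallDescriptor]:
    """Descriptors for every label, keyed by grid index."""
    out = {}
    for label in label_map.label_ids:
        desc = describe_ball(volume, label_map, label, min_voxels=min_voxels)
        out[desc.grid_index] = desc
    return out


def match_homologous(
    ref: dict[tuple[int, int, int], BallDescriptor],
    dist: dict[tuple[int, int, int], BallDescriptor],
) -> list[tuple[tuple[int, int, int], BallDescriptor, BallDescriptor | None]]:
    """Pair reference and distorted descriptors by grid index.

    Indices missing or disappeared on the distorted side are paired with
    ``None`` / the disappeared descriptor; distorted indices absent from the
    reference indicate mismatched phantom specs and raise.
    """
    extra = set(dist) - set(ref)
    if extra:
        raise ValueError(
            f"distorted scan contains grid indices absent from the reference "
            f"(mismatched phantom specs?): {sorted(extra)[:5]}"
        )
    return [(gidx, ref[gidx], dist.get(gidx)) for gidx in sorted(ref)]


def compare(
    ref_desc: BallDescriptor, dist_desc: BallDescriptor | None
) -> ComparativeRecord:
    """Comparative record for one homologous pair.

    The reference ball must be intact (reference scans are implant-free);
    a disappeared distorted ball yields dV = -1 with the remaining deltas
    undefined (NaN) and the record flagged.
    """
    if ref_desc.disappeared:
        raise ValueError(
            f"reference ball {ref_desc.grid_index} is disappeared; reference "
            "scans must be implant-free and fully segmentable"
        )
    if dist_desc is None or dist_desc.disappeared:
        return ComparativeRecord(
            grid_index=ref_desc.grid_index,
            dCL=math.nan,
            dV=-1.0,
            dORM=math.nan,
            dGV=math.nan,
            disappeared=True,
            ref_center=ref_desc.center,
        )
    dcl = float(
        np.linalg.norm(np.asarray(dist_desc.center) - np.asarray(ref_desc.center))
    )
    return ComparativeRecord(
        grid_index=ref_desc.grid_index,
        dCL=dcl,
        dV=(dist_desc.volume_mm3 - ref_desc.volume_mm3) / ref_desc.volume_mm3,
        dORM=dist_desc.out_of_round - ref_desc.out_of_round,
        dGV=(dist_desc.mean_gray - ref_desc.mean_gray) / ref_desc.mean_gray,
        disappeared=False,
        ref_center=ref_desc.center,
    )


def compare_scans(
    ref: dict[tuple[int, int, int], BallDescriptor],
    dist: dict[tuple[int, int, int], BallDescriptor],
) -> list[ComparativeRecord]:
    return [compare(r, d) for _, r, d in match_homologous(ref, dist)]


def summarize(
    dist_descs: dict[tuple[int, int, int], BallDescriptor],
    records: list[ComparativeRecord],
) -> dict[str, float]:
    """Scan-level extrema: the quantities tracked per implant and sequence."""
    volumes = [d.volume_mm3 for d in dist_descs.values()]
    orms = [d.out_of_round for d in dist_descs.values() if not d.disappeared]
    intact = [r for r in records if not r.disappeared]
    summary = {
        "V_min_mm3": float(np.min(volumes)) if volumes else math.nan,
        "V_max_mm3": float(np.max(volumes)) if volumes else math.nan,
        "ORM_min": float(np.min(orms)) if orms else math.nan,
        "ORM_max": float(np.max(orms)) if orms else math.nan,
        "dCL_max_mm": float(np.max([r.dCL for r in intact])) if intact else math.nan,
        "dV_max": float(np.max([abs(r.dV) for r in records])) if records else math.nan,
        "dORM_max": float(np.max([abs(r.dORM) for r in intact])) if intact else math.nan,
        "dGV_max": float(np.max([abs(r.dGV) for r in intact])) if intact else math.nan,
        "n_disappeared": float(sum(r.disappeared for r in records)),
    }
    return summary


def descriptors_to_frame(descs: dict[tuple[int, int, int], BallDescriptor]) -> pd.DataFrame:
    rows = []
    for gidx in sorted(descs):
        d = descs[gidx]
        rows.append(
            {
                "i": gidx[0],
                "j": gidx[1],
                "k": gidx[2],
                "cx_mm": d.center[0],
                "cy_mm": d.center[1],
                "cz_mm": d.center[2],
                "V_mm3": d.volume_mm3,
                "GV": d.mean_gray,
                "RM_mm": d.r_upper,
                "Rm_mm": d.r_lower,
                "ORM": d.out_of_round,
                "n_voxels": d.n_voxels,
                "disappeared": d.disappeared,
            }
        )
    return pd.DataFrame(rows)


def frame_to_descriptors(frame: pd.DataFrame) -> dict[tuple[int, int, int], BallDescriptor]:
    descs = {}
    for _, row in frame.iterrows():
        gidx = (int(row["i"]), int(row["j"]), int(row["k"]))
        descs[gidx] = BallDescriptor(
            grid_index=gidx,
            center=(float(row["cx_mm"]), float(row["cy_mm"]), float(row["cz_mm"])),
            volume_mm3=float(row["V_mm3"]),
            mean_gray=float(row["GV"]),
            r_upper=float(row["RM_mm"]),
            r_lower=float(row["Rm_mm"]),
            out_of_round=float(row["ORM"]),
            n_voxels=int(row["n_voxels"]),
            disappeared=bool(row["disappeared"]),
        )
    return descs


def records_to_frame(records: list[ComparativeRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append(
            {
                "i": r.grid_index[0],
                "j": r.grid_index[1],
                "k": r.grid_index[2],
                "dCL_mm": r.dCL,
                "dV": r.dV,
                "dORM": r.dORM,
                "dGV": r.dGV,
                "disappeared": r.disappeared,
                "ref_cx_mm": r.ref_center[0],
                "ref_cy_mm": r.ref_center[1],
                "ref_cz_mm": r.ref_center[2],
            }
        )
    return pd.DataFrame(rows)
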