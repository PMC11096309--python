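"""Uncertainty calibration and critical-radius analysis.

Repeat scans of the implant-free phantom calibrate the reproducibility of
every comparative metric: the first scan serves as reference, each repeat is
compared against it, and the per-metric uncertainty is the worst-case
(maximum absolute) deviation over all balls and repeats.  Thresholds for the
critical-radius analysis are set to twice the uncertainties, guaranteeing
that flagged distortions stand clear of scan-to-scan noise.

The critical radius Rcr of a metric is the radius of the region around the
implant (at the isocenter) inside which the metric exceeds its threshold:
the largest distance from the isocenter to the center of an affected
reference ball, plus the nominal ball radius (20 mm) as a conservative outer
envelope.  Rcr = 0 when no ball is affected.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import (
    METRIC_NAMES,
    BallDescriptor,
    ComparativeRecord,
    compare_scans,
    descriptors_to_frame,
    records_to_frame,
    summarize,
)
from .phantom import equivalent_diameter

__all__ = [
    "UncertaintyModel",
    "CriticalRadiusResult",
    "assess_uncertainty",
    "critical_radius",
    "report",
]

NOMINAL_BALL_RADIUS_MM = 20.0


@dataclass(frozen=True)
class UncertaintyModel:
    """Repeat-scan reproducibility of the comparative metrics.

    ``placement_uncertainty`` (mm) is the worst-case dCL between homologous
    balls of implant-free repeats; ``metric_uncertainties`` likewise for the
    dimensionless metrics.  Thresholds are *structurally* twice the
    uncertainties (never stored separately), so the 2x rule can not drift.
    """

    placement_uncertainty: float
    metric_uncertainties: dict[str, float]
    n_repeats: int
    volume_range_mm3: tuple[float, float]
    diameter_range_mm: tuple[float, float]

    def __post_init__(self) -> None:
        if self.n_repeats < 2:
            raise ValueError("uncertainty assessment needs at least two scans in total")
        if self.placement_uncertainty < 0 or any(
            v < 0 for v in self.metric_uncertainties.values()
        ):
            raise ValueError("uncertainties must be >= 0")
        missing = {"dV", "dORM", "dGV"} - set(self.metric_uncertainties)
        if missing:
            raise ValueError(f"metric_uncertainties missing {sorted(missing)}")

    @property
    def thresholds(self) -> dict[str, float]:
        """Per-metric thresholds: exactly twice the uncertainty levels."""
        out = {"dCL": 2.0 * self.placement_uncertainty}
        for name, unc in self.metric_uncertainties.items():
            out[name] = 2.0 * unc
        return out


@dataclass(frozen=True)
class CriticalRadiusResult:
    metric: str
    threshold: float
    radius_mm: float
    affected: tuple[tuple[int, int, int], ...]


def assess_uncertainty(
    reference: dict[tuple[int, int, int], BallDescriptor],
    repeats: list[dict[tuple[int, int, int], BallDescriptor]],
) -> UncertaintyModel:
    """Calibrate uncertainties from implant-free repeat scans.

    Aggregation is the maximum absolute deviation over all balls and all
    repeat-vs-reference comparisons (worst case, not standard deviation).
    Also reports the reconstructed-volume range over all scans and its
    equivalent-diameter range, the spatial-uncertainty surrogate.
    """
    if not repeats:
        raise ValueError("at least one repeat scan is required")
    placement = 0.0
    metric_unc = {"dV": 0.0, "dORM": 0.0, "dGV": 0.0}
    volumes = [d.volume_mm3 for d in reference.values()]
    for repeat in repeats:
        records = compare_scans(reference, repeat)
        if any(r.disappeared for r in records):
            bad = [r.grid_index for r in records if r.disappeared]
            raise ValueError(
                f"repeat scan has disappeared balls {bad[:5]}; repeats must be "
                "implant-free"
            )
        placement = max(placement, max(abs(r.dCL) for r in records))
        for name in metric_unc:
            metric_unc[name] = max(
                metric_unc[name], max(abs(r.value(name)) for r in records)
            )
        volumes.extend(d.volume_mm3 for d in repeat.values())
    v_min, v_max = float(np.min(volumes)), float(np.max(volumes))
    return UncertaintyModel(
        placement_uncertainty=placement,
        metric_uncertainties=metric_unc,
        n_repeats=len(repeats) + 1,
        volume_range_mm3=(v_min, v_max),
        diameter_range_mm=(equivalent_diameter(v_min), equivalent_diameter(v_max)),
    )


def critical_radius(
    records: list[ComparativeRecord],
    metric: str,
    threshold: float,
    nominal_radius: float = NOMINAL_BALL_RADIUS_MM,
    isocenter=(0.0, 0.0, 0.0),
) -> CriticalRadiusResult:
    """Critical radius of one metric at a given threshold.

    A ball is affected when |metric| exceeds the threshold; disappeared
    balls always count as affected for dV (their volume loss is total, and
    the other metrics are undefined for them).  Distances are measured from
    the isocenter to the *reference* ball centers.
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}; expected one of {METRIC_NAMES}")
    if threshold < 0:
        raise ValueError(f"threshold must be >= 0, got {threshold}")
    iso = np.asarray(isocenter, dtype=float)
    affected = []
    dists = []
    for r in records:
        value = r.value(metric)
        hit = (not math.isnan(value)) and abs(value) > threshold
        if r.disappeared and metric == "dV":
            hit = True
        if hit:
            affected.append(r.grid_index)
            dists.append(float(np.linalg.norm(np.asarray(r.ref_center) - iso)))
    radius = max(dists) + nominal_radius if dists else 0.0
    return CriticalRadiusResult(
        metric=metric,
        threshold=float(threshold),
        radius_mm=float(radius),
        affected=tuple(affected),
    )


def report(
    ref_descs: dict[tuple[int, int, int], BallDescriptor],
    dist_descs: dict[tuple[int, int, int], BallDescriptor],
    uncertainty: UncertaintyModel,
    out_dir=None,
    nominal_radius: float = NOMINAL_BALL_RADIUS_MM,
    isocenter=(0.0, 0.0, 0.0),
) -> dict:
    """Full comparative report for one reference/implant scan pair.

    Returns (and optionally writes) the per-ball comparative table, the
    scan-level summary extrema, the critical radius per metric, and a 3D
    displacement plot of reference vs distorted centers inside the dCL
    critical radius.
    """
    records = compare_scans(ref_descs, dist_descs)
    summary = summarize(dist_descs, records)
    rcr = {
        name: critical_radius(
            records, name, uncertainty.thresholds[name], nominal_radius, isocenter
        )
        for name in METRIC_NAMES
    }
    for name, res in rcr.items():
        summary[f"Rcr_{name}_mm"] = res.radius_mm
    bundle = {
        "records": records,
        "summary": summary,
        "critical_radii": rcr,
        "per_ball": records_to_frame(records),
        "distorted_balls": descriptors_to_frame(dist_descs),
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        bundle["per_ball"].to_csv(out_dir / "per_ball.csv", index=False)
        pd.DataFrame([summary]).to_csv(out_dir / "summary.csv", index=False)
        rcr_payload = {
            name: {
                "threshold": res.threshold,
                "radius_mm": res.radius_mm,
                "affected": [list(g) for g in res.affected],
            }
            for name, res in rcr.items()
        }
        (out_dir / "rcr.json").write_text(json.dumps(rcr_payload, indent=2))
        _displacement_plot(records, dist_descs, rcr["dCL"], out_dir / "displacement.png")
    return bundle


def _displacement_plot(
    records: list[ComparativeRecord],
    dist_descs: dict[tuple[int, int, int], BallDescriptor],
    rcr_dcl: CriticalRadiusResult,
    path: Path,
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(7, 6))
    ax = fig.add_subplot(projection="3d")
    shown = set(rcr_dcl.affected)
    for r in records:
        if r.grid_index not in shown or r.disappeared:
            continue
        rc = np.asarray(r.ref_center)
        dc = np.asarray(dist_descs[r.grid_index].center)
        ax.scatter(*rc, color="lightblue", s=18)
        ax.scatter(*dc, color="magenta", s=18)
        ax.plot(*np.stack([rc, dc]).T, color="black", linewidth=0.8)
    ax.set_xlabel("x (mm)")
    ax.set_ylabel("y (mm)")
    ax.set_zlabel("z (mm)")
    ax.set_title(
        f"Ball displacements inside Rcr(dCL) = {rcr_dcl.radius_mm:.0f} mm"
    )
    fig.savefig(path, dpi=110)
    plt.close(fig)
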