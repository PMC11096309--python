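"""Uncertainty calibration and critical-radius rules."""

import math

import numpy as np
import pytest

import mrdistort as md
from conftest import segment_scan


def make_record(gidx, ref_center, **metrics):
    values = {"dCL": 0.0, "dV": 0.0, "dORM": 0.0, "dGV": 0.0}
    values.update(metrics)
    return md.ComparativeRecord(
        grid_index=gidx,
        dCL=values["dCL"],
        dV=values["dV"],
        dORM=values["dORM"],
        dGV=values["dGV"],
        disappeared=values.get("disappeared", False),
        ref_center=ref_center,
    )


class TestUncertaintyModel:
    def test_thresholds_are_exactly_twice_uncertainties(self):
        model = md.UncertaintyModel(
            placement_uncertainty=3.5,
            metric_uncertainties={"dV": 0.12, "dORM": 0.09, "dGV": 0.02},
            n_repeats=4,
            volume_range_mm3=(25.3e3, 35.3e3),
            diameter_range_mm=(36.4, 40.7),
        )
        assert model.thresholds == {
            "dCL": 7.0,
            "dV": 0.24,
            "dORM": 0.18,
            "dGV": 0.04,
        }

    def test_negative_uncertainty_rejected(self):
        with pytest.raises(ValueError):
            md.UncertaintyModel(
                placement_uncertainty=-1.0,
                metric_uncertainties={"dV": 0.0, "dORM": 0.0, "dGV": 0.0},
                n_repeats=2,
                volume_range_mm3=(0, 0),
                diameter_range_mm=(0, 0),
            )

    def test_identical_repeats_give_zero_uncertainty(self, small_descriptors):
        model = md.assess_uncertainty(small_descriptors, [small_descriptors] * 3)
        assert model.placement_uncertainty == 0.0
        assert all(v == 0.0 for v in model.metric_uncertainties.values())
        assert all(v == 0.0 for v in model.thresholds.values())
        assert model.n_repeats == 4

    def test_volume_and_diameter_range_reported(self, small_descriptors):
        model = md.assess_uncertainty(small_descriptors, [small_descriptors])
        v_min, v_max = model.volume_range_mm3
        assert v_min == min(d.volume_mm3 for d in small_descriptors.values())
        assert model.diameter_range_mm[0] == pytest.approx(
            md.equivalent_diameter(v_min)
        )
        assert model.diameter_range_mm[1] == pytest.approx(
            md.equivalent_diameter(v_max)
        )

    def test_repeat_with_disappeared_ball_rejected(self, small_descriptors):
        from dataclasses import replace

        broken = dict(small_descriptors)
        gidx = next(iter(broken))
        broken[gidx] = replace(broken[gidx], disappeared=True, n_voxels=2)
        with pytest.raises(ValueError, match="implant-free"):
            md.assess_uncertainty(small_descriptors, [broken])

    def test_uncertainty_grows_with_noise(self):
        # common random numbers: the same seeds across noise levels, so each
        # repeat's perturbation scales coherently with sigma; 27 balls give
        # the worst-case statistic enough granularity to move at every level
        spec = md.PhantomSpec(grid_shape=(3, 3, 3), omitted_indices=frozenset())
        volume = md.rasterize(spec, 2.0, supersampling=4)
        reference = segment_scan(volume, spec)
        sigmas = [0.005, 0.01, 0.02]
        uncertainties = []
        for sigma in sigmas:
            repeats = [
                segment_scan(md.add_noise(volume, sigma, seed=100 + i), spec)
                for i in range(2)
            ]
            model = md.assess_uncertainty(reference, repeats)
            uncertainties.append(
                (
                    model.placement_uncertainty,
                    model.metric_uncertainties["dV"],
                    model.metric_uncertainties["dGV"],
                )
            )
        for low, high in zip(uncertainties, uncertainties[1:]):
            # dCL and dV are quantized by the voxel lattice and may tie
            # between adjacent noise levels; dGV is continuous in the noise
            assert low[0] <= high[0]  # placement (dCL)
            assert low[1] <= high[1]  # dV
            assert low[2] < high[2]  # dGV
        assert uncertainties[0][0] < uncertainties[-1][0]
        assert uncertainties[0][1] < uncertainties[-1][1]


class TestCriticalRadius:
    def test_no_affected_balls_gives_zero(self):
        records = [make_record((0, 0, 0), (100.0, 0, 0))]
        res = md.critical_radius(records, "dCL", threshold=7.0)
        assert res.radius_mm == 0.0
        assert res.affected == ()

    def test_single_affected_ball_arithmetic(self):
        records = [make_record((1, 2, 3), (60.0, 80.0, 0.0), dCL=10.0)]
        res = md.critical_radius(records, "dCL", threshold=7.0, nominal_radius=20.0)
        assert res.radius_mm == pytest.approx(120.0)
        assert res.affected == ((1, 2, 3),)

    def test_monotone_nonincreasing_in_threshold(self):
        rng = np.random.default_rng(5)
        records = [
            make_record(
                (i, 0, 0),
                tuple(rng.uniform(-120, 120, 3)),
                dV=float(rng.uniform(-0.5, 0.5)),
            )
            for i in range(30)
        ]
        radii = [
            md.critical_radius(records, "dV", t).radius_mm
            for t in np.linspace(0.0, 0.6, 13)
        ]
        assert all(a >= b for a, b in zip(radii, radii[1:]))
        # doubling any threshold never increases the radius
        for t in (0.01, 0.1, 0.3):
            assert (
                md.critical_radius(records, "dV", 2 * t).radius_mm
                <= md.critical_radius(records, "dV", t).radius_mm
            )

    def test_disappeared_ball_always_affected_for_dv(self):
        records = [
            make_record(
                (0, 0, 0), (40.0, 0, 0), dV=-1.0, dCL=math.nan, disappeared=True
            )
        ]
        res_dv = md.critical_radius(records, "dV", threshold=10.0)
        assert res_dv.affected == ((0, 0, 0),)
        assert res_dv.radius_mm == pytest.approx(60.0)
        res_dcl = md.critical_radius(records, "dCL", threshold=10.0)
        assert res_dcl.affected == ()

    def test_unknown_metric_rejected(self):
        with pytest.raises(KeyError):
            md.critical_radius([], "dX", 1.0)

    def test_bounded_by_phantom_half_diagonal(self):
        spec = md.default_spec()
        half_diag = float(np.linalg.norm(spec.centers(), axis=1).max())
        records = [
            make_record(gidx, tuple(spec.center(gidx)), dV=1.0)
            for gidx in spec.present_indices()
        ]
        res = md.critical_radius(records, "dV", threshold=0.0)
        assert res.radius_mm <= half_diag + 20.0 + 1e-9


class TestReport:
    def test_identity_report_all_zero(self, small_descriptors, tmp_path):
        unc = md.assess_uncertainty(small_descriptors, [small_descriptors])
        bundle = md.report(
            small_descriptors, small_descriptors, unc, out_dir=tmp_path
        )
        summary = bundle["summary"]
        assert summary["dCL_max_mm"] == 0.0
        assert summary["dV_max"] == 0.0
        assert summary["n_disappeared"] == 0
        for name in md.METRIC_NAMES:
            assert summary[f"Rcr_{name}_mm"] == 0.0
        assert (tmp_path / "displacement.png").exists()
        assert (tmp_path / "rcr.json").exists()

    def test_summary_csv_roundtrips(self, small_descriptors, tmp_path):
        import pandas as pd

        unc = md.assess_uncertainty(small_descriptors, [small_descriptors])
        bundle = md.report(small_descriptors, small_descriptors, unc, out_dir=tmp_path)
        back = pd.read_csv(tmp_path / "summary.csv")
        for key, value in bundle["summary"].items():
            assert back[key].iloc[0] == pytest.approx(value)
        per_ball = pd.read_csv(tmp_path / "per_ball.csv")
        assert len(per_ball) == len(small_descriptors)
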