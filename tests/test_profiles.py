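"""Cross-section measurement geometry and cell morphometrics."""

import numpy as np
import pytest

from groovebend import (
    BeamParameters,
    CrossSectionProfile,
    GeometryError,
    GrooveMeasurement,
    MeasurementConfig,
    NotSpanningError,
    elongation_parameter,
    equimomental_ellipse,
    generate_profile,
    is_aligned,
    measure_groove,
    read_records_csv,
    segment_by_bending_angle,
    write_records_csv,
)

BEAM = BeamParameters(load_ratio=1.2e17)


def _trapezoid_profile(depth=0.1, h=0.35, L=1.0):
    """Hand-built groove with a sinusoidal membrane dip of known geometry."""
    memb = [(-1.0, h), (-0.5, h), (0.0, h)]
    xs = np.linspace(0.001, 0.999, 200)
    memb += [(x, h - depth * np.sin(np.pi * x / L)) for x in xs]
    memb += [(L, h), (1.5, h), (2.0, h)]
    sub = [(-1.0, h), (0.0, h), (0.05, 0.0), (0.95, 0.0), (L, h), (2.0, h)]
    return np.asarray(memb), np.asarray(sub)


class TestMeasureGroove:
    def test_flat_membrane_on_flat_ridges(self):
        prof = generate_profile(1e-6, 0.0, BeamParameters(q=0.0, EI=1e-20))
        m = measure_groove(prof)
        assert m.L == pytest.approx(1e-6, rel=1e-12)
        assert m.d == 0.0
        assert m.theta_M == pytest.approx(0.0, abs=1e-9)
        assert m.theta_S == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize(
        "theta_M,theta_S,L",
        [(5.0, 44.0, 4e-7), (15.0, 10.0, 5e-7), (30.0, 20.0, 1e-6),
         (25.0, 70.0, 1e-6), (10.0, 0.0, 1.8e-6)],
    )
    def test_round_trip_recovers_generator_truth(self, theta_M, theta_S, L):
        prof = generate_profile(
            L, theta_M, BEAM, theta_S_deg=theta_S, n_points=1000
        )
        assert not prof.metadata["clipped"]
        m = measure_groove(prof)
        truth = prof.metadata
        assert m.L == pytest.approx(truth["true_L_m"], rel=1e-9)
        assert m.d == pytest.approx(truth["true_d_m"], rel=0.01)
        assert m.theta_M == pytest.approx(truth["true_theta_M_deg"], rel=0.01)
        assert m.theta_S == pytest.approx(truth["true_theta_S_deg"], rel=0.01)

    def test_discretization_error_shrinks_with_point_density(self):
        errs = []
        for n in (200, 1600):
            prof = generate_profile(1e-6, 20.0, BEAM, theta_S_deg=0.0,
                                    n_points=n)
            m = measure_groove(prof)
            errs.append(abs(m.theta_M - 20.0))
        assert errs[1] < errs[0]

    def test_mirror_symmetric_profile_has_equal_endpoint_angles(self):
        prof = generate_profile(1e-6, 25.0, BEAM, theta_S_deg=10.0)
        m = measure_groove(prof)
        det = m.endpoint_detail
        assert det["theta_M_A_deg"] == pytest.approx(
            det["theta_M_B_deg"], abs=1e-6
        )
        assert det["theta_S_A_deg"] == pytest.approx(
            det["theta_S_B_deg"], abs=1e-6
        )

    def test_scale_equivariance(self):
        memb, sub = _trapezoid_profile()
        m1 = measure_groove(CrossSectionProfile(membrane=memb, substrate=sub))
        m2 = measure_groove(
            CrossSectionProfile(membrane=memb * 3.0, substrate=sub * 3.0)
        )
        assert m2.L == pytest.approx(3.0 * m1.L, rel=1e-12)
        assert m2.d == pytest.approx(3.0 * m1.d, rel=1e-12)
        assert m2.theta_M == pytest.approx(m1.theta_M, abs=1e-9)
        assert m2.theta_S == pytest.approx(m1.theta_S, abs=1e-9)

    def test_rigid_motion_invariance(self):
        memb, sub = _trapezoid_profile()
        m1 = measure_groove(CrossSectionProfile(membrane=memb, substrate=sub))
        th = np.radians(3.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        shift = np.array([5.0, -2.0])
        m2 = measure_groove(
            CrossSectionProfile(
                membrane=memb @ R.T + shift, substrate=sub @ R.T + shift
            )
        )
        assert m2.L == pytest.approx(m1.L, rel=1e-9)
        assert m2.d == pytest.approx(m1.d, rel=1e-9)
        assert m2.theta_M == pytest.approx(m1.theta_M, abs=1e-6)
        assert m2.theta_S == pytest.approx(m1.theta_S, abs=1e-6)

    def test_membrane_not_spanning_raises(self):
        # membrane trace stops in the middle of the groove
        h = 0.35
        memb = [(-1.0, h), (-0.5, h), (0.0, h)]
        memb += [(x, h - 0.05) for x in np.linspace(0.01, 0.4, 50)]
        sub = [(-1.0, h), (0.0, h), (0.05, 0.0), (0.95, 0.0), (1.0, h), (2.0, h)]
        prof = CrossSectionProfile(
            membrane=np.asarray(memb), substrate=np.asarray(sub)
        )
        with pytest.raises(NotSpanningError):
            measure_groove(prof)

    def test_flat_substrate_raises_geometry_error(self):
        x = np.linspace(0.0, 2.0, 50)
        prof = CrossSectionProfile(
            membrane=np.column_stack([x, np.full_like(x, 0.35)]),
            substrate=np.column_stack([x, np.full_like(x, 0.35)]),
        )
        with pytest.raises(GeometryError):
            measure_groove(prof)

    def test_profile_json_round_trip(self, tmp_path):
        prof = generate_profile(1e-6, 15.0, BEAM, theta_S_deg=5.0,
                                grating_class="1um")
        path = tmp_path / "prof.json"
        prof.to_json(path)
        back = CrossSectionProfile.from_json(path)
        np.testing.assert_allclose(back.membrane, prof.membrane)
        np.testing.assert_allclose(back.substrate, prof.substrate)
        assert back.grating_class == "1um"


class TestEquimomentalEllipse:
    def test_near_circle_is_isotropic(self):
        t = np.linspace(0.0, 2 * np.pi, 64, endpoint=False)
        poly = np.column_stack([np.cos(t), np.sin(t)])
        long_ax, short_ax, _ = equimomental_ellipse(poly)
        assert long_ax / short_ax == pytest.approx(1.0, abs=1e-3)

    def test_rectangle_closed_form(self):
        # a w x h rectangle has central moments w^2/12 and h^2/12 per unit
        # area, so the axis ratio is w/h and the orientation is 0
        poly = np.array([[0, 0], [10, 0], [10, 1], [0, 1]], dtype=float)
        long_ax, short_ax, orient = equimomental_ellipse(poly)
        assert long_ax / short_ax == pytest.approx(10.0, abs=1e-6)
        assert orient == pytest.approx(0.0, abs=1e-9)
        assert long_ax == pytest.approx(2 * 10 / np.sqrt(12) * 2, rel=1e-9)

    def test_rotation_equivariance(self):
        poly = np.array([[0, 0], [10, 0], [10, 1], [0, 1]], dtype=float)
        th = np.radians(30.0)
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        _, _, orient = equimomental_ellipse(poly @ R.T)
        assert orient == pytest.approx(30.0, abs=1e-6)

    def test_vertex_order_does_not_matter(self):
        poly = np.array([[0, 0], [10, 0], [10, 1], [0, 1]], dtype=float)
        cw = poly[::-1]
        assert equimomental_ellipse(cw)[0] == pytest.approx(
            equimomental_ellipse(poly)[0], rel=1e-12
        )

    def test_degenerate_polygon_rejected(self):
        with pytest.raises(ValueError):
            equimomental_ellipse(np.array([[0, 0], [1, 1], [2, 2]], float))


class TestMorphometrics:
    def test_elongation_reference_points(self):
        assert elongation_parameter(1.0, 1.0) == 0.0
        assert elongation_parameter(5.0, 1.0) == 4.0
        assert elongation_parameter(2.0, 1.0) == 1.0
        with pytest.raises(ValueError):
            elongation_parameter(1.0, 0.0)

    @pytest.mark.parametrize(
        "orient,axis,elong,expected",
        [
            (10.0, 0.0, 5.0, True),
            (15.0, 0.0, 5.0, False),   # strict inequality at 15 degrees
            (0.0, 0.0, 3.0, False),    # not elongated enough
            (170.0, 0.0, 5.0, True),   # folded: 170 vs 0 is 10 degrees
            (95.0, 0.0, 5.0, False),   # folded to 85 degrees
            (4.0, 172.0, 5.0, True),   # folded difference 12 degrees
        ],
    )
    def test_alignment_criterion(self, orient, axis, elong, expected):
        assert is_aligned(orient, axis, elong) is expected


class TestSegmentation:
    def _rec(self, theta_M, L=1e-6, d=5e-8):
        return GrooveMeasurement(L=L, d=d, theta_M=theta_M, theta_S=10.0)

    def test_boundary_assignment(self):
        groups = segment_by_bending_angle([self._rec(14.9), self._rec(15.0)])
        assert groups["theta_M < 15"]["n"] == 1
        assert groups["15 <= theta_M < 30"]["n"] == 1

    def test_partition_is_disjoint_and_complete(self, noisy_records):
        groups = segment_by_bending_angle(noisy_records)
        total = sum(g["n"] for g in groups.values())
        assert total == len(noisy_records)
        seen = set()
        for g in groups.values():
            ids = {id(r) for r in g["records"]}
            assert not ids & seen
            seen |= ids

    def test_empty_input_gives_four_flagged_groups(self):
        groups = segment_by_bending_angle([])
        assert len(groups) == 4
        for g in groups.values():
            assert g["n"] == 0
            assert np.isnan(g["mean_theta_M_deg"])

    def test_group_means_recover_generator_truth(self, rng):
        # synthetic groups drawn around the study's reported group means
        truth = [5.0, 21.0, 33.0, 46.0]
        recs = []
        for mu in truth:
            for val in rng.normal(mu, 1.5, 80):
                recs.append(self._rec(float(np.clip(val, 0.0, 89.0))))
        groups = segment_by_bending_angle(recs)
        for mu, g in zip(truth, groups.values()):
            se = g["sd_theta_M_deg"] / np.sqrt(g["n"])
            assert abs(g["mean_theta_M_deg"] - mu) < 4 * se + 0.2


class TestRecordIO:
    def test_csv_round_trip(self, tmp_path, noisy_records):
        path = tmp_path / "records.csv"
        write_records_csv(noisy_records, path)
        back = read_records_csv(path)
        assert len(back) == len(noisy_records)
        assert back[0].L == pytest.approx(noisy_records[0].L, rel=1e-12)
        assert back[0].theta_M == pytest.approx(
            noisy_records[0].theta_M, rel=1e-12
        )

    def test_missing_columns_reported(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("L_m,d_m\n1e-6,1e-8\n")
        with pytest.raises(ValueError, match="theta_M_deg"):
            read_records_csv(path)

    def test_non_finite_rows_skipped(self, tmp_path):
        path = tmp_path / "records.csv"
        path.write_text(
            "L_m,d_m,theta_M_deg,theta_S_deg\n"
            "1e-6,1e-8,10,5\n"
            "1e-6,nan,10,5\n"
        )
        assert len(read_records_csv(path)) == 1


class TestInvariantGuards:
    def test_measurement_invariants_enforced(self):
        with pytest.raises(ValueError):
            GrooveMeasurement(L=-1e-6, d=0.0, theta_M=0.0, theta_S=0.0)
        with pytest.raises(ValueError):
            GrooveMeasurement(L=1e-6, d=-1e-9, theta_M=0.0, theta_S=0.0)
        with pytest.raises(ValueError):
            GrooveMeasurement(L=1e-6, d=0.0, theta_M=95.0, theta_S=0.0)

    def test_profile_requires_increasing_x(self):
        bad = np.array([[0.0, 0.0], [1.0, 0.0], [0.5, 0.0]])
        good = np.array([[0.0, 0.0], [1.0, 0.0], [2.0, 0.0]])
        with pytest.raises(ValueError):
            CrossSectionProfile(membrane=bad, substrate=good)
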