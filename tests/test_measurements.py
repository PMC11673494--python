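import numpy as np
import pytest

import facemetry as fm
from facemetry.measurements import ALL_MEASUREMENTS, ANGLE_NAMES, LINEAR_NAMES


class TestAngleAt:
    @pytest.mark.parametrize(
        "apex,p,q,expected",
        [
            ((0, 0, 0), (0, 1, 1), (0, -1, 1), 90.0),
            ((0, 0, 0), (1, 0, 0), (-2, 0, 0), 180.0),
            ((0, 0, 0), (1, 0, 0), (1, 1, 0), 45.0),
        ],
    )
    def test_known_angles(self, apex, p, q, expected):
        assert fm.angle_at(apex, p, q) == pytest.approx(expected, abs=1e-9)

    def test_coincident_point_rejected(self):
        with pytest.raises(fm.DegenerateInputError):
            fm.angle_at((0, 0, 0), (0, 0, 0), (1, 0, 0))


class TestMeasureAll:
    def test_all_nineteen_present_on_template(self, template):
        _, lms, _ = template
        report = fm.measure_all(lms)
        assert set(report.values) == set(ALL_MEASUREMENTS)
        assert not report.missing

    def test_angles_in_valid_range(self, template):
        _, lms, _ = template
        report = fm.measure_all(lms)
        for name in ANGLE_NAMES:
            assert 0 < report[name] <= 180

    def test_linear_items_non_negative(self, template):
        _, lms, _ = template
        report = fm.measure_all(lms)
        for name in LINEAR_NAMES:
            assert report[name] >= 0

    def test_outercanthal_width_from_known_points(self, template):
        _, lms, _ = template
        pts = lms.to_dict()
        pts["ExL"] = [50.0, 40.0, 0.0]
        pts["ExR"] = [-50.0, 40.0, 0.0]
        report = fm.measure_all(fm.LandmarkSet(pts))
        assert report["outercanthal_width"] == pytest.approx(100.0)

    def test_upper_lip_protrusion_from_frame_z(self, template):
        """|Prn - Ls|z with Prn at z=20 and Ls at z=12 in the frame is 8 mm."""
        _, lms, _ = template
        frame = fm.build_frame(lms)  # identity for the canonical template
        pts = lms.to_dict()
        pts["Prn"] = [0.0, -5.0, 20.0]
        pts["Ls"] = [0.0, -28.0, 12.0]
        report = fm.measure_all(fm.LandmarkSet(pts), frame=frame)
        assert report["upper_lip_protrusion"] == pytest.approx(8.0)

    def test_nasolabial_right_angle_construction(self, template):
        _, lms, _ = template
        frame = fm.build_frame(lms)
        pts = lms.to_dict()
        sn = np.asarray(pts["Sn"])
        pts["Prn"] = list(sn + [0, 1, 1])
        pts["Ls"] = list(sn + [0, -1, 1])
        report = fm.measure_all(fm.LandmarkSet(pts), frame=frame)
        assert report["nasolabial_angle"] == pytest.approx(90.0, abs=1e-9)

    def test_missing_landmark_flags_only_its_items(self, template):
        _, lms, _ = template
        pts = {n: p for n, p in lms.to_dict().items() if n != "PhiF"}
        report = fm.measure_all(fm.LandmarkSet(pts))
        assert report.missing == {"philtral_depth"}
        assert len(report.values) == len(ALL_MEASUREMENTS) - 1

    def test_rigid_invariance(self, template):
        """All 19 items are unchanged when landmarks (and hence the frame)
        undergo a common rigid transform."""
        _, lms, _ = template
        base = fm.measure_all(lms, frame=fm.build_frame(lms))
        T = fm.RigidTransform.from_axis_angle([1, -0.4, 0.7], 0.9, [12, 5, -8])
        moved = lms.transformed(T)
        after = fm.measure_all(moved, frame=fm.build_frame(moved))
        for name in ALL_MEASUREMENTS:
            assert after[name] == pytest.approx(base[name], abs=1e-6)

    def test_mirror_symmetry_for_symmetric_landmarks(self, template):
        """Midsagittal mirroring of a symmetric landmark set leaves all
        measurements unchanged."""
        _, lms, _ = template
        sym = {}
        flip = {"L": "R", "R": "L"}
        for name, p in lms.to_dict().items():
            # symmetrize: average with the mirrored contralateral landmark
            if name[-1] in flip and name[:-1] + flip[name[-1]] in lms:
                q = lms[name[:-1] + flip[name[-1]]]
                sym[name] = [(p[0] - q[0]) / 2, (p[1] + q[1]) / 2, (p[2] + q[2]) / 2]
            else:
                sym[name] = [0.0, p[1], p[2]]
        sym_lms = fm.LandmarkSet(sym)
        mirrored = fm.LandmarkSet(
            {
                (name[:-1] + flip[name[-1]] if name[-1] in flip and name[:-1] + flip[name[-1]] in sym else name):
                [-p[0], p[1], p[2]]
                for name, p in sym_lms.to_dict().items()
            }
        )
        a = fm.measure_all(sym_lms)
        b = fm.measure_all(mirrored)
        for name in ALL_MEASUREMENTS:
            assert b[name] == pytest.approx(a[name], abs=1e-9)

    def test_projected_mode_bounded_by_euclidean(self, template):
        _, lms, _ = template
        frame = fm.build_frame(lms)
        eu = fm.measure_all(lms, frame=frame, projected=False)
        pr = fm.measure_all(lms, frame=frame, projected=True)
        for name in ("outercanthal_width", "facial_height", "upper_lip_height"):
            assert pr[name] <= eu[name] + 1e-12


class TestCompareMeasurementSets:
    def _reports(self, lms, n, offset=0.0, rng=None):
        out = []
        for i in range(n):
            pts = lms.to_dict()
            if rng is not None:
                pts = {k: np.asarray(v) + rng.normal(0, 0.3, 3) for k, v in pts.items()}
            r = fm.measure_all(fm.LandmarkSet(pts))
            if offset:
                r.values["outercanthal_width"] += offset
            out.append(r)
        return out

    def test_identical_lists_show_no_differences(self, template):
        _, lms, _ = template
        reports = self._reports(lms, 5)
        table = fm.compare_measurement_sets(reports, reports)
        assert np.allclose(table["mean_diff"], 0)
        assert not table["significant"].any()

    def test_constant_offset_detected(self, template, rng):
        _, lms, _ = template
        a = self._reports(lms, 23, rng=None)
        b = self._reports(lms, 23)
        for r in a:
            r.values["outercanthal_width"] += 1.0
        table = fm.compare_measurement_sets(a, b)
        row = table.loc["outercanthal_width"]
        assert row["mean_diff"] == pytest.approx(1.0)
        assert row["sd_diff"] == pytest.approx(0.0)

    def test_length_mismatch_rejected(self, template):
        _, lms, _ = template
        a = self._reports(lms, 3)
        with pytest.raises(fm.InvalidArgumentError):
            fm.compare_measurement_sets(a, a[:2], paired=True)

    def test_t_statistic_matches_known_difference_distribution(self, rng):
        """Pairs differing by N(1, 1) at n = 23 give t values centred on
        1 / (1/sqrt(23)) ~ 4.80 over replicates."""
        ts = []
        for _ in range(500):
            d = rng.normal(1.0, 1.0, 23)
            ts.append(fm.paired_t_from_pairs(d, np.zeros(23)).t)
        assert np.mean(ts) == pytest.approx(np.sqrt(23), abs=0.25)
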