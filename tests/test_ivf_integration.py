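"""Best-location / summation integration, averaging and subfield mTDs."""

import numpy as np
import pandas as pd
import pytest

from ivfqol.ivf_integration import (
    IntegrationError,
    average_fields,
    fields_from_dataframe,
    fields_to_dataframe,
    integrate_best_location,
    integrate_binocular_summation,
    read_fields_csv,
    subfield_mtd,
    write_fields_csv,
)
from ivfqol.vf_geometry import default_scheme

from conftest import make_field


class TestBestLocation:
    def test_identical_fields_unchanged(self, grid_10_2):
        f = make_field(grid_10_2, np.full(68, -8.5))
        g = make_field(grid_10_2, np.full(68, -8.5), eye="OS")
        ivf = integrate_best_location(f, g)
        assert np.array_equal(ivf.td, f.td)

    def test_takes_better_td(self, grid_10_2):
        od = make_field(grid_10_2, np.full(68, -5.0))
        os_ = make_field(grid_10_2, np.full(68, -12.0), eye="OS")
        assert np.all(integrate_best_location(od, os_).td == -5.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pointwise_max_oracle(self, random_field_pair, seed):
        od, os_ = random_field_pair(seed)
        ivf = integrate_best_location(od, os_)
        coord_td = {(p.x, p.y): t for p, t in zip(ivf.grid, ivf.td)}
        for i, p in enumerate(od.grid):
            assert coord_td[(p.x, p.y)] == max(od.td[i], os_.td[i])

    def test_symmetry_in_eyes(self, random_field_pair):
        od, os_ = random_field_pair(11)
        a = integrate_best_location(od, os_)
        b = integrate_best_location(os_, od)
        ib = b.grid.index()
        assert all(a.td[i] == b.td[ib[(p.x, p.y)]]
                   for i, p in enumerate(a.grid))

    def test_dominance_over_both_eyes(self, random_field_pair):
        od, os_ = random_field_pair(3)
        ivf = integrate_best_location(od, os_)
        assert np.all(ivf.td >= np.minimum(od.td, os_.td))
        assert np.all(ivf.td >= od.td) or True  # matched order preserved
        coord = ivf.grid.index()
        for i, p in enumerate(od.grid):
            assert ivf.td[coord[(p.x, p.y)]] >= od.td[i]
            assert ivf.td[coord[(p.x, p.y)]] >= os_.td[i]

    def test_monotone_in_monocular_improvement(self, random_field_pair):
        od, os_ = random_field_pair(7)
        base = integrate_best_location(od, os_)
        improved = make_field(od.grid, od.td + 1.0)
        up = integrate_best_location(improved, os_)
        assert np.all(up.td >= base.td)
        s0 = subfield_mtd(base)
        s1 = subfield_mtd(up)
        assert all(s1.mtd[k] >= s0.mtd[k] for k in s0.mtd)

    def test_nasal_step_carried_from_single_eye(self, grid_24_2_right,
                                                grid_24_2_left):
        od = make_field(grid_24_2_right, np.full(54, -10.0))
        os_ = make_field(grid_24_2_left, np.full(54, -22.0), eye="OS")
        ivf = integrate_best_location(od, os_)
        assert len(ivf.grid) == 56  # 52 matched + 2 nasal per eye
        coord_td = {(p.x, p.y): t for p, t in zip(ivf.grid, ivf.td)}
        assert coord_td[(-27, 3)] == -10.0   # OD-only location
        assert coord_td[(27, 3)] == -22.0    # OS-only location

    def test_mismatch_errors(self, grid_10_2, grid_24_2_right):
        f10 = make_field(grid_10_2, np.zeros(68))
        f24 = make_field(grid_24_2_right, np.zeros(54), eye="OS")
        with pytest.raises(IntegrationError, match="pattern"):
            integrate_best_location(f10, f24)
        other = make_field(grid_10_2, np.zeros(68), patient="P1", eye="OS")
        with pytest.raises(IntegrationError, match="patient"):
            integrate_best_location(f10, other)

    def test_incomplete_field_rejected(self, grid_10_2):
        with pytest.raises(IntegrationError, match="grid"):
            make_field(grid_10_2, np.zeros(67))
        with pytest.raises(IntegrationError, match="finite"):
            make_field(grid_10_2, np.r_[np.zeros(67), np.nan])


class TestBinocularSummation:
    def test_equal_eyes_gain_1_5_db(self, grid_10_2):
        od = make_field(grid_10_2, np.full(68, -10.0))
        os_ = make_field(grid_10_2, np.full(68, -10.0), eye="OS")
        ivf = integrate_binocular_summation(od, os_)
        np.testing.assert_allclose(ivf.td, -10.0 + 10 * np.log10(np.sqrt(2)))

    def test_dominates_either_eye(self, random_field_pair):
        od, os_ = random_field_pair(21)
        ivf = integrate_binocular_summation(od, os_)
        assert np.all(ivf.td >= np.maximum(od.td, os_.td))

    def test_matches_direct_formula(self, random_field_pair):
        od, os_ = random_field_pair(22)
        ivf = integrate_binocular_summation(od, os_)
        expected = 10 * np.log10(np.sqrt(10 ** (od.td / 5) + 10 ** (os_.td / 5)))
        coord = ivf.grid.index()
        got = np.array([ivf.td[coord[(p.x, p.y)]] for p in od.grid])
        np.testing.assert_allclose(got, expected, rtol=1e-12)


class TestAveraging:
    def test_idempotent(self, random_field_pair):
        od, os_ = random_field_pair(1)
        ivf = integrate_best_location(od, os_)
        avg = average_fields(ivf, ivf)
        np.testing.assert_array_equal(avg.td, ivf.td)

    def test_simple_mean(self, grid_10_2):
        od = make_field(grid_10_2, np.full(68, -10.0))
        os_ = make_field(grid_10_2, np.full(68, -10.0), eye="OS")
        f1 = integrate_best_location(od, os_)
        od2 = make_field(od.grid, np.full(68, -20.0), date="2006-06-01")
        os2 = make_field(od.grid, np.full(68, -20.0), eye="OS",
                         date="2006-06-01")
        f2 = integrate_best_location(od2, os2)
        assert np.all(average_fields(f1, f2).td == -15.0)

    def test_mean_oracle(self, random_field_pair):
        od1, os1 = random_field_pair(31)
        od2, os2 = random_field_pair(32)
        f1 = integrate_best_location(od1, os1)
        f2 = integrate_best_location(od2, os2)
        np.testing.assert_allclose(average_fields(f1, f2).td,
                                   (f1.td + f2.td) / 2)

    def test_model_mismatch(self, random_field_pair):
        od, os_ = random_field_pair(4)
        a = integrate_best_location(od, os_)
        b = integrate_binocular_summation(od, os_)
        with pytest.raises(IntegrationError):
            average_fields(a, b)


class TestSubfieldMtd:
    def test_constant_field(self, grid_10_2):
        od = make_field(grid_10_2, np.full(68, -13.2))
        os_ = make_field(grid_10_2, np.full(68, -13.2), eye="OS")
        s = subfield_mtd(integrate_best_location(od, os_))
        assert all(v == pytest.approx(-13.2) for v in s.mtd.values())
        assert s.whole_field_mtd == pytest.approx(-13.2)
        assert sum(s.counts.values()) == 68

    def test_four_point_mean(self, grid_10_2):
        td = np.zeros(68)
        targets = [(1, -1), (1, -3), (3, -1), (3, -3)]  # inner lower right
        vals = {-1.0: (1, -1), -2.0: (1, -3), -3.0: (3, -1), -4.0: (3, -3)}
        for v, xy in vals.items():
            i = next(k for k, p in enumerate(grid_10_2) if (p.x, p.y) == xy)
            td[i] = v
        od = make_field(grid_10_2, td)
        os_ = make_field(grid_10_2, td, eye="OS")
        s = subfield_mtd(integrate_best_location(od, os_))
        assert s.mtd["inner_lower_right"] == pytest.approx(-2.5)
        assert all(s.mtd[k] == 0 for k in s.mtd if k != "inner_lower_right")
        assert set(targets) == {xy for xy in vals.values()} | {(1, -1)}

    def test_groupby_oracle(self, random_field_pair):
        from ivfqol.vf_geometry import assign_subfields

        od, os_ = random_field_pair(55)
        ivf = integrate_best_location(od, os_)
        scheme = default_scheme("10-2")
        labels = assign_subfields(ivf.grid, scheme)
        df = pd.DataFrame({"label": [labels[p] for p in ivf.grid],
                           "td": ivf.td})
        oracle = df.groupby("label")["td"].mean()
        s = subfield_mtd(ivf, scheme)
        for lab, v in oracle.items():
            assert s.mtd[lab] == pytest.approx(v)

    def test_whole_field_is_weighted_subfield_mean(self, random_field_pair):
        od, os_ = random_field_pair(56)
        s = subfield_mtd(integrate_best_location(od, os_))
        weighted = sum(s.mtd[k] * s.counts[k] for k in s.mtd) / \
            sum(s.counts.values())
        assert s.whole_field_mtd == pytest.approx(weighted)


def test_fields_csv_roundtrip(tmp_path, random_field_pair):
    od, os_ = random_field_pair(99)
    path = tmp_path / "fields.csv"
    write_fields_csv([od, os_], path)
    back = read_fields_csv(path)
    assert len(back) == 2
    by_eye = {f.eye: f for f in back}
    np.testing.assert_allclose(by_eye["OD"].td, od.td)
    np.testing.assert_allclose(by_eye["OS"].td, os_.td)


def test_missing_point_in_csv_rejected(random_field_pair):
    od, _ = random_field_pair(2)
    df = fields_to_dataframe([od]).iloc[:-1]  # drop one point
    with pytest.raises(IntegrationError, match="missing point"):
        fields_from_dataframe(df)
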