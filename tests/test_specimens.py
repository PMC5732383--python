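"""Specimen table validation, transect geometry and grouping rules."""

import numpy as np
import pandas as pd
import pytest

from hybridcline import (
    Transect,
    assign_period,
    assign_sector,
    cluster_localities,
    read_fasta,
    read_specimen_table,
)
from hybridcline.errors import CoordinateError, DegenerateGeometryError, SchemaError
from hybridcline.specimens import KM_PER_DEG, MORPH_COLUMNS

from conftest import straight_line_points


BASE_ROW = dict(latitude=3.8, longitude=-76.9, year=1956)


class TestReadSpecimenTable:
    def test_well_formed_rows_load_verbatim(self, specimen_csv):
        rows = [dict(id=f"s{i}", **BASE_ROW) for i in range(3)]
        table = read_specimen_table(specimen_csv(rows))
        assert len(table.records) == 3
        assert table.rejected == []

    def test_out_of_range_latitude_rejected_with_reason(self, specimen_csv):
        rows = [
            dict(id="ok", **BASE_ROW),
            dict(id="bad", latitude=91.0, longitude=-76.9, year=1956),
        ]
        table = read_specimen_table(specimen_csv(rows))
        assert list(table.records["id"]) == ["ok"]
        assert len(table.rejected) == 1
        assert "latitude" in table.rejected[0].reason
        assert table.rejected[0].specimen_id == "bad"

    def test_absent_morph_columns_become_all_missing(self, specimen_csv):
        table = read_specimen_table(specimen_csv([dict(id="a", **BASE_ROW)]))
        for col in MORPH_COLUMNS:
            assert col in table.records.columns
            assert table.records[col].isna().all()

    def test_missing_required_column_names_it(self, specimen_csv):
        path = specimen_csv([dict(id="a", latitude=3.8, longitude=-76.9)])
        with pytest.raises(SchemaError, match="year"):
            read_specimen_table(path)

    def test_duplicate_ids_error_lists_them(self, specimen_csv):
        rows = [dict(id="dup", **BASE_ROW), dict(id="dup", **BASE_ROW)]
        with pytest.raises(SchemaError, match="dup"):
            read_specimen_table(specimen_csv(rows))

    def test_pre1800_year_rejected(self, specimen_csv):
        rows = [dict(id="old", latitude=3.8, longitude=-76.9, year=1750)]
        table = read_specimen_table(specimen_csv(rows))
        assert len(table.records) == 0 and "1750" in table.rejected[0].reason


class TestTransect:
    def test_collinear_points_recover_line_exactly(self):
        df = straight_line_points(slope=-0.6)
        t = Transect().fit(df)
        assert t.slope_ == pytest.approx(-0.6, abs=1e-12)
        assert t.intercept_ == pytest.approx(3.9 + 0.6 * -77.0, abs=1e-9)

    def test_distance_matches_haversine_for_100km_pair(self):
        # two points 100 km apart on an oblique (45 degree) line
        lat0 = 3.0
        dlat = 100 / np.sqrt(2) / KM_PER_DEG
        dlon = 100 / np.sqrt(2) / (KM_PER_DEG * np.cos(np.radians(lat0)))
        df = pd.DataFrame(
            {
                "longitude": [-77.0, -77.0 + dlon],
                "latitude": [lat0, lat0 + dlat],
            }
        )
        t = Transect().fit(df)
        d = t.transform(df)[:, 0]

        # haversine oracle
        r = 6371.0088
        p1, p2 = np.radians(df[["latitude", "longitude"]].to_numpy())
        a = (
            np.sin((p2[0] - p1[0]) / 2) ** 2
            + np.cos(p1[0]) * np.cos(p2[0]) * np.sin((p2[1] - p1[1]) / 2) ** 2
        )
        hav = 2 * r * np.arcsin(np.sqrt(a))
        assert abs(d[1] - d[0] - hav) / hav < 0.005

    def test_projection_residuals_orthogonal_to_direction(self, rng):
        df = pd.DataFrame(
            {
                "longitude": -77.0 + rng.uniform(0, 1.0, 10),
                "latitude": 3.5 + rng.uniform(0, 0.8, 10),
            }
        )
        t = Transect().fit(df)
        pts = t.plane_coords(df)
        proj = t.transform(df)
        feet = t._p0 + (proj[:, 0] + t.t0_)[:, None] * t.direction_
        resid = pts - feet
        assert np.all(np.abs(resid @ t.direction_) < 1e-10)

    def test_projection_idempotent_on_foot_points(self, default_bundle):
        recs = default_bundle["specimens"]
        t = Transect().fit(recs)
        proj = t.transform(recs)
        feet_lonlat = t.lonlat_at(proj[:, 0], 0.0)
        again = t.transform(feet_lonlat)
        assert np.max(np.abs(again[:, 0] - proj[:, 0])) < 1e-9
        assert np.max(np.abs(again[:, 1])) < 1e-9

    def test_perpendicular_displacement_keeps_distance(self):
        df = straight_line_points()
        t = Transect().fit(df)
        proj = t.transform(df)
        displaced = t.lonlat_at(proj[:, 0], 3.0)
        proj2 = t.transform(displaced)
        np.testing.assert_allclose(proj2[:, 0], proj[:, 0], atol=1e-9)
        np.testing.assert_allclose(proj2[:, 1], 3.0, atol=1e-9)

    def test_origin_projects_to_zero(self, default_bundle):
        t = Transect().fit(default_bundle["specimens"])
        out = t.transform(t.origin_lonlat_.reshape(1, 2))
        assert out[0, 0] == pytest.approx(0.0, abs=1e-9)
        assert out[0, 1] == pytest.approx(0.0, abs=1e-9)

    def test_all_fitted_distances_nonnegative(self, default_bundle):
        recs = default_bundle["specimens"]
        t = Transect().fit(recs)
        d = t.transform(recs)[:, 0]
        assert d.min() >= 0
        assert 120 < d.max() < 145  # ~transect length of the default world

    def test_translation_invariance_of_distances(self, rng):
        df = pd.DataFrame(
            {
                "longitude": -77.0 + rng.uniform(0, 1.2, 15),
                "latitude": 3.2 + rng.uniform(0, 0.9, 15),
            }
        )
        d1 = Transect().fit(df).transform(df)[:, 0]
        shifted = df + np.array([0.5, 0.5])
        d2 = Transect().fit(shifted).transform(shifted)[:, 0]
        assert np.max(np.abs(d1 - d2)) / np.max(d1) < 1e-3

    def test_single_point_cloud_errors(self):
        df = pd.DataFrame({"longitude": [-77.0] * 3, "latitude": [3.5] * 3})
        with pytest.raises(DegenerateGeometryError):
            Transect().fit(df)

    def test_vertical_cloud_advises_axis_swap(self):
        df = pd.DataFrame({"longitude": [-77.0] * 4, "latitude": [3.0, 3.2, 3.4, 3.6]})
        with pytest.raises(DegenerateGeometryError, match="swap"):
            Transect().fit(df)


class TestSectorsPeriodsLocalities:
    @pytest.mark.parametrize(
        "distance,expected",
        [
            (30.0, 1),
            (76.7, 2),  # the recent morphometric cline center falls in sector 2
            (45.0, 2),  # boundary: half-open [45, 90)
            (0.0, 1),
            (90.0, 3),
            (135.0, 3),  # domain end closed
            (136.0, None),
        ],
    )
    def test_sector_assignment(self, distance, expected):
        got = assign_sector(distance)
        if expected is None:
            assert pd.isna(got)
        else:
            assert got == expected

    def test_sectors_partition_the_domain(self, rng):
        d = rng.uniform(0, 135, 500)
        sec = assign_sector(d)
        assert not sec.isna().any()
        np.testing.assert_array_equal(
            np.asarray(sec, dtype=int), np.searchsorted([45, 90], d, side="right") + 1
        )

    def test_negative_distance_errors(self):
        with pytest.raises(CoordinateError):
            assign_sector(-1.0)

    @pytest.mark.parametrize(
        "year,expected",
        [
            (1894, "P1911"),
            (1911, "P1911"),
            (1956, "P1956"),
            (1986, "P1956"),
            (2007, "P2010"),
            (2010, "P2010"),
            (1930, "unassigned"),
            (1999, "unassigned"),
        ],
    )
    def test_period_assignment(self, year, expected):
        assert assign_period(year) == expected

    def _positions(self, dists):
        return pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(len(dists))],
                "x_km": dists,
                "y_km": 0.0,
                "distance_km": dists,
            }
        )

    def test_pair_within_radius_shares_locality(self):
        loc = cluster_localities(self._positions([10.0, 10.5]))
        assert loc[0] == loc[1]

    def test_distant_pair_split(self):
        loc = cluster_localities(self._positions([10.0, 15.0]))
        assert loc[0] != loc[1]

    def test_chain_merges_under_single_linkage(self):
        # A-B 0.9, B-C 0.9, A-C 1.8: one locality despite A-C > 1 km
        loc = cluster_localities(self._positions([0.0, 0.9, 1.8]))
        assert loc.nunique() == 1

    def test_matches_connected_components_oracle(self, rng):
        pts = rng.uniform(0, 8, (20, 2))
        pos = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(20)],
                "x_km": pts[:, 0],
                "y_km": pts[:, 1],
                "distance_km": pts[:, 0],
            }
        )
        got = cluster_localities(pos)
        # brute-force union-find on the <= 1 km graph
        parent = list(range(20))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        for i in range(20):
            for j in range(i + 1, 20):
                if np.hypot(*(pts[i] - pts[j])) <= 1.0:
                    parent[find(i)] = find(j)
        oracle = [find(i) for i in range(20)]
        # same partition
        for i in range(20):
            for j in range(20):
                assert (got[i] == got[j]) == (oracle[i] == oracle[j])

    def test_locality_ids_stable_under_row_order(self, rng):
        pts = rng.uniform(0, 30, (15, 2))
        pos = pd.DataFrame(
            {
                "id": [f"s{i}" for i in range(15)],
                "x_km": pts[:, 0],
                "y_km": pts[:, 1],
                "distance_km": pts[:, 0],
            }
        )
        a = cluster_localities(pos)
        perm = rng.permutation(15)
        b = cluster_localities(pos.iloc[perm].reset_index(drop=True))
        mapped = {pos["id"][i]: a[i] for i in range(15)}
        for i, row_id in enumerate(pos.iloc[perm]["id"].to_numpy()):
            assert b[i] == mapped[row_id]


class TestReadFasta:
    def test_three_sequences(self, fasta_file):
        path = fasta_file({"a": "ACGT", "b": "ACGA", "c": "ACG-"})
        seqs = read_fasta(path)
        assert set(seqs) == {"a", "b", "c"}

    def test_duplicate_header_errors(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">x\nACGT\n>x\nACGT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_fasta(path)

    def test_lowercase_normalized(self, fasta_file):
        seqs = read_fasta(fasta_file({"a": "acgtn-"}))
        assert seqs["a"] == "ACGTN-"

    def test_illegal_character_names_position(self, fasta_file):
        with pytest.raises(ValueError, match="position 3"):
            read_fasta(fasta_file({"a": "ACXT"}))
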