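"""Specimen tables, transect geometry and spatial/temporal grouping.

Museum skins enter the analysis as rows of a CSV table (id, coordinates,
collection year, sex, six morphometric characters).  The hybrid zone runs
roughly northwest-southeast, so specimens are projected onto a straight
transect line fitted to their coordinates; every downstream analysis works
with the distance (km) of each bird from the northwest (coastal) end of
that line.  This module also assigns the coarse spatial sectors used by the
AMOVA, groups specimens collected within 1 km into localities, and maps
collection years onto the three sampling periods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import CoordinateError, DegenerateGeometryError, SchemaError

#: km per degree of latitude (spherical Earth, equirectangular projection)
KM_PER_DEG = 111.32

REQUIRED_COLUMNS = ("id", "latitude", "longitude", "year")
MORPH_COLUMNS = (
    "wing_mm",
    "culmen_mm",
    "bill_depth_mm",
    "bill_width_mm",
    "tail_mm",
    "tarsus_mm",
)
OPTIONAL_COLUMNS = ("sex",) + MORPH_COLUMNS + ("spectrum_id", "sequence_id")

#: default sector breakpoints: sectors [0,45), [45,90), [90,135]
DEFAULT_SECTOR_BOUNDS = (45.0, 90.0, 135.0)

PERIODS = ("P1911", "P1956", "P2010")


@dataclass
class RowReport:
    """Per-row validation outcome for a rejected specimen row."""

    row: int
    specimen_id: str
    reason: str


@dataclass
class SpecimenTable:
    """Validated specimen records plus the rejection report."""

    records: pd.DataFrame
    rejected: list[RowReport] = field(default_factory=list)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return len(self.records)


def read_specimen_table(path, schema: dict[str, str] | None = None) -> SpecimenTable:
    """Read and validate a specimen CSV.

    Parameters
    ----------
    path : str or file-like
        CSV with required columns ``id, latitude, longitude, year`` and any of
        the optional columns (sex, the six morphometric characters in mm,
        spectrum_id, sequence_id).
    schema : dict, optional
        Mapping from the file's column names to the canonical names, for
        tables using different headers.

    Returns
    -------
    SpecimenTable
        ``records`` holds one row per accepted specimen (morph columns always
        present, missing values as NaN); ``rejected`` reports rows dropped for
        unparseable or out-of-range coordinates/years.

    Raises
    ------
    SchemaError
        If a required column is missing or specimen ids are duplicated.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if schema:
        df = df.rename(columns=schema)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")

    dup = df["id"][df["id"].duplicated()].unique()
    if len(dup):
        raise SchemaError(f"duplicate specimen id(s): {', '.join(map(str, dup))}")

    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = "unknown" if col == "sex" else np.nan

    rejected: list[RowReport] = []
    keep = np.ones(len(df), dtype=bool)

    lat = pd.to_numeric(df["latitude"], errors="coerce")
    lon = pd.to_numeric(df["longitude"], errors="coerce")
    year = pd.to_numeric(df["year"], errors="coerce")

    for i in range(len(df)):
        sid = str(df["id"].iloc[i])
        if not np.isfinite(lat.iloc[i]) or not np.isfinite(lon.iloc[i]):
            rejected.append(RowReport(i, sid, "unparseable coordinates"))
            keep[i] = False
        elif not -90.0 <= lat.iloc[i] <= 90.0:
            rejected.append(RowReport(i, sid, f"latitude {lat.iloc[i]} outside [-90, 90]"))
            keep[i] = False
        elif not -180.0 <= lon.iloc[i] <= 180.0:
            rejected.append(RowReport(i, sid, f"longitude {lon.iloc[i]} outside [-180, 180]"))
            keep[i] = False
        elif not np.isfinite(year.iloc[i]):
            rejected.append(RowReport(i, sid, "unparseable year"))
            keep[i] = False
        elif year.iloc[i] < 1800:
            rejected.append(RowReport(i, sid, f"year {year.iloc[i]:.0f} before 1800"))
            keep[i] = False

    out = df.loc[keep].copy()
    out["latitude"] = lat[keep]
    out["longitude"] = lon[keep]
    out["year"] = year[keep].astype(int)
    out["sex"] = out["sex"].fillna("unknown").astype(str).str.lower()
    out.loc[~out["sex"].isin(["male", "female"]), "sex"] = "unknown"
    for col in MORPH_COLUMNS:
        out[col] = pd.to_numeric(out[col], errors="coerce")
        bad = out[col] <= 0
        if bad.any():
            for i in out.index[bad]:
                rejected.append(
                    RowReport(int(i), str(out.at[i, "id"]), f"non-positive {col}")
                )
            out.loc[bad, col] = np.nan
    out = out.reset_index(drop=True)
    return SpecimenTable(records=out, rejected=rejected)


class Transect(TransformerMixin, BaseEstimator):
    """Straight transect fitted to specimen coordinates.

    Latitude is regressed on longitude by ordinary least squares; coordinates
    are converted to a local planar frame (equirectangular, km) about the mean
    latitude.  The transect origin (distance 0) is the perpendicular foot of
    the most-northwest specimen, and the unit direction points inland
    (southeast), so fitted specimens project to non-negative distances.

    Parameters
    ----------
    min_lon_spread : float, default 1e-6
        Minimum longitude standard deviation (degrees).  Below this the point
        cloud is effectively vertical and a latitude-on-longitude regression
        is meaningless; an error advises swapping axes.

    Attributes
    ----------
    slope_, intercept_ : float
        Regression line ``lat = intercept_ + slope_ * lon`` in degrees.
    lat0_, lon0_ : float
        Projection reference (means of the training coordinates).
    kx_, ky_ : float
        km per degree of longitude / latitude at the reference latitude.
    direction_ : ndarray (2,)
        Unit along-line direction in the planar km frame, pointing southeast.
    t0_ : float
        Along-line coordinate of the origin in the planar frame.
    origin_lonlat_ : ndarray (2,)
        (lon, lat) of the transect origin.
    length_km_ : float
        Along-line span of the training specimens.
    """

    def __init__(self, min_lon_spread: float = 1e-6):
        self.min_lon_spread = min_lon_spread

    def _to_plane(self, lon, lat):
        x = (np.asarray(lon, float) - self.lon0_) * self.kx_
        y = (np.asarray(lat, float) - self.lat0_) * self.ky_
        return x, y

    def fit(self, X, y=None):
        """Fit the transect line.

        ``X`` is a DataFrame with ``latitude``/``longitude`` columns or an
        (n, 2) array of (longitude, latitude) pairs in decimal degrees.
        """
        lon, lat = _coords(X)
        if len(lon) < 2 or (np.ptp(lon) == 0 and np.ptp(lat) == 0):
            raise DegenerateGeometryError(
                "need at least two distinct coordinates to fit a transect"
            )
        if np.std(lon) < self.min_lon_spread:
            raise DegenerateGeometryError(
                "longitude variance is ~0; latitude-on-longitude regression is "
                "degenerate — swap axes (regress longitude on latitude) instead"
            )
        self.lat0_ = float(np.mean(lat))
        self.lon0_ = float(np.mean(lon))
        self.ky_ = KM_PER_DEG
        self.kx_ = KM_PER_DEG * math.cos(math.radians(self.lat0_))

        self.slope_, self.intercept_ = np.polyfit(lon, lat, 1)
        self.slope_ = float(self.slope_)
        self.intercept_ = float(self.intercept_)

        # line in the planar frame: passes through p0 with direction d
        x0 = 0.0
        y0 = (self.intercept_ + self.slope_ * self.lon0_ - self.lat0_) * self.ky_
        d = np.array([self.kx_, self.slope_ * self.ky_])
        d /= np.linalg.norm(d)
        # orient southeast/inland: positive east, else southward
        if d[0] < 0 or (d[0] == 0 and d[1] > 0):
            d = -d
        self._p0 = np.array([x0, y0])
        self.direction_ = d

        px, py = self._to_plane(lon, lat)
        t = (px - x0) * d[0] + (py - y0) * d[1]
        self.t0_ = float(t.min())
        self.length_km_ = float(t.max() - t.min())
        origin = self._p0 + self.t0_ * d
        self.origin_lonlat_ = np.array(
            [origin[0] / self.kx_ + self.lon0_, origin[1] / self.ky_ + self.lat0_]
        )
        return self

    def transform(self, X):
        """Project coordinates; returns an (n, 2) array [distance_km, offset_km].

        ``offset_km`` is the signed perpendicular displacement from the line
        (positive to the left of the along-line direction).
        """
        check_is_fitted(self, "direction_")
        lon, lat = _coords(X)
        px, py = self._to_plane(lon, lat)
        dx = px - self._p0[0]
        dy = py - self._p0[1]
        d = self.direction_
        t = dx * d[0] + dy * d[1]
        offset = -dx * d[1] + dy * d[0]
        return np.column_stack([t - self.t0_, offset])

    def plane_coords(self, X):
        """Planar km coordinates (x east, y north) about the fitted reference."""
        check_is_fitted(self, "direction_")
        lon, lat = _coords(X)
        return np.column_stack(self._to_plane(lon, lat))

    def lonlat_at(self, distance_km, offset_km=0.0):
        """Inverse map: (lon, lat) of a point at a transect position."""
        check_is_fitted(self, "direction_")
        t = np.asarray(distance_km, float) + self.t0_
        off = np.asarray(offset_km, float)
        d = self.direction_
        n = np.array([-d[1], d[0]])
        x = self._p0[0] + t * d[0] + off * n[0]
        y = self._p0[1] + t * d[1] + off * n[1]
        return np.column_stack([x / self.kx_ + self.lon0_, y / self.ky_ + self.lat0_])


def _coords(X):
    if isinstance(X, pd.DataFrame):
        return X["longitude"].to_numpy(float), X["latitude"].to_numpy(float)
    arr = np.asarray(X, float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError("expected a DataFrame with latitude/longitude or an (n, 2) array")
    return arr[:, 0], arr[:, 1]


def fit_transect(records: pd.DataFrame, **kwargs) -> Transect:
    """Fit a :class:`Transect` to specimen records (thin wrapper)."""
    return Transect(**kwargs).fit(records)


def assign_sector(distance_km, bounds=DEFAULT_SECTOR_BOUNDS):
    """Map transect distances to sectors 1..k (half-open intervals).

    With the default bounds (45, 90, 135): sector 1 = [0, 45), sector 2 =
    [45, 90), sector 3 = [90, 135].  Distances beyond the domain end get
    ``pd.NA`` (no sector); negative distances raise.
    """
    d = np.asarray(distance_km, float)
    scalar = d.ndim == 0
    d = np.atleast_1d(d)
    if (d < 0).any():
        raise CoordinateError("negative transect distance")
    edges = [0.0] + list(bounds)
    sec = np.searchsorted(edges, d, side="right")  # 1-based
    out = pd.array(sec, dtype="Int64")
    out[d > edges[-1]] = pd.NA
    # closed at the domain end
    out[d == edges[-1]] = len(bounds)
    if scalar:
        return out[0]
    return out


def assign_period(year):
    """Map collection years to sampling periods.

    ``year <= 1911`` -> P1911; ``1956-1986`` -> P1956; ``2007-2010`` -> P2010
    (the recent series was collected over 2007-2010); anything else ->
    ``"unassigned"`` and is excluded from cline analyses.
    """
    y = np.atleast_1d(np.asarray(year))
    out = np.full(y.shape, "unassigned", dtype=object)
    out[y <= 1911] = "P1911"
    out[(y >= 1956) & (y <= 1986)] = "P1956"
    out[(y >= 2007) & (y <= 2010)] = "P2010"
    if np.isscalar(year) or np.ndim(year) == 0:
        return out[0]
    return out


def cluster_localities(positions: pd.DataFrame, radius_km: float = 1.0) -> pd.Series:
    """Group specimens within ``radius_km`` of each other into localities.

    Single-linkage clustering: localities are the connected components of the
    graph joining pairs at planar distance <= ``radius_km`` (so chains A-B-C
    with consecutive gaps under the radius form one locality).  Ids are
    integers from 1, ordered by the locality's minimum ``distance_km`` (ties
    broken by specimen id), hence stable under row order.

    ``positions`` needs columns ``x_km, y_km, distance_km, id``.
    """
    pts = positions[["x_km", "y_km"]].to_numpy(float)
    n = len(pts)
    if n == 0:
        return pd.Series([], dtype="Int64")
    diff = pts[:, None, :] - pts[None, :, :]
    adj = (diff**2).sum(-1) <= radius_km**2
    _, labels = connected_components(csr_matrix(adj), directed=False)
    # stable relabel: order components by (min distance, min id)
    order_key = {}
    for lab in np.unique(labels):
        mask = labels == lab
        dmin = positions["distance_km"].to_numpy(float)[mask].min()
        idmin = min(map(str, positions["id"].to_numpy()[mask]))
        order_key[lab] = (dmin, idmin)
    ranked = sorted(order_key, key=order_key.get)
    remap = {lab: i + 1 for i, lab in enumerate(ranked)}
    return pd.Series([remap[l] for l in labels], index=positions.index, dtype="Int64")


def build_positions(
    table: SpecimenTable | pd.DataFrame,
    transect: Transect | None = None,
    sector_bounds=DEFAULT_SECTOR_BOUNDS,
    locality_radius_km: float = 1.0,
) -> tuple[pd.DataFrame, Transect]:
    """Full spatial preparation: fit/project the transect, assign groupings.

    Returns a positions table (id, distance_km, offset_km, x_km, y_km, sector,
    locality_id, period, plus carried-through specimen columns) and the fitted
    transect.
    """
    records = table.records if isinstance(table, SpecimenTable) else table
    if transect is None:
        transect = Transect().fit(records)
    proj = transect.transform(records)
    plane = transect.plane_coords(records)
    pos = records.copy().reset_index(drop=True)
    pos["distance_km"] = proj[:, 0]
    pos["offset_km"] = proj[:, 1]
    pos["x_km"] = plane[:, 0]
    pos["y_km"] = plane[:, 1]
    dist = np.clip(pos["distance_km"].to_numpy(float), 0.0, None)
    pos["sector"] = assign_sector(dist, bounds=sector_bounds)
    pos["locality_id"] = cluster_localities(pos, radius_km=locality_radius_km)
    pos["period"] = assign_period(pos["year"].to_numpy())
    return pos, transect


_VALID_BASES = set("ACGTN-")


def read_fasta(path) -> dict[str, str]:
    """Read aligned sequences into an id -> sequence dict.

    Sequences are uppercased; the alphabet is restricted to ``A C G T N -``.
    Duplicate headers and illegal characters raise ``ValueError`` (the latter
    naming the offending position).  Equal lengths are *not* enforced here —
    alignment checks happen downstream where an alignment is actually needed.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id: {rec.id}")
        s = str(rec.seq).upper()
        for pos, ch in enumerate(s):
            if ch not in _VALID_BASES:
                raise ValueError(
                    f"illegal character {ch!r} at position {pos + 1} in {rec.id}"
                )
        seqs[rec.id] = s
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    """Write sequences in FASTA (60-column wrap), deterministically ordered."""
    with open(path, "w") as fh:
        for sid, s in seqs.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(s), 60):
                fh.write(s[i : i + 60] + "\n")
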