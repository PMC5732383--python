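"""Morphometric and plumage-color phenotypes.

Two phenotype axes feed the cline analysis: a body-size score (PC1 of six
morphometric characters, computed separately per sex on the correlation
matrix) and plumage chroma from rump reflectance spectra, summarized by
segment classification — the 400-700 nm spectrum is split into four equal
wavelength segments whose relative reflectances yield brightness, chroma
(saturation) and hue.  Yellow-rumped birds and scarlet-rumped birds differ
in where reflectance is concentrated, so chroma/hue track the plumage
gradient across the hybrid zone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted

from .errors import InsufficientDataError
from .specimens import MORPH_COLUMNS

__all__ = [
    "complete_case_filter",
    "SizePCA",
    "compute_pca",
    "ColorMetrics",
    "segment_metrics",
    "segment_metrics_table",
    "read_spectra",
    "attach_phenotypes",
]


def complete_case_filter(
    morph: pd.DataFrame, columns=MORPH_COLUMNS
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Drop rows with any missing required measurement.

    Returns the filtered table and a per-column count of missing cells among
    the dropped rows.  Fewer than 3 complete rows raises
    :class:`InsufficientDataError` (a 6-character PCA needs at least that).
    """
    cols = list(columns)
    present = morph[cols].notna().all(axis=1)
    dropped = morph.loc[~present]
    report = {c: int(dropped[c].isna().sum()) for c in cols}
    kept = morph.loc[present].copy()
    if len(kept) < 3:
        raise InsufficientDataError(
            f"only {len(kept)} complete rows after filtering; need >= 3"
        )
    return kept, report


class SizePCA(TransformerMixin, BaseEstimator):
    """PCA of morphometric characters with a body-size sign convention.

    By default the PCA runs on the correlation matrix (characters are
    z-scored), appropriate for lengths of very different magnitudes.  PC1 is
    oriented so that wing length loads positively: larger birds get larger
    scores, matching the larger inland form.  Remaining axes are oriented so
    their largest-magnitude loading is positive (a deterministic convention).

    Parameters
    ----------
    scale : {"correlation", "covariance"}
        Whether to standardize columns before the eigendecomposition.
    size_column : str
        Column whose PC1 loading fixes the sign (default ``wing_mm``).

    Attributes
    ----------
    loadings_ : ndarray (p, p)
        Columns are unit-norm principal axes.
    explained_variance_ratio_ : ndarray (p,)
    mean_, scale_factors_ : ndarray (p,)
    columns_ : list of str
    """

    def __init__(self, scale: str = "correlation", size_column: str = "wing_mm"):
        self.scale = scale
        self.size_column = size_column

    def _prepare(self, X):
        if isinstance(X, pd.DataFrame):
            return X[self.columns_].to_numpy(float)
        return np.asarray(X, float)

    def fit(self, X, y=None):
        if isinstance(X, pd.DataFrame):
            self.columns_ = list(X.columns)
        else:
            X = np.asarray(X, float)
            self.columns_ = [f"x{i}" for i in range(X.shape[1])]
            X = pd.DataFrame(X, columns=self.columns_)
        M = X.to_numpy(float)
        if len(M) < 3:
            raise InsufficientDataError("PCA needs at least 3 complete rows")
        if np.isnan(M).any():
            raise ValueError("missing values: run complete_case_filter first")
        self.mean_ = M.mean(axis=0)
        sd = M.std(axis=0, ddof=1)
        zero = np.where(sd == 0)[0]
        if zero.size:
            raise ValueError(
                f"zero-variance column(s): {', '.join(self.columns_[i] for i in zero)}"
            )
        self.scale_factors_ = sd if self.scale == "correlation" else np.ones_like(sd)
        Z = (M - self.mean_) / self.scale_factors_
        # SVD of the centered/scaled matrix == eigendecomposition of corr/cov
        _, s, Vt = np.linalg.svd(Z, full_matrices=False)
        var = s**2 / (len(M) - 1)
        self.explained_variance_ = var
        self.explained_variance_ratio_ = var / var.sum()
        V = Vt.T
        # sign conventions
        if self.size_column in self.columns_:
            k = self.columns_.index(self.size_column)
            if V[k, 0] < 0:
                V[:, 0] = -V[:, 0]
        for j in range(1, V.shape[1]):
            if V[np.argmax(np.abs(V[:, j])), j] < 0:
                V[:, j] = -V[:, j]
        self.loadings_ = V
        return self

    def transform(self, X):
        """Project onto the principal axes; scores are centered."""
        check_is_fitted(self, "loadings_")
        M = self._prepare(X)
        Z = (M - self.mean_) / self.scale_factors_
        return Z @ self.loadings_


@dataclass
class PcaResult:
    """Loadings, per-specimen scores and variance shares for one sex."""

    loadings: pd.DataFrame
    scores: pd.DataFrame
    explained_variance_ratio: np.ndarray
    sex: str


def compute_pca(
    morph: pd.DataFrame,
    sex: str | None = None,
    columns=MORPH_COLUMNS,
    scale: str = "correlation",
) -> PcaResult:
    """Run the per-sex morphometric PCA on complete cases.

    ``morph`` must carry ``id`` and ``sex`` columns plus the measurement
    columns.  Returns loadings, scores (PC1.. named columns, indexed by
    specimen id) and variance proportions.
    """
    sub = morph if sex is None else morph[morph["sex"] == sex]
    kept, _ = complete_case_filter(sub, columns)
    est = SizePCA(scale=scale).fit(kept[list(columns)])
    scores = est.transform(kept[list(columns)])
    names = [f"PC{i + 1}" for i in range(scores.shape[1])]
    return PcaResult(
        loadings=pd.DataFrame(est.loadings_, index=list(columns), columns=names),
        scores=pd.DataFrame(scores, index=kept["id"].astype(str), columns=names),
        explained_variance_ratio=est.explained_variance_ratio_,
        sex=sex or "all",
    )


# ---------------------------------------------------------------------------
# Segment classification of reflectance spectra
# ---------------------------------------------------------------------------

#: 1-nm evaluation grid; 300 points so the four segments have exactly 75 each
WAVE_GRID = np.arange(400, 700)
_SEGMENTS = np.split(np.arange(WAVE_GRID.size), 4)


@dataclass
class ColorMetrics:
    """Segment-classification summary of one reflectance spectrum.

    ``q1..q4`` are the fractions of total reflectance in the four equal
    wavelength segments (400-475, 475-550, 550-625, 625-700 nm); ``lm = q4 -
    q2`` and ``ms = q3 - q1`` span a red-green / yellow-blue opponent plane;
    chroma is the radial distance in that plane and hue its angle
    (``atan2(ms, lm)``, radians).  ``degenerate`` marks spectra with no
    spectral contrast (chroma ~ 0) or zero total reflectance, where hue is
    reported as 0 but carries no information.
    """

    brightness: float
    q1: float
    q2: float
    q3: float
    q4: float
    lm: float
    ms: float
    chroma: float
    hue: float
    degenerate: bool = False


def _on_grid(wavelengths, reflectance):
    w = np.asarray(wavelengths, float)
    r = np.asarray(reflectance, float)
    if w.ndim != 1 or w.shape != r.shape:
        raise ValueError("wavelengths and reflectance must be equal-length 1-D")
    if not np.all(np.diff(w) > 0):
        raise ValueError("wavelengths must be strictly increasing")
    if w[0] < 400 - 1e-9 or w[-1] > 700 + 1e-9:
        raise ValueError("wavelengths must lie within [400, 700] nm")
    if (r < 0).any():
        raise ValueError("negative reflectance")
    # coverage: at least one reading per 25-nm bin
    bins = np.floor((w - 400) / 25).astype(int)
    if set(range(12)) - set(bins.tolist()):
        raise ValueError("spectrum must cover every 25-nm bin of 400-700 nm")
    return np.interp(WAVE_GRID, w, r)


def segment_metrics(wavelengths, reflectance) -> ColorMetrics:
    """Brightness, chroma and hue of a spectrum by segment classification.

    The spectrum is linearly interpolated onto a 1-nm grid and split into four
    equal segments; see :class:`ColorMetrics` for the definitions.  A spectrum
    with zero total reflectance returns brightness 0 and degenerate color.
    """
    r = _on_grid(wavelengths, reflectance)
    total = r.sum()
    brightness = float(r.mean())
    if total <= 0:
        return ColorMetrics(0.0, *([0.0] * 8), degenerate=True)
    q = np.array([r[idx].sum() for idx in _SEGMENTS]) / total
    lm = float(q[3] - q[1])
    ms = float(q[2] - q[0])
    chroma = float(np.hypot(lm, ms))
    degenerate = chroma < 1e-12
    hue = 0.0 if degenerate else float(np.arctan2(ms, lm))
    return ColorMetrics(brightness, *q, lm, ms, chroma, hue, degenerate)


def read_spectra(path) -> pd.DataFrame:
    """Read a wide spectra CSV: column ``wavelength_nm`` then one column per id."""
    df = pd.read_csv(path)
    if "wavelength_nm" not in df.columns:
        raise ValueError("spectra CSV must have a 'wavelength_nm' column")
    return df


def segment_metrics_table(spectra: pd.DataFrame) -> pd.DataFrame:
    """Segment metrics for every spectrum column of a wide spectra table.

    Columns sharing a base name before a ``_rep`` suffix (replicate scans of
    one specimen) are averaged on the 1-nm grid before metrics are computed.
    Returns a DataFrame indexed by spectrum_id.
    """
    w = spectra["wavelength_nm"].to_numpy(float)
    groups: dict[str, list[np.ndarray]] = {}
    for col in spectra.columns:
        if col == "wavelength_nm":
            continue
        base = col.split("_rep")[0]
        groups.setdefault(base, []).append(
            np.interp(WAVE_GRID, w, spectra[col].to_numpy(float))
        )
    rows = {}
    for sid, reps in groups.items():
        mean_r = np.mean(reps, axis=0)
        m = segment_metrics(WAVE_GRID, mean_r)
        rows[sid] = {
            "brightness": m.brightness,
            "chroma": m.chroma,
            "hue": m.hue,
            "degenerate": m.degenerate,
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "spectrum_id"
    return out


def attach_phenotypes(
    positions: pd.DataFrame,
    pca: PcaResult | None = None,
    colors: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Join positions with PC1 scores and color metrics into one analysis table.

    One row per specimen in ``positions`` with ``distance_km, period, sex,
    pc1, brightness, chroma, hue``; phenotypes missing for a specimen stay
    NaN.  Phenotype ids absent from the positions table are dropped and
    reported in the returned warning list.
    """
    out = positions.copy()
    out["id"] = out["id"].astype(str)
    warnings: list[str] = []
    if pca is not None:
        pc1 = pca.scores["PC1"]
        orphans = set(pc1.index) - set(out["id"])
        if orphans:
            warnings.append(
                f"PCA scores for ids absent from positions: {sorted(orphans)}"
            )
        out = out.merge(
            pc1.rename("pc1"), left_on="id", right_index=True, how="left"
        )
    else:
        out["pc1"] = np.nan
    if colors is not None:
        key = "spectrum_id" if "spectrum_id" in out.columns else "id"
        known = set(out[key].dropna().astype(str))
        orphans = set(colors.index.astype(str)) - known
        if orphans:
            warnings.append(
                f"spectra without a matching specimen: {sorted(orphans)}"
            )
        out = out.merge(
            colors[["brightness", "chroma", "hue"]],
            left_on=key,
            right_index=True,
            how="left",
        )
    else:
        out[["brightness", "chroma", "hue"]] = np.nan
    return out, warnings
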