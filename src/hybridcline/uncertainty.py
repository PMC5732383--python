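"""Bootstrap uncertainty for cline parameters and cross-period comparisons.

Sampling effort along the transect differs wildly between collection
periods, so point estimates of cline center and width are accompanied by a
case-resampling bootstrap: individuals are resampled with replacement at
constant sample size and the cline refitted.  Replicates are retained only
if the refit converged and placed the center inside the geographic bounds
of the study region (0-140 km by default) — with small samples some
resamples are simply not clinal.  Periods are then compared by one-way
ANOVA and Tukey HSD treating bootstrap replicates as independent
observations.  That treatment is pseudo-replication (replicates from one
period share one underlying dataset), so all P-values are labelled
``bootstrap-replicate ANOVA``; they order the evidence but overstate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .cline import HillCline
from .errors import UnstableBootstrapWarning

__all__ = [
    "BootstrapDistribution",
    "bootstrap_cline",
    "anova_periods",
    "tukey_hsd",
    "summarize_movement",
]


@dataclass
class BootstrapDistribution:
    """Retained (center, width) bootstrap replicates for one trait x period."""

    trait: str
    period: str
    requested: int
    centers: np.ndarray
    widths: np.ndarray
    bounds: tuple[float, float]
    n_data: int
    point_center: float
    point_width: float
    n_nonconverged: int = 0
    #: replicates whose width exceeds the transect length (reported, not dropped)
    n_width_unrealistic: int = 0
    transect_length: float = 135.0

    @property
    def retained(self) -> int:
        return len(self.centers)

    @property
    def retention_rate(self) -> float:
        return self.retained / self.requested

    @property
    def mean_center(self) -> float:
        return float(np.mean(self.centers))

    @property
    def mean_width(self) -> float:
        return float(np.mean(self.widths))

    @property
    def ci_center(self) -> tuple[float, float]:
        return tuple(np.percentile(self.centers, [2.5, 97.5]))

    @property
    def ci_width(self) -> tuple[float, float]:
        return tuple(np.percentile(self.widths, [2.5, 97.5]))

    @property
    def width_unrealistic_fraction(self) -> float:
        return self.n_width_unrealistic / max(self.retained, 1)

    @property
    def width_ci_omitted(self) -> bool:
        """Flag mirroring the reporting rule for wildly unstable width
        bootstraps: when more than half the retained replicates imply a cline
        wider than the transect itself, the width CI is not reported."""
        return self.width_unrealistic_fraction > 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trait": self.trait,
                "period": self.period,
                "center_km": self.centers,
                "width_km": self.widths,
            }
        )

    def summary(self) -> dict:
        lo_c, hi_c = self.ci_center
        out = {
            "trait": self.trait,
            "period": self.period,
            "center": self.mean_center,
            "width": self.mean_width,
            "center_ci": [lo_c, hi_c],
            "width_ci": None if self.width_ci_omitted else list(self.ci_width),
            "point_center": self.point_center,
            "point_width": self.point_width,
            "retained": self.retained,
            "requested": self.requested,
            "retention_rate": self.retention_rate,
        }
        return out


def bootstrap_cline(
    x,
    y,
    reps: int = 1000,
    bounds: tuple[float, float] = (0.0, 140.0),
    seed: int | None = None,
    trait: str = "trait",
    period: str = "all",
    x_offset: float = 0.1,
    transect_length: float = 135.0,
    min_retained_warn: int = 50,
    **fit_kwargs,
) -> BootstrapDistribution:
    """Case-resampling bootstrap of cline center and width.

    Each replicate resamples the n individuals with replacement and refits the
    Hill cline (warm-started from the parent fit, falling back to the full
    multistart grid).  A replicate is retained iff the fit converged and its
    center lies within ``bounds``.  Replicate r draws its resample from the
    deterministic substream ``default_rng([seed, r])``, so runs are
    bit-reproducible and independent of execution order.

    Raises if no replicate is retained; warns (:class:`UnstableBootstrapWarning`)
    below ``min_retained_warn`` retained replicates.
    """
    if seed is None:
        raise ValueError("a seed is required for a reproducible bootstrap")
    x = np.asarray(x, float).reshape(-1)
    y = np.asarray(y, float).reshape(-1)
    mask = np.isfinite(x) & np.isfinite(y)
    x, y = x[mask], y[mask]
    n = len(x)

    parent = HillCline(x_offset=x_offset, **fit_kwargs).fit(x, y)
    warm = (
        [(parent.B_, np.log(parent.E_))]
        if parent.converged_
        else []
    )
    # replicates warm-start from the parent fit only; the full multistart
    # grid is retried when the warm start fails to converge
    est_warm = HillCline(x_offset=x_offset, b_starts=(), **fit_kwargs)
    est_full = HillCline(x_offset=x_offset, **fit_kwargs)

    centers, widths = [], []
    n_nc = 0
    n_wide = 0
    for r in range(reps):
        rng = np.random.default_rng([seed, r])
        idx = rng.integers(0, n, n)
        est = None
        try:
            if warm:
                est = est_warm.fit(x[idx], y[idx], extra_starts=warm)
            if est is None or not est.converged_:
                est = est_full.fit(x[idx], y[idx], extra_starts=warm)
        except Exception:
            n_nc += 1
            continue
        if not est.converged_:
            n_nc += 1
            continue
        c = est.center_
        if not bounds[0] <= c <= bounds[1]:
            continue
        centers.append(c)
        widths.append(est.width_)
        if est.width_ > transect_length:
            n_wide += 1

    if not centers:
        raise RuntimeError(
            f"bootstrap retained 0 of {reps} replicates for {trait}/{period}"
        )
    if len(centers) < min_retained_warn:
        warnings.warn(
            f"only {len(centers)} of {reps} bootstrap replicates retained for "
            f"{trait}/{period}; intervals are unstable",
            UnstableBootstrapWarning,
        )
    return BootstrapDistribution(
        trait=trait,
        period=period,
        requested=reps,
        centers=np.asarray(centers),
        widths=np.asarray(widths),
        bounds=tuple(bounds),
        n_data=n,
        point_center=parent.center_,
        point_width=parent.width_,
        n_nonconverged=n_nc,
        n_width_unrealistic=n_wide,
        transect_length=transect_length,
    )


def anova_periods(groups) -> tuple[float, float]:
    """One-way fixed-effects ANOVA over replicate values per period.

    ``groups`` is a sequence (or dict) of 1-D arrays.  Returns (F, P).  If
    every group has zero variance but means differ, F is infinite and P = 0.
    """
    if isinstance(groups, dict):
        groups = list(groups.values())
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs >= 2 groups with >= 2 values each")
    if all(np.ptp(g) == 0 for g in groups):
        means = [g[0] for g in groups]
        if np.ptp(means) > 0:
            return np.inf, 0.0
        return 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f, p = stats.f_oneway(*groups)
    return float(f), float(p)


def tukey_hsd(groups, labels=None) -> pd.DataFrame:
    """Tukey HSD pairwise P-values (Tukey-Kramer for unequal n).

    Returns a symmetric DataFrame of P-values with NaN on the diagonal.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        groups = list(groups.values())
    groups = [np.asarray(g, float) for g in groups]
    if labels is None:
        labels = [f"g{i}" for i in range(len(groups))]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("Tukey HSD needs >= 2 groups with >= 2 values each")
    k = len(groups)
    P = np.full((k, k), np.nan)
    if all(np.ptp(g) == 0 for g in groups) and np.ptp([g[0] for g in groups]) == 0:
        P[~np.eye(k, dtype=bool)] = 1.0
    else:
        res = stats.tukey_hsd(*groups)
        pv = np.asarray(res.pvalue)
        P = pv.copy().astype(float)
        np.fill_diagonal(P, np.nan)
    return pd.DataFrame(P, index=labels, columns=labels)


@dataclass
class MovementReport:
    """Cross-period summary for one trait: per-period parameters plus tests."""

    trait: str
    per_period: pd.DataFrame
    center_shifts: pd.DataFrame
    anova: dict = field(default_factory=dict)
    tukey: dict = field(default_factory=dict)
    pvalue_label: str = "bootstrap-replicate ANOVA (pseudo-replication; see docs)"

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "per_period": self.per_period.to_dict(orient="records"),
            "center_shifts": self.center_shifts.to_dict(orient="records"),
            "anova": self.anova,
            "tukey": {k: v.to_dict() for k, v in self.tukey.items()},
            "pvalue_label": self.pvalue_label,
        }


def summarize_movement(boots: dict[str, BootstrapDistribution], alpha: float = 0.05) -> MovementReport:
    """Summarize zone movement for one trait across >= 1 periods.

    Builds the per-period center/width table (means and 95% percentile CIs),
    pairwise center shifts with CI-overlap flags, and — when at least two
    periods are present — ANOVA and Tukey tests on the bootstrap replicates
    for center and for width.  Periods whose width bootstrap is flagged
    unrealistic are excluded from the width comparison (their width CI is
    omitted in the summary).
    """
    periods = list(boots)
    trait = boots[periods[0]].trait
    rows = [boots[p].summary() for p in periods]
    per_period = pd.DataFrame(rows)

    shift_rows = []
    for a, b in combinations(periods, 2):
        ca, cb = boots[a], boots[b]
        lo_a, hi_a = ca.ci_center
        lo_b, hi_b = cb.ci_center
        shift_rows.append(
            {
                "from": a,
                "to": b,
                "shift_km": cb.mean_center - ca.mean_center,
                "ci_overlap": (lo_a <= hi_b) and (lo_b <= hi_a),
            }
        )
    center_shifts = pd.DataFrame(
        shift_rows, columns=["from", "to", "shift_km", "ci_overlap"]
    )

    anova: dict = {}
    tukey: dict = {}
    if len(periods) >= 2:
        center_groups = {p: boots[p].centers for p in periods}
        f, pval = anova_periods(center_groups)
        anova["center"] = {"F": f, "P": pval}
        tukey["center"] = tukey_hsd(center_groups)

        width_periods = [p for p in periods if not boots[p].width_ci_omitted]
        if len(width_periods) >= 2:
            width_groups = {p: boots[p].widths for p in width_periods}
            f, pval = anova_periods(width_groups)
            anova["width"] = {"F": f, "P": pval}
            tukey["width"] = tukey_hsd(width_groups)
    return MovementReport(
        trait=trait,
        per_period=per_period,
        center_shifts=center_shifts,
        anova=anova,
        tukey=tukey,
    )
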