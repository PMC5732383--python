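"""mtDNA haplotype summaries and hierarchical AMOVA.

Cytochrome-b haplotypes from two collection periods are compared for
spatial structure along the transect.  Individuals are grouped into
localities (specimens within 1 km) nested in three transect sectors, and
molecular variance is decomposed at three levels — among sectors, among
localities within sectors, within localities — following the standard
squared-distance AMOVA.  The associated fixation indices are

    F_CT = sigma2_a / sigma2_total          (among sectors)
    F_SC = sigma2_b / (sigma2_b + sigma2_c) (among localities within sectors)
    F_ST = (sigma2_a + sigma2_b) / sigma2_total

with significance from the conventional three permutation schemes.
Distances are raw pairwise nucleotide difference counts with pairwise
deletion of gaps/ambiguities.  Variance components may legitimately be
negative (they are method-of-moments estimates) and are reported as
computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import CoordinateError

__all__ = [
    "trim_to_region",
    "haplotype_summary",
    "pairwise_diff_matrix",
    "AmovaResult",
    "amova",
]


def trim_to_region(seqs: dict[str, str], start: int, end: int) -> dict[str, str]:
    """Cut every sequence to the 1-based inclusive region [start, end].

    Used to trim long recent sequences down to the short region recoverable
    from historical toepad samples, making periods comparable.
    """
    if start < 1 or end < start:
        raise CoordinateError(f"bad region [{start}, {end}]")
    out = {}
    for sid, s in seqs.items():
        if end > len(s):
            raise CoordinateError(
                f"region end {end} beyond length {len(s)} of sequence {sid}"
            )
        out[sid] = s[start - 1 : end]
    return out


def _encode(seqs) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Uppercase, check alignment, return ids, byte matrix and validity mask."""
    ids = list(seqs)
    if not ids:
        raise ValueError("empty alignment")
    lengths = {len(seqs[i]) for i in ids}
    if len(lengths) != 1:
        raise ValueError(f"sequences are not aligned: lengths {sorted(lengths)}")
    M = np.array([list(seqs[i].upper()) for i in ids], dtype="U1")
    valid = np.isin(M, list("ACGT"))
    return ids, M, valid


def haplotype_summary(seqs: dict[str, str]) -> dict:
    """Distinct haplotypes, segregating sites and mean uncorrected p-distance.

    Haplotypes are distinct sequence strings (after uppercasing); segregating
    sites are alignment columns with >= 2 observed unambiguous states; the
    p-distance between two sequences is the proportion of differing sites
    among those where both carry an unambiguous base (pairwise deletion).
    """
    ids, M, valid = _encode(seqs)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences")
    n_hap = len({seqs[i].upper() for i in ids})
    seg = 0
    for j in range(M.shape[1]):
        states = set(M[valid[:, j], j])
        if len(states) >= 2:
            seg += 1
    diffs, sites = _pairwise_counts(M, valid)
    iu = np.triu_indices(len(ids), k=1)
    with np.errstate(invalid="ignore"):
        pdist = diffs[iu] / sites[iu]
    mean_p = float(np.nanmean(pdist)) if np.isfinite(pdist).any() else np.nan
    return {
        "n_sequences": len(ids),
        "alignment_length": M.shape[1],
        "n_haplotypes": n_hap,
        "segregating_sites": seg,
        "mean_p_distance": mean_p,
    }


def _pairwise_counts(M, valid):
    n = M.shape[0]
    diffs = np.zeros((n, n))
    sites = np.zeros((n, n))
    for i in range(n):
        both = valid[i] & valid
        neq = (M[i] != M) & both
        diffs[i] = neq.sum(axis=1)
        sites[i] = both.sum(axis=1)
    return diffs, sites


def pairwise_diff_matrix(seqs: dict[str, str]) -> tuple[list[str], np.ndarray]:
    """Symmetric matrix of pairwise difference counts (pairwise deletion)."""
    ids, M, valid = _encode(seqs)
    if len(ids) < 2:
        raise ValueError("need >= 2 sequences")
    diffs, _ = _pairwise_counts(M, valid)
    np.fill_diagonal(diffs, 0.0)
    return ids, diffs


@dataclass
class AmovaResult:
    """Three-level AMOVA decomposition with permutation P-values."""

    sigma2_among_sectors: float
    sigma2_among_localities: float
    sigma2_within_localities: float
    f_ct: float
    f_sc: float
    f_st: float
    percent_variation: dict = field(default_factory=dict)
    p_values: dict = field(default_factory=dict)
    df: dict = field(default_factory=dict)
    n_permutations: int = 0
    monomorphic: bool = False

    def to_dict(self) -> dict:
        def clean(v):
            return None if v is None or (isinstance(v, float) and np.isnan(v)) else v

        return {
            "variance_components": {
                "among_sectors": clean(self.sigma2_among_sectors),
                "among_localities_within_sectors": clean(self.sigma2_among_localities),
                "within_localities": clean(self.sigma2_within_localities),
            },
            "percent_variation": {k: clean(v) for k, v in self.percent_variation.items()},
            "F_CT": clean(self.f_ct),
            "F_SC": clean(self.f_sc),
            "F_ST": clean(self.f_st),
            "P": {k: clean(v) for k, v in self.p_values.items()},
            "df": self.df,
            "n_permutations": self.n_permutations,
            "monomorphic": self.monomorphic,
        }


def _ssd(d2, members) -> float:
    """SSD of a set: sum of squared distances over pairs / set size."""
    idx = np.asarray(members)
    if idx.size == 0:
        return 0.0
    sub = d2[np.ix_(idx, idx)]
    return float(sub.sum() / (2.0 * idx.size))


def _components(d2, sectors, localities):
    """Variance components and F-statistics for one labelling.

    ``sectors``/``localities`` are integer label arrays over individuals;
    localities are globally unique (not nested codes).  Returns the component
    triple, F triple, and the degrees of freedom.
    """
    n_tot = len(sectors)
    all_idx = np.arange(n_tot)
    ssd_total = _ssd(d2, all_idx)

    sec_labels = np.unique(sectors)
    loc_labels = np.unique(localities)
    G = len(sec_labels)
    P = len(loc_labels)

    ssd_wp = 0.0
    loc_sizes = {}
    loc_sector = {}
    for l in loc_labels:
        idx = all_idx[localities == l]
        ssd_wp += _ssd(d2, idx)
        loc_sizes[l] = idx.size
        loc_sector[l] = sectors[idx[0]]
    ssd_groups = 0.0
    for g in sec_labels:
        ssd_groups += _ssd(d2, all_idx[sectors == g])
    ssd_ag = ssd_total - ssd_groups
    ssd_ap = ssd_groups - ssd_wp

    df_ag = G - 1
    df_ap = P - G
    df_wp = n_tot - P

    sizes_by_sector = {g: sum(v for l, v in loc_sizes.items() if loc_sector[l] == g)
                       for g in sec_labels}
    sum_np2_over_ng = sum(
        loc_sizes[l] ** 2 / sizes_by_sector[loc_sector[l]] for l in loc_labels
    )
    sum_np2 = sum(v**2 for v in loc_sizes.values())
    sum_ng2 = sum(v**2 for v in sizes_by_sector.values())

    sigma_c = ssd_wp / df_wp if df_wp > 0 else np.nan
    if df_ap > 0:
        n1 = (n_tot - sum_np2_over_ng) / df_ap
        sigma_b = (ssd_ap / df_ap - sigma_c) / n1
    else:
        sigma_b = np.nan
    n2 = (sum_np2_over_ng - sum_np2 / n_tot) / df_ag
    n3 = (n_tot - sum_ng2 / n_tot) / df_ag
    sb = 0.0 if not np.isfinite(sigma_b) else sigma_b
    sigma_a = (ssd_ag / df_ag - sigma_c - n2 * sb) / n3

    total = sigma_a + sb + sigma_c
    if total == 0 or not np.isfinite(total):
        f_ct = f_sc = f_st = np.nan
    else:
        f_ct = sigma_a / total
        f_st = (sigma_a + sb) / total
        f_sc = sigma_b / (sb + sigma_c) if np.isfinite(sigma_b) and (sb + sigma_c) != 0 else np.nan
    return (
        (sigma_a, sigma_b, sigma_c),
        (f_ct, f_sc, f_st),
        {"among_sectors": df_ag, "among_localities": df_ap, "within_localities": df_wp},
        (ssd_ag, ssd_ap, ssd_wp, ssd_total),
    )


def amova(
    dists: np.ndarray,
    sectors,
    localities,
    n_perm: int = 10_000,
    seed: int | None = None,
    statistics: tuple[str, ...] = ("F_CT", "F_SC", "F_ST"),
) -> AmovaResult:
    """Three-level AMOVA on a pairwise distance-count matrix.

    Parameters
    ----------
    dists : (n, n) array
        Pairwise difference counts (treated as squared distances).
    sectors, localities : array-like of labels per individual
        Localities need not be globally unique; they are nested within their
        sector internally.
    n_perm : int
        Permutations per statistic.  P-values use the standard scheme per
        statistic — F_ST: individuals permuted across all localities; F_SC:
        individuals permuted among localities within their sector; F_CT:
        whole localities permuted among sectors — and include the observed
        statistic in the null set, so P >= 1/(n_perm + 1).
    seed : int
        Required when ``n_perm > 0``.
    statistics : tuple of str
        Which F-statistics to attach permutation P-values to (all three by
        default; restricting saves two-thirds of the permutation work in
        large calibration experiments).
    """
    d2 = np.asarray(dists, float)
    sectors = np.asarray(sectors)
    localities = np.asarray(localities)
    if d2.shape[0] != d2.shape[1] or len(sectors) != d2.shape[0]:
        raise ValueError("distance matrix and label lengths disagree")
    sec_labels, sec_codes = np.unique(sectors, return_inverse=True)
    if len(sec_labels) < 2:
        raise ValueError("AMOVA needs >= 2 sectors")
    # nest localities within sectors -> globally unique integer codes
    pairs = np.array(list(zip(sec_codes, localities)), dtype=object)
    _, loc_codes = np.unique([f"{a}|{b}" for a, b in pairs], return_inverse=True)

    comps, fstats, df, _ = _components(d2, sec_codes, loc_codes)
    sigma_a, sigma_b, sigma_c = comps
    f_ct, f_sc, f_st = fstats

    total = np.nansum([sigma_a, sigma_b if np.isfinite(sigma_b) else 0.0, sigma_c])
    monomorphic = bool(np.allclose(d2, 0.0))
    if monomorphic:
        f_ct = f_sc = f_st = np.nan
    pct = {}
    if total != 0 and np.isfinite(total) and not monomorphic:
        pct = {
            "among_sectors": 100.0 * sigma_a / total,
            "among_localities_within_sectors": (
                100.0 * sigma_b / total if np.isfinite(sigma_b) else None
            ),
            "within_localities": 100.0 * sigma_c / total,
        }

    pvals: dict[str, float | None] = {"F_CT": None, "F_SC": None, "F_ST": None}
    if n_perm > 0 and not monomorphic:
        if seed is None:
            raise ValueError("a seed is required for permutation tests")
        rng = np.random.default_rng(seed)
        n = len(sec_codes)

        def pval(observed, draw):
            if not np.isfinite(observed):
                return None
            ge = 1  # include the observed draw
            for _ in range(n_perm):
                stat = draw()
                if np.isfinite(stat) and stat >= observed - 1e-12:
                    ge += 1
            return ge / (n_perm + 1)

        # F_ST: permute individuals across everything
        def draw_fst():
            perm = rng.permutation(n)
            return _components(d2, sec_codes[perm], loc_codes[perm])[1][2]

        # F_SC: permute individuals among localities within sectors
        def draw_fsc():
            perm = np.arange(n)
            for g in range(len(sec_labels)):
                idx = np.where(sec_codes == g)[0]
                perm[idx] = rng.permutation(idx)
            return _components(d2, sec_codes, loc_codes[perm])[1][1]

        # F_CT: permute whole localities among sectors (keep counts per sector)
        uniq_locs = np.unique(loc_codes)
        loc_sec = np.array(
            [sec_codes[loc_codes == l][0] for l in uniq_locs]
        )

        def draw_fct():
            shuffled = rng.permutation(loc_sec)
            new_sec = shuffled[np.searchsorted(uniq_locs, loc_codes)]
            return _components(d2, new_sec, loc_codes)[1][0]

        if "F_ST" in statistics:
            pvals["F_ST"] = pval(f_st, draw_fst)
        if "F_SC" in statistics:
            pvals["F_SC"] = pval(f_sc, draw_fsc)
        if "F_CT" in statistics:
            pvals["F_CT"] = pval(f_ct, draw_fct)

    return AmovaResult(
        sigma2_among_sectors=sigma_a,
        sigma2_among_localities=sigma_b,
        sigma2_within_localities=sigma_c,
        f_ct=f_ct,
        f_sc=f_sc,
        f_st=f_st,
        percent_variation=pct,
        p_values=pvals,
        df=df,
        n_permutations=n_perm,
        monomorphic=monomorphic,
    )
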