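"""Synthetic specimen, spectra and sequence data with known ground truth.

The real museum material behind this kind of study is not machine-readable,
so every pipeline stage is exercised against a generator that emulates its
statistical structure: three collection periods with uneven, opportunistic
sampling along a ~135 km transect; sigmoid (Hill) clines in a latent body
size and in a plumage mixing fraction whose centers shift a few km and
whose widths change between periods; yellow-to-red reflectance spectra
driven by transect position; and short mtDNA alignments whose sector-level
haplotype frequencies are structured in the historical period and
homogeneous in the recent one.  Default cline centers/widths are set to the
magnitudes reported for the study system (PC1 centers 67.67 / 73.85 / 76.69
km; chroma 72.92 / 73.04 / 76.33 km) — generator settings, not reproduced
results.  Every dataset is emitted together with its generating parameters.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cline import hill_predict
from .specimens import KM_PER_DEG, MORPH_COLUMNS, write_fasta

__all__ = [
    "steepness_for_width",
    "ClineTruth",
    "PeriodConfig",
    "HaplotypeModel",
    "SimulationConfig",
    "simulate_specimens",
    "simulate_spectra",
    "simulate_sequences",
    "simulate_alignment",
    "simulate_all",
    "yellow_template",
    "red_template",
]


def steepness_for_width(E: float, width: float) -> float:
    """Steepness B (< 0, increasing cline) giving the requested ED90 - ED10.

    Inverts ``width = E * (9**s - 9**(-s))`` with ``s = 1/|B|``.
    """
    if E <= 0 or width <= 0:
        raise ValueError("E and width must be > 0")
    r = width / E
    u = (r + math.sqrt(r * r + 4.0)) / 2.0  # u = 9**s
    s = math.log(u) / math.log(9.0)
    return -1.0 / s


@dataclass
class ClineTruth:
    """Generating Hill parameters plus derived center/width."""

    C: float
    D: float
    B: float
    E: float

    @property
    def center(self) -> float:
        return self.E

    @property
    def width(self) -> float:
        s = 1.0 / abs(self.B)
        return self.E * (9.0**s - 9.0**-s)

    def curve(self, x):
        return hill_predict((self.C, self.D, self.B, self.E), x)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["center_km"] = self.center
        d["width_km"] = self.width
        return d


def _cline(C, D, E, width) -> ClineTruth:
    return ClineTruth(C=C, D=D, B=steepness_for_width(E, width), E=E)


@dataclass
class PeriodConfig:
    """Stated sampling and cline conditions for one collection period."""

    n: int
    year_range: tuple[int, int]
    pc1: ClineTruth
    mix: ClineTruth  # plumage mixing fraction, plateaus in [0, 1]
    #: fraction of specimens drawn from a zone-center-biased component
    center_bias: float = 0.2
    center_bias_sd_km: float = 15.0
    #: master noise scale; 0 gives fully deterministic phenotypes
    noise_sd: float = 1.0

    def __post_init__(self):
        if self.n < 8:
            raise ValueError("need n >= 8 per period for a 4-parameter fit")


@dataclass
class HaplotypeModel:
    """Sector-level haplotype frequencies for one period's alignment."""

    length: int
    n_segregating: int
    #: (n_sectors, n_haplotypes) row-stochastic frequency matrix
    frequencies: np.ndarray
    #: 1-based region holding all segregating sites (the cross-period window)
    region: tuple[int, int] = (1, 210)

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, float)
        if not np.allclose(self.frequencies.sum(axis=1), 1.0):
            raise ValueError("haplotype frequency rows must sum to 1")
        start, end = self.region
        if not (1 <= start <= end <= self.length):
            raise ValueError("haplotype region outside the sequence length")
        if self.n_segregating > end - start + 1:
            raise ValueError("more segregating sites than region positions")


STRUCTURED_FREQS = np.array(
    [
        [0.70, 0.12, 0.08, 0.04, 0.03, 0.03],
        [0.25, 0.40, 0.15, 0.10, 0.05, 0.05],
        [0.06, 0.10, 0.54, 0.20, 0.05, 0.05],
    ]
)
UNSTRUCTURED_FREQS = np.tile([0.55, 0.15, 0.12, 0.08, 0.05, 0.05], (3, 1))


@dataclass
class SimulationConfig:
    """The stated world of the synthetic hybrid zone."""

    periods: dict[str, PeriodConfig]
    haplotypes: dict[str, HaplotypeModel]
    #: transect start (coast) and heading in the planar km frame
    start_lat: float = 3.88
    start_lon: float = -77.06
    heading_deg: float = -40.0  # degrees from east, negative = southward
    length_km: float = 135.0
    offset_sd_km: float = 1.2
    male_fraction: float = 0.62
    missing_morph_rate: float = 0.03
    spectrum_noise: float = 0.5
    mix_noise: float = 0.06
    seed: int = 20_100_731

    @classmethod
    def default(cls) -> "SimulationConfig":
        periods = {
            "P1911": PeriodConfig(
                n=40,
                year_range=(1894, 1911),
                pc1=_cline(-1.6, 1.6, 67.67, 41.75),
                mix=_cline(0.0, 1.0, 72.92, 31.48),
                center_bias=0.4,
            ),
            "P1956": PeriodConfig(
                n=60,
                year_range=(1956, 1986),
                pc1=_cline(-1.6, 1.6, 73.85, 21.97),
                mix=_cline(0.0, 1.0, 73.04, 32.37),
                center_bias=0.2,
            ),
            "P2010": PeriodConfig(
                n=65,
                year_range=(2007, 2010),
                pc1=_cline(-1.6, 1.6, 76.69, 33.12),
                mix=_cline(0.0, 1.0, 76.33, 6.71),
                center_bias=0.1,
            ),
        }
        haplotypes = {
            "P1956": HaplotypeModel(
                length=210, n_segregating=9, frequencies=STRUCTURED_FREQS,
                region=(1, 210),
            ),
            "P2010": HaplotypeModel(
                length=1008, n_segregating=9, frequencies=UNSTRUCTURED_FREQS,
                region=(401, 610),
            ),
        }
        return cls(periods=periods, haplotypes=haplotypes)

    # --- geometry helpers -------------------------------------------------
    def _direction(self):
        th = math.radians(self.heading_deg)
        return np.array([math.cos(th), math.sin(th)])

    def lonlat_at(self, distance_km, offset_km=0.0):
        """(lon, lat) of transect positions in the generator's frame."""
        d = self._direction()
        nvec = np.array([-d[1], d[0]])
        t = np.asarray(distance_km, float)
        o = np.asarray(offset_km, float)
        kx = KM_PER_DEG * math.cos(math.radians(self.start_lat))
        x = t * d[0] + o * nvec[0]
        y = t * d[1] + o * nvec[1]
        return np.column_stack(
            [self.start_lon + x / kx, self.start_lat + y / KM_PER_DEG]
        )

    def truth(self) -> dict:
        """Serializable ground truth for the configured world."""
        return {
            "seed": self.seed,
            "length_km": self.length_km,
            "periods": {
                name: {
                    "n": pc.n,
                    "year_range": list(pc.year_range),
                    "pc1": pc.pc1.to_dict(),
                    "mix": pc.mix.to_dict(),
                    "noise_sd": pc.noise_sd,
                }
                for name, pc in self.periods.items()
            },
            "haplotypes": {
                name: {
                    "length": hm.length,
                    "n_segregating": hm.n_segregating,
                    "region": list(hm.region),
                    "frequencies": hm.frequencies.tolist(),
                }
                for name, hm in self.haplotypes.items()
            },
        }


#: morph character construction: intercept, loading on the latent size trait,
#: and residual sd (mm).  Wing and tail carry the size signal, as in the
#: study system; bill dimensions are nearly size-free.
_MORPH_MODEL = {
    "wing_mm": (68.0, 1.25, 1.10),
    "culmen_mm": (16.0, 0.12, 0.60),
    "bill_depth_mm": (8.0, 0.06, 0.35),
    "bill_width_mm": (7.0, 0.05, 0.32),
    "tail_mm": (72.0, 1.35, 1.10),
    "tarsus_mm": (19.0, 0.25, 0.70),
}


def simulate_specimens(
    config: SimulationConfig | None = None, seed: int | None = None
) -> tuple[pd.DataFrame, dict]:
    """Generate the specimen table and its ground truth.

    Distances are drawn from a uniform/center-biased mixture per period,
    perpendicular scatter is Gaussian, and the six morph characters are
    affine in the latent size cline plus noise, so that a correlation-matrix
    PCA recovers the size axis as PC1.  With ``noise_sd = 0`` phenotypes are
    deterministic functions of position and refitting recovers the generating
    cline exactly.
    """
    config = config or SimulationConfig.default()
    master = config.seed if seed is None else seed
    rows = []
    latent = []
    for p_idx, (period, pc) in enumerate(sorted(config.periods.items())):
        rng = np.random.default_rng([master, 101, p_idx])
        n = pc.n
        n_bias = rng.binomial(n, pc.center_bias)
        d_uni = rng.uniform(1.0, config.length_km - 1.0, n - n_bias)
        d_bias = rng.normal(pc.pc1.E, pc.center_bias_sd_km, n_bias)
        dist = np.clip(np.concatenate([d_uni, d_bias]), 1.0, config.length_km - 1.0)
        dist.sort()
        offset = rng.normal(0.0, config.offset_sd_km, n)
        lonlat = config.lonlat_at(dist, offset)
        years = rng.integers(pc.year_range[0], pc.year_range[1] + 1, n)
        sex = np.where(rng.random(n) < config.male_fraction, "male", "female")

        s = pc.pc1.curve(dist)
        t_mix = np.clip(
            pc.mix.curve(dist) + pc.noise_sd * config.mix_noise * rng.normal(size=n),
            0.0,
            1.0,
        )
        for i in range(n):
            sid = f"{period}-{i + 1:03d}"
            row = {
                "id": sid,
                "latitude": lonlat[i, 1],
                "longitude": lonlat[i, 0],
                "year": int(years[i]),
                "sex": sex[i],
                "spectrum_id": sid,
                "sequence_id": sid if period in config.haplotypes else np.nan,
            }
            for col, (b0, b1, sd) in _MORPH_MODEL.items():
                row[col] = b0 + b1 * s[i] + pc.noise_sd * sd * rng.normal()
            rows.append(row)
            latent.append(
                {
                    "id": sid,
                    "period": period,
                    "true_distance_km": dist[i],
                    "true_offset_km": offset[i],
                    "latent_size": s[i],
                    "mix_fraction": t_mix[i],
                }
            )
        # knock out occasional measurements
        if config.missing_morph_rate > 0:
            miss = rng.random(n) < config.missing_morph_rate
            which = rng.integers(0, len(MORPH_COLUMNS), n)
            base = len(rows) - n
            for i in np.where(miss)[0]:
                rows[base + i][MORPH_COLUMNS[which[i]]] = np.nan

    df = pd.DataFrame(rows)
    truth = config.truth()
    truth["specimens"] = latent
    return df, truth


# ---------------------------------------------------------------------------
# Reflectance spectra
# ---------------------------------------------------------------------------

_GRID = np.arange(400, 701, 2)  # written grid; metrics re-interpolate anyway


def yellow_template(w=_GRID):
    """Yellowish rump: broad, mildly tilted reflectance (low chroma)."""
    w = np.asarray(w, float)
    return 30.0 + 10.0 / (1.0 + np.exp(-(w - 540.0) / 20.0))


def _red_raw(w):
    return 3.0 + 62.0 / (1.0 + np.exp(-(w - 622.0) / 7.0))


# normalize the red template to the yellow template's total reflectance:
# segment fractions (hence chroma) of a t-mixture are then affine in t, so
# the chroma cline inherits the mixing cline's center almost exactly
_GRID_1NM = np.arange(400, 700)
_RED_SCALE = yellow_template(_GRID_1NM).sum() / _red_raw(_GRID_1NM).sum()


def red_template(w=_GRID):
    """Scarlet rump: reflectance concentrated beyond ~620 nm (high chroma)."""
    w = np.asarray(w, float)
    return _RED_SCALE * _red_raw(w)


def simulate_spectra(
    truth_specimens: list[dict] | pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Wide spectra table: one column per specimen, mixing red into yellow.

    Each spectrum is ``t * red + (1 - t) * yellow`` plus measurement noise,
    with t the specimen's latent mixing fraction, so chroma increases toward
    the scarlet (inland) end of the transect.
    """
    config = config or SimulationConfig.default()
    master = config.seed if seed is None else seed
    rng = np.random.default_rng([master, 202])
    if isinstance(truth_specimens, pd.DataFrame):
        recs = truth_specimens.to_dict(orient="records")
    else:
        recs = truth_specimens
    out = {"wavelength_nm": _GRID}
    yel = yellow_template()
    red = red_template()
    for rec in recs:
        t = float(rec["mix_fraction"])
        noise = config.spectrum_noise * rng.normal(size=_GRID.size)
        out[rec["id"]] = np.clip(t * red + (1.0 - t) * yel + noise, 0.0, None)
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# Haplotype alignments
# ---------------------------------------------------------------------------

_ALT = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _haplotype_pool(length, k_sites, n_hap, region, rng):
    """Reference plus n_hap haplotypes differing at k sites within region."""
    if k_sites < n_hap - 1:
        raise ValueError("need at least n_haplotypes - 1 segregating sites")
    ref = rng.choice(list("ACGT"), size=length)
    start, end = region
    sites = np.sort(rng.choice(np.arange(start - 1, end), size=k_sites, replace=False))
    # partition sites among the non-reference haplotypes
    blocks = np.array_split(sites, n_hap - 1)
    haps = [ref.copy()]
    for block in blocks:
        h = ref.copy()
        for s in block:
            h[s] = _ALT[h[s]]
        haps.append(h)
    return ["".join(h) for h in haps[:n_hap]]


def simulate_alignment(
    frequencies,
    length: int = 210,
    n_segregating: int = 9,
    localities_per_sector: int = 4,
    n_per_locality: int = 5,
    region: tuple[int, int] | None = None,
    seed: int = 0,
    prefix: str = "seq",
):
    """Standalone alignment with explicit sector/locality labels.

    ``frequencies`` is a (n_sectors, n_haplotypes) matrix; individuals in a
    sector draw haplotypes i.i.d. from its row.  Returns (seqs, labels) where
    labels is a DataFrame with id, sector, locality columns — ready for
    :func:`hybridcline.popgen.amova` calibration experiments.
    """
    freqs = np.asarray(frequencies, float)
    rng = np.random.default_rng(seed)
    region = region or (1, length)
    pool = _haplotype_pool(length, n_segregating, freqs.shape[1], region, rng)
    seqs: dict[str, str] = {}
    labels = []
    i = 0
    for sec in range(freqs.shape[0]):
        for loc in range(localities_per_sector):
            for _ in range(n_per_locality):
                i += 1
                sid = f"{prefix}{i:03d}"
                h = rng.choice(len(pool), p=freqs[sec])
                seqs[sid] = pool[h]
                labels.append({"id": sid, "sector": sec + 1, "locality": loc + 1})
    return seqs, pd.DataFrame(labels)


def simulate_sequences(
    specimens: pd.DataFrame,
    config: SimulationConfig | None = None,
    seed: int | None = None,
    sector_bounds=(45.0, 90.0, 135.0),
) -> dict[str, dict[str, str]]:
    """Per-period FASTA alignments for specimens carrying a sequence_id.

    Specimens are assigned to sectors from their generating distance (columns
    ``true_distance_km`` if present, else recomputed from coordinates is the
    caller's job) and draw haplotypes from their sector's frequency vector.
    """
    config = config or SimulationConfig.default()
    master = config.seed if seed is None else seed
    out: dict[str, dict[str, str]] = {}
    for p_idx, (period, model) in enumerate(sorted(config.haplotypes.items())):
        rng = np.random.default_rng([master, 303, p_idx])
        pool = _haplotype_pool(
            model.length,
            model.n_segregating,
            model.frequencies.shape[1],
            model.region,
            rng,
        )
        sub = specimens[
            specimens["id"].str.startswith(period) & specimens["sequence_id"].notna()
        ]
        seqs: dict[str, str] = {}
        for _, row in sub.iterrows():
            d = float(row["true_distance_km"])
            sec = int(np.searchsorted(sector_bounds, d, side="right"))
            sec = min(sec, model.frequencies.shape[0] - 1)
            h = rng.choice(len(pool), p=model.frequencies[sec])
            seqs[str(row["id"])] = pool[h]
        out[period] = seqs
    return out


def simulate_all(
    config: SimulationConfig | None = None,
    out_dir=None,
    seed: int | None = None,
) -> dict:
    """Generate the full dataset bundle; optionally write it to ``out_dir``.

    Returns {"specimens": DataFrame, "spectra": DataFrame, "sequences":
    {period: seqs}, "truth": dict}.  Writing is deterministic: the same seed
    produces byte-identical files.
    """
    config = config or SimulationConfig.default()
    master = config.seed if seed is None else seed
    specimens, truth = simulate_specimens(config, master)
    truth_rows = pd.DataFrame(truth["specimens"])
    spec_with_truth = specimens.merge(truth_rows, on="id")
    spectra = simulate_spectra(truth["specimens"], config, master)
    sequences = simulate_sequences(spec_with_truth, config, master)
    bundle = {
        "specimens": specimens,
        "spectra": spectra,
        "sequences": sequences,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        specimens.to_csv(out / "specimens.csv", index=False)
        spectra.to_csv(out / "spectra.csv", index=False)
        for period, seqs in sequences.items():
            write_fasta(seqs, out / f"seqs_{period}.fasta")
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return bundle
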