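"""End-to-end orchestration: inputs -> transect -> phenotypes -> clines ->
bootstrap -> period comparisons -> AMOVA -> diffusion report.

A run is configured by a :class:`RunConfig` (loadable from YAML), executes
stages in dependency order, and writes text-only outputs (CSV/JSON) plus a
manifest recording input hashes, seeds and the package version, so reruns
with the same seeds are byte-identical and diffable.  A stage failure stops
the run but leaves completed stage outputs in place and names the failed
stage.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import PipelineError
from .cline import fit_cline
from .diffusion import DiffusionScenario, width_envelope
from .phenotypes import attach_phenotypes, compute_pca, read_spectra, segment_metrics_table
from .popgen import amova, pairwise_diff_matrix, trim_to_region
from .simulate import SimulationConfig, simulate_all
from .specimens import (
    DEFAULT_SECTOR_BOUNDS,
    SpecimenTable,
    build_positions,
    read_fasta,
    read_specimen_table,
)
from .uncertainty import bootstrap_cline, summarize_movement

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Configuration for one pipeline run (all paths or simulation)."""

    out_dir: str = "results"
    #: run on simulated data when no specimen table is given
    specimens: str | None = None
    spectra: str | None = None
    sequences: dict[str, str] = field(default_factory=dict)  # period -> FASTA
    simulate: bool = True
    sector_bounds: tuple = DEFAULT_SECTOR_BOUNDS
    locality_radius_km: float = 1.0
    traits: tuple = ("pc1", "chroma")
    sex: str = "male"
    bootstrap_reps: int = 1000
    bootstrap_bounds: tuple = (0.0, 140.0)
    x_offset: float = 0.1
    amova_permutations: int = 10_000
    #: 1-based common region per period for cross-period comparability
    #: (default matches the simulator: trim long 2010 sequences to the 210-bp
    #: window recoverable from the historical material)
    amova_region: dict = field(default_factory=lambda: {"P2010": (401, 610)})
    diffusion: DiffusionScenario = field(default_factory=DiffusionScenario)
    seed: int = 17

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "diffusion" in raw:
            d = raw["diffusion"]
            raw["diffusion"] = DiffusionScenario(
                sigma_km=tuple(d.get("sigma_km", (1.0, 20.0))),
                generation_time_years=tuple(d.get("generation_time_years", (1.0, 2.0))),
                age_years=d.get("age_years", 6000.0),
            )
        for key in ("sector_bounds", "bootstrap_bounds", "traits"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _dump_json(obj, path: Path):
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(type(o))

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis; returns the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        # out_dir is deliberately excluded: two runs of the same analysis
        # into different directories must produce byte-identical bundles
        "config": {
            k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
            for k, v in asdict(config).items()
            if k != "out_dir"
        },
        "stages": [],
        "inputs": {},
        "outputs": {},
        "skipped": [],
    }
    state: dict = {}

    def stage(name):
        def deco(fn):
            try:
                fn()
            except Exception as exc:  # noqa: BLE001 - reported via PipelineError
                manifest["failed_stage"] = {"stage": name, "error": str(exc)}
                _dump_json(manifest, out / "manifest.json")
                raise PipelineError(name, exc) from exc
            manifest["stages"].append(name)
            return fn

        return deco

    @stage("inputs")
    def _inputs():
        if config.specimens is None:
            if not config.simulate:
                raise ValueError("no specimen table and simulate=False")
            sim_dir = out / "simulated"
            bundle = simulate_all(SimulationConfig.default(), sim_dir, config.seed)
            state["table"] = SpecimenTable(records=bundle["specimens"])
            state["spectra"] = bundle["spectra"]
            state["sequences"] = bundle["sequences"]
            for f in sorted(sim_dir.iterdir()):
                manifest["inputs"][f"simulated/{f.name}"] = _sha256(f)
        else:
            manifest["inputs"][config.specimens] = _sha256(Path(config.specimens))
            state["table"] = read_specimen_table(config.specimens)
            if config.spectra:
                manifest["inputs"][config.spectra] = _sha256(Path(config.spectra))
                state["spectra"] = read_spectra(config.spectra)
            else:
                state["spectra"] = None
            state["sequences"] = {}
            for period, path in (config.sequences or {}).items():
                manifest["inputs"][path] = _sha256(Path(path))
                state["sequences"][period] = read_fasta(path)

    @stage("transect")
    def _transect():
        positions, transect = build_positions(
            state["table"],
            sector_bounds=config.sector_bounds,
            locality_radius_km=config.locality_radius_km,
        )
        state["positions"] = positions
        state["transect"] = transect
        cols = [
            "id",
            "distance_km",
            "offset_km",
            "sector",
            "locality_id",
            "period",
        ]
        positions[cols].to_csv(out / "positions.csv", index=False)
        manifest["outputs"]["positions.csv"] = _sha256(out / "positions.csv")
        manifest["transect"] = {
            "slope": transect.slope_,
            "intercept": transect.intercept_,
            "origin_lonlat": transect.origin_lonlat_.tolist(),
            "length_km": transect.length_km_,
        }

    @stage("phenotypes")
    def _phenotypes():
        pos = state["positions"]
        pca = compute_pca(pos, sex=config.sex)
        pca.scores.to_csv(out / f"pca_{config.sex}.csv")
        manifest["pca"] = {
            "sex": config.sex,
            "explained_variance_ratio": pca.explained_variance_ratio.tolist(),
        }
        colors = None
        if state.get("spectra") is not None:
            colors = segment_metrics_table(state["spectra"])
            colors.to_csv(out / "colors.csv")
        else:
            manifest["skipped"].append(
                {"stage": "phenotypes", "what": "color metrics", "reason": "no spectra input"}
            )
        table, warn = attach_phenotypes(pos, pca, colors)
        if warn:
            manifest.setdefault("warnings", []).extend(warn)
        state["analysis"] = table
        keep = [
            "id",
            "distance_km",
            "sector",
            "locality_id",
            "period",
            "sex",
            "pc1",
            "brightness",
            "chroma",
            "hue",
        ]
        table[[c for c in keep if c in table.columns]].to_csv(
            out / "analysis_table.csv", index=False
        )
        manifest["outputs"]["analysis_table.csv"] = _sha256(out / "analysis_table.csv")

    @stage("clines")
    def _clines():
        table = state["analysis"]
        fits = []
        boots: dict[str, dict] = {}
        for trait in config.traits:
            if trait not in table.columns or table[trait].notna().sum() == 0:
                manifest["skipped"].append(
                    {"stage": "clines", "what": trait, "reason": "no data for trait"}
                )
                continue
            sub_all = table if trait != "pc1" else table[table["sex"] == config.sex]
            boots[trait] = {}
            for period in ("P1911", "P1956", "P2010"):
                sub = sub_all[(sub_all["period"] == period) & sub_all[trait].notna()]
                if len(sub) < 8:
                    manifest["skipped"].append(
                        {
                            "stage": "clines",
                            "what": f"{trait}/{period}",
                            "reason": f"n={len(sub)} < 8",
                        }
                    )
                    continue
                x = sub["distance_km"].to_numpy(float)
                y = sub[trait].to_numpy(float)
                fit = fit_cline(
                    x, y, trait=trait, period=period, x_offset=config.x_offset
                )
                fits.append(fit.to_dict())
                bt = bootstrap_cline(
                    x,
                    y,
                    reps=config.bootstrap_reps,
                    bounds=config.bootstrap_bounds,
                    seed=config.seed,
                    trait=trait,
                    period=period,
                    x_offset=config.x_offset,
                )
                boots[trait][period] = bt
                bt.to_frame().to_csv(
                    out / f"bootstrap_{trait}_{period}.csv", index=False
                )
        _dump_json(fits, out / "fits.json")
        manifest["outputs"]["fits.json"] = _sha256(out / "fits.json")
        state["boots"] = boots

    @stage("compare")
    def _compare():
        reports = {}
        for trait, per_period in state["boots"].items():
            if per_period:
                reports[trait] = summarize_movement(per_period).to_dict()
        _dump_json(reports, out / "comparison.json")
        manifest["outputs"]["comparison.json"] = _sha256(out / "comparison.json")

    @stage("amova")
    def _amova():
        results = {}
        pos = state["positions"].set_index("id")
        for period, seqs in (state.get("sequences") or {}).items():
            if not seqs:
                continue
            region = config.amova_region.get(period)
            if region is not None:
                lens = {len(s) for s in seqs.values()}
                if max(lens) >= region[1]:
                    seqs = trim_to_region(seqs, *region)
            ids = [
                i
                for i in seqs
                if i in pos.index
                and pd.notna(pos.at[i, "sector"])
                and pd.notna(pos.at[i, "locality_id"])
            ]
            if len(ids) < 4:
                manifest["skipped"].append(
                    {"stage": "amova", "what": period, "reason": "too few labelled sequences"}
                )
                continue
            sub = {i: seqs[i] for i in ids}
            mat_ids, d = pairwise_diff_matrix(sub)
            sectors = pos.loc[mat_ids, "sector"].astype(int).to_numpy()
            locs = pos.loc[mat_ids, "locality_id"].astype(int).to_numpy()
            res = amova(
                d,
                sectors,
                locs,
                n_perm=config.amova_permutations,
                seed=config.seed,
            )
            results[period] = res.to_dict()
        _dump_json(results, out / "amova.json")
        manifest["outputs"]["amova.json"] = _sha256(out / "amova.json")

    @stage("diffusion")
    def _diffusion():
        report = width_envelope(config.diffusion)
        fitted = {
            trait: {
                period: bt.mean_width for period, bt in per_period.items()
            }
            for trait, per_period in state["boots"].items()
        }
        report["fitted_mean_widths_km"] = fitted
        report["narrower_than_neutral"] = {
            trait: {
                period: w < report["min_km"] for period, w in widths.items()
            }
            for trait, widths in fitted.items()
        }
        _dump_json(report, out / "diffusion.json")
        manifest["outputs"]["diffusion.json"] = _sha256(out / "diffusion.json")

    _dump_json(manifest, out / "manifest.json")
    return manifest
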