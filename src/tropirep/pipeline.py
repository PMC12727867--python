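"""End-to-end pipeline: literature table + covariates -> representativeness.

Stage order mirrors the analysis workflow: (optional) synthetic inputs ->
read & habitat-filter the literature database -> build the buffered domain
and assign biomes -> background sample & point extraction -> biome summary
and density grids -> environmental-space histograms -> pseudo-absence
ensemble model, probability map, coverage -> cross-validated AUC.  A manifest
records every parameter and derived seed needed to reproduce a run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from . import envspace, geodomain, litdb, raster, represent, synthetic

log = logging.getLogger("tropirep")

__all__ = ["PipelineConfig", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """Declarative configuration of a pipeline run.

    Either ``synthetic=True`` (inputs are generated and written into
    ``outdir/inputs``) or the three input paths must point at existing files.
    Defaults mirror the analysis constants: 100 km buffer, background
    n = 100,000 (scaled by ``background_n``), collinearity threshold 0.70,
    coverage threshold 0.5, 99 permutations at a 70/30 split.
    """

    outdir: str = "tropirep_out"
    seed: int = 0
    synthetic: bool = True
    synthetic_config: dict = field(default_factory=dict)
    n_biomes: int = 5
    literature_path: str | None = None
    biome_path: str | None = None
    stack_manifest: str | None = None
    buffer_km: float = 100.0
    excluded_habitats: tuple[str, ...] = ("urban", "agricultural")
    background_n: int = 100_000
    n_bins: int = 50
    pairs: tuple[tuple[str, str], ...] = envspace.DEFAULT_PAIRS
    cell_deg: float = 3.0
    collinearity_threshold: float = 0.70
    coverage_threshold: float = 0.5
    model_params: dict = field(default_factory=dict)
    n_perm: int = 99
    train_frac: float = 0.7
    log_level: str = "INFO"

    def validate_paths(self) -> None:
        if self.synthetic:
            return
        for label, p in (
            ("literature_path", self.literature_path),
            ("biome_path", self.biome_path),
            ("stack_manifest", self.stack_manifest),
        ):
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"{label} does not exist: {p!r}")


def load_config(path) -> PipelineConfig:
    import yaml

    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "pairs" in raw:
        raw["pairs"] = tuple(tuple(p) for p in raw["pairs"])
    if "excluded_habitats" in raw:
        raw["excluded_habitats"] = tuple(raw["excluded_habitats"])
    return PipelineConfig(**raw)


def _json_dump(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns a result bundle of in-memory objects.

    Writes: biome summary CSV, density grids, environmental-space histogram
    JSONs, probability map, coverage + CV JSON, filter/clip reports and a run
    manifest.  Any stage error propagates annotated with the stage name.
    """
    logging.basicConfig(level=config.log_level)
    config.validate_paths()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = {
        name: int(s.generate_state(1)[0] % (2**31))
        for name, s in zip(
            ("background", "pseudo_absence", "model", "cv"),
            np.random.SeedSequence(config.seed).spawn(4),
        )
    }
    manifest: dict[str, Any] = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "derived_seeds": seeds,
        "stages": [],
        "outputs": {},
    }

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"].append(name)

    try:
        # -- inputs ---------------------------------------------------------
        if config.synthetic:
            stage("synth")
            syn = synthetic.SyntheticConfig(
                seed=config.seed, **config.synthetic_config
            )
            stack = synthetic.gen_stack(syn)
            biomes = synthetic.gen_biomes(stack, config.n_biomes, seed=config.seed)
            lit, truth = synthetic.gen_literature(stack, syn)
            inputs = outdir / "inputs"
            inputs.mkdir(exist_ok=True)
            raster.write_stack(stack, inputs)
            geodomain.write_biome_layer(biomes, inputs / "biomes.geojson")
            litdb.write_literature_csv(lit, inputs / "literature.csv")
            _json_dump(truth, inputs / "truth.json")
            lit = litdb.read_literature_table(inputs / "literature.csv")
        else:
            stage("read")
            lit = litdb.read_literature_table(config.literature_path)
            biomes = geodomain.read_biome_layer(config.biome_path)
            stack = raster.read_stack(config.stack_manifest)

        # -- domain & clip before the habitat filter (analysis order) -------
        stage("domain")
        domain = geodomain.build_domain(biomes, buffer_km=config.buffer_km)
        lit, clip = geodomain.assign_locations(lit, biomes, domain)

        stage("filter")
        lit, filt = litdb.filter_natural_habitats(lit, config.excluded_habitats)
        counts = litdb.summarize_counts(lit)
        _json_dump(
            {
                "clip": clip._asdict(),
                "habitat_filter": filt.to_dict(),
                "final_counts": counts._asdict(),
            },
            outdir / "filter_report.json",
        )

        # -- summaries ------------------------------------------------------
        stage("summarize")
        areas = geodomain.biome_areas(biomes, domain)
        summary = geodomain.biome_summary(lit, areas)
        summary.to_csv(outdir / "biome_summary.csv", float_format="%.6f")
        for weight in ("locations", "citations"):
            dens, cnt = geodomain.grid_density(
                lit, domain, cell_deg=config.cell_deg, weight=weight
            )
            raster.write_ascii_grid(dens, outdir / f"density_{weight}.asc")

        # -- extraction & environmental space -------------------------------
        stage("extract")
        background = raster.sample_background(
            stack, n=config.background_n, seed=seeds["background"]
        )
        loc_cov = raster.extract_at_points(
            stack, lit.locations["longitude"], lit.locations["latitude"]
        )
        loc_cov["allocated_citations"] = lit.locations[
            "allocated_citations"
        ].to_numpy()

        stage("envspace")
        histograms = envspace.env_space_comparison(
            background, loc_cov, pairs=config.pairs, n_bins=config.n_bins
        )
        for (xn, yn), triple in histograms.items():
            for kind, hist in triple.items():
                hist.to_json(outdir / f"hist_{xn}_{yn}_{kind}.json")

        # -- representativeness model ---------------------------------------
        stage("represent")
        pa = represent.make_pseudo_absences(
            stack,
            lit.locations["longitude"],
            lit.locations["latitude"],
            seed=seeds["pseudo_absence"],
        )
        screen = represent.CollinearityFilter(config.collinearity_threshold)
        X = screen.fit_transform(pa.X)
        model = represent.SamplingEnsemble(
            random_state=seeds["model"], **config.model_params
        )
        model.fit(X, pa.y)
        prob = represent.predict_map(model, stack, covariates=screen.retained_)
        raster.write_ascii_grid(prob, outdir / "probability.asc")
        fraction, covered_km2 = represent.coverage_area(
            prob, threshold=config.coverage_threshold
        )

        stage("crossval")
        screened = represent.PresenceAbsenceTable(
            pa.frame, tuple(screen.retained_)
        )
        cv = represent.cross_validate(
            screened,
            represent.SamplingEnsemble(
                random_state=seeds["model"], **config.model_params
            ),
            n_perm=config.n_perm,
            train_frac=config.train_frac,
            seed=seeds["cv"],
        )
        _json_dump(
            {
                "screen": screen.report(),
                "coverage": {
                    "threshold": config.coverage_threshold,
                    "covered_fraction": fraction,
                    "covered_area_km2": covered_km2,
                },
                "cross_validation": cv.to_dict(),
            },
            outdir / "model_report.json",
        )
    except Exception as exc:
        failed = manifest["stages"][-1] if manifest["stages"] else "startup"
        manifest["failed_stage"] = failed
        _json_dump(manifest, outdir / "manifest.json")
        raise RuntimeError(f"pipeline stage {failed!r} failed: {exc}") from exc

    manifest["outputs"] = {
        "biome_summary": "biome_summary.csv",
        "filter_report": "filter_report.json",
        "density_grids": ["density_locations.asc", "density_citations.asc"],
        "histograms": sorted(p.name for p in outdir.glob("hist_*.json")),
        "probability_map": "probability.asc",
        "model_report": "model_report.json",
    }
    _json_dump(manifest, outdir / "manifest.json")
    return {
        "literature": lit,
        "domain": domain,
        "summary": summary,
        "histograms": histograms,
        "model": model,
        "screen": screen,
        "probability": prob,
        "coverage": (fraction, covered_km2),
        "cv": cv,
        "counts": counts,
        "clip": clip,
        "manifest": manifest,
    }
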