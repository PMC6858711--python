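"""End-to-end pipeline driver: simulate/detect -> profile -> score -> associate.

A :class:`PipelineConfig` holds every numeric parameter that affects any
number in the results; :func:`run_pipeline` executes the enabled stages,
writes all tabular outputs, and records a manifest (package version,
parameters, seeds, SHA-256 checksum per output file) so a run is fully
reproducible from its config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .association import (cohort_summary, derive_endpoints,
                          fit_response_model, fit_survival_model, km_estimate)
from .cohort import CohortConfig, generate_cohort
from .detection import FieldSpec, PixelClassParams, classify_pixels, detect_cells
from .errors import ConfigError
from .io import write_cells, write_cohort, write_geometry, write_image
from .scoring import score_fractions
from .spatial import band_histogram, compartment_densities, plot_profile
from .synthetic import SceneConfig, generate_tissue_scene, render_ihc_image


@dataclass(frozen=True)
class PipelineConfig:
    """Flat configuration for a full run.  Unknown keys are rejected."""

    # stage toggles
    do_render_detect: bool = False
    do_cohort: bool = True
    make_plots: bool = False
    # scene / rendering
    scene: SceneConfig = field(default_factory=SceneConfig)
    um_per_pixel: float = 0.5
    nucleus_radius_um: float = 3.0
    positive_radius_um: float = 4.0
    noise_sd: float = 0.0
    detection: PixelClassParams = field(default_factory=PixelClassParams)
    slide_marker: str = "CD8"
    field_spec: FieldSpec = field(default_factory=FieldSpec)
    # profiling
    band_width_um: float = 20.0
    extent_um: float = 100.0
    peritumoral_extent_um: float = 500.0
    # cohort / association
    cohort: CohortConfig = field(default_factory=CohortConfig)
    biomarker_term: str = "group"

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        kwargs = {}
        for name, sub_cls in (("scene", SceneConfig),
                              ("detection", PixelClassParams),
                              ("field_spec", FieldSpec),
                              ("cohort", CohortConfig)):
            if name in data:
                sub = data.pop(name)
                if not isinstance(sub, dict):
                    raise ConfigError(f"{name} must be a mapping")
                known = {f.name for f in dataclasses.fields(sub_cls)}
                unknown = set(sub) - known
                if unknown:
                    raise ConfigError(
                        f"unknown {name} keys: {sorted(unknown)}")
                kwargs[name] = sub_cls(**sub)
        known = {f.name for f in dataclasses.fields(cls) if f.init}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**kwargs, **data)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the enabled stages; return the manifest (also written to disk)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []
    log: list[str] = []

    # -- scene -------------------------------------------------------------
    scene = generate_tissue_scene(config.scene)
    log.append(f"simulate: {len(scene.cells)} cells")
    write_cells(scene.cells, outdir / "cells.csv")
    write_geometry(scene.geometry, outdir / "margin.wkt")
    outputs += [outdir / "cells.csv", outdir / "margin.wkt"]

    cells = scene.cells
    if config.do_render_detect:
        render = render_ihc_image(scene, config.um_per_pixel,
                                  config.nucleus_radius_um,
                                  config.positive_radius_um,
                                  config.noise_sd)
        write_image(render.image, outdir / "slide.tif", render.um_per_pixel)
        outputs += [outdir / "slide.tif",
                    outdir / "slide.tif.json"]
        mask = classify_pixels(render.image, render.um_per_pixel,
                               config.detection)
        cells = detect_cells(mask, render.um_per_pixel, config.detection,
                             marker=config.slide_marker)
        log.append(f"detect: {len(cells)} cells from "
                   f"{len(scene.cells)} simulated")
        write_cells(cells, outdir / "cells_detected.csv")
        outputs.append(outdir / "cells_detected.csv")

    # -- spatial profile ---------------------------------------------------
    profile = band_histogram(cells, scene.geometry, config.band_width_um,
                             config.extent_um)
    profile.to_frame().to_csv(outdir / "profile.csv", index=False)
    outputs.append(outdir / "profile.csv")
    log.append(f"profile: {int(profile.counts.to_numpy().sum())} cells in "
               f"bands, {profile.n_excluded} excluded")
    if config.make_plots:
        plot_profile(profile, str(outdir / "profile.png"))
        outputs.append(outdir / "profile.png")

    comp = compartment_densities(cells, scene.geometry,
                                 config.peritumoral_extent_um)
    comp_rows = []
    for compartment in comp.counts.index:
        for marker in comp.counts.columns:
            frac = comp.fraction(marker, compartment)
            score = float(score_fractions([frac])[0])
            comp_rows.append({
                "compartment": compartment, "marker": marker,
                "count": int(comp.counts.loc[compartment, marker]),
                "area_mm2": comp.areas_mm2[compartment],
                "density_per_mm2": comp.density(marker, compartment),
                "positive_fraction_pct": frac,
                "score": score,
                "dichot": "high" if score >= 2 else "low",
            })
    pd.DataFrame(comp_rows).to_csv(outdir / "compartments.csv", index=False)
    outputs.append(outdir / "compartments.csv")

    # -- cohort + association ----------------------------------------------
    results: dict = {}
    if config.do_cohort:
        cohort = derive_endpoints(generate_cohort(config.cohort))
        write_cohort(cohort, outdir / "cohort.csv")
        outputs.append(outdir / "cohort.csv")
        log.append(f"cohort: {len(cohort)} patients, "
                   f"{int(cohort['responder'].sum())} responders")
        summary = cohort_summary(cohort, ["response", "stage", "treatment"])
        summary.to_csv(outdir / "cohort_summary.csv", index=False)
        outputs.append(outdir / "cohort_summary.csv")

        term = config.biomarker_term
        models = {
            "response": fit_response_model(cohort, term),
            "pfs": fit_survival_model(cohort, "pfs", term),
            "os": fit_survival_model(cohort, "os", term),
        }
        for name, res in models.items():
            results[name] = {
                "model": res.model, "n": res.n, "n_events": res.n_events,
                "estimable": res.estimable,
                "terms": {
                    str(ix): {"estimate": float(row["estimate"]),
                              "ci_low": float(row["ci_low"]),
                              "ci_high": float(row["ci_high"]),
                              "p": float(row["p"])}
                    for ix, row in res.table.iterrows()},
            }
        km = km_estimate(cohort, "os")
        km.curve.to_csv(outdir / "km_os.csv", index=False)
        outputs.append(outdir / "km_os.csv")
        results["km_os"] = {"median": km.median, "q25": km.q25,
                            "q75": km.q75, "n": km.n,
                            "n_events": km.n_events}
        (outdir / "results.json").write_text(json.dumps(results, indent=2,
                                                        default=float))
        outputs.append(outdir / "results.json")

    manifest = {
        "package": "immunocontext",
        "version": __version__,
        "config": dataclasses.asdict(config),
        "log": log,
        "checksums": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     default=str))
    return manifest
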