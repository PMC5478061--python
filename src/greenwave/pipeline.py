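"""End-to-end green-wave nutritional-benefit analysis on one world.

Runs the full chain on a (synthetic or user-supplied) landscape: screen
fixes, classify tactics from NSD, build summer home ranges and seasonal
contrasts, fit pixel phenology along each animal's space-time matrix,
accumulate CIRG, assemble the covariate table, and fit/select the mixed
models.  This is the programmatic equivalent of the study's analysis
script and is what the acceptance runner executes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import covariates, homerange, movement, phenology, stats, synthetic

logger = logging.getLogger(__name__)

#: Expert relevance ranking used by the correlation screen: summer-range
#: elevation is kept over the covariates known to track it (slope, coast
#: distance, delta-elevation, within-range elevation SD).
DEFAULT_RELEVANCE = [
    "elevation_mean", "prop_forest", "prop_mountain", "prop_pasture",
    "prop_other", "northness", "dist_fjord_km", "dist_summer_winter_km",
    "slope_mean", "dist_coast_km", "delta_elevation_m", "elevation_sd",
]

#: Global fixed effects offered to model selection (transformed names),
#: subject to the correlation screen.
DEFAULT_MAIN_TERMS = ["resident", "elevation_mean", "prop_forest",
                      "prop_mountain", "northness", "male"]
DEFAULT_INTERACTIONS = [("resident", "elevation_mean"),
                        ("resident", "prop_forest"),
                        ("resident", "prop_mountain")]


@dataclass
class PipelineResult:
    """Everything the end-to-end run produces."""

    landscape: synthetic.LandscapeBundle
    phen: phenology.PhenologyRaster
    tracks: list
    classifications: list
    table: pd.DataFrame  # raw covariate table, one row per animal
    model_table: pd.DataFrame  # transformed, analysis-ready rows
    transform_spec: stats.TransformSpec | None
    retained: list[str]
    exclusions: list[dict]
    selection: stats.SelectionResult | None
    accounting: dict


def default_transform_spec() -> stats.TransformSpec:
    """Transforms used in the reference analysis: log elevation
    (standardized), arcsine-sqrt habitat proportions."""
    return stats.TransformSpec(
        transforms={
            "elevation_mean": "log",
            "prop_forest": "asin_sqrt",
            "prop_mountain": "asin_sqrt",
            "prop_pasture": "asin_sqrt",
            "prop_other": "asin_sqrt",
        },
        standardize=("elevation_mean",),
    )


def run_pipeline(config: synthetic.SimulationConfig,
                 main_terms=None, interactions=None,
                 run_selection: bool = True) -> PipelineResult:
    """Simulate a world and run the full analysis on it."""
    landscape = synthetic.generate_landscape(config)
    phen = synthetic.generate_ndvi_series(landscape, config)
    tracks = synthetic.simulate_deer(landscape, config)
    return analyse(landscape, phen, tracks, main_terms=main_terms,
                   interactions=interactions, run_selection=run_selection)


def analyse(landscape, phen, tracks, main_terms=None, interactions=None,
            run_selection: bool = True) -> PipelineResult:
    """Run the analysis chain on existing landscape/NDVI/track inputs."""
    screened = []
    for track in tracks:
        marking = track.fixes["timestamp"].iloc[0]
        screened.append(movement.screen_fixes(track, marking))

    classifications = []
    resolved_tracks = {}
    for track in screened:
        cls = movement.classify_tactic(movement.nsd(track))
        classifications.append(cls)
        if cls.tactic in ("migrant", "resident"):
            resolved_tracks[cls.id] = track

    summer_ranges = {}
    pairs = {}
    for cls in classifications:
        track = resolved_tracks.get(cls.id)
        if track is None:
            continue
        try:
            hr, pair = homerange.seasonal_ranges(track, cls, landscape.dem)
        except ValueError as err:
            logger.info("seasonal ranges failed for %s: %s", cls.id, err)
            continue
        summer_ranges[cls.id] = hr
        pairs[cls.id] = pair

    matrix = phenology.build_space_time_matrix(list(resolved_tracks.values()), phen)
    cirg_results = {}
    for animal_id in resolved_tracks:
        try:
            cirg_results[animal_id] = phenology.cumulative_irg(matrix, animal_id)
        except (KeyError, ValueError) as err:
            logger.info("CIRG unavailable for %s: %s", animal_id, err)

    meta = {t.id: {"sex": t.sex, "year": t.year} for t in screened}
    table = covariates.assemble_table(cirg_results, classifications,
                                      summer_ranges, pairs, landscape, meta=meta)
    accounting = table.attrs["accounting"]

    spec = None
    retained: list[str] = []
    exclusions: list[dict] = []
    selection = None
    model_table = table.copy()
    if run_selection:
        spec = default_transform_spec()
        complete = table.dropna(subset=["cirg", "elevation_mean"]).copy()
        model_table = stats.apply_transforms(complete, spec)
        model_table["resident"] = (model_table["tactic"] == "resident").astype(float)
        model_table["male"] = (model_table["sex"] == "M").astype(float)

        main = list(main_terms) if main_terms is not None else list(DEFAULT_MAIN_TERMS)
        # constant covariates cannot enter the design matrix
        for col in list(main):
            if model_table[col].nunique(dropna=True) < 2:
                logger.info("dropping constant covariate %s", col)
                main.remove(col)
        screen_cols = [c for c in main if c not in ("resident", "male")]
        if len(screen_cols) > 1:
            kept, exclusions = stats.correlation_screen(
                model_table, screen_cols, DEFAULT_RELEVANCE)
            main = [c for c in main if c in kept or c in ("resident", "male")]
        inter = list(interactions) if interactions is not None else [
            (a, b) for a, b in DEFAULT_INTERACTIONS if a in main and b in main]
        retained = main
        selection = stats.all_subsets_selection(model_table, "cirg", main, inter)

    return PipelineResult(
        landscape=landscape, phen=phen, tracks=screened,
        classifications=classifications, table=table, model_table=model_table,
        transform_spec=spec, retained=retained, exclusions=exclusions,
        selection=selection, accounting=accounting,
    )
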