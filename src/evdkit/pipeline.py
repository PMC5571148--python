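"""End-to-end orchestration: screening -> fitting -> curves -> EVDs ->
overlay -> ranking, with plain-text artifacts between stages.

Every stage writes CSV artifacts that the next stage can re-read, so
partial reruns (e.g. re-deriving EVDs at a different impact threshold from
cached curves) reproduce the monolithic run exactly. A run manifest records
the configuration snapshot, seed, input digests and every record count that
a stage filtered or dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .curves import ResponseCurve, curves_table, site_response, sweep_grid
from .dataset import (
    RunConfig,
    SurveyDataset,
    directions_for_role,
    read_table,
    write_table,
)
from .evd import (
    EVD,
    CriticalLevel,
    EVDError,
    build_evd,
    evd_suitability,
    exceedance_table,
    invert_curve,
    levels_table,
)
from .overlay import (
    OverlayReport,
    classify_sites,
    combine_directional_reports,
    rank_stressors,
    site_map_table,
)
from .screening import ScreenedPredictors, screen, standardize
from .sdm import AveragedSDM, fit_species_sdm, filter_species, sdm_table

logger = logging.getLogger("evdkit")


@dataclass
class PipelineResult:
    config: RunConfig
    screened: ScreenedPredictors
    modelled_sites: list[str]
    species: list[str]
    sdms: list[AveragedSDM]
    curves: dict[str, dict[str, ResponseCurve]]  # stressor -> site_id -> curve
    evds: list[EVD]
    unsupported: list[tuple[str, str, str]]  # (stressor, direction, reason)
    reports: list[OverlayReport]
    combined_reports: list[OverlayReport]
    ranking: pd.DataFrame
    ranking_combined: pd.DataFrame
    manifest: dict = field(default_factory=dict)


# -----------------------------------------------------------------------------
# stages


def screen_stage(dataset: SurveyDataset, config: RunConfig) -> ScreenedPredictors:
    screened = screen(dataset.env, dataset.modelled_variables, config.vif_limit)
    for v, vif_at_removal in screened.dropped:
        logger.info("screening dropped %s (VIF %.2f at removal)", v, vif_at_removal)
    return screened


def fit_stage(
    dataset: SurveyDataset,
    config: RunConfig,
    screened: ScreenedPredictors,
) -> tuple[list[AveragedSDM], list[str], list[str]]:
    """Fit an averaged SDM per retained species.

    Returns (sdms, modelled_site_ids, species). The species universe is the
    set observed at reference sites unless ``all_species_mode`` opens it to
    the whole community; either way the occurrence filter applies.
    """
    modelled_sites = list(dataset.complete_sites(screened.kept))
    n_dropped = len(dataset.site_ids) - len(modelled_sites)
    if n_dropped:
        logger.info("dropped %d sites with missing modelled variables", n_dropped)
    occ = dataset.occ.loc[modelled_sites]
    if config.all_species_mode:
        universe = None
    else:
        ref_occ = dataset.occ.loc[[s for s in dataset.reference_ids if s in set(modelled_sites)]]
        universe = [sp for sp in dataset.species if ref_occ[sp].any()]
    species = filter_species(occ, config.min_occurrences, species_universe=universe)
    logger.info("fitting %d species over %d sites, %d predictors",
                len(species), len(modelled_sites), len(screened.kept))

    Z = standardize(dataset.env.loc[modelled_sites], screened).to_numpy()
    sdms = []
    for sp in species:
        sdms.append(
            fit_species_sdm(
                sp, occ[sp].to_numpy(), Z, screened.kept,
                delta_aic=config.delta_aic, use_aicc=config.use_aicc,
                separation_cap=config.separation_cap,
                full_averaging=config.full_averaging,
            )
        )
    if config.auc_exclude_below is not None:
        before = len(sdms)
        sdms = [s for s in sdms if s.auc >= config.auc_exclude_below]
        logger.info("AUC floor %.2f excluded %d species", config.auc_exclude_below, before - len(sdms))
        if not sdms:
            raise ValueError("AUC floor excluded every species")
    return sdms, modelled_sites, [s.species for s in sdms]


def curves_stage(
    dataset: SurveyDataset,
    config: RunConfig,
    screened: ScreenedPredictors,
    sdms: Sequence[AveragedSDM],
    modelled_sites: Sequence[str],
) -> dict[str, dict[str, ResponseCurve]]:
    """Response curves for every reference site and stressor-role variable
    that survived screening."""
    stressors = [v for v in screened.kept if dataset.variable_roles.get(v) != "covariate"]
    if not stressors:
        raise ValueError("no stressor-role variable survived screening")
    modelled = set(modelled_sites)
    ref_sites = [s for s in dataset.reference_ids if s in modelled]
    skipped = len(dataset.reference_ids) - len(ref_sites)
    if skipped:
        logger.info("skipped %d reference sites with incomplete environment", skipped)
    env_modelled = dataset.env.loc[list(modelled_sites)]
    curves: dict[str, dict[str, ResponseCurve]] = {}
    for stressor in stressors:
        grid = sweep_grid(
            env_modelled, stressor, config.sweep_quantiles, config.sweep_points,
            bounds=config.variable_bounds.get(stressor),
            include=list(dataset.env.loc[ref_sites, stressor].dropna()),
        )
        curves[stressor] = {
            site: site_response(dataset, site, stressor, list(sdms), screened, config, grid=grid)
            for site in ref_sites
        }
    return curves


def evd_stage(
    dataset: SurveyDataset,
    config: RunConfig,
    curves: dict[str, dict[str, ResponseCurve]],
) -> tuple[list[EVD], list[tuple[str, str, str]]]:
    """Invert curves per (stressor, direction) and assemble the EVDs."""
    evds: list[EVD] = []
    unsupported: list[tuple[str, str, str]] = []
    for stressor, site_curves in curves.items():
        role = dataset.variable_roles[stressor]
        for direction in directions_for_role(role):
            levels = [
                invert_curve(c, config.threshold_T, direction) for c in site_curves.values()
            ]
            n_censored = sum(l.censored for l in levels)
            try:
                evd = build_evd(levels, stressor, direction)
            except EVDError as exc:
                logger.warning("EVD unsupported for %s/%s: %s", stressor, direction, exc)
                unsupported.append((stressor, direction, str(exc)))
                continue
            evd.suitability = evd_suitability(
                list(site_curves.values()), levels, config.threshold_T, direction,
                config.low_response_censored_frac, config.complex_response_frac,
            )
            logger.info(
                "EVD %s/%s: %d sites (%d censored), suitability=%s",
                stressor, direction, len(levels), n_censored, evd.suitability,
            )
            evds.append(evd)
    return evds, unsupported


def overlay_stage(
    dataset: SurveyDataset, evds: Sequence[EVD]
) -> tuple[list[OverlayReport], list[OverlayReport], pd.DataFrame, pd.DataFrame]:
    """Classify the whole region against each EVD and rank stressors.

    Directional reports are always emitted; a both-direction stressor also
    gets a worst-case combined report, and the combined ranking table uses
    that single row in place of its two directional ones.
    """
    reports = [classify_sites(e, dataset.env) for e in evds]
    by_stressor: dict[str, list[OverlayReport]] = {}
    for r in reports:
        by_stressor.setdefault(r.stressor, []).append(r)
    combined = [
        combine_directional_reports(rs[0], rs[1]) for rs in by_stressor.values() if len(rs) == 2
    ]
    ranking = rank_stressors(reports)
    merged = [rs[0] if len(rs) == 1 else combine_directional_reports(rs[0], rs[1])
              for rs in by_stressor.values()]
    ranking_combined = rank_stressors(merged)
    return reports, combined, ranking, ranking_combined


# -----------------------------------------------------------------------------
# the monolithic run


def run_pipeline(
    dataset: SurveyDataset,
    config: RunConfig | None = None,
    outdir: str | Path | None = None,
    input_digests: dict[str, str] | None = None,
) -> PipelineResult:
    """Run every stage in order and (optionally) write all artifacts."""
    config = config or RunConfig()
    screened = screen_stage(dataset, config)
    sdms, modelled_sites, species = fit_stage(dataset, config, screened)
    curves = curves_stage(dataset, config, screened, sdms, modelled_sites)
    evds, unsupported = evd_stage(dataset, config, curves)
    reports, combined, ranking, ranking_combined = overlay_stage(dataset, evds)

    manifest = {
        "software": {"name": "evdkit", "version": __version__},
        "seed": config.random_seed,
        "config": config.to_dict(),
        "inputs": input_digests or {},
        "counts": {
            "sites_total": len(dataset.site_ids),
            "sites_modelled": len(modelled_sites),
            "reference_sites": len(dataset.reference_ids),
            "variables_candidate": len(dataset.modelled_variables),
            "variables_kept": len(screened.kept),
            "variables_dropped": len(screened.dropped),
            "species_total": len(dataset.species),
            "species_modelled": len(species),
            "candidates_excluded_separation": int(sum(s.n_candidates_excluded for s in sdms)),
            "evds_supported": len(evds),
            "evds_unsupported": len(unsupported),
            "sites_censored_per_evd": {
                f"{e.stressor}/{e.direction}": int(sum(l.censored for l in e.levels)) for e in evds
            },
        },
    }
    result = PipelineResult(
        config=config, screened=screened, modelled_sites=modelled_sites,
        species=species, sdms=sdms, curves=curves, evds=evds,
        unsupported=unsupported, reports=reports, combined_reports=combined,
        ranking=ranking, ranking_combined=ranking_combined, manifest=manifest,
    )
    if outdir is not None:
        write_outputs(result, dataset, Path(outdir))
    return result


# -----------------------------------------------------------------------------
# artifact I/O (stage-wise reruns read these back)


def write_outputs(result: PipelineResult, dataset: SurveyDataset, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_screening(result.screened, outdir)
    write_table(sdm_table(result.sdms, result.screened), outdir / "sdm_coefficients.csv")
    all_curves = [c for d in result.curves.values() for c in d.values()]
    save_curves(all_curves, outdir / "response_curves.csv")
    if result.evds:
        write_table(levels_table(result.evds), outdir / "evd_levels.csv")
        write_table(exceedance_table(result.evds), outdir / "evd_exceedance.csv")
        summary = pd.DataFrame(
            [
                {
                    "stressor": e.stressor, "direction": e.direction,
                    "suitability": e.suitability,
                    "evd_min": e.range[0], "evd_max": e.range[1],
                    "n_sites": e.n_sites,
                    "n_censored": int(sum(l.censored for l in e.levels)),
                }
                for e in result.evds
            ]
        )
        write_table(summary, outdir / "evd_summary.csv")
    if result.reports:
        cls = pd.concat(
            [
                pd.DataFrame(
                    {
                        "site_id": r.classifications.index,
                        "stressor": r.stressor,
                        "direction": r.direction,
                        "classification": r.classifications.values,
                    }
                )
                for r in result.reports + result.combined_reports
            ],
            ignore_index=True,
        )
        write_table(cls, outdir / "overlay_classifications.csv")
        write_table(result.ranking, outdir / "ranking.csv")
        write_table(result.ranking_combined, outdir / "ranking_combined.csv")
        if dataset.coords is not None and not dataset.coords.empty:
            write_table(site_map_table(result.reports, dataset), outdir / "site_map.csv")
    (outdir / "manifest.yaml").write_text(yaml.safe_dump(result.manifest, sort_keys=True))


def write_screening(screened: ScreenedPredictors, outdir: Path) -> None:
    outdir = Path(outdir)
    write_table(screened.report(), outdir / "screening_report.csv")
    std = pd.DataFrame(
        {
            "variable": screened.kept,
            "mean": [screened.means[v] for v in screened.kept],
            "sd": [screened.sds[v] for v in screened.kept],
        }
    )
    write_table(std, outdir / "standardization.csv")


def load_screening(outdir: Path) -> ScreenedPredictors:
    outdir = Path(outdir)
    report = read_table(outdir / "screening_report.csv")
    std = read_table(outdir / "standardization.csv")
    dropped = [
        (row.variable, float(row.vif))
        for row in report.itertuples()
        if row.status == "dropped"
    ]
    return ScreenedPredictors(
        kept=list(std["variable"]),
        dropped=dropped,
        means=dict(zip(std["variable"], std["mean"].astype(float))),
        sds=dict(zip(std["variable"], std["sd"].astype(float))),
    )


def load_sdms(path: Path, predictors: Sequence[str]) -> list[AveragedSDM]:
    table = read_table(path)
    sdms = []
    for row in table.itertuples():
        sdms.append(
            AveragedSDM(
                species=row.species,
                predictors=tuple(predictors),
                intercept=float(row.intercept),
                linear={v: float(getattr(row, f"{v}_linear")) for v in predictors},
                quadratic={v: float(getattr(row, f"{v}_quadratic")) for v in predictors},
                n_models_averaged=int(row.n_models_averaged),
                best_aic=float(row.best_aic),
                auc=float(row.auc),
                n_presences=int(row.n_presences),
                n_sites=int(getattr(row, "n_sites", 0)) if hasattr(row, "n_sites") else 0,
            )
        )
    return sdms


def save_curves(curves: Sequence[ResponseCurve], path: Path) -> None:
    table = curves_table(curves)
    meta = {
        (c.site_id, c.stressor): (c.observed_value, c.richness_at_reference, ";".join(c.species_pool))
        for c in curves
    }
    table["observed_value"] = [meta[(s, v)][0] for s, v in zip(table.site_id, table.stressor)]
    table["richness_at_reference"] = [meta[(s, v)][1] for s, v in zip(table.site_id, table.stressor)]
    table["species_pool"] = [meta[(s, v)][2] for s, v in zip(table.site_id, table.stressor)]
    write_table(table, path)


def load_curves(path: Path) -> dict[str, dict[str, ResponseCurve]]:
    table = read_table(path, dtype={"site_id": str})
    out: dict[str, dict[str, ResponseCurve]] = {}
    for (stressor, site), sub in table.groupby(["stressor", "site_id"], sort=False):
        sub = sub.sort_values("grid_value")
        curve = ResponseCurve(
            site_id=site,
            stressor=stressor,
            grid=sub["grid_value"].to_numpy(float),
            rsr=sub["rsr"].to_numpy(float),
            observed_value=float(sub["observed_value"].iloc[0]),
            richness_at_reference=float(sub["richness_at_reference"].iloc[0]),
            species_pool=tuple(str(sub["species_pool"].iloc[0]).split(";")),
        )
        out.setdefault(stressor, {})[site] = curve
    return out


def load_evds(levels_path: Path) -> list[EVD]:
    table = read_table(levels_path, dtype={"site_id": str})
    evds = []
    for (stressor, direction), sub in table.groupby(["stressor", "direction"], sort=False):
        levels = [
            CriticalLevel(
                site_id=row.site_id, stressor=stressor, direction=direction,
                level=float(row.critical_level), censored=bool(row.censored),
                rsr_at_level=float(row.rsr_at_level),
            )
            for row in sub.itertuples()
        ]
        evds.append(build_evd(levels, stressor, direction))
    return evds
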