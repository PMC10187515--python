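"""End-to-end study drivers.

Two entry points reproduce the structure of the full analysis on synthetic
inputs: :func:`hindcast_study` calibrates the five-variable (PCA-rotated)
niche model on the present fine grid and projects it over the past series,
deriving the MUT-binarized range series and its statistics;
:func:`forecast_study` calibrates the VIF-filtered 19-variable model and
projects it onto every (emulator, ssp, period) future, deriving habitat
classes, fragmentation metrics and the scenario comparisons.

Desk-scale defaults keep both studies to a couple of minutes: the tuning
grid is a 2 x 2 subset of the full feature-class x regularization grid and
the background defaults to the full 10,000-point sample.  Every knob is an
argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ensemble import SmallModelEnsemble, assign_spatial_folds, ensemble_predict, tune_and_fit
from .grids import ClimateSeries, GridRaster, HINDCAST_LAYERS
from .landscape import classify_hsi, landscape_table, permanova_two_way, prepare_landscape_response
from .points import (
    BackgroundSet,
    OccurrenceSet,
    build_background_region,
    simulate_background,
    simulate_occurrences,
)
from .prep import PCATransform, aggregate_raster, fit_pca, mess, screen_variables_by_mess, vif_filter
from .rangedyn import RangeSeries, TrendFit, TrendModel, brown_forsythe, build_range_series, compute_mut
from .synthio import ClimateConfig, RegionConfig, RegionSet, generate_climate_series, generate_regions

__all__ = ["HindcastStudy", "ForecastStudy", "hindcast_study", "forecast_study"]


def _values_at(stack, cell_index: np.ndarray, names: list[str]) -> np.ndarray:
    return np.column_stack(
        [stack[n].values[cell_index[:, 0], cell_index[:, 1]] for n in names]
    )


@dataclass
class HindcastStudy:
    series: ClimateSeries
    regions: RegionSet
    occurrences: OccurrenceSet
    background: BackgroundSet
    pca: PCATransform
    retained_scores: list[str]
    ensemble: SmallModelEnsemble
    hsi_maps: list[GridRaster]
    present_hsi: GridRaster
    mut: float
    range_series: RangeSeries
    bf_mean_hsi: tuple[float, float]
    bf_range_area: tuple[float, float]
    temperature_trend: TrendFit
    altitude_trend: TrendFit

    def summary(self) -> str:
        tab = self.range_series.table
        return "\n".join(
            [
                f"hindcast study: {len(self.hsi_maps)} time bins, MUT = {self.mut:.2f}",
                f"occurrences: {len(self.occurrences)}, background: {len(self.background)}",
                self.ensemble.summary(),
                f"bins better than present: {int(tab.better_flag.sum())}, "
                f"similar: {int(tab.similar_flag.sum())}",
                f"Brown-Forsythe (mean HSI, young vs old): "
                f"F = {self.bf_mean_hsi[0]:.3f}, p = {self.bf_mean_hsi[1]:.3g}",
                f"temperature trend: {self.temperature_trend.summary()}",
                f"altitude trend: {self.altitude_trend.summary()}",
            ]
        )


def hindcast_study(
    seed: int = 0,
    climate_config: ClimateConfig | None = None,
    region_config: RegionConfig | None = None,
    n_occurrences: int = 200,
    n_background: int = 10_000,
    k_folds: int = 12,
    feature_classes: tuple[str, ...] = ("LQ", "LQH"),
    reg_multipliers: tuple[float, ...] = (1.0, 2.0),
    variance_split_ka: float | None = None,
) -> HindcastStudy:
    """Full hindcast pipeline on one seed.

    Calibration uses the five hindcast layers of the fine present grid,
    rotated by a standardized PCA; five 4-of-5 small models are tuned with
    spatial-block CV; the ensemble is projected onto every past bin and
    the coarse present; MESS screening, MUT binarization, the per-bin
    comparisons and the variance / trend statistics follow.
    """
    cfg = climate_config or ClimateConfig()
    series = generate_climate_series(cfg, seed=seed)
    regions = generate_regions(region_config, cfg, seed=seed)
    grid = series.present_fine.grid
    occ = simulate_occurrences(regions, grid, n=n_occurrences, seed=seed + 1)
    region = build_background_region(regions)
    bg = simulate_background(region, occ, grid, n=n_background, seed=seed + 2)

    hind = series.present_fine.subset(list(HINDCAST_LAYERS))
    pca = fit_pca(hind)
    Sp = pca.transform_matrix(_values_at(hind, occ.cell_index, list(HINDCAST_LAYERS)))
    Sb = pca.transform_matrix(_values_at(hind, bg.cell_index, list(HINDCAST_LAYERS)))

    # transferability screening on the PC variables across all past bins
    ref = {name: np.concatenate([Sp[:, i], Sb[:, i]]) for i, name in enumerate(pca.score_names)}
    mess_maps = [mess(ref, pca.transform(s)) for s in series.past]
    retained = screen_variables_by_mess(mess_maps)

    cols = [pca.score_names.index(v) for v in retained]
    folds = assign_spatial_folds(occ, k=k_folds, seed=seed + 3)
    ens = tune_and_fit(
        Sp[:, cols], Sb[:, cols], retained, max(1, len(retained) - 1), folds,
        feature_classes=feature_classes, reg_multipliers=reg_multipliers,
    )

    hsi_maps = [ensemble_predict(ens, pca.transform(s)) for s in series.past]
    present_hsi = ensemble_predict(ens, pca.transform(series.present_coarse))
    mut = compute_mut(hsi_maps + [present_hsi]).mut
    alt_coarse = aggregate_raster(regions.altitude, cfg.coarse_factor)
    temps = [s["BIO10"] for s in series.past]
    rs = build_range_series(
        hsi_maps, series.past_times, present_hsi,
        altitude=alt_coarse, temperature_maps=temps, mut=mut,
    )
    tab = rs.table
    split = variance_split_ka if variance_split_ka is not None else cfg.cycle_switch_ka
    young = tab[tab.time_ka <= split]
    old = tab[tab.time_ka > split]
    bf_hsi = brown_forsythe(young.mean_hsi.to_numpy(), old.mean_hsi.to_numpy())
    bf_area = brown_forsythe(young.range_area.to_numpy(), old.range_area.to_numpy())
    trend_t = TrendModel(
        np.log10(tab.range_area.to_numpy()), tab.mean_temperature.to_numpy()
    ).fit(max_ma=3, auto_grid=(2, 1, 2))
    trend_a = TrendModel(
        np.log10(tab.range_area.to_numpy()), np.log10(tab.mean_altitude.to_numpy())
    ).fit(max_ma=3, auto_grid=(2, 1, 2))
    return HindcastStudy(
        series=series, regions=regions, occurrences=occ, background=bg,
        pca=pca, retained_scores=retained, ensemble=ens, hsi_maps=hsi_maps,
        present_hsi=present_hsi, mut=mut, range_series=rs,
        bf_mean_hsi=bf_hsi, bf_range_area=bf_area,
        temperature_trend=trend_t, altitude_trend=trend_a,
    )


@dataclass
class ForecastStudy:
    retained_variables: list[str]
    ensemble: SmallModelEnsemble
    present_hsi: GridRaster
    future_hsi: dict[tuple[str, str, int], GridRaster]
    metrics: pd.DataFrame
    permanova: pd.DataFrame
    best_class_loss: pd.DataFrame

    def summary(self) -> str:
        return "\n".join(
            [
                f"forecast study: {len(self.retained_variables)} variables retained "
                f"after VIF filtering ({', '.join(self.retained_variables)})",
                f"{len(self.ensemble.members)} small models "
                f"(6-variable subsets), {len(self.future_hsi)} future scenarios",
                "PerMANOVA (emulator, period; strata = ssp):",
                self.permanova.to_string(index=False),
            ]
        )


def forecast_study(
    seed: int = 0,
    climate_config: ClimateConfig | None = None,
    region_config: RegionConfig | None = None,
    n_occurrences: int = 200,
    n_background: int = 10_000,
    k_folds: int = 12,
    subset_size: int | None = None,
    feature_classes: tuple[str, ...] = ("LQ",),
    reg_multipliers: tuple[float, ...] = (1.0, 2.0),
    vif_threshold: float = 3.0,
    n_perm: int = 9999,
    aggregate_factor: int = 1,
) -> ForecastStudy:
    """Full forecast pipeline on one seed.

    The 19 bioclimatic layers are pruned by the iterative VIF filter; one
    small model per 6-variable subset of the retained set is tuned and the
    ensemble projected onto the present and every future stack; habitat
    classes, fragmentation metrics, and the two-way stratified PerMANOVA
    plus the patch-area loss summary follow.
    """
    cfg = climate_config or ClimateConfig()
    series = generate_climate_series(cfg, seed=seed)
    regions = generate_regions(region_config, cfg, seed=seed)
    grid = series.present_fine.grid
    occ = simulate_occurrences(regions, grid, n=n_occurrences, seed=seed + 1)
    bg = simulate_background(
        build_background_region(regions), occ, grid, n=n_background, seed=seed + 2
    )

    names19 = [f"BIO{i}" for i in range(1, 20)]
    retained = vif_filter(series.present_fine, threshold=vif_threshold, layer_names=names19)
    k = subset_size if subset_size is not None else max(1, len(retained) - 2)
    Xp = _values_at(series.present_fine, occ.cell_index, retained)
    Xb = _values_at(series.present_fine, bg.cell_index, retained)
    folds = assign_spatial_folds(occ, k=k_folds, seed=seed + 3)
    ens = tune_and_fit(
        Xp, Xb, retained, k, folds,
        feature_classes=feature_classes, reg_multipliers=reg_multipliers,
    )

    def project(stack):
        sub = stack.subset(retained)
        hsi = ensemble_predict(ens, sub)
        return aggregate_raster(hsi, aggregate_factor) if aggregate_factor > 1 else hsi

    present_hsi = project(series.present_fine)
    future_hsi = {key: project(stack) for key, stack in series.future.items()}

    class_maps = {key: classify_hsi(h) for key, h in future_hsi.items()}
    metrics = landscape_table(class_maps)
    kept, Y = prepare_landscape_response(metrics)
    perm = permanova_two_way(
        Y,
        kept["emulator"].to_numpy(),
        kept["period"].to_numpy(),
        strata=kept["ssp"].to_numpy(),
        n_perm=n_perm,
        seed=seed + 4,
    )
    perm["term"] = ["emulator", "period"]

    # good-to-best habitat (HSI >= 0.5, classes 3-4) loss per scenario
    # relative to the present
    pres_best = float((classify_hsi(present_hsi).values >= 3).sum())
    rows = []
    for (emu, ssp, year), cmap in class_maps.items():
        best = float((cmap.values >= 3).sum())
        loss = 100.0 * (1.0 - best / pres_best) if pres_best > 0 else np.nan
        rows.append({"emulator": emu, "ssp": ssp, "period": year, "best_loss_pct": loss})
    loss_tab = pd.DataFrame(rows)
    return ForecastStudy(
        retained_variables=retained, ensemble=ens, present_hsi=present_hsi,
        future_hsi=future_hsi, metrics=metrics, permanova=perm,
        best_class_loss=loss_tab,
    )
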