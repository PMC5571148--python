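"""Site-specific stressor-response curves of relative species richness.

For a reference site and one stressor, the fitted species models are
stacked: the stressor is swept across its regional range while every other
variable is pinned at the site's observed value, per-species occurrence
probabilities are summed into an expected species richness, and the curve
is normalized to 1 at the site's observed stressor level (the point of
departure). Values above 1 mean the hypothetical level would support more
of the site's species than current conditions; below 1, fewer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import RunConfig, SurveyDataset
from .screening import ScreenedPredictors
from .sdm import AveragedSDM, predict_matrix


class CurveError(ValueError):
    pass


@dataclass
class ResponseCurve:
    """Relative species richness of one site along one swept stressor."""

    site_id: str
    stressor: str
    grid: np.ndarray  # native units, strictly increasing, contains the observed value
    rsr: np.ndarray
    observed_value: float  # the point of departure (RSR = 1 there)
    richness_at_reference: float  # expected richness at observed conditions
    species_pool: tuple[str, ...]

    @property
    def observed_index(self) -> int:
        return int(np.argmin(np.abs(self.grid - self.observed_value)))

    def rsr_at(self, value: float) -> float:
        return float(np.interp(value, self.grid, self.rsr))


def sweep_grid(
    env: pd.DataFrame,
    stressor: str,
    sweep_quantiles: tuple[float, float] = (0.01, 0.99),
    sweep_points: int = 1001,
    bounds: tuple[float, float] | None = None,
    include: Sequence[float] = (),
) -> np.ndarray:
    """Evenly spaced native-unit grid over the regional stressor range.

    The span runs between the configured regional quantiles (extreme
    outliers are thereby left out), clipped to any declared natural bounds,
    and extended to cover every value in ``include`` (a reference site's
    observed level must always be on the grid).
    """
    values = env[stressor].dropna().to_numpy(float)
    if len(values) == 0:
        raise CurveError(f"no observed values for stressor {stressor!r}")
    lo, hi = np.quantile(values, sweep_quantiles)
    if include:
        lo = min(lo, *include)
        hi = max(hi, *include)
    if bounds is not None:
        lo = max(lo, bounds[0])
        hi = min(hi, bounds[1])
    if not hi > lo:
        raise CurveError(f"zero-width sweep range for {stressor!r}: [{lo}, {hi}]")
    return np.linspace(lo, hi, sweep_points)


def _insert_value(grid: np.ndarray, value: float) -> np.ndarray:
    """Grid with ``value`` inserted as an exact point (kept sorted, unique)."""
    if np.any(grid == value):
        return grid
    return np.sort(np.append(grid, value))


def site_response(
    dataset: SurveyDataset,
    site_id: str,
    stressor: str,
    sdms: Sequence[AveragedSDM],
    screened: ScreenedPredictors,
    config: RunConfig,
    grid: np.ndarray | None = None,
) -> ResponseCurve:
    """Stack the fitted models into this site's response curve.

    The species pool is the site's observed species (default) or every
    modelled species (``all_species_mode``, the as-if-present-everywhere
    variant). Expected richness at each grid value is the sum over the pool
    of occurrence probabilities with the swept variable substituted and all
    other variables held at the site's observed values.
    """
    if not sdms:
        raise CurveError("no fitted species models supplied")
    predictors = sdms[0].predictors
    if stressor not in predictors:
        raise CurveError(f"stressor {stressor!r} is not among the modelled predictors {predictors}")
    env_row = dataset.env.loc[site_id, list(predictors)]
    if env_row.isna().any():
        missing = list(env_row.index[env_row.isna()])
        raise CurveError(f"site {site_id!r} is missing value(s) for {missing}")
    observed = float(env_row[stressor])

    if config.all_species_mode:
        pool = [s.species for s in sdms]
    else:
        present = dataset.occ.loc[site_id]
        pool = [s.species for s in sdms if present.get(s.species, 0) == 1]
    if not pool:
        raise CurveError(f"site {site_id!r} has no modelled species in its pool")
    pool_sdms = [s for s in sdms if s.species in set(pool)]

    if grid is None:
        grid = sweep_grid(
            dataset.env.loc[dataset.complete_sites(predictors)],
            stressor,
            config.sweep_quantiles,
            config.sweep_points,
            bounds=config.variable_bounds.get(stressor),
        )
    grid = _insert_value(np.asarray(grid, float), observed)

    # standardized design: swept column varies, all others fixed at site values
    j = predictors.index(stressor)
    z_row = np.array([screened.standardize_values(v, float(env_row[v])) for v in predictors])
    Z = np.tile(z_row, (len(grid), 1))
    Z[:, j] = screened.standardize_values(stressor, grid)

    richness = np.zeros(len(grid))
    for s in pool_sdms:
        richness += predict_matrix(s, Z)
    ref_richness = float(richness[np.argmax(grid == observed)])
    if ref_richness < 1e-6:
        raise CurveError(
            f"degenerate normalization at site {site_id!r}: expected richness {ref_richness:.2e}"
        )
    return ResponseCurve(
        site_id=site_id,
        stressor=stressor,
        grid=grid,
        rsr=richness / ref_richness,
        observed_value=observed,
        richness_at_reference=ref_richness,
        species_pool=tuple(pool),
    )


def curves_table(curves: Sequence[ResponseCurve]) -> pd.DataFrame:
    """Long-format export: (site_id, stressor, grid_value, rsr)."""
    frames = [
        pd.DataFrame(
            {
                "site_id": c.site_id,
                "stressor": c.stressor,
                "grid_value": c.grid,
                "rsr": c.rsr,
            }
        )
        for c in curves
    ]
    return pd.concat(frames, ignore_index=True)
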