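"""Survey dataset contract, table I/O and run configuration.

The pipeline consumes two wide, site-keyed tables — one of continuous
environmental variables, one of species presence/absence — plus a list of
reference-site identifiers and a mapping of each variable to its role
(stressor acting by increase, by decrease, in both directions, or plain
covariate). Everything downstream treats the resulting
:class:`SurveyDataset` as the single source of observational truth.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("evdkit")

#: Recognised variable roles.
ROLE_STRESSOR_INCREASE = "stressor_increase"
ROLE_STRESSOR_DECREASE = "stressor_decrease"
ROLE_STRESSOR_BOTH = "stressor_both"
ROLE_COVARIATE = "covariate"
VALID_ROLES = frozenset(
    {ROLE_STRESSOR_INCREASE, ROLE_STRESSOR_DECREASE, ROLE_STRESSOR_BOTH, ROLE_COVARIATE}
)

DIRECTION_INCREASE = "increase"
DIRECTION_DECREASE = "decrease"


class DatasetError(ValueError):
    """Raised when input tables violate the dataset contract."""


def directions_for_role(role: str) -> tuple[str, ...]:
    """Stress directions implied by a variable role (empty for covariates)."""
    return {
        ROLE_STRESSOR_INCREASE: (DIRECTION_INCREASE,),
        ROLE_STRESSOR_DECREASE: (DIRECTION_DECREASE,),
        ROLE_STRESSOR_BOTH: (DIRECTION_INCREASE, DIRECTION_DECREASE),
        ROLE_COVARIATE: (),
    }[role]


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Defaults mirror the method's canonical settings: a 5% species-richness
    loss threshold, a 20-occurrence minimum per modelled species, VIF < 5
    collinearity screening, a two-AIC-unit model confidence set, and a sweep
    clamped to the regional 1st-99th percentile range.
    """

    threshold_T: float = 0.05
    min_occurrences: int = 20
    vif_limit: float = 5.0
    delta_aic: float = 2.0
    sweep_points: int = 1001
    sweep_quantiles: tuple[float, float] = (0.01, 0.99)
    band_quantiles: tuple[float, float] = (0.05, 0.95)
    all_species_mode: bool = False
    random_seed: int = 0
    #: full (shrinkage) model averaging; absent terms enter as zeros.
    full_averaging: bool = True
    #: small-sample AIC correction switch.
    use_aicc: bool = False
    #: optional AUC floor; species below it are dropped before stacking.
    auc_exclude_below: float | None = None
    #: |coefficient| cap (standardized scale) beyond which a candidate fit
    #: is treated as separated and excluded from the confidence set.
    separation_cap: float = 15.0
    #: advisory EVD suitability cutoffs.
    low_response_censored_frac: float = 0.5
    complex_response_frac: float = 0.25
    #: natural bounds per variable, e.g. {"mspaf": [0.0, 1.0]}; sweep grids
    #: are clipped to these.
    variable_bounds: dict[str, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.threshold_T < 1.0):
            raise ValueError(f"threshold_T must be in (0, 1), got {self.threshold_T}")
        lo, hi = self.sweep_quantiles
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"sweep_quantiles must be strictly ordered in [0, 1], got {self.sweep_quantiles}")
        if self.sweep_points < 3:
            raise ValueError(f"sweep_points must be >= 3, got {self.sweep_points}")
        if self.min_occurrences < 0:
            raise ValueError("min_occurrences must be non-negative")
        if self.vif_limit <= 1.0:
            raise ValueError("vif_limit must exceed 1")

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("sweep_quantiles", "band_quantiles"):
            if key in d:
                d[key] = tuple(d[key])
        if "variable_bounds" in d:
            d["variable_bounds"] = {k: tuple(v) for k, v in d["variable_bounds"].items()}
        return cls(**d)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sweep_quantiles"] = list(self.sweep_quantiles)
        d["band_quantiles"] = list(self.band_quantiles)
        d["variable_bounds"] = {k: list(v) for k, v in self.variable_bounds.items()}
        return d


@dataclass
class SurveyDataset:
    """Joined site-by-environment and site-by-species observations.

    Attributes
    ----------
    env : DataFrame
        Site-indexed environmental variables in native units. Missing values
        are allowed; sites missing a modelled variable are dropped from
        fitting and sweeps downstream.
    occ : DataFrame
        Site-indexed binary presence/absence, one column per species.
    reference_ids : list of str
        Subset of site ids taken to represent minimally disturbed conditions.
    variable_roles : dict
        Variable name -> role (one of :data:`VALID_ROLES`).
    coords : DataFrame or None
        Optional ``x``/``y`` site coordinates, passed through unchanged.
    """

    env: pd.DataFrame
    occ: pd.DataFrame
    reference_ids: list[str]
    variable_roles: dict[str, str]
    coords: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        env_idx, occ_idx = self.env.index, self.occ.index
        if env_idx.has_duplicates or occ_idx.has_duplicates:
            dups = sorted(set(env_idx[env_idx.duplicated()]) | set(occ_idx[occ_idx.duplicated()]))
            raise DatasetError(f"duplicate site ids after aggregation: {dups[:10]}")
        if set(env_idx) != set(occ_idx):
            orphans = sorted(set(env_idx) ^ set(occ_idx))
            raise DatasetError(f"site universes of env and occ tables differ; orphan ids: {orphans[:10]}")
        # align occ rows to env order
        self.occ = self.occ.loc[env_idx]
        occ_vals = self.occ.to_numpy()
        bad = ~np.isin(occ_vals, (0, 1)) | ~np.isfinite(occ_vals.astype(float))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise DatasetError(
                f"occurrence values must be 0/1; found {occ_vals[i, j]!r} at "
                f"site {self.occ.index[i]!r}, species {self.occ.columns[j]!r}"
            )
        self.occ = self.occ.astype(np.int8)
        missing_ref = sorted(set(self.reference_ids) - set(env_idx))
        if missing_ref:
            raise DatasetError(f"reference ids absent from site tables: {missing_ref[:10]}")
        if len(set(self.reference_ids)) < 2:
            raise DatasetError("at least two reference sites are required (a one-point EVD is degenerate)")
        self.reference_ids = list(dict.fromkeys(self.reference_ids))
        unknown_vars = sorted(set(self.variable_roles) - set(self.env.columns))
        if unknown_vars:
            raise DatasetError(f"variables in roles config absent from env table: {unknown_vars}")
        bad_roles = {v: r for v, r in self.variable_roles.items() if r not in VALID_ROLES}
        if bad_roles:
            raise DatasetError(f"invalid roles: {bad_roles}; valid roles are {sorted(VALID_ROLES)}")
        if not any(r != ROLE_COVARIATE for r in self.variable_roles.values()):
            raise DatasetError("no stressors configured: every variable has role 'covariate'")

    # -- convenience accessors -------------------------------------------------

    @property
    def site_ids(self) -> list[str]:
        return list(self.env.index)

    @property
    def species(self) -> list[str]:
        return list(self.occ.columns)

    @property
    def stressors(self) -> list[str]:
        return [v for v, r in self.variable_roles.items() if r != ROLE_COVARIATE]

    @property
    def modelled_variables(self) -> list[str]:
        return list(self.variable_roles)

    def complete_sites(self, variables: Sequence[str]) -> pd.Index:
        """Site ids with no missing value in any of ``variables``."""
        sub = self.env[list(variables)]
        return self.env.index[sub.notna().all(axis=1)]


# -----------------------------------------------------------------------------
# loading


def _collapse_repeats(env: pd.DataFrame, occ: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    # median across repeat samplings for environment; ever-observed for species
    if env.index.has_duplicates:
        env = env.groupby(level=0, sort=False).median()
    if occ.index.has_duplicates:
        occ = occ.groupby(level=0, sort=False).max()
    return env, occ


def load_dataset(
    env_table: str | Path,
    occ_table: str | Path,
    reference_list: str | Path,
    roles: Mapping[str, str],
    coords_columns: tuple[str, str] = ("x", "y"),
) -> SurveyDataset:
    """Read and validate the two CSV tables and the reference-site list.

    Repeat rows for a site collapse to the per-site median of each
    environmental variable and to the maximum (ever observed) of each
    species' presence. Optional coordinate columns named ``x``/``y`` in the
    environment table are split off as pass-through coordinates.
    """
    env = pd.read_csv(env_table, dtype={"site_id": str})
    occ = pd.read_csv(occ_table, dtype={"site_id": str})
    for name, frame in (("env", env), ("occ", occ)):
        if "site_id" not in frame.columns:
            raise DatasetError(f"{name} table has no 'site_id' column")
    env = env.set_index("site_id")
    occ = occ.set_index("site_id")

    coords = None
    coord_cols = [c for c in coords_columns if c in env.columns]
    if coord_cols:
        coords = env[coord_cols].groupby(level=0, sort=False).first()
        env = env.drop(columns=coord_cols)

    n_env_rows, n_occ_rows = len(env), len(occ)
    env, occ = _collapse_repeats(env, occ)
    if len(env) != n_env_rows or len(occ) != n_occ_rows:
        logger.info(
            "collapsed repeat samplings: env %d -> %d rows, occ %d -> %d rows",
            n_env_rows, len(env), n_occ_rows, len(occ),
        )

    reference_ids = [
        line.strip()
        for line in Path(reference_list).read_text().splitlines()
        if line.strip() and not line.lstrip().startswith("#")
    ]
    return SurveyDataset(
        env=env, occ=occ, reference_ids=reference_ids,
        variable_roles=dict(roles), coords=coords,
    )


def load_config(path: str | Path) -> tuple[RunConfig, dict]:
    """Read a YAML run configuration.

    Returns the :class:`RunConfig` built from the ``run`` section and the
    full raw document (which also carries ``inputs``/``roles``/``synthetic``
    sections for the pipeline driver).
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    cfg = RunConfig.from_dict(raw.get("run", {}))
    return cfg, raw


# -----------------------------------------------------------------------------
# writing


def write_table(records: pd.DataFrame, path: str | Path) -> Path:
    """Write a tabular output as CSV with full float precision.

    Uses the shortest round-trippable decimal representation so that
    ``read(write(x))`` reproduces every numeric field exactly.
    """
    if records.shape[1] == 0:
        raise ValueError("refusing to write a table with no columns")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    records.to_csv(path, index=False, float_format=lambda v: repr(float(v)))
    return path


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table` with exact float parsing."""
    return pd.read_csv(path, float_precision="round_trip", **kwargs)


def write_dataset(dataset: SurveyDataset, outdir: str | Path) -> dict[str, Path]:
    """Write a dataset back to its canonical three-file CSV layout."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    env = dataset.env.copy()
    if dataset.coords is not None:
        env = dataset.coords.join(env)
    paths = {
        "env": write_table(env.reset_index(), outdir / "env.csv"),
        "occ": write_table(dataset.occ.reset_index(), outdir / "occ.csv"),
    }
    ref_path = outdir / "reference_sites.txt"
    ref_path.write_text("\n".join(dataset.reference_ids) + "\n")
    paths["reference"] = ref_path
    roles_path = outdir / "roles.yaml"
    roles_path.write_text(yaml.safe_dump({"roles": dataset.variable_roles}))
    paths["roles"] = roles_path
    return paths


def file_digest(path: str | Path) -> str:
    """SHA-256 of a file, for the run manifest."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
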