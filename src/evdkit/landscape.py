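"""Virtual monitoring landscapes with known species niches.

The generator draws continuous environmental gradients (optionally
correlated through a Gaussian copula), computes each species' true
occurrence probability from a quadratic-logit niche model on the
standardized scale — the same model family the fitting stage estimates —
and samples presence/absence as Bernoulli draws, optionally thinned by an
imperfect detection probability. Because the generating coefficients are
known, every downstream quantity (response curve, critical level, stressor
ranking) has an exact ground truth to validate against.

Reference sites are picked as the least-stressed sites by mean standardized
stress over the stressor-role variables, a pragmatic stand-in for
field-based reference-site designation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .curves import ResponseCurve, _insert_value, sweep_grid
from .dataset import (
    DIRECTION_DECREASE,
    DIRECTION_INCREASE,
    ROLE_COVARIATE,
    ROLE_STRESSOR_BOTH,
    ROLE_STRESSOR_DECREASE,
    RunConfig,
    SurveyDataset,
)
from .evd import CriticalLevel, invert_curve


class LandscapeError(ValueError):
    pass


@dataclass
class VariableSpec:
    """Marginal distribution and role of one environmental variable."""

    name: str
    dist: str  # "uniform" | "normal" | "lognormal"
    params: tuple[float, float]  # uniform: (low, high); (log)normal: (mu, sigma)
    role: str = "stressor_increase"

    def ppf(self, u: np.ndarray) -> np.ndarray:
        a, b = self.params
        if self.dist == "uniform":
            return a + (b - a) * u
        if self.dist == "normal":
            return norm.ppf(u, loc=a, scale=b)
        if self.dist == "lognormal":
            return np.exp(norm.ppf(u, loc=a, scale=b))
        raise LandscapeError(f"unknown marginal distribution {self.dist!r}")


@dataclass
class SpeciesSpec:
    """True niche of one species on the standardized environmental scale."""

    name: str
    beta0: float
    linear: dict[str, float] = field(default_factory=dict)
    quadratic: dict[str, float] = field(default_factory=dict)
    detection: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 < self.detection <= 1.0):
            raise LandscapeError(f"detection must be in (0, 1], got {self.detection}")


@dataclass
class VirtualLandscapeSpec:
    """Full recipe for one virtual landscape."""

    n_sites: int
    variables: list[VariableSpec]
    species: list[SpeciesSpec]
    n_reference: int
    reference_rule: str = "low_stress_quantile"  # or "random"
    correlation: np.ndarray | None = None  # among variables, Gaussian-copula scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reference >= self.n_sites:
            raise LandscapeError("n_reference must be smaller than n_sites")
        if self.correlation is not None:
            C = np.asarray(self.correlation, float)
            if C.shape != (len(self.variables), len(self.variables)):
                raise LandscapeError("correlation matrix shape does not match the variable list")
            if np.linalg.eigvalsh(C).min() <= 0:
                raise LandscapeError("correlation matrix must be positive definite")
            self.correlation = C

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    @property
    def roles(self) -> dict[str, str]:
        return {v.name: v.role for v in self.variables}


@dataclass
class VirtualLandscape:
    """A realized landscape: the survey dataset plus its generating truth.

    Ground-truth curves and critical levels depend on the realized
    environment (niches are expressed on the standardized scale of the
    generated sample), so they live here rather than on the bare spec.
    """

    spec: VirtualLandscapeSpec
    dataset: SurveyDataset
    true_prob: pd.DataFrame  # site x species occurrence probability
    means: dict[str, float]  # standardization used by the generating model
    sds: dict[str, float]

    def standardize_values(self, variable: str, values):
        return (np.asarray(values, float) - self.means[variable]) / self.sds[variable]

    def _species_by_name(self) -> dict[str, SpeciesSpec]:
        return {s.name: s for s in self.spec.species}

    def true_response_curve(
        self,
        site_id: str,
        stressor: str,
        grid: np.ndarray | None = None,
        config: RunConfig | None = None,
        all_species_mode: bool = False,
    ) -> ResponseCurve:
        """Exact RSR curve from the generating coefficients (no fitting),
        with the same stacking and normalization rules as the pipeline."""
        config = config or RunConfig()
        env_row = self.dataset.env.loc[site_id]
        observed = float(env_row[stressor])
        if grid is None:
            grid = sweep_grid(
                self.dataset.env, stressor, config.sweep_quantiles, config.sweep_points,
                bounds=config.variable_bounds.get(stressor),
            )
        grid = _insert_value(np.asarray(grid, float), observed)

        if all_species_mode:
            pool = [s.name for s in self.spec.species]
        else:
            present = self.dataset.occ.loc[site_id]
            pool = [s.name for s in self.spec.species if present.get(s.name, 0) == 1]
        if not pool:
            raise LandscapeError(f"site {site_id!r} has an empty species pool")

        z_row = {v: self.standardize_values(v, env_row[v]) for v in self.spec.variable_names}
        z_sweep = self.standardize_values(stressor, grid)
        specs = self._species_by_name()
        richness = np.zeros(len(grid))
        for name in pool:
            sp = specs[name]
            eta = np.full(len(grid), sp.beta0)
            for v in self.spec.variable_names:
                z = z_sweep if v == stressor else np.full(len(grid), z_row[v])
                eta += sp.linear.get(v, 0.0) * z + sp.quadratic.get(v, 0.0) * z**2
            richness += expit(eta)
        ref = float(richness[np.argmax(grid == observed)])
        if ref < 1e-6:
            raise LandscapeError(f"degenerate true normalization at site {site_id!r}")
        return ResponseCurve(
            site_id=site_id, stressor=stressor, grid=grid, rsr=richness / ref,
            observed_value=observed, richness_at_reference=ref, species_pool=tuple(pool),
        )

    def true_critical_level(
        self,
        site_id: str,
        stressor: str,
        T: float,
        direction: str,
        config: RunConfig | None = None,
        all_species_mode: bool = False,
    ) -> CriticalLevel:
        """First crossing of 1 - T on the true curve, computed on a grid ten
        times denser than the pipeline's sweep."""
        config = config or RunConfig()
        dense = sweep_grid(
            self.dataset.env, stressor, config.sweep_quantiles,
            (config.sweep_points - 1) * 10 + 1,
            bounds=config.variable_bounds.get(stressor),
        )
        curve = self.true_response_curve(
            site_id, stressor, grid=dense, config=config, all_species_mode=all_species_mode
        )
        return invert_curve(curve, T, direction)


def _stress_score(z: pd.DataFrame, roles: dict[str, str]) -> pd.Series:
    """Mean standardized stress per site over stressor-role variables.

    Increase-direction stressors contribute their standardized value,
    decrease-direction ones its negative, both-direction ones its magnitude
    (departure from the regional centre in either direction is stressful).
    """
    parts = []
    for v, role in roles.items():
        if role == ROLE_COVARIATE:
            continue
        if role == ROLE_STRESSOR_DECREASE:
            parts.append(-z[v])
        elif role == ROLE_STRESSOR_BOTH:
            parts.append(z[v].abs())
        else:
            parts.append(z[v])
    if not parts:
        raise LandscapeError("no stressor-role variables to score reference sites by")
    return sum(parts) / len(parts)


def generate(spec: VirtualLandscapeSpec) -> VirtualLandscape:
    """Draw one fully reproducible virtual landscape from its spec."""
    rng = np.random.default_rng(spec.seed)
    n, p = spec.n_sites, len(spec.variables)

    if spec.correlation is not None:
        L = np.linalg.cholesky(spec.correlation)
        gauss = rng.standard_normal((n, p)) @ L.T
        u = norm.cdf(gauss)
    else:
        u = rng.random((n, p))
    site_ids = [f"site{i:05d}" for i in range(n)]
    env = pd.DataFrame(
        {v.name: v.ppf(u[:, j]) for j, v in enumerate(spec.variables)}, index=site_ids
    )
    env.index.name = "site_id"

    means = {v: float(env[v].mean()) for v in env.columns}
    sds = {v: float(env[v].std(ddof=1)) for v in env.columns}
    z = (env - pd.Series(means)) / pd.Series(sds)

    prob = {}
    occ = {}
    for sp in spec.species:
        eta = np.full(n, sp.beta0)
        for v, b in sp.linear.items():
            eta += b * z[v].to_numpy()
        for v, b in sp.quadratic.items():
            eta += b * z[v].to_numpy() ** 2
        pr = expit(eta)
        prob[sp.name] = pr
        occ[sp.name] = (rng.random(n) < pr * sp.detection).astype(np.int8)
    prob = pd.DataFrame(prob, index=site_ids)
    occ = pd.DataFrame(occ, index=site_ids)
    occ.index.name = "site_id"

    if spec.reference_rule == "random":
        ref_ids = list(rng.choice(site_ids, size=spec.n_reference, replace=False))
    elif spec.reference_rule == "low_stress_quantile":
        score = _stress_score(z, spec.roles)
        ref_ids = list(score.nsmallest(spec.n_reference).index)
    else:
        raise LandscapeError(f"unknown reference rule {spec.reference_rule!r}")

    dataset = SurveyDataset(
        env=env, occ=occ, reference_ids=ref_ids, variable_roles=spec.roles
    )
    return VirtualLandscape(spec=spec, dataset=dataset, true_prob=prob, means=means, sds=sds)


# -----------------------------------------------------------------------------
# a ready-made, realistically sized landscape for demos and validation


def demo_spec(
    n_sites: int = 2000,
    n_species: int = 30,
    n_reference: int = 18,
    seed: int = 0,
) -> VirtualLandscapeSpec:
    """A freshwater-flavoured landscape: a lognormal nutrient, a bell-shaped
    acidity optimum, a beneficial habitat-quality index and a drainage-area
    covariate, with species niches drawn once from the given seed.

    Most species get concave (unimodal) responses with optima and breadths
    that vary across the community; a minority respond linearly; intercepts
    vary enough that some species fall under the occurrence filter.
    """
    variables = [
        VariableSpec("total_p", "lognormal", (-1.5, 0.9), "stressor_increase"),
        VariableSpec("ph", "normal", (7.6, 0.7), "stressor_both"),
        VariableSpec("habitat_quality", "normal", (62.0, 14.0), "stressor_decrease"),
        VariableSpec("drainage_area", "lognormal", (4.0, 1.1), "covariate"),
    ]
    rng = np.random.default_rng(seed)
    names = [f"sp{i:03d}" for i in range(n_species)]
    n_rare = max(1, n_species // 10)  # prevalence heterogeneity: some species
    species = []                      # stay under the occurrence filter
    for i, name in enumerate(names):
        linear: dict[str, float] = {}
        quadratic: dict[str, float] = {}
        for var in variables:
            if rng.random() < 0.25:  # this species ignores this variable
                continue
            if rng.random() < 0.7:  # unimodal niche: optimum + breadth in z-units
                opt = rng.normal(0.0, 1.0)
                breadth = rng.uniform(0.8, 2.2)
                scale = rng.uniform(0.6, 1.6)
                quadratic[var.name] = -scale / breadth**2
                linear[var.name] = 2.0 * scale * opt / breadth**2
            else:  # monotone response
                linear[var.name] = rng.normal(0.0, 1.0)
        # bias habitat quality towards beneficial, nutrients towards harmful
        if "habitat_quality" in linear:
            linear["habitat_quality"] += 0.6
        if "total_p" in linear:
            linear["total_p"] -= 0.6
        if i >= n_species - n_rare:
            beta0 = rng.normal(-5.5, 0.4)
        else:
            beta0 = rng.normal(0.3, 1.0)
        species.append(SpeciesSpec(name=name, beta0=beta0, linear=linear, quadratic=quadratic))
    return VirtualLandscapeSpec(
        n_sites=n_sites,
        variables=variables,
        species=species,
        n_reference=n_reference,
        reference_rule="low_stress_quantile",
        seed=seed,
    )


def spec_from_dict(d: dict, default_seed: int = 0) -> VirtualLandscapeSpec:
    """Build a landscape spec from a configuration mapping.

    A mapping with explicit ``variables`` and ``species`` lists is taken
    verbatim; otherwise the entries are treated as size knobs for
    :func:`demo_spec`.
    """
    if "variables" in d or "species" in d:
        variables = [
            VariableSpec(
                name=v["name"], dist=v["dist"], params=tuple(v["params"]),
                role=v.get("role", "stressor_increase"),
            )
            for v in d["variables"]
        ]
        species = [
            SpeciesSpec(
                name=s["name"], beta0=float(s["beta0"]),
                linear={k: float(b) for k, b in (s.get("linear") or {}).items()},
                quadratic={k: float(b) for k, b in (s.get("quadratic") or {}).items()},
                detection=float(s.get("detection", 1.0)),
            )
            for s in d["species"]
        ]
        corr = np.asarray(d["correlation"], float) if d.get("correlation") is not None else None
        return VirtualLandscapeSpec(
            n_sites=int(d["n_sites"]),
            variables=variables,
            species=species,
            n_reference=int(d["n_reference"]),
            reference_rule=d.get("reference_rule", "low_stress_quantile"),
            correlation=corr,
            seed=int(d.get("seed", default_seed)),
        )
    return demo_spec(
        n_sites=int(d.get("n_sites", 2000)),
        n_species=int(d.get("n_species", 30)),
        n_reference=int(d.get("n_reference", 18)),
        seed=int(d.get("seed", default_seed)),
    )


def two_stressor_spec(
    n_sites: int = 600,
    n_species: int = 12,
    n_reference: int = 10,
    seed: int = 0,
    dominance: float = 3.0,
) -> VirtualLandscapeSpec:
    """A landscape with one dominant stressor for ranking validation.

    Two increase-direction stressors share the same lognormal regional
    distribution, but every species' response to ``stress_a`` is
    ``dominance`` times steeper than to ``stress_b``, so critical levels for
    the dominant stressor sit much closer to reference conditions and far
    more regional sites exceed them.
    """
    variables = [
        VariableSpec("stress_a", "lognormal", (0.0, 0.7), "stressor_increase"),
        VariableSpec("stress_b", "lognormal", (0.0, 0.7), "stressor_increase"),
        VariableSpec("natural_cov", "normal", (0.0, 1.0), "covariate"),
    ]
    rng = np.random.default_rng(seed)
    species = []
    for i in range(n_species):
        slope_a = -rng.uniform(0.9, 1.5)
        species.append(
            SpeciesSpec(
                name=f"sp{i:03d}",
                beta0=rng.normal(0.8, 0.6),
                linear={
                    "stress_a": slope_a,
                    "stress_b": slope_a / dominance,
                    "natural_cov": rng.normal(0.0, 0.4),
                },
            )
        )
    return VirtualLandscapeSpec(
        n_sites=n_sites, variables=variables, species=species,
        n_reference=n_reference, reference_rule="low_stress_quantile", seed=seed,
    )
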