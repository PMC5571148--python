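"""Per-species distribution models: all-subsets logistic fits, AIC model
averaging, and ROC-AUC accuracy scoring.

Each species' presence/absence is modelled on the logit scale as

    logit P(occurrence) = b0 + sum_n (b_n * z_n + b'_n * z_n**2)

over standardized environmental variables z_n. Every combination of
per-predictor term states {absent, linear, linear+quadratic} is fitted —
3^p candidates, a quadratic term never appearing without its linear term —
candidates are ranked by AIC, and coefficients are averaged with Akaike
weights over the models within `delta_aic` (default 2) units of the best.
Absent terms enter the average as zeros (full, shrinkage-style averaging).
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit
from sklearn.metrics import roc_auc_score

from .screening import ScreenedPredictors

logger = logging.getLogger("evdkit")

ABSENT, LINEAR, QUADRATIC = 0, 1, 2  # per-predictor term states


class FitError(ValueError):
    pass


@dataclass
class CandidateModel:
    """One fitted term-state assignment for one species."""

    terms: tuple[int, ...]  # per predictor: ABSENT / LINEAR / QUADRATIC
    intercept: float
    linear: tuple[float, ...]  # 0.0 where absent
    quadratic: tuple[float, ...]
    log_likelihood: float
    k: int
    aic: float
    converged: bool

    def max_abs_coef(self) -> float:
        return max(
            abs(self.intercept),
            max((abs(c) for c in self.linear), default=0.0),
            max((abs(c) for c in self.quadratic), default=0.0),
        )


@dataclass
class AveragedSDM:
    """AIC-averaged coefficient set for one species, standardized scale."""

    species: str
    predictors: tuple[str, ...]
    intercept: float
    linear: dict[str, float]
    quadratic: dict[str, float]
    n_models_averaged: int
    best_aic: float
    auc: float
    n_presences: int
    n_sites: int
    n_candidates_excluded: int = 0

    def linear_predictor(self, Z: np.ndarray) -> np.ndarray:
        """Logit-scale prediction for standardized rows ``Z`` (n, p)."""
        Z = np.atleast_2d(np.asarray(Z, float))
        bl = np.array([self.linear[v] for v in self.predictors])
        bq = np.array([self.quadratic[v] for v in self.predictors])
        return self.intercept + Z @ bl + (Z**2) @ bq

    def native_coefficients(self, screened: ScreenedPredictors) -> dict[str, float]:
        """Expand the standardized polynomial into native-unit coefficients."""
        out = {"intercept": self.intercept}
        for v in self.predictors:
            m, s = screened.means[v], screened.sds[v]
            bl, bq = self.linear[v], self.quadratic[v]
            out["intercept"] += -bl * m / s + bq * m * m / (s * s)
            out[f"{v}_linear"] = bl / s - 2.0 * bq * m / (s * s)
            out[f"{v}_quadratic"] = bq / (s * s)
        return out


def filter_species(
    occ: pd.DataFrame,
    min_occurrences: int,
    species_universe: Sequence[str] | None = None,
) -> list[str]:
    """Species with at least ``min_occurrences`` presences, optionally
    restricted to a universe (e.g. species observed at reference sites)."""
    counts = occ.sum(axis=0)
    kept = [s for s in occ.columns if counts[s] >= min_occurrences]
    if species_universe is not None:
        universe = set(species_universe)
        kept = [s for s in kept if s in universe]
    if not kept:
        raise FitError(
            f"no species with >= {min_occurrences} occurrences"
            + (" in the requested universe" if species_universe is not None else "")
        )
    return kept


def enumerate_models(predictors: Sequence[str]) -> Iterator[tuple[int, ...]]:
    """Yield all 3^p per-predictor term-state assignments.

    States are {absent, linear, linear+quadratic}; a quadratic term is only
    ever emitted together with its linear term by construction. Enumeration
    order is the lexicographic product, so the intercept-only model comes
    first.
    """
    if not predictors:
        raise FitError("at least one predictor is required")
    yield from itertools.product((ABSENT, LINEAR, QUADRATIC), repeat=len(predictors))


def design_matrix(Z: np.ndarray, terms: tuple[int, ...]) -> np.ndarray:
    """Intercept + active term columns for a term-state assignment."""
    cols = [np.ones(len(Z))]
    for j, state in enumerate(terms):
        if state >= LINEAR:
            cols.append(Z[:, j])
        if state == QUADRATIC:
            cols.append(Z[:, j] ** 2)
    return np.column_stack(cols)


def _unpack(terms: tuple[int, ...], params: np.ndarray) -> tuple[float, tuple, tuple]:
    intercept = float(params[0])
    lin, quad = [], []
    i = 1
    for state in terms:
        if state >= LINEAR:
            lin.append(float(params[i])); i += 1
        else:
            lin.append(0.0)
        if state == QUADRATIC:
            quad.append(float(params[i])); i += 1
        else:
            quad.append(0.0)
    return intercept, tuple(lin), tuple(quad)


def fit_logistic(
    occ_vector: np.ndarray,
    Z: np.ndarray,
    terms: tuple[int, ...],
    use_aicc: bool = False,
) -> CandidateModel:
    """Maximum-likelihood logistic fit of one term-state assignment.

    Fitting is iteratively reweighted least squares (statsmodels GLM with a
    binomial family and logit link), converged when the deviance change
    drops below 1e-8 or after 100 iterations.
    """
    y = np.asarray(occ_vector, float)
    n = len(y)
    n_pres = int(y.sum())
    if n_pres == 0 or n_pres == n:
        raise FitError("response is all-absent or all-present; cannot fit a logistic model")
    X = design_matrix(np.asarray(Z, float), terms)
    k = X.shape[1]
    if n < k + 1:
        raise FitError(f"{n} sites cannot identify {k} parameters")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(maxiter=100, tol=1e-8)
            params = np.asarray(res.params, float)
            llf = float(res.llf)
            converged = bool(getattr(res, "converged", True)) and np.all(np.isfinite(params))
        except Exception:  # perfect separation or a singular IRLS step
            params = np.zeros(k)
            llf = -np.inf
            converged = False
    aic = 2.0 * k - 2.0 * llf
    if use_aicc and n - k - 1 > 0:
        aic += 2.0 * k * (k + 1) / (n - k - 1)
    intercept, lin, quad = _unpack(terms, params)
    return CandidateModel(
        terms=tuple(terms), intercept=intercept, linear=lin, quadratic=quad,
        log_likelihood=llf, k=k, aic=aic, converged=converged,
    )


def average_models(
    candidates: Sequence[CandidateModel],
    delta_aic: float,
    species: str,
    predictors: Sequence[str],
    n_presences: int,
    n_sites: int,
    separation_cap: float = 15.0,
    full_averaging: bool = True,
) -> AveragedSDM:
    """Akaike-weighted coefficient average over the AIC confidence set.

    The confidence set holds every converged candidate within ``delta_aic``
    of the lowest AIC; weights are w_i ∝ exp(-Δ_i / 2). With full averaging
    a term absent from a model contributes zero to its average (the default);
    conditional averaging instead normalizes each term's weight over only
    the models that include it.

    Candidates that failed to converge or show coefficients beyond
    ``separation_cap`` on the standardized scale (a symptom of quasi-complete
    separation) are excluded before ranking, with a logged count.
    """
    if not candidates:
        raise FitError("no candidate models to average")
    usable = [
        c for c in candidates
        if c.converged and np.isfinite(c.aic) and c.max_abs_coef() <= separation_cap
    ]
    n_excluded = len(candidates) - len(usable)
    if n_excluded:
        logger.info("%s: excluded %d non-converged/separated candidates", species, n_excluded)
    if not usable:
        raise FitError(f"{species}: every candidate model failed to converge cleanly")

    best = min(c.aic for c in usable)
    conf = [c for c in usable if c.aic - best <= delta_aic]
    w = np.exp(-0.5 * np.array([c.aic - best for c in conf]))
    w /= w.sum()

    p = len(predictors)
    lin = np.zeros(p)
    quad = np.zeros(p)
    intercept = float(np.sum(w * np.array([c.intercept for c in conf])))
    L = np.array([c.linear for c in conf])        # (m, p), zeros where absent
    Q = np.array([c.quadratic for c in conf])
    if full_averaging:
        lin = w @ L
        quad = w @ Q
    else:
        has_lin = np.array([[s >= LINEAR for s in c.terms] for c in conf], float)
        has_quad = np.array([[s == QUADRATIC for s in c.terms] for c in conf], float)
        with np.errstate(invalid="ignore"):
            lin = np.where(
                (w @ has_lin) > 0, (w[:, None] * L).sum(0) / np.maximum(w @ has_lin, 1e-300), 0.0
            )
            quad = np.where(
                (w @ has_quad) > 0, (w[:, None] * Q).sum(0) / np.maximum(w @ has_quad, 1e-300), 0.0
            )
    return AveragedSDM(
        species=species,
        predictors=tuple(predictors),
        intercept=intercept,
        linear={v: float(b) for v, b in zip(predictors, lin)},
        quadratic={v: float(b) for v, b in zip(predictors, quad)},
        n_models_averaged=len(conf),
        best_aic=float(best),
        auc=float("nan"),
        n_presences=n_presences,
        n_sites=n_sites,
        n_candidates_excluded=n_excluded,
    )


def predict_occurrence(sdm: AveragedSDM, env_row: Sequence[float] | dict) -> float:
    """Occurrence probability for one standardized environment row."""
    if isinstance(env_row, dict):
        missing = [v for v in sdm.predictors if v not in env_row]
        if missing:
            raise FitError(f"missing predictor value(s): {missing}")
        env_row = [env_row[v] for v in sdm.predictors]
    z = np.asarray(env_row, float)
    if z.shape[-1] != len(sdm.predictors):
        raise FitError(f"expected {len(sdm.predictors)} predictor values, got {z.shape[-1]}")
    return float(expit(sdm.linear_predictor(z))[0])


def predict_matrix(sdm: AveragedSDM, Z: np.ndarray) -> np.ndarray:
    """Vectorized occurrence probabilities for standardized rows ``Z``."""
    return expit(sdm.linear_predictor(Z))


def auc(scores: np.ndarray, occ_vector: np.ndarray) -> float:
    """In-sample ROC AUC: the Mann-Whitney probability that a random
    presence outranks a random absence, ties counted one half."""
    y = np.asarray(occ_vector)
    if y.min() == y.max():
        raise FitError("AUC needs both presences and absences")
    return float(roc_auc_score(y, np.asarray(scores, float)))


def fit_species_sdm(
    species: str,
    occ_vector: np.ndarray,
    Z: np.ndarray,
    predictors: Sequence[str],
    delta_aic: float = 2.0,
    use_aicc: bool = False,
    separation_cap: float = 15.0,
    full_averaging: bool = True,
) -> AveragedSDM:
    """All-subsets enumeration, fit, averaging and AUC for one species."""
    y = np.asarray(occ_vector, float)
    candidates = [
        fit_logistic(y, Z, terms, use_aicc=use_aicc) for terms in enumerate_models(predictors)
    ]
    avg = average_models(
        candidates, delta_aic, species, predictors,
        n_presences=int(y.sum()), n_sites=len(y),
        separation_cap=separation_cap, full_averaging=full_averaging,
    )
    avg.auc = auc(predict_matrix(avg, Z), y)
    return avg


def sdm_table(sdms: Sequence[AveragedSDM], screened: ScreenedPredictors | None = None) -> pd.DataFrame:
    """Per-species coefficient/diagnostic table (standardized scale, plus
    native-unit coefficients when standardization parameters are given)."""
    rows = []
    for s in sdms:
        row = {
            "species": s.species,
            "n_presences": s.n_presences,
            "n_models_averaged": s.n_models_averaged,
            "best_aic": s.best_aic,
            "auc": s.auc,
            "intercept": s.intercept,
        }
        for v in s.predictors:
            row[f"{v}_linear"] = s.linear[v]
            row[f"{v}_quadratic"] = s.quadratic[v]
        if screened is not None:
            for key, val in s.native_coefficients(screened).items():
                row[f"native_{key}"] = val
        rows.append(row)
    return pd.DataFrame(rows)
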