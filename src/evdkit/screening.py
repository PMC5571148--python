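"""Collinearity screening and predictor standardization.

Candidate environmental variables are pruned by sequential variance
inflation factor (VIF) elimination: while any candidate's VIF meets or
exceeds the limit (default 5), the single worst offender is removed and all
VIFs are recomputed. Survivors are standardized to zero mean and unit
sample standard deviation over the modelled sites; the standardization
parameters are retained so sweep grids built in native units can be mapped
onto the fitted scale and back.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class ScreeningError(ValueError):
    pass


@dataclass
class ScreenedPredictors:
    """Outcome of VIF screening plus the standardization parameters."""

    kept: list[str]
    dropped: list[tuple[str, float]]  # (variable, VIF at removal)
    means: dict[str, float]
    sds: dict[str, float]

    def standardize_values(self, variable: str, values: np.ndarray | float) -> np.ndarray | float:
        return (values - self.means[variable]) / self.sds[variable]

    def destandardize_values(self, variable: str, values: np.ndarray | float) -> np.ndarray | float:
        return values * self.sds[variable] + self.means[variable]

    def report(self) -> pd.DataFrame:
        rows = [{"variable": v, "status": "kept", "vif": np.nan} for v in self.kept]
        rows += [{"variable": v, "status": "dropped", "vif": vif} for v, vif in self.dropped]
        return pd.DataFrame(rows, columns=["variable", "status", "vif"])


def vif(env: pd.DataFrame, variable: str, candidates: list[str] | None = None) -> float:
    """Variance inflation factor of ``variable`` among ``candidates``.

    1 / (1 - R²) with R² from the intercept-included least-squares
    regression of the variable on all other candidates; +inf when the
    regression is numerically exact.
    """
    if candidates is None:
        candidates = list(env.columns)
    others = [c for c in candidates if c != variable]
    if not others:
        raise ScreeningError("VIF needs at least two candidate variables")
    sub = env[[variable] + others].dropna()
    n, p = len(sub), len(others)
    if n < p + 2:
        raise ScreeningError(
            f"unidentifiable VIF regression for {variable!r}: {n} sites for {p} predictors"
        )
    y = sub[variable].to_numpy(float)
    X = np.column_stack([np.ones(n), sub[others].to_numpy(float)])
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0.0:
        raise ScreeningError(f"variable {variable!r} has zero variance")
    r2 = 1.0 - np.sum(resid**2) / ss_tot
    if r2 >= 1.0 - 1e-12:
        return float("inf")
    return float(1.0 / (1.0 - r2))


def screen(env: pd.DataFrame, candidates: list[str], vif_limit: float = 5.0) -> ScreenedPredictors:
    """Sequentially remove the highest-VIF candidate until all VIFs < limit.

    Ties on the maximum VIF are broken by removing the variable that comes
    later in the input order, so the result is deterministic. The removal
    order and the VIF each variable had when removed are recorded.
    """
    missing = sorted(set(candidates) - set(env.columns))
    if missing:
        raise ScreeningError(f"candidates absent from env table: {missing}")
    kept = list(candidates)
    dropped: list[tuple[str, float]] = []
    while len(kept) >= 2:
        vifs = {v: vif(env, v, kept) for v in kept}
        worst = max(vifs.values())
        if worst < vif_limit:
            break
        # later-in-input-order tie-break: scan from the end
        victim = next(v for v in reversed(kept) if vifs[v] == worst)
        kept.remove(victim)
        dropped.append((victim, worst))
    if not kept:
        raise ScreeningError("VIF screening eliminated every candidate; no model possible")

    sub = env[kept].dropna()
    means = {v: float(sub[v].mean()) for v in kept}
    sds = {v: float(sub[v].std(ddof=1)) for v in kept}
    zero_var = [v for v in kept if not sds[v] > 0]
    if zero_var:
        raise ScreeningError(f"zero-variance column(s): {zero_var}")
    return ScreenedPredictors(kept=kept, dropped=dropped, means=means, sds=sds)


def standardize(env: pd.DataFrame, screened: ScreenedPredictors) -> pd.DataFrame:
    """Standardize the kept columns with the stored (mean, sd) parameters."""
    out = {}
    for v in screened.kept:
        out[v] = (env[v] - screened.means[v]) / screened.sds[v]
    return pd.DataFrame(out, index=env.index)


def destandardize(z: pd.DataFrame, screened: ScreenedPredictors) -> pd.DataFrame:
    """Inverse of :func:`standardize`."""
    out = {}
    for v in z.columns:
        out[v] = z[v] * screened.sds[v] + screened.means[v]
    return pd.DataFrame(out, index=z.index)
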