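"""Ecosystem vulnerability distributions.

Each reference site's response curve is inverted at the impact threshold T:
walking from the point of departure along the stress direction, the first
crossing of RSR = 1 - T gives that site's critical stressor level (linearly
interpolated between grid points). A site whose curve never reaches 1 - T
within the swept range is censored; censored sites stay in the exceedance
denominator, so they dilute, never inflate, apparent risk. The collection
of critical levels over the reference sites is the EVD, summarized by its
empirical exceedance function: the fraction of reference sites whose
critical level a given stressor value has passed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .curves import ResponseCurve
from .dataset import DIRECTION_DECREASE, DIRECTION_INCREASE

SUPPORTED = "supported"
LOW_RESPONSE = "low_response"
COMPLEX_RESPONSE = "complex_response"


class EVDError(ValueError):
    pass


@dataclass
class CriticalLevel:
    """One reference site's threshold stressor level in one direction."""

    site_id: str
    stressor: str
    direction: str
    level: float  # native units; the grid endpoint when censored
    censored: bool
    rsr_at_level: float


@dataclass
class EVD:
    """Per-(stressor, direction) distribution of critical levels."""

    stressor: str
    direction: str
    levels: list[CriticalLevel]
    suitability: str = SUPPORTED

    @property
    def n_sites(self) -> int:
        return len(self.levels)

    @property
    def uncensored(self) -> list[CriticalLevel]:
        return [l for l in self.levels if not l.censored]

    @property
    def range(self) -> tuple[float, float]:
        """(min, max) of uncensored critical levels on the native axis."""
        vals = [l.level for l in self.uncensored]
        if not vals:
            raise EVDError(f"EVD for {self.stressor}/{self.direction} has no uncensored levels")
        return (min(vals), max(vals))

    def exceedance(self, values: np.ndarray | float) -> np.ndarray | float:
        """Fraction of reference sites whose critical level ``values`` has
        passed, moving along the stress direction. Censored sites never
        count as exceeded."""
        v = np.asarray(values, float)
        levels = np.array([l.level for l in self.uncensored])
        if self.direction == DIRECTION_INCREASE:
            counts = (levels[None, ...] <= v.reshape(-1, 1)).sum(axis=1)
        else:
            counts = (levels[None, ...] >= v.reshape(-1, 1)).sum(axis=1)
        out = counts / self.n_sites
        return float(out[0]) if np.isscalar(values) or v.ndim == 0 else out.reshape(v.shape)


def _walk(curve: ResponseCurve, direction: str) -> tuple[np.ndarray, np.ndarray]:
    """Grid and RSR ordered outward from the point of departure."""
    i0 = int(np.argmax(curve.grid == curve.observed_value))
    if direction == DIRECTION_INCREASE:
        return curve.grid[i0:], curve.rsr[i0:]
    if direction == DIRECTION_DECREASE:
        return curve.grid[i0::-1], curve.rsr[i0::-1]
    raise EVDError(f"unknown direction {direction!r}")


def invert_curve(curve: ResponseCurve, T: float, direction: str) -> CriticalLevel:
    """First crossing of RSR = 1 - T along the stress direction.

    The crossing is located on the first grid interval where RSR falls from
    above to at-or-below 1 - T and placed by linear interpolation; with no
    crossing before the grid end the level is censored at the endpoint.
    """
    target = 1.0 - T
    g, r = _walk(curve, direction)
    below = r <= target
    if not below.any() or len(g) < 2:
        return CriticalLevel(
            site_id=curve.site_id, stressor=curve.stressor, direction=direction,
            level=float(g[-1]), censored=True, rsr_at_level=float(r[-1]),
        )
    i = int(np.argmax(below))  # first grid point at or below the target
    if i == 0:
        level = float(g[0])  # departs at (or numerically below) the target
    else:
        frac = (r[i - 1] - target) / (r[i - 1] - r[i])
        level = float(g[i - 1] + frac * (g[i] - g[i - 1]))
    return CriticalLevel(
        site_id=curve.site_id, stressor=curve.stressor, direction=direction,
        level=level, censored=False, rsr_at_level=target,
    )


def count_crossings(curve: ResponseCurve, T: float, direction: str) -> int:
    """Number of times RSR crosses 1 - T along the stress direction."""
    _, r = _walk(curve, direction)
    below = r <= (1.0 - T)
    return int(np.count_nonzero(np.diff(below.astype(int)) != 0))


def build_evd(levels: Sequence[CriticalLevel], stressor: str, direction: str) -> EVD:
    """Assemble per-site critical levels into an EVD.

    Raises when every contributing site is censored (the stressor produces
    no detectable richness response within the swept range — the analogue
    of a variable judged unsuitable for an EVD).
    """
    levels = [l for l in levels if l.stressor == stressor and l.direction == direction]
    if len(levels) < 2:
        raise EVDError(f"an EVD needs >= 2 reference sites; got {len(levels)}")
    if all(l.censored for l in levels):
        raise EVDError(
            f"all {len(levels)} reference sites censored for {stressor}/{direction}; "
            "EVD unsupported"
        )
    return EVD(stressor=stressor, direction=direction, levels=list(levels))


def evd_suitability(
    curves: Sequence[ResponseCurve],
    levels: Sequence[CriticalLevel],
    T: float,
    direction: str,
    low_response_censored_frac: float = 0.5,
    complex_response_frac: float = 0.25,
) -> str:
    """Advisory flag mirroring the judgment that some variables support no
    meaningful EVD: ``low_response`` when most sites never lose enough
    richness within the swept range, ``complex_response`` when many curves
    re-cross the threshold (multi-modal or oscillating responses)."""
    if not levels:
        raise EVDError("no critical levels supplied")
    censored_frac = sum(l.censored for l in levels) / len(levels)
    if censored_frac > low_response_censored_frac:
        return LOW_RESPONSE
    multi = sum(count_crossings(c, T, direction) >= 2 for c in curves)
    if curves and multi / len(curves) > complex_response_frac:
        return COMPLEX_RESPONSE
    return SUPPORTED


def levels_table(evds: Sequence[EVD]) -> pd.DataFrame:
    """Long-format export: one row per (stressor, direction, reference site)."""
    rows = [
        {
            "stressor": e.stressor,
            "direction": e.direction,
            "site_id": l.site_id,
            "critical_level": l.level,
            "censored": l.censored,
            "rsr_at_level": l.rsr_at_level,
        }
        for e in evds
        for l in e.levels
    ]
    return pd.DataFrame(
        rows, columns=["stressor", "direction", "site_id", "critical_level", "censored", "rsr_at_level"]
    )


def exceedance_table(evds: Sequence[EVD], n_points: int = 201) -> pd.DataFrame:
    """Exceedance curves evaluated on each EVD's uncensored-level span."""
    frames = []
    for e in evds:
        lo, hi = e.range
        pad = 0.05 * (hi - lo) if hi > lo else max(abs(hi), 1.0) * 0.05
        grid = np.linspace(lo - pad, hi + pad, n_points)
        frames.append(
            pd.DataFrame(
                {
                    "stressor": e.stressor,
                    "direction": e.direction,
                    "stressor_value": grid,
                    "exceedance": e.exceedance(grid),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
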