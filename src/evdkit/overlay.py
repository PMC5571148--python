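"""Overlay of EVDs with regional stressor levels; site classification and
stressor ranking.

A site whose observed stressor value lies before the EVD range (on the
stress axis) is not at risk: even the most vulnerable reference assemblage
would lose less than the threshold fraction of species there. A value
inside the range (endpoints inclusive) puts the site at risk, and a value
beyond the range implies an impacted status. Stressors are ranked by the
fraction of impacted sites, then at-risk sites; a stressor whose regional
values never reach its EVD range is "not identified" as acting in the
region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataset import DIRECTION_DECREASE, DIRECTION_INCREASE, SurveyDataset
from .evd import EVD

NOT_AT_RISK = "not_at_risk"
AT_RISK = "at_risk"
IMPACTED = "impacted"
CLASSES = (NOT_AT_RISK, AT_RISK, IMPACTED)


class OverlayError(ValueError):
    pass


@dataclass
class OverlayReport:
    """Regional classification for one (stressor, direction)."""

    stressor: str
    direction: str
    classifications: pd.Series  # site_id -> class label
    evd_range: tuple[float, float]
    n_sites: int
    n_excluded: int  # sites lacking a stressor value

    @property
    def fractions(self) -> tuple[float, float, float]:
        counts = self.classifications.value_counts()
        n = self.n_sites
        return tuple(counts.get(c, 0) / n for c in CLASSES)

    @property
    def identified(self) -> bool:
        f_not, f_risk, f_imp = self.fractions
        return (f_risk + f_imp) > 0.0


def classify_sites(evd: EVD, env: pd.DataFrame) -> OverlayReport:
    """Compare every site's observed stressor value with the EVD range.

    For decrease-direction stressors (e.g. a habitat-quality index) the
    stress axis is reversed: lower observed values mean more stress, so a
    value below the EVD minimum is impacted, not safe.
    """
    if evd.stressor not in env.columns:
        raise OverlayError(f"stressor {evd.stressor!r} absent from env table")
    values = env[evd.stressor]
    n_excluded = int(values.isna().sum())
    values = values.dropna().astype(float)
    lo, hi = evd.range
    if evd.direction == DIRECTION_INCREASE:
        labels = np.where(values < lo, NOT_AT_RISK, np.where(values > hi, IMPACTED, AT_RISK))
    elif evd.direction == DIRECTION_DECREASE:
        labels = np.where(values > hi, NOT_AT_RISK, np.where(values < lo, IMPACTED, AT_RISK))
    else:
        raise OverlayError(f"unknown direction {evd.direction!r}")
    return OverlayReport(
        stressor=evd.stressor,
        direction=evd.direction,
        classifications=pd.Series(labels, index=values.index, name="classification"),
        evd_range=(lo, hi),
        n_sites=len(values),
        n_excluded=n_excluded,
    )


_SEVERITY = {NOT_AT_RISK: 0, AT_RISK: 1, IMPACTED: 2}


def combine_directional_reports(a: OverlayReport, b: OverlayReport) -> OverlayReport:
    """Worst-case per-site combination of the two directional reports of a
    both-direction stressor (the single-bar view for ranking figures)."""
    if a.stressor != b.stressor:
        raise OverlayError("cannot combine reports for different stressors")
    common = a.classifications.index.intersection(b.classifications.index)
    sev = np.maximum(
        a.classifications.loc[common].map(_SEVERITY),
        b.classifications.loc[common].map(_SEVERITY),
    )
    inv = {v: k for k, v in _SEVERITY.items()}
    return OverlayReport(
        stressor=a.stressor,
        direction="both",
        classifications=sev.map(inv).rename("classification"),
        evd_range=(min(a.evd_range[0], b.evd_range[0]), max(a.evd_range[1], b.evd_range[1])),
        n_sites=len(common),
        n_excluded=max(a.n_excluded, b.n_excluded),
    )


def rank_stressors(reports: Sequence[OverlayReport]) -> pd.DataFrame:
    """Rank by fraction impacted, ties by fraction at risk, then by name.

    Returns a table with one row per report, a 1-based ``rank`` column and
    an ``identified`` flag (false when the regional values never overlap the
    EVD range).
    """
    if not reports:
        raise OverlayError("no overlay reports to rank")
    rows = []
    for r in reports:
        f_not, f_risk, f_imp = r.fractions
        rows.append(
            {
                "stressor": r.stressor,
                "direction": r.direction,
                "f_not_at_risk": f_not,
                "f_at_risk": f_risk,
                "f_impacted": f_imp,
                "identified": r.identified,
                "evd_min": r.evd_range[0],
                "evd_max": r.evd_range[1],
                "n_sites": r.n_sites,
            }
        )
    table = pd.DataFrame(rows)
    table = table.sort_values(
        ["f_impacted", "f_at_risk", "stressor", "direction"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).reset_index(drop=True)
    table.insert(0, "rank", np.arange(1, len(table) + 1))
    return table


def site_map_table(
    reports: Sequence[OverlayReport], dataset: SurveyDataset
) -> pd.DataFrame:
    """Geo-referenced classification table: (site_id, x, y, stressor,
    direction, classification) for sites with coordinates."""
    if dataset.coords is None or dataset.coords.empty:
        raise OverlayError("dataset has no site coordinates; cannot build a map table")
    rows = []
    n_skipped = 0
    for r in reports:
        for site_id, label in r.classifications.items():
            if site_id not in dataset.coords.index:
                n_skipped += 1
                continue
            x, y = dataset.coords.loc[site_id, ["x", "y"]]
            rows.append(
                {
                    "site_id": site_id,
                    "x": x,
                    "y": y,
                    "stressor": r.stressor,
                    "direction": r.direction,
                    "classification": label,
                }
            )
    import logging

    if n_skipped:
        logging.getLogger("evdkit").info("map table: %d site rows without coordinates omitted", n_skipped)
    return pd.DataFrame(rows, columns=["site_id", "x", "y", "stressor", "direction", "classification"])
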