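"""Richness-evaluation statistics for stacked niche-model predictions.

Implements every summary the stacked-model analysis reports:

* the species-area *z* coefficient recomputed from the predicted/reported
  richness pair and the bounding-box/flora area pair,
  ``z = (log S_pred - log S_rep) / (log A_bbox - log A_flora)`` —
  values far above the classical 0.1-0.35 range indicate that overprediction
  is not an artefact of the boxes being larger than the floras;
* ordinary least-squares regressions of predicted on reported richness,
  overall and within each decadal size class, with Fisher-transform
  confidence intervals for the correlation coefficient (truncated at 0);
* per-flora community confusion matrices over the modelled roster, yielding
  sensitivity a/(a+c) and specificity d/(b+d);
* overprediction ratios S_pred/S_rep and their regression on log area;
* per-species environmental-breadth summaries (mean layer values at
  occurrence cells).

Logarithms are base 10 throughout; z itself is base-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .curation import CuratedOccurrences
from .simulate import EnvLayerSet, FloraSpec
from .stacking import FloraPrediction

__all__ = [
    "ZRecord",
    "ConfusionCounts",
    "RegressionSummary",
    "z_coefficient",
    "build_z_records",
    "species_area_scatter",
    "fit_regression",
    "fisher_ci",
    "confusion_counts",
    "sensitivity",
    "specificity",
    "ratio_area_regression",
    "assign_size_class",
    "niche_breadth_summary",
]


# ---------------------------------------------------------------------------
# species-area z
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ZRecord:
    flora_id: str
    s_pred: int
    s_rep: int
    a_bbox: float
    a_flora: float

    @property
    def z(self) -> float:
        return z_coefficient(self.s_pred, self.s_rep, self.a_bbox, self.a_flora)


def z_coefficient(s_pred: float, s_rep: float, a_bbox: float, a_flora: float) -> float:
    """Species-area slope implied by the predicted/reported pair.

    NaN when either richness is zero (log undefined) or the areas coincide
    (zero denominator).  Negative inputs are rejected.
    """
    if min(s_pred, s_rep) < 0 or a_flora <= 0 or a_bbox < a_flora:
        raise ValueError("require s_pred, s_rep >= 0 and a_bbox >= a_flora > 0")
    if s_pred == 0 or s_rep == 0 or a_bbox == a_flora:
        return float("nan")
    return float(
        (np.log10(s_pred) - np.log10(s_rep)) / (np.log10(a_bbox) - np.log10(a_flora))
    )


def build_z_records(
    preds: list[FloraPrediction],
    floras: dict[str, FloraSpec],
    bbox_areas: dict[str, float],
) -> list[ZRecord]:
    return [
        ZRecord(
            flora_id=p.flora_id,
            s_pred=p.s_pred,
            s_rep=p.s_rep_modeled,
            a_bbox=bbox_areas[p.flora_id],
            a_flora=floras[p.flora_id].area_ha,
        )
        for p in preds
    ]


def species_area_scatter(records: list[ZRecord]) -> pd.DataFrame:
    """Per-flora (delta logA, delta logS) pairs where both are defined."""
    rows = []
    for r in records:
        if not np.isnan(r.z):
            rows.append(
                {
                    "flora_id": r.flora_id,
                    "dlog_area": np.log10(r.a_bbox) - np.log10(r.a_flora),
                    "dlog_richness": np.log10(r.s_pred) - np.log10(r.s_rep),
                }
            )
    return pd.DataFrame(rows, columns=["flora_id", "dlog_area", "dlog_richness"])


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------


@dataclass
class RegressionSummary:
    label: str
    n: int
    slope: float
    intercept: float
    r_squared: float
    r: float
    r_ci: tuple[float, float]
    reason: str | None = None  # set when the fit is degenerate


def fit_regression(
    s_rep: np.ndarray, s_pred: np.ndarray, label: str = "all", ci_level: float = 0.95
) -> RegressionSummary:
    """OLS of predicted on reported richness for one flora subset."""
    s_rep = np.asarray(s_rep, dtype=float)
    s_pred = np.asarray(s_pred, dtype=float)
    n = s_rep.size
    if n < 3:
        raise ValueError("need at least 3 floras for a regression")
    if np.ptp(s_rep) == 0:
        return RegressionSummary(
            label, n, np.nan, np.nan, np.nan, np.nan, (np.nan, np.nan),
            reason="zero variance in reported richness",
        )
    res = stats.linregress(s_rep, s_pred)
    r = float(res.rvalue)
    ci = fisher_ci(r, n, level=ci_level) if n >= 4 else (np.nan, np.nan)
    return RegressionSummary(
        label=label,
        n=n,
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=r * r,
        r=r,
        r_ci=ci,
    )


def fisher_ci(r: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Fisher-transform confidence interval for r, truncated below at 0.

    ``tanh(atanh(r) +- z_{alpha/2} / sqrt(n - 3))``; any negative bound is
    replaced by 0, following the truncation convention used when plotting
    correlation trends across size classes.
    """
    if n < 4:
        raise ValueError("Fisher interval requires n >= 4")
    if abs(r) >= 1:
        return (r, r)
    zeta = np.arctanh(r)
    half = stats.norm.ppf(0.5 + level / 2.0) / np.sqrt(n - 3)
    lo, hi = np.tanh(zeta - half), np.tanh(zeta + half)
    return (float(max(lo, 0.0)), float(max(hi, 0.0)))


def regressions_by_size_class(
    preds: list[FloraPrediction], floras: dict[str, FloraSpec]
) -> list[RegressionSummary]:
    """One regression for all floras plus one per decadal size class."""
    df = pd.DataFrame(
        {
            "s_rep": [p.s_rep_modeled for p in preds],
            "s_pred": [p.s_pred for p in preds],
            "size_class": [floras[p.flora_id].size_class for p in preds],
        }
    )
    out = [fit_regression(df["s_rep"], df["s_pred"], label="all")]
    for k, sub in df.groupby("size_class", sort=True):
        if len(sub) >= 3:
            out.append(
                fit_regression(sub["s_rep"], sub["s_pred"], label=f"10^{k}")
            )
    return out


# ---------------------------------------------------------------------------
# confusion matrices
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ConfusionCounts:
    """Community confusion matrix over the modelled roster for one flora.

    a: predicted present & reported; b: predicted present & unreported;
    c: predicted absent & reported;  d: predicted absent & unreported.
    """

    flora_id: str
    a: int
    b: int
    c: int
    d: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


def confusion_counts(
    pred: FloraPrediction, flora: FloraSpec, roster: set[str]
) -> ConfusionCounts:
    reported = flora.reported_species & roster
    predicted = set(pred.predicted_species) & roster
    a = len(predicted & reported)
    b = len(predicted - reported)
    c = len(reported - predicted)
    d = len(roster) - a - b - c
    return ConfusionCounts(flora_id=pred.flora_id, a=a, b=b, c=c, d=d)


def sensitivity(cc: ConfusionCounts) -> float:
    """a/(a+c); NaN for floras with no reported presences."""
    return cc.a / (cc.a + cc.c) if (cc.a + cc.c) > 0 else float("nan")


def specificity(cc: ConfusionCounts) -> float:
    """d/(b+d); NaN when every modelled species is reported."""
    return cc.d / (cc.b + cc.d) if (cc.b + cc.d) > 0 else float("nan")


# ---------------------------------------------------------------------------
# overprediction ratios
# ---------------------------------------------------------------------------


def ratio_area_regression(
    preds: list[FloraPrediction], floras: dict[str, FloraSpec]
) -> tuple[pd.DataFrame, RegressionSummary | None, dict[str, float]]:
    """Overprediction ratios and their trend with flora area.

    Returns the per-flora ratio table (floras with both richnesses > 0),
    the OLS fit of log10 ratio on log10 area (None when fewer than 3 floras
    qualify), and summary factors: the mean of per-flora ratios (headline
    overprediction factor), its reciprocal companion, and the ratio of
    summed richnesses.
    """
    rows = []
    for p in preds:
        if p.s_pred > 0 and p.s_rep_modeled > 0:
            rows.append(
                {
                    "flora_id": p.flora_id,
                    "area_ha": floras[p.flora_id].area_ha,
                    "s_pred": p.s_pred,
                    "s_rep": p.s_rep_modeled,
                    "ratio_pred_over_rep": p.s_pred / p.s_rep_modeled,
                    "ratio_rep_over_pred": p.s_rep_modeled / p.s_pred,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "flora_id", "area_ha", "s_pred", "s_rep",
            "ratio_pred_over_rep", "ratio_rep_over_pred",
        ],
    )
    summary = {}
    reg = None
    if len(table):
        summary["mean_ratio_pred_over_rep"] = float(
            table["ratio_pred_over_rep"].mean()
        )
        summary["mean_ratio_rep_over_pred"] = float(
            table["ratio_rep_over_pred"].mean()
        )
        summary["pooled_ratio_pred_over_rep"] = float(
            table["s_pred"].sum() / table["s_rep"].sum()
        )
    if len(table) >= 3:
        reg = fit_regression(
            np.log10(table["area_ha"]),
            np.log10(table["ratio_pred_over_rep"]),
            label="log-ratio vs log-area",
        )
    return table, reg, summary


# ---------------------------------------------------------------------------
# size classes and niche breadth
# ---------------------------------------------------------------------------


def assign_size_class(area_ha: float) -> int:
    """Decadal class exponent k with 10^(k-1) < area <= 10^k, k in 2..7."""
    if not 10.0 < area_ha <= 1e7:
        raise ValueError(f"area {area_ha} ha outside the classed range (10, 1e7]")
    k = int(np.ceil(np.log10(area_ha)))
    # exact powers of ten belong to their own class (upper bound inclusive)
    if 10.0**k < area_ha:  # pragma: no cover - guards float rounding
        k += 1
    return max(k, 2)


def niche_breadth_summary(
    curated: list[CuratedOccurrences],
    env: EnvLayerSet,
    variables: list[str] | None = None,
) -> pd.DataFrame:
    """Per-species mean of selected layers over kept occurrence cells.

    The spread of these means across a guild summarises its environmental
    breadth: generalist guilds scatter widely, specialists cluster.
    """
    variables = variables if variables is not None else env.names
    missing = [v for v in variables if v not in env.layers]
    if missing:
        raise KeyError(f"unknown layers requested: {missing}")
    rows = []
    for cur in curated:
        if cur.n_kept == 0:
            continue
        vals = env.values_at(cur.kept_cells, variables)
        rows.append(
            {"species_id": cur.species_id}
            | {v: float(np.nanmean(vals[:, j])) for j, v in enumerate(variables)}
        )
    return pd.DataFrame(rows, columns=["species_id", *variables])
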