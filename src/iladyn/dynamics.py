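"""The per-person emotion-dynamics battery: 11 measures per method.

Measures
--------
* ``pa_mean`` / ``na_mean`` -- mean level
* ``pa_sd`` / ``na_sd`` -- variability (within-person sample SD, n-1)
* ``pa_rmssd`` / ``na_rmssd`` -- instability (root mean square successive
  difference over lag pairs retained by the method's gap rules)
* ``pa_inertia`` / ``na_inertia`` -- person-specific autoregressive slope,
  estimated as empirical-Bayes slopes of a multilevel random-slope model
* ``density`` -- emotion network density: sum of absolute values of the
  person's 2 autoregressive and 2 cross-lagged EB parameters
* ``mixed_emotions`` -- MIN index, mean over time of (PA+NA) - |PA-NA|
* ``dialecticism`` -- within-person correlation of PA and NA

Mean/SD/RMSSD/MIN/dialecticism are computed independently per person;
inertia and density pool all persons of one method through the
multilevel engine.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import (
    Affect,
    LagPair,
    PersonSeries,
    StudyDataset,
    lagged_pairs,
    method_lag_rules,
)
from .multilevel import MixedModelSpec, fit_random_slope_model

__all__ = [
    "MEASURE_COLUMNS",
    "mean_level",
    "variability",
    "instability",
    "min_index",
    "mixed_emotions",
    "dialecticism",
    "inertia",
    "network_density",
    "compute_profiles",
]

MEASURE_COLUMNS = [
    "pa_mean",
    "na_mean",
    "pa_sd",
    "na_sd",
    "pa_rmssd",
    "na_rmssd",
    "pa_inertia",
    "na_inertia",
    "density",
    "mixed_emotions",
    "dialecticism",
]


def mean_level(s: PersonSeries, affect: Affect | str) -> float:
    """Arithmetic mean of the person's ratings."""
    values = s.values(affect)
    if not values:
        raise ValueError("empty series")
    return float(np.mean(values))


def variability(s: PersonSeries, affect: Affect | str) -> float:
    """Within-person sample SD (n-1 denominator); NaN below 2 observations."""
    values = s.values(affect)
    if len(values) < 2:
        return math.nan
    return float(np.std(values, ddof=1))


def instability(
    s: PersonSeries, pairs: Iterable[LagPair], affect: Affect | str
) -> float:
    """RMSSD over retained lag pairs; NaN when no pair survives the rules."""
    diffs = [p.diff(affect) for p in pairs]
    if not diffs:
        return math.nan
    return float(np.sqrt(np.mean(np.square(diffs))))


def min_index(pa: float, na: float) -> float:
    """Pointwise mixed-emotions score: total affect minus polarity."""
    return (pa + na) - abs(pa - na)


def mixed_emotions(s: PersonSeries) -> float:
    """Mean MIN index over the person's time points (0-200 scale)."""
    if len(s) == 0:
        raise ValueError("empty series")
    return float(
        np.mean([min_index(o.pa, o.na) for o in s.observations])
    )


def dialecticism(s: PersonSeries, rank: bool = False) -> float:
    """Within-person PA-NA correlation; NaN if either affect is constant.

    Values near -1 indicate bipolarity; near 0 or above, co-occurrence.
    ``rank=True`` switches to a Spearman correlation.
    """
    if len(s) < 3:
        return math.nan
    pa = np.asarray(s.values(Affect.PA))
    na = np.asarray(s.values(Affect.NA))
    if np.std(pa) == 0 or np.std(na) == 0:
        return math.nan
    if rank:
        return float(stats.spearmanr(pa, na).statistic)
    return float(np.corrcoef(pa, na)[0, 1])


# ---------------------------------------------------------------------------
# multilevel measures (pooled over persons within one method)


def _lag_rows(
    series_map: Mapping[str, PersonSeries],
    max_gap_hours,
    cross_day_rule,
) -> pd.DataFrame:
    rows = []
    for pid in sorted(series_map):
        for p in lagged_pairs(series_map[pid], max_gap_hours, cross_day_rule):
            rows.append(
                {
                    "person_id": pid,
                    "prev_pa": p.prev.pa,
                    "prev_na": p.prev.na,
                    "next_pa": p.next.pa,
                    "next_na": p.next.na,
                    "gap_hours": p.gap_hours,
                }
            )
    return pd.DataFrame(
        rows,
        columns=["person_id", "prev_pa", "prev_na", "next_pa", "next_na", "gap_hours"],
    )


def inertia(
    series_map: Mapping[str, PersonSeries],
    affect: Affect | str,
    center: bool = True,
    lag_rules: dict | None = None,
) -> pd.Series:
    """EB autoregressive slope per person for one affect.

    Fits next-rating on previous-rating with a random intercept and a
    random slope; the lag predictor is within-person centered by default
    so the slope is not conflated with the person's mean level.
    """
    a = Affect(affect).value
    if lag_rules is None:
        method = next(iter(series_map.values())).method
        lag_rules = method_lag_rules(method)
    rows = _lag_rows(series_map, **lag_rules)
    spec = MixedModelSpec(
        outcome=f"next_{a}", predictors=(f"prev_{a}",), center_within=center
    )
    fit = fit_random_slope_model(rows, spec)
    return fit.eb[f"prev_{a}"].rename(f"{a}_inertia")


def network_density(
    series_map: Mapping[str, PersonSeries],
    center: bool = True,
    lag_rules: dict | None = None,
) -> pd.Series:
    """Per-person network density over both affects.

    Two multilevel models are fit -- PA and NA each regressed on the
    lagged PA and lagged NA ratings entered simultaneously as
    within-person centered predictors, with random slopes. Density is the
    sum of the absolute values of the person's 4 EB lagged parameters.
    """
    if lag_rules is None:
        method = next(iter(series_map.values())).method
        lag_rules = method_lag_rules(method)
    rows = _lag_rows(series_map, **lag_rules)
    total = None
    for outcome in ("next_pa", "next_na"):
        spec = MixedModelSpec(
            outcome=outcome, predictors=("prev_pa", "prev_na"), center_within=center
        )
        fit = fit_random_slope_model(rows, spec)
        part = fit.eb[["prev_pa", "prev_na"]].abs().sum(axis=1)
        total = part if total is None else total.add(part, fill_value=np.nan)
    return total.rename("density")


# ---------------------------------------------------------------------------
# full battery


def compute_profiles(
    dataset: StudyDataset,
    center_inertia: bool = True,
    rank_dialecticism: bool = False,
) -> pd.DataFrame:
    """All 11 measures per (person, method), plus observation counts.

    DRM series must already carry midpoint timestamps (the ingest layer
    does this). Inertia and density pool persons per method; the dataset
    should have passed the inclusion filter first.
    """
    records = []
    for method in dataset.methods():
        series_map = dataset.series_for_method(method)
        rules = method_lag_rules(method)
        pairs_map = {
            pid: lagged_pairs(s, **rules) for pid, s in series_map.items()
        }
        inert = {
            a: inertia(series_map, a, center=center_inertia, lag_rules=rules)
            for a in ("pa", "na")
        }
        dens = network_density(series_map, center=center_inertia, lag_rules=rules)
        for pid in sorted(series_map):
            s = series_map[pid]
            pairs = pairs_map[pid]
            gaps = [p.gap_hours for p in pairs]
            records.append(
                {
                    "person_id": pid,
                    "method": method.value,
                    "pa_mean": mean_level(s, "pa"),
                    "na_mean": mean_level(s, "na"),
                    "pa_sd": variability(s, "pa"),
                    "na_sd": variability(s, "na"),
                    "pa_rmssd": instability(s, pairs, "pa"),
                    "na_rmssd": instability(s, pairs, "na"),
                    "pa_inertia": inert["pa"].get(pid, np.nan),
                    "na_inertia": inert["na"].get(pid, np.nan),
                    "density": dens.get(pid, np.nan),
                    "mixed_emotions": mixed_emotions(s),
                    "dialecticism": dialecticism(s, rank=rank_dialecticism),
                    "n_obs": len(s),
                    "n_pairs": len(pairs),
                    "mean_gap_hours": float(np.mean(gaps)) if gaps else math.nan,
                }
            )
    df = pd.DataFrame(records)
    return df.sort_values(["method", "person_id"]).reset_index(drop=True)
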