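"""Radar-area soil quality index (SQI).

Each soil indicator is rescaled to a linear score SL_i in [0, 1] by a
direction-aware min-max transform computed within one depth layer.  The
scores are laid out as spokes of a radar chart with n equally spaced axes
and summarised by the area-style index

    SQI = 0.5 * sum_i SL_i^2 * sin(2*pi/n)

Each spoke contributes its own squared term, so the index is invariant to
indicator ordering.  A literal polygon area would instead use adjacent
products SL_i * SL_{i+1}; that variant is available behind an explicit
flag but is not the default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_INDICATORS",
    "IndicatorScoreSet",
    "SQIResult",
    "linear_score",
    "sqi_area",
    "sqi_pipeline",
]

#: Default SQI indicator set: the 11 physicochemical variables plus the
#: six hydrolase activities.  Fully configurable per call.
PHYSICOCHEMICAL = (
    "SOC", "TN", "MBC", "MBN", "DOC", "DON", "AHN", "AP", "AK", "BD", "SW",
)
ENZYMES = ("BG", "CB", "XYL", "NAG", "LAP", "ALP")
DEFAULT_INDICATORS = PHYSICOCHEMICAL + ENZYMES

#: Direction defaults: every indicator is scored more-is-better.  Whether
#: bulk density and dissolved organic N should be reverse-scored is an
#: open modelling choice; an alternative direction map for sensitivity
#: analysis treats BD as less-is-better.
DEFAULT_DIRECTIONS: dict[str, str] = {name: "more" for name in DEFAULT_INDICATORS}
BD_REVERSED_DIRECTIONS = {**DEFAULT_DIRECTIONS, "BD": "less"}

_VALID_DIRECTIONS = {"more", "less", "more-is-better", "less-is-better"}


@dataclass
class IndicatorScoreSet:
    """Per-sample linear scores for one depth layer."""

    depth: str
    indicator_names: list[str]
    directions: dict[str, str]
    raw_values: pd.DataFrame  # samples x indicators
    scores: pd.DataFrame  # samples x indicators, each in [0, 1]


@dataclass
class SQIResult:
    """Per-sample radar-area SQI for one depth layer."""

    depth: str
    n_indicators: int
    sqi: pd.Series  # indexed by (treatment, replicate)
    scores: IndicatorScoreSet
    treatment_means: pd.Series
    percent_change_vs_reference: pd.Series


def linear_score(values, direction: str = "more") -> np.ndarray:
    """Direction-aware min-max linear score onto [0, 1].

    ``direction`` is ``"more"`` (more-is-better) or ``"less"``; min and
    max are taken over the supplied samples, which should come from a
    single depth layer.  A constant column carries no ranking information:
    all its scores are set to the neutral value 0.5 and a warning is
    emitted, which keeps the indicator count stable across depths.
    """
    if direction not in _VALID_DIRECTIONS:
        raise ValueError(f"unknown scoring direction {direction!r}")
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("min-max scoring needs at least 2 samples")
    lo, hi = x.min(), x.max()
    if hi == lo:
        warnings.warn(
            "constant indicator column: all scores set to neutral 0.5",
            stacklevel=2,
        )
        return np.full_like(x, 0.5)
    if direction.startswith("more"):
        return (x - lo) / (hi - lo)
    return (hi - x) / (hi - lo)


def sqi_area(scores, *, polygon: bool = False) -> float:
    """Radar-area soil quality index of a score vector.

    With ``polygon=False`` (default) returns 0.5 * sum(SL_i^2) * sin(2pi/n),
    the per-spoke form, which is order-invariant.  With ``polygon=True``
    returns the literal radar polygon area 0.5 * sum(SL_i*SL_{i+1}) *
    sin(2pi/n) over adjacent spokes (cyclic), which depends on ordering.
    """
    s = np.asarray(scores, dtype=float)
    n = s.size
    if n < 3:
        raise ValueError(f"radar area needs n >= 3 indicators, got {n}")
    if np.any(s < 0) or np.any(s > 1):
        raise ValueError("scores must lie in [0, 1]")
    sin_term = math.sin(2 * math.pi / n)
    if polygon:
        return 0.5 * float(np.sum(s * np.roll(s, -1))) * sin_term
    return 0.5 * float(np.sum(s * s)) * sin_term


def sqi_max(n: int) -> float:
    """Upper bound of the index for n indicators (all scores 1)."""
    return 0.5 * n * math.sin(2 * math.pi / n)


def score_indicators(
    wide: pd.DataFrame,
    depth: str,
    indicators=DEFAULT_INDICATORS,
    directions: dict[str, str] | None = None,
) -> IndicatorScoreSet:
    """Min-max score the named indicators within one depth layer.

    ``wide`` is a samples x variables table indexed by (treatment,
    replicate, depth).  Scoring never pools across depths.
    """
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    sub = wide.xs(depth, level="depth")
    missing = [
        c for c in indicators if c not in sub.columns or sub[c].isna().all()
    ]
    if missing:
        raise KeyError(f"indicators absent at depth {depth!r}: {missing}")
    if sub[list(indicators)].isna().any().any():
        incomplete = sub.columns[sub[list(indicators)].isna().any()].tolist()
        raise KeyError(f"indicators with missing samples at depth {depth!r}: {incomplete}")
    raw = sub[list(indicators)]
    scores = pd.DataFrame(
        {
            name: linear_score(raw[name].to_numpy(), directions.get(name, "more"))
            for name in indicators
        },
        index=raw.index,
    )
    return IndicatorScoreSet(
        depth=depth,
        indicator_names=list(indicators),
        directions=directions,
        raw_values=raw,
        scores=scores,
    )


def sqi_pipeline(
    dataset,
    indicators=DEFAULT_INDICATORS,
    directions: dict[str, str] | None = None,
    reference: str = "CK",
    *,
    polygon: bool = False,
) -> dict[str, SQIResult]:
    """Score indicators and compute per-sample SQI for every depth layer.

    Returns a mapping depth -> :class:`SQIResult` with per-sample index
    values, treatment means, and percent change of each treatment mean
    relative to the ``reference`` treatment.
    """
    wide = dataset.to_wide()
    depths = wide.index.get_level_values("depth").unique()
    results: dict[str, SQIResult] = {}
    for depth in depths:
        sub = wide.xs(depth, level="depth")
        present = [c for c in indicators if c in sub.columns and sub[c].notna().any()]
        if not present:
            # layers without soil indicators (e.g. plot-level yield rows)
            continue
        scored = score_indicators(wide, depth, indicators, directions)
        sqi = scored.scores.apply(
            lambda row: sqi_area(row.to_numpy(), polygon=polygon), axis=1
        )
        sqi.name = "SQI"
        means = sqi.groupby(level="treatment").mean()
        if reference not in means.index:
            raise KeyError(f"reference treatment {reference!r} not in dataset")
        ref = means[reference]
        pct = (means - ref) / ref * 100.0
        results[depth] = SQIResult(
            depth=depth,
            n_indicators=len(scored.indicator_names),
            sqi=sqi,
            scores=scored,
            treatment_means=means,
            percent_change_vs_reference=pct,
        )
    return results
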