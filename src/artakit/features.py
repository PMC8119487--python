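"""Threshold feature arrays and chi-square pattern comparison.

A feature array summarizes an ARTA as a contingency-style count of its
grid points: each predicted threshold (one per prediction age and
frequency) is classified by hearing-loss degree and by frequency band
(low / mid / high), and the counts per (degree, band) cell form the
array.  Two progression patterns are compared by a chi-square
goodness-of-fit test of one array against the cell proportions of the
other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .arta import ArtaResults
from .audiogram import DEFAULT_DEGREE_SCALE, DegreeScale

__all__ = [
    "FrequencyBands",
    "FeatureArray",
    "DEFAULT_BANDS",
    "BAND_ORDER",
    "assign_band",
    "build_feature_array",
    "profile_feature_array",
    "compare_feature_arrays",
]

BAND_ORDER: Tuple[str, ...] = ("lf", "mf", "hf")


@dataclass(frozen=True)
class FrequencyBands:
    """Mapping from test frequency (kHz) to band label lf / mf / hf."""

    mapping: Mapping[float, str]

    def __post_init__(self) -> None:
        bad = {b for b in self.mapping.values() if b not in BAND_ORDER}
        if bad:
            raise ValueError(f"unknown band labels: {sorted(bad)}")

    def __getitem__(self, freq_khz: float) -> str:
        f = float(freq_khz)
        if f not in self.mapping:
            raise KeyError(
                f"frequency {f} kHz has no band assignment "
                f"(mapped: {sorted(self.mapping)})"
            )
        return self.mapping[f]


#: Symmetric two-per-band split of the six ARTA frequencies.
DEFAULT_BANDS = FrequencyBands(
    {0.25: "lf", 0.5: "lf", 1.0: "mf", 2.0: "mf", 4.0: "hf", 8.0: "hf"}
)


def assign_band(freq_khz: float, bands: FrequencyBands = DEFAULT_BANDS) -> str:
    """Band label for a frequency; raises KeyError if unmapped."""
    return bands[freq_khz]


@dataclass
class FeatureArray:
    """Counts of ARTA grid points per (degree class, frequency band)."""

    counts: pd.DataFrame  # rows: degree classes, columns: bands

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("feature array counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    def to_csv(self, path) -> None:
        self.counts.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "FeatureArray":
        return cls(pd.read_csv(path, index_col=0))


def build_feature_array(
    results: ArtaResults,
    scale: DegreeScale = DEFAULT_DEGREE_SCALE,
    bands: FrequencyBands = DEFAULT_BANDS,
    include_normal: bool = True,
) -> FeatureArray:
    """Tally ARTA grid points into (degree class, band) cells.

    Every predicted threshold at every (prediction age, frequency) pair
    contributes exactly one count, so the total equals
    ``len(prediction_ages) * len(fitted frequencies)`` (48 under the
    defaults: 8 decade ages x 6 frequencies).
    """
    pred = results.predict()
    labels = list(scale.labels)
    if not include_normal:
        labels = [l for l in labels if l != "normal"]
    counts = pd.DataFrame(
        0, index=pd.Index(labels, name="degree"), columns=list(BAND_ORDER)
    )
    for f in pred.columns:
        band = bands[f]
        for t in pred[f]:
            degree = scale.classify(t)
            if degree in counts.index:
                counts.loc[degree, band] += 1
    return FeatureArray(counts)


def profile_feature_array(
    profile,
    ages: Sequence[float] = (10, 20, 30, 40, 50, 60, 70, 80),
    scale: DegreeScale = DEFAULT_DEGREE_SCALE,
    bands: FrequencyBands = DEFAULT_BANDS,
    include_normal: bool = True,
) -> FeatureArray:
    """Feature array implied by a progression profile's trend lines.

    Each frequency's line ``baseline + atd * (age - onset)`` is
    evaluated at the prediction ages and tallied exactly like a fitted
    ARTA grid; this is the noise-free reference pattern for a profile.
    """
    labels = list(scale.labels)
    if not include_normal:
        labels = [l for l in labels if l != "normal"]
    counts = pd.DataFrame(
        0, index=pd.Index(labels, name="degree"), columns=list(BAND_ORDER)
    )
    for f in profile.freqs:
        band = bands[f]
        for a in ages:
            t = profile.baseline_db[f] + profile.atd_db_per_year[f] * (
                a - profile.onset_age_years
            )
            degree = scale.classify(t)
            if degree in counts.index:
                counts.loc[degree, band] += 1
    return FeatureArray(counts)


def compare_feature_arrays(
    observed: FeatureArray,
    reference: FeatureArray,
    alpha: float = 0.05,
    min_expected: float = 1.0,
) -> Dict[str, object]:
    """Chi-square goodness of fit of one pattern against another.

    Expected counts are the reference's cell proportions scaled to the
    observed total.  Cells whose expected count falls below
    ``min_expected`` are pooled into a single remainder cell before the
    test (the classical validity guard for sparse goodness-of-fit
    tables); degrees of freedom are (#retained cells - 1).

    Returns ``{"chi2", "df", "p", "different"}`` with ``different``
    true when p < alpha.
    """
    if observed.counts.shape != reference.counts.shape or not (
        observed.counts.index.equals(reference.counts.index)
        and observed.counts.columns.equals(reference.counts.columns)
    ):
        raise ValueError("observed and reference arrays have different cell layouts")
    obs = observed.counts.to_numpy(dtype=float).ravel()
    ref = reference.counts.to_numpy(dtype=float).ravel()
    n_obs = obs.sum()
    n_ref = ref.sum()
    if n_obs <= 0:
        raise ValueError("observed feature array is empty")
    if n_ref <= 0:
        raise ValueError("reference feature array is empty")
    expected = ref / n_ref * n_obs

    keep = expected >= min_expected
    if keep.sum() == 0:
        raise ValueError(
            "all reference mass lies in cells below the pooling threshold"
        )
    obs_cells = list(obs[keep])
    exp_cells = list(expected[keep])
    if (~keep).any():
        obs_cells.append(obs[~keep].sum())
        exp_cells.append(expected[~keep].sum())
    obs_arr = np.asarray(obs_cells)
    exp_arr = np.asarray(exp_cells)
    if len(obs_arr) < 2:
        raise ValueError("fewer than two cells retained; test undefined")
    # A zero-expectation cell (possible when the remainder pools only
    # reference-empty cells) contributes nothing if also observed empty,
    # and makes the statistic unbounded if observed occupied: the
    # observed pattern puts mass where the reference puts none.
    zero = exp_arr == 0
    if (obs_arr[zero] > 0).any():
        df = int((~(zero & (obs_arr == 0))).sum() - 1)
        return {"chi2": float("inf"), "df": df, "p": 0.0, "different": bool(alpha > 0)}
    keep2 = ~zero
    obs_arr, exp_arr = obs_arr[keep2], exp_arr[keep2]
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = int(len(obs_arr) - 1)
    p = float(stats.chi2.sf(chi2, df))
    return {"chi2": chi2, "df": df, "p": p, "different": bool(p < alpha)}
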