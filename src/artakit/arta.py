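"""Age-Related Typical Audiograms (ARTA) by cross-sectional regression.

The ARTA model pools binaural thresholds from many patients (and repeat
visits) and fits, independently at each test frequency, an ordinary
least squares regression of threshold (dB HL) on age (years).  The
fitted slope is the annual threshold deterioration (ATD, dB/year); the
fitted line evaluated at fixed ages (by default each decade from 10 to
80) is the age-related typical audiogram.

The API follows the model/results convention: build an :class:`Arta`
from data, call :meth:`Arta.fit`, and read estimates off the returned
:class:`ArtaResults`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .audiogram import ARTA_GRID, BinauralAudiogram, FrequencyGrid, THRESHOLD_RANGE_DB

__all__ = ["Arta", "ArtaResults", "DEFAULT_PREDICTION_AGES", "fit_arta"]

#: Fixed prediction ages: one audiogram per decade of life.
DEFAULT_PREDICTION_AGES: Tuple[float, ...] = (10, 20, 30, 40, 50, 60, 70, 80)

_RESID_TOL = 1e-10  # residual variance below this counts as degenerate


class Arta:
    """Cross-sectional threshold-on-age regression model.

    Parameters
    ----------
    data
        Long-format DataFrame with columns ``age_years``, ``freq_khz``
        and ``threshold_db``; one row per (audiogram, frequency) point.
        Repeat visits of one subject are separate rows (pooled), which
        matches how cross-sectional audiometric progression data are
        usually analysed.
    grid
        Frequencies to fit; defaults to the six-frequency ARTA grid
        0.25-8 kHz.
    prediction_ages
        Ages at which typical audiograms are predicted.
    alpha
        Two-sided significance level for the slope-equals-zero test.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        grid: FrequencyGrid = ARTA_GRID,
        prediction_ages: Sequence[float] = DEFAULT_PREDICTION_AGES,
        alpha: float = 0.05,
    ) -> None:
        required = {"age_years", "freq_khz", "threshold_db"}
        missing = required - set(data.columns)
        if missing:
            raise ValueError(f"data lacks required columns: {sorted(missing)}")
        if not 0 < alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {alpha}")
        self.data = data.dropna(subset=["age_years", "threshold_db"]).copy()
        self.grid = grid
        self.prediction_ages = tuple(float(a) for a in prediction_ages)
        self.alpha = float(alpha)

    @classmethod
    def from_audiograms(
        cls,
        audiograms: Iterable[BinauralAudiogram],
        grid: FrequencyGrid = ARTA_GRID,
        prediction_ages: Sequence[float] = DEFAULT_PREDICTION_AGES,
        alpha: float = 0.05,
    ) -> "Arta":
        """Build the model from binaural audiograms (one row per point)."""
        rows = []
        for ag in audiograms:
            for f, t in ag.thresholds.items():
                rows.append(
                    {
                        "subject_id": ag.subject_id,
                        "age_years": ag.age_years,
                        "freq_khz": f,
                        "threshold_db": t,
                    }
                )
        df = pd.DataFrame(rows, columns=["subject_id", "age_years", "freq_khz", "threshold_db"])
        return cls(df, grid=grid, prediction_ages=prediction_ages, alpha=alpha)

    # alias following the from_formula/from_dataframe convention
    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "Arta":
        return cls(data, **kwargs)

    def fit(self) -> "ArtaResults":
        """Fit per-frequency OLS and return an :class:`ArtaResults`."""
        records = []
        unfittable = []
        for f in self.grid:
            sub = self.data[self.data["freq_khz"] == f]
            age = sub["age_years"].to_numpy(dtype=float)
            y = sub["threshold_db"].to_numpy(dtype=float)
            n = len(y)
            if n < 3:
                unfittable.append((f, f"only {n} observations (need >= 3)"))
                continue
            if np.ptp(age) == 0:
                unfittable.append((f, "all observations at the same age"))
                continue
            model = sm.OLS(y, sm.add_constant(age))
            res = model.fit()
            intercept, slope = res.params
            slope_se = res.bse[1]
            # Degenerate zero-residual fits: a flat line cannot reject
            # slope=0 (p := 1); an exactly linear trend is certain (p := 0).
            if res.ssr / n < _RESID_TOL:
                slope_se = 0.0
                if abs(slope) < 1e-12:
                    slope, p = 0.0, 1.0  # flat data cannot reject anything
                else:
                    p = 0.0
            else:
                p = float(res.pvalues[1])
            records.append(
                {
                    "freq_khz": f,
                    "slope_db_per_year": float(slope),
                    "intercept_db": float(intercept),
                    "slope_se": float(slope_se),
                    "p_value": p,
                    "n_points": n,
                    "significant": bool(p < self.alpha),
                }
            )
        params = pd.DataFrame(
            records,
            columns=[
                "freq_khz",
                "slope_db_per_year",
                "intercept_db",
                "slope_se",
                "p_value",
                "n_points",
                "significant",
            ],
        ).set_index("freq_khz")
        return ArtaResults(self, params, unfittable)


@dataclass
class ArtaResults:
    """Fitted ARTA: per-frequency ATD estimates and typical audiograms.

    Attributes
    ----------
    params
        DataFrame indexed by frequency with columns
        ``slope_db_per_year`` (the ATD), ``intercept_db``, ``slope_se``,
        ``p_value``, ``n_points`` and ``significant``.
    unfittable
        List of ``(freq_khz, reason)`` for frequencies that could not be
        fitted (flagged, never silently dropped).
    """

    model: Arta
    params: pd.DataFrame
    unfittable: list

    @property
    def slopes(self) -> pd.Series:
        return self.params["slope_db_per_year"]

    @property
    def atd(self) -> pd.Series:
        """Annual threshold deterioration in dB/year (alias of slopes)."""
        return self.slopes

    def predict(
        self,
        ages: Optional[Sequence[float]] = None,
        clip_to_audiometer: bool = False,
    ) -> pd.DataFrame:
        """Typical audiograms: rows = ages, columns = frequencies (dB HL).

        Predictions are the raw regression lines; set
        ``clip_to_audiometer`` to confine them to the instrument range
        (for plotting only).
        """
        if ages is None:
            ages = self.model.prediction_ages
        ages = np.asarray(list(ages), dtype=float)
        pred = pd.DataFrame(
            ages[:, None] * self.params["slope_db_per_year"].to_numpy()[None, :]
            + self.params["intercept_db"].to_numpy()[None, :],
            index=pd.Index(ages, name="age_years"),
            columns=self.params.index,
        )
        if clip_to_audiometer:
            pred = pred.clip(*THRESHOLD_RANGE_DB)
        return pred

    def atd_table(self) -> pd.DataFrame:
        """ATD table: frequency, slope, SE, p, n, significance flag."""
        return self.params.reset_index()

    def summary(self) -> str:
        """Human-readable fit summary."""
        lines = [
            "Age-Related Typical Audiogram (ARTA) - per-frequency OLS of threshold on age",
            f"alpha = {self.model.alpha}; prediction ages = {list(self.model.prediction_ages)}",
            "",
            "freq_khz   ATD(dB/yr)   intercept    SE(slope)   p-value      n   significant",
        ]
        for f, row in self.params.iterrows():
            lines.append(
                f"{f:8.3g}   {row.slope_db_per_year:10.3f}   {row.intercept_db:9.2f}"
                f"   {row.slope_se:9.4f}   {row.p_value:9.3g}   {int(row.n_points):4d}"
                f"   {'yes' if row.significant else 'no'}"
            )
        for f, reason in self.unfittable:
            lines.append(f"{f:8.3g}   unfittable: {reason}")
        return "\n".join(lines)

    def to_tsv(self, arta_path, atd_path) -> None:
        """Write the ARTA matrix and the ATD table as TSV files."""
        self.predict().to_csv(arta_path, sep="\t")
        self.atd_table().to_csv(atd_path, sep="\t", index=False)

    def plot(self, ax=None, clip_to_audiometer: bool = True):
        """Plot the ARTA in clinical orientation (inverted dB axis)."""
        from .plotting import plot_arta

        return plot_arta(self, ax=ax, clip_to_audiometer=clip_to_audiometer)


def fit_arta(
    audiograms: Iterable[BinauralAudiogram],
    grid: FrequencyGrid = ARTA_GRID,
    prediction_ages: Sequence[float] = DEFAULT_PREDICTION_AGES,
    alpha: float = 0.05,
) -> ArtaResults:
    """One-call convenience: build an :class:`Arta` and fit it."""
    return Arta.from_audiograms(
        audiograms, grid=grid, prediction_ages=prediction_ages, alpha=alpha
    ).fit()
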