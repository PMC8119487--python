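"""Pure-tone audiogram data types and elementary operations.

Thresholds are air-conduction values in dB HL (decibels hearing level,
higher = worse hearing), measured per ear at a fixed set of test
frequencies in kHz.  The clinical 10-down/5-up threshold search yields
values quantized to 5 dB; binaural means may therefore end in 2.5 dB
half-steps and are never re-quantized downstream.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

__all__ = [
    "FrequencyGrid",
    "EarAudiogram",
    "BinauralAudiogram",
    "DegreeScale",
    "SymmetryRule",
    "DEFAULT_GRID",
    "ARTA_GRID",
    "DEFAULT_DEGREE_SCALE",
    "THRESHOLD_RANGE_DB",
    "binaural_mean",
    "pair_binaural",
    "check_symmetry",
    "classify_degree",
]

#: Audiometer output range in dB HL.
THRESHOLD_RANGE_DB: Tuple[float, float] = (-10.0, 120.0)


@dataclass(frozen=True)
class FrequencyGrid:
    """An ordered set of test frequencies in kHz (strictly increasing, > 0)."""

    freqs_khz: Tuple[float, ...]

    def __post_init__(self) -> None:
        fs = tuple(float(f) for f in self.freqs_khz)
        if not fs:
            raise ValueError("frequency grid must be non-empty")
        if any(f <= 0 for f in fs):
            raise ValueError("frequencies must be positive (kHz)")
        if any(b <= a for a, b in zip(fs, fs[1:])):
            raise ValueError("frequencies must be strictly increasing")
        object.__setattr__(self, "freqs_khz", fs)

    def __iter__(self):
        return iter(self.freqs_khz)

    def __len__(self) -> int:
        return len(self.freqs_khz)


#: Full clinical grid, 125 Hz – 8 kHz.
DEFAULT_GRID = FrequencyGrid((0.125, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0))

#: Frequencies entering ARTA/ATD analysis (the six with reported slopes).
ARTA_GRID = FrequencyGrid((0.25, 0.5, 1.0, 2.0, 4.0, 8.0))


def _validate_thresholds(thresholds: Mapping[float, float], quantized_warning: bool = True) -> Dict[float, float]:
    out: Dict[float, float] = {}
    lo, hi = THRESHOLD_RANGE_DB
    for f, t in thresholds.items():
        f = float(f)
        t = float(t)
        if not math.isfinite(t):
            raise ValueError(f"threshold at {f} kHz is not finite: {t}")
        if not (lo <= t <= hi):
            raise ValueError(f"threshold {t} dB HL at {f} kHz outside [{lo}, {hi}]")
        if quantized_warning and (t % 5.0) != 0.0:
            warnings.warn(
                f"threshold {t} dB HL at {f} kHz is not a multiple of 5 dB",
                stacklevel=3,
            )
        out[f] = t
    return out


@dataclass
class EarAudiogram:
    """A single-ear pure-tone audiogram at one test session.

    Parameters
    ----------
    thresholds
        Mapping freq_khz -> threshold in dB HL.  Frequencies without a
        measurable response are simply absent (missing).
    censored
        Frequencies where no response was obtained at the audiometer
        maximum; the stored threshold is the maximum output level.
    """

    subject_id: str
    family_id: str
    ear: str
    age_years: float
    thresholds: Dict[float, float]
    censored: Set[float] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.ear not in ("left", "right"):
            raise ValueError(f"ear must be 'left' or 'right', got {self.ear!r}")
        age = float(self.age_years)
        if not math.isfinite(age) or age < 0:
            raise ValueError(f"age must be finite and non-negative, got {age}")
        self.age_years = age
        self.thresholds = _validate_thresholds(self.thresholds)
        self.censored = {float(f) for f in self.censored}

    @property
    def freqs(self) -> Tuple[float, ...]:
        return tuple(sorted(self.thresholds))


@dataclass
class BinauralAudiogram:
    """Per-frequency arithmetic mean of left and right ear thresholds."""

    subject_id: str
    age_years: float
    thresholds: Dict[float, float]
    family_id: str = ""

    @property
    def freqs(self) -> Tuple[float, ...]:
        return tuple(sorted(self.thresholds))


@dataclass(frozen=True)
class DegreeScale:
    """Hearing-loss degree bands over dB HL.

    ``upper_bounds`` are inclusive upper edges of all classes but the
    last, which is open above.  The default encodes normal (<= 20),
    mild (21-40), moderate (41-70), severe (71-90), profound (> 90).
    """

    labels: Tuple[str, ...] = ("normal", "mild", "moderate", "severe", "profound")
    upper_bounds: Tuple[float, ...] = (20.0, 40.0, 70.0, 90.0)

    def __post_init__(self) -> None:
        if len(self.upper_bounds) != len(self.labels) - 1:
            raise ValueError("need exactly one fewer bound than labels")
        if any(b <= a for a, b in zip(self.upper_bounds, self.upper_bounds[1:])):
            raise ValueError("bounds must be strictly increasing")

    def classify(self, threshold_db: float) -> str:
        t = float(threshold_db)
        if not math.isfinite(t):
            raise ValueError(f"threshold must be finite, got {t}")
        for label, bound in zip(self.labels, self.upper_bounds):
            if t <= bound:
                return label
        return self.labels[-1]


DEFAULT_DEGREE_SCALE = DegreeScale()


def classify_degree(threshold_db: float, scale: DegreeScale = DEFAULT_DEGREE_SCALE) -> str:
    """Classify a threshold into a hearing-loss degree band.

    >>> classify_degree(30)
    'mild'
    >>> classify_degree(95)
    'profound'
    """
    return scale.classify(threshold_db)


def binaural_mean(
    left: EarAudiogram,
    right: EarAudiogram,
    age_tolerance_years: float = 0.1,
) -> BinauralAudiogram:
    """Average left and right ear thresholds frequency by frequency.

    Frequencies missing in either ear are missing in the output.  The
    two records must belong to the same subject and the same test
    session (ages within ``age_tolerance_years``).
    """
    if left.subject_id != right.subject_id:
        raise ValueError(
            f"ear records belong to different subjects: "
            f"{left.subject_id!r} (left) vs {right.subject_id!r} (right)"
        )
    if abs(left.age_years - right.age_years) > age_tolerance_years:
        raise ValueError(
            f"ear records of {left.subject_id!r} differ in age: "
            f"{left.age_years} vs {right.age_years} years"
        )
    common = set(left.thresholds) & set(right.thresholds)
    thresholds = {f: (left.thresholds[f] + right.thresholds[f]) / 2.0 for f in common}
    return BinauralAudiogram(
        subject_id=left.subject_id,
        age_years=(left.age_years + right.age_years) / 2.0,
        thresholds=thresholds,
        family_id=left.family_id,
    )


def pair_binaural(
    audiograms: Iterable[EarAudiogram],
    age_tolerance_years: float = 0.1,
) -> List["BinauralAudiogram"]:
    """Pair left/right records per (subject, session age) into binaural means.

    Records without a matching contralateral ear are dropped (single-ear
    sessions do not enter the default analysis).
    """
    by_key: Dict[Tuple[str, float], Dict[str, EarAudiogram]] = {}
    for ag in audiograms:
        by_key.setdefault((ag.subject_id, round(ag.age_years, 1)), {})[ag.ear] = ag
    out = []
    for key in sorted(by_key):
        ears = by_key[key]
        if "left" in ears and "right" in ears:
            out.append(
                binaural_mean(ears["left"], ears["right"], age_tolerance_years)
            )
    return out


@dataclass(frozen=True)
class SymmetryRule:
    """Interaural symmetry criterion.

    The default flags an audiogram pair asymmetric when the interaural
    difference reaches ``min_diff_db`` at ``min_count`` or more of the
    speech-range frequencies in ``freqs_khz``.
    """

    min_diff_db: float = 15.0
    freqs_khz: Tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    min_count: int = 2


def check_symmetry(
    left: EarAudiogram,
    right: EarAudiogram,
    rule: SymmetryRule = SymmetryRule(),
) -> Dict[str, object]:
    """Interaural threshold differences and a symmetry verdict.

    Returns ``{"symmetric": bool, "per_freq_diff": {freq: |L-R|}}``.
    Requires at least three overlapping frequencies.
    """
    common = sorted(set(left.thresholds) & set(right.thresholds))
    if len(common) < 3:
        raise ValueError(
            f"only {len(common)} overlapping frequencies; need >= 3 to judge symmetry"
        )
    diffs = {f: abs(left.thresholds[f] - right.thresholds[f]) for f in common}
    n_exceed = sum(
        1 for f in rule.freqs_khz if f in diffs and diffs[f] >= rule.min_diff_db
    )
    return {"symmetric": n_exceed < rule.min_count, "per_freq_diff": diffs}
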