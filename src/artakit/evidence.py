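"""ACMG-style variant evidence: rarity (PM2), co-segregation (PP1),
and deterministic evidence combining.

This layer reproduces the genotype-phenotype evidence workflow used to
classify dominant hearing-loss variants: a variant is supported by being
very rare or absent in population databases (PM2), and by co-segregating
with the phenotype across informative meioses in multigenerational
families (PP1, with strength scaled by the number of concordant
transmissions).  The criteria are combined under the standard
combining-rule table into benign .. pathogenic classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Tuple, Union

from .pedigree import Pedigree, VariantObservation

__all__ = [
    "PopulationFrequencyRecord",
    "ABSENT",
    "Pm2Result",
    "SegregationCount",
    "Pp1Tiers",
    "Criterion",
    "EvidenceSet",
    "evaluate_pm2",
    "count_segregations",
    "grade_pp1",
    "combine_acmg",
    "classify_variant",
    "cohort_prevalence",
    "ACMG_CODES",
    "STRENGTHS",
]

#: Sentinel for "variant not present in this database".
ABSENT = None

STRENGTHS = ("supporting", "moderate", "strong", "very_strong")

#: Standard criterion vocabulary with default strengths.
ACMG_CODES: Dict[str, str] = {
    "PVS1": "very_strong",
    **{f"PS{i}": "strong" for i in range(1, 5)},
    **{f"PM{i}": "moderate" for i in range(1, 7)},
    **{f"PP{i}": "supporting" for i in range(1, 6)},
    "BA1": "stand_alone",
    **{f"BS{i}": "strong" for i in range(1, 5)},
    **{f"BP{i}": "supporting" for i in range(1, 8)},
}


@dataclass
class PopulationFrequencyRecord:
    """Allele frequencies of one variant across population databases.

    ``af_by_db`` maps a database name (e.g. gnomAD, UK10K, EVS) to an
    allele frequency in [0, 1], or :data:`ABSENT` (None) when the
    variant is not present in that database.
    """

    variant_id: str
    af_by_db: Dict[str, Optional[float]]

    def __post_init__(self) -> None:
        for db, af in self.af_by_db.items():
            if af is ABSENT:
                continue
            if not 0.0 <= float(af) <= 1.0:
                raise ValueError(f"{self.variant_id}/{db}: frequency {af} outside [0, 1]")


@dataclass
class Pm2Result:
    met: bool
    rationale: str


def evaluate_pm2(rec: PopulationFrequencyRecord, max_af: float = 2e-5) -> Pm2Result:
    """Rarity criterion: absent from, or very rare in, every database.

    Met when each queried database reports the variant absent or with
    allele frequency <= ``max_af`` (default 2e-5, appropriate for a
    dominant disorder with reduced-frequency expectation).
    """
    if not rec.af_by_db:
        raise ValueError(f"{rec.variant_id}: no population databases queried")
    offending = {
        db: af for db, af in rec.af_by_db.items() if af is not ABSENT and af > max_af
    }
    if offending:
        listing = ", ".join(f"{db}={af:g}" for db, af in sorted(offending.items()))
        return Pm2Result(False, f"frequency above {max_af:g} in {listing}")
    parts = []
    for db, af in sorted(rec.af_by_db.items()):
        parts.append(f"{db}: absent" if af is ABSENT else f"{db}: {af:g}")
    return Pm2Result(True, "absent or rare in all databases (" + "; ".join(parts) + ")")


@dataclass
class SegregationCount:
    n_informative: int
    n_concordant: int
    discordants: List[str]


def count_segregations(
    ped: Pedigree,
    obs: VariantObservation,
    penetrance_mode: str = "full",
    onset_age_years: Optional[float] = None,
) -> SegregationCount:
    """Count informative meioses and phenotype-genotype concordance.

    An informative meiosis is a parent -> offspring transmission where
    the parent is a genotyped heterozygous carrier and the offspring is
    genotyped (het or ref) with known affection status.  The
    transmission that produced the proband's own genotype is excluded
    (the proband's ascertainment cannot count as evidence).

    Concordance: (het and affected) or (ref and unaffected).  Everything
    else informative is discordant and the offspring is listed.

    Under ``penetrance_mode="age_dependent"``, an unaffected carrier
    offspring younger than ``onset_age_years`` is treated as
    non-informative (hearing loss may simply not have started yet)
    instead of discordant.
    """
    if penetrance_mode not in ("full", "age_dependent"):
        raise ValueError(f"unknown penetrance mode {penetrance_mode!r}")
    if penetrance_mode == "age_dependent" and onset_age_years is None:
        raise ValueError("age_dependent mode requires onset_age_years")
    obs.validate_against(ped)
    if ped.proband_id is None:
        raise ValueError("pedigree has no proband")
    if obs.genotype(ped.proband_id) != "het":
        raise ValueError(
            f"proband {ped.proband_id!r} is not a genotyped het carrier "
            f"({obs.genotype(ped.proband_id)!r})"
        )

    n_informative = 0
    n_concordant = 0
    discordants: List[str] = []
    for parent_id, child_id in ped.transmissions():
        if child_id == ped.proband_id:
            continue  # ascertainment meiosis
        if obs.genotype(parent_id) != "het":
            continue
        g = obs.genotype(child_id)
        child = ped.members[child_id]
        if g == "untyped" or child.affected == "unknown":
            continue
        if (
            penetrance_mode == "age_dependent"
            and g == "het"
            and child.affected == "no"
            and child.age_years is not None
            and child.age_years < onset_age_years
        ):
            continue  # pre-onset carrier: uninformative
        n_informative += 1
        concordant = (g == "het" and child.affected == "yes") or (
            g == "ref" and child.affected == "no"
        )
        if concordant:
            n_concordant += 1
        else:
            discordants.append(child_id)
    return SegregationCount(n_informative, n_concordant, discordants)


@dataclass(frozen=True)
class Pp1Tiers:
    """Meiosis-count thresholds for PP1 strength escalation."""

    supporting: int = 3
    moderate: int = 5
    strong: int = 7


def grade_pp1(
    n_concordant: int,
    discordants_empty: bool,
    tiers: Pp1Tiers = Pp1Tiers(),
) -> str:
    """Grade co-segregation evidence from concordant-meiosis counts.

    Defaults: >=3 concordant meioses -> supporting, >=5 -> moderate,
    >=7 -> strong.  Any discordant segregation (under full penetrance)
    caps the grade at ``"none"``.
    """
    if n_concordant < 0:
        raise ValueError(f"negative concordant count: {n_concordant}")
    if not discordants_empty:
        return "none"
    if n_concordant >= tiers.strong:
        return "strong"
    if n_concordant >= tiers.moderate:
        return "moderate"
    if n_concordant >= tiers.supporting:
        return "supporting"
    return "none"


@dataclass(frozen=True)
class Criterion:
    """One ACMG criterion with an (optionally escalated) strength."""

    code: str
    strength: Optional[str] = None  # None -> default strength for the code

    def resolved_strength(self) -> str:
        if self.code not in ACMG_CODES:
            raise ValueError(f"unknown ACMG criterion code {self.code!r}")
        if self.strength is None:
            return ACMG_CODES[self.code]
        if self.strength not in STRENGTHS + ("stand_alone",):
            raise ValueError(f"invalid strength {self.strength!r}")
        return self.strength

    @property
    def benign_side(self) -> bool:
        return self.code.startswith("B")


@dataclass
class EvidenceSet:
    """A set of criteria (one strength per code) to be combined."""

    criteria: Tuple[Criterion, ...]

    def __init__(self, criteria: Iterable[Union[Criterion, Tuple[str, str], str]]):
        norm: Dict[str, Criterion] = {}
        for c in criteria:
            if isinstance(c, Criterion):
                crit = c
            elif isinstance(c, str):
                crit = Criterion(c)
            else:
                crit = Criterion(*c)
            crit.resolved_strength()  # validates
            if crit.code in norm:
                raise ValueError(f"duplicate criterion {crit.code!r}")
            norm[crit.code] = crit
        self.criteria = tuple(norm.values())

    def strength_counts(self, benign: bool) -> Dict[str, int]:
        counts = {s: 0 for s in STRENGTHS + ("stand_alone",)}
        for c in self.criteria:
            if c.benign_side == benign:
                counts[c.resolved_strength()] += 1
        return counts


def _pathogenic_tier(vs: int, s: int, m: int, p: int) -> str:
    """Classify the pathogenic-side evidence alone."""
    pathogenic = (
        (vs >= 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2))
        or s >= 2
        or (s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)))
    )
    if pathogenic:
        return "pathogenic"
    likely = (
        (vs == 1 and m == 1)
        or (s == 1 and 1 <= m <= 2)
        or (s == 1 and p >= 2)
        or m >= 3
        or (m == 2 and p >= 2)
        or (m == 1 and p >= 4)
    )
    if likely:
        return "likely_pathogenic"
    return "VUS"


def _benign_tier(stand_alone: int, s: int, p: int) -> str:
    if stand_alone >= 1 or s >= 2:
        return "benign"
    if (s == 1 and p >= 1) or p >= 2:
        return "likely_benign"
    return "VUS"


def combine_acmg(evidence: EvidenceSet) -> str:
    """Combine criteria into a five-tier class.

    Deterministic application of the standard combining-rule table
    (e.g. one strong plus one moderate criterion -> likely pathogenic).
    Combinations reached by neither the pathogenic nor the benign rules,
    and contradictory combinations satisfying both, yield ``"VUS"``.
    """
    pc = evidence.strength_counts(benign=False)
    bc = evidence.strength_counts(benign=True)
    path = _pathogenic_tier(pc["very_strong"], pc["strong"], pc["moderate"], pc["supporting"])
    ben = _benign_tier(bc["stand_alone"], bc["strong"], bc["supporting"])
    if path != "VUS" and ben != "VUS":
        return "VUS"  # conflicting evidence
    if path != "VUS":
        return path
    if ben != "VUS":
        return ben
    return "VUS"


def classify_variant(
    ped: Pedigree,
    obs: VariantObservation,
    freq_record: PopulationFrequencyRecord,
    max_af: float = 2e-5,
    pp1_tiers: Pp1Tiers = Pp1Tiers(),
    penetrance_mode: str = "full",
    onset_age_years: Optional[float] = None,
) -> Dict[str, object]:
    """Run the full evidence chain for one variant in one family.

    Returns a JSON-serializable report with the per-criterion rationale
    and the combined class.
    """
    pm2 = evaluate_pm2(freq_record, max_af=max_af)
    seg = count_segregations(
        ped, obs, penetrance_mode=penetrance_mode, onset_age_years=onset_age_years
    )
    pp1_grade = grade_pp1(seg.n_concordant, not seg.discordants, tiers=pp1_tiers)
    criteria: List[Criterion] = []
    if pm2.met:
        criteria.append(Criterion("PM2"))
    if pp1_grade != "none":
        criteria.append(Criterion("PP1", pp1_grade))
    acmg_class = combine_acmg(EvidenceSet(criteria))
    return {
        "variant": obs.variant_id,
        "family": ped.family_id,
        "criteria": [
            {"code": c.code, "strength": c.resolved_strength()} for c in criteria
        ],
        "class": acmg_class,
        "rationale": {
            "PM2": pm2.rationale,
            "PP1": (
                f"{seg.n_concordant}/{seg.n_informative} informative meioses "
                f"concordant; discordant: {seg.discordants or 'none'}; "
                f"grade: {pp1_grade}"
            ),
        },
        "segregation": {
            "n_informative": seg.n_informative,
            "n_concordant": seg.n_concordant,
            "discordants": seg.discordants,
        },
    }


def cohort_prevalence(n_positive: int, n_screened: int) -> Dict[str, float]:
    """Share of screened families explained by a gene, in percent.

    ``cohort_prevalence(4, 102)["percent"]`` is 3.92, the
    "approximately 4 %" style figure reported for gene-level yield.
    """
    if n_screened <= 0:
        raise ValueError("n_screened must be positive")
    if not 0 <= n_positive <= n_screened:
        raise ValueError("n_positive must lie in [0, n_screened]")
    frac = n_positive / n_screened
    return {
        "n_positive": n_positive,
        "n_screened": n_screened,
        "fraction": frac,
        "percent": 100.0 * frac,
    }
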