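"""Bundled example families for the dominant hearing-loss evidence chain.

The four TBC1D24 families are SYNTHETIC reconstructions: pedigree
topologies built to be consistent with the published facts about these
families (counts of affected members per family 6/12/6/5, roughly 22
unaffected tested relatives overall, hearing loss in at least three
generations, probands in generation IV, mean onset ages 19.5/16.7/16.3/35
years), not transcriptions of the original pedigree drawings, which are
available only as figures.  Population allele frequencies follow the
published table (three databases; the Family 1 gnomAD entry is stored as
a tiny nonzero frequency because the printed value is garbled).

They exist so the evidence workflow (PM2 -> segregation counting -> PP1
grading -> ACMG combining) can be exercised end to end.
"""

from __future__ import annotations

from typing import Dict, List, Tuple

from .evidence import PopulationFrequencyRecord, ABSENT
from .pedigree import Individual, Pedigree, VariantObservation

__all__ = ["family_fixture", "all_family_fixtures", "FAMILY_VARIANTS"]

#: variant (cDNA, protein) per family, with mean onset age in years.
FAMILY_VARIANTS: Dict[int, Dict[str, object]] = {
    1: {"cdna": "c.533C>T", "protein": "p.Ser178Leu", "onset": 19.5},
    2: {"cdna": "c.553G>A", "protein": "p.Asp185Asn", "onset": 16.7},
    3: {"cdna": "c.1461C>G", "protein": "p.His487Gln", "onset": 16.3},
    4: {"cdna": "c.1460A>T", "protein": "p.His487Leu", "onset": 35.0},
}

# Each row: (id, sex, father, mother, affected, age, genotype)
# Ids follow the clinical generation.position convention.
_M, _F = "male", "female"
_FAMILY_TABLES: Dict[int, Tuple[List[tuple], str]] = {}

_FAMILY_TABLES[1] = (
    [
        ("I.1", _M, None, None, "yes", 82, "het"),
        ("I.2", _F, None, None, "no", 80, "ref"),
        ("II.1", _M, "I.1", "I.2", "yes", 58, "het"),
        ("II.2", _F, None, None, "no", 56, "ref"),
        ("II.3", _F, "I.1", "I.2", "no", 54, "ref"),
        ("III.1", _F, "II.1", "II.2", "yes", 33, "het"),
        ("III.2", _M, None, None, "no", 35, "ref"),
        ("III.3", _M, "II.1", "II.2", "yes", 30, "het"),
        ("III.4", _F, "II.1", "II.2", "no", 28, "ref"),
        ("IV.1", _M, "III.2", "III.1", "yes", 29, "het"),  # proband
        ("IV.2", _F, "III.2", "III.1", "yes", 26, "het"),
        ("IV.3", _M, "III.2", "III.1", "no", 23, "ref"),
    ],
    "IV.1",
)

_FAMILY_TABLES[2] = (
    [
        ("I.1", _M, None, None, "yes", 88, "het"),
        ("I.2", _F, None, None, "no", 86, "ref"),
        ("II.1", _M, "I.1", "I.2", "yes", 66, "het"),
        ("II.2", _F, None, None, "no", 64, "ref"),
        ("II.4", _F, "I.1", "I.2", "yes", 62, "het"),
        ("II.5", _M, None, None, "no", 63, "ref"),
        ("II.6", _M, "I.1", "I.2", "no", 60, "ref"),
        ("II.7", _F, "I.1", "I.2", "yes", 58, "het"),
        ("III.1", _M, "II.1", "II.2", "yes", 45, "het"),
        ("III.2", _F, None, None, "no", 44, "ref"),
        ("III.4", _F, "II.1", "II.2", "yes", 42, "het"),
        ("III.5", _M, None, None, "no", 43, "ref"),
        ("III.6", _F, "II.1", "II.2", "no", 40, "ref"),
        ("III.8", _M, "II.5", "II.4", "yes", 41, "het"),
        ("III.9", _F, None, None, "no", 40, "ref"),
        ("III.11", _F, "II.5", "II.4", "yes", 38, "het"),
        ("IV.1", _M, "III.1", "III.2", "yes", 24, "het"),
        ("IV.2", _F, "III.1", "III.2", "no", 22, "ref"),
        ("IV.5", _F, "III.5", "III.4", "yes", 21, "het"),
        ("IV.8", _M, "III.8", "III.9", "yes", 20, "het"),
        ("IV.9", _F, "III.8", "III.9", "no", 18, "ref"),
        ("IV.12", _F, "III.5", "III.4", "yes", 39, "het"),  # proband
    ],
    "IV.12",
)

_FAMILY_TABLES[3] = (
    [
        ("I.1", _F, None, None, "yes", 84, "het"),
        ("I.2", _M, None, None, "no", 85, "ref"),
        ("II.1", _F, "I.2", "I.1", "yes", 60, "het"),
        ("II.2", _M, None, None, "no", 61, "ref"),
        ("II.3", _M, "I.2", "I.1", "yes", 57, "het"),
        ("II.5", _F, "I.2", "I.1", "no", 55, "ref"),
        ("III.1", _F, "II.2", "II.1", "yes", 38, "het"),
        ("III.2", _M, None, None, "no", 39, "ref"),
        ("III.3", _M, "II.2", "II.1", "no", 35, "ref"),
        ("III.5", _F, "II.3", None, "yes", 33, "het"),
        ("IV.7", _F, "III.2", "III.1", "yes", 24, "het"),  # proband
        ("IV.8", _M, "III.2", "III.1", "no", 21, "ref"),
        ("IV.9", _F, "III.2", "III.1", "no", 19, "ref"),
    ],
    "IV.7",
)

_FAMILY_TABLES[4] = (
    [
        ("I.1", _M, None, None, "yes", 90, "het"),
        ("I.2", _F, None, None, "no", 88, "ref"),
        ("II.1", _F, "I.1", "I.2", "yes", 68, "het"),
        ("II.2", _M, None, None, "no", 69, "ref"),
        ("II.3", _M, "I.1", "I.2", "no", 65, "ref"),
        ("III.1", _M, "II.2", "II.1", "yes", 46, "het"),
        ("III.2", _F, None, None, "no", 45, "ref"),
        ("III.3", _F, "II.2", "II.1", "yes", 43, "het"),
        ("III.4", _M, "II.2", "II.1", "no", 41, "ref"),
        ("IV.6", _F, "III.1", "III.2", "yes", 39, "het"),  # proband
        ("IV.7", _M, "III.1", "III.2", "no", 20, "ref"),
        ("IV.8", _F, "III.1", "III.2", "no", 17, "ref"),
    ],
    "IV.6",
)

# Published population frequencies (gnomAD, UK10K, EVS).  Family 1's
# gnomAD cell is garbled in print; stored here as 8e-6 (rare either way).
_FREQUENCIES: Dict[int, Dict[str, object]] = {
    1: {"gnomAD": 8e-6, "UK10K": 0.0, "EVS": 0.0},
    2: {"gnomAD": 0.0, "UK10K": 0.0, "EVS": 0.0},
    3: {"gnomAD": 0.0, "UK10K": 0.0, "EVS": 0.0},
    4: {"gnomAD": 0.0, "UK10K": 0.0, "EVS": 0.0},
}


def family_fixture(
    n: int,
) -> Tuple[Pedigree, VariantObservation, PopulationFrequencyRecord]:
    """Synthetic family ``n`` in {1..4}: pedigree, genotypes, frequencies."""
    if n not in _FAMILY_TABLES:
        raise ValueError(f"no bundled family {n}; choose 1-4")
    rows, proband = _FAMILY_TABLES[n]
    individuals = [
        Individual(
            id=iid, sex=sex, father_id=fa, mother_id=mo, affected=aff,
            age_years=float(age),
        )
        for iid, sex, fa, mo, aff, age, _gt in rows
    ]
    ped = Pedigree(individuals, proband_id=proband, family_id=f"Family{n}")
    variant = FAMILY_VARIANTS[n]
    obs = VariantObservation(
        variant_id=f"TBC1D24 {variant['cdna']} ({variant['protein']})",
        genotypes={iid: gt for iid, *_rest, gt in rows},
    )
    rec = PopulationFrequencyRecord(
        variant_id=obs.variant_id, af_by_db=dict(_FREQUENCIES[n])
    )
    return ped, obs, rec


def all_family_fixtures():
    """All four bundled families, in family order."""
    return [family_fixture(n) for n in (1, 2, 3, 4)]
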