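"""Synthetic cohorts of autosomal-dominant progressive hearing loss.

Generates multigenerational families segregating a fully penetrant
dominant hearing-loss variant, together with longitudinal pure-tone
audiograms for every member, so the whole analysis pipeline (binaural
averaging, ARTA/ATD regression, feature arrays, segregation evidence)
can be exercised and validated without patient data.

The phenotype model is deliberately the simplest one consistent with
slowly progressive postlingual sensorineural hearing loss: a carrier's
true threshold at frequency f is

    baseline(f) + atd(f) * max(0, age - onset)

i.e. stable until the onset age and then deteriorating linearly at the
annual threshold deterioration rate atd(f).  Non-carriers keep a flat
normal-hearing audiogram.  Measured thresholds add independent
Gaussian test-retest noise per ear, are confined to the audiometer
output range, and are quantized to the 5 dB resolution of the clinical
10-down/5-up threshold search.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .audiogram import ARTA_GRID, EarAudiogram, FrequencyGrid, THRESHOLD_RANGE_DB
from .pedigree import Individual, Pedigree, VariantObservation

__all__ = [
    "ProgressionProfile",
    "CohortConfig",
    "CohortDataset",
    "AVERAGE_PROFILE",
    "SER178LEU_PROFILE",
    "ASP185ASN_PROFILE",
    "HIS487LEU_PROFILE",
    "NORMAL_HEARING_BASELINE",
    "simulate_pedigree",
    "simulate_audiogram",
    "simulate_cohort",
]


@dataclass(frozen=True)
class ProgressionProfile:
    """Variant-specific hearing-loss progression parameters.

    ``baseline_db`` is the true threshold at the onset age;
    ``atd_db_per_year`` the per-frequency annual deterioration.
    ``noise_sd_db`` is the per-ear test-retest measurement noise SD
    (7 dB by default, typical clinical repeatability).
    """

    variant_label: str
    onset_age_years: float
    baseline_db: Dict[float, float]
    atd_db_per_year: Dict[float, float]
    noise_sd_db: float = 7.0
    audiometer_range: Tuple[float, float] = THRESHOLD_RANGE_DB

    def __post_init__(self) -> None:
        if set(self.baseline_db) != set(self.atd_db_per_year):
            raise ValueError("baseline and ATD maps must cover the same frequencies")
        if any(v < 0 for v in self.atd_db_per_year.values()):
            raise ValueError("ATD must be non-negative for a progressive-HL profile")
        if self.noise_sd_db < 0:
            raise ValueError("noise SD must be non-negative")

    @property
    def freqs(self) -> Tuple[float, ...]:
        return tuple(sorted(self.baseline_db))

    def true_threshold(self, freq_khz: float, age_years: float) -> float:
        years = max(0.0, age_years - self.onset_age_years)
        return self.baseline_db[freq_khz] + self.atd_db_per_year[freq_khz] * years


#: Flat normal-hearing audiogram used for non-carriers (no age effect,
#: so fitted slopes on non-carriers should be indistinguishable from 0).
NORMAL_HEARING_BASELINE: Dict[float, float] = {f: 5.0 for f in ARTA_GRID}

# Reported ATD ranges give the slope at each range's endpoint frequency;
# values at the remaining frequencies are interpolated once and fixed.
AVERAGE_PROFILE = ProgressionProfile(
    variant_label="TBC1D24-average",
    onset_age_years=17.0,
    baseline_db={0.25: 25.0, 0.5: 25.0, 1.0: 30.0, 2.0: 30.0, 4.0: 45.0, 8.0: 45.0},
    atd_db_per_year={0.25: 0.75, 0.5: 0.75, 1.0: 0.70, 2.0: 0.70, 4.0: 0.65, 8.0: 0.61},
)

SER178LEU_PROFILE = ProgressionProfile(
    variant_label="p.Ser178Leu",
    onset_age_years=19.5,
    baseline_db={0.25: 20.0, 0.5: 20.0, 1.0: 25.0, 2.0: 30.0, 4.0: 40.0, 8.0: 40.0},
    atd_db_per_year={0.25: 0.95, 0.5: 1.00, 1.0: 1.08, 2.0: 1.05, 4.0: 0.88, 8.0: 0.92},
)

ASP185ASN_PROFILE = ProgressionProfile(
    variant_label="p.Asp185Asn",
    onset_age_years=16.7,
    baseline_db={0.25: 30.0, 0.5: 30.0, 1.0: 35.0, 2.0: 35.0, 4.0: 50.0, 8.0: 50.0},
    atd_db_per_year={0.25: 0.83, 0.5: 1.00, 1.0: 1.40, 2.0: 1.72, 4.0: 1.50, 8.0: 1.30},
)

HIS487LEU_PROFILE = ProgressionProfile(
    variant_label="p.His487Leu",
    onset_age_years=35.0,
    baseline_db={0.25: 20.0, 0.5: 20.0, 1.0: 25.0, 2.0: 30.0, 4.0: 40.0, 8.0: 40.0},
    atd_db_per_year={0.25: 0.95, 0.5: 1.03, 1.0: 0.90, 2.0: 0.80, 4.0: 0.59, 8.0: 0.70},
)


@dataclass(frozen=True)
class CohortConfig:
    """Structure of the simulated cohort.

    Defaults target a pooled dataset of roughly 80 affected binaural
    audiograms (the scale of a multi-family cross-sectional progression
    study): five 4-generation families, about three children per
    couple, and up to three audiometric visits per affected subject;
    the analysis layer then caps the pooled set at 81 sessions.
    """

    seed: int
    n_families: int = 5
    generations: int = 4
    mean_offspring: float = 3.0
    visits_per_subject: int = 3
    visit_spacing_years: float = 5.0
    genotyping_missingness: float = 0.0
    audiometry_missingness: float = 0.0

    def __post_init__(self) -> None:
        if self.generations < 3:
            raise ValueError("families must span at least three generations")
        if self.n_families < 1:
            raise ValueError("need at least one family")
        if not 0 <= self.genotyping_missingness < 1:
            raise ValueError("genotyping missingness must be in [0, 1)")
        if not 0 <= self.audiometry_missingness < 1:
            raise ValueError("audiometry missingness must be in [0, 1)")


def _generation_age(generation: int, total: int, rng: np.random.Generator) -> float:
    """Draw an age for a member of the given generation (0 = founders)."""
    mean = 85.0 - 22.0 * generation
    return float(np.clip(rng.normal(mean, 4.0), 1.0, 95.0))


def simulate_pedigree(
    cfg: CohortConfig,
    rng: np.random.Generator,
    family_id: str = "F1",
    onset_age_years: float = 17.0,
    variant_id: str = "simulated",
) -> Tuple[Pedigree, VariantObservation]:
    """Gene-drop a dominant variant through a multigenerational family.

    The founder is a heterozygous carrier; each child of a carrier
    inherits the variant with probability 1/2; married-in spouses are
    reference.  Affection status is carrier AND age >= onset (full
    penetrance).  Genotypes may be masked at the configured missingness
    rate, except the proband, who is always a genotyped het.
    """
    members: List[Individual] = []
    carrier: Dict[str, bool] = {}
    counter = [0]

    def new_id() -> str:
        counter[0] += 1
        return f"{family_id}-{counter[0]:03d}"

    def add(sex, gen, is_carrier, father=None, mother=None) -> str:
        iid = new_id()
        age = _generation_age(gen, cfg.generations, rng)
        affected = "yes" if (is_carrier and age >= onset_age_years) else "no"
        members.append(
            Individual(
                id=iid, sex=sex, father_id=father, mother_id=mother,
                affected=affected, age_years=age,
            )
        )
        carrier[iid] = is_carrier
        return iid

    founder = add("male" if rng.random() < 0.5 else "female", 0, True)
    spouse_sex = "female" if members[0].sex == "male" else "male"
    spouse = add(spouse_sex, 0, False)
    couples = [(founder, spouse)]

    for gen in range(1, cfg.generations):
        next_couples = []
        for f_id, m_id in couples:
            father_id = f_id if members_by_id(members)[f_id].sex == "male" else m_id
            mother_id = m_id if father_id == f_id else f_id
            n_children = max(1, int(rng.poisson(cfg.mean_offspring)))
            parent_carrier = carrier[f_id] or carrier[m_id]
            for i in range(n_children):
                sex = "male" if rng.random() < 0.5 else "female"
                child_carrier = parent_carrier and bool(rng.random() < 0.5)
                child = add(sex, gen, child_carrier, father=father_id, mother=mother_id)
                # Carrier children and each couple's first child marry and
                # reproduce (the latter keeps every family spanning the full
                # configured depth without conditioning on genotype); the
                # final generation stays single.
                if (child_carrier or i == 0) and gen < cfg.generations - 1:
                    partner = add("female" if sex == "male" else "male", gen, False)
                    next_couples.append((child, partner))
        couples = next_couples

    # proband: youngest-generation affected carrier (falls back to founder)
    affected_carriers = [m for m in members if carrier[m.id] and m.affected == "yes"]
    proband = max(
        affected_carriers,
        key=lambda m: (m.father_id is not None, -m.age_years),
        default=members[0],
    )

    genotypes: Dict[str, str] = {}
    for m in members:
        if m.id != proband.id and rng.random() < cfg.genotyping_missingness:
            continue
        genotypes[m.id] = "het" if carrier[m.id] else "ref"

    ped = Pedigree(members, proband_id=proband.id, family_id=family_id)
    obs = VariantObservation(variant_id=variant_id, genotypes=genotypes)
    return ped, obs


def members_by_id(members: Sequence[Individual]) -> Dict[str, Individual]:
    return {m.id: m for m in members}


def simulate_audiogram(
    subject_age: float,
    carrier: bool,
    profile: ProgressionProfile,
    rng: np.random.Generator,
    subject_id: str = "S",
    family_id: str = "",
) -> Tuple[EarAudiogram, EarAudiogram]:
    """One test session: left and right ear audiograms.

    Both ears share the same true threshold; measurement noise is
    independent per ear.  Order of operations (fixed so tests can be
    exact): clip the true value to the audiometer range, add noise,
    clip again, round to the nearest 5 dB.
    """
    lo, hi = profile.audiometer_range
    ears = []
    for ear in ("left", "right"):
        thresholds: Dict[float, float] = {}
        censored = set()
        for f in profile.freqs:
            if carrier:
                true = profile.true_threshold(f, subject_age)
            else:
                true = NORMAL_HEARING_BASELINE.get(f, 5.0)
            true = min(max(true, lo), hi)
            measured = true + (rng.normal(0.0, profile.noise_sd_db) if profile.noise_sd_db else 0.0)
            measured = min(max(measured, lo), hi)
            measured = float(np.round(measured / 5.0) * 5.0)
            thresholds[f] = measured
            if measured >= hi:
                censored.add(f)
        ears.append(
            EarAudiogram(
                subject_id=subject_id,
                family_id=family_id,
                ear=ear,
                age_years=subject_age,
                thresholds=thresholds,
                censored=censored,
            )
        )
    return ears[0], ears[1]


@dataclass
class CohortDataset:
    """Everything one simulated cohort produced, plus the ground truth."""

    audiograms: List[EarAudiogram]
    pedigrees: List[Pedigree]
    observations: List[VariantObservation]
    ground_truth: Dict[str, object]

    def write(self, outdir) -> Dict[str, str]:
        """Write audiogram CSV, PED + genotype sidecars, truth JSON."""
        from . import io as akio
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {"audiograms": str(outdir / "audiograms.csv")}
        akio.write_audiograms(self.audiograms, paths["audiograms"])
        for ped, obs in zip(self.pedigrees, self.observations):
            stem = outdir / ped.family_id
            akio.write_pedigree(ped, f"{stem}.ped")
            akio.write_genotypes(obs, ped, f"{stem}.genotypes.csv")
            paths[ped.family_id] = f"{stem}.ped"
        truth_path = outdir / "ground_truth.json"
        truth_path.write_text(json.dumps(self.ground_truth, indent=2, sort_keys=True))
        paths["ground_truth"] = str(truth_path)
        return paths


def affected_binaural_audiograms(
    dataset: "CohortDataset",
    max_n: Optional[int] = 81,
    rng: Optional[np.random.Generator] = None,
):
    """Binaural audiograms of affected subjects, the ARTA input.

    When the cohort yields more sessions than ``max_n`` a random subset
    of that size is analysed, keeping the pooled dataset at the scale
    of a typical multi-family cross-sectional study (81 sessions).
    """
    from .audiogram import pair_binaural

    affected = {
        s for s, rec in dataset.ground_truth["subjects"].items()
        if rec["affected"] == "yes"
    }
    binaurals = [b for b in pair_binaural(dataset.audiograms) if b.subject_id in affected]
    if max_n is not None and len(binaurals) > max_n:
        if rng is None:
            rng = np.random.default_rng(0)
        idx = rng.choice(len(binaurals), size=max_n, replace=False)
        binaurals = [binaurals[i] for i in sorted(idx)]
    return binaurals


def simulate_cohort(
    cfg: CohortConfig,
    profile: ProgressionProfile = AVERAGE_PROFILE,
) -> CohortDataset:
    """Simulate families plus audiometry for every member.

    Affected subjects contribute up to ``visits_per_subject`` sessions
    at ages spaced ``visit_spacing_years`` apart, never earlier than
    their onset (patients present for audiometry only once hearing loss
    has begun); unaffected members contribute a single session.
    """
    rng = np.random.default_rng(cfg.seed)
    audiograms: List[EarAudiogram] = []
    pedigrees: List[Pedigree] = []
    observations: List[VariantObservation] = []
    truth_subjects: Dict[str, object] = {}

    for k in range(cfg.n_families):
        fam = f"FAM{k + 1}"
        ped, obs = simulate_pedigree(
            cfg, rng, family_id=fam,
            onset_age_years=profile.onset_age_years,
            variant_id=profile.variant_label,
        )
        pedigrees.append(ped)
        observations.append(obs)
        for m in ped.members.values():
            is_carrier = obs.genotype(m.id) == "het" or (
                obs.genotype(m.id) == "untyped" and m.affected == "yes"
            )
            truth_subjects[m.id] = {
                "family": fam,
                "carrier": is_carrier,
                "affected": m.affected,
                "age_years": m.age_years,
            }
            if rng.random() < cfg.audiometry_missingness:
                continue
            if m.affected == "yes":
                ages = [
                    max(profile.onset_age_years, m.age_years - j * cfg.visit_spacing_years)
                    for j in range(cfg.visits_per_subject)
                ]
                ages = sorted(set(round(a, 1) for a in ages))
            else:
                ages = [round(m.age_years, 1)]
            for a in ages:
                left, right = simulate_audiogram(
                    a, is_carrier, profile, rng, subject_id=m.id, family_id=fam
                )
                audiograms.extend([left, right])

    ground_truth = {
        "profile": {
            "variant_label": profile.variant_label,
            "onset_age_years": profile.onset_age_years,
            "baseline_db": {str(f): v for f, v in profile.baseline_db.items()},
            "atd_db_per_year": {str(f): v for f, v in profile.atd_db_per_year.items()},
            "noise_sd_db": profile.noise_sd_db,
        },
        "config": asdict(cfg),
        "subjects": truth_subjects,
    }
    return CohortDataset(audiograms, pedigrees, observations, ground_truth)
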