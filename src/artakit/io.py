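"""Readers and writers for the pipeline's plain-text interchange formats.

* Audiograms: long-format CSV with columns ``subject_id, family_id,
  ear, age_years, freq_khz, threshold_db, censored`` (UTF-8, header
  required, missing threshold = empty cell).
* Pedigrees: 6-column PED (family, individual, father, mother, sex,
  phenotype; ``0`` = missing parent, sex 1/2 = male/female, phenotype
  1/2 = unaffected/affected, 0/-9 = unknown) with an optional 7th
  column carrying age in years, plus a genotype CSV sidecar
  (``individual_id, genotype``).
* Run configuration: YAML with strict (unknown keys rejected) parsing.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import yaml

from .audiogram import EarAudiogram
from .pedigree import Individual, Pedigree, VariantObservation

__all__ = [
    "read_audiograms",
    "write_audiograms",
    "read_pedigree",
    "write_pedigree",
    "write_genotypes",
    "RunConfig",
    "load_run_config",
]

AUDIOGRAM_COLUMNS = [
    "subject_id",
    "family_id",
    "ear",
    "age_years",
    "freq_khz",
    "threshold_db",
    "censored",
]


@dataclass
class RowError:
    line: int
    reason: str


def read_audiograms(path) -> Tuple[List[EarAudiogram], List[RowError]]:
    """Read ear audiograms from long-format CSV.

    Rows are grouped into one :class:`EarAudiogram` per
    (subject, ear, age) triple.  Malformed rows are collected as
    :class:`RowError` with their line numbers and skipped; thresholds
    that are not multiples of 5 dB are kept with a warning (real data
    may deviate from the 5 dB quantization).
    """
    path = Path(path)
    errors: List[RowError] = []
    groups: Dict[Tuple[str, str, float], Dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise ValueError(f"{path}: empty file")
        missing_cols = set(AUDIOGRAM_COLUMNS[:6]) - set(reader.fieldnames)
        if missing_cols:
            raise ValueError(f"{path}: header lacks columns {sorted(missing_cols)}")
        n_rows = 0
        for lineno, row in enumerate(reader, start=2):
            n_rows += 1
            try:
                subject = row["subject_id"].strip()
                family = (row.get("family_id") or "").strip()
                ear = row["ear"].strip().lower()
                age = float(row["age_years"])
                freq = float(row["freq_khz"])
                if age < 0:
                    raise ValueError(f"negative age {age}")
                raw_thr = (row.get("threshold_db") or "").strip()
                if raw_thr == "":
                    continue  # missing threshold at this frequency
                threshold = float(raw_thr)
                censored = (row.get("censored") or "").strip().lower() in (
                    "1", "true", "yes",
                )
            except (KeyError, ValueError) as exc:
                errors.append(RowError(lineno, str(exc)))
                continue
            key = (subject, ear, age)
            g = groups.setdefault(
                key,
                {"family": family, "thresholds": {}, "censored": set(), "line": lineno},
            )
            g["thresholds"][freq] = threshold
            if censored:
                g["censored"].add(freq)
    if n_rows == 0:
        raise ValueError(f"{path}: no data rows")

    audiograms: List[EarAudiogram] = []
    for (subject, ear, age), g in groups.items():
        try:
            audiograms.append(
                EarAudiogram(
                    subject_id=subject,
                    family_id=g["family"],
                    ear=ear,
                    age_years=age,
                    thresholds=g["thresholds"],
                    censored=g["censored"],
                )
            )
        except ValueError as exc:
            errors.append(RowError(g["line"], str(exc)))
    return audiograms, errors


def write_audiograms(audiograms: Iterable[EarAudiogram], path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(AUDIOGRAM_COLUMNS)
        for ag in audiograms:
            for f in sorted(ag.thresholds):
                writer.writerow(
                    [
                        ag.subject_id,
                        ag.family_id,
                        ag.ear,
                        ag.age_years,
                        f,
                        ag.thresholds[f],
                        int(f in ag.censored),
                    ]
                )


_SEX_FROM_PED = {"1": "male", "2": "female"}
_SEX_TO_PED = {"male": "1", "female": "2", "unknown": "0"}
_AFF_FROM_PED = {"1": "no", "2": "yes", "0": "unknown", "-9": "unknown"}
_AFF_TO_PED = {"no": "1", "yes": "2", "unknown": "0"}


def read_pedigree(
    ped_path,
    genotype_path=None,
    proband_id: Optional[str] = None,
    variant_id: str = "unknown",
) -> Tuple[Pedigree, Optional[VariantObservation]]:
    """Read a 6(+1)-column PED file and an optional genotype sidecar."""
    ped_path = Path(ped_path)
    individuals: List[Individual] = []
    family_id = ""
    for lineno, line in enumerate(ped_path.read_text(encoding="utf-8").splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 6:
            raise ValueError(f"{ped_path}:{lineno}: expected >= 6 columns, got {len(fields)}")
        fam, iid, father, mother, sex, pheno = fields[:6]
        family_id = family_id or fam
        age = float(fields[6]) if len(fields) > 6 else None
        individuals.append(
            Individual(
                id=iid,
                sex=_SEX_FROM_PED.get(sex, "unknown"),
                father_id=None if father == "0" else father,
                mother_id=None if mother == "0" else mother,
                affected=_AFF_FROM_PED.get(pheno, "unknown"),
                age_years=age,
            )
        )
    ped = Pedigree(individuals, proband_id=proband_id, family_id=family_id)

    obs = None
    if genotype_path is not None:
        genotypes: Dict[str, str] = {}
        with Path(genotype_path).open(newline="", encoding="utf-8") as fh:
            for row in csv.DictReader(fh):
                iid = row["individual_id"].strip()
                if iid not in ped.members:
                    raise ValueError(
                        f"{genotype_path}: genotype for unknown individual {iid!r}"
                    )
                genotypes[iid] = row["genotype"].strip()
        obs = VariantObservation(variant_id=variant_id, genotypes=genotypes)
        obs.validate_against(ped)
    return ped, obs


def write_pedigree(ped: Pedigree, path) -> None:
    lines = []
    for ind in ped.members.values():
        cols = [
            ped.family_id or "FAM",
            ind.id,
            ind.father_id or "0",
            ind.mother_id or "0",
            _SEX_TO_PED[ind.sex],
            _AFF_TO_PED[ind.affected],
        ]
        if ind.age_years is not None:
            cols.append(f"{ind.age_years:g}")
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_genotypes(obs: VariantObservation, ped: Pedigree, path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["individual_id", "genotype"])
        for iid in ped.members:
            writer.writerow([iid, obs.genotype(iid)])


_RUNCONFIG_KEYS = {
    "audiogram_csv",
    "ped_file",
    "genotype_csv",
    "proband_id",
    "variant_id",
    "frequencies_khz",
    "prediction_ages",
    "alpha",
    "band_map",
    "degree_bounds",
    "pp1_tiers",
    "pm2_max_af",
    "seed",
    "output_dir",
}


@dataclass
class RunConfig:
    """Effective parameters of one pipeline run (all logged)."""

    audiogram_csv: Optional[str] = None
    ped_file: Optional[str] = None
    genotype_csv: Optional[str] = None
    proband_id: Optional[str] = None
    variant_id: str = "unknown"
    frequencies_khz: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
    prediction_ages: Sequence[float] = (10, 20, 30, 40, 50, 60, 70, 80)
    alpha: float = 0.05
    band_map: Dict[float, str] = field(
        default_factory=lambda: {0.25: "lf", 0.5: "lf", 1.0: "mf", 2.0: "mf", 4.0: "hf", 8.0: "hf"}
    )
    degree_bounds: Sequence[float] = (20.0, 40.0, 70.0, 90.0)
    pp1_tiers: Dict[str, int] = field(
        default_factory=lambda: {"supporting": 3, "moderate": 5, "strong": 7}
    )
    pm2_max_af: float = 2e-5
    seed: int = 0
    output_dir: str = "artakit-out"


def load_run_config(path) -> RunConfig:
    """Load a YAML run configuration, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    unknown = set(raw) - _RUNCONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown configuration keys {sorted(unknown)}")
    return RunConfig(**raw)
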