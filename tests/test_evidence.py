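"""PM2 rarity, segregation counting, PP1 grading, ACMG combining."""

import numpy as np
import pytest

from artakit.datasets import all_family_fixtures, family_fixture
from artakit.evidence import (
    ABSENT,
    Criterion,
    EvidenceSet,
    PopulationFrequencyRecord,
    Pp1Tiers,
    classify_variant,
    cohort_prevalence,
    combine_acmg,
    count_segregations,
    evaluate_pm2,
    grade_pp1,
)
from artakit.pedigree import Individual, Pedigree, VariantObservation
from artakit.simulate import CohortConfig, simulate_pedigree


def rec(**af):
    return PopulationFrequencyRecord("v", af_by_db=af or {"gnomAD": 0.0})


class TestPm2:
    def test_zero_in_all_databases_met(self):
        assert evaluate_pm2(rec(gnomAD=0.0, UK10K=0.0, EVS=0.0)).met

    def test_common_variant_not_met(self):
        out = evaluate_pm2(rec(gnomAD=0.01))
        assert not out.met and "gnomAD" in out.rationale

    def test_absent_everywhere_met(self):
        assert evaluate_pm2(rec(gnomAD=ABSENT, UK10K=ABSENT)).met

    def test_threshold_boundary(self):
        assert evaluate_pm2(rec(gnomAD=2e-5)).met
        assert not evaluate_pm2(rec(gnomAD=2.1e-5)).met

    def test_empty_record_is_an_error(self):
        with pytest.raises(ValueError, match="no population databases"):
            evaluate_pm2(PopulationFrequencyRecord("v", af_by_db={}))

    def test_invalid_frequency_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            rec(gnomAD=1.5)


def trio(child_affected="yes", child_gt="het", proband_extra=True):
    """Affected het father, ref mother, proband + one sibling."""
    inds = [
        Individual("dad", "male", affected="yes"),
        Individual("mum", "female", affected="no"),
        Individual("kid", "unknown", "dad", "mum", affected=child_affected),
    ]
    gts = {"dad": "het", "mum": "ref", "kid": child_gt}
    if proband_extra:
        inds.append(Individual("pro", "unknown", "dad", "mum", affected="yes"))
        gts["pro"] = "het"
        proband = "pro"
    else:
        proband = "kid"
    ped = Pedigree(inds, proband_id=proband, family_id="T")
    return ped, VariantObservation("v", gts)


class TestCountSegregations:
    def test_trio_single_informative_concordant(self):
        ped, obs = trio()
        out = count_segregations(ped, obs)
        assert out.n_informative == 1 and out.n_concordant == 1
        assert not out.discordants

    def test_proband_meiosis_excluded(self):
        ped, obs = trio(proband_extra=False)
        out = count_segregations(ped, obs)
        assert out.n_informative == 0

    def test_unaffected_het_discordant_under_full_penetrance(self):
        ped, obs = trio(child_affected="no", child_gt="het")
        out = count_segregations(ped, obs)
        assert out.discordants == ["kid"]
        assert out.n_concordant == 0 and out.n_informative == 1

    def test_young_unaffected_het_excluded_under_age_dependent(self):
        inds = [
            Individual("dad", "male", affected="yes", age_years=50),
            Individual("mum", "female", affected="no", age_years=48),
            Individual("kid", "unknown", "dad", "mum", affected="no", age_years=12),
            Individual("pro", "unknown", "dad", "mum", affected="yes", age_years=25),
        ]
        obs = VariantObservation("v", {"dad": "het", "mum": "ref", "kid": "het", "pro": "het"})
        ped = Pedigree(inds, proband_id="pro")
        out = count_segregations(ped, obs, penetrance_mode="age_dependent", onset_age_years=17)
        assert out.n_informative == 0 and not out.discordants

    def test_untyped_offspring_not_informative(self):
        ped, obs = trio(child_gt="untyped")
        assert count_segregations(ped, obs).n_informative == 0

    def test_non_het_proband_is_an_error(self):
        ped, obs = trio()
        obs.genotypes["pro"] = "ref"
        with pytest.raises(ValueError, match="proband"):
            count_segregations(ped, obs)

    def test_seven_descendant_family_counts_six_nonproband(self):
        # het founder -> 4 affected het children; one child has 3 affected
        # het children of their own, one of whom is the proband: 7 affected
        # het descendants, 7 typed transmissions, minus the proband's = 6
        inds = [
            Individual("f", "male", affected="yes"),
            Individual("fw", "female", affected="no"),
            Individual("c1", "male", "f", "fw", affected="yes"),
            Individual("c1w", "female", affected="no"),
            Individual("c2", "female", "f", "fw", affected="yes"),
            Individual("c3", "male", "f", "fw", affected="yes"),
            Individual("c4", "female", "f", "fw", affected="yes"),
            Individual("g1", "male", "c1", "c1w", affected="yes"),
            Individual("g2", "female", "c1", "c1w", affected="yes"),
            Individual("g3", "male", "c1", "c1w", affected="yes"),
        ]
        gts = {i.id: "het" for i in inds if i.affected == "yes"}
        gts.update({"fw": "ref", "c1w": "ref"})
        ped = Pedigree(inds, proband_id="g3")
        out = count_segregations(ped, VariantObservation("v", gts))
        assert out.n_informative == 6 and out.n_concordant == 6

    @pytest.mark.parametrize("seed", range(25))
    def test_agrees_with_brute_force_on_random_pedigrees(self, seed):
        rng = np.random.default_rng(seed)
        cfg = CohortConfig(seed=seed, n_families=1, generations=3,
                           mean_offspring=2.0, genotyping_missingness=0.2)
        ped, obs = simulate_pedigree(cfg, rng, onset_age_years=17)
        if len(ped) > 15 or obs.genotype(ped.proband_id) != "het":
            pytest.skip("outside the small-pedigree regime")
        out = count_segregations(ped, obs)
        # independent enumeration straight off the individual records
        n_inf = n_con = 0
        disc = []
        for ind in ped.members.values():
            if ind.id == ped.proband_id:
                continue
            for pid in (ind.father_id, ind.mother_id):
                if pid is None or obs.genotype(pid) != "het":
                    continue
                g = obs.genotype(ind.id)
                if g == "untyped" or ind.affected == "unknown":
                    continue
                n_inf += 1
                if (g == "het") == (ind.affected == "yes"):
                    n_con += 1
                else:
                    disc.append(ind.id)
        assert out.n_informative == n_inf
        assert out.n_concordant == n_con
        assert sorted(out.discordants) == sorted(disc)


class TestGradePp1:
    @pytest.mark.parametrize(
        "n,grade",
        [(0, "none"), (2, "none"), (3, "supporting"), (4, "supporting"),
         (5, "moderate"), (6, "moderate"), (7, "strong"), (20, "strong")],
    )
    def test_default_tiers(self, n, grade):
        assert grade_pp1(n, discordants_empty=True) == grade

    def test_discordance_caps_at_none(self):
        assert grade_pp1(5, discordants_empty=False) == "none"

    def test_monotone_in_concordant_count(self):
        order = {"none": 0, "supporting": 1, "moderate": 2, "strong": 3}
        grades = [order[grade_pp1(n, True)] for n in range(15)]
        assert grades == sorted(grades)

    def test_negative_count_is_an_error(self):
        with pytest.raises(ValueError):
            grade_pp1(-1, True)


class TestCombineAcmg:
    @pytest.mark.parametrize(
        "criteria,expected",
        [
            ([("PM2", None), ("PP1", "strong")], "likely_pathogenic"),
            ([], "VUS"),
            ([("PVS1", None), ("PS1", None)], "pathogenic"),
            ([("PVS1", None), ("PM2", None)], "likely_pathogenic"),
            ([("PM1", None), ("PM2", None), ("PM4", None)], "likely_pathogenic"),
            ([("PS1", None), ("PM1", None), ("PM2", None), ("PM4", None)], "pathogenic"),
            ([("PM2", None)], "VUS"),
            ([("BA1", None)], "benign"),
            ([("BS1", None), ("BS2", None)], "benign"),
            ([("BS1", None), ("BP1", None)], "likely_benign"),
            # contradictory: benign (BS+BP) and pathogenic (S+M) rules both fire
            ([("BS1", None), ("BP1", None), ("PS1", None), ("PM1", None)], "VUS"),
            # a lone BS does not reach likely_benign, so no contradiction
            ([("BS1", None), ("PS1", None), ("PM1", None)], "likely_pathogenic"),
        ],
    )
    def test_combining_rule_table(self, criteria, expected):
        assert combine_acmg(EvidenceSet(criteria)) == expected

    def test_unknown_code_is_an_error(self):
        with pytest.raises(ValueError, match="unknown ACMG"):
            EvidenceSet([("PX9", None)])

    def test_adding_pathogenic_evidence_never_moves_toward_benign(self):
        order = ["benign", "likely_benign", "VUS", "likely_pathogenic", "pathogenic"]
        base_sets = [
            [], [("PM2", None)], [("PS1", None)], [("BS1", None), ("BP1", None)],
            [("PM2", None), ("PP1", "strong")],
        ]
        extras = [("PVS1", None), ("PS2", None), ("PM5", None), ("PP3", None)]
        for base in base_sets:
            before = order.index(combine_acmg(EvidenceSet(base)))
            for extra in extras:
                if extra in base:
                    continue
                after = order.index(combine_acmg(EvidenceSet(base + [extra])))
                assert after >= before


class TestFixtures:
    def test_all_four_families_likely_pathogenic(self):
        for ped, obs, freq in all_family_fixtures():
            report = classify_variant(ped, obs, freq)
            assert report["class"] == "likely_pathogenic", ped.family_id
            codes = {c["code"]: c["strength"] for c in report["criteria"]}
            assert codes == {"PM2": "moderate", "PP1": "strong"}

    def test_affected_counts_match_published_families(self):
        expected = {1: 6, 2: 12, 3: 6, 4: 5}
        for n, want in expected.items():
            ped, _, _ = family_fixture(n)
            got = sum(1 for i in ped.members.values() if i.affected == "yes")
            assert got == want

    def test_no_discordant_segregations_in_fixtures(self):
        for ped, obs, _ in all_family_fixtures():
            out = count_segregations(ped, obs)
            assert not out.discordants and out.n_concordant >= 7


class TestPrevalence:
    def test_four_of_102_rounds_to_four_percent(self):
        out = cohort_prevalence(4, 102)
        assert out["percent"] == pytest.approx(3.9215686, abs=1e-6)
        assert round(out["percent"]) == 4

    @pytest.mark.parametrize("pos,n", [(-1, 10), (11, 10), (0, 0)])
    def test_invalid_counts_rejected(self, pos, n):
        with pytest.raises(ValueError):
            cohort_prevalence(pos, n)
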