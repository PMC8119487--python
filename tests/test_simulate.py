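"""Synthetic cohort generator: determinism, Mendelian transmission,
quantization, and parameter recovery."""

import numpy as np
import pytest

from artakit.arta import Arta
from artakit.audiogram import pair_binaural
from artakit.simulate import (
    ASP185ASN_PROFILE,
    AVERAGE_PROFILE,
    HIS487LEU_PROFILE,
    SER178LEU_PROFILE,
    CohortConfig,
    ProgressionProfile,
    affected_binaural_audiograms,
    simulate_audiogram,
    simulate_cohort,
    simulate_pedigree,
)

QUIET = ProgressionProfile(
    variant_label="quiet",
    onset_age_years=20.0,
    baseline_db={1.0: 30.0, 2.0: 40.0},
    atd_db_per_year={1.0: 0.5, 2.0: 0.0},
    noise_sd_db=0.0,
)


class TestProfiles:
    def test_published_slope_range_endpoints(self):
        # the reported ATD ranges pin the slope at each endpoint frequency
        assert AVERAGE_PROFILE.atd_db_per_year[8.0] == 0.61
        assert AVERAGE_PROFILE.atd_db_per_year[0.25] == 0.75
        assert AVERAGE_PROFILE.atd_db_per_year[0.5] == 0.75
        assert ASP185ASN_PROFILE.atd_db_per_year[0.25] == 0.83
        assert ASP185ASN_PROFILE.atd_db_per_year[2.0] == 1.72
        assert SER178LEU_PROFILE.atd_db_per_year[4.0] == 0.88
        assert SER178LEU_PROFILE.atd_db_per_year[1.0] == 1.08
        assert HIS487LEU_PROFILE.atd_db_per_year[4.0] == 0.59
        assert HIS487LEU_PROFILE.atd_db_per_year[0.5] == 1.03

    def test_negative_atd_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ProgressionProfile("x", 20, {1.0: 30}, {1.0: -0.1})

    def test_mismatched_frequency_maps_rejected(self):
        with pytest.raises(ValueError, match="same frequencies"):
            ProgressionProfile("x", 20, {1.0: 30}, {2.0: 0.5})


class TestSimulateAudiogram:
    def test_no_progression_at_onset_without_noise(self, rng):
        left, right = simulate_audiogram(20.0, True, QUIET, rng)
        assert left.thresholds == {1.0: 30.0, 2.0: 40.0}
        assert left.thresholds == right.thresholds

    def test_flat_profile_identical_across_ages(self, rng):
        flat = ProgressionProfile("flat", 20, {1.0: 40.0}, {1.0: 0.0}, noise_sd_db=0.0)
        a30, _ = simulate_audiogram(30.0, True, flat, rng)
        a70, _ = simulate_audiogram(70.0, True, flat, rng)
        assert a30.thresholds == a70.thresholds

    def test_emitted_thresholds_quantized_and_in_range(self, rng):
        prof = ProgressionProfile(
            "noisy", 15, {1.0: 100.0, 4.0: 110.0}, {1.0: 1.5, 4.0: 1.5}, noise_sd_db=12.0
        )
        for age in (10, 50, 90):
            for ear in simulate_audiogram(float(age), True, prof, rng):
                for t in ear.thresholds.values():
                    assert t % 5 == 0
                    assert -10 <= t <= 120

    def test_noncarrier_gets_flat_normal_audiogram(self, rng):
        quiet = ProgressionProfile("q", 20, dict(QUIET.baseline_db), dict(QUIET.atd_db_per_year), noise_sd_db=0.0)
        a, _ = simulate_audiogram(60.0, False, quiet, rng)
        assert all(t <= 20 for t in a.thresholds.values())


class TestSimulatePedigree:
    def test_deterministic_under_fixed_seed(self):
        cfg = CohortConfig(seed=42, n_families=2)
        d1 = simulate_cohort(cfg, AVERAGE_PROFILE)
        d2 = simulate_cohort(cfg, AVERAGE_PROFILE)
        assert d1.ground_truth == d2.ground_truth
        assert [a.thresholds for a in d1.audiograms] == [a.thresholds for a in d2.audiograms]

    def test_every_family_spans_at_least_three_generations(self):
        for seed in range(5):
            ped, _ = simulate_pedigree(
                CohortConfig(seed=seed), np.random.default_rng(seed)
            )
            depth = {}
            for iid in sorted(
                ped.members, key=lambda i: (ped.members[i].father_id is not None, i)
            ):
                ind = ped.members[iid]
                parents = [p for p in (ind.father_id, ind.mother_id) if p]
                depth[iid] = 1 + max((depth.get(p, 1) for p in parents), default=0)
            assert max(depth.values()) >= 3

    def test_transmission_ratio_near_half(self):
        # pool transmissions from genotyped het parents over many families
        n_trans = n_carrier = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            ped, obs = simulate_pedigree(CohortConfig(seed=seed), rng)
            for parent, child in ped.transmissions():
                if obs.genotype(parent) == "het" and obs.genotype(child) != "untyped":
                    n_trans += 1
                    n_carrier += obs.genotype(child) == "het"
        assert n_trans > 300
        se = 0.5 / np.sqrt(n_trans)
        assert abs(n_carrier / n_trans - 0.5) < 3 * se

    def test_config_invariants_enforced(self):
        with pytest.raises(ValueError, match="three generations"):
            CohortConfig(seed=1, generations=2)
        with pytest.raises(ValueError, match="missingness"):
            CohortConfig(seed=1, genotyping_missingness=1.5)

    def test_affection_follows_carrier_and_onset(self):
        rng = np.random.default_rng(9)
        ped, obs = simulate_pedigree(CohortConfig(seed=9), rng, onset_age_years=17)
        for ind in ped.members.values():
            g = obs.genotype(ind.id)
            if g == "het":
                assert ind.affected == ("yes" if ind.age_years >= 17 else "no")
            elif g == "ref":
                assert ind.affected == "no"


class TestCohortRecovery:
    def test_slope_recovery_within_two_se(self):
        true = AVERAGE_PROFILE.atd_db_per_year
        nrep, hits, total = 40, 0, 0
        for seed in range(nrep):
            ds = simulate_cohort(CohortConfig(seed=seed), AVERAGE_PROFILE)
            b = affected_binaural_audiograms(ds, rng=np.random.default_rng(seed + 1))
            res = Arta.from_audiograms(b).fit()
            for f, row in res.params.iterrows():
                total += 1
                hits += abs(row.slope_db_per_year - true[f]) <= 2 * row.slope_se
        assert hits / total > 0.88  # nominal ~0.95 coverage

    def test_noncarrier_slope_ci_covers_zero(self):
        covered = total = 0
        for seed in range(30):
            ds = simulate_cohort(CohortConfig(seed=seed + 100, n_families=2), AVERAGE_PROFILE)
            carriers = {
                s for s, r in ds.ground_truth["subjects"].items() if r["carrier"]
            }
            b = [x for x in pair_binaural(ds.audiograms) if x.subject_id not in carriers]
            res = Arta.from_audiograms(b).fit()
            for f, row in res.params.iterrows():
                total += 1
                covered += abs(row.slope_db_per_year) <= 2 * row.slope_se
        assert total > 0
        assert covered / total >= 0.9

    def test_roundtrip_through_files(self, tmp_path):
        from artakit.io import read_audiograms, read_pedigree

        ds = simulate_cohort(CohortConfig(seed=5, n_families=1), AVERAGE_PROFILE)
        paths = ds.write(tmp_path)
        ags, errors = read_audiograms(paths["audiograms"])
        assert not errors
        orig = {(a.subject_id, a.ear, a.age_years): a.thresholds for a in ds.audiograms}
        back = {(a.subject_id, a.ear, a.age_years): a.thresholds for a in ags}
        assert back == orig
        fam = ds.pedigrees[0].family_id
        ped, obs = read_pedigree(
            paths[fam], str(tmp_path / f"{fam}.genotypes.csv"),
            proband_id=ds.pedigrees[0].proband_id,
        )
        assert set(ped.members) == set(ds.pedigrees[0].members)
        assert obs.genotypes == {
            i: ds.observations[0].genotype(i) for i in ped.members
        }
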