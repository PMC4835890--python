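import itertools
from dataclasses import replace

import numpy as np
import pytest

from couplebiome.simulate import (
    GeneratorConfig,
    male_baseline,
    simulate_cohort,
    simulate_compositions,
    simulate_count_cohort,
    simulate_male_composition,
    simulate_novel_genus,
    simulate_reads,
    simulate_reference,
    simulate_vaginal_composition,
    species_roles,
)
from couplebiome.taxonomy import percent_identity
from couplebiome.types import ValidationError

SMALL = GeneratorConfig(
    n_bv_couples=2, n_normal_couples=1,
    depth_mean={"vagina": 50.0, "penile_skin": 40.0, "urethra": 40.0},
    seed=7,
)


class TestReference:
    def test_counts_and_labels(self):
        db, tree = simulate_reference(10, 3, 500, np.random.default_rng(0))
        assert len(db) == 30
        assert len(list(tree.tips())) == 30
        assert {t.name for t in tree.tips()} == set(db.species())

    def test_within_genus_identity_exceeds_between(self, small_reference):
        db, _ = small_reference
        within, between = [], []
        for a, b in itertools.combinations(db.entries[:12], 2):
            pid = percent_identity(a.sequence, b.sequence)
            (within if a.genus == b.genus else between).append(pid)
        assert np.mean(within) > np.mean(between) + 5

    def test_determinism(self):
        db1, _ = simulate_reference(6, 2, 300, np.random.default_rng(42))
        db2, _ = simulate_reference(6, 2, 300, np.random.default_rng(42))
        assert [e.sequence for e in db1.entries] == [e.sequence for e in db2.entries]

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            simulate_reference(4, 2, 100, np.random.default_rng(0))

    def test_novel_genus_distant_from_all(self, small_reference):
        db, _ = small_reference
        novel = simulate_novel_genus(db, rng=np.random.default_rng(1))
        pids = [percent_identity(novel[0].sequence, e.sequence)
                for e in db.entries[::6]]
        assert max(pids) < 85.0


class TestCompositions:
    @pytest.fixture(scope="class")
    def roles(self, small_reference):
        return species_roles(small_reference[0])

    def test_simplex(self, roles):
        rng = np.random.default_rng(2)
        for state in ("BV", "normal"):
            comp = simulate_vaginal_composition(state, roles, rng)
            assert comp.min() >= 0 and comp.sum() == pytest.approx(1.0, abs=1e-9)

    def test_normal_dominated_bv_diverse(self, roles):
        rng = np.random.default_rng(3)
        normal = [simulate_vaginal_composition("normal", roles, rng)
                  for _ in range(300)]
        bv = [simulate_vaginal_composition("BV", roles, rng) for _ in range(300)]
        assert np.mean([c.max() for c in normal]) >= 0.7
        n_rich = np.mean([(c > 0.01).sum() for c in bv])
        assert n_rich > np.mean([(c > 0.01).sum() for c in normal])
        assert np.mean([(c > 0.01).sum() >= 10 for c in bv]) > 0.95

    def test_bv_entropy_higher(self, roles):
        rng = np.random.default_rng(4)

        def entropy(c):
            nz = c[c > 0]
            return -(nz * np.log(nz)).sum()

        normal = np.mean([entropy(simulate_vaginal_composition("normal", roles, rng))
                          for _ in range(300)])
        bv = np.mean([entropy(simulate_vaginal_composition("BV", roles, rng))
                      for _ in range(300)])
        assert bv > normal


class TestMaleComposition:
    @pytest.fixture(scope="class")
    def roles(self, small_reference):
        return species_roles(small_reference[0])

    def test_kappa_one_equals_partner(self, roles):
        rng = np.random.default_rng(5)
        partner = simulate_vaginal_composition("BV", roles, rng)
        base = male_baseline("penile_skin", roles, rng)
        comp = simulate_male_composition("penile_skin", base, partner, 1.0, rng)
        np.testing.assert_allclose(comp, partner, atol=1e-12)

    def test_kappa_zero_ignores_partner(self, roles):
        rng1 = np.random.default_rng(6)
        rng2 = np.random.default_rng(6)
        base = male_baseline("penile_skin", roles, np.random.default_rng(1))
        p1 = simulate_vaginal_composition("BV", roles, np.random.default_rng(2))
        p2 = simulate_vaginal_composition("BV", roles, np.random.default_rng(3))
        c1 = simulate_male_composition("penile_skin", base, p1, 0.0, rng1)
        c2 = simulate_male_composition("penile_skin", base, p2, 0.0, rng2)
        np.testing.assert_allclose(c1, c2)

    def test_kappa_out_of_range(self, roles):
        rng = np.random.default_rng(7)
        base = male_baseline("urethra", roles, rng)
        with pytest.raises(ValidationError):
            simulate_male_composition("urethra", base, base, 1.5, rng)


class TestReads:
    def test_no_noise_reads_are_reference_prefixes(self, small_reference):
        db, _ = small_reference
        roles = species_roles(db)
        comp = np.zeros(len(roles.species))
        comp[roles.bv[:5]] = 0.2
        reads, sources, defects = simulate_reads(
            comp, 50, db, 0.0, {}, np.random.default_rng(8))
        seq_of = {e.species: e.sequence for e in db.entries}
        for r, s, d in zip(reads, sources, defects):
            assert d == "none"
            assert len(r) >= 200
            assert seq_of[s].startswith(r.bases)

    def test_short_defect_rate(self, small_reference):
        db, _ = small_reference
        roles = species_roles(db)
        comp = np.zeros(len(roles.species))
        comp[roles.bv[0]] = 1.0
        _, _, defects = simulate_reads(
            comp, 4000, db, 0.0, {"short": 0.1}, np.random.default_rng(9))
        frac = sum(d == "short" for d in defects) / 4000
        assert frac == pytest.approx(0.10, abs=3 * np.sqrt(0.1 * 0.9 / 4000))

    def test_determinism(self, small_reference):
        db, _ = small_reference
        roles = species_roles(db)
        comp = np.zeros(len(roles.species))
        comp[roles.skin[:3]] = 1 / 3
        r1, s1, d1 = simulate_reads(comp, 30, db, 0.01,
                                    {"short": 0.1}, np.random.default_rng(10))
        r2, s2, d2 = simulate_reads(comp, 30, db, 0.01,
                                    {"short": 0.1}, np.random.default_rng(10))
        assert r1 == r2 and s1 == s2 and d1 == d2

    def test_zero_depth_rejected(self, small_reference):
        db, _ = small_reference
        with pytest.raises(ValidationError):
            simulate_reads(np.ones(len(db.species())) / len(db.species()),
                           0, db, 0.0, {}, np.random.default_rng(0))


class TestCohort:
    def test_three_specimens_per_couple(self):
        specimens, truth = simulate_compositions(GeneratorConfig(seed=1))
        assert len(specimens) == 288  # 96 couples x 3 sites
        couples = {s.couple_id for s in specimens}
        assert len(couples) == 96
        groups = {s.couple_id: s.group for s in specimens}
        assert sum(g == "BV" for g in groups.values()) == 65

    def test_group_shared_within_couple_and_circumcision_rules(self):
        specimens, _ = simulate_compositions(GeneratorConfig(seed=2))
        by_couple = {}
        for s in specimens:
            by_couple.setdefault(s.couple_id, []).append(s)
        for members in by_couple.values():
            assert len({m.group for m in members}) == 1
            for m in members:
                if m.site == "vagina":
                    assert m.circumcised is None
                else:
                    assert isinstance(m.circumcised, bool)

    def test_determinism_with_reads(self):
        s1, t1 = simulate_cohort(SMALL)
        s2, t2 = simulate_cohort(SMALL)
        assert [spec.reads for spec in s1] == [spec.reads for spec in s2]
        for sid in t1.compositions:
            np.testing.assert_array_equal(t1.compositions[sid],
                                          t2.compositions[sid])

    def test_count_cohort_depths_near_site_means(self):
        cfg = replace(GeneratorConfig(seed=3), n_bv_couples=10, n_normal_couples=5)
        specimens, table, _ = simulate_count_cohort(cfg)
        depths = dict(zip(table.specimen_ids, table.depths()))
        vaginal = [depths[s.specimen_id] for s in specimens if s.site == "vagina"]
        assert np.mean(vaginal) == pytest.approx(6053, rel=0.05)

    def test_partner_effect_monotone_in_kappa(self):
        """Mean (partner - non-partner) UniFrac distance decreases with the
        homogenisation weight; presence-based UniFrac saturates above
        kappa ~ 0.25, so higher levels are compared with a noise margin."""
        from couplebiome.experiments import mean_partner_effect

        effects = [mean_partner_effect(10, 77, k) for k in (0.0, 0.25, 0.5, 0.75)]
        assert abs(effects[0]) < 0.01  # no couple structure at the null
        assert effects[1] < effects[0] - 0.05
        assert effects[2] <= effects[1] + 0.01
        assert effects[3] <= effects[2] + 0.01

    def test_kappa_zero_no_couple_structure(self):
        cfg = replace(SMALL, kappa_bv=0.0, kappa_normal=0.0,
                      urethra_kappa_scale_circumcised=0.0,
                      urethra_kappa_scale_uncircumcised=0.0)
        _, truth = simulate_compositions(cfg)
        # male compositions share no information with the partner beyond
        # the common baseline: correlation across couples ~ 0 for BV taxa
        for cid in ("C001", "C002"):
            v = truth.compositions[f"{cid}V"]
            p = truth.compositions[f"{cid}P"]
            assert not np.allclose(v, p)
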