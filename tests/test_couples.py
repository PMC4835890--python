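import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix

from couplebiome.couples import (
    abundance_group_compare,
    contingency_test,
    fisher_z_compare,
    paired_partner_test,
    partner_nonpartner,
    prevalence_filter,
    spearman_couple_correlations,
    stratified_partner_analysis,
)
from couplebiome.types import OtuTable, ValidationError


def toy_metadata(n_couples=3, group="BV"):
    rows = []
    for i in range(n_couples):
        cid = f"C{i}"
        rows.append((f"{cid}V", f"{cid}F", cid, "vagina", group, None))
        rows.append((f"{cid}P", f"{cid}M", cid, "penile_skin", group, i % 2 == 0))
        rows.append((f"{cid}U", f"{cid}M", cid, "urethra", group, i % 2 == 0))
    return pd.DataFrame(
        rows, columns=["specimen_id", "subject_id", "couple_id", "site",
                       "group", "circumcised"])


def toy_dm(meta, fill):
    ids = list(meta["specimen_id"])
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = fill(ids[i], ids[j])
    return DistanceMatrix(d, ids=ids)


class TestPartnerNonpartner:
    def test_hand_computed_means(self):
        meta = toy_metadata(3)
        values = {("C0P", "C0V"): 0.1, ("C0P", "C1V"): 0.5, ("C0P", "C2V"): 0.7,
                  ("C1P", "C1V"): 0.2, ("C1P", "C0V"): 0.4, ("C1P", "C2V"): 0.6,
                  ("C2P", "C2V"): 0.3, ("C2P", "C0V"): 0.8, ("C2P", "C1V"): 0.9}

        def fill(a, b):
            key = (a, b) if (a, b) in values else (b, a)
            return values.get(key, 0.55)

        records = partner_nonpartner(toy_dm(meta, fill), meta, "penile_skin", "BV")
        by_man = {r.male_specimen_id: r for r in records}
        assert by_man["C0P"].partner_distance == pytest.approx(0.1)
        assert by_man["C0P"].nonpartner_distance == pytest.approx((0.5 + 0.7) / 2)
        assert by_man["C1P"].nonpartner_distance == pytest.approx((0.4 + 0.6) / 2)
        assert all(r.n_nonpartners == 2 for r in records)

    def test_two_couples_single_nonpartner(self):
        meta = toy_metadata(2)
        records = partner_nonpartner(
            toy_dm(meta, lambda a, b: 0.5), meta, "penile_skin", "BV")
        assert all(r.n_nonpartners == 1 for r in records)

    def test_constant_matrix_equalizes(self):
        meta = toy_metadata(4)
        records = partner_nonpartner(
            toy_dm(meta, lambda a, b: 0.42), meta, "urethra", "BV")
        for r in records:
            assert r.partner_distance == pytest.approx(r.nonpartner_distance)

    def test_single_couple_rejected(self):
        meta = toy_metadata(1)
        with pytest.raises(ValidationError):
            partner_nonpartner(toy_dm(meta, lambda a, b: 0.5), meta,
                               "penile_skin", "BV")

    def test_missing_specimen_skipped(self):
        meta = toy_metadata(3)
        dm_meta = meta[meta["specimen_id"] != "C1V"]
        dm = toy_dm(dm_meta, lambda a, b: 0.5)
        records = partner_nonpartner(dm, meta, "penile_skin", "BV")
        assert {r.male_specimen_id for r in records} == {"C0P", "C2P"}
        assert all(r.n_nonpartners == 1 for r in records)


class TestPairedPartnerTest:
    def test_null_identity(self):
        meta = toy_metadata(4)
        records = partner_nonpartner(
            toy_dm(meta, lambda a, b: 0.3), meta, "penile_skin", "BV")
        res = paired_partner_test(records)
        assert (res.t, res.p) == (0.0, 1.0)

    def test_constant_nonzero_difference_degenerate(self):
        meta = toy_metadata(3)

        def fill(a, b):
            if a.endswith("P") and b.endswith("V") or \
               a.endswith("V") and b.endswith("P"):
                return 0.2 if a[:2] == b[:2] else 0.4
            return 0.5

        records = partner_nonpartner(toy_dm(meta, fill), meta,
                                     "penile_skin", "BV")
        with pytest.raises(ValidationError):
            paired_partner_test(records)

    def test_matches_scipy_ttest_rel(self):
        rng = np.random.default_rng(0)
        meta = toy_metadata(8)
        dm = toy_dm(meta, lambda a, b: float(rng.uniform(0.2, 0.9)))
        records = partner_nonpartner(dm, meta, "penile_skin", "BV")
        res = paired_partner_test(records)
        partner = [r.partner_distance for r in records]
        nonpartner = [r.nonpartner_distance for r in records]
        t, p = stats.ttest_rel(partner, nonpartner)
        assert (res.t, res.p) == (pytest.approx(t), pytest.approx(p))


class TestStratified:
    def test_deterministic_and_covers_strata(self):
        rng = np.random.default_rng(1)
        meta = pd.concat([toy_metadata(6, "BV"), toy_metadata(6, "normal")],
                         ignore_index=True)
        meta["specimen_id"] = meta["group"] + meta["specimen_id"]
        meta["couple_id"] = meta["group"] + meta["couple_id"]
        dm = toy_dm(meta, lambda a, b: float(rng.uniform(0.1, 1.0)))
        r1 = stratified_partner_analysis(dm, meta)
        r2 = stratified_partner_analysis(dm, meta)
        assert r1 == r2
        strata = {(r.group, r.site, r.circumcised) for r in r1}
        assert len(strata) == 8


class TestPrevalenceFilter:
    def test_boundary_at_thirty_percent(self):
        counts = np.zeros((2, 65), dtype=int)
        counts[0, :20] = 1  # 20/65 = 30.8 % -> included
        counts[1, :19] = 1  # 19/65 = 29.2 % -> excluded
        table = OtuTable(["in", "out"], [f"s{i}" for i in range(65)], counts)
        assert prevalence_filter(table, table.specimen_ids) == ["in"]

    def test_zero_threshold_keeps_any_occurrence(self):
        counts = np.array([[1, 0], [0, 0]])
        table = OtuTable(["a", "b"], ["s1", "s2"], counts)
        assert prevalence_filter(table, table.specimen_ids, 0.0) == ["a"]


class TestSpearman:
    def build(self, vaginal, male):
        n = len(vaginal)
        meta = toy_metadata(n)
        taxa = ["tax", "rest"]
        ids, cols = [], []
        for i in range(n):
            ids += [f"C{i}V", f"C{i}P", f"C{i}U"]
            cols += [[vaginal[i], 100 - vaginal[i]],
                     [male[i], 100 - male[i]],
                     [0, 100]]
        return OtuTable(taxa, ids, np.array(cols).T), meta

    def test_perfect_monotone(self):
        table, meta = self.build([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        res = spearman_couple_correlations(table, meta, ["tax"], "BV")
        by_pair = {c.site_pair: c for c in res}
        assert by_pair["VG-PS"].rho == pytest.approx(1.0)

    def test_matches_rank_based_oracle(self):
        rng = np.random.default_rng(2)
        v = list(rng.integers(0, 30, size=8))
        m = list(rng.integers(0, 30, size=8))
        table, meta = self.build(v, m)
        res = {c.site_pair: c.rho
               for c in spearman_couple_correlations(table, meta, ["tax"], "BV")}
        # oracle: Pearson correlation of average ranks of relative abundances
        rel_v = np.array(v) / 100.0
        rel_m = np.array(m) / 100.0
        oracle = np.corrcoef(stats.rankdata(rel_v), stats.rankdata(rel_m))[0, 1]
        assert res["VG-PS"] == pytest.approx(oracle)

    def test_too_few_couples_absent(self):
        table, meta = self.build([1, 2, 3], [3, 2, 1])
        res = spearman_couple_correlations(table, meta, ["tax"], "BV")
        assert all(c.rho is None for c in res)

    def test_null_correlations_small(self):
        rng = np.random.default_rng(3)
        rhos = []
        for _ in range(50):
            v = list(rng.integers(0, 50, size=12))
            m = list(rng.integers(0, 50, size=12))
            table, meta = self.build(v, m)
            res = {c.site_pair: c.rho for c in
                   spearman_couple_correlations(table, meta, ["tax"], "BV")}
            rhos.append(res["VG-PS"])
        assert abs(np.mean(rhos)) < 0.15
        assert np.mean(np.abs(rhos) < 2 / np.sqrt(12)) > 0.5


class TestFisherZ:
    def test_equal_correlations(self):
        z, p = fisher_z_compare(0.4, 30, 0.4, 50)
        assert (z, p) == (pytest.approx(0.0), pytest.approx(1.0))

    def test_worked_value(self):
        z, _ = fisher_z_compare(0.5, 50, 0.0, 50)
        assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 47), abs=1e-9)
        assert z == pytest.approx(2.66, abs=0.01)

    def test_antisymmetry(self):
        z1, _ = fisher_z_compare(0.7, 40, 0.2, 35)
        z2, _ = fisher_z_compare(0.2, 35, 0.7, 40)
        assert z1 == pytest.approx(-z2)

    def test_degenerate_rho(self):
        with pytest.raises(ValidationError):
            fisher_z_compare(1.0, 30, 0.5, 30)


class TestContingency:
    def test_chi2_matches_expected_counts_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            table = rng.integers(1, 60, size=(2, 2))
            stat, _ = contingency_test(table, "chi2")
            # from-scratch Pearson statistic
            row = table.sum(axis=1, keepdims=True)
            col = table.sum(axis=0, keepdims=True)
            expected = row * col / table.sum()
            oracle = ((table - expected) ** 2 / expected).sum()
            assert stat == pytest.approx(oracle, abs=1e-10)

    def test_independent_table_null(self):
        table = np.outer([2, 3], [5, 7])
        stat, p = contingency_test(table, "chi2")
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValidationError):
            contingency_test([[0, 5], [0, 3]], "chi2")

    def test_fisher_two_sided_point_probability(self):
        stat, p = contingency_test([[8, 2], [1, 5]], "fisher")
        _, expected = stats.fisher_exact([[8, 2], [1, 5]])
        assert p == pytest.approx(expected)


class TestAbundanceCompare:
    def test_identical_groups_null(self):
        counts = np.tile(np.array([[5], [10], [1]]), (1, 8))
        table = OtuTable(["a", "b", "c"], [f"s{i}" for i in range(8)], counts)
        df = abundance_group_compare(table, table.specimen_ids[:4],
                                     table.specimen_ids[4:])
        assert (df["p"] > 0.9).all()

    def test_bh_monotone_in_sorted_p(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 40, size=(12, 20))
        table = OtuTable([f"t{i}" for i in range(12)],
                         [f"s{i}" for i in range(20)], counts)
        df = abundance_group_compare(table, table.specimen_ids[:10],
                                     table.specimen_ids[10:])
        df = df.sort_values("p")
        assert (np.diff(df["q"]) >= -1e-12).all()

    def test_shifted_taxon_detected(self):
        rng = np.random.default_rng(6)
        n_a, n_b = 20, 12
        base = rng.integers(80, 120, size=(3, n_a + n_b))
        shifted = np.concatenate([rng.integers(200, 400, size=n_a),
                                  rng.integers(5, 30, size=n_b)])
        counts = np.vstack([shifted, base])
        table = OtuTable(["hit", "x", "y", "z"],
                         [f"s{i}" for i in range(n_a + n_b)], counts)
        df = abundance_group_compare(table, table.specimen_ids[:n_a],
                                     table.specimen_ids[n_a:])
        assert df.loc[df["taxon"] == "hit", "q"].iloc[0] < 0.05
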