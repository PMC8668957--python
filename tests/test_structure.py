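"""Clustering post-processing: parsing, deltaK, alignment, estimators."""

import itertools

import numpy as np
import pandas as pd
import pytest

from wheatdiv.structure import (
    QMatrix,
    RunLogProb,
    align_runs,
    assign_membership,
    best_k_evanno,
    evanno,
    parse_structure_run,
    puechmaille,
    regional_summary,
    write_q_csv,
)

NATIVE_FIXTURE = """\
STRUCTURE-style output (synthetic fixture)

Estimated Ln Prob of Data   = -1234.5

Inferred ancestry of individuals:
        Label (%Miss) :  Inferred clusters
  1      ind1    (0)   :  0.900 0.100
  2      ind2    (2)   :  0.250 0.750
  3      ind3    (0)   :  0.500 0.500

"""

CSV_FIXTURE = """\
# lnP=-1234.5
individual_id,group,q_1,q_2
ind1,HU,0.900,0.100
ind2,HU,0.250,0.750
ind3,RO,0.500,0.500
"""


class TestParsing:
    def test_native_fixture(self, tmp_path):
        path = tmp_path / "run.txt"
        path.write_text(NATIVE_FIXTURE)
        q, lnp = parse_structure_run(path)
        assert q.K == 2 and q.individual_ids == ["ind1", "ind2", "ind3"]
        assert lnp.lnP == -1234.5
        assert q.q[0].tolist() == [0.9, 0.1]

    def test_cross_dialect_identity(self, tmp_path):
        native = tmp_path / "run.txt"
        native.write_text(NATIVE_FIXTURE)
        csv = tmp_path / "run.csv"
        csv.write_text(CSV_FIXTURE)
        q1, lnp1 = parse_structure_run(native)
        q2, lnp2 = parse_structure_run(csv)
        assert np.allclose(q1.q, q2.q)
        assert lnp1.lnP == lnp2.lnP

    def test_row_sum_renormalized_with_warning(self, caplog):
        with caplog.at_level("WARNING"):
            q = QMatrix("r", 2, ["i1"], np.array([[0.5, 0.502]]))
        assert "renormalized" in caplog.text
        assert q.q.sum() == pytest.approx(1.0)

    def test_missing_block_is_error(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("Estimated Ln Prob of Data = -10\nno block here\n")
        with pytest.raises(ValueError, match="ancestry"):
            parse_structure_run(path)

    def test_inconsistent_k_is_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("# lnP=-1\nindividual_id,group,q_1,q_2\ni1,g,0.5,0.5\ni2,g,1.0\n")
        with pytest.raises(ValueError, match="inconsistent K"):
            parse_structure_run(path)

    def test_csv_round_trip(self, tmp_path):
        rng = np.random.default_rng(80)
        raw = rng.dirichlet([1, 1, 1], size=5)
        q = QMatrix("r1", 3, [f"i{i}" for i in range(5)], raw)
        lnp = RunLogProb("r1", 3, -555.25)
        write_q_csv(q, lnp, tmp_path / "q.csv")
        q2, lnp2 = parse_structure_run(tmp_path / "q.csv", run_id="r1")
        assert np.allclose(q.q, q2.q, atol=1e-5)
        assert lnp2.lnP == -555.25


class TestEvanno:
    def test_hand_computation(self):
        runs = (
            [RunLogProb(f"a{i}", 1, -1000.0) for i in range(3)]
            + [RunLogProb(f"b{i}", 2, v) for i, v in enumerate([-790.0, -800.0, -810.0])]
            + [RunLogProb(f"c{i}", 3, -780.0) for i in range(3)]
            + [RunLogProb(f"d{i}", 4, -775.0) for i in range(3)]
        )
        table = evanno(runs)
        assert table.loc[2, "deltaK"] == pytest.approx(18.0)
        assert best_k_evanno(table) == 2

    def test_linear_curve_gives_zero(self):
        rng = np.random.default_rng(81)
        runs = []
        for K in range(1, 6):
            for r in range(4):
                runs.append(RunLogProb(f"K{K}r{r}", K, -1000.0 + 50.0 * K + 0.0))
        # add identical jitter per replicate index so sd > 0 but curve linear
        runs = [
            RunLogProb(x.run_id, x.K, x.lnP + [0.0, 1.0, 2.0, 3.0][int(x.run_id[-1])])
            for x in runs
        ]
        table = evanno(runs)
        defined = table["deltaK"].dropna()
        assert np.allclose(defined.values, 0.0)

    def test_endpoints_undefined(self):
        runs = [RunLogProb(f"K{K}r{r}", K, -100.0 * K + r) for K in (1, 2, 3) for r in range(2)]
        table = evanno(runs)
        assert np.isnan(table.loc[1, "deltaK"]) and np.isnan(table.loc[3, "deltaK"])

    def test_unequal_replicates_rejected(self):
        runs = [RunLogProb("a", 1, -1.0), RunLogProb("b", 1, -2.0),
                RunLogProb("c", 2, -1.0), RunLogProb("d", 2, -2.0),
                RunLogProb("e", 3, -1.0), RunLogProb("f", 3, -2.0), RunLogProb("g", 3, -3.0)]
        with pytest.raises(ValueError, match="replicate"):
            evanno(runs)


def random_q(rng, n, K, run_id="r"):
    return QMatrix(run_id, K, [f"i{i}" for i in range(n)], rng.dirichlet([1.0] * K, size=n))


class TestAlignRuns:
    def test_permuted_copy_recovered(self):
        rng = np.random.default_rng(82)
        ref = random_q(rng, 12, 4, "ref")
        perm = [2, 0, 3, 1]
        moved = QMatrix("moved", 4, ref.individual_ids, ref.q[:, perm])
        aligned, perms = align_runs([ref, moved])
        assert np.allclose(aligned[1].q, ref.q)
        assert perms["ref"] == (0, 1, 2, 3)

    def test_cost_not_worse_than_identity_and_optimal(self):
        rng = np.random.default_rng(83)
        ref = random_q(rng, 10, 4, "ref")
        for trial in range(20):
            noisy = QMatrix(
                f"t{trial}", 4, ref.individual_ids,
                np.abs(ref.q[:, rng.permutation(4)] + rng.normal(0, 0.05, ref.q.shape)),
            )
            aligned, perms = align_runs([ref, noisy])
            cost_aligned = ((ref.q - aligned[1].q) ** 2).sum()
            cost_raw = ((ref.q - noisy.q) ** 2).sum()
            assert cost_aligned <= cost_raw + 1e-9
            # exhaustive K! check
            best = min(
                ((ref.q - noisy.q[:, list(p)]) ** 2).sum()
                for p in itertools.permutations(range(4))
            )
            assert cost_aligned == pytest.approx(best)

    def test_k_mismatch_rejected(self):
        rng = np.random.default_rng(84)
        with pytest.raises(ValueError, match="equal K"):
            align_runs([random_q(rng, 5, 3), random_q(rng, 5, 4)])


class TestPuechmaille:
    def make_q(self, rows, run_id="r"):
        rows = np.asarray(rows, dtype=float)
        return QMatrix(run_id, rows.shape[1], [f"i{i}" for i in range(rows.shape[0])], rows)

    def test_two_genuine_clusters(self):
        rows = [[0.8, 0.1, 0.1]] * 3 + [[0.1, 0.8, 0.1]] * 3
        groups = {f"i{i}": ("g1" if i < 3 else "g2") for i in range(6)}
        result = puechmaille([self.make_q(rows, f"r{j}") for j in range(3)], groups)
        assert (result.med_mea_k, result.max_mea_k, result.med_med_k, result.max_med_k) == (2, 2, 2, 2)

    def test_uniform_memberships_count_zero(self):
        rows = [[1 / 3] * 3] * 4
        groups = {f"i{i}": "g1" for i in range(4)}
        result = puechmaille([self.make_q(rows)], groups)
        assert result.max_mea_k == 0

    def test_one_to_one_groups(self):
        rows = np.eye(4).repeat(2, axis=0) * 0.97 + 0.0075
        groups = {f"i{i}": f"g{i // 2}" for i in range(8)}
        result = puechmaille([self.make_q(rows)], groups)
        assert result.max_mea_k == result.med_med_k == 4

    def test_label_permutation_invariance(self):
        rng = np.random.default_rng(85)
        qs = [random_q(rng, 9, 3, f"r{j}") for j in range(4)]
        groups = {f"i{i}": f"g{i % 3}" for i in range(9)}
        base = puechmaille(qs, groups)
        permuted = [q.permuted(rng.permutation(3)) for q in qs]
        again = puechmaille(permuted, groups)
        assert base.per_k.equals(again.per_k)

    def test_med_below_max(self):
        rng = np.random.default_rng(86)
        qs = [random_q(rng, 12, 4, f"r{j}") for j in range(6)]
        groups = {f"i{i}": f"g{i % 4}" for i in range(12)}
        result = puechmaille(qs, groups)
        assert (result.per_k["MedMedK"] <= result.per_k["MaxMedK"]).all()
        assert (result.per_k["MedMeaK"] <= result.per_k["MaxMeaK"]).all()

    def test_unlabeled_individual_rejected(self):
        rng = np.random.default_rng(87)
        with pytest.raises(ValueError, match="group label"):
            puechmaille([random_q(rng, 3, 2)], {"i0": "g"})


class TestMembership:
    def test_clear_winner(self):
        q = QMatrix("r", 3, ["i1"], np.array([[0.6, 0.3, 0.1]]))
        assert assign_membership(q).loc["i1"] == 0

    def test_tie_unassigned(self):
        q = QMatrix("r", 2, ["i1"], np.array([[0.5, 0.5]]))
        assert assign_membership(q).loc["i1"] == -1

    def test_matches_brute_force(self):
        rng = np.random.default_rng(88)
        q = random_q(rng, 30, 4)
        assigned = assign_membership(q, threshold=0.5)
        for i, ind in enumerate(q.individual_ids):
            winners = [k for k in range(4) if q.q[i, k] > 0.5]
            assert assigned.loc[ind] == (winners[0] if winners else -1)


class TestRegionalSummary:
    def make_meta(self, ids, regions, chrono="landrace"):
        return pd.DataFrame(
            {"region": regions, "chrono_class": chrono}, index=pd.Index(ids)
        )

    def test_singleton_region(self):
        q = QMatrix("r", 2, ["i1", "i2"], np.array([[0.7, 0.3], [0.2, 0.8]]))
        meta = self.make_meta(["i1", "i2"], ["R1", "R2"])
        summary = regional_summary(q, meta)
        assert summary.loc["R1"].tolist() == pytest.approx([0.7, 0.3])

    def test_rows_sum_to_one_and_match_groupby(self):
        rng = np.random.default_rng(89)
        q = random_q(rng, 20, 3)
        regions = [f"R{i % 4}" for i in range(20)]
        meta = self.make_meta(q.individual_ids, regions)
        summary = regional_summary(q, meta)
        assert np.allclose(summary.sum(axis=1), 1.0, atol=1e-9)
        for region in set(regions):
            members = [i for i, r in enumerate(regions) if r == region]
            expected = q.q[members].mean(axis=0)
            assert np.allclose(summary.loc[region].values, expected)

    def test_chrono_filter(self):
        q = QMatrix("r", 2, ["i1", "i2"], np.array([[1.0, 0.0], [0.0, 1.0]]))
        meta = pd.DataFrame(
            {"region": ["R1", "R1"], "chrono_class": ["landrace", "modern"]},
            index=["i1", "i2"],
        )
        summary = regional_summary(q, meta, chrono_class="landrace")
        assert summary.loc["R1"].tolist() == [1.0, 0.0]
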