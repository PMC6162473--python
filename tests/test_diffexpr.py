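import numpy as np
import pandas as pd
import pytest

from mgtkit import ExpressionMatrix, SimulationConfig
import mgtkit.diffexpr as de
from mgtkit.diffexpr import partition_subtypes, summarize_degs
from mgtkit.simulate import generate_annotation, simulate_expression


def matrix_from_groups(tumor_rows, normal_rows, gene_ids=None, subtype="complex"):
    """Build an ExpressionMatrix from per-gene tumour / normal value lists."""
    nt, nn = len(tumor_rows[0]), len(normal_rows[0])
    meta = pd.DataFrame({
        "animal_id": [f"a{i}" for i in range(nt)] + [f"b{i}" for i in range(nn)],
        "condition": ["tumor"] * nt + ["normal"] * nn,
        "subtype": [subtype] * (nt + nn),
    }, index=[f"t{i}" for i in range(nt)] + [f"n{i}" for i in range(nn)])
    gene_ids = gene_ids or [f"g{i}" for i in range(len(tumor_rows))]
    values = pd.DataFrame(
        [list(t) + list(n) for t, n in zip(tumor_rows, normal_rows)],
        index=gene_ids, columns=meta.index, dtype=float)
    return ExpressionMatrix(values=values, meta=meta)


class TestDifferentialTest:
    def test_log2fc_with_pseudocount(self):
        m = matrix_from_groups([[8, 8, 8]], [[2, 2, 2]])
        rec = de.test_differential(m, "complex", eps=0.1)
        assert rec.loc[0, "log2fc"] == pytest.approx(np.log2(8.1 / 2.1), abs=1e-9)
        assert abs(rec.loc[0, "log2fc"] - 1.948) < 1e-3
        assert abs(rec.loc[0, "log2fc"]) >= 1  # clears the 2-fold gate

    def test_identical_groups_null_under_permutation(self):
        m = matrix_from_groups([[1, 2, 3]], [[1, 2, 3]])
        rec = de.test_differential(m, "complex", test="permutation")
        assert rec.loc[0, "log2fc"] == 0
        assert rec.loc[0, "p_value"] == 1.0
        assert rec.loc[0, "direction"] == "none"

    def test_exact_twofold_passes_gate(self):
        # eps=0 makes the fold change exactly 2; zero within-group variance
        # drives p to 0, so the inclusive |log2fc| >= 1 gate decides.
        m = matrix_from_groups([[4, 4, 4]], [[2, 2, 2]])
        rec = de.test_differential(m, "complex", eps=0.0)
        assert rec.loc[0, "log2fc"] == pytest.approx(1.0)
        assert bool(rec.loc[0, "passes"])

    def test_alpha_is_strict(self):
        # 3v3 full separation under the permutation test gives exactly
        # p = 2/20 = 0.1; at alpha = 0.1 the strict '<' must reject it.
        m = matrix_from_groups([[40, 41, 42]], [[1, 2, 3]])
        rec = de.test_differential(m, "complex", test="permutation", alpha=0.1)
        assert rec.loc[0, "p_value"] == pytest.approx(0.1)
        assert not bool(rec.loc[0, "passes"])
        rec2 = de.test_differential(m, "complex", test="permutation", alpha=0.11)
        assert bool(rec2.loc[0, "passes"])

    def test_small_group_errors(self):
        m = matrix_from_groups([[1, 2]], [[3]])
        with pytest.raises(ValueError, match="complex"):
            de.test_differential(m, "complex")

    def test_planted_gene_is_the_only_hit(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(5, 50, size=10)
        tumor = np.tile(base, (3, 1)).T * rng.normal(1, 0.01, size=(10, 3))
        normal = np.tile(base, (3, 1)).T * rng.normal(1, 0.01, size=(10, 3))
        tumor[4] *= 8  # planted log2fc = 3
        m = matrix_from_groups(tumor.tolist(), normal.tolist())
        rec = de.test_differential(m, "complex")
        assert rec["passes"].sum() == 1
        assert rec.loc[rec["passes"], "gene_id"].item() == "g4"

    def test_permutation_null_is_valid(self):
        """Under the global null, P(p <= alpha) <= alpha + enumeration granularity."""
        rng = np.random.default_rng(3)
        vals = rng.lognormal(2, 0.5, size=(300, 6))
        m = matrix_from_groups(vals[:, :3].tolist(), vals[:, 3:].tolist())
        rec = de.test_differential(m, "complex", test="permutation")
        for alpha in (0.1, 0.2, 0.5):
            frac = (rec["p_value"] <= alpha).mean()
            assert frac <= alpha + 1 / 20 + 3 * np.sqrt(alpha * (1 - alpha) / 300)

    def test_passes_iff_both_gates(self, simulated):
        _, expr = simulated
        m = ExpressionMatrix(values=expr.fpkm, meta=expr.meta)
        rec = de.test_differential(m, "overall")
        expect = (rec["log2fc"].abs() >= 1) & (rec["p_value"] < 0.01)
        assert (rec["passes"] == expect).all()
        up = rec.loc[rec["direction"] == "up"]
        assert (up["log2fc"] > 0).all() and up["passes"].all()


class TestPartition:
    def frame(self, up, down=()):
        rows = [{"gene_id": g, "comparison": "x", "log2fc": 2.0, "p_value": 1e-4,
                 "direction": "up", "passes": True} for g in up]
        rows += [{"gene_id": g, "comparison": "x", "log2fc": -2.0, "p_value": 1e-4,
                  "direction": "down", "passes": True} for g in down]
        rows.append({"gene_id": "bg", "comparison": "x", "log2fc": 0.0, "p_value": 0.9,
                     "direction": "none", "passes": False})
        return pd.DataFrame(rows)

    def test_three_way_and_union(self):
        part = partition_subtypes({
            "complex": self.frame({"a", "b"}),
            "ductal": self.frame({"b", "c"}),
            "simple": self.frame({"b", "d"}),
        })
        cells = part.venn_cells("up")
        assert cells["complex+ductal+simple"] == {"b"}
        assert set().union(*cells.values()) == {"a", "b", "c", "d"}
        assert part.exclusive("complex") == {"a"}

    def test_disjoint_sets_have_empty_intersections(self):
        part = partition_subtypes({
            "complex": self.frame({"a"}), "ductal": self.frame({"b"}), "simple": self.frame({"c"}),
        })
        cells = part.venn_cells("up")
        assert cells["complex+ductal+simple"] == set()
        assert all(not v for k, v in cells.items() if "+" in k)

    def test_venn_cells_partition_each_subtype(self):
        part = partition_subtypes({
            "complex": self.frame({"a", "b", "e"}, {"z"}),
            "ductal": self.frame({"b", "c"}, {"z", "y"}),
            "simple": self.frame({"b", "d", "e"}),
        })
        for direction in ("up", "down"):
            cells = part.venn_cells(direction)
            sets = part.up if direction == "up" else part.down
            # cells are disjoint and cover the union
            union = set().union(*cells.values())
            assert union == set().union(*sets.values())
            assert sum(len(v) for v in cells.values()) == len(union)
            # triple cell is inside every pairwise intersection
            triple = cells["complex+ductal+simple"]
            for a in ("complex", "ductal", "simple"):
                assert triple <= sets[a]

    def test_direction_counts_conserved(self):
        f = self.frame({"a", "b"}, {"c"})
        part = partition_subtypes({"complex": f, "ductal": f, "simple": f})
        assert len(part.up["complex"]) + len(part.down["complex"]) == int(f["passes"].sum())


class TestSummary:
    def records(self, lfcs, p=1e-4):
        return pd.DataFrame([
            {"gene_id": f"g{i}", "comparison": "overall", "log2fc": l, "p_value": p,
             "direction": "up" if l > 0 else "down", "passes": True}
            for i, l in enumerate(lfcs)])

    def test_top_by_signed_fold_change(self):
        out = summarize_degs(self.records([2.0, -3.0, 1.0]), n=1)
        up = out[out["which"] == "up"]
        down = out[out["which"] == "down"]
        assert up["log2fc"].item() == 2.0 and down["log2fc"].item() == -3.0

    def test_neg_log10_p(self):
        out = summarize_degs(self.records([2.0], p=0.00005), n=1)
        assert out["neg_log10_p"].item() == pytest.approx(4.301029996, abs=1e-8)

    def test_ties_broken_lexicographically(self):
        recs = self.records([2.0, 2.0, 2.0])
        recs["gene_id"] = ["gc", "ga", "gb"]
        out = summarize_degs(recs, n=3)
        assert list(out.loc[out["which"] == "up", "gene_id"]) == ["ga", "gb", "gc"]

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            summarize_degs(pd.DataFrame())
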