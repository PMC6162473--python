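import warnings

import numpy as np
import pandas as pd
import pytest

from mgtkit.annotation import build_prompt_regions, parse_gtf, write_gtf
from mgtkit.quantify import count_fragments, features_from_regions
from mgtkit.simulate import (
    ConfigError,
    SimulationConfig,
    choose_prompt_pairs,
    generate_annotation,
    sample_table,
    simulate_all,
    simulate_expression,
    simulate_prompt_fragments,
    simulate_qpcr,
)


class TestConfig:
    def test_defaults_validate(self):
        SimulationConfig().validate()

    @pytest.mark.parametrize("kwargs", [
        {"gene_length_range": (0, 100)},
        {"intergenic_gap_range": (500, 100)},
        {"planted_log2fc_range": (0.5, 2.0)},
        {"n_genes": 5, "n_planted_degs_overall": 10},
        {"n_prompt_positive": 50},
        {"qpcr_n_pairs": 1},
        {"nb_dispersion": -0.1},
        {"n_genes": 10, "n_chromosomes": 0},
    ])
    def test_inconsistent_configs_rejected(self, kwargs):
        with pytest.raises(ConfigError):
            SimulationConfig(**kwargs).validate()

    def test_paired_design_sample_table(self):
        meta = sample_table(SimulationConfig())
        assert len(meta) == 16  # 8 animals x (tumor, normal)
        assert (meta.groupby("animal_id")["condition"].nunique() == 2).all()
        assert meta["subtype"].value_counts().to_dict() == {"complex": 6, "ductal": 6, "simple": 4}


class TestAnnotation:
    def test_same_seed_identical_gtf_bytes(self, tmp_path):
        cfg = SimulationConfig(seed=7, n_genes=50)
        a, b = tmp_path / "a.gtf", tmp_path / "b.gtf"
        write_gtf(generate_annotation(cfg), a)
        write_gtf(generate_annotation(cfg), b)
        assert a.read_bytes() == b.read_bytes()

    def test_zero_genes_yields_valid_empty_gtf(self, tmp_path):
        genes = generate_annotation(SimulationConfig(n_genes=0, n_planted_degs_overall=0,
                                                     n_planted_degs_per_subtype=0,
                                                     n_prompt_positive=0, n_prompt_negative=0))
        assert genes == []
        p = tmp_path / "empty.gtf"
        write_gtf(genes, p)
        assert parse_gtf(p) == []

    def test_genes_do_not_overlap_within_chromosome(self):
        genes = generate_annotation(SimulationConfig(seed=3, n_genes=80))
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs = sorted(gs, key=lambda g: g.start)
            for a, b in zip(gs, gs[1:]):
                assert a.end <= b.start

    def test_both_strands_present(self):
        genes = generate_annotation(SimulationConfig(seed=1, n_genes=40))
        assert {g.strand for g in genes} == {"+", "-"}

    def test_close_upstream_neighbors_exist_when_gaps_allow(self):
        cfg = SimulationConfig(seed=5, n_genes=40, intergenic_gap_range=(500, 1400))
        genes = generate_annotation(cfg)
        gaps = []
        by_chrom = {}
        for g in genes:
            by_chrom.setdefault(g.chrom, []).append(g)
        for gs in by_chrom.values():
            gs = sorted(gs, key=lambda g: g.start)
            gaps += [b.start - a.end for a, b in zip(gs, gs[1:])]
        assert any(g < 1500 for g in gaps)

    def test_generated_gtf_parses_without_warnings(self, tmp_path):
        p = tmp_path / "g.gtf"
        write_gtf(generate_annotation(SimulationConfig(seed=2)), p)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            genes = parse_gtf(p)
        assert len(genes) == SimulationConfig().n_genes


class TestExpression:
    def test_truth_has_k_rows_per_subtype(self, simulated):
        _, expr = simulated
        cfg = SimulationConfig()
        counts = expr.truth["comparison"].value_counts()
        for st in ("complex", "ductal", "simple"):
            assert counts[st] == cfg.n_planted_degs_per_subtype
        assert counts["overall"] == cfg.n_planted_degs_overall

    def test_same_seed_identical_matrices(self):
        cfg = SimulationConfig(seed=9)
        genes = generate_annotation(cfg)
        a = simulate_expression(genes, cfg)
        b = simulate_expression(genes, cfg)
        pd.testing.assert_frame_equal(a.counts, b.counts)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_low_dispersion_mean_ratio_matches_planted_fold(self):
        """Near the Poisson limit the tumour/normal mean ratio is 2^log2fc within 1%."""
        cfg = SimulationConfig(
            seed=13, n_genes=10, n_chromosomes=1, nb_dispersion=1e-9,
            n_animals_per_subtype={"complex": 600},  # >= 1000 paired draws
            n_planted_degs_overall=4, n_planted_degs_per_subtype=0,
            n_prompt_positive=2, n_prompt_negative=1,
            planted_log2fc_range=(2.0, 2.0),
            animal_sigma=0.0, normal_extra_sigma=0.0,
        )
        genes = generate_annotation(cfg)
        expr = simulate_expression(genes, cfg)
        tumor = expr.meta.index[expr.meta["condition"] == "tumor"]
        normal = expr.meta.index[expr.meta["condition"] == "normal"]
        for _, row in expr.truth.iterrows():
            ratio = expr.counts.loc[row["gene_id"], tumor].mean() / \
                expr.counts.loc[row["gene_id"], normal].mean()
            assert ratio == pytest.approx(2.0 ** row["log2fc"], rel=0.01)

    def test_empty_annotation_rejected(self):
        cfg = SimulationConfig(n_genes=0, n_planted_degs_overall=0,
                               n_planted_degs_per_subtype=0,
                               n_prompt_positive=0, n_prompt_negative=0)
        with pytest.raises(ValueError):
            simulate_expression([], cfg)


class TestPromptFragments:
    def setup_pieces(self, cfg):
        genes = generate_annotation(cfg)
        expr = simulate_expression(genes, cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            regions = build_prompt_regions(genes)
        pos, neg = choose_prompt_pairs(expr.truth, regions, cfg)
        return genes, expr, regions, pos, neg

    def test_zero_background_rate_leaves_unplanted_windows_empty(self):
        cfg = SimulationConfig(seed=4, prompt_background_rate=0.0)
        genes, expr, regions, pos, neg = self.setup_pieces(cfg)
        frags, _ = simulate_prompt_fragments(regions, expr.meta, pos, neg, expr.truth, cfg)
        counts = count_fragments(features_from_regions(regions), frags,
                                strand_mode="ignore", samples=list(expr.meta.index))
        planted = set(pos) | set(neg)
        background = counts.drop(index=[g for g in counts.index if g in planted])
        assert (background.to_numpy() == 0).all()
        assert (counts.loc[sorted(planted)].to_numpy().sum(axis=1) > 0).all()

    def test_positive_window_ratio_at_least_two(self):
        cfg = SimulationConfig(seed=8, prompt_fragment_rate=20.0, prompt_planted_fold=4.0)
        genes, expr, regions, pos, neg = self.setup_pieces(cfg)
        frags, truth = simulate_prompt_fragments(regions, expr.meta, pos, neg, expr.truth, cfg)
        counts = count_fragments(features_from_regions(regions), frags,
                                strand_mode="ignore", samples=list(expr.meta.index))
        tumor = expr.meta.index[expr.meta["condition"] == "tumor"]
        normal = expr.meta.index[expr.meta["condition"] == "normal"]
        gene_sign = expr.truth.set_index("gene_id")["log2fc"]
        for g in pos:
            t = counts.loc[g, tumor].mean() + 0.5
            n = counts.loc[g, normal].mean() + 0.5
            ratio = t / n if gene_sign[g] > 0 else n / t
            assert ratio >= 2.0  # planted 4-fold, Poisson noise over 8v8 samples

    def test_fragments_stay_inside_their_window(self):
        cfg = SimulationConfig(seed=6)
        genes, expr, regions, pos, neg = self.setup_pieces(cfg)
        frags, _ = simulate_prompt_fragments(regions, expr.meta, pos, neg, expr.truth, cfg)
        allowed = []
        for r in regions:
            allowed += [(r.chrom, s, e) for s, e in r.intervals]
        for _, fr in frags.sample(50, random_state=0).iterrows():
            assert any(c == fr["chrom"] and s <= fr["start"] and fr["end"] <= e
                       for c, s, e in allowed)
        assert (frags["start"] >= 0).all()

    def test_same_seed_identical_fragments(self):
        cfg = SimulationConfig(seed=10)
        genes, expr, regions, pos, neg = self.setup_pieces(cfg)
        a, _ = simulate_prompt_fragments(regions, expr.meta, pos, neg, expr.truth, cfg)
        b, _ = simulate_prompt_fragments(regions, expr.meta, pos, neg, expr.truth, cfg)
        pd.testing.assert_frame_equal(a, b)

    def test_planted_gene_with_empty_window_skipped(self):
        cfg = SimulationConfig(seed=4)
        genes, expr, regions, pos, neg = self.setup_pieces(cfg)
        emptied = []
        for r in regions:
            if r.gene_id == pos[0]:
                from mgtkit.annotation import PromptRegion
                emptied.append(PromptRegion(r.gene_id, r.chrom, r.strand, [], r.window_length))
            else:
                emptied.append(r)
        with pytest.warns(UserWarning, match="fully excluded"):
            _, truth = simulate_prompt_fragments(emptied, expr.meta, pos, neg, expr.truth, cfg)
        assert truth.set_index("gene_id").loc[pos[0], "class"] == "skipped"


class TestQpcr:
    def test_rows_per_gene(self):
        cfg = SimulationConfig(seed=1, qpcr_n_pairs=12)
        table = simulate_qpcr(cfg, {"A": 2.0, "B": 0.5})
        assert (table.groupby("gene").size() == 24).all()

    def test_unit_fold_change_has_unit_mean_expression(self):
        cfg = SimulationConfig(seed=5, qpcr_n_pairs=500, qpcr_sd_ct=0.5)
        from mgtkit.validation import ddct
        out = ddct(simulate_qpcr(cfg, {"NULL": 1.0}))
        t = out.loc[out["condition"] == "tumor", "rel_expr"]
        # 2^-ddCt of a null gene: log-mean is 0, so the median sits at 1
        assert np.median(t) == pytest.approx(1.0, abs=0.15)

    def test_reference_ct_condition_independent(self):
        cfg = SimulationConfig(seed=2, qpcr_n_pairs=400, qpcr_sd_ct=0.8)
        table = simulate_qpcr(cfg, {"A": 8.0})
        m = table.groupby("condition")["ct_reference"].mean()
        assert abs(m["tumor"] - m["normal"]) < 0.15


class TestSimulateAll:
    def test_deterministic_files(self, tmp_path):
        cfg = SimulationConfig(seed=17)
        p1 = simulate_all(cfg, tmp_path / "a")
        p2 = simulate_all(cfg, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name
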