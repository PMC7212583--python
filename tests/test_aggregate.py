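import numpy as np
import pandas as pd
import pytest

from pwmbench import (ALL_ASSAYS, FamilyAnnotation, PerformanceMatrix,
                      QualityThresholds, aggregate_rank_score,
                      best_matrix_per_gene, best_matrix_report,
                      family_cross_table, nonredundant_library,
                      quality_filter, ranks_within_experiment)


def make_perf(values, assays=None, genes=None):
    """values: dict experiment_id -> dict matrix_id -> value."""
    df = pd.DataFrame(values).T
    n = len(df)
    meta = pd.DataFrame({
        "gene_symbol": genes or ["G1"] * n,
        "assay": assays or ["chipseq"] * n,
    }, index=df.index)
    return PerformanceMatrix(df, meta)


class TestRanks:
    def test_best_value_gets_rank_one(self):
        row = pd.Series({"a": 0.9, "b": 0.7, "c": 0.8})
        assert ranks_within_experiment(row).to_dict() == {"a": 1, "b": 3, "c": 2}

    def test_ties_average_spanned_ranks(self):
        row = pd.Series({"a": 0.9, "b": 0.9})
        assert ranks_within_experiment(row).to_dict() == {"a": 1.5, "b": 1.5}

    def test_single_value_and_missing(self):
        row = pd.Series({"a": 0.4, "b": np.nan})
        ranks = ranks_within_experiment(row)
        assert ranks.to_dict() == {"a": 1.0}
        with pytest.raises(ValueError):
            ranks_within_experiment(pd.Series({"a": np.nan}))


class TestAggregateRankScore:
    def test_single_experiment_is_its_rank(self):
        perf = make_perf({"e1": {"a": 0.5, "b": 0.7, "c": 0.9}})
        assert aggregate_rank_score("a", "G1", "chipseq", perf) == 3.0

    def test_geometric_mean_of_ranks(self):
        perf = make_perf({
            "e1": {"a": 0.9, "b": 0.5, "c": 0.4, "d": 0.3},  # a rank 1
            "e2": {"a": 0.4, "b": 0.9, "c": 0.8, "d": 0.7},  # a rank 4
        })
        assert aggregate_rank_score("a", "G1", "chipseq", perf) == \
            pytest.approx(2.0)

    def test_always_ranked_first_attains_lower_bound(self):
        perf = make_perf({f"e{i}": {"a": 0.9, "b": 0.1} for i in range(4)})
        assert aggregate_rank_score("a", "G1", "chipseq", perf) == 1.0

    def test_no_qualifying_experiments_rejected(self):
        perf = make_perf({"e1": {"a": 0.9, "b": np.nan}})
        with pytest.raises(ValueError):
            aggregate_rank_score("b", "G1", "chipseq", perf)

    @pytest.mark.parametrize("seed", range(10))
    def test_bounds_and_permutation_invariance(self, seed):
        rng = np.random.default_rng(seed)
        vals = {f"e{i}": {f"m{j}": rng.random() for j in range(6)}
                for i in range(5)}
        perf = make_perf(vals)
        score = aggregate_rank_score("m0", "G1", "chipseq", perf)
        assert 1.0 <= score <= 6.0
        order = rng.permutation(5)
        shuffled = make_perf({f"e{i}": vals[f"e{order[i]}"] for i in range(5)})
        assert aggregate_rank_score("m0", "G1", "chipseq", shuffled) == \
            pytest.approx(score)


class TestBestMatrix:
    def test_uniformly_better_wins(self):
        perf = make_perf({"e1": {"a": 0.9, "b": 0.5},
                          "e2": {"a": 0.8, "b": 0.6}})
        assert best_matrix_per_gene("G1", "chipseq", perf) == "a"

    def test_tie_broken_by_mean_raw_performance(self):
        # both matrices rank 1 in one experiment and 2 in the other
        perf = make_perf({"e1": {"a": 0.9, "b": 0.8},
                          "e2": {"a": 0.7, "b": 0.75}})
        # aggregate scores equal (sqrt(2) each); a has higher mean value
        assert best_matrix_per_gene("G1", "chipseq", perf) == "a"

    def test_single_matrix_is_best(self):
        perf = make_perf({"e1": {"a": 0.2}})
        assert best_matrix_per_gene("G1", "chipseq", perf) == "a"

    @pytest.mark.parametrize("seed", range(5))
    def test_adding_dominated_matrix_changes_nothing(self, seed):
        rng = np.random.default_rng(seed)
        vals = {f"e{i}": {f"m{j}": rng.uniform(0.3, 1.0) for j in range(5)}
                for i in range(4)}
        best_before = best_matrix_per_gene("G1", "chipseq", make_perf(vals))
        for e in vals:
            vals[e]["zzz_dominated"] = min(vals[e].values()) - 0.1
        assert best_matrix_per_gene("G1", "chipseq", make_perf(vals)) == \
            best_before


class TestQualityFilter:
    def make_report(self):
        return pd.DataFrame([
            {"gene_symbol": "G1", "assay_group": "chipseq", "matrix_id": "a",
             "aggregate_rank_score": 1.0, "best_value": 0.75},
            {"gene_symbol": "G2", "assay_group": "chipseq", "matrix_id": "b",
             "aggregate_rank_score": 1.0, "best_value": 0.76},
            {"gene_symbol": "G3", "assay_group": "pbm", "matrix_id": "c",
             "aggregate_rank_score": 1.0, "best_value": 0.36},
        ])

    def test_strict_inequality_at_boundary(self):
        out = quality_filter(self.make_report())
        assert list(out["gene_symbol"]) == ["G2", "G3"]  # 0.75 exactly fails

    def test_gene_passing_only_via_pbm_kept_in_pooled_group(self):
        perf = make_perf({"e1": {"a": 0.5}, "e2": {"a": 0.4}},
                         assays=["chipseq", "pbm"], genes=["G1", "G1"])
        report = best_matrix_report(perf, assay_groups=(ALL_ASSAYS,))
        kept = quality_filter(report, QualityThresholds(), perf=perf)
        assert list(kept["gene_symbol"]) == ["G1"]  # r=0.4 > 0.35 suffices
        strict = quality_filter(report, QualityThresholds(r_min=0.45),
                                perf=perf)
        assert strict.empty


class TestFamilyCrossTable:
    def test_single_cell_mean(self):
        perf = make_perf({"e1": {"a": 0.8, "b": 0.8},
                          "e2": {"a": 0.8, "b": 0.8}},
                         genes=["G1", "G2"])
        fam = FamilyAnnotation({"a": "F", "b": "F"}, {"G1": "F", "G2": "F"})
        table = family_cross_table(perf, fam)
        assert table.loc["F", "F"] == pytest.approx(0.8)

    def test_small_families_omitted(self):
        perf = make_perf({"e1": {"a": 0.9, "b": 0.5},
                          "e2": {"a": 0.9, "b": 0.5}},
                         genes=["G1", "G2"])
        fam = FamilyAnnotation({"a": "F1", "b": "F2"},
                               {"G1": "E", "G2": "E"})
        table = family_cross_table(perf, fam)  # one PWM per family
        assert table.empty or ("F1" not in table.index
                               and "F2" not in table.index)

    def test_same_family_signal_dominates_diagonal(self):
        rng = np.random.default_rng(0)
        genes = [f"G{i}" for i in range(4)]
        families = {"G0": "FA", "G1": "FA", "G2": "FB", "G3": "FB"}
        mat_fam = {f"m{i}": families[f"G{i}"] for i in range(4)}
        vals, gene_order = {}, []
        for rep in range(2):
            for g in genes:
                eid = f"{g}_r{rep}"
                vals[eid] = {
                    m: (0.9 if mat_fam[m] == families[g] else 0.5)
                    + rng.normal(0, 0.01) for m in mat_fam}
                gene_order.append(g)
        perf = make_perf(vals, genes=gene_order)
        table = family_cross_table(perf, FamilyAnnotation(mat_fam, families))
        diag = np.mean([table.loc["FA", "FA"], table.loc["FB", "FB"]])
        off = np.mean([table.loc["FA", "FB"], table.loc["FB", "FA"]])
        assert diag > off

    def test_cell_values_bounded_by_contributions(self):
        perf = make_perf({"e1": {"a": 0.7, "b": 0.9}}, genes=["G1"])
        fam = FamilyAnnotation({"a": "F", "b": "F"}, {"G1": "E"})
        table = family_cross_table(perf, fam, min_pwms=1, min_datasets=1)
        assert 0.7 <= table.loc["F", "E"] <= 0.9


class TestNonredundantLibrary:
    def test_shared_best_matrix_collapses(self):
        perf = make_perf({"e1": {"a": 0.9, "b": 0.1},
                          "e2": {"a": 0.9, "b": 0.1},
                          "e3": {"a": 0.9, "b": 0.1}},
                         genes=["G1", "G2", "G3"])
        assert nonredundant_library(perf) == {"a"}

    def test_disjoint_bests_all_kept(self):
        perf = make_perf({"e1": {"a": 0.9, "b": 0.1, "c": 0.1},
                          "e2": {"a": 0.1, "b": 0.9, "c": 0.1},
                          "e3": {"a": 0.1, "b": 0.1, "c": 0.9}},
                         genes=["G1", "G2", "G3"])
        assert nonredundant_library(perf) == {"a", "b", "c"}
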