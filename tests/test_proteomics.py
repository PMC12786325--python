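"""Presence filtering, imputation, TMM, ranks, differential test, overlaps."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from aliflow.proteomics import (
    AbundanceTable,
    differential_rank_test,
    impute_low_quantile,
    overlap_percent,
    presence_filter,
    rank_proteins,
    tmm_factors,
    top_n_list,
)
from aliflow.synth import generate_protein_table


def make_table(values, conditions, protein_ids=None):
    values = np.asarray(values, dtype=float)
    protein_ids = protein_ids or [f"P{i}" for i in range(values.shape[0])]
    sample_ids = [f"S{i}" for i in range(values.shape[1])]
    frame = pd.DataFrame(values, index=pd.Index(protein_ids, name="protein_id"), columns=sample_ids)
    cond = pd.Series(conditions, index=sample_ids, name="condition")
    return AbundanceTable(values=frame, conditions=cond)


class TestPresenceFilter:
    def test_exact_boundary_fraction_is_dropped(self):
        # detected in 3/4 samples of one condition = 0.75 exactly: strict > drops it
        values = [[1.0, 1.0, 1.0, np.nan, np.nan, np.nan, np.nan, np.nan]]
        tab = make_table(values, ["A"] * 4 + ["B"] * 4)
        assert presence_filter(tab, min_frac=0.75).values.shape[0] == 0

    def test_fully_detected_condition_keeps_protein(self):
        values = [[1.0, 1.0, 1.0, 1.0, np.nan, np.nan, np.nan, np.nan]]
        tab = make_table(values, ["A"] * 4 + ["B"] * 4)
        assert presence_filter(tab).values.shape[0] == 1

    def test_survivors_match_hand_enumeration(self):
        rng = np.random.default_rng(0)
        n, per = 10, 4
        detected = rng.random((n, 2 * per)) < 0.7
        values = np.where(detected, 1.0, np.nan)
        tab = make_table(values, ["A"] * per + ["B"] * per)
        expected = [
            f"P{i}"
            for i in range(n)
            if detected[i, :per].mean() > 0.75 or detected[i, per:].mean() > 0.75
        ]
        assert list(presence_filter(tab).values.index) == expected

    def test_raising_threshold_never_adds_proteins(self):
        tab = generate_protein_table(n_proteins=300, missing_rate=0.3, seed=6)
        kept = [set(presence_filter(tab, f).values.index) for f in (0.25, 0.5, 0.75, 0.9)]
        for lo, hi in zip(kept, kept[1:]):
            assert hi <= lo


class TestImputation:
    def test_complete_table_is_unchanged(self):
        tab = make_table([[1.0, 2.0], [3.0, 4.0]], ["A", "B"])
        out = impute_low_quantile(tab)
        assert out.values.equals(tab.values)
        assert not out.imputed.to_numpy().any()

    def test_imputed_value_is_the_sample_quantile(self):
        detected = np.arange(1.0, 101.0)
        col = np.concatenate([detected, [np.nan]])
        other = np.concatenate([detected, [50.0]])
        tab = make_table(np.column_stack([col, other]), ["A", "B"])
        out = impute_low_quantile(tab, q=0.025)
        expected = np.quantile(detected, 0.025)
        assert out.values.iloc[-1, 0] == pytest.approx(expected)
        assert out.imputed.iloc[-1, 0]

    def test_imputation_is_per_sample_not_global(self):
        a = np.array([10.0, 20.0, 30.0, np.nan])
        b = np.array([1000.0, 2000.0, 3000.0, np.nan])
        tab = make_table(np.column_stack([a, b]), ["A", "B"])
        out = impute_low_quantile(tab)
        assert out.values.iloc[-1, 1] == pytest.approx(100 * out.values.iloc[-1, 0])

    def test_all_missing_sample_rejected(self):
        tab = make_table([[np.nan], [np.nan]], ["A"])
        with pytest.raises(ValueError, match="no detected"):
            impute_low_quantile(tab)

    def test_filter_and_impute_commute_on_the_survivor_set(self):
        # imputation records what it filled in, so presence filtering sees the
        # same detection pattern whether it runs before or after imputation
        tab = generate_protein_table(n_proteins=200, missing_rate=0.2, seed=12)
        filtered_then_imputed = impute_low_quantile(presence_filter(tab))
        imputed_then_filtered = presence_filter(impute_low_quantile(tab))
        assert list(filtered_then_imputed.values.index) == list(
            imputed_then_filtered.values.index
        )
        assert not filtered_then_imputed.values.isna().any().any()


class TestTmm:
    def test_identical_samples_get_unit_factors(self):
        col = np.random.default_rng(0).lognormal(3, 1, 50)
        tab = make_table(np.column_stack([col, col]), ["A", "B"])
        f = tmm_factors(tab)
        assert np.allclose(f.to_numpy(), 1.0)

    def test_scale_equivariance(self):
        col = np.random.default_rng(1).lognormal(3, 1, 200)
        tab = make_table(np.column_stack([col, 4.0 * col, col]), ["A", "A", "B"])
        f = tmm_factors(tab)
        assert f.iloc[1] / f.iloc[0] == pytest.approx(4.0, abs=1e-6)

    def test_factors_have_geometric_mean_one(self):
        tab = generate_protein_table(
            n_proteins=300, n_samples_per_condition=5, missing_rate=0.0,
            loading_factors=[1, 2, 0.5, 1, 3, 1, 1, 0.7, 1, 1], seed=2,
        )
        f = tmm_factors(tab)
        assert np.exp(np.mean(np.log(f.to_numpy()))) == pytest.approx(1.0, abs=1e-12)

    def test_loading_factors_are_recovered(self):
        loadings = np.array([1, 1, 1, 1, 1, 10, 1, 1, 1, 1], dtype=float)
        tab = generate_protein_table(
            n_proteins=800, n_samples_per_condition=5, missing_rate=0.0,
            loading_factors=loadings, seed=3,
        )
        f = tmm_factors(tab)
        assert f.iloc[5] / f.iloc[0] == pytest.approx(10.0, rel=0.05)

    def test_incomplete_table_rejected(self):
        tab = make_table([[1.0, np.nan], [2.0, 3.0]], ["A", "B"])
        with pytest.raises(ValueError, match="complete"):
            tmm_factors(tab)

    def test_matches_bioconductor_edger(self, tmp_path):
        """Cross-implementation oracle: edgeR's published TMM on the same
        matrix (effective factors = normalization factor x library size,
        scaled to geometric mean 1)."""
        rscript = shutil.which("Rscript")
        assert rscript is not None, "Rscript is part of the supported environment"
        rng = np.random.default_rng(7)
        base = rng.lognormal(4, 1, 400)
        x = np.column_stack([
            base * rng.lognormal(0, 0.1, 400),
            2.5 * base * rng.lognormal(0, 0.1, 400),
            base * rng.lognormal(0, 0.1, 400),
        ])
        # shift 10% of proteins strongly in sample 3 (asymmetric composition)
        x[:40, 2] *= 8.0
        tab = make_table(x, ["A", "A", "B"])
        csv = tmp_path / "matrix.csv"
        tab.values.to_csv(csv)
        script = tmp_path / "tmm.R"
        script.write_text(
            """
            suppressMessages(library(edgeR))
            args <- commandArgs(trailingOnly=TRUE)
            x <- as.matrix(read.csv(args[1], row.names=1))
            nf <- calcNormFactors(x, method="TMM")
            eff <- nf * colSums(x)
            eff <- eff / exp(mean(log(eff)))
            cat(sprintf("%.10f", eff), sep="\\n")
            """
        )
        out = subprocess.run(
            [rscript, str(script), str(csv)], capture_output=True, text=True, check=True
        )
        expected = np.array([float(v) for v in out.stdout.strip().splitlines()])
        ours = tmm_factors(tab).to_numpy()
        assert np.allclose(ours, expected, rtol=0.02)


class TestRanks:
    def test_rank_one_is_most_abundant(self):
        tab = make_table([[10.0], [5.0], [1.0]], ["A"])
        ranks = rank_proteins(tab)
        assert list(ranks.ranks["S0"]) == [1.0, 2.0, 3.0]

    def test_ties_get_average_rank(self):
        tab = make_table([[7.0], [7.0], [1.0]], ["A"])
        ranks = rank_proteins(tab)
        assert list(ranks.ranks["S0"]) == [1.5, 1.5, 3.0]

    def test_undetected_share_worst_tied_rank(self):
        tab = make_table([[9.0], [np.nan], [np.nan], [1.0]], ["A"])
        ranks = rank_proteins(tab)
        # detected occupy ranks 1 and 2; the two missing share (3+4)/2
        assert list(ranks.ranks["S0"]) == [1.0, 3.5, 3.5, 2.0]

    def test_monotone_transform_leaves_ranks_unchanged(self):
        tab = generate_protein_table(n_proteins=100, missing_rate=0.1, seed=8)
        transformed = AbundanceTable(
            values=1000.0 * tab.values**1.3, conditions=tab.conditions
        )
        assert rank_proteins(tab).ranks.equals(rank_proteins(transformed).ranks)


class TestDifferentialRankTest:
    def test_identical_conditions_show_no_differences(self):
        col = np.random.default_rng(4).lognormal(3, 1, (30, 3))
        x = np.column_stack([col, col])  # same three samples under both labels
        tab = make_table(x, ["A"] * 3 + ["B"] * 3)
        res = differential_rank_test(rank_proteins(tab), "A", "B")
        assert np.allclose(res["rank_diff"], 0.0)
        assert not res["significant"].any()

    def test_enriched_proteins_dominate_the_hit_list(self):
        enriched = [f"P{i:05d}" for i in range(50)]
        tab = generate_protein_table(
            n_proteins=1000, missing_rate=0.05,
            enriched_set=enriched, effect=6.0, seed=13,
        )
        tab = impute_low_quantile(presence_filter(tab))
        res = differential_rank_test(rank_proteins(tab), "CTL", "EV")
        top100 = set(res.index[:100])
        recovered = len(top100 & set(enriched))
        assert recovered >= 45
        sig = set(res.index[res["significant"]])
        assert len(sig & set(enriched)) >= 0.9 * len(set(enriched) & set(res.index))

    def test_missing_condition_rejected(self):
        tab = make_table([[1.0, 2.0]], ["A", "B"])
        with pytest.raises(ValueError, match="not present"):
            differential_rank_test(rank_proteins(tab), "A", "Z")


class TestTopNAndOverlap:
    def test_full_roster_when_n_is_everything(self):
        tab = generate_protein_table(n_proteins=30, missing_rate=0.0, seed=1)
        ranks = rank_proteins(tab)
        assert set(top_n_list(ranks, "CTL", n=30)) == set(tab.values.index)

    def test_dominant_proteins_always_make_the_cut(self):
        rng = np.random.default_rng(5)
        x = rng.lognormal(2, 0.5, (50, 6))
        x[:10] *= 1e6  # ten proteins dwarf everything in every sample
        tab = make_table(x, ["A"] * 3 + ["B"] * 3)
        top10 = top_n_list(rank_proteins(tab), "A", n=10)
        assert set(top10) == {f"P{i}" for i in range(10)}

    def test_sample_column_order_is_irrelevant(self):
        tab = generate_protein_table(n_proteins=60, missing_rate=0.0, seed=9)
        shuffled = AbundanceTable(
            values=tab.values.iloc[:, ::-1], conditions=tab.conditions.iloc[::-1]
        )
        assert top_n_list(rank_proteins(tab), "CTL", n=20) == top_n_list(
            rank_proteins(shuffled), "CTL", n=20
        )

    def test_identical_lists_overlap_fully(self):
        ids = [f"P{i}" for i in range(20)]
        assert overlap_percent(ids, list(ids)).percent == 100

    def test_disjoint_lists_do_not_overlap(self):
        res = overlap_percent(["A", "B"], ["C", "D"])
        assert res.percent == 0
        assert res.union == 4

    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="unique"):
            overlap_percent(["A", "A"], ["B"])

    def test_empty_union_rejected(self):
        with pytest.raises(ValueError):
            overlap_percent([], [])
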