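"""Statistical workflow: pre-processing, ANOVA selection, CI vectors,
profile matching and the end-to-end pipeline."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from interaction_modes.classify import (
    ExpressionExperiment,
    ci_comparison_vector,
    classify_genes,
    collapse_probesets,
    detection_filter,
    interaction_anova,
    learn_profile,
    match_profile,
    one_way_anova,
    select_nonadditive,
    select_regulated,
)
from interaction_modes.simulate import SimulationConfig, simulate_experiment


def make_experiment(rows: dict[str, list[float]], nrep: int = 3,
                    symbols: dict[str, str] | None = None):
    samples = [f"{c}_r{k+1}" for c in ("CTRL", "X", "Y", "XY")
               for k in range(nrep)]
    matrix = pd.DataFrame(rows, index=samples).T
    design = pd.DataFrame(
        {"condition": [s.split("_")[0] for s in samples],
         "replicate": [int(s[-1]) for s in samples]},
        index=pd.Index(samples, name="sample_id"),
    )
    sym = pd.Series(symbols) if symbols else None
    return ExpressionExperiment(matrix, design, sym)


def replicate_rows(means, nrep=3, sigma=0.0, rng=None):
    vals = np.repeat(np.asarray(means, dtype=float), nrep)
    if sigma and rng is not None:
        vals = vals + rng.normal(0, sigma, size=vals.size)
    return list(vals)


class TestPreprocessing:
    def test_collapse_keeps_highest_mean_probe(self):
        exp = make_experiment(
            {"p1": [6.1] * 12, "p2": [7.3] * 12, "p3": [5.0] * 12},
            symbols={"p1": "GENEA", "p2": "GENEA", "p3": "GENEB"},
        )
        out = collapse_probesets(exp)
        assert sorted(out.matrix.index) == ["GENEA", "GENEB"]
        assert out.matrix.loc["GENEA"].iloc[0] == 7.3

    def test_collapse_tie_breaks_lexicographically(self):
        exp = make_experiment(
            {"pB": [6.0] * 12, "pA": [6.0] * 12},
            symbols={"pB": "G", "pA": "G"},
        )
        out = collapse_probesets(exp)
        # the retained row is the lexicographically smaller feature id
        assert len(out.matrix) == 1

    def test_collapse_without_symbols_warns(self):
        exp = make_experiment({"p1": [6.0] * 12})
        with pytest.warns(UserWarning):
            out = collapse_probesets(exp)
        assert list(out.matrix.index) == ["p1"]

    @pytest.mark.parametrize(
        "values,kept",
        [
            ([3.0] * 4, False),  # never above threshold
            ([4.2, 4.5, 4.1] + [3.0] * 9, True),  # CTRL fully detected
            ([4.0, 5.0, 5.0] * 4, False),  # one replicate == 4 everywhere
        ],
    )
    def test_detection_filter(self, values, kept):
        if len(values) == 4:
            values = [v for v in values for _ in range(3)]
        exp = make_experiment({"g": values})
        out = detection_filter(exp, threshold=4.0)
        assert ("g" in out.matrix.index) is kept


class TestAnova:
    def test_one_way_matches_scipy(self):
        rng = np.random.default_rng(1)
        exp = make_experiment(
            {f"g{i}": list(rng.normal(7, 1, 12)) for i in range(20)}
        )
        ours = one_way_anova(exp)
        cols = exp.condition_columns
        for g in exp.matrix.index:
            groups = [exp.matrix.loc[g, cols[c]].to_numpy()
                      for c in ("CTRL", "X", "Y", "XY")]
            f, p = st.f_oneway(*groups)
            assert ours.loc[g, "F"] == pytest.approx(f, rel=1e-6)
            assert ours.loc[g, "p"] == pytest.approx(p, rel=1e-6)

    def test_interaction_matches_statsmodels_factorial(self):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        rng = np.random.default_rng(2)
        exp = make_experiment({"g": list(rng.normal(8, 0.5, 12))})
        ours = interaction_anova(exp)
        df = pd.DataFrame(
            {
                "y": exp.matrix.loc["g"].to_numpy(),
                "x": exp.design["condition"].isin(["X", "XY"]).astype(int),
                "z": exp.design["condition"].isin(["Y", "XY"]).astype(int),
            }
        )
        fit = ols("y ~ x * z", data=df).fit()
        tab = sm.stats.anova_lm(fit, typ=2)
        assert ours.loc["g", "p"] == pytest.approx(tab.loc["x:z", "PR(>F)"],
                                                   rel=1e-6)
        assert ours.loc["g", "F"] == pytest.approx(tab.loc["x:z", "F"],
                                                   rel=1e-6)

    def test_select_regulated_power(self):
        rng = np.random.default_rng(3)
        rows = {"flat": replicate_rows((5, 5, 5, 5), 3, 0.1, rng),
                "hit": replicate_rows((5, 8, 8, 11), 3, 0.1, rng)}
        rows.update({f"null{i}": replicate_rows((6, 6, 6, 6), 3, 0.1, rng)
                     for i in range(20)})
        exp = make_experiment(rows)
        selected, table = select_regulated(exp, fdr=0.05)
        assert "hit" in selected
        assert "flat" not in selected
        # q-values are monotone in p
        srt = table.sort_values("p")
        assert (np.diff(srt["q"]) >= -1e-12).all()

    def test_select_nonadditive_contrast_and_power(self):
        rng = np.random.default_rng(4)
        rows = {"additive": replicate_rows((5, 7, 6, 8), 3, 0.1, rng),
                "emergent": replicate_rows((5, 5, 5, 8), 3, 0.1, rng)}
        exp = make_experiment(rows)
        selected, table = select_nonadditive(exp, list(rows), fdr=0.05)
        assert selected == ["emergent"]
        assert table.loc["emergent", "contrast"] == pytest.approx(3, abs=0.5)
        assert table.loc["additive", "contrast"] == pytest.approx(0, abs=0.5)

    def test_empty_input_gives_empty_output(self):
        exp = make_experiment({"g": [5.0] * 12})
        empty = exp.subset([])
        assert select_regulated(empty)[0] == []
        assert select_nonadditive(exp, [])[0] == []


class TestComparisonVectors:
    def test_noiseless_example_vector(self):
        groups = {c: np.full(3, v) for c, v in
                  zip(("CTRL", "X", "Y", "XY"), (5, 5, 5, 8))}
        assert ci_comparison_vector(groups) == (0, 0, 1, 0, 1, 1)

    def test_all_identical_gives_zero_vector(self):
        groups = {c: np.full(3, 7.0) for c in ("CTRL", "X", "Y", "XY")}
        assert ci_comparison_vector(groups) == (0, 0, 0, 0, 0, 0)

    def test_underpowered_data_can_be_intransitive(self, catalog):
        # only the XY-vs-X comparison reaches significance: the resulting
        # vector is no weak ordering and fails catalog matching
        rng = np.random.default_rng(3)
        groups = {
            "CTRL": 5 + rng.normal(0, 0.45, 4),
            "X": 5.4 + rng.normal(0, 0.05, 4),
            "Y": 5 + rng.normal(0, 0.45, 4),
            "XY": 5.8 + rng.normal(0, 0.05, 4),
        }
        vec = ci_comparison_vector(groups)
        assert vec == (0, 0, 0, 0, 1, 0)
        from interaction_modes.catalog import ComparisonVector

        assert not ComparisonVector(*vec).is_valid_ranking()
        assert match_profile(vec, 1, catalog) is None

    def test_equivalence_tolerance_forces_zero(self):
        groups = {c: np.full(3, v) for c, v in
                  zip(("CTRL", "X", "Y", "XY"), (5, 5.05, 5, 8))}
        assert ci_comparison_vector(groups)[0] == 1
        assert ci_comparison_vector(groups, equiv_tol=0.1)[0] == 0

    def test_requires_two_replicates(self):
        groups = {c: np.array([5.0]) for c in ("CTRL", "X", "Y", "XY")}
        with pytest.raises(ValueError):
            ci_comparison_vector(groups)


class TestMatching:
    def test_match_examples(self, catalog):
        assert match_profile((0, 0, 1, 0, 1, 1), 1, catalog) == \
            "0,0,+1,0,+1,+1|pos"
        assert match_profile((0, 0, 0, 0, 0, 0), 1, catalog) is None
        assert match_profile((1, 1, 1, 0, 1, 1), -1, catalog) == \
            "+1,+1,+1,0,+1,+1|neg"
        assert match_profile((1, 1, 1, 0, 1, 1), 0, catalog) is None

    def test_learn_exact_prototype_is_fixed_point(self, catalog):
        for p in list(catalog.profiles)[::7]:
            sign = 1 if p.sign == "positive" else -1
            assert learn_profile(p.prototype, sign, catalog) == p.id

    def test_learn_is_scale_invariant_in_the_increment(self, catalog):
        a = learn_profile((5, 5, 5, 7.9), 1, catalog)
        b = learn_profile((5, 5, 5, 8), 1, catalog)
        assert a == b == "0,0,+1,0,+1,+1|pos"

    def test_learn_respects_observed_sign(self, catalog):
        for sign in (1, -1):
            pid = learn_profile((5, 6, 7, 9), sign, catalog)
            assert catalog.by_id[pid].sign == (
                "positive" if sign > 0 else "negative"
            )

    def test_learn_constant_profile_unclassifiable(self, catalog):
        assert learn_profile((6, 6, 6, 6), 1, catalog) is None
        assert learn_profile((5, 6, 7, 9), 0, catalog) is None


class TestPipeline:
    def test_noiseless_recovery_all_matched(self, catalog):
        cfg = SimulationConfig(genes_per_profile=1, n_additive=30,
                               n_inactive=30, n_replicates=5, sigma=0.0,
                               seed=8)
        exp, truth = simulate_experiment(cfg, catalog)
        res = classify_genes(exp, catalog, equiv_tol=1e-9)
        calls = {c.gene: c for c in res.calls}
        planted = truth[truth.kind == "profile"]
        hits = [g for g in planted.index
                if g in calls and calls[g].origin == "matched"
                and calls[g].profile_id == planted.loc[g, "profile_id"]
                and calls[g].mode == planted.loc[g, "mode"]]
        assert len(hits) == 82

    def test_additive_only_experiment_yields_few_calls(self, catalog):
        cfg = SimulationConfig(genes_per_profile=0, n_additive=100,
                               n_inactive=0, n_replicates=3, sigma=0.2,
                               seed=9)
        exp, _ = simulate_experiment(cfg, catalog)
        res = classify_genes(exp, catalog)
        # all calls are false positives; BH at 5% keeps them rare
        assert len(res.calls) <= 5

    def test_pipeline_invariant_to_sample_and_gene_order(self, catalog):
        cfg = SimulationConfig(genes_per_profile=1, n_additive=20,
                               n_inactive=20, n_replicates=3, sigma=0.1,
                               seed=10)
        exp, _ = simulate_experiment(cfg, catalog)
        res = classify_genes(exp, catalog)
        rng = np.random.default_rng(0)
        cols = list(exp.matrix.columns)
        rows = list(exp.matrix.index)
        rng.shuffle(cols)
        rng.shuffle(rows)
        shuffled = ExpressionExperiment(
            exp.matrix.loc[rows, cols], exp.design.copy()
        )
        res2 = classify_genes(shuffled, catalog)
        a = {c.gene: (c.profile_id, c.mode, c.origin) for c in res.calls}
        b = {c.gene: (c.profile_id, c.mode, c.origin) for c in res2.calls}
        assert a == b

    def test_matched_fraction_decays_with_noise(self, catalog):
        fracs = []
        for sigma in (0.05, 0.4, 1.2):
            cfg = SimulationConfig(genes_per_profile=3, n_additive=0,
                                   n_inactive=0, n_replicates=5,
                                   sigma=sigma, seed=12)
            exp, truth = simulate_experiment(cfg, catalog)
            res = classify_genes(exp, catalog)
            n_called = max(len(res.calls), 1)
            matched = sum(c.origin == "matched" for c in res.calls)
            fracs.append(matched / n_called)
        assert fracs[0] >= fracs[1] - 0.02 >= fracs[2] - 0.04

    def test_fdr_tightening_shrinks_selection(self, catalog):
        cfg = SimulationConfig(seed=13)
        exp, _ = simulate_experiment(cfg, catalog)
        res5 = classify_genes(exp, catalog, fdr=0.05)
        res1 = classify_genes(exp, catalog, fdr=0.01)
        assert {c.gene for c in res1.calls} <= {c.gene for c in res5.calls}

    def test_summary_normalization_divides_by_profiles_per_mode(self, catalog):
        from interaction_modes.modes import profiles_per_mode

        cfg = SimulationConfig(genes_per_profile=1, n_additive=10,
                               n_inactive=10, n_replicates=4, sigma=0.05,
                               seed=14)
        exp, _ = simulate_experiment(cfg, catalog)
        res = classify_genes(exp, catalog, equiv_tol=0.5)
        ppm = profiles_per_mode(catalog)
        for mode, cnt in res.summary["per_mode"].items():
            assert res.summary["normalized_per_mode"][mode] == \
                pytest.approx(cnt / ppm[mode])


class TestExperimentValidation:
    def test_missing_condition_is_named(self):
        samples = [f"{c}_r{k}" for c in ("CTRL", "X", "Y") for k in (1, 2)]
        matrix = pd.DataFrame([[5.0] * 6], index=["g"], columns=samples)
        design = pd.DataFrame(
            {"condition": [s.split("_")[0] for s in samples],
             "replicate": [1, 2] * 3},
            index=pd.Index(samples, name="sample_id"),
        )
        with pytest.raises(ValueError, match="XY"):
            ExpressionExperiment(matrix, design)

    def test_unknown_condition_is_named(self):
        matrix = pd.DataFrame([[5.0]], index=["g"], columns=["s1"])
        design = pd.DataFrame({"condition": ["MOCK"], "replicate": [1]},
                              index=pd.Index(["s1"], name="sample_id"))
        with pytest.raises(ValueError, match="MOCK"):
            ExpressionExperiment(matrix, design)
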