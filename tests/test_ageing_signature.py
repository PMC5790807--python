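import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from agealign import (
    AnovaDesign,
    ExpressionStudy,
    activity_foldchange,
    age_label_permutation_null,
    bh_adjust,
    check_model_assumptions,
    compute_process_activity,
    derive_signature,
    differential_genes,
    filter_gene_sets_min_genes,
    filter_unexpressed_genes,
    fit_age_anova,
    generate_expression_study,
    individual_activity_change,
    lifespan_correlation,
    normalize_activities,
    run_signature_analysis,
)
from agealign.ageing_signature import backward_select_batch, term_name


def balanced_meta(n_rep=5, ages=("young", "old_1")):
    rows = []
    for age in ages:
        for sp in ("zebrafish", "mouse"):
            for ti in ("liver", "brain"):
                for r in range(n_rep):
                    rows.append({"age_group": age, "species": sp, "tissue": ti})
    return pd.DataFrame(rows)


class TestAssumptionChecks:
    def test_extreme_outlier_fails_normality(self):
        rng = np.random.default_rng(7)
        meta = balanced_meta(n_rep=5)
        y = rng.normal(0.0, 1.0, size=len(meta))
        y[0] += 30.0  # |z| >> 8 residual outlier
        design = AnovaDesign(meta)
        check = check_model_assumptions(y, design)
        assert not check.passed
        assert check.shapiro_p <= 0.005

    def test_clean_balanced_data_passes(self):
        rng = np.random.default_rng(11)
        meta = balanced_meta(n_rep=5)
        y = rng.normal(0.0, 1.0, size=len(meta))
        assert check_model_assumptions(y, AnovaDesign(meta)).passed

    def test_alpha_monotonicity(self):
        # every process failing at 0.005 also fails at 0.05
        rng = np.random.default_rng(3)
        meta = balanced_meta(n_rep=4)
        design = AnovaDesign(meta)
        for _ in range(20):
            y = rng.standard_t(df=2, size=len(meta))  # heavy tails
            strict = check_model_assumptions(y, design, alpha=0.005)
            loose = check_model_assumptions(y, design, alpha=0.05)
            if not strict.passed:
                assert not loose.passed

    def test_constant_response_degenerate(self):
        meta = balanced_meta(n_rep=3)
        check = check_model_assumptions(np.ones(len(meta)), AnovaDesign(meta))
        assert not check.passed
        assert check.reason == "degenerate"


def explicit_balanced_ss(df, factors):
    """Sequential = type-II sums of squares on a balanced full factorial,
    from explicit cell/marginal means."""
    grand = df["y"].mean()
    ss = {}
    for f in factors:
        means = df.groupby(f)["y"].mean()
        counts = df.groupby(f)["y"].count()
        ss[(f,)] = float((counts * (means - grand) ** 2).sum())
    for i, a in enumerate(factors):
        for b in factors[i + 1:]:
            cell = df.groupby([a, b])["y"].agg(["mean", "count"])
            ma = df.groupby(a)["y"].mean()
            mb = df.groupby(b)["y"].mean()
            total = 0.0
            for (la, lb), row in cell.iterrows():
                total += row["count"] * (row["mean"] - ma[la] - mb[lb] + grand) ** 2
            ss[(a, b)] = float(total)
    return ss


class TestTypeIIAnova:
    def test_balanced_two_factor_matches_explicit_ss(self):
        rng = np.random.default_rng(5)
        meta = balanced_meta(n_rep=4)[["age_group", "species"]]
        y = rng.normal(size=len(meta))
        df = meta.assign(y=y)
        design = AnovaDesign(meta, factors=("age_group", "species"), max_order=2)
        table, rss_full, df_resid = design.type2_table(y, frozenset(design.terms))
        oracle = explicit_balanced_ss(df, ["age_group", "species"])
        for term, expected_ss in oracle.items():
            got = table[table["term"] == term_name(term)].iloc[0]
            assert got["ss"] == pytest.approx(expected_ss, abs=1e-9)
        # residual df: n - cells
        assert df_resid == len(meta) - 4

    def test_unbalanced_matches_statsmodels_type2(self):
        rng = np.random.default_rng(13)
        meta = balanced_meta(n_rep=4)
        # unbalance by dropping samples
        keep = rng.random(len(meta)) > 0.2
        meta = meta[keep].reset_index(drop=True)
        y = rng.normal(size=len(meta)) + (meta["age_group"] == "old_1") * 0.5
        design = AnovaDesign(meta)
        table, _, _ = design.type2_table(y.to_numpy(), frozenset(design.terms))
        fit = smf.ols(
            "y ~ C(age_group) * C(species) * C(tissue)", data=meta.assign(y=y)
        ).fit()
        sm_table = sm.stats.anova_lm(fit, typ=2)
        name_map = {
            "C(age_group)": "age_group",
            "C(species)": "species",
            "C(tissue)": "tissue",
            "C(age_group):C(species)": "age_group:species",
            "C(age_group):C(tissue)": "age_group:tissue",
            "C(species):C(tissue)": "species:tissue",
            "C(age_group):C(species):C(tissue)": "age_group:species:tissue",
        }
        for sm_name, ours in name_map.items():
            got = table[table["term"] == ours].iloc[0]
            assert got["F"] == pytest.approx(sm_table.loc[sm_name, "F"], rel=1e-8)
            assert got["p"] == pytest.approx(sm_table.loc[sm_name, "PR(>F)"], rel=1e-6)

    def test_planted_pure_age_effect_recovered(self):
        rng = np.random.default_rng(21)
        meta = balanced_meta(n_rep=5)
        y = rng.normal(0.0, 0.01, size=len(meta))
        y[meta["age_group"] == "old_1"] += 0.5
        fit = fit_age_anova(y, AnovaDesign(meta))
        assert not fit.age_removed
        assert fit.age_p < 1e-6

    def test_age_removed_sentinel_when_no_age_signal(self):
        rng = np.random.default_rng(2)
        meta = balanced_meta(n_rep=6)
        # response driven purely by species; age and its interactions vanish
        y = (meta["species"] == "mouse") * 3.0 + rng.normal(0, 0.05, len(meta))
        fit = fit_age_anova(y.to_numpy(), AnovaDesign(meta))
        assert fit.age_removed
        assert fit.age_p is None

    def test_marginality_respected_during_selection(self):
        # strong three-way interaction: no contained term may be removed
        rng = np.random.default_rng(17)
        meta = balanced_meta(n_rep=6)
        cell = (
            (meta["age_group"] == "old_1")
            & (meta["species"] == "mouse")
            & (meta["tissue"] == "liver")
        )
        y = cell * 2.0 + rng.normal(0, 0.05, len(meta))
        fit = fit_age_anova(y.to_numpy(), AnovaDesign(meta))
        assert ("age_group", "species", "tissue") in fit.model
        for t in [("age_group",), ("species",), ("tissue",)]:
            assert t in fit.model
        assert not fit.age_removed


class TestSignatureDerivation:
    def test_bh_matches_stepup_oracle(self):
        raw = np.linspace(0.001, 0.1, 10)
        adj = bh_adjust(raw)
        # independent step-up computation
        n = len(raw)
        order = np.argsort(raw)
        expected = np.empty(n)
        running = 1.0
        for rank_i in range(n - 1, -1, -1):
            idx = order[rank_i]
            running = min(running, raw[idx] * n / (rank_i + 1))
            expected[idx] = running
        np.testing.assert_allclose(adj, expected, atol=1e-12)

    def _species_dir(self, rows):
        return pd.DataFrame(
            rows, index=["A", "B", "C"],
            columns=["zebrafish", "killifish", "mouse", "human"],
        )

    def test_conservation_rule(self):
        pvals = pd.Series([1e-5, 1e-5, 0.9], index=["A", "B", "C"])
        fold = pd.Series([0.3, 0.2, 0.1], index=["A", "B", "C"])
        # A: up in killifish and mouse (one fish + one mammal agree) -> kept
        # B: fish up, mammals down -> rejected despite significance
        # C: not significant
        dirs = self._species_dir(
            [[-1, 1, 1, -1], [1, 1, -1, -1], [1, 1, 1, 1]]
        )
        sig = derive_signature(pvals, fold, dirs)
        assert sig.selected == ["A"]
        assert sig.table.loc["A", "direction"] == "up"
        assert bool(sig.table.loc["B", "significant"])
        assert not bool(sig.table.loc["B", "conserved"])

    def test_direction_matches_foldchange_sign(self):
        pvals = pd.Series([1e-4, 1e-4, 0.5], index=["A", "B", "C"])
        fold = pd.Series([0.3, -0.2, 0.0], index=["A", "B", "C"])
        dirs = self._species_dir(
            [[1, 1, 1, 1], [-1, -1, -1, -1], [1, 1, 1, 1]]
        )
        sig = derive_signature(pvals, fold, dirs)
        assert sig.table.loc["A", "direction"] == "up"
        assert sig.table.loc["B", "direction"] == "down"
        assert sig.table.loc["C", "direction"] == "flat"

    def test_missing_clade_is_error(self):
        pvals = pd.Series([0.01], index=["A"])
        fold = pd.Series([0.3], index=["A"])
        dirs = pd.DataFrame([[1, 1]], index=["A"], columns=["mouse", "human"])
        with pytest.raises(ValueError, match="fish"):
            derive_signature(pvals, fold, dirs)

    def test_fdr_never_below_raw_p(self):
        rng = np.random.default_rng(0)
        raw = rng.uniform(size=50)
        assert (bh_adjust(raw) >= raw - 1e-15).all()


def _contrast_study(young_vals, old_vals):
    genes = [f"g{i}" for i in range(len(young_vals))]
    young_cols = [f"y{j}" for j in range(np.shape(young_vals)[1])]
    old_cols = [f"o{j}" for j in range(np.shape(old_vals)[1])]
    values = pd.DataFrame(
        np.hstack([young_vals, old_vals]), index=genes,
        columns=young_cols + old_cols,
    )
    meta = pd.DataFrame(
        {
            "species": "mouse",
            "tissue": "liver",
            "age_group": ["young"] * len(young_cols)
            + ["old_1", "old_1", "old_2", "old_2", "old_2"][: len(old_cols)],
        },
        index=values.columns,
    )
    return ExpressionStudy(values=values, meta=meta)


class TestDifferentialGenes:
    def test_doubling_gene_exact_ranksum_p(self):
        young = np.array([[1.0, 1.1, 1.2, 1.3, 1.4]])
        study = _contrast_study(young, 2 * young)
        induced, repressed, table = differential_genes(study)
        # complete separation of 5 vs 5: exact two-sided p = 2/252
        assert table.loc["g0", "p"] == pytest.approx(2 / 252)
        assert "g0" in induced and "g0" not in repressed

    def test_constant_gene_in_neither_set(self):
        young = np.array([[1.0, 1.1, 1.2, 1.3, 1.4], [2.0, 2.0, 2.0, 2.0, 2.0]])
        old = np.array([[2.0, 2.2, 2.4, 2.6, 2.8], [2.0, 2.0, 2.0, 2.0, 2.0]])
        induced, repressed, table = differential_genes(_contrast_study(young, old))
        assert table.loc["g1", "p"] == 1.0
        assert "g1" not in induced and "g1" not in repressed

    def test_label_swap_swaps_induced_and_repressed(self):
        rng = np.random.default_rng(9)
        young = rng.gamma(2.0, 1.0, size=(30, 5))
        old = rng.gamma(2.0, 1.0, size=(30, 5)) * np.where(
            rng.random(30) < 0.5, 4.0, 0.25
        )[:, None]
        fwd = _contrast_study(young, old)
        # swap: feed old as young and vice versa
        rev = _contrast_study(old, young)
        u1, r1, _ = differential_genes(fwd)
        u2, r2, _ = differential_genes(rev)
        assert u1 == r2
        assert r1 == u2


class TestLifespanCorrelation:
    def test_proportional_change_gives_r_one(self):
        lifespans = pd.Series([100.0, 200.0, 300.0, 400.0], index=list("abcd"))
        changes = pd.DataFrame([lifespans * 0.01], index=["P"])
        out = lifespan_correlation(changes, lifespans)
        assert out.loc["P", "r"] == pytest.approx(1.0)

    def test_negating_changes_negates_r(self):
        rng = np.random.default_rng(4)
        lifespans = pd.Series(rng.uniform(50, 500, 10), index=[f"i{k}" for k in range(10)])
        changes = pd.DataFrame(
            rng.normal(size=(3, 10)), index=["P1", "P2", "P3"],
            columns=lifespans.index,
        )
        out1 = lifespan_correlation(changes, lifespans)
        out2 = lifespan_correlation(-changes, lifespans)
        np.testing.assert_allclose(out1["r"].to_numpy(), -out2["r"].to_numpy())

    def test_independent_change_is_uncorrelated(self):
        rng = np.random.default_rng(123)
        n = 50
        lifespans = pd.Series(rng.uniform(50, 500, n), index=[f"i{k}" for k in range(n)])
        changes = pd.DataFrame(
            rng.normal(size=(1, n)), index=["P"], columns=lifespans.index
        )
        out = lifespan_correlation(changes, lifespans)
        assert abs(out.loc["P", "r"]) < 0.3
        assert out.loc["P", "p"] > 0.05

    def test_zero_variance_flagged(self):
        lifespans = pd.Series([100.0, 200.0, 300.0], index=list("abc"))
        changes = pd.DataFrame([[1.0, 1.0, 1.0]], index=["P"], columns=list("abc"))
        out = lifespan_correlation(changes, lifespans)
        assert np.isnan(out.loc["P", "r"])

    def test_longitudinal_generator_roundtrip(self):
        study, sets, truth = generate_expression_study(
            n_species=2, n_tissues=1, n_genes=300, n_processes=30,
            n_regulated=6, n_per_cell=10, effect=1.0, longitudinal=True, seed=8,
        )
        study = filter_unexpressed_genes(study)
        kept = filter_gene_sets_min_genes(sets, study)
        act = normalize_activities(compute_process_activity(study, kept))
        changes = individual_activity_change(act.values, study.meta)
        lifespans = study.meta.groupby("individual_id")["lifespan"].first()
        out = lifespan_correlation(changes, lifespans)
        induced = [
            p for p, d in truth.regulated_processes.items() if d > 0 and p in out.index
        ]
        repressed = [
            p for p, d in truth.regulated_processes.items() if d < 0 and p in out.index
        ]
        # stronger planted progression shortens lifespan: induced processes
        # correlate negatively, repressed positively, on average
        assert out.loc[induced, "r"].mean() < 0
        assert out.loc[repressed, "r"].mean() > 0


@pytest.fixture(scope="module")
def small_null():
    study, sets, _ = generate_expression_study(
        n_species=2, n_tissues=2, n_genes=200, n_processes=20,
        n_regulated=0, n_per_cell=4, effect=0.0, seed=31,
    )
    study = filter_unexpressed_genes(study)
    kept = filter_gene_sets_min_genes(sets, study)
    act = normalize_activities(compute_process_activity(study, kept))
    return act, study.meta


class TestPermutationNull:
    def test_same_seed_identical_distributions(self, small_null):
        act, meta = small_null
        a = age_label_permutation_null(act, meta, n_reps=5, seed=99)
        b = age_label_permutation_null(act, meta, n_reps=5, seed=99)
        np.testing.assert_array_equal(a, b)

    def test_null_median_zero(self, small_null):
        act, meta = small_null
        sizes = age_label_permutation_null(act, meta, n_reps=10, seed=5)
        assert np.median(sizes) == 0

    def test_invalid_reps(self, small_null):
        act, meta = small_null
        with pytest.raises(ValueError):
            age_label_permutation_null(act, meta, n_reps=0, seed=1)


class TestNullFdrCalibration:
    def test_empirical_fdr_on_fully_null_data(self):
        # on null data every discovery is false, so the empirical FDR is
        # the fraction of replicates with a non-empty signature; BH keeps
        # it at or below the nominal 0.05 up to binomial fluctuation
        n_reps = 200
        hits = 0
        for seed in range(n_reps):
            study, sets, _ = generate_expression_study(
                n_species=2, n_tissues=2, n_genes=200, n_processes=20,
                n_regulated=0, effect=0.0, n_per_cell=4, seed=10_000 + seed,
            )
            study = filter_unexpressed_genes(study)
            kept = filter_gene_sets_min_genes(sets, study)
            act = normalize_activities(compute_process_activity(study, kept))
            hits += len(run_signature_analysis(act, study.meta).selected) > 0
        bound = 0.05 + 1.96 * np.sqrt(0.05 * 0.95 / n_reps)
        assert hits / n_reps <= bound


class TestEndToEndRecovery:
    def test_planted_processes_recovered(self, default_simulation):
        study, sets, truth = default_simulation
        study = filter_unexpressed_genes(study)
        kept = filter_gene_sets_min_genes(sets, study)
        act = normalize_activities(compute_process_activity(study, kept))
        sig = run_signature_analysis(act, study.meta)
        planted = set(truth.regulated_processes)
        selected = set(sig.selected)
        recall = len(selected & planted) / len(planted)
        assert recall >= 0.9
        # foldchange sign matches the planted direction for recovered processes
        for pid in selected & planted:
            assert np.sign(sig.table.loc[pid, "foldchange"]) == truth.regulated_processes[pid]

    def test_observed_signature_beats_permutation_null(self, default_simulation):
        study, sets, truth = default_simulation
        study = filter_unexpressed_genes(study)
        kept = filter_gene_sets_min_genes(sets, study)
        act = normalize_activities(compute_process_activity(study, kept))
        observed = len(run_signature_analysis(act, study.meta).selected)
        null_sizes = age_label_permutation_null(act, study.meta, n_reps=20, seed=77)
        assert observed > np.quantile(null_sizes, 0.95)
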