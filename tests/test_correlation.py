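import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from anchorcorr import (
    SelectionPolicy,
    SimulationConfig,
    correlate_anchor,
    correlation_pvalue,
    pearson_r,
    select_candidates,
    simulate_dataset,
)
from anchorcorr.correlation import CorrelationRecord


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [2, 4, 6], 1.0),
            ([1, 2, 3], [6, 4, 2], -1.0),
            ([1, 2, 3, 4], [1, 3, 2, 4], 0.8),
        ],
    )
    def test_worked_examples(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_matches_scipy_on_complete_data(self, rng):
        x = rng.normal(size=60)
        y = 0.4 * x + rng.normal(size=60)
        assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_pairwise_complete_ignores_missing(self, rng):
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        xm, ym = x.copy(), y.copy()
        xm[3], ym[7] = np.nan, np.nan
        keep = np.isfinite(xm) & np.isfinite(ym)
        assert pearson_r(xm, ym) == pytest.approx(
            stats.pearsonr(x[keep], y[keep]).statistic
        )

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    @given(
        a=st.floats(0.01, 50.0), b=st.floats(-100.0, 100.0),
        flip=st.booleans(),
    )
    def test_affine_invariance_and_sign_flip(self, a, b, flip):
        rng = np.random.default_rng(99)
        x = rng.normal(size=25)
        y = 0.6 * x + rng.normal(size=25)
        base = pearson_r(x, y)
        scale = -a if flip else a
        transformed = pearson_r(scale * x + b, y)
        assert transformed == pytest.approx(-base if flip else base, abs=1e-9)


class TestFisherZPvalue:
    def test_r_zero_gives_p_one(self):
        assert correlation_pvalue(0.0, 30) == pytest.approx(1.0)

    def test_frozen_worked_example(self):
        # r=0.8, n=28: z=1.0986, statistic 5.493
        assert correlation_pvalue(0.8, 28) == pytest.approx(3.95e-8, rel=0.01)

    def test_perfect_correlation_convention(self):
        assert correlation_pvalue(1.0, 10) == 0.0
        assert correlation_pvalue(-1.0, 10) == 0.0

    def test_monotone_in_r_and_n(self):
        rs = np.linspace(0.05, 0.95, 10)
        ps = [correlation_pvalue(r, 30) for r in rs]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        ns = [5, 10, 30, 100, 500]
        ps = [correlation_pvalue(0.3, n) for n in ns]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 3)

    @pytest.mark.parametrize("n,rel", [(20, 0.15), (50, 0.10), (100, 0.10), (200, 0.10)])
    def test_agrees_with_exact_t_test_at_moderate_p(self, n, rel):
        # the normal approximation tracks the exact t-based p within ~10%
        # relative error wherever the p-value is not extreme (p >= 0.01,
        # slightly looser at n=20); it degrades in the far tail, where
        # only the ranking remains equivalent
        for r in np.linspace(0.0, 0.9, 46):
            p_z = correlation_pvalue(r, n)
            if r == 0:
                p_t = 1.0
            else:
                t = r * np.sqrt(n - 2) / np.sqrt(1 - r**2)
                p_t = 2 * stats.t.sf(t, n - 2)
            if p_t < 0.01:
                continue
            assert p_z == pytest.approx(p_t, rel=rel)

    def test_rank_equivalence_with_exact_t_everywhere(self):
        rs = np.linspace(0.05, 0.99, 30)
        p_z = [correlation_pvalue(r, 25) for r in rs]
        t = rs * np.sqrt(23) / np.sqrt(1 - rs**2)
        p_t = 2 * stats.t.sf(t, 23)
        assert np.array_equal(np.argsort(p_z), np.argsort(p_t))


class TestCorrelateAnchor:
    def test_anchor_excluded_and_ranks_ordered(self, planted_dataset):
        ds, _ = planted_dataset
        records = correlate_anchor(ds, "PSME3")
        genes = [rec.gene for rec in records]
        assert "PSME3" not in genes
        assert [rec.rank for rec in records] == list(range(1, len(records) + 1))
        ps = [rec.p_value for rec in records]
        assert ps == sorted(ps)

    def test_planted_genes_lead_the_ranking(self, planted_dataset):
        ds, _ = planted_dataset
        records = correlate_anchor(ds, "PSME3")
        assert {records[0].gene, records[1].gene} == {"PGPOS", "PGNEG"}
        assert records[0].r > 0.6
        assert any(rec.r < -0.5 for rec in records[:2])

    def test_strong_planted_gene_ranks_first_across_replicates(self):
        wins = 0
        for rep in range(50):
            config = SimulationConfig(
                n_genes=999, planted_genes=(("PG1", 0.9),),
                output_scale="log2", seed=rep,
            )
            ds, _ = simulate_dataset(config, dataset_id="r01")
            records = correlate_anchor(ds, "PSME3")
            wins += records[0].gene == "PG1"
        assert wins >= 48

    def test_null_p_values_behave_like_uniforms(self):
        config = SimulationConfig(n_genes=1000, anchor_fold_change=1.0,
                                  output_scale="log2", seed=31)
        ds, _ = simulate_dataset(config, dataset_id="null01")
        records = correlate_anchor(ds, "PSME3")
        ps = np.array([rec.p_value for rec in records])
        # smallest of 1000 uniforms is below 0.01 with prob ~1 - e^-10
        assert ps.min() < 0.01
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_missing_anchor_rejected(self, planted_dataset):
        ds, _ = planted_dataset
        with pytest.raises(ValueError, match="absent"):
            correlate_anchor(ds, "NOPE")


def _records(ps, dataset_id="d1"):
    order = np.argsort(ps)
    ranks = np.empty(len(ps), dtype=int)
    ranks[order] = np.arange(1, len(ps) + 1)
    return [
        CorrelationRecord(
            gene=f"G{i:03d}", dataset_id=dataset_id, r=0.5, n_eff=50,
            p_value=float(p), rank=int(k),
        )
        for i, (p, k) in enumerate(zip(ps, ranks))
    ]


class TestSelectCandidates:
    def test_top_fraction_of_candidates(self):
        # 6 of 10 records pass p<0.001; fraction 0.5 keeps the 3 smallest p
        ps = [1e-6, 5e-6, 1e-5, 5e-5, 1e-4, 5e-4, 0.01, 0.1, 0.5, 0.9]
        policy = SelectionPolicy(top_fraction={"colon": 0.5}, min_candidates=1)
        out = select_candidates(_records(ps), policy, "colon")
        chosen = {rec.gene for rec in out if rec.selected}
        assert chosen == {"G000", "G001", "G002"}

    def test_thyroid_quota_worked_example(self):
        ps = list(np.linspace(1e-9, 9e-4, 1000))  # 1,000 candidates
        policy = SelectionPolicy(min_candidates=1)
        out = select_candidates(_records(ps), policy, "thyroid")
        assert sum(rec.selected for rec in out) == 200

    def test_fraction_one_selects_all_candidates(self):
        ps = [1e-5, 1e-4, 0.01, 0.5]
        policy = SelectionPolicy(top_fraction={"lung": 1.0}, min_candidates=1)
        out = select_candidates(_records(ps), policy, "lung")
        assert sum(rec.selected for rec in out) == 2

    def test_monotone_in_p_cutoff(self):
        ps = [1e-6, 1e-5, 1e-4, 5e-4, 2e-3, 0.03, 0.2]
        loose = SelectionPolicy(p_cutoff=0.01, top_fraction={"liver": 1.0}, min_candidates=1)
        tight = SelectionPolicy(p_cutoff=0.001, top_fraction={"liver": 1.0}, min_candidates=1)
        chosen_tight = {r.gene for r in select_candidates(_records(ps), tight, "liver") if r.selected}
        chosen_loose = {r.gene for r in select_candidates(_records(ps), loose, "liver") if r.selected}
        assert chosen_tight <= chosen_loose

    def test_low_candidate_count_warns(self, caplog):
        import logging

        ps = [0.5, 0.9]
        policy = SelectionPolicy(top_fraction={"colon": 0.2})
        with caplog.at_level(logging.WARNING, logger="anchorcorr.correlation"):
            select_candidates(_records(ps), policy, "colon")
        assert any("candidates" in msg for msg in caplog.messages)

    def test_unknown_tissue_rejected(self):
        with pytest.raises(KeyError):
            SelectionPolicy().fraction_for("kidney")
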