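"""Module scores vs a direct two-mean oracle, cell-cycle calling, the
pathway-dynamics pattern classifier, and the paired pathway comparison."""

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mammaclock import scoring
from mammaclock.scoring import (
    call_cell_cycle,
    classify_pattern,
    counts_to_log2_tpm,
    module_score,
    paired_pathway_compare,
    pathway_dynamics,
)


def module_score_oracle(adata, gene_set, n_bins, n_controls, seed):
    """Independent plain-python re-computation of the bin-matched score."""
    rng = np.random.default_rng(seed)
    Y = np.asarray(adata.X, dtype=float)
    gene_mean = Y.mean(axis=0)
    order = np.argsort(gene_mean, kind="stable")
    ranks = np.empty_like(order)
    ranks[order] = np.arange(len(order))
    bins = (ranks * n_bins) // len(order)
    name_to_idx = {g: i for i, g in enumerate(adata.var_names)}
    set_idx = [name_to_idx[g] for g in gene_set]
    control = set()
    for gi in set_idx:
        pool = [j for j in range(Y.shape[1]) if bins[j] == bins[gi] and j != gi]
        take = min(n_controls, len(pool))
        control.update(rng.choice(np.array(pool), size=take, replace=False).tolist())
    control = sorted(control - set(set_idx))
    return Y[:, set_idx].mean(axis=1) - Y[:, control].mean(axis=1)


@pytest.fixture(scope="module")
def small_norm():
    rng = np.random.default_rng(10)
    n, g = 80, 300
    vals = rng.lognormal(0, 1, size=(n, g))
    return ad.AnnData(
        X=np.log1p(vals),
        obs=pd.DataFrame(index=[f"c{i}" for i in range(n)]),
        var=pd.DataFrame(index=[f"g{j}" for j in range(g)]),
    )


class TestModuleScore:
    def test_equals_direct_two_mean_oracle(self, small_norm):
        genes = [f"g{j}" for j in (3, 17, 40, 99, 150)]
        res = module_score(small_norm, genes, n_bins=10, n_controls=20, seed=11)
        oracle = module_score_oracle(small_norm, genes, 10, 20, 11)
        assert np.allclose(res.scores.to_numpy(), oracle, atol=1e-12)

    def test_random_sets_score_near_zero(self, small_norm):
        rng = np.random.default_rng(0)
        means = []
        for rep in range(50):
            genes = list(rng.choice(small_norm.var_names, size=8, replace=False))
            res = module_score(small_norm, genes, n_bins=10, n_controls=30, seed=rep)
            means.append(res.scores.mean())
        se = np.std(means, ddof=1) / np.sqrt(len(means))
        assert abs(np.mean(means)) < 2 * se + 1e-3

    def test_shift_invariance(self, small_norm):
        genes = ["g1", "g2", "g3"]
        res1 = module_score(small_norm, genes, seed=4)
        shifted = small_norm.copy()
        shifted.X = np.asarray(shifted.X) + 5.0
        res2 = module_score(shifted, genes, seed=4)
        assert np.allclose(res1.scores, res2.scores, atol=1e-10)

    def test_unmatched_set_raises_with_names(self, small_norm):
        with pytest.raises(ValueError, match="Nope1"):
            module_score(small_norm, ["Nope1", "Nope2"])

    def test_case_insensitive_matching(self, small_norm):
        res = module_score(small_norm, ["G1", "G2"], seed=0)
        assert res.matched_genes == ["g1", "g2"]

    def test_sasp_score_elevated_in_senescent_states(self, trajectory_run):
        norm = trajectory_run["norm"]
        truth = trajectory_run["truth"]
        states = trajectory_run["states"].states
        res = module_score(norm, truth.gene_sets["SASP"], "SASP", seed=0)
        by_state = res.scores.groupby(states).mean()
        assert min(by_state[3], by_state[4]) > max(by_state[1], by_state[2])


class TestCellCycle:
    def test_low_correlation_gene_excluded(self):
        rng = np.random.default_rng(1)
        n = 120
        phase = rng.choice(["G1/S", "S", "G2", "G2/M", "M/G1"], size=n)
        cols = {}
        lists = []
        for ph in ("G1/S", "S", "G2", "G2/M", "M/G1"):
            tag = ph.replace("/", "")
            for i in range(4):
                g = f"{tag}_{i}"
                cols[g] = np.where(phase == ph, 6.0, 1.0) + rng.normal(0, 0.3, n)
                lists.append({"gene": g, "phase": ph})
        # an anti-correlated decoy in the G1/S list
        cols["decoy"] = -np.where(phase == "G1/S", 6.0, 1.0) + rng.normal(0, 0.3, n)
        lists.append({"gene": "decoy", "phase": "G1/S"})
        log_tpm = pd.DataFrame(cols, index=[f"c{i}" for i in range(n)])
        call = call_cell_cycle(log_tpm, pd.DataFrame(lists))
        assert "decoy" not in call.retained_genes["G1/S"]

    def test_g0_rule_on_crafted_scores(self):
        # the quiescence rule is exact: G0 iff z(G1/S)<0 and z(G2/M)<0
        z = pd.DataFrame(
            {
                "G1/S": [-0.5, -0.5, 0.2, -0.1],
                "S": [-1.0, 0.1, 0.1, -2.0],
                "G2": [-1.0, 0.1, 0.1, -2.0],
                "G2/M": [-0.3, 0.4, -0.2, 0.0],
                "M/G1": [-1.0, 0.1, 0.3, -2.0],
            },
            index=list("abcd"),
        )
        is_g0 = (z["G1/S"] < 0) & (z["G2/M"] < 0)
        called = z.idxmax(axis=1).where(~is_g0, "G0")
        assert list(called) == ["G0", "G2/M", "M/G1", "G2/M"]

    def test_planted_phase_recovery(self, cycle_call, truth_frames):
        truth_phase = truth_frames["phase_true"].reindex(cycle_call.phases.index)
        acc = (cycle_call.phases == truth_phase).mean()
        assert acc >= 0.8

    def test_g0_fraction_recovered_within_tolerance(self):
        # averaged over replicate simulations to test the estimator, not
        # one realization's binomial noise
        from mammaclock import qc
        from mammaclock.simulate import SimulationConfig, generate_aging_dataset

        errs = []
        for seed in (0, 1, 2):
            adata, truth = generate_aging_dataset(SimulationConfig(seed=seed))
            norm = qc.normalize(qc.filter_cells_and_genes(adata))
            call = call_cell_cycle(counts_to_log2_tpm(norm), truth.phase_gene_table)
            truth_phase = pd.Series(truth.phase_true, index=adata.obs_names).reindex(
                call.phases.index
            )
            errs.append(
                abs((truth_phase == "G0").mean() - (call.phases == "G0").mean())
            )
        assert np.mean(errs) <= 0.05

    def test_invariance_to_tpm_rescaling(self, normalized):
        norm, truth = normalized
        lt = counts_to_log2_tpm(norm)
        call1 = call_cell_cycle(lt, truth.phase_gene_table)
        call2 = call_cell_cycle(lt + np.log2(7.0), truth.phase_gene_table)
        assert (call1.phases == call2.phases).all()

    def test_gene_order_invariance(self, normalized):
        norm, truth = normalized
        lt = counts_to_log2_tpm(norm)
        rng = np.random.default_rng(0)
        call1 = call_cell_cycle(lt, truth.phase_gene_table)
        call2 = call_cell_cycle(
            lt.iloc[:, rng.permutation(lt.shape[1])], truth.phase_gene_table
        )
        assert (call1.phases == call2.phases).all()


class TestPatternClassifier:
    @pytest.mark.parametrize(
        "a,expected",
        [
            ((1.0, 0.7, 0.3, 0.0), 1),  # gradual decline across the course
            ((0.2, 1.0, 0.3, 0.1), 2),  # transient early peak
            ((0.2, 0.1, 1.0, 0.3), 3),  # peak in e-Sen, drop in l-Sen
            ((0.0, 0.1, 0.95, 1.0), 4),  # plateau persisting into l-Sen
            ((0.0, 0.2, 0.6, 1.0), 5),  # continuous rise through senescence
            ((0.0, 0.05, 0.08, 1.0), 6),  # late-only activation
        ],
    )
    def test_documented_examples(self, a, expected):
        assert classify_pattern(a) == expected

    def test_flat_curve_unclassified(self):
        assert classify_pattern((0.25, 0.25, 0.25, 0.25)) is None

    @settings(max_examples=300, deadline=None, derandomize=True)
    @given(st.tuples(*[st.floats(0, 1) for _ in range(4)]))
    def test_classifier_is_total(self, a):
        out = classify_pattern(a)
        assert out in {1, 2, 3, 4, 5, 6, None}

    def test_pathway_dynamics_on_planted_programs(self, trajectory_run, truth_frames):
        norm = trajectory_run["norm"]
        pt = trajectory_run["pseudotime"]
        states = trajectory_run["states"]
        pattern = truth_frames["pattern_true"]
        sets = {
            f"pattern{p}": list(pattern.index[pattern == p])[:40]
            for p in (1, 3, 5)
        }
        dyn = pathway_dynamics(norm, pt, states, sets, seed=0)
        by_name = {d.name: d for d in dyn}
        # pattern-1 programs decline: state-1 mean is the maximum
        assert np.argmax(by_name["pattern1"].state_means) == 0
        # pattern-3 programs peak in e-Sen
        assert np.argmax(by_name["pattern3"].state_means) == 2
        # pattern-5 programs are maximal in l-Sen
        assert np.argmax(by_name["pattern5"].state_means) == 3


class TestPairedCompare:
    def _frames(self, diffs, base=None, seed=0):
        rng = np.random.default_rng(seed)
        n = len(diffs)
        genes = [f"g{i}" for i in range(4)]
        b = rng.normal(5, 1, size=(n, 4)) if base is None else base
        a = b + np.asarray(diffs)[:, None]
        idx = [f"s{i}" for i in range(n)]
        return (pd.DataFrame(a, index=idx, columns=genes),
                pd.DataFrame(b, index=idx, columns=genes), genes)

    def test_identical_pairs_give_null_result(self):
        a, b, genes = self._frames([0, 0, 0])
        out = paired_pathway_compare(a, b, genes)
        assert out["t"] == 0.0 and out["p"] == 1.0

    def test_constant_nonzero_differences_flagged(self):
        a, b, genes = self._frames([1.0, 1.0, 1.0])
        out = paired_pathway_compare(a, b, genes)
        assert out["zero_variance"]
        assert out["p"] <= np.finfo(float).tiny

    def test_t_statistic_matches_closed_form(self):
        diffs = np.array([0.5, -0.2, 0.8, 0.1, 0.3])
        a, b, genes = self._frames(diffs)
        out = paired_pathway_compare(a, b, genes)
        expected_t = diffs.mean() / (diffs.std(ddof=1) / np.sqrt(5))
        assert np.isclose(out["t"], expected_t, atol=1e-10)

    def test_single_pair_rejected(self):
        a, b, genes = self._frames([0.5])
        with pytest.raises(ValueError, match="2 pairs"):
            paired_pathway_compare(a, b, genes)
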