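"""MCMC engine: diagnostics, summaries, move correctness, pipelines."""

import math

import numpy as np
import pytest
from scipy.stats import kstest

from gestaltree import (
    Alignment,
    EditingParams,
    UNEDITED,
    effective_sample_size,
    hpd_interval,
    mcc_tree,
)
from gestaltree.mcmc import (
    CutRatesSpec,
    ExponentialPrior,
    GestaltMCMC,
    LogNormalPrior,
    PosteriorTrace,
    RunConfig,
    ScalarSpec,
    UniformPrior,
    propose_scale,
)
from gestaltree.simulate import simulate_alignment, simulate_pure_birth_n_tips
from gestaltree.trees import LineageTree, Node

from conftest import cherry_tree, make_design, make_params


class TestESS:
    def test_iid_normal(self):
        x = np.random.default_rng(0).normal(size=10_000)
        assert 8_000 < effective_sample_size(x) < 12_000

    def test_ar1_series(self):
        """AR(1) with coefficient 0.9 has ESS ~ n (1-phi)/(1+phi)."""
        rng = np.random.default_rng(1)
        phi, n = 0.9, 50_000
        x = np.empty(n)
        x[0] = 0.0
        eps = rng.normal(size=n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + eps[i]
        theory = n * (1 - phi) / (1 + phi)
        ess = effective_sample_size(x)
        assert theory / 1.5 < ess < theory * 1.5

    def test_duplication_halves_ess_ratio(self):
        x = np.random.default_rng(2).normal(size=5_000)
        ratio = effective_sample_size(x) / len(x)
        dup = np.repeat(x, 2)
        ratio_dup = effective_sample_size(dup) / len(dup)
        assert ratio_dup == pytest.approx(0.5 * ratio, rel=0.15)

    def test_constant_series_convention(self):
        assert effective_sample_size(np.ones(100)) == 100.0


class TestHPD:
    def test_point_mass_zero_width(self):
        lo, hi = hpd_interval(np.full(100, 3.25), 0.9)
        assert lo == hi == 3.25

    def test_uniform_width(self):
        x = np.random.default_rng(3).uniform(size=100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert hi - lo == pytest.approx(0.95, abs=0.02)

    def test_standard_normal(self):
        x = np.random.default_rng(4).normal(size=100_000)
        lo, hi = hpd_interval(x, 0.95)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)


class TestMoveStationarity:
    def test_scale_move_preserves_exponential_target(self):
        """Metropolis with only the scale move must leave the target
        invariant; compare the chain against the exact CDF."""
        rng = np.random.default_rng(5)
        x = 1.0
        samples = []
        for i in range(100_000):
            prop, log_hr = propose_scale(x, 0.9, rng)
            log_alpha = (-prop) - (-x) + log_hr
            if log_alpha >= 0 or rng.random() < math.exp(log_alpha):
                x = prop
            if i % 10 == 0:
                samples.append(x)
        res = kstest(samples[500:], lambda v: 1 - np.exp(-np.asarray(v)))
        assert res.pvalue > 0.001

    def test_topology_moves_sample_yule_law(self, design2, params2):
        """Prior-only full-tree chain on 4 taxa: labeled topology
        frequencies must match the equal-rates-Markov law (balanced
        topologies 2/18 each, caterpillars 1/18 each)."""
        tree = simulate_pure_birth_n_tips(4, birth_rate=1.0, seed=8)
        aln = Alignment(design=design2,
                        cells=[(lab.label, UNEDITED) for lab in tree.leaves()])
        cfg = RunConfig(
            replicates=[(tree, aln)],
            editing_template=params2,
            scalars=[ScalarSpec("birth_rate", ExponentialPrior(1.0),
                                init=1.0, weight=0.0)],
            cut_rates=None,
            mode="full-tree",
            tree_prior="birth-death",
            iterations=150_000,
            thin=60,
            burn_in=0.1,
            seed=6,
            likelihood="off",
            sample_trees=True,
        )
        trace = GestaltMCMC(cfg).run()
        topos = [t.topology_key() for t in trace.trees[0]]
        start = len(topos) // 10
        from collections import Counter
        counts = Counter(topos[start:])
        n = sum(counts.values())
        labels = sorted(l.label for l in tree.leaves())
        # enumerate all 15 labeled topologies' expected probabilities
        balanced, caterpillar = [], []
        import itertools
        for combo in itertools.combinations(labels, 2):
            rest = [l for l in labels if l not in combo]
            key = frozenset({frozenset(combo), frozenset(rest),
                             frozenset(labels)})
            if key not in balanced:
                balanced.append(key)
        seen = set(balanced)
        for cherry_pair in itertools.combinations(labels, 2):
            for third in labels:
                if third in cherry_pair:
                    continue
                key = frozenset({frozenset(cherry_pair),
                                 frozenset(set(cherry_pair) | {third}),
                                 frozenset(labels)})
                if key not in seen:
                    caterpillar.append(key)
                    seen.add(key)
        assert len(balanced) == 3 and len(caterpillar) == 12
        observed = np.array([counts.get(k, 0) for k in balanced + caterpillar],
                            dtype=float)
        expected = np.array([2 / 18] * 3 + [1 / 18] * 12) * n
        from scipy.stats import chisquare
        res = chisquare(observed, expected)
        assert res.pvalue > 0.001


class TestSampler:
    def test_prior_only_matches_prior_quantiles(self):
        tpl = EditingParams(cut_rates=(1.0,) * 3)
        cfg = RunConfig(
            replicates=[], editing_template=tpl,
            scalars=[ScalarSpec("clock_rate",
                                LogNormalPrior(math.log(0.02), 0.5),
                                window=1.0)],
            cut_rates=CutRatesSpec(),
            iterations=120_000, thin=60, burn_in=0.1, seed=9,
            likelihood="off")
        trace = GestaltMCMC(cfg).run()
        x = trace.series("clock_rate", 0.1)
        from scipy.stats import lognorm
        res = kstest(x, lambda v: lognorm.cdf(v, 0.5, scale=0.02))
        assert res.pvalue > 0.01

    def test_fixed_topology_keeps_topology(self, design3, params3):
        tree = simulate_pure_birth_n_tips(6, birth_rate=1.0, seed=10)
        aln = simulate_alignment(tree, design3, params3, seed=11)
        key = tree.topology_key()
        cfg = RunConfig(
            replicates=[(tree, aln)], editing_template=params3,
            scalars=[ScalarSpec("clock_rate", LogNormalPrior(0.0, 0.5),
                                init=1.0)],
            cut_rates=None, mode="fixed-topology",
            iterations=2_000, thin=100, burn_in=0.0, seed=12,
            likelihood="fast", sample_trees=True)
        trace = GestaltMCMC(cfg).run()
        assert all(t.topology_key() == key for t in trace.trees[0])

    def test_pooled_sharpens_shared_parameter(self, design3):
        """Pooling identical replicates multiplies their likelihoods and
        narrows the shared clock posterior."""
        params = make_params(3, clock_rate=0.05)
        tree = simulate_pure_birth_n_tips(8, birth_rate=0.3, seed=13)
        aln = simulate_alignment(tree, design3, params, seed=14)
        prior = LogNormalPrior(math.log(0.05), 1.0)

        def width(replicates, seed):
            cfg = RunConfig(
                replicates=replicates, editing_template=params,
                scalars=[ScalarSpec("clock_rate", prior, window=0.8)],
                cut_rates=None, iterations=40_000, thin=20, burn_in=0.3,
                seed=seed, likelihood="fast")
            tr = GestaltMCMC(cfg).run()
            lo, hi = hpd_interval(tr.series("clock_rate", 0.3), 0.95)
            return hi - lo

        wins = 0
        for s in range(3):
            w1 = width([(tree, aln)], seed=20 + s)
            w3 = width([(tree.copy(), aln)] * 3, seed=40 + s)
            wins += w3 < w1
        assert wins >= 2

    def test_nonfinite_initial_posterior_reports_component(self, design3,
                                                           params3):
        cfg = RunConfig(
            replicates=[], editing_template=params3,
            scalars=[ScalarSpec("clock_rate", UniformPrior(1.0, 2.0),
                                init=5.0)],  # outside the prior support
            cut_rates=None, iterations=100, thin=10, seed=0,
            likelihood="off")
        with pytest.raises(ValueError, match="prior"):
            GestaltMCMC(cfg).run()


class TestTrace:
    def test_log_round_trip(self, tmp_path):
        tpl = EditingParams(cut_rates=(1.0,))
        cfg = RunConfig(replicates=[], editing_template=tpl,
                        scalars=[ScalarSpec("clock_rate",
                                            ExponentialPrior(1.0))],
                        cut_rates=None, iterations=1_000, thin=100,
                        seed=1, likelihood="off")
        trace = GestaltMCMC(cfg).run()
        path = tmp_path / "run.log"
        trace.to_log_tsv(str(path))
        again = PosteriorTrace.from_log_tsv(str(path))
        assert np.allclose(again.params["clock_rate"],
                           trace.params["clock_rate"])
        assert (again.params["iteration"].diff().dropna() > 0).all()

    def test_burn_in_removal_idempotent(self):
        tpl = EditingParams(cut_rates=(1.0,))
        cfg = RunConfig(replicates=[], editing_template=tpl,
                        scalars=[ScalarSpec("clock_rate",
                                            ExponentialPrior(1.0))],
                        cut_rates=None, iterations=2_000, thin=10,
                        seed=2, likelihood="off")
        trace = GestaltMCMC(cfg).run()
        x = trace.series("clock_rate", 0.3)
        # removing burn-in from an already-trimmed series at fraction 0
        assert np.array_equal(x[int(0 * len(x)):], x)


class TestMCC:
    def _trees(self):
        t1 = simulate_pure_birth_n_tips(5, birth_rate=1.0, seed=30)
        t2 = t1.copy()
        # alternative topology: swap two tips' labels
        a, b = t2.leaves()[0], t2.leaves()[-1]
        a.label, b.label = b.label, a.label
        return t1, t2

    def test_identical_samples(self):
        t1, _ = self._trees()
        summary = mcc_tree([t1.copy() for _ in range(10)])
        assert summary.tree.topology_key() == t1.topology_key()
        assert all(v == 1.0 for v in summary.supports.values())

    def test_majority_topology_selected(self):
        t1, t2 = self._trees()
        samples = [t1.copy() for _ in range(9)] + [t2.copy()]
        summary = mcc_tree(samples)
        assert summary.tree.topology_key() == t1.topology_key()

    def test_supports_in_unit_interval_root_is_one(self):
        t1, t2 = self._trees()
        summary = mcc_tree([t1.copy() for _ in range(5)] + [t2.copy()] * 5)
        vals = list(summary.supports.values())
        assert all(0.0 <= v <= 1.0 for v in vals)
        root_clade = frozenset(l.label for l in summary.tree.leaves())
        assert summary.supports[root_clade] == 1.0

    def test_median_heights(self):
        t1, _ = self._trees()
        samples = []
        for shift in (-0.1, 0.0, 0.1):
            t = t1.copy()
            t.root.time += shift  # vary the root age across samples
            samples.append(t)
        summary = mcc_tree(samples)
        assert summary.tree.root.time == pytest.approx(t1.root.time)
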