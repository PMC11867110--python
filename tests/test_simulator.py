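"""Forward simulator: determinism, closed-form marginals, CTMC consistency."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare

from gestaltree import (
    Alignment,
    TargetStatus,
    UNEDITED,
    total_status_hazard,
)
from gestaltree.editing import tract_of_indel
from gestaltree.simulate import (
    BirthDeathSimConfig,
    SimulationError,
    simulate_alignment,
    simulate_birth_death_tree,
    simulate_pure_birth_n_tips,
    summarize_alignment,
    _evolve_allele,
)
from gestaltree.trees import Node, LineageTree

from conftest import make_design, make_params


class TestBirthDeathTree:
    def test_seed_determinism(self):
        config = BirthDeathSimConfig(birth_rate=0.8, duration=3.0,
                                     n_min=2, n_max=100, seed=42)
        t1 = simulate_birth_death_tree(config)
        t2 = simulate_birth_death_tree(config)
        assert t1.to_newick() == t2.to_newick()

    def test_mean_tip_count_pure_birth(self):
        """With no death and full sampling the tip count is geometric with
        mean e^{beta T}; conditioning on >= 2 tips shifts the mean to
        (e^{bT} - e^{-bT}) / (1 - e^{-bT} - bT-term...) computed exactly."""
        beta, T = 0.5, 3.0
        config = BirthDeathSimConfig(birth_rate=beta, duration=T,
                                     n_min=2, n_max=10_000, seed=1)
        rng = np.random.default_rng(1)
        n = [simulate_birth_death_tree(config, rng=rng).n_leaves
             for _ in range(400)]
        # N ~ Geometric on {1,2,...} with success prob p = e^{-beta T},
        # so E[N] = e^{beta T} and E[N | N >= 2] = (1/p - p) / (1 - p)
        p = math.exp(-beta * T)
        mean_cond = (1 / p - p) / (1 - p)
        se = np.std(n, ddof=1) / math.sqrt(len(n))
        assert abs(np.mean(n) - mean_cond) < 3 * se

    def test_tip_count_range_respected(self):
        config = BirthDeathSimConfig(birth_rate=0.8, duration=3.0,
                                     n_min=5, n_max=15, seed=3)
        rng = np.random.default_rng(3)
        for _ in range(10):
            tree = simulate_birth_death_tree(config, rng=rng)
            assert 5 <= tree.n_leaves <= 15
            tree.validate()

    def test_impossible_range_raises(self):
        config = BirthDeathSimConfig(birth_rate=0.1, duration=0.5,
                                     n_min=500, n_max=600, seed=0)
        with pytest.raises(SimulationError, match="rejections"):
            simulate_birth_death_tree(config)

    def test_sampling_prunes_tree(self):
        config = BirthDeathSimConfig(birth_rate=1.2, duration=3.0,
                                     sampling_prob=0.3, n_min=3, n_max=50,
                                     seed=5)
        tree = simulate_birth_death_tree(config)
        tree.validate()
        assert all(len(n.children) == 2 for n in tree.internal_nodes())


class TestAlignmentSimulation:
    def test_zero_rate_all_unedited(self, design3):
        params = make_params(3, clock_rate=1e-300)
        tree = simulate_pure_birth_n_tips(5, seed=0)
        aln = simulate_alignment(tree, design3, params, seed=1)
        assert all(a == UNEDITED for _, a in aln.cells)

    def test_seed_determinism(self, design3, params3):
        tree = simulate_pure_birth_n_tips(5, seed=0)
        a1 = simulate_alignment(tree, design3, params3, seed=7)
        a2 = simulate_alignment(tree, design3, params3, seed=7)
        assert a1.cells == a2.cells

    def test_unedited_fraction_closed_form(self):
        """Single target, single branch: P(unedited) = e^{-h r t}."""
        design = make_design(1)
        params = make_params(1)
        h = total_status_hazard(TargetStatus.all_active(1), design, params)
        t = 0.6
        rng = np.random.default_rng(11)
        n = 10_000
        unedited = sum(
            _evolve_allele(UNEDITED, t, params.clock_rate, design, params,
                           rng) == UNEDITED
            for _ in range(n))
        p = math.exp(-h * params.clock_rate * t)
        se = math.sqrt(p * (1 - p) / n)
        assert abs(unedited / n - p) < 3 * se

    def test_first_event_tract_frequencies(self, design2, params2):
        """Conditioned on exactly one event, the tract class frequencies
        follow the hazard ratios (chi-square)."""
        from gestaltree.editing import enumerate_tracts, tract_hazard
        rng = np.random.default_rng(13)
        t = 0.25
        counts = Counter()
        for _ in range(20_000):
            a = _evolve_allele(UNEDITED, t, 1.0, design2, params2, rng)
            if a.n_indels == 1:
                counts[tract_of_indel(a.indels[0], design2)] += 1
        tracts = enumerate_tracts(TargetStatus.all_active(2), design2)
        hazards = np.array([tract_hazard(tr, params2) for tr in tracts])
        # one-event paths may also be (event + masking) — negligible here
        observed = np.array([counts.get(tr, 0) for tr in tracts], dtype=float)
        expected = hazards / hazards.sum() * observed.sum()
        res = chisquare(observed, expected)
        assert res.pvalue > 0.001

    def test_statuses_monotone_along_lineages(self, design3, params3):
        tree = simulate_pure_birth_n_tips(6, seed=2)
        aln = simulate_alignment(tree, design3, params3, seed=3)
        for _, allele in aln.cells:
            allele.validate(design3)

    def test_single_branch_tv_distance_to_ctmc(self):
        """Empirical allele distribution vs expm row (total variation)."""
        from gestaltree.oracle import enumerate_allele_space
        from scipy.sparse.linalg import expm_multiply
        design = make_design(1)
        params = make_params(1)
        space = enumerate_allele_space(design, params)
        t = 0.7
        v = np.zeros(len(space.alleles))
        v[0] = 1.0
        probs = expm_multiply(space.generator(params).T * t, v)
        rng = np.random.default_rng(17)
        n = 10_000
        emp = np.zeros_like(probs)
        for _ in range(n):
            a = _evolve_allele(UNEDITED, t, 1.0, design, params, rng)
            emp[space.index[a]] += 1 / n
        tv = 0.5 * np.abs(emp - probs).sum()
        assert tv < 0.03


class TestSummarize:
    def test_all_unedited(self, design3):
        aln = Alignment(design=design3,
                        cells=[("a", UNEDITED), ("b", UNEDITED)])
        s = summarize_alignment(aln)
        assert s["mean_indels_per_site"] == 0.0
        assert s["n_unique_alleles"] == 1

    def test_fully_edited(self, design3):
        from gestaltree.editing import TargetTract, indel_for_detail
        indels = tuple(indel_for_detail(TargetTract(k, k, k, k), design3, 1, 0, "")
                       for k in (1, 2, 3))
        from gestaltree import Allele
        aln = Alignment(design=design3, cells=[("a", Allele(indels))])
        assert summarize_alignment(aln)["mean_indels_per_site"] == 1.0

    def test_validation_regime_editing_level(self):
        """Clock ~0.02 indels/site/unit over a 25-unit experiment on a
        4-target design gives roughly half the target sites edited."""
        from gestaltree import v7_like_design, EditingParams
        design = v7_like_design(n_targets=4)
        params = EditingParams(clock_rate=0.02, cut_rates=(1.0,) * 4,
                               double_cut_weight=0.05, long_trim_left=0.05,
                               long_trim_right=0.05)
        rng = np.random.default_rng(23)
        means = []
        for _ in range(10):
            tree = simulate_pure_birth_n_tips(10, seed=rng)
            scale = 25.0 / tree.height
            for node in tree.postorder():
                node.time *= scale
            aln = simulate_alignment(tree, design, params, seed=rng)
            means.append(summarize_alignment(aln)["mean_indels_per_site"])
        assert 0.3 < np.mean(means) < 0.7
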