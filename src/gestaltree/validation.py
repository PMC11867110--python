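"""Simulation-based calibration and tree-shape diagnostics.

The calibration study is the end-to-end correctness check of the whole
inference stack: draw editing parameters from their priors, simulate a
tree and an alignment, infer the parameters back with the same priors and
the tree fixed to truth, and measure how often each alpha-level highest-
posterior-density interval contains the true value.  When simulation and
inference models match, coverage at level alpha is Binomial(n, alpha);
points outside the binomial band indicate miscalibration (the negative
control deliberately mis-scales the inference model's editing rates to
demonstrate the check has power).

Tree-shape diagnostics: the Colless imbalance index (sum over internal
nodes of the absolute difference of child clade sizes) and its exact
expectation under the Yule / constant-rate birth-death topology law via
the uniform-root-split recurrence

    E_1 = E_2 = 0,
    E_n = (1/(n-1)) * sum_{i=1}^{n-1} (|n - 2i| + E_i + E_{n-i}).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.stats import binom

from .barcode import BarcodeDesign, v7_like_design
from .editing import EditingParams, TrimMeans
from .mcmc import (
    CutRatesSpec,
    DirichletWeights,
    GestaltMCMC,
    LogNormalPrior,
    RunConfig,
    ScalarSpec,
    effective_sample_size,
    hpd_interval,
)
from .simulate import simulate_alignment, simulate_pure_birth_n_tips
from .trees import LineageTree


# ---------------------------------------------------------------------------
# Colless imbalance
# ---------------------------------------------------------------------------

def colless_index(tree: LineageTree) -> int:
    """Sum of |n_left - n_right| over all internal nodes (topology only)."""
    sizes: dict[int, int] = {}
    total = 0
    for node in tree.postorder():
        if node.is_leaf:
            sizes[id(node)] = 1
            continue
        if len(node.children) != 2:
            raise ValueError("Colless index requires a bifurcating tree")
        a, b = (sizes[id(c)] for c in node.children)
        total += abs(a - b)
        sizes[id(node)] = a + b
    return total


def expected_colless_yule(n: int) -> float:
    """Exact expected Colless index of an n-tip Yule (ERM) topology.

    Under the equal-rates-Markov law shared by all constant-rate
    birth-death processes, the root splits n tips into (i, n-i) with
    probability 1/(n-1) each, giving the recurrence documented above.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    E = [0.0] * (n + 1)
    for m in range(3, n + 1):
        E[m] = sum(abs(m - 2 * i) + E[i] + E[m - i]
                   for i in range(1, m)) / (m - 1)
    return E[n]


def colless_mc_mean(n_tips: int, n_trees: int, seed: int = 0,
                    birth_rate: float = 1.0) -> tuple[float, float]:
    """Monte Carlo mean (and standard error) of the Colless index over
    simulated n-tip birth-death trees."""
    rng = np.random.default_rng(seed)
    vals = np.array([
        colless_index(simulate_pure_birth_n_tips(n_tips, birth_rate, rng))
        for _ in range(n_trees)], dtype=float)
    return float(vals.mean()), float(vals.std(ddof=1) / math.sqrt(n_trees))


# ---------------------------------------------------------------------------
# Calibration study
# ---------------------------------------------------------------------------

@dataclass
class CalibrationPriors:
    """Priors for the editing parameters (simulation = inference)."""

    clock: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(math.log(0.02), 0.4))
    double_cut: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(math.log(0.05), 0.4))
    long_left: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(math.log(0.05), 0.4))
    long_right: LogNormalPrior = field(default_factory=lambda: LogNormalPrior(math.log(0.05), 0.4))
    cut_rate_concentration: float = 10.0


@dataclass
class CalibrationSimConfig:
    """Simulation regime: V7-style design shortened to 4 targets, trees
    with ~10 tips and an experiment duration of 25 time units, matching a
    low editing regime of ~0.5 expected indels per target site."""

    n_targets: int = 4
    n_tips: int = 10
    duration: float = 25.0
    trim_means: TrimMeans = field(default_factory=lambda: TrimMeans(3.0, 3.0, 3.0, 3.0))
    insert_mean: float = 1.0
    max_insert_len: int = 10


@dataclass
class CalibrationChainConfig:
    iterations: int = 200_000
    thin: int = 20
    burn_in: float = 0.3
    ess_threshold: float = 200.0
    rate_factor: float = 1.0  # != 1 deliberately mis-specifies the inference


@dataclass
class CalibrationReport:
    """Coverage table and per-replicate convergence diagnostics."""

    table: pd.DataFrame        # param, level, coverage, ci_low, ci_high, within
    levels: tuple[float, ...]
    n_replicates: int
    ess: pd.DataFrame          # per replicate x param effective sample sizes
    converged: list[bool]
    truths: list[dict]
    seed: int

    def all_within(self, params: list[str] | None = None) -> bool:
        t = self.table
        if params is not None:
            t = t[t["param"].isin(params)]
        return bool(t["within"].all())


DEFAULT_LEVELS = tuple(round(0.05 + 0.1 * k, 2) for k in range(10))  # 0.05..0.95


def _draw_truth(priors: CalibrationPriors, sim: CalibrationSimConfig,
                rng: np.random.Generator) -> EditingParams:
    m = sim.n_targets
    w = DirichletWeights(priors.cut_rate_concentration, m).rvs(rng)
    return EditingParams(
        clock_rate=priors.clock.rvs(rng),
        cut_rates=tuple(m * w),
        double_cut_weight=priors.double_cut.rvs(rng),
        long_trim_left=priors.long_left.rvs(rng),
        long_trim_right=priors.long_right.rvs(rng),
        trim_means=sim.trim_means,
        insert_mean=sim.insert_mean,
        max_insert_len=sim.max_insert_len,
    )


def run_calibration(n_replicates: int = 30,
                    priors: CalibrationPriors | None = None,
                    sim_config: CalibrationSimConfig | None = None,
                    chain_config: CalibrationChainConfig | None = None,
                    seed: int = 0,
                    levels: tuple[float, ...] = DEFAULT_LEVELS,
                    design: BarcodeDesign | None = None) -> CalibrationReport:
    """Run the well-calibrated simulation study at the configured scale.

    For each replicate: draw editing parameters from the priors, simulate
    a tree (pure-birth, stopped at the target tip count, rescaled to the
    experiment duration) and an alignment along it, then run MCMC with
    matched priors and the tree fixed to its true value.  Coverage is the
    fraction of replicates whose alpha-HPD interval contains the truth;
    the binomial band is the 95% interval of Binomial(n, alpha).
    Non-converged replicates (any ESS below the threshold) are flagged in
    the report, not dropped.
    """
    priors = priors or CalibrationPriors()
    sim = sim_config or CalibrationSimConfig()
    chain = chain_config or CalibrationChainConfig()
    design = design or v7_like_design(n_targets=sim.n_targets)
    rng = np.random.default_rng(seed)

    param_names = (["clock_rate", "double_cut_weight",
                    "long_trim_left", "long_trim_right"]
                   + [f"cut_rate_{k + 1}" for k in range(sim.n_targets)])
    hits = {p: np.zeros(len(levels), dtype=int) for p in param_names}
    ess_rows = []
    converged = []
    truths = []

    for rep in range(n_replicates):
        truth = _draw_truth(priors, sim, rng)
        truths.append(truth.to_dict())
        tree = simulate_pure_birth_n_tips(sim.n_tips, birth_rate=1.0, seed=rng)
        scale = sim.duration / tree.height
        for node in tree.postorder():
            node.time *= scale
        tree.origin_time = 0.0
        aln = simulate_alignment(tree, design, truth, seed=rng)

        template = EditingParams(
            clock_rate=float(np.exp(priors.clock.mean_log)),
            cut_rates=(1.0,) * sim.n_targets,
            double_cut_weight=float(np.exp(priors.double_cut.mean_log)),
            long_trim_left=float(np.exp(priors.long_left.mean_log)),
            long_trim_right=float(np.exp(priors.long_right.mean_log)),
            trim_means=sim.trim_means, insert_mean=sim.insert_mean,
            max_insert_len=sim.max_insert_len)
        config = RunConfig(
            replicates=[(tree, aln)],
            editing_template=template,
            scalars=[
                ScalarSpec("clock_rate", priors.clock, window=0.4),
                ScalarSpec("double_cut_weight", priors.double_cut, window=0.7),
                ScalarSpec("long_trim_left", priors.long_left, window=0.8),
                ScalarSpec("long_trim_right", priors.long_right, window=0.8),
            ],
            cut_rates=CutRatesSpec(concentration=priors.cut_rate_concentration),
            mode="fixed-tree",
            iterations=chain.iterations,
            thin=chain.thin,
            burn_in=chain.burn_in,
            seed=int(rng.integers(2 ** 31 - 1)),
            likelihood="fast",
            likelihood_rate_factor=chain.rate_factor,
        )
        trace = GestaltMCMC(config).run()

        truth_values = {
            "clock_rate": truth.clock_rate,
            "double_cut_weight": truth.double_cut_weight,
            "long_trim_left": truth.long_trim_left,
            "long_trim_right": truth.long_trim_right,
        }
        for k in range(sim.n_targets):
            truth_values[f"cut_rate_{k + 1}"] = truth.cut_rates[k]

        ess_row = {"replicate": rep}
        ok = True
        for p in param_names:
            samples = trace.series(p, burn_in=chain.burn_in)
            ess = effective_sample_size(samples)
            ess_row[p] = ess
            ok = ok and ess > chain.ess_threshold
            for li, level in enumerate(levels):
                lo, hi = hpd_interval(samples, level)
                if lo <= truth_values[p] <= hi:
                    hits[p][li] += 1
        ess_rows.append(ess_row)
        converged.append(ok)

    rows = []
    for p in param_names:
        for li, level in enumerate(levels):
            k = int(hits[p][li])
            lo = binom.ppf(0.025, n_replicates, level) / n_replicates
            hi = binom.ppf(0.975, n_replicates, level) / n_replicates
            cov = k / n_replicates
            rows.append({"param": p, "level": level, "coverage": cov,
                         "ci_low": lo, "ci_high": hi,
                         "within": bool(lo <= cov <= hi)})
    return CalibrationReport(
        table=pd.DataFrame(rows), levels=levels, n_replicates=n_replicates,
        ess=pd.DataFrame(ess_rows), converged=converged, truths=truths,
        seed=seed)
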