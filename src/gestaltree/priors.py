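"""Log-densities of the tree-generating models and derived quantities.

Two standard phylodynamic models for an exponentially growing cell
population sampled once at the present:

* the constant-rate **birth-death-sampling** process with division rate
  beta, death rate delta and present-day sampling fraction rho, under
  which the expected population size is ``N(t) = exp((beta - delta) t)``;
* the **coalescent with exponential growth**, a deterministic trajectory
  ``N(t) = exp(g t)`` (N = 1 at the founder) with the usual pairwise
  coalescence intensity ``1/N``.

Node times are stored forward (root smallest); the densities convert to
ages internally.  The birth-death density follows the standard
constant-rate sampling formulas:

    p0(t) = 1 - rho (b-d) / (rho b + (b(1-rho) - d) e^{-(b-d)t})
    p1(t) = rho (b-d)^2 e^{-(b-d)t} / (rho b + (b(1-rho) - d) e^{-(b-d)t})^2

with density per oriented sampled tree, given the origin age x0,
``p1(x0) * prod_i b p1(x_i)`` over internal node ages, conditioned on
survival by 1/(1 - p0(x0)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .trees import LineageTree, TreeError


@dataclass(frozen=True)
class BirthDeathParams:
    """beta (division rate), delta (death rate), rho (sampling fraction)."""

    birth_rate: float
    death_rate: float = 0.0
    sampling_prob: float = 1.0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("need birth_rate > 0 and death_rate >= 0")
        if not (0 < self.sampling_prob <= 1):
            raise ValueError("sampling_prob must be in (0, 1]")


@dataclass(frozen=True)
class CoalescentExpParams:
    """Exponential-growth coalescent: growth rate g and size at sampling."""

    growth_rate: float
    pop_size_at_sampling: float = 1.0

    def __post_init__(self) -> None:
        if self.pop_size_at_sampling <= 0:
            raise ValueError("population size must be > 0")


def _bd_denominator(params: BirthDeathParams, t: float) -> float:
    b, d, rho = params.birth_rate, params.death_rate, params.sampling_prob
    return rho * b + (b * (1 - rho) - d) * math.exp(-(b - d) * t)


def _is_critical(params: BirthDeathParams) -> bool:
    return abs(params.birth_rate - params.death_rate) < 1e-12


def bd_p0(params: BirthDeathParams, t: float) -> float:
    """Probability a single lineage at age t leaves no sampled descendant."""
    b, d, rho = params.birth_rate, params.death_rate, params.sampling_prob
    if _is_critical(params):
        return 1.0 - rho / (1.0 + rho * b * t)
    return 1.0 - rho * (b - d) / _bd_denominator(params, t)


def bd_log_p1(params: BirthDeathParams, t: float) -> float:
    """log probability density that a lineage at age t has exactly one
    sampled descendant."""
    b, d, rho = params.birth_rate, params.death_rate, params.sampling_prob
    if _is_critical(params):
        return math.log(rho) - 2 * math.log1p(rho * b * t)
    return (math.log(rho) + 2 * math.log(b - d) - (b - d) * t
            - 2 * math.log(_bd_denominator(params, t)))


def _bd_int_bp1(params: BirthDeathParams, x0: float) -> float:
    """Closed form of ``int_0^{x0} b * p1(t) dt`` (node-age normalizer)."""
    b, d, rho = params.birth_rate, params.death_rate, params.sampling_prob
    if _is_critical(params):
        return 1.0 - 1.0 / (1.0 + rho * b * x0)
    A = b - d
    B = b * (1 - rho) - d
    if abs(B) < 1e-12:
        # boundary case b(1-rho) == d: the denominator is constant rho*b
        return (A / (rho * b)) * (1.0 - math.exp(-A * x0))
    q0 = _bd_denominator(params, 0.0)
    qx = _bd_denominator(params, x0)
    return b * rho * A / B * (1.0 / qx - 1.0 / q0)


def _node_ages(tree: LineageTree) -> tuple[list[float], float]:
    tip = tree.tip_time
    ages = []
    for node in tree.internal_nodes():
        age = tip - node.time
        if age < -1e-12:
            raise TreeError("negative node age")
        ages.append(age)
    return ages, tip


def birth_death_log_density(tree: LineageTree, params: BirthDeathParams,
                            conditioning: str = "origin",
                            origin_time: float | None = None) -> float:
    """Log-density of a time tree under the birth-death-sampling model.

    conditioning:
      * ``"origin"`` — given the origin age (from ``origin_time`` or the
        tree's own ``origin_time``), conditioned on survival;
      * ``"root"`` — given the root age, both root children conditioned on
        leaving sampled descendants; no factor for the root split itself;
      * ``"origin_ntips"`` — given the origin age *and* the number of
        tips: the n-1 internal-node ages are then i.i.d. with density
        ``b p1(x) / int b p1``; integrates to 1 over node-age space.
    """
    ages, tip = _node_ages(tree)
    root_age = max(ages)
    b = params.birth_rate
    if conditioning in ("origin", "origin_ntips"):
        if origin_time is None:
            origin_time = tree.origin_time
        if origin_time is None:
            raise ValueError("origin conditioning requires an origin time")
        x0 = tip - origin_time
        if x0 < root_age - 1e-12:
            raise ValueError("origin age must exceed the root age")
        if conditioning == "origin":
            logf = bd_log_p1(params, x0) - math.log1p(-bd_p0(params, x0))
            for x in ages:
                logf += math.log(b) + bd_log_p1(params, x)
            return logf
        z = _bd_int_bp1(params, x0)
        return sum(math.log(b) + bd_log_p1(params, x) - math.log(z) for x in ages)
    if conditioning == "root":
        logf = 2 * bd_log_p1(params, root_age) \
            - 2 * math.log1p(-bd_p0(params, root_age))
        for x in ages:
            if x != root_age:
                logf += math.log(b) + bd_log_p1(params, x)
        return logf
    raise ValueError(f"unknown conditioning {conditioning!r}")


def coalescent_exp_log_density(tree: LineageTree,
                               params: CoalescentExpParams) -> float:
    """Log-density of the node times under the exponential-growth coalescent.

    Backward time s runs from the tips; the trajectory is
    ``N(s) = N_sampling * exp(-g s)``.  With g = 0 this is exactly the
    constant-size Kingman coalescent.
    """
    g = params.growth_rate
    n0 = params.pop_size_at_sampling
    ages, _ = _node_ages(tree)
    for node in tree.postorder():
        if node.parent is not None and node.time < node.parent.time - 1e-12:
            raise TreeError("negative branch length")
    events = sorted(ages)
    n_tips = tree.n_leaves

    def inv_n_integral(s0: float, s1: float) -> float:
        # int_{s0}^{s1} ds / (n0 e^{-g s})
        if g == 0:
            return (s1 - s0) / n0
        return (math.exp(g * s1) - math.exp(g * s0)) / (g * n0)

    logf = 0.0
    k = n_tips
    s_prev = 0.0
    for s in events:
        pairs = k * (k - 1) / 2.0
        logf -= pairs * inv_n_integral(s_prev, s)
        logf += -math.log(n0) + g * s  # log(1 / N(s))
        s_prev = s
        k -= 1
    return logf


def expected_population_size(birth_rate: float, death_rate: float,
                             t: float) -> float:
    """E[N(t)] = exp((beta - delta) t) for the birth-death process."""
    if t < 0:
        raise ValueError("t must be >= 0")
    return math.exp((birth_rate - death_rate) * t)


def coalescent_sampling_proportion(n_sampled: float, growth_rate: float,
                                   t: float) -> float:
    """Sampling proportion s / N(t) with N(t) = exp(g t).

    With g = 0 the population size stays at the founder's size 1 and the
    ratio degenerates to s itself.
    """
    if n_sampled < 1 or t <= 0:
        raise ValueError("need n_sampled >= 1 and t > 0")
    return n_sampled / math.exp(growth_rate * t)
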