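"""Metropolis-Hastings sampling of editing parameters, node times,
topologies and phylodynamic parameters.

The sampler supports the three analysis pipelines: independent inference
on a single dataset, pooled inference where replicates share editing and
growth parameters (the target is the product of the replicate
likelihoods), and fixed-topology inference where only node times move.
Proposals are classic phylogenetic MCMC kernels: multiplicative scale
moves on positive scalars, a mean-preserving transfer move on the cut-rate
simplex, a whole-tree age scaler, uniform node-time slides, narrow
exchange and Wilson-Balding topology moves.

Also here: trace containers and BEAST-style log I/O, the effective sample
size estimator (initial positive-sequence truncation), highest-posterior-
density intervals, and maximum-clade-credibility tree summaries.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .editing import EditingParams
from .priors import (
    BirthDeathParams,
    CoalescentExpParams,
    birth_death_log_density,
    coalescent_exp_log_density,
)
from .trees import LineageTree, Node

__all__ = [
    "LogNormalPrior", "ExponentialPrior", "UniformPrior", "DirichletWeights",
    "ScalarSpec", "CutRatesSpec", "RunConfig", "PosteriorTrace",
    "GestaltMCMC", "run_mcmc", "effective_sample_size", "hpd_interval",
    "mcc_tree", "MCCSummary", "propose_scale",
]


# ---------------------------------------------------------------------------
# Priors
# ---------------------------------------------------------------------------

class LogNormalPrior:
    """Log-normal prior parameterized by the log-scale mean and sd."""

    def __init__(self, mean_log: float, sd_log: float):
        self.mean_log, self.sd_log = float(mean_log), float(sd_log)

    def logpdf(self, x: float) -> float:
        if x <= 0:
            return -math.inf
        z = (math.log(x) - self.mean_log) / self.sd_log
        return -0.5 * z * z - math.log(x * self.sd_log * math.sqrt(2 * math.pi))

    def rvs(self, rng: np.random.Generator) -> float:
        return float(math.exp(rng.normal(self.mean_log, self.sd_log)))

    def ppf(self, q):
        from scipy.stats import norm
        return np.exp(norm.ppf(q, loc=self.mean_log, scale=self.sd_log))


class ExponentialPrior:
    def __init__(self, mean: float):
        self.mean = float(mean)

    def logpdf(self, x: float) -> float:
        if x < 0:
            return -math.inf
        return -math.log(self.mean) - x / self.mean

    def rvs(self, rng: np.random.Generator) -> float:
        return float(rng.exponential(self.mean))

    def ppf(self, q):
        return -self.mean * np.log1p(-np.asarray(q))


class UniformPrior:
    def __init__(self, low: float, high: float):
        self.low, self.high = float(low), float(high)

    def logpdf(self, x: float) -> float:
        if self.low <= x <= self.high:
            return -math.log(self.high - self.low)
        return -math.inf

    def rvs(self, rng: np.random.Generator) -> float:
        return float(rng.uniform(self.low, self.high))

    def ppf(self, q):
        return self.low + (self.high - self.low) * np.asarray(q)


class DirichletWeights:
    """Symmetric Dirichlet prior on simplex weights w (cut rates = M * w)."""

    def __init__(self, concentration: float, dim: int):
        self.concentration, self.dim = float(concentration), int(dim)

    def logpdf(self, w: np.ndarray) -> float:
        w = np.asarray(w)
        if np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-9:
            return -math.inf
        a = self.concentration
        return float((a - 1) * np.log(w).sum()
                     + math.lgamma(a * self.dim) - self.dim * math.lgamma(a))

    def rvs(self, rng: np.random.Generator) -> np.ndarray:
        return rng.dirichlet([self.concentration] * self.dim)


# ---------------------------------------------------------------------------
# Proposal kernels
# ---------------------------------------------------------------------------

def propose_scale(value: float, window: float, rng: np.random.Generator):
    """Multiplicative random walk x' = x e^u, u ~ U(-window, window).

    Returns (proposal, log Hastings ratio); the ratio is u (the Jacobian
    of the log transform).
    """
    u = rng.uniform(-window, window)
    return value * math.exp(u), u


def _simplex_transfer(w: np.ndarray, delta: float, rng: np.random.Generator):
    """Move mass between two random components; symmetric on the simplex."""
    i, j = rng.choice(len(w), size=2, replace=False)
    eps = rng.uniform(-delta, delta)
    w2 = w.copy()
    w2[i] += eps
    w2[j] -= eps
    if w2[i] <= 0 or w2[j] <= 0:
        return None
    return w2, 0.0


# ---------------------------------------------------------------------------
# Tree moves (mutate in place; return (logHR, undo) or None if invalid)
# ---------------------------------------------------------------------------

def _internal_nonroot(tree: LineageTree) -> list[Node]:
    return [n for n in tree.internal_nodes() if n is not tree.root]


def move_node_slide(tree: LineageTree, rng: np.random.Generator):
    """Uniform slide of one internal node's time within its bracket."""
    nodes = _internal_nonroot(tree)
    if not nodes:
        return None
    node = nodes[int(rng.integers(len(nodes)))]
    lo = node.parent.time
    hi = min(c.time for c in node.children)
    if hi <= lo:
        return None
    old = node.time
    node.time = rng.uniform(lo, hi)

    def undo():
        node.time = old
    return 0.0, undo


def move_tree_scale(tree: LineageTree, window: float, rng: np.random.Generator):
    """Scale all internal-node ages (tips fixed); the root-age scaler."""
    tip = tree.tip_time
    internals = tree.internal_nodes()
    u = rng.uniform(-window, window)
    s = math.exp(u)
    old_times = [(n, n.time) for n in internals]
    for n in internals:
        n.time = tip - (tip - n.time) * s
    root_ok = tree.origin_time is None or tree.root.time >= tree.origin_time
    ok = root_ok and all(
        n.time <= min(c.time for c in n.children) + 1e-12 for n in internals)
    if not ok:
        for n, t in old_times:
            n.time = t
        return None

    def undo():
        for n, t in old_times:
            n.time = t
    return len(internals) * u, undo


def move_narrow_exchange(tree: LineageTree, rng: np.random.Generator):
    """Swap a random child of an internal node with the node's sibling.

    The selection sets (internal non-root node, one of its two children)
    have fixed sizes, and the reverse move selects the same node with the
    swapped child, so the proposal is symmetric (Hastings ratio 1); time
    infeasibility is handled by rejection.
    """
    nodes = _internal_nonroot(tree)
    if not nodes:
        return None
    u = nodes[int(rng.integers(len(nodes)))]
    p = u.parent
    s = next(c for c in p.children if c is not u)
    c = u.children[int(rng.integers(2))]
    if s.time <= u.time:
        return None
    si = p.children.index(s)
    ci = u.children.index(c)
    p.children[si], u.children[ci] = c, s
    c.parent, s.parent = p, u

    def undo():
        p.children[si], u.children[ci] = s, c
        s.parent, c.parent = p, u
    return 0.0, undo


def _subtree_nodes(node: Node) -> set[int]:
    out, stack = set(), [node]
    while stack:
        n = stack.pop()
        out.add(id(n))
        stack.extend(n.children)
    return out


def move_wilson_balding(tree: LineageTree, rng: np.random.Generator):
    """Prune a subtree and regraft it onto a random branch.

    The pruned node i is chosen uniformly among nodes with a grandparent
    (a set of fixed size 2n-4); after detaching i's parent, the
    destination child j is chosen uniformly among the remaining non-root
    nodes (re-selecting i's old sibling re-inserts on the original branch,
    a pure node-time move).  The reattachment time is uniform on the
    feasible window, giving Hastings ratio window_new / window_reverse;
    infeasible destinations are rejected.
    """
    pruneable = [n for n in tree.postorder()
                 if n.parent is not None and n.parent.parent is not None]
    if not pruneable:
        return None
    i = pruneable[int(rng.integers(len(pruneable)))]
    ip = i.parent
    ipp = ip.parent
    cp = next(c for c in ip.children if c is not i)
    window_rev = min(cp.time, i.time) - ipp.time
    forbidden = _subtree_nodes(i)

    # destination: any node of the detached tree that has a parent
    dests = [n for n in tree.postorder()
             if n.parent is not None and id(n) not in forbidden and n is not ip]
    # cp's effective parent after detachment is ipp
    j = dests[int(rng.integers(len(dests)))]
    jp = ipp if j is cp else j.parent
    window_new = min(j.time, i.time) - jp.time
    if window_new <= 0 or window_rev <= 0:
        return None
    t_new = rng.uniform(jp.time, jp.time + window_new)

    if j is cp:  # re-insertion on the original branch: a pure time change
        old_ip_time = ip.time
        ip.time = t_new

        def undo():
            ip.time = old_ip_time
        return math.log(window_new) - math.log(window_rev), undo

    # detach ip (and i) from its place; cp takes ip's slot under ipp
    old_ip_time = ip.time
    ipp.children[ipp.children.index(ip)] = cp
    cp.parent = ipp
    # insert ip on branch (jp -> j)
    jp.children[jp.children.index(j)] = ip
    ip.parent = jp
    ip.children = [i, j]
    i.parent = ip
    j.parent = ip
    ip.time = t_new

    def undo():
        jp.children[jp.children.index(ip)] = j
        j.parent = jp
        ipp.children[ipp.children.index(cp)] = ip
        ip.parent = ipp
        ip.children = [i, cp]
        cp.parent = ip
        i.parent = ip
        ip.time = old_ip_time
    return math.log(window_new) - math.log(window_rev), undo


# ---------------------------------------------------------------------------
# Run configuration and trace
# ---------------------------------------------------------------------------

@dataclass
class ScalarSpec:
    """One estimated positive scalar: prior, initial value, move window."""

    name: str
    prior: object
    init: float | None = None
    window: float = 0.6
    weight: float = 1.0


@dataclass
class CutRatesSpec:
    """Cut-rate vector, constrained to mean 1 via simplex weights.

    The transfer-move step size and selection weight default to values
    that balance per-iteration effective sample size between the cut
    rates and the scalar parameters.
    """

    concentration: float = 10.0
    delta: float = 0.15
    weight: float = 4.0


@dataclass
class RunConfig:
    """Configuration of one MCMC run.

    mode: "fixed-tree" (no tree moves), "fixed-topology" (node-time moves
    only) or "full-tree".  Multiple replicates imply pooled inference:
    editing and phylodynamic parameters are shared, each replicate keeps
    its own tree, and the target multiplies the replicate likelihoods.
    """

    replicates: list  # list of (LineageTree, Alignment)
    editing_template: EditingParams
    scalars: list[ScalarSpec] = field(default_factory=list)
    cut_rates: CutRatesSpec | None = None
    mode: str = "fixed-tree"
    tree_prior: str | None = None  # None | "birth-death" | "coalescent"
    tree_prior_scalars: list[ScalarSpec] = field(default_factory=list)
    bd_death_rate: float = 0.0
    bd_sampling_prob: float = 1.0
    iterations: int = 100_000
    thin: int = 100
    burn_in: float = 0.3
    seed: int = 0
    likelihood: str = "fast"  # "fast" | "reference" | "off"
    #: multiply all editing rates in the *inference* model only; != 1 is a
    #: deliberate model mis-specification used by negative-control checks
    likelihood_rate_factor: float = 1.0
    max_states: int = 256
    sample_trees: bool = False

    def __post_init__(self) -> None:
        if self.iterations <= 0 or self.thin <= 0:
            raise ValueError("iterations and thin must be positive")
        if not (0 <= self.burn_in < 1):
            raise ValueError("burn-in fraction must be in [0, 1)")
        if self.mode not in ("fixed-tree", "fixed-topology", "full-tree"):
            raise ValueError(f"unknown mode {self.mode!r}")


@dataclass
class PosteriorTrace:
    """Sampled iterations x (posterior, likelihood, prior, parameters)."""

    params: pd.DataFrame
    trees: list[list[LineageTree]] = field(default_factory=list)

    def series(self, name: str, burn_in: float = 0.0) -> np.ndarray:
        x = self.params[name].to_numpy()
        return x[int(len(x) * burn_in):]

    def to_log_tsv(self, path: str) -> None:
        df = self.params.rename(columns={"iteration": "Sample"})
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_log_tsv(cls, path: str) -> "PosteriorTrace":
        df = pd.read_csv(path, sep="\t")
        return cls(params=df.rename(columns={"Sample": "iteration"}))


# ---------------------------------------------------------------------------
# The sampler
# ---------------------------------------------------------------------------

class GestaltMCMC:
    def __init__(self, config: RunConfig):
        self.config = config
        self.rng = np.random.default_rng(config.seed)
        self._setup()

    # -- setup -------------------------------------------------------------

    def _setup(self) -> None:
        cfg = self.config
        self.trees = [tree for tree, _ in cfg.replicates]
        self.alignments = [aln for _, aln in cfg.replicates]
        self.scalars = {s.name: (s.prior.rvs(self.rng) if s.init is None else s.init)
                        for s in cfg.scalars + cfg.tree_prior_scalars}
        self._scalar_specs = {s.name: s for s in cfg.scalars + cfg.tree_prior_scalars}
        m = cfg.editing_template.n_targets
        if cfg.cut_rates is not None:
            self.cut_weights = np.full(m, 1.0 / m)
            self._dirichlet = DirichletWeights(cfg.cut_rates.concentration, m)
        else:
            self.cut_weights = None

        self._likes = []
        if cfg.likelihood == "fast":
            from .fastlike import FixedTreeLikelihood
            for tree, aln in cfg.replicates:
                self._likes.append(FixedTreeLikelihood(
                    tree, aln, cfg.editing_template, max_states=cfg.max_states))
        elif cfg.likelihood == "reference":
            from .likelihood import TreeLikelihood
            for tree, aln in cfg.replicates:
                self._likes.append(TreeLikelihood(
                    tree, aln, cfg.editing_template, max_states=cfg.max_states))

        self._moves = self._build_moves()

    def _build_moves(self):
        cfg = self.config
        moves = []
        for name, spec in self._scalar_specs.items():
            moves.append((spec.weight, ("scalar", name)))
        if self.cut_weights is not None:
            moves.append((cfg.cut_rates.weight, ("simplex", None)))
        if cfg.mode in ("fixed-topology", "full-tree"):
            for idx in range(len(self.trees)):
                moves.append((2.0, ("slide", idx)))
                moves.append((1.0, ("treescale", idx)))
        if cfg.mode == "full-tree":
            for idx in range(len(self.trees)):
                moves.append((1.0, ("narrow", idx)))
                moves.append((1.0, ("wb", idx)))
        weights = np.array([w for w, _ in moves])
        if weights.sum() <= 0:
            raise ValueError("no moves configured")
        return [m for _, m in moves], weights / weights.sum()

    # -- target ------------------------------------------------------------

    def current_editing_params(self) -> EditingParams:
        from dataclasses import replace
        tpl = self.config.editing_template
        kwargs = {}
        for key in ("clock_rate", "double_cut_weight",
                    "long_trim_left", "long_trim_right"):
            if key in self.scalars:
                kwargs[key] = self.scalars[key]
        if self.cut_weights is not None:
            kwargs["cut_rates"] = tuple(len(self.cut_weights) * self.cut_weights)
        return replace(tpl, **kwargs)

    def log_prior(self) -> float:
        lp = 0.0
        for name, spec in self._scalar_specs.items():
            lp += spec.prior.logpdf(self.scalars[name])
            if lp == -math.inf:
                return lp
        if self.cut_weights is not None:
            lp += self._dirichlet.logpdf(self.cut_weights)
        return lp

    def log_tree_prior(self) -> float:
        cfg = self.config
        if cfg.tree_prior is None:
            return 0.0
        lp = 0.0
        for tree in self.trees:
            if cfg.tree_prior == "birth-death":
                params = BirthDeathParams(
                    birth_rate=self.scalars["birth_rate"],
                    death_rate=cfg.bd_death_rate,
                    sampling_prob=self.scalars.get("sampling_prob",
                                                   cfg.bd_sampling_prob))
                lp += birth_death_log_density(tree, params, conditioning="origin")
            elif cfg.tree_prior == "coalescent":
                g = self.scalars["growth_rate"]
                origin_age = tree.tip_time - (tree.origin_time
                                              if tree.origin_time is not None
                                              else tree.root.time)
                params = CoalescentExpParams(
                    growth_rate=g, pop_size_at_sampling=math.exp(g * origin_age))
                lp += coalescent_exp_log_density(tree, params)
            else:
                raise ValueError(f"unknown tree prior {cfg.tree_prior!r}")
            if lp == -math.inf:
                return lp
        return lp

    def log_likelihood(self) -> float:
        cfg = self.config
        if cfg.likelihood == "off":
            return 0.0
        params = self.current_editing_params()
        if cfg.likelihood_rate_factor != 1.0:
            from dataclasses import replace
            params = replace(params,
                             clock_rate=params.clock_rate * cfg.likelihood_rate_factor)
        total = 0.0
        for i, like in enumerate(self._likes):
            if cfg.likelihood == "fast":
                total += like.log_likelihood_params(params)
            else:
                like.set_params(params)
                total += like.log_likelihood()
            if total == -math.inf:
                return total
        return total

    def log_posterior(self) -> float:
        lp = self.log_prior()
        if lp == -math.inf:
            return lp
        ltp = self.log_tree_prior()
        if ltp == -math.inf:
            return -math.inf
        ll = self.log_likelihood()
        return lp + ltp + ll

    # -- sampling ----------------------------------------------------------

    def run(self) -> PosteriorTrace:
        cfg = self.config
        rng = self.rng
        moves, move_p = self._moves

        log_prior = self.log_prior()
        log_treeprior = self.log_tree_prior()
        log_like = self.log_likelihood()
        post = log_prior + log_treeprior + log_like
        if not np.isfinite(post):
            bad = [("prior", log_prior), ("tree prior", log_treeprior),
                   ("likelihood", log_like)]
            name = next(n for n, v in bad if not np.isfinite(v))
            raise ValueError(f"non-finite initial posterior: {name} = "
                             f"{dict(bad)[name]}")

        records = []
        tree_samples: list[list[LineageTree]] = [[] for _ in self.trees]
        n_topo_moves = 0

        for it in range(cfg.iterations + 1):
            if it % cfg.thin == 0:
                row = {"iteration": it, "posterior": post, "likelihood": log_like,
                       "prior": log_prior + log_treeprior}
                row.update(self.scalars)
                if self.cut_weights is not None:
                    m = len(self.cut_weights)
                    for k in range(m):
                        row[f"cut_rate_{k + 1}"] = m * self.cut_weights[k]
                records.append(row)
                if cfg.sample_trees:
                    for idx, tree in enumerate(self.trees):
                        tree_samples[idx].append(tree.copy())
            if it == cfg.iterations:
                break

            kind, arg = moves[int(rng.choice(len(moves), p=move_p))]
            log_hr = 0.0
            undo = None
            tree_changed = None

            if kind == "scalar":
                spec = self._scalar_specs[arg]
                old = self.scalars[arg]
                new, log_hr = propose_scale(old, spec.window, rng)
                self.scalars[arg] = new
                def undo(a=arg, o=old):
                    self.scalars[a] = o
            elif kind == "simplex":
                res = _simplex_transfer(self.cut_weights,
                                        cfg.cut_rates.delta, rng)
                if res is None:
                    continue
                old_w = self.cut_weights
                self.cut_weights, log_hr = res
                def undo(o=old_w):
                    self.cut_weights = o
            else:
                tree = self.trees[arg]
                if kind == "slide":
                    res = move_node_slide(tree, rng)
                elif kind == "treescale":
                    res = move_tree_scale(tree, 0.3, rng)
                elif kind == "narrow":
                    res = move_narrow_exchange(tree, rng)
                    n_topo_moves += 1
                else:
                    res = move_wilson_balding(tree, rng)
                    n_topo_moves += 1
                if res is None:
                    continue
                log_hr, undo = res
                tree_changed = arg

            new_prior = self.log_prior()
            if new_prior == -math.inf:
                undo()
                continue
            if tree_changed is not None and cfg.likelihood == "fast":
                self._likes[tree_changed].refresh_branch_lengths()
            new_treeprior = self.log_tree_prior()
            new_like = self.log_likelihood() if new_treeprior > -math.inf else -math.inf
            new_post = new_prior + new_treeprior + new_like
            if new_post > -math.inf and (
                    new_post - post + log_hr >= 0
                    or rng.random() < math.exp(new_post - post + log_hr)):
                post, log_prior, log_treeprior, log_like = (
                    new_post, new_prior, new_treeprior, new_like)
            else:
                undo()
                if tree_changed is not None and cfg.likelihood == "fast":
                    self._likes[tree_changed].refresh_branch_lengths()

        return PosteriorTrace(params=pd.DataFrame.from_records(records),
                              trees=tree_samples if cfg.sample_trees else [])


def run_mcmc(config: RunConfig) -> PosteriorTrace:
    """Run Metropolis-Hastings under the given configuration."""
    return GestaltMCMC(config).run()


# ---------------------------------------------------------------------------
# Diagnostics and summaries
# ---------------------------------------------------------------------------

def effective_sample_size(series) -> float:
    """ESS = n / (1 + 2 sum of autocorrelations), truncated at the first
    non-positive autocorrelation.  A constant series has ESS = n by
    convention."""
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    nfft = int(2 ** math.ceil(math.log2(2 * n)))
    f = np.fft.rfft(x, nfft)
    acov = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real / n
    rho = acov / acov[0]
    s = 0.0
    for k in range(1, n):
        if rho[k] <= 0:
            break
        s += rho[k]
    return float(n / (1 + 2 * s))


def hpd_interval(samples, level: float) -> tuple[float, float]:
    """Narrowest contiguous interval containing ceil(level * n) samples."""
    if not (0 < level < 1):
        raise ValueError("level must be in (0, 1)")
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples")
    m = int(math.ceil(level * n))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m - 1:] - x[: n - m + 1]
    i = int(np.argmin(widths))
    return float(x[i]), float(x[i + m - 1])


@dataclass
class MCCSummary:
    """Maximum clade credibility tree with per-clade posterior support."""

    tree: LineageTree
    supports: dict  # frozenset of tip labels -> posterior frequency

    def annotated_newick(self) -> str:
        sets = self.tree.clade_leafsets()

        def fmt(node) -> str:
            bl = f":{node.branch_length:.12g}"
            if node.is_leaf:
                return f"{node.label}{bl}"
            inner = ",".join(fmt(c) for c in node.children)
            sup = self.supports.get(sets[id(node)], 1.0)
            return f"({inner}){sup:.3f}{bl}"

        inner = ",".join(fmt(c) for c in self.tree.root.children)
        return f"({inner});"


def mcc_tree(tree_samples: list[LineageTree], burn_in: float = 0.0,
             heights: str = "median") -> MCCSummary:
    """Maximum clade credibility summary of a posterior tree sample.

    Picks the sampled tree maximizing the product of posterior clade
    frequencies; node heights are set to the per-clade median age across
    samples containing the clade (``heights="common"`` keeps the selected
    tree's own heights).
    """
    start = int(len(tree_samples) * burn_in)
    trees = tree_samples[start:]
    if not trees:
        raise ValueError("no post-burn-in trees")
    freq: dict = {}
    ages: dict = {}
    for tree in trees:
        tip = tree.tip_time
        sets = tree.clade_leafsets()
        for node in tree.internal_nodes():
            cl = sets[id(node)]
            freq[cl] = freq.get(cl, 0) + 1
            ages.setdefault(cl, []).append(tip - node.time)
    n = len(trees)
    best, best_score = None, -math.inf
    for tree in trees:
        sets = tree.clade_leafsets()
        score = sum(math.log(freq[sets[id(node)]] / n)
                    for node in tree.internal_nodes())
        if score > best_score:
            best, best_score = tree, score
    summary = best.copy()
    tip = summary.tip_time
    sets = summary.clade_leafsets()
    if heights == "median":
        for node in summary.internal_nodes():
            node.time = tip - float(np.median(ages[sets[id(node)]]))
        # enforce parent-older-than-child after independent medians
        for node in summary.preorder():
            if node.parent is not None and not node.is_leaf:
                node.time = max(node.time, node.parent.time)
    supports = {cl: c / n for cl, c in freq.items()}
    return MCCSummary(tree=summary, supports=supports)
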