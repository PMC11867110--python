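"""Phylogenetic likelihood of a GESTALT alignment on a time-scaled tree.

The observed data at each tip is an allele (a set of indels).  The editing
CTMC runs along branches with transition probabilities ``P = expm(Q r t)``;
the clock rate r converts branch lengths to expected indels per target
site.  Two features distinguish this likelihood from textbook pruning:

* **Irreversibility** — targets, once edited, stay edited; ancestral states
  are restricted to alleles compatible with every leaf below.
* **Masking** — an inter-target (double-cut) deletion physically removes
  earlier indels lying strictly inside it.  An ancestral indel may
  therefore be invisible at some or all tips.  Unobserved ("hidden")
  events are integrated out: within a branch through an augmented branch
  state space, and across nodes through hidden-target-span components of
  the node states.

A node state is ``(allele, hidden)`` where ``hidden`` is a set of disjoint
1-based target spans deactivated by events that are never observed and
will be masked by deletions seen below the node.  A branch state is
``(A, H)``: the subset ``A`` of the child's new indels already introduced
and the currently pending hidden spans.  All events incompatible with the
branch endpoint leak to an implicit absorbing sink, so the chain generator
is sub-stochastic and the branch probability is a single matrix-exponential
entry, multiplied by the detail probabilities of the introduced indels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.linalg import expm

from .barcode import Allele, Alignment, BarcodeDesign, Indel, TargetStatus, UNEDITED
from .editing import (
    EditingParams,
    TargetTract,
    detail_log_probability,
    enumerate_tracts,
    tract_hazard,
    tract_of_indel,
    windows_for,
    _trim_logpmf,
    _insert_logpmf,
    _log_null_detail,
)

NEG_INF = -math.inf

Span = tuple[int, int]


class StateSpaceError(RuntimeError):
    """Raised when ancestral-state enumeration exceeds the configured cap."""


@dataclass(frozen=True)
class NodeState:
    """Ancestral state at a node: a candidate allele plus hidden spans."""

    allele: Allele
    hidden: frozenset = frozenset()


def allele_tracts(allele: Allele, design: BarcodeDesign) -> tuple[TargetTract, ...]:
    return tuple(tract_of_indel(ind, design) for ind in allele.indels)


def allele_status(allele: Allele, design: BarcodeDesign,
                  extra_spans: tuple[Span, ...] = ()) -> TargetStatus:
    """Target status implied by an allele's tract spans plus hidden spans."""
    status = TargetStatus.all_active(design.n_targets)
    deact = []
    for tract in allele_tracts(allele, design):
        lo, hi = tract.span
        deact.extend(range(lo, hi + 1))
    for lo, hi in extra_spans:
        deact.extend(range(lo, hi + 1))
    return status.deactivate(deact)


def strictly_inside(inner: Indel, outer: Indel) -> bool:
    """True if ``inner``'s whole footprint is strictly within ``outer``'s deletion."""
    if outer.del_len == 0:
        return False
    if inner.del_len == 0:
        return outer.start < inner.start < outer.end
    return outer.start < inner.start and inner.end < outer.end


def _span_inside(span: Span, targets: frozenset[int]) -> bool:
    lo, hi = span
    return all(k in targets for k in range(lo, hi + 1))


def _spans_overlap(s1: Span, s2: Span) -> bool:
    return s1[0] <= s2[1] and s2[0] <= s1[1]


def p_fit(tract: TargetTract, cover: Indel, design: BarcodeDesign,
          params: EditingParams) -> float:
    """Probability that a hidden event of ``tract`` fits strictly inside
    the deletion of ``cover``.

    Insert length is marginalized fully (inserted bases are deleted along
    with the hidden indel); trim lengths are summed over values whose
    deleted interval fits strictly inside the covering deletion.
    """
    win = windows_for(design)
    c_j = design.cut_positions[tract.j - 1]
    c_jp = design.cut_positions[tract.jp - 1]
    lo_l, pl = _trim_logpmf(win, params, tract.j, "left", tract.long_left)
    lo_r, pr = _trim_logpmf(win, params, tract.jp, "right", tract.long_right)
    total = 0.0
    zero_zero_fits = False
    for li, lp in enumerate(pl):
        left = lo_l + li
        if c_j - left <= cover.start:
            continue
        for ri, rp in enumerate(pr):
            right = lo_r + ri
            if c_jp + right >= cover.end:
                continue
            total += math.exp(lp + rp)
            if left == 0 and right == 0:
                zero_zero_fits = True
    if not tract.is_double and not tract.long_left and not tract.long_right:
        p0 = math.exp(_log_null_detail(win, params, tract.j))
        if zero_zero_fits:
            total -= p0
        total /= 1.0 - p0
    return min(max(total, 0.0), 1.0)


# ---------------------------------------------------------------------------
# Ancestral state sets
# ---------------------------------------------------------------------------

def _leaf_maskable_spans(allele: Allele, design: BarcodeDesign) -> set[Span]:
    """Spans a hidden event could occupy and still be masked at this leaf."""
    spans: set[Span] = set()
    for tract in allele_tracts(allele, design):
        inner = sorted(tract.inner_targets)  # contiguous by construction
        for i, lo in enumerate(inner):
            for hi in inner[i:]:
                spans.add((lo, hi))
    return spans


def _compatible_subsets(universe: list[Indel], max_states: int) -> list[Allele]:
    """All valid alleles formed from subsets of ``universe`` (smallest first)."""
    out: list[Allele] = []
    for size in range(len(universe) + 1):
        for combo in itertools.combinations(universe, size):
            try:
                out.append(Allele(indels=combo))
            except Exception:
                continue
            if len(out) > max_states:
                raise StateSpaceError(
                    f"ancestral candidate count exceeds max_states={max_states}; "
                    "raise the cap to proceed")
    return out


def ancestral_state_sets(tree, alignment: Alignment,
                         max_states: int = 256) -> dict[int, list[NodeState]]:
    """Per-node candidate states (allele + hidden spans), keyed by id(node).

    Candidate indels at a node are those observed in some leaf below it and
    compatible with every leaf below (identically present, or strictly
    inside one of the leaf's deletions).  Hidden spans must be maskable at
    every leaf below.  The root is fixed to the unedited state.
    """
    design = alignment.design
    obs = {cid: allele for cid, allele in alignment.cells}
    states: dict[int, list[NodeState]] = {}
    leafsets: dict[int, list[str]] = {}

    for node in tree.postorder():
        if node.is_leaf:
            if node.label not in obs:
                raise KeyError(f"tip {node.label!r} not in alignment")
            leafsets[id(node)] = [node.label]
            states[id(node)] = [NodeState(allele=obs[node.label])]
            continue
        labels = [lab for c in node.children for lab in leafsets[id(c)]]
        leafsets[id(node)] = labels
        if node is tree.root:
            states[id(node)] = [NodeState(allele=UNEDITED)]
            continue

        leaf_alleles = [obs[lab] for lab in labels]
        universe: list[Indel] = []
        seen = set()
        for la in leaf_alleles:
            for ind in la.indels:
                if ind in seen:
                    continue
                seen.add(ind)
                ok = True
                for other in leaf_alleles:
                    if ind in other.indels:
                        continue
                    if not any(strictly_inside(ind, d) for d in other.indels):
                        ok = False
                        break
                if ok:
                    universe.append(ind)
        universe.sort()
        alleles = _compatible_subsets(universe, max_states)

        mask_sets = [_leaf_maskable_spans(la, design) for la in leaf_alleles]
        common = set.intersection(*mask_sets) if mask_sets else set()
        node_states: list[NodeState] = []
        for allele in alleles:
            tract_spans = [t.span for t in allele_tracts(allele, design)]
            free = sorted(s for s in common
                          if not any(_spans_overlap(s, ts) for ts in tract_spans))
            for k in range(len(free) + 1):
                for spans in itertools.combinations(free, k):
                    if any(_spans_overlap(s1, s2)
                           for s1, s2 in itertools.combinations(spans, 2)):
                        continue
                    node_states.append(NodeState(allele=allele, hidden=frozenset(spans)))
                    if len(node_states) > max_states:
                        raise StateSpaceError(
                            f"node state count exceeds max_states={max_states}; "
                            "raise the cap to proceed")
        node_states.sort(key=lambda st: (st.allele.n_indels, len(st.hidden), repr(st)))
        states[id(node)] = node_states
    return states


# ---------------------------------------------------------------------------
# Branch state space and transition probability
# ---------------------------------------------------------------------------

@dataclass
class BranchChain:
    """Sub-stochastic generator of a branch's augmented editing chain.

    ``edges`` are (from, to, tract, pfit) with rate hazard(tract)*pfit; the
    per-state leak to the implicit sink is the difference between the total
    tract hazard of the state's status and the explicit outgoing rates.
    """

    states: list[tuple[frozenset, frozenset]]
    statuses: list[TargetStatus]
    edges: list[tuple[int, int, TargetTract, float]]
    accept: int
    detail_log: float

    def generator(self, params: EditingParams, design: BarcodeDesign) -> np.ndarray:
        n = len(self.states)
        G = np.zeros((n, n))
        for i, status in enumerate(self.statuses):
            G[i, i] = -sum(tract_hazard(t, params)
                           for t in enumerate_tracts(status, design))
        for frm, to, tract, pfit in self.edges:
            G[frm, to] += tract_hazard(tract, params) * pfit
        return G


def build_branch_chain(a: NodeState, b: NodeState, design: BarcodeDesign,
                       params: EditingParams) -> BranchChain | None:
    """Construct the branch chain from parent state ``a`` to child ``b``.

    Returns None if the endpoint is unreachable (transition probability 0).
    """
    a_ind = set(a.allele.indels)
    b_ind = set(b.allele.indels)
    D = sorted(b_ind - a_ind)
    removed = sorted(a_ind - b_ind)
    surviving = a_ind & b_ind
    tract_of = {ind: tract_of_indel(ind, design) for ind in a_ind | b_ind}

    # masked parent indels must fit strictly inside a new deletion
    for e in removed:
        cover = [d for d in D if strictly_inside(e, d)
                 and _span_set(tract_of[e].span) <= tract_of[d].inner_targets]
        if not cover:
            return None
    # incoming hidden spans must be masked here or persist to the child
    for s in a.hidden:
        if s in b.hidden:
            continue
        if not any(_span_set(s) <= tract_of[d].inner_targets for d in D):
            return None
    # child hidden spans cannot overlap the child's own indel tracts
    for s in b.hidden:
        if any(_spans_overlap(s, tract_of[d].span) for d in b_ind):
            return None

    surviving_spans = [tract_of[f].span for f in surviving]
    a_spans = [tract_of[f].span for f in a_ind]
    detail_log = sum(detail_log_probability(d, tract_of[d], design, params) for d in D)

    init = (frozenset(), frozenset(a.hidden))
    accept = (frozenset(range(len(D))), frozenset(b.hidden))
    index: dict[tuple[frozenset, frozenset], int] = {init: 0}
    states = [init]
    statuses: list[TargetStatus] = []
    edges: list[tuple[int, int, TargetTract, float]] = []
    queue = [init]

    def status_of(state) -> TargetStatus:
        A, H = state
        spans = list(a_spans)
        spans += [tract_of[D[i]].span for i in A]
        spans += list(H)
        deact = [k for lo, hi in spans for k in range(lo, hi + 1)]
        return TargetStatus.all_active(design.n_targets).deactivate(deact)

    while queue:
        state = queue.pop()
        i = index[state]
        while len(statuses) <= i:
            statuses.append(None)  # type: ignore[arg-type]
        status = status_of(state)
        statuses[i] = status
        A, H = state
        available = enumerate_tracts(status, design)
        avail_set = {(t.j0, t.j, t.jp, t.j1) for t in available}

        introduced_spans = [tract_of[D[k]].span for k in A]

        def add_edge(to_state, tract, pfit):
            if to_state not in index:
                index[to_state] = len(states)
                states.append(to_state)
                queue.append(to_state)
            edges.append((i, index[to_state], tract, pfit))

        # observed introductions
        for k, d in enumerate(D):
            if k in A:
                continue
            tt = tract_of[d]
            if (tt.j0, tt.j, tt.jp, tt.j1) not in avail_set:
                continue
            newH = frozenset(s for s in H if not _span_set(s) <= tt.inner_targets)
            add_edge((A | {k}, newH), tt, 1.0)

        # hidden introductions
        pending = [(k, D[k]) for k in range(len(D)) if k not in A]
        for tt in available:
            span = tt.span
            # must not mask a surviving or already-introduced observed indel
            if any(_span_set(fs) <= tt.inner_targets or _spans_overlap(fs, span)
                   for fs in surviving_spans + introduced_spans):
                continue
            cover = next((d for _, d in pending
                          if _span_set(span) <= tract_of[d].inner_targets), None)
            if span in b.hidden:
                pfit = 1.0
            elif cover is not None:
                pfit = p_fit(tt, cover, design, params)
            else:
                continue
            if pfit <= 0.0:
                continue
            newH = frozenset(s for s in H if not _span_set(s) <= tt.inner_targets)
            add_edge((A, newH | {span}), tt, pfit)

    if accept not in index:
        return None
    return BranchChain(states=states, statuses=statuses, edges=edges,
                       accept=index[accept], detail_log=detail_log)


@lru_cache(maxsize=100000)
def _span_set_cached(span: Span) -> frozenset[int]:
    return frozenset(range(span[0], span[1] + 1))


def _span_set(span: Span) -> frozenset[int]:
    return _span_set_cached(span)


def branch_transition_log_probability(a, b, t: float, r: float,
                                      params: EditingParams,
                                      design: BarcodeDesign) -> float:
    """log P of evolving from state ``a`` to state ``b`` along a branch.

    ``a`` and ``b`` may be :class:`NodeState` or plain :class:`Allele`
    (no hidden spans).  The result depends on the branch only through the
    product ``r * t``.  Incompatible endpoints yield ``-inf``.
    """
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if isinstance(a, Allele):
        a = NodeState(allele=a)
    if isinstance(b, Allele):
        b = NodeState(allele=b)
    chain = build_branch_chain(a, b, design, params)
    if chain is None:
        return NEG_INF
    G = chain.generator(params, design)
    P = expm(G * (r * t))
    p = P[0, chain.accept]
    if p <= 0.0:
        return NEG_INF
    return math.log(p) + chain.detail_log


# ---------------------------------------------------------------------------
# Pruning over candidate state sets, with per-node structural caching
# ---------------------------------------------------------------------------

def _logsumexp_pairs(terms: list[float]) -> float:
    mx = max(terms)
    if mx == NEG_INF:
        return NEG_INF
    return mx + math.log(sum(math.exp(x - mx) for x in terms))


class TreeLikelihood:
    """Pruning likelihood with caching of partials for unchanged subtrees.

    Partial results per node are keyed by a structural signature (child
    signatures, branch rate-lengths, parameter version), so repeated
    evaluations after local tree moves only recompute the path from the
    changed region to the root.  Changing parameters invalidates all
    partials.
    """

    def __init__(self, tree, alignment: Alignment, params: EditingParams,
                 max_states: int = 256, use_origin: bool = False):
        self.tree = tree
        self.alignment = alignment
        self.design = alignment.design
        self.max_states = max_states
        self.use_origin = use_origin
        self._params = params
        self._params_version = 0
        self._branch_cache: dict = {}
        self._partial_cache: dict = {}
        self._state_cache: dict = {}

    @property
    def params(self) -> EditingParams:
        return self._params

    def set_params(self, params: EditingParams) -> None:
        if params == self._params:
            return
        self._params = params
        self._params_version += 1
        self._branch_cache.clear()
        self._partial_cache.clear()

    # -- internals ---------------------------------------------------------

    def _node_states(self) -> dict[int, list[NodeState]]:
        key = self.tree.topology_key()
        if key not in self._state_cache:
            self._state_cache[key] = ancestral_state_sets(
                self.tree, self.alignment, max_states=self.max_states)
        return self._state_cache[key]

    def _branch_logP(self, x: NodeState, y: NodeState, rt: float) -> float:
        key = (x, y, rt, self._params_version)
        if key not in self._branch_cache:
            self._branch_cache[key] = branch_transition_log_probability(
                x, y, rt, 1.0, self._params, self.design)
        return self._branch_cache[key]

    def log_likelihood(self) -> float:
        states = self._node_states()
        r = self._params.clock_rate
        partials: dict[int, tuple] = {}
        for node in self.tree.postorder():
            if node.is_leaf:
                sig = ("leaf", node.label, self._params_version)
                partials[id(node)] = (sig, {states[id(node)][0]: 0.0})
                continue
            child_info = []
            for c in node.children:
                sig_c, _ = partials[id(c)]
                rt = r * c.rate_multiplier * (c.time - node.time)
                child_info.append((sig_c, rt, c))
            sig = ("node", tuple((s, rt) for s, rt, _ in child_info))
            cached = self._partial_cache.get(id(node))
            if cached is not None and cached[0] == sig:
                partials[id(node)] = cached
                continue
            table: dict[NodeState, float] = {}
            for x in states[id(node)]:
                total = 0.0
                for sig_c, rt, c in child_info:
                    terms = []
                    child_partial = partials[id(c)][1]
                    for y, ly in child_partial.items():
                        if ly == NEG_INF:
                            continue
                        lp = self._branch_logP(x, y, rt)
                        if lp > NEG_INF:
                            terms.append(lp + ly)
                    total += _logsumexp_pairs(terms) if terms else NEG_INF
                    if total == NEG_INF:
                        break
                table[x] = total
            partials[id(node)] = (sig, table)
            self._partial_cache[id(node)] = partials[id(node)]

        root_table = partials[id(self.tree.root)][1]
        root_state = NodeState(allele=UNEDITED)
        if not self.use_origin or self.tree.origin_time is None:
            return root_table.get(root_state, NEG_INF)
        rt = r * (self.tree.root.time - self.tree.origin_time)
        # a stem branch above the root: the unedited state evolves to the
        # root state (still constrained to unedited candidate here)
        lp = self._branch_logP(root_state, root_state, rt)
        val = root_table.get(root_state, NEG_INF)
        return lp + val


def tree_log_likelihood(tree, alignment: Alignment, params: EditingParams,
                        max_states: int = 256, use_origin: bool = False) -> float:
    """Log-likelihood of an alignment on a time-scaled tree (root unedited)."""
    return TreeLikelihood(tree, alignment, params, max_states=max_states,
                          use_origin=use_origin).log_likelihood()
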