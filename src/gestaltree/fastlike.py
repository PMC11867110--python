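"""Compiled fixed-tree likelihood evaluator.

MCMC over editing parameters with the tree held fixed (the calibration
study, and the fixed-topology pipeline up to node-time moves) evaluates
the same pruning structure millions of times with different rates.  This
module precompiles that structure once — ancestral node states, branch
chains, tract tables — into flat arrays, and evaluates the log-likelihood
in a numba kernel: tract hazards from the current parameters, each branch
transition probability by uniformization of its small sub-stochastic
generator, and the pruning recursion with log-sum-exp.

The evaluator is verified against the pure-Python reference
(:func:`gestaltree.likelihood.tree_log_likelihood`) in the test suite;
detail-law parameters (trim means, insert law) are fixed at construction.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

from .barcode import Alignment
from .editing import EditingParams, enumerate_tracts, tract_hazard
from .likelihood import NEG_INF, ancestral_state_sets, build_branch_chain

_PAIR_IMPOSSIBLE = -1


@njit(cache=True)
def _kernel(lam, omega, g0, g1, clock,
            tract_isd, tract_j, tract_jp, tract_ll, tract_lr,
            status_ptr, status_tract,
            chain_state_ptr, state_status, chain_accept, chain_detail,
            chain_edge_ptr, edge_from, edge_to, edge_tract, edge_pfit,
            pair_chain, pair_t,
            islot_ptr, seg_entry_ptr, entry_pair, entry_childslot,
            islot_slot, n_slots, root_slot,
            leaf_slots):
    # --- tract hazards ---
    nt = tract_isd.shape[0]
    haz = np.empty(nt)
    sl0 = 1.0 / (1.0 + g0)
    sl1 = g0 / (1.0 + g0)
    sr0 = 1.0 / (1.0 + g1)
    sr1 = g1 / (1.0 + g1)
    for i in range(nt):
        if tract_isd[i] == 1:
            base = omega * (lam[tract_j[i]] + lam[tract_jp[i]])
        else:
            base = lam[tract_j[i]]
        base *= sl1 if tract_ll[i] == 1 else sl0
        base *= sr1 if tract_lr[i] == 1 else sr0
        haz[i] = base

    # --- per-status total leaving rates ---
    ns = status_ptr.shape[0] - 1
    srate = np.zeros(ns)
    for s in range(ns):
        acc = 0.0
        for k in range(status_ptr[s], status_ptr[s + 1]):
            acc += haz[status_tract[k]]
        srate[s] = acc

    # --- branch-pair transition log probabilities ---
    npair = pair_chain.shape[0]
    pair_logp = np.empty(npair)
    max_states = 0
    for c in range(chain_state_ptr.shape[0] - 1):
        n = chain_state_ptr[c + 1] - chain_state_ptr[c]
        if n > max_states:
            max_states = n
    v = np.empty(max_states)
    w = np.empty(max_states)
    for p in range(npair):
        cid = pair_chain[p]
        if cid < 0:
            pair_logp[p] = -np.inf
            continue
        tau = pair_t[p] * clock
        s0 = chain_state_ptr[cid]
        n = chain_state_ptr[cid + 1] - s0
        acc_idx = chain_accept[cid]
        if tau <= 0.0:
            pair_logp[p] = (0.0 if acc_idx == 0 else -np.inf) + chain_detail[cid]
            continue
        lam_max = 0.0
        for i in range(n):
            lr = srate[state_status[s0 + i]]
            if lr > lam_max:
                lam_max = lr
        if lam_max <= 0.0:
            pair_logp[p] = (0.0 if acc_idx == 0 else -np.inf) + chain_detail[cid]
            continue
        big = lam_max * 1.0000001
        a = big * tau
        for i in range(n):
            v[i] = 0.0
        v[0] = 1.0
        # Poisson weights via iterative scaling; sum to tail < 1e-14
        logw = -a
        wk = math.exp(logw)
        cum = wk
        prob = wk * v[acc_idx]
        k = 0
        e0 = chain_edge_ptr[cid]
        e1 = chain_edge_ptr[cid + 1]
        while cum < 1.0 - 1e-14 and k < 100000:
            k += 1
            # v <- v T
            for i in range(n):
                w[i] = v[i] * (1.0 - srate[state_status[s0 + i]] / big)
            for e in range(e0, e1):
                w[edge_to[e]] += v[edge_from[e]] * haz[edge_tract[e]] * edge_pfit[e] / big
            for i in range(n):
                v[i] = w[i]
            wk *= a / k
            cum += wk
            prob += wk * v[acc_idx]
        if prob <= 0.0:
            pair_logp[p] = -np.inf
        else:
            pair_logp[p] = math.log(prob) + chain_detail[cid]

    # --- pruning with log-sum-exp ---
    L = np.zeros(n_slots)
    for i in range(leaf_slots.shape[0]):
        L[leaf_slots[i]] = 0.0
    nint = islot_ptr.shape[0] - 1
    for ii in range(nint):
        slot = islot_slot[ii]
        total = 0.0
        for seg in range(islot_ptr[ii], islot_ptr[ii + 1]):
            lo = seg_entry_ptr[seg]
            hi = seg_entry_ptr[seg + 1]
            m = -np.inf
            for e in range(lo, hi):
                val = pair_logp[entry_pair[e]] + L[entry_childslot[e]]
                if val > m:
                    m = val
            if m == -np.inf:
                total = -np.inf
                break
            ssum = 0.0
            for e in range(lo, hi):
                val = pair_logp[entry_pair[e]] + L[entry_childslot[e]]
                ssum += math.exp(val - m)
            total += m + math.log(ssum)
        L[slot] = total
    return L[root_slot]


class FixedTreeLikelihood:
    """Precompiled pruning likelihood for a fixed tree topology.

    Editing rate parameters (clock, cut rates, double-cut weight,
    long-trim factors) vary per evaluation; trim and insert length laws
    are frozen from the template parameters.  Node times may change via
    :meth:`refresh_branch_lengths`.
    """

    def __init__(self, tree, alignment: Alignment, params_template: EditingParams,
                 max_states: int = 256):
        self.tree = tree
        self.alignment = alignment
        self.design = alignment.design
        self.template = params_template
        self._build(max_states)

    # -- template construction --------------------------------------------

    def _build(self, max_states: int) -> None:
        design, params = self.design, self.template
        states = ancestral_state_sets(self.tree, self.alignment, max_states=max_states)

        tract_index: dict = {}
        tracts: list = []

        def tid(tract) -> int:
            key = (tract.j0, tract.j, tract.jp, tract.j1)
            if key not in tract_index:
                tract_index[key] = len(tracts)
                tracts.append(tract)
            return tract_index[key]

        status_index: dict = {}
        status_lists: list[list[int]] = []

        def sid(status) -> int:
            key = status.active
            if key not in status_index:
                status_index[key] = len(status_lists)
                status_lists.append([tid(t) for t in enumerate_tracts(status, design)])
            return status_index[key]

        # chains, deduplicated on (parent state, child state)
        chain_index: dict = {}
        chain_states_ptr = [0]
        state_status: list[int] = []
        chain_accept: list[int] = []
        chain_detail: list[float] = []
        chain_edge_ptr = [0]
        edge_from: list[int] = []
        edge_to: list[int] = []
        edge_tract: list[int] = []
        edge_pfit: list[float] = []

        def chain_id(x, y) -> int:
            key = (x, y)
            if key in chain_index:
                return chain_index[key]
            chain = build_branch_chain(x, y, design, params)
            if chain is None:
                chain_index[key] = _PAIR_IMPOSSIBLE
                return _PAIR_IMPOSSIBLE
            cid = len(chain_accept)
            for status in chain.statuses:
                state_status.append(sid(status))
            chain_states_ptr.append(len(state_status))
            chain_accept.append(chain.accept)
            chain_detail.append(chain.detail_log)
            for frm, to, tract, pfit in chain.edges:
                edge_from.append(frm)
                edge_to.append(to)
                edge_tract.append(tid(tract))
                edge_pfit.append(pfit)
            chain_edge_ptr.append(len(edge_from))
            chain_index[key] = cid
            return cid

        # slots
        slot_of: dict[tuple[int, int], int] = {}
        n_slots = 0
        for node in self.tree.postorder():
            for i, _ in enumerate(states[id(node)]):
                slot_of[(id(node), i)] = n_slots
                n_slots += 1

        pair_index: dict = {}
        pair_chain: list[int] = []
        self._pair_child: list = []

        def pair_id(x, y, child_node) -> int:
            key = (x, y, id(child_node))
            if key in pair_index:
                return pair_index[key]
            pid = len(pair_chain)
            pair_chain.append(chain_id(x, y))
            self._pair_child.append(child_node)
            pair_index[key] = pid
            return pid

        islot_ptr = [0]
        islot_slot: list[int] = []
        seg_entry_ptr = [0]
        entry_pair: list[int] = []
        entry_childslot: list[int] = []
        leaf_slots: list[int] = []

        for node in self.tree.postorder():
            node_states = states[id(node)]
            if node.is_leaf:
                leaf_slots.append(slot_of[(id(node), 0)])
                continue
            for i, x in enumerate(node_states):
                for child in node.children:
                    child_states = states[id(child)]
                    for jdx, y in enumerate(child_states):
                        entry_pair.append(pair_id(x, y, child))
                        entry_childslot.append(slot_of[(id(child), jdx)])
                    seg_entry_ptr.append(len(entry_pair))
                islot_ptr.append(len(seg_entry_ptr) - 1)
                islot_slot.append(slot_of[(id(node), i)])

        root_states = states[id(self.tree.root)]
        assert len(root_states) == 1

        self._arrays = dict(
            tract_isd=np.array([1 if t.is_double else 0 for t in tracts], dtype=np.int8),
            tract_j=np.array([t.j - 1 for t in tracts], dtype=np.int64),
            tract_jp=np.array([t.jp - 1 for t in tracts], dtype=np.int64),
            tract_ll=np.array([1 if t.long_left else 0 for t in tracts], dtype=np.int8),
            tract_lr=np.array([1 if t.long_right else 0 for t in tracts], dtype=np.int8),
            status_ptr=np.cumsum([0] + [len(s) for s in status_lists]).astype(np.int64),
            status_tract=np.array([t for s in status_lists for t in s] or [0],
                                  dtype=np.int64),
            chain_state_ptr=np.array(chain_states_ptr, dtype=np.int64),
            state_status=np.array(state_status or [0], dtype=np.int64),
            chain_accept=np.array(chain_accept or [0], dtype=np.int64),
            chain_detail=np.array(chain_detail or [0.0], dtype=np.float64),
            chain_edge_ptr=np.array(chain_edge_ptr, dtype=np.int64),
            edge_from=np.array(edge_from or [0], dtype=np.int64),
            edge_to=np.array(edge_to or [0], dtype=np.int64),
            edge_tract=np.array(edge_tract or [0], dtype=np.int64),
            edge_pfit=np.array(edge_pfit or [0.0], dtype=np.float64),
            pair_chain=np.array(pair_chain, dtype=np.int64),
            islot_ptr=np.array(islot_ptr, dtype=np.int64),
            seg_entry_ptr=np.array(seg_entry_ptr, dtype=np.int64),
            entry_pair=np.array(entry_pair, dtype=np.int64),
            entry_childslot=np.array(entry_childslot, dtype=np.int64),
            islot_slot=np.array(islot_slot, dtype=np.int64),
            n_slots=n_slots,
            root_slot=slot_of[(id(self.tree.root), 0)],
            leaf_slots=np.array(leaf_slots, dtype=np.int64),
        )
        self.refresh_branch_lengths()

    def refresh_branch_lengths(self) -> None:
        """Re-read branch durations from the tree (after node-time moves)."""
        self._pair_t = np.array(
            [max(c.time - c.parent.time, 0.0) * c.rate_multiplier
             for c in self._pair_child] or [0.0], dtype=np.float64)

    # -- evaluation --------------------------------------------------------

    def log_likelihood(self, clock_rate: float | None = None,
                       cut_rates=None, double_cut_weight: float | None = None,
                       long_trim_left: float | None = None,
                       long_trim_right: float | None = None) -> float:
        t = self.template
        lam = np.asarray(cut_rates if cut_rates is not None else t.cut_rates,
                         dtype=np.float64)
        a = self._arrays
        return float(_kernel(
            lam,
            t.double_cut_weight if double_cut_weight is None else double_cut_weight,
            t.long_trim_left if long_trim_left is None else long_trim_left,
            t.long_trim_right if long_trim_right is None else long_trim_right,
            t.clock_rate if clock_rate is None else clock_rate,
            a["tract_isd"], a["tract_j"], a["tract_jp"], a["tract_ll"], a["tract_lr"],
            a["status_ptr"], a["status_tract"],
            a["chain_state_ptr"], a["state_status"], a["chain_accept"],
            a["chain_detail"],
            a["chain_edge_ptr"], a["edge_from"], a["edge_to"], a["edge_tract"],
            a["edge_pfit"],
            a["pair_chain"], self._pair_t,
            a["islot_ptr"], a["seg_entry_ptr"], a["entry_pair"],
            a["entry_childslot"],
            a["islot_slot"], a["n_slots"], a["root_slot"],
            a["leaf_slots"]))

    def log_likelihood_params(self, params: EditingParams) -> float:
        return self.log_likelihood(
            clock_rate=params.clock_rate, cut_rates=params.cut_rates,
            double_cut_weight=params.double_cut_weight,
            long_trim_left=params.long_trim_left,
            long_trim_right=params.long_trim_right)
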