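"""Brute-force reference likelihood by full state-space enumeration.

For tiny designs (a few targets, tightly bounded trim and insert lengths)
the complete set of reachable alleles is finite and small.  This module
enumerates it, builds the exact allele-level CTMC — every tract times
every admissible detail and insert sequence, with masking applied by
physically removing indels strictly inside a new deletion — and evaluates
the alignment likelihood by summing over all internal-node allele
assignments via the action of the matrix exponential on per-node partial
vectors.

This is the package's independent correctness oracle for the pruned,
lumped-state likelihood: it shares the model definition (hazards, detail
laws, masking rule) but none of the ancestral-state or branch-state-space
machinery.

The state-space *structure* depends on the design and on the detail-law
parameters (trim means, insert law) but not on the rate parameters, so an
:class:`AlleleSpace` can be reused across instances that vary only cut
rates, the double-cut weight, long-trim factors or the clock.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import expm_multiply

from .barcode import Allele, Alignment, BarcodeDesign, UNEDITED
from .editing import (
    EditingParams,
    TargetTract,
    enumerate_details,
    enumerate_tracts,
    indel_for_detail,
    tract_hazard,
)
from .likelihood import NEG_INF, allele_status, strictly_inside

_ALPHABET = "ACGT"


class OracleSizeError(RuntimeError):
    pass


@dataclass
class AlleleSpace:
    """Enumerated allele space with a parametric generator."""

    design: BarcodeDesign
    alleles: list[Allele]
    index: dict[Allele, int]
    tracts: list[TargetTract]
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_tract: np.ndarray
    edge_detail_logp: np.ndarray  # includes the insert-content factor

    def generator(self, params: EditingParams) -> csr_matrix:
        hazards = np.array([tract_hazard(t, params) for t in self.tracts])
        rates = hazards[self.edge_tract] * np.exp(self.edge_detail_logp)
        n = len(self.alleles)
        Q = csr_matrix((rates, (self.edge_src, self.edge_dst)), shape=(n, n))
        out = np.asarray(Q.sum(axis=1)).ravel()
        Q = Q - csr_matrix((out, (np.arange(n), np.arange(n))), shape=(n, n))
        return Q.tocsr()


def _apply_event(allele: Allele, new_indel) -> Allele:
    kept = []
    for ind in allele.indels:
        if strictly_inside(ind, new_indel):
            continue
        if ind.start < new_indel.end and ind.end > new_indel.start:
            raise AssertionError(
                f"partial overlap between {ind} and {new_indel}: "
                "trim windows should make this impossible")
        kept.append(ind)
    return Allele(indels=tuple(kept) + (new_indel,))


def enumerate_allele_space(design: BarcodeDesign, params: EditingParams,
                           max_states: int = 40000) -> AlleleSpace:
    """Breadth-first enumeration of every reachable allele and event edge."""
    index: dict[Allele, int] = {UNEDITED: 0}
    alleles: list[Allele] = [UNEDITED]
    tract_index: dict[TargetTract, int] = {}
    tracts: list[TargetTract] = []
    src, dst, etr, elp = [], [], [], []
    queue = [UNEDITED]
    while queue:
        allele = queue.pop()
        i = index[allele]
        status = allele_status(allele, design)
        for tract in enumerate_tracts(status, design):
            if tract not in tract_index:
                tract_index[tract] = len(tracts)
                tracts.append(tract)
            ti = tract_index[tract]
            for left, right, ins_len, logp in enumerate_details(tract, design, params):
                content_lp = logp + ins_len * math.log(0.25)
                for content in itertools.product(_ALPHABET, repeat=ins_len):
                    new_indel = indel_for_detail(tract, design, left, right,
                                                 "".join(content))
                    target = _apply_event(allele, new_indel)
                    if target not in index:
                        if len(index) >= max_states:
                            raise OracleSizeError(
                                f"allele space exceeds {max_states} states")
                        index[target] = len(alleles)
                        alleles.append(target)
                        queue.append(target)
                    src.append(i)
                    dst.append(index[target])
                    etr.append(ti)
                    elp.append(content_lp)
    return AlleleSpace(design=design, alleles=alleles, index=index, tracts=tracts,
                       edge_src=np.array(src), edge_dst=np.array(dst),
                       edge_tract=np.array(etr), edge_detail_logp=np.array(elp))


def brute_force_log_likelihood(tree, alignment: Alignment, params: EditingParams,
                               design: BarcodeDesign | None = None,
                               max_states: int = 40000,
                               space: AlleleSpace | None = None) -> float:
    """Exact log-likelihood by summing over the full allele space.

    Only feasible for tiny instances (M <= 3 targets, a handful of leaves,
    bounded details); raises :class:`OracleSizeError` beyond the cap.
    """
    design = design or alignment.design
    if space is None:
        space = enumerate_allele_space(design, params, max_states=max_states)
    Q = space.generator(params)
    obs = {cid: allele for cid, allele in alignment.cells}
    n = len(space.alleles)
    r = params.clock_rate

    log_scale: dict[int, float] = {}

    def partial(node) -> np.ndarray:
        if node.is_leaf:
            vec = np.zeros(n)
            allele = obs[node.label]
            if allele not in space.index:
                raise OracleSizeError(f"observed allele of {node.label} outside "
                                      "the enumerated space")
            vec[space.index[allele]] = 1.0
            log_scale[id(node)] = 0.0
            return vec
        vec = np.ones(n)
        scale = 0.0
        for child in node.children:
            lv = partial(child)
            rt = r * child.rate_multiplier * (child.time - node.time)
            if rt > 0:
                down = expm_multiply(Q * rt, lv)
            else:
                down = lv
            down = np.maximum(down, 0.0)
            vec *= down
            scale += log_scale[id(child)]
            mx = vec.max()
            if mx > 0 and (mx < 1e-200 or mx > 1e200):
                vec /= mx
                scale += math.log(mx)
        log_scale[id(node)] = scale
        return vec

    root_vec = partial(tree.root)
    p = root_vec[space.index[UNEDITED]]
    if p <= 0.0:
        return NEG_INF
    return math.log(p) + log_scale[id(tree.root)]
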