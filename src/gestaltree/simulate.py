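"""Forward simulation: birth-death trees and GESTALT alignments along them.

The tree simulator runs a forward Gillespie birth-death process from a
single founder cell, samples each survivor at the end of the experiment
with probability rho, and prunes the tree to the sampled tips.  The
sequence simulator then runs the editing CTMC along every branch using
competing exponentials over the tracts available in the current target
status, so that simulated alignments are draws from exactly the process
the likelihood integrates over (including masking of earlier indels by
spanning deletions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .barcode import Alignment, Allele, BarcodeDesign, UNEDITED
from .editing import (
    EditingParams,
    TargetTract,
    enumerate_tracts,
    indel_for_detail,
    tract_hazard,
    windows_for,
    _trim_logpmf,
    _insert_logpmf,
)
from .likelihood import allele_status, strictly_inside
from .trees import LineageTree, Node

_ALPHABET = np.array(list("ACGT"))


class SimulationError(RuntimeError):
    pass


@dataclass(frozen=True)
class BirthDeathSimConfig:
    """Conditions for tree simulation.

    ``birth_rate`` (divisions per time unit), ``death_rate`` (apoptosis),
    ``sampling_prob`` rho (fraction of surviving cells sequenced),
    ``duration`` T of the experiment, and an accepted tip-count range
    enforced by rejection resampling.
    """

    birth_rate: float
    death_rate: float = 0.0
    sampling_prob: float = 1.0
    duration: float = 1.0
    n_min: int = 2
    n_max: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.birth_rate <= 0 or self.death_rate < 0:
            raise ValueError("need birth_rate > 0 and death_rate >= 0")
        if not (0 < self.sampling_prob <= 1):
            raise ValueError("sampling_prob must be in (0, 1]")
        if self.duration <= 0 or self.n_min > self.n_max or self.n_min < 2:
            raise ValueError("bad duration or tip-count range")


def _prune_to_sampled(root: Node, sampled: set[int]) -> Node | None:
    """Drop unsampled subtrees and suppress unifurcations; None if empty."""

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            return node if id(node) in sampled else None
        kept = [c for c in (rec(c) for c in list(node.children)) if c is not None]
        if not kept:
            return None
        if len(kept) == 1:
            kept[0].parent = None
            return kept[0]
        node.children = kept
        for c in kept:
            c.parent = node
        return node

    return rec(root)


def simulate_birth_death_tree(config: BirthDeathSimConfig,
                              rng: np.random.Generator | None = None) -> LineageTree:
    """Forward Gillespie birth-death simulation with present-day sampling.

    Starts from one lineage at time 0; every extant lineage splits at the
    birth rate and dies at the death rate; at the end of the experiment
    each survivor is kept with probability rho; the tree is pruned to the
    sampled tips.  Rejection-resamples until the tip count falls in the
    configured range (raises after 1000 consecutive rejections).
    """
    rng = rng or np.random.default_rng(config.seed)
    beta, delta, rho, T = (config.birth_rate, config.death_rate,
                           config.sampling_prob, config.duration)
    for attempt in range(1000):
        root = Node(time=0.0)
        extant: list[Node] = [root]
        t = 0.0
        ok = True
        while extant:
            k = len(extant)
            if k > 200_000:  # runaway population guard
                ok = False
                break
            rate = k * (beta + delta)
            t += rng.exponential(1.0 / rate)
            if t >= T:
                break
            node = extant[int(rng.integers(k))]
            node.time = t
            extant.remove(node)
            if rng.random() < beta / (beta + delta):
                extant.extend([node.add_child(Node(time=t)),
                               node.add_child(Node(time=t))])
            # on death the lineage simply ends as an unsampled leaf
        if not ok:
            continue
        sampled: set[int] = set()
        idx = 0
        for node in extant:
            node.time = T
            if rng.random() < rho:
                node.label = f"cell{idx}"
                idx += 1
                sampled.add(id(node))
        if len(sampled) < config.n_min or len(sampled) > config.n_max:
            continue
        pruned = _prune_to_sampled(root, sampled)
        if pruned is None or pruned.is_leaf:
            continue
        pruned.parent = None
        return LineageTree(pruned, origin_time=0.0)
    raise SimulationError(
        "1000 consecutive rejections: tip-count range "
        f"[{config.n_min}, {config.n_max}] is incompatible with "
        f"beta={beta}, delta={delta}, rho={rho}, T={T}")


def simulate_pure_birth_n_tips(n_tips: int, birth_rate: float = 1.0,
                               seed: int | np.random.Generator = 0) -> LineageTree:
    """Pure-birth (Yule) tree stopped when the n-th lineage appears.

    The standard way to simulate a birth-death topology conditioned on its
    tip count; the topology law (ERM) is shared by all constant-rate
    birth-death processes.  A final Exp(n * birth_rate) waiting time is
    appended so terminal branches are non-degenerate.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    root = Node(time=0.0)
    extant = [root]
    t = 0.0
    while len(extant) < n_tips:
        k = len(extant)
        t += rng.exponential(1.0 / (k * birth_rate))
        node = extant.pop(int(rng.integers(k)))
        node.time = t
        extant.extend([node.add_child(Node(time=t)), node.add_child(Node(time=t))])
    t += rng.exponential(1.0 / (n_tips * birth_rate))
    for i, node in enumerate(extant):
        node.time = t
        node.label = f"cell{i}"
    return LineageTree(root, origin_time=0.0)


# ---------------------------------------------------------------------------
# Sequence simulation
# ---------------------------------------------------------------------------

def _draw_trim(rng, windows, params, target: int, side: str, long: bool) -> int:
    lo, logp = _trim_logpmf(windows, params, target, side, long)
    p = np.exp(np.array(logp))
    p /= p.sum()
    return lo + int(rng.choice(len(p), p=p))


def _draw_detail(rng, tract: TargetTract, design: BarcodeDesign,
                 params: EditingParams):
    win = windows_for(design)
    pins = np.exp(np.array(_insert_logpmf(params)))
    pins /= pins.sum()
    plain_single = not tract.is_double and not tract.long_left and not tract.long_right
    while True:
        left = _draw_trim(rng, win, params, tract.j, "left", tract.long_left)
        right = _draw_trim(rng, win, params, tract.jp, "right", tract.long_right)
        ins_len = int(rng.choice(len(pins), p=pins))
        if plain_single and left == 0 and right == 0 and ins_len == 0:
            continue  # the null detail is excluded and renormalized
        insert = "".join(rng.choice(_ALPHABET, size=ins_len)) if ins_len else ""
        return left, right, insert


def _evolve_allele(allele: Allele, duration: float, rate: float,
                   design: BarcodeDesign, params: EditingParams,
                   rng: np.random.Generator) -> Allele:
    """Run the editing chain for ``duration`` at clock ``rate``."""
    t = 0.0
    while True:
        status = allele_status(allele, design)
        tracts = enumerate_tracts(status, design)
        if not tracts:
            return allele
        hazards = np.array([tract_hazard(tr, params) for tr in tracts]) * rate
        total = hazards.sum()
        t += rng.exponential(1.0 / total)
        if t >= duration:
            return allele
        tract = tracts[int(rng.choice(len(tracts), p=hazards / total))]
        left, right, insert = _draw_detail(rng, tract, design, params)
        new_indel = indel_for_detail(tract, design, left, right, insert)
        kept = []
        for ind in allele.indels:
            if strictly_inside(ind, new_indel):
                continue  # masked by the spanning deletion
            if ind.start < new_indel.end and ind.end > new_indel.start:
                raise AssertionError("partial indel overlap in simulation")
            kept.append(ind)
        allele = Allele(indels=tuple(kept) + (new_indel,))


def simulate_alignment(tree: LineageTree, design: BarcodeDesign,
                       params: EditingParams,
                       seed: int | np.random.Generator = 0,
                       include_origin: bool = False) -> Alignment:
    """Simulate a GESTALT alignment along a time-scaled tree.

    Editing starts from the unedited barcode at the root (or at the origin
    when ``include_origin`` and the tree has one), accumulates indels at
    rate ``clock_rate * branch multiplier`` along each branch, and masks
    earlier indels overwritten by spanning deletions.  Deterministic under
    a fixed seed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = params.clock_rate
    states: dict[int, Allele] = {}
    root_allele = UNEDITED
    if include_origin and tree.origin_time is not None:
        root_allele = _evolve_allele(UNEDITED, tree.root.time - tree.origin_time,
                                     r, design, params, rng)
    states[id(tree.root)] = root_allele
    cells = []
    for node in tree.preorder():
        if node is tree.root:
            allele = states[id(node)]
        else:
            allele = _evolve_allele(states[id(node.parent)],
                                    node.time - node.parent.time,
                                    r * node.rate_multiplier, design, params, rng)
            states[id(node)] = allele
        if node.is_leaf:
            allele.validate(design)
            cells.append((node.label, allele))
    return Alignment(design=design, cells=cells)


def summarize_alignment(alignment: Alignment) -> dict:
    """Summary statistics of a GESTALT alignment.

    ``mean_indels_per_site`` is the average fraction of target sites
    occupied by an edit (total edited-target occupancies / (M * n_cells)),
    the quantity tuned to ~0.5 in the low-rate validation regime.
    """
    from .barcode import target_status

    design = alignment.design
    m = design.n_targets
    n = alignment.n_cells
    per_cell = [allele.n_indels for _, allele in alignment.cells]
    edited_counts = np.zeros(m)
    occupied = 0
    for _, allele in alignment.cells:
        status = target_status(allele, design)
        for k, act in enumerate(status.active):
            if not act:
                edited_counts[k] += 1
                occupied += 1
    return {
        "n_cells": n,
        "indels_per_cell": per_cell,
        "mean_indels_per_cell": float(np.mean(per_cell)) if n else 0.0,
        "mean_indels_per_site": occupied / (m * n) if n else 0.0,
        "n_unique_alleles": len({allele for _, allele in alignment.cells}),
        "per_target_edit_frequency": (edited_counts / n).tolist() if n else [0.0] * m,
    }
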