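"""The GESTALT editing process as a continuous-time Markov chain.

Editing events are lumped into *target tracts* ``(j0, j, j', j1)``: Cas9
cuts target ``j`` (and ``j'`` for a double cut, ``j < j'``), repair trims
bases left of ``c(j)`` and right of ``c(j')``, and the trims may be *long*,
reaching into (and thereby deactivating) the adjacent target ``j0 = j-1``
or ``j1 = j'+1``.  Everything between the two cut sites of a double cut is
deleted outright, which is how previously edited inner targets get masked.

A tract determines the set of targets it deactivates and its hazard; the
exact trim lengths and the inserted sequence are the tract's *details*,
drawn from truncated-Poisson length laws with uniform nucleotide content.
Factorizing events as hazard x detail-law is what keeps the state space of
the phylogenetic likelihood finite.

Trim-length support (per design geometry):

* short left at ``j``:  ``0 .. min(c(j)-s_j, c(j)-c(j-1)-1)`` — the
  deletion stays inside the cut target;
* long  left at ``j``:  ``c(j)-e_{j-1}+1 .. c(j)-c(j-1)-1`` — the deletion
  reaches into target ``j-1``'s interval but stops short of its cut site;
* right-hand classes are mirror images.

Long trims are parameterized as window-minimum plus a truncated-Poisson
offset; short trims are truncated Poisson on the absolute length.  For
single cuts the all-zero detail (no trims, no insert) is excluded and the
law renormalized, since it would be an unobservable self-transition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy.linalg import expm

from .barcode import Allele, BarcodeDesign, BarcodeError, Indel, TargetStatus

LOG_QUARTER = math.log(0.25)


@dataclass(frozen=True)
class TrimMeans:
    """Mean trim lengths (bases) for the four trim classes."""

    short_left: float = 3.0
    long_left: float = 3.0
    short_right: float = 3.0
    long_right: float = 3.0


@dataclass(frozen=True)
class EditingParams:
    """Parameters of the editing CTMC.

    clock_rate
        r, indels per target site per time unit; scales branch lengths via
        ``P = expm(Q * r * t)``.
    cut_rates
        lambda_1..lambda_M, relative per-target cut rates.  For inference
        these are constrained to mean 1 so the clock carries the time
        scale; the operations themselves accept any positive values.
    double_cut_weight
        omega, frequency of double-cut events relative to single cuts.
    long_trim_left / long_trim_right
        gamma_0 / gamma_1, odds of a long vs short trim on each side.
    """

    clock_rate: float = 0.02
    cut_rates: tuple[float, ...] = (1.0,)
    double_cut_weight: float = 0.3
    long_trim_left: float = 0.1
    long_trim_right: float = 0.1
    trim_means: TrimMeans = field(default_factory=TrimMeans)
    insert_mean: float = 1.0
    max_insert_len: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "cut_rates", tuple(float(x) for x in self.cut_rates))
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be > 0")
        if any(lam <= 0 for lam in self.cut_rates):
            raise ValueError("cut rates must be > 0")
        if self.double_cut_weight <= 0:
            raise ValueError("double_cut_weight must be > 0")
        if self.long_trim_left < 0 or self.long_trim_right < 0:
            raise ValueError("long-trim factors must be >= 0")
        if self.insert_mean < 0 or self.max_insert_len < 0:
            raise ValueError("insert law parameters must be >= 0")

    @property
    def n_targets(self) -> int:
        return len(self.cut_rates)

    def with_mean_one_cut_rates(self) -> "EditingParams":
        m = np.mean(self.cut_rates)
        return replace(self, cut_rates=tuple(x / m for x in self.cut_rates))

    def to_dict(self) -> dict:
        return {
            "clock_rate": self.clock_rate,
            "cut_rates": list(self.cut_rates),
            "double_cut_weight": self.double_cut_weight,
            "long_trim_left": self.long_trim_left,
            "long_trim_right": self.long_trim_right,
            "trim_means": {
                "short_left": self.trim_means.short_left,
                "long_left": self.trim_means.long_left,
                "short_right": self.trim_means.short_right,
                "long_right": self.trim_means.long_right,
            },
            "insert_mean": self.insert_mean,
            "max_insert_len": self.max_insert_len,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "EditingParams":
        tm = data.get("trim_means", {})
        return cls(
            clock_rate=data["clock_rate"],
            cut_rates=tuple(data["cut_rates"]),
            double_cut_weight=data["double_cut_weight"],
            long_trim_left=data["long_trim_left"],
            long_trim_right=data["long_trim_right"],
            trim_means=TrimMeans(**tm) if tm else TrimMeans(),
            insert_mean=data["insert_mean"],
            max_insert_len=data["max_insert_len"],
        )


@dataclass(frozen=True, order=True)
class TargetTract:
    """Lumped event class (j0, j, j', j1), 1-based target indices.

    ``j..j'`` are the cut targets (equal for a single cut); ``j0 = j-1``
    marks a long left trim deactivating target ``j-1`` (else ``j0 = j``)
    and symmetrically for ``j1``.
    """

    j0: int
    j: int
    jp: int
    j1: int

    def __post_init__(self) -> None:
        if not (self.j0 <= self.j <= self.jp <= self.j1):
            raise ValueError(f"tract indices out of order: {self}")
        if self.j0 not in (self.j - 1, self.j) or self.j1 not in (self.jp, self.jp + 1):
            raise ValueError(f"trim span may extend at most one target: {self}")
        if self.j0 < 1:
            raise ValueError("target indices are 1-based")

    @property
    def is_double(self) -> bool:
        return self.j < self.jp

    @property
    def long_left(self) -> bool:
        return self.j0 < self.j

    @property
    def long_right(self) -> bool:
        return self.j1 > self.jp

    @property
    def span(self) -> tuple[int, int]:
        """Deactivated targets (inclusive 1-based range)."""
        return (self.j0, self.j1)

    @property
    def required_targets(self) -> frozenset[int]:
        """Targets that must be active for this tract to occur."""
        req = {self.j, self.jp}
        if self.long_left:
            req.add(self.j0)
        if self.long_right:
            req.add(self.j1)
        return frozenset(req)

    @property
    def inner_targets(self) -> frozenset[int]:
        """Targets strictly between the two cut targets (maskable)."""
        return frozenset(range(self.j + 1, self.jp))


# ---------------------------------------------------------------------------
# Design geometry: admissible trim windows
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrimWindows:
    """Per-target admissible trim-length windows (inclusive)."""

    short_left: tuple[tuple[int, int], ...]
    long_left: tuple[tuple[int, int] | None, ...]
    short_right: tuple[tuple[int, int], ...]
    long_right: tuple[tuple[int, int] | None, ...]

    def window(self, target: int, side: str, long: bool) -> tuple[int, int] | None:
        arr = getattr(self, ("long_" if long else "short_") + side)
        return arr[target - 1]


def trim_windows(design: BarcodeDesign) -> TrimWindows:
    m = design.n_targets
    cuts = design.cut_positions
    sl, ll, sr, lr = [], [], [], []
    for k in range(m):
        s, e = design.targets[k]
        c = cuts[k]
        smax = c - s
        if k > 0:
            smax = min(smax, c - cuts[k - 1] - 1)
        sl.append((0, max(0, smax)))
        if k > 0:
            lo = c - design.targets[k - 1][1] + 1
            hi = c - cuts[k - 1] - 1
            ll.append((lo, hi) if lo <= hi else None)
        else:
            ll.append(None)
        smax_r = e - c
        if k < m - 1:
            smax_r = min(smax_r, cuts[k + 1] - c - 1)
        sr.append((0, max(0, smax_r)))
        if k < m - 1:
            lo = design.targets[k + 1][0] - c + 1
            hi = cuts[k + 1] - c - 1
            lr.append((lo, hi) if lo <= hi else None)
        else:
            lr.append(None)
    return TrimWindows(short_left=tuple(sl), long_left=tuple(ll),
                       short_right=tuple(sr), long_right=tuple(lr))


@lru_cache(maxsize=None)
def _cached_windows(design_key: tuple) -> TrimWindows:
    seq_len, targets, cuts = design_key
    design = BarcodeDesign(sequence="A" * seq_len, targets=targets, cut_positions=cuts)
    return trim_windows(design)


def windows_for(design: BarcodeDesign) -> TrimWindows:
    return _cached_windows((len(design.sequence), design.targets, design.cut_positions))


# ---------------------------------------------------------------------------
# Truncated-Poisson length laws
# ---------------------------------------------------------------------------

@lru_cache(maxsize=4096)
def truncated_poisson_logpmf(mean: float, lo: int, hi: int) -> tuple[float, ...]:
    """log pmf of Poisson(mean) truncated to {lo..hi}, indexed by k-lo."""
    if hi < lo:
        raise ValueError("empty support")
    ks = np.arange(lo, hi + 1, dtype=float)
    if mean <= 0:
        logp = np.full(ks.shape, -np.inf)
        logp[0] = 0.0
        return tuple(logp)
    with np.errstate(divide="ignore"):
        raw = ks * math.log(mean) - mean - np.array([math.lgamma(k + 1) for k in ks])
    norm = _logsumexp(raw)
    return tuple(raw - norm)


def _logsumexp(x) -> float:
    x = np.asarray(x, dtype=float)
    mx = np.max(x)
    if not np.isfinite(mx):
        return -math.inf
    return float(mx + np.log(np.sum(np.exp(x - mx))))


def _trim_logpmf(windows: TrimWindows, params: EditingParams, target: int,
                 side: str, long: bool) -> tuple[int, tuple[float, ...]]:
    """(window lo, log pmf over the window) for one trim class at a target."""
    win = windows.window(target, side, long)
    if win is None:
        raise ValueError(f"no {'long' if long else 'short'} {side} window at target {target}")
    lo, hi = win
    mean = getattr(params.trim_means, ("long_" if long else "short_") + side)
    if long:
        # offset parameterization: length = lo + TruncPois(mean) on {0..hi-lo}
        return lo, truncated_poisson_logpmf(mean, 0, hi - lo)
    return lo, truncated_poisson_logpmf(mean, lo, hi)


def _insert_logpmf(params: EditingParams) -> tuple[float, ...]:
    return truncated_poisson_logpmf(params.insert_mean, 0, params.max_insert_len)


def _log_null_detail(windows: TrimWindows, params: EditingParams, j: int) -> float:
    """log probability of the unobservable (no trim, no insert) detail."""
    lo_l, pl = _trim_logpmf(windows, params, j, "left", False)
    lo_r, pr = _trim_logpmf(windows, params, j, "right", False)
    return pl[0 - lo_l] + pr[0 - lo_r] + _insert_logpmf(params)[0]


# ---------------------------------------------------------------------------
# Tract enumeration and hazards
# ---------------------------------------------------------------------------

def enumerate_tracts(status: TargetStatus, design: BarcodeDesign) -> list[TargetTract]:
    """All tracts introducible given a target status.

    The cut targets (and, for long trims, the adjacent trim target) must be
    active and the trim window non-empty; inner targets of a double cut are
    unrestricted — cutting across an edited inner target is precisely the
    masking event.
    """
    m = design.n_targets
    win = windows_for(design)
    active = status.active
    tracts: list[TargetTract] = []

    def left_opts(j: int) -> list[int]:
        opts = [j]
        if j > 1 and active[j - 2] and win.long_left[j - 1] is not None:
            opts.append(j - 1)
        return opts

    def right_opts(jp: int) -> list[int]:
        opts = [jp]
        if jp < m and active[jp] and win.long_right[jp - 1] is not None:
            opts.append(jp + 1)
        return opts

    for j in range(1, m + 1):
        if not active[j - 1]:
            continue
        for j0 in left_opts(j):
            for j1 in right_opts(j):
                tracts.append(TargetTract(j0, j, j, j1))
        for jp in range(j + 1, m + 1):
            if not active[jp - 1]:
                continue
            for j0 in left_opts(j):
                for j1 in right_opts(jp):
                    tracts.append(TargetTract(j0, j, jp, j1))
    return tracts


def tract_hazard(tract: TargetTract, params: EditingParams) -> float:
    """Instantaneous rate of a tract (trim-class probability folded in)."""
    lam = params.cut_rates
    if tract.is_double:
        base = params.double_cut_weight * (lam[tract.j - 1] + lam[tract.jp - 1])
    else:
        base = lam[tract.j - 1]
    g0, g1 = params.long_trim_left, params.long_trim_right
    base *= g0 / (1 + g0) if tract.long_left else 1 / (1 + g0)
    base *= g1 / (1 + g1) if tract.long_right else 1 / (1 + g1)
    return base


def total_status_hazard(status: TargetStatus, design: BarcodeDesign,
                        params: EditingParams) -> float:
    return sum(tract_hazard(t, params) for t in enumerate_tracts(status, design))


def tract_of_indel(indel: Indel, design: BarcodeDesign) -> TargetTract:
    """The tract implied by an observed indel (deterministic)."""
    cuts = design.cut_positions
    m = design.n_targets
    if indel.del_len == 0:
        k = design.target_of_bond(indel.start) or (
            indel.start in cuts and cuts.index(indel.start) + 1)
        if not k:
            raise BarcodeError(f"insertion bond {indel.start} in no target")
        return TargetTract(k, k, k, k)
    covered = [k for k in range(1, m + 1) if indel.start <= cuts[k - 1] <= indel.end]
    if not covered:
        raise BarcodeError(f"indel {indel} covers no cut site")
    j, jp = covered[0], covered[-1]
    j0 = j - 1 if (j > 1 and indel.start < design.targets[j - 2][1]) else j
    j1 = jp + 1 if (jp < m and indel.end > design.targets[jp][0]) else jp
    return TargetTract(j0, j, jp, j1)


def indel_for_detail(tract: TargetTract, design: BarcodeDesign,
                     left: int, right: int, insert: str) -> Indel:
    """Materialize a concrete indel from a tract and its details."""
    c_j = design.cut_positions[tract.j - 1]
    c_jp = design.cut_positions[tract.jp - 1]
    start = c_j - left
    del_len = (c_jp + right) - start
    return Indel(start=start, del_len=del_len, insert=insert,
                 min_target=tract.j, max_target=tract.jp)


def detail_log_probability(indel: Indel, tract: TargetTract,
                           design: BarcodeDesign, params: EditingParams) -> float:
    """log P(trim lengths, insert | tract) for an observed indel.

    Sums to 1 over all details admissible for the tract; insert content is
    uniform over nucleotides, hence the (1/4)^len factor.
    """
    if tract_of_indel(indel, design) != tract:
        raise ValueError(f"indel {indel} does not realize tract {tract}")
    win = windows_for(design)
    c_j = design.cut_positions[tract.j - 1]
    c_jp = design.cut_positions[tract.jp - 1]
    left = c_j - indel.start
    right = indel.end - c_jp if indel.del_len > 0 else 0
    ins_len = len(indel.insert)
    if ins_len > params.max_insert_len:
        return -math.inf

    lo_l, pl = _trim_logpmf(win, params, tract.j, "left", tract.long_left)
    lo_r, pr = _trim_logpmf(win, params, tract.jp, "right", tract.long_right)
    if not (0 <= left - lo_l < len(pl)) or not (0 <= right - lo_r < len(pr)):
        return -math.inf
    logp = pl[left - lo_l] + pr[right - lo_r]
    logp += _insert_logpmf(params)[ins_len] + ins_len * LOG_QUARTER
    if not tract.is_double and not tract.long_left and not tract.long_right:
        log_p0 = _log_null_detail(win, params, tract.j)
        logp -= math.log1p(-math.exp(log_p0))
    return logp


def enumerate_details(tract: TargetTract, design: BarcodeDesign, params: EditingParams,
                      max_insert_len: int | None = None) -> Iterator[tuple[int, int, int, float]]:
    """Yield (left, right, insert_len, log prob) over a tract's support.

    The insert-content factor is *not* included: the yielded log prob is
    the total probability of all ``4**insert_len`` sequences of that
    length.  Used by the oracle, the simulator and normalization checks.
    """
    win = windows_for(design)
    cap = params.max_insert_len if max_insert_len is None else min(
        max_insert_len, params.max_insert_len)
    lo_l, pl = _trim_logpmf(win, params, tract.j, "left", tract.long_left)
    lo_r, pr = _trim_logpmf(win, params, tract.jp, "right", tract.long_right)
    pins = _insert_logpmf(params)
    plain_single = not tract.is_double and not tract.long_left and not tract.long_right
    log_norm = 0.0
    if plain_single:
        log_norm = math.log1p(-math.exp(_log_null_detail(win, params, tract.j)))
    for li, lp in enumerate(pl):
        for ri, rp in enumerate(pr):
            for ins in range(cap + 1):
                left, right = lo_l + li, lo_r + ri
                if plain_single and left == 0 and right == 0 and ins == 0:
                    continue
                yield left, right, ins, lp + rp + pins[ins] - log_norm


# ---------------------------------------------------------------------------
# Lumped rate matrices over target statuses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateMatrix:
    """A finite lumped CTMC: ordered states and generator Q (rows sum to 0)."""

    states: tuple
    Q: np.ndarray

    def __post_init__(self) -> None:
        q = np.asarray(self.Q, dtype=float)
        if q.shape[0] != q.shape[1] or q.shape[0] != len(self.states):
            raise ValueError("Q shape does not match states")
        off = q - np.diag(np.diag(q))
        if np.any(off < -1e-12):
            raise ValueError("negative off-diagonal rate")
        if np.max(np.abs(q.sum(axis=1))) > 1e-9:
            raise ValueError("rows of Q must sum to 0")
        object.__setattr__(self, "Q", q)

    def index(self, state) -> int:
        return self.states.index(state)


def build_status_rate_matrix(design: BarcodeDesign, params: EditingParams) -> RateMatrix:
    """Generator of the target-status chain (states: 2^M active-sets).

    States are ordered by number of edited targets, then lexicographically,
    so the matrix is upper triangular — a structural statement of the
    irreversibility of editing.
    """
    m = design.n_targets
    masks = sorted(range(1 << m), key=lambda x: (bin(x).count("1"), x))
    statuses = [TargetStatus(tuple(not (mask >> k) & 1 for k in range(m))) for mask in masks]
    idx = {mask: i for i, mask in enumerate(masks)}
    n = len(masks)
    q = np.zeros((n, n))
    for i, (mask, status) in enumerate(zip(masks, statuses)):
        for tract in enumerate_tracts(status, design):
            lo, hi = tract.span
            new_mask = mask
            for k in range(lo, hi + 1):
                new_mask |= 1 << (k - 1)
            h = tract_hazard(tract, params)
            q[i, idx[new_mask]] += h
            q[i, i] -= h
    return RateMatrix(states=tuple(statuses), Q=q)


def transition_probability_matrix(rate_matrix: RateMatrix, r: float, t: float) -> np.ndarray:
    """P = expm(Q * r * t): clock-scaled transition probabilities."""
    if t < 0:
        raise ValueError("t must be >= 0")
    if r <= 0:
        raise ValueError("clock rate must be > 0")
    return expm(rate_matrix.Q * (r * t))
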