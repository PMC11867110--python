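"""Barcode designs, indels, alleles and alignment I/O.

A GESTALT barcode is a synthetic DNA construct containing an ordered array
of M CRISPR/Cas9 target sites.  Cas9 cuts at a fixed inter-base bond inside
each target; error-prone repair leaves an insertion and/or deletion (an
*indel*) behind.  Editing a target is irreversible — once its sequence is
disrupted, the guide RNA no longer binds.  A cell's *allele* is the set of
indels its barcode carries, and an *alignment* is a collection of alleles
for sequenced cells.

Coordinate conventions
----------------------
All coordinates are 0-based.  Target intervals are half-open ``[s_k, e_k)``
over barcode positions; cut sites ``c(k)`` are inter-base bond indices with
``s_k <= c(k) < e_k``.  Target indices are 1-based in the public types and
in the on-disk dialects, matching the usual 1..M numbering of GESTALT
target sites.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence


class BarcodeError(ValueError):
    """Raised for invalid designs, indels or alleles."""


class AlleleTableParseError(BarcodeError):
    """Raised when an allele-table file cannot be parsed."""


_DNA = set("ACGT")


@dataclass(frozen=True)
class BarcodeDesign:
    """The unedited barcode: sequence, target intervals and cut sites.

    Parameters
    ----------
    sequence
        Unedited barcode sequence over {A, C, G, T}.
    targets
        Ordered, non-overlapping, strictly increasing half-open intervals
        ``[s_k, e_k)``, one per target site.
    cut_positions
        Bond index ``c(k)`` of the Cas9 double-strand cut inside each
        target, strictly increasing, with ``s_k <= c(k) < e_k``.
    """

    sequence: str
    targets: tuple[tuple[int, int], ...]
    cut_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "targets", tuple(tuple(t) for t in self.targets))
        object.__setattr__(self, "cut_positions", tuple(self.cut_positions))
        if not self.sequence or set(self.sequence) - _DNA:
            raise BarcodeError("sequence must be a non-empty DNA string over ACGT")
        m = len(self.targets)
        if m < 1:
            raise BarcodeError("design needs at least one target")
        if len(self.cut_positions) != m:
            raise BarcodeError("one cut position per target required")
        prev_end = 0
        for k, ((s, e), c) in enumerate(zip(self.targets, self.cut_positions), 1):
            if not (0 <= s < e <= len(self.sequence)):
                raise BarcodeError(f"target {k} interval [{s},{e}) outside barcode")
            if s < prev_end:
                raise BarcodeError(f"target {k} overlaps or is out of order")
            if not (s <= c < e):
                raise BarcodeError(f"cut position {c} outside target {k} interval")
            prev_end = e
        if list(self.cut_positions) != sorted(self.cut_positions):
            raise BarcodeError("cut positions must be strictly increasing")

    @property
    def n_targets(self) -> int:
        return len(self.targets)

    def target_of_bond(self, bond: int) -> int:
        """1-based target whose interval contains ``bond`` as a position, or 0."""
        for k, (s, e) in enumerate(self.targets, 1):
            if s <= bond < e:
                return k
        return 0

    def to_json(self) -> str:
        return json.dumps(
            {
                "sequence": self.sequence,
                "targets": [list(t) for t in self.targets],
                "cut_positions": list(self.cut_positions),
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "BarcodeDesign":
        """Load a design from JSON.

        ``cut_positions`` may be given as absolute bond indices, or the key
        ``cut_offsets_3prime`` may give each cut site's offset from the 3'
        end of its target (the convention used in GESTALT metadata);
        offsets are converted to absolute bonds ``c(k) = e_k - offset``.
        """
        data = json.loads(text)
        targets = [tuple(t) for t in data["targets"]]
        if "cut_positions" in data:
            cuts = list(data["cut_positions"])
        elif "cut_offsets_3prime" in data:
            cuts = [e - off for (s, e), off in zip(targets, data["cut_offsets_3prime"])]
        else:
            raise BarcodeError("design JSON needs cut_positions or cut_offsets_3prime")
        return cls(sequence=data["sequence"], targets=tuple(targets), cut_positions=tuple(cuts))


def v7_like_design(n_targets: int = 10, target_len: int = 23, cut_offset_3prime: int = 6,
                   seed: int = 0) -> BarcodeDesign:
    """A contiguous array design in the style of the V7 GESTALT barcode.

    V7 consists of 10 target sites of 23 bp each; Cas9 cuts 3 bp upstream
    of the PAM, i.e. 6 bp from the 3' end of each 23-bp unit.  The filler
    sequence is an arbitrary deterministic DNA string (the model only uses
    lengths and cut positions, never sequence content of the reference).
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    seq = "".join(rng.choice(list("ACGT"), size=n_targets * target_len))
    targets = tuple((i * target_len, (i + 1) * target_len) for i in range(n_targets))
    cuts = tuple(e - cut_offset_3prime for (_, e) in targets)
    return BarcodeDesign(sequence=seq, targets=targets, cut_positions=cuts)


@dataclass(frozen=True, order=True)
class Indel:
    """One observed editing event.

    ``start`` is the 0-based coordinate of the first deleted base (for a
    pure insertion, the bond at which the insert sits), ``del_len >= 0``
    the number of deleted bases, ``insert`` the inserted sequence, and
    ``min_target``/``max_target`` the 1-based extreme targets whose cut
    sites lie inside the event.
    """

    start: int
    del_len: int
    insert: str
    min_target: int
    max_target: int

    def __post_init__(self) -> None:
        if self.del_len < 0:
            raise BarcodeError("negative deletion length")
        if self.del_len == 0 and not self.insert:
            raise BarcodeError("indel must delete or insert something")
        if set(self.insert) - _DNA:
            raise BarcodeError("insert must be a DNA string")
        if self.min_target > self.max_target or self.min_target < 1:
            raise BarcodeError("bad target span")

    @property
    def end(self) -> int:
        """One past the last deleted base (equals ``start`` for insertions)."""
        return self.start + self.del_len

    def touches_bond(self, bond: int) -> bool:
        """True if the event destroys or occupies inter-base bond ``bond``."""
        return self.start <= bond <= self.end

    def validate(self, design: BarcodeDesign) -> None:
        if self.start < 0 or self.end > len(design.sequence):
            raise BarcodeError(f"indel {self} outside barcode bounds")
        if self.max_target > design.n_targets:
            raise BarcodeError(f"indel {self} names target beyond design")
        for k in (self.min_target, self.max_target):
            if not self.touches_bond(design.cut_positions[k - 1]):
                raise BarcodeError(f"indel {self} does not reach cut site of target {k}")


@dataclass(frozen=True)
class Allele:
    """A cell's barcode state: sorted, non-overlapping indels."""

    indels: tuple[Indel, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "indels", tuple(sorted(self.indels)))
        prev: Indel | None = None
        for ind in self.indels:
            if prev is not None:
                if ind.start < prev.end or (ind.start == prev.end and
                                            (prev.del_len == 0 or ind.del_len == 0)):
                    raise BarcodeError(f"overlapping indels {prev} and {ind}")
                if ind.min_target <= prev.max_target:
                    raise BarcodeError("two indels claim the same target")
            prev = ind

    @property
    def n_indels(self) -> int:
        return len(self.indels)

    def validate(self, design: BarcodeDesign) -> None:
        for ind in self.indels:
            ind.validate(design)


UNEDITED = Allele()


@dataclass(frozen=True)
class TargetStatus:
    """Which targets are still editable (True = active)."""

    active: tuple[bool, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "active", tuple(bool(a) for a in self.active))

    @property
    def n_active(self) -> int:
        return sum(self.active)

    @classmethod
    def all_active(cls, m: int) -> "TargetStatus":
        return cls(active=(True,) * m)

    def deactivate(self, targets: Iterable[int]) -> "TargetStatus":
        """Return a copy with the given 1-based targets switched off."""
        act = list(self.active)
        for k in targets:
            act[k - 1] = False
        return TargetStatus(active=tuple(act))


@dataclass
class Alignment:
    """An alignment: a barcode design plus one allele per cell."""

    design: BarcodeDesign
    cells: list[tuple[str, Allele]] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [cid for cid, _ in self.cells]
        if len(set(ids)) != len(ids):
            raise BarcodeError("duplicate cell ids")
        for cid, allele in self.cells:
            try:
                allele.validate(self.design)
            except BarcodeError as exc:
                raise BarcodeError(f"cell {cid!r}: {exc}") from exc

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def allele(self, cell_id: str) -> Allele:
        for cid, a in self.cells:
            if cid == cell_id:
                return a
        raise KeyError(cell_id)


def target_status(allele: Allele, design: BarcodeDesign) -> TargetStatus:
    """Active/inactive state of every target given an allele.

    A target is inactive once any indel's deleted interval intersects its
    interval, any deletion destroys its cut-site bond, or a pure insertion
    sits at a bond strictly inside it.
    """
    active = [True] * design.n_targets
    for ind in allele.indels:
        for k, ((s, e), c) in enumerate(zip(design.targets, design.cut_positions), 1):
            if ind.del_len > 0:
                if ind.start < e and ind.end > s:
                    active[k - 1] = False
                elif ind.touches_bond(c):
                    active[k - 1] = False
            else:
                if s < ind.start < e or ind.start == c:
                    active[k - 1] = False
    return TargetStatus(active=tuple(active))


def _merge_group(group: list[Indel], design: BarcodeDesign) -> Indel:
    start = min(i.start for i in group)
    end = max(i.end for i in group)
    insert = "".join(i.insert for i in sorted(group, key=lambda i: i.start))
    del_len = end - start
    cuts = [k for k, c in enumerate(design.cut_positions, 1) if start <= c <= end]
    if not cuts:
        raise BarcodeError("merged indel covers no cut site")
    return Indel(start=start, del_len=del_len, insert=insert,
                 min_target=min(cuts), max_target=max(cuts))


def normalize_allele(raw_indels: Sequence[Indel], design: BarcodeDesign) -> Allele:
    """Merge raw indels that overlap or edit the same target into one event.

    Indels whose deleted intervals overlap, or whose intervals touch the
    same target's interval, are replaced by a single spanning indel: the
    deleted interval is the union hull and insert sequences are
    concatenated in genomic order.  The operation is idempotent.
    """
    for ind in raw_indels:
        ind.validate(design)
    if not raw_indels:
        return UNEDITED

    def targets_touched(ind: Indel) -> set[int]:
        touched = set(range(ind.min_target, ind.max_target + 1))
        for k, (s, e) in enumerate(design.targets, 1):
            if ind.del_len > 0 and ind.start < e and ind.end > s:
                touched.add(k)
            elif ind.del_len == 0 and s < ind.start < e:
                touched.add(k)
        return touched

    items = sorted(raw_indels, key=lambda i: (i.start, i.end))
    groups: list[list[Indel]] = []
    group_targets: list[set[int]] = []
    for ind in items:
        tt = targets_touched(ind)
        merged = False
        for g, gt in zip(groups, group_targets):
            overlap = any(ind.start < other.end and ind.end > other.start for other in g)
            if overlap or (tt & gt):
                g.append(ind)
                gt |= tt
                merged = True
                break
        if merged:
            # a late merge may bridge two earlier groups; re-consolidate
            changed = True
            while changed:
                changed = False
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        if group_targets[a] & group_targets[b] or any(
                            x.start < y.end and x.end > y.start
                            for x in groups[a] for y in groups[b]
                        ):
                            groups[a].extend(groups[b])
                            group_targets[a] |= group_targets[b]
                            del groups[b], group_targets[b]
                            changed = True
                            break
                    if changed:
                        break
        else:
            groups.append([ind])
            group_targets.append(tt)

    merged_indels = []
    for g in groups:
        merged_indels.append(g[0] if len(g) == 1 else _merge_group(g, design))
    allele = Allele(indels=tuple(merged_indels))
    allele.validate(design)
    return allele


def apply_allele(design: BarcodeDesign, allele: Allele) -> str:
    """Reconstruct the edited DNA sequence for display / round-trip checks."""
    seq = design.sequence
    out = []
    pos = 0
    for ind in allele.indels:
        out.append(seq[pos:ind.start])
        out.append(ind.insert)
        pos = ind.end
    out.append(seq[pos:])
    return "".join(out)


# ---------------------------------------------------------------------------
# Allele-table dialect: UTF-8 TSV, header "cell_id\tindels"; the indels
# column is a comma-separated list of start:del_len:insert:min_target:max_target
# tokens, with the empty string denoting an unedited barcode.
# ---------------------------------------------------------------------------

def _format_indel(ind: Indel) -> str:
    return f"{ind.start}:{ind.del_len}:{ind.insert}:{ind.min_target}:{ind.max_target}"


def _parse_indel_token(token: str, lineno: int) -> Indel:
    parts = token.split(":")
    if len(parts) != 5:
        raise AlleleTableParseError(f"line {lineno}: malformed indel token {token!r}")
    try:
        start, del_len = int(parts[0]), int(parts[1])
        min_t, max_t = int(parts[3]), int(parts[4])
    except ValueError as exc:
        raise AlleleTableParseError(f"line {lineno}: non-integer field in {token!r}") from exc
    try:
        return Indel(start=start, del_len=del_len, insert=parts[2],
                     min_target=min_t, max_target=max_t)
    except BarcodeError as exc:
        raise AlleleTableParseError(f"line {lineno}: {exc}") from exc


def parse_allele_table(text: str, design: BarcodeDesign) -> Alignment:
    """Parse the TSV allele-table dialect into a validated Alignment.

    Each cell's raw indels are passed through :func:`normalize_allele`, so
    files with mergeable (overlapping / same-target) events load cleanly.
    """
    lines = text.splitlines()
    if not lines or lines[0].split("\t")[:2] != ["cell_id", "indels"]:
        raise AlleleTableParseError("line 1: expected header 'cell_id\\tindels'")
    cells: list[tuple[str, Allele]] = []
    for lineno, line in enumerate(lines[1:], 2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 1 or not fields[0]:
            raise AlleleTableParseError(f"line {lineno}: missing cell_id")
        cid = fields[0]
        token_field = fields[1] if len(fields) > 1 else ""
        raw = [_parse_indel_token(tok, lineno)
               for tok in token_field.split(",") if tok != ""]
        try:
            allele = normalize_allele(raw, design)
        except BarcodeError as exc:
            raise BarcodeError(f"cell {cid!r}: {exc}") from exc
        cells.append((cid, allele))
    return Alignment(design=design, cells=cells)


def write_allele_table(alignment: Alignment) -> str:
    rows = ["cell_id\tindels"]
    for cid, allele in alignment.cells:
        rows.append(f"{cid}\t" + ",".join(_format_indel(i) for i in allele.indels))
    return "\n".join(rows) + "\n"
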