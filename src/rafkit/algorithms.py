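"""Set-theoretic core: closure, RAF/CAF detection and decomposition.

A subset R' of the reactions of a CRS is a *RAF* (reflexively autocatalytic
and food-generated) set when, with W the closure of the food set F under R',

* (RA) every reaction in R' has at least one catalyst in W, and
* (F)  every reaction in R' has all of its reactants in W.

The *maximal* RAF of a CRS is unique (the union of all RAF subsets) and is
found by the classical polynomial-time reduction: repeatedly strip reactions
violating RA or F relative to the closure of the survivors.  A *CAF* adds a
constructibility requirement — a reaction may only ever fire with its
catalyst already present — and is computed by forward construction from F.
Irreducible RAFs (irrRAFs) are found by seeded greedy deletion from the
maximal RAF; sub-RAF enumeration and inhibition handling are exact,
exhaustive, and deliberately limited to small reaction sets.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .crs import CRS
from .errors import (NoRafError, PreconditionError, SizeLimitError,
                     UnknownIdError)

_EMPTY: frozenset = frozenset()


class _Structure:
    """Catalysis-independent adjacency index of a reaction network.

    Shared between CRSs that differ only in their catalysis draw (the random
    polymer generator reuses one structure across thousands of replicates).
    """

    __slots__ = ("reactants", "products", "consumers")

    def __init__(self, reactions):
        self.reactants = {rid: frozenset(r.reactants)
                          for rid, r in reactions.items()}
        self.products = {rid: tuple(dict.fromkeys(r.products))
                         for rid, r in reactions.items()}
        consumers: dict[str, list[str]] = defaultdict(list)
        for rid, rs in self.reactants.items():
            for mid in rs:
                consumers[mid].append(rid)
        self.consumers = dict(consumers)


class _Index:
    __slots__ = ("structure", "catalysts", "inhibitors")

    def __init__(self, crs: CRS):
        self.structure = getattr(crs, "_raf_structure", None) \
            or _Structure(crs.reactions)
        catalysts: dict[str, set[str]] = defaultdict(set)
        for mid, rid in crs.catalysis:
            catalysts[rid].add(mid)
        self.catalysts = dict(catalysts)
        inhibitors: dict[str, set[str]] = defaultdict(set)
        for mid, rid in crs.inhibition:
            inhibitors[rid].add(mid)
        self.inhibitors = dict(inhibitors)


def _idx(crs: CRS) -> _Index:
    idx = crs.__dict__.get("_raf_idx")
    if idx is None:
        idx = crs.__dict__["_raf_idx"] = _Index(crs)
    return idx


def _check_ids(crs: CRS, reactions=None, molecules=None):
    if reactions is not None:
        bad = set(reactions) - crs.reactions.keys()
        if bad:
            raise UnknownIdError(f"unknown reaction ids: {sorted(bad)}")
    if molecules is not None:
        bad = set(molecules) - crs.molecules.keys()
        if bad:
            raise UnknownIdError(f"unknown molecule ids: {sorted(bad)}")


def closure(crs: CRS, reactions: Optional[Iterable[str]] = None,
            start: Optional[Iterable[str]] = None) -> frozenset[str]:
    """Least fixed point of molecule production: cl_{R'}(X').

    All molecules reachable from ``start`` (default: the food set) by firing
    reactions from ``reactions`` (default: all of R) whose reactants are
    already entirely available.  Catalysis plays no role in closures.
    """
    if reactions is None:
        rset = set(crs.reactions)
    else:
        rset = set(reactions)
        _check_ids(crs, reactions=rset)
    if start is None:
        start = crs.food
    else:
        start = set(start)
        _check_ids(crs, molecules=start)
    st = _idx(crs).structure
    W = set(start)
    need: dict[str, int] = {}
    stack: list[str] = []
    for rid in rset:
        missing = len(st.reactants[rid] - W)
        need[rid] = missing
        if missing == 0:
            stack.append(rid)
    fired: set[str] = set()
    while stack:
        rid = stack.pop()
        if rid in fired:
            continue
        fired.add(rid)
        for mid in st.products[rid]:
            if mid not in W:
                W.add(mid)
                for r2 in st.consumers.get(mid, ()):
                    if r2 in need and r2 not in fired:
                        need[r2] -= 1
                        if need[r2] == 0:
                            stack.append(r2)
    return frozenset(W)


@dataclass(frozen=True)
class RafCheck:
    """Verdict of a RAF membership test, truthy iff the subset is a RAF.

    ``failures`` maps each offending reaction id to a description of the
    violated condition; ``support`` is the closure of the food set under the
    tested subset.
    """

    ok: bool
    failures: dict[str, str]
    support: frozenset[str]

    def __bool__(self) -> bool:
        return self.ok


def _raf_check(crs: CRS, subset, food) -> RafCheck:
    sub = set(subset)
    _check_ids(crs, reactions=sub)
    idx = _idx(crs)
    W = closure(crs, sub, food)
    failures: dict[str, str] = {}
    for rid in sorted(sub):
        missing = idx.structure.reactants[rid] - W
        if missing:
            failures[rid] = f"F condition: reactants {sorted(missing)} not producible"
        elif not (idx.catalysts.get(rid, _EMPTY) & W):
            failures[rid] = "RA condition: no catalyst available"
    ok = bool(sub) and not failures
    return RafCheck(ok=ok, failures=failures, support=W)


def is_raf(crs: CRS, subset: Iterable[str]) -> RafCheck:
    """Test the RA and F conditions for a reaction subset over the food set.

    The empty subset is by convention not a RAF.  The returned
    :class:`RafCheck` is truthy exactly when the subset is a RAF and carries
    per-reaction diagnostics otherwise.
    """
    return _raf_check(crs, subset, crs.food)


@dataclass(frozen=True)
class RafResult:
    """A reaction subset plus a status flag (``"raf"`` or ``"none"``).

    Distinguishes "the maximal RAF is empty, i.e. no RAF exists" from an
    accidental empty set.
    """

    reactions: frozenset[str]
    status: str

    def __bool__(self) -> bool:
        return self.status == "raf"

    def __len__(self) -> int:
        return len(self.reactions)


def max_raf(crs: CRS, within: Optional[Iterable[str]] = None) -> RafResult:
    """The unique maximal RAF of the CRS (restricted to ``within`` if given).

    Iteratively removes reactions violating RA or F relative to the closure
    of the surviving set, sweeping to a fixed point.  Returns an empty
    subset with status ``"none"`` when the CRS contains no RAF.
    """
    idx = _idx(crs)
    if within is None:
        current = set(crs.reactions)
    else:
        current = set(within)
        _check_ids(crs, reactions=current)
    while current:
        W = closure(crs, current, crs.food)
        keep = {rid for rid in current
                if not (idx.structure.reactants[rid] - W)
                and (idx.catalysts.get(rid, _EMPTY) & W)}
        if keep == current:
            break
        current = keep
    status = "raf" if current else "none"
    return RafResult(frozenset(current), status)


def max_caf(crs: CRS, within: Optional[Iterable[str]] = None) -> frozenset[str]:
    """The maximal constructively autocatalytic F-generated (CAF) set.

    Forward construction from W = F: repeatedly fire any reaction whose
    reactants *and* at least one catalyst are already in W, adding its
    products.  Returns every reaction that ever fired; always a subset of
    the maximal RAF.
    """
    idx = _idx(crs)
    if within is None:
        pool = list(crs.reactions)
    else:
        pool = sorted(set(within))
        _check_ids(crs, reactions=pool)
    W = set(crs.food)
    added: set[str] = set()
    changed = True
    while changed:
        changed = False
        for rid in pool:
            if rid in added:
                continue
            if not (idx.structure.reactants[rid] - W) \
                    and (idx.catalysts.get(rid, _EMPTY) & W):
                added.add(rid)
                W.update(idx.structure.products[rid])
                changed = True
    return frozenset(added)


def find_irr_raf(crs: CRS, seed: int) -> frozenset[str]:
    """One irreducible RAF, by seeded greedy deletion from the maximal RAF.

    Repeatedly picks a reaction in a seed-determined random order, removes
    it, and keeps the maximal RAF of the remainder if one survives; the
    permutation is redrawn after each successful deletion.  The result is a
    RAF from which no single reaction can be dropped without destroying the
    RAF property.  Different seeds may reach different irrRAFs when several
    exist.
    """
    start = max_raf(crs)
    if not start:
        raise NoRafError("CRS has no RAF, so no irreducible RAF exists")
    rng = np.random.default_rng(seed)
    current = set(start.reactions)
    progress = True
    while progress:
        progress = False
        order = [str(r) for r in rng.permutation(sorted(current))]
        for rid in order:
            survivor = max_raf(crs, within=current - {rid})
            if survivor:
                current = set(survivor.reactions)
                progress = True
                break
    return frozenset(current)


@dataclass(frozen=True)
class SubRafLattice:
    """All RAF subsets of a CRS plus immediate-containment (Hasse) edges.

    ``rafs`` is sorted by size then lexicographically; ``hasse_edges`` holds
    index pairs ``(i, j)`` with ``rafs[i]`` a maximal proper sub-RAF of
    ``rafs[j]``.
    """

    rafs: tuple[frozenset[str], ...]
    hasse_edges: tuple[tuple[int, int], ...]

    def __len__(self) -> int:
        return len(self.rafs)

    def __iter__(self):
        return iter(self.rafs)


def enumerate_subrafs(crs: CRS, hard_limit: int = 20) -> SubRafLattice:
    """Exact exhaustive enumeration of every RAF subset.

    Only subsets of the maximal RAF can be RAFs, so enumeration runs over
    2^|maxRAF| candidates; the guard on |R| keeps this a desk-scale
    operation.
    """
    if len(crs.reactions) > hard_limit:
        raise SizeLimitError(
            f"|R| = {len(crs.reactions)} exceeds the hard limit {hard_limit} "
            "for exhaustive enumeration; use find_irr_raf for large systems")
    base = sorted(max_raf(crs).reactions)
    rafs: list[frozenset[str]] = []
    for mask in range(1, 1 << len(base)):
        subset = frozenset(base[i] for i in range(len(base)) if mask >> i & 1)
        if is_raf(crs, subset):
            rafs.append(subset)
    rafs.sort(key=lambda s: (len(s), tuple(sorted(s))))
    edges = []
    for i, a in enumerate(rafs):
        for j, b in enumerate(rafs):
            if not (len(a) < len(b) and a < b):
                continue
            if any(a < c < b for c in rafs):
                continue
            edges.append((i, j))
    return SubRafLattice(tuple(rafs), tuple(edges))


def relative_food(crs: CRS, raf: Iterable[str]) -> frozenset[str]:
    """Extended food set F' = cl_{raf}(F) generated by an existing RAF."""
    raf = frozenset(raf)
    if not is_raf(crs, raf):
        raise PreconditionError("relative_food requires a RAF subset")
    return closure(crs, raf, crs.food)


def is_co_raf(crs: CRS, subset: Iterable[str],
              relative_to: Iterable[str]) -> bool:
    """Is ``subset`` a co-RAF (periphery) of the RAF ``relative_to``?

    True iff the subset is *not* a RAF over the plain food set F but *is*
    one over the extended food set generated by ``relative_to``.  The two
    subsets must be disjoint.
    """
    subset = frozenset(subset)
    relative_to = frozenset(relative_to)
    if subset & relative_to:
        raise PreconditionError(
            f"subset overlaps the reference RAF: {sorted(subset & relative_to)}")
    extended = relative_food(crs, relative_to)  # checks the RAF precondition
    if is_raf(crs, subset):
        return False
    return bool(_raf_check(crs, subset, extended))


def max_raf_with_inhibition(crs: CRS, hard_limit: int = 20) -> RafResult:
    """Largest RAF compatible with strong inhibition, by exhaustive search.

    A candidate subset is disqualified if any reaction in it has an
    inhibitor inside the closure of the subset over F ("strong" semantics:
    a producible inhibitor always wins).  Inhibition makes this problem
    NP-complete in general, hence the exact search is limited to small |R|.
    Ties in size break towards the lexicographically smallest subset.
    """
    if not crs.inhibition:
        return max_raf(crs)
    if len(crs.reactions) > hard_limit:
        raise SizeLimitError(
            f"|R| = {len(crs.reactions)} exceeds the hard limit {hard_limit} "
            "for the exhaustive inhibition-aware search")
    idx = _idx(crs)
    base = sorted(max_raf(crs).reactions)  # valid subsets are RAFs sans inhibition
    best: Optional[frozenset[str]] = None
    best_key = None
    for mask in range(1, 1 << len(base)):
        subset = frozenset(base[i] for i in range(len(base)) if mask >> i & 1)
        check = is_raf(crs, subset)
        if not check:
            continue
        if any(idx.inhibitors.get(rid, _EMPTY) & check.support for rid in subset):
            continue
        key = (-len(subset), tuple(sorted(subset)))
        if best is None or key < best_key:
            best, best_key = subset, key
    if best is None:
        return RafResult(frozenset(), "none")
    return RafResult(best, "raf")
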