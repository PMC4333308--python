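"""Self-generated boundaries as catalysts, and emergent higher-level RAFs.

Confinement inside a boundary (e.g. a lipid-like aggregate that closes in on
itself once it reaches a minimal size B) raises the rate of the enclosed
reactions by keeping their reactants and catalysts in proximity.  Since a
catalyst is, by definition, anything that speeds a reaction up without being
consumed, the boundary aggregates ``base^n`` (B <= n <= L) can be recorded
as additional catalysts of the enclosed reactions — a pure extension of the
catalysis set C that needs no new machinery.

With that extension a two-level structure can arise: a core RAF generates an
extended food set that *enables* a periphery (co-RAF), and the periphery's
products — the boundary — catalyze the core in return.  When both hold, the
pair forms a higher-level, *emergent* RAF of RAF subsets.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from .algorithms import (_idx, closure, is_co_raf, is_raf, max_raf,
                         relative_food)
from .crs import CRS, aggregate_id
from .errors import InvalidSpecError, PreconditionError, UnknownIdError


@dataclass(frozen=True)
class BoundarySpec:
    """A boundary-forming aggregate family and the reactions it encloses.

    Aggregates ``base^n`` with B <= n <= L (``min_closing_size`` to
    ``max_size``) are large enough to close into a boundary around
    ``enclosed_reactions``.  ``self_catalysis`` additionally makes the
    closed aggregates catalysts of their own formation (the aggregation
    family's reactions), as lipid layers promote further lipid uptake;
    off by default.
    """

    base_monomer: str
    min_closing_size: int
    max_size: int
    enclosed_reactions: frozenset[str]
    self_catalysis: bool = False

    def __post_init__(self):
        object.__setattr__(self, "enclosed_reactions",
                           frozenset(self.enclosed_reactions))
        if not 2 <= self.min_closing_size <= self.max_size:
            raise InvalidSpecError(
                f"boundary sizes must satisfy 2 <= B <= L, got "
                f"B={self.min_closing_size}, L={self.max_size}")


def add_boundary_catalysis(crs: CRS, spec: BoundarySpec) -> CRS:
    """Record the boundary aggregates as catalysts of the enclosed reactions.

    Adds the pair ``(base^n, r)`` for every B <= n <= L and every enclosed
    reaction ``r``.  X, R and F are untouched, so the maximal RAF can only
    grow.  Idempotent (set union).
    """
    missing = spec.enclosed_reactions - crs.reactions.keys()
    if missing:
        raise UnknownIdError(f"unknown enclosed reactions: {sorted(missing)}")
    aggregates = [aggregate_id(spec.base_monomer, n)
                  for n in range(spec.min_closing_size, spec.max_size + 1)]
    absent = [a for a in aggregates if a not in crs.molecules]
    if absent:
        raise UnknownIdError(
            f"boundary aggregates missing from X (expand families first?): {absent}")
    pairs = {(agg, rid) for agg in aggregates for rid in spec.enclosed_reactions}
    if spec.self_catalysis:
        base = spec.base_monomer
        builders = [rid for rid, r in crs.reactions.items()
                    if any(crs.molecules[p].aggregate_base == base
                           for p in r.products if p in crs.molecules)]
        pairs |= {(agg, rid) for agg in aggregates for rid in builders}
    return crs.with_catalysis(pairs)


@dataclass(frozen=True)
class ActivationResult:
    """Outcome of a spontaneous-kickstart simulation.

    ``order`` is the firing order (each reaction at its first firing);
    ``molecules`` the molecule types present at the end;
    ``unfired_spontaneous`` the stalled prefix — spontaneous reactions whose
    reactants were never available; ``full_raf_activated`` is true when the
    fired set covers the whole (non-empty) maximal RAF.
    """

    order: tuple[str, ...]
    molecules: frozenset[str]
    unfired_spontaneous: tuple[str, ...]
    full_raf_activated: bool


def activation_order(crs: CRS, spontaneous: Sequence[str]) -> ActivationResult:
    """Which reactions come alive if some fire spontaneously (uncatalyzed) once?

    None of a RAF's reactions may be able to fire catalyzed at the start
    (no CAF); a rare uncatalyzed event can still seed it.  Each listed
    spontaneous reaction fires once, in list order, provided its reactants
    are available; thereafter reactions fire only with reactants *and* a
    catalyst present, appended deterministically in CRS declaration order,
    until nothing more qualifies.
    """
    idx = _idx(crs)
    bad = set(spontaneous) - crs.reactions.keys()
    if bad:
        raise UnknownIdError(f"unknown spontaneous reactions: {sorted(bad)}")
    W = set(crs.food)
    order: list[str] = []
    fired: set[str] = set()
    unfired: list[str] = []
    for rid in spontaneous:
        if idx.structure.reactants[rid] - W:
            unfired.append(rid)
            continue
        if rid not in fired:
            fired.add(rid)
            order.append(rid)
        W.update(idx.structure.products[rid])
    progress = True
    while progress:
        progress = False
        for rid in crs.reactions:
            if rid in fired:
                continue
            if idx.structure.reactants[rid] - W:
                continue
            if not (idx.catalysts.get(rid, frozenset()) & W):
                continue
            fired.add(rid)
            order.append(rid)
            W.update(idx.structure.products[rid])
            progress = True
    mr = max_raf(crs)
    full = bool(mr) and mr.reactions <= fired
    return ActivationResult(tuple(order), frozenset(W), tuple(unfired), full)


@dataclass(frozen=True)
class EmergenceReport:
    """Core/periphery decomposition evidence for an emergent RAF.

    ``enablement``: the periphery is a co-RAF of the core (it lives off the
    core's extended food set but not off F alone).  ``reciprocity``: the
    catalysis pairs ``(m, r)`` whose catalyst ``m`` is a genuine periphery
    product and whose reaction ``r`` is in the core.  ``emergent`` requires
    both — mutual dependence between the two levels.
    """

    core: frozenset[str]
    periphery: frozenset[str]
    extended_food: frozenset[str]
    enablement: bool
    reciprocity: frozenset[tuple[str, str]]
    emergent: bool


def detect_emergence(crs: CRS, core: Iterable[str],
                     periphery: Iterable[str]) -> EmergenceReport:
    """Test whether core + periphery form a higher-level, emergent RAF.

    The core must itself be a RAF and be disjoint from the periphery.
    Enablement is co-RAF membership of the periphery relative to the core;
    reciprocity collects catalysis pairs whose catalyst lies in the
    periphery's closure over the extended food set but not in the extended
    food set itself (pass-through food species do not count as "produced").
    """
    core = frozenset(core)
    periphery = frozenset(periphery)
    if core & periphery:
        raise PreconditionError(
            f"core and periphery overlap: {sorted(core & periphery)}")
    if not is_raf(crs, core):
        raise PreconditionError("core must be a RAF")
    extended = relative_food(crs, core)
    enablement = bool(periphery) and is_co_raf(crs, periphery, core)
    produced = closure(crs, periphery, extended) - extended
    reciprocity = frozenset((m, r) for m, r in crs.catalysis
                            if m in produced and r in core)
    return EmergenceReport(core=core, periphery=periphery,
                           extended_food=extended, enablement=enablement,
                           reciprocity=reciprocity,
                           emergent=enablement and bool(reciprocity))
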