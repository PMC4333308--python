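"""Data model for chemical reaction systems (CRS).

A CRS is the tuple (X, R, C, F): a set of molecule types X, a set of
reactions R (reactant types -> product types), a catalysis relation
C ⊆ X × R saying which molecule types speed up which reactions, and a food
set F ⊆ X of nutrients assumed freely available from the environment.  An
optional inhibition relation I ⊆ X × R may be attached.

Two modelling conventions hold throughout the package:

* Everything is *type level* and presence based: one present molecule type
  satisfies any number of reactant slots, so ``e + e -> e^2`` fires as soon
  as the type ``e`` is available.  Stoichiometry, concentrations and
  kinetics are out of scope.
* Reactions are directed as written; a reversible reaction is modelled as
  two reactions.

Aggregate species (polymers of a single monomer, written ``base^n``) and
shorthand reaction *families* that build them step by step are first-class:
a family with maximal size L expands into the L-1 concrete reactions
``base + base -> base^2``, ``base + base^n -> base^(n+1)`` for n < L.

CRS instances are treated as immutable: operations that "modify" a CRS
return a new one sharing the unchanged parts.  Never mutate the dictionaries
of an existing CRS in place.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InvalidSpecError, ValidationError

_AGGREGATE_RE = re.compile(r"^(?P<base>[^\s^]+)\^(?P<n>[1-9]\d*)$")


def aggregate_id(base: str, n: int) -> str:
    """Canonical id of an aggregate of ``n`` monomers of ``base``.

    ``n == 1`` is the bare monomer and renders as ``base`` itself; larger
    aggregates render in the caret dialect, e.g. ``e^3``.
    """
    if n < 1:
        raise InvalidSpecError(f"aggregate size must be >= 1, got {n}")
    return base if n == 1 else f"{base}^{n}"


@dataclass(frozen=True)
class MoleculeType:
    """A named chemical species.

    ``aggregate_base``/``aggregate_size`` are set together for aggregate
    species ``base^n``; ``partition`` and ``compartment`` are free tags used
    by the partitioned polymer model and by transport reactions.
    """

    id: str
    aggregate_base: Optional[str] = None
    aggregate_size: Optional[int] = None
    partition: Optional[str] = None
    compartment: Optional[str] = None


def molecule_from_id(mol_id: str, *, partition: Optional[str] = None,
                     compartment: Optional[str] = None) -> MoleculeType:
    """Build a MoleculeType from an id, recognising the caret dialect.

    ``"e^3"`` becomes an aggregate with base ``"e"`` and size 3; any other
    token is a plain species.
    """
    m = _AGGREGATE_RE.match(mol_id)
    if m and int(m.group("n")) >= 2:
        return MoleculeType(mol_id, aggregate_base=m.group("base"),
                            aggregate_size=int(m.group("n")),
                            partition=partition, compartment=compartment)
    return MoleculeType(mol_id, partition=partition, compartment=compartment)


@dataclass(frozen=True)
class Reaction:
    """A directed reaction over molecule-type ids.

    ``family`` names the shorthand family the reaction was expanded from,
    if any; ``tag`` is a free label (e.g. ``"transport"`` for reactions that
    move a species across a compartment boundary).
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    family: Optional[str] = None
    tag: Optional[str] = None

    def __post_init__(self):
        object.__setattr__(self, "reactants", tuple(self.reactants))
        object.__setattr__(self, "products", tuple(self.products))


@dataclass(frozen=True)
class ReactionFamily:
    """Shorthand for the L-1 aggregation reactions building ``base^2..base^L``."""

    family_id: str
    base_monomer: str
    max_size: int
    catalyst_ids: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "catalyst_ids", tuple(self.catalyst_ids))

    def member_id(self, n: int) -> str:
        """Id of the member producing the size-``n`` aggregate (2 <= n <= L)."""
        return f"{self.family_id}_{n}"

    def expand(self) -> list[Reaction]:
        if self.max_size < 2:
            raise InvalidSpecError(
                f"family {self.family_id}: max size L must be >= 2, "
                f"got {self.max_size}")
        base = self.base_monomer
        out = []
        for n in range(2, self.max_size + 1):
            reactants = (base, base) if n == 2 else (base, aggregate_id(base, n - 1))
            out.append(Reaction(self.member_id(n), reactants,
                                (aggregate_id(base, n),), family=self.family_id))
        return out


@dataclass
class CRS:
    """The tuple (X, R, C, F) with optional inhibition relation.

    ``molecules`` and ``reactions`` are insertion-ordered mappings keyed by
    id; ``catalysis`` and ``inhibition`` are frozensets of
    ``(molecule_id, reaction_id)`` pairs; ``food`` is a frozenset of
    molecule ids.  ``families`` holds not-yet-expanded reaction families
    (see :func:`expand_families`).
    """

    molecules: dict[str, MoleculeType]
    reactions: dict[str, Reaction]
    catalysis: frozenset[tuple[str, str]]
    food: frozenset[str]
    inhibition: frozenset[tuple[str, str]] = frozenset()
    families: tuple[ReactionFamily, ...] = ()

    @classmethod
    def build(cls, reactions: Iterable[Reaction] = (),
              catalysis: Iterable[tuple[str, str]] = (),
              food: Iterable[str] = (),
              molecules: Iterable[MoleculeType] = (),
              inhibition: Iterable[tuple[str, str]] = (),
              families: Iterable[ReactionFamily] = ()) -> "CRS":
        """Construct a CRS, declaring any molecule implied by its usage.

        Molecule ids appearing in reactions, catalysis/inhibition pairs, the
        food set or family definitions but not listed explicitly are created
        with :func:`molecule_from_id` (so caret ids become aggregates).
        """
        reactions = list(reactions)
        families = tuple(families)
        mol_map: dict[str, MoleculeType] = {}
        for m in molecules:
            mol_map[m.id] = m
        used: list[str] = []
        for r in reactions:
            used.extend(r.reactants)
            used.extend(r.products)
        used.extend(food)
        for m, _ in catalysis:
            used.append(m)
        for m, _ in inhibition:
            used.append(m)
        for fam in families:
            used.append(fam.base_monomer)
            used.extend(fam.catalyst_ids)
        for mid in used:
            if mid not in mol_map:
                mol_map[mid] = molecule_from_id(mid)
        return cls(molecules=mol_map,
                   reactions={r.id: r for r in reactions},
                   catalysis=frozenset(catalysis),
                   food=frozenset(food),
                   inhibition=frozenset(inhibition),
                   families=families)

    def with_catalysis(self, extra: Iterable[tuple[str, str]]) -> "CRS":
        """Return a copy whose catalysis set additionally contains ``extra``."""
        return replace(self, catalysis=self.catalysis | frozenset(extra))

    def restrict(self, reaction_ids: Iterable[str]) -> "CRS":
        """Return a copy keeping only the given reactions (X, C, F filtered)."""
        keep = set(reaction_ids)
        reactions = {rid: r for rid, r in self.reactions.items() if rid in keep}
        return replace(
            self, reactions=reactions,
            catalysis=frozenset(p for p in self.catalysis if p[1] in keep),
            inhibition=frozenset(p for p in self.inhibition if p[1] in keep))


def validate(crs: CRS) -> list[str]:
    """Check every CRS invariant; return a (possibly empty) list of violations.

    Violations are returned, never raised, so callers can present them all at
    once.  An empty list means the CRS is structurally sound.
    """
    out: list[str] = []
    for mid, mol in crs.molecules.items():
        if not mid or any(c.isspace() for c in mid):
            out.append(f"molecule id {mid!r} is not a valid token")
        if mid != mol.id:
            out.append(f"molecule {mol.id!r} keyed under wrong id {mid!r}")
        has_base = mol.aggregate_base is not None
        has_size = mol.aggregate_size is not None
        if has_base != has_size:
            out.append(f"molecule {mid!r}: aggregate_base and aggregate_size "
                       "must be set together")
        elif has_base:
            if mol.aggregate_size < 1:
                out.append(f"molecule {mid!r}: aggregate_size must be >= 1")
            elif mid != aggregate_id(mol.aggregate_base, mol.aggregate_size):
                out.append(f"molecule {mid!r}: id does not match aggregate "
                           f"({mol.aggregate_base!r}, {mol.aggregate_size})")
    for rid, r in crs.reactions.items():
        if not rid or any(c.isspace() for c in rid):
            out.append(f"reaction id {rid!r} is not a valid token")
        if rid != r.id:
            out.append(f"reaction {r.id!r} keyed under wrong id {rid!r}")
        if not r.reactants:
            out.append(f"reaction {rid!r} has no reactants")
        if not r.products:
            out.append(f"reaction {rid!r} has no products")
        for mid in (*r.reactants, *r.products):
            if mid not in crs.molecules:
                out.append(f"reaction {rid!r} references unknown molecule {mid!r}")
    for label, pairs in (("catalysis", crs.catalysis),
                         ("inhibition", crs.inhibition)):
        for mid, rid in pairs:
            if mid not in crs.molecules:
                out.append(f"{label} pair ({mid!r}, {rid!r}): unknown molecule {mid!r}")
            if rid not in crs.reactions:
                out.append(f"{label} pair ({mid!r}, {rid!r}): unknown reaction {rid!r}")
    for pair in crs.catalysis & crs.inhibition:
        out.append(f"pair {pair!r} appears in both catalysis and inhibition")
    for mid in crs.food:
        if mid not in crs.molecules:
            out.append(f"food molecule {mid!r} is not in X")
    for fam in crs.families:
        if fam.max_size < 2:
            out.append(f"family {fam.family_id!r}: max size must be >= 2")
        if fam.base_monomer not in crs.molecules:
            out.append(f"family {fam.family_id!r}: unknown base {fam.base_monomer!r}")
        for cid in fam.catalyst_ids:
            if cid not in crs.molecules:
                out.append(f"family {fam.family_id!r}: unknown catalyst {cid!r}")
    return out


def expand_families(crs: CRS) -> CRS:
    """Replace every shorthand family by its L-1 concrete reactions.

    Each member reaction carries a catalysis pair for every family catalyst.
    Aggregate molecules ``base^2 .. base^L`` (and the bare monomer) are
    declared as needed.  Expanding an already-expanded CRS is a no-op, and
    the result always passes :func:`validate` when the template only
    references declared molecules.
    """
    if not crs.families:
        return crs
    molecules = dict(crs.molecules)
    reactions = dict(crs.reactions)
    catalysis = set(crs.catalysis)
    for fam in crs.families:
        members = fam.expand()  # raises InvalidSpecError for L < 2
        base = fam.base_monomer
        molecules.setdefault(base, molecule_from_id(base))
        for n in range(2, fam.max_size + 1):
            agg = aggregate_id(base, n)
            molecules.setdefault(agg, molecule_from_id(agg))
        for rxn in members:
            if rxn.id in reactions and reactions[rxn.id] != rxn:
                raise ValidationError(
                    [f"family {fam.family_id!r} member id {rxn.id!r} clashes "
                     "with an existing reaction"])
            reactions[rxn.id] = rxn
            for cid in fam.catalyst_ids:
                catalysis.add((cid, rxn.id))
    expanded = CRS(molecules=molecules, reactions=reactions,
                   catalysis=frozenset(catalysis), food=crs.food,
                   inhibition=crs.inhibition, families=())
    violations = validate(expanded)
    if violations:
        raise ValidationError(violations)
    return expanded
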