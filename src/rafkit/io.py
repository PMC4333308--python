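"""Readers/writers for the CRS text dialect and graph exports.

The line-oriented text dialect (``#`` starts a comment)::

    mol e^4 [partition=p1] [compartment=in]   # optional; ids declare implicitly
    family r5: e ^ L=5 catalyzed_by c
    r1: f1 + f2 -> a [family=...] [tag=transport]
    cat d r1
    inh x r2
    food f1 f2 f3

Molecule ids using the caret dialect (``e^3``) are parsed as aggregates.
A YAML (key/value) serialization mirrors the same fields; both formats
round-trip CRSs exactly.  Writers emit a canonical ordering — molecules,
families, reactions, catalysis, inhibition, food — each block sorted by id.

Graph export renders the bipartite reaction network: molecule nodes,
reaction nodes, solid reactant/product edges and catalysis (dashed) /
inhibition edges distinguished by a ``kind`` attribute.
"""
from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Union

import networkx as nx
import yaml

from .crs import (CRS, MoleculeType, Reaction, ReactionFamily,
                  molecule_from_id, validate)
from .errors import InvalidSpecError, ParseError, ValidationError

TEXT_DIALECT = "crs-text/1"
YAML_DIALECT = "crs-yaml/1"

_FAMILY_RE = re.compile(
    r"^family\s+(?P<fid>\S+)\s*:\s*(?P<base>[^\s^]+)\s*\^\s*L=(?P<L>\d+)"
    r"(?:\s+catalyzed_by\s+(?P<cats>.+))?$")


@dataclass
class CrsDocument:
    """A parsed CRS together with its provenance and reader warnings."""

    crs: CRS
    source: Optional[str] = None
    dialect: str = TEXT_DIALECT
    warnings: list[str] = field(default_factory=list)


def _is_yaml_path(name: str) -> bool:
    return name.endswith((".yaml", ".yml"))


def read_crs(source, fmt: Optional[str] = None) -> CrsDocument:
    """Parse a CRS document from a path, string of text, or open file.

    ``fmt`` is ``"text"`` or ``"yaml"``; by default it is inferred from the
    file extension (text otherwise).  Unknown directives produce warnings,
    not failures; a CRS that fails validation raises
    :class:`~rafkit.errors.ValidationError` with the full violation list.
    """
    name = None
    if hasattr(source, "read"):
        text = source.read()
        name = getattr(source, "name", None)
    elif isinstance(source, (str, Path)) and (
            isinstance(source, Path) or "\n" not in source) and Path(source).exists():
        name = str(source)
        text = Path(source).read_text()
    else:
        text = str(source)
    if fmt is None:
        fmt = "yaml" if (name and _is_yaml_path(name)) else "text"
    if fmt == "yaml":
        crs = _crs_from_dict(yaml.safe_load(text))
        doc = CrsDocument(crs, source=name, dialect=YAML_DIALECT)
    elif fmt == "text":
        crs, warnings = _parse_text(text)
        doc = CrsDocument(crs, source=name, dialect=TEXT_DIALECT,
                          warnings=warnings)
    else:
        raise InvalidSpecError(f"unknown CRS format {fmt!r}")
    violations = validate(doc.crs)
    if violations:
        raise ValidationError(violations)
    return doc


def _parse_text(text: str) -> tuple[CRS, list[str]]:
    explicit: dict[str, MoleculeType] = {}
    reactions: list[Reaction] = []
    families: list[ReactionFamily] = []
    catalysis: list[tuple[str, str]] = []
    inhibition: list[tuple[str, str]] = []
    food: list[str] = []
    warnings: list[str] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        tokens = line.split()
        head = tokens[0]
        if head == "mol":
            if len(tokens) < 2:
                raise ParseError("mol line needs an id", lineno)
            attrs = {}
            for tok in tokens[2:]:
                if "=" not in tok:
                    raise ParseError(f"bad molecule attribute {tok!r}", lineno)
                k, v = tok.split("=", 1)
                if k not in ("partition", "compartment"):
                    warnings.append(f"line {lineno}: ignoring molecule "
                                    f"attribute {k!r}")
                    continue
                attrs[k] = v
            explicit[tokens[1]] = molecule_from_id(tokens[1], **attrs)
        elif head == "family":
            m = _FAMILY_RE.match(line)
            if not m:
                raise ParseError("malformed family line", lineno)
            cats = tuple(m.group("cats").split()) if m.group("cats") else ()
            families.append(ReactionFamily(m.group("fid"), m.group("base"),
                                           int(m.group("L")), cats))
        elif head == "cat" or head == "inh":
            if len(tokens) != 3:
                raise ParseError(f"{head} line needs a molecule and a "
                                 "reaction id", lineno)
            pair = (tokens[1], tokens[2])
            target = catalysis if head == "cat" else inhibition
            if pair in target:
                warnings.append(f"line {lineno}: duplicate {head} pair {pair}")
            target.append(pair)
        elif head == "food":
            for mid in tokens[1:]:
                if mid in food:
                    warnings.append(f"line {lineno}: duplicate food id {mid!r}")
                else:
                    food.append(mid)
        elif ":" in line:
            reactions.append(_parse_reaction(line, lineno))
        else:
            warnings.append(f"line {lineno}: unknown directive {head!r}")
    crs = CRS.build(reactions=reactions, catalysis=catalysis, food=food,
                    molecules=explicit.values(), inhibition=inhibition,
                    families=tuple(families))
    return crs, warnings


def _parse_reaction(line: str, lineno: int) -> Reaction:
    rid, _, rest = line.partition(":")
    rid = rid.strip()
    if not rid or any(c.isspace() for c in rid):
        raise ParseError(f"bad reaction id {rid!r}", lineno)
    lhs, arrow, rhs = rest.partition("->")
    if not arrow:
        raise ParseError("reaction line lacks '->'", lineno)
    reactants = [t for t in lhs.split() if t != "+"]
    family = tag = None
    products = []
    for tok in rhs.split():
        if tok == "+":
            continue
        if tok.startswith("family="):
            family = tok[len("family="):]
        elif tok.startswith("tag="):
            tag = tok[len("tag="):]
        else:
            products.append(tok)
    if not reactants or not products:
        raise ParseError("reaction needs reactants and products", lineno)
    return Reaction(rid, tuple(reactants), tuple(products),
                    family=family, tag=tag)


def _mol_line(mol: MoleculeType) -> str:
    parts = ["mol", mol.id]
    if mol.partition is not None:
        parts.append(f"partition={mol.partition}")
    if mol.compartment is not None:
        parts.append(f"compartment={mol.compartment}")
    return " ".join(parts)


def _rxn_line(r: Reaction) -> str:
    line = (f"{r.id}: {' + '.join(r.reactants)} -> "
            f"{' + '.join(r.products)}")
    if r.family is not None:
        line += f" family={r.family}"
    if r.tag is not None:
        line += f" tag={r.tag}"
    return line


def _family_line(fam: ReactionFamily) -> str:
    line = f"family {fam.family_id}: {fam.base_monomer} ^ L={fam.max_size}"
    if fam.catalyst_ids:
        line += " catalyzed_by " + " ".join(fam.catalyst_ids)
    return line


def write_crs(crs: CRS, sink=None, fmt: Optional[str] = None) -> Optional[str]:
    """Serialize a CRS canonically; validation failures emit nothing.

    ``sink`` may be a path, an open file, or None (the document is then
    returned as a string).  Format is inferred from the path extension when
    not given (text otherwise).
    """
    violations = validate(crs)
    if violations:
        raise ValidationError(violations)
    name = str(sink) if isinstance(sink, (str, Path)) else None
    if fmt is None:
        fmt = "yaml" if (name and _is_yaml_path(name)) else "text"
    if fmt == "yaml":
        text = yaml.safe_dump(_crs_to_dict(crs), sort_keys=False)
    elif fmt == "text":
        lines = [f"# {TEXT_DIALECT}"]
        lines += [_mol_line(crs.molecules[mid]) for mid in sorted(crs.molecules)]
        lines += [_family_line(f) for f in
                  sorted(crs.families, key=lambda f: f.family_id)]
        lines += [_rxn_line(crs.reactions[rid]) for rid in sorted(crs.reactions)]
        lines += [f"cat {m} {r}" for m, r in sorted(crs.catalysis)]
        lines += [f"inh {m} {r}" for m, r in sorted(crs.inhibition)]
        if crs.food:
            lines.append("food " + " ".join(sorted(crs.food)))
        text = "\n".join(lines) + "\n"
    else:
        raise InvalidSpecError(f"unknown CRS format {fmt!r}")
    if sink is None:
        return text
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        Path(sink).write_text(text)
    return None


def _crs_to_dict(crs: CRS) -> dict:
    def mol_entry(m: MoleculeType) -> dict:
        d = {"id": m.id}
        if m.partition is not None:
            d["partition"] = m.partition
        if m.compartment is not None:
            d["compartment"] = m.compartment
        return d

    def rxn_entry(r: Reaction) -> dict:
        d = {"id": r.id, "reactants": list(r.reactants),
             "products": list(r.products)}
        if r.family is not None:
            d["family"] = r.family
        if r.tag is not None:
            d["tag"] = r.tag
        return d

    return {
        "dialect": YAML_DIALECT,
        "molecules": [mol_entry(crs.molecules[m]) for m in sorted(crs.molecules)],
        "families": [{"id": f.family_id, "base": f.base_monomer,
                      "max_size": f.max_size,
                      "catalysts": list(f.catalyst_ids)}
                     for f in sorted(crs.families, key=lambda f: f.family_id)],
        "reactions": [rxn_entry(crs.reactions[r]) for r in sorted(crs.reactions)],
        "catalysis": [list(p) for p in sorted(crs.catalysis)],
        "inhibition": [list(p) for p in sorted(crs.inhibition)],
        "food": sorted(crs.food),
    }


def _crs_from_dict(data: dict) -> CRS:
    if not isinstance(data, dict):
        raise ParseError("YAML CRS document must be a mapping")
    molecules = [molecule_from_id(m["id"], partition=m.get("partition"),
                                  compartment=m.get("compartment"))
                 for m in data.get("molecules", [])]
    reactions = [Reaction(r["id"], tuple(r["reactants"]), tuple(r["products"]),
                          family=r.get("family"), tag=r.get("tag"))
                 for r in data.get("reactions", [])]
    families = [ReactionFamily(f["id"], f["base"], int(f["max_size"]),
                               tuple(f.get("catalysts", ())))
                for f in data.get("families", [])]
    return CRS.build(reactions=reactions,
                     catalysis=[tuple(p) for p in data.get("catalysis", [])],
                     food=data.get("food", []),
                     molecules=molecules,
                     inhibition=[tuple(p) for p in data.get("inhibition", [])],
                     families=families)


def to_networkx(crs: CRS,
                highlight: Optional[Iterable[str]] = None) -> nx.MultiDiGraph:
    """Bipartite reaction-network graph (molecule nodes vs reaction nodes).

    Edge ``kind`` is one of reactant/product/catalysis/inhibition; node
    ``kind`` is molecule or reaction, with food and highlight flags.  A
    multigraph, since a catalyst may also be a reactant of the same
    reaction.
    """
    highlight = frozenset(highlight or ())
    clash = crs.molecules.keys() & crs.reactions.keys()
    if clash:
        raise InvalidSpecError(
            f"molecule and reaction ids overlap, cannot export: {sorted(clash)}")
    g = nx.MultiDiGraph()
    for mid in crs.molecules:
        g.add_node(mid, kind="molecule", bipartite=0,
                   food=mid in crs.food)
    for rid in crs.reactions:
        g.add_node(rid, kind="reaction", bipartite=1,
                   highlight=rid in highlight)
    for rid, r in crs.reactions.items():
        for mid in dict.fromkeys(r.reactants):
            g.add_edge(mid, rid, kind="reactant")
        for mid in dict.fromkeys(r.products):
            g.add_edge(rid, mid, kind="product")
    for mid, rid in crs.catalysis:
        g.add_edge(mid, rid, kind="catalysis")
    for mid, rid in crs.inhibition:
        g.add_edge(mid, rid, kind="inhibition")
    return g


def export_graph(crs: CRS, highlight: Optional[Iterable[str]] = None,
                 fmt: str = "dot") -> str:
    """Render the reaction network as a DOT or GraphML document."""
    if fmt not in ("dot", "graphml"):
        raise InvalidSpecError(f"unknown graph format {fmt!r}; "
                               "use 'dot' or 'graphml'")
    g = to_networkx(crs, highlight=highlight)
    if fmt == "graphml":
        return "\n".join(nx.generate_graphml(g)) + "\n"
    return _to_dot(g)


def _quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def _to_dot(g: nx.MultiDiGraph) -> str:
    lines = ["digraph crs {"]
    for node, data in sorted(g.nodes(data=True)):
        attrs = [f"kind={data['kind']}"]
        if data["kind"] == "molecule":
            attrs.append("shape=point")
            if data.get("food"):
                attrs.append("food=true")
        else:
            attrs.append("shape=box")
            if data.get("highlight"):
                attrs.append("highlight=true")
        lines.append(f"  {_quote(node)} [{', '.join(attrs)}];")
    for u, v, data in sorted(g.edges(data=True)):
        attrs = [f"kind={data['kind']}"]
        if data["kind"] == "catalysis":
            attrs.append("style=dashed")
            attrs.append("color=gray")
        elif data["kind"] == "inhibition":
            attrs.append("style=dotted")
        lines.append(f"  {_quote(u)} -> {_quote(v)} [{', '.join(attrs)}];")
    lines.append("}")
    return "\n".join(lines) + "\n"
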