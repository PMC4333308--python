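"""Model CRS generators and the catalysis-level phase-transition estimator.

Three families of systems are produced here, all pure functions of their
parameters and seed:

* ``worked_example`` — a small hand-built network of five reactions (one of
  them an aggregation family) whose maximal RAF, irreducible core
  {r1, r2, r3}, co-RAF periphery and boundary-driven emergent RAF are known
  in closed form.  It is the reference fixture for the whole package.
* ``polymer_crs`` — the random polymer model: all strings over a finite
  alphabet up to length n, every ligation u + v -> uv and its cleavage
  counterpart, food = all strings up to length t, and an independent
  Bernoulli catalysis draw per (molecule, reaction) pair.  With two
  partitions, reactions stay within a partition while catalysis may cross.
* ``random_crs`` — small arbitrary CRSs for cross-validation against
  brute-force oracles.

``estimate_transition`` sweeps the mean catalysis level f (expected
reactions catalyzed per molecule type, f = p|R|) and locates the level at
which the probability that a RAF exists crosses 1/2.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np

from .algorithms import _Structure, max_raf
from .boundary import BoundarySpec, add_boundary_catalysis
from .crs import (CRS, MoleculeType, Reaction, ReactionFamily,
                  expand_families)
from .errors import InvalidSpecError

_ALPHABET = "0123456789abcdefghijklmnopqrstuvwxyz"


def worked_example(L: int = 5, B: Optional[int] = None,
                   with_boundary: bool = False) -> CRS:
    """The reference example CRS, expanded, with optional boundary catalysis.

    Reactions::

        r1: f1 + f2 -> a        (catalyzed by d)
        r2: f2 + f3 -> b + c    (catalyzed by a)
        r3: a + b   -> d        (catalyzed by c)
        r4: c       -> e        (catalyzed by d)
        r5: e + e^n -> e^(n+1)  (family, n < L, catalyzed by c)

    Food is {f1, f2, f3}.  The whole reaction set is the maximal RAF;
    {r1, r2, r3} is its unique irreducible RAF; {r4} plus the r5 family is a
    co-RAF living off the extended food set {f1, f2, f3, a, b, c, d}.

    With ``with_boundary`` the aggregates ``e^B .. e^L`` are added to the
    catalysis set as boundary catalysts of {r1, r2, r3}, which makes the
    core/periphery pair an emergent RAF.
    """
    if L < 2:
        raise InvalidSpecError(f"worked example requires L >= 2, got {L}")
    template = CRS.build(
        reactions=[
            Reaction("r1", ("f1", "f2"), ("a",)),
            Reaction("r2", ("f2", "f3"), ("b", "c")),
            Reaction("r3", ("a", "b"), ("d",)),
            Reaction("r4", ("c",), ("e",)),
        ],
        catalysis=[("d", "r1"), ("a", "r2"), ("c", "r3"), ("d", "r4")],
        food=["f1", "f2", "f3"],
        families=[ReactionFamily("r5", "e", L, ("c",))],
    )
    crs = expand_families(template)
    if with_boundary:
        if B is None:
            raise InvalidSpecError("with_boundary requires B")
        spec = BoundarySpec("e", B, L, frozenset({"r1", "r2", "r3"}))
        crs = add_boundary_catalysis(crs, spec)
    return crs


@dataclass(frozen=True)
class PolymerModelParams:
    """Parameters of the random polymer model.

    Exactly one of ``catalysis_prob`` (per-pair probability p) or
    ``mean_catalyzed`` (expected reactions catalyzed per molecule type,
    f = p * number of catalysis targets) must be given.  ``food_max_length``
    t must be below ``max_length`` n; ``partitions`` is 1 or 2.

    ``paired_catalysis`` (default on) treats each ligation and its cleavage
    counterpart as the two directions of one reversible reaction for the
    purposes of catalysis: a catalyst is drawn per (molecule,
    ligation/cleavage pair) and catalyzes both directions, and the mean
    catalysis level counts reversible reactions (|R|/2 targets).  This is
    the standard binary polymer convention, under which the critical level
    of catalysis falls between one and two reactions per molecule type for
    moderate n.  With ``paired_catalysis=False`` every directed reaction is
    an independent catalysis target.
    """

    alphabet_size: int = 2
    max_length: int = 8
    food_max_length: int = 2
    catalysis_prob: Optional[float] = None
    mean_catalyzed: Optional[float] = None
    partitions: int = 1
    paired_catalysis: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.alphabet_size < 1:
            raise InvalidSpecError("alphabet_size must be >= 1")
        if self.alphabet_size > len(_ALPHABET):
            raise InvalidSpecError(f"alphabet_size must be <= {len(_ALPHABET)}")
        if self.max_length < 2:
            raise InvalidSpecError("max_length must be >= 2")
        if not 1 <= self.food_max_length < self.max_length:
            raise InvalidSpecError("need 1 <= food_max_length < max_length")
        if (self.catalysis_prob is None) == (self.mean_catalyzed is None):
            raise InvalidSpecError(
                "give exactly one of catalysis_prob / mean_catalyzed")
        if self.partitions not in (1, 2):
            raise InvalidSpecError("partitions must be 1 or 2")


@lru_cache(maxsize=8)
def _polymer_skeleton(alphabet_size: int, max_length: int,
                      food_max_length: int, partitions: int):
    """Catalysis-independent part of the polymer model, cached and shared."""
    chars = _ALPHABET[:alphabet_size]
    molecules: dict[str, MoleculeType] = {}
    reactions: dict[str, Reaction] = {}
    rxn_pairs: list[tuple[str, str]] = []
    food: set[str] = set()
    for part in range(1, partitions + 1):
        prefix = "" if partitions == 1 else f"p{part}."
        ptag = None if partitions == 1 else f"p{part}"
        for k in range(1, max_length + 1):
            for tup in itertools.product(chars, repeat=k):
                s = "".join(tup)
                mid = prefix + s
                molecules[mid] = MoleculeType(mid, partition=ptag)
                if k <= food_max_length:
                    food.add(mid)
        for k in range(2, max_length + 1):
            for tup in itertools.product(chars, repeat=k):
                s = "".join(tup)
                for cut in range(1, k):
                    u, v = prefix + s[:cut], prefix + s[cut:]
                    lig = f"lig_{u}+{v}"
                    reactions[lig] = Reaction(lig, (u, v), (prefix + s,))
                    clv = f"clv_{u}+{v}"
                    reactions[clv] = Reaction(clv, (prefix + s,), (u, v))
                    rxn_pairs.append((lig, clv))
    structure = _Structure(reactions)
    return (molecules, reactions, frozenset(food),
            tuple(molecules), tuple(reactions), tuple(rxn_pairs), structure)


def polymer_crs(params: PolymerModelParams) -> CRS:
    """Draw one random polymer CRS; byte-identical for identical params.

    The catalysis set is an independent Bernoulli(p) draw over all
    (molecule, target) pairs — targets being reversible reactions under
    ``paired_catalysis`` (a hit catalyzes both directions) and directed
    reactions otherwise — realised as a binomial count plus a uniform
    without-replacement pick of pair indices.  Food molecules may catalyze,
    and a molecule may catalyze a reaction producing it.
    """
    (molecules, reactions, food, mol_ids, rxn_ids, rxn_pairs,
     structure) = _polymer_skeleton(
        params.alphabet_size, params.max_length,
        params.food_max_length, params.partitions)
    targets = rxn_pairs if params.paired_catalysis else rxn_ids
    n_tgt = len(targets)
    p = (params.catalysis_prob if params.catalysis_prob is not None
         else params.mean_catalyzed / n_tgt)
    if not 0.0 <= p <= 1.0:
        raise InvalidSpecError(f"catalysis probability {p} outside [0, 1]")
    rng = np.random.default_rng(params.seed)
    n_cells = len(mol_ids) * n_tgt
    pairs: set[tuple[str, str]] = set()
    if p > 0.0:
        k = int(rng.binomial(n_cells, p))
        if k:
            flat = rng.choice(n_cells, size=k, replace=False)
            for i in flat:
                mid = mol_ids[int(i) // n_tgt]
                tgt = targets[int(i) % n_tgt]
                if params.paired_catalysis:
                    pairs.add((mid, tgt[0]))
                    pairs.add((mid, tgt[1]))
                else:
                    pairs.add((mid, tgt))
    crs = CRS(molecules=molecules, reactions=reactions,
              catalysis=frozenset(pairs), food=food)
    crs.__dict__["_raf_structure"] = structure
    return crs


def random_crs(seed: int, max_reactions: int = 12,
               catalysis_prob: float = 0.15) -> CRS:
    """A small arbitrary CRS for oracle cross-validation and property tests.

    Sizes, reaction wiring, food set and catalysis are all drawn from the
    seed; the mix is tuned so that RAFs exist in a non-trivial fraction of
    draws.  Not a model of any particular chemistry.
    """
    rng = np.random.default_rng(seed)
    n_mol = int(rng.integers(6, 11))
    mols = [f"m{i}" for i in range(n_mol)]
    food = [mols[i] for i in rng.choice(n_mol, int(rng.integers(2, 5)),
                                        replace=False)]
    n_rxn = int(rng.integers(3, max_reactions + 1))
    reactions = []
    for i in range(n_rxn):
        reactants = tuple(mols[j] for j in rng.choice(
            n_mol, int(rng.integers(1, 3)), replace=False))
        products = tuple(mols[j] for j in rng.choice(
            n_mol, int(rng.integers(1, 3)), replace=False))
        reactions.append(Reaction(f"r{i}", reactants, products))
    catalysis = [(mols[i], f"r{j}")
                 for i in range(n_mol) for j in range(n_rxn)
                 if rng.random() < catalysis_prob]
    return CRS.build(reactions=reactions, catalysis=catalysis, food=food)


@dataclass(frozen=True)
class TransitionEstimate:
    """Monte-Carlo estimate of the critical catalysis level.

    ``raf_fraction[i]`` is the fraction of replicate CRSs at
    ``levels[i]`` whose maximal RAF is non-empty.  ``critical_level`` is the
    linear interpolation of the first upward crossing of 1/2, or None with
    ``status = "out-of-range"`` when the probed levels do not bracket the
    crossing.
    """

    levels: tuple[float, ...]
    raf_fraction: tuple[float, ...]
    critical_level: Optional[float]
    status: str
    replicates: int
    seed: int

    def rows(self):
        """(level, raf_fraction, replicates) rows for tabular output."""
        return [(lv, fr, self.replicates)
                for lv, fr in zip(self.levels, self.raf_fraction)]


def _child_seed(seed: int, *key: int) -> int:
    state = np.random.SeedSequence([seed, *key]).generate_state(1)[0]
    return int(state) & 0x7FFFFFFF


def estimate_transition(levels: Sequence[float], replicates: int, seed: int,
                        *, alphabet_size: int = 2, max_length: int = 8,
                        food_max_length: int = 2, partitions: int = 1,
                        paired_catalysis: bool = True) -> TransitionEstimate:
    """Locate the catalysis level where RAF existence becomes likely.

    For each probed mean-catalysis level f, ``replicates`` independent
    polymer CRSs are drawn (seeds derived from ``seed``) and the fraction
    with a non-empty maximal RAF recorded.  The critical level is where that
    fraction first crosses 1/2, linearly interpolated between the two
    bracketing probed levels.
    """
    if replicates < 1:
        raise InvalidSpecError("replicates must be >= 1")
    levels = tuple(float(x) for x in levels)
    if len(levels) < 1 or any(b <= a for a, b in zip(levels, levels[1:])):
        raise InvalidSpecError("levels must be strictly increasing")
    fractions = []
    for i, level in enumerate(levels):
        hits = 0
        for j in range(replicates):
            params = PolymerModelParams(
                alphabet_size=alphabet_size, max_length=max_length,
                food_max_length=food_max_length, partitions=partitions,
                paired_catalysis=paired_catalysis,
                mean_catalyzed=level, seed=_child_seed(seed, i, j))
            if max_raf(polymer_crs(params)):
                hits += 1
        fractions.append(hits / replicates)
    critical = None
    status = "out-of-range"
    for i in range(1, len(levels)):
        if fractions[i - 1] < 0.5 <= fractions[i]:
            lo, hi = levels[i - 1], levels[i]
            flo, fhi = fractions[i - 1], fractions[i]
            critical = lo + (0.5 - flo) * (hi - lo) / (fhi - flo)
            status = "ok"
            break
    return TransitionEstimate(levels=levels, raf_fraction=tuple(fractions),
                              critical_level=critical, status=status,
                              replicates=replicates, seed=seed)
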