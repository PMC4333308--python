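# Methods

## Model and semantics

rafkit works on chemical reaction systems Q = (X, R, C) with a food set
F ⊆ X and, optionally, an inhibition relation I ⊆ X × R. The framework is
purely set-theoretic: no rates, concentrations, thermodynamics or mass
balance. Two conventions follow from that and are applied uniformly:

* **Presence-based, type-level semantics.** The closure operator asks only
  whether a molecule *type* is available, so a reaction like
  `e + e -> e^2` fires as soon as the single type `e` is present.
  Stoichiometric counts are never tracked.
* **Directed reactions.** Reactions fire as written; reversibility is
  modelled by listing both directions as separate reactions. Transport
  across a semi-permeable compartment boundary is an ordinary reaction
  tagged `transport` whose reactant and product are the same base species
  with different compartment tags; no algorithm treats it specially.

A subset R′ ⊆ R is a RAF when, with W = cl_{R′}(F), every reaction in R′
has all reactants in W (F condition) and at least one catalyst in W (RA
condition). The empty set is by convention **not** a RAF; "no RAF exists"
is reported as an empty subset with a distinct status flag rather than by
exception. A catalyst may be a product of the reaction it catalyzes, may be
produced only downstream of it, or may be a food molecule.

## Algorithms

* **Closure** is a least fixed point computed by a worklist pass over a
  precomputed molecule→consumer index with per-reaction counts of unmet
  distinct reactants: O(total reactant arity) per call.
* **Maximal RAF** repeats full reduction sweeps — recompute the closure of
  the survivors, drop every reaction violating RA or F — until a fixed
  point. A single pass is not enough because a removal can strand earlier
  survivors. The result is the union of all RAF subsets, hence unique.
* **Maximal CAF** is the forward-constructible counterpart: starting from
  W = F, fire any reaction whose reactants *and* a catalyst are already in
  W. A CAF never exceeds the maximal RAF; the gap between the two is
  exactly what spontaneous (uncatalyzed) events must bridge, which
  `activation_order` simulates. Spontaneous reactions fire once each, in
  list order (a repeat event is modelled by listing the reaction again —
  immaterial at type level); subsequent catalyzed firings append in CRS
  declaration order, which makes the trace deterministic.
* **Irreducible RAFs** are sampled by greedy deletion from the maximal RAF:
  try reactions in a seeded pseudorandom order, accept a deletion when the
  remainder still contains a RAF (the remainder's maximal RAF becomes the
  new current set), and redraw the permutation after every success. The
  result is always an irrRAF; *which* one depends on the seed when several
  exist. The seed is a required argument — there is no silent default.
* **Sub-RAF enumeration** and the **inhibition-aware search** are exact and
  exponential, guarded by a hard limit (default 20 reactions ≈ 10^6
  subsets); both only need to enumerate subsets of the maximal RAF.
  Inhibition uses *strong* semantics: a candidate subset is disqualified if
  any inhibitor of any of its reactions lies in the subset's closure over
  F. This is the simplest testable choice; weaker semantics (e.g.
  inhibitor-vs-catalyst competition) would need rate information, which the
  framework deliberately omits. Ties in size break toward the
  lexicographically smallest subset.

## Boundaries and emergence

A boundary spec names a monomer `base`, a closing-size window B ≤ n ≤ L
(2 ≤ B ≤ L; whether B may be as small as 2 is chemically unconstrained
here, so B is a free parameter) and the enclosed reactions. Registering the
boundary adds the catalysis pairs (base^n, r) for every n in the window and
every enclosed r — per-reaction pairs, the explicit set-level reading of
"the boundary catalyzes the enclosed subnetwork as a whole". The optional
`self_catalysis` flag also adds (base^n, family member) pairs for the
aggregation reactions building `base` aggregates, mirroring lipid layers
promoting their own growth; it defaults off because it does not change the
emergence verdict in the reference example.

`detect_emergence(core, periphery)` requires the core to be a RAF disjoint
from the periphery and reports:

* **enablement** — the periphery is a co-RAF of the core: not a RAF over F,
  but a RAF over the extended food set F′ = cl_core(F);
* **reciprocity** — all catalysis pairs (m, r) with r in the core and m a
  *genuine* periphery product: in the periphery's closure over F′ but not
  in F′ itself (pass-through food species do not count);
* **emergent** — both at once, i.e. mutual dependence between the levels.

The co-RAF test takes its reference RAF explicitly rather than assuming an
irreducible one, since any RAF generates a well-defined extended food set.

## Generators

`worked_example(L, B, with_boundary)` builds the reference five-reaction
network (family expanded, 4 + (L−1) reactions). Its defaults (L = 5,
boundary window B = 4) give the 12-molecule, 8-reaction system used
throughout the documentation.

`polymer_crs` builds the random polymer model: all strings over an
alphabet of size k (k = 2, binary, by default) up to length n, every
ligation u + v → uv and its cleavage counterpart, food = all strings up to
length t. Defaults n = 8, t = 2 give |X| = 510 and |R| = 6152 directed
reactions (3076 reversible pairs) — a moderate-size network that one CPU
can sweep in seconds. Catalysis is an independent Bernoulli(p) draw per
(molecule, target) cell, realised exactly as a binomial count plus a
without-replacement index draw.

**Catalysis targets and the level of catalysis.** By default
(`paired_catalysis=True`) the target is the reversible reaction: a drawn
catalyst catalyzes both the ligation and its cleavage, and the mean level
f = p × |R|/2 counts reversible reactions catalyzed per molecule type.
This is the standard convention for the binary polymer model and is what
places the critical level between one and two. Setting
`paired_catalysis=False` draws every directed reaction independently
(f = p × |R|); the measured critical level then roughly doubles in those
units — the same physics under a different counting convention.

The two-partition variant duplicates the molecule universe with partition
tags; reactions never mix partitions while catalysis draws run over the
full molecule × target product, so catalysis can cross — a minimal stand-in
for coupled metabolic/genetic subnetworks.

`estimate_transition` sweeps mean-catalysis levels, draws `replicates`
CRSs per level (child seeds from a SeedSequence over the master seed) and
records the fraction with a non-empty maximal RAF. The critical level is
the linear interpolation of the first upward crossing of 1/2 — the
simplest defensible estimator, and documented so results are comparable;
no crossing in range is reported as a status, not an exception. At the
default conditions (n = 8, 100 replicates, levels 0.5–3.0) the estimate is
stable to about ±0.05 across master seeds because the transition is sharp.

`random_crs` draws small arbitrary CRSs (≤ 12 reactions) purely for
cross-validation against brute-force subset enumeration; it models no
particular chemistry.

What the generators do **not** emulate: real reaction energetics or
selectivity, molecule abundances, spatial structure, template-directed
replication, or empirically derived catalysis networks. Passing tests
therefore demonstrate the set-theoretic machinery and the random-model
phase behaviour, not claims about any specific experimental chemistry.

## Problem sizes and verification

The exact algorithms are cross-checked against independent brute-force
oracles (naive sweep closures; 2^|R| subset enumeration) on 200 seeded
random systems with |R| ≤ 12, and the closure/RAF invariants (extensive,
monotone, idempotent closure; union-closedness of RAFs; monotonicity of
the maximal RAF under added catalysis; CAF ⊆ RAF) run as property tests.
The phase-transition check uses n = 8, 100 replicates at six levels — the
size at which the model is conventionally reported and comfortably
desk-scale.

## Known limitations

* Sub-RAF enumeration and inhibition handling are exponential by design;
  the polynomial special-case algorithm for bounded inhibitor counts is not
  implemented, nor are pseudo-RAFs or any dynamics on RAF networks.
* `find_irr_raf` samples one irrRAF per seed; it does not enumerate the
  (potentially exponentially many) irrRAFs of a large maximal RAF.
* The scaling of the critical catalysis level with polymer length n is not
  swept; only the n = 8 conditions are measured here.
* The CRS text dialect is package-specific; SBML import/export is future
  work (the set-theoretic CRS does not align with SBML's kinetic focus).
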