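"""Brute-force reference implementations used to cross-check rafkit.

These deliberately share no code with the package: closures are computed by
naive repeated sweeps and RAF detection by testing every subset, so they
serve as independent oracles on small instances.
"""


def naive_closure(crs, reaction_ids, start):
    """Fixed point by repeated full sweeps over the reaction list."""
    W = set(start)
    changed = True
    while changed:
        changed = False
        for rid in reaction_ids:
            r = crs.reactions[rid]
            if set(r.reactants) <= W and not set(r.products) <= W:
                W |= set(r.products)
                changed = True
    return W


def naive_is_raf(crs, subset):
    """Direct check of the RA and F conditions against the naive closure."""
    subset = set(subset)
    if not subset:
        return False
    W = naive_closure(crs, subset, crs.food)
    for rid in subset:
        r = crs.reactions[rid]
        if not set(r.reactants) <= W:
            return False
        if not any((m, rid) in crs.catalysis for m in W):
            return False
    return True


def brute_force_rafs(crs):
    """Every RAF subset, found by exhaustive subset testing."""
    rids = sorted(crs.reactions)
    found = []
    for mask in range(1, 1 << len(rids)):
        subset = frozenset(rids[i] for i in range(len(rids)) if mask >> i & 1)
        if naive_is_raf(crs, subset):
            found.append(subset)
    return found


def brute_max_raf(crs):
    """Union of all RAF subsets — the maximal RAF, by enumeration."""
    union = set()
    for subset in brute_force_rafs(crs):
        union |= subset
    return union
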