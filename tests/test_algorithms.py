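"""Closure, RAF/CAF detection, irrRAFs, sub-RAF enumeration, inhibition."""
import pytest

from _oracles import brute_force_rafs, brute_max_raf, naive_closure
from conftest import family_ids
from rafkit import (CRS, Reaction, closure, enumerate_subrafs, find_irr_raf,
                    is_co_raf, is_raf, max_caf, max_raf,
                    max_raf_with_inhibition, random_crs, relative_food,
                    worked_example)
from rafkit.errors import (NoRafError, PreconditionError, SizeLimitError,
                           UnknownIdError)

CORE = {"r1", "r2", "r3"}
EXTENDED_FOOD = {"f1", "f2", "f3", "a", "b", "c", "d"}


class TestClosure:
    def test_core_closure_is_the_extended_food_set(self, example5):
        assert closure(example5, CORE, {"f1", "f2", "f3"}) == EXTENDED_FOOD

    def test_no_reactions_is_identity(self, example5):
        assert closure(example5, set(), {"f1", "e"}) == {"f1", "e"}

    def test_all_reactions_reach_all_molecules(self, example3):
        assert closure(example3) == set(example3.molecules)

    def test_unknown_ids_rejected(self, example5):
        with pytest.raises(UnknownIdError):
            closure(example5, {"nope"}, None)
        with pytest.raises(UnknownIdError):
            closure(example5, None, {"nope"})

    @pytest.mark.parametrize("seed", range(15))
    def test_matches_naive_fixed_point(self, seed):
        crs = random_crs(seed)
        rids = sorted(crs.reactions)[::2]
        assert closure(crs, rids) == naive_closure(crs, rids, crs.food)


class TestIsRaf:
    def test_full_worked_example_is_a_raf(self, example5):
        assert is_raf(example5, set(example5.reactions))

    def test_periphery_alone_is_not(self, example5, periphery5):
        check = is_raf(example5, periphery5)
        assert not check
        assert "r4" in check.failures
        assert "F condition" in check.failures["r4"]

    def test_empty_subset_is_not_a_raf(self, example5):
        assert not is_raf(example5, set())

    def test_diagnostics_name_the_missing_catalyst(self):
        crs = CRS.build(reactions=[Reaction("r1", ("f",), ("x",))], food=["f"])
        check = is_raf(crs, {"r1"})
        assert "RA condition" in check.failures["r1"]


class TestMaxRaf:
    @pytest.mark.parametrize("L", [2, 3, 5, 10])
    def test_worked_example_maxraf_is_everything(self, L):
        crs = worked_example(L)
        result = max_raf(crs)
        assert result.status == "raf"
        assert result.reactions == set(crs.reactions)

    def test_no_catalysis_means_no_raf(self, example5):
        stripped = CRS(molecules=example5.molecules,
                       reactions=example5.reactions,
                       catalysis=frozenset(), food=example5.food)
        result = max_raf(stripped)
        assert result.status == "none" and not result.reactions

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_union_of_all_raf_subsets(self, seed):
        crs = random_crs(seed)
        assert max_raf(crs).reactions == brute_max_raf(crs)

    def test_result_passes_is_raf_when_nonempty(self):
        for seed in range(40):
            crs = random_crs(seed)
            result = max_raf(crs)
            if result:
                assert is_raf(crs, result.reactions)


class TestMaxCaf:
    def test_worked_example_is_not_constructible(self, example5):
        assert max_caf(example5) == frozenset()

    def test_reaction_with_food_reactants_and_catalyst_is_constructible(self):
        crs = CRS.build(reactions=[Reaction("r1", ("f1",), ("x",))],
                        catalysis=[("f2", "r1")], food=["f1", "f2"])
        assert max_caf(crs) == {"r1"}

    def test_caf_chains_through_new_products(self):
        crs = CRS.build(reactions=[Reaction("r1", ("f1",), ("x",)),
                                   Reaction("r2", ("x",), ("y",))],
                        catalysis=[("f1", "r1"), ("x", "r2")], food=["f1"])
        assert max_caf(crs) == {"r1", "r2"}

    @pytest.mark.parametrize("seed", range(50))
    def test_contained_in_max_raf(self, seed):
        crs = random_crs(seed)
        assert max_caf(crs) <= max_raf(crs).reactions


class TestFindIrrRaf:
    @pytest.mark.parametrize("seed", [0, 1, 7, 42, 12345])
    def test_worked_example_unique_irr_raf(self, example5, seed):
        assert find_irr_raf(example5, seed) == CORE

    def test_already_irreducible_maxraf_is_returned(self, example5):
        sub = example5.restrict(CORE)
        assert find_irr_raf(sub, seed=0) == CORE

    def test_requires_a_raf(self, example5):
        stripped = CRS(molecules=example5.molecules,
                       reactions=example5.reactions,
                       catalysis=frozenset(), food=example5.food)
        with pytest.raises(NoRafError):
            find_irr_raf(stripped, seed=0)

    @pytest.mark.parametrize("seed", range(20))
    def test_result_is_an_irreducible_raf(self, seed):
        crs = random_crs(seed)
        if not max_raf(crs):
            return
        irr = find_irr_raf(crs, seed)
        assert is_raf(crs, irr)
        for rid in irr:
            assert not max_raf(crs, within=irr - {rid})


class TestEnumerateSubrafs:
    def test_worked_example_l3_has_four_subrafs(self, example3):
        lattice = enumerate_subrafs(example3)
        expected = [frozenset(CORE),
                    frozenset(CORE | {"r4"}),
                    frozenset(CORE | {"r4", "r5_2"}),
                    frozenset(CORE | {"r4", "r5_2", "r5_3"})]
        assert list(lattice) == expected
        # a strict chain in the containment order
        assert lattice.hasse_edges == ((0, 1), (1, 2), (2, 3))

    def test_no_catalysis_no_subrafs(self, example5):
        stripped = CRS(molecules=example5.molecules,
                       reactions=example5.reactions,
                       catalysis=frozenset(), food=example5.food)
        assert len(enumerate_subrafs(stripped)) == 0

    def test_matches_brute_force_on_random_systems(self):
        for seed in range(10):
            crs = random_crs(seed, max_reactions=8)
            assert sorted(enumerate_subrafs(crs),
                          key=lambda s: (len(s), tuple(sorted(s)))) == \
                sorted(brute_force_rafs(crs),
                       key=lambda s: (len(s), tuple(sorted(s))))

    def test_union_of_subrafs_is_a_subraf(self, example3):
        lattice = enumerate_subrafs(example3)
        rafs = set(lattice)
        for a in rafs:
            for b in rafs:
                assert a | b in rafs

    def test_size_limit_advises_irr_raf_search(self):
        crs = worked_example(18)  # 4 + 17 = 21 reactions
        with pytest.raises(SizeLimitError, match="find_irr_raf"):
            enumerate_subrafs(crs)


class TestRelativeFood:
    def test_core_extended_food(self, example5):
        assert relative_food(example5, CORE) == EXTENDED_FOOD

    def test_full_raf_gives_closure_of_everything(self, example5):
        assert relative_food(example5, set(example5.reactions)) == \
            closure(example5)

    def test_requires_a_raf(self, example5):
        with pytest.raises(PreconditionError):
            relative_food(example5, {"r4"})

    def test_monotone_over_the_subraf_chain(self, example3):
        lattice = enumerate_subrafs(example3)
        foods = [relative_food(example3, s) for s in lattice]
        for small, large in zip(foods, foods[1:]):
            assert small <= large


class TestIsCoRaf:
    def test_periphery_is_a_co_raf_of_the_core(self, example5, periphery5):
        assert is_co_raf(example5, periphery5, CORE) is True

    def test_overlap_with_reference_rejected(self, example5):
        with pytest.raises(PreconditionError):
            is_co_raf(example5, CORE, CORE)

    def test_a_raf_is_never_a_co_raf(self):
        # two independent self-sustaining loops: each is a plain RAF, so
        # neither is a co-RAF of the other
        crs = CRS.build(reactions=[Reaction("rA", ("f",), ("x",)),
                                   Reaction("rB", ("f",), ("y",))],
                        catalysis=[("x", "rA"), ("y", "rB")], food=["f"])
        assert is_co_raf(crs, {"rA"}, {"rB"}) is False

    def test_core_reference_must_be_raf(self, example5, periphery5):
        with pytest.raises(PreconditionError):
            is_co_raf(example5, CORE, periphery5)

    def test_family_alone_is_not_a_co_raf(self, example5):
        # e is not in the extended food set, so the F condition fails
        assert is_co_raf(example5, set(family_ids(5)), CORE) is False


class TestInhibition:
    def test_producible_inhibitor_kills_every_raf(self, example5):
        crs = CRS(molecules=example5.molecules, reactions=example5.reactions,
                  catalysis=example5.catalysis, food=example5.food,
                  inhibition=frozenset({("d", "r1")}))
        result = max_raf_with_inhibition(crs)
        assert result.status == "none" and not result.reactions

    def test_without_inhibition_reduces_to_max_raf(self, example5):
        assert max_raf_with_inhibition(example5).reactions == \
            max_raf(example5).reactions

    def test_size_limit_enforced(self):
        crs = worked_example(18)
        crs = CRS(molecules=crs.molecules, reactions=crs.reactions,
                  catalysis=crs.catalysis, food=crs.food,
                  inhibition=frozenset({("d", "r1")}))
        with pytest.raises(SizeLimitError):
            max_raf_with_inhibition(crs)

    @pytest.mark.parametrize("seed", range(50))
    def test_result_is_self_consistent(self, seed):
        import numpy as np
        crs = random_crs(seed, max_reactions=10)
        rng = np.random.default_rng(seed + 1000)
        mols = sorted(crs.molecules)
        pairs = {(mols[int(rng.integers(len(mols)))], rid)
                 for rid in crs.reactions if rng.random() < 0.3}
        pairs -= crs.catalysis
        crs = CRS(molecules=crs.molecules, reactions=crs.reactions,
                  catalysis=crs.catalysis, food=crs.food,
                  inhibition=frozenset(pairs))
        result = max_raf_with_inhibition(crs)
        if result:
            check = is_raf(crs, result.reactions)
            assert check
            for rid in result.reactions:
                inhibitors = {m for m, r in crs.inhibition if r == rid}
                assert not (inhibitors & check.support)
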