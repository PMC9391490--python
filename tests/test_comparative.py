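"""Diet summaries, the mass-rate permutation test, and BM ancestral states."""

import dendropy
import numpy as np
import pytest

from dentinechron.comparative import (
    ASRResult,
    DietCategory,
    TaxonTrait,
    bm_ancestral_states,
    branch_gradient,
    group_summary,
    mass_rate_association,
)
from dentinechron.errors import (
    IncompleteDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)
from oracles import brute_force_permutation_p, gls_ancestral_states, random_binary_tree


def trait(taxon, diet=DietCategory.CARNIVORE, **kw):
    return TaxonTrait(taxon=taxon, diet=diet, **kw)


class TestGroupSummary:
    def test_herbivore_family_rate_range(self):
        traits = [
            trait("Oromycter", DietCategory.HERBIVORE, rate_days=391),
            trait("Ennatosaurus_d07", DietCategory.HERBIVORE, rate_days=431),
            trait("Ennatosaurus_d08", DietCategory.HERBIVORE, rate_days=459),
            trait("Edaphosaurus", DietCategory.HERBIVORE, rate_days=381),
        ]
        df = group_summary(traits)
        row = df[(df.diet == "herbivore") & (df.trait == "rate_days")].iloc[0]
        assert row["min"] == 381 and row["max"] == 459

    def test_minima_excluded_from_mean_kept_in_range(self):
        traits = [
            trait("A", rate_days=100),
            trait("B", rate_days=300, rate_is_min=True),
        ]
        df = group_summary(traits)
        row = df[df.trait == "rate_days"].iloc[0]
        assert row["mean"] == 100.0
        assert row["max"] == 300
        assert bool(row["range_includes_minima"])

    def test_single_taxon_group(self):
        df = group_summary([trait("A", DietCategory.OMNIVORE, rate_days=77)])
        row = df[df.trait == "rate_days"].iloc[0]
        assert row["mean"] == row["min"] == row["max"] == 77

    def test_empty_groups_omitted(self):
        df = group_summary([trait("A", rate_days=10)])
        assert set(df["diet"]) == {"carnivore"}


class TestMassRateAssociation:
    def test_perfect_linearity(self):
        traits = [
            trait(f"t{i}", body_mass_kg=10.0**i, rate_days=100 + 50 * i)
            for i in range(5)
        ]
        res = mass_rate_association(traits)
        assert res.r == pytest.approx(1.0)
        assert res.exhaustive

    def test_exhaustive_matches_brute_force_at_n4(self):
        masses = [0.5, 3.0, 40.0, 200.0]
        rates = [80.0, 150.0, 95.0, 400.0]
        traits = [
            trait(f"t{i}", body_mass_kg=m, rate_days=int(r))
            for i, (m, r) in enumerate(zip(masses, rates))
        ]
        res = mass_rate_association(traits)
        expected = brute_force_permutation_p(
            np.log10(masses), np.asarray(rates, dtype=float)
        )
        assert res.exhaustive
        assert res.p_perm == pytest.approx(expected, abs=1e-12)

    def test_degenerate_rates_rejected(self):
        traits = [trait(f"t{i}", body_mass_kg=2.0**i, rate_days=100) for i in range(4)]
        with pytest.raises(UndefinedCorrelationError):
            mass_rate_association(traits)

    def test_minimum_rates_excluded(self):
        traits = [
            trait(f"t{i}", body_mass_kg=2.0**i, rate_days=100 + 7 * i) for i in range(4)
        ] + [trait("m", body_mass_kg=50.0, rate_days=500, rate_is_min=True)]
        assert mass_rate_association(traits).n == 4

    def test_monte_carlo_reproducible_under_seed(self):
        rng = np.random.default_rng(5)
        traits = [
            trait(f"t{i}", body_mass_kg=float(m), rate_days=int(r))
            for i, (m, r) in enumerate(
                zip(rng.lognormal(1, 1, 9), rng.integers(50, 400, 9))
            )
        ]
        a = mass_rate_association(traits, n_permutations=2000, seed=42)
        b = mass_rate_association(traits, n_permutations=2000, seed=42)
        assert not a.exhaustive
        assert a.p_perm == b.p_perm


def simple_tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


class TestBMAncestralStates:
    def test_two_tip_symmetry(self):
        res = bm_ancestral_states(simple_tree("(A:1,B:1);"), {"A": 1.0, "B": 3.0})
        assert res.node_states["N0"] == pytest.approx(2.0)

    def test_three_tip_closed_form(self):
        res = bm_ancestral_states(
            simple_tree("((A:1,B:1):1,C:2);"), {"A": 0.0, "B": 0.0, "C": 3.0}
        )
        assert res.node_states["N0"] == pytest.approx(9.0 / 7.0, abs=1e-12)

    def test_star_tree_is_arithmetic_mean(self):
        res = bm_ancestral_states(
            simple_tree("(A:2,B:2,C:2,D:2);"), {"A": 1, "B": 2, "C": 3, "D": 6}
        )
        assert res.node_states["N0"] == pytest.approx(3.0)

    def test_missing_tip_value(self):
        with pytest.raises(IncompleteDataError):
            bm_ancestral_states(simple_tree("(A:1,B:1);"), {"A": 1.0})

    @pytest.mark.parametrize("n_tips", [5, 6, 7, 8])
    def test_agrees_with_gls_closed_form(self, n_tips):
        rng = np.random.default_rng(100 + n_tips)
        for _ in range(5):
            tree, tips = random_binary_tree(n_tips, rng)
            res = bm_ancestral_states(tree, tips)
            oracle = gls_ancestral_states(tree, tips)
            for node_id, expected in oracle.items():
                assert res.node_states[node_id] == pytest.approx(expected, abs=1e-9)

    def test_states_within_tip_range(self):
        rng = np.random.default_rng(7)
        tree, tips = random_binary_tree(8, rng)
        res = bm_ancestral_states(tree, tips)
        lo, hi = min(tips.values()), max(tips.values())
        assert all(lo - 1e-9 <= s <= hi + 1e-9 for s in res.node_states.values())

    def test_shift_and_scale_equivariance(self):
        rng = np.random.default_rng(9)
        tree, tips = random_binary_tree(6, rng)
        base = bm_ancestral_states(tree, tips)
        shifted = bm_ancestral_states(tree, {k: v + 13.5 for k, v in tips.items()})
        scaled = bm_ancestral_states(tree, {k: 2.5 * v for k, v in tips.items()})
        for nid, s in base.node_states.items():
            assert shifted.node_states[nid] == pytest.approx(s + 13.5, abs=1e-9)
            assert scaled.node_states[nid] == pytest.approx(2.5 * s, abs=1e-9)


class TestBranchGradient:
    def test_interior_samples(self):
        res = ASRResult(
            node_states={"p": 0.0, "c": 10.0},
            branch_endpoints={"c": (0.0, 10.0)},
            branch_lengths={"c": 1.0},
        )
        np.testing.assert_allclose(branch_gradient(res, 3)["c"], [2.5, 5.0, 7.5])

    def test_constant_tree_constant_gradient(self):
        res = bm_ancestral_states(
            simple_tree("((A:1,B:1):1,C:2);"), {"A": 5.0, "B": 5.0, "C": 5.0}
        )
        for vals in branch_gradient(res, 4).values():
            np.testing.assert_allclose(vals, 5.0)

    def test_continuity_at_nodes(self):
        rng = np.random.default_rng(3)
        tree, tips = random_binary_tree(6, rng)
        res = bm_ancestral_states(tree, tips)
        # endpoints of the branch into a node and the branches out of it
        # all equal that node's state
        for child_id, (parent_state, child_state) in res.branch_endpoints.items():
            assert child_state == pytest.approx(res.node_states[child_id])


class TestTraitValidation:
    def test_nonpositive_mass_rejected(self):
        with pytest.raises(InvalidInputError):
            TaxonTrait(taxon="x", diet=DietCategory.CARNIVORE, body_mass_kg=0.0)

    def test_empty_trait_list_rejected(self):
        with pytest.raises(InvalidInputError):
            group_summary([])
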