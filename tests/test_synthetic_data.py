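"""Planted-structure generator: exactness, recovery, perturbation."""

import numpy as np
import pytest

from circuitsym.circuits import CircuitError
from circuitsym.group_structure import closure, factorize
from circuitsym.symmetry import (automorphism_group, commutator_norm,
                                 epsilon, find_pseudosymmetries)
from circuitsym.synthetic_data import (PlantSpec, SectorSpec, perturb,
                                       plant_circuit)

from conftest import brute_force_automorphisms


def pair_spec(hub_weight=1):
    return PlantSpec(
        hubs=("hub",),
        sectors=(SectorSpec("C_2", ("x", "y"), hub_weight=hub_weight),),
    )


SPEC_GRID = [
    pair_spec(),
    PlantSpec(hubs=("hub",),
              sectors=(SectorSpec("S_4", ("a", "b", "c", "d")),
                       SectorSpec("C_2", ("p", "q"), hub_weight=3))),
    PlantSpec(hubs=("h1", "h2"), hub_edges=(("h1", "h2", 2),),
              hub_pairs=(("h1", "h2"),),
              sectors=(SectorSpec("S_3", ("m1", "m2", "m3")),
                       # coupling [[1,1],[1,0]] leaves exactly the
                       # block-swap involution (a c)(b d) intact
                       SectorSpec("D_1", ("a", "b", "c", "d"),
                                  hub_weight=2,
                                  blocks=(("a", "b"), ("c", "d")),
                                  coupling=((1, 1), (1, 0))))),
]


class TestPlant:
    def test_pair_on_hub_contains_transposition(self):
        c, truth = plant_circuit(pair_spec())
        for gens in truth.generators:
            for g in gens:
                assert commutator_norm(c, g) == 0

    def test_forward_fixture_group_order_by_oracle(self, forward_fixture):
        c, truth = forward_fixture
        grp = automorphism_group(c)
        # the planted direct product is the whole group: order
        # 2*2*120*2*2*2 = 3840 with six factors
        assert grp.order == 3840
        assert truth.group().elements == grp.elements
        # sector-wise brute-force oracle: enumerate all permutations that
        # fix everything outside one sector, count the exact ones
        import itertools

        sector_orders = []
        for sector in truth.sectors:
            idx = [c.labels.index(l) for l in sector]
            count = 0
            A = c.weights
            for perm in itertools.permutations(idx):
                imgs = list(range(c.n))
                for i, j in zip(idx, perm):
                    imgs[i] = j
                imgs = np.asarray(imgs)
                if np.array_equal(A, A[np.ix_(imgs, imgs)]):
                    count += 1
            sector_orders.append(count)
        assert int(np.prod(sector_orders)) == grp.order

    def test_aib_rim_involution_exact(self, aib_rim):
        c, truth = aib_rim
        (gen,) = truth.generators[0]
        assert commutator_norm(c, gen) == 0
        assert gen.support == frozenset({"AIBL", "AIBR", "RIML", "RIMR"})

    def test_breaking_coupling_is_detected(self):
        spec = PlantSpec(
            hubs=("hub",),
            sectors=(SectorSpec("D_1", ("a", "b", "c", "d"),
                                hub_weight={"a": 1, "b": 2,
                                            "c": 9, "d": 9},
                                blocks=(("a", "b"), ("c", "d")),
                                coupling=((1, 0), (0, 1))),),
        )
        with pytest.raises(CircuitError, match="broken"):
            plant_circuit(spec)

    @pytest.mark.parametrize("spec", SPEC_GRID)
    def test_recovery_of_planted_structure_at_eps_zero(self, spec):
        c, truth = plant_circuit(spec)
        grp = automorphism_group(c)
        fact = factorize(grp)
        assert not fact.residual
        assert sorted(fact.sectors) == sorted(truth.sectors)
        assert sorted(fact.names()) == sorted(truth.names)

    @pytest.mark.parametrize("spec", SPEC_GRID[:2])
    def test_planted_group_matches_exhaustive_oracle(self, spec):
        c, truth = plant_circuit(spec)
        if c.n <= 7:
            grp = automorphism_group(c)
            oracle = {p.images for p in brute_force_automorphisms(c)}
            assert grp.elements == oracle


class TestPerturb:
    def test_zero_fraction_is_identity(self, forward_fixture):
        c, _ = forward_fixture
        out, realized = perturb(c, 0.0, seed=1)
        assert out == c and realized == 0.0

    def test_single_broken_link_gives_expected_eps(self):
        # remove one unit so the analyzed circuit has 20 link units and
        # the planted pair swap reads eps = 1/20 = 0.05
        spec = PlantSpec(
            hubs=("hub", "pad"),
            hub_edges=(("hub", "pad", 13),),
            sectors=(SectorSpec("C_2", ("x", "y"), hub_weight=2),),
        )
        c, truth = plant_circuit(spec)
        assert c.total_weight == 21
        A = c.weights.copy()
        i, j = c.labels.index("x"), c.labels.index("hub")
        A[i, j] -= 1
        A[j, i] -= 1
        from circuitsym.circuits import Circuit

        broken = Circuit(c.labels, A, directed=c.directed,
                         link_type=c.link_type)
        (gen,) = truth.generators[0]
        assert epsilon(broken, gen).eps == pytest.approx(1 / 20)
        found = find_pseudosymmetries(broken, eps_max=0.06)
        assert any(s.perm.support == {"x", "y"} and
                   s.eps == pytest.approx(0.05) for s in found["swaps"])

    @pytest.mark.parametrize("seed", range(25))
    def test_generator_eps_bounded_by_twice_fraction(self, seed,
                                                     forward_fixture):
        c, truth = forward_fixture
        f = 0.1
        out, realized = perturb(c, f, seed=seed)
        assert realized == pytest.approx(round(f * c.total_weight)
                                         / c.total_weight)
        for gens in truth.generators:
            for g in gens:
                # each changed link unit shifts at most two orbit
                # comparisons; denominator uses the unperturbed M
                norm = commutator_norm(out, g)
                assert norm / c.total_weight <= 2 * realized + 1e-12

    def test_quarter_variability_usually_leaves_plausible_generator(
            self, forward_fixture):
        c, truth = forward_fixture
        hits = 0
        trials = 30
        for seed in range(trials):
            out, _ = perturb(c, 0.25, seed=seed)
            gens = [g for gs in truth.generators for g in gs]
            if any(epsilon(out, g).eps <= 0.25 for g in gens):
                hits += 1
        assert hits >= trials * 0.9

    def test_realized_fraction_reported(self, forward_fixture):
        c, _ = forward_fixture
        out, realized = perturb(c, 0.25, seed=0)
        assert realized == round(0.25 * c.total_weight) / c.total_weight
        delta = np.abs(out.weights.astype(int) - c.weights.astype(int)).sum()
        assert delta > 0

    def test_yaml_round_trip(self):
        spec = SPEC_GRID[2]
        again = PlantSpec.from_yaml(spec.to_yaml())
        assert again == spec
        c1, _ = plant_circuit(spec)
        c2, _ = plant_circuit(again)
        assert c1 == c2
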