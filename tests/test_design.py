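"""Candidate mutations, Pareto designs and the cross-model merge rules."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from conftest import single_atom_structure
from episcope.design import (ContactStabilityScorer, DesignParams, Mutation,
                             SolvationStabilityScorer, allowed_substitutions,
                             candidate_mutations, disruptiveness,
                             merge_and_annotate, pareto_designs,
                             stability_delta)
from episcope.docking import DockingEnsemble, DockingModel
from episcope.potentials import AMINO_ACIDS, PairPotential, default_potential
from episcope.structures import ResidueKey, Structure, mean_pairwise_ca_distance


def additive_potential(values: dict[str, float]) -> PairPotential:
    """p(a, b) = v_a + v_b — so p(mut, x) - p(wt, x) = v_mut - v_wt."""
    v = np.array([values.get(a, 0.0) for a in AMINO_ACIDS])
    return PairPotential(v[:, None] + v[None, :], name="additive")


def sparse_potential(entries: dict[tuple[str, str], float]) -> PairPotential:
    m = np.zeros((20, 20))
    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    for (a, b), val in entries.items():
        m[idx[a], idx[b]] = m[idx[b], idx[a]] = val
    return PairPotential(m, name="sparse")


def line_antigen(seq, spacing=6.0):
    return single_atom_structure(
        [("A", i + 1, aa, (i * spacing, 0.0, 0.0)) for i, aa in enumerate(seq)])


def pose_over(antigen, numbers, ab_seq=None, height=4.0, model_id="m0"):
    ab_seq = ab_seq or "Y" * len(numbers)
    spec = []
    for j, (n, aa) in enumerate(zip(numbers, ab_seq)):
        ca = antigen.ca(ResidueKey("A", n))
        spec.append(("H", j + 1, aa, (ca[0], ca[1] + height, ca[2])))
    return DockingModel(id=model_id, ab=single_atom_structure(spec), ag=antigen)


class TestAllowedSubstitutions:
    def test_column_tally(self):
        ag = line_antigen("AC")
        msa = ["AC", "AC", "SC", "-C"]
        table = allowed_substitutions(msa, ag)
        assert table[ResidueKey("A", 1)] == {"S"}
        assert table[ResidueKey("A", 2)] == set()  # identical in all homologs

    def test_gapped_reference_row(self):
        ag = line_antigen("AC")
        msa = ["A-C", "AGC", "SG-"]
        table = allowed_substitutions(msa, ag)
        assert table[ResidueKey("A", 1)] == {"S"}
        assert table[ResidueKey("A", 2)] == set()

    def test_min_count(self):
        ag = line_antigen("A")
        msa = ["A", "S", "S", "T"]
        assert allowed_substitutions(msa, ag, min_count=2)[ResidueKey("A", 1)] == {"S"}

    def test_hand_tallied_synthetic_msa(self, rng):
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=12))
        ag = line_antigen(seq)
        rows = ["".join(rng.choice(list(AMINO_ACIDS), size=12)) for _ in range(5)]
        table = allowed_substitutions([seq] + rows, ag)
        for i, wt in enumerate(seq):
            expected = {r[i] for r in rows if r[i] != wt}
            assert table[ResidueKey("A", i + 1)] == expected

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="match the antigen"):
            allowed_substitutions(["AAC", "AAC"], line_antigen("AA"))


class TestDisruptiveness:
    def test_wild_type_is_zero(self):
        ag = line_antigen("AAAA")
        m = pose_over(ag, [2])
        assert disruptiveness(ResidueKey("A", 2), "A", m, default_potential()) == 0.0

    def test_constructed_shift_counts_contacts(self):
        """p(mut, .) = p(wt, .) + 1 and 3 antibody contacts -> 3.0."""
        ag = line_antigen("AAAA", spacing=2.0)
        # three antibody atoms all within 5 A of residue 2
        ca = ag.ca(ResidueKey("A", 2))
        spec = [("H", j + 1, "Y", (ca[0], ca[1] + 3.0 + 0.5 * j, ca[2]))
                for j in range(3)]
        m = DockingModel(id="m0", ab=single_atom_structure(spec), ag=ag)
        p = additive_potential({"S": 1.0, "A": 0.0})
        assert disruptiveness(ResidueKey("A", 2), "S", m, p) == pytest.approx(3.0)

    def test_antisymmetric_under_role_swap(self):
        ag_fwd = line_antigen("A")
        ag_rev = line_antigen("S")
        p = additive_potential({"S": 2.0, "A": 0.5})
        fwd = disruptiveness(ResidueKey("A", 1), "S",
                             pose_over(ag_fwd, [1]), p)
        rev = disruptiveness(ResidueKey("A", 1), "A",
                             pose_over(ag_rev, [1]), p)
        assert fwd == pytest.approx(-rev)

    def test_outside_footprint_rejected(self):
        ag = line_antigen("AAAA")
        m = pose_over(ag, [1])
        with pytest.raises(ValueError, match="outside"):
            disruptiveness(ResidueKey("A", 4), "S", m, default_potential())


class TestStabilityDelta:
    def test_empty_set_is_zero(self):
        assert stability_delta(line_antigen("AAA"), []) == 0.0

    def test_no_intra_contacts_is_zero(self):
        ag = line_antigen("AAA", spacing=20.0)
        mut = Mutation(ResidueKey("A", 2), "A", "S")
        assert stability_delta(ag, [mut], ContactStabilityScorer()) == 0.0

    def test_hand_summed_contact_delta(self):
        """3-residue toy: the delta equals the summed pairwise differences."""
        ag = line_antigen("ACD", spacing=4.0)  # neighbours within 5 A only
        p = sparse_potential({("S", "C"): 2.0, ("A", "C"): 0.5,
                              ("S", "D"): -1.0, ("A", "D"): 0.0})
        mut = Mutation(ResidueKey("A", 1), "A", "S")
        # position 1 contacts only residue 2 (C) at 4 A
        got = stability_delta(ag, [mut], ContactStabilityScorer(potential=p))
        assert got == pytest.approx((2.0 - 0.5))

    def test_clash_penalty_infinite(self):
        ag = line_antigen("AAA", spacing=2.0)
        muts = [Mutation(ResidueKey("A", 1), "A", "S"),
                Mutation(ResidueKey("A", 2), "A", "T")]
        assert stability_delta(ag, muts, ContactStabilityScorer()) == np.inf

    def test_solvation_scorer_favours_polar_at_exposed_sites(self):
        ag = line_antigen("LLL", spacing=20.0)  # fully exposed, no contacts
        mut_polar = Mutation(ResidueKey("A", 2), "L", "D")
        mut_hydro = Mutation(ResidueKey("A", 2), "L", "I")
        scorer = SolvationStabilityScorer()
        assert scorer(ag, [mut_polar]) < 0 < scorer(ag, [mut_hydro])


class TestCandidateMutations:
    def _subs(self, table):
        from episcope.design import SubstitutionTable

        return SubstitutionTable(allowed={
            ResidueKey("A", n): set(aas) for n, aas in table.items()})

    def test_footprint_disjoint_from_surface(self):
        ag = line_antigen("AAAA")
        m = pose_over(ag, [1, 2])
        out = candidate_mutations(m, {ResidueKey("A", 4)},
                                  self._subs({4: "S"}), default_potential())
        assert out == []

    def test_sign_filter(self):
        ag = line_antigen("AAAA")
        m = pose_over(ag, [2])
        p = additive_potential({"D": 2.0, "G": -1.0, "A": 0.0})
        out = candidate_mutations(m, set(ag.keys()),
                                  self._subs({2: "DG"}), p)
        assert [(mu.position.number, mu.mut) for mu in out] == [(2, "D")]

    def test_matches_exhaustive_enumeration(self, small_scenario):
        sc = small_scenario
        p = default_potential()
        table = allowed_substitutions([q for _, q in sc.msa], sc.antigen)
        surface = set(sc.antigen.keys())
        for m in sc.ensemble.models[:3]:
            got = {(mu.position, mu.mut) for mu in
                   candidate_mutations(m, surface, table, p)}
            expected = set()
            for pos in m.footprint & surface:
                for aa in table[pos]:
                    if aa != m.ag.residues[pos].aa and \
                       disruptiveness(pos, aa, m, p) > 0:
                        expected.add((pos, aa))
            assert got == expected


class TestParetoDesigns:
    def _setup(self, scores, stabilities, positions=None, spacing=6.0):
        """Candidates with prescribed per-position score and stability."""
        n = len(scores)
        positions = positions or list(range(1, n + 1))
        ag = line_antigen("A" * max(positions), spacing=spacing)
        m = pose_over(ag, positions, model_id="m0")
        cands = [Mutation(ResidueKey("A", pos), "A", "S", (("m0", sc),))
                 for pos, sc in zip(positions, scores)]
        stab_map = {ResidueKey("A", pos): st
                    for pos, st in zip(positions, stabilities)}

        def scorer(s, muts):
            return sum(stab_map[mu.position] for mu in muts)

        return ag, m, cands, scorer, stab_map

    @pytest.mark.parametrize("k", [1, 2, 3, 4])
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_frontier(self, k, seed):
        rng = np.random.default_rng(seed)
        n = 8
        scores = rng.uniform(0.5, 5.0, size=n)
        stabilities = rng.uniform(-2.0, 0.5, size=n)
        ag, m, cands, scorer, stab_map = self._setup(scores, stabilities,
                                                     spacing=3.0)
        params = DesignParams(k=k, max_spread=12.0)
        got = pareto_designs(m, cands, params, ag, scorer)
        # independent oracle: enumerate, filter, dominance-check
        feasible = []
        for combo in itertools.combinations(range(n), min(k, n)):
            keys = [ResidueKey("A", i + 1) for i in combo]
            spread = mean_pairwise_ca_distance(ag, keys)
            stab = sum(stab_map[key] for key in keys)
            if spread > params.max_spread or stab > 0:
                continue
            feasible.append((tuple(keys), scores[list(combo)].sum(), stab))
        frontier = set()
        for keys, d, st in feasible:
            if not any((d2 >= d and st2 <= st) and (d2 > d or st2 < st)
                       for _, d2, st2 in feasible):
                frontier.add(keys)
        assert {d.positions for d in got} == frontier
        for d in got:  # annotations are consistent
            assert d.stability_delta <= 0
            assert d.spread <= params.max_spread

    def test_most_disruptive_substitution_per_position(self):
        ag = line_antigen("AAA")
        m = pose_over(ag, [1, 2])
        cands = [Mutation(ResidueKey("A", 1), "A", "S", (("m0", 1.0),)),
                 Mutation(ResidueKey("A", 1), "A", "D", (("m0", 3.0),)),
                 Mutation(ResidueKey("A", 2), "A", "T", (("m0", 2.0),))]
        got = pareto_designs(m, cands, DesignParams(k=2), ag,
                             lambda s, muts: -1.0)
        assert len(got) == 1
        assert {mu.mut for mu in got[0].mutations} == {"D", "T"}
        assert got[0].total_disruption == pytest.approx(5.0)

    def test_spread_filter_empties_output(self):
        scores = [1.0, 1.0, 1.0]
        ag, m, cands, scorer, _ = self._setup(scores, [-1.0] * 3, spacing=20.0)
        got = pareto_designs(m, cands, DesignParams(k=3), ag, scorer)
        assert got == []

    def test_single_candidate_k1(self):
        ag, m, cands, scorer, _ = self._setup([2.0], [-1.0])
        got = pareto_designs(m, cands, DesignParams(k=1), ag, scorer)
        assert len(got) == 1
        assert got[0].spread == 0.0
        assert len(got[0].mutations) == 1

    def test_cap_and_deterministic_order(self):
        rng = np.random.default_rng(0)
        ag, m, cands, scorer, _ = self._setup(rng.uniform(1, 2, 6),
                                              rng.uniform(-2, -0.1, 6),
                                              spacing=3.0)
        params = DesignParams(k=2, pareto_cap=2)
        got = pareto_designs(m, cands, params, ag, scorer)
        assert len(got) <= 2
        again = pareto_designs(m, cands, params, ag, scorer)
        assert [d.positions for d in got] == [d.positions for d in again]


class TestMergeAndAnnotate:
    def test_anti_disruptive_mutation_removed(self):
        """A mutation must disrupt every model whose footprint contains it."""
        ag = line_antigen("AAAA")
        m1 = pose_over(ag, [1, 2], ab_seq="RR", model_id="m1")
        m2 = pose_over(ag, [2, 3], ab_seq="DD", model_id="m2")
        e = DockingEnsemble(models=[m1, m2], antigen=ag)
        # S at position 2 disrupts the R-paratope but favours the D-paratope
        p = sparse_potential({("S", "R"): 2.0, ("S", "D"): -1.0})
        d = pareto_designs(m1, candidate_mutations(
            m1, set(ag.keys()),
            _table({1: "S", 2: "S"}), p),
            DesignParams(k=2), ag, lambda s, mu: -1.0)
        merged = merge_and_annotate(d, e, p, lambda s, mu: -1.0)
        for design in merged:
            assert all(mu.position != ResidueKey("A", 2)
                       for mu in design.mutations)

    def test_identical_position_unified_to_most_disruptive(self):
        ag = line_antigen("AAAA")
        m1 = pose_over(ag, [1, 2], model_id="m1")
        m2 = pose_over(ag, [2, 3], model_id="m2")
        e = DockingEnsemble(models=[m1, m2], antigen=ag)
        p = sparse_potential({("E", "Y"): 3.0, ("Q", "Y"): 1.0, ("T", "Y"): 0.5})
        designs = (
            pareto_designs(m1, [Mutation(ResidueKey("A", 2), "A", "E", (("m1", 6.0),)),
                                Mutation(ResidueKey("A", 1), "A", "T", (("m1", 0.5),))],
                           DesignParams(k=2), ag, lambda s, mu: -1.0)
            + pareto_designs(m2, [Mutation(ResidueKey("A", 2), "A", "Q", (("m2", 2.0),)),
                                  Mutation(ResidueKey("A", 3), "A", "T", (("m2", 0.5),))],
                             DesignParams(k=2), ag, lambda s, mu: -1.0))
        merged = merge_and_annotate(designs, e, p, lambda s, mu: -1.0)
        subs_at_2 = {mu.mut for d in merged for mu in d.mutations
                     if mu.position == ResidueKey("A", 2)}
        assert subs_at_2 == {"E"}

    def test_coverage_matches_brute_force(self, small_scenario):
        from episcope.workflow import design_panel

        sc = small_scenario
        res = design_panel(sc.antigen, sc.ensemble, msa=[q for _, q in sc.msa])
        p = default_potential()
        for d in res.designs:
            expected = set()
            for m in sc.ensemble.models:
                for mu in d.mutations:
                    if mu.position in m.footprint and \
                       disruptiveness(mu.position, mu.mut, m, p) > 0:
                        expected.add(m.id)
            assert set(d.covered_models) == expected

    def test_duplicates_collapsed_and_ids_deterministic(self, small_scenario):
        from episcope.workflow import design_panel

        sc = small_scenario
        res = design_panel(sc.antigen, sc.ensemble, msa=[q for _, q in sc.msa])
        sigs = [tuple((mu.position, mu.mut) for mu in d.mutations)
                for d in res.designs]
        assert len(sigs) == len(set(sigs))
        assert [d.id for d in res.designs] == sorted(
            (d.id for d in res.designs),
            key=lambda x: int("".join(c for c in x if c.isdigit())))


def _table(spec):
    from episcope.design import SubstitutionTable
    from episcope.structures import ResidueKey

    return SubstitutionTable(allowed={
        ResidueKey("A", n): set(aas) for n, aas in spec.items()})
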