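import logging
import math

import numpy as np
import pytest

import glycopath as gp
from glycopath.markov import MarkovError
from glycopath.scoring import ReactionState

from oracles import monte_carlo_absorption


def _pathway(edges, roots=("A",), terminals=None):
    """Tiny pathway from (reaction id, substrate, product) triples."""
    nodes = sorted({x for _, s, p in edges for x in (s, p)})
    substrates = {s for _, s, _ in edges}
    terminals = set(terminals) if terminals is not None else \
        {n for n in nodes if n not in substrates}
    structures = {
        n: gp.GlycanStructure(n, n, {"Man": 1}, is_root=(n in roots),
                              is_terminal=(n in terminals))
        for n in nodes
    }
    reactions = {
        rid: gp.Reaction(rid, s, p, gp.parse_requirement(f"GENE{rid}"))
        for rid, s, p in edges
    }
    return gp.Pathway("tiny", structures, reactions)


def _states(scores):
    return {
        rid: ReactionState(rid, score, "expressed" if score > 0 else "absent",
                           1.0, "black")
        for rid, score in scores.items()
    }


class TestBuildMarkov:
    def test_linear_chain_probability_one(self):
        pathway = _pathway([("r1", "A", "B"), ("r2", "B", "C")])
        model = gp.build_markov(pathway, _states({"r1": 5.0, "r2": 5.0}))
        assert model.transient_states == ["A", "B"]
        assert model.absorbing_states == ["C"]
        assert model.Q[0, 1] == 1.0 and model.R[1, 0] == 1.0

    def test_branch_proportional_to_scores(self):
        pathway = _pathway([("r1", "A", "B"), ("r2", "A", "C")])
        model = gp.build_markov(pathway, _states({"r1": 3.0, "r2": 1.0}))
        dist = gp.absorption_distribution(model)
        assert dist == {"B": 0.75, "C": 0.25}

    def test_exit_weight_adds_escape_states(self):
        pathway = _pathway([("r1", "A", "B"), ("r2", "A", "C")])
        model = gp.build_markov(
            pathway, _states({"r1": 3.0, "r2": 1.0}), exit_weight=4.0
        )
        dist = gp.absorption_distribution(model)
        assert dist["B"] == pytest.approx(0.375)
        assert dist["C"] == pytest.approx(0.125)
        assert dist["exited@A"] == pytest.approx(0.5)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)

    def test_dead_end_converted_to_absorbing_with_warning(self, caplog):
        pathway = _pathway([("r1", "A", "B"), ("r2", "B", "C")],
                           terminals={"C"})
        with caplog.at_level(logging.WARNING, logger="glycopath.markov"):
            model = gp.build_markov(pathway, _states({"r1": 5.0, "r2": 0.0}))
        assert "B" in model.absorbing_states
        assert any("B" in rec.message for rec in caplog.records)
        assert gp.absorption_distribution(model) == {"B": 1.0, "C": 0.0}

    def test_unknown_reactions_carry_no_flux(self, queuosine_pathway):
        profile = gp.ExpressionProfile(
            "q", {g: 10.0 for g in queuosine_pathway.genes}
        )
        states = gp.score_pathway(queuosine_pathway, profile)
        model = gp.build_markov(queuosine_pathway, states)
        dist = gp.absorption_distribution(model)
        # the unknown Q_FREE -> QUEUINE step scores 0: mass stops at Q_FREE
        assert dist["QUEUINE"] == 0.0
        assert dist["Q_FREE"] > 0.0

    def test_no_absorbing_state_rejected(self):
        pathway = _pathway([("r1", "A", "B"), ("r2", "B", "A")],
                           terminals=set())
        with pytest.raises(MarkovError, match="absorbing"):
            gp.build_markov(pathway, _states({"r1": 1.0, "r2": 1.0}))

    def test_negative_exit_weight_rejected(self, toy_pathway,
                                           all_active_profile):
        states = gp.score_pathway(toy_pathway, all_active_profile)
        with pytest.raises(ValueError):
            gp.build_markov(toy_pathway, states, exit_weight=-1.0)


class TestRowStochasticity:
    @pytest.mark.parametrize("seed", range(12))
    @pytest.mark.parametrize("exit_weight", [0.0, 1.0])
    def test_rows_sum_to_one(self, seed, exit_weight):
        pathway = gp.generate_synthetic_pathway(15, 1.6, seed=seed)
        profile = gp.generate_synthetic_expression(
            sorted(set(pathway.genes)), seed=seed
        )
        states = gp.score_pathway(pathway, profile)
        model = gp.build_markov(pathway, states, exit_weight=exit_weight)
        assert np.allclose(model.row_sums(), 1.0, atol=1e-12, rtol=0)


class TestAbsorptionDistribution:
    def test_linear_chain_all_mass_on_terminal(self):
        pathway = _pathway([("r1", "A", "B"), ("r2", "B", "C")])
        model = gp.build_markov(pathway, _states({"r1": 2.0, "r2": 7.0}))
        assert gp.absorption_distribution(model) == {"C": 1.0}

    def test_mass_conservation_random_models(self):
        for seed in range(8):
            pathway = gp.generate_synthetic_pathway(20, 1.5, seed=seed)
            profile = gp.generate_synthetic_expression(pathway.genes, seed=seed)
            states = gp.score_pathway(pathway, profile)
            model = gp.build_markov(pathway, states, exit_weight=0.5)
            dist = gp.absorption_distribution(model)
            assert sum(dist.values()) == pytest.approx(1.0, abs=1e-9)
            assert all(v >= 0 for v in dist.values())

    def test_trapped_cycle_reported(self):
        pathway = _pathway(
            [("r1", "A", "B"), ("r2", "B", "C"), ("r3", "C", "B"),
             ("r4", "A", "D")],
            terminals={"D"},
        )
        # B <-> C loop with no way out: every score positive keeps B, C
        # transient but absorption is unreachable from them
        states = _states({"r1": 1.0, "r2": 1.0, "r3": 1.0, "r4": 1.0})
        model = gp.build_markov(pathway, states)
        with pytest.raises(MarkovError, match="trapped.*'B'"):
            gp.absorption_distribution(model)

    @pytest.mark.parametrize("seed", range(3))
    def test_monte_carlo_agreement(self, seed):
        pathway = gp.generate_synthetic_pathway(15, 1.6, seed=seed)
        profile = gp.generate_synthetic_expression(pathway.genes, seed=seed)
        states = gp.score_pathway(pathway, profile)
        model = gp.build_markov(pathway, states, exit_weight=0.2)
        exact = gp.absorption_distribution(model)
        n_walks = 20_000
        empirical = monte_carlo_absorption(model, n_walks, seed=seed)
        for sid, p in exact.items():
            se = math.sqrt(max(p * (1 - p), 1e-12) / n_walks)
            assert abs(empirical[sid] - p) <= 3 * se + 1e-9

    def test_scale_invariance_without_exit(self, toy_pathway):
        profile = gp.generate_synthetic_expression(toy_pathway.genes, seed=4)
        scaled = gp.ExpressionProfile(
            "x7", {g: 7.0 * v for g, v in profile.tpm.items()}
        )
        dists = []
        for prof in (profile, scaled):
            states = gp.score_pathway(toy_pathway, prof)
            model = gp.build_markov(toy_pathway, states, exit_weight=0.0)
            dists.append(gp.absorption_distribution(model))
        assert dists[0].keys() == dists[1].keys()
        for sid in dists[0]:
            assert dists[0][sid] == pytest.approx(dists[1][sid], abs=1e-12)


class TestExpectedVisits:
    def test_linear_chain_visited_once(self):
        pathway = _pathway([("r1", "A", "B"), ("r2", "B", "C")])
        model = gp.build_markov(pathway, _states({"r1": 1.0, "r2": 1.0}))
        assert gp.expected_visits(model) == {"A": 1.0, "B": 1.0}

    def test_unreachable_state_never_visited(self):
        pathway = _pathway([("r1", "A", "B"), ("r2", "X", "B")],
                           roots=("A",))
        model = gp.build_markov(pathway, _states({"r1": 1.0, "r2": 1.0}))
        visits = gp.expected_visits(model)
        assert visits["X"] == 0.0 and visits["A"] == 1.0

    def test_cycle_geometric_series(self):
        # A -> B (p 1/2), A -> T (p 1/2), B -> A (p 1): return probability
        # 1/2 per loop, so A is visited 1 / (1 - 1/2) = 2 times
        pathway = _pathway(
            [("r1", "A", "B"), ("r2", "A", "T"), ("r3", "B", "A")],
            terminals={"T"},
        )
        model = gp.build_markov(
            pathway, _states({"r1": 1.0, "r2": 1.0, "r3": 1.0})
        )
        visits = gp.expected_visits(model)
        assert visits["A"] == pytest.approx(2.0, abs=1e-12)
        assert visits["B"] == pytest.approx(1.0, abs=1e-12)


class TestKnockdownScan:
    def test_factor_one_is_identity(self, toy_pathway, all_active_profile):
        states = gp.score_pathway(toy_pathway, all_active_profile)
        baseline = gp.absorption_distribution(
            gp.build_markov(toy_pathway, states)
        )
        (scan,) = gp.knockdown_scan(
            toy_pathway, all_active_profile, "MGAT3", [1.0]
        )
        assert scan == baseline

    def test_full_knockdown_zeroes_sole_branch(self, toy_pathway,
                                               all_active_profile):
        (scan,) = gp.knockdown_scan(
            toy_pathway, all_active_profile, "MGAT3", [0.0]
        )
        assert scan["SIA_BIS"] == 0.0

    def test_bisecting_mass_monotone_in_knockdown(self, toy_pathway,
                                                  all_active_profile):
        factors = [1.0, 0.5, 0.2, 0.05, 0.0]
        scans = gp.knockdown_scan(
            toy_pathway, all_active_profile, "MGAT3", factors
        )
        masses = [scan["SIA_BIS"] for scan in scans]
        assert masses == sorted(masses, reverse=True)
        assert masses[0] > 0

    def test_unknown_gene_rejected(self, toy_pathway, all_active_profile):
        with pytest.raises(KeyError, match="NOSUCHGENE"):
            gp.knockdown_scan(toy_pathway, all_active_profile, "NOSUCHGENE",
                              [0.5])

    def test_factor_out_of_range_rejected(self, toy_pathway,
                                          all_active_profile):
        with pytest.raises(ValueError):
            gp.knockdown_scan(toy_pathway, all_active_profile, "MGAT3", [1.5])
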