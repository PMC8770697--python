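"""GPR evaluation, the evidence-agreement MILP, and context model assembly."""

import itertools

import numpy as np
import pytest

import _oracles
from conftest import build_model
from fluxspan import lp_analysis
from fluxspan.context_extraction import (
    ExpressionEvidence,
    GprError,
    ReactionEvidence,
    build_context_model,
    canonicalize_gpr,
    evaluate_gpr,
    gpr_genes,
    imat_extract,
    map_expression_to_reactions,
    parse_gpr,
)
from fluxspan.model_core import Reaction, stoichiometric_matrix
from fluxspan.synthetic_data import ToySpec, planted_expression, toy_host


class TestGpr:
    @pytest.mark.parametrize("gpr,cats,expected", [
        ("g1 and g2", {"g1": "high", "g2": "low"}, "low"),
        ("g1 or g2", {"g1": "low", "g2": "high"}, "high"),
        ("g1 and g2", {"g1": "high", "g2": "NA"}, "high"),
        ("g1 and (g2 or g3)", {"g1": "medium", "g2": "low", "g3": "high"}, "medium"),
        ("g1", {}, None),
        ("", {"g1": "high"}, None),
    ])
    def test_ordinal_evaluation(self, gpr, cats, expected):
        assert evaluate_gpr(gpr, cats) == expected

    def test_genes_extraction(self):
        assert gpr_genes("a and (b or c) and a") == {"a", "b", "c"}

    def test_malformed_raises(self):
        with pytest.raises(GprError):
            parse_gpr("g1 and (g2 or")

    def test_canonicalization_strips_redundant_parens(self):
        assert canonicalize_gpr("(g1 and g2)") == "g1 and g2"
        assert canonicalize_gpr("g1 and (g2 or g3)") == "g1 and (g2 or g3)"

    def test_evaluation_vs_exhaustive_truth_assignment(self):
        """The min/max ordinal shortcut agrees with brute-force evaluation
        over the known-gene sub-expression for every category assignment."""
        gpr = "ga and (gb or gc)"
        order = {"low": 0, "medium": 1, "high": 2}
        inv = {v: k for k, v in order.items()}
        for cats in itertools.product(["high", "medium", "low", "NA"], repeat=3):
            assign = dict(zip(["ga", "gb", "gc"], cats))
            known = {g: c for g, c in assign.items() if c != "NA"}

            def brute(node):
                kind = node[0]
                if kind == "gene":
                    return order.get(known.get(node[1], "NA"))
                vals = [brute(c) for c in node[1]]
                vals = [v for v in vals if v is not None]
                if not vals:
                    return None
                return min(vals) if kind == "and" else max(vals)

            expected = brute(parse_gpr(gpr))
            got = evaluate_gpr(gpr, assign)
            assert got == (None if expected is None else inv[expected])


class TestMapping:
    def test_categories_to_core_sets(self, host):
        ev = ExpressionEvidence({"g_glyc1": "high", "g_glyc2": "medium",
                                 "g_ldh": "low"})
        rev = map_expression_to_reactions(host, ev)
        assert "GLYC" in rev.core_active      # min(high, medium) = medium
        assert "LDH" in rev.core_inactive
        assert "FOLS" in rev.uncategorized    # no informative gene

    def test_overrides_force_categories(self, host):
        ev = ExpressionEvidence({"g_ldh": "low"})
        rev = map_expression_to_reactions(host, ev, overrides={"g_ldh": "high"})
        assert "LDH" in rev.core_active

    def test_boundary_and_biomass_never_categorized(self, host):
        ev = ExpressionEvidence({g: "high" for r in host.reactions
                                 for g in gpr_genes(r.gpr)})
        rev = map_expression_to_reactions(host, ev)
        assert "BIOMASS_host" in rev.uncategorized
        assert all(not rid.startswith("EX_") for rid in rev.core_active)

    def test_invalid_category_rejected(self):
        with pytest.raises(ValueError):
            ExpressionEvidence({"g": "very_high"})


def _tiny_conflict_model():
    """The only route activating the core-active reaction runs through a
    core-inactive one: the MILP must sacrifice a term."""
    m = build_model(
        ["A[c]", "B[c]", "C[c]"],
        [("SRC", {"A[c]": 1}, 0, 10),
         ("RL1", {"A[c]": -1, "B[c]": 1}, 0, 10),
         ("RH1", {"B[c]": -1, "C[c]": 1}, 0, 10),
         ("SNK", {"C[c]": -1}, 0, 10)],
    )
    return m


class TestImat:
    def test_single_core_reaction_activated(self, chain_model):
        rev = ReactionEvidence(core_active=["R1"], core_inactive=[])
        res = imat_extract(chain_model, rev, epsilon=1.0)
        assert res.objective == 1
        assert res.activity["R1"] == "active_fwd"
        assert res.flux["R1"] >= 1.0 - 1e-6

    def test_conflict_instance_matches_enumeration(self):
        m = _tiny_conflict_model()
        rev = ReactionEvidence(core_active=["RH1", "SNK"], core_inactive=["RL1"])
        res = imat_extract(m, rev, epsilon=1.0)
        S = stoichiometric_matrix(m).toarray()
        lb = [r.lb for r in m.reactions]
        ub = [r.ub for r in m.reactions]
        ridx = m.reaction_index()
        oracle = _oracles.imat_by_enumeration(
            S, lb, ub, [ridx["RH1"], ridx["SNK"]], [ridx["RL1"]], 1.0)
        assert res.objective == oracle == 2

    def test_epsilon_above_capacity_drops_score(self):
        m = _tiny_conflict_model()
        m.get_reaction("RH1").ub = 5.0
        rev = ReactionEvidence(core_active=["RH1"], core_inactive=[])
        low = imat_extract(m, rev, epsilon=1.0)
        high = imat_extract(m, rev, epsilon=10.0)
        assert low.objective - high.objective == 1  # RH1 can no longer score

    def test_objective_monotone_in_epsilon(self, host):
        ev, _ = planted_expression(host)
        rev = map_expression_to_reactions(host, ev)
        scores = [imat_extract(host, rev, epsilon=e).objective
                  for e in (0.1, 0.25, 1.0, 5.0)]
        assert scores == sorted(scores, reverse=True)

    def test_milp_matches_enumeration_on_random_instances(self):
        """MILP optimum equals exhaustive binary enumeration on instances
        with few evidence reactions."""
        from conftest import random_toy_instance

        rng = np.random.default_rng(11)
        for _ in range(6):
            m = random_toy_instance(rng, n_rxns=6)
            rids = m.reaction_ids
            picks = rng.permutation(len(rids))
            rh = [rids[j] for j in picks[:2]]
            rl = [rids[j] for j in picks[2:4]]
            rev = ReactionEvidence(core_active=rh, core_inactive=rl)
            res = imat_extract(m, rev, epsilon=0.5)
            S = stoichiometric_matrix(m).toarray()
            ridx = m.reaction_index()
            oracle = _oracles.imat_by_enumeration(
                S, [r.lb for r in m.reactions], [r.ub for r in m.reactions],
                [ridx[r] for r in rh], [ridx[r] for r in rl], 0.5)
            assert res.objective == oracle

    def test_planted_recovery_exact(self, host):
        """Full agreement and exact activity on the planted fixture."""
        ev, truth = planted_expression(host)
        rev = map_expression_to_reactions(host, ev)
        res = imat_extract(host, rev, epsilon=0.25)
        assert res.objective == truth.imat_objective
        assert res.activity == truth.imat_activity

    def test_overlapping_evidence_rejected(self, chain_model):
        rev = ReactionEvidence(core_active=["R1"], core_inactive=["R1"])
        with pytest.raises(ValueError):
            imat_extract(chain_model, rev)


class TestBuildContextModel:
    def test_silenced_terminal_branch_removed(self, host):
        ev, _ = planted_expression(host)
        rev = map_expression_to_reactions(host, ev)
        res = imat_extract(host, rev, epsilon=0.25)
        ctx, log = build_context_model(host, res, repair=True)
        assert not any(r.id.startswith("SYN_hb") for r in ctx.reactions)
        # backbone intact and still growing
        assert lp_analysis.fba(ctx).objective == pytest.approx(
            lp_analysis.fba(host).objective, abs=1e-5)

    def test_downstream_of_silenced_step_pruned(self, host):
        """Silencing the branch synthesis steps leaves their transports and
        exchanges blocked; repair prunes them, matching the hand count."""
        ev, _ = planted_expression(host)
        rev = map_expression_to_reactions(host, ev)
        res = imat_extract(host, rev, epsilon=0.25)
        ctx, _ = build_context_model(host, res, repair=True)
        n_branches = sum(r.id.startswith("SYN_hb") for r in host.reactions)
        # per branch: SYN (silenced) + T + EX all gone
        assert len(host.reactions) - len(ctx.reactions) == 3 * n_branches

    def test_repair_false_reports_not_prunes(self, host):
        ev, _ = planted_expression(host)
        rev = map_expression_to_reactions(host, ev)
        res = imat_extract(host, rev, epsilon=0.25)
        ctx, log = build_context_model(host, res, repair=False)
        reported = [r["target"] for r in log.records
                    if r["action"] == "report_blocked"]
        assert any(rid.startswith("T_hb") for rid in reported)
        assert any(r.id.startswith("T_hb") for r in ctx.reactions)

    def test_biomass_always_retained(self, host):
        ev = ExpressionEvidence({g: "low" for r in host.reactions
                                 for g in gpr_genes(r.gpr)})
        rev = map_expression_to_reactions(host, ev)
        res = imat_extract(host, rev, epsilon=0.25)
        ctx, _ = build_context_model(host, res, repair=True)
        assert ctx.biomass_reactions()

    def test_no_new_leaks(self, host):
        ev, _ = planted_expression(host)
        rev = map_expression_to_reactions(host, ev)
        res = imat_extract(host, rev, epsilon=0.25)
        ctx, _ = build_context_model(host, res, repair=True)
        assert ctx.annotations["sanity"]["leaking_metabolites"] == []
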