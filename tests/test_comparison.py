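"""Flux-span ratio, secretome profiling, minNorm deltas, enrichment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import _oracles
from conftest import build_model
from fluxspan import lp_analysis
from fluxspan.comparison import (
    FsrRecord,
    classify_fsr,
    compare_secretomes,
    flux_enrichment,
    flux_span_ratio,
    minnorm_delta,
    percent_flux_increase,
    secretome_profile,
    SecretomeProfile,
)
from fluxspan.model_core import Reaction
from fluxspan.synthetic_data import perturbation_pair


class TestFluxSpanRatio:
    def test_model_vs_itself_unity(self, microbe):
        res = lp_analysis.fva(microbe, gamma=0.9)
        records, only_a, only_b = flux_span_ratio(res, res, tol=1e-4)
        assert only_a == only_b == []
        for rec in records:
            if rec.klass != "degenerate":
                assert rec.fsr == pytest.approx(1.0, abs=1e-9)

    def test_crafted_widening_gives_known_ratio(self):
        """Condition B gains a demand widening one span 2 -> 10: fsr 0.2."""
        base = build_model(
            ["A[e]", "B[c]", "C[c]"],
            [("EX_A[e]", {"A[e]": -1}, -10, 0),
             ("R1", {"A[e]": -1, "B[c]": 1}, 0, 1000),
             ("R2", {"B[c]": -1, "C[c]": 1}, 0, 2),
             ("DM_C", {"C[c]": -1}, 0, 1000, "demand"),
             ("DM_B", {"B[c]": -1}, 0, 1000, "demand")],
            {"DM_B": 1.0},
        )
        cond_b = base.copy()
        cond_b.get_reaction("R2").ub = 10.0
        fva_a = lp_analysis.fva(base, gamma=0.0)
        fva_b = lp_analysis.fva(cond_b, gamma=0.0)
        records, _, _ = flux_span_ratio(fva_a, fva_b)
        by_id = {r.reaction_id: r for r in records}
        assert by_id["R2"].span_a == pytest.approx(2.0, abs=1e-6)
        assert by_id["R2"].span_b == pytest.approx(10.0, abs=1e-6)
        assert by_id["R2"].fsr == pytest.approx(0.2, abs=1e-6)

    def test_vanishing_denominator_flagged_infinite(self):
        a = {"r": (0.0, 3.0)}
        b = {"r": (0.0, 0.0)}
        fva_a = lp_analysis.FvaResult(ranges=a, gamma=1.0, objective_floor=0)
        fva_b = lp_analysis.FvaResult(ranges=b, gamma=1.0, objective_floor=0)
        (rec,), _, _ = flux_span_ratio(fva_a, fva_b)
        assert math.isinf(rec.fsr) and rec.degenerate_denominator

    def test_disjoint_ids_rejected(self):
        fva_a = lp_analysis.FvaResult(ranges={"r1": (0, 1)}, gamma=1, objective_floor=0)
        fva_b = lp_analysis.FvaResult(ranges={"r2": (0, 1)}, gamma=1, objective_floor=0)
        with pytest.raises(ValueError):
            flux_span_ratio(fva_a, fva_b)


class TestClassify:
    @pytest.mark.parametrize("fsr,klass", [
        (0.5, "increased_in_b"),
        (1.0, "unchanged"),
        (2.5, "decreased_in_b"),
        (0.8, "unchanged"),   # band edges belong to unchanged
        (2.0, "unchanged"),
    ])
    def test_thresholds(self, fsr, klass):
        rec = FsrRecord("r", 1.0, 1.0, fsr)
        classify_fsr([rec])
        assert rec.klass == klass

    def test_partition_is_exact(self):
        records = [FsrRecord(f"r{i}", 1, 1, f) for i, f in
                   enumerate([0.1, 0.9, 1.5, 2.1, 3.0])]
        affected = classify_fsr(records)
        classes = {r.klass for r in records}
        assert classes <= {"increased_in_b", "decreased_in_b", "unchanged"}
        assert len(affected) == 3
        assert all(r.klass != "unchanged" for r in affected)

    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_antisymmetry_property(self, sa, sb):
        """Swapping conditions inverts the ratio and swaps the classes."""
        fwd = FsrRecord("r", sa, sb, sa / sb)
        rev = FsrRecord("r", sb, sa, sb / sa)
        classify_fsr([fwd])
        classify_fsr([rev])
        assert fwd.fsr == pytest.approx(1.0 / rev.fsr, rel=1e-9)
        swap = {"increased_in_b": "decreased_in_b",
                "decreased_in_b": "increased_in_b",
                "unchanged": "unchanged"}
        # classes swap except inside the (asymmetric) band (0.8, 2)
        if not (0.8 <= fwd.fsr <= 2.0 or 0.8 <= rev.fsr <= 2.0):
            assert rev.klass == swap[fwd.klass]

    def test_swapped_conditions_on_fixture(self):
        model_a, model_b, truth, _ = perturbation_pair()
        fva_a = lp_analysis.fva(model_a)
        fva_b = lp_analysis.fva(model_b)
        fwd, _, _ = flux_span_ratio(fva_a, fva_b, tol=1e-4)
        rev, _, _ = flux_span_ratio(fva_b, fva_a, tol=1e-4)
        fwd_by = {r.reaction_id: r for r in fwd}
        for rec in rev:
            other = fwd_by[rec.reaction_id]
            if rec.klass != "degenerate" and not math.isinf(other.fsr) \
                    and not math.isinf(rec.fsr) and other.fsr > 0:
                assert rec.fsr == pytest.approx(1.0 / other.fsr, rel=1e-6)


class TestMinnormDelta:
    def test_identical_models_zero_delta(self, microbe):
        df = minnorm_delta(microbe, microbe)
        assert np.allclose(df.delta.abs(), 0.0, atol=1e-4)

    def test_folate_drain_raises_folate_branch(self):
        model_a, model_b, _, _ = perturbation_pair()
        df = minnorm_delta(model_a, model_b)
        fol = df[df.reaction_id.isin(["FOLS", "FOLR"])]
        assert (fol.delta > 1e-3).all()

    def test_missing_reactions_marked_not_dropped(self):
        model_a, model_b, _, _ = perturbation_pair()
        df = minnorm_delta(model_a, model_b)
        b_only = df[df.reaction_id == "ROS_FENTON"]
        assert len(b_only) == 1
        assert math.isnan(b_only.v_a.iloc[0])


class TestSecretome:
    def test_toy_secretion_capacity(self, parallel_model):
        prof = secretome_profile(parallel_model, gamma=0.0)
        assert prof.fluxes["EX_B[e]"] == pytest.approx(10.0, abs=1e-6)

    def test_closed_model_all_zero(self, parallel_model):
        closed = parallel_model.copy()
        closed.get_reaction("EX_A[e]").lb = 0.0
        prof = secretome_profile(closed, gamma=0.0)
        assert all(v <= 1e-6 for v in prof.fluxes.values())

    def test_compartment_filter(self, host):
        prof = secretome_profile(host, compartment_filter="b", gamma=0.9)
        assert prof.fluxes
        assert all("[b]" in rid for rid in prof.fluxes)

    @pytest.mark.parametrize("a,b,klass", [
        (10.0, 15.0, "increased"),
        (10.0, 10.2, "same"),
        (10.0, 0.0, "decreased"),
    ])
    def test_three_way_classification(self, a, b, klass):
        pa = SecretomeProfile({"EX_x": a})
        pb = SecretomeProfile({"EX_x": b})
        df = compare_secretomes(pa, pb, rel_tol=0.05)
        assert df["class"].iloc[0] == klass

    @given(st.floats(min_value=0.01, max_value=100))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rescaling_invariance(self, scale):
        pa = SecretomeProfile({"EX_x": 10.0, "EX_y": 1.0})
        pb = SecretomeProfile({"EX_x": 14.0, "EX_y": 1.02})
        ref = compare_secretomes(pa, pb)["class"].tolist()
        pa2 = SecretomeProfile({k: v * scale for k, v in pa.fluxes.items()})
        pb2 = SecretomeProfile({k: v * scale for k, v in pb.fluxes.items()})
        assert compare_secretomes(pa2, pb2)["class"].tolist() == ref


class TestEnrichment:
    def test_worked_tail_sum(self, host):
        """N=100, K=10, n=5, k=4 has an exact combinatorial tail."""
        expected = _oracles.hypergeom_upper_tail(4, 100, 10, 5)
        from scipy import stats

        assert float(stats.hypergeom.sf(3, 100, 10, 5)) == pytest.approx(
            expected, rel=1e-12)

    def test_zero_hits_p_one(self, microbe):
        res = flux_enrichment([], microbe)
        assert (res.table.p == 1.0).all()

    def test_concentrated_hits_minimal_p(self, microbe):
        folate = [r.id for r in microbe.reactions
                  if r.subsystem == "Folate metabolism"]
        res = flux_enrichment(folate, microbe)
        top = res.table.iloc[0]
        assert top.subsystem == "Folate metabolism"
        assert top.p == res.table.p.min()

    def test_matches_exact_oracle_small_universes(self, microbe):
        """p-values equal the exact combinatorial tail for every subsystem
        (N <= 30 on the toy)."""
        affected = ["FOLS", "FOLR", "AASYN", "PTA"]
        res = flux_enrichment(affected, microbe)
        N = len(microbe.reactions)
        assert N <= 30
        for row in res.table.itertuples():
            assert row.p == pytest.approx(
                _oracles.hypergeom_upper_tail(row.k, N, row.K, len(affected)),
                rel=1e-9) or (row.k == 0 and row.p == 1.0)

    def test_stray_affected_rejected(self, microbe):
        with pytest.raises(ValueError):
            flux_enrichment(["nope"], microbe)


class TestPercentIncrease:
    def test_printed_biomass_pair(self):
        """0.0003 vs 0.0223 mmol/g-DW/h -> ~98.7% increase."""
        assert percent_flux_increase(0.0003, 0.0223) == pytest.approx(
            98.654708, abs=1e-4)

    def test_zero_condition_rejected(self):
        with pytest.raises(ZeroDivisionError):
            percent_flux_increase(1.0, 0.0)
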