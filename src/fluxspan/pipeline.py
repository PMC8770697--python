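"""End-to-end workflows with config, logging and provenance capture.

Three reproducible workflows mirror the study design:

``run_ros_workflow``
    expand a microbe model with reactive-species chemistry, debug it,
    FVA both conditions, flux-span-ratio comparison and classification,
    minimum-norm delta attribution and subsystem enrichment.
``run_host_workflow``
    categorical expression evidence -> iMAT extraction -> healthy-colon
    and disease (CRC-like) context models -> biomass comparison (percent
    difference), pairwise FSr, body-fluid secretomes.
``run_community_workflow``
    pair each context model with the perturbed microbe through a shared
    lumen on a defined diet, run interaction FVA and a four-condition
    secretome classification matrix.

Every workflow writes its tables as TSV plus the resolved configuration
beside them; reruns from the resolved config are byte-identical (fixed
solver settings, seeded generators, no timestamps in outputs).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, comparison, curation, lp_analysis
from .context_extraction import build_context_model, imat_extract, map_expression_to_reactions
from .curation import CurationLog
from .host_microbe import CouplingSpec, PairedModel, interaction_fva, pair_models
from .model_core import MediumSpec, MetabolicModel, read_model, write_model
from .synthetic_data import (
    PLANTED_EPSILON,
    HOST_ACTIVE_SET,
    ToySpec,
    perturbation_pair,
    planted_expression,
    toy_host,
)

log = logging.getLogger("fluxspan.pipeline")

__all__ = ["PipelineConfig", "run_ros_workflow", "run_host_workflow",
           "run_community_workflow", "build_context_pair"]


@dataclass
class PipelineConfig:
    """Resolved settings of a workflow run; fully serializable.

    Thresholds: ``gamma`` is the FVA optimality fraction, ``epsilon`` the
    minimum active flux of the extraction MILP (0.25 matches the planted
    toy fixtures), ``fsr_low``/``fsr_high`` the affected-reaction band,
    ``fsr_tol`` the span below which a reaction counts as degenerate
    (kept above solver slack).  Input paths are optional; when absent the
    seeded synthetic fixtures are used.
    """

    seed: int = 0
    out_dir: str = "fluxspan_out"
    gamma: float = 1.0
    epsilon: float = PLANTED_EPSILON
    fsr_low: float = 0.8
    fsr_high: float = 2.0
    fsr_tol: float = 1e-4
    secretome_rel_tol: float = 0.05
    norm: str = "euclidean"
    coupling_enabled: bool = False
    c_coupling: float = 400.0
    u_coupling: float = 0.01
    n_branches: int = 4
    model_a_path: str | None = None
    model_b_path: str | None = None
    host_path: str | None = None
    medium_path: str | None = None
    diet_path: str | None = None
    evidence_colon_path: str | None = None
    evidence_disease_path: str | None = None
    model_format: str = "tsv"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        stray = sorted(set(doc) - known)
        if stray:
            raise ValueError(f"unknown config keys: {stray}")
        return cls(**doc)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _prepare_out(config: PipelineConfig, name: str) -> Path:
    out = Path(config.out_dir) / name
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "resolved_config.yaml")
    with open(out / "provenance.yaml", "w") as fh:
        yaml.safe_dump({
            "tool": "fluxspan", "version": __version__, "workflow": name,
            "thresholds": {
                "gamma": config.gamma, "epsilon": config.epsilon,
                "fsr_low": config.fsr_low, "fsr_high": config.fsr_high,
                "fsr_tol": config.fsr_tol,
                "feasibility_tol": lp_analysis.FEASIBILITY_TOL,
                "blocked_tol": lp_analysis.BLOCKED_TOL,
            },
            "seed": config.seed,
        }, fh, sort_keys=True)
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


# ---------------------------------------------------------------------------
# reactive-species workflow
# ---------------------------------------------------------------------------

def run_ros_workflow(config: PipelineConfig) -> dict:
    """Expand -> debug -> FVA x2 -> FSr -> classify -> minNorm delta ->
    enrichment.  Returns the report bundle (also written under
    ``out_dir/ros``)."""
    out = _prepare_out(config, "ros")
    if config.model_a_path:
        model_a = read_model(config.model_a_path, config.model_format)
        if not config.model_b_path:
            raise FileNotFoundError("model_b_path required with model_a_path")
        model_b = read_model(config.model_b_path, config.model_format)
        clog = CurationLog()
    else:
        spec = ToySpec(seed=config.seed, n_branches=config.n_branches)
        model_a, model_b, _truth, clog = perturbation_pair(spec)
    if config.medium_path:
        medium = MediumSpec.from_tsv(config.medium_path)
        model_a = curation.apply_medium(model_a, medium)
        model_b = curation.apply_medium(model_b, medium)

    log.info("FVA on condition A (%d reactions)", len(model_a.reactions))
    fva_a = lp_analysis.fva(model_a, gamma=config.gamma)
    log.info("FVA on condition B (%d reactions)", len(model_b.reactions))
    fva_b = lp_analysis.fva(model_b, gamma=config.gamma)
    records, only_a, only_b = comparison.flux_span_ratio(
        fva_a, fva_b, tol=config.fsr_tol
    )
    affected = comparison.classify_fsr(records, config.fsr_low, config.fsr_high)
    affected_ids = sorted(r.reaction_id for r in affected)
    log.info("%d affected reactions: %s", len(affected_ids), affected_ids)

    delta = comparison.minnorm_delta(model_a, model_b,
                                     reactions=affected_ids or None,
                                     norm=config.norm)
    enrich = comparison.flux_enrichment(affected_ids, model_a)

    _write_tsv(comparison.fsr_table(records), out / "fsr.tsv")
    _write_tsv(pd.DataFrame({"reaction_id": affected_ids}), out / "affected.tsv")
    _write_tsv(delta, out / "minnorm_delta.tsv")
    _write_tsv(enrich.table, out / "enrichment.tsv")
    clog.to_jsonl(out / "curation_log.jsonl")
    write_model(model_b, out / "model_b", "tsv")
    return {
        "model_a": model_a, "model_b": model_b, "curation_log": clog,
        "fva_a": fva_a, "fva_b": fva_b, "fsr_records": records,
        "affected": affected_ids, "only_in_a": only_a, "only_in_b": only_b,
        "minnorm_delta": delta, "enrichment": enrich, "out_dir": out,
    }


# ---------------------------------------------------------------------------
# host (context extraction) workflow
# ---------------------------------------------------------------------------

def build_context_pair(
    host: MetabolicModel,
    evidence_colon,
    evidence_disease,
    epsilon: float,
) -> dict:
    """Extract healthy-colon and disease context models from one host model.

    The colon model's biomass is edited after extraction — the replicating
    nucleobase precursor is removed and the folate dependency strengthened
    — and the model re-debugged; the disease model keeps the original
    biomass.
    """
    rev_colon = map_expression_to_reactions(host, evidence_colon)
    rev_dis = map_expression_to_reactions(host, evidence_disease)
    imat_colon = imat_extract(host, rev_colon, epsilon=epsilon)
    imat_dis = imat_extract(host, rev_dis, epsilon=epsilon)
    colon, log_colon = build_context_model(host, imat_colon, repair=True)
    disease, log_dis = build_context_model(host, imat_dis, repair=True)
    if "gua[c]" in colon.biomass_reactions()[0].stoichiometry:
        colon, elog = curation.edit_biomass(
            colon, remove=["gua[c]"], add={"mlthf[c]": -1.0}
        )
        log_colon.extend(elog)
        blocked = lp_analysis.find_blocked_reactions(colon)
        blocked = [r for r in blocked
                   if colon.get_reaction(r).kind not in ("biomass",)]
        if blocked:
            for rid in blocked:
                log_colon.append("remove_reaction", rid,
                                 reason="blocked after biomass edit")
            colon.remove_reactions(blocked)
            colon.prune_orphan_metabolites()
    return {
        "colon": colon, "disease": disease,
        "imat_colon": imat_colon, "imat_disease": imat_dis,
        "log_colon": log_colon, "log_disease": log_dis,
        "evidence_colon": rev_colon, "evidence_disease": rev_dis,
    }


def _default_host_evidence(host: MetabolicModel, seed: int):
    """Synthetic evidence pair: the healthy colon silences the side
    branches; the disease condition expresses everything."""
    colon_ev, _ = planted_expression(host, seed=seed)
    branches = sorted(r.id for r in host.reactions if r.id.startswith("SYN_hb"))
    disease_ev, _ = planted_expression(
        host,
        active_set=[rid for rid in HOST_ACTIVE_SET
                    if rid in set(host.reaction_ids)] + branches,
        low_set=[],
        seed=seed,
    )
    return colon_ev, disease_ev


def run_host_workflow(config: PipelineConfig) -> dict:
    """Evidence -> iMAT -> context models -> sanity -> biomass comparison ->
    pairwise FSr -> body-fluid secretomes."""
    from .context_extraction import ExpressionEvidence

    out = _prepare_out(config, "host")
    host = (read_model(config.host_path, config.model_format)
            if config.host_path
            else toy_host(ToySpec(seed=config.seed, n_branches=config.n_branches)))
    if config.evidence_colon_path and config.evidence_disease_path:
        ev_colon = ExpressionEvidence.from_tsv(config.evidence_colon_path)
        ev_dis = ExpressionEvidence.from_tsv(config.evidence_disease_path)
    else:
        ev_colon, ev_dis = _default_host_evidence(host, config.seed)
    ctx = build_context_pair(host, ev_colon, ev_dis, config.epsilon)
    colon, disease = ctx["colon"], ctx["disease"]

    z_colon = lp_analysis.fba(colon).objective
    z_dis = lp_analysis.fba(disease).objective
    pct = comparison.percent_flux_increase(z_colon, z_dis)
    log.info("biomass: colon %.4f, disease %.4f (+%.1f%%)", z_colon, z_dis, pct)

    fva_colon = lp_analysis.fva(colon, gamma=config.gamma)
    fva_dis = lp_analysis.fva(disease, gamma=config.gamma)
    records, only_a, only_b = comparison.flux_span_ratio(
        fva_colon, fva_dis, tol=config.fsr_tol
    )
    affected = comparison.classify_fsr(records, config.fsr_low, config.fsr_high)

    sec_colon = comparison.secretome_profile(colon, compartment_filter="b",
                                             gamma=config.gamma, condition="colon")
    sec_dis = comparison.secretome_profile(disease, compartment_filter="b",
                                           gamma=config.gamma, condition="disease")
    sec_cmp = comparison.compare_secretomes(sec_colon, sec_dis,
                                            rel_tol=config.secretome_rel_tol)

    biomass_df = pd.DataFrame(
        [("colon", z_colon), ("disease", z_dis)],
        columns=["condition", "biomass_flux"],
    )
    biomass_df["percent_increase_vs_colon"] = [0.0, pct]
    _write_tsv(biomass_df, out / "biomass.tsv")
    _write_tsv(comparison.fsr_table(records), out / "fsr.tsv")
    _write_tsv(sec_cmp, out / "secretome_compare.tsv")
    ctx["log_colon"].to_jsonl(out / "curation_log_colon.jsonl")
    ctx["log_disease"].to_jsonl(out / "curation_log_disease.jsonl")
    write_model(colon, out / "colon_model", "tsv")
    write_model(disease, out / "disease_model", "tsv")
    return {
        "host": host, "colon": colon, "disease": disease,
        "imat_colon": ctx["imat_colon"], "imat_disease": ctx["imat_disease"],
        "biomass_colon": z_colon, "biomass_disease": z_dis,
        "percent_increase": pct,
        "fsr_records": records,
        "affected": sorted(r.reaction_id for r in affected),
        "secretome_compare": sec_cmp, "out_dir": out,
    }


# ---------------------------------------------------------------------------
# community workflow
# ---------------------------------------------------------------------------

def _community_diet() -> MediumSpec:
    """Lumen diet: glucose only — thymidine must come from the microbe."""
    return MediumSpec({"EX_glc[u]": (-10.0, 1000.0)})


def run_community_workflow(config: PipelineConfig) -> dict:
    """Pair -> diet -> FBA/FVA -> interaction FVA -> secretome matrix
    across {host, host+microbe} x {colon, disease}."""
    out = _prepare_out(config, "community")
    spec = ToySpec(seed=config.seed, n_branches=config.n_branches)
    _, microbe_b, _truth, _ = perturbation_pair(spec)
    host = (read_model(config.host_path, config.model_format)
            if config.host_path
            else toy_host(spec))
    ev_colon, ev_dis = _default_host_evidence(host, config.seed)
    ctx = build_context_pair(host, ev_colon, ev_dis, config.epsilon)
    diet = (MediumSpec.from_tsv(config.diet_path) if config.diet_path
            else _community_diet())
    coupling = (CouplingSpec(c_coupling=config.c_coupling,
                             u_coupling=config.u_coupling)
                if config.coupling_enabled else None)

    pairs: dict[str, PairedModel] = {}
    rows = []
    interactions = {}
    for label, ctx_model in (("colon", ctx["colon"]), ("disease", ctx["disease"])):
        paired = pair_models(ctx_model, microbe_b, lumen_medium=diet,
                             coupling=coupling)
        pairs[label] = paired
        z = lp_analysis.fba(paired.model).objective
        rows.append((f"{label}_microbe", z))
        ifva = interaction_fva(paired, gamma=config.gamma)
        interactions[label] = ifva
        obligate = sorted(
            rid for rid, (vmin, vmax) in ifva.ranges.items()
            if vmin > config.fsr_tol or vmax < -config.fsr_tol
        )
        log.info("%s-microbe: host biomass %.4f, obligate interactions %s",
                 label, z, obligate)

    # four-condition body-fluid secretome matrix
    profiles = {
        "colon": comparison.secretome_profile(ctx["colon"], "b", config.gamma, "colon"),
        "disease": comparison.secretome_profile(ctx["disease"], "b", config.gamma, "disease"),
    }
    for label, paired in pairs.items():
        profiles[f"{label}_microbe"] = comparison.secretome_profile(
            paired.model, "b", config.gamma, f"{label}_microbe"
        )

    def _strip_prefix(rid: str, prefix: str) -> str:
        return rid[len(prefix):] if rid.startswith(prefix) else rid

    # host exchanges in the paired models carry the host prefix
    norm_profiles = {}
    for label, prof in profiles.items():
        norm_profiles[label] = {
            _strip_prefix(rid, "H_"): v for rid, v in prof.fluxes.items()
        }
    # union of body-fluid exchanges: an exchange absent from a condition's
    # context model has zero secretion capacity there
    shared = sorted(set.union(*[set(p) for p in norm_profiles.values()]))
    baseline = norm_profiles["colon"]
    matrix_rows = []
    for rid in shared:
        row = {"exchange_id": rid}
        for label in ("colon", "disease", "colon_microbe", "disease_microbe"):
            v = norm_profiles[label].get(rid, 0.0)
            b = baseline.get(rid, 0.0)
            denom = max(abs(v), abs(b))
            rel = 0.0 if denom == 0 else (v - b) / denom
            klass = ("increased" if rel > config.secretome_rel_tol
                     else "decreased" if rel < -config.secretome_rel_tol
                     else "same")
            row[f"{label}_flux"] = v
            row[f"{label}_class"] = klass
        matrix_rows.append(row)
    matrix = pd.DataFrame(matrix_rows)

    biomass_df = pd.DataFrame(rows, columns=["condition", "host_biomass_flux"])
    _write_tsv(biomass_df, out / "biomass.tsv")
    _write_tsv(matrix, out / "secretome_matrix.tsv")
    for label, ifva in interactions.items():
        df = pd.DataFrame(
            [(rid, vmin, vmax) for rid, (vmin, vmax) in sorted(ifva.ranges.items())],
            columns=["reaction_id", "vmin", "vmax"],
        )
        _write_tsv(df, out / f"interaction_fva_{label}.tsv")
    return {
        "pairs": pairs, "interactions": interactions,
        "secretome_matrix": matrix, "biomass": biomass_df,
        "colon": ctx["colon"], "disease": ctx["disease"],
        "microbe": microbe_b, "out_dir": out,
    }
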