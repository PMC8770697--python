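"""Quality-controlled model expansion and debugging.

Implements the curation protocol used when grafting a literature-derived
reaction set (here, reactive-species chemistry) onto an existing
reconstruction: add the reactions with duplicate/consistency checks, test
each new reaction for blockage, and resolve still-blocked reactions either
from user-supplied literature reactions or automatically by adding demand
reactions for orphan products and sink reactions for orphan reactants.
Every action is recorded in an append-only :class:`CurationLog` whose replay
on the base model reproduces the curated model exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from . import lp_analysis
from .model_core import (
    MediumSpec,
    MetabolicModel,
    Metabolite,
    Reaction,
)

__all__ = [
    "ReactionSet",
    "CurationLog",
    "CurationError",
    "add_reactions_qc",
    "expand_with_ros",
    "unblock_reactions",
    "apply_medium",
    "edit_biomass",
    "replay_log",
]

#: conventional bounds for auto-added boundary reactions
DEMAND_BOUNDS = (0.0, 1000.0)
SINK_BOUNDS = (-1000.0, 1000.0)


class CurationError(ValueError):
    pass


@dataclass
class ReactionSet:
    """A curated bundle of reactions plus the metabolites they introduce.

    ``provenance`` maps reaction id -> citation string.  Consistency means
    every metabolite a reaction references is either in ``new_metabolites``
    or expected to pre-exist in the target model.
    """

    reactions: list[Reaction] = field(default_factory=list)
    new_metabolites: list[Metabolite] = field(default_factory=list)
    provenance: dict[str, str] = field(default_factory=dict)

    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]


@dataclass
class CurationLog:
    """Ordered, replayable record of model edits.

    Each record is a plain dict with an ``action`` key in
    ``{add_reaction, add_demand, add_sink, set_bound, edit_biomass,
    skip_duplicate, remove_reaction}`` and enough payload to reapply the
    edit.  Serialized as JSON-lines.
    """

    records: list[dict] = field(default_factory=list)

    def append(self, action: str, target: str, reason: str = "",
               citation: str = "", **payload) -> None:
        self.records.append({
            "action": action, "target": target, "reason": reason,
            "citation": citation, **payload,
        })

    def extend(self, other: "CurationLog") -> None:
        self.records.extend(other.records)

    def to_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for rec in self.records:
                fh.write(json.dumps(rec, sort_keys=True) + "\n")

    @classmethod
    def from_jsonl(cls, path: str | Path) -> "CurationLog":
        log = cls()
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    log.records.append(json.loads(line))
        return log


def _rxn_payload(rxn: Reaction) -> dict:
    return {
        "id": rxn.id, "name": rxn.name, "stoichiometry": dict(rxn.stoichiometry),
        "lb": rxn.lb, "ub": rxn.ub, "subsystem": rxn.subsystem,
        "gpr": rxn.gpr, "kind": rxn.kind,
    }


def _met_payload(met: Metabolite) -> dict:
    return {
        "id": met.id, "name": met.name, "compartment": met.compartment,
        "formula": met.formula, "charge": met.charge,
    }


# ---------------------------------------------------------------------------
# quality-controlled addition
# ---------------------------------------------------------------------------

def add_reactions_qc(
    model: MetabolicModel, rset: ReactionSet
) -> tuple[MetabolicModel, CurationLog]:
    """Add a reaction set with duplicate and consistency checks.

    New metabolites are registered before any reaction.  A reaction whose id
    already exists with *identical* content is skipped and logged; an id
    collision with differing content is a hard error, as is a reaction
    referencing a metabolite neither present nor declared new.  Duplicates
    by content (identical stoichiometry and bounds under a different id)
    are also rejected.
    """
    out = model.copy()
    log = CurationLog()
    existing_mets = {m.id for m in out.metabolites}
    for met in rset.new_metabolites:
        if met.id in existing_mets:
            log.append("skip_duplicate", met.id, reason="metabolite already present")
            continue
        out.add_metabolite(met.copy())
        existing_mets.add(met.id)
        log.append("add_metabolite", met.id, metabolite=_met_payload(met))

    by_id = {r.id: r for r in out.reactions}
    by_content = {
        (tuple(sorted(r.stoichiometry.items())), r.lb, r.ub): r.id
        for r in out.reactions
    }
    for rxn in rset.reactions:
        citation = rset.provenance.get(rxn.id, "")
        if rxn.id in by_id:
            old = by_id[rxn.id]
            same = (old.stoichiometry == rxn.stoichiometry
                    and old.lb == rxn.lb and old.ub == rxn.ub)
            if same:
                log.append("skip_duplicate", rxn.id,
                           reason="identical reaction already present")
                continue
            raise CurationError(
                f"reaction id {rxn.id!r} already exists with different content"
            )
        key = (tuple(sorted(rxn.stoichiometry.items())), rxn.lb, rxn.ub)
        if key in by_content:
            log.append("skip_duplicate", rxn.id,
                       reason=f"content-identical to existing {by_content[key]!r}")
            continue
        missing = sorted(set(rxn.stoichiometry) - existing_mets)
        if missing:
            raise CurationError(
                f"reaction {rxn.id!r} references unregistered metabolite(s) {missing}"
            )
        out.add_reaction(rxn.copy())
        by_id[rxn.id] = rxn
        by_content[key] = rxn.id
        log.append("add_reaction", rxn.id, citation=citation,
                   reaction=_rxn_payload(rxn))
    return out, log


def expand_with_ros(
    model: MetabolicModel, ros_set: ReactionSet
) -> tuple[MetabolicModel, CurationLog, list[str]]:
    """Graft a reactive-species reaction set onto a model.

    Composition of :func:`add_reactions_qc` followed by a per-new-reaction
    blockage check; returns ``(expanded model, log, still-blocked new
    reaction ids)`` so the caller can debug them (see
    :func:`unblock_reactions`).  Pre-existing reactions are never touched.
    """
    expanded, log = add_reactions_qc(model, ros_set)
    added = [rec["target"] for rec in log.records if rec["action"] == "add_reaction"]
    blocked = lp_analysis.find_blocked_reactions(expanded, reactions=added)
    return expanded, log, blocked


# ---------------------------------------------------------------------------
# unblocking protocol
# ---------------------------------------------------------------------------

def _orphans_for(model: MetabolicModel, rxn: Reaction) -> tuple[list[str], list[str]]:
    """(orphan products, orphan reactants) of one reaction, i.e. its
    metabolites that are currently dead ends in the model."""
    dead = set(lp_analysis.find_dead_end_metabolites(model))
    products = sorted(m for m, c in rxn.stoichiometry.items() if c > 0 and m in dead)
    reactants = sorted(m for m, c in rxn.stoichiometry.items() if c < 0 and m in dead)
    return products, reactants


def unblock_reactions(
    model: MetabolicModel,
    blocked: list[str],
    mode: str = "auto",
    literature: ReactionSet | None = None,
) -> tuple[MetabolicModel, CurationLog, list[str]]:
    """Resolve blocked reactions by demand/sink additions.

    ``auto``: for each blocked reaction (deterministic id-sorted order) add a
    demand ``DM_<met>`` for every dead-end product and a sink ``SK_<met>``
    for every dead-end reactant, then re-test; iterate until the reaction
    unblocks or no orphan remains.  ``literature_first``: apply the supplied
    :class:`ReactionSet` first, then fall back to auto for whatever stays
    blocked.  Reactions that remain blocked after all additions are returned,
    never silently dropped.
    """
    if mode not in ("auto", "literature_first"):
        raise ValueError(f"unknown mode {mode!r}")
    out = model.copy()
    log = CurationLog()
    known = set(out.reaction_ids)
    missing = sorted(set(blocked) - known)
    if missing:
        raise CurationError(f"blocked ids not in model: {missing}")

    if mode == "literature_first" and literature is not None:
        out, lit_log = add_reactions_qc(out, literature)
        log.extend(lit_log)

    def _add_boundary(mid: str, which: str) -> bool:
        bid = f"{'DM' if which == 'demand' else 'SK'}_{mid}"
        if any(r.id == bid for r in out.reactions):
            return False
        lo, hi = DEMAND_BOUNDS if which == "demand" else SINK_BOUNDS
        out.add_reaction(Reaction(
            id=bid, name=f"{which} for {mid}", stoichiometry={mid: -1.0},
            lb=lo, ub=hi, kind=which,
        ))
        log.append(f"add_{which}" if which == "demand" else "add_sink", bid,
                   reason="no literature evidence", metabolite=mid, lb=lo, ub=hi)
        return True

    # one reaction's sink/demand can be the missing piece for another, so
    # sweep the blocked list to a fixpoint rather than once
    still_blocked = sorted(blocked)
    for _ in range(len(blocked) + 1):
        progress = False
        remaining = set(lp_analysis.find_blocked_reactions(out, reactions=still_blocked))
        for rid in sorted(remaining):
            rxn = out.get_reaction(rid)
            products, reactants = _orphans_for(out, rxn)
            for mid in products:
                progress |= _add_boundary(mid, "demand")
            for mid in reactants:
                progress |= _add_boundary(mid, "sink")
        still_blocked = sorted(
            lp_analysis.find_blocked_reactions(out, reactions=still_blocked)
        )
        if not still_blocked or not progress:
            break
    return out, log, still_blocked


# ---------------------------------------------------------------------------
# medium constraining & biomass editing
# ---------------------------------------------------------------------------

def apply_medium(
    model: MetabolicModel, medium: MediumSpec, close_others: bool = True
) -> MetabolicModel:
    """Constrain exchange reactions to a medium composition.

    Listed exchanges get the stated bounds; with ``close_others`` every
    other exchange has its uptake closed (lb raised to 0, secretion bound
    untouched).  Idempotent.  Unknown exchange ids are an error listing all
    of them.
    """
    known = {r.id for r in model.reactions if r.kind == "exchange"}
    missing = sorted(set(medium.entries) - known)
    if missing:
        raise CurationError(f"medium names absent exchange reaction(s): {missing}")
    out = model.copy()
    for r in out.reactions:
        if r.kind != "exchange":
            continue
        if r.id in medium.entries:
            r.lb, r.ub = medium.entries[r.id]
        elif close_others:
            r.lb = max(r.lb, 0.0)
    return out


def edit_biomass(
    model: MetabolicModel,
    remove: list[str] | None = None,
    add: dict[str, float] | None = None,
) -> tuple[MetabolicModel, CurationLog]:
    """Edit the (single) biomass reaction's precursor stoichiometry.

    ``remove`` lists metabolite ids whose terms are deleted (error if a
    listed metabolite is not a biomass participant); ``add`` merges new
    coefficients (overwriting any existing term).  Old and new coefficients
    are logged.
    """
    biomass = model.biomass_reactions()
    if len(biomass) != 1:
        raise CurationError(
            f"model must have exactly one biomass reaction, found {len(biomass)}"
        )
    out = model.copy()
    rxn = out.get_reaction(biomass[0].id)
    log = CurationLog()
    for mid in (remove or []):
        if mid not in rxn.stoichiometry:
            raise CurationError(
                f"metabolite {mid!r} is not part of biomass reaction {rxn.id!r}"
            )
        log.append("edit_biomass", rxn.id, metabolite=mid,
                   old=rxn.stoichiometry[mid], new=None)
        del rxn.stoichiometry[mid]
    for mid, coef in (add or {}).items():
        if mid not in {m.id for m in out.metabolites}:
            raise CurationError(f"metabolite {mid!r} not in model")
        log.append("edit_biomass", rxn.id, metabolite=mid,
                   old=rxn.stoichiometry.get(mid), new=coef)
        rxn.stoichiometry[mid] = coef
    return out, log


# ---------------------------------------------------------------------------
# log replay
# ---------------------------------------------------------------------------

def replay_log(model: MetabolicModel, log: CurationLog) -> MetabolicModel:
    """Re-apply a curation log to a base model.

    Deterministic: the result is field-by-field identical to the model the
    log was recorded against.
    """
    out = model.copy()
    for rec in log.records:
        action = rec["action"]
        if action == "add_metabolite":
            p = rec["metabolite"]
            out.add_metabolite(Metabolite(
                id=p["id"], name=p["name"], compartment=p["compartment"],
                formula=p["formula"], charge=p["charge"],
            ))
        elif action == "add_reaction":
            p = rec["reaction"]
            out.add_reaction(Reaction(
                id=p["id"], name=p["name"],
                stoichiometry={k: float(v) for k, v in p["stoichiometry"].items()},
                lb=p["lb"], ub=p["ub"], subsystem=p["subsystem"],
                gpr=p["gpr"], kind=p["kind"],
            ))
        elif action in ("add_demand", "add_sink"):
            kind = "demand" if action == "add_demand" else "sink"
            out.add_reaction(Reaction(
                id=rec["target"],
                name=f"{kind} for {rec['metabolite']}",
                stoichiometry={rec["metabolite"]: -1.0},
                lb=rec["lb"], ub=rec["ub"], kind=kind,
            ))
        elif action == "set_bound":
            r = out.get_reaction(rec["target"])
            r.lb, r.ub = rec["lb"], rec["ub"]
        elif action == "edit_biomass":
            r = out.get_reaction(rec["target"])
            if rec["new"] is None:
                del r.stoichiometry[rec["metabolite"]]
            else:
                r.stoichiometry[rec["metabolite"]] = rec["new"]
        elif action == "remove_reaction":
            out.remove_reactions([rec["target"]])
        elif action == "remove_metabolite":
            out.metabolites = [m for m in out.metabolites if m.id != rec["target"]]
        elif action in ("skip_duplicate", "report_blocked"):
            pass
        else:
            raise CurationError(f"unknown log action {action!r}")
    return out
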