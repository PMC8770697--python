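"""Host-microbe community model construction and interaction analysis.

Two organism models are merged into one community model built around a
shared lumen compartment ``u``: every extracellular metabolite of either
organism is bridged into the lumen by a reversible intercellular transport,
the organism-level exchange reactions are replaced by community exchanges
``EX_<met>[u]`` whose bounds encode the diet, and the host keeps its
body-fluid compartment ``b`` exchanges untouched (host-only secretome).
Optional coupling constraints tie each organism's reaction fluxes to its
biomass flux,

    |v_j| <= c * v_biomass + u        (c default 400, u default 0.01),

preventing flux through a non-growing organism.  These rows live in
``MetabolicModel.extra_constraints`` and are honoured by every LP analysis.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from . import lp_analysis
from .lp_analysis import FvaResult
from .model_core import MediumSpec, MetabolicModel, Metabolite, Reaction

__all__ = [
    "CouplingSpec",
    "PairedModel",
    "PairingError",
    "tag_model",
    "pair_models",
    "add_coupling_constraints",
    "interaction_fva",
    "close_organism",
]

LUMEN_TAG = "u"
BODY_FLUID_TAG = "b"
TRANSPORT_BOUND = 1000.0


class PairingError(ValueError):
    pass


@dataclass
class CouplingSpec:
    """Parameters of the community coupling constraints."""

    c_coupling: float = 400.0
    u_coupling: float = 0.01
    host_biomass: str = ""
    microbe_biomass: str = ""
    couple_host: bool = False

    def __post_init__(self) -> None:
        if self.c_coupling <= 0:
            raise ValueError("c_coupling must be > 0")
        if self.u_coupling < 0:
            raise ValueError("u_coupling must be >= 0")


@dataclass
class PairedModel:
    """A merged host+microbe model with organism attribution.

    ``organism_tags`` maps every reaction id to ``host``, ``microbe`` or
    ``community`` (lumen exchanges); the partition is total.
    """

    model: MetabolicModel
    organism_tags: dict[str, str]
    host_prefix: str
    microbe_prefix: str
    coupling: CouplingSpec | None = None
    lumen_tag: str = LUMEN_TAG

    def reactions_of(self, organism: str) -> list[str]:
        return [rid for rid, org in self.organism_tags.items() if org == organism]


# ---------------------------------------------------------------------------
# tagging
# ---------------------------------------------------------------------------

def _prefix_met(prefix: str, mid: str) -> str:
    return f"{prefix}{mid}"


def tag_model(
    model: MetabolicModel,
    prefix: str,
    compartment_renames: dict[str, str] | None = None,
) -> MetabolicModel:
    """Prefix every reaction and metabolite id with an organism tag.

    ``compartment_renames`` maps old compartment tags to new ones (the
    bracket suffix in metabolite ids is rewritten accordingly).  GPRs are
    untouched.  Re-tagging an already-tagged model is an error.
    """
    if not prefix:
        raise ValueError("prefix must be non-empty")
    if model.annotations.get("organism_prefix"):
        raise PairingError(
            f"model already tagged with prefix "
            f"{model.annotations['organism_prefix']!r}"
        )
    renames = compartment_renames or {}
    out = MetabolicModel(id=f"{prefix}{model.id}")

    def _rename_mid(mid: str) -> str:
        new = mid
        m = re.search(r"\[([^\[\]]+)\]$", mid)
        if m and m.group(1) in renames:
            new = mid[: m.start()] + f"[{renames[m.group(1)]}]"
        return _prefix_met(prefix, new)

    for met in model.metabolites:
        out.add_metabolite(Metabolite(
            id=_rename_mid(met.id),
            name=met.name,
            compartment=renames.get(met.compartment, met.compartment),
            formula=met.formula,
            charge=met.charge,
        ))
    for r in model.reactions:
        out.add_reaction(Reaction(
            id=f"{prefix}{r.id}",
            name=r.name,
            stoichiometry={_rename_mid(mid): c for mid, c in r.stoichiometry.items()},
            lb=r.lb, ub=r.ub, subsystem=r.subsystem, gpr=r.gpr, kind=r.kind,
        ))
    out.objective = {f"{prefix}{rid}": w for rid, w in model.objective.items()}
    out.extra_constraints = [
        ({f"{prefix}{rid}": coef for rid, coef in coeffs.items()}, sense, rhs)
        for (coeffs, sense, rhs) in model.extra_constraints
    ]
    out.annotations = dict(model.annotations)
    out.annotations["organism_prefix"] = prefix
    return out


# ---------------------------------------------------------------------------
# pairing
# ---------------------------------------------------------------------------

def _base_of(mid: str) -> str:
    """Strip a trailing compartment suffix: ``glc[e]`` -> ``glc``."""
    return re.sub(r"\[[^\[\]]+\]$", "", mid)


def pair_models(
    host: MetabolicModel,
    microbe: MetabolicModel,
    lumen_medium: MediumSpec | None = None,
    coupling: CouplingSpec | None = None,
    host_prefix: str = "H_",
    microbe_prefix: str = "M_",
    extracellular_tag: str = "e",
    objective: str = "host_biomass",
) -> PairedModel:
    """Merge a host and a microbe model through a shared lumen.

    Bookkeeping: with ``e_h``/``e_m`` extracellular species per organism and
    ``s`` distinct base species overall, the merged model has
    ``n_h + n_m - (absorbed organism exchanges) + (e_h + e_m)`` transports
    ``+ s`` lumen exchanges.  Community exchange ``EX_<base>[u]`` bounds come
    from ``lumen_medium`` (closed to uptake by default).  The community
    objective defaults to the host biomass; ``objective='joint'`` sums both
    biomasses.
    """
    for m, label in ((host, "host"), (microbe, "microbe")):
        if not m.biomass_reactions():
            if coupling is not None or label == "host":
                raise PairingError(f"{label} model has no biomass reaction")
    th = tag_model(host, host_prefix)
    tm = tag_model(microbe, microbe_prefix)

    merged = MetabolicModel(id=f"{host.id}__{microbe.id}")
    tags: dict[str, str] = {}
    lumen_bases: dict[str, str] = {}  # base -> lumen metabolite id

    for tagged, org in ((th, "host"), (tm, "microbe")):
        prefix = host_prefix if org == "host" else microbe_prefix
        ex_mids = {m.id for m in tagged.metabolites
                   if m.compartment == extracellular_tag}
        for met in tagged.metabolites:
            merged.add_metabolite(met.copy())
        for r in tagged.reactions:
            # organism-level exchanges on extracellular species are absorbed
            if r.kind == "exchange" and set(r.stoichiometry) <= ex_mids:
                continue
            merged.add_reaction(r.copy())
            tags[r.id] = org
        for mid in sorted(ex_mids):
            base = _base_of(mid[len(prefix):])
            if base not in lumen_bases:
                lmid = f"{base}[{LUMEN_TAG}]"
                merged.add_metabolite(Metabolite(id=lmid, compartment=LUMEN_TAG))
                lumen_bases[base] = lmid
            t_id = f"T{prefix}{base}_{LUMEN_TAG}"
            merged.add_reaction(Reaction(
                id=t_id,
                name=f"{org} <-> lumen transport of {base}",
                stoichiometry={mid: -1.0, lumen_bases[base]: 1.0},
                lb=-TRANSPORT_BOUND, ub=TRANSPORT_BOUND,
                subsystem="Intercellular transport", kind="transport",
            ))
            tags[t_id] = org

    medium = lumen_medium.entries if lumen_medium else {}
    for base, lmid in sorted(lumen_bases.items()):
        ex_id = f"EX_{base}[{LUMEN_TAG}]"
        lb, ub = medium.get(ex_id, (0.0, TRANSPORT_BOUND))
        merged.add_reaction(Reaction(
            id=ex_id, name=f"community exchange of {base}",
            stoichiometry={lmid: -1.0}, lb=lb, ub=ub, kind="exchange",
        ))
        tags[ex_id] = "community"
    unknown = sorted(set(medium) - {f"EX_{b}[{LUMEN_TAG}]" for b in lumen_bases})
    if unknown:
        raise PairingError(f"lumen medium names absent exchange(s): {unknown}")

    host_bio = f"{host_prefix}{host.biomass_reactions()[0].id}"
    if objective == "host_biomass":
        merged.objective = {host_bio: 1.0}
    elif objective == "joint":
        merged.objective = {host_bio: 1.0}
        if microbe.biomass_reactions():
            merged.objective[f"{microbe_prefix}{microbe.biomass_reactions()[0].id}"] = 1.0
    else:
        raise ValueError(f"unknown objective {objective!r}")

    paired = PairedModel(
        model=merged, organism_tags=tags,
        host_prefix=host_prefix, microbe_prefix=microbe_prefix,
        coupling=coupling,
    )
    if coupling is not None:
        mic_bio = f"{microbe_prefix}{microbe.biomass_reactions()[0].id}"
        spec = CouplingSpec(
            c_coupling=coupling.c_coupling, u_coupling=coupling.u_coupling,
            host_biomass=host_bio, microbe_biomass=mic_bio,
            couple_host=coupling.couple_host,
        )
        paired.coupling = spec
        add_coupling_constraints(
            merged, paired.reactions_of("microbe"), mic_bio, spec,
        )
        if spec.couple_host:
            add_coupling_constraints(
                merged, paired.reactions_of("host"), host_bio, spec,
            )
    return paired


def add_coupling_constraints(
    model: MetabolicModel,
    organism_rxns: list[str],
    biomass_id: str,
    spec: CouplingSpec,
) -> MetabolicModel:
    """Append ``v_j - c v_bio <= u`` and ``-v_j - c v_bio <= u`` for every
    organism reaction ``j`` (the biomass itself excluded).  Rows are stored
    in ``extra_constraints`` and preserved by all LP analyses."""
    if biomass_id not in organism_rxns:
        raise PairingError(
            f"biomass {biomass_id!r} is not among the organism's reactions"
        )
    known = set(model.reaction_ids)
    missing = sorted(set(organism_rxns) - known)
    if missing:
        raise PairingError(f"organism reactions not in model: {missing}")
    c, u = spec.c_coupling, spec.u_coupling
    for rid in organism_rxns:
        if rid == biomass_id:
            continue
        model.extra_constraints.append(({rid: 1.0, biomass_id: -c}, "<=", u))
        model.extra_constraints.append(({rid: -1.0, biomass_id: -c}, "<=", u))
    return model


# ---------------------------------------------------------------------------
# analyses on the paired model
# ---------------------------------------------------------------------------

def interaction_fva(
    paired: PairedModel,
    targets: list[str] | None = None,
    gamma: float = 1.0,
) -> FvaResult:
    """FVA over the interaction surface of a paired model.

    By default restricted to the intercellular (organism <-> lumen)
    transports and the community lumen exchanges — the reactions through
    which cross-feeding must flow.  Naming an absent reaction raises.
    """
    model = paired.model
    known = set(model.reaction_ids)
    if targets is None:
        targets = sorted(
            rid for rid, r in zip(model.reaction_ids, model.reactions)
            if (r.kind == "transport" and r.subsystem == "Intercellular transport")
            or paired.organism_tags.get(rid) == "community"
        )
    else:
        missing = sorted(set(targets) - known)
        if missing:
            raise KeyError(f"interaction FVA targets not in model: {missing}")
    return lp_analysis.fva(model, gamma=gamma, reactions=targets)


def close_organism(paired: PairedModel, organism: str) -> PairedModel:
    """Return a copy of the paired model with one organism shut off: its
    lumen transports, boundary reactions and biomass all bounded to zero."""
    model = paired.model.copy()
    rids = set(paired.reactions_of(organism))
    for r in model.reactions:
        if r.id in rids and (
            r.subsystem == "Intercellular transport"
            or r.kind in ("exchange", "sink", "demand", "biomass")
        ):
            r.lb = r.ub = 0.0
    return PairedModel(
        model=model, organism_tags=dict(paired.organism_tags),
        host_prefix=paired.host_prefix, microbe_prefix=paired.microbe_prefix,
        coupling=paired.coupling,
    )
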