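"""Deterministic toy fixtures: microbe/host networks, a reactive-species
reaction set, planted expression evidence, and perturbation pairs with
known ground truth.

The networks are hand-designed templates, not random graphs, so every
ground truth below is provable by hand; the ``seed`` only shuffles cosmetic
aspects (record ordering of NA-category noise genes), never the planted
structure.  Flux units are normalised to a maximum substrate uptake of 10
mmol/g-DW/h so hand-derived numbers stay small.

Toy microbe
    A glycolysis-like backbone (glucose -> pyruvate + ATP) feeding a
    biomass reaction, a folate-like branch (pyruvate -> folate ->
    methylene-THF) required by biomass, SCFA-like acetate secretion, a
    thymidine synthesis/secretion path (the cross-feeding handle), amino
    acid (ala) and nucleobase (gua) synthesis as targets for
    reactive-species damage chemistry, and ``n_branches`` independent
    secreted side products.  Maximal growth is ATP-limited at Z* = 10.

Reactive-species set (``ros_fixture``)
    8 reactions over 11 new metabolites: superoxide dismutation, a
    Fenton-style hydroxyl-radical source, an NO-synthase stand-in,
    peroxynitrite formation, and four damage reactions hitting the amino
    acid and nucleobase pools.  Superoxide is deliberately never produced
    (needs one sink) and seven products are never consumed (need seven
    demands), exercising the full debugging protocol.

Perturbation pair
    Condition A is the plain microbe; condition B adds the
    reactive-species set, auto-debugs it, and adds a demand draining the
    folate species.  Exactly four pre-existing reactions provably widen
    their flux spans in B — the folate branch (via the folate demand) and
    the ala/gua synthesis steps (via the damage drains) — and are recorded
    as ground truth with class ``increased_in_b``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import curation
from .context_extraction import ExpressionEvidence, gpr_genes
from .curation import CurationLog, ReactionSet
from .model_core import MediumSpec, MetabolicModel, Metabolite, Reaction

__all__ = [
    "ToySpec",
    "PerturbationTruth",
    "toy_microbe",
    "toy_host",
    "ros_fixture",
    "planted_expression",
    "perturbation_pair",
    "default_host_medium",
    "default_microbe_medium",
    "ROS_REACTION_COUNT",
    "ROS_METABOLITE_COUNT",
    "ROS_EXPECTED_DEMANDS",
    "ROS_EXPECTED_SINKS",
]

#: documented constants of the reactive-species fixture
ROS_REACTION_COUNT = 8
ROS_METABOLITE_COUNT = 11
ROS_EXPECTED_DEMANDS = 7
ROS_EXPECTED_SINKS = 1

#: epsilon at which the planted host active set is feasible (the thinnest
#: active flux is the gua branch at 0.05 * Z* ~ 0.49)
PLANTED_EPSILON = 0.25


@dataclass
class ToySpec:
    """Parameters of the toy generators; generation is a pure function of
    this spec."""

    seed: int = 0
    n_branches: int = 4
    include_folate_branch: bool = True
    include_ros_targets: bool = True
    biomass_precursors: dict[str, float] | None = None


@dataclass
class PerturbationTruth:
    """Ground truth planted in a synthetic fixture, computable by
    construction before any solver runs."""

    affected_reactions: list[str] = field(default_factory=list)
    fsr_classes: dict[str, str] = field(default_factory=dict)
    imat_activity: dict[str, str] = field(default_factory=dict)
    imat_objective: int | None = None


def _met(model: MetabolicModel, mid: str, name: str = "", charge: int | None = None) -> None:
    model.add_metabolite(Metabolite(id=mid, name=name, charge=charge))


def _rxn(model: MetabolicModel, rid: str, formula_stoich: dict[str, float],
         lb: float = 0.0, ub: float = 1000.0, subsystem: str = "",
         gpr: str = "", kind: str = "internal", name: str = "") -> None:
    model.add_reaction(Reaction(
        id=rid, name=name or rid, stoichiometry=formula_stoich,
        lb=lb, ub=ub, subsystem=subsystem, gpr=gpr, kind=kind,
    ))


# ---------------------------------------------------------------------------
# toy microbe
# ---------------------------------------------------------------------------

_MICROBE_BIOMASS = {
    "atp[c]": -2.0, "pyr[c]": -0.5, "mlthf[c]": -0.1,
    "ala[c]": -0.2, "gua[c]": -0.05,
}


def toy_microbe(spec: ToySpec | None = None) -> MetabolicModel:
    """A ~25-reaction gut-microbe stand-in; grows at Z* = 10 on glucose.

    ATP is the binding resource: glycolysis yields 2 ATP per glucose
    (uptake <= 10) and biomass burns 2 per unit, so maximal biomass is 10.
    """
    spec = spec or ToySpec()
    m = MetabolicModel(id="toy_microbe")
    m.annotations["generator"] = {"name": "toy_microbe", "seed": spec.seed}

    for mid, name in [
        ("glc[e]", "glucose"), ("glc[c]", "glucose"),
        ("pyr[c]", "pyruvate"), ("atp[c]", "ATP"),
        ("ac[c]", "acetate"), ("ac[e]", "acetate"),
        ("thd[c]", "thymidine"), ("thd[e]", "thymidine"),
    ]:
        _met(m, mid, name)
    if spec.include_folate_branch:
        _met(m, "fol[c]", "folate")
        _met(m, "mlthf[c]", "5,10-methylene-THF")
    if spec.include_ros_targets:
        _met(m, "ala[c]", "alanine")
        _met(m, "gua[c]", "guanine")

    _rxn(m, "EX_glc[e]", {"glc[e]": -1.0}, lb=-10.0, ub=1000.0, kind="exchange")
    _rxn(m, "T_glc", {"glc[e]": -1.0, "glc[c]": 1.0}, subsystem="Transport",
         kind="transport")
    _rxn(m, "GLYC", {"glc[c]": -1.0, "pyr[c]": 2.0, "atp[c]": 2.0},
         subsystem="Glycolysis")
    _rxn(m, "PTA", {"pyr[c]": -1.0, "ac[c]": 1.0}, subsystem="SCFA metabolism")
    _rxn(m, "T_ac", {"ac[c]": -1.0, "ac[e]": 1.0}, subsystem="Transport",
         kind="transport")
    _rxn(m, "EX_ac[e]", {"ac[e]": -1.0}, lb=0.0, ub=1000.0, kind="exchange")
    _rxn(m, "THDS", {"pyr[c]": -1.0, "thd[c]": 1.0},
         subsystem="Nucleotide metabolism")
    _rxn(m, "T_thd", {"thd[c]": -1.0, "thd[e]": 1.0}, subsystem="Transport",
         kind="transport")
    _rxn(m, "EX_thd[e]", {"thd[e]": -1.0}, lb=0.0, ub=1000.0, kind="exchange")
    if spec.include_folate_branch:
        _rxn(m, "FOLS", {"pyr[c]": -1.0, "fol[c]": 1.0},
             subsystem="Folate metabolism")
        _rxn(m, "FOLR", {"fol[c]": -1.0, "mlthf[c]": 1.0},
             subsystem="Folate metabolism")
    if spec.include_ros_targets:
        _rxn(m, "AASYN", {"pyr[c]": -1.0, "ala[c]": 1.0},
             subsystem="Amino acid metabolism")
        _rxn(m, "GUASYN", {"pyr[c]": -2.0, "gua[c]": 1.0},
             subsystem="Nucleotide metabolism")

    for k in range(1, spec.n_branches + 1):
        _met(m, f"bm{k}[c]")
        _met(m, f"bm{k}[e]")
        _rxn(m, f"SYN_b{k}", {"pyr[c]": -1.0, f"bm{k}[c]": 1.0},
             subsystem=f"Secondary pathway {k}")
        _rxn(m, f"T_b{k}", {f"bm{k}[c]": -1.0, f"bm{k}[e]": 1.0},
             subsystem="Transport", kind="transport")
        _rxn(m, f"EX_bm{k}[e]", {f"bm{k}[e]": -1.0}, lb=0.0, ub=1000.0,
             kind="exchange")

    biomass = dict(spec.biomass_precursors or _MICROBE_BIOMASS)
    if not spec.include_folate_branch:
        biomass.pop("mlthf[c]", None)
    if not spec.include_ros_targets:
        biomass.pop("ala[c]", None)
        biomass.pop("gua[c]", None)
    _rxn(m, "BIOMASS_microbe", biomass, subsystem="Biomass", kind="biomass")
    m.objective = {"BIOMASS_microbe": 1.0}
    return m


def default_microbe_medium() -> MediumSpec:
    """Glucose-limited defined medium for the toy microbe (MRS stand-in)."""
    return MediumSpec({"EX_glc[e]": (-10.0, 1000.0)})


# ---------------------------------------------------------------------------
# toy host
# ---------------------------------------------------------------------------

_HOST_BIOMASS = {
    "atp[c]": -2.0, "pyr[c]": -0.5, "mlthf[c]": -0.1,
    "ala[c]": -0.2, "gua[c]": -0.05, "dtmp[c]": -0.05,
}

#: internal/transport reactions of the planted active subnetwork (R_H)
HOST_ACTIVE_SET = [
    "T_glc", "GLYC", "AASYN", "GUASYN", "FOLS", "FOLR",
    "T_thd", "DTMP", "LDH", "T_lac",
]


def toy_host(spec: ToySpec | None = None) -> MetabolicModel:
    """A colon-epithelium stand-in with a body-fluid compartment ``b``.

    Like the microbe but with thymidine *uptake* feeding a dTMP step the
    biomass requires (the cross-feeding handle), lactate overflow secreted
    into the body fluid, and a parseable GPR on every internal and
    transport reaction so context extraction can be exercised.
    """
    spec = spec or ToySpec()
    m = MetabolicModel(id="toy_host")
    m.annotations["generator"] = {"name": "toy_host", "seed": spec.seed}

    for mid, name in [
        ("glc[e]", "glucose"), ("glc[c]", "glucose"),
        ("pyr[c]", "pyruvate"), ("atp[c]", "ATP"),
        ("thd[e]", "thymidine"), ("thd[c]", "thymidine"),
        ("dtmp[c]", "dTMP"), ("lac[c]", "lactate"), ("lac[b]", "lactate"),
        ("ala[c]", "alanine"), ("gua[c]", "guanine"),
    ]:
        _met(m, mid, name)
    if spec.include_folate_branch:
        _met(m, "fol[c]", "folate")
        _met(m, "mlthf[c]", "5,10-methylene-THF")

    _rxn(m, "EX_glc[e]", {"glc[e]": -1.0}, lb=-10.0, ub=1000.0, kind="exchange")
    _rxn(m, "T_glc", {"glc[e]": -1.0, "glc[c]": 1.0}, subsystem="Transport",
         gpr="g_tglc", kind="transport")
    _rxn(m, "GLYC", {"glc[c]": -1.0, "pyr[c]": 2.0, "atp[c]": 2.0},
         subsystem="Glycolysis", gpr="g_glyc1 and g_glyc2")
    _rxn(m, "AASYN", {"pyr[c]": -1.0, "ala[c]": 1.0},
         subsystem="Amino acid metabolism", gpr="g_aasyn")
    _rxn(m, "GUASYN", {"pyr[c]": -2.0, "gua[c]": 1.0},
         subsystem="Nucleotide metabolism", gpr="g_guasyn")
    if spec.include_folate_branch:
        # ATP-costly folate synthesis: makes a strengthened folate
        # dependency in the healthy-colon biomass slow growth down
        _rxn(m, "FOLS", {"pyr[c]": -1.0, "atp[c]": -1.0, "fol[c]": 1.0},
             subsystem="Folate metabolism", gpr="g_fols")
        _rxn(m, "FOLR", {"fol[c]": -1.0, "mlthf[c]": 1.0},
             subsystem="Folate metabolism", gpr="g_folr1 or g_folr2")
    _rxn(m, "EX_thd[e]", {"thd[e]": -1.0}, lb=-5.0, ub=1000.0, kind="exchange")
    _rxn(m, "T_thd", {"thd[e]": -1.0, "thd[c]": 1.0}, subsystem="Transport",
         gpr="g_tthd", kind="transport")
    _rxn(m, "DTMP", {"thd[c]": -1.0, "atp[c]": -1.0, "dtmp[c]": 1.0},
         subsystem="Pyrimidine metabolism", gpr="g_dtmp")
    _rxn(m, "LDH", {"pyr[c]": -1.0, "lac[c]": 1.0}, subsystem="Glycolysis",
         gpr="g_ldh")
    _rxn(m, "T_lac", {"lac[c]": -1.0, "lac[b]": 1.0}, subsystem="Transport",
         gpr="g_tlac", kind="transport")
    _rxn(m, "EX_lac[b]", {"lac[b]": -1.0}, lb=0.0, ub=1000.0, kind="exchange")

    for k in range(1, spec.n_branches + 1):
        _met(m, f"hb{k}[c]")
        _met(m, f"hb{k}[b]")
        _rxn(m, f"SYN_hb{k}", {"pyr[c]": -1.0, f"hb{k}[c]": 1.0},
             subsystem=f"Secondary pathway {k}", gpr=f"g_hb{k}")
        _rxn(m, f"T_hb{k}", {f"hb{k}[c]": -1.0, f"hb{k}[b]": 1.0},
             subsystem="Transport", gpr=f"g_thb{k}", kind="transport")
        _rxn(m, f"EX_hb{k}[b]", {f"hb{k}[b]": -1.0}, lb=0.0, ub=1000.0,
             kind="exchange")

    biomass = dict(spec.biomass_precursors or _HOST_BIOMASS)
    if not spec.include_folate_branch:
        biomass.pop("mlthf[c]", None)
    _rxn(m, "BIOMASS_host", biomass, subsystem="Biomass", kind="biomass")
    m.objective = {"BIOMASS_host": 1.0}
    return m


def default_host_medium(with_thymidine: bool = True) -> MediumSpec:
    """DMEM-like defined medium for the toy host."""
    entries = {"EX_glc[e]": (-10.0, 1000.0)}
    if with_thymidine:
        entries["EX_thd[e]"] = (-5.0, 1000.0)
    return MediumSpec(entries)


# ---------------------------------------------------------------------------
# reactive-species fixture
# ---------------------------------------------------------------------------

def ros_fixture() -> ReactionSet:
    """The synthetic reactive-species reaction set (8 reactions, 11 new
    metabolites): superoxide/hydroxyl/nitric-oxide chemistry hitting the
    amino-acid and nucleobase pools.

    Synthetic stand-in: structurally mirrors a literature-curated set (one
    never-produced reactant -> one sink; seven never-consumed products ->
    seven demands) without claiming chemical balance.  A genuine curated
    set can be loaded from TSV via ``curation.ReactionSet`` instead.
    """
    mets = [
        Metabolite("o2s[c]", "superoxide anion", charge=-1),
        Metabolite("h2o2[c]", "hydrogen peroxide", charge=0),
        Metabolite("o2[c]", "oxygen", charge=0),
        Metabolite("oh1[c]", "hydroxyl radical", charge=0),
        Metabolite("no[c]", "nitric oxide", charge=0),
        Metabolite("onoo[c]", "peroxynitrite", charge=-1),
        Metabolite("alaox[c]", "oxidized alanine", charge=0),
        Metabolite("8oxog[c]", "8-oxo-guanine", charge=0),
        Metabolite("cysox[c]", "peroxidized amino acid", charge=0),
        Metabolite("tyrno2[c]", "nitrated amino acid", charge=0),
        Metabolite("no3[c]", "nitrate", charge=-1),
    ]
    rxns = [
        Reaction("ROS_DISMUT", "superoxide dismutation",
                 {"o2s[c]": -2.0, "h2o2[c]": 1.0, "o2[c]": 1.0},
                 lb=0.0, ub=1000.0, subsystem="ROS detoxification"),
        Reaction("ROS_FENTON", "Fenton-type hydroxyl radical generation",
                 {"h2o2[c]": -1.0, "oh1[c]": 2.0},
                 lb=0.0, ub=1000.0, subsystem="ROS generation"),
        Reaction("ROS_NOSYN", "nitric oxide synthase (stand-in)",
                 {"ala[c]": -1.0, "no[c]": 1.0, "pyr[c]": 1.0},
                 lb=0.0, ub=1000.0, subsystem="ROS generation"),
        Reaction("ROS_PNFORM", "peroxynitrite formation",
                 {"o2s[c]": -1.0, "no[c]": -1.0, "onoo[c]": 1.0},
                 lb=0.0, ub=1000.0, subsystem="ROS generation"),
        Reaction("ROS_AANIT", "amino acid nitration",
                 {"ala[c]": -1.0, "no[c]": -1.0, "oh1[c]": -1.0,
                  "tyrno2[c]": 1.0, "no3[c]": 1.0},
                 lb=0.0, ub=1000.0, subsystem="ROS damage"),
        Reaction("ROS_AAOX", "amino acid oxidation by hydroxyl radical",
                 {"ala[c]": -1.0, "oh1[c]": -1.0, "alaox[c]": 1.0},
                 lb=0.0, ub=1000.0, subsystem="ROS damage"),
        Reaction("ROS_NAOX", "nucleobase oxidation by hydroxyl radical",
                 {"gua[c]": -1.0, "oh1[c]": -1.0, "8oxog[c]": 1.0},
                 lb=0.0, ub=1000.0, subsystem="ROS damage"),
        Reaction("ROS_AAPER", "amino acid peroxidation",
                 {"ala[c]": -1.0, "h2o2[c]": -1.0, "cysox[c]": 1.0},
                 lb=0.0, ub=1000.0, subsystem="ROS damage"),
    ]
    provenance = {r.id: "synthetic stand-in for literature-curated chemistry"
                  for r in rxns}
    assert len(rxns) == ROS_REACTION_COUNT
    assert len(mets) == ROS_METABOLITE_COUNT
    return ReactionSet(reactions=rxns, new_metabolites=mets,
                       provenance=provenance)


# ---------------------------------------------------------------------------
# planted expression evidence
# ---------------------------------------------------------------------------

def planted_expression(
    model: MetabolicModel,
    active_set: list[str] | None = None,
    seed: int = 0,
    low_set: list[str] | None = None,
    n_noise_genes: int = 5,
) -> tuple[ExpressionEvidence, PerturbationTruth]:
    """Gene categories with a planted reaction-level truth.

    Genes of ``active_set`` reactions go ``high``, genes of ``low_set``
    (default: the host's side-branch synthesis steps, which are
    simultaneously silenceable) go ``low``, every other gene ``NA``.  The
    seed only shuffles the ordering/naming of NA noise genes.  The truth
    records the expected optimal agreement: every core-active reaction
    carries forward flux and every core-inactive reaction is silenced.
    """
    if active_set is None:
        active_set = [rid for rid in HOST_ACTIVE_SET
                      if rid in set(model.reaction_ids)]
    if low_set is None:
        low_set = sorted(
            r.id for r in model.reactions
            if r.id.startswith("SYN_hb") or r.id.startswith("SYN_b")
        )
    overlap = set(active_set) & set(low_set)
    if overlap:
        raise ValueError(f"active and low sets overlap: {sorted(overlap)}")
    cats: dict[str, str] = {}
    for rid in active_set:
        for g in sorted(gpr_genes(model.get_reaction(rid).gpr)):
            cats[g] = "high"
    for rid in low_set:
        for g in sorted(gpr_genes(model.get_reaction(rid).gpr)):
            if cats.get(g) == "high":
                raise ValueError(f"gene {g} shared between active and low sets")
            cats[g] = "low"
    for r in model.reactions:
        for g in sorted(gpr_genes(r.gpr)):
            cats.setdefault(g, "NA")
    rng = random.Random(seed)
    noise = [f"g_na{i}" for i in range(n_noise_genes)]
    rng.shuffle(noise)
    for g in noise:
        cats[g] = "NA"

    truth = PerturbationTruth(
        imat_activity={**{rid: "active_fwd" for rid in active_set},
                       **{rid: "silenced" for rid in low_set}},
        imat_objective=len(active_set) + len(low_set),
    )
    return ExpressionEvidence(cats, source="planted"), truth


# ---------------------------------------------------------------------------
# perturbation pair
# ---------------------------------------------------------------------------

def perturbation_pair(
    spec: ToySpec | None = None,
    include_demand: bool = True,
) -> tuple[MetabolicModel, MetabolicModel, PerturbationTruth, CurationLog]:
    """(model_a, model_b, truth, curation log of B).

    A is the plain toy microbe.  With ``include_demand`` (the default), B
    is A expanded with the reactive-species set, auto-debugged (7 demands +
    1 sink) and given a demand draining the folate species; the provably
    widened reactions are FOLS/FOLR (folate drain) and AASYN/GUASYN
    (amino-acid/nucleobase drains through the damage chemistry), all
    ``increased_in_b``.  Without it, B carries the reactive-species set
    un-debugged: every new reaction stays blocked, no span changes, and
    the truth set is empty (negative control).
    """
    spec = spec or ToySpec()
    if not (spec.include_folate_branch and spec.include_ros_targets):
        raise ValueError("perturbation pair requires folate branch and "
                         "reactive-species targets")
    model_a = toy_microbe(spec)
    expanded, log, blocked = curation.expand_with_ros(model_a, ros_fixture())
    if not include_demand:
        return model_a, expanded, PerturbationTruth(), log
    model_b, unblock_log, still = curation.unblock_reactions(
        expanded, blocked, mode="auto"
    )
    if still:  # cannot happen on the shipped fixture
        raise RuntimeError(f"fixture debugging left blocked reactions: {still}")
    log.extend(unblock_log)
    model_b.add_reaction(Reaction(
        id="DM_mlthf[c]", name="demand draining the folate pool",
        stoichiometry={"mlthf[c]": -1.0}, lb=0.0, ub=1000.0, kind="demand",
    ))
    log.append("add_demand", "DM_mlthf[c]",
               reason="perturbation: folate pool drain",
               metabolite="mlthf[c]", lb=0.0, ub=1000.0)
    affected = ["AASYN", "FOLR", "FOLS", "GUASYN"]
    truth = PerturbationTruth(
        affected_reactions=affected,
        fsr_classes={rid: "increased_in_b" for rid in affected},
    )
    return model_a, model_b, truth, log
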