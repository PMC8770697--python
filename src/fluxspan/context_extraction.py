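"""Context-specific model extraction from categorical expression evidence.

Workflow: categorical protein-expression evidence (gene -> high / medium /
low / NA, emulating tissue-atlas categories) is pushed through each
reaction's gene-protein-reaction (GPR) rule to give reaction-level evidence
— high/medium reactions form the core-active set R_H, low reactions the
core-inactive set R_L.  An iMAT-style mixed-integer program then finds the
steady-state flux distribution that maximizes agreement with the evidence:

    max  sum_{i in R_H} (y+_i + y-_i)  +  sum_{i in R_L} z_i
    s.t. S v = 0,  lb <= v <= ub
         i in R_H:  v_i + y+_i (lb_i - eps) >= lb_i
                    v_i + y-_i (ub_i + eps) <= ub_i
                    y+_i + y-_i <= 1
         i in R_L:  lb_i (1 - z_i) <= v_i <= ub_i (1 - z_i)
         y+, y-, z binary

y+_i = 1 forces v_i >= eps (active forward), y-_i = 1 forces v_i <= -eps,
z_i = 1 forces v_i = 0 (silenced).  The context model keeps the reactions
the witness leaves active, always retains biomass, and is optionally
repaired for consistency.

The MILP is solved with HiGHS through ``scipy.optimize.milp``; unbounded
reaction bounds are clamped to +-1000 before the MILP (logged in the
result).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, milp
from scipy.optimize import Bounds as OptBounds

from . import curation, lp_analysis
from .curation import CurationLog
from .model_core import MetabolicModel, stoichiometric_matrix

__all__ = [
    "ExpressionEvidence",
    "ReactionEvidence",
    "ImatResult",
    "GprError",
    "parse_gpr",
    "gpr_genes",
    "evaluate_gpr",
    "map_expression_to_reactions",
    "imat_extract",
    "build_context_model",
]

CATEGORIES = ("high", "medium", "low", "NA")
_ORDINAL = {"low": 0, "medium": 1, "high": 2}

DEFAULT_EPSILON = 1.0
_BOUND_CLAMP = 1000.0


class GprError(ValueError):
    pass


@dataclass
class ExpressionEvidence:
    """Categorical expression evidence: gene -> high/medium/low/NA."""

    categories: dict[str, str]
    source: str = ""

    def __post_init__(self) -> None:
        bad = {g: c for g, c in self.categories.items() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"categories outside {CATEGORIES}: {bad}")

    @classmethod
    def from_tsv(cls, path, source: str = "") -> "ExpressionEvidence":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        if not {"gene_id", "category"}.issubset(df.columns):
            raise ValueError(f"{path}: need columns gene_id, category")
        return cls({r.gene_id: r.category for r in df.itertuples()}, source=source)


@dataclass
class ReactionEvidence:
    """Reaction-level evidence partition: core-active (R_H), core-inactive
    (R_L), uncategorized."""

    core_active: list[str] = field(default_factory=list)
    core_inactive: list[str] = field(default_factory=list)
    uncategorized: list[str] = field(default_factory=list)


@dataclass
class ImatResult:
    """Outcome of the evidence-agreement MILP."""

    objective: int
    activity: dict[str, str]  # active_fwd | active_rev | silenced | unset
    flux: dict[str, float]
    epsilon: float
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# GPR parsing & evaluation
# ---------------------------------------------------------------------------

_TOKEN = re.compile(r"\(|\)|[^\s()]+")


def parse_gpr(gpr: str):
    """Parse a boolean GPR string into a nested AST.

    Nodes are ``("and", [children])``, ``("or", [children])`` or
    ``("gene", name)``.  ``or`` binds looser than ``and``.  Returns None
    for an empty rule.
    """
    tokens = _TOKEN.findall(gpr)
    if not tokens:
        return None
    pos = 0

    def peek():
        return tokens[pos] if pos < len(tokens) else None

    def take():
        nonlocal pos
        tok = tokens[pos]
        pos += 1
        return tok

    def parse_or():
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            take()
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            take()
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom():
        tok = peek()
        if tok is None:
            raise GprError(f"unexpected end of GPR {gpr!r}")
        if tok == "(":
            take()
            node = parse_or()
            if peek() != ")":
                raise GprError(f"unbalanced parentheses in GPR {gpr!r}")
            take()
            return node
        if tok in (")",) or tok.lower() in ("and", "or"):
            raise GprError(f"unexpected token {tok!r} in GPR {gpr!r}")
        return ("gene", take())

    tree = parse_or()
    if pos != len(tokens):
        raise GprError(f"trailing tokens in GPR {gpr!r}")
    return tree


def format_gpr(tree) -> str:
    """Serialize a GPR AST back to the canonical infix form (``or`` binds
    loosest; parentheses only where required)."""
    if tree is None:
        return ""
    kind = tree[0]
    if kind == "gene":
        return tree[1]
    if kind == "and":
        parts = []
        for child in tree[1]:
            s = format_gpr(child)
            if child[0] == "or":
                s = f"({s})"
            parts.append(s)
        return " and ".join(parts)
    return " or ".join(format_gpr(child) for child in tree[1])


def canonicalize_gpr(gpr: str) -> str:
    return format_gpr(parse_gpr(gpr))


def gpr_genes(gpr: str) -> set[str]:
    tree = parse_gpr(gpr)
    out: set[str] = set()

    def walk(node):
        if node is None:
            return
        kind = node[0]
        if kind == "gene":
            out.add(node[1])
        else:
            for child in node[1]:
                walk(child)

    walk(tree)
    return out


def evaluate_gpr(gpr: str, categories: dict[str, str]) -> str | None:
    """Evaluate a GPR over ordinal categories (low < medium < high).

    AND takes the minimum and OR the maximum over genes with a *known*
    category; genes that are NA or absent from the evidence are skipped, so
    an AND of (high, NA) evaluates to high.  Returns None when no gene in
    the rule has a known category (or the rule is empty).
    """
    tree = parse_gpr(gpr)

    def walk(node) -> int | None:
        if node is None:
            return None
        kind = node[0]
        if kind == "gene":
            cat = categories.get(node[1], "NA")
            return _ORDINAL.get(cat)
        vals = [v for v in (walk(c) for c in node[1]) if v is not None]
        if not vals:
            return None
        return min(vals) if kind == "and" else max(vals)

    val = walk(tree)
    if val is None:
        return None
    return {v: k for k, v in _ORDINAL.items()}[val]


def map_expression_to_reactions(
    model: MetabolicModel,
    evidence: ExpressionEvidence,
    overrides: dict[str, str] | None = None,
) -> ReactionEvidence:
    """Reaction-level evidence from gene-level categories via GPRs.

    high/medium reactions join the core-active set R_H, low reactions the
    core-inactive set R_L; reactions with no rule or no informative gene are
    uncategorized.  ``overrides`` force gene categories (e.g. a literature
    list of upregulated genes mapped to ``high``) before evaluation.
    Biomass and boundary reactions are left uncategorized regardless of
    evidence — biomass is always retained downstream.
    """
    cats = dict(evidence.categories)
    for gene, cat in (overrides or {}).items():
        if cat not in CATEGORIES:
            raise ValueError(f"override category {cat!r} not in {CATEGORIES}")
        cats[gene] = cat
    rev = ReactionEvidence()
    for r in model.reactions:
        if r.kind != "internal" and r.kind != "transport":
            rev.uncategorized.append(r.id)
            continue
        level = evaluate_gpr(r.gpr, cats)
        if level is None:
            rev.uncategorized.append(r.id)
        elif level in ("high", "medium"):
            rev.core_active.append(r.id)
        else:
            rev.core_inactive.append(r.id)
    return rev


# ---------------------------------------------------------------------------
# iMAT MILP
# ---------------------------------------------------------------------------

def imat_extract(
    model: MetabolicModel,
    revidence: ReactionEvidence,
    epsilon: float = DEFAULT_EPSILON,
) -> ImatResult:
    """Solve the evidence-agreement MILP (docstring at module top).

    The formulation is always feasible (all binaries zero reduces to plain
    FBA feasibility), so an infeasible status indicates a broken model and
    raises.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    rh = list(dict.fromkeys(revidence.core_active))
    rl = list(dict.fromkeys(revidence.core_inactive))
    if set(rh) & set(rl):
        raise ValueError(f"R_H and R_L overlap: {sorted(set(rh) & set(rl))}")
    ridx = model.reaction_index()
    for rid in rh + rl:
        if rid not in ridx:
            raise KeyError(f"evidence reaction {rid!r} not in model")

    n = len(model.reactions)
    notes: list[str] = []
    lb = np.array([r.lb for r in model.reactions], dtype=float)
    ub = np.array([r.ub for r in model.reactions], dtype=float)
    clamped = []
    for j in range(n):
        if lb[j] < -_BOUND_CLAMP:
            lb[j] = -_BOUND_CLAMP
            clamped.append(model.reactions[j].id)
        if ub[j] > _BOUND_CLAMP:
            ub[j] = _BOUND_CLAMP
            if model.reactions[j].id not in clamped:
                clamped.append(model.reactions[j].id)
    if clamped:
        notes.append(f"bounds clamped to +-{_BOUND_CLAMP} for: {clamped}")

    nh, nl = len(rh), len(rl)
    nvar = n + 2 * nh + nl  # [v, y+, y-, z]
    S = stoichiometric_matrix(model)

    rows, lo_list, hi_list = [], [], []

    def add_row(coeffs: dict[int, float], lo: float, hi: float) -> None:
        row = np.zeros(nvar)
        for j, cval in coeffs.items():
            row[j] = cval
        rows.append(row)
        lo_list.append(lo)
        hi_list.append(hi)

    # steady state
    Sd = S.toarray()
    for i in range(Sd.shape[0]):
        row = np.zeros(nvar)
        row[:n] = Sd[i]
        rows.append(row)
        lo_list.append(0.0)
        hi_list.append(0.0)
    # extra (coupling) rows
    for coeffs, sense, rhs in model.extra_constraints:
        row = np.zeros(nvar)
        for rid, coef in coeffs.items():
            row[ridx[rid]] = coef
        rows.append(row)
        if sense == "==":
            lo_list.append(rhs)
            hi_list.append(rhs)
        elif sense == "<=":
            lo_list.append(-np.inf)
            hi_list.append(rhs)
        else:
            lo_list.append(rhs)
            hi_list.append(np.inf)

    for a, rid in enumerate(rh):
        j = ridx[rid]
        yp = n + a
        ym = n + nh + a
        # v_j + y+ (lb_j - eps) >= lb_j
        add_row({j: 1.0, yp: lb[j] - epsilon}, lb[j], np.inf)
        # v_j + y- (ub_j + eps) <= ub_j
        add_row({j: 1.0, ym: ub[j] + epsilon}, -np.inf, ub[j])
        add_row({yp: 1.0, ym: 1.0}, -np.inf, 1.0)
    for b, rid in enumerate(rl):
        j = ridx[rid]
        z = n + 2 * nh + b
        # lb_j (1 - z) <= v_j  ->  v_j + lb_j z >= lb_j
        add_row({j: 1.0, z: lb[j]}, lb[j], np.inf)
        # v_j <= ub_j (1 - z)  ->  v_j + ub_j z <= ub_j
        add_row({j: 1.0, z: ub[j]}, -np.inf, ub[j])

    A = sparse.csr_matrix(np.vstack(rows))
    constraints = LinearConstraint(A, np.array(lo_list), np.array(hi_list))
    var_lb = np.concatenate([lb, np.zeros(2 * nh + nl)])
    var_ub = np.concatenate([ub, np.ones(2 * nh + nl)])
    integrality = np.concatenate([np.zeros(n), np.ones(2 * nh + nl)])
    cost = np.zeros(nvar)
    cost[n:] = -1.0  # maximize satisfied evidence terms

    res = milp(
        c=cost,
        constraints=constraints,
        bounds=OptBounds(var_lb, var_ub),
        integrality=integrality,
        options={"mip_rel_gap": 0.0, "presolve": True},
    )
    if res.status != 0 or res.x is None:
        raise lp_analysis.SolverError(
            f"iMAT MILP did not solve cleanly: {res.message}"
        )
    x = res.x
    activity: dict[str, str] = {}
    score = 0
    for a, rid in enumerate(rh):
        yp, ym = x[n + a] > 0.5, x[n + nh + a] > 0.5
        if yp:
            activity[rid] = "active_fwd"
            score += 1
        elif ym:
            activity[rid] = "active_rev"
            score += 1
        else:
            activity[rid] = "unset"
    for b, rid in enumerate(rl):
        if x[n + 2 * nh + b] > 0.5:
            activity[rid] = "silenced"
            score += 1
        else:
            activity[rid] = "unset"
    flux = {r.id: float(x[j]) for j, r in enumerate(model.reactions)}
    return ImatResult(objective=score, activity=activity, flux=flux,
                      epsilon=epsilon, notes=notes)


# ---------------------------------------------------------------------------
# context model assembly
# ---------------------------------------------------------------------------

def build_context_model(
    model: MetabolicModel,
    result: ImatResult,
    repair: bool = True,
    transporters: "curation.ReactionSet | None" = None,
) -> tuple[MetabolicModel, CurationLog]:
    """Materialize the context-specific model from an iMAT witness.

    Reactions silenced by the witness (z = 1) are removed — except biomass,
    which is always retained.  With ``repair`` the reduced model is pruned
    of newly blocked reactions (again sparing biomass and boundary
    reactions feeding it), literature transporters are added when supplied,
    and remaining dead ends are resolved with demand/sink additions; without
    it, blocked reactions are only reported in the log.  A sanity report is
    stored under ``model.annotations['sanity']``.
    """
    out = model.copy()
    log = CurationLog()
    biomass_ids = {r.id for r in model.biomass_reactions()}
    silenced = [rid for rid, act in result.activity.items()
                if act == "silenced" and rid not in biomass_ids]
    for rid in silenced:
        log.append("remove_reaction", rid, reason="silenced by evidence (z=1)")
    out.remove_reactions(silenced)

    if transporters is not None:
        out, tlog = curation.add_reactions_qc(out, transporters)
        log.extend(tlog)

    blocked = [rid for rid in lp_analysis.find_blocked_reactions(out)
               if rid not in biomass_ids]
    if repair:
        for rid in blocked:
            log.append("remove_reaction", rid, reason="blocked after extraction")
        out.remove_reactions(blocked)
        dropped = out.prune_orphan_metabolites()
        for mid in dropped:
            log.append("remove_metabolite", mid, reason="orphaned by pruning")
        dead = lp_analysis.find_dead_end_metabolites(out)
        if dead:
            # resolve remaining dead ends through the standard debugging path
            still = lp_analysis.find_blocked_reactions(out)
            if still:
                out, ulog, _ = curation.unblock_reactions(out, still, mode="auto")
                log.extend(ulog)
    else:
        for rid in blocked:
            log.append("report_blocked", rid,
                       reason="blocked after extraction (repair disabled)")
    rep = lp_analysis.run_sanity_checks(out)
    out.annotations["sanity"] = {
        "leaking_metabolites": rep.leaking_metabolites,
        "blocked_reactions": rep.blocked_reactions,
        "dead_end_metabolites": rep.dead_end_metabolites,
    }
    return out, log
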