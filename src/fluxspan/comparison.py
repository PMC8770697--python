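"""Comparison statistics between two model conditions.

The central statistic is the flux-span ratio (FSr): for each reaction shared
by a reference ("healthy", condition A) and a perturbed ("disease",
condition B) model,

    FSr_i = span_A(i) / span_B(i),   span = vmax - vmin from FVA,

with reactions called *affected* when FSr falls outside the band
``[low, high]`` (default ``[0.8, 2]``): FSr < low means the reaction's
flux span widened in the perturbed condition (``increased_in_b``), FSr >
high that it narrowed (``decreased_in_b``).  An alternative ``maxabs`` mode
ratios ``|vmax|`` instead of spans.

Also here: minimum-norm flux deltas grouped by subsystem, secretome
profiling (maximal exchange secretion fluxes) with three-way comparison,
and hypergeometric flux-enrichment of affected reactions by subsystem with
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import lp_analysis
from .lp_analysis import FvaResult
from .model_core import MetabolicModel

__all__ = [
    "FsrRecord",
    "SecretomeProfile",
    "EnrichmentResult",
    "flux_span_ratio",
    "classify_fsr",
    "minnorm_delta",
    "secretome_profile",
    "compare_secretomes",
    "flux_enrichment",
    "percent_flux_increase",
    "fsr_table",
]

FSR_LOW = 0.8
FSR_HIGH = 2.0


@dataclass
class FsrRecord:
    """Flux-span ratio of one reaction across two conditions."""

    reaction_id: str
    span_a: float
    span_b: float
    fsr: float  # span_a / span_b; +inf when only span_b vanishes
    klass: str = "unchanged"  # increased_in_b | decreased_in_b | unchanged | degenerate
    degenerate_denominator: bool = False


@dataclass
class SecretomeProfile:
    """Maximal secretion flux per exchange reaction for one condition."""

    fluxes: dict[str, float]
    condition: str = ""
    gamma: float = 1.0


@dataclass
class EnrichmentResult:
    """Per-subsystem hypergeometric enrichment of affected reactions."""

    table: pd.DataFrame  # columns: subsystem, k, K, n, N, p, p_adj

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table.p_adj <= alpha]


# ---------------------------------------------------------------------------
# FSr
# ---------------------------------------------------------------------------

def flux_span_ratio(
    fva_a: FvaResult,
    fva_b: FvaResult,
    tol: float = 1e-6,
    mode: str = "span",
) -> tuple[list[FsrRecord], list[str], list[str]]:
    """FSr records on the shared reactions of two FVA results.

    Returns ``(records, only_in_a, only_in_b)``; ids unique to one condition
    are reported separately, never silently dropped.  ``mode='span'`` ratios
    FVA spans; ``mode='maxabs'`` ratios ``|vmax|``.  Records where both
    quantities are below ``tol`` are tagged ``degenerate``; a vanishing
    denominator alone gives FSr = +inf with ``degenerate_denominator`` set.
    """
    if mode not in ("span", "maxabs"):
        raise ValueError(f"unknown FSr mode {mode!r}")
    ids_a, ids_b = set(fva_a.ranges), set(fva_b.ranges)
    shared = sorted(ids_a & ids_b)
    if not shared:
        raise ValueError("FVA results share no reaction ids")

    def _measure(res: FvaResult, rid: str) -> float:
        vmin, vmax = res.ranges[rid]
        return (vmax - vmin) if mode == "span" else abs(vmax)

    records = []
    for rid in shared:
        sa, sb = _measure(fva_a, rid), _measure(fva_b, rid)
        if sa < tol and sb < tol:
            records.append(FsrRecord(rid, sa, sb, math.nan, klass="degenerate"))
        elif sb < tol:
            records.append(FsrRecord(rid, sa, sb, math.inf,
                                     degenerate_denominator=True))
        else:
            records.append(FsrRecord(rid, sa, sb, sa / sb))
    return records, sorted(ids_a - ids_b), sorted(ids_b - ids_a)


def classify_fsr(
    records: list[FsrRecord],
    low: float = FSR_LOW,
    high: float = FSR_HIGH,
) -> list[FsrRecord]:
    """Classify records in place and return the affected subset.

    FSr < ``low``: span widened in condition B (``increased_in_b``);
    FSr > ``high``: narrowed (``decreased_in_b``); otherwise unchanged.
    Degenerate records (both measures below tolerance) are excluded.
    """
    if not (0 < low < high):
        raise ValueError("thresholds must satisfy 0 < low < high")
    affected = []
    for rec in records:
        if rec.klass == "degenerate":
            continue
        if rec.fsr < low:
            rec.klass = "increased_in_b"
            affected.append(rec)
        elif rec.fsr > high:
            rec.klass = "decreased_in_b"
            affected.append(rec)
        else:
            rec.klass = "unchanged"
    return affected


def fsr_table(records: list[FsrRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (r.reaction_id, r.span_a, r.span_b, r.fsr, r.klass,
             r.degenerate_denominator)
            for r in records
        ],
        columns=["reaction_id", "span_a", "span_b", "fsr", "class",
                 "degenerate_denominator"],
    )


# ---------------------------------------------------------------------------
# minNorm deltas
# ---------------------------------------------------------------------------

def minnorm_delta(
    model_a: MetabolicModel,
    model_b: MetabolicModel,
    reactions: list[str] | None = None,
    norm: str = "euclidean",
) -> pd.DataFrame:
    """Per-reaction flux change between the two models' minimum-norm optima.

    Returns a table ``(reaction_id, subsystem, v_a, v_b, delta)`` sorted by
    ``|delta|`` descending; reactions present in only one model keep a NaN
    on the missing side rather than being dropped.
    """
    sol_a = lp_analysis.min_norm_solution(model_a, norm=norm)
    sol_b = lp_analysis.min_norm_solution(model_b, norm=norm)
    if not (sol_a.optimal and sol_b.optimal):
        raise lp_analysis.SolverError(
            f"minNorm failed: A={sol_a.status}, B={sol_b.status}"
        )
    subsys = {r.id: r.subsystem for r in model_a.reactions}
    subsys.update({r.id: r.subsystem for r in model_b.reactions
                   if r.id not in subsys})
    if reactions is None:
        reactions = sorted(set(sol_a.fluxes) | set(sol_b.fluxes))
    rows = []
    for rid in reactions:
        va = sol_a.fluxes.get(rid, math.nan)
        vb = sol_b.fluxes.get(rid, math.nan)
        delta = vb - va if not (math.isnan(va) or math.isnan(vb)) else math.nan
        rows.append((rid, subsys.get(rid, ""), va, vb, delta))
    df = pd.DataFrame(rows, columns=["reaction_id", "subsystem", "v_a", "v_b", "delta"])
    df["abs_delta"] = df.delta.abs()
    df = df.sort_values(["abs_delta", "reaction_id"],
                        ascending=[False, True], na_position="last")
    return df.drop(columns="abs_delta").reset_index(drop=True)


# ---------------------------------------------------------------------------
# secretome
# ---------------------------------------------------------------------------

def secretome_profile(
    model: MetabolicModel,
    compartment_filter: str | None = None,
    gamma: float = 1.0,
    condition: str = "",
) -> SecretomeProfile:
    """Maximal secretion flux (FVA vmax) of every exchange reaction.

    Exchanges follow the export convention (positive flux = secretion; see
    ``model_core.normalize_exchanges``).  ``compartment_filter`` restricts
    to exchanges whose metabolite sits in the named compartment (e.g. the
    host body-fluid tag ``b`` or the community lumen ``u``).
    """
    targets = []
    for r in model.exchanges():
        (mid,), = (list(r.stoichiometry),)
        if compartment_filter is not None:
            met = model.get_metabolite(mid)
            if met.compartment != compartment_filter:
                continue
        targets.append(r.id)
    res = lp_analysis.fva(model, gamma=gamma, reactions=targets)
    return SecretomeProfile(
        fluxes={rid: max(0.0, vmax) for rid, (_, vmax) in res.ranges.items()},
        condition=condition,
        gamma=gamma,
    )


def compare_secretomes(
    prof_a: SecretomeProfile,
    prof_b: SecretomeProfile,
    rel_tol: float = 0.05,
) -> pd.DataFrame:
    """Three-way classification of shared exchanges: increased / same /
    decreased in condition B, by relative difference
    ``(b - a) / max(|a|, |b|)``.  Invariant to uniform rescaling of both
    profiles."""
    shared = sorted(set(prof_a.fluxes) & set(prof_b.fluxes))
    if not shared:
        raise ValueError("secretome profiles share no exchange ids")
    rows = []
    for rid in shared:
        a, b = prof_a.fluxes[rid], prof_b.fluxes[rid]
        denom = max(abs(a), abs(b))
        rel = 0.0 if denom == 0 else (b - a) / denom
        if rel > rel_tol:
            klass = "increased"
        elif rel < -rel_tol:
            klass = "decreased"
        else:
            klass = "same"
        rows.append((rid, a, b, rel, klass))
    return pd.DataFrame(rows, columns=["exchange_id", "flux_a", "flux_b",
                                       "rel_diff", "class"])


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def flux_enrichment(
    affected: list[str],
    model: MetabolicModel,
    grouping: str = "subsystem",
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Hypergeometric upper-tail enrichment of affected reactions per
    subsystem, Benjamini-Hochberg adjusted.

    Universe N = reactions in the model; for a subsystem of size K with k
    hits among the n affected reactions, p = P[X >= k] with
    X ~ Hypergeometric(N, K, n).
    """
    if grouping != "subsystem":
        raise ValueError("only grouping='subsystem' is supported")
    known = set(model.reaction_ids)
    stray = sorted(set(affected) - known)
    if stray:
        raise ValueError(f"affected reactions not in model: {stray}")
    universe = model.reaction_ids
    N = len(universe)
    n = len(set(affected))
    hits = set(affected)
    groups: dict[str, list[str]] = {}
    for r in model.reactions:
        groups.setdefault(r.subsystem or "(none)", []).append(r.id)
    rows = []
    for name in sorted(groups):
        members = groups[name]
        K = len(members)
        k = len(hits & set(members))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        rows.append((name, k, K, n, N, min(1.0, p)))
    df = pd.DataFrame(rows, columns=["subsystem", "k", "K", "n", "N", "p"])
    # Benjamini-Hochberg step-up
    from statsmodels.stats.multitest import multipletests

    if len(df):
        _, p_adj, _, _ = multipletests(df.p.values, alpha=alpha, method="fdr_bh")
        df["p_adj"] = p_adj
    else:
        df["p_adj"] = []
    return EnrichmentResult(table=df.sort_values(["p", "subsystem"]).reset_index(drop=True))


# ---------------------------------------------------------------------------
# scalar helpers
# ---------------------------------------------------------------------------

def percent_flux_increase(z_reference: float, z_condition: float) -> float:
    """Percent increase of a flux relative to the larger condition value:
    ``(z_condition - z_reference) / z_condition * 100``.

    This is the convention used to compare biomass fluxes between a disease
    model and its healthy counterpart (e.g. 0.0223 vs 0.0003 mmol/g-DW/h
    gives ~98.7%).
    """
    if z_condition == 0:
        raise ZeroDivisionError("condition flux is zero")
    return (z_condition - z_reference) / z_condition * 100.0
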