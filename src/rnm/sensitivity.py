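"""Full-factorial sensitivity screening with factorial ANOVA.

The protocol: enumerate all n^p level combinations of p factor nodes (two
levels, 0 and 1), use each combination as the *initial state* of the factor
nodes (never clamped), integrate to steady state, and record the response
nodes.  Effects — main and second-order — are screened with a fixed-effects
factorial ANOVA on ±1-coded contrasts; the reported statistic is
F = (MSB/MSW) × 100, with significance computed from the unscaled ratio
(the ×100 is presentational).  Significant effects (p ≤ 0.05) are ranked in
a Pareto table on a log10 scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .dynamics import SimulationConfig, integrate_to_steady_state
from .network import RegulatoryNetwork, UnknownNodeError

__all__ = [
    "FactorialDesign",
    "EffectRecord",
    "SensitivityReport",
    "full_factorial",
    "run_design",
    "anova_effects",
    "aggregate_groups",
    "pareto_table",
    "STRUCTURAL_GROUP",
    "ENZYME_GROUP",
]

# the two response groups screened in the disc model
STRUCTURAL_GROUP = ("ACAN", "COL1A", "COL2A")
ENZYME_GROUP = ("ADAMTS4/5", "MMP1", "MMP2", "MMP3", "MMP9", "MMP13")

ALPHA = 0.05  # significance threshold for the Pareto table


@dataclass
class FactorialDesign:
    """All n^p level combinations of the factors, last factor fastest."""

    factors: list[str]
    levels: tuple[float, float]
    rows: np.ndarray  # shape (n^p, p)

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def coded(self) -> np.ndarray:
        """±1 coding: low level → −1, high level → +1."""
        lo, hi = sorted(self.levels)
        return np.where(np.isclose(self.rows, hi), 1.0, -1.0)


@dataclass
class EffectRecord:
    """One 1-df effect (a factor or an unordered factor pair) on one
    response node."""

    effect: tuple[str, ...]
    response: str
    MSB: float
    MSW: float
    F: float  # (MSB/MSW) × 100; inf when MSW = 0
    p: float
    sign: str | None  # '+'/'−' for significant main effects, else None
    coefficient: float
    perfect_fit: bool = False

    @property
    def effect_label(self) -> str:
        return "×".join(self.effect)


@dataclass
class SensitivityReport:
    records: list[EffectRecord]
    groups: dict[str, list[str]]
    group_table: pd.DataFrame = field(default_factory=pd.DataFrame)


def full_factorial(
    factors: list[str], levels: tuple[float, float] = (0.0, 1.0)
) -> FactorialDesign:
    """Generate the full n^p design in canonical order (last factor varies
    fastest); deterministic."""
    factors = list(factors)
    if len(factors) < 1:
        raise ValueError("need at least one factor")
    if len(set(factors)) != len(factors):
        dup = sorted({f for f in factors if factors.count(f) > 1})
        raise ValueError(f"duplicate factor names: {dup}")
    if len(set(levels)) != 2:
        raise ValueError("levels must be two distinct values")
    rows = np.array(list(product(levels, repeat=len(factors))), dtype=float)
    return FactorialDesign(factors=factors, levels=tuple(levels), rows=rows)


def run_design(
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None,
    design: FactorialDesign,
    background,
    responses: list[str],
) -> pd.DataFrame:
    """Integrate every design row to steady state and record the responses.

    Factor nodes take the row's levels as *initial values*; all other nodes
    start from ``background`` (a mapping node → value or an array in node
    order, typically the baseline ensemble's per-node median).  Factors are
    not clamped: they evolve freely after t=0.
    """
    cfg = cfg or SimulationConfig()
    names = net.node_names
    index = {n: i for i, n in enumerate(names)}
    for f in design.factors + list(responses):
        if f not in index:
            raise UnknownNodeError(f)
    if isinstance(background, dict):
        bg = np.array([float(background[n]) for n in names])
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (len(names),):
            raise ValueError(f"background must have shape ({len(names)},)")
    factor_idx = [index[f] for f in design.factors]
    resp_idx = [index[r] for r in responses]
    out = np.empty((design.n_rows, len(responses)))
    import warnings as _warnings

    for k, row in enumerate(design.rows):
        x0 = bg.copy()
        x0[factor_idx] = row
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                _, x_ss = integrate_to_steady_state(x0, net, cfg)
        except Exception as exc:
            raise RuntimeError(f"design row {k} failed: {exc}") from exc
        out[k] = x_ss[resp_idx]
    frame = pd.DataFrame(out, columns=list(responses))
    frame.index.name = "row"
    return frame


def _effect_terms(factors: list[str], order: str) -> list[tuple[str, ...]]:
    terms: list[tuple[str, ...]] = [(f,) for f in factors]
    if order == "main+second":
        terms += [tuple(pair) for pair in combinations(factors, 2)]
    elif order != "main":
        raise ValueError(f"unknown order {order!r}")
    return terms


def anova_effects(
    design: FactorialDesign,
    responses: pd.DataFrame,
    order: str = "main+second",
    alpha: float = ALPHA,
) -> list[EffectRecord]:
    """Fixed-effects factorial ANOVA of every response on ±1-coded contrasts.

    For a balanced two-level design each effect carries 1 df with contrast
    column c (the elementwise product of the coded factor columns): the
    effect coefficient is b = cᵀy/N and its sum of squares N·b².  The
    residual after removing all modelled effects gives MSW; F is reported
    as (MSB/MSW)×100 while p comes from the unscaled ratio on
    (1, N−1−k) df.  A perfectly modelled response (MSW = 0) is flagged with
    F = +inf, p = 0.
    """
    coded = design.coded()
    n = design.n_rows
    terms = _effect_terms(design.factors, order)
    if n - 1 - len(terms) <= 0:
        raise ValueError(
            f"design too small for {len(terms)} effects: N={n} leaves no "
            "residual degrees of freedom"
        )
    col = {f: coded[:, i] for i, f in enumerate(design.factors)}
    records: list[EffectRecord] = []
    for response in responses.columns:
        y = responses[response].to_numpy(dtype=float)
        ss_total = float(np.sum((y - y.mean()) ** 2))
        coeffs, ss_effects = {}, {}
        for term in terms:
            c = np.ones(n)
            for f in term:
                c = c * col[f]
            b = float(c @ y) / n
            coeffs[term] = b
            ss_effects[term] = n * b * b
        ss_res = max(ss_total - sum(ss_effects.values()), 0.0)
        df_res = n - 1 - len(terms)
        msw = ss_res / df_res
        for term in terms:
            msb = ss_effects[term]  # 1 df
            if msw <= 1e-300:
                # zero residual: either the response is constant (every SS
                # at rounding level) or this effect models it perfectly
                perfect = msb > 1e-20
                f_scaled = np.inf if perfect else 0.0
                p = 0.0 if perfect else 1.0
            else:
                perfect = False
                ratio = msb / msw
                f_scaled = ratio * 100.0
                p = float(f_dist.sf(ratio, 1, df_res))
            sign = None
            if len(term) == 1 and p <= alpha and coeffs[term] != 0:
                sign = "+" if coeffs[term] > 0 else "−"
            records.append(
                EffectRecord(
                    effect=term,
                    response=str(response),
                    MSB=msb,
                    MSW=msw,
                    F=f_scaled,
                    p=p,
                    sign=sign,
                    coefficient=coeffs[term],
                    perfect_fit=perfect,
                )
            )
    return records


def aggregate_groups(
    records: list[EffectRecord],
    groups: dict[str, list[str]] | None = None,
    alpha: float = ALPHA,
) -> SensitivityReport:
    """Aggregate per-response effects to response groups.

    An effect is significant for a group when p ≤ alpha for at least one
    response node in the group; the group F is the maximum F across the
    group's responses.  Non-significant effects are retained and flagged.
    """
    if groups is None:
        groups = {
            "structural-proteins": list(STRUCTURAL_GROUP),
            "degrading-enzymes": list(ENZYME_GROUP),
        }
    rows = []
    for gname, members in groups.items():
        member_set = set(members)
        by_effect: dict[tuple[str, ...], list[EffectRecord]] = {}
        for rec in records:
            if rec.response in member_set:
                by_effect.setdefault(rec.effect, []).append(rec)
        for effect, recs in by_effect.items():
            best = max(recs, key=lambda r: (r.F, r.response))
            significant = any(r.p <= alpha for r in recs)
            sig_mains = [r.sign for r in recs if r.sign is not None]
            rows.append(
                {
                    "group": gname,
                    "effect": "×".join(effect),
                    "order": len(effect),
                    "F": best.F,
                    "p": min(r.p for r in recs),
                    "best_response": best.response,
                    "significant": significant,
                    "sign": sig_mains[0] if sig_mains else None,
                }
            )
    table = pd.DataFrame(rows)
    return SensitivityReport(records=records, groups=dict(groups), group_table=table)


def pareto_table(
    report: SensitivityReport,
    group: str | None = None,
    main_effects_only: bool = False,
    significant_only: bool = True,
    alpha: float = ALPHA,
) -> pd.DataFrame:
    """Pareto ranking of effects: descending F (infinite-F records first),
    with log10(F) attached for plotting; ties broken by (effect, response).

    ``significant_only`` keeps the paper's convention that only p ≤ 0.05
    effects enter the chart; ``main_effects_only`` restricts to direct
    effects (the cytokine view), while the growth-factor view keeps
    interactions.
    """
    table = report.group_table
    if table.empty:
        return pd.DataFrame(
            columns=["group", "effect", "order", "F", "p", "log10_F", "sign"]
        )
    if group is not None:
        table = table[table["group"] == group]
    if main_effects_only:
        table = table[table["order"] == 1]
    if significant_only:
        table = table[table["p"] <= alpha]
    table = table.copy()
    with np.errstate(divide="ignore"):
        table["log10_F"] = np.log10(table["F"].to_numpy(dtype=float))
    table["_inf"] = ~np.isfinite(table["F"])
    table = table.sort_values(
        by=["_inf", "F", "effect", "best_response"],
        ascending=[False, False, True, True],
        kind="mergesort",
    ).drop(columns="_inf")
    return table.reset_index(drop=True)
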