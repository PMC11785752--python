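"""In-silico perturbation experiments: clamping, rescue, and node-wise
Mann–Whitney comparison of steady-state ensembles.

A perturbation clamps one or more nodes (e.g. TNF=1 to emulate sustained
pro-inflammatory stimulation) and re-integrates every baseline steady state
under the clamp, giving an ensemble paired run-by-run with the baseline.
Shifts are tested per node with a two-sided Mann–Whitney U test; a rescue
experiment adds anti-inflammatory/growth-factor clamps on top of a
degenerate (clamped) baseline.  A phenotype call contrasts mean activation
of anabolic nodes (ACAN, COL2A, growth factors) against catabolic ones
(MMPs, ADAMTS4/5, pro-inflammatory cytokines).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .dynamics import SimulationConfig, validate_clamps
from .ensemble import EnsembleResult, run_ensemble_from_states
from .network import RegulatoryNetwork

__all__ = [
    "PerturbationProtocol",
    "ComparisonResult",
    "PhenotypeScore",
    "run_perturbation",
    "compare_distributions",
    "rescue_experiment",
    "classify_phenotype",
    "default_phenotype_groups",
    "mann_whitney",
]


@dataclass
class PerturbationProtocol:
    """A named clamping protocol.

    start_mode "from-baseline-SS" continues each baseline run's steady state
    under the new clamps (the default: perturbations are applied to an
    equilibrated system); "from-random" re-draws random initial states.
    """

    label: str
    added_clamps: dict[str, float]
    baseline_clamps: dict[str, float] = field(default_factory=dict)
    start_mode: str = "from-baseline-SS"

    def __post_init__(self):
        if self.start_mode not in ("from-baseline-SS", "from-random"):
            raise ValueError(f"unknown start_mode {self.start_mode!r}")
        for key, val in self.added_clamps.items():
            if key in self.baseline_clamps and self.baseline_clamps[key] != val:
                raise ValueError(
                    f"clamp {key!r} appears in both sets with different values"
                )

    @property
    def clamps(self) -> dict[str, float]:
        merged = dict(self.baseline_clamps)
        merged.update(self.added_clamps)
        return merged


@dataclass
class ComparisonResult:
    """Node-wise Mann–Whitney statistics between two ensembles."""

    stats: pd.DataFrame  # index node; columns U, p, direction, significant
    alpha: float

    def significant_nodes(self) -> list[str]:
        return list(self.stats.index[self.stats["significant"]])

    def direction(self, node: str) -> str:
        return str(self.stats.loc[node, "direction"])


@dataclass
class PhenotypeScore:
    anabolic_index: float
    catabolic_index: float
    call: str  # pro-anabolic | pro-catabolic | balanced
    margin: float


def run_perturbation(
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None,
    protocol: PerturbationProtocol,
    baseline: EnsembleResult,
) -> EnsembleResult:
    """Apply a clamping protocol on top of a baseline ensemble.

    With start_mode "from-baseline-SS", run k of the result is the steady
    state reached from baseline run k's steady state under the union of
    clamps — the perturbed ensemble is paired run-by-run with the baseline.
    """
    cfg = cfg or SimulationConfig()
    clamps = validate_clamps(protocol.clamps, net)
    if list(baseline.node_names) != list(net.node_names):
        raise ValueError("baseline ensemble does not match the network's nodes")
    if protocol.start_mode == "from-baseline-SS":
        starts = baseline.steady_states.to_numpy(dtype=float)
    else:
        from .ensemble import sample_initial_conditions

        seed0 = baseline.seeds[0] if baseline.seeds else 0
        starts = sample_initial_conditions(
            len(net.nodes), baseline.n_runs, seed0
        )
    return run_ensemble_from_states(
        net, cfg, initial_states=starts, clamps=clamps, seeds=baseline.seeds
    )


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann–Whitney U on two samples.

    Returns (U, p) with U = min(U1, U2).  Exact null distribution when
    min(n1, n2) ≤ 20 and the pooled sample is tie-free; otherwise the
    normal approximation with tie correction.  Two identical constant
    samples give U = n1·n2/2, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return n1 * n2 / 2.0, 1.0
    has_ties = len(np.unique(pooled)) < n1 + n2
    method = "exact" if (min(n1, n2) <= 20 and not has_ties) else "asymptotic"
    res = mannwhitneyu(x, y, alternative="two-sided", method=method)
    u1 = float(res.statistic)
    u = min(u1, n1 * n2 - u1)
    return u, float(res.pvalue)


def compare_distributions(
    baseline: EnsembleResult | pd.DataFrame,
    perturbed: EnsembleResult | pd.DataFrame,
    alpha: float = 0.05,
) -> ComparisonResult:
    """Node-wise two-sided Mann–Whitney U between two ensembles.

    direction: "up" / "down" from the sign of the perturbed−baseline median
    shift, "unchanged" when the medians coincide.  significant ⇔ p < alpha.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    base = baseline.steady_states if isinstance(baseline, EnsembleResult) else baseline
    pert = perturbed.steady_states if isinstance(perturbed, EnsembleResult) else perturbed
    if list(base.columns) != list(pert.columns):
        raise ValueError("ensembles cover different node sets")
    rows = []
    for node in base.columns:
        xb = base[node].to_numpy(dtype=float)
        xp = pert[node].to_numpy(dtype=float)
        u, p = mann_whitney(xb, xp)
        shift = float(np.median(xp) - np.median(xb))
        if shift > 0:
            direction = "up"
        elif shift < 0:
            direction = "down"
        else:
            direction = "unchanged"
        rows.append(
            {
                "node": node,
                "U": u,
                "p": p,
                "direction": direction,
                "significant": bool(p < alpha),
            }
        )
    return ComparisonResult(stats=pd.DataFrame(rows).set_index("node"), alpha=alpha)


def rescue_experiment(
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None,
    degenerate_clamps: dict[str, float],
    rescue_clamps: dict[str, float],
    baseline: EnsembleResult,
    alpha: float = 0.05,
    mode: str = "from-degenerate-SS",
) -> tuple[EnsembleResult, ComparisonResult]:
    """Rescue stimulation on top of a degenerate clamped baseline.

    First derives the degenerate ensemble (baseline continued under
    ``degenerate_clamps``; co-stimulation sets like {TNF:1, IL-1β:1} are one
    clamp set).  Then applies ``rescue_clamps`` in addition:

    - "from-degenerate-SS" (default): rescue runs start from the degenerate
      steady states (stimulation after the degenerate state equilibrated);
    - "from-baseline-SS": degenerate and rescue clamps applied together
      starting from the original baseline steady states.

    Returns the rescue ensemble and its node-wise comparison against the
    degenerate ensemble.
    """
    cfg = cfg or SimulationConfig()
    overlap = {
        k
        for k, v in rescue_clamps.items()
        if k in degenerate_clamps and degenerate_clamps[k] != v
    }
    if overlap:
        raise ValueError(f"rescue clamps conflict with degenerate clamps: {overlap}")
    degenerate = run_perturbation(
        net,
        cfg,
        PerturbationProtocol(label="degenerate", added_clamps=degenerate_clamps),
        baseline,
    )
    merged = dict(degenerate_clamps)
    merged.update(rescue_clamps)
    if mode == "from-degenerate-SS":
        start = degenerate
    elif mode == "from-baseline-SS":
        start = baseline
    else:
        raise ValueError(f"unknown rescue mode {mode!r}")
    rescued = run_perturbation(
        net,
        cfg,
        PerturbationProtocol(label="rescue", added_clamps=merged),
        start,
    )
    return rescued, compare_distributions(degenerate, rescued, alpha=alpha)


def default_phenotype_groups(net: RegulatoryNetwork) -> dict[str, list[str]]:
    """Anabolic/catabolic node groups from network categories: anabolic =
    ACAN & COL2A (when present) plus growth factors; catabolic = degrading
    enzymes plus pro-inflammatory cytokines."""
    cats = net.categories()
    anabolic = [n for n in ("ACAN", "COL2A") if n in cats]
    anabolic += [n for n, c in cats.items() if c == "growth-factor"]
    catabolic = [
        n
        for n, c in cats.items()
        if c in ("degrading-enzyme", "pro-inflammatory-cytokine")
    ]
    return {"anabolic": anabolic, "catabolic": catabolic}


def classify_phenotype(
    state,
    groups: dict[str, list[str]],
    margin: float = 0.1,
) -> PhenotypeScore:
    """Contrast mean anabolic vs catabolic activation of one steady state.

    ``state`` is a mapping node → level (or pandas Series).  call is
    pro-anabolic when anabolic − catabolic > margin, pro-catabolic when
    < −margin, balanced otherwise.
    """
    if isinstance(state, pd.Series):
        state = state.to_dict()
    for key in ("anabolic", "catabolic"):
        if not groups.get(key):
            raise ValueError(f"empty {key!r} group")
    anabolic = float(np.mean([state[n] for n in groups["anabolic"]]))
    catabolic = float(np.mean([state[n] for n in groups["catabolic"]]))
    diff = anabolic - catabolic
    if diff > margin:
        call = "pro-anabolic"
    elif diff < -margin:
        call = "pro-catabolic"
    else:
        call = "balanced"
    return PhenotypeScore(
        anabolic_index=anabolic,
        catabolic_index=catabolic,
        call=call,
        margin=margin,
    )
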