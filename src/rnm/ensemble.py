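"""Baseline ensembles: random initial conditions, attractor clustering and
per-node steady-state statistics.

The baseline protocol integrates the network from many uniformly random
initial states (one Mersenne-Twister stream per run, seeded seed_base+k),
collects the steady states, groups them into attractor clusters by
single-linkage under the Chebyshev (max-coordinate) metric, and reports the
share of runs in the dominant cluster together with boxplot-style summaries
per node.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist
from scipy.stats import skew

from .dynamics import CompiledModel, SimulationConfig, integrate_to_steady_state
from .network import RegulatoryNetwork

__all__ = [
    "EnsembleResult",
    "sample_initial_conditions",
    "run_baseline_ensemble",
    "run_ensemble_from_states",
    "cluster_attractors",
    "summarize_baseline",
]


@dataclass
class EnsembleResult:
    """Steady states of one ensemble of runs over a fixed network/config."""

    steady_states: pd.DataFrame  # index: run id, columns: node names
    seeds: list[int]
    converged: np.ndarray  # bool per run
    clusters: list[list[int]]  # run positions of converged runs, largest first
    dominant_fraction: float
    per_node_summary: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n_runs(self) -> int:
        return len(self.steady_states)

    @property
    def node_names(self) -> list[str]:
        return list(self.steady_states.columns)

    def values(self, node: str) -> np.ndarray:
        return self.steady_states[node].to_numpy()


def sample_initial_conditions(
    n_nodes: int, n_runs: int, seed_base: int = 0
) -> np.ndarray:
    """Uniform random initial states on [0,1]^n, one Mersenne-Twister stream
    per run seeded ``seed_base + k``; deterministic for fixed arguments."""
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    states = np.empty((n_runs, n_nodes))
    for k in range(n_runs):
        states[k] = np.random.RandomState(seed_base + k).uniform(size=n_nodes)
    return states


def cluster_attractors(steady_states, tol: float = 0.01) -> list[list[int]]:
    """Single-linkage grouping of steady-state rows at Chebyshev distance
    ≤ tol.  Clusters are returned largest first (ties: smallest first row
    index), each cluster sorted by row position."""
    ss = np.asarray(steady_states, dtype=float)
    if ss.ndim != 2 or len(ss) == 0:
        raise ValueError("need a non-empty 2-D array of steady states")
    if len(ss) == 1:
        return [[0]]
    labels = fcluster(
        linkage(pdist(ss, metric="chebyshev"), method="single"),
        t=tol,
        criterion="distance",
    )
    groups: dict[int, list[int]] = {}
    for pos, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(pos)
    return sorted(groups.values(), key=lambda g: (-len(g), g[0]))


def summarize_baseline(result) -> pd.DataFrame:
    """Boxplot-style statistics per node: median, quartiles, 1.5×IQR
    whiskers (clipped to observed values), outlier count and skewness note.

    Accepts an :class:`EnsembleResult` or a runs × nodes DataFrame.
    """
    frame = (
        result.steady_states if isinstance(result, EnsembleResult) else result
    )
    if len(frame) == 0:
        raise ValueError("empty ensemble")
    rows = []
    for node in frame.columns:
        x = frame[node].to_numpy(dtype=float)
        q1, med, q3 = np.percentile(x, [25, 50, 75])
        iqr = q3 - q1
        lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
        inside = x[(x >= lo_fence) & (x <= hi_fence)]
        if np.ptp(x) > 1e-12:
            import warnings as _warnings

            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # near-constant columns
                sk = float(skew(x))
        else:
            sk = 0.0
        if abs(sk) < 1e-12:
            shape = "symmetric"
        else:
            shape = "right-skewed" if sk > 0 else "left-skewed"
        rows.append(
            {
                "node": node,
                "median": med,
                "q1": q1,
                "q3": q3,
                "whisker_low": float(inside.min()),
                "whisker_high": float(inside.max()),
                "n_outliers": int(np.sum((x < lo_fence) | (x > hi_fence))),
                "skewness": sk,
                "shape": shape,
            }
        )
    return pd.DataFrame(rows).set_index("node")


def run_ensemble_from_states(
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None = None,
    initial_states: np.ndarray | None = None,
    clamps: dict[str, float] | None = None,
    seeds: list[int] | None = None,
    method: str = "adaptive",
) -> EnsembleResult:
    """Integrate every row of ``initial_states`` to steady state and collect
    the ensemble.  Unconverged runs are kept and flagged, but excluded from
    attractor clustering."""
    cfg = cfg or SimulationConfig()
    model = CompiledModel(net, cfg, clamps)  # early clamp/shape validation
    initial_states = np.asarray(initial_states, dtype=float)
    if initial_states.ndim != 2 or initial_states.shape[1] != model.n_nodes:
        raise ValueError(
            f"initial_states must be (n_runs, {model.n_nodes}), "
            f"got {initial_states.shape}"
        )
    finals = np.empty_like(initial_states)
    converged = np.zeros(len(initial_states), dtype=bool)
    import warnings as _warnings

    for k, x0 in enumerate(initial_states):
        try:
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")  # input-node note once per run
                _, x_ss = integrate_to_steady_state(
                    x0, net, cfg, clamps, method=method
                )
        except Exception as exc:
            raise RuntimeError(f"run {k} failed: {exc}") from exc
        finals[k] = x_ss
        converged[k] = model.residual(x_ss) <= cfg.ss_tol
    frame = pd.DataFrame(finals, columns=model.names)
    frame.index.name = "run"
    conv_pos = np.where(converged)[0]
    if conv_pos.size:
        clusters_local = cluster_attractors(finals[conv_pos], tol=cfg.cluster_tol)
        clusters = [[int(conv_pos[i]) for i in grp] for grp in clusters_local]
        dominant = len(clusters[0]) / conv_pos.size
    else:
        clusters, dominant = [], 0.0
    result = EnsembleResult(
        steady_states=frame,
        seeds=list(seeds or []),
        converged=converged,
        clusters=clusters,
        dominant_fraction=float(dominant),
    )
    result.per_node_summary = summarize_baseline(result)
    return result


def run_baseline_ensemble(
    net: RegulatoryNetwork,
    cfg: SimulationConfig | None = None,
    clamps: dict[str, float] | None = None,
    n_runs: int = 100,
    seed_base: int = 0,
    method: str = "adaptive",
) -> EnsembleResult:
    """The baseline protocol: ``n_runs`` random initial conditions (streams
    seeded seed_base..seed_base+n_runs−1), each integrated to steady state."""
    cfg = cfg or SimulationConfig()
    states = sample_initial_conditions(len(net.nodes), n_runs, seed_base)
    return run_ensemble_from_states(
        net,
        cfg,
        initial_states=states,
        clamps=clamps,
        seeds=[seed_base + k for k in range(n_runs)],
        method=method,
    )
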