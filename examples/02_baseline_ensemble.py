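"""The baseline protocol: 100 random initial conditions to steady state.

Each run starts from a uniformly random activation state (one Mersenne-
Twister stream per run), integrates the fuzzy-logic ODE system to steady
state, and the resulting steady states are clustered into attractors.  The
dominant-attractor share measures how strongly the topology determines the
outcome regardless of where the system starts.
"""

from rnm import SimulationConfig, generate_paper_like_fixture, run_baseline_ensemble

net = generate_paper_like_fixture(seed=0)
cfg = SimulationConfig()  # h=10, gamma=1, alpha=beta=1, horizon 30 time units

result = run_baseline_ensemble(net, cfg, n_runs=100, seed_base=0)
print(f"converged runs: {int(result.converged.sum())}/100")
print(
    f"dominant attractor: {100 * result.dominant_fraction:.0f}% of runs "
    f"({len(result.clusters)} attractor cluster(s) at Chebyshev tol {cfg.cluster_tol})"
)

summary = result.per_node_summary
print("\nper-node steady-state medians (0 = silent, 1 = fully active):")
for node in ("ACAN", "COL2A", "TGF-β", "IL-1β", "TNF", "MMP3"):
    row = summary.loc[node]
    print(f"  {node:7s} median {row['median']:.3f}  IQR [{row['q1']:.3f}, {row['q3']:.3f}]  {row['shape']}")
print(
    "\nhigh structural/growth-factor activity with low cytokine/protease "
    "activity reads as a healthy (pro-anabolic) baseline."
)
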