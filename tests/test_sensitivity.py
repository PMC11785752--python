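"""Full-factorial design generation, batch evaluation and factorial ANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest

from rnm import (
    SimulationConfig,
    aggregate_groups,
    anova_effects,
    full_factorial,
    pareto_table,
    run_design,
)
from rnm.sensitivity import EffectRecord, SensitivityReport

from conftest import make_net


def cell_means_ss(design, y, term):
    """Brute-force sums of squares from group means: SSB for a main effect,
    and the cell-means interaction SS (cells minus mains) for a pair."""
    rows = design.rows
    y = np.asarray(y, dtype=float)
    grand = y.mean()
    idx = {f: k for k, f in enumerate(design.factors)}

    def ssb(cols):
        keys = [tuple(row[c] for c in cols) for row in rows]
        total = 0.0
        for key in set(keys):
            mask = np.array([k == key for k in keys])
            total += mask.sum() * (y[mask].mean() - grand) ** 2
        return total

    if len(term) == 1:
        return ssb([idx[term[0]]])
    a, b = term
    return ssb([idx[a], idx[b]]) - ssb([idx[a]]) - ssb([idx[b]])


class TestDesign:
    def test_two_factor_canonical_order(self):
        d = full_factorial(["A", "B"])
        assert d.rows.tolist() == [[0, 0], [0, 1], [1, 0], [1, 1]]

    def test_duplicate_factor_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            full_factorial(["A", "A"])

    def test_degenerate_levels_rejected(self):
        with pytest.raises(ValueError):
            full_factorial(["A"], levels=(1.0, 1.0))

    @pytest.mark.parametrize("p", [1, 2, 3, 4, 5])
    def test_balance_and_orthogonality(self, p):
        d = full_factorial([f"F{i}" for i in range(p)])
        assert d.n_rows == 2**p
        coded = d.coded()
        assert np.all(coded.sum(axis=0) == 0)  # balanced
        for i, j in itertools.combinations(range(p), 2):
            assert coded[:, i] @ coded[:, j] == 0  # orthogonal


class TestRunDesign:
    def test_zero_state_fixed_point_gives_zero_responses(self, cfg):
        # activation-only chain: x=0 is a fixed point of every node
        net = make_net([("A", "B", 1), ("B", "C", 1)])
        design = full_factorial(["A"])  # row 0 is the all-zero initial state
        resp = run_design(net, cfg, design, {"A": 0.0, "B": 0.0, "C": 0.0}, ["B", "C"])
        assert np.allclose(resp.iloc[0].to_numpy(), 0.0, atol=1e-6)

    def test_factor_level_raises_downstream_response(self, cfg):
        net = make_net([("F", "R", 1)])
        design = full_factorial(["F"])
        resp = run_design(net, cfg, design, {"F": 0.0, "R": 0.0}, ["R"])
        assert resp.iloc[1, 0] > resp.iloc[0, 0]

    def test_row_count_contract(self, cfg):
        net = make_net([("F", "R", 1), ("G", "R", -1)])
        design = full_factorial(["F", "G"])
        resp = run_design(net, cfg, design, {"F": 0, "G": 0, "R": 0}, ["R"])
        assert len(resp) == design.n_rows

    def test_unknown_factor_rejected(self, cfg):
        from rnm import UnknownNodeError

        net = make_net([("F", "R", 1)])
        with pytest.raises(UnknownNodeError):
            run_design(net, cfg, full_factorial(["Z"]), {"F": 0, "R": 0}, ["R"])


class TestAnova:
    def test_constant_response(self):
        d = full_factorial(["A", "B", "C"])
        resp = pd.DataFrame({"Y": np.full(8, 0.4)})
        for rec in anova_effects(d, resp):
            assert rec.F == 0.0 and rec.p == 1.0

    def test_perfectly_explained_response_flagged(self):
        d = full_factorial(["A", "B", "C"])
        resp = pd.DataFrame({"Y": d.coded()[:, 0]})
        recs = {r.effect: r for r in anova_effects(d, resp)}
        assert recs[("A",)].perfect_fit and np.isinf(recs[("A",)].F)
        assert recs[("A",)].p == 0.0
        for term, rec in recs.items():
            if term != ("A",):
                assert rec.MSB == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("p", [3, 4])
    def test_effect_ss_matches_cell_means_oracle(self, p, rng):
        d = full_factorial([f"F{i}" for i in range(p)])
        y = rng.uniform(size=d.n_rows)
        recs = anova_effects(d, pd.DataFrame({"Y": y}))
        total = np.sum((y - y.mean()) ** 2)
        ss_sum = 0.0
        for rec in recs:
            ss_ref = cell_means_ss(d, y, rec.effect)
            assert rec.MSB == pytest.approx(ss_ref, rel=1e-10, abs=1e-12)
            ss_sum += rec.MSB
        residual = total - ss_sum
        # decomposition closes: sum of effect SS + residual SS = total SS
        assert ss_sum + residual == pytest.approx(total, rel=1e-8)
        assert residual >= -1e-10

    def test_row_permutation_leaves_effects_unchanged(self, rng):
        d = full_factorial(["A", "B", "C"])
        y = rng.uniform(size=8)
        ref = {r.effect: (r.MSB, r.F, r.p) for r in anova_effects(d, pd.DataFrame({"Y": y}))}
        perm = rng.permutation(8)
        d_perm = full_factorial(["A", "B", "C"])
        d_perm.rows = d_perm.rows[perm]
        got = {
            r.effect: (r.MSB, r.F, r.p)
            for r in anova_effects(d_perm, pd.DataFrame({"Y": y[perm]}))
        }
        for term in ref:
            assert got[term] == pytest.approx(ref[term])

    def test_scaling_applies_to_f_not_p(self, rng):
        from scipy.stats import f as f_dist

        d = full_factorial(["A", "B", "C"])
        y = rng.uniform(size=8)
        for rec in anova_effects(d, pd.DataFrame({"Y": y})):
            if rec.MSW > 0:
                ratio = rec.F / 100.0
                assert rec.p == pytest.approx(float(f_dist.sf(ratio, 1, 8 - 1 - 6)))

    def test_main_only_order(self):
        d = full_factorial(["A", "B", "C"])
        recs = anova_effects(d, pd.DataFrame({"Y": d.coded()[:, 1]}), order="main")
        assert {r.effect for r in recs} == {("A",), ("B",), ("C",)}


def _record(effect, response, F, p, sign=None):
    return EffectRecord(
        effect=effect, response=response, MSB=F, MSW=1.0, F=F, p=p,
        sign=sign, coefficient=1.0,
    )


class TestAggregation:
    def test_effect_listed_only_for_its_group(self):
        recs = [
            _record(("IL-6",), "COL2A", 500.0, 0.01, "+"),
            _record(("IL-6",), "MMP3", 5.0, 0.4),
        ]
        report = aggregate_groups(recs)
        table = report.group_table.set_index(["group", "effect"])
        assert table.loc[("structural-proteins", "IL-6"), "significant"]
        assert not table.loc[("degrading-enzymes", "IL-6"), "significant"]

    def test_non_significant_effect_retained(self):
        recs = [_record(("IL-8",), "COL2A", 2.0, 0.9)]
        report = aggregate_groups(recs)
        row = report.group_table.iloc[0]
        assert not row["significant"]

    def test_group_f_is_member_maximum(self):
        recs = [
            _record(("TGF-β",), "ACAN", 300.0, 0.01, "+"),
            _record(("TGF-β",), "COL2A", 900.0, 0.001, "+"),
        ]
        report = aggregate_groups(recs)
        row = report.group_table.set_index(["group", "effect"]).loc[
            ("structural-proteins", "TGF-β")
        ]
        assert row["F"] == 900.0 and row["best_response"] == "COL2A"


class TestPareto:
    def test_descending_with_log10(self):
        recs = [
            _record(("A",), "ACAN", 4.0, 0.01, "+"),
            _record(("B",), "ACAN", 400.0, 0.01, "+"),
            _record(("C",), "ACAN", 40.0, 0.01, "+"),
        ]
        table = pareto_table(aggregate_groups(recs), group="structural-proteins")
        assert table["F"].tolist() == [400.0, 40.0, 4.0]
        assert table["log10_F"].tolist() == pytest.approx(
            [np.log10(400), np.log10(40), np.log10(4)]
        )

    def test_infinite_f_sorts_first(self):
        recs = [
            _record(("A",), "ACAN", 1e6, 0.001, "+"),
            _record(("B",), "ACAN", np.inf, 0.0, "+"),
        ]
        table = pareto_table(aggregate_groups(recs), group="structural-proteins")
        assert table.iloc[0]["effect"] == "B"

    def test_tie_break_deterministic(self):
        recs = [
            _record(("Z",), "ACAN", 50.0, 0.01, "+"),
            _record(("A",), "ACAN", 50.0, 0.01, "+"),
        ]
        table = pareto_table(aggregate_groups(recs), group="structural-proteins")
        assert table["effect"].tolist() == ["A", "Z"]

    def test_main_effects_only_view(self):
        recs = [
            _record(("A",), "ACAN", 50.0, 0.01, "+"),
            _record(("A", "B"), "ACAN", 80.0, 0.01),
        ]
        table = pareto_table(
            aggregate_groups(recs), main_effects_only=True
        )
        assert table["order"].tolist() == [1]

    def test_significance_filter(self):
        recs = [
            _record(("A",), "ACAN", 50.0, 0.01, "+"),
            _record(("B",), "ACAN", 5.0, 0.5),
        ]
        report = aggregate_groups(recs)
        assert pareto_table(report)["effect"].tolist() == ["A"]
        assert len(pareto_table(report, significant_only=False)) == 2

    def test_empty_report(self):
        table = pareto_table(SensitivityReport(records=[], groups={}))
        assert table.empty
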