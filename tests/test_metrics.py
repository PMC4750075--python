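import itertools

import numpy as np
import pandas as pd
import pytest

from fusegrn.io import GoldStandard
from fusegrn.metrics import (
    make_universe,
    overall_score,
    roc_pr,
    selector_value,
    type_fractions,
)
from fusegrn.network import Network, normalize_edges


def scored_network(weights: dict, signs: dict | None = None) -> Network:
    rows = []
    for (r, t), w in sorted(weights.items(), key=lambda kv: -kv[1]):
        rows.append(
            {
                "regulator": r,
                "target": t,
                "consensus": w * (signs or {}).get((r, t), 1),
                "normalized_weight": w,
                "sign": (signs or {}).get((r, t), 1),
            }
        )
    return Network(pd.DataFrame(
        rows, columns=["regulator", "target", "consensus", "normalized_weight",
                       "sign"]
    ), [])


def brute_force_auroc(scores, labels):
    """Mann-Whitney probability that a positive outranks a negative (ties 1/2)."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocPr:
    def test_perfect_ranking_gives_auroc_one(self):
        universe = make_universe(["A", "B"], ["x", "y"])
        gold = GoldStandard({("A", "x"): 0, ("B", "y"): 0})
        net = scored_network({("A", "x"): 1.0, ("B", "y"): 0.9, ("A", "y"): 0.1})
        report = roc_pr(net, gold, universe)
        assert report.auroc == pytest.approx(1.0)

    def test_auroc_matches_brute_force_mann_whitney(self):
        # full enumeration on toy universes, random scores with heavy ties
        rng = np.random.default_rng(0)
        for n_reg, n_tgt in [(3, 3), (4, 4), (8, 8)]:
            regs = [f"R{i}" for i in range(n_reg)]
            tgts = [f"T{i}" for i in range(n_tgt)]
            universe = make_universe(regs, tgts)
            for _ in range(5):
                labels = rng.random(len(universe)) < 0.3
                if labels.all() or not labels.any():
                    continue
                scores = rng.choice([0.0, 0.2, 0.5, 0.5, 0.9, 1.0],
                                    size=len(universe))
                net = scored_network(
                    {p: s for p, s in zip(universe, scores) if s > 0}
                )
                gold = GoldStandard(
                    {p: 0 for p, l in zip(universe, labels) if l}
                )
                report = roc_pr(net, gold, universe)
                assert report.auroc == pytest.approx(
                    brute_force_auroc(scores, labels), abs=1e-12
                )

    def test_empty_network_scores_at_chance(self):
        universe = make_universe(["A", "B"], ["x", "y"])
        gold = GoldStandard({("A", "x"): 0})
        net = scored_network({})
        report = roc_pr(net, gold, universe)
        assert report.auroc == pytest.approx(0.5)
        assert report.tpr_at_fpr == 0.0

    def test_tpr_at_fpr_reads_step_curve(self):
        regs = [f"R{i}" for i in range(10)]
        universe = make_universe(regs, ["x"])
        gold = GoldStandard({("R0", "x"): 0, ("R5", "x"): 0})
        # R0 top-ranked, one false positive above R5
        weights = {("R0", "x"): 1.0, ("R1", "x"): 0.8, ("R5", "x"): 0.6}
        net = scored_network(weights)
        report = roc_pr(net, gold, universe, fpr_target=0.03)
        # at FPR <= 0.03 only R0 is recovered: TPR = 0.5
        assert report.tpr_at_fpr == pytest.approx(0.5)

    def test_gold_edge_outside_universe_rejected(self):
        universe = make_universe(["A"], ["x"])
        gold = GoldStandard({("Z", "q"): 0})
        with pytest.raises(ValueError, match="outside"):
            roc_pr(scored_network({}), gold, universe)

    def test_empty_gold_rejected(self):
        universe = make_universe(["A"], ["x"])
        with pytest.raises(ValueError, match="empty"):
            roc_pr(scored_network({}), GoldStandard({}), universe)


class TestSelectorValue:
    def test_top_ranked_true_positive_gives_one(self):
        net = scored_network({("A", "x"): 1.0, ("B", "x"): 0.4})
        assert selector_value(net, GoldStandard({("A", "x"): 0})) == 1.0

    def test_constructed_third_rank_case(self):
        net = scored_network(
            {("A", "x"): 1.0, ("B", "x"): 0.8, ("C", "x"): 0.7, ("D", "x"): 0.2}
        )
        gold = GoldStandard({("C", "x"): 0, ("D", "x"): 0})
        assert selector_value(net, gold) == pytest.approx(0.7)

    def test_no_true_positive_gives_zero_with_warning(self, caplog):
        import logging

        net = scored_network({("A", "x"): 1.0})
        with caplog.at_level(logging.WARNING, logger="fusegrn"):
            val = selector_value(net, GoldStandard({("B", "x"): 0}))
        assert val == 0.0
        assert "no true positive" in caplog.text

    def test_dominates_every_lower_ranked_true_positive(self):
        rng = np.random.default_rng(1)
        weights = {(f"R{i}", "x"): w for i, w in
                   enumerate(sorted(rng.random(12), reverse=True))}
        net = normalize_edges(
            scored_network(weights), top_n=12
        )
        gold = GoldStandard({("R3", "x"): 0, ("R7", "x"): 0, ("R11", "x"): 0})
        sel = selector_value(net, gold)
        tp_weights = [
            w for (r, t), w in net.edge_weights().items() if (r, t) in gold.edges
        ]
        assert sel == pytest.approx(max(tp_weights))


class TestOverallScore:
    def test_constant_inputs_reduce_to_plain_average(self):
        _, _, score = overall_score([(0.6, 0.01)] * 5)
        assert score == pytest.approx((0.6 + 0.01) / 2.0)

    def test_symmetric_under_data_set_permutation(self):
        pairs = [(0.6, 0.005), (0.65, 0.004), (0.62, 0.006)]
        assert overall_score(pairs) == pytest.approx(overall_score(pairs[::-1]))

    def test_single_data_set_reduces_to_mean_of_auroc_and_aupr(self):
        _, _, score = overall_score([(0.7, 0.2)])
        assert score == pytest.approx(0.45)

    def test_geometric_means_computed_per_metric(self):
        auroc_s, aupr_s, score = overall_score([(0.4, 0.01), (0.9, 0.04)])
        assert auroc_s == pytest.approx(np.sqrt(0.4 * 0.9))
        assert aupr_s == pytest.approx(np.sqrt(0.01 * 0.04))
        assert score == pytest.approx((auroc_s + aupr_s) / 2.0)

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValueError):
            overall_score([(0.5, 0.0)])
        with pytest.raises(ValueError):
            overall_score([])


class TestTypeFractions:
    universe = make_universe(["A", "B", "C"], ["x", "y"])
    gold = GoldStandard(
        {("A", "x"): 1, ("A", "y"): 1, ("B", "x"): 1, ("B", "y"): -1,
         ("C", "x"): -1}
    )

    def test_perfect_signed_prediction(self):
        signs = dict(self.gold.edges)
        net = scored_network({e: 0.9 for e in signs}, signs)
        plus, minus, tp, tn = type_fractions(net, self.gold, self.universe)
        assert (plus, minus, tp, tn) == (1.0, 1.0, 1.0, 1.0)

    def test_flipping_all_signs_zeroes_fractions_but_not_tp(self):
        signs = {e: -s for e, s in self.gold.edges.items()}
        net = scored_network({e: 0.9 for e in signs}, signs)
        plus, minus, tp, _ = type_fractions(net, self.gold, self.universe)
        assert plus == 0.0 and minus == 0.0 and tp == 1.0

    def test_hand_enumerated_partial_prediction(self):
        # 4 predictions: 2 correct activating, 1 wrong-sign repressing,
        # 1 false positive (C,y)
        signs = {("A", "x"): 1, ("A", "y"): 1, ("B", "y"): 1, ("C", "y"): 1}
        net = scored_network({e: 0.5 for e in signs}, signs)
        plus, minus, tp, tn = type_fractions(net, self.gold, self.universe)
        assert plus == pytest.approx(2.0 / 3.0)   # of 3 activating gold edges
        assert minus == pytest.approx(0.0)        # of 2 repressing gold edges
        assert tp == pytest.approx(3.0 / 5.0)     # 3 of 5 gold edges predicted
        assert tn == pytest.approx(0.0)           # the only non-gold pair is hit

    def test_unsigned_gold_rejected(self):
        gold = GoldStandard({("A", "x"): 0})
        with pytest.raises(ValueError, match="signed"):
            type_fractions(scored_network({}), gold, self.universe)
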