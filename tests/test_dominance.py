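"""Twelve-pattern dominance classification: the decision table, its
exhaustiveness, label symmetry, summaries and candidate extraction."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from polyhet import de, dominance, sets, simulate
from polyhet.dominance import classify_gene


class TestClassifyGene:
    @pytest.mark.parametrize("calls,group", [
        (("+", "+", "0"), "transgressive_up"),    # F1 above both, parents equal
        (("-", "-", "0"), "transgressive_down"),
        (("-", "+", "+"), "additive"),            # P1 high, F1 in between
        (("+", "-", "-"), "additive"),            # P2 high, F1 in between
        (("0", "+", "+"), "hp_eld"),              # F1 = P1 = high parent
        (("+", "0", "-"), "hp_eld"),
        (("0", "-", "-"), "lp_eld"),
        (("-", "0", "+"), "lp_eld"),
        (("0", "0", "0"), "unclassified"),
        (("0", "0", "+"), "unclassified"),        # parents differ, F1 like both
        (("-", "+", "-"), "unclassified"),        # cyclic contradiction
    ])
    def test_decision_table(self, calls, group):
        assert classify_gene(*calls)[1] == group

    def test_invalid_call_rejected(self):
        with pytest.raises(ValueError):
            classify_gene("x", "+", "0")

    def test_twelve_patterns_exclusive_and_exhaustive(self):
        """Across all 27 call combinations: exactly 12 map to a pattern,
        each pattern appears once, and the five groups have 2+2+2+3+3
        members."""
        seen_patterns = []
        group_sizes: dict[str, int] = {}
        for calls in product("+-0", repeat=3):
            pattern, group = classify_gene(*calls)
            if group != "unclassified":
                seen_patterns.append(pattern)
                group_sizes[group] = group_sizes.get(group, 0) + 1
        assert len(seen_patterns) == 12
        assert len(set(seen_patterns)) == 12
        assert group_sizes == {"additive": 2, "hp_eld": 2, "lp_eld": 2,
                               "transgressive_up": 3, "transgressive_down": 3}

    def test_parent_label_swap_leaves_group_invariant(self):
        """Relabelling the parents (swap the two F1 calls, negate the
        parent call) cannot change the biological group."""
        flip = {"+": "-", "-": "+", "0": "0"}
        for c1, c2, c3 in product("+-0", repeat=3):
            _, g = classify_gene(c1, c2, c3)
            _, g_swapped = classify_gene(c2, c1, flip[c3])
            assert g == g_swapped, (c1, c2, c3)


class TestClassifyAll:
    def test_only_requested_genes_classified(self):
        res = pd.DataFrame({
            "mean_a": [10.0, 10.0], "mean_b": [10.0, 10.0],
            "log2fc": [2.0, 0.0], "p_raw": [0.001, 0.9],
            "q_fdr": [0.01, 0.95], "tested": True,
        }, index=pd.Index(["g1", "g2"], name="gene_id"))
        out = dominance.classify_all(["g1"], res, res, res)
        assert list(out["gene_id"]) == ["g1"]

    def test_missing_contrast_gene_errors(self):
        res = pd.DataFrame({"mean_a": [1.0], "mean_b": [1.0],
                            "log2fc": [0.0], "p_raw": [1.0],
                            "q_fdr": [1.0], "tested": True},
                           index=pd.Index(["g1"], name="gene_id"))
        with pytest.raises(ValueError, match="lacks results"):
            dominance.classify_all(["g1", "g9"], res, res, res)

    def test_recovery_on_strong_simulation(self):
        """With 4-fold planted effects at dispersion 0.05 and n=3, at least
        90% of classified genes carry their planted group."""
        cfg = simulate.SimConfig(n_genes=2000, seed=7, dispersion=0.05,
                                 ploidies=("4x",), stages=("meiosis",))
        exp = simulate.generate_experiment(cfg)
        c_f1m = de.test_contrast(exp.counts, exp.design,
                                 {"role": "hybrid"}, {"role": "maternal"})
        c_f1f = de.test_contrast(exp.counts, exp.design,
                                 {"role": "hybrid"}, {"role": "paternal"})
        c_mf = de.test_contrast(exp.counts, exp.design,
                                {"role": "maternal"}, {"role": "paternal"})
        th = de.DegThresholds()
        fam = sets.build_family(de.call_degs(c_mf, th),
                                de.call_degs(c_f1m, th),
                                de.call_degs(c_f1f, th),
                                ploidy="4x", stage="meiosis")
        dom = dominance.classify_all(fam.degs_hp, c_f1m, c_f1f, c_mf, th)
        merged = dom.merge(exp.truth.rename("truth").reset_index(),
                           on="gene_id")
        classified = merged[merged["group"] != "unclassified"]
        assert len(classified) > 300
        accuracy = (classified["group"] == classified["truth"]).mean()
        assert accuracy >= 0.90
        # confusion off-diagonal mass below 10% group-wise for the big groups
        for group in ("transgressive_down", "hp_eld", "lp_eld"):
            sub = classified[classified["truth"] == group]
            assert (sub["group"] == group).mean() > 0.90

    def test_null_simulation_yields_near_empty_classification(self):
        cfg = simulate.SimConfig(n_genes=2000, seed=31, pattern_fractions={},
                                 ploidies=("4x",), stages=("meiosis",))
        exp = simulate.generate_experiment(cfg)
        c_f1m = de.test_contrast(exp.counts, exp.design,
                                 {"role": "hybrid"}, {"role": "maternal"})
        c_f1f = de.test_contrast(exp.counts, exp.design,
                                 {"role": "hybrid"}, {"role": "paternal"})
        c_mf = de.test_contrast(exp.counts, exp.design,
                                {"role": "maternal"}, {"role": "paternal"})
        th = de.DegThresholds()
        hp = set(de.call_degs(c_f1m, th)["gene_id"]) | set(
            de.call_degs(c_f1f, th)["gene_id"])
        dom = dominance.classify_all(hp, c_f1m, c_f1f, c_mf, th)
        # under the null almost nothing passes the dual gate in a contrast
        assert len(dom) < 0.01 * cfg.n_genes


class TestSummaryAndCandidates:
    MEIOSIS = {"additive": 24, "hp_eld": 107, "lp_eld": 198,
               "transgressive_down": 549, "transgressive_up": 26}
    MICROSPORE = {"additive": 21, "hp_eld": 37, "lp_eld": 4,
                  "transgressive_down": 2, "transgressive_up": 4}

    @staticmethod
    def _calls(counts: dict) -> pd.DataFrame:
        rows = []
        for group, n in counts.items():
            for i in range(n):
                rows.append({"gene_id": f"{group}_{i}", "pattern": "?",
                             "group": group})
        return pd.DataFrame(rows)

    def test_meiosis_group_percentages(self):
        summary = dominance.summarize(self._calls(self.MEIOSIS))
        got = dict(zip(summary["group"], summary["percent"]))
        assert got == {"additive": 2.65, "hp_eld": 11.84, "lp_eld": 21.90,
                       "transgressive_down": 60.73, "transgressive_up": 2.88}

    def test_microspore_additive_percentage(self):
        summary = dominance.summarize(self._calls(self.MICROSPORE))
        got = dict(zip(summary["group"], summary["percent"]))
        assert got["additive"] == 30.88

    def test_single_group_is_100_percent(self):
        summary = dominance.summarize(self._calls({"hp_eld": 7}))
        got = dict(zip(summary["group"], summary["percent"]))
        assert got["hp_eld"] == 100.00

    @pytest.mark.parametrize("counts", [MEIOSIS, MICROSPORE])
    def test_percents_sum_to_100(self, counts):
        summary = dominance.summarize(self._calls(counts))
        assert abs(summary["percent"].sum() - 100.0) <= 0.05
        assert summary["count"].sum() == sum(counts.values())

    @pytest.mark.parametrize("counts,expected", [(MEIOSIS, 133),
                                                 (MICROSPORE, 41)])
    def test_candidate_counts(self, counts, expected):
        cand = dominance.heterosis_candidates(self._calls(counts))
        assert len(cand) == expected

    def test_no_candidate_groups_empty_set(self):
        cand = dominance.heterosis_candidates(
            self._calls({"lp_eld": 5, "transgressive_down": 3}))
        assert cand == frozenset()

    @pytest.mark.parametrize("s1,s2,expected", [
        ({"a", "b"}, {"b", "c"}, {"b"}),
        ({"a"}, {"b"}, set()),
        ({"a", "b"}, {"a", "b"}, {"a", "b"}),
    ])
    def test_cross_stage_common(self, s1, s2, expected):
        assert dominance.cross_stage_common(s1, s2) == expected
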