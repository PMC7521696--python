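"""Normalization, replicate QC, the NB Wald contrast and DEG calling."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polyhet import de, simulate
from polyhet.de import DegThresholds


def _brute_force_size_factors(counts: pd.DataFrame) -> np.ndarray:
    """Direct median-of-ratios re-computation, gene by gene."""
    vals = counts.to_numpy(dtype=float)
    keep = [i for i in range(vals.shape[0]) if (vals[i] > 0).all()]
    ref = [np.prod(vals[i]) ** (1.0 / vals.shape[1]) for i in keep]
    raw = []
    for j in range(vals.shape[1]):
        ratios = [vals[i, j] / ref[q] for q, i in enumerate(keep)]
        raw.append(np.median(ratios))
    raw = np.asarray(raw)
    return raw / np.prod(raw) ** (1.0 / len(raw))


class TestSizeFactors:
    def test_identical_samples_give_unit_factors(self):
        counts = pd.DataFrame({"a": [5, 10, 3], "b": [5, 10, 3],
                               "c": [5, 10, 3]})
        assert np.allclose(de.size_factors(counts), 1.0)

    def test_doubled_sample_ratio_preserved(self):
        counts = pd.DataFrame({"a": [5, 10, 30], "b": [10, 20, 60]})
        f = de.size_factors(counts)
        assert np.isclose(f["b"] / f["a"], 2.0)
        assert np.isclose(np.exp(np.mean(np.log(f))), 1.0)

    def test_matches_brute_force_on_random_matrix(self, rng):
        counts = pd.DataFrame(rng.poisson(50, size=(200, 6)) + 1,
                              columns=list("abcdef"))
        assert np.allclose(de.size_factors(counts),
                           _brute_force_size_factors(counts))

    def test_all_zero_reference_errors(self):
        counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
        with pytest.raises(ValueError, match="fallback"):
            de.size_factors(counts)


class TestQcReplicates:
    @staticmethod
    def _design(samples):
        return pd.DataFrame(
            {"ploidy": "2x", "role": "hybrid", "stage": "meiosis",
             "replicate": range(1, len(samples) + 1)},
            index=pd.Index(samples, name="sample_id"))

    def test_identical_replicates_all_retained(self):
        counts = pd.DataFrame({"r1": [5, 9, 2], "r2": [5, 9, 2],
                               "r3": [5, 9, 2]})
        retained = de.qc_replicates(counts, self._design(counts.columns))
        assert retained == ["r1", "r2", "r3"]

    def test_noise_replicate_dropped(self, rng):
        base = rng.poisson(np.exp(rng.normal(4, 1.5, size=3000)))
        good = np.array([rng.poisson(np.maximum(base, 1)) for _ in range(2)]).T
        noise = rng.poisson(np.exp(rng.normal(4, 1.5, size=3000)))
        counts = pd.DataFrame(np.column_stack([good, noise]),
                              columns=["r1", "r2", "r3"])
        retained = de.qc_replicates(counts, self._design(counts.columns))
        assert retained == ["r1", "r2"]

    def test_min_corr_zero_retains_all(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(100, 3)) + 1,
                              columns=["r1", "r2", "r3"])
        assert de.qc_replicates(counts, self._design(counts.columns),
                                min_corr=0.0) == ["r1", "r2", "r3"]

    def test_never_below_two_replicates(self, rng):
        counts = pd.DataFrame(rng.poisson(20, size=(50, 3)) + 1,
                              columns=["r1", "r2", "r3"])
        with pytest.warns(UserWarning, match="below 2 replicates"):
            retained = de.qc_replicates(counts, self._design(counts.columns),
                                        min_corr=1.1)
        assert len(retained) == 2


class TestContrast:
    def test_identical_groups_null_gene(self, rng):
        # group B duplicates group A column-for-column, so size factors
        # match pairwise and every gene is exactly null
        block = rng.poisson(40, size=(60, 3)) + 1
        counts = pd.DataFrame(
            np.hstack([block, block]),
            index=pd.Index([f"g{i}" for i in range(60)], name="gene_id"),
            columns=["a1", "a2", "a3", "b1", "b2", "b3"])
        design = pd.DataFrame(
            {"ploidy": "2x", "role": ["hybrid"] * 3 + ["maternal"] * 3,
             "stage": "meiosis", "replicate": [1, 2, 3, 1, 2, 3]},
            index=counts.columns.rename("sample_id"))
        res = de.test_contrast(counts, design, ["a1", "a2", "a3"],
                               ["b1", "b2", "b3"])
        assert np.allclose(res["log2fc"], 0.0)
        assert (res["p_raw"] > 0.9).all()

    def test_overlapping_groups_rejected(self, small_experiment):
        exp = small_experiment
        a = [c for c in exp.counts if c.startswith("4x_meiosis_hybrid")]
        with pytest.raises(ValueError, match="overlap"):
            de.test_contrast(exp.counts, exp.design, a, a)

    def test_unknown_group_rejected(self, small_experiment):
        exp = small_experiment
        with pytest.raises(ValueError):
            de.test_contrast(exp.counts, exp.design,
                             ["nonexistent_sample", "x"],
                             [exp.counts.columns[0], exp.counts.columns[1]])

    def test_all_zero_genes_reported_untested(self, small_experiment):
        exp = small_experiment
        counts = exp.counts.copy()
        counts.iloc[5, :] = 0
        a = {"role": "hybrid", "ploidy": "4x", "stage": "meiosis"}
        b = {"role": "maternal", "ploidy": "4x", "stage": "meiosis"}
        res = de.test_contrast(counts, exp.design, a, b)
        gene = counts.index[5]
        assert not res.loc[gene, "tested"]
        assert np.isnan(res.loc[gene, "q_fdr"])

    def test_scale_invariance_of_log2fc(self, small_experiment):
        """Multiplying one sample by a constant is absorbed by its size
        factor and leaves fold changes essentially unchanged."""
        exp = small_experiment
        cols = [c for c in exp.counts if c.startswith("4x_meiosis")]
        counts = exp.counts[cols]
        a = {"role": "hybrid", "ploidy": "4x", "stage": "meiosis"}
        b = {"role": "maternal", "ploidy": "4x", "stage": "meiosis"}
        res1 = de.test_contrast(counts, exp.design, a, b)
        scaled = counts.copy()
        scaled[cols[0]] = scaled[cols[0]] * 4
        f = de.size_factors(scaled)
        assert f[cols[0]] / de.size_factors(counts)[cols[0]] == pytest.approx(
            4.0 ** (1 - 1 / len(cols)), rel=0.05)  # after geometric rescale
        res2 = de.test_contrast(scaled, exp.design, a, b)
        keep = res1["tested"] & (counts.min(axis=1) > 0)
        assert np.allclose(res1.loc[keep, "log2fc"],
                           res2.loc[keep, "log2fc"], atol=0.2)

    def test_power_on_planted_fourfold_change(self):
        """A 4-fold change at dispersion 0.05 with n=3 is recovered at
        FDR <= 0.05 in at least 95% of 200 simulated data sets."""
        recovered = 0
        for rep in range(200):
            cfg = simulate.SimConfig(
                n_genes=300, seed=20_000 + rep, dispersion=0.05,
                pattern_fractions={"transgressive_up": 0.034},
                ploidies=("4x",), stages=("meiosis",))
            exp = simulate.generate_experiment(cfg)
            res = de.test_contrast(exp.counts, exp.design,
                                   {"role": "hybrid"}, {"role": "maternal"})
            gene = exp.truth[exp.truth == "transgressive_up"].index[0]
            recovered += res.loc[gene, "q_fdr"] <= 0.05
        assert recovered / 200 >= 0.95


def _brute_force_bh(p: np.ndarray) -> np.ndarray:
    """Textbook step-up: q_(i) = min over j>=i of p_(j) * m / j."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        running = min(running, p[order[rank - 1]] * m / rank)
        q_sorted[rank - 1] = running
    q = np.empty(m)
    q[order] = q_sorted
    return q


class TestBhAdjust:
    def test_worked_example(self):
        assert np.allclose(de.bh_adjust([0.01, 0.02, 0.03]),
                           [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert de.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_stay_one(self):
        assert np.allclose(de.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            de.bh_adjust([0.1, float("nan")])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1,
                    max_size=200))
    def test_matches_brute_force(self, ps):
        p = np.asarray(ps)
        assert np.allclose(de.bh_adjust(p), _brute_force_bh(p))


class TestCallDegs:
    @staticmethod
    def _result(log2fc, q):
        return pd.DataFrame({
            "mean_a": 10.0, "mean_b": 10.0, "log2fc": log2fc,
            "p_raw": q, "q_fdr": q, "tested": True,
        }, index=pd.Index([f"g{i}" for i in range(len(log2fc))],
                          name="gene_id"))

    def test_inclusive_boundaries_called(self):
        res = self._result([1.0, -1.0], [0.05, 0.05])
        calls = de.call_degs(res)
        assert set(calls["gene_id"]) == {"g0", "g1"}
        assert list(calls["direction"]) == ["up", "down"]

    def test_fc_gate_blocks_small_changes(self):
        res = self._result([0.9], [0.001])
        assert de.call_degs(res).empty

    def test_fdr_gate_blocks_insignificant(self):
        res = self._result([3.0], [0.051])
        assert de.call_degs(res).empty

    def test_monotone_in_both_thresholds(self, rng):
        res = self._result(rng.normal(0, 2, 300), rng.uniform(0, 1, 300))
        strict = set(de.call_degs(res, DegThresholds(2.0, 0.05))["gene_id"])
        relax_fc = set(de.call_degs(res, DegThresholds(1.5, 0.05))["gene_id"])
        relax_q = set(de.call_degs(res, DegThresholds(2.0, 0.2))["gene_id"])
        assert strict <= relax_fc and strict <= relax_q


class TestDdct:
    @pytest.mark.parametrize("cts,expected", [
        ((20.0, 20.0, 20.0, 20.0), 1.0),
        ((19.0, 20.0, 20.0, 20.0), 2.0),   # ddCt = -1
        ((20.0, 18.0, 24.0, 18.0), 16.0),  # ddCt = 2 - 6 = -4
    ])
    def test_closed_form(self, cts, expected):
        assert de.relative_expression_ddct(*cts) == pytest.approx(expected)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            de.relative_expression_ddct(np.inf, 20, 20, 20)
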