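"""Spike-in size factors, signature scores, signal2noise and enrichment."""

import numpy as np
import pytest

from mycnload.errors import ConfigError, DataError
from mycnload.normalize import (
    apply_size_factors,
    enrichment_score,
    gsea_lite,
    signal2noise,
    signature_score,
    spike_size_factors,
    total_size_factors,
)

from conftest import make_expression
from helpers import running_sum_es


def two_sample_expr(scale_b=2.0):
    """Sample b's spikes are exactly scale_b x sample a's."""
    return make_expression(
        {
            "g1": [10.0, 10.0],
            "ERCC-1": [100.0, 100.0 * scale_b],
            "ERCC-2": [50.0, 50.0 * scale_b],
            "ERCC-3": [20.0, 20.0 * scale_b],
        },
        {"a": "control", "b": "treated"},
        spikes={"ERCC-1", "ERCC-2", "ERCC-3"},
    )


class TestSpikeSizeFactors:
    def test_doubled_spikes_closed_form(self):
        expr = two_sample_expr(2.0)
        sf = spike_size_factors(expr)
        assert sf.factors["a"] == pytest.approx(1 / np.sqrt(2))
        assert sf.factors["b"] == pytest.approx(np.sqrt(2))
        norm = apply_size_factors(expr, sf)
        fc = np.log2(norm.values.at["g1", "b"] / norm.values.at["g1", "a"])
        assert fc == pytest.approx(-1.0)

    def test_identical_spikes_identity(self):
        expr = two_sample_expr(1.0)
        sf = spike_size_factors(expr)
        assert sf.factors.to_numpy() == pytest.approx([1.0, 1.0])

    def test_geometric_mean_is_one(self, rng):
        values = {f"ERCC-{i}": list(rng.lognormal(3, 1, 4)) for i in range(10)}
        values["g1"] = list(rng.lognormal(2, 1, 4))
        expr = make_expression(
            values,
            {f"s{i}": ("control" if i < 2 else "treated") for i in range(4)},
            spikes={k for k in values if k.startswith("ERCC-")},
        )
        sf = spike_size_factors(expr)
        assert np.log(sf.factors.to_numpy()).mean() == pytest.approx(0.0, abs=1e-9)

    def test_global_rescale_of_one_sample_cancels_up_to_common_constant(self):
        # scaling one of S samples by c moves every normalized value by the
        # same c**(1/S) (a consequence of the unit-geometric-mean constraint);
        # all between-sample ratios are exactly invariant
        expr = two_sample_expr(2.0)
        scaled = expr.with_values(expr.values.assign(b=expr.values["b"] * 7.0))
        norm1 = apply_size_factors(expr, spike_size_factors(expr))
        norm2 = apply_size_factors(scaled, spike_size_factors(scaled))
        ratio = norm2.values.to_numpy() / norm1.values.to_numpy()
        assert ratio == pytest.approx(np.full_like(ratio, 7.0**0.5))
        fc1 = norm1.values["b"] / norm1.values["a"]
        fc2 = norm2.values["b"] / norm2.values["a"]
        assert fc2.to_numpy() == pytest.approx(fc1.to_numpy())

    def test_zero_spike_dropped_and_too_few_errors(self):
        expr = make_expression(
            {"ERCC-1": [0.0, 5.0], "ERCC-2": [10.0, 10.0], "g1": [1.0, 1.0]},
            {"a": "control", "b": "treated"},
            spikes={"ERCC-1", "ERCC-2"},
        )
        with pytest.raises(ConfigError):
            spike_size_factors(expr)

    def test_total_factors_absorb_amplitude(self):
        # all genes halve; total-signal factors normalize that away
        expr = make_expression(
            {"g1": [10.0, 5.0], "g2": [30.0, 15.0], "ERCC-1": [5.0, 5.0], "ERCC-2": [7.0, 7.0]},
            {"a": "control", "b": "treated"},
            spikes={"ERCC-1", "ERCC-2"},
        )
        norm = apply_size_factors(expr, total_size_factors(expr))
        assert norm.values.at["g1", "b"] == pytest.approx(norm.values.at["g1", "a"])


class TestSignatureScore:
    def _expr(self):
        return make_expression(
            {
                "a": [10.0, 10.0, 5.0, 5.0],
                "b": [10.0, 10.0, 5.0, 5.0],
                "c": [10.0, 10.0, 5.0, 5.0],
                "other": [1.0, 1.0, 1.0, 1.0],
            },
            {"c1": "control", "c2": "control", "t1": "treated", "t2": "treated"},
        )

    def test_median_ratio_arithmetic(self):
        s = signature_score(self._expr(), {"a", "b", "c"}, "treated", "control", eps=1.0)
        assert s.score == pytest.approx(np.log2(6 / 11))

    def test_identical_conditions_score_zero(self):
        expr = make_expression(
            {"a": [4.0, 4.0], "b": [9.0, 9.0]}, {"c1": "control", "t1": "treated"}
        )
        assert signature_score(expr, {"a", "b"}, "treated", "control").score == 0.0

    def test_missing_members_skipped_and_counted(self):
        s = signature_score(self._expr(), {"a", "b", "zzz"}, "treated", "control")
        assert s.n_members_used == 2 and s.n_members_missing == 1

    def test_empty_intersection_is_data_error(self):
        with pytest.raises(DataError):
            signature_score(self._expr(), {"nope"}, "treated", "control")

    def test_order_invariance(self, rng):
        expr = self._expr()
        s1 = signature_score(expr, {"a", "b", "c"}, "treated", "control")
        shuffled = expr.with_values(expr.values[["t2", "c1", "t1", "c2"]])
        s2 = signature_score(shuffled, {"c", "a", "b"}, "treated", "control")
        assert s1.score == pytest.approx(s2.score)


class TestSignal2Noise:
    def test_floored_denominator_example(self):
        # sigma_b = 1 floored to 0.2*6 = 1.2 -> (2-6)/(1+1.2)
        assert signal2noise([1, 2, 3], [5, 6, 7]) == pytest.approx(-4 / 2.2)

    def test_identical_groups_zero(self):
        assert signal2noise([2, 3, 4], [2, 3, 4]) == 0.0

    def test_zero_variance_floor(self):
        assert signal2noise([5, 5, 5], [1, 2, 3]) == pytest.approx(1.5)

    def test_zero_mean_floor(self):
        # mu_a = 0 with sigma 0 -> floor 0.2
        assert signal2noise([0, 0], [1, 1]) == pytest.approx(-1 / (0.2 + 0.2))

    def test_requires_two_replicates(self):
        with pytest.raises(ConfigError):
            signal2noise([1], [2, 3])


class TestEnrichment:
    def test_degenerate_sets(self):
        metric = np.array([3.0, 2.0, 1.0, 0.5])
        assert enrichment_score(metric, [True, False, False, False]) == pytest.approx(1.0)
        assert enrichment_score(metric, [False, False, False, True]) == pytest.approx(-1.0)
        assert enrichment_score(metric, [True, True, True, True]) == pytest.approx(1.0)

    def test_matches_running_sum_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 31))
            metric = np.sort(rng.normal(size=n))[::-1]
            k = int(rng.integers(1, n))
            mask = np.zeros(n, dtype=bool)
            mask[rng.choice(n, size=k, replace=False)] = True
            got = enrichment_score(metric, mask)
            assert got == pytest.approx(running_sum_es(metric, mask), abs=1e-12)
            assert -1.0 <= got <= 1.0

    def test_antisymmetric_under_rank_reversal(self, rng):
        n = 20
        metric = np.sort(rng.normal(size=n))[::-1]
        mask = np.zeros(n, dtype=bool)
        mask[[0, 3, 7]] = True
        fwd = enrichment_score(np.abs(metric), mask)  # same |r| pattern reversed
        rev = enrichment_score(np.abs(metric)[::-1], mask[::-1])
        assert fwd == pytest.approx(-rev)


class TestGseaLite:
    def _expr(self, rng, n_genes=60, n_reps=3, shift_genes=()):
        values = {}
        for i in range(n_genes):
            base = rng.lognormal(2, 0.3, 2 * n_reps)
            if f"g{i}" in shift_genes:
                base[n_reps:] *= 3.0
            values[f"g{i}"] = list(base)
        conds = {f"c{r}": "control" for r in range(n_reps)}
        conds.update({f"t{r}": "treated" for r in range(n_reps)})
        return make_expression(values, conds)

    def test_planted_set_enriched_and_reproducible(self, rng):
        planted = {f"g{i}" for i in range(8)}
        expr = self._expr(rng, shift_genes=planted)
        r1 = gsea_lite(expr, "treated", "control", planted, n_perm=200, seed=4)
        r2 = gsea_lite(expr, "treated", "control", planted, n_perm=200, seed=4)
        assert r1.es == r2.es and r1.nominal_p == r2.nominal_p
        assert r1.es > 0.5
        assert r1.nominal_p <= 0.05
        assert r1.perm_mode == "gene_set"  # 3 replicates < 4 per condition
        assert r1.nominal_p >= 1 / (r1.n_perm + 1)

    def test_phenotype_mode_with_four_replicates(self, rng):
        expr = self._expr(rng, n_genes=30, n_reps=4)
        res = gsea_lite(expr, "treated", "control", {"g0", "g1", "g2"}, n_perm=50, seed=2)
        assert res.perm_mode == "phenotype"

    def test_small_set_is_data_error(self, rng):
        expr = self._expr(rng, n_genes=10)
        with pytest.raises(DataError):
            gsea_lite(expr, "treated", "control", {"g0"}, n_perm=10, seed=0)
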