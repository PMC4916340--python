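"""Audic-Claverie exact test, TPM normalisation and DEG calling."""

import mpmath
import numpy as np
import pandas as pd
import pytest

from tagdge import (
    SimConfig,
    audic_claverie_point,
    audic_claverie_pvalue,
    bh_adjust,
    bonferroni_adjust,
    call_degs,
    categorize_degs,
    tpm_normalize,
)

mpmath.mp.dps = 60


def ac_point_oracle(x, y, n1, n2):
    """Arbitrary-precision direct evaluation of the equal-expression
    probability (N2/N1)^y (x+y)!/(x!y!) (1+N2/N1)^-(x+y+1)."""
    r = mpmath.mpf(n2) / mpmath.mpf(n1)
    return (
        r**y
        * mpmath.factorial(x + y)
        / (mpmath.factorial(x) * mpmath.factorial(y))
        * (1 + r) ** (-(x + y + 1))
    )


class TestTpm:
    def test_scaling(self):
        assert tpm_normalize(10, 1_000_000) == 10.0
        assert tpm_normalize(0, 1_000_000) == 0.0

    def test_count_near_floor_on_large_library(self):
        # 59 tags in a 5.9-million-tag library sit just under 10 TPM
        tpm = tpm_normalize(59, 5_902_114)
        assert 9.99 < tpm < 10.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            tpm_normalize(5, 0)


class TestPointProbability:
    def test_symmetric_zero_counts(self):
        assert audic_claverie_point(0, 0, 100, 100) == pytest.approx(0.5)

    def test_symmetric_one_one(self):
        assert audic_claverie_point(1, 1, 100, 100) == pytest.approx(0.25)

    @pytest.mark.parametrize(
        "x,y,n1,n2",
        [
            (50, 100, 1_000_000, 1_200_000),
            (0, 0, 10, 20),
            (7, 3, 500, 900),
            (200, 180, 5_902_114, 5_709_974),
            (1000, 900, 5_902_114, 5_709_974),
        ],
    )
    def test_twelve_digit_agreement_with_high_precision_oracle(self, x, y, n1, n2):
        got = audic_claverie_point(x, y, n1, n2)
        want = float(ac_point_oracle(x, y, n1, n2))
        assert got == pytest.approx(want, rel=1e-12)

    @pytest.mark.parametrize("ratio", [0.5, 1.0, 2.0])
    @pytest.mark.parametrize("x", [0, 1, 10, 200])
    def test_normalization_sums_to_one(self, x, ratio):
        n1 = 1_000_000
        n2 = int(ratio * n1)
        k = np.arange(0, 20_000)
        total = audic_claverie_point(x, k, n1, n2).sum()
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            audic_claverie_point(-1, 0, 10, 10)


class TestPValue:
    def test_center_capped_at_one(self):
        assert audic_claverie_pvalue(100, 100, 1000, 1000) == 1.0

    def test_geometric_tail_closed_form(self):
        # for x=0 and N1=N2 the distribution of y is geometric(1/2), so
        # the upper tail from y=10 is 2^-10 and the two-sided p doubles it
        assert audic_claverie_pvalue(0, 10, 500, 500) == pytest.approx(
            2 * 2.0**-10, rel=1e-12
        )

    def test_library_swap_symmetry(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            x = int(rng.integers(0, 300))
            y = int(rng.integers(0, 300))
            n1 = int(rng.integers(10_000, 1_000_000))
            n2 = int(rng.integers(10_000, 1_000_000))
            p_ab = audic_claverie_pvalue(x, y, n1, n2)
            p_ba = audic_claverie_pvalue(y, x, n2, n1)
            assert abs(p_ab - p_ba) < 1e-9

    def test_upper_tail_monotone_beyond_mode(self):
        x, n1, n2 = 40, 100_000, 120_000
        ys = np.arange(60, 400)
        p = audic_claverie_pvalue(x, ys, n1, n2, alternative="greater")
        assert (np.diff(p) <= 1e-15).all()

    def test_one_sided_tails_sum_above_one(self):
        # lower and upper tails overlap at y itself
        lo = audic_claverie_pvalue(5, 9, 1000, 1000, alternative="less")
        hi = audic_claverie_pvalue(5, 9, 1000, 1000, alternative="greater")
        assert lo + hi > 1.0


class TestAdjustment:
    def test_bonferroni_scales_and_caps(self):
        out = bonferroni_adjust([0.001, 0.5], m=100)
        assert out[0] == pytest.approx(0.1)
        assert out[1] == 1.0

    def test_order_preserved(self):
        p = [0.03, 0.001, 0.2]
        out = bonferroni_adjust(p, m=10)
        assert list(out) == [pytest.approx(v * 10 if v * 10 < 1 else 1.0) for v in p]

    def test_bh_matches_reference_example(self):
        p = np.array([0.01, 0.04, 0.03, 0.005])
        # hand-computed step-up values
        assert bh_adjust(p) == pytest.approx([0.02, 0.04, 0.04, 0.02])


class TestCallDegs:
    def test_low_tpm_in_both_libraries_excluded(self):
        table = call_degs({"g": 5}, {"g": 8}, 1_000_000, 1_000_000)
        assert table.loc[0, "call"] == "excluded"
        assert np.isnan(table.loc[0, "p_raw"])

    def test_equal_counts_not_significant(self):
        table = call_degs({"g": 100}, {"g": 100}, 1_000_000, 1_000_000)
        assert table.loc[0, "call"] == "not_significant"
        assert table.loc[0, "p_adj"] == 1.0

    def test_zero_count_defaults_to_one(self):
        table = call_degs({"g": 500}, {}, 1_000_000, 1_000_000)
        assert np.isfinite(table.loc[0, "log2_ratio"])
        assert table.loc[0, "log2_ratio"] == pytest.approx(np.log2(1 / 500))
        assert table.loc[0, "call"] == "down"

    def test_empty_input(self):
        assert call_degs({}, {}, 10, 10).empty

    def test_family_size_is_tested_genes_only(self):
        counts1 = {"hi": 1000, "lo": 1}
        counts2 = {"hi": 1000, "lo": 2}
        table = call_degs(counts1, counts2, 1_000_000, 1_000_000).set_index("gene_id")
        # 'lo' is excluded, so m=1 and p_adj of 'hi' equals its p_raw
        assert table.loc["lo", "call"] == "excluded"
        assert table.loc["hi", "p_adj"] == pytest.approx(table.loc["hi", "p_raw"])

    def test_type_i_error_controlled_on_null_genes(self):
        # 10,000 genes with equal true abundance, depth 1e5 per library:
        # under Bonferroni at 0.001 the expected family-wise false-call
        # count is < 0.001, so observing more than 1 would be alarming
        rng = np.random.default_rng(123)
        n_genes, depth = 10_000, 100_000
        abund = rng.lognormal(0, 1.0, n_genes)
        abund /= abund.sum()
        x = rng.multinomial(depth, abund)
        y = rng.multinomial(depth, abund)
        genes = [f"g{i}" for i in range(n_genes)]
        table = call_degs(
            dict(zip(genes, x)), dict(zip(genes, y)), depth, depth
        )
        false_calls = int(table["call"].isin(["up", "down"]).sum())
        assert false_calls <= 1

    def test_recovery_of_strong_true_effects(self):
        # 1,000 genes, 50 perturbed at |log2fc| = 2, depth 1e6: every
        # perturbed gene with decent coverage must be called, no nulls
        cfg = SimConfig(
            seed=42,
            n_genes=1000,
            depth_per_library=1_000_000,
            deg_fraction=0.05,
            log2_effect=2.0,
            error_rate=0.0,
            antisense_fraction=0.0,
            abundance_dispersion=1.0,
        )
        rng = np.random.default_rng(cfg.seed)
        raw = rng.lognormal(0, cfg.abundance_dispersion, cfg.n_genes)
        a1 = raw / raw.sum()
        deg_idx = rng.choice(cfg.n_genes, size=50, replace=False)
        log2fc = np.zeros(cfg.n_genes)
        log2fc[deg_idx[:25]] = 2.0
        log2fc[deg_idx[25:]] = -2.0
        a2 = a1 * np.exp2(log2fc)
        a2 /= a2.sum()
        x = rng.multinomial(cfg.depth_per_library, a1)
        y = rng.multinomial(cfg.depth_per_library, a2)
        genes = np.array([f"g{i}" for i in range(cfg.n_genes)])
        table = call_degs(
            dict(zip(genes, x)),
            dict(zip(genes, y)),
            cfg.depth_per_library,
            cfg.depth_per_library,
        ).set_index("gene_id")
        calls = table["call"]
        true_deg = set(genes[log2fc != 0])
        called = set(calls[calls.isin(["up", "down"])].index)
        # no false positives among null genes
        assert not (called - true_deg)
        # every well-powered true effect is recovered
        min_count = np.minimum(x, y)
        well_powered = set(genes[(log2fc != 0) & (min_count >= 50)])
        assert well_powered <= called
        # direction is correct
        for g in called:
            assert calls[g] == ("up" if log2fc[list(genes).index(g)] > 0 else "down")

    def test_log2_ratio_recovers_true_effect(self):
        # a gene with true log2fc=2 and expected counts >= 500 estimates
        # its ratio within +-0.2 (well beyond 5 binomial sigma)
        rng = np.random.default_rng(9)
        depth = 1_000_000
        a1 = np.array([0.001] + [0.999 / 99] * 99)
        a2 = a1.copy()
        a2[0] *= 4.0
        a2 /= a2.sum()
        x = rng.multinomial(depth, a1)
        y = rng.multinomial(depth, a2)
        genes = [f"g{i}" for i in range(100)]
        table = call_degs(
            dict(zip(genes, x)), dict(zip(genes, y)), depth, depth
        ).set_index("gene_id")
        # composition renormalisation shifts all ratios by log2(sum a2*4
        # vs 1) ~= 0.004; negligible at this scale
        assert abs(table.loc["g0", "log2_ratio"] - 2.0) < 0.2


class TestCategorize:
    def make_deg_table(self, calls):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(calls))],
                "call": calls,
            }
        )

    def test_unassigned_tallied_separately(self):
        table = self.make_deg_table(["up"] * 4 + ["down"] * 6)
        mapping = {f"g{i}": "protein" for i in range(4)}
        cats = categorize_degs(table, mapping).set_index("category")
        assert cats.loc["protein", "pct"] == 100.0
        assert cats.loc["unassigned", "n_degs"] == 6

    def test_empty_degs(self):
        table = self.make_deg_table(["not_significant"] * 3)
        assert categorize_degs(table, {"g0": "protein"}).empty

    def test_three_to_one_split(self):
        table = self.make_deg_table(["up"] * 4)
        mapping = {"g0": "RNA", "g1": "RNA", "g2": "RNA", "g3": "transport"}
        cats = categorize_degs(table, mapping).set_index("category")
        assert cats.loc["RNA", "pct"] == 75.0
        assert cats.loc["transport", "pct"] == 25.0
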