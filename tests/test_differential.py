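"""Normality-gated replicate testing and differential tables."""

import numpy as np
import pytest

from ampedit.differential import (
    MANN_WHITNEY,
    T_TEST,
    compare_isoforms,
    compare_sites,
    gated_test,
    multiple_testing,
    normality_gate,
)
from ampedit.profiling import profile_from_counts
from ampedit.simulate import (
    SimulationConfig,
    jitter_probs,
    sample_pattern_counts,
)


def make_cohort(
    rng,
    wt_probs=(0.65, 0.50, 0.10, 0.15, 0.35),
    ko_probs=None,
    n_mice=10,
    n_reads=20_000,
    mouse_sd=0.01,
    region="hypothalamus",
):
    """Two-genotype cohort of profiles drawn from the multinomial model."""
    ko_probs = ko_probs if ko_probs is not None else wt_probs
    profiles = []
    for geno, probs in (("WT", wt_probs), ("KO", ko_probs)):
        for m in range(n_mice):
            p = jitter_probs(probs, mouse_sd, rng)
            cfg = SimulationConfig(per_site_probs=p, n_reads=n_reads)
            counts = sample_pattern_counts(cfg, rng)
            profiles.append(
                profile_from_counts(f"{geno}_m{m}", counts, geno, region)
            )
    return profiles


class TestNormalityGate:
    def test_gaussian_groups_choose_t_test(self, rng):
        g1, g2 = rng.normal(10, 1, 10), rng.normal(10, 1, 10)
        assert normality_gate(g1, g2) == T_TEST

    def test_extreme_outliers_choose_mann_whitney(self, rng):
        g1 = np.concatenate([rng.normal(10, 0.1, 9), [1000.0]])
        g2 = rng.normal(10, 0.1, 10)
        assert normality_gate(g1, g2) == MANN_WHITNEY

    def test_tiny_groups_default_to_mann_whitney(self):
        assert normality_gate([1.0, 2.0], [3.0, 4.0]) == MANN_WHITNEY

    def test_constant_group_uses_mann_whitney(self):
        assert normality_gate([5.0] * 6, [1.0, 2.0, 3.0, 4.0, 5.0, 6.0]) == MANN_WHITNEY

    def test_identical_constant_groups_give_p_one(self):
        test, p = gated_test([3.0] * 5, [3.0] * 5)
        assert test == MANN_WHITNEY and p == 1.0


class TestCompareSites:
    def test_identical_groups_no_signal(self, rng):
        counts = [sample_pattern_counts(SimulationConfig(n_reads=5000), rng)]
        profiles = []
        for geno in ("WT", "KO"):
            for m in range(5):
                profiles.append(
                    profile_from_counts(f"{geno}{m}", counts[0], geno, "r1")
                )
        df = compare_sites(profiles)
        assert np.allclose(df["diff"], 0.0)
        assert (df["p"] == 1.0).all()

    def test_three_point_shift_detected(self, rng):
        wt = (0.65, 0.50, 0.10, 0.15, 0.35)
        ko = (0.65, 0.50, 0.10, 0.18, 0.35)  # +3 pp at site C
        profiles = make_cohort(rng, wt, ko)
        df = compare_sites(profiles).set_index("site")
        assert df.loc["C", "significant"]
        assert df.loc["C", "diff"] == pytest.approx(3.0, abs=1.5)

    def test_label_swap_antisymmetry(self, rng):
        profiles = make_cohort(rng, n_mice=6, n_reads=5000)
        fwd = compare_sites(profiles, genotypes=("WT", "KO"))
        rev = compare_sites(profiles, genotypes=("KO", "WT"))
        assert np.allclose(fwd["diff"].values, -rev["diff"].values)
        assert np.allclose(fwd["p"].values, rev["p"].values)

    def test_p_invariant_under_within_group_reordering(self, rng):
        profiles = make_cohort(rng, n_mice=6, n_reads=5000)
        shuffled = profiles[::-1]
        assert np.allclose(
            compare_sites(profiles)["p"].values,
            compare_sites(shuffled)["p"].values,
        )


class TestCompareIsoforms:
    def test_identical_groups_all_ratios_one(self, rng):
        counts = sample_pattern_counts(SimulationConfig(n_reads=5000), rng)
        profiles = [
            profile_from_counts(f"{g}{m}", counts, g, "r1")
            for g in ("WT", "KO")
            for m in range(5)
        ]
        df = compare_isoforms(profiles)
        present = df[df["wt_mean_pct"] > 0]
        assert np.allclose(present["ko_wt_ratio"], 1.0)
        assert not df["significant"].any()

    def test_doubled_rare_isoform_flagged_low_abundance(self, rng):
        # WT ~2% for the fully edited class, KO ~4%: configure via explicit
        # haplotype frequencies so only that class moves.
        base = np.full(32, (1 - 0.02) / 31)
        wt_freq = base.copy()
        wt_freq[31] = 0.02
        ko_freq = base * (1 - 0.04) / (1 - 0.02)
        ko_freq[31] = 0.04
        profiles = []
        for geno, freq in (("WT", wt_freq), ("KO", ko_freq)):
            for m in range(12):
                cfg = SimulationConfig(
                    linkage_mode="explicit_haplotypes",
                    haplotype_freqs=tuple(freq),
                    n_reads=50_000,
                )
                counts = sample_pattern_counts(cfg, rng)
                profiles.append(profile_from_counts(f"{geno}{m}", counts, geno, "r"))
        df = compare_isoforms(profiles).set_index("bits")
        row = df.loc["11111"]
        assert row["significant"]
        assert row["ko_wt_ratio"] == pytest.approx(2.0, rel=0.25)
        assert row["low_abundance"]

    def test_permutation_null_significance_rate(self, rng):
        # shuffling genotype labels should leave ~alpha of rows significant
        profiles = make_cohort(rng, n_mice=8, n_reads=10_000)
        n_sig = n_rows = 0
        for rep in range(20):
            labels = ["WT"] * 8 + ["KO"] * 8
            perm = rng.permutation(labels)
            for p, lab in zip(profiles, perm):
                p.genotype = lab
            df = compare_isoforms(profiles)
            n_sig += int(df["significant"].sum())
            n_rows += len(df)
        assert n_sig / n_rows < 0.15


class TestMultipleTesting:
    def test_none_copies_raw_p(self, rng):
        profiles = make_cohort(rng, n_mice=4, n_reads=2000)
        df = multiple_testing(compare_sites(profiles), "none")
        assert np.allclose(df["p_adj"], df["p"])

    def test_bh_hand_example(self):
        import pandas as pd

        rows = pd.DataFrame(
            {"region": ["r"] * 4, "p": [0.01, 0.02, 0.03, 0.04]}
        )
        out = multiple_testing(rows, "bh")
        assert np.allclose(out["p_adj"], [0.04, 0.04, 0.04, 0.04])

    def test_bh_single_row_equals_raw(self):
        import pandas as pd

        rows = pd.DataFrame({"region": ["r"], "p": [0.03]})
        out = multiple_testing(rows, "bh")
        assert out["p_adj"].iloc[0] == pytest.approx(0.03)

    def test_unknown_method_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            multiple_testing(pd.DataFrame({"region": [], "p": []}), "bonferroni")
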