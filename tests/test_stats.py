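import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from leafstress.stats import (
    GroupSummary,
    anova_from_summary,
    anova_oneway,
    compact_letters,
    duncan_mrt,
    letter_matrix,
    pearson_matrix,
    percent_change,
)


class TestAnova:
    def test_textbook_hand_computation(self):
        # groups {1,2,3},{2,3,4},{5,6,7}: SSB = 26, SSW = 6 -> F = 13
        res = anova_oneway({"g1": [1, 2, 3], "g2": [2, 3, 4], "g3": [5, 6, 7]})
        assert res.F == pytest.approx(13.0)
        assert res.p == pytest.approx(0.006591796875)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_equal_means_give_near_zero_f(self):
        res = anova_oneway({"a": [1.0, 2.0, 3.0], "b": [3.0, 2.0, 1.0]})
        assert res.F == pytest.approx(0.0, abs=1e-12)

    def test_label_permutation_symmetry(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [5, 6, 7]}
        renamed = {"c": groups["a"], "a": groups["b"], "b": groups["c"]}
        assert anova_oneway(groups).F == pytest.approx(anova_oneway(renamed).F)

    def test_zero_within_variance_reported_explicitly(self):
        res = anova_oneway({"a": [1.0, 1.0], "b": [2.0, 2.0]})
        assert math.isinf(res.F)
        assert res.p == 0.0

    def test_agreement_with_scipy_f_oneway(self, rng):
        for _ in range(10):
            groups = {f"g{i}": rng.normal(i * 0.3, 1.0, size=5) for i in range(4)}
            ours = anova_oneway(groups)
            ref = sps.f_oneway(*groups.values())
            assert ours.F == pytest.approx(ref.statistic, rel=1e-10)
            assert ours.p == pytest.approx(ref.pvalue, rel=1e-8)


class TestAnovaFromSummary:
    def test_published_epidermis_summaries(self):
        # second-period upper-epidermis means/SEs across the four treatments;
        # oracle: raw ANOVA on constructed triples {m - SE*sqrt(3), m, m + SE*sqrt(3)}
        summaries = [
            GroupSummary("CK", 14.2, 0.1),
            GroupSummary("T1", 13.8, 0.3),
            GroupSummary("T2", 13.1, 0.3),
            GroupSummary("T3", 12.6, 0.3),
        ]
        res = anova_from_summary(summaries)
        assert res.F == pytest.approx(7.273809523809502, rel=1e-9)
        assert res.p == pytest.approx(0.011290799256465804, rel=1e-6)
        assert res.p < 0.05

    def test_identical_summaries_give_zero_f(self):
        res = anova_from_summary([GroupSummary(str(i), 5.0, 0.4) for i in range(3)])
        assert res.F == 0.0

    def test_equivalence_with_raw_anova_on_matched_sufficient_statistics(self, rng):
        for _ in range(50):
            k = rng.integers(3, 6)
            n = rng.integers(3, 8)
            raw = {f"g{i}": rng.normal(rng.normal(0, 2), 1.0, size=n) for i in range(k)}
            summaries = [
                GroupSummary(
                    label,
                    float(np.mean(v)),
                    float(np.std(v, ddof=1) / math.sqrt(len(v))),
                    n=len(v),
                )
                for label, v in raw.items()
            ]
            a, b = anova_oneway(raw), anova_from_summary(summaries)
            assert b.F == pytest.approx(a.F, abs=1e-10)
            assert b.p == pytest.approx(a.p, abs=1e-10)


class TestDuncan:
    MVT_S2 = [
        GroupSummary("CK", 862.5, 0.7),
        GroupSummary("T1", 855.2, 4.5),
        GroupSummary("T2", 836.8, 4.3),
        GroupSummary("T3", 821.4, 4.2),
    ]

    def test_published_main_vein_letters(self):
        # the published lowercase annotation for main-vein thickness in the
        # second period is a, a, b, c
        letters = duncan_mrt(self.MVT_S2).letters()
        assert letters == {"CK": "a", "T1": "a", "T2": "b", "T3": "c"}

    def test_identical_groups_share_one_letter(self):
        groups = {l: [5.0, 5.1, 4.9] for l in "abcd"}
        res = duncan_mrt(groups)
        assert not res.significant
        assert set(res.letters().values()) == {"a"}

    def test_wide_separation_gives_all_distinct_letters(self):
        groups = {"g1": [100.0, 100.1, 99.9], "g2": [50.0, 50.1, 49.9], "g3": [1.0, 1.1, 0.9]}
        letters = duncan_mrt(groups).letters()
        assert sorted(letters.values()) == ["a", "b", "c"]

    def test_unequal_n_warns_and_uses_harmonic_mean(self):
        groups = {"a": [1.0, 2.0, 3.0], "b": [4.0, 5.0, 6.0, 7.0]}
        with pytest.warns(UserWarning, match="harmonic"):
            duncan_mrt(groups)

    def test_sandwich_between_tukey_and_lsd(self, rng):
        """Duncan declares at least as many significant pairs as Tukey HSD
        and at most as many as unadjusted LSD."""
        alpha = 0.05
        for _ in range(20):
            k, n = 4, 5
            means = rng.normal(0, 1.5, size=k)
            groups = {f"g{i}": rng.normal(means[i], 1.0, size=n) for i in range(k)}
            res = duncan_mrt(groups, alpha=alpha)
            msw, dfw = res.ms_within, res.df_within
            se = math.sqrt(msw / n)
            q_tukey = sps.studentized_range.ppf(1 - alpha, k, dfw)
            t_lsd = sps.t.ppf(1 - alpha / 2, dfw)
            tukey = set()
            lsd = set()
            for i, j in itertools.combinations(range(k), 2):
                diff = abs(res.means[i] - res.means[j])
                if diff > q_tukey * se:
                    tukey.add(frozenset({res.labels[i], res.labels[j]}))
                if diff > t_lsd * se * math.sqrt(2):
                    lsd.add(frozenset({res.labels[i], res.labels[j]}))
            assert tukey <= res.significant <= lsd


class TestCompactLetters:
    def test_no_significant_pairs(self):
        assert compact_letters(("x", "y", "z"), frozenset()) == {
            "x": "a", "y": "a", "z": "a",
        }

    def test_fully_separated_chain(self):
        sig = frozenset(
            frozenset(p) for p in itertools.combinations(("x", "y", "z"), 2)
        )
        assert compact_letters(("x", "y", "z"), sig) == {"x": "a", "y": "b", "z": "c"}

    def test_overlap_pattern_brute_force_minimal(self):
        # 1~2, 2~3, 1 != 3 -> a, ab, b (verified by enumerating all letterings
        # of <= 2 letters satisfying the sharing rule)
        sig = frozenset({frozenset({"g1", "g3"})})
        letters = compact_letters(("g1", "g2", "g3"), sig)
        assert letters == {"g1": "a", "g2": "ab", "g3": "b"}
        assert self._minimal_letters(("g1", "g2", "g3"), sig) == 2

    @staticmethod
    def _minimal_letters(labels, sig):
        """Brute-force smallest number of letter classes consistent with the
        sharing rule: shared letter <=> non-significant pair."""
        pairs = set(map(frozenset, itertools.combinations(labels, 2)))
        nonsig = pairs - set(sig)
        for m in range(1, len(labels) + 1):
            for assignment in itertools.product(range(2 ** m), repeat=len(labels)):
                if any(a == 0 for a in assignment):
                    continue
                ok = True
                for pair in pairs:
                    a, b = tuple(pair)
                    shared = assignment[labels.index(a)] & assignment[labels.index(b)]
                    if pair in sig and shared:
                        ok = False
                    if pair in nonsig and not shared:
                        ok = False
                    if not ok:
                        break
                if ok:
                    return m
        return None


class TestLetterMatrix:
    def test_published_pattern_from_summary_reconstruction(self):
        # reconstruct raw triples from the published main-vein summaries and
        # check the second-period lowercase pattern a, a, b, c
        rows = []
        for g in TestDuncan.MVT_S2:
            spread = g.se * math.sqrt(3)
            for rep, v in enumerate([g.mean - spread, g.mean, g.mean + spread], 1):
                rows.append((g.label, "S2", rep, "Mvt", v, "um"))
        # a second period so the uppercase family is well-defined
        for g in TestDuncan.MVT_S2:
            spread = g.se * math.sqrt(3)
            for rep, v in enumerate([g.mean + 59, g.mean + 60, g.mean + 61], 1):
                rows.append((g.label, "S1", rep, "Mvt", v, "um"))
        table = pd.DataFrame(
            rows, columns=["treatment", "period", "replicate", "trait", "value", "units"]
        )
        grid = letter_matrix(table, "Mvt")
        s2 = grid[grid["period"] == "S2"].set_index("treatment")["lower"]
        assert s2.to_dict() == {"CK": "a", "T1": "a", "T2": "b", "T3": "c"}

    def test_label_shuffle_equivariance(self, trait_table):
        grid = letter_matrix(trait_table, "Mvt")
        relabeled = trait_table.copy()
        mapping = {"CK": "T3", "T1": "T2", "T2": "T1", "T3": "CK"}
        relabeled["treatment"] = relabeled["treatment"].map(mapping)
        grid2 = letter_matrix(relabeled, "Mvt")
        for _, rec in grid.iterrows():
            twin = grid2[
                (grid2["treatment"] == mapping[rec["treatment"]])
                & (grid2["period"] == rec["period"])
            ].iloc[0]
            assert twin["lower"] == rec["lower"]

    def test_missing_cells_are_named(self, trait_table):
        broken = trait_table[
            ~(
                (trait_table["treatment"] == "T2")
                & (trait_table["period"] == "S3")
            )
        ]
        with pytest.raises(ValueError, match="T2"):
            letter_matrix(broken, "Mvt")


class TestPearson:
    def test_trivial_correlations(self):
        rows = []
        for rep, (x, y) in enumerate(zip([1.0, 2.0, 3.0], [3.0, 2.0, 1.0]), 1):
            rows.append(("CK", "S1", rep, "x", x, ""))
            rows.append(("CK", "S1", rep, "y", y, ""))
        table = pd.DataFrame(
            rows, columns=["treatment", "period", "replicate", "trait", "value", "units"]
        )
        r, p = pearson_matrix(table)
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "y"] == pytest.approx(-1.0)

    def test_affine_invariance(self, trait_table):
        r1, _ = pearson_matrix(trait_table, ["Chl", "a_star", "Mvt"])
        scaled = trait_table.copy()
        mask = scaled["trait"] == "Chl"
        scaled.loc[mask, "value"] = scaled.loc[mask, "value"] * 7.0 + 3.0
        r2, _ = pearson_matrix(scaled, ["Chl", "a_star", "Mvt"])
        assert np.allclose(r1.to_numpy(), r2.to_numpy())

    def test_constant_trait_marked_undefined(self):
        rows = []
        for rep in (1, 2, 3):
            rows.append(("CK", "S1", rep, "x", float(rep), ""))
            rows.append(("CK", "S1", rep, "y", 4.0, ""))
        table = pd.DataFrame(
            rows, columns=["treatment", "period", "replicate", "trait", "value", "units"]
        )
        r, _ = pearson_matrix(table)
        assert np.isnan(r.loc["x", "y"])


class TestPercentChange:
    def test_conventions(self):
        assert percent_change(20.0, 20.0) == 0.0
        assert percent_change(20.0, 15.0) == pytest.approx(25.0)
        assert percent_change(100.0, 175.7, direction="increase") == pytest.approx(75.7)

    def test_zero_reference_raises(self):
        with pytest.raises(ValueError):
            percent_change(0.0, 1.0)
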