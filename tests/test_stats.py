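"""Group comparison: mean +/- SD, ANOVA, Tukey HSD, compact letter display."""

import itertools

import numpy as np
import pytest
from scipy import stats as sps

from microclot import (
    DegenerateVarianceError,
    InvalidInputError,
    anova_tukey,
    compact_letter_display,
    compare_conditions,
    summarize,
)


def brute_force_letter_check(letters: dict[str, str], significant) -> bool:
    """Oracle: two groups share a letter iff their pair is not significant."""
    for g1, g2 in itertools.combinations(letters, 2):
        shares = bool(set(letters[g1]) & set(letters[g2]))
        if shares == significant(g1, g2):
            return False
    return all(letters[g] for g in letters)


def minimal_letter_count(names, significant) -> int:
    """Smallest clique cover of the non-significance graph (k <= 5 only)."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(names)
    for a, b in itertools.combinations(names, 2):
        if not significant(a, b):
            g.add_edge(a, b)
    cliques = list(nx.find_cliques(g))
    needed = [frozenset(e) for e in g.edges] + [frozenset([n]) for n in names]
    for k in range(1, len(cliques) + 1):
        for combo in itertools.combinations(cliques, k):
            sets = [set(c) for c in combo]
            if all(any(req <= s for s in sets) for req in needed):
                return k
    return len(cliques)


class TestSummarize:
    def test_two_point_group(self):
        out = summarize({"a": [70.0, 74.0], "b": [1.0, 2.0]}).set_index("condition")
        assert out.loc["a", "mean"] == pytest.approx(72.0)
        assert out.loc["a", "sd"] == pytest.approx(np.sqrt(8.0))

    def test_constant_group_has_zero_sd(self):
        out = summarize({"a": [5.0, 5.0, 5.0], "b": [1.0, 2.0]}).set_index("condition")
        assert out.loc["a", "sd"] == 0.0

    def test_seeded_sample_mean_near_population_mean(self):
        rng = np.random.default_rng(11)
        sample = rng.normal(72.0, 4.0, size=8)
        out = summarize({"s": sample, "t": [0.0, 1.0]}).set_index("condition")
        assert abs(out.loc["s", "mean"] - 72.0) <= 3 * 4.0 / np.sqrt(8)

    def test_small_groups_rejected(self):
        with pytest.raises(InvalidInputError):
            summarize({"a": [1.0], "b": [1.0, 2.0]})
        with pytest.raises(InvalidInputError):
            summarize({"a": [1.0, 2.0]})


class TestAnovaTukey:
    def test_two_group_tukey_equals_pooled_t_test(self):
        rng = np.random.default_rng(4)
        g1 = rng.normal(70, 4, size=8)
        g2 = rng.normal(78, 4, size=8)
        result = anova_tukey({"g1": g1, "g2": g2})
        _, p_t = sps.ttest_ind(g1, g2, equal_var=True)
        assert result.pairwise.loc["g1", "g2"] == pytest.approx(p_t, rel=1e-6)
        # with k = 2 the ANOVA F test is the squared t test
        assert result.p_value == pytest.approx(p_t, rel=1e-6)

    def test_distant_group_separates_from_near_pair(self):
        rng = np.random.default_rng(7)
        groups = {
            "near1": rng.normal(0, 1, size=8),
            "near2": rng.normal(0, 1, size=8),
            "far": rng.normal(10, 1, size=8),
        }
        result = compare_conditions(groups)
        assert result.significant("far", "near1")
        assert result.significant("far", "near2")
        assert not result.significant("near1", "near2")
        assert not (set(result.letters["far"]) & set(result.letters["near1"]))
        assert set(result.letters["near1"]) & set(result.letters["near2"])

    def test_zero_within_variance_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            anova_tukey({"a": [5.0, 5.0], "b": [7.0, 7.0]})

    def test_type_i_error_rate_near_alpha(self):
        rng = np.random.default_rng(123)
        rejections = 0
        n_sim = 400
        for _ in range(n_sim):
            groups = {f"g{i}": rng.normal(0, 1, size=8) for i in range(3)}
            rejections += anova_tukey(groups).p_value < 0.05
        assert 0.03 <= rejections / n_sim <= 0.07


class TestCompactLetterDisplay:
    def test_all_non_significant_single_letter(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(0, 1, size=8) for i in range(4)}
        result = compare_conditions(groups)
        assert all(v == "a" for v in result.letters.values())

    def test_all_significant_distinct_letters(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(20.0 * i, 1, size=8) for i in range(4)}
        result = compare_conditions(groups)
        letters = list(result.letters.values())
        assert len(set(letters)) == 4
        assert all(len(v) == 1 for v in letters)

    def test_chain_structure_matches_exhaustive_oracle(self):
        # adjacent means overlap, distant ones separate -> overlapping letters
        rng = np.random.default_rng(8)
        groups = {f"g{i}": rng.normal(3.2 * i, 1, size=8) for i in range(4)}
        result = compare_conditions(groups)
        assert brute_force_letter_check(result.letters, result.significant)
        n_letters = len(set("".join(result.letters.values())))
        assert n_letters == minimal_letter_count(list(groups), result.significant)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6])
    def test_random_designs_satisfy_share_iff_not_significant(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(3, 6))
        means = rng.uniform(0, 12, size=k)
        groups = {f"g{i}": rng.normal(means[i], 1.5, size=8) for i in range(k)}
        result = compare_conditions(groups)
        assert brute_force_letter_check(result.letters, result.significant)

    def test_letters_invariant_to_input_order(self):
        rng = np.random.default_rng(10)
        groups = {f"g{i}": rng.normal(3.0 * i, 1, size=8) for i in range(4)}
        forward = compare_conditions(dict(groups))
        reversed_ = compare_conditions(dict(reversed(list(groups.items()))))
        assert forward.letters == reversed_.letters

    def test_asymmetric_p_matrix_rejected(self):
        rng = np.random.default_rng(2)
        result = anova_tukey({"a": rng.normal(0, 1, 8), "b": rng.normal(5, 1, 8)})
        result.pairwise.iloc[0, 1] = 0.9
        with pytest.raises(InvalidInputError):
            compact_letter_display(result)
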