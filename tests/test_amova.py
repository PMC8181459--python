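"""Repeat-count distances, AMOVA variance components, and R_ST inference.

The oracle here is a deliberately naive re-derivation of the one-level
AMOVA arithmetic (pure-Python loops over the definitional sums of
squares), checked against the module on random small tables.
"""

import numpy as np
import pytest

from ystrkit.amova import (
    amova_rst,
    pairwise_rst,
    repeat_distance_sq,
    squared_distance_matrix,
)
from ystrkit.errors import InvalidParameterError, UndefinedRstError
from ystrkit.haplotypes import HaplotypeTable
from ystrkit.panel import PanelConfig
from ystrkit.simulate import SimConfig, simulate_smm_populations

from conftest import make_haplotype


# --- independent oracle ----------------------------------------------------


def brute_force_rst(d2, labels):
    """Direct evaluation of SS, MS and variance components, loops only."""
    n = len(labels)
    groups = sorted(set(labels))
    ss_total = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            ss_total += d2[i][j]
    ss_total /= n
    ss_within = 0.0
    for g in groups:
        members = [i for i in range(n) if labels[i] == g]
        acc = 0.0
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                acc += d2[members[a]][members[b]]
        if members:
            ss_within += acc / len(members)
    ss_among = ss_total - ss_within
    df_among = len(groups) - 1
    df_within = n - len(groups)
    ms_among = ss_among / df_among
    ms_within = ss_within / df_within if df_within else 0.0
    n0 = (n - sum(labels.count(g) ** 2 for g in groups) / n) / df_among
    var_among = (ms_among - ms_within) / n0
    var_within = ms_within
    return var_among / (var_among + var_within)


def random_table(panel, rng, n_per_group=(3, 3)):
    rows = []
    for g, size in enumerate(n_per_group):
        for i in range(size):
            rows.append(
                make_haplotype(
                    panel,
                    f"G{g}S{i}",
                    f"POP{g}",
                    {
                        "DYS19": int(rng.integers(10, 16)),
                        "DYS390": int(rng.integers(20, 26)),
                        "DYS391": int(rng.integers(8, 14)),
                        "DYS385a/b": [int(rng.integers(11, 18)), int(rng.integers(11, 18))],
                    },
                )
            )
    return HaplotypeTable(panel, rows)


SINGLE_LOCUS_PANEL = PanelConfig(loci=("DYS19",), multicopy_loci=frozenset())


class TestRepeatDistance:
    def test_identical_haplotypes_zero(self, small_panel):
        h = make_haplotype(small_panel, "A", "P", {"DYS19": 14, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]})
        assert repeat_distance_sq(h, h, small_panel) == 0.0

    def test_single_repeat_step_is_one(self, small_panel):
        base = {"DYS19": 14, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}
        a = make_haplotype(small_panel, "A", "P", base)
        b = make_haplotype(small_panel, "B", "P", {**base, "DYS391": 11})
        assert repeat_distance_sq(a, b, small_panel) == 1.0

    def test_microvariant_face_value(self, small_panel):
        base = {"DYS19": 14, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}
        a = make_haplotype(small_panel, "A", "P", base)
        b = make_haplotype(small_panel, "B", "P", {**base, "DYS19": "14.1"})
        assert repeat_distance_sq(a, b, small_panel) == pytest.approx(0.01)
        assert repeat_distance_sq(a, b, small_panel, microvariants="truncate") == 0.0

    def test_multicopy_excluded_by_default_but_togglable(self, small_panel):
        base = {"DYS19": 14, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}
        a = make_haplotype(small_panel, "A", "P", base)
        b = make_haplotype(small_panel, "B", "P", {**base, "DYS385a/b": [13, 19]})
        assert repeat_distance_sq(a, b, small_panel) == 0.0
        full = small_panel.with_distance_loci(small_panel.loci)
        assert repeat_distance_sq(a, b, full) == 4.0

    def test_missing_locus_pairwise_deletion(self, small_panel):
        base = {"DYS19": 14, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}
        a = make_haplotype(small_panel, "A", "P", {**base, "DYS19": None})
        b = make_haplotype(small_panel, "B", "P", {**base, "DYS391": 12})
        assert repeat_distance_sq(a, b, small_panel) == 4.0  # only DYS391 differs


class TestAmovaRst:
    def test_matches_brute_force_battery(self, small_panel):
        """Module R_ST equals the naive variance-component oracle to 1e-12."""
        rng = np.random.default_rng(12345)
        for trial in range(60):
            sizes = tuple(int(rng.integers(2, 5)) for _ in range(int(rng.integers(2, 4))))
            table = random_table(small_panel, rng, sizes)
            d2 = squared_distance_matrix(table)
            labels = [h.population for h in table]
            try:
                expected = brute_force_rst(d2.tolist(), labels)
            except ZeroDivisionError:
                continue
            if not np.isfinite(expected):
                continue
            got = amova_rst(table).rst
            assert got == pytest.approx(expected, abs=1e-12)

    def test_two_monomorphic_groups_give_rst_one(self, small_panel):
        rows = [make_haplotype(small_panel, f"A{i}", "A", {"DYS19": 10, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}) for i in range(3)]
        rows += [make_haplotype(small_panel, f"B{i}", "B", {"DYS19": 14, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}) for i in range(3)]
        assert amova_rst(HaplotypeTable(small_panel, rows)).rst == pytest.approx(1.0)

    def test_identical_group_multisets_give_nonpositive_rst(self, small_panel):
        rows = []
        for g, pop in enumerate(["A", "B"]):
            for i, allele in enumerate([10, 11, 12]):
                rows.append(make_haplotype(small_panel, f"{pop}{i}", pop, {"DYS19": allele, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}))
        assert amova_rst(HaplotypeTable(small_panel, rows)).rst <= 0.0

    def test_single_locus_worked_example(self):
        """A = {10,10,11}, B = {12,13,13} against the brute-force oracle."""
        rows = [
            make_haplotype(SINGLE_LOCUS_PANEL, f"A{i}", "A", {"DYS19": v})
            for i, v in enumerate([10, 10, 11])
        ] + [
            make_haplotype(SINGLE_LOCUS_PANEL, f"B{i}", "B", {"DYS19": v})
            for i, v in enumerate([12, 13, 13])
        ]
        table = HaplotypeTable(SINGLE_LOCUS_PANEL, rows)
        d2 = squared_distance_matrix(table)
        expected = brute_force_rst(d2.tolist(), [h.population for h in table])
        res = amova_rst(table)
        assert res.rst == pytest.approx(expected, abs=1e-12)
        assert res.ss_among >= 0 and res.ss_within >= 0 and res.rst <= 1

    def test_invariant_to_order_and_label_renaming(self, small_panel):
        rng = np.random.default_rng(7)
        table = random_table(small_panel, rng, (4, 3))
        base = amova_rst(table).rst
        shuffled = HaplotypeTable(small_panel, list(table.haplotypes[::-1]))
        assert amova_rst(shuffled).rst == pytest.approx(base, abs=1e-12)
        renamed = {h.sample_id: {"POP0": "Z", "POP1": "Q"}[h.population] for h in table}
        assert amova_rst(table, grouping=renamed).rst == pytest.approx(base, abs=1e-12)

    def test_identical_data_rst_undefined(self, small_panel):
        base = {"DYS19": 14, "DYS390": 23, "DYS391": 10, "DYS385a/b": [13, 17]}
        rows = [make_haplotype(small_panel, f"S{i}", "AB"[i % 2], base) for i in range(4)]
        with pytest.raises(UndefinedRstError):
            amova_rst(HaplotypeTable(small_panel, rows))


class TestPermutationAndPairwise:
    def test_diverged_populations_give_significant_p(self):
        cfg = SimConfig(
            seed=424,
            n_populations=2,
            sample_sizes=10,
            panel=PanelConfig(loci=tuple(f"L{i}" for i in range(10)), multicopy_loci=frozenset()),
            mu=0.002,
            divergence_generations=5000,
            within_generations=0,
        )
        table, _ = simulate_smm_populations(cfg)
        res = amova_rst(table, n_permutations=9999, seed=99)
        assert res.p_value <= 0.001

    def test_matrix_symmetry_and_zero_diagonal(self, small_panel):
        rng = np.random.default_rng(3)
        table = random_table(small_panel, rng, (4, 4, 3))
        res = pairwise_rst(table, n_permutations=49, seed=11)
        d = res.distances.data
        assert np.allclose(d, d.T) and np.all(np.diag(d) == 0) and np.all(d >= 0)
        p = res.p_values.to_numpy()
        assert np.allclose(p, p.T, equal_nan=True)
        assert res.raw.shape == (3, 3)

    def test_null_split_rst_near_zero(self, small_panel):
        """A single population split at random should center R_ST near 0."""
        rng = np.random.default_rng(8)
        table = random_table(small_panel, rng, (16,))
        estimates = []
        for rep in range(40):
            perm = rng.permutation(16)
            grouping = {
                table.haplotypes[i].sample_id: ("X" if rank < 8 else "Y")
                for rank, i in enumerate(perm)
            }
            estimates.append(amova_rst(table, grouping=grouping).rst)
        assert abs(float(np.mean(estimates))) < 0.05

    def test_invalid_parameters(self, small_panel):
        rng = np.random.default_rng(4)
        table = random_table(small_panel, rng, (3, 3))
        with pytest.raises(InvalidParameterError):
            pairwise_rst(table, n_permutations=0, seed=1)
        with pytest.raises(InvalidParameterError):
            pairwise_rst(table, n_permutations=99, seed=None)
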