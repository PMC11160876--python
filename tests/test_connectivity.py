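"""Connectivity change detection: bootstrap adjacency, permutation null, predicates."""

import numpy as np
import pandas as pd
import pytest

from netprog.connectivity import (
    AdjacencyMatrix,
    bootstrap_adjacency,
    categorize_changes,
    classify_nodes,
    confirm_changes,
    detect_gain_loss,
    filter_anatomical,
    permutation_dr_threshold,
)
from netprog.exceptions import DegenerateDataError, DomainError, LabelMismatchError
from netprog.expression import NetworkPattern

from test_expression import profiles_from


def adj_from(entries, labels):
    n = len(labels)
    m = np.full((n, n), np.nan)
    for (i, j), r in entries.items():
        m[i, j] = m[j, i] = r
    return AdjacencyMatrix(r=pd.DataFrame(m, index=labels, columns=labels))


class TestBootstrapAdjacency:
    def test_duplicated_region_has_median_one(self, rng):
        x = rng.normal(10, 1, (8, 3))
        x[:, 1] = x[:, 0]  # two regions exactly equal across subjects
        adj = bootstrap_adjacency(profiles_from(x), B=20, seed=0)
        assert adj.r.iloc[0, 1] == pytest.approx(1.0)

    def test_single_iterate_is_plain_resample_correlation(self, rng):
        x = rng.normal(10, 1, (8, 4))
        adj = bootstrap_adjacency(profiles_from(x), B=1, seed=3)
        idx = np.random.default_rng(3).integers(0, 8, size=8)
        expected = np.corrcoef(x[idx], rowvar=False)
        got = adj.r.to_numpy()
        off = ~np.eye(4, dtype=bool)
        assert np.allclose(got[off], expected[off])

    def test_independent_noise_rarely_exceeds_half(self):
        """Independent-noise regions at n=17: the aggregate fraction of
        median-bootstrap |r| entries below 0.5 is ~0.95 (simulation puts the
        bootstrap-median sd at ~0.27, slightly above the 0.25 of a plain
        sample correlation)."""
        fracs = []
        for s in range(10):
            x = np.random.default_rng(s).normal(0, 1, (17, 30))
            adj = bootstrap_adjacency(profiles_from(np.exp(x)), B=100, seed=1000 + s)
            off = adj.r.to_numpy()[~np.eye(30, dtype=bool)]
            fracs.append((np.abs(off) < 0.5).mean())
        assert np.mean(fracs) >= 0.94

    def test_requires_five_subjects(self, rng):
        with pytest.raises(DegenerateDataError):
            bootstrap_adjacency(profiles_from(rng.normal(5, 1, (4, 3))), B=10)


class TestPermutationThreshold:
    def test_alpha_one_gives_null_minimum(self, rng):
        prof = profiles_from(rng.normal(10, 1, (8, 6)))
        null = permutation_dr_threshold(prof, P=200, alpha=1.0, seed=0)
        assert null.threshold == pytest.approx(null.null_abs_dr.min())

    def test_two_regions_degenerate_null(self, rng):
        prof = profiles_from(rng.normal(10, 1, (8, 2)))
        null = permutation_dr_threshold(prof, P=100, seed=0)
        assert null.threshold == 0.0

    def test_threshold_is_empirical_quantile(self, rng):
        prof = profiles_from(rng.normal(10, 1, (10, 8)))
        null = permutation_dr_threshold(prof, P=200, alpha=0.05, seed=1)
        assert null.threshold == pytest.approx(np.quantile(null.null_abs_dr, 0.95))

    def test_invalid_p_rejected_and_low_p_warns(self, rng):
        prof = profiles_from(rng.normal(10, 1, (8, 4)))
        with pytest.raises(DomainError):
            permutation_dr_threshold(prof, P=0)
        with pytest.warns(UserWarning):
            permutation_dr_threshold(prof, P=50, seed=0)


class TestDetectGainLoss:
    labels = ["A", "B", "C"]

    def test_threshold_predicate_table(self):
        case = adj_from({(0, 1): 0.9, (0, 2): 0.65, (1, 2): 0.1}, self.labels)
        hc = adj_from({(0, 1): 0.1, (0, 2): 0.55, (1, 2): 0.85}, self.labels)
        changes = {(c.region_a, c.region_b): c.status
                   for c in detect_gain_loss(case, hc)}
        assert changes == {("A", "B"): "gained", ("B", "C"): "lost"}
        # (A, C): |dr| = 0.10 <= 0.4 -> no change

    def test_identical_matrices_give_empty_list(self):
        a = adj_from({(0, 1): 0.9, (0, 2): 0.2, (1, 2): 0.7}, self.labels)
        assert detect_gain_loss(a, a) == []

    def test_swap_symmetry(self, rng):
        vals = {(i, j): float(rng.uniform(-1, 1))
                for i in range(3) for j in range(i + 1, 3)}
        vals2 = {k: float(rng.uniform(-1, 1)) for k in vals}
        a, b = adj_from(vals, self.labels), adj_from(vals2, self.labels)
        fwd = {(c.region_a, c.region_b): c.status for c in detect_gain_loss(a, b)}
        rev = {(c.region_a, c.region_b): c.status for c in detect_gain_loss(b, a)}
        swap = {"gained": "lost", "lost": "gained"}
        assert rev == {k: swap[v] for k, v in fwd.items()}

    def test_gained_and_lost_sets_disjoint(self, rng):
        n = 12
        m1 = np.clip(rng.uniform(-1, 1, (n, n)), -1, 1)
        m2 = np.clip(rng.uniform(-1, 1, (n, n)), -1, 1)
        labels = [f"R{i}" for i in range(n)]
        a = adj_from({(i, j): m1[i, j] for i in range(n) for j in range(i + 1, n)}, labels)
        b = adj_from({(i, j): m2[i, j] for i in range(n) for j in range(i + 1, n)}, labels)
        changes = detect_gain_loss(a, b)
        keys = [(c.region_a, c.region_b) for c in changes]
        assert len(keys) == len(set(keys))

    def test_label_mismatch_reports_regions(self):
        a = adj_from({(0, 1): 0.5}, ["A", "B"])
        b = adj_from({(0, 1): 0.5}, ["A", "C"])
        with pytest.raises(LabelMismatchError, match="C"):
            detect_gain_loss(a, b)

    def test_magnitude_dr_mode(self):
        case = adj_from({(0, 1): -0.9}, ["A", "B"])
        hc = adj_from({(0, 1): 0.55}, ["A", "B"])
        signed = detect_gain_loss(case, hc, dr_mode="signed")
        mag = detect_gain_loss(case, hc, dr_mode="magnitude")
        assert signed[0].abs_dr == pytest.approx(1.45)
        assert mag == []  # ||-0.9| - |0.55|| = 0.35 <= 0.4


class TestAnatomicalFilter:
    anatomy = [("A", "B"), ("B", "C"), ("C", "D"), ("D", "E")]

    def _mk(self, a, b):
        from netprog.connectivity import ConnectionChange

        return ConnectionChange(region_a=a, region_b=b, status="gained",
                                r_case=0.9, r_hc=0.0, abs_dr=0.9)

    def test_direct_and_two_hop_retained(self):
        kept = filter_anatomical([self._mk("A", "B"), self._mk("A", "C")], self.anatomy)
        assert len(kept) == 2 and all(c.anatomical_ok for c in kept)

    def test_three_hops_dropped(self):
        assert filter_anatomical([self._mk("A", "D")], self.anatomy) == []

    def test_unknown_region_dropped(self):
        assert filter_anatomical([self._mk("A", "Z")], self.anatomy) == []

    def test_empty_anatomy_drops_everything(self):
        import networkx as nx

        assert filter_anatomical([self._mk("A", "B")], nx.Graph()) == []


class TestCategorize:
    pdrp = NetworkPattern(name="PDRP", weights=pd.Series([0.7, -0.7], index=["A", "B"]))
    pdcp = NetworkPattern(name="PDCP", weights=pd.Series([0.7, -0.7], index=["C", "D"]))

    def _mk(self, a, b, status="gained"):
        from netprog.connectivity import ConnectionChange

        return ConnectionChange(region_a=a, region_b=b, status=status,
                                r_case=0.9, r_hc=0.0, abs_dr=0.9)

    def test_all_within_motor_pattern(self):
        table = categorize_changes([self._mk("A", "B")], self.pdrp, self.pdcp)
        rr = table[(table.category == "RR")]
        assert rr["pct"].iloc[0] == 100.0

    def test_percentages(self):
        changes = (
            [self._mk("A", "B") for _ in range(5)]
            + [self._mk("A", "C") for _ in range(3)]
            + [self._mk("C", "D") for _ in range(2)]
        )
        table = categorize_changes(changes, self.pdrp, self.pdcp)
        pcts = table.set_index("category")["pct"]
        assert pcts["RR"] == 50.0 and pcts["RC"] == 30.0 and pcts["CC"] == 20.0
        assert table["pct"].sum() == pytest.approx(100.0, abs=1e-9)

    def test_empty_changes_give_empty_table(self):
        table = categorize_changes([], self.pdrp, self.pdcp)
        assert table.empty and not table.isna().any().any()

    def test_endpoint_outside_patterns_excluded(self):
        table = categorize_changes(
            [self._mk("A", "B"), self._mk("A", "Z")], self.pdrp, self.pdcp
        )
        assert int(table["count"].sum()) == 1


class TestClassifyNodes:
    def test_active_vs_underactive(self, rng):
        base = 5 + rng.normal(0, 0.01, (6, 2))
        case = base.copy()
        case[:, 0] += 1.0
        pat = NetworkPattern(name="P", weights=pd.Series([0.7, -0.7], index=["R0", "R1"]))
        out = classify_nodes(profiles_from(case), profiles_from(base), pat)
        assert "R0" in out.active and "R1" not in out.active

    def test_core_is_top_half_by_weight_magnitude(self, rng):
        pat = NetworkPattern(
            name="P", weights=pd.Series([3.0, 2.0, -1.0, -0.5],
                                        index=["a", "b", "c", "d"])
        )
        prof = profiles_from(np.exp(rng.normal(0, 0.1, (5, 4))),
                             labels=["a", "b", "c", "d"])
        out = classify_nodes(prof, prof, pat)
        assert out.core == frozenset({"a", "b"})

    def test_all_equal_weights_all_core(self, rng):
        pat = NetworkPattern(name="P", weights=pd.Series([0.5, 0.5, -0.5, -0.5],
                                                         index=list("abcd")))
        prof = profiles_from(np.exp(rng.normal(0, 0.1, (5, 4))), labels=list("abcd"))
        out = classify_nodes(prof, prof, pat)
        assert out.core == frozenset("abcd")


class TestConfirmation:
    def test_confirmation_keeps_strong_planted_edge(self, rng):
        # two strongly correlated regions in "case", independent in "hc"
        n = 20
        shared = rng.normal(0, 1, n)
        case = np.column_stack([shared + 0.2 * rng.normal(0, 1, n),
                                shared + 0.2 * rng.normal(0, 1, n),
                                rng.normal(0, 1, n)])
        hc = rng.normal(0, 1, (n, 3))
        cp, hp = profiles_from(np.exp(case)), profiles_from(np.exp(hc))
        adj_c = bootstrap_adjacency(cp, B=50, seed=0)
        adj_h = bootstrap_adjacency(hp, B=50, seed=1)
        changes = detect_gain_loss(adj_c, adj_h)
        assert any(c.status == "gained" for c in changes)
        kept = confirm_changes(changes, cp, hp, n_iter=100, seed=2)
        assert any(c.region_a == "R0" and c.region_b == "R1" for c in kept)
        assert all(c.confirmation_frac > 0.5 for c in kept)
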