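"""Threshold interpolation, bond-fraction analytics, fragment
distributions and the family comparison table."""

import math

import networkx as nx
import numpy as np
import pytest

from capsidperc import (
    NoThresholdError,
    PercolationResult,
    RemovalSpec,
    expected_edge_fraction,
    family_comparison_table,
    fragment_size_distribution,
    fragmentation_threshold,
    estimate_fragmentation_threshold,
)
from capsidperc.percolation import mean_edge_fraction_mc
from capsidperc.thresholds import PLANAR_REFERENCE


def _analytic_curve(counts, pcon, n_elements, se=None):
    counts = np.asarray(counts)
    pcon = np.asarray(pcon, dtype=float)
    if se is None:
        se = np.zeros_like(pcon)
    return PercolationResult(
        mode="vertex", counts=counts, pcon=pcon, se=np.asarray(se),
        replicates=1, seed=0, n_elements=n_elements, n_vertices=n_elements,
    )


class TestFragmentationThreshold:
    def test_cycle12_analytic_interpolation(self):
        """P_con(1)=1, P_con(2)=12/66: the 0.5 crossing interpolates to
        (1 + 0.5/(1 - 12/66)) / 12."""
        curve = _analytic_curve(
            [0, 1, 2, 3],
            [1.0, 1.0, 12 / 66, 12 / math.comb(12, 3)],
            12,
        )
        est = fragmentation_threshold(curve)
        expected = (1 + 0.5 / (1 - 12 / 66)) / 12
        assert est.threshold == pytest.approx(expected, abs=1e-12)
        assert (est.i_low, est.i_high) == (1, 2)

    def test_noisy_curve_is_isotonic_smoothed(self):
        # non-monotone jitter around a clean sigmoid must not break the
        # bracket search
        counts = np.arange(11)
        clean = 1 / (1 + np.exp(1.5 * (counts - 5)))
        rng = np.random.default_rng(0)
        noisy = np.clip(clean + rng.normal(0, 0.02, 11), 0, 1)
        est = fragmentation_threshold(
            _analytic_curve(counts, noisy, 20, se=np.full(11, 0.02))
        )
        assert 4 / 20 <= est.threshold <= 6 / 20

    def test_no_crossing_raises(self):
        with pytest.raises(NoThresholdError, match="does not cross"):
            fragmentation_threshold(_analytic_curve([0, 1, 2], [1, 1, 1], 8))

    def test_complete_graph_has_no_threshold(self):
        with pytest.raises(NoThresholdError):
            estimate_fragmentation_threshold(
                nx.complete_graph(8), "vertex", replicates=500,
                coarse_replicates=500,
            )

    def test_estimate_reproducible(self, t3_networks):
        g = t3_networks["triangular"]
        a, _ = estimate_fragmentation_threshold(g, "vertex", 3000, seed=9)
        b, _ = estimate_fragmentation_threshold(g, "vertex", 3000, seed=9)
        assert a.threshold == b.threshold

    def test_bracket_invariant(self, t3_networks):
        est, curve = estimate_fragmentation_threshold(
            t3_networks["rhombic"], "vertex", 5000, seed=3
        )
        assert est.i_high == est.i_low + 1
        assert est.i_low / 90 < est.threshold <= est.i_high / 90


class TestExpectedEdgeFraction:
    def test_boundaries(self):
        assert expected_edge_fraction(1.0, 60) == 1.0
        assert expected_edge_fraction(0.0, 60) == 0.0
        assert expected_edge_fraction(1 / 60, 60) == 0.0  # single survivor

    def test_half_removal_value(self):
        assert expected_edge_fraction(0.5, 60) == pytest.approx(870 / 3540)

    def test_non_integer_count_rejected(self):
        with pytest.raises(ValueError, match="not an integer"):
            expected_edge_fraction(0.123, 60)

    def test_graph_independent_against_mc(self, t3_networks):
        """The expectation is valency-free: it must match the empirical
        mean surviving-edge fraction on every network."""
        for g in t3_networks.values():
            V = g.n_tiles
            mean, se = mean_edge_fraction_mc(g, V // 2, 100_000, 17)
            assert abs(mean - expected_edge_fraction(0.5, V)) <= 3 * se


class TestFragmentDistribution:
    def test_zero_removal_point_mass(self, t3_networks):
        g = t3_networks["triangular"]
        dist = fragment_size_distribution(g, "vertex", f=0.0, replicates=50)
        assert dist.pdf[-1] == 1.0  # all mass at size V0
        assert dist.pdf[:-1].sum() == 0.0

    def test_pdf_normalised_cdf_monotone(self, t3_networks):
        g = t3_networks["kite"]
        dist = fragment_size_distribution(
            g, "vertex", f=0.3, sd=0.02, replicates=2000, seed=1
        )
        assert dist.pdf.sum() == pytest.approx(1.0)
        assert np.all(np.diff(dist.cdf) >= -1e-12)
        assert dist.cdf[-1] == pytest.approx(1.0)

    def test_cycle6_enumerated_fragment_pattern(self):
        """Removing 2 of 6 cycle vertices: 6 adjacent pairs leave one
        4-fragment, 6 distance-2 pairs leave {1,3}, 3 opposite pairs
        leave {2,2}; the fragment-size PDF is uniform on {1,2,3,4}."""
        dist = fragment_size_distribution(
            nx.cycle_graph(6), "vertex", f=2 / 6, replicates=200_000, seed=2
        )
        assert dist.pdf[:4] == pytest.approx([0.25] * 4, abs=0.01)
        assert dist.pdf[4:].sum() == 0.0

    def test_bond_mode_accounts_for_all_subunits(self):
        # bond breakage on a path: all n vertices always appear
        dist = fragment_size_distribution(
            nx.path_graph(6), "bond", f=0.5, replicates=1000, seed=3
        )
        sizes = dist.sizes
        mean_total = (dist.pdf * sizes).sum() / dist.pdf.sum()
        # mean fragment size times mean fragment count = 6 exactly per
        # replicate; just check support covers singletons and normalisation
        assert dist.pdf.sum() == pytest.approx(1.0)
        assert dist.pdf[0] > 0  # isolated subunits counted
        assert mean_total > 0

    def test_invalid_fraction_rejected(self, t3_networks):
        with pytest.raises(ValueError, match="in \\[0, 1\\]"):
            fragment_size_distribution(t3_networks["kite"], "vertex", f=1.2)


class TestComparisonTable:
    def test_empty_families_gives_header_only(self):
        table = family_comparison_table(families=(), replicates=10)
        assert len(table) == 0

    def test_structure_small(self):
        table = family_comparison_table(
            T_values=(3,), families=("triangular", "kite"),
            replicates=2000, coarse_replicates=1000, seed=5,
        )
        assert list(table["family"]) == ["triangular", "kite"]
        assert set(table.columns) >= {"family", "T", "k0", "V0", "E0",
                                      "f_T", "f_T_se", "f_T_e", "f_T_e_se"}
        row = table.iloc[0]
        assert (row["V0"], row["E0"], row["k0"]) == (60, 90, 3)
        assert 0 < row["f_T"] < 0.5 and 0 < row["f_T_e"] < 0.5

    def test_unsupported_combination_skipped_with_reason(self):
        table = family_comparison_table(
            T_values=(5,), families=("triangular",), replicates=10
        )
        assert len(table) == 1
        assert "unsupported" in table.iloc[0]["note"]
        assert math.isnan(table.iloc[0]["f_T"])


def test_planar_reference_constants_stored_verbatim():
    ref = PLANAR_REFERENCE.as_dict()
    assert ref["triangular"] == {"p_c": 0.303, "p_c_e": 0.347}
    assert ref["kite"] == {"p_c": 0.378, "p_c_e": 0.475}
    assert ref["rhombic"] == {"p_c": 0.347, "p_c_e": 0.476}
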