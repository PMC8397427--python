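"""Model/Results interface for capsid percolation analysis.

:class:`PercolationModel` wraps a bond network (a capsid tiling built
from (family, h, k), or any user graph) together with a removal mode;
``fit()`` runs the Monte Carlo percolation protocol and returns a
:class:`PercolationResults` object holding the P_con curve, the
interpolated fragmentation threshold with its standard error, and a
``summary()`` table.  Fragment-size simulation and plotting hang off
these two objects.

Example
-------
>>> model = PercolationModel.from_tiling("rhombic", 2, 0)  # T=4, HBV-like
>>> res = model.fit(replicates=100_000, seed=1)
>>> res.threshold.threshold        # doctest: +SKIP
0.2599...
"""

from __future__ import annotations

import numpy as np

from .percolation import MODES, PercolationResult, RemovalSpec, pcon_curve
from .thresholds import (
    FragmentDistribution,
    NoThresholdError,
    ThresholdEstimate,
    fragment_size_distribution,
    fragmentation_threshold,
    estimate_fragmentation_threshold,
)
from .tilings import CapsidGraph, TilingSpec, capsid_network, validate_network

__all__ = ["PercolationModel", "PercolationResults"]


class PercolationModel:
    """Site or bond percolation model of an intersubunit bond network.

    Parameters
    ----------
    graph : CapsidGraph or networkx.Graph
        The bond network to perforate.
    mode : {"vertex", "bond"}
        Whether subunits (vertices, with incident bonds) or individual
        bonds (edges) are removed.
    """

    def __init__(self, graph, mode: str = "vertex"):
        if mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
        self.graph = graph
        self.mode = mode
        if isinstance(graph, CapsidGraph):
            report = validate_network(graph)
            if not report.ok:
                raise ValueError(f"invalid capsid network:\n{report}")

    @classmethod
    def from_tiling(cls, family: str, h: int, k: int = 0,
                    mode: str = "vertex") -> "PercolationModel":
        """Build the bond network of a capsid tiling and wrap it."""
        return cls(capsid_network(TilingSpec(family, h, k)), mode=mode)

    @property
    def n_elements(self) -> int:
        return RemovalSpec(self.mode, 0).total_elements(self.graph)

    def fit(self, replicates: int = 100_000, seed: int = 0,
            grid=None, coarse_replicates: int = 3_000,
            window: int = 6) -> "PercolationResults":
        """Estimate the P_con curve and fragmentation threshold.

        With ``grid=None`` the transition is bracketed by a cheap coarse
        scan and the integer-complete neighbourhood of the crossing is
        estimated at full ``replicates``; an explicit grid of removal
        counts skips the coarse pass.
        """
        if grid is not None:
            curve = pcon_curve(self.graph, self.mode, grid, replicates, seed)
            try:
                threshold = fragmentation_threshold(curve)
            except NoThresholdError:
                threshold = None
        else:
            try:
                threshold, curve = estimate_fragmentation_threshold(
                    self.graph, self.mode, replicates=replicates, seed=seed,
                    coarse_replicates=coarse_replicates, window=window,
                )
            except NoThresholdError:
                threshold = None
                total = self.n_elements
                stride = max(1, total // 40)
                curve = pcon_curve(self.graph, self.mode,
                                   range(0, total + 1, stride),
                                   coarse_replicates, seed)
        return PercolationResults(self, curve, threshold)

    def fragment_distribution(self, f: float, sd: float | None = None,
                              replicates: int = 100_000,
                              seed: int = 0) -> FragmentDistribution:
        """Connected-fragment size distribution at mean deleted fraction
        ``f`` (fixed regime, or Normal(f, sd) truncated to [0, 1])."""
        return fragment_size_distribution(
            self.graph, mode=self.mode, f=f, sd=sd,
            replicates=replicates, seed=seed,
        )


class PercolationResults:
    """Results of a fitted :class:`PercolationModel`.

    Attributes
    ----------
    curve : PercolationResult
        P_con estimates with binomial SEs over the removal-count grid.
    threshold : ThresholdEstimate or None
        Interpolated P_con = 0.5 crossing; None when the curve never
        crosses 0.5 on the grid (e.g. complete graphs).
    """

    def __init__(self, model: PercolationModel, curve: PercolationResult,
                 threshold: ThresholdEstimate | None):
        self.model = model
        self.curve = curve
        self.threshold = threshold

    def summary(self) -> str:
        g = self.model.graph
        lines = ["Capsid percolation results", "=" * 26]
        if isinstance(g, CapsidGraph):
            lines.append(f"network:    {g.describe()}")
        else:
            lines.append(
                f"network:    user graph, {g.number_of_nodes()} vertices, "
                f"{g.number_of_edges()} edges"
            )
        lines.append(f"mode:       {self.model.mode} removal")
        lines.append(
            f"grid:       counts {int(self.curve.counts[0])}.."
            f"{int(self.curve.counts[-1])} of {self.curve.n_elements}"
        )
        lines.append(f"replicates: {self.curve.replicates} per grid point")
        lines.append(f"seed:       {self.curve.seed}")
        t = self.threshold
        if t is None:
            lines.append("threshold:  no P_con = 0.5 crossing in grid")
        else:
            lines.append(
                f"threshold:  {t.symbol} = {t.threshold:.4f} +/- {t.se:.4f} "
                f"(bracket {t.i_low}..{t.i_high})"
            )
        return "\n".join(lines)

    def plot(self, ax=None):
        """P_con against deleted fraction, with the threshold gridline."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.errorbar(self.curve.fractions, self.curve.pcon,
                    yerr=3 * self.curve.se, fmt=".-", capsize=2)
        ax.axhline(0.5, color="grey", lw=0.8, ls=":")
        if self.threshold is not None:
            ax.axvline(self.threshold.threshold, color="grey", lw=0.8, ls="--")
        sym = "f_v^d" if self.curve.mode == "vertex" else "f_e^d"
        ax.set_xlabel(f"deleted fraction {sym}")
        ax.set_ylabel("P_con")
        return ax

    def fragment_distribution(self, f: float, sd: float | None = None,
                              replicates: int = 100_000,
                              seed: int = 0) -> FragmentDistribution:
        return self.model.fragment_distribution(f, sd, replicates, seed)
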