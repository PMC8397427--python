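"""Fragmentation thresholds, bond-fraction analytics and fragment-size
distributions.

The fragmentation threshold f_T (subunit removal) or f_T^e (bond
breakage) is the deleted fraction at which the network is, on average,
disconnected: P_con = 0.5.  It is located by isotonic regression of the
Monte Carlo curve (P_con is non-increasing in the removal count) followed
by linear interpolation between the two bracketing integer counts; the
interpolation error is below 1/V0 and hence below Monte Carlo noise at
1e5 replicates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .percolation import (
    PercolationResult,
    RemovalSpec,
    _kernel_seed,
    graph_arrays,
    pcon_curve,
)
from .tilings import FAMILY_COUNTS, CapsidGraph, TilingSpec, capsid_network

__all__ = [
    "ThresholdEstimate",
    "NoThresholdError",
    "ReferenceConstants",
    "PLANAR_REFERENCE",
    "fragmentation_threshold",
    "estimate_fragmentation_threshold",
    "expected_edge_fraction",
    "FragmentDistribution",
    "fragment_size_distribution",
    "family_comparison_table",
    "TABLE1_T_VALUES",
]

#: T-numbers of the published family comparison (triangular and rhombic).
TABLE1_T_VALUES = (3, 4, 7, 9, 12, 27, 36)


class NoThresholdError(ValueError):
    """The P_con curve never crosses 0.5 on the supplied grid (e.g. a
    complete graph, or a grid that stops short of the transition)."""


@dataclass(frozen=True)
class ThresholdEstimate:
    """Interpolated P_con = 0.5 crossing of a percolation curve."""

    mode: str                 # "vertex" -> f_T, "bond" -> f_T^e
    threshold: float          # deleted fraction at the crossing
    i_low: int
    i_high: int
    se: float                 # delta-method SE on the fraction scale
    n_elements: int
    replicates: int
    seed: int
    family: str | None = None
    T: int | None = None

    @property
    def symbol(self) -> str:
        return "f_T" if self.mode == "vertex" else "f_T^e"

    def __str__(self) -> str:
        tag = f"{self.family} T={self.T} " if self.family else ""
        return (
            f"{tag}{self.symbol} = {self.threshold:.4f} +/- {self.se:.4f} "
            f"(bracket {self.i_low}..{self.i_high} of {self.n_elements}, "
            f"{self.replicates} replicates)"
        )


@dataclass(frozen=True)
class ReferenceConstants:
    """Literature site/bond deletion thresholds of the infinite planar
    lattices underlying each tiling family (stored verbatim, never
    recomputed here).  Family order: (triangular, kite, rhombic)."""

    p_c: tuple = (0.303, 0.378, 0.347)
    p_c_e: tuple = (0.347, 0.475, 0.476)
    families: tuple = ("triangular", "kite", "rhombic")

    def as_dict(self) -> dict:
        return {
            fam: {"p_c": s, "p_c_e": b}
            for fam, s, b in zip(self.families, self.p_c, self.p_c_e)
        }


PLANAR_REFERENCE = ReferenceConstants()


def _isotonic_decreasing(counts: np.ndarray, pcon: np.ndarray,
                         weights: np.ndarray | None = None) -> np.ndarray:
    from sklearn.isotonic import IsotonicRegression

    iso = IsotonicRegression(increasing=False, out_of_bounds="clip")
    return iso.fit_transform(counts.astype(float), pcon, sample_weight=weights)


def fragmentation_threshold(curve: PercolationResult) -> ThresholdEstimate:
    """Locate the P_con = 0.5 crossing of a percolation curve.

    The Monte Carlo curve is first isotonic-regressed (non-increasing), the
    first bracketing pair of consecutive grid counts is found, and the
    crossing count is linearly interpolated within the bracket.  The SE is
    propagated from the bracket estimates by the delta method.

    Raises :class:`NoThresholdError` when the smoothed curve never drops
    below 0.5.
    """
    counts = np.asarray(curve.counts)
    yhat = _isotonic_decreasing(counts, np.asarray(curve.pcon))
    below = np.flatnonzero(yhat < 0.5)
    if len(below) == 0 or below[0] == 0:
        raise NoThresholdError(
            "P_con does not cross 0.5 within the grid "
            f"(smoothed range {yhat.min():.3f}..{yhat.max():.3f})"
        )
    hi = below[0]
    lo = hi - 1
    p_lo, p_hi = yhat[lo], yhat[hi]
    i_lo, i_hi = int(counts[lo]), int(counts[hi])
    # linear interpolation in (count, P_con)
    a = p_lo - 0.5
    b = p_lo - p_hi
    t = i_lo + (a / b) * (i_hi - i_lo)
    # delta method on t = i_lo + a/b with independent bracket estimates
    se_lo, se_hi = curve.se[lo], curve.se[hi]
    dt_dplo = (b - a) / b**2
    dt_dphi = a / b**2
    var_t = (dt_dplo * se_lo) ** 2 + (dt_dphi * se_hi) ** 2
    return ThresholdEstimate(
        mode=curve.mode,
        threshold=t / curve.n_elements,
        i_low=i_lo,
        i_high=i_hi,
        se=math.sqrt(var_t) * abs(i_hi - i_lo) / curve.n_elements,
        n_elements=curve.n_elements,
        replicates=curve.replicates,
        seed=curve.seed,
        family=curve.family,
        T=curve.T,
    )


def estimate_fragmentation_threshold(
    g,
    mode: str = "vertex",
    replicates: int = 100_000,
    seed: int = 0,
    coarse_replicates: int = 3_000,
    window: int = 6,
) -> tuple[ThresholdEstimate, PercolationResult]:
    """Two-pass threshold estimation on a capsid (or arbitrary) network.

    A coarse strided scan with ``coarse_replicates`` brackets the
    transition; the integer-complete neighbourhood (``+/- window`` counts)
    is then re-estimated at full ``replicates`` and interpolated.  Returns
    the estimate together with the fine-grid curve.
    """
    total = RemovalSpec(mode, 0).total_elements(g)
    stride = max(1, total // 40)
    sub = np.random.SeedSequence(seed).generate_state(2, np.uint32) & 0x7FFFFFFF
    coarse_grid = list(range(0, total + 1, stride))
    if coarse_grid[-1] != total:
        coarse_grid.append(total)
    coarse = pcon_curve(g, mode, coarse_grid, coarse_replicates, int(sub[0]))
    # interpolated coarse crossing centres the fine window
    centre = fragmentation_threshold(coarse).threshold * total
    lo = hi = int(round(centre))
    w = window
    while True:
        fine_grid = list(range(max(0, lo - w), min(total, hi + w) + 1))
        fine = pcon_curve(g, mode, fine_grid, replicates, int(sub[1]))
        fine.seed = int(seed)  # provenance carries the master seed
        try:
            est = fragmentation_threshold(fine)
            return est, fine
        except NoThresholdError:
            if fine_grid[0] == 0 and fine_grid[-1] == total:
                raise
            lo, hi, w = fine_grid[0], fine_grid[-1], w + max(4, total // 20)


# ---------------------------------------------------------------------------
# Expected surviving-bond fraction
# ---------------------------------------------------------------------------

def expected_edge_fraction(p_V: float, V: int) -> float:
    """Exact expectation of the surviving-edge fraction p_E given the
    surviving-vertex fraction p_V under uniform removal of exactly
    ``(1 - p_V) * V`` vertices.

    An edge survives iff both endpoints survive; under the exact-count
    (hypergeometric) ensemble that probability is R(R-1)/(V(V-1)) with
    R = p_V * V, for every simple graph regardless of valency.
    """
    if V < 1:
        raise ValueError("V must be a positive integer")
    R = p_V * V
    R_int = round(R)
    if abs(R - R_int) > 1e-9:
        raise ValueError(
            f"p_V * V = {R} is not an integer; the exact-count ensemble "
            "requires a whole number of surviving vertices"
        )
    R = R_int
    if not 0 <= R <= V:
        raise ValueError(f"surviving count {R} outside 0..{V}")
    if R <= 1 or V == 1:
        return 0.0 if R <= 1 else 1.0
    return R * (R - 1) / (V * (V - 1))


# ---------------------------------------------------------------------------
# Fragment size distributions
# ---------------------------------------------------------------------------

@dataclass
class FragmentDistribution:
    """Empirical distribution of connected-fragment sizes.

    ``pdf[s-1]`` is the probability that a randomly chosen fragment (over
    all replicates) has size s; removed subunits are excluded in vertex
    mode while bond mode accounts for every subunit.
    """

    mode: str
    sizes: np.ndarray         # 1..V0
    pdf: np.ndarray
    cdf: np.ndarray
    mean_fraction: float      # requested mean deleted fraction
    sd_fraction: float | None
    replicates: int
    seed: int
    n_vertices: int
    family: str | None = None
    T: int | None = None

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"size": self.sizes, "pdf": self.pdf, "cdf": self.cdf})

    def mass_at_least(self, size: int) -> float:
        """Probability mass on fragments of at least ``size`` subunits."""
        return float(self.pdf[self.sizes >= size].sum())


def _round_half_even(x: np.ndarray) -> np.ndarray:
    return np.rint(x).astype(np.int64)


def fragment_size_distribution(
    g,
    mode: str = "vertex",
    f: float = 0.0,
    sd: float | None = None,
    replicates: int = 100_000,
    seed: int = 0,
) -> FragmentDistribution:
    """Distribution of connected-fragment sizes under a removal regime.

    ``f`` is the mean deleted fraction; with ``sd`` set, each replicate
    draws its own fraction from Normal(f, sd) truncated to [0, 1] (the
    spread a disassembly experiment produces); with ``sd=None`` the
    fraction is fixed.  Fractions are converted to integer counts by
    round-half-to-even.
    """
    if not 0.0 <= f <= 1.0:
        raise ValueError(f"mean deleted fraction must be in [0, 1], got {f}")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    eu, ev, n = graph_arrays(g)
    total = n if mode == "vertex" else len(eu)
    rng = np.random.default_rng(seed)
    if sd is None:
        fractions = np.full(replicates, f)
    else:
        fractions = np.clip(rng.normal(f, sd, size=replicates), 0.0, 1.0)
    counts = np.clip(_round_half_even(fractions * total), 0, total)
    kseed = _kernel_seed(seed, 1_000_003)
    if mode == "vertex":
        hist = _kernels.fragment_hist_vertex(eu, ev, n, counts, kseed)
    elif mode == "bond":
        hist = _kernels.fragment_hist_bond(eu, ev, n, counts, kseed)
    else:
        raise ValueError(f"mode must be 'vertex' or 'bond', got {mode!r}")
    hist = hist[1:]  # sizes 1..V0
    tot = hist.sum()
    pdf = hist / tot if tot else hist.astype(float)
    fam = g.family if isinstance(g, CapsidGraph) else None
    T = g.T if isinstance(g, CapsidGraph) else None
    return FragmentDistribution(
        mode=mode, sizes=np.arange(1, n + 1), pdf=pdf, cdf=np.cumsum(pdf),
        mean_fraction=f, sd_fraction=sd, replicates=replicates, seed=seed,
        n_vertices=n, family=fam, T=T,
    )


# ---------------------------------------------------------------------------
# Family comparison table
# ---------------------------------------------------------------------------

def family_comparison_table(
    T_values=TABLE1_T_VALUES,
    families=("triangular", "rhombic", "kite"),
    replicates: int = 100_000,
    seed: int = 0,
    coarse_replicates: int = 3_000,
    window: int = 6,
    progress=None,
):
    """Subunit and bond fragmentation thresholds per (family, T).

    Returns a DataFrame with one row per supported combination (kite only
    at T=3; unsupported rows are kept with a ``note`` and NaN thresholds).
    Within the triangular and rhombic families both thresholds decrease
    with capsid size T.
    """
    import pandas as pd

    rows = []
    run = 0
    for family in families:
        fam_T = [3] if family == "kite" else list(T_values)
        for T in fam_T:
            spec = _spec_for(family, T)
            if spec is None:
                rows.append({
                    "family": family, "T": T, "k0": FAMILY_COUNTS[family][1],
                    "V0": np.nan, "E0": np.nan, "f_T": np.nan, "f_T_se": np.nan,
                    "f_T_e": np.nan, "f_T_e_se": np.nan,
                    "note": f"unsupported combination ({family}, T={T})",
                })
                continue
            g = capsid_network(spec)
            row = {
                "family": family, "T": T, "k0": g.k0,
                "V0": g.n_tiles, "E0": g.n_contacts, "note": "",
            }
            for mode, key in (("vertex", "f_T"), ("bond", "f_T_e")):
                est, _ = estimate_fragmentation_threshold(
                    g, mode=mode, replicates=replicates,
                    seed=seed + 1000 * run, coarse_replicates=coarse_replicates,
                    window=window,
                )
                row[key] = est.threshold
                row[f"{key}_se"] = est.se
                run += 1
                if progress is not None:
                    progress(f"{family} T={T} {est}")
            rows.append(row)
    return pd.DataFrame(rows)


def _spec_for(family: str, T: int) -> TilingSpec | None:
    """TilingSpec for a (family, T) pair, or None when unsupported."""
    hk = _hk_for_T(T)
    if hk is None:
        return None
    try:
        return TilingSpec(family, *hk)
    except ValueError:
        return None


def _hk_for_T(T: int) -> tuple[int, int] | None:
    for h in range(int(math.isqrt(T)) + 1, 0, -1):
        for k in range(0, h + 1):
            if h * h + h * k + k * k == T:
                return (h, k)
    return None
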