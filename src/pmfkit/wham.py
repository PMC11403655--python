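"""Self-consistent WHAM unbiasing and PMF construction.

Umbrella sampling restrains the reaction coordinate xi near a ladder of
centers xi_i with harmonic biases w_i(xi) = K/2 (xi - xi_i)^2.  The weighted
histogram analysis method (WHAM) combines the biased window histograms into
one unbiased probability distribution P(xi) by iterating the coupled
equations

    P(xi_b) = sum_i c_i(b) / sum_i n_i exp(beta [F_i - w_i(xi_b)])
    F_i     = -kT ln sum_b P(xi_b) exp(-beta w_i(xi_b))

to a fixed point, where c_i(b) are window i's bin counts, n_i its total
count, and F_i the free-energy shift the bias induces on window i.

The PMF follows as W(xi) = -kT ln P(xi) (+ an entropic correction when xi is
a radial distance coordinate), shifted so the profile averages to zero over
a declared large-separation plateau.  For a radial coordinate the sampling
volume grows as xi^2, so a non-interacting pair has P(xi) proportional to
xi^2; the correction +2 kT ln(xi) removes exactly this trend, and its sign
is pinned by that flat-free-particle contract.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import KB, kt
from .geometry import TimeSeries

__all__ = [
    "UmbrellaWindow",
    "BinGrid",
    "HistogramSet",
    "WhamSolution",
    "PmfProfile",
    "AnalysisOptions",
    "harmonic_bias",
    "build_histograms",
    "solve_wham",
    "jacobian_correction",
    "pmf_from_solution",
    "analyze_windows",
]


@dataclass(frozen=True)
class UmbrellaWindow:
    """One restrained window: id, restraint center (nm), spring constant
    (kJ mol^-1 nm^-2) and the sampled xi time series.

    A zero spring constant is allowed and means an unbiased window
    (the Boltzmann-inversion limit).
    """

    id: str
    center: float
    k: float
    samples: TimeSeries

    def __post_init__(self) -> None:
        if self.k < 0:
            raise ValueError(f"window {self.id}: spring constant must be >= 0")
        if not np.isfinite(self.center):
            raise ValueError(f"window {self.id}: non-finite center")


@dataclass(frozen=True)
class BinGrid:
    """Uniform bin grid along xi (nm)."""

    edges: np.ndarray

    def __post_init__(self) -> None:
        edges = np.asarray(self.edges, dtype=float)
        if edges.ndim != 1 or edges.size < 2:
            raise ValueError("grid needs at least 2 edges")
        widths = np.diff(edges)
        if not np.all(widths > 0):
            raise ValueError("edges must be strictly increasing")
        if not np.allclose(widths, widths[0], rtol=1e-9):
            raise ValueError("grid must be uniform")
        object.__setattr__(self, "edges", edges)

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def width(self) -> float:
        return float(self.edges[1] - self.edges[0])

    @property
    def n_bins(self) -> int:
        return self.edges.size - 1


@dataclass(frozen=True)
class HistogramSet:
    """Per-window biased histograms on a shared grid.

    counts is (n_windows, n_bins); n_i are the per-window totals after
    burn-in removal.  Row sums equal n_i by construction.
    """

    grid: BinGrid
    counts: np.ndarray
    window_ids: tuple[str, ...]

    @property
    def n_i(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total_counts(self) -> np.ndarray:
        return self.counts.sum(axis=0)


@dataclass(frozen=True)
class WhamSolution:
    """Converged (or best-effort) WHAM output.

    p is the unbiased probability per bin, normalized over occupied bins
    (zero on empty bins); f_i are the window shifts in kJ/mol with the
    gauge F_0 = 0.
    """

    grid: BinGrid
    p: np.ndarray
    f_i: np.ndarray
    temperature: float
    iterations: int
    converged: bool
    residual: float


@dataclass(frozen=True)
class PmfProfile:
    """Free energy W(xi) in kJ/mol on bin centers; NaN on unoccupied bins.

    shift_c is the constant subtracted so that W averages to zero over
    plateau_region; plateau_region is None for an unshifted profile.
    """

    xi: np.ndarray
    w: np.ndarray
    temperature: float
    error: np.ndarray | None = None
    shift_c: float = 0.0
    correction_applied: bool = False
    plateau_region: tuple[float, float] | None = None

    @property
    def is_shifted(self) -> bool:
        return self.plateau_region is not None

    @property
    def occupied(self) -> np.ndarray:
        return np.isfinite(self.w)

    def to_tsv(self, path) -> None:
        err = self.error if self.error is not None else np.full_like(self.w, np.nan)
        pd.DataFrame(
            {"xi_nm": self.xi, "W_kJ_mol": self.w, "err_kJ_mol": err}
        ).to_csv(path, sep="\t", index=False, na_rep="nan")

    @classmethod
    def from_tsv(cls, path, temperature: float = 310.0,
                 plateau_region: tuple[float, float] | None = None) -> "PmfProfile":
        df = pd.read_csv(path, sep="\t")
        err = df["err_kJ_mol"].to_numpy()
        return cls(
            xi=df["xi_nm"].to_numpy(),
            w=df["W_kJ_mol"].to_numpy(),
            temperature=temperature,
            error=None if np.all(np.isnan(err)) else err,
            plateau_region=plateau_region,
        )


def harmonic_bias(xi, window: UmbrellaWindow):
    """Harmonic restraint energy w_i(xi) = K/2 (xi - xi_i)^2 in kJ/mol."""
    return _bias_energy(np.asarray(xi, dtype=float), window.center, window.k)


def _bias_energy(xi, center: float, k: float):
    return 0.5 * k * (xi - center) ** 2


def build_histograms(
    windows: Sequence[UmbrellaWindow],
    bin_width: float = 0.01,
    burn_in_fraction: float = 0.1,
) -> HistogramSet:
    """Histogram every window's post-burn-in samples on one shared grid.

    The grid is anchored at integer multiples of bin_width so that the
    binning of a sample does not depend on which other windows are present.
    Samples falling exactly on an interior edge land in the upper bin
    (numpy half-open convention).
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if not windows:
        raise ValueError("need at least one window")
    trimmed = []
    for win in windows:
        series = win.samples.discard_burn_in(burn_in_fraction)
        if len(series) == 0:
            raise ValueError(f"window {win.id}: no samples after burn-in")
        trimmed.append(series.values)
    lo = min(v.min() for v in trimmed)
    hi = max(v.max() for v in trimmed)
    start = np.floor(lo / bin_width) * bin_width
    n_bins = int(np.ceil((hi - start) / bin_width))
    if hi >= start + n_bins * bin_width:  # guard against roundoff at the top edge
        n_bins += 1
    edges = start + bin_width * np.arange(n_bins + 1)
    grid = BinGrid(edges)
    counts = np.empty((len(windows), n_bins), dtype=np.int64)
    for row, v in enumerate(trimmed):
        counts[row], _ = np.histogram(v, bins=edges)
        if counts[row].sum() != v.size:
            raise AssertionError("histogram lost counts")  # pragma: no cover
    return HistogramSet(grid, counts, tuple(w.id for w in windows))


def _check_connected(counts: np.ndarray) -> None:
    """Raise if the occupied bins split into blocks no window bridges."""
    total = counts.sum(axis=0)
    occupied = total > 0
    # label contiguous blocks of occupied bins
    block = -np.ones(occupied.size, dtype=int)
    current = -1
    prev = False
    for b, occ in enumerate(occupied):
        if occ and not prev:
            current += 1
        if occ:
            block[b] = current
        prev = occ
    n_blocks = current + 1
    if n_blocks <= 1:
        return
    parent = list(range(n_blocks))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for row in counts:
        touched = np.unique(block[row > 0])
        for other in touched[1:]:
            ra, rb = find(int(touched[0])), find(int(other))
            parent[rb] = ra
    roots = {find(i) for i in range(n_blocks)}
    if len(roots) > 1:
        raise ValueError(
            f"histogram support is disconnected: {len(roots)} regions with no "
            "window overlap between them; add intermediate windows"
        )


def solve_wham(
    hist: HistogramSet,
    windows: Sequence[UmbrellaWindow],
    temperature: float = 310.0,
    tol: float = 1e-5,
    max_iter: int = 100_000,
    omega: float = 1.0,
    f_init: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> WhamSolution:
    """Iterate the WHAM equations to self-consistency.

    Parameters
    ----------
    hist : HistogramSet
        Per-window histograms on a shared grid (rows aligned with windows).
    windows : sequence of UmbrellaWindow
        Supplies restraint centers and spring constants.
    temperature : float
        K; sets beta = 1/(k_B T).
    tol : float
        Convergence threshold on max_i |delta F_i| in kJ/mol.
    max_iter : int
        Iteration cap; non-convergence returns converged=False with a warning.
    omega : float
        Over-relaxation factor on the F_i update (1.0 = plain iteration).
    f_init : array, optional
        Warm-start F_i values in kJ/mol (e.g. from a previous solve).
    weights : array, optional
        Non-negative per-window multipliers on counts and n_i (used by the
        Bayesian bootstrap); zero-weight windows drop out.

    Notes
    -----
    Computations run in log space with a max-shift, so that in the unbiased
    single-window limit P reduces bitwise to the normalized raw histogram.
    """
    beta = 1.0 / kt(temperature)
    if len(windows) != hist.counts.shape[0]:
        raise ValueError("windows and histogram rows do not match")
    counts = np.asarray(hist.counts, dtype=float)
    if weights is not None:
        weights = np.asarray(weights, dtype=float)
        if weights.shape != (counts.shape[0],) or np.any(weights < 0):
            raise ValueError("weights must be non-negative, one per window")
        counts = counts * weights[:, None]
    active = counts.sum(axis=1) > 0
    if not np.any(active):
        raise ValueError("no counts in any window")
    _check_connected(counts[active])

    centers = hist.grid.centers
    total = counts.sum(axis=0)
    occ = total > 0
    xi_occ = centers[occ]
    n_i = counts[active].sum(axis=1)
    bias = np.array(
        [_bias_energy(xi_occ, w.center, w.k) for w, a in zip(windows, active) if a]
    )  # (n_active, n_occ)
    # bias Boltzmann factors; underflow to 0 is benign (bin unreachable by
    # that window), but a window reaching no occupied bin at all is an error
    with np.errstate(under="ignore"):
        bias_factor = np.exp(-beta * bias)
    if np.any(bias_factor.max(axis=1) == 0.0):
        bad = [w.id for w, a in zip(windows, active) if a][
            int(np.argmax(bias_factor.max(axis=1) == 0.0))
        ]
        raise ValueError(f"window {bad}: bias reaches no occupied bin")

    g = np.zeros(len(n_i))  # beta * F_i
    if f_init is not None:
        f_init = np.asarray(f_init, dtype=float)
        g = beta * (f_init[active] - f_init[active][0])

    total_occ = total[occ]
    p_occ = np.empty_like(total_occ)
    iterations = 0
    residual = np.inf
    converged = False
    for iterations in range(1, max_iter + 1):
        denom = (n_i * np.exp(g)) @ bias_factor  # per occupied bin
        denom = denom / denom.min()
        p_occ = total_occ / denom
        p_occ /= p_occ.sum()
        g_new = -np.log(bias_factor @ p_occ)
        g_new -= g_new[0]
        residual = float(np.max(np.abs(g_new - g)) / beta)
        if omega != 1.0:
            g = g + omega * (g_new - g)
            g -= g[0]
        else:
            g = g_new
        if residual < tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"WHAM did not converge in {max_iter} iterations "
            f"(residual {residual:.3g} kJ/mol > tol {tol:g})",
            RuntimeWarning,
        )
    p = np.zeros(hist.grid.n_bins)
    p[occ] = p_occ
    f_full = np.zeros(len(windows))
    f_full[active] = g / beta
    return WhamSolution(
        grid=hist.grid,
        p=p,
        f_i=f_full,
        temperature=temperature,
        iterations=iterations,
        converged=converged,
        residual=residual,
    )


def jacobian_correction(xi, temperature: float):
    """Entropic correction +2 kT ln(xi) for a radial distance coordinate.

    Added to -kT ln P(xi), it yields a flat profile for a non-interacting
    pair, whose sampling volume (hence P) grows as xi^2.  Vanishes at
    xi = 1 nm.  Raises for xi <= 0.
    """
    xi = np.asarray(xi, dtype=float)
    if np.any(xi <= 0):
        raise ValueError("jacobian correction undefined for xi <= 0")
    result = 2.0 * kt(temperature) * np.log(xi)
    return float(result) if result.ndim == 0 else result


def pmf_from_solution(
    sol: WhamSolution,
    apply_correction: bool = False,
    plateau_region: tuple[float, float] | None = None,
) -> PmfProfile:
    """Build W(xi) = -kT ln P(xi) (+ radial correction), plateau-zeroed.

    Empty bins get NaN.  When plateau_region = (lo, hi) is given, every bin
    with center in [lo, hi] must be occupied; the mean of W over those bins
    defines the shift constant C subtracted from the whole profile.
    """
    centers = sol.grid.centers
    ktemp = kt(sol.temperature)
    w = np.full(sol.p.size, np.nan)
    occ = sol.p > 0
    w[occ] = -ktemp * np.log(sol.p[occ])
    if apply_correction:
        w[occ] += jacobian_correction(centers[occ], sol.temperature)
    shift_c = 0.0
    if plateau_region is not None:
        lo, hi = plateau_region
        if not lo < hi:
            raise ValueError("plateau region must satisfy lo < hi")
        in_plateau = (centers >= lo) & (centers <= hi)
        if not np.any(in_plateau):
            raise ValueError(f"plateau region [{lo}, {hi}] contains no bins")
        if np.any(~occ & in_plateau):
            raise ValueError(
                f"plateau region [{lo}, {hi}] contains empty bins; "
                "extend sampling or shrink the region"
            )
        shift_c = float(np.mean(w[in_plateau]))
        w = w - shift_c
    return PmfProfile(
        xi=centers,
        w=w,
        temperature=sol.temperature,
        shift_c=shift_c,
        correction_applied=apply_correction,
        plateau_region=plateau_region,
    )


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs for the histogram/WHAM/PMF stage.

    bin_width resolves the 0.05 nm window spacing five-fold by default;
    burn_in_fraction discards residual equilibration at the head of each
    window; tol and max_iter control the self-consistency loop.
    """

    temperature: float = 310.0
    bin_width: float = 0.01
    burn_in_fraction: float = 0.1
    tol: float = 1e-5
    max_iter: int = 100_000
    omega: float = 1.0
    apply_correction: bool = False
    plateau_region: tuple[float, float] | None = None


def analyze_windows(
    windows: Sequence[UmbrellaWindow],
    options: AnalysisOptions = AnalysisOptions(),
    f_init: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> tuple[HistogramSet, WhamSolution, PmfProfile]:
    """Histogram -> WHAM -> plateau-zeroed PMF in one call."""
    hist = build_histograms(windows, options.bin_width, options.burn_in_fraction)
    sol = solve_wham(
        hist,
        windows,
        temperature=options.temperature,
        tol=options.tol,
        max_iter=options.max_iter,
        omega=options.omega,
        f_init=f_init,
        weights=weights,
    )
    profile = pmf_from_solution(
        sol,
        apply_correction=options.apply_correction,
        plateau_region=options.plateau_region,
    )
    return hist, sol, profile
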