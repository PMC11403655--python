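"""Binding free energies and well structure of a PMF.

With the profile zeroed at the large-separation plateau, the depth of the
global minimum is the dimerization (binding) free energy relative to the
separated pair; no standard-state volume correction is applied, and that
convention is recorded in the report.  Wells are located as local minima
with a prominence threshold (default 1 kJ/mol, below half k_B T at 310 K
such features would be noise): the smallest-xi well is the contact pair,
the next the solvent-separated pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .constants import kt
from .wham import PmfProfile

__all__ = [
    "PmfFeatures",
    "ProfileComparison",
    "binding_free_energy",
    "find_minima",
    "extract_features",
    "compare_profiles",
]


@dataclass(frozen=True)
class PmfFeatures:
    """Well structure of a plateau-zeroed PMF."""

    dg_bind: float  # kJ/mol, depth of the global minimum
    minima: tuple[tuple[float, float], ...]  # (xi nm, depth kJ/mol), sorted by xi
    barriers: tuple[float, ...]  # kJ/mol between consecutive minima
    binding: bool  # False when no thermally significant well exists

    @property
    def contact_minimum(self) -> tuple[float, float] | None:
        return self.minima[0] if self.minima else None

    @property
    def solvent_separated_minimum(self) -> tuple[float, float] | None:
        return self.minima[1] if len(self.minima) > 1 else None


def _require_shifted(profile: PmfProfile) -> None:
    if not profile.is_shifted:
        raise ValueError(
            "profile must be plateau-zeroed first (no plateau region recorded)"
        )


def binding_free_energy(profile: PmfProfile) -> float:
    """Depth of the global minimum of a plateau-zeroed PMF, kJ/mol.

    By the zero-at-plateau convention this is the free energy of the bound
    pair relative to the separated pair.
    """
    _require_shifted(profile)
    occupied = profile.occupied
    if not np.any(occupied):
        raise ValueError("profile has no occupied bins")
    return float(np.min(profile.w[occupied]))


def _refine_minimum(xi: np.ndarray, w: np.ndarray, idx: int,
                    half: int = 10) -> tuple[float, float]:
    """Parabolic vertex fit around a grid minimum.

    A least-squares quadratic over +-half bins suppresses the bin-level
    noise jitter of the raw argmin; falls back to the grid point when the
    fit is not convex or the window is too short.
    """
    lo, hi = max(0, idx - half), min(len(w), idx + half + 1)
    x, y = xi[lo:hi], w[lo:hi]
    mask = np.isfinite(y)
    if mask.sum() < 4:
        return float(xi[idx]), float(w[idx])
    coeff = np.polyfit(x[mask], y[mask], 2)
    if coeff[0] <= 0:
        return float(xi[idx]), float(w[idx])
    vertex = -coeff[1] / (2 * coeff[0])
    if not x[mask][0] <= vertex <= x[mask][-1]:
        return float(xi[idx]), float(w[idx])
    return float(vertex), float(np.polyval(coeff, vertex))


def find_minima(
    profile: PmfProfile, min_prominence: float = 1.0, refine: bool = True
) -> list[tuple[float, float]]:
    """Local minima of W with at least `min_prominence` kJ/mol prominence.

    Returns (xi, depth) sorted by xi; empty for monotone profiles.  Only the
    contiguous occupied region containing each minimum is considered.  With
    refine=True (default) positions and depths come from a local parabolic
    fit rather than the raw grid argmin.
    """
    xi, w = profile.xi, profile.w
    finite = np.isfinite(w)
    minima: list[tuple[float, float]] = []
    # process each contiguous occupied stretch separately
    boundaries = np.flatnonzero(np.diff(finite.astype(int)))
    starts = [0] + (boundaries + 1).tolist()
    for start in starts:
        if not finite[start:].any():
            break
        stop = start
        while stop < len(w) and finite[stop]:
            stop += 1
        if stop - start < 3:
            continue
        seg = w[start:stop]
        peaks, _ = find_peaks(-seg, prominence=min_prominence)
        for p in peaks:
            if refine:
                minima.append(_refine_minimum(xi[start:stop], seg, int(p)))
            else:
                minima.append((float(xi[start + p]), float(seg[p])))
    return sorted(minima)


def extract_features(
    profile: PmfProfile,
    min_prominence: float = 1.0,
    binding_threshold: float | None = None,
) -> PmfFeatures:
    """Binding free energy, wells and inter-well barriers of a profile.

    A profile with dg_bind above -k_B T (or `binding_threshold` if given)
    has no thermally significant well and is flagged non-binding.
    """
    _require_shifted(profile)
    dg = binding_free_energy(profile)
    minima = tuple(find_minima(profile, min_prominence))
    threshold = (
        binding_threshold
        if binding_threshold is not None
        else -kt(profile.temperature)
    )
    barriers = []
    for (xi_a, _), (xi_b, _) in zip(minima, minima[1:]):
        between = (profile.xi > xi_a) & (profile.xi < xi_b) & profile.occupied
        barriers.append(float(np.max(profile.w[between])) if between.any() else np.nan)
    return PmfFeatures(
        dg_bind=dg,
        minima=minima,
        barriers=tuple(barriers),
        binding=dg < threshold,
    )


@dataclass(frozen=True)
class ProfileComparison:
    """Reference-vs-treated PMF comparison."""

    ddg: float  # kJ/mol, dg_treated - dg_reference
    dg_reference: float
    dg_treated: float
    classification: str  # "favorable" | "unfavorable" | "marginal"
    minima_reference: tuple[tuple[float, float], ...]
    minima_treated: tuple[tuple[float, float], ...]


def compare_profiles(
    reference: PmfProfile,
    treated: PmfProfile,
    min_prominence: float = 1.0,
) -> ProfileComparison:
    """Compare a treated (e.g. drugged) profile against a reference.

    The treated profile is interpolated onto the reference grid over their
    overlapping xi range.  Binding in the treated system is classified
    "favorable" when dg_treated < -k_B T, "unfavorable" when
    dg_treated > -k_B T, and "marginal" within 0.1 k_B T of the cutoff.
    """
    _require_shifted(reference)
    _require_shifted(treated)
    ref_occ = reference.occupied
    trt_occ = treated.occupied
    lo = max(reference.xi[ref_occ].min(), treated.xi[trt_occ].min())
    hi = min(reference.xi[ref_occ].max(), treated.xi[trt_occ].max())
    if lo >= hi:
        raise ValueError("profiles have no overlapping occupied xi range")
    mask = ref_occ & (reference.xi >= lo) & (reference.xi <= hi)
    treated_interp = np.interp(
        reference.xi[mask], treated.xi[trt_occ], treated.w[trt_occ]
    )
    dg_ref = float(np.min(reference.w[mask]))
    dg_trt = float(np.min(treated_interp))
    ktemp = kt(reference.temperature)
    if abs(dg_trt + ktemp) < 0.1 * ktemp:
        classification = "marginal"
    elif dg_trt < -ktemp:
        classification = "favorable"
    else:
        classification = "unfavorable"
    return ProfileComparison(
        ddg=dg_trt - dg_ref,
        dg_reference=dg_ref,
        dg_treated=dg_trt,
        classification=classification,
        minima_reference=tuple(find_minima(reference, min_prominence)),
        minima_treated=tuple(find_minima(treated, min_prominence)),
    )
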