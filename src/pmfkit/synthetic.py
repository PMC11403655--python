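"""Synthetic umbrella-sampling experiments with analytic ground truth.

Running the actual MD is out of scope here; what WHAM consumes is only the
stationary distribution of xi in each biased window.  This module therefore
generates window time series by Metropolis sampling from analytically known
free-energy surfaces W(xi), so every downstream stage (WHAM, PMF, errors,
binding features) can be tested against ground truth.

Two coordinate conventions are supported, mirroring the analysis side:

* ``linear``: the stationary density in a window is proportional to
  exp(-beta [W(xi) + w_i(xi)]).
* ``radial``: an extra xi^2 volume factor multiplies the density, exactly
  the factor the Jacobian entropic correction removes during analysis.

The default experiment emulates the published setup: 80 windows spaced
0.05 nm apart, a 1000 kJ mol^-1 nm^-2 spring constant, 310 K, and a dimer
surface with a contact minimum near 0.5 nm, a shallow solvent-separated
minimum near 1.2 nm, and a flat plateau beyond 2.5 nm.  Labeled
ligand-pocket distance traces emulate pocket abandonment: an
Ornstein-Uhlenbeck fluctuation about the bound level that, in flagged
windows, switches to the unbound level at a set time and stays there.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from .constants import kt
from .geometry import TimeSeries
from .io import WindowMeta, write_window_metadata, write_window_series
from .occupancy import DistanceTrace
from .wham import UmbrellaWindow

__all__ = [
    "SyntheticSurface",
    "GeneratorConfig",
    "AbandonmentSpec",
    "Experiment",
    "make_dimer_surface",
    "flat_surface",
    "sample_window",
    "generate_experiment",
    "make_distance_traces",
]


@dataclass(frozen=True)
class SyntheticSurface:
    """An analytic free-energy surface W(xi) in kJ/mol on a finite support.

    kind is "linear" or "radial"; radial surfaces carry the xi^2 sampling
    volume factor in their stationary density.
    """

    kind: str
    w: Callable[[np.ndarray], np.ndarray]
    support: tuple[float, float]
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("linear", "radial"):
            raise ValueError(f"kind must be 'linear' or 'radial', got {self.kind!r}")
        lo, hi = self.support
        if not lo < hi:
            raise ValueError("support must satisfy lo < hi")
        if self.kind == "radial" and lo <= 0:
            raise ValueError("radial surfaces need support with lo > 0")
        probe = self.w(np.linspace(lo, hi, 64))
        if not np.all(np.isfinite(probe)):
            raise ValueError("W must be finite on the support")


def _gaussian(xi, center, sigma):
    return np.exp(-0.5 * ((xi - center) / sigma) ** 2)


def make_dimer_surface(
    depth_contact: float = -32.0,
    xi_contact: float = 0.5,
    depth_solventsep: float = -4.0,
    xi_solventsep: float = 1.2,
    barrier: float = -1.0,
    plateau_onset: float = 2.5,
    support: tuple[float, float] = (0.3, 4.3),
    kind: str = "radial",
) -> SyntheticSurface:
    """Double-well dimerization surface with an exact flat plateau.

    Three Gaussians (contact well, inter-well barrier, solvent-separated
    well) have their amplitudes solved from a 3x3 linear system so that
    W(xi_contact) = depth_contact, W at the inter-well midpoint equals
    `barrier`, and W(xi_solventsep) = depth_solventsep, cross-terms
    included.  A cosine taper then forces W identically to zero beyond
    plateau_onset, emulating the large-separation plateau against which
    the profile is zeroed.

    Defaults mirror the dimer case this package targets: a -32 kJ/mol
    contact minimum at 0.5 nm, a shallow solvent-separated minimum at
    1.2 nm, and a plateau from 2.5 nm on.
    """
    if not xi_contact < xi_solventsep < plateau_onset:
        raise ValueError(
            "need xi_contact < xi_solventsep < plateau_onset, got "
            f"{xi_contact}, {xi_solventsep}, {plateau_onset}"
        )
    if depth_contact > 0 or depth_solventsep > 0:
        raise ValueError("well depths must be <= 0")
    gap = xi_solventsep - xi_contact
    xi_barrier = 0.5 * (xi_contact + xi_solventsep)
    sigmas = (0.22 * gap, 0.16 * gap, 0.30 * gap)
    nodes = (xi_contact, xi_barrier, xi_solventsep)
    design = np.array(
        [[_gaussian(x, c, s) for c, s in zip(nodes, sigmas)] for x in nodes]
    )
    amplitudes = np.linalg.solve(design, np.array(
        [depth_contact, barrier, depth_solventsep]
    ))
    taper_start = xi_solventsep + 0.6 * (plateau_onset - xi_solventsep)
    amps = tuple(float(a) for a in amplitudes)

    def _w_scalar(x: float) -> float:
        raw = sum(
            a * math.exp(-0.5 * ((x - c) / s) ** 2)
            for a, c, s in zip(amps, nodes, sigmas)
        )
        if x >= plateau_onset:
            return 0.0
        if x > taper_start:
            raw *= 0.5 * (1.0 + math.cos(
                math.pi * (x - taper_start) / (plateau_onset - taper_start)
            ))
        return raw

    def w(xi):
        if np.ndim(xi) == 0:
            return _w_scalar(float(xi))
        xi = np.asarray(xi, dtype=float)
        raw = sum(
            a * _gaussian(xi, c, s) for a, c, s in zip(amps, nodes, sigmas)
        )
        ramp = (xi > taper_start) & (xi < plateau_onset)
        taper = np.where(
            ramp,
            0.5 * (1.0 + np.cos(np.pi * (xi - taper_start)
                                / (plateau_onset - taper_start))),
            1.0,
        )
        taper = np.where(xi >= plateau_onset, 0.0, taper)
        return raw * taper

    return SyntheticSurface(
        kind=kind,
        w=w,
        support=support,
        params={
            "depth_contact": depth_contact,
            "xi_contact": xi_contact,
            "depth_solventsep": depth_solventsep,
            "xi_solventsep": xi_solventsep,
            "barrier": barrier,
            "plateau_onset": plateau_onset,
        },
    )


def flat_surface(kind: str = "linear",
                 support: tuple[float, float] = (0.3, 4.3)) -> SyntheticSurface:
    """W identically zero: a free particle on the chosen coordinate."""

    def w(xi):
        if np.ndim(xi) == 0:
            return 0.0
        return np.zeros_like(np.asarray(xi, dtype=float))

    return SyntheticSurface(kind=kind, w=w, support=support, params={"flat": True})


def _log_target(surface: SyntheticSurface, center: float, k: float,
                beta: float) -> Callable[[float], float]:
    radial = surface.kind == "radial"

    def logp(x: float) -> float:
        value = -beta * (float(surface.w(x)) + 0.5 * k * (x - center) ** 2)
        if radial:
            value += 2.0 * math.log(x)
        return value

    return logp


def _target_moments(surface, center, k, beta, n_grid=2048):
    lo, hi = surface.support
    grid = np.linspace(lo, hi, n_grid)
    logw = -beta * (surface.w(grid) + 0.5 * k * (grid - center) ** 2)
    if surface.kind == "radial":
        logw = logw + 2.0 * np.log(grid)
    logw = logw - logw.max()
    dens = np.exp(logw)
    dens /= np.trapezoid(dens, grid)
    mean = np.trapezoid(grid * dens, grid)
    var = np.trapezoid((grid - mean) ** 2 * dens, grid)
    mode = float(grid[np.argmax(dens)])
    return mode, float(np.sqrt(max(var, 1e-12)))


def sample_window(
    surface: SyntheticSurface,
    center: float,
    k: float,
    temperature: float = 310.0,
    n: int = 5000,
    correlation_time: float = 1.0,
    seed=0,
    dt_ps: float = 1.0,
    burn_in_fraction: float = 0.1,
) -> TimeSeries:
    """Metropolis-sample xi from one biased window.

    The chain targets exp(-beta [W(xi) + K/2 (xi - center)^2]) (times xi^2
    for radial surfaces) on the surface's support.  The Gaussian proposal
    width is tuned from the target's standard deviation (step ~ 2.4 sigma,
    roughly 40% acceptance), giving a raw-chain integrated autocorrelation
    of a few steps.  `correlation_time` sets the autocorrelation scale of
    the *recorded* series, emulating the frame-to-frame correlation of MD:
    below the raw-chain scale the chain is thinned, above it the proposal
    step is shrunk so successive recorded samples correlate over
    approximately that many steps.  The first `burn_in_fraction` of the
    chain (run in addition to the n recorded steps) is discarded, and the
    start point is the target mode, so recorded samples are equilibrated.
    Identical seeds give bit-identical series.
    """
    lo, hi = surface.support
    if not lo <= center <= hi:
        raise ValueError(f"window center {center} outside support [{lo}, {hi}]")
    if n < 1:
        raise ValueError("need n >= 1 samples")
    if k < 0:
        raise ValueError("spring constant must be >= 0")
    beta = 1.0 / kt(temperature)
    logp = _log_target(surface, center, k, beta)
    mode, sigma = _target_moments(surface, center, k, beta)
    tau = max(float(correlation_time), 1.0)
    # a tuned random-walk chain decorrelates over ~RAW_IAT raw steps
    RAW_IAT = 6.0
    if tau < RAW_IAT:
        stride = int(round(RAW_IAT / tau))
        step = 2.4 * sigma
    else:
        stride = 1
        step = 2.4 * sigma * np.sqrt(RAW_IAT / tau)
    step = min(step, 0.5 * (hi - lo))

    burn = int(np.ceil(n * burn_in_fraction / (1.0 - burn_in_fraction)))
    total = (n + burn) * stride
    rng = np.random.default_rng(seed)
    increments = rng.normal(0.0, step, size=total)
    log_u = np.log(rng.random(total))
    x = mode
    lp = logp(x)
    out = np.empty(total)
    for i in range(total):
        prop = x + increments[i]
        if lo <= prop <= hi:
            lp_prop = logp(prop)
            if log_u[i] < lp_prop - lp:
                x, lp = prop, lp_prop
        out[i] = x
    values = out[(burn * stride)::stride][:n] if stride > 1 else out[burn:]
    times = dt_ps * np.arange(n, dtype=float)
    return TimeSeries(times, values)


@dataclass(frozen=True)
class GeneratorConfig:
    """Umbrella-experiment layout and sampling settings.

    Defaults emulate the target setup: 80 windows, 0.05 nm spacing,
    K = 1000 kJ mol^-1 nm^-2, 310 K.  xi_start of None places the first
    window center at the surface's support minimum.
    """

    n_windows: int = 80
    spacing: float = 0.05
    k: float = 1000.0
    temperature: float = 310.0
    samples_per_window: int = 5000
    correlation_time: float = 1.0
    seed: int = 0
    xi_start: float | None = None
    dt_ps: float = 1.0

    def __post_init__(self) -> None:
        if self.n_windows < 1 or self.samples_per_window < 0:
            raise ValueError("n_windows must be >= 1, samples_per_window >= 0")
        if self.spacing <= 0 or self.k < 0 or self.temperature <= 0:
            raise ValueError("spacing, temperature must be positive; k >= 0")
        if self.samples_per_window == 0:
            raise ValueError("samples_per_window must be >= 1")


@dataclass(frozen=True)
class Experiment:
    """A generated window set plus its ground truth."""

    windows: tuple[UmbrellaWindow, ...]
    metadata: tuple[WindowMeta, ...]
    surface: SyntheticSurface
    config: GeneratorConfig


def generate_experiment(
    surface: SyntheticSurface,
    config: GeneratorConfig = GeneratorConfig(),
    out_dir: str | Path | None = None,
) -> Experiment:
    """Sample every window of an umbrella experiment from `surface`.

    Window centers sit at xi_start + spacing * i and must all lie inside the
    surface support.  Per-window seeds are spawned deterministically from
    config.seed.  When out_dir is given, window series (xvg dialect),
    the metadata TSV and a JSON manifest (surface parameters, config, seed)
    are written there.
    """
    lo, hi = surface.support
    start = config.xi_start if config.xi_start is not None else lo
    centers = start + config.spacing * np.arange(config.n_windows)
    if centers[0] < lo or centers[-1] > hi:
        raise ValueError(
            f"window centers [{centers[0]:.3f}, {centers[-1]:.3f}] exceed "
            f"surface support [{lo}, {hi}]"
        )
    children = np.random.SeedSequence(config.seed).spawn(config.n_windows)
    windows = []
    metadata = []
    for i, (center, child) in enumerate(zip(centers, children)):
        wid = f"w{i:03d}"
        series = sample_window(
            surface,
            center=float(center),
            k=config.k,
            temperature=config.temperature,
            n=config.samples_per_window,
            correlation_time=config.correlation_time,
            seed=child,
            dt_ps=config.dt_ps,
        )
        windows.append(UmbrellaWindow(wid, float(center), config.k, series))
        metadata.append(WindowMeta(wid, float(center), config.k))
    experiment = Experiment(tuple(windows), tuple(metadata), surface, config)
    if out_dir is not None:
        _write_experiment(experiment, Path(out_dir))
    return experiment


def _write_experiment(experiment: Experiment, out_dir: Path) -> None:
    windows_dir = out_dir / "windows"
    windows_dir.mkdir(parents=True, exist_ok=True)
    for window in experiment.windows:
        write_window_series(
            windows_dir / f"{window.id}.xvg",
            window.samples,
            comment=f"window {window.id} center {window.center} nm",
        )
    write_window_metadata(out_dir / "metadata.tsv", experiment.metadata)
    manifest = {
        "surface": {
            "kind": experiment.surface.kind,
            "support": list(experiment.surface.support),
            "params": experiment.surface.params,
        },
        "config": asdict(experiment.config),
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))


@dataclass(frozen=True)
class AbandonmentSpec:
    """Ground truth for labeled pocket-abandonment distance traces.

    Traces fluctuate about bound_level with an Ornstein-Uhlenbeck process
    (relaxation time tau_ps, stationary std sigma).  Windows flagged in
    `labels` switch their mean to unbound_level at their switch time and
    stay there.
    """

    labels: tuple[bool, ...]
    bound_level: float = 0.3  # nm
    unbound_level: float = 1.5  # nm
    switch_fraction: float = 0.5  # switch time as a fraction of the trace
    tau_ps: float = 50.0
    sigma: float = 0.05  # nm

    def __post_init__(self) -> None:
        if not self.bound_level < self.unbound_level:
            raise ValueError("bound_level must be below unbound_level")
        if not 0 < self.switch_fraction < 1:
            raise ValueError("switch_fraction must be in (0, 1)")
        if self.tau_ps <= 0 or self.sigma <= 0:
            raise ValueError("tau_ps and sigma must be positive")

    @classmethod
    def with_n_abandoned(cls, n_windows: int, n_abandoned: int,
                         **kwargs) -> "AbandonmentSpec":
        """Labels with n_abandoned True flags spread evenly over the windows."""
        if not 0 <= n_abandoned <= n_windows:
            raise ValueError("need 0 <= n_abandoned <= n_windows")
        labels = np.zeros(n_windows, dtype=bool)
        if n_abandoned:
            idx = np.round(np.linspace(0, n_windows - 1, n_abandoned)).astype(int)
            labels[idx] = True
        return cls(labels=tuple(bool(x) for x in labels), **kwargs)


def make_distance_traces(
    spec: AbandonmentSpec,
    n_samples: int = 1000,
    dt_ps: float = 10.0,
    seed: int = 0,
) -> list[DistanceTrace]:
    """Generate one labeled minimum-distance trace per window.

    Exact OU discretization: x_{k+1} = mu + (x_k - mu) a + sigma sqrt(1-a^2) z
    with a = exp(-dt/tau); mu jumps from bound_level to unbound_level at the
    switch time in labeled windows.  Distances are clipped at zero.
    """
    if n_samples < 2:
        raise ValueError("need at least 2 samples per trace")
    alpha = np.exp(-dt_ps / spec.tau_ps)
    noise_scale = spec.sigma * np.sqrt(1.0 - alpha**2)
    children = np.random.SeedSequence(seed).spawn(len(spec.labels))
    switch_index = int(round(spec.switch_fraction * n_samples))
    times = dt_ps * np.arange(n_samples, dtype=float)
    traces = []
    for i, (abandoned, child) in enumerate(zip(spec.labels, children)):
        rng = np.random.default_rng(child)
        z = rng.standard_normal(n_samples)
        mu = np.full(n_samples, spec.bound_level)
        if abandoned:
            mu[switch_index:] = spec.unbound_level
        x = np.empty(n_samples)
        x[0] = spec.bound_level + spec.sigma * z[0]
        for t in range(1, n_samples):
            x[t] = mu[t] + (x[t - 1] - mu[t]) * alpha + noise_scale * z[t]
        np.clip(x, 0.0, None, out=x)
        traces.append(DistanceTrace(f"w{i:03d}", TimeSeries(times, x)))
    return traces
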