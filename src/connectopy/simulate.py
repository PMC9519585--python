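"""Synthetic multi-run BOLD-like timeseries with a known 2-D topography.

The simulator stands in for retinotopic-mapping fMRI data: an ROI whose
vertices tile a rectangular grid of (eccentricity, polar angle) coordinates,
timeseries whose pairwise correlation decays smoothly with distance on that
grid, non-ROI sources that are mixtures of the same latent signals, and
matched-moment noise controls.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

__all__ = [
    "RetinotopicGrid",
    "SimulationConfig",
    "Timeseries",
    "make_retinotopic_grid",
    "simulate_roi_timeseries",
    "simulate_nonroi_timeseries",
    "noise_substitute",
    "split_odd_even",
    "percent_signal_change",
]

#: Baseline signal level added before percent-signal-change conversion,
#: in arbitrary scanner units.  Only its being large and positive matters.
BASELINE = 100.0


@dataclass(frozen=True)
class RetinotopicGrid:
    """ROI vertex set with ground-truth eccentricity / polar-angle coordinates.

    Vertices are ordered row-major over a ``(n_ecc, n_pol)`` grid.
    ``ecc`` is in degrees of visual angle (> 0), ``polar`` in radians within
    a single hemifield, so neither map wraps within the ROI.
    """

    ecc: np.ndarray
    polar: np.ndarray
    grid_shape: tuple[int, int]

    def __post_init__(self) -> None:
        ecc = np.asarray(self.ecc, dtype=float)
        polar = np.asarray(self.polar, dtype=float)
        object.__setattr__(self, "ecc", ecc)
        object.__setattr__(self, "polar", polar)
        n_ecc, n_pol = self.grid_shape
        if ecc.shape != (n_ecc * n_pol,) or polar.shape != (n_ecc * n_pol,):
            raise ValueError("coordinate vectors must have length n_ecc * n_pol")
        if not (np.isfinite(ecc).all() and np.isfinite(polar).all()):
            raise ValueError("grid coordinates must be finite")

    @property
    def vertex_count(self) -> int:
        return self.grid_shape[0] * self.grid_shape[1]

    def grid_coordinates(self) -> np.ndarray:
        """(N, 2) integer grid indices (ecc axis, polar axis), row-major."""
        n_ecc, n_pol = self.grid_shape
        ii, jj = np.meshgrid(np.arange(n_ecc), np.arange(n_pol), indexing="ij")
        return np.column_stack([ii.ravel(), jj.ravel()]).astype(float)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic ground-truth world.

    ``correlation_length`` is in grid-index units; ``manifold_curvature``
    bends the latent coordinate sheet into an arc (units 1/grid-index) so
    that chord distances fold and linear embeddings underperform.
    """

    grid_shape: tuple[int, int] = (12, 10)
    timepoints_per_run: int = 300
    n_runs: int = 4
    correlation_length: float = 1.5
    noise_sd: float = 0.5
    n_nonroi_sources: int = 650
    manifold_curvature: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.timepoints_per_run < 4:
            raise ValueError("timepoints_per_run must be >= 4")
        if self.n_runs < 2 or self.n_runs % 2 != 0:
            raise ValueError("n_runs must be even and >= 2 for odd/even splitting")
        if self.correlation_length <= 0:
            raise ValueError("correlation_length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.manifold_curvature < 0:
            raise ValueError("manifold_curvature must be >= 0")
        if self.n_nonroi_sources < 1:
            raise ValueError("n_nonroi_sources must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Timeseries:
    """Rows = vertices or sources, columns = timepoints; percent signal change.

    ``run_offsets`` delimits scan runs: strictly increasing, starting at 0
    and ending at the total number of timepoints.
    """

    data: np.ndarray
    run_offsets: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (rows x timepoints)")
        if not np.isfinite(self.data).all():
            raise ValueError("timeseries contains NaN or Inf")
        t_total = self.data.shape[1]
        offs = list(self.run_offsets) if self.run_offsets else [0, t_total]
        if offs[0] != 0 or offs[-1] != t_total or any(
            b <= a for a, b in zip(offs, offs[1:])
        ):
            raise ValueError(
                "run_offsets must be strictly increasing from 0 to n_timepoints"
            )
        self.run_offsets = offs

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[1]

    @property
    def n_runs(self) -> int:
        return len(self.run_offsets) - 1

    def runs(self) -> list[np.ndarray]:
        """Views of the data, one per scan run."""
        return [
            self.data[:, a:b] for a, b in zip(self.run_offsets, self.run_offsets[1:])
        ]


def make_retinotopic_grid(
    grid_shape: tuple[int, int] = (12, 10),
    ecc_range: tuple[float, float] = (1.0, 8.0),
    polar_range: tuple[float, float] = (0.0, np.pi),
) -> RetinotopicGrid:
    """Evenly spaced ground-truth eccentricity / polar-angle maps on a grid.

    Eccentricity increases along the first grid axis, polar angle along the
    second.  Deterministic.
    """
    n_ecc, n_pol = grid_shape
    if n_ecc < 2 or n_pol < 2:
        raise ValueError("grid_shape components must be >= 2")
    for name, (lo, hi) in (("ecc_range", ecc_range), ("polar_range", polar_range)):
        if not hi > lo:
            raise ValueError(f"{name} is degenerate: min must be < max")
    ecc_axis = np.linspace(ecc_range[0], ecc_range[1], n_ecc)
    pol_axis = np.linspace(polar_range[0], polar_range[1], n_pol)
    ecc, polar = np.meshgrid(ecc_axis, pol_axis, indexing="ij")
    return RetinotopicGrid(ecc.ravel(), polar.ravel(), (n_ecc, n_pol))


def _warped_positions(grid: RetinotopicGrid, curvature: float) -> np.ndarray:
    """Grid-index coordinates, optionally bent into a 3-D arc.

    With curvature kappa > 0 the first grid axis is rolled onto a circle of
    radius 1/kappa (arc length preserved), so Euclidean distances between the
    warped positions fold while geodesic distances along the sheet do not.
    """
    pos = grid.grid_coordinates()
    if curvature == 0:
        return pos
    u, v = pos[:, 0], pos[:, 1]
    theta = curvature * u
    return np.column_stack(
        [np.sin(theta) / curvature, (1.0 - np.cos(theta)) / curvature, v]
    )


def _latent_mixing_weights(grid: RetinotopicGrid, config: SimulationConfig) -> np.ndarray:
    """N x N Gaussian mixing weights from each vertex to each latent source.

    One latent source sits at every grid node, guaranteeing both map axes
    are represented in the correlation structure.
    """
    pos = _warped_positions(grid, config.manifold_curvature)
    d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
    return np.exp(-d2 / (2.0 * config.correlation_length**2))


def _simulate_latents(config: SimulationConfig, n_sources: int, rng) -> list[np.ndarray]:
    """Per-run latent source matrices, i.i.d. standard normal."""
    return [
        rng.standard_normal((n_sources, config.timepoints_per_run))
        for _ in range(config.n_runs)
    ]


def simulate_roi_timeseries(
    grid: RetinotopicGrid,
    config: SimulationConfig,
    *,
    return_latents: bool = False,
):
    """Simulate ROI vertex timeseries carrying the grid topography.

    Each vertex is a Gaussian-weighted mixture of latent sources placed at
    every grid node plus i.i.d. noise, generated independently per run on a
    constant baseline and converted to percent signal change run-wise.  The
    expected pairwise correlation decays monotonically with grid distance.

    When ``return_latents`` is true, also returns the per-run latent source
    matrices (for building correlated non-ROI sources).
    """
    rng = np.random.default_rng(config.seed)
    weights = _latent_mixing_weights(grid, config)
    n = grid.vertex_count
    latents = _simulate_latents(config, n, rng)
    run_blocks = []
    for z in latents:
        noise = rng.standard_normal((n, config.timepoints_per_run))
        run_blocks.append(BASELINE + weights @ z + config.noise_sd * noise)
    raw = Timeseries(
        np.concatenate(run_blocks, axis=1),
        _offsets(config.n_runs, config.timepoints_per_run),
    )
    ts = percent_signal_change(raw)
    if return_latents:
        return ts, latents
    return ts


def simulate_nonroi_timeseries(
    roi_latents: list[np.ndarray],
    config: SimulationConfig,
    mode: str = "cortex",
) -> Timeseries:
    """Simulate non-ROI source timeseries (the connectivity targets).

    ``cortex`` and ``subcortex`` rows are random mixtures of the same latent
    sources that drive the ROI (subcortex draws on a smaller random subset,
    emulating its narrower functional repertoire); ``unrelated`` rows are
    pure noise sharing nothing with the ROI.
    """
    if mode not in {"cortex", "subcortex", "unrelated"}:
        raise ValueError(f"unknown non-ROI mode: {mode!r}")
    m = config.n_nonroi_sources
    n_latent = roi_latents[0].shape[0]
    # offset the seed per mode so cortex/subcortex/unrelated are independent
    rng = np.random.default_rng(
        (config.seed, {"cortex": 1, "subcortex": 2, "unrelated": 3}[mode])
    )
    t = config.timepoints_per_run
    if mode == "unrelated":
        blocks = [rng.standard_normal((m, t)) for _ in range(config.n_runs)]
    else:
        if mode == "subcortex":
            n_used = max(2, n_latent // 4)
            used = rng.choice(n_latent, size=n_used, replace=False)
        else:
            used = np.arange(n_latent)
        mix = rng.standard_normal((m, used.size))
        blocks = []
        for z in roi_latents:
            noise = rng.standard_normal((m, t))
            blocks.append(mix @ z[used] + config.noise_sd * noise)
    raw = Timeseries(
        BASELINE + np.concatenate(blocks, axis=1),
        _offsets(config.n_runs, t),
    )
    return percent_signal_change(raw)


def noise_substitute(ts: Timeseries, seed: int = 0) -> Timeseries:
    """Replace each row with Gaussian noise matched in mean and variance.

    This is the 'noise' connectivity-source control: amplitude structure
    over rows is preserved, temporal structure is destroyed.
    """
    if ts.data.size == 0:
        raise ValueError("empty timeseries")
    rng = np.random.default_rng(seed)
    mu = ts.data.mean(axis=1, keepdims=True)
    sd = ts.data.std(axis=1, ddof=1, keepdims=True)
    out = mu + sd * rng.standard_normal(ts.data.shape)
    return Timeseries(out, list(ts.run_offsets))


def split_odd_even(ts: Timeseries) -> tuple[Timeseries, Timeseries]:
    """Partition scan runs into odd (1st, 3rd, ...) and even (2nd, 4th, ...).

    Runs are 1-indexed as in scanning convention, so the first returned
    half holds runs 1, 3, ... .
    """
    if ts.n_runs < 2:
        raise ValueError("need at least 2 runs to split odd/even")
    runs = ts.runs()
    return (
        _concat_runs(runs[0::2]),
        _concat_runs(runs[1::2]),
    )


def percent_signal_change(raw: Timeseries) -> Timeseries:
    """Convert each row to percent signal change about its run-wise mean.

    x -> 100 * (x - mean(x)) / mean(x), computed per run and re-concatenated.
    """
    out_runs = []
    for block in raw.runs():
        mu = block.mean(axis=1, keepdims=True)
        if np.any(np.abs(mu) < 1e-12):
            bad = int(np.argmin(np.abs(mu)))
            raise ValueError(
                f"row {bad} has (near-)zero temporal mean; cannot convert to "
                "percent signal change"
            )
        out_runs.append(100.0 * (block - mu) / mu)
    return Timeseries(np.concatenate(out_runs, axis=1), list(raw.run_offsets))


def _offsets(n_runs: int, t_per_run: int) -> list[int]:
    return [i * t_per_run for i in range(n_runs + 1)]


def _concat_runs(runs: list[np.ndarray]) -> Timeseries:
    lengths = [r.shape[1] for r in runs]
    offsets = [0]
    for length in lengths:
        offsets.append(offsets[-1] + length)
    return Timeseries(np.concatenate(runs, axis=1), offsets)
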