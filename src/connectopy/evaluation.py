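"""Benchmarking connectopic maps against ground truth.

Embedding components carry an inherent sign ambiguity and no guaranteed
order, so evaluation first matches the two components to the two
ground-truth maps greedily on absolute Pearson correlation, then scores
each matched pair by |r|.  Hyper-parameters are selected by Bayesian
optimization on one odd/even data split and applied to the other.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.spatial.distance import pdist
from scipy.stats import pearsonr

from .connectivity import Fingerprints, build_connectivity
from .embeddings import (
    DiffusionMapGradients,
    ICAGradients,
    IsomapGradients,
    KernelPCAGradients,
    LTSAGradients,
    MLLEGradients,
    PCAGradients,
    SpectralGradients,
    TSNEGradients,
)
from .graphs import DisconnectedGraphError
from .optimize import Integer, OptimizeResult, Real, SearchSpace, bayes_maximize
from .simulate import Timeseries, split_odd_even

__all__ = [
    "GroundTruthMaps",
    "AccuracyRecord",
    "MAP_TYPES",
    "ALGORITHMS",
    "make_estimator",
    "default_search_space",
    "greedy_pair",
    "match_components",
    "prediction_accuracy",
    "crossval_optimize",
    "split_half_reliability",
    "cross_task_reliability",
    "run_subject",
]

MAP_TYPES = ("eccentricity", "polar")


@dataclass(frozen=True)
class GroundTruthMaps:
    """Per-vertex eccentricity and polar-angle values, ROI row order."""

    ecc: np.ndarray
    polar: np.ndarray

    def __post_init__(self):
        ecc = np.asarray(self.ecc, dtype=float)
        polar = np.asarray(self.polar, dtype=float)
        if ecc.shape != polar.shape or ecc.ndim != 1:
            raise ValueError("ecc and polar must be 1-D and equally long")
        if not (np.isfinite(ecc).all() and np.isfinite(polar).all()):
            raise ValueError("ground-truth maps must be finite")
        if ecc.std() == 0 or polar.std() == 0:
            raise ValueError("ground-truth maps must be non-constant")
        object.__setattr__(self, "ecc", ecc)
        object.__setattr__(self, "polar", polar)

    def as_matrix(self) -> np.ndarray:
        return np.column_stack([self.ecc, self.polar])


@dataclass
class AccuracyRecord:
    """One benchmark observation: |r| for one matched map pair."""

    subject: str
    task: str
    algorithm: str
    variant: str
    source_mode: str
    split: str
    map_type: str
    abs_r: float

    def __post_init__(self):
        if not 0.0 <= self.abs_r <= 1.0:
            raise ValueError("abs_r must lie in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# algorithm registry
# ---------------------------------------------------------------------------

#: name -> (estimator class, fixed kwargs, variant label).  Spectral entries
#: are one algorithm with five graph variants; the others have none.
ALGORITHMS = {
    "spectral_knn_unweighted": (SpectralGradients, {"variant": "knn_unweighted"}, "knn_unweighted"),
    "spectral_knn_weighted": (SpectralGradients, {"variant": "knn_weighted"}, "knn_weighted"),
    "spectral_radius_unweighted": (SpectralGradients, {"variant": "radius_unweighted"}, "radius_unweighted"),
    "spectral_radius_weighted": (SpectralGradients, {"variant": "radius_weighted"}, "radius_weighted"),
    "spectral_full_weighted": (SpectralGradients, {"variant": "full_weighted"}, "full_weighted"),
    "pca": (PCAGradients, {}, ""),
    "ica": (ICAGradients, {}, ""),
    "kpca_poly": (KernelPCAGradients, {"kernel": "poly2"}, ""),
    "kpca_rbf": (KernelPCAGradients, {"kernel": "rbf"}, ""),
    "mlle": (MLLEGradients, {}, ""),
    "ltsa": (LTSAGradients, {}, ""),
    "isomap": (IsomapGradients, {}, ""),
    "diffusion": (DiffusionMapGradients, {}, ""),
    "tsne": (TSNEGradients, {}, ""),
}

_SEEDED = {"ica", "tsne"}


def base_algorithm(name: str) -> str:
    return "spectral" if name.startswith("spectral") else name


def make_estimator(name: str, params: dict | None = None, seed: int = 0):
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm: {name!r}")
    cls, fixed, _ = ALGORITHMS[name]
    kwargs = dict(fixed)
    kwargs.update(params or {})
    if name in _SEEDED:
        kwargs.setdefault("seed", seed)
    return cls(**kwargs)


def default_search_space(name: str, X: np.ndarray) -> list:
    """Data-dependent hyper-parameter bounds for one algorithm.

    Neighbourhood sizes are log-spaced integers in [3, n/2]; kernel spreads
    are log-uniform around the median pairwise (squared) distance; radius
    thresholds span the 1st-99th percentile of squared distances.
    """
    if name not in ALGORITHMS:
        raise ValueError(f"unknown algorithm: {name!r}")
    n = X.shape[0]
    k_dim = Integer("k", 3, max(4, n // 2), log=True)
    if name in ("spectral_knn_unweighted", "spectral_knn_weighted", "isomap",
                "mlle", "ltsa"):
        return [k_dim]
    if name in ("spectral_radius_unweighted", "spectral_radius_weighted"):
        d2 = pdist(X, metric="sqeuclidean")
        lo, hi = np.percentile(d2, [1, 99])
        return [Real("eps_radius", float(max(lo, 1e-12)), float(hi), log=True)]
    if name == "kpca_rbf":
        med2 = float(np.median(pdist(X, metric="sqeuclidean")))
        return [Real("gamma", 1e-4 / med2, 1e4 / med2, log=True)]
    if name == "diffusion":
        med2 = float(np.median(pdist(X, metric="sqeuclidean")))
        return [
            k_dim,
            Real("eps_diff", 1e-4 * med2, 1e4 * med2, log=True),
            Real("alpha", 0.0, 1.0),
        ]
    if name == "tsne":
        return [
            Real("perplexity", 5.0, max(6.0, n / 4.0)),
            Real("learning_rate", 10.0, 1000.0, log=True),
        ]
    return []  # pca, ica, kpca_poly, spectral_full_weighted: parameter-free


# ---------------------------------------------------------------------------
# component matching and accuracy
# ---------------------------------------------------------------------------

def greedy_pair(abs_r: np.ndarray) -> list[int]:
    """Greedy 2x2 assignment on a |r| matrix (rows = maps, cols = components).

    The largest |r| cell is matched first, then the remaining pair; ties
    prefer the eccentricity row (row 0), then the first component.
    Returns ``pairing`` with ``pairing[map_index] = component_index``.
    """
    abs_r = np.asarray(abs_r, dtype=float)
    if abs_r.shape != (2, 2):
        raise ValueError("expected a 2x2 matrix")
    first = np.unravel_index(np.argmax(abs_r), (2, 2))  # row-major: ecc wins ties
    second = (1 - first[0], 1 - first[1])
    pairing = [0, 0]
    pairing[first[0]] = first[1]
    pairing[second[0]] = second[1]
    return pairing


def match_components(E: np.ndarray, G: np.ndarray):
    """Greedy 2x2 matching of embedding components to ground-truth maps.

    Computes all pairwise correlations, assigns the pair with the largest
    absolute correlation first, then the remaining pair — so each map is
    matched to exactly one component even when both components correlate
    best with the same map.  Ties prefer the eccentricity map, then the
    first component.

    Returns ``(pairing, signed_r)`` where ``pairing[i]`` is the component
    index matched to map ``i``.
    """
    E = np.asarray(E, dtype=float)
    G = np.asarray(G, dtype=float)
    if E.shape != G.shape or E.ndim != 2 or E.shape[1] != 2:
        raise ValueError("E and G must both be (n, 2)")
    if E.shape[0] < 3:
        raise ValueError("need at least 3 vertices")
    for label, M in (("component", E), ("map", G)):
        if np.any(M.std(axis=0) == 0):
            raise ValueError(f"constant {label} column; correlation undefined")
    r = np.empty((2, 2))
    for i in range(2):
        for j in range(2):
            r[i, j] = pearsonr(G[:, i], E[:, j]).statistic
    pairing = greedy_pair(np.abs(r))
    signed = np.array([r[0, pairing[0]], r[1, pairing[1]]])
    return pairing, signed


def prediction_accuracy(E: np.ndarray, G: np.ndarray) -> dict[str, float]:
    """|Pearson r| of each matched map pair, keyed by map type."""
    _, signed = match_components(E, G)
    return {"eccentricity": float(abs(signed[0])), "polar": float(abs(signed[1]))}


def _reliability(E_ref: np.ndarray, E_other: np.ndarray) -> dict[str, float]:
    pairing, signed = match_components(E_other, E_ref)
    return {
        "component_1": float(abs(signed[0])),
        "component_2": float(abs(signed[1])),
    }


def split_half_reliability(E_split1, E_split2) -> dict[str, float]:
    """|r| between the two splits' maps after greedy component matching."""
    return _reliability(np.asarray(E_split1), np.asarray(E_split2))


def cross_task_reliability(E_task1_split, E_task2_split) -> dict[str, float]:
    """|r| between maps from different tasks and complementary splits."""
    return _reliability(np.asarray(E_task1_split), np.asarray(E_task2_split))


# ---------------------------------------------------------------------------
# cross-validated parameter selection
# ---------------------------------------------------------------------------

def _objective_score(name, params, X, G, seed):
    try:
        est = make_estimator(name, params, seed=seed)
        emb = est.fit(X).embedding_
        acc = prediction_accuracy(emb, G)
    except (DisconnectedGraphError, np.linalg.LinAlgError, ValueError):
        return -np.inf
    return 0.5 * (acc["eccentricity"] + acc["polar"])


def crossval_optimize(
    algorithm: str,
    fingerprints_train: Fingerprints | np.ndarray,
    G: GroundTruthMaps | np.ndarray,
    bounds: list | None = None,
    budget: int | None = None,
    seed: int = 0,
    return_result: bool = False,
):
    """Select hyper-parameters maximizing mean matched |r| on one split.

    ``budget`` is the number of optimizer iterations per free parameter
    (default 100), of which 10% are random starts.  Invalid trials (e.g.
    disconnected graphs) score ``-inf``.  Parameter-free algorithms return
    ``{}`` without running the optimizer.
    """
    X = (
        fingerprints_train.values
        if isinstance(fingerprints_train, Fingerprints)
        else np.asarray(fingerprints_train, dtype=float)
    )
    G_mat = G.as_matrix() if isinstance(G, GroundTruthMaps) else np.asarray(G)
    dims = bounds if bounds is not None else default_search_space(algorithm, X)
    if not dims:
        empty = OptimizeResult({}, _objective_score(algorithm, {}, X, G_mat, seed), [])
        return (empty.best_params, empty) if return_result else empty.best_params
    space = SearchSpace(dims)
    n_calls = (budget if budget is not None else 100) * space.n_dims
    n_random = max(1, round(0.1 * n_calls))
    result = bayes_maximize(
        lambda p: _objective_score(algorithm, p, X, G_mat, seed),
        space,
        n_calls=n_calls,
        n_random_starts=n_random,
        seed=seed,
    )
    return (result.best_params, result) if return_result else result.best_params


# ---------------------------------------------------------------------------
# per-subject orchestration
# ---------------------------------------------------------------------------

def run_subject(
    data: dict[str, tuple[Timeseries, dict[str, Timeseries] | None]],
    truth: GroundTruthMaps,
    algorithms: list[str],
    source_modes: list[str] = ("all",),
    subject: str = "sub-01",
    seed: int = 0,
    budget: int | None = None,
    directions: tuple[str, ...] = ("odd", "even"),
    within_roi_pca: bool = False,
):
    """Run the full pipeline for one subject.

    ``data`` maps task name -> (ROI timeseries, source blocks).  For every
    (task, source mode, algorithm), the runs are split odd/even,
    fingerprints are built per split, hyper-parameters are optimized on one
    split and the held-out split is embedded and scored (both directions by
    default).  Returns ``(records, embeddings, traces)``: ``embeddings`` is
    keyed by ``(task, algorithm, source_mode, evaluated_split)`` — the raw
    material for split-half and cross-task reliability — and ``traces``
    holds every optimizer trial keyed by the training split.
    """
    G = truth.as_matrix()
    records: list[AccuracyRecord] = []
    embeddings: dict[tuple, np.ndarray] = {}
    traces: dict[tuple, list] = {}
    rng = np.random.default_rng(seed)
    for task in sorted(data):
        roi_ts, sources = data[task]
        halves = dict(zip(("odd", "even"), split_odd_even(roi_ts)))
        split_sources = {"odd": {}, "even": {}}
        if sources:
            for key, block in sources.items():
                for split_name, half in zip(("odd", "even"), split_odd_even(block)):
                    split_sources[split_name][key] = half
        for mode in source_modes:
            fps = {
                s: build_connectivity(
                    halves[s],
                    split_sources[s] or None,
                    mode=mode,
                    seed=int(rng.integers(2**31 - 1)),
                    within_roi_pca=within_roi_pca,
                    split_id=s,
                )
                for s in ("odd", "even")
            }
            for name in algorithms:
                alg_seed = int(rng.integers(2**31 - 1))
                for train in directions:
                    test = "even" if train == "odd" else "odd"
                    params, opt = crossval_optimize(
                        name, fps[train], truth, budget=budget, seed=alg_seed,
                        return_result=True,
                    )
                    traces[(task, name, mode, train)] = opt.trials
                    est = make_estimator(name, params, seed=alg_seed)
                    emb = est.fit(fps[test].values).embedding_
                    embeddings[(task, name, mode, test)] = emb
                    acc = prediction_accuracy(emb, G)
                    for map_type in MAP_TYPES:
                        records.append(
                            AccuracyRecord(
                                subject=subject,
                                task=task,
                                algorithm=base_algorithm(name),
                                variant=ALGORITHMS[name][2],
                                source_mode=mode,
                                split=test,
                                map_type=map_type,
                                abs_r=acc[
                                    "eccentricity" if map_type == "eccentricity" else "polar"
                                ],
                            )
                        )
    return records, embeddings, traces
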