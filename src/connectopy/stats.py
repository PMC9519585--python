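"""Statistical framework for comparing benchmark accuracies.

One-sample and paired t-tests with Holm-Bonferroni correction, fully
within-subject repeated-measures ANOVA (1-4 factors, balanced designs)
with Greenhouse-Geisser correction and partial / generalized eta-squared
effect sizes, Tukey studentized-range contrasts, and the non-central
power calculations used for sample-size planning.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "one_sample_t",
    "paired_t",
    "holm_bonferroni",
    "rm_anova",
    "gg_epsilon",
    "tukey_contrasts",
    "cohens_f_from_partial_eta",
    "power_one_sample_t",
    "power_rm_anova_spss",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    d_z: float


def one_sample_t(x, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test with the standardized effect d_z = mean/sd."""
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance; t-test undefined")
    res = sps.ttest_1samp(x, mu0)
    return TTestResult(
        float(res.statistic), int(x.size - 1), float(res.pvalue),
        float((x.mean() - mu0) / sd),
    )


def paired_t(x, y) -> TTestResult:
    """Paired-samples t-test; identical to a one-sample test on x - y."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    return one_sample_t(x - y, 0.0)


def holm_bonferroni(p_values, alpha: float = 0.05):
    """Holm's step-down correction; returns (reject, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any((p < 0) | (p > 1)) or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=alpha, method="holm")
    return reject, p_adj


# ---------------------------------------------------------------------------
# repeated-measures ANOVA
# ---------------------------------------------------------------------------

def _orthonormal_contrasts(levels: int) -> np.ndarray:
    """(levels-1) x levels matrix with orthonormal rows orthogonal to 1."""
    basis = np.column_stack([np.ones(levels), np.eye(levels)[:, : levels - 1]])
    q, _ = np.linalg.qr(basis)
    return q[:, 1:].T


def _subset_means(Y: np.ndarray, cache: dict, keep: frozenset) -> np.ndarray:
    """Mean of Y over all axes not in ``keep`` (keepdims), memoized."""
    if keep not in cache:
        axes = tuple(ax for ax in range(Y.ndim) if ax not in keep)
        cache[keep] = Y.mean(axis=axes, keepdims=True) if axes else Y
    return cache[keep]


def _effect_ss(Y: np.ndarray, keep: frozenset, cache: dict) -> float:
    """Sum of squares of the ANOVA effect spanned by axes ``keep``.

    Balanced-design inclusion-exclusion: the effect estimate at each cell is
    the alternating sum of means over subsets of ``keep``; its squared sum
    over the full tensor is the effect SS.
    """
    keep = frozenset(keep)
    effect = np.zeros((1,) * Y.ndim)
    members = sorted(keep)
    for r in range(len(members) + 1):
        for sub in combinations(members, r):
            sign = (-1) ** (len(members) - r)
            effect = effect + sign * _subset_means(Y, cache, frozenset(sub))
    # broadcasting the effect over collapsed axes multiplies by their sizes
    scale = np.prod([Y.shape[ax] for ax in range(Y.ndim) if ax not in keep])
    return float(scale * np.sum(effect**2))


def _contrast_scores(Y: np.ndarray, factor_axes: tuple[int, ...]) -> np.ndarray:
    """Subjects x df matrix of orthonormal within-subject contrast scores
    for the effect spanned by ``factor_axes`` (axis 0 is subjects)."""
    other = [ax for ax in range(1, Y.ndim) if ax not in factor_axes]
    W = Y.mean(axis=tuple(other)) if other else Y
    # W has shape (n_subj, levels of the involved factors, in axis order)
    C = np.ones((1, 1))
    for ax in sorted(factor_axes):
        C = np.kron(C, _orthonormal_contrasts(Y.shape[ax]))
    flat = W.reshape(W.shape[0], -1)
    return flat @ C.T


def gg_epsilon(covariance, k: int | None = None) -> float:
    """Greenhouse-Geisser epsilon from a k x k level covariance matrix.

    Computed on the orthonormal-contrast transform of the covariance and
    clamped to [1/(k-1), 1].  Under compound symmetry (sphericity holds)
    epsilon = 1; k = 2 always gives 1.
    """
    S = np.asarray(covariance, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise ValueError("covariance must be square")
    if not np.allclose(S, S.T, atol=1e-10):
        raise ValueError("covariance must be symmetric")
    if np.linalg.eigvalsh(S).min() < -1e-8 * max(1.0, np.abs(S).max()):
        raise ValueError("covariance must be positive semi-definite")
    k = S.shape[0] if k is None else k
    if k < 2:
        raise ValueError("k must be >= 2")
    C = _orthonormal_contrasts(k)
    return _epsilon_from_contrast_cov(C @ S @ C.T)


def _epsilon_from_contrast_cov(V: np.ndarray) -> float:
    d = V.shape[0]
    if d == 0:
        return 1.0
    tr = np.trace(V)
    denom = d * np.sum(V * V)
    if denom <= 0 or tr <= 0:
        return 1.0
    return float(np.clip(tr**2 / denom, 1.0 / d, 1.0))


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    within: list[str],
    subject: str,
) -> pd.DataFrame:
    """Fully within-subject repeated-measures ANOVA on a balanced long table.

    Supports 1-4 within-subject factors.  Each effect is tested against its
    own subject-by-effect error stratum; Greenhouse-Geisser correction is
    applied to every effect (a no-op for single-df effects); effect sizes
    are partial eta-squared and generalized eta-squared (all factors treated
    as manipulated).
    """
    if not 1 <= len(within) <= 4:
        raise ValueError("between 1 and 4 within-subject factors supported")
    df = data[[subject, *within, dv]].copy()
    if df[dv].isna().any():
        raise ValueError("missing values in the dependent variable")
    subjects = sorted(df[subject].unique())
    levels = {f: sorted(df[f].unique()) for f in within}
    n_cells = int(np.prod([len(levels[f]) for f in within]))
    counts = df.groupby([subject, *within], sort=True).size()
    if len(counts) != len(subjects) * n_cells or (counts != 1).any():
        raise ValueError(
            "design must be balanced and complete: exactly one observation "
            "per subject per cell"
        )
    n_subj = len(subjects)
    if n_subj < 2:
        raise ValueError("need at least 2 subjects")

    idx = df.set_index([subject, *within]).sort_index()[dv]
    shape = (n_subj, *[len(levels[f]) for f in within])
    Y = idx.to_numpy().reshape(shape)

    cache: dict = {}
    k = len(within)
    factor_axes = {f: i + 1 for i, f in enumerate(within)}

    rows = []
    all_error_ss = _effect_ss(Y, frozenset({0}), cache)  # subject stratum
    effect_sets = []
    for r in range(1, k + 1):
        effect_sets.extend(combinations(within, r))
    err_ss = {}
    for S in effect_sets:
        axes = frozenset(factor_axes[f] for f in S)
        err_ss[S] = _effect_ss(Y, axes | {0}, cache)
        all_error_ss += err_ss[S]

    for S in effect_sets:
        axes = tuple(sorted(factor_axes[f] for f in S))
        ss_eff = _effect_ss(Y, frozenset(axes), cache)
        ss_err = err_ss[S]
        df_num = int(np.prod([len(levels[f]) - 1 for f in S]))
        df_den = (n_subj - 1) * df_num
        if ss_err <= 1e-12 * max(1.0, ss_eff):
            f_stat = 0.0 if ss_eff <= 1e-12 else np.inf
        else:
            f_stat = (ss_eff / df_num) / (ss_err / df_den)
        Z = _contrast_scores(Y, axes)
        if df_num == 1:
            eps = 1.0
        else:
            V = np.cov(Z, rowvar=False)
            eps = _epsilon_from_contrast_cov(np.atleast_2d(V))
        if np.isinf(f_stat):
            p_gg = 0.0
        elif f_stat == 0.0:
            p_gg = 1.0
        else:
            p_gg = float(sps.f.sf(f_stat, df_num * eps, df_den * eps))
        denom_p = ss_eff + ss_err
        eta_p2 = 0.0 if denom_p == 0 else ss_eff / denom_p
        denom_g = ss_eff + all_error_ss
        eta_g2 = 0.0 if denom_g == 0 else ss_eff / denom_g
        rows.append(
            {
                "effect": " x ".join(S),
                "ss_effect": ss_eff,
                "ss_error": ss_err,
                "df_num": df_num,
                "df_den": df_den,
                "F": f_stat,
                "eps_gg": eps,
                "p_gg": p_gg,
                "eta_p2": eta_p2,
                "eta_g2": eta_g2,
            }
        )
    return pd.DataFrame(rows).set_index("effect")


def tukey_contrasts(cell_means, error_ms: float, df_err: float, n: int):
    """Tukey HSD p-values for all pairwise cell contrasts.

    ``error_ms`` is the mean square of the effect's own error stratum and
    ``n`` the number of observations averaged into each cell mean.  With
    two cells the studentized range reduces to the unadjusted two-sided t.
    """
    means = np.asarray(cell_means, dtype=float)
    k = means.size
    if k < 2:
        raise ValueError("need at least 2 cells")
    if df_err < 1:
        raise ValueError("df_err must be >= 1")
    if error_ms < 0 or n < 1:
        raise ValueError("error_ms must be >= 0 and n >= 1")
    se = np.sqrt(error_ms / n)
    rows = []
    for i, j in combinations(range(k), 2):
        diff = means[i] - means[j]
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df_err))
        rows.append({"cell_i": i, "cell_j": j, "diff": diff, "p": p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# power analyses
# ---------------------------------------------------------------------------

def cohens_f_from_partial_eta(eta_p2: float) -> float:
    """Cohen's f = sqrt(eta_p^2 / (1 - eta_p^2))."""
    if not 0 <= eta_p2 < 1:
        raise ValueError("partial eta-squared must lie in [0, 1)")
    return float(np.sqrt(eta_p2 / (1.0 - eta_p2)))


def power_one_sample_t(
    d: float, n: int, alpha: float = 0.05, two_sided: bool = True
) -> float:
    """Power of a one-sample t-test for standardized effect d at sample size n.

    Exact non-central t computation: noncentrality d * sqrt(n).
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df = n - 1
    nc = d * np.sqrt(n)
    if two_sided:
        tcrit = sps.t.isf(alpha / 2.0, df)
        upper = sps.nct.sf(tcrit, df, nc)
        lower = sps.nct.cdf(-tcrit, df, nc)
        if np.isnan(lower):  # scipy underflows in the far tail; the mass is ~0
            lower = 0.0
        power = upper + lower
    else:
        tcrit = sps.t.isf(alpha, df)
        power = sps.nct.sf(tcrit, df, nc)
    return float(power)


def power_rm_anova_spss(
    f: float, m_levels: int, n: int, alpha: float = 0.05
) -> float:
    """Power of a one-way repeated-measures ANOVA effect, SPSS convention.

    Effect size f is on the partial-eta scale already incorporating the
    repeated-measures correlation ("as in SPSS"), so the noncentrality is
    lambda = f^2 * n with df = (m-1, (n-1)(m-1)).
    """
    if m_levels < 2:
        raise ValueError("need at least 2 levels")
    if f < 0:
        raise ValueError("f must be >= 0")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    df1 = m_levels - 1
    df2 = (n - 1) * df1
    lam = f**2 * n
    fcrit = sps.f.isf(alpha, df1, df2)
    if lam == 0:  # scipy's ncf is unreliable at zero noncentrality
        return float(alpha)
    return float(sps.ncf.sf(fcrit, df1, df2, lam))
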