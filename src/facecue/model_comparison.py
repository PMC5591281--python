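"""Group-level model comparison.

Two complementary routes, as in the study:

* paired two-sided Wilcoxon signed-rank tests on per-subject maximized log
  likelihoods (all models have five free parameters, so log likelihoods are
  compared directly, with no complexity correction);

* random-effects Bayesian model selection (RFX-BMS): a variational
  Dirichlet posterior over population model frequencies, exceedance
  probabilities by Monte-Carlo integration, and the Bayes omnibus risk
  (BOR) — the posterior probability that all models are equally frequent —
  which "protects" the exceedance probabilities:

      pxp_k = (1 - BOR) * xp_k + BOR / K.

The variational scheme iterates per-subject model responsibilities
g_nk ∝ exp(L_nk + ψ(α_k) − ψ(Σα)) against the Dirichlet update
α = α0 + Σ_n g_n, starting from the uniform prior α0 = 1.  BOR compares the
free energy of the frequency model against the null of equal frequencies,
F0 = Σ_n [logsumexp(L_n) − log K].
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, gammaln, logsumexp, ndtr

__all__ = [
    "WilcoxonResult",
    "BMSResult",
    "paired_loglik_comparison",
    "rfx_bms",
]


@dataclass
class WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test on paired differences (a − b)."""

    median_diff: float
    iqr: tuple[float, float]
    z: float
    p_value: float
    n_effective: int
    p_exact: float | None = None
    degenerate: bool = False


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p by enumeration of all 2^n sign assignments."""
    n = len(ranks)
    combos = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
    w_all = combos @ ranks
    p_ge = np.mean(w_all >= w_plus - 1e-12)
    p_le = np.mean(w_all <= w_plus + 1e-12)
    return float(min(1.0, 2.0 * min(p_ge, p_le)))


def paired_loglik_comparison(ll_a, ll_b, exact_max_n: int = 12) -> WilcoxonResult:
    """Compare two models' per-subject log likelihoods.

    Zero differences are dropped; ties among |differences| get averaged
    ranks with a tie-corrected normal-approximation variance, and no
    continuity correction is applied.  For ``n_effective <= exact_max_n``
    an exact enumeration p-value is also reported.
    """
    a = np.asarray(ll_a, dtype=float)
    b = np.asarray(ll_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("ll_a and ll_b must be 1-D arrays of equal length")
    if len(a) < 5:
        raise ValueError("need at least 5 pairs")
    d = a - b
    median_diff = float(np.median(d))
    iqr = (float(np.percentile(d, 25)), float(np.percentile(d, 75)))

    d_nz = d[d != 0.0]
    n = len(d_nz)
    if n == 0:
        return WilcoxonResult(median_diff, iqr, 0.0, 1.0, 0, p_exact=1.0, degenerate=True)

    ranks = pd.Series(np.abs(d_nz)).rank(method="average").to_numpy()
    w_plus = float(np.sum(ranks[d_nz > 0]))
    mean_w = n * (n + 1) / 4.0
    var_w = n * (n + 1) * (2 * n + 1) / 24.0
    _, counts = np.unique(np.abs(d_nz), return_counts=True)
    var_w -= np.sum(counts**3 - counts) / 48.0  # tie correction
    if var_w <= 0:
        return WilcoxonResult(median_diff, iqr, 0.0, 1.0, n, p_exact=1.0, degenerate=True)
    z = (w_plus - mean_w) / np.sqrt(var_w)
    p = float(2.0 * (1.0 - ndtr(abs(z))))
    p_exact = _exact_signed_rank_p(ranks, w_plus) if n <= exact_max_n else None
    return WilcoxonResult(median_diff, iqr, float(z), min(p, 1.0), n, p_exact=p_exact)


@dataclass
class BMSResult:
    """Random-effects BMS output over K candidate models."""

    models: list[str]
    alpha: np.ndarray                  # Dirichlet posterior parameters
    expected_freq: np.ndarray          # alpha / sum(alpha)
    xp: np.ndarray                     # exceedance probabilities
    bor: float                         # Bayes omnibus risk
    pxp: np.ndarray                    # protected exceedance probabilities
    subject_posteriors: np.ndarray     # N x K responsibilities (rows sum to 1)
    n_iterations: int = 0

    def to_dict(self) -> dict:
        return {
            "models": self.models,
            "alpha": self.alpha.tolist(),
            "expected_freq": self.expected_freq.tolist(),
            "xp": self.xp.tolist(),
            "bor": self.bor,
            "pxp": self.pxp.tolist(),
            "subject_posteriors": self.subject_posteriors.tolist(),
            "n_iterations": self.n_iterations,
        }


def _as_matrix(ll) -> tuple[np.ndarray, list[str]]:
    if isinstance(ll, pd.DataFrame):
        return ll.to_numpy(dtype=float), [str(c) for c in ll.columns]
    arr = np.asarray(ll, dtype=float)
    return arr, [f"m{k}" for k in range(arr.shape[1])]


def rfx_bms(
    ll,
    n_mc_samples: int = 1_000_000,
    seed: int = 0,
    alpha0: float = 1.0,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> BMSResult:
    """Random-effects Bayesian model selection over a subjects x models
    log-evidence matrix (maximized log likelihoods; equal parameter counts).
    """
    L, names = _as_matrix(ll)
    if L.ndim != 2 or L.shape[0] < 2 or L.shape[1] < 2:
        raise ValueError("log-evidence matrix must be N>=2 subjects x K>=2 models")
    if not np.all(np.isfinite(L)):
        raise ValueError("log-evidence matrix contains non-finite entries")
    n_sub, n_mod = L.shape
    a0 = np.full(n_mod, float(alpha0))

    # variational iteration
    alpha = a0.copy()
    g = np.full((n_sub, n_mod), 1.0 / n_mod)
    trace = []
    for it in range(max_iter):
        log_u = L + digamma(alpha) - digamma(alpha.sum())
        g = np.exp(log_u - logsumexp(log_u, axis=1, keepdims=True))
        alpha_new = a0 + g.sum(axis=0)
        step = float(np.max(np.abs(alpha_new - alpha)))
        trace.append(step)
        alpha = alpha_new
        if step < tol:
            break
    else:
        raise RuntimeError(f"RFX-BMS did not converge in {max_iter} iterations; trace tail {trace[-5:]}")

    # exceedance probabilities by Dirichlet Monte Carlo
    rng = np.random.default_rng(seed)
    draws = rng.dirichlet(alpha, size=n_mc_samples)
    xp = np.bincount(np.argmax(draws, axis=1), minlength=n_mod) / n_mc_samples

    # free energy of the frequency model (variational bound)
    elog_r = digamma(alpha) - digamma(alpha.sum())
    f1 = float(
        np.sum(g * (L + elog_r - np.log(np.clip(g, 1e-300, None))))
        + gammaln(a0.sum()) - np.sum(gammaln(a0))
        - gammaln(alpha.sum()) + np.sum(gammaln(alpha))
        + np.sum((a0 - alpha) * elog_r)
    )
    # null model: all frequencies equal
    f0 = float(np.sum(logsumexp(L, axis=1) - np.log(n_mod)))
    bor = float(1.0 / (1.0 + np.exp(f1 - f0)))
    pxp = (1.0 - bor) * xp + bor / n_mod

    return BMSResult(
        models=names,
        alpha=alpha,
        expected_freq=alpha / alpha.sum(),
        xp=xp,
        bor=bor,
        pxp=pxp,
        subject_posteriors=g,
        n_iterations=it + 1,
    )
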