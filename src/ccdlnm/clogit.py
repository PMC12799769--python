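"""Conditional logistic regression on 1:M matched sets.

Each stratum contains exactly one case and M >= 1 controls, so the
conditional (matched-set) likelihood is exact — no Breslow/Efron tie
handling is needed:

    l(beta) = sum_s [ x_case(s) . beta - log sum_{j in s} exp(x_j . beta) ]

The log-likelihood is concave; it is maximised by Newton-Raphson from
beta = 0 with step-halving, and the covariance is the inverse observed
information at the optimum.  Monotone likelihoods (separation: some linear
combination perfectly ranks the case above its controls) are detected by the
coefficient norm escaping a declared bound while the likelihood still
improves, and flagged rather than reported as converged estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["FitResult", "conditional_loglik", "fit_clogit", "likelihood_ratio_test"]


@dataclass
class FitResult:
    beta: np.ndarray          # log-odds per design column
    cov: "np.ndarray | None"  # inverse observed information
    loglik: float
    n_strata: int
    n_iterations: int
    converged: bool
    separation: bool = False
    column_names: "list[str] | None" = None

    def se(self) -> np.ndarray:
        if self.cov is None:
            raise ValueError("covariance unavailable (separation or failed fit)")
        return np.sqrt(np.diag(self.cov))

    def to_dict(self) -> dict:
        return {
            "beta": self.beta.tolist(),
            "cov": None if self.cov is None else self.cov.tolist(),
            "loglik": float(self.loglik),
            "n_strata": int(self.n_strata),
            "n_iterations": int(self.n_iterations),
            "converged": bool(self.converged),
            "separation": bool(self.separation),
            "column_names": self.column_names,
        }


def _prepare(design, case, strata):
    X = np.asarray(design, dtype=float)
    y = np.asarray(case).astype(bool)
    g = np.asarray(strata)
    if X.ndim != 2 or X.shape[0] != y.size or y.size != g.size:
        raise ValueError("design, case indicators and stratum index must align")
    order = np.argsort(g, kind="stable")
    X, y, g = X[order], y[order], g[order]
    _, start = np.unique(g, return_index=True)
    bounds = np.append(start, y.size)
    for s, e in zip(bounds[:-1], bounds[1:]):
        ncase = int(y[s:e].sum())
        if ncase != 1:
            raise ValueError(
                f"stratum {g[s]!r} has {ncase} cases; exactly one is required")
        if e - s < 2:
            raise ValueError(f"stratum {g[s]!r} has no controls")
    return X, y, bounds


def _loglik_parts(beta, X, y, bounds, want=2):
    """Log-likelihood, score and observed information in one pass.

    Strata are processed in groups of equal size so the softmax, score and
    information reduce to batched tensor contractions.
    """
    eta = X @ beta
    ll = 0.0
    score = np.zeros(X.shape[1])
    info = np.zeros((X.shape[1], X.shape[1]))
    sizes = np.diff(bounds)
    for m in np.unique(sizes):
        starts = bounds[:-1][sizes == m]
        rows = (starts[:, None] + np.arange(m)[None, :]).ravel()
        E = eta[rows].reshape(-1, m)
        Y = y[rows].reshape(-1, m)
        mx = E.max(axis=1)
        W = np.exp(E - mx[:, None])
        tot = W.sum(axis=1)
        ll += float(np.sum(E[Y] - mx - np.log(tot)))
        if want >= 1:
            P = W / tot[:, None]
            Xg = X[rows].reshape(-1, m, X.shape[1])
            xbar = np.einsum("sm,smp->sp", P, Xg)
            score += Xg[Y].sum(axis=0) - xbar.sum(axis=0)
        if want >= 2:
            Xc = Xg - xbar[:, None, :]
            info += np.einsum("smp,sm,smq->pq", Xc, P, Xc, optimize=True)
    return ll, score, info


def conditional_loglik(beta, design, case, strata) -> float:
    """Exact 1:M matched-set log-likelihood at ``beta``.

    Raises if any stratum does not contain exactly one case and >= 1 control.
    """
    X, y, bounds = _prepare(design, case, strata)
    beta = np.asarray(beta, dtype=float)
    ll, _, _ = _loglik_parts(beta, X, y, bounds, want=0)
    return float(ll)


def conditional_score(beta, design, case, strata) -> np.ndarray:
    X, y, bounds = _prepare(design, case, strata)
    _, score, _ = _loglik_parts(np.asarray(beta, float), X, y, bounds, want=1)
    return score


def fit_clogit(design, case, strata, tol: float = 1e-8, max_iter: int = 50,
               separation_bound: float = 15.0,
               column_names: "list[str] | None" = None) -> FitResult:
    """Newton-Raphson fit of the conditional logistic model.

    Convergence requires both the relative log-likelihood change and the
    maximum absolute score to fall below ``tol``.  Up to 30 step-halvings per
    iteration keep the likelihood non-decreasing.  If ``||beta||_inf`` exceeds
    ``separation_bound`` while the likelihood is still improving the fit is
    flagged as separated and the covariance withheld.
    """
    X, y, bounds = _prepare(design, case, strata)
    n_strata = bounds.size - 1
    p = X.shape[1]
    # columns constant within every stratum carry no information and make the
    # information matrix singular; reject them explicitly
    within_var = np.zeros(p)
    sizes = np.diff(bounds)
    for m in np.unique(sizes):
        starts = bounds[:-1][sizes == m]
        rows = (starts[:, None] + np.arange(m)[None, :]).ravel()
        Xg = X[rows].reshape(-1, m, p)
        within_var += np.var(Xg, axis=1).sum(axis=0) * m
    col_scale = np.maximum(np.mean(X * X, axis=0), np.finfo(float).tiny)
    degenerate = within_var <= 1e-12 * col_scale * X.shape[0]
    if np.any(degenerate):
        j = int(np.argmax(degenerate))
        name = column_names[j] if column_names else f"column {j}"
        raise ValueError(
            f"design column {name!r} is constant within every stratum "
            "(singular information)")
    # fit on internally rescaled columns (unit pooled within-stratum SD):
    # pure conditioning, mapped back exactly afterwards
    scale = np.sqrt(within_var / X.shape[0])
    X = X / scale
    beta = np.zeros(p)
    ll, score, info = _loglik_parts(beta, X, y, bounds)
    it = 0
    converged = False
    separated = False
    for it in range(1, max_iter + 1):
        try:
            step = np.linalg.solve(info, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, score, rcond=None)[0]
        # damp oversized steps (trust region of 2 within-SD units) so a
        # single early overshoot is never mistaken for monotone likelihood
        biggest = np.max(np.abs(step))
        if biggest > 2.0:
            step = step * (2.0 / biggest)
        new_beta, new_ll = beta, ll
        for _ in range(30):
            cand = beta + step
            cll, _, _ = _loglik_parts(cand, X, y, bounds, want=0)
            if cll >= ll - 1e-12:
                new_beta, new_ll = cand, cll
                break
            step = step / 2.0
        prev_norm = np.max(np.abs(beta / scale))
        beta = new_beta
        prev_ll, ll = ll, new_ll
        ll, score, info = _loglik_parts(beta, X, y, bounds)
        norm = np.max(np.abs(beta / scale))  # bound applies in design units
        # monotone likelihood: the coefficient norm escapes the bound and is
        # still travelling, with the likelihood still improving.  A finite
        # optimum just beyond the bound settles (norm stops growing) and is
        # not flagged.
        if (norm > separation_bound and norm > prev_norm + 0.5
                and ll > prev_ll + tol * abs(prev_ll)):
            separated = True
            break
        rel = abs(ll - prev_ll) / (abs(prev_ll) + 1e-12)
        # the score is a sum over strata, so its tolerance carries that scale
        if rel < tol and np.max(np.abs(score)) < tol * max(1.0, n_strata):
            converged = True
            break
    cov = None
    if converged and not separated:
        try:
            cov = np.linalg.inv(info)
        except np.linalg.LinAlgError as err:
            raise ValueError("singular information matrix at the optimum") from err
        cov = cov / np.outer(scale, scale)
    beta = beta / scale
    return FitResult(beta=beta, cov=cov, loglik=float(ll), n_strata=n_strata,
                     n_iterations=it, converged=converged and not separated,
                     separation=separated, column_names=column_names)


def null_loglik(strata) -> float:
    """Log-likelihood of the empty (no-covariate) model: -sum_s log |s|."""
    g = np.asarray(strata)
    _, counts = np.unique(g, return_counts=True)
    return float(-np.sum(np.log(counts)))


def likelihood_ratio_test(full: FitResult, reduced: FitResult):
    """LRT of nested conditional-logit fits.

    Returns ``(statistic, df, p)`` with the statistic ``2 (l_full - l_red)``
    and ``p`` from the upper tail of chi-square(df).
    """
    if not (full.converged and reduced.converged):
        raise ValueError("both fits must have converged")
    df = full.beta.size - reduced.beta.size
    if df < 0:
        raise ValueError("models are not nested: reduced has more columns than full")
    if full.column_names and reduced.column_names:
        if not set(reduced.column_names) <= set(full.column_names):
            raise ValueError("models are not nested: reduced columns are not a "
                             "subset of the full model's")
    stat = 2.0 * (full.loglik - reduced.loglik)
    if stat < -1e-6:
        raise ValueError("negative LR statistic: models are not nested or a fit "
                         "did not reach its optimum")
    stat = max(stat, 0.0)
    if df == 0:
        return 0.0, 0, 1.0
    p = float(stats.chi2.sf(stat, df))
    return float(stat), int(df), p
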