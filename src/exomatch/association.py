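"""Gene-level logistic regression for the case-only design.

The unit of analysis is the gene, not the subject: over the analysis
universe (GOI plus matched control genes from the clusters of interest) the
model

    GOI ~ LOF + MIS + SYN

regresses an indicator of gene-of-interest membership on the per-gene
counts of qualifying loss-of-function, missense and synonymous variants
aggregated across the case sample.  A positive slope means genes carrying
more variants of that class have higher odds of belonging to the
hypothesis set.

Fitting is plain maximum likelihood via iteratively reweighted least
squares (score-norm tolerance 1e-8, max 100 iterations, step-halving on
likelihood decrease).  Complete or quasi-complete separation is detected
and reported — the fit is flagged non-converged rather than returning a
silently diverging estimate.  An optional Firth (Jeffreys-prior) penalty is
available for separated data but is off by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .cluster import COISelection
from .variants import GeneVariantCounts

__all__ = [
    "TERMS",
    "AssociationResult",
    "fit_logistic",
    "fit_case_only_model",
    "adjust_alpha",
    "significance_report",
]

TERMS = ("intercept", "lof", "mis", "syn")


def _log_likelihood(X: np.ndarray, y: np.ndarray, beta: np.ndarray) -> float:
    eta = X @ beta
    # log(p)·y + log(1-p)·(1-y), numerically stable
    return float(np.sum(y * eta - np.logaddexp(0.0, eta)))


@dataclass
class AssociationResult:
    """One fitted gene-level logistic model."""

    terms: tuple[str, ...]
    estimate: np.ndarray  # log-odds scale
    se: np.ndarray
    n_goi: int
    n_control: int
    converged: bool
    diagnostic: str = ""
    loglik: float = float("nan")

    @property
    def z(self) -> np.ndarray:
        with np.errstate(divide="ignore", invalid="ignore"):
            return self.estimate / self.se

    @property
    def p_value(self) -> np.ndarray:
        from scipy.stats import norm

        return 2.0 * norm.sf(np.abs(self.z))

    @property
    def odds_ratio(self) -> np.ndarray:
        return np.exp(self.estimate)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": self.terms,
                "estimate": self.estimate,
                "se": self.se,
                "z": self.z,
                "p_value": self.p_value,
                "odds_ratio": self.odds_ratio,
            }
        )


def fit_logistic(
    X: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
    firth: bool = False,
):
    """Maximum-likelihood logistic fit by IRLS.

    Returns ``(beta, se, converged, diagnostic, loglik)``.  Convergence is
    declared when the score norm drops below ``tol``.  With ``firth=True``
    the score is Firth-adjusted (Jeffreys prior), which yields finite
    estimates under separation.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    n, k = X.shape
    beta = np.zeros(k)
    converged = False
    diagnostic = ""
    ll = _log_likelihood(X, y, beta)
    H = np.eye(k)
    for _ in range(max_iter):
        eta = X @ beta
        p = expit(eta)
        w = p * (1.0 - p)
        Xw = X * w[:, None]
        H = X.T @ Xw
        if firth:
            # hat diagonal of the weighted design
            try:
                Hinv = np.linalg.inv(H)
            except np.linalg.LinAlgError:
                Hinv = np.linalg.pinv(H)
            h = np.einsum("ij,jk,ik->i", Xw, Hinv, X)
            score = X.T @ (y - p + h * (0.5 - p))
        else:
            score = X.T @ (y - p)
        if np.linalg.norm(score) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(H, score)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, score, rcond=None)[0]
        # step-halving keeps plain IRLS from overshooting
        new_beta = beta + step
        new_ll = _log_likelihood(X, y, new_beta)
        halvings = 0
        while not firth and new_ll < ll - 1e-12 and halvings < 30:
            step *= 0.5
            new_beta = beta + step
            new_ll = _log_likelihood(X, y, new_beta)
            halvings += 1
        beta = new_beta
        ll = new_ll
    ll = _log_likelihood(X, y, beta)
    eta = X @ beta
    cases, controls = eta[y == 1], eta[y == 0]
    separated = (
        len(cases) > 0
        and len(controls) > 0
        and np.ptp(eta) > 1e-6
        and cases.min() >= controls.max() - 1e-8
    )
    if separated:
        # the fitted direction perfectly orders GOI above controls: the MLE
        # is infinite, even if the score happens to vanish numerically
        converged = False
        diagnostic = (
            "complete or quasi-complete separation: a linear combination of "
            "the count predictors perfectly orders GOI above controls"
        )
    elif not converged:
        if np.abs(beta).max() > 15:
            diagnostic = "estimates diverging (likely quasi-separation)"
        else:
            diagnostic = "IRLS did not reach score tolerance"
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, np.inf))
    return beta, se, converged, diagnostic, ll


def fit_case_only_model(
    counts: GeneVariantCounts,
    coi: COISelection,
    firth: bool = False,
) -> AssociationResult:
    """Fit GOI ~ LOF + MIS + SYN over a COI selection's analysis universe.

    The response is 1 for GOI, 0 for control genes; predictors are the
    per-gene class counts (genes absent from the count table contribute
    implicit zeros).
    """
    genes = coi.analysis_genes
    goi = coi.goi
    if not goi or not coi.control_genes:
        raise ValueError(
            f"need at least one GOI and one control gene "
            f"(got {len(goi)} GOI, {len(coi.control_genes)} controls)"
        )
    y = np.fromiter((1.0 if g in goi else 0.0 for g in genes), dtype=np.float64)
    X = np.column_stack([np.ones(len(genes)), counts.matrix(genes)])
    beta, se, converged, diagnostic, ll = fit_logistic(X, y, firth=firth)
    return AssociationResult(
        terms=TERMS,
        estimate=beta,
        se=se,
        n_goi=int(y.sum()),
        n_control=int(len(y) - y.sum()),
        converged=converged,
        diagnostic=diagnostic,
        loglik=ll,
    )


def adjust_alpha(family_alpha: float, n_models: int) -> float:
    """Bonferroni-style per-test level for a family of non-independent models."""
    if not 0.0 < family_alpha < 1.0:
        raise ValueError("family_alpha must be in (0, 1)")
    if n_models < 1:
        raise ValueError("n_models must be >= 1")
    return family_alpha / n_models


def significance_report(results, alpha: float) -> pd.DataFrame:
    """Tabulate fitted models with a strict ``p < alpha`` significance flag.

    ``results`` maps a set name to an :class:`AssociationResult` (or is an
    iterable of such pairs).  The strict comparison means a p-value equal to
    the adjusted level — or rounding to it — is *not* flagged.
    """
    pairs = results.items() if hasattr(results, "items") else results
    frames = []
    for name, res in pairs:
        frame = res.as_frame()
        frame.insert(0, "set", name)
        frame["n_goi"] = res.n_goi
        frame["n_control"] = res.n_control
        frame["converged"] = res.converged
        frame["significant"] = (frame["p_value"] < alpha) & (
            frame["parameter"] != "intercept"
        )
        frames.append(frame)
    if not frames:
        return pd.DataFrame(
            columns=[
                "set", "parameter", "estimate", "se", "z", "p_value",
                "odds_ratio", "n_goi", "n_control", "converged", "significant",
            ]
        )
    return pd.concat(frames, ignore_index=True)
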