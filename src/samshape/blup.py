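"""Replicate summarisation of phenotypes by BLUP + coefficient.

Raw measurements are replicated per line (the study grew each line in two
repeated experiments).  The per-line summary value is obtained from the
linear mixed model

    y_ij = μ + rep_j + u_i + ε_ij,      u_i ~ N(0, σ²_u),  ε_ij ~ N(0, σ²_e)

with replicate a fixed effect (sum-to-zero coded, so μ is the
average-replicate intercept) and line a random effect.  The reported value is
μ + û_i: the fixed-effect coefficient plus the best linear unbiased predictor
of the line effect, i.e. the line mean shrunk toward the grand mean according
to the REML variance components.

REML is computed by profiling the restricted likelihood in the variance ratio
γ = σ²_u/σ²_e.  Because the random effect is a line indicator, (I + γZZ')⁻¹
has the closed Woodbury form I − Z·diag(γ/(1+γn_i))·Z', so each likelihood
evaluation costs O(n·p²); the scalar profile is minimised to high precision
by bounded search on log γ.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["BlupSummary", "BlupFit", "blup_summarize"]


@dataclass(frozen=True)
class BlupSummary:
    """Replicate-summarised phenotype for one line."""

    line_id: str
    trait: str
    blup_plus_coefficient: float
    n_replicates: int


@dataclass
class BlupFit:
    """Fitted variance components and per-line summaries for one trait."""

    trait: str
    sigma2_line: float
    sigma2_resid: float
    mu: float
    summaries: list[BlupSummary]
    converged: bool

    def as_series(self) -> pd.Series:
        """line_id -> BLUP + coefficient, for joining into phenotype tables."""
        return pd.Series(
            {s.line_id: s.blup_plus_coefficient for s in self.summaries},
            name=self.trait,
        )


def _design(df: pd.DataFrame, trait: str):
    y = df[trait].to_numpy(dtype=float)
    lines, line_idx = np.unique(df["line_id"].astype(str).to_numpy(), return_inverse=True)
    reps, rep_idx = np.unique(df["replicate"].astype(str).to_numpy(), return_inverse=True)
    n = y.size
    # fixed effects: intercept + sum-to-zero replicate contrasts
    p = len(reps)
    X = np.ones((n, p))  # columns: intercept, rep contrasts 1..p-1
    for j in range(1, p):  # level j-1 vs the last level
        X[:, j] = (rep_idx == j - 1).astype(float) - (rep_idx == p - 1).astype(float)
    return y, X, lines, line_idx


def _profile(y, X, line_idx, n_lines, log_gamma):
    """-2 restricted log-likelihood (up to a constant) profiled over σ²_e."""
    gamma = math.exp(log_gamma)
    n, p = X.shape
    counts = np.bincount(line_idx, minlength=n_lines).astype(float)
    d = gamma / (1.0 + gamma * counts)  # diag of the Woodbury correction

    ZtX = np.zeros((n_lines, p))
    np.add.at(ZtX, line_idx, X)
    Zty = np.bincount(line_idx, weights=y, minlength=n_lines)

    A = X.T @ X - ZtX.T @ (d[:, None] * ZtX)  # X' V*^-1 X
    b = X.T @ y - ZtX.T @ (d * Zty)
    beta = np.linalg.solve(A, b)
    e = y - X @ beta
    s = np.bincount(line_idx, weights=e, minlength=n_lines)  # per-line residual sums
    ypy = float(e @ e - np.sum(d * s**2))

    logdet_v = float(np.sum(np.log1p(gamma * counts)))
    sign, logdet_a = np.linalg.slogdet(A)
    if sign <= 0 or ypy <= 0:
        return np.inf, None
    neg2ll = logdet_v + logdet_a + (n - p) * math.log(ypy)
    return neg2ll, (beta, d, s, ypy)


def blup_summarize(
    phenotypes: pd.DataFrame,
    trait: str,
    tol: float = 1e-10,
) -> BlupFit:
    """Summarise a replicated per-line table to one BLUP + coefficient per line.

    ``phenotypes`` must have columns ``line_id``, ``replicate`` and ``trait``;
    rows with missing trait values are dropped.  When no line has two or more
    replicates the shrinkage ratio is unidentifiable and plain line means are
    returned with a warning.
    """
    df = phenotypes.dropna(subset=[trait])
    if df.empty:
        raise ValueError(f"no non-missing values for trait {trait!r}")
    y, X, lines, line_idx = _design(df, trait)
    n_lines = len(lines)
    counts = np.bincount(line_idx, minlength=n_lines)

    if counts.max() < 2:
        warnings.warn(
            "all lines have a single replicate; shrinkage is undefined, returning means",
            stacklevel=2,
        )
        means = np.bincount(line_idx, weights=y, minlength=n_lines) / counts
        summaries = [
            BlupSummary(str(l), trait, float(m), int(c))
            for l, m, c in zip(lines, means, counts)
        ]
        return BlupFit(trait, float("nan"), float(np.var(y, ddof=1)),
                       float(y.mean()), summaries, converged=True)

    res = minimize_scalar(
        lambda lg: _profile(y, X, line_idx, n_lines, lg)[0],
        bounds=(-25.0, 25.0),
        method="bounded",
        options={"xatol": tol},
    )
    neg2ll, aux = _profile(y, X, line_idx, n_lines, float(res.x))
    if aux is None:
        raise RuntimeError("REML profile evaluation failed at the optimum")
    beta, d, s, ypy = aux
    gamma = math.exp(float(res.x))
    n, p = X.shape
    sigma2_e = ypy / (n - p)
    sigma2_u = gamma * sigma2_e
    u_hat = d * s  # gamma * s_i / (1 + gamma * n_i)
    mu = float(beta[0])

    summaries = [
        BlupSummary(str(l), trait, float(mu + u), int(c))
        for l, u, c in zip(lines, u_hat, counts)
    ]
    return BlupFit(trait, float(sigma2_u), float(sigma2_e), mu, summaries,
                   converged=bool(res.success))
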