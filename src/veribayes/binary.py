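"""Posterior accuracy of two paired binary tests under verification bias.

The model treats the joint outcome probabilities θ_ij = P[Y1=i, Y2=j] and the
cell-wise disease probabilities φ_ij = P[D=1 | Y1=i, Y2=j] as the free
parameters.  Under missing-at-random verification and an improper (or
uniform) prior the posterior factorises into independent betas per cell and a
Dirichlet over the cells, so posterior draws are exact iid conjugate samples
— no MCMC and no burn-in.

From each draw the accuracy quantities follow by Bayes' theorem:

* per test,  tpf = φ θ / P[D=1]  and  fpf = (1-φ) θ / P[D=0]  using the
  marginal φ's;
* combined via the believe-the-positive rule (positive if either test is
  positive) and the believe-the-negative rule (positive only if both are).

Marginal disease probabilities φ_1. and φ_.1 are by default drawn as
independent betas from the aggregated counts (s_1. = s_11 + s_10, ...), even
though they are functions of the joint parameters; ``marginals="derived"``
computes them from the joint draw instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import (
    BinaryVerificationTable,
    DrawMatrix,
    PosteriorSummary,
    PriorSpec,
    hyperparameters,
    summarize,
)

__all__ = [
    "BinaryPosteriorDraws",
    "AccuracyDraws",
    "ACCURACY_QUANTITIES",
    "sample_binary_posterior",
    "accuracy_from_parameters",
    "binary_accuracy_analysis",
]

ACCURACY_QUANTITIES = ("tpf1", "fpf1", "tpf2", "fpf2", "tpfbn", "fpfbn", "tpfbp", "fpfbp")


@dataclass(frozen=True)
class BinaryPosteriorDraws:
    """Joint posterior draws for the paired binary model.

    ``phi[n, i, j]`` are the cell disease probabilities, ``theta[n, i, j]``
    the joint outcome probabilities; ``phi_marg1[n, i]`` holds φ_i. =
    P[D=1 | Y1=i] and ``phi_marg2[n, j]`` holds φ_.j.
    """

    phi: np.ndarray
    theta: np.ndarray
    phi_marg1: np.ndarray
    phi_marg2: np.ndarray
    seed: int

    @property
    def n_draws(self) -> int:
        return self.phi.shape[0]


@dataclass(frozen=True)
class AccuracyDraws:
    """Per-draw accuracy quantities (all probabilities)."""

    tpf1: np.ndarray
    fpf1: np.ndarray
    tpf2: np.ndarray
    fpf2: np.ndarray
    tpfbp: np.ndarray
    fpfbp: np.ndarray
    tpfbn: np.ndarray
    fpfbn: np.ndarray
    pd: np.ndarray

    def matrix(self, seed: int = 0) -> DrawMatrix:
        cols = [getattr(self, q) for q in ACCURACY_QUANTITIES]
        return DrawMatrix(
            names=ACCURACY_QUANTITIES,
            draws=np.column_stack([np.atleast_1d(c) for c in cols]),
            seed=seed,
        )


def sample_binary_posterior(
    table: BinaryVerificationTable,
    prior: PriorSpec = PriorSpec(),
    n_draws: int = 45_000,
    *,
    seed: int,
    marginals: str = "independent",
) -> BinaryPosteriorDraws:
    """Draw iid samples from the conjugate posterior.

    θ is drawn as normalised gamma deviates (the gamma rate cancels after
    normalisation); the cell φ's are independent betas.  With
    ``marginals="independent"`` (the default) φ_i. and φ_.j are extra
    independent beta draws from the row/column-aggregated counts; with
    ``"derived"`` they are computed from the joint (φ, θ) draw.
    """
    if marginals not in ("independent", "derived"):
        raise ValueError("marginals must be 'independent' or 'derived'")
    hp = hyperparameters(table, prior)
    rng = np.random.default_rng(seed)
    phi = rng.beta(hp.a, hp.b, size=(n_draws, 2, 2))
    g = rng.gamma(hp.d, size=(n_draws, 4))
    theta = (g / g.sum(axis=1, keepdims=True)).reshape(n_draws, 2, 2)
    if marginals == "independent":
        row_a, row_b = hp.a.sum(axis=1), hp.b.sum(axis=1)  # s_i., r_i.
        col_a, col_b = hp.a.sum(axis=0), hp.b.sum(axis=0)  # s_.j, r_.j
        phi_marg1 = rng.beta(row_a, row_b, size=(n_draws, 2))
        phi_marg2 = rng.beta(col_a, col_b, size=(n_draws, 2))
    else:
        phi_marg1 = (phi * theta).sum(axis=2) / theta.sum(axis=2)
        phi_marg2 = (phi * theta).sum(axis=1) / theta.sum(axis=1)
    return BinaryPosteriorDraws(
        phi=phi, theta=theta, phi_marg1=phi_marg1, phi_marg2=phi_marg2, seed=seed
    )


def accuracy_from_parameters(
    phi: np.ndarray,
    theta: np.ndarray,
    phi_marg1: np.ndarray,
    phi_marg2: np.ndarray,
) -> AccuracyDraws:
    """Accuracy quantities from parameter values (vectorised over leading axes).

    ``phi``/``theta`` have trailing shape (2, 2) indexed [y1, y2];
    ``phi_marg1``/``phi_marg2`` trailing shape (2,).  The fpf denominators are
    1 - P[D=1] throughout (P[D=0]).
    """
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi_marg1 = np.asarray(phi_marg1, dtype=float)
    phi_marg2 = np.asarray(phi_marg2, dtype=float)

    theta_row = theta.sum(axis=-1)  # θ_i.
    theta_col = theta.sum(axis=-2)  # θ_.j

    pd1 = (phi_marg1 * theta_row).sum(axis=-1)
    pd2 = (phi_marg2 * theta_col).sum(axis=-1)
    pd = (phi * theta).sum(axis=(-1, -2))
    for p, label in ((pd1, "test 1"), (pd2, "test 2"), (pd, "joint")):
        if np.any(p <= 0.0) or np.any(p >= 1.0):
            raise ValueError(f"degenerate disease prevalence for the {label} parameters")

    tpf1 = phi_marg1[..., 1] * theta_row[..., 1] / pd1
    fpf1 = (1.0 - phi_marg1[..., 1]) * theta_row[..., 1] / (1.0 - pd1)
    tpf2 = phi_marg2[..., 1] * theta_col[..., 1] / pd2
    fpf2 = (1.0 - phi_marg2[..., 1]) * theta_col[..., 1] / (1.0 - pd2)

    bn_num = phi[..., 1, 1] * theta[..., 1, 1]
    tpfbp = (pd - phi[..., 0, 0] * theta[..., 0, 0]) / pd
    fpfbp = (
        (1.0 - phi[..., 1, 1]) * theta[..., 1, 1]
        + (1.0 - phi[..., 1, 0]) * theta[..., 1, 0]
        + (1.0 - phi[..., 0, 1]) * theta[..., 0, 1]
    ) / (1.0 - pd)
    tpfbn = bn_num / pd
    fpfbn = (1.0 - phi[..., 1, 1]) * theta[..., 1, 1] / (1.0 - pd)

    return AccuracyDraws(
        tpf1=tpf1, fpf1=fpf1, tpf2=tpf2, fpf2=fpf2,
        tpfbp=tpfbp, fpfbp=fpfbp, tpfbn=tpfbn, fpfbn=fpfbn, pd=pd,
    )


def binary_accuracy_analysis(
    table: BinaryVerificationTable,
    prior: PriorSpec = PriorSpec(),
    n_draws: int = 45_000,
    *,
    seed: int,
    marginals: str = "independent",
) -> dict[str, PosteriorSummary]:
    """Full posterior analysis: sample, map to accuracies, summarize.

    Returns summaries keyed tpf1, fpf1, tpf2, fpf2, tpfbn, fpfbn, tpfbp, fpfbp.
    """
    draws = sample_binary_posterior(table, prior, n_draws, seed=seed, marginals=marginals)
    acc = accuracy_from_parameters(draws.phi, draws.theta, draws.phi_marg1, draws.phi_marg2)
    return summarize(acc.matrix(seed=seed))
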