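"""ROC areas for paired ordinal tests under verification bias.

Each test rates subjects on an ordinal scale 1..K (ascending suspicion of
disease).  The posterior uses the same conjugate structure as the binary
model: θ over the K² joint cells is Dirichlet, and the marginal disease
probabilities φ_i. = P[D=1 | T1=i] (and φ_.i for test 2) are independent
betas from the row/column-aggregated verified counts.  Bayes' theorem then
gives the category distributions within each disease class,

    α_i = P[T=i | D=1] ∝ φ_i. θ_i.,     β_i = P[T=i | D=0] ∝ (1-φ_i.) θ_i.,

and the ROC area is the Mann-Whitney probability with half-credit for ties,

    A = Σ_{i>j} α_i β_j + ½ Σ_i α_i β_i.

``auc_from_dirichlet_counts`` exposes the same tie-corrected AUC for two
independent Dirichlet-distributed category distributions given directly by
their hyperparameter (count) vectors; because the kernel is bilinear in the
two independent probability vectors, the posterior mean of the AUC equals the
plug-in AUC at the Dirichlet mean vectors exactly in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .tables import (
    DrawMatrix,
    OrdinalVerificationTable,
    PosteriorSummary,
    PriorSpec,
    hyperparameters,
    summarize,
)

__all__ = [
    "OrdinalParamDraws",
    "OrdinalROCDraws",
    "sample_ordinal_posterior",
    "ordinal_roc_from_parameters",
    "ordinal_analysis",
    "auc_from_dirichlet_counts",
    "auc_with_ties",
    "plugin_auc",
]


@dataclass(frozen=True)
class OrdinalParamDraws:
    """Posterior draws: joint θ (n, K, K) and marginal φ per row/column (n, K)."""

    theta: np.ndarray
    phi_row: np.ndarray
    phi_col: np.ndarray
    seed: int

    @property
    def K(self) -> int:
        return self.theta.shape[-1]


@dataclass(frozen=True)
class OrdinalROCDraws:
    """Class-conditional category distributions and ROC areas per draw."""

    alpha1: np.ndarray
    beta1: np.ndarray
    alpha2: np.ndarray
    beta2: np.ndarray
    A1: np.ndarray
    A2: np.ndarray


def auc_with_ties(p_diseased: np.ndarray, p_nondiseased: np.ndarray) -> np.ndarray:
    """P[Y > X] + ½ P[Y = X] for Y ~ p_diseased, X ~ p_nondiseased.

    Categories are ordered ascending along the last axis.  Vectorised over
    leading axes.
    """
    a = np.asarray(p_diseased, dtype=float)
    b = np.asarray(p_nondiseased, dtype=float)
    below = np.cumsum(b, axis=-1) - b  # P[X < category i]
    return (a * below).sum(axis=-1) + 0.5 * (a * b).sum(axis=-1)


def plugin_auc(counts_diseased, counts_nondiseased) -> float:
    """Deterministic tie-corrected AUC from two category count vectors."""
    a = np.asarray(counts_diseased, dtype=float)
    b = np.asarray(counts_nondiseased, dtype=float)
    if a.shape != b.shape:
        raise ValueError("count vectors must have equal length")
    return float(auc_with_ties(a / a.sum(), b / b.sum()))


def sample_ordinal_posterior(
    table: OrdinalVerificationTable,
    prior: PriorSpec = PriorSpec(),
    n_draws: int = 55_000,
    *,
    seed: int,
) -> OrdinalParamDraws:
    """Draw θ ~ Dirichlet(m) and marginal φ's as independent betas.

    Row/column beta parameters aggregate the per-cell hyperparameters, so a
    uniform prior or zero-cell fix propagates consistently.
    """
    hp = hyperparameters(table, prior)
    K = table.K
    rng = np.random.default_rng(seed)
    g = rng.gamma(hp.d, size=(n_draws, K * K))
    theta = (g / g.sum(axis=1, keepdims=True)).reshape(n_draws, K, K)
    a = hp.a.reshape(K, K)
    b = hp.b.reshape(K, K)
    phi_row = rng.beta(a.sum(axis=1), b.sum(axis=1), size=(n_draws, K))
    phi_col = rng.beta(a.sum(axis=0), b.sum(axis=0), size=(n_draws, K))
    return OrdinalParamDraws(theta=theta, phi_row=phi_row, phi_col=phi_col, seed=seed)


def ordinal_roc_from_parameters(
    theta: np.ndarray, phi_row: np.ndarray, phi_col: np.ndarray
) -> OrdinalROCDraws:
    """Map parameter draws to class-conditional distributions and ROC areas."""
    theta = np.asarray(theta, dtype=float)
    phi_row = np.asarray(phi_row, dtype=float)
    phi_col = np.asarray(phi_col, dtype=float)
    theta_row = theta.sum(axis=-1)
    theta_col = theta.sum(axis=-2)

    def _bayes(phi, th):
        num_a = phi * th
        num_b = (1.0 - phi) * th
        ta = num_a.sum(axis=-1, keepdims=True)
        tb = num_b.sum(axis=-1, keepdims=True)
        if np.any(ta == 0.0) or np.any(tb == 0.0):
            raise ValueError("degenerate disease class: zero normalizer")
        return num_a / ta, num_b / tb

    alpha1, beta1 = _bayes(phi_row, theta_row)
    alpha2, beta2 = _bayes(phi_col, theta_col)
    return OrdinalROCDraws(
        alpha1=alpha1, beta1=beta1, alpha2=alpha2, beta2=beta2,
        A1=auc_with_ties(alpha1, beta1), A2=auc_with_ties(alpha2, beta2),
    )


def ordinal_analysis(
    table: OrdinalVerificationTable,
    prior: PriorSpec = PriorSpec(),
    n_draws: int = 55_000,
    *,
    seed: int,
) -> dict[str, PosteriorSummary]:
    """Posterior summaries of the two ROC areas and their difference.

    Keys: ``A1``, ``A2``, ``diff`` (= A1 - A2).
    """
    draws = sample_ordinal_posterior(table, prior, n_draws, seed=seed)
    roc = ordinal_roc_from_parameters(draws.theta, draws.phi_row, draws.phi_col)
    dm = DrawMatrix(
        names=("A1", "A2", "diff"),
        draws=np.column_stack([roc.A1, roc.A2, roc.A1 - roc.A2]),
        seed=seed,
    )
    return summarize(dm)


def auc_from_dirichlet_counts(
    a_diseased,
    a_nondiseased,
    n_draws: int = 55_000,
    *,
    seed: int,
) -> dict[str, PosteriorSummary]:
    """Posterior AUC for two independent Dirichlet category distributions.

    ``a_diseased`` and ``a_nondiseased`` are positive (possibly fractional)
    Dirichlet hyperparameter vectors over the same ascending category order.
    Returns summaries for ``A1`` = P[Y > X] (strict), ``A2`` = P[Y = X]
    (tie probability) and ``auc`` = A1 + A2/2.
    """
    a1 = np.asarray(a_diseased, dtype=float)
    a0 = np.asarray(a_nondiseased, dtype=float)
    if a1.shape != a0.shape or a1.ndim != 1:
        raise ValueError("hyperparameter vectors must be 1-D and of equal length")
    if np.any(a1 <= 0.0) or np.any(a0 <= 0.0):
        raise ValueError("Dirichlet hyperparameters must be positive")
    rng = np.random.default_rng(seed)
    g1 = rng.gamma(a1, size=(n_draws, a1.size))
    g0 = rng.gamma(a0, size=(n_draws, a0.size))
    p = g1 / g1.sum(axis=1, keepdims=True)
    q = g0 / g0.sum(axis=1, keepdims=True)
    strict = (p * (np.cumsum(q, axis=1) - q)).sum(axis=1)
    ties = (p * q).sum(axis=1)
    dm = DrawMatrix(
        names=("A1", "A2", "auc"),
        draws=np.column_stack([strict, ties, strict + 0.5 * ties]),
        seed=seed,
    )
    return summarize(dm)
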