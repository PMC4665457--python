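"""Accuracy under extreme verification bias.

When no test-negative subject is ever referred to the gold standard the
disease prevalence — and with it the true and false positive fractions — is
not estimable.  What remains estimable per test are the detection
probability DP = P[test positive, D=1] = ρ·TPF and the false referral
probability FRP = P[test positive, D=0] = (1-ρ)·FPF, and for the combined
test the ratios of the believe-the-positive rule's TPF (and FPF) to the
believe-the-negative rule's, in which the unknown prevalence cancels.

All quantities are deterministic functions of the same joint (φ, θ) draw used
by :mod:`veribayes.binary`, so their posteriors come from the identical
conjugate sampler.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .binary import sample_binary_posterior
from .tables import (
    BinaryVerificationTable,
    DrawMatrix,
    PosteriorSummary,
    PriorSpec,
    summarize,
)

__all__ = [
    "ExtremeBiasDraws",
    "EXTREME_QUANTITIES",
    "extreme_bias_from_parameters",
    "naive_extreme_estimates",
    "extreme_bias_analysis",
]

EXTREME_QUANTITIES = ("dp1", "dp2", "frp1", "frp2", "ratio_tpf", "ratio_fpf",
                      "ratio_dp", "ratio_frp")


@dataclass(frozen=True)
class ExtremeBiasDraws:
    """Per-draw quantities estimable under extreme verification bias.

    ``ratio_tpf`` is tpf(BP)/tpf(BN) and ``ratio_fpf`` is fpf(BP)/fpf(BN);
    both are at least 1 because the BP rule adds non-negative probability
    mass to the BN cell.  ``ratio_dp`` and ``ratio_frp`` compare the two
    tests (test 1 over test 2).
    """

    dp1: np.ndarray
    dp2: np.ndarray
    frp1: np.ndarray
    frp2: np.ndarray
    ratio_tpf: np.ndarray
    ratio_fpf: np.ndarray
    ratio_dp: np.ndarray
    ratio_frp: np.ndarray

    def matrix(self, seed: int = 0) -> DrawMatrix:
        cols = [np.atleast_1d(getattr(self, q)) for q in EXTREME_QUANTITIES]
        return DrawMatrix(names=EXTREME_QUANTITIES, draws=np.column_stack(cols), seed=seed)


def extreme_bias_from_parameters(
    phi: np.ndarray,
    theta: np.ndarray,
    phi_marg1: np.ndarray,
    phi_marg2: np.ndarray,
) -> ExtremeBiasDraws:
    """Detection/false-referral probabilities and BP:BN ratios from parameters."""
    phi = np.asarray(phi, dtype=float)
    theta = np.asarray(theta, dtype=float)
    phi_marg1 = np.asarray(phi_marg1, dtype=float)
    phi_marg2 = np.asarray(phi_marg2, dtype=float)

    theta_row = theta.sum(axis=-1)
    theta_col = theta.sum(axis=-2)

    dp1 = theta_row[..., 1] * phi_marg1[..., 1]
    dp2 = theta_col[..., 1] * phi_marg2[..., 1]
    frp1 = (1.0 - phi_marg1[..., 1]) * theta_row[..., 1]
    frp2 = (1.0 - phi_marg2[..., 1]) * theta_col[..., 1]

    bn_tp = theta[..., 1, 1] * phi[..., 1, 1]
    bn_fp = theta[..., 1, 1] * (1.0 - phi[..., 1, 1])
    # degenerate double-positive cells make a ratio undefined: signal and
    # propagate NaN rather than discard the (well-defined) DP/FRP draws
    if np.any(bn_tp == 0.0):
        warnings.warn(
            "theta11 * phi11 = 0 in some draws: BP:BN TPF ratio undefined (NaN)",
            stacklevel=2,
        )
    if np.any(bn_fp == 0.0):
        warnings.warn(
            "theta11 * (1 - phi11) = 0 in some draws: BP:BN FPF ratio undefined (NaN)",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_tpf = (
            bn_tp + theta[..., 1, 0] * phi[..., 1, 0] + theta[..., 0, 1] * phi[..., 0, 1]
        ) / bn_tp
        ratio_fpf = (
            bn_fp
            + theta[..., 1, 0] * (1.0 - phi[..., 1, 0])
            + theta[..., 0, 1] * (1.0 - phi[..., 0, 1])
        ) / bn_fp

    with np.errstate(divide="ignore", invalid="ignore"):
        ratio_dp = dp1 / dp2
        ratio_frp = frp1 / frp2
    return ExtremeBiasDraws(
        dp1=dp1, dp2=dp2, frp1=frp1, frp2=frp2,
        ratio_tpf=ratio_tpf, ratio_fpf=ratio_fpf,
        ratio_dp=ratio_dp, ratio_frp=ratio_frp,
    )


def _is_extreme_design(table: BinaryVerificationTable) -> bool:
    u = table.u
    return int(u[0, 1] + u[1, 0] + u[1, 1]) == 0


def naive_extreme_estimates(table: BinaryVerificationTable) -> dict[str, float]:
    """Naive (count-ratio) point estimates for the extreme-bias design.

    Divides observed joint counts by the grand total; ratios divide the BP
    numerator counts by the double-positive cell.  Warns if the table is not
    actually of extreme-bias structure (unverified mass outside the
    double-negative cell).
    """
    if not _is_extreme_design(table):
        warnings.warn(
            "table has unverified subjects outside the double-negative cell; "
            "naive extreme-bias estimates assume all positives are verified",
            stacklevel=2,
        )
    s, r = table.s, table.r
    n = table.n_subjects
    out = {
        "dp1": (s[1, 1] + s[1, 0]) / n,
        "dp2": (s[1, 1] + s[0, 1]) / n,
        "frp1": (r[1, 1] + r[1, 0]) / n,
        "frp2": (r[1, 1] + r[0, 1]) / n,
    }
    if s[1, 1] == 0:
        raise ValueError("s11 = 0: naive TPF ratio undefined")
    if r[1, 1] == 0:
        raise ValueError("r11 = 0: naive FPF ratio undefined")
    out["ratio_tpf"] = (s[1, 1] + s[1, 0] + s[0, 1]) / s[1, 1]
    out["ratio_fpf"] = (r[1, 1] + r[1, 0] + r[0, 1]) / r[1, 1]
    return out


def extreme_bias_analysis(
    table: BinaryVerificationTable,
    prior: PriorSpec = PriorSpec(zero_fix="add_one"),
    n_draws: int = 55_000,
    *,
    seed: int,
) -> dict[str, PosteriorSummary]:
    """Posterior summaries of DP, FRP and BP:BN ratios for both tests.

    The heavy-tailed FPF ratio is better summarised by its posterior median
    than its mean; both are reported.
    """
    draws = sample_binary_posterior(table, prior, n_draws, seed=seed)
    ext = extreme_bias_from_parameters(
        draws.phi, draws.theta, draws.phi_marg1, draws.phi_marg2
    )
    return summarize(ext.matrix(seed=seed))
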