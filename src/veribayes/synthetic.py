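"""Synthetic verification-bias data with the model's assumed structure.

The generator draws, per subject, a joint test-outcome cell from a
multinomial over θ, a disease indicator from the cell's conditional disease
probability φ, and a verification indicator from the cell's verification
probability v.  Because v depends only on the test outcomes, the data are
missing at random by construction — exactly the assumption the conjugate
posterior relies on.  An optional per-cell ``v_diseased`` override makes
verification depend on disease status too (missing not at random), for
demonstrating what happens when the assumption fails.

``recovery_experiment`` closes the loop: it generates a table from known
parameters, runs the posterior analysis, and reports whether each 95%
credible interval covers its generating truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .binary import accuracy_from_parameters, sample_binary_posterior
from .tables import BinaryVerificationTable, OrdinalVerificationTable, PriorSpec

__all__ = ["GeneratorSpec", "RecoveryResult", "generate_table", "recovery_experiment"]


@dataclass(frozen=True)
class GeneratorSpec:
    """True parameters of the data-generating process.

    ``theta``: joint outcome probabilities, flat cell order (length 4 for
    binary, K² for ordinal, T1-major).  ``phi``: disease probability per
    cell.  ``v``: verification probability per cell (scalar allowed).
    ``v_diseased``: optional per-cell verification probability applying to
    diseased subjects only — setting it breaks MAR deliberately.
    """

    design: str
    theta: np.ndarray
    phi: np.ndarray
    v: np.ndarray
    n: int
    seed: int
    K: int = 2
    v_diseased: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.design not in ("binary", "ordinal"):
            raise ValueError(f"unknown design {self.design!r}")
        n_cells = 4 if self.design == "binary" else self.K * self.K
        theta = np.asarray(self.theta, dtype=float)
        phi = np.asarray(self.phi, dtype=float)
        v = np.broadcast_to(np.asarray(self.v, dtype=float), (n_cells,)).copy()
        if theta.shape != (n_cells,) or phi.shape != (n_cells,):
            raise ValueError(f"theta and phi must have length {n_cells}")
        if not np.isclose(theta.sum(), 1.0):
            raise ValueError("theta must sum to 1")
        for name, arr in (("theta", theta), ("phi", phi), ("v", v)):
            if np.any(arr < 0.0) or np.any(arr > 1.0):
                raise ValueError(f"{name} entries must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be positive")
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "phi", phi)
        object.__setattr__(self, "v", v)
        if self.v_diseased is not None:
            vd = np.broadcast_to(np.asarray(self.v_diseased, dtype=float), (n_cells,)).copy()
            if np.any(vd < 0.0) or np.any(vd > 1.0):
                raise ValueError("v_diseased entries must lie in [0, 1]")
            object.__setattr__(self, "v_diseased", vd)

    @property
    def n_cells(self) -> int:
        return 4 if self.design == "binary" else self.K * self.K


def generate_table(spec: GeneratorSpec):
    """Simulate one study and tally it into a verification table.

    Per cell the (s, r, u) split is multinomial with probabilities
    (φv₁, (1-φ)v₀, remainder) where v₁/v₀ are the verification probabilities
    for diseased/non-diseased subjects (equal under MAR).
    """
    rng = np.random.default_rng(spec.seed)
    m = rng.multinomial(spec.n, spec.theta)
    v0 = spec.v
    v1 = spec.v if spec.v_diseased is None else spec.v_diseased
    s = np.empty(spec.n_cells, dtype=int)
    r = np.empty(spec.n_cells, dtype=int)
    for c in range(spec.n_cells):
        p = np.array([
            spec.phi[c] * v1[c],
            (1.0 - spec.phi[c]) * v0[c],
            0.0,
        ])
        p[2] = 1.0 - p[0] - p[1]
        s[c], r[c], _ = rng.multinomial(m[c], p)
    u = m - s - r
    if spec.design == "binary":
        return BinaryVerificationTable(s=s.reshape(2, 2), r=r.reshape(2, 2), u=u.reshape(2, 2))
    return OrdinalVerificationTable(K=spec.K, s=s, r=r, u=u)


@dataclass(frozen=True)
class RecoveryResult:
    """Truth vs posterior for one simulated study."""

    truth: dict
    post_mean: dict
    post_sd: dict
    covered: dict  # 95% interval contains truth
    table: object = field(repr=False)

    def coverage_fraction(self) -> float:
        vals = list(self.covered.values())
        return sum(vals) / len(vals)


def recovery_experiment(
    spec: GeneratorSpec,
    prior: PriorSpec = PriorSpec(),
    n_draws: int = 4_000,
    *,
    seed: int,
) -> RecoveryResult:
    """Generate a binary study and check posterior recovery of the truth.

    Reports, for every φ cell, θ cell and derived accuracy quantity, the
    generating truth, the posterior mean and sd, and whether the central 95%
    credible interval covers the truth.  Raises if the generated table has a
    verified-count zero that the prior cannot resolve (the caller chooses the
    zero-cell policy).
    """
    if spec.design != "binary":
        raise NotImplementedError("recovery_experiment currently supports the binary design")
    table = generate_table(spec)
    verified = table.s + table.r
    if (verified == 0).any() and prior.kind == "improper" and prior.zero_fix == "error":
        raise ValueError(
            f"generated table has empty verified cell(s) at {np.argwhere(verified == 0).tolist()}; "
            "increase n, adjust v, or choose a zero-cell policy"
        )
    draws = sample_binary_posterior(table, prior, n_draws, seed=seed, marginals="derived")
    acc = accuracy_from_parameters(draws.phi, draws.theta, draws.phi_marg1, draws.phi_marg2)

    phi_t = spec.phi.reshape(2, 2)
    theta_t = spec.theta.reshape(2, 2)
    marg1_t = (phi_t * theta_t).sum(axis=1) / theta_t.sum(axis=1)
    marg2_t = (phi_t * theta_t).sum(axis=0) / theta_t.sum(axis=0)
    acc_t = accuracy_from_parameters(phi_t, theta_t, marg1_t, marg2_t)

    quantities: dict[str, tuple[float, np.ndarray]] = {}
    for i in range(2):
        for j in range(2):
            quantities[f"phi{i}{j}"] = (float(phi_t[i, j]), draws.phi[:, i, j])
            quantities[f"theta{i}{j}"] = (float(theta_t[i, j]), draws.theta[:, i, j])
    for q in ("tpf1", "fpf1", "tpf2", "fpf2", "tpfbp", "fpfbp", "tpfbn", "fpfbn", "pd"):
        quantities[q] = (float(getattr(acc_t, q)), getattr(acc, q))

    truth, mean, sd, covered = {}, {}, {}, {}
    for name, (tval, column) in quantities.items():
        lo, hi = np.quantile(column, [0.025, 0.975])
        truth[name] = tval
        mean[name] = float(column.mean())
        sd[name] = float(column.std(ddof=1))
        covered[name] = bool(lo <= tval <= hi)
    return RecoveryResult(truth=truth, post_mean=mean, post_sd=sd, covered=covered, table=table)
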