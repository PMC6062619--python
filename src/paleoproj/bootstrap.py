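"""Marker-resampling bootstrap standard errors for admixture proportions.

Each replicate draws M markers with replacement (columns of the dosage
vector and the frequency matrix jointly) and refits the projection.  A
resample that repeats column m ``w_m`` times has exactly the log-likelihood
``sum_m w_m * loglik_m(q)``, so replicates are realized as multinomial
column weights and all B refits run together as one weighted, batched EM.
Replicate r of a given individual uses an RNG stream derived
deterministically from (seed, individual_id, r), so results are
reproducible and independent of execution order.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass

import numpy as np

from .panel import DIPLOID
from .projection import ProjectionOptions, _check_simplex, _prepare, _snap_boundary, project_individual

__all__ = ["BootstrapResult", "bootstrap_standard_errors"]

_REDRAW_CAP_FACTOR = 10


@dataclass
class BootstrapResult:
    """Bootstrap replicates and per-ancestry standard errors for one individual."""

    individual_id: str
    replicates: np.ndarray  # (B, K), each row on the simplex
    se: np.ndarray  # (K,), sample standard deviation over replicates
    B: int
    seed: int


def _replicate_rng(seed: int, individual_id: str, r: int) -> np.random.Generator:
    key = zlib.crc32(individual_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, key, r]))


def _batched_em(Q, p, a, c, W, opts, check_every: int = 4):
    """Weighted EM on B rows at once; each row is an independent fit.

    Q: (B, K) starting points; p: (K, M) clamped frequencies; a: (M,) allele
    counts out of c; W: (B, M) non-negative marker weights (0 on missing).
    Stops once every row's relative log-likelihood change falls below tol;
    the check is amortized over ``check_every`` iterations (the per-iteration
    criterion is scaled accordingly), since the log evaluation costs as much
    as the EM step itself.
    """
    Wsum = W.sum(axis=1)  # effective marker count per replicate
    ca = c - a
    Wa = W * a
    Wca = W * ca
    ll = None
    n_iter = 0
    for n_iter in range(1, opts.max_iter + 1):
        F = Q @ p
        if (n_iter - 1) % check_every == 0:
            ll_new = np.einsum("bm,bm->b", Wa, np.log(F)) + np.einsum(
                "bm,bm->b", Wca, np.log1p(-F)
            )
            if ll is not None and np.all(
                np.abs(ll_new - ll) <= check_every * opts.tol * np.abs(ll_new)
            ):
                break
            ll = ll_new
        T = ((Wa / F) @ p.T) + ((Wca / (1.0 - F)) @ (1.0 - p).T)
        Q = Q * T / (c * Wsum)[:, None]
        Q /= Q.sum(axis=1, keepdims=True)
    return Q, n_iter


def bootstrap_standard_errors(dosages, freqs, ploidy: str = DIPLOID,
                              opts: ProjectionOptions | None = None,
                              B: int = 200, seed: int = 0,
                              individual_id: str = "",
                              point_estimate=None) -> BootstrapResult:
    """Bootstrap SEs by resampling markers with replacement, B replicates.

    ``se_k`` is the sample standard deviation (denominator B-1) of the
    replicate estimates of ``q_k``.  Replicates whose resample contains no
    non-missing marker are redrawn, up to ``10 * B`` total draws.  Each
    replicate optimization starts from the point estimate; the likelihood is
    concave in q, so the start does not change the optimum.
    """
    if B < 2:
        raise ValueError("bootstrap needs B >= 2 replicates")
    opts = opts or ProjectionOptions()
    if point_estimate is None:
        point_estimate = project_individual(
            dosages, freqs, ploidy, opts, individual_id=individual_id
        ).q
    q_hat = _check_simplex(point_estimate)

    a, c, obs, p = _prepare(dosages, freqs, ploidy, opts.freq_clamp)
    M = a.size
    uniform = np.full(M, 1.0 / M)

    weights = np.empty((B, M))
    draws = 0
    r_stream = 0
    filled = 0
    while filled < B:
        if draws >= _REDRAW_CAP_FACTOR * B:
            raise RuntimeError(
                f"individual {individual_id or '<unnamed>'}: exceeded "
                f"{_REDRAW_CAP_FACTOR * B} bootstrap draws with all-missing resamples"
            )
        rng = _replicate_rng(seed, individual_id, r_stream)
        w = rng.multinomial(M, uniform).astype(float)
        r_stream += 1
        draws += 1
        if (w * obs).sum() == 0:
            continue
        weights[filled] = w * obs  # missing columns contribute nothing
        filled += 1

    # zero components of the start are absorbing, so the fit can be run on
    # the support of the point estimate only
    support = q_hat > 0
    Q0 = np.tile(q_hat[support], (B, 1))
    Qs, _ = _batched_em(Q0, p[support], a, c, weights, opts)
    Q = np.zeros((B, q_hat.size))
    Q[:, support] = Qs
    Q = np.vstack([_snap_boundary(row, opts.zero_tol) for row in Q])
    se = Q.std(axis=0, ddof=1)
    if not np.all(np.isfinite(se)):
        warnings.warn(
            f"individual {individual_id}: non-finite bootstrap SE", stacklevel=2
        )
    return BootstrapResult(
        individual_id=individual_id, replicates=Q, se=se, B=B, seed=seed
    )
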