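"""Supervised projection: maximum-likelihood admixture proportions.

Given fixed ancestry-specific counted-allele frequencies ``p`` (K x M) and an
individual's dosages ``g``, the model treats each marker as an independent
binomial draw with success probability ``f_m = sum_k q_k p_km``.  A diploid
genotype contributes ``g ln f + (2 - g) ln(1 - f)`` to the log-likelihood; a
pseudo-haploid call is a single allele, contributing
``(g/2) ln f + (1 - g/2) ln(1 - f)``.  The log-likelihood is concave in ``q``
over the probability simplex, so plain multiplicative EM from the uniform
start finds the global maximum and is monotone in the likelihood at every
step.

Only ``q`` is estimated; the panel frequencies are never updated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .panel import DIPLOID, PSEUDO_HAPLOID, AlignedDataset

__all__ = [
    "ProjectionOptions",
    "AncestryEstimate",
    "log_likelihood",
    "em_update",
    "project_individual",
    "project_cohort",
]

_SIMPLEX_TOL = 1e-6


@dataclass(frozen=True)
class ProjectionOptions:
    """Numerical settings for the EM fit.

    tol
        Relative log-likelihood change below which iteration stops.
    max_iter
        Iteration cap.
    freq_clamp
        Panel frequencies are clamped into [eps, 1-eps]; frequencies of
        exactly 0 or 1 otherwise make the log-likelihood unbounded.
    min_markers
        Minimum non-missing aligned markers required to attempt a fit.
    zero_tol
        Components below this value after convergence are snapped to the
        boundary (exactly 0) and the rest renormalized.  Under the relative
        stopping rule, truly absent ancestries stall at small positive
        values; the snap makes the boundary identifiable.
    """

    tol: float = 1e-6
    max_iter: int = 2000
    freq_clamp: float = 1e-6
    min_markers: int = 100
    zero_tol: float = 5e-3

    def __post_init__(self) -> None:
        if not 0 < self.tol < 1:
            raise ValueError("tol must be in (0, 1)")
        if not 0 < self.freq_clamp < 0.5:
            raise ValueError("freq_clamp must be in (0, 0.5)")
        if self.max_iter < 1 or self.min_markers < 1:
            raise ValueError("max_iter and min_markers must be positive")
        if not 0 <= self.zero_tol < 0.05:
            raise ValueError("zero_tol must be small and non-negative")


@dataclass
class AncestryEstimate:
    """One individual's fitted admixture-proportion vector."""

    individual_id: str
    q: np.ndarray
    log_likelihood: float
    n_markers_used: int
    n_iterations: int
    converged: bool
    se: np.ndarray | None = None
    failed: bool = False
    error: str | None = None
    ll_trace: np.ndarray | None = field(default=None, repr=False)


def _check_simplex(q: np.ndarray, tol: float = _SIMPLEX_TOL) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    if np.any(q < -tol) or abs(q.sum() - 1.0) > tol:
        raise ValueError(f"q is not on the probability simplex: {q}")
    return np.clip(q, 0.0, None)


def _prepare(dosages, freqs, ploidy, freq_clamp):
    """Common setup: allele counts a out of c trials per non-missing marker."""
    g = np.asarray(dosages, dtype=float)
    p = np.clip(np.asarray(freqs, dtype=float), freq_clamp, 1.0 - freq_clamp)
    if g.ndim != 1 or p.ndim != 2 or p.shape[1] != g.size:
        raise ValueError(f"dosages ({g.shape}) do not align with freqs ({p.shape})")
    obs = np.isfinite(g)
    if ploidy == PSEUDO_HAPLOID:
        c = 1.0
        a = np.where(obs, g / 2.0, 0.0)
    elif ploidy == DIPLOID:
        c = 2.0
        a = np.where(obs, g, 0.0)
    else:
        raise ValueError(f"unknown ploidy flag {ploidy!r}")
    return a, c, obs, p


def log_likelihood(q, dosages, freqs, ploidy: str = DIPLOID,
                   freq_clamp: float = 1e-6) -> float:
    """Binomial log-likelihood of ``q`` given dosages and panel frequencies.

    Missing markers contribute 0; with all markers missing the value is 0.
    """
    q = _check_simplex(q)
    a, c, obs, p = _prepare(dosages, freqs, ploidy, freq_clamp)
    if not obs.any():
        return 0.0
    f = q @ p[:, obs]
    ao = a[obs]
    return float(ao @ np.log(f) + (c - ao) @ np.log1p(-f))


def em_update(q, dosages, freqs, ploidy: str = DIPLOID,
              freq_clamp: float = 1e-6) -> np.ndarray:
    """One multiplicative EM step; zero entries of ``q`` stay zero."""
    q = _check_simplex(q)
    a, c, obs, p = _prepare(dosages, freqs, ploidy, freq_clamp)
    if not obs.any():
        return q.copy()
    po = p[:, obs]
    f = q @ po
    ao = a[obs]
    t = po @ (ao / f) + (1.0 - po) @ ((c - ao) / (1.0 - f))
    q_new = q * t / (c * obs.sum())
    # guard float drift; the update preserves the simplex analytically
    return q_new / q_new.sum()


def _snap_boundary(q: np.ndarray, zero_tol: float) -> np.ndarray:
    if zero_tol <= 0:
        return q
    out = np.where(q < zero_tol, 0.0, q)
    s = out.sum()
    if s <= 0:  # all entries tiny: keep the largest
        out = np.zeros_like(q)
        out[int(np.argmax(q))] = 1.0
        return out
    return out / s


def project_individual(dosages, freqs, ploidy: str = DIPLOID,
                       opts: ProjectionOptions | None = None,
                       init=None, individual_id: str = "") -> AncestryEstimate:
    """EM fit of one individual's admixture proportions.

    Iterates from ``init`` (default uniform) until the relative
    log-likelihood change drops below ``opts.tol`` or ``opts.max_iter`` is
    reached.  The trace of log-likelihood values is kept on the returned
    estimate for diagnostics.
    """
    opts = opts or ProjectionOptions()
    g = np.asarray(dosages, dtype=float)
    p = np.asarray(freqs, dtype=float)
    K = p.shape[0]
    n_obs = int(np.isfinite(g).sum())
    if n_obs < opts.min_markers:
        raise ValueError(
            f"individual {individual_id or '<unnamed>'}: only {n_obs} non-missing "
            f"markers, need at least {opts.min_markers}"
        )
    q = np.full(K, 1.0 / K) if init is None else _check_simplex(init).copy()

    ll = log_likelihood(q, g, p, ploidy, opts.freq_clamp)
    trace = [ll]
    converged = False
    it = 0
    for it in range(1, opts.max_iter + 1):
        q = em_update(q, g, p, ploidy, opts.freq_clamp)
        ll_new = log_likelihood(q, g, p, ploidy, opts.freq_clamp)
        trace.append(ll_new)
        if abs(ll_new - ll) <= opts.tol * abs(ll):
            ll = ll_new
            converged = True
            break
        ll = ll_new

    q = _snap_boundary(q, opts.zero_tol)
    ll = log_likelihood(q, g, p, ploidy, opts.freq_clamp)
    return AncestryEstimate(
        individual_id=individual_id,
        q=q,
        log_likelihood=ll,
        n_markers_used=n_obs,
        n_iterations=it,
        converged=converged,
        ll_trace=np.asarray(trace),
    )


def project_cohort(aligned: AlignedDataset,
                   opts: ProjectionOptions | None = None) -> list[AncestryEstimate]:
    """Fit every individual in an aligned dataset, isolating failures.

    An individual that cannot be fitted (e.g. too few non-missing markers)
    yields a flagged record rather than aborting the cohort.
    """
    opts = opts or ProjectionOptions()
    gm = aligned.genotypes
    K = aligned.panel.n_ancestries
    out: list[AncestryEstimate] = []
    for i, ind in enumerate(gm.individuals):
        try:
            est = project_individual(
                gm.dosages[i], aligned.panel.freqs, gm.ploidy[i], opts,
                individual_id=ind,
            )
        except ValueError as exc:
            est = AncestryEstimate(
                individual_id=ind,
                q=np.full(K, np.nan),
                log_likelihood=np.nan,
                n_markers_used=int(np.isfinite(gm.dosages[i]).sum()),
                n_iterations=0,
                converged=False,
                failed=True,
                error=str(exc),
            )
        out.append(est)
    return out
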