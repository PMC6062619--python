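"""Sample-level ancestry profiles: inverse-variance combination, CI
sparsification, renormalization, and summary ratio statistics.

Individuals within an archaeological sample are combined per ancestry by
random-effects inverse-variance weighting.  The between-individual variance
component tau^2 is the DerSimonian-Laird moment estimator; weights are
1/(se_i^2 + tau^2).  An ancestry is retained only when its two-sided
normal-approximation 95% confidence interval excludes 0; the retained
proportions are renormalized to sum to 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .projection import AncestryEstimate

__all__ = [
    "SampleProfile",
    "dl_between_variance",
    "ivw_combine",
    "sparsify_and_renormalize",
    "combine_sample",
    "summarize_group",
    "ancestry_ratio",
    "profiles_to_frame",
]

_SE_FLOOR = 1e-6


@dataclass
class SampleProfile:
    """IVW-combined, sparsified, renormalized ancestry profile of one sample."""

    sample_id: str
    n_individuals: int
    ancestries: list[str]
    combined_mean: np.ndarray
    combined_se: np.ndarray
    tau2: np.ndarray
    significant: np.ndarray  # boolean mask
    final_proportions: np.ndarray

    def __post_init__(self) -> None:
        nz = self.final_proportions[self.significant]
        if self.significant.any() and abs(nz.sum() - 1.0) > 1e-8:
            raise ValueError("nonzero final proportions must sum to 1")
        if np.any(self.final_proportions[~self.significant] != 0.0):
            raise ValueError("non-significant ancestries must be exactly 0")


def _floored_ses(ses: np.ndarray, context: str) -> np.ndarray:
    ses = np.asarray(ses, dtype=float)
    if np.any(ses <= 0):
        warnings.warn(
            f"{context}: standard error of 0 floored at {_SE_FLOOR}", stacklevel=3
        )
        ses = np.maximum(ses, _SE_FLOOR)
    return ses


def dl_between_variance(estimates, ses) -> float:
    """DerSimonian-Laird moment estimator of the between-unit variance tau^2.

    With fixed-effect weights w_i = 1/se_i^2 and Q the weighted sum of squared
    deviations from the fixed-effect mean,
    tau^2 = max(0, (Q - (n-1)) / (sum w - sum w^2 / sum w)).
    A single estimate gives tau^2 = 0 by convention.
    """
    x = np.asarray(estimates, dtype=float)
    if x.size == 0:
        raise ValueError("no estimates to combine")
    if x.size == 1:
        return 0.0
    ses = _floored_ses(ses, "dl_between_variance")
    if ses.shape != x.shape:
        raise ValueError("estimates and ses must have matching length")
    w = 1.0 / ses**2
    x_fe = np.sum(w * x) / np.sum(w)
    Q = np.sum(w * (x - x_fe) ** 2)
    denom = np.sum(w) - np.sum(w**2) / np.sum(w)
    if denom <= 0:
        return 0.0
    return float(max(0.0, (Q - (x.size - 1)) / denom))


def ivw_combine(estimates, ses, tau2: float | None = None
                ) -> tuple[float, float, float]:
    """Random-effects inverse-variance combination of one ancestry's estimates.

    Returns (mean, se, tau2) with weights 1/(se_i^2 + tau^2); tau^2 is the
    DerSimonian-Laird estimate unless given explicitly (tau2=0 gives the
    fixed-effect combination).  A single estimate passes through unchanged.
    """
    x = np.asarray(estimates, dtype=float)
    if x.size == 0:
        raise ValueError("no estimates to combine")
    if x.size == 1:
        return float(x[0]), float(np.asarray(ses, dtype=float).ravel()[0]), 0.0
    ses = _floored_ses(ses, "ivw_combine")
    if tau2 is None:
        tau2 = dl_between_variance(x, ses)
    w = 1.0 / (ses**2 + tau2)
    mean = float(np.sum(w * x) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    return mean, se, tau2


def sparsify_and_renormalize(means, ses, alpha: float = 0.05
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Zero out ancestries whose two-sided (1-alpha) CI includes 0; renormalize.

    Ancestry k is retained iff mean_k - z * se_k > 0 with
    z = Phi^{-1}(1 - alpha/2).  If nothing survives, the single largest mean
    is retained at 1.0 with a warning.
    """
    means = np.asarray(means, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if np.any(means < 0) or np.any(ses < 0):
        raise ValueError("means and ses must be non-negative")
    if not np.any(means > 0):
        raise ValueError("all combined means are 0; nothing to sparsify")
    z = stats.norm.ppf(1.0 - alpha / 2.0)
    significant = (means - z * ses) > 0
    if not significant.any():
        warnings.warn(
            "no ancestry significant at the requested level; "
            "retaining the largest mean at 1.0",
            stacklevel=2,
        )
        significant = np.zeros_like(means, dtype=bool)
        significant[int(np.argmax(means))] = True
    final = np.where(significant, means, 0.0)
    final /= final.sum()
    return significant, final


def combine_sample(sample_id: str, estimates: list[AncestryEstimate],
                   ancestries: list[str], alpha: float = 0.05) -> SampleProfile:
    """Build one sample's profile from its individuals' estimates + SEs."""
    usable = [e for e in estimates if not e.failed]
    if not usable:
        raise ValueError(f"sample {sample_id}: no successfully fitted individuals")
    for e in usable:
        if e.se is None:
            raise ValueError(
                f"sample {sample_id}: individual {e.individual_id} lacks bootstrap SEs"
            )
    K = len(ancestries)
    X = np.vstack([e.q for e in usable])
    S = np.vstack([e.se for e in usable])
    if X.shape[1] != K:
        raise ValueError("estimate length does not match ancestry labels")
    mean = np.empty(K)
    se = np.empty(K)
    tau2 = np.empty(K)
    for k in range(K):
        if not (X[:, k].any() or S[:, k].any()):
            # ancestry absent in every individual: trivially 0, no flooring
            mean[k] = se[k] = tau2[k] = 0.0
        else:
            mean[k], se[k], tau2[k] = ivw_combine(X[:, k], S[:, k])
    significant, final = sparsify_and_renormalize(mean, se, alpha=alpha)
    return SampleProfile(
        sample_id=sample_id,
        n_individuals=len(usable),
        ancestries=list(ancestries),
        combined_mean=mean,
        combined_se=se,
        tau2=tau2,
        significant=significant,
        final_proportions=final,
    )


def summarize_group(profiles: list[SampleProfile], sizes) -> np.ndarray:
    """Size-weighted mean of sample profiles, renormalized to sum to 1."""
    if not profiles:
        raise ValueError("no profiles to summarize")
    sizes = np.asarray(sizes, dtype=float)
    if sizes.size != len(profiles) or np.any(sizes < 1):
        raise ValueError("sizes must match profiles and be >= 1")
    labels = profiles[0].ancestries
    for prof in profiles[1:]:
        if prof.ancestries != labels:
            raise ValueError("ancestry labels differ across profiles")
    P = np.vstack([prof.final_proportions for prof in profiles])
    mean = sizes @ P / sizes.sum()
    return mean / mean.sum()


def ancestry_ratio(proportions, numerator: str, denominator: str) -> float:
    """Ratio of two named ancestry proportions (e.g. Southern European /
    Western Asian); summaries print it rounded to 1 decimal."""
    series = pd.Series(proportions) if not isinstance(proportions, pd.Series) else proportions
    num = float(series[numerator])
    den = float(series[denominator])
    if den == 0:
        raise ZeroDivisionError(f"denominator ancestry {denominator!r} has proportion 0")
    return num / den


def profiles_to_frame(profiles: list[SampleProfile],
                      sizes: dict[str, int] | None = None) -> pd.DataFrame:
    """Sample-by-ancestry table of final proportions (3-decimal display)."""
    labels = profiles[0].ancestries
    rows = []
    for prof in profiles:
        row = {"sample_id": prof.sample_id,
               "size": sizes.get(prof.sample_id, prof.n_individuals) if sizes
               else prof.n_individuals}
        row.update(dict(zip(labels, prof.final_proportions)))
        rows.append(row)
    return pd.DataFrame(rows)
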