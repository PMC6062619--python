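"""Synthetic frequency panels, admixed cohorts, and full mock studies.

The generator reproduces the statistical structure the projection model
assumes: ancestry-specific allele frequencies diverge from a common
ancestral frequency under the Balding-Nichols model at a chosen F_ST,
individuals carry Dirichlet-distributed admixture proportions, and diploid
genotypes are binomial draws from the individual's mixed allele frequency.
Missingness is marker-i.i.d.; a configurable fraction of individuals is
coded pseudo-haploid (one sampled allele, written as homozygous).

Defaults mirror the target study's panel: 21 ancestries, 19,075 SNPs.
Markers are unlinked, matching the independence assumption of the
projection likelihood.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .panel import DIPLOID, PSEUDO_HAPLOID, FrequencyPanel, GenotypeMatrix, Marker, write_vcf

__all__ = [
    "SparseDirichlet",
    "SimulationConfig",
    "TruthSet",
    "simulate_panel",
    "simulate_individuals",
    "simulate_study",
]

_FREQ_EPS = 1e-6


@dataclass(frozen=True)
class SparseDirichlet:
    """Sparse admixture prior: a Dirichlet draw confined to a small support.

    ``n_support`` ancestries are chosen at random (or ``support`` fixes
    them); proportions on the support are Dirichlet(``concentration``),
    redrawn until every supported component is at least ``min_prop`` so the
    support is well separated from zero.
    """

    n_support: int | None = None
    support: tuple[int, ...] | None = None
    concentration: float = 1.0
    min_prop: float = 0.05

    def __post_init__(self) -> None:
        if self.n_support is None and self.support is None:
            raise ValueError("sparse specification needs n_support or support")
        if self.support is not None and len(self.support) == 0:
            raise ValueError("sparse support must be non-empty")
        if self.concentration <= 0:
            raise ValueError("concentration must be positive")

    def draw(self, K: int, rng: np.random.Generator) -> np.ndarray:
        support = (np.asarray(self.support)
                   if self.support is not None
                   else rng.choice(K, size=self.n_support, replace=False))
        alpha = np.full(support.size, self.concentration)
        for _ in range(1000):
            probs = rng.dirichlet(alpha)
            if probs.min() >= self.min_prop:
                break
        q = np.zeros(K)
        q[support] = probs
        return q


@dataclass
class SimulationConfig:
    """Study-generation settings; defaults follow the emulated panel."""

    K: int = 21
    M: int = 19075
    fst: float = 0.1
    n_individuals: int = 10
    dirichlet_alpha: float | list[float] | SparseDirichlet = 1.0
    missing_rate: float = 0.0
    pseudo_haploid_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1 or self.M < 1 or self.n_individuals < 1:
            raise ValueError("K, M and n_individuals must be positive")
        if not 0 < self.fst < 1:
            raise ValueError("fst must be in (0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.pseudo_haploid_fraction <= 1:
            raise ValueError("pseudo_haploid_fraction must be in [0, 1]")
        if not isinstance(self.dirichlet_alpha, SparseDirichlet):
            alpha = np.atleast_1d(np.asarray(self.dirichlet_alpha, dtype=float))
            if np.any(alpha <= 0):
                raise ValueError("dirichlet_alpha entries must be positive")
            if alpha.size not in (1, self.K):
                raise ValueError("dirichlet_alpha must be scalar or length K")


@dataclass
class TruthSet:
    """Simulated panel, true admixture proportions, and genotypes."""

    panel: FrequencyPanel
    q_true: np.ndarray  # (N, K)
    genotypes: GenotypeMatrix


def simulate_panel(K: int, M: int, fst: float, seed: int) -> FrequencyPanel:
    """Balding-Nichols frequency panel.

    Per marker, an ancestral frequency p is uniform on [0.05, 0.95]; each
    ancestry then draws Beta(p(1-F)/F, (1-p)(1-F)/F), whose mean is p and
    whose variance is F p(1-p) -- the standard single-parameter model of
    F_ST-controlled divergence.  Positions are strictly increasing on one
    synthetic chromosome.
    """
    rng = np.random.default_rng(seed)
    ancestral = rng.uniform(0.05, 0.95, size=M)
    scale = (1.0 - fst) / fst
    freqs = rng.beta(ancestral * scale, (1.0 - ancestral) * scale, size=(K, M))
    freqs = np.clip(freqs, _FREQ_EPS, 1.0 - _FREQ_EPS)
    # non-ambiguous allele pair so alignment keeps every marker
    markers = [
        Marker(id=f"snp{j:06d}", chrom="1", pos=(j + 1) * 10,
               counted_allele="A", other_allele="G")
        for j in range(M)
    ]
    ancestries = [f"Ancestry{k + 1:02d}" for k in range(K)]
    return FrequencyPanel(markers=markers, ancestries=ancestries, freqs=freqs)


def _draw_q(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    if isinstance(config.dirichlet_alpha, SparseDirichlet):
        rows = [config.dirichlet_alpha.draw(config.K, rng)
                for _ in range(config.n_individuals)]
        return np.vstack(rows)
    alpha = np.broadcast_to(
        np.atleast_1d(np.asarray(config.dirichlet_alpha, dtype=float)), (config.K,)
    )
    return rng.dirichlet(alpha, size=config.n_individuals)


def simulate_individuals(panel: FrequencyPanel, config: SimulationConfig,
                         q_true: np.ndarray | None = None,
                         ids: list[str] | None = None) -> TruthSet:
    """Admixed individuals genotyped on the panel.

    ``q_true`` optionally fixes the proportion rows (e.g. one shared profile
    per sample); otherwise rows are drawn from the configured Dirichlet or
    sparse prior.  The first ``pseudo_haploid_fraction`` of individuals emit
    one Bernoulli(f) allele coded {0, 2}; the rest are Binomial(2, f)
    diploids.  Missingness is i.i.d. over the whole matrix.
    """
    rng = np.random.default_rng(config.seed)
    N, K, M = config.n_individuals, config.K, config.M
    if panel.n_ancestries != K or panel.n_markers != M:
        raise ValueError("panel dimensions disagree with the configuration")
    if q_true is None:
        q_true = _draw_q(config, rng)
    q_true = np.asarray(q_true, dtype=float)
    if q_true.shape != (N, K):
        raise ValueError(f"q_true shape {q_true.shape} != ({N}, {K})")

    f = q_true @ panel.freqs  # (N, M) individual mixed allele frequencies
    n_ph = int(round(config.pseudo_haploid_fraction * N))
    dosages = np.empty((N, M))
    dosages[n_ph:] = rng.binomial(2, f[n_ph:]).astype(float)
    if n_ph:
        dosages[:n_ph] = 2.0 * rng.binomial(1, f[:n_ph]).astype(float)
    if config.missing_rate > 0:
        mask = rng.random((N, M)) < config.missing_rate
        dosages[mask] = np.nan

    individuals = ids if ids is not None else [f"ind{i:04d}" for i in range(N)]
    ploidy = [PSEUDO_HAPLOID] * n_ph + [DIPLOID] * (N - n_ph)
    gm = GenotypeMatrix(
        individuals=list(individuals),
        markers=list(panel.markers),
        dosages=dosages,
        ploidy=ploidy,
    )
    return TruthSet(panel=panel, q_true=q_true, genotypes=gm)


def simulate_study(config: SimulationConfig, n_samples: int,
                   individuals_per_sample: int, out_dir=None
                   ) -> tuple[TruthSet, pd.DataFrame, dict[str, str]]:
    """Full mock study: samples of individuals sharing a true profile.

    Each sample draws one true admixture vector (all its individuals share
    it, i.e. samples are ancestrally homogeneous groups); genotypes then vary
    only through binomial sampling and missingness.  When ``out_dir`` is
    given, writes panel TSV, genotype VCF, a sample map, and the truth table,
    returning their paths.
    """
    N = n_samples * individuals_per_sample
    cfg = SimulationConfig(
        K=config.K, M=config.M, fst=config.fst, n_individuals=N,
        dirichlet_alpha=config.dirichlet_alpha,
        missing_rate=config.missing_rate,
        pseudo_haploid_fraction=config.pseudo_haploid_fraction,
        seed=config.seed,
    )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 917]))
    panel = simulate_panel(cfg.K, cfg.M, cfg.fst, seed=cfg.seed)

    per_sample = (
        [config.dirichlet_alpha.draw(cfg.K, rng) for _ in range(n_samples)]
        if isinstance(config.dirichlet_alpha, SparseDirichlet)
        else list(_draw_q(SimulationConfig(
            K=cfg.K, M=cfg.M, fst=cfg.fst, n_individuals=n_samples,
            dirichlet_alpha=config.dirichlet_alpha, seed=cfg.seed), rng))
    )
    q_true = np.repeat(np.vstack(per_sample), individuals_per_sample, axis=0)
    ids = [f"s{s:02d}_ind{i:02d}" for s in range(n_samples)
           for i in range(individuals_per_sample)]
    truth = simulate_individuals(panel, cfg, q_true=q_true, ids=ids)

    sample_map = pd.DataFrame(
        {
            "individual": ids,
            "sample": [f"sample{s:02d}" for s in range(n_samples)
                       for _ in range(individuals_per_sample)],
            "group": "simulated",
        }
    )
    paths: dict[str, str] = {}
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        paths["panel"] = os.path.join(out_dir, "panel.tsv")
        paths["vcf"] = os.path.join(out_dir, "genotypes.vcf")
        paths["sample_map"] = os.path.join(out_dir, "samples.tsv")
        paths["truth"] = os.path.join(out_dir, "truth_q.tsv")
        panel.to_tsv(paths["panel"])
        write_vcf(truth.genotypes, paths["vcf"])
        sample_map.to_csv(paths["sample_map"], sep="\t", index=False)
        truth_df = pd.DataFrame(truth.q_true, columns=panel.ancestries)
        truth_df.insert(0, "individual", ids)
        truth_df.to_csv(paths["truth"], sep="\t", index=False)
    return truth, sample_map, paths
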