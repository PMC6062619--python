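"""Study-level evaluation routines: published-statistic reproduction and
simulation benchmarks of the estimation pipeline.

Everything here either recomputes statistics from the packaged study tables
or measures the estimator on synthetic data with known truth.  These
routines back the validation suite; problem sizes are chosen so each check
runs in minutes on one core while remaining statistically meaningful
(standard errors and support detection scale with marker count, so the
M used for the end-to-end check is smaller than the emulated panel's).
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats

from . import fixtures
from .aggregate import ancestry_ratio, combine_sample
from .bootstrap import bootstrap_standard_errors
from .haplogroups import haplogroup_composition
from .panel import DIPLOID
from .projection import ProjectionOptions, project_individual
from .simulate import SimulationConfig, SparseDirichlet, simulate_individuals, simulate_panel, simulate_study

__all__ = [
    "COPPER_AGE_SAMPLES",
    "published_statistics",
    "em_vs_grid_search",
    "parameter_recovery_rmse",
    "bootstrap_repeat_difference",
    "bootstrap_coverage_percent",
    "support_recovery_percent",
    "table1_max_row_sum_deviation",
]

#: the Copper Age subset of the Middle Neolithic to Copper Age group
COPPER_AGE_SAMPLES = (
    "Sweden", "Remedello", "Tyrol", "Iberia_Chalcolithic", "Spain", "Anatolia_ChL",
)
MIDDLE_NEOLITHIC_SAMPLES = ("Iberia_MN", "Central_MN")

STEPPE_EMBA = "Eneolithic to Middle Bronze Age steppe"
MNCA_EUROPE = "Middle Neolithic to Copper Age Europe"
BRONZE_EUROPE = "Bronze Age Europe"
LBIA_STEPPE = "Late Bronze to Iron Age steppe"
EARLY_NEOLITHIC = "Early Neolithic"


def published_statistics() -> dict[str, float]:
    """Recompute the headline haplogroup percentages and ancestry ratios
    from the packaged study tables.

    Haplogroup percentages use prefix matching on the haplogroup table;
    ratios divide the printed group mean ancestry percentages (and, for the
    Western hunter-gatherers, the published per-sample profile row).
    """
    t2 = fixtures.load_haplogroup_table()

    def pct(locus, prefixes, groups=None, samples=None):
        return haplogroup_composition(
            t2, locus, prefixes, groups=groups, samples=samples
        ).percent_rounded

    out = {
        "steppe_emba_y_r1b_percent": pct("Y", ["R1b"], groups=STEPPE_EMBA),
        "steppe_emba_mt_hjtu_percent": pct("MT", ["H", "J", "T", "U"], groups=STEPPE_EMBA),
        "copper_age_y_i_percent": pct(
            "Y", ["I"], groups=MNCA_EUROPE, samples=list(COPPER_AGE_SAMPLES)
        ),
        "copper_age_mt_hukj_percent": pct(
            "MT", ["H", "U", "K", "J"], groups=MNCA_EUROPE, samples=list(COPPER_AGE_SAMPLES)
        ),
        "bronze_age_y_r_percent": pct("Y", ["R"], groups=BRONZE_EUROPE),
        "bronze_age_mt_hvkujt_percent": pct(
            "MT", ["H", "V", "K", "U", "J", "T"], groups=BRONZE_EUROPE
        ),
        "late_steppe_mt_hvukjt_percent": pct(
            "MT", ["H", "V", "U", "K", "J", "T"], groups=LBIA_STEPPE
        ),
        "early_neolithic_mt_r_descendants_percent": pct(
            "MT", ["H", "V", "J", "T", "U", "K"], groups=EARLY_NEOLITHIC
        ),
        "late_steppe_y_record_count": float(
            haplogroup_composition(t2, "Y", [""], groups=LBIA_STEPPE).total
        ),
    }

    means = fixtures.load_group_means().set_index(["group", "ancestry"])["percent"]
    for key, group in [
        ("early_neolithic_se_wa_ratio", "Early Neolithic farmers"),
        ("copper_age_se_wa_ratio", "Copper Age Europe"),
        ("bronze_age_se_wa_ratio", "Bronze Age Europe"),
    ]:
        out[key] = round(
            ancestry_ratio(means[group], "Southern European", "Western Asian"), 1
        )

    t1 = fixtures.load_sample_profiles()
    western = t1[
        (t1["group"] == "European hunter-gatherers") & (t1["sample"] == "Western")
    ].iloc[0]
    out["western_hg_ne_se_ratio"] = round(
        ancestry_ratio(western[fixtures.ANCESTRY_COLUMNS], "Northern European",
                       "Southern European"), 1
    )
    return out


def table1_max_row_sum_deviation() -> float:
    """Largest |row sum - 1| over the published sample-profile rows."""
    t1 = fixtures.load_sample_profiles()
    sums = t1[fixtures.ANCESTRY_COLUMNS].sum(axis=1)
    return float((sums - 1.0).abs().max())


def grid_search_q1(dosages, freqs, step: float = 0.001) -> float:
    """Brute-force maximizer of the K=2 likelihood over q1 on a fixed grid.

    Evaluates the diploid binomial log-likelihood directly through
    scipy.stats at every grid point -- an oracle independent of the EM code
    path.
    """
    g = np.asarray(dosages, dtype=float)
    obs = np.isfinite(g)
    g = g[obs]
    p = np.asarray(freqs, dtype=float)[:, obs]
    grid = np.arange(0.0, 1.0 + step / 2, step)
    f = grid[:, None] * p[0] + (1.0 - grid[:, None]) * p[1]
    f = np.clip(f, 1e-12, 1 - 1e-12)
    ll = stats.binom.logpmf(g, 2, f).sum(axis=1)
    return float(grid[int(np.argmax(ll))])


def em_vs_grid_search(seed: int, n_instances: int = 20, M: int = 50,
                      fst: float = 0.2) -> float:
    """Max |q1_EM - q1_grid| over random two-ancestry toy instances.

    Tiny-M likelihoods are nearly flat around the optimum, so the EM is run
    to a much tighter tolerance than the production default; the comparison
    probes whether the optimizer finds the maximum, not the stopping rule.
    """
    root = np.random.SeedSequence([seed, 101])
    opts = ProjectionOptions(min_markers=1, tol=1e-12, max_iter=100_000)
    worst = 0.0
    for child in root.spawn(n_instances):
        sub = int(child.generate_state(1)[0] % 2**31)
        panel = simulate_panel(K=2, M=M, fst=fst, seed=sub)
        cfg = SimulationConfig(K=2, M=M, fst=fst, n_individuals=1,
                               dirichlet_alpha=[3.0, 7.0], seed=sub + 1)
        truth = simulate_individuals(panel, cfg)
        g = truth.genotypes.dosages[0]
        est = project_individual(g, panel.freqs, DIPLOID, opts)
        q1_grid = grid_search_q1(g, panel.freqs)
        worst = max(worst, abs(est.q[0] - q1_grid))
    return worst


def parameter_recovery_rmse(seed: int, n_individuals: int = 50, K: int = 5,
                            M: int = 20000, fst: float = 0.1,
                            missing_rate: float = 0.2) -> float:
    """RMSE of estimated vs true admixture proportions over a cohort."""
    panel = simulate_panel(K=K, M=M, fst=fst, seed=seed)
    cfg = SimulationConfig(K=K, M=M, fst=fst, n_individuals=n_individuals,
                           dirichlet_alpha=1.0, missing_rate=missing_rate,
                           seed=seed + 1)
    truth = simulate_individuals(panel, cfg)
    qs = np.vstack([
        project_individual(truth.genotypes.dosages[i], panel.freqs, DIPLOID,
                           individual_id=truth.genotypes.individuals[i]).q
        for i in range(n_individuals)
    ])
    return float(np.sqrt(np.mean((qs - truth.q_true) ** 2)))


def bootstrap_repeat_difference(seed: int, K: int = 3, M: int = 2000,
                                B: int = 200) -> float:
    """Max |difference| between two identically seeded bootstrap runs."""
    panel = simulate_panel(K=K, M=M, fst=0.1, seed=seed)
    cfg = SimulationConfig(K=K, M=M, fst=0.1, n_individuals=1,
                           dirichlet_alpha=5.0, missing_rate=0.1, seed=seed + 1)
    truth = simulate_individuals(panel, cfg)
    g = truth.genotypes.dosages[0]
    runs = [
        bootstrap_standard_errors(g, panel.freqs, DIPLOID, B=B, seed=seed,
                                  individual_id="rep")
        for _ in range(2)
    ]
    return float(
        max(np.abs(runs[0].replicates - runs[1].replicates).max(),
            np.abs(runs[0].se - runs[1].se).max())
    )


def bootstrap_coverage_percent(seed: int, n_individuals: int = 200, K: int = 3,
                               M: int = 2000, B: int = 100) -> float:
    """Empirical coverage (%) of q_hat +/- 1.96 se over simulated individuals.

    Truths are interior (symmetric Dirichlet with concentration 5), so the
    normal approximation should give near-nominal coverage per component.
    """
    panel = simulate_panel(K=K, M=M, fst=0.1, seed=seed)
    cfg = SimulationConfig(K=K, M=M, fst=0.1, n_individuals=n_individuals,
                           dirichlet_alpha=5.0, missing_rate=0.1, seed=seed + 1)
    truth = simulate_individuals(panel, cfg)
    z = stats.norm.ppf(0.975)
    covered = 0
    for i in range(n_individuals):
        g = truth.genotypes.dosages[i]
        est = project_individual(g, panel.freqs, DIPLOID,
                                 individual_id=truth.genotypes.individuals[i])
        res = bootstrap_standard_errors(
            g, panel.freqs, DIPLOID, B=B, seed=seed,
            individual_id=truth.genotypes.individuals[i], point_estimate=est.q,
        )
        covered += int(
            np.sum(np.abs(est.q - truth.q_true[i]) <= z * res.se)
        )
    return 100.0 * covered / (n_individuals * K)


def support_recovery_percent(seed: int, n_runs: int = 20, K: int = 21,
                             n_support: int = 4, M: int = 8000, B: int = 50,
                             individuals_per_sample: int = 10,
                             missing_rate: float = 0.2) -> float:
    """Share of simulated studies whose sparsified sample profile has
    exactly the true ancestry support.

    Each run simulates one sample of individuals sharing a sparse truth,
    runs projection + bootstrap + IVW + CI sparsification, and compares the
    significance mask with the truth's nonzero pattern.
    """
    n_exact = 0
    for r in range(n_runs):
        run_seed = int((seed + 1) * 10007 + r) % 2**31
        cfg = SimulationConfig(
            K=K, M=M, fst=0.1,
            dirichlet_alpha=SparseDirichlet(n_support=n_support),
            missing_rate=missing_rate, seed=run_seed,
        )
        truth, _, _ = simulate_study(cfg, n_samples=1,
                                     individuals_per_sample=individuals_per_sample)
        panel, gm = truth.panel, truth.genotypes
        ests = []
        for i in range(gm.n_individuals):
            est = project_individual(gm.dosages[i], panel.freqs, gm.ploidy[i],
                                     individual_id=gm.individuals[i])
            res = bootstrap_standard_errors(
                gm.dosages[i], panel.freqs, gm.ploidy[i], B=B, seed=run_seed,
                individual_id=gm.individuals[i], point_estimate=est.q,
            )
            est.se = res.se
            ests.append(est)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # floored zero SEs are expected here
            profile = combine_sample("sim", ests, panel.ancestries)
        if np.array_equal(profile.significant, truth.q_true[0] > 0):
            n_exact += 1
    return 100.0 * n_exact / n_runs
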