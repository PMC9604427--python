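"""Reusable simulation harnesses for calibration, power and recovery studies.

These drive the full pipeline (population simulation, case-control
ascertainment, null fitting, both score components, both combinations)
at desk scale and are shared by the test suite and the reproduction
script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import simulate as sim
from .expression import fit_weights
from .gxe import MistiGxE


@dataclass
class NullStudyConfig:
    """Conditions for the null-calibration study: a 50-SNP gene, balanced
    case-control sample of size n ascertained from a 20x population,
    modest exposure and expression main effects (odds ratios ~1.1), and
    no interaction (beta_TE = tau = 0 unless overridden)."""

    n: int = 2000
    n_blocks: int = 5
    block_size: int = 10
    rho: float = 0.6
    beta_E: float = 0.1
    beta_T: float = 0.1
    beta_TE: float = 0.0
    tau: float = 0.0
    ld_seed: int = 42
    weight_seed: int = 20000


def _study_weights(config: NullStudyConfig) -> np.ndarray:
    p = config.n_blocks * config.block_size
    rng = np.random.default_rng(config.weight_seed)
    w = np.zeros(p)
    idx = rng.choice(p, 5, replace=False)
    w[idx] = rng.normal(0.0, 0.4, 5)
    return w


def simulate_gene_replicate(config: NullStudyConfig, seed: int):
    """One ascertained cohort replicate under the configured truth.

    Returns (y, X, E, G, w) ready for :class:`~misti.gxe.MistiGxE`."""
    spec = sim.LDSpec(n_blocks=config.n_blocks, block_size=config.block_size,
                      within_block_rho=config.rho, seed=config.ld_seed)
    w = _study_weights(config)
    pop = sim.simulate_ld_genotypes(20 * config.n, spec, sample_seed=seed)
    truth = sim.CohortTruth(beta_E=config.beta_E, beta_T=config.beta_T,
                            beta_TE=config.beta_TE, tau=config.tau,
                            seed=seed + 1_000_003)
    cohort, pheno = sim.simulate_cohort(pop, w, sim.ExposureSim(name="exposure"),
                                        truth, config.n // 2, config.n - config.n // 2)
    y = pheno["case_status"].to_numpy(float)
    E = pheno["exposure"].to_numpy(float)
    X = np.column_stack(
        [np.ones(config.n), (pheno["study"] == "study1").to_numpy(float),
         pheno["age"].to_numpy(float)]
        + [pheno[f"pc{k}"].to_numpy(float) for k in range(1, 6)]
    )
    return y, X, E, cohort.dosages, w


def run_null_replicates(n_reps: int, seed: int, config: NullStudyConfig | None = None) -> np.ndarray:
    """Simulate ``n_reps`` cohorts and return the four p-values per
    replicate as an (n_reps, 4) array: fixed, random, fisher, amisti."""
    config = config or NullStudyConfig()
    out = np.empty((n_reps, 4))
    for r in range(n_reps):
        y, X, E, G, w = simulate_gene_replicate(config, seed + 17 * r)
        res = MistiGxE(y, X, E, G, w).fit()
        out[r] = (res.p_fixed, res.p_random, res.p_fisher, res.p_amisti)
    return out


def power_at_effect(beta_te: float, n_reps: int, seed: int, alpha: float = 0.05,
                    config: NullStudyConfig | None = None) -> float:
    """Empirical power of the adaptive combined p-value at a given fixed
    interaction effect size."""
    config = config or NullStudyConfig()
    cfg = NullStudyConfig(**{**config.__dict__, "beta_TE": beta_te})
    hits = 0
    for r in range(n_reps):
        y, X, E, G, w = simulate_gene_replicate(cfg, seed + 23 * r)
        res = MistiGxE(y, X, E, G, w).fit()
        hits += res.p_amisti < alpha
    return hits / n_reps


def weight_recovery_correlation(n_reps: int, seed: int, n_train: int = 1000,
                                n_test: int = 500, h2: float = 0.5,
                                n_causal: int = 10, p: int = 100,
                                scheme: str = "enet") -> float:
    """Mean held-out correlation between predicted expression and the true
    genetic value, training one weight scheme (elastic net by default)
    per replicate."""
    cors = []
    for r in range(n_reps):
        spec = sim.LDSpec(n_blocks=p // 10, block_size=10, within_block_rho=0.5,
                          seed=seed + 31 * r)
        panel = sim.simulate_ld_genotypes(n_train + n_test, spec,
                                          sample_seed=seed + 31 * r + 1)
        rng = np.random.default_rng(seed + 31 * r + 2)
        idx = tuple(int(i) for i in rng.choice(p, n_causal, replace=False))
        eff = tuple(float(e) for e in rng.normal(size=n_causal))
        y = sim.simulate_expression_panel(panel, sim.ExpressionTruth(idx, eff, h2),
                                          seed=seed + 31 * r + 3)
        G = panel.dosages
        train = slice(0, n_train)
        test = slice(n_train, n_train + n_test)
        best_w, _ = fit_weights(G[train], y[train], scheme, seed=0)
        w_true = np.zeros(p)
        w_true[list(idx)] = eff
        pred = G[test] @ best_w
        truth_val = G[test] @ w_true
        if pred.std() == 0:
            cors.append(0.0)
        else:
            cors.append(float(np.corrcoef(pred, truth_val)[0, 1]))
    return float(np.mean(cors))
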