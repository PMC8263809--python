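"""Reproducible simulation studies used for validation.

Each study simulates complete inputs (genotypes with local LD, effects
under a chosen heritability profile, phenotypes, GWAS summaries and
disjoint reference panels), runs the pipeline under test, and measures the
quantity of interest. They are deliberately deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classical import classical_grid_fit, predict_scores
from .formats import GenotypeMatrix, Phenotype
from .hermodel import build_annotations, fit_taus
from .ld import compute_ld_pairs
from .megaprs import MegaConfig, make_pseudo_sumstats, run_megaprs
from .simulate import SimConfig, gwas_linear, simulate_effects, simulate_genotypes
from .vb import PriorSpec


def _seeds(seed: int, n: int) -> np.ndarray:
    return np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)


def _r2(y: np.ndarray, pred: np.ndarray) -> float:
    if pred.std() == 0:
        return 0.0
    return float(np.corrcoef(y, pred)[0, 1] ** 2)


@dataclass
class TauRecoveryResult:
    tau_true: float
    tau_hat_mean: float
    relative_bias: float
    tau_hats: np.ndarray


def tau_recovery(n: int = 10_000, m: int = 5_000, h2: float = 0.5,
                 n_ref: int = 1_000, n_reps: int = 50,
                 seed: int = 1) -> TauRecoveryResult:
    """Recover the constant-model coefficient tau = h2 / m by regression of
    chi-squared statistics on LD scores, across seeded replicates."""
    seeds = _seeds(seed, n_reps)
    tau_true = h2 / m
    tau_hats = np.empty(n_reps)
    for rep, s in enumerate(seeds):
        s = int(s)
        cfg = SimConfig(n=n + n_ref, m=m, h2=h2, seed=s)
        panel, G = simulate_genotypes(cfg, dtype=np.float32)
        G_train = GenotypeMatrix(G.dosages[:n], snp_ids=panel.snp_id)
        G_ref = GenotypeMatrix(G.dosages[n:], snp_ids=panel.snp_id)
        eff = simulate_effects(panel, np.ones(m), PriorSpec.ridge(), h2,
                               seed=s + 1)
        y = simulate_phenotype_split(G_train, eff, seed=s + 2)
        ss = gwas_linear(G_train, y, panel)
        store = compute_ld_pairs(G_ref, panel)
        fitted = fit_taus(ss, store, build_annotations(panel, "gcta"))
        tau_hats[rep] = fitted.tau[0]
    mean = float(tau_hats.mean())
    return TauRecoveryResult(
        tau_true=tau_true, tau_hat_mean=mean,
        relative_bias=(mean - tau_true) / tau_true, tau_hats=tau_hats,
    )


def simulate_phenotype_split(G: GenotypeMatrix, effects, seed: int) -> Phenotype:
    from .simulate import simulate_phenotype

    return simulate_phenotype(G, effects, seed=seed)


@dataclass
class BenchmarkResult:
    mega_r2: np.ndarray
    classical_r2: np.ndarray
    win_rate: float


def megaprs_vs_classical(n_train: int = 20_000, m: int = 5_000,
                         h2: float = 0.5, n_test: int = 2_000,
                         n_ref: int = 1_000, n_reps: int = 20,
                         tool: str = "ridge", seed: int = 1,
                         effect_weights: str = "gcta",
                         hermodel_kind: str = "gcta") -> BenchmarkResult:
    """Holdout R^2 of the summary-statistic pipeline against the classical
    clumping+thresholding baseline, on traits simulated under a constant
    (or MAF-dependent) per-SNP heritability profile."""
    seeds = _seeds(seed, n_reps)
    mega_r2 = np.empty(n_reps)
    clas_r2 = np.empty(n_reps)
    for rep, s in enumerate(seeds):
        s = int(s)
        n_total = n_train + n_test + 2 * n_ref
        cfg = SimConfig(n=n_total, m=m, h2=h2, seed=s)
        panel, G = simulate_genotypes(cfg, dtype=np.float32)
        i0, i1, i2, i3 = (
            n_train, n_train + n_test, n_train + n_test + n_ref, n_total
        )
        G_train = GenotypeMatrix(G.dosages[:i0], snp_ids=panel.snp_id)
        G_test = GenotypeMatrix(G.dosages[i0:i1], snp_ids=panel.snp_id)
        G_ref_ab = GenotypeMatrix(G.dosages[i1:i2], snp_ids=panel.snp_id)
        G_ref_c = GenotypeMatrix(G.dosages[i2:i3], snp_ids=panel.snp_id)

        if effect_weights == "gcta":
            weights = np.ones(m)
        else:
            p = panel.maf
            weights = (2.0 * p * (1.0 - p)) ** 0.75
        eff = simulate_effects(panel, weights, PriorSpec.ridge(), h2,
                               seed=s + 1)
        y_train = simulate_phenotype_split(G_train, eff, seed=s + 2)
        y_test = simulate_phenotype_split(G_test, eff, seed=s + 3)
        ss = gwas_linear(G_train, y_train, panel)

        store_ab = compute_ld_pairs(G_ref_ab, panel)
        store_c = compute_ld_pairs(G_ref_c, panel)
        prs = run_megaprs(
            ss, G_ref_ab, G_ref_c, panel, tool,
            hermodel_kind=hermodel_kind, seed=s + 4,
            stores=(store_ab, store_c),
        )
        pseudo = make_pseudo_sumstats(ss, G_ref_ab, seed=s + 4)
        clas = classical_grid_fit(
            pseudo.train, store_ab, test_ss=pseudo.test, store_b=store_c,
            ss_full=ss, panel=panel,
        )
        mega_r2[rep] = _r2(y_test.values, predict_scores(G_test, prs))
        clas_r2[rep] = _r2(y_test.values, predict_scores(G_test, clas))
    return BenchmarkResult(
        mega_r2=mega_r2, classical_r2=clas_r2,
        win_rate=float((mega_r2 > clas_r2).mean()),
    )


@dataclass
class ModelComparisonResult:
    matched_r2: np.ndarray
    constant_r2: np.ndarray

    @property
    def mean_gain(self) -> float:
        return float(self.matched_r2.mean() - self.constant_r2.mean())


def matched_vs_constant_model(n_train: int = 10_000, m: int = 2_000,
                              h2: float = 0.5, n_test: int = 2_000,
                              n_ref: int = 1_000, n_reps: int = 20,
                              tool: str = "ridge", rho: float = 0.5,
                              seed: int = 1) -> ModelComparisonResult:
    """Under a MAF-dependent simulated architecture, compare holdout R^2
    of the pipeline run with the matched (MAF-dependent) heritability
    model against the constant model, pairwise across replicates."""
    seeds = _seeds(seed, n_reps)
    matched = np.empty(n_reps)
    constant = np.empty(n_reps)
    for rep, s in enumerate(seeds):
        s = int(s)
        n_total = n_train + n_test + 2 * n_ref
        cfg = SimConfig(n=n_total, m=m, h2=h2, rho=rho,
                        maf_range=(0.01, 0.5), seed=s)
        panel, G = simulate_genotypes(cfg, dtype=np.float32)
        i0, i1, i2, i3 = (
            n_train, n_train + n_test, n_train + n_test + n_ref, n_total
        )
        G_train = GenotypeMatrix(G.dosages[:i0], snp_ids=panel.snp_id)
        G_test = GenotypeMatrix(G.dosages[i0:i1], snp_ids=panel.snp_id)
        G_ref_ab = GenotypeMatrix(G.dosages[i1:i2], snp_ids=panel.snp_id)
        G_ref_c = GenotypeMatrix(G.dosages[i2:i3], snp_ids=panel.snp_id)

        p = panel.maf
        weights = (2.0 * p * (1.0 - p)) ** 0.75
        eff = simulate_effects(panel, weights, PriorSpec.ridge(), h2,
                               seed=s + 1)
        y_train = simulate_phenotype_split(G_train, eff, seed=s + 2)
        y_test = simulate_phenotype_split(G_test, eff, seed=s + 3)
        ss = gwas_linear(G_train, y_train, panel)
        store_ab = compute_ld_pairs(G_ref_ab, panel)
        store_c = compute_ld_pairs(G_ref_c, panel)
        for kind, out in (("ldak-thin", matched), ("gcta", constant)):
            prs = run_megaprs(
                ss, G_ref_ab, G_ref_c, panel, tool, hermodel_kind=kind,
                seed=s + 4, stores=(store_ab, store_c),
            )
            out[rep] = _r2(y_test.values, predict_scores(G_test, prs))
    return ModelComparisonResult(matched_r2=matched, constant_r2=constant)
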