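"""Synthetic genotypes, effect sizes, phenotypes and GWAS summaries.

Genotypes come from a first-order haplotype-copying process: each allele is
copied from the previous SNP with probability rho, otherwise drawn fresh at
that SNP's frequency, giving approximately geometric LD decay
corr(j, l) ~ rho^|j-l|. Two haplotypes are summed to a dosage. SNPs are
equally spaced on the genetic map.

True effects are drawn from any of the four prior families with per-SNP
variance proportional to a chosen heritability profile, then rescaled so
the summed per-SNP heritability hits the target h2 exactly (so downstream
checks carry no h2-sampling noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .formats import GenotypeMatrix, Phenotype, SnpPanel, SummaryStats
from .vb import PriorSpec, component_variances


@dataclass
class SimConfig:
    n: int = 1000
    m: int = 500
    maf_range: tuple = (0.05, 0.5)
    rho: float = 0.9              # LD decay per adjacent SNP pair
    length_cm: float | None = None  # default: m / 100 (100 SNPs per cM)
    h2: float = 0.5
    prior: PriorSpec = field(default_factory=lambda: PriorSpec.ridge())
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho < 1.0):
            raise ValueError("rho must lie in [0, 1)")
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError("h2 must lie in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf range must be within (0, 0.5]")
        if self.length_cm is None:
            self.length_cm = self.m / 100.0


@dataclass
class TrueEffects:
    """Per-SNP standardized effect sizes; h2_j = beta_j^2."""

    beta: np.ndarray

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=np.float64)

    @property
    def h2_j(self) -> np.ndarray:
        return self.beta**2

    @property
    def h2(self) -> float:
        return float((self.beta**2).sum())


def _child_seed(seed: int, label: str) -> int:
    ss = np.random.SeedSequence([seed, abs(hash(label)) % (2**31)])
    return int(ss.generate_state(1)[0] % (2**31 - 1)) + 1


def simulate_genotypes(cfg: SimConfig, max_retries: int = 10,
                       dtype=np.float64):
    """Draw (SnpPanel, GenotypeMatrix) under the copying process.

    ``dtype=np.float32`` halves memory traffic for large benchmark panels
    (dosages are small integers, exact in either precision).
    """
    rng = np.random.default_rng(cfg.seed)
    p = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.m)
    kernel_seed = int(rng.integers(1, 2**31 - 1))
    H = _kernels.haplotype_copy_kernel(p, cfg.rho, 2 * cfg.n, kernel_seed)
    dosages = (H[: cfg.n] + H[cfg.n:]).astype(dtype)

    # resample rare monomorphic columns independently (bounded retries)
    for _ in range(max_retries):
        mono = dosages.std(axis=0) == 0
        if not mono.any():
            break
        for j in np.where(mono)[0]:
            dosages[:, j] = rng.binomial(1, p[j], cfg.n) + rng.binomial(
                1, p[j], cfg.n
            )
    else:
        raise RuntimeError("could not resample monomorphic columns")

    spacing = cfg.length_cm / cfg.m
    cm = np.arange(cfg.m) * spacing
    bp = np.round(cm * 1e6).astype(np.int64) + 1
    freq = dosages.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    panel = SnpPanel(
        snp_id=np.array([f"snp{j + 1}" for j in range(cfg.m)], dtype=object),
        chromosome=np.ones(cfg.m, dtype=np.int64),
        bp_position=bp,
        cm_position=cm,
        allele1=np.array(["A"] * cfg.m, dtype=object),
        allele2=np.array(["G"] * cfg.m, dtype=object),
        maf=maf,
    )
    return panel, GenotypeMatrix(dosages, snp_ids=panel.snp_id)


def simulate_effects(panel: SnpPanel, weights, family: PriorSpec,
                     h2: float, seed: int = 0) -> TrueEffects:
    """Draw per-SNP effects with variance proportional to ``weights``.

    ``weights`` is a relative E[h2_j] profile (e.g. all-ones for the
    constant model, or [2p(1-p)]^0.75 for the MAF-dependent model); a
    fitted HeritabilityModel's e_j vector works directly. Effects are
    rescaled so sum(beta_j^2) = h2 exactly.
    """
    w = np.asarray(weights, dtype=float)
    if w.ndim == 2:
        w = w[:, 0]
    if len(w) != panel.m:
        raise ValueError("weights misaligned with panel")
    if np.all(w <= 0):
        raise ValueError("all heritability weights are zero")
    w = np.clip(w, 0.0, None)
    e_j = np.where(w > 0, w / w.sum() * max(h2, 1e-8), 0.0)
    rng = np.random.default_rng(seed)
    beta = np.zeros(panel.m)
    live = e_j > 0
    if family.tool == "bayesr" and family.pis[0] == 1.0:
        # pure point mass: every effect is zero, so h2 must be zero too
        if h2 > 0:
            raise ValueError("all simulated effects are zero but h2 > 0")
        return TrueEffects(beta)
    if family.tool == "lasso":
        comp = component_variances(family, e_j[live])
        beta[live] = rng.laplace(scale=1.0 / np.asarray(comp.rate), size=live.sum())
    else:
        comp = component_variances(family, e_j[live])
        choice = rng.choice(
            len(comp.weights), size=int(live.sum()), p=comp.weights
        )
        var = np.take_along_axis(comp.variances, choice[:, None], axis=1)[:, 0]
        beta[live] = rng.standard_normal(int(live.sum())) * np.sqrt(var)
    total = (beta**2).sum()
    if h2 == 0:
        return TrueEffects(np.zeros(panel.m))
    if total == 0:
        raise ValueError("all simulated effects are zero but h2 > 0")
    return TrueEffects(beta * np.sqrt(h2 / total))


def simulate_phenotype(G: GenotypeMatrix, effects: TrueEffects,
                       seed: int = 0) -> Phenotype:
    """Y = X beta + e with e ~ N(0, 1 - h2), then standardized."""
    h2 = effects.h2
    if h2 >= 1:
        raise ValueError("total heritability must be below 1")
    rng = np.random.default_rng(seed)
    X = G.standardized()
    genetic = (X @ effects.beta.astype(X.dtype)).astype(np.float64)
    noise = rng.standard_normal(G.n) * np.sqrt(1.0 - h2)
    return Phenotype(genetic + noise)


def gwas_linear(G: GenotypeMatrix, Y: Phenotype,
                panel: SnpPanel) -> SummaryStats:
    """Single-SNP linear regression on standardized data.

    r_j = X_j^T Y / n and S_j = n r_j^2 / (1 - r_j^2).
    """
    X = G.standardized()
    y = Y.values if isinstance(Y, Phenotype) else np.asarray(Y, dtype=float)
    n = G.n
    r = (X.T @ y.astype(X.dtype)).astype(np.float64) / n
    if not np.all(np.isfinite(r)):
        raise ValueError("non-finite marginal correlation")
    if np.any(np.abs(r) >= 1.0 - 1e-12):
        raise ValueError("|r_j| = 1: degenerate input (phenotype equals a SNP)")
    return SummaryStats.from_r(
        panel.snp_id, panel.allele1, panel.allele2,
        np.full(panel.m, n, dtype=np.int64), r,
    )
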