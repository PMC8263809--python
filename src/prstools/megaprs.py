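"""Summary-statistic polygenic-score pipeline.

Three steps: (1) estimate a sparse local LD panel from reference genotypes;
(2) fit effect sizes by sliding-window variational Bayes for a grid of
prior parameters, once on (pseudo-)training summary statistics and once on
the full statistics; (3) score each training model against (pseudo-)test
summary statistics using a second, distinct reference panel, and report the
full model paired with the best-scoring training model.

Pseudo summary statistics split one set of GWAS results into synthetic
training and test results whose sum reconstructs the originals exactly and
whose added noise matches the sampling covariance implied by the LD of the
reference panel.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .formats import GenotypeMatrix, SnpPanel, SummaryStats
from .hermodel import build_annotations, fit_taus
from .ld import LdPairStore, compute_ld_pairs
from .model import PrsModel
from .vb import PriorSpec, component_variances

logger = logging.getLogger(__name__)

_SCALE_FACTORS = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)
_BOLT_P = (0.01, 0.02, 0.05, 0.1, 0.2, 0.5)
_BOLT_F2 = (0.1, 0.3, 0.5)
_BAYESR_VALUES = (0.0, 0.01, 0.05, 0.1, 0.2)


@dataclass
class PseudoSumstats:
    """Synthetic training/test split of one set of summary statistics."""

    train: SummaryStats
    test: SummaryStats
    frac: float
    seed: int
    n_a: int
    n_b: int


@dataclass
class ModelScore:
    """Estimated train-model/test-phenotype correlation R and its parts."""

    r: float
    numerator: float
    denominator: float


@dataclass
class MegaConfig:
    ld_window_cm: float = 3.0
    ld_p_threshold: float = 0.01
    window_cm: float = 1.0
    step_cm: float = 0.125
    tol: float = 1e-5
    max_iter: int = 50
    pseudo_frac: float = 0.9
    grid: list | None = None
    exclude_regions: list | None = None  # (chrom, start_bp, end_bp)


# ---------------------------------------------------------------------------
# pseudo summary statistics


def make_pseudo_sumstats(full: SummaryStats, G_ref: GenotypeMatrix,
                         frac: float = 0.9, seed: int = 0) -> PseudoSumstats:
    """Sample pseudo training/test summary statistics.

    X_A^T Y_A / n_A is drawn about X^T Y / n with covariance
    (n_B / (n_A n)) C estimated from the reference panel, by adding
    (n_B / (n_A n))^{1/2} X'^T g / sqrt(n') with g standard normal; the
    test statistics are fixed by the exact identity
    X_B^T Y_B = X^T Y - X_A^T Y_A.
    """
    if not (0.0 < frac < 1.0):
        raise ValueError("training fraction must lie in (0, 1)")
    if G_ref.n < 2:
        raise ValueError("reference panel too small")
    ns = np.unique(full.n)
    if len(ns) != 1:
        raise ValueError("pseudo summary statistics need a single sample size")
    n = int(ns[0])
    n_a = int(round(frac * n))
    n_b = n - n_a
    if n_a < 2 or n_b < 1:
        raise ValueError("split leaves too few samples")
    rng = np.random.default_rng(seed)
    Xp = G_ref.standardized()
    g = rng.standard_normal(G_ref.n)
    proj = (Xp.T @ g.astype(Xp.dtype)).astype(np.float64)
    noise = np.sqrt(n_b / (n_a * n)) * proj / np.sqrt(G_ref.n)
    gamma = full.r
    gamma_a = gamma + noise
    xty_a = n_a * gamma_a
    xty_b = n * gamma - xty_a
    gamma_b = xty_b / n_b
    lim = 1.0 - 1e-10
    if np.any(np.abs(gamma_a) >= 1) or np.any(np.abs(gamma_b) >= 1):
        warnings.warn("pseudo correlations clipped to (-1, 1)", stacklevel=2)
        gamma_a = np.clip(gamma_a, -lim, lim)
        gamma_b = np.clip(gamma_b, -lim, lim)
    train = SummaryStats.from_r(
        full.snp_id, full.allele1, full.allele2,
        np.full(full.m, n_a, dtype=np.int64), gamma_a,
    )
    test = SummaryStats.from_r(
        full.snp_id, full.allele1, full.allele2,
        np.full(full.m, n_b, dtype=np.int64), gamma_b,
    )
    return PseudoSumstats(train=train, test=test, frac=frac, seed=seed,
                          n_a=n_a, n_b=n_b)


# ---------------------------------------------------------------------------
# sliding-window solver


def _build_windows(panel: SnpPanel, window_cm: float, step_cm: float):
    """Window index ranges per chromosome, stepping step_cm along the map."""
    starts: list[int] = []
    ends: list[int] = []
    for chrom in np.unique(panel.chromosome):
        sel = np.where(panel.chromosome == chrom)[0]
        cm = panel.cm_position[sel]
        off = int(sel[0])
        pos = float(cm[0])
        last = float(cm[-1])
        while pos <= last:
            i0 = int(np.searchsorted(cm, pos, side="left"))
            i1 = int(np.searchsorted(cm, pos + window_cm, side="left"))
            if i1 > i0:
                starts.append(off + i0)
                ends.append(off + i1)
            pos += step_cm
    return (np.asarray(starts, dtype=np.int64),
            np.asarray(ends, dtype=np.int64))


def _prior_arrays(spec: PriorSpec, e_j: np.ndarray):
    comp = component_variances(spec, e_j)
    if comp.kind == "laplace":
        rates = np.ascontiguousarray(np.asarray(comp.rate, dtype=np.float64))
        return (np.ones(1), np.zeros((len(e_j), 1)), rates, True)
    weights = np.ascontiguousarray(comp.weights, dtype=np.float64)
    variances = np.ascontiguousarray(comp.variances, dtype=np.float64)
    return (weights, variances, np.zeros(len(e_j)), False)


def solve_windows(ss: SummaryStats, store: LdPairStore, panel: SnpPanel,
                  spec: PriorSpec, e_j: np.ndarray,
                  window_cm: float = 1.0, step_cm: float = 0.125,
                  tol: float = 1e-5, max_iter: int = 50,
                  beta0: np.ndarray | None = None):
    """Sliding-window conditional-mean updates on summary statistics.

    Each 1 cM window is iterated until the estimated variance explained by
    its SNPs (beta_w^T C_w beta_w with stored LD) changes by less than
    ``tol``; the window then slides ``step_cm`` along the genome. Within a
    window the residual variance is taken as 1. Windows failing to
    converge within ``max_iter`` iterations are rolled back and counted.
    Returns (beta, diagnostics).
    """
    if ss.m != store.m or ss.m != panel.m:
        raise ValueError("summary statistics, store and panel misaligned")
    n = float(np.mean(ss.n))
    nr = ss.n.astype(np.float64) * ss.r
    wstart, wend = _build_windows(panel, window_cm, step_cm)
    weights, variances, rates, use_laplace = _prior_arrays(spec, e_j)
    if beta0 is None:
        beta0 = np.zeros(ss.m)
    beta, resets = _kernels.solve_windows_kernel(
        nr, n, store.indptr, store.indices, store.values,
        wstart, wend, weights, variances, rates, use_laplace,
        1.0, tol, max_iter, np.asarray(beta0, dtype=np.float64),
    )
    if resets:
        logger.info("solve_windows: %d of %d windows reset", resets,
                    len(wstart))
    return beta, {"window_resets": int(resets), "n_windows": len(wstart)}


# ---------------------------------------------------------------------------
# prior grids


def bayesr_triplets(ordered: bool = True):
    """(pi2, pi3, pi4) triplets over {0, 0.01, 0.05, 0.1, 0.2}.

    With the ordering restriction pi4 <= pi3 <= pi2 and sum > 0 there are
    34; without any restriction there are 125.
    """
    if ordered:
        return [
            (p2, p3, p4)
            for p2, p3, p4 in itertools.product(_BAYESR_VALUES, repeat=3)
            if p4 <= p3 <= p2 and p2 + p3 + p4 > 0
        ]
    return list(itertools.product(_BAYESR_VALUES, repeat=3))


def default_grid(tool: str, base: PriorSpec | None = None,
                 ordered: bool = True) -> list[PriorSpec]:
    """Default cross-validation grid of prior parameters per tool.

    ridge/lasso: 11 global prior-variance scale factors; bolt: 18 (p, f2)
    pairs; bayesr: the ridge configuration plus 34 ordered slab triplets
    (35 total; 126 with the ordering restriction dropped).
    """
    if tool == "ridge":
        v0 = base.v if base is not None else 1.0
        return [PriorSpec.ridge(v=v0 * s) for s in _SCALE_FACTORS]
    if tool == "lasso":
        lam0 = base.lam if base is not None else float(np.sqrt(2.0))
        # scale factor applies to the prior variance, i.e. to lambda^-2
        return [PriorSpec.lasso(lam=lam0 / np.sqrt(s)) for s in _SCALE_FACTORS]
    if tool == "bolt":
        return [PriorSpec.bolt(p, f2) for p in _BOLT_P for f2 in _BOLT_F2]
    if tool == "bayesr":
        grid = [PriorSpec.bayesr(0.0, 0.0, 1.0)]
        for p2, p3, p4 in bayesr_triplets(ordered=ordered):
            grid.append(PriorSpec.bayesr(p2, p3, p4))
        return grid
    raise ValueError(f"unknown tool {tool!r}")


# ---------------------------------------------------------------------------
# scoring


def _region_mask(panel: SnpPanel, regions) -> np.ndarray:
    mask = np.zeros(panel.m, dtype=bool)
    for chrom, start, end in regions:
        mask |= (
            (panel.chromosome == chrom)
            & (panel.bp_position >= start)
            & (panel.bp_position <= end)
        )
    return mask


def score_pseudo_R(beta: np.ndarray, test_ss: SummaryStats,
                   store_b: LdPairStore, panel: SnpPanel | None = None,
                   exclude_regions=None) -> ModelScore:
    """R = beta^T X^T Y / (n beta^T X^T X beta)^{1/2} from test statistics.

    X^T Y comes from the test summary statistics and X^T X = n C from the
    scoring reference panel, which must be distinct from the panel used to
    build the models. SNPs inside ``exclude_regions`` (long-range LD) are
    zeroed before scoring. An all-zero model scores -inf for ranking.
    """
    beta = np.asarray(beta, dtype=float).copy()
    if exclude_regions:
        if panel is None:
            raise ValueError("exclude_regions needs the SNP panel")
        beta[_region_mask(panel, exclude_regions)] = 0.0
    if np.all(beta == 0):
        return ModelScore(r=-np.inf, numerator=0.0, denominator=0.0)
    num = float(beta @ test_ss.r)
    quad = float(beta @ beta + beta @ (store_b.to_sparse() @ beta))
    if quad <= 0:
        return ModelScore(r=-np.inf, numerator=num, denominator=0.0)
    denom = float(np.sqrt(quad))
    return ModelScore(r=num / denom, numerator=num, denominator=denom)


# ---------------------------------------------------------------------------
# the full pipeline


def run_megaprs(full_ss: SummaryStats, G_ref_ab: GenotypeMatrix,
                G_ref_c: GenotypeMatrix, panel: SnpPanel, tool: str,
                hermodel_kind: str = "gcta",
                custom_annotations: np.ndarray | None = None,
                config: MegaConfig | None = None, seed: int = 0,
                stores: tuple | None = None) -> PrsModel:
    """End-to-end summary-statistic PRS construction.

    Returns the full-statistics model whose training twin scored the
    highest pseudo-test R; the per-candidate score table is attached under
    ``extras['candidates']``. Precomputed (store_ab, store_c) LD panels may
    be passed via ``stores`` to skip Step 1.
    """
    cfg = config or MegaConfig()
    if full_ss.m != panel.m:
        raise ValueError("summary statistics must be harmonized to the panel")
    try:
        if stores is not None:
            store_ab, store_c = stores
        else:
            store_ab = compute_ld_pairs(
                G_ref_ab, panel, cfg.ld_window_cm, cfg.ld_p_threshold
            )
            store_c = compute_ld_pairs(
                G_ref_c, panel, cfg.ld_window_cm, cfg.ld_p_threshold
            )
    except Exception as exc:
        raise RuntimeError(f"step 1 (LD estimation) failed: {exc}") from exc

    try:
        ann = build_annotations(
            panel, hermodel_kind, G_ref=G_ref_ab,
            custom_table=custom_annotations,
        )
        fitted = fit_taus(full_ss, store_ab, ann)
        e_j = fitted.e_j
    except Exception as exc:
        raise RuntimeError(f"heritability-model fit failed: {exc}") from exc

    pseudo = make_pseudo_sumstats(full_ss, G_ref_ab, cfg.pseudo_frac, seed)
    grid = cfg.grid if cfg.grid is not None else default_grid(tool)
    if not grid:
        raise ValueError("empty prior grid")

    best_idx = -1
    best_r = -np.inf
    best_beta = None
    best_resets = 0
    candidates = []
    for i, spec in enumerate(grid):
        beta_train, diag_tr = solve_windows(
            pseudo.train, store_ab, panel, spec, e_j,
            cfg.window_cm, cfg.step_cm, cfg.tol, cfg.max_iter,
        )
        beta_full, diag_full = solve_windows(
            full_ss, store_ab, panel, spec, e_j,
            cfg.window_cm, cfg.step_cm, cfg.tol, cfg.max_iter,
        )
        score = score_pseudo_R(
            beta_train, pseudo.test, store_c, panel, cfg.exclude_regions
        )
        candidates.append(
            {"prior": spec.label(), "pseudo_R": score.r,
             "train_resets": diag_tr["window_resets"],
             "full_resets": diag_full["window_resets"]}
        )
        if score.r > best_r:
            best_idx = i
            best_r = score.r
            best_beta = beta_full
            best_resets = diag_full["window_resets"]
    if best_beta is None:
        raise RuntimeError("step 3 produced no scoreable model")
    return PrsModel(
        snp_id=panel.snp_id, allele1=panel.allele1, allele2=panel.allele2,
        beta=best_beta, centre=2.0 * panel.maf,
        sd=np.sqrt(2.0 * panel.maf * (1.0 - panel.maf)),
        prior=grid[best_idx], hermodel=hermodel_kind, score_r=best_r,
        window_resets=best_resets,
        extras={"candidates": candidates, "e_j": e_j, "tau": fitted.tau},
    )
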