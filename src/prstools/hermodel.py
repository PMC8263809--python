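"""Heritability models: E[h2_j] as a linear function of SNP annotations.

E[h2_j] = sum_k a_jk tau_k, where the a_jk are pre-specified annotations
(all-ones for the constant model; w_j [2 p_j (1-p_j)]^0.75 with duplicate
thinning for the MAF-dependent model; arbitrary user columns otherwise).
The tau_k are estimated by regressing observed chi-squared statistics on
their expectation under the model,

    E[S_j] = 1 + n * sum_k tau_k * (sum_l c2_jl a_lk),

with the inner sums supplied by :func:`prstools.ld.ld_scores`. The fitted
model yields per-SNP expected heritabilities e_j (floored at a small
positive value so every prior variance stays positive) and the residual
variance sigma2_e = 1 - sum_j e_j.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .formats import GenotypeMatrix, SnpPanel, SummaryStats
from .ld import LdPairStore, ld_scores

SIGMA2_E_MIN = 0.05


@dataclass
class HeritabilityModel:
    annotations: np.ndarray          # m x K
    names: list
    tau: np.ndarray | None = None
    tau_se: np.ndarray | None = None
    e_j: np.ndarray | None = None
    sigma2_e: float | None = None

    @property
    def m(self) -> int:
        return self.annotations.shape[0]

    @property
    def K(self) -> int:
        return self.annotations.shape[1]


def thin_duplicates(panel: SnpPanel, G_ref: GenotypeMatrix,
                    window_bp: int = 100_000, r2_max: float = 0.98) -> np.ndarray:
    """Greedy duplicate thinning: keep a SNP unless it is near-identical
    (c^2 > r2_max within window_bp) to an already-kept SNP."""
    X = G_ref.standardized()
    n = G_ref.n
    bp = panel.bp_position
    chrom = panel.chromosome
    keep = np.ones(panel.m, dtype=bool)
    kept: list[int] = []
    for j in range(panel.m):
        ok = True
        for k in reversed(kept):
            if chrom[k] != chrom[j] or bp[j] - bp[k] > window_bp:
                break
            c = float(X[:, k] @ X[:, j]) / n
            if c * c > r2_max:
                ok = False
                break
        if ok:
            kept.append(j)
        else:
            keep[j] = False
    return keep


def build_annotations(panel: SnpPanel, kind: str,
                      G_ref: GenotypeMatrix | None = None,
                      custom_table: np.ndarray | None = None,
                      thin_window_bp: int = 100_000,
                      thin_r2: float = 0.98) -> HeritabilityModel:
    """Construct the annotation matrix for a named heritability model.

    kind='gcta'      -> single all-ones column (constant E[h2_j])
    kind='ldak-thin' -> single column w_j [2 p_j (1-p_j)]^0.75, with w_j=1
                        for survivors of duplicate thinning
    kind='custom'    -> user-supplied table (m x K)
    """
    if kind == "gcta":
        A = np.ones((panel.m, 1))
        return HeritabilityModel(A, ["Base"])
    if kind == "ldak-thin":
        if G_ref is None:
            raise ValueError("ldak-thin annotations need reference genotypes")
        w = thin_duplicates(panel, G_ref, thin_window_bp, thin_r2)
        p = panel.maf
        A = (w * (2.0 * p * (1.0 - p)) ** 0.75)[:, None]
        return HeritabilityModel(A, ["LDAK-Thin"])
    if kind == "custom":
        if custom_table is None:
            raise ValueError("custom model needs an annotation table")
        A = np.atleast_2d(np.asarray(custom_table, dtype=float))
        if A.shape[0] != panel.m:
            A = A.T
        if A.shape[0] != panel.m or A.shape[1] < 1:
            raise ValueError("annotation table misaligned with panel")
        if not np.all(np.isfinite(A)):
            raise ValueError("annotations must be finite")
        if np.all(A <= 0):
            raise ValueError("annotation table is non-positive everywhere")
        return HeritabilityModel(A, [f"A{k + 1}" for k in range(A.shape[1])])
    raise ValueError(f"unknown heritability model kind {kind!r}")


def expected_stat(taus: np.ndarray, scores: np.ndarray, n) -> np.ndarray:
    """E[S_j] = 1 + n * sum_k tau_k * ldscore_jk."""
    taus = np.asarray(taus, dtype=float)
    scores = np.atleast_2d(np.asarray(scores, dtype=float))
    if scores.shape[1] != len(taus):
        raise ValueError("tau / LD-score shape mismatch")
    return 1.0 + np.asarray(n, dtype=float) * (scores @ taus)


def fit_taus(ss: SummaryStats, store: LdPairStore,
             model: HeritabilityModel,
             snp_weights: np.ndarray | None = None) -> HeritabilityModel:
    """Least-squares estimate of tau from S_j - 1 = n_j sum_k tau_k l_jk.

    No intercept and no confounding-inflation term. ``snp_weights`` is an
    optional per-SNP weighting hook (defaults to unweighted OLS).
    """
    A = model.annotations
    if A.shape[1] >= ss.m:
        raise ValueError("more annotations than SNPs")
    scores = ld_scores(store, A)
    design = ss.n[:, None] * scores
    y = ss.stat - 1.0
    if snp_weights is not None:
        sw = np.sqrt(np.asarray(snp_weights, dtype=float))
        design = design * sw[:, None]
        y = y * sw
    gram = design.T @ design
    cond = np.linalg.cond(gram)
    if not np.isfinite(cond) or cond > 1e12:
        corr = np.corrcoef(design.T)
        bad = [
            (model.names[i], model.names[j])
            for i in range(len(model.names))
            for j in range(i + 1, len(model.names))
            if abs(corr[i, j]) > 0.9999
        ]
        raise ValueError(f"singular design; collinear annotations: {bad}")
    tau = np.linalg.solve(gram, design.T @ y)
    resid = y - design @ tau
    dof = max(len(y) - A.shape[1], 1)
    sigma2 = float(resid @ resid) / dof
    se = np.sqrt(np.diag(np.linalg.inv(gram)) * sigma2)
    fitted = HeritabilityModel(A, model.names, tau=tau, tau_se=se)
    fitted.e_j, fitted.sigma2_e = per_snp_expectations(tau, A)
    return fitted


def per_snp_expectations(taus: np.ndarray, annotations: np.ndarray,
                         floor: float | None = None):
    """e_j = sum_k a_jk tau_k (floored positive) and sigma2_e = 1 - sum e_j.

    The floor keeps every prior variance positive; sigma2_e is clamped at
    SIGMA2_E_MIN with a warning when sum(e_j) >= 0.95, since sampling noise
    can push the summed expectations past 1.
    """
    A = np.atleast_2d(np.asarray(annotations, dtype=float))
    e = A @ np.asarray(taus, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite per-SNP expectations")
    if floor is None:
        scale = float(np.clip(e, 0.0, None).mean())
        floor = max(1e-10 * scale, 1e-16)
    e = np.maximum(e, floor)
    total = float(e.sum())
    if total >= 0.95:
        warnings.warn(
            f"sum of per-SNP expected heritabilities is {total:.3f}; "
            f"residual variance clamped to {SIGMA2_E_MIN}",
            stacklevel=2,
        )
        return e, SIGMA2_E_MIN
    return e, 1.0 - total
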