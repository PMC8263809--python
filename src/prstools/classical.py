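"""Classical clumping+thresholding PRS and evaluation metrics.

The classical score keeps, greedily by significance, index SNPs whose
stored LD with any more significant kept SNP stays below a c^2 threshold,
and uses the marginal correlations r_j of the kept SNPs as effect sizes.
A small grid of p-value and clumping thresholds is tuned on validation
data (individual-level R^2, or pseudo-test R for summary data).

Metrics: R^2 (squared observed/predicted correlation) with a delete-one-
block jackknife standard deviation, mean absolute error on standardized
scales, and AUC for binary traits.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .formats import GenotypeMatrix, Phenotype, SnpPanel, SummaryStats
from .ld import LdPairStore
from .megaprs import score_pseudo_R
from .model import PrsModel

logger = logging.getLogger(__name__)

P_THRESHOLDS = (5e-8, 1e-4, 1e-3, 0.01, 0.1, 1.0)
R2_THRESHOLDS = (0.2, 0.5, 0.8, None)  # None = no clumping


@dataclass
class ClumpResult:
    kept: np.ndarray            # index SNPs in selection order
    keep_flag: np.ndarray       # per-SNP kept indicator
    p_max: float
    r2_max: float | None


@dataclass
class Metrics:
    r2: float
    mae: float
    auc: float | None
    jackknife_sd: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r2 <= 1.0):
            raise ValueError("R^2 out of range")
        if self.jackknife_sd < 0:
            raise ValueError("jackknife s.d. must be non-negative")


def p_values(ss: SummaryStats) -> np.ndarray:
    """Two-sided p-values from the chi-squared(1) statistics."""
    return chi2.sf(ss.stat, df=1)


def clump(ss: SummaryStats, store: LdPairStore, p_max: float = 1.0,
          r2_max: float | None = None) -> ClumpResult:
    """Greedy clumping: repeatedly keep the most significant remaining SNP
    and remove its stored neighbours with c^2 above ``r2_max``."""
    pv = p_values(ss)
    order = np.argsort(pv, kind="stable")
    removed = np.zeros(ss.m, dtype=bool)
    keep_flag = np.zeros(ss.m, dtype=bool)
    kept: list[int] = []
    for j in order:
        if removed[j] or pv[j] > p_max:
            continue
        kept.append(int(j))
        keep_flag[j] = True
        if r2_max is not None:
            nbr, c = store.neighbors(j)
            removed[nbr[c * c > r2_max]] = True
    return ClumpResult(
        kept=np.asarray(kept, dtype=np.int64), keep_flag=keep_flag,
        p_max=p_max, r2_max=r2_max,
    )


def classical_grid_fit(ss_train: SummaryStats, store: LdPairStore,
                       test_ss: SummaryStats | None = None,
                       store_b: LdPairStore | None = None,
                       valid_G: GenotypeMatrix | None = None,
                       valid_Y=None,
                       ss_full: SummaryStats | None = None,
                       panel: SnpPanel | None = None,
                       p_thresholds=P_THRESHOLDS,
                       r2_thresholds=R2_THRESHOLDS) -> PrsModel:
    """Tune (p, c^2) thresholds and return the refitted classical model.

    Candidates are scored either by pseudo-test R (give ``test_ss`` and
    ``store_b``) or by validation R^2 (give ``valid_G`` and ``valid_Y``).
    The winning thresholds are re-applied to ``ss_full`` (defaults to
    ``ss_train``) to produce the final model.
    """
    summary_route = test_ss is not None
    if summary_route and store_b is None:
        raise ValueError("summary-route validation needs a second LD store")
    if not summary_route and (valid_G is None or valid_Y is None):
        raise ValueError("need either test sumstats or validation data")
    best = (-np.inf, None)
    any_kept = False
    for p_max in p_thresholds:
        for r2_max in r2_thresholds:
            res = clump(ss_train, store, p_max, r2_max)
            beta = np.where(res.keep_flag, ss_train.r, 0.0)
            if len(res.kept) == 0:
                continue
            any_kept = True
            if summary_route:
                score = score_pseudo_R(beta, test_ss, store_b).r
            else:
                y = (valid_Y.values if isinstance(valid_Y, Phenotype)
                     else np.asarray(valid_Y, float))
                pred = valid_G.standardized() @ beta
                if pred.std() == 0:
                    score = 0.0
                else:
                    score = float(np.corrcoef(y, pred)[0, 1] ** 2)
            if score > best[0]:
                best = (score, (p_max, r2_max))
    ids = ss_train.snp_id
    if not any_kept or best[1] is None:
        warnings.warn("no candidate kept any SNP; returning a zero model",
                      stacklevel=2)
        beta_final = np.zeros(ss_train.m)
        thresholds = (np.nan, np.nan)
        score = 0.0
    else:
        score, thresholds = best
        refit_ss = ss_full if ss_full is not None else ss_train
        res = clump(refit_ss, store, *thresholds)
        beta_final = np.where(res.keep_flag, refit_ss.r, 0.0)
    if panel is not None:
        return PrsModel.from_panel(
            panel, beta_final, prior=None, score_r=score,
            extras={"thresholds": thresholds},
        )
    m = ss_train.m
    return PrsModel(
        snp_id=ids, allele1=ss_train.allele1, allele2=ss_train.allele2,
        beta=beta_final, centre=np.zeros(m), sd=np.ones(m),
        score_r=score, extras={"thresholds": thresholds},
    )


def predict_scores(G_test: GenotypeMatrix, model: PrsModel,
                   panel: SnpPanel | None = None) -> np.ndarray:
    """Per-individual polygenic scores: standardized genotypes x beta.

    If ``panel`` describes the test genotypes, SNPs are aligned by id;
    model SNPs missing from the panel contribute 0 (logged).
    """
    if panel is not None:
        pos = {sid: j for j, sid in enumerate(panel.snp_id)}
        cols = np.array([pos.get(s, -1) for s in model.snp_id])
        missing = int((cols < 0).sum())
        if missing == len(cols):
            raise ValueError("no model SNPs present in the test panel")
        if missing:
            logger.info("predict_scores: %d model SNPs absent from panel",
                        missing)
        beta = np.zeros(panel.m)
        ok = cols >= 0
        beta[cols[ok]] = model.beta[ok]
    else:
        if G_test.m != model.m:
            raise ValueError("test genotypes misaligned with model")
        beta = model.beta
    X = G_test.standardized()
    return (X @ beta.astype(X.dtype)).astype(np.float64)


def predict_scores_raw(dosages: np.ndarray, model: PrsModel) -> np.ndarray:
    """Raw-scale scoring: (dosage - centre) x Effect_raw."""
    raw_eff = model.beta / model.sd
    return (np.asarray(dosages, float) - model.centre) @ raw_eff


def evaluate(obs, pred, binary: bool = False, blocks: int = 200) -> Metrics:
    """R^2, MAE, optional AUC, and a delete-one-block jackknife s.d. of R^2."""
    y = obs.values if isinstance(obs, Phenotype) else np.asarray(obs, float)
    p = np.asarray(pred, dtype=float)
    if len(y) != len(p):
        raise ValueError("length mismatch")
    n = len(y)
    if n < blocks:
        raise ValueError("need at least as many observations as blocks")

    def _r2(yy, pp):
        if pp.std() == 0 or yy.std() == 0:
            return 0.0
        return float(np.corrcoef(yy, pp)[0, 1] ** 2)

    if p.std() == 0:
        warnings.warn("constant predictions; R^2 reported as 0", stacklevel=2)
    r2 = _r2(y, p)

    ys = (y - y.mean()) / y.std() if y.std() > 0 else y - y.mean()
    ps = (p - p.mean()) / p.std() if p.std() > 0 else p - p.mean()
    mae = float(np.mean(np.abs(ys - ps)))

    auc = None
    if binary:
        labels = np.unique(y)
        if len(labels) != 2:
            raise ValueError("binary evaluation needs exactly two classes")
        pos = p[y == labels.max()]
        neg = p[y == labels.min()]
        # Mann-Whitney statistic scaled to [0, 1]
        rank = np.argsort(np.argsort(np.concatenate([pos, neg])))
        r_pos = rank[: len(pos)] + 1.0
        u = r_pos.sum() - len(pos) * (len(pos) + 1) / 2.0
        auc = float(u / (len(pos) * len(neg)))

    edges = np.linspace(0, n, blocks + 1).astype(int)
    loo = np.empty(blocks)
    for b in range(blocks):
        mask = np.ones(n, dtype=bool)
        mask[edges[b]: edges[b + 1]] = False
        loo[b] = _r2(y[mask], p[mask])
    jk_sd = float(np.sqrt((blocks - 1) / blocks * ((loo - loo.mean()) ** 2).sum()))
    return Metrics(r2=r2, mae=mae, auc=auc, jackknife_sd=jk_sd)
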