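"""Effect-size priors and conditional-posterior updates.

Four prior families are supported, all parameterised through e_j, the
expected heritability of SNP j under the assumed heritability model:

* lasso  — double exponential, beta_j ~ DE(lambda / sqrt(e_j))
* ridge  — single Gaussian, beta_j ~ N(0, v e_j)
* bolt   — two Gaussians, p N(0, (1-f2)/p e_j) + (1-p) N(0, f2/(1-p) e_j)
* bayesr — point mass plus three Gaussians with variances
           (0, s e_j/100, s e_j/10, s e_j), s = (pi2/100 + pi3/10 + pi4)^-1

For bolt and bayesr the mixture variance equals e_j for every admissible
parameter choice; for ridge it is v e_j; the lasso rate is chosen so the
prior variance is 2 e_j / lambda^2.

Given t_j = X_j^T (residual + X_j beta_j) and X_j^T X_j, the conditional
posterior of beta_j is a mixture of Gaussians (or a two-piece truncated
Gaussian for the lasso); ``conditional_update`` returns its components and
moments. All responsibility computations run in log space.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels

_TOOLS = ("lasso", "ridge", "bolt", "bayesr")


@dataclass(frozen=True)
class PriorSpec:
    """Prior family and its tool-level parameters."""

    tool: str
    lam: float = np.sqrt(2.0)     # lasso rate scale
    v: float = 1.0                # ridge variance scale
    p: float = 0.5                # bolt mixing weight of the big component
    f2: float = 0.5               # bolt share of variance in the small component
    pis: tuple = (0.0, 0.0, 0.0, 1.0)  # bayesr (pi1, pi2, pi3, pi4)

    def __post_init__(self) -> None:
        if self.tool not in _TOOLS:
            raise ValueError(f"unknown tool {self.tool!r}")
        if self.tool == "bolt":
            if not (0.0 < self.p <= 1.0):
                raise ValueError("bolt p must lie in (0, 1]")
            if self.p < 1.0 and not (0.0 < self.f2 < 1.0):
                raise ValueError("bolt f2 must lie in (0, 1)")
        if self.tool == "bayesr":
            pis = np.asarray(self.pis, dtype=float)
            if pis.shape != (4,) or np.any(pis < 0):
                raise ValueError("bayesr needs four non-negative pi values")
            if abs(pis.sum() - 1.0) > 1e-12:
                raise ValueError("bayesr pi values must sum to 1")
        if self.tool == "lasso" and self.lam <= 0:
            raise ValueError("lasso scale must be positive")
        if self.tool == "ridge" and self.v <= 0:
            raise ValueError("ridge scale must be positive")

    @property
    def s(self) -> float:
        """BayesR variance scale s = (pi2/100 + pi3/10 + pi4)^-1."""
        _, pi2, pi3, pi4 = self.pis
        denom = pi2 / 100.0 + pi3 / 10.0 + pi4
        if denom <= 0:
            raise ValueError("bayesr slab weights are all zero")
        return 1.0 / denom

    def label(self) -> str:
        if self.tool == "lasso":
            return f"lasso(lam={self.lam:.4g})"
        if self.tool == "ridge":
            return f"ridge(v={self.v:.4g})"
        if self.tool == "bolt":
            return f"bolt(p={self.p:.4g},f2={self.f2:.4g})"
        return "bayesr(pi=%s)" % (",".join(f"{x:.4g}" for x in self.pis))

    # constructors
    @classmethod
    def lasso(cls, lam: float = np.sqrt(2.0)) -> "PriorSpec":
        return cls(tool="lasso", lam=lam)

    @classmethod
    def ridge(cls, v: float = 1.0) -> "PriorSpec":
        return cls(tool="ridge", v=v)

    @classmethod
    def bolt(cls, p: float, f2: float) -> "PriorSpec":
        return cls(tool="bolt", p=p, f2=f2)

    @classmethod
    def bayesr(cls, pi2: float, pi3: float, pi4: float) -> "PriorSpec":
        pi1 = 1.0 - pi2 - pi3 - pi4
        return cls(tool="bayesr", pis=(pi1, pi2, pi3, pi4))


@dataclass
class PriorComponents:
    """Per-SNP realised prior: Gaussian mixture or Laplace rate."""

    kind: str                      # "mixture" or "laplace"
    weights: np.ndarray | None = None    # (C,)
    variances: np.ndarray | None = None  # (..., C); 0 = point mass
    rate: np.ndarray | float | None = None

    def mixture_variance(self):
        return (self.variances * self.weights).sum(axis=-1)


def component_variances(spec: PriorSpec, e_j) -> PriorComponents:
    """Realise the prior for SNP(s) with expected heritability e_j."""
    e_j = np.asarray(e_j, dtype=float)
    if np.any(e_j <= 0):
        raise ValueError("e_j must be positive")
    if spec.tool == "ridge":
        return PriorComponents(
            kind="mixture",
            weights=np.array([1.0]),
            variances=(spec.v * e_j)[..., None],
        )
    if spec.tool == "bolt":
        if spec.p == 1.0:
            return PriorComponents(
                kind="mixture", weights=np.array([1.0]),
                variances=e_j[..., None],
            )
        w = np.array([spec.p, 1.0 - spec.p])
        var = np.stack(
            [(1.0 - spec.f2) / spec.p * e_j, spec.f2 / (1.0 - spec.p) * e_j],
            axis=-1,
        )
        return PriorComponents(kind="mixture", weights=w, variances=var)
    if spec.tool == "bayesr":
        s = spec.s
        w = np.asarray(spec.pis, dtype=float)
        var = np.stack(
            [np.zeros_like(e_j), s * e_j / 100.0, s * e_j / 10.0, s * e_j],
            axis=-1,
        )
        return PriorComponents(kind="mixture", weights=w, variances=var)
    # lasso: DE rate lambda / sqrt(e_j)
    return PriorComponents(kind="laplace", rate=spec.lam / np.sqrt(e_j))


@dataclass
class PosteriorMoments:
    """Conditional posterior of one effect size: components and moments."""

    means: np.ndarray
    variances: np.ndarray
    responsibilities: np.ndarray
    mean: float
    second_moment: float

    def __post_init__(self) -> None:
        r = self.responsibilities
        if np.any(r < -1e-12) or abs(r.sum() - 1.0) > 1e-9:
            raise ValueError("responsibilities must be a distribution")


def conditional_update(spec: PriorSpec, e_j: float, t_j: float, xtx_j: float,
                       s2_e: float, mode: bool = False) -> PosteriorMoments:
    """Conditional posterior of beta_j given all other effects.

    t_j is X_j^T (residual + X_j beta_j); xtx_j is X_j^T X_j. For the
    lasso, ``mode=True`` returns the posterior mode (soft threshold) as
    the point estimate instead of the posterior mean.
    """
    if s2_e <= 0 or xtx_j <= 0:
        raise ValueError("s2_e and xtx_j must be positive")
    comp = component_variances(spec, float(e_j))
    if comp.kind == "laplace":
        rate = float(comp.rate)
        mean, second = _kernels.laplace_update(t_j, xtx_j, s2_e, rate)
        point = _kernels.laplace_mode(t_j, xtx_j, s2_e, rate) if mode else mean
        # report the two truncated pieces as components
        s2 = s2_e / xtx_j
        mu_p = (t_j - rate * s2_e) / xtx_j
        mu_m = (t_j + rate * s2_e) / xtx_j
        s = np.sqrt(s2)
        lw = np.array([
            0.5 * mu_p**2 / s2 + _kernels.log_ndtr(mu_p / s),
            0.5 * mu_m**2 / s2 + _kernels.log_ndtr(-mu_m / s),
        ])
        w = np.exp(lw - lw.max())
        w /= w.sum()
        return PosteriorMoments(
            means=np.array([mu_p, mu_m]), variances=np.array([s2, s2]),
            responsibilities=w, mean=point, second_moment=second,
        )
    weights = comp.weights
    variances = np.atleast_1d(np.asarray(comp.variances, dtype=float))
    mean, second = _kernels.gaussian_mixture_update(
        t_j, xtx_j, s2_e, weights, variances
    )
    # recompute component detail (same math as the kernel)
    mus = np.zeros_like(variances)
    vs = np.zeros_like(variances)
    logr = np.full_like(variances, -np.inf)
    live = weights > 0
    slab = live & (variances > 0)
    denom = xtx_j + s2_e / variances[slab]
    mus[slab] = t_j / denom
    vs[slab] = s2_e / denom
    logr[slab] = (
        np.log(weights[slab]) + 0.5 * (np.log(vs[slab]) - np.log(variances[slab]))
        + 0.5 * mus[slab] ** 2 / vs[slab]
    )
    point_mass = live & (variances <= 0)
    logr[point_mass] = np.log(weights[point_mass])
    r = np.exp(logr - logr.max())
    r /= r.sum()
    return PosteriorMoments(
        means=mus, variances=vs, responsibilities=r,
        mean=mean, second_moment=second,
    )


def posterior_h2_contribution(moments: PosteriorMoments) -> float:
    """E[beta_j^2] under the conditional posterior."""
    return float(moments.second_moment)
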