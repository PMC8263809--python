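import numpy as np
import pytest
from scipy import integrate

import prstools as pt


@pytest.fixture(scope="session")
def toy_sim():
    """Small simulated dataset shared across tests: genotypes with LD,
    a polygenic trait at h2 = 0.5, GWAS summaries and an LD store."""
    cfg = pt.SimConfig(n=600, m=150, h2=0.5, rho=0.6, seed=11)
    panel, G = pt.simulate_genotypes(cfg)
    eff = pt.simulate_effects(panel, np.ones(cfg.m), pt.PriorSpec.ridge(),
                              cfg.h2, seed=12)
    y = pt.simulate_phenotype(G, eff, seed=13)
    ss = pt.gwas_linear(G, y, panel)
    store = pt.compute_ld_pairs(G, panel)
    return {"cfg": cfg, "panel": panel, "G": G, "effects": eff,
            "pheno": y, "ss": ss, "store": store}


def quadrature_posterior(t, xtx, s2e, prior_logpdf, lim=3.0):
    """Independent oracle: posterior mean and second moment of a single
    effect by numerical integration of likelihood x prior."""

    def unnorm(b):
        return np.exp(t * b / s2e - xtx * b * b / (2 * s2e) + prior_logpdf(b))

    z, _ = integrate.quad(unnorm, -lim, lim, limit=400)
    m1, _ = integrate.quad(lambda b: b * unnorm(b), -lim, lim, limit=400)
    m2, _ = integrate.quad(lambda b: b * b * unnorm(b), -lim, lim, limit=400)
    return m1 / z, m2 / z


def quadrature_posterior_mixture(t, xtx, s2e, weights, variances, lim=3.0):
    """Quadrature oracle for a Gaussian mixture prior that may include a
    point mass at zero (zero variance component): the point mass keeps
    likelihood weight exp(0) = 1 and contributes nothing to the moments."""
    weights = np.asarray(weights, float)
    variances = np.asarray(variances, float)
    slab = (weights > 0) & (variances > 0)
    w_pm = weights[(weights > 0) & (variances <= 0)].sum()
    logpdf = gaussian_mixture_logpdf(weights[slab], variances[slab])

    def unnorm(b):
        return np.exp(t * b / s2e - xtx * b * b / (2 * s2e) + logpdf(b))

    z, _ = integrate.quad(unnorm, -lim, lim, limit=400)
    m1, _ = integrate.quad(lambda b: b * unnorm(b), -lim, lim, limit=400)
    m2, _ = integrate.quad(lambda b: b * b * unnorm(b), -lim, lim, limit=400)
    z_tot = z + w_pm
    return m1 / z_tot, m2 / z_tot


def gaussian_mixture_logpdf(weights, variances):
    weights = np.asarray(weights, float)
    variances = np.asarray(variances, float)

    def logpdf(b):
        dens = 0.0
        for w, v in zip(weights, variances):
            if w <= 0:
                continue
            dens += w * np.exp(-b * b / (2 * v)) / np.sqrt(2 * np.pi * v)
        if dens == 0.0:
            return -np.inf
        return np.log(dens)

    return logpdf


def laplace_logpdf(rate):
    return lambda b: np.log(rate / 2.0) - rate * abs(b)
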