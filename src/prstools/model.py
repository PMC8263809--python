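"""Shared polygenic-score model container."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np


@dataclass
class PrsModel:
    """Per-SNP effect sizes on the standardized scale, with score metadata.

    ``centre`` and ``sd`` are the training-panel column means and standard
    deviations of the raw dosages, so effects can be exported on the raw
    scale (Effect_raw = beta / sd) and raw-dosage scoring of centred
    genotypes reproduces standardized scoring.
    """

    snp_id: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    beta: np.ndarray
    centre: np.ndarray
    sd: np.ndarray
    prior: Any = None
    hermodel: str | None = None
    score_r: float | None = None
    window_resets: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        self.beta = np.asarray(self.beta, dtype=np.float64)
        self.centre = np.asarray(self.centre, dtype=np.float64)
        self.sd = np.asarray(self.sd, dtype=np.float64)
        if not np.all(np.isfinite(self.beta)):
            raise ValueError("effect sizes must be finite")

    @property
    def m(self) -> int:
        return len(self.snp_id)

    @classmethod
    def from_panel(cls, panel, beta, G=None, **kwargs) -> "PrsModel":
        """Build a model aligned to a SnpPanel; centres/sds from G if given."""
        if G is not None:
            centre, sd = G.col_means, G.col_sds
        else:
            centre = 2.0 * panel.maf
            sd = np.sqrt(2.0 * panel.maf * (1.0 - panel.maf))
        return cls(
            snp_id=panel.snp_id, allele1=panel.allele1, allele2=panel.allele2,
            beta=np.asarray(beta, dtype=np.float64),
            centre=np.asarray(centre, dtype=np.float64),
            sd=np.asarray(sd, dtype=np.float64), **kwargs,
        )
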