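"""File formats and normalisation contracts.

PLINK 1 binary genotypes (.bed/.bim/.fam), whitespace-delimited
summary-statistic and effect-size tables. Everything downstream assumes the
standardisation contract enforced here: genotype columns and phenotypes have
mean 0 and *population* variance 1 (denominator n), so that X_j^T X_j = n
exactly and the marginal correlation is r_j = X_j^T Y / n.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# PLINK 1 2-bit codes (SNP-major): 00 hom A1, 01 missing, 10 het, 11 hom A2.
# Dosage counts copies of allele1.
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Malformed file content."""


@dataclass
class SnpPanel:
    """Ordered SNP metadata: map positions, alleles and allele frequency."""

    snp_id: np.ndarray
    chromosome: np.ndarray
    bp_position: np.ndarray
    cm_position: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    maf: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.chromosome = np.asarray(self.chromosome, dtype=np.int64)
        self.bp_position = np.asarray(self.bp_position, dtype=np.int64)
        self.cm_position = np.asarray(self.cm_position, dtype=np.float64)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        self.maf = np.asarray(self.maf, dtype=np.float64)
        self.validate()

    @property
    def m(self) -> int:
        return len(self.snp_id)

    def validate(self) -> None:
        for chrom in np.unique(self.chromosome):
            sel = self.chromosome == chrom
            bp = self.bp_position[sel]
            cm = self.cm_position[sel]
            if np.any(np.diff(bp) <= 0):
                raise FormatError(
                    f"bp positions not strictly increasing on chromosome {chrom}"
                )
            if np.any(np.diff(cm) < 0):
                raise FormatError(
                    f"cM positions decrease on chromosome {chrom}"
                )
        if np.any(self.maf <= 0):
            bad = self.snp_id[self.maf <= 0]
            raise FormatError(f"monomorphic SNPs not allowed: {list(bad[:5])}")

    def subset(self, idx: np.ndarray) -> "SnpPanel":
        return SnpPanel(
            self.snp_id[idx],
            self.chromosome[idx],
            self.bp_position[idx],
            self.cm_position[idx],
            self.allele1[idx],
            self.allele2[idx],
            self.maf[idx],
        )


@dataclass
class GenotypeMatrix:
    """n x m dosage matrix (NaN = missing) plus its standardized view.

    ``standardized()`` imputes missing entries to the column mean of observed
    values, then centres and scales each column to population variance 1.
    Column means and standard deviations of the (imputed) raw dosages are
    kept for raw-scale scoring.
    """

    dosages: np.ndarray
    snp_ids: np.ndarray | None = None
    _std: np.ndarray | None = field(default=None, repr=False)
    _means: np.ndarray | None = field(default=None, repr=False)
    _sds: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.dosages)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.dosages = arr
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (individuals x SNPs)")
        n, m = self.dosages.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 individuals and 1 SNP")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def _snp_name(self, j: int) -> str:
        if self.snp_ids is not None:
            return str(self.snp_ids[j])
        return f"column {j}"

    def _compute(self) -> None:
        X = self.dosages.copy()
        missing = np.isnan(X)
        if missing.any():
            obs_counts = (~missing).sum(axis=0)
            col_means = np.nanmean(np.where(missing, np.nan, X), axis=0)
            if np.any(obs_counts == 0):
                j = int(np.argmax(obs_counts == 0))
                raise ValueError(f"SNP {self._snp_name(j)} entirely missing")
            idx = np.where(missing)
            X[idx] = col_means[idx[1]].astype(X.dtype)
        # float64 accumulators even for float32 storage
        means = X.mean(axis=0, dtype=np.float64)
        sds = X.std(axis=0, dtype=np.float64)  # population sd, denominator n
        if np.any(sds == 0):
            j = int(np.argmax(sds == 0))
            raise ValueError(f"SNP {self._snp_name(j)} is monomorphic")
        self._means = means
        self._sds = sds
        X -= means.astype(X.dtype)
        X /= sds.astype(X.dtype)
        self._std = X

    def standardized(self) -> np.ndarray:
        if self._std is None:
            self._compute()
        return self._std

    @property
    def col_means(self) -> np.ndarray:
        if self._means is None:
            self._compute()
        return self._means

    @property
    def col_sds(self) -> np.ndarray:
        if self._sds is None:
            self._compute()
        return self._sds

    def subset_rows(self, idx: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.dosages[idx], snp_ids=self.snp_ids)


def standardize(G: GenotypeMatrix) -> GenotypeMatrix:
    """Return a GenotypeMatrix whose dosages are the standardized values."""
    return GenotypeMatrix(G.standardized().copy(), snp_ids=G.snp_ids)


def standardize_columns(X: np.ndarray) -> np.ndarray:
    """Standardize columns of a plain array (mean 0, population variance 1)."""
    X = np.asarray(X, dtype=np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        raise ValueError("constant column cannot be standardized")
    return (X - mu) / sd


@dataclass
class Phenotype:
    """Per-individual trait values, standardized to mean 0, variance 1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        y = np.asarray(self.values, dtype=np.float64)
        sd = y.std()
        if sd == 0:
            raise ValueError("phenotype is constant")
        self.values = (y - y.mean()) / sd

    @property
    def n(self) -> int:
        return len(self.values)


def _check_stat_consistency(n, r, stat) -> None:
    expect = n * r**2 / (1.0 - r**2)
    denom = np.maximum(np.abs(expect), 1.0)
    if np.any(np.abs(stat - expect) / denom > 1e-8):
        raise ValueError("chi-squared statistic inconsistent with n and r")


@dataclass
class SummaryStats:
    """Per-SNP single-SNP regression results.

    ``r`` is the signed marginal correlation X_j^T Y / n and
    ``stat`` the 1-d.f. chi-squared statistic S_j = n r_j^2 / (1 - r_j^2).
    """

    snp_id: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    n: np.ndarray
    r: np.ndarray
    stat: np.ndarray

    def __post_init__(self) -> None:
        self.snp_id = np.asarray(self.snp_id, dtype=object)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)
        self.n = np.asarray(self.n, dtype=np.int64)
        self.r = np.asarray(self.r, dtype=np.float64)
        self.stat = np.asarray(self.stat, dtype=np.float64)
        if np.any(self.n <= 1):
            raise ValueError("sample size must exceed 1")
        if np.any(np.abs(self.r) >= 1):
            raise ValueError("|r| must be < 1 (degenerate summary statistic)")
        if np.any(self.stat < 0):
            raise ValueError("chi-squared statistics must be non-negative")
        _check_stat_consistency(self.n, self.r, self.stat)

    @property
    def m(self) -> int:
        return len(self.snp_id)

    @classmethod
    def from_r(cls, snp_id, allele1, allele2, n, r) -> "SummaryStats":
        n = np.asarray(n, dtype=np.int64)
        r = np.asarray(r, dtype=np.float64)
        stat = n * r**2 / (1.0 - r**2)
        return cls(snp_id, allele1, allele2, n, r, stat)

    @classmethod
    def from_stat(cls, snp_id, allele1, allele2, n, stat, sign=None) -> "SummaryStats":
        n = np.asarray(n, dtype=np.int64)
        stat = np.asarray(stat, dtype=np.float64)
        if sign is None:
            sign = np.ones_like(stat)
        r = np.sign(sign + (np.asarray(sign) == 0)) * np.sqrt(stat / (n + stat))
        return cls(snp_id, allele1, allele2, n, r, stat)

    def subset(self, idx) -> "SummaryStats":
        return SummaryStats(
            self.snp_id[idx], self.allele1[idx], self.allele2[idx],
            self.n[idx], self.r[idx], self.stat[idx],
        )


# ---------------------------------------------------------------------------
# PLINK 1 binary


def read_plink(prefix: str | Path):
    """Read ``prefix``.bed/.bim/.fam into (SnpPanel, GenotypeMatrix, samples).

    Monomorphic SNPs are rejected. If the .bim cM column is entirely zero,
    the conventional 1 cM per Mb surrogate is used.
    """
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"), sep=r"\s+", header=None,
        names=["chrom", "snp", "cm", "bp", "a1", "a2"],
        dtype={"chrom": np.int64, "snp": str, "cm": float, "bp": np.int64,
               "a1": str, "a2": str},
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"), sep=r"\s+", header=None,
        names=["fid", "iid", "father", "mother", "sex", "phenotype"],
        dtype={"fid": str, "iid": str},
    )
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError("not a PLINK 1 SNP-major .bed file (bad magic bytes)")
    bytes_per_snp = (n + 3) // 4
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3)
    if len(payload) != bytes_per_snp * m:
        raise FormatError(
            f".bed payload has {len(payload)} bytes, expected "
            f"{bytes_per_snp * m} for {n} samples x {m} SNPs"
        )
    codes = payload.reshape(m, bytes_per_snp)
    # expand 2-bit codes, individual i in bits (2i mod 8) of byte i//4
    shifts = np.arange(4, dtype=np.uint8) * 2
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    expanded = expanded.reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[expanded].T.copy()  # n x m

    cm = bim["cm"].to_numpy(dtype=float)
    if np.all(cm == 0):
        cm = bim["bp"].to_numpy(dtype=float) / 1e6

    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    panel = SnpPanel(
        bim["snp"].to_numpy(), bim["chrom"].to_numpy(), bim["bp"].to_numpy(),
        cm, bim["a1"].to_numpy(), bim["a2"].to_numpy(), maf,
    )
    G = GenotypeMatrix(dosages, snp_ids=panel.snp_id)
    return panel, G, fam


def write_plink(prefix: str | Path, panel: SnpPanel, G: GenotypeMatrix,
                samples: pd.DataFrame | None = None) -> None:
    """Write PLINK 1 .bed/.bim/.fam with bit-exact 2-bit SNP-major encoding."""
    prefix = Path(prefix)
    n, m = G.n, G.m
    if m != panel.m:
        raise ValueError("panel and genotype SNP counts differ")
    if samples is None:
        samples = pd.DataFrame({
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
        })
    dos = G.dosages
    # dosage -> 2-bit code
    codes = np.full((m, n), 1, dtype=np.uint8)  # missing
    d = dos.T
    codes[d == 2] = 0
    codes[d == 1] = 2
    codes[d == 0] = 3
    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((m, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = (
        padded[:, 0::4]
        | (padded[:, 1::4] << 2)
        | (padded[:, 2::4] << 4)
        | (padded[:, 3::4] << 6)
    )
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim = pd.DataFrame({
        "chrom": panel.chromosome, "snp": panel.snp_id,
        "cm": panel.cm_position, "bp": panel.bp_position,
        "a1": panel.allele1, "a2": panel.allele2,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    samples.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# allele harmonization


def harmonize(ss: SummaryStats, panel: SnpPanel,
              drop_ambiguous: bool = False) -> SummaryStats:
    """Align summary statistics to a SNP panel.

    SNPs absent from the panel are dropped; allele pairs matching after a
    swap get the correlation sign flipped; strand flips (complement) are
    resolved; A/T and C/G pairs are dropped when ``drop_ambiguous``;
    irreconcilable pairs are dropped with a logged count.
    """
    by_id = {sid: i for i, sid in enumerate(ss.snp_id)}
    keep_rows: list[int] = []
    signs: list[float] = []
    n_irreconcilable = 0
    for j in range(panel.m):
        i = by_id.get(panel.snp_id[j])
        if i is None:
            continue
        a1, a2 = str(ss.allele1[i]).upper(), str(ss.allele2[i]).upper()
        p1, p2 = str(panel.allele1[j]).upper(), str(panel.allele2[j]).upper()
        if drop_ambiguous and _COMPLEMENT.get(a1) == a2:
            continue
        c1, c2 = _COMPLEMENT.get(a1), _COMPLEMENT.get(a2)
        if (a1, a2) == (p1, p2) or (c1, c2) == (p1, p2):
            sign = 1.0
        elif (a2, a1) == (p1, p2) or (c2, c1) == (p1, p2):
            sign = -1.0
        else:
            n_irreconcilable += 1
            continue
        keep_rows.append(i)
        signs.append(sign)
    if n_irreconcilable:
        logger.info("harmonize: dropped %d irreconcilable SNPs", n_irreconcilable)
    idx = np.array(keep_rows, dtype=np.int64)
    signs_arr = np.array(signs)
    if len(idx) == 0:
        raise ValueError("no SNPs left after harmonization")
    panel_pos = {sid: j for j, sid in enumerate(panel.snp_id)}
    return SummaryStats(
        ss.snp_id[idx],
        np.array([panel.allele1[panel_pos[s]] for s in ss.snp_id[idx]], dtype=object),
        np.array([panel.allele2[panel_pos[s]] for s in ss.snp_id[idx]], dtype=object),
        ss.n[idx],
        ss.r[idx] * signs_arr,
        ss.stat[idx],
    )


# ---------------------------------------------------------------------------
# summary-statistic tables


def read_sumstats(path: str | Path) -> SummaryStats:
    """Read a whitespace table with header Predictor A1 A2 n Stat|Correlation."""
    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    required = {"Predictor", "A1", "A2", "n"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"summary file missing columns: {sorted(missing)}")
    if np.any(df["n"].to_numpy() <= 1):
        raise ValueError("sample size must exceed 1")
    if "Correlation" in df.columns:
        return SummaryStats.from_r(
            df["Predictor"].to_numpy(dtype=object),
            df["A1"].to_numpy(dtype=object), df["A2"].to_numpy(dtype=object),
            df["n"].to_numpy(), df["Correlation"].to_numpy(),
        )
    if "Stat" not in df.columns:
        raise FormatError("summary file needs a Stat or Correlation column")
    sign = df["Direction"].to_numpy() if "Direction" in df.columns else None
    return SummaryStats.from_stat(
        df["Predictor"].to_numpy(dtype=object),
        df["A1"].to_numpy(dtype=object), df["A2"].to_numpy(dtype=object),
        df["n"].to_numpy(), df["Stat"].to_numpy(), sign=sign,
    )


def write_sumstats(ss: SummaryStats, path: str | Path) -> None:
    df = pd.DataFrame({
        "Predictor": ss.snp_id, "A1": ss.allele1, "A2": ss.allele2,
        "n": ss.n,
        "Correlation": [f"{x:.17g}" for x in ss.r],
        "Stat": [f"{x:.17g}" for x in ss.stat],
    })
    df.to_csv(path, sep=" ", index=False)


# ---------------------------------------------------------------------------
# effect-size tables


def write_effects(model, path: str | Path) -> None:
    """Write per-SNP effects: standardized scale and the raw-dosage scale.

    Effect_raw = Effect_standardized / sd(genotype), so scoring centred raw
    dosages with Effect_raw reproduces standardized-scale scoring.
    """
    ids = np.asarray(model.snp_id, dtype=object)
    if len(np.unique(ids.astype(str))) != len(ids):
        raise ValueError("duplicate snp_id in effect model")
    # prefer a previously read raw column so round trips are bit-stable
    raw = model.extras.get("effect_raw")
    if raw is None:
        raw = model.beta / model.sd
    df = pd.DataFrame({
        "Predictor": ids, "A1": model.allele1, "A2": model.allele2,
        "Centre": [f"{x:.17g}" for x in model.centre],
        "Effect_standardized": [f"{x:.17g}" for x in model.beta],
        "Effect_raw": [f"{x:.17g}" for x in raw],
    })
    df.to_csv(path, sep=" ", index=False)


def read_effects(path: str | Path):
    from .model import PrsModel

    df = pd.read_csv(path, sep=r"\s+", float_precision="round_trip")
    required = {"Predictor", "A1", "A2", "Centre", "Effect_standardized",
                "Effect_raw"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"effect file missing columns: {sorted(missing)}")
    beta = df["Effect_standardized"].to_numpy(dtype=float)
    raw = df["Effect_raw"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sd = np.where(raw != 0, beta / raw, 1.0)
    return PrsModel(
        snp_id=df["Predictor"].to_numpy(dtype=object),
        allele1=df["A1"].to_numpy(dtype=object),
        allele2=df["A2"].to_numpy(dtype=object),
        beta=beta,
        centre=df["Centre"].to_numpy(dtype=float),
        sd=sd,
        extras={"effect_raw": raw},
    )
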