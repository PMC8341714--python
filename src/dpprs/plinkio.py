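"""Reference / validation genotypes: PLINK 1 bed/bim/fam I/O and scoring.

The panel container accepts either hard-call dosages in {0,1,2} (NaN for
missing) or continuous genotype values (as produced by the Gaussian
simulator); standardization and scoring are identical for both. Missing
entries are mean-imputed before standardization, which keeps every column
exactly mean zero.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# 2-bit PLINK codes -> dosage of the bim A1 allele; 0b01 = missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PanelGenotypes:
    """Genotype panel with metadata, sorted by (chrom, pos).

    Parameters
    ----------
    values : ndarray (n_individuals, n_snps)
        Dosages of the A1 allele (0/1/2, NaN missing) or continuous values.
    meta : DataFrame
        Columns ``snp_id, chrom, pos, a1, a2``.
    """

    def __init__(self, values: np.ndarray, meta: pd.DataFrame):
        values = np.asarray(values, dtype=np.float32)
        if values.ndim != 2 or values.shape[1] != len(meta):
            raise InputError("genotype matrix shape does not match metadata")
        order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
        self.meta = meta.iloc[order].reset_index(drop=True)
        self.values = values[:, order]
        self._std = None

    @property
    def n_ref(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def __repr__(self) -> str:
        return f"PanelGenotypes({self.n_ref} individuals, {self.n_snps} SNPs)"

    @property
    def freq_a1(self) -> np.ndarray:
        """A1 allele frequency (dosage panels)."""
        return np.nanmean(self.values, axis=0) / 2.0

    @property
    def maf(self) -> np.ndarray:
        f = self.freq_a1
        return np.minimum(f, 1.0 - f)

    def dosages(self, j: int) -> np.ndarray:
        """Column j with missing entries mean-imputed."""
        col = self.values[:, j].astype(float)
        nan = np.isnan(col)
        if nan.any():
            col[nan] = np.nanmean(col)
        return col

    def standardized(self) -> np.ndarray:
        """Mean-0, variance-1 (ddof=0) matrix; monomorphic columns -> 0."""
        if self._std is None:
            x = self.values.astype(np.float64)
            mu = np.nanmean(x, axis=0)
            idx = np.where(np.isnan(x))
            x[idx] = np.take(mu, idx[1])
            x -= x.mean(axis=0)
            sd = x.std(axis=0)
            sd[sd == 0] = 1.0
            x /= sd
            self._std = x
        return self._std

    def filter_maf(self, min_maf: float) -> "PanelGenotypes":
        keep = self.maf >= min_maf
        return self.subset(np.where(keep)[0])

    def subset(self, idx) -> "PanelGenotypes":
        idx = np.asarray(idx)
        return PanelGenotypes(self.values[:, idx], self.meta.iloc[idx].reset_index(drop=True))


def read_plink(prefix: str) -> PanelGenotypes:
    """Read a PLINK 1 fileset (``prefix``.bed/.bim/.fam), SNP-major bed."""
    bim = pd.read_csv(
        f"{prefix}.bim",
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": int, "snp_id": str, "pos": int, "a1": str, "a2": str},
    )
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None)
    n, m = len(fam), len(bim)
    with open(f"{prefix}.bed", "rb") as fh:
        header = fh.read(3)
        if header != _BED_MAGIC:
            raise InputError(f"{prefix}.bed is not a SNP-major PLINK 1 bed file")
        data = np.frombuffer(fh.read(), dtype=np.uint8)
    bps = (n + 3) // 4  # bytes per SNP
    if len(data) != bps * m:
        raise InputError(f"{prefix}.bed has unexpected size")
    data = data.reshape(m, bps)
    # unpack 2-bit codes, samples little-end first within each byte
    codes = np.empty((m, bps * 4), dtype=np.uint8)
    for shift in range(4):
        codes[:, shift::4] = (data >> (2 * shift)) & 0b11
    geno = _CODE_TO_DOSAGE[codes[:, :n]].T  # (n, m)
    meta = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    return PanelGenotypes(geno, meta)


def write_plink(prefix: str, panel: PanelGenotypes) -> None:
    """Write hard-call dosages as a PLINK 1 fileset (values rounded to 0/1/2)."""
    meta = panel.meta
    n, m = panel.n_ref, panel.n_snps
    bim = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "snp_id": meta["snp_id"],
            "cm": 0,
            "pos": meta["pos"],
            "a1": meta["a1"],
            "a2": meta["a2"],
        }
    )
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(f"{prefix}.fam", sep="\t", header=False, index=False)

    vals = panel.values.astype(float)
    codes = np.full(vals.shape, 1, dtype=np.uint8)  # missing
    with np.errstate(invalid="ignore"):
        codes[np.round(vals) == 2] = 0b00
        codes[np.round(vals) == 1] = 0b10
        codes[np.round(vals) == 0] = 0b11
    bps = (n + 3) // 4
    packed = np.zeros((m, bps * 4), dtype=np.uint8)
    packed[:, :n] = codes.T
    out = np.zeros((m, bps), dtype=np.uint8)
    for shift in range(4):
        out |= packed[:, shift::4] << (2 * shift)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())


def score_prs(panel, effects) -> np.ndarray:
    """Polygenic score: standardized genotypes times per-SNP effects.

    Parameters
    ----------
    panel : PanelGenotypes or ndarray
        If an ndarray, it is taken to be already standardized (n x m).
    effects : DataFrame with SNP/A1/EFFECT columns, or ndarray of length m.

    The effects must be aligned to the panel (same SNP ids in the same
    order, same effect allele); a mismatch raises :class:`InputError`.
    """
    if isinstance(panel, PanelGenotypes):
        x = panel.standardized()
        meta = panel.meta
    else:
        x = np.asarray(panel, dtype=float)
        meta = None
    if isinstance(effects, np.ndarray):
        e = effects.astype(float)
        if e.shape[0] != x.shape[1]:
            raise InputError("effects length does not match panel SNP count")
    else:
        if meta is None:
            raise InputError("DataFrame effects require a PanelGenotypes input")
        if len(effects) != len(meta) or not np.array_equal(
            effects["SNP"].to_numpy(), meta["snp_id"].to_numpy()
        ):
            raise InputError("effects SNP ids do not match panel order")
        if not np.array_equal(effects["A1"].to_numpy(), meta["a1"].to_numpy()):
            raise InputError("effects effect alleles do not match panel A1")
        e = effects["EFFECT"].to_numpy(dtype=float)
    return x @ e
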