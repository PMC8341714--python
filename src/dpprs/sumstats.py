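"""GWAS summary-statistics ingestion, quality control and allele alignment.

Summary statistics are per-SNP marginal regression results. Throughout the
package the marginal effect ``beta_hat`` is carried on the standardized
scale (both genotype and phenotype standardized), which is the scale on
which the likelihood relating marginal to joint effects is written. When a
file provides only a z-score and a sample size, ``beta_hat = z / sqrt(n)``;
when it provides per-allele effects together with the effect-allele
frequency ``f``, multiplying by ``sqrt(2 f (1 - f))`` converts to the
standardized scale.

QC mirrors common practice for summary-statistics methods: drop INDELs and
non-ACGT alleles, drop strand-ambiguous (A/T, G/C) pairs, drop SNPs whose
per-SNP sample size falls below a fraction of a high percentile of the
sample-size distribution, and optionally drop the MHC region
(chr6:28-34 Mb) whose extreme long-range LD violates the block model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError, InputError

VALID_ALLELES = {"A", "C", "G", "T"}
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: canonical column order for summary-statistics TSV output
SS_COLUMNS = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "P", "N"]

_DEFAULT_COLUMN_MAP = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "a1": "A1",
    "a2": "A2",
    "beta_hat": "BETA",
    "z": "Z",
    "n": "N",
    "pval": "P",
    "freq": "FRQ",
}


class SummaryStats:
    """Per-SNP marginal GWAS results.

    Thin wrapper over a :class:`pandas.DataFrame` with columns
    ``snp_id, chrom, pos, a1, a2, beta_hat, n, pval`` (``chrom``/``pos``
    may be absent when the source file lacks them).
    """

    def __init__(self, df: pd.DataFrame):
        missing = {"snp_id", "a1", "a2", "beta_hat", "n", "pval"} - set(df.columns)
        if missing:
            raise ConfigError(f"SummaryStats missing columns: {sorted(missing)}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"SummaryStats({len(self)} SNPs)"

    @property
    def snp_id(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    @property
    def beta_hat(self) -> np.ndarray:
        return self.df["beta_hat"].to_numpy(dtype=float)

    @property
    def n(self) -> np.ndarray:
        return self.df["n"].to_numpy(dtype=float)


@dataclass
class QCConfig:
    """Quality-control switches and thresholds.

    ``neff_fraction``/``neff_percentile`` implement the per-SNP sample-size
    filter: drop SNPs with n below ``neff_fraction`` times the
    ``neff_percentile``-th percentile of n (nearest-rank convention).
    """

    drop_ambiguous: bool = True
    drop_indels: bool = True
    neff_fraction: float = 0.67
    neff_percentile: float = 90.0
    mhc_exclude: bool = True
    mhc_region: tuple[int, float, float] = (6, 28e6, 34e6)
    min_maf: float = 0.01  # applied on the panel side

    def __post_init__(self):
        if not (0 < self.neff_fraction <= 1):
            raise ConfigError("neff_fraction must be in (0, 1]")
        if not (0 < self.neff_percentile <= 100):
            raise ConfigError("neff_percentile must be in (0, 100]")


@dataclass
class QCReport:
    """Counts of SNPs removed by each QC rule, in application order."""

    n_input: int = 0
    n_indel: int = 0
    n_ambiguous: int = 0
    n_low_n: int = 0
    n_mhc: int = 0
    n_output: int = 0
    n_threshold: float = float("nan")

    def to_text(self) -> str:
        lines = [
            f"input_snps: {self.n_input}",
            f"removed_indel_or_nonacgt: {self.n_indel}",
            f"removed_strand_ambiguous: {self.n_ambiguous}",
            f"removed_low_sample_size: {self.n_low_n}",
            f"removed_mhc: {self.n_mhc}",
            f"sample_size_threshold: {self.n_threshold:g}",
            f"output_snps: {self.n_output}",
        ]
        return "\n".join(lines) + "\n"


@dataclass
class AlignmentReport:
    """Bookkeeping from allele alignment against a reference panel."""

    n_matched: int = 0
    n_flipped: int = 0
    n_mismatch: int = 0
    n_missing_from_panel: int = 0


def read_summary_stats(path, column_map: dict | None = None) -> SummaryStats:
    """Read a whitespace/tab-delimited summary-statistics file.

    Parameters
    ----------
    path : str or Path
        File with a header line.
    column_map : dict, optional
        Maps internal names (``snp_id, chrom, pos, a1, a2, beta_hat, z, n,
        pval, freq``) to the file's header names. Defaults cover the common
        SNP/CHR/POS/A1/A2/BETA/Z/N/P/FRQ convention.

    Notes
    -----
    If ``beta_hat`` is absent but ``z`` present, effects are derived as
    z/sqrt(n). If ``freq`` is present alongside ``beta_hat`` the effect is
    assumed per-allele and converted to the standardized scale by
    sqrt(2 f (1-f)). Rows with unparseable numerics are dropped and counted
    in the ``n_dropped_unparseable`` attribute of the result.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep=r"\s+", dtype=str)
    cols = set(raw.columns)

    def have(key):
        return cmap[key] in cols

    for key in ("snp_id", "a1", "a2", "n", "pval"):
        if not have(key):
            raise ConfigError(
                f"required column '{cmap[key]}' (for {key}) not found in {path}"
            )
    if not have("beta_hat") and not have("z"):
        raise ConfigError(
            f"neither effect column '{cmap['beta_hat']}' nor z column "
            f"'{cmap['z']}' found in {path}"
        )

    df = pd.DataFrame()
    df["snp_id"] = raw[cmap["snp_id"]].astype(str)
    df["a1"] = raw[cmap["a1"]].str.upper()
    df["a2"] = raw[cmap["a2"]].str.upper()
    for key, out in (("chrom", "chrom"), ("pos", "pos")):
        if have(key):
            df[out] = pd.to_numeric(raw[cmap[key]], errors="coerce")
    df["n"] = pd.to_numeric(raw[cmap["n"]], errors="coerce")
    df["pval"] = pd.to_numeric(raw[cmap["pval"]], errors="coerce")
    if have("beta_hat"):
        df["beta_hat"] = pd.to_numeric(raw[cmap["beta_hat"]], errors="coerce")
        if have("freq"):
            f = pd.to_numeric(raw[cmap["freq"]], errors="coerce")
            df["beta_hat"] = df["beta_hat"] * np.sqrt(2.0 * f * (1.0 - f))
    else:
        z = pd.to_numeric(raw[cmap["z"]], errors="coerce")
        df["beta_hat"] = z / np.sqrt(df["n"])

    numeric = ["beta_hat", "n", "pval"]
    ok = df[numeric].notna().all(axis=1) & np.isfinite(df[numeric]).all(axis=1)
    ok &= df["n"] > 0
    n_dropped = int((~ok).sum())
    df = df[ok]
    if len(df) == 0:
        raise InputError(f"no parseable summary-statistics rows in {path}")
    ss = SummaryStats(df)
    ss.n_dropped_unparseable = n_dropped
    return ss


def effective_sample_size(n_case: float, n_control: float) -> float:
    """Effective sample size of a case-control GWAS.

    ``4 * n_case * n_control / (n_case + n_control)``, the quantitative-trait
    sample size giving equivalent power at a 50/50 case fraction.
    """
    if n_case <= 0 or n_control <= 0:
        raise InputError("case and control counts must be positive")
    return 4.0 * n_case * n_control / (n_case + n_control)


def _nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    # type-1 (inverted CDF) percentile: deterministic, exact at ties
    return float(np.percentile(values, q, method="inverted_cdf"))


def qc_filter(ss: SummaryStats, cfg: QCConfig | None = None) -> tuple[SummaryStats, QCReport]:
    """Apply QC rules in order; return filtered stats and per-rule counts.

    Order: INDEL / non-ACGT alleles, strand-ambiguous pairs, low per-SNP
    sample size, MHC region (when chrom/pos available).
    """
    if len(ss) == 0:
        raise InputError("qc_filter: empty summary statistics")
    cfg = cfg or QCConfig()
    df = ss.df
    report = QCReport(n_input=len(df))

    if cfg.drop_indels:
        keep = df["a1"].isin(VALID_ALLELES) & df["a2"].isin(VALID_ALLELES)
        keep &= df["a1"] != df["a2"]
        report.n_indel = int((~keep).sum())
        df = df[keep]

    if cfg.drop_ambiguous and len(df):
        amb = [
            (a1, a2) in AMBIGUOUS_PAIRS
            for a1, a2 in zip(df["a1"], df["a2"])
        ]
        amb = np.asarray(amb, dtype=bool)
        report.n_ambiguous = int(amb.sum())
        df = df[~amb]

    if len(df):
        thr = cfg.neff_fraction * _nearest_rank_percentile(
            df["n"].to_numpy(dtype=float), cfg.neff_percentile
        )
        report.n_threshold = thr
        keep = df["n"].to_numpy(dtype=float) >= thr
        report.n_low_n = int((~keep).sum())
        df = df[keep]

    if cfg.mhc_exclude and len(df) and {"chrom", "pos"} <= set(df.columns):
        chrom, lo, hi = cfg.mhc_region
        in_mhc = (
            (df["chrom"] == chrom)
            & (df["pos"] >= lo)
            & (df["pos"] <= hi)
        )
        report.n_mhc = int(in_mhc.sum())
        df = df[~in_mhc]

    if len(df) == 0:
        raise InputError("qc_filter removed every SNP")
    report.n_output = len(df)
    return SummaryStats(df), report


def align_alleles(ss: SummaryStats, panel) -> tuple[SummaryStats, AlignmentReport]:
    """Intersect with a panel and orient effects to the panel's effect allele.

    Where the summary-statistics alleles are the panel's pair swapped, the
    effect sign is flipped and alleles swapped; SNPs whose alleles match
    neither orientation are dropped. Output rows follow panel SNP order.
    Strand complements are deliberately not attempted (ambiguous SNPs are
    removed upstream).
    """
    meta = panel.meta
    panel_idx = {sid: k for k, sid in enumerate(meta["snp_id"])}
    rep = AlignmentReport()
    rows = []
    order = []
    for _, row in ss.df.iterrows():
        k = panel_idx.get(row["snp_id"])
        if k is None:
            rep.n_missing_from_panel += 1
            continue
        pa1, pa2 = meta["a1"].iat[k], meta["a2"].iat[k]
        r = row.copy()
        if (row["a1"], row["a2"]) == (pa1, pa2):
            rep.n_matched += 1
        elif (row["a1"], row["a2"]) == (pa2, pa1):
            r["a1"], r["a2"] = pa1, pa2
            r["beta_hat"] = -row["beta_hat"]
            rep.n_flipped += 1
        else:
            rep.n_mismatch += 1
            continue
        r["chrom"] = meta["chrom"].iat[k]
        r["pos"] = meta["pos"].iat[k]
        rows.append(r)
        order.append(k)
    if not rows:
        raise InputError("align_alleles: empty intersection with panel")
    out = pd.DataFrame(rows)
    out = out.iloc[np.argsort(np.asarray(order), kind="stable")]
    return SummaryStats(out), rep


def write_summary_stats(ss: SummaryStats, path) -> None:
    df = ss.df
    out = pd.DataFrame(
        {
            "SNP": df["snp_id"],
            "CHR": df.get("chrom", pd.Series([0] * len(df))).astype("Int64"),
            "POS": df.get("pos", pd.Series([0] * len(df))).astype("Int64"),
            "A1": df["a1"],
            "A2": df["a2"],
            "BETA": df["beta_hat"],
            "P": df["pval"],
            "N": df["n"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def write_effects(path, snp_id, a1, effect) -> None:
    """Posterior effects TSV: SNP, A1, EFFECT (standardized scale)."""
    pd.DataFrame({"SNP": snp_id, "A1": a1, "EFFECT": effect}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_effects(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=r"\s+")
    need = {"SNP", "A1", "EFFECT"}
    if not need <= set(df.columns):
        raise ConfigError(f"effects file {path} must have columns {sorted(need)}")
    return df
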