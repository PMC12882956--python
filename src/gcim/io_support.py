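"""File formats and configuration.

PLINK1 binary genotypes (bed/bim/fam triples) are read and written directly:
the bed payload is two bits per genotype in SNP-major order, decoded here
with a four-entry lookup (00 → two copies of A1, 10 → one, 11 → zero,
01 → missing, carried as NaN).  Missing genotypes are kept as missing by
default; operations that cannot handle them refuse, and callers opt in to
mean imputation explicitly.

Phenotype/covariate tables are tab-separated with FID/IID leading columns.
Scenario configurations round-trip through YAML.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from .errors import FormatError
from .experiments import ScenarioSpec
from .synthetic_data import EffectCovConfig, GenotypeMatrix, PhenotypePair

__all__ = [
    "read_plink",
    "write_plink",
    "mean_impute",
    "PhenotypeTable",
    "read_phenotypes",
    "write_phenotypes",
    "align_phenotypes",
    "load_scenario",
    "dump_scenario",
]

log = logging.getLogger("gcim")

_BED_MAGIC = b"\x6c\x1b"
# 2-bit code -> A1 allele count (index by code value)
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK1 bed/bim/fam triple into a GenotypeMatrix.

    Counts are copies of the bim A1 allele (the scored effect allele).
    Missing genotypes are carried as NaN; no imputation is applied.
    """
    prefix = Path(prefix)
    bed_path, bim_path, fam_path = (prefix.with_suffix(s) for s in (".bed", ".bim", ".fam"))
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FormatError(f"missing PLINK file: {p}")

    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["FID", "IID", "PAT", "MAT", "SEX", "PHENO"], dtype=str)
    bim = pd.read_csv(bim_path, sep=r"\s+", header=None,
                      names=["CHR", "SNP", "CM", "POS", "A1", "A2"], dtype=str)
    n, m = len(fam), len(bim)
    if fam["IID"].duplicated().any():
        raise FormatError("duplicate individual IDs in .fam")
    if bim["SNP"].duplicated().any():
        raise FormatError("duplicate SNP IDs in .bim")

    raw = bed_path.read_bytes()
    if len(raw) < 3 or raw[:2] != _BED_MAGIC:
        raise FormatError(f"{bed_path}: bad magic bytes (not a PLINK1 .bed file)")
    if raw[2] != 0x01:
        raise FormatError(f"{bed_path}: only SNP-major .bed files are supported")
    bytes_per_snp = (n + 3) // 4
    if len(raw) - 3 != bytes_per_snp * m:
        raise FormatError(
            f"{bed_path}: payload size {len(raw) - 3} does not match "
            f"{n} individuals x {m} SNPs"
        )
    packed = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bytes_per_snp)
    shifts = np.arange(4, dtype=np.uint8) * 2
    codes = (packed[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    counts = _CODE_TO_COUNT[codes].T.copy()  # (n, m)

    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(counts, axis=0) / 2.0
    return GenotypeMatrix(
        counts=counts,
        snp_ids=bim["SNP"].to_numpy(),
        allele_freqs=freqs,
        individual_ids=fam["IID"].to_numpy(),
        a1=bim["A1"].to_numpy(),
        a2=bim["A2"].to_numpy(),
    )


def write_plink(prefix, G: GenotypeMatrix, phenotype: Optional[np.ndarray] = None) -> None:
    """Write a GenotypeMatrix as a PLINK1 bed/bim/fam triple."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n, G.m

    a1 = G.a1 if G.a1 is not None else np.repeat("A", m)
    a2 = G.a2 if G.a2 is not None else np.repeat("G", m)
    bim = pd.DataFrame({
        "CHR": 1, "SNP": G.snp_ids, "CM": 0, "POS": np.arange(1, m + 1),
        "A1": a1, "A2": a2,
    })
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    pheno = phenotype if phenotype is not None else np.full(n, -9)
    fam = pd.DataFrame({
        "FID": G.individual_ids, "IID": G.individual_ids,
        "PAT": 0, "MAT": 0, "SEX": 0, "PHENO": pheno,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    counts = G.counts
    codes = np.full(counts.shape, 0b01, dtype=np.uint8)  # missing
    codes[counts == 2] = 0b00
    codes[counts == 1] = 0b10
    codes[counts == 0] = 0b11
    bytes_per_snp = (n + 3) // 4
    padded = np.full((m, bytes_per_snp * 4), 0b11, dtype=np.uint8)  # pad with hom A2
    padded[:, :n] = codes.T
    packed = np.zeros((m, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << np.uint8(2 * k)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + b"\x01")
        fh.write(packed.tobytes())


def mean_impute(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing genotypes with the per-SNP mean allele count."""
    counts = G.counts.copy()
    if np.isnan(counts).any():
        col_mean = np.nanmean(counts, axis=0)
        nan_r, nan_c = np.where(np.isnan(counts))
        counts[nan_r, nan_c] = col_mean[nan_c]
    return dataclasses.replace(G, counts=counts)


@dataclasses.dataclass
class PhenotypeTable:
    """Typed phenotype/covariate table keyed by individual id."""

    ids: np.ndarray
    frame: pd.DataFrame  # indexed by IID

    def column(self, name: str) -> np.ndarray:
        return self.frame[name].to_numpy(dtype=float)


def read_phenotypes(
    path,
    outcome: Optional[str] = None,
    exposure: Optional[str] = None,
    covariates: Sequence[str] = (),
    binary: Sequence[str] = (),
) -> PhenotypeTable:
    """Read a delimited phenotype table (FID/IID or IID leading columns).

    Named trait columns must parse as numeric; columns listed in ``binary``
    must contain only 0/1 (or missing).
    """
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python")
    if "IID" not in df.columns:
        raise FormatError(f"{path}: expected an IID column, found {list(df.columns)}")
    if df["IID"].astype(str).duplicated().any():
        raise FormatError(f"{path}: duplicate IIDs")
    wanted = [c for c in (outcome, exposure, *covariates) if c is not None]
    for col in wanted:
        if col not in df.columns:
            raise FormatError(f"{path}: column {col!r} not found")
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise FormatError(f"{path}: non-numeric value in column {col!r} at data row {row}")
        df[col] = vals
    for col in binary:
        vals = df[col].dropna()
        if not vals.isin([0, 1]).all():
            offending = sorted(set(vals[~vals.isin([0, 1])]))
            raise FormatError(f"{path}: binary column {col!r} contains values {offending}")
    ids = df["IID"].astype(str).to_numpy()
    frame = df.set_index(df["IID"].astype(str))
    return PhenotypeTable(ids=ids, frame=frame)


def write_phenotypes(path, G: GenotypeMatrix, phen: PhenotypePair,
                     covariates: Optional[pd.DataFrame] = None) -> None:
    """Export phenotypes (and optional covariates) as FID/IID-keyed TSV."""
    df = pd.DataFrame({"FID": G.individual_ids, "IID": G.individual_ids,
                       "y": phen.y, "c": phen.c})
    if covariates is not None:
        df = pd.concat([df, covariates.reset_index(drop=True)], axis=1)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def align_phenotypes(
    table: PhenotypeTable, G: GenotypeMatrix
) -> Tuple[PhenotypeTable, int]:
    """Inner-join the table onto the genotype individual order.

    Rows present in the phenotype table but not in the genotypes (or vice
    versa) are dropped; the number of dropped phenotype rows is returned and
    logged.
    """
    geno_ids = G.individual_ids.astype(str)
    table_ids = set(table.ids.astype(str).tolist())
    keep = np.array([i for i in geno_ids if i in table_ids])
    dropped = len(table.ids) - len(keep)
    if dropped:
        log.info("align_phenotypes: dropped %d phenotype rows without genotypes", dropped)
    frame = table.frame.loc[keep]
    return PhenotypeTable(ids=keep, frame=frame), dropped


# -- scenario configuration ---------------------------------------------------

def dump_scenario(spec: ScenarioSpec, path) -> None:
    data = dataclasses.asdict(spec)
    data["cfg"] = dataclasses.asdict(spec.cfg)
    data["maf"] = list(spec.maf)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def load_scenario(path) -> ScenarioSpec:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    try:
        cfg = EffectCovConfig(**data.pop("cfg"))
        if "maf" in data:
            data["maf"] = tuple(data["maf"])
        return ScenarioSpec(cfg=cfg, **data)
    except TypeError as exc:
        raise FormatError(f"{path}: invalid scenario file: {exc}") from exc
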