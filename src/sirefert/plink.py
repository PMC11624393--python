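"""Readers and writers for PLINK genotype files and phenotype tables.

Supports the binary bed/bim/fam triplet (SNP-major, v1.00 magic
``0x6c 0x1b 0x01``) and the text "raw" additive-dosage format produced by
``plink --recode A``.  Dosages count the A1 / counted allele, matching the
.raw convention.  Phenotype tables are tab-separated with columns
``id, scr, n_breedings, reliability``.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix

__all__ = [
    "PlinkFormatError",
    "read_genotypes",
    "read_bed",
    "write_bed",
    "read_raw",
    "write_raw",
    "read_phenotypes",
    "write_phenotypes",
]

_BED_MAGIC = bytes((0x6C, 0x1B, 0x01))

# 2-bit bed codes (SNP-major): 00 = hom A1 (dosage 2), 01 = missing,
# 10 = het (1), 11 = hom A2 (0)
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class PlinkFormatError(ValueError):
    """Malformed or mutually inconsistent PLINK files."""


def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read genotypes from a PLINK fileset.

    ``path`` is a prefix (or any member file) of a bed/bim/fam triplet, or
    a ``.raw`` file.  ``format`` may be ``"plink-bed"`` or ``"plink-raw"``;
    when omitted it is inferred from the file extension.
    """
    path = Path(path)
    if format is None:
        format = "plink-raw" if path.suffix == ".raw" else "plink-bed"
    if format == "plink-bed":
        return read_bed(path)
    if format == "plink-raw":
        return read_raw(path)
    raise ValueError(f"unknown genotype format {format!r}")


def _triplet(prefix: Path) -> tuple[Path, Path, Path]:
    if prefix.suffix in (".bed", ".bim", ".fam"):
        prefix = prefix.with_suffix("")
    return (
        prefix.with_suffix(".bed"),
        prefix.with_suffix(".bim"),
        prefix.with_suffix(".fam"),
    )


def read_bed(prefix) -> GenotypeMatrix:
    """Read a PLINK bed/bim/fam triplet (SNP-major v1 layout)."""
    bed_path, bim_path, fam_path = _triplet(Path(prefix))
    for f in (bed_path, bim_path, fam_path):
        if not f.exists():
            raise FileNotFoundError(f"missing PLINK file: {f}")

    fam = pd.read_csv(
        fam_path,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "pat", "mat", "sex", "pheno"],
        dtype={"iid": str},
    )
    bim = pd.read_csv(
        bim_path,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    n, p = len(fam), len(bim)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if len(raw) < 3 or bytes(raw[:3]) != _BED_MAGIC:
        raise PlinkFormatError(
            f"{bed_path}: bad magic bytes {bytes(raw[:3])!r} at offset 0 "
            f"(expected {_BED_MAGIC!r}, SNP-major v1.00)"
        )
    body = raw[3:]
    bytes_per_snp = (n + 3) // 4
    if len(body) != bytes_per_snp * p:
        raise PlinkFormatError(
            f"{bed_path}: {len(body)} data bytes inconsistent with "
            f"{n} individuals x {p} SNPs ({bytes_per_snp * p} expected)"
        )

    blocks = body.reshape(p, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    codes = np.empty((p, bytes_per_snp * 4), dtype=np.uint8)
    for k in range(4):
        codes[:, k::4] = (blocks >> (2 * k)) & 0b11
    dosage = _CODE_TO_DOSAGE[codes[:, :n]].T  # individuals x SNPs

    snps = pd.DataFrame(
        {
            "chrom": bim["chrom"].to_numpy(),
            "pos": bim["pos"].to_numpy(),
            "counted_allele": bim["a1"].to_numpy(),
            "other_allele": bim["a2"].to_numpy(),
        },
        index=pd.Index(bim["snp_id"], name="snp_id"),
    )
    return GenotypeMatrix(dosage=dosage, individual_ids=fam["iid"], snps=snps)


def write_bed(g: GenotypeMatrix, prefix) -> None:
    """Write a GenotypeMatrix as a PLINK bed/bim/fam triplet."""
    bed_path, bim_path, fam_path = _triplet(Path(prefix))
    n, p = g.n_individuals, g.n_snps

    fam = pd.DataFrame(
        {
            "fid": g.individual_ids,
            "iid": g.individual_ids,
            "pat": 0,
            "mat": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(fam_path, sep="\t", header=False, index=False)

    bim = pd.DataFrame(
        {
            "chrom": g.snps["chrom"],
            "snp_id": g.snps.index,
            "cm": 0,
            "pos": g.snps["pos"],
            "a1": g.snps["counted_allele"],
            "a2": g.snps["other_allele"],
        }
    )
    bim.to_csv(bim_path, sep="\t", header=False, index=False)

    dosage = g.dosage
    codes = np.empty((p, n), dtype=np.uint8)
    dT = dosage.T
    codes[np.isnan(dT)] = 0b01
    codes[dT == 2.0] = 0b00
    codes[dT == 1.0] = 0b10
    codes[dT == 0.0] = 0b11

    bytes_per_snp = (n + 3) // 4
    padded = np.zeros((p, bytes_per_snp * 4), dtype=np.uint8)
    padded[:, :n] = codes
    packed = np.zeros((p, bytes_per_snp), dtype=np.uint8)
    for k in range(4):
        packed |= padded[:, k::4] << (2 * k)
    with open(bed_path, "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


def read_raw(path) -> GenotypeMatrix:
    """Read a PLINK .raw additive-dosage text file (``--recode A``).

    Header columns ``FID IID PAT MAT SEX PHENOTYPE`` are followed by one
    column per SNP named ``<snp_id>_<counted_allele>``.  Dosage tokens must
    be 0, 1, 2 or NA.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=r"\s+", dtype=str, keep_default_na=False)
    required = ["FID", "IID", "PAT", "MAT", "SEX", "PHENOTYPE"]
    if list(df.columns[:6]) != required:
        raise PlinkFormatError(
            f"{path}: expected header starting with {' '.join(required)}, "
            f"got {' '.join(df.columns[:6])}"
        )
    snp_cols = list(df.columns[6:])
    snp_ids, counted = [], []
    for c in snp_cols:
        sid, _, allele = c.rpartition("_")
        if not sid:
            raise PlinkFormatError(f"{path}: SNP column {c!r} lacks an allele suffix")
        snp_ids.append(sid)
        counted.append(allele)

    values = df[snp_cols].to_numpy(dtype=object)
    dosage = np.full(values.shape, np.nan)
    token_map = {"0": 0.0, "1": 1.0, "2": 2.0, "NA": np.nan}
    for (i, j), tok in np.ndenumerate(values):
        try:
            dosage[i, j] = token_map[str(tok)]
        except KeyError:
            raise PlinkFormatError(
                f"{path}: invalid dosage token {tok!r} at data row {i + 1}, "
                f"column {snp_cols[j]!r} (expected 0, 1, 2 or NA)"
            ) from None

    snps = pd.DataFrame(
        {
            "chrom": "0",
            "pos": np.arange(1, len(snp_ids) + 1),
            "counted_allele": counted,
            "other_allele": "0",
        },
        index=pd.Index(snp_ids, name="snp_id"),
    )
    return GenotypeMatrix(dosage=dosage, individual_ids=df["IID"], snps=snps)


def write_raw(g: GenotypeMatrix, path) -> None:
    """Write a GenotypeMatrix as a PLINK .raw additive-dosage text file."""
    cols = [
        f"{sid}_{al}"
        for sid, al in zip(g.snps.index, g.snps["counted_allele"])
    ]
    out = pd.DataFrame(g.dosage, columns=cols)
    out = out.map(lambda v: "NA" if np.isnan(v) else str(int(v)))
    meta = pd.DataFrame(
        {
            "FID": g.individual_ids,
            "IID": g.individual_ids,
            "PAT": 0,
            "MAT": 0,
            "SEX": 0,
            "PHENOTYPE": -9,
        }
    )
    pd.concat([meta.reset_index(drop=True), out], axis=1).to_csv(
        path, sep=" ", index=False
    )


def read_phenotypes(path) -> pd.DataFrame:
    """Read a tab-separated phenotype table (id, scr, n_breedings, reliability)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    required = {"id", "scr", "n_breedings", "reliability"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: phenotype table missing columns {sorted(missing)}")
    if df["id"].duplicated().any():
        dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
        raise ValueError(f"{path}: duplicate phenotype record for individual {dup!r}")
    if (df["reliability"] <= 0).any() or (df["reliability"] > 1).any():
        raise ValueError(f"{path}: reliabilities must lie in (0, 1]")
    return df


def write_phenotypes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
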