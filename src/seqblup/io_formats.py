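"""Core containers and on-disk formats.

Containers: :class:`VariantTable`, :class:`GenotypeMatrix`, :class:`SampleTable`.
Formats: PLINK1 ``.bed/.bim/.fam`` triples (SNP-major, hard calls), GCTA
``.grm.bin/.grm.id`` binaries, and tab-separated sample/result tables.

Conventions, fixed package-wide:

* dosages count copies of the A1 allele (the first allele column of the
  ``.bim`` file), coded 0/1/2 with ``MISSING = -1``;
* base-pair positions are 1-based inclusive;
* panels are nested: every 50k-array variant is on the HD panel and every
  HD variant is in the sequence set;
* TSV files are tab-separated UTF-8 with ``.`` for missing values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = -1

#: nested genotype panels, smallest first
PANELS = ("ARRAY50K", "HD", "WGS")

PLINK_MAGIC = bytes([0x6C, 0x1B])
SNP_MAJOR = 0x01

# PLINK1 2-bit codes -> A1-allele dosage (00 = 2 copies of A1, 01 = missing,
# 10 = het, 11 = 0 copies).  Index by the 2-bit value.
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}

SAMPLE_ROLES = ("DISCOVERY", "TRAINING", "VALIDATION", "UNUSED")


class FormatError(ValueError):
    """A file does not conform to its declared binary/text format."""


class ValidationError(ValueError):
    """A container violates one of its documented invariants."""


# ---------------------------------------------------------------------------
# variant table
# ---------------------------------------------------------------------------

@dataclass
class VariantTable:
    """Variant coordinates plus panel membership flags.

    ``df`` columns: variant_id, chrom, pos_bp, allele_a1, allele_a2, and one
    boolean column per panel name in :data:`PANELS`.
    """

    df: pd.DataFrame

    REQUIRED = ("variant_id", "chrom", "pos_bp", "allele_a1", "allele_a2")

    def __post_init__(self) -> None:
        df = self.df
        for col in self.REQUIRED:
            if col not in df.columns:
                raise ValidationError(f"variant table missing column {col!r}")
        for p in PANELS:
            if p not in df.columns:
                df[p] = p == "WGS"
        self.validate()

    def validate(self) -> None:
        df = self.df
        if df["variant_id"].duplicated().any():
            dup = df.loc[df["variant_id"].duplicated(), "variant_id"].iloc[0]
            raise ValidationError(f"duplicate variant id {dup!r}")
        if (df["pos_bp"] < 1).any():
            raise ValidationError("pos_bp must be >= 1 (1-based coordinates)")
        for chrom, sub in df.groupby("chrom", sort=False):
            if not sub["pos_bp"].is_monotonic_increasing:
                raise ValidationError(f"positions not sorted on chromosome {chrom}")
        # panel nesting ARRAY50K <= HD <= WGS
        for small, big in zip(PANELS[:-1], PANELS[1:]):
            if (df[small] & ~df[big]).any():
                raise ValidationError(f"panel nesting violated: {small} not within {big}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["variant_id"].to_numpy()

    def panel_mask(self, panel: str) -> np.ndarray:
        """Boolean mask over variants for a named panel or ``'TOP'``-style custom sets."""
        if panel not in self.df.columns:
            raise KeyError(f"unknown panel {panel!r}")
        return self.df[panel].to_numpy(dtype=bool)


# ---------------------------------------------------------------------------
# genotype matrix
# ---------------------------------------------------------------------------

@dataclass
class GenotypeMatrix:
    """Hard-call dosage matrix (samples x variants), A1-allele counts."""

    samples: list[str]
    variants: VariantTable
    dosage: np.ndarray  # int8, entries in {0,1,2,MISSING}

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=np.int8)
        n, m = self.dosage.shape
        if n != len(self.samples):
            raise ValidationError(f"{len(self.samples)} samples but {n} dosage rows")
        if m != len(self.variants):
            raise ValidationError(f"{len(self.variants)} variants but {m} dosage columns")
        bad = ~np.isin(self.dosage, [0, 1, 2, MISSING])
        if bad.any():
            raise ValidationError("dosage entries must be in {0,1,2,MISSING}")
        all_missing = (self.dosage == MISSING).all(axis=0)
        if all_missing.any():
            ids = self.variants.ids[all_missing]
            warnings.warn(f"{all_missing.sum()} variant(s) entirely missing, e.g. {ids[0]!r}")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def subset(self, sample_ids=None, variant_mask=None) -> "GenotypeMatrix":
        """Restrict to a list of sample ids and/or a boolean variant mask."""
        dos = self.dosage
        samples = self.samples
        vt = self.variants
        if sample_ids is not None:
            idx = _index_of(self.samples, sample_ids)
            dos = dos[idx]
            samples = list(sample_ids)
        if variant_mask is not None:
            variant_mask = np.asarray(variant_mask)
            if variant_mask.dtype == bool:
                cols = np.flatnonzero(variant_mask)
            else:
                cols = variant_mask
            dos = dos[:, cols]
            vt = VariantTable(vt.df.iloc[cols].reset_index(drop=True).copy())
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return GenotypeMatrix(samples, vt, dos.copy())

    def allele_freq(self) -> np.ndarray:
        """Observed A1 allele frequency per variant (missing excluded)."""
        dos = self.dosage
        obs = dos != MISSING
        counts = np.where(obs, dos, 0).sum(axis=0)
        n_obs = obs.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_obs > 0, counts / (2.0 * np.maximum(n_obs, 1)), np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def dosage_float(self, impute_mean: bool = False) -> np.ndarray:
        """Dosage as float64; missing as NaN, or mean-imputed to 2p if requested."""
        x = self.dosage.astype(np.float64)
        miss = self.dosage == MISSING
        if not miss.any():
            return x
        if impute_mean:
            fill = 2.0 * self.allele_freq()
            x[miss] = np.broadcast_to(fill, x.shape)[miss]
        else:
            x[miss] = np.nan
        return x


def _index_of(haystack: list[str], needles) -> np.ndarray:
    pos = {s: i for i, s in enumerate(haystack)}
    try:
        return np.array([pos[s] for s in needles], dtype=np.intp)
    except KeyError as e:
        raise KeyError(f"sample id {e.args[0]!r} not present") from None


# ---------------------------------------------------------------------------
# sample table
# ---------------------------------------------------------------------------

@dataclass
class SampleTable:
    """Per-animal phenotype, pedigree and breed-composition records.

    ``df`` columns: sample_id, sire_id, dam_id, data_source, phenotype,
    corrected_phenotype, role, plus one ``breed_<name>`` column per breed
    group (entries >= 0 summing to 1 per row).
    """

    df: pd.DataFrame

    REQUIRED = ("sample_id", "sire_id", "dam_id", "data_source",
                "phenotype", "corrected_phenotype", "role")

    def __post_init__(self) -> None:
        for col in self.REQUIRED:
            if col not in self.df.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        if not self.breed_columns:
            raise ValidationError("sample table needs at least one breed_* column")
        self.validate()

    @property
    def breed_columns(self) -> list[str]:
        return [c for c in self.df.columns if c.startswith("breed_")]

    def validate(self) -> None:
        df = self.df
        if df["sample_id"].duplicated().any():
            raise ValidationError("duplicate sample ids")
        props = df[self.breed_columns].to_numpy(dtype=float)
        if (props < -1e-12).any():
            raise ValidationError("negative breed proportion")
        bad = np.abs(props.sum(axis=1) - 1.0) > 1e-9
        if bad.any():
            sid = df.loc[bad, "sample_id"].iloc[0]
            raise ValidationError(f"breed proportions of {sid!r} do not sum to 1")
        roles = df["role"].fillna("UNUSED")
        unknown = ~roles.isin(SAMPLE_ROLES)
        if unknown.any():
            raise ValidationError(f"unknown role {roles[unknown].iloc[0]!r}")
        val = df[roles == "VALIDATION"]
        if val["corrected_phenotype"].isna().any():
            raise ValidationError("VALIDATION sample with missing corrected_phenotype")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> np.ndarray:
        return self.df["sample_id"].to_numpy()

    def breed_matrix(self, subgroup_columns: bool = False) -> np.ndarray:
        """Breed-proportion matrix Q (n x n_breeds), row order = table order."""
        cols = self.breed_columns
        if not subgroup_columns:
            cols = [c for c in cols if not c.startswith("breed_sub")]
        return self.df[cols].to_numpy(dtype=float)

    def ids_with_role(self, role: str) -> list[str]:
        return self.df.loc[self.df["role"] == role, "sample_id"].tolist()

    def with_roles(self, role_by_id: dict[str, str]) -> "SampleTable":
        df = self.df.copy()
        df["role"] = df["sample_id"].map(role_by_id).fillna(df["role"])
        return SampleTable(df)


# ---------------------------------------------------------------------------
# PLINK1 bed/bim/fam
# ---------------------------------------------------------------------------

def write_plink(g: GenotypeMatrix, path_prefix) -> None:
    """Write a PLINK1 SNP-major ``.bed/.bim/.fam`` triple."""
    if g.n_samples == 0:
        raise ValidationError("cannot write PLINK files with zero samples")
    if g.n_variants == 0:
        raise ValidationError("cannot write PLINK files with zero variants")
    prefix = str(path_prefix)
    n = g.n_samples
    # .fam: FID IID father mother sex phenotype
    with open(prefix + ".fam", "w") as fh:
        for s in g.samples:
            fh.write(f"0\t{s}\t0\t0\t0\t-9\n")
    vdf = g.variants.df
    with open(prefix + ".bim", "w") as fh:
        for row in vdf.itertuples(index=False):
            fh.write(f"{row.chrom}\t{row.variant_id}\t0\t{row.pos_bp}"
                     f"\t{row.allele_a1}\t{row.allele_a2}\n")
    # .bed: per variant, samples packed 4 to a byte, LSB-first
    codes = np.empty_like(g.dosage, dtype=np.uint8)
    for dos, code in _DOSAGE_TO_CODE.items():
        codes[g.dosage == dos] = code
    n_bytes = (n + 3) // 4
    payload = np.zeros((g.n_variants, n_bytes), dtype=np.uint8)
    for k in range(4):
        idx = np.arange(k, n, 4)
        chunk = codes[idx, :].T.astype(np.uint8) << (2 * k)
        payload[:, : len(idx)] |= chunk
    with open(prefix + ".bed", "wb") as fh:
        fh.write(PLINK_MAGIC)
        fh.write(bytes([SNP_MAJOR]))
        fh.write(payload.tobytes())


def read_plink(path_prefix) -> GenotypeMatrix:
    """Read a PLINK1 SNP-major triple into a :class:`GenotypeMatrix`."""
    prefix = str(path_prefix)
    fam = pd.read_csv(prefix + ".fam", sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    bim = pd.read_csv(prefix + ".bim", sep=r"\s+", header=None,
                      names=["chrom", "variant_id", "cm", "pos_bp",
                             "allele_a1", "allele_a2"],
                      dtype={"chrom": str, "variant_id": str,
                             "allele_a1": str, "allele_a2": str})
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        raw = fh.read()
    if raw[:2] != PLINK_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:2]!r}")
    if raw[2] != SNP_MAJOR:
        raise FormatError(f"{prefix}.bed: not SNP-major (mode byte {raw[2]:#x})")
    n_bytes = (n + 3) // 4
    if len(raw) != 3 + n_bytes * m:
        raise FormatError(f"{prefix}.bed: expected {3 + n_bytes * m} bytes, got {len(raw)}")
    payload = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, n_bytes)
    dosage = np.empty((n, m), dtype=np.int8)
    for k in range(4):
        idx = np.arange(k, n, 4)
        two_bit = (payload[:, : len(idx)] >> (2 * k)) & 0b11
        dosage[idx, :] = _CODE_TO_DOSAGE[two_bit].T
    vt_df = bim[["variant_id", "chrom", "pos_bp", "allele_a1", "allele_a2"]].copy()
    return GenotypeMatrix(fam["iid"].tolist(), VariantTable(vt_df), dosage)


# ---------------------------------------------------------------------------
# GCTA GRM binary
# ---------------------------------------------------------------------------

def write_grm_bin(values: np.ndarray, sample_ids, path_prefix,
                  n_variants_used: int | None = None) -> None:
    """Write GCTA-format ``.grm.bin`` (float32 lower triangle, row-major,
    diagonal included) plus ``.grm.id``; optionally ``.grm.N.bin``."""
    values = np.asarray(values, dtype=np.float64)
    n = len(sample_ids)
    if values.shape != (n, n):
        raise ValidationError("GRM shape does not match id count")
    prefix = str(path_prefix)
    tri = values[np.tril_indices(n)]
    tri.astype("<f4").tofile(prefix + ".grm.bin")
    with open(prefix + ".grm.id", "w") as fh:
        for s in sample_ids:
            fh.write(f"0\t{s}\n")
    if n_variants_used is not None:
        np.full(tri.shape, n_variants_used, dtype="<f4").tofile(prefix + ".grm.N.bin")


def read_grm_bin(path_prefix) -> tuple[np.ndarray, list[str]]:
    """Read a GCTA GRM binary; returns (symmetric matrix, sample ids)."""
    prefix = str(path_prefix)
    ids = pd.read_csv(prefix + ".grm.id", sep="\t", header=None,
                      names=["fid", "iid"], dtype=str)["iid"].tolist()
    n = len(ids)
    tri = np.fromfile(prefix + ".grm.bin", dtype="<f4")
    expect = n * (n + 1) // 2
    if tri.size != expect:
        raise FormatError(f"{prefix}.grm.bin holds {tri.size} values, "
                          f"expected {expect} for {n} ids")
    out = np.zeros((n, n), dtype=np.float64)
    out[np.tril_indices(n)] = tri
    out = out + np.tril(out, -1).T
    return out, ids


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def write_table(df: pd.DataFrame, path) -> None:
    """Write any result table as tab-separated UTF-8, '.' for missing."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_samples(path) -> SampleTable:
    """Read a sample table TSV (see :class:`SampleTable` for columns)."""
    df = pd.read_csv(path, sep="\t", na_values=["."], dtype={"sample_id": str})
    for col in ("sire_id", "dam_id", "data_source", "role"):
        if col in df.columns:
            df[col] = df[col].astype("string").astype(object)
            df.loc[df[col].isna(), col] = None
    if "role" in df.columns:
        df["role"] = df["role"].fillna("UNUSED") if df["role"].notna().any() else "UNUSED"
    return SampleTable(df)


def write_samples(table: SampleTable, path) -> None:
    write_table(table.df, path)


def read_variant_ids(path) -> list[str]:
    """Read a one-id-per-line variant list (panel membership file)."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_variant_ids(ids, path) -> None:
    with open(path, "w") as fh:
        for v in ids:
            fh.write(f"{v}\n")
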