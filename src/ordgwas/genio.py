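"""Readers, writers and the core data model shared by all other modules.

Genotypes are held as an ``n x m`` matrix of non-reference allele counts
in ``{0, 1, 2}`` (inbred panels occupy ``{0, 2}``), stored as floats with
``numpy.nan`` as the missing sentinel.  Marker coordinates are 1-based
base pairs, as in VCF.

Two on-disk formats are supported:

* a wide tab-separated layout with header
  ``marker  chrom  pos  <sample1> ... <sampleN>`` and cells in
  ``{0, 1, 2, NA}``;
* standard VCF 4.x (biallelic SNPs; the GT field is converted to the
  alternate-allele count, phased and unphased treated identically).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("ordgwas")

__all__ = [
    "FormatError",
    "ValidationError",
    "GenotypeMatrix",
    "OrdinalPhenotype",
    "ContinuousPhenotype",
    "CovariateDesign",
    "read_genotypes",
    "write_genotypes",
    "read_phenotype",
    "read_qmatrix",
    "filter_maf",
    "impute_missing",
    "build_covariates",
]


class FormatError(ValueError):
    """A file does not follow the declared on-disk layout."""


class ValidationError(ValueError):
    """An in-memory object violates a data-model invariant."""


_VALID_DOSAGES = (0.0, 1.0, 2.0)


@dataclass
class GenotypeMatrix:
    """Biallelic marker panel: samples, marker map and allele-count dosages."""

    samples: list[str]
    markers: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.validate()

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def m(self) -> int:
        return len(self.markers)

    def validate(self) -> None:
        if self.dosages.shape != (self.n, self.m):
            raise ValidationError(
                f"dosage matrix has shape {self.dosages.shape}, "
                f"expected ({self.n}, {self.m})"
            )
        if len(set(self.markers)) != self.m:
            dupes = pd.Index(self.markers)
            dupes = sorted(set(dupes[dupes.duplicated()]))
            raise ValidationError(f"duplicate marker ids: {dupes[:5]}")
        if len(self.chrom) != self.m or len(self.pos) != self.m:
            raise ValidationError("marker map length does not match marker count")
        if self.m and self.pos.min() < 0:
            raise ValidationError("marker positions must be >= 0")
        obs = self.dosages[np.isfinite(self.dosages)]
        bad = obs[~np.isin(obs, _VALID_DOSAGES)]
        if bad.size:
            i, j = np.argwhere(
                np.isfinite(self.dosages)
                & ~np.isin(self.dosages, _VALID_DOSAGES)
            )[0]
            raise ValidationError(
                f"dosage {self.dosages[i, j]!r} for marker "
                f"{self.markers[j]!r}, sample {self.samples[i]!r} "
                "is not in {0, 1, 2, NA}"
            )

    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency over non-missing dosages."""
        freq = np.nanmean(self.dosages, axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    def take(self, indices) -> "GenotypeMatrix":
        """Column subset preserving sample order and the marker map."""
        idx = np.asarray(indices, dtype=int)
        return GenotypeMatrix(
            samples=list(self.samples),
            markers=[self.markers[j] for j in idx],
            chrom=self.chrom[idx],
            pos=self.pos[idx],
            dosages=self.dosages[:, idx],
        )

    def centered(self, indices=None) -> np.ndarray:
        """Dosage columns centered by their (non-missing) mean.

        Centering makes the intercept interpretable and leaves slopes and
        their tests unchanged; all model fits consume centered columns.
        """
        X = self.dosages if indices is None else self.dosages[:, np.asarray(indices, int)]
        return X - np.nanmean(X, axis=0, keepdims=True)


@dataclass
class OrdinalPhenotype:
    """An ordinal (hierarchical) trait: n integer levels among L ordered ones."""

    values: np.ndarray
    levels: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 1:
            raise ValidationError("ordinal phenotype must be a 1-d vector")
        observed = np.unique(self.values)
        if self.levels is None:
            self.levels = observed
        else:
            self.levels = np.unique(np.asarray(self.levels))
            extra = np.setdiff1d(observed, self.levels)
            if extra.size:
                raise ValidationError(
                    f"values {extra.tolist()} are not among declared levels"
                )
        if len(self.levels) < 2:
            raise ValidationError("an ordinal trait needs at least 2 levels")
        if observed.size < 2:
            raise ValidationError(
                "degenerate trait: fewer than two distinct levels observed"
            )

    @property
    def L(self) -> int:
        return len(self.levels)

    @property
    def n(self) -> int:
        return len(self.values)

    def codes(self) -> np.ndarray:
        """Integer level codes 1..L (1 = lowest level)."""
        return np.searchsorted(self.levels, self.values) + 1

    def as_numeric(self) -> np.ndarray:
        """Level codes as floats — the working response of the linear model."""
        return self.codes().astype(float)


@dataclass
class ContinuousPhenotype:
    """A real-valued phenotype with its provenance (OData, CPData or index)."""

    values: np.ndarray
    provenance: str = "OData"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValidationError("continuous phenotype must be a 1-d vector")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("continuous phenotype contains non-finite values")

    @property
    def n(self) -> int:
        return len(self.values)


@dataclass
class CovariateDesign:
    """Fixed-effect design: intercept column plus population-structure terms."""

    W: np.ndarray
    column_names: list[str]

    def __post_init__(self) -> None:
        self.W = np.asarray(self.W, dtype=float)
        if self.W.ndim != 2:
            raise ValidationError("W must be 2-d")
        if not np.allclose(self.W[:, 0], 1.0):
            raise ValidationError("first covariate column must be the intercept")
        if np.linalg.matrix_rank(self.W) < self.W.shape[1]:
            raise ValidationError("covariate design is rank deficient")

    @property
    def c(self) -> int:
        return self.W.shape[1]

    @property
    def n(self) -> int:
        return self.W.shape[0]


def build_covariates(q_matrix=None, n: int | None = None) -> CovariateDesign:
    """Assemble ``W = [1 | Q]`` from a membership-proportion Q matrix.

    Because the K membership columns sum to one, only the first K-1 are
    kept alongside the intercept; the reduced design is full rank by
    construction whenever subpopulations are distinguishable.
    """
    if q_matrix is None:
        if n is None:
            raise ValidationError("either q_matrix or n must be given")
        return CovariateDesign(np.ones((n, 1)), ["intercept"])
    Q = np.asarray(q_matrix, dtype=float)
    if Q.ndim != 2:
        raise ValidationError("Q matrix must be 2-d")
    if n is not None and Q.shape[0] != n:
        raise ValidationError(
            f"Q matrix has {Q.shape[0]} rows, expected {n} samples"
        )
    rs = Q.sum(axis=1)
    if not np.allclose(rs, 1.0, atol=1e-3):
        logger.warning(
            "Q-matrix rows do not sum to 1 (max deviation %.3g); "
            "using the columns as given", float(np.max(np.abs(rs - 1.0)))
        )
    K = Q.shape[1]
    W = np.column_stack([np.ones(Q.shape[0]), Q[:, : max(K - 1, 0)]])
    names = ["intercept"] + [f"q{k + 1}" for k in range(max(K - 1, 0))]
    return CovariateDesign(W, names)


def filter_maf(G: GenotypeMatrix, floor: float) -> GenotypeMatrix:
    """Drop markers whose minor-allele frequency is <= ``floor`` (strict keep)."""
    if not 0 <= floor < 0.5:
        raise ValidationError("MAF floor must lie in [0, 0.5)")
    keep = np.flatnonzero(G.maf() > floor)
    if keep.size == 0:
        raise ValidationError("MAF filter removed every marker")
    if keep.size < G.m:
        logger.info("MAF filter removed %d of %d markers", G.m - keep.size, G.m)
    return G.take(keep)


def impute_missing(G: GenotypeMatrix) -> GenotypeMatrix:
    """Replace missing dosages by the marker's mean over non-missing samples."""
    D = G.dosages
    miss = ~np.isfinite(D)
    if not miss.any():
        return G
    all_missing = np.flatnonzero(miss.all(axis=0))
    if all_missing.size:
        raise ValidationError(
            f"marker {G.markers[all_missing[0]]!r} has no observed genotypes"
        )
    out = D.copy()
    col_mean = np.nanmean(D, axis=0)
    rows, cols = np.nonzero(miss)
    out[rows, cols] = col_mean[cols]
    logger.info("imputed %d missing genotype cells", rows.size)
    g = GenotypeMatrix.__new__(GenotypeMatrix)
    g.samples = list(G.samples)
    g.markers = list(G.markers)
    g.chrom = G.chrom.copy()
    g.pos = G.pos.copy()
    g.dosages = out  # imputed means are fractional; skip {0,1,2} validation
    return g


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str | None = None) -> GenotypeMatrix:
    """Read a genotype panel from wide TSV or VCF (inferred from the suffix)."""
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix in {".vcf", ".gz", ".bcf"} else "tsv"
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "vcf":
        return _read_genotypes_vcf(path)
    raise FormatError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["marker", "chrom", "pos"]
    if list(df.columns[:3]) != required:
        raise FormatError(
            f"genotype TSV must start with columns {required}, "
            f"found {list(df.columns[:3])}"
        )
    sample_cols = list(df.columns[3:])
    if not sample_cols:
        raise FormatError("genotype TSV has no sample columns")
    markers = df["marker"].tolist()
    body = df[sample_cols].replace("NA", np.nan)
    try:
        dosages = body.to_numpy(dtype=float).T  # (n, m)
    except ValueError as exc:
        raise FormatError(f"non-numeric genotype cell: {exc}") from exc
    obs = dosages[np.isfinite(dosages)]
    if obs.size and not np.all(np.isin(obs, _VALID_DOSAGES)):
        i, j = np.argwhere(
            np.isfinite(dosages) & ~np.isin(dosages, _VALID_DOSAGES)
        )[0]
        raise ValidationError(
            f"dosage {dosages[i, j]!r} for marker {markers[j]!r}, "
            f"sample {sample_cols[i]!r} is not in {{0, 1, 2, NA}}"
        )
    try:
        pos = df["pos"].astype(np.int64).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-integer position: {exc}") from exc
    return GenotypeMatrix(
        samples=sample_cols,
        markers=markers,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos=pos,
        dosages=dosages,
    )


def _read_genotypes_vcf(path: Path) -> GenotypeMatrix:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF requires the cyvcf2 extra") from exc
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    markers, chroms, poss, cols = [], [], [], []
    skipped = 0
    for var in vcf:
        if len(var.ALT) != 1:
            skipped += 1
            continue
        ident = var.ID if var.ID not in (None, ".") else f"{var.CHROM}_{var.POS}"
        markers.append(ident)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        gts = np.array([g[:2] for g in var.genotypes], dtype=float)
        gts[gts < 0] = np.nan  # -1 encodes a missing allele
        cols.append(gts.sum(axis=1))
    if skipped:
        logger.warning("skipped %d non-biallelic VCF records", skipped)
    dosages = np.column_stack(cols) if cols else np.empty((len(samples), 0))
    return GenotypeMatrix(
        samples=samples,
        markers=markers,
        chrom=np.array(chroms, dtype=object),
        pos=np.array(poss, dtype=np.int64),
        dosages=dosages,
    )


def write_genotypes(G: GenotypeMatrix, path) -> None:
    """Write the wide TSV dialect; exact round-trip for unimputed panels."""
    def fmt(v: float) -> str:
        if not np.isfinite(v):
            return "NA"
        if v == int(v):
            return str(int(v))
        return repr(v)

    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(["marker", "chrom", "pos", *G.samples]) + "\n")
        for j in range(G.m):
            cells = [fmt(v) for v in G.dosages[:, j]]
            fh.write(
                "\t".join([G.markers[j], str(G.chrom[j]), str(G.pos[j]), *cells])
                + "\n"
            )


def read_phenotype(path) -> pd.Series:
    """Read a `sample  value` phenotype TSV into a Series indexed by sample."""
    df = pd.read_csv(path, sep="\t")
    if list(df.columns[:2]) != ["sample", "value"]:
        raise FormatError(
            f"phenotype TSV must have columns ['sample', 'value'], "
            f"found {list(df.columns[:2])}"
        )
    return df.set_index("sample")["value"]


def read_qmatrix(path) -> pd.DataFrame:
    """Read a `sample  q1 ... qK` population-structure TSV."""
    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "sample":
        raise FormatError("Q-matrix TSV must have a leading 'sample' column")
    return df.set_index("sample")
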