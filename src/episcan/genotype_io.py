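"""Reading, writing and validation of case/control genotype matrices.

The native on-disk layout is a whitespace-delimited TSV with one row per
SNP (first column = SNP id, remaining columns = per-sample genotype codes
0/1/2 or ``NA`` for missing) plus a phenotype file with one label per line
(0 = control, 1 = case) aligned with the sample columns.  The PLINK
``.raw`` dialect (rows = samples, six leading metadata columns, additive
dosage coding) is supported as an alternative input format.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np

#: Internal sentinel for a missing genotype call. On disk this is "NA".
MISSING: int = -1

#: Tokens accepted as a missing genotype when parsing.
_MISSING_TOKENS = frozenset({"NA", "na", ".", "-9", "nan", "NaN"})

_VALID_CODES = frozenset({0, 1, 2, MISSING})


class GenotypeParseError(ValueError):
    """A genotype or phenotype token could not be interpreted."""


class GenotypeCodingError(ValueError):
    """Values are parseable but violate the 0/1/2/NA (or 0/1) coding."""


class DimensionError(ValueError):
    """Genotype and phenotype dimensions disagree."""


@dataclass
class GenotypeMatrix:
    """An m-SNP x n-sample genotype matrix with binary phenotype labels.

    Genotypes count copies of the variant allele (0, 1 or 2 in diploids);
    :data:`MISSING` (-1) marks a failed call.  Phenotypes are 0 for
    controls and 1 for cases.
    """

    snp_ids: list[str]
    genotypes: np.ndarray  # (m, n) int8, codes {0,1,2,MISSING}
    phenotypes: np.ndarray  # (n,) int8, codes {0,1}
    sample_ids: list[str] = field(default_factory=list)
    #: permit a cohort with only one phenotype class (unlabeled
    #: simulator output, before phenotype assignment); scans reject it.
    allow_single_class: bool = False

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        self.phenotypes = np.asarray(self.phenotypes, dtype=np.int8)
        if self.genotypes.ndim != 2:
            raise DimensionError("genotypes must be a 2-D (SNPs x samples) array")
        m, n = self.genotypes.shape
        if m < 1 or n < 1:
            raise DimensionError("need at least one SNP and one sample")
        if not self.sample_ids:
            self.sample_ids = [f"sample{i}" for i in range(n)]
        if len(self.snp_ids) != m:
            raise DimensionError(f"{len(self.snp_ids)} SNP ids for {m} SNP rows")
        if len(self.sample_ids) != n:
            raise DimensionError(f"{len(self.sample_ids)} sample ids for {n} samples")
        if self.phenotypes.shape != (n,):
            raise DimensionError(
                f"phenotype length {self.phenotypes.shape} does not match {n} samples"
            )
        bad = set(np.unique(self.genotypes).tolist()) - _VALID_CODES
        if bad:
            raise GenotypeCodingError(f"invalid genotype codes {sorted(bad)}")
        if set(np.unique(self.phenotypes).tolist()) - {0, 1}:
            raise GenotypeCodingError("phenotypes must be 0 (control) or 1 (case)")
        if not self.allow_single_class and (
            not (self.phenotypes == 0).any() or not (self.phenotypes == 1).any()
        ):
            raise GenotypeCodingError("need at least one case and one control")
        if len(set(self.snp_ids)) != m:
            raise GenotypeCodingError("SNP ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise GenotypeCodingError("sample ids must be unique")

    @property
    def m(self) -> int:
        """Number of SNPs."""
        return self.genotypes.shape[0]

    @property
    def n(self) -> int:
        """Number of samples."""
        return self.genotypes.shape[1]

    @property
    def n_cases(self) -> int:
        return int((self.phenotypes == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.phenotypes == 0).sum())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.snp_ids == other.snp_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.genotypes, other.genotypes)
            and np.array_equal(self.phenotypes, other.phenotypes)
        )


def _parse_genotype_token(tok: str, row: int, col: int, where: str) -> int:
    if tok in _MISSING_TOKENS:
        return MISSING
    try:
        val = int(tok)
    except ValueError:
        raise GenotypeParseError(
            f"{where}: unparseable genotype token {tok!r} at row {row}, column {col}"
        ) from None
    if val not in (0, 1, 2):
        raise GenotypeParseError(
            f"{where}: genotype code {val} outside {{0,1,2}} at row {row}, column {col}"
        )
    return val


def _read_phenotype_file(path: str | os.PathLike) -> np.ndarray:
    labels: list[int] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            tok = line.strip()
            if not tok:
                continue
            try:
                val = int(tok)
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: unparseable phenotype {tok!r} on line {lineno}"
                ) from None
            labels.append(val)
    arr = np.array(labels, dtype=np.int8)
    if set(np.unique(arr).tolist()) - {0, 1}:
        raise GenotypeCodingError(f"{path}: phenotypes must be coded 0/1")
    return arr


def _read_native_tsv(genotype_path: str | os.PathLike) -> tuple[list[str], np.ndarray]:
    snp_ids: list[str] = []
    rows: list[list[int]] = []
    with open(genotype_path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            snp_ids.append(fields[0])
            rows.append(
                [
                    _parse_genotype_token(tok, lineno, c + 2, str(genotype_path))
                    for c, tok in enumerate(fields[1:])
                ]
            )
    if not rows:
        raise GenotypeParseError(f"{genotype_path}: no genotype rows found")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise DimensionError(f"{genotype_path}: ragged rows with widths {sorted(widths)}")
    return snp_ids, np.array(rows, dtype=np.int8)


def _read_plink_raw(path: str | os.PathLike) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Parse a PLINK ``.raw`` additive-dosage export (rows = samples)."""
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) < 7 or header[:2] != ["FID", "IID"]:
            raise GenotypeParseError(f"{path}: not a PLINK .raw header: {header[:6]}")
        snp_ids = header[6:]
        sample_ids: list[str] = []
        phenos: list[int] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, 2):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 6 + len(snp_ids):
                raise DimensionError(
                    f"{path}: line {lineno} has {len(fields)} fields, "
                    f"expected {6 + len(snp_ids)}"
                )
            sample_ids.append(f"{fields[0]}_{fields[1]}")
            try:
                phenos.append(int(fields[5]))
            except ValueError:
                raise GenotypeParseError(
                    f"{path}: unparseable phenotype {fields[5]!r} on line {lineno}"
                ) from None
            rows.append(
                [
                    _parse_genotype_token(tok, lineno, c + 7, str(path))
                    for c, tok in enumerate(fields[6:])
                ]
            )
    if not rows:
        raise GenotypeParseError(f"{path}: no sample rows found")
    pheno = np.array(phenos, dtype=np.int8)
    values = set(np.unique(pheno).tolist())
    if values <= {1, 2}:  # PLINK case/control coding: 1 = control, 2 = case
        pheno = pheno - 1
    elif not values <= {0, 1}:
        raise GenotypeCodingError(
            f"{path}: phenotype values {sorted(values)} not 1/2 (PLINK) or 0/1"
        )
    # transpose to SNPs x samples
    return snp_ids, sample_ids, np.array(rows, dtype=np.int8).T, pheno


def read_genotype_matrix(
    genotype_path: str | os.PathLike,
    phenotype_path: str | os.PathLike | None = None,
    format: str = "native_tsv",
) -> GenotypeMatrix:
    """Load a :class:`GenotypeMatrix` from disk.

    Parameters
    ----------
    genotype_path
        Genotype TSV (``native_tsv``, rows = SNPs) or PLINK ``.raw`` file
        (``plink_raw``, rows = samples; phenotype taken from column 6).
    phenotype_path
        Phenotype file, one 0/1 label per line.  Required for
        ``native_tsv``; ignored for ``plink_raw``.
    format
        ``"native_tsv"`` or ``"plink_raw"``.
    """
    if format == "native_tsv":
        if phenotype_path is None:
            raise ValueError("native_tsv requires a phenotype file")
        snp_ids, geno = _read_native_tsv(genotype_path)
        pheno = _read_phenotype_file(phenotype_path)
        if pheno.shape[0] != geno.shape[1]:
            raise DimensionError(
                f"{pheno.shape[0]} phenotypes for {geno.shape[1]} samples"
            )
        return GenotypeMatrix(snp_ids=snp_ids, genotypes=geno, phenotypes=pheno)
    if format == "plink_raw":
        snp_ids, sample_ids, geno, pheno = _read_plink_raw(genotype_path)
        return GenotypeMatrix(
            snp_ids=snp_ids, genotypes=geno, phenotypes=pheno, sample_ids=sample_ids
        )
    raise ValueError(f"unknown format {format!r}; expected native_tsv or plink_raw")


def write_genotype_matrix(
    gm: GenotypeMatrix,
    genotype_path: str | os.PathLike,
    phenotype_path: str | os.PathLike,
) -> None:
    """Write ``gm`` in the native TSV layout (round-trips exactly)."""
    with open(genotype_path, "w") as fh:
        for i, sid in enumerate(gm.snp_ids):
            toks = ["NA" if g == MISSING else str(int(g)) for g in gm.genotypes[i]]
            fh.write(sid + "\t" + "\t".join(toks) + "\n")
    with open(phenotype_path, "w") as fh:
        for y in gm.phenotypes:
            fh.write(f"{int(y)}\n")
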