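"""Genotype matrices and the ancient-DNA text interchange formats.

The central container is :class:`GenotypeMatrix`: an ordered list of sample
records, an ordered list of SNP records, and an ``n_samples x n_snps`` array
of alt-allele counts in {0, 1, 2} with ``MISSING`` (-1) for no-calls.
Pseudo-haploid data, common for low-coverage ancient samples, is simply a
matrix whose calls are restricted to {0, 2, MISSING}; no flag distinguishes
it, because all downstream math treats calls as allele-count estimates.

Supported on-disk formats:

* EIGENSTRAT ``.geno/.snp/.ind`` — one line per SNP in ``.geno``, one digit
  per sample, ``9`` meaning missing.
* PLINK text in the ``.traw`` dialect (numeric allele-dosage table, one row
  per SNP) paired with a ``.fam`` file for sample records.
* A sample-metadata TSV (``sample_id, population, sex, date_start, date_end,
  role``) carrying the archaeological annotations the three-file formats
  cannot hold.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MISSING",
    "SNPRecord",
    "SampleRecord",
    "GenotypeMatrix",
    "GenotypeParseError",
    "read_genotypes",
    "write_genotypes",
    "read_metadata",
    "write_metadata",
    "subset",
]

#: Internal code for a missing call (EIGENSTRAT writes it as ``9``).
MISSING: int = -1

_VALID_CODES = frozenset({0, 1, 2, MISSING})
_SEXES = frozenset({"M", "F", "U"})
_ROLES = frozenset({"source", "target", "reference", "outgroup", "unknown"})
_IUPAC = frozenset("ACGTRYSWKMBDHVN")


class GenotypeParseError(ValueError):
    """Structured parse failure naming the offending file and line."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc = f" [{path}" + (f", line {line}" if line is not None else "") + "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


@dataclass(frozen=True)
class SNPRecord:
    """One biallelic autosomal site."""

    snp_id: str
    chromosome: str
    genetic_pos: float  # morgans
    physical_pos: int  # 1-based bp
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        for a in (self.ref_allele, self.alt_allele):
            if len(a) != 1 or a.upper() not in _IUPAC:
                raise ValueError(f"{self.snp_id}: invalid allele {a!r}")
        if self.physical_pos < 1:
            raise ValueError(f"{self.snp_id}: physical_pos must be >= 1")
        if self.genetic_pos < 0:
            raise ValueError(f"{self.snp_id}: genetic_pos must be >= 0")


@dataclass(frozen=True)
class SampleRecord:
    """One individual with its archaeological metadata.

    ``date_range`` is (start, end) in integer years, negative for BCE.
    ``role`` marks how the sample enters admixture modeling.
    """

    sample_id: str
    population: str
    sex: str = "U"
    date_range: tuple[int, int] = (0, 0)
    role: str = "unknown"

    def __post_init__(self):
        if not self.population:
            raise ValueError(f"{self.sample_id}: empty population label")
        if self.sex not in _SEXES:
            raise ValueError(f"{self.sample_id}: sex must be one of {sorted(_SEXES)}")
        if self.role not in _ROLES:
            raise ValueError(f"{self.sample_id}: unknown role {self.role!r}")
        if self.date_range[0] > self.date_range[1]:
            raise ValueError(f"{self.sample_id}: date_range start > end")


@dataclass
class GenotypeMatrix:
    """Samples x SNPs alt-allele counts with per-axis records."""

    samples: list[SampleRecord]
    snps: list[SNPRecord]
    calls: np.ndarray  # int8, shape (n_samples, n_snps)

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        bad = ~np.isin(self.calls, list(_VALID_CODES))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"invalid call code {int(self.calls[i, j])} at sample "
                f"{self.samples[i].sample_id}, SNP {self.snps[j].snp_id}"
            )
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sample_id")
        sids = [s.snp_id for s in self.snps]
        if len(set(sids)) != len(sids):
            raise ValueError("duplicate snp_id")

    # -- convenience views ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]

    @property
    def populations(self) -> list[str]:
        return [s.population for s in self.samples]

    def population_index(self) -> dict[str, np.ndarray]:
        """Map population label -> integer row indices."""
        out: dict[str, list[int]] = {}
        for i, s in enumerate(self.samples):
            out.setdefault(s.population, []).append(i)
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def __eq__(self, other) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.calls, other.calls)
        )


# ---------------------------------------------------------------------------
# subsetting
# ---------------------------------------------------------------------------

def subset(
    matrix: GenotypeMatrix,
    sample_ids: Sequence[str] | None = None,
    snp_ids: Sequence[str] | None = None,
    populations: Sequence[str] | None = None,
) -> GenotypeMatrix:
    """Restrict a matrix to the requested samples/SNPs/populations.

    Original file order is preserved; requesting an unknown id raises with
    the full list of missing ids.
    """
    all_sample_ids = matrix.sample_ids
    all_snp_ids = matrix.snp_ids
    rows = np.arange(matrix.n_samples)
    if populations is not None:
        known = set(matrix.populations)
        missing = sorted(set(populations) - known)
        if missing:
            raise KeyError(f"unknown populations: {missing}")
        keep = set(populations)
        rows = np.asarray(
            [i for i in rows if matrix.samples[i].population in keep], dtype=int
        )
    if sample_ids is not None:
        missing = sorted(set(sample_ids) - set(all_sample_ids))
        if missing:
            raise KeyError(f"unknown sample ids: {missing}")
        want = set(sample_ids)
        rows = np.asarray([i for i in rows if all_sample_ids[i] in want], dtype=int)
    cols = np.arange(matrix.n_snps)
    if snp_ids is not None:
        missing = sorted(set(snp_ids) - set(all_snp_ids))
        if missing:
            raise KeyError(f"unknown snp ids: {missing}")
        want = set(snp_ids)
        cols = np.asarray([j for j in cols if all_snp_ids[j] in want], dtype=int)
    return GenotypeMatrix(
        samples=[matrix.samples[i] for i in rows],
        snps=[matrix.snps[j] for j in cols],
        calls=matrix.calls[np.ix_(rows, cols)].copy(),
    )


# ---------------------------------------------------------------------------
# EIGENSTRAT
# ---------------------------------------------------------------------------

_EIG_TO_CODE = {"0": 0, "1": 1, "2": 2, "9": MISSING}
_CODE_TO_EIG = {0: "0", 1: "1", 2: "2", MISSING: "9"}


def _read_eigenstrat(geno_path, snp_path, ind_path) -> GenotypeMatrix:
    snps: list[SNPRecord] = []
    with open(snp_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise GenotypeParseError(
                    f"expected 6 columns, found {len(parts)}", snp_path, ln
                )
            snps.append(
                SNPRecord(
                    snp_id=parts[0],
                    chromosome=parts[1],
                    genetic_pos=float(parts[2]),
                    physical_pos=int(parts[3]),
                    ref_allele=parts[4],
                    alt_allele=parts[5],
                )
            )
    samples: list[SampleRecord] = []
    with open(ind_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 3:
                raise GenotypeParseError(
                    f"expected 3 columns, found {len(parts)}", ind_path, ln
                )
            samples.append(
                SampleRecord(sample_id=parts[0], sex=parts[1], population=parts[2])
            )
    calls = np.full((len(samples), len(snps)), MISSING, dtype=np.int8)
    with open(geno_path) as fh:
        row = 0
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if row >= len(snps):
                raise GenotypeParseError(
                    f"more genotype lines than the {len(snps)} SNPs in {snp_path}",
                    geno_path,
                    ln,
                )
            if len(line) != len(samples):
                raise GenotypeParseError(
                    f"genotype line has {len(line)} characters but .ind lists "
                    f"{len(samples)} samples",
                    geno_path,
                    ln,
                )
            try:
                calls[:, row] = [_EIG_TO_CODE[c] for c in line]
            except KeyError as exc:
                raise GenotypeParseError(
                    f"unknown genotype code {exc.args[0]!r}", geno_path, ln
                ) from None
            row += 1
    if row != len(snps):
        raise GenotypeParseError(
            f"{row} genotype lines but {len(snps)} SNPs in {snp_path}", geno_path
        )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def _write_eigenstrat(matrix: GenotypeMatrix, geno_path, snp_path, ind_path) -> None:
    with open(snp_path, "w") as fh:
        for s in matrix.snps:
            # repr keeps morgans lossless across a write/read round trip
            fh.write(
                f"{s.snp_id}\t{s.chromosome}\t{s.genetic_pos!r}"
                f"\t{s.physical_pos}\t{s.ref_allele}\t{s.alt_allele}\n"
            )
    with open(ind_path, "w") as fh:
        for s in matrix.samples:
            fh.write(f"{s.sample_id}\t{s.sex}\t{s.population}\n")
    with open(geno_path, "w") as fh:
        for j in range(matrix.n_snps):
            fh.write("".join(_CODE_TO_EIG[int(c)] for c in matrix.calls[:, j]) + "\n")


# ---------------------------------------------------------------------------
# PLINK text (.traw dialect + .fam)
# ---------------------------------------------------------------------------

_FAM_SEX = {"1": "M", "2": "F", "0": "U"}
_SEX_FAM = {"M": "1", "F": "2", "U": "0"}


def _read_plink_text(traw_path, fam_path) -> GenotypeMatrix:
    samples: list[SampleRecord] = []
    with open(fam_path) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) < 6:
                raise GenotypeParseError(
                    f"expected 6 columns, found {len(parts)}", fam_path, ln
                )
            samples.append(
                SampleRecord(
                    sample_id=parts[1],
                    population=parts[0],
                    sex=_FAM_SEX.get(parts[4], "U"),
                )
            )
    snps: list[SNPRecord] = []
    rows: list[np.ndarray] = []
    with open(traw_path) as fh:
        header = fh.readline().split("\t")
        if header[:6] != ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]:
            raise GenotypeParseError("not a .traw header", traw_path, 1)
        n_cols = len(header)
        if n_cols - 6 != len(samples):
            raise GenotypeParseError(
                f"{n_cols - 6} genotype columns but .fam lists {len(samples)} samples",
                traw_path,
                1,
            )
        for ln, line in enumerate(fh, 2):
            parts = line.rstrip("\n").split("\t")
            if parts == [""]:
                continue
            if len(parts) != n_cols:
                raise GenotypeParseError(
                    f"expected {n_cols} columns, found {len(parts)}", traw_path, ln
                )
            # COUNTED is the alt allele in this dialect, ALT holds the ref.
            snps.append(
                SNPRecord(
                    snp_id=parts[1],
                    chromosome=parts[0],
                    genetic_pos=float(parts[2]),
                    physical_pos=int(parts[3]),
                    ref_allele=parts[5],
                    alt_allele=parts[4],
                )
            )
            row = np.empty(len(samples), dtype=np.int8)
            for i, tok in enumerate(parts[6:]):
                if tok in ("NA", "nan", ""):
                    row[i] = MISSING
                else:
                    try:
                        val = int(float(tok))
                    except ValueError:
                        raise GenotypeParseError(
                            f"unknown genotype value {tok!r}", traw_path, ln
                        ) from None
                    if val not in (0, 1, 2):
                        raise GenotypeParseError(
                            f"genotype value {tok!r} outside 0/1/2", traw_path, ln
                        )
                    row[i] = val
            rows.append(row)
    calls = (
        np.stack(rows, axis=1)
        if rows
        else np.empty((len(samples), 0), dtype=np.int8)
    )
    return GenotypeMatrix(samples=samples, snps=snps, calls=calls)


def _write_plink_text(matrix: GenotypeMatrix, traw_path, fam_path) -> None:
    with open(fam_path, "w") as fh:
        for s in matrix.samples:
            fh.write(
                f"{s.population}\t{s.sample_id}\t0\t0\t{_SEX_FAM[s.sex]}\t-9\n"
            )
    with open(traw_path, "w") as fh:
        cols = [f"{s.population}_{s.sample_id}" for s in matrix.samples]
        fh.write("\t".join(["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"] + cols) + "\n")
        for j, s in enumerate(matrix.snps):
            vals = [
                "NA" if c == MISSING else str(int(c)) for c in matrix.calls[:, j]
            ]
            fh.write(
                "\t".join(
                    [
                        s.chromosome,
                        s.snp_id,
                        repr(s.genetic_pos),
                        str(s.physical_pos),
                        s.alt_allele,
                        s.ref_allele,
                    ]
                    + vals
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# public read/write
# ---------------------------------------------------------------------------

def read_genotypes(geno_path, snp_path, ind_path, format: str = "eigenstrat") -> GenotypeMatrix:
    """Read a genotype matrix.

    For ``format="eigenstrat"`` the three paths are ``.geno``, ``.snp`` and
    ``.ind``.  For ``format="plink_text"`` pass the ``.traw`` path as
    ``geno_path`` and the ``.fam`` path as ``ind_path`` (``snp_path`` is
    ignored: the traw table carries the SNP map).
    """
    for p in (geno_path, ind_path) + ((snp_path,) if format == "eigenstrat" else ()):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    if format == "eigenstrat":
        return _read_eigenstrat(geno_path, snp_path, ind_path)
    if format == "plink_text":
        return _read_plink_text(geno_path, ind_path)
    raise ValueError(f"unknown format {format!r}")


def write_genotypes(matrix: GenotypeMatrix, prefix, format: str = "eigenstrat") -> dict[str, Path]:
    """Write ``matrix`` under ``prefix`` and return the written paths.

    Output is byte-stable for identical input: no timestamps or environment
    information enter the data files.
    """
    if matrix.n_samples == 0:
        raise ValueError("no samples: refusing to write an empty matrix")
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if format == "eigenstrat":
        paths = {
            "geno": prefix.with_suffix(".geno"),
            "snp": prefix.with_suffix(".snp"),
            "ind": prefix.with_suffix(".ind"),
        }
        _write_eigenstrat(matrix, paths["geno"], paths["snp"], paths["ind"])
        return paths
    if format == "plink_text":
        paths = {
            "traw": prefix.with_suffix(".traw"),
            "fam": prefix.with_suffix(".fam"),
        }
        _write_plink_text(matrix, paths["traw"], paths["fam"])
        return paths
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# metadata TSV
# ---------------------------------------------------------------------------

_META_COLS = ["sample_id", "population", "sex", "date_start", "date_end", "role"]


def write_metadata(matrix: GenotypeMatrix, path) -> None:
    rows = [
        {
            "sample_id": s.sample_id,
            "population": s.population,
            "sex": s.sex,
            "date_start": s.date_range[0],
            "date_end": s.date_range[1],
            "role": s.role,
        }
        for s in matrix.samples
    ]
    pd.DataFrame(rows, columns=_META_COLS).to_csv(path, sep="\t", index=False)


def read_metadata(path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "population": str})
    missing = set(_META_COLS) - set(df.columns)
    if missing:
        raise GenotypeParseError(f"metadata missing columns {sorted(missing)}", path)
    return [
        SampleRecord(
            sample_id=r.sample_id,
            population=r.population,
            sex=r.sex,
            date_range=(int(r.date_start), int(r.date_end)),
            role=r.role,
        )
        for r in df.itertuples()
    ]


def attach_metadata(matrix: GenotypeMatrix, records: Iterable[SampleRecord]) -> GenotypeMatrix:
    """Replace sample records with richer metadata, matched by sample_id."""
    by_id = {r.sample_id: r for r in records}
    missing = [s.sample_id for s in matrix.samples if s.sample_id not in by_id]
    if missing:
        raise KeyError(f"metadata missing for samples: {missing}")
    return dataclasses.replace(
        matrix, samples=[by_id[s.sample_id] for s in matrix.samples]
    )
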