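"""Core domain types for SNP-based baldness prediction.

Genotypes are stored as minor-allele dosages: autosomal calls in {0, 1, 2},
male X-chromosome calls as a single hemizygous allele in {0, 1} (never
expanded to a diploid pair), and -1 for missing.  Phenotypes follow the
four-category design crossing age (<50 / >=50 years) with baldness severity
on the Norwood-Hamilton scale (grades I-II = non-bald, III-VII = bald).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

MISSING = -1

VALID_BASES = frozenset("ACGT")
VALID_CHROMS = frozenset([str(c) for c in range(1, 23)] + ["X"])

MODEL_SCHEMA_VERSION = 1


class GenotypeValidationError(ValueError):
    """Raised when a genotype table cell or column fails validation."""


@dataclass(frozen=True)
class SNPInfo:
    """Metadata for one biallelic SNP on the GRCh37 build."""

    rsid: str
    chrom: str
    pos: int
    major_allele: str
    minor_allele: str
    maf: float
    risk_allele: str | None = None

    def __post_init__(self) -> None:
        if self.chrom not in VALID_CHROMS:
            raise ValueError(f"{self.rsid}: invalid chromosome {self.chrom!r}")
        if self.major_allele not in VALID_BASES or self.minor_allele not in VALID_BASES:
            raise ValueError(f"{self.rsid}: alleles must be A/C/G/T")
        if self.major_allele == self.minor_allele:
            raise ValueError(f"{self.rsid}: major and minor allele identical")
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside [0, 0.5]")
        if self.risk_allele is not None and self.risk_allele not in (
            self.major_allele,
            self.minor_allele,
        ):
            raise ValueError(
                f"{self.rsid}: risk allele {self.risk_allele!r} is neither "
                f"major ({self.major_allele}) nor minor ({self.minor_allele})"
            )

    @property
    def x_linked(self) -> bool:
        return self.chrom == "X"

    def with_risk_allele(self, allele: str) -> "SNPInfo":
        return replace(self, risk_allele=allele)


# Norwood-Hamilton grades; III or higher counts as significant baldness.
GRADES = ("I", "II", "III", "IV", "V", "VI", "VII")
_GRADE_NUM = {g: i + 1 for i, g in enumerate(GRADES)}


def grade_number(grade: str | int) -> int:
    """Convert a Norwood-Hamilton grade (Roman numeral or 1-7) to an integer."""
    if isinstance(grade, (int, np.integer)):
        num = int(grade)
    else:
        try:
            num = _GRADE_NUM[str(grade).strip().upper()]
        except KeyError:
            raise ValueError(f"unknown Norwood-Hamilton grade {grade!r}") from None
    if not 1 <= num <= 7:
        raise ValueError(f"Norwood-Hamilton grade {grade!r} outside I-VII")
    return num


def assign_category(age: int, grade: str | int) -> tuple[int, int]:
    """Map (age, Norwood-Hamilton grade) to a phenotype category and label.

    Category 1: age < 50, grade >= III (early significant baldness) -> bald.
    Category 2: age >= 50, grade <= II (no baldness despite age) -> non-bald.
    Category 3: age < 50, grade <= II -> non-bald.
    Category 4: age >= 50, grade >= III -> bald.

    Returns ``(category, label)`` with label 1 for bald (categories 1 and 4),
    0 for non-bald (categories 2 and 3).
    """
    if age < 18:
        raise ValueError(f"age {age} below adult minimum of 18")
    num = grade_number(grade)
    bald = num >= 3
    old = age >= 50
    if bald:
        category = 4 if old else 1
    else:
        category = 2 if old else 3
    return category, int(bald)


@dataclass(frozen=True)
class SampleRecord:
    """One study subject: identifier, age, baldness grade, population."""

    sample_id: str
    age: int
    grade: str
    population: str = "EUR"
    category: int = field(init=False)
    label: int = field(init=False)

    def __post_init__(self) -> None:
        category, label = assign_category(self.age, self.grade)
        object.__setattr__(self, "category", category)
        object.__setattr__(self, "label", label)


class GenotypeMatrix:
    """Samples x SNPs dosage store with per-SNP metadata.

    ``dosage[i, j]`` is the minor-allele count of sample i at SNP j:
    0/1/2 for autosomal SNPs, 0/1 for male X-linked SNPs (one allele),
    and -1 for a missing call.
    """

    def __init__(
        self,
        samples: list[SampleRecord],
        snps: list[SNPInfo],
        dosage: np.ndarray,
    ) -> None:
        dosage = np.asarray(dosage, dtype=np.int8)
        if dosage.shape != (len(samples), len(snps)):
            raise ValueError(
                f"dosage shape {dosage.shape} does not match "
                f"{len(samples)} samples x {len(snps)} SNPs"
            )
        for j, snp in enumerate(snps):
            col = dosage[:, j]
            hi = 1 if snp.x_linked else 2
            bad = (col != MISSING) & ((col < 0) | (col > hi))
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise GenotypeValidationError(
                    f"sample {samples[i].sample_id}, SNP {snp.rsid}: "
                    f"dosage {col[i]} outside 0..{hi}"
                )
        self.samples = list(samples)
        self.snps = list(snps)
        self.dosage = dosage
        self._index = {s.rsid: j for j, s in enumerate(self.snps)}

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def rsids(self) -> list[str]:
        return [s.rsid for s in self.snps]

    def snp_index(self, rsid: str) -> int:
        try:
            return self._index[rsid]
        except KeyError:
            raise KeyError(f"SNP {rsid!r} not in genotype matrix") from None

    def snp(self, rsid: str) -> SNPInfo:
        return self.snps[self.snp_index(rsid)]

    def column(self, rsid: str) -> np.ndarray:
        return self.dosage[:, self.snp_index(rsid)]

    def labels(self) -> np.ndarray:
        return np.array([s.label for s in self.samples], dtype=np.int8)

    def categories(self) -> np.ndarray:
        return np.array([s.category for s in self.samples], dtype=np.int8)

    def ages(self) -> np.ndarray:
        return np.array([s.age for s in self.samples], dtype=int)

    def completion_rate(self) -> pd.Series:
        """Fraction of non-missing calls per SNP (paper reports >99%)."""
        ok = (self.dosage != MISSING).mean(axis=0)
        return pd.Series(ok, index=self.rsids, name="completion_rate")

    def subset_samples(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.snps, self.dosage[idx, :]
        )

    def subset_categories(self, categories: tuple[int, ...]) -> "GenotypeMatrix":
        cats = self.categories()
        return self.subset_samples(np.isin(cats, categories))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GenotypeMatrix):
            return NotImplemented
        return (
            self.samples == other.samples
            and self.snps == other.snps
            and np.array_equal(self.dosage, other.dosage)
        )


# ---------------------------------------------------------------------------
# Table IO


def _parse_cell(cell: object, snp: SNPInfo, sample_id: str) -> int:
    """Parse one genotype cell (allele string or integer code) to a dosage."""
    if cell is None or (isinstance(cell, float) and np.isnan(cell)):
        return MISSING
    text = str(cell).strip().upper()
    if text in ("", "NA", "NAN", "."):
        return MISSING
    hi = 1 if snp.x_linked else 2
    if text.isdigit() or (text.startswith("-") and text[1:].isdigit()):
        code = int(text)
        if code == MISSING:
            return MISSING
        if not 0 <= code <= hi:
            raise GenotypeValidationError(
                f"sample {sample_id}, SNP {snp.rsid}: coded value {code} "
                f"outside 0..{hi}"
            )
        return code
    expected_len = 1 if snp.x_linked else 2
    if len(text) != expected_len or any(b not in VALID_BASES for b in text):
        raise GenotypeValidationError(
            f"sample {sample_id}, SNP {snp.rsid}: malformed call {text!r}"
        )
    count = 0
    for base in text:
        if base == snp.minor_allele:
            count += 1
        elif base != snp.major_allele:
            raise GenotypeValidationError(
                f"sample {sample_id}, SNP {snp.rsid}: allele {base!r} is "
                f"neither major ({snp.major_allele}) nor minor "
                f"({snp.minor_allele})"
            )
    return count


def read_genotype_table(
    path,
    snp_meta: list[SNPInfo],
    sample_meta: pd.DataFrame | None = None,
    sep: str | None = None,
) -> GenotypeMatrix:
    """Read a delimited genotype table (rows = samples, columns = rsIDs).

    Cells may hold allele-pair strings ("CT"), single alleles for male X
    SNPs ("C"), or pre-coded dosages; the dialect is auto-detected per cell.
    ``sample_meta``, if given, is a DataFrame indexed by sample_id with
    ``age`` and ``grade`` columns (and optionally ``population``); without
    it, placeholder phenotype records are created.

    Raises :class:`GenotypeValidationError` listing any rsID column absent
    from ``snp_meta``, or naming the first offending cell.
    """
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    table = pd.read_csv(path, sep=sep, dtype=str)
    id_col = table.columns[0]
    known = {s.rsid: s for s in snp_meta}
    unknown = [c for c in table.columns[1:] if c not in known]
    if unknown:
        raise GenotypeValidationError(
            f"unknown rsID column(s): {', '.join(unknown)}"
        )
    snps = [known[c] for c in table.columns[1:]]  # preserve column order
    sample_ids = table[id_col].astype(str).tolist()

    dosage = np.full((len(sample_ids), len(snps)), MISSING, dtype=np.int8)
    for j, snp in enumerate(snps):
        col = table.iloc[:, j + 1]
        for i, cell in enumerate(col):
            dosage[i, j] = _parse_cell(cell, snp, sample_ids[i])

    samples = []
    for sid in sample_ids:
        if sample_meta is not None:
            row = sample_meta.loc[sid]
            samples.append(
                SampleRecord(
                    sample_id=sid,
                    age=int(row["age"]),
                    grade=str(row["grade"]),
                    population=str(row.get("population", "EUR")),
                )
            )
        else:
            samples.append(SampleRecord(sample_id=sid, age=18, grade="I"))
    return GenotypeMatrix(samples, snps, dosage)


def write_genotype_table(gm: GenotypeMatrix, path, allele_strings: bool = True) -> None:
    """Write a genotype matrix as TSV; inverse of :func:`read_genotype_table`."""
    data = {}
    for j, snp in enumerate(gm.snps):
        col = gm.dosage[:, j]
        if allele_strings:
            if snp.x_linked:
                lut = {0: snp.major_allele, 1: snp.minor_allele, MISSING: "NA"}
            else:
                lut = {
                    0: snp.major_allele * 2,
                    1: snp.major_allele + snp.minor_allele,
                    2: snp.minor_allele * 2,
                    MISSING: "NA",
                }
            data[snp.rsid] = [lut[int(c)] for c in col]
        else:
            data[snp.rsid] = ["NA" if c == MISSING else str(int(c)) for c in col]
    out = pd.DataFrame(data, index=[s.sample_id for s in gm.samples])
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_snp_meta(path) -> list[SNPInfo]:
    """Read SNP metadata TSV: rsid, chrom, pos, major/minor alleles, maf, risk."""
    table = pd.read_csv(path, sep="\t", dtype=str)
    snps = []
    for _, row in table.iterrows():
        risk = row.get("risk_allele")
        if risk is not None and (pd.isna(risk) or str(risk).strip() in ("", ".")):
            risk = None
        snps.append(
            SNPInfo(
                rsid=row["rsid"],
                chrom=str(row["chrom"]),
                pos=int(row["pos"]),
                major_allele=row["major_allele"],
                minor_allele=row["minor_allele"],
                maf=float(row["maf"]),
                risk_allele=risk,
            )
        )
    return snps


def write_snp_meta(snps: list[SNPInfo], path) -> None:
    pd.DataFrame(
        {
            "rsid": [s.rsid for s in snps],
            "chrom": [s.chrom for s in snps],
            "pos": [s.pos for s in snps],
            "major_allele": [s.major_allele for s in snps],
            "minor_allele": [s.minor_allele for s in snps],
            "maf": [s.maf for s in snps],
            "risk_allele": [s.risk_allele or "" for s in snps],
        }
    ).to_csv(path, sep="\t", index=False)


def read_sample_meta(path) -> pd.DataFrame:
    """Read sample phenotype TSV (sample_id, age, grade[, population])."""
    table = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    table["age"] = table["age"].astype(int)
    return table


def write_sample_meta(samples: list[SampleRecord], path) -> None:
    pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "age": [s.age for s in samples],
            "grade": [s.grade for s in samples],
            "population": [s.population for s in samples],
            "category": [s.category for s in samples],
            "label": [s.label for s in samples],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Prediction-model JSON round-trip


class ModelSchemaError(ValueError):
    """Raised when a model file does not match the expected JSON schema."""


def write_model(model, path) -> None:
    """Serialize a PredictionModel to JSON (schema-versioned)."""
    payload = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "snps": list(model.snps),
        "codings": list(model.codings),
        "intercept": model.intercept,
        "betas": list(model.betas),
        "train_auc": model.train_auc,
        "nagelkerke_r2": model.nagelkerke_r2,
        "overall_p": model.overall_p,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_model(path):
    """Read a PredictionModel from JSON; inverse of :func:`write_model`."""
    from .predictor import PredictionModel  # deferred: avoid import cycle

    with open(path) as fh:
        payload = json.load(fh)
    version = payload.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise ModelSchemaError(
            f"schema_version {version!r} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    required = {"snps", "codings", "intercept", "betas"}
    missing = required - payload.keys()
    if missing:
        raise ModelSchemaError(f"missing field(s): {', '.join(sorted(missing))}")
    if len(payload["snps"]) != len(payload["betas"]):
        raise ModelSchemaError("field 'betas' length does not match 'snps'")
    try:
        return PredictionModel(
            snps=tuple(payload["snps"]),
            codings=tuple(payload["codings"]),
            intercept=float(payload["intercept"]),
            betas=tuple(float(b) for b in payload["betas"]),
            train_auc=payload.get("train_auc"),
            nagelkerke_r2=payload.get("nagelkerke_r2"),
            overall_p=payload.get("overall_p"),
        )
    except (TypeError, ValueError) as exc:
        raise ModelSchemaError(f"corrupted model field: {exc}") from exc
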