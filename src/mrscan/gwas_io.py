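"""Reading, validating and writing GWAS summary-statistic tables.

The on-disk dialect is a tab-separated file with a header row. Default
column names are ``CHR, POS, EA, OA, EAF, BETA, SE, P, N``; any other
header can be mapped onto the canonical fields through a ``column_map``.
Positions are 1-based, chromosome labels are normalized by stripping a
leading ``chr`` prefix, and alleles are uppercased on input.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, EmptyDatasetError

logger = logging.getLogger(__name__)

#: canonical field -> default header name
DEFAULT_COLUMNS = {
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pvalue": "P",
    "n": "N",
}

MANDATORY_FIELDS = ("chrom", "pos", "effect_allele", "other_allele", "beta", "se", "pvalue")

_NUCLEOTIDES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: smallest positive double; p-values printed as 0 are clamped here
MIN_PVALUE = np.nextafter(0.0, 1.0)


def normalize_chrom(label: str) -> str:
    """Strip a leading ``chr`` prefix and surrounding whitespace."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


def chrom_sort_key(chrom: str) -> tuple:
    """Deterministic ordering: numeric chromosomes first, then labels."""
    return (0, int(chrom), "") if chrom.isdigit() else (1, 0, chrom)


@dataclass(frozen=True, order=False)
class VariantKey:
    """Identity of a variant: position plus the two observed alleles.

    ``effect_allele`` is the allele whose dosage the reported beta refers
    to. Indel or multi-nucleotide alleles are permitted but flagged
    non-harmonizable via :meth:`is_snp`.
    """

    chrom: str
    pos: int
    effect_allele: str
    other_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.effect_allele == self.other_allele:
            raise ValueError("effect and other allele must differ")

    @property
    def is_snp(self) -> bool:
        return (
            len(self.effect_allele) == 1
            and len(self.other_allele) == 1
            and self.effect_allele in _NUCLEOTIDES
            and self.other_allele in _NUCLEOTIDES
        )

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G pairs: strand orientation is not decidable from labels."""
        return self.is_snp and _COMPLEMENT[self.effect_allele] == self.other_allele

    @property
    def alleles(self) -> frozenset:
        return frozenset((self.effect_allele, self.other_allele))

    def sort_key(self) -> tuple:
        return (*chrom_sort_key(self.chrom), self.pos)


@dataclass(frozen=True)
class AssociationRecord:
    """One variant's summary association with one trait.

    beta is the per-effect-allele effect: log-odds for a binary trait,
    standardized units for a continuous one. ``eaf`` and ``n`` are
    optional; records missing both are retained but are ineligible for
    eaf-based R^2 and palindrome inference.
    """

    variant: VariantKey
    beta: float
    se: float
    pvalue: float
    eaf: Optional[float] = None
    n: Optional[int] = None
    n_cases: Optional[int] = None
    pvalue_clamped: bool = False

    def __post_init__(self) -> None:
        if not (self.se > 0):
            raise ValueError(f"se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValueError(f"pvalue must be in (0, 1], got {self.pvalue}")
        if self.eaf is not None and not (0 < self.eaf < 1):
            raise ValueError(f"eaf must be in (0, 1), got {self.eaf}")
        if self.n is not None and self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


@dataclass
class SummaryDataset:
    """A trait's full set of association records plus trait metadata.

    Records are keyed by ``(chrom, pos)``; at most one record is kept per
    position (collisions resolve to the lowest p-value at read time).
    """

    trait_name: str
    trait_type: str  # "binary" | "continuous"
    population: str = "European"
    records: dict = field(default_factory=dict)  # (chrom, pos) -> AssociationRecord

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"unknown trait_type {self.trait_type!r}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AssociationRecord]:
        return iter(self.records.values())

    def add(self, rec: AssociationRecord) -> None:
        self.records[(rec.variant.chrom, rec.variant.pos)] = rec

    def get(self, chrom: str, pos: int) -> Optional[AssociationRecord]:
        return self.records.get((chrom, pos))

    def lookup(self, variant: VariantKey) -> Optional[AssociationRecord]:
        return self.get(variant.chrom, variant.pos)

    def sorted_records(self) -> list:
        return sorted(self.records.values(), key=lambda r: r.variant.sort_key())


def _parse_row(row: dict, row_number: int) -> tuple:
    """Return (AssociationRecord | None, rejection_reason | None)."""
    try:
        chrom = normalize_chrom(row["chrom"])
        pos = int(row["pos"])
        ea = str(row["effect_allele"]).strip().upper()
        oa = str(row["other_allele"]).strip().upper()
        beta = float(row["beta"])
        se = float(row["se"])
        pvalue = float(row["pvalue"])
    except (ValueError, TypeError) as exc:
        return None, f"unparseable field: {exc}"

    if not chrom:
        return None, "empty chromosome label"
    if not all(math.isfinite(x) for x in (beta, se, pvalue)):
        return None, "non-finite beta/se/p"

    clamped = False
    if pvalue == 0.0:
        pvalue = MIN_PVALUE
        clamped = True

    eaf = row.get("eaf")
    if eaf is not None:
        try:
            eaf = float(eaf)
        except (ValueError, TypeError):
            return None, "unparseable eaf"
        if math.isnan(eaf):
            eaf = None
    n = row.get("n")
    if n is not None:
        try:
            n_f = float(n)
            n = None if math.isnan(n_f) else int(round(n_f))
        except (ValueError, TypeError):
            return None, "unparseable n"

    try:
        variant = VariantKey(chrom, pos, ea, oa)
        rec = AssociationRecord(
            variant=variant, beta=beta, se=se, pvalue=pvalue,
            eaf=eaf, n=n, pvalue_clamped=clamped,
        )
    except ValueError as exc:
        return None, str(exc)
    return rec, None


def read_summary_table(
    path,
    column_map: Optional[dict] = None,
    trait_name: str = "trait",
    trait_type: str = "binary",
    population: str = "European",
) -> SummaryDataset:
    """Read a tab-separated summary-statistic table into a :class:`SummaryDataset`.

    Parameters
    ----------
    path
        Path to the TSV file (header row required).
    column_map
        Mapping from canonical field names (``chrom``, ``pos``,
        ``effect_allele``, ``other_allele``, ``beta``, ``se``, ``pvalue``,
        optionally ``eaf`` and ``n``) to the file's header names. Defaults
        to the ``CHR/POS/EA/OA/EAF/BETA/SE/P/N`` dialect.

    Every row is either parsed into a record or rejected with a logged
    reason and row number; duplicate keys keep the lowest-p record.

    Raises
    ------
    ConfigurationError
        If a mandatory column is missing from the map or the file.
    EmptyDatasetError
        If no row survives validation.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    missing = [f for f in MANDATORY_FIELDS if f not in cmap]
    if missing:
        raise ConfigurationError(f"column_map missing mandatory fields: {missing}")

    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except OSError:
        raise
    except Exception as exc:  # malformed file
        raise OSError(f"cannot read summary table {path}: {exc}") from exc

    absent = [cmap[f] for f in MANDATORY_FIELDS if cmap[f] not in df.columns]
    if absent:
        raise ConfigurationError(f"{path}: mandatory columns not in file: {absent}")

    has_eaf = cmap.get("eaf") in df.columns
    has_n = cmap.get("n") in df.columns

    ds = SummaryDataset(trait_name=trait_name, trait_type=trait_type, population=population)
    n_rejected = 0
    for i, raw in enumerate(df.itertuples(index=False), start=2):  # line 1 is the header
        raw = dict(zip(df.columns, raw))
        row = {f: raw[cmap[f]] for f in MANDATORY_FIELDS}
        row["eaf"] = raw[cmap["eaf"]] if has_eaf else None
        row["n"] = raw[cmap["n"]] if has_n else None
        rec, reason = _parse_row(row, i)
        if rec is None:
            n_rejected += 1
            logger.warning("%s line %d rejected: %s", path, i, reason)
            continue
        key = (rec.variant.chrom, rec.variant.pos)
        prev = ds.records.get(key)
        if prev is not None:
            keep, drop = (rec, prev) if rec.pvalue < prev.pvalue else (prev, rec)
            logger.warning(
                "%s line %d: duplicate key %s:%d, keeping p=%.3g dropping p=%.3g",
                path, i, key[0], key[1], keep.pvalue, drop.pvalue,
            )
            n_rejected += 1
            ds.records[key] = keep
        else:
            ds.records[key] = rec

    if not ds.records:
        raise EmptyDatasetError(f"{path}: 0 valid rows ({n_rejected} rejected)")
    assert len(df) == len(ds.records) + n_rejected  # every row accounted for
    return ds


def _fmt(x) -> str:
    if x is None:
        return "NA"
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    return repr(float(x))


def write_summary_table(ds: SummaryDataset, path) -> None:
    """Write ``ds`` in the default dialect; floats use ``repr`` so that
    reading the file back reproduces the dataset field-for-field."""
    if len(ds) == 0:
        raise EmptyDatasetError("refusing to write an empty dataset")
    cols = ["CHR", "POS", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for rec in ds.sorted_records():
            v = rec.variant
            fh.write(
                "\t".join(
                    [
                        v.chrom,
                        str(v.pos),
                        v.effect_allele,
                        v.other_allele,
                        _fmt(rec.eaf),
                        _fmt(rec.beta),
                        _fmt(rec.se),
                        _fmt(rec.pvalue),
                        _fmt(rec.n),
                    ]
                )
                + "\n"
            )
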