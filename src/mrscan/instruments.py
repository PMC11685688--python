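"""Instrument selection for a two-sample MR exposure.

Four filters are applied in sequence to the exposure GWAS:

1. genome-wide significance with the exposure (p <= 5e-8 by default);
2. greedy LD clumping: r^2 <= 0.001 and a 100-kb genomic window around
   each retained index SNP;
3. exclusion of SNPs associated with the outcome (p <= 5e-5 removed);
4. a cross-trait pleiotropy screen dropping SNPs that are genome-wide
   significant in five or more other exposure traits.

Instrument strength is summarized by F = R^2 (n - 1 - k) / ((1 - R^2) k)
with R^2 the total variance in the exposure explained by the k retained
instruments; F > 20 is conventionally taken as strong. All p-value
comparisons are inclusive (<=); ties break by genomic coordinate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, List, Optional, Sequence

from .exceptions import ConfigurationError, DomainError
from .gwas_io import AssociationRecord, SummaryDataset, VariantKey

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8
OUTCOME_EXCLUDE_P = 5e-5
DEFAULT_CLUMP_R2 = 0.001
DEFAULT_CLUMP_WINDOW_KB = 100.0
F_STRONG = 20.0

#: LD lookup signature: (VariantKey, VariantKey) -> correlation r
LDLookup = Callable[[VariantKey, VariantKey], float]


def zero_ld(a: VariantKey, b: VariantKey) -> float:
    """Fallback LD lookup: every pair uncorrelated."""
    return 1.0 if a == b else 0.0


def _p_sort_key(rec: AssociationRecord) -> tuple:
    return (rec.pvalue, *rec.variant.sort_key())


def select_by_pvalue(
    ds: SummaryDataset, p_threshold: float = GENOME_WIDE_P
) -> List[AssociationRecord]:
    """Records with p <= threshold, ascending p, coordinate tie-break."""
    hits = [rec for rec in ds if rec.pvalue <= p_threshold]
    hits.sort(key=_p_sort_key)
    return hits


def clump(
    candidates: Sequence[AssociationRecord],
    ld: LDLookup,
    r2_threshold: float = DEFAULT_CLUMP_R2,
    window_kb: float = DEFAULT_CLUMP_WINDOW_KB,
) -> List[AssociationRecord]:
    """Greedy LD clumping of p-sorted candidates.

    Repeatedly takes the lowest-p remaining SNP as an index and removes
    every remaining SNP that is on the same chromosome within
    ``window_kb`` kilobases of it, or whose squared correlation with it
    exceeds ``r2_threshold``. Returns index SNPs in selection order.
    """
    if r2_threshold < 0 or window_kb < 0:
        raise ConfigurationError("r2_threshold and window_kb must be non-negative")
    window_bp = window_kb * 1000.0
    remaining = sorted(candidates, key=_p_sort_key)
    retained: List[AssociationRecord] = []
    while remaining:
        index = remaining.pop(0)
        retained.append(index)
        iv = index.variant

        def removed(rec: AssociationRecord) -> bool:
            v = rec.variant
            if v.chrom == iv.chrom and abs(v.pos - iv.pos) <= window_bp:
                return True
            return ld(iv, v) ** 2 > r2_threshold

        remaining = [rec for rec in remaining if not removed(rec)]
    return retained


def exclude_outcome_associated(
    snps: Iterable[AssociationRecord],
    outcome_ds: SummaryDataset,
    p_exclude: float = OUTCOME_EXCLUDE_P,
) -> List[AssociationRecord]:
    """Drop instruments associated with the outcome (outcome p <= p_exclude).

    Instruments absent from the outcome dataset are retained here (they
    are dropped later, at harmonization) and logged.
    """
    kept = []
    for rec in snps:
        out = outcome_ds.lookup(rec.variant)
        if out is None:
            logger.info(
                "instrument %s:%d absent from outcome %s; deferred to harmonization",
                rec.variant.chrom, rec.variant.pos, outcome_ds.trait_name,
            )
            kept.append(rec)
        elif out.pvalue <= p_exclude:
            logger.info(
                "instrument %s:%d dropped: outcome p=%.3g <= %.3g",
                rec.variant.chrom, rec.variant.pos, out.pvalue, p_exclude,
            )
        else:
            kept.append(rec)
    return kept


def cross_trait_pleiotropy_filter(
    snps: Iterable[AssociationRecord],
    other_exposures: Sequence[SummaryDataset],
    max_traits: int = 5,
    p_significant: float = GENOME_WIDE_P,
) -> List[AssociationRecord]:
    """Drop SNPs genome-wide significant in >= ``max_traits`` other exposures.

    With no other exposures supplied the filter is the identity.
    """
    if not other_exposures:
        return list(snps)
    kept = []
    for rec in snps:
        n_sig = 0
        for other in other_exposures:
            hit = other.lookup(rec.variant)
            if hit is not None and hit.pvalue <= p_significant:
                n_sig += 1
        if n_sig >= max_traits:
            logger.info(
                "instrument %s:%d dropped: significant in %d other exposure traits",
                rec.variant.chrom, rec.variant.pos, n_sig,
            )
        else:
            kept.append(rec)
    return kept


def snp_r2(rec: AssociationRecord) -> float:
    """Variance in the exposure explained by one SNP.

    Uses the standardized-trait approximation r2 = 2 eaf (1-eaf) beta^2
    when the effect-allele frequency is available, otherwise the
    z-statistic fallback r2 = z^2 / (z^2 + n - 2).
    """
    if rec.eaf is not None:
        r2 = 2.0 * rec.eaf * (1.0 - rec.eaf) * rec.beta ** 2
    else:
        if rec.n is None or rec.n < 3:
            raise DomainError(
                "r2 undefined: eaf missing and n is missing or < 3"
            )
        z = rec.beta / rec.se
        r2 = z * z / (z * z + rec.n - 2)
    return min(r2, 1.0 - 1e-15)


def f_statistic(r2_total: float, n: int, k: int) -> float:
    """Instrument-strength F = R^2 (n - 1 - k) / ((1 - R^2) k)."""
    if not (0.0 <= r2_total < 1.0):
        raise DomainError(f"r2_total must be in [0, 1), got {r2_total}")
    if k < 1:
        raise DomainError(f"k must be >= 1, got {k}")
    if n <= k + 1:
        raise DomainError(f"need n > k + 1, got n={n}, k={k}")
    return r2_total * (n - 1 - k) / ((1.0 - r2_total) * k)


@dataclass
class InstrumentSet:
    """Final instruments for one exposure with strength diagnostics."""

    exposure_trait: str
    snps: List[AssociationRecord]
    provenance: dict = field(default_factory=dict)  # stage -> count or notes
    r2_total: float = 0.0
    f_stat: float = float("nan")
    n_used: Optional[int] = None

    @property
    def k(self) -> int:
        return len(self.snps)

    @property
    def is_strong(self) -> bool:
        return self.f_stat > F_STRONG


def assemble_instrument_set(
    exposure_trait: str,
    snps: Sequence[AssociationRecord],
    provenance: Optional[dict] = None,
) -> InstrumentSet:
    """Sum per-SNP R^2 and compute F for a final instrument list.

    The sample size entering F is the largest per-record n (GWAS tables
    occasionally vary n by SNP). SNPs with neither eaf nor usable n
    contribute zero R^2 and are noted in the provenance.
    """
    iset = InstrumentSet(exposure_trait, list(snps), provenance=dict(provenance or {}))
    if not snps:
        return iset
    r2 = 0.0
    skipped = 0
    for rec in snps:
        try:
            r2 += snp_r2(rec)
        except DomainError:
            skipped += 1
    r2 = min(r2, 1.0 - 1e-12)
    iset.r2_total = r2
    if skipped:
        iset.provenance["r2_ineligible_snps"] = skipped
    ns = [rec.n for rec in snps if rec.n is not None]
    if ns:
        n = max(ns)
        iset.n_used = n
        if n > iset.k + 1:
            iset.f_stat = f_statistic(r2, n, iset.k)
    return iset
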