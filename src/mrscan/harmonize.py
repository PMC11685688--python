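"""Align exposure and outcome records to a common effect allele.

Standard two-sample MR harmonization: outcome records reported on the
swapped allele pair have their beta sign-flipped; records reported on
the opposite strand are complemented (A<->T, C<->G); palindromic SNPs
(A/T or C/G pairs), where strand cannot be decided from allele labels,
are resolved by effect-allele frequency when both studies report an eaf
clearly away from 0.5 — otherwise dropped as ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Optional

from .exceptions import HarmonizationError
from .gwas_io import AssociationRecord, SummaryDataset, VariantKey, _COMPLEMENT

#: harmonization outcomes
KEPT_AS_IS = "kept_as_is"
SIGN_FLIPPED = "sign_flipped"
STRAND_FLIPPED = "strand_flipped"
DROPPED = "dropped"

DEFAULT_PALINDROME_EAF_WINDOW = 0.08


@dataclass(frozen=True)
class HarmonizedPair:
    """An exposure/outcome record pair expressed on the exposure's effect allele."""

    variant: VariantKey  # exposure orientation
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str
    drop_reason: Optional[str] = None
    eaf_exp: Optional[float] = None
    eaf_out: Optional[float] = None

    @property
    def kept(self) -> bool:
        return self.action != DROPPED


def _complement_allele(a: str) -> Optional[str]:
    if len(a) == 1 and a in _COMPLEMENT:
        return _COMPLEMENT[a]
    return None


def _dropped(exp_rec: AssociationRecord, out_rec: AssociationRecord, reason: str) -> HarmonizedPair:
    return HarmonizedPair(
        variant=exp_rec.variant,
        beta_exp=exp_rec.beta, se_exp=exp_rec.se,
        beta_out=out_rec.beta, se_out=out_rec.se,
        action=DROPPED, drop_reason=reason,
        eaf_exp=exp_rec.eaf, eaf_out=out_rec.eaf,
    )


def harmonize_pair(
    exp_rec: AssociationRecord,
    out_rec: AssociationRecord,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
    drop_palindromic: bool = False,
) -> HarmonizedPair:
    """Harmonize one exposure/outcome record pair to the exposure allele frame.

    ``palindrome_eaf_window`` is the half-width of the ambiguity band
    around eaf = 0.5 inside which a palindromic SNP's strand cannot be
    inferred from frequency (default band 0.42-0.58).
    ``drop_palindromic=True`` drops every palindromic SNP outright.
    """
    ev, ov = exp_rec.variant, out_rec.variant
    if (ev.chrom, ev.pos) != (ov.chrom, ov.pos):
        raise HarmonizationError(
            f"records at different positions: {ev.chrom}:{ev.pos} vs {ov.chrom}:{ov.pos}"
        )
    if not ev.is_snp or not ov.is_snp:
        return _dropped(exp_rec, out_rec, "non_snp")

    if ev.is_palindromic:
        if ov.alleles != ev.alleles:
            return _dropped(exp_rec, out_rec, "allele_mismatch")
        if drop_palindromic:
            return _dropped(exp_rec, out_rec, "palindromic_ambiguous")
        return _harmonize_palindrome(exp_rec, out_rec, palindrome_eaf_window)

    # label alignment: direct / swapped / strand-complement of either
    if (ov.effect_allele, ov.other_allele) == (ev.effect_allele, ev.other_allele):
        action, flip = KEPT_AS_IS, False
    elif (ov.effect_allele, ov.other_allele) == (ev.other_allele, ev.effect_allele):
        action, flip = SIGN_FLIPPED, True
    else:
        cea, coa = _complement_allele(ov.effect_allele), _complement_allele(ov.other_allele)
        if (cea, coa) == (ev.effect_allele, ev.other_allele):
            action, flip = STRAND_FLIPPED, False
        elif (cea, coa) == (ev.other_allele, ev.effect_allele):
            action, flip = STRAND_FLIPPED, True
        else:
            return _dropped(exp_rec, out_rec, "allele_mismatch")

    beta_out = -out_rec.beta if flip else out_rec.beta
    eaf_out = None if out_rec.eaf is None else (1.0 - out_rec.eaf if flip else out_rec.eaf)
    return HarmonizedPair(
        variant=ev,
        beta_exp=exp_rec.beta, se_exp=exp_rec.se,
        beta_out=beta_out, se_out=out_rec.se,
        action=action, eaf_exp=exp_rec.eaf, eaf_out=eaf_out,
    )


def _harmonize_palindrome(
    exp_rec: AssociationRecord, out_rec: AssociationRecord, window: float
) -> HarmonizedPair:
    """Resolve an A/T or C/G pair by allele frequency.

    Both studies must report an eaf outside [0.5 - window, 0.5 + window].
    After aligning allele labels (swap flips sign and frequency), a
    concordant frequency confirms the same strand; a discordant one
    means the outcome is on the opposite strand, which for a palindrome
    is equivalent to one more label swap, i.e. another sign flip.
    """
    ev, ov = exp_rec.variant, out_rec.variant
    if exp_rec.eaf is None or out_rec.eaf is None:
        return _dropped(exp_rec, out_rec, "palindromic_ambiguous")

    if ov.effect_allele == ev.effect_allele:
        beta_out, eaf_out, swapped = out_rec.beta, out_rec.eaf, False
    else:  # labels swapped
        beta_out, eaf_out, swapped = -out_rec.beta, 1.0 - out_rec.eaf, True

    lo, hi = 0.5 - window, 0.5 + window
    for eaf in (exp_rec.eaf, eaf_out):
        if lo <= eaf <= hi:
            return _dropped(exp_rec, out_rec, "palindromic_ambiguous")

    concordant = (exp_rec.eaf < 0.5) == (eaf_out < 0.5)
    if concordant:
        action = SIGN_FLIPPED if swapped else KEPT_AS_IS
    else:  # opposite strand: complement == swap for a palindrome
        action = STRAND_FLIPPED
        beta_out, eaf_out = -beta_out, 1.0 - eaf_out
    return HarmonizedPair(
        variant=ev,
        beta_exp=exp_rec.beta, se_exp=exp_rec.se,
        beta_out=beta_out, se_out=out_rec.se,
        action=action, eaf_exp=exp_rec.eaf, eaf_out=eaf_out,
    )


def harmonize_set(
    instruments: Iterable[AssociationRecord],
    outcome_ds: SummaryDataset,
    palindrome_eaf_window: float = DEFAULT_PALINDROME_EAF_WINDOW,
    drop_palindromic: bool = False,
) -> List[HarmonizedPair]:
    """Harmonize each instrument against the outcome dataset.

    Instruments absent from the outcome are emitted as dropped pairs
    with reason ``missing_in_outcome``, so that every input instrument
    appears exactly once in the result (count conservation).
    """
    pairs: List[HarmonizedPair] = []
    for rec in instruments:
        out = outcome_ds.lookup(rec.variant)
        if out is None:
            pairs.append(
                HarmonizedPair(
                    variant=rec.variant,
                    beta_exp=rec.beta, se_exp=rec.se,
                    beta_out=float("nan"), se_out=float("nan"),
                    action=DROPPED, drop_reason="missing_in_outcome",
                    eaf_exp=rec.eaf,
                )
            )
        else:
            pairs.append(
                harmonize_pair(rec, out, palindrome_eaf_window, drop_palindromic)
            )
    return pairs


def kept_pairs(pairs: Iterable[HarmonizedPair]) -> List[HarmonizedPair]:
    return [p for p in pairs if p.kept]


def write_audit(pairs: Iterable[HarmonizedPair], path) -> None:
    """Write the harmonization audit TSV: variant, action, drop_reason."""
    with open(path, "w") as fh:
        fh.write("CHR\tPOS\tEA\tOA\taction\tdrop_reason\n")
        for p in pairs:
            v = p.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.effect_allele}\t{v.other_allele}\t"
                f"{p.action}\t{p.drop_reason or ''}\n"
            )
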