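"""Synthetic two-sample GWAS summary statistics with known causal truth.

The generator works directly at the summary level: for each locus one
index SNP carries a true exposure effect gamma ~ N(0, gamma_sd^2) (for
the causal fraction of loci), neighbouring SNPs inherit the attenuated
marginal effect rho * gamma under an exchangeable within-locus LD model,
the true outcome effect is Gamma = causal_beta * gamma + alpha with an
optional pleiotropic direct effect alpha, and observed betas are drawn
as Normal(truth, se^2) with the standard standardized-trait GWAS
standard error se = 1 / sqrt(2 n maf (1 - maf)). Binary outcomes are
approximated on the log-odds scale with the same machinery.

This is sufficient for two-sample MR (which only ever sees summary
statistics) and orders of magnitude faster than individual-level
genotype simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy import stats

from .exceptions import ConfigurationError
from .gwas_io import (
    AssociationRecord,
    SummaryDataset,
    VariantKey,
    write_summary_table,
    MIN_PVALUE,
)

# non-palindromic allele pairs: harmonization can always resolve these
_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]
_PALINDROMIC_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

_LOCUS_SPACING_BP = 10_000_000  # loci far apart: never inside one clump window
_SNP_SPACING_BP = 1_000         # within-locus SNPs inside the 100-kb window


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one simulated two-sample study.

    Defaults correspond to a well-powered no-pleiotropy design: 50
    single-SNP loci, both GWAS at n = 100 000, true causal effect 0.2 on
    the log-odds scale, per-SNP exposure effects with SD 0.05.
    """

    n_loci: int = 50
    snps_per_locus: int = 1
    ld_rho: float = 0.0
    maf_range: tuple = (0.05, 0.5)
    n_exposure: int = 100_000
    n_outcome: int = 100_000
    causal_beta: float = 0.2
    prop_causal_snps: float = 1.0
    gamma_sd: float = 0.05
    pleiotropy_prop: float = 0.0
    pleiotropy_sd: float = 0.0
    seed: int = 0
    palindromic: bool = False  # emit A/T-C/G allele pairs (harmonization stress)

    def validate(self) -> None:
        if self.n_loci < 1 or self.snps_per_locus < 1:
            raise ConfigurationError("n_loci and snps_per_locus must be >= 1")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigurationError("ld_rho must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must satisfy 0 < low <= high <= 0.5")
        if self.n_exposure < 100 or self.n_outcome < 100:
            raise ConfigurationError("sample sizes must be >= 100")
        for name in ("prop_causal_snps", "pleiotropy_prop"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.prop_causal_snps > 0 and self.gamma_sd <= 0:
            raise ConfigurationError("gamma_sd must be > 0 when prop_causal_snps > 0")
        if self.pleiotropy_sd < 0:
            raise ConfigurationError("pleiotropy_sd must be >= 0")


@dataclass
class SimulatedStudy:
    """Paired exposure/outcome summary datasets plus the generating truth."""

    config: SimulationConfig
    exposure: SummaryDataset
    outcome: SummaryDataset
    ld: list = field(default_factory=list)  # per-locus correlation matrices
    variants: list = field(default_factory=list)     # VariantKey, generation order
    gamma_true: dict = field(default_factory=dict)   # variant -> marginal exposure effect
    alpha_true: dict = field(default_factory=dict)   # variant -> direct outcome effect
    locus_of: dict = field(default_factory=dict)     # variant -> locus index

    @property
    def causal_beta(self) -> float:
        return self.config.causal_beta

    def ld_lookup(self, a: VariantKey, b: VariantKey):
        """Pairwise correlation r under the exchangeable model; 0 across loci."""
        if a == b:
            return 1.0
        la, lb = self.locus_of.get(a), self.locus_of.get(b)
        if la is None or lb is None or la != lb:
            return 0.0
        return self.config.ld_rho


def ld_matrix_for_locus(study: SimulatedStudy, locus_index: int) -> np.ndarray:
    """Exchangeable correlation matrix of one locus (unit diagonal, off-diagonal rho)."""
    if not (0 <= locus_index < len(study.ld)):
        raise IndexError(f"locus index {locus_index} out of range [0, {len(study.ld)})")
    return study.ld[locus_index]


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta) / se)
    return np.clip(p, MIN_PVALUE, 1.0)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate one paired exposure/outcome study.

    Pure function of ``config``: the same seed yields bit-identical
    output. One RNG substream per locus (plus one for study-level
    assignments) is derived deterministically from ``config.seed``.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(config.n_loci + 1)
    rng_global = np.random.default_rng(children[0])

    causal_locus = rng_global.random(config.n_loci) < config.prop_causal_snps
    pleiotropic_locus = rng_global.random(config.n_loci) < config.pleiotropy_prop

    exposure = SummaryDataset("synthetic_exposure", "continuous", "synthetic")
    outcome = SummaryDataset("synthetic_outcome", "binary", "synthetic")
    study = SimulatedStudy(config=config, exposure=exposure, outcome=outcome)

    m = config.snps_per_locus
    pairs = _PALINDROMIC_PAIRS if config.palindromic else _ALLELE_PAIRS
    for locus in range(config.n_loci):
        rng = np.random.default_rng(children[locus + 1])
        chrom = str(locus % 22 + 1)
        base = _LOCUS_SPACING_BP * (locus // 22 + 1)

        gamma_index = rng.normal(0.0, config.gamma_sd) if causal_locus[locus] else 0.0
        alpha_index = (
            rng.normal(0.0, config.pleiotropy_sd)
            if pleiotropic_locus[locus] and config.pleiotropy_sd > 0
            else 0.0
        )
        # marginal (LD-leaked) effects: r=1 for the index SNP, rho otherwise
        r_to_index = np.full(m, config.ld_rho)
        r_to_index[0] = 1.0
        gamma = r_to_index * gamma_index
        alpha = r_to_index * alpha_index
        big_gamma = config.causal_beta * gamma + alpha

        maf = rng.uniform(*config.maf_range, size=m)
        se_exp = 1.0 / np.sqrt(2.0 * config.n_exposure * maf * (1.0 - maf))
        se_out = 1.0 / np.sqrt(2.0 * config.n_outcome * maf * (1.0 - maf))
        beta_exp = rng.normal(gamma, se_exp)
        beta_out = rng.normal(big_gamma, se_out)
        p_exp = _two_sided_p(beta_exp, se_exp)
        p_out = _two_sided_p(beta_out, se_out)
        allele_idx = rng.integers(0, len(pairs), size=m)

        for j in range(m):
            ea, oa = pairs[allele_idx[j]]
            v = VariantKey(chrom, base + j * _SNP_SPACING_BP, ea, oa)
            exposure.add(
                AssociationRecord(v, float(beta_exp[j]), float(se_exp[j]),
                                  float(p_exp[j]), eaf=float(maf[j]), n=config.n_exposure)
            )
            outcome.add(
                AssociationRecord(v, float(beta_out[j]), float(se_out[j]),
                                  float(p_out[j]), eaf=float(maf[j]), n=config.n_outcome)
            )
            study.variants.append(v)
            study.gamma_true[v] = float(gamma[j])
            study.alpha_true[v] = float(alpha[j])
            study.locus_of[v] = locus

        mat = np.full((m, m), config.ld_rho)
        np.fill_diagonal(mat, 1.0)
        study.ld.append(mat)

    return study


def write_study(study: SimulatedStudy, outdir) -> dict:
    """Write a study to disk in the gwas_io dialect.

    Emits ``exposure.tsv`` and ``outcome.tsv``, a ``truth.tsv`` with the
    generating per-SNP effects, per-locus LD matrices as plain-text
    square matrices under ``ld/``, and a pairwise ``ld_pairs.tsv``
    (variant_a, variant_b, r2) consumable by the scan pipeline.
    Returns the paths written.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposure": outdir / "exposure.tsv",
        "outcome": outdir / "outcome.tsv",
        "truth": outdir / "truth.tsv",
        "ld_pairs": outdir / "ld_pairs.tsv",
        "ld_dir": outdir / "ld",
    }
    write_summary_table(study.exposure, paths["exposure"])
    write_summary_table(study.outcome, paths["outcome"])

    with open(paths["truth"], "w") as fh:
        fh.write("CHR\tPOS\tEA\tOA\tgamma_true\talpha_true\tcausal_beta\n")
        for v in study.variants:
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.effect_allele}\t{v.other_allele}\t"
                f"{study.gamma_true[v]!r}\t{study.alpha_true[v]!r}\t"
                f"{study.config.causal_beta!r}\n"
            )

    paths["ld_dir"].mkdir(exist_ok=True)
    for i, mat in enumerate(study.ld):
        np.savetxt(paths["ld_dir"] / f"locus_{i:04d}.txt", mat, fmt="%.10g")

    with open(paths["ld_pairs"], "w") as fh:
        fh.write("variant_a\tvariant_b\tr2\n")
        rho2 = study.config.ld_rho ** 2
        if rho2 > 0:
            by_locus: dict = {}
            for v in study.variants:
                by_locus.setdefault(study.locus_of[v], []).append(v)
            for members in by_locus.values():
                for i in range(len(members)):
                    for j in range(i + 1, len(members)):
                        a, b = members[i], members[j]
                        fh.write(
                            f"{a.chrom}:{a.pos}\t{b.chrom}:{b.pos}\t{rho2!r}\n"
                        )
    return paths
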