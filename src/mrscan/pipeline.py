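"""Exposure x outcome scan orchestration.

A run manifest (YAML) lists exposure and outcome summary-stat tables,
an LD source, and the analysis thresholds. For every exposure-outcome
pair the scan executes: genome-wide p-value selection -> LD clumping ->
outcome-association exclusion -> cross-trait pleiotropy screen ->
harmonization -> k-based model selection -> estimation -> OR/CI
reporting. Pairs with zero surviving instruments yield a flagged row
instead of an error, so a full scan always produces one row per pair.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import pandas as pd
import yaml

from .exceptions import ConfigurationError, MRScanError
from .gwas_io import SummaryDataset, VariantKey, read_summary_table
from .harmonize import harmonize_set, kept_pairs, write_audit
from .instruments import (
    LDLookup,
    assemble_instrument_set,
    clump,
    cross_trait_pleiotropy_filter,
    exclude_outcome_associated,
    select_by_pvalue,
    zero_ld,
)
from .estimators import MREstimate, estimate

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Thresholds:
    """Tuning constants of the scan (defaults are the standard analysis values)."""

    p_exposure: float = 5e-8
    p_outcome_exclude: float = 5e-5
    clump_r2: float = 0.001
    clump_window_kb: float = 100.0
    f_flag: float = 20.0
    alpha: float = 0.05
    pleiotropy_max_traits: int = 5
    random_min_k: int = 3

    def validate(self) -> None:
        for name in ("p_exposure", "p_outcome_exclude", "clump_r2",
                     "clump_window_kb", "f_flag", "alpha"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"threshold {name} must be positive")


@dataclass
class DatasetSpec:
    trait_name: str
    path: str
    column_map: Optional[dict] = None
    trait_type: str = "binary"


@dataclass
class RunManifest:
    """Everything needed to run one scan."""

    exposures: List[DatasetSpec]
    outcomes: List[DatasetSpec]
    ld_source: str = "none"  # path to pairwise r2 TSV | "synthetic" | "none"
    thresholds: Thresholds = field(default_factory=Thresholds)
    seed: int = 0
    output_dir: str = "results"

    def validate(self) -> None:
        if not self.exposures or not self.outcomes:
            raise ConfigurationError("manifest needs >= 1 exposure and >= 1 outcome")
        self.thresholds.validate()

    @classmethod
    def from_yaml(cls, path) -> "RunManifest":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            exposures = [DatasetSpec(**e) for e in raw["exposures"]]
            outcomes = [DatasetSpec(**o) for o in raw["outcomes"]]
        except (KeyError, TypeError) as exc:
            raise ConfigurationError(f"bad manifest {path}: {exc}") from exc
        thresholds = Thresholds(**raw.get("thresholds", {}))
        manifest = cls(
            exposures=exposures,
            outcomes=outcomes,
            ld_source=str(raw.get("ld_source", "none")),
            thresholds=thresholds,
            seed=int(raw.get("seed", 0)),
            output_dir=str(raw.get("output_dir", "results")),
        )
        manifest.validate()
        return manifest


class PairwiseLD:
    """LD lookup backed by a pairwise r2 table (variant_a, variant_b, r2).

    Absent pairs default to r = 0 (logged once).
    """

    def __init__(self, r2: Dict[frozenset, float]):
        self._r2 = r2
        self._warned = False

    @classmethod
    def from_tsv(cls, path) -> "PairwiseLD":
        df = pd.read_csv(path, sep="\t", dtype={"variant_a": str, "variant_b": str})
        table: Dict[frozenset, float] = {}
        for a, b, r2 in zip(df["variant_a"], df["variant_b"], df["r2"]):
            table[frozenset((a, b))] = float(r2)
        return cls(table)

    def __call__(self, a: VariantKey, b: VariantKey) -> float:
        if a == b:
            return 1.0
        key = frozenset((f"{a.chrom}:{a.pos}", f"{b.chrom}:{b.pos}"))
        r2 = self._r2.get(key)
        if r2 is None:
            if not self._warned:
                logger.warning("LD pair absent from table; defaulting r2 = 0")
                self._warned = True
            return 0.0
        return float(r2) ** 0.5


def _resolve_ld(ld_source: str, exposure_path: Optional[str]) -> LDLookup:
    if ld_source == "none":
        logger.warning("no LD source configured; all pairs treated as uncorrelated")
        return zero_ld
    if ld_source == "synthetic":
        # simulator convention: ld_pairs.tsv next to the exposure table
        if exposure_path is None:
            return zero_ld
        candidate = Path(exposure_path).parent / "ld_pairs.tsv"
        if candidate.exists():
            return PairwiseLD.from_tsv(candidate)
        logger.warning("%s not found; defaulting to zero LD", candidate)
        return zero_ld
    return PairwiseLD.from_tsv(ld_source)


@dataclass
class ScanResultRow:
    """One exposure-outcome cell of the scan grid."""

    exposure: str
    outcome: str
    estimate: Optional[MREstimate]
    f_stat: float
    n_candidates: int
    n_clumped: int
    n_after_outcome_filter: int
    n_harmonized: int
    status: str = "ok"  # ok | no_instruments | failed:<reason>
    qvalue: Optional[float] = None


def analyze_pair(
    exposure_ds: SummaryDataset,
    outcome_ds: SummaryDataset,
    ld: LDLookup = zero_ld,
    thresholds: Thresholds = Thresholds(),
    other_exposures: Sequence[SummaryDataset] = (),
    audit_path=None,
) -> ScanResultRow:
    """Run the full instrument-selection -> harmonization -> estimation
    funnel for one exposure/outcome pair, entirely in memory."""
    th = thresholds
    candidates = select_by_pvalue(exposure_ds, th.p_exposure)
    clumped = clump(candidates, ld, th.clump_r2, th.clump_window_kb)
    filtered = exclude_outcome_associated(clumped, outcome_ds, th.p_outcome_exclude)
    filtered = cross_trait_pleiotropy_filter(
        filtered, other_exposures, th.pleiotropy_max_traits
    )
    pairs = harmonize_set(filtered, outcome_ds)
    if audit_path is not None:
        write_audit(pairs, audit_path)
    kept = kept_pairs(pairs)

    row = ScanResultRow(
        exposure=exposure_ds.trait_name,
        outcome=outcome_ds.trait_name,
        estimate=None,
        f_stat=float("nan"),
        n_candidates=len(candidates),
        n_clumped=len(clumped),
        n_after_outcome_filter=len(filtered),
        n_harmonized=len(kept),
    )
    if not kept:
        row.status = "no_instruments"
        return row

    kept_variants = {p.variant for p in kept}
    exp_records = [rec for rec in filtered if rec.variant in kept_variants]
    iset = assemble_instrument_set(exposure_ds.trait_name, exp_records)
    row.f_stat = iset.f_stat
    row.estimate = estimate(kept, alpha=th.alpha, random_min_k=th.random_min_k)
    return row


def run_scan(manifest: RunManifest) -> List[ScanResultRow]:
    """Execute the manifest's full exposure x outcome grid.

    Unreadable datasets fail their pairs (flagged rows) without aborting
    the scan; a per-pair harmonization audit is written under
    ``output_dir/audit/``. The run is deterministic given the manifest.
    """
    manifest.validate()
    outdir = Path(manifest.output_dir)
    audit_dir = outdir / "audit"
    audit_dir.mkdir(parents=True, exist_ok=True)

    exposures: Dict[int, SummaryDataset] = {}
    exposure_errors: Dict[int, str] = {}
    for i, spec in enumerate(manifest.exposures):
        try:
            exposures[i] = read_summary_table(
                spec.path, spec.column_map, spec.trait_name, spec.trait_type
            )
        except (OSError, MRScanError) as exc:
            exposure_errors[i] = str(exc)
            logger.error("exposure %s unreadable: %s", spec.trait_name, exc)

    outcomes: Dict[int, SummaryDataset] = {}
    outcome_errors: Dict[int, str] = {}
    for j, spec in enumerate(manifest.outcomes):
        try:
            outcomes[j] = read_summary_table(
                spec.path, spec.column_map, spec.trait_name, spec.trait_type
            )
        except (OSError, MRScanError) as exc:
            outcome_errors[j] = str(exc)
            logger.error("outcome %s unreadable: %s", spec.trait_name, exc)

    rows: List[ScanResultRow] = []
    for i, espec in enumerate(manifest.exposures):
        ld = _resolve_ld(manifest.ld_source, espec.path) if i in exposures else zero_ld
        others = [ds for k, ds in exposures.items() if k != i]
        for j, ospec in enumerate(manifest.outcomes):
            if i in exposure_errors or j in outcome_errors:
                reason = exposure_errors.get(i) or outcome_errors.get(j)
                rows.append(
                    ScanResultRow(
                        exposure=espec.trait_name, outcome=ospec.trait_name,
                        estimate=None, f_stat=float("nan"),
                        n_candidates=0, n_clumped=0,
                        n_after_outcome_filter=0, n_harmonized=0,
                        status=f"failed:{reason}",
                    )
                )
                continue
            audit_path = audit_dir / f"{espec.trait_name}__{ospec.trait_name}.tsv"
            row = analyze_pair(
                exposures[i], outcomes[j], ld, manifest.thresholds,
                other_exposures=others, audit_path=audit_path,
            )
            rows.append(row)
            _write_pair_log(audit_dir / "scan_log.jsonl", row)
    return rows


def _write_pair_log(path, row: ScanResultRow) -> None:
    entry = {
        "exposure": row.exposure,
        "outcome": row.outcome,
        "status": row.status,
        "n_candidates": row.n_candidates,
        "n_clumped": row.n_clumped,
        "n_after_outcome_filter": row.n_after_outcome_filter,
        "n_harmonized": row.n_harmonized,
    }
    if row.estimate is not None:
        entry.update(method=row.estimate.method, beta=row.estimate.beta,
                     se=row.estimate.se, pvalue=row.estimate.pvalue)
    with open(path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")


def adjust_multiplicity(
    rows: Sequence[ScanResultRow], method: str = "none"
) -> List[ScanResultRow]:
    """Attach q-values across the scan's estimated rows.

    ``none`` copies each p-value; ``benjamini_hochberg`` applies the
    standard step-up FDR procedure.
    """
    if method not in ("none", "benjamini_hochberg"):
        raise ConfigurationError(f"unknown multiplicity method {method!r}")
    estimated = [r for r in rows if r.estimate is not None]
    if method == "none":
        for r in estimated:
            r.qvalue = r.estimate.pvalue
    elif estimated:
        from statsmodels.stats.multitest import multipletests

        pvals = [r.estimate.pvalue for r in estimated]
        _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
        for r, q in zip(estimated, qvals):
            r.qvalue = float(q)
    return list(rows)


_RESULT_COLUMNS = [
    "exposure", "outcome", "status", "k", "method", "beta", "se",
    "OR", "CI_low", "CI_high", "pvalue", "Q", "Q_df", "Q_pvalue",
    "F", "significant",
]


def results_frame(rows: Sequence[ScanResultRow], alpha: float = 0.05) -> pd.DataFrame:
    """Scan rows as a tidy DataFrame (one line per exposure-outcome pair)."""
    out = []
    for r in rows:
        e = r.estimate
        out.append({
            "exposure": r.exposure,
            "outcome": r.outcome,
            "status": r.status,
            "k": e.k if e else 0,
            "method": e.method if e else "",
            "beta": e.beta if e else float("nan"),
            "se": e.se if e else float("nan"),
            "OR": e.or_ if e else float("nan"),
            "CI_low": e.ci_low if e else float("nan"),
            "CI_high": e.ci_high if e else float("nan"),
            "pvalue": e.pvalue if e else float("nan"),
            "Q": e.q_stat if e and e.q_stat is not None else float("nan"),
            "Q_df": e.q_df if e and e.q_df is not None else 0,
            "Q_pvalue": e.q_pvalue if e and e.q_pvalue is not None else float("nan"),
            "F": r.f_stat,
            "significant": bool(e and e.pvalue < alpha),
        })
    return pd.DataFrame(out, columns=_RESULT_COLUMNS)


def write_results_tsv(rows: Sequence[ScanResultRow], path, alpha: float = 0.05) -> None:
    results_frame(rows, alpha).to_csv(path, sep="\t", index=False, float_format="%.6g")


def export_forest_data(
    rows: Sequence[ScanResultRow],
    path,
    significant_only: bool = False,
    alpha: float = 0.05,
) -> int:
    """Write forest-plot-ready data: one TSV line per estimated pair with
    OR, CI bounds, p, method and k. Returns the number of data lines."""
    rows = [r for r in rows if r.estimate is not None]
    if significant_only:
        rows = [r for r in rows if r.estimate.pvalue < alpha]
    if not rows:
        raise MRScanError("no rows to export")
    with open(path, "w") as fh:
        fh.write("exposure\toutcome\tOR\tCI_low\tCI_high\tpvalue\tmethod\tk\n")
        for r in rows:
            e = r.estimate
            fh.write(
                f"{r.exposure}\t{r.outcome}\t{e.or_:.6g}\t{e.ci_low:.6g}\t"
                f"{e.ci_high:.6g}\t{e.pvalue:.6g}\t{e.method}\t{e.k}\n"
            )
    return len(rows)
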