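"""Panel-wide parent-of-origin scan with Bonferroni correction.

Runs QC and the per-SNP imprinting fit across a panel, flags SNPs
significant at the family-wise level (alpha divided by the number of SNPs
actually tested, i.e. passing QC), and emits the ranked results table
plus plot-ready data: a Manhattan table (chromosome, position, -log10 p)
and the per-SNP relative risks grouped by pathway.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedio import MISSING, Panel, SnpMeta
from .poe_fit import ModelConfig, fit_snp
from .snp_qc import QcThresholds, qc_filter

__all__ = ["ScanConfig", "ScanResult", "bonferroni_threshold", "run_scan"]


@dataclass(frozen=True)
class ScanConfig:
    alpha: float = 0.05
    top_k: int = 20
    model: ModelConfig = field(default_factory=ModelConfig)
    qc: QcThresholds = field(default_factory=QcThresholds)
    run_qc: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha {self.alpha} outside (0, 1)")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")


@dataclass
class ScanResult:
    results: pd.DataFrame       # one row per tested SNP, ascending p
    manhattan: pd.DataFrame     # chr, pos, neg_log10_p
    rr_by_pathway: pd.DataFrame  # snp_id, pathway, rr_poe
    qc_report: pd.DataFrame
    threshold: float
    n_tested: int


def bonferroni_threshold(alpha: float, n_snps: int) -> float:
    """Per-test significance level controlling family-wise error at
    ``alpha`` over ``n_snps`` tests — exact division, no rounding."""
    if n_snps < 1:
        raise ValueError(f"n_snps must be >= 1, got {n_snps}")
    if not 0 < alpha < 1:
        raise ValueError(f"alpha {alpha} outside (0, 1)")
    return alpha / n_snps


def _annotate(panel: Panel, annotation: list[SnpMeta] | None) -> list[SnpMeta]:
    if annotation is None:
        return panel.snps
    by_id = {meta.snp_id: meta for meta in annotation}
    out = []
    for meta in panel.snps:
        out.append(by_id.get(meta.snp_id, meta))
    return out


def _chrom_sort_key(chrom: str):
    return (0, int(chrom)) if chrom.isdigit() else (1, chrom)


def run_scan(
    panel: Panel,
    annotation: list[SnpMeta] | None = None,
    config: ScanConfig | None = None,
) -> ScanResult:
    """QC + per-SNP imprinting fit + Bonferroni calls over a panel.

    The Bonferroni denominator is the number of SNPs actually tested
    (post-QC).  Rows are sorted by ascending p-value, ties broken by
    (chromosome, position); no SNP is silently dropped — excluded ones
    appear in the QC report with their failure reasons.
    """
    config = config or ScanConfig()
    if config.run_qc:
        passed, qc_report = qc_filter(panel, config.qc)
    else:
        passed, qc_report = panel, pd.DataFrame(
            {"snp_id": [s.snp_id for s in panel.snps], "pass": True}
        )

    metas = _annotate(passed, annotation)
    n_tested = passed.n_snps
    if n_tested == 0:
        warnings.warn("no SNPs passed QC; scan output is empty", stacklevel=2)
        empty = pd.DataFrame()
        return ScanResult(empty, empty, empty, qc_report, float("nan"), 0)

    threshold = bonferroni_threshold(config.alpha, n_tested)
    rows = []
    for k, meta in enumerate(metas):
        trios = [t for t in passed.trios_for_snp(k) if t.c != MISSING]
        fit = fit_snp(trios, config.model)
        rows.append(
            {
                "snp_id": meta.snp_id,
                "alleles": f"{meta.allele_major}/{meta.allele_minor}",
                "chr": meta.chromosome,
                "pos": meta.position,
                "gene": meta.gene,
                "pathway": meta.pathway,
                "rr_poe": fit.rr_poe,
                "ci_low": fit.ci95[0],
                "ci_high": fit.ci95[1],
                "p_value": fit.p_value,
                "lrt_stat": fit.lrt_stat,
                "n_informative": fit.n_informative,
                "converged": fit.converged,
                "significant": fit.p_value <= threshold,
            }
        )
    results = pd.DataFrame(rows)
    results["_chr_key"] = [_chrom_sort_key(c) for c in results["chr"]]
    results = (
        results.sort_values(["p_value", "_chr_key", "pos"])
        .drop(columns="_chr_key")
        .reset_index(drop=True)
    )
    results["top_k"] = np.arange(len(results)) < config.top_k

    manhattan = pd.DataFrame(
        {
            "chr": results["chr"],
            "pos": results["pos"],
            "neg_log10_p": -np.log10(results["p_value"].clip(lower=1e-300)),
        }
    )
    rr_by_pathway = results[["snp_id", "pathway", "rr_poe"]].copy()
    return ScanResult(
        results=results,
        manhattan=manhattan,
        rr_by_pathway=rr_by_pathway,
        qc_report=qc_report,
        threshold=threshold,
        n_tested=n_tested,
    )


def significance_calls(p_values, alpha: float, n_tested: int) -> np.ndarray:
    """Reproduce the significant flags from p-values alone."""
    thr = bonferroni_threshold(alpha, n_tested)
    return np.asarray(p_values) <= thr
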