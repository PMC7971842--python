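"""Per-SNP quality control for case-family panels.

Implements the four marker-level exclusion filters commonly applied to
family genotype panels before parent-of-origin modelling:

* no-call rate above a maximum (default 10%),
* trio Mendelian-error rate above a maximum (default 5%),
* founder minor allele frequency below a minimum (default 5%),
* Hardy-Weinberg disequilibrium in at least one population stratum
  (exact test on founders; default alpha 1e-4).

SNPs failing any filter are dropped before modelling, never imputed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .pedio import MISSING, Panel

__all__ = [
    "QcThresholds",
    "mendelian_consistent",
    "duo_impossible",
    "hwe_exact_p",
    "qc_filter",
]


@dataclass(frozen=True)
class QcThresholds:
    """Exclusion thresholds; a SNP must satisfy all four to pass."""

    max_nocall: float = 0.10
    max_mendel_error: float = 0.05
    min_maf: float = 0.05
    hwe_alpha: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("max_nocall", "max_mendel_error", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")


def _alleles(dosage: int) -> tuple[int, ...]:
    return {0: (0,), 1: (0, 1), 2: (1,)}[dosage]


def mendelian_consistent(m: int, f: int, c: int) -> bool:
    """True iff child dosage ``c`` can arise from one allele of each parent.

    All three dosages must be non-missing; trios with a missing member are
    skipped for the Mendelian-error metric.
    """
    for d in (m, f, c):
        if d not in (0, 1, 2):
            raise ValueError(f"dosage {d!r} outside {{0, 1, 2}}")
    return any(am + af == c for am in _alleles(m) for af in _alleles(f))


def duo_impossible(parent: int, child: int) -> bool:
    """Parent-child pair impossible under Mendelian transmission
    (opposite homozygotes)."""
    for d in (parent, child):
        if d not in (0, 1, 2):
            raise ValueError(f"dosage {d!r} outside {{0, 1, 2}}")
    return (parent == 0 and child == 2) or (parent == 2 and child == 0)


def hwe_exact_p(n0: int, n1: int, n2: int) -> float:
    """Two-sided exact Hardy-Weinberg test p-value for genotype counts.

    ``n0``/``n1``/``n2`` are major-homozygote, heterozygote and
    minor-homozygote counts among founders of one stratum.  Uses the
    probability-ordering convention: conditional on the observed allele
    counts, sum the probabilities of all heterozygote counts whose exact
    probability does not exceed that of the observed table.
    """
    for n in (n0, n1, n2):
        if n < 0 or int(n) != n:
            raise ValueError(f"genotype count {n!r} must be a nonnegative integer")
    n0, n1, n2 = int(n0), int(n1), int(n2)
    n = n0 + n1 + n2
    if n == 0:
        warnings.warn("HWE test on zero genotypes; returning p = 1", stacklevel=2)
        return 1.0
    n_minor = n1 + 2 * n2
    n_major = n1 + 2 * n0
    rare = min(n_minor, n_major)

    # P(het = h | allele counts) up to a constant, on the log scale.
    hets = np.arange(rare % 2, rare + 1, 2)
    homr = (rare - hets) // 2
    homc = n - hets - homr
    logp = (
        gammaln(n + 1)
        - gammaln(hets + 1)
        - gammaln(homr + 1)
        - gammaln(homc + 1)
        + hets * np.log(2.0)
        - (gammaln(2 * n + 1) - gammaln(rare + 1) - gammaln(2 * n - rare + 1))
    )
    probs = np.exp(logp - logp.max())
    probs /= probs.sum()
    observed = np.flatnonzero(hets == n1)
    if observed.size == 0:  # n1 parity inconsistent with allele counts
        raise ValueError("heterozygote count inconsistent with allele counts")
    p_obs = probs[observed[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _snp_metrics(panel: Panel, k: int) -> tuple[float, float, float, dict[str, float]]:
    """(nocall_rate, mendel_error_rate, maf, hwe_p_by_stratum) for SNP k."""
    m_col, f_col, c_col = panel.m[:, k], panel.f[:, k], panel.c[:, k]
    mother_in, father_in = panel.mother_present, panel.father_present

    # No-call rate over genotype slots of individuals present in the pedigree.
    slots = int(mother_in.sum() + father_in.sum() + len(c_col))
    missing = (
        int((m_col[mother_in] == MISSING).sum())
        + int((f_col[father_in] == MISSING).sum())
        + int((c_col == MISSING).sum())
    )
    nocall = missing / slots if slots else 0.0

    # Mendelian error rate over informative family comparisons: complete
    # trios checked in full; parent-child duos only for impossible pairs.
    errors = 0
    informative = 0
    for i in range(panel.n_families):
        mi, fi, ci = int(m_col[i]), int(f_col[i]), int(c_col[i])
        if ci == MISSING:
            continue
        if mi != MISSING and fi != MISSING:
            informative += 1
            errors += not mendelian_consistent(mi, fi, ci)
        elif mi != MISSING or fi != MISSING:
            parent = mi if mi != MISSING else fi
            informative += 1
            errors += duo_impossible(parent, ci)
    mendel = errors / informative if informative else 0.0

    # MAF from founders pooled across strata; dosage counts the minor
    # allele, but an annotation-fixed orientation can put the labelled
    # minor above 0.5, so fold.
    minor, major = panel.founder_allele_counts(k)
    total = minor + major
    freq = minor / total if total else 0.0
    maf = min(freq, 1.0 - freq)

    # HWE exact test on founders within each stratum.
    hwe: dict[str, float] = {}
    strata = np.asarray(panel.strata)
    for stratum in sorted(set(panel.strata)):
        sel = strata == stratum
        counts = [0, 0, 0]
        for col, present in ((m_col, mother_in), (f_col, father_in)):
            vals = col[sel & present]
            for g in (0, 1, 2):
                counts[g] += int((vals == g).sum())
        if sum(counts) == 0:
            hwe[stratum] = 1.0
            continue
        hwe[stratum] = hwe_exact_p(*counts)
    return nocall, mendel, maf, hwe


def qc_filter(
    panel: Panel, thresholds: QcThresholds | None = None
) -> tuple[Panel, pd.DataFrame]:
    """Apply all four filters; return the passing sub-panel and a report.

    The report covers every input SNP, including excluded ones, with one
    row per SNP: the measured rates, the minimum HWE p-value over strata,
    a pass flag, and comma-joined failure reasons drawn from
    {nocall, mendel, maf, hwe}.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    thr = thresholds or QcThresholds()
    rows = []
    keep = []
    strata_names = sorted(set(panel.strata))
    for k, meta in enumerate(panel.snps):
        nocall, mendel, maf, hwe = _snp_metrics(panel, k)
        reasons = []
        if nocall > thr.max_nocall:
            reasons.append("nocall")
        if mendel > thr.max_mendel_error:
            reasons.append("mendel")
        if maf < thr.min_maf:
            reasons.append("maf")
        if min(hwe.values()) < thr.hwe_alpha:
            reasons.append("hwe")
        if not reasons:
            keep.append(k)
        row = {
            "snp_id": meta.snp_id,
            "nocall_rate": nocall,
            "mendel_error_rate": mendel,
            "maf": maf,
            "hwe_min_p": min(hwe.values()),
            "pass": not reasons,
            "fail_reasons": ",".join(reasons),
        }
        for stratum in strata_names:
            row[f"hwe_p_{stratum}"] = hwe[stratum]
        rows.append(row)
    report = pd.DataFrame(rows)
    return panel.subset_snps(keep), report
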