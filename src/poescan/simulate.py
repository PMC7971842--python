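"""Synthetic case-family panel generator.

Emulates the statistical structure the parent-of-origin analysis assumes:
biallelic SNPs with configurable minor allele frequencies, parental
genotypes drawn under Hardy-Weinberg random mating, fair Mendelian
transmission with tracked (then discarded) parental origin, and
ascertainment of case families by rejection sampling proportional to the
log-linear disease-risk multiplier R_c * S_m * W^[paternal het].  Family
completeness follows the study design being emulated: by default 38.7%
full trios, with 90% of incomplete families missing the father.

Random mating makes the fitted model's mating-stratum weights mu
recoverable (they are implied by the HWE mating-pair frequencies), but
the fitting code never assumes HWE.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .pedio import MISSING, Panel, SnpMeta, TrioGenotype
from .poe_model import PoeParams, stratum_index

__all__ = ["SimConfig", "simulate_family", "simulate_panel", "hwe_mating_mu"]

_PATHWAY_CYCLE = ("folate", "homocysteine", "transsulfuration", "other")


@dataclass(frozen=True)
class SimConfig:
    """Panel-level simulation settings.

    Defaults mirror the emulated study: 569 case families of which 38.7%
    are full trios, and markers kept only above 5% minor allele
    frequency.  ``signal_snps`` maps SNP index to the true
    :class:`PoeParams` at that marker; all other SNPs are null (all
    effect parameters 1).
    """

    n_families: int = 569
    n_snps: int = 10
    maf_range: tuple[float, float] = (0.05, 0.5)
    signal_snps: dict[int, PoeParams] = field(default_factory=dict)
    full_trio_fraction: float = 0.387
    father_missing_given_incomplete: float = 0.9
    nocall_rate: float = 0.0
    stratum2_fraction: float = 0.0
    stratum2_inbreeding: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1 or self.n_families < 1:
            raise ValueError("n_families and n_snps must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range {self.maf_range} outside (0, 0.5]")
        for name in (
            "full_trio_fraction",
            "father_missing_given_incomplete",
            "nocall_rate",
            "stratum2_fraction",
            "stratum2_inbreeding",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for k in self.signal_snps:
            if not 0 <= k < self.n_snps:
                raise ValueError(f"signal SNP index {k} out of range")


def _genotype_probs(maf: float, inbreeding: float = 0.0) -> np.ndarray:
    p, q = maf, 1.0 - maf
    f = inbreeding
    return np.array(
        [q * q + f * p * q, 2 * p * q * (1 - f), p * p + f * p * q]
    )


def _max_multiplier(params: PoeParams) -> float:
    r = np.array([1.0, params.R1, params.R2])
    s = np.array([1.0, params.S1, params.S2])
    return float(r.max() * s.max() * max(params.W, 1.0))


def _simulate_complete(
    n: int,
    maf: float,
    params: PoeParams,
    rng: np.random.Generator,
    inbreeding: float = 0.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """n accepted complete trios: (m, f, c, paternal_origin) arrays.

    ``paternal_origin`` is True where a heterozygous child's minor allele
    came from the father; it is internal bookkeeping — callers modelling
    observable data must discard it.
    """
    geno_p = _genotype_probs(maf, inbreeding)
    mmax = _max_multiplier(params)
    r = np.array([1.0, params.R1, params.R2])
    s = np.array([1.0, params.S1, params.S2])

    out_m = np.empty(n, dtype=np.int8)
    out_f = np.empty(n, dtype=np.int8)
    out_c = np.empty(n, dtype=np.int8)
    out_pat = np.empty(n, dtype=bool)
    filled = 0
    # Rejection sampling: exact ascertainment at the cost of extra draws.
    while filled < n:
        batch = max(64, int(1.5 * (n - filled) * mmax))
        m = rng.choice(3, size=batch, p=geno_p).astype(np.int8)
        f = rng.choice(3, size=batch, p=geno_p).astype(np.int8)
        am = np.where(m == 1, rng.integers(0, 2, size=batch), m // 2)
        af = np.where(f == 1, rng.integers(0, 2, size=batch), f // 2)
        c = (am + af).astype(np.int8)
        paternal = (c == 1) & (af == 1)
        mult = r[c] * s[m] * np.where(paternal, params.W, 1.0)
        accept = rng.random(batch) * mmax < mult
        take = min(int(accept.sum()), n - filled)
        idx = np.flatnonzero(accept)[:take]
        out_m[filled : filled + take] = m[idx]
        out_f[filled : filled + take] = f[idx]
        out_c[filled : filled + take] = c[idx]
        out_pat[filled : filled + take] = paternal[idx]
        filled += take
    return out_m, out_f, out_c, out_pat


def simulate_family(
    maf: float, params: PoeParams, rng: np.random.Generator
) -> TrioGenotype:
    """One accepted complete case trio; the origin tag is discarded
    (it is unobservable in real data)."""
    if not 0 < maf <= 0.5:
        raise ValueError(f"maf {maf} outside (0, 0.5]")
    m, f, c, _ = _simulate_complete(1, maf, params, rng)
    return TrioGenotype(family_id="sim", m=int(m[0]), f=int(f[0]), c=int(c[0]))


def hwe_mating_mu(maf: float) -> tuple[float, ...]:
    """Mating-stratum weights implied by HWE random mating at ``maf``,
    gauged so the {0,0} stratum equals 1.  Under random mating the two
    orders of a heterogeneous pair are equally likely, so the shared
    stratum weight is the ordered-pair probability."""
    g = _genotype_probs(maf)
    mu = [0.0] * 6
    for gm in range(3):
        for gf in range(3):
            j = stratum_index(gm, gf)
            mu[j] = g[gm] * g[gf]  # same product for either order
    gauge = mu[5]
    return tuple(v / gauge for v in mu)


def simulate_panel(config: SimConfig) -> Panel:
    """Generate a rectangular case-family panel under the model.

    Family completeness is assigned once per family, so missingness is
    consistent across SNPs; additional per-genotype no-calls are applied
    independently at ``nocall_rate``.  SNPs are independent (no linkage
    disequilibrium).
    """
    rng = np.random.default_rng(config.seed)
    n_fam, n_snp = config.n_families, config.n_snps

    mafs = rng.uniform(*config.maf_range, size=n_snp)
    in_stratum2 = rng.random(n_fam) < config.stratum2_fraction
    strata = ["S2" if flag else "S1" for flag in in_stratum2] if (
        config.stratum2_fraction > 0
    ) else ["ALL"] * n_fam

    full = rng.random(n_fam) < config.full_trio_fraction
    father_gone = ~full & (
        rng.random(n_fam) < config.father_missing_given_incomplete
    )
    mother_gone = ~full & ~father_gone
    mother_present = ~mother_gone
    father_present = ~father_gone

    m = np.full((n_fam, n_snp), MISSING, dtype=np.int8)
    f = np.full((n_fam, n_snp), MISSING, dtype=np.int8)
    c = np.full((n_fam, n_snp), MISSING, dtype=np.int8)
    snps = []
    for k in range(n_snp):
        params = config.signal_snps.get(k, PoeParams.null())
        for flag, inbreeding in (
            (False, 0.0),
            (True, config.stratum2_inbreeding),
        ):
            sel = np.flatnonzero(in_stratum2 == flag)
            if sel.size == 0:
                continue
            mk, fk, ck, _ = _simulate_complete(
                sel.size, float(mafs[k]), params, rng, inbreeding
            )
            m[sel, k], f[sel, k], c[sel, k] = mk, fk, ck
        snps.append(
            SnpMeta(
                snp_id=f"snp{k + 1:04d}",
                chromosome=str(k % 22 + 1),
                position=10_000 + 1_000 * k,
                allele_minor="A",
                allele_major="G",
                gene=f"GENE{k // 5 + 1}",
                pathway=_PATHWAY_CYCLE[k % 4],
            )
        )

    m[mother_gone, :] = MISSING
    f[father_gone, :] = MISSING
    if config.nocall_rate > 0:
        for mat, present in ((m, mother_present), (f, father_present)):
            drop = rng.random((n_fam, n_snp)) < config.nocall_rate
            mat[drop & present[:, None]] = MISSING
        c[rng.random((n_fam, n_snp)) < config.nocall_rate] = MISSING

    return Panel(
        snps=snps,
        family_ids=[f"fam{i + 1:04d}" for i in range(n_fam)],
        m=m, f=f, c=c,
        mother_present=mother_present,
        father_present=father_present,
        strata=strata,
    )


def write_truth(config: SimConfig, path: str | Path) -> None:
    """True per-SNP parameters as JSON, for recovery testing."""
    truth = {}
    for k in range(config.n_snps):
        params = config.signal_snps.get(k, PoeParams.null())
        truth[f"snp{k + 1:04d}"] = {
            "R1": params.R1, "R2": params.R2,
            "S1": params.S1, "S2": params.S2, "W": params.W,
        }
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=1)
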