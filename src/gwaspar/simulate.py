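"""Case-control GWAS summary-statistics generator with known ground truth.

Stands in for published per-ancestry meta-analysis summary statistics so
every pipeline stage is testable without external downloads.  Two levels
of fidelity:

* single variants — allele counts drawn binomially from a case-control
  allelic disease model (HWE allele sampling, rare-disease control
  frequency ~ population frequency), with the log odds ratio, Wald
  standard error and two-sided p-value computed from the sampled 2x2
  table exactly as a GWAS would;
* per-locus blocks — z-scores for a set of variants in LD drawn from a
  multivariate normal with AR(1) correlation R (R_ij = rho^|i-j|) and
  mean R @ (lambda e_causal), the standard summary-statistics (RSS)
  approximation; each z is converted back to (beta, se, p) at the
  variant's allele frequency.  LD acts at the z-score level only — no
  individual genotypes are simulated.

A configurable fraction of records is emitted in the flipped
(protective-looking) orientation, exercising harmonization downstream.
All randomness flows from one integer seed; the same seed reproduces the
whole study byte-identically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import harmonize_variant
from .par import compute_par
from .records import ConfigError, LocusBlock, VariantRecord, AncestryStratum

# smallest positive normal double: keeps p_value within (0, 1] at huge z
_P_FLOOR = 5e-308

_RISK_ALLELE = "A"
_OTHER_ALLELE = "G"


@dataclass
class AncestrySpec:
    label: str
    n_cases: int
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ConfigError(f"{self.label}: sample sizes must be positive")


@dataclass
class LocusSpec:
    """One locus's generating truth.

    ``true_or`` / ``true_raf`` may be a single number (shared across
    ancestries) or a mapping from ancestry label to value, which is how
    ancestry-specific architectures are expressed.
    """

    locus: str
    n_variants: int = 1
    causal_index: int = 0
    true_or: float | dict[str, float] = 1.2
    true_raf: float | dict[str, float] = 0.3
    ld_rho: float = 0.0

    def __post_init__(self) -> None:
        if self.n_variants < 1:
            raise ConfigError(f"{self.locus}: n_variants must be >= 1")
        if not (0 <= self.causal_index < self.n_variants):
            raise ConfigError(f"{self.locus}: causal_index out of range")
        if not (0.0 <= self.ld_rho < 1.0):
            raise ConfigError(f"{self.locus}: ld_rho {self.ld_rho} outside [0, 1)")

    def or_for(self, ancestry: str) -> float:
        v = self.true_or[ancestry] if isinstance(self.true_or, dict) else self.true_or
        if v <= 0:
            raise ConfigError(f"{self.locus}: true_or must be positive")
        return float(v)

    def raf_for(self, ancestry: str) -> float:
        v = self.true_raf[ancestry] if isinstance(self.true_raf, dict) else self.true_raf
        if not (0.0 < v < 1.0):
            raise ConfigError(f"{self.locus}: true_raf outside (0, 1)")
        return float(v)


@dataclass
class SimulationConfig:
    seed: int
    ancestries: list[AncestrySpec]
    loci: list[LocusSpec]
    prevalence: float = 0.005
    protective_fraction: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 < self.prevalence < 0.5):
            raise ConfigError(f"prevalence {self.prevalence} outside (0, 0.5)")
        if not (0.0 <= self.protective_fraction <= 1.0):
            raise ConfigError("protective_fraction outside [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        return cls(
            seed=int(d["seed"]),
            ancestries=[AncestrySpec(**a) for a in d["ancestries"]],
            loci=[LocusSpec(**l) for l in d["loci"]],
            prevalence=float(d.get("prevalence", 0.005)),
            protective_fraction=float(d.get("protective_fraction", 0.3)),
        )


def case_frequency(raf: float, odds_ratio: float) -> float:
    """Risk-allele frequency among case alleles given the control (~
    population) frequency and allelic odds ratio."""
    return odds_ratio * raf / (1.0 + raf * (odds_ratio - 1.0))


def expected_z(true_or: float, true_raf: float, n_cases: int, n_controls: int) -> float:
    """Expected Wald z of the log allelic OR at the study's sample sizes."""
    pc = case_frequency(true_raf, true_or)
    var = 1.0 / (2 * n_cases * pc * (1 - pc)) + 1.0 / (
        2 * n_controls * true_raf * (1 - true_raf)
    )
    return math.log(true_or) / math.sqrt(var)


def _wald_from_table(a: float, b: float, c: float, d: float) -> tuple[float, float, float]:
    """(beta, se, p) from a 2x2 allele table; Haldane-Anscombe 0.5 added
    to every cell when any cell is zero."""
    if min(a, b, c, d) == 0:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    beta = math.log(a * d / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    p = max(2.0 * stats.norm.sf(abs(beta) / se), _P_FLOOR)
    return beta, se, p


def simulate_single_variant(
    n_cases: int,
    n_controls: int,
    true_raf: float,
    true_or: float,
    rng: np.random.Generator,
    *,
    variant_id: str = "rs1",
    chrom: str = "1",
    pos: int = 1,
    locus: str = "LOC",
    ancestry: str = "EUR",
    protective_fraction: float = 0.0,
    max_attempts: int = 100,
) -> VariantRecord:
    """Draw one variant's summary statistics from the allelic disease model.

    Case allele counts are binomial at the case frequency implied by the
    odds ratio; control counts binomial at the population frequency
    (rare-disease approximation).  With probability
    ``protective_fraction`` the record is emitted in the flipped
    orientation — alleles swapped, frequency complemented, beta negated —
    mimicking summary statistics whose effect allele is the protective
    one.  Monomorphic draws are redrawn, up to ``max_attempts``.
    """
    p_case = case_frequency(true_raf, true_or)
    m_case, m_ctrl = 2 * n_cases, 2 * n_controls
    for _ in range(max_attempts):
        a = int(rng.binomial(m_case, p_case))
        c = int(rng.binomial(m_ctrl, true_raf))
        b, d = m_case - a, m_ctrl - c
        if (a + c) == 0 or (b + d) == 0:
            continue  # monomorphic in the pooled sample
        beta, se, p = _wald_from_table(a, b, c, d)
        eaf = (a + c) / (m_case + m_ctrl)
        if not (0.0 < eaf < 1.0):
            continue
        flip = rng.random() < protective_fraction
        if flip:
            return VariantRecord(
                variant_id=variant_id, chrom=chrom, pos=pos,
                effect_allele=_OTHER_ALLELE, other_allele=_RISK_ALLELE,
                beta=-beta, se=se, p_value=p, eaf=1.0 - eaf,
                locus=locus, ancestry=ancestry,
            )
        return VariantRecord(
            variant_id=variant_id, chrom=chrom, pos=pos,
            effect_allele=_RISK_ALLELE, other_allele=_OTHER_ALLELE,
            beta=beta, se=se, p_value=p, eaf=eaf,
            locus=locus, ancestry=ancestry,
        )
    raise RuntimeError(
        f"{variant_id}: monomorphic draws persisted for {max_attempts} attempts"
    )


def ar1_ld(n: int, rho: float) -> np.ndarray:
    """AR(1) correlation matrix R_ij = rho^|i-j| (symmetric positive definite)."""
    idx = np.arange(n)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def simulate_locus_block(
    locus_spec: LocusSpec,
    ancestry_spec: AncestrySpec,
    rng: np.random.Generator,
    *,
    protective_fraction: float = 0.0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
) -> LocusBlock:
    """Simulate a multi-variant locus at the z-score level.

    z ~ MVN(R @ (lambda e_causal), R) with R the AR(1) LD matrix and
    lambda the causal variant's expected z; each z converts back to
    (beta, se, p) at the variant's frequency.  Non-causal variant
    frequencies are drawn uniform on (0.05, 0.95).  Records are returned
    harmonized (the fine-mapping input convention) with R attached.
    """
    records, ld = _simulate_block_records(
        locus_spec, ancestry_spec, rng,
        protective_fraction=protective_fraction, chrom=chrom, start_pos=start_pos,
    )
    return LocusBlock(
        locus=locus_spec.locus,
        variants=[harmonize_variant(r) for r in records],
        ld=ld,
    )


def _simulate_block_records(
    locus_spec: LocusSpec,
    ancestry_spec: AncestrySpec,
    rng: np.random.Generator,
    *,
    protective_fraction: float = 0.0,
    chrom: str = "1",
    start_pos: int = 1_000_000,
) -> tuple[list[VariantRecord], np.ndarray]:
    n = locus_spec.n_variants
    anc = ancestry_spec.label
    true_or = locus_spec.or_for(anc)
    true_raf = locus_spec.raf_for(anc)
    ci = locus_spec.causal_index

    freqs = rng.uniform(0.05, 0.95, size=n)
    freqs[ci] = true_raf

    nc, nn = ancestry_spec.n_cases, ancestry_spec.n_controls
    se = np.sqrt(1.0 / (2 * nc * freqs * (1 - freqs)) + 1.0 / (2 * nn * freqs * (1 - freqs)))
    # causal se at its case-enriched frequency, consistent with expected_z
    lam = expected_z(true_or, true_raf, nc, nn)
    se[ci] = math.log(true_or) / lam if lam != 0 else se[ci]

    R = ar1_ld(n, locus_spec.ld_rho)
    mean = R[:, ci] * lam
    L = np.linalg.cholesky(R)
    z = mean + L @ rng.standard_normal(n)

    records = []
    for i in range(n):
        beta = float(z[i] * se[i])
        p = max(2.0 * stats.norm.sf(abs(z[i])), _P_FLOOR)
        eaf = float(freqs[i])
        ea, oa = _RISK_ALLELE, _OTHER_ALLELE
        if rng.random() < protective_fraction:
            beta, eaf, ea, oa = -beta, 1.0 - eaf, _OTHER_ALLELE, _RISK_ALLELE
        records.append(
            VariantRecord(
                variant_id=f"{locus_spec.locus}:snp{i}",
                chrom=chrom,
                pos=start_pos + 1000 * i,
                effect_allele=ea,
                other_allele=oa,
                beta=beta,
                se=float(se[i]),
                p_value=float(p),
                eaf=eaf,
                locus=locus_spec.locus,
                ancestry=anc,
            )
        )
    return records, R


def simulate_study(
    cfg: SimulationConfig,
) -> tuple[dict[str, AncestryStratum], pd.DataFrame]:
    """Generate a whole multi-ancestry study plus its ground-truth table.

    Returns per-ancestry strata (single-variant loci drawn from the
    allele-count model, multi-variant loci from the z-score model) and a
    truth table with each causal variant's generating OR, RAF and the PAR
    they imply — the reference for recovery tests.  Deterministic given
    ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    strata: dict[str, AncestryStratum] = {}
    truth_rows = []
    for anc_spec in cfg.ancestries:
        records: list[VariantRecord] = []
        for li, locus_spec in enumerate(cfg.loci):
            true_or = locus_spec.or_for(anc_spec.label)
            true_raf = locus_spec.raf_for(anc_spec.label)
            chrom = str(1 + li % 22)
            if locus_spec.n_variants == 1:
                rec = simulate_single_variant(
                    anc_spec.n_cases, anc_spec.n_controls, true_raf, true_or, rng,
                    variant_id=f"{locus_spec.locus}:snp0",
                    chrom=chrom, pos=1_000_000,
                    locus=locus_spec.locus, ancestry=anc_spec.label,
                    protective_fraction=cfg.protective_fraction,
                )
                records.append(rec)
                causal_id = rec.variant_id
            else:
                block_records, _ = _simulate_block_records(
                    locus_spec, anc_spec, rng,
                    protective_fraction=cfg.protective_fraction, chrom=chrom,
                )
                records.extend(block_records)
                causal_id = f"{locus_spec.locus}:snp{locus_spec.causal_index}"
            risk_or = true_or if true_or >= 1.0 else 1.0 / true_or
            risk_raf = true_raf if true_or >= 1.0 else 1.0 - true_raf
            truth_rows.append(
                {
                    "ancestry": anc_spec.label,
                    "locus": locus_spec.locus,
                    "causal_variant": causal_id,
                    "true_or": risk_or,
                    "true_raf": risk_raf,
                    "true_par": compute_par(risk_raf, risk_or),
                }
            )
        strata[anc_spec.label] = AncestryStratum(
            label=anc_spec.label, variants=records, source_name=f"simulated(seed={cfg.seed})"
        )
    truth = pd.DataFrame(
        truth_rows,
        columns=["ancestry", "locus", "causal_variant", "true_or", "true_raf", "true_par"],
    )
    return strata, truth
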