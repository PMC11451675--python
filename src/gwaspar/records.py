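"""Core record types shared across the pipeline.

Every record is a small frozen dataclass validated on construction, so a
record that exists is a record that satisfies its invariants.  The pipeline
works on one internal effect scale throughout: ``beta`` is the natural-log
odds ratio.  Inputs that report an odds ratio are converted on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional, Sequence

import numpy as np

_NUCLEOTIDES = frozenset("ACGT")


class ValidationError(ValueError):
    """A record violates one of its type invariants."""


class SchemaError(ValueError):
    """An input table is missing or mislabels a required column."""


class ConfigError(ValueError):
    """A configuration value is outside its stated domain."""


@dataclass(frozen=True)
class VariantRecord:
    """One summary-statistics row as reported by a GWAS.

    The effect allele is oriented arbitrarily: ``beta`` may be negative
    (protective orientation).  ``eaf`` is the frequency of the reported
    effect allele, taken at face value.

    Parameters
    ----------
    variant_id : str
        rsID or chr:pos:ref:alt identifier.
    chrom, pos : str, int
        1-based coordinates; build is free-text provenance only.
    effect_allele, other_allele : str
        Single nucleotides in {A, C, G, T}; must differ.
    beta : float
        Log odds ratio (natural log) for the effect allele.
    se : float
        Standard error of ``beta``; strictly positive.
    p_value : float
        Two-sided association p-value in (0, 1].
    eaf : float
        Effect-allele frequency in (0, 1).
    locus : str
        Nearest-gene / locus label used for per-locus selection.
    ancestry : str
        Ancestry stratum label, e.g. "EUR", "AFR", "EAS", "AMR".
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p_value: float
    eaf: float
    locus: str
    ancestry: str

    def __post_init__(self) -> None:
        if self.effect_allele not in _NUCLEOTIDES:
            raise ValidationError(
                f"{self.variant_id}: effect allele {self.effect_allele!r} is not a single nucleotide"
            )
        if self.other_allele not in _NUCLEOTIDES:
            raise ValidationError(
                f"{self.variant_id}: other allele {self.other_allele!r} is not a single nucleotide"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.variant_id}: identical effect and other alleles")
        if self.pos <= 0:
            raise ValidationError(f"{self.variant_id}: non-positive position {self.pos}")
        if not np.isfinite(self.beta):
            raise ValidationError(f"{self.variant_id}: non-finite beta")
        if not (self.se > 0 and np.isfinite(self.se)):
            raise ValidationError(f"{self.variant_id}: se must be positive, got {self.se}")
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(f"{self.variant_id}: p-value {self.p_value} outside (0, 1]")
        if not (0.0 < self.eaf < 1.0):
            raise ValidationError(f"{self.variant_id}: eaf {self.eaf} outside (0, 1)")

    @property
    def is_palindromic(self) -> bool:
        """A/T or C/G strand-ambiguous SNP (not resolved, only flagged)."""
        return {self.effect_allele, self.other_allele} in ({"A", "T"}, {"C", "G"})


@dataclass(frozen=True)
class HarmonizedVariant:
    """A variant oriented to its risk allele: odds_ratio >= 1, RAF defined.

    ``beta`` here is the harmonized (non-negative) log odds ratio; the
    original reported sign is recoverable from ``flipped``.
    """

    variant_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p_value: float
    eaf: float
    locus: str
    ancestry: str
    risk_allele: str
    odds_ratio: float
    raf: float
    flipped: bool
    proxy_for: str = ""

    def __post_init__(self) -> None:
        if self.beta < 0 or self.odds_ratio < 1.0:
            raise ValidationError(f"{self.variant_id}: harmonized odds ratio below 1")
        if not (0.0 < self.raf < 1.0):
            raise ValidationError(f"{self.variant_id}: raf {self.raf} outside (0, 1)")


@dataclass(frozen=True)
class PAREstimate:
    """Per-variant, per-ancestry population attributable risk.

    ``rank`` is 0 until assigned by the ranking stage (1 = highest PAR,
    dense within ancestry).
    """

    variant_id: str
    locus: str
    ancestry: str
    raf: float
    odds_ratio: float
    par: float
    rank: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.par < 1.0):
            raise ValidationError(f"{self.variant_id}: PAR {self.par} outside [0, 1)")


@dataclass
class AncestryStratum:
    """One ancestry's summary statistics, order preserved from the source."""

    label: str
    variants: list[VariantRecord] = field(default_factory=list)
    source_name: str = ""

    def __post_init__(self) -> None:
        for v in self.variants:
            if v.ancestry != self.label:
                raise ValidationError(
                    f"{v.variant_id}: ancestry {v.ancestry!r} != stratum label {self.label!r}"
                )
        ids = [v.variant_id for v in self.variants]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate variant ids in stratum {self.label}: {dupes}")

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self):
        return iter(self.variants)


@dataclass
class LocusBlock:
    """A named locus's member variants with an optional LD matrix.

    ``ld`` holds pairwise allelic correlations r; it is accepted for
    provenance and simulation, the single-causal ABF estimator itself does
    not use it.
    """

    locus: str
    variants: list[HarmonizedVariant]
    ld: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.variants) < 1:
            raise ValidationError(f"locus {self.locus}: empty block")
        ancestries = {v.ancestry for v in self.variants}
        if len(ancestries) > 1:
            raise ValidationError(f"locus {self.locus}: mixed ancestries {sorted(ancestries)}")
        if self.ld is not None:
            ld = np.asarray(self.ld, dtype=float)
            n = len(self.variants)
            if ld.shape != (n, n):
                raise ValidationError(f"locus {self.locus}: LD shape {ld.shape} != ({n}, {n})")
            if not np.allclose(ld, ld.T, atol=1e-10):
                raise ValidationError(f"locus {self.locus}: LD matrix not symmetric")
            if not np.allclose(np.diag(ld), 1.0, atol=1e-10):
                raise ValidationError(f"locus {self.locus}: LD diagonal not unit")
            object.__setattr__(self, "ld", ld)

    @property
    def ancestry(self) -> str:
        return self.variants[0].ancestry


def record_fields(record_type) -> Sequence[str]:
    """Ordered field names of a record dataclass (for table headers)."""
    return tuple(f.name for f in fields(record_type))
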