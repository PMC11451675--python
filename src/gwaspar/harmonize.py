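"""Risk-allele harmonization.

GWAS summary statistics report effects for an arbitrarily chosen effect
allele, so a protective association (beta < 0) is the mirror image of a
risk association for the opposite allele.  Attributable-risk comparison
needs every variant oriented the same way: the harmonized record carries
the risk allele, an odds ratio >= 1 (OR = exp|beta|), and the risk-allele
frequency RAF.  For protective inputs the alleles are swapped and the
frequency complemented, RAF = 1 - EAF; risk inputs pass through with
RAF = EAF.

A reported beta of exactly 0 is kept as a degenerate risk variant
(OR = 1, downstream PAR = 0) rather than rejected.  Strand-ambiguous
A/T and C/G SNPs are not resolved — only counted in a log warning —
since no reference panel is in scope.
"""

from __future__ import annotations

import logging
import math

from .records import AncestryStratum, HarmonizedVariant, VariantRecord

logger = logging.getLogger(__name__)


def harmonize_variant(v: VariantRecord) -> HarmonizedVariant:
    """Orient one variant to its risk allele.

    Protective orientation (beta < 0) flips alleles and complements the
    frequency; p-value, standard error, locus and ancestry are unchanged.
    The harmonized beta is |beta|, so the operation is idempotent.
    """
    flipped = v.beta < 0
    if flipped:
        risk_allele = v.other_allele
        raf = 1.0 - v.eaf
    else:
        risk_allele = v.effect_allele
        raf = v.eaf
    beta = abs(v.beta)
    return HarmonizedVariant(
        variant_id=v.variant_id,
        chrom=v.chrom,
        pos=v.pos,
        effect_allele=v.effect_allele,
        other_allele=v.other_allele,
        beta=beta,
        se=v.se,
        p_value=v.p_value,
        eaf=v.eaf,
        locus=v.locus,
        ancestry=v.ancestry,
        risk_allele=risk_allele,
        odds_ratio=math.exp(beta),
        raf=raf,
        flipped=flipped,
    )


def harmonize_stratum(s: AncestryStratum) -> list[HarmonizedVariant]:
    """Element-wise :func:`harmonize_variant`, order preserved."""
    out = [harmonize_variant(v) for v in s.variants]
    n_flipped = sum(h.flipped for h in out)
    n_ambiguous = sum(v.is_palindromic for v in s.variants)
    logger.info(
        "harmonized %d variants in %s: %d flipped to risk orientation, %d strand-ambiguous",
        len(out), s.label, n_flipped, n_ambiguous,
    )
    return out
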