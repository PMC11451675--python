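r"""Population attributable risk via Levin's formula.

PAR estimates the proportion of disease cases in a population that would
be removed if an exposure were absent.  With the risk allele as the
exposure, exposure prevalence p equal to the risk allele frequency (RAF)
and the case-control odds ratio standing in for the relative risk (valid
for rare diseases), Levin's formula gives

    PAR = p (OR - 1) / (p (OR - 1) + 1)

per variant.  The exposure unit is the allele: p is the RAF itself, not a
diploid carrier frequency, so no genotype model enters.  The odds ratio
is used as supplied (no rare-disease correction), and only point
estimates are produced.
"""

from __future__ import annotations

from typing import Sequence

from .records import HarmonizedVariant, PAREstimate


def compute_par(raf: float, odds_ratio: float) -> float:
    """Levin attributable fraction p(OR-1)/(p(OR-1)+1).

    Parameters
    ----------
    raf : float
        Risk-allele frequency (exposure prevalence), in (0, 1].
    odds_ratio : float
        Harmonized odds ratio, >= 1 (relative-risk surrogate).

    Returns
    -------
    float
        PAR in [0, 1); 0 exactly when odds_ratio == 1.  Strictly
        increasing in each argument when the other exceeds its null value.
    """
    if not (0.0 < raf <= 1.0):
        raise ValueError(f"raf {raf} outside (0, 1]")
    if odds_ratio < 1.0:
        raise ValueError(f"odds ratio {odds_ratio} below 1; harmonize first")
    excess = raf * (odds_ratio - 1.0)
    return excess / (excess + 1.0)


def par_for_variants(variants: Sequence[HarmonizedVariant]) -> list[PAREstimate]:
    """One PAR estimate per harmonized variant, input order preserved.

    The ``rank`` field is left 0; the ranking stage assigns it.
    """
    out: list[PAREstimate] = []
    for v in variants:
        try:
            par = compute_par(v.raf, v.odds_ratio)
        except ValueError as exc:
            raise ValueError(f"{v.variant_id}: {exc}") from exc
        out.append(
            PAREstimate(
                variant_id=v.variant_id,
                locus=v.locus,
                ancestry=v.ancestry,
                raf=v.raf,
                odds_ratio=v.odds_ratio,
                par=par,
            )
        )
    return out
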