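"""Variant selection: significance filter, per-locus lead, proxy substitution.

Only nominally significant variants (p < alpha, default 0.05) enter the
attributable-risk comparison; requiring nominal significance increases
confidence in effect directionality.  Each named locus is then represented
by its single most significant variant (ties broken by larger harmonized
|beta|, then lexicographically smallest variant id, so selection is
deterministic under input permutation).  A user-declared proxy map can
substitute a correlated stand-in when the variant of interest is absent
or poorly typed in a dataset (e.g. using APOE rs1065853 in place of
rs7412 in summary statistics that lack the latter).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .records import ConfigError, HarmonizedVariant, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class ProxyMap:
    """Mapping from a target variant id to the correlated proxy used in
    its place, with a free-text justification per entry."""

    entries: dict[str, str] = field(default_factory=dict)
    justification: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for target, proxy in self.entries.items():
            if target == proxy:
                raise ValidationError(f"proxy map: {target} maps to itself")
        proxies = list(self.entries.values())
        if len(set(proxies)) != len(proxies):
            raise ValidationError("proxy map is not injective")

    @classmethod
    def from_file(cls, path) -> "ProxyMap":
        """Two-column (+ optional comment) delimited file: target, proxy[, note]."""
        df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
        cols = list(df.columns)
        entries = dict(zip(df[cols[0]], df[cols[1]]))
        notes = dict(zip(df[cols[0]], df[cols[2]])) if len(cols) > 2 else {}
        return cls(entries=entries, justification=notes)

    def __len__(self) -> int:
        return len(self.entries)


def filter_significant(
    variants: Sequence[HarmonizedVariant], alpha: float = 0.05
) -> list[HarmonizedVariant]:
    """Keep exactly the variants with p_value < alpha, order preserved.

    Nominal significance is the inclusion criterion: variants failing it
    are removed.
    """
    if not (0.0 < alpha < 1.0) and alpha != 1.0:
        raise ConfigError(f"alpha {alpha} outside (0, 1)")
    return [v for v in variants if v.p_value < alpha]


def _lead_key(v: HarmonizedVariant):
    # smallest p first, then largest harmonized |beta|, then smallest id
    return (v.p_value, -v.beta, v.variant_id)


def select_lead_per_locus(
    variants: Sequence[HarmonizedVariant],
) -> list[HarmonizedVariant]:
    """One lead variant per distinct locus label: minimal p-value, ties by
    larger |beta| then lexicographically smallest variant id.

    Output is ordered by locus label so the selected set is identical for
    any permutation of the input.
    """
    by_locus: dict[str, HarmonizedVariant] = {}
    for v in variants:
        best = by_locus.get(v.locus)
        if best is None or _lead_key(v) < _lead_key(best):
            by_locus[v.locus] = v
    return [by_locus[locus] for locus in sorted(by_locus)]


def apply_proxies(
    variants: Sequence[HarmonizedVariant],
    proxies: ProxyMap,
    pool: Sequence[HarmonizedVariant],
) -> list[HarmonizedVariant]:
    """Replace each mapped variant by its proxy's record from ``pool``.

    The replacement record is annotated with ``proxy_for=<target id>``.
    A proxy id absent from the pool leaves the original in place with a
    warning.
    """
    pool_by_id: Mapping[str, HarmonizedVariant] = {p.variant_id: p for p in pool}
    out: list[HarmonizedVariant] = []
    for v in variants:
        proxy_id = proxies.entries.get(v.variant_id)
        if proxy_id is None:
            out.append(v)
            continue
        proxy = pool_by_id.get(proxy_id)
        if proxy is None:
            logger.warning(
                "proxy %s for %s absent from pool; original retained", proxy_id, v.variant_id
            )
            out.append(v)
            continue
        out.append(dataclasses.replace(proxy, proxy_for=v.variant_id))
    return out
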