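"""One-shot pipeline runner: harmonize -> filter -> select -> PAR ->
fine-map -> rank, with a JSON manifest of what was done.

Each stage writes its table to the output directory; the manifest records
input files, the effective configuration and its hash, and per-stage row
counts, so a rerun on identical inputs and configuration is verifiable
byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import io as gio
from .finemap import FineMapConfig, finemap_locus
from .harmonize import harmonize_stratum
from .par import par_for_variants
from .ranking import build_comparison, classify_loci, rank_within_ancestry
from .records import HarmonizedVariant, LocusBlock, PAREstimate
from .selection import ProxyMap, apply_proxies, filter_significant, select_lead_per_locus

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; mirrors the CLI flags."""

    inputs: dict[str, str]  # ancestry label -> summary-statistics path
    out_dir: str
    alpha: float = 0.05
    proxy_map: Optional[str] = None
    prior_sd: float = 0.2
    pp_threshold: float = 0.80
    top_k: int = 10
    min_ancestries: Optional[int] = None
    column_map: Optional[dict[str, str]] = None
    log_level: str = "INFO"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        return cls(**{k: v for k, v in d.items() if k in known})

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _config_hash(cfg: PipelineConfig, input_digests: dict[str, str]) -> str:
    payload = json.dumps(
        {"config": cfg.to_dict(), "inputs": input_digests}, sort_keys=True
    ).encode()
    return hashlib.sha256(payload).hexdigest()


def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages in order; returns the manifest (also written to
    ``manifest.json`` in the output directory)."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # canonical ancestry order (sorted labels) so reruns are byte-identical
    # regardless of how the config serialized its mapping
    inputs = dict(sorted(cfg.inputs.items()))
    strata = {
        label: gio.read_sumstats(path, label, column_map=cfg.column_map)
        for label, path in inputs.items()
    }
    counts: dict[str, int] = {"input": sum(len(s) for s in strata.values())}

    # harmonize
    harmonized: dict[str, list[HarmonizedVariant]] = {
        label: harmonize_stratum(s) for label, s in strata.items()
    }
    all_harmonized = [v for vs in harmonized.values() for v in vs]
    gio.write_records(all_harmonized, HarmonizedVariant, out / "harmonized.tsv")
    counts["harmonized"] = len(all_harmonized)

    # filter
    filtered = {label: filter_significant(vs, cfg.alpha) for label, vs in harmonized.items()}
    all_filtered = [v for vs in filtered.values() for v in vs]
    gio.write_records(all_filtered, HarmonizedVariant, out / "filtered.tsv")
    counts["filtered"] = len(all_filtered)

    # select lead per locus (per ancestry), then proxies
    proxies = ProxyMap.from_file(cfg.proxy_map) if cfg.proxy_map else ProxyMap()
    selected: dict[str, list[HarmonizedVariant]] = {}
    for label, vs in filtered.items():
        leads = select_lead_per_locus(vs)
        selected[label] = apply_proxies(leads, proxies, harmonized[label])
    all_selected = [v for vs in selected.values() for v in vs]
    gio.write_records(all_selected, HarmonizedVariant, out / "selected.tsv")
    counts["selected"] = len(all_selected)

    # PAR
    estimates = {label: par_for_variants(vs) for label, vs in selected.items()}
    all_estimates = [e for es in estimates.values() for e in es]
    gio.write_records(all_estimates, PAREstimate, out / "par.tsv")
    counts["par"] = len(all_estimates)

    # fine-map every locus with members in the filtered set
    fm_cfg = FineMapConfig(prior_sd=cfg.prior_sd, pp_threshold=cfg.pp_threshold)
    fm_rows = []
    for label, vs in filtered.items():
        by_locus: dict[str, list[HarmonizedVariant]] = {}
        for v in vs:
            by_locus.setdefault(v.locus, []).append(v)
        for locus in sorted(by_locus):
            res = finemap_locus(LocusBlock(locus=locus, variants=by_locus[locus]), fm_cfg)
            cs = set(res.credible_set_95)
            for vid, pip, high in zip(res.variant_ids, res.pip, res.high_confidence):
                fm_rows.append(
                    {
                        "locus": locus,
                        "ancestry": label,
                        "variant_id": vid,
                        "pip": gio.FLOAT_FORMAT % pip,
                        "in_credible_set_95": vid in cs,
                        "high_confidence": high,
                    }
                )
    pd.DataFrame(
        fm_rows,
        columns=["locus", "ancestry", "variant_id", "pip", "in_credible_set_95", "high_confidence"],
    ).to_csv(out / "finemap.tsv", sep="\t", index=False)
    counts["finemap"] = len(fm_rows)

    # rank + cross-ancestry comparison + classification
    ranked = {label: rank_within_ancestry(es) for label, es in estimates.items()}
    all_ranked = [e for es in ranked.values() for e in es]
    gio.write_records(all_ranked, PAREstimate, out / "ranked.tsv")
    cmp = build_comparison(ranked)
    long = cmp.to_long()
    long["par"] = long["par"].map(lambda x: gio.FLOAT_FORMAT % x)
    long.to_csv(out / "ranks.tsv", sep="\t", index=False)
    counts["ranks"] = len(long)

    labels = classify_loci(cmp, top_k=cfg.top_k, min_ancestries=cfg.min_ancestries)
    pd.DataFrame(
        [{"locus": l, "classification": c} for l, c in labels.items()],
        columns=["locus", "classification"],
    ).to_csv(out / "classification.tsv", sep="\t", index=False)
    counts["classification"] = len(labels)

    input_digests = {label: _digest(path) for label, path in inputs.items()}
    manifest = {
        "inputs": {label: str(path) for label, path in inputs.items()},
        "input_sha256": input_digests,
        "config": cfg.to_dict(),
        "config_hash": _config_hash(cfg, input_digests),
        "row_counts": counts,
        "artifacts": [
            "harmonized.tsv", "filtered.tsv", "selected.tsv", "par.tsv",
            "finemap.tsv", "ranked.tsv", "ranks.tsv", "classification.tsv",
        ],
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
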