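"""Generate the static 4-ancestry, 3-locus test fixture (run once; outputs frozen)."""
from pathlib import Path

import gwaspar as g
from gwaspar import io as gio

OUT = Path(__file__).resolve().parent.parent / "tests" / "data" / "fixture"
OUT.mkdir(parents=True, exist_ok=True)

cfg = g.SimulationConfig(
    seed=20240917,
    ancestries=[
        g.AncestrySpec("EUR", 20000, 20000),
        g.AncestrySpec("AFR", 5000, 8000),
        g.AncestrySpec("EAS", 8000, 10000),
        g.AncestrySpec("AMR", 4000, 6000),
    ],
    loci=[
        g.LocusSpec("APOE", n_variants=4, causal_index=1,
                    true_or={"EUR": 2.6, "AFR": 2.2, "EAS": 2.9, "AMR": 1.9},
                    true_raf={"EUR": 0.15, "AFR": 0.21, "EAS": 0.10, "AMR": 0.12},
                    ld_rho=0.6),
        g.LocusSpec("PICALM", n_variants=3, causal_index=0,
                    true_or=1.18, true_raf={"EUR": 0.36, "AFR": 0.30, "EAS": 0.44, "AMR": 0.33},
                    ld_rho=0.5),
        g.LocusSpec("GBA1", n_variants=1, causal_index=0,
                    true_or={"EUR": 1.10, "AFR": 1.55, "EAS": 1.08, "AMR": 1.0},
                    true_raf={"EUR": 0.02, "AFR": 0.07, "EAS": 0.03, "AMR": 0.04}),
    ],
    protective_fraction=0.3,
)
strata, truth = g.simulate_study(cfg)
for label, stratum in strata.items():
    gio.write_table(stratum.variants, OUT / f"{label}.tsv")
truth.to_csv(OUT / "truth.tsv", sep="\t", index=False, float_format=gio.FLOAT_FORMAT)
print("written to", OUT)
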