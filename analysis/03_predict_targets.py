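#!/usr/bin/env python
"""Scan expressed guides against the transcriptome with the tier rules."""

import argparse
from pathlib import Path

import numpy as np

from pirslice import io as pio
from pirslice import pipeline as pl
from pirslice.simulate import demo_config, simulate_all

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=42)
ap.add_argument("--outdir", type=str, default="results")
args = ap.parse_args()

out = Path(args.outdir) / "03_pairing"
out.mkdir(parents=True, exist_ok=True)

study = simulate_all(demo_config(args.seed))
sr = pl.smallrna_stage(study, np.random.default_rng(args.seed + 1))
pr = pl.pairing_stage(study, sr["expressed"], sr["ablated_flag"])
pio.write_tsv(out / "pairing_hits.tsv", pr["hits"])
tiers = pr["hits"]["tier"].value_counts().to_dict()
pio.write_json(out / "tier_counts.json", tiers)
print(f"{len(pr['hits'])} qualifying sites ({tiers}) -> {out}")
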