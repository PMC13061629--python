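#!/usr/bin/env python
"""Generate the synthetic study for a seed and write its raw artefacts."""

import argparse
from pathlib import Path

from pirslice import io as pio
from pirslice.simulate import demo_config, simulate_all

ap = argparse.ArgumentParser(description=__doc__)
ap.add_argument("--seed", type=int, default=42)
ap.add_argument("--outdir", type=str, default="results")
args = ap.parse_args()

out = Path(args.outdir) / "01_simulation"
out.mkdir(parents=True, exist_ok=True)

study = simulate_all(demo_config(args.seed))
pio.write_fasta(out / "transcripts.fa", study.transcriptome.sequences)
pio.write_tsv(out / "pirna_pool.tsv", study.pool.species)
pio.write_tsv(out / "pirna_ppm.tsv", study.pool.ppm, index=True)
pio.write_tsv(out / "truth_sites.tsv", study.truth.sites)
pio.write_tsv(out / "degradome_ends.tsv", study.degradome)
pio.write_tsv(out / "counts.tsv", study.expression["counts"], index=True)
pio.write_bed(out / "pirna_origins.bed", study.annotation["origins"])
print(f"study (seed {args.seed}) written to {out}")
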