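"""Run the full pipeline end to end and write a deterministic result bundle.

Equivalent to `abrkit run --seed 17 --out demo_out/`: synthesize the demo
cohort, preprocess every condition, measure monaural waves, audiograms and
DN1-vs-ITD series, run the statistics layer, and write CSV tables plus a
provenance log whose hashes are identical across reruns.
"""
from pathlib import Path

from abrkit import RunConfig, run_pipeline

out = Path("scratch/demo_out")
bundle = run_pipeline(RunConfig(), seed=17, out_dir=out)

print(f"tables written to {out}/:")
for name, table in sorted(bundle.tables.items()):
    print(f"  {name}.csv  ({len(table)} rows)")
print("\nbic_series head:")
print(bundle.tables["bic_series"].head(5).to_string(index=False))
print("\nRe-running with the same config and seed reproduces every file hash:")
print({k: v[:12] for k, v in sorted(bundle.hashes.items())})
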