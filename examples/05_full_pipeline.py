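"""Run the whole pipeline (simulate -> ... -> report) from a config dict.

Equivalent to: cutcoord all --config cfg.yaml --outdir out
"""

from pathlib import Path

from cutcoord.pipeline import run_pipeline

config = {
    "seed": 4,
    "dataset": {"n_subjects": 3, "cycles_per_subject": 3},
    "stats": {"n_perm": 200, "alpha": 0.05},
    "train": {"epochs": 5, "plateau_patience": None},
}

outdir = Path("scratch") / "pipeline_demo"
manifest = run_pipeline(config, outdir=outdir)
for stage, seconds in manifest.stages.items():
    print(f"{stage:<12} {seconds:6.1f}s  "
          f"{len(manifest.outputs.get(stage, []))} outputs")
print(f"\nreport: {outdir / 'report.md'}")
print((outdir / "report.md").read_text()[:600])
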