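"""Full post-processing run on a synthetic dual-tracer labeling experiment.

Simulates a feature table for the default two-compound panel (a glutamine-
like metabolite under 13C+15N tracing and a PC(36:4)-like lipid), then runs
match -> NA-correct -> metrics -> cluster -> export and prints the
recovered labeling time course.
"""

import tempfile
from pathlib import Path

from isoscope import RunConfig, run_pipeline
from isoscope.chem import TRACER_13C, TRACER_15N
from isoscope.export import read_table
from isoscope.synthetic import default_panel, emit_feature_table

workdir = Path(tempfile.mkdtemp(prefix="isoscope_demo_"))
data = emit_feature_table(
    default_panel(),
    {"glutamine": [TRACER_13C, TRACER_15N], "PC(36:4)": [TRACER_13C]},
    times_h=(0, 2, 4, 8),
    replicates=3,
    seed=0,
)
data["features"].to_csv(workdir / "features.csv", index=False)
data["metadata"].to_csv(workdir / "metadata.csv", index=False)
data["compound_db"].to_csv(workdir / "compounds.csv", index=False)

out = run_pipeline(
    RunConfig(
        features_path=str(workdir / "features.csv"),
        compound_db_path=str(workdir / "compounds.csv"),
        metadata_path=str(workdir / "metadata.csv"),
        output_dir=str(workdir / "out"),
        seed=0,
    )
)
print(f"outputs in {out}\n")

summary = read_table(out / "metrics_summary.csv")
gln = summary[
    (summary["compound"] == "glutamine") & (summary["metric"] == "nmol_labeled")
]
print("glutamine: nmol labeled product formed (mean +/- SD over 3 replicates)")
for _, row in gln.iterrows():
    print(f"  t = {row['time_h']:>3.0f} h: {row['mean']:6.2f} +/- {row['std']:.2f} nmol")
print("\n(the pool is 50 nmol with asymptotic labeled fraction 0.7 and rate "
      "0.4/h, so the curve approaches 35 nmol)")
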