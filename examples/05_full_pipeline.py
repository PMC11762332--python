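"""Run the whole chain with one call and read the generated report.

simulate -> extract -> evaluate -> contribute -> report, all driven by a
single config and master seed.  A reduced cohort (6 + 6 subjects, 3
laps) keeps this example quick; drop the overrides for the full default
protocol.  Equivalent shell command:

    drivecog run --config my_config.yaml
"""

import tempfile
import warnings
from pathlib import Path

from drivecog.pipeline import PipelineConfig, run_pipeline
from drivecog.synthetic import CircuitConfig, CohortConfig

out = Path(tempfile.mkdtemp()) / "demo_run"
config = PipelineConfig(
    out_dir=str(out),
    seed=7,
    cohort=CohortConfig(n_healthy=6, n_mci=6, circuit=CircuitConfig(laps=3)),
    k=2,
    # QDA needs more than 5 training subjects per class for a full-rank
    # class covariance on 5 PCA scores; the demo cohort is too small
    models=("KNN", "LogisticRegression", "RandomForest", "SVM"),
)
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    run_dir = run_pipeline(config)

print(f"artifacts in {run_dir}:")
for p in sorted(run_dir.rglob("*")):
    if p.is_file():
        print(f"  {p.relative_to(run_dir)}")
print("\n--- report.md ---\n")
print((run_dir / "report.md").read_text())
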