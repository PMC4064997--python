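"""Run the whole profiling pipeline from files to artifacts.

Simulates a screen, writes the matrix and labels to disk, then runs the
chained pipeline (matrix load -> assay filter -> relevance ranking ->
panel selection -> S scoring) and prints the provenance manifest.
"""
import json
import logging
import tempfile
from pathlib import Path

from toxprofile import (
    RunConfig,
    SyntheticSpec,
    run_pipeline,
    simulate,
    write_labels,
    write_matrix,
)

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

with tempfile.TemporaryDirectory() as tmp:
    tmp = Path(tmp)
    matrix, truth = simulate(SyntheticSpec(n_compounds=500, n_assays=60,
                                           n_relevant_assays=8, seed=123))
    write_matrix(matrix, tmp / "matrix.tsv")
    write_labels(truth.labels, tmp / "labels.tsv")

    config = RunConfig(
        labels=tmp / "labels.tsv",
        matrix=tmp / "matrix.tsv",
        out_dir=tmp / "out",
        seed=123,
    )
    artifacts = run_pipeline(config)

    print("\nArtifacts written:")
    for name, path in artifacts.items():
        print(f"  {name}: {path.name}")
    manifest = json.loads(artifacts["manifest"].read_text())
    print("\nManifest (parameters + run summary):")
    print(json.dumps(manifest, indent=2))
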