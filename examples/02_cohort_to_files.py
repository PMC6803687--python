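"""Generate a small cohort on disk and read it back.

Writes the canonical file layout — one whitespace-delimited T x K node
time-series text file per subject, a phenotype CSV, a manifest and the fully
echoed cohort configuration — into ./example_cohort, then parses one file.
"""

import dynconn as dc
from dynconn.io import read_node_timeseries

config = dc.CohortConfig(n_subjects=4, n_nodes=6, n_runs=2, run_length=300, seed=11)
manifest = dc.write_cohort(config, "example_cohort")
print(manifest.to_string(index=False))

first = manifest.iloc[0]
ts = read_node_timeseries(
    "example_cohort/" + first["path"], n_runs=config.n_runs, subject_id=first["subject_id"]
)
print(f"{ts.subject_id}: {ts.n_timepoints} timepoints x {ts.n_nodes} nodes, "
      f"runs start at {ts.run_boundaries}")
print("Phenotypes include the five NEO-FFI traits plus age, sex, education, "
      "handedness, intelligence and head-motion RMS.")
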