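"""End-to-end pipeline on a small cohort (2 feet, coarse settings).

Generates the cohort, solves preop + MDCO at 4/8/12 mm for each foot,
measures morphometry, scores regions, and writes the comparison tables,
the validation CCC table and the run manifest.  With only two feet the
statistics are illustrative; the full study profile uses 8 feet.

Expect a few minutes of runtime.
"""

from pedfem.pipeline import RunConfig, run_cohort
from pedfem.fem import SolverOptions

config = RunConfig(
    cohort_size=2,
    base_seed=1,
    out_dir="scratch_cohort_run",
    solver=SolverOptions(rtol=1e-3, increments=3, max_iter=50),
)
manifest = run_cohort(config)
print("config hash:", manifest.config_hash)
for entry in manifest.models:
    print(f"model {entry['model']}: severity {entry['severity']}, "
          f"solves: { {k: v['converged'] for k, v in entry['solves'].items()} }")
print("tables:", *manifest.files, sep="\n  ")
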