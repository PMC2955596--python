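"""Generate a synthetic amputee cohort and run the full scoring pipeline.

Simulates 200 participants (prosthesis walkers, walking-aid users,
wheelchair users) with raw scores on each instrument's native scale and
configurable negative-modulator prevalences, writes the cohort CSV, then
scores it: dichotomization, weighted composites, categories and profile
groups.
"""

import tempfile
from pathlib import Path

from mobscore import CohortConfig, run_score, run_simulate

workdir = Path(tempfile.mkdtemp(prefix="mobscore_"))

config = CohortConfig(n_participants=200, seed=42)
cohort_path, sim_manifest = run_simulate(config, workdir / "sim")
print(f"wrote {cohort_path} (seed={sim_manifest.seed}, "
      f"n={sim_manifest.n_read})")

profiles, summary, manifest = run_score(cohort_path, workdir / "scored")
print(f"scored {manifest.n_scored}/{manifest.n_read} participants "
      f"({manifest.n_excluded} excluded)")
print("group sizes:", {g.value: n for g, n in summary.group_sizes.items()})
for dim, counts in summary.category_counts.items():
    print(f"{dim.value:>10}:", {c.value: n for c, n in counts.items()})

# scores_long.csv holds one row per participant-dimension (weighted score
# and category) — the table behind a per-participant profile chart.
print("\noutputs in", workdir / "scored")
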