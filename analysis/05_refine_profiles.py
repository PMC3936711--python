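"""Build and refine a scoring profile for a synthetic novel family.

Length-filters the seed set, runs the recruit-above-worst-seed refinement
against a database containing three near-duplicate true members and fifty
decoys, and records the gathering/trusted/noise cutoffs.  Writes
results/profile.json.
"""

import sys
from pathlib import Path

from casforge.profile_refinement import drop_length_outliers, refine_profile
from casforge.synthetic_data import make_refinement_scenario

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1

seeds, database, members = make_refinement_scenario(seed=SEED)
seeds = drop_length_outliers(seeds)
profile = refine_profile(seeds, database)
Path("results").mkdir(exist_ok=True)
profile.to_json("results/profile.json")

recruited = set(profile.seed_ids) - set(seeds)
print(f"{profile.n_iterations} iterations; recruited "
      f"{len(members & recruited)}/{len(members)} held-out members and "
      f"{sum(r.startswith('decoy') for r in recruited)} decoys; "
      f"gathering=trusted={profile.gathering_cutoff:.1f} bits, "
      f"noise={profile.noise_cutoff:.1f} bits")
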