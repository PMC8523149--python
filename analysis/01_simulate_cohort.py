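#!/usr/bin/env python
"""Generate the demonstration cohort: 4 animals (2 D1-like, 2 D2-like),
3 sessions each (saline, first and second cocaine), 24 neurons per animal,
with responder fractions rising over days and known ground truth.

Bulk outputs (traces, centroid tracks, photometry) go to scratch/cohort/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from spnsens.synth import SynthConfig, gen_cohort

cfg = SynthConfig(
    out_dir="scratch/cohort",
    seed=2024,
    n_neurons=24,
    n_animals_per_class=2,
    responder_fractions=(0.05, 0.25, 0.45),
)
path, truth = gen_cohort(cfg)
n_sessions = len(cfg.days) * 2 * cfg.n_animals_per_class
print(f"cohort written to {path}: {n_sessions} sessions, "
      f"{cfg.n_neurons} neurons each, seed {cfg.seed}")
print(f"designed responder fractions per day: {cfg.responder_fractions}")
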