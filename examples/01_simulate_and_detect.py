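"""Simulate a small cohort with planted A-to-I edits and run detection.

Builds a 190 kb toy genome with 8 genes and Alu/LINE repeats, plants 60
editing sites at known per-sample ratios plus 10 known SNPs, writes
single-end alignments for 8 samples, then runs the full filter cascade
(region rules, known-variant exclusion, dual-aligner concordance,
read-evidence criteria) and scores the calls against the truth set.
"""

import tempfile
from pathlib import Path

from editome.pipeline import detect_study, score_detection
from editome.simulate import SimConfig, simulate_study

with tempfile.TemporaryDirectory() as tmp:
    study = simulate_study(SimConfig(seed=42, n_samples=8), Path(tmp))
    detection = detect_study(study)
    score = score_detection(detection, study, min_ratio=0.2)

    sample = study.cohort.samples[0]
    print("per-stage funnel for sample", sample)
    print(detection.funnels[sample].to_tsv())
    print(f"called events (all samples): {len(detection.events)}")
    print(f"site-level sensitivity (true ratio >= 0.2): "
          f"{score.sensitivity_high_ratio:.3f}")
    print(f"planted SNPs surviving the cascade:  {score.surviving_snps}")
    print(f"region decoys surviving the cascade: {score.surviving_decoys}")

# The funnel shows how many candidate mismatches each filter removes.
# Sensitivity near 1 with zero surviving SNPs/decoys means the cascade
# keeps real edits while the database and region rules absorb the traps.
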