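"""Compare tDR length and arm structure between WT and RNaseT2-mutant-like
libraries.

The mutant condition scales the tRNA class up 2.5x and moves 60% of tDR
mass into 31-36 nt 5' halves, emulating the loss of tRNA-half processing.
The script prints the 5' arm percentage and the >30 nt (tRNA-half) fraction
for both conditions, plus a per-nucleotide coverage comparison for the
Gly-GCC isoacceptor.
"""

from tdrprof.classify import sequential_classify
from tdrprof.stattests import depth_profile_test
from tdrprof.synthetic import (
    RNST2_MUTANT_EFFECT,
    WT_EFFECT,
    demo_bundle,
    male_library_spec,
    simulate_library,
)
from tdrprof.tdr_metrics import arm_summary, build_profiles, isoacceptor_rollup

bundle = demo_bundle()
models = bundle.trna_by_name()

profiles = {}
for effect in (WT_EFFECT, RNST2_MUTANT_EFFECT):
    reads, _ = simulate_library(male_library_spec(20_000, seed=7), effect, bundle=bundle)
    assignments = sequential_classify(reads, bundle)
    reads_by_id = {r.read_id: r for r in reads}
    arms = arm_summary(assignments, models)
    per_trna = build_profiles(assignments, reads_by_id, models)
    rolled = isoacceptor_rollup(per_trna)
    long_total = sum(p.long_count for p in per_trna.values())
    total = sum(p.total for p in per_trna.values())
    print(
        f"{effect.label:<14} 5' tDRs: {arms.five_prime_pct:5.1f}%   "
        f">30 nt (halves): {100 * long_total / total:5.1f}% of tDRs"
    )
    profiles[effect.label] = rolled["Gly-GCC"]["depth"]

res = depth_profile_test(
    profiles["WT"], profiles["rnst2_mutant"], lib_size_a=20_000, lib_size_b=20_000
)
print(
    f"\nGly-GCC per-nucleotide depth, WT vs mutant (Welch's t over positions): "
    f"t = {res.statistic:.1f}, p = {res.p_value:.2e}"
)
# The mutant library shows a higher 5' fraction and a large jump in >30 nt
# tDRs; the depth comparison registers the genome-wide abundance gain of
# Gly-GCC fragments as a highly significant location shift.
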