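"""Compare segmentation methods across a severe scanner gap.

Trains on scanner A, tests on scanner B (direction AB) and also runs the
same-scanner reference (direction AA).  Without the FST the appearance
features mislead the classifier; with it, most of the same-scanner
performance is recovered.
"""

import fstseg

study = fstseg.generate_study(fstseg.StudyConfig(), master_seed=1)
result = fstseg.run_comparison(
    study,
    ["atlas_mv", "svm_atlas", "svm", "svm_fst"],
    directions=("AB", "AA"),
)
print(result.format_table())
print()
print("Mean Dice per method; *...* marks the best method and any method not")
print("significantly worse (signed-rank, alpha 0.05).  AB = cross-scanner,")
print("AA = same-scanner reference.")
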