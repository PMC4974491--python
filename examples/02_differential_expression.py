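"""Moderated differential expression along the time course.

Preprocesses the simulated dataset (detection filter, quantile normalization)
and counts differentially expressed probes (BH q < 0.05) for each
IFN-vs-no-IFN contrast at every timepoint, reproducing the study's DE-count
kinetics: an early IFN-alpha burst peaking at 6 h versus a gradually growing
IFN-gamma response.
"""

from ascnet import (
    de_counts,
    filter_undetected,
    moderated_t,
    quantile_normalize,
    simulate_timecourse,
    study_default_config,
)

x, det, _ = simulate_timecourse(study_default_config(seed=0))
xq = quantile_normalize(filter_undetected(x, det))
print(f"{len(xq.probes)} probes survive the detection filter")

results = [
    moderated_t(xq, (trt, "none"), tp)
    for trt in ("ifn_alpha", "ifn_gamma")
    for tp in xq.timepoints
]
table = de_counts(results, fdr=0.05)
wide = table.pivot(index="timepoint", columns="contrast", values="count")
print("\nDE probes (q < 0.05) per timepoint:")
print(wide.to_string())
print(
    "\n-> the IFN-alpha response peaks at "
    f"{wide['ifn_alpha_vs_none'].idxmax():g} h and plateaus, while the "
    "IFN-gamma response keeps growing over the 96 h course."
)
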