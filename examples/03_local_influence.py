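"""Case-weight local influence: curvatures for the three perturbation schemes.

Contaminates a simulated cohort with two influential patients (extreme
tumor-size values plus an implausibly fast relapse), then shows how the
conformal normal curvature flags them, and how truncating the covariate
(the 80-mm-style recode) makes the model more robust.
"""

import numpy as np

import msinfluence as mi

data, _ = mi.simulate_cohort(mi.SimulationConfig(n=300, seed=3))
contaminated, ids = mi.inject_outliers(data, mi.Contamination(), seed=4)
print(f"injected outliers: {ids}")

fitted = mi.fit(contaminated)
for build, what in ((mi.delta_scheme1, "(transition, patient) records"),
                    (mi.delta_scheme2, "transitions"),
                    (mi.delta_scheme3, "patients")):
    res = mi.curvature_matrix(fitted, build(fitted))
    flagged = mi.flag_influential(res)
    print(f"\n{res.scheme.name}: r = {res.scheme.r} {what}")
    print(f"  cutoff mean+2sd = {res.cutoff:.5f}; flagged: "
          f"{flagged[:6]}{' ...' if len(flagged) > 6 else ''}")

res = mi.curvature_matrix(fitted, mi.delta_scheme3(fitted))
labels = list(res.scheme.labels)
print("\noutlier curvatures before truncation:",
      {i: float(round(res.B_i[labels.index(i)], 4)) for i in ids})

truncated = mi.truncate_covariate(contaminated, "size", 80.0)
ft = mi.fit(truncated)
rt = mi.curvature_matrix(ft, mi.delta_scheme3(ft))
labels_t = list(rt.scheme.labels)
print("outlier curvatures after 80-mm recode: ",
      {i: float(round(rt.B_i[labels_t.index(i)], 4)) for i in ids})
print("\nB_i above the dashed mean+2sd cutoff marks a potentially "
      "influential unit; capping the extreme covariate shrinks the "
      "outliers' leverage, i.e. the recoded model is more robust.")
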