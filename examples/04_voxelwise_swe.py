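"""Voxel-wise marginal-model (sandwich estimator) analysis of Jacobian maps
with wild-bootstrap cluster-extent FWE correction.

A group-by-time effect (-5% log-Jacobian per year in patients) is injected
into a 3x3x3-voxel region of a 16^3 grid; the analysis should recover one
large FWE-significant cluster there and nothing elsewhere.
"""
import numpy as np

import longimorph as lm
from longimorph.cohort import CohortDesign

design = CohortDesign(
    n_wolfram=10, n_control=10,
    visit_count_probs={"wolfram": [0, 0, 1.0, 0, 0, 0, 0], "control": [0, 0, 1.0]},
)
cohort = lm.generate_cohort(design, seed=3)

shape = (16, 16, 16)
mask = lm.ellipsoid_mask(shape)
cluster = np.zeros(shape, bool)
cluster[7:10, 7:10, 7:10] = True
effect = lm.TBMEffect(cluster=cluster, slope={"wolfram": -0.05, "control": 0.0})
stack = lm.simulate_tbm_stack(cohort, shape=shape, mask=mask, effect=effect,
                              noise_sd=0.02, seed=3)

vd = lm.build_design(stack, covariates=("group", "time"),
                     interactions=("group:time",),
                     participants=cohort.participants, variant="to_midpoint")
ct = lm.wild_bootstrap_fwe(stack, vd, "group:time", n_bootstrap=199,
                           cluster_forming_p=0.001, seed=3)
print(ct.table.round(4).to_string(index=False))

# Interpretation: the top cluster should sit at the injected location
# (peak near voxel 8,8,8) with fwe_p at or near the attainable floor
# 1/(B+1) = 0.005; any other clusters should have fwe_p >> 0.05.
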