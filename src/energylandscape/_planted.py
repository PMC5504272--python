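"""Frozen planted MEM parameters for the synthetic cohort generator.

Two parameter sets over the seven canonical networks (DMN, FPN, SAN, ATN,
SMN, AUD, VIS; this order defines the pattern-code bit order) whose energy
landscapes share the same six local minima:

* two 'major' minima pairs -- codes {56, 62} and {65, 71}, funnels around
  the anticorrelated DMN/VIS-vs-rest activation patterns;
* two 'minor' minima -- codes 49 (DMN/SMN/AUD active) and 78 (its
  complement), the intermediate state.

The TD-like set has deep minor basins (12/128 patterns each); the ASD-like
set raises the minor funnel and trims the minor basins to 3/128 while
keeping all six minima strictly stable, so the intermediate state is
visited far less often.  The sets were calibrated once (multi-funnel
target energies projected onto the pairwise form; a minimal-L1 linear
program shapes the ASD-like minor basins; a global inverse-temperature
factor matches the two groups' direct-transition rates) and are shipped
frozen so every synthetic cohort draws from exactly the same study
conditions.
"""

import numpy as np

__all__ = ["H_TD", "J_TD", "H_ASD", "J_ASD", "PLANTED_MINIMA", "PLANTED_GROUPING"]

#: the six local minima shared by both planted landscapes
PLANTED_MINIMA = (49, 56, 62, 65, 71, 78)

#: ground-truth state assignment of the planted minima
PLANTED_GROUPING = {
    56: "major1", 62: "major1",
    65: "major2", 71: "major2",
    49: "minor1", 78: "minor2",
}


H_TD = np.array([-1.1908449322445444e-16, -1.1591206798995148e-17, -3.0044327774698433e-17, -3.054306077404176e-17, 7.541460195712765e-17, 6.062171752610879e-17, -1.385332711126618e-16])

J_TD = np.array([[0.0, -0.05390624999999994, -0.05390625000000019, -0.4585625, -0.10781249999999995, -0.10781249999999987, 0.06325000000000017], [-0.05390624999999994, 0.0, 0.5210937500000001, 0.09846874999999994, -0.035937500000000115, -0.035937500000000004, 0.03593750000000009], [-0.05390625000000019, 0.5210937500000001, 0.0, 0.053906250000000086, -0.03593750000000005, -0.03593750000000002, 0.03593750000000006], [-0.4585625, 0.09846874999999994, 0.053906250000000086, 0.0, 0.1078125, 0.1078124999999999, -0.10781250000000007], [-0.10781249999999995, -0.035937500000000115, -0.03593750000000005, 0.1078125, 0.0, 0.26953125, -0.26953125000000017], [-0.10781249999999987, -0.035937500000000004, -0.03593750000000002, 0.1078124999999999, 0.26953125, 0.0, -0.26953124999999994], [0.06325000000000017, 0.03593750000000009, 0.03593750000000006, -0.10781250000000007, -0.26953125000000017, -0.26953124999999994, 0.0]])

H_ASD = np.array([3.252643236733594e-17, -5.2302289147400164e-17, 1.0506423517800838e-16, -1.9001764909650894e-16, 4.063400292232856e-17, 9.188888274999846e-17, -9.486649721379433e-17])

J_ASD = np.array([[0.0, -0.004531250000000003, -0.004531250000000091, -0.6932812499999998, -0.12234375000000021, -0.10421875000000012, 0.2582812499999998], [-0.004531250000000003, 0.0, 0.7204687500000003, 0.0045312500000001575, -0.0045312500000001255, -0.004531249999999996, 0.00453125000000005], [-0.004531250000000091, 0.7204687500000003, 0.0, 0.12234375000000007, -0.004531250000000069, -0.004531249999999984, 0.004531249999999865], [-0.6932812499999998, 0.0045312500000001575, 0.12234375000000007, 0.0, 0.2401562500000001, 0.25828125, -0.10421874999999985], [-0.12234375000000021, -0.0045312500000001255, -0.004531250000000069, 0.2401562500000001, 0.0, 0.28546875000000016, -0.28546874999999994], [-0.10421875000000012, -0.004531249999999996, -0.004531249999999984, 0.25828125, 0.28546875000000016, 0.0, -0.28546874999999994], [0.2582812499999998, 0.00453125000000005, 0.004531249999999865, -0.10421874999999985, -0.28546874999999994, -0.28546874999999994, 0.0]])
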