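"""From raw triplicate C_T wells to normalised relative quantities (NRQ).

Runs the full RQ-PCR processing chain on a small synthetic validation run:
triplicate aggregation with the 0.28-cycle SD gate and single-outlier
rescue, inter-plate calibration against the IAC, then comparative-ΔCT
quantification scaled to the lowest-expressing sample and normalised to
miR-16.
"""

from collections import Counter

from circmir import (CohortSpec, aggregate_triplicates, calibrate_interplate,
                     compute_expression, generate_triplicate_plates)

panel = ["miR-29a", "miR-181a", "miR-16"]
spec = CohortSpec(n_cases=8, n_controls=8, n_probes=3, probe_ids=tuple(panel),
                  planted_probe_ids=frozenset(panel[:2]), delta_ct_shift=1.0,
                  seed=9)
sheet, ct = generate_triplicate_plates(spec, panel)

summaries = aggregate_triplicates(ct)
print("QC flags:", dict(Counter(s.qc_flag for s in summaries)))

calibrated = calibrate_interplate(summaries)
expression = compute_expression(calibrated)
print(f"\nNRQ table ({len(expression.sample_ids)} samples):")
print(expression.nrq.head(6).round(3).to_string())

import numpy as np

log_nrq = np.log2(expression.nrq["miR-29a"])
case_gm = 2 ** log_nrq.filter(like="vcase").mean()
ctrl_gm = 2 ** log_nrq.filter(like="vctrl").mean()
print(f"\nmiR-29a geometric-mean NRQ: cases {case_gm:.2f} vs controls {ctrl_gm:.2f} "
      f"(ratio {case_gm / ctrl_gm:.2f})")
print("the 1-cycle planted shift roughly halves case expression (expected")
print("ratio 2^-1 = 0.5 up to biological noise at n = 8 per group); the")
print("reference column miR-16 is identically 1 by construction.")
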