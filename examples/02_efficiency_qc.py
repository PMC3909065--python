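"""Amplification-efficiency QC from a 10-fold dilution series.

A five-point series is regressed as C_T against log10 input; the slope maps
to efficiency via E = (10^(-1/slope) - 1) x 100. Perfect doubling gives a
slope of -3.32 cycles per decade and E = 100%; assays outside 90-110% fail
the gate and should not be quantified by the assumed-doubling ΔCT method.
"""

from circmir import compute_efficiency, generate_dilution_series

for true_eff, noise in ((100.0, 0.0), (93.07, 0.0), (121.2, 0.0), (98.0, 0.15)):
    series = generate_dilution_series(true_eff, n_points=5, top_ct=20.0,
                                      noise_sd=noise, seed=3)
    res = compute_efficiency(series)
    verdict = "accepted" if res.accepted else "REJECTED"
    print(f"true E = {true_eff:6.2f}%  noise = {noise:4.2f} cycles -> "
          f"slope {res.slope:7.4f}, estimated E = {res.efficiency_pct:6.2f}%  {verdict}")

print("\nThe noise-free estimates recover the true efficiency exactly; with")
print("0.15-cycle noise the estimate moves by a few percent, which is why the")
print("acceptance window is +/-10% rather than a point value.")
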