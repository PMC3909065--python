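"""Combine three modest single markers into a logistic biomarker panel.

Reproduces the panel-evaluation regime on synthetic data: three planted
miRNAs, each with single-miRNA AUC around 0.65-0.70 after ΔCT processing of
a 44-case / 46-control triplicate cohort, are combined by binary logistic
regression on log10 NRQ and scored by the in-sample ROC at the Youden
operating point.
"""

from circmir.experiments import panel_regime_experiment

res = panel_regime_experiment(seed=1)
print("single-miRNA AUCs:")
for m, auc in res.single_aucs.items():
    print(f"  {m:<10} {auc:.3f}")
print(f"\n3-miRNA logistic panel: AUC {res.panel_auc:.3f}, "
      f"sensitivity {100 * res.sensitivity:.0f}%, "
      f"specificity {100 * res.specificity:.0f}% "
      f"({res.n_cases} cases / {res.n_controls} controls)")
print("\nNo single marker is clinically useful on its own, but three")
print("independent ~0.67-AUC markers combine to ~0.8 — the regime in which")
print("circulating miRNA panels become competitive with existing biomarkers.")
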