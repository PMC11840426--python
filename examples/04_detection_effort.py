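"""How many pellets must be assessed to detect a species with confidence?

If C of N assessed pellets contain the target, the cumulative probability of
detection after n pellets is pn = 1 - (1 - C/N)^n.  The report gives, per
site, the single-pellet detection probability p1 and the smallest n with
pn > 0.95 — the effort needed for confident detection at alpha = 0.05.
"""

from owlpellets import DetectionQuery, detection_curve, detection_report

# pellet occurrence of Planigale spp. in the three present-day collections
sites = [("Initial", 32, 280), ("Winter", 19, 269), ("Summer", 8, 157)]
report, summary = detection_report(sites, species="Planigale spp.")
print(report.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\nrequired pellets across sites: min {summary['required_n_min']}, "
      f"max {summary['required_n_max']}, mean {summary['required_n_mean']:.1f}")

curve = detection_curve(DetectionQuery(C=32, N=280), n_max=30)
print("\ndetection curve (Initial), first pellets:")
print(curve.head(5).to_string(index=False, float_format=lambda v: f"{v:.3f}"))
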