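"""Mini parameter-recovery study: repeat the pipeline over master seeds.

The full study uses ten master seeds on a 200x200 world (see
scripts/acceptance.py); this example runs two seeds so it finishes in
about half a minute, and prints the same summary structure.
"""

from enmstack.pipeline import parameter_recovery_study

study = parameter_recovery_study([1, 2])
s = study["summary"]

print("R^2 of predicted-vs-reported richness by flora size class:")
for label, r2 in s["r2_by_size_class"].items():
    print(f"  {label:>5} ha: {r2:.3f}")
print("(the relationship should strengthen toward larger extents)\n")

for guild in ("narrow", "broad"):
    print(f"{guild:>6} guild: sensitivity {s['mean_sensitivity'][guild]:.3f}, "
          f"specificity {s['mean_specificity'][guild]:.3f}, "
          f"overprediction ratio {s['mean_overprediction_ratio'][guild]:.2f}")
print("\n(the dispersal-limited narrow guild should show higher sensitivity,"
      "\n lower specificity, and a ratio well above 1)")
print(f"\nmean test omission of well-sampled species: "
      f"{100 * s['mean_test_omission']:.1f}% (tolerable band: 5-20%)")
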