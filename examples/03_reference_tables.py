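"""Reproduce the reference descriptive statistics and ice-effect ratios.

Pushes the shipped 22-whale deployment summary through the duration and
footer pathways, and evaluates the ice-effect ratio formulas on the
shipped best pooled-model coefficients.
"""

import ctcrw

table = ctcrw.datasets.deployment_summary()

overall = ctcrw.migration_duration_stats(table, "all").iloc[0]
print(f"migratory duration, all whales (n={overall['n']:.0f}): "
      f"mean {overall['mean']:.1f} d, median {overall['median']:.0f} d, "
      f"range {overall['min']:.0f}-{overall['max']:.0f} d")
for grouping in ("sex", "period"):
    for _, row in ctcrw.migration_duration_stats(table, grouping).iterrows():
        print(f"  {row['group']:8s} mean {row['mean']:.1f} d, "
              f"median {row['median']:.0f} d")

foot = ctcrw.footer_stats(table)
print(f"fix counts: mean {foot.loc['mean','locs']:.1f}, "
      f"median {foot.loc['median','locs']:.0f}")
print(f"tracking duration: median {foot.loc['median','td']:.1f} d, "
      f"sample SD {foot.loc['sd','td']:.1f} d")

coefs, se = ctcrw.datasets.best_pmodel()
print("\nice-effect ratios (expected parameter in ice-free vs ice-covered "
      "habitat):")
print("  sigma, males+ :", round(ctcrw.ice_effect_ratio(coefs, "sigma",
                                                        "reference"), 2))
print("  beta,  males+ :", round(ctcrw.ice_effect_ratio(coefs, "beta",
                                                        "reference"), 3))
print("  beta,  mothers:", round(ctcrw.ice_effect_ratio(coefs, "beta",
                                                        "deviated"), 2))
# a beta ratio of 0.07 for mothers means beta is ~14x higher (movement
# far less persistent - area-restricted search) where winter ice occurred
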