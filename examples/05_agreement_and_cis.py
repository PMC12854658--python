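"""Interrater agreement and binomial confidence intervals.

Computes Fleiss kappa for a small items x raters table with its
Landis-Koch interpretation band, and Wilson 95% CIs for a few detector
sensitivities, illustrating the validation statistics on their own.
"""

from bleedwatch.evaluation import fleiss_kappa, wilson_ci

ratings = [
    ["MB", "MB", "MB"],
    ["CRNMB", "CRNMB", "CRNMB"],
    ["MB", "MB", "CRNMB"],
    ["none", "none", "none"],
    ["CRNMB", "none", "CRNMB"],
    ["MB", "MB", "MB"],
]
kappa, band = fleiss_kappa(ratings)
print(f"Fleiss kappa over {len(ratings)} cases x 3 reviewers: "
      f"{kappa:.3f} ({band})")
print("-> chance-corrected agreement; 0.61-0.80 would read 'substantial'.")

print("\nWilson 95% CIs for detected/total bleeding cases:")
for detected, total in ((232, 276), (104, 144), (88, 132)):
    lo, hi = wilson_ci(detected, total)
    print(f"  {detected:3d}/{total} = {detected/total:.2f} "
          f"(95% CI {lo:.2f}-{hi:.2f})")
print("-> the score interval stays inside [0, 1] and is asymmetric near the")
print("   edges, unlike the normal-approximation interval.")
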