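"""Minimum detectable odds ratios for cis-pQTL MR of prostate cancer.

Builds the overall and aggressive case-control designs, asks for the
smallest odds ratio detectable at 80% power given an instrument explaining
1% of protein variance, and prints the result.  An OR of 1.14 means the
study can detect a 14% change in odds per SD of genetically predicted
protein level.
"""

from protmr import CaseControlDesign, detectable_or, mr_power

overall = CaseControlDesign(n_cases=85_554, n_controls=91_972,
                            pve=0.01, alpha=0.05)
aggressive = CaseControlDesign(n_cases=15_167, n_controls=58_308,
                               pve=0.01, alpha=0.05)

for name, design in [("overall", overall), ("aggressive", aggressive)]:
    mdo = detectable_or(0.80, design)
    print(f"{name}: {design.n_cases:,} cases / {design.n_controls:,} controls"
          f" -> minimum detectable OR at 80% power = {mdo:.2f}")

print(f"power to detect OR 1.14 in the overall design: "
      f"{mr_power(1.14, overall):.3f}")
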