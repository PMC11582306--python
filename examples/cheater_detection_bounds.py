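"""Cheater detection on the two-sub-samples design, and the SP-no bridge.

Solves the cheater-detection model exactly for a worked example, shows
the prevalence bounds, and walks the parameter correspondence between
the CDM and SP-no formulations.
"""

from rrbias import (
    TrueCategoryProbs,
    cdm_spno_correspondence,
    invert_cdm_subsamples,
    misreport_fraction,
)

# observed conditional probabilities (n|1, y|1, n|2, y|2) at p = .8;
# n|1 + n|2 = 1.1 > 1 flags the presence of all-'no' cheaters
pi_star = [0.7, 0.3, 0.4, 0.6]
tau, (lo, hi) = invert_cdm_subsamples(pi_star, p=0.8)
print(f"observed pi* = {pi_star}")
print(f"CDM solution: tau_n = {tau.values[0]:.3f}, tau_y = {tau.values[1]:.3f}, "
      f"tau_c = {tau.cheater_prob:.3f}")
print(f"carrier prevalence bounds: [{lo:.3f}, {hi:.3f}]\n")

print("SP-no reparameterizations of the same fit:")
for variant in ("theta_equal", "theta_n_zero", "theta_y_zero"):
    pi, theta = cdm_spno_correspondence(tau, variant)
    print(f"  {variant:<13} pi_y = {pi.values[1]:.3f}, theta = {theta:.3f}")

print("\nHow many SP-no sayers actually misreport? With pi_y=.1, theta=.2 and")
print("p_nn=5/6 (five of six non-carriers must answer no anyway):")
print(f"  misreport fraction = {misreport_fraction(0.1, 0.2, 5/6):.3f}")
print("  (less than a quarter of the SP-no sayers ever contradict the truth)")
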