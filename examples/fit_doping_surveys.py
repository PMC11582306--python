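"""Fit the bundled doping surveys with and without evasive-bias correction.

Study I asked 2,269 male gym users ever/last-year questions about
anabolic steroids and an ever question about SARMs, all randomized with
p = 5/6; Study II asked 1,050 elite athletes two ever/last-year sets
(anabolics, blood manipulations).  The null model assumes everyone
follows the randomizer; the SP-no model adds a latent class of
self-protective no-sayers; the CDM adds a cheater category instead.
"""

from rrbias import fit_ml, load_fixture

coll = load_fixture("study1_anabolics_collapsed")
print("=== Study I, anabolics only (4 profiles) ===")
for model in ("null", "sp_no", "cdm"):
    fit = fit_ml(coll.layout, model, coll.counts, seed=0)
    print(fit.summary())
print("Reading: about 4.3% former and 4.7% last-year users of anabolics;")
print("the SP-no/cheating estimate (~4.6%) is not significant here, and the")
print("AIC keeps the null model.\n")

s1 = load_fixture("study1")
print("=== Study I, anabolics + SARMs (8 profiles) ===")
for model in ("null", "sp_no", "sp_last_year"):
    fit = fit_ml(s1.layout, model, s1.counts, seed=0)
    print(fit.summary())
print("Reading: the extra question lifts the power; the SP-no estimate of")
print("evasive all-'no' responding is now 6.4% and the AIC prefers it.\n")

s2 = load_fixture("study2")
print("=== Study II, anabolics + blood manipulations (16 profiles) ===")
for model in ("null", "sp_no"):
    fit = fit_ml(s2.layout, model, s2.counts, seed=0)
    print(fit.summary())
print("Reading: two ever/last-year sets identify a 7.1% SP-no/cheating class;")
print("SP-no and CDM fits have identical likelihoods (reparameterizations).")
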