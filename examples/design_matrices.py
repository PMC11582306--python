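"""Build and inspect the transition matrices of the supported designs.

A transition matrix collects P(observed profile | true category); the
forward model for observed randomized-response profiles is pi* = P pi.
"""

from rrbias import (
    RandomizationSpec,
    append_cheater_column,
    everlastyear_matrix,
    kronecker_chain,
    splastyear_matrix,
    subsamples_matrix,
    symmetric_2x2,
)

rand = RandomizationSpec(5 / 6)

print("Single question, p = 5/6 (rows = observed, cols = true):")
print(symmetric_2x2(rand).to_frame().round(3), "\n")

print("Ever/last-year design (true categories never / former / last-year;")
print("the 'never but last-year' profile is structurally impossible):")
print(everlastyear_matrix(rand).to_frame().round(3), "\n")

print("Two sub-samples with complementary probabilities, cheater column added:")
print(append_cheater_column(subsamples_matrix(RandomizationSpec(0.8))).to_frame(), "\n")

print("Ever/last-year + third question: P(8x6) = P(4x3) (x) P(2x2):")
T = kronecker_chain([everlastyear_matrix(rand), symmetric_2x2(rand)])
print(T.to_frame().round(3), "\n")

print("SP(last-year) matrix at theta=.1, theta_yy->yn=.2 (columns still sum to 1):")
M = splastyear_matrix(rand, 0.1, 0.2)
print(M.to_frame().round(3))
print("column sums:", M.values.sum(axis=0).round(12))
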