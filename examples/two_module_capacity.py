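"""Capacity of a two-module grid code and its sensitivity to the scale ratio.

Builds two-module systems with different scale ratios, estimates the
capacity constant c-hat with the record-window estimator, and prints the
resulting coding ranges.  The golden ratio is the best possible choice; a
rational ratio collapses entirely; the transcendental e sits in between.
"""

from gridcode import NoiseModel, ScaleSystem, coding_range
from gridcode.diophantine import c_hat_window

for label, tokens in [("golden ratio", ["1", "phi"]),
                      ("rational 3/2", ["1", "3/2"]),
                      ("e", ["1", "e"])]:
    system = ScaleSystem.from_symbolic(tokens)
    est = c_hat_window(system, 0.001, 0.05)
    print(f"{label:13s}  c_hat = {est.value:.4f} (prints as {est.rounded})  "
          f"record window l = {est.l_window}")

# c_hat/delta is the coding range: how far a noisy two-module code stays
# unambiguous, in units of the smaller grid period
system = ScaleSystem.from_symbolic(["1", "phi"])
for delta in (0.05, 0.01, 0.001):
    L = coding_range(system, NoiseModel(delta))
    print(f"delta = {delta:5.3f}  ->  L_max = {L}  (c_hat/delta ~ {0.276/delta:.0f})")
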