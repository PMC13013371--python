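"""Number-Needed-to-Label from learning-curve arithmetic.

Fits the baseline F1-vs-alpha line, converts a pre-training gain into the
extra label fraction the baseline would need, and prices it in videos and
person-hours.
"""

from weaksurg import annotation_hours, fit_baseline_curve, nnl

# baseline weighted-F1 (points) at the four label fractions
curve = fit_baseline_curve({0.25: 61.0, 0.5: 64.0, 0.75: 65.0, 1.0: 70.0},
                           procedure="demo")
print(f"baseline curve: F1 = {curve.intercept:.2f} + {curve.slope:.2f}*alpha")

delta_f1 = 6.35          # pre-training gain at alpha0 = 0.25, in points
n_train = 68             # non-test pool size in videos
result = nnl(delta_f1, curve, n_train)

print(f"delta-F1 at alpha0={result.alpha0}: {result.delta_f1:.2f} points")
print(f"delta-alpha = dF1 / slope = {result.delta_alpha:.2f}")
print(f"NNL = delta-alpha x N_train = {result.nnl} videos")
print(f"at 40 min/case: {annotation_hours(result.nnl_exact, 40):.0f} person-hours")

# NNL reads as: the baseline would need this many additional step-annotated
# videos to match the weakly pre-trained model at the same label fraction.
# It scales with the pool size, which is what makes it a budgeting tool.
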