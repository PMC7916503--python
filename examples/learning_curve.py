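"""Fit the inverse-power-law learning curve accuracy(n) = a - b * n^(-c).

Classifier accuracy as a function of training-set size typically follows
an inverse power law; the fitted plateau ``a`` is the accuracy the model
would approach with unlimited data, which tells you whether collecting
more events is worth it.  Here the fit is demonstrated on noisy points
generated from a known curve.
"""

import numpy as np

import drowseeg as dg

rng = np.random.default_rng(0)
n = np.array([10, 20, 40, 80, 160, 320, 640])
true = (95.0, 30.0, 0.5)
acc = true[0] - true[1] * n ** (-true[2]) + 0.5 * rng.standard_normal(n.size)

fit = dg.fit_learning_curve(list(zip(n, acc)))
print("points (n, accuracy %):")
for ni, ai in zip(n, acc):
    print(f"  {ni:5d}  {ai:6.2f}")
print(f"\nfit: a = {fit.a:.2f}, b = {fit.b:.2f}, c = {fit.c:.3f} "
      f"(true a = {true[0]}, b = {true[1]}, c = {true[2]})")
print(f"extrapolated plateau accuracy: {fit.plateau:.2f}%  "
      f"(the ceiling more training events would buy)")
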