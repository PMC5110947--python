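"""Encode fast-mode feature vectors and classify residues with Gaussian naive Bayes.

Uses two synthetic chains: one to train the classifier on planted hot-spot
labels, one to test it.  Features are the components of the three fastest
modes in a 3-residue sliding window (mode-major ordering).
"""

import numpy as np

from gnmhot import (
    FeatureScheme, GNMParameters, SyntheticSpec,
    build_kirchhoff, decompose, encode, generate_chain, plant_labels,
    fit, predict, predict_proba, compute_metrics,
)

spec = SyntheticSpec(seed=11)
params = GNMParameters(cutoff=spec.planted_cutoff)
scheme = FeatureScheme("top_m", mode=3, window=3)

data = {}
for index in (0, 1):
    chain = generate_chain(spec, index)
    spectrum = decompose(build_kirchhoff(chain, params), params)
    x = encode(spectrum, scheme, chain_id=chain.chain_id).values
    y = plant_labels(chain, spec, index).join(chain)
    data[index] = (x, y)

x_train, y_train = data[0]
x_test, y_test = data[1]
model = fit(x_train, y_train)
print(f"trained on {len(y_train)} residues ({y_train.sum()} hot spots); "
      f"priors P(y=0)={model.priors[0]:.3f}, P(y=1)={model.priors[1]:.3f}")

y_hat = predict(model, x_test)
proba = predict_proba(model, x_test)
report = compute_metrics(y_test, y_hat)
print(f"held-out chain: sen={report.sen:.3f} pre={report.pre:.3f} F1={report.f1:.3f}")
print(f"max posterior P(hot spot | X) on the test chain: {proba.max():.3f}")
print("sensitivity = fraction of true hot spots recovered; precision = fraction")
print("of predicted hot spots that are real; F1 balances the two.")
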