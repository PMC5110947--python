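"""Classical MSF/MSDF threshold baselines on the same planted benchmark.

Predicts hot spots by thresholding the normalized fast-mode MSF — with the
constant 0.005 rule and the length-scaled 6/N rule — and ranks residues by
MSDF, then compares them against the planted labels.
"""

import numpy as np

from gnmhot import (
    GNMParameters, SyntheticSpec, ThresholdRule,
    build_kirchhoff, decompose, generate_dataset,
    msf_threshold_predict, msdf_score, compute_metrics,
)

spec = SyntheticSpec(n_chains=12, length_range=(60, 120), seed=8)
chains, labels = generate_dataset(spec)
params = GNMParameters(cutoff=7.0)
spectra = {c.chain_id: decompose(build_kirchhoff(c, params), params) for c in chains}
y_true = np.concatenate([labels.join(c) for c in chains])

for name, rule in [("constant 0.005", ThresholdRule("constant", value=0.005)),
                   ("length-scaled 6/N", ThresholdRule("length_scaled", scale=6.0))]:
    y_pred = np.concatenate(
        [msf_threshold_predict(spectra[c.chain_id], 3, rule, params) for c in chains]
    )
    m = compute_metrics(y_true, y_pred)
    print(f"{name:>18s}: sen={m.sen:.4f} spe={m.spe:.4f} pre={m.pre:.4f} F1={m.f1:.4f}")
print("6/N is the stricter threshold for chains shorter than 1200 residues, so")
print("it trades sensitivity for specificity relative to the constant rule.")

chain = chains[0]
score = msdf_score(spectra[chain.chain_id], 3, params, aggregate="max")
top = np.argsort(score)[::-1][:5]
print(f"\nchain {chain.chain_id} top-5 residues by MSDF ranking score:",
      [chain.residues[i][0] for i in top])
print("MSDF ranks residues by how strongly their pair distances fluctuate in")
print("the fast modes; the final labeling cutoff is left to the user.")
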