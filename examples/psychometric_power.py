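"""Cross-validated ΔLogLik: how much does surprisal improve reading-time fit?

A baseline regression (length, frequency, position, previous word's
length and frequency) is compared against the same model plus surprisal
of the current and previous word.  Tenfold cross-validation measures the
held-out log-likelihood gain per word; fold p-values are combined with
Fisher's method.  Positive ΔLogLik per 1,000 words means surprisal adds
real predictive power beyond the control baseline.
"""

import surpread as sp

config = sp.SyntheticConfig(
    structure=sp.TextStructure(kind="sentences", n_sentences=250),
    participants=4,
    seed=1234,
)
records, truth, _, _ = sp.make_corpus(config)
table, _ = sp.apply_exclusions(sp.attach_spillover(records, truth))
table = table.iloc[:5000]
print(f"evaluating {len(table)} analysis rows (true surprisal as predictor)\n")

for measure in ("ffd", "gd", "trt"):
    res = sp.cv_delta_loglik(table, sp.RegressionSpec(response=measure),
                             k=10, seed=77)
    print(f"{measure.upper():>4s}: ΔLogLik/1000 words = {res.per_1000:6.2f} "
          f"(SE {1000 * res.se:.2f}), Fisher p = {res.fisher_p:.2e}")

print("\nGaze duration shows the clearest gain: the generator injects the")
print("surprisal effect into first-pass reading, while TRT adds rereading")
print("noise and FFD only carries a share of the gaze duration.")
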