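"""Run the whole chain — simulate → score → evaluate → linearity — in one call.

Everything is driven by a single RunConfig; outputs (corpus, surprisal
table, per-measure evaluation JSON, exclusion report, linearity result,
prediction curves) land in the output directory together with a manifest
of content digests, so the same config reproduces identical files.
"""

import json
from pathlib import Path

import surpread as sp

out_dir = Path("scratch_pipeline_demo")
config = sp.RunConfig(
    out_dir=str(out_dir),
    synthetic=sp.SyntheticConfig(
        structure=sp.TextStructure(kind="sentences", n_sentences=80),
        participants=3,
        seed=7,
    ),
    lm_source="ngram",   # train a 5-gram on the generated text and use it
    ngram_order=5,
    measures=("gd",),
    k=10,
    n_perm=500,
)
bundle = sp.run_pipeline(config)

print("stages run:", [s["stage"] for s in bundle["manifest"]["stages"]])
res = bundle["eval"]["gd"]
print(f"5-gram surprisal, GD: ΔLogLik/1000 words = {res.per_1000:.2f}, "
      f"Fisher p = {res.fisher_p:.3g}")
lin = bundle["linearity"]
print(f"linearity permutation p = {lin.permutation_p:.3g} "
      f"(n_perm = {lin.n_perm})")
print("outputs:", sorted(p.name for p in out_dir.iterdir()))
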