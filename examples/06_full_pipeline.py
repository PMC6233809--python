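"""Run the seeded end-to-end pipeline and print the headline metrics.

Equivalent to `tastepe run-all --seed 5 --out tastepe_demo` from a shell.
"""

import json

from tastepe import PipelineConfig, run_pipeline

config = PipelineConfig(output_dir="tastepe_demo", seed=5)
manifest = run_pipeline(config)

print(json.dumps(manifest["headline"], indent=2))
print("outputs:")
for name, path in manifest["outputs"].items():
    print(f"  {name}: {path}")

# Headline metrics: the Wilks lambda and caudate F of the rank-MANOVA, the
# recovered ventral-striatum/hypothalamus direction per group (vs_to_hyp in
# the AN-like group, hyp_to_vs in controls), and the cortisol Welch t.
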