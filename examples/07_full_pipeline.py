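"""The whole workflow in one call, from a config object to an output directory.

Equivalent to ``vespagen run --config cfg.yaml`` on the shell; every artifact
is listed with its checksum in manifest.json, so identical configs give
byte-identical runs.
"""

import json

import vespagen as vg

cfg = vg.fixture_config("pipeline_example_out", seed=1)
out = vg.run_pipeline(cfg)
manifest = json.load(open(out / "manifest.json"))
print("per-stage counts:")
for stage, counts in manifest["stages"].items():
    print(f"  {stage}: {counts}")
print(f"\n{len(manifest['outputs'])} artifacts in {out}/ "
      "(VCF, relatedness matrix, unrelated subset, fROH table, PCA scores, mitotypes)")
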