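"""Run the whole analysis from one config and inspect the manifest.

Every stage writes plain CSV into the output directory; the manifest
records parameters, seeds and input hashes so the run can be reproduced.
"""

import json

import ethonet as en

config = en.RunConfig(
    output_dir="scratch/example_run",
    simulate={"subjects_per_community": 4, "videos_per_subject": 6},
    n_boot=100,
    seed=3,
)
manifest = en.run_full_analysis(config)

print(f"{len(manifest['outputs'])} output files in {config.output_dir}:")
for name in manifest["outputs"]:
    print("  ", name)
print("ENA summary:", json.dumps(manifest["ena"], indent=2)[:400], "...")
for note in manifest["notices"]:
    print("notice:", note)
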