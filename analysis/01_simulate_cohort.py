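#!/usr/bin/env python
"""Generate the default synthetic multi-omics bundle used by every later step.

Writes a TCGA-like study (4 cancer types x 300 tumors + 50 normals, 400
genes, latent glycolysis-hypoxia correlation 0.8, one gained oncogene, one
lost suppressor, one mutated driver) plus a spatial single-cell dataset
(8 patients x 90 cells, core/edge/middle regions) to results/bundle/.
"""

import json
from pathlib import Path

from glycoscape.simulate import SimConfig, write_fixture_bundle

SEED = 20260920
OUT = Path(__file__).resolve().parents[1] / "results" / "bundle"


def main() -> None:
    digests = write_fixture_bundle(OUT, SimConfig(seed=SEED), force=True)
    print(f"wrote {len(digests)} files to {OUT}")
    for name, sha in digests.items():
        print(f"  {name}  sha256:{sha[:12]}")
    with open(OUT.parent / "bundle_digests.json", "w") as fh:
        json.dump(digests, fh, indent=2)


if __name__ == "__main__":
    main()
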