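#!/usr/bin/env python
"""Map predicted beta diversity across the study region.

Rasters of the model's kept predictors are transformed to biological
space (partial ecological distance), reduced to three principal
components, and rendered as an RGB map: pixels with similar colors are
predicted to share similar insect communities.
"""

from betascape.pipeline import fixture_config, run_stage

OUT = "results/run"
SEED = 1


def main() -> None:
    cfg = fixture_config(OUT, seed=SEED)
    entry = run_stage("map", cfg)
    c = entry["counts"]
    print(f"transformed {c['n_layers']} predictor rasters to biological space")
    print(f"RGB beta-diversity map over {c['n_valid_pixels']} pixels:")
    print(f"  {OUT}/beta_map.tif (3-band GeoTIFF), {OUT}/beta_map.png (preview)")


if __name__ == "__main__":
    main()
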