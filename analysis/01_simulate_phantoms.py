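#!/usr/bin/env python
"""Generate the synthetic study material used by the downstream analyses.

Writes a small panel of phantom specimens (paired white-light / IR images
with ground-truth masks) plus one deformed section pair and one IHC slide
to ``scratch/phantoms`` (binary PNGs), and a cohort manifest with the
generator truth to ``results/phantom_manifest.csv``.
"""

import dataclasses
import json
from pathlib import Path

from fgsquant import imgio, synth

SEED = 1
OUT_IMAGES = Path("scratch/phantoms")
OUT_RESULTS = Path("results")


def main() -> None:
    OUT_IMAGES.mkdir(parents=True, exist_ok=True)
    OUT_RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, tbr in enumerate((1.0, 1.5, 3.0, 5.0)):
        cfg = synth.PhantomConfig(true_tbr=tbr, noise_sd=2.0, tumor_shape="blob",
                                  seed=SEED + i)
        case = synth.make_phantom(cfg)
        stem = f"case_tbr{tbr:g}"
        imgio.write_image(case.white_image, OUT_IMAGES / f"{stem}_white.png")
        imgio.write_image(case.ir_image, OUT_IMAGES / f"{stem}_ir.png")
        imgio.write_image(case.tumor_mask, OUT_IMAGES / f"{stem}_tumor.png")
        (OUT_IMAGES / f"{stem}_truth.json").write_text(
            json.dumps(dataclasses.asdict(cfg), indent=2)
        )
        rows.append({"case": stem, "true_tbr": tbr, "noise_sd": cfg.noise_sd,
                     "tumor_px": int(case.tumor_mask.sum()),
                     "clipped": case.clipped, "seed": cfg.seed})
    pair = synth.make_section_pair(
        synth.make_phantom(synth.PhantomConfig(tumor_shape="blob", seed=SEED)),
        synth.MOUNTING_ARTEFACT_DEFORM,
    )
    imgio.write_image(pair.histo_tissue_mask, OUT_IMAGES / "section_histo_tissue.png")
    imgio.write_image(pair.fft_tissue_mask, OUT_IMAGES / "section_fft_tissue.png")
    ihc_phantom = synth.make_ihc_phantom(0.32, 0.07, seed=SEED)
    imgio.write_image(ihc_phantom.image, OUT_IMAGES / "ihc_slide.png")

    imgio.write_results(rows, OUT_RESULTS / "phantom_manifest.csv")
    print(f"wrote {len(rows)} phantom specimens to {OUT_IMAGES}")
    print(f"manifest -> {OUT_RESULTS / 'phantom_manifest.csv'}")


if __name__ == "__main__":
    main()
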