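"""Compare preprocessing methods (none, SG, SNV, MSC) with full-band PLSR.

Writes results/preprocessing_comparison.csv — the preprocessing-selection
table that motivates using SG for the later stages.
"""

from pathlib import Path

import firspec as fs

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    path = OUT / "spectra.csv"
    if not path.exists():  # allow running out of order
        fs.simulate_dataset(fs.SyntheticConfig(seed=SEED)).to_csv(path)
    data = fs.SpectraSet.from_csv(path)
    cfg = fs.PipelineConfig(
        preprocess_methods=("none", "sg", "snv", "msc"),
        selectors=("full",),
        models=("plsr",),
        seed=SEED,
    )
    report = fs.run_pipeline(data, cfg)
    report.to_csv(OUT / "preprocessing_comparison.csv")
    cols = ["index", "preprocessing", "r2_c", "rmse_c", "r2_p", "rmse_p"]
    print(report.table[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
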