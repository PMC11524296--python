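"""Fit the full model grid: {full, SPA, CARS} x {PLSR, SVR, ANN} x {LCC, LWC}.

All on SG-preprocessed spectra with the stratified 126/54 split.  Writes
results/model_comparison.csv and prints the comparison table.
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
        preprocess_methods=("sg",),
        selectors=("full", "spa", "cars"),
        models=("plsr", "svr", "ann"),
        cars_config=fs.CarsConfig(pls_components=8),
        seed=SEED,
    )
    report = fs.run_pipeline(data, cfg)
    report.to_csv(OUT / "model_comparison.csv")
    cols = ["index", "selector", "n_bands", "model", "r2_c", "rmse_c", "r2_p", "rmse_p"]
    print(report.table[cols].round(4).to_string(index=False))
    best = (report.table[report.table["status"] == "ok"]
            .sort_values("r2_p", ascending=False).groupby("index").head(1))
    print("\nBest model per trait (by prediction R^2):")
    print(best[cols].round(4).to_string(index=False))


if __name__ == "__main__":
    main()
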