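"""Select characteristic wavelengths with SPA and CARS on SG-preprocessed spectra.

Writes one selection JSON per (method, trait) to results/ and prints the
selected band counts next to the retention fractions of the published
reference band sets for this instrument grid.
"""

import json
from pathlib import Path

import firspec as fs
from firspec import reported

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    path = OUT / "spectra.csv"
    if not path.exists():  # allow running out of order
        fs.simulate_dataset(fs.SyntheticConfig(seed=SEED)).to_csv(path)
    data = fs.SpectraSet.from_csv(path)
    plan = fs.split_calibration_prediction(data, seed=SEED)
    prep = fs.Preprocessor(fs.PreprocessSpec(method="sg"))
    cal = prep.fit_transform(data.subset(plan.calibration_ids))

    for target in ("lcc", "lwc"):
        y = cal.target(target)
        for name, result in {
            "spa": fs.spa_select(cal.matrix, y, fs.SpaConfig(seed=SEED), grid=data.grid),
            "cars": fs.cars_select(cal.matrix, y,
                                   fs.CarsConfig(seed=SEED, pls_components=8),
                                   grid=data.grid),
        }.items():
            path = OUT / f"selection_{name}_{target}.json"
            path.write_text(json.dumps({
                "method": result.method,
                "target": target,
                "selected_indices": result.selected_indices.tolist(),
                "selected_wavelengths_nm": result.selected_wavelengths_nm.tolist(),
                "rmse_trajectory": result.rmse_trajectory.tolist(),
                "chosen_point": result.chosen_point,
                "retained_counts": (result.retained_counts.tolist()
                                    if result.retained_counts is not None else None),
            }, indent=2))
            pct = 100.0 * result.n_selected / data.grid.n_bands
            print(f"{name.upper():4s} {target.upper()}: {result.n_selected:3d} bands "
                  f"({pct:.2f}% of {data.grid.n_bands}) -> {path.name}")

    print("\nPublished reference band sets on the same 512-band grid:")
    for label, wl in [("CARS LCC", reported.CARS_LCC_WAVELENGTHS_NM),
                      ("CARS LWC", reported.CARS_LWC_WAVELENGTHS_NM),
                      ("SPA LCC", reported.SPA_LCC_WAVELENGTHS_NM),
                      ("SPA LWC", reported.SPA_LWC_WAVELENGTHS_NM)]:
        print(f"  {label}: {len(wl)} bands "
              f"({reported.band_retention_percent(wl):.2f}%)")


if __name__ == "__main__":
    main()
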