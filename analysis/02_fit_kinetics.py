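"""Fit the irreversible two-tissue model to every simulated depot TAC.

Reads the TAC CSVs written by 01_simulate_cohort.py and the shared input
function, runs the multi-start bounded least-squares fit per curve, and
writes per-fit parameters (K1, k2, k3, vb), the derived net uptake rate Ki,
and fit diagnostics to results/cohort_fits.csv.
"""

from pathlib import Path

import pandas as pd

ROOT = Path(__file__).resolve().parents[1]

import bcaapet as bp


def main() -> None:
    results = ROOT / "results"
    tac_dir = ROOT / "scratch" / "cohort_tacs"
    if not tac_dir.is_dir():
        raise SystemExit("run analysis/01_simulate_cohort.py first")
    input_fn = bp.PlasmaInputFunction.from_json(
        str(results / "input_function.json")
    )
    rows = []
    for path in sorted(tac_dir.glob("*.csv")):
        subject_id, depot = path.stem.rsplit("_", 1)
        tac = bp.TimeActivityCurve.from_csv(path)
        fit = bp.fit_tac(tac, input_fn)
        rows.append(
            {"subject_id": subject_id, "depot": depot, **fit.to_dict()}
        )
    df = pd.DataFrame(rows).drop(columns=["per_param_se"], errors="ignore")
    df.to_csv(results / "cohort_fits.csv", index=False)
    med = df.groupby("depot")["ki"].median()
    print(f"fitted {len(df)} TACs; median Ki by depot (mL/min/cm^3):")
    print(med.to_string(float_format=lambda v: f"{v:.5f}"))


if __name__ == "__main__":
    main()
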