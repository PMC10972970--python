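"""Scenario analyses: the full registry of named variants of the base case.

Writes a scenario-table-shaped summary (discounted QALYs/LYs, costs, deltas
and ICER per row) to ``results/scenarios.csv``.  Structure-only entries
(EQ-5D-3L utilities, values not published) are listed with the reason they
were skipped.
"""

import argparse
import logging
from pathlib import Path

from tavi_cea import load_inputs, reporting, run_comparison
from tavi_cea.sensitivity import load_scenario_registry, run_all_scenarios

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None, help="input YAML (default: packaged)")
    ap.add_argument("--out", default="results", help="output directory")
    args = ap.parse_args()
    out = Path(args.out)
    out.mkdir(parents=True, exist_ok=True)

    bundle = load_inputs(args.config)
    results = {"base_case": run_comparison(bundle)}
    scen_results, skipped = run_all_scenarios(bundle)
    results.update(scen_results)

    df = reporting.summary_frame(results)
    df.to_csv(out / "scenarios.csv", index=False)
    reporting.write_manifest(out, command="scenarios",
                             config=args.config or "packaged",
                             scenarios=list(results), skipped=skipped)

    with_icer = df[["scenario", "qaly_tavi", "qaly_savr", "delta_qaly",
                    "delta_cost", "icer"]]
    print(with_icer.to_string(index=False))
    for name, reason in skipped.items():
        print(f"skipped {name}: requires user-supplied utilities "
              f"({reason.split(':')[0]})")


if __name__ == "__main__":
    main()
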