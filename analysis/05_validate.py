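"""Model validation: survival projections vs general-population anchors.

Checks (a) the synthetic lifetable calibration (remaining life expectancy at
age 74 vs the published 13.0 y male / 15.8 y female), (b) the projected
base-case life years against the mixed-cohort expectation, and (c) the
structural invariants (occupancy conservation, absorbing death, discounting
consistency).  Exits non-zero if any check fails.
"""

import argparse
import logging
import sys

import numpy as np

from tavi_cea import life_expectancy, load_inputs, run_comparison
from tavi_cea.pipeline import lifetables_for

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(name)s: %(message)s")


def main() -> int:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--config", default=None, help="input YAML (default: packaged)")
    args = ap.parse_args()

    bundle = load_inputs(args.config)
    cfg = bundle.config
    tables = lifetables_for(cfg)
    failures = []

    le = {sex: life_expectancy(tables[sex], age=74) for sex in ("male", "female")}
    for sex, target in (("male", cfg.le_target_male), ("female", cfg.le_target_female)):
        ok = abs(le[sex] - target) <= 0.01
        print(f"LE(74) {sex}: {le[sex]:.3f} y (target {target}) "
              f"{'OK' if ok else 'FAIL'}")
        if not ok:
            failures.append(f"lifetable calibration ({sex})")

    res = run_comparison(bundle, tables)
    mixed_le = (cfg.pct_female * le["female"] + (1 - cfg.pct_female) * le["male"])
    for arm in ("TAVI", "SAVR"):
        ly = res.econ[arm].scalar("ly")
        # a low-risk cohort is expected to track general-population survival:
        # projected LY should sit below the age-74 mixed LE (the cohort is
        # slightly older and carries trial-period mortality) but within ~1 y
        ok = mixed_le - 1.0 <= ly <= mixed_le + 0.3
        print(f"{arm} projected LY {ly:.2f} vs mixed-cohort LE(74) {mixed_le:.2f} "
              f"{'OK' if ok else 'FAIL'}")
        if not ok:
            failures.append(f"survival projection ({arm})")

    for arm, trace in res.traces.items():
        occ = trace.no_stroke + trace.post_stroke + trace.dead
        filled = trace.alive.max(axis=1) > 0   # rows before early termination
        drift = float(np.max(np.abs(occ[filled] - 1.0)))
        ok = drift < 1e-12
        print(f"{arm} occupancy conservation: max drift {drift:.2e} "
              f"{'OK' if ok else 'FAIL'}")
        if not ok:
            failures.append(f"occupancy conservation ({arm})")
        if np.any(np.diff(trace.dead[:, 0]) < -1e-15):
            print(f"{arm} absorbing-death violated FAIL")
            failures.append(f"absorbing death ({arm})")

    undisc = run_comparison(bundle.with_config(discount_rate_annual=0.0), tables)
    consistent = np.isclose(undisc.econ["TAVI"].scalar("qaly"),
                            undisc.econ["TAVI"].scalar("qaly_disc"), rtol=0, atol=0)
    print(f"zero-rate discounting equals undiscounted exactly: "
          f"{'OK' if consistent else 'FAIL'}")
    if not consistent:
        failures.append("discounting consistency")

    if failures:
        print("VALIDATION FAILED:", "; ".join(failures))
        return 1
    print("all validation checks passed")
    return 0


if __name__ == "__main__":
    sys.exit(main())
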