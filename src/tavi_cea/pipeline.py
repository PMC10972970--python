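"""End-to-end runs: inputs -> lifetables -> traces -> economics -> CEA."""

from __future__ import annotations

from dataclasses import dataclass

from .cea import CEAResult, compare
from .economics import EconResult, evaluate_arm
from .engine import MarkovTrace, run_cohort
from .lifetable import Lifetable, build_lifetables, load_lifetable_file
from .parameters import ARMS, InputBundle, ModelConfig, load_inputs


@dataclass
class ComparisonResult:
    """Everything a base-case or scenario run produces."""

    econ: dict[str, EconResult]
    cea: CEAResult
    traces: dict[str, MarkovTrace]
    config: ModelConfig

    def summary_row(self) -> dict:
        t, s = self.econ["TAVI"], self.econ["SAVR"]
        return {
            "qaly_tavi": t.scalar("qaly_disc"),
            "qaly_savr": s.scalar("qaly_disc"),
            "ly_tavi": t.scalar("ly_disc"),
            "ly_savr": s.scalar("ly_disc"),
            "cost_tavi": t.scalar("cost_total_disc"),
            "cost_savr": s.scalar("cost_total_disc"),
            "delta_qaly": self.cea.delta_qaly,
            "delta_ly": self.cea.delta_ly,
            "delta_cost": self.cea.delta_cost,
            "icer": self.cea.icer_label,
            "nmb_at_wtp": self.cea.nmb,
        }


def lifetables_for(config: ModelConfig) -> dict[str, Lifetable]:
    """Calibrated synthetic lifetables, or a user-supplied override file."""
    if config.lifetable_file:
        return load_lifetable_file(config.lifetable_file)
    return build_lifetables(config.gompertz_shape, config.le_target_male,
                            config.le_target_female)


def run_comparison(bundle: InputBundle,
                   tables: dict[str, Lifetable] | None = None) -> ComparisonResult:
    """Run both arms under the bundle's configuration and compare them."""
    config = bundle.config
    if tables is None:
        tables = lifetables_for(config)
    traces = {arm: run_cohort(bundle, arm, config, tables) for arm in ARMS}
    econ = {arm: evaluate_arm(traces[arm], bundle, arm) for arm in ARMS}
    return ComparisonResult(
        econ=econ,
        cea=compare(econ["TAVI"], econ["SAVR"], config.wtp_per_qaly),
        traces=traces,
        config=config,
    )


def run_base_case(config_path=None) -> ComparisonResult:
    """Convenience: load inputs (packaged defaults if None) and run the base case."""
    return run_comparison(load_inputs(config_path))
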