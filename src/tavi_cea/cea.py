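"""Incremental cost-effectiveness comparison: ICER, dominance, NMB, threshold.

Conventions: deltas are TAVI minus SAVR.  The ICER is reported only when
incremental cost and effect share a sign; opposite signs are dominance
(one strategy is cheaper *and* more effective).  A zero effect difference
with a non-zero cost difference is classified as dominance by cost and
flagged rather than reported as an infinite ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DOMINANT_TAVI = "dominant_TAVI"
DOMINANT_SAVR = "dominant_SAVR"
UNDEFINED = "undefined"


@dataclass
class CEAResult:
    """Incremental comparison of TAVI vs SAVR at a willingness-to-pay."""

    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | None          # EUR per QALY when defined, else None
    classification: str         # 'icer', dominance label, or 'undefined'
    dominance_by_cost: bool     # delta_qaly == 0 with delta_cost != 0
    wtp: float
    nmb: float

    @property
    def icer_label(self) -> str:
        if self.icer is not None:
            return f"{self.icer:,.0f}"
        return {DOMINANT_TAVI: "TAVI dominant",
                DOMINANT_SAVR: "SAVR dominant"}.get(self.classification,
                                                    self.classification)


def classify_icer(delta_cost: float, delta_effect: float):
    """(icer-or-None, classification, dominance_by_cost flag) for a quadrant."""
    if not (np.isfinite(delta_cost) and np.isfinite(delta_effect)):
        raise ValueError("incremental cost and effect must be finite")
    if delta_cost == 0.0 and delta_effect == 0.0:
        return None, UNDEFINED, False
    if delta_effect == 0.0:
        label = DOMINANT_TAVI if delta_cost < 0 else DOMINANT_SAVR
        return None, label, True
    if delta_cost * delta_effect > 0.0:
        return delta_cost / delta_effect, "icer", False
    # opposite (weak) signs: dominance
    if delta_cost <= 0.0 and delta_effect >= 0.0:
        return None, DOMINANT_TAVI, False
    return None, DOMINANT_SAVR, False


def icer(delta_cost: float, delta_effect: float):
    """ICER value when defined, else the dominance label."""
    value, label, _ = classify_icer(delta_cost, delta_effect)
    return value if value is not None else label


def nmb_delta(delta_cost, delta_qaly, wtp: float):
    """Incremental net monetary benefit ``wtp * dQALY - dCost`` (EUR).

    Positive favours TAVI at that willingness-to-pay.  Accepts arrays
    (used for CEAC construction from PSA draws).
    """
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    out = wtp * np.asarray(delta_qaly, dtype=float) - np.asarray(delta_cost, dtype=float)
    return float(out) if out.ndim == 0 else out


def threshold_incremental_cost(delta_qaly: float, wtp: float) -> float:
    """Maximum incremental cost keeping the ICER at or below the threshold."""
    if delta_qaly < 0:
        raise ValueError("threshold analysis requires a non-negative QALY gain")
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * delta_qaly


def compare(econ_tavi, econ_savr, wtp: float) -> CEAResult:
    """Build the incremental comparison from two per-arm economic results."""
    d_cost = econ_tavi.scalar("cost_total_disc") - econ_savr.scalar("cost_total_disc")
    d_qaly = econ_tavi.scalar("qaly_disc") - econ_savr.scalar("qaly_disc")
    d_ly = econ_tavi.scalar("ly_disc") - econ_savr.scalar("ly_disc")
    value, label, by_cost = classify_icer(d_cost, d_qaly)
    return CEAResult(
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        icer=value,
        classification=label,
        dominance_by_cost=by_cost,
        wtp=wtp,
        nmb=nmb_delta(d_cost, d_qaly, wtp),
    )
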