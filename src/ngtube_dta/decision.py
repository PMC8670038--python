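"""Decision-analytic model of chest X-ray demand and cost.

Per 1000 eligible patient checks: a fraction have the tube in the
stomach, a fraction of those yield an aspirate, and each aspirated
patient is tested with one strip.  A reading above the cut-off sends the
patient to a confirmatory chest X-ray (CXR), so a strip with sensitivity
s spares s of the aspirated gastric patients the X-ray.  The model
compares total CXR counts between the standard and novel strips; the
difference, priced at the NHS reference cost per CXR and optionally
inflation-adjusted, is the saving.  In the *recheck* scenario an
above-cutoff reading triggers a second test with the same sensitivity,
so the per-strip CXR count becomes aspirated × (1 − s)².

Patients whose tube is not gastric, or who cannot be aspirated, go to
CXR under either strip and cancel out of the savings.

Counts are rounded to whole patients at the identified-patients step
before costing, matching the published worked arithmetic; ``exact=True``
disables all intermediate rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Optional, Sequence

__all__ = [
    "DecisionModelParams",
    "ScenarioResult",
    "run_standard_scenario",
    "run_recheck_scenario",
    "run_scenario",
    "inflate_cost",
    "sweep",
]


def _round_half_up(x: float) -> int:
    return int(Decimal(repr(x)).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class DecisionModelParams:
    """Inputs of the CXR cost model (defaults are the published ones)."""

    sens_standard: float
    sens_novel: float
    cutoff: float = 5.5
    cohort_size: int = 1000
    gastric_rate: float = 0.90
    aspiration_success: float = 0.70
    cxr_unit_cost: float = 28.53  # GBP, NHS reference price per CXR
    inflation_rate: float = 0.035
    inflation_years: float = 2.0
    scenario: str = "standard"
    exact: bool = False

    def __post_init__(self) -> None:
        for name in ("sens_standard", "sens_novel", "gastric_rate", "aspiration_success"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.cohort_size < 0 or self.cxr_unit_cost < 0:
            raise ValueError("cohort_size and cxr_unit_cost must be >= 0")
        if self.inflation_rate < 0 or self.inflation_years < 0:
            raise ValueError("inflation must be >= 0")
        if self.scenario not in ("standard", "recheck"):
            raise ValueError("scenario must be 'standard' or 'recheck'")


@dataclass(frozen=True)
class ScenarioResult:
    """Outcome counts and savings for one parameter set."""

    scenario: str
    cutoff: float
    aspirated: float
    identified_standard: float
    identified_novel: float
    cxr_standard: float
    cxr_novel: float
    cxr_saved: float
    cost_saved_nominal: float
    cost_saved_inflated: float

    def to_dict(self) -> dict:
        from dataclasses import asdict

        return asdict(self)


def inflate_cost(amount: float, rate: float, years: float) -> float:
    """Compound an amount forward: amount × (1 + rate)^years."""
    if rate < 0 or years < 0:
        raise ValueError("rate and years must be >= 0")
    return amount * (1.0 + rate) ** years


def run_scenario(params: DecisionModelParams) -> ScenarioResult:
    """Dispatch on ``params.scenario``."""
    if params.scenario == "recheck":
        return run_recheck_scenario(params)
    return run_standard_scenario(params)


def _finish(
    params: DecisionModelParams,
    aspirated: float,
    identified_s: float,
    identified_n: float,
) -> ScenarioResult:
    cxr_s = aspirated - identified_s
    cxr_n = aspirated - identified_n
    saved = cxr_s - cxr_n
    nominal = params.cxr_unit_cost * saved
    return ScenarioResult(
        scenario=params.scenario,
        cutoff=params.cutoff,
        aspirated=aspirated,
        identified_standard=identified_s,
        identified_novel=identified_n,
        cxr_standard=cxr_s,
        cxr_novel=cxr_n,
        cxr_saved=saved,
        cost_saved_nominal=nominal,
        cost_saved_inflated=inflate_cost(
            nominal, params.inflation_rate, params.inflation_years
        ),
    )


def run_standard_scenario(params: DecisionModelParams) -> ScenarioResult:
    """One pH test per aspirated patient; above-cutoff readings go to CXR."""
    p = params
    aspirated = p.cohort_size * p.gastric_rate * p.aspiration_success
    if not p.exact:
        aspirated = _round_half_up(aspirated)
    identified_s = aspirated * p.sens_standard
    identified_n = aspirated * p.sens_novel
    if not p.exact:
        identified_s = _round_half_up(identified_s)
        identified_n = _round_half_up(identified_n)
    return _finish(p, aspirated, identified_s, identified_n)


def run_recheck_scenario(params: DecisionModelParams) -> ScenarioResult:
    """Above-cutoff readings are retested once before any CXR request.

    With identical sensitivity on the second test, the per-strip CXR
    count is aspirated × (1 − s)²; identified counts are the complement.
    """
    p = params
    aspirated = p.cohort_size * p.gastric_rate * p.aspiration_success
    if not p.exact:
        aspirated = _round_half_up(aspirated)
    cxr_s = aspirated * (1.0 - p.sens_standard) ** 2
    cxr_n = aspirated * (1.0 - p.sens_novel) ** 2
    if not p.exact:
        cxr_s = _round_half_up(cxr_s)
        cxr_n = _round_half_up(cxr_n)
    return _finish(p, aspirated, aspirated - cxr_s, aspirated - cxr_n)


def sweep(
    params: DecisionModelParams,
    cutoff_sensitivities: Optional[Mapping[float, tuple[float, float]]] = None,
    margins: Optional[Sequence[float]] = None,
) -> list[ScenarioResult]:
    """Evaluate the model over cut-offs and/or sensitivity margins.

    ``cutoff_sensitivities`` maps cut-off -> (sens_standard, sens_novel);
    ``margins`` evaluates sens_novel = sens_standard + margin at the
    base cut-off, emulating per-site performance.
    """
    if not cutoff_sensitivities and not margins:
        raise ValueError("nothing to sweep: give cutoff sensitivities or margins")
    results: list[ScenarioResult] = []
    if cutoff_sensitivities:
        for cutoff in sorted(cutoff_sensitivities):
            s, v = cutoff_sensitivities[cutoff]
            results.append(
                run_scenario(
                    replace(params, cutoff=cutoff, sens_standard=s, sens_novel=v)
                )
            )
    if margins:
        for margin in margins:
            results.append(
                run_scenario(
                    replace(params, sens_novel=min(1.0, params.sens_standard + margin))
                )
            )
    return results
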