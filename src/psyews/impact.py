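"""Intervention-targeting arithmetic.

A crisis-resolution-style intervention is assumed to reduce the *odds* of
6-month hospitalisation by a fixed fraction in everyone it is applied to.
Flagged patients hospitalise at a rate equal to the flagging strategy's
PPV, so treating ``n`` flagged patients prevents
``n * (ppv - treated_risk)`` expected hospitalisations. Comparing two
strategies at a common prevention target yields the resource saving of the
better-targeted one.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class ImpactScenario:
    n_treated: int
    ppv: float
    odds_reduction: float

    def __post_init__(self):
        if not 0 < self.ppv < 1:
            raise ValueError("ppv must lie strictly inside (0, 1)")
        if not 0 <= self.odds_reduction < 1:
            raise ValueError("odds_reduction must lie in [0, 1)")


def treated_risk(ppv: float, odds_reduction: float) -> float:
    """Post-intervention hospitalisation risk of a treated flagged patient.

    The intervention scales the odds: odds' = (1 - odds_reduction) *
    ppv / (1 - ppv); the returned risk is odds' / (1 + odds').
    """
    if not 0 < ppv < 1:
        raise ValueError("ppv must lie strictly inside (0, 1)")
    if not 0 <= odds_reduction < 1:
        raise ValueError("odds_reduction must lie in [0, 1)")
    odds = (1.0 - odds_reduction) * ppv / (1.0 - ppv)
    return odds / (1.0 + odds)


def prevented(scenario: ImpactScenario) -> float:
    """Expected hospitalisations prevented by treating the flagged group."""
    return scenario.n_treated * (
        scenario.ppv - treated_risk(scenario.ppv, scenario.odds_reduction)
    )


def n_needed(target_prevented: float, ppv: float, odds_reduction: float) -> int:
    """People to treat (nearest integer) to prevent ``target_prevented``
    hospitalisations at the given PPV and odds reduction."""
    per_person = ppv - treated_risk(ppv, odds_reduction)
    if per_person <= 0:
        raise ValueError("per-person prevention is zero; cannot reach any target")
    return int(round(target_prevented / per_person))


def saving_fraction(n_reference: int, n_needed_: int) -> float:
    """Percentage resource saving of needing ``n_needed_`` instead of
    ``n_reference`` treatments."""
    if n_reference <= 0:
        raise ValueError("n_reference must be positive")
    return 100.0 * (n_reference - n_needed_) / n_reference


def benchmark_comparison(
    ppv_benchmark: float = 0.054,
    ppv_model: float = 0.098,
    odds_reduction: float = 0.80,
    n_treated: int = 1000,
) -> dict[str, float]:
    """The worked targeting comparison between two flagging strategies.

    Treats ``n_treated`` under each strategy, then asks how many
    model-strategy treatments match the benchmark's (rounded) prevention
    total, and the implied saving.
    """
    prev_bench = prevented(ImpactScenario(n_treated, ppv_benchmark, odds_reduction))
    prev_model = prevented(ImpactScenario(n_treated, ppv_model, odds_reduction))
    target = round(prev_bench)
    needed = n_needed(target, ppv_model, odds_reduction)
    return {
        "prevented_benchmark": prev_bench,
        "prevented_model": prev_model,
        "target_prevented": float(target),
        "n_needed_model": needed,
        "saving_pct": saving_fraction(n_treated, needed),
    }
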