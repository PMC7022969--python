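"""Deterministic and stochastic sensitivity of the partial budget.

Two complementary views:

* :func:`scenario_table` — one-at-a-time +/-10% perturbations of each
  budget input (trait annual changes, herd size, the two labor day-rates,
  and the combined hardware+software investment), re-evaluating the full
  budget per scenario. For days open the scenario labels follow the
  improvement direction: the "-10%" row *strengthens* the reduction
  (multiplies the magnitude of the negative annual change by 1.1), so a
  row label always means "10% worse/better milk-era economics" in the
  same sense across inputs.
* :func:`monte_carlo` — all inputs drawn jointly and independently
  (default: uniform on +/-10% around base), budget evaluated per draw,
  and Pearson correlations of each input with the gross margin and the
  marginal return rate reported. The sampling distributions are a
  package convention; correlation magnitudes depend on them, so only
  signs and rankings are comparable across studies.

Note: perturbing the combined hardware+software investment by 10% moves
the five-year budget by $140; published tables that show a $70 effect for
this row imply a different (unstated) perturbation base, so treat that
scenario as qualitative.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .budget import BudgetInputs, TraitChange, evaluate


@dataclass(frozen=True)
class ScenarioRow:
    varied_input: str
    direction: str          # "-10%" / "+10%"
    perturbed_value: float
    gross_margin: float
    delta_gm: float
    mrr: float
    delta_mrr: float


def _perturb_trait(inputs: BudgetInputs, name: str, factor: float) -> BudgetInputs:
    traits = tuple(
        replace(t, annual_change=t.annual_change * factor) if t.name == name else t
        for t in inputs.traits
    )
    return replace(inputs, traits=traits)


def _scenarios(inputs: BudgetInputs, d: float):
    """(label, direction, perturbed inputs, perturbed value) quadruples.

    ``d`` is the perturbation fraction. For improvement-by-reduction
    traits (negative annual change) the "-d" direction strengthens the
    improvement, mirroring how such tables are conventionally labelled.
    """
    for t in inputs.traits:
        better, worse = 1.0 + d, 1.0 - d
        if t.annual_change >= 0:
            yield (f"{t.name} annual change", f"-{d:.0%}",
                   _perturb_trait(inputs, t.name, worse),
                   t.annual_change * worse)
            yield (f"{t.name} annual change", f"+{d:.0%}",
                   _perturb_trait(inputs, t.name, better),
                   t.annual_change * better)
        else:
            yield (f"{t.name} annual change", f"-{d:.0%}",
                   _perturb_trait(inputs, t.name, better),
                   t.annual_change * better)
            yield (f"{t.name} annual change", f"+{d:.0%}",
                   _perturb_trait(inputs, t.name, worse),
                   t.annual_change * worse)
    for sign, factor in (("-", 1.0 - d), ("+", 1.0 + d)):
        yield ("herd size", f"{sign}{d:.0%}",
               replace(inputs, herd_cows=inputs.herd_cows * factor),
               inputs.herd_cows * factor)
    for sign, factor in (("-", 1.0 - d), ("+", 1.0 + d)):
        yield ("data entry cost", f"{sign}{d:.0%}",
               replace(inputs, entry_day_wage=inputs.wage_entry * factor),
               inputs.wage_entry * factor)
    for sign, factor in (("-", 1.0 - d), ("+", 1.0 + d)):
        yield ("data collection cost", f"{sign}{d:.0%}",
               replace(inputs, collection_day_wage=inputs.wage_collection * factor),
               inputs.wage_collection * factor)
    combined = inputs.hardware_cost + inputs.software_cost
    for sign, factor in (("-", 1.0 - d), ("+", 1.0 + d)):
        yield ("hardware and software cost", f"{sign}{d:.0%}",
               replace(inputs, hardware_cost=inputs.hardware_cost * factor,
                       software_cost=inputs.software_cost * factor),
               combined * factor)


def scenario_table(inputs: BudgetInputs, perturbation: float = 0.10
                   ) -> pd.DataFrame:
    """One-at-a-time perturbation table: GM, MRR, and their changes
    versus the base scenario, each re-evaluated from scratch."""
    base = evaluate(inputs)
    rows = []
    for name, direction, pert, value in _scenarios(inputs, perturbation):
        res = evaluate(pert)
        rows.append(ScenarioRow(
            varied_input=name, direction=direction, perturbed_value=value,
            gross_margin=res.gross_margin,
            delta_gm=res.gross_margin - base.gross_margin,
            mrr=res.marginal_return_rate,
            delta_mrr=res.marginal_return_rate - base.marginal_return_rate,
        ))
    return pd.DataFrame([r.__dict__ for r in rows])


#: Inputs randomized by default in the Monte-Carlo analysis, with the
#: attribute path used to perturb them.
MC_INPUTS = ("DMY annual change", "DO annual change", "herd size",
             "data entry cost", "data collection cost",
             "hardware and software cost")


@dataclass
class MonteCarloResult:
    n_draws: int
    seed: int
    draws: pd.DataFrame          # sampled input values + GM, MRR per draw
    correlations: pd.DataFrame   # per input: r with GM, r with MRR


def _apply_draw(inputs: BudgetInputs, name: str, value: float) -> BudgetInputs:
    if name.endswith("annual change"):
        trait = name.split()[0]
        traits = tuple(replace(t, annual_change=value) if t.name == trait else t
                       for t in inputs.traits)
        return replace(inputs, traits=traits)
    if name == "herd size":
        return replace(inputs, herd_cows=value)
    if name == "data entry cost":
        return replace(inputs, entry_day_wage=value)
    if name == "data collection cost":
        return replace(inputs, collection_day_wage=value)
    if name == "hardware and software cost":
        combined = inputs.hardware_cost + inputs.software_cost
        share = inputs.hardware_cost / combined if combined else 0.5
        return replace(inputs, hardware_cost=value * share,
                       software_cost=value * (1 - share))
    raise KeyError(name)


def _base_value(inputs: BudgetInputs, name: str) -> float:
    if name.endswith("annual change"):
        trait = name.split()[0]
        return next(t.annual_change for t in inputs.traits if t.name == trait)
    if name == "herd size":
        return inputs.herd_cows
    if name == "data entry cost":
        return inputs.wage_entry
    if name == "data collection cost":
        return inputs.wage_collection
    if name == "hardware and software cost":
        return inputs.hardware_cost + inputs.software_cost
    raise KeyError(name)


def monte_carlo(inputs: BudgetInputs,
                spec: dict[str, tuple[float, float]] | None = None,
                n_draws: int = 10_000, seed: int = 42) -> MonteCarloResult:
    """Joint independent sampling of budget inputs with per-draw budget
    evaluation.

    ``spec`` maps input names to (low, high) uniform bounds; by default
    every input in :data:`MC_INPUTS` spans +/-10% around its base value.
    Degenerate (zero-variance) inputs get an undefined (NaN) correlation.
    """
    if n_draws < 100:
        raise ValueError("n_draws must be >= 100")
    if spec is None:
        spec = {}
        for name in MC_INPUTS:
            base = _base_value(inputs, name)
            lo, hi = sorted((0.9 * base, 1.1 * base))
            spec[name] = (lo, hi)
    rng = np.random.default_rng(seed)
    names = list(spec)
    samples = {n: rng.uniform(*spec[n], n_draws) for n in names}
    gm = np.empty(n_draws)
    mrr = np.empty(n_draws)
    for i in range(n_draws):
        cur = inputs
        for n in names:
            cur = _apply_draw(cur, n, samples[n][i])
        res = evaluate(cur)
        gm[i] = res.gross_margin
        mrr[i] = res.marginal_return_rate
    draws = pd.DataFrame(samples)
    draws["gross_margin"] = gm
    draws["mrr"] = mrr
    corr_rows = []
    for n in names:
        x = samples[n]
        if np.std(x) == 0:
            corr_rows.append((n, np.nan, np.nan))
        else:
            corr_rows.append((n,
                              float(np.corrcoef(x, gm)[0, 1]),
                              float(np.corrcoef(x, mrr)[0, 1])))
    corrs = pd.DataFrame(corr_rows, columns=["input", "r_gm", "r_mrr"]
                         ).set_index("input")
    return MonteCarloResult(n_draws=n_draws, seed=seed, draws=draws,
                            correlations=corrs)
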