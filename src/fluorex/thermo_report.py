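"""Four-state conformational model assembly and tabular reporting.

The slow (seconds) fold-switch equilibrium between the inactive and active
manifolds and the fast (milliseconds) compact/extended equilibrium within
each manifold combine, under timescale separation, into a four-state
network.  Joint state populations are products of the manifold population
and the conditional within-manifold population; free-energy levels follow
from Boltzmann inversion of the joint populations.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import pandas as pd

from .constants import R_KCAL, T_DEFAULT
from .exchange_models import SlowExchangeParams, TwoStateFastParams

__all__ = [
    "FourStateModel",
    "assemble_four_state_model",
    "free_energy_levels",
    "render_results_tables",
]

#: Canonical state order: manifold x conformation.
STATE_ORDER = (
    "inactive-compact",
    "inactive-extended",
    "active-extended",
    "active-compact",
)


@dataclass(frozen=True)
class FourStateModel:
    """The assembled active/inactive x compact/extended network.

    ``populations`` maps each state name in :data:`STATE_ORDER` to its
    joint population; ``slow`` holds the inter-manifold rates and
    ``fast_inactive``/``fast_active`` the within-manifold equilibria.
    """

    populations: dict
    slow: SlowExchangeParams
    fast_inactive: TwoStateFastParams
    fast_active: TwoStateFastParams
    condition: str
    temperature: float = T_DEFAULT

    def __post_init__(self) -> None:
        total = sum(self.populations.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"joint populations sum to {total}, not 1")
        if any(p < 0 for p in self.populations.values()):
            raise ValueError("populations must be non-negative")


def assemble_four_state_model(
    slow: SlowExchangeParams,
    fast_inactive: TwoStateFastParams,
    fast_active: TwoStateFastParams,
    temperature: float = T_DEFAULT,
    condition: str | None = None,
    p_extended_inactive: float | None = None,
    p_extended_active: float | None = None,
) -> FourStateModel:
    """Combine slow and fast equilibria into joint state populations.

    The fast equilibria are treated as conditionally independent within
    each slow manifold (the processes are separated by three orders of
    magnitude in rate), so e.g.

        p(inactive-compact) = p_inactive * p_compact|inactive.

    The dispersion fit alone does not say which of its two populations is
    the extended conformation; by default the minor state is taken as
    extended in the inactive manifold and the major state as extended in
    the active manifold (the assignment supported by solvent-exposure
    shifts).  Override with ``p_extended_*`` if assigning differently.
    """
    if condition is None:
        condition = slow.condition
    elif condition != slow.condition:
        raise ValueError(
            f"condition mismatch: {condition!r} vs slow params {slow.condition!r}"
        )
    if p_extended_inactive is None:
        p_extended_inactive = min(fast_inactive.p_a, fast_inactive.p_b)
    if p_extended_active is None:
        p_extended_active = max(fast_active.p_a, fast_active.p_b)

    populations = {
        "inactive-compact": slow.p_inactive * (1.0 - p_extended_inactive),
        "inactive-extended": slow.p_inactive * p_extended_inactive,
        "active-extended": slow.p_active * p_extended_active,
        "active-compact": slow.p_active * (1.0 - p_extended_active),
    }
    return FourStateModel(
        populations=populations,
        slow=slow,
        fast_inactive=fast_inactive,
        fast_active=fast_active,
        condition=condition,
        temperature=temperature,
    )


def free_energy_levels(model: FourStateModel) -> dict:
    """Free energy of each state relative to the most populated one.

    dG_state = -RT ln(p_state / p_ref), kcal/mol; the reference (most
    populated) state sits at 0 and less populated states lie higher.  A
    zero population gives an unbounded level, reported as +inf.
    """
    rt = R_KCAL * model.temperature
    p_ref = max(model.populations.values())
    levels = {}
    for state in STATE_ORDER:
        p = model.populations[state]
        levels[state] = math.inf if p == 0 else -rt * math.log(p / p_ref)
    return levels


def _fmt(x, nd=3):
    if x is None or (isinstance(x, float) and math.isnan(x)):
        return "nan"
    # round-half-even at display precision; full precision stays in the
    # machine-readable columns
    return f"{round(float(x), nd):.{nd}f}"


def render_results_tables(
    models: dict,
    slow_fits: dict,
    global_fits: dict,
    shifts: dict | None = None,
    precision: int = 3,
) -> str:
    """Tab-separated report mirroring the two standard result tables.

    ``models`` maps condition -> FourStateModel, ``slow_fits`` condition ->
    SlowExchangeParams, ``global_fits`` resonance -> GlobalFitResult,
    ``shifts`` optionally (resonance, condition) -> ppm.  The report has a
    slow-exchange block (rates, populations, k_s, dG) and, when dispersion
    fits are present, a fast-exchange block (k_i, populations, |ddelta|);
    a third block lists the joint four-state populations and free-energy
    levels.  Display values are rounded half-even; a full-precision column
    accompanies each.
    """
    if not slow_fits:
        raise ValueError("at least one condition is required")
    buf = io.StringIO()
    conditions = sorted(slow_fits)

    rows = []
    for cond in conditions:
        s = slow_fits[cond]
        u = s.uncertainties
        rows.append(
            {
                "condition": cond,
                "k_IA_s-1": _fmt(s.k_mn, precision),
                "k_AI_s-1": _fmt(s.k_nm, precision),
                "k_s_s-1": _fmt(s.k_s, precision),
                "p_active": _fmt(s.p_active, precision),
                "p_inactive": _fmt(s.p_inactive, precision),
                "dG_active_minus_inactive_kcal_mol": _fmt(s.delta_g, precision),
                "dG_err": _fmt(u.get("delta_g", math.nan), precision),
                "k_s_full": repr(s.k_s),
                "dG_full": repr(s.delta_g),
            }
        )
    buf.write("# table: slow_exchange (saturation transfer)\n")
    pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)

    if global_fits:
        rows = []
        for resonance in sorted(global_fits):
            g = global_fits[resonance]
            for cond in sorted(g.per_condition):
                p = g.per_condition[cond]
                shift = (shifts or {}).get((resonance, cond), math.nan)
                rows.append(
                    {
                        "condition": cond,
                        "resonance": resonance,
                        "shift_ppm": _fmt(shift, 1),
                        "k_i_s-1": _fmt(p.k_i, 0),
                        "p_major": _fmt(max(p.p_a, p.p_b), precision),
                        "p_minor": _fmt(min(p.p_a, p.p_b), precision),
                        "abs_ddelta_ppm": _fmt(g.delta_delta, precision),
                        "k_i_full": repr(p.k_i),
                        "ddelta_full": repr(g.delta_delta),
                        "converged": g.converged,
                    }
                )
        buf.write("# table: fast_exchange (CPMG relaxation dispersion)\n")
        pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)

    if models:
        rows = []
        for cond in sorted(models):
            m = models[cond]
            levels = free_energy_levels(m)
            for state in STATE_ORDER:
                rows.append(
                    {
                        "condition": cond,
                        "state": state,
                        "population": _fmt(m.populations[state], precision),
                        "dG_vs_ground_kcal_mol": _fmt(levels[state], precision),
                        "population_full": repr(m.populations[state]),
                    }
                )
        buf.write("# table: four_state_model\n")
        pd.DataFrame(rows).to_csv(buf, sep="\t", index=False)

    return buf.getvalue()
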