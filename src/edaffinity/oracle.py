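"""Brute-force equilibrium oracle.

An independent re-derivation of the two-chamber competitive equilibrium used
only as a cross-check against :func:`edaffinity.binding.solve_equilibrium`.
It shares no code with the production solver: the mass balances are written
out from scratch and resolved by fixed-count exhaustive nested bisection.
"""

from __future__ import annotations

import math

from .binding import BindingSystem, EquilibriumState

_ITERATIONS = 90  # halves the bracket 90 times: width / 2^90, far below 1e-6 nM


def oracle_equilibrium(system: BindingSystem) -> EquilibriumState:
    """Exhaustive nested-bisection solution of the cassette equilibrium."""
    vs = system.geometry.v_sample
    vb = system.geometry.v_buffer
    sites = system.sites.site_conc * system.sites.valence

    amt_t = system.tracer.initial_amount
    kd_t = system.tracer.kd_site
    if system.inhibitor is None:
        amt_i = 0.0
        kd_i = math.inf
    else:
        amt_i = system.inhibitor.initial_amount
        kd_i = system.inhibitor.kd_site

    def occupancy_t(ft: float, fi: float) -> float:
        # Langmuir competitive isotherm, tracer site occupancy * site conc
        t_term = ft / kd_t if kd_t != math.inf else 0.0
        i_term = fi / kd_i if kd_i != math.inf else 0.0
        return sites * t_term / (1.0 + t_term + i_term)

    def occupancy_i(ft: float, fi: float) -> float:
        t_term = ft / kd_t if kd_t != math.inf else 0.0
        i_term = fi / kd_i if kd_i != math.inf else 0.0
        return sites * i_term / (1.0 + t_term + i_term)

    def inhibitor_free(ft: float) -> float:
        if amt_i <= 0.0:
            return 0.0
        low = 0.0
        high = amt_i / (vs + vb)
        for _ in range(_ITERATIONS):
            fi = (low + high) / 2.0
            total = fi * (vs + vb) + occupancy_i(ft, fi) * vs
            if total > amt_i:
                high = fi
            else:
                low = fi
        return (low + high) / 2.0

    if amt_t <= 0.0:
        ft = 0.0
    else:
        low = 0.0
        high = amt_t / (vs + vb)
        for _ in range(_ITERATIONS):
            ft = (low + high) / 2.0
            fi = inhibitor_free(ft)
            total = ft * (vs + vb) + occupancy_t(ft, fi) * vs
            if total > amt_t:
                high = ft
            else:
                low = ft
        ft = (low + high) / 2.0
    fi = inhibitor_free(ft)
    return EquilibriumState(ft, fi, occupancy_t(ft, fi), occupancy_i(ft, fi))
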