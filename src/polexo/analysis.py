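"""Derived quantities: site occupancies, thermodynamics, and mismatch fate.

The fate of a mismatched primer is computed two independent ways — ODE
integration to absorption and branch-probability algebra on the embedded
jump chain — and the two routes are required to agree, which guards the
numerics of both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .engine import Phase, Protocol, integrate_with_extents
from .flux import completion_horizon
from .models import KineticScheme

__all__ = [
    "R_GAS",
    "ThermoResult",
    "FateReport",
    "InternalConsistencyError",
    "pol_site_occupancy",
    "reverse_transfer_rate",
    "vant_hoff",
    "fold_change",
    "mismatch_fate",
    "contribution_factor",
]

R_GAS = 8.314  # J/(mol K)

FATE_ROUTE_TOL = 1e-4


class InternalConsistencyError(RuntimeError):
    """The two independent fate computations disagree."""


def pol_site_occupancy(K3: float) -> float:
    """Percentage of enzyme-bound DNA at the pol site at internal
    equilibrium: 100 / (1 + K3)."""
    if K3 <= 0:
        raise ValueError("K3 must be positive")
    return 100.0 / (1.0 + K3)


def reverse_transfer_rate(k3: float, K3: float) -> float:
    """Rate of transfer back from the exo to the pol site: k3 / K3."""
    if K3 <= 0:
        raise ValueError("K3 must be positive")
    return k3 / K3


def fold_change(K_a: float, K_b: float) -> float:
    if K_b <= 0:
        raise ValueError("reference equilibrium constant must be positive")
    return K_a / K_b


@dataclass
class ThermoResult:
    delta_G: float       # kJ/mol at the higher temperature
    delta_H: float       # kJ/mol
    temperatures: tuple[float, float]  # K (low, high)
    K_values: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "delta_G_kJ_mol": self.delta_G,
            "delta_H_kJ_mol": self.delta_H,
            "temperatures_K": list(self.temperatures),
            "K_values": list(self.K_values),
        }


def vant_hoff(K_low: float, T_low: float, K_high: float, T_high: float) -> ThermoResult:
    """Two-point estimate of ΔG° (at the higher temperature) and ΔH°.

    ΔG° = −R·T_high·ln(K_high); ΔH° = R·ln(K_high/K_low)/(1/T_low − 1/T_high).
    The (K, T) pairs may be given in either order.
    """
    if min(K_low, T_low, K_high, T_high) <= 0:
        raise ValueError("all inputs must be positive")
    if T_low == T_high:
        raise ValueError("temperatures must differ")
    if T_low > T_high:
        K_low, T_low, K_high, T_high = K_high, T_high, K_low, T_low
    delta_G = -R_GAS * T_high * math.log(K_high) / 1000.0
    delta_H = R_GAS * math.log(K_high / K_low) / (1.0 / T_low - 1.0 / T_high) / 1000.0
    return ThermoResult(
        delta_G=delta_G,
        delta_H=delta_H,
        temperatures=(T_low, T_high),
        K_values=(K_low, K_high),
    )


# ---------------------------------------------------------------------------
# mismatch fate
# ---------------------------------------------------------------------------


@dataclass
class FateReport:
    """Ultimate fate of an initially mismatched primer, in percent.

    ``fraction_excised`` is material excised before any extension,
    ``fraction_extended_once`` extended once but then excised, and
    ``fraction_buried`` extended past the chain's last stage (the fraction
    escaping proofreading).  The three sum to 100.
    ``extension_is_limit`` records that an extension input was only an
    upper bound, making ``fraction_buried`` itself an upper bound.
    """

    fraction_excised: float
    fraction_extended_once: float
    fraction_buried: float
    branch_probabilities: dict[str, float]
    extension_is_limit: bool = False

    def to_dict(self) -> dict:
        return {
            "fraction_excised_pct": self.fraction_excised,
            "fraction_extended_once_pct": self.fraction_extended_once,
            "fraction_buried_pct": self.fraction_buried,
            "branch_probabilities": self.branch_probabilities,
            "extension_is_limit": self.extension_is_limit,
        }


def _jump_chain_absorption(scheme: KineticScheme) -> dict[str, float]:
    """Absorbing probabilities of the embedded jump chain.

    Requires every reaction to be unimolecular with a single product (true
    for fate schemes).  Returns probability of ultimate absorption into
    each absorbing species, starting from the initial distribution.
    """
    names = scheme.species_names
    absorbing = set(scheme.species_by_role("absorbing-product"))
    transient = [n for n in names if n not in absorbing]
    t_index = {n: i for i, n in enumerate(transient)}
    a_list = sorted(absorbing)
    a_index = {n: i for i, n in enumerate(a_list)}

    out_rate = {n: 0.0 for n in transient}
    for r in scheme.reactions:
        if len(r.reactants) != 1 or len(r.products) != 1:
            raise ValueError("jump-chain route requires a purely unimolecular scheme")
        src = r.reactants[0]
        if src in out_rate:
            out_rate[src] += r.rate_constant

    nt, na = len(transient), len(a_list)
    Q = np.zeros((nt, nt))
    Rm = np.zeros((nt, na))
    for r in scheme.reactions:
        src, dst = r.reactants[0], r.products[0]
        if src in absorbing or out_rate[src] == 0:
            continue
        p = r.rate_constant / out_rate[src]
        if dst in absorbing:
            Rm[t_index[src], a_index[dst]] += p
        else:
            Q[t_index[src], t_index[dst]] += p
    # B[i, j] = P(absorb in j | start in transient i)
    B = np.linalg.solve(np.eye(nt) - Q, Rm)

    total = sum(scheme.initial_conditions.values())
    start = np.zeros(nt)
    for n, c in scheme.initial_conditions.items():
        if n in t_index:
            start[t_index[n]] = c / total
        elif c > 0:
            raise ValueError("initial material in an absorbing state")
    probs = start @ B
    return {n: float(probs[a_index[n]]) for n in a_list}


def _ode_absorption(scheme: KineticScheme):
    """Integrate to absorption; returns (absorbing fractions, extension
    probability through the stage-0 extension edge)."""
    horizon = completion_horizon(scheme, None)
    series, extents = integrate_with_extents(
        scheme, Protocol([Phase(horizon)]), np.array([horizon])
    )
    total = sum(scheme.initial_conditions.values())
    absorbed = {
        n: float(series[n][-1] / total)
        for n in scheme.species_by_role("absorbing-product")
    }
    p_ext0 = extents.get("k_ext[n0]", 0.0) / total
    return absorbed, p_ext0


def mismatch_fate(scheme: KineticScheme) -> FateReport:
    """Fate report for a chained excision-vs-extension scheme.

    Absorbing probabilities are computed by ODE integration to absorption
    and, independently, by jump-chain algebra; disagreement beyond 10⁻⁴
    raises :class:`InternalConsistencyError`.
    """
    absorbing = scheme.species_by_role("absorbing-product")
    if "excised" not in absorbing:
        raise ValueError("fate scheme must have an 'excised' absorbing state")

    chain = _jump_chain_absorption(scheme)
    ode_absorbed, ode_p_ext0 = _ode_absorption(scheme)

    for name in absorbing:
        if abs(chain.get(name, 0.0) - ode_absorbed.get(name, 0.0)) > FATE_ROUTE_TOL:
            raise InternalConsistencyError(
                f"ODE and jump-chain absorption for {name!r} disagree: "
                f"{ode_absorbed.get(name, 0.0):.6g} vs {chain.get(name, 0.0):.6g}"
            )

    # extension probability per stage from the jump chain (exact algebra)
    p_ext0 = _stage_extension_probability(scheme, stage=0)
    if abs(p_ext0 - ode_p_ext0) > FATE_ROUTE_TOL:
        raise InternalConsistencyError(
            f"stage-0 extension probability disagrees: ODE {ode_p_ext0:.6g} "
            f"vs chain {p_ext0:.6g}"
        )
    buried = chain.get("buried", 0.0)
    p_ext1 = buried / p_ext0 if p_ext0 > 0 else 0.0

    extension_is_limit = any(r.label == "k_ext[n1]" for r in scheme.reactions)
    return FateReport(
        fraction_excised=100.0 * (1.0 - p_ext0),
        fraction_extended_once=100.0 * (p_ext0 - buried),
        fraction_buried=100.0 * buried,
        branch_probabilities={"extend[n0]": p_ext0, "extend[n1]": p_ext1},
        extension_is_limit=extension_is_limit,
    )


def _stage_extension_probability(scheme: KineticScheme, stage: int) -> float:
    """P(leave stage ``stage`` by extension) from the jump chain, computed
    by making the stage's extension target absorbing."""
    label = f"k_ext[n{stage}]"
    edge = next((r for r in scheme.reactions if r.label == label), None)
    if edge is None:
        return 0.0
    target = edge.products[0]
    # restrict to stage species + excised + target as absorbing
    sub_reactions = [
        r
        for r in scheme.reactions
        if r.reactants[0].startswith(f"M{stage}_") or r.label == label
    ]
    from .models import KineticScheme as KS, Species

    keep = {f"M{stage}_p", f"M{stage}_x", "excised", target}
    species = [
        Species(n, "absorbing-product" if n in ("excised", target) else "complex")
        for n in keep
        if n in scheme.species_names or n in ("excised", target)
    ]
    sub = KS(
        species=species,
        reactions=sub_reactions,
        initial_conditions={f"M{stage}_p": 1.0},
        dna_moiety={},
        enzyme_moiety={},
    )
    return _jump_chain_absorption(sub).get(target, 0.0)


def contribution_factor(report: FateReport) -> tuple[float, bool]:
    """Fold contribution of proofreading to fidelity: 100 / fraction_buried.

    Returns ``(factor, is_lower_bound)``; the factor is a lower bound
    whenever the underlying extension kinetics were upper limits.  A zero
    buried fraction is reported as unbounded (infinity, lower-bound flag
    set)."""
    if report.fraction_buried < 0:
        raise ValueError("negative buried fraction")
    if report.fraction_buried == 0:
        return math.inf, True
    return 100.0 / report.fraction_buried, report.extension_is_limit
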