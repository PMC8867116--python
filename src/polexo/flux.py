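"""Integrated flux partitioning between competing branches of a scheme.

The flux through a reaction is its time-integrated mass-action rate
(µM of throughput).  A partition between two branches leaving the same
state is the percentage of total outflow carried by one of them.  One-way
mode integrates forward rates only; net mode subtracts the reverse rate
when a reverse reaction exists.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .engine import Phase, Protocol, _Compiled, _solve, integrate_with_extents
from .models import KineticScheme

__all__ = [
    "FluxPartition",
    "UndefinedPartitionError",
    "integrated_flux",
    "binding_partition",
    "edp_partition",
    "completion_horizon",
]

REACTION_COMPLETE = "reaction-complete"


class UndefinedPartitionError(ZeroDivisionError):
    pass


@dataclass
class FluxPartition:
    from_state: str
    branch_a: str
    branch_b: str
    percent_a: float
    mode: str
    horizon: float | str
    notice: str | None = None

    @property
    def percent_b(self) -> float:
        return 100.0 - self.percent_a

    def to_dict(self) -> dict:
        return {
            "from_state": self.from_state,
            "branch_a": self.branch_a,
            "branch_b": self.branch_b,
            "percent_a": self.percent_a,
            "percent_b": self.percent_b,
            "mode": self.mode,
            "horizon": self.horizon,
            "notice": self.notice,
        }


def completion_horizon(scheme: KineticScheme, protocol: Protocol | None = None) -> float:
    """Time at which the reaction is effectively complete (all derivatives
    below the engine's equilibrium tolerance), found by window doubling."""
    comp = _Compiled(scheme)
    y = comp.initial_state()
    if protocol is not None:
        for phase in protocol.phases:
            for name, conc in phase.injections.items():
                y[comp.index[name]] += conc
    window = 0.01
    total = 0.0
    for _ in range(40):
        y = _solve(comp, y, (0.0, window), np.array([window]), "completion horizon")[:, -1]
        total += window
        if np.max(np.abs(comp.rhs(0.0, y))) < 1e-8:
            return total
        window *= 10.0
    raise RuntimeError("reaction did not reach completion within the horizon search")


def _edges(scheme: KineticScheme, src: str, dst: str):
    forward = [
        r for r in scheme.reactions if src in r.reactants and dst in r.products
    ]
    reverse = [
        r for r in scheme.reactions if dst in r.reactants and src in r.products
    ]
    return forward, reverse


def _resolve_horizon(scheme, protocol, horizon) -> float:
    if horizon == REACTION_COMPLETE:
        return completion_horizon(scheme, protocol)
    return float(horizon)


def integrated_flux(
    scheme: KineticScheme,
    protocol: Protocol | None,
    from_species: str,
    to_species: str,
    mode: str = "one-way",
    horizon: float | str = REACTION_COMPLETE,
) -> float:
    """Time-integrated flux (µM) from one species to another.

    One-way mode returns ∫ rate_forward dt; net mode returns
    ∫ (rate_forward − rate_reverse) dt over the horizon.
    """
    if mode not in ("one-way", "net"):
        raise ValueError(f"unknown flux mode {mode!r}")
    forward, reverse = _edges(scheme, from_species, to_species)
    if not forward:
        raise ValueError(f"no reaction {from_species} -> {to_species} in scheme")
    t_end = _resolve_horizon(scheme, protocol, horizon)
    if protocol is None:
        protocol = Protocol([Phase(t_end)])
    else:
        protocol = Protocol(
            [p for p in protocol.phases if p.duration == "to-equilibrium"]
            + [Phase(t_end)]
        )
    _, extents = integrate_with_extents(scheme, protocol, np.array([t_end]))
    flux = sum(extents[r.label] for r in forward)
    if mode == "net":
        flux -= sum(extents[r.label] for r in reverse)
    return flux


def _partition(
    scheme, protocol, from_state, branch_a, branch_b, mode, horizon, notice=None
) -> FluxPartition:
    fa = integrated_flux(scheme, protocol, from_state, branch_a, mode, horizon)
    fb = integrated_flux(scheme, protocol, from_state, branch_b, mode, horizon)
    total = fa + fb
    if total <= 0:
        raise UndefinedPartitionError(
            f"zero total flux out of {from_state} over the horizon"
        )
    return FluxPartition(
        from_state=from_state,
        branch_a=branch_a,
        branch_b=branch_b,
        percent_a=100.0 * fa / total,
        mode=mode,
        horizon=horizon,
        notice=notice,
    )


def binding_partition(
    scheme: KineticScheme,
    protocol: Protocol | None = None,
    mode: str = "one-way",
    horizon: float | str = REACTION_COMPLETE,
) -> FluxPartition:
    """Percentage of DNA binding events going directly to the exo site
    (branch_a = ED_x) versus the pol site (branch_b = ED_p)."""
    for name in ("D", "ED_p", "ED_x"):
        if name not in scheme.species_names:
            raise ValueError("scheme lacks the two binding branches")
    return _partition(scheme, protocol, "D", "ED_x", "ED_p", mode, horizon)


def edp_partition(
    scheme: KineticScheme,
    protocol: Protocol | None = None,
    mode: str = "one-way",
    horizon: float | str = REACTION_COMPLETE,
) -> FluxPartition:
    """Percentage of pol-site complex outflow transferring to the exo site
    (branch_a = ED_x) versus the inhibited state (branch_b = ED_I).

    When the inhibited branch is absent the partition is reported as 100%
    to ED_x with an explanatory notice instead of an error.
    """
    if "ED_I" not in scheme.species_names:
        return FluxPartition(
            from_state="ED_p",
            branch_a="ED_x",
            branch_b="ED_I",
            percent_a=100.0,
            mode=mode,
            horizon=horizon,
            notice="inhibited-state branch absent from scheme; partition trivially 100%",
        )
    return _partition(scheme, protocol, "ED_p", "ED_x", "ED_I", mode, horizon)
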