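"""Synthetic quench-flow-like datasets and the bundled parameter catalogue.

The catalogue transcribes the fitted rate-constant tables for the four
experiment families (terminal-mismatch excision at 4 °C and 20 °C,
buried-mismatch excision at 20 °C, buried-mismatch extension at 20 °C)
plus the Michaelis–Menten / upper-limit extension kinetics used by the
fate analysis.  Entries keep their printed standard errors and upper-limit
or not-determined markers, so limit semantics survive a round trip.

Generators produce noiseless means identical to the simulation engine's
output, with optional proportional-plus-floor Gaussian noise applied per
replicate under a seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .engine import TimeCourse, default_protocol, integrate, log_time_grid, observe
from .models import (
    ExtensionParams,
    MismatchExtensionKinetics,
    ProofreadingParams,
    build_extension_scheme,
    build_proofreading_scheme,
)

__all__ = [
    "Value",
    "Fixture",
    "NoiseModel",
    "ExperimentDesign",
    "fixtures",
    "generate_excision",
    "generate_extension",
    "catalogue_to_dict",
    "catalogue_from_dict",
]


@dataclass(frozen=True)
class Value:
    """One tabulated number with its uncertainty semantics.

    ``limit="<"`` marks an upper bound; ``nd`` marks a value whose standard
    error was not determined; ``locked`` marks a constant that was held
    fixed rather than fitted.
    """

    value: float | None
    stderr: float | None = None
    limit: str | None = None
    locked: bool = False
    nd: bool = False


@dataclass(frozen=True)
class Fixture:
    table: str
    row: str
    temperature: str  # °C label
    entries: dict[str, Value]

    def get(self, name: str) -> float | None:
        v = self.entries.get(name)
        return None if v is None else v.value

    # -- conversions -------------------------------------------------------
    def proofreading_params(self) -> ProofreadingParams:
        k4 = self.get("k4")
        km4 = self.get("k-4")
        if (k4 is None) != (km4 is None):  # lone limit cell: drop the branch
            k4 = km4 = None
        return ProofreadingParams(
            k2=self.get("k2") or 0.0,
            k3=self.get("k3") or 0.0,
            K3=self.get("K3"),
            k4=k4,
            k_minus4=km4,
        )

    def extension_params(self, dntp_conc: float = 500.0) -> ExtensionParams:
        """Two-state extension parameters.

        Rows with only a rate upper limit have no collision/primed split;
        they are modelled as fully primed material extending at the rate
        implied by the kcat/Km bound at ``dntp_conc`` µM.
        """
        k1p, km1p, kpol = self.get("k1'"), self.get("k-1'"), self.get("k_pol")
        if k1p is None or km1p is None:
            limit = self.entries.get("kcat_over_Km_limit")
            if limit is None or limit.value is None:
                raise KeyError(
                    f"fixture ({self.table}, {self.row}) has no usable extension kinetics"
                )
            rate = limit.value * dntp_conc * 1e-6
            return ExtensionParams(
                k1_prime=1.0, k_minus1_prime=0.0, k_pol=rate, dntp_conc=dntp_conc
            )
        return ExtensionParams(
            k1_prime=k1p, k_minus1_prime=km1p, k_pol=kpol or 0.0, dntp_conc=dntp_conc
        )

    def extension_kinetics(self) -> MismatchExtensionKinetics:
        if self.get("kcat") is not None:
            return MismatchExtensionKinetics(kcat=self.get("kcat"), Km=self.get("Km"))
        return MismatchExtensionKinetics(
            kcat_over_Km_limit=self.get("kcat_over_Km_limit")
        )


def _v(value, stderr=None, limit=None, locked=False, nd=False):
    return Value(value, stderr, limit, locked, nd)


def _excision_row(flux_bind, flux_tr, k3, K3, k2, k4, km4):
    return {
        "flux_to_exo_pct": flux_bind,
        "flux_transfer_pct": flux_tr,
        "k3": k3,
        "K3": K3,
        "k2": k2,
        "k4": k4,
        "k-4": km4,
    }


# fitted constants for the four experiment families; locked companions
# (k1 = 300 µM⁻¹s⁻¹, k-1 = k-2 = 0.2 s⁻¹, k_exo = 1000 s⁻¹) are defaults of
# ProofreadingParams.  None means the step was absent from the model.
_EXCISION_4C = {
    "0": _excision_row(_v(1, limit="<"), None, _v(0.0003), _v(0.01, limit="<"), None, None, None),
    "1": _excision_row(_v(3), _v(7), _v(0.28, 0.10), _v(0.033), _v(9.8, 1.5), _v(4.0, 1.9), _v(0.5, limit="<")),
    "2": _excision_row(_v(4), _v(35), _v(4.4, 0.7), _v(0.042), _v(12.7, 4.1), _v(10.5, 2.6), _v(1.0, 0.5)),
    "3": _excision_row(_v(14), _v(45), _v(3.7, 0.7), _v(0.157), _v(47, 4), _v(9.2, 3.0), _v(2.6, 0.8)),
    "4": _excision_row(_v(27), _v(76), _v(7.2, 0.3), _v(0.360), _v(108, 3), _v(2.9, 0.5), _v(0.72, 0.45)),
    "5": _excision_row(_v(32), _v(76), _v(12.0, 0.7), _v(0.463), _v(139, 5), _v(5.1, 0.8), _v(1.13, 0.44)),
}

_EXCISION_20C = {
    "0": _excision_row(_v(1, limit="<"), None, _v(0.023, 0.006), _v(0.0087), _v(2.6, 1.6), None, None),
    "1": _excision_row(_v(6), _v(38), _v(2.9, 0.3), _v(0.061), _v(18.3, 3.5), _v(5.42, 0.73), _v(0.33, 0.05)),
    "2": _excision_row(_v(33), _v(78), _v(7.7, 0.7), _v(0.473), _v(142, 7), _v(2.22, 0.96), _v(3.2, 1.2)),
    "3": _excision_row(_v(37), _v(82), _v(16.6, 1.8), _v(0.573), _v(172, 11), _v(3.9, 1.2), _v(1.8, 0.7)),
    "4": _excision_row(_v(50), _v(100), _v(69, 8), _v(1.003), _v(301, 25), None, None),
    "5": _excision_row(_v(59), _v(100), _v(102, 10), _v(1.400), _v(420, 28), None, None),
}

_BURIED_EXCISION_20C = {
    "n-0": _excision_row(_v(6), _v(35), _v(2.9, 0.3), _v(0.061), _v(18.3, 3.5), _v(5.42, 0.73), _v(0.33, 0.05)),
    "n-1": _excision_row(_v(38), _v(88), _v(14.9, 1.3), _v(0.597), _v(179, 11), _v(2.33, 0.58), _v(0.62, 0.27)),
    "n-2": _excision_row(_v(55), _v(100), _v(31, 3), _v(1.193), _v(357, 24), None, None),
    "n-3": _excision_row(_v(29), _v(72), _v(7.3, 0.6), _v(0.393), _v(118, 6), _v(3.0, 0.7), _v(2.3, 0.4)),
    "n-4": _excision_row(_v(1, limit="<"), None, _v(0.22, 0.01), _v(0.007), _v(2, limit="<"), None, None),
    "n-5": _excision_row(_v(5), None, _v(0.29, 0.01), _v(0.049), _v(14.7, 3.1), None, None),
    "n-7": _excision_row(_v(1, limit="<"), None, _v(0.078, 0.003), _v(0.007), _v(2, limit="<"), None, None),
    "n-10": _excision_row(_v(1, limit="<"), None, _v(0.028, 0.001), _v(0.007), _v(2, limit="<"), None, None),
}


def _extension_row(k_pol, primed_pct, k1p, km1p, limit=None):
    row = {
        "k_pol": k_pol,
        "fraction_primed_pct": primed_pct,
        "k1'": k1p,
        "k-1'": km1p,
    }
    if limit is not None:
        row["kcat_over_Km_limit"] = limit
    return row


_BURIED_EXTENSION_20C = {
    "n-1": _extension_row(_v(0.001, limit="<"), None, None, None, limit=_v(0.1, limit="<")),
    "n-2": _extension_row(_v(0.001, limit="<"), None, None, None, limit=_v(0.1, limit="<")),
    "n-3": _extension_row(_v(13.2, 9.6), _v(36), _v(0.82, 0.25), _v(1.46, 1.38)),
    "n-5": _extension_row(_v(400, locked=True), _v(61), _v(8.1, 5.2), _v(5.2, 4.1)),
    "n-7": _extension_row(_v(400, locked=True), _v(93), _v(2, nd=True), _v(0.15, nd=True)),
    "n-10": _extension_row(_v(400, locked=True), _v(98), _v(1.5, nd=True), _v(0.04, nd=True)),
}

# steady-state extension kinetics used by the fate analysis: measured
# Michaelis–Menten constants for a terminal mismatch, upper limits for
# mismatches buried by one or two correct bases
_MISMATCH_EXTENSION = {
    "n-0": {"kcat": _v(0.025), "Km": _v(87)},
    "n-1": {"kcat_over_Km_limit": _v(0.1, limit="<")},
    "n-2": {"kcat_over_Km_limit": _v(0.1, limit="<")},
}

_TABLES: dict[str, tuple[str, dict]] = {
    "excision_4C": ("4", _EXCISION_4C),
    "excision_20C": ("20", _EXCISION_20C),
    "buried_excision_20C": ("20", _BURIED_EXCISION_20C),
    "buried_extension_20C": ("20", _BURIED_EXTENSION_20C),
    "mismatch_extension": ("20", _MISMATCH_EXTENSION),
}


def fixtures() -> dict[tuple[str, str], Fixture]:
    """Catalogue of every tabulated parameter set, keyed by (table, row)."""
    out = {}
    for table, (temp, rows) in _TABLES.items():
        for row, entries in rows.items():
            out[(table, row)] = Fixture(table, row, temp, dict(entries))
    return out


def get_fixture(table: str, row: str) -> Fixture:
    cat = fixtures()
    try:
        return cat[(table, row)]
    except KeyError:
        raise KeyError(f"no fixture ({table!r}, {row!r}); known tables: {sorted(_TABLES)}")


# ---------------------------------------------------------------------------
# noise and experiment designs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NoiseModel:
    """Proportional Gaussian noise with a small additive floor, truncated
    at zero concentration."""

    proportional_sd: float = 0.05
    floor_sd: float = 0.002  # µM

    def __post_init__(self) -> None:
        if self.proportional_sd < 0 or self.floor_sd < 0:
            raise ValueError("noise components must be non-negative")

    def apply(self, rng: np.random.Generator, mean: np.ndarray) -> np.ndarray:
        sd = np.hypot(self.proportional_sd * mean, self.floor_sd)
        return np.clip(rng.normal(mean, sd), 0.0, None)


@dataclass
class ExperimentDesign:
    substrate_id: str
    table: str
    row: str
    conc_E: float = 1.0
    conc_D: float = 0.25
    times: np.ndarray = field(default_factory=lambda: log_time_grid(1e-3, 10.0, 20))
    replicates: int = 1
    seed: int = 0
    noise: NoiseModel | None = field(default_factory=NoiseModel)
    dntp_conc: float = 500.0  # µM, extension experiments only

    def fixture(self) -> Fixture:
        return get_fixture(self.table, self.row)


def _generate(design: ExperimentDesign, scheme, observable: str) -> list[TimeCourse]:
    protocol = default_protocol(scheme, float(design.times[-1]))
    series = integrate(scheme, protocol, design.times)
    mean = observe(
        scheme,
        series,
        observable,
        design.times,
        substrate_id=design.substrate_id,
        temperature=design.fixture().temperature,
    ).values
    rng = np.random.default_rng(design.seed)
    out = []
    for rep in range(design.replicates):
        values = mean if design.noise is None else design.noise.apply(rng, mean)
        out.append(
            TimeCourse(
                substrate_id=design.substrate_id,
                temperature=design.fixture().temperature,
                times=design.times.copy(),
                values=values.copy(),
                observable=observable,
                replicate=rep,
            )
        )
    return out


def generate_excision(design: ExperimentDesign) -> list[TimeCourse]:
    """Remaining-primer decay replicates for an excision fixture."""
    params = design.fixture().proofreading_params()
    scheme = build_proofreading_scheme(params, design.conc_E, design.conc_D)
    return _generate(design, scheme, "remaining-starting-primer")


def generate_extension(design: ExperimentDesign) -> list[TimeCourse]:
    """Extended-product replicates for an extension fixture, including the
    pre-equilibration phase before nucleotide addition."""
    params = design.fixture().extension_params(design.dntp_conc)
    scheme = build_extension_scheme(params, design.conc_E, design.conc_D)
    return _generate(design, scheme, "extended-product")


# ---------------------------------------------------------------------------
# catalogue serialization (lossless round trip)
# ---------------------------------------------------------------------------


def catalogue_to_dict(cat: dict[tuple[str, str], Fixture]) -> dict:
    out: dict = {}
    for (table, row), fx in sorted(cat.items()):
        entry = out.setdefault(table, {"temperature": fx.temperature, "rows": {}})
        entry["rows"][row] = {
            name: None
            if v is None
            else {
                "value": v.value,
                "stderr": v.stderr,
                "limit": v.limit,
                "locked": v.locked,
                "nd": v.nd,
            }
            for name, v in fx.entries.items()
        }
    return out


def catalogue_from_dict(data: dict) -> dict[tuple[str, str], Fixture]:
    cat = {}
    for table, entry in data.items():
        for row, entries in entry["rows"].items():
            cat[(table, row)] = Fixture(
                table,
                row,
                entry["temperature"],
                {
                    name: None if v is None else Value(**v)
                    for name, v in entries.items()
                },
            )
    return cat
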