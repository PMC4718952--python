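"""Synthetic competition-ED data generator.

Turns a :class:`~edaffinity.binding.BindingSystem` plus an assay design into
noisy replicate-level "measured" chamber concentrations — the stand-in for
the UPLC/MS/MS readout — including membrane-transport time courses and
first-order drug degradation in dilute serum.

The defaults encode the wet-assay conditions this package emulates:
100 µL sample + 300 µL buffer chambers, 5 nM deuterated tracer loaded in the
sample chamber, inhibitor loaded in the buffer chamber, triplicate
measurements with ~2 % multiplicative noise, 24 h incubation, and
dilution-dependent serum hydrolysis that is fastest for heroin, slower for
6-acetylmorphine (6-AM), and slowest for morphine.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .binding import (
    BindingSystem,
    DialysisGeometry,
    Ligand,
    AntibodySites,
    LevelScale,
    correction_factor,
    level_scale_factor,
    solve_equilibrium,
)

__all__ = [
    "DrugRates",
    "DegradationModel",
    "AssayDesign",
    "MeasuredDataset",
    "DATASET_COLUMNS",
    "degradation_remaining",
    "simulate_timecourse",
    "generate_dataset",
    "calibrate_site_conc",
    "default_titration",
    "DEFAULT_PERMEABILITY",
]

#: Passive relaxation rate (h⁻¹) of the chamber concentration difference.
#: ln(100)/6 closes ≥99 % of the gap to equilibrium by 6 h, the observed
#: tracer equilibration time.
DEFAULT_PERMEABILITY = math.log(100.0) / 6.0

DATASET_COLUMNS = [
    "condition_id",
    "inhibitor_level_nM",
    "chamber",
    "analyte",
    "replicate",
    "conc_nM",
    "dilution",
    "esterase_inhibitors",
]

NEGATIVE_CONTROL_ID = "negative_control"


@dataclass(frozen=True)
class DrugRates:
    """First-order decay rates (h⁻¹) for one drug.

    Total rate at serum dilution ``d``::

        k = buffer_rate
            + serum_rate * (reference_dilution / d)   if d < serum_cutoff_dilution
            scaled by (1 - esterase_inhibitor_efficacy) when esterase
            inhibitors are present.

    ``serum_cutoff_dilution`` captures the observed hard thresholds: above it
    serum-mediated hydrolysis is undetectable and only the spontaneous
    (buffer) term remains.
    """

    buffer_rate: float = 0.0
    serum_rate: float = 0.0
    reference_dilution: float = 400.0
    serum_cutoff_dilution: float = math.inf
    esterase_inhibitor_efficacy: float = 0.0

    def __post_init__(self) -> None:
        if self.buffer_rate < 0 or self.serum_rate < 0:
            raise ValueError("rates must be >= 0")
        if not 0.0 <= self.esterase_inhibitor_efficacy <= 1.0:
            raise ValueError("efficacy must be a fraction in [0, 1]")

    def total_rate(self, dilution: float | None, esterase_inhibitors: bool) -> float:
        k = self.buffer_rate
        if dilution is not None and dilution < self.serum_cutoff_dilution:
            serum = self.serum_rate * self.reference_dilution / dilution
            if esterase_inhibitors:
                serum *= 1.0 - self.esterase_inhibitor_efficacy
            k += serum
        return k


# Spontaneous heroin hydrolysis calibrated so 79.9 % remains after 24 h in
# buffer; serum esterase rate set so <5 % heroin survives 24 h even at 1:400.
# Esterase inhibitors (iso-OMPA/BNPP) block the serum-specific pathway
# completely, leaving only spontaneous hydrolysis.
_HEROIN_BUFFER_RATE = math.log(1.0 / 0.799) / 24.0


def _default_rate_table() -> dict[str, DrugRates]:
    return {
        "heroin": DrugRates(
            buffer_rate=_HEROIN_BUFFER_RATE,
            serum_rate=0.125,
            reference_dilution=400.0,
            serum_cutoff_dilution=math.inf,
            esterase_inhibitor_efficacy=1.0,
        ),
        # C6-ester hydrolysis of 6-AM: detectable only below 1:200 dilution
        "6-AM": DrugRates(
            buffer_rate=0.0,
            serum_rate=0.02,
            reference_dilution=25.0,
            serum_cutoff_dilution=200.0,
        ),
        # morphine: slow serum loss, undetectable at >=1:100
        "morphine": DrugRates(
            buffer_rate=0.0,
            serum_rate=0.01,
            reference_dilution=25.0,
            serum_cutoff_dilution=100.0,
        ),
    }


@dataclass(frozen=True)
class DegradationModel:
    """Per-drug first-order degradation rate table."""

    rates: dict[str, DrugRates] = field(default_factory=_default_rate_table)

    def for_drug(self, drug: str) -> DrugRates:
        try:
            return self.rates[drug]
        except KeyError:
            raise KeyError(
                f"no degradation rates for drug {drug!r}; known: {sorted(self.rates)}"
            ) from None


def degradation_remaining(
    drug: str,
    dilution: float | None,
    esterase_inhibitors: bool,
    t: float,
    model: DegradationModel | None = None,
) -> float:
    """Fraction of drug remaining intact after ``t`` hours.

    ``dilution`` is the serum dilution fold (e.g. 400 for 1:400); ``None``
    means buffer only (no serum).  Deuterated tracers degrade at the rate of
    their parent drug (a leading ``"D3-"`` prefix is stripped).
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if dilution is not None and dilution < 1:
        raise ValueError("dilution fold must be >= 1")
    model = model or DegradationModel()
    key = drug[3:] if drug.startswith("D3-") else drug
    k = model.for_drug(key).total_rate(dilution, esterase_inhibitors)
    return math.exp(-k * t)


def simulate_timecourse(
    system: BindingSystem,
    times: Sequence[float],
    permeability: float = DEFAULT_PERMEABILITY,
    dt: float = 0.005,
) -> pd.DataFrame:
    """Two-compartment relaxation of free drug toward dialysis equilibrium.

    Flux across the membrane is proportional to the free-concentration
    difference; antibody binding inside the sample chamber is treated as
    instantaneously equilibrated at every step (binding kinetics are much
    faster than membrane transport).  ``permeability`` is the passive
    relaxation rate (h⁻¹) of the concentration difference; the trajectory
    converges to the :func:`~edaffinity.binding.solve_equilibrium` state.

    Returns a tidy frame with columns ``time_h, analyte, chamber,
    total_conc_nM`` (chamber totals, i.e. free + bound in the sample
    chamber).
    """
    times = sorted(float(t) for t in times)
    if times and times[0] < 0:
        raise ValueError("times must be >= 0")
    if permeability < 0:
        raise ValueError("permeability must be >= 0")
    geom = system.geometry
    vs, vb = geom.v_sample, geom.v_buffer
    # amount-transfer coefficient (µL/h) giving the requested passive rate
    p_amount = permeability / (1.0 / vs + 1.0 / vb)

    ligands = [system.tracer] + ([system.inhibitor] if system.inhibitor else [])
    # amounts (nM·µL) per ligand per chamber
    amt_s = np.array(
        [lig.initial_amount if lig.loaded_chamber == "sample" else 0.0 for lig in ligands]
    )
    amt_b = np.array(
        [lig.initial_amount if lig.loaded_chamber == "buffer" else 0.0 for lig in ligands]
    )
    kds = np.array([lig.kd_site for lig in ligands])
    s_conc = system.sites.effective_conc

    def free_sample(amounts: np.ndarray) -> np.ndarray:
        """Free concentrations in the sample chamber given chamber amounts."""
        if s_conc == 0.0:
            return amounts / vs
        # nested bisection on free concentrations within the single chamber
        free = amounts / vs
        for _ in range(200):
            ratios = np.where(np.isinf(kds), 0.0, free / kds)
            den = 1.0 + ratios.sum()
            bound = s_conc * ratios / den
            new_free = np.maximum(amounts / vs - bound, 0.0)
            if np.max(np.abs(new_free - free)) < 1e-13:
                free = new_free
                break
            free = 0.5 * free + 0.5 * new_free
        return free

    records: list[tuple[float, str, str, float]] = []
    t_now = 0.0
    for t_target in times:
        while t_now < t_target - 1e-12:
            step = min(dt, t_target - t_now)
            f_s = free_sample(amt_s)
            f_b = amt_b / vb
            flux = p_amount * (f_s - f_b) * step  # nM·µL moved sample -> buffer
            flux = np.clip(flux, -amt_b, amt_s)
            amt_s = amt_s - flux
            amt_b = amt_b + flux
            t_now += step
        for j, lig in enumerate(ligands):
            records.append((t_target, lig.name, "sample", amt_s[j] / vs))
            records.append((t_target, lig.name, "buffer", amt_b[j] / vb))
    return pd.DataFrame(records, columns=["time_h", "analyte", "chamber", "total_conc_nM"])


@dataclass(frozen=True)
class AssayDesign:
    """Full design of one simulated competition-ED run.

    ``titration_amounts`` are loaded inhibitor amounts in nM·µL (must start
    at 0); when ``None`` a default grid of eight half-log-spaced levels
    bracketing the expected I50, plus zero, is generated.
    """

    site_conc: float
    tracer_kd: float
    inhibitor_kd: float | None = None
    tracer_conc: float = 5.0
    tracer_name: str = "D3-morphine"
    tracer_drug: str = "morphine"
    inhibitor_name: str = "morphine"
    inhibitor_drug: str | None = None
    titration_amounts: tuple[float, ...] | None = None
    geometry: DialysisGeometry = field(default_factory=DialysisGeometry)
    dilution: float | None = 400.0
    esterase_inhibitors: bool = False
    replicates: int = 3
    noise_cv: float = 0.02
    incubation_time: float = 24.0
    seed: int = 0
    i50_scale: LevelScale = "buffer-initial"
    include_negative_control: bool = True
    degradation: DegradationModel = field(default_factory=DegradationModel)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.incubation_time < 0:
            raise ValueError("incubation_time must be >= 0")
        if self.titration_amounts is not None:
            amounts = tuple(self.titration_amounts)
            if len(amounts) < 2 or amounts[0] != 0.0 or any(
                b <= a for a, b in zip(amounts, amounts[1:])
            ):
                raise ValueError("titration_amounts must be ascending and start at 0")


@dataclass
class MeasuredDataset:
    """Tidy replicate-level measured concentrations plus cassette geometry."""

    frame: pd.DataFrame
    geometry: DialysisGeometry = field(default_factory=DialysisGeometry)
    i50_scale: LevelScale = "buffer-initial"

    def __post_init__(self) -> None:
        missing = [c for c in DATASET_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns: {missing}")
        if (self.frame["conc_nM"] < 0).any():
            raise ValueError("measured concentrations must be >= 0")

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def calibrate_site_conc(
    target_b: float,
    tracer_kd: float,
    tracer_conc: float = 5.0,
    geometry: DialysisGeometry | None = None,
) -> float:
    """Antibody site concentration (nM) yielding a target bound fraction ``b``.

    ``b`` increases monotonically with site concentration, so a bracketed
    bisection on the no-inhibitor equilibrium suffices.  Used to steer
    simulated assays into the valid estimation window b ∈ [0.4, 0.7].
    """
    if not 0.0 < target_b < 1.0:
        raise ValueError("target_b must be in (0, 1)")
    geom = geometry or DialysisGeometry()

    def b_of(site: float) -> float:
        st = solve_equilibrium(BindingSystem.standard(site, tracer_kd, tracer_conc, geometry=geom))
        return st.bound_tracer / st.total_tracer_sample

    lo, hi = 0.0, max(10.0 * tracer_kd, 10.0)
    while b_of(hi) < target_b:
        hi *= 2.0
        if hi > 1e9:
            raise RuntimeError("cannot reach target b")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if b_of(mid) < target_b:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def default_titration(design: AssayDesign) -> tuple[float, ...]:
    """Eight half-log levels bracketing the expected I50, plus zero (nM·µL)."""
    if design.inhibitor_kd is None:
        raise ValueError("design has no inhibitor")
    base = BindingSystem.standard(
        design.site_conc, design.tracer_kd, design.tracer_conc, geometry=design.geometry
    )
    state = solve_equilibrium(base)
    if state.bound_tracer <= 0:
        # no binding: still emit a wide grid so the pipeline can classify
        levels = 10.0 ** np.arange(0.0, 4.0, 0.5)
    else:
        b = state.bound_tracer / state.total_tracer_sample
        t_t = (
            state.total_tracer_sample * design.geometry.v_sample
            + state.total_tracer_buffer * design.geometry.v_buffer
        ) / design.geometry.v_total
        i50_expected = design.inhibitor_kd / correction_factor(b) + t_t
        levels = i50_expected * 10.0 ** ((np.arange(8) - 3.5) * 0.5)
    amounts = levels * level_scale_factor(design.geometry, design.i50_scale)
    return (0.0, *amounts)


def _lognormal_factors(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0.0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size))


def generate_dataset(design: AssayDesign) -> MeasuredDataset:
    """Simulate one full competition-ED plate to a tidy measured dataset.

    For every condition the loaded drug amounts are first attenuated by
    first-order degradation over the incubation time (degradation and binding
    are treated as separable), the cassette equilibrium is solved exactly,
    and replicate sample/buffer-chamber tracer concentrations are drawn with
    independent mean-one multiplicative lognormal noise.  Fully reproducible
    from ``design.seed``.
    """
    rng = np.random.default_rng(design.seed)
    geom = design.geometry
    scale_div = level_scale_factor(geom, design.i50_scale)

    tracer_amount = design.tracer_conc * geom.v_sample
    tracer_remaining = degradation_remaining(
        design.tracer_drug, design.dilution, design.esterase_inhibitors,
        design.incubation_time, design.degradation,
    )
    inhibitor_drug = design.inhibitor_drug or design.inhibitor_name
    if design.inhibitor_kd is not None:
        inhibitor_remaining = degradation_remaining(
            inhibitor_drug, design.dilution, design.esterase_inhibitors,
            design.incubation_time, design.degradation,
        )
        amounts = (
            design.titration_amounts
            if design.titration_amounts is not None
            else default_titration(design)
        )
    else:
        inhibitor_remaining = 1.0
        amounts = (0.0,)

    conditions: list[tuple[str, float, float, float]] = []
    # (condition_id, site_conc, inhibitor_amount, level)
    for idx, amount in enumerate(amounts):
        cid = f"inhibitor_{idx:02d}" if amount > 0 else "inhibitor_00"
        conditions.append((cid, design.site_conc, float(amount), float(amount) / scale_div))
    if design.include_negative_control:
        conditions.append((NEGATIVE_CONTROL_ID, 0.0, 0.0, 0.0))

    rows: list[dict] = []
    for cid, site, amount, level in conditions:
        tracer = Ligand(
            design.tracer_name, design.tracer_kd, tracer_amount * tracer_remaining, "sample"
        )
        inhibitor = None
        if design.inhibitor_kd is not None and amount > 0:
            inhibitor = Ligand(
                design.inhibitor_name, design.inhibitor_kd, amount * inhibitor_remaining, "buffer"
            )
        state = solve_equilibrium(
            BindingSystem(geom, AntibodySites(site), tracer, inhibitor)
        )
        truth = {"sample": state.total_tracer_sample, "buffer": state.total_tracer_buffer}
        for chamber in ("sample", "buffer"):
            noise = _lognormal_factors(rng, design.noise_cv, design.replicates)
            for r in range(design.replicates):
                rows.append(
                    {
                        "condition_id": cid,
                        "inhibitor_level_nM": level,
                        "chamber": chamber,
                        "analyte": design.tracer_name,
                        "replicate": r + 1,
                        "conc_nM": truth[chamber] * noise[r],
                        "dilution": design.dilution if design.dilution is not None else np.nan,
                        "esterase_inhibitors": design.esterase_inhibitors,
                    }
                )
    frame = pd.DataFrame(rows, columns=DATASET_COLUMNS)
    return MeasuredDataset(frame, geom, design.i50_scale)
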