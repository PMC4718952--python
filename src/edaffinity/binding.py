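"""Mass-action equilibrium of a two-chamber dialysis cassette.

A dialysis insert holds a small *sample* chamber (default 100 µL, containing
antibody and tracer) and a larger *buffer* chamber (default 300 µL, containing
the competitive inhibitor), separated by a membrane whose molecular-weight
cutoff passes small drugs freely but retains IgG.  At equilibrium the free
concentration of every permeant ligand is therefore equal in both chambers,
while antibody-bound ligand exists only in the sample chamber.

For a single-site antibody with binding-site concentration ``S`` (nM, sample
chamber), tracer dissociation constant ``K_T`` and inhibitor dissociation
constant ``K_I``, competitive occupancy at free concentrations ``f`` (tracer)
and ``i`` (inhibitor) is

    bound_tracer    = S * (f/K_T) / (1 + f/K_T + i/K_I)
    bound_inhibitor = S * (i/K_I) / (1 + f/K_T + i/K_I)

and the equilibrium is fixed by simultaneous mass balance of both ligands
over the whole insert (free amount across both chambers plus bound amount in
the sample chamber equals the loaded amount).

Units are fixed package-wide: concentrations in nM, volumes in µL, amounts in
nM·µL (equal to attomol; 1 nM in 100 µL = 100 nM·µL).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "DialysisGeometry",
    "Ligand",
    "AntibodySites",
    "BindingSystem",
    "EquilibriumState",
    "InhibitionCurve",
    "ConvergenceError",
    "solve_equilibrium",
    "correction_factor",
    "muller_kd",
    "predict_inhibition_curve",
    "level_scale_factor",
]

#: Default chamber volumes (µL): 100 µL sample + 300 µL buffer = 400 µL insert.
DEFAULT_V_SAMPLE = 100.0
DEFAULT_V_BUFFER = 300.0

Chamber = Literal["sample", "buffer"]
LevelScale = Literal["total-volume", "buffer-initial"]


class ConvergenceError(RuntimeError):
    """Raised when the equilibrium solver fails its mass-balance residual check."""


@dataclass(frozen=True)
class DialysisGeometry:
    """Chamber volumes of one dialysis insert (µL)."""

    v_sample: float = DEFAULT_V_SAMPLE
    v_buffer: float = DEFAULT_V_BUFFER

    def __post_init__(self) -> None:
        if not (self.v_sample > 0 and self.v_buffer > 0):
            raise ValueError("chamber volumes must be positive")

    @property
    def v_total(self) -> float:
        return self.v_sample + self.v_buffer


@dataclass(frozen=True)
class Ligand:
    """A membrane-permeant small molecule loaded into one chamber.

    Parameters
    ----------
    name : str
        Identifier, e.g. ``"D3-morphine"``.
    kd_site : float
        Single-site dissociation constant versus the antibody (nM).  Use
        ``math.inf`` for a species the antibody does not bind.
    initial_amount : float
        Loaded substance amount in nM·µL (concentration × loaded volume).
    loaded_chamber : {"sample", "buffer"}
        Chamber the ligand is pipetted into at t = 0.  Irrelevant at
        equilibrium, but it drives the time-course simulator.
    """

    name: str
    kd_site: float
    initial_amount: float
    loaded_chamber: Chamber = "sample"

    def __post_init__(self) -> None:
        if not self.kd_site > 0:
            raise ValueError(f"{self.name}: kd_site must be > 0 (or inf)")
        if self.initial_amount < 0:
            raise ValueError(f"{self.name}: initial_amount must be >= 0")
        if self.loaded_chamber not in ("sample", "buffer"):
            raise ValueError(f"{self.name}: unknown chamber {self.loaded_chamber!r}")

    @classmethod
    def from_concentration(
        cls,
        name: str,
        kd_site: float,
        conc_nm: float,
        volume_ul: float,
        loaded_chamber: Chamber = "sample",
    ) -> "Ligand":
        """Build from a loading concentration (nM) and loaded volume (µL)."""
        return cls(name, kd_site, conc_nm * volume_ul, loaded_chamber)


@dataclass(frozen=True)
class AntibodySites:
    """Impermeant antibody binding sites confined to the sample chamber.

    ``site_conc`` is the nominal antibody concentration (nM); the assay
    arithmetic treats one antibody as one effective site. ``valence`` is an
    optional multiplier for users who prefer to count two IgG arms.
    """

    site_conc: float
    impermeant: bool = True
    valence: float = 1.0

    def __post_init__(self) -> None:
        if self.site_conc < 0:
            raise ValueError("site_conc must be >= 0")
        if self.valence <= 0:
            raise ValueError("valence must be > 0")
        if not self.impermeant:
            raise ValueError("antibody must be impermeant (retained by the membrane)")

    @property
    def effective_conc(self) -> float:
        return self.site_conc * self.valence


@dataclass(frozen=True)
class BindingSystem:
    """One cassette: geometry + antibody sites + tracer (+ optional inhibitor)."""

    geometry: DialysisGeometry
    sites: AntibodySites
    tracer: Ligand
    inhibitor: Ligand | None = None

    @classmethod
    def standard(
        cls,
        site_conc: float,
        tracer_kd: float,
        tracer_conc: float = 5.0,
        inhibitor_kd: float | None = None,
        inhibitor_amount: float = 0.0,
        geometry: DialysisGeometry | None = None,
        tracer_name: str = "D3-tracer",
        inhibitor_name: str = "inhibitor",
    ) -> "BindingSystem":
        """Standard assay layout: tracer at ``tracer_conc`` nM in the sample
        chamber, inhibitor amount (nM·µL) in the buffer chamber."""
        geom = geometry or DialysisGeometry()
        tracer = Ligand.from_concentration(
            tracer_name, tracer_kd, tracer_conc, geom.v_sample, "sample"
        )
        inhibitor = None
        if inhibitor_kd is not None:
            inhibitor = Ligand(inhibitor_name, inhibitor_kd, inhibitor_amount, "buffer")
        return cls(geom, AntibodySites(site_conc), tracer, inhibitor)


@dataclass(frozen=True)
class EquilibriumState:
    """Solved concentrations (nM) at dialysis equilibrium.

    Free concentrations are identical in both chambers; bound concentrations
    refer to the sample chamber.  ``total_tracer_sample`` is what an
    instrument sampling the sample chamber reports (free + bound);
    ``total_tracer_buffer`` equals the free concentration.
    """

    free_tracer: float
    free_inhibitor: float
    bound_tracer: float
    bound_inhibitor: float

    @property
    def total_tracer_sample(self) -> float:
        return self.free_tracer + self.bound_tracer

    @property
    def total_tracer_buffer(self) -> float:
        return self.free_tracer

    @property
    def total_inhibitor_sample(self) -> float:
        return self.free_inhibitor + self.bound_inhibitor

    @property
    def total_inhibitor_buffer(self) -> float:
        return self.free_inhibitor


def _ratio(free: float, kd: float) -> float:
    # f/K with K possibly infinite (non-binder -> occupancy 0)
    return 0.0 if math.isinf(kd) else free / kd


def solve_equilibrium(
    system: BindingSystem,
    tol: float = 1e-12,
    residual_rtol: float = 1e-9,
) -> EquilibriumState:
    """Solve the competitive two-chamber equilibrium exactly.

    Bracketed bisection on the free tracer concentration, with a nested
    bisection on the free inhibitor concentration at each outer step; both
    loops run to an absolute tolerance of ``tol`` nM.  Deterministic, no
    randomness.  Raises :class:`ConvergenceError` if the final mass-balance
    residual exceeds ``residual_rtol`` relative to the loaded amounts.
    """
    geom = system.geometry
    v_s, v_tot = geom.v_sample, geom.v_total
    s_conc = system.sites.effective_conc
    a_t = system.tracer.initial_amount
    k_t = system.tracer.kd_site
    if system.inhibitor is not None:
        a_i = system.inhibitor.initial_amount
        k_i = system.inhibitor.kd_site
    else:
        a_i, k_i = 0.0, math.inf

    def bound_pair(f_t: float, f_i: float) -> tuple[float, float]:
        if s_conc == 0.0:
            return 0.0, 0.0
        x_t, x_i = _ratio(f_t, k_t), _ratio(f_i, k_i)
        den = 1.0 + x_t + x_i
        return s_conc * x_t / den, s_conc * x_i / den

    def free_inhibitor_at(f_t: float) -> float:
        # inhibitor mass balance is strictly increasing in f_i
        if a_i == 0.0:
            return 0.0
        lo, hi = 0.0, a_i / v_tot
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            resid = mid * v_tot + bound_pair(f_t, mid)[1] * v_s - a_i
            if resid < 0.0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    def tracer_residual(f_t: float) -> float:
        f_i = free_inhibitor_at(f_t)
        return f_t * v_tot + bound_pair(f_t, f_i)[0] * v_s - a_t

    if a_t == 0.0:
        f_t = 0.0
    else:
        lo, hi = 0.0, a_t / v_tot
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            if tracer_residual(mid) < 0.0:
                lo = mid
            else:
                hi = mid
        f_t = 0.5 * (lo + hi)
    f_i = free_inhibitor_at(f_t)
    b_t, b_i = bound_pair(f_t, f_i)

    # mass-balance check (relative to loaded amounts)
    for amount, resid in (
        (a_t, f_t * v_tot + b_t * v_s - a_t),
        (a_i, f_i * v_tot + b_i * v_s - a_i),
    ):
        if amount > 0 and abs(resid) / amount > residual_rtol:
            raise ConvergenceError(
                f"equilibrium solver mass-balance residual {resid:.3e} nM·µL "
                f"exceeds {residual_rtol:.1e} relative on amount {amount:.3e}"
            )
    return EquilibriumState(f_t, f_i, b_t, b_i)


def correction_factor(b: float) -> float:
    """Bound-fraction correction term ``1 − 1.5·b + 0.5·b²``.

    Equal to ``(1 − b)(1 − b/2)``; multiplies the interpolated inhibition
    midpoint in the Müller estimator.  ``b`` is the fraction of tracer bound
    in the absence of inhibitor and must lie in [0, 1].
    """
    if not 0.0 <= b <= 1.0:
        raise ValueError(f"b must be in [0, 1], got {b}")
    return 1.0 - 1.5 * b + 0.5 * b * b


def muller_kd(i50: float, t_t: float, b: float) -> float:
    """Apparent dissociation constant ``K_d = (I50 − T_t)·(1 − 1.5b + 0.5b²)``.

    Parameters
    ----------
    i50 : float
        Inhibitor concentration (nM) giving 50 % inhibition of tracer binding.
    t_t : float
        Total tracer concentration (nM) in the insert after equilibration.
    b : float
        Fraction of tracer bound without inhibitor.

    Raises
    ------
    ValueError
        If ``i50 < t_t`` (a negative K_d is physically impossible) or ``b``
        is outside [0, 1].
    """
    if i50 < t_t:
        raise ValueError(f"invalid estimate: I50 ({i50}) < T_t ({t_t}) implies Kd < 0")
    return (i50 - t_t) * correction_factor(b)


def level_scale_factor(geometry: DialysisGeometry, scale: LevelScale) -> float:
    """Divisor converting a loaded inhibitor amount (nM·µL) to a reported level (nM)."""
    if scale == "total-volume":
        return geometry.v_total
    if scale == "buffer-initial":
        return geometry.v_buffer
    raise ValueError(f"unknown inhibitor level scale {scale!r}")


@dataclass
class InhibitionCurve:
    """% inhibition of tracer binding versus inhibitor level.

    ``levels`` are on the chosen reporting scale (nM); the zero-inhibitor
    point is included with 0 % inhibition.  ``sd`` and ``n`` carry replicate
    scatter when the curve comes from measured data (zeros / 1 for a
    noiseless model curve).
    """

    levels: np.ndarray
    mean_inhibition: np.ndarray
    sd: np.ndarray
    n: np.ndarray
    zero_bound: float
    scale: LevelScale = "buffer-initial"

    def __post_init__(self) -> None:
        self.levels = np.asarray(self.levels, dtype=float)
        self.mean_inhibition = np.asarray(self.mean_inhibition, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        self.n = np.asarray(self.n)
        if self.levels.ndim != 1 or len(self.levels) < 2:
            raise ValueError("curve needs at least two levels")
        if np.any(np.diff(self.levels) <= 0):
            raise ValueError("levels must be strictly increasing")
        if np.any(self.n < 1):
            raise ValueError("replicate counts must be >= 1")


def predict_inhibition_curve(
    system: BindingSystem,
    inhibitor_amounts: Sequence[float],
    scale: LevelScale = "buffer-initial",
) -> InhibitionCurve:
    """Noiseless model inhibition curve over a titration of inhibitor amounts.

    ``inhibitor_amounts`` (nM·µL, ascending, first element 0) are loaded into
    the buffer chamber one cassette at a time; % inhibition is relative to the
    zero-inhibitor bound tracer.  Raises ``ValueError`` when the system binds
    no tracer at all (inhibition undefined).
    """
    amounts = np.asarray(list(inhibitor_amounts), dtype=float)
    if len(amounts) < 2 or amounts[0] != 0.0 or np.any(np.diff(amounts) <= 0):
        raise ValueError("inhibitor_amounts must be ascending and start at 0")
    if system.inhibitor is None:
        raise ValueError("system has no inhibitor species to titrate")

    bound = []
    for amount in amounts:
        sys_a = BindingSystem(
            system.geometry,
            system.sites,
            system.tracer,
            Ligand(
                system.inhibitor.name,
                system.inhibitor.kd_site,
                float(amount),
                system.inhibitor.loaded_chamber,
            ),
        )
        bound.append(solve_equilibrium(sys_a).bound_tracer)
    bound = np.asarray(bound)
    if bound[0] <= 0.0:
        raise ValueError("zero-inhibitor bound tracer is 0; % inhibition undefined")
    inhibition = 100.0 * (1.0 - bound / bound[0])
    levels = amounts / level_scale_factor(system.geometry, scale)
    zeros = np.zeros_like(levels)
    return InhibitionCurve(levels, inhibition, zeros, np.ones_like(levels, dtype=int),
                           float(bound[0]), scale)
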