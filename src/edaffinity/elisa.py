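"""Competition-ELISA IC50 fitting and the IC50-versus-K_d discrepancy report.

Competition ELISA reads antibody affinity as the inhibitor concentration
halving the plate signal (IC50, fitted with a four-parameter logistic, 4PL).
Because the plate surface presents hapten at high local density, bivalent
IgG binds avidly and the IC50 lands orders of magnitude above the
solution-phase dissociation constant measured by equilibrium dialysis.  This
module fits 4PL curves, simulates them phenomenologically (the avidity gap
is an input, not a model), and computes IC50/K_d ratios over the bundled
reference tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "FourPLFit",
    "FixtureTables",
    "load_fixture_tables",
    "fit_4pl",
    "simulate_elisa_curve",
    "ic50_kd_ratio",
]


@dataclass
class FourPLFit:
    """Four-parameter logistic fit of normalized response vs log10 concentration.

    Model: ``y = bottom + (top − bottom) / (1 + 10^(hill·(log10 x − log10 ic50)))``
    so the response falls from ``top`` toward ``bottom`` as the inhibitor
    concentration rises; ``ic50`` is the inflection on the concentration
    scale (µM).  ``no_inhibition`` is set (and ``ic50`` is None) for flat
    curves whose response range is under 10 %.
    """

    top: float
    bottom: float
    hill: float
    ic50: float | None
    residual_ss: float
    converged: bool
    no_inhibition: bool = False


def _four_pl(logx: np.ndarray, top: float, bottom: float, log_ic50: float, hill: float) -> np.ndarray:
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logx - log_ic50)))


def fit_4pl(levels: np.ndarray, normalized_responses: np.ndarray) -> FourPLFit:
    """Least-squares 4PL fit on log10 concentration.

    ``levels`` are inhibitor concentrations (µM, > 0, ≥ 5 values spanning the
    transition); ``normalized_responses`` are % of the uninhibited signal.
    Initialization is deterministic: top/bottom from the response extremes,
    ic50 from the level nearest the half-range response, hill = 1.
    """
    x = np.asarray(levels, dtype=float)
    y = np.asarray(normalized_responses, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise ValueError("levels and responses must be matching 1-D arrays")
    if len(x) < 5:
        raise ValueError("need at least 5 concentration levels")
    if np.any(x <= 0):
        raise ValueError("levels must be > 0")

    if float(np.ptp(y)) < 10.0:
        return FourPLFit(
            top=float(y.max()), bottom=float(y.min()), hill=math.nan, ic50=None,
            residual_ss=float(np.sum((y - y.mean()) ** 2)), converged=True,
            no_inhibition=True,
        )

    logx = np.log10(x)
    top0, bottom0 = float(y.max()), float(y.min())
    half = 0.5 * (top0 + bottom0)
    log_ic50_0 = float(logx[np.argmin(np.abs(y - half))])
    p0 = (top0, bottom0, log_ic50_0, 1.0)
    span = y.max() - y.min()
    bounds = (
        [y.min() - 0.5 * span, y.min() - 0.5 * span, logx.min() - 3.0, 0.05],
        [y.max() + 0.5 * span, y.max() + 0.5 * span, logx.max() + 3.0, 10.0],
    )
    try:
        popt, _ = curve_fit(_four_pl, logx, y, p0=p0, bounds=bounds, maxfev=20000)
        converged = True
    except RuntimeError:
        popt, converged = np.array(p0), False
    top, bottom, log_ic50, hill = (float(v) for v in popt)
    if bottom > top:  # canonical orientation: top is the uninhibited plateau
        top, bottom, hill = bottom, top, -hill
    resid = y - _four_pl(logx, *popt)
    return FourPLFit(
        top=top, bottom=bottom, hill=hill, ic50=10.0 ** log_ic50,
        residual_ss=float(np.sum(resid ** 2)), converged=converged,
    )


def simulate_elisa_curve(
    ic50_true: float,
    hill: float = 1.0,
    noise_cv: float = 0.02,
    seed: int = 0,
    n_levels: int = 8,
    replicates: int = 1,
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded noisy 4PL samples at half-log-spaced inhibitor levels.

    Returns ``(levels, responses)`` with responses of shape
    ``(n_levels,)`` for a single replicate or ``(replicates, n_levels)``
    otherwise.  Noise is mean-one multiplicative lognormal with the given CV.
    The avidity-inflated ``ic50_true`` (µM) is taken as given — the surface
    chemistry producing it is deliberately not modeled.
    """
    if ic50_true <= 0:
        raise ValueError("ic50_true must be > 0")
    offsets = (np.arange(n_levels) - (n_levels - 1) / 2.0) * 0.5
    levels = ic50_true * 10.0 ** offsets
    clean = _four_pl(np.log10(levels), 100.0, 0.0, math.log10(ic50_true), hill)
    if noise_cv == 0.0:
        out = np.tile(clean, (replicates, 1))
    else:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log(1.0 + noise_cv ** 2))
        factors = np.exp(rng.normal(-0.5 * sigma ** 2, sigma, (replicates, n_levels)))
        out = clean[None, :] * factors
    return levels, (out[0] if replicates == 1 else out)


# ---------------------------------------------------------------------------
# bundled reference tables


@dataclass
class FixtureTables:
    """Bundled reference measurements for five hapten conjugates.

    ``monoclonal``: affinity series of the anti-morphine monoclonal ab1060
    (antibody/tracer concentrations, bound fraction b, Müller K_d).
    ``serum_kd``: dialysis-derived K_d (nM) of pooled anti-hapten sera per
    drug, with low-affinity / no-binding classifications.
    ``elisa_ic50``: endpoint titers and competition-ELISA IC50 (µM) per
    serum × drug; censored cells (">1000 µM") carry a flag, never a number.
    """

    monoclonal: pd.DataFrame
    serum_kd: pd.DataFrame
    elisa_ic50: pd.DataFrame


def load_fixture_tables(directory=None) -> FixtureTables:
    """Load the packaged reference tables (or CSVs from ``directory``)."""
    if directory is not None:
        from pathlib import Path

        directory = Path(directory)
        read = lambda name: pd.read_csv(directory / name)  # noqa: E731
    else:
        root = resources.files("edaffinity") / "data"
        read = lambda name: pd.read_csv(root / name)  # noqa: E731
    return FixtureTables(
        monoclonal=read("monoclonal_affinity.csv"),
        serum_kd=read("serum_kd.csv"),
        elisa_ic50=read("elisa_ic50.csv"),
    )


def ic50_kd_ratio(tables: FixtureTables) -> pd.DataFrame:
    """Per serum × drug ratio IC50/K_d on a common nM scale.

    A ratio is emitted only where the ELISA IC50 is an uncensored number and
    the dialysis K_d is quantifiable; all other pairs are reported with
    ``computable = False`` and a reason (censored IC50, low-affinity /
    no-binding classification, or no dialysis measurement).
    """
    kd = tables.serum_kd.set_index(["serum", "drug"])
    rows = []
    for _, r in tables.elisa_ic50.iterrows():
        key = (r["serum"], r["drug"])
        censored = bool(r["censored"])
        ic50_um = r["ic50_um"]
        entry = {
            "serum": r["serum"],
            "drug": r["drug"],
            "ic50_um": None if censored else float(ic50_um),
            "kd_nM": None,
            "ratio": None,
            "computable": False,
            "reason": "",
        }
        if key not in kd.index:
            entry["reason"] = "no dialysis K_d measurement"
        else:
            krow = kd.loc[key]
            cls = krow["classification"]
            if censored:
                entry["reason"] = f"IC50 censored (>{r['censor_limit_um']:g} uM)"
            elif cls != "quantifiable":
                entry["reason"] = f"dialysis classification: {cls}"
            else:
                kd_nm = float(krow["kd_nm"])
                ic50_nm = float(ic50_um) * 1000.0  # µM → nM
                entry.update(
                    kd_nM=kd_nm, ratio=ic50_nm / kd_nm, computable=True, reason="ok"
                )
        rows.append(entry)
    return pd.DataFrame(rows)
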