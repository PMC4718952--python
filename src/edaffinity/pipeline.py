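"""Estimation pipeline: measured chamber concentrations → b, T_t, I50, K_d.

The chain mirrors the competition-ED workflow: the bound tracer fraction
``b`` comes from the sample/buffer concentration difference in the
zero-inhibitor cassette, the total tracer concentration ``T_t`` is the
volume-weighted chamber mean, % inhibition at each inhibitor level is
relative to the zero-inhibitor bound tracer, the midpoint ``I50`` is read
off the inhibition curve by log-linear interpolation, and the apparent
dissociation constant follows from Müller's estimator

    K_d = (I50 − T_t) · (1 − 1.5·b + 0.5·b²).

Quality gates: the estimator is endorsed only for b in [0.4, 0.7] (estimates
outside the window are still computed, but flagged) and only when the drug
survives the incubation (stability gate).  Sera whose inhibition curve never
reaches 50 % fall back to a low-affinity / no-binding classification based
on the 5 % bound-tracer rules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .binding import (
    DialysisGeometry,
    InhibitionCurve,
    LevelScale,
    correction_factor,
    muller_kd,
)
from .simulate import (
    DegradationModel,
    MeasuredDataset,
    NEGATIVE_CONTROL_ID,
    degradation_remaining,
)

__all__ = [
    "KdEstimate",
    "EstimateConfig",
    "I50NotReachedError",
    "percent_drug",
    "percent_remaining",
    "compute_b",
    "compute_tt",
    "percent_inhibition",
    "percent_bound_heroin",
    "interpolate_i50",
    "classify_binding",
    "stability_gate",
    "estimate_kd",
    "muller_bias_table",
]

Classification = Literal["quantifiable", "low_affinity", "no_binding", "not_determined"]


class I50NotReachedError(ValueError):
    """The inhibition curve has no 50 % crossing among its positive levels."""


def percent_drug(conc_sample: float, conc_buffer: float) -> float:
    """Percent of drug in one chamber: 100·c_chamber/(c_sample + c_buffer)."""
    total = conc_sample + conc_buffer
    if total <= 0:
        raise ValueError("both chamber concentrations are zero; % drug undefined")
    return 100.0 * conc_sample / total


def percent_remaining(conc_t: float, conc_initial: float) -> float:
    """Percent of drug remaining intact at time t: 100·c_t/c_0."""
    if conc_initial <= 0:
        raise ValueError("initial concentration must be > 0")
    return 100.0 * conc_t / conc_initial


def compute_b(conc_sample: float, conc_buffer: float) -> float:
    """Bound tracer fraction (c_sample − c_buffer)/c_sample, clamped to ≥ 0.

    Measurement noise can put the buffer chamber above the sample chamber;
    such negative bound fractions are clamped to 0 with a warning.
    """
    if conc_sample <= 0:
        raise ValueError("sample-chamber concentration must be > 0")
    b = (conc_sample - conc_buffer) / conc_sample
    if b < 0:
        warnings.warn(
            f"negative bound fraction {b:.4g} clamped to 0 "
            "(buffer chamber above sample chamber)",
            stacklevel=2,
        )
        return 0.0
    return b


def compute_tt(
    conc_sample: float, conc_buffer: float, geometry: DialysisGeometry
) -> float:
    """Total tracer concentration over the insert (volume-weighted mean, nM)."""
    return (
        conc_sample * geometry.v_sample + conc_buffer * geometry.v_buffer
    ) / geometry.v_total


def percent_inhibition(bound_i: float, bound_i0: float) -> tuple[float, bool]:
    """% inhibition 100·(1 − bound_I/bound_I0), clamped to [0, 100].

    Returns ``(value, clamped)``; ``clamped`` is True when the raw value fell
    outside [0, 100] (noise can drive bound_I above bound_I0 or below 0).
    """
    if bound_i0 <= 0:
        raise ValueError("zero-inhibitor bound tracer must be > 0")
    raw = 100.0 * (1.0 - bound_i / bound_i0)
    if raw < 0.0:
        return 0.0, True
    if raw > 100.0:
        return 100.0, True
    return raw, False


def percent_bound_heroin(conc_sample: float, conc_buffer: float) -> float:
    """% bound drug 100·(c_s − c_b)/c_s; negative values clamp to 0 with a warning.

    Same quantity as :func:`compute_b` expressed as a percentage; used for
    heroin, whose K_d cannot be estimated, as a binding readout in its own
    right.
    """
    return 100.0 * compute_b(conc_sample, conc_buffer)


def interpolate_i50(curve: InhibitionCurve) -> float:
    """Midpoint of the inhibition curve by log-linear interpolation (nM).

    Uses the mean inhibition at strictly positive levels.  A point at
    exactly 50 % is returned directly; otherwise the first ascending
    crossing is interpolated linearly in log10 of the inhibitor level.
    Raises :class:`I50NotReachedError` when no bracketing pair exists.
    """
    mask = curve.levels > 0
    levels = curve.levels[mask]
    y = curve.mean_inhibition[mask]
    if len(levels) == 0:
        raise I50NotReachedError("curve has no positive inhibitor levels")
    exact = np.nonzero(y == 50.0)[0]
    if exact.size:
        return float(levels[exact[0]])
    for j in range(len(levels) - 1):
        if y[j] < 50.0 < y[j + 1]:
            frac = (50.0 - y[j]) / (y[j + 1] - y[j])
            log_i50 = math.log10(levels[j]) + frac * (
                math.log10(levels[j + 1]) - math.log10(levels[j])
            )
            return 10.0 ** log_i50
    raise I50NotReachedError(
        f"inhibition curve never crosses 50 % (max {np.max(y):.1f} %)"
    )


def classify_binding(
    pct_bound_1_25: float, pct_bound_1_400: float | None = None, threshold: float = 5.0
) -> Classification:
    """Low-affinity / no-binding classification from bound-tracer percentages.

    ``no_binding`` when <5 % of tracer is bound at 1:25 serum dilution;
    ``low_affinity`` when >5 % is bound at 1:25 but <5 % at 1:400;
    ``quantifiable`` otherwise.
    """
    if not 0.0 <= pct_bound_1_25 <= 100.0:
        raise ValueError("percentages must be in [0, 100]")
    if pct_bound_1_25 < threshold:
        return "no_binding"
    if pct_bound_1_400 is None:
        raise ValueError("pct_bound_1_400 required when 1:25 binding exceeds threshold")
    if not 0.0 <= pct_bound_1_400 <= 100.0:
        raise ValueError("percentages must be in [0, 100]")
    if pct_bound_1_400 < threshold:
        return "low_affinity"
    return "quantifiable"


def stability_gate(remaining_24h: float, threshold: float = 0.90) -> str:
    """Pass iff the fraction of drug surviving the incubation is ≥ threshold."""
    if not 0.0 <= remaining_24h <= 1.0:
        raise ValueError("remaining fraction must be in [0, 1]")
    return "pass" if remaining_24h >= threshold else "fail"


@dataclass(frozen=True)
class EstimateConfig:
    """Tunables of the estimation pipeline.

    ``per_replicate`` computes b, I50 and K_d replicate-wise and summarizes
    as mean ± SD (the default); when False, replicate concentrations are
    averaged first and a single estimate is returned.
    """

    b_window: tuple[float, float] = (0.4, 0.7)
    stability_threshold: float = 0.90
    classification_threshold: float = 5.0  # % bound tracer
    per_replicate: bool = True
    degradation: DegradationModel | None = field(default_factory=DegradationModel)
    incubation_time: float = 24.0


@dataclass
class KdEstimate:
    """Result bundle of one K_d estimation.

    ``kd`` is populated whenever the arithmetic is possible, even when a QC
    gate fails (flags carry the verdicts); ``reportable_kd`` is None unless
    every gate passes and the serum is classified quantifiable.
    """

    b_mean: float
    b_sd: float
    t_t: float
    i50: float | None
    correction: float | None
    kd: float | None
    kd_sd: float | None
    qc_b_window: str
    qc_stability: str
    classification: Classification
    n_replicates: int
    flags: list[str] = field(default_factory=list)

    @property
    def reportable_kd(self) -> float | None:
        if (
            self.kd is not None
            and self.qc_b_window == "pass"
            and self.qc_stability == "pass"
            and self.classification == "quantifiable"
        ):
            return self.kd
        return None

    def to_dict(self) -> dict:
        return {
            "b_mean": self.b_mean,
            "b_sd": self.b_sd,
            "t_t_nM": self.t_t,
            "i50_nM": self.i50,
            "correction": self.correction,
            "kd_nM": self.kd,
            "kd_sd_nM": self.kd_sd,
            "qc_b_window": self.qc_b_window,
            "qc_stability": self.qc_stability,
            "classification": self.classification,
            "n_replicates": self.n_replicates,
            "flags": list(self.flags),
        }


def _chamber_matrix(frame: pd.DataFrame) -> pd.DataFrame:
    """Pivot one condition to replicate rows × (sample, buffer) columns."""
    wide = frame.pivot_table(
        index="replicate", columns="chamber", values="conc_nM", aggfunc="mean"
    )
    if "sample" not in wide or "buffer" not in wide:
        raise ValueError("condition is missing a chamber")
    return wide


def estimate_kd(dataset: MeasuredDataset, config: EstimateConfig | None = None) -> KdEstimate:
    """Run the full pipeline on one measured dataset.

    Requires a zero-inhibitor condition (for b and T_t); titration conditions
    feed the inhibition curve.  When the curve never reaches 50 % the serum
    is classified (low-affinity / no-binding) instead of quantified.
    """
    config = config or EstimateConfig()
    frame = dataset.frame
    geom = dataset.geometry
    test = frame[frame["condition_id"] != NEGATIVE_CONTROL_ID]
    zero = test[test["inhibitor_level_nM"] == 0]
    if zero.empty:
        raise ValueError("dataset has no zero-inhibitor condition")

    flags: list[str] = []
    zero_wide = _chamber_matrix(zero)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamping warnings summarized in flags
        b_reps = np.array(
            [compute_b(row["sample"], row["buffer"]) for _, row in zero_wide.iterrows()]
        )
    tt_reps = np.array(
        [compute_tt(row["sample"], row["buffer"], geom) for _, row in zero_wide.iterrows()]
    )
    bound0_reps = (zero_wide["sample"] - zero_wide["buffer"]).clip(lower=0.0).to_numpy()
    n = len(b_reps)
    b_mean = float(b_reps.mean())
    b_sd = float(b_reps.std(ddof=1)) if n > 1 else 0.0
    t_t = float(tt_reps.mean())

    # stability gate on the tracer's parent drug at the dataset's dilution
    qc_stability = "pass"
    if config.degradation is not None and not test.empty:
        dil = test["dilution"].iloc[0]
        est_flag = bool(test["esterase_inhibitors"].iloc[0])
        drug = str(test["analyte"].iloc[0])
        dil_val = None if pd.isna(dil) else float(dil)
        try:
            remaining = degradation_remaining(
                drug, dil_val, est_flag, config.incubation_time, config.degradation
            )
        except KeyError:
            remaining = 1.0
            flags.append(f"no degradation rates for {drug!r}; stability gate skipped")
        qc_stability = stability_gate(remaining, config.stability_threshold)

    lo, hi = config.b_window
    qc_b = "pass" if lo <= b_mean <= hi else "fail"
    if qc_b == "fail":
        flags.append(f"b={b_mean:.3f} outside endorsed window [{lo}, {hi}]")

    pct_bound = 100.0 * b_mean
    if pct_bound < config.classification_threshold or bound0_reps.mean() <= 0:
        return KdEstimate(
            b_mean, b_sd, t_t, None, None, None, None,
            qc_b, qc_stability, "no_binding", n, flags,
        )

    # inhibition curve per level
    levels = np.array(sorted(test.loc[test["inhibitor_level_nM"] > 0, "inhibitor_level_nM"].unique()))
    if levels.size == 0:
        flags.append("no titration levels; classification only")
        return KdEstimate(
            b_mean, b_sd, t_t, None, None, None, None,
            qc_b, qc_stability, "low_affinity", n, flags,
        )

    inhib_by_level = {}  # level -> per-replicate % inhibition
    for level in levels:
        wide = _chamber_matrix(test[test["inhibitor_level_nM"] == level])
        bound = (wide["sample"] - wide["buffer"]).clip(lower=0.0).to_numpy()
        m = min(len(bound), n)
        vals = []
        for r in range(m):
            v, clamped = percent_inhibition(bound[r], bound0_reps[r] if bound0_reps[r] > 0 else bound0_reps.mean())
            if clamped:
                flags.append(f"inhibition clamped at level {level:g} nM replicate {r + 1}")
            vals.append(v)
        inhib_by_level[level] = np.array(vals)

    def curve_from(values_fn) -> InhibitionCurve:
        means = np.array([values_fn(level) for level in levels])
        sds = np.array([inhib_by_level[level].std(ddof=1) if len(inhib_by_level[level]) > 1 else 0.0
                        for level in levels])
        ns = np.array([len(inhib_by_level[level]) for level in levels])
        return InhibitionCurve(
            np.concatenate([[0.0], levels]),
            np.concatenate([[0.0], means]),
            np.concatenate([[0.0], sds]),
            np.concatenate([[n], ns]),
            float(bound0_reps.mean()),
            dataset.i50_scale,
        )

    mean_curve = curve_from(lambda level: inhib_by_level[level].mean())
    try:
        i50_mean_curve = interpolate_i50(mean_curve)
    except I50NotReachedError:
        cls: Classification = (
            "no_binding" if pct_bound < config.classification_threshold else "low_affinity"
        )
        flags.append("I50 not reached on mean inhibition curve")
        return KdEstimate(
            b_mean, b_sd, t_t, None, None, None, None,
            qc_b, qc_stability, cls, n, flags,
        )

    if config.per_replicate and n > 1:
        # The midpoint is read once off the mean inhibition curve (as one
        # would interpolate a single plotted curve); replicate scatter enters
        # through b and T_t, giving the triplicate-wise K_d mean ± SD.
        kd_reps = []
        for r in range(n):
            try:
                kd_reps.append(
                    muller_kd(i50_mean_curve, float(tt_reps[r]), float(b_reps[r]))
                )
            except ValueError as exc:
                flags.append(f"replicate {r + 1} dropped: {exc}")
        if kd_reps:
            kd_arr = np.array(kd_reps)
            kd = float(kd_arr.mean())
            kd_sd = float(kd_arr.std(ddof=1)) if len(kd_arr) > 1 else 0.0
            corr = correction_factor(b_mean)
            return KdEstimate(
                b_mean, b_sd, t_t, i50_mean_curve, corr, kd, kd_sd,
                qc_b, qc_stability, "quantifiable", n, flags,
            )
        flags.append("all replicates failed; falling back to mean-curve estimate")

    corr = correction_factor(b_mean)
    try:
        kd = muller_kd(i50_mean_curve, t_t, b_mean)
    except ValueError as exc:
        flags.append(str(exc))
        return KdEstimate(
            b_mean, b_sd, t_t, i50_mean_curve, corr, None, None,
            qc_b, qc_stability, "not_determined", n, flags,
        )
    return KdEstimate(
        b_mean, b_sd, t_t, i50_mean_curve, corr, kd, None,
        qc_b, qc_stability, "quantifiable", n, flags,
    )


def muller_bias_table(
    kd_true_values: tuple[float, ...] = (0.5, 1.0, 2.0, 5.0),
    b_targets: tuple[float, ...] = (0.40, 0.50, 0.60, 0.70),
    i50_scale: LevelScale = "buffer-initial",
) -> pd.DataFrame:
    """Bias of the Müller estimator on noiseless mechanistic data.

    For each (true K_d, target b) cell an exact self-competition assay
    (inhibitor affinity = tracer affinity) is simulated without noise, the
    pipeline is run, and the ratio estimate/truth is tabulated.  Documents
    the systematic bias introduced by the inhibitor-level reporting
    convention; see docs/methods.md.
    """
    from .simulate import AssayDesign, calibrate_site_conc, generate_dataset

    rows = []
    for kd_true in kd_true_values:
        for b_target in b_targets:
            site = calibrate_site_conc(b_target, kd_true)
            design = AssayDesign(
                site_conc=site,
                tracer_kd=kd_true,
                inhibitor_kd=kd_true,
                replicates=1,
                noise_cv=0.0,
                i50_scale=i50_scale,
                include_negative_control=False,
            )
            est = estimate_kd(generate_dataset(design), EstimateConfig(per_replicate=False))
            rows.append(
                {
                    "kd_true_nM": kd_true,
                    "b": b_target,
                    "kd_est_nM": est.kd,
                    "ratio": est.kd / kd_true if est.kd is not None else np.nan,
                    "i50_scale": i50_scale,
                }
            )
    return pd.DataFrame(rows)
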