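"""qPCR preprocessing: SDM Cq calling, interplate calibration, spike-in QC
and reference-gene delta-Cq normalization.

The quantification cycle is the second-derivative maximum (SDM) of the
amplification curve. Because the SDM peak of a sharp curve is narrower than
the one-cycle sampling interval, the caller fits a four-parameter logistic
model to the trace (Levenberg-Marquardt with an analytic Jacobian) and takes
the SDM analytically at m - ln(2 + sqrt(3)) / k from the fitted midpoint m
and slope k; a smoothed second difference provides the initial guess. Wells
whose amplitude rise stays below a noise-scaled detection gate are reported
as undetermined (NaN), which is how blank and non-amplifying wells surface.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import OptimizeWarning, curve_fit

from .synthetic_data import SDM_OFFSET, AmplificationCurve

logger = logging.getLogger(__name__)

#: Undetermined Cq marker (no amplification detected).
UNDETERMINED = math.nan

CQ_COLUMNS = ["sample_id", "plate_id", "assay_name", "well_class", "cq"]


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the edges keep the raw values."""
    if window <= 1:
        return y.copy()
    kernel = np.ones(window) / window
    sm = np.convolve(y, kernel, mode="same")
    h = window // 2
    sm[:h] = y[:h]
    sm[-h:] = y[-h:]
    return sm


def _logistic(c, baseline, f_max, k, m):
    return baseline + f_max / (1.0 + np.exp(-k * (c - m)))


def _logistic_jac(c, baseline, f_max, k, m):
    z = np.exp(-k * (c - m))
    L = 1.0 / (1.0 + z)
    core = f_max * L * L * z
    return np.stack([np.ones_like(c), L, core * (c - m), -core * k], axis=1)


def call_cq_sdm(
    curve: AmplificationCurve,
    smoothing_window: int = 5,
    detection_snr: float = 5.0,
) -> float:
    """SDM Cq of one amplification curve, or NaN when undetermined.

    Parameters
    ----------
    curve
        The raw trace; at least 10 strictly increasing cycles.
    smoothing_window
        Odd width of the centered moving average used for the detection gate
        and the initial guess (not for the final estimate, which comes from
        the model fit).
    detection_snr
        A well is called undetermined when its smoothed amplitude rise is
        below ``detection_snr`` times the baseline noise estimate.
    """
    c, y = curve.cycles, curve.fluorescence
    if smoothing_window % 2 == 0 or smoothing_window >= c.size:
        raise ValueError("smoothing_window must be odd and smaller than the cycle count")

    ys = _moving_average(y, smoothing_window)
    rise = float(ys.max() - ys.min())
    noise = float(np.std(y - ys))
    if rise <= max(detection_snr * noise, 1e-9):
        return UNDETERMINED

    # Initial guess: midpoint at the half-rise crossing of the smoothed trace
    # (robust to smoothing-edge artifacts, unlike the discrete second
    # difference), unit slope.
    base0 = float(np.median(ys[: max(3, smoothing_window)]))
    half = base0 + (float(ys.max()) - base0) / 2.0
    m0 = float(c[int(np.argmax(ys >= half))])
    p0 = [base0, rise, 1.0, m0]
    try:
        # overflow in exp() for wandering trial parameters is expected and
        # harmless (saturates the logistic); silence it and the covariance
        # warning, which is irrelevant since only the point estimate is used
        with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            popt, _ = curve_fit(
                _logistic, c, y, p0=p0, jac=_logistic_jac, maxfev=400
            )
    except RuntimeError:
        return UNDETERMINED
    baseline, f_max, k, m = popt
    if f_max <= 0 or k <= 0:
        return UNDETERMINED
    cq = m - SDM_OFFSET / k
    if not (c[0] <= cq <= c[-1]):
        return UNDETERMINED
    return float(cq)


def call_cq_table(
    curves: pd.DataFrame, smoothing_window: int = 5, detection_snr: float = 5.0
) -> pd.DataFrame:
    """Call Cq for every well in a long-format curve table.

    Expects columns plate_id, well_id, sample_id, assay_name, well_class,
    cycle, fluorescence; returns one CqRecord row per (sample, well).
    """
    records = []
    group_cols = ["sample_id", "plate_id", "well_id", "assay_name", "well_class"]
    curves = curves.copy()
    # blank wells carry an empty assay name, which file round-trips turn into
    # NaN; restore it so groupby keeps the blanks
    curves["assay_name"] = curves["assay_name"].fillna("")
    for keys, grp in curves.groupby(group_cols, sort=True):
        grp = grp.sort_values("cycle")
        curve = AmplificationCurve(
            well_id=keys[2],
            cycles=grp["cycle"].to_numpy(),
            fluorescence=grp["fluorescence"].to_numpy(),
        )
        cq = call_cq_sdm(curve, smoothing_window, detection_snr)
        records.append(dict(zip(group_cols, keys)) | {"cq": cq})
    out = pd.DataFrame(records)
    return out[["sample_id", "plate_id", "well_id", "assay_name", "well_class", "cq"]]


def interplate_calibrate(cq_records: pd.DataFrame) -> pd.DataFrame:
    """Remove between-plate Cq offsets using the interplate calibrator wells.

    Subtracts (plate-mean calibrator Cq - global-mean calibrator Cq) from
    every Cq on that plate; idempotent. A plate whose calibrators are all
    undetermined is a QC failure.
    """
    cal = cq_records[
        (cq_records["well_class"] == "interplate_calibrator")
        & cq_records["cq"].notna()
    ]
    plates = cq_records["plate_id"].unique()
    failed = sorted(set(plates) - set(cal["plate_id"].unique()))
    if failed:
        raise ValueError(f"plates with no defined interplate calibrator Cq: {failed}")
    plate_means = cal.groupby("plate_id")["cq"].mean()
    offsets = plate_means - cal["cq"].mean()
    out = cq_records.copy()
    out["cq"] = out["cq"] - out["plate_id"].map(offsets)
    return out


def qc_spike_ins(
    cq_records: pd.DataFrame, tolerance_sd: float = 3.0, min_sd: float = 0.125
) -> pd.DataFrame:
    """Per-sample spike-in QC report.

    Each sample's spike-in Cq is compared, per spike-in assay, against the
    leave-one-out mean and SD across the remaining samples; a sample fails
    when any spike-in deviates by more than ``tolerance_sd`` such SDs (or has
    an undetermined spike-in Cq). The SD enters through max(SD, ``min_sd``):
    spike QC is meant to catch gross per-sample technical failures, so
    deviations below the technical-noise floor (default 3 x 0.125 = 0.375
    cycles) never flag a sample. With identical spike-ins everywhere the
    deviation is zero and everything passes. Fewer than three samples, or no
    spike-in records, yields an all-pass (empty) report.
    """
    spikes = cq_records[cq_records["well_class"] == "spike_in"]
    if spikes.empty:
        return pd.DataFrame(columns=["sample_id", "max_abs_z", "passed"])
    wide = spikes.pivot_table(
        index="sample_id", columns="assay_name", values="cq", aggfunc="mean", dropna=False
    )
    n = wide.shape[0]
    rows = []
    for sid in wide.index:
        worst = 0.0
        ok = True
        for assay in wide.columns:
            v = wide.loc[sid, assay]
            if pd.isna(v):
                ok = False
                worst = math.inf
                continue
            others = wide[assay].drop(index=sid).dropna()
            if len(others) < 2 or n < 3:
                continue
            mu, sd = float(others.mean()), float(others.std(ddof=1))
            dev = abs(v - mu)
            z = 0.0 if dev == 0 else dev / max(sd, min_sd)
            worst = max(worst, z)
            if z > tolerance_sd:
                ok = False
        rows.append({"sample_id": sid, "max_abs_z": worst, "passed": ok})
    return pd.DataFrame(rows)


@dataclass
class ExpressionMatrix:
    """Normalized relative expression (2^-dCq), miRNAs x samples.

    ``condition_order`` fixes which label is condition 1 vs condition 2 for
    downstream differential ranking.
    """

    values: pd.DataFrame
    conditions: pd.Series
    condition_order: tuple[str, str]

    def __post_init__(self) -> None:
        labels = set(self.conditions.unique())
        if labels != set(self.condition_order) or len(labels) != 2:
            raise ValueError(
                f"condition labels {sorted(labels)} must match the two names "
                f"in condition_order {self.condition_order}"
            )
        if set(self.values.columns) != set(self.conditions.index):
            raise ValueError("matrix columns and condition labels disagree")
        vals = self.values.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and finite.min() <= 0:
            raise ValueError("relative expression must be positive where defined")

    def samples_of(self, condition: str) -> list[str]:
        return list(self.conditions.index[self.conditions == condition])


def normalize_delta_cq(
    cq_records: pd.DataFrame,
    conditions: Mapping[str, str] | pd.Series,
    condition_order: tuple[str, str] | None = None,
    max_undetermined_frac: float | None = 0.5,
) -> ExpressionMatrix:
    """Reference-gene delta-Cq normalization to relative expression.

    Per sample, dCq(miRNA) = Cq(miRNA) - mean(reference-gene Cq) and relative
    expression = 2^-dCq. Undetermined Cq propagates to a missing value (never
    zero). miRNAs undetermined in more than ``max_undetermined_frac`` of the
    samples of either condition are dropped (set to None to keep all). A
    sample with no defined reference-gene Cq is a QC failure.
    """
    conditions = pd.Series(dict(conditions) if not isinstance(conditions, pd.Series) else conditions)
    refs = cq_records[
        (cq_records["well_class"] == "reference_gene") & cq_records["cq"].notna()
    ]
    ref_mean = refs.groupby("sample_id")["cq"].mean()
    samples = [s for s in conditions.index if s in set(cq_records["sample_id"])]
    missing_ref = sorted(set(samples) - set(ref_mean.index))
    if missing_ref:
        raise ValueError(f"samples with no defined reference-gene Cq: {missing_ref}")

    mirnas = cq_records[cq_records["well_class"] == "mirna_assay"]
    cq_wide = mirnas.pivot_table(
        index="assay_name", columns="sample_id", values="cq", aggfunc="mean", dropna=False
    )[samples]
    delta = cq_wide.sub(ref_mean[samples], axis="columns")
    expr = np.power(2.0, -delta)

    if max_undetermined_frac is not None:
        keep = pd.Series(True, index=expr.index)
        for cond in conditions.unique():
            cols = [s for s in samples if conditions[s] == cond]
            frac_na = expr[cols].isna().mean(axis=1)
            keep &= frac_na <= max_undetermined_frac
        dropped = sorted(expr.index[~keep])
        if dropped:
            logger.info(
                "normalize_delta_cq: dropped %d miRNAs undetermined in >%.0f%% "
                "of samples in a condition: %s",
                len(dropped), 100 * max_undetermined_frac, dropped,
            )
        expr = expr.loc[keep]

    if condition_order is None:
        seen = list(dict.fromkeys(conditions[samples]))
        condition_order = (seen[0], seen[1])
    return ExpressionMatrix(
        values=expr, conditions=conditions[samples], condition_order=condition_order
    )
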