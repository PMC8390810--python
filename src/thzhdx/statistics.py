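"""Intensity-ratio statistics and acceleration/deceleration calls.

The effect of a perturbation (sub-THz irradiation or heat conduction) on a
residue's HDX is evaluated through the ratio of its methyl-normalized amide
intensity to that of the unperturbed control,

    R_t = I_pert,t / I_GC,t                      (t = 3, 6, 12 min),

and, because the sample temperature only equilibrates after ~3 min, through
differences from the 3-min reference,

    dR_t = R_t - R_3.

Errors are propagated from signal-to-noise ratios,

    Error(R_t) = R_t * sqrt(SNR_pert^-2 + SNR_GC^-2),

and combined over the two time points (quadrature by default).  A residue is
called *accelerated* when ``dR + Error(dR) < 0`` and *decelerated* when
``dR - Error(dR) > 0`` (strict inequalities); otherwise it is *unchanged*.
Calls at 6 and 12 min are merged into a final label with an onset tier
(detected at both time points, or only at 12 min).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .peaktable import PeakRecord, PeakTable

__all__ = [
    "SNR_MIN_DEFAULT",
    "FLOOR_MULTIPLE_DEFAULT",
    "TIMEPOINTS_MIN",
    "RatioResult",
    "ClassificationResult",
    "normalize_intensities",
    "ratio_R",
    "error_R",
    "delta_R",
    "error_delta_R",
    "classify",
    "combine_timepoints",
    "select_residues",
    "fit_hdx_rate",
    "ph_sensitivity",
    "compare_conditions",
]

#: SNR selection threshold; 33.3 corresponds to a >3% noise level.
SNR_MIN_DEFAULT = 33.3
#: Intensity floor (in multiples of the noise rms) below which a residue is
#: treated as already exchanged during storage ("fast exchanger").
FLOOR_MULTIPLE_DEFAULT = 3.0
#: Perturbation durations probed by the protocol; 3 min is the reference.
TIMEPOINTS_MIN = (3, 6, 12)

LABELS = ("accelerated", "decelerated", "unchanged")
ONSETS = ("at_6_and_12", "only_12", "none")


@dataclass(frozen=True)
class RatioResult:
    residue_number: int
    timepoint_min: int
    R_t: float
    error_R: float


@dataclass(frozen=True)
class ClassificationResult:
    residue_number: int
    delta_R_6: float
    delta_R_12: float
    error_delta_R_6: float
    error_delta_R_12: float
    label: str
    onset: str


def normalize_intensities(
    amide_records: Sequence[PeakRecord],
    methyl_records: Sequence[PeakRecord],
) -> dict[int, float]:
    """Normalize amide intensities by the sample's mean methyl height.

    Returns ``{residue_number: normalized intensity}``.  Normalization cancels
    sample-to-sample concentration differences; SNR values are unaffected
    (ratios of like-scaled quantities).
    """
    if not methyl_records:
        raise ValueError("at least one methyl internal-standard record is required")
    methyl_mean = float(np.mean([m.intensity for m in methyl_records]))
    if methyl_mean <= 0:
        raise ValueError("methyl mean intensity must be positive")
    return {a.signal_id: a.intensity / methyl_mean for a in amide_records}


def ratio_R(i_pert: float, i_gc: float) -> float:
    """Perturbed-to-control intensity ratio; < 1 under acceleration."""
    if i_gc <= 0:
        raise ValueError(f"control intensity must be positive, got {i_gc!r}")
    return i_pert / i_gc


def error_R(r: float, snr_pert: float, snr_gc: float) -> float:
    """SNR-propagated error of the ratio: ``R * sqrt(SNR_p^-2 + SNR_gc^-2)``."""
    if snr_pert <= 0 or snr_gc <= 0:
        raise ValueError("SNR values must be positive")
    return abs(r) * math.sqrt(snr_pert**-2 + snr_gc**-2)


def delta_R(r_t: float, r_3min: float, timepoint_min: int | None = None) -> float:
    """Difference of ``R_t`` from the 3-min reference ratio."""
    if timepoint_min == 3:
        raise ValueError("t = 3 min is the reference point; delta is undefined there")
    return r_t - r_3min


def error_delta_R(error_r_t: float, error_r_3min: float, method: str = "quadrature") -> float:
    """Combine the two ratio errors into Error(dR).

    ``quadrature`` (default) is standard propagation for a difference;
    ``sum`` and ``half_sum`` are literal readings of the published combiner.
    """
    if error_r_t < 0 or error_r_3min < 0:
        raise ValueError("errors must be non-negative")
    if method == "quadrature":
        return math.hypot(error_r_t, error_r_3min)
    if method == "sum":
        return error_r_t + error_r_3min
    if method == "half_sum":
        return 0.5 * (error_r_t + error_r_3min)
    raise ValueError(f"unknown method {method!r}; expected quadrature, sum or half_sum")


def classify(delta_r: float, error_delta_r: float) -> str:
    """Call one (residue, time point): strict threshold on dR against its error."""
    if error_delta_r < 0:
        raise ValueError("error must be non-negative")
    if delta_r + error_delta_r < 0:
        return "accelerated"
    if delta_r - error_delta_r > 0:
        return "decelerated"
    return "unchanged"


def combine_timepoints(class_6: str, class_12: str) -> tuple[str, str]:
    """Merge 6- and 12-min calls into (final label, onset tier).

    Same directional call at both time points -> strong onset; a directional
    call only at 12 min -> weak onset; no call at 12 min -> unchanged.
    Conflicting directions collapse to unchanged with a warning.
    """
    for c in (class_6, class_12):
        if c not in LABELS:
            raise ValueError(f"unknown classification {c!r}")
    if class_12 == "unchanged":
        return ("unchanged", "none")
    if class_6 == class_12:
        return (class_12, "at_6_and_12")
    if class_6 == "unchanged":
        return (class_12, "only_12")
    warnings.warn(
        f"conflicting calls at 6 min ({class_6}) and 12 min ({class_12}); "
        "treating the residue as unchanged",
        stacklevel=2,
    )
    return ("unchanged", "none")


def select_residues(
    tables: Sequence[PeakTable],
    snr_min: float = SNR_MIN_DEFAULT,
    floor_multiple: float = FLOOR_MULTIPLE_DEFAULT,
) -> tuple[set[int], dict[int, str]]:
    """Apply the residue-selection rules across all tables of a run.

    Excluded are residues that (a) have already exchanged during storage
    (control intensity below ``floor_multiple * noise_rms`` at the first time
    point; reason ``fast_exchanger``), (b) fall below the SNR threshold in any
    table (``low_snr``), or (c) carry an overlap flag (``overlap``).  Returns
    the included residue set and per-residue exclusion reasons.
    """
    if not tables:
        raise ValueError("at least one peak table is required")
    if snr_min <= 0:
        raise ValueError("snr_min must be positive")
    universe: set[int] = set()
    for t in tables:
        ids = {a.signal_id for a in t.amides()}
        universe = universe & ids if universe else ids
    if not universe:
        raise ValueError("tables share no amide residues")

    gc_tables = [t for t in tables if t.design.condition == "GC"]
    first_gc = min(gc_tables, key=lambda t: t.design.perturbation_minutes) if gc_tables else None

    reasons: dict[int, str] = {}
    for res in sorted(universe):
        if first_gc is not None and first_gc.noise_rms > 0:
            if first_gc.amide(res).intensity < floor_multiple * first_gc.noise_rms:
                reasons[res] = "fast_exchanger"
                continue
        if any(t.amide(res).snr < snr_min for t in tables):
            reasons[res] = "low_snr"
            continue
        if any(t.amide(res).overlap for t in tables):
            reasons[res] = "overlap"
    included = universe - set(reasons)
    return included, reasons


def fit_hdx_rate(
    time_series: Sequence[tuple[float, float]],
    sigma: float | None = None,
) -> tuple[float, float]:
    """Fit ``I(t) = A * exp(-k t)`` to a (time in h, intensity) series.

    Nonlinear least squares on the linear scale (additive-noise model);
    ``k >= 0`` is enforced through bounds.  Returns ``(k, standard error)``
    with the standard error taken from the fit covariance.  When the
    measurement noise is known (e.g. from the spectrum SNR), pass it as
    ``sigma`` so the standard error is absolute rather than rescaled by the
    few-point residual variance.
    """
    if len(time_series) < 3:
        raise ValueError("at least 3 points are required")
    times = np.asarray([t for t, _ in time_series], dtype=float)
    intens = np.asarray([i for _, i in time_series], dtype=float)
    if np.any(intens <= 0):
        raise ValueError("intensities must be positive")
    if np.allclose(times, times[0]):
        raise ValueError("degenerate series: all time points equal")
    span = times.max() - times.min()
    with np.errstate(divide="ignore"):
        slope = -(np.log(intens[-1]) - np.log(intens[0])) / span
    p0 = (float(intens.max()), float(max(slope, 0.0)))
    popt, pcov = curve_fit(
        lambda t, a, k: a * np.exp(-k * t),
        times,
        intens,
        p0=p0,
        sigma=None if sigma is None else np.full(times.size, sigma),
        absolute_sigma=sigma is not None,
        bounds=([0.0, 0.0], [np.inf, np.inf]),
        maxfev=10000,
    )
    k = float(popt[1])
    stderr = float(np.sqrt(pcov[1, 1])) if np.isfinite(pcov[1, 1]) else math.inf
    return k, stderr


def ph_sensitivity(k_ex_ph1: float, k_ex_ph2: float, ph1: float, ph2: float) -> float:
    """Apparent exchange-rate order in decades per pH unit.

    Ideal EX2 with a pH-independent opening equilibrium gives exactly 1.0
    (tenfold per pH unit); protected residues whose K_op responds to
    conditions fall below it.
    """
    if k_ex_ph1 <= 0 or k_ex_ph2 <= 0:
        raise ValueError("rates must be positive")
    if ph1 == ph2:
        raise ValueError("pH values must differ")
    return math.log10(k_ex_ph2 / k_ex_ph1) / (ph2 - ph1)


def _ratio_for(
    residue: int,
    timepoint: int,
    gc_table: PeakTable,
    pert_table: PeakTable,
) -> RatioResult:
    norm_gc = normalize_intensities(gc_table.amides(), gc_table.methyls())
    norm_p = normalize_intensities(pert_table.amides(), pert_table.methyls())
    r = ratio_R(norm_p[residue], norm_gc[residue])
    err = error_R(r, pert_table.amide(residue).snr, gc_table.amide(residue).snr)
    return RatioResult(residue, timepoint, r, err)


def compare_conditions(
    gc_tables: Mapping[int, PeakTable],
    pert_tables: Mapping[int, PeakTable],
    *,
    snr_min: float = SNR_MIN_DEFAULT,
    floor_multiple: float = FLOOR_MULTIPLE_DEFAULT,
    errdr_method: str = "quadrature",
) -> tuple[pd.DataFrame, dict[int, ClassificationResult]]:
    """Run the full statistics for one perturbed condition against control.

    ``gc_tables`` and ``pert_tables`` map the time point (3, 6, 12 min) to the
    corresponding sample's peak table.  Returns a per-residue results frame
    (excluded residues keep their exclusion reason and NaN statistics) and the
    classification results for the included residues.
    """
    for t in TIMEPOINTS_MIN:
        if t not in gc_tables or t not in pert_tables:
            raise ValueError(f"missing peak table for the {t}-min time point")
    all_tables = [gc_tables[t] for t in TIMEPOINTS_MIN] + [pert_tables[t] for t in TIMEPOINTS_MIN]
    included, reasons = select_residues(all_tables, snr_min=snr_min, floor_multiple=floor_multiple)

    rows = []
    classifications: dict[int, ClassificationResult] = {}
    universe = sorted(included | set(reasons))
    for res in universe:
        if res not in included:
            rows.append({"residue": res, "label": "", "onset": "", "exclusion_reason": reasons[res]})
            continue
        ratios = {t: _ratio_for(res, t, gc_tables[t], pert_tables[t]) for t in TIMEPOINTS_MIN}
        dr, edr, calls = {}, {}, {}
        for t in (6, 12):
            dr[t] = delta_R(ratios[t].R_t, ratios[3].R_t)
            edr[t] = error_delta_R(ratios[t].error_R, ratios[3].error_R, method=errdr_method)
            calls[t] = classify(dr[t], edr[t])
        label, onset = combine_timepoints(calls[6], calls[12])
        result = ClassificationResult(
            residue_number=res,
            delta_R_6=dr[6],
            delta_R_12=dr[12],
            error_delta_R_6=edr[6],
            error_delta_R_12=edr[12],
            label=label,
            onset=onset,
        )
        classifications[res] = result
        rows.append(
            {
                "residue": res,
                "R3": ratios[3].R_t,
                "err3": ratios[3].error_R,
                "R6": ratios[6].R_t,
                "err6": ratios[6].error_R,
                "R12": ratios[12].R_t,
                "err12": ratios[12].error_R,
                "dR6": dr[6],
                "errdR6": edr[6],
                "dR12": dr[12],
                "errdR12": edr[12],
                "label": label,
                "onset": onset,
                "exclusion_reason": "",
            }
        )
    columns = [
        "residue", "R3", "err3", "R6", "err6", "R12", "err12",
        "dR6", "errdR6", "dR12", "errdR12", "label", "onset", "exclusion_reason",
    ]
    frame = pd.DataFrame(rows).reindex(columns=columns)
    return frame, classifications
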