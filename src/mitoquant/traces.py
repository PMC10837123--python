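"""Split-luciferase import-trace processing and TMRM ΔΨ quantification.

The split-luciferase (MitoLuc) assay reports precursor arrival in the
mitochondrial matrix as a luminescence rise after substrate injection;
the import amplitude (plateau minus the 30 s pre-injection baseline) is
proportional to the amount of protein imported.  Normalisation follows a
fixed four-stage order:

1. divide each well's luminescence by its eqFP670 fluorescence (controls
   for variation in the mitochondrial 11S acceptor);
2. average technical replicates per condition and time point;
3. divide by the maximum amplitude of the run;
4. divide by the control condition's amplitude → percent of control.

The stage order is part of the contract — permuting stages 3 and 4
changes percent-of-control whenever the control is not the run maximum.

TMRM quantification: average the first ``n_first`` frames, threshold the
mitochondria on that average, subtract the average of the final
``n_last`` frames (after CCCP collapse, i.e. background), and report the
mean corrected intensity within the mask.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import ImageStack, binarize

__all__ = [
    "AmplitudeResult",
    "amplitude",
    "normalize_traces",
    "percent_reduction",
    "tmrm_intensity",
]

REQUIRED_COLUMNS = ("time_s", "well", "condition", "technical_rep",
                    "luminescence", "eqfp670_fluor")


@dataclass(frozen=True)
class AmplitudeResult:
    """Import amplitude of one condition's (averaged) trace.

    ``amplitude = plateau - baseline`` in the units of the input trace;
    ``normalized_amplitude`` is the amplitude as a fraction of the run
    maximum (stage 3); ``percent_of_control`` is relative to the control
    condition (stage 4; NaN when no control was supplied).
    """

    condition: str
    baseline: float
    plateau: float
    amplitude: float
    normalized_amplitude: float = float("nan")
    percent_of_control: float = float("nan")


def amplitude(time_s: np.ndarray, lum: np.ndarray,
              baseline_window_s: float = 30.0,
              plateau_frac: float = 0.1,
              condition: str = "trace") -> AmplitudeResult:
    """Baseline, plateau and amplitude of one luminescence trace.

    Baseline: mean over samples strictly before ``baseline_window_s``
    (the pre-injection read).  Plateau: mean over the final
    ``plateau_frac`` of samples — traces are read to saturation, so the
    tail mean estimates the plateau without a kinetic fit.
    """
    t = np.asarray(time_s, dtype=float)
    y = np.asarray(lum, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise ValueError("time_s and lum must be matching 1-D arrays")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time_s must be strictly increasing")
    base_sel = t < baseline_window_s
    if not base_sel.any() or t[-1] <= baseline_window_s:
        raise ValueError(
            f"trace shorter than the {baseline_window_s}s baseline window")
    n_tail = max(1, int(round(plateau_frac * t.size)))
    baseline = float(y[base_sel].mean())
    plateau = float(y[-n_tail:].mean())
    return AmplitudeResult(condition=condition, baseline=baseline,
                           plateau=plateau, amplitude=plateau - baseline)


def _validate(traces: pd.DataFrame) -> None:
    missing = set(REQUIRED_COLUMNS) - set(traces.columns)
    if missing:
        raise ValueError(f"traces missing columns: {sorted(missing)}")
    if (traces["eqfp670_fluor"] <= 0).any():
        raise ValueError("eqfp670_fluor must be positive")
    dt = traces.groupby("well")["time_s"].apply(
        lambda s: np.diff(np.sort(s.to_numpy())))
    for well, gaps in dt.items():
        if len(gaps) and gaps.max() > 6.0 + 1e-9:
            warnings.warn(
                f"well {well}: sampling interval {gaps.max():.1f}s exceeds "
                "the 6s acquisition spec", stacklevel=3)


def normalize_traces(traces: pd.DataFrame,
                     control_condition: str | None = None,
                     baseline_window_s: float = 30.0,
                     plateau_frac: float = 0.1
                     ) -> tuple[pd.DataFrame, list[AmplitudeResult]]:
    """Four-stage normalisation of a plate-reader run (see module docs).

    Parameters
    ----------
    traces : long-format table with columns ``time_s, well, condition,
        technical_rep, luminescence, eqfp670_fluor``.
    control_condition : condition name used for stage 4. If ``None`` or
        absent from the run, stages 1–3 are applied and
        ``percent_of_control`` stays NaN (flagged output).

    Returns
    -------
    (normalized, results) : per-condition averaged traces (columns
        time_s, condition, lum_norm — on the run-max scale) and one
        :class:`AmplitudeResult` per condition.
    """
    _validate(traces)
    df = traces.copy()
    # stage 1: per-well eqFP670 normalisation
    df["lum_norm"] = df["luminescence"] / df["eqfp670_fluor"]
    # stage 2: average technical replicates
    avg = (df.groupby(["condition", "time_s"], sort=True)["lum_norm"]
             .mean().reset_index())

    results = [
        amplitude(sub["time_s"].to_numpy(), sub["lum_norm"].to_numpy(),
                  baseline_window_s, plateau_frac, condition=cond)
        for cond, sub in avg.groupby("condition", sort=True)
    ]
    # stage 3: normalise to the maximum amplitude of the run
    run_max = max(r.amplitude for r in results)
    if run_max <= 0:
        raise ValueError("run-maximum amplitude is not positive")
    avg["lum_norm"] = avg["lum_norm"] / run_max
    results = [AmplitudeResult(
        condition=r.condition, baseline=r.baseline, plateau=r.plateau,
        amplitude=r.amplitude, normalized_amplitude=r.amplitude / run_max)
        for r in results]

    # stage 4: normalise to the control condition
    conditions = {r.condition for r in results}
    if control_condition is not None and control_condition not in conditions:
        warnings.warn(f"control condition {control_condition!r} absent; "
                      "returning stage-3 output", stacklevel=2)
        control_condition = None
    if control_condition is not None:
        ctrl = next(r for r in results if r.condition == control_condition)
        results = [AmplitudeResult(
            condition=r.condition, baseline=r.baseline, plateau=r.plateau,
            amplitude=r.amplitude,
            normalized_amplitude=r.normalized_amplitude,
            percent_of_control=100.0 * r.amplitude / ctrl.amplitude)
            for r in results]
    return avg, results


def percent_reduction(amp_condition: float, amp_reference: float) -> float:
    """Percent loss of import amplitude relative to a reference:
    ``100·(1 − amp_condition/amp_reference)``."""
    if amp_reference == 0:
        raise ValueError("reference amplitude is zero")
    return 100.0 * (1.0 - amp_condition / amp_reference)


def tmrm_intensity(series: ImageStack | np.ndarray, n_first: int = 10,
                   n_last: int = 3,
                   threshold_method: str | float = "otsu") -> float:
    """Background-corrected TMRM intensity of the mitochondrial mask.

    ``A`` = mean of the first ``n_first`` frames (polarised);
    mask = binarised ``A``; ``B`` = mean of the final ``n_last`` frames
    (post-CCCP background). Returns the mean of ``A − B`` within the
    mask.
    """
    movie = series.pixels if isinstance(series, ImageStack) else \
        np.asarray(series, dtype=float)
    if movie.ndim != 3:
        raise ValueError("TMRM series must be (T, H, W)")
    if movie.shape[0] < n_first + n_last:
        raise ValueError(
            f"series has {movie.shape[0]} frames; needs at least "
            f"{n_first + n_last}")
    pre = movie[:n_first].mean(axis=0)
    post = movie[-n_last:].mean(axis=0)
    mask = binarize(pre, threshold_method)
    if not mask.any():
        raise ValueError("TMRM threshold produced an empty mask")
    corrected = pre - post
    return float(corrected[mask].mean())
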