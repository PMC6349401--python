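"""FRAP trace correction, normalization, fitting, and mobile-fraction estimation.

Raw ROI means are double-normalized: background-subtracted, divided by the
background-subtracted reference ROI (which corrects acquisition
photobleaching), and scaled so the pre-bleach mean is 1.  The post-bleach
recovery is fit with a single-exponential model

    F(t) = f0 + (f_inf - f0) * (1 - exp(-(t - t_bleach) / tau)),

the standard empirical model for recovery dominated by one exchange process.
The mobile fraction is the recovered share of the bleached pool,

    mobile % = 100 * (f_inf - f0) / (1 - f0),

with the pre-bleach level normalized to 1; tau is the exchange time constant
and the recovery half-time is tau * ln 2.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .stack_model import FrapTrace

logger = logging.getLogger(__name__)

RECOVERY_MODEL = "single_exponential"


@dataclass
class FrapResult:
    """Fitted FRAP recovery parameters for one trace."""

    mobile_fraction: float  # percent, in [0, 100]
    tau: float  # seconds
    half_time: float  # seconds, = tau * ln 2
    f0: float  # normalized post-bleach floor
    f_inf: float  # normalized plateau
    fit_rss: float
    n_frames: int
    mode: str = "full_bleach"
    label: str = ""
    model: str = RECOVERY_MODEL


def correct_and_normalize(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Double normalization of a raw FRAP trace.

    F(t) = R(t) / mean_pre(R),   R(t) = (bleach - bg) / (ref - bg)

    where ``mean_pre`` averages over the pre-bleach frames.  Dividing by the
    reference corrects acquisition bleaching (which hits both ROIs alike);
    dividing by the pre-bleach mean of the corrected ratio scales the
    pre-bleach mean of F to exactly 1 (with a noiseless reference this
    equals the familiar two-factor form
    (bleach/ref) * mean_pre(ref)/mean_pre(bleach)).

    Returns (times, normalized values).
    """
    bleach = trace.bleach_roi - trace.background_roi
    ref = trace.reference_roi - trace.background_roi
    if np.any(ref <= 0):
        raise ValueError(
            "invalid reference: reference - background must be positive at "
            "every frame"
        )
    npre = trace.n_prebleach
    ratio = bleach / ref
    pre_ratio = ratio[:npre].mean()
    if pre_ratio <= 0:
        raise ValueError("invalid trace: nonpositive pre-bleach bleach-ROI signal")
    f = ratio / pre_ratio
    return trace.times.copy(), f


def _recovery(t, f0, f_inf, tau):
    return f0 + (f_inf - f0) * (1.0 - np.exp(-t / tau))


def fit_recovery(
    times: np.ndarray,
    values: np.ndarray,
    n_prebleach: int,
    mode: str = "full_bleach",
    label: str = "",
) -> FrapResult:
    """Least-squares single-exponential fit of the post-bleach recovery.

    Initialization is data-driven: f0 from the first post-bleach value,
    f_inf from the mean of the last 10% of frames, tau from the time taken
    to reach halfway between them.  The mobile fraction is clamped to
    [0, 100] with a warning if the fit strays outside.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    post_t = times[n_prebleach:]
    post_f = values[n_prebleach:]
    if post_t.size < 10:
        raise ValueError("need at least 10 post-bleach frames to fit")
    pre_level = float(values[:n_prebleach].mean())
    if not post_f[0] < pre_level:
        raise ValueError(
            "first post-bleach value is not below the pre-bleach level; "
            "is n_prebleach correct?"
        )
    t_bleach = post_t[0]
    t = post_t - t_bleach

    f0_init = float(post_f[0])
    tail = max(1, post_f.size // 10)
    finf_init = float(post_f[-tail:].mean())
    if finf_init <= f0_init:
        finf_init = f0_init + 1e-3
    halfway = f0_init + 0.5 * (finf_init - f0_init)
    above = np.nonzero(post_f >= halfway)[0]
    tau_init = float(t[above[0]]) if above.size and t[above[0]] > 0 else float(
        max(t[-1] / 10.0, np.diff(times).mean())
    )

    try:
        popt, _ = curve_fit(
            _recovery,
            t,
            post_f,
            p0=[f0_init, finf_init, tau_init],
            bounds=([-np.inf, -np.inf, 1e-9], [np.inf, np.inf, np.inf]),
            maxfev=10000,
        )
    except RuntimeError as err:
        raise RuntimeError(
            f"FRAP fit failed ({err}); init f0={f0_init:.3g}, "
            f"f_inf={finf_init:.3g}, tau={tau_init:.3g}, "
            f"n_post={post_f.size}, range=({post_f.min():.3g}, {post_f.max():.3g})"
        ) from err
    f0, f_inf, tau = (float(v) for v in popt)
    rss = float(np.sum((post_f - _recovery(t, *popt)) ** 2))
    mobile = 100.0 * (f_inf - f0) / (1.0 - f0) if f0 < 1.0 else float("nan")
    if not np.isnan(mobile) and (mobile < 0 or mobile > 100):
        warnings.warn(
            f"mobile fraction {mobile:.1f}% outside [0, 100]; clamping",
            stacklevel=2,
        )
        mobile = float(np.clip(mobile, 0.0, 100.0))
    return FrapResult(
        mobile_fraction=mobile,
        tau=tau,
        half_time=tau * np.log(2.0),
        f0=f0,
        f_inf=f_inf,
        fit_rss=rss,
        n_frames=int(times.size),
        mode=mode,
        label=label,
    )


def analyze_trace(trace: FrapTrace, mode: str = "full_bleach") -> FrapResult:
    """Correct, normalize, and fit one raw trace."""
    times, values = correct_and_normalize(trace)
    return fit_recovery(times, values, trace.n_prebleach, mode=mode,
                        label=trace.label)


def batch_frap(
    traces: list[FrapTrace], mode: str = "full_bleach"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Analyze a group of traces and summarize as mean ± sd with N.

    Per-trace failures are recorded (logged, with the failure reason in the
    table) rather than fatal.  Returns (per-trace table, group summary with
    columns mean, sd, n).  With a single successful trace the sd is NaN.
    """
    if len(traces) == 0:
        raise ValueError("batch_frap needs at least one trace")
    rows = []
    for trace in traces:
        try:
            res = analyze_trace(trace, mode=mode)
            rows.append(
                {
                    "label": trace.label,
                    "mobile_fraction_pct": res.mobile_fraction,
                    "tau_s": res.tau,
                    "half_time_s": res.half_time,
                    "f0": res.f0,
                    "f_inf": res.f_inf,
                    "fit_rss": res.fit_rss,
                    "n_frames": res.n_frames,
                    "mode": res.mode,
                    "model": res.model,
                    "error": "",
                }
            )
        except (ValueError, RuntimeError) as err:
            logger.warning("trace %s failed: %s", trace.label, err)
            rows.append(
                {"label": trace.label, "mobile_fraction_pct": np.nan,
                 "tau_s": np.nan, "half_time_s": np.nan, "f0": np.nan,
                 "f_inf": np.nan, "fit_rss": np.nan,
                 "n_frames": len(trace.times), "mode": mode,
                 "model": RECOVERY_MODEL, "error": str(err)}
            )
    table = pd.DataFrame(rows)
    ok = table[table["error"] == ""]
    summary = pd.DataFrame(
        [
            {
                "mode": mode,
                "mobile_fraction_mean_pct": ok["mobile_fraction_pct"].mean(),
                "mobile_fraction_sd_pct": ok["mobile_fraction_pct"].std(ddof=1),
                "tau_mean_s": ok["tau_s"].mean(),
                "n": int(len(ok)),
            }
        ]
    )
    return table, summary
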