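"""Nano-flow trace burst detection, phenotyping and SSC size calibration.

Events are contiguous excursions of the side-scatter (SSC) channel above a
robust threshold: median baseline plus ``k_sigma`` times the MAD-scaled
robust SD.  Robust statistics are used because bursts bias the plain
mean/SD upward.  Fluorescence heights are read at the SSC peak sample of
each excursion (no inter-channel lag: same flow cell).  Phenotype
percentages are reported over all SSC events, double negatives included;
``recalc_without_double_negatives`` rescales them over positives only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DEFAULT_K_SIGMA = 5.0
MAD_SCALE = 1.4826  # MAD -> SD for a Gaussian
MIN_EVENTS_RECOMMENDED = 1000

FLOW_PHENOTYPES = ("double_negative", "CD9_only", "CD81_only", "double_positive")


@dataclass
class FlowTrace:
    """Equal-length channel traces; ``time_ms`` strictly increasing."""

    time_ms: np.ndarray
    ssc: np.ndarray
    fl1: np.ndarray  # AF488 / CD9
    fl2: np.ndarray  # AF647 / CD81

    def __post_init__(self) -> None:
        lengths = {len(self.time_ms), len(self.ssc), len(self.fl1), len(self.fl2)}
        if len(lengths) != 1:
            raise ValueError("trace channels have unequal lengths")
        if len(self.time_ms) and self.duration <= 0:
            raise ValueError("duration must be > 0")

    @property
    def duration(self) -> float:
        return float(self.time_ms[-1] - self.time_ms[0]) if len(self.time_ms) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.time_ms, "ssc": self.ssc, "fl1": self.fl1, "fl2": self.fl2}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FlowTrace":
        return cls(
            time_ms=df["time_ms"].to_numpy(float),
            ssc=df["ssc"].to_numpy(float),
            fl1=df["fl1"].to_numpy(float),
            fl2=df["fl2"].to_numpy(float),
        )


@dataclass
class FlowEvent:
    """One coincident burst (row-object view of the event table)."""

    time_ms: float
    ssc_height: float
    fl1_height: float
    fl2_height: float
    phenotype: str = "double_negative"
    est_diameter_nm: float | None = None


@dataclass
class SscSizeCalibration:
    """Bead ladder (diameter nm vs SSC) with a log-log linear interpolant."""

    diameters_nm: np.ndarray
    ssc: np.ndarray
    coeffs: tuple[float, float] = field(init=False)

    def __post_init__(self) -> None:
        d = np.asarray(self.diameters_nm, dtype=float)
        s = np.asarray(self.ssc, dtype=float)
        if len(d) < 2:
            raise ValueError("need at least 2 bead points")
        order = np.argsort(d)
        d, s = d[order], s[order]
        if not (np.diff(d) > 0).all() or not (np.diff(s) > 0).all():
            raise ValueError("bead table must be strictly monotone increasing")
        self.diameters_nm, self.ssc = d, s
        slope, intercept = np.polyfit(np.log(s), np.log(d), 1)
        self.coeffs = (float(slope), float(intercept))

    def diameter(self, ssc_height: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(diameter nm, extrapolated flag) via piecewise log-log interpolation.

        Outside the bead range the end segments are extended (global log-log
        fit for a 2-point ladder reduces to the same line).
        """
        h = np.asarray(ssc_height, dtype=float)
        log_s = np.log(self.ssc)
        log_d = np.log(self.diameters_nm)
        with np.errstate(divide="ignore"):
            log_h = np.log(h)
        extrapolated = (h < self.ssc[0]) | (h > self.ssc[-1])
        out = np.interp(log_h, log_s, log_d)
        # extend end segments linearly in log-log space
        lo = log_h < log_s[0]
        hi = log_h > log_s[-1]
        slope_lo = (log_d[1] - log_d[0]) / (log_s[1] - log_s[0])
        slope_hi = (log_d[-1] - log_d[-2]) / (log_s[-1] - log_s[-2])
        out[lo] = log_d[0] + slope_lo * (log_h[lo] - log_s[0])
        out[hi] = log_d[-1] + slope_hi * (log_h[hi] - log_s[-1])
        return np.exp(out), extrapolated


def _excursions(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    edges = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask)]
    return starts, ends


def detect_events(
    trace: FlowTrace, k_sigma: float = DEFAULT_K_SIGMA, low_fraction: float = 0.5
) -> pd.DataFrame:
    """Detect SSC bursts; one event per supra-threshold excursion.

    Double-threshold (hysteresis) detection: a candidate region is a
    contiguous excursion above the low threshold (``low_fraction`` of the
    way to the high one); it becomes an event iff it reaches the high
    threshold (baseline + k_sigma * robust SD).  This keeps noise wiggles at
    a pulse's edges from splitting one burst into several while two pulses
    separated by a genuinely sub-threshold gap stay distinct.

    Returns an event table (time_ms, ssc_height, fl1_height, fl2_height,
    peak_index) with per-channel heights read at the SSC peak sample.
    A flat SSC trace (zero robust SD) triggers a no-events warning.
    """
    ssc = np.asarray(trace.ssc, dtype=float)
    if len(ssc) < 100:
        raise ValueError("trace too short for baseline estimation (need >= 100 samples)")
    baseline = float(np.median(ssc))
    sigma = MAD_SCALE * float(np.median(np.abs(ssc - baseline)))
    if sigma == 0:
        warnings.warn("flat SSC baseline (robust SD = 0)", RuntimeWarning)
    threshold = baseline + k_sigma * sigma
    low = baseline + low_fraction * k_sigma * sigma

    above = ssc > threshold
    if not above.any():
        return pd.DataFrame(
            columns=["time_ms", "ssc_height", "fl1_height", "fl2_height", "peak_index"]
        )
    starts, ends = _excursions(ssc > low)

    rows = []
    for s, e in zip(starts, ends):
        if not above[s:e].any():
            continue
        peak = s + int(np.argmax(ssc[s:e]))
        rows.append(
            (
                float(trace.time_ms[peak]),
                float(ssc[peak]),
                float(trace.fl1[peak]),
                float(trace.fl2[peak]),
                peak,
            )
        )
    return pd.DataFrame(
        rows, columns=["time_ms", "ssc_height", "fl1_height", "fl2_height", "peak_index"]
    )


def call_flow_phenotypes(
    events: pd.DataFrame,
    fl1_threshold: float,
    fl2_threshold: float,
    min_events: int = MIN_EVENTS_RECOMMENDED,
) -> dict:
    """Phenotype percentages over all SSC events (sum to 100).

    fl1 (CD9/AF488) and fl2 (CD81/AF647) positivity is height strictly above
    the per-channel threshold.  Returns percentages keyed by phenotype plus
    ``n_events`` and a ``below_min_events`` warning flag.
    """
    n = len(events)
    if n == 0:
        raise ValueError("no events to phenotype")
    cd9 = events["fl1_height"].to_numpy(float) > fl1_threshold
    cd81 = events["fl2_height"].to_numpy(float) > fl2_threshold
    counts = {
        "double_negative": int((~cd9 & ~cd81).sum()),
        "CD9_only": int((cd9 & ~cd81).sum()),
        "CD81_only": int((~cd9 & cd81).sum()),
        "double_positive": int((cd9 & cd81).sum()),
    }
    out = {k: 100.0 * v / n for k, v in counts.items()}
    out["n_events"] = n
    out["below_min_events"] = n < min_events
    return out


def recalc_without_double_negatives(percentages: dict) -> dict:
    """Rescale the three positive percentages over positives only (sum 100).

    Scale-invariant and idempotent; undefined when every event is double
    negative.
    """
    dn = float(percentages["double_negative"])
    pos = [float(percentages[p]) for p in ("CD9_only", "CD81_only", "double_positive")]
    total_pos = sum(pos)
    if total_pos <= 0:
        raise ValueError("all events are double negative; recalculation undefined")
    return {
        p: 100.0 * v / total_pos
        for p, v in zip(("CD9_only", "CD81_only", "double_positive"), pos)
    }


def calibrate_size(
    cal: SscSizeCalibration, events: pd.DataFrame
) -> pd.DataFrame:
    """Attach ``est_diameter_nm`` (and ``extrapolated`` flag) to events."""
    out = events.copy()
    if len(out) == 0:
        out["est_diameter_nm"] = pd.Series(dtype=float)
        out["extrapolated"] = pd.Series(dtype=bool)
        return out
    diam, extr = cal.diameter(out["ssc_height"].to_numpy(float))
    out["est_diameter_nm"] = diam
    out["extrapolated"] = extr
    return out


def recovery_rate(
    conc_before: float, conc_after: float, dilution_factor: float = 1.0
) -> float:
    """Percentage of particles recovered across a processing step."""
    if conc_before <= 0:
        raise ValueError("conc_before must be > 0")
    return 100.0 * (conc_after * dilution_factor) / conc_before
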