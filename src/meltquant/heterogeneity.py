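"""Detection of heterogeneous-methylation melt profiles.

A homogeneous sample is a mixture of fully methylated and fully
unmethylated template whose components melt at the assay's two intrinsic
midpoints, typically ~3 °C apart (a 50% standard is exactly such a
2-component mixture).  Heterogeneous methylation — different patterns
across molecules/CpG sites — produces transitions *outside* that intrinsic
span, visible as extra peaks in the negative derivative -dF/dT of the
normalized melt curve.

We operationalize "unusual melting profile" as >=2 local maxima of the
Savitzky-Golay-smoothed derivative that (a) have prominence above a
fraction (default 10%) of the trace's own maximum derivative, and (b) are
mutually separated by more than the assay's intrinsic Tm span (default
minimum separation 3.5 °C, just above the typical 3 °C
methylated/unmethylated melt distance).  Without the separation rule every
intermediate-methylation sample would be flagged, since its two expected
components resolve at default smoothing.  Peaks are searched in the melt
region (assay window ± 2.5 °C); the flat pre/post-melt plateaus contribute
only noise.  Flagged samples keep their methylation estimate; the flag
marks them for follow-up with a pattern-resolving assay.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .errors import ValidationError
from .melt_io import AssayConfig, MeltCurveSet

__all__ = ["MeltProfileScore", "derivative_melt", "flag_heterogeneous"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MeltProfileScore:
    """Peak census of one well's derivative melt curve."""

    well: str
    n_transitions: int
    prominences: tuple[float, ...]
    heterogeneous: bool


def derivative_melt(trace: np.ndarray, temperatures: np.ndarray,
                    cfg: AssayConfig) -> np.ndarray:
    """Smoothed negative derivative -dF/dT (RFU/°C); melts become positive peaks."""
    trace = np.asarray(trace, float)
    if trace.size < cfg.het_smooth_points:
        raise ValidationError(
            f"trace of {trace.size} points shorter than smoothing window "
            f"({cfg.het_smooth_points})"
        )
    step = float(np.mean(np.diff(temperatures)))
    return -savgol_filter(trace, cfg.het_smooth_points, cfg.het_smooth_order,
                          deriv=1, delta=step)


#: half-width (°C) added to the assay window when searching for melt peaks
SEARCH_MARGIN = 2.5


def count_transitions(trace: np.ndarray, temperatures: np.ndarray,
                      cfg: AssayConfig, well: str = "") -> MeltProfileScore:
    """Count prominent, well-separated derivative peaks in the melt region."""
    deriv = derivative_melt(trace, temperatures, cfg)
    lo, hi = cfg.window_lo - SEARCH_MARGIN, cfg.window_hi + SEARCH_MARGIN
    region = np.flatnonzero((temperatures >= lo) & (temperatures <= hi))
    sub = deriv[region[0]:region[-1] + 1] if region.size else deriv
    peak_max = float(sub.max(initial=0.0))
    if peak_max <= 0:
        return MeltProfileScore(well, 0, (), False)
    threshold = cfg.het_prominence_frac * peak_max
    step = float(np.mean(np.diff(temperatures)))
    distance = max(1, int(round(cfg.het_min_separation / step)))
    peaks, props = find_peaks(sub, prominence=threshold, distance=distance)
    proms = tuple(float(p) for p in props["prominences"])
    n = len(peaks)
    return MeltProfileScore(well, n, proms, n >= 2)


def flag_heterogeneous(trace: np.ndarray, temperatures: np.ndarray,
                       cfg: AssayConfig,
                       standards: MeltCurveSet | None = None,
                       well: str = "") -> MeltProfileScore:
    """Score one normalized trace; optionally sanity-check the standards.

    Standards are homogeneous mixtures of at most two components, so any
    standard scoring more than 2 transitions indicates a run problem and is
    logged as a warning (the sample's own score is returned regardless).
    """
    if standards is not None:
        for w in standards.wells:
            score = count_transitions(standards.trace(w), standards.temperatures,
                                      cfg, well=w)
            if score.n_transitions > 2:
                logger.warning(
                    "standard well %s shows %d melt transitions (expected <=2); "
                    "check the run", w, score.n_transitions
                )
    return count_transitions(np.asarray(trace, float), temperatures, cfg, well=well)
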