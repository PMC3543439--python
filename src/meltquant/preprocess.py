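"""HRM curve normalization and windowed mean fluorescence.

Normalization follows the standard two-window scheme: a straight line is
least-squares-fitted to the pre-melt window (the fully double-stranded
plateau, upper baseline U(T)) and another to the post-melt window (fully
melted, lower baseline L(T)); the trace is rescaled to

    F_norm(T) = 100 * (F(T) - L(T)) / (U(T) - L(T))

so every well reads ~100 before the melt and ~0 after it, removing
well-to-well amplitude and baseline-drift differences.  The windowed mean
RFU — the arithmetic mean of the normalized trace over the assay's melt
window — is the single number per well that feeds the standard curve.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import DegenerateBaselineError, ValidationError
from .melt_io import AssayConfig, MeltCurveSet

__all__ = ["WindowedRFU", "normalize_curves", "window_mean_rfu", "window_mask"]

#: endpoint tolerance for closed-interval window inclusion (°C)
EDGE_TOL = 1e-9


@dataclass(frozen=True)
class WindowedRFU:
    """Mean normalized fluorescence of one well over the assay window."""

    well: str
    mean_rfu: float
    n_points: int


def _fit_baseline(t: np.ndarray, f: np.ndarray, window: tuple[float, float],
                  label: str) -> np.ndarray:
    mask = (t >= window[0] - EDGE_TOL) & (t <= window[1] + EDGE_TOL)
    if mask.sum() < 3:
        raise ValidationError(
            f"{label} window {window} covers only {int(mask.sum())} grid points; "
            "need >=3"
        )
    slope, intercept = np.polyfit(t[mask], f[mask], 1)
    return slope * t + intercept


def normalize_curves(raw: MeltCurveSet, cfg: AssayConfig) -> MeltCurveSet:
    """Two-window baseline normalization onto the 0–100 relative scale.

    Idempotent: renormalizing an already-normalized set fits baselines of
    ~100 and ~0 and leaves the traces essentially unchanged.

    Raises
    ------
    DegenerateBaselineError
        If for some well the fitted upper baseline does not exceed the lower
        baseline everywhere on the grid (no melt signal to normalize).
    """
    t = raw.temperatures
    out = np.empty_like(raw.rfu)
    for i, well in enumerate(raw.wells):
        f = raw.rfu[i]
        upper = _fit_baseline(t, f, cfg.premelt, "pre-melt")
        lower = _fit_baseline(t, f, cfg.postmelt, "post-melt")
        span = upper - lower
        if np.any(span <= 0):
            raise DegenerateBaselineError(well)
        out[i] = 100.0 * (f - lower) / span
    # overshoot beyond the [-5, 105] contract only happens for pathological
    # noise levels; clip the tolerated sliver rather than fail downstream
    np.clip(out, -5.0, 105.0, out=out)
    return replace(raw, rfu=out, normalized=True)


def window_mask(temperatures: np.ndarray, lo: float, hi: float) -> np.ndarray:
    """Boolean mask of grid points inside the closed interval [lo, hi]."""
    return (temperatures >= lo - EDGE_TOL) & (temperatures <= hi + EDGE_TOL)


def window_mean_rfu(curves: MeltCurveSet, cfg: AssayConfig) -> list[WindowedRFU]:
    """Per-well arithmetic mean of the normalized trace over the assay window."""
    if not curves.normalized:
        raise ValidationError("window_mean_rfu expects normalized curves")
    mask = window_mask(curves.temperatures, cfg.window_lo, cfg.window_hi)
    n = int(mask.sum())
    if n < 3:
        raise ValidationError(
            f"assay window [{cfg.window_lo}, {cfg.window_hi}] intersects the grid "
            f"in {n} points; need >=3"
        )
    means = curves.rfu[:, mask].mean(axis=1)
    return [WindowedRFU(w, float(m), n) for w, m in zip(curves.wells, means)]
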