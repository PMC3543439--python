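"""Interpolating-polynomial standard curve and methylation estimation.

The standard curve maps windowed mean fluorescence to methylation
percentage.  With n standard levels (0, 12.5, 25, 50, 75, 100% by
convention) the calibration is the unique degree-(n-1) polynomial P with

    P(mean_rfu_i) = nominal_pct_i        for every standard level i,

so evaluating P at a sample's mean RFU ("imputation") yields a single
methylation percentage rather than a bracketing range.  P is evaluated
through a barycentric Lagrange representation, which is numerically stable
and exact at the nodes; a degree-(n-1) least-squares fit yields the same
polynomial and supplies power-basis coefficients for the audit dump.

The Net Temperature Shift (NTS) is the alternative single-value estimator:
the sample's normalized curve minus the fully-methylated control's, summed
at 0.1 °C intervals over a 10 °C melt range and divided by 100.  A fully
methylated sample has NTS 0; less methylated samples melt earlier and give
increasingly negative NTS.  An OLS line calibrated on the standards maps
NTS to percent.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BarycentricInterpolator

from .errors import CalibrationError, ValidationError
from .heterogeneity import flag_heterogeneous
from .melt_io import AssayConfig, MeltCurveSet, SampleSheet
from .preprocess import WindowedRFU, normalize_curves, window_mean_rfu

__all__ = [
    "StandardPoint",
    "Calibration",
    "NTSCalibration",
    "QuantResult",
    "fit_interpolation",
    "estimate_methylation",
    "nts",
    "calibrate_nts",
    "quantify_plate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardPoint:
    """One standard level: replicate-averaged windowed RFU at a known %."""

    nominal_pct: float
    mean_rfu: float
    n_replicates: int = 1


@dataclass
class Calibration:
    """The fitted interpolating polynomial pct = P(mean_rfu).

    ``rfu_range`` spans the standards' mean RFU; predictions outside it are
    extrapolations.  ``monotone_ok`` is False when dP/dRFU changes sign on
    the range (Runge-type oscillation) — surfaced as a warning, never
    silently corrected.
    """

    standards: list[StandardPoint]
    assay: str = ""
    coefficients: np.ndarray = field(init=False)  # power basis, ascending
    degree: int = field(init=False)
    rfu_range: tuple[float, float] = field(init=False)
    monotone_ok: bool = field(init=False)
    _interp: BarycentricInterpolator = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pts = sorted(self.standards, key=lambda p: p.nominal_pct)
        if len(pts) < 2:
            raise CalibrationError("need at least 2 standard points")
        rfu = np.array([p.mean_rfu for p in pts])
        pct = np.array([p.nominal_pct for p in pts])
        if np.unique(pct).size != pct.size:
            raise CalibrationError("duplicate nominal levels among standards")
        if np.min(np.abs(np.diff(np.sort(rfu)))) < 1e-12:
            raise CalibrationError(
                "duplicate standard mean RFU values; interpolation is singular"
            )
        diffs = np.diff(rfu)  # pct is sorted ascending here
        if not (np.all(diffs > 0) or np.all(diffs < 0)):
            raise CalibrationError(
                "standard RFU ordering disagrees with methylation ordering; "
                "the melt run failed (standards must melt in order)"
            )
        self.standards = pts
        self.degree = len(pts) - 1
        self.rfu_range = (float(rfu.min()), float(rfu.max()))
        self._interp = BarycentricInterpolator(rfu, pct)
        # equivalent least-squares polynomial of full degree, for the audit
        # dump; fitted on a shifted/scaled domain for conditioning
        poly = np.polynomial.Polynomial.fit(rfu, pct, deg=self.degree)
        self.coefficients = poly.convert().coef
        self.monotone_ok = self._check_monotone()
        if not self.monotone_ok:
            logger.warning(
                "calibration %s: interpolating polynomial is non-monotone on "
                "its RFU range (Runge-type oscillation); estimates between "
                "standards may be unreliable", self.assay or "<unnamed>"
            )
        resid = np.abs(self.predict(rfu) - pct).max()
        if resid > 1e-6:
            raise CalibrationError(
                f"interpolation failed to reproduce standards (max residual {resid:g})"
            )

    def _check_monotone(self, n_grid: int = 1000) -> bool:
        grid = np.linspace(*self.rfu_range, n_grid)
        dp = np.gradient(self.predict(grid), grid)
        return bool(np.all(dp >= 0) or np.all(dp <= 0))

    def predict(self, rfu) -> np.ndarray:
        """Evaluate P at one or more mean-RFU values."""
        return np.asarray(self._interp(np.asarray(rfu, dtype=float)))

    def to_dict(self) -> dict:
        return {
            "assay": self.assay,
            "degree": int(self.degree),
            "coefficients": [float(c) for c in self.coefficients],
            "rfu_range": [float(x) for x in self.rfu_range],
            "monotone_ok": bool(self.monotone_ok),
            "standards": [
                {"nominal_pct": p.nominal_pct, "mean_rfu": p.mean_rfu,
                 "n_replicates": p.n_replicates}
                for p in self.standards
            ],
        }


@dataclass
class QuantResult:
    """Methylation estimate for one sample (replicate group)."""

    sample: str
    pct_interp: float          #: polynomial estimate clamped to [0, 100]
    pct_raw: float             #: unclamped polynomial value
    extrapolated: bool         #: sample RFU outside the standards' range
    pct_nts: float | None = None      #: NTS-calibrated estimate, if available
    replicate_sd: float | None = None  #: SD of per-replicate percentages
    n_replicates: int = 1
    heterogeneous: bool = False
    assay: str = ""


def fit_interpolation(standards: list[StandardPoint],
                      assay: str = "") -> Calibration:
    """Fit the degree-(n-1) interpolating polynomial through the standards."""
    return Calibration(standards=list(standards), assay=assay)


def estimate_methylation(cal: Calibration, w: WindowedRFU | float,
                         sample: str | None = None) -> QuantResult:
    """Impute one windowed mean RFU into the calibration polynomial.

    Out-of-range RFU is clamped into [0, 100] and flagged ``extrapolated``
    rather than raising — real plates contain samples beyond the 0%/100%
    standards' exact fluorescence.
    """
    if isinstance(w, WindowedRFU):
        rfu, name = w.mean_rfu, sample or w.well
    else:
        rfu, name = float(w), sample or ""
    raw = float(cal.predict(rfu))
    lo, hi = cal.rfu_range
    return QuantResult(
        sample=name,
        pct_interp=float(np.clip(raw, 0.0, 100.0)),
        pct_raw=raw,
        extrapolated=not (lo <= rfu <= hi),
        assay=cal.assay,
    )


def nts(sample_trace: np.ndarray, control_trace: np.ndarray,
        temperatures: np.ndarray, cfg: AssayConfig) -> float:
    """Net Temperature Shift of a sample against the methylated control.

    Both normalized traces are linearly resampled to a ``cfg.nts_step``
    (default 0.1 °C) grid over a ``cfg.nts_span`` (default 10 °C) melt range
    centered on the assay window midpoint, endpoints included; the summed
    sample-minus-control difference is divided by 100.
    """
    mid = 0.5 * (cfg.window_lo + cfg.window_hi)
    lo, hi = mid - cfg.nts_span / 2.0, mid + cfg.nts_span / 2.0
    if lo < temperatures[0] - 1e-9 or hi > temperatures[-1] + 1e-9:
        raise ValidationError(
            f"NTS melt range [{lo}, {hi}] exceeds the acquisition grid "
            f"[{temperatures[0]}, {temperatures[-1]}]"
        )
    n = int(round(cfg.nts_span / cfg.nts_step)) + 1
    grid = lo + cfg.nts_step * np.arange(n)
    s = np.interp(grid, temperatures, sample_trace)
    c = np.interp(grid, temperatures, control_trace)
    return float(np.sum(s - c) / 100.0)


@dataclass
class NTSCalibration:
    """OLS line pct = slope * NTS + intercept, clamped to [0, 100]."""

    slope: float
    intercept: float

    def predict(self, value) -> np.ndarray:
        return np.clip(self.slope * np.asarray(value, float) + self.intercept,
                       0.0, 100.0)


def calibrate_nts(standards: list[tuple[float, float]]) -> NTSCalibration:
    """Least-squares line through (nominal_pct, NTS) standard pairs."""
    if len(standards) < 2:
        raise CalibrationError("need at least 2 standards for NTS calibration")
    pct = np.array([p for p, _ in standards], float)
    val = np.array([v for _, v in standards], float)
    if np.ptp(val) < 1e-12:
        raise CalibrationError("zero NTS variance across standards")
    design = np.column_stack([val, np.ones_like(val)])
    (slope, intercept), *_ = np.linalg.lstsq(design, pct, rcond=None)
    return NTSCalibration(float(slope), float(intercept))


def _standard_points(sheet: SampleSheet, assay: str,
                     rfu_by_well: dict[str, float]) -> list[StandardPoint]:
    std = sheet.wells_with_role("standard", assay)
    points = []
    for pct, grp in std.groupby("nominal_pct"):
        vals = [rfu_by_well[w] for w in grp["well"]]
        points.append(StandardPoint(float(pct), float(np.mean(vals)), len(vals)))
    return points


def quantify_plate(curves: MeltCurveSet, sheet: SampleSheet, cfg: AssayConfig,
                   normalize: bool = True, pool_rfu: bool = False
                   ) -> tuple[list[QuantResult], Calibration]:
    """Full pipeline for one assay: normalize, average the melt window,
    fit the standard curve, and quantify every sample replicate group.

    Replicates are quantified individually and reported as mean ± SD of
    percentages; ``pool_rfu=True`` averages RFU across replicates first.
    The NTS channel is filled when a methylated control (or a 100%
    standard) is on the plate.  Heterogeneity flags come from the
    derivative-peak detector applied to each sample's normalized curves.
    """
    sheet.check_wells(curves)
    assay = cfg.assay
    in_assay = sheet.table[sheet.table["assay"] == assay]
    if in_assay.empty:
        raise ValidationError(f"no wells for assay {assay!r} in the sample sheet")
    if sheet.wells_with_role("standard", assay).empty:
        raise ValidationError(f"no standards for assay {assay!r}")

    plate = curves.subset(list(in_assay["well"]))
    norm = normalize_curves(plate, cfg) if normalize else _as_normalized(plate)
    windowed = {w.well: w.mean_rfu for w in window_mean_rfu(norm, cfg)}

    cal = fit_interpolation(_standard_points(sheet, assay, windowed), assay=assay)

    # NTS reference: methylated-control wells, else the 100% standards
    ctrl = sheet.wells_with_role("methylated_control", assay)["well"].tolist()
    if not ctrl:
        std = sheet.wells_with_role("standard", assay)
        ctrl = std.loc[std["nominal_pct"] == 100.0, "well"].tolist()
    nts_cal = None
    control_trace = None
    if ctrl:
        control_trace = np.mean([norm.trace(w) for w in ctrl], axis=0)
        std = sheet.wells_with_role("standard", assay)
        pairs = []
        for pct, grp in std.groupby("nominal_pct"):
            vals = [nts(norm.trace(w), control_trace, norm.temperatures, cfg)
                    for w in grp["well"]]
            pairs.append((float(pct), float(np.mean(vals))))
        try:
            nts_cal = calibrate_nts(pairs)
        except CalibrationError:
            logger.warning("assay %s: NTS calibration degenerate; channel skipped",
                           assay)

    results: list[QuantResult] = []
    samples = sheet.wells_with_role("sample", assay)
    for group, grp in samples.groupby("replicate_group", sort=True):
        wells = grp["well"].tolist()
        rfus = np.array([windowed[w] for w in wells])
        if pool_rfu:
            res = estimate_methylation(cal, float(rfus.mean()), sample=str(group))
            res.replicate_sd = None
        else:
            per_rep = [estimate_methylation(cal, r, sample=str(group)) for r in rfus]
            res = QuantResult(
                sample=str(group),
                pct_interp=float(np.mean([r.pct_interp for r in per_rep])),
                pct_raw=float(np.mean([r.pct_raw for r in per_rep])),
                extrapolated=any(r.extrapolated for r in per_rep),
                replicate_sd=float(np.std([r.pct_interp for r in per_rep], ddof=1))
                if len(per_rep) > 1 else None,
                assay=assay,
            )
        res.n_replicates = len(wells)
        if nts_cal is not None and control_trace is not None:
            vals = [nts(norm.trace(w), control_trace, norm.temperatures, cfg)
                    for w in wells]
            res.pct_nts = float(np.mean(nts_cal.predict(vals)))
        res.heterogeneous = any(
            flag_heterogeneous(norm.trace(w), norm.temperatures, cfg).heterogeneous
            for w in wells
        )
        results.append(res)
    return results, cal


def _as_normalized(plate: MeltCurveSet) -> MeltCurveSet:
    # raw-mode replication (--no-normalize): treat traces as already scaled
    from dataclasses import replace
    return replace(plate, rfu=np.clip(plate.rfu, -5, 105), normalized=True)
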