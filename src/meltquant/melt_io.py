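"""Input/output for melt-curve tables, sample sheets, assay configs and results.

File dialects
-------------
Melt CSV       ``temperature,<well1>,<well2>,...`` — one row per acquisition,
               dot decimal separator, header mandatory.  A ``decimal_comma``
               flag accepts European exports.
Sample sheet   ``well,role,nominal_pct,replicate_group,assay``.
Assay config   YAML keyed by assay label (see :class:`AssayConfig`).

All readers validate the type invariants at the boundary: a strictly
increasing, uniform temperature grid; a rectangular finite RFU matrix; a
sample sheet whose standards carry nominal percentages in [0, 100].
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import GridError, ParseError, ValidationError

__all__ = [
    "MeltCurveSet",
    "SampleSheet",
    "AssayConfig",
    "ROLES",
    "read_melt_csv",
    "write_melt_csv",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_assay_yaml",
    "write_results_csv",
    "write_calibration_yaml",
]

ROLES = frozenset({"standard", "sample", "methylated_control", "unmethylated_control"})

#: uniform-grid tolerance in °C
GRID_TOL = 1e-6


@dataclass
class MeltCurveSet:
    """A temperature grid plus one RFU trace per well.

    Parameters
    ----------
    temperatures
        Strictly increasing, uniformly spaced grid in °C.
    wells
        Well identifiers (opaque strings; plate geometry is not modeled).
    rfu
        Matrix of fluorescence values, shape ``(n_wells, n_temperatures)``.
    normalized
        True once traces are on the 0–100 relative scale.
    """

    temperatures: np.ndarray
    wells: list[str]
    rfu: np.ndarray
    normalized: bool = False

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.rfu = np.asarray(self.rfu, dtype=float)
        self.validate()

    def validate(self) -> None:
        t = self.temperatures
        if t.ndim != 1 or t.size < 2:
            raise GridError("temperature grid needs at least 2 points")
        steps = np.diff(t)
        if np.any(steps <= 0):
            raise GridError("temperatures must be strictly increasing")
        if np.ptp(steps) > GRID_TOL:
            raise GridError(
                f"non-uniform temperature grid: step range [{steps.min():.6g}, "
                f"{steps.max():.6g}] exceeds tolerance {GRID_TOL:g} °C"
            )
        if self.rfu.shape != (len(self.wells), t.size):
            raise ValidationError(
                f"rfu shape {self.rfu.shape} does not match "
                f"({len(self.wells)} wells, {t.size} temperatures)"
            )
        if len(set(self.wells)) != len(self.wells):
            raise ValidationError("duplicate well identifiers")
        if not np.all(np.isfinite(self.rfu)):
            raise ValidationError("non-finite RFU values")
        if self.normalized and (self.rfu.min() < -5 or self.rfu.max() > 105):
            raise ValidationError(
                "normalized traces must lie in [-5, 105]; got "
                f"[{self.rfu.min():.3g}, {self.rfu.max():.3g}]"
            )

    @property
    def step(self) -> float:
        return float(np.mean(np.diff(self.temperatures)))

    def trace(self, well: str) -> np.ndarray:
        """Return the RFU trace of one well."""
        try:
            i = self.wells.index(well)
        except ValueError:
            raise KeyError(f"unknown well {well!r}") from None
        return self.rfu[i]

    def subset(self, wells: Sequence[str]) -> "MeltCurveSet":
        idx = [self.wells.index(w) for w in wells]
        return replace(self, wells=list(wells), rfu=self.rfu[idx])


@dataclass
class SampleSheet:
    """Well → role / nominal % / replicate group / assay mapping.

    ``nominal_pct`` is required for standards; control roles imply 100
    (methylated) or 0 (unmethylated) and are filled in automatically.
    """

    table: pd.DataFrame

    REQUIRED = ("well", "role", "nominal_pct", "replicate_group", "assay")

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in self.REQUIRED if c not in df.columns]
        if missing:
            raise ValidationError(f"sample sheet missing columns: {missing}")
        df["well"] = df["well"].astype(str)
        df["role"] = df["role"].astype(str)
        bad = sorted(set(df["role"]) - ROLES)
        if bad:
            raise ValidationError(f"unknown role(s) {bad}; allowed: {sorted(ROLES)}")
        if df["well"].duplicated().any():
            dups = df.loc[df["well"].duplicated(), "well"].tolist()
            raise ValidationError(f"duplicate wells in sample sheet: {dups}")
        df["nominal_pct"] = pd.to_numeric(df["nominal_pct"], errors="coerce")
        df.loc[df["role"] == "methylated_control", "nominal_pct"] = 100.0
        df.loc[df["role"] == "unmethylated_control", "nominal_pct"] = 0.0
        std = df["role"] == "standard"
        if df.loc[std, "nominal_pct"].isna().any():
            bad_wells = df.loc[std & df["nominal_pct"].isna(), "well"].tolist()
            raise ValidationError(f"standard wells without nominal_pct: {bad_wells}")
        pct = df.loc[std, "nominal_pct"]
        if ((pct < 0) | (pct > 100)).any():
            raise ValidationError("standard nominal_pct outside [0, 100]")
        for assay, grp in df[std].groupby("assay"):
            if grp["nominal_pct"].nunique() < 2:
                raise ValidationError(
                    f"assay {assay!r} has fewer than 2 distinct standard levels"
                )
        self.table = df.reset_index(drop=True)

    def check_wells(self, curves: MeltCurveSet) -> None:
        """Every well of `curves` must appear exactly once in the sheet."""
        sheet_wells = set(self.table["well"])
        curve_wells = set(curves.wells)
        if sheet_wells != curve_wells:
            only_curves = sorted(curve_wells - sheet_wells)
            only_sheet = sorted(sheet_wells - curve_wells)
            raise ValidationError(
                f"sheet/curves well mismatch: missing from sheet {only_curves}, "
                f"missing from curves {only_sheet}"
            )

    def wells_with_role(self, role: str, assay: str | None = None) -> pd.DataFrame:
        df = self.table
        m = df["role"] == role
        if assay is not None:
            m &= df["assay"] == assay
        return df[m]

    @property
    def assays(self) -> list[str]:
        return sorted(self.table["assay"].astype(str).unique())


@dataclass
class AssayConfig:
    """Per-assay analysis windows and detection parameters.

    ``window_lo``/``window_hi`` bound the RFU-averaging window in °C (the
    temperatures over which the template is actively melting, e.g. 74–80 °C
    for the APC assay).  Normalization baselines are fitted on the pre-melt
    window (below the melt) and post-melt window (above it); defaults are
    ``[window_lo-4, window_lo-2]`` and ``[window_hi+2, window_hi+4]`` — one
    degree clear of the window so transitions slightly outside it
    (heterogeneous samples) do not destabilize the baseline fits.
    """

    assay: str
    window_lo: float
    window_hi: float
    premelt: tuple[float, float] = None  # type: ignore[assignment]
    postmelt: tuple[float, float] = None  # type: ignore[assignment]
    nts_step: float = 0.1
    nts_span: float = 10.0
    het_smooth_points: int = 11
    het_smooth_order: int = 3
    het_prominence_frac: float = 0.10
    het_min_separation: float = 3.5

    def __post_init__(self) -> None:
        if not self.window_lo < self.window_hi:
            raise ValidationError("window_lo must be < window_hi")
        if self.premelt is None:
            self.premelt = (self.window_lo - 4.0, self.window_lo - 2.0)
        if self.postmelt is None:
            self.postmelt = (self.window_hi + 2.0, self.window_hi + 4.0)
        self.premelt = (float(self.premelt[0]), float(self.premelt[1]))
        self.postmelt = (float(self.postmelt[0]), float(self.postmelt[1]))
        if not self.premelt[0] < self.premelt[1] <= self.window_lo:
            raise ValidationError("pre-melt window must lie entirely below window_lo")
        if not self.window_hi <= self.postmelt[0] < self.postmelt[1]:
            raise ValidationError("post-melt window must lie entirely above window_hi")
        if self.nts_step <= 0 or self.nts_span <= 0:
            raise ValidationError("nts_step and nts_span must be positive")

    @classmethod
    def default(cls, assay: str = "APC") -> "AssayConfig":
        """Built-in windows: 74–80 °C (APC-like); 76–84 °C for 'CDKN2A'."""
        if assay.upper() == "CDKN2A":
            return cls(assay=assay, window_lo=76.0, window_hi=84.0)
        return cls(assay=assay, window_lo=74.0, window_hi=80.0)

    def to_dict(self) -> dict:
        return {
            "window": [self.window_lo, self.window_hi],
            "premelt": list(self.premelt),
            "postmelt": list(self.postmelt),
            "nts_step": self.nts_step,
            "nts_span": self.nts_span,
            "het_smooth_points": self.het_smooth_points,
            "het_smooth_order": self.het_smooth_order,
            "het_prominence_frac": self.het_prominence_frac,
            "het_min_separation": self.het_min_separation,
        }


# ---------------------------------------------------------------------------
# readers / writers


def _read_csv(path, decimal_comma: bool) -> pd.DataFrame:
    return pd.read_csv(path, decimal="," if decimal_comma else ".")


def read_melt_csv(path: str | Path, decimal_comma: bool = False) -> MeltCurveSet:
    """Read a melt-curve export: a temperature column plus one column per well.

    Raises
    ------
    GridError
        If the temperature grid is non-increasing or non-uniform.
    ParseError
        If any cell is missing or non-numeric (the message names row/column).
    """
    df = _read_csv(path, decimal_comma)
    if df.shape[1] < 2:
        raise ParseError(f"{path}: need a temperature column and >=1 well column")
    tcol = df.columns[0]
    for col in df.columns:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ParseError(
                f"{path}: missing or non-numeric value at row {row + 2}, "
                f"column {col!r}"
            )
        df[col] = vals
    return MeltCurveSet(
        temperatures=df[tcol].to_numpy(float),
        wells=[str(c) for c in df.columns[1:]],
        rfu=df.iloc[:, 1:].to_numpy(float).T,
    )


def write_melt_csv(curves: MeltCurveSet, path: str | Path) -> None:
    df = pd.DataFrame(curves.rfu.T, columns=curves.wells)
    df.insert(0, "temperature", curves.temperatures)
    df.to_csv(path, index=False)


def read_sample_sheet(path: str | Path, decimal_comma: bool = False) -> SampleSheet:
    """Read and validate a ``well,role,nominal_pct,replicate_group,assay`` CSV."""
    return SampleSheet(_read_csv(path, decimal_comma))


def write_sample_sheet(sheet: SampleSheet, path: str | Path) -> None:
    sheet.table.to_csv(path, index=False)


def read_assay_yaml(path: str | Path) -> dict[str, AssayConfig]:
    """Read per-assay configuration, YAML keyed by assay label."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: assay YAML must map assay label -> settings")
    configs: dict[str, AssayConfig] = {}
    for assay, settings in raw.items():
        settings = dict(settings or {})
        try:
            window = settings.pop("window")
            lo, hi = float(window[0]), float(window[1])
        except (KeyError, TypeError, IndexError):
            raise ValidationError(f"assay {assay!r}: 'window: [lo, hi]' is required")
        kwargs = {}
        for key in ("premelt", "postmelt"):
            if key in settings:
                pair = settings.pop(key)
                kwargs[key] = (float(pair[0]), float(pair[1]))
        for key in ("nts_step", "nts_span", "het_prominence_frac",
                    "het_min_separation"):
            if key in settings:
                kwargs[key] = float(settings.pop(key))
        for key in ("het_smooth_points", "het_smooth_order"):
            if key in settings:
                kwargs[key] = int(settings.pop(key))
        if settings:
            raise ValidationError(f"assay {assay!r}: unknown keys {sorted(settings)}")
        configs[str(assay)] = AssayConfig(str(assay), lo, hi, **kwargs)
    return configs


RESULT_COLUMNS = [
    "sample", "assay", "pct_interp", "pct_nts", "pct_raw",
    "replicate_sd", "n_replicates", "extrapolated", "heterogeneous",
]


def write_results_csv(results, path: str | Path) -> None:
    """Write quantification results or a comparison report as CSV.

    Percentages are rounded to 2 decimal places; flags stay booleans;
    column order is fixed.  ``results`` is either a nonempty list of
    :class:`~meltquant.quantify.QuantResult` or a
    :class:`~meltquant.compare.ComparisonReport`.
    """
    from .compare import ComparisonReport  # local import avoids cycle

    if isinstance(results, ComparisonReport):
        results.to_frame().to_csv(path, index=False)
        return
    results = list(results)
    if not results:
        raise ValidationError("no results to write")
    rows = []
    for r in results:
        rows.append({
            "sample": r.sample,
            "assay": r.assay,
            "pct_interp": round(float(r.pct_interp), 2),
            "pct_nts": "" if r.pct_nts is None else round(float(r.pct_nts), 2),
            "pct_raw": round(float(r.pct_raw), 2),
            "replicate_sd": "" if r.replicate_sd is None else round(float(r.replicate_sd), 2),
            "n_replicates": r.n_replicates,
            "extrapolated": bool(r.extrapolated),
            "heterogeneous": bool(r.heterogeneous),
        })
    pd.DataFrame(rows, columns=RESULT_COLUMNS).to_csv(path, index=False)


def write_calibration_yaml(calibration, path: str | Path) -> None:
    """Dump a fitted calibration (coefficients, range, diagnostics) for audit."""
    with open(path, "w") as fh:
        yaml.safe_dump(calibration.to_dict(), fh, sort_keys=False)
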