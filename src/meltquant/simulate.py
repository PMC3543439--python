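"""Synthetic MS-HRM plates with ground truth, plus a simulated
pyrosequencing reference channel.

Melting is modeled as a two-state logistic: the fraction of template still
double-stranded at temperature T is

    S(T) = m * sigma((Tm_meth - T)/s_m) + (1 - m) * sigma((Tm_unmeth - T)/s_u)

with sigma the logistic function, m the methylated fraction, and Tm_meth >
Tm_unmeth because the bisulfite-converted methylated amplicon retains its
GC content and melts later.  The raw fluorescence adds linear upper/lower
baselines (dye fluorescence drifts with temperature) and Gaussian
instrument noise:

    F(T) = L(T) + (U(T) - L(T)) * S(T) + eps,   eps ~ N(0, noise_sd).

Heterogeneous methylation (different patterns across molecules) is modeled
as extra logistic components at Tm offsets from the sample's nominal melt
temperature, which produces the multi-transition "unusual" profiles that
the heterogeneity detector flags.

Defaults place the unmethylated and methylated melts 3 °C apart (76 / 79
°C) inside a 70–90 °C ramp read every 0.2 °C, a typical MS-HRM setup.
All randomness flows from one seed through numpy SeedSequence spawning.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .melt_io import MeltCurveSet, SampleSheet

__all__ = [
    "MeltModelParams",
    "TruthEntry",
    "TruthTable",
    "STANDARD_LEVELS",
    "simulate_curve",
    "simulate_plate",
    "simulate_pyro",
    "random_truth",
]

#: the standard dilution series: fully methylated into unmethylated control
#: DNA at known ratios
STANDARD_LEVELS = (0.0, 12.5, 25.0, 50.0, 75.0, 100.0)


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class MeltModelParams:
    """Parameters of the two-state logistic melt model."""

    tm_meth: float = 79.0        #: melting midpoint of methylated amplicon (°C)
    tm_unmeth: float = 76.0      #: melting midpoint of unmethylated amplicon (°C)
    slope_meth: float = 0.5      #: logistic transition width, methylated (°C)
    slope_unmeth: float = 0.5    #: logistic transition width, unmethylated (°C)
    amplitude: float = 100.0     #: RFU span between baselines at ramp start
    baseline_slope_pre: float = -0.8   #: upper-baseline drift (RFU/°C)
    baseline_slope_post: float = -0.2  #: lower-baseline drift (RFU/°C)
    noise_sd: float = 0.0        #: additive Gaussian RFU noise
    t_start: float = 70.0
    t_end: float = 90.0
    t_step: float = 0.2

    def __post_init__(self) -> None:
        if not self.tm_meth > self.tm_unmeth:
            raise ValidationError("tm_meth must exceed tm_unmeth")
        if not (self.t_start < self.tm_unmeth and self.tm_meth < self.t_end):
            raise ValidationError("melting midpoints must lie inside the ramp")
        if self.t_step <= 0:
            raise ValidationError("t_step must be positive")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.t_end - self.t_start) / self.t_step)) + 1
        return self.t_start + self.t_step * np.arange(n)

    def helix_fraction(self, m: float,
                       components: list[tuple[float, float]] | None = None
                       ) -> np.ndarray:
        """Double-stranded fraction S(T) on the grid for methylated fraction m."""
        t = self.grid
        if components is None:
            return (m * _logistic((self.tm_meth - t) / self.slope_meth)
                    + (1.0 - m) * _logistic((self.tm_unmeth - t) / self.slope_unmeth))
        # heterogeneous: components at Tm offsets from the nominal melt
        tm0 = self.tm_unmeth + m * (self.tm_meth - self.tm_unmeth)
        s = np.zeros_like(t)
        for offset, weight in components:
            s += weight * _logistic((tm0 + offset - t) / self.slope_unmeth)
        return s


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one simulated sample."""

    sample: str
    m: float                                   #: true methylated fraction in [0, 1]
    components: tuple[tuple[float, float], ...] | None = None  #: (ΔTm °C, weight)
    cpg_pct: tuple[float, ...] = ()            #: true per-CpG methylation (%)

    def __post_init__(self) -> None:
        if not 0.0 <= self.m <= 1.0:
            raise ValidationError(f"methylated fraction {self.m} outside [0, 1]")
        if self.components is not None:
            total = sum(w for _, w in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValidationError("component weights must sum to 1")
        if self.cpg_pct:
            arr = np.asarray(self.cpg_pct)
            if arr.min() < 0 or arr.max() > 100:
                raise ValidationError("per-CpG values must lie in [0, 100]")
            if abs(arr.mean() - 100.0 * self.m) > 1e-9:
                raise ValidationError("per-CpG mean must equal 100*m")

    @property
    def heterogeneous(self) -> bool:
        return self.components is not None and len(self.components) > 1


@dataclass
class TruthTable:
    entries: list[TruthEntry] = field(default_factory=list)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "sample": [e.sample for e in self.entries],
            "true_pct": [100.0 * e.m for e in self.entries],
            "heterogeneous": [e.heterogeneous for e in self.entries],
        })


def default_cpg_pct(m: float, n_cpg: int,
                    heterogeneous: bool = False) -> tuple[float, ...]:
    """Per-CpG truth with mean exactly 100*m.

    Homogeneous samples methylate every CpG equally; heterogeneous samples
    split the CpGs into a high and a low group straddling the mean.
    """
    target = 100.0 * m
    if not heterogeneous:
        return (target,) * n_cpg
    spread = min(target, 100.0 - target, 40.0)
    vals = [target + spread] * (n_cpg // 2) + [target - spread] * (n_cpg // 2)
    if n_cpg % 2:
        vals.append(target)
    return tuple(vals)


def simulate_curve(m: float, params: MeltModelParams,
                   seed: int | np.random.Generator | None = None,
                   components: list[tuple[float, float]] | None = None
                   ) -> np.ndarray:
    """One raw melt trace for methylated fraction ``m`` on ``params.grid``."""
    if not 0.0 <= m <= 1.0:
        raise ValidationError(f"methylated fraction {m} outside [0, 1]")
    t = params.grid
    upper = params.amplitude + params.baseline_slope_pre * (t - params.t_start)
    lower = params.baseline_slope_post * (t - params.t_start)
    f = lower + (upper - lower) * params.helix_fraction(m, components)
    if params.noise_sd > 0:
        rng = seed if isinstance(seed, np.random.Generator) \
            else np.random.default_rng(seed)
        f = f + rng.normal(0.0, params.noise_sd, size=t.size)
    return f


def simulate_plate(levels=STANDARD_LEVELS,
                   samples: TruthTable | None = None,
                   params: MeltModelParams = MeltModelParams(),
                   seed: int = 0,
                   standard_replicates: int = 3,
                   sample_replicates: int = 1,
                   assay: str = "APC") -> tuple[MeltCurveSet, SampleSheet]:
    """Simulate a plate of standards (triplicate by default) plus samples.

    Returns the raw (un-normalized) curves and a matching sample sheet.
    Reproducible: the same seed yields bit-identical RFU matrices.
    """
    levels = list(levels)
    if not levels:
        raise ValidationError("at least one standard level is required")
    samples = samples or TruthTable()
    n_wells = len(levels) * standard_replicates + len(samples) * sample_replicates
    ss = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in ss.spawn(max(n_wells, 1))]

    wells: list[str] = []
    rows: list[np.ndarray] = []
    sheet_rows: list[dict] = []
    k = 0
    for pct in levels:
        for rep in range(standard_replicates):
            well = f"STD{pct:g}_{rep + 1}"
            wells.append(well)
            rows.append(simulate_curve(pct / 100.0, params, rngs[k]))
            sheet_rows.append({"well": well, "role": "standard",
                               "nominal_pct": pct,
                               "replicate_group": f"STD{pct:g}", "assay": assay})
            k += 1
    for entry in samples:
        comps = list(entry.components) if entry.components else None
        for rep in range(sample_replicates):
            well = f"{entry.sample}_{rep + 1}"
            wells.append(well)
            rows.append(simulate_curve(entry.m, params, rngs[k], comps))
            sheet_rows.append({"well": well, "role": "sample",
                               "nominal_pct": np.nan,
                               "replicate_group": entry.sample, "assay": assay})
            k += 1
    curves = MeltCurveSet(params.grid, wells, np.vstack(rows))
    sheet = SampleSheet(pd.DataFrame(sheet_rows))
    return curves, sheet


def simulate_pyro(truth: TruthTable, n_cpg: int = 7,
                  noise_sd_pct: float = 3.0, seed: int = 0) -> pd.DataFrame:
    """Simulated pyrosequencing reference: noisy per-CpG reads, then the mean.

    Observed per-CpG % = true per-CpG % + N(0, noise_sd_pct), clamped to
    [0, 100]; the reference value per sample is the mean across CpGs.
    Returns a frame ``sample, pct_reference, cpg_1..cpg_n``.
    """
    if n_cpg < 1:
        raise ValidationError("n_cpg must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    for entry in truth:
        true_cpg = np.asarray(entry.cpg_pct or
                              default_cpg_pct(entry.m, n_cpg, entry.heterogeneous))
        if true_cpg.size != n_cpg:
            raise ValidationError(
                f"sample {entry.sample}: truth has {true_cpg.size} CpGs, "
                f"expected {n_cpg}"
            )
        obs = true_cpg + rng.normal(0.0, noise_sd_pct, size=n_cpg) \
            if noise_sd_pct > 0 else true_cpg.astype(float)
        obs = np.clip(obs, 0.0, 100.0)
        row = {"sample": entry.sample, "pct_reference": float(obs.mean())}
        row.update({f"cpg_{i + 1}": float(v) for i, v in enumerate(obs)})
        rows.append(row)
    return pd.DataFrame(rows)


def random_truth(n_samples: int, seed: int = 0, n_cpg: int = 7,
                 het_fraction: float = 0.0, het_delta_tm: float = 6.0,
                 prefix: str = "S") -> TruthTable:
    """Random truth table: m ~ Uniform[0, 1]; a fraction of samples carry
    two-component heterogeneous melting with the given Tm separation."""
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n_het = int(round(het_fraction * n_samples))
    het_idx = set(rng.choice(n_samples, size=n_het, replace=False)) if n_het else set()
    entries = []
    for i in range(n_samples):
        het = i in het_idx
        # an equal-weight bimodal mixture has intermediate mean methylation
        # by construction, so heterogeneous truth draws m mid-range
        m = float(rng.uniform(0.3, 0.7)) if het else float(rng.uniform(0.0, 1.0))
        comps = ((-het_delta_tm / 2, 0.5), (het_delta_tm / 2, 0.5)) if het else None
        entries.append(TruthEntry(
            sample=f"{prefix}{i + 1:03d}", m=m, components=comps,
            cpg_pct=default_cpg_pct(m, n_cpg, het),
        ))
    return TruthTable(entries)
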