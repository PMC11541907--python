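"""Spike-in normalization and per-variant exponential decay fitting.

Count tables hold RNA read counts at the chase timepoints, DNA reads at T0,
and one reserved ``SPIKEIN`` row with the spike-in control counts. The
normalized ratio for variant *v* at timepoint *i* is

    R_i = (N_i / N_0) / CR_i,   CR_i = C_i / C_0

where ``N`` are the variant's RNA counts and ``C`` the spike-in counts. The
series is fit to ``M(t) = exp(-k t)`` with ``k`` the single free parameter
(the T0 point, identically 1, is included); half-life is ``ln 2 / k`` and
goodness of fit is the squared Pearson correlation of observed vs fitted
ratios on the linear scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from mrnadecay._errors import DataError, ValidationError

SPIKEIN_ID = "SPIKEIN"
DEFAULT_TIMEPOINTS: tuple[float, ...] = (0.0, 2.0, 4.0, 8.0, 16.0)

#: fitted k values at/below this bound are treated as "no measurable decay"
K_LOWER_BOUND = 1e-4
K_UPPER_BOUND = 50.0

STATUS_OK = "ok"
STATUS_LOW_READS = "low_reads"
STATUS_FIT_FAILED = "fit_failed"
STATUS_NONEXPONENTIAL = "nonexponential"

PSEUDOCOUNT = 0.5


def rna_column(t: float) -> str:
    return f"rna_t{int(t)}"


class CountTable:
    """Per-variant read counts plus the reserved spike-in row.

    Wraps a DataFrame indexed by variant_id with columns ``dna_t0`` and
    ``rna_t{t}`` for each timepoint. The ``SPIKEIN`` row carries the
    spike-in control counts in the rna columns.
    """

    def __init__(self, df: pd.DataFrame, timepoints: Sequence[float] = DEFAULT_TIMEPOINTS):
        timepoints = tuple(float(t) for t in timepoints)
        if len(timepoints) < 2 or timepoints[0] != 0.0:
            raise ValidationError("timepoints must start at 0 and contain at least two points")
        if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
            raise ValidationError("timepoints must be strictly increasing")
        required = ["dna_t0"] + [rna_column(t) for t in timepoints]
        missing = [c for c in required if c not in df.columns]
        if missing:
            raise ValidationError(f"count table missing columns: {missing}")
        if SPIKEIN_ID not in df.index:
            raise ValidationError(f"count table missing reserved row {SPIKEIN_ID!r}")
        if (df[required].to_numpy() < 0).any():
            raise ValidationError("counts must be non-negative")
        self.df = df[required].copy()
        self.timepoints = timepoints

    @property
    def variant_ids(self) -> list[str]:
        return [v for v in self.df.index if v != SPIKEIN_ID]

    @property
    def rna_columns(self) -> list[str]:
        return [rna_column(t) for t in self.timepoints]

    def variant_frame(self) -> pd.DataFrame:
        return self.df.loc[self.variant_ids]

    def spike_counts(self) -> np.ndarray:
        return self.df.loc[SPIKEIN_ID, self.rna_columns].to_numpy(dtype=float)

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index_label="variant_id")

    @classmethod
    def from_tsv(cls, path: str | Path, timepoints: Sequence[float] = DEFAULT_TIMEPOINTS) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="variant_id")
        return cls(df, timepoints)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountTable):
            return NotImplemented
        return self.timepoints == other.timepoints and self.df.equals(other.df)


@dataclass
class NormalizedSeries:
    """Spike-in normalized decay ratios for one variant."""

    variant_id: str
    r: np.ndarray  # normalized ratios, one per timepoint; R[0] == 1 when N0 > 0
    low_reads: bool


@dataclass
class DecayFit:
    variant_id: str
    k: float
    half_life: float
    r_squared: float
    m0: float
    status: str


def normalize(table: CountTable) -> pd.DataFrame:
    """Compute R_i = (N_i/N_0)/CR_i per variant.

    Returns a DataFrame (variants x timepoints) of normalized ratios with a
    boolean ``low_reads`` column; low-read variants (N_0 == 0) have NaN
    ratios. Raises :class:`DataError` if the spike-in T0 count is zero.
    """
    spike = table.spike_counts()
    if spike[0] <= 0:
        raise DataError("spike-in count at T0 is zero; cannot normalize")
    cr = spike / spike[0]
    if (cr <= 0).any():
        raise DataError("spike-in count of zero at a later timepoint; cannot normalize")
    counts = table.variant_frame()[table.rna_columns].to_numpy(dtype=float)
    n0 = counts[:, 0]
    low = n0 <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (counts / n0[:, None]) / cr[None, :]
    r[low] = np.nan
    out = pd.DataFrame(r, index=table.variant_ids, columns=[f"r_t{int(t)}" for t in table.timepoints])
    out["low_reads"] = low
    return out


def _pearson_r2_rows(obs: np.ndarray, fit: np.ndarray) -> np.ndarray:
    """Row-wise squared Pearson correlation; 0 where either side is constant."""
    obs_c = obs - obs.mean(axis=1, keepdims=True)
    fit_c = fit - fit.mean(axis=1, keepdims=True)
    num = (obs_c * fit_c).sum(axis=1)
    den = np.sqrt((obs_c**2).sum(axis=1) * (fit_c**2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = num / den
    r2 = r**2
    r2[~np.isfinite(r2)] = 0.0
    return np.clip(r2, 0.0, 1.0)


def _sse(r: np.ndarray, t: np.ndarray, k: np.ndarray) -> np.ndarray:
    """SSE(k) per row for model exp(-k t); k is one value per row."""
    pred = np.exp(-np.outer(k, t))
    return ((r - pred) ** 2).sum(axis=1)


def _fit_k_batch(r: np.ndarray, t: np.ndarray, n_grid: int = 256, refine_iters: int = 70) -> np.ndarray:
    """Vectorized 1-D least squares over k >= 0: coarse log-grid + golden refine."""
    grid = np.concatenate(([0.0], np.geomspace(K_LOWER_BOUND, K_UPPER_BOUND, n_grid)))
    # SSE for every row at every grid point: (n_rows, n_grid+1)
    pred = np.exp(-np.outer(grid, t))  # (g, T)
    sse = ((r[:, None, :] - pred[None, :, :]) ** 2).sum(axis=2)
    j = np.argmin(sse, axis=1)
    a = grid[np.maximum(j - 1, 0)]
    b = grid[np.minimum(j + 1, len(grid) - 1)]
    # golden-section search on [a, b] per row
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    for _ in range(refine_iters):
        x1 = b - invphi * (b - a)
        x2 = a + invphi * (b - a)
        left = _sse(r, t, x1) < _sse(r, t, x2)
        b = np.where(left, x2, b)
        a = np.where(left, a, x1)
    return (a + b) / 2.0


def fit_decay_table(
    series: pd.DataFrame,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    r2_threshold: float = 0.75,
) -> pd.DataFrame:
    """Fit exp(-k t) to each variant's normalized series.

    ``series`` is the output of :func:`normalize`. Returns a DataFrame with
    columns k, half_life_min, r_squared, status indexed by variant_id.
    """
    t = np.asarray(timepoints, dtype=float)
    rcols = [f"r_t{int(tp)}" for tp in timepoints]
    r = series[rcols].to_numpy(dtype=float)
    low = series["low_reads"].to_numpy(dtype=bool) if "low_reads" in series else np.zeros(len(series), bool)
    finite_ok = np.isfinite(r).sum(axis=1) >= 3

    k = np.full(len(series), np.nan)
    r2 = np.zeros(len(series))
    fit_rows = (~low) & finite_ok
    if fit_rows.any():
        r_fit = np.where(np.isfinite(r[fit_rows]), r[fit_rows], 0.0)
        k_hat = _fit_k_batch(r_fit, t)
        k[fit_rows] = k_hat
        pred = np.exp(-np.outer(k_hat, t))
        r2[fit_rows] = _pearson_r2_rows(r_fit, pred)

    status = np.full(len(series), STATUS_OK, dtype=object)
    status[low | ~finite_ok] = STATUS_LOW_READS
    at_bound = fit_rows & (k <= K_LOWER_BOUND * 1.5)
    status[fit_rows & (r2 <= r2_threshold)] = STATUS_NONEXPONENTIAL
    status[at_bound] = STATUS_NONEXPONENTIAL  # flat series: no measurable decay
    status[fit_rows & ~np.isfinite(k)] = STATUS_FIT_FAILED

    with np.errstate(divide="ignore"):
        half_life = np.where(k > K_LOWER_BOUND * 1.5, math.log(2.0) / k, np.inf)
    return pd.DataFrame(
        {"k": k, "half_life_min": half_life, "r_squared": r2, "status": status},
        index=series.index,
    )


def fit_decay(r: Iterable[float], timepoints: Sequence[float] = DEFAULT_TIMEPOINTS) -> DecayFit:
    """Fit a single normalized series; see :func:`fit_decay_table`."""
    r = np.asarray(list(r), dtype=float)
    if np.isfinite(r).sum() < 3:
        return DecayFit("", math.nan, math.nan, 0.0, 1.0, STATUS_LOW_READS)
    df = pd.DataFrame([list(r) + [False]], columns=[f"r_t{int(t)}" for t in timepoints] + ["low_reads"], index=["_"])
    row = fit_decay_table(df, timepoints).iloc[0]
    return DecayFit("", float(row.k), float(row.half_life_min), float(row.r_squared), 1.0, str(row.status))


def apply_qc(
    fits: pd.DataFrame,
    table: CountTable,
    min_reads: int = 100,
    r2_threshold: float = 0.75,
) -> tuple[pd.DataFrame, dict]:
    """Filter fits by read depth and fit quality.

    Retains variants with DNA T0 reads >= min_reads, RNA T0 reads >=
    min_reads, and r_squared > r2_threshold. Returns the retained fits and a
    QC report with per-timepoint medians and tally of exclusions.
    """
    counts = table.variant_frame()
    fits = fits.loc[counts.index]
    dna_ok = counts["dna_t0"] >= min_reads
    rna_ok = counts[rna_column(0)] >= min_reads
    fit_ok = (fits["r_squared"] > r2_threshold) & (fits["status"] == STATUS_OK)
    keep = dna_ok & rna_ok & fit_ok
    report = {
        "n_variants": int(len(counts)),
        "n_dna_pass": int(dna_ok.sum()),
        "n_rna_t0_pass": int(rna_ok.sum()),
        "n_fit_pass": int((fits["r_squared"] > r2_threshold).sum()),
        "n_retained": int(keep.sum()),
        "min_reads": int(min_reads),
        "r2_threshold": float(r2_threshold),
        "median_counts": {c: float(counts[c].median()) for c in counts.columns},
        "pct_at_least_min_reads": {
            c: float(100.0 * (counts[c] >= min_reads).mean()) for c in counts.columns
        },
    }
    return fits.loc[keep].copy(), report


def steady_state_level(table: CountTable, timepoint: float = 0.0) -> pd.Series:
    """ln(RNA_t / DNA_0) per variant with 0.5 pseudocount for zero counts."""
    counts = table.variant_frame()
    rna = counts[rna_column(timepoint)].to_numpy(dtype=float)
    dna = counts["dna_t0"].to_numpy(dtype=float)
    rna = np.where(rna <= 0, PSEUDOCOUNT, rna)
    dna = np.where(dna <= 0, PSEUDOCOUNT, dna)
    return pd.Series(np.log(rna / dna), index=counts.index, name=f"ln_level_t{int(timepoint)}")


def level_outcomes(table: CountTable) -> pd.DataFrame:
    """ln-level outcome per timepoint (columns ln_level_t{t})."""
    return pd.concat([steady_state_level(table, t) for t in table.timepoints], axis=1)
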