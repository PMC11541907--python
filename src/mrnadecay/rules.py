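"""Design-rule extraction: systematic model queries and stratified analysis.

Sweeps hold a baseline feature vector fixed and vary one feature family at a
time — all isoform blocks are set to identical values so the queried effect
is unambiguous. Stratified analysis slices the measured dataset (stable
5'-terminal 4-mers, translation-rate bounds, moderate ssRNA) and reports
Pearson correlations with two-tailed p-values plus Tukey box statistics.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from mrnadecay._errors import ConfigurationError, ValidationError
from mrnadecay.features.schema import FeatureSchema
from mrnadecay.model import ModelBundle

RNA = "ACGU"


# ---------------------------------------------------------------------------
# feature-vector editing helpers
# ---------------------------------------------------------------------------

def _isoform_ranks(schema: FeatureSchema) -> range:
    return range(1, schema.n_isoforms + 1)


def set_isoform_feature(vec: np.ndarray, schema: FeatureSchema, name: str, value: float) -> None:
    """Set one named feature to the same value in every isoform block."""
    for r in _isoform_ranks(schema):
        vec[schema.index(f"iso{r}_{name}")] = value


def set_rpph_site(vec: np.ndarray, schema: FeatureSchema, site: str) -> None:
    site = site.upper().replace("T", "U")
    if len(site) != 4 or any(b not in RNA for b in site):
        raise ConfigurationError(f"invalid 4-mer {site!r}")
    for p in range(4):
        for b in RNA:
            set_isoform_feature(vec, schema, f"rpph_p{p}_{b}", 1.0 if site[p] == b else 0.0)
    set_isoform_feature(vec, schema, "rpph_skew", max(site.count(b) for b in RNA) / 4.0)


def baseline_from_features(X: pd.DataFrame, k: pd.Series, schema: FeatureSchema,
                           quantile: float = 0.1) -> np.ndarray:
    """Default sweep baseline: the median feature vector of the most stable
    (lowest measured k) slice of the dataset, with all isoform blocks copied
    from the rank-1 block."""
    stable = k.sort_values().index[: max(1, int(len(k) * quantile))]
    vec = X.loc[stable].median(axis=0).to_numpy(dtype=float).copy()
    for name in _block_feature_names(schema):
        v1 = vec[schema.index(f"iso1_{name}")]
        set_isoform_feature(vec, schema, name, v1)
    return vec


def _block_feature_names(schema: FeatureSchema) -> list[str]:
    prefix = "iso1_"
    return [n[len(prefix):] for n in schema.names if n.startswith(prefix)]


# ---------------------------------------------------------------------------
# sweeps
# ---------------------------------------------------------------------------

@dataclass
class SweepResult:
    swept_feature: str
    grid: list
    delta_ln_level: np.ndarray  # predicted steady-state ln-level minus baseline
    k_pred: np.ndarray
    baseline_ln_level: float
    baseline_k: float
    plateau_onset: float | None = None
    extra: dict = field(default_factory=dict)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "grid": self.grid,
                "delta_ln_level": self.delta_ln_level,
                "k_pred": self.k_pred,
            }
        )


def _predict_point(bundle: ModelBundle, schema: FeatureSchema, vec: np.ndarray) -> tuple[float, float]:
    X = pd.DataFrame([vec], columns=schema.names)
    ln_level = float(bundle.predict_ln_levels(X).iloc[0, 0])
    k = float(bundle.predict_k(X)[0])
    return ln_level, k


def _predict_grid(bundle: ModelBundle, schema: FeatureSchema, vectors: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    X = pd.DataFrame(np.vstack(vectors), columns=schema.names)
    ln_levels = bundle.predict_ln_levels(X).iloc[:, 0].to_numpy()
    ks = bundle.predict_k(X)
    return ln_levels, ks


def sweep_rpph(baseline: np.ndarray, bundle: ModelBundle, schema: FeatureSchema) -> pd.DataFrame:
    """Predicted effect of every 4-nt 5'-terminal site, ranked by stability.

    Returns a 256-row frame with delta_ln_level (steady-state, relative to
    the baseline vector) and k_pred, sorted from most to least stabilizing.
    """
    base_ln, _ = _predict_point(bundle, schema, baseline.copy())
    sites = ["".join(p) for p in itertools.product(RNA, repeat=4)]
    vectors = []
    for site in sites:
        vec = baseline.copy()
        set_rpph_site(vec, schema, site)
        vectors.append(vec)
    ln_levels, ks = _predict_grid(bundle, schema, vectors)
    out = pd.DataFrame(
        {"site": sites, "delta_ln_level": ln_levels - base_ln, "k_pred": ks}
    ).sort_values("delta_ln_level", ascending=False, ignore_index=True)
    return out


SCALAR_SWEEPS = ("tir", "ssrna", "dsrna")


def sweep_scalar(
    baseline: np.ndarray,
    bundle: ModelBundle,
    schema: FeatureSchema,
    feature: str,
    grid: Sequence[float],
    composition: str = "A",
    plateau_tolerance: float = 0.05,
) -> SweepResult:
    """Vary one scalar design factor across a grid.

    feature='tir'   : log TIR (grid in au)
    feature='ssrna' : total ssRNA nt with homopolymer ``composition``
    feature='dsrna' : duplexed nt at fixed ssRNA (one hairpin grows)
    For TIR the result carries the plateau onset: the first grid point whose
    prediction is within ``plateau_tolerance`` of the asymptote (top-of-grid
    prediction), measured relative to the full response range.
    """
    if feature not in SCALAR_SWEEPS:
        raise ConfigurationError(f"feature must be one of {SCALAR_SWEEPS}")
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ConfigurationError("grid must be strictly increasing")
    base_ln, base_k = _predict_point(bundle, schema, baseline.copy())
    vectors = []
    for value in grid:
        vec = baseline.copy()
        if feature == "tir":
            set_isoform_feature(vec, schema, "log_tir", math.log(value))
        elif feature == "ssrna":
            _apply_ssrna(vec, schema, value, composition)
        else:
            _apply_dsrna(vec, schema, value)
        vectors.append(vec)
    ln_levels, ks = _predict_grid(bundle, schema, vectors)
    result = SweepResult(
        swept_feature=feature,
        grid=grid,
        delta_ln_level=ln_levels - base_ln,
        k_pred=ks,
        baseline_ln_level=base_ln,
        baseline_k=base_k,
    )
    if feature == "tir":
        result.plateau_onset = _plateau_onset(np.asarray(grid, float), ln_levels, plateau_tolerance)
    return result


def _plateau_onset(grid: np.ndarray, response: np.ndarray, tolerance: float) -> float | None:
    """First grid point from which the response stays within ``tolerance``
    (relative to the full response range) of the top-of-grid asymptote."""
    span = response.max() - response.min()
    if span <= 0:
        return None
    within = np.abs(response - response[-1]) <= tolerance * span
    stays = np.logical_and.accumulate(within[::-1])[::-1]
    return float(grid[int(np.argmax(stays))])


def _apply_ssrna(vec: np.ndarray, schema: FeatureSchema, ss_nt: float, composition: str) -> None:
    set_isoform_feature(vec, schema, "ssrna_total_nt", ss_nt)
    set_isoform_feature(vec, schema, "ssrna_max_segment", ss_nt)
    set_isoform_feature(vec, schema, "ssrna_mean_segment", ss_nt)
    set_isoform_feature(vec, schema, "ssrna_n_segments", 1.0 if ss_nt > 0 else 0.0)
    for b in RNA:
        set_isoform_feature(vec, schema, f"ssrna_frac_{b}", 1.0 if b == composition else 0.0)
    # the UTR physically grows with added ssRNA
    base_structured = vec[schema.index("iso1_utr_len")] - vec[schema.index("iso1_ssrna_total_nt")]
    set_isoform_feature(vec, schema, "utr_len", max(base_structured, 0.0) + ss_nt)


def _apply_dsrna(vec: np.ndarray, schema: FeatureSchema, ds_nt: float) -> None:
    bp = ds_nt / 2.0
    set_isoform_feature(vec, schema, "duplex_total_bp", bp)
    set_isoform_feature(vec, schema, "duplex_max_len", bp)
    set_isoform_feature(vec, schema, "duplex_mean_len", bp)
    set_isoform_feature(vec, schema, "hairpin_count", 1.0 if ds_nt > 0 else 0.0)
    set_isoform_feature(vec, schema, "loop_total_nt", 4.0 if ds_nt > 0 else 0.0)
    set_isoform_feature(vec, schema, "loop_max_len", 4.0 if ds_nt > 0 else 0.0)
    set_isoform_feature(vec, schema, "loop_mean_len", 4.0 if ds_nt > 0 else 0.0)
    ss = vec[schema.index("iso1_ssrna_total_nt")]
    utr = ss + ds_nt + (4.0 if ds_nt > 0 else 0.0)
    set_isoform_feature(vec, schema, "utr_len", utr)
    set_isoform_feature(vec, schema, "paired_frac", ds_nt / utr if utr > 0 else 0.0)


# ---------------------------------------------------------------------------
# sequence-built sweeps
# ---------------------------------------------------------------------------


class SequenceSweeper:
    """Model queries through designed single-factor construct series.

    Instead of editing feature values in place, each grid point is realised
    as an actual UTR sequence (built the same way the design groups are),
    featurized with the standard pipeline, and then queried; this keeps all
    correlated features (composition, dinucleotides, folding anatomy)
    coherent. TIR is injected after featurization since it is a provider
    value, not a sequence-derived one.
    """

    def __init__(self, bundle: ModelBundle, schema: FeatureSchema, fold_provider=None):
        from mrnadecay.features import NussinovFolder

        self.bundle = bundle
        self.schema = schema
        self.fold_provider = fold_provider or NussinovFolder()

    def _featurize_utr(self, utr: str, tir_au: float) -> np.ndarray:
        from mrnadecay import synthetic_data as sd
        from mrnadecay.features import (
            DesignedTirProvider,
            DesignedTxProvider,
            ProviderSet,
            featurize_construct,
        )

        providers = ProviderSet(
            DesignedTxProvider(len(sd.PROMOTER)),
            DesignedTirProvider({}, default=tir_au),
            self.fold_provider,
        )
        construct = sd.PROMOTER + (utr + sd.CDS_WINDOW).replace("U", "T")
        cds_start = len(sd.PROMOTER) + len(utr)
        vec = featurize_construct(construct, cds_start, providers, self.schema)
        # all predominant isoforms treated as having identical features
        for name in _block_feature_names(self.schema):
            set_isoform_feature(vec, self.schema, name, vec[self.schema.index(f"iso1_{name}")])
        return vec

    def _rbs_tail(self, rbs_index: int) -> str:
        from mrnadecay import synthetic_data as sd

        return sd.RBS_VARIANTS[rbs_index][0]

    def rpph(self, ss_nt: int = 16, rbs_index: int = 4, tir_au: float = 1e4) -> pd.DataFrame:
        """All 256 4-nt 5'-terminal sites on a fixed polyA-spacer backbone."""
        sites = ["".join(p) for p in itertools.product(RNA, repeat=4)]
        tail = "A" * ss_nt + self._rbs_tail(rbs_index)
        vectors = [self._featurize_utr(site + tail, tir_au) for site in sites]
        ln_levels, ks = _predict_grid(self.bundle, self.schema, vectors)
        base = float(np.median(ln_levels))
        return pd.DataFrame(
            {"site": sites, "delta_ln_level": ln_levels - base, "k_pred": ks}
        ).sort_values("delta_ln_level", ascending=False, ignore_index=True)

    def ssrna(self, grid, composition: str = "A", site: str = "AACG",
              rbs_index: int = 4, tir_au: float = 1e5) -> SweepResult:
        """Grow a homopolymer single-stranded region across the grid."""
        vectors = [
            self._featurize_utr(site + composition * int(n) + self._rbs_tail(rbs_index), tir_au)
            for n in grid
        ]
        ln_levels, ks = _predict_grid(self.bundle, self.schema, vectors)
        return SweepResult(
            swept_feature=f"ssrna_{composition}",
            grid=list(grid),
            delta_ln_level=ln_levels - ln_levels[0],
            k_pred=ks,
            baseline_ln_level=float(ln_levels[0]),
            baseline_k=float(ks[0]),
        )

    def dsrna(self, stem_grid, ss_nt: int = 8, site: str = "AACG",
              rbs_index: int = 4, tir_au: float = 1e5) -> SweepResult:
        """Grow a hairpin duplex at fixed ssRNA amount."""
        from mrnadecay.synthetic_data import _hairpin

        vectors = [
            self._featurize_utr(
                site + "A" * ss_nt + _hairpin(int(s)) + self._rbs_tail(rbs_index), tir_au
            )
            for s in stem_grid
        ]
        ln_levels, ks = _predict_grid(self.bundle, self.schema, vectors)
        return SweepResult(
            swept_feature="dsrna",
            grid=[2 * int(s) for s in stem_grid],
            delta_ln_level=ln_levels - ln_levels[0],
            k_pred=ks,
            baseline_ln_level=float(ln_levels[0]),
            baseline_k=float(ks[0]),
        )

    def tir(self, grid, ss_nt: int = 4, site: str = "AACG", rbs_index: int = 4,
            plateau_tolerance: float = 0.05) -> SweepResult:
        """Vary the translation initiation rate on a short-ssRNA backbone."""
        base_vec = self._featurize_utr(site + "A" * ss_nt + self._rbs_tail(rbs_index), 1e3)
        grid = list(grid)
        vectors = []
        for value in grid:
            vec = base_vec.copy()
            set_isoform_feature(vec, self.schema, "log_tir", math.log(value))
            vectors.append(vec)
        ln_levels, ks = _predict_grid(self.bundle, self.schema, vectors)
        result = SweepResult(
            swept_feature="tir",
            grid=grid,
            delta_ln_level=ln_levels - ln_levels[0],
            k_pred=ks,
            baseline_ln_level=float(ln_levels[0]),
            baseline_k=float(ks[0]),
        )
        result.plateau_onset = _plateau_onset(
            np.asarray(grid, float), ln_levels, plateau_tolerance
        )
        return result


# ---------------------------------------------------------------------------
# stratified analysis
# ---------------------------------------------------------------------------

@dataclass
class StratumSummary:
    description: str
    n: int
    pearson_r: float
    p_value: float
    quartiles: tuple[float, float, float]  # q1, median, q3 of k
    whiskers: tuple[float, float]
    n_outliers: int


def stable_rpph_sites(fits: pd.DataFrame, sites: pd.Series, top_m: int = 20) -> list[str]:
    """The top_m most stable 4-mers ranked by median fitted k (data-derived)."""
    merged = pd.DataFrame({"k": fits["k"], "site": sites.loc[fits.index]})
    medians = merged.groupby("site")["k"].median().sort_values()
    return list(medians.index[:top_m])


def stratify(
    fits: pd.DataFrame,
    features: pd.DataFrame,
    sites: pd.Series,
    x: str,
    rpph_top_m: int | None = 20,
    tir_bound: tuple[str, float] | None = None,
    ssrna_range: tuple[float, float] | None = (11, 40),
    y: str = "k",
) -> StratumSummary:
    """Filter to a stratum and correlate ``x`` (feature column) with ``y``.

    Filters: membership of the variant's 5'-terminal 4-mer in the data-derived
    stable set (rpph_top_m), a TIR bound ('>' or '<', au) on exp(iso1_log_tir),
    and an inclusive ssRNA range in nt.
    """
    idx = fits.index.intersection(features.index)
    fits = fits.loc[idx]
    features = features.loc[idx]
    mask = pd.Series(True, index=idx)
    parts = []
    if rpph_top_m is not None:
        stable = set(stable_rpph_sites(fits, sites, rpph_top_m))
        mask &= sites.loc[idx].isin(stable)
        parts.append(f"stable 4-mer (top {rpph_top_m})")
    if tir_bound is not None:
        op, bound = tir_bound
        tir = np.exp(features["iso1_log_tir"])
        mask &= (tir > bound) if op == ">" else (tir < bound)
        parts.append(f"TIR {op} {bound:g} au")
    if ssrna_range is not None:
        lo, hi = ssrna_range
        ss = features["iso1_ssrna_total_nt"]
        mask &= (ss >= lo) & (ss <= hi)
        parts.append(f"ssRNA in [{lo}, {hi}] nt")

    sub_x = features.loc[mask, x] if x in features.columns else fits.loc[mask, x]
    sub_y = fits.loc[mask, y]
    n = int(mask.sum())
    if n < 3:
        return StratumSummary("; ".join(parts), n, math.nan, math.nan,
                              (math.nan,) * 3, (math.nan,) * 2, 0)
    r, p = stats.pearsonr(sub_x.to_numpy(float), sub_y.to_numpy(float))
    q1, med, q3 = np.percentile(sub_y, [25, 50, 75])
    iqr = q3 - q1
    lo_w, hi_w = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    in_dist = sub_y[(sub_y >= lo_w) & (sub_y <= hi_w)]
    outliers = int(((sub_y < lo_w) | (sub_y > hi_w)).sum())
    return StratumSummary(
        description="; ".join(parts),
        n=n,
        pearson_r=float(r),
        p_value=float(p),
        quartiles=(float(q1), float(med), float(q3)),
        whiskers=(float(in_dist.min()), float(in_dist.max())),
        n_outliers=outliers,
    )


# ---------------------------------------------------------------------------
# tertiary-structure comparison
# ---------------------------------------------------------------------------

@dataclass
class TertiaryComparison:
    bins: list[tuple[float, float]]
    median_k_tertiary: list[float]
    median_k_control: list[float]
    control_slope: float  # fitted k per secondary-only ssRNA nt on the control arm
    control_slope_r: float
    tertiary_k_range: float  # max - min of per-bin medians on the tertiary arm


def tertiary_comparison(
    fits: pd.DataFrame,
    secondary_only_ssrna: pd.Series,
    is_tertiary: pd.Series,
    max_ss_nt: float = 33.0,
    bin_width: float = 4.0,
) -> TertiaryComparison:
    """Per-bin median decay rates: tertiary-structure arm vs control arm.

    Both arms are indexed by the ssRNA amount computed as if only secondary
    structure could form; the control-arm slope is a least-squares fit of k
    against ssRNA nt up to ``max_ss_nt``.
    """
    idx = fits.index
    ss = secondary_only_ssrna.loc[idx]
    tert = is_tertiary.loc[idx].astype(bool)
    if tert.sum() == 0 or (~tert).sum() == 0:
        raise ValidationError("both tertiary and control variants are required")
    edges = np.arange(0.0, max_ss_nt + bin_width, bin_width)
    bins, med_t, med_c = [], [], []
    for lo, hi in zip(edges, edges[1:]):
        in_bin = (ss >= lo) & (ss < hi)
        bins.append((float(lo), float(hi)))
        kt = fits.loc[in_bin & tert, "k"]
        kc = fits.loc[in_bin & ~tert, "k"]
        med_t.append(float(kt.median()) if len(kt) else math.nan)
        med_c.append(float(kc.median()) if len(kc) else math.nan)
    ctrl = (~tert) & (ss <= max_ss_nt)
    res = stats.linregress(ss[ctrl].to_numpy(float), fits.loc[ctrl, "k"].to_numpy(float))
    finite_t = [m for m in med_t if not math.isnan(m)]
    return TertiaryComparison(
        bins=bins,
        median_k_tertiary=med_t,
        median_k_control=med_c,
        control_slope=float(res.slope),
        control_slope_r=float(res.rvalue),
        tertiary_k_range=(max(finite_t) - min(finite_t)) if finite_t else math.nan,
    )


# ---------------------------------------------------------------------------
# optional plotting
# ---------------------------------------------------------------------------

def plot_sweep(result: SweepResult, path, log_x: bool = False) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(result.grid, result.delta_ln_level, marker="o", ms=3)
    if log_x:
        ax.set_xscale("log")
    ax.set_xlabel(result.swept_feature)
    ax.set_ylabel("predicted delta ln-level")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
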