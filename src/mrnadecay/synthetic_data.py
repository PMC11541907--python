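"""Synthetic barcoded decay-assay libraries with known ground truth.

Generates design libraries (full-factorial 4-nt 5'-end site x RBS groups,
structure series, G-quadruplex / i-motif groups, motif insertions, RBS
sweeps), barcode sets with a guaranteed minimum pairwise Hamming distance,
ground-truth decay constants assembled from documented additive/multiplicative
effect rules, multinomial read sampling with a constant-mass spike-in, and
FASTQ emission with substitution errors.

Ground-truth decay model (all rates in 1/min):

    exposure E  = comp_factor * min(ss_nt, ss_sat) + (1 - phi(TIR)) * cds_exposure_nt
    k_struct    = slope * min(E, ss_sat)            # pinned at slope*g4_cap_nt
                                                    # when a G-quadruplex forms
    k_pre       = baseline + k_struct  (+ i-motif penalty pushing toward 0.5)
    k_det       = k_pre * rpph_multiplier(first 4 nt)
    k_true      = clip(k_det * exp(sigma * z), k_min, k_max)

comp_factor makes C/A-rich single-stranded regions more accessible than
U/G-rich ones (stiffer backbones expose more RNase landing area).

phi(TIR) is an increasing logistic in log10(TIR) (ribosome protection with a
ceiling near 5e4 au); the 5'-terminal 4-mer multiplier spans a fourfold range
keyed on composition skew (homopolymeric sites decay fastest). Initial
abundance defaults to the steady-state value tx_rate / k_det.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mrnadecay._errors import CapacityError, ConfigurationError
from mrnadecay.kinetics import (
    DEFAULT_TIMEPOINTS,
    SPIKEIN_ID,
    CountTable,
    rna_column,
)

RNA_ALPHABET = "ACGU"
DNA_ALPHABET = "ACGT"

#: constant promoter placed upstream of every designed 5' UTR
PROMOTER = "TTGACGGCTAGCTCAGTCCTAGGTACAGTGCTAGC"
#: first 30 nt of the constant reporter CDS (starts with AUG)
CDS_WINDOW = "AUGCGUAAAGGCGAAGAACUGUUCACUGGU"

#: five RBS region variants of increasing Shine-Dalgarno strength, with the
#: translation initiation rate (au) assigned to each at design time
RBS_VARIANTS: tuple[tuple[str, float], ...] = (
    ("CAACACCAUCAACA", 1e1),
    ("CAAGGACAUCAACA", 1e2),
    ("CAAGGAGAUCAACA", 1e3),
    ("CAAGGAGGUCAACA", 1e4),
    ("UAAGGAGGUAAACA", 1e5),
)

SPACER_MOTIFS: Mapping[str, str] = {
    "full_factorial_polyA": "A",
    "full_factorial_polyU": "U",
    "full_factorial_AAACAAA": "AAACAAA",
    "full_factorial_AAAGAAA": "AAAGAAA",
    "full_factorial_UUUGUUU": "UUUGUUU",
}

DESIGN_GROUPS = tuple(SPACER_MOTIFS) + (
    "structure_series",
    "g_quadruplex",
    "i_motif",
    "motif_insertion",
    "rbs_sweep",
)

#: barcode reserved for the spike-in control amplicon
SPIKEIN_BARCODE = "ACGTACGTACGTACG"

#: default amplicon layout for emitted reads: anchor5 + barcode + anchor3
READ_ANCHOR5 = "GTCCTGACGT"
READ_ANCHOR3 = "TCAGGCATCGGATGC"

#: simple defaults for destabilizing / protein-binding motif insertions
DEFAULT_RNASE_E_MOTIFS: Mapping[str, str] = {"rnase_e_au": "AUUUU"}
DEFAULT_CSRA_MOTIFS: Mapping[str, str] = {"csra_gga": "AGGA"}


@dataclass
class UtrVariant:
    variant_id: str
    design_group: str
    utr_seq: str  # RNA alphabet
    barcode: str  # 15-nt DNA, assigned by attach_barcodes
    rbs_variant_index: int
    # design-time metadata used by the truth generator
    designed_tir: float = 1e3
    ss_len: int = 0  # designed unstructured nt (5'-end site + spacers + loops)
    ss_comp_factor: float = 1.0  # composition modifier of ssRNA accessibility
    has_g4: bool = False
    has_imotif: bool = False
    stem_len: int = 0
    tx_rate: float = 1.0

    @property
    def rpph_site(self) -> str:
        return self.utr_seq[:4]

    def construct(self) -> str:
        """Full sense-strand construct: promoter + UTR + CDS window (DNA)."""
        return PROMOTER + (self.utr_seq + CDS_WINDOW).replace("U", "T")


@dataclass
class TruthRecord:
    variant_id: str
    k_true: float
    m0_true: float
    effect_components: dict[str, float]


@dataclass
class TruthParams:
    baseline: float = 0.07
    ss_slope: float = 0.01  # (1/min) per accessible ssRNA nt
    ss_sat_nt: float = 33.0
    cds_exposure_nt: float = 33.0  # extra accessible nt on an unprotected CDS
    g4_cap_nt: float = 13.0  # G-quadruplex caps accessibility (k ~ 0.2)
    imotif_target: float = 0.5
    tir_midpoint_au: float = 5e3
    tir_log10_width: float = 0.33  # protection saturates in the few-1e4 au range
    rpph_multipliers: tuple[float, float, float, float] = (0.5, 1.0, 1.4, 2.0)
    rpph_jitter: float = 0.05
    k_min: float = 0.027
    k_max: float = 2.24
    sigma: float = 0.1  # lognormal noise on k
    m0_scale: float = 1.0
    m0_mode: str = "steady_state"  # or "uniform"
    m0_sigma: float = 0.15

    def validate(self) -> None:
        if self.sigma < 0 or self.m0_sigma < 0:
            raise ConfigurationError("noise sigma must be non-negative")
        if self.ss_slope <= 0 or self.ss_sat_nt <= 0:
            raise ConfigurationError("ssRNA slope and saturation must be positive")
        if self.k_min <= 0 or self.k_max <= self.k_min:
            raise ConfigurationError("require 0 < k_min < k_max")
        if self.m0_mode not in ("steady_state", "uniform"):
            raise ConfigurationError(f"unknown m0_mode {self.m0_mode!r}")


# ---------------------------------------------------------------------------
# barcodes
# ---------------------------------------------------------------------------

def generate_barcodes(
    n: int,
    length: int = 15,
    min_distance: int = 3,
    seed: int = 0,
    max_attempts_per_code: int = 200,
) -> list[str]:
    """Random DNA barcodes with all pairwise Hamming distances >= min_distance.

    Greedy rejection sampling; deterministic for a fixed seed. Raises
    :class:`CapacityError` when the requested set provably or practically
    cannot be placed.
    """
    if n < 1:
        raise ConfigurationError("n must be >= 1")
    # Singleton-style pigeonhole bound: codes with distance d satisfy
    # |C| <= 4^(L - d + 1)
    if length - min_distance + 1 < 0 or n > 4 ** max(0, length - min_distance + 1):
        raise CapacityError(
            f"cannot place {n} codes of length {length} at distance {min_distance}"
        )
    rng = np.random.default_rng(seed)
    accepted = np.empty((n, length), dtype=np.uint8)
    count = 0
    budget = max_attempts_per_code * n
    while count < n:
        if budget <= 0:
            raise CapacityError(
                f"iteration budget exhausted after accepting {count}/{n} barcodes"
            )
        budget -= 1
        cand = rng.integers(0, 4, size=length, dtype=np.uint8)
        if count:
            dists = (accepted[:count] != cand[None, :]).sum(axis=1)
            if int(dists.min()) < min_distance:
                continue
        accepted[count] = cand
        count += 1
    lut = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    return ["".join(chr(c) for c in lut[row]) for row in accepted]


# ---------------------------------------------------------------------------
# design library
# ---------------------------------------------------------------------------

def _spacer(group: str, length: int = 16) -> str:
    motif = SPACER_MOTIFS[group]
    reps = -(-length // len(motif))
    return (motif * reps)[:length]


def _all_4mers() -> list[str]:
    return ["".join(p) for p in itertools.product(RNA_ALPHABET, repeat=4)]


_COMP = str.maketrans("ACGU", "UGCA")


def _revcomp_rna(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _random_rna(rng: np.random.Generator, length: int, alphabet: str = RNA_ALPHABET) -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), size=length))


def ss_composition_factor(ss_region: str, strength: float = 0.25) -> float:
    """Accessibility modifier of a single-stranded region's composition.

    C/A-rich regions are more accessible (factor up to 1 + strength), U/G-rich
    regions less (down to 1 - strength); an even mix is neutral.
    """
    if not ss_region:
        return 1.0
    n = len(ss_region)
    ac = (ss_region.count("A") + ss_region.count("C")) / n
    ug = (ss_region.count("U") + ss_region.count("G")) / n
    return 1.0 + strength * (ac - ug)


def quadruplex_block(rng: np.random.Generator, base: str = "G", runs: int = 4, run_len: int = 3, loop_len: int = 6) -> str:
    """[(3G-6N)_4]-style block; loops avoid the run base so runs stay exact."""
    loop_alpha = RNA_ALPHABET.replace(base, "")
    parts = []
    for i in range(runs):
        parts.append(base * run_len)
        if i < runs - 1:
            parts.append(_random_rna(rng, loop_len, loop_alpha))
    return "".join(parts)


def default_library_config(scale: float = 1.0) -> dict:
    """Demo library configuration (~3,000 variants at scale=1).

    Group sizes scale linearly except the full-factorial group, which is
    always the complete 256 x n_rbs cross.
    """
    def s(n: int) -> int:
        return max(4, int(round(n * scale)))

    return {
        "full_factorial_polyA": {"n_rbs": 5},
        "structure_series": {
            "ss_lengths": list(range(0, 41, 2)),
            "stem_lengths": [0, 2, 8, 16],
            "rpph_sites": ["AACG", "ACGU", "GACU", "UGCA", "AAAA", "CCCC", "AAGA", "CACA"],
            "rbs_indices": [0, 4],
        },
        "g_quadruplex": {"n": s(260), "rbs_indices": [4], "ss_lengths": list(range(0, 34, 1))},
        "i_motif": {"n": s(260), "rbs_indices": [4], "ss_lengths": list(range(0, 34, 1))},
        "motif_insertion": {"n": s(120)},
        "rbs_sweep": {"n": s(900), "tir_range": (1e2, 1e5)},
    }


def generate_design_library(config: Mapping[str, Mapping], seed: int = 0) -> list[UtrVariant]:
    """Enumerate design groups into a list of variants (barcodes unassigned).

    ``config`` maps design-group names to per-group options; unknown names
    raise :class:`ConfigurationError`. Use :func:`attach_barcodes` to assign
    barcodes afterwards.
    """
    if not config:
        raise ConfigurationError("config names no design groups")
    unknown = [g for g in config if g not in DESIGN_GROUPS]
    if unknown:
        raise ConfigurationError(f"unknown design group(s): {unknown}")
    rng = np.random.default_rng(seed)
    variants: list[UtrVariant] = []
    for group in config:
        opts = dict(config[group] or {})
        if group in SPACER_MOTIFS:
            variants.extend(_gen_full_factorial(group, opts))
        elif group == "structure_series":
            variants.extend(_gen_structure_series(opts))
        elif group == "g_quadruplex":
            variants.extend(_gen_tertiary(group, opts, rng, base="G"))
        elif group == "i_motif":
            variants.extend(_gen_tertiary(group, opts, rng, base="C"))
        elif group == "motif_insertion":
            variants.extend(_gen_motif_insertion(opts, rng))
        elif group == "rbs_sweep":
            variants.extend(_gen_rbs_sweep(opts, rng))
    ids = [v.variant_id for v in variants]
    if len(set(ids)) != len(ids):
        raise ConfigurationError("duplicate variant_ids generated")
    return variants


def _gen_full_factorial(group: str, opts: Mapping) -> list[UtrVariant]:
    n_rbs = int(opts.get("n_rbs", 5))
    spacer_len = int(opts.get("spacer_len", 16))
    if not 1 <= n_rbs <= len(RBS_VARIANTS):
        raise ConfigurationError(f"n_rbs must be in 1..{len(RBS_VARIANTS)}")
    spacer = _spacer(group, spacer_len)
    out = []
    i = 0
    for site in _all_4mers():
        for rbs_idx in range(n_rbs):
            rbs_seq, tir = RBS_VARIANTS[rbs_idx]
            out.append(
                UtrVariant(
                    variant_id=f"{group}_{i:05d}",
                    design_group=group,
                    utr_seq=site + spacer + rbs_seq,
                    barcode="",
                    rbs_variant_index=rbs_idx,
                    designed_tir=tir,
                    ss_len=4 + spacer_len,
                    ss_comp_factor=ss_composition_factor(spacer),
                )
            )
            i += 1
    return out


def _hairpin(stem: int, loop: str = "GAAA") -> str:
    arm = ("GCGUGCCUGGCAGCCGUA" * 2)[:stem]
    return arm + loop + _revcomp_rna(arm) if stem > 0 else ""


def _gen_structure_series(opts: Mapping) -> list[UtrVariant]:
    ss_lengths = list(opts.get("ss_lengths", range(0, 41, 2)))
    stems = list(opts.get("stem_lengths", [0, 2, 8, 16]))
    sites = list(opts.get("rpph_sites", ["AACG", "AAAA"]))
    rbs_indices = list(opts.get("rbs_indices", [0, 4]))
    out = []
    i = 0
    for site in sites:
        for ss in ss_lengths:
            for stem in stems:
                for rbs_idx in rbs_indices:
                    rbs_seq, tir = RBS_VARIANTS[rbs_idx]
                    hp = _hairpin(stem)
                    out.append(
                        UtrVariant(
                            variant_id=f"structure_series_{i:05d}",
                            design_group="structure_series",
                            utr_seq=site + "A" * ss + hp + rbs_seq,
                            barcode="",
                            rbs_variant_index=rbs_idx,
                            designed_tir=tir,
                            ss_len=4 + ss + (4 if stem > 0 else 0),
                            ss_comp_factor=ss_composition_factor("A" * max(ss, 1)),
                            stem_len=stem,
                        )
                    )
                    i += 1
    return out


def _gen_tertiary(group: str, opts: Mapping, rng: np.random.Generator, base: str) -> list[UtrVariant]:
    n = int(opts.get("n", 256))
    ss_lengths = list(opts.get("ss_lengths", range(0, 34)))
    rbs_indices = list(opts.get("rbs_indices", [4]))
    # default sites are skew-neutral (max single-nt count 2) so the tertiary
    # arms are not confounded by 5'-end-site effects
    sites = list(opts.get("rpph_sites", ["AACG", "CCAU", "GGAU", "UUCG"]))
    out = []
    for i in range(n):
        ss = ss_lengths[i % len(ss_lengths)]
        rbs_idx = rbs_indices[i % len(rbs_indices)]
        site = sites[(i // len(ss_lengths)) % len(sites)]
        rbs_seq, tir = RBS_VARIANTS[rbs_idx]
        block = quadruplex_block(rng, base=base)
        out.append(
            UtrVariant(
                variant_id=f"{group}_{i:05d}",
                design_group=group,
                utr_seq=site + "A" * ss + block + rbs_seq,
                barcode="",
                rbs_variant_index=rbs_idx,
                designed_tir=tir,
                ss_len=4 + ss,
                ss_comp_factor=ss_composition_factor("A" * max(ss, 1)),
                has_g4=(base == "G"),
                has_imotif=(base == "C"),
            )
        )
    return out


def _gen_motif_insertion(opts: Mapping, rng: np.random.Generator) -> list[UtrVariant]:
    n = int(opts.get("n", 128))
    motifs = list(opts.get("motifs", list(DEFAULT_RNASE_E_MOTIFS.values()) + list(DEFAULT_CSRA_MOTIFS.values())))
    rbs_indices = list(opts.get("rbs_indices", [2]))
    out = []
    for i in range(n):
        n_ins = 1 + (i % 5)
        motif = motifs[i % len(motifs)]
        rbs_idx = rbs_indices[i % len(rbs_indices)]
        rbs_seq, tir = RBS_VARIANTS[rbs_idx]
        filler = _random_rna(rng, 4, "ACAC")
        region = (motif + filler) * n_ins
        region = region[:30].ljust(30, "A")
        site = _all_4mers()[int(rng.integers(0, 256))]
        out.append(
            UtrVariant(
                variant_id=f"motif_insertion_{i:05d}",
                design_group="motif_insertion",
                utr_seq=site + region + rbs_seq,
                barcode="",
                rbs_variant_index=rbs_idx,
                designed_tir=tir,
                ss_len=4 + 30,
                ss_comp_factor=ss_composition_factor(region),
            )
        )
    return out


def _gen_rbs_sweep(opts: Mapping, rng: np.random.Generator) -> list[UtrVariant]:
    n = int(opts.get("n", 256))
    tir_range = opts.get("tir_range", (1e1, 1e5))
    sites = _all_4mers()
    out = []
    log_lo, log_hi = math.log10(tir_range[0]), math.log10(tir_range[1])
    for i in range(n):
        tir = 10 ** (log_lo + (log_hi - log_lo) * rng.random())
        site = sites[int(rng.integers(0, 256))]
        rbs_seq = _random_rna(rng, 14)
        out.append(
            UtrVariant(
                variant_id=f"rbs_sweep_{i:05d}",
                design_group="rbs_sweep",
                utr_seq=site + "A" * 12 + rbs_seq,
                barcode="",
                rbs_variant_index=i,
                designed_tir=tir,
                ss_len=4 + 12,
                ss_comp_factor=ss_composition_factor("A" * 12),
            )
        )
    return out


def attach_barcodes(
    library: Sequence[UtrVariant], seed: int = 0, length: int = 15, min_distance: int = 3
) -> tuple[list[UtrVariant], str]:
    """Assign a distinct barcode to every variant; returns (library, spike barcode)."""
    codes = generate_barcodes(len(library) + 1, length=length, min_distance=min_distance, seed=seed)
    # reserve index 0 as the spike-in barcode for this library
    return [replace(v, barcode=c) for v, c in zip(library, codes[1:])], codes[0]


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def translation_protection(tir_au: float | np.ndarray, params: TruthParams) -> np.ndarray:
    """Ribosome protection fraction phi in (0,1), increasing in log10(TIR)."""
    x = (np.log10(np.maximum(tir_au, 1e-6)) - math.log10(params.tir_midpoint_au)) / params.tir_log10_width
    return 1.0 / (1.0 + np.exp(-x))


def rpph_multiplier(site: str, params: TruthParams) -> float:
    """Composition-skew multiplier for the first four transcribed nt.

    Keyed on the maximum single-nucleotide count (1..4): balanced sites are
    most stable, homopolymers decay fastest; spans a fourfold range plus a
    small deterministic per-site jitter.
    """
    max_count = max(site.count(b) for b in RNA_ALPHABET)
    base = params.rpph_multipliers[max_count - 1]
    if params.rpph_jitter > 0:
        h = 0
        for ch in site:
            h = (h * 131 + ord(ch)) % 100003
        u = (h / 100003.0) * 2.0 - 1.0  # deterministic in [-1, 1)
        base *= math.exp(params.rpph_jitter * u)
    return base


def generate_truth(
    library: Sequence[UtrVariant],
    params: TruthParams | None = None,
    seed: int = 0,
) -> list[TruthRecord]:
    """Ground-truth decay constants and initial abundances for a library."""
    if not library:
        raise ConfigurationError("library is empty")
    params = params or TruthParams()
    params.validate()
    rng = np.random.default_rng(seed)
    out = []
    for v in library:
        phi = float(translation_protection(v.designed_tir, params))
        ss_nt = v.ss_comp_factor * min(v.ss_len, params.ss_sat_nt)
        ss_capped = min(ss_nt, params.ss_sat_nt)
        exposure = min(ss_nt + (1.0 - phi) * params.cds_exposure_nt, params.ss_sat_nt)
        ssrna_comp = params.ss_slope * ss_capped
        translation_comp = params.ss_slope * (exposure - ss_capped)
        # a formed G-quadruplex dominates the 5' end: accessibility is pinned
        # at a constant regardless of the surrounding ssRNA or translation
        g4_comp = params.ss_slope * (params.g4_cap_nt - exposure) if v.has_g4 else 0.0
        k_pre = params.baseline + ssrna_comp + translation_comp + g4_comp
        imotif_comp = max(0.0, params.imotif_target - k_pre) if v.has_imotif else 0.0
        k_pre += imotif_comp
        mult = rpph_multiplier(v.rpph_site, params)
        rpph_comp = k_pre * (mult - 1.0)
        k_det = k_pre + rpph_comp
        noise = math.exp(params.sigma * rng.standard_normal()) if params.sigma > 0 else 1.0
        k_true = float(np.clip(k_det * noise, params.k_min, params.k_max))
        if params.m0_mode == "steady_state":
            m0 = params.m0_scale * v.tx_rate / k_det
        else:
            m0 = params.m0_scale * v.tx_rate
        if params.m0_sigma > 0:
            m0 *= math.exp(params.m0_sigma * rng.standard_normal())
        out.append(
            TruthRecord(
                variant_id=v.variant_id,
                k_true=k_true,
                m0_true=float(m0),
                effect_components={
                    "baseline": params.baseline,
                    "rpph": rpph_comp,
                    "ssrna": ssrna_comp,
                    "translation": translation_comp,
                    "g4": g4_comp,
                    "imotif": imotif_comp,
                    "noise": k_true - float(np.clip(k_det, params.k_min, params.k_max)),
                },
            )
        )
    return out


# ---------------------------------------------------------------------------
# count simulation
# ---------------------------------------------------------------------------

# Spike mass as a fraction of T0 mRNA mass. Calibrated so that, for the
# default demo library, the spike-in read share at 16 min is ~10x its T0
# share (the regime the assay design targets).
DEFAULT_SPIKE_FRACTION = 0.075


def simulate_counts(
    truth: Sequence[TruthRecord],
    depth: int,
    timepoints: Sequence[float] = DEFAULT_TIMEPOINTS,
    spike_mass: float | None = None,
    seed: int = 0,
    dna_depth: int | None = None,
    dna_sigma: float = 0.2,
    expected: bool = False,
) -> CountTable:
    """Multinomial read sampling over {variants + spike-in} per timepoint.

    The latent abundance of variant v at time t is ``m0 * exp(-k t)``; the
    spike-in contributes a constant absolute mass (default: 7.5% of the
    total T0 mRNA mass), so its read share rises as the pool decays. DNA T0
    counts are multinomial over abundance-independent library frequencies.
    With ``expected=True``, returns noise-free expected counts (floats).
    """
    if depth <= 0 or (spike_mass is not None and spike_mass <= 0):
        raise ConfigurationError("depth and spike_mass must be positive")
    if not timepoints or timepoints[0] != 0:
        raise ConfigurationError("timepoints must start at 0")
    rng = np.random.default_rng(seed)
    ids = [tr.variant_id for tr in truth]
    m0 = np.array([tr.m0_true for tr in truth])
    k = np.array([tr.k_true for tr in truth])
    if spike_mass is None:
        spike_mass = DEFAULT_SPIKE_FRACTION * float(m0.sum())

    data: dict[str, np.ndarray] = {}
    for t in timepoints:
        mass = m0 * np.exp(-k * float(t))
        probs = np.append(mass, spike_mass)
        probs = probs / probs.sum()
        if expected:
            counts = depth * probs
        else:
            counts = rng.multinomial(depth, probs).astype(float)
        data[rna_column(t)] = counts

    lib_freq = np.exp(dna_sigma * rng.standard_normal(len(ids))) if dna_sigma > 0 else np.ones(len(ids))
    lib_freq = np.append(lib_freq, 0.0)
    lib_freq = lib_freq / lib_freq.sum()
    nd = dna_depth if dna_depth is not None else depth
    data["dna_t0"] = nd * lib_freq if expected else rng.multinomial(nd, lib_freq).astype(float)

    df = pd.DataFrame(data, index=ids + [SPIKEIN_ID])
    if not expected:
        df = df.astype(np.int64)
    return CountTable(df, timepoints)


# ---------------------------------------------------------------------------
# read emission
# ---------------------------------------------------------------------------

def emit_reads(
    counts: CountTable,
    barcode_map: Mapping[str, str],
    outdir: str | Path,
    error_rate: float = 0.0,
    seed: int = 0,
    anchor5: str = READ_ANCHOR5,
    anchor3: str = READ_ANCHOR3,
) -> dict[str, Path]:
    """Write one FASTQ per sample; each read is anchor5 + barcode + anchor3.

    ``barcode_map`` maps variant_id -> DNA barcode and must include the
    spike-in row id. Per-base substitution errors are i.i.d. at
    ``error_rate``; read totals match the count table exactly.
    """
    if not 0 <= error_rate < 0.25:
        raise ConfigurationError("error_rate must be in [0, 0.25)")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    lut = np.frombuffer(DNA_ALPHABET.encode(), dtype=np.uint8)
    inv = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(DNA_ALPHABET):
        inv[ord(b)] = i

    paths: dict[str, Path] = {}
    for col in ["dna_t0"] + counts.rna_columns:
        rows = counts.df.index if col != "dna_t0" else counts.variant_ids
        templates, reps = [], []
        for vid in rows:
            n = int(counts.df.loc[vid, col])
            if n <= 0:
                continue
            read = anchor5 + barcode_map[vid] + anchor3
            templates.append(np.frombuffer(read.encode(), dtype=np.uint8))
            reps.append(n)
        path = outdir / f"{col}.fastq"
        with open(path, "w") as fh:
            if templates:
                mat = np.repeat(np.stack(templates), reps, axis=0)
                codes = inv[mat]
                if error_rate > 0:
                    mask = rng.random(codes.shape) < error_rate
                    shift = rng.integers(1, 4, size=codes.shape)
                    codes = np.where(mask, (codes + shift) % 4, codes)
                seqs = lut[codes]
                qual = "I" * seqs.shape[1]
                for i, row in enumerate(seqs):
                    fh.write(f"@{col}_read{i}\n{row.tobytes().decode()}\n+\n{qual}\n")
        paths[col] = path
    return paths


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

LIBRARY_COLUMNS = [
    "variant_id", "design_group", "utr_seq", "barcode", "rbs_variant_index",
    "designed_tir", "ss_len", "ss_comp_factor", "has_g4", "has_imotif",
    "stem_len", "tx_rate",
]


def library_to_frame(library: Sequence[UtrVariant]) -> pd.DataFrame:
    return pd.DataFrame([{c: getattr(v, c) for c in LIBRARY_COLUMNS} for v in library])


def library_from_frame(df: pd.DataFrame) -> list[UtrVariant]:
    out = []
    for row in df.itertuples(index=False):
        out.append(
            UtrVariant(
                variant_id=str(row.variant_id),
                design_group=str(row.design_group),
                utr_seq=str(row.utr_seq),
                barcode=str(row.barcode),
                rbs_variant_index=int(row.rbs_variant_index),
                designed_tir=float(getattr(row, "designed_tir", 1e3)),
                ss_len=int(getattr(row, "ss_len", 0)),
                ss_comp_factor=float(getattr(row, "ss_comp_factor", 1.0)),
                has_g4=bool(getattr(row, "has_g4", False)),
                has_imotif=bool(getattr(row, "has_imotif", False)),
                stem_len=int(getattr(row, "stem_len", 0)),
                tx_rate=float(getattr(row, "tx_rate", 1.0)),
            )
        )
    return out


def truth_to_frame(truth: Sequence[TruthRecord]) -> pd.DataFrame:
    rows = []
    for tr in truth:
        row = {"variant_id": tr.variant_id, "k_true": tr.k_true, "m0_true": tr.m0_true}
        row.update({f"effect_{k}": v for k, v in tr.effect_components.items()})
        rows.append(row)
    return pd.DataFrame(rows)
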