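"""Pluggable transcription, translation, and folding providers.

Providers are deterministic callables addressed by name. The surrogate
transcription and translation providers are documented simplified scoring
models — stand-ins for full thermodynamic calculators — while the
``Designed*`` providers look design-time values up from a synthetic library,
which is the default wiring for simulated runs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Protocol, Sequence

from mrnadecay._errors import ConfigurationError, ValidationError
from mrnadecay.features.folding import NussinovFolder


@dataclass(order=True)
class Isoform:
    sort_key: tuple = field(init=False, repr=False)
    tss_offset: int
    tx_rate: float
    mrna_seq: str
    rank: int = 0

    def __post_init__(self):
        self.sort_key = (-self.tx_rate, self.tss_offset)

    @property
    def rpph_site(self) -> str:
        return self.mrna_seq[:4].replace("T", "U")


class TxProvider(Protocol):
    def __call__(self, construct: str) -> list[tuple[int, float]]: ...


class TirProvider(Protocol):
    def __call__(self, mrna: str, cds_start: int) -> float: ...


def enumerate_isoforms(construct: str, tx_provider: TxProvider, n: int = 5) -> list[Isoform]:
    """Top-n start sites ranked by transcription rate (ties: smaller offset)."""
    sites = tx_provider(construct)
    if not sites:
        raise ValidationError("transcription provider returned no candidate sites")
    isoforms = [
        Isoform(tss_offset=off, tx_rate=rate, mrna_seq=construct[off:].replace("T", "U"))
        for off, rate in sites
        if len(construct) - off >= 4
    ]
    isoforms.sort()
    out = isoforms[:n]
    for r, iso in enumerate(out, start=1):
        iso.rank = r
    return out


def _matches(window: str, consensus: str) -> int:
    return sum(1 for a, b in zip(window, consensus) if a == b)


class SurrogateTxProvider:
    """Hexamer-consensus + initial-transcribed-region scoring.

    score(o) = w10 * match(seq[o-12:o-6], TATAAT)
             + w35 * match(seq[o-36:o-30], TTGACA)
             + w_itr * AT fraction of seq[o:o+20]
             + w_pur * purine fraction of seq[o:o+6]
    rate = exp(score). Sensitive to changes in the first 20 transcribed nt
    through the ITR and purine terms; strictly positive and deterministic.
    """

    def __init__(self, w10: float = 1.2, w35: float = 0.6, w_itr: float = 1.5, w_pur: float = 0.3):
        self.w10, self.w35, self.w_itr, self.w_pur = w10, w35, w_itr, w_pur

    def __call__(self, construct: str) -> list[tuple[int, float]]:
        seq = construct.upper().replace("U", "T")
        pad = "N" * 36
        padded = pad + seq
        out = []
        for off in range(0, len(seq) - 3):
            p = off + 36
            itr = seq[off : off + 20]
            at = (itr.count("A") + itr.count("T")) / max(len(itr), 1)
            first6 = seq[off : off + 6]
            pur = (first6.count("A") + first6.count("G")) / max(len(first6), 1)
            score = (
                self.w10 * _matches(padded[p - 12 : p - 6], "TATAAT")
                + self.w35 * _matches(padded[p - 36 : p - 30], "TTGACA")
                + self.w_itr * at
                + self.w_pur * pur
            )
            out.append((off, math.exp(score)))
        out.sort(key=lambda t: (-t[1], t[0]))
        return out


ANTI_SD = "AGGAGG"  # consensus complement of the 16S anti-SD tail


class SurrogateTirProvider:
    """Shine-Dalgarno complementarity minus structure-occlusion scoring.

    TIR = scale * exp(a * sd_score - b * occlusion), where sd_score is the
    best consensus match over spacings 4..10 nt upstream of the start codon
    (with a penalty away from the optimal 7-nt spacing) and occlusion is the
    paired fraction of the ribosome footprint window [cds_start-12,
    cds_start+3] in the folded leader. Spans roughly 1e0..1e5 au at the
    default scale.
    """

    def __init__(self, scale: float = 1.0, a: float = 1.9, b: float = 5.0,
                 folder: Callable | None = None, optimal_spacing: int = 7,
                 spacing_penalty: float = 0.25):
        self.scale, self.a, self.b = scale, a, b
        self.folder = folder or NussinovFolder()
        self.optimal_spacing = optimal_spacing
        self.spacing_penalty = spacing_penalty

    def __call__(self, mrna: str, cds_start: int) -> float:
        seq = mrna.upper().replace("T", "U")
        if not 0 <= cds_start <= len(seq):
            raise ValidationError("cds_start outside sequence")
        sd_best = 0.0
        for spacing in range(4, 11):
            end = cds_start - spacing
            start = end - len(ANTI_SD)
            if start < 0:
                continue
            m = _matches(seq[start:end], ANTI_SD.replace("T", "U"))
            sd_best = max(sd_best, m - self.spacing_penalty * abs(spacing - self.optimal_spacing))
        window_start = max(0, cds_start - 25)
        window = seq[window_start : cds_start + 14]
        pair_table = self.folder(window)
        foot_lo = max(0, cds_start - 12 - window_start)
        foot_hi = min(len(window), cds_start + 3 - window_start)
        footprint = range(foot_lo, foot_hi)
        occl = (
            sum(1 for i in footprint if pair_table[i] >= 0) / len(footprint)
            if len(footprint) else 0.0
        )
        return max(self.scale * math.exp(self.a * sd_best - self.b * occl), 1e-6)


class DesignedTxProvider:
    """Looks up the designed transcription start and rate for each construct.

    Default provider for synthetic libraries: one dominant start site at the
    promoter/UTR junction with the design-time transcription rate.
    """

    def __init__(self, promoter_len: int, tx_rates: Mapping[str, float] | None = None,
                 construct_to_id: Mapping[str, str] | None = None):
        self.promoter_len = promoter_len
        self.tx_rates = tx_rates or {}
        self.construct_to_id = construct_to_id or {}

    def __call__(self, construct: str) -> list[tuple[int, float]]:
        vid = self.construct_to_id.get(construct)
        rate = self.tx_rates.get(vid, 1.0)
        return [(self.promoter_len, rate)]


class DesignedTirProvider:
    """Looks up the design-time translation initiation rate by mRNA sequence."""

    def __init__(self, tir_by_mrna: Mapping[str, float], default: float = 1e3):
        self.tir_by_mrna = dict(tir_by_mrna)
        self.default = default

    def __call__(self, mrna: str, cds_start: int) -> float:
        return self.tir_by_mrna.get(mrna.upper().replace("T", "U"), self.default)


@dataclass
class ProviderSet:
    tx_provider: TxProvider
    tir_provider: TirProvider
    fold_provider: Callable

    @classmethod
    def surrogate(cls) -> "ProviderSet":
        return cls(SurrogateTxProvider(), SurrogateTirProvider(), NussinovFolder())


def providers_for_library(library) -> ProviderSet:
    """Designed-value providers wired to a synthetic library (plus DP folder)."""
    from mrnadecay import synthetic_data as sd

    tx_rates = {v.variant_id: v.tx_rate for v in library}
    construct_to_id = {v.construct(): v.variant_id for v in library}
    tir_by_mrna = {
        (v.utr_seq + sd.CDS_WINDOW).replace("T", "U"): v.designed_tir for v in library
    }
    return ProviderSet(
        DesignedTxProvider(len(sd.PROMOTER), tx_rates, construct_to_id),
        DesignedTirProvider(tir_by_mrna),
        NussinovFolder(),
    )
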