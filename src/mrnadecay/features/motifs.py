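"""Sequence motif scanning: IUPAC motifs and quadruplex-type patterns."""

from __future__ import annotations

import re
from typing import Mapping

from mrnadecay._errors import ConfigurationError

IUPAC_RNA: Mapping[str, str] = {
    "A": "A", "C": "C", "G": "G", "U": "U", "T": "U",
    "R": "AG", "Y": "CU", "S": "CG", "W": "AU", "K": "GU", "M": "AC",
    "B": "CGU", "D": "AGU", "H": "ACU", "V": "ACG", "N": "ACGU",
}


def iupac_to_regex(motif: str) -> str:
    parts = []
    for ch in motif.upper():
        try:
            bases = IUPAC_RNA[ch]
        except KeyError:
            raise ConfigurationError(f"invalid IUPAC character {ch!r} in motif {motif!r}") from None
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def count_motifs(seq: str, motif_set: Mapping[str, str]) -> dict[str, int]:
    """Overlapping occurrence counts per IUPAC motif."""
    seq = seq.upper().replace("T", "U")
    out = {}
    for name, motif in motif_set.items():
        pat = re.compile(f"(?=({iupac_to_regex(motif)}))")
        out[name] = sum(1 for _ in pat.finditer(seq))
    return out


def detect_quadruplex(
    seq: str,
    runs: int = 4,
    run_len: int = 3,
    loop_min: int = 6,
    loop_max: int = 6,
    base: str = "G",
) -> list[tuple[int, int]]:
    """Leftmost non-overlapping [(3G-6N)_4]-style spans as (start, end) pairs.

    Four runs of ``base`` of length ``run_len`` separated by loops of
    ``loop_min``..``loop_max`` arbitrary nt. ``base='C'`` detects i-motifs.
    """
    if runs < 2 or run_len < 1 or loop_min < 0 or loop_max < loop_min:
        raise ConfigurationError("invalid quadruplex pattern parameters")
    seq = seq.upper().replace("T", "U")
    unit = f"{base}{{{run_len}}}[ACGU]{{{loop_min},{loop_max}}}"
    pat = re.compile(f"(?:{unit}){{{runs - 1}}}{base}{{{run_len}}}")
    return [(m.start(), m.end()) for m in pat.finditer(seq)]
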