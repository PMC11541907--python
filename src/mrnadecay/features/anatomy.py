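"""Structure anatomy: ssRNA segments, helices, loops, bulges, tertiary spans.

Anatomy is computed over a region of interest (the 5' UTR). Tertiary spans
(G-quadruplex / i-motif matches) are handled in two modes: ``g4_aware``
blocks their positions from pairing and excludes them from the ssRNA tally;
``secondary_only`` ignores them entirely, as if only secondary structure
could form.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from mrnadecay._errors import ConfigurationError, ValidationError
from mrnadecay.features import motifs
from mrnadecay.features.folding import validate_pair_table

TERTIARY_MODES = ("g4_aware", "secondary_only")


@dataclass
class StructureAnatomy:
    length: int
    ssrna_total_nt: int
    ssrna_segment_lengths: list[int]
    ssrna_composition: dict[str, float]  # fraction A/C/G/U of unpaired nt
    paired_nt: int
    tertiary_nt: int
    hairpin_count: int
    duplex_lengths: list[int]
    loop_lengths: list[int]
    bulge_count: int
    internal_loop_count: int
    g4_present: bool
    g4_spans: list[tuple[int, int]]
    imotif_present: bool
    imotif_spans: list[tuple[int, int]]


def _helices(pairs: dict[int, int]) -> list[int]:
    """Lengths of maximal stacks of consecutive pairs."""
    lengths = []
    seen: set[int] = set()
    for i in sorted(pairs):
        j = pairs[i]
        if j < i or i in seen:
            continue
        length = 0
        a, b = i, j
        while a in pairs and pairs[a] == b and b > a:
            seen.add(a)
            length += 1
            a, b = a + 1, b - 1
        lengths.append(length)
    return lengths


def _loop_stats(pair_table: Sequence[int]) -> tuple[int, list[int], int, int]:
    """(hairpin_count, hairpin_loop_lengths, bulge_count, internal_loop_count).

    Walks every pair's enclosed region: a pair with no enclosed pairs closes
    a hairpin loop; a pair enclosing exactly one directly-nested pair closes
    a stack (0/0), bulge (one side 0) or internal loop (both sides > 0).
    """
    n = len(pair_table)
    hairpins = 0
    loop_lengths: list[int] = []
    bulges = 0
    internals = 0
    for i, j in enumerate(pair_table):
        if j <= i:
            continue
        # direct children: maximal pairs immediately inside (i, j)
        children = []
        k = i + 1
        while k < j:
            if pair_table[k] > k:
                children.append((k, pair_table[k]))
                k = pair_table[k] + 1
            else:
                k += 1
        if not children:
            hairpins += 1
            loop_lengths.append(j - i - 1)
        elif len(children) == 1:
            (a, b) = children[0]
            left, right = a - i - 1, j - b - 1
            if left == 0 and right == 0:
                pass  # stacked pair, same helix
            elif left == 0 or right == 0:
                bulges += 1
            else:
                internals += 1
        # multiloops are tallied implicitly via their children
    return hairpins, loop_lengths, bulges, internals


def annotate(
    seq: str,
    pair_table: Sequence[int],
    tertiary_spans: Sequence[tuple[int, int]] = (),
) -> StructureAnatomy:
    """Derive anatomy from a sequence and its (region-local) pair table."""
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if len(pair_table) != n:
        raise ValidationError("pair table length does not match sequence")
    validate_pair_table(pair_table)

    tertiary = set()
    for a, b in tertiary_spans:
        tertiary.update(range(a, b))
    paired = {i for i, j in enumerate(pair_table) if j >= 0}
    # paired positions win over tertiary membership so the partition is exact
    tertiary -= paired

    segments: list[int] = []
    run = 0
    unpaired_nt: list[str] = []
    for i in range(n):
        if i not in paired and i not in tertiary:
            run += 1
            unpaired_nt.append(seq[i])
        else:
            if run:
                segments.append(run)
            run = 0
    if run:
        segments.append(run)

    total_ss = sum(segments)
    comp = {b: (unpaired_nt.count(b) / total_ss if total_ss else 0.0) for b in "ACGU"}
    pairs = {i: j for i, j in enumerate(pair_table) if j >= 0}
    hairpins, loop_lengths, bulges, internals = _loop_stats(pair_table)

    g4 = motifs.detect_quadruplex(seq, base="G")
    im = motifs.detect_quadruplex(seq, base="C")
    assert total_ss + len(paired) + len(tertiary) == n
    return StructureAnatomy(
        length=n,
        ssrna_total_nt=total_ss,
        ssrna_segment_lengths=segments,
        ssrna_composition=comp,
        paired_nt=len(paired),
        tertiary_nt=len(tertiary),
        hairpin_count=hairpins,
        duplex_lengths=_helices(pairs),
        loop_lengths=loop_lengths,
        bulge_count=bulges,
        internal_loop_count=internals,
        g4_present=bool(g4),
        g4_spans=g4,
        imotif_present=bool(im),
        imotif_spans=im,
    )


def fold_and_annotate(
    seq: str,
    fold_provider,
    tertiary_mode: str = "g4_aware",
    quadruplex_kwargs: dict | None = None,
) -> StructureAnatomy:
    """Fold a region and annotate it, with configurable tertiary handling."""
    if not seq:
        raise ConfigurationError("cannot annotate an empty sequence")
    if tertiary_mode not in TERTIARY_MODES:
        raise ConfigurationError(f"tertiary_mode must be one of {TERTIARY_MODES}")
    kwargs = quadruplex_kwargs or {}
    seq = seq.upper().replace("T", "U")
    g4 = motifs.detect_quadruplex(seq, base="G", **kwargs)
    im = motifs.detect_quadruplex(seq, base="C", **kwargs)
    if tertiary_mode == "g4_aware":
        blocked = [p for a, b in g4 + im for p in range(a, b)]
        spans = g4 + im
    else:
        blocked, spans = [], []
    pair_table = fold_provider(seq, blocked=blocked)
    return annotate(seq, pair_table, spans)
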