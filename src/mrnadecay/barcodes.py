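"""Hash-based barcode mapping with single-mismatch tolerance.

An index maps every designed barcode plus all of its Hamming-distance-1
mutants to a variant id. When input barcodes have pairwise distance >= 3 the
single-substitution balls are disjoint and mapping is unambiguous; mutants
shared between closer barcodes are logged as collisions and never mapped.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from mrnadecay._errors import ParseError, ValidationError

DNA_ALPHABET = "ACGT"


@dataclass
class BarcodeIndex:
    exact_map: dict[str, str]
    neighbor_map: dict[str, str]  # Hamming-1 mutants -> variant_id (collisions excluded)
    collision_log: list[str]
    length: int

    def lookup(self, candidate: str) -> str | None:
        hit = self.exact_map.get(candidate)
        if hit is not None:
            return hit
        return self.neighbor_map.get(candidate)

    def __len__(self) -> int:
        return len(self.exact_map) + len(self.neighbor_map)


def _mutants(barcode: str) -> Iterator[str]:
    for pos, base in enumerate(barcode):
        for alt in DNA_ALPHABET:
            if alt != base:
                yield barcode[:pos] + alt + barcode[pos + 1 :]


def build_index(barcodes: Mapping[str, str] | Sequence[str]) -> BarcodeIndex:
    """Build exact + Hamming-1 lookup maps.

    ``barcodes`` is either a mapping variant_id -> barcode or a plain
    sequence (ids become bc0, bc1, ...). Duplicate barcodes raise
    :class:`ValidationError`; ambiguous mutants (possible when inputs are at
    distance 2) are recorded in ``collision_log`` and excluded.
    """
    if not isinstance(barcodes, Mapping):
        barcodes = {f"bc{i}": b for i, b in enumerate(barcodes)}
    lengths = {len(b) for b in barcodes.values()}
    if len(lengths) != 1:
        raise ValidationError(f"barcodes must share one length, got {sorted(lengths)}")
    (length,) = lengths
    bad = [b for b in barcodes.values() if any(ch not in DNA_ALPHABET for ch in b)]
    if bad:
        raise ValidationError(f"non-DNA barcode(s): {bad[:3]}")

    exact: dict[str, str] = {}
    for vid, bc in barcodes.items():
        if bc in exact:
            raise ValidationError(f"duplicate barcode {bc!r}")
        exact[bc] = vid

    neighbor: dict[str, str] = {}
    collisions: set[str] = set()
    for bc, vid in exact.items():
        for mut in _mutants(bc):
            if mut in exact:
                # the mutant IS another designed barcode (distance-1 inputs);
                # exact lookup takes precedence, log the ambiguity
                collisions.add(mut)
                continue
            prev = neighbor.get(mut)
            if prev is None:
                neighbor[mut] = vid
            elif prev != vid:
                collisions.add(mut)
    for mut in collisions:
        neighbor.pop(mut, None)
    return BarcodeIndex(exact, neighbor, sorted(collisions), length)


@dataclass
class BarcodeLocator:
    """Locates the barcode substring in a read.

    Uses two flanking anchors when given (the 3' anchor, if set, must follow
    immediately after the barcode), falling back to a fixed offset.
    """

    length: int
    anchor5: str | None = None
    anchor3: str | None = None
    offset: int | None = None

    def locate(self, read: str) -> str | None:
        if self.anchor5 is not None:
            start = read.find(self.anchor5)
            if start < 0:
                return None
            start += len(self.anchor5)
            end = start + self.length
            if end > len(read):
                return None
            if self.anchor3 is not None and not read[end:].startswith(self.anchor3):
                return None
            return read[start:end]
        if self.offset is not None:
            sub = read[self.offset : self.offset + self.length]
            return sub if len(sub) == self.length else None
        raise ValidationError("locator needs an anchor or a fixed offset")


def _open_maybe_gzip(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def iter_fastq(source: str | Path | IO[str]) -> Iterator[str]:
    """Yield read sequences from a FASTQ file, reporting malformed records."""
    fh = _open_maybe_gzip(source) if isinstance(source, (str, Path)) else source
    n = 0
    try:
        for record in SeqIO.parse(fh, "fastq"):
            n += 1
            yield str(record.seq)
    except ValueError as exc:
        raise ParseError(f"malformed FASTQ record {n + 1}: {exc}", record_number=n + 1) from exc
    finally:
        if isinstance(source, (str, Path)):
            fh.close()


@dataclass
class CountResult:
    counts: dict[str, int]
    unmapped: int
    total: int
    dropped_n: int = 0

    def report(self) -> dict:
        return {
            "total_reads": self.total,
            "mapped_reads": self.total - self.unmapped - self.dropped_n,
            "unmapped_reads": self.unmapped,
            "dropped_n_reads": self.dropped_n,
            "n_variants_observed": sum(1 for c in self.counts.values() if c > 0),
        }


def count_reads(
    reads: str | Path | Iterable[str],
    index: BarcodeIndex,
    locator: BarcodeLocator,
    drop_n: bool = False,
) -> CountResult:
    """Count reads per variant with at-most-one-mismatch barcode mapping.

    ``reads`` is a FASTQ path (gzip allowed) or an iterable of sequences.
    Reads whose located barcode is unmatched, ambiguous, or unlocatable are
    tallied as unmapped; mapped + unmapped + dropped == total.
    """
    if isinstance(reads, (str, Path)):
        reads = iter_fastq(reads)
    counts: dict[str, int] = {vid: 0 for vid in index.exact_map.values()}
    unmapped = 0
    dropped = 0
    total = 0
    for seq in reads:
        total += 1
        if drop_n and "N" in seq:
            dropped += 1
            continue
        candidate = locator.locate(seq.upper())
        vid = index.lookup(candidate) if candidate is not None else None
        if vid is None:
            unmapped += 1
        else:
            counts[vid] += 1
    return CountResult(counts, unmapped, total, dropped)


def count_samples(
    sample_paths: Mapping[str, str | Path],
    index: BarcodeIndex,
    locator: BarcodeLocator,
    drop_n: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Count several FASTQ samples into a counts frame + mapping report."""
    columns = {}
    report = {}
    for sample, path in sample_paths.items():
        res = count_reads(path, index, locator, drop_n=drop_n)
        columns[sample] = pd.Series(res.counts)
        report[sample] = res.report()
    return pd.DataFrame(columns).fillna(0).astype(int), report


def write_report(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True))
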