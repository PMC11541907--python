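"""Versioned feature schema: fixed name ordering, padding, and hashing.

The default schema has 64 named features per isoform block (ranks 1..5)
plus 3 global features, padded with constant zero columns to a total
dimension of 496. Excluding feature families yields a smaller, unpadded
schema; absent isoform blocks are filled with a sentinel value.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from mrnadecay._errors import SchemaError

DEFAULT_DIMENSION = 496
SENTINEL = -1.0

RNA = "ACGU"

PER_ISOFORM_FEATURES: tuple[str, ...] = tuple(
    [f"rpph_p{p}_{b}" for p in range(4) for b in RNA]
    + ["rpph_skew"]  # max single-nt count of the first 4 transcribed nt, /4
    + ["log_tx_rate", "log_tir", "utr_len", "gc_frac"]
    + [f"itr_frac_{b}" for b in RNA]
    + [f"dinuc_{a}{b}" for a in RNA for b in RNA]
    + ["ssrna_total_nt", "ssrna_n_segments", "ssrna_max_segment", "ssrna_mean_segment"]
    + [f"ssrna_frac_{b}" for b in RNA]
    + [
        "hairpin_count", "duplex_total_bp", "duplex_max_len", "duplex_mean_len",
        "loop_total_nt", "loop_max_len", "loop_mean_len",
        "bulge_count", "internal_loop_count", "paired_frac",
    ]
    + ["g4_present", "g4_span_nt", "imotif_present", "imotif_span_nt"]
    + ["rnase_e_motif_count", "csra_motif_count"]
)

GLOBAL_FEATURES: tuple[str, ...] = ("construct_len", "construct_gc", "n_isoforms")


@dataclass(frozen=True)
class FeatureSchema:
    names: tuple[str, ...]
    n_isoforms: int

    @property
    def dimension(self) -> int:
        return len(self.names)

    @property
    def version_hash(self) -> str:
        return hashlib.sha256("\n".join(self.names).encode()).hexdigest()[:16]

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise SchemaError(f"unknown feature {name!r}") from None

    def isoform_feature(self, rank: int, name: str) -> str:
        return f"iso{rank}_{name}"

    def to_json_dict(self) -> dict:
        return {
            "names": list(self.names),
            "n_isoforms": self.n_isoforms,
            "version_hash": self.version_hash,
        }


def build_schema(
    n_isoforms: int = 5,
    exclude: Sequence[str] = (),
    pad_to: int | None = None,
) -> FeatureSchema:
    """Construct a schema; pads the default (no exclusions) schema to 496.

    ``exclude`` names per-isoform features to drop (e.g. low-importance
    structure counters); an excluded-feature schema is not padded unless
    ``pad_to`` is given explicitly.
    """
    unknown = [e for e in exclude if e not in PER_ISOFORM_FEATURES]
    if unknown:
        raise SchemaError(f"cannot exclude unknown feature(s): {unknown}")
    per_iso = [f for f in PER_ISOFORM_FEATURES if f not in set(exclude)]
    names = [f"iso{r}_{f}" for r in range(1, n_isoforms + 1) for f in per_iso]
    names += list(GLOBAL_FEATURES)
    if pad_to is None and not exclude and n_isoforms == 5:
        pad_to = DEFAULT_DIMENSION
    if pad_to is not None:
        if pad_to < len(names):
            raise SchemaError(f"pad_to={pad_to} smaller than named dimension {len(names)}")
        names += [f"pad_{i:03d}" for i in range(pad_to - len(names))]
    return FeatureSchema(tuple(names), n_isoforms)


def assemble_features(
    schema: FeatureSchema,
    isoform_blocks: Sequence[Mapping[str, float]],
    global_features: Mapping[str, float],
) -> np.ndarray:
    """Deterministic vector assembly; missing isoform blocks get sentinels."""
    if len(isoform_blocks) > schema.n_isoforms:
        raise SchemaError(
            f"{len(isoform_blocks)} isoform blocks exceed schema capacity {schema.n_isoforms}"
        )
    values = {}
    for rank, block in enumerate(isoform_blocks, start=1):
        for key, val in block.items():
            values[f"iso{rank}_{key}"] = float(val)
    for key, val in global_features.items():
        values[key] = float(val)

    out = np.zeros(schema.dimension)
    absent = {
        f"iso{r}_" for r in range(len(isoform_blocks) + 1, schema.n_isoforms + 1)
    }
    for i, name in enumerate(schema.names):
        if name.startswith("pad_"):
            out[i] = 0.0
        elif any(name.startswith(p) for p in absent):
            out[i] = SENTINEL
        else:
            if name in values:
                out[i] = values[name]
            elif name in GLOBAL_FEATURES or any(
                name.startswith(f"iso{r}_") for r in range(1, len(isoform_blocks) + 1)
            ):
                raise SchemaError(f"missing value for schema feature {name!r}")
    return out
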