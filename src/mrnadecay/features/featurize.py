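"""High-level featurization: construct -> isoforms -> per-isoform features."""

from __future__ import annotations

import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from mrnadecay._errors import ValidationError
from mrnadecay.features import motifs
from mrnadecay.features.anatomy import StructureAnatomy, fold_and_annotate
from mrnadecay.features.providers import Isoform, ProviderSet, enumerate_isoforms
from mrnadecay.features.schema import FeatureSchema, assemble_features, build_schema

RNA = "ACGU"

DEFAULT_MOTIF_SETS = {
    "rnase_e_motif_count": {"rnase_e_au": "AUUUU"},
    "csra_motif_count": {"csra_gga": "AGGA"},
}


def _composition(seq: str) -> dict[str, float]:
    n = max(len(seq), 1)
    return {b: seq.count(b) / n for b in RNA}


def _dinuc_freqs(seq: str) -> dict[str, float]:
    n = max(len(seq) - 1, 1)
    out = {f"{a}{b}": 0.0 for a in RNA for b in RNA}
    for i in range(len(seq) - 1):
        key = seq[i : i + 2]
        if key in out:
            out[key] += 1.0 / n
    return out


def isoform_block(
    iso: Isoform,
    utr_region: str,
    anatomy: StructureAnatomy,
    tir: float,
    motif_sets: Mapping[str, Mapping[str, str]] = DEFAULT_MOTIF_SETS,
) -> dict[str, float]:
    """Named features for one isoform (see schema.PER_ISOFORM_FEATURES)."""
    block: dict[str, float] = {}
    site = iso.rpph_site.ljust(4, "A")
    for p in range(4):
        for b in RNA:
            block[f"rpph_p{p}_{b}"] = 1.0 if site[p] == b else 0.0
    block["rpph_skew"] = max(site.count(b) for b in RNA) / 4.0
    block["log_tx_rate"] = math.log(max(iso.tx_rate, 1e-12))
    block["log_tir"] = math.log(max(tir, 1e-12))
    block["utr_len"] = float(len(utr_region))
    gc = (utr_region.count("G") + utr_region.count("C")) / max(len(utr_region), 1)
    block["gc_frac"] = gc
    itr = iso.mrna_seq[:20]
    for b, frac in _composition(itr).items():
        block[f"itr_frac_{b}"] = frac
    for key, freq in _dinuc_freqs(utr_region).items():
        block[f"dinuc_{key}"] = freq

    segs = anatomy.ssrna_segment_lengths
    block["ssrna_total_nt"] = float(anatomy.ssrna_total_nt)
    block["ssrna_n_segments"] = float(len(segs))
    block["ssrna_max_segment"] = float(max(segs)) if segs else 0.0
    block["ssrna_mean_segment"] = float(np.mean(segs)) if segs else 0.0
    for b in RNA:
        block[f"ssrna_frac_{b}"] = anatomy.ssrna_composition[b]

    dup = anatomy.duplex_lengths
    loops = anatomy.loop_lengths
    block["hairpin_count"] = float(anatomy.hairpin_count)
    block["duplex_total_bp"] = float(sum(dup))
    block["duplex_max_len"] = float(max(dup)) if dup else 0.0
    block["duplex_mean_len"] = float(np.mean(dup)) if dup else 0.0
    block["loop_total_nt"] = float(sum(loops))
    block["loop_max_len"] = float(max(loops)) if loops else 0.0
    block["loop_mean_len"] = float(np.mean(loops)) if loops else 0.0
    block["bulge_count"] = float(anatomy.bulge_count)
    block["internal_loop_count"] = float(anatomy.internal_loop_count)
    block["paired_frac"] = anatomy.paired_nt / max(anatomy.length, 1)

    block["g4_present"] = 1.0 if anatomy.g4_present else 0.0
    block["g4_span_nt"] = float(sum(b - a for a, b in anatomy.g4_spans))
    block["imotif_present"] = 1.0 if anatomy.imotif_present else 0.0
    block["imotif_span_nt"] = float(sum(b - a for a, b in anatomy.imotif_spans))

    for feat_name, motif_set in motif_sets.items():
        block[feat_name] = float(sum(motifs.count_motifs(utr_region, motif_set).values()))
    return block


def featurize_construct(
    construct: str,
    cds_start: int,
    providers: ProviderSet,
    schema: FeatureSchema | None = None,
    tertiary_mode: str = "g4_aware",
    motif_sets: Mapping[str, Mapping[str, str]] = DEFAULT_MOTIF_SETS,
) -> np.ndarray:
    """Feature vector for one construct (DNA or RNA; cds_start is 0-based)."""
    schema = schema or build_schema()
    rna = construct.upper().replace("T", "U")
    isoforms = [
        iso for iso in enumerate_isoforms(rna, providers.tx_provider, n=schema.n_isoforms)
        if iso.tss_offset < cds_start
    ]
    if not isoforms:
        raise ValidationError("no isoform starts upstream of the CDS")
    blocks = []
    for iso in isoforms:
        utr_region = rna[iso.tss_offset : cds_start]
        anatomy = fold_and_annotate(utr_region, providers.fold_provider, tertiary_mode)
        tir = providers.tir_provider(iso.mrna_seq, cds_start - iso.tss_offset)
        blocks.append(isoform_block(iso, utr_region, anatomy, tir, motif_sets))
    global_features = {
        "construct_len": float(len(rna)),
        "construct_gc": (rna.count("G") + rna.count("C")) / max(len(rna), 1),
        "n_isoforms": float(len(blocks)),
    }
    return assemble_features(schema, blocks, global_features)


def featurize_library(
    library: Sequence,
    providers: ProviderSet,
    schema: FeatureSchema | None = None,
    tertiary_mode: str = "g4_aware",
) -> pd.DataFrame:
    """Feature matrix for a synthetic library (variants x schema columns)."""
    from mrnadecay import synthetic_data as sd

    schema = schema or build_schema()
    rows = {}
    for v in library:
        construct = v.construct()
        cds_start = len(sd.PROMOTER) + len(v.utr_seq)
        rows[v.variant_id] = featurize_construct(
            construct, cds_start, providers, schema, tertiary_mode
        )
    return pd.DataFrame.from_dict(rows, orient="index", columns=schema.names)
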