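"""Tabular I/O: count tables, sample metadata, responses, taxonomy, config.

All tables are tab-separated UTF-8 with a mandatory header row; counts must
be explicit non-negative integers (no missing-value placeholder).
"""
from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from .datatypes import RANKS, CountTable, ResponseSet, TaxonomyTable, ValidationError

log = logging.getLogger("phyloresponse")


def read_count_table(counts_path, meta_path) -> CountTable:
    """Read an OTU x sample TSV plus a sample/location/arm metadata TSV.

    Errors name the offending cell (non-integer or negative counts) or the
    sample missing from the metadata.
    """
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    counts.index = counts.index.astype(str)
    counts.columns = counts.columns.astype(str)
    for col in counts.columns:
        coerced = pd.to_numeric(counts[col], errors="coerce")
        if coerced.isna().any():
            otu = counts.index[coerced.isna()][0]
            raise ValidationError(
                f"non-integer cell {counts.at[otu, col]!r} at OTU {otu!r}, "
                f"sample {col!r} in {counts_path}"
            )
        counts[col] = coerced
    meta = pd.read_csv(meta_path, sep="\t")
    required = {"sample", "location", "arm"}
    if not required.issubset(meta.columns):
        raise ValidationError(
            f"metadata {meta_path} must have columns {sorted(required)}"
        )
    meta = meta.set_index("sample")
    meta.index = meta.index.astype(str)
    missing = [s for s in counts.columns if s not in meta.index]
    if missing:
        raise ValidationError(
            f"samples present in counts but absent from metadata: {missing}"
        )
    return CountTable(counts, meta)


def write_count_table(table: CountTable, counts_path, meta_path) -> None:
    table.counts.rename_axis("otu_id").to_csv(counts_path, sep="\t")
    table.sample_meta.rename_axis("sample").to_csv(meta_path, sep="\t")


def read_response(path, location: str | None = None) -> ResponseSet:
    df = pd.read_csv(path, sep="\t")
    if not {"otu_id", "log2fc"}.issubset(df.columns):
        raise ValidationError(f"response table {path} needs otu_id and log2fc")
    series = df.set_index("otu_id")["log2fc"]
    series.index = series.index.astype(str)
    return ResponseSet(series, location or str(path))


def write_response(response: ResponseSet, path) -> None:
    df = pd.DataFrame(
        {
            "otu_id": response.otu_ids,
            "log2fc": response.log2fc.to_numpy(),
            "direction": response.direction.to_numpy(),
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyTable:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index = df.index.astype(str)
    df.index.name = None
    missing = [r for r in RANKS if r not in df.columns]
    if missing:
        raise ValidationError(f"taxonomy table {path} lacks ranks {missing}")
    return TaxonomyTable(df)


def write_taxonomy(taxonomy: TaxonomyTable, path) -> None:
    taxonomy.assignments.rename_axis("otu_id").to_csv(path, sep="\t")


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


DEFAULT_CONFIG = {
    "consensus_threshold": 0.90,
    "n_randomizations": 1000,
    "n_permutations": 999,
    "min_occupancy_fraction": 0.5,
    "relaxed_min_plots": 2,
    "min_otus_for_primary_rule": 900,
    "pseudocount": 0.5,
    "min_locations": 3,
    "alpha": 0.05,
    "min_group_size": 5,
    "singleton_rule": "patristic",  # or "pendant"
    "merged_tree": "prune",  # or "rebuild"
    "seed": 0,
}


def load_config(path=None) -> dict:
    """Run configuration: YAML overrides layered on the documented defaults."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(cfg)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def log_stage(stage: str, **params) -> None:
    """Structured one-line log of a stage's parameters."""
    kv = " ".join(f"{k}={v}" for k, v in sorted(params.items()))
    log.info("stage=%s %s", stage, kv)
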