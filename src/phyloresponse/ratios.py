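"""Per-location OTU filtering, normalization, and log2 response ratios.

Rare OTUs are removed before ratio estimation because low-occupancy taxa
give very noisy ratios: the primary rule keeps OTUs present in at least
half of the plots at a location; when that leaves fewer than 900 OTUs the
rule is relaxed to presence in two or more plots. Counts are normalized
with median-of-ratios size factors (geometric-mean reference over positive
counts only, so sparse tables are handled), and the per-OTU response is
log2 of the mean normalized abundance in treatment plots over control
plots, with a symmetric pseudocount keeping ratios finite for OTUs absent
from one arm.
"""
from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .datatypes import (
    CONTROL,
    TREATMENT,
    CountTable,
    FilterReport,
    ResponseSet,
    ValidationError,
)


def filter_low_occupancy(
    table: CountTable,
    min_fraction: float = 0.5,
    relaxed_min_plots: int = 2,
    min_otus: int = 900,
) -> tuple[CountTable, FilterReport]:
    """Occupancy filter with the documented fallback.

    Primary rule: keep OTUs with nonzero counts in >= ceil(min_fraction *
    n_plots) plots. If fewer than ``min_otus`` OTUs survive, relax to
    presence in >= ``relaxed_min_plots`` plots instead. The report records
    which rule fired.
    """
    if len(table.otu_ids) == 0:
        raise ValidationError("empty count table")
    n_plots = len(table.sample_ids)
    occupancy = (table.counts > 0).sum(axis=1)
    primary_cut = math.ceil(min_fraction * n_plots)
    primary_keep = occupancy[occupancy >= primary_cut].index
    if len(primary_keep) >= min_otus:
        kept, rule = primary_keep, "primary"
        threshold = f"present in >= {primary_cut} of {n_plots} plots"
    else:
        kept = occupancy[occupancy >= relaxed_min_plots].index
        rule = "relaxed"
        threshold = f"present in >= {relaxed_min_plots} plots (primary left " \
                    f"{len(primary_keep)} < {min_otus} OTUs)"
    report = FilterReport(
        n_input_otus=len(table.otu_ids),
        n_after_primary=len(kept),
        rule_applied=rule,
        threshold_used=threshold,
    )
    filtered = CountTable(table.counts.loc[kept], table.sample_meta)
    return filtered, report


def size_factors(table: CountTable) -> pd.Series:
    """Median-of-ratios size factors, positive-count reference, geomean 1.

    Reference per OTU: geometric mean of its counts over the samples where
    the count is positive. Factor per sample: median, over the OTUs with a
    positive count in that sample, of count/reference; factors are then
    rescaled to geometric mean 1.
    """
    if len(table.sample_ids) < 2:
        raise ValidationError("size factors need >= 2 samples")
    counts = table.counts.to_numpy().astype(float)
    pos = counts > 0
    nz_sets = [set(np.where(pos[:, j])[0]) for j in range(counts.shape[1])]
    for j, s in enumerate(nz_sets):
        others = set().union(*(nz_sets[:j] + nz_sets[j + 1:]))
        if not (s & others):
            raise ValidationError(
                f"sample {table.sample_ids[j]!r} shares no nonzero OTU "
                "with any other sample"
            )
    logc = np.zeros_like(counts)
    np.log(counts, out=logc, where=pos)
    n_pos = pos.sum(axis=1)
    mean_log = np.zeros(counts.shape[0])
    np.divide(logc.sum(axis=1), n_pos, out=mean_log, where=n_pos > 0)
    ref = np.exp(mean_log)
    factors = np.empty(counts.shape[1])
    for j in range(counts.shape[1]):
        mask = pos[:, j] & (n_pos > 0)
        if not mask.any():
            raise ValidationError(
                f"sample {table.sample_ids[j]!r} has no positive counts"
            )
        factors[j] = np.median(counts[mask, j] / ref[mask])
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=table.sample_ids, name="size_factor")


def log2_response_ratios(
    table: CountTable,
    factors: pd.Series | None = None,
    pseudocount: float = 0.5,
) -> ResponseSet:
    """log2 of mean normalized treatment abundance over control abundance.

    The pseudocount is applied symmetrically to both arm means on the
    normalized-count scale, multiplied by the mean per-sample scaling
    (mean of 1/factor), so ratios stay finite when an OTU is absent from
    one arm while the offset is identical for both arms (which makes the
    estimator exactly antisymmetric under swapping the arm labels).
    """
    if factors is None:
        factors = size_factors(table)
    factors = factors.loc[table.sample_ids]
    if (factors <= 0).any():
        raise ValidationError("size factors must be positive")
    ctrl = table.samples_in_arm(CONTROL)
    trt = table.samples_in_arm(TREATMENT)
    if not ctrl or not trt:
        raise ValidationError(
            f"need both arms; got {len(ctrl)} control / {len(trt)} treatment"
        )
    norm = table.counts / factors
    offset = pseudocount * float((1.0 / factors).mean())
    mean_t = norm[trt].mean(axis=1)
    mean_c = norm[ctrl].mean(axis=1)
    # difference of logs (not log of ratio): exactly antisymmetric in the arms
    log2fc = np.log2(mean_t + offset) - np.log2(mean_c + offset)
    return ResponseSet(pd.Series(log2fc, index=table.counts.index),
                       location=table.location)
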