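"""Within-sample and spike-in normalizations.

Provides DESeq2-style median-of-ratios size factors, TPM, and spike-in
scaling (ERCC for RNA assays, heterologous-genome features for ChIP).
Spike-in scaling puts samples on a common absolute per-cell scale, so
fold changes computed downstream reflect per-total-RNA changes rather
than compositional ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic_data import AssayCounts

PSEUDOCOUNT = 0.5


@dataclass
class SizeFactors:
    factors: pd.Series  # sample -> positive scale factor
    method: str

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("size factors must be strictly positive")


@dataclass
class NormalizedMatrix:
    values: pd.DataFrame
    scale: str  # relative | tpm | absolute_spikein
    spike_scale: pd.Series | None = None


def _as_frame(counts: AssayCounts | pd.DataFrame) -> pd.DataFrame:
    if isinstance(counts, AssayCounts):
        return counts.counts
    return counts


def median_of_ratios_size_factors(counts: AssayCounts | pd.DataFrame) -> SizeFactors:
    """DESeq2-style size factors: per-sample median ratio to the per-gene
    geometric mean, over genes positive in every sample."""
    mat = _as_frame(counts)
    if mat.shape[1] < 2:
        raise ValueError("need at least two samples")
    positive = (mat > 0).all(axis=1)
    if not positive.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; "
            "filter genes or add a pseudocount before normalizing"
        )
    ref = mat.loc[positive]
    log_geomean = np.log(ref).mean(axis=1)
    factors = np.exp(np.log(ref).sub(log_geomean, axis=0).median(axis=0))
    return SizeFactors(factors=factors, method="median_of_ratios")


def tpm(
    counts: AssayCounts | pd.DataFrame,
    lengths: pd.Series,
) -> NormalizedMatrix:
    """Transcripts per million: length-normalize, then scale columns to 1e6."""
    mat = _as_frame(counts)
    lengths = lengths.reindex(mat.index)
    if lengths.isna().any():
        missing = list(mat.index[lengths.isna()])[:5]
        raise ValueError(f"missing lengths for genes: {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("gene lengths must be strictly positive")
    rate = mat.div(lengths, axis=0)
    totals = rate.sum(axis=0)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"zero column total in samples: {bad}")
    return NormalizedMatrix(values=rate.div(totals, axis=1) * 1e6, scale="tpm")


def _spikein_scale(spikes: pd.DataFrame, method: str) -> pd.Series:
    if method == "spikein_total":
        totals = spikes.sum(axis=0).astype(float)
        if (totals <= 0).any():
            bad = list(totals.index[totals <= 0])
            raise ValueError(f"zero spike-in total in samples: {bad}")
        scale = 1.0 / totals
    elif method == "spikein_median":
        positive = (spikes > 0).all(axis=1)
        if not positive.any():
            raise ValueError("no spike positive in all samples")
        ref = spikes.loc[positive].astype(float)
        log_geomean = np.log(ref).mean(axis=1)
        scale = 1.0 / np.exp(np.log(ref).sub(log_geomean, axis=0).median(axis=0))
    else:
        raise ValueError(f"unknown spike-in method: {method}")
    # fix the arbitrary global constant: geometric mean 1 across samples
    scale = scale / np.exp(np.log(scale).mean())
    return scale


def ercc_normalize(
    counts: AssayCounts | pd.DataFrame,
    spike_counts: pd.DataFrame | None = None,
    method: str = "spikein_total",
) -> NormalizedMatrix:
    """Scale each sample by the reciprocal of its spike-in recovery.

    Absolute up to one global constant shared by all samples (fixed here so
    the per-sample scale factors have geometric mean 1); fold changes
    between samples are per-total-RNA absolute changes.
    """
    if spike_counts is None:
        if not isinstance(counts, AssayCounts) or counts.spikes is None:
            raise ValueError("spike_counts required (none attached to counts)")
        spike_counts = counts.spikes
    mat = _as_frame(counts)
    if list(mat.columns) != list(spike_counts.columns):
        spike_counts = spike_counts.reindex(columns=mat.columns)
        if spike_counts.isna().any().any():
            raise ValueError("gene and spike tables must share samples")
    scale = _spikein_scale(spike_counts, method)
    return NormalizedMatrix(
        values=mat.mul(scale, axis=1),
        scale="absolute_spikein",
        spike_scale=scale,
    )


def chip_spike_normalize(
    polII_counts: AssayCounts | pd.DataFrame,
    spike_genome_counts: pd.DataFrame | None = None,
    method: str = "spikein_total",
) -> NormalizedMatrix:
    """Heterologous-chromatin spike normalization of occupancy counts.

    Same contract as :func:`ercc_normalize`; spike rows are features of the
    spiked genome rather than ERCC species.
    """
    return ercc_normalize(polII_counts, spike_genome_counts, method=method)


def normalized_counts(
    counts: AssayCounts | pd.DataFrame,
    size_factors: SizeFactors | None = None,
) -> pd.DataFrame:
    """Counts divided by per-sample size factors (relative scale)."""
    mat = _as_frame(counts)
    if size_factors is None:
        size_factors = median_of_ratios_size_factors(mat)
    return mat.div(size_factors.factors, axis=1)
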