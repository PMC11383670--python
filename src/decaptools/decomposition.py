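"""Transcription-vs-decay decomposition of spike-in-normalized mRNA changes.

Spike-in normalization gives per-total-RNA fold changes.  Multiplying by a
ribosome-content factor (the fraction of ribosomes retained per cell in
the mutant, default 0.7 from an isogenic decapping-enzyme deletion
measurement) converts them to per-cell fold changes, because bulk RNA is
dominated by rRNA and cells are harvested per-OD.  Dividing the per-cell
fold change by the spike-normalized Pol II occupancy fold change then
isolates the decay (stabilization) component:

    percell_fc = normalized_mrna_fc * ribosome_factor
    decay_component_fc = percell_fc / polII_fc

A decay component near 1 means transcription explains the change; above 1
means transcript stabilization contributes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

DEFAULT_RIBOSOME_FACTOR = 0.7


def round_sig(x: float, sig: int = 2) -> float:
    """Round to `sig` significant figures (reporting convention)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class DecompositionResult:
    set_label: str
    normalized_mrna_fc: float
    ribosome_factor: float
    percell_fc: float
    polII_fc: float
    decay_component_fc: float

    def __post_init__(self) -> None:
        for name in ("normalized_mrna_fc", "ribosome_factor", "percell_fc",
                     "polII_fc", "decay_component_fc"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not math.isclose(self.percell_fc,
                            self.normalized_mrna_fc * self.ribosome_factor,
                            rel_tol=1e-9):
            raise ValueError("percell_fc must equal normalized_mrna_fc * ribosome_factor")
        if not math.isclose(self.percell_fc,
                            self.polII_fc * self.decay_component_fc,
                            rel_tol=1e-9):
            raise ValueError("percell_fc must equal polII_fc * decay_component_fc")

    @property
    def percell_fc_reported(self) -> float:
        return round_sig(self.percell_fc, 2)

    @property
    def decay_component_fc_reported(self) -> float:
        return round_sig(self.decay_component_fc, 2)


def per_cell_correction(normalized_fc: float, ribosome_factor: float = DEFAULT_RIBOSOME_FACTOR) -> float:
    """Per-cell fold change from a spike-normalized fold change."""
    if normalized_fc <= 0 or ribosome_factor <= 0:
        raise ValueError("fold changes and ribosome factor must be positive")
    return normalized_fc * ribosome_factor


def transcription_decay_split(percell_fc: float, polII_fc: float) -> float:
    """Decay-component fold change: per-cell change not explained by Pol II."""
    if percell_fc <= 0 or polII_fc <= 0:
        raise ValueError("fold changes must be positive")
    return percell_fc / polII_fc


def decompose(
    normalized_mrna_fc: float,
    polII_fc: float,
    ribosome_factor: float = DEFAULT_RIBOSOME_FACTOR,
    set_label: str = "",
) -> DecompositionResult:
    """Full decomposition of one gene-set (or per-gene) fold change."""
    percell = per_cell_correction(normalized_mrna_fc, ribosome_factor)
    decay = transcription_decay_split(percell, polII_fc)
    return DecompositionResult(
        set_label=set_label,
        normalized_mrna_fc=normalized_mrna_fc,
        ribosome_factor=ribosome_factor,
        percell_fc=percell,
        polII_fc=polII_fc,
        decay_component_fc=decay,
    )
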