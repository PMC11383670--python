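"""Decapping-state metrics.

C/T ratio: CAGE TPM over RNA-seq TPM, a relative proxy for the capped
proportion of each transcript's molecules (relative because CAGE and
RNA-seq are normalized independently; only contrasts between genes or
genotypes are meaningful, not the absolute level).

CPI (codon protection index): log2 enrichment of 5'P degradome ends in
the ribosome-protected codon frame over the other two frames.  Three-
nucleotide periodicity of 5'P ends arises when 5'->3' exonucleolytic
decay trails the last translating ribosome, so a high CPI marks
co-translationally decaying (decapped) intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class CapRatio:
    gene_id: str
    c_tpm: float
    t_tpm: float
    ct_ratio: float


def capped_total_ratio(
    cage_tpm: pd.DataFrame | pd.Series,
    rna_tpm: pd.DataFrame | pd.Series,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-gene C/T ratios from paired CAGE and RNA-seq TPM tables.

    Replicate columns are averaged on the log scale (geometric mean),
    since ratios are multiplicative.  Genes present in only one assay are
    dropped with a warning column-free contract: the returned frame covers
    the intersection.  Columns: c_tpm, t_tpm, ct_ratio.
    """
    if isinstance(cage_tpm, pd.Series):
        cage_tpm = cage_tpm.to_frame()
    if isinstance(rna_tpm, pd.Series):
        rna_tpm = rna_tpm.to_frame()
    common = cage_tpm.index.intersection(rna_tpm.index)
    if len(common) < len(cage_tpm.index.union(rna_tpm.index)):
        import warnings

        warnings.warn("genes absent in one assay were omitted from C/T", stacklevel=2)
    c = np.exp(np.log(cage_tpm.loc[common] + pseudocount).mean(axis=1)) - pseudocount
    t = np.exp(np.log(rna_tpm.loc[common] + pseudocount).mean(axis=1)) - pseudocount
    ct = (c + pseudocount) / (t + pseudocount)
    return pd.DataFrame({"c_tpm": c, "t_tpm": t, "ct_ratio": ct}, index=common)


def codon_protection_index(
    frame_counts: pd.DataFrame,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    protected_frame: int = 0,
) -> pd.DataFrame:
    """CPI per gene from framed 5'P end counts.

    cpi = log2((n_protected + pc) / (mean of the other two frames + pc)).
    Zero when the protected frame matches the mean of the others; invariant
    to uniform count scaling in the pc -> 0 limit.
    """
    if frame_counts.shape[1] != 3:
        raise ValueError("frame_counts needs exactly three frame columns")
    if (frame_counts < 0).any().any():
        raise ValueError("frame counts must be non-negative")
    arr = frame_counts.to_numpy(dtype=float)
    prot = arr[:, protected_frame]
    others = arr[:, [i for i in range(3) if i != protected_frame]]
    cpi = np.log2((prot + pseudocount) / (others.mean(axis=1) + pseudocount))
    out = frame_counts.copy()
    out.columns = ["frame0", "frame1", "frame2"]
    out["cpi"] = cpi
    return out


def optimality_correlation(
    log2fc: pd.Series,
    stai: pd.Series,
) -> tuple[float, float]:
    """Pearson correlation between expression changes and codon optimality.

    Two-sided t-based p-value; requires >=3 finite pairs and non-constant
    vectors.
    """
    df = pd.concat({"fc": log2fc, "stai": stai}, axis=1, join="inner").dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 paired finite values")
    if df["fc"].nunique() == 1 or df["stai"].nunique() == 1:
        raise ValueError("correlation undefined for a constant vector")
    r, p = stats.pearsonr(df["fc"], df["stai"])
    return float(r), float(p)


def median_stai(stai: pd.Series, genes: set[str] | frozenset[str] | None = None) -> float:
    """Median codon-optimality score, optionally over a gene set."""
    vals = stai if genes is None else stai.reindex(list(genes))
    vals = vals.dropna()
    if vals.empty:
        raise ValueError("no finite sTAI values in the requested set")
    return float(vals.median())
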