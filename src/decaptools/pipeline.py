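"""End-to-end runner: simulate -> normalize -> test -> classify -> report.

Also houses the small reporting statistics used throughout: notched-box
summaries and hierarchical clustering / rank-correlation of fold-change
profiles.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy

from . import io as dio
from .decap_metrics import capped_total_ratio, codon_protection_index
from .decomposition import decompose
from .differential import Contrast, call_regulated_sets, run_differential, te_shift_test
from .normalization import ercc_normalize, tpm
from .setops import (
    GeneSet,
    classify_redundancy,
    esr_signature,
    exclude_esr,
    patterns_from_sets,
    venn3,
)
from .synthetic_data import SimulationConfig, SyntheticDataset, simulate

logger = logging.getLogger("decaptools")

MUTANT_KEYS = {"scd6": "scd6d", "edc3": "edc3d", "double": "scd6d_edc3d"}


@dataclass(frozen=True)
class BoxSummary:
    n: int
    median: float
    q1: float
    q3: float
    notch_low: float
    notch_high: float


def boxplot_summary(values) -> BoxSummary:
    """Notched-box summary: type-7 quartiles, notches = median +/- 1.58*IQR/sqrt(n).

    Non-overlapping notches between two groups give roughly 95% confidence
    that the medians differ.
    """
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    if arr.size == 0:
        raise ValueError("boxplot summary of an empty vector")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])  # linear interpolation (type 7)
    half = 1.58 * (q3 - q1) / np.sqrt(arr.size)
    return BoxSummary(n=int(arr.size), median=float(med), q1=float(q1), q3=float(q3),
                      notch_low=float(med - half), notch_high=float(med + half))


def cluster_profiles(
    log2fc: pd.DataFrame,
    clip: float = 5.0,
) -> tuple[list[str], pd.DataFrame]:
    """Hierarchically cluster gene fold-change profiles across contrasts.

    Rows with missing values are dropped and values clipped to (-clip, clip);
    complete-linkage on Euclidean row distance.  Returns the leaf-ordered
    gene list and the Spearman rho matrix between contrast columns.
    """
    if log2fc.shape[1] < 2:
        raise ValueError("need at least two contrasts to cluster")
    mat = log2fc.dropna(axis=0, how="any").clip(-clip, clip)
    if mat.shape[0] < 2:
        raise ValueError("fewer than two complete rows after filtering")
    Z = hierarchy.linkage(mat.to_numpy(), method="complete", metric="euclidean")
    order = hierarchy.leaves_list(Z)
    rho, _ = stats.spearmanr(mat.to_numpy())
    if np.ndim(rho) == 0:  # scipy collapses the 2-column case to a scalar
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
    rho_df = pd.DataFrame(rho, index=mat.columns, columns=mat.columns)
    return [str(g) for g in mat.index[order]], rho_df


@dataclass
class PipelineConfig:
    """Thresholds and knobs of the full analysis.

    Defaults are the study's printed thresholds: mRNA/RPF sets at >1.5-fold
    with FDR<0.05, TE sets at >1.41-fold with FDR<0.10.  The ribosome
    factor converts spike-normalized to per-cell fold changes; 1.0 is
    appropriate for the simulator (which holds ribosome content constant),
    0.7 is the value assumed for real decapping-mutant data.
    """

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    te_fc_threshold: float = 1.41
    te_fdr_threshold: float = 0.10
    ribosome_factor: float = 1.0
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimulationConfig(**raw.pop("simulation", {}))
        cfg = cls(simulation=sim, **raw)
        return cfg


@dataclass
class ReportBundle:
    config: PipelineConfig
    paths: dict[str, Path]
    summary: dict

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, (Path,)):
                return str(o)
            if isinstance(o, (np.integer,)):
                return int(o)
            if isinstance(o, (np.floating,)):
                return float(o)
            raise TypeError(type(o))

        return json.dumps(self.summary, indent=2, default=default, sort_keys=True)


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def analyze_dataset(ds: SyntheticDataset, cfg: PipelineConfig) -> dict:
    """All analysis stages on an in-memory dataset; returns the summary dict."""
    t0 = _stage("differential")
    rna, rpf = ds.assays["rna"], ds.assays["rpf"]
    contrasts = {k: Contrast(v) for k, v in MUTANT_KEYS.items()}

    diff = {}
    for key, ctr in contrasts.items():
        diff[("mRNA", key)] = run_differential(rna, ctr, measure="mRNA")
        diff[("RPF", key)] = run_differential(rpf, ctr, measure="RPF")
        diff[("TE", key)] = te_shift_test(rpf, rna, ctr)
    logger.info("differential done in %.1fs", time.time() - t0)

    _stage("set calling")
    esr_ann = pd.Series({t.gene_id: t.esr_class for t in ds.truth})
    sets: dict[tuple, GeneSet] = {}
    retained: dict[str, float] = {}
    for (measure, key), res in diff.items():
        fc = cfg.te_fc_threshold if measure == "TE" else cfg.fc_threshold
        fdr = cfg.te_fdr_threshold if measure == "TE" else cfg.fdr_threshold
        for direction in ("up", "down"):
            s = call_regulated_sets(res, fc, fdr, direction)
            if measure == "mRNA":
                s, kept = exclude_esr(s, esr_ann, direction)
                retained[f"{measure}_{direction}_{key}"] = kept
            sets[(measure, key, direction)] = s

    _stage("redundancy classification")
    genes = [t.gene_id for t in ds.truth]
    patterns = patterns_from_sets(
        genes,
        {k: sets[("mRNA", k, "up")] for k in contrasts},
        {k: sets[("mRNA", k, "down")] for k in contrasts},
    )
    calls = classify_redundancy(patterns)
    call_by_gene = {c.gene_id: c.call for c in calls}
    truth_class = {t.gene_id: t.targeting_class for t in ds.truth}
    confusion = (
        pd.DataFrame(
            {"truth": pd.Series(truth_class), "call": pd.Series(call_by_gene)}
        )
        .groupby(["truth", "call"])
        .size()
        .unstack(fill_value=0)
    )
    redundant_genes = [g for g, c in truth_class.items() if c == "redundant_s6e3"]
    recovered = [g for g in redundant_genes if call_by_gene.get(g) == "redundant_double_only"]
    redundant_recall = 100.0 * len(recovered) / len(redundant_genes) if redundant_genes else float("nan")

    _stage("ESR signature")
    iesr = {t.gene_id for t in ds.truth if t.esr_class == "iESR"}
    resr = {t.gene_id for t in ds.truth if t.esr_class == "rESR"}
    if iesr and resr:
        esr_medians = esr_signature(diff[("mRNA", "double")].table["log2_fc"], iesr, resr)
    else:
        esr_medians = (float("nan"), float("nan"))

    _stage("Venn")
    up_sets = [sets[("mRNA", k, "up")] for k in ("scd6", "edc3", "double")]
    venn = venn3(*up_sets)

    _stage("C/T and CPI")
    lengths = pd.Series({t.gene_id: t.cds_length for t in ds.truth})
    cage_tpm = tpm(ds.assays["cage"], lengths).values
    rna_tpm = tpm(rna, lengths).values
    genos = dict(zip(ds.design["sample_id"], ds.design["genotype"]))
    ct_by_geno = {}
    for g in ds.config.genotypes:
        cols = [s for s in cage_tpm.columns if genos[s] == g]
        ct_by_geno[g] = capped_total_ratio(cage_tpm[cols], rna_tpm[cols])
    up_double = sets[("mRNA", "double", "up")].members
    ct_summary = {}
    for g in ("WT", "scd6d_edc3d"):
        ct = ct_by_geno[g]["ct_ratio"]
        ct_summary[g] = {
            "all_median": float(ct.median()),
            "upset_median": float(ct.reindex(list(up_double)).dropna().median())
            if up_double else float("nan"),
        }
    cpi_by_geno = {
        g: float(codon_protection_index(fr).loc[:, "cpi"].median())
        for g, fr in ds.fivep_frames.items()
    }

    _stage("decomposition")
    mrna_abs = ercc_normalize(rna).values
    polII_abs = ercc_normalize(ds.assays["polII"]).values
    wt_cols = [s for s, g in genos.items() if g == "WT"]
    dbl_cols = [s for s, g in genos.items() if g == "scd6d_edc3d"]

    def _set_fc(mat: pd.DataFrame, members) -> float:
        sub = mat.reindex(list(members)).dropna() if members else mat
        ratio = (sub[dbl_cols].mean(axis=1) + 0.5) / (sub[wt_cols].mean(axis=1) + 0.5)
        return float(np.exp(np.log(ratio).median()))

    decomp = {}
    for direction in ("up", "down"):
        members = sets[("mRNA", "double", direction)].members
        if not members:
            continue
        res = decompose(
            _set_fc(mrna_abs, members),
            _set_fc(polII_abs, members),
            ribosome_factor=cfg.ribosome_factor,
            set_label=f"mRNA_{direction}_double",
        )
        decomp[direction] = {
            "normalized_mrna_fc": res.normalized_mrna_fc,
            "percell_fc": res.percell_fc,
            "percell_fc_reported": res.percell_fc_reported,
            "polII_fc": res.polII_fc,
            "decay_component_fc": res.decay_component_fc,
        }

    _stage("clustering")
    fc_matrix = pd.DataFrame(
        {k: diff[("mRNA", k)].table["log2_fc"] for k in contrasts}
    )
    any_up = set().union(*(s.members for s in up_sets)) if up_sets else set()
    cluster_rows = fc_matrix.reindex(sorted(any_up)).dropna()
    if len(cluster_rows) >= 2:
        _, rho = cluster_profiles(cluster_rows)
        rho_dict = {f"{a}:{b}": float(rho.loc[a, b]) for a in rho.index for b in rho.columns if a < b}
    else:
        rho_dict = {}

    return {
        "set_sizes": {
            f"{m}_{d}_{k}": len(sets[(m, k, d)])
            for (m, k, d) in sets
        },
        "esr_retained_pct": retained,
        "redundancy_class_counts": pd.Series(call_by_gene).value_counts().to_dict(),
        "redundancy_confusion": {
            str(i): row.to_dict() for i, row in confusion.iterrows()
        },
        "redundant_recall_pct": redundant_recall,
        "esr_signature_double": {"iESR_median": esr_medians[0], "rESR_median": esr_medians[1]},
        "venn_mrna_up": {
            "totals": venn.totals,
            "exclusive": venn.exclusive,
            "pairwise_only": venn.pairwise_only,
            "triple": venn.triple,
        },
        "ct_ratio": ct_summary,
        "cpi_median_by_genotype": cpi_by_geno,
        "decomposition": decomp,
        "spearman_rho": rho_dict,
        "_sets": sets,
        "_diff": diff,
    }


def run_pipeline(cfg: PipelineConfig) -> ReportBundle:
    """Simulate (seed-deterministic), analyze, and write all stage outputs."""
    ds = simulate(cfg.simulation)
    summary = analyze_dataset(ds, cfg)
    sets = summary.pop("_sets")
    diff = summary.pop("_diff")

    paths: dict[str, Path] = {}
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths.update(dio.write_dataset(ds, out / "data"))
        res_dir = out / "results"
        res_dir.mkdir(exist_ok=True)
        for (measure, key), res in diff.items():
            p = res_dir / f"diff_{measure}_{key}.tsv"
            res.table.to_csv(p, sep="\t", index_label="gene_id")
            paths[f"diff_{measure}_{key}"] = p
        for (measure, key, direction), s in sets.items():
            p = res_dir / f"set_{measure}_{key}_{direction}.txt"
            dio.write_gene_set(s, p)
        p = res_dir / "summary.json"
        bundle = ReportBundle(config=cfg, paths=paths, summary=summary)
        p.write_text(bundle.to_json())
        paths["summary"] = p
        return bundle
    return ReportBundle(config=cfg, paths=paths, summary=summary)
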