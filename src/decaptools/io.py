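"""Tab-separated text I/O for counts, designs, truth tables and gene sets."""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .setops import GeneSet
from .synthetic_data import AssayCounts, SyntheticDataset


def write_counts(counts: pd.DataFrame, path: str | Path, index_label: str = "gene_id") -> None:
    counts.to_csv(path, sep="\t", index_label=index_label)


def read_counts(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_design(design: pd.DataFrame, path: str | Path) -> None:
    design.to_csv(path, sep="\t", index=False)


def read_design(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_set(gene_set: GeneSet, path: str | Path) -> None:
    """One gene per line, provenance in a leading comment."""
    with open(path, "w") as fh:
        fh.write(f"# {gene_set.label}\t{gene_set.provenance}\n")
        for g in sorted(gene_set.members):
            fh.write(g + "\n")


def read_gene_set(path: str | Path) -> GeneSet:
    label, provenance, members = Path(path).stem, "", []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                parts = line[1:].strip().split("\t")
                label = parts[0] or label
                provenance = parts[1] if len(parts) > 1 else ""
            elif line:
                members.append(line)
    return GeneSet(label=label, members=frozenset(members), provenance=provenance)


def write_dataset(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Serialize a simulated experiment as tab-separated text files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, assay in dataset.assays.items():
        p = out / f"counts_{name}.tsv"
        write_counts(assay.counts, p)
        paths[f"counts_{name}"] = p
        if assay.spikes is not None:
            sp = out / f"spikes_{name}.tsv"
            write_counts(assay.spikes, sp, index_label="spike_id")
            paths[f"spikes_{name}"] = sp
    for genotype, frames in dataset.fivep_frames.items():
        p = out / f"fivep_frames_{genotype}.tsv"
        write_counts(frames, p)
        paths[f"fivep_frames_{genotype}"] = p
    p = out / "design.tsv"
    write_design(dataset.design, p)
    paths["design"] = p
    p = out / "truth.tsv"
    dataset.truth_frame().to_csv(p, sep="\t")
    paths["truth"] = p
    return paths


def read_assay(counts_path: str | Path, design: pd.DataFrame, assay: str,
               spikes_path: str | Path | None = None) -> AssayCounts:
    spikes = read_counts(spikes_path) if spikes_path else None
    return AssayCounts(assay=assay, counts=read_counts(counts_path),
                       design=design, spikes=spikes)
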