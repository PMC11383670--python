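"""Ground-truthed multi-assay count simulator.

Emulates a yeast decapping-activator deletion panel (WT, scd6Δ, edc3Δ,
scd6Δedc3Δ) measured by five count-based assays: RNA-seq, ribosome
profiling (RPF), CAGE, framed 5′P degradome ends, and Pol II ChIP.
Per-gene abundances follow a steady-state synthesis/decay model; counts
are negative-binomial with per-sample depth scaling and paired spike-in
tables whose true scale multipliers are stored so that normalization
recovery is assertable downstream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

GENOTYPES = ("WT", "scd6d", "edc3d", "scd6d_edc3d")

#: which factors remain present in each genotype of the panel
_FACTORS_PRESENT = {
    "WT": frozenset({"scd6", "edc3"}),
    "scd6d": frozenset({"edc3"}),
    "edc3d": frozenset({"scd6"}),
    "scd6d_edc3d": frozenset(),
}

TARGETING_CLASSES = (
    "untargeted",
    "redundant_s6e3",
    "edc3_exclusive",
    "dhh1_pat1_like",
    "concerted",
)

ASSAYS = ("rna", "rpf", "cage", "fivep", "polII")


class ConfigurationError(ValueError):
    """Raised when a SimulationConfig violates its invariants."""


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the study design: four genotypes, two biological
    replicates each, bulk library depths of ~2e6 reads per assay, and a
    targeting-class mixture in which most genes are untargeted and a
    minority are redundantly repressed by Scd6/Edc3.
    """

    n_genes: int = 2000
    genotypes: tuple[str, ...] = GENOTYPES
    n_replicates: int = 2
    library_depth: float = 2e6
    dispersion_base: float = 0.05
    class_proportions: dict[str, float] = field(
        default_factory=lambda: {
            "untargeted": 0.70,
            "redundant_s6e3": 0.12,
            "edc3_exclusive": 0.04,
            "dhh1_pat1_like": 0.09,
            "concerted": 0.05,
        }
    )
    effect_size_range: tuple[float, float] = (3.0, 6.0)
    te_effect_range: tuple[float, float] = (1.8, 4.0)
    esr_fraction: float = 0.10
    esr_log2_shift: float = 1.0
    n_spikes: int = 50
    #: spike-ins are exogenous standards: only technical (pipetting +
    #: counting) noise, far below the biological dispersion of genes
    spike_dispersion: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_genes <= 0:
            raise ConfigurationError("n_genes must be positive")
        if self.n_replicates <= 0:
            raise ConfigurationError("n_replicates must be positive")
        if self.library_depth <= 0:
            raise ConfigurationError("library_depth must be positive")
        if self.dispersion_base < 0:
            raise ConfigurationError("dispersion_base must be non-negative")
        if "WT" not in self.genotypes:
            raise ConfigurationError("genotype panel must contain WT")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(
                f"class_proportions must sum to 1, got {total!r}"
            )
        unknown = set(self.class_proportions) - set(TARGETING_CLASSES)
        if unknown:
            raise ConfigurationError(f"unknown targeting classes: {unknown}")
        lo, hi = self.effect_size_range
        if not (1.0 <= lo <= hi):
            raise ConfigurationError("effect_size_range must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.esr_fraction < 1.0:
            raise ConfigurationError("esr_fraction must be in [0, 1)")


@dataclass(frozen=True)
class GeneTruth:
    """Generative parameters for one gene."""

    gene_id: str
    synthesis_rate: float          # transcripts per unit time
    base_decay: float              # 1/time, decay with decapping relieved
    targeting_class: str
    decay_effect: float            # multiplier >= 1 when targeting active
    te_true: float                 # translational efficiency, repression relieved
    te_effect: float               # TE gain when translational repression relieved
    capped_fraction: dict[str, float]  # per genotype, in (0, 1]
    periodicity: float             # in [0, 1], 5'P frame bias
    esr_class: str                 # none / iESR / rESR
    cds_length: int                # nt, multiple of 3
    stai: float                    # codon-optimality score


@dataclass
class AssayCounts:
    """Gene-by-sample integer counts for one assay plus paired spike-ins."""

    assay: str
    counts: pd.DataFrame                 # genes x samples, int
    design: pd.DataFrame                 # sample_id, genotype, replicate
    spikes: pd.DataFrame | None = None   # spike_id x samples, int

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)


@dataclass
class SyntheticDataset:
    """Full simulated experiment with its ground truth."""

    config: SimulationConfig
    truth: list[GeneTruth]
    assays: dict[str, AssayCounts]
    design: pd.DataFrame
    spike_multipliers: dict[str, pd.Series]      # assay -> per-sample true scale
    fivep_frames: dict[str, pd.DataFrame]        # genotype -> genes x 3 frame counts

    def truth_frame(self) -> pd.DataFrame:
        """Ground truth as a flat table (capped fractions as one col/genotype)."""
        rows = []
        for t in self.truth:
            row = {
                "gene_id": t.gene_id,
                "synthesis_rate": t.synthesis_rate,
                "base_decay": t.base_decay,
                "targeting_class": t.targeting_class,
                "decay_effect": t.decay_effect,
                "te_true": t.te_true,
                "te_effect": t.te_effect,
                "periodicity": t.periodicity,
                "esr_class": t.esr_class,
                "cds_length": t.cds_length,
                "stai": t.stai,
            }
            for g, cf in t.capped_fraction.items():
                row[f"capped_fraction_{g}"] = cf
            rows.append(row)
        return pd.DataFrame(rows).set_index("gene_id")


def _substream(seed: int, name: str) -> np.random.Generator:
    """Named, order-independent child RNG of the master seed."""
    key = zlib.crc32(name.encode())
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def _decapping_active(targeting_class: str, genotype: str) -> bool:
    """Whether activator-stimulated decapping acts on this gene in this genotype.

    Redundant Scd6/Edc3 targets lose repression only when both factors are
    gone; Edc3-exclusive targets whenever Edc3 is present.  Dhh1/Pat1-type
    and concerted targets need dhh1/pat1 deletions outside this panel, so
    their repression is always on here.
    """
    present = _FACTORS_PRESENT[genotype]
    if targeting_class == "untargeted":
        return False
    if targeting_class == "redundant_s6e3":
        return "scd6" in present or "edc3" in present
    if targeting_class == "edc3_exclusive":
        return "edc3" in present
    if targeting_class in ("dhh1_pat1_like", "concerted"):
        return True
    raise ValueError(f"unknown targeting class: {targeting_class}")


def genotype_decay_rate(truth: GeneTruth, genotype: str) -> float:
    """Decay rate (1/time) of a gene in a genotype of the panel."""
    if genotype not in _FACTORS_PRESENT:
        raise ValueError(f"unknown genotype: {genotype}")
    if _decapping_active(truth.targeting_class, genotype):
        return truth.base_decay * truth.decay_effect
    return truth.base_decay


def genotype_te(truth: GeneTruth, genotype: str) -> float:
    """Translational efficiency of a gene in a genotype.

    Classes with translational repression (same OR-logic as decay) have
    TE = te_true / te_effect while repression is active.
    """
    if genotype not in _FACTORS_PRESENT:
        raise ValueError(f"unknown genotype: {genotype}")
    if _decapping_active(truth.targeting_class, genotype):
        return truth.te_true / truth.te_effect
    return truth.te_true


def steady_state_abundance(synthesis: float, decay: float) -> float:
    """Steady-state transcript abundance, synthesis / decay."""
    if decay <= 0:
        raise ValueError("decay rate must be strictly positive")
    return synthesis / decay


_ESR_SEVERITY = {"WT": 0.0, "scd6d": 0.25, "edc3d": 0.25, "scd6d_edc3d": 1.0}


def esr_shift(truth: GeneTruth, genotype: str, esr_log2_shift: float) -> float:
    """Multiplicative indirect-stress shift applied to a gene's abundance.

    iESR genes go up and rESR genes down, scaled by genotype severity
    (strongest in the slow-growing double mutant).
    """
    sev = _ESR_SEVERITY.get(genotype, 1.0)
    if truth.esr_class == "iESR":
        return float(2.0 ** (sev * esr_log2_shift))
    if truth.esr_class == "rESR":
        return float(2.0 ** (-sev * esr_log2_shift))
    return 1.0


def true_abundance(truth: GeneTruth, genotype: str, esr_log2_shift: float = 0.0) -> float:
    """Noise-free steady-state abundance in a genotype, ESR shift included."""
    ab = steady_state_abundance(truth.synthesis_rate, genotype_decay_rate(truth, genotype))
    return ab * esr_shift(truth, genotype, esr_log2_shift)


def assign_gene_truth(config: SimulationConfig) -> list[GeneTruth]:
    """Draw per-gene generative parameters. Deterministic for a fixed seed."""
    config.validate()
    rng = _substream(config.seed, "truth")
    n = config.n_genes

    # class assignment: largest-remainder rounding so counts match proportions
    classes = [c for c in TARGETING_CLASSES if config.class_proportions.get(c, 0) > 0]
    raw = np.array([config.class_proportions[c] * n for c in classes])
    counts = np.floor(raw).astype(int)
    remainder = n - counts.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    for i in order[:remainder]:
        counts[i] += 1
    labels = np.repeat(classes, counts)
    rng.shuffle(labels)

    synthesis = rng.lognormal(mean=np.log(10.0), sigma=1.0, size=n)
    base_decay = rng.lognormal(mean=np.log(0.2), sigma=0.5, size=n)
    lo, hi = config.effect_size_range
    decay_effect = rng.uniform(lo, hi, size=n)
    te_lo, te_hi = config.te_effect_range
    te_effect = rng.uniform(te_lo, te_hi, size=n)
    te_true = rng.lognormal(mean=0.0, sigma=0.5, size=n)
    periodicity = rng.uniform(0.0, 0.9, size=n)
    cds_codons = np.maximum(100, rng.lognormal(np.log(450), 0.5, size=n).astype(int))
    stai = rng.uniform(0.2, 0.55, size=n)
    capped_active = rng.uniform(0.30, 0.60, size=n)    # decapping acting: low capped frac
    capped_inactive = rng.uniform(0.75, 0.95, size=n)  # repression relieved / untargeted

    # ESR labels drawn preferentially from untargeted genes so the indirect
    # stress signature is separable from direct decapping targets
    esr = np.array(["none"] * n, dtype=object)
    n_esr = int(round(config.esr_fraction * n))
    untargeted_idx = np.flatnonzero(labels == "untargeted")
    pool = untargeted_idx if len(untargeted_idx) >= n_esr else np.arange(n)
    chosen = rng.choice(pool, size=min(n_esr, len(pool)), replace=False)
    half = len(chosen) // 2
    esr[chosen[:half]] = "iESR"
    esr[chosen[half:]] = "rESR"

    truths = []
    width = len(str(n))
    for i in range(n):
        cls = labels[i]
        eff = float(decay_effect[i]) if cls != "untargeted" else 1.0
        teff = float(te_effect[i]) if cls != "untargeted" else 1.0
        cf = {}
        for g in config.genotypes:
            active = _decapping_active(cls, g)
            cf[g] = float(capped_active[i] if active else capped_inactive[i])
        truths.append(
            GeneTruth(
                gene_id=f"gene_{i:0{width}d}",
                synthesis_rate=float(synthesis[i]),
                base_decay=float(base_decay[i]),
                targeting_class=str(cls),
                decay_effect=eff,
                te_true=float(te_true[i]),
                te_effect=teff,
                capped_fraction=cf,
                periodicity=float(periodicity[i]),
                esr_class=str(esr[i]),
                cds_length=int(cds_codons[i]) * 3,
                stai=float(stai[i]),
            )
        )
    return truths


def make_design(config: SimulationConfig) -> pd.DataFrame:
    rows = [
        {"sample_id": f"{g}_rep{r + 1}", "genotype": g, "replicate": r + 1}
        for g in config.genotypes
        for r in range(config.n_replicates)
    ]
    return pd.DataFrame(rows)


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB counts with mean mu and variance mu + alpha*mu^2 (Poisson if alpha=0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha <= 0:
        return rng.poisson(mu)
    size_param = 1.0 / alpha
    p = size_param / (size_param + mu)
    return rng.negative_binomial(size_param, p)


def _assay_expectation(truth: GeneTruth, genotype: str, assay: str, cfg: SimulationConfig) -> float:
    """Unnormalized per-cell expectation of one gene in one assay."""
    if assay == "polII":
        # occupancy tracks synthesis only; no ESR transcriptional component
        # beyond what the steady-state model attributes to decay
        return truth.synthesis_rate
    ab = true_abundance(truth, genotype, cfg.esr_log2_shift)
    if assay == "rna":
        return ab
    if assay == "rpf":
        return ab * genotype_te(truth, genotype)
    if assay == "cage":
        return ab * truth.capped_fraction[genotype]
    if assay == "fivep":
        # decapped molecules feed the 5'P degradome
        return ab * (1.0 - truth.capped_fraction[genotype] + 0.05)
    raise ValueError(f"unknown assay: {assay}")


def sample_assay_counts(
    truth: list[GeneTruth],
    design: pd.DataFrame,
    config: SimulationConfig,
) -> SyntheticDataset:
    """Sample the full five-assay dataset with spike-ins and 5′P frame tables.

    The per-sample read budget is split between genes and spikes in
    proportion to cellular content: a fixed absolute amount of spike
    material per cell competes with a genotype-dependent total mRNA pool,
    so global mRNA-per-cell shifts are encoded in spike recovery exactly as
    in an ERCC / heterologous-chromatin experiment.
    """
    config.validate()
    gene_ids = [t.gene_id for t in truth]
    samples = list(design["sample_id"])
    genos = dict(zip(design["sample_id"], design["genotype"]))

    assays: dict[str, AssayCounts] = {}
    spike_mult: dict[str, pd.Series] = {}
    spike_ids = [f"spike_{i:03d}" for i in range(config.n_spikes)]
    rng_sp = _substream(config.seed, "spike_profile")
    spike_profile = rng_sp.lognormal(mean=0.0, sigma=1.0, size=config.n_spikes)
    spike_profile /= spike_profile.sum()

    for assay in ASSAYS:
        rng = _substream(config.seed, f"assay:{assay}")
        expect = np.array(
            [[_assay_expectation(t, g, assay, config) for g in config.genotypes] for t in truth]
        )  # genes x genotypes
        geno_index = {g: k for k, g in enumerate(config.genotypes)}
        # spike pool worth ~5% of the WT cellular signal of this assay
        spike_pool = 0.05 * expect[:, geno_index["WT"]].sum()

        counts = np.empty((len(truth), len(samples)), dtype=np.int64)
        spikes = np.empty((config.n_spikes, len(samples)), dtype=np.int64)
        truth_scale = []
        for j, s in enumerate(samples):
            g = genos[s]
            e = expect[:, geno_index[g]]
            cell_total = e.sum() + spike_pool
            depth = config.library_depth * rng.lognormal(0.0, 0.1)
            mu_genes = depth * e / cell_total
            mu_spikes = depth * spike_pool * spike_profile / cell_total
            counts[:, j] = _nb_draw(rng, mu_genes, config.dispersion_base)
            spikes[:, j] = _nb_draw(rng, mu_spikes, config.spike_dispersion)
            # reads-per-cellular-unit: the factor spike normalization removes
            truth_scale.append(depth / cell_total)
        assays[assay] = AssayCounts(
            assay=assay,
            counts=pd.DataFrame(counts, index=gene_ids, columns=samples),
            design=design.copy(),
            spikes=pd.DataFrame(spikes, index=spike_ids, columns=samples),
        )
        spike_mult[assay] = pd.Series(truth_scale, index=samples, name="true_scale")

    # framed 5'P ends per genotype: replicate-pooled multinomial split of the
    # fivep totals into codon frames; frame 0 is the ribosome-protected frame
    frames: dict[str, pd.DataFrame] = {}
    rng_f = _substream(config.seed, "fivep_frames")
    fivep = assays["fivep"].counts
    for g in config.genotypes:
        cols = [s for s in samples if genos[s] == g]
        totals = fivep[cols].sum(axis=1).to_numpy()
        p = np.array([t.periodicity for t in truth])
        probs = np.column_stack([(1 + 2 * p) / 3, (1 - p) / 3, (1 - p) / 3])
        fr = np.array(
            [rng_f.multinomial(totals[i], probs[i]) for i in range(len(truth))]
        )
        frames[g] = pd.DataFrame(
            fr, index=gene_ids, columns=["frame0", "frame1", "frame2"]
        )

    return SyntheticDataset(
        config=config,
        truth=truth,
        assays=assays,
        design=design,
        spike_multipliers=spike_mult,
        fivep_frames=frames,
    )


def simulate(config: SimulationConfig | None = None, **overrides) -> SyntheticDataset:
    """One-call generator: truth, design, counts."""
    if config is None:
        config = SimulationConfig()
    if overrides:
        config = replace(config, **overrides)
    config.validate()
    truth = assign_gene_truth(config)
    design = make_design(config)
    return sample_assay_counts(truth, design, config)
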