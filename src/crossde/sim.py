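"""Synthetic-data generation for the whole pipeline.

The generator emulates the structure of the study design it is built for:
a bulk RNA-seq comparison of mutant versus wild-type hypothalamus with 4
biological replicates per genotype, NB-distributed counts with a
mean-dispersion trend alpha(mu) = a0/mu + a1, planted log2 fold changes
within +/-2 (balanced up/down in the "rat" experiment), mouse reference
sets planted at configured concordance/TG-only/opposite/other-region
rates with an up-skewed NULL set, a partial 1:1 ortholog map, a human
validation panel with planted outcome labels, and aligned reads whose
union-exon counts round-trip a target count matrix.

Every operation draws from its own RNG stream derived from
(config seed, operation tag), so adding an operation never perturbs the
draws of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .concordance import OrthologMap, ReferenceSets
from .counting import AlignedRead, CountMatrix, GeneModel, GenomicInterval
from .validation import VALIDATION_LABELS, ValidationRecord

__all__ = [
    "SimulationConfig",
    "MIN_CALLABLE_LOG2FC",
    "simulate_count_experiment",
    "simulate_reference_sets",
    "simulate_ortholog_map",
    "simulate_validation_panel",
    "simulate_reads",
    "default_library_size_factors",
]

# log2(1.5): planted effects at or above the fold-change call threshold
MIN_CALLABLE_LOG2FC = float(np.log2(1.5))

CONDITION_A = "wildtype"
CONDITION_B = "mutant"


def _stream(seed: int, tag: str) -> np.random.Generator:
    """Independent RNG stream per operation: seeded from (seed, crc32(tag))."""
    return np.random.default_rng([seed & 0x7FFFFFFF, zlib.crc32(tag.encode()) & 0x7FFFFFFF])


def default_library_size_factors(n_samples: int) -> tuple[float, ...]:
    """Deterministic sequencing-depth factors spanning ~0.8x-1.2x, geometric mean 1."""
    log_f = np.linspace(-0.2, 0.2, n_samples)
    log_f -= log_f.mean()
    return tuple(np.exp(log_f))


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults encode the emulated study conditions: 4 replicates per
    genotype, effects within log2 +/- 2 and above the 1.5-fold call
    threshold, balanced up/down planted directions in the rat experiment,
    an up-skewed NULL reference set, and category rates matching the
    published concordance proportions.
    """

    n_genes: int = 2000
    n_per_group: int = 4
    de_fraction: float = 0.1
    up_fraction_rat: float = 0.5
    up_fraction_null: float = 0.75
    max_abs_log2fc: float = 2.0
    mean_log10_range: tuple[float, float] = (0.5, 3.0)
    dispersion_model: tuple[float, float] = (0.8, 0.05)  # (a0, a1) of a0/mu + a1
    concordance_rate: float = 0.41
    tg_only_rate: float = 0.05
    opposite_rate: float = 0.02
    other_region_rate: float = 0.05
    ortholog_dropout_rate: float = 0.0
    validation_label_proportions: Mapping[str, float] = field(
        default_factory=lambda: {
            "predicted_direction": 0.25,
            "opposite_direction": 0.17,
            "undetectable_in_case": 0.10,
            "not_significant": 0.40,
            "not_expressed": 0.08,
        }
    )
    library_size_factors: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes <= 0 or self.n_per_group <= 0:
            raise ValueError("n_genes and n_per_group must be positive")
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2 (dispersion needs replicates)")
        for name in (
            "de_fraction",
            "up_fraction_rat",
            "up_fraction_null",
            "concordance_rate",
            "tg_only_rate",
            "opposite_rate",
            "other_region_rate",
            "ortholog_dropout_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        rate_sum = (
            self.concordance_rate
            + self.tg_only_rate
            + self.opposite_rate
            + self.other_region_rate
        )
        if rate_sum > 1.0 + 1e-12:
            raise ValueError(f"planted category rates sum to {rate_sum} > 1")
        if self.max_abs_log2fc <= 0:
            raise ValueError("max_abs_log2fc must be positive")
        if self.max_abs_log2fc < MIN_CALLABLE_LOG2FC:
            raise ValueError(
                f"max_abs_log2fc must be >= log2(1.5) = {MIN_CALLABLE_LOG2FC:.4f}"
            )
        lo, hi = self.mean_log10_range
        if not lo < hi:
            raise ValueError("mean_log10_range must be an increasing pair")
        a0, a1 = self.dispersion_model
        if a0 < 0 or a1 < 0:
            raise ValueError("dispersion trend coefficients must be non-negative")
        props = dict(self.validation_label_proportions)
        if set(props) - set(VALIDATION_LABELS):
            raise ValueError(f"unknown validation labels {set(props) - set(VALIDATION_LABELS)}")
        if abs(sum(props.values()) - 1.0) > 1e-9:
            raise ValueError("validation label proportions must sum to 1")
        if self.library_size_factors is not None:
            sf = np.asarray(self.library_size_factors, dtype=float)
            if len(sf) != 2 * self.n_per_group:
                raise ValueError("library_size_factors must have one entry per sample")
            if not np.all(sf > 0):
                raise ValueError("library_size_factors must be positive")

    @property
    def n_samples(self) -> int:
        return 2 * self.n_per_group

    def size_factors(self) -> np.ndarray:
        if self.library_size_factors is not None:
            return np.asarray(self.library_size_factors, dtype=float)
        return np.asarray(default_library_size_factors(self.n_samples))

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("mean_log10_range", "dispersion_model", "library_size_factors"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Draw NB(mean, alpha) counts with variance = mean + alpha * mean^2."""
    mean = np.asarray(mean, dtype=float)
    alpha = np.broadcast_to(np.asarray(alpha, dtype=float), mean.shape)
    out = np.empty(mean.shape, dtype=np.int64)
    poisson = alpha < 1e-12
    if poisson.any():
        out[poisson] = rng.poisson(mean[poisson])
    nb = ~poisson
    if nb.any():
        size = 1.0 / alpha[nb]
        p = size / (size + mean[nb])
        out[nb] = rng.negative_binomial(size, p)
    return out


def simulate_count_experiment(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Simulate the two-genotype NB count experiment plus its truth table.

    The truth table (indexed by gene) records true_log2fc, true_de,
    true_direction and a planted_category column (filled by
    :func:`simulate_reference_sets`, ``none`` until then). Exactly
    round(de_fraction * n_genes) genes carry a nonzero effect; effect
    magnitudes are uniform on [log2(1.5), max_abs_log2fc] with sign up at
    probability up_fraction_rat, applied to the mutant condition.
    """
    rng = _stream(config.seed, "counts")
    n = config.n_genes
    genes = [f"G{i:06d}" for i in range(n)]
    lo, hi = config.mean_log10_range
    base_mean = 10.0 ** rng.uniform(lo, hi, size=n)
    a0, a1 = config.dispersion_model
    alpha = a0 / base_mean + a1

    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    log2fc = np.zeros(n)
    magnitude = rng.uniform(MIN_CALLABLE_LOG2FC, config.max_abs_log2fc, size=n_de)
    sign = np.where(rng.random(n_de) < config.up_fraction_rat, 1.0, -1.0)
    log2fc[de_idx] = sign * magnitude

    sf = config.size_factors()
    samples = [f"wt_{i+1}" for i in range(config.n_per_group)] + [
        f"mut_{i+1}" for i in range(config.n_per_group)
    ]
    conditions = {s: CONDITION_A for s in samples[: config.n_per_group]}
    conditions.update({s: CONDITION_B for s in samples[config.n_per_group :]})

    counts = np.empty((n, config.n_samples), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = base_mean * (2.0 ** log2fc if conditions[sample] == CONDITION_B else 1.0)
        counts[:, j] = _nb_sample(rng, sf[j] * mu, alpha)

    truth = pd.DataFrame(
        {
            "true_log2fc": log2fc,
            "true_de": log2fc != 0.0,
            "true_direction": np.where(
                log2fc > 0, "up", np.where(log2fc < 0, "down", "none")
            ),
            "base_mean": base_mean,
            "dispersion": alpha,
            "planted_category": "none",
        },
        index=pd.Index(genes, name="gene"),
    )
    matrix = CountMatrix(pd.DataFrame(counts, index=genes, columns=samples), conditions)
    return matrix, truth


def _mouse_id(rat_gene: str) -> str:
    return f"m_{rat_gene}"


def simulate_reference_sets(
    truth: pd.DataFrame, config: SimulationConfig
) -> ReferenceSets:
    """Plant rat-true-DE genes into the mouse reference sets at configured rates.

    Each true-DE gene is assigned at most one planted category; planted
    counts are round(rate * n_de) per category. Concordant genes enter
    NULL_HYP with the rat direction (and TG_HYP with the opposite direction,
    the activated/repressed pattern); the up/down composition of the
    concordant NULL planting is steered toward up_fraction_null as far as
    the available rat directions allow. TG-only genes enter TG_HYP with the
    rat direction, opposite genes enter NULL_HYP with the flipped direction,
    other-region genes enter CER or AMY. The truth table's planted_category
    column is filled in place. Reference sets are keyed by mouse gene ids
    (see :func:`simulate_ortholog_map`).
    """
    rng = _stream(config.seed, "reference_sets")
    de = truth[truth["true_de"]]
    n_de = len(de)
    n_conc = int(round(config.concordance_rate * n_de))
    n_tg = int(round(config.tg_only_rate * n_de))
    n_opp = int(round(config.opposite_rate * n_de))
    n_other = int(round(config.other_region_rate * n_de))
    if n_conc + n_tg + n_opp + n_other > n_de:
        raise ValueError("planted category rates sum to > 1 for this gene count")

    up_pool = list(de.index[de["true_direction"] == "up"])
    down_pool = list(de.index[de["true_direction"] == "down"])
    rng.shuffle(up_pool)
    rng.shuffle(down_pool)

    # steer the concordant planting toward the NULL up-skew, best effort
    want_up = int(round(config.up_fraction_null * n_conc))
    take_up = min(want_up, len(up_pool))
    take_down = min(n_conc - take_up, len(down_pool))
    take_up = min(n_conc - take_down, len(up_pool))  # backfill if downs ran out
    concordant = [up_pool.pop() for _ in range(take_up)] + [
        down_pool.pop() for _ in range(take_down)
    ]

    rest = up_pool + down_pool
    rng.shuffle(rest)
    tg_only = [rest.pop() for _ in range(min(n_tg, len(rest)))]
    opposite = [rest.pop() for _ in range(min(n_opp, len(rest)))]
    other_region = [rest.pop() for _ in range(min(n_other, len(rest)))]

    sets = ReferenceSets()
    direction = truth["true_direction"]

    def flip(d: str) -> str:
        return "down" if d == "up" else "up"

    for gene in concordant:
        d = direction[gene]
        sets.null_hyp[_mouse_id(gene)] = d
        sets.tg_hyp[_mouse_id(gene)] = flip(d)
        truth.loc[gene, "planted_category"] = "concordant_null"
    for gene in tg_only:
        sets.tg_hyp[_mouse_id(gene)] = direction[gene]
        truth.loc[gene, "planted_category"] = "tg_only"
    for gene in opposite:
        sets.null_hyp[_mouse_id(gene)] = flip(direction[gene])
        truth.loc[gene, "planted_category"] = "opposite_null_or_like_tg"
    for gene in other_region:
        target = sets.cer if rng.random() < 0.5 else sets.amy
        target[_mouse_id(gene)] = direction[gene]
        truth.loc[gene, "planted_category"] = "other_region"
    remaining_de = truth.index[(truth["true_de"]) & (truth["planted_category"] == "none")]
    truth.loc[remaining_de, "planted_category"] = "unique_rat"
    return sets


def simulate_ortholog_map(
    genes: Sequence[str], dropout_rate: float = 0.0, seed: int = 0
) -> OrthologMap:
    """1:1 rat->mouse map dropping each gene independently at dropout_rate."""
    if not 0.0 <= dropout_rate <= 1.0:
        raise ValueError("dropout_rate must lie in [0, 1]")
    if len(set(genes)) != len(genes):
        raise ValueError("gene identifiers must be unique")
    rng = _stream(seed, "ortholog_map")
    keep = rng.random(len(genes)) >= dropout_rate
    return OrthologMap({g: _mouse_id(g) for g, k in zip(genes, keep) if k})


def simulate_validation_panel(
    candidates: Sequence[tuple[str, str, str]],
    config: SimulationConfig,
) -> tuple[list[ValidationRecord], list[str]]:
    """Build a validation panel with planted outcome labels.

    ``candidates`` are (gene, rodent_category, rodent_direction) triples,
    with categories in {common_rat_mouse, unique_rat, unique_mouse}. Each
    record's outcome is drawn from validation_label_proportions and its
    detection/significance/direction fields are constructed to realise that
    label. Returns the records together with the parallel planted labels.
    """
    rng = _stream(config.seed, "validation_panel")
    labels = list(VALIDATION_LABELS)
    probs = np.array([config.validation_label_proportions.get(l, 0.0) for l in labels])
    records: list[ValidationRecord] = []
    planted: list[str] = []
    for gene, category, direction in candidates:
        label = labels[int(rng.choice(len(labels), p=probs))]
        rel = None
        if label == "predicted_direction":
            human, det_case, det_ctrl, sig = direction, True, True, True
            rel = float(2.0 ** (0.5 if direction == "up" else -0.5))
        elif label == "opposite_direction":
            human = "down" if direction == "up" else "up"
            det_case, det_ctrl, sig = True, True, True
            rel = float(2.0 ** (0.5 if human == "up" else -0.5))
        elif label == "undetectable_in_case":
            human, det_case, det_ctrl, sig = "none", False, True, False
        elif label == "not_expressed":
            human, det_case, det_ctrl, sig = "none", False, False, False
        else:  # not_significant
            human, det_case, det_ctrl, sig = "none", True, True, False
        records.append(
            ValidationRecord(
                gene=gene,
                rodent_category=category,
                rodent_direction=direction,
                detected_case=det_case,
                detected_control=det_ctrl,
                significant=sig,
                human_direction=human,
                relative_expression=rel,
            )
        )
        planted.append(label)
    return records, planted


def simulate_reads(
    model: GeneModel,
    target_counts: CountMatrix,
    read_length: int = 100,
    seed: int = 0,
) -> dict[str, list[AlignedRead]]:
    """Place reads wholly inside each gene's exon union to hit target counts.

    Each read is a single contiguous interval of ``read_length`` bases that
    fits inside one merged exon-union interval, so union-exon counting of
    the output reproduces ``target_counts`` exactly whenever genes do not
    overlap. Raises ValueError naming any target gene whose exon union
    cannot hold a read.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    rng = _stream(seed, "reads")
    placements: dict[str, tuple[np.ndarray, list[GenomicInterval]]] = {}
    for gene in target_counts.gene_ids:
        if gene not in model:
            raise ValueError(f"gene {gene} missing from the gene model")
        fits = [iv for iv in model.exons(gene) if len(iv) >= read_length]
        if not fits:
            raise ValueError(
                f"gene {gene}: exon union has no interval of length >= {read_length}"
            )
        weights = np.array([len(iv) - read_length + 1 for iv in fits], dtype=float)
        placements[gene] = (weights / weights.sum(), fits)

    reads: dict[str, list[AlignedRead]] = {}
    for sample in target_counts.sample_ids:
        sample_reads: list[AlignedRead] = []
        for gene in target_counts.gene_ids:
            k = int(target_counts.counts.loc[gene, sample])
            if k == 0:
                continue
            probs, fits = placements[gene]
            choices = rng.choice(len(fits), size=k, p=probs)
            for r, c in enumerate(choices):
                iv = fits[c]
                start = int(rng.integers(iv.start, iv.end - read_length + 1))
                sample_reads.append(
                    AlignedRead(
                        f"{sample}:{gene}:{r}",
                        GenomicInterval(iv.chrom, start, start + read_length, iv.strand),
                    )
                )
        reads[sample] = sample_reads
    return reads
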