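"""Cross-species concordance classification of DE genes.

Each rat DE gene (with its direction) is compared, through an ortholog map,
against four mouse reference sets: hypothalamus genes altered in the
loss-of-function NULL model, hypothalamus genes altered in the
gain-of-function TG (MeCP2-overexpressing) model, and genes reported
altered in cerebellum (CER) or amygdala (AMY). The decision tree:

1. present in NULL or TG hypothalamus sets -> ``shared_hyp``, annotated as
   concordant_null (direction matches NULL), tg_only (TG membership only),
   opposite_both (contradicts NULL and the TG-implied expectation) or
   opposite_null_or_like_tg;
2. else present in CER or AMY -> ``shared_other_region``;
3. else -> ``unique_rat``.

The TG-implied expectation for a loss-of-function comparison is the
opposite of the TG direction (a gene that goes up with excess MeCP2 — a
MeCP2-"activated" gene — is expected down without it). ``regulation_class``
is set to activated (NULL down, TG up) or repressed (NULL up, TG down)
when both memberships determine it.

The summary table counts, per rat direction and in a grand-total row, the
shared/other-region/unique partition together with the TG-only, opposite
and opposite-both sub-annotations of the shared column, and expresses each
grand-total column as a percentage of all classified genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "ReferenceSets",
    "OrthologMap",
    "ClassifiedGene",
    "map_orthologs",
    "classify_gene",
    "classify_genes",
    "summarize_concordance",
    "SUMMARY_COLUMNS",
]

DIRECTIONS = ("up", "down")
REFERENCE_MODELS = ("NULL_HYP", "TG_HYP", "CER", "AMY")
PRIMARY_CATEGORIES = ("shared_hyp", "shared_other_region", "unique_rat")
ANNOTATIONS = (
    "concordant_null",
    "tg_only",
    "opposite_null_or_like_tg",
    "opposite_both",
    "none",
)
SUMMARY_COLUMNS = (
    "total",
    "common",
    "tg_only",
    "opposite",
    "opposite_both",
    "other_region",
    "unique",
)


def _check_direction(direction: str, what: str) -> None:
    if direction not in DIRECTIONS:
        raise ValueError(f"invalid {what} direction token {direction!r}")


@dataclass
class ReferenceSets:
    """Mouse altered-gene sets: gene -> direction maps for NULL_HYP, TG_HYP, CER, AMY."""

    null_hyp: dict[str, str] = field(default_factory=dict)
    tg_hyp: dict[str, str] = field(default_factory=dict)
    cer: dict[str, str] = field(default_factory=dict)
    amy: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, mapping in self.as_dict().items():
            for gene, direction in mapping.items():
                _check_direction(direction, f"{name}[{gene}]")

    def as_dict(self) -> dict[str, dict[str, str]]:
        return {
            "NULL_HYP": self.null_hyp,
            "TG_HYP": self.tg_hyp,
            "CER": self.cer,
            "AMY": self.amy,
        }

    def to_tsv(self, path) -> None:
        rows = [
            {"gene": g, "model": model, "direction": d}
            for model, mapping in self.as_dict().items()
            for g, d in sorted(mapping.items())
        ]
        pd.DataFrame(rows, columns=["gene", "model", "direction"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "ReferenceSets":
        frame = pd.read_csv(path, sep="\t")
        sets = cls()
        lookup = {
            "NULL_HYP": sets.null_hyp,
            "TG_HYP": sets.tg_hyp,
            "CER": sets.cer,
            "AMY": sets.amy,
        }
        for row in frame.itertuples(index=False):
            if row.model not in lookup:
                raise ValueError(f"unknown reference model {row.model!r}")
            _check_direction(row.direction, row.model)
            lookup[row.model][row.gene] = row.direction
        return sets


@dataclass
class OrthologMap:
    """Partial 1:1 rat-to-mouse gene identifier map (injective)."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        targets = list(self.mapping.values())
        if len(set(targets)) != len(targets):
            raise ValueError("ortholog map must be injective (1:1)")

    def get(self, rat_gene: str) -> str | None:
        return self.mapping.get(rat_gene)

    def __len__(self) -> int:
        return len(self.mapping)

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            sorted(self.mapping.items()), columns=["rat_gene", "mouse_gene"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "OrthologMap":
        frame = pd.read_csv(path, sep="\t")
        return cls(dict(zip(frame["rat_gene"], frame["mouse_gene"])))


@dataclass(frozen=True)
class ClassifiedGene:
    gene: str
    rat_direction: str
    primary_category: str
    annotation: str = "none"
    regulation_class: str = "none"

    def __post_init__(self) -> None:
        _check_direction(self.rat_direction, "rat")
        if self.primary_category not in PRIMARY_CATEGORIES:
            raise ValueError(f"invalid primary category {self.primary_category!r}")
        if self.annotation not in ANNOTATIONS:
            raise ValueError(f"invalid annotation {self.annotation!r}")
        if self.annotation != "none" and self.primary_category != "shared_hyp":
            raise ValueError("annotations apply only to shared_hyp genes")


def map_orthologs(
    rat_genes: Sequence[str], ortholog_map: OrthologMap
) -> tuple[list[tuple[str, str]], list[str]]:
    """Partition rat genes into (rat, mouse) mapped pairs and an unmapped list."""
    mapped, unmapped = [], []
    for gene in rat_genes:
        target = ortholog_map.get(gene)
        if target is None:
            unmapped.append(gene)
        else:
            mapped.append((gene, target))
    return mapped, unmapped


def classify_gene(
    gene: str,
    rat_direction: str,
    null_dir: str | None = None,
    tg_dir: str | None = None,
    in_cer: bool = False,
    in_amy: bool = False,
) -> ClassifiedGene:
    """Classify one rat DE gene against the mouse reference memberships."""
    _check_direction(rat_direction, "rat")
    for d, what in ((null_dir, "NULL"), (tg_dir, "TG")):
        if d is not None:
            _check_direction(d, what)

    regulation = "none"
    if null_dir is not None and tg_dir is not None:
        if null_dir == "down" and tg_dir == "up":
            regulation = "activated"
        elif null_dir == "up" and tg_dir == "down":
            regulation = "repressed"

    if null_dir is not None or tg_dir is not None:
        if null_dir is not None and rat_direction == null_dir:
            annotation = "concordant_null"
        elif null_dir is None:
            annotation = "tg_only"
        else:
            # rat direction contradicts NULL; the TG-implied expectation for a
            # loss-of-function comparison is the opposite of the TG direction
            tg_implied = None if tg_dir is None else ("down" if tg_dir == "up" else "up")
            if tg_implied is not None and rat_direction != tg_implied:
                annotation = "opposite_both"
            else:
                annotation = "opposite_null_or_like_tg"
        return ClassifiedGene(gene, rat_direction, "shared_hyp", annotation, regulation)
    if in_cer or in_amy:
        return ClassifiedGene(gene, rat_direction, "shared_other_region")
    return ClassifiedGene(gene, rat_direction, "unique_rat")


def classify_genes(
    rat_de: Mapping[str, str],
    references: ReferenceSets,
    ortholog_map: OrthologMap | None = None,
) -> tuple[list[ClassifiedGene], list[str]]:
    """Classify every rat DE gene (gene -> direction map).

    Genes without a mouse ortholog are classified ``unique_rat`` and also
    returned separately as a diagnostic list.
    """
    classified: list[ClassifiedGene] = []
    unmapped: list[str] = []
    for gene, direction in rat_de.items():
        mouse = gene if ortholog_map is None else ortholog_map.get(gene)
        if mouse is None:
            unmapped.append(gene)
            classified.append(ClassifiedGene(gene, direction, "unique_rat"))
            continue
        classified.append(
            classify_gene(
                gene,
                direction,
                null_dir=references.null_hyp.get(mouse),
                tg_dir=references.tg_hyp.get(mouse),
                in_cer=mouse in references.cer,
                in_amy=mouse in references.amy,
            )
        )
    return classified, unmapped


def summarize_concordance(classified: Iterable[ClassifiedGene]) -> pd.DataFrame:
    """Tally classifications into the summary table.

    Rows ``down``, ``up``, ``total`` and ``percent_of_total``; columns
    ``total / common / tg_only / opposite / opposite_both / other_region /
    unique``. ``common`` counts all shared-hypothalamus genes; tg_only,
    opposite and opposite_both are sub-annotations within that column, so
    common + other_region + unique == total in every count row. Percentages
    are 100 * grand-total cell / grand total, to two decimals (0 for an
    empty input).
    """
    counts = pd.DataFrame(
        0, index=["down", "up", "total"], columns=list(SUMMARY_COLUMNS), dtype=float
    )
    for cg in classified:
        row = cg.rat_direction
        counts.loc[row, "total"] += 1
        if cg.primary_category == "shared_hyp":
            counts.loc[row, "common"] += 1
            if cg.annotation == "tg_only":
                counts.loc[row, "tg_only"] += 1
            elif cg.annotation == "opposite_null_or_like_tg":
                counts.loc[row, "opposite"] += 1
            elif cg.annotation == "opposite_both":
                counts.loc[row, "opposite_both"] += 1
        elif cg.primary_category == "shared_other_region":
            counts.loc[row, "other_region"] += 1
        else:
            counts.loc[row, "unique"] += 1
    counts.loc["total"] = counts.loc[["down", "up"]].sum()
    grand = counts.loc["total", "total"]
    if grand > 0:
        percent = (100.0 * counts.loc["total"] / grand).round(2)
    else:
        percent = pd.Series(0.0, index=counts.columns)
    counts.loc["percent_of_total"] = percent
    return counts
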