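"""Worked-example data: published cross-species concordance tallies and the
human RTT-brain QPCR validation panel.

Two small datasets ship with the package so the classification and
validation logic can be exercised against published numbers without any
simulation:

- the grand summary of a rat hypothalamus DE experiment (1,268 genes)
  compared against mouse NULL/TG hypothalamus and other-region reference
  sets, as per-direction cell counts;
- the enumerated portion of an 82-gene human cortex QPCR panel (the 25
  genes with significant case/control calls, given by name), plus
  synthetic filler records reproducing the published composition of the
  remaining outcome groups (undetectable in case, not significant, not
  expressed), whose gene names are placeholders, not published symbols.
"""

from __future__ import annotations

from .concordance import ClassifiedGene
from .validation import ValidationRecord

__all__ = [
    "CONCORDANCE_SUMMARY_CELLS",
    "concordance_example_genes",
    "qpcr_panel_enumerated",
    "qpcr_panel_full",
]

# Per-direction cell counts of the published rat-vs-mouse comparison.
# "common" counts all shared-hypothalamus genes; tg_only / opposite /
# opposite_both are sub-annotations within that column, so
# common + other_region + unique == total per direction.
CONCORDANCE_SUMMARY_CELLS: dict[str, dict[str, int]] = {
    "down": {
        "total": 638,
        "common": 397,
        "tg_only": 29,
        "opposite": 4,
        "opposite_both": 0,
        "other_region": 16,
        "unique": 225,
    },
    "up": {
        "total": 630,
        "common": 211,
        "tg_only": 32,
        "opposite": 22,
        "opposite_both": 1,
        "other_region": 50,
        "unique": 369,
    },
}


def concordance_example_genes() -> list[ClassifiedGene]:
    """Expand the published summary cells into per-gene classifications.

    Gene identifiers are positional placeholders; only the category and
    direction tallies carry information.
    """
    genes: list[ClassifiedGene] = []

    def add(n: int, direction: str, primary: str, annotation: str = "none") -> None:
        start = len(genes)
        for i in range(n):
            genes.append(
                ClassifiedGene(
                    f"{direction}_{primary}_{annotation}_{start + i:04d}",
                    direction,
                    primary,
                    annotation,
                )
            )

    for direction, cells in CONCORDANCE_SUMMARY_CELLS.items():
        concordant = (
            cells["common"]
            - cells["tg_only"]
            - cells["opposite"]
            - cells["opposite_both"]
        )
        add(concordant, direction, "shared_hyp", "concordant_null")
        add(cells["tg_only"], direction, "shared_hyp", "tg_only")
        add(cells["opposite"], direction, "shared_hyp", "opposite_null_or_like_tg")
        add(cells["opposite_both"], direction, "shared_hyp", "opposite_both")
        add(cells["other_region"], direction, "shared_other_region")
        add(cells["unique"], direction, "unique_rat")
    return genes


# The 25 enumerated panel genes with a significant human case/control call:
# (gene, rodent category, rodent direction, human direction).
_PANEL_PREDICTED = [
    ("NEXN", "common_rat_mouse", "up", "up"),
    ("TSHZ3", "common_rat_mouse", "up", "up"),
    ("STEAP2", "common_rat_mouse", "up", "up"),
    ("GLIS3", "unique_rat", "up", "up"),
    ("TMEM52", "unique_rat", "up", "up"),
    ("GPATCH4", "unique_rat", "up", "up"),
    ("GUCA2A", "unique_mouse", "up", "up"),
    ("IFNA6", "unique_mouse", "up", "up"),
    ("SUN5", "unique_mouse", "up", "up"),
    ("FAM60A", "unique_mouse", "up", "up"),
    ("CLSTN2", "unique_mouse", "up", "up"),
]
_PANEL_OPPOSITE = [
    ("GAST", "common_rat_mouse", "down", "up"),
    ("MMP14", "common_rat_mouse", "down", "up"),
    ("NXPH4", "common_rat_mouse", "down", "up"),
    ("HTR1A", "common_rat_mouse", "down", "up"),
    ("VGF", "common_rat_mouse", "down", "up"),
    ("MEF2C", "common_rat_mouse", "up", "down"),
    ("WISP1", "unique_rat", "down", "up"),
    ("TRIM58", "unique_rat", "down", "up"),
    ("MUC20", "unique_rat", "down", "up"),
    ("F12", "unique_rat", "down", "up"),
    ("SSX9", "unique_mouse", "down", "up"),
    ("GPR4", "unique_mouse", "down", "up"),
    ("CHRNA6", "unique_mouse", "down", "up"),
    ("HS6ST3", "unique_mouse", "up", "down"),
]


def qpcr_panel_enumerated() -> list[ValidationRecord]:
    """The 25 enumerated panel genes (significant human case/control calls)."""
    return [
        ValidationRecord(
            gene=gene,
            rodent_category=category,
            rodent_direction=rodent_dir,
            detected_case=True,
            detected_control=True,
            significant=True,
            human_direction=human_dir,
        )
        for gene, category, rodent_dir, human_dir in _PANEL_PREDICTED + _PANEL_OPPOSITE
    ]


def qpcr_panel_full() -> list[ValidationRecord]:
    """The full 82-gene panel composition.

    The 25 significant genes are the published symbols; the remaining 57
    records are synthetic stand-ins reproducing the published outcome-group
    sizes — 18 detected in control but not case (8 of them in the
    down common category), 33 detected but not significantly altered, and
    6 expressed in neither group.
    """
    records = qpcr_panel_enumerated()
    undetectable_categories = (
        [("common_rat_mouse", "down")] * 8
        + [("common_rat_mouse", "up")] * 3
        + [("unique_rat", "down")] * 2
        + [("unique_rat", "up")] * 2
        + [("unique_mouse", "down")] * 2
        + [("unique_mouse", "up")] * 1
    )
    for i, (category, direction) in enumerate(undetectable_categories):
        records.append(
            ValidationRecord(
                gene=f"SYN_UNDETECTABLE_{i:02d}",
                rodent_category=category,
                rodent_direction=direction,
                detected_case=False,
                detected_control=True,
                significant=False,
            )
        )
    for i in range(33):
        records.append(
            ValidationRecord(
                gene=f"SYN_NOT_SIGNIFICANT_{i:02d}",
                rodent_category=("common_rat_mouse", "unique_rat", "unique_mouse")[i % 3],
                rodent_direction=("up", "down")[i % 2],
                detected_case=True,
                detected_control=True,
                significant=False,
            )
        )
    for i in range(6):
        records.append(
            ValidationRecord(
                gene=f"SYN_NOT_EXPRESSED_{i:02d}",
                rodent_category=("common_rat_mouse", "unique_rat", "unique_mouse")[i % 3],
                rodent_direction=("up", "down")[i % 2],
                detected_case=False,
                detected_control=False,
                significant=False,
            )
        )
    assert len(records) == 82
    return records
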