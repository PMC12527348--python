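"""Read-assignment QC, gene-level deduplication, molecule counts, tail filters.

Nanopore reads can align to more than one transcript; a read id therefore
appears once ("unique"), twice ("duplicated") or three or more times
("multiple") within a sample. At the transcript level those duplicates are
usually left in place (which transcript the molecule came from cannot be
resolved), but at the gene level a read contributing the same tail length
twice within one gene would double-count a molecule, so exactly one copy per
(sample, read, gene, length) is kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

LEVELS = ("transcript_id", "gene_id")
GROUPINGS = ("sample_name", "group")


@dataclass
class DuplicationSummary:
    """Counts of read-to-transcript assignment multiplicity, per sample.

    ``unique + duplicated + multiple`` equals the number of distinct
    (sample_name, read_id) pairs.
    """

    unique: int
    duplicated: int
    multiple: int
    read_ids: dict[str, list[tuple[str, str]]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"class": ["unique", "duplicated", "multiple"],
             "count": [self.unique, self.duplicated, self.multiple]}
        )


def classify_read_assignments(polya: pd.DataFrame) -> DuplicationSummary:
    """Classify each (sample, read) by how many alignments it contributed."""
    if len(polya) == 0:
        raise ValidationError("poly(A) table is empty")
    counts = polya.groupby(["sample_name", "read_id"], sort=False).size()
    classes = {"unique": counts == 1, "duplicated": counts == 2, "multiple": counts >= 3}
    read_ids = {
        name: sorted(counts.index[mask].tolist()) for name, mask in classes.items()
    }
    return DuplicationSummary(
        unique=int(classes["unique"].sum()),
        duplicated=int(classes["duplicated"].sum()),
        multiple=int(classes["multiple"].sum()),
        read_ids=read_ids,
    )


def drop_gene_level_duplicates(polya: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep one record per (sample, read, gene, tail length); report removals.

    Records that differ in gene or tail length are all kept — only exact
    within-gene repeats of the same molecule's estimate are collapsed. The
    first record in input order survives, so the operation is deterministic
    and idempotent.
    """
    if "gene_id" not in polya.columns:
        raise SchemaError("gene_id column required; run gene annotation first")
    keep = ~polya.duplicated(
        subset=["sample_name", "read_id", "gene_id", "polyA_length"], keep="first"
    )
    # rows with missing gene_id are never collapsed with one another
    keep |= polya["gene_id"].isna()
    removed = int((~keep).sum())
    if removed:
        logger.info("removed %d within-gene duplicate records", removed)
    return polya[keep].reset_index(drop=True), removed


def count_molecules(
    polya: pd.DataFrame,
    level: str = "transcript_id",
    grouping: str = "group",
) -> pd.DataFrame:
    """Count molecules and summarize tail lengths per feature and grouping value.

    Returns one row per (feature_id, grouping_value) with ``count``,
    ``avg_polyA_length`` and ``median_polyA_length``. Records with a missing
    feature id (unannotated transcripts at gene level) are excluded and the
    exclusion is logged.
    """
    if level not in polya.columns:
        raise SchemaError(f"level column {level!r} not present in the poly(A) table")
    if grouping not in polya.columns:
        raise SchemaError(f"grouping column {grouping!r} not present")
    usable = polya[polya[level].notna()]
    n_excluded = len(polya) - len(usable)
    if n_excluded:
        logger.info("excluded %d records with missing %s", n_excluded, level)
    out = (
        usable.groupby([level, grouping], sort=True)["polyA_length"]
        .agg(count="size", avg_polyA_length="mean", median_polyA_length="median")
        .reset_index()
        .rename(columns={level: "feature_id", grouping: "grouping_value"})
    )
    out["count"] = out["count"].astype(int)
    return out


def filter_min_tails(
    polya: pd.DataFrame,
    level: str = "gene_id",
    min_tails: int = 10,
    scope: str = "per_group",
) -> pd.DataFrame:
    """Drop features with too few poly(A) tails to support a comparison.

    scope="per_group" removes a feature if *any* group has fewer than
    ``min_tails`` tails for it; scope="total" uses the feature's overall tail
    count. Features with a missing level value are dropped (not testable at
    that level). Default threshold 10.
    """
    if min_tails < 1:
        raise ValidationError("min_tails must be >= 1")
    if scope not in ("per_group", "total"):
        raise ValidationError(f"unknown scope {scope!r}")
    if level not in polya.columns:
        raise SchemaError(f"level column {level!r} not present")
    usable = polya[polya[level].notna()]
    if scope == "total":
        counts = usable.groupby(level).size()
        ok = counts.index[counts >= min_tails]
    else:
        per_group = usable.groupby([level, "group"]).size().unstack(fill_value=0)
        ok = per_group.index[(per_group >= min_tails).all(axis=1)]
    return usable[usable[level].isin(set(ok))].reset_index(drop=True)
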