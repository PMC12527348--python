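"""Transcript→gene mapping from GTF and gene-id annotation of the poly(A) table.

The pipeline works in transcriptome space: each alignment's reference name is
a transcript id, and gene-level analyses need the transcript→gene relation
from the annotation the transcriptome was built against (e.g. a stringtie
GTF). Only column 9 attributes are consulted; both the quoted
(``transcript_id "t1";``) and unquoted (``transcript_id t1;``) attribute
dialects are accepted because stringtie/gffread outputs vary.
"""

from __future__ import annotations

import logging
import re

import pandas as pd

from .errors import ConflictError, SchemaError, ValidationError

logger = logging.getLogger(__name__)

_ATTR_RE_TEMPLATE = r'(?:^|;)\s*{attr}\s+"?([^";]+)"?\s*(?:;|$)'


def parse_gtf_transcript_gene_map(
    gtf_path: str,
    transcript_attr: str = "transcript_id",
    gene_attr: str = "gene_id",
) -> dict[str, str]:
    """Build a transcript→gene map from the attribute column of a GTF file.

    Every line carrying both attributes contributes one pair; repeats of the
    same pair (exon lines etc.) collapse. A transcript mapped to two different
    genes raises :class:`ConflictError` listing the offenders.
    """
    tx_re = re.compile(_ATTR_RE_TEMPLATE.format(attr=re.escape(transcript_attr)))
    gene_re = re.compile(_ATTR_RE_TEMPLATE.format(attr=re.escape(gene_attr)))
    mapping: dict[str, str] = {}
    conflicts: dict[str, set[str]] = {}
    saw_tx_attr = saw_gene_attr = False
    with open(gtf_path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 9:
                continue
            attrs = cols[8]
            tx_m = tx_re.search(attrs)
            gene_m = gene_re.search(attrs)
            saw_tx_attr = saw_tx_attr or tx_m is not None
            saw_gene_attr = saw_gene_attr or gene_m is not None
            if tx_m is None or gene_m is None:
                continue
            tx, gene = tx_m.group(1).strip(), gene_m.group(1).strip()
            if not tx or not gene:
                continue
            prev = mapping.get(tx)
            if prev is not None and prev != gene:
                conflicts.setdefault(tx, {prev}).add(gene)
            else:
                mapping[tx] = gene
    if not saw_tx_attr:
        raise ValidationError(
            f"attribute {transcript_attr!r} not found on any line of {gtf_path}"
        )
    if not saw_gene_attr:
        raise ValidationError(
            f"attribute {gene_attr!r} not found on any line of {gtf_path}"
        )
    if conflicts:
        detail = "; ".join(
            f"{tx} -> {{{', '.join(sorted(genes))}}}" for tx, genes in sorted(conflicts.items())
        )
        raise ConflictError(f"transcript(s) mapped to multiple genes: {detail}")
    if not mapping:
        raise ValidationError(f"no transcript/gene pairs parsed from {gtf_path}")
    return mapping


def attach_gene_ids(polya: pd.DataFrame, mapping: dict[str, str]) -> pd.DataFrame:
    """Attach a ``gene_id`` column by transcript id, keeping unmatched rows.

    Rows whose transcript has no map entry keep a missing ``gene_id`` (they
    stay available for transcript-level analysis); the unmatched count is
    logged. Row count and order are unchanged.
    """
    if len(polya) == 0:
        raise ValidationError("poly(A) table is empty")
    if "transcript_id" not in polya.columns:
        raise SchemaError("poly(A) table has no transcript_id column")
    out = polya.copy()
    out["gene_id"] = out["transcript_id"].map(mapping)
    n_unmatched = int(out["gene_id"].isna().sum())
    if n_unmatched:
        logger.warning(
            "%d of %d records have no gene for their transcript; gene_id left missing",
            n_unmatched, len(out),
        )
    return out


def unmatched_count(polya: pd.DataFrame) -> int:
    """Number of records whose gene_id is missing after annotation."""
    if "gene_id" not in polya.columns:
        raise SchemaError("poly(A) table has no gene_id column")
    return int(polya["gene_id"].isna().sum())
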