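"""Experiment design I/O and per-read poly(A) extraction from tagged BAMs.

The entry point of every analysis is a *samples table* (one BAM per row with a
sample name and a group label) and the BAM files themselves, which must carry
an integer auxiliary tag holding the basecaller's per-read poly(A) tail-length
estimate (dorado writes ``pt:i:<n>`` when run with ``--estimate-poly-a``).
``extract_polya`` turns those into a single tidy table with one row per
retained alignment — the central exchange format of the package.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import pandas as pd
import pysam

from .errors import FormatError, SchemaError, ValidationError

#: Canonical column order of the tidy per-read table.
POLYA_COLUMNS = ["read_id", "transcript_id", "polyA_length", "sample_name", "group"]

SAMPLES_COLUMNS = ["bam_path", "sample_name", "group"]

#: Alignment-filter policies for extract_polya.
POLICIES = ("primary", "all")

#: Reasons an alignment can be skipped, in reporting order.
SKIP_REASONS = ("unmapped", "filtered_by_policy", "tag_missing", "tag_nonpositive")


class PolyAIOError(OSError):
    """I/O failure while reading a BAM, naming the offending file."""


@dataclass
class ExtractionReport:
    """Provenance of an extraction run: what was scanned and why rows were skipped.

    Invariant: ``emitted + sum(skipped.values()) == scanned`` for every run.
    """

    tag_name: str
    policy: str
    scanned: int = 0
    emitted: int = 0
    skipped: dict[str, int] = field(
        default_factory=lambda: {reason: 0 for reason in SKIP_REASONS}
    )

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reason": "emitted", "count": self.emitted}]
        rows += [{"reason": r, "count": self.skipped[r]} for r in SKIP_REASONS]
        rows.append({"reason": "scanned", "count": self.scanned})
        return pd.DataFrame(rows)


def validate_samples_table(samples: pd.DataFrame, check_paths: bool = True) -> pd.DataFrame:
    """Validate an in-memory samples table and return it with canonical columns."""
    lower = {c.lower(): c for c in samples.columns}
    missing = [c for c in SAMPLES_COLUMNS if c not in lower]
    if missing:
        raise SchemaError(
            f"samples table is missing required column(s): {', '.join(missing)}"
        )
    out = samples.rename(columns={lower[c]: c for c in SAMPLES_COLUMNS})
    out = out[SAMPLES_COLUMNS].copy()
    out["bam_path"] = out["bam_path"].astype(str)
    out["sample_name"] = out["sample_name"].astype(str)
    out["group"] = out["group"].astype(str)
    if len(out) == 0:
        raise ValidationError("samples table has no rows")
    dups = out["sample_name"][out["sample_name"].duplicated()].unique()
    if len(dups):
        raise ValidationError(f"duplicate sample_name(s): {', '.join(dups)}")
    if check_paths:
        for p in out["bam_path"]:
            if not os.path.exists(p):
                raise ValidationError(f"BAM path does not exist: {p}")
    return out.reset_index(drop=True)


def read_samples_table(path: str, dialect: str | None = None, check_paths: bool = True) -> pd.DataFrame:
    """Read the experiment design (CSV or TSV) mapping BAM → sample → group.

    Parameters
    ----------
    path
        CSV/TSV file with header columns ``bam_path,sample_name,group``
        (case-insensitive, any order).
    dialect
        ``"csv"`` or ``"tsv"``; inferred from the extension when omitted.
    check_paths
        Verify that every ``bam_path`` exists.
    """
    if dialect is None:
        dialect = "tsv" if str(path).endswith((".tsv", ".txt")) else "csv"
    if dialect not in ("csv", "tsv"):
        raise ValidationError(f"unknown samples-table dialect: {dialect!r}")
    sep = "\t" if dialect == "tsv" else ","
    try:
        df = pd.read_csv(path, sep=sep, dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise ValidationError(f"samples table is empty: {path}") from exc
    return validate_samples_table(df, check_paths=check_paths)


def group_sizes(samples: pd.DataFrame) -> pd.Series:
    """Number of samples per group (reported when the design is loaded)."""
    return samples.groupby("group", sort=True)["sample_name"].count()


def _extract_one_bam(
    bam_path: str,
    sample_name: str,
    group: str,
    tag_name: str,
    policy: str,
    report: ExtractionReport,
) -> list[tuple]:
    rows: list[tuple] = []
    try:
        bam = pysam.AlignmentFile(bam_path, "rb", check_sq=False)
    except (OSError, ValueError) as exc:
        raise PolyAIOError(f"cannot read BAM file {bam_path}: {exc}") from exc
    with bam:
        for aln in bam.fetch(until_eof=True):
            report.scanned += 1
            if aln.is_unmapped:
                report.skipped["unmapped"] += 1
                continue
            if policy == "primary" and (aln.is_secondary or aln.is_supplementary):
                report.skipped["filtered_by_policy"] += 1
                continue
            if not aln.has_tag(tag_name):
                report.skipped["tag_missing"] += 1
                continue
            value = aln.get_tag(tag_name)
            if isinstance(value, float) and not float(value).is_integer():
                raise FormatError(
                    f"tag {tag_name} on read {aln.query_name} in {bam_path} "
                    f"is not an integer: {value!r}"
                )
            if not isinstance(value, (int, float)):
                raise FormatError(
                    f"tag {tag_name} on read {aln.query_name} in {bam_path} "
                    f"is not numeric: {value!r}"
                )
            length = int(value)
            if length < 1:
                report.skipped["tag_nonpositive"] += 1
                continue
            rows.append((aln.query_name, aln.reference_name, length, sample_name, group))
            report.emitted += 1
    return rows


def extract_polya(
    samples: pd.DataFrame,
    tag_name: str = "pt",
    policy: str = "primary",
) -> tuple[pd.DataFrame, ExtractionReport]:
    """Extract one poly(A) record per retained alignment across all samples.

    Parameters
    ----------
    samples
        Validated samples table (see :func:`read_samples_table`).
    tag_name
        Two-character BAM auxiliary tag holding the integer tail estimate.
        Default ``"pt"``, the tag dorado writes.
    policy
        ``"primary"`` keeps primary mapped alignments only (one estimate per
        molecule); ``"all"`` also keeps secondary/supplementary alignments,
        leaving multi-assignment to the QC module.

    Returns
    -------
    (table, report)
        ``table`` has columns ``read_id, transcript_id, polyA_length,
        sample_name, group`` in stable order (by samples-table row, then BAM
        record order). ``report`` accounts for every scanned alignment.
    """
    if policy not in POLICIES:
        raise ValidationError(f"unknown alignment filter policy: {policy!r}")
    if len(tag_name) != 2:
        raise ValidationError(f"tag name must be two characters, got {tag_name!r}")
    samples = validate_samples_table(samples)
    report = ExtractionReport(tag_name=tag_name, policy=policy)
    rows: list[tuple] = []
    for rec in samples.itertuples(index=False):
        rows.extend(
            _extract_one_bam(rec.bam_path, rec.sample_name, rec.group, tag_name, policy, report)
        )
    table = pd.DataFrame(rows, columns=POLYA_COLUMNS)
    table["polyA_length"] = table["polyA_length"].astype(int) if len(table) else table["polyA_length"]
    return table, report


def read_polya_table(path: str) -> pd.DataFrame:
    """Read a tidy poly(A) table written by :func:`write_polya_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "transcript_id": str,
                                            "sample_name": str, "group": str})
    missing = [c for c in POLYA_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"poly(A) table missing column(s): {', '.join(missing)}")
    return df


def write_polya_table(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)
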