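"""Extract per-read poly(A) tail lengths from tagged BAMs and attach genes.

Builds a small synthetic experiment (tagged BAMs + GTF), runs the extraction
and annotation steps, and prints the per-group read counts and median tails.
"""

import tempfile

from polytail import (
    SimulationDesign,
    attach_gene_ids,
    default_references,
    extract_polya,
    parse_gtf_transcript_gene_map,
    simulate_polya_table,
    write_sample_bams,
    write_synthetic_gtf,
)

design = SimulationDesign.two_group(seed=7, n_genes=20, n_affected=4,
                                    shift_nt=-25.0, reads_per_gene_per_sample=20)
polya, truth = simulate_polya_table(design)

with tempfile.TemporaryDirectory() as workdir:
    samples = write_sample_bams(polya, default_references(design), workdir)
    gtf = write_synthetic_gtf(design.transcript_gene_map(), f"{workdir}/tx.gtf")

    table, report = extract_polya(samples, tag_name="pt", policy="primary")
    print(f"scanned {report.scanned} alignments, emitted {report.emitted} records")
    print(f"skipped by reason: {report.skipped}")

    annotated = attach_gene_ids(table, parse_gtf_transcript_gene_map(gtf))
    summary = annotated.groupby("group")["polyA_length"].agg(["size", "median"])
    print(summary)
    # Every alignment carried a valid tag, so emitted == scanned; the HIGH
    # group's median tail is shorter because 4 of 20 genes carry a -25 nt shift.
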