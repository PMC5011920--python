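"""End-to-end stage orchestration behind the command-line interface.

Each ``run_*`` function is a pure-Python entry point that reads standard
files, executes the library stages and writes tabular reports plus a
machine-readable run summary (JSON) capturing every parameter, input
checksum and headline count, so a run can be reproduced from the summary
alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__, akdist, classify, copynum, motifs, regulatory
from .errors import InputError
from .seq_io import (
    NUCLEOTIDE,
    PROTEIN,
    GenomicFeature,
    read_expression_table,
    read_fasta,
    read_gff3,
    read_sequences,
    reverse_complement,
    write_gff3,
)
from .synthetic_data import SimulationConfig, generate_genome, write_dataset

logger = logging.getLogger("histokit")

DEFAULT_UPSTREAM_LEN = 120
DEFAULT_UTR_LEN = 60


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _summary(stage: str, seed: Optional[int], inputs: dict, parameters: dict, results: dict) -> dict:
    return {
        "tool": "histokit",
        "version": __version__,
        "stage": stage,
        "seed": seed,
        "inputs": {name: {"path": str(p), "sha256": _sha256(p)} for name, p in inputs.items()},
        "parameters": parameters,
        "results": results,
    }


def _write_summary(summary: dict, out_dir: Path) -> Path:
    path = out_dir / "summary.json"
    with open(path, "w", newline="\n") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def extract_gene_context(
    genome: str,
    gene: GenomicFeature,
    upstream_len: int = DEFAULT_UPSTREAM_LEN,
    utr_len: int = DEFAULT_UTR_LEN,
) -> tuple[str, str]:
    """(upstream, 3'-UTR) of a coding span, strand-aware, clipped at ends."""
    if gene.strand == "+":
        upstream = genome[max(0, gene.start - upstream_len) : gene.start]
        utr = genome[gene.end : gene.end + utr_len]
    else:
        upstream = reverse_complement(genome[gene.end : gene.end + upstream_len])
        utr = reverse_complement(genome[max(0, gene.start - utr_len) : gene.start])
    return upstream, utr


def _genomic_interval(gene: GenomicFeature, rel_start: int, length: int, region: str) -> tuple:
    """Map a gene-space interval back to genome coordinates.

    ``region`` is 'upstream' (rel_start negative, relative to the ATG) or
    'utr' (rel_start >= 0, relative to the base after the stop codon).
    """
    if region == "upstream":
        anchor_plus = gene.start
        anchor_minus = gene.end
        rel = rel_start
    else:
        anchor_plus = gene.end
        anchor_minus = gene.start
        rel = rel_start
    if gene.strand == "+":
        start = anchor_plus + rel
        return (start, start + length)
    if region == "upstream":
        # gene-space r maps to genome index anchor_minus - 1 - r
        end = anchor_minus - rel
        return (end - length, end)
    start = anchor_minus - rel - length
    return (start, start + length)


def run_annotate(
    genome_path: str | Path,
    proteins_path: str | Path,
    genes_path: str | Path,
    expression_path: Optional[str | Path] = None,
    out_dir: str | Path = ".",
    min_identity: float = classify.DEFAULT_MIN_IDENTITY,
    stability_threshold: float = regulatory.DEFAULT_STABILITY_THRESHOLD,
    stem_loop_consensus: str = regulatory.DEFAULT_STEM_LOOP_CONSENSUS,
    seed: Optional[int] = None,
) -> dict:
    """Classify proteins, scan loci and call replication-dependency.

    Inputs: the genome FASTA, a protein FASTA whose ids match the ``ID``
    attributes of ``gene`` features in the gene-model GFF3 (coding spans),
    and an optional per-stage expression table.  Tandem copies of a gene
    (same ``ID``) are collapsed to their first instance.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genomes = {r.id: r.residues for r in read_fasta(genome_path, NUCLEOTIDE)}
    proteins = read_fasta(proteins_path, PROTEIN)
    features = read_gff3(genes_path)
    expression = read_expression_table(expression_path) if expression_path else []

    genes: dict[str, GenomicFeature] = {}
    for f in features:
        if f.ftype != "gene":
            continue
        gid = f.attr.get("ID")
        if gid and gid not in genes:
            genes[gid] = f

    logger.info("annotate: %d proteins, %d gene models", len(proteins), len(genes))
    refs = classify.load_references()
    calls = [classify.assign_family(p, refs, min_identity=min_identity) for p in proteins]
    class_df = classify.classification_table(calls)
    inv_df = classify.inventory(calls)

    spkk_reports = [motifs.count_spkk(p.residues, protein_id=p.id) for p in proteins]
    profiles, flagged = motifs.protamine_screen(proteins)
    motif_df = motifs.motif_table(spkk_reports, profiles)

    dep_rows = []
    out_features: list[GenomicFeature] = []
    for gid, gene in genes.items():
        if gene.seq_id not in genomes:
            raise InputError(f"gene {gid!r} references unknown sequence {gene.seq_id!r}")
        upstream, utr = extract_gene_context(genomes[gene.seq_id], gene)
        feats = regulatory.compute_utr_features(
            gid, upstream, utr, consensus=stem_loop_consensus
        )
        call = regulatory.call_dependency(feats, expression, stability_threshold)
        sl = feats.stem_loop
        dep_rows.append(
            {
                "gene_id": gid,
                "verdict": call.verdict,
                "tata_hits": len(feats.tata_hits),
                "stem_loop_offset": "" if sl is None else sl.offset_after_stop,
                "stem_mismatches": "" if sl is None else sl.stem_mismatches,
                "stability": "" if sl is None else sl.stability_score,
                "hde_fraction": "" if feats.hde is None else round(feats.hde[1], 3),
                "polyA": "" if feats.polyA is None else feats.polyA,
                "rationale": "; ".join(call.rationale),
            }
        )
        for t in feats.tata_hits:
            s, e = _genomic_interval(gene, t, 6, "upstream")
            out_features.append(
                GenomicFeature(gene.seq_id, s, e, gene.strand, "TATA_box", {"Parent": gid})
            )
        if sl is not None:
            s, e = _genomic_interval(gene, sl.offset_after_stop, regulatory.ELEMENT_LEN, "utr")
            out_features.append(
                GenomicFeature(
                    gene.seq_id, s, e, gene.strand, "stem_loop",
                    {
                        "Parent": gid,
                        "stem_mismatches": str(sl.stem_mismatches),
                        "stability": f"{sl.stability_score:g}",
                    },
                )
            )
        if feats.hde is not None:
            s, e = _genomic_interval(gene, feats.hde[0], regulatory.DEFAULT_HDE_WIDTH, "utr")
            out_features.append(
                GenomicFeature(
                    gene.seq_id, s, e, gene.strand, "HDE",
                    {"Parent": gid, "purine_fraction": f"{feats.hde[1]:.3f}"},
                )
            )
        if feats.polyA is not None:
            s, e = _genomic_interval(gene, feats.polyA, 6, "utr")
            out_features.append(
                GenomicFeature(gene.seq_id, s, e, gene.strand, "polyA_signal", {"Parent": gid})
            )
    # SPKK repeats: protein-coordinate features, attribute-encoded on the locus
    for rep in spkk_reports:
        gene = genes.get(rep.protein_id)
        if gene is None or rep.count == 0:
            continue
        out_features.append(
            GenomicFeature(
                gene.seq_id, gene.start, gene.end, gene.strand, "SPKK_repeat",
                {
                    "Parent": rep.protein_id,
                    "count": str(rep.count),
                    "protein_positions": ",".join(map(str, rep.match_positions)),
                },
            )
        )
    dep_df = pd.DataFrame(dep_rows)

    class_df.to_csv(out / "classification.tsv", sep="\t", index=False, lineterminator="\n")
    inv_df.to_csv(out / "inventory.tsv", sep="\t", index=False, lineterminator="\n")
    motif_df.to_csv(out / "motifs.tsv", sep="\t", index=False, lineterminator="\n")
    dep_df.to_csv(out / "dependency.tsv", sep="\t", index=False, lineterminator="\n")
    lengths = {rid: len(seq) for rid, seq in genomes.items()}
    write_gff3(out_features, out / "features.gff3", seq_lengths=lengths)

    inputs = {"genome": genome_path, "proteins": proteins_path, "gene_models": genes_path}
    if expression_path:
        inputs["expression"] = expression_path
    summary = _summary(
        "annotate",
        seed,
        inputs,
        {
            "min_identity": min_identity,
            "stability_threshold": stability_threshold,
            "stem_loop_consensus": stem_loop_consensus,
            "upstream_len": DEFAULT_UPSTREAM_LEN,
            "utr_len": DEFAULT_UTR_LEN,
        },
        {
            "n_proteins": len(proteins),
            "n_genes": len(genes),
            "inventory": {
                f"{row.family}/{row.variant}" if row.variant else row.family: int(row["count"])
                for _, row in inv_df.iterrows()
                if row["count"]
            },
            "verdicts": dep_df.verdict.value_counts().to_dict() if not dep_df.empty else {},
            "protamine_like": [p.protein_id for p in flagged],
        },
    )
    _write_summary(summary, out)
    return {
        "classification": class_df,
        "inventory": inv_df,
        "motifs": motif_df,
        "dependency": dep_df,
        "features": out_features,
        "summary": summary,
    }


def run_copynum(
    reads_paths: Sequence[str | Path],
    region_path: str | Path,
    out_dir: str | Path = ".",
    k: int = copynum.DEFAULT_K,
    min_multiplicity: int = copynum.DEFAULT_MIN_MULTIPLICITY,
    seed: Optional[int] = None,
) -> dict:
    """k-mer histogram, diploid peak and repeat copy-number estimate."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reads: list[str] = []
    for path in reads_paths:
        reads.extend(r.residues for r in read_sequences(path, NUCLEOTIDE))
    region = read_fasta(region_path, NUCLEOTIDE)[0]
    logger.info("copynum: %d reads, region %s (%d nt), k=%d", len(reads), region.id, len(region), k)
    estimate, hist = copynum.estimate_from_reads(
        reads, region.residues, k=k, min_multiplicity=min_multiplicity, region_id=region.id
    )
    hist.to_frame().to_csv(out / "histogram.tsv", sep="\t", index=False, lineterminator="\n")
    est_df = pd.DataFrame([asdict(estimate)])
    est_df.to_csv(out / "estimate.tsv", sep="\t", index=False, lineterminator="\n")
    summary = _summary(
        "copynum",
        seed,
        {"region": region_path, **{f"reads_{i}": p for i, p in enumerate(reads_paths)}},
        {"k": k, "min_multiplicity": min_multiplicity},
        {"estimate": asdict(estimate), "n_reads": len(reads)},
    )
    _write_summary(summary, out)
    return {"estimate": estimate, "histogram": hist, "summary": summary}


def run_simulate(
    out_dir: str | Path,
    seed: int = 0,
    config_path: Optional[str | Path] = None,
    reads: bool = True,
    **overrides,
) -> dict:
    """Generate a synthetic dataset on disk and report the planted truth."""
    if config_path is not None:
        config = SimulationConfig.from_yaml(config_path, seed=seed, **overrides)
    else:
        config = SimulationConfig(seed=seed, **overrides)
    dataset = generate_genome(config)
    paths = write_dataset(dataset, out_dir, reads=reads)
    logger.info(
        "simulate: genome %d nt, %d genes, cluster x%d",
        len(dataset.genome),
        len(dataset.truth.genes),
        config.cluster_copies,
    )
    summary = _summary(
        "simulate",
        seed,
        {},
        {f: getattr(config, f) for f in ("background_length", "background_gc", "cluster_copies", "read_length", "coverage", "error_rate", "paired")},
        {
            "genome_length": len(dataset.genome),
            "n_genes": len(dataset.truth.genes),
            "cluster_copies": dataset.truth.cluster_copies,
            "outputs": paths,
        },
    )
    _write_summary(summary, Path(out_dir))
    return {"dataset": dataset, "paths": paths, "summary": summary}


def run_distances(
    elements_path: str | Path,
    out_dir: str | Path = ".",
    k: int = akdist.DEFAULT_K,
    linkage: str = "average",
    seed: Optional[int] = None,
) -> dict:
    """Alignment-free distance matrix and dendrogram over short elements."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records = read_fasta(elements_path, NUCLEOTIDE)
    matrix = akdist.all_pairs([(r.id, r.residues) for r in records], k=k)
    dendro = akdist.cluster(matrix, linkage=linkage)
    matrix.to_frame().to_csv(out / "distances.tsv", sep="\t", lineterminator="\n")
    (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
    summary = _summary(
        "distances",
        seed,
        {"elements": elements_path},
        {"k": k, "linkage": linkage},
        {
            "n_elements": len(records),
            "last_to_join": list(dendro.last_to_join()),
            "max_height": dendro.merges[-1][2],
        },
    )
    _write_summary(summary, out)
    return {"matrix": matrix, "dendrogram": dendro, "summary": summary}
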