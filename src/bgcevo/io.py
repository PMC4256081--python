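"""Readers and writers for cluster corpora.

A corpus lives on disk as a JSON manifest listing one entry per cluster.
Each entry points either to a GenBank file (CDS features; domain annotations
as ``/note`` qualifiers of the form ``domain:domain_id|pfam_id|aa_start-aa_end
[|nrps_pks_type|module_index]``) or to a nucleotide FASTA plus an annotation
TSV. The TSV uses one row per gene (empty domain columns) and one row per
domain::

    cluster_id gene_id domain_id pfam_id start end strand nrps_pks_type \
        module_index aa_start aa_end

Writing then re-reading a corpus yields field-identical clusters, and output
is byte-stable for fixed input.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Optional

from Bio import SeqIO

from .model import (
    Corpus,
    DomainAnnotation,
    Gene,
    GeneCluster,
    assign_order_index,
    sort_corpus,
)

TSV_COLUMNS = [
    "cluster_id",
    "gene_id",
    "domain_id",
    "pfam_id",
    "start",
    "end",
    "strand",
    "nrps_pks_type",
    "module_index",
    "aa_start",
    "aa_end",
]


def _opt_int(v: str) -> Optional[int]:
    return int(v) if v not in ("", ".") else None


def _opt_str(v: str) -> Optional[str]:
    return v if v not in ("", ".") else None


# ---------------------------------------------------------------------------
# reading


def read_cluster_set(manifest_path: str | Path) -> Corpus:
    """Read a corpus from a JSON manifest; deterministic order by cluster_id."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise FileNotFoundError(f"manifest not found: {manifest_path}")
    entries = json.loads(manifest_path.read_text())["clusters"]
    base = manifest_path.parent
    corpus: Corpus = []
    for entry in entries:
        if "genbank" in entry:
            corpus.append(_read_genbank_cluster(base / entry["genbank"], entry))
        else:
            corpus.append(
                _read_fasta_tsv_cluster(
                    base / entry["fasta"],
                    base / entry["annotations"],
                    base / entry["proteins"] if "proteins" in entry else None,
                    entry,
                )
            )
    return sort_corpus(corpus)


def _read_genbank_cluster(path: Path, entry: dict) -> GeneCluster:
    if not path.exists():
        raise FileNotFoundError(f"GenBank file not found: {path}")
    record = SeqIO.read(str(path), "genbank")
    genes: list[Gene] = []
    domains: list[DomainAnnotation] = []
    for feat in record.features:
        if feat.type != "CDS":
            continue
        gene_id = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", ["?"]))[0]
        protein = feat.qualifiers.get("translation", [""])[0]
        start = int(feat.location.start)  # Biopython already 0-based
        end = int(feat.location.end)
        strand = 1 if (feat.location.strand or 1) >= 0 else -1
        genes.append(Gene(gene_id, start, end, strand, protein))
        for note in feat.qualifiers.get("note", []):
            if not note.startswith("domain:"):
                continue
            fields = note[len("domain:") :].split("|")
            dom_id, pfam_id, span = fields[0], fields[1], fields[2]
            aa_start, aa_end = (int(x) for x in span.split("-"))
            domains.append(
                DomainAnnotation(
                    domain_id=dom_id,
                    pfam_id=pfam_id,
                    gene_id=gene_id,
                    order_index=0,
                    aa_seq=protein[aa_start:aa_end],
                    nrps_pks_type=fields[3] if len(fields) > 3 and fields[3] else None,
                    module_index=int(fields[4]) if len(fields) > 4 and fields[4] else None,
                    aa_start=aa_start,
                    aa_end=aa_end,
                )
            )
    genes.sort(key=lambda g: g.start)
    return GeneCluster(
        cluster_id=entry.get("cluster_id", record.id),
        organism_id=entry["organism_id"],
        genes=genes,
        domains=assign_order_index(genes, domains),
        sequence=str(record.seq).upper() if len(record.seq) else None,
        class_label=entry.get("class_label", ""),
    )


def _read_fasta_tsv_cluster(
    fasta: Path, annotations: Path, proteins: Optional[Path], entry: dict
) -> GeneCluster:
    for p in (fasta, annotations):
        if not p.exists():
            raise FileNotFoundError(f"input file not found: {p}")
    record = SeqIO.read(str(fasta), "fasta")
    prot_by_gene: dict[str, str] = {}
    if proteins is not None and proteins.exists():
        for rec in SeqIO.parse(str(proteins), "fasta"):
            _, gene_id = rec.id.rsplit("|", 1)
            prot_by_gene[gene_id] = str(rec.seq)
    genes: list[Gene] = []
    dom_rows: list[dict] = []
    with open(annotations, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            if row["domain_id"] in ("", "."):
                start, end = int(row["start"]), int(row["end"])
                if end <= start:
                    raise ValueError(
                        f"gene {row['gene_id']!r}: end {end} <= start {start}"
                    )
                genes.append(
                    Gene(
                        gene_id=row["gene_id"],
                        start=start,
                        end=end,
                        strand=int(row["strand"]),
                        protein=prot_by_gene.get(row["gene_id"], ""),
                    )
                )
            else:
                dom_rows.append(row)
    genes.sort(key=lambda g: g.start)
    gene_by_id = {g.gene_id: g for g in genes}
    domains = []
    for row in dom_rows:
        gene = gene_by_id.get(row["gene_id"])
        if gene is None:
            raise ValueError(
                f"domain {row['domain_id']!r} references unknown gene "
                f"{row['gene_id']!r}"
            )
        aa_start, aa_end = _opt_int(row["aa_start"]), _opt_int(row["aa_end"])
        domains.append(
            DomainAnnotation(
                domain_id=row["domain_id"],
                pfam_id=row["pfam_id"],
                gene_id=row["gene_id"],
                order_index=0,
                aa_seq=gene.protein[aa_start:aa_end]
                if aa_start is not None
                else gene.protein,
                nrps_pks_type=_opt_str(row["nrps_pks_type"]),
                module_index=_opt_int(row["module_index"]),
                aa_start=aa_start,
                aa_end=aa_end,
            )
        )
    return GeneCluster(
        cluster_id=entry["cluster_id"],
        organism_id=entry["organism_id"],
        genes=genes,
        domains=assign_order_index(genes, domains),
        sequence=str(record.seq).upper() if len(record.seq) else None,
        class_label=entry.get("class_label", ""),
    )


# ---------------------------------------------------------------------------
# writing


def write_cluster_set(corpus: Corpus, out_dir: str | Path) -> Path:
    """Write a corpus as FASTA + TSV + manifest; returns the manifest path.

    Files: per-cluster nucleotide FASTA and annotation TSV, per-cluster gene
    protein FASTA (headers ``cluster_id|gene_id``), one corpus-wide domain
    amino-acid FASTA (headers ``cluster_id|domain_id|pfam_id``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    corpus = sort_corpus(corpus)
    entries = []
    domain_records: list[str] = []
    for cluster in corpus:
        cid = cluster.cluster_id
        fasta = out_dir / f"{cid}.fna"
        prot = out_dir / f"{cid}.faa"
        tsv = out_dir / f"{cid}.domains.tsv"
        with open(fasta, "w") as fh:
            fh.write(f">{cid}\n")
            seq = cluster.sequence or ""
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
        with open(prot, "w") as fh:
            for g in cluster.genes:
                fh.write(f">{cid}|{g.gene_id}\n{g.protein}\n")
        with open(tsv, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(TSV_COLUMNS)
            for g in cluster.genes:
                w.writerow([cid, g.gene_id, "", "", g.start, g.end, g.strand,
                            "", "", "", ""])
            for d in cluster.domains_in_order():
                gene = cluster.gene(d.gene_id)
                w.writerow(
                    [cid, d.gene_id, d.domain_id, d.pfam_id, gene.start,
                     gene.end, gene.strand, d.nrps_pks_type or "",
                     "" if d.module_index is None else d.module_index,
                     "" if d.aa_start is None else d.aa_start,
                     "" if d.aa_end is None else d.aa_end]
                )
                domain_records.append(
                    f">{cid}|{d.domain_id}|{d.pfam_id}\n{d.aa_seq}\n"
                )
        entries.append(
            {
                "cluster_id": cid,
                "organism_id": cluster.organism_id,
                "class_label": cluster.class_label,
                "fasta": fasta.name,
                "proteins": prot.name,
                "annotations": tsv.name,
            }
        )
    (out_dir / "domains.faa").write_text("".join(domain_records))
    manifest = out_dir / "manifest.json"
    manifest.write_text(json.dumps({"clusters": entries}, indent=1, sort_keys=True) + "\n")
    return manifest
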