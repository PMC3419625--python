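"""Readers and writers for the pipeline's external representations.

Supported formats: FASTA (gene/protein sequences, via Biopython), GFF3 or
6-column TSV gene tables, 12-column BLAST tabular hits, the correspondence
table TSV and the functional-category catalog TSV.  Readers validate and
reject malformed rows with their row number — they never silently coerce.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import (
    DEFAULT_NAMING,
    MAIN,
    REPEAT,
    CategoryNode,
    ChromNaming,
    CorrespondenceRecord,
    GeneModel,
    MatchHit,
)

# --------------------------------------------------------------------------
# FASTA

def read_fasta(path) -> dict:
    """Read a FASTA file into an ordered {id: sequence} dict."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


# --------------------------------------------------------------------------
# Gene tables (GFF3 or 6/7-column TSV)

_GFF_COLS = 9
_TSV_COLS = (6, 7)


def read_gene_table(
    path,
    version_label: str,
    naming: ChromNaming = DEFAULT_NAMING,
) -> list[GeneModel]:
    """Read a gene table (GFF3 or tab-separated) into validated GeneModels.

    TSV rows carry ``chromosome  feature  start  end  strand  gene_id`` with
    an optional 7th ``track`` column.  GFF3 rows use the ``ID`` attribute as
    the gene id and an optional ``track=repeat`` attribute (or a ``repeat``
    source column) for the repeat track.  Repeat-track genes are loaded but
    flagged; excluding them from matching is the caller's decision.
    """
    genes: list[GeneModel] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if len(fields) == _GFF_COLS:
                    gene = _parse_gff_row(fields, version_label, naming)
                elif len(fields) in _TSV_COLS:
                    gene = _parse_tsv_row(fields, version_label, naming)
                else:
                    raise ValueError(
                        f"expected {_GFF_COLS} (GFF3) or {_TSV_COLS} (TSV) columns, "
                        f"got {len(fields)}"
                    )
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from None
            if gene is None:
                continue
            if gene.gene_id in seen:
                raise ValueError(
                    f"{path}: row {lineno}: duplicate gene_id {gene.gene_id!r} "
                    f"within version {version_label!r}"
                )
            seen.add(gene.gene_id)
            genes.append(gene)
    return genes


def _parse_int(text: str, what: str) -> int:
    try:
        return int(text)
    except ValueError:
        raise ValueError(f"malformed {what} {text!r}") from None


def _parse_gff_row(fields, version_label, naming) -> Optional[GeneModel]:
    chrom, source, ftype, start, end, _score, strand, _phase, attrs = fields
    if ftype not in ("gene", "mRNA"):
        return None
    attr_map = {}
    for item in attrs.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            attr_map[k.strip()] = v.strip()
    gene_id = attr_map.get("ID")
    if not gene_id:
        raise ValueError("GFF3 gene row lacks an ID attribute")
    track = REPEAT if (attr_map.get("track") == REPEAT or source == REPEAT) else MAIN
    return GeneModel.with_naming(
        gene_id=gene_id,
        version_label=version_label,
        chromosome=chrom,
        start=_parse_int(start, "start"),
        end=_parse_int(end, "end"),
        strand=strand,
        track=track,
        naming=naming,
    )


def _parse_tsv_row(fields, version_label, naming) -> GeneModel:
    chrom, _feature, start, end, strand, gene_id = fields[:6]
    track = fields[6] if len(fields) == 7 else MAIN
    return GeneModel.with_naming(
        gene_id=gene_id,
        version_label=version_label,
        chromosome=chrom,
        start=_parse_int(start, "start"),
        end=_parse_int(end, "end"),
        strand=strand,
        track=track,
        naming=naming,
    )


def write_gene_table(genes: Iterable[GeneModel], path) -> None:
    """Write gene models as minimal GFF3 (gene features, ID + track attrs)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.track == REPEAT:
                attrs += ";track=repeat"
            fh.write(
                f"{g.chromosome}\t{g.version_label}\tgene\t{g.start}\t{g.end}"
                f"\t.\t{g.strand}\t.\t{attrs}\n"
            )


# --------------------------------------------------------------------------
# BLAST 12-column tabular hits

_HIT_COLS = [
    "query_id", "subject_id", "pct_identity", "aln_length", "mismatches",
    "gap_opens", "q_start", "q_end", "s_start", "s_end", "e_value", "bit_score",
]


def read_tabular_hits(path) -> list[MatchHit]:
    """Parse 12-column alignment tabular rows, unfiltered.

    ``s_start > s_end`` rows are preserved as minus-strand evidence; an empty
    file yields an empty collection; a wrong column count is rejected with
    its row number.
    """
    hits: list[MatchHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: row {lineno}: expected 12 columns, got {len(fields)}"
                )
            try:
                hits.append(
                    MatchHit(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pct_identity=float(fields[2]),
                        aln_length=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        q_start=int(fields[6]),
                        q_end=int(fields[7]),
                        s_start=int(fields[8]),
                        s_end=int(fields[9]),
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: row {lineno}: {exc}") from None
    return hits


def write_tabular_hits(hits: Iterable[MatchHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_length}"
                f"\t{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}"
                f"\t{h.s_start}\t{h.s_end}\t{h.e_value:.3g}\t{h.bit_score:.1f}\n"
            )


# --------------------------------------------------------------------------
# Correspondence table

def write_correspondence_table(
    records: Sequence[CorrespondenceRecord], path, sources: Optional[Sequence[str]] = None
) -> None:
    """Write the correspondence table as TSV.

    One ``id[source]`` / ``position[source]`` column pair per source, in
    priority order, followed by the cardinality comment, track, annotation,
    semicolon-joined categories, the re-review flag and the four-group label.
    Round-trips losslessly through :func:`read_correspondence_table`.
    """
    if sources is None:
        seen: dict[str, None] = {}
        for r in records:
            for s in r.ids_by_source:
                seen.setdefault(s, None)
        sources = list(seen)
    rows = []
    for r in records:
        row = {"unique_id": r.unique_id}
        for s in sources:
            row[f"id[{s}]"] = r.ids_by_source.get(s, "")
            row[f"position[{s}]"] = r.positions_by_source.get(s, "")
        row["cardinality_comment"] = r.cardinality_comment
        row["track"] = r.track
        row["functional_annotation"] = r.annotation
        row["categories"] = ";".join(r.categories)
        row["needs_review"] = "true" if r.needs_review else "false"
        row["four_group"] = r.four_group
        rows.append(row)
    cols = (["unique_id"]
            + [c for s in sources for c in (f"id[{s}]", f"position[{s}]")]
            + ["cardinality_comment", "track", "functional_annotation",
               "categories", "needs_review", "four_group"])
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def read_correspondence_table(path) -> list[CorrespondenceRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    sources = [c[3:-1] for c in df.columns if c.startswith("id[") and c.endswith("]")]
    records = []
    for _, row in df.iterrows():
        ids = {s: row[f"id[{s}]"] for s in sources if row[f"id[{s}]"]}
        positions = {s: row[f"position[{s}]"] for s in sources
                     if row.get(f"position[{s}]", "")}
        rank = next((i + 1 for i, s in enumerate(sources) if s in ids), 0)
        cats = [c for c in row["categories"].split(";") if c]
        records.append(
            CorrespondenceRecord(
                unique_id=row["unique_id"],
                source_rank=rank,
                ids_by_source=ids,
                positions_by_source=positions,
                cardinality_comment=row["cardinality_comment"],
                track=row["track"],
                annotation=row["functional_annotation"],
                categories=cats,
                needs_review=row["needs_review"] == "true",
                four_group=row["four_group"],
            )
        )
    return records


# --------------------------------------------------------------------------
# Functional-category catalog

_CATALOG_COLS = [
    "category_name", "code", "level", "go_name", "go_id", "network",
    "mips_name", "mips_code", "n_genes",
]


def read_category_catalog(path) -> dict[str, CategoryNode]:
    """Read the category catalog TSV into a validated {code: node} mapping.

    Parent links are implied by the dotted code (parent of ``1.2.3`` is
    ``1.2``); every non-root parent must exist and levels must increase by
    one along each link.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("category_name", "code", "level") if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: catalog lacks required columns {missing}")
    catalog: dict[str, CategoryNode] = {}
    for i, row in df.iterrows():
        code = row["code"]
        if code in catalog:
            raise ValueError(f"{path}: row {i + 2}: duplicate category code {code!r}")
        level = _parse_int(row["level"], "level")
        parent = code.rsplit(".", 1)[0] if "." in code else None
        node = CategoryNode(
            code=code,
            name=row["category_name"],
            level=level,
            go_id=row.get("go_id") or None,
            mips_code=row.get("mips_code") or None,
            parent_code=parent,
        )
        catalog[code] = node
    for node in catalog.values():
        if node.parent_code is not None:
            parent = catalog.get(node.parent_code)
            if parent is None:
                raise ValueError(
                    f"{path}: category {node.code}: parent {node.parent_code} "
                    "missing from catalog"
                )
            if node.level != parent.level + 1:
                raise ValueError(
                    f"{path}: category {node.code}: level {node.level} is not "
                    f"parent level + 1 ({parent.level + 1})"
                )
    return catalog


def write_category_catalog(catalog: Mapping[str, CategoryNode], path) -> None:
    rows = []
    for node in catalog.values():
        rows.append({
            "category_name": node.name,
            "code": node.code,
            "level": node.level,
            "go_name": "",
            "go_id": node.go_id or "",
            "network": "",
            "mips_name": "",
            "mips_code": node.mips_code or "",
            "n_genes": "",
        })
    pd.DataFrame(rows, columns=_CATALOG_COLS).to_csv(path, sep="\t", index=False)
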