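"""File formats: GTF input, the JSON graph dialect, and the TSV tables.

Schemas (all versioned through the ``format_version`` manifest field):

* graph JSON: ``{"gene_id", "vertices": [{"id", "kind", "length", "chrom",
  "start", "end", "strand"}], "edges": [[u, v]], "transcripts": [[...]]}``;
  coordinates 0-based half-open.
* fragment TSV: columns ``fragment_id, gene_id, path, start_offset,
  frag_len, affinity`` — one row per candidate mapping, ``path`` a
  comma-joined list of vertex ids.
* FLD TSV: columns ``length, probability``.
* flow TSV: ``src, dst, label, weight``; abundance TSV: ``path, count,
  eff_len, abundance``; PSI TSV: ``gene, e_first, e_mid, e_last, psi``.

GTF coordinates (1-based inclusive) are converted to 0-based half-open on
read; minus-strand genes are reversed into transcription order.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .effective_length import FragLenDist
from .flow import Flow
from .phasing import FragmentMapping, FragmentRecord, PhasingSet
from .splice_graph import (
    GraphError,
    QuantifiedTranscriptSet,
    SpliceGraph,
    Vertex,
    build_splice_graph,
)

__all__ = [
    "graph_to_json",
    "graph_from_json",
    "write_graph_json",
    "read_graph_json",
    "write_fragments_tsv",
    "read_fragments_tsv",
    "write_fld_tsv",
    "read_fld_tsv",
    "write_flow_tsv",
    "write_abundance_tsv",
    "write_truth_tsv",
    "write_psi_tsv",
    "read_gtf",
    "graphs_from_gtf",
    "write_manifest",
]

FORMAT_VERSION = "1"


# ---------------------------------------------------------------------------
# JSON graph dialect


def graph_to_json(g: SpliceGraph) -> dict:
    vertices = []
    for v in g.vertices:
        rec = {"id": v.id, "kind": v.kind}
        if v.kind == "exon":
            rec["length"] = v.length
            if v.start is not None:
                rec.update(chrom=v.chrom, start=v.start, end=v.end, strand=v.strand)
        vertices.append(rec)
    return {
        "format_version": FORMAT_VERSION,
        "gene_id": g.gene_id,
        "vertices": vertices,
        "edges": sorted([int(u), int(v)] for u, v in g.edges),
    }


def graph_from_json(doc: dict) -> SpliceGraph:
    import networkx as nx

    vertices: dict[int, Vertex] = {}
    source = sink = None
    for rec in doc["vertices"]:
        kind = rec["kind"]
        vid = int(rec["id"])
        if kind == "S":
            source = vid
            vertices[vid] = Vertex(id=vid, kind="S")
        elif kind == "T":
            sink = vid
            vertices[vid] = Vertex(id=vid, kind="T")
        else:
            length = rec.get("length")
            start, end = rec.get("start"), rec.get("end")
            if length is None:
                if start is None or end is None:
                    raise GraphError(f"exon {vid}: neither length nor coordinates")
                length = int(end) - int(start)
            vertices[vid] = Vertex(
                id=vid,
                kind="exon",
                length=int(length),
                chrom=rec.get("chrom"),
                start=None if start is None else int(start),
                end=None if end is None else int(end),
                strand=rec.get("strand", "."),
            )
    if source is None or sink is None:
        raise GraphError("graph JSON must contain S and T vertices")
    nxg = nx.DiGraph()
    nxg.add_nodes_from(vertices)
    nxg.add_edges_from((int(u), int(v)) for u, v in doc["edges"])
    return SpliceGraph(
        gene_id=doc["gene_id"], _vertices=vertices, nxg=nxg, source=source, sink=sink
    )


def write_graph_json(g: SpliceGraph, path: str | Path) -> None:
    Path(path).write_text(json.dumps(graph_to_json(g), indent=1) + "\n")


def read_graph_json(path: str | Path) -> SpliceGraph:
    return graph_from_json(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# TSV tables


def _path_str(p) -> str:
    return ",".join(str(v) for v in p)


def write_fragments_tsv(fragments: list[FragmentRecord], path: str | Path) -> None:
    rows = []
    for f in fragments:
        for m in f.mappings:
            rows.append(
                {
                    "fragment_id": f.fragment_id,
                    "gene_id": m.gene_id or "",
                    "path": _path_str(m.path),
                    "start_offset": m.start_offset,
                    "frag_len": m.frag_len,
                    "affinity": m.affinity,
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_fragments_tsv(path: str | Path) -> list[FragmentRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"fragment_id": str, "gene_id": str})
    records = []
    for fid, grp in df.groupby("fragment_id", sort=False):
        mappings = [
            FragmentMapping(
                path=tuple(int(x) for x in str(row.path).split(",")),
                start_offset=int(row.start_offset),
                frag_len=int(row.frag_len),
                affinity=float(row.affinity),
                gene_id=(row.gene_id or None)
                if isinstance(row.gene_id, str) and row.gene_id
                else None,
            )
            for row in grp.itertuples()
        ]
        records.append(FragmentRecord(fragment_id=str(fid), mappings=mappings))
    return records


def write_fld_tsv(D: FragLenDist, path: str | Path) -> None:
    rows = [(t, p) for t, p in D.to_dict().items()]
    pd.DataFrame(rows, columns=["length", "probability"]).to_csv(
        path, sep="\t", index=False
    )


def read_fld_tsv(path: str | Path) -> FragLenDist:
    df = pd.read_csv(path, sep="\t")
    return FragLenDist.from_pmf(
        dict(zip(df["length"].astype(int), df["probability"].astype(float)))
    )


def write_flow_tsv(flow: Flow, path: str | Path) -> None:
    pg = flow.graph
    rows = [
        {
            "src": _path_str(pg.vertex_keys[e.src]),
            "dst": _path_str(pg.vertex_keys[e.dst]),
            "label": _path_str(e.label),
            "weight": flow.edge_weights[e.id],
        }
        for e in pg.edges
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_abundance_tsv(
    P: PhasingSet, c: np.ndarray, path: str | Path
) -> None:
    rows = [
        {
            "path": _path_str(p),
            "count": P.counts[i],
            "eff_len": P.eff_lengths[i],
            "abundance": float(c[i]),
        }
        for i, p in enumerate(P.paths)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_truth_tsv(qts: QuantifiedTranscriptSet, path: str | Path) -> None:
    rows = [
        {"transcript": _path_str(t), "abundance": c, "length": int(l)}
        for t, c, l in zip(qts.transcripts, qts.abundances, qts.lengths)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_psi_tsv(rows: list[dict], path: str | Path) -> None:
    pd.DataFrame(
        rows, columns=["gene", "e_first", "e_mid", "e_last", "psi"]
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GTF


def read_gtf(path: str | Path) -> dict[str, dict]:
    """Per-gene exon/junction/transcript tables from a GTF file.

    Returns ``{gene_id: {"exons": [(chrom, start, end, strand)],
    "junctions": [(u, v)], "transcripts": [[exon ids]]}}`` with exons in
    transcription order (minus-strand genes reversed) and coordinates
    converted to 0-based half-open.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    genes: dict[str, dict] = {}
    tx_exons: dict[str, dict[str, list]] = {}
    for feat in db.features_of_type("exon"):
        try:
            gid = feat.attributes["gene_id"][0]
            tid = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise GraphError(
                f"GTF line without gene_id/transcript_id near "
                f"{feat.seqid}:{feat.start}"
            ) from exc
        exon = (feat.seqid, feat.start - 1, feat.end, feat.strand)
        tx_exons.setdefault(gid, {}).setdefault(tid, []).append(exon)
    for gid, txs in tx_exons.items():
        strand = next(iter(txs.values()))[0][3]
        reverse = strand == "-"
        exon_set = sorted(
            {e for exons in txs.values() for e in exons},
            key=lambda e: e[1],
            reverse=reverse,
        )
        exon_id = {e: i + 1 for i, e in enumerate(exon_set)}
        chains = []
        junctions = set()
        for tid in sorted(txs):
            exons = sorted(txs[tid], key=lambda e: e[1], reverse=reverse)
            chain = [exon_id[e] for e in exons]
            chains.append(chain)
            junctions.update(zip(chain, chain[1:]))
        genes[gid] = {
            "exons": exon_set,
            "junctions": sorted(junctions),
            "transcripts": chains,
        }
    return genes


def graphs_from_gtf(path: str | Path) -> dict[str, SpliceGraph]:
    """Build one splice graph per gene from a GTF annotation."""
    return {
        gid: build_splice_graph(
            rec["exons"], rec["junctions"], gene_id=gid, transcripts=rec["transcripts"]
        )
        for gid, rec in read_gtf(path).items()
    }


# ---------------------------------------------------------------------------
# manifests


def write_manifest(path: str | Path, config: dict, seed: int | None = None) -> None:
    from . import __version__

    blob = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "format_version": FORMAT_VERSION,
        "graphquant_version": __version__,
        "config": config,
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=1, default=str) + "\n")
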