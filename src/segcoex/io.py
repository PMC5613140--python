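"""Readers and writers for the plain-text formats used throughout.

All tabular files are tab-separated UTF-8; lines starting with ``#`` are
treated as comments (and used for light metadata such as the declared
scale). Readers and writers are mutually inverse on valid files.

Coordinate conventions: layout and segment coordinates are 1-based
inclusive in memory and in the layout TSV; the segment table is BED-like,
i.e. 0-based half-open.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import (
    ExpressionMatrix,
    GenomeLayout,
    LayoutElement,
    ReferenceOperons,
    SampleDesign,
)
from .errors import DataError

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------- expression

def read_expression_matrix(
    path: str | Path,
    scale: str = "linear",
    background_ids: Iterable[str] | str | Path | None = None,
) -> ExpressionMatrix:
    """Read an elements x samples TSV (first column = element id).

    ``background_ids`` may be an iterable of ids or a path to a one-id-per-
    line text file.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str},
                     float_precision="round_trip")
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise DataError(f"{path}: duplicate element id(s): {dup}")
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise DataError(
                f"{path}: non-numeric value at element {row!r}, sample {col!r}: "
                f"{df.loc[row, col]!r}"
            )
        df[col] = converted.astype(float)
    if background_ids is None:
        bg: frozenset[str] = frozenset()
    elif isinstance(background_ids, (str, Path)):
        bg = frozenset(read_id_list(background_ids))
    else:
        bg = frozenset(background_ids)
    return ExpressionMatrix(df, scale=scale, background_ids=bg)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        matrix.data.to_csv(fh, sep="\t", index_label="element_id")


def read_id_list(path: str | Path) -> list[str]:
    """One id per line, '#' comments ignored."""
    out = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            out.append(line)
    return out


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{i}\n" for i in ids))


# -------------------------------------------------------------------- design

def read_design(path: str | Path, reference_condition: str) -> SampleDesign:
    """Two-column TSV (sample_id, condition) -> :class:`SampleDesign`."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    if df.shape[1] < 2:
        raise DataError(f"{path}: design table needs columns sample_id, condition")
    sample_col, cond_col = df.columns[:2]
    mapping = dict(zip(df[sample_col], df[cond_col]))
    if len(mapping) != len(df):
        raise DataError(f"{path}: duplicate sample id in design table")
    return SampleDesign(mapping, reference_condition)


def write_design(design: SampleDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# reference={design.reference_condition}\n")
        fh.write("sample_id\tcondition\n")
        for s, c in design.condition_of.items():
            fh.write(f"{s}\t{c}\n")


# -------------------------------------------------------------------- layout

def read_genome_layout(
    path: str | Path,
    circular: bool = True,
    feature_types: Sequence[str] = ("gene",),
    genome_length: int | None = None,
) -> GenomeLayout:
    """Read a genome layout from GFF3 (``.gff``/``.gff3``) or 4/5-column TSV.

    TSV columns: id, start, end, strand[, kind]. Rows out of genomic order
    are sorted with a logged notice.
    """
    path = Path(path)
    if path.suffix.lower() in (".gff", ".gff3"):
        return _read_layout_gff3(path, circular, feature_types)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    need = {"id", "start", "end", "strand"}
    if not need.issubset(df.columns):
        raise DataError(f"{path}: layout TSV needs columns {sorted(need)}")
    if "kind" not in df.columns:
        df["kind"] = "gene"
    starts = df["start"].to_numpy()
    if np.any(np.diff(starts) < 0):
        logger.info("%s: layout rows out of order; sorting by start", path)
    elements = [
        LayoutElement(str(r.id), int(r.start), int(r.end), str(r.strand), str(r.kind))
        for r in df.itertuples(index=False)
    ]
    glen = genome_length
    for line in path.read_text().splitlines():
        if line.startswith("# genome_length="):
            glen = int(line.split("=", 1)[1])
    return GenomeLayout(elements, circular=circular, genome_length=glen)


def _read_layout_gff3(path: Path, circular: bool, feature_types: Sequence[str]) -> GenomeLayout:
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    elements = []
    chrom = "genome"
    for ftype in feature_types:
        for feat in db.features_of_type(ftype):
            fid = feat.attributes.get("locus_tag", [None])[0] or feat.id
            kind = "intergenic" if ftype == "intergenic" else "gene"
            elements.append(LayoutElement(fid, feat.start, feat.end, feat.strand, kind))
            chrom = feat.seqid
    genome_length = None
    for d in db.directives:
        if d.startswith("sequence-region"):
            parts = d.split()
            if len(parts) >= 4:
                genome_length = int(parts[3])
    layout = GenomeLayout(elements, circular=circular, genome_length=genome_length)
    layout.chrom = chrom
    return layout


def write_genome_layout(layout: GenomeLayout, path: str | Path) -> None:
    with open(path, "w") as fh:
        if layout.genome_length is not None:
            fh.write(f"# genome_length={layout.genome_length}\n")
        fh.write("id\tstart\tend\tstrand\tkind\n")
        for e in layout.elements:
            fh.write(f"{e.id}\t{e.start}\t{e.end}\t{e.strand}\t{e.kind}\n")


# ------------------------------------------------------------------- network

def write_network(network, path: str | Path) -> None:
    """Edge list TSV: node_a, node_b, rho, p_adj, mic (mic may be NA)."""
    rows = []
    for a, b, attrs in network.edges(data=True):
        a, b = sorted((a, b))
        mic = attrs.get("mic")
        rows.append((a, b, attrs["rho"], attrs["p_adj"], "NA" if mic is None else mic))
    rows.sort()
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\trho\tp_adj\tmic\n")
        for a, b, rho, p_adj, mic in rows:
            mic_s = mic if isinstance(mic, str) else f"{mic:.6g}"
            fh.write(f"{a}\t{b}\t{rho:.6g}\t{p_adj:.6g}\t{mic_s}\n")


def read_network(path: str | Path, nodes: Iterable[str] | None = None):
    """Read an edge-list TSV into a networkx Graph."""
    import networkx as nx

    g = nx.Graph()
    if nodes is not None:
        g.add_nodes_from(nodes)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"node_a": str, "node_b": str})
    for r in df.itertuples(index=False):
        mic = None if (isinstance(r.mic, str) and r.mic == "NA") else (
            None if pd.isna(r.mic) else float(r.mic))
        g.add_edge(r.node_a, r.node_b, rho=float(r.rho), p_adj=float(r.p_adj), mic=mic)
    return g


# ------------------------------------------------------------------ segments

SEGMENT_COLUMNS = (
    "chrom", "start", "end", "name", "density",
    "members", "reachable", "strandedness",
)


def write_segments(segments, layout: GenomeLayout, path: str | Path) -> None:
    """Write segments as a BED-like TSV (0-based half-open coordinates).

    One row per segment, sorted by (start coordinate, spanned length).
    Wrapping segments on circular layouts are emitted with end < start;
    member order disambiguates.
    """
    from .gtsegments import classify_strandedness

    rows = []
    known = set(layout.ids)
    for seg in segments:
        unknown = [m for m in seg.member_ids if m not in known]
        if unknown:
            raise DataError(f"segment references unknown id(s): {unknown}")
        first = layout.by_id(seg.member_ids[0])
        last = layout.by_id(seg.member_ids[-1])
        bed_start = first.start - 1
        bed_end = last.end
        strandedness = classify_strandedness(seg, layout)
        rows.append((
            layout.chrom, bed_start, bed_end,
            f"{seg.density:.6g}",
            ",".join(seg.member_ids),
            ",".join(sorted(seg.reachable)),
            strandedness,
        ))
    rows.sort(key=lambda r: (r[1], r[2] - r[1], r[4]))
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SEGMENT_COLUMNS) + "\n")
        for i, (chrom, s, e, dens, members, reach, strd) in enumerate(rows, 1):
            fh.write(f"{chrom}\t{s}\t{e}\tseg_{i:05d}\t{dens}\t{members}\t{reach}\t{strd}\n")


def read_segments(path: str | Path, layout: GenomeLayout):
    """Read a segments TSV back into :class:`~segcoex.gtsegments.GTSegment`s."""
    from .gtsegments import GTSegment

    order = layout.ordered_ids(genes_only=True)
    pos_gene = {g: i for i, g in enumerate(order)}
    order_all = layout.ordered_ids(genes_only=False)
    pos_all = {g: i for i, g in enumerate(order_all)}

    segments = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != len(SEGMENT_COLUMNS):
                raise DataError(f"{path}: malformed segment row: {line!r}")
            _, _, _, _, dens, members_s, reach_s, _ = parts
            members = tuple(members_s.split(","))
            first = members[0]
            if first in pos_gene and all(m in pos_gene for m in members):
                start = pos_gene[first]
            elif first in pos_all:
                start = pos_all[first]
            else:
                raise DataError(f"{path}: segment member {first!r} not in layout")
            segments.append(GTSegment(
                start=start,
                member_ids=members,
                reachable=frozenset(reach_s.split(",")),
                density=float(dens),
            ))
    return segments


# ---------------------------------------------------------------- references

def read_reference_operons(path: str | Path) -> ReferenceOperons:
    """One operon per line: comma-separated element ids in genomic order."""
    operons = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        operons.append(tuple(line.split(",")))
    return ReferenceOperons(operons)


def write_reference_operons(ref: ReferenceOperons, path: str | Path) -> None:
    Path(path).write_text("".join(",".join(o) + "\n" for o in ref.operons))
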