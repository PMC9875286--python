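"""Readers for gene structures: GFF3/GTF annotation, length tables, gene sets.

The annotation reader selects exactly one transcript per protein-coding
gene (canonical tag first, longest CDS, then longest transcript, ties by
transcript id) and derives intron lengths from the selected transcript's
exon intervals.  A plain per-gene intron-length TSV is supported as a
lightweight alternative to a full annotation.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Sequence

import gffutils

from .models import GeneModel

logger = logging.getLogger(__name__)

DEFAULT_CANONICAL_TAGS = ("MANE_Select", "Ensembl_canonical", "canonical")
TRANSCRIPT_FEATURES = ("mRNA", "transcript")
_PROTEIN_CODING_KEYS = ("biotype", "gene_biotype", "gene_type")

LENGTH_TABLE_HEADER = "gene_id\tsymbol\tintron_lengths"


def derive_introns(
    exons: Sequence[tuple[int, int]], strand: str, gene_id: str = "?"
) -> list[int]:
    """Intron lengths between consecutive exons, in transcription order.

    ``exons`` must be sorted by genomic start and non-overlapping; with
    1-based inclusive intervals the gap between (s1,e1) and (s2,e2) is
    s2 - e1 - 1.  On the minus strand the genomic-order gaps are
    reversed so index 1 is the 5'-most intron.
    """
    if not exons:
        raise ValueError(f"gene {gene_id}: no exons")
    if strand not in ("+", "-"):
        raise ValueError(f"gene {gene_id}: invalid strand {strand!r}")
    lengths = []
    for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
        if s2 <= e1 + 1:
            raise ValueError(
                f"gene {gene_id}: exons ({s1},{e1}) and ({s2},{e2}) "
                "overlap or abut"
            )
        lengths.append(s2 - e1 - 1)
    if strand == "-":
        lengths.reverse()
    return lengths


def _has_canonical_tag(feature, tags: Sequence[str]) -> bool:
    attrs = feature.attributes
    tag_values = set(attrs.get("tag", []))
    for t in tags:
        if t in tag_values or t in attrs:
            return True
    return False


def _feature_span(features) -> int:
    return sum(f.end - f.start + 1 for f in features)


def _is_protein_coding(gene) -> bool:
    for key in _PROTEIN_CODING_KEYS:
        if key in gene.attributes:
            return gene.attributes[key][0] == "protein_coding"
    return True  # no biotype annotation: keep the gene


def _gene_symbol(gene) -> str:
    for key in ("Name", "gene_name", "gene_symbol"):
        if key in gene.attributes:
            return gene.attributes[key][0]
    return gene.id


def parse_annotation(
    path: str | Path,
    selector: str = "tagged-canonical",
    canonical_tags: Sequence[str] = DEFAULT_CANONICAL_TAGS,
    fmt: str | None = None,
) -> list[GeneModel]:
    """Parse GFF3/GTF into one :class:`GeneModel` per protein-coding gene.

    ``selector`` is ``tagged-canonical`` (canonical tag, falling back to
    longest CDS then longest transcript) or ``longest-CDS-fallback``
    (skip the tag step).  Genes lacking any transcript with exons are
    skipped and counted in a log summary.
    """
    if selector not in ("tagged-canonical", "longest-CDS-fallback"):
        raise ValueError(f"unknown selector {selector!r}")
    path = Path(path)
    if fmt is None:
        fmt = "gtf" if path.suffix.lower() == ".gtf" else "gff3"
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
            disable_infer_genes=(fmt == "gff3"),
            disable_infer_transcripts=(fmt == "gff3"),
        )
    except Exception as exc:  # unparseable file is a hard error
        raise ValueError(f"cannot parse annotation {path}: {exc}") from exc
    if not any(f.start is not None for f in db.all_features()):
        raise ValueError(f"cannot parse annotation {path}: no usable features found")

    models: list[GeneModel] = []
    n_skipped = 0
    for gene in db.features_of_type("gene"):
        if not _is_protein_coding(gene):
            continue
        transcripts = [
            t
            for ft in TRANSCRIPT_FEATURES
            for t in db.children(gene, featuretype=ft, level=1)
        ]
        candidates = [
            t for t in transcripts if list(db.children(t, featuretype="exon"))
        ]
        if not candidates:
            n_skipped += 1
            continue
        chosen = _select_transcript(db, candidates, selector, canonical_tags)
        exons = sorted(
            (e.start, e.end)
            for e in db.children(chosen, featuretype="exon")
        )
        strand = gene.strand if gene.strand in ("+", "-") else "+"
        models.append(
            GeneModel(
                gene_id=gene.id,
                symbol=_gene_symbol(gene),
                transcript_id=chosen.id,
                strand=strand,
                exons=exons,
                intron_lengths=derive_introns(exons, strand, gene.id),
            )
        )
    if n_skipped:
        logger.info("parse_annotation: skipped %d gene(s) without a selectable transcript", n_skipped)
    logger.info("parse_annotation: %d gene model(s) from %s", len(models), path)
    return models


def _select_transcript(db, candidates, selector, canonical_tags):
    if selector == "tagged-canonical":
        tagged = [t for t in candidates if _has_canonical_tag(t, canonical_tags)]
        if tagged:
            candidates = tagged
            if len(candidates) == 1:
                return candidates[0]
    # longest total CDS, then longest transcript (exon span), tie by id
    def key(t):
        cds = _feature_span(db.children(t, featuretype="CDS"))
        exon = _feature_span(db.children(t, featuretype="exon"))
        return (-cds, -exon, t.id)

    return min(candidates, key=key)


def read_length_table(path: str | Path) -> list[GeneModel]:
    """Read the per-gene intron-length TSV dialect.

    Header ``gene_id<TAB>symbol<TAB>intron_lengths``; lengths are
    comma-separated positive integers, empty for intronless genes; lines
    starting with ``#`` are comments.
    """
    models = []
    with open(path, encoding="utf-8") as fh:
        header_seen = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if not header_seen:
                if line != LENGTH_TABLE_HEADER:
                    raise ValueError(
                        f"{path}:{lineno}: expected header {LENGTH_TABLE_HEADER!r}"
                    )
                header_seen = True
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(f"{path}:{lineno}: expected 3 tab-separated fields")
            gene_id, symbol, lengths_field = parts
            lengths: list[int] = []
            if lengths_field:
                for tok in lengths_field.split(","):
                    try:
                        val = int(tok)
                    except ValueError:
                        raise ValueError(
                            f"{path}:{lineno}: non-integer intron length {tok!r}"
                        ) from None
                    if val < 1:
                        raise ValueError(
                            f"{path}:{lineno}: non-positive intron length {val}"
                        )
                    lengths.append(val)
            models.append(
                GeneModel(
                    gene_id=gene_id,
                    symbol=symbol,
                    transcript_id=None,
                    strand="+",
                    exons=[],
                    intron_lengths=lengths,
                )
            )
    if not header_seen:
        raise ValueError(f"{path}: missing header line")
    return models


def write_length_table(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write models in the length-table TSV dialect (round-trip safe)."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(LENGTH_TABLE_HEADER + "\n")
        for m in models:
            fh.write(
                f"{m.gene_id}\t{m.symbol}\t"
                + ",".join(str(l) for l in m.intron_lengths)
                + "\n"
            )


def read_gene_set(path: str | Path) -> set[str]:
    """Read a one-symbol-per-line gene set; `#` comments and blanks ignored."""
    symbols: set[str] = set()
    n_dup = 0
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            sym = raw.strip()
            if not sym or sym.startswith("#"):
                continue
            if sym in symbols:
                n_dup += 1
            symbols.add(sym)
    if n_dup:
        logger.info("read_gene_set: %d duplicate symbol(s) in %s", n_dup, path)
    if not symbols:
        raise ValueError(f"{path}: gene set is empty")
    return symbols
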