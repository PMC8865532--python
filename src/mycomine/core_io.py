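"""Readers/writers for the standard formats the pipeline touches, plus the
shared coordinate model.

Coordinates are 1-based and inclusive everywhere inside the package (the GFF3
convention); only BED export converts to 0-based half-open.  Strand never
enters interval arithmetic: clustering, gap search and centromere calling are
strand-agnostic.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GENE_KINDS = ("protein_coding", "lncRNA", "rRNA", "tRNA", "other")


@dataclass(frozen=True)
class GeneRecord:
    """One annotated gene: coordinates, strand, kind and functional labels."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    kind: str = "protein_coding"
    length_nt: int | None = None
    labels: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(
                f"gene {self.gene_id}: invalid interval {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"gene {self.gene_id}: unknown kind {self.kind!r}")
        if self.length_nt is None:
            object.__setattr__(self, "length_nt", self.end - self.start + 1)

    @property
    def span_nt(self) -> int:
        return self.end - self.start + 1


@dataclass
class ChromosomeRecord:
    """A chromosome/scaffold, optionally with its nucleotide sequence."""

    name: str
    length: int
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.sequence is not None:
            self.sequence = self.sequence.upper()
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"{self.name}: sequence length {len(self.sequence)} != declared {self.length}"
                )
        if self.length <= 0:
            raise ValueError(f"{self.name}: non-positive length")


class GenomeAnnotation:
    """Chromosomes plus genes, with a per-chromosome gene-order index.

    Ranks are assigned by a stable sort on (start, end, gene_id) within each
    chromosome, so ties are deterministic.  Overlapping genes are permitted
    but recorded in :attr:`overlapping_ids`.
    """

    def __init__(
        self,
        chromosomes: Sequence[ChromosomeRecord],
        genes: Sequence[GeneRecord],
    ) -> None:
        self.chromosomes = list(chromosomes)
        self.genes = list(genes)
        chrom_names = [c.name for c in self.chromosomes]
        if len(set(chrom_names)) != len(chrom_names):
            raise ValueError("duplicate chromosome names")
        self._chrom_by_name = {c.name: c for c in self.chromosomes}
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene_id {g.gene_id}")
            seen.add(g.gene_id)
            if g.chrom not in self._chrom_by_name:
                raise ValueError(f"gene {g.gene_id}: unknown chromosome {g.chrom}")
        # rank index: chrom -> ordered list of genes
        self._order: dict[str, list[GeneRecord]] = {n: [] for n in chrom_names}
        for g in self.genes:
            self._order[g.chrom].append(g)
        for name in self._order:
            self._order[name].sort(key=lambda g: (g.start, g.end, g.gene_id))
        self._rank: dict[str, tuple[str, int]] = {}
        for name, ordered in self._order.items():
            for i, g in enumerate(ordered):
                self._rank[g.gene_id] = (name, i)
        self.overlapping_ids = self._find_overlaps()

    def _find_overlaps(self) -> frozenset[str]:
        flagged: set[str] = set()
        for ordered in self._order.values():
            for a, b in zip(ordered, ordered[1:]):
                if b.start <= a.end:
                    flagged.update((a.gene_id, b.gene_id))
        return frozenset(flagged)

    # -- lookups -------------------------------------------------------
    def chromosome(self, name: str) -> ChromosomeRecord:
        return self._chrom_by_name[name]

    def has_chromosome(self, name: str) -> bool:
        return name in self._chrom_by_name

    def genes_on(self, chrom: str, kind: str | None = None) -> list[GeneRecord]:
        """Genes on ``chrom`` in rank order, optionally restricted to a kind."""
        ordered = self._order[chrom]
        if kind is None:
            return list(ordered)
        return [g for g in ordered if g.kind == kind]

    def gene(self, gene_id: str) -> GeneRecord:
        chrom, rank = self._rank[gene_id]
        return self._order[chrom][rank]

    def rank_of(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, rank) of a gene; rank is the 0-based position in the
        start-sorted gene order of its chromosome."""
        try:
            return self._rank[gene_id]
        except KeyError:
            raise KeyError(f"unknown gene_id {gene_id}") from None

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[ChromosomeRecord]:
    """Read a FASTA file into ChromosomeRecords (sequences upper-cased)."""
    records: list[ChromosomeRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate FASTA header {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        records.append(ChromosomeRecord(rec.id, len(seq), seq))
    if not records:
        raise ValueError(f"no records in FASTA file {path}")
    return records


def write_fasta(chromosomes: Iterable[ChromosomeRecord], path: str | Path) -> None:
    """Write chromosomes as FASTA, 60-column wrapped."""
    recs = []
    for c in chromosomes:
        if c.sequence is None:
            raise ValueError(f"{c.name}: cannot write FASTA without sequence")
        recs.append(SeqRecord(Seq(c.sequence), id=c.name, description=""))
    with open(path, "w", encoding="utf-8") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_KIND_ALIASES = {
    "protein_coding": "protein_coding",
    "mrna": "protein_coding",
    "lncrna": "lncRNA",
    "lnc_rna": "lncRNA",
    "rrna": "rRNA",
    "trna": "tRNA",
}


def _infer_kind(feature: gffutils.Feature) -> str:
    biotype = feature.attributes.get("gene_biotype") or feature.attributes.get(
        "biotype"
    )
    if biotype:
        return _KIND_ALIASES.get(biotype[0].lower(), "other")
    return "protein_coding"


def read_gff3(path: str | Path) -> GenomeAnnotation:
    """Read gene features from GFF3 into a GenomeAnnotation.

    Chromosome lengths come from ``##sequence-region`` directives when
    present, otherwise from the furthest gene end.
    """
    text = Path(path).read_text(encoding="utf-8")
    lengths: dict[str, int] = {}
    order: list[str] = []
    for line in text.splitlines():
        if line.startswith("##sequence-region"):
            parts = line.split()
            lengths[parts[1]] = int(parts[3])
            order.append(parts[1])
    db = gffutils.create_db(
        text, dbfn=":memory:", from_string=True, force=True, keep_order=True,
        merge_strategy="error",
    )
    genes: list[GeneRecord] = []
    for feat in db.features_of_type("gene"):
        ids = feat.attributes.get("ID")
        if not ids:
            raise ValueError(f"gene feature without ID at {feat.seqid}:{feat.start}")
        if feat.end < feat.start:
            raise ValueError(f"gene {ids[0]}: end < start")
        labels = frozenset(feat.attributes.get("label", []))
        genes.append(
            GeneRecord(
                gene_id=ids[0],
                chrom=feat.seqid,
                start=feat.start,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                kind=_infer_kind(feat),
                labels=labels,
            )
        )
    for g in genes:
        if g.chrom not in lengths:
            lengths[g.chrom] = 0
            order.append(g.chrom)
        lengths[g.chrom] = max(lengths[g.chrom], g.end)
    chromosomes = [ChromosomeRecord(name, lengths[name]) for name in order]
    return GenomeAnnotation(chromosomes, genes)


def write_gff3(annotation: GenomeAnnotation, path: str | Path) -> None:
    """Write gene features (one ``gene`` line each) as GFF3."""
    kind_to_biotype = {"protein_coding": "protein_coding", "lncRNA": "lncRNA",
                       "rRNA": "rRNA", "tRNA": "tRNA", "other": "other"}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("##gff-version 3\n")
        for c in annotation.chromosomes:
            fh.write(f"##sequence-region {c.name} 1 {c.length}\n")
        for c in annotation.chromosomes:
            for g in annotation.genes_on(c.name):
                attrs = f"ID={g.gene_id};gene_biotype={kind_to_biotype[g.kind]}"
                if g.labels:
                    attrs += ";label=" + ",".join(sorted(g.labels))
                fh.write(
                    f"{g.chrom}\tmycomine\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


# ---------------------------------------------------------------------------
# RepeatMasker .out
# ---------------------------------------------------------------------------

def read_repeatmasker_out(path: str | Path):
    """Parse the classic 15-column RepeatMasker ``.out`` dialect.

    Header/blank lines are tolerated.  Returns a list of
    :class:`mycomine.repeats.RepeatHit` with class I/II mapped from the
    repeat class/family string (LTR/LINE/SINE -> I, DNA -> II, else other).
    """
    from .repeats import RepeatHit, classify_repeat_class

    hits = []
    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            if not parts[0].lstrip("-").isdigit():
                continue  # header rows start with "SW" / "score"
            if len(parts) < 11:
                raise ValueError(f"{path}:{line_no}: malformed RepeatMasker row")
            try:
                score = int(parts[0])
                chrom = parts[4]
                start = int(parts[5])
                end = int(parts[6])
                family = parts[9]
                class_family = parts[10]
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{line_no}: malformed RepeatMasker row"
                ) from exc
            hits.append(
                RepeatHit(
                    chrom=chrom,
                    start=start,
                    end=end,
                    sw_score=score,
                    family=family,
                    repeat_class=classify_repeat_class(class_family),
                    class_family=class_family,
                )
            )
    return hits


def write_repeatmasker_out(hits, path: str | Path) -> None:
    """Write hits in the 15-column ``.out`` dialect (with standard header)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "   SW  perc perc perc  query     position in query    matching"
            "  repeat        position in repeat\n"
            "score  div. del. ins.  sequence  begin end   (left)   repeat"
            "        class/family  begin end (left)  ID\n\n"
        )
        for i, h in enumerate(hits, 1):
            fh.write(
                f"{h.sw_score:>5d}  0.0  0.0  0.0  {h.chrom}  {h.start} {h.end}"
                f" (0) + {h.family}  {h.class_family or h.family}  1 {h.length} (0)  {i}\n"
            )


# ---------------------------------------------------------------------------
# BED export
# ---------------------------------------------------------------------------

def intervals_to_bed(
    intervals: Iterable[tuple[str, int, int, str]], path: str | Path
) -> None:
    """Write (chrom, start, end, name) 1-based inclusive intervals as BED
    (0-based half-open)."""
    with open(path, "w", encoding="utf-8") as fh:
        for chrom, start, end, name in intervals:
            fh.write(f"{chrom}\t{start - 1}\t{end}\t{name}\n")
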