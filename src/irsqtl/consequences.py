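"""Protein-level consequences of retaining one intron.

A retained intron inserts its sequence into the spliced CDS. If the intron
length is a multiple of 3 the downstream reading frame is preserved and any
stop codon inside the intron produces an in-frame premature termination
codon (PTC); otherwise the frame shifts and the first stop encountered in
the shifted frame terminates translation. The classifier translates the
retained-intron CDS from the annotated start codon with the standard
nuclear codon table and compares the first stop against the annotated stop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq


class ConsequenceClass(str, Enum):
    NO_PTC = "NO_PTC"
    PTC_INFRAME = "PTC_INFRAME"
    PTC_FRAMESHIFT = "PTC_FRAMESHIFT"


class NotCdsIntronError(ValueError):
    """The intron is not flanked by two consecutive CDS segments."""


@dataclass
class GeneModel:
    """A protein-coding gene: ordered CDS segments on one strand.

    ``cds`` holds 1-based inclusive genomic intervals sorted in ascending
    genomic order; transcription order is ascending for '+' genes and
    descending for '-'. Total CDS length (including the stop codon) must be
    divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    cds: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError("strand must be + or -")
        self.cds = sorted((int(a), int(b)) for a, b in self.cds)
        for (a1, b1), (a2, b2) in zip(self.cds, self.cds[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping CDS segments in {self.gene_id}")
        if self.cds_length % 3 != 0:
            raise ValueError(
                f"CDS length of {self.gene_id} not divisible by 3")

    @property
    def cds_length(self) -> int:
        return sum(b - a + 1 for a, b in self.cds)

    @property
    def protein_length(self) -> int:
        """Annotated protein length in aa (stop codon excluded)."""
        return self.cds_length // 3 - 1

    @property
    def span(self) -> tuple[int, int]:
        return self.cds[0][0], self.cds[-1][1]

    def cds_in_transcription_order(self) -> list[tuple[int, int]]:
        return self.cds if self.strand == "+" else list(reversed(self.cds))


def _fetch(genome, chrom: str, start0: int, end0: int) -> str:
    """0-based half-open slice from a pyfaidx Fasta or a plain mapping."""
    if hasattr(genome, "get_seq") or not isinstance(genome, Mapping):
        return str(genome[chrom][start0:end0]).upper()
    return genome[chrom][start0:end0].upper()


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def spliced_cds_sequence(gene: GeneModel, genome) -> str:
    """The annotated (fully spliced) CDS in transcription order."""
    parts = []
    for a, b in gene.cds_in_transcription_order():
        s = _fetch(genome, gene.chrom, a - 1, b)
        parts.append(s if gene.strand == "+" else _revcomp(s))
    return "".join(parts)


def build_ir_isoform(gene: GeneModel, intron: tuple[str, int, int],
                     genome) -> str:
    """CDS with one retained intron, in transcription order.

    ``intron`` is (chrom, start, end) in junction convention: the intron
    occupies genomic bases [start, end-1] and must sit exactly between two
    consecutive CDS segments of the gene. The result has length
    CDS length + intron length; minus-strand genes are reverse-complemented.
    """
    chrom, start, end = intron
    if chrom != gene.chrom:
        raise NotCdsIntronError(
            f"intron on {chrom} but gene {gene.gene_id} on {gene.chrom}")
    hit = None
    for (a1, b1), (a2, b2) in zip(gene.cds, gene.cds[1:]):
        if start == b1 + 1 and end == a2:
            hit = True
            break
    if hit is None:
        raise NotCdsIntronError(
            f"intron {chrom}:{start}:{end} is not flanked by consecutive "
            f"CDS segments of {gene.gene_id}")
    parts = []
    segments = sorted(gene.cds + [(start, end - 1)])
    if gene.strand == "-":
        segments = list(reversed(segments))
    for a, b in segments:
        s = _fetch(genome, gene.chrom, a - 1, b)
        parts.append(s if gene.strand == "+" else _revcomp(s))
    seq = "".join(parts)
    expected = gene.cds_length + (end - start)
    if len(seq) != expected:  # genome shorter than annotation
        raise IndexError(
            f"sequence for {gene.gene_id} truncated by genome bounds")
    return seq


@dataclass
class IsoformConsequence:
    """Predicted outcome of retaining one intron in a coding transcript."""

    event_id: str
    gene_id: str
    cls: ConsequenceClass
    truncated_protein_length: int
    truncation: int            # aa lost vs annotated protein (<= 0: longer)
    stop_position: int | None  # 1-based transcript coordinate of the stop


def classify_consequence(isoform_seq: str, gene: GeneModel,
                         event_id: str = "") -> IsoformConsequence:
    """Classify a retained-intron CDS as NO_PTC / PTC_INFRAME / PTC_FRAMESHIFT.

    Translation starts at the annotated start codon using the standard
    codon table. A stop codon appearing before the annotated stop position
    is premature: in-frame retention (intron length divisible by 3) gives
    PTC_INFRAME, otherwise PTC_FRAMESHIFT. In-frame retention without a
    premature stop yields NO_PTC with a protein longer by length/3 aa. A
    frameshifted transcript whose shifted frame reaches the transcript end
    without any stop is reported NO_PTC (stop-loss read-through). Unknown
    (N) bases translate to X and never count as stops.
    """
    seq = isoform_seq.upper()
    intron_len = len(seq) - gene.cds_length
    if intron_len <= 0:
        intron_len = 0
    in_frame = intron_len % 3 == 0
    if not seq.startswith("ATG"):
        warnings.warn(f"{gene.gene_id}: isoform lacks an ATG start codon; "
                      "translating from the segment start")
    prot = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
    stop_idx = prot.find("*")
    ann_len = gene.protein_length
    # index of the annotated stop codon in the retained-intron transcript
    full_len = len(seq) // 3 - 1

    if stop_idx == -1 or (in_frame and stop_idx >= full_len):
        cls = ConsequenceClass.NO_PTC
        trunc_len = full_len if in_frame else len(prot)
        stop_pos = (3 * full_len + 1) if (in_frame and stop_idx != -1) \
            else None
    else:
        cls = (ConsequenceClass.PTC_INFRAME if in_frame
               else ConsequenceClass.PTC_FRAMESHIFT)
        trunc_len = stop_idx
        stop_pos = 3 * stop_idx + 1
    return IsoformConsequence(
        event_id=event_id, gene_id=gene.gene_id, cls=cls,
        truncated_protein_length=int(trunc_len),
        truncation=int(ann_len - trunc_len), stop_position=stop_pos)


def predict_consequences(events: pd.DataFrame, genes: Mapping[str, GeneModel],
                         genome) -> pd.DataFrame:
    """Consequence table for events with columns chrom/start/end/gene.

    Events whose intron is not a CDS intron of the mapped gene are reported
    with class NOT_CDS_INTRON and no truncation numbers.
    """
    rows = []
    for event_id, r in events.iterrows():
        gene = genes.get(r["gene"])
        if gene is None:
            continue
        try:
            iso = build_ir_isoform(
                gene, (str(r["chrom"]), int(r["start"]), int(r["end"])),
                genome)
        except NotCdsIntronError:
            rows.append({"event_id": event_id, "gene": gene.gene_id,
                         "class": "NOT_CDS_INTRON",
                         "truncated_aa": pd.NA, "lost_aa": pd.NA})
            continue
        res = classify_consequence(iso, gene, event_id=str(event_id))
        rows.append({"event_id": event_id, "gene": gene.gene_id,
                     "class": res.cls.value,
                     "truncated_aa": res.truncated_protein_length,
                     "lost_aa": res.truncation})
    return pd.DataFrame(rows, columns=["event_id", "gene", "class",
                                       "truncated_aa", "lost_aa"])


# ---------------------------------------------------------------------------
# GFF3 / FASTA IO
# ---------------------------------------------------------------------------

def read_gene_models(gff3_path: str | Path) -> dict[str, GeneModel]:
    """Load protein-coding gene models (gene + CDS features) from GFF3."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    out: dict[str, GeneModel] = {}
    for gene in db.features_of_type("gene"):
        cds = [(c.start, c.end)
               for c in db.children(gene, featuretype="CDS", order_by="start")]
        if not cds:
            continue
        out[gene.id] = GeneModel(gene_id=gene.id, chrom=gene.seqid,
                                 strand=gene.strand, cds=cds)
    return out


def gene_spans_from_gff3(gff3_path: str | Path) -> pd.DataFrame:
    """Gene spans (gene_id, chrom, start, end) straight from GFF3 gene rows."""
    import gffutils

    db = gffutils.create_db(str(gff3_path), ":memory:",
                            merge_strategy="create_unique", keep_order=True)
    rows = [{"gene_id": g.id, "chrom": g.seqid, "start": g.start,
             "end": g.end} for g in db.features_of_type("gene")]
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end"])


def load_genome(fasta_path: str | Path):
    """Open a FASTA with random access (pyfaidx)."""
    from pyfaidx import Fasta

    return Fasta(str(fasta_path), as_raw=True, sequence_always_upper=True)
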