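"""Rule cascades acting on precomputed annotation evidence.

* lncRNA candidates: assembled transcripts are accepted only when they lie
  at a non-gene locus, are at least 200 nt long, exceed FPKM 1, are called
  non-coding by all coding-potential evaluators, carry no known protein
  (Pfam) domain, and are supported by enough lncRNA prediction tools.
* Effector candidates: predicted secreted proteins (signal peptide present,
  no transmembrane domain, no GPI anchor) shorter than 300 amino acids.

Both cascades report per-stage exclusion tallies that sum, together with
the accepted set, to the input size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

MIN_LNCRNA_LEN = 200
MIN_LNCRNA_FPKM = 1.0
MIN_PREDICTOR_SUPPORT = 3
MAX_EFFECTOR_LEN = 300


@dataclass(frozen=True)
class TranscriptEvidence:
    """Evidence row for one assembled transcript."""

    transcript_id: str
    at_gene_locus: bool
    length_nt: int
    fpkm: float
    noncoding_calls: tuple[bool, ...]  # one flag per coding-potential tool
    pfam_domain: bool
    predictor_support: int

    def __post_init__(self) -> None:
        if self.length_nt < 1:
            raise ValueError(f"{self.transcript_id}: length_nt must be >= 1")
        if self.predictor_support < 0:
            raise ValueError(f"{self.transcript_id}: negative predictor support")


@dataclass(frozen=True)
class ProteinEvidence:
    """Evidence row for one predicted protein."""

    protein_id: str
    length_aa: int
    signal_peptide: bool
    tm_domains: int
    gpi_anchor: bool

    def __post_init__(self) -> None:
        if self.length_aa < 1:
            raise ValueError(f"{self.protein_id}: length_aa must be >= 1")
        if self.tm_domains < 0:
            raise ValueError(f"{self.protein_id}: negative TM domain count")


def filter_lncrna(
    evidence_rows: Sequence[TranscriptEvidence],
    min_len: int = MIN_LNCRNA_LEN,
    min_fpkm: float = MIN_LNCRNA_FPKM,
    min_support: int = MIN_PREDICTOR_SUPPORT,
    coding_mode: str = "any",
    literal_conjunction: bool = False,
) -> tuple[set[str], dict[str, int]]:
    """Run the lncRNA candidate cascade; returns (accepted ids, tallies).

    Stages, applied in order with each transcript counted at its first
    failure: gene_locus, length (< min_len excluded), fpkm (<= min_fpkm
    excluded), coding_potential, pfam_domain, predictor_support.  By
    default length and FPKM are independent exclusions; with
    ``literal_conjunction`` a transcript is excluded at a combined
    length_fpkm stage only when it fails both.  ``coding_mode`` "any"
    removes transcripts any evaluator calls coding; "majority" requires
    most evaluators to call it coding.
    """
    if coding_mode not in ("any", "majority"):
        raise ValueError("coding_mode must be 'any' or 'majority'")
    if literal_conjunction:
        stages = ["gene_locus", "length_fpkm", "coding_potential",
                  "pfam_domain", "predictor_support"]
    else:
        stages = ["gene_locus", "length", "fpkm", "coding_potential",
                  "pfam_domain", "predictor_support"]
    tallies = {s: 0 for s in stages}
    accepted: set[str] = set()
    for row in evidence_rows:
        failed = None
        if row.at_gene_locus:
            failed = "gene_locus"
        elif literal_conjunction:
            if row.length_nt < min_len and row.fpkm <= min_fpkm:
                failed = "length_fpkm"
        elif row.length_nt < min_len:
            failed = "length"
        elif row.fpkm <= min_fpkm:
            failed = "fpkm"
        if failed is None:
            n_coding = sum(1 for nc in row.noncoding_calls if not nc)
            coding = (
                n_coding > 0
                if coding_mode == "any"
                else n_coding * 2 > len(row.noncoding_calls)
            )
            if coding:
                failed = "coding_potential"
            elif row.pfam_domain:
                failed = "pfam_domain"
            elif row.predictor_support < min_support:
                failed = "predictor_support"
        if failed is None:
            accepted.add(row.transcript_id)
        else:
            tallies[failed] += 1
    tallies["accepted"] = len(accepted)
    return accepted, tallies


def filter_effectors(
    protein_rows: Sequence[ProteinEvidence],
    max_len: int = MAX_EFFECTOR_LEN,
) -> tuple[set[str], dict[str, int]]:
    """Effector-candidate rule: secreted (signal peptide, no TM domain, no
    GPI anchor) and strictly shorter than ``max_len`` amino acids."""
    stages = ["signal_peptide", "tm_domains", "gpi_anchor", "length"]
    tallies = {s: 0 for s in stages}
    accepted: set[str] = set()
    for row in protein_rows:
        if not row.signal_peptide:
            tallies["signal_peptide"] += 1
        elif row.tm_domains > 0:
            tallies["tm_domains"] += 1
        elif row.gpi_anchor:
            tallies["gpi_anchor"] += 1
        elif row.length_aa >= max_len:
            tallies["length"] += 1
        else:
            accepted.add(row.protein_id)
    tallies["accepted"] = len(accepted)
    return accepted, tallies


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def read_transcript_evidence(path: str | Path) -> list[TranscriptEvidence]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    rows = []
    for r in df.itertuples(index=False):
        rows.append(
            TranscriptEvidence(
                transcript_id=str(r.transcript_id),
                at_gene_locus=bool(r.at_gene_locus),
                length_nt=int(r.length_nt),
                fpkm=float(r.fpkm),
                noncoding_calls=tuple(
                    bool(int(x)) for x in str(r.noncoding_calls).split(",")
                ),
                pfam_domain=bool(r.pfam_domain),
                predictor_support=int(r.predictor_support),
            )
        )
    return rows


def read_protein_evidence(path: str | Path) -> list[ProteinEvidence]:
    df = pd.read_csv(path, sep="\t")
    return [
        ProteinEvidence(
            protein_id=str(r.protein_id),
            length_aa=int(r.length_aa),
            signal_peptide=bool(r.signal_peptide),
            tm_domains=int(r.tm_domains),
            gpi_anchor=bool(r.gpi_anchor),
        )
        for r in df.itertuples(index=False)
    ]


def write_transcript_evidence(
    rows: Sequence[TranscriptEvidence], path: str | Path
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "transcript_id\tat_gene_locus\tlength_nt\tfpkm\t"
            "noncoding_calls\tpfam_domain\tpredictor_support\n"
        )
        for r in rows:
            calls = ",".join("1" if c else "0" for c in r.noncoding_calls)
            fh.write(
                f"{r.transcript_id}\t{int(r.at_gene_locus)}\t{r.length_nt}\t"
                f"{r.fpkm!r}\t{calls}\t{int(r.pfam_domain)}\t{r.predictor_support}\n"
            )


def write_protein_evidence(rows: Sequence[ProteinEvidence], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("protein_id\tlength_aa\tsignal_peptide\ttm_domains\tgpi_anchor\n")
        for r in rows:
            fh.write(
                f"{r.protein_id}\t{r.length_aa}\t{int(r.signal_peptide)}\t"
                f"{r.tm_domains}\t{int(r.gpi_anchor)}\n"
            )
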