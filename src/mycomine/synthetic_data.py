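"""Seeded simulators for every input the pipeline consumes.

The generators emulate the structure of a polypore mushroom genome and its
expression data at test scale: multi-chromosome genomes with terminal
telomeric repeat tracts, one long ORF-free retrotransposon-dense gap per
chromosome (the centromere stand-in), interspersed class I/II repeat hits
whose lengths and scores straddle the confidence thresholds, gene tables
with planted CAZyme clusters and rule-violating decoys, near-identical
mitogenome pairs, and negative-binomial count matrices with a planted set
of up-regulated genes across three sample groups (monokaryotic mycelium,
dikaryotic mycelium, fruiting body).

Every generator is deterministic for a given seed and returns
machine-readable ground truth alongside the data, so downstream tests
compare against planted truth rather than re-derivation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation_filters import ProteinEvidence, TranscriptEvidence
from .cazgc import GeneRole, SignatureTable
from .chromosome_features import CoverageTrack, TELOMERE_MOTIF, reverse_complement
from .core_io import ChromosomeRecord, GeneRecord, GenomeAnnotation
from .repeats import RepeatHit, classify_repeat_class

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_CAZ_FAMILIES = ("GH5", "GH18", "GH105", "AA9", "AA3", "CBM1", "CE4", "PL8", "GT2")
_REPEAT_FAMILIES = (
    ("Gypsy", "LTR/Gypsy"),
    ("Copia", "LTR/Copia"),
    ("L1", "LINE/L1"),
    ("Tad1", "LINE/Tad1"),
    ("TcMar-Tc1", "DNA/TcMar-Tc1"),
    ("hAT-Ac", "DNA/hAT-Ac"),
    ("Helitron", "RC/Helitron"),
    ("(TA)n", "Simple_repeat"),
)

#: pattern characters: C = CAZyme, T = transporter, F = transcription factor,
#: "." = plain gene spacer inside the pattern
DEFAULT_PLANTED_CLUSTERS = ("CCC", "CTC", "CC.C")
#: (pattern, the one rule it violates)
DEFAULT_DECOYS = (("CC", "membership"), ("C..C", "spacing"), ("C.T", "membership"))


@dataclass
class GenomeSimSpec:
    """Study conditions for one synthetic genome."""

    seed: int = 0
    n_chromosomes: int = 3
    genes_per_chromosome: int = 40
    gene_length: tuple[int, int] = (300, 1500)
    intergenic_gap: tuple[int, int] = (100, 800)
    telomere_copies: Sequence[tuple[int, int]] | None = None  # (5', 3') per chrom
    telomere_copy_range: tuple[int, int] = (3, 9)
    centromere_length: int = 20_000
    centromere_rt_fill: float = 0.8
    repeats_per_chromosome: int = 50
    planted_clusters: Sequence[str] = DEFAULT_PLANTED_CLUSTERS
    decoy_clusters: Sequence[tuple[str, str]] = DEFAULT_DECOYS
    background_depth: float = 50.0
    depth_window: int = 1000


@dataclass
class GenomeTruth:
    """Machine-readable ground truth for one simulated genome."""

    telomeres: dict[str, tuple[int, int]]
    centromeres: dict[str, dict]
    clusters: list[tuple[str, tuple[str, ...]]]
    decoys: list[tuple[str, tuple[str, ...], str]]
    repeat_survivors: list[int]  # indices into the hits list
    hit_families: list[str]


@dataclass
class GenomeSim:
    spec: GenomeSimSpec
    annotation: GenomeAnnotation
    hits: list[RepeatHit]
    signatures: SignatureTable
    tracks: dict[str, CoverageTrack]
    truth: GenomeTruth

    def write(self, outdir: str | Path) -> None:
        from . import core_io
        from .chromosome_features import write_depth_tsv

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        core_io.write_fasta(self.annotation.chromosomes, outdir / "genome.fasta")
        core_io.write_gff3(self.annotation, outdir / "genes.gff3")
        core_io.write_repeatmasker_out(self.hits, outdir / "repeats.out")
        self.signatures.to_tsv(outdir / "signatures.tsv")
        write_depth_tsv(self.tracks, outdir / "depth.tsv")
        with open(outdir / "truth_clusters.tsv", "w", encoding="utf-8") as fh:
            fh.write("chrom\tmembers\n")
            for chrom, members in self.truth.clusters:
                fh.write(f"{chrom}\t{','.join(members)}\n")
        with open(outdir / "truth_features.tsv", "w", encoding="utf-8") as fh:
            fh.write("chrom\ttel5\ttel3\tcen_start\tcen_end\trt_fraction\n")
            for chrom, (t5, t3) in self.truth.telomeres.items():
                c = self.truth.centromeres[chrom]
                fh.write(
                    f"{chrom}\t{t5}\t{t3}\t{c['start']}\t{c['end']}\t{c['rt_fraction']}\n"
                )


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice(_BASES, size=n)


def _pattern_roles(pattern: str) -> list[str]:
    mapping = {"C": "cazyme", "T": "transporter", "F": "transcription_factor",
               ".": "other"}
    try:
        return [mapping[ch] for ch in pattern]
    except KeyError as exc:
        raise ValueError(f"bad pattern character in {pattern!r}") from exc


def _pattern_is_valid_cluster(pattern: str) -> bool:
    """Would this pattern, planted contiguously, satisfy the cluster rules?
    Used only to sanity-check the spec at construction time."""
    roles = _pattern_roles(pattern)
    caz = [i for i, r in enumerate(roles) if r == "cazyme"]
    sig = [i for i, r in enumerate(roles) if r in ("transporter", "transcription_factor")]
    if len(caz) < 2:
        return False
    # linkage: consecutive CAZymes within 2 ranks, signatures within 2 of a CAZyme
    for a, b in zip(caz, caz[1:]):
        if b - a > 2:
            return False
    if len(caz) >= 3:
        return True
    return any(min(abs(s - c) for c in caz) <= 2 for s in sig)


def generate_genome(spec: GenomeSimSpec) -> GenomeSim:
    """Simulate one genome with planted features and its ground truth."""
    rng = np.random.default_rng(spec.seed)
    for pattern in spec.planted_clusters:
        if not _pattern_is_valid_cluster(pattern):
            raise ValueError(f"planted pattern {pattern!r} violates the cluster rules")
    for pattern, _rule in spec.decoy_clusters:
        if _pattern_is_valid_cluster(pattern):
            raise ValueError(f"decoy pattern {pattern!r} satisfies the cluster rules")

    if spec.telomere_copies is not None:
        tel_copies = list(spec.telomere_copies)
        if len(tel_copies) != spec.n_chromosomes:
            raise ValueError("telomere_copies must have one pair per chromosome")
    else:
        lo, hi = spec.telomere_copy_range
        tel_copies = [
            (int(rng.integers(lo, hi + 1)), int(rng.integers(lo, hi + 1)))
            for _ in range(spec.n_chromosomes)
        ]

    motif = TELOMERE_MOTIF
    rc_motif = reverse_complement(motif)
    chromosomes: list[ChromosomeRecord] = []
    genes: list[GeneRecord] = []
    hits: list[RepeatHit] = []
    roles: dict[str, GeneRole] = {}
    tracks: dict[str, CoverageTrack] = {}
    truth_tel: dict[str, tuple[int, int]] = {}
    truth_cen: dict[str, dict] = {}
    truth_clusters: list[tuple[str, tuple[str, ...]]] = []
    truth_decoys: list[tuple[str, tuple[str, ...], str]] = []
    survivors: list[int] = []

    # round-robin assignment of planted/decoy patterns to chromosomes
    per_chrom_patterns: list[list[tuple[str, str | None]]] = [
        [] for _ in range(spec.n_chromosomes)
    ]
    for i, pattern in enumerate(spec.planted_clusters):
        per_chrom_patterns[i % spec.n_chromosomes].append((pattern, None))
    for i, (pattern, rule) in enumerate(spec.decoy_clusters):
        per_chrom_patterns[(i + 1) % spec.n_chromosomes].append((pattern, rule))

    for ci in range(spec.n_chromosomes):
        chrom = f"chr{ci + 1}"
        n_genes = spec.genes_per_chromosome
        patterns = per_chrom_patterns[ci]
        needed = sum(len(p) for p, _ in patterns) + 4 * (len(patterns) + 1)
        if needed > n_genes:
            raise ValueError(f"{chrom}: too many planted genes for {n_genes} slots")

        # assign roles per rank: place patterns with >= 4 plain genes between
        rank_roles = ["other"] * n_genes
        pattern_members: list[tuple[list[int], str | None]] = []
        cursor = 0
        free = n_genes - needed
        for pattern, rule in patterns:
            cursor += 4 + int(rng.integers(0, max(1, free // (len(patterns) + 1))))
            member_ranks = []
            for ch, role in zip(pattern, _pattern_roles(pattern)):
                if cursor >= n_genes:
                    raise ValueError("pattern placement overflow")
                rank_roles[cursor] = role
                if role != "other":
                    member_ranks.append(cursor)
                cursor += 1
            pattern_members.append((member_ranks, rule))

        # lay the chromosome out left to right
        tel5, tel3 = tel_copies[ci]
        parts: list[np.ndarray] = []
        pos = 0

        def _append(arr: np.ndarray) -> None:
            nonlocal pos
            parts.append(arr)
            pos += len(arr)

        _append(np.frombuffer((rc_motif * tel5).encode(), dtype=np.uint8))
        _append(np.frombuffer(b"G", dtype=np.uint8))  # break the tandem run
        _append(_random_seq(rng, 400))

        cen_after = n_genes // 2
        cen_interval: tuple[int, int] | None = None
        gene_coords: list[tuple[int, int]] = []
        for gi in range(n_genes):
            gap = int(rng.integers(*spec.intergenic_gap))
            if gi == cen_after:
                gap = spec.centromere_length
                cen_interval = (pos + 1, pos + gap)  # 1-based inclusive
            _append(_random_seq(rng, gap))
            glen = int(rng.integers(*spec.gene_length))
            gene_coords.append((pos + 1, pos + glen))
            _append(_random_seq(rng, glen))
        _append(_random_seq(rng, 400))
        # "C" guard: the 6-mer preceding the 3' tract can never match the
        # motif (which ends in G), so the tandem run cannot extend leftward
        _append(np.frombuffer(b"C", dtype=np.uint8))
        _append(np.frombuffer((motif * tel3).encode(), dtype=np.uint8))
        seq = bytes(np.concatenate(parts)).decode()
        chrom_len = len(seq)
        chromosomes.append(ChromosomeRecord(chrom, chrom_len, seq))
        truth_tel[chrom] = (tel5, tel3)

        # gene records + roles
        for gi, (gs, ge) in enumerate(gene_coords):
            gene_id = f"{chrom}_g{gi + 1:03d}"
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(GeneRecord(gene_id, chrom, gs, ge, strand))
            role = rank_roles[gi]
            if role == "cazyme":
                fams = tuple(rng.choice(_CAZ_FAMILIES, size=1))
                roles[gene_id] = GeneRole("cazyme", fams)
            elif role != "other":
                roles[gene_id] = GeneRole(role)
        for member_ranks, rule in pattern_members:
            ids = tuple(f"{chrom}_g{r + 1:03d}" for r in member_ranks)
            if rule is None:
                truth_clusters.append((chrom, ids))
            else:
                truth_decoys.append((chrom, ids, rule))

        # centromere RT fill: non-overlapping class I blocks covering the
        # stated fraction of the gap
        assert cen_interval is not None
        cs, ce = cen_interval
        clen = ce - cs + 1
        n_blocks = 10
        block = int(clen * spec.centromere_rt_fill / n_blocks)
        stride = clen // n_blocks
        covered = 0
        for b in range(n_blocks):
            s = cs + b * stride
            e = min(s + block - 1, ce)
            if e < s:
                continue
            covered += e - s + 1
            survivors.append(len(hits))
            hits.append(
                RepeatHit(chrom, s, e, int(rng.integers(1500, 4000)),
                          "Gypsy", "I", "LTR/Gypsy")
            )
        truth_cen[chrom] = {
            "start": cs,
            "end": ce,
            "rt_fraction": covered / clen,
            "expr_ratio": 0.0,
        }

        # interspersed repeat hits straddling the filter thresholds,
        # kept out of the centromere interval so its RT fraction is exact
        for _ in range(spec.repeats_per_chromosome):
            category = rng.choice(("pass", "len_fail", "score_fail", "both_fail"),
                                  p=(0.45, 0.2, 0.2, 0.15))
            if category in ("pass", "score_fail"):
                length = int(rng.integers(140, 800)) if rng.random() > 0.1 else 140
            else:
                length = int(rng.integers(60, 140)) if rng.random() > 0.1 else 139
            if category in ("pass", "len_fail"):
                score = int(rng.integers(450, 3000)) if rng.random() > 0.1 else 450
            else:
                score = int(rng.integers(100, 450)) if rng.random() > 0.1 else 449
            while True:
                s = int(rng.integers(1, chrom_len - length))
                e = s + length - 1
                if e < cs - 1 or s > ce:  # outside the centromere gap
                    break
            family, class_family = _REPEAT_FAMILIES[
                int(rng.integers(0, len(_REPEAT_FAMILIES)))
            ]
            if category == "pass":
                survivors.append(len(hits))
            hits.append(
                RepeatHit(chrom, s, e, score, family,
                          classify_repeat_class(class_family), class_family)
            )

        # expression depth track: background Poisson depth, zero across any
        # window touching the centromere interval
        n_windows = -(-chrom_len // spec.depth_window)
        depths = rng.poisson(spec.background_depth, size=n_windows).astype(float)
        first_w = (cs - 1) // spec.depth_window
        last_w = (ce - 1) // spec.depth_window
        depths[first_w : last_w + 1] = 0.0
        tracks[chrom] = CoverageTrack(chrom, spec.depth_window, depths)

    annotation = GenomeAnnotation(chromosomes, genes)
    truth = GenomeTruth(
        telomeres=truth_tel,
        centromeres=truth_cen,
        clusters=truth_clusters,
        decoys=truth_decoys,
        repeat_survivors=survivors,
        hit_families=[h.family for h in hits],
    )
    return GenomeSim(spec, annotation, hits, SignatureTable(roles), tracks, truth)


# ---------------------------------------------------------------------------
# Mitogenome pairs
# ---------------------------------------------------------------------------

def generate_mitogenome_pair(
    length: int = 10_000,
    n_substitutions: int = 7,
    deletion_lengths: Sequence[int] = (),
    seed: int = 0,
) -> tuple[str, str, dict]:
    """A pair of near-identical sequences with k planted substitutions and
    optional planted deletions (bases present in the first sequence only).

    Edit sites are kept >= 30 bp apart and away from the termini so the
    optimal alignment recovers exactly the planted differences.
    """
    rng = np.random.default_rng(seed)
    n_sites = n_substitutions + len(deletion_lengths)
    if length < 60 * (n_sites + 2):
        raise ValueError("sequence too short for well-separated edit sites")
    seq_a = bytes(_random_seq(rng, length)).decode()
    positions = np.sort(
        rng.choice(
            np.arange(50, length - 50 - max(deletion_lengths, default=0), 30),
            size=n_sites,
            replace=False,
        )
    )
    rng.shuffle(kinds := (["sub"] * n_substitutions + [f"del{d}" for d in deletion_lengths]))
    b = list(seq_a)
    # apply right-to-left so positions stay valid
    for p, kind in sorted(zip(positions.tolist(), kinds), reverse=True):
        if kind == "sub":
            old = b[p]
            b[p] = rng.choice([c for c in "ACGT" if c != old])
        else:
            d = int(kind[3:])
            del b[p : p + d]
    seq_b = "".join(b)
    truth = {
        "substitutions": n_substitutions,
        "insertions": 0,
        "deletions": int(sum(deletion_lengths)),
    }
    return seq_a, seq_b, truth


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class ExprSimSpec:
    """Study conditions for one synthetic expression experiment.

    Defaults mirror the sampled study design: monokaryotic mycelia,
    dikaryotic mycelia and fruiting bodies, with negative-binomial counts
    (per-gene dispersion 0.1) and a planted set of genes induced 5-fold in
    fruiting bodies.
    """

    seed: int = 0
    n_genes: int = 2000
    samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"FB": 3, "mono_mycelium": 4, "di_mycelium": 2}
    )
    up_group: str = "FB"
    n_up: int = 100
    fold: float = 5.0
    dispersion: float = 0.1
    base_mean_log_mu: float = 4.0
    base_mean_log_sigma: float = 1.0
    library_factor_range: tuple[float, float] = (0.8, 1.25)
    transcript_length: tuple[int, int] = (500, 4000)


@dataclass
class ExprSim:
    spec: ExprSimSpec
    matrix: "object"           # expression.CountMatrix
    up_genes: set[str]


def generate_counts(spec: ExprSimSpec) -> ExprSim:
    """Negative-binomial count matrix with a planted up-regulated gene set.

    Planted genes have group-mean expectations ``fold`` times higher in the
    ``up_group`` than elsewhere; dispersion 0 degenerates to Poisson.
    """
    from .expression import CountMatrix

    rng = np.random.default_rng(spec.seed)
    gene_ids = [f"g{i + 1:05d}" for i in range(spec.n_genes)]
    lengths = pd.Series(
        rng.integers(*spec.transcript_length, size=spec.n_genes),
        index=gene_ids, name="length",
    )
    base_mean = rng.lognormal(spec.base_mean_log_mu, spec.base_mean_log_sigma,
                              size=spec.n_genes)
    up_idx = rng.choice(spec.n_genes, size=spec.n_up, replace=False)
    up_genes = {gene_ids[i] for i in up_idx}
    fold_vec = np.ones(spec.n_genes)
    fold_vec[up_idx] = spec.fold

    samples, groups = [], {}
    for group, n in spec.samples_per_group.items():
        for r in range(n):
            sid = f"{group}_{r + 1}"
            samples.append(sid)
            groups[sid] = group

    counts = {}
    for sid in samples:
        lib = rng.uniform(*spec.library_factor_range)
        mu = base_mean * lib
        if groups[sid] == spec.up_group:
            mu = mu * fold_vec
        if spec.dispersion <= 0:
            counts[sid] = rng.poisson(mu)
        else:
            r_nb = 1.0 / spec.dispersion
            counts[sid] = rng.negative_binomial(r_nb, r_nb / (r_nb + mu))
    matrix = CountMatrix(pd.DataFrame(counts, index=gene_ids), lengths, groups)
    return ExprSim(spec, matrix, up_genes)


# ---------------------------------------------------------------------------
# Evidence tables for the filter cascades
# ---------------------------------------------------------------------------

def generate_transcript_evidence(
    n: int = 1000, n_accept: int = 87, seed: int = 0, n_tools: int = 3
) -> tuple[list[TranscriptEvidence], set[str], dict[str, int]]:
    """Transcript evidence with planted accept/reject truth.

    Each rejected row is built to fail exactly one cascade stage (the one
    recorded in the tally truth), passing all earlier stages; boundary
    values (199 nt, FPKM exactly 1.0) appear among the rejects.
    Returns (rows, accepted ids, expected per-stage tallies).
    """
    rng = np.random.default_rng(seed)
    stages = ["gene_locus", "length", "fpkm", "coding_potential",
              "pfam_domain", "predictor_support"]
    tallies = {s: 0 for s in stages}
    rows: list[TranscriptEvidence] = []
    accepted: set[str] = set()
    accept_flags = np.zeros(n, dtype=bool)
    accept_flags[rng.choice(n, size=n_accept, replace=False)] = True
    for i in range(n):
        tid = f"t{i + 1:05d}"
        passing = dict(
            at_gene_locus=False,
            length_nt=int(rng.integers(200, 3000)) if rng.random() > 0.05 else 200,
            fpkm=float(rng.uniform(1.01, 50.0)),
            noncoding_calls=tuple([True] * n_tools),
            pfam_domain=False,
            predictor_support=int(rng.integers(3, n_tools + 3)),
        )
        if accept_flags[i]:
            rows.append(TranscriptEvidence(tid, **passing))
            accepted.add(tid)
            continue
        stage = stages[int(rng.integers(0, len(stages)))]
        if stage == "gene_locus":
            passing["at_gene_locus"] = True
        elif stage == "length":
            passing["length_nt"] = 199 if rng.random() < 0.3 else int(rng.integers(50, 199))
        elif stage == "fpkm":
            passing["fpkm"] = 1.0 if rng.random() < 0.3 else float(rng.uniform(0.0, 1.0))
        elif stage == "coding_potential":
            calls = [True] * n_tools
            calls[int(rng.integers(0, n_tools))] = False
            passing["noncoding_calls"] = tuple(calls)
        elif stage == "pfam_domain":
            passing["pfam_domain"] = True
        else:
            passing["predictor_support"] = int(rng.integers(0, 3))
        tallies[stage] += 1
        rows.append(TranscriptEvidence(tid, **passing))
    tallies["accepted"] = n_accept
    return rows, accepted, tallies


def generate_protein_evidence(
    n: int = 500, n_accept: int = 42, seed: int = 0
) -> tuple[list[ProteinEvidence], set[str], dict[str, int]]:
    """Protein evidence with planted effector-candidate truth; rejects fail
    exactly one stage (boundary length 300 aa appears among them)."""
    rng = np.random.default_rng(seed)
    stages = ["signal_peptide", "tm_domains", "gpi_anchor", "length"]
    tallies = {s: 0 for s in stages}
    rows: list[ProteinEvidence] = []
    accepted: set[str] = set()
    accept_flags = np.zeros(n, dtype=bool)
    accept_flags[rng.choice(n, size=n_accept, replace=False)] = True
    for i in range(n):
        pid = f"p{i + 1:04d}"
        passing = dict(
            length_aa=int(rng.integers(60, 300)) if rng.random() > 0.05 else 299,
            signal_peptide=True,
            tm_domains=0,
            gpi_anchor=False,
        )
        if accept_flags[i]:
            rows.append(ProteinEvidence(pid, **passing))
            accepted.add(pid)
            continue
        stage = stages[int(rng.integers(0, len(stages)))]
        if stage == "signal_peptide":
            passing["signal_peptide"] = False
        elif stage == "tm_domains":
            passing["tm_domains"] = int(rng.integers(1, 8))
        elif stage == "gpi_anchor":
            passing["gpi_anchor"] = True
        else:
            passing["length_aa"] = 300 if rng.random() < 0.3 else int(rng.integers(300, 900))
        tallies[stage] += 1
        rows.append(ProteinEvidence(pid, **passing))
    tallies["accepted"] = n_accept
    return rows, accepted, tallies


# ---------------------------------------------------------------------------
# Ortholog hit tables
# ---------------------------------------------------------------------------

def generate_ortholog_hits(
    query_ids: Sequence[str],
    subject_pool: Sequence[str],
    covered_subjects: Sequence[str],
    e_cut: float = 1e-5,
    seed: int = 0,
) -> pd.DataFrame:
    """Hit table (query, subject, evalue) in which exactly
    ``covered_subjects`` receive at least one hit below the cutoff; other
    listed subjects only appear (if at all) above the cutoff."""
    rng = np.random.default_rng(seed)
    rows = []
    queries = list(query_ids)
    for subj in covered_subjects:
        q = queries[int(rng.integers(0, len(queries)))]
        rows.append((q, subj, float(e_cut * 10 ** -rng.uniform(1, 30))))
    weak = [s for s in subject_pool if s not in set(covered_subjects)]
    for subj in weak[: len(weak) // 3]:
        q = queries[int(rng.integers(0, len(queries)))]
        rows.append((q, subj, float(e_cut * 10 ** rng.uniform(1, 4))))
    return pd.DataFrame(rows, columns=["query", "subject", "evalue"])
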