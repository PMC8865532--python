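"""Expression quantification and differential-expression statistics.

Quantification follows the RPK/TPM convention: RPK = read count divided by
transcript length in kilobases; TPM rescales the per-sample RPK vector to
sum to one million.  Differential calls use a two-sided Fisher exact test
on pooled group counts (gene vs rest-of-library), Benjamini-Hochberg FDR,
and three conjunctive call rules: fold change >= 3 (or <= 1/3 for down),
FDR below 0.05, and a mean-TPM floor of 0.5 in at least one group.

Fruiting-related genes (FRGs) are genes up-regulated in fruiting bodies
relative to BOTH monokaryotic and dikaryotic vegetative mycelia; the same
machinery with swapped direction yields vegetative-phase gene sets.  FRGs
are partitioned by orthology into fruiting-body-initiation-gene (FBIG)
orthologs, fruiting-body-development-gene (FBDG) orthologs, genes with
some other ortholog, and species-specific genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

FC_THRESHOLD = 3.0
ALPHA = 0.05
TPM_FLOOR = 0.5
E_CUT_ORTHOLOG = 1e-5
E_CUT_FRG_SEARCH = 1e-17


@dataclass
class CountMatrix:
    """Genes x samples integer counts with transcript lengths and groups."""

    counts: pd.DataFrame            # index gene_id, columns sample_id
    lengths: pd.Series              # bp per gene
    groups: Mapping[str, str]       # sample_id -> group label

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(np.int64)
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any() or (self.lengths <= 0).any():
            raise ValueError("every gene needs a positive transcript length")
        missing = set(self.counts.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        cols = [s for s in self.counts.columns if self.groups[s] == group]
        if not cols:
            raise ValueError(f"no sample in group {group!r}")
        return cols

    # -- TSV round trip ------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_path: str | Path, groups_path: str | Path) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        lengths = df.pop("length")
        gmap = pd.read_csv(groups_path, sep="\t", index_col=0)["group"].to_dict()
        return cls(df, lengths, gmap)

    def to_tsv(self, counts_path: str | Path, groups_path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(counts_path, sep="\t", index_label="gene_id")
        pd.Series(dict(self.groups), name="group").rename_axis("sample_id").to_csv(
            groups_path, sep="\t"
        )


# ---------------------------------------------------------------------------
# Quantification
# ---------------------------------------------------------------------------

def rpk(count: float, transcript_length: int) -> float:
    """Reads per kilobase of transcript: count / (length / 1000)."""
    if transcript_length <= 0:
        raise ValueError("transcript length must be positive")
    return count / (transcript_length / 1000.0)


def tpm(matrix: CountMatrix) -> pd.DataFrame:
    """Transcripts per million: per-sample RPK scaled to sum to 1e6.

    All-zero samples stay all zero.
    """
    rpk_table = matrix.counts.div(matrix.lengths / 1000.0, axis=0)
    sums = rpk_table.sum(axis=0)
    out = rpk_table.div(sums.replace(0, np.nan), axis=1) * 1e6
    return out.fillna(0.0)


def fpkm(count: float, transcript_length: int, library_size: int) -> float:
    """Fragments per kilobase per million mapped reads."""
    if transcript_length <= 0 or library_size <= 0:
        raise ValueError("length and library size must be positive")
    return count * 1e9 / (transcript_length * library_size)


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def fisher_exact_de(
    gene_count_a: int, rest_a: int, gene_count_b: int, rest_b: int
) -> float:
    """Two-sided Fisher exact p for the 2x2 table (gene vs rest of library,
    condition A vs B): the sum of hypergeometric probabilities no larger
    than that of the observed table."""
    for v in (gene_count_a, rest_a, gene_count_b, rest_b):
        if v < 0 or v != int(v):
            raise ValueError("counts must be non-negative integers")
    if gene_count_a + rest_a == 0 or gene_count_b + rest_b == 0:
        raise ValueError("both margins must be positive")
    _, p = stats.fisher_exact(
        [[gene_count_a, rest_a], [gene_count_b, rest_b]], alternative="two-sided"
    )
    return float(min(p, 1.0))


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_deg(
    matrix: CountMatrix,
    group_a: str,
    group_b: str,
    fc: float = FC_THRESHOLD,
    alpha: float = ALPHA,
    tpm_floor: float = TPM_FLOOR,
    pseudocount_tpm: float = 0.0,
    use_raw_p: bool = False,
    test_fn: Callable[[int, int, int, int], float] | None = None,
) -> pd.DataFrame:
    """Differential expression contrast of group A versus group B.

    Per gene: p-value from the pooled-count Fisher exact test (pluggable
    via ``test_fn``), BH FDR, fold change on group-mean TPM (zero
    denominators map to +inf unless a pseudocount is given), and a call in
    {up, down, ns} requiring |log fold| past the threshold, FDR (or raw p
    with ``use_raw_p``) below ``alpha``, and mean TPM above ``tpm_floor``
    in at least one group.
    """
    test = test_fn or fisher_exact_de
    cols_a = matrix.samples_in(group_a)
    cols_b = matrix.samples_in(group_b)
    pooled_a = matrix.counts[cols_a].sum(axis=1).to_numpy()
    pooled_b = matrix.counts[cols_b].sum(axis=1).to_numpy()
    total_a, total_b = int(pooled_a.sum()), int(pooled_b.sum())
    tpm_table = tpm(matrix)
    mean_a = tpm_table[cols_a].mean(axis=1).to_numpy() + pseudocount_tpm
    mean_b = tpm_table[cols_b].mean(axis=1).to_numpy() + pseudocount_tpm

    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            mean_b > 0, mean_a / mean_b, np.where(mean_a > 0, np.inf, np.nan)
        )

    pvals = np.array(
        [
            test(int(a), total_a - int(a), int(b), total_b - int(b))
            for a, b in zip(pooled_a, pooled_b)
        ]
    )
    fdr = bh_fdr(pvals)
    signif = (pvals if use_raw_p else fdr) < alpha
    floor_ok = np.maximum(mean_a - pseudocount_tpm, mean_b - pseudocount_tpm) > tpm_floor

    call = np.full(len(fold), "ns", dtype=object)
    up = signif & floor_ok & (fold >= fc)
    down = signif & floor_ok & ~np.isnan(fold) & (fold <= 1.0 / fc)
    call[up] = "up"
    call[down] = "down"

    return pd.DataFrame(
        {
            "fold_change": fold,
            "p_value": pvals,
            "fdr": fdr,
            "mean_tpm_a": mean_a - pseudocount_tpm,
            "mean_tpm_b": mean_b - pseudocount_tpm,
            "call": call,
        },
        index=matrix.counts.index,
    )


# ---------------------------------------------------------------------------
# FRG classification
# ---------------------------------------------------------------------------

def classify_frg(
    deg_vs_mono: pd.DataFrame,
    deg_vs_di: pd.DataFrame,
    require_both: bool = True,
    direction: str = "up",
) -> set[str]:
    """Genes called in ``direction`` in both contrasts (default), or in
    either with ``require_both=False``.  The same machinery with
    direction="up" on mycelium-vs-FB contrasts yields vegetative sets."""
    if set(deg_vs_mono.index) != set(deg_vs_di.index):
        raise ValueError("contrasts computed on different gene universes")
    in_mono = set(deg_vs_mono.index[deg_vs_mono["call"] == direction])
    in_di = set(deg_vs_di.index[deg_vs_di["call"] == direction])
    return in_mono & in_di if require_both else in_mono | in_di


def _hit_subjects(ortholog_hits: pd.DataFrame, e_cut: float) -> pd.DataFrame:
    required = {"query", "subject", "evalue"}
    if not required <= set(ortholog_hits.columns):
        raise ValueError(f"ortholog table needs columns {sorted(required)}")
    if (ortholog_hits["evalue"] < 0).any():
        raise ValueError("negative e-value")
    return ortholog_hits[ortholog_hits["evalue"] <= e_cut]


def venn_classes(
    frg_set: set[str],
    ortholog_hits: pd.DataFrame,
    fbig_ids: set[str],
    fbdg_ids: set[str],
    e_cut: float = E_CUT_ORTHOLOG,
) -> dict[str, set[str]]:
    """Partition FRGs by orthology to the reference mushroom's gene sets.

    Classes (exhaustive, disjoint; FBIG takes precedence over FBDG):
    ``fbig_ortholog``, ``fbdg_ortholog``, ``other_ortholog`` (has an
    ortholog that is neither), ``species_specific`` (no ortholog at all).
    """
    kept = _hit_subjects(ortholog_hits, e_cut)
    by_query: dict[str, set[str]] = (
        kept.groupby("query")["subject"].agg(set).to_dict()
    )
    out: dict[str, set[str]] = {
        "fbig_ortholog": set(),
        "fbdg_ortholog": set(),
        "other_ortholog": set(),
        "species_specific": set(),
    }
    for gene in frg_set:
        subjects = by_query.get(gene, set())
        if not subjects:
            out["species_specific"].add(gene)
        elif subjects & fbig_ids:
            out["fbig_ortholog"].add(gene)
        elif subjects & fbdg_ids:
            out["fbdg_ortholog"].add(gene)
        else:
            out["other_ortholog"].add(gene)
    return out


def fbig_coverage(
    ortholog_hits: pd.DataFrame,
    fbig_ids: set[str],
    e_cut: float = E_CUT_ORTHOLOG,
) -> tuple[int, float]:
    """How many reference FB-initiation genes have >= 1 homolog.

    Returns (count, percent of the FBIG set, rounded to one decimal).
    """
    if not fbig_ids:
        raise ValueError("fbig_ids must be non-empty")
    kept = _hit_subjects(ortholog_hits, e_cut)
    covered = set(kept["subject"]) & set(fbig_ids)
    count = len(covered)
    return count, round(count / len(fbig_ids) * 100, 1)
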