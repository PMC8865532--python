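"""Shared fixtures: small hand-built annotations and seeded simulations."""

from __future__ import annotations

import numpy as np
import pytest

from mycomine.cazgc import GeneRole, SignatureTable
from mycomine.core_io import ChromosomeRecord, GeneRecord, GenomeAnnotation
from mycomine import synthetic_data as sd


def make_chromosome_annotation(
    roles: str,
    chrom: str = "chr1",
    gene_len: int = 100,
    gap: int = 50,
    chrom_pad: int = 500,
) -> tuple[GenomeAnnotation, SignatureTable]:
    """Build one chromosome from a role string (C/T/F/. per gene, evenly
    spaced), e.g. ``"..CCC.."``.  Gene ids are ``g0, g1, ...`` by rank."""
    genes = []
    role_map = {}
    pos = 1
    for i, ch in enumerate(roles):
        gid = f"g{i}"
        genes.append(GeneRecord(gid, chrom, pos, pos + gene_len - 1))
        role = {"C": "cazyme", "T": "transporter", "F": "transcription_factor",
                ".": "other"}[ch]
        if role == "cazyme":
            role_map[gid] = GeneRole("cazyme", ("GH5",))
        elif role != "other":
            role_map[gid] = GeneRole(role)
        pos += gene_len + gap
    length = pos + chrom_pad
    ann = GenomeAnnotation([ChromosomeRecord(chrom, length)], genes)
    return ann, SignatureTable(role_map)


def random_instance(seed: int) -> tuple[GenomeAnnotation, SignatureTable]:
    """A random <= 20-gene chromosome with random roles, for oracle checks."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 21))
    roles = "".join(
        rng.choice(list("CTF...."), size=n, p=[0.3, 0.1, 0.1, *([0.5 / 4] * 4)])
    )
    return make_chromosome_annotation(
        roles, gene_len=int(rng.integers(50, 300)), gap=int(rng.integers(10, 400))
    )


@pytest.fixture(scope="session")
def genome_sim() -> sd.GenomeSim:
    return sd.generate_genome(sd.GenomeSimSpec(seed=11))


@pytest.fixture(scope="session")
def expr_sim() -> sd.ExprSim:
    return sd.generate_counts(sd.ExprSimSpec(seed=7))
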