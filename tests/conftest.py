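import numpy as np
import pytest

from anomito.mitoio import GeneFeature, MitoGenome
from anomito.synthetic import (CRSpec, SyntheticGenomeSpec, evolve_codon_pair,
                               generate_genome)


@pytest.fixture(scope="session")
def synthetic_genome():
    """One deterministic synthetic genome with its truth bundle."""
    return generate_genome(SyntheticGenomeSpec(seed=42))


@pytest.fixture(scope="session")
def genome_pair_omega01():
    """Two annotated genomes whose 13 PCGs share ancestors evolved at
    omega = 0.1 (moderate synonymous divergence)."""
    from anomito.mitoio import PCGS
    from anomito.synthetic import CodonPairSpec, _PCG_CODONS

    genomes = []
    seqs1, seqs2 = {}, {}
    for k, gene in enumerate(sorted(PCGS)):
        s1, s2, _ = evolve_codon_pair(CodonPairSpec(
            n_codons=_PCG_CODONS[gene], omega=0.1, t=0.4, seed=1000 + k))
        seqs1[gene], seqs2[gene] = s1 + "TAA", s2 + "TAA"
    for acc, seqs in (("PAIRA01", seqs1), ("PAIRB01", seqs2)):
        features, pieces, pos = [], [], 0
        for gene in sorted(seqs):
            seq = seqs[gene]
            features.append(GeneFeature(gene, pos + 1, pos + len(seq),
                                        "+", "PCG"))
            pieces.append(seq)
            pos += len(seq)
        genomes.append(MitoGenome(acc, f"Synthetic {acc}", "".join(pieces),
                                  features=features))
    return tuple(genomes)


def random_feature_genome(rng: np.random.Generator) -> MitoGenome:
    """A cheap random annotated genome (random gene subset and gaps)."""
    from anomito.mitoio import GENE_VOCABULARY

    genes = [g for g in GENE_VOCABULARY if g != "CR"]
    k = int(rng.integers(5, 20))
    chosen = list(rng.choice(genes, size=k, replace=False))
    pos = int(rng.integers(1, 50))
    feats = []
    for g in chosen:
        length = int(rng.integers(50, 400))
        feats.append(GeneFeature(g, pos, pos + length - 1,
                                 "+" if rng.random() < 0.7 else "-",
                                 "PCG" if g in ("cox1", "nad5") else "tRNA"))
        pos += length + int(rng.integers(0, 900))
    total = pos + int(rng.integers(0, 500))
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=total)])
    return MitoGenome("RND", "random", seq, features=feats)
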