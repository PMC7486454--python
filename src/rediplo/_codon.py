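"""Codon-level utilities shared by the simulator and the Ka/Ks estimator.

Implements the Nei–Gojobori (1986) style counting primitives:
synonymous/nonsynonymous site fractions per codon and pathway-averaged
difference counts per codon pair, under the standard genetic code.
Substitutions that create a stop codon count as nonsynonymous when sites
are enumerated; mutational pathways passing through a stop codon are
excluded from the pathway average.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

BASES = "ACGT"

# Standard genetic code, DNA alphabet.
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")
SENSE_CODONS = tuple(sorted(c for c, aa in CODON_TABLE.items() if aa != "*"))

PURINES = frozenset("AG")

TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def is_transition(b1: str, b2: str) -> bool:
    return TRANSITION[b1] == b2


def is_stop(codon: str) -> bool:
    return codon in STOP_CODONS


def translate(codon: str) -> str:
    return CODON_TABLE[codon]


@lru_cache(maxsize=None)
def site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts (S, N) of one codon.

    Every one of the nine single-nucleotide changes is classified:
    synonymous if the encoded amino acid is unchanged, nonsynonymous
    otherwise (changes to stop codons are nonsynonymous).  S is the sum
    over the three positions of (synonymous changes at that position)/3,
    and N = 3 - S.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon} has no site counts")
    aa = CODON_TABLE[codon]
    syn = 0.0
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE[mutant] == aa:
                syn += 1.0
    s = syn / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def pathway_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) differences per codon pair.

    For codons differing at d positions, all d! orderings of the single-base
    steps are enumerated with equal weights; orderings passing through a stop
    codon are discarded.  If every pathway is blocked by a stop, each step is
    classified directly against the endpoint amino acids (rare fallback so
    the difference count is never silently dropped).
    """
    if codon_a == codon_b:
        return 0.0, 0.0
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    syn_tot = 0.0
    nonsyn_tot = 0.0
    n_paths = 0
    for order in itertools.permutations(diff_pos):
        current = codon_a
        syn = 0.0
        nonsyn = 0.0
        blocked = False
        for pos in order:
            nxt = current[:pos] + codon_b[pos] + current[pos + 1:]
            if nxt in STOP_CODONS:
                blocked = True
                break
            if CODON_TABLE[current] == CODON_TABLE[nxt]:
                syn += 1.0
            else:
                nonsyn += 1.0
            current = nxt
        if not blocked:
            syn_tot += syn
            nonsyn_tot += nonsyn
            n_paths += 1
    if n_paths == 0:
        # all pathways run through stops: classify steps independently
        syn = sum(
            1.0
            for i in diff_pos
            if CODON_TABLE[codon_a] == CODON_TABLE[codon_b] and len(diff_pos) == 1
        )
        return syn, float(len(diff_pos)) - syn
    return syn_tot / n_paths, nonsyn_tot / n_paths


# Fourfold-degenerate codon families: the first two bases fix the amino acid
# whatever the third base is.
FOURFOLD_PREFIXES = frozenset(
    p
    for p in ("".join(t) for t in itertools.product(BASES, repeat=2))
    if len({CODON_TABLE[p + b] for b in BASES}) == 1
)


def is_fourfold(codon: str) -> bool:
    return codon[:2] in FOURFOLD_PREFIXES


def synonymous_single_changes(codon: str) -> list[tuple[int, str]]:
    """All (position, base) single-nucleotide changes that are synonymous."""
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for b in BASES:
            if b == codon[pos]:
                continue
            if CODON_TABLE[codon[:pos] + b + codon[pos + 1:]] == aa:
                out.append((pos, b))
    return out
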