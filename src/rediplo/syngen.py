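"""Forward simulator of a recently duplicated (post-WGD) genome.

The generator emulates the situation in a young autotetraploid: an ancestral
genome is duplicated in full, the two copies then evolve independently for
``divergence_time`` years at a synonymous substitution rate ``syn_rate``
(defaults 1.23 My and 3.51e-9 /site/yr, so the expected pairwise synonymous
divergence between copies is 2rT ≈ 0.0086).  After the substitution phase,
transposon copies and random-sequence indels are inserted independently into
each lineage, with TA target-site preference, a point-mutation hot zone
within ``hypermut_radius`` of each insertion, population SNPs laid down as a
Poisson process (elevated inside the hot zones), and a gene × tissue FPKM
matrix in which transposon-overlapping genes are silenced less often and the
overlapped member of a mixed ohnolog pair is expression-boosted.

Everything is driven by one integer seed; identical configuration gives
byte-identical output files.  Ground truth (ohnolog map, insertions,
hypermutated intervals, expression effects) is recorded so downstream
estimators can be scored.
"""

from __future__ import annotations

import dataclasses
import json
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from ._codon import (
    CODON_TABLE,
    SENSE_CODONS,
    STOP_CODONS,
    site_counts,
)
from .io import (
    GeneModel,
    write_expression,
    write_fasta,
    write_gff3,
    write_te_table,
    write_vcf,
)

_BASES = "ACGT"
_ENC = {b: i for i, b in enumerate(_BASES)}  # A=0 C=1 G=2 T=3


@dataclasses.dataclass(frozen=True)
class TEFamily:
    """A transposon family available to the simulator.

    ``copy_count`` sets the family's share of inserted copies; ``burst_age``
    (years) is the mean age of the expansion burst, and per-copy ages are
    drawn Normal(burst_age, age_sd) truncated at zero.  Copies are mutated
    away from a random family consensus by age × syn_rate substitutions per
    site, so percent divergence from consensus reconstructs the burst.
    """

    name: str
    te_class: str
    consensus_len: int
    copy_count: int
    burst_age: float
    age_sd: float = 4.0e5


DEFAULT_TE_FAMILIES = (
    TEFamily("TcMar-Tc1", "DNA", 1600, 130, 3.0e6),
    TEFamily("hAT-Ac", "DNA", 1100, 100, 3.0e6),
    TEFamily("L2", "LINE", 2400, 90, 3.0e6),
    TEFamily("Rex-Babar", "LINE", 1900, 80, 3.0e6),
)


@dataclasses.dataclass
class SimulationConfig:
    seed: int = 0
    n_contigs: int = 4
    contig_len: int = 500_000
    gc_content: float = 0.42
    n_genes_per_contig: int = 60
    cds_len: int = 1500
    utr_len: int = 1000
    divergence_time: float = 1.23e6
    syn_rate: float = 3.51e-9
    omega: float = 0.2
    kappa: float = 2.0
    intergenic_rate: float | None = None  # defaults to syn_rate
    te_families: tuple[TEFamily, ...] = DEFAULT_TE_FAMILIES
    te_indel_fraction: float = 0.85
    ta_preference: float = 0.8
    cds_insertion_prob: float = 0.05
    hypermut_radius: int = 500
    hypermut_multiplier: float = 3.0
    snp_rate_per_kb: float = 5.0
    n_tissues: int = 15
    fpkm_lognormal_params: tuple[float, float] = (3.0, 1.2)
    silencing_prob: float = 0.3
    te_activation_boost: float = 0.15
    o_pair_log2fc: float = 1.0
    tissue_noise_sigma: float = 0.3
    off_threshold: float = 1.0

    def validate(self) -> None:
        if self.cds_len % 3:
            raise ValueError("cds_len must be a multiple of 3")
        for name in ("gc_content", "te_indel_fraction", "ta_preference",
                     "cds_insertion_prob", "silencing_prob",
                     "te_activation_boost"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for name in ("syn_rate", "kappa"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.divergence_time < 0 or self.omega < 0:
            raise ValueError("divergence_time and omega must be ≥ 0")
        if self.hypermut_multiplier < 1:
            raise ValueError("hypermut_multiplier must be ≥ 1")
        slot = self.contig_len // max(self.n_genes_per_contig, 1)
        span = self.cds_len + 2 * self.utr_len
        if self.n_genes_per_contig and slot < span + 400:
            raise ValueError(
                f"genes cannot fit: need ≥{span + 400} bp per gene slot, "
                f"have {slot}"
            )

    @property
    def branch_length(self) -> float:
        """Expected substitutions per synonymous site on one lineage (rT)."""
        return self.syn_rate * self.divergence_time

    @property
    def expected_ks(self) -> float:
        return 2.0 * self.branch_length


@dataclasses.dataclass
class SimulationTruth:
    ohnolog_map: dict[str, str] = dataclasses.field(default_factory=dict)
    te_insertions: list = dataclasses.field(default_factory=list)
    non_te_indels: list = dataclasses.field(default_factory=list)
    hypermut_intervals: dict[str, list] = dataclasses.field(default_factory=dict)
    expression_effects: dict = dataclasses.field(default_factory=dict)
    expected_ks: float = 0.0
    syn_changes: dict[str, tuple[int, float]] = dataclasses.field(default_factory=dict)
    warnings: list[str] = dataclasses.field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "ohnolog_map": self.ohnolog_map,
            "te_insertions": self.te_insertions,
            "non_te_indels": self.non_te_indels,
            "hypermut_intervals": self.hypermut_intervals,
            "expression_effects": {
                g: {"activated": bool(a), "boost": float(b)}
                for g, (a, b) in self.expression_effects.items()
            },
            "expected_ks": self.expected_ks,
            "syn_changes": {g: [int(n), float(s)] for g, (n, s) in self.syn_changes.items()},
            "warnings": self.warnings,
        }
        Path(path).write_text(json.dumps(payload, indent=1))


# ----------------------------------------------------------------- encoding

def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    out = np.full(arr.shape, 255, dtype=np.uint8)
    for b, i in _ENC.items():
        out[arr == ord(b)] = i
    return out


_DECODE_TABLE = np.frombuffer(b"ACGTN", dtype=np.uint8)


def _decode_fast(enc: np.ndarray) -> str:
    return _DECODE_TABLE[np.minimum(enc, 4)].tobytes().decode()


def _random_dna(n: int, gc: float, rng: np.random.Generator) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=n, p=p).astype(np.uint8)


def _substitute(enc: np.ndarray, positions: np.ndarray, kappa: float,
                rng: np.random.Generator) -> None:
    """Kappa-weighted point substitutions in place (A<->G, C<->T transitions)."""
    if positions.size == 0:
        return
    cur = enc[positions]
    p_ts = kappa / (kappa + 2.0)
    u = rng.random(positions.size)
    new = np.where(u < p_ts, cur ^ 2,
                   np.where(u < p_ts + (1 - p_ts) / 2, cur ^ 1, cur ^ 3))
    enc[positions] = new.astype(np.uint8)


# ------------------------------------------------------------ ancestral genome

def _random_cds(n_codons: int, rng: np.random.Generator) -> str:
    """ATG + random sense codons + stop; no internal stops."""
    body = rng.choice(SENSE_CODONS, size=n_codons - 2)
    stop = rng.choice(("TAA", "TAG", "TGA"))
    return "ATG" + "".join(body) + stop


def simulate_ancestral_genome(config: SimulationConfig,
                              rng: np.random.Generator | None = None
                              ) -> tuple[dict[str, str], list[GeneModel]]:
    """Build the pre-duplication genome: random contigs at the requested GC
    with non-overlapping genes (gene body = 5'UTR + CDS + 3'UTR) on random
    strands."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sequences: dict[str, str] = {}
    genes: list[GeneModel] = []
    span = config.cds_len + 2 * config.utr_len
    for ci in range(config.n_contigs):
        contig = f"ctg{ci + 1:02d}"
        enc = _random_dna(config.contig_len, config.gc_content, rng)
        if config.n_genes_per_contig:
            slot = config.contig_len // config.n_genes_per_contig
            for gi in range(config.n_genes_per_contig):
                lo = gi * slot + 100
                hi = (gi + 1) * slot - span - 100
                start = int(rng.integers(lo, max(hi, lo + 1)))
                strand = "+" if rng.random() < 0.5 else "-"
                cds = _random_cds(config.cds_len // 3, rng)
                cds_enc = _encode(cds)
                if strand == "-":
                    cds_enc = (cds_enc[::-1] ^ 3).astype(np.uint8)
                cds_start = start + config.utr_len
                enc[cds_start:cds_start + config.cds_len] = cds_enc
                genes.append(GeneModel(
                    gene_id=f"{contig}g{gi + 1:03d}", contig=contig,
                    start=start, end=start + span, strand=strand,
                    cds_start=cds_start, cds_end=cds_start + config.cds_len,
                ))
        sequences[contig] = _decode_fast(enc)
    return sequences, genes


# ------------------------------------------------------------ CDS evolution

@lru_cache(maxsize=None)
def _codon_syn_weight(codon: str, kappa: float) -> float:
    """Expected synonymous acceptances per proposal landing in this codon,
    summed over its 3 positions with kappa-weighted target choice."""
    total = 0.0
    aa = CODON_TABLE[codon]
    for pos in range(3):
        ref = codon[pos]
        for b in _BASES:
            if b == ref:
                continue
            w = kappa if {ref, b} in ({"A", "G"}, {"C", "T"}) else 1.0
            mutant = codon[:pos] + b + codon[pos + 1:]
            if CODON_TABLE.get(mutant) == aa:
                total += w / (kappa + 2.0)
    return total


@lru_cache(maxsize=None)
def _nonsyn_changes(codon: str) -> tuple[tuple[int, str], ...]:
    """All (position, base) single changes that swap the amino acid without
    creating a stop."""
    aa = CODON_TABLE[codon]
    out = []
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mutant = codon[:pos] + b + codon[pos + 1:]
            maa = CODON_TABLE[mutant]
            if maa != aa and maa != "*":
                out.append((pos, b))
    return tuple(out)


def evolve_cds(cds: str, branch_length: float, omega: float, kappa: float,
               rng: np.random.Generator) -> tuple[str, int, int]:
    """Evolve one coding sequence along one lineage.

    Point mutations are proposed as a Poisson process and accepted with
    probability 1 if synonymous, ``omega`` if nonsynonymous, 0 if they
    create a stop codon.  The proposal intensity is calibrated so the
    expected number of accepted synonymous changes equals S × branch_length,
    with S the NG86 synonymous site count of the sequence — i.e. the
    realized Ks matches the nominal branch length.  For omega > 1 (positive
    selection) nonsynonymous proposals are always accepted and additional
    directed amino-acid changes are drawn so the expected nonsynonymous
    divergence per nonsynonymous site reaches omega × branch_length.  The
    start codon and the terminal stop are held fixed.

    Returns (evolved_cds, n_synonymous, n_nonsynonymous).
    """
    codons = [cds[i:i + 3] for i in range(0, len(cds), 3)]
    first = 1  # keep ATG
    last = len(codons) - 1 if codons[-1] in STOP_CODONS else len(codons)
    mutable = list(range(first, last))
    if not mutable or branch_length <= 0:
        return cds, 0, 0
    S = sum(site_counts(codons[i])[0] for i in mutable)
    p_syn = sum(_codon_syn_weight(codons[i], kappa) for i in mutable) / (
        3.0 * len(mutable))
    if p_syn <= 0:
        return cds, 0, 0
    n_prop = rng.poisson(S * branch_length / p_syn)
    p_ts = kappa / (kappa + 2.0)
    n_syn = n_nonsyn = 0
    for _ in range(n_prop):
        idx = mutable[int(rng.integers(len(mutable)))]
        pos = int(rng.integers(3))
        codon = codons[idx]
        ref = codon[pos]
        u = rng.random()
        if u < p_ts:
            new_base = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
        else:
            tvs = [b for b in _BASES if b != ref
                   and {ref, b} not in ({"A", "G"}, {"C", "T"})]
            new_base = tvs[0] if u < p_ts + (1 - p_ts) / 2 else tvs[1]
        mutant = codon[:pos] + new_base + codon[pos + 1:]
        if mutant in STOP_CODONS:
            continue
        if CODON_TABLE[mutant] == CODON_TABLE[codon]:
            codons[idx] = mutant
            n_syn += 1
        elif rng.random() < min(omega, 1.0):
            codons[idx] = mutant
            n_nonsyn += 1
    if omega > 1.0:
        # directed amino-acid changes on top of the neutral proposal flux
        N = 3.0 * len(mutable) - S
        n_extra = rng.poisson(N * branch_length * (omega - 1.0))
        for _ in range(n_extra):
            idx = mutable[int(rng.integers(len(mutable)))]
            choices = _nonsyn_changes(codons[idx])
            if not choices:
                continue
            pos, b = choices[int(rng.integers(len(choices)))]
            codons[idx] = codons[idx][:pos] + b + codons[idx][pos + 1:]
            n_nonsyn += 1
    return "".join(codons), n_syn, n_nonsyn


def _revcomp_enc(enc: np.ndarray) -> np.ndarray:
    return (enc[::-1] ^ 3).astype(np.uint8)


def apply_wgd_and_evolve(sequences: dict[str, str], genes: list[GeneModel],
                         config: SimulationConfig,
                         rng: np.random.Generator,
                         ) -> tuple[dict[str, str], list[GeneModel], SimulationTruth]:
    """Duplicate every contig into an _R1 and _R2 copy and evolve both
    independently: codon-aware propose/accept substitutions inside CDS,
    kappa-weighted substitutions at rate ``intergenic_rate × T`` elsewhere."""
    truth = SimulationTruth(expected_ks=config.expected_ks)
    bl = config.branch_length
    inter_bl = (config.intergenic_rate or config.syn_rate) * config.divergence_time
    if config.expected_ks >= 0.75:
        truth.warnings.append(
            f"expected_ks={config.expected_ks:.3f} ≥ 0.75: Jukes–Cantor "
            "correction undefined at this divergence"
        )
    out_seqs: dict[str, str] = {}
    out_genes: list[GeneModel] = []
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)
    syn_counts: dict[str, list] = {}
    for contig in sequences:
        base_enc = _encode(sequences[contig])
        for lineage in ("R1", "R2"):
            enc = base_enc.copy()
            cds_mask = np.zeros(enc.size, dtype=bool)
            for g in genes_by_contig.get(contig, []):
                cds_str = sequences[contig][g.cds_start:g.cds_end]
                if g.strand == "-":
                    cds_str = _decode_fast(_revcomp_enc(_encode(cds_str)))
                evolved, n_syn, _ = evolve_cds(cds_str, bl, config.omega,
                                               config.kappa, rng)
                S_anc = sum(site_counts(evolved[i:i + 3])[0]
                            for i in range(3, len(evolved) - 3, 3))
                ev_enc = _encode(evolved)
                if g.strand == "-":
                    ev_enc = _revcomp_enc(ev_enc)
                enc[g.cds_start:g.cds_end] = ev_enc
                cds_mask[g.cds_start:g.cds_end] = True
                rec = syn_counts.setdefault(g.gene_id, [0, 0.0])
                rec[0] += n_syn
                rec[1] = S_anc
            # non-coding substitutions
            noncds = np.flatnonzero(~cds_mask)
            n_sub = rng.poisson(noncds.size * inter_bl)
            if n_sub:
                picks = rng.choice(noncds, size=min(n_sub, noncds.size),
                                   replace=False)
                _substitute(enc, picks, config.kappa, rng)
            name = f"{contig}_{lineage}"
            out_seqs[name] = _decode_fast(enc)
            for g in genes_by_contig.get(contig, []):
                out_genes.append(dataclasses.replace(
                    g, gene_id=f"{g.gene_id}_{lineage}", contig=name))
    for g in genes:
        truth.ohnolog_map[f"{g.gene_id}_R1"] = f"{g.gene_id}_R2"
        truth.syn_changes[g.gene_id] = tuple(syn_counts[g.gene_id])
    return out_seqs, out_genes, truth


# ------------------------------------------------------------- transposons

def _find_ta(enc: np.ndarray) -> np.ndarray:
    """Positions i where enc[i:i+2] spells TA (insertion goes between)."""
    return np.flatnonzero((enc[:-1] == 3) & (enc[1:] == 0))


def insert_transposons(sequences: dict[str, str], genes: list[GeneModel],
                       config: SimulationConfig, truth: SimulationTruth,
                       rng: np.random.Generator,
                       ) -> tuple[dict[str, str], list[GeneModel], pd.DataFrame]:
    """Place post-WGD indels independently per lineage.

    A fraction ``te_indel_fraction`` of the indels are transposon copies
    (family drawn ∝ copy_count, sequence = consensus mutated by the copy's
    sampled age), the rest are random sequence 100–2000 bp.  Insertion sites
    fall inside a TA dinucleotide with probability ``ta_preference`` and
    uniformly otherwise; proposals landing in a CDS are accepted only with
    probability ``cds_insertion_prob`` (purifying selection against coding
    disruptions).  Every insertion registers a ±hypermut_radius interval in
    the truth table, and the carrier lineage receives extra point mutations
    in those flanks at (hypermut_multiplier − 1) × syn_rate × T per site —
    the insertional-mutagenesis signal downstream stages test for.
    """
    fams = list(config.te_families)
    total = sum(f.copy_count for f in fams)
    if total == 0:
        empty = pd.DataFrame(columns=["contig", "start", "end", "family",
                                      "score", "strand", "te_class",
                                      "pct_divergence"])
        for contig in sequences:
            truth.hypermut_intervals[contig] = []
        return dict(sequences), list(genes), empty
    n_te = int(round(total * config.te_indel_fraction))
    n_non_te = total - n_te
    consensus = {
        f.name: _random_dna(f.consensus_len, 0.5, rng) for f in fams
    }
    fam_p = np.array([f.copy_count for f in fams], dtype=float)
    fam_p /= fam_p.sum()

    contig_names = list(sequences)
    lens = np.array([len(sequences[c]) for c in contig_names], dtype=float)
    contig_p = lens / lens.sum()

    # draw all insertion specs: (contig, kind, family_index, seq)
    specs: dict[str, list] = {c: [] for c in contig_names}
    fam_idx = rng.choice(len(fams), size=n_te, p=fam_p)
    te_contigs = rng.choice(len(contig_names), size=n_te, p=contig_p)
    for fi, ci in zip(fam_idx, te_contigs):
        fam = fams[fi]
        age = max(0.0, rng.normal(fam.burst_age, fam.age_sd))
        div = age * config.syn_rate
        seq = consensus[fam.name].copy()
        nmut = rng.binomial(seq.size, min(div, 0.75))
        if nmut:
            pos = rng.choice(seq.size, size=nmut, replace=False)
            _substitute(seq, pos, config.kappa, rng)
        pct = 100.0 * nmut / seq.size
        specs[contig_names[ci]].append((fam, seq, pct))
    nt_contigs = rng.choice(len(contig_names), size=n_non_te, p=contig_p)
    for ci in nt_contigs:
        length = int(rng.integers(100, 2001))
        specs[contig_names[ci]].append((None, _random_dna(length, config.gc_content, rng), None))

    out_seqs: dict[str, str] = {}
    out_genes: list[GeneModel] = []
    te_rows = []
    genes_by_contig: dict[str, list[GeneModel]] = {}
    for g in genes:
        genes_by_contig.setdefault(g.contig, []).append(g)

    r = config.hypermut_radius
    for contig in contig_names:
        enc = _encode(sequences[contig])
        contig_specs = specs[contig]
        cds_iv = sorted((g.cds_start, g.cds_end)
                        for g in genes_by_contig.get(contig, []))
        cds_starts = np.array([s for s, _ in cds_iv])
        cds_ends = np.array([e for _, e in cds_iv])
        ta_pos = _find_ta(enc)

        def in_cds(p: int) -> bool:
            if cds_starts.size == 0:
                return False
            i = np.searchsorted(cds_starts, p, side="right") - 1
            return i >= 0 and p < cds_ends[i]

        positions = []
        for _fam, _seq, _pct in contig_specs:
            for _try in range(200):
                if ta_pos.size and rng.random() < config.ta_preference:
                    p = int(ta_pos[rng.integers(ta_pos.size)]) + 1
                else:
                    p = int(rng.integers(1, enc.size - 1))
                if not in_cds(p) or rng.random() < config.cds_insertion_prob:
                    break
            positions.append(p)

        order = np.argsort(positions, kind="stable")
        parts = []
        prev = 0
        offset = 0
        placed = []  # (final_start, final_end, fam, pct, length)
        for oi in order:
            fam, ins, pct = contig_specs[oi]
            p = positions[oi]
            parts.append(enc[prev:p])
            parts.append(ins)
            fs = p + offset
            fe = fs + ins.size
            placed.append((fs, fe, fam, pct, ins.size, p))
            offset += ins.size
            prev = p
        parts.append(enc[prev:])
        new_enc = np.concatenate(parts) if parts else enc
        lineage = contig.rsplit("_", 1)[-1]

        hyper = []
        for fs, fe, fam, pct, length, _p in placed:
            hyper.append((max(0, fs - r), min(new_enc.size, fe + r)))
            if fam is not None:
                te_rows.append((contig, fs, fe, fam.name, 0, "+",
                                fam.te_class, round(pct, 3)))
                truth.te_insertions.append(
                    {"contig": contig, "start": int(fs), "end": int(fe),
                     "family": fam.name, "length": int(length),
                     "lineage": lineage})
            else:
                truth.non_te_indels.append(
                    {"contig": contig, "start": int(fs), "length": int(length)})
        # merge hot intervals
        merged = []
        for s, e in sorted(hyper):
            if merged and s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        truth.hypermut_intervals[contig] = [[int(s), int(e)] for s, e in merged]

        # insertional mutagenesis on the carrier: extra substitutions in the
        # flanks (TE bodies excluded so copies keep their recorded divergence)
        extra = (config.hypermut_multiplier - 1.0) * config.branch_length
        if extra > 0 and placed:
            body = np.zeros(new_enc.size, dtype=bool)
            flank = np.zeros(new_enc.size, dtype=bool)
            for fs, fe, *_ in placed:
                body[fs:fe] = True
                flank[max(0, fs - r):min(new_enc.size, fe + r)] = True
            flank &= ~body
            cand = np.flatnonzero(flank)
            n_sub = rng.poisson(cand.size * extra)
            if n_sub:
                picks = rng.choice(cand, size=min(n_sub, cand.size), replace=False)
                _substitute(new_enc, picks, config.kappa, rng)

        # shift gene coordinates
        ins_pos = np.array([p for *_x, p in placed], dtype=int)
        ins_len = np.array([length for _fs, _fe, _fam, _pct, length, _p in placed],
                           dtype=int)
        sort_i = np.argsort(ins_pos, kind="stable")
        ins_pos, ins_len = ins_pos[sort_i], ins_len[sort_i]
        cum = np.concatenate([[0], np.cumsum(ins_len)])

        def shift(coord: int, before: bool) -> int:
            side = "right" if before else "left"
            return coord + int(cum[np.searchsorted(ins_pos, coord, side=side)])

        for g in genes_by_contig.get(contig, []):
            out_genes.append(dataclasses.replace(
                g,
                start=shift(g.start, False),
                end=shift(g.end, True),
                cds_start=shift(g.cds_start, False),
                cds_end=shift(g.cds_end, True),
            ))
        out_seqs[contig] = _decode_fast(new_enc)

    te = pd.DataFrame(te_rows, columns=["contig", "start", "end", "family",
                                        "score", "strand", "te_class",
                                        "pct_divergence"])
    return out_seqs, out_genes, te


# -------------------------------------------------------------------- SNPs

def simulate_population_snps(sequences: dict[str, str],
                             hypermut_intervals: dict[str, list],
                             config: SimulationConfig,
                             rng: np.random.Generator) -> pd.DataFrame:
    """Poisson SNPs at base rate snp_rate_per_kb, multiplied by
    hypermut_multiplier inside the recorded hot intervals."""
    rho = config.snp_rate_per_kb / 1000.0
    rows = []
    for contig, seq in sequences.items():
        L = len(seq)
        n0 = rng.poisson(rho * L)
        pos = rng.integers(0, L, size=n0)
        ivs = hypermut_intervals.get(contig, [])
        if ivs and config.hypermut_multiplier > 1:
            lens = np.array([e - s for s, e in ivs])
            n1 = rng.poisson(rho * (config.hypermut_multiplier - 1) * lens.sum())
            if n1:
                which = rng.choice(len(ivs), size=n1, p=lens / lens.sum())
                offs = rng.random(n1)
                extra = np.array([
                    int(ivs[w][0] + offs[k] * (ivs[w][1] - ivs[w][0]))
                    for k, w in enumerate(which)
                ])
                pos = np.concatenate([pos, extra])
        pos = np.unique(pos)
        enc = _encode(seq)
        refs = enc[pos]
        alts = (refs + rng.integers(1, 4, size=pos.size)) % 4
        for p, rb, ab in zip(pos, refs, alts):
            if rb > 3:
                continue
            rows.append((contig, int(p), _BASES[rb], _BASES[ab]))
    return pd.DataFrame(rows, columns=["contig", "pos", "ref", "alt"])


# -------------------------------------------------------------- expression

def simulate_expression(genes: list[GeneModel], ohnolog_map: dict[str, str],
                        te_table: pd.DataFrame, config: SimulationConfig,
                        truth: SimulationTruth,
                        rng: np.random.Generator) -> pd.DataFrame:
    """Gene × tissue FPKM matrix.

    Per-gene baseline is lognormal; in each tissue a gene is silenced
    (near-zero FPKM) with probability silencing_prob, reduced by
    te_activation_boost for TE-overlapping genes.  Within an ohnolog pair
    the silencing state is driven by one shared uniform draw per tissue
    (the duplicates inherit a common ancestral regulatory state), so the
    pair members fall silent together unless a TE has shifted one member's
    silencing probability — asymmetric TE insertion is what decouples
    expression.  In pairs where exactly one gene overlaps a TE, that gene's
    baseline is additionally raised by o_pair_log2fc log2 units.
    """
    from intervaltree import IntervalTree

    trees: dict[str, IntervalTree] = {}
    for row in te_table.itertuples(index=False):
        trees.setdefault(row.contig, IntervalTree()).addi(row.start, row.end)
    overlap = {
        g.gene_id: bool(trees.get(g.contig) and trees[g.contig].overlap(g.start, g.end))
        for g in genes
    }
    mu, sigma = config.fpkm_lognormal_params
    ln2 = np.log(2.0)
    baseline = {}
    boost = {}
    for g in genes:
        baseline[g.gene_id] = rng.normal(mu, sigma)
        boost[g.gene_id] = 0.0
    for ga, gb in ohnolog_map.items():
        if ga not in baseline or gb not in baseline:
            continue
        # ohnologs share their ancestral baseline plus small regulatory drift
        shared = rng.normal(mu, sigma)
        baseline[ga] = shared + rng.normal(0, 0.2)
        baseline[gb] = shared + rng.normal(0, 0.2)
        if overlap.get(ga) != overlap.get(gb):
            hit = ga if overlap.get(ga) else gb
            baseline[hit] += config.o_pair_log2fc * ln2
            boost[hit] = config.o_pair_log2fc
    tissues = [f"tissue{t + 1:02d}" for t in range(config.n_tissues)]
    partner = dict(ohnolog_map)
    partner.update({b: a for a, b in ohnolog_map.items()})
    # one shared silencing draw per pair per tissue
    pair_u: dict[str, np.ndarray] = {}
    for ga, gb in ohnolog_map.items():
        u = rng.random(len(tissues))
        pair_u[ga] = u
        pair_u[gb] = u
    mat = np.zeros((len(genes), len(tissues)))
    for i, g in enumerate(genes):
        p_off = config.silencing_prob - (
            config.te_activation_boost if overlap[g.gene_id] else 0.0)
        p_off = min(max(p_off, 0.0), 1.0)
        u = pair_u.get(g.gene_id)
        if u is None:
            u = rng.random(len(tissues))
        off = u < p_off
        vals = np.exp(baseline[g.gene_id]
                      + rng.normal(0, config.tissue_noise_sigma, len(tissues)))
        vals[off] = np.exp(rng.normal(np.log(0.05), 0.5, int(off.sum())))
        mat[i] = vals
        truth.expression_effects[g.gene_id] = (overlap[g.gene_id],
                                               boost[g.gene_id])
    return pd.DataFrame(mat, index=[g.gene_id for g in genes], columns=tissues)


# -------------------------------------------------------------- orchestration

@dataclasses.dataclass
class SimDataset:
    config: SimulationConfig
    ancestral_sequences: dict[str, str]
    ancestral_genes: list[GeneModel]
    sequences: dict[str, str]
    genes: list[GeneModel]
    te_table: pd.DataFrame
    snps: pd.DataFrame
    expression: pd.DataFrame
    truth: SimulationTruth

    @property
    def contig_lengths(self) -> dict[str, int]:
        return {c: len(s) for c, s in self.sequences.items()}


def simulate(config: SimulationConfig) -> SimDataset:
    """Run the full generator: ancestral genome → WGD + substitutions →
    transposon/indel insertion → population SNPs → expression."""
    config.validate()
    root = np.random.default_rng(config.seed)
    r_anc, r_evo, r_te, r_snp, r_expr = root.spawn(5)
    anc_seqs, anc_genes = simulate_ancestral_genome(config, r_anc)
    dup_seqs, dup_genes, truth = apply_wgd_and_evolve(anc_seqs, anc_genes,
                                                      config, r_evo)
    final_seqs, final_genes, te_table = insert_transposons(
        dup_seqs, dup_genes, config, truth, r_te)
    snps = simulate_population_snps(final_seqs, truth.hypermut_intervals,
                                    config, r_snp)
    expression = simulate_expression(final_genes, truth.ohnolog_map, te_table,
                                     config, truth, r_expr)
    return SimDataset(
        config=config,
        ancestral_sequences=anc_seqs,
        ancestral_genes=anc_genes,
        sequences=final_seqs,
        genes=final_genes,
        te_table=te_table,
        snps=snps,
        expression=expression,
        truth=truth,
    )


def write_all(ds: SimDataset, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "genes": outdir / "genes.gff3",
        "te": outdir / "te.bed",
        "vcf": outdir / "snps.vcf",
        "expression": outdir / "expression.tsv",
        "truth": outdir / "truth.json",
    }
    write_fasta(ds.sequences, paths["genome"])
    write_gff3(ds.genes, paths["genes"])
    write_te_table(ds.te_table, paths["te"])
    write_vcf(ds.snps, ds.contig_lengths, paths["vcf"])
    write_expression(ds.expression, paths["expression"])
    ds.truth.to_json(paths["truth"])
    return paths
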