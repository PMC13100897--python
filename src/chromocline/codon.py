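"""Standard-code codon machinery shared by the dN/dS estimator and the sequence simulator.

Everything here is precomputed once at import time from the standard nuclear
genetic code: per-codon synonymous/nonsynonymous site counts (Nei–Gojobori
style, mutations to stop codons counted as nonsynonymous so that S + N = 3
holds exactly for every sense codon), and pathway-averaged synonymous /
nonsynonymous difference counts for every ordered pair of sense codons
(uniform averaging over the k! single-step orderings, pathways through stop
codons excluded with renormalization).
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
from Bio.Data import CodonTable

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
STOP_CODONS = frozenset(_STANDARD.stop_codons)

#: codon string -> amino acid letter, stop codons mapped to "*"
AMINO_ACID = dict(_STANDARD.forward_table)
for _stop in STOP_CODONS:
    AMINO_ACID[_stop] = "*"

#: the 61 sense codons of the standard code, lexicographic order
SENSE_CODONS = tuple(sorted(c for c in AMINO_ACID if AMINO_ACID[c] != "*"))
SENSE_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
N_SENSE = len(SENSE_CODONS)

#: all 64 codons, lexicographic, for encoding arbitrary (incl. stop) codons
ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
ALL_INDEX = {c: i for i, c in enumerate(ALL_CODONS)}


def is_sense(codon: str) -> bool:
    return codon in SENSE_INDEX


def neighbors(codon: str):
    """All 9 single-nucleotide mutational neighbors of a codon (may include stops)."""
    out = []
    for pos in range(3):
        for alt in BASES:
            if alt != codon[pos]:
                out.append(codon[:pos] + alt + codon[pos + 1 :])
    return out


def _site_counts(codon: str) -> tuple[float, float]:
    syn = 0
    for nb in neighbors(codon):
        if AMINO_ACID[nb] == AMINO_ACID[codon] and nb not in STOP_CODONS:
            syn += 1
    s = syn / 3.0
    return s, 3.0 - s


# per-sense-codon site counts, indexed by SENSE_INDEX
SYN_SITES = np.empty(N_SENSE)
NONSYN_SITES = np.empty(N_SENSE)
for _i, _c in enumerate(SENSE_CODONS):
    SYN_SITES[_i], NONSYN_SITES[_i] = _site_counts(_c)


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Pathway-averaged (synonymous, nonsynonymous) difference counts c1 -> c2.

    Averages uniformly over all orderings of the differing positions.
    Orderings that pass through a stop codon are dropped and the remainder
    renormalized; in the (not observed for the standard code) case where every
    ordering is blocked, all orderings are used with steps into or out of a
    stop counted as nonsynonymous.
    """
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff):
        cur = c1
        steps = []
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                blocked = True
            steps.append(AMINO_ACID[cur] == AMINO_ACID[nxt] and not blocked)
            cur = nxt
        paths.append((blocked, steps))
    open_paths = [steps for blocked, steps in paths if not blocked]
    if not open_paths:  # fall back: count stop-crossing steps as nonsynonymous
        open_paths = [steps for _, steps in paths]
    sd = float(np.mean([sum(steps) for steps in open_paths]))
    return sd, len(diff) - sd


# pathway-averaged difference counts for every ordered pair of sense codons
PAIR_SD = np.zeros((N_SENSE, N_SENSE))
PAIR_ND = np.zeros((N_SENSE, N_SENSE))
for _i, _a in enumerate(SENSE_CODONS):
    for _j, _b in enumerate(SENSE_CODONS):
        if _i < _j:
            _sd, _nd = _pathway_counts(_a, _b)
            PAIR_SD[_i, _j] = PAIR_SD[_j, _i] = _sd
            PAIR_ND[_i, _j] = PAIR_ND[_j, _i] = _nd


def encode_sense(seq: str) -> np.ndarray:
    """Encode a coding sequence as an int array of sense-codon indices.

    Raises ValueError on length violations, non-ACGT characters, or stop codons.
    """
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    idx = np.empty(len(seq) // 3, dtype=np.int64)
    for k in range(0, len(seq), 3):
        codon = seq[k : k + 3]
        try:
            idx[k // 3] = SENSE_INDEX[codon]
        except KeyError:
            if codon in STOP_CODONS:
                raise ValueError(f"stop codon {codon} at codon position {k // 3}")
            raise ValueError(f"invalid codon {codon!r} at codon position {k // 3}")
    return idx


def decode(idx: np.ndarray) -> str:
    return "".join(SENSE_CODONS[i] for i in idx)
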