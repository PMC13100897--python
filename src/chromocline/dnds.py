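"""Pairwise synonymous / nonsynonymous substitution rate estimation (NG86).

Implements the Nei–Gojobori (1986) counting estimator: per-codon synonymous
and nonsynonymous site counts, pathway-averaged difference counts, and the
Jukes–Cantor multiple-hit correction, plus the record-level exclusion rules
used downstream (total-divergence thresholding and removal of orthologs that
moved between autosomes and the X chromosome in one of the two species).

The estimator operates on pre-aligned coding sequences. Codon columns in
which either sequence carries a gap or an ambiguous base are dropped pairwise
before counting; internal stop codons are an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from . import codon as _codon

__all__ = [
    "DnDsEstimate",
    "FilterReport",
    "codon_site_counts",
    "pairwise_differences",
    "jc_correct",
    "pairwise_dnds",
    "filter_estimates",
    "exclude_translocated",
]


@dataclass(frozen=True)
class DnDsEstimate:
    """Output of the pairwise counting estimator.

    ``S``/``N`` are synonymous / nonsynonymous site counts averaged over the
    two sequences, ``Sd``/``Nd`` pathway-averaged difference counts, ``pS``/
    ``pN`` the raw proportions, ``dS``/``dN`` their Jukes–Cantor corrections
    (NaN when saturated), ``omega`` = dN/dS (NaN when dS is 0 or undefined)
    and ``t`` = 3·(S·dS + N·dN)/(S + N), the expected number of substitutions
    per codon. ``valid`` is False whenever a correction saturated or a site
    class is empty.
    """

    S: float
    N: float
    Sd: float
    Nd: float
    pS: float
    pN: float
    dS: float
    dN: float
    omega: float
    t: float
    valid: bool
    n_codons: int


def codon_site_counts(codon: str) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each of the 9 single-nucleotide neighbors contributes 1/3 site to the
    synonymous class if it encodes the same amino acid (mutations to stop
    codons count as nonsynonymous), so the two counts always sum to 3.
    """
    if not _codon.is_sense(codon):
        raise ValueError(f"not a sense codon of the standard code: {codon!r}")
    i = _codon.SENSE_INDEX[codon]
    return float(_codon.SYN_SITES[i]), float(_codon.NONSYN_SITES[i])


def _clean_pair(seq1: str, seq2: str) -> tuple[np.ndarray, np.ndarray, int]:
    """Validate an aligned pair and drop gapped/ambiguous codon columns."""
    seq1, seq2 = seq1.upper(), seq2.upper()
    if len(seq1) != len(seq2):
        raise ValueError(f"aligned sequences differ in length: {len(seq1)} vs {len(seq2)}")
    if len(seq1) % 3 != 0:
        raise ValueError(f"alignment length {len(seq1)} is not a multiple of 3")
    keep1, keep2 = [], []
    n_dropped = 0
    for k in range(0, len(seq1), 3):
        c1, c2 = seq1[k : k + 3], seq2[k : k + 3]
        ok1, ok2 = all(b in _codon.BASES for b in c1), all(b in _codon.BASES for b in c2)
        if not (ok1 and ok2):
            n_dropped += 1
            continue
        if c1 in _codon.STOP_CODONS or c2 in _codon.STOP_CODONS:
            raise ValueError(f"stop codon in aligned pair at codon column {k // 3}")
        keep1.append(_codon.SENSE_INDEX[c1])
        keep2.append(_codon.SENSE_INDEX[c2])
    return np.asarray(keep1, dtype=np.int64), np.asarray(keep2, dtype=np.int64), n_dropped


def pairwise_differences(seq1: str, seq2: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) difference counts between two aligned CDSs.

    For a codon pair differing at k sites the synonymous / nonsynonymous
    change counts are averaged uniformly over the k! orderings of single-step
    pathways, excluding pathways through stop codons (renormalized).
    """
    i1, i2, _ = _clean_pair(seq1, seq2)
    return float(_codon.PAIR_SD[i1, i2].sum()), float(_codon.PAIR_ND[i1, i2].sum())


def jc_correct(p: float) -> float:
    """Jukes–Cantor correction −(3/4)·ln(1 − 4p/3); NaN at saturation (p ≥ 3/4)."""
    if p < 0:
        raise ValueError(f"proportion must be nonnegative, got {p}")
    if p >= 0.75:
        return math.nan
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def pairwise_dnds(seq1: str, seq2: str, method: str = "NG86") -> DnDsEstimate:
    """Estimate dS, dN, omega and t for one aligned coding sequence pair."""
    if method != "NG86":
        raise NotImplementedError(
            f"method {method!r} not implemented; NG86 is the supported estimator"
        )
    i1, i2, _ = _clean_pair(seq1, seq2)
    n_codons = len(i1)
    if n_codons == 0:
        raise ValueError("no analyzable codon columns after dropping gapped/ambiguous ones")
    S = 0.5 * (_codon.SYN_SITES[i1].sum() + _codon.SYN_SITES[i2].sum())
    N = 0.5 * (_codon.NONSYN_SITES[i1].sum() + _codon.NONSYN_SITES[i2].sum())
    Sd = float(_codon.PAIR_SD[i1, i2].sum())
    Nd = float(_codon.PAIR_ND[i1, i2].sum())
    pS = Sd / S if S > 0 else math.nan
    pN = Nd / N if N > 0 else math.nan
    dS = jc_correct(pS) if not math.isnan(pS) else math.nan
    dN = jc_correct(pN) if not math.isnan(pN) else math.nan
    valid = not (math.isnan(dS) or math.isnan(dN))
    omega = dN / dS if valid and dS > 0 else math.nan
    t = 3.0 * (S * dS + N * dN) / (S + N) if valid else math.nan
    return DnDsEstimate(
        S=float(S), N=float(N), Sd=Sd, Nd=Nd, pS=float(pS), pN=float(pN),
        dS=float(dS), dN=float(dN), omega=float(omega), t=float(t),
        valid=valid, n_codons=n_codons,
    )


@dataclass
class FilterReport:
    """Counts of records removed by each exclusion rule."""

    n_input: int
    n_invalid: int
    n_below_t_min: int
    n_above_t_max: int
    n_kept: int


def filter_estimates(
    records: pd.DataFrame, t_min: float = 0.01, t_max: float = 2.0
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the total-divergence filter: keep valid records with t in [t_min, t_max].

    The interval is closed — the thresholds exclude strictly smaller / larger
    divergences, so boundary values are retained.
    """
    if records.empty:
        return records.copy(), FilterReport(0, 0, 0, 0, 0)
    valid = records["valid"].astype(bool) & records["t"].notna()
    below = valid & (records["t"] < t_min)
    above = valid & (records["t"] > t_max)
    keep = valid & ~below & ~above
    report = FilterReport(
        n_input=len(records),
        n_invalid=int((~valid).sum()),
        n_below_t_min=int(below.sum()),
        n_above_t_max=int(above.sum()),
        n_kept=int(keep.sum()),
    )
    return records.loc[keep].copy(), report


def exclude_translocated(
    class_a: Mapping[str, str] | pd.Series, class_b: Mapping[str, str] | pd.Series
) -> tuple[list[str], list[str]]:
    """Retain orthologs whose autosome/X assignment agrees between the species.

    ``class_a`` and ``class_b`` map ortholog id -> chromosome class
    ("autosome" or "X") in each species. Returns (retained ids, removed ids);
    ids present in only one mapping raise ValueError.
    """
    a = dict(class_a)
    b = dict(class_b)
    if set(a) != set(b):
        missing = set(a) ^ set(b)
        raise ValueError(f"ortholog ids not matched between species: {sorted(missing)[:5]}")
    kept, removed = [], []
    for gid in a:
        (kept if a[gid] == b[gid] else removed).append(gid)
    return sorted(kept), sorted(removed)


def estimate_batch(
    pairs: Iterable[tuple[str, tuple[str, str]]], method: str = "NG86"
) -> pd.DataFrame:
    """Run pairwise_dnds over (gene_id, (seq1, seq2)) pairs into a table."""
    rows = []
    for gid, (s1, s2) in pairs:
        est = pairwise_dnds(s1, s2, method=method)
        rows.append({"gene_id": gid, **est.__dict__})
    return pd.DataFrame(rows)
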