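"""Seeded synthetic inputs with the statistical structure the analyses assume.

The generator emulates a shark-like karyotype — many chromosomes spanning a
wide length range with one short X — in which the expected synonymous rate of
a gene decays exponentially with distance from the nearest chromosome end
("chromocline"), the X carries a genome-wide multiplicative dS reduction
(male-driven evolution), GC is elevated toward chromosome ends, and male /
female read-depth tracks reflect male heterogamety (X at half depth in males,
Y male-only, pseudoautosomal regions at equal depth).

All simulators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import codon as _codon

__all__ = [
    "ChromosomeRecord",
    "Karyotype",
    "ClineParams",
    "DepthSimSpec",
    "simulate_karyotype",
    "add_y_scaffolds",
    "place_genes",
    "expected_ds",
    "simulate_codon_pair",
    "simulate_gene_rates",
    "simulate_depth_tracks",
    "simulate_gc_track",
    "simulate_gene_trees",
]

AUTOSOME = "autosome"
X = "X"
Y_CANDIDATE = "y-candidate"


@dataclass(frozen=True)
class ChromosomeRecord:
    """One scaffold/chromosome: id, length in bp, and class label."""

    id: str
    length: int
    chrom_class: str = AUTOSOME

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError(f"chromosome {self.id}: length must be positive")


@dataclass(frozen=True)
class Karyotype:
    """Ordered chromosome set, sorted by descending length."""

    chromosomes: tuple[ChromosomeRecord, ...]

    def __post_init__(self):
        ids = [c.id for c in self.chromosomes]
        if len(set(ids)) != len(ids):
            raise ValueError("chromosome ids must be unique")
        lens = [c.length for c in self.chromosomes]
        if any(a < b for a, b in zip(lens, lens[1:])):
            raise ValueError("chromosomes must be sorted by descending length")
        if sum(c.chrom_class == X for c in self.chromosomes) > 1:
            raise ValueError("at most one chromosome may be labeled X")

    def __iter__(self):
        return iter(self.chromosomes)

    def __len__(self):
        return len(self.chromosomes)

    def __getitem__(self, chrom_id: str) -> ChromosomeRecord:
        for c in self.chromosomes:
            if c.id == chrom_id:
                return c
        raise KeyError(chrom_id)

    @property
    def x_id(self) -> str | None:
        for c in self.chromosomes:
            if c.chrom_class == X:
                return c.id
        return None

    @property
    def lengths(self) -> dict[str, int]:
        return {c.id: c.length for c in self.chromosomes}

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [c.id for c in self.chromosomes],
                "length": [c.length for c in self.chromosomes],
                "chrom_class": [c.chrom_class for c in self.chromosomes],
            }
        )


@dataclass(frozen=True)
class ClineParams:
    """Generative parameters of the positional substitution-rate model.

    ``ds_center`` is the expected dS far from chromosome ends, ``ds_end`` the
    expectation at distance 0, ``lambda_bp`` the exponential decay length in
    bp, ``x_factor`` a multiplicative reduction applied to dS (not dN) on the
    X chromosome, ``omega`` the central dN/dS, ``noise_cv`` the coefficient
    of variation of the per-gene mutation-rate multiplier (shared scale of
    dS), and ``omega_cv`` the dispersion of per-gene dN/dS around ``omega``
    (selective constraint varies across genes far more than mutation rate
    does, so dN is much more overdispersed than dS in real ortholog sets).
    """

    ds_center: float = 0.06
    ds_end: float = 0.12
    lambda_bp: float = 3e6
    x_factor: float = 0.7
    omega: float = 0.25
    noise_cv: float = 0.25
    omega_cv: float = 1.4

    def __post_init__(self):
        if not (self.ds_end >= self.ds_center > 0):
            raise ValueError("require ds_end >= ds_center > 0")
        if self.lambda_bp <= 0:
            raise ValueError("lambda_bp must be positive")
        if not (0 < self.x_factor <= 1):
            raise ValueError("x_factor must be in (0, 1]")
        if self.omega <= 0:
            raise ValueError("omega must be positive")
        if self.noise_cv < 0 or self.omega_cv < 0:
            raise ValueError("noise_cv and omega_cv must be nonnegative")


@dataclass(frozen=True)
class DepthSimSpec:
    """Parameters of the window-level read-depth simulator.

    ``par_spans`` are (chrom id, start, end) intervals on the X simulated at
    autosomal (equal-sex) depth; ``y_ids`` are scaffolds simulated as Y
    (male-only coverage, with a small female background from spurious
    mapping); ``overdispersion`` is the variance inflation of the
    mean-preserving gamma multiplicative noise (1 = noiseless).
    """

    coverage_mean: float = 1.0
    window_bp: int = 10_000
    par_spans: tuple[tuple[str, int, int], ...] = ()
    y_ids: tuple[str, ...] = ()
    overdispersion: float = 1.003
    y_female_background: float = 0.02

    def __post_init__(self):
        if self.window_bp <= 0:
            raise ValueError("window_bp must be positive")
        if self.overdispersion < 1:
            raise ValueError("overdispersion must be >= 1")

    def validate_for(self, karyotype: Karyotype) -> None:
        for chrom_id, start, end in self.par_spans:
            rec = karyotype[chrom_id]
            if rec.chrom_class != X:
                raise ValueError(f"PAR span on non-X chromosome {chrom_id}")
            if not (0 <= start < end <= rec.length):
                raise ValueError(f"PAR span ({start}, {end}) outside {chrom_id}")
        for y in self.y_ids:
            karyotype[y]  # raises KeyError if absent


def simulate_karyotype(
    n_chrom: int,
    min_len: float,
    max_len: float,
    x_rank: int,
    seed: int = 0,
    x_len: float | None = None,
) -> Karyotype:
    """Karyotype with log-uniformly spaced lengths, sorted descending.

    Chromosome ids are ``chr1`` (longest) .. ``chrN``; the chromosome at
    position ``x_rank`` (1-based, by descending length) is labeled X. The
    length spectrum is a deterministic geometric progression between the two
    extremes, so the output does not depend on ``seed`` (accepted for API
    uniformity with the other simulators).

    When ``x_len`` is given the spectrum is anchored through it: lengths run
    log-uniformly from ``max_len`` down to ``x_len`` at ``x_rank`` and on to
    ``min_len``, letting the X sit at a length that a single geometric
    progression could not place at its rank (karyotypes with few macro- and
    many micro-chromosomes are steeper at the top than log-uniform).
    """
    if n_chrom < 2:
        raise ValueError("n_chrom must be >= 2")
    if not (0 < min_len <= max_len):
        raise ValueError("require 0 < min_len <= max_len")
    if not (1 <= x_rank <= n_chrom):
        raise ValueError("x_rank must be between 1 and n_chrom")
    if x_len is None:
        lengths = np.geomspace(max_len, min_len, n_chrom)
    else:
        if not (min_len <= x_len <= max_len):
            raise ValueError("x_len must lie between min_len and max_len")
        upper = np.geomspace(max_len, x_len, x_rank)
        lower = np.geomspace(x_len, min_len, n_chrom - x_rank + 1)
        lengths = np.concatenate([upper, lower[1:]])
    records = tuple(
        ChromosomeRecord(
            id=f"chr{i + 1}",
            length=int(round(L)),
            chrom_class=X if i + 1 == x_rank else AUTOSOME,
        )
        for i, L in enumerate(lengths)
    )
    return Karyotype(records)


def add_y_scaffolds(
    karyotype: Karyotype, lengths: Sequence[int], ids: Sequence[str] | None = None
) -> Karyotype:
    """Append Y-candidate scaffolds (must be shorter than the smallest chromosome)."""
    if ids is None:
        ids = [f"scaffoldY{i + 1}" for i in range(len(lengths))]
    order = np.argsort(lengths)[::-1]
    recs = tuple(ChromosomeRecord(ids[i], int(lengths[i]), Y_CANDIDATE) for i in order)
    return Karyotype(karyotype.chromosomes + recs)


def place_genes(
    karyotype: Karyotype, genes_per_mb: float, seed: int = 0
) -> pd.DataFrame:
    """Place genes with Poisson counts and uniform midpoints per chromosome.

    Returns a DataFrame (gene_id, chrom, midpoint) with midpoints strictly
    inside (0, length). Y-candidate scaffolds receive no genes.
    """
    if genes_per_mb < 0:
        raise ValueError("genes_per_mb must be nonnegative")
    rng = np.random.default_rng(seed)
    rows = []
    for rec in karyotype:
        if rec.chrom_class == Y_CANDIDATE:
            continue
        n = rng.poisson(rec.length * genes_per_mb / 1e6)
        mid = rng.uniform(0.0, rec.length, size=n)
        mid = np.clip(mid, 0.5, rec.length - 0.5)  # open-interval support
        for m in np.sort(mid):
            rows.append((f"{rec.id}_g{len(rows) + 1}", rec.id, float(m)))
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "midpoint"])


def _cline(distance, center: float, end: float, lambda_bp: float):
    return center + (end - center) * np.exp(-np.asarray(distance, dtype=float) / lambda_bp)


def expected_ds(position: float, chrom: ChromosomeRecord, params: ClineParams) -> float:
    """Expected dS of a gene at ``position`` on ``chrom`` under the cline model.

    dS(d) = ds_center + (ds_end − ds_center)·exp(−d/lambda_bp) with
    d = min(position, length − position), multiplied by ``x_factor`` on the X.
    Symmetric about the chromosome midpoint by construction.
    """
    if not (0 < position < chrom.length):
        raise ValueError(f"position {position} outside (0, {chrom.length})")
    d = min(position, chrom.length - position)
    val = float(_cline(d, params.ds_center, params.ds_end, params.lambda_bp))
    if chrom.chrom_class == X:
        val *= params.x_factor
    return val


# --- codon pair simulator -------------------------------------------------

# neighbor index (into SENSE_CODONS, -1 for stops) and synonymy flags, (61, 9)
_NEIGH = np.full((_codon.N_SENSE, 9), -1, dtype=np.int64)
_IS_SYN = np.zeros((_codon.N_SENSE, 9), dtype=bool)
for _i, _c in enumerate(_codon.SENSE_CODONS):
    for _j, _nb in enumerate(_codon.neighbors(_c)):
        if _nb in _codon.SENSE_INDEX:
            _NEIGH[_i, _j] = _codon.SENSE_INDEX[_nb]
            _IS_SYN[_i, _j] = _codon.AMINO_ACID[_nb] == _codon.AMINO_ACID[_c]


def _evolve(states: np.ndarray, r: float, omega: float, t_branch: float, rng) -> np.ndarray:
    """Evolve codon states for time t_branch under the continuous-time process.

    Per-codon rates: r to each synonymous neighbor, omega*r to each sense
    nonsynonymous neighbor, 0 to stops. The synonymous rate per synonymous
    site is therefore 3r regardless of the current codon.
    """
    if t_branch <= 0 or r <= 0:
        return states
    weights = np.where(_NEIGH >= 0, np.where(_IS_SYN, 1.0, omega), 0.0)
    total = r * weights.sum(axis=1)
    cum = np.cumsum(weights, axis=1)
    time_left = np.full(states.shape, float(t_branch))
    active = np.arange(states.size)
    while active.size:
        s = states[active]
        rate = total[s]
        dt = rng.exponential(1.0, size=active.size) / np.where(rate > 0, rate, np.inf)
        time_left[active] -= dt
        hit = time_left[active] > 0
        active = active[hit]
        if active.size:
            s = states[active]
            u = rng.random(active.size) * cum[s, -1]
            choice = (u[:, None] >= cum[s]).sum(axis=1)
            states[active] = _NEIGH[s, choice]
    return states


def simulate_codon_pair(
    true_ds: float, omega: float, n_codons: int, seed: int = 0
) -> tuple[str, str]:
    """Aligned coding-sequence pair with known expected synonymous divergence.

    Two descendants diverge from a uniform-sense-codon ancestor under a
    continuous-time codon process in which every synonymous single-nucleotide
    change has rate r, every nonsynonymous change rate omega*r, and changes
    to stop codons are forbidden. Rates are scaled so the expected number of
    synonymous substitutions per synonymous site over the whole pair equals
    ``true_ds``. Sequences contain only sense codons.
    """
    if true_ds < 0:
        raise ValueError("true_ds must be nonnegative")
    if omega < 0:
        raise ValueError("omega must be nonnegative")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    ancestor = rng.integers(0, _codon.N_SENSE, size=n_codons)
    # 3r * T_total = true_ds  =>  with T_total = 1, r = true_ds / 3
    r = true_ds / 3.0
    s1 = _evolve(ancestor.copy(), r, omega, 0.5, rng)
    s2 = _evolve(ancestor.copy(), r, omega, 0.5, rng)
    return _codon.decode(s1), _codon.decode(s2)


# --- gene-level rate tables -----------------------------------------------

_MEAN_SYN_FRACTION = float(_codon.SYN_SITES.mean() / 3.0)


def _gamma_multiplier(rng, cv: float, size: int) -> np.ndarray:
    if cv == 0:
        return np.ones(size)
    shape = 1.0 / cv**2
    return rng.gamma(shape, 1.0 / shape, size=size)


def _jc_inverse(d):
    return 0.75 * (1.0 - np.exp(-4.0 * np.asarray(d, dtype=float) / 3.0))


def _jc_vec(p):
    p = np.asarray(p, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = p < 0.75
    out[ok] = -0.75 * np.log1p(-4.0 * p[ok] / 3.0)
    return out


def simulate_gene_rates(
    karyotype: Karyotype,
    params: ClineParams,
    genes_per_mb: float = 3.6,
    seed: int = 0,
    n_codons: int | None = 500,
) -> pd.DataFrame:
    """Per-gene rate table under the cline model, without sequence simulation.

    Expected dS follows the positional cline (times ``x_factor`` on the X);
    expected dN is ``omega`` times the positional cline *without* the X
    reduction. Each gene's rates get independent mean-preserving gamma noise
    (CV ``noise_cv``); when ``n_codons`` is given, binomial counting noise of
    an NG86-style estimate at that gene length is layered on top. The default
    gene density (3.6/Mb) matches a vertebrate-like ~11.6k orthologs on a
    3.2-Gb genome.
    """
    rng = np.random.default_rng(seed)
    genes = place_genes(karyotype, genes_per_mb, seed=int(rng.integers(2**31)))
    if genes.empty:
        cols = ["gene_id", "chrom", "length", "midpoint", "distance_from_end",
                "chrom_class", "true_ds", "ds", "dn", "omega", "t", "valid"]
        return pd.DataFrame(columns=cols)
    lengths = genes["chrom"].map(karyotype.lengths).astype(float)
    classes = genes["chrom"].map(
        {c.id: c.chrom_class for c in karyotype}
    )
    dist = np.minimum(genes["midpoint"], lengths - genes["midpoint"]).to_numpy()
    base = _cline(dist, params.ds_center, params.ds_end, params.lambda_bp)
    on_x = (classes == X).to_numpy()
    ds_true = base * np.where(on_x, params.x_factor, 1.0)
    n = len(genes)
    # shared mutation-rate multiplier; gene-specific selective constraint
    mu = _gamma_multiplier(rng, params.noise_cv, n)
    omega_gene = params.omega * _gamma_multiplier(rng, params.omega_cv, n)
    ds = ds_true * mu
    dn = base * omega_gene * mu  # X reduction applies to dS only
    if n_codons is not None:
        s_eff = max(int(round(_MEAN_SYN_FRACTION * 3 * n_codons)), 1)
        n_eff = 3 * n_codons - s_eff
        sd = rng.binomial(s_eff, np.clip(_jc_inverse(ds), 0, 0.999))
        nd = rng.binomial(n_eff, np.clip(_jc_inverse(dn), 0, 0.999))
        ds = _jc_vec(sd / s_eff)
        dn = _jc_vec(nd / n_eff)
        s_sites, n_sites = float(s_eff), float(n_eff)
    else:
        s_sites = _MEAN_SYN_FRACTION * 3 * (n_codons or 500)
        n_sites = 3 * (n_codons or 500) - s_sites
    with np.errstate(divide="ignore", invalid="ignore"):
        omega_hat = np.where(ds > 0, dn / ds, np.nan)
    t = 3.0 * (s_sites * ds + n_sites * dn) / (s_sites + n_sites)
    out = genes.copy()
    out["length"] = lengths.astype(int)
    out["distance_from_end"] = dist
    out["chrom_class"] = classes.to_numpy()
    out["true_ds"] = ds_true
    out["ds"] = ds
    out["dn"] = dn
    out["omega"] = omega_hat
    out["t"] = t
    out["valid"] = ~(np.isnan(ds) | np.isnan(dn))
    return out


# --- depth and GC tracks ---------------------------------------------------

def _windows(length: int, window_bp: int) -> tuple[np.ndarray, np.ndarray]:
    starts = np.arange(0, length, window_bp, dtype=np.int64)
    ends = np.minimum(starts + window_bp, length)
    return starts, ends


def simulate_depth_tracks(
    karyotype: Karyotype, spec: DepthSimSpec, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-window normalized depth tracks (female, male) as bedGraph frames.

    Expected normalized depth per (class, sex): autosome 1/1; X non-PAR 1/0.5;
    PAR 1/1; Y ``y_female_background``/0.5. Multiplicative gamma noise with
    variance ``overdispersion − 1`` (mean-preserving) is applied per window.
    """
    spec.validate_for(karyotype)
    rng = np.random.default_rng(seed)
    pars: dict[str, list[tuple[int, int]]] = {}
    for chrom_id, start, end in spec.par_spans:
        pars.setdefault(chrom_id, []).append((start, end))
    frames_f, frames_m = [], []
    for rec in karyotype:
        starts, ends = _windows(rec.length, spec.window_bp)
        mids = 0.5 * (starts + ends)
        exp_f = np.full(starts.shape, 1.0)
        exp_m = np.full(starts.shape, 1.0)
        if rec.id in spec.y_ids or rec.chrom_class == Y_CANDIDATE:
            exp_f[:] = spec.y_female_background
            exp_m[:] = 0.5
        elif rec.chrom_class == X:
            exp_m[:] = 0.5
            for a, b in pars.get(rec.id, []):
                in_par = (mids >= a) & (mids < b)
                exp_m[in_par] = 1.0
        exp_f *= spec.coverage_mean
        exp_m *= spec.coverage_mean
        var = spec.overdispersion - 1.0
        if var > 0:
            shape = 1.0 / var
            noise_f = rng.gamma(shape, var, size=starts.size)
            noise_m = rng.gamma(shape, var, size=starts.size)
        else:
            noise_f = noise_m = np.ones(starts.size)
        frames_f.append(pd.DataFrame(
            {"chrom": rec.id, "start": starts, "end": ends, "depth": exp_f * noise_f}))
        frames_m.append(pd.DataFrame(
            {"chrom": rec.id, "start": starts, "end": ends, "depth": exp_m * noise_m}))
    return (
        pd.concat(frames_f, ignore_index=True),
        pd.concat(frames_m, ignore_index=True),
    )


def simulate_gc_track(
    karyotype: Karyotype,
    gc_center: float = 0.41,
    gc_end: float = 0.46,
    lambda_bp: float = 5e6,
    window_bp: int = 10_000,
    seed: int = 0,
    concentration: float = 500.0,
) -> pd.DataFrame:
    """Per-window GC fraction decaying from chromosome ends, with beta noise.

    Expected GC follows the same exponential distance-from-end form as the
    dS cline; per-window values are Beta-distributed around the expectation
    with the given concentration (values always in (0, 1)).
    """
    if not (0 < gc_center < 1 and 0 < gc_end < 1):
        raise ValueError("gc_center and gc_end must be in (0, 1)")
    if lambda_bp <= 0 or window_bp <= 0 or concentration <= 0:
        raise ValueError("lambda_bp, window_bp and concentration must be positive")
    rng = np.random.default_rng(seed)
    frames = []
    for rec in karyotype:
        starts, ends = _windows(rec.length, window_bp)
        mids = 0.5 * (starts + ends)
        dist = np.minimum(mids, rec.length - mids)
        mean = _cline(dist, gc_center, gc_end, lambda_bp)
        gc = rng.beta(mean * concentration, (1.0 - mean) * concentration)
        frames.append(pd.DataFrame({"chrom": rec.id, "start": starts, "end": ends, "gc": gc}))
    return pd.concat(frames, ignore_index=True)


# --- gene tree fixtures ----------------------------------------------------

SPECIES_TAGS = ("Rty", "Sti", "Cpl", "Ara", "Cmi")
FOCAL_A, FOCAL_B = "Rty", "Sti"


def simulate_gene_trees(
    n_pass: int, n_fail_paralog: int, n_fail_topology: int, seed: int = 0
) -> list[tuple[str, bool]]:
    """Five-species Newick fixtures with planted pass/fail monophyly status.

    Pass trees have the two focal species as a single-copy sister pair; the
    failure modes duplicate the first focal species (copy-number) or separate
    the focal pair by an outgroup leaf (topology). Branch lengths are random
    but seeded. Returns (newick, expected_pass) tuples in shuffled order.
    """
    if min(n_pass, n_fail_paralog, n_fail_topology) < 0:
        raise ValueError("tree counts must be nonnegative")
    rng = np.random.default_rng(seed)

    def bl() -> str:
        return f"{rng.uniform(0.01, 0.3):.4f}"

    trees: list[tuple[str, bool]] = []
    k = 0
    for _ in range(n_pass):
        k += 1
        nwk = (
            f"((Rty_g{k}:{bl()},Sti_g{k}:{bl()}):{bl()},"
            f"(Cpl_g{k}:{bl()},(Ara_g{k}:{bl()},Cmi_g{k}:{bl()}):{bl()}):{bl()});"
        )
        trees.append((nwk, True))
    for _ in range(n_fail_paralog):
        k += 1
        nwk = (
            f"(((Rty_g{k}a:{bl()},Rty_g{k}b:{bl()}):{bl()},Sti_g{k}:{bl()}):{bl()},"
            f"(Cpl_g{k}:{bl()},(Ara_g{k}:{bl()},Cmi_g{k}:{bl()}):{bl()}):{bl()});"
        )
        trees.append((nwk, False))
    for _ in range(n_fail_topology):
        k += 1
        nwk = (
            f"((Rty_g{k}:{bl()},Cpl_g{k}:{bl()}):{bl()},"
            f"(Sti_g{k}:{bl()},(Ara_g{k}:{bl()},Cmi_g{k}:{bl()}):{bl()}):{bl()});"
        )
        trees.append((nwk, False))
    order = rng.permutation(len(trees))
    return [trees[i] for i in order]
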