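"""Positional and chromosomal statistics of substitution rates and GC content.

The questions addressed: do shorter chromosomes have higher median
substitution rates (length effect); do rates decline with a gene's distance
from the nearest chromosome end (the "chromocline" gradient); does the length
effect survive once position is held fixed (end-proximal vs central subsets);
and is the X chromosome's dS reduced beyond what its length and gene
positions predict (randomization test of X vs autosomes)?

`ChromoclineModel` bundles the battery behind a fit/results interface:

    model = ChromoclineModel(genes, karyotype)
    res = model.fit(seed=1)
    print(res.summary())

where ``genes`` is a per-gene table with columns (gene_id, chrom, midpoint,
ds, dn, omega, t) and chromosome lengths come from the karyotype. The
individual operations are module-level functions and usable on their own.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

from .synth import Karyotype

__all__ = [
    "RegressionResult",
    "PermutationResult",
    "distance_from_end",
    "chromosome_summaries",
    "length_rate_regression",
    "position_regressions",
    "SlopeTally",
    "quadratic_fit",
    "QuadraticFit",
    "loess_fit",
    "LoessFit",
    "gc_window_stats",
    "gc_from_fasta",
    "subset_by_position",
    "permutation_test_groups",
    "x_effect_analysis",
    "ChromoclineModel",
    "ChromoclineResults",
]

RESPONSES = ("ds", "dn", "omega")


@dataclass(frozen=True)
class RegressionResult:
    """Simple OLS summary: slope, intercept, slope SE, two-sided p, r, n."""

    slope: float
    intercept: float
    slope_se: float
    p_value: float
    r: float
    n: int
    transform: str = ""

    @property
    def significant(self) -> bool:
        return bool(self.p_value < 0.05)


@dataclass(frozen=True)
class PermutationResult:
    """Randomization test of a difference of group medians."""

    observed: float
    n_permutations: int
    p_value: float
    seed: int | None
    tail: str = "two-sided on |median(X) - median(autosome)|"


def distance_from_end(midpoint: float, length: float) -> float:
    """Distance from the nearest chromosome end: min(midpoint, length − midpoint)."""
    if not (0 < midpoint < length):
        raise ValueError(f"midpoint {midpoint} outside (0, {length})")
    return float(min(midpoint, length - midpoint))


def _with_positions(genes: pd.DataFrame, lengths: Mapping[str, int]) -> pd.DataFrame:
    out = genes.copy()
    if "length" not in out.columns:
        out["length"] = out["chrom"].map(dict(lengths))
        if out["length"].isna().any():
            bad = out.loc[out["length"].isna(), "chrom"].unique()
            raise ValueError(f"chromosome length unknown for: {list(bad)[:5]}")
    out["distance_from_end"] = np.minimum(out["midpoint"], out["length"] - out["midpoint"])
    return out


def chromosome_summaries(genes: pd.DataFrame, min_genes: int = 10) -> pd.DataFrame:
    """Per-chromosome medians of ds, dn and omega.

    Chromosomes with strictly more than ``min_genes`` genes are marked
    included; smaller ones are still reported but flagged excluded, since
    medians over few orthologs are unstable.
    """
    cols = [c for c in RESPONSES if c in genes.columns]
    grouped = genes.groupby("chrom", sort=False)
    summ = grouped[cols].median()
    summ["n_genes"] = grouped.size()
    if "length" in genes.columns:
        summ["length"] = grouped["length"].first()
    if "chrom_class" in genes.columns:
        summ["chrom_class"] = grouped["chrom_class"].first()
    summ["included"] = summ["n_genes"] > min_genes
    return summ.reset_index()


def _ols(x: np.ndarray, y: np.ndarray, transform: str = "") -> RegressionResult:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    r = float(np.corrcoef(x, y)[0, 1]) if len(x) > 2 else np.nan
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        r=r,
        n=len(x),
        transform=transform,
    )


def length_rate_regression(
    summaries: pd.DataFrame,
    response: str = "ds",
    include_x: bool = True,
) -> RegressionResult:
    """OLS of log10(per-chromosome median response) on log10(chromosome length).

    Only chromosomes flagged included enter the fit; nonpositive medians are
    dropped with a warning (they cannot be logged). The X chromosome is
    included by default and can be excluded with ``include_x=False``.
    """
    df = summaries[summaries["included"]]
    if not include_x and "chrom_class" in df.columns:
        df = df[df["chrom_class"] != "X"]
    pos = df[response] > 0
    if (~pos).any():
        warnings.warn(f"dropping {(~pos).sum()} chromosomes with nonpositive {response} median")
        df = df[pos]
    if len(df) < 3:
        raise ValueError(f"need >= 3 chromosomes for the length regression, got {len(df)}")
    return _ols(
        np.log10(df["length"].to_numpy(dtype=float)),
        np.log10(df[response].to_numpy(dtype=float)),
        transform="log10(median) ~ log10(length)",
    )


@dataclass(frozen=True)
class SlopeTally:
    """Sign/significance tally of per-chromosome positional slopes."""

    n_negative: int
    n_negative_significant: int
    n_positive: int
    n_positive_significant: int

    @property
    def n_total(self) -> int:
        return self.n_negative + self.n_positive


def position_regressions(
    genes: pd.DataFrame,
    lengths: Mapping[str, int] | None = None,
    response: str = "ds",
    min_genes_per_chrom: int = 3,
) -> tuple[pd.DataFrame, SlopeTally, RegressionResult]:
    """Per-chromosome and pooled regressions of a rate on distance from the end.

    Per-chromosome fits are on linear axes (slope signs tallied at raw
    two-sided P < 0.05, plus a Benjamini–Hochberg column for transparency);
    the pooled fit is on log10 axes, excluding nonpositive responses with
    their count recorded in the transform note. Chromosomes with fewer than
    ``min_genes_per_chrom`` genes are skipped.
    """
    df = _with_positions(genes, lengths or {}) if lengths is not None else genes
    if "distance_from_end" not in df.columns:
        raise ValueError("need chromosome lengths or a distance_from_end column")
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        sub = sub.dropna(subset=[response])
        if len(sub) < min_genes_per_chrom or sub["distance_from_end"].nunique() < 2:
            continue
        res = _ols(
            sub["distance_from_end"].to_numpy(dtype=float),
            sub[response].to_numpy(dtype=float),
            transform=f"{response} ~ distance (linear)",
        )
        rows.append({
            "chrom": chrom, "n": res.n, "slope": res.slope,
            "slope_se": res.slope_se, "p_value": res.p_value,
            "significant": res.significant,
        })
    per_chrom = pd.DataFrame(rows)
    if not per_chrom.empty:
        per_chrom["bh_q"] = scipy.stats.false_discovery_control(per_chrom["p_value"])
        neg = per_chrom["slope"] < 0
        tally = SlopeTally(
            n_negative=int(neg.sum()),
            n_negative_significant=int((neg & per_chrom["significant"]).sum()),
            n_positive=int((~neg).sum()),
            n_positive_significant=int((~neg & per_chrom["significant"]).sum()),
        )
    else:
        tally = SlopeTally(0, 0, 0, 0)
    pool = df.dropna(subset=[response])
    ok = (pool[response] > 0) & (pool["distance_from_end"] > 0)
    n_dropped = int((~ok).sum())
    pool = pool[ok]
    pooled = _ols(
        np.log10(pool["distance_from_end"].to_numpy(dtype=float)),
        np.log10(pool[response].to_numpy(dtype=float)),
        transform=f"log10({response}) ~ log10(distance); {n_dropped} nonpositive dropped",
    )
    return per_chrom, tally, pooled


@dataclass(frozen=True)
class QuadraticFit:
    """Quadratic OLS of a rate on absolute position along one chromosome."""

    coef: tuple[float, float, float]  # intercept, linear, quadratic
    quad_ci: tuple[float, float]  # 95% CI of the quadratic coefficient
    u_shaped: bool  # CI entirely positive
    n: int


def quadratic_fit(
    positions: Sequence[float], response: Sequence[float]
) -> QuadraticFit:
    """Fit response ~ position + position² (absolute bp) with a U-shape verdict.

    The chromosome is called U-shaped when the 95% confidence interval of the
    quadratic coefficient is entirely positive (concave-up).
    """
    x = np.asarray(positions, dtype=float)
    y = np.asarray(response, dtype=float)
    if len(x) < 5:
        raise ValueError(f"need >= 5 genes for a quadratic fit, got {len(x)}")
    if np.unique(x).size < 3:
        raise ValueError("degenerate positions: need >= 3 distinct values")
    # fit on positions scaled to [0, 1] for conditioning, report in bp units
    scale = float(np.max(np.abs(x))) or 1.0
    z = x / scale
    X = sm.add_constant(np.column_stack([z, z**2]))
    fit = sm.OLS(y, X).fit()
    lo, hi = fit.conf_int()[2]
    return QuadraticFit(
        coef=(
            float(fit.params[0]),
            float(fit.params[1]) / scale,
            float(fit.params[2]) / scale**2,
        ),
        quad_ci=(float(lo) / scale**2, float(hi) / scale**2),
        u_shaped=bool(lo > 0),
        n=len(x),
    )


@dataclass
class LoessFit:
    """LOESS curve with pointwise 95% band."""

    x: np.ndarray
    fitted: np.ndarray
    se: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    span: float
    sigma: float


def loess_fit(
    x: Sequence[float],
    y: Sequence[float],
    span: float = 0.75,
    degree: int = 1,
    eval_x: Sequence[float] | None = None,
) -> LoessFit:
    """Local (tricube-weighted) polynomial regression with a 95% band.

    At each evaluation point the span-fraction nearest neighbors are fitted
    by weighted least squares of the given degree; the pointwise standard
    error is sigma·||l(x0)|| with l the equivalent-kernel weights and sigma
    estimated from the LOESS residuals with the usual one/two-delta degrees
    of freedom correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError(f"need >= 10 points for loess, got {n}")
    if not (0 < span <= 1):
        raise ValueError("span must be in (0, 1]")
    k = int(np.ceil(span * n))
    if k < degree + 2:
        raise ValueError(f"span {span} too small for n={n} at degree {degree}")

    def l_vector(x0: float) -> np.ndarray:
        d = np.abs(x - x0)
        dmax = np.partition(d, k - 1)[k - 1]
        if dmax == 0:
            w = (d == 0).astype(float)
        else:
            w = np.clip(1 - (d / dmax) ** 3, 0, None) ** 3
        X = np.vander(x - x0, degree + 1, increasing=True)
        WX = X * w[:, None]
        beta_map = np.linalg.pinv(X.T @ WX) @ WX.T
        return beta_map[0]  # fitted value at x0 is the intercept

    L = np.array([l_vector(xi) for xi in x])
    fitted_at_data = L @ y
    resid = y - fitted_at_data
    nu1 = float(np.trace(L))
    nu2 = float((L * L).sum())
    dof = max(n - 2 * nu1 + nu2, 1.0)
    sigma = float(np.sqrt((resid**2).sum() / dof))
    if eval_x is None:
        eval_points = x
        l_rows = L
    else:
        eval_points = np.asarray(eval_x, dtype=float)
        l_rows = np.array([l_vector(xi) for xi in eval_points])
    fitted = l_rows @ y
    se = sigma * np.sqrt((l_rows**2).sum(axis=1))
    return LoessFit(
        x=eval_points, fitted=fitted, se=se,
        lower=fitted - 1.96 * se, upper=fitted + 1.96 * se,
        span=span, sigma=sigma,
    )


def gc_window_stats(
    gc_track: pd.DataFrame, lengths: Mapping[str, int]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Distance-from-end annotation and per-chromosome GC gradients.

    ``gc_track`` has columns (chrom, start, end, gc). Returns the annotated
    window table and a per-chromosome OLS table of GC on distance (linear
    axes), with significance at two-sided P < 0.05.
    """
    if not gc_track["gc"].between(0, 1).all():
        raise ValueError("GC fractions must lie in [0, 1]")
    df = gc_track.copy()
    lens = df["chrom"].map(dict(lengths))
    if lens.isna().any():
        raise ValueError("GC track contains chromosomes with unknown length")
    mids = 0.5 * (df["start"] + df["end"])
    df["distance_from_end"] = np.minimum(mids, lens - mids)
    rows = []
    for chrom, sub in df.groupby("chrom", sort=False):
        if len(sub) < 3 or sub["distance_from_end"].nunique() < 2:
            continue
        res = _ols(
            sub["distance_from_end"].to_numpy(dtype=float),
            sub["gc"].to_numpy(dtype=float),
            transform="gc ~ distance (linear)",
        )
        rows.append({
            "chrom": chrom, "n": res.n, "slope": res.slope,
            "p_value": res.p_value, "significant": res.significant,
        })
    return df, pd.DataFrame(rows)


def gc_from_fasta(fasta_path, window_bp: int = 10_000, max_n_fraction: float = 0.5) -> pd.DataFrame:
    """Windowed GC fractions from a genome FASTA.

    GC is (G+C)/(A+C+G+T) per window; N bases are excluded from the
    denominator and windows with more than ``max_n_fraction`` N are dropped.
    """
    from Bio import SeqIO

    rows = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seq = str(rec.seq).upper()
        for start in range(0, len(seq), window_bp):
            win = seq[start : start + window_bp]
            counts = {b: win.count(b) for b in "ACGTN"}
            denom = counts["A"] + counts["C"] + counts["G"] + counts["T"]
            if denom == 0 or counts["N"] > max_n_fraction * len(win):
                continue
            rows.append({
                "chrom": rec.id, "start": start, "end": start + len(win),
                "gc": (counts["G"] + counts["C"]) / denom,
            })
    return pd.DataFrame(rows)


def subset_by_position(
    genes: pd.DataFrame,
    mode: str,
    span_bp: float | None = None,
    lengths: Mapping[str, int] | None = None,
) -> pd.DataFrame:
    """Positional gene subsets: end-proximal or chromosome-central.

    ``ends`` keeps genes within ``span_bp`` (default 5 Mb) of the nearest
    chromosome end. ``center`` keeps genes inside the central window
    [L/2 − span/2, L/2 + span/2] (default span 10 Mb); chromosomes shorter
    than the span contribute all their genes (the window is intersected with
    the chromosome).
    """
    df = _with_positions(genes, lengths or {}) if lengths is not None else genes
    if mode == "ends":
        span = 5e6 if span_bp is None else span_bp
        if span <= 0:
            raise ValueError("span_bp must be positive")
        return df[df["distance_from_end"] <= span].copy()
    if mode == "center":
        span = 10e6 if span_bp is None else span_bp
        if span <= 0:
            raise ValueError("span_bp must be positive")
        half = df["length"] / 2.0
        lo = np.maximum(half - span / 2.0, 0.0)
        hi = np.minimum(half + span / 2.0, df["length"])
        return df[(df["midpoint"] >= lo) & (df["midpoint"] <= hi)].copy()
    raise ValueError(f"mode must be 'ends' or 'center', got {mode!r}")


def permutation_test_groups(
    values: Sequence[float],
    is_focal: Sequence[bool],
    n_perm: int = 10_000,
    seed: int | None = None,
) -> PermutationResult:
    """Randomization test of median(focal) − median(rest).

    Group labels are shuffled over genes ``n_perm`` times with group sizes
    fixed; the two-sided p-value is (#{|null| ≥ |observed|} + 1)/(n_perm + 1).
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray(is_focal, dtype=bool)
    keep = ~np.isnan(v)
    v, g = v[keep], g[keep]
    n_focal = int(g.sum())
    if n_focal == 0 or n_focal == len(v):
        raise ValueError("both groups must be non-empty")
    observed = float(np.median(v[g]) - np.median(v[~g]))
    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(v)
        null[i] = np.median(perm[:n_focal]) - np.median(perm[n_focal:])
    p = (np.count_nonzero(np.abs(null) >= abs(observed)) + 1) / (n_perm + 1)
    return PermutationResult(
        observed=observed, n_permutations=n_perm, p_value=float(p), seed=seed
    )


def x_effect_analysis(
    genes: pd.DataFrame,
    n_perm: int = 10_000,
    seed: int | None = None,
    ends_span_bp: float = 5e6,
    responses: Sequence[str] = RESPONSES,
) -> pd.DataFrame:
    """X-vs-autosome randomization tests on all genes and the ends-only subset.

    For each response (ds, dn, omega) the difference of medians between
    X-linked and autosomal genes is tested by label permutation, once using
    every gene and once restricted to genes within ``ends_span_bp`` of a
    chromosome end (controls for the positional gradient, since the X is
    short and thus enriched for end-proximal genes).
    """
    if "chrom_class" not in genes.columns:
        raise ValueError("genes need a chrom_class column (autosome / X)")
    subsets = {
        "all": genes,
        "ends": subset_by_position(genes, "ends", ends_span_bp),
    }
    rng = np.random.default_rng(seed)
    rows = []
    for subset_name, sub in subsets.items():
        is_x = (sub["chrom_class"] == "X").to_numpy()
        for resp in responses:
            res = permutation_test_groups(
                sub[resp].to_numpy(dtype=float), is_x,
                n_perm=n_perm, seed=int(rng.integers(2**31)),
            )
            rows.append({
                "subset": subset_name, "response": resp,
                "median_x": float(np.nanmedian(sub.loc[is_x, resp])),
                "median_autosome": float(np.nanmedian(sub.loc[~is_x, resp])),
                "observed_diff": res.observed,
                "p_value": res.p_value,
                "n_x": int(is_x.sum()), "n_autosome": int((~is_x).sum()),
                "n_perm": n_perm,
            })
    return pd.DataFrame(rows)


class ChromoclineModel:
    """Positional-statistics model over a per-gene substitution-rate table.

    Parameters
    ----------
    genes : DataFrame with columns (gene_id, chrom, midpoint, ds, dn, omega)
        and optionally t/valid/chrom_class.
    karyotype : Karyotype or mapping chrom -> length (bp). Supplies lengths
        and, when a Karyotype, the autosome/X class labels.
    min_genes : per-chromosome gene count strictly required for a chromosome
        to enter median summaries (default 10).
    ends_span_bp, center_span_bp : positional subset windows (5 Mb / 10 Mb).
    """

    def __init__(
        self,
        genes: pd.DataFrame,
        karyotype: Karyotype | Mapping[str, int],
        min_genes: int = 10,
        ends_span_bp: float = 5e6,
        center_span_bp: float = 10e6,
    ):
        if isinstance(karyotype, Karyotype):
            lengths = karyotype.lengths
            classes = {c.id: c.chrom_class for c in karyotype}
        else:
            lengths = dict(karyotype)
            classes = None
        df = _with_positions(genes, lengths)
        if "chrom_class" not in df.columns:
            if classes is None:
                raise ValueError(
                    "genes need a chrom_class column or a Karyotype with class labels"
                )
            df["chrom_class"] = df["chrom"].map(classes)
        self.genes = df
        self.lengths = lengths
        self.min_genes = min_genes
        self.ends_span_bp = ends_span_bp
        self.center_span_bp = center_span_bp

    @classmethod
    def from_tables(cls, genes_tsv, karyotype_tsv, **kwargs) -> "ChromoclineModel":
        from . import io as _io

        genes = pd.read_csv(genes_tsv, sep="\t")
        lengths = _io.read_chrom_sizes(karyotype_tsv)
        return cls(genes, lengths, **kwargs)

    def fit(
        self,
        n_perm: int = 10_000,
        seed: int | None = None,
        include_x_in_length_fit: bool = True,
        gc_track: pd.DataFrame | None = None,
    ) -> "ChromoclineResults":
        genes = self.genes
        summaries = chromosome_summaries(genes, self.min_genes)
        subsets = {
            "all": genes,
            "ends": subset_by_position(genes, "ends", self.ends_span_bp),
            "center": subset_by_position(genes, "center", self.center_span_bp),
        }
        # chromosome inclusion (>min_genes orthologs) is decided genome-wide;
        # positional subsets then require only enough genes for a stable median
        included_chroms = set(summaries.loc[summaries["included"], "chrom"])
        length_regressions: dict[str, dict[str, RegressionResult]] = {}
        subset_summaries: dict[str, pd.DataFrame] = {}
        for name, sub in subsets.items():
            ss = chromosome_summaries(sub, 0)
            ss["included"] = ss["chrom"].isin(included_chroms) & (ss["n_genes"] >= 3)
            subset_summaries[name] = ss
            length_regressions[name] = {}
            for resp in RESPONSES:
                if resp not in sub.columns:
                    continue
                try:
                    length_regressions[name][resp] = length_rate_regression(
                        subset_summaries[name], resp, include_x=include_x_in_length_fit
                    )
                except ValueError:
                    pass
        per_chrom, tally, pooled = position_regressions(genes, response="ds")
        quadratics = {}
        for chrom, sub in genes.groupby("chrom", sort=False):
            sub = sub.dropna(subset=["ds"])
            if len(sub) < 5:
                continue
            try:
                quadratics[chrom] = quadratic_fit(sub["midpoint"], sub["ds"])
            except ValueError:
                continue
        x_effect = None
        if (genes["chrom_class"] == "X").any():
            x_effect = x_effect_analysis(
                genes, n_perm=n_perm, seed=seed, ends_span_bp=self.ends_span_bp
            )
        gc_windows = gc_regressions = None
        if gc_track is not None:
            gc_windows, gc_regressions = gc_window_stats(gc_track, self.lengths)
        return ChromoclineResults(
            model=self,
            chrom_summaries=summaries,
            subset_summaries=subset_summaries,
            length_regressions=length_regressions,
            position_per_chrom=per_chrom,
            position_tally=tally,
            position_pooled=pooled,
            quadratics=quadratics,
            x_effect=x_effect,
            gc_windows=gc_windows,
            gc_regressions=gc_regressions,
            n_perm=n_perm,
            seed=seed,
        )


@dataclass
class ChromoclineResults:
    """Fitted positional-statistics battery; see `summary` for a report."""

    model: ChromoclineModel
    chrom_summaries: pd.DataFrame
    subset_summaries: dict[str, pd.DataFrame]
    length_regressions: dict[str, dict[str, RegressionResult]]
    position_per_chrom: pd.DataFrame
    position_tally: SlopeTally
    position_pooled: RegressionResult
    quadratics: dict[str, QuadraticFit]
    x_effect: pd.DataFrame | None
    gc_windows: pd.DataFrame | None
    gc_regressions: pd.DataFrame | None
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        lines = ["Chromocline analysis", "=" * 60]
        inc = self.chrom_summaries[self.chrom_summaries["included"]]
        if not inc.empty:
            lines.append(
                f"chromosomes with >{self.model.min_genes} genes: {len(inc)}"
                f" of {len(self.chrom_summaries)}"
            )
            lines.append(
                f"median dS across chromosomes: {inc['ds'].min():.4g}"
                f" to {inc['ds'].max():.4g}"
            )
        lines.append("")
        lines.append("Length effect (log10 median rate ~ log10 length):")
        for name in ("all", "ends", "center"):
            for resp, res in self.length_regressions.get(name, {}).items():
                lines.append(
                    f"  [{name:6s}] {resp:5s} slope={res.slope:+.3f}"
                    f" (SE {res.slope_se:.3f}) p={res.p_value:.3g}"
                    f" {'*' if res.significant else 'ns'} (n={res.n})"
                )
        t = self.position_tally
        lines.append("")
        lines.append("Distance-from-end gradients (per-chromosome dS slopes):")
        lines.append(
            f"  {t.n_negative} of {t.n_total} chromosomes negative"
            f" ({t.n_negative_significant} significant);"
            f" {t.n_positive} positive ({t.n_positive_significant} significant)"
        )
        lines.append(
            f"  pooled log-log fit: slope={self.position_pooled.slope:+.3f}"
            f" p={self.position_pooled.p_value:.3g}"
        )
        n_u = sum(q.u_shaped for q in self.quadratics.values())
        lines.append(f"  U-shaped quadratic verdicts: {n_u} of {len(self.quadratics)}")
        if self.gc_regressions is not None and not self.gc_regressions.empty:
            neg = (self.gc_regressions["slope"] < 0).sum()
            lines.append(
                f"  GC gradients: {neg} of {len(self.gc_regressions)} chromosomes negative"
            )
        if self.x_effect is not None:
            lines.append("")
            lines.append(f"X vs autosomes (randomization, {self.n_perm} permutations):")
            for _, row in self.x_effect.iterrows():
                lines.append(
                    f"  [{row['subset']:4s}] {row['response']:5s}"
                    f" diff={row['observed_diff']:+.4g} p={row['p_value']:.4g}"
                    f" (n_X={row['n_x']})"
                )
        return "\n".join(lines)

    # --- plots ------------------------------------------------------------

    def plot_length_effect(self, response: str = "ds", ax=None):
        """Per-chromosome median rate against chromosome length (log-log)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        inc = self.chrom_summaries[self.chrom_summaries["included"]]
        auto = inc[inc.get("chrom_class", "autosome") != "X"]
        xchr = inc[inc.get("chrom_class", "autosome") == "X"]
        ax.scatter(auto["length"], auto[response], marker="o", label="autosome")
        if not xchr.empty:
            ax.scatter(xchr["length"], xchr[response], marker="^", s=80, label="X")
        res = self.length_regressions["all"].get(response)
        if res is not None:
            xs = np.linspace(
                np.log10(inc["length"].min()), np.log10(inc["length"].max()), 50
            )
            style = "-" if res.significant else "--"
            ax.plot(10**xs, 10 ** (res.intercept + res.slope * xs), style, color="k")
        ax.set_xscale("log")
        ax.set_yscale("log")
        ax.set_xlabel("chromosome length (bp)")
        ax.set_ylabel(f"median {response}")
        ax.legend()
        return ax

    def plot_chromosome(self, chrom: str, response: str = "ds", ax=None):
        """Rates along one chromosome with quadratic and LOESS overlays."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sub = self.model.genes[self.model.genes["chrom"] == chrom].dropna(subset=[response])
        ax.scatter(sub["midpoint"], sub[response], s=10, alpha=0.5)
        xs = np.linspace(sub["midpoint"].min(), sub["midpoint"].max(), 200)
        q = self.quadratics.get(chrom)
        if q is not None:
            a, b, c = q.coef
            ax.plot(xs, a + b * xs + c * xs**2, color="purple", label="quadratic")
        if len(sub) >= 10:
            lo = loess_fit(sub["midpoint"], sub[response], eval_x=xs)
            ax.plot(xs, lo.fitted, color="orange", label="LOESS")
            ax.fill_between(xs, lo.lower, lo.upper, color="orange", alpha=0.2)
        ax.set_xlabel(f"position on {chrom} (bp)")
        ax.set_ylabel(response)
        ax.legend()
        return ax

    def plot_x_boxplot(self, response: str = "ds", ax=None):
        """X vs autosome boxplots for all genes and the ends-only subset."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        genes = self.model.genes
        ends = subset_by_position(genes, "ends", self.model.ends_span_bp)
        data, labels = [], []
        for name, sub in [("all", genes), ("ends", ends)]:
            for cls in ("autosome", "X"):
                vals = sub.loc[sub["chrom_class"] == cls, response].dropna()
                data.append(vals)
                labels.append(f"{cls}\n({name})")
        ax.boxplot(data, tick_labels=labels)
        ax.set_ylabel(response)
        return ax
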