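"""Sex-chromosome classification from male/female read depth.

Scaffolds are classified from normalized per-window depth tracks of one
female and one male individual: in a male-heterogametic (XY) species the X
shows a female-to-male depth ratio near 2, Y scaffolds show male-restricted
coverage, and pseudoautosomal regions (PARs) at the X ends show equal depth
between sexes. Depth tracks are bedGraph-style DataFrames with columns
(chrom, start, end, depth), 0-based half-open.

`DepthRatioModel` wraps the individual steps into a fit/results interface:

    model = DepthRatioModel(female, male, lengths)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "normalize_depth",
    "summarize_scaffolds",
    "classify_x",
    "classify_y",
    "detect_par",
    "ParInterval",
    "ParScan",
    "DepthRatioModel",
    "DepthRatioResults",
]

_TRACK_COLS = ["chrom", "start", "end", "depth"]


def _check_track(track: pd.DataFrame) -> None:
    missing = [c for c in _TRACK_COLS if c not in track.columns]
    if missing:
        raise ValueError(f"depth track missing columns: {missing}")


def normalize_depth(track: pd.DataFrame) -> pd.DataFrame:
    """Divide a raw depth track by its genome-wide length-weighted mean.

    After normalization the length-weighted genome-wide mean is exactly 1,
    which makes the operation idempotent and scale-invariant.
    """
    _check_track(track)
    widths = (track["end"] - track["start"]).to_numpy(dtype=float)
    mean = np.average(track["depth"].to_numpy(dtype=float), weights=widths)
    if mean <= 0:
        raise ValueError("genome-wide mean depth is zero; cannot normalize")
    out = track.copy()
    out["depth"] = track["depth"] / mean
    return out


def summarize_scaffolds(
    female: pd.DataFrame, male: pd.DataFrame, lengths: dict[str, int]
) -> pd.DataFrame:
    """Per-scaffold depth medians and female-to-male ratio.

    The ratio is +inf when the male median is 0 with female coverage, and NaN
    (flagged in ``ratio_defined``) when both medians are 0.
    """
    _check_track(female)
    _check_track(male)
    fmed = female.groupby("chrom")["depth"].median()
    mmed = male.groupby("chrom")["depth"].median()
    rows = []
    for chrom, length in lengths.items():
        if chrom not in fmed.index or chrom not in mmed.index:
            raise ValueError(f"scaffold {chrom} missing from depth tracks")
        f, m = float(fmed[chrom]), float(mmed[chrom])
        if m > 0:
            ratio, defined = f / m, True
        elif f > 0:
            ratio, defined = np.inf, True
        else:
            ratio, defined = np.nan, False
        rows.append({
            "chrom": chrom, "length": int(length),
            "female_median": f, "male_median": m,
            "fm_ratio": ratio, "ratio_defined": defined,
        })
    return pd.DataFrame(rows)


def classify_x(
    summaries: pd.DataFrame,
    ratio_low: float = 1.5,
    ratio_high: float = 2.5,
    chrom_scale_bp: int = 1_000_000,
) -> list[str]:
    """Scaffolds with female-to-male ratio in [ratio_low, ratio_high] (closed).

    Warns when more than one chromosome-scale scaffold qualifies.
    """
    hit = summaries["ratio_defined"] & summaries["fm_ratio"].between(
        ratio_low, ratio_high, inclusive="both"
    )
    ids = summaries.loc[hit, "chrom"].tolist()
    big = summaries.loc[hit & (summaries["length"] >= chrom_scale_bp), "chrom"]
    if len(big) > 1:
        warnings.warn(
            f"{len(big)} chromosome-scale scaffolds in the X ratio band: {list(big)}"
        )
    return ids


def classify_y(
    summaries: pd.DataFrame,
    ratio_max: float = 0.1,
    female_max: float = 0.1,
    male_min: float = 0.3,
    len_min: int = 100_000,
) -> list[str]:
    """Y-candidate scaffolds: all four depth/length criteria, strict inequalities.

    Requires female-to-male ratio < ratio_max, female depth < female_max,
    male depth > male_min, and length > len_min.
    """
    hit = (
        summaries["ratio_defined"]
        & (summaries["fm_ratio"] < ratio_max)
        & (summaries["female_median"] < female_max)
        & (summaries["male_median"] > male_min)
        & (summaries["length"] > len_min)
    )
    return summaries.loc[hit, "chrom"].tolist()


@dataclass(frozen=True)
class ParInterval:
    """A pseudoautosomal interval anchored to one chromosome end."""

    chrom: str
    start: int
    end: int
    side: str  # "left" or "right"


@dataclass
class ParScan:
    """PAR calls plus interior equal-depth anomalies and warnings."""

    pars: list[ParInterval] = field(default_factory=list)
    anomalies: list[ParInterval] = field(default_factory=list)
    not_x_like: bool = False


def detect_par(
    female_x: pd.DataFrame,
    male_x: pd.DataFrame,
    ratio_band: tuple[float, float] = (0.75, 1.33),
    min_run_windows: int = 3,
) -> ParScan:
    """Detect PARs as terminal runs of equal-depth windows on the X.

    Scans per-window female/male ratios for maximal runs of at least
    ``min_run_windows`` consecutive windows inside ``ratio_band``; runs
    containing the first or last window are PAR calls (left/right), interior
    runs are reported as anomalies. When the scaffold-wide median ratio
    itself falls inside the band the scaffold is flagged not-X-like and no
    PAR is called.
    """
    _check_track(female_x)
    _check_track(male_x)
    chroms = set(female_x["chrom"]) | set(male_x["chrom"])
    if len(chroms) != 1:
        raise ValueError(f"expected a single X scaffold, got {sorted(chroms)}")
    (chrom,) = chroms
    f = female_x.sort_values("start").reset_index(drop=True)
    m = male_x.sort_values("start").reset_index(drop=True)
    if len(f) != len(m) or not (f["start"].to_numpy() == m["start"].to_numpy()).all():
        raise ValueError("female and male X tracks have mismatched windows")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = f["depth"].to_numpy() / m["depth"].to_numpy()
    lo, hi = ratio_band
    scan = ParScan()
    overall = np.nanmedian(ratio)
    if lo <= overall <= hi:
        warnings.warn(f"scaffold {chrom} has sex-balanced depth overall; not X-like")
        scan.not_x_like = True
        return scan
    in_band = (ratio >= lo) & (ratio <= hi)
    n = len(in_band)
    i = 0
    while i < n:
        if not in_band[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_band[j + 1]:
            j += 1
        if j - i + 1 >= min_run_windows:
            iv_start, iv_end = int(f.loc[i, "start"]), int(f.loc[j, "end"])
            if i == 0:
                scan.pars.append(ParInterval(chrom, iv_start, iv_end, "left"))
            elif j == n - 1:
                scan.pars.append(ParInterval(chrom, iv_start, iv_end, "right"))
            else:
                scan.anomalies.append(ParInterval(chrom, iv_start, iv_end, "interior"))
        i = j + 1
    return scan


class DepthRatioModel:
    """Sex-chromosome classification model over paired depth tracks.

    Parameters are the raw (or already normalized) female and male bedGraph
    frames and a scaffold-length mapping. ``fit`` normalizes both tracks,
    summarizes each scaffold, applies the X and Y classification rules, and
    scans any X candidate for pseudoautosomal regions.
    """

    def __init__(
        self,
        female: pd.DataFrame,
        male: pd.DataFrame,
        lengths: dict[str, int],
    ):
        _check_track(female)
        _check_track(male)
        self.female = female
        self.male = male
        self.lengths = dict(lengths)

    def fit(
        self,
        ratio_low: float = 1.5,
        ratio_high: float = 2.5,
        y_ratio_max: float = 0.1,
        y_female_max: float = 0.1,
        y_male_min: float = 0.3,
        y_len_min: int = 100_000,
        par_band: tuple[float, float] = (0.75, 1.33),
        par_min_run: int = 3,
    ) -> "DepthRatioResults":
        female = normalize_depth(self.female)
        male = normalize_depth(self.male)
        summaries = summarize_scaffolds(female, male, self.lengths)
        x_ids = classify_x(summaries, ratio_low, ratio_high)
        y_ids = classify_y(summaries, y_ratio_max, y_female_max, y_male_min, y_len_min)
        cls = pd.Series("autosome", index=summaries.index)
        cls[summaries["chrom"].isin(x_ids)] = "X"
        cls[summaries["chrom"].isin(y_ids)] = "y-candidate"
        summaries = summaries.assign(chrom_class=cls)
        par_scans = {}
        for x in x_ids:
            par_scans[x] = detect_par(
                female[female["chrom"] == x],
                male[male["chrom"] == x],
                ratio_band=par_band,
                min_run_windows=par_min_run,
            )
        return DepthRatioResults(
            summaries=summaries, x_ids=x_ids, y_ids=y_ids, par_scans=par_scans,
            female=female, male=male,
        )


@dataclass
class DepthRatioResults:
    """Classification table, X/Y calls and PAR scans from `DepthRatioModel.fit`."""

    summaries: pd.DataFrame
    x_ids: list[str]
    y_ids: list[str]
    par_scans: dict[str, ParScan]
    female: pd.DataFrame
    male: pd.DataFrame

    @property
    def pars(self) -> list[ParInterval]:
        return [p for scan in self.par_scans.values() for p in scan.pars]

    def summary(self) -> str:
        lines = [
            "Sex chromosome classification (female/male depth ratio)",
            f"  scaffolds: {len(self.summaries)}",
            f"  X candidates: {self.x_ids or 'none'}",
            f"  Y candidates: {self.y_ids or 'none'}",
        ]
        for x, scan in self.par_scans.items():
            if scan.pars:
                for p in scan.pars:
                    lines.append(
                        f"  PAR on {x} ({p.side}): {p.start:,}-{p.end:,} bp"
                    )
            else:
                lines.append(f"  PAR on {x}: none detected")
        top = self.summaries.nlargest(min(len(self.summaries), 12), "length")
        lines.append("")
        lines.append(top.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Scatter of per-scaffold female-to-male ratio against length."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for cls, marker in [("autosome", "o"), ("X", "^"), ("y-candidate", "s")]:
            sub = self.summaries[self.summaries["chrom_class"] == cls]
            if not sub.empty:
                ax.scatter(sub["length"], sub["fm_ratio"], marker=marker, label=cls)
        ax.set_xscale("log")
        ax.set_xlabel("scaffold length (bp)")
        ax.set_ylabel("female / male depth ratio")
        ax.legend()
        return ax
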