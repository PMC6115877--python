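"""Windowed genome scan and the three-stage introgression filter cascade.

Stage 1 keeps windows whose Patterson's D is significant by the contiguous-
block z-test and passes the magnitude criteria (|D| above a floor, the
|ABBA − BABA| gap above a floor).  Stage 2 keeps candidates whose f_d is at
or above a high genome-wide percentile, guarding against windows where low
variation inflates D.  Stage 3 keeps candidates whose donor-recipient d_xy
is significantly LOWER than the scaffold background — the signature that
separates true introgression (recent common ancestry over the tract) from
incomplete lineage sorting (old ancestry, normal divergence).

Windows are tumbling (step = size) by default, matching adjacent-window
genome scans; set step < size for a sliding scan.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .stats import (
    DResult,
    DxyResult,
    FdResult,
    PatternWeights,
    ScaffoldBackground,
    d_ztest,
    dxy,
    dxy_ztest,
    fd_statistic,
)
from .variant_io import PolarizedSiteTable

logger = logging.getLogger(__name__)

__all__ = [
    "WindowSpec",
    "WindowStats",
    "SignificanceCriteria",
    "IntrogressedRegion",
    "ScaffoldBackground",
    "make_windows",
    "compute_window_stats",
    "scaffold_background",
    "stage1_d_filter",
    "stage2_fd_filter",
    "stage3_dxy_filter",
    "run_scan",
    "ScanResult",
    "clade_summary",
    "windows_to_dataframe",
    "write_window_tsv",
    "write_regions_bed",
]

WINDOW_PRESETS = (5_000, 50_000, 100_000, 500_000)


@dataclass(frozen=True)
class WindowSpec:
    """Window size and step in bp; step defaults to size (tumbling)."""

    size: int
    step: Optional[int] = None

    def __post_init__(self):
        if self.step is None:
            object.__setattr__(self, "step", self.size)
        if not 0 < self.step <= self.size:
            raise ValueError("require 0 < step <= size")


@dataclass(frozen=True)
class SignificanceCriteria:
    """Filter thresholds for the cascade (defaults as used genome-wide:
    z-test p < 1e-3 with |D| > 0.59 and |ABBA − BABA| > 10 at stage 1,
    the top decile of f_d at stage 2, and d_xy z-test p < 0.01 at stage 3)."""

    p_threshold: float = 1e-3
    abs_d_min: float = 0.59
    min_abba_baba_gap: float = 10.0
    fd_percentile: float = 90.0
    dxy_p: float = 0.01

    def __post_init__(self):
        if min(self.p_threshold, self.abs_d_min, self.min_abba_baba_gap,
               self.dxy_p) <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.fd_percentile < 100:
            raise ValueError("fd_percentile must be in (0, 100)")


@dataclass
class WindowStats:
    """One genomic window with its statistics and filter provenance."""

    scaffold: str
    start: int  # 0-based half-open
    end: int
    n_sites: int = 0
    weights: Optional[PatternWeights] = None
    d_result: Optional[DResult] = None
    fd_result: Optional[FdResult] = None
    dxy_result: Optional[DxyResult] = None
    dxy_z: Optional[float] = None
    dxy_p: Optional[float] = None
    partial: bool = False  # terminal window shorter than the spec size
    stage_flags: dict = field(default_factory=dict)
    site_slice: Optional[tuple] = None  # (lo, hi) into the source table

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.scaffold, self.start, self.end)

    def passed(self, stage: str) -> bool:
        return bool(self.stage_flags.get(stage))


@dataclass
class IntrogressedRegion:
    """A window surviving all three stages, with the order they applied."""

    window: WindowStats
    stage_order: tuple = ("d_significance", "fd_top_percentile", "dxy_reduction")

    def __post_init__(self):
        missing = [s for s in self.stage_order if not self.window.passed(s)]
        if missing:
            raise ValueError(f"region window failed stages: {missing}")

    @property
    def interval(self) -> tuple[str, int, int]:
        return self.window.interval


def make_windows(table: PolarizedSiteTable, spec: WindowSpec) -> list[WindowStats]:
    """Tile a scaffold from position 0; the final partial window is retained
    and flagged.  Each site belongs to every window containing its 0-based
    coordinate (pos - 1)."""
    windows = []
    length = table.scaffold_length
    start = 0
    while start < length:
        end = min(start + spec.size, length)
        pos0 = table.pos - 1
        lo = int(np.searchsorted(pos0, start, side="left"))
        hi = int(np.searchsorted(pos0, end, side="left"))
        windows.append(
            WindowStats(
                scaffold=table.scaffold,
                start=start,
                end=end,
                n_sites=hi - lo,
                partial=(end - start) < spec.size,
                site_slice=(lo, hi),
            )
        )
        start += spec.step
    return windows


def compute_window_stats(
    table: PolarizedSiteTable,
    windows: list[WindowStats],
    n_blocks: int = 20,
    dxy_pair: tuple[int, int] = (1, 2),
) -> list[WindowStats]:
    """Fill D (with its block z-test), f_d and d_xy for each window.

    ``dxy_pair`` gives the 0-based quartet columns for the divergence pair,
    default (P2, P3) — the donor/recipient pair whose divergence
    introgression reduces.  The d_xy divisor is the count of callable
    aligned positions in the window when the table carries them, else the
    window length in bp (monomorphic positions contribute zero either way).
    """
    ix, iy = dxy_pair
    for w in windows:
        lo, hi = w.site_slice
        freqs = table.freqs[lo:hi]
        w.d_result = d_ztest(freqs, n_blocks=n_blocks)
        w.weights = w.d_result.weights
        w.fd_result = fd_statistic(freqs)
        if table.callable_pos is not None:
            cp = table.callable_pos - 1
            n = int(
                np.searchsorted(cp, w.end, side="left")
                - np.searchsorted(cp, w.start, side="left")
            )
            mode = "aligned_sites"
        else:
            n = w.end - w.start
            mode = "bp"
        w.dxy_result = dxy(freqs[:, ix], freqs[:, iy], n=n, mode=mode)
    return windows


def scaffold_background(
    windows: Sequence[WindowStats], scaffold: str
) -> ScaffoldBackground:
    """Mean and standard deviation of d_xy over the scaffold's full-size
    windows (partial terminal windows are excluded to avoid length-driven
    variance; candidate windows are included — the background is the whole
    scaffold)."""
    values = [
        w.dxy_result.dxy
        for w in windows
        if w.scaffold == scaffold and not w.partial and w.dxy_result is not None
        and w.dxy_result.defined
    ]
    n = len(values)
    if n < 2:
        return ScaffoldBackground(scaffold=scaffold, mean_dxy=float("nan"),
                                  se=0.0, n_windows=n)
    arr = np.asarray(values)
    return ScaffoldBackground(
        scaffold=scaffold,
        mean_dxy=float(arr.mean()),
        se=float(arr.std(ddof=1)),
        n_windows=n,
    )


def stage1_d_filter(
    windows: Sequence[WindowStats], criteria: SignificanceCriteria
) -> list[WindowStats]:
    """Retain windows with block z-test p < p_threshold, |D| > abs_d_min and
    |ABBA − BABA| > min_abba_baba_gap; undefined D never passes."""
    kept = []
    for w in windows:
        r = w.d_result
        ok = (
            r is not None
            and r.defined
            and r.p is not None
            and r.p < criteria.p_threshold
            and abs(r.d) > criteria.abs_d_min
            and r.weights.gap > criteria.min_abba_baba_gap
        )
        w.stage_flags["d_significance"] = ok
        if ok:
            kept.append(w)
    return kept


def stage2_fd_filter(
    candidates: Sequence[WindowStats],
    all_windows: Sequence[WindowStats],
    criteria: SignificanceCriteria,
) -> list[WindowStats]:
    """Retain candidates whose f_d reaches the genome-wide
    ``fd_percentile``-th percentile of defined f_d values (linear
    interpolation); undefined f_d is excluded."""
    if not candidates:
        return []
    fd_values = [
        w.fd_result.fd for w in all_windows if w.fd_result is not None
        and w.fd_result.defined
    ]
    if not fd_values:
        raise RuntimeError(
            "no window has a defined f_d; cannot compute the percentile cutoff"
        )
    cutoff = float(np.percentile(fd_values, criteria.fd_percentile,
                                 method="linear"))
    kept = []
    for w in candidates:
        ok = w.fd_result is not None and w.fd_result.defined \
            and w.fd_result.fd >= cutoff
        w.stage_flags["fd_top_percentile"] = ok
        if ok:
            kept.append(w)
    return kept


def stage3_dxy_filter(
    candidates: Sequence[WindowStats],
    backgrounds: dict,
    criteria: SignificanceCriteria,
) -> list[IntrogressedRegion]:
    """Retain candidates with one-sided-lower d_xy z-test p < dxy_p against
    their scaffold background; candidates on unusable backgrounds are
    dropped with an explicit flag and a log line, never silently."""
    regions = []
    for w in candidates:
        bg = backgrounds.get(w.scaffold)
        if bg is None or not bg.usable:
            w.stage_flags["dxy_reduction"] = False
            w.stage_flags["dxy_background_unusable"] = True
            logger.warning(
                "%s:[%d,%d): dropped — scaffold d_xy background unusable",
                w.scaffold, w.start, w.end,
            )
            continue
        z, p = dxy_ztest(w.dxy_result, bg)
        w.dxy_z, w.dxy_p = z, p
        ok = p is not None and p < criteria.dxy_p
        w.stage_flags["dxy_reduction"] = ok
        if ok:
            regions.append(IntrogressedRegion(window=w))
    return regions


@dataclass
class ScanResult:
    """Everything one window-size scan produced."""

    spec: WindowSpec
    criteria: SignificanceCriteria
    windows: list
    stage1: list
    stage2: list
    regions: list
    backgrounds: dict

    @property
    def attrition(self) -> dict:
        return {
            "windows_tested": len(self.windows),
            "stage1_d_significant": len(self.stage1),
            "stage2_fd_retained": len(self.stage2),
            "stage3_dxy_regions": len(self.regions),
        }


def run_scan(
    tables: Sequence[PolarizedSiteTable],
    spec: WindowSpec,
    criteria: SignificanceCriteria = SignificanceCriteria(),
    n_blocks: int = 20,
    dxy_pair: tuple[int, int] = (1, 2),
) -> ScanResult:
    """Window every scaffold, compute statistics and run the full cascade."""
    windows: list[WindowStats] = []
    for table in tables:
        w = make_windows(table, spec)
        compute_window_stats(table, w, n_blocks=n_blocks, dxy_pair=dxy_pair)
        windows.extend(w)
    backgrounds = {
        t.scaffold: scaffold_background(windows, t.scaffold) for t in tables
    }
    stage1 = stage1_d_filter(windows, criteria)
    stage2 = stage2_fd_filter(stage1, windows, criteria)
    regions = stage3_dxy_filter(stage2, backgrounds, criteria)
    logger.info(
        "scan size=%d: %d windows -> %d (D) -> %d (f_d) -> %d (d_xy)",
        spec.size, len(windows), len(stage1), len(stage2), len(regions),
    )
    return ScanResult(
        spec=spec, criteria=criteria, windows=windows,
        stage1=stage1, stage2=stage2, regions=regions, backgrounds=backgrounds,
    )


def clade_summary(window_results: dict) -> pd.DataFrame:
    """Per-quartet summary of a 500-kb adjacent-window scan: the count and
    fraction of windows with stage-1 D significance (this deliberately uses
    only the D stage — a clade-level introgression incidence overview).

    ``window_results`` maps a quartet label to its list of WindowStats with
    the ``d_significance`` flag set (e.g. ``ScanResult.windows``).
    """
    rows = []
    for quartet, windows in window_results.items():
        n = len(windows)
        k = sum(1 for w in windows if w.passed("d_significance"))
        rows.append(
            {
                "quartet": quartet,
                "n_windows_tested": n,
                "n_windows_significant": k,
                "fraction": k / n if n else 0.0,
            }
        )
    return pd.DataFrame(rows, columns=[
        "quartet", "n_windows_tested", "n_windows_significant", "fraction"
    ])


# ---------------------------------------------------------------------------
# Tabular output

def _fmt(x, nd=6) -> str:
    return "NA" if x is None else f"{x:.{nd}g}"


def windows_to_dataframe(windows: Sequence[WindowStats]) -> pd.DataFrame:
    rows = []
    for w in windows:
        d = w.d_result
        rows.append(
            {
                "scaffold": w.scaffold,
                "start": w.start,
                "end": w.end,
                "n_sites": w.n_sites,
                "abba": _fmt(w.weights.abba if w.weights else None),
                "baba": _fmt(w.weights.baba if w.weights else None),
                "D": _fmt(d.d if d else None),
                "se": _fmt(d.se if d else None),
                "z": _fmt(d.z if d else None),
                "p": _fmt(d.p if d else None),
                "fd": _fmt(w.fd_result.fd if w.fd_result else None),
                "dxy": _fmt(w.dxy_result.dxy if w.dxy_result else None),
                "stage_flags": ";".join(
                    k for k, v in sorted(w.stage_flags.items()) if v
                ) or ".",
            }
        )
    return pd.DataFrame(rows)


def write_window_tsv(windows: Sequence[WindowStats], path) -> None:
    windows_to_dataframe(windows).to_csv(path, sep="\t", index=False)


def write_regions_bed(regions: Sequence[IntrogressedRegion], path) -> None:
    """BED6; the score is |D| scaled to 0-1000."""
    with open(path, "w") as fh:
        for k, r in enumerate(regions):
            w = r.window
            score = int(round(min(abs(w.d_result.d), 1.0) * 1000))
            fh.write(
                f"{w.scaffold}\t{w.start}\t{w.end}\tintrogressed_{k}\t{score}\t.\n"
            )


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
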