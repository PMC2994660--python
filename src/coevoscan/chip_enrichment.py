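"""Hybrid-genome ChIP-Seq windowed IP/Input enrichment.

The pipeline starts after read mapping: per-base coverage tracks over a
concatenated two-species ("hybrid") genome are summarized as medians in
100 bp windows sliding in 50 bp steps; enrichment at a region of
interest is the mean IP/Input ratio over the windows covering it,
normalized by the same quantity at a non-silenced control region.
Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "CoverageTrack",
    "WindowMedianTrack",
    "GenomeRegion",
    "EnrichmentSummary",
    "concat_hybrid_genome",
    "coverage_from_fragments",
    "window_medians",
    "per_base_ratio",
    "region_enrichment",
    "window_correlation",
]


@dataclass
class CoverageTrack:
    """Per-base non-negative read counts over one contig."""

    contig: str
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def length(self) -> int:
        return len(self.counts)


@dataclass
class WindowMedianTrack:
    contig: str
    starts: np.ndarray
    medians: np.ndarray
    window: int = 100
    step: int = 50

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.window


@dataclass
class GenomeRegion:
    contig: str
    start: int
    end: int
    label: str
    role: str = "query"   # query | control

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"bad region coordinates for {self.label!r}")


@dataclass
class EnrichmentSummary:
    label: str
    mean_ratio: float
    normalized_ratio: float
    sem: float
    n_windows: int


def concat_hybrid_genome(genome_a: dict, genome_b: dict,
                         prefix_a: str, prefix_b: str
                         ) -> tuple[dict, pd.DataFrame]:
    """Concatenate two genomes into one contig dict with species-prefixed
    names; returns (hybrid, manifest) where the manifest maps each
    prefixed contig back to its source species."""
    hybrid, rows = {}, []
    for prefix, genome, source in ((prefix_a, genome_a, "a"),
                                   (prefix_b, genome_b, "b")):
        for name, seq in genome.items():
            new = f"{prefix}{name}"
            if new in hybrid:
                raise ValueError(f"duplicate contig name after prefixing: {new}")
            hybrid[new] = seq
            rows.append({"contig": new, "source": source,
                         "original_name": name})
    return hybrid, pd.DataFrame(rows, columns=["contig", "source",
                                               "original_name"])


def coverage_from_fragments(fragments, contig_lengths: dict
                            ) -> dict[str, CoverageTrack]:
    """Per-base coverage from mapped fragment intervals (contig, start,
    end): the count at base b is the number of fragments with
    start <= b < end."""
    diffs = {c: np.zeros(L + 1, dtype=np.int64)
             for c, L in contig_lengths.items()}
    for i, (contig, start, end) in enumerate(fragments):
        if contig not in diffs:
            raise ValueError(f"fragment {i}: unknown contig {contig!r}")
        L = contig_lengths[contig]
        if not (0 <= start < end <= L):
            raise ValueError(f"fragment {i}: [{start}, {end}) out of bounds "
                             f"on {contig} (length {L})")
        diffs[contig][start] += 1
        diffs[contig][end] -= 1
    return {c: CoverageTrack(c, np.cumsum(d[:-1])) for c, d in diffs.items()}


def window_medians(track: CoverageTrack, window: int = 100, step: int = 50
                   ) -> WindowMedianTrack:
    """Median per-base count in windows at starts 0, step, 2*step, ...
    whose end fits on the contig; trailing partial windows are dropped.
    An even window size takes the mean of the two central order
    statistics."""
    L = track.length
    if L < window:
        warnings.warn(f"contig {track.contig} shorter than window; "
                      "empty median track")
        return WindowMedianTrack(track.contig, np.array([], int),
                                 np.array([], float), window, step)
    view = np.lib.stride_tricks.sliding_window_view(track.counts, window)
    starts = np.arange(0, L - window + 1, step)
    medians = np.median(view[starts], axis=1)
    return WindowMedianTrack(track.contig, starts, medians, window, step)


def per_base_ratio(ip: CoverageTrack, input_: CoverageTrack
                   ) -> tuple[np.ndarray, float]:
    """IP/Input ratio at each base; bases with zero input coverage are
    masked (NaN).  Returns (ratio, masked_fraction)."""
    if ip.contig != input_.contig or ip.length != input_.length:
        raise ValueError("tracks must cover the same contig and length")
    inp = input_.counts.astype(float)
    ratio = np.full(ip.length, np.nan)
    ok = inp > 0
    ratio[ok] = ip.counts[ok] / inp[ok]
    return ratio, float((~ok).mean())


def _as_track_dict(tracks) -> dict[str, WindowMedianTrack]:
    if isinstance(tracks, WindowMedianTrack):
        return {tracks.contig: tracks}
    return dict(tracks)


def _region_window_ratios(ip_w, input_w, region: GenomeRegion) -> np.ndarray:
    ipt = ip_w.get(region.contig)
    int_ = input_w.get(region.contig)
    if ipt is None or int_ is None:
        raise ValueError(f"no window track for contig {region.contig!r}")
    if len(ipt.starts) != len(int_.starts) or \
            not np.array_equal(ipt.starts, int_.starts):
        raise ValueError("IP and input window grids differ")
    covers = (ipt.starts < region.end) & (ipt.ends > region.start)
    usable = covers & (int_.medians > 0)
    return ipt.medians[usable] / int_.medians[usable]


def region_enrichment(ip_windows, input_windows, regions: list[GenomeRegion],
                      control: GenomeRegion) -> list[EnrichmentSummary]:
    """Mean windowed IP/Input per region, normalized to a control region.

    A window covers a region if their spans overlap by at least 1 bp;
    windows with zero input median are skipped.  The summary carries the
    raw mean ratio, the control-normalized ratio, and the standard error
    of the mean over covering windows.  Expected region size is 600 bp
    (a warning, not an error, otherwise).
    """
    ip_w = _as_track_dict(ip_windows)
    in_w = _as_track_dict(input_windows)
    ctrl_ratios = _region_window_ratios(ip_w, in_w, control)
    if ctrl_ratios.size == 0:
        raise ValueError("control region has no usable windows")
    ctrl_mean = float(ctrl_ratios.mean())
    out = []
    for region in regions:
        if region.end - region.start != 600:
            warnings.warn(f"region {region.label!r} is "
                          f"{region.end - region.start} bp, not 600 bp")
        ratios = _region_window_ratios(ip_w, in_w, region)
        if ratios.size == 0:
            raise ValueError(f"region {region.label!r} has no covering windows")
        sem = float(ratios.std(ddof=1) / np.sqrt(ratios.size)) \
            if ratios.size > 1 else 0.0
        out.append(EnrichmentSummary(
            region.label, float(ratios.mean()),
            float(ratios.mean() / ctrl_mean), sem, int(ratios.size)))
    return out


def window_correlation(a, b) -> float:
    """Genome-wide Pearson correlation of paired window medians."""
    aw, bw = _as_track_dict(a), _as_track_dict(b)
    if set(aw) != set(bw):
        raise ValueError("track collections cover different contigs")
    xs, ys = [], []
    for contig in sorted(aw):
        ta, tb = aw[contig], bw[contig]
        if not np.array_equal(ta.starts, tb.starts):
            raise ValueError(f"window grids differ on contig {contig!r}")
        xs.append(ta.medians)
        ys.append(tb.medians)
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero variance in a window-median vector")
    return float(np.corrcoef(x, y)[0, 1])
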