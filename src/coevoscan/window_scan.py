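"""Sliding-window omega scan and the empirical genome-window null.

Windows of 102 nt (34 codons) advance in 3 nt steps along the alignment,
each fitted with the single-ratio model; windows touching any gapped or
ambiguous column are excluded.  Because short windows are noisy, the
scan is read against an empirical null built from the same-sized windows
of a collection of background genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_core import CodonAlignment, OMEGA_CAP, fit_M0
from .trees import PhyloTree

__all__ = [
    "AlignmentWindow",
    "WindowSet",
    "ScanResult",
    "EmpiricalNull",
    "enumerate_windows",
    "scan_omega",
    "build_empirical_null",
    "summarize_scan",
]


@dataclass
class AlignmentWindow:
    """Half-open nucleotide interval [start, end) in alignment frame."""

    start: int
    end: int
    gap_free: bool

    @property
    def codon_start(self) -> int:
        return self.start // 3

    @property
    def codon_end(self) -> int:
        return self.end // 3


@dataclass
class WindowSet:
    windows: list[AlignmentWindow]      # gap-free windows only
    n_excluded: int
    window_size: int
    step: int
    alignment_length: int


@dataclass
class ScanResult:
    table: pd.DataFrame                 # start, end, omega, kappa, converged, capped
    window_size: int
    step: int
    mode: str
    n_excluded: int

    @property
    def summary(self) -> dict:
        om = self.table["omega"].to_numpy(float)
        valid = om[np.isfinite(om)]
        return {
            "n_windows": int(len(self.table)),
            "n_excluded": int(self.n_excluded),
            "median_omega": float(np.median(valid)) if valid.size else float("nan"),
            "min_omega": float(valid.min()) if valid.size else float("nan"),
            "max_omega": float(valid.max()) if valid.size else float("nan"),
            "frac_gt1": float((valid > 1).mean()) if valid.size else float("nan"),
            "mode": self.mode,
        }


@dataclass
class EmpiricalNull:
    values: np.ndarray
    sources: list
    seed: int
    window_size: int

    @property
    def n(self) -> int:
        return len(self.values)

    @property
    def median(self) -> float:
        return float(np.median(self.values))

    @property
    def interval95(self) -> tuple[float, float]:
        """Central 95% interval as order statistics of the stored sample."""
        lo = float(np.quantile(self.values, 0.025, method="closest_observation"))
        hi = float(np.quantile(self.values, 0.975, method="closest_observation"))
        return lo, hi


def enumerate_windows(alignment: CodonAlignment, window_size: int = 102,
                      step: int = 3) -> WindowSet:
    """All codon-frame windows [k*step, k*step + window_size) whose end
    fits in the alignment; windows overlapping any gap column are
    dropped and counted in ``n_excluded``."""
    if window_size % 3 or step % 3:
        raise ValueError("window_size and step must be divisible by 3 "
                         "to preserve the codon frame")
    L = alignment.nucleotide_length
    if window_size > L:
        warnings.warn("window size exceeds alignment length; no windows")
        return WindowSet([], 0, window_size, step, L)
    gap_cols = alignment.gap_columns()
    # prefix sums over codon columns for O(1) gap-overlap queries
    cum = np.concatenate([[0], np.cumsum(gap_cols)])
    windows, n_excl = [], 0
    for start in range(0, L - window_size + 1, step):
        c0, c1 = start // 3, (start + window_size) // 3
        if cum[c1] - cum[c0] == 0:
            windows.append(AlignmentWindow(start, start + window_size, True))
        else:
            n_excl += 1
    return WindowSet(windows, n_excl, window_size, step, L)


def _fit_window(sub: CodonAlignment, tree: PhyloTree, seed: int) -> dict:
    try:
        fit = fit_M0(sub, tree, optimize_branch_lengths=False,
                     n_starts=1, seed=seed)
        om = fit.params.omega
        return {"omega": om, "kappa": fit.params.kappa,
                "converged": fit.converged,
                "capped": bool(np.isfinite(om) and om >= OMEGA_CAP)}
    except Exception as exc:  # fit failures flag the window, not the scan
        return {"omega": np.nan, "kappa": np.nan, "converged": False,
                "capped": False, "error": str(exc)}


def scan_omega(alignment: CodonAlignment, tree: PhyloTree,
               window_size: int = 102, step: int = 3,
               mode: str = "fixed-branch-lengths", seed: int = 0
               ) -> ScanResult:
    """Single-ratio omega in each gap-free window along the alignment.

    In the default "fixed-branch-lengths" mode the whole-gene M0 branch
    lengths are estimated once and reused in every window (omega and
    kappa are still estimated per window); "refit-all" re-estimates
    branch lengths inside each window as well.
    """
    if mode not in ("fixed-branch-lengths", "refit-all"):
        raise ValueError(f"unknown scan mode {mode!r}")
    ws = enumerate_windows(alignment, window_size, step)
    if not ws.windows:
        return ScanResult(pd.DataFrame(
            columns=["start", "end", "omega", "kappa", "converged", "capped"]),
            window_size, step, mode, ws.n_excluded)
    if mode == "fixed-branch-lengths":
        gene_fit = fit_M0(alignment, tree, optimize_branch_lengths=True,
                          n_starts=2, seed=seed)
        scan_tree = gene_fit.tree
    else:
        scan_tree = tree
    rows = []
    for w in ws.windows:
        sub = alignment.slice_codons(w.codon_start, w.codon_end)
        if mode == "refit-all":
            rec = _refit_window(sub, scan_tree, seed)
        else:
            rec = _fit_window(sub, scan_tree, seed)
        rec.update(start=w.start, end=w.end)
        rows.append(rec)
    table = pd.DataFrame(rows)[
        ["start", "end", "omega", "kappa", "converged", "capped"]]
    return ScanResult(table, window_size, step, mode, ws.n_excluded)


def _refit_window(sub: CodonAlignment, tree: PhyloTree, seed: int) -> dict:
    try:
        fit = fit_M0(sub, tree, optimize_branch_lengths=True,
                     n_starts=1, seed=seed)
        om = fit.params.omega
        return {"omega": om, "kappa": fit.params.kappa,
                "converged": fit.converged,
                "capped": bool(np.isfinite(om) and om >= OMEGA_CAP)}
    except Exception as exc:
        return {"omega": np.nan, "kappa": np.nan, "converged": False,
                "capped": False, "error": str(exc)}


def build_empirical_null(gene_alignments, tree: PhyloTree,
                         n_windows: int = 1500, window_size: int = 102,
                         step: int = 3, seed: int = 0) -> EmpiricalNull:
    """Empirical omega null from windows of background genes.

    Gap-free windows are pooled across all genes, ``n_windows`` are
    sampled uniformly without replacement (all of them, with a warning,
    if fewer are available), and each sampled window gets a single-ratio
    omega fit reusing per-gene M0 branch lengths.
    """
    pool = []
    gene_trees = {}
    for g, aln in enumerate(gene_alignments):
        ws = enumerate_windows(aln, window_size, step)
        pool.extend((g, w) for w in ws.windows)
    if not pool:
        raise ValueError("no gap-free windows in the gene set")
    rng = np.random.default_rng(seed)
    if n_windows >= len(pool):
        if n_windows > len(pool):
            warnings.warn(f"requested {n_windows} windows but only "
                          f"{len(pool)} available; using all")
        chosen = list(range(len(pool)))
    else:
        chosen = rng.choice(len(pool), size=n_windows, replace=False)
    values, sources = [], []
    for idx in chosen:
        g, w = pool[int(idx)]
        if g not in gene_trees:
            gene_trees[g] = fit_M0(gene_alignments[g], tree,
                                   optimize_branch_lengths=True,
                                   n_starts=1, seed=seed).tree
        sub = gene_alignments[g].slice_codons(w.codon_start, w.codon_end)
        rec = _fit_window(sub, gene_trees[g], seed)
        if np.isfinite(rec["omega"]):
            values.append(rec["omega"])
            sources.append((g, w.start))
    return EmpiricalNull(np.asarray(values, float), sources, seed, window_size)


def summarize_scan(scan: ScanResult, null: EmpiricalNull,
                   beb: pd.DataFrame | None = None) -> dict:
    """Scan-versus-null report plus a plot-ready (midpoint, omega) table.

    If a BEB site-posterior table is given, flagged codons are mapped to
    alignment nucleotide coordinates and to the windows containing them.
    """
    if scan.table.empty:
        raise ValueError("empty scan")
    om = scan.table["omega"].to_numpy(float)
    valid = np.isfinite(om)
    lo, hi = null.interval95
    report = {
        "scan_median": float(np.median(om[valid])),
        "null_median": null.median,
        "null_interval95": (lo, hi),
        "frac_above_null_q975": float((om[valid] > hi).mean()),
        "frac_gt1": float((om[valid] > 1).mean()),
        "n_windows": int(valid.sum()),
    }
    plot = pd.DataFrame({
        "midpoint": (scan.table["start"] + scan.table["end"]) / 2.0,
        "omega": om,
    })
    report["plot_table"] = plot
    if beb is not None:
        flagged = beb[beb["flagged"]]
        starts = scan.table["start"].to_numpy()
        ends = scan.table["end"].to_numpy()
        sites = []
        for _, row in flagged.iterrows():
            nt = 3 * int(row["site"])
            covering = np.where((starts <= nt) & (nt + 3 <= ends))[0]
            sites.append({
                "site": int(row["site"]),
                "ref_position": row["ref_position"],
                "nt_start": nt,
                "covering_windows": [int(starts[i]) for i in covering],
            })
        report["beb_flagged"] = sites
    return report
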