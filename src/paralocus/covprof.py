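"""Depth profiles, sliding-window coverage tracks and per-gene coverage.

Two depth tracks are maintained per reference: *total* depth, where each read
contributes at its best placement(s) (ties count at every tied-best position
by default), and *unique* depth, restricted to reads with a single best
placement. The contrast between the two is the mappability signal that
separates single-copy from duplicated sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mapper import MappedRead
from .synthlocus import GeneModel


@dataclass(frozen=True)
class WindowParams:
    """Window sizes for the sliding-window analyses: 300 bp for coverage
    tracks, 500 bp for block identity, 250 bp for dot-plots; the positive
    control convention keeps positions with depth above ``control_min_depth``."""

    coverage_window: int = 300
    identity_window: int = 500
    dotplot_window: int = 250
    control_min_depth: int = 1000

    def __post_init__(self) -> None:
        for w in (self.coverage_window, self.identity_window, self.dotplot_window):
            if w < 50:
                raise ValueError("windows must be >= 50 bp")
        if self.control_min_depth < 1:
            raise ValueError("control_min_depth must be >= 1")


@dataclass
class DepthProfile:
    ref_id: str
    total_depth: np.ndarray
    unique_depth: np.ndarray

    def __post_init__(self) -> None:
        if self.total_depth.shape != self.unique_depth.shape:
            raise ValueError("depth track lengths differ")
        if np.any(self.unique_depth > self.total_depth):
            raise ValueError("unique depth exceeds total depth")


def depth_profile(
    mapped: list[MappedRead],
    ref_length: int,
    ref_id: str = "ref",
    multi_policy: str = "all_best",
) -> DepthProfile:
    """Accumulate per-position total and unique depth for one reference.

    ``multi_policy`` governs multi-mapping reads in the *total* track:
    "all_best" (default) counts them at every tied-best placement; "exclude"
    drops them. Unique depth always counts only uniquely mapping reads.
    Hits on other references are ignored; out-of-bounds hits are an error.
    """
    if multi_policy not in ("all_best", "exclude"):
        raise ValueError(f"unknown multi_policy {multi_policy!r}")
    total = np.zeros(ref_length + 1, dtype=np.int64)
    unique = np.zeros(ref_length + 1, dtype=np.int64)
    for mr in mapped:
        if not mr.hits:
            continue
        best = mr.hits[0].mismatches
        is_unique = mr.uniqueness == "unique"
        if not is_unique and multi_policy == "exclude":
            continue
        for h in mr.hits:
            if h.mismatches != best or h.ref_id != ref_id:
                continue
            if h.start < 0 or h.start + mr.read_length > ref_length:
                raise ValueError(f"hit out of bounds: {h} (read {mr.read_id})")
            total[h.start] += 1
            total[h.start + mr.read_length] -= 1
            if is_unique:
                unique[h.start] += 1
                unique[h.start + mr.read_length] -= 1
    return DepthProfile(ref_id, np.cumsum(total[:-1]), np.cumsum(unique[:-1]))


def sliding_mean_depth(depth: np.ndarray, window: int = 300) -> np.ndarray:
    """Mean depth per sliding window (step 1), value at window start;
    output length N - window + 1."""
    n = len(depth)
    if window > n:
        raise ValueError(f"window {window} exceeds profile length {n}")
    csum = np.concatenate(([0], np.cumsum(depth, dtype=np.float64)))
    return (csum[window:] - csum[:-window]) / window


def gene_coverage_pct(
    profile: DepthProfile,
    gene: GeneModel,
    use_unique: bool = True,
    min_depth: int = 1,
    exonic_only: bool = False,
) -> float:
    """Percent of a gene's positions with depth >= ``min_depth``.

    By default the genomic span (introns included) is assessed; with
    ``exonic_only`` only exon positions count. ``use_unique`` selects the
    unique-depth track (the presence-evidence convention) over total depth.
    """
    track = profile.unique_depth if use_unique else profile.total_depth
    s, e = gene.span
    if e > len(track):
        raise ValueError(f"gene {gene.gene_id} outside reference")
    if exonic_only:
        idx = np.concatenate([np.arange(a, b) for a, b in gene.exons])
        sel = track[idx]
    else:
        sel = track[s:e]
    if sel.size == 0:
        return 0.0
    return 100.0 * float(np.count_nonzero(sel >= min_depth)) / sel.size


def coverage_report(profile: DepthProfile, genes: list[GeneModel], min_depth: int = 1):
    """Per-gene coverage rows: (gene_id, group, span_bp, total_pct,
    unique_pct, mean_depth)."""
    rows = []
    for g in genes:
        s, e = g.span
        rows.append(
            (
                g.gene_id,
                g.group,
                e - s,
                gene_coverage_pct(profile, g, use_unique=False, min_depth=min_depth),
                gene_coverage_pct(profile, g, use_unique=True, min_depth=min_depth),
                float(profile.total_depth[s:e].mean()) if e > s else 0.0,
            )
        )
    return rows


def write_bedgraph(path, profile: DepthProfile, track: str = "unique") -> None:
    depth = profile.unique_depth if track == "unique" else profile.total_depth
    with open(path, "w") as fh:
        start = 0
        for i in range(1, len(depth) + 1):
            if i == len(depth) or depth[i] != depth[start]:
                fh.write(f"{profile.ref_id}\t{start}\t{i}\t{int(depth[start])}\n")
                start = i
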