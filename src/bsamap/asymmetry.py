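"""Pool-to-parent inheritance ratios and the per-segment asymmetry statistic.

Each pool was mapped to each reference separately, so each (pool, genome)
combination is one library of mapped reads with its own total. For each
segment s the four normalized ratios are (genome A plays the
switching-competent parent's role):

    SW_A = (n[s, SW, A] / N[SW, A]) / (n[s, parent_A, A] / N[parent_A, A])
    NS_A = (n[s, NS, A] / N[NS, A]) / (n[s, parent_A, A] / N[parent_A, A])
    SW_B = (n[s, SW, B] / N[SW, B]) / (n[s, parent_B, B] / N[parent_B, B])
    NS_B = (n[s, NS, B] / N[NS, B]) / (n[s, parent_B, B] / N[parent_B, B])

where N[lib, g] is that library's total reads retained as exclusive to
genome g. With this normalization an unbiased segment has expected ratio 1,
and a pool in which every clone inherited one parent's allele approaches 2
(the pool's genome-wide retained total is roughly half of either parent's
because each clone is a 50:50 mosaic). The asymmetry statistic is the
clamped product

    max(SW_A - 1, 0) * max(1 - NS_A, 0) * max(NS_B - 1, 0) * max(1 - SW_B, 0)

which is zero unless all four inheritance biases point in the direction
predicted by the phenotype simultaneously. Segments whose parental
denominator is zero are flagged invalid and score zero (no pseudocount by
default; ``pseudocount`` adds alpha to every count instead).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .segments import Segment, SegmentCountMatrix, SegmentMap

RATIO_COLUMNS = ("SW_A", "NS_A", "SW_B", "NS_B")


def merge_mating_types(matrix: SegmentCountMatrix) -> SegmentCountMatrix:
    """Sum the MATa and MATalpha libraries of each phenotype countwise."""
    needed = {"SW_a", "SW_alpha", "NS_a", "NS_alpha"}
    have = set(lib for lib, _ in matrix.counts.columns)
    missing = needed - have
    if missing:
        raise KeyError(f"cannot merge mating types; missing libraries {sorted(missing)}")
    out = {}
    for lib in sorted(have - needed):
        out[lib] = matrix.counts[lib]
    merged = {
        "SW": matrix.counts["SW_a"] + matrix.counts["SW_alpha"],
        "NS": matrix.counts["NS_a"] + matrix.counts["NS_alpha"],
    }
    out.update(merged)
    frames = []
    for lib in sorted(out):
        df = out[lib].copy()
        df.columns = pd.MultiIndex.from_product([[lib], df.columns],
                                                names=["library", "genome"])
        frames.append(df)
    counts = pd.concat(frames, axis=1)
    totals = {}
    for g in ("A", "B"):
        for lib in sorted(have - needed):
            totals[(lib, g)] = matrix.totals[(lib, g)]
        totals[("SW", g)] = matrix.totals[("SW_a", g)] + matrix.totals[("SW_alpha", g)]
        totals[("NS", g)] = matrix.totals[("NS_a", g)] + matrix.totals[("NS_alpha", g)]
    return SegmentCountMatrix(counts, totals)


def compute_ratios(matrix: SegmentCountMatrix,
                   pseudocount: float = 0.0) -> pd.DataFrame:
    """The four normalized pool/parent ratios per segment.

    Returns a DataFrame indexed by segment with columns SW_A, NS_A, SW_B,
    NS_B and boolean validity columns ``<ratio>_valid`` (False where the
    parental denominator count is zero).
    """
    pairing = {
        "SW_A": ("SW", "parent_A", "A"),
        "NS_A": ("NS", "parent_A", "A"),
        "SW_B": ("SW", "parent_B", "B"),
        "NS_B": ("NS", "parent_B", "B"),
    }
    for pool, parent, genome in pairing.values():
        for lib in (pool, parent):
            if (lib, genome) not in matrix.totals:
                raise KeyError(f"missing library {lib!r}; merge mating types first")
            if matrix.totals[(lib, genome)] <= 0:
                raise ValueError(
                    f"library {lib!r} has zero reads exclusive to genome {genome}")
    a = pseudocount
    c = matrix.counts
    out = pd.DataFrame(index=c.index)
    for name, (pool, parent, genome) in pairing.items():
        num = (c[(pool, genome)] + a) / matrix.totals[(pool, genome)]
        den = (c[(parent, genome)] + a) / matrix.totals[(parent, genome)]
        valid = den > 0
        ratio = np.where(valid, num / den.where(valid, 1.0), np.nan)
        out[name] = ratio
        out[f"{name}_valid"] = valid.to_numpy()
    return out


def asymmetry_value(sw_a: float, ns_a: float, sw_b: float, ns_b: float) -> float:
    """The clamped-product statistic for one segment.

    Any NaN (invalid ratio) yields 0; negative ratios are rejected.
    """
    vals = (sw_a, ns_a, sw_b, ns_b)
    if any(v is not None and not np.isnan(v) and v < 0 for v in vals):
        raise ValueError(f"ratios must be non-negative, got {vals}")
    if any(v is None or np.isnan(v) for v in vals):
        return 0.0
    return (max(sw_a - 1.0, 0.0) * max(1.0 - ns_a, 0.0)
            * max(ns_b - 1.0, 0.0) * max(1.0 - sw_b, 0.0))


def asymmetry_profile(ratios: pd.DataFrame) -> pd.Series:
    """Vectorized asymmetry over a ratio table (NaN-invalid segments -> 0)."""
    sw_a = ratios["SW_A"].to_numpy(dtype=float)
    ns_a = ratios["NS_A"].to_numpy(dtype=float)
    sw_b = ratios["SW_B"].to_numpy(dtype=float)
    ns_b = ratios["NS_B"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        val = (np.maximum(sw_a - 1.0, 0.0) * np.maximum(1.0 - ns_a, 0.0)
               * np.maximum(ns_b - 1.0, 0.0) * np.maximum(1.0 - sw_b, 0.0))
    val = np.where(np.isnan(val), 0.0, val)
    return pd.Series(val, index=ratios.index, name="asymmetry")


@dataclass(frozen=True)
class Peak:
    rank: int
    chrom: str
    segment_ids: Tuple[str, ...]   # the contiguous positive run
    apex_segment: str
    apex_value: float
    apex_ortholog_pair: Optional[Tuple[str, str]]

    def __contains__(self, segment_id: str) -> bool:
        return segment_id in self.segment_ids


def rank_peaks(profile: pd.Series, segment_map: SegmentMap,
               min_value: float = 0.0) -> List[Peak]:
    """Maximal runs of segments with asymmetry > min_value, ranked by apex.

    Runs never span chromosomes. Ties in apex value break by genomic order.
    """
    raw: List[Tuple[float, int, List[Segment], Segment]] = []
    order = 0
    for chrom in segment_map.chromosomes:
        run: List[Segment] = []
        for seg in segment_map.on_chromosome(chrom) + [None]:
            value = float(profile.get(seg.segment_id, 0.0)) if seg is not None else 0.0
            if seg is not None and value > min_value:
                run.append(seg)
            elif run:
                apex = max(run, key=lambda s: float(profile[s.segment_id]))
                raw.append((float(profile[apex.segment_id]), order, run, apex))
                order += 1
                run = []
    raw.sort(key=lambda t: (-t[0], t[1]))
    peaks = []
    for rank, (apex_value, _, run, apex) in enumerate(raw, start=1):
        pair = (apex.gene_a, apex.gene_b) if apex.kind == "gene" else None
        peaks.append(Peak(rank, apex.chrom, tuple(s.segment_id for s in run),
                          apex.segment_id, apex_value, pair))
    return peaks


def plot_profile(profile: pd.Series, segment_map: SegmentMap, path: str,
                 highlight: Optional[str] = None) -> None:
    """Simple genome-wide asymmetry track, one panel per chromosome."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = segment_map.chromosomes
    fig, axes = plt.subplots(1, len(chroms), figsize=(2.2 * len(chroms), 2.6),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[0], chroms):
        segs = segment_map.on_chromosome(chrom)
        mids = [(s.a_start + s.a_end) / 2e3 for s in segs]
        vals = [float(profile[s.segment_id]) for s in segs]
        ax.plot(mids, vals, lw=0.8, color="steelblue")
        ax.set_title(chrom, fontsize=8)
        ax.set_xlabel("kb", fontsize=7)
        if highlight is not None:
            try:
                seg = segment_map.gene_segment(highlight)
            except KeyError:
                seg = None
            if seg is not None and seg.chrom == chrom:
                ax.axvline((seg.a_start + seg.a_end) / 2e3, color="red",
                           lw=0.8, ls="--")
    axes[0][0].set_ylabel("asymmetry")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
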