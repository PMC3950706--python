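"""A simplified enrichment caller and the two peak-selection filters.

The caller is deliberately plain plumbing so the pipeline runs end-to-end
without external software: a Poisson sliding-window test against the larger
of the genome-wide background rate and the depth-scaled control count, with
an empirical false discovery rate obtained by swapping treatment and
control. Externally called peaks can be ingested instead and pass through
the same selection filters: exclusion of peaks carrying more than a
threshold of control tags, and retention of peaks at or below an FDR
cutoff.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import poisson

from .model import ConfigurationError, Interval, Peak, Tag, ValidationError
from .tags import TagIndex

__all__ = [
    "CallerParams",
    "PeakCallingWarning",
    "call_peaks",
    "exclude_by_control",
    "filter_fdr",
]


class PeakCallingWarning(UserWarning):
    pass


@dataclass(frozen=True, slots=True)
class CallerParams:
    """Sliding-window caller parameters.

    ``genome_size`` sets the background rate (total treatment tags divided
    by genome length); windows of ``window`` bp advance by ``step`` bp so
    neighbouring significant windows overlap and merge into one peak.
    """

    genome_size: int
    window: int = 300
    step: int = 100
    pvalue_cutoff: float = 1e-5
    fdr_cutoff: float = 0.001

    def __post_init__(self) -> None:
        if self.genome_size <= 0:
            raise ConfigurationError("genome_size must be a positive integer")
        if not (0 < self.step <= self.window):
            raise ValidationError(
                f"need 0 < step <= window, got step={self.step}, window={self.window}"
            )
        if not (0.0 < self.pvalue_cutoff < 1.0):
            raise ValidationError(f"pvalue_cutoff must lie in (0, 1), got {self.pvalue_cutoff}")


def _raw_windows(
    treat: TagIndex, ctrl: TagIndex, params: CallerParams
) -> list[tuple[Interval, float]]:
    """Significant-window candidates merged into (interval, min p) runs."""
    n_t = treat.n_tags
    n_c = ctrl.n_tags
    bg_rate = n_t / params.genome_size
    scale = (n_t / n_c) if n_c > 0 else 0.0

    out: list[tuple[Interval, float]] = []
    for chrom in treat.chroms():
        extent = max(treat.max_position(chrom), ctrl.max_position(chrom)) + params.window
        starts = np.arange(0, extent, params.step, dtype=np.int64)
        ends = starts + params.window
        x = treat.count_five_prime_in_many(chrom, starts, ends)
        c = ctrl.count_five_prime_in_many(chrom, starts, ends)
        lam = np.maximum(bg_rate * params.window, c * scale)
        lam = np.maximum(lam, 1e-12)
        with np.errstate(divide="ignore"):
            p = poisson.sf(x - 1, lam)  # upper tail P(X >= x)
        sel = (p <= params.pvalue_cutoff) & (x > 0)
        if not sel.any():
            continue
        run_start = run_end = None
        run_p = 1.0
        for s, e, pv in zip(starts[sel], ends[sel], p[sel]):
            if run_end is not None and s < run_end:  # overlapping windows merge
                run_end = max(run_end, int(e))
                run_p = min(run_p, float(pv))
            else:
                if run_end is not None:
                    out.append((Interval(chrom, run_start, run_end), run_p))
                run_start, run_end, run_p = int(s), int(e), float(pv)
        out.append((Interval(chrom, run_start, run_end), run_p))
    return out


def call_peaks(
    treatment: Sequence[Tag], control: Sequence[Tag], params: CallerParams
) -> list[Peak]:
    """Call enriched peaks with a swap-based empirical FDR.

    Each peak's FDR is the step function
    ``#(control-vs-treatment peaks with p ≤ p_i) / #(treatment peaks with
    p ≤ p_i)``, clipped to [0, 1] — the number of peaks the same procedure
    finds in the swapped comparison at least as significant as this one,
    relative to the number found in the real comparison. ``tag_count`` is
    filled with the 5′-in-interval treatment count.
    """
    if len(treatment) == 0:
        warnings.warn("no treatment tags: returning no peaks", PeakCallingWarning)
        return []
    t_idx = TagIndex(treatment)
    c_idx = TagIndex(control)

    fwd = _raw_windows(t_idx, c_idx, params)
    if not fwd:
        return []
    swapped = _raw_windows(c_idx, t_idx, params) if c_idx.n_tags else []

    t_ps = np.sort(np.array([p for _, p in fwd]))
    c_ps = np.sort(np.array([p for _, p in swapped])) if swapped else np.array([])

    peaks: list[Peak] = []
    for iv, p in fwd:
        n_at_least = int(np.searchsorted(t_ps, p, side="right"))
        n_swap = int(np.searchsorted(c_ps, p, side="right")) if c_ps.size else 0
        fdr = min(1.0, n_swap / n_at_least)
        score = -10.0 * math.log10(max(p, 1e-300))
        peaks.append(
            Peak(iv, score, fdr, tag_count=t_idx.count_five_prime_in(iv))
        )
    return peaks


def _control_indexes(
    controls: "Sequence[Tag] | Mapping[str, Sequence[Tag]] | Sequence[Sequence[Tag]]",
) -> list[TagIndex]:
    if isinstance(controls, Mapping):
        return [TagIndex(v) for _, v in sorted(controls.items())]
    seq = list(controls)
    if not seq:
        return []
    if isinstance(seq[0], Tag):
        return [TagIndex(seq)]  # a single control library
    return [TagIndex(c) for c in seq]


def exclude_by_control(
    peaks: Sequence[Peak],
    controls: "Sequence[Tag] | Mapping[str, Sequence[Tag]] | Sequence[Sequence[Tag]]",
    threshold: int = 100,
) -> tuple[list[Peak], list[Peak]]:
    """Partition peaks by control occupancy.

    A peak is excluded iff its raw 5′-in-interval tag count exceeds
    ``threshold`` (strictly) in ANY supplied control library; a count of
    exactly ``threshold`` is kept. Returns (kept, excluded), a disjoint
    partition of the input in input order.
    """
    idxs = _control_indexes(controls)
    kept: list[Peak] = []
    excluded: list[Peak] = []
    for p in peaks:
        if any(idx.count_five_prime_in(p.interval) > threshold for idx in idxs):
            excluded.append(p)
        else:
            kept.append(p)
    return kept, excluded


def filter_fdr(peaks: Iterable[Peak], cutoff: float = 0.001) -> list[Peak]:
    """Retain peaks with FDR ≤ cutoff (inclusive)."""
    out: list[Peak] = []
    for p in peaks:
        if p.fdr is None:
            raise ValidationError(f"peak {p.interval} carries no FDR")
        if p.fdr <= cutoff:
            out.append(p)
    return out
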