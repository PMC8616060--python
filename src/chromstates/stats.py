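"""Per-state genome-fraction summaries and protein enrichment statistics.

Compartments (e.g. the heterochromatic 3LHet+3RHet region versus the
euchromatic remainder) are compared state by state: how much of the unmasked
sequence each chromatin state occupies, and whether a protein's bin-level
signal within a state differs from the genomic background.  Significance
follows a fixed two-sided rank-sum rule at p < 0.001, with no multiple-testing
correction by default (a Bonferroni option is provided).

Caveat recorded in the output metadata: the sampling unit is the genome bin,
and neighbouring bins are autocorrelated, so p-values are anti-conservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hmm import Segmentation, segmentation_to_path
from .intervals import BinnedGenome, GenomicInterval, SignalTrack, intervals_to_track

__all__ = [
    "StateProportions",
    "state_proportions",
    "mann_whitney_u",
    "pairwise_wilcoxon",
    "enrichment_table",
]

#: Maximum pooled sample size for exact Mann-Whitney enumeration.
_EXACT_LIMIT = 16


@dataclass
class StateProportions:
    """Fraction of unmasked bp per state label within a compartment."""

    compartment: str
    fractions: dict[str, float]

    def __post_init__(self):
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


def _merge(intervals: list[GenomicInterval]) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chrom, []).append((iv.start, iv.end))
    out = {}
    for chrom, spans in by_chrom.items():
        spans.sort()
        merged = [list(spans[0])]
        for s, e in spans[1:]:
            if s <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        out[chrom] = [(s, e) for s, e in merged]
    return out


def state_proportions(seg: Segmentation, regions: list[GenomicInterval],
                      compartment: str = "") -> StateProportions:
    """bp fraction of each state within ``regions`` (regions merged first)."""
    merged = _merge(list(regions))
    bp: dict[str, int] = {}
    total = 0
    for iv, lab in seg:
        for rs, re in merged.get(iv.chrom, ()):
            ov = min(iv.end, re) - max(iv.start, rs)
            if ov > 0:
                bp[lab] = bp.get(lab, 0) + ov
                total += ov
    if total == 0:
        raise ValueError("segmentation does not intersect the given regions")
    return StateProportions(compartment, {lab: v / total for lab, v in bp.items()})


def mann_whitney_u(x, y, alternative: str = "two-sided") -> tuple[float, float]:
    """Mann–Whitney U rank-sum test with midrank tie handling.

    The null distribution is enumerated exactly when the pooled sample has at
    most 16 observations and no ties; otherwise a tie-corrected normal
    approximation with continuity correction is used.  Returns (U, p) where U
    counts (x_i > y_j) pairs plus half-ties.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:  # every value tied: no evidence either way
        return float(x.size * y.size / 2), 1.0
    exact = (x.size + y.size <= _EXACT_LIMIT
             and np.unique(pooled).size == pooled.size)
    res = sps.mannwhitneyu(x, y, alternative=alternative,
                           method="exact" if exact else "asymptotic",
                           use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Two-sided rank-sum p-values for every unordered pair of states.

    The comparisons are between unpaired bin samples, so the rank-sum
    (Mann–Whitney) form of the Wilcoxon test is used.  Returns a symmetric
    matrix with unit diagonal, indexed by state label.
    """
    keys = [k for k, v in samples.items() if np.asarray(v).size > 0]
    if len(keys) < 2:
        raise ValueError("need at least two nonempty samples")
    mat = pd.DataFrame(np.ones((len(keys), len(keys))), index=keys, columns=keys)
    for i, a in enumerate(keys):
        for b in keys[i + 1:]:
            _, p = mann_whitney_u(samples[a], samples[b])
            mat.loc[a, b] = mat.loc[b, a] = p
    return mat


def enrichment_table(
    tracks: list[SignalTrack],
    seg: Segmentation,
    compartment: list[GenomicInterval],
    background: list[GenomicInterval],
    grid: BinnedGenome,
    alpha: float = 0.001,
    compartment_name: str = "compartment",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Per (track, state) enrichment of bin-level signal over background.

    For each state, ``mean_in`` averages the track over bins of that state
    inside the compartment; ``mean_background`` averages over all background
    bins.  The effect size is log2(mean_in / mean_background) and significance
    comes from a two-sided Mann–Whitney test between the two bin samples.
    Rows whose state-in-compartment bin set is empty are emitted with missing
    statistics and ``flagged=True``.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0,1)")
    labels = sorted({lab for _, lab in seg})
    label_to_state = {lab: i for i, lab in enumerate(labels)}
    path = segmentation_to_path(seg, grid, label_to_state)
    comp = intervals_to_track(compartment, grid, "presence").values > 0
    bg = intervals_to_track(background, grid, "presence").values > 0

    n_tests = len(tracks) * len(labels)
    thresh = alpha / n_tests if bonferroni else alpha
    rows = []
    for track in tracks:
        if track.values.size != grid.n_bins:
            raise ValueError(f"track {track.track_id!r} not on the given grid")
        bg_sample = track.values[bg & track.mask]
        for lab in labels:
            in_mask = comp & track.mask & (path == label_to_state[lab])
            in_sample = track.values[in_mask]
            row = {"track_id": track.track_id, "state": lab,
                   "compartment": compartment_name,
                   "n_in": int(in_sample.size), "n_background": int(bg_sample.size)}
            if in_sample.size == 0 or bg_sample.size == 0:
                row.update(mean_in=np.nan, mean_background=np.nan,
                           log2_enrichment=np.nan, U_statistic=np.nan,
                           p_value=np.nan, significant=False, flagged=True)
            else:
                mean_in = float(in_sample.mean())
                mean_bg = float(bg_sample.mean())
                log2 = np.log2(mean_in / mean_bg) if mean_in > 0 and mean_bg > 0 else np.nan
                u, p = mann_whitney_u(in_sample, bg_sample)
                row.update(mean_in=mean_in, mean_background=mean_bg,
                           log2_enrichment=log2, U_statistic=u, p_value=p,
                           significant=bool(p < thresh),
                           flagged=not np.isfinite(log2))
            rows.append(row)
    table = pd.DataFrame(rows)
    table.attrs.update(alpha=alpha, bonferroni=bonferroni, n_tests=n_tests,
                       bin_size=grid.bin_size, compartment=compartment_name,
                       sampling_unit="bin (autocorrelated; p-values anti-conservative)")
    return table
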