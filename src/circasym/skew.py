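"""Cumulated nucleotide-skew profiles and replication-origin breakpoints.

Strand-asymmetric mutation pressure around a replication origin leaves an
excess of G over C (and A over T) on one replichore and the mirror excess on
the other.  The cumulated GC-skew ``sum((G-C)/(G+C))`` over windows therefore
changes slope where the leading/lagging strand assignment switches, so
breakpoints of a piecewise-linear fit to the cumulated curve are candidate
replication origins.

Gene-orientation bias confounds this signal.  The classic workaround is to
build an artificial "rearranged" chromosome in which every gene is flipped
onto a single strand and concatenated in genomic order: transcription-related
skew is then constant by construction and surviving slope changes are
replication-associated.

Breakpoints are found by exact dynamic-programming least-squares segmentation
of the cumulated curve with per-segment linear fits, the number of segments
chosen by BIC.  This is deterministic and oracle-checkable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genome_io import CircularGenome, GeneRecord

_BASE_PAIRS = {"GC": ("G", "C"), "AT": ("A", "T")}


class SkewError(ValueError):
    pass


@dataclass(frozen=True)
class SkewProfile:
    genome_id: str
    mode: str  # "GC" or "AT"
    x: np.ndarray  # normalized window centers in [0, 1]
    s: np.ndarray  # per-window skew
    S: np.ndarray  # cumulated (prefix-sum) skew
    normalized: bool

    @property
    def window_count(self) -> int:
        return len(self.s)


def _window_bounds(L: int, W: int) -> np.ndarray:
    """W + 1 near-equal window boundaries partitioning [0, L]."""
    return np.round(np.linspace(0, L, W + 1)).astype(int)


def cumulated_skew(
    genome: CircularGenome | str,
    mode: str = "AT",
    W: int = 100,
    normalized: bool = True,
    genome_id: str | None = None,
) -> SkewProfile:
    """Windowed skew s_i and cumulated skew S (prefix sums) over W windows.

    With ``normalized=True`` the cumulated values are divided by W (and window
    centers by genome length), putting all genomes on one scale.  Windows with
    no informative bases get s_i = 0.  Ns are excluded from all counts.
    """
    if mode not in _BASE_PAIRS:
        raise SkewError(f"mode must be GC or AT, got {mode!r}")
    if isinstance(genome, CircularGenome):
        seq, gid = genome.sequence, genome.id
    else:
        seq, gid = genome, (genome_id or "seq")
    L = len(seq)
    if W < 2 or L < W:
        raise SkewError(f"need W >= 2 and genome length >= W (L={L}, W={W})")
    plus, minus = _BASE_PAIRS[mode]
    arr = np.frombuffer(seq.encode(), dtype="S1")
    is_plus = (arr == plus.encode()).astype(np.int64)
    is_minus = (arr == minus.encode()).astype(np.int64)
    if not (is_plus.any() or is_minus.any()) and set(seq) <= {"N"}:
        raise SkewError("all-N genome has no defined skew")
    cp, cm = np.concatenate([[0], np.cumsum(is_plus)]), np.concatenate([[0], np.cumsum(is_minus)])
    bounds = _window_bounds(L, W)
    p = cp[bounds[1:]] - cp[bounds[:-1]]
    m = cm[bounds[1:]] - cm[bounds[:-1]]
    denom = p + m
    s = np.zeros(W, dtype=float)
    nz = denom > 0
    s[nz] = (p[nz] - m[nz]) / denom[nz]
    S = np.cumsum(s)
    centers = (bounds[:-1] + bounds[1:]) / 2.0
    if normalized:
        S = S / W
        x = centers / L
    else:
        x = centers
    return SkewProfile(genome_id=gid, mode=mode, x=x, s=s, S=S, normalized=normalized)


@dataclass(frozen=True)
class RearrangedChromosome:
    """All genes oriented to one strand, concatenated in genomic order."""

    genome_id: str
    sequence: str
    gene_boundaries: tuple[int, ...]  # cumulative end offsets, one per gene


def build_rearranged_chromosome(
    genome: CircularGenome,
    genes: Sequence[GeneRecord],
    strand_mode: str = "forward",
) -> RearrangedChromosome:
    """Concatenate gene sequences, each flipped onto ``strand_mode``.

    Genes are taken in genomic order of their start in the current (anchored)
    frame; intergenic sequence is discarded.  Overlapping genes are extracted
    independently.
    """
    if strand_mode not in ("forward", "reverse"):
        raise SkewError(f"strand_mode must be forward or reverse, got {strand_mode!r}")
    if not genes:
        raise SkewError("no genes to rearrange")
    from .genome_io import reverse_complement

    parts: list[str] = []
    bounds: list[int] = []
    total = 0
    for gene in sorted(genes, key=lambda g: g.start):
        # extract() already orients to the coding strand, which is exactly the
        # forward-rearranged orientation; reverse mode flips every gene
        coding = gene.extract(genome)
        parts.append(coding if strand_mode == "forward" else reverse_complement(coding))
        total += len(coding)
        bounds.append(total)
    return RearrangedChromosome(genome.id, "".join(parts), tuple(bounds))


# ---------------------------------------------------------------------------
# Breakpoint detection: exact DP least-squares segmentation + BIC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BreakpointSet:
    genome_id: str
    mode: str
    breakpoints: tuple[float, ...]  # normalized positions, strictly increasing
    n_segments: int
    fit_score: float  # residual sum of squares of the selected model


def _segment_cost_matrix(x: np.ndarray, y: np.ndarray, min_len: int) -> np.ndarray:
    """cost[i, j] = RSS of the OLS line through points i..j inclusive."""
    n = len(x)
    one = np.ones(n)
    cs = {k: np.concatenate([[0.0], np.cumsum(v)]) for k, v in
          {"1": one, "x": x, "y": y, "xx": x * x, "xy": x * y, "yy": y * y}.items()}
    cost = np.full((n, n), np.inf)
    for i in range(n):
        for j in range(i + min_len - 1, n):
            m = j - i + 1
            sx = cs["x"][j + 1] - cs["x"][i]
            sy = cs["y"][j + 1] - cs["y"][i]
            sxx = cs["xx"][j + 1] - cs["xx"][i]
            sxy = cs["xy"][j + 1] - cs["xy"][i]
            syy = cs["yy"][j + 1] - cs["yy"][i]
            vx = sxx - sx * sx / m
            cxy = sxy - sx * sy / m
            vy = syy - sy * sy / m
            rss = vy - (cxy * cxy / vx if vx > 1e-15 else 0.0)
            cost[i, j] = max(rss, 0.0)
    return cost


def detect_breakpoints(
    profile: SkewProfile, max_breaks: int = 3, min_segment: int = 3
) -> BreakpointSet:
    """Segment the cumulated curve S(x) into piecewise-linear pieces.

    Exact dynamic programming minimizes the residual sum of squares for each
    candidate number of breakpoints in 0..max_breaks; BIC selects among them.
    A flat or perfectly linear profile yields zero breakpoints.
    """
    if profile.window_count < 10:
        raise SkewError("need at least 10 windows for breakpoint detection")
    if not 1 <= max_breaks <= 5:
        raise SkewError("max_breaks must be between 1 and 5")
    x, y = np.asarray(profile.x, float), np.asarray(profile.S, float)
    n = len(x)
    cost = _segment_cost_matrix(x, y, min_segment)
    # dp[k][j] = min RSS of fitting points 0..j with k segments
    dp = np.full((max_breaks + 2, n), np.inf)
    back = np.zeros((max_breaks + 2, n), dtype=int)
    dp[1] = cost[0]
    for k in range(2, max_breaks + 2):
        for j in range((k - 1) * min_segment + min_segment - 1, n):
            # segment k starts at i, previous segments cover 0..i-1
            cands = dp[k - 1, (k - 1) * min_segment - 1 : j - min_segment + 1] + \
                cost[(k - 1) * min_segment : j - min_segment + 2, j]
            if len(cands) == 0:
                continue
            best = int(np.argmin(cands))
            dp[k, j] = cands[best]
            back[k, j] = (k - 1) * min_segment + best
    # BIC model selection: n*ln(RSS/n) + p*ln(n), p = 3 per extra segment
    best_k, best_bic = 1, None
    for k in range(1, max_breaks + 2):
        rss = dp[k, n - 1]
        if not np.isfinite(rss):
            continue
        p_params = 2 * k + (k - 1)
        bic = n * np.log(max(rss, 1e-12) / n) + p_params * np.log(n)
        if best_bic is None or bic < best_bic - 1e-9:
            best_bic, best_k = bic, k
    # backtrack segment starts
    starts = []
    j, k = n - 1, best_k
    while k > 1:
        i = back[k, j]
        starts.append(i)
        j, k = i - 1, k - 1
    starts.reverse()
    # breakpoint position = boundary between last point of a segment and the
    # first point of the next, placed at the midpoint of their window centers
    bps = tuple(float((x[i - 1] + x[i]) / 2.0) for i in starts)
    return BreakpointSet(
        genome_id=profile.genome_id,
        mode=profile.mode,
        breakpoints=bps,
        n_segments=best_k,
        fit_score=float(dp[best_k, n - 1]),
    )
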