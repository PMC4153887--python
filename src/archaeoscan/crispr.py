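"""De novo CRISPR direct-repeat/spacer array detection and summaries.

CRISPR loci are runs of a genome-specific conserved direct repeat (DR)
separated by variable spacers recording past invasions.  The detector seeds
on exact k-mers that recur with a period compatible with one repeat-spacer
unit, chains them into candidate arrays, extends the repeat to its maximal
agreeing length across units, builds a column-majority DR consensus, trims
divergent terminal units, and reports non-overlapping arrays with at least
``min_units`` repeats.  The default parameter envelope (DR 23-47 bp,
spacers 20-60 bp) covers the repeat and spacer sizes typical of archaeal
gut-methanogen arrays (31-36 bp DRs, 25-40 bp spacers).
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .align import align_dna
from .genome_io import GenomeRecord


@dataclass
class CrisprParams:
    dr_len_min: int = 23
    dr_len_max: int = 47
    spacer_len_min: int = 20
    spacer_len_max: int = 60
    min_units: int = 3
    max_dr_mismatch_fraction: float = 0.2
    seed_k: int = 16

    def __post_init__(self) -> None:
        if self.dr_len_min > self.dr_len_max or self.spacer_len_min > self.spacer_len_max:
            raise ValueError("length minima must not exceed maxima")
        if self.min_units < 2:
            raise ValueError("min_units must be >= 2")
        if self.seed_k > self.dr_len_min:
            raise ValueError("seed_k must not exceed dr_len_min")


@dataclass
class CrisprArray:
    dr_consensus: str
    repeat_positions: list[tuple[int, int]]  # 1-based inclusive, sorted
    spacers: list[str]  # ordered, between consecutive repeats
    start: int
    end: int

    @property
    def n_repeats(self) -> int:
        return len(self.repeat_positions)

    @property
    def n_spacers(self) -> int:
        return len(self.spacers)


@dataclass
class SpacerHit:
    spacer_index: int
    subject_id: str
    identity: float  # percent, matches / alignment columns
    matches: int
    alignment_length: int


def find_arrays(genome: GenomeRecord, params: CrisprParams | None = None) -> list[CrisprArray]:
    """Detect CRISPR arrays de novo; empty list is a valid result."""
    params = params or CrisprParams()
    seq = genome.sequence
    k = params.seed_k
    if len(seq) <= params.dr_len_min + params.spacer_len_min:
        return []
    period_lo = params.dr_len_min + params.spacer_len_min
    period_hi = params.dr_len_max + params.spacer_len_max

    positions: dict[str, list[int]] = defaultdict(list)
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            positions[kmer].append(i)

    # Chains of seed positions with unit-compatible periods.
    chains: list[list[int]] = []
    for kmer in sorted(positions):
        pos = positions[kmer]
        if len(pos) < params.min_units:
            continue
        run = [pos[0]]
        for p in pos[1:]:
            if period_lo <= p - run[-1] <= period_hi:
                run.append(p)
            else:
                if len(run) >= params.min_units:
                    chains.append(run)
                run = [p]
        if len(run) >= params.min_units:
            chains.append(run)

    chains.sort(key=lambda c: (-len(c), c[0]))
    arrays: list[CrisprArray] = []
    claimed: list[tuple[int, int]] = []
    for chain in chains:
        span = (chain[0], chain[-1] + k)
        if any(s < span[1] and span[0] < e for s, e in claimed):
            continue
        arr = _build_array(seq, chain, k, params)
        if arr is None:
            continue
        claimed.append((arr.start - 1, arr.end))
        arrays.append(arr)
    arrays.sort(key=lambda a: a.start)
    return arrays


def _column_agrees(bases: list[str], min_fraction: float) -> tuple[bool, str]:
    counts = Counter(bases)
    base, n = max(sorted(counts.items()), key=lambda kv: kv[1])
    return n / len(bases) >= min_fraction, base


def _build_array(seq: str, chain: list[int], k: int, params: CrisprParams):
    starts = list(chain)
    n = len(starts)
    agree = 1.0 - params.max_dr_mismatch_fraction

    # Extend left from the seed while the column is conserved across units.
    left = 0
    while True:
        d = left + 1
        if starts[0] - d < 0 or k + left >= params.dr_len_max:
            break
        # a longer repeat must not squeeze any spacer below its minimum
        if any(
            starts[i] - d < starts[i - 1] + k + params.spacer_len_min - 1
            for i in range(1, n)
        ):
            break
        ok, _ = _column_agrees([seq[p - d] for p in starts], agree)
        if not ok:
            break
        left = d
    right = 0
    while True:
        d = right + 1
        if starts[-1] + k + d > len(seq) or k + left + right >= params.dr_len_max:
            break
        if any(
            starts[i] + k + d - 1 > starts[i + 1] - left - params.spacer_len_min
            for i in range(n - 1)
        ):
            break
        ok, _ = _column_agrees([seq[p + k + d - 1] for p in starts], agree)
        if not ok:
            break
        right = d

    dr_len = k + left + right
    if dr_len < params.dr_len_min:
        return None
    rep_starts = [p - left for p in starts]
    units = [seq[s : s + dr_len] for s in rep_starts]
    consensus = "".join(
        _column_agrees([u[j] for u in units], 0.0)[1] for j in range(dr_len)
    )

    def mism_frac(u: str) -> float:
        return sum(a != b for a, b in zip(u, consensus)) / dr_len

    # Trim divergent terminal units.
    lo, hi = 0, len(units)
    while lo < hi and mism_frac(units[lo]) > params.max_dr_mismatch_fraction:
        lo += 1
    while hi > lo and mism_frac(units[hi - 1]) > params.max_dr_mismatch_fraction:
        hi -= 1
    rep_starts, units = rep_starts[lo:hi], units[lo:hi]
    if len(units) < params.min_units:
        return None
    if any(mism_frac(u) > params.max_dr_mismatch_fraction for u in units):
        return None

    spacers = []
    for i in range(len(rep_starts) - 1):
        sp = seq[rep_starts[i] + dr_len : rep_starts[i + 1]]
        if not (params.spacer_len_min <= len(sp) <= params.spacer_len_max):
            return None
        spacers.append(sp)
    consensus = "".join(
        _column_agrees([u[j] for u in units], 0.0)[1] for j in range(dr_len)
    )
    repeat_positions = [(s + 1, s + dr_len) for s in rep_starts]
    return CrisprArray(
        dr_consensus=consensus,
        repeat_positions=repeat_positions,
        spacers=spacers,
        start=repeat_positions[0][0],
        end=repeat_positions[-1][1],
    )


def array_summary(array: CrisprArray) -> dict:
    """DR length, spacer count and spacer size range of one array."""
    lens = [len(s) for s in array.spacers]
    return {
        "dr_length": len(array.dr_consensus),
        "n_spacers": array.n_spacers,
        "spacer_len_min": min(lens) if lens else 0,
        "spacer_len_max": max(lens) if lens else 0,
        "start": array.start,
        "end": array.end,
    }


def match_spacer(
    spacers: list[str],
    query_db: dict[str, str],
    min_identity: float = 80.0,
    min_coverage: float = 80.0,
) -> list[SpacerHit]:
    """Best local nucleotide alignment of each spacer against a sequence set.

    Identity is matches over alignment columns, reported as the exact
    fraction in percent alongside the matches/length breakdown.  The
    alignment must also cover ``min_coverage`` percent of the spacer, so a
    short chance-perfect local match does not count as a hit.
    """
    if not spacers or not query_db:
        raise ValueError("spacers and query_db must be non-empty")
    hits = []
    for i, spacer in enumerate(spacers):
        best = None
        for sid in sorted(query_db):
            score, matches, columns, aligned_q = align_dna(spacer, query_db[sid])
            if columns == 0:
                continue
            if best is None or score > best[0]:
                best = (score, sid, matches, columns, aligned_q)
        if best is None:
            continue
        _, sid, matches, columns, aligned_q = best
        identity = 100.0 * matches / columns
        coverage = 100.0 * aligned_q / len(spacer)
        if identity >= min_identity and coverage >= min_coverage:
            hits.append(SpacerHit(i, sid, identity, matches, columns))
    return hits
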