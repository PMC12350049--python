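"""Control-region feature detection: conserved sequence blocks and tandem
repeats.

The mitochondrial control region (D-loop) of cyprinid fishes carries four
short conserved sequence blocks (CSB-D, CSB-1, CSB-2, CSB-3, appearing in
that order) and, in some species, tandemly repeated motifs.  Block
consensus sequences are built from an alignment by majority rule over seed
windows; single control regions are then scanned for the best ungapped
match per block under Hamming distance.

The tandem-repeat detector is a deterministic seed-and-verify procedure
with scoring in the style of Tandem Repeats Finder (match +2, mismatch −7
by default): candidate periods come from runs of matches in the lag-``p``
self-comparison of the sequence, and each candidate array is verified
against its own periodic majority consensus.  It reproduces the outputs a
report consumes — period, copy number to one decimal, consensus motif and
span — not the probabilistic model of the original program.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from importlib import resources

from .molevol import AlignedMatrix

CSB_ORDER = ("CSB-D", "CSB-1", "CSB-2", "CSB-3")

#: canonical block lengths (bp) in cyprinid control regions
CSB_LENGTHS = {"CSB-D": 18, "CSB-1": 21, "CSB-2": 18, "CSB-3": 20}


def load_default_csb_motifs() -> dict[str, str]:
    """Synthetic seed motifs shipped with the package (fixture data for the
    simulator and tests; not empirical consensus calls)."""
    raw = resources.files("mitochar.data").joinpath(
        "csb_seed_motifs.synthetic.json").read_text(encoding="utf-8")
    return {k: v for k, v in json.loads(raw).items() if k in CSB_ORDER}


@dataclass(frozen=True)
class CSBHit:
    block: str
    label: str
    start: int           # 1-based, CR coordinates
    end: int
    matched: str
    mismatches: int
    found: bool = True


@dataclass(frozen=True)
class TandemRepeat:
    period: int
    copies: float        # span / period, 1 dp
    consensus: str
    start: int           # 1-based
    end: int
    score: int
    pct_match: float     # percent identity between adjacent copies


def _majority(column: str) -> str:
    counts = Counter(c for c in column if c in "ACGT")
    if not counts:
        return "N"
    best = max(counts.values())
    # deterministic tie-break: alphabetical among the most frequent
    return sorted(b for b, n in counts.items() if n == best)[0]


def build_csb_consensus(aln: AlignedMatrix,
                        seed_windows: dict[str, tuple[int, int]],
                        ) -> tuple[dict[str, str], dict[str, dict[str, int]]]:
    """Majority-rule consensus per block over alignment seed windows.

    ``seed_windows`` maps block id to a 1-based inclusive column range.
    Returns (block -> consensus, block -> per-row mismatch counts).
    """
    if aln.n < 3:
        raise ValueError("need at least 3 rows to call a consensus")
    consensus: dict[str, str] = {}
    mismatches: dict[str, dict[str, int]] = {}
    for block, (lo, hi) in seed_windows.items():
        if not (1 <= lo <= hi <= aln.length):
            raise ValueError(f"{block}: seed window {lo}..{hi} outside alignment")
        cols = ["".join(r[i] for r in aln.rows) for i in range(lo - 1, hi)]
        cons = "".join(_majority(c) for c in cols)
        consensus[block] = cons
        mismatches[block] = {
            lab: sum(1 for a, b in zip(row[lo - 1:hi], cons) if a != b)
            for lab, row in zip(aln.labels, aln.rows)
        }
    return consensus, mismatches


def scan_csb(cr_seq: str, consensus: dict[str, str], max_mismatch: int = 4,
             label: str = "") -> list[CSBHit]:
    """Best ungapped Hamming match per block, reported in CR order.

    A block whose best match exceeds ``max_mismatch`` yields an explicit
    absence record (``found=False``).
    """
    seq = cr_seq.upper()
    hits = []
    for block in CSB_ORDER:
        if block not in consensus:
            continue
        motif = consensus[block].upper()
        L = len(motif)
        best_pos, best_mm = None, L + 1
        for i in range(len(seq) - L + 1):
            mm = sum(1 for a, b in zip(seq[i:i + L], motif) if a != b)
            if mm < best_mm:
                best_pos, best_mm = i, mm
        if best_pos is None or best_mm > max_mismatch:
            hits.append(CSBHit(block, label, 0, 0, "", best_mm, found=False))
        else:
            hits.append(CSBHit(block, label, best_pos + 1, best_pos + L,
                               seq[best_pos:best_pos + L], best_mm))
    return hits


# ---------------------------------------------------------------------------
# tandem repeats

def _periodic_consensus(seq: str, period: int) -> str:
    cols = ["".join(seq[i] for i in range(k, len(seq), period)) for k in range(period)]
    return "".join(_majority(c) for c in cols)


def _score_against_consensus(seq: str, cons: str, match: int, mismatch: int) -> int:
    p = len(cons)
    return sum(match if seq[i] == cons[i % p] else mismatch for i in range(len(seq)))


def find_tandem_repeats(seq: str, max_period: int = 50, min_copies: float = 1.5,
                        min_alignment_score: int = 20, match: int = 2,
                        mismatch: int = -7) -> list[TandemRepeat]:
    """Detect tandem arrays up to ``max_period`` bp.

    For each period ``p`` the sequence is compared against itself at lag
    ``p``; maximal positively scoring runs (Kadane walk with the
    match/mismatch scores) seed candidate arrays, each of which is verified
    by scoring the full array against its periodic majority consensus.
    Overlapping reports are merged keeping the higher score (ties: the
    shorter period, then the earlier start).
    """
    seq = seq.upper()
    n = len(seq)
    candidates: list[TandemRepeat] = []
    for p in range(1, min(max_period, n // 2) + 1):
        # Kadane walk over the lag-p match profile
        score = 0
        run_start = 0
        best: list[tuple[int, int]] = []
        i = 0
        seg_best, seg_best_end = 0, -1
        while i <= n - p - 1:
            score += match if seq[i] == seq[i + p] else mismatch
            if score > seg_best:
                seg_best, seg_best_end = score, i
            if score <= 0 or i == n - p - 1:
                if seg_best >= match * p:  # at least one extra full copy
                    best.append((run_start, seg_best_end))
                score = 0
                run_start = i + 1
                seg_best, seg_best_end = 0, -1
            i += 1
        for lo, hi in best:
            a, b = lo, hi + p  # candidate array spans [a, b] inclusive
            span = seq[a:b + 1]
            if len(span) / p < min_copies:
                continue
            cons = _periodic_consensus(span, p)
            sc = _score_against_consensus(span, cons, match, mismatch)
            if sc < min_alignment_score:
                continue
            adj = sum(1 for k in range(len(span) - p) if span[k] == span[k + p])
            candidates.append(TandemRepeat(
                period=p, copies=round(len(span) / p, 1), consensus=cons,
                start=a + 1, end=b + 1, score=sc,
                pct_match=round(100.0 * adj / (len(span) - p), 1),
            ))
    # merge overlapping reports, higher score wins
    candidates.sort(key=lambda r: (-r.score, r.period, r.start))
    kept: list[TandemRepeat] = []
    for cand in candidates:
        if all(cand.end < k.start or cand.start > k.end for k in kept):
            kept.append(cand)
    kept.sort(key=lambda r: r.start)
    return kept
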