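"""Pairwise molecular-evolution statistics on aligned sequences.

Implements the classical desk-scale estimators used in comparative
mitogenomics reports:

* transition/transversion tallies with complete pairwise deletion of
  gapped or ambiguous sites;
* Kimura two-parameter (K2P) and F84 distances in closed form;
* sliding-window nucleotide diversity (π), default 200-bp windows stepped
  by 25 bp;
* Nei–Gojobori (1986) Ka/Ks with Jukes–Cantor correction under the
  vertebrate mitochondrial code, equal-weight averaging over mutational
  pathways for multi-hit codons (stop-creating changes count as
  nonsynonymous);
* distance matrices with within/between group means and a transition/
  transversion-versus-F84 saturation profile.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon_usage import STOPS2, TABLE2, split_codons

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")
_VALID = frozenset("ACGT")


@dataclass
class AlignedMatrix:
    """Equal-length gapped sequences over {A,C,G,T,N,-}."""

    labels: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.labels) != len(self.rows):
            raise ValueError("labels and rows differ in number")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")
        self.rows = [r.upper() for r in self.rows]
        bad = set("".join(self.rows)) - set("ACGTN-")
        if bad:
            raise ValueError(f"invalid alignment characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.rows[0])

    @property
    def n(self) -> int:
        return len(self.rows)

    @classmethod
    def from_fasta(cls, path) -> "AlignedMatrix":
        from Bio import SeqIO
        recs = list(SeqIO.parse(path, "fasta"))
        return cls([r.id for r in recs], [str(r.seq) for r in recs])


@dataclass(frozen=True)
class PairDiffs:
    sites: int          # compared (ungapped, unambiguous in both)
    transitions: int    # s
    transversions: int  # v

    @property
    def P(self) -> float:
        return self.transitions / self.sites

    @property
    def Q(self) -> float:
        return self.transversions / self.sites

    @property
    def p_distance(self) -> float:
        return (self.transitions + self.transversions) / self.sites


def pair_diffs(row_i: str, row_j: str) -> PairDiffs:
    """Transition/transversion counts under complete pairwise deletion."""
    if len(row_i) != len(row_j):
        raise ValueError("rows differ in length")
    s = v = sites = 0
    for a, b in zip(row_i.upper(), row_j.upper()):
        if a not in _VALID or b not in _VALID:
            continue
        sites += 1
        if a == b:
            continue
        if (a in PURINES) == (b in PURINES):
            s += 1
        else:
            v += 1
    if sites == 0:
        raise ValueError("zero comparable sites")
    return PairDiffs(sites, s, v)


def k2p(d: PairDiffs) -> float | None:
    """K2P distance -(1/2) ln((1-2P-Q) sqrt(1-2Q)); None when saturated."""
    w1 = 1 - 2 * d.P - d.Q
    w2 = 1 - 2 * d.Q
    if w1 <= 0 or w2 <= 0:
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


def _pair_base_freqs(row_i: str, row_j: str) -> dict[str, float]:
    pooled = [c for c in (row_i + row_j).upper() if c in _VALID]
    n = len(pooled)
    return {b: pooled.count(b) / n for b in "ACGT"}


def f84(d: PairDiffs, base_freqs: dict[str, float]) -> float | None:
    """F84 maximum-likelihood distance in closed form.

    With ``A = πAπG/πR + πCπT/πY``, ``B = πAπG + πCπT`` and ``C = πRπY``:
    ``d = -2A ln(1 - P/2A - (A-B)Q/2AC) + 2(A-B-C) ln(1 - Q/2C)``.
    Reduces to K2P at equal base frequencies.  None on saturation.
    """
    fr = {b: base_freqs[b] for b in "ACGT"}
    tot = sum(fr.values())
    if not math.isclose(tot, 1.0, abs_tol=1e-6):
        raise ValueError("base frequencies must sum to 1")
    pR = fr["A"] + fr["G"]
    pY = fr["C"] + fr["T"]
    if min(pR, pY) <= 0:
        return None
    A = fr["A"] * fr["G"] / pR + fr["C"] * fr["T"] / pY
    B = fr["A"] * fr["G"] + fr["C"] * fr["T"]
    C = pR * pY
    if A <= 0:
        return None
    w1 = 1 - d.P / (2 * A) - (A - B) * d.Q / (2 * A * C)
    w2 = 1 - d.Q / (2 * C)
    if w1 <= 0 or w2 <= 0:
        return None
    return -2 * A * math.log(w1) + 2 * (A - B - C) * math.log(w2)


# ---------------------------------------------------------------------------
# nucleotide diversity

@dataclass
class DiversityProfile:
    starts: list[int]        # 1-based window start, alignment coordinates
    window: int
    step: int
    pi: list[float]
    last_truncated: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "window_start": self.starts,
            "window_mid": [s + self.window // 2 for s in self.starts],
            "pi": self.pi,
        })


def _window_pi(rows: list[str], lo: int, hi: int) -> float:
    """Mean over row pairs of (differences / compared sites) in [lo, hi)."""
    vals = []
    for a, b in itertools.combinations(rows, 2):
        diffs = sites = 0
        for x, y in zip(a[lo:hi], b[lo:hi]):
            if x in _VALID and y in _VALID:
                sites += 1
                diffs += x != y
        if sites:
            vals.append(diffs / sites)
    return float(np.mean(vals)) if vals else float("nan")


def nucleotide_diversity(m: AlignedMatrix) -> float:
    """Whole-alignment π (average pairwise difference proportion, no
    n/(n-1) sample correction)."""
    return _window_pi(m.rows, 0, m.length)


def sliding_pi(m: AlignedMatrix, window: int = 200, step: int = 25) -> DiversityProfile:
    """π profile over sliding windows; the final partial window is kept and
    flagged truncated when the alignment is not a whole number of steps."""
    if m.n < 2:
        raise ValueError("need at least two rows")
    starts, pis = [], []
    truncated = False
    if m.length <= window:
        return DiversityProfile([1], window, step, [_window_pi(m.rows, 0, m.length)],
                                last_truncated=m.length < window)
    pos = 0
    while pos + window <= m.length:
        starts.append(pos + 1)
        pis.append(_window_pi(m.rows, pos, pos + window))
        pos += step
    if pos < m.length and (m.length - (starts[-1] - 1)) > window:
        starts.append(pos + 1)
        pis.append(_window_pi(m.rows, pos, m.length))
        truncated = True
    return DiversityProfile(starts, window, step, pis, truncated)


# ---------------------------------------------------------------------------
# Nei-Gojobori Ka/Ks

def _syn_site_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts for one codon.

    Each position contributes the fraction of its three one-step changes
    that are synonymous; changes producing a stop codon are nonsynonymous.
    """
    aa = TABLE2.forward_table[codon]
    syn = 0.0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if mut not in STOPS2 and TABLE2.forward_table[mut] == aa:
                syn += 1 / 3
    return syn, 3.0 - syn


def _aa(codon: str) -> str | None:
    return None if codon in STOPS2 else TABLE2.forward_table[codon]


def _path_diffs(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) observed differences, averaged with equal weight over
    every ordering of the differing positions."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    k = len(diff_pos)
    if k == 0:
        return 0.0, 0.0
    sd = nd = 0.0
    npaths = math.factorial(k)
    for order in itertools.permutations(diff_pos):
        cur = c1
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if _aa(cur) is not None and _aa(cur) == _aa(nxt):
                sd += 1 / npaths
            else:
                nd += 1 / npaths
            cur = nxt
    return sd, nd


def jukes_cantor(p: float) -> float | None:
    """JC69 multiple-hit correction; None at or beyond saturation (p >= 3/4)."""
    if p >= 0.75:
        return None
    return -0.75 * math.log(1 - 4 * p / 3)


@dataclass(frozen=True)
class PairwiseRates:
    gene: str
    pair: tuple[str, str]
    ka: float | None
    ks: float | None
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float

    @property
    def ratio(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0:
            return None
        return self.ka / self.ks


def nei_gojobori(codon_seq_i: str, codon_seq_j: str, gene: str = "",
                 labels: tuple[str, str] = ("seq1", "seq2")) -> PairwiseRates:
    """NG86 Ka/Ks between two in-frame codon sequences of equal length.

    Site counts are averaged over the two sequences; codons containing a
    gap/ambiguity in either sequence, or an internal stop, are skipped as a
    pair (complete pairwise deletion at codon resolution).
    """
    if len(codon_seq_i) != len(codon_seq_j):
        raise ValueError("codon sequences differ in length")
    cods1, cods2 = split_codons(codon_seq_i), split_codons(codon_seq_j)
    S = N = Sd = Nd = 0.0
    for c1, c2 in zip(cods1, cods2):
        if not (set(c1) <= _VALID and set(c2) <= _VALID):
            continue
        if c1 in STOPS2 or c2 in STOPS2:
            continue
        s1, n1 = _syn_site_fraction(c1)
        s2, n2 = _syn_site_fraction(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _path_diffs(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no comparable codons")
    ks = jukes_cantor(Sd / S)
    ka = jukes_cantor(Nd / N)
    return PairwiseRates(gene=gene, pair=labels, ka=ka, ks=ks,
                         syn_sites=S, nonsyn_sites=N, syn_diffs=Sd, nonsyn_diffs=Nd)


# ---------------------------------------------------------------------------
# distance matrices

@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray  # square, symmetric, nan where undefined
    model: str

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    @property
    def overall_mean(self) -> float:
        iu = np.triu_indices(len(self.labels), k=1)
        vals = self.values[iu]
        return float(np.nanmean(vals))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        lines = [f" {len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            cells = " ".join(f"{v:.6f}" if np.isfinite(v) else "NA" for v in row)
            lines.append(f"{lab:<10s} {cells}")
        return "\n".join(lines) + "\n"


def distance_matrix(m: AlignedMatrix, model: str = "K2P") -> DistanceMatrix:
    """Pairwise model distances (``p``, ``K2P`` or ``F84``); saturated pairs
    are NaN and excluded (with reduced n) from summary means."""
    n = m.n
    vals = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d = pair_diffs(m.rows[i], m.rows[j])
        if model == "p":
            est = d.p_distance
        elif model == "K2P":
            est = k2p(d)
        elif model == "F84":
            est = f84(d, _pair_base_freqs(m.rows[i], m.rows[j]))
        else:
            raise ValueError(f"unknown model {model!r}")
        vals[i, j] = vals[j, i] = np.nan if est is None else est
    return DistanceMatrix(list(m.labels), vals, model)


def group_means(D: DistanceMatrix, groups: dict[str, str]) -> pd.DataFrame:
    """Within- and between-group mean distances for a label→group map."""
    missing = [lab for lab in D.labels if lab not in groups]
    if missing:
        raise ValueError(f"labels without group assignment: {missing}")
    names = sorted(set(groups.values()))
    rows = []
    for ga, gb in itertools.combinations_with_replacement(names, 2):
        vals = []
        for i, j in itertools.combinations(range(len(D.labels)), 2):
            pa, pb = groups[D.labels[i]], groups[D.labels[j]]
            if {pa, pb} == {ga, gb} or (ga == gb and pa == pb == ga):
                v = D.values[i, j]
                if np.isfinite(v):
                    vals.append(v)
        rows.append({
            "group_a": ga, "group_b": gb,
            "kind": "within" if ga == gb else "between",
            "mean": float(np.mean(vals)) if vals else float("nan"),
            "n_pairs": len(vals),
        })
    return pd.DataFrame(rows)


def saturation_profile(m: AlignedMatrix) -> pd.DataFrame:
    """Per-pair transition/transversion proportions against F84 divergence —
    the table behind the classic saturation scatter plot."""
    rows = []
    for i, j in itertools.combinations(range(m.n), 2):
        d = pair_diffs(m.rows[i], m.rows[j])
        rows.append({
            "pair": f"{m.labels[i]}|{m.labels[j]}",
            "sites": d.sites, "s": d.transitions, "v": d.transversions,
            "P": d.P, "Q": d.Q,
            "f84": f84(d, _pair_base_freqs(m.rows[i], m.rows[j])),
        })
    return pd.DataFrame(rows)
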