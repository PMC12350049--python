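"""Nucleotide composition, A+T content, and strand-skew statistics.

Skews follow the standard strand-asymmetry definitions
``AT-skew = (A - T)/(A + T)`` and ``GC-skew = (G - C)/(G + C)``, computed on
heavy-strand counts.  Ambiguous residues (N) are excluded from all counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .io_annotation import CircularSequence, MitoAnnotation, extract_gene_sequence


def at_skew(a: float, t: float) -> float | None:
    """(A - T)/(A + T) from counts or percentages; None when A + T == 0."""
    return None if a + t == 0 else (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float | None:
    """(G - C)/(G + C) from counts or percentages; None when G + C == 0."""
    return None if g + c == 0 else (g - c) / (g + c)


@dataclass(frozen=True)
class CompositionSummary:
    a: int
    c: int
    g: int
    t: int
    n_excluded: int = 0

    @property
    def counted(self) -> int:
        return self.a + self.c + self.g + self.t

    def _pct(self, x: int) -> float:
        return 100.0 * x / self.counted

    @property
    def pct_a(self) -> float:
        return self._pct(self.a)

    @property
    def pct_c(self) -> float:
        return self._pct(self.c)

    @property
    def pct_g(self) -> float:
        return self._pct(self.g)

    @property
    def pct_t(self) -> float:
        return self._pct(self.t)

    @property
    def at_content(self) -> float:
        """A + T as percent of counted residues."""
        return self.pct_a + self.pct_t

    @property
    def at_skew(self) -> float | None:
        return at_skew(self.a, self.t)

    @property
    def gc_skew(self) -> float | None:
        return gc_skew(self.g, self.c)

    def __add__(self, other: "CompositionSummary") -> "CompositionSummary":
        return CompositionSummary(self.a + other.a, self.c + other.c,
                                  self.g + other.g, self.t + other.t,
                                  self.n_excluded + other.n_excluded)

    def as_row(self, ndigits_pct: int = 2, ndigits_skew: int = 3) -> dict:
        def rnd(v, nd):
            return None if v is None else round(v, nd)
        return {
            "size": self.counted + self.n_excluded,
            "A_pct": rnd(self.pct_a, ndigits_pct),
            "T_pct": rnd(self.pct_t, ndigits_pct),
            "G_pct": rnd(self.pct_g, ndigits_pct),
            "C_pct": rnd(self.pct_c, ndigits_pct),
            "AT_pct": rnd(self.at_content, ndigits_pct),
            "AT_skew": rnd(self.at_skew, ndigits_skew),
            "GC_skew": rnd(self.gc_skew, ndigits_skew),
        }


def summarize(seq: str | CircularSequence) -> CompositionSummary:
    """Base counts and derived statistics over the unambiguous residues."""
    res = seq.residues if isinstance(seq, CircularSequence) else seq.upper()
    if len(res) == 0:
        raise ValueError("empty sequence")
    cnt = {b: res.count(b) for b in "ACGT"}
    summary = CompositionSummary(
        a=cnt["A"], c=cnt["C"], g=cnt["G"], t=cnt["T"],
        n_excluded=len(res) - sum(cnt.values()),
    )
    if summary.counted == 0:
        raise ValueError("sequence contains no unambiguous residues")
    return summary


def summarize_partitions(
    genome: CircularSequence,
    annotation: MitoAnnotation,
    strand_oriented: bool = False,
) -> dict[str, CompositionSummary]:
    """Composition per partition: whole mitogenome plus PCG/rRNA/tRNA/CR.

    Partition sequences are the concatenated annotated spans in genome
    order.  By default spans are taken on H-strand coordinates without
    reverse-complementing L-strand genes — the convention that keeps
    partition skews comparable with the whole-genome skew; pass
    ``strand_oriented=True`` to count each gene on its coding strand
    instead.  Bases inside an overlap belong to every feature containing
    them.
    """
    out = {"mitogenome": summarize(genome)}
    for cls in ("PCG", "rRNA", "tRNA", "CR"):
        feats = annotation.of_class(cls)
        if not feats:
            raise ValueError(f"annotation has no features of class {cls}")
        parts = []
        for f in feats:
            if strand_oriented:
                parts.append(extract_gene_sequence(genome, f))
            else:
                parts.append(genome.residues[f.start - 1:f.end])
        out[cls] = summarize("".join(parts))
    return out


def partition_table(summaries: dict[str, CompositionSummary],
                    species: str = "") -> "pd.DataFrame":
    """Tidy report table (one row per partition) at printed precision."""
    import pandas as pd

    rows = []
    for part, s in summaries.items():
        row = {"Species": species, "Partition": part}
        row.update(s.as_row())
        rows.append(row)
    return pd.DataFrame(rows)
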