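"""Codon counting, relative synonymous codon usage (RSCU) and amino-acid
composition over the protein-coding genes, under the vertebrate
mitochondrial genetic code (translation table 2).

RSCU for codon ``c`` in synonymous family ``F`` is ``|F| * n_c / sum_F n``:
1 means the codon is used exactly as often as expected with no bias.  Two
family partitions are available because published RSCU figures convention-
ally show AUG (Met) and UGG (Trp) at exactly 1:

* ``"report"`` (default) — families grouped by the table-2 amino acid but
  with ATG and TGG split out as single-codon families (their table-2
  partners ATA and TGA then also stand alone), reproducing the figure
  convention;
* ``"table2"`` — families are exactly the table-2 synonymous sets
  (Met = {ATA, ATG}, Trp = {TGA, TGG}).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from Bio.Data import CodonTable

from .io_annotation import CircularSequence, MitoAnnotation, extract_gene_sequence

TABLE2 = CodonTable.unambiguous_dna_by_id[2]
STOPS2 = frozenset(TABLE2.stop_codons)  # TAA, TAG, AGA, AGG
ALL_CODONS = ["".join(p) for p in itertools.product("TCAG", repeat=3)]
SENSE_CODONS = [c for c in ALL_CODONS if c not in STOPS2]

AA3 = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys", "Q": "Gln",
    "E": "Glu", "G": "Gly", "H": "His", "I": "Ile", "L": "Leu", "K": "Lys",
    "M": "Met", "F": "Phe", "P": "Pro", "S": "Ser", "T": "Thr", "W": "Trp",
    "Y": "Tyr", "V": "Val",
}


def translate(codon: str) -> str:
    """One-letter amino acid under table 2; '*' for stops."""
    codon = codon.upper()
    return "*" if codon in STOPS2 else TABLE2.forward_table[codon]


def synonymous_families(family_mode: str = "report") -> dict[str, list[str]]:
    """family key -> sorted codon list (sense codons only)."""
    fams: dict[str, list[str]] = {}
    for c in SENSE_CODONS:
        aa = translate(c)
        if family_mode == "report" and c in ("ATG", "TGG", "ATA", "TGA"):
            key = f"{aa}:{c}"  # singleton family
        elif family_mode == "table2":
            key = aa
        elif family_mode == "report":
            key = aa
        else:
            raise ValueError(f"unknown family_mode {family_mode!r}")
        fams.setdefault(key, []).append(c)
    return {k: sorted(v) for k, v in fams.items()}


@dataclass
class CodonCountTable:
    """Sense-codon counts (stop codons tallied separately)."""

    counts: dict[str, int]
    stop_counts: dict[str, int] = field(default_factory=dict)
    genetic_code_id: int = 2

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        c = {k: self.counts.get(k, 0) + other.counts.get(k, 0) for k in ALL_CODONS}
        s = {k: self.stop_counts.get(k, 0) + other.stop_counts.get(k, 0)
             for k in set(self.stop_counts) | set(other.stop_counts)}
        return CodonCountTable({k: v for k, v in c.items() if k not in STOPS2}, s)


def split_codons(gene_seq: str) -> list[str]:
    """In-frame codons; a trailing 1–2 nt incomplete codon is dropped."""
    return [gene_seq[i:i + 3].upper()
            for i in range(0, len(gene_seq) - len(gene_seq) % 3, 3)]


def count_codons(genome: CircularSequence, annotation: MitoAnnotation) -> CodonCountTable:
    """Pool in-frame codons over all strand-oriented PCGs.

    L-strand genes are read from their reverse-complemented (sense)
    sequence.  Complete terminal stop codons land in ``stop_counts`` and are
    excluded from RSCU and amino-acid statistics.
    """
    counts = {c: 0 for c in SENSE_CODONS}
    stops: dict[str, int] = {}
    for f in annotation.pcgs:
        seq = extract_gene_sequence(genome, f)
        if len(seq) < 3:
            raise ValueError(f"{f.name}: gene shorter than one codon")
        for codon in split_codons(seq):
            if codon in STOPS2:
                stops[codon] = stops.get(codon, 0) + 1
            elif set(codon) <= set("ACGT"):
                counts[codon] += 1
    return CodonCountTable(counts, stops)


def rscu(t: CodonCountTable, family_mode: str = "report") -> dict[str, float | None]:
    """Per-codon RSCU; ``None`` for codons whose whole family is unobserved."""
    out: dict[str, float | None] = {}
    for fam in synonymous_families(family_mode).values():
        fam_total = sum(t.counts.get(c, 0) for c in fam)
        for c in fam:
            out[c] = None if fam_total == 0 else len(fam) * t.counts[c] / fam_total
    return out


def amino_acid_profile(t: CodonCountTable) -> dict[str, float]:
    """Percent of counted (non-stop) codons per amino acid, table-2
    translation; the two Leu and two Ser codon families are merged by the
    shared amino acid."""
    totals: dict[str, float] = {aa: 0 for aa in AA3}
    for codon, n in t.counts.items():
        totals[translate(codon)] += n
    grand = t.total
    if grand == 0:
        raise ValueError("empty codon table")
    return {aa: 100.0 * n / grand for aa, n in totals.items()}


def rscu_table(t: CodonCountTable, family_mode: str = "report") -> "pd.DataFrame":
    """Per-codon report: codon, amino acid, count, RSCU."""
    import pandas as pd

    vals = rscu(t, family_mode)
    rows = [{"codon": c, "aa": AA3[translate(c)], "count": t.counts[c],
             "RSCU": None if vals[c] is None else round(vals[c], 2)}
            for c in SENSE_CODONS]
    return pd.DataFrame(rows)
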