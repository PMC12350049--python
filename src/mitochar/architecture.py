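"""Gene-architecture ledger: spacers/overlaps, partition totals, codon calls.

The ledger follows the gene-table convention of mitogenome reports: one
signed intergenic-nucleotide (IN) value per consecutive feature pair, where
``IN = downstream.start - upstream.end - 1`` — positive values are spacers,
negative values overlaps, zero means abutting genes.  The pair that wraps
across the replication origin (last feature back to the first) is reported
separately and excluded from the linear ledger.
"""

from __future__ import annotations

from dataclasses import dataclass

from .io_annotation import (
    AnnotationError, CircularSequence, GeneFeature, MitoAnnotation,
    extract_gene_sequence,
)

#: complete stop codons of the vertebrate mitochondrial code (table 2)
STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})


@dataclass(frozen=True)
class SpacerOverlap:
    upstream: str
    downstream: str
    intergenic: int  # signed IN; >0 spacer, <0 overlap, 0 contiguous


@dataclass
class SpacerOverlapLedger:
    pairs: list[SpacerOverlap]
    wraparound: SpacerOverlap | None = None  # last feature -> first, across origin

    @property
    def spacers(self) -> list[SpacerOverlap]:
        return [p for p in self.pairs if p.intergenic > 0]

    @property
    def overlaps(self) -> list[SpacerOverlap]:
        return [p for p in self.pairs if p.intergenic < 0]

    @property
    def contiguous_count(self) -> int:
        return sum(1 for p in self.pairs if p.intergenic == 0)

    @property
    def max_spacer(self) -> SpacerOverlap | None:
        return max(self.spacers, key=lambda p: p.intergenic, default=None)

    @property
    def max_overlap(self) -> SpacerOverlap | None:
        return min(self.overlaps, key=lambda p: p.intergenic, default=None)

    def summary(self) -> dict:
        d = {
            "n_pairs": len(self.pairs),
            "n_spacers": len(self.spacers),
            "n_overlaps": len(self.overlaps),
            "n_contiguous": self.contiguous_count,
        }
        if self.max_spacer:
            d["max_spacer"] = (self.max_spacer.upstream, self.max_spacer.downstream,
                               self.max_spacer.intergenic)
        if self.max_overlap:
            d["max_overlap"] = (self.max_overlap.upstream, self.max_overlap.downstream,
                                self.max_overlap.intergenic)
        return d


def build_ledger(a: MitoAnnotation) -> SpacerOverlapLedger:
    """Signed IN ledger over consecutive feature pairs (sorted by start)."""
    feats = a.features
    starts = [f.start for f in feats]
    if starts != sorted(starts):
        raise AnnotationError("features must be sorted by start")
    pairs = [
        SpacerOverlap(u.name, d.name, d.start - u.end - 1)
        for u, d in zip(feats, feats[1:])
    ]
    wrap = None
    if len(feats) >= 2:
        # distance across the origin: from last.end forward to first.start
        last, first = feats[-1], feats[0]
        wrap = SpacerOverlap(
            last.name, first.name,
            (a.genome_length - last.end) + (first.start - 1),
        )
    return SpacerOverlapLedger(pairs=pairs, wraparound=wrap)


def partition_totals(a: MitoAnnotation) -> dict:
    """Total bp per feature class plus the PCG fraction of the genome."""
    totals = {cls: sum(f.size for f in a.of_class(cls))
              for cls in ("PCG", "tRNA", "rRNA", "CR")}
    totals["pcg_fraction"] = totals["PCG"] / a.genome_length
    return totals


@dataclass(frozen=True)
class CodonCall:
    gene: str
    start_codon: str
    stop_codon: str       # "TAA", "TA-", "T--", ...
    completeness: str     # "complete" | "incomplete"
    annotated_start: str | None = None  # as given in a feature table, if any
    annotated_stop: str | None = None


def _render_stop(trailing: str) -> str:
    return trailing + "-" * (3 - len(trailing))


def call_codons(genome: CircularSequence, a: MitoAnnotation,
                stop_set: frozenset = STOP_CODONS) -> list[CodonCall]:
    """Start/stop codon calls recomputed from sequence for every PCG.

    The stop call is the trailing residue block after the last full internal
    codon: 3 nt when ``size % 3 == 0``, else the 1–2 nt remnant padded with
    ``-`` (the incomplete-stop convention completed by polyadenylation in
    vivo).  A 3-nt trailing block is "complete" only when it is in the
    configured stop set; annotated values from the feature table are carried
    alongside, never overwritten.
    """
    calls = []
    for f in a.pcgs:
        seq = extract_gene_sequence(genome, f)
        if len(seq) < 6:
            raise AnnotationError(f"{f.name}: PCG shorter than 6 nt")
        start = seq[:3]
        rem = len(seq) % 3
        trailing = seq[-3:] if rem == 0 else seq[-rem:]
        stop = _render_stop(trailing)
        complete = len(trailing) == 3 and trailing in stop_set
        calls.append(CodonCall(
            gene=f.name, start_codon=start, stop_codon=stop,
            completeness="complete" if complete else "incomplete",
            annotated_start=f.start_codon, annotated_stop=f.stop_codon,
        ))
    return calls


def conservation_check(a: MitoAnnotation) -> bool:
    """Sum of feature sizes plus signed inter-feature gaps spans the genome
    exactly when the annotation starts at 1 and ends at genome_length."""
    ledger = build_ledger(a)
    total = sum(f.size for f in a.features) + sum(p.intergenic for p in ledger.pairs)
    return (a.features[0].start == 1 and a.features[-1].end == a.genome_length
            and total == a.genome_length)
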