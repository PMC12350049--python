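"""Readers, writers and coordinate plumbing for annotated mitogenomes.

The central data model mirrors the gene-organization table of a typical
vertebrate mitogenome report: one row per feature (13 protein-coding genes,
22 tRNAs, 2 rRNAs, one control region), 1-based inclusive coordinates on the
heavy strand, and an ``H``/``L`` strand flag.  Coordinates stay 1-based
inclusive throughout the package; conversion to 0-based half-open happens
only at format boundaries (GenBank/FASTA slicing).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

FEATURE_CLASSES = ("PCG", "tRNA", "rRNA", "CR")

#: column order of the tab-delimited feature table
TABLE_COLUMNS = [
    "Genes", "Start", "End", "Strand", "Size",
    "Intergenic nucleotide", "Anti-codon", "Start codon", "Stop codon",
]

_CR_ALIASES = {"cr", "d-loop", "dloop", "d loop", "control region", "control-region"}


class AnnotationError(ValueError):
    """Raised for malformed or internally inconsistent annotations."""


@dataclass(frozen=True)
class CircularSequence:
    """A (usually circular) DNA sequence over ``{A,C,G,T,N}``."""

    id: str
    residues: str
    circular: bool = True

    def __post_init__(self):
        if len(self.residues) == 0:
            raise AnnotationError(f"{self.id}: empty sequence")
        res = self.residues.upper()
        bad = set(res) - set("ACGTN")
        if bad:
            raise AnnotationError(f"{self.id}: non-DNA residues {sorted(bad)}")
        object.__setattr__(self, "residues", res)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class GeneFeature:
    """One annotated feature in 1-based inclusive genome coordinates."""

    name: str
    cls: str
    start: int
    end: int
    strand: str
    anticodon: str | None = None
    start_codon: str | None = None
    stop_codon: str | None = None

    def __post_init__(self):
        if self.cls not in FEATURE_CLASSES:
            raise AnnotationError(f"{self.name}: unknown feature class {self.cls!r}")
        if self.strand not in ("H", "L"):
            raise AnnotationError(f"{self.name}: strand must be H or L, got {self.strand!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"{self.name}: invalid span {self.start}..{self.end}"
            )
        if self.anticodon is not None and self.cls != "tRNA":
            raise AnnotationError(f"{self.name}: anticodon on non-tRNA feature")

    @property
    def size(self) -> int:
        return self.end - self.start + 1


@dataclass
class MitoAnnotation:
    """An ordered set of features over one mitogenome."""

    genome_id: str
    features: list[GeneFeature]
    genome_length: int
    species: str = ""

    def __post_init__(self):
        self.features = sorted(
            self.features, key=lambda f: (f.start, f.end, f.name)
        )
        for f in self.features:
            if f.end > self.genome_length:
                raise AnnotationError(
                    f"feature {f.name} ({f.start}..{f.end}) exceeds genome "
                    f"length {self.genome_length}"
                )

    def __len__(self) -> int:
        return len(self.features)

    def of_class(self, cls: str) -> list[GeneFeature]:
        if cls not in FEATURE_CLASSES:
            raise AnnotationError(f"unknown feature class {cls!r}")
        return [f for f in self.features if f.cls == cls]

    @property
    def pcgs(self) -> list[GeneFeature]:
        return self.of_class("PCG")


# ---------------------------------------------------------------------------
# name / class normalization

def _normalize_name(name: str) -> str:
    return "CR" if name.strip().lower() in _CR_ALIASES else name.strip()


def _infer_class(name: str) -> str:
    low = name.lower()
    if low == "cr":
        return "CR"
    if low.startswith("trna"):
        return "tRNA"
    if "rrna" in low or low in ("12s", "16s", "rrns", "rrnl"):
        return "rRNA"
    return "PCG"


def disambiguate_duplicate_trnas(features: list[GeneFeature]) -> list[GeneFeature]:
    """Tag duplicated tRNA names with the (S1)/(S2), (L1)/(L2) convention.

    For mitochondrial Ser and Leu the copy is resolved by anticodon when
    present (Ser: TGA→S2, GCT→S1; Leu: TAA→L2, TAG→L1), else by order of
    occurrence.
    """
    by_anticodon = {"TGA": "S2", "GCT": "S1", "TAA": "L2", "TAG": "L1"}
    counts: dict[str, int] = {}
    for f in features:
        counts[f.name] = counts.get(f.name, 0) + 1
    seen: dict[str, int] = {}
    out = []
    for f in features:
        if f.cls == "tRNA" and counts[f.name] > 1 and "(" not in f.name:
            seen[f.name] = seen.get(f.name, 0) + 1
            tag = None
            if f.anticodon and f.anticodon.upper() in by_anticodon:
                tag = by_anticodon[f.anticodon.upper()]
            else:
                tag = f"{f.name[-3]}{seen[f.name]}"  # first letter of aa + index
            out.append(
                GeneFeature(
                    f"{f.name}({tag})", f.cls, f.start, f.end, f.strand,
                    f.anticodon, f.start_codon, f.stop_codon,
                )
            )
        else:
            out.append(f)
    return out


# ---------------------------------------------------------------------------
# feature table I/O

def read_feature_table(path_or_buffer) -> MitoAnnotation:
    """Read a tab-delimited gene table (Genes/Start/End/Strand/Size/...).

    The ``Size`` column, when present, is validated against
    ``end - start + 1``; a mismatch is a hard error.  Missing optional cells
    may be ``.``, ``-`` alone, or empty.
    """
    df = pd.read_csv(path_or_buffer, sep="\t", dtype=str).fillna(".")
    df.columns = [c.strip() for c in df.columns]
    required = {"Genes", "Start", "End", "Strand"}
    if not required.issubset(df.columns):
        raise AnnotationError(f"feature table missing columns {required - set(df.columns)}")

    feats = []
    for _, row in df.iterrows():
        name = _normalize_name(str(row["Genes"]))
        try:
            start = int(str(row["Start"]).replace(",", ""))
            end = int(str(row["End"]).replace(",", ""))
        except ValueError as exc:
            raise AnnotationError(f"{name}: non-numeric coordinates") from exc
        strand = str(row["Strand"]).strip()
        if strand not in ("H", "L"):
            raise AnnotationError(f"{name}: strand {strand!r} not in {{H, L}}")

        def _opt(col):
            if col not in df.columns:
                return None
            v = str(row[col]).strip()
            return None if v in (".", "", "nan") else v

        size_txt = _opt("Size") or _opt("Size (bp)")
        if size_txt is not None:
            size = int(size_txt.replace(",", ""))
            if size != end - start + 1:
                raise AnnotationError(
                    f"{name}: declared size {size} != {end - start + 1} "
                    f"implied by coordinates {start}..{end}"
                )
        cls = _infer_class(name)
        feats.append(
            GeneFeature(
                name=name, cls=cls, start=start, end=end, strand=strand,
                anticodon=_opt("Anti-codon") if cls == "tRNA" else None,
                start_codon=_opt("Start codon"),
                stop_codon=_opt("Stop codon"),
            )
        )
    if not feats:
        raise AnnotationError("no annotatable features")
    feats = disambiguate_duplicate_trnas(feats)
    genome_length = max(f.end for f in feats)
    gid = getattr(path_or_buffer, "name", str(path_or_buffer))
    return MitoAnnotation(genome_id=Path(str(gid)).stem, features=feats,
                          genome_length=genome_length)


def write_feature_table(a: MitoAnnotation, path=None) -> str:
    """Serialize an annotation back to the tab-delimited table layout.

    The intergenic-nucleotide column is recomputed from coordinates (blank
    for the last feature, which has no linear downstream neighbour).
    """
    rows = []
    for i, f in enumerate(a.features):
        if i + 1 < len(a.features):
            inter = a.features[i + 1].start - f.end - 1
        else:
            inter = "."
        rows.append({
            "Genes": f.name, "Start": f.start, "End": f.end,
            "Strand": f.strand, "Size": f.size,
            "Intergenic nucleotide": inter,
            "Anti-codon": f.anticodon or ".",
            "Start codon": f.start_codon or ".",
            "Stop codon": f.stop_codon or ".",
        })
    df = pd.DataFrame(rows, columns=TABLE_COLUMNS)
    text = df.to_csv(sep="\t", index=False)
    if path is not None:
        Path(path).write_text(text, encoding="utf-8")
    return text


# ---------------------------------------------------------------------------
# GenBank / FASTA

_GENBANK_CLASS = {"CDS": "PCG", "tRNA": "tRNA", "rRNA": "rRNA",
                  "D-loop": "CR", "misc_feature": None}


def read_genbank(path) -> tuple[CircularSequence, MitoAnnotation]:
    """Read an annotated mitogenome from a GenBank flat file.

    CDS/tRNA/rRNA/D-loop features are mapped to :class:`GeneFeature`;
    ``complement(...)`` locations become strand ``L``.  ``gene`` features are
    ignored (they duplicate CDS/tRNA/rRNA spans).
    """
    rec = SeqIO.read(path, "genbank")
    if len(rec.seq) == 0:
        raise AnnotationError(f"{rec.id}: GenBank record has no ORIGIN sequence")
    seq = CircularSequence(rec.id, str(rec.seq))

    feats = []
    for ft in rec.features:
        cls = _GENBANK_CLASS.get(ft.type)
        if cls is None:
            continue
        start = int(ft.location.start) + 1  # 0-based half-open -> 1-based incl.
        end = int(ft.location.end)
        if end > seq.length:
            raise AnnotationError(
                f"feature {ft.type} {start}..{end} beyond sequence length {seq.length}")
        quals = ft.qualifiers
        name = (quals.get("gene") or quals.get("product") or [ft.type])[0]
        if cls == "CR":
            name = "CR"
        strand = "L" if ft.location.strand == -1 else "H"
        anticodon = None
        if cls == "tRNA" and "anticodon" in quals:
            ac = quals["anticodon"][0]
            anticodon = ac.split("seq:")[-1].rstrip(")").upper().replace("U", "T") \
                if "seq:" in ac else ac.upper().replace("U", "T")
        feats.append(GeneFeature(_normalize_name(name), cls, start, end, strand,
                                 anticodon=anticodon))
    if not feats:
        raise AnnotationError(f"{rec.id}: no annotatable features")
    feats = disambiguate_duplicate_trnas(feats)
    ann = MitoAnnotation(genome_id=rec.id, features=feats,
                         genome_length=seq.length,
                         species=rec.annotations.get("organism", ""))
    return seq, ann


def read_fasta(path) -> list[CircularSequence]:
    return [CircularSequence(r.id, str(r.seq)) for r in SeqIO.parse(path, "fasta")]


def write_fasta(seqs: Iterable[CircularSequence], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, s.length, 70):
                fh.write(s.residues[i:i + 70] + "\n")


# ---------------------------------------------------------------------------
# sequence extraction

def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def extract_gene_sequence(genome: CircularSequence, f: GeneFeature) -> str:
    """Strand-oriented gene sequence: the H-strand span for ``H`` features,
    its reverse complement for ``L`` features. Length always equals ``f.size``."""
    if f.end > genome.length:
        raise AnnotationError(
            f"{f.name}: span {f.start}..{f.end} outside genome of {genome.length} bp")
    span = genome.residues[f.start - 1:f.end]
    return reverse_complement(span) if f.strand == "L" else span


# ---------------------------------------------------------------------------
# bundled example data

def load_reference_annotation() -> MitoAnnotation:
    """The Cyclocheilichthys repasson mitogenome gene table (GenBank PP937077),
    shipped with the package as the canonical worked example and as the
    simulator's gene-order template."""
    ref = resources.files("mitochar.data").joinpath(
        "cyclocheilichthys_repasson_features.tsv")
    ann = read_feature_table(io.StringIO(ref.read_text(encoding="utf-8")))
    ann.genome_id = "PP937077"
    ann.species = "Cyclocheilichthys repasson"
    return ann


def load_reference_composition() -> pd.DataFrame:
    """Published per-partition base percentages for four Cyclocheilichthys
    mitogenomes (columns Species/Partition/Size/A_pct/.../GC_skew)."""
    ref = resources.files("mitochar.data").joinpath(
        "cyclocheilichthys_composition.tsv")
    return pd.read_csv(io.StringIO(ref.read_text(encoding="utf-8")), sep="\t")
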