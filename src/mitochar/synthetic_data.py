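"""Synthetic annotated mitogenomes and congeneric sets with known truth.

The generator emulates the statistical structure of a cyprinid mitogenome:
a circular ~16.6 kb genome laid out on the standard vertebrate gene order
(13 protein-coding genes, 22 tRNAs, 2 rRNAs, one control region, with the
usual L-strand genes), per-partition base composition matching published
values, protein-coding genes with valid start codons, no internal stops
under the vertebrate mitochondrial code and the annotated complete or
incomplete terminal stops, and a control region that can carry implanted
conserved sequence blocks and a tandem repeat.

Divergence is simulated by a two-rate (transition/transversion, κ) event
process: candidate substitutions arrive as a Poisson stream at
``branch_length`` expected events per site; inside protein-coding genes a
candidate that would create an internal stop is rejected and a candidate
that changes the amino acid is accepted with per-gene probability ω.
Every dataset is emitted with a truth bundle (realized substitutions and
syn/nonsyn counts per gene, implant coordinates) so estimators can be
validated against known values.  All randomness flows from a single seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field

import numpy as np

from .codon_usage import SENSE_CODONS, STOPS2, TABLE2
from .control_region import load_default_csb_motifs
from .io_annotation import (
    CircularSequence, GeneFeature, MitoAnnotation, load_reference_annotation,
)
from .molevol import AlignedMatrix

_COMP = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: per-partition base fractions (A, C, G, T) of a cyprinid mitogenome
DEFAULT_COMPOSITION = {
    "mitogenome": {"A": 0.3304, "C": 0.2710, "G": 0.1520, "T": 0.2466},
    "PCG": {"A": 0.3115, "C": 0.2762, "G": 0.1460, "T": 0.2664},
    "rRNA": {"A": 0.3521, "C": 0.2466, "G": 0.2049, "T": 0.1964},
    "tRNA": {"A": 0.3114, "C": 0.2502, "G": 0.1940, "T": 0.2444},
    "CR": {"A": 0.3617, "C": 0.1917, "G": 0.1209, "T": 0.3257},
}

#: per-gene nonsynonymous acceptance probabilities; the two extremes follow
#: published congeneric estimates, the rest sit inside that range
DEFAULT_OMEGA = {
    "ND4L": 0.0093, "Cytb": 0.0687, "COI": 0.015, "COII": 0.02, "COIII": 0.02,
    "ATP6": 0.04, "ATP8": 0.05, "ND1": 0.03, "ND2": 0.04, "ND3": 0.03,
    "ND4": 0.03, "ND5": 0.035, "ND6": 0.045,
}


@dataclass
class SimulationConfig:
    seed: int = 0
    kappa: float = 4.0                       # transition/transversion rate ratio
    composition: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_COMPOSITION))
    omega: dict = field(default_factory=lambda: dict(DEFAULT_OMEGA))
    default_omega: float = 0.03
    #: label -> branch length (expected candidate substitutions/site) from
    #: the common ancestor (star phylogeny)
    tree: dict = field(default_factory=lambda: {"taxon1": 0.02, "taxon2": 0.02,
                                                "taxon3": 0.05, "taxon4": 0.05})
    #: control-region implants
    csb_motifs: dict | None = None           # None -> packaged synthetic motifs
    csb_offsets: dict = field(default_factory=lambda: {
        "CSB-D": 560, "CSB-1": 640, "CSB-2": 740, "CSB-3": 800})
    cr_repeat_motif: str | None = None       # e.g. a 17-mer
    cr_repeat_copies: float = 2.2
    cr_repeat_offset: int = 60               # 0-based offset inside the CR

    def __post_init__(self):
        for part, fr in self.composition.items():
            tot = sum(fr.values())
            if abs(tot - 1.0) > 5e-3:
                raise ValueError(f"{part}: composition fractions must sum to 1")
            if tot != 1.0:  # absorb rounding residue from printed percentages
                self.composition[part] = {b: v / tot for b, v in fr.items()}
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.csb_motifs is None:
            self.csb_motifs = load_default_csb_motifs()

    def omega_for(self, gene: str) -> float:
        return self.omega.get(gene, self.default_omega)


def _sample_base(rng, fractions: dict[str, float]) -> str:
    return rng.choice(list("ACGT"), p=[fractions[b] for b in "ACGT"])


def _nonstop_codon_distribution(fr: dict[str, float]) -> tuple[list[str], np.ndarray]:
    """Distribution over the 60 sense codons whose base-composition marginal
    equals ``fr`` exactly.

    Sampling codon positions i.i.d. from ``fr`` and rejecting stops would
    bias the realized composition (the four table-2 stops are A/T/G-rich);
    iterative proportional fitting of per-base weights removes that bias.
    """
    codons = list(SENSE_CODONS)
    counts = np.array([[c.count(b) for b in _BASES] for c in codons], float)
    target = np.array([fr[b] for b in _BASES])
    w = target.copy()
    for _ in range(200):
        p = np.prod(np.power(w, counts), axis=1)
        p /= p.sum()
        marginal = (p[:, None] * counts).sum(axis=0) / 3.0
        if np.max(np.abs(marginal - target)) < 1e-12:
            break
        w *= target / marginal
    return codons, p


def _sense_fractions(fr: dict[str, float], strand: str) -> dict[str, float]:
    """Partition composition targets are stated in genome (H-strand)
    orientation; sampling an L-strand gene in sense orientation therefore
    uses the complementary distribution."""
    if strand == "H":
        return fr
    return {"A": fr["T"], "C": fr["G"], "G": fr["C"], "T": fr["A"]}


def _stop_letters(annotated: str | None, trail_len: int) -> str:
    """Terminal residues for a gene: the annotated stop where usable,
    else TAA (or its prefix for incomplete stops)."""
    letters = (annotated or "").replace("-", "").replace("‐", "").upper()
    if trail_len == 3:
        return letters if letters in STOPS2 else "TAA"
    return (letters + "TAA")[:trail_len] if letters else "TAA"[:trail_len]


class _GenomeBuilder:
    def __init__(self, template: MitoAnnotation, cfg: SimulationConfig, rng):
        self.t = template
        self.cfg = cfg
        self.rng = rng
        L = template.genome_length
        mito = cfg.composition["mitogenome"]
        self.arr = list(rng.choice(list("ACGT"), size=L,
                                   p=[mito[b] for b in "ACGT"]))
        self.locked = np.zeros(L, dtype=bool)
        self.truth: dict = {"csb_positions": {}, "repeat": None}

    # sense index s of feature f -> 0-based genome index
    def _gpos(self, f: GeneFeature, s: int) -> int:
        return (f.start - 1 + s) if f.strand == "H" else (f.end - 1 - s)

    def _write_sense(self, f: GeneFeature, s: int, base: str, lock=True):
        g = self._gpos(f, s)
        self.arr[g] = base if f.strand == "H" else base.translate(_COMPLEMENT)
        if lock:
            self.locked[g] = True

    def _read_sense(self, f: GeneFeature, s: int) -> str:
        g = self._gpos(f, s)
        b = self.arr[g]
        return b if f.strand == "H" else b.translate(_COMPLEMENT)

    def lock_pcg_termini(self):
        for f in self.t.pcgs:
            start = (f.start_codon or "ATG").upper()
            for s, b in enumerate(start):
                g = self._gpos(f, s)
                if self.locked[g]:
                    raise ValueError(f"{f.name}: conflicting start-codon constraint")
                self._write_sense(f, s, b)
            rem = f.size % 3
            trail_len = 3 if rem == 0 else rem
            trail = _stop_letters(f.stop_codon, trail_len)
            for k, b in enumerate(trail):
                s = f.size - trail_len + k
                g = self._gpos(f, s)
                if self.locked[g]:
                    want = b if f.strand == "H" else b.translate(_COMPLEMENT)
                    if self.arr[g] != want:
                        raise ValueError(
                            f"{f.name}: stop-codon constraint conflicts at "
                            f"genome position {g + 1}")
                    continue
                self._write_sense(f, s, b)

    def fill_pcg_bodies(self):
        fr = self.cfg.composition["PCG"]
        dists = {s: _nonstop_codon_distribution(_sense_fractions(fr, s))
                 for s in ("H", "L")}
        for f in self.t.pcgs:
            codons, probs = dists[f.strand]
            base_p = [_sense_fractions(fr, f.strand)[b] for b in "ACGT"]
            rem = f.size % 3
            n_body = f.size // 3 - (1 if rem == 0 else 0)  # codons after the start
            for ci in range(1, n_body):
                sense = [ci * 3, ci * 3 + 1, ci * 3 + 2]
                free = [s for s in sense if not self.locked[self._gpos(f, s)]]
                if len(free) == 3:
                    codon = codons[self.rng.choice(len(codons), p=probs)]
                    for s, b in zip(sense, codon):
                        self._write_sense(f, s, b, lock=False)
                    continue
                # partially locked codon (overlap with a neighbouring gene):
                # fill free positions by per-base rejection sampling
                for _ in range(200):
                    for s in free:
                        self._write_sense(f, s,
                                          self.rng.choice(list("ACGT"), p=base_p),
                                          lock=False)
                    codon = "".join(self._read_sense(f, s) for s in sense)
                    if codon not in STOPS2:
                        break
                else:
                    if not free:
                        raise ValueError(
                            f"{f.name}: locked codon {ci} is a stop — "
                            "infeasible template")
            self.locked[f.start - 1:f.end] = True

    def fill_rna(self):
        for cls in ("tRNA", "rRNA"):
            fr = self.cfg.composition[cls]
            for f in self.t.of_class(cls):
                p = [_sense_fractions(fr, f.strand)[b] for b in "ACGT"]
                for s in range(f.size):
                    g = self._gpos(f, s)
                    if not self.locked[g]:
                        b = self.rng.choice(list("ACGT"), p=p)
                        self.arr[g] = b if f.strand == "H" else b.translate(_COMPLEMENT)
                if f.cls == "tRNA" and f.anticodon and f.size >= 38:
                    off = 31  # anticodon sits in the central loop
                    for k, b in enumerate(f.anticodon.upper()):
                        if not self.locked[self._gpos(f, off + k)]:
                            self._write_sense(f, off + k, b, lock=False)
                self.locked[f.start - 1:f.end] = True

    def fill_cr(self):
        cfg = self.cfg
        fr = cfg.composition["CR"]
        p = [fr[b] for b in "ACGT"]
        crs = self.t.of_class("CR")
        for f in crs:
            for s in range(f.size):
                g = self._gpos(f, s)
                if not self.locked[g]:
                    self.arr[g] = self.rng.choice(list("ACGT"), p=p)
            if cfg.cr_repeat_motif:
                motif = cfg.cr_repeat_motif.upper()
                span = int(round(len(motif) * cfg.cr_repeat_copies))
                off = cfg.cr_repeat_offset
                if off + span > f.size:
                    raise ValueError("tandem repeat does not fit in the CR")
                for k in range(span):
                    self._write_sense(f, off + k, motif[k % len(motif)], lock=False)
                self.truth["repeat"] = {
                    "period": len(motif),
                    "copies": round(span / len(motif), 1),
                    "cr_start": off + 1, "cr_end": off + span,
                }
            for block, motif in (cfg.csb_motifs or {}).items():
                off = cfg.csb_offsets.get(block)
                if off is None:
                    continue
                if off + len(motif) > f.size:
                    raise ValueError(f"{block} does not fit in the CR")
                for k, b in enumerate(motif.upper()):
                    self._write_sense(f, off + k, b, lock=False)
                self.truth["csb_positions"][block] = {
                    "cr_start": off + 1, "cr_end": off + len(motif)}
            self.locked[f.start - 1:f.end] = True


def make_ancestor(cfg: SimulationConfig,
                  template: MitoAnnotation | None = None,
                  genome_id: str = "ancestor",
                  ) -> tuple[CircularSequence, MitoAnnotation, dict]:
    """Generate one annotated genome on the template gene order.

    Returns (sequence, annotation, truth) where truth records control-
    region implant coordinates.  Same config (and seed) → identical bytes.
    """
    template = template or load_reference_annotation()
    rng = np.random.default_rng(cfg.seed)
    b = _GenomeBuilder(template, cfg, rng)
    b.lock_pcg_termini()
    b.fill_pcg_bodies()
    b.fill_rna()
    b.fill_cr()
    seq = CircularSequence(genome_id, "".join(b.arr))
    ann = MitoAnnotation(genome_id=genome_id, features=list(template.features),
                         genome_length=template.genome_length,
                         species="synthetic")
    return seq, ann, b.truth


# ---------------------------------------------------------------------------
# divergence simulation

def _site_gene_map(ann: MitoAnnotation) -> dict[int, list[tuple[GeneFeature, int]]]:
    """0-based genome index -> [(PCG feature, sense index)]."""
    out: dict[int, list[tuple[GeneFeature, int]]] = {}
    for f in ann.pcgs:
        for s in range(f.size):
            g = (f.start - 1 + s) if f.strand == "H" else (f.end - 1 - s)
            out.setdefault(g, []).append((f, s))
    return out


def _mutate_base(rng, base: str, kappa: float) -> str:
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    if rng.random() < kappa / (kappa + 2.0):
        return transitions[base]
    tv = [b for b in "ACGT" if b != base and b != transitions[base]]
    return tv[rng.integers(0, 2)]


def _codon_context(seq: list[str], f: GeneFeature, s: int) -> tuple[int, str]:
    ci = s // 3
    sense = []
    for k in range(3):
        g = (f.start - 1 + ci * 3 + k) if f.strand == "H" else (f.end - 1 - ci * 3 - k)
        b = seq[g]
        sense.append(b if f.strand == "H" else b.translate(_COMPLEMENT))
    return ci, "".join(sense)


def _aa_of(codon: str) -> str | None:
    return None if codon in STOPS2 else TABLE2.forward_table[codon]


def evolve_branch(seq: CircularSequence, ann: MitoAnnotation, cfg: SimulationConfig,
                  branch_length: float, rng, label: str,
                  ) -> tuple[CircularSequence, dict]:
    """Evolve one lineage; returns (child sequence, per-branch truth)."""
    arr = list(seq.residues)
    smap = _site_gene_map(ann)
    counts = {f.name: {"syn": 0, "nonsyn": 0} for f in ann.pcgs}
    accepted = 0
    n_events = rng.poisson(branch_length * len(arr))
    for _ in range(n_events):
        g = int(rng.integers(0, len(arr)))
        old = arr[g]
        if old not in "ACGT":
            continue
        new = _mutate_base(rng, old, cfg.kappa)
        affected = smap.get(g, [])
        verdicts = []  # (gene name, is_nonsyn)
        ok = True
        for f, s in affected:
            _, before = _codon_context(arr, f, s)
            arr[g] = new
            _, after = _codon_context(arr, f, s)
            arr[g] = old
            # incomplete trailing codon residues: no frame to evaluate
            if s // 3 >= f.size // 3 and f.size % 3 != 0:
                continue
            if after in STOPS2 and before not in STOPS2:
                ok = False
                break
            if before in STOPS2 or after in STOPS2:
                continue  # annotated terminal stop: neutral bookkeeping
            verdicts.append((f.name, _aa_of(before) != _aa_of(after)))
        if not ok:
            continue
        for gene, nonsyn in verdicts:
            if nonsyn and rng.random() >= cfg.omega_for(gene):
                ok = False
                break
        if not ok:
            continue
        arr[g] = new
        accepted += 1
        for gene, nonsyn in verdicts:
            counts[gene]["nonsyn" if nonsyn else "syn"] += 1
    child = CircularSequence(label, "".join(arr))
    truth = {"label": label, "branch_length": branch_length,
             "candidate_events": int(n_events), "accepted_substitutions": accepted,
             "per_gene": counts}
    return child, truth


def evolve(ancestor: CircularSequence, ann: MitoAnnotation, cfg: SimulationConfig,
           ) -> tuple[list[tuple[CircularSequence, MitoAnnotation]], dict]:
    """Evolve the ancestor along a star phylogeny (cfg.tree: label -> branch
    length).  Returns ([(genome, annotation)], truth bundle)."""
    rng = np.random.default_rng(cfg.seed + 1)
    out = []
    truth = {"branches": []}
    for label in sorted(cfg.tree):
        child, bt = evolve_branch(ancestor, ann, cfg, cfg.tree[label], rng, label)
        child_ann = MitoAnnotation(genome_id=label, features=list(ann.features),
                                   genome_length=ann.genome_length,
                                   species="synthetic")
        out.append((child, child_ann))
        truth["branches"].append(bt)
    return out, truth


# ---------------------------------------------------------------------------
# focused simulators for estimator validation

def simulate_nucleotide_pair(n_sites: int, distance: float, kappa: float,
                             seed: int, base_freqs: dict | None = None,
                             ) -> tuple[str, str]:
    """Two sequences whose true (multiple-hit) divergence is ``distance``
    expected candidate substitutions per site, split evenly over the two
    lineages, under the two-rate κ process."""
    rng = np.random.default_rng(seed)
    fr = base_freqs or {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}
    anc = rng.choice(list("ACGT"), size=n_sites, p=[fr[b] for b in "ACGT"])
    seqs = []
    for _ in range(2):
        arr = list(anc)
        for _ in range(rng.poisson(distance / 2 * n_sites)):
            g = int(rng.integers(0, n_sites))
            arr[g] = _mutate_base(rng, arr[g], kappa)
        seqs.append("".join(arr))
    return seqs[0], seqs[1]


def simulate_codon_pair(n_codons: int, distance: float, kappa: float,
                        omega: float, seed: int) -> tuple[str, str, dict]:
    """Two in-frame codon sequences diverged from a random sense-codon
    ancestor; stop-creating candidates rejected, amino-acid-changing
    candidates accepted with probability ω.  Truth records realized
    syn/nonsyn substitution counts."""
    rng = np.random.default_rng(seed)
    anc = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), size=n_codons)]
    truth = {"syn": 0, "nonsyn": 0}
    seqs = []
    for _ in range(2):
        cods = list(anc)
        n_sites = 3 * n_codons
        for _ in range(rng.poisson(distance / 2 * n_sites)):
            site = int(rng.integers(0, n_sites))
            ci, pos = divmod(site, 3)
            before = cods[ci]
            new = _mutate_base(rng, before[pos], kappa)
            after = before[:pos] + new + before[pos + 1:]
            if after in STOPS2:
                continue
            nonsyn = TABLE2.forward_table[before] != TABLE2.forward_table[after]
            if nonsyn and rng.random() >= omega:
                continue
            cods[ci] = after
            truth["nonsyn" if nonsyn else "syn"] += 1
        seqs.append("".join(cods))
    return seqs[0], seqs[1], truth


def simulate_cr_alignment(n_rows: int, length: int, seed: int,
                          csb_motifs: dict | None = None,
                          csb_offsets: dict | None = None,
                          noise_rate: float = 0.02,
                          max_block_mismatch: int = 1,
                          ) -> tuple[AlignedMatrix, dict]:
    """Gap-free control-region alignment: a random consensus with the CSB
    motifs implanted, plus per-row substitution noise capped at
    ``max_block_mismatch`` inside each block window."""
    rng = np.random.default_rng(seed)
    motifs = csb_motifs or load_default_csb_motifs()
    offsets = csb_offsets or {"CSB-D": int(length * 0.60), "CSB-1": int(length * 0.70),
                              "CSB-2": int(length * 0.80), "CSB-3": int(length * 0.88)}
    fr = DEFAULT_COMPOSITION["CR"]
    cons = list(rng.choice(list("ACGT"), size=length, p=[fr[b] for b in "ACGT"]))
    windows = {}
    for block, motif in motifs.items():
        off = offsets[block]
        cons[off:off + len(motif)] = list(motif.upper())
        windows[block] = (off + 1, off + len(motif))  # 1-based
    cons = "".join(cons)
    rows = []
    for r in range(n_rows):
        arr = list(cons)
        block_hits = {b: 0 for b in motifs}
        for i in range(length):
            if rng.random() >= noise_rate:
                continue
            inside = [b for b, (lo, hi) in windows.items() if lo - 1 <= i <= hi - 1]
            if inside and any(block_hits[b] >= max_block_mismatch for b in inside):
                continue
            alt = [x for x in "ACGT" if x != arr[i]]
            arr[i] = alt[rng.integers(0, 3)]
            for b in inside:
                block_hits[b] += 1
        rows.append("".join(arr))
    labels = [f"sp{r + 1:02d}" for r in range(n_rows)]
    return AlignedMatrix(labels, rows), {"consensus": cons, "windows": windows}


def write_truth(truth: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
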