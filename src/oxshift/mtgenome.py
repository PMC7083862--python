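"""Human mitochondrial (rCRS) gene model and SNV consequence annotation.

The package ships the 16,569-bp revised Cambridge Reference Sequence
(NC_012920.1) and its standard gene annotation as package data.  Variants are
annotated at codon level using the vertebrate mitochondrial genetic code
(NCBI translation table 2).  All coordinates are 1-based inclusive rCRS
positions, the convention used by MitoMap and by mtDNA variant nomenclature
(e.g. m.11991T>C).

Two quirks of mammalian mtDNA biology are handled explicitly:

* several protein genes end in an incomplete stop codon (``T`` or ``TA``)
  that is completed to ``TAA`` by post-transcriptional polyadenylation; the
  terminal codon is completed with ``A`` before translation;
* position 3107 is a historical placeholder (``N``) kept to preserve legacy
  numbering; variants there are rejected as reference mismatches.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Literal, Optional

__all__ = [
    "MtGene",
    "VariantConsequence",
    "GeneModel",
    "MT_GENOME_LENGTH",
    "CONTROL_REGION_SEGMENTS",
    "VERTEBRATE_MITO_CODE",
    "load_rcrs_sequence",
    "load_gene_model",
    "translate_codon",
    "annotate_variant",
]

MT_GENOME_LENGTH = 16569

#: The non-coding control region (D-loop) wraps around the origin: it spans
#: 16024..16569 followed by 1..576.
CONTROL_REGION_SEGMENTS = ((16024, 16569), (1, 576))

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

# NCBI translation table 2 (vertebrate mitochondrial).  Differences from the
# standard code: AGA/AGG -> STOP, ATA -> Met, TGA -> Trp.
_BASES = "TCAG"
_TABLE2_AA = (
    "FFLLSSSSYY**CCWWLLLLPPPPHHQQRRRRIIMMTTTTNNKKSS**VVVVAAAADDEEGGGG"
)
VERTEBRATE_MITO_CODE = {
    a + b + c: _TABLE2_AA[16 * i + 4 * j + k]
    for i, a in enumerate(_BASES)
    for j, b in enumerate(_BASES)
    for k, c in enumerate(_BASES)
}


class SchemaError(ValueError):
    """A gene-model source file violates the documented schema."""


class ReferenceMismatchError(ValueError):
    """The supplied ref allele does not match the embedded rCRS base."""

    def __init__(self, pos: int, expected: str, got: str):
        self.pos, self.expected, self.got = pos, expected, got
        super().__init__(
            f"ref allele {got!r} at m.{pos} does not match rCRS ({expected!r})"
        )


class UnsupportedVariantError(ValueError):
    """Only single-nucleotide substitutions are annotated."""


@dataclass(frozen=True)
class MtGene:
    """One rCRS locus (gene or the control region)."""

    name: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: Literal["heavy", "light"]
    kind: Literal["protein", "tRNA", "rRNA", "control"]
    complex_assignment: Literal["CI", "CIII", "CIV", "CV", "none"] = "none"

    def __post_init__(self):
        if not (1 <= self.start <= self.end <= MT_GENOME_LENGTH):
            raise SchemaError(
                f"{self.name}: interval {self.start}..{self.end} outside "
                f"1..{MT_GENOME_LENGTH} or end < start"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


@dataclass(frozen=True)
class VariantConsequence:
    """Codon-level consequence of an SNV in one overlapped gene."""

    gene: str
    synonymy: Literal[
        "synonymous", "non_synonymous", "noncoding", "tRNA", "rRNA", "control_region"
    ]
    codon_index: Optional[int] = None
    ref_aa: Optional[str] = None
    alt_aa: Optional[str] = None

    @property
    def protein_change(self) -> Optional[str]:
        if self.ref_aa is None:
            return None
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"


def _data_path(name: str) -> Path:
    return Path(str(resources.files("oxshift").joinpath("data", name)))


def load_rcrs_sequence() -> str:
    """Return the embedded rCRS sequence as an uppercase string of length 16569."""
    text = _data_path("rcrs.fasta").read_text()
    seq = "".join(l.strip() for l in text.splitlines() if not l.startswith(">"))
    if len(seq) != MT_GENOME_LENGTH:
        raise SchemaError(f"embedded rCRS has length {len(seq)}")
    return seq.upper()


@dataclass
class GeneModel:
    """The 37-gene rCRS annotation plus the control-region record."""

    genes: list[MtGene]
    sequence: str = field(repr=False)

    def __post_init__(self):
        self.genes = sorted(self.genes, key=lambda g: (g.start, g.end))
        self._by_name = {g.name: g for g in self.genes}

    def __iter__(self):
        return iter(self.genes)

    def __getitem__(self, name: str) -> MtGene:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def protein_genes(self) -> list[MtGene]:
        return [g for g in self.genes if g.kind == "protein"]

    def overlapping(self, pos: int) -> list[MtGene]:
        """Genes overlapping ``pos`` (control region handled separately)."""
        return [g for g in self.genes if g.kind != "control" and g.contains(pos)]

    def in_control_region(self, pos: int) -> bool:
        return any(a <= pos <= b for a, b in CONTROL_REGION_SEGMENTS)

    def cds(self, gene: MtGene) -> str:
        """Coding-strand CDS of a protein gene, incomplete stop completed with A."""
        if gene.kind != "protein":
            raise ValueError(f"{gene.name} is not protein-coding")
        seq = self.sequence[gene.start - 1 : gene.end]
        if gene.strand == "light":
            seq = reverse_complement(seq)
        pad = (3 - len(seq) % 3) % 3
        return seq + "A" * pad

    def translate_cds(self, gene: MtGene) -> str:
        cds = self.cds(gene)
        return "".join(
            translate_codon(cds[i : i + 3]) for i in range(0, len(cds), 3)
        )

    def to_bed(self) -> str:
        """Gene intervals as BED (0-based half-open; control region as 2 lines)."""
        rows = []
        for g in self.genes:
            if g.kind == "control":
                for a, b in CONTROL_REGION_SEGMENTS:
                    rows.append((a - 1, b, g.name, g.strand))
            else:
                rows.append((g.start - 1, g.end, g.name, g.strand))
        rows.sort()
        strand_sym = {"heavy": "+", "light": "-"}
        return "".join(
            f"chrM\t{s}\t{e}\t{n}\t0\t{strand_sym[st]}\n" for s, e, n, st in rows
        )

    def to_gff3(self) -> str:
        strand_sym = {"heavy": "+", "light": "-"}
        kindmap = {
            "protein": "gene",
            "tRNA": "tRNA_gene",
            "rRNA": "rRNA_gene",
            "control": "region",
        }
        lines = ["##gff-version 3\n"]
        for g in self.genes:
            segs = (
                CONTROL_REGION_SEGMENTS if g.kind == "control" else ((g.start, g.end),)
            )
            for a, b in segs:
                lines.append(
                    "chrM\toxshift\t%s\t%d\t%d\t.\t%s\t.\tID=%s;complex=%s\n"
                    % (kindmap[g.kind], a, b, strand_sym[g.strand], g.name,
                       g.complex_assignment)
                )
        return "".join(lines)


def reverse_complement(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def translate_codon(codon: str) -> str:
    """Translate one codon under the vertebrate mitochondrial code.

    Returns a 1-letter amino acid, or ``"*"`` for a stop codon.
    """
    codon = codon.upper()
    if len(codon) != 3 or any(b not in "ACGT" for b in codon):
        raise ValueError(f"codon must be 3 bases of A/C/G/T, got {codon!r}")
    return VERTEBRATE_MITO_CODE[codon]


_VALID_KINDS = {"protein", "tRNA", "rRNA", "control"}
_VALID_STRANDS = {"heavy", "light"}
_VALID_COMPLEX = {"CI", "CIII", "CIV", "CV", "none"}
_CONTROL_RECORD = MtGene("MT-CR", 1, MT_GENOME_LENGTH, "heavy", "control", "none")


def load_gene_model(source: Optional[str | Path] = None) -> GeneModel:
    """Load the rCRS gene model (37 genes + control-region record).

    Parameters
    ----------
    source
        Optional path to a TSV with columns
        ``name  start  end  strand  kind  complex_assignment``.  When omitted
        the embedded annotation is used.  The control-region record is always
        appended; it represents 16024..16569 plus 1..576 (see
        :data:`CONTROL_REGION_SEGMENTS`).
    """
    path = Path(source) if source is not None else _data_path("rcrs_genes.tsv")
    genes: list[MtGene] = []
    lines = path.read_text().splitlines()
    if not lines:
        raise SchemaError(f"{path}: empty gene-model file")
    header = lines[0].rstrip("\n").split("\t")
    expected = ["name", "start", "end", "strand", "kind", "complex_assignment"]
    if header != expected:
        raise SchemaError(f"{path}: header must be {expected}, got {header}")
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) != 6:
            raise SchemaError(f"{path}:{ln}: expected 6 columns, got {len(fields)}")
        name, start, end, strand, kind, cplx = fields
        try:
            start_i, end_i = int(start), int(end)
        except ValueError as exc:
            raise SchemaError(f"{path}:{ln}: non-integer coordinate") from exc
        if strand not in _VALID_STRANDS or kind not in _VALID_KINDS \
                or cplx not in _VALID_COMPLEX:
            raise SchemaError(f"{path}:{ln}: invalid strand/kind/complex field")
        try:
            genes.append(MtGene(name, start_i, end_i, strand, kind, cplx))
        except SchemaError as exc:
            raise SchemaError(f"{path}:{ln}: {exc}") from exc
    genes.append(_CONTROL_RECORD)
    return GeneModel(genes=genes, sequence=load_rcrs_sequence())


def annotate_variant(
    pos: int,
    ref: str,
    alt: str,
    model: GeneModel,
) -> list[VariantConsequence]:
    """Annotate a single-nucleotide rCRS variant.

    Returns one :class:`VariantConsequence` per overlapped gene; overlapping
    protein genes (MT-ATP8/MT-ATP6, MT-ND4L/MT-ND4) therefore yield two
    consequences.  For light-strand genes (MT-ND6 and several tRNAs) the
    coding-strand complement of ref/alt is used for translation.  Positions in
    no gene return a single ``control_region`` or ``noncoding`` consequence.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1:
        raise UnsupportedVariantError(
            f"only single-nucleotide variants are supported, got {ref!r}>{alt!r}"
        )
    if ref not in "ACGT" or alt not in "ACGT":
        raise UnsupportedVariantError(f"alleles must be A/C/G/T, got {ref!r}>{alt!r}")
    if ref == alt:
        raise UnsupportedVariantError("ref and alt are identical")
    if not (1 <= pos <= MT_GENOME_LENGTH):
        raise ValueError(f"position {pos} outside 1..{MT_GENOME_LENGTH}")
    expected = model.sequence[pos - 1]
    if expected != ref:
        # covers the 3107 'N' placeholder as well
        raise ReferenceMismatchError(pos, expected, ref)

    hits = model.overlapping(pos)
    if not hits:
        if model.in_control_region(pos):
            return [VariantConsequence(gene="MT-CR", synonymy="control_region")]
        return [VariantConsequence(gene="intergenic", synonymy="noncoding")]

    out: list[VariantConsequence] = []
    for gene in hits:
        if gene.kind == "tRNA":
            out.append(VariantConsequence(gene=gene.name, synonymy="tRNA"))
            continue
        if gene.kind == "rRNA":
            out.append(VariantConsequence(gene=gene.name, synonymy="rRNA"))
            continue
        # protein gene: work on the coding strand
        if gene.strand == "heavy":
            offset = pos - gene.start + 1  # 1-based offset within CDS
            ref_c, alt_c = ref, alt
        else:
            offset = gene.end - pos + 1
            ref_c, alt_c = _COMPLEMENT[ref], _COMPLEMENT[alt]
        codon_index = math.ceil(offset / 3)
        cds = model.cds(gene)
        codon = cds[3 * (codon_index - 1) : 3 * codon_index]
        within = (offset - 1) % 3
        assert codon[within] == ref_c
        alt_codon = codon[:within] + alt_c + codon[within + 1 :]
        ref_aa = translate_codon(codon)
        alt_aa = translate_codon(alt_codon)
        out.append(
            VariantConsequence(
                gene=gene.name,
                synonymy="synonymous" if ref_aa == alt_aa else "non_synonymous",
                codon_index=codon_index,
                ref_aa=ref_aa,
                alt_aa=alt_aa,
            )
        )
    return out
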