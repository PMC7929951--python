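"""Reference gene model: exon structure, domain partition and key residues.

Every other stage of the pipeline expresses coordinates in terms of one
canonical reference gene model (for PCSK9: the 692-residue human protein,
a 2079-bp CDS spread over 12 exons).  This module houses that model, the
coordinate transforms between protein, CDS and genomic space, and the
validation of functionally critical residues (catalytic triad, oxyanion
hole, conserved cysteines) against a reference coding sequence.

Conventions
-----------
* Internal coordinates are 0-based half-open; everything written to or read
  from files (GFF3, reports) is 1-based inclusive.
* Minus-strand loci are reverse-complemented on ingest so that all
  downstream logic sees the gene in plus orientation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml
from Bio.Seq import Seq

__all__ = [
    "Exon",
    "GeneModel",
    "DomainRegion",
    "DomainPartition",
    "KeyResidue",
    "KeyResidueSet",
    "GeneModelError",
    "load_gene_model",
    "write_gene_model",
    "load_key_residue_config",
    "load_reference_bundle",
    "protein_to_cds",
    "cds_to_protein",
    "validate_key_residues",
]


class GeneModelError(ValueError):
    """Raised when a gene model violates its structural invariants."""


@dataclass(frozen=True)
class Exon:
    """One exon: ``start``/``end`` are 0-based half-open genomic coordinates
    on the plus-oriented locus; ``coding_bp`` is the number of coding bases
    the exon contributes to the CDS."""

    index: int
    start: int
    end: int
    coding_bp: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    exons: tuple[Exon, ...]
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"invalid strand {self.strand!r}")
        prev_end = -1
        for exon in self.exons:
            if exon.start >= exon.end:
                raise GeneModelError(f"exon {exon.index}: empty interval")
            if exon.start < prev_end:
                raise GeneModelError(
                    f"exon {exon.index} overlaps or is out of order"
                )
            if not 0 < exon.coding_bp <= exon.length:
                raise GeneModelError(
                    f"exon {exon.index}: coding_bp outside exon bounds"
                )
            prev_end = exon.end
        if self.cds_length % 3:
            raise GeneModelError(
                f"CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def cds_length(self) -> int:
        return sum(e.coding_bp for e in self.exons)

    @property
    def protein_length(self) -> int:
        """Residues in the encoded protein, excluding the stop codon."""
        return self.cds_length // 3 - 1

    # -- coordinate bookkeeping -------------------------------------------

    def exon_cds_offsets(self) -> list[tuple[int, int]]:
        """0-based half-open CDS interval contributed by each exon."""
        out, pos = [], 0
        for exon in self.exons:
            out.append((pos, pos + exon.coding_bp))
            pos += exon.coding_bp
        return out

    def exon_of_cds_pos(self, cds_pos: int) -> Exon:
        """Exon containing 0-based CDS position ``cds_pos``."""
        for exon, (lo, hi) in zip(self.exons, self.exon_cds_offsets()):
            if lo <= cds_pos < hi:
                return exon
        raise GeneModelError(f"CDS position {cds_pos} outside CDS")

    def exon_of_codon(self, codon: int) -> Exon:
        """Exon containing the first base of 1-based codon ``codon``."""
        return self.exon_of_cds_pos(3 * (codon - 1))

    def splice_donors(self) -> list[int]:
        """0-based genomic start of each intron's donor dinucleotide."""
        return [e.end for e in self.exons[:-1]]

    def splice_acceptors(self) -> list[int]:
        """0-based genomic start of each intron's acceptor dinucleotide."""
        return [e.start - 2 for e in self.exons[1:]]


@dataclass(frozen=True)
class DomainRegion:
    name: str
    first: int  # 1-based residue, inclusive
    last: int


DOMAIN_NAMES = (
    "signal_peptide",
    "prodomain",
    "catalytic",
    "v_domain",
    "c_terminal_tail",
)


@dataclass(frozen=True)
class DomainPartition:
    """Tiling of the canonical protein into named functional regions."""

    regions: tuple[DomainRegion, ...]
    analysis_start: int = 31  # residues outside the signal peptide

    def __post_init__(self) -> None:
        pos = 1
        for region in self.regions:
            if region.first != pos:
                raise GeneModelError(
                    f"domain {region.name} starts at {region.first}, "
                    f"expected {pos}: regions must tile the protein"
                )
            if region.last < region.first:
                raise GeneModelError(f"domain {region.name} is empty")
            pos = region.last + 1

    @property
    def protein_length(self) -> int:
        return self.regions[-1].last

    def region_of(self, residue: int) -> DomainRegion:
        for region in self.regions:
            if region.first <= residue <= region.last:
                return region
        raise GeneModelError(f"residue {residue} outside partition")

    def get(self, name: str) -> DomainRegion:
        for region in self.regions:
            if region.name == name:
                return region
        raise KeyError(name)


@dataclass(frozen=True)
class KeyResidue:
    position: int  # canonical (human) protein numbering
    expected_aa: str
    role: str  # triad | oxyanion | cysteine
    domain: str = ""  # catalytic | v_domain for cysteines


@dataclass(frozen=True)
class KeyResidueSet:
    """Functionally critical residues in canonical protein numbering.

    ``triad`` and the oxyanion-hole asparagine are required for the
    autocatalytic processing without which the protein is not secreted;
    their substitution is treated as inactivating.  Conserved cysteines
    are structural (disulfide bonds) and their substitution is only
    suspicious, not proof of pseudogenization.
    """

    triad: tuple[KeyResidue, ...]
    oxyanion: KeyResidue
    cysteines: tuple[KeyResidue, ...]
    late_truncation_threshold: int = 681

    def __post_init__(self) -> None:
        if len(self.triad) != 3:
            raise GeneModelError("catalytic triad must have 3 residues")
        for c in self.cysteines:
            if c.expected_aa != "C":
                raise GeneModelError("cysteine entry not a cysteine")
            if c.domain not in ("catalytic", "v_domain"):
                raise GeneModelError(f"cysteine {c.position}: bad domain tag")

    @property
    def hard_positions(self) -> frozenset[int]:
        """Residues whose substitution is inactivating (triad + oxyanion)."""
        return frozenset(r.position for r in self.triad) | {
            self.oxyanion.position
        }

    @property
    def soft_positions(self) -> frozenset[int]:
        return frozenset(c.position for c in self.cysteines)

    def all_residues(self) -> tuple[KeyResidue, ...]:
        return (*self.triad, self.oxyanion, *self.cysteines)

    def cysteines_in(self, domain: str) -> tuple[KeyResidue, ...]:
        return tuple(c for c in self.cysteines if c.domain == domain)


# ---------------------------------------------------------------------------
# GFF3 ingest / emit
# ---------------------------------------------------------------------------


def _parse_gff3_lines(lines: Iterable[str]):
    for line in lines:
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GeneModelError(f"malformed GFF3 line: {line[:60]}")
        yield cols


def load_gene_model(
    gff3_path: str | Path, locus_length: int | None = None
) -> GeneModel:
    """Load a gene model from GFF3 ``exon``/``CDS`` records.

    Exon rows define genomic intervals; CDS rows define the coding part of
    each exon.  Records may appear in any order in the file.  For a
    minus-strand gene, coordinates are flipped onto the reverse complement
    of the locus (``locus_length`` required) so the returned model is
    plus-oriented.
    """
    gff3_path = Path(gff3_path)
    gene_id = gff3_path.stem
    strand = "+"
    exon_rows: list[tuple[int, int]] = []
    cds_rows: list[tuple[int, int]] = []
    for cols in _parse_gff3_lines(gff3_path.read_text().splitlines()):
        _, _, ftype, start, end, _, strd, _, attrs = cols
        lo, hi = int(start) - 1, int(end)  # GFF3 is 1-based inclusive
        if ftype == "gene":
            strand = strd
            for item in attrs.split(";"):
                if item.startswith("ID="):
                    gene_id = item[3:]
        elif ftype == "exon":
            exon_rows.append((lo, hi))
        elif ftype == "CDS":
            cds_rows.append((lo, hi))
    if not exon_rows or not cds_rows:
        raise GeneModelError(f"{gff3_path}: no exon/CDS records")
    if strand == "-":
        if locus_length is None:
            raise GeneModelError("minus-strand model needs locus_length")
        flip = lambda lo, hi: (locus_length - hi, locus_length - lo)
        exon_rows = [flip(*r) for r in exon_rows]
        cds_rows = [flip(*r) for r in cds_rows]
    exon_rows.sort()
    cds_rows.sort()
    if len(exon_rows) != len(cds_rows):
        raise GeneModelError(
            "every exon must have exactly one CDS segment in this model"
        )
    exons = []
    for i, ((elo, ehi), (clo, chi)) in enumerate(
        zip(exon_rows, cds_rows), start=1
    ):
        if not (elo <= clo and chi <= ehi):
            raise GeneModelError(f"CDS segment outside exon {i}")
        exons.append(Exon(index=i, start=elo, end=ehi, coding_bp=chi - clo))
    return GeneModel(gene_id=gene_id, exons=tuple(exons), strand="+")


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Emit the model as GFF3 (1-based inclusive, plus strand)."""
    lines = ["##gff-version 3"]
    seqid = model.gene_id + "_locus"
    span = (model.exons[0].start + 1, model.exons[-1].end)
    lines.append(
        f"{seqid}\tgenedecay\tgene\t{span[0]}\t{span[1]}\t.\t+\t.\t"
        f"ID={model.gene_id}"
    )
    for exon in model.exons:
        lines.append(
            f"{seqid}\tgenedecay\texon\t{exon.start + 1}\t{exon.end}\t.\t+\t.\t"
            f"ID={model.gene_id}.exon{exon.index};Parent={model.gene_id}"
        )
        # CDS occupies the 5' part of each exon in this single-transcript model
        lines.append(
            f"{seqid}\tgenedecay\tCDS\t{exon.start + 1}\t"
            f"{exon.start + exon.coding_bp}\t.\t+\t0\t"
            f"ID={model.gene_id}.cds{exon.index};Parent={model.gene_id}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# key-residue / domain configuration
# ---------------------------------------------------------------------------


def load_key_residue_config(
    path: str | Path,
) -> tuple[KeyResidueSet, DomainPartition]:
    """Read the structured key-residue + domain configuration (YAML)."""
    cfg = yaml.safe_load(Path(path).read_text())
    triad = tuple(
        KeyResidue(int(pos), aa, "triad", "catalytic")
        for pos, aa in sorted(cfg["catalytic_triad"].items())
    )
    (oxy_pos, oxy_aa), = cfg["oxyanion"].items()
    oxyanion = KeyResidue(int(oxy_pos), oxy_aa, "oxyanion", "catalytic")
    cysteines = tuple(
        KeyResidue(int(pos), "C", "cysteine", domain)
        for domain in ("catalytic", "v_domain")
        for pos in cfg["cysteines"][domain]
    )
    keyres = KeyResidueSet(
        triad=triad,
        oxyanion=oxyanion,
        cysteines=cysteines,
        late_truncation_threshold=int(
            cfg.get("late_truncation_threshold", 681)
        ),
    )
    regions = tuple(
        DomainRegion(name, int(lo), int(hi))
        for name, (lo, hi) in (
            (n, cfg["domains"][n]) for n in DOMAIN_NAMES
        )
    )
    partition = DomainPartition(
        regions=regions, analysis_start=int(cfg.get("analysis_start", 31))
    )
    return keyres, partition


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------


def protein_to_cds(model: GeneModel, residue: int) -> tuple[int, int, int]:
    """1-based CDS base positions (b1, b2, b3) of 1-based ``residue``."""
    if not 1 <= residue <= model.protein_length:
        raise GeneModelError(
            f"residue {residue} outside 1..{model.protein_length}"
        )
    b1 = 3 * residue - 2
    return (b1, b1 + 1, b1 + 2)


def cds_to_protein(cds_pos: int) -> int:
    """1-based residue index containing 1-based CDS base ``cds_pos``."""
    if cds_pos < 1:
        raise GeneModelError(f"CDS position {cds_pos} < 1")
    return (cds_pos - 1) // 3 + 1


def cds_to_genomic(model: GeneModel, cds_pos: int) -> int:
    """0-based genomic coordinate of 0-based CDS position ``cds_pos``."""
    for exon, (lo, hi) in zip(model.exons, model.exon_cds_offsets()):
        if lo <= cds_pos < hi:
            return exon.start + (cds_pos - lo)
    raise GeneModelError(f"CDS position {cds_pos} outside CDS")


# ---------------------------------------------------------------------------
# key-residue validation
# ---------------------------------------------------------------------------


def translate_cds(cds: str) -> str:
    """Translate a CDS; raises on internal stops or length not 3n."""
    if len(cds) % 3:
        raise GeneModelError("CDS length not divisible by 3")
    protein = str(Seq(cds).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise GeneModelError("internal stop codon in reference CDS")
    return protein


def validate_key_residues(
    keyres: KeyResidueSet, reference_cds: str
) -> list[dict]:
    """Check each key residue against the translated reference CDS.

    Returns one report row per residue with the observed amino acid and a
    match flag.  Mismatches are flagged, never fatal: the reference may
    legitimately deviate from the canonical annotation.
    """
    protein = translate_cds(reference_cds)
    report = []
    for res in keyres.all_residues():
        observed = (
            protein[res.position - 1]
            if res.position <= len(protein)
            else "-"
        )
        report.append(
            {
                "position": res.position,
                "role": res.role,
                "domain": res.domain,
                "expected": res.expected_aa,
                "observed": observed,
                "match": observed == res.expected_aa,
            }
        )
    return report


# ---------------------------------------------------------------------------
# bundled synthetic reference
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReferenceBundle:
    model: GeneModel
    cds: str
    locus: str
    key_residues: KeyResidueSet
    domains: DomainPartition


def _read_fasta_one(text: str) -> str:
    seq = []
    for line in text.splitlines():
        if not line.startswith(">"):
            seq.append(line.strip())
    return "".join(seq)


def load_reference_bundle() -> ReferenceBundle:
    """Load the bundled synthetic PCSK9-like reference.

    The bundle is a synthetic stand-in for the human PCSK9 annotation: it
    reproduces the printed structural facts (12 exons, 692-residue protein,
    catalytic triad D186/H226/S386, oxyanion N317, 25 catalytic+C-terminal
    cysteines of which 18 are in the V-domain, canonical GT/AG introns) on a
    synthetic sequence; the per-exon base counts are constructed, not
    copied from the human genome.
    """
    data = resources.files("genedecay.data")
    with resources.as_file(
        data / "pcsk9_reference_synthetic.gff3"
    ) as gff3:
        model = load_gene_model(gff3)
    cds = _read_fasta_one(
        (data / "pcsk9_reference_synthetic_cds.fasta").read_text()
    )
    locus = _read_fasta_one(
        (data / "pcsk9_reference_synthetic_locus.fasta").read_text()
    )
    with resources.as_file(
        data / "pcsk9_key_residues.yaml"
    ) as cfg:
        keyres, domains = load_key_residue_config(cfg)
    return ReferenceBundle(
        model=model,
        cds=cds,
        locus=locus,
        key_residues=keyres,
        domains=domains,
    )
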