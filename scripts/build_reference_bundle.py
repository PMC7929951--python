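"""Generate the bundled synthetic PCSK9-like reference (run once, commit).

Produces a deterministic synthetic stand-in for the human PCSK9 annotation:
a 692-residue protein with the canonical key residues at their published
human-numbering positions, a 2079-bp CDS over 12 exons, and a genomic locus
with canonical GT/AG introns and intergenic flanks.  Per-exon base counts
are constructed (the real values are not reproduced); every count the
pipeline asserts (12 exons, 25 + 18 cysteines, triad, N317) is exact.

Usage: python scripts/build_reference_bundle.py
"""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "src" / "genedecay" / "data"

PROTEIN_LENGTH = 692
EXON_CODING_BP = [139, 186, 114, 153, 93, 135, 150, 186, 174, 120, 444, 185]
INTRON_LENGTHS = [420, 310, 365, 280, 330, 410, 295, 350, 305, 385, 340]
FLANK = 800
UTR3 = 200

TRIAD = {186: "D", 226: "H", 386: "S"}
OXYANION = {317: "N"}
CATALYTIC_CYS = [223, 255, 323, 358, 363, 378, 428]
V_DOMAIN_CYS = [
    457, 477, 486, 527, 534, 562, 588, 600, 601, 608,
    617, 623, 635, 654, 661, 668, 672, 679,
]
DOMAINS = {
    "signal_peptide": [1, 30],
    "prodomain": [31, 152],
    "catalytic": [153, 452],
    "v_domain": [453, 682],
    "c_terminal_tail": [683, 692],
}

CODONS = {
    "A": ["GCT", "GCC", "GCA"],
    "R": ["CGT", "CGC", "AGA"],
    "N": ["AAT", "AAC"],
    "D": ["GAT", "GAC"],
    "C": ["TGT", "TGC"],
    "Q": ["CAA", "CAG"],
    "E": ["GAA", "GAG"],
    "G": ["GGT", "GGC", "GGA"],
    "H": ["CAT", "CAC"],
    "I": ["ATT", "ATC"],
    "L": ["CTT", "CTC", "CTG", "TTA"],
    "K": ["AAA", "AAG"],
    "M": ["ATG"],
    "F": ["TTT", "TTC"],
    "P": ["CCT", "CCC", "CCA"],
    "S": ["TCT", "TCC", "AGC"],
    "T": ["ACT", "ACC", "ACA"],
    "W": ["TGG"],
    "Y": ["TAT", "TAC"],
    "V": ["GTT", "GTC", "GTG"],
}
# amino acids used to fill non-key positions (no C, no M: those are placed
# explicitly so the key-residue counts stay exact)
FILLER_AA = "ARNDQEGHILKFPSTWYV"


def build_protein(rng: np.random.Generator) -> str:
    protein = [FILLER_AA[rng.integers(len(FILLER_AA))] for _ in range(PROTEIN_LENGTH)]
    protein[0] = "M"
    for pos, aa in {**TRIAD, **OXYANION}.items():
        protein[pos - 1] = aa
    for pos in CATALYTIC_CYS + V_DOMAIN_CYS:
        protein[pos - 1] = "C"
    return "".join(protein)


def build_cds(protein: str, rng: np.random.Generator) -> str:
    codons = [CODONS[aa][rng.integers(len(CODONS[aa]))] for aa in protein]
    codons.append("TAA")
    return "".join(codons)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def main() -> int:
    assert sum(EXON_CODING_BP) == 3 * (PROTEIN_LENGTH + 1)
    rng = np.random.default_rng(20210130)
    protein = build_protein(rng)
    cds = build_cds(protein, rng)

    # assemble locus: flank + (exon [+UTR on last] + intron)*
    parts = [random_dna(rng, FLANK)]
    pos = FLANK
    exon_rows = []  # (index, start, end, coding_bp) 0-based half-open
    cds_pos = 0
    for i, coding in enumerate(EXON_CODING_BP, start=1):
        exon_seq = cds[cds_pos:cds_pos + coding]
        cds_pos += coding
        exon_len = coding + (UTR3 if i == 12 else 0)
        if i == 12:
            exon_seq += random_dna(rng, UTR3)
        exon_rows.append((i, pos, pos + exon_len, coding))
        parts.append(exon_seq)
        pos += exon_len
        if i < 12:
            ilen = INTRON_LENGTHS[i - 1]
            intron = "GT" + random_dna(rng, ilen - 4) + "AG"
            parts.append(intron)
            pos += ilen
    parts.append(random_dna(rng, FLANK))
    locus = "".join(parts)

    DATA.mkdir(parents=True, exist_ok=True)

    def fasta(name: str, header: str, seq: str) -> None:
        lines = [f">{header}"]
        lines += [seq[i:i + 70] for i in range(0, len(seq), 70)]
        (DATA / name).write_text("\n".join(lines) + "\n")

    fasta(
        "pcsk9_reference_synthetic_cds.fasta",
        "PCSK9_synthetic_reference_cds 2079 bp, synthetic stand-in",
        cds,
    )
    fasta(
        "pcsk9_reference_synthetic_locus.fasta",
        "PCSK9_synthetic_reference_locus synthetic stand-in",
        locus,
    )

    gff = ["##gff-version 3"]
    seqid = "PCSK9_locus"
    gff.append(
        f"{seqid}\tgenedecay\tgene\t{exon_rows[0][1] + 1}\t{exon_rows[-1][2]}"
        f"\t.\t+\t.\tID=PCSK9"
    )
    for i, start, end, coding in exon_rows:
        gff.append(
            f"{seqid}\tgenedecay\texon\t{start + 1}\t{end}\t.\t+\t.\t"
            f"ID=PCSK9.exon{i};Parent=PCSK9"
        )
        gff.append(
            f"{seqid}\tgenedecay\tCDS\t{start + 1}\t{start + coding}\t.\t+\t0\t"
            f"ID=PCSK9.cds{i};Parent=PCSK9"
        )
    (DATA / "pcsk9_reference_synthetic.gff3").write_text("\n".join(gff) + "\n")

    cfg = [
        "# Key residues and domain partition, canonical human numbering.",
        "# Positions the source literature names are exact; the full",
        "# cysteine lists are a synthetic completion to the printed counts",
        "# (25 catalytic + C-terminal, of which 18 in the V-domain).",
        "gene_id: PCSK9",
        "late_truncation_threshold: 681",
        "analysis_start: 31",
        "catalytic_triad: {186: D, 226: H, 386: S}",
        "oxyanion: {317: N}",
        "cysteines:",
        f"  catalytic: {CATALYTIC_CYS}",
        f"  v_domain: {V_DOMAIN_CYS}",
        "domains:",
    ] + [f"  {name}: {span}" for name, span in DOMAINS.items()]
    (DATA / "pcsk9_key_residues.yaml").write_text("\n".join(cfg) + "\n")

    print(f"wrote bundle to {DATA} (locus {len(locus)} bp, CDS {len(cds)} bp)")
    return 0


if __name__ == "__main__":
    sys.exit(main())
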