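"""One-pot sgRNA design.

Finds Cas9 targets (20-nt spacer + NGG PAM) in a sequence, assembles the
single forward primer used for one-pot PCR + T7 in vitro transcription
(minimal T7 promoter, spacer, scaffold-annealing overlap), predicts the
transcribed sgRNA, lays designs out on 96-well order plates, and predicts
the deletion produced by a pair of sgRNAs together with the diagnostic
genotyping amplicon sizes.

Coordinates are 0-based, half-open, reported on the + strand throughout.
The Cas9 cut is modelled as blunt, falling between the 3rd and 4th
nucleotide upstream of the PAM; ``cut_site = i`` means the double-strand
break lies between reference positions ``i - 1`` and ``i``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio.Seq import Seq

__all__ = [
    "MINIMAL_T7_PROMOTER",
    "SgRNADesign",
    "ScaffoldTemplate",
    "PairedDeletionDesign",
    "find_targets",
    "assemble_forward_primer",
    "predict_sgrna",
    "plate_layout_96",
    "predict_pair_deletion",
]

#: Minimal (truncated) T7 promoter.  The trailing G is the +1 base of
#: transcription; a further G is prefixed to spacers that do not start
#: with G, because T7 RNA polymerase initiates poorly on other bases.
MINIMAL_T7_PROMOTER = "TAATACGACTCACTATAG"

#: Canonical S. pyogenes sgRNA conserved region (scaffold) as DNA,
#: including the poly-T terminator.  This is a synthetic stand-in default:
#: any project-specific double-stranded scaffold template can be supplied
#: instead (e.g. loaded from FASTA).
CANONICAL_SCAFFOLD_DNA = (
    "GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGG"
    "CACCGAGTCGGTGCTTTTTTT"
)

_DNA = set("ACGT")


def _check_dna(seq: str, what: str) -> str:
    seq = seq.upper()
    if not seq:
        raise ValueError(f"{what} must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise ValueError(f"{what} contains non-ACGT characters: {sorted(bad)}")
    return seq


@dataclass(frozen=True)
class SgRNADesign:
    """A single Cas9 target and (optionally) its one-pot primer products.

    ``cut_site`` is the + strand index of the base immediately 3' of the
    blunt cut (the break lies between ``cut_site - 1`` and ``cut_site``),
    i.e. 3 nt from the PAM-proximal end of the protospacer.
    """

    spacer: str
    pam: str
    strand: str
    cut_site: int
    name: str = ""
    forward_primer: str = ""
    predicted_sgrna: str = ""

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError("spacer must be exactly 20 nt")
        _check_dna(self.spacer, "spacer")
        if len(self.pam) != 3 or self.pam[1:] != "GG":
            raise ValueError("PAM must be 3 nt matching NGG")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class ScaffoldTemplate:
    """Double-stranded DNA template encoding the sgRNA conserved region.

    ``overlap_region`` is the 3' tail of the forward primer that anneals
    to the template during one-pot PCR; it must be an exact prefix of the
    template sequence.
    """

    sequence: str = CANONICAL_SCAFFOLD_DNA
    overlap_length: int = 15

    def __post_init__(self) -> None:
        _check_dna(self.sequence, "scaffold sequence")
        if not 1 <= self.overlap_length <= len(self.sequence):
            raise ValueError("overlap_length must lie within the scaffold")

    @property
    def overlap_region(self) -> str:
        return self.sequence[: self.overlap_length]

    @property
    def length_bp(self) -> int:
        return len(self.sequence)

    @property
    def rna(self) -> str:
        return self.sequence.replace("T", "U")


@dataclass(frozen=True)
class PairedDeletionDesign:
    """Deletion predicted for a pair of sgRNAs plus genotyping amplicons."""

    sg_a: SgRNADesign
    sg_b: SgRNADesign
    expected_deletion_bp: int
    wt_amplicon_bp: int
    edited_amplicon_bp: int
    genotyping_primers: tuple[str, str]
    name: str = ""

    def __post_init__(self) -> None:
        if self.expected_deletion_bp != abs(self.sg_b.cut_site - self.sg_a.cut_site):
            raise ValueError("expected_deletion_bp inconsistent with cut sites")
        if self.edited_amplicon_bp != self.wt_amplicon_bp - self.expected_deletion_bp:
            raise ValueError("edited_amplicon_bp inconsistent with deletion size")


def _scan_plus(sequence: str):
    """Yield (spacer, pam, pam_start) for every NGG window on + strand."""
    for pam_start in range(20, len(sequence) - 2):
        if sequence[pam_start + 1 : pam_start + 3] == "GG":
            yield sequence[pam_start - 20 : pam_start], sequence[
                pam_start : pam_start + 3
            ], pam_start


def find_targets(sequence: str, name_prefix: str = "sg") -> list[SgRNADesign]:
    """Enumerate all Cas9 targets (20-nt spacer + NGG PAM) on both strands.

    Windows containing ambiguous bases (anything outside ACGT) are skipped
    with a warning.  Cut sites are reported in + strand coordinates; for a
    - strand target the protospacer lies 3' of the CCN on the + strand and
    the cut bond falls between ``pam_start + 5`` and ``pam_start + 6``.
    """
    sequence = sequence.upper()
    if len(sequence) < 23:
        raise ValueError("sequence must be at least 23 nt")
    ambiguous = set(sequence) - _DNA
    if ambiguous:
        warnings.warn(
            f"sequence contains ambiguous bases {sorted(ambiguous)}; "
            "candidates overlapping them are skipped",
            stacklevel=2,
        )

    designs: list[SgRNADesign] = []
    for spacer, pam, pam_start in _scan_plus(sequence):
        if set(spacer + pam) <= _DNA:
            designs.append(
                SgRNADesign(
                    spacer=spacer,
                    pam=pam,
                    strand="+",
                    cut_site=pam_start - 3,
                )
            )
    rc = str(Seq(sequence).reverse_complement())
    n = len(sequence)
    for spacer, pam, pam_start_rc in _scan_plus(rc):
        if set(spacer + pam) <= _DNA:
            # PAM occupies rc[pam_start_rc : pam_start_rc+3], i.e. + strand
            # [n - pam_start_rc - 3, n - pam_start_rc).  The cut bond sits
            # between the 3rd and 4th nt upstream of the PAM on the - strand,
            # which is + strand bond (plus_pam_start + 5 | plus_pam_start + 6).
            plus_pam_start = n - pam_start_rc - 3
            designs.append(
                SgRNADesign(
                    spacer=spacer,
                    pam=pam,
                    strand="-",
                    cut_site=plus_pam_start + 6,
                )
            )
    designs.sort(key=lambda d: (d.cut_site, d.strand))
    if name_prefix:
        designs = [
            SgRNADesign(
                spacer=d.spacer,
                pam=d.pam,
                strand=d.strand,
                cut_site=d.cut_site,
                name=f"{name_prefix}{i + 1}",
            )
            for i, d in enumerate(designs)
        ]
    return designs


def _g_prefixed(spacer: str) -> str:
    return spacer if spacer.startswith("G") else "G" + spacer


def assemble_forward_primer(
    spacer: str,
    scaffold: ScaffoldTemplate | None = None,
    t7_min: str = MINIMAL_T7_PROMOTER,
) -> str:
    """Assemble the one-pot forward primer for a spacer.

    Layout: minimal T7 promoter, then the spacer (G-prefixed if it does
    not already start with G, to satisfy T7 initiation), then the overlap
    that anneals to the scaffold template.  Deterministic concatenation.
    """
    if scaffold is None:
        scaffold = ScaffoldTemplate()
    if len(spacer) != 20:
        raise ValueError("spacer must be exactly 20 nt")
    spacer = _check_dna(spacer, "spacer")
    t7_min = _check_dna(t7_min, "t7_min")
    return t7_min + _g_prefixed(spacer) + scaffold.overlap_region


def predict_sgrna(design: SgRNADesign, scaffold: ScaffoldTemplate | None = None) -> str:
    """Predict the single sgRNA produced by one-pot transcription.

    The transcript is the (possibly G-prefixed) spacer followed by the
    conserved scaffold, as RNA.
    """
    if scaffold is None:
        scaffold = ScaffoldTemplate()
    return _g_prefixed(design.spacer).replace("T", "U") + scaffold.rna


_ROWS = "ABCDEFGH"


def plate_layout_96(
    designs: Sequence[SgRNADesign | str],
    replicates: int = 1,
) -> list[dict[str, SgRNADesign | str]]:
    """Lay designs out on 96-well order plates, column-major (A1, B1, ...).

    Each design occupies ``replicates`` consecutive wells.  Entries beyond
    96 wells spill over onto additional plates; the return value is a list
    of plates, each a mapping from well id to design.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    plates: list[dict[str, SgRNADesign | str]] = []
    current: dict[str, SgRNADesign | str] = {}
    i = 0
    for design in designs:
        for _ in range(replicates):
            if i == 96:
                plates.append(current)
                current, i = {}, 0
            well = f"{_ROWS[i % 8]}{i // 8 + 1}"
            current[well] = design
            i += 1
    if current or not plates:
        plates.append(current)
    return plates


def predict_pair_deletion(
    sg_a: SgRNADesign,
    sg_b: SgRNADesign,
    primers: tuple[str, str],
    reference: str,
    name: str = "",
) -> PairedDeletionDesign:
    """Predict the deletion made by two sgRNAs and the gel band sizes.

    The genotyping amplicon is delimited by exact matches of the two
    primers in ``reference`` (forward primer on the + strand, reverse
    primer as given on the - strand).  The expected deletion spans the
    two cut sites; the edited amplicon is shorter by exactly that much.
    """
    if sg_a.cut_site == sg_b.cut_site:
        raise ValueError("paired sgRNAs must have distinct cut sites")
    reference = _check_dna(reference, "reference")
    fwd = _check_dna(primers[0], "forward primer")
    rev = _check_dna(primers[1], "reverse primer")

    start = reference.find(fwd)
    if start < 0:
        raise ValueError("forward primer not found in reference")
    rev_on_plus = str(Seq(rev).reverse_complement())
    end_idx = reference.rfind(rev_on_plus)
    if end_idx < 0:
        raise ValueError("reverse primer not found in reference")
    end = end_idx + len(rev_on_plus)
    wt_amplicon_bp = end - start
    if wt_amplicon_bp <= 0:
        raise ValueError("primers do not delimit a forward amplicon")

    lo, hi = sorted((sg_a.cut_site, sg_b.cut_site))
    if not (start < lo and hi < end):
        raise ValueError("both cut sites must lie strictly inside the amplicon")

    deletion = hi - lo
    return PairedDeletionDesign(
        sg_a=sg_a,
        sg_b=sg_b,
        expected_deletion_bp=deletion,
        wt_amplicon_bp=wt_amplicon_bp,
        edited_amplicon_bp=wt_amplicon_bp - deletion,
        genotyping_primers=(fwd, rev),
        name=name or f"{sg_a.name}+{sg_b.name}",
    )
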