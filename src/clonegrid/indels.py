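"""Amplicon indel quantification and gel genotyping.

Aligns amplicon reads to their reference with an affine-gap semi-global
aligner (the read aligns globally, reference overhangs are free), calls
insertion/deletion events in a window around the expected Cas9 cut site,
classifies reading frame from the net indel length, summarises the
wild-type / indel / in-frame composition and deletion:insertion mixture
of a read set, builds per-base match-frequency profiles, and calls
WT / monoallelic / biallelic genotypes from genotyping-gel band tables.

Conventions: coordinates are 0-based reference positions; a deletion of
length L at position p removes ``ref[p:p+L]``; an insertion at position p
sits in the bond before ``ref[p]``.  Indels are left-aligned within
repeats so equivalent placements have one canonical form.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align

from .design import SgRNADesign
from .design import PairedDeletionDesign

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentScoring",
    "AmpliconReference",
    "IndelEvent",
    "ReadAlignment",
    "IndelCall",
    "EditSummary",
    "GelGenotype",
    "align_read",
    "call_indels",
    "summarize",
    "per_base_profile",
    "genotype_from_gel",
    "expected_inframe_fraction",
    "uniform_length_distribution",
]


@dataclass(frozen=True)
class AlignmentScoring:
    """Affine-gap scores: a gap of length L scores open + (L-1)*extend."""

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -8.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class AmpliconReference:
    """An amplicon reference with its sgRNA target(s) and primer margins."""

    name: str
    sequence: str
    sgrna_designs: tuple[SgRNADesign, ...] = ()
    primer_lengths: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if set(seq) - set("ACGT"):
            raise ValueError("reference sequence must be uppercase ACGT")
        object.__setattr__(self, "sequence", seq)
        object.__setattr__(self, "sgrna_designs", tuple(self.sgrna_designs))
        left, right = self.primer_lengths
        for d in self.sgrna_designs:
            if not left <= d.cut_site < len(seq) - right:
                raise ValueError(
                    f"cut site {d.cut_site} outside the inter-primer region"
                )

    @property
    def cut_sites(self) -> list[int]:
        return [d.cut_site for d in self.sgrna_designs]


@dataclass(frozen=True)
class IndelEvent:
    kind: Literal["ins", "del", "sub"]
    ref_pos: int
    length: int
    seq: str = ""  # inserted bases (insertions only)


@dataclass(frozen=True)
class ReadAlignment:
    """A read aligned semi-globally to its reference.

    ``aligned_read``/``aligned_ref`` are equal-length gapped strings;
    removing the gaps recovers the inputs.  ``events`` are the non-end-gap
    differences in reference coordinates, with indels left-normalised.
    ``ref_start``/``ref_end`` delimit the reference span covered by the
    read (half-open).
    """

    aligned_read: str
    aligned_ref: str
    score: float
    events: tuple[IndelEvent, ...]
    ref_start: int
    ref_end: int
    read_id: str = ""

    def __post_init__(self) -> None:
        if len(self.aligned_read) != len(self.aligned_ref):
            raise ValueError("gapped strings must have equal length")


@lru_cache(maxsize=8)
def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    a.open_gap_score = scoring.gap_open
    a.extend_gap_score = scoring.gap_extend
    # Free end gaps where the reference overhangs the read (gaps in the
    # read row): the read is global, the reference is not.
    a.open_left_deletion_score = 0.0
    a.extend_left_deletion_score = 0.0
    a.open_right_deletion_score = 0.0
    a.extend_right_deletion_score = 0.0
    return a


def _left_normalize(events: list[IndelEvent], ref: str) -> list[IndelEvent]:
    out = []
    for ev in events:
        if ev.kind == "del":
            p, L = ev.ref_pos, ev.length
            while p > 0 and ref[p - 1] == ref[p + L - 1]:
                p -= 1
            out.append(IndelEvent("del", p, L))
        elif ev.kind == "ins":
            p, s = ev.ref_pos, ev.seq
            while p > 0 and s and s[-1] == ref[p - 1]:
                s = ref[p - 1] + s[:-1]
                p -= 1
            out.append(IndelEvent("ins", p, ev.length, s))
        else:
            out.append(ev)
    return sorted(out, key=lambda e: (e.ref_pos, e.kind))


def _extract_events(
    aligned_ref: str, aligned_read: str
) -> tuple[list[IndelEvent], int, int]:
    """Walk alignment columns; return (events, ref_start, ref_end).

    Gaps in the read row outside the read's aligned span are reference
    overhangs (free end gaps), not deletions.
    """
    n = len(aligned_ref)
    read_cols = [i for i in range(n) if aligned_read[i] != "-"]
    if not read_cols:
        return [], 0, 0
    first, last = read_cols[0], read_cols[-1]

    events: list[IndelEvent] = []
    ref_pos = aligned_ref[:first].count("-") * 0 + sum(
        1 for c in aligned_ref[:first] if c != "-"
    )
    ref_start = ref_pos
    i = first
    while i <= last:
        r, q = aligned_ref[i], aligned_read[i]
        if r != "-" and q != "-":
            if r != q:
                events.append(IndelEvent("sub", ref_pos, 1))
            ref_pos += 1
            i += 1
        elif q == "-":  # deletion from the read
            start = ref_pos
            L = 0
            while i <= last and aligned_read[i] == "-":
                if aligned_ref[i] != "-":
                    ref_pos += 1
                    L += 1
                i += 1
            events.append(IndelEvent("del", start, L))
        else:  # r == "-": insertion into the read
            ins = []
            while i <= last and aligned_ref[i] == "-":
                if aligned_read[i] != "-":
                    ins.append(aligned_read[i])
                i += 1
            events.append(IndelEvent("ins", ref_pos, len(ins), "".join(ins)))
    return events, ref_start, ref_pos


def align_read(
    read: str,
    ref: "AmpliconReference | str",
    scoring: AlignmentScoring | None = None,
    read_id: str = "",
) -> ReadAlignment:
    """Optimal semi-global alignment of a read against an amplicon.

    The read aligns end to end; unaligned reference overhangs cost
    nothing.  Ties are broken deterministically (first optimal alignment
    in the aligner's canonical enumeration order), and indels are then
    left-aligned within repeats.
    """
    ref_seq = ref.sequence if isinstance(ref, AmpliconReference) else ref
    read = read.upper()
    ref_seq = ref_seq.upper()
    if not read or not ref_seq:
        raise ValueError("read and reference must be non-empty")
    allowed = set("ACGTN")
    if (set(read) | set(ref_seq)) - allowed:
        raise ValueError("sequences must be over ACGT (N allowed)")
    scoring = scoring or AlignmentScoring()
    aln = _aligner(scoring).align(ref_seq, read)
    best = aln[0]
    aligned_ref, aligned_read = str(best[0]), str(best[1])
    raw_events, ref_start, ref_end = _extract_events(aligned_ref, aligned_read)
    events = tuple(_left_normalize(raw_events, ref_seq))
    return ReadAlignment(
        aligned_read=aligned_read,
        aligned_ref=aligned_ref,
        score=float(aln.score),
        events=events,
        ref_start=ref_start,
        ref_end=ref_end,
        read_id=read_id,
    )


@dataclass(frozen=True)
class IndelCall:
    read_id: str
    classification: Literal["WT", "indel"]
    frame: Literal["in_frame", "frameshift", "NA"]
    net_length: int
    events: tuple[IndelEvent, ...] = ()


def call_indels(
    aln: ReadAlignment,
    ref: AmpliconReference,
    window_nt: int = 100,
    sg_index: int = 0,
) -> IndelCall:
    """Classify a read as WT or indel from events near the cut site.

    The window is ``[cut - window_nt//2, cut + window_nt//2)``.  Only
    insertion/deletion events whose reference footprint intersects the
    window count; substitutions never do.  ``net_length`` sums insertions
    as positive and deletions as negative; an indel read is in frame iff
    its net length is divisible by 3.
    """
    if not ref.sgrna_designs:
        raise ValueError("reference carries no sgRNA design / cut site")
    cut = ref.cut_sites[sg_index]
    half = window_nt // 2
    w0, w1 = cut - half, cut + half
    if w0 < 0 or w1 > len(ref.sequence):
        raise ValueError("indel window extends outside the reference")

    counted = []
    net = 0
    for ev in aln.events:
        if ev.kind == "del":
            if ev.ref_pos < w1 and ev.ref_pos + ev.length > w0:
                counted.append(ev)
                net -= ev.length
        elif ev.kind == "ins":
            if w0 <= ev.ref_pos < w1:
                counted.append(ev)
                net += ev.length
    if not counted:
        return IndelCall(aln.read_id, "WT", "NA", 0)
    frame = "in_frame" if net % 3 == 0 else "frameshift"
    return IndelCall(aln.read_id, "indel", frame, net, tuple(counted))


@dataclass(frozen=True)
class EditSummary:
    n_reads: int
    frac_wt: float
    frac_indel: float
    frac_inframe: float
    n_deletion_reads: int
    n_insertion_reads: int
    per_base_match_freq: tuple[float, ...] | None = None

    @property
    def deletion_fraction_of_indels(self) -> float:
        """Fraction of net-deletion reads among del/ins reads."""
        denom = self.n_deletion_reads + self.n_insertion_reads
        return self.n_deletion_reads / denom if denom else math.nan


def summarize(calls: Sequence[IndelCall]) -> EditSummary:
    """Aggregate per-read calls into WT/indel/in-frame fractions.

    A read counts as a deletion (insertion) read if its net length is
    negative (positive).  Indel reads with net length exactly zero are
    counted as in-frame indels but excluded from the deletion/insertion
    tallies, with a log note.
    """
    if not calls:
        raise ValueError("summarize requires at least one call")
    n = len(calls)
    n_indel = sum(1 for c in calls if c.classification == "indel")
    n_inframe = sum(
        1 for c in calls if c.classification == "indel" and c.frame == "in_frame"
    )
    n_del = sum(1 for c in calls if c.classification == "indel" and c.net_length < 0)
    n_ins = sum(1 for c in calls if c.classification == "indel" and c.net_length > 0)
    n_zero = n_indel - n_del - n_ins
    if n_zero:
        logger.info(
            "%d indel reads with net length 0 excluded from del/ins tallies", n_zero
        )
    return EditSummary(
        n_reads=n,
        frac_wt=(n - n_indel) / n,
        frac_indel=n_indel / n,
        frac_inframe=n_inframe / n,
        n_deletion_reads=n_del,
        n_insertion_reads=n_ins,
    )


def per_base_profile(
    alignments: Sequence[ReadAlignment],
    ref: AmpliconReference,
) -> pd.DataFrame:
    """Per-reference-position fraction of reads matching the reference.

    A substitution or a deletion at a position is a non-match; inserted
    bases have no reference footprint.  Positions a read does not span
    (free end gaps) do not enter that read's denominator.  Primer-binding
    margins are flagged ``masked`` (their apparent match frequency is an
    artefact of priming).  Returns a DataFrame with columns
    ``position, match_freq, coverage, masked``.
    """
    if not alignments:
        raise ValueError("per_base_profile requires at least one alignment")
    n = len(ref.sequence)
    matches = np.zeros(n, dtype=float)
    coverage = np.zeros(n, dtype=float)
    for aln in alignments:
        ref_pos = aln.ref_start
        started = False
        for r, q in zip(aln.aligned_ref, aln.aligned_read):
            if q != "-":
                started = True
            if r == "-":
                continue
            if not started:
                continue
            if ref_pos >= aln.ref_end:
                break
            coverage[ref_pos] += 1
            if q == r:
                matches[ref_pos] += 1
            ref_pos += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(coverage > 0, matches / np.maximum(coverage, 1), np.nan)
    left, right = ref.primer_lengths
    masked = np.zeros(n, dtype=bool)
    if left:
        masked[:left] = True
    if right:
        masked[n - right :] = True
    return pd.DataFrame(
        {
            "position": np.arange(n),
            "match_freq": freq,
            "coverage": coverage.astype(int),
            "masked": masked,
        }
    )


@dataclass(frozen=True)
class GelGenotype:
    clone_id: str
    bands_bp: tuple[int, ...]
    call: Literal["WT", "monoallelic", "biallelic", "no_call"]


def genotype_from_band_sizes(
    bands_bp: Sequence[int],
    wt_bp: int,
    deletion_sizes_bp: Sequence[int],
    tol_bp: float | None = None,
    clone_id: str = "",
) -> GelGenotype:
    """Size-level genotype call (see :func:`genotype_from_gel` for the rule)."""

    def tol(size: float) -> float:
        return 0.1 * size if tol_bp is None else tol_bp

    bands = [int(b) for b in bands_bp]
    if any(b <= 0 for b in bands):
        raise ValueError("band sizes must be positive")
    if not bands:
        logger.warning("clone %s has an empty band list; no_call", clone_id or "?")
        return GelGenotype(clone_id, (), "no_call")

    has_wt = any(abs(b - wt_bp) <= tol(wt_bp) for b in bands)
    has_del = any(
        any(abs(b - d) <= tol(d) for d in deletion_sizes_bp) for b in bands
    )
    if has_wt and not has_del:
        call = "WT"
    elif has_wt and has_del:
        call = "monoallelic"
    elif has_del:
        call = "biallelic"
    else:
        call = "no_call"
    return GelGenotype(clone_id, tuple(sorted(bands, reverse=True)), call)


def genotype_from_gel(
    bands_bp: Sequence[int],
    designs: "PairedDeletionDesign | Sequence[PairedDeletionDesign]",
    tol_bp: float | None = None,
    clone_id: str = "",
) -> GelGenotype:
    """Call a clone genotype from its gel band sizes.

    A band within tolerance of the full-length amplicon is a WT band; a
    band within tolerance of any design's edited amplicon is a deletion
    band.  Rule: WT band only -> WT; WT band plus at least one deletion
    band -> monoallelic; at least one deletion band and no WT band ->
    biallelic; no recognised band -> no_call.  The default tolerance is
    10% of each predicted size (gel sizing is semi-quantitative);
    unrecognised bands never affect the call.
    """
    if isinstance(designs, PairedDeletionDesign):
        designs = [designs]
    if not designs:
        raise ValueError("at least one paired design is required")
    wt_sizes = {d.wt_amplicon_bp for d in designs}
    if len(wt_sizes) != 1:
        raise ValueError("designs must share one genotyping amplicon")
    wt = wt_sizes.pop()
    del_sizes = sorted({d.edited_amplicon_bp for d in designs})
    return genotype_from_band_sizes(bands_bp, wt, del_sizes, tol_bp, clone_id)


def uniform_length_distribution(lo: int = 1, hi: int = 30) -> dict[int, float]:
    """Uniform distribution over indel lengths lo..hi inclusive."""
    if not 1 <= lo <= hi:
        raise ValueError("need 1 <= lo <= hi")
    n = hi - lo + 1
    return {k: 1.0 / n for k in range(lo, hi + 1)}


def expected_inframe_fraction(length_dist: Mapping[int, float]) -> float:
    """Probability that an indel length drawn from ``length_dist`` is a
    multiple of 3, by exact enumeration over the (finite) support."""
    if not length_dist:
        raise ValueError("length distribution has empty support")
    if any(int(k) < 1 or int(k) != k for k in length_dist):
        raise ValueError("lengths must be positive integers")
    total = float(sum(length_dist.values()))
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError("probabilities must sum to 1")
    return sum(p for k, p in length_dist.items() if int(k) % 3 == 0)
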