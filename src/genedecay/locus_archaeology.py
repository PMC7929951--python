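"""Genomic-scale archaeology of degraded gene loci.

A pseudogene locus is compared to an intact reference locus by seeded
local alignment: exact k-mer anchors are merged along diagonals into
gap-free segments, segments are chained co-linearly, and the chain is
interrogated three ways:

* per-exon presence/absence/partial calls (:func:`detect_exons`),
* splice-site integrity at intron junctions, including the search for a
  rescuing cryptic acceptor (:func:`check_splice_sites`),
* deletion breakpoints, reported with a microhomology ambiguity interval
  because a junction flanked by identical bases can slide
  (:func:`find_breakpoints`).

This mirrors, at desk scale, the practice of localizing ancient deletion
junctions by aligning a decayed locus against an intact ortholog and
recording where homology ends and resumes.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from Bio.Seq import Seq

from .lesion_scanner import HARD, Lesion
from .reference_model import GeneModel

__all__ = [
    "ArchaeologyParams",
    "ChainSegment",
    "LocusChain",
    "Breakpoint",
    "ExonCall",
    "ExonPresence",
    "chain_locus",
    "find_breakpoints",
    "detect_exons",
    "check_splice_sites",
]


@dataclass(frozen=True)
class ArchaeologyParams:
    k: int = 11  # anchor k-mer size
    max_kmer_copies: int = 4  # ignore reference k-mers more repetitive
    max_join_gap: int = 30  # bp; co-diagonal segments closer merge
    max_join_diag: int = 15  # bp; diagonal jitter tolerated within a block
    min_deletion: int = 30  # bp; smaller reference gaps are alignment noise
    min_segment: int = 15  # bp; shorter anchored segments are discarded
    present_fraction: float = 0.80
    partial_fraction: float = 0.20
    cryptic_acceptor_window: int = 100  # bp upstream scanned for a rescue AG


@dataclass(frozen=True)
class ChainSegment:
    """Gap-free aligned segment; 0-based half-open, equal lengths."""

    ref_start: int
    ref_end: int
    q_start: int
    q_end: int

    @property
    def diag(self) -> int:
        return self.ref_start - self.q_start

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start


@dataclass
class LocusChain:
    segments: list[ChainSegment]
    strand: str  # orientation of the query that matched
    whole_locus_lost: bool = False

    def ref_to_query(self, ref_pos: int) -> int | None:
        """Query coordinate aligned to 0-based ``ref_pos``, if covered."""
        for seg in self.segments:
            if seg.ref_start <= ref_pos < seg.ref_end:
                return ref_pos - seg.diag
        return None

    def aligned_ref_length(self) -> int:
        return sum(s.length for s in self.segments)


@dataclass(frozen=True)
class Breakpoint:
    """A reference span absent from the query locus.

    ``left_ref`` is the 1-based reference coordinate of the last base
    before homology ends; ``right_ref`` the first base where it resumes.
    ``ambiguity`` gives how far the junction can slide left/right through
    flanking microhomology; two breakpoints in different species are
    considered the same event when their ambiguity intervals overlap on
    both anchors.
    """

    left_ref: int
    right_ref: int
    query_junction: int
    ambiguity_left: int = 0
    ambiguity_right: int = 0

    @property
    def span(self) -> int:
        return self.right_ref - self.left_ref

    def left_interval(self) -> tuple[int, int]:
        return (self.left_ref - self.ambiguity_left,
                self.left_ref + self.ambiguity_right)

    def right_interval(self) -> tuple[int, int]:
        return (self.right_ref - self.ambiguity_left,
                self.right_ref + self.ambiguity_right)

    def matches(self, other: "Breakpoint") -> bool:
        """Overlapping ambiguity intervals on both anchors."""

        def overlap(a, b):
            return a[0] <= b[1] and b[0] <= a[1]

        return overlap(self.left_interval(), other.left_interval()) and (
            overlap(self.right_interval(), other.right_interval())
        )

    def to_dict(self) -> dict:
        return {
            "left_ref": self.left_ref,
            "right_ref": self.right_ref,
            "span": self.span,
            "query_junction": self.query_junction,
            "ambiguity_left": self.ambiguity_left,
            "ambiguity_right": self.ambiguity_right,
        }


# ---------------------------------------------------------------------------
# anchoring and chaining
# ---------------------------------------------------------------------------


def _anchor_segments(query: str, reference: str, p: ArchaeologyParams):
    """Exact k-mer matches merged along diagonals into segments."""
    k = p.k
    index: dict[str, list[int]] = defaultdict(list)
    for i in range(len(reference) - k + 1):
        index[reference[i:i + k]].append(i)
    # diagonal -> sorted query positions of matches
    diags: dict[int, list[int]] = defaultdict(list)
    for q in range(len(query) - k + 1):
        hits = index.get(query[q:q + k])
        if hits is None or len(hits) > p.max_kmer_copies:
            continue
        for r in hits:
            diags[r - q].append(q)
    segments = []
    for diag, qs in diags.items():
        qs.sort()
        start = prev = qs[0]
        for q in qs[1:]:
            if q - prev <= k:  # overlapping/adjacent anchors: same run
                prev = q
                continue
            segments.append(
                ChainSegment(start + diag, prev + diag + k, start, prev + k)
            )
            start = prev = q
        segments.append(
            ChainSegment(start + diag, prev + diag + k, start, prev + k)
        )
    return [s for s in segments if s.length >= p.min_segment]


def _chain(segments: list[ChainSegment]) -> list[ChainSegment]:
    """Highest-coverage co-linear chain (quadratic DP; deterministic)."""
    segs = sorted(segments, key=lambda s: (s.ref_start, s.q_start))
    n = len(segs)
    if n == 0:
        return []
    best = [s.length for s in segs]
    back = [-1] * n
    slack = 5  # bp of anchor overlap tolerated; trimmed below
    for i in range(n):
        for j in range(i):
            if (
                segs[j].ref_start < segs[i].ref_start
                and segs[j].q_start < segs[i].q_start
                and segs[j].ref_end <= segs[i].ref_start + slack
                and segs[j].q_end <= segs[i].q_start + slack
            ):
                cand = best[j] + segs[i].length
                if cand > best[i]:
                    best[i] = cand
                    back[i] = j
    end = max(range(n), key=lambda i: best[i])
    chain = []
    while end != -1:
        chain.append(segs[end])
        end = back[end]
    chain.reverse()
    # trim residual overlaps between consecutive segments
    trimmed: list[ChainSegment] = []
    for seg in chain:
        if trimmed:
            prev = trimmed[-1]
            cut = max(prev.ref_end - seg.ref_start, prev.q_end - seg.q_start)
            if cut > 0:
                if seg.length - cut <= 0:
                    continue
                seg = ChainSegment(
                    seg.ref_start + cut, seg.ref_end,
                    seg.q_start + cut, seg.q_end,
                )
        trimmed.append(seg)
    return trimmed


def _extend_segments(
    segments: list[ChainSegment],
    query: str,
    reference: str,
    xdrop: int = 6,
) -> list[ChainSegment]:
    """Extend segment ends through isolated mismatches (x-drop rule).

    Gap-free extension scoring +1/match, -2/mismatch; extension stops
    when the running score falls ``xdrop`` below its best, and the end is
    cut back to the best-scoring position.  Isolated background
    substitutions are crossed; at a true breakpoint junction homology
    decays to random matching and extension halts within a few bases.
    """

    def extend(r: int, q: int, limit_r: int, limit_q: int, step: int):
        best, score, best_off = 0, 0, 0
        off = 0
        while True:
            nr, nq = r + step * (off + 1), q + step * (off + 1)
            if step > 0 and (nr > limit_r or nq > limit_q):
                break
            if step < 0 and (nr < limit_r or nq < limit_q):
                break
            probe_r = nr - 1 if step > 0 else nr
            probe_q = nq - 1 if step > 0 else nq
            score += 1 if reference[probe_r] == query[probe_q] else -2
            off += 1
            if score > best:
                best, best_off = score, off
            elif best - score > xdrop:
                break
        return best_off

    out = []
    for idx, seg in enumerate(segments):
        rs, re_, qs, qe = seg.ref_start, seg.ref_end, seg.q_start, seg.q_end
        lo_r = segments[idx - 1].ref_end if idx else 0
        lo_q = segments[idx - 1].q_end if idx else 0
        back = extend(rs, qs, lo_r, lo_q, step=-1)
        rs, qs = rs - back, qs - back
        hi_r = (
            segments[idx + 1].ref_start
            if idx + 1 < len(segments)
            else len(reference)
        )
        hi_q = (
            segments[idx + 1].q_start
            if idx + 1 < len(segments)
            else len(query)
        )
        fwd = extend(re_, qe, hi_r, hi_q, step=1)
        out.append(ChainSegment(rs, re_ + fwd, qs, qe + fwd))
    return out


def _merge_blocks(
    segments: list[ChainSegment], p: ArchaeologyParams
) -> list[ChainSegment]:
    """Merge near-co-diagonal neighbours so small indels don't split blocks."""
    merged: list[ChainSegment] = []
    for seg in segments:
        if merged:
            prev = merged[-1]
            ref_gap = seg.ref_start - prev.ref_end
            q_gap = seg.q_start - prev.q_end
            if (
                0 <= ref_gap <= p.max_join_gap
                and 0 <= q_gap <= p.max_join_gap
                and abs(seg.diag - prev.diag) <= p.max_join_diag
            ):
                merged[-1] = ChainSegment(
                    prev.ref_start, seg.ref_end, prev.q_start, seg.q_end
                )
                continue
        merged.append(seg)
    return merged


def chain_locus(
    query: str,
    reference: str,
    params: ArchaeologyParams | None = None,
) -> LocusChain:
    """Anchor, chain and extend; auto-detects query orientation."""
    p = params or ArchaeologyParams()
    query, reference = query.upper(), reference.upper()
    candidates = []
    for strand, qseq in (
        ("+", query),
        ("-", str(Seq(query).reverse_complement())),
    ):
        segs = _chain(_anchor_segments(qseq, reference, p))
        candidates.append((sum(s.length for s in segs), strand, qseq, segs))
    total, strand, qseq, segs = max(candidates, key=lambda c: (c[0], c[1]))
    if total == 0:
        return LocusChain(segments=[], strand="+", whole_locus_lost=True)
    segs = _merge_blocks(_extend_segments(segs, qseq, reference), p)
    return LocusChain(segments=segs, strand=strand)


# ---------------------------------------------------------------------------
# breakpoints
# ---------------------------------------------------------------------------


def _microhomology(reference: str, L: int, R: int) -> tuple[int, int]:
    """How far a deletion junction ref[L:R) can slide left/right."""
    left = 0
    while L - 1 - left >= 0 and R - 1 - left >= 0 and (
        reference[L - 1 - left] == reference[R - 1 - left]
    ):
        left += 1
    right = 0
    while R + right < len(reference) and L + right < len(reference) and (
        reference[L + right] == reference[R + right]
    ):
        right += 1
    return left, right


def find_breakpoints(
    query: str,
    reference: str,
    params: ArchaeologyParams | None = None,
) -> tuple[list[Breakpoint], LocusChain]:
    """Deletion breakpoints: reference gaps between adjacent chain blocks."""
    p = params or ArchaeologyParams()
    chain = chain_locus(query, reference, p)
    breakpoints = []
    for prev, nxt in zip(chain.segments, chain.segments[1:]):
        ref_gap = nxt.ref_start - prev.ref_end
        q_gap = nxt.q_start - prev.q_end
        if ref_gap - max(q_gap, 0) < p.min_deletion:
            continue
        L, R = prev.ref_end, nxt.ref_start  # 0-based: deleted ref[L:R)
        amb_left, amb_right = _microhomology(reference.upper(), L, R)
        breakpoints.append(
            Breakpoint(
                left_ref=L,  # 1-based last homologous base == 0-based L
                right_ref=R + 1,
                query_junction=prev.q_end + 1,
                ambiguity_left=amb_left,
                ambiguity_right=amb_right,
            )
        )
    return breakpoints, chain


# ---------------------------------------------------------------------------
# exon presence
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExonCall:
    index: int
    state: str  # present | partial | absent
    matched_bp: int
    exon_bp: int
    identity: float  # percent identity over matched positions

    @property
    def matched_fraction(self) -> float:
        return self.matched_bp / self.exon_bp


@dataclass
class ExonPresence:
    calls: list[ExonCall]
    strand: str
    whole_locus_lost: bool = False

    def states(self) -> dict[int, str]:
        return {c.index: c.state for c in self.calls}

    def absent_exons(self) -> list[int]:
        return [c.index for c in self.calls if c.state == "absent"]


def detect_exons(
    genomic_query: str,
    model: GeneModel,
    reference_locus: str,
    params: ArchaeologyParams | None = None,
    chain: LocusChain | None = None,
) -> ExonPresence:
    """Assign present/partial/absent to each model exon on the query locus."""
    p = params or ArchaeologyParams()
    if chain is None:
        chain = chain_locus(genomic_query, reference_locus, p)
    reference_locus = reference_locus.upper()
    qseq = (
        genomic_query.upper()
        if chain.strand == "+"
        else str(Seq(genomic_query.upper()).reverse_complement())
    )
    calls = []
    for exon in model.exons:
        matched = 0
        identical = 0
        for seg in chain.segments:
            lo = max(exon.start, seg.ref_start)
            hi = min(exon.end, seg.ref_end)
            if lo >= hi:
                continue
            matched += hi - lo
            off = seg.q_start - seg.ref_start
            for r in range(lo, hi):
                if reference_locus[r] == qseq[r + off]:
                    identical += 1
        frac = matched / exon.length
        if frac >= p.present_fraction:
            state = "present"
        elif frac >= p.partial_fraction:
            state = "partial"
        else:
            state = "absent"
        calls.append(
            ExonCall(
                index=exon.index,
                state=state,
                matched_bp=matched,
                exon_bp=exon.length,
                identity=100.0 * identical / matched if matched else 0.0,
            )
        )
    return ExonPresence(
        calls=calls, strand=chain.strand,
        whole_locus_lost=chain.whole_locus_lost,
    )


# ---------------------------------------------------------------------------
# splice sites
# ---------------------------------------------------------------------------


def check_splice_sites(
    genomic_query: str,
    model: GeneModel,
    reference_locus: str,
    params: ArchaeologyParams | None = None,
    chain: LocusChain | None = None,
    presence: ExonPresence | None = None,
) -> tuple[list[Lesion], list[dict]]:
    """Check donor (GT) and acceptor (AG) dinucleotides at each intron.

    Returns inactivating ``splice_disruption`` lesions plus a full report
    row per site (including sites whose flank is missing, reported as
    ``unknown`` rather than disrupted).  A disrupted acceptor triggers a
    scan for a rescuing cryptic AG within ``cryptic_acceptor_window`` bp
    upstream; the implied 5' exon extension length is recorded.
    """
    p = params or ArchaeologyParams()
    if chain is None:
        chain = chain_locus(genomic_query, reference_locus, p)
    if presence is None:
        presence = detect_exons(
            genomic_query, model, reference_locus, p, chain=chain
        )
    qseq = (
        genomic_query.upper()
        if chain.strand == "+"
        else str(Seq(genomic_query.upper()).reverse_complement())
    )
    states = presence.states()
    offsets = model.exon_cds_offsets()
    lesions: list[Lesion] = []
    report: list[dict] = []

    def query_dinuc(site: str, exon_edge_ref: int) -> str | None:
        """Junction dinucleotide read off the query, anchored at the
        aligned exon edge (the intron bases themselves may be unaligned
        precisely because they are mutated)."""
        a = chain.ref_to_query(exon_edge_ref)
        if a is None:
            return None
        if site == "donor":
            dinuc = qseq[a + 1:a + 3]
        else:
            dinuc = qseq[max(0, a - 2):a]
        return dinuc if len(dinuc) == 2 else None

    for intron_idx, (exon, nxt) in enumerate(
        zip(model.exons, model.exons[1:]), start=1
    ):
        for site, edge_ref, expected, exon_needed in (
            ("donor", exon.end - 1, "GT", exon.index),
            ("acceptor", nxt.start, "AG", nxt.index),
        ):
            row = {
                "intron": intron_idx,
                "site": site,
                "expected": expected,
                "observed": None,
                "status": "unknown",
                "extension_bp": None,
            }
            if states.get(exon_needed) == "absent":
                report.append(row)
                continue
            observed = query_dinuc(site, edge_ref)
            row["observed"] = observed
            if observed is None:
                report.append(row)
                continue
            if observed == expected:
                row["status"] = "canonical"
                report.append(row)
                continue
            row["status"] = "disrupted"
            note = f"intron {intron_idx} {site} {expected}>{observed}"
            if site == "acceptor":
                ext = _cryptic_acceptor_extension(
                    qseq, chain, nxt.start, p.cryptic_acceptor_window
                )
                if ext is not None:
                    row["extension_bp"] = ext
                    note += f"; cryptic acceptor implies {ext}-bp exon extension"
            # anchor the lesion at the adjacent exon boundary in CDS bp
            cds_bp = (
                offsets[exon.index - 1][1]
                if site == "donor"
                else offsets[nxt.index - 1][0] + 1
            )
            lesions.append(
                Lesion(
                    "splice_disruption",
                    max(1, cds_bp),
                    max(1, cds_bp),
                    f"{expected}>{observed}",
                    HARD,
                    note=note,
                )
            )
            report.append(row)
    return lesions, report


def _cryptic_acceptor_extension(
    qseq: str, chain: LocusChain, exon_ref_start: int, window: int
) -> int | None:
    """Distance from the nearest upstream AG to the ancestral exon start."""
    q_start = chain.ref_to_query(exon_ref_start)
    if q_start is None:
        return None
    lo = max(0, q_start - 2 - window)
    for pos in range(q_start - 3, lo - 1, -1):
        if qseq[pos:pos + 2] == "AG":
            return q_start - (pos + 2)
    return None
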