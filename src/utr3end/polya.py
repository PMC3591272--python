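"""Map 3' RACE reads to cloned constructs and call cleavage-site profiles.

A 3' RACE read is primed from the poly(A) tail, so on the sequenced strand it
carries a 12-nt random UMI, a poly(T) block, and then the reverse complement
of the transcript's 3' end.  The junction between the poly(T) and the mapped
genomic sequence is the cleavage site; genomic A's adjacent to the true site
are indistinguishable from the tail, so calls resolve to the first non-A
nucleotide at or upstream of the real site.

The reference here is tiny (at most ~100 cloned sequences of <= 1 kb), so
mapping uses a built-in exact 15-mer seed index over both strands with
ungapped extension allowing up to 2 mismatches.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io import CleavageProfile, Construct, ValidationError

__all__ = [
    "TrimmedRead",
    "ReadRejected",
    "MapHit",
    "ReferenceIndex",
    "trim_race_read",
    "map_read",
    "call_cleavage_position",
    "build_cleavage_profile",
    "PolyAResult",
    "process_race_reads",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_UMI_LEN = 12


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class TrimmedRead:
    """A read reduced to its mappable part, in genomic orientation."""

    read_id: str
    umi: str
    insert: str
    tail_len: int


class ReadRejected(ValueError):
    """A read failed trimming/mapping; ``reason`` is a short machine tag."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


# ---------------------------------------------------------------------------
# Trimming
# ---------------------------------------------------------------------------


def trim_race_read(
    read_id: str, sequence: str, min_tail: int = 8, min_insert: int = 20
) -> TrimmedRead:
    """Strip the UMI and poly(T) block and return the genomic-orientation insert.

    The 12-nt UMI is positional; the following T-run is extended greedily,
    tolerating one mismatch per 10 nt of tail — but only inside the first 18
    nt, the stretch the poly(T) primer itself guarantees, and only when the
    mismatch is immediately followed by three more T's.  Beyond 18 nt every T
    is potentially a genomic A read through in reverse complement, so the run
    extends over literal T's only and the poly(T)/genome junction is never
    chewed into upstream sequence.  The remainder is reverse-complemented
    into genomic orientation.  Raises :class:`ReadRejected` with reason
    ``"too_short"`` or ``"no_tail"``.
    """
    seq = sequence.upper()
    if len(seq) < _UMI_LEN + min_tail + min_insert:
        raise ReadRejected("too_short", f"{read_id}: length {len(seq)}")
    umi = seq[:_UMI_LEN]
    i = _UMI_LEN
    mismatches = 0
    last_t = i - 1  # index of the last T seen inside the run
    while i < len(seq):
        if seq[i] == "T":
            last_t = i
        else:
            run = i - _UMI_LEN
            if (
                run >= 18
                or mismatches + 1 > run // 10
                or seq[i + 1: i + 4] != "TTT"
            ):
                break
            mismatches += 1
        i += 1
    tail_end = last_t + 1  # run ends on its last T
    tail_len = tail_end - _UMI_LEN
    if tail_len < min_tail:
        raise ReadRejected("no_tail", f"{read_id}: T-run of {tail_len} < {min_tail}")
    insert = _revcomp(seq[tail_end:])
    if len(insert) < min_insert:
        raise ReadRejected("too_short", f"{read_id}: insert of {len(insert)} nt")
    return TrimmedRead(read_id=read_id, umi=umi, insert=insert, tail_len=tail_len)


# ---------------------------------------------------------------------------
# Mapping
# ---------------------------------------------------------------------------


@dataclass
class MapHit:
    gene_id: str
    #: 0-based offset of the 3'-most aligned base on the construct.
    end_offset: int
    mismatches: int
    strand: str = "+"


class ReferenceIndex:
    """Exact k-mer seed index over both strands of a small construct set."""

    def __init__(self, constructs: Sequence[Construct], k: int = 15):
        if not constructs:
            raise ValidationError("empty reference")
        self.k = k
        self.sequences = {c.gene_id: c.sequence for c in constructs}
        self._seeds: dict[str, list[tuple[str, int, str]]] = defaultdict(list)
        for gene, seq in self.sequences.items():
            for strand, s in (("+", seq), ("-", _revcomp(seq))):
                for pos in range(len(s) - k + 1):
                    self._seeds[s[pos: pos + k]].append((gene, pos, strand))

    def candidates(self, insert: str) -> set[tuple[str, int, str]]:
        """Candidate (gene, insert-start-on-strand, strand) placements.

        Seeds are taken at three non-overlapping offsets (0, k, 2k), so any
        placement with <= 2 mismatches on an insert of >= 3k nt is guaranteed
        to be found (pigeonhole).
        """
        found = set()
        for off in (0, self.k, 2 * self.k):
            if off + self.k > len(insert):
                break
            for gene, pos, strand in self._seeds.get(insert[off: off + self.k], ()):
                start = pos - off
                if start >= 0:
                    found.add((gene, start, strand))
        return found


def _count_mismatches(a: str, b: str, limit: int) -> int:
    if a == b:
        return 0
    n = 0
    for x, y in zip(a, b):
        if x != y:
            n += 1
            if n > limit:
                return n
    return n


def map_read(
    insert: str,
    index: ReferenceIndex,
    max_mismatches: int = 2,
    uniqueness_margin: int = 2,
) -> MapHit:
    """Place an insert on the construct reference.

    The unique best placement with at most ``max_mismatches`` wins, provided
    no second placement comes within ``uniqueness_margin`` mismatches of it;
    otherwise the read is rejected (:class:`ReadRejected` with reason
    ``"ambiguous"``, ``"unmatched"`` or ``"reverse_strand"``).  The reported
    offset is the 0-based position of the 3'-most aligned base.
    """
    hits = []
    for gene, start, strand in index.candidates(insert):
        strand_seq = index.sequences[gene]
        if strand == "-":
            strand_seq = _revcomp(strand_seq)
        segment = strand_seq[start: start + len(insert)]
        if len(segment) < len(insert):
            continue
        mm = _count_mismatches(insert, segment, max_mismatches)
        if mm <= max_mismatches:
            hits.append((mm, gene, start, strand))
    if not hits:
        raise ReadRejected("unmatched")
    hits.sort(key=lambda h: h[0])
    best = hits[0]
    if len(hits) > 1 and hits[1][0] - best[0] < uniqueness_margin:
        raise ReadRejected("ambiguous")
    mm, gene, start, strand = best
    if strand == "-":
        # 3' RACE inserts are genomic-orientation by construction; a
        # reverse-strand placement cannot yield a cleavage call.
        raise ReadRejected("reverse_strand")
    return MapHit(gene_id=gene, end_offset=start + len(insert) - 1, mismatches=mm)


# ---------------------------------------------------------------------------
# Cleavage-site calling
# ---------------------------------------------------------------------------


def call_cleavage_position(end_offset: int, reference_seq: str) -> int:
    """Resolve the poly(T)/genome junction to the first non-A position.

    Trimming absorbs genomic A's at the junction into the tail, so the mapped
    3' end is by construction the first non-A at or upstream of the true
    cleavage site; this walks upstream over any remaining A's and asserts the
    returned base is not an A.  Raises :class:`ReadRejected`
    (``"a_run_unresolvable"``) if the entire upstream context is A's.
    """
    if not 0 <= end_offset < len(reference_seq):
        raise ValidationError(f"end_offset {end_offset} outside reference")
    p = end_offset
    while p >= 0 and reference_seq[p] == "A":
        p -= 1
    if p < 0:
        raise ReadRejected("a_run_unresolvable")
    assert reference_seq[p] != "A"
    return p


# ---------------------------------------------------------------------------
# Profiles and the full pipeline
# ---------------------------------------------------------------------------


def build_cleavage_profile(
    calls: Iterable[tuple],
    depth_threshold: int = 1000,
    dedupe: bool = False,
) -> list[CleavageProfile]:
    """Histogram (gene, position) calls into per-gene cleavage profiles.

    ``calls`` holds (gene, position) or (gene, position, umi) tuples.  With
    ``dedupe`` identical (gene, umi, position) triples collapse to one count
    before histogramming.  ``passes_depth`` uses a strict ``>`` against
    ``depth_threshold``.  Genes failing depth are retained but flagged.
    """
    calls = list(calls)
    if not calls:
        raise ValidationError("no cleavage calls to histogram")
    if dedupe:
        calls = list({(c[0], c[1], c[2] if len(c) > 2 else None) for c in calls})
    per_gene: dict[str, Counter] = defaultdict(Counter)
    for call in calls:
        per_gene[call[0]][int(call[1])] += 1
    return [
        CleavageProfile.from_counts(gene, counts, depth_threshold)
        for gene, counts in sorted(per_gene.items())
    ]


@dataclass
class PolyAResult:
    profiles: list[CleavageProfile]
    rejections: Counter
    n_reads: int
    n_mapped: int

    @property
    def mapped_fraction(self) -> float:
        return self.n_mapped / self.n_reads if self.n_reads else 0.0

    def summary(self) -> dict:
        return {
            "n_reads": self.n_reads,
            "n_mapped": self.n_mapped,
            "mapped_pct": 100.0 * self.mapped_fraction,
            "rejected_pct": 100.0 * (1 - self.mapped_fraction),
            "rejections": dict(self.rejections),
            "genes_passing_depth": sum(p.passes_depth for p in self.profiles),
        }


def process_race_reads(
    reads: Iterable[tuple[str, str]],
    constructs: Sequence[Construct],
    *,
    min_tail: int = 8,
    min_insert: int = 20,
    max_mismatches: int = 2,
    depth_threshold: int = 1000,
    dedupe: bool = False,
) -> PolyAResult:
    """Full pipeline: trim, map, call and histogram a set of RACE reads.

    ``reads`` yields (read_id, sequence) pairs.  Every rejection is counted
    by reason; the sum of profile counts equals the number of reads that
    survived all three stages (each read is counted exactly once).
    """
    index = ReferenceIndex(constructs)
    rejections: Counter = Counter()
    calls = []
    n_reads = 0
    for read_id, sequence in reads:
        n_reads += 1
        try:
            trimmed = trim_race_read(read_id, sequence, min_tail, min_insert)
            hit = map_read(trimmed.insert, index, max_mismatches)
            pos = call_cleavage_position(hit.end_offset, index.sequences[hit.gene_id])
        except ReadRejected as rej:
            rejections[rej.reason] += 1
            continue
        calls.append((hit.gene_id, pos, trimmed.umi))
    profiles = (
        build_cleavage_profile(calls, depth_threshold, dedupe) if calls else []
    )
    return PolyAResult(
        profiles=profiles,
        rejections=rejections,
        n_reads=n_reads,
        n_mapped=len(calls),
    )
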