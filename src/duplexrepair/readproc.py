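"""Per-read annotation: sample, UMI, strand identity and junction call.

The stages mirror the order of the wet protocol: demultiplex by the 6-nt
sample barcode (phasing-tolerant), locate the adapter flank to pull out the
UMI, read the 5-nt strand-ID variant to decide which physical strand the
read came from, and finally match the read against the enumerated junction
references by bounded edit distance.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

from ._edit import bounded_infix_distance
from .dna import hamming, is_dna, revcomp
from .simulate import DEFAULT_ADAPTER_FLANK
from .substrate import ExpectedProductSet, SubstrateSpec

UNDETERMINED = "undetermined"
UNCLASSIFIED = "unclassified"


class ReadRecord(NamedTuple):
    read_id: str
    sequence: str
    qualities: str
    sample: Optional[str] = None


class JunctionCall(NamedTuple):
    label: str
    edit_distance: int
    matched_window: Optional[Tuple[int, int]] = None


class AnnotatedRead(NamedTuple):
    read_id: str
    sample: Optional[str]
    umi: str
    strand: str  # top / bottom / undetermined
    label: str
    edit_distance: int


@dataclass(frozen=True)
class AdapterSpec:
    """UMI length plus the constant sequence immediately 3' of the UMI."""

    umi_length: int = 10
    flank: str = DEFAULT_ADAPTER_FLANK


DEFAULT_ADAPTER = AdapterSpec()


# ---------------------------------------------------------------------------
# demultiplexing

def validate_barcode_table(barcode_table: Dict[str, str], max_mismatch: int) -> None:
    """Reject ambiguous tables up front (min pairwise distance must exceed 2k)."""
    barcodes = list(barcode_table.items())
    if not barcodes:
        raise ValueError("empty barcode table")
    lengths = {len(b) for _, b in barcodes}
    if len(lengths) != 1:
        raise ValueError("barcodes must all have the same length")
    for label, b in barcodes:
        if not is_dna(b):
            raise ValueError(f"barcode {label!r} contains non-ACGT characters")
    for i, (la, a) in enumerate(barcodes):
        for lb, b in barcodes[i + 1:]:
            d = hamming(a, b)
            if d <= 2 * max_mismatch:
                raise ValueError(
                    f"ambiguous barcode table: {la!r} and {lb!r} are "
                    f"Hamming distance {d} apart (need > {2 * max_mismatch})"
                )


class Demultiplexer:
    """Phasing-tolerant barcode assignment over the first len+5 positions."""

    def __init__(self, barcode_table: Dict[str, str], max_mismatch: int = 1,
                 max_phasing: int = 5):
        validate_barcode_table(barcode_table, max_mismatch)
        self.barcode_table = dict(barcode_table)
        self.by_barcode = {b: label for label, b in barcode_table.items()}
        self.length = len(next(iter(self.by_barcode)))
        self.max_mismatch = max_mismatch
        self.max_phasing = max_phasing

    def assign(self, sequence: str) -> Optional[str]:
        blen = self.length
        exact = self.by_barcode
        for offset in range(self.max_phasing + 1):
            candidate = sequence[offset:offset + blen]
            if len(candidate) < blen:
                break
            label = exact.get(candidate)
            if label is not None:
                return label
        if self.max_mismatch == 0:
            return None
        for offset in range(self.max_phasing + 1):
            candidate = sequence[offset:offset + blen]
            if len(candidate) < blen:
                break
            for barcode, label in exact.items():
                if hamming(candidate, barcode) <= self.max_mismatch:
                    return label
        return None


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_table: Dict[str, str],
    max_mismatch: int = 1,
    max_phasing: int = 5,
) -> List[ReadRecord]:
    """Annotate each read with its sample; unassignable reads get 'undetermined'."""
    demux = Demultiplexer(barcode_table, max_mismatch, max_phasing)
    out = []
    for read in reads:
        label = demux.assign(read.sequence)
        out.append(read._replace(sample=label if label is not None else UNDETERMINED))
    return out


# ---------------------------------------------------------------------------
# pair merging

def merge_pairs(
    read1: ReadRecord,
    read2: ReadRecord,
    min_overlap: int = 20,
    max_mismatch_rate: float = 0.1,
) -> Optional[ReadRecord]:
    """Merge inward-facing mates on their best suffix/prefix overlap.

    The overlap minimising the mismatch rate (ties to the longer overlap)
    wins; disagreeing bases are resolved toward the higher quality score.
    Returns None when no overlap of at least ``min_overlap`` passes the
    mismatch-rate ceiling.
    """
    seq2 = revcomp(read2.sequence)
    qual2 = read2.qualities[::-1]
    best: Optional[Tuple[float, int]] = None
    limit = min(len(read1.sequence), len(seq2))
    for overlap in range(min_overlap, limit + 1):
        tail = read1.sequence[-overlap:]
        head = seq2[:overlap]
        mismatches = sum(a != b for a, b in zip(tail, head))
        rate = mismatches / overlap
        if rate <= max_mismatch_rate and (best is None or rate < best[0]
                                          or (rate == best[0] and overlap > best[1])):
            best = (rate, overlap)
    if best is None:
        return None
    overlap = best[1]
    left_seq = read1.sequence[:-overlap] if overlap else read1.sequence
    left_qual = read1.qualities[:-overlap] if overlap else read1.qualities
    merged_seq = []
    merged_qual = []
    q1 = read1.qualities[-overlap:]
    s1 = read1.sequence[-overlap:]
    for i in range(overlap):
        if s1[i] == seq2[i] or q1[i] >= qual2[i]:
            merged_seq.append(s1[i])
            merged_qual.append(max(q1[i], qual2[i]))
        else:
            merged_seq.append(seq2[i])
            merged_qual.append(qual2[i])
    return ReadRecord(
        read_id=read1.read_id,
        sequence=left_seq + "".join(merged_seq) + seq2[overlap:],
        qualities=left_qual + "".join(merged_qual) + qual2[overlap:],
        sample=read1.sample,
    )


# ---------------------------------------------------------------------------
# UMI extraction

def _find_with_one_mismatch(text: str, pattern: str) -> int:
    """Leftmost occurrence of pattern in text with at most one substitution."""
    pos = text.find(pattern)
    if pos != -1:
        return pos
    m = len(pattern)
    for start in range(len(text) - m + 1):
        mismatches = 0
        for a, b in zip(pattern, text[start:start + m]):
            if a != b:
                mismatches += 1
                if mismatches > 1:
                    break
        else:
            return start
    return -1


def extract_umi(read: ReadRecord, adapter: AdapterSpec = DEFAULT_ADAPTER,
                ) -> Optional[Tuple[str, str]]:
    """(umi, insert) from the adapter flank position, or None if not locatable."""
    seq = read.sequence
    pos = _find_with_one_mismatch(seq, adapter.flank)
    if pos < adapter.umi_length:
        return None
    umi = seq[pos - adapter.umi_length:pos]
    insert = seq[pos + len(adapter.flank):]
    return umi, insert


# ---------------------------------------------------------------------------
# strand assignment

class StrandAssigner:
    """Decide top/bottom from the 5-nt strand-ID variant.

    The locus is located by its constant flanking sequence in either the
    top-sense or bottom-sense orientation; the observed variant is then
    compared by Hamming distance to both expected variants in that frame.
    The winner needs distance <= ``max_best`` and a margin of at least
    ``min_margin`` over the loser, so on fully mismatched variants a single
    sequencing error can never flip the call.
    """

    FLANK = 6

    def __init__(self, spec: SubstrateSpec, max_best: int = 1, min_margin: int = 2):
        self.max_best = max_best
        self.min_margin = min_margin
        sid = spec.strand_id
        self.var_len = sid.length

        t_lo, t_hi = spec.strand_id_interval("top")
        b_lo, b_hi = spec.strand_id_interval("bottom")
        f = self.FLANK
        if t_lo < f or t_hi + f > len(spec.top_seq):
            raise ValueError("strand-ID region too close to a strand end for "
                             f"{f}-nt locator flanks")
        self.top_left = spec.top_seq[t_lo - f:t_lo]
        self.top_right = spec.top_seq[t_hi:t_hi + f]
        self.bottom_left = spec.bottom_seq[b_lo - f:b_lo]
        self.bottom_right = spec.bottom_seq[b_hi:b_hi + f]
        # candidate variants per located frame
        self.top_frame = {"top": sid.top_variant, "bottom": revcomp(sid.bottom_variant)}
        self.bottom_frame = {"bottom": sid.bottom_variant, "top": revcomp(sid.top_variant)}

    def _locate(self, insert: str, left: str, right: str) -> Optional[str]:
        f = self.FLANK
        v = self.var_len
        pos = insert.find(left)
        while pos != -1:
            obs_start = pos + f
            if insert[obs_start + v:obs_start + v + f] == right:
                return insert[obs_start:obs_start + v]
            pos = insert.find(left, pos + 1)
        # mismatch-tolerant scan: one substitution allowed across both flanks
        span = f + v + f
        for start in range(len(insert) - span + 1):
            window = insert[start:start + span]
            mismatches = 0
            for a, b in zip(left, window[:f]):
                if a != b:
                    mismatches += 1
            if mismatches > 1:
                continue
            for a, b in zip(right, window[f + v:]):
                if a != b:
                    mismatches += 1
                    if mismatches > 1:
                        break
            if mismatches <= 1:
                return window[f:f + v]
        return None

    def assign(self, insert: str) -> str:
        obs = self._locate(insert, self.top_left, self.top_right)
        frame = self.top_frame
        if obs is None:
            obs = self._locate(insert, self.bottom_left, self.bottom_right)
            frame = self.bottom_frame
        if obs is None or len(obs) != self.var_len:
            return UNDETERMINED
        distances = {strand: hamming(obs, variant) for strand, variant in frame.items()}
        (s1, d1), (s2, d2) = sorted(distances.items(), key=lambda kv: kv[1])
        if d1 <= self.max_best and d2 - d1 >= self.min_margin:
            return s1
        return UNDETERMINED


def assign_strand(insert: str, spec: SubstrateSpec, max_best: int = 1,
                  min_margin: int = 2) -> str:
    return StrandAssigner(spec, max_best, min_margin).assign(insert)


# ---------------------------------------------------------------------------
# junction classification

class JunctionClassifier:
    """Bounded edit-distance matching against the enumerated references.

    A read is labelled with the unique best-matching reference window at
    distance <= ``max_edit``.  Ties between references with identical
    windows (declared degenerate) collapse to a canonical joint label
    ("a|b"); ties between distinguishable references are unclassifiable.
    """

    def __init__(self, products: ExpectedProductSet, strand: str, max_edit: int = 1):
        self.max_edit = max_edit
        self.strand = strand
        self.windows = dict(products.windows[strand])
        self.labels = list(self.windows)
        self._groups = {
            frozenset(g) for g in products.degenerate_groups(strand)
        }

    def _resolve(self, candidates: List[str], distance: int,
                 span: Optional[Tuple[int, int]]) -> JunctionCall:
        if len(candidates) == 1:
            return JunctionCall(candidates[0], distance, span)
        group = frozenset(candidates)
        for declared in self._groups:
            if group <= declared:
                return JunctionCall("|".join(sorted(group)), distance, span)
        return JunctionCall(UNCLASSIFIED, distance, None)

    def classify(self, insert: str) -> JunctionCall:
        # exact-substring fast path: nothing can beat distance 0
        exact: List[str] = []
        exact_span = None
        for label in self.labels:
            pos = insert.find(self.windows[label])
            if pos != -1:
                exact.append(label)
                exact_span = (pos, pos + len(self.windows[label]))
        if exact:
            return self._resolve(exact, 0, exact_span)

        best = self.max_edit + 1
        best_labels: List[str] = []
        best_span = None
        for label in self.labels:
            d, span = bounded_infix_distance(self.windows[label], insert,
                                             self.max_edit)
            if d < best:
                best = d
                best_labels = [label]
                best_span = span
            elif d == best:
                best_labels.append(label)
        if best > self.max_edit:
            return JunctionCall(UNCLASSIFIED, best, None)
        return self._resolve(best_labels, best, best_span)


def call_junction(insert: str, strand: str, products: ExpectedProductSet,
                  max_edit: int = 1) -> JunctionCall:
    if strand not in ("top", "bottom"):
        raise ValueError("strand must be 'top' or 'bottom'")
    return JunctionClassifier(products, strand, max_edit).classify(insert)


# ---------------------------------------------------------------------------
# full annotation pipeline

@dataclass
class AnnotationStats:
    """Per-stage read accounting for the run log."""

    n_input: int = 0
    n_sample_undetermined: int = 0
    n_adapter_not_found: int = 0
    n_strand_undetermined: int = 0
    n_unclassified: int = 0
    n_annotated: int = 0
    samples: Counter = field(default_factory=Counter)

    def as_dict(self) -> Dict:
        d = {k: getattr(self, k) for k in (
            "n_input", "n_sample_undetermined", "n_adapter_not_found",
            "n_strand_undetermined", "n_unclassified", "n_annotated")}
        d["samples"] = dict(self.samples)
        return d


def annotate_reads(
    records: Iterable[Tuple[str, str, str]],
    spec: SubstrateSpec,
    products: ExpectedProductSet,
    barcode_table: Dict[str, str],
    *,
    adapter: AdapterSpec = DEFAULT_ADAPTER,
    max_mismatch: int = 1,
    max_phasing: int = 5,
    max_edit: int = 1,
) -> Tuple[List[AnnotatedRead], AnnotationStats]:
    """Run all per-read stages over (read_id, sequence, quality) records.

    Reads whose adapter flank cannot be located are dropped (counted);
    everything else is kept, with 'undetermined' / 'unclassified' markers
    where a stage could not decide.
    """
    demux = Demultiplexer(barcode_table, max_mismatch, max_phasing)
    assigner = StrandAssigner(spec)
    classifiers = {
        "top": JunctionClassifier(products, "top", max_edit),
        "bottom": JunctionClassifier(products, "bottom", max_edit),
    }
    stats = AnnotationStats()
    out: List[AnnotatedRead] = []
    for read_id, sequence, _qual in records:
        stats.n_input += 1
        sample = demux.assign(sequence)
        if sample is None:
            sample = UNDETERMINED
            stats.n_sample_undetermined += 1
        stats.samples[sample] += 1
        extracted = extract_umi(ReadRecord(read_id, sequence, ""), adapter)
        if extracted is None:
            stats.n_adapter_not_found += 1
            continue
        umi, insert = extracted
        strand = assigner.assign(insert)
        if strand == UNDETERMINED:
            stats.n_strand_undetermined += 1
            out.append(AnnotatedRead(read_id, sample, umi, strand, UNCLASSIFIED, -1))
            continue
        call = classifiers[strand].classify(insert)
        if call.label == UNCLASSIFIED:
            stats.n_unclassified += 1
        stats.n_annotated += 1
        out.append(AnnotatedRead(read_id, sample, umi, strand, call.label,
                                 call.edit_distance))
    return out, stats
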