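"""Designed double-strand-break substrates and their expected repair products.

A substrate is a linear duplex drawn with the top strand 5'->3' left to
right.  The left end is the *head*, the right end the *tail*; repair joins
substrate molecules head-to-tail, so each strand's junction is formed
between its own 3' terminus (tail side) and 5' terminus (head side).  A
short fully mismatched duplex region (the *strand ID*) identifies which
physical strand a sequencing read came from.

Both strand sequences are stored 5'->3'.  Top-strand index ``t`` pairs with
bottom-strand index ``b = R - t`` where ``R`` depends only on the tail end
structure (see :meth:`SubstrateSpec.pairing_offset`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

from .dna import is_dna, revcomp

FIVE_PRIME = "five_prime_overhang"
THREE_PRIME = "three_prime_overhang"
BLUNT = "blunt"
_POLARITIES = (FIVE_PRIME, THREE_PRIME, BLUNT)

#: maximum designed overhang length
MAX_OVERHANG = 10

#: columns at either end of the paired region where designed terminal
#: mispairs are tolerated by validation
TERMINAL_MISPAIR_SLACK = 2

DIRECT = "direct"
MODEL2_PREFIX = "model2_copy_of_"

#: default junction window length (nt), centred on the ligation point
DEFAULT_WINDOW = 40

#: default single-strand insertion products for processed ends
DEFAULT_INSERTIONS = ("C", "TC", "CTC")


def ins_label(insertion: str) -> str:
    return f"ins:{insertion}"


def model2_label(source_label: str) -> str:
    return MODEL2_PREFIX + source_label


def model2_source(label: str) -> str | None:
    """Label of the opposite-strand product a model-2 label copies, or None."""
    if label.startswith(MODEL2_PREFIX):
        return label[len(MODEL2_PREFIX):]
    return None


def is_autonomous(label: str) -> bool:
    """True for products a strand can form on its own (direct or ins:*)."""
    return label == DIRECT or label.startswith("ins:")


@dataclass(frozen=True)
class EndStructure:
    """One end of the duplex: polarity plus the overhanging bases (5'->3')."""

    polarity: str
    overhang_seq: str = ""
    label: str = ""

    def __post_init__(self) -> None:
        if self.polarity not in _POLARITIES:
            raise ValueError(f"unknown end polarity {self.polarity!r}")

    @property
    def overhang_length(self) -> int:
        return len(self.overhang_seq)


@dataclass(frozen=True)
class StrandIdRegion:
    """Fully mismatched duplex region identifying the strand of origin.

    ``start``/``end`` are 0-based half-open coordinates on the top strand;
    ``bottom_variant`` is given as read on the bottom strand, 5'->3'.
    """

    start: int
    end: int
    top_variant: str
    bottom_variant: str

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.top_variant):
            raise ValueError("strand-ID interval length != variant length")
        if len(self.top_variant) != len(self.bottom_variant):
            raise ValueError("strand-ID variants differ in length")

    @property
    def length(self) -> int:
        return self.end - self.start

    def mismatch_positions(self) -> List[int]:
        """Variant offsets where the two strands are non-complementary."""
        paired = revcomp(self.bottom_variant)
        return [i for i, (a, b) in enumerate(zip(self.top_variant, paired)) if a != b]

    def fully_mismatched(self) -> bool:
        return len(self.mismatch_positions()) == self.length


@dataclass(frozen=True)
class SubstrateSpec:
    name: str
    top_seq: str
    bottom_seq: str
    head: EndStructure
    tail: EndStructure
    strand_id: StrandIdRegion

    def pairing_offset(self) -> int:
        """R such that top index t pairs with bottom index R - t."""
        n_tail = self.tail.overhang_length
        tail3 = n_tail if self.tail.polarity == THREE_PRIME else 0
        tail5 = n_tail if self.tail.polarity == FIVE_PRIME else 0
        return len(self.top_seq) - 1 - tail3 + tail5

    def strand_seq(self, strand: str) -> str:
        if strand == "top":
            return self.top_seq
        if strand == "bottom":
            return self.bottom_seq
        raise ValueError(f"unknown strand {strand!r}")

    def strand_id_interval(self, strand: str) -> Tuple[int, int]:
        """Strand-ID interval in the given strand's own 5'->3' coordinates."""
        if strand == "top":
            return self.strand_id.start, self.strand_id.end
        r = self.pairing_offset()
        return r - self.strand_id.end + 1, r - self.strand_id.start + 1

    def strand_id_variant(self, strand: str) -> str:
        return (
            self.strand_id.top_variant
            if strand == "top"
            else self.strand_id.bottom_variant
        )


class ValidationReport(list):
    """List of human-readable invariant violations; empty means valid."""

    @property
    def ok(self) -> bool:
        return not self


def _check_overhang(spec: SubstrateSpec, end: EndStructure, which: str,
                    report: ValidationReport) -> None:
    if end.polarity == BLUNT:
        if end.overhang_seq:
            report.append(f"{which}: overhang/polarity mismatch (blunt end with overhang)")
        return
    if not end.overhang_seq:
        report.append(f"{which}: overhang/polarity mismatch (overhang end with empty sequence)")
        return
    if end.overhang_length > MAX_OVERHANG:
        report.append(f"{which}: overhang longer than {MAX_OVERHANG} nt")
    n = end.overhang_length
    # which strand carries the overhang depends on end + polarity
    if which == "head":
        observed = spec.bottom_seq[-n:] if end.polarity == THREE_PRIME else spec.top_seq[:n]
    else:
        observed = spec.top_seq[-n:] if end.polarity == THREE_PRIME else spec.bottom_seq[:n]
    if observed != end.overhang_seq:
        report.append(
            f"{which}: overhang sequence {end.overhang_seq!r} inconsistent with "
            f"strand terminal bases {observed!r}"
        )


def validate_substrate(spec: SubstrateSpec, *, require_full_mismatch: bool = True,
                       ) -> ValidationReport:
    """Check every SubstrateSpec invariant; violations are data, not errors.

    ``require_full_mismatch=False`` relaxes the strand-ID constraint to at
    least one mismatched position (for user-supplied substrates whose
    designed variants are only partially mismatched).
    """
    report = ValidationReport()
    for strand, seq in (("top", spec.top_seq), ("bottom", spec.bottom_seq)):
        if not seq:
            report.append(f"{strand} strand sequence is empty")
        elif not is_dna(seq):
            report.append(f"{strand} strand contains non-ACGT characters")
    if report:
        return report

    _check_overhang(spec, spec.head, "head", report)
    _check_overhang(spec, spec.tail, "tail", report)

    sid = spec.strand_id
    top_len = len(spec.top_seq)
    if not (0 <= sid.start < sid.end <= top_len):
        report.append(
            f"strand-ID interval [{sid.start},{sid.end}) outside top strand [0,{top_len})"
        )
        return report
    if spec.top_seq[sid.start:sid.end] != sid.top_variant:
        report.append(
            f"top strand bases at [{sid.start},{sid.end}) != declared top variant"
        )
    b_lo, b_hi = spec.strand_id_interval("bottom")
    if not (0 <= b_lo < b_hi <= len(spec.bottom_seq)):
        report.append("strand-ID interval maps outside the bottom strand")
        return report
    if spec.bottom_seq[b_lo:b_hi] != sid.bottom_variant:
        report.append(
            f"bottom strand bases at [{b_lo},{b_hi}) != declared bottom variant"
        )

    n_mismatch = len(sid.mismatch_positions())
    if require_full_mismatch and n_mismatch < sid.length:
        report.append(
            f"strand-ID region not mismatched at every position "
            f"({n_mismatch}/{sid.length} mismatched)"
        )
    elif n_mismatch == 0:
        report.append("strand-ID region not mismatched")

    # complementarity outside the strand-ID region and terminal mispairs
    r = spec.pairing_offset()
    lb = len(spec.bottom_seq)
    t_lo = max(0, r - (lb - 1))
    t_hi = min(top_len - 1, r)
    paired_top = revcomp(spec.bottom_seq)
    for t in range(t_lo, t_hi + 1):
        if sid.start <= t < sid.end:
            continue
        if t - t_lo < TERMINAL_MISPAIR_SLACK or t_hi - t < TERMINAL_MISPAIR_SLACK:
            continue  # designed terminal mispairs live here
        b = r - t
        if spec.top_seq[t] != paired_top[len(paired_top) - 1 - b]:
            report.append(
                f"strands not complementary at top position {t} "
                f"(bottom position {b}) outside strand-ID region"
            )
    return report


@dataclass
class ExpectedProductSet:
    """Reference junction sequences for every enumerated repair product.

    ``windows[strand][label]`` is the J-nt junction window used for read
    classification; ``full_sequences`` holds the complete repaired-strand
    sequences (two substrate copies joined head-to-tail) the windows were
    cut from.  ``degenerate_pairs[strand]`` lists label pairs whose windows
    are string-identical and therefore indistinguishable on that strand.
    """

    substrate: str
    window: int
    windows: Dict[str, Dict[str, str]]
    full_sequences: Dict[str, Dict[str, str]]
    degenerate_pairs: Dict[str, List[Tuple[str, str]]] = field(default_factory=dict)

    def labels(self, strand: str) -> List[str]:
        return list(self.windows[strand])

    def degenerate_groups(self, strand: str) -> List[frozenset]:
        """Maximal groups of mutually degenerate labels."""
        groups: Dict[str, set] = {}
        for a, b in self.degenerate_pairs.get(strand, []):
            key = self.windows[strand][a]
            groups.setdefault(key, set()).update((a, b))
        return [frozenset(g) for g in groups.values()]


def _insertion_seq(label: str) -> str:
    if label == DIRECT:
        return ""
    if label.startswith("ins:"):
        return label[4:]
    raise ValueError(f"not an autonomous product label: {label!r}")


def _window_bounds(seq_len: int, ins_len: int, window: int) -> Tuple[int, int]:
    start = seq_len + (ins_len - window) // 2
    return start, start + window


def _own_junction(seq: str, insertion: str, window: int) -> Tuple[str, str]:
    """Full repaired strand (tail end + insertion + head end) and its window."""
    full = seq + insertion + seq
    start, stop = _window_bounds(len(seq), len(insertion), window)
    if start < 0 or stop > len(full):
        raise ValueError(
            f"window {window} exceeds available junction context "
            f"(strand length {len(seq)}, insertion {len(insertion)} nt)"
        )
    return full, full[start:stop]


def _model2_junction(spec: SubstrateSpec, strand: str, opposite_label: str,
                     window: int) -> Tuple[str, str]:
    """Junction copied from the opposite strand's repaired product.

    The copied strand is complementary to the opposite product everywhere
    except the strand-ID region, which retains this strand's own variant.
    """
    opposite = "bottom" if strand == "top" else "top"
    oseq = spec.strand_seq(opposite)
    insertion = _insertion_seq(opposite_label)
    full_opp = oseq + insertion + oseq
    copied = list(revcomp(full_opp))
    total = len(full_opp)
    o_lo, o_hi = spec.strand_id_interval(opposite)
    own_variant = spec.strand_id_variant(strand)
    copy_offsets = (0, len(oseq) + len(insertion))
    for off in copy_offsets:
        a, b = off + o_lo, off + o_hi
        # interval [a,b) of full_opp maps to [total-b, total-a) after revcomp
        copied[total - b:total - a] = own_variant
    full = "".join(copied)
    start, stop = _window_bounds(len(oseq), len(insertion), window)
    if start < 0 or stop > len(full):
        raise ValueError("window exceeds available junction context")
    return full, full[start:stop]


def enumerate_expected_products(
    spec: SubstrateSpec,
    insertion_labels: Sequence[str] = (),
    window: int = DEFAULT_WINDOW,
) -> ExpectedProductSet:
    """Enumerate reference junctions for every repair path on both strands.

    ``insertion_labels`` are the raw inserted sequences (e.g. ``["C", "TC",
    "CTC"]``); each yields one ``ins:<seq>`` product per strand.  Every
    opposite-strand product additionally yields a ``model2_copy_of_<label>``
    junction on this strand.
    """
    if spec.head.polarity != spec.tail.polarity and BLUNT not in (
        spec.head.polarity, spec.tail.polarity
    ):
        raise ValueError(
            "head and tail overhang polarities cannot be juxtaposed for ligation"
        )
    for insertion in insertion_labels:
        if not insertion or not is_dna(insertion):
            raise ValueError(f"invalid insertion sequence {insertion!r}")
    max_ins = max((len(i) for i in insertion_labels), default=0)
    max_over = max(spec.head.overhang_length, spec.tail.overhang_length)
    min_window = 2 * (max_over + max_ins + 2)
    if window < min_window:
        raise ValueError(
            f"window {window} shorter than the distinguishing context "
            f"({min_window} nt) for this substrate"
        )

    own_labels = [DIRECT] + [ins_label(i) for i in insertion_labels]
    windows: Dict[str, Dict[str, str]] = {"top": {}, "bottom": {}}
    fulls: Dict[str, Dict[str, str]] = {"top": {}, "bottom": {}}
    for strand in ("top", "bottom"):
        seq = spec.strand_seq(strand)
        for label in own_labels:
            full, win = _own_junction(seq, _insertion_seq(label), window)
            windows[strand][label] = win
            fulls[strand][label] = full
    for strand in ("top", "bottom"):
        for label in own_labels:
            full, win = _model2_junction(spec, strand, label, window)
            m2 = model2_label(label)
            windows[strand][m2] = win
            fulls[strand][m2] = full

    degenerate: Dict[str, List[Tuple[str, str]]] = {"top": [], "bottom": []}
    for strand in ("top", "bottom"):
        labels = list(windows[strand])
        for i, a in enumerate(labels):
            for b in labels[i + 1:]:
                if windows[strand][a] == windows[strand][b]:
                    degenerate[strand].append((a, b))

    return ExpectedProductSet(
        substrate=spec.name,
        window=window,
        windows=windows,
        full_sequences=fulls,
        degenerate_pairs=degenerate,
    )


# ---------------------------------------------------------------------------
# bundled demonstration substrates

# strand-ID variant sits mid-core, clear of the default 40-nt junction window
_DEMO_CORE = (
    "TCACGGATTGAACCTGGATCCTTAG"  # head-proximal context (25 nt)
    "ACGTC"                      # top strand-ID variant
    "CAGTGACCAGTTCGAATGCACTGGT"  # tail-proximal context (25 nt)
)
_SID_START = 25
_SID_TOP = "ACGTC"
_SID_BOTTOM = "TCATG"  # mismatched against the top variant at all 5 positions


def _core_bottom(core_top: str, start: int, top_var: str, bottom_var: str) -> str:
    out = list(revcomp(core_top))
    n = len(core_top)
    lo = n - start - len(top_var)
    out[lo:lo + len(bottom_var)] = bottom_var
    return "".join(out)


def _demo_gag3() -> SubstrateSpec:
    """Symmetric non-complementary 3' overhangs (GAG-3' at both ends)."""
    top = _DEMO_CORE + "GAG"
    bottom = _core_bottom(_DEMO_CORE, _SID_START, _SID_TOP, _SID_BOTTOM) + "GAG"
    return SubstrateSpec(
        name="gag3",
        top_seq=top,
        bottom_seq=bottom,
        head=EndStructure(THREE_PRIME, "GAG", "head"),
        tail=EndStructure(THREE_PRIME, "GAG", "tail"),
        strand_id=StrandIdRegion(_SID_START, _SID_START + 5, _SID_TOP, _SID_BOTTOM),
    )


def _demo_gt5() -> SubstrateSpec:
    """Symmetric 4-nt 5' overhangs whose ligation leaves terminal G:T mispairs."""
    top = "GCGT" + _DEMO_CORE
    bottom = "GCGT" + _core_bottom(_DEMO_CORE, _SID_START, _SID_TOP, _SID_BOTTOM)
    sid = StrandIdRegion(4 + _SID_START, 4 + _SID_START + 5, _SID_TOP, _SID_BOTTOM)
    return SubstrateSpec(
        name="gt5",
        top_seq=top,
        bottom_seq=bottom,
        head=EndStructure(FIVE_PRIME, "GCGT", "head"),
        tail=EndStructure(FIVE_PRIME, "GCGT", "tail"),
        strand_id=sid,
    )


def _demo_blunt() -> SubstrateSpec:
    """Blunt, fully complementary ends; model paths are indistinguishable."""
    top = _DEMO_CORE
    bottom = _core_bottom(_DEMO_CORE, _SID_START, _SID_TOP, _SID_BOTTOM)
    return SubstrateSpec(
        name="blunt",
        top_seq=top,
        bottom_seq=bottom,
        head=EndStructure(BLUNT, "", "head"),
        tail=EndStructure(BLUNT, "", "tail"),
        strand_id=StrandIdRegion(_SID_START, _SID_START + 5, _SID_TOP, _SID_BOTTOM),
    )


_DEMOS = {"gag3": _demo_gag3, "gt5": _demo_gt5, "blunt": _demo_blunt}


def demo_substrate(name: str) -> SubstrateSpec:
    """One of the bundled demonstration substrates: gag3, gt5 or blunt."""
    try:
        return _DEMOS[name]()
    except KeyError:
        raise ValueError(
            f"unknown demo substrate {name!r}; choose from {sorted(_DEMOS)}"
        ) from None


def demo_substrate_names() -> List[str]:
    return sorted(_DEMOS)


# ---------------------------------------------------------------------------
# config round-tripping

def substrate_to_mapping(spec: SubstrateSpec) -> Dict:
    return {
        "name": spec.name,
        "top_seq": spec.top_seq,
        "bottom_seq": spec.bottom_seq,
        "head": {
            "polarity": spec.head.polarity,
            "overhang_seq": spec.head.overhang_seq,
            "label": spec.head.label,
        },
        "tail": {
            "polarity": spec.tail.polarity,
            "overhang_seq": spec.tail.overhang_seq,
            "label": spec.tail.label,
        },
        "strand_id": {
            "start": spec.strand_id.start,
            "end": spec.strand_id.end,
            "top_variant": spec.strand_id.top_variant,
            "bottom_variant": spec.strand_id.bottom_variant,
        },
    }


def substrate_from_mapping(data: Mapping) -> SubstrateSpec:
    def end(d: Mapping) -> EndStructure:
        return EndStructure(
            polarity=d["polarity"],
            overhang_seq=d.get("overhang_seq", ""),
            label=d.get("label", ""),
        )

    sid = data["strand_id"]
    spec = SubstrateSpec(
        name=data["name"],
        top_seq=data["top_seq"].upper(),
        bottom_seq=data["bottom_seq"].upper(),
        head=end(data["head"]),
        tail=end(data["tail"]),
        strand_id=StrandIdRegion(
            start=int(sid["start"]),
            end=int(sid["end"]),
            top_variant=sid["top_variant"].upper(),
            bottom_variant=sid["bottom_variant"].upper(),
        ),
    )
    report = validate_substrate(spec, require_full_mismatch=False)
    if report:
        raise ValueError("invalid substrate config:\n  " + "\n  ".join(report))
    return spec


def substrate_fasta(spec: SubstrateSpec) -> str:
    """Two-record FASTA of the strand sequences."""
    return (
        f">{spec.name}_top\n{spec.top_seq}\n"
        f">{spec.name}_bottom\n{spec.bottom_seq}\n"
    )
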