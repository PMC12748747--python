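"""Single-molecule duplex reconstruction from UMI-sharing reads.

Reads that share a UMI came from the two strands of one adapter-ligated
duplex molecule.  After removing under-sampled UMI families (below 2% of
the mean oversampling ratio) and minor strands (below 20% of a family's
reads), each surviving family is called as one molecule: which strands are
joined, and — when both are — whether the pair of junction labels indicates
parallel/symmetric repair (model 1) or ordered templated copying of the
first strand's product (model 2).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .readproc import AnnotatedRead, UNCLASSIFIED, UNDETERMINED
from .substrate import ExpectedProductSet, is_autonomous, model2_source

AMBIGUOUS = "ambiguous"

MOLECULE_CLASSES = ("both_joined", "top_only", "bottom_only", "ambiguous")
PATHS = ("model1", "model2", "indeterminate", "not_applicable")


@dataclass(frozen=True)
class FilterParams:
    """Thresholds for family and strand retention.

    ``min_family_fraction`` is applied to the mean oversampling ratio
    (total reads / input template molecules); ``min_strand_fraction`` to a
    family's total read count.  Both cuts are strict "less than".
    """

    min_family_fraction: float = 0.02
    min_strand_fraction: float = 0.20
    n_input_templates: int = 1

    def __post_init__(self) -> None:
        for name in ("min_family_fraction", "min_strand_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if self.n_input_templates < 1:
            raise ValueError("n_input_templates must be >= 1")


def family_read_threshold(total_reads: int, params: FilterParams) -> float:
    """Minimum family size: min_family_fraction x mean oversampling ratio."""
    mean_oversampling = total_reads / params.n_input_templates
    return params.min_family_fraction * mean_oversampling


@dataclass
class UmiFamily:
    umi: str
    reads_top: List[AnnotatedRead] = field(default_factory=list)
    reads_bottom: List[AnnotatedRead] = field(default_factory=list)
    consensus_top: Optional[str] = None
    consensus_bottom: Optional[str] = None

    @property
    def n_top(self) -> int:
        return len(self.reads_top)

    @property
    def n_bottom(self) -> int:
        return len(self.reads_bottom)

    @property
    def n_reads(self) -> int:
        return self.n_top + self.n_bottom


@dataclass(frozen=True)
class DuplexCall:
    umi: str
    top_label: Optional[str]
    bottom_label: Optional[str]
    molecule_class: str
    path: str

    def __post_init__(self) -> None:
        if (self.path != "not_applicable") != (self.molecule_class == "both_joined"):
            raise ValueError(
                "path must be not_applicable exactly when molecule_class "
                "is not both_joined"
            )


def group_by_umi(reads: Iterable[AnnotatedRead]) -> List[UmiFamily]:
    """Exact-string UMI grouping; undetermined-strand reads are excluded."""
    families: Dict[str, UmiFamily] = {}
    for read in reads:
        if read.strand == UNDETERMINED:
            continue
        fam = families.get(read.umi)
        if fam is None:
            fam = families[read.umi] = UmiFamily(read.umi)
        if read.strand == "top":
            fam.reads_top.append(read)
        else:
            fam.reads_bottom.append(read)
    return list(families.values())


def cluster_umis(families: Sequence[UmiFamily], max_mismatch: int = 1,
                 ) -> List[UmiFamily]:
    """Optional directional clustering: merge small families into a larger
    family whose UMI is within ``max_mismatch`` substitutions (off by
    default in the pipeline; exact grouping is the reference behaviour)."""
    ordered = sorted(families, key=lambda f: -f.n_reads)
    merged: List[UmiFamily] = []
    for fam in ordered:
        target = None
        for big in merged:
            if big.n_reads >= 2 * fam.n_reads - 1 and len(big.umi) == len(fam.umi):
                mism = sum(a != b for a, b in zip(big.umi, fam.umi))
                if mism <= max_mismatch:
                    target = big
                    break
        if target is None:
            merged.append(UmiFamily(fam.umi, list(fam.reads_top),
                                    list(fam.reads_bottom)))
        else:
            target.reads_top.extend(fam.reads_top)
            target.reads_bottom.extend(fam.reads_bottom)
    return merged


def filter_families(families: Sequence[UmiFamily], total_reads: int,
                    params: FilterParams) -> List[UmiFamily]:
    """Drop families with fewer reads than 2% of the mean oversampling ratio.

    The exclusion is strict: a family is removed iff its read count is
    *less than* the threshold, so a family sitting exactly on it survives.
    """
    if total_reads < sum(f.n_reads for f in families):
        raise ValueError("total_reads smaller than the number of grouped reads")
    threshold = family_read_threshold(total_reads, params)
    return [f for f in families if not f.n_reads < threshold]


def filter_strands(family: UmiFamily, params: FilterParams) -> UmiFamily:
    """Remove a strand whose reads are <20% of the family's read sum.

    The majority strand always holds at least half the reads, so at most
    one strand can ever be removed.
    """
    total = family.n_reads
    if total == 0:
        return family
    cut = params.min_strand_fraction * total
    keep_top = not family.n_top < cut
    keep_bottom = not family.n_bottom < cut
    return UmiFamily(
        umi=family.umi,
        reads_top=list(family.reads_top) if keep_top else [],
        reads_bottom=list(family.reads_bottom) if keep_bottom else [],
    )


def call_consensus(family: UmiFamily) -> UmiFamily:
    """Per-strand plurality junction label; ties (or no classifiable reads)
    give an 'ambiguous' consensus."""

    def consensus(reads: List[AnnotatedRead]) -> Optional[str]:
        if not reads:
            return None
        counts = Counter(r.label for r in reads if r.label != UNCLASSIFIED)
        if not counts:
            return AMBIGUOUS
        ranked = counts.most_common()
        if len(ranked) > 1 and ranked[0][1] == ranked[1][1]:
            return AMBIGUOUS
        return ranked[0][0]

    return UmiFamily(
        umi=family.umi,
        reads_top=family.reads_top,
        reads_bottom=family.reads_bottom,
        consensus_top=consensus(family.reads_top),
        consensus_bottom=consensus(family.reads_bottom),
    )


def _joint_label(label: str) -> bool:
    return "|" in label


def _path_for(top_label: str, bottom_label: str) -> str:
    if _joint_label(top_label) or _joint_label(bottom_label):
        return "indeterminate"  # degenerate windows cannot separate the paths
    top_copies = model2_source(top_label) == bottom_label
    bottom_copies = model2_source(bottom_label) == top_label
    if is_autonomous(top_label) and is_autonomous(bottom_label):
        return "model1"
    if top_copies != bottom_copies:
        return "model2"
    return "indeterminate"


def classify_molecule(family: UmiFamily,
                      products: ExpectedProductSet) -> DuplexCall:
    """One DuplexCall per surviving family (consensus must be called)."""
    top = family.consensus_top
    bottom = family.consensus_bottom
    top_ok = top is not None and top != AMBIGUOUS
    bottom_ok = bottom is not None and bottom != AMBIGUOUS
    if top_ok and bottom_ok:
        molecule_class = "both_joined"
        path = _path_for(top, bottom)
    elif top_ok:
        molecule_class, path = "top_only", "not_applicable"
    elif bottom_ok:
        molecule_class, path = "bottom_only", "not_applicable"
    else:
        molecule_class, path = "ambiguous", "not_applicable"
    return DuplexCall(
        umi=family.umi,
        top_label=top if top_ok else None,
        bottom_label=bottom if bottom_ok else None,
        molecule_class=molecule_class,
        path=path,
    )


@dataclass
class RepairSummary:
    sample: str
    timepoint: Optional[float]
    n_molecules: int
    class_counts: Dict[str, int]
    path_counts: Dict[str, int]
    label_counts: Dict[str, Dict[str, int]]

    @property
    def class_frequencies(self) -> Dict[str, float]:
        return {k: v / self.n_molecules for k, v in self.class_counts.items()}

    @property
    def path_frequencies(self) -> Dict[str, float]:
        """Path frequencies among both-joined molecules."""
        n_both = self.class_counts.get("both_joined", 0)
        if n_both == 0:
            return {}
        return {k: v / n_both for k, v in self.path_counts.items()}

    def exact_class_frequencies(self) -> Dict[str, Fraction]:
        return {k: Fraction(v, self.n_molecules) for k, v in self.class_counts.items()}

    def as_dict(self) -> Dict:
        return {
            "sample": self.sample,
            "timepoint": self.timepoint,
            "n_molecules": self.n_molecules,
            "class_counts": dict(self.class_counts),
            "class_frequencies": self.class_frequencies,
            "path_counts": dict(self.path_counts),
            "path_frequencies": self.path_frequencies,
            "label_counts": {k: dict(v) for k, v in self.label_counts.items()},
        }


def summarize(calls: Sequence[DuplexCall], sample: str = "sample",
              timepoint: Optional[float] = None) -> RepairSummary:
    if not calls:
        raise ValueError("cannot summarize an empty set of duplex calls")
    class_counts = Counter(c.molecule_class for c in calls)
    path_counts = Counter(
        c.path for c in calls if c.molecule_class == "both_joined"
    )
    label_counts = {"top": Counter(), "bottom": Counter()}
    for c in calls:
        if c.top_label is not None:
            label_counts["top"][c.top_label] += 1
        if c.bottom_label is not None:
            label_counts["bottom"][c.bottom_label] += 1
    return RepairSummary(
        sample=sample,
        timepoint=timepoint,
        n_molecules=len(calls),
        class_counts={k: class_counts.get(k, 0) for k in MOLECULE_CLASSES},
        path_counts=dict(path_counts),
        label_counts={k: dict(v) for k, v in label_counts.items()},
    )


@dataclass(frozen=True)
class PreferenceRatio:
    """Ratio of model-1 to model-2 frequency among both-joined molecules.

    Indeterminate-path molecules are excluded from both numerator and
    denominator and reported separately.  A zero denominator is flagged
    rather than raised; the ratio is then infinite.
    """

    model1_to_model2: float
    model2_to_model1: float
    n_model1: int
    n_model2: int
    n_indeterminate: int
    zero_denominator: bool


def preference_ratio(summary: RepairSummary) -> PreferenceRatio:
    n1 = summary.path_counts.get("model1", 0)
    n2 = summary.path_counts.get("model2", 0)
    n_ind = summary.path_counts.get("indeterminate", 0)
    if summary.class_counts.get("both_joined", 0) == 0:
        raise ValueError("preference ratio requires both-joined molecules")
    return PreferenceRatio(
        model1_to_model2=n1 / n2 if n2 else float("inf"),
        model2_to_model1=n2 / n1 if n1 else float("inf"),
        n_model1=n1,
        n_model2=n2,
        n_indeterminate=n_ind,
        zero_denominator=(n1 == 0 or n2 == 0),
    )


def reconstruct_molecules(
    annotated: Iterable[AnnotatedRead],
    products: ExpectedProductSet,
    params: FilterParams,
    total_reads: Optional[int] = None,
    *,
    umi_clustering: bool = False,
) -> Tuple[List[DuplexCall], Dict]:
    """Full grouping -> filtering -> consensus -> classification chain.

    ``total_reads`` defaults to the number of annotated reads supplied;
    pass the raw library read count when annotation dropped reads, as the
    oversampling ratio is defined over total sequenced reads.  Returns the
    calls plus a log dictionary of thresholds and per-stage counts.
    """
    annotated = list(annotated)
    families = group_by_umi(annotated)
    if umi_clustering:
        families = cluster_umis(families)
    n_grouped = sum(f.n_reads for f in families)
    if total_reads is None:
        total_reads = len(annotated)
    threshold = family_read_threshold(total_reads, params)
    retained = filter_families(families, total_reads, params)
    calls = []
    for family in retained:
        family = filter_strands(family, params)
        family = call_consensus(family)
        calls.append(classify_molecule(family, products))
    log = {
        "n_annotated_reads": len(annotated),
        "n_grouped_reads": n_grouped,
        "n_strand_undetermined_excluded": len(annotated) - n_grouped,
        "total_reads": total_reads,
        "n_input_templates": params.n_input_templates,
        "mean_oversampling": total_reads / params.n_input_templates,
        "family_read_threshold": threshold,
        "min_family_fraction": params.min_family_fraction,
        "min_strand_fraction": params.min_strand_fraction,
        "n_families": len(families),
        "n_families_retained": len(retained),
    }
    return calls, log
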