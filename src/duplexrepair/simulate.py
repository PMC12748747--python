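"""Ground-truth simulation of two-strand repair and UMI-tagged libraries.

Two kinetic regimes are modelled with continuous-time exponential hazards:

* ``parallel_independent`` — each strand break is ligated on its own clock,
  independent of the other strand.
* ``ordered`` — the second strand's clock only starts once the first strand
  has joined, and its product is the templated copy of the first strand's
  product.

Joined strands are rendered to full repaired sequences, tagged with one
10-nt UMI per duplex molecule (shared by both strands, as for a
double-stranded adapter), oversampled into error-bearing reads and emitted
as FASTQ together with a per-read ground-truth table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, TextIO, Tuple

import numpy as np
import pandas as pd

from .dna import DNA_BASES, _BASE_ARRAY, is_dna, random_dna
from .substrate import (
    ExpectedProductSet,
    SubstrateSpec,
    model2_label,
)

PARALLEL = "parallel_independent"
ORDERED = "ordered"

#: number of distinct UMI sequences for a given adapter length
def umi_space_size(umi_length: int = 10) -> int:
    """Size of the random-UMI sequence space (4 ** length)."""
    if umi_length < 1:
        raise ValueError("umi_length must be >= 1")
    return 4 ** umi_length


@dataclass(frozen=True)
class KineticsModel:
    """Hazard-rate description of how the two strand breaks are repaired."""

    mode: str = PARALLEL
    k_top: float = 0.2
    k_bottom: float = 0.2
    k_second: float = 0.1
    first_strand: str = "top"  # "top", "bottom" or "either" (ordered mode)
    insertion_probs: Dict[str, float] = field(
        default_factory=lambda: {"direct": 1.0}
    )
    p_ribo: float = 0.0
    k_rer: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in (PARALLEL, ORDERED):
            raise ValueError(f"unknown kinetics mode {self.mode!r}")
        for name in ("k_top", "k_bottom", "k_second", "k_rer"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.first_strand not in ("top", "bottom", "either"):
            raise ValueError("first_strand must be top, bottom or either")
        total = sum(self.insertion_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"insertion_probs sum to {total}, expected 1")
        if any(p < 0 for p in self.insertion_probs.values()):
            raise ValueError("insertion_probs must be non-negative")
        if not 0.0 <= self.p_ribo <= 1.0:
            raise ValueError("p_ribo must lie in [0, 1]")


@dataclass(frozen=True)
class RepairOutcome:
    joined: bool
    product_label: Optional[str] = None
    contains_ribo: bool = False
    join_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.joined and (self.product_label is None or self.join_time is None):
            raise ValueError("joined outcome requires product_label and join_time")
        if not self.joined and (self.product_label is not None
                                or self.join_time is not None):
            raise ValueError("unjoined outcome cannot carry product or time")


UNJOINED = RepairOutcome(joined=False)


@dataclass(frozen=True)
class MoleculeState:
    molecule_id: int
    top: RepairOutcome
    bottom: RepairOutcome
    harvest_time: float


def _exponential_times(rng: np.random.Generator, hazard: float, n: int) -> np.ndarray:
    if hazard == 0:
        return np.full(n, np.inf)
    return rng.exponential(scale=1.0 / hazard, size=n)


def _draw_labels(rng: np.random.Generator, probs: Dict[str, float], n: int,
                 ) -> np.ndarray:
    labels = np.array(list(probs), dtype=object)
    p = np.array([probs[l] for l in labels], dtype=float)
    p = p / p.sum()
    return rng.choice(labels, size=n, p=p)


def _ribo_flags(rng: np.random.Generator, labels: np.ndarray, joined: np.ndarray,
                times: np.ndarray, harvest: float, p_ribo: float, k_rer: float,
                ) -> np.ndarray:
    """Ribonucleotide marking with RER decay after joining.

    Only insertion products can carry a ribonucleotide; the mark survives to
    harvest with probability exp(-k_rer * (harvest - join_time)).
    """
    insertion = np.array([str(l).startswith("ins:") for l in labels])
    marked = insertion & joined & (rng.random(len(labels)) < p_ribo)
    if k_rer > 0:
        dt = np.where(joined, harvest - times, 0.0)
        survives = rng.random(len(labels)) < np.exp(-k_rer * dt)
        marked &= survives
    else:
        rng.random(len(labels))  # keep draw count stable across k_rer values
    return marked


def simulate_repair(
    spec: SubstrateSpec,
    kinetics: KineticsModel,
    n_molecules: int,
    harvest_time: float,
    seed: int,
) -> List[MoleculeState]:
    """Simulate per-molecule, per-strand repair up to ``harvest_time`` minutes."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    if harvest_time < 0:
        raise ValueError("harvest_time must be >= 0")
    rng = np.random.default_rng(seed)
    n = n_molecules

    if kinetics.mode == PARALLEL:
        t_top = _exponential_times(rng, kinetics.k_top, n)
        t_bottom = _exponential_times(rng, kinetics.k_bottom, n)
        j_top = t_top <= harvest_time
        j_bottom = t_bottom <= harvest_time
        lab_top = _draw_labels(rng, kinetics.insertion_probs, n)
        lab_bottom = _draw_labels(rng, kinetics.insertion_probs, n)
        ribo_top = _ribo_flags(rng, lab_top, j_top, t_top, harvest_time,
                               kinetics.p_ribo, kinetics.k_rer)
        ribo_bottom = _ribo_flags(rng, lab_bottom, j_bottom, t_bottom,
                                  harvest_time, kinetics.p_ribo, kinetics.k_rer)
        first_is_top = np.ones(n, dtype=bool)  # unused in parallel mode
    else:
        if kinetics.first_strand == "either":
            t_a = _exponential_times(rng, kinetics.k_top, n)
            t_b = _exponential_times(rng, kinetics.k_bottom, n)
            first_is_top = t_a <= t_b
            t_first = np.minimum(t_a, t_b)
        else:
            first_is_top = np.full(n, kinetics.first_strand == "top")
            hazard = kinetics.k_top if kinetics.first_strand == "top" else kinetics.k_bottom
            t_first = _exponential_times(rng, hazard, n)
        t_second = t_first + _exponential_times(rng, kinetics.k_second, n)
        j_first = t_first <= harvest_time
        j_second = j_first & (t_second <= harvest_time)
        lab_first = _draw_labels(rng, kinetics.insertion_probs, n)
        ribo_first = _ribo_flags(rng, lab_first, j_first, t_first, harvest_time,
                                 kinetics.p_ribo, kinetics.k_rer)
        lab_second = np.array([model2_label(str(l)) for l in lab_first], dtype=object)
        j_top = np.where(first_is_top, j_first, j_second)
        j_bottom = np.where(first_is_top, j_second, j_first)
        t_top = np.where(first_is_top, t_first, t_second)
        t_bottom = np.where(first_is_top, t_second, t_first)
        lab_top = np.where(first_is_top, lab_first, lab_second)
        lab_bottom = np.where(first_is_top, lab_second, lab_first)
        # templated second-strand synthesis is purely DNA
        ribo_top = np.where(first_is_top, ribo_first, False)
        ribo_bottom = np.where(first_is_top, False, ribo_first)

    states = []
    for i in range(n):
        top = (
            RepairOutcome(True, str(lab_top[i]), bool(ribo_top[i]), float(t_top[i]))
            if j_top[i]
            else UNJOINED
        )
        bottom = (
            RepairOutcome(True, str(lab_bottom[i]), bool(ribo_bottom[i]),
                          float(t_bottom[i]))
            if j_bottom[i]
            else UNJOINED
        )
        states.append(MoleculeState(i, top, bottom, harvest_time))
    return states


def render_strand_sequences(
    state: MoleculeState,
    spec: SubstrateSpec,
    products: ExpectedProductSet,
) -> Dict[str, str]:
    """Full repaired-strand sequence per joined strand; unjoined strands absent."""
    out: Dict[str, str] = {}
    for strand in ("top", "bottom"):
        outcome: RepairOutcome = getattr(state, strand)
        if not outcome.joined:
            continue
        label = outcome.product_label
        try:
            out[strand] = products.full_sequences[strand][label]
        except KeyError:
            raise ValueError(
                f"product label {label!r} not enumerated for {strand} strand "
                f"of substrate {spec.name!r}"
            ) from None
    return out


def draw_umis(n: int, umi_length: int, rng: np.random.Generator) -> List[str]:
    """One uniform random UMI per molecule (double-stranded adapter model)."""
    idx = rng.integers(0, 4, size=(n, umi_length))
    flat = _BASE_ARRAY[idx]
    return [row.tobytes().decode() for row in flat]


#: default constant sequence between the UMI and the insert (mosaic-end like)
DEFAULT_ADAPTER_FLANK = "AGATGTGTATAAGAGACAG"

_SUBSTITUTE = {
    base: np.frombuffer("".join(b for b in DNA_BASES if b != base).encode(),
                        dtype=np.uint8)
    for base in DNA_BASES
}


@dataclass
class LibraryTruth:
    """Per-read ground truth emitted alongside a synthetic library."""

    frame: pd.DataFrame  # read_id, molecule_id, strand, product_label, ribo_flag

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def synthesize_reads(
    states: Sequence[MoleculeState],
    spec: SubstrateSpec,
    products: ExpectedProductSet,
    *,
    umi_length: int = 10,
    oversampling_mean: float = 30.0,
    error_rate: float = 0.0,
    barcode: str = "ACGTAC",
    sample: str = "s1",
    max_phasing: int = 5,
    adapter_flank: str = DEFAULT_ADAPTER_FLANK,
    overdispersion: Optional[float] = None,
    exact_oversampling: bool = False,
    quality_char: str = "?",  # Phred+33 Q30
    seed: int = 0,
    fastq_out: Optional[TextIO] = None,
    keep_records: Optional[bool] = None,
) -> Tuple[Optional[List[Tuple[str, str, str]]], LibraryTruth]:
    """Synthesise an oversampled, barcoded, UMI-tagged amplicon library.

    Each read is ``phasing + barcode + UMI + adapter_flank + insert`` where
    the insert is the joined strand's full repaired sequence.  Per joined
    strand, the read count is Poisson(``oversampling_mean``) (or negative
    binomial when ``overdispersion`` is set); substitution errors are
    applied i.i.d. at ``error_rate`` across the entire read.  Reads are
    returned in memory and/or streamed to ``fastq_out``.

    Returns ``(records, truth)``; ``records`` is None when ``keep_records``
    is disabled (default when streaming to a file).
    """
    if oversampling_mean <= 0:
        raise ValueError("oversampling_mean must be > 0")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must lie in [0, 0.5)")
    if not is_dna(barcode):
        raise ValueError(f"barcode {barcode!r} contains non-ACGT characters")
    if keep_records is None:
        keep_records = fastq_out is None

    rng = np.random.default_rng(seed)
    umis = draw_umis(len(states), umi_length, rng)

    entries = []  # (molecule_idx, strand, label, ribo, insert)
    for idx, state in enumerate(states):
        rendered = render_strand_sequences(state, spec, products)
        for strand, insert in rendered.items():
            outcome: RepairOutcome = getattr(state, strand)
            entries.append((idx, strand, outcome.product_label,
                            outcome.contains_ribo, insert))

    if exact_oversampling:
        counts = np.full(len(entries), int(round(oversampling_mean)))
    elif overdispersion is None:
        counts = rng.poisson(oversampling_mean, size=len(entries))
    else:
        # negative binomial with mean oversampling_mean, shape overdispersion
        r = float(overdispersion)
        p = r / (r + oversampling_mean)
        counts = rng.negative_binomial(r, p, size=len(entries))

    total_reads = int(counts.sum())
    phasing_lengths = rng.integers(0, max_phasing + 1, size=total_reads)
    phasing_pool = random_dna(rng, int(phasing_lengths.sum()))

    fixed_len = len(barcode) + umi_length + len(adapter_flank)
    insert_lens = np.array([len(e[4]) for e in entries])
    read_lens = np.repeat(insert_lens + fixed_len, counts) + phasing_lengths
    n_errors = (
        rng.binomial(read_lens, error_rate)
        if error_rate > 0
        else np.zeros(total_reads, dtype=int)
    )

    records: Optional[List[Tuple[str, str, str]]] = [] if keep_records else None
    truth_rows = {
        "read_id": [],
        "molecule_id": [],
        "strand": [],
        "product_label": [],
        "ribo_flag": [],
    }
    read_idx = 0
    pool_pos = 0
    for (mol_idx, strand, label, ribo, insert), n_reads in zip(entries, counts):
        umi = umis[mol_idx]
        molecule_id = states[mol_idx].molecule_id
        for _ in range(int(n_reads)):
            plen = int(phasing_lengths[read_idx])
            phasing = phasing_pool[pool_pos:pool_pos + plen]
            pool_pos += plen
            seq = f"{phasing}{barcode}{umi}{adapter_flank}{insert}"
            n_err = int(n_errors[read_idx])
            if n_err:
                seq_arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
                positions = rng.choice(len(seq), size=min(n_err, len(seq)),
                                       replace=False)
                for pos in positions:
                    base = chr(seq_arr[pos])
                    seq_arr[pos] = rng.choice(_SUBSTITUTE.get(base, _SUBSTITUTE["A"]))
                seq = seq_arr.tobytes().decode()
            read_id = f"{sample}.{read_idx}"
            qual = quality_char * len(seq)
            if fastq_out is not None:
                fastq_out.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            if records is not None:
                records.append((read_id, seq, qual))
            truth_rows["read_id"].append(read_id)
            truth_rows["molecule_id"].append(molecule_id)
            truth_rows["strand"].append(strand)
            truth_rows["product_label"].append(label)
            truth_rows["ribo_flag"].append(bool(ribo))
            read_idx += 1

    truth = LibraryTruth(pd.DataFrame(truth_rows))
    return records, truth


def molecule_truth_table(states: Sequence[MoleculeState]) -> pd.DataFrame:
    """Molecule-level ground truth: join status, labels, times, ribo flags."""
    rows = []
    for s in states:
        rows.append({
            "molecule_id": s.molecule_id,
            "top_joined": s.top.joined,
            "bottom_joined": s.bottom.joined,
            "top_label": s.top.product_label,
            "bottom_label": s.bottom.product_label,
            "top_join_time": s.top.join_time,
            "bottom_join_time": s.bottom.join_time,
            "top_ribo": s.top.contains_ribo,
            "bottom_ribo": s.bottom.contains_ribo,
            "harvest_time": s.harvest_time,
        })
    return pd.DataFrame(rows)


def split_into_pairs(
    record: Tuple[str, str, str],
    read_length: int,
) -> Tuple[Tuple[str, str, str], Tuple[str, str, str]]:
    """Split a merged record into inward-facing mates for merger testing."""
    from .dna import revcomp

    read_id, seq, qual = record
    r1 = (read_id + "/1", seq[:read_length], qual[:read_length])
    r2 = (read_id + "/2", revcomp(seq[-read_length:]), qual[-read_length:][::-1])
    return r1, r2


def emulate_alkali_qpcr(
    n_templates: int,
    frac_ribo: float,
    seed: int = 0,
    *,
    noise_sd: float = 0.0,
    reference_ct: float = 30.0,
) -> Tuple[float, float]:
    """(ct_mock, ct_alkali) for a template pool with the given RNA fraction.

    Alkali cleaves ribonucleotide-containing templates, so the alkali Ct
    rises by -log2(1 - frac_ribo) relative to mock.  With ``noise_sd`` of 0
    this is the exact inverse of :func:`duplexrepair.quant.fraction_rna`.
    """
    if n_templates < 1:
        raise ValueError("n_templates must be >= 1")
    if not 0.0 <= frac_ribo < 1.0:
        if frac_ribo == 1.0:
            raise ValueError(
                "frac_ribo = 1 leaves no alkali-resistant template (censored)"
            )
        raise ValueError("frac_ribo must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    ct_mock = reference_ct - math.log2(n_templates)
    ct_alkali = ct_mock - math.log2(1.0 - frac_ribo)
    if noise_sd > 0:
        ct_mock += rng.normal(0.0, noise_sd)
        ct_alkali += rng.normal(0.0, noise_sd)
    return ct_mock, ct_alkali
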