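"""File round-tripping for every table and sequence format the pipeline emits.

Tables are TSV read/written through pandas (unknown columns are preserved),
run metadata is JSON, substrates load from YAML or JSON, and FASTQ goes
through Biopython's fast tuple iterator with transparent gzip handling.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Dict, Iterable, Iterator, Tuple, Union

import pandas as pd
import yaml
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .substrate import SubstrateSpec, substrate_from_mapping, substrate_to_mapping

PathLike = Union[str, Path]


class ParseError(ValueError):
    """Malformed input file; message names the offending location."""


def _opener(path: PathLike, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fastq(path: PathLike) -> Iterator[Tuple[str, str, str]]:
    """Yield (read_id, sequence, quality) tuples; gz-transparent."""
    with _opener(path) as handle:
        for title, seq, qual in FastqGeneralIterator(handle):
            yield title.split()[0], seq, qual


def write_fastq(path: PathLike, records: Iterable[Tuple[str, str, str]]) -> int:
    n = 0
    with _opener(path, "wt") as handle:
        for read_id, seq, qual in records:
            handle.write(f"@{read_id}\n{seq}\n+\n{qual}\n")
            n += 1
    return n


def write_table(frame: pd.DataFrame, path: PathLike) -> None:
    frame.to_csv(path, sep="\t", index=False)


def read_table(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t")
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_json(data: Dict, path: PathLike) -> None:
    with open(path, "w") as handle:
        json.dump(data, handle, indent=2, sort_keys=True)
        handle.write("\n")


def read_json(path: PathLike) -> Dict:
    with open(path) as handle:
        try:
            return json.load(handle)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: line {exc.lineno}: {exc.msg}") from exc


def load_substrate(path: PathLike) -> SubstrateSpec:
    """Substrate config from YAML or JSON (chosen by extension)."""
    path = Path(path)
    with open(path) as handle:
        if path.suffix in (".yaml", ".yml"):
            data = yaml.safe_load(handle)
        else:
            data = json.load(handle)
    if not isinstance(data, dict):
        raise ParseError(f"{path}: expected a mapping at top level")
    return substrate_from_mapping(data)


def save_substrate(spec: SubstrateSpec, path: PathLike) -> None:
    path = Path(path)
    data = substrate_to_mapping(spec)
    with open(path, "w") as handle:
        if path.suffix in (".yaml", ".yml"):
            yaml.safe_dump(data, handle, sort_keys=False)
        else:
            json.dump(data, handle, indent=2)
            handle.write("\n")
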