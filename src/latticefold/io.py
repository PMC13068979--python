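"""File I/O: FASTA sequences, CSV interaction matrices, JSON models/results."""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Union

from Bio import SeqIO

from .encoders.base import EncodedModel
from .fold import InteractionMatrix, Sequence
from .solvers.sampleset import SampleSet

PathLike = Union[str, Path]


def read_sequence(path: PathLike) -> Sequence:
    """Read a sequence from FASTA (first record) or a plain one-line file.

    Lowercase residues are normalized to uppercase with a warning.
    """
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith(">"):
        record = next(SeqIO.parse(str(path), "fasta"), None)
        if record is None:
            raise ValueError(f"{path}: no FASTA records found")
        raw = str(record.seq)
    else:
        raw = text.strip()
    if raw != raw.upper():
        warnings.warn(f"{path}: lowercase residues normalized to uppercase")
        raw = raw.upper()
    return Sequence(raw)


def parse_sequence(text: str) -> Sequence:
    if text != text.upper():
        warnings.warn("lowercase residues normalized to uppercase")
        text = text.upper()
    return Sequence(text)


def read_interaction_matrix(path: PathLike) -> InteractionMatrix:
    return InteractionMatrix.from_csv(Path(path).read_text())


def write_model(model: EncodedModel, path: PathLike) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def read_model(path: PathLike) -> EncodedModel:
    return EncodedModel.from_dict(json.loads(Path(path).read_text()))


def write_sampleset(samples: SampleSet, path: PathLike) -> None:
    Path(path).write_text(json.dumps(samples.to_dict(), indent=1))


def read_sampleset(path: PathLike) -> SampleSet:
    return SampleSet.from_dict(json.loads(Path(path).read_text()))


def file_sha256(path: PathLike) -> str:
    """Content hash recorded in run logs for reproducibility."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
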