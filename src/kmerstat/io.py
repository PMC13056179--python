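"""Sequence and model document I/O: FASTA/FASTQ (plain or gzip), model JSON.

Sequence parsing is delegated to Biopython's SeqIO with format and gzip
auto-detection layered on top; records stream without loading whole files.
Fitted models round-trip through a small versioned JSON document so a fit
can be reused by the characterization tools without refitting.
"""

from __future__ import annotations

import gzip
import io as _io
import json
import logging
import platform
from dataclasses import dataclass
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterator

import numpy as np

from .mixture import ComponentSpec, FitResult, MixtureModel

__all__ = [
    "ReadRecord",
    "read_sequences",
    "write_fasta",
    "write_fastq",
    "write_model",
    "read_model",
    "write_manifest",
    "SequenceFormatError",
    "ModelSchemaError",
]

logger = logging.getLogger(__name__)

MODEL_SCHEMA_VERSION = 1


class SequenceFormatError(ValueError):
    """Malformed or mixed-format sequence input."""


class ModelSchemaError(ValueError):
    """Model JSON does not match the expected schema."""


@dataclass
class ReadRecord:
    """One sequencing read: identifier, sequence, optional Phred qualities."""

    identifier: str
    sequence: str
    qualities: np.ndarray | None = None  # per-base Phred scores

    def __post_init__(self) -> None:
        if self.qualities is not None:
            self.qualities = np.asarray(self.qualities)
            if len(self.qualities) != len(self.sequence):
                raise SequenceFormatError(
                    f"record {self.identifier!r}: quality length {len(self.qualities)} "
                    f"!= sequence length {len(self.sequence)}"
                )

    @property
    def quality_string(self) -> str | None:
        if self.qualities is None:
            return None
        return "".join(chr(int(q) + 33) for q in self.qualities)


def _open_maybe_gzip(path: Path):
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return _io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_sequences(path) -> Iterator[ReadRecord]:
    """Stream records from a FASTA or FASTQ file, plain or gzip-compressed.

    The format is auto-detected from the first record character ('>' FASTA,
    '@' FASTQ).  Malformed records and truncated gzip streams raise
    :class:`SequenceFormatError` with the failing record's position.
    """
    from Bio import SeqIO

    path = Path(path)
    with _open_maybe_gzip(path) as probe:
        try:
            first = probe.read(1)
        except (EOFError, OSError) as exc:
            raise SequenceFormatError(f"{path}: unreadable input: {exc}") from exc
    if not first:
        return
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise SequenceFormatError(f"{path}: not FASTA/FASTQ (starts with {first!r})")
    handle = _open_maybe_gzip(path)
    try:
        record_no = 0
        try:
            for rec in SeqIO.parse(handle, fmt):
                record_no += 1
                quals = None
                if fmt == "fastq":
                    quals = np.asarray(rec.letter_annotations["phred_quality"], dtype=np.int16)
                yield ReadRecord(rec.id, str(rec.seq).upper(), quals)
        except (ValueError, EOFError, OSError) as exc:
            raise SequenceFormatError(f"{path}: record {record_no + 1}: {exc}") from exc
    finally:
        handle.close()


def write_fasta(records, path) -> int:
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            fh.write(f">{rec.identifier}\n{rec.sequence}\n")
            n += 1
    return n


def write_fastq(records, path) -> int:
    n = 0
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for rec in records:
            q = rec.quality_string
            if q is None:
                q = "I" * len(rec.sequence)
            fh.write(f"@{rec.identifier}\n{rec.sequence}\n+\n{q}\n")
            n += 1
    return n


# -- model documents ------------------------------------------------------


def _model_to_doc(model: MixtureModel, meta: dict | None = None) -> dict:
    return {
        "schema_version": MODEL_SCHEMA_VERSION,
        "c": model.c,
        "components": [
            {"family": s.family, "params": dict(s.params), "weight": float(s.weight)}
            for s in model.components
        ],
        "fit": meta or {},
    }


def write_model(fit_or_model: FitResult | MixtureModel, path) -> None:
    """Serialize a fitted model (and fit metadata) to JSON."""
    if isinstance(fit_or_model, FitResult):
        meta = {
            "err": float(fit_or_model.err),
            "generations": int(fit_or_model.n_generations),
            "seed": int(fit_or_model.seed),
            "converged": bool(fit_or_model.converged),
        }
        model = fit_or_model.model
    else:
        meta, model = {}, fit_or_model
    with open(path, "w") as fh:
        json.dump(_model_to_doc(model, meta), fh, indent=2)


def read_model(path) -> tuple[MixtureModel, dict]:
    """Load a model JSON document; returns (model, fit metadata)."""
    try:
        doc = json.loads(Path(path).read_text())
    except ValueError as exc:
        raise ModelSchemaError(f"{path}: not valid JSON: {exc}") from None
    for fld in ("schema_version", "c", "components"):
        if fld not in doc:
            raise ModelSchemaError(f"{path}: missing required field {fld!r}")
    if doc["schema_version"] != MODEL_SCHEMA_VERSION:
        raise ModelSchemaError(
            f"{path}: schema version {doc['schema_version']} unsupported "
            f"(expected {MODEL_SCHEMA_VERSION})"
        )
    comps = []
    for i, cd in enumerate(doc["components"]):
        for fld in ("family", "params", "weight"):
            if fld not in cd:
                raise ModelSchemaError(f"{path}: component {i}: missing field {fld!r}")
        comps.append(ComponentSpec(cd["family"], dict(cd["params"]), float(cd["weight"])))
    total = sum(s.weight for s in comps)
    if abs(total - 1.0) > 1e-6:
        raise ModelSchemaError(f"{path}: component weights sum to {total}, expected 1")
    return MixtureModel(comps, int(doc["c"])), dict(doc.get("fit", {}))


def write_manifest(path, **params) -> None:
    """Machine-readable run manifest: parameters, seeds, versions, time."""
    import kmerstat

    doc = {
        "tool": "kmerstat",
        "version": kmerstat.__version__,
        "python": platform.python_version(),
        "numpy": np.__version__,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": {k: (str(v) if isinstance(v, Path) else v) for k, v in params.items()},
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=str)
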